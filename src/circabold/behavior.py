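"""Session-level behavioural measures.

Covers the sleepiness side (per-session KSS as the mean of the pre- and
post-scan ratings, group-mean profiles and their z-scored weights) and the
reaction-time side (the fast / intermediate / slow / lapse partition that
defines the event types of the first-level fMRI model).

Conventions fixed here because results depend on them:

* percentiles use linear interpolation between order statistics
  (``numpy.percentile`` default);
* lapses (RT > 500 ms) are excluded before computing the 25th/75th
  percentiles and the lapse label takes precedence over the speed labels;
* z-scoring uses the population standard deviation (ddof=0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pvt import LAPSE_MS

log = logging.getLogger(__name__)

SPEED_LABELS = ("fast", "intermediate", "slow", "lapse")
MIN_RTS_FOR_PARTITION = 8


@dataclass
class SleepinessProfile:
    """Group-mean KSS time course for one arm and its z-scored weights."""

    condition: str
    mean_kss: np.ndarray        # 5-vector, KSS units
    z_weights: np.ndarray       # 5-vector, unitless, mean 0 / pop-SD 1
    n_subjects: np.ndarray      # subjects contributing per session


@dataclass
class RTPartition:
    """Per-trial speed labels and the thresholds that produced them."""

    labels: np.ndarray          # array of SPEED_LABELS strings
    p25: float                  # ms, over non-lapse RTs
    p75: float                  # ms


def session_kss(pre, post):
    """Session sleepiness = mean of the pre- and post-scan rating.

    Either rating may be missing (None/NaN); the other is then used and the
    value is flagged.  Returns ``(value, single_rating_flag)``; with both
    ratings missing the value is NaN.
    """
    def _missing(x):
        return x is None or (isinstance(x, float) and np.isnan(x))

    pre_m, post_m = _missing(pre), _missing(post)
    if pre_m and post_m:
        return np.nan, True
    if pre_m or post_m:
        return float(post if pre_m else pre), True
    return 0.5 * (float(pre) + float(post)), False


def zscore_profile(means) -> np.ndarray:
    """Z-score a session profile (mean 0, population SD 1, order preserved)."""
    means = np.asarray(means, dtype=float)
    sd = means.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant profile (zero variance)")
    return (means - means.mean()) / sd


def partition_rts(rts) -> RTPartition:
    """Label each RT as fast / intermediate / slow / lapse.

    Lapses are RTs above 500 ms; they are excluded from the percentile
    computation, and fast/slow are strict exceedances of the 25th/75th
    percentile of the remaining RTs.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < MIN_RTS_FOR_PARTITION:
        log.warning("refusing to partition %d RTs (<%d)", rts.size, MIN_RTS_FOR_PARTITION)
        raise ValueError(
            f"need at least {MIN_RTS_FOR_PARTITION} RTs for a stable partition"
        )
    if np.any(rts <= 0) or np.any(~np.isfinite(rts)):
        raise ValueError("RTs must be positive and finite")

    lapse = rts > LAPSE_MS
    valid = rts[~lapse]
    if valid.size == 0:
        p25 = p75 = np.nan
    else:
        p25, p75 = np.percentile(valid, [25, 75])

    labels = np.full(rts.shape, "intermediate", dtype=object)
    labels[rts < p25] = "fast"
    labels[rts > p75] = "slow"
    labels[lapse] = "lapse"
    return RTPartition(labels=labels.astype(str), p25=float(p25), p75=float(p75))


def sleepiness_profile(kss_table: pd.DataFrame, condition: str) -> SleepinessProfile:
    """Group-mean session KSS profile for one arm.

    ``kss_table`` needs columns subject_id, condition, session (0-based),
    kss (the per-session pre/post mean).
    """
    sub = kss_table[kss_table["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no ratings for condition {condition!r}")
    g = sub.groupby("session")["kss"]
    means = g.mean().reindex(range(5)).to_numpy()
    n = g.count().reindex(range(5), fill_value=0).to_numpy()
    if np.any(np.isnan(means)):
        raise ValueError("incomplete session profile")
    return SleepinessProfile(condition=condition, mean_kss=means,
                             z_weights=zscore_profile(means), n_subjects=n)


def _paired_signflip_p(diffs: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided sign-flipping permutation p for a paired mean difference."""
    diffs = diffs[np.isfinite(diffs)]
    n = diffs.size
    if n < 3:
        return np.nan
    obs = abs(diffs.mean())
    if n <= 16:  # exhaustive
        signs = np.array(
            [[1 if (i >> j) & 1 else -1 for j in range(n)] for i in range(2 ** n)]
        )
        null = np.abs(signs @ diffs) / n
        return float(np.mean(null >= obs - 1e-12))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.abs(signs @ diffs) / n
    return float((1 + np.sum(null >= obs - 1e-12)) / (n_perm + 1))


def behavioral_summary(kss_table: pd.DataFrame, rt_tables: pd.DataFrame,
                       n_perm: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Condition x session table of mean KSS, fast/slow RT and lapse counts.

    ``rt_tables`` needs columns subject_id, condition, session,
    response_time_ms (clock trials only).  Returns one row per
    condition x session with cell means, SEMs, mean per-class counts, and a
    paired sign-flip permutation p-value for the SD-vs-NP difference of the
    KSS and lapse-count cells.
    """
    rng = np.random.default_rng(seed)
    rows = []
    per_subject = {}
    for (cond, sess, subj), g in rt_tables.groupby(
            ["condition", "session", "subject_id"]):
        rts = g["response_time_ms"].to_numpy(dtype=float)
        rts = rts[np.isfinite(rts)]
        try:
            part = partition_rts(rts)
        except ValueError:
            continue
        lab = part.labels
        per_subject[(cond, sess, subj)] = {
            "fast_rt": rts[lab == "fast"].mean() if np.any(lab == "fast") else np.nan,
            "slow_rt": rts[lab == "slow"].mean() if np.any(lab == "slow") else np.nan,
            "n_fast": int(np.sum(lab == "fast")),
            "n_slow": int(np.sum(lab == "slow")),
            "n_intermediate": int(np.sum(lab == "intermediate")),
            "n_lapse": int(np.sum(lab == "lapse")),
            "n_trials": int(rts.size),
        }

    kss_cells = kss_table.set_index(["condition", "session", "subject_id"])["kss"]
    subjects = sorted(kss_table["subject_id"].unique())

    for sess in range(5):
        paired_kss, paired_lapse = [], []
        for subj in subjects:
            try:
                dk = kss_cells.loc[("SD", sess, subj)] - kss_cells.loc[("NP", sess, subj)]
            except KeyError:
                dk = np.nan
            sd_rec = per_subject.get(("SD", sess, subj))
            np_rec = per_subject.get(("NP", sess, subj))
            dl = (sd_rec["n_lapse"] - np_rec["n_lapse"]) if sd_rec and np_rec else np.nan
            paired_kss.append(dk)
            paired_lapse.append(dl)
        p_kss = _paired_signflip_p(np.asarray(paired_kss, float), n_perm, rng)
        p_lapse = _paired_signflip_p(np.asarray(paired_lapse, float), n_perm, rng)

        for cond in ("SD", "NP"):
            kvals = kss_table.query("condition == @cond and session == @sess")["kss"]
            recs = [v for (c, s, _), v in per_subject.items()
                    if c == cond and s == sess]
            def _m(key):
                vals = np.array([r[key] for r in recs], dtype=float)
                vals = vals[np.isfinite(vals)]
                return (vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals))
                        if len(vals) > 1 else 0.0) if len(vals) else (np.nan, np.nan)
            fast_m, fast_sem = _m("fast_rt")
            slow_m, slow_sem = _m("slow_rt")
            lapse_m, lapse_sem = _m("n_lapse")
            nfast_m, _ = _m("n_fast")
            rows.append({
                "condition": cond, "session": sess,
                "kss_mean": kvals.mean(), "kss_sem": kvals.sem(ddof=1),
                "fast_rt_mean": fast_m, "fast_rt_sem": fast_sem,
                "slow_rt_mean": slow_m, "slow_rt_sem": slow_sem,
                "lapses_mean": lapse_m, "lapses_sem": lapse_sem,
                "fast_events_mean": nfast_m,
                "p_condition_kss": p_kss, "p_condition_lapses": p_lapse,
            })
    return pd.DataFrame(rows)


def missing_session_check(profile_with_gap, reference) -> bool:
    """Inclusion rule for subjects with missing sessions.

    True iff the subject's available session values correlate positively and
    significantly (one-sided Pearson, alpha = 0.05) with the group reference
    profile over the shared sessions.
    """
    x = np.asarray(profile_with_gap, dtype=float)
    ref = np.asarray(reference, dtype=float)
    ok = np.isfinite(x) & np.isfinite(ref)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 shared sessions; subject not includable")
        return False
    r, p = stats.pearsonr(x[ok], ref[ok], alternative="greater")
    return bool(p < 0.05)
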