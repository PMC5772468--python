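"""In-silico study cohort with known ground truth at every stage.

``simulate_cohort`` generates a complete balanced cross-over study: per
subject, two-process sleepiness parameters, KSS ratings around every scan
session (and around every nap in the NP arm), in-scanner PVT event streams,
nap hypnograms, and baseline/recovery sleep-EEG spectra.  BOLD volumes are
materialised on demand per subject/arm/session through the forward model in
:mod:`circabold.bold`, with region-specific session-amplitude profiles
planted so the downstream sleepiness-anchored analysis has a known answer:

* thalamus and putamen carry a positive fast-event profile proportional to
  the SD-specific component of the sleepiness course (the z-scored SD
  profile orthogonalised against the z-scored NP profile) - so they respond
  to the homeostatic-by-circadian interaction but not to the purely
  circadian profile;
* postcentral, parietal and lingual cortex carry the negated profile
  (activation declining as SD-specific sleepiness builds);
* frontal cortex carries a negated profile whose per-subject amplitude
  grows with the planted delta rebound, and the thalamic amplitude grows
  with the planted circadian promotion strength, providing ground truth for
  the covariate analyses;
* the NP arm and (mostly) the slow event class carry no planted effects.

All randomness derives from a single integer seed via hierarchical
``SeedSequence`` keying, so identical seeds give bit-identical cohorts
regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior
from .bold import (DEFAULT_SHAPE, BOLDDataset, NoiseConfig, PlantedEffect,
                   make_atlas, simulate_bold)
from .pvt import PVTSession, RTCoeffs, simulate_pvt_session
from .schedule import ProtocolSchedule, np_schedule, sd_schedule
from .sleep import (EEGConfig, HypnoCoeffs, Hypnogram, SleepEEGSpectra,
                    simulate_hypnograms, simulate_sleep_eeg)
from .twoprocess import (DEFAULT_KSS_COEFFS, KSSSeries, SubjectParams,
                         latent_sleepiness, two_process_sleepiness)

# population heterogeneity (SDs of subject-level deviations)
HET = {
    "S0": 0.04,
    "tau_rise": 1.2,
    "tau_decay": 0.35,
    "circ_amp": 0.08,
    "circ_phase": 0.9,        # h; wake-time spread of ~52 min
    "k0": 0.45,               # KSS trait spread
    "lapse_x0": 0.30,
    "rebound_mean": 80.0,     # uV^2
    "rebound_sd": 30.0,
    "baseline_delta_mean": 400.0,
    "baseline_delta_sd": 40.0,
    "circ_strength_sd": 0.40,
}

OUTLIER_REBOUND = -150.0      # planted gross-negative rebound, uV^2


@dataclass
class CohortConfig:
    n_subjects: int = 31
    shape: tuple = DEFAULT_SHAPE
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    rt_coeffs: RTCoeffs = field(default_factory=RTCoeffs)
    hypno_coeffs: HypnoCoeffs = field(default_factory=HypnoCoeffs)
    eeg: EEGConfig = field(default_factory=EEGConfig)
    eeg_n_subjects: int = 26          # subjects with usable sleep EEG
    n_rebound_outliers: int = 1       # planted gross-negative rebounds
    planted_amplitude: float = 0.11   # % signal change, base effect size
    wake_time: float = 7.2
    include: tuple = ("kss", "pvt", "hypno", "eeg")


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


@dataclass
class Cohort:
    config: CohortConfig
    seed: int
    schedules: dict                   # condition -> ProtocolSchedule
    subjects: list                    # SubjectParams
    kss_series: dict                  # (subject_id, condition) -> KSSSeries
    kss_table: pd.DataFrame           # scan-session ratings, long format
    nap_kss_table: pd.DataFrame       # nap ratings (NP arm)
    pvt: dict                         # (subject_id, condition, session) -> PVTSession
    hypnograms: dict                  # subject_id -> [Hypnogram] (NP arm)
    eeg: dict                         # (subject_id, night) -> SleepEEGSpectra
    planted: list                     # base PlantedEffect list
    atlas: np.ndarray

    # ---------------- behavioural views --------------------------------
    def rt_table(self) -> pd.DataFrame:
        rows = []
        for (sid, cond, sess), session in self.pvt.items():
            for rt in session.rts:
                rows.append({"subject_id": sid, "condition": cond,
                             "session": sess, "response_time_ms": rt})
        return pd.DataFrame(rows)

    def sleepiness_profile(self, condition: str) -> behavior.SleepinessProfile:
        return behavior.sleepiness_profile(self.kss_table, condition)

    def grand_mean_kss(self, condition: str) -> float:
        sub = self.kss_table[self.kss_table["condition"] == condition]
        return float(sub["kss"].mean())

    def rem_kss_pairs(self):
        """Per-nap REM sleep minutes paired with the surrounding KSS rating,
        across all subjects (the unit of the REM-sleepiness correlation)."""
        rem, kss = [], []
        nap_kss = self.nap_kss_table.set_index(["subject_id", "nap_index"])["kss"]
        for sid, hyps in self.hypnograms.items():
            for h in hyps:
                rem.append(0.5 * float(np.sum(h.stages == "REM")))  # minutes
                kss.append(float(nap_kss.loc[(sid, h.nap_index)]))
        return np.asarray(rem), np.asarray(kss)

    # ---------------- marker truths ------------------------------------
    def marker_truth(self) -> pd.DataFrame:
        rows = [{"subject_id": p.subject_id,
                 "delta_rebound_true": p.delta_rebound_true,
                 "circ_strength_true": p.circ_strength_true}
                for p in self.subjects]
        return pd.DataFrame(rows)

    def covariate_z(self, params: SubjectParams, name: str) -> float:
        if name == "delta_rebound":
            return (params.delta_rebound_true - HET["rebound_mean"]) / HET["rebound_sd"]
        if name == "circ_strength":
            return (params.circ_strength_true - 1.0) / HET["circ_strength_sd"]
        raise ValueError(f"unknown covariate {name!r}")

    # ---------------- BOLD on demand -----------------------------------
    def planted_for_subject(self, params: SubjectParams) -> list:
        effects = []
        for eff in self.planted:
            scale = 1.0
            if eff.covariate is not None:
                z = self.covariate_z(params, eff.covariate)
                scale = 1.0 + eff.covariate_gain * z
            effects.append(replace(eff, amplitudes=tuple(
                a * scale for a in eff.amplitudes)))
        return effects

    def simulate_session_bold(self, subject_index: int, condition: str,
                              session: int, noise: NoiseConfig | None = None):
        """Materialise one session's BOLD dataset (dataset, design, motion)."""
        params = self.subjects[subject_index]
        pvt = self.pvt[(params.subject_id, condition, session)]
        rng = _rng(self.seed, subject_index, 7, 0 if condition == "SD" else 1,
                   session)
        return simulate_bold(pvt, self.atlas,
                             self.planted_for_subject(params),
                             noise if noise is not None else self.config.noise,
                             rng)


# --------------------------------------------------------------------------
# planted-effect construction

def mean_latent_profiles(wake_time: float = 7.2):
    """Deterministic population-mean latent sleepiness per session and arm."""
    p = SubjectParams(subject_id="pop-mean")
    out = {}
    for sched in (sd_schedule(wake_time), np_schedule(wake_time)):
        out[sched.condition] = latent_sleepiness(
            p, sched, np.asarray(sched.session_times))
    return out


def sd_specific_profile(wake_time: float = 7.2) -> np.ndarray:
    """Unit-variance session profile of the SD-specific sleepiness component.

    The z-scored SD latent profile orthogonalised against the z-scored NP
    latent profile: the part of the sleepiness course unique to extended
    wakefulness (the homeostatic-circadian interaction beyond the circadian
    course itself).
    """
    prof = mean_latent_profiles(wake_time)
    z_sd = behavior.zscore_profile(prof["SD"])
    z_np = behavior.zscore_profile(prof["NP"])
    u = z_sd - (z_sd @ z_np) / (z_np @ z_np) * z_np
    sd = u.std(ddof=0)
    if sd < 1e-12:
        raise RuntimeError("degenerate SD-specific profile")
    return u / sd


def default_planted_effects(amplitude: float = 0.8,
                            wake_time: float = 7.2) -> list:
    """Ground-truth regional effect profiles of the default cohort."""
    u = tuple(sd_specific_profile(wake_time))
    neg = tuple(-x for x in u)

    def scaled(vec, s):
        return tuple(s * v for v in vec)

    A = amplitude
    return [
        # compact subcortical blocks get larger nominal amplitudes so their
        # spatially smoothed effective amplitude matches the cortical slabs
        PlantedEffect("thalamus", "fast", "SD", scaled(u, 1.8 * A),
                      covariate="circ_strength", covariate_gain=0.3),
        PlantedEffect("putamen", "fast", "SD", scaled(u, 1.5 * A)),
        PlantedEffect("postcentral", "fast", "SD", scaled(neg, 1.4 * A)),
        PlantedEffect("parietal", "fast", "SD", scaled(neg, 1.15 * A)),
        PlantedEffect("lingual", "fast", "SD", scaled(neg, 0.8 * A)),
        # the marker explains most of the frontal between-subject variance,
        # making the slope FWE-detectable at n ~ 26
        PlantedEffect("frontal", "fast", "SD", scaled(neg, 0.8 * A),
                      covariate="delta_rebound", covariate_gain=2.0),
        # slow-range effects are sparser and exclude the thalamus
        PlantedEffect("lingual", "slow", "SD", scaled(neg, 0.6 * A)),
        PlantedEffect("frontal", "slow", "SD", scaled(neg, 0.5 * A)),
    ]


# --------------------------------------------------------------------------

def simulate_cohort(n_subjects: int = 31, config: CohortConfig | None = None,
                    seed: int = 1) -> Cohort:
    """Generate the full in-silico study.

    BOLD volumes are not materialised here (they can be large); use
    :meth:`Cohort.simulate_session_bold`, which is deterministic in the
    cohort seed.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for group inference")
    cfg = config or CohortConfig()
    cfg = replace(cfg, n_subjects=n_subjects)

    schedules = {"SD": sd_schedule(cfg.wake_time), "NP": np_schedule(cfg.wake_time)}
    include = set(cfg.include)

    subjects, kss_series, pvt, hypnograms, eeg = [], {}, {}, {}, {}
    kss_rows, nap_rows = [], []

    for i in range(n_subjects):
        rng = _rng(seed, i, 0)
        k0, ks, kc, ksc = DEFAULT_KSS_COEFFS
        params = SubjectParams(
            subject_id=f"sub-{i:02d}",
            S0=float(np.clip(0.38 + rng.normal(0, HET["S0"]), 0.2, 0.6)),
            tau_rise=float(max(5.0, 18.2 + rng.normal(0, HET["tau_rise"]))),
            tau_decay=float(max(1.0, 4.2 + rng.normal(0, HET["tau_decay"]))),
            circ_amp=float(max(0.3, 1.0 + rng.normal(0, HET["circ_amp"]))),
            circ_phase=float(15.0 + rng.normal(0, HET["circ_phase"])),
            kss_coeffs=(k0 + rng.normal(0, HET["k0"]), ks, kc, ksc),
            rt_coeffs=replace(cfg.rt_coeffs,
                              lapse_x0=cfg.rt_coeffs.lapse_x0
                              + rng.normal(0, HET["lapse_x0"])),
            delta_rebound_true=float(rng.normal(HET["rebound_mean"],
                                                HET["rebound_sd"])),
            circ_strength_true=float(max(0.25, rng.normal(
                1.0, HET["circ_strength_sd"]))),
        )
        if i < cfg.n_rebound_outliers:
            params.delta_rebound_true = OUTLIER_REBOUND
        subjects.append(params)

        for ci, cond in enumerate(("SD", "NP")):
            sched = schedules[cond]
            if "kss" in include:
                series = two_process_sleepiness(params, sched, _rng(seed, i, 1, ci))
                kss_series[(params.subject_id, cond)] = series
                for s in range(5):
                    val, flag = behavior.session_kss(series.pre_scan[s],
                                                     series.post_scan[s])
                    kss_rows.append({"subject_id": params.subject_id,
                                     "condition": cond, "session": s,
                                     "pre": series.pre_scan[s],
                                     "post": series.post_scan[s],
                                     "kss": val, "single_rating": flag})
                if cond == "NP":
                    for j in range(len(sched.nap_windows)):
                        val, _ = behavior.session_kss(series.nap_pre[j],
                                                      series.nap_post[j])
                        nap_rows.append({"subject_id": params.subject_id,
                                         "nap_index": j,
                                         "mid_h": 0.5 * sum(sched.nap_windows[j]),
                                         "kss": val})
            if "pvt" in include:
                lat = latent_sleepiness(params, sched,
                                        np.asarray(sched.session_times))
                for s in range(5):
                    pvt[(params.subject_id, cond, s)] = simulate_pvt_session(
                        float(lat[s]), params.rt_coeffs,
                        _rng(seed, i, 2, ci, s),
                        subject_id=params.subject_id, condition=cond,
                        session_index=s)

        if "hypno" in include:
            hypnograms[params.subject_id] = simulate_hypnograms(
                params, schedules["NP"], _rng(seed, i, 3),
                coeffs=cfg.hypno_coeffs)

        if "eeg" in include and i < cfg.eeg_n_subjects:
            base = float(_rng(seed, i, 4).normal(HET["baseline_delta_mean"],
                                                 HET["baseline_delta_sd"]))
            for ni, night in enumerate(("baseline", "recovery")):
                eeg[(params.subject_id, night)] = simulate_sleep_eeg(
                    params, night, _rng(seed, i, 5, ni), config=cfg.eeg,
                    baseline_delta=base)

    return Cohort(
        config=cfg, seed=seed, schedules=schedules, subjects=subjects,
        kss_series=kss_series,
        kss_table=pd.DataFrame(kss_rows),
        nap_kss_table=pd.DataFrame(nap_rows),
        pvt=pvt, hypnograms=hypnograms, eeg=eeg,
        planted=default_planted_effects(cfg.planted_amplitude, cfg.wake_time),
        atlas=make_atlas(cfg.shape),
    )
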