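"""Homeostatic and circadian physiology markers.

* Homeostatic marker: NREM delta-band (0.7-4 Hz) spectral power, averaged
  over artifact-free NREM epochs, and its recovery-minus-baseline rebound.
  Subjects whose rebound falls more than two interquartile ranges below the
  25th percentile of the group are excluded as outliers.
* Circadian marker: a composite sleep-wake-promotion score from the nap
  protocol - the REM-sleep peak (highest REM percentage of total nap sleep
  time across the ten naps) plus the percentage of wakefulness during the
  first-day evening nap (the wake maintenance zone).  Both terms are
  expressed as percentages so they are commensurate before summing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import ProtocolSchedule
from .sleep import DELTA_BAND, NREM_STAGES, SleepEEGSpectra

ARTIFACT_RMS_FACTOR = 5.0


@dataclass
class MarkerTable:
    """Per-subject covariates with exclusion flags."""

    table: pd.DataFrame    # subject_id, delta_rebound, circ_strength, excluded, reason

    def included(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]]


def artifact_mask(spectra: SleepEEGSpectra) -> np.ndarray:
    """True for epochs flagged as artifacts (RMS > 5x the median epoch RMS)."""
    rms = np.sqrt(spectra.epoch_total_power())
    return rms > ARTIFACT_RMS_FACTOR * np.median(rms)


def nrem_delta_power(spectra: SleepEEGSpectra,
                     stages: np.ndarray | None = None) -> float:
    """Mean delta-band power (uV^2) over artifact-free NREM epochs.

    Band edges are inclusive; a frequency bin belongs to the band if its
    centre lies in [0.7, 4] Hz.
    """
    stages = spectra.stages if stages is None else np.asarray(stages)
    if stages.shape[0] != spectra.psd.shape[0]:
        raise ValueError("stage labels and spectral epochs are not aligned")
    nrem = np.isin(stages, NREM_STAGES)
    keep = nrem & ~artifact_mask(spectra)
    if not np.any(keep):
        raise ValueError("no artifact-free NREM epochs")
    band = (spectra.freqs >= DELTA_BAND[0]) & (spectra.freqs <= DELTA_BAND[1])
    return float((spectra.psd[np.ix_(keep, band)].sum(axis=1) * spectra.df).mean())


def delta_rebound(baseline_power: float, recovery_power: float) -> float:
    """Recovery-minus-baseline NREM delta power (uV^2)."""
    return recovery_power - baseline_power


def flag_low_outliers(values) -> np.ndarray:
    """Flag values more than 2 IQRs below the 25th percentile.

    Percentiles use linear interpolation.  Requires at least 5 values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values to flag outliers")
    p25, p75 = np.percentile(values, [25, 75])
    cut = p25 - 2.0 * (p75 - p25)
    return values < cut


def circadian_strength(hypnograms: list, schedule: ProtocolSchedule) -> float:
    """Composite circadian sleep-wake-promotion score.

    max over naps of (REM epochs / sleep epochs, %) plus (wake epochs in the
    first-day evening nap / nap epochs, %).
    """
    ev = schedule.evening_nap_index()
    by_index = {h.nap_index: h for h in hypnograms}
    if ev not in by_index:
        raise ValueError("evening nap missing from hypnograms")
    rem = [h.rem_percent_of_sleep() for h in hypnograms]
    rem = [r for r in rem if np.isfinite(r)]
    rem_peak = max(rem) if rem else 0.0
    return rem_peak + by_index[ev].wake_percent()


def rem_sleepiness_correlation(rem_amounts, kss_values):
    """Spearman rank correlation (with exact tie handling) and two-sided p."""
    x = np.asarray(rem_amounts, dtype=float)
    y = np.asarray(kss_values, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("need at least 5 paired values")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def build_marker_table(subject_ids, rebounds, circ_scores) -> MarkerTable:
    """Assemble the covariate table, applying the low-rebound outlier rule."""
    rebounds = np.asarray(rebounds, dtype=float)
    flags = flag_low_outliers(rebounds)
    rows = []
    for sid, reb, cs, fl in zip(subject_ids, rebounds, circ_scores, flags):
        rows.append({
            "subject_id": sid,
            "delta_rebound": reb,
            "circ_strength": cs,
            "excluded": bool(fl),
            "reason": "delta rebound > 2 IQR below p25" if fl else "",
        })
    return MarkerTable(table=pd.DataFrame(rows))
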