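"""Nap hypnograms and sleep-EEG spectra.

Hypnograms.  Each 80-min nap of the nap protocol is scored in 30-s epochs
(160 per nap).  Stage draws follow time-varying propensities: the chance of
lying awake peaks in the wake maintenance zone (the circadian evening,
~14 h after habitual wake), scaled by the subject's circadian
promotion-strength latent; REM propensity within sleep follows a circadian
bump peaking in the late biological night / early morning, scaled by the
same latent, plus a sleepiness-coupled component so that naps taken when the
subject is sleepier carry more REM (the basis of the REM-sleepiness rank
correlation the analysis recovers).  Stages are drawn in 2-min blocks to
give some state persistence; per-epoch expected fractions equal the
propensities.

Sleep EEG.  Baseline and recovery nights (8 h, 30-s epochs) are generated
as per-epoch power spectra: each epoch's time series is white background
activity plus a delta-band tone whose amplitude is set so that the expected
NREM delta-band (0.7-4 Hz) power equals the subject's planted night mean -
baseline for the baseline night, baseline + planted rebound for recovery.
Spectra are Hanning-window periodograms (density scaling), so a tone of
amplitude a at a bin-centred frequency contributes exactly a^2/2 to the
band power.  A configurable fraction of epochs is amplitude-scaled to mimic
movement artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .schedule import ProtocolSchedule
from .twoprocess import SubjectParams, latent_sleepiness, process_s

EPOCH_S = 30.0
NAP_EPOCHS = 160
STAGES = ("wake", "N1", "N2", "N3", "N4", "REM")
NREM_STAGES = ("N1", "N2", "N3", "N4")

EEG_FS = 32.0                  # Hz; delta-focused synthetic EEG
NIGHT_HOURS = 8.0
DELTA_BAND = (0.7, 4.0)        # Hz, inclusive


@dataclass
class HypnoCoeffs:
    """Propensity parameters of the nap stage model (logit scales)."""

    wake_base: float = -1.5          # logit of wake propensity outside the WMZ
    wake_wmz_gain: float = 3.8       # x circ_strength x WMZ bump
    wake_s_gain: float = 2.0         # homeostatic suppression of wake
    wake_time_gain: float = 0.8      # slow decline of wake ability over 40 h
    wmz_center_h: float = 14.0       # elapsed h of the wake maintenance zone
    wmz_kappa: float = 6.0
    rem_base: float = -1.45          # logit of REM share within sleep
    rem_circ_gain: float = 2.6       # x circ_strength x circadian REM bump
    rem_center_h: float = 25.0       # late night / early morning peak
    rem_kappa: float = 3.0
    rem_sleepiness_gain: float = 0.6  # coupling to nap-time latent sleepiness
    rem_noise_sd: float = 0.4       # nap-level REM propensity noise
    block_epochs: int = 4            # stage persistence (2 min)
    nrem_split: tuple = (0.12, 0.55, 0.23, 0.10)   # N1..N4 shares


@dataclass
class Hypnogram:
    subject_id: str
    nap_index: int
    window_h: tuple              # (start, end) elapsed hours
    stages: np.ndarray           # NAP_EPOCHS stage labels

    def fraction(self, stage: str) -> float:
        return float(np.mean(self.stages == stage))

    @property
    def sleep_epochs(self) -> int:
        return int(np.sum(self.stages != "wake"))

    def rem_percent_of_sleep(self) -> float:
        """REM epochs as % of total sleep epochs in this nap (NaN if no sleep)."""
        ns = self.sleep_epochs
        if ns == 0:
            return np.nan
        return 100.0 * float(np.sum(self.stages == "REM")) / ns

    def wake_percent(self) -> float:
        return 100.0 * self.fraction("wake")


def _bump(t, center, kappa):
    """Von-Mises-shaped 24-h periodic bump in [0, 1], peak at `center`."""
    return np.exp(kappa * (np.cos(2 * np.pi * (t - center) / 24.0) - 1.0))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_hypnograms(params: SubjectParams, schedule: ProtocolSchedule,
                        seed, coeffs: HypnoCoeffs | None = None) -> list:
    """Simulate the ten nap hypnograms of one subject under the NP schedule."""
    if schedule.condition != "NP":
        raise ValueError("hypnograms require the NP schedule (SD has no naps)")
    co = coeffs or HypnoCoeffs()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # circadian modulation scales with both the subject's circadian amplitude
    # and the planted promotion-strength latent
    g = params.circ_strength_true * params.circ_amp

    mids = np.array([0.5 * (a + b) for a, b in schedule.nap_windows])
    nap_latent = latent_sleepiness(params, schedule, mids)
    rem_noise = rng.normal(0.0, co.rem_noise_sd, size=len(mids))

    hypnos = []
    for j, (a, b) in enumerate(schedule.nap_windows):
        t_epochs = a + (np.arange(NAP_EPOCHS) + 0.5) * EPOCH_S / 3600.0
        s_vals = process_s(params, schedule, np.minimum(t_epochs, b))
        p_wake = _sigmoid(
            co.wake_base
            + co.wake_wmz_gain * g * _bump(t_epochs, co.wmz_center_h, co.wmz_kappa)
            - co.wake_s_gain * (s_vals - 0.35)
            - co.wake_time_gain * (t_epochs / 40.0)
        )
        p_rem = _sigmoid(
            co.rem_base
            + co.rem_circ_gain * g * _bump(t_epochs, co.rem_center_h, co.rem_kappa)
            + co.rem_sleepiness_gain * (nap_latent[j] - 5.0)
            + rem_noise[j]
        )

        stages = np.empty(NAP_EPOCHS, dtype=object)
        nrem_p = np.asarray(co.nrem_split) / np.sum(co.nrem_split)
        for start in range(0, NAP_EPOCHS, co.block_epochs):
            k = slice(start, min(start + co.block_epochs, NAP_EPOCHS))
            if rng.uniform() < p_wake[start]:
                stages[k] = "wake"
            elif rng.uniform() < p_rem[start]:
                stages[k] = "REM"
            else:
                stages[k] = NREM_STAGES[rng.choice(4, p=nrem_p)]
        hypnos.append(Hypnogram(subject_id=params.subject_id, nap_index=j,
                                window_h=(a, b), stages=stages.astype(str)))
    return hypnos


# --------------------------------------------------------------------------
# sleep EEG

@dataclass
class EEGConfig:
    fs: float = EEG_FS
    night_hours: float = NIGHT_HOURS
    background_sd: float = 20.0       # uV, white background activity
    rem_wake_delta: float = 50.0      # uV^2, residual delta outside NREM
    decay_h: float = 2.5              # across-night decline of SWA
    artifact_fraction: float = 0.02
    artifact_scale: float = 8.0       # amplitude multiplier of artifact epochs


@dataclass
class SleepEEGSpectra:
    subject_id: str
    night: str                   # "baseline" | "recovery"
    freqs: np.ndarray            # Hz, resolution 1/30
    psd: np.ndarray              # (n_epochs, n_bins), uV^2/Hz
    stages: np.ndarray           # per-epoch stage labels

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def epoch_total_power(self) -> np.ndarray:
        return self.psd.sum(axis=1) * self.df


def simulate_night_hypnogram(rng: np.random.Generator, n_epochs: int,
                             recovery: bool) -> np.ndarray:
    """Coarse whole-night stage sequence; only the NREM/REM/wake identity
    matters downstream."""
    hours = (np.arange(n_epochs) + 0.5) * EPOCH_S / 3600.0
    p_wake = np.full(n_epochs, 0.03 if recovery else 0.06)
    p_rem = 0.08 + 0.14 * hours / hours[-1]        # REM-rich late night
    stages = np.empty(n_epochs, dtype=object)
    deep_bias = 0.12 if recovery else 0.0
    for start in range(0, n_epochs, 10):           # 5-min blocks
        k = slice(start, min(start + 10, n_epochs))
        u = rng.uniform()
        if u < p_wake[start]:
            stages[k] = "wake"
        elif u < p_wake[start] + p_rem[start]:
            stages[k] = "REM"
        else:
            p = np.array([0.08, 0.50 - deep_bias, 0.27 + deep_bias / 2,
                          0.15 + deep_bias / 2])
            stages[k] = NREM_STAGES[rng.choice(4, p=p / p.sum())]
    return stages.astype(str)


def simulate_sleep_eeg(params: SubjectParams, night: str, seed,
                       config: EEGConfig | None = None,
                       baseline_delta: float = 400.0) -> SleepEEGSpectra:
    """Per-epoch Hanning periodograms for one night of sleep EEG.

    The expected artifact-free NREM delta-band power is ``baseline_delta``
    for the baseline night and ``baseline_delta + params.delta_rebound_true``
    for the recovery night.
    """
    if night not in ("baseline", "recovery"):
        raise ValueError(f"unknown night label {night!r}")
    cfg = config or EEGConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_epochs = int(cfg.night_hours * 3600 / EPOCH_S)
    n_samp = int(EPOCH_S * cfg.fs)
    stages = simulate_night_hypnogram(rng, n_epochs, recovery=(night == "recovery"))
    nrem = np.isin(stages, NREM_STAGES)

    target_mean = baseline_delta + (params.delta_rebound_true
                                    if night == "recovery" else 0.0)
    # across-night exponential decline, normalised to the target mean over
    # the NREM epochs actually present
    hours = (np.arange(n_epochs) + 0.5) * EPOCH_S / 3600.0
    shape = np.exp(-hours / cfg.decay_h)
    shape = shape / shape[nrem].mean()
    target = np.where(nrem, target_mean * shape, cfg.rem_wake_delta)

    # background white noise contributes band power sigma^2 * bw / nyquist
    nyq = cfg.fs / 2.0
    bw = DELTA_BAND[1] - DELTA_BAND[0] + 1.0 / EPOCH_S   # inclusive bins
    bg_band = cfg.background_sd ** 2 * bw / nyq
    tone_power = np.maximum(target - bg_band, 0.0)
    amp = np.sqrt(2.0 * tone_power)

    # tone frequencies on exact bins inside the band
    df = 1.0 / EPOCH_S
    lo_bin, hi_bin = int(np.ceil(0.8 / df)), int(np.floor(3.5 / df))
    bins = rng.integers(lo_bin, hi_bin + 1, size=n_epochs)
    phases = rng.uniform(0, 2 * np.pi, size=n_epochs)

    t = np.arange(n_samp) / cfg.fs
    x = rng.normal(0.0, cfg.background_sd, size=(n_epochs, n_samp))
    x += amp[:, None] * np.cos(2 * np.pi * (bins * df)[:, None] * t[None, :]
                               + phases[:, None])

    n_art = int(round(cfg.artifact_fraction * n_epochs))
    if n_art:
        art_idx = rng.choice(n_epochs, size=n_art, replace=False)
        x[art_idx] *= cfg.artifact_scale

    freqs, psd = periodogram(x, fs=cfg.fs, window="hann", detrend="constant",
                             axis=-1)
    return SleepEEGSpectra(subject_id=params.subject_id, night=night,
                           freqs=freqs, psd=psd.astype(np.float64), stages=stages)
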