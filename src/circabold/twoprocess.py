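"""Two-process model of sleep-wake regulation and its mapping to sleepiness.

Process S (homeostatic sleep pressure) rises saturating-exponentially during
wake toward an upper asymptote U and decays exponentially during sleep toward
a lower asymptote L.  Process C (circadian drive) is a 24-h sinusoid whose
positive phase promotes sleepiness.  Subjective sleepiness on the Karolinska
Sleepiness Scale (KSS, 1-9) is modelled as an affine combination of S, C and
their product; the interaction term makes the circadian modulation of
sleepiness larger when homeostatic pressure is high, which is the behaviour
seen when wakefulness is extended into the biological night.

    S_wake(t)  = U - (U - S0) * exp(-dt / tau_rise)
    S_sleep(t) = L + (S0 - L) * exp(-dt / tau_decay)
    C(t)       = circ_amp * sin(2*pi*(t - circ_phase) / 24)
    latent(t)  = k0 + kS*S(t) + kC*C(t) + kSC*S(t)*C(t)

Ratings are the latent plus Gaussian rating noise, rounded to the nearest
integer and clipped to the 1-9 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import ProtocolSchedule

S_UPPER = 1.0
S_LOWER = 0.0

# Default sleepiness-mapping coefficients (k0, kS, kC, kSC).  kC and kSC are
# chosen so the effective circadian amplitude of the latent, kC + kSC*S,
# roughly doubles between rested (S ~ 0.35) and sleep-deprived (S ~ 0.9)
# states; k0 and kS are calibrated once against the group-mean KSS anchors
# of the emulated study design (grand means 5.7 under SD and 4.3 under NP)
# and frozen here.
DEFAULT_KSS_COEFFS = (3.3084, 3.4378, 0.3, 1.5)


@dataclass
class SubjectParams:
    """Per-subject generative parameters for both study arms."""

    subject_id: str
    S0: float = 0.38                     # homeostatic level at habitual wake
    tau_rise: float = 18.2               # h, build-up time constant
    tau_decay: float = 4.2               # h, dissipation time constant
    circ_amp: float = 1.0                # circadian amplitude (unitless)
    circ_phase: float = 15.0             # h; sleepiness-promoting peak at phase+6
    kss_coeffs: tuple = DEFAULT_KSS_COEFFS
    kss_noise_sd: float = 0.45           # rating noise, KSS units
    rt_coeffs: "RTCoeffs | None" = None  # set by the cohort generator
    delta_rebound_true: float = 80.0     # planted NREM delta rebound, uV^2
    circ_strength_true: float = 1.0      # planted circadian promotion latent

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if not (S_LOWER <= self.S0 <= S_UPPER):
            raise ValueError("S0 must lie in [0, 1]")


@dataclass
class KSSSeries:
    """Ratings around each scan session (and, for NP, around each nap)."""

    subject_id: str
    condition: str
    latent: np.ndarray           # noise-free latent at the 5 session times
    pre_scan: np.ndarray         # 5 ratings, 1-9
    post_scan: np.ndarray        # 5 ratings, 1-9
    nap_latent: np.ndarray | None = None   # NP: latent at each nap midpoint
    nap_pre: np.ndarray | None = None      # NP: rating just before each nap
    nap_post: np.ndarray | None = None     # NP: rating just after each nap


def process_s(params: SubjectParams, schedule: ProtocolSchedule,
              times: np.ndarray) -> np.ndarray:
    """Homeostatic pressure S at elapsed `times`, tracked through the
    schedule's wake and nap segments."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(times > schedule.duration_h):
        raise ValueError("requested time outside the 40-h protocol")

    # Build the breakpoint sequence: (start, end, asleep?)
    segments = []
    t = 0.0
    for a, b in schedule.nap_windows:
        if a > t:
            segments.append((t, a, False))
        segments.append((a, b, True))
        t = b
    if t < schedule.duration_h:
        segments.append((t, schedule.duration_h, False))

    # S value at each segment start, propagated analytically.
    s = params.S0
    out = np.empty_like(times)
    for (a, b, asleep) in segments:
        sel = (times >= a) & (times <= b)
        dt = times[sel] - a
        if asleep:
            out[sel] = S_LOWER + (s - S_LOWER) * np.exp(-dt / params.tau_decay)
            s = S_LOWER + (s - S_LOWER) * np.exp(-(b - a) / params.tau_decay)
        else:
            out[sel] = S_UPPER - (S_UPPER - s) * np.exp(-dt / params.tau_rise)
            s = S_UPPER - (S_UPPER - s) * np.exp(-(b - a) / params.tau_rise)
    return out


def process_c(params: SubjectParams, times: np.ndarray) -> np.ndarray:
    """Circadian sleepiness drive C at elapsed `times` (sleepiness-positive)."""
    times = np.asarray(times, dtype=float)
    return params.circ_amp * np.sin(2 * np.pi * (times - params.circ_phase) / 24.0)


def latent_sleepiness(params: SubjectParams, schedule: ProtocolSchedule,
                      times: np.ndarray) -> np.ndarray:
    """Noise-free latent KSS-scale sleepiness at elapsed `times`."""
    s = process_s(params, schedule, times)
    c = process_c(params, times)
    k0, ks, kc, ksc = params.kss_coeffs
    return k0 + ks * s + kc * c + ksc * s * c


def rate_kss(latent, noise_sd: float, rng: np.random.Generator | None):
    """Turn latent sleepiness into an integer KSS rating (1-9)."""
    latent = np.asarray(latent, dtype=float)
    if rng is None or noise_sd == 0:
        raw = latent
    else:
        raw = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    return np.clip(np.rint(raw), 1, 9)


def two_process_sleepiness(params: SubjectParams, schedule: ProtocolSchedule,
                           rng: np.random.Generator | None = None) -> KSSSeries:
    """Latent sleepiness plus pre/post ratings for one subject and arm.

    With ``rng=None`` the ratings are the noise-free latent rounded to the
    scale, which is convenient for deterministic checks.
    """
    times = np.asarray(schedule.session_times, dtype=float)
    lat = latent_sleepiness(params, schedule, times)
    pre = rate_kss(lat, params.kss_noise_sd, rng)
    post = rate_kss(lat, params.kss_noise_sd, rng)

    nap_latent = nap_pre = nap_post = None
    if schedule.condition == "NP":
        mids = np.array([0.5 * (a + b) for a, b in schedule.nap_windows])
        # Ratings are taken at lights-off and lights-on; the latent at the
        # nap midpoint stands for the sleepiness level around the nap.
        nap_latent = latent_sleepiness(params, schedule, mids)
        nap_pre = rate_kss(nap_latent, params.kss_noise_sd, rng)
        nap_post = rate_kss(nap_latent, params.kss_noise_sd, rng)

    return KSSSeries(
        subject_id=params.subject_id,
        condition=schedule.condition,
        latent=lat,
        pre_scan=pre,
        post_scan=post,
        nap_latent=nap_latent,
        nap_pre=nap_pre,
        nap_post=nap_post,
    )
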