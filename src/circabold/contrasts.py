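"""Sleepiness-anchored across-session contrasts.

The z-scored group-mean sleepiness profile of each arm defines weights for a
fixed-effect combination of the five session contrast volumes:

* ``CxS_SD``       - z(SD profile) applied to SD sessions: activation following
                     the interacting homeostatic x circadian sleepiness course;
* ``C_on_SD``      - z(NP profile) applied to SD sessions: a purely circadian
                     sleepiness course under high sleep pressure;
* ``C_on_NP``      - z(NP profile) applied to NP sessions;
* ``S_minus_C_SD`` - [z(SD) - z(NP)] applied to SD sessions: the near-linear
                     profile left after removing the circadian course.

The subtraction direction is z(SD) - z(NP), which rises with time awake
(a near-linear homeostatic slope); ``sign`` flips it for the opposite
reading.  Each contrast comes as a T+/T- pair, the T- weights being the
exact negation.  All weight vectors sum to zero, so session-constant
offsets cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import SleepinessProfile, missing_session_check, zscore_profile

CONTRAST_NAMES = ("CxS_SD", "C_on_SD", "C_on_NP", "S_minus_C_SD")
DEGENERATE_NORM = 1e-8


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    condition: str          # arm the weights are applied to
    weights: np.ndarray     # 5-vector, sums to zero
    direction: str          # "T+" | "T-"
    speed: str              # event class the session maps come from
    degenerate: bool = False

    def __post_init__(self):
        if abs(float(np.sum(self.weights))) > 1e-10:
            raise ValueError("contrast weights must sum to zero")

    def negated(self) -> "ContrastSpec":
        return ContrastSpec(name=self.name, condition=self.condition,
                            weights=-np.asarray(self.weights),
                            direction="T-" if self.direction == "T+" else "T+",
                            speed=self.speed, degenerate=self.degenerate)


def make_contrast_specs(sd_profile: SleepinessProfile,
                        np_profile: SleepinessProfile,
                        speed: str = "fast", sign: float = 1.0) -> dict:
    """Build the four T+ anchored contrast specs (T- is ``spec.negated()``)."""
    z_sd = zscore_profile(sd_profile.mean_kss)
    z_np = zscore_profile(np_profile.mean_kss)
    diff = sign * (z_sd - z_np)
    diff = diff - diff.mean()        # exact zero sum
    degenerate = bool(np.linalg.norm(diff) < DEGENERATE_NORM)

    def spec(name, cond, w, degen=False):
        return ContrastSpec(name=name, condition=cond,
                            weights=np.asarray(w, dtype=float),
                            direction="T+", speed=speed, degenerate=degen)

    return {
        "CxS_SD": spec("CxS_SD", "SD", z_sd),
        "C_on_SD": spec("C_on_SD", "SD", z_np),
        "C_on_NP": spec("C_on_NP", "NP", z_np),
        "S_minus_C_SD": spec("S_minus_C_SD", "SD", diff, degenerate),
    }


def restandardize_weights(weights: np.ndarray, available: np.ndarray) -> np.ndarray:
    """Re-centre (and re-scale to unit population SD) weights over the
    available sessions; unavailable entries are zeroed."""
    w = np.asarray(weights, dtype=float)
    available = np.asarray(available, dtype=bool)
    sub = w[available]
    sd = sub.std(ddof=0)
    if sd < DEGENERATE_NORM:
        raise ValueError("weights degenerate over available sessions")
    out = np.zeros_like(w)
    out[available] = (sub - sub.mean()) / sd
    return out


def apply_anchored_contrast(session_maps, spec: ContrastSpec,
                            available=None, subject_profile=None,
                            reference_profile=None) -> np.ndarray:
    """Voxelwise weighted sum of the session contrast volumes.

    ``session_maps`` is a sequence of five 3D arrays (missing sessions may
    be None when ``available`` marks them absent).  With at least four
    available sessions, a subject may still be included if the subject's
    own gapped sleepiness profile (``subject_profile``) passes the lag-0
    correlation check against the group ``reference_profile``; the weights
    are then re-standardised over the available sessions.
    """
    if available is None:
        available = np.array([m is not None for m in session_maps])
    available = np.asarray(available, dtype=bool)
    if available.sum() < 4:
        raise ValueError("need at least 4 available sessions")

    if available.all():
        weights = spec.weights
    else:
        if subject_profile is not None and reference_profile is not None:
            if not missing_session_check(subject_profile, reference_profile):
                raise ValueError("subject fails the missing-session inclusion check")
        weights = restandardize_weights(spec.weights, available)

    shapes = {m.shape for m, a in zip(session_maps, available) if a}
    if len(shapes) != 1:
        raise ValueError("session maps have mismatching geometry")

    out = None
    for w, m, a in zip(weights, session_maps, available):
        if not a:
            continue
        term = w * np.asarray(m, dtype=float)
        out = term if out is None else out + term
    return out
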