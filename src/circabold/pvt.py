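"""In-scanner psychomotor vigilance task (PVT) simulator.

Each 10-min session is a stream of trials.  A trial is either a *clock*
event (a millisecond counter the subject stops by button press) or a *null*
event (the counter runs but no response is required), with null events making
up 25% of trials.  Inter-stimulus intervals are uniform on 2-10 s.  A clock
trial occupies its ISI plus a fixed response-and-feedback slot; a null event
occupies its own 2-10 s counter display in place of the fixation period.

Responses follow a two-part model driven by latent sleepiness L:

* lapse (RT > 500 ms) with probability  p(L) = 1 / (1 + exp(-(L - x0)/s));
* otherwise a shifted lognormal RT truncated below 500 ms, whose median
  rises linearly with L.

Both the lapse probability and the RT location are non-decreasing in L, and
the lapse indicator uses a per-trial uniform draw compared against p(L), so
with a common seed a sleepier session lapses on a superset of trials.
The coefficients are calibrated once against the per-session mean
fast-event and lapse counts of the emulated study design and frozen as
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SESSION_DURATION_S = 600.0
ISI_RANGE_S = (2.0, 10.0)
NULL_FRACTION = 0.25
LAPSE_MS = 500.0
RESPONSE_SLOT_S = 1.5          # response window + 1-s RT feedback
NULL_DURATION_S = (2.0, 10.0)


@dataclass
class RTCoeffs:
    """Mapping from latent sleepiness to the RT / lapse model."""

    lapse_x0: float = 7.708      # KSS units; logistic midpoint of lapse prob
    lapse_scale: float = 1.632   # KSS units; logistic width
    rt_shift_ms: float = 150.0   # irreducible motor latency
    rt_median_base_ms: float = 90.0    # median of (RT - shift) at latent 0
    rt_median_slope_ms: float = 12.0   # ms per latent KSS unit
    rt_sigma_log: float = 0.22   # lognormal shape
    lapse_tail_ms: float = 120.0  # mean of the exponential lapse tail


@dataclass
class PVTSession:
    """One simulated 10-min PVT run."""

    subject_id: str
    condition: str
    session_index: int           # 0-based
    trials: pd.DataFrame         # onset_s, trial_type, response_time_ms
    duration_s: float = SESSION_DURATION_S

    @property
    def rts(self) -> np.ndarray:
        """Reaction times of responded (clock) trials, ms."""
        m = self.trials["trial_type"].eq("clock")
        return self.trials.loc[m, "response_time_ms"].to_numpy(dtype=float)


def lapse_probability(latent: float, coeffs: RTCoeffs) -> float:
    return float(1.0 / (1.0 + np.exp(-(latent - coeffs.lapse_x0) / coeffs.lapse_scale)))


def simulate_pvt_session(latent_sleepiness: float, rt_coeffs: RTCoeffs | None,
                         seed, subject_id: str = "sub-00", condition: str = "SD",
                         session_index: int = 0) -> PVTSession:
    """Simulate one PVT session at a given latent sleepiness level.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Trial timing is
    drawn before any response draws, so two sessions simulated with the same
    seed share an identical trial schedule regardless of sleepiness.
    """
    if not np.isfinite(latent_sleepiness):
        raise ValueError("latent sleepiness must be finite")
    coeffs = rt_coeffs or RTCoeffs()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # --- trial schedule (independent of sleepiness) ---------------------
    onsets, types = [], []
    t = 0.0
    while True:
        isi = rng.uniform(*ISI_RANGE_S)
        is_null = rng.uniform() < NULL_FRACTION
        null_len = rng.uniform(*NULL_DURATION_S)
        if is_null:
            onset, t_next = t, t + null_len
        else:
            onset, t_next = t + isi, t + isi + RESPONSE_SLOT_S
        if onset >= SESSION_DURATION_S:
            break
        onsets.append(onset)
        types.append("null" if is_null else "clock")
        t = t_next

    onsets = np.asarray(onsets)
    types = np.asarray(types)
    clock = types == "clock"
    n_clock = int(clock.sum())

    # --- responses ------------------------------------------------------
    p_lapse = lapse_probability(latent_sleepiness, coeffs)
    u = rng.uniform(size=n_clock)
    lapses = u < p_lapse

    med = coeffs.rt_median_base_ms + coeffs.rt_median_slope_ms * latent_sleepiness
    mu = np.log(max(med, 1.0))
    z = rng.normal(size=n_clock)
    rt = coeffs.rt_shift_ms + np.exp(mu + coeffs.rt_sigma_log * z)
    # truncate the non-lapse branch below the lapse criterion
    rt = np.minimum(rt, LAPSE_MS - 1e-3)
    tail = rng.exponential(coeffs.lapse_tail_ms, size=n_clock)
    rt[lapses] = LAPSE_MS + tail[lapses]

    response = np.full(onsets.shape, np.nan)
    response[clock] = rt

    trials = pd.DataFrame(
        {"onset_s": onsets, "trial_type": types, "response_time_ms": response}
    )
    return PVTSession(subject_id=subject_id, condition=condition,
                      session_index=session_index, trials=trials)
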