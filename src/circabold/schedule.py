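"""Study protocol schedules.

Both protocols start at habitual wake time (elapsed hour 0) and span 40 h.
Five scan sessions are placed at 5, 13, 21, 29 and 37 h elapsed.  The sleep
deprivation arm (SD) contains no sleep opportunity; the nap protocol (NP)
alternates 160 min of scheduled wakefulness with 80-min nap windows, ten
cycles in total.  The biological night is the 16-24 h elapsed window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SESSION_TIMES_H = (5.0, 13.0, 21.0, 29.0, 37.0)
PROTOCOL_HOURS = 40.0
NIGHT_WINDOW_H = (16.0, 24.0)

_CYCLE_H = 4.0          # 160 min wake + 80 min nap
_WAKE_PER_CYCLE_H = 160.0 / 60.0
_NAP_LEN_H = 80.0 / 60.0
N_NAPS = 10


@dataclass(frozen=True)
class ProtocolSchedule:
    """Timing of one study arm, in hours elapsed since habitual wake."""

    condition: str                       # "SD" or "NP"
    wake_time: float = 7.2               # habitual wake, clock hours
    session_times: tuple = SESSION_TIMES_H
    nap_windows: tuple = ()              # ((start, end), ...) elapsed hours
    night_window: tuple = NIGHT_WINDOW_H

    def __post_init__(self):
        if self.condition not in ("SD", "NP"):
            raise ValueError(f"condition must be 'SD' or 'NP', got {self.condition!r}")
        if self.condition == "SD" and self.nap_windows:
            raise ValueError("SD schedule cannot contain nap windows")
        if self.condition == "NP" and len(self.nap_windows) != N_NAPS:
            raise ValueError(f"NP schedule requires exactly {N_NAPS} nap windows")

    @property
    def duration_h(self) -> float:
        return PROTOCOL_HOURS

    def evening_nap_index(self) -> int:
        """Index of the first-day evening nap (wake maintenance zone).

        The evening of day one corresponds to roughly 12-16 h elapsed for a
        habitual riser; the nap whose midpoint falls closest to 15 h elapsed
        is taken as the wake-maintenance-zone nap.
        """
        if self.condition != "NP":
            raise ValueError("evening nap only defined for the NP schedule")
        mids = [0.5 * (a + b) for a, b in self.nap_windows]
        return min(range(len(mids)), key=lambda i: abs(mids[i] - 15.0))


def sd_schedule(wake_time: float = 7.2) -> ProtocolSchedule:
    return ProtocolSchedule(condition="SD", wake_time=wake_time)


def np_schedule(wake_time: float = 7.2) -> ProtocolSchedule:
    naps = tuple(
        (i * _CYCLE_H + _WAKE_PER_CYCLE_H, (i + 1) * _CYCLE_H) for i in range(N_NAPS)
    )
    return ProtocolSchedule(condition="NP", wake_time=wake_time, nap_windows=naps)
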