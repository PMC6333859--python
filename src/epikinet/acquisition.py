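"""Dynamic-scan frame schedules and frame averaging.

A dynamic PET acquisition is reconstructed into contiguous time frames of
varying duration (short frames around the bolus, long frames late).  The
:class:`FrameSchedule` holds the timing grid in **seconds**; kinetic rate
constants elsewhere in the package are per **minute** (the convention of the
tracer-kinetics literature), with explicit converters.

All activity curves handled here are assumed to be decay-corrected to
injection time, so no decay term appears anywhere in the models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "FrameSchedule",
    "InvalidProtocolError",
    "make_frame_schedule",
    "frame_average",
    "SECONDS_PER_MINUTE",
]

SECONDS_PER_MINUTE = 60.0


class InvalidProtocolError(ValueError):
    """Raised for frame schedules that violate the acquisition contract."""


@dataclass(frozen=True)
class FrameSchedule:
    """Timing grid of a dynamic acquisition.

    Parameters
    ----------
    starts
        Frame start times in seconds, strictly increasing.
    durations
        Frame durations in seconds, all positive.  Frames may be contiguous
        or gapped but never overlap.
    """

    starts: np.ndarray
    durations: np.ndarray
    mids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if starts.ndim != 1 or durations.ndim != 1:
            raise InvalidProtocolError("starts and durations must be 1-D")
        if len(starts) != len(durations):
            raise InvalidProtocolError("starts and durations differ in length")
        if len(starts) == 0:
            raise InvalidProtocolError("empty frame schedule")
        if np.any(durations <= 0):
            raise InvalidProtocolError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise InvalidProtocolError("frame starts must be strictly increasing")
        ends = starts + durations
        if np.any(ends[:-1] > starts[1:] + 1e-9):
            raise InvalidProtocolError("frames overlap")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "mids", starts + durations / 2.0)

    @property
    def n_frames(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        """End of the last frame, in seconds (frames start at their own t0)."""
        return float(self.ends[-1])

    # --- unit converters -------------------------------------------------
    @property
    def starts_min(self) -> np.ndarray:
        return self.starts / SECONDS_PER_MINUTE

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations / SECONDS_PER_MINUTE

    @property
    def mids_min(self) -> np.ndarray:
        return self.mids / SECONDS_PER_MINUTE

    def to_table(self):
        """Two-column table (frame_start_s, frame_duration_s)."""
        import pandas as pd

        return pd.DataFrame(
            {"frame_start_s": self.starts, "frame_duration_s": self.durations}
        )


def make_frame_schedule(groups: list[tuple[int, float]]) -> FrameSchedule:
    """Lay out frame groups end-to-end from t = 0.

    ``groups`` is a list of ``(count, duration_seconds)`` pairs, e.g. the
    39-frame clinical brain protocol
    ``[(12, 5), (6, 10), (6, 30), (6, 120), (10, 300)]`` (4020 s total).
    """
    if not groups:
        raise InvalidProtocolError("empty group list")
    durations: list[float] = []
    for count, dur in groups:
        if int(count) != count or count < 1:
            raise InvalidProtocolError(f"invalid frame count {count!r}")
        if dur <= 0:
            raise InvalidProtocolError(f"non-positive frame duration {dur!r}")
        durations.extend([float(dur)] * int(count))
    durations_arr = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations_arr)[:-1]])
    return FrameSchedule(starts=starts, durations=durations_arr)


def frame_average(curve, schedule: FrameSchedule) -> np.ndarray:
    """Average a continuous-time curve over each frame.

    ``curve`` is a callable of time in seconds, defined on
    ``[0, schedule end]``.  Each frame value is
    ``(1/T) * integral of curve over the frame``, computed with adaptive
    quadrature (falling back to a 64-point fixed Gauss rule when the
    adaptive routine struggles).
    """
    values = np.empty(schedule.n_frames)
    for i, (a, d) in enumerate(zip(schedule.starts, schedule.durations)):
        b = a + d
        try:
            integral, err = integrate.quad(curve, a, b, epsabs=1e-8, epsrel=1e-8, limit=200)
            if not np.isfinite(integral):
                raise ValueError("non-finite quadrature result")
        except Exception:
            integral = float(integrate.fixed_quad(np.vectorize(curve), a, b, n=64)[0])
        values[i] = integral / d
    return values
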