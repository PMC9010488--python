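"""Acquisition protocol: the contract every CEST stack is validated against.

Defaults reproduce a 3 T CrCEST exercise protocol: saturation offsets at
±1.5, ±1.8 and ±2.1 ppm around water, one image set every 24 s, five
baseline frames before a 2 min in-scanner plantar-flexion exercise, and
8 min of post-exercise imaging.  Frame times are expressed relative to the
end of exercise: baseline frames carry negative times, the first
post-exercise frame is at t = 0 s (the exercise interval itself is not
imaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["AcquisitionProtocol", "ProtocolError"]


class ProtocolError(ValueError):
    """Raised when protocol parameters are inconsistent."""


DEFAULT_OFFSETS_PPM = (-2.1, -1.8, -1.5, 1.5, 1.8, 2.1)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, saturation and geometry parameters of a CrCEST session.

    Parameters
    ----------
    offsets_ppm
        Saturation offsets relative to water, must come in ± pairs.
    frame_interval_s
        Temporal resolution (one full offset set per frame).
    n_baseline_frames
        Pre-exercise frames.
    exercise_duration_s
        In-scanner exercise duration (not imaged).
    post_duration_s
        Post-exercise imaging window; must be an integer number of frames.
    sat_b1_uT, sat_duration_ms
        Saturation pulse amplitude and length (recorded, not simulated at
        pulse level).
    matrix, fov_mm
        In-plane matrix size and field of view.
    """

    offsets_ppm: tuple[float, ...] = DEFAULT_OFFSETS_PPM
    frame_interval_s: float = 24.0
    n_baseline_frames: int = 5
    exercise_duration_s: float = 120.0
    post_duration_s: float = 480.0
    sat_b1_uT: float = 3.0
    sat_duration_ms: float = 500.0
    matrix: tuple[int, int] = (128, 128)
    fov_mm: tuple[float, float] = (160.0, 160.0)

    def __post_init__(self) -> None:
        offs = np.asarray(self.offsets_ppm, dtype=float)
        if offs.size == 0 or offs.size % 2:
            raise ProtocolError("offsets_ppm must be a non-empty set of ± pairs")
        if not np.allclose(np.sort(offs), -np.sort(-offs)[::-1]):
            # every +ω must have its −ω partner
            pos = np.sort(offs[offs > 0])
            neg = np.sort(-offs[offs < 0])
            if pos.size != neg.size or not np.allclose(pos, neg):
                raise ProtocolError("offsets_ppm must come in ± pairs")
        if np.any(offs == 0):
            raise ProtocolError("offsets_ppm must exclude 0 (water)")
        if self.frame_interval_s <= 0:
            raise ProtocolError("frame_interval_s must be positive")
        if self.n_baseline_frames < 1:
            raise ProtocolError("n_baseline_frames must be >= 1")
        n_post = self.post_duration_s / self.frame_interval_s
        if n_post <= 0 or abs(n_post - round(n_post)) > 1e-9:
            raise ProtocolError(
                "post_duration_s must be a positive integer multiple of "
                "frame_interval_s"
            )
        if len(self.matrix) != 2 or min(self.matrix) < 8:
            raise ProtocolError("matrix must be 2-D and at least 8 pixels")

    # -- derived quantities -------------------------------------------------

    @property
    def n_post_frames(self) -> int:
        return int(round(self.post_duration_s / self.frame_interval_s))

    @property
    def n_frames(self) -> int:
        return self.n_baseline_frames + self.n_post_frames

    @property
    def frame_times_s(self) -> np.ndarray:
        """Frame times relative to end of exercise (baseline negative)."""
        dt = self.frame_interval_s
        baseline = -dt * np.arange(self.n_baseline_frames, 0, -1)
        post = dt * np.arange(self.n_post_frames)
        return np.concatenate([baseline, post])

    @property
    def sorted_offsets(self) -> np.ndarray:
        return np.sort(np.asarray(self.offsets_ppm, dtype=float))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["offsets_ppm"] = list(self.offsets_ppm)
        d["matrix"] = list(self.matrix)
        d["fov_mm"] = list(self.fov_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        for k in ("offsets_ppm", "matrix", "fov_mm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)
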