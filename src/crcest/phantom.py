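"""Synthetic CrCEST phantom: anatomy, two-pool z-spectra and kinetics.

The forward signal model is an analytic sum of two Lorentzian lines — the
direct water saturation line at 0 ppm and the creatine amine pool at
+1.8 ppm — rather than a numerical Bloch–McConnell integration:

    Z(Δω) = 1 − a_w · L(Δω − b0; γ_w) − s(b1) · A_cr · L(Δω − b0 − δ_cr; γ_cr)

with L(x; γ) = γ² / (γ² + x²) a unit-peak Lorentzian, b0 the per-voxel
water-centre shift (ppm), and s(b1) a saturation-efficiency factor for the
relative B1 amplitude, s(b1) = 2·b1² / (1 + b1²), normalised so s(1) = 1.
The creatine amplitude A_cr is the dial that sets the CrCEST contrast; it
is calibrated in closed form so that the z-spectrum asymmetry at 1.8 ppm
hits a requested %asymmetry exactly.

Exercise-driven creatine kinetics follow the phosphocreatine shuttle
picture: a step increase ΔCrCEST at end of exercise followed by an
exponential return with muscle-specific time constant τCr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from crcest.protocol import AcquisitionProtocol

__all__ = [
    "MuscleKinetics",
    "TissuePhantom",
    "CestStack",
    "WassrStack",
    "SimulatedSession",
    "MUSCLE_LABELS",
    "lorentzian",
    "saturation_efficiency",
    "zspectrum_forward",
    "calibrate_cr_amplitude",
    "cr_time_course",
    "make_anatomy",
    "polynomial_field",
    "simulate_acquisition",
    "CalibrationError",
]

#: label codes of the segmented plantar-flexor muscles
MUSCLE_LABELS = {"LG": 1, "MG": 2, "Sol": 3}

# water line defaults: direct-saturation depth and half-width at 3 T with a
# 3 µT / 500 ms pulse (γ·3 µT ≈ 1 ppm at 128 MHz, so the direct-saturation
# line is broad); creatine amine line broadened by chemical exchange
# (k_ex ≈ 1 kHz ≈ 1.2 ppm at 3 T).  Widths this smooth also keep the
# three-point-per-side offset sampling of the acquisition protocol
# quadratically interpolable to well under 0.1 %asymmetry.
DEFAULT_WATER_AMP = 0.85
DEFAULT_WATER_WIDTH_PPM = 1.8
DEFAULT_CR_WIDTH_PPM = 1.2
DEFAULT_CR_CENTER_PPM = 1.8


class CalibrationError(ValueError):
    """Requested CrCEST level cannot be produced by the forward model."""


def lorentzian(x: np.ndarray, width_ppm: float) -> np.ndarray:
    """Unit-peak Lorentzian with half-width-at-half-maximum `width_ppm`."""
    w2 = width_ppm * width_ppm
    return w2 / (w2 + np.square(x))


def saturation_efficiency(b1_rel: np.ndarray) -> np.ndarray:
    """Relative saturation efficiency s(b1) = 2 b1² / (1 + b1²).

    Monotone increasing, bounded in (0, 2), and normalised so that the
    nominal B1 amplitude (b1_rel = 1) has unit efficiency.
    """
    b2 = np.square(np.asarray(b1_rel, dtype=float))
    return 2.0 * b2 / (1.0 + b2)


def zspectrum_forward(
    offset_ppm,
    water_width_ppm: float = DEFAULT_WATER_WIDTH_PPM,
    cr_amplitude=0.0,
    cr_center_ppm: float = DEFAULT_CR_CENTER_PPM,
    b0_ppm=0.0,
    b1_rel=1.0,
    water_amp: float = DEFAULT_WATER_AMP,
    cr_width_ppm: float = DEFAULT_CR_WIDTH_PPM,
):
    """Two-pool z-spectrum signal fraction at saturation offset `offset_ppm`.

    All arguments broadcast; returns values clipped to [0, 1].  A
    model-validity warning is emitted if the un-clipped signal leaves
    [0, 1] by more than 1e-6 (the parameters then over-drive the model).
    """
    if water_width_ppm <= 0:
        raise ValueError("water_width_ppm must be positive")
    if np.any(np.asarray(cr_amplitude) < 0):
        raise ValueError("cr_amplitude must be non-negative")
    if np.any(np.asarray(b1_rel) <= 0):
        raise ValueError("b1_rel must be positive")
    x = np.asarray(offset_ppm, dtype=float) - np.asarray(b0_ppm, dtype=float)
    z = (
        1.0
        - water_amp * lorentzian(x, water_width_ppm)
        - saturation_efficiency(b1_rel)
        * np.asarray(cr_amplitude)
        * lorentzian(x - cr_center_ppm, cr_width_ppm)
    )
    if np.any(z < -1e-6) or np.any(z > 1.0 + 1e-6):
        warnings.warn(
            "z-spectrum outside [0, 1] before clipping: pool amplitudes "
            "over-drive the two-Lorentzian model",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.clip(z, 0.0, 1.0)


def asymmetry_pct(z_neg, z_pos) -> np.ndarray:
    """MTR_asym in % with the S(−Δω) denominator convention."""
    return 100.0 * (np.asarray(z_neg) - np.asarray(z_pos)) / np.asarray(z_neg)


def calibrate_cr_amplitude(
    target_asym_pct,
    water_width_ppm: float = DEFAULT_WATER_WIDTH_PPM,
    cr_center_ppm: float = DEFAULT_CR_CENTER_PPM,
    water_amp: float = DEFAULT_WATER_AMP,
    cr_width_ppm: float = DEFAULT_CR_WIDTH_PPM,
    eval_offset_ppm: float = DEFAULT_CR_CENTER_PPM,
):
    """Creatine amplitude that yields `target_asym_pct` at the evaluation offset.

    Inverts the forward model in closed form at b0 = 0, b1_rel = 1.  With
    Z0 = 1 − a_w·L_w(ω), c = L_cr(−ω − δ_cr) the creatine tail under the
    reference side, and t the target fraction, the asymmetry

        t = A (L_cr(ω − δ_cr) − c) / (Z0 − A c)

    solves to A = t·Z0 / (L_cr(ω − δ_cr) − c + t·c).
    """
    t = np.asarray(target_asym_pct, dtype=float) / 100.0
    if np.any(t < 0) or np.any(t >= 0.5):
        raise CalibrationError("target asymmetry must be in [0, 50) %")
    z0 = 1.0 - water_amp * lorentzian(np.asarray(eval_offset_ppm), water_width_ppm)
    peak = lorentzian(eval_offset_ppm - cr_center_ppm, cr_width_ppm)
    tail = lorentzian(-eval_offset_ppm - cr_center_ppm, cr_width_ppm)
    denom = peak - tail + t * tail
    amp = t * z0 / denom
    if np.any(z0 - amp * peak < 1e-3):
        raise CalibrationError(
            "target asymmetry would drive the saturated signal to zero"
        )
    return amp if amp.shape else float(amp)


def cr_time_course(
    rest_asym_pct: float,
    delta_asym_pct: float,
    tau_s: float,
    protocol: AcquisitionProtocol,
) -> np.ndarray:
    """Ground-truth per-frame CrCEST %asymmetry for one muscle.

    Baseline frames sit at the resting level; from the first post-exercise
    frame (t₁ = 0) the contrast decays as rest + Δ·exp(−(t − t₁)/τ).
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    times = protocol.frame_times_s
    out = np.full(times.shape, float(rest_asym_pct))
    post = times >= 0
    t1 = times[post][0]
    out[post] = rest_asym_pct + delta_asym_pct * np.exp(-(times[post] - t1) / tau_s)
    return out


# ---------------------------------------------------------------------------
# anatomy and field maps


def make_anatomy(matrix: int | tuple[int, int], seed: int = 0) -> np.ndarray:
    """Label map with three disjoint, simply connected calf muscles.

    Labels: 0 background, 1 LG, 2 MG, 3 Sol.  Ellipse centres and radii are
    jittered deterministically from `seed`; placement guarantees the three
    regions never touch.
    """
    if isinstance(matrix, (int, np.integer)):
        matrix = (int(matrix), int(matrix))
    nx, ny = matrix
    if min(nx, ny) < 32:
        raise ValueError("matrix must be at least 32 pixels to place 3 muscles")
    rng = np.random.default_rng(seed)
    # fractional centres mimic a calf cross-section: the two gastrocnemius
    # heads posterior-lateral/medial, the larger soleus anterior
    base = [
        ("LG", (0.30, 0.32), (0.13, 0.11)),
        ("MG", (0.70, 0.32), (0.13, 0.11)),
        ("Sol", (0.50, 0.70), (0.20, 0.13)),
    ]
    yy, xx = np.mgrid[0:nx, 0:ny]
    label_map = np.zeros((nx, ny), dtype=np.int16)
    for name, (cx, cy), (rx, ry) in base:
        jitter = rng.uniform(-0.02, 0.02, size=4)
        cxp = (cx + jitter[0]) * ny
        cyp = (cy + jitter[1]) * nx
        rxp = (rx + 0.2 * rx * jitter[2]) * ny
        ryp = (ry + 0.2 * ry * jitter[3]) * nx
        mask = ((xx - cxp) / rxp) ** 2 + ((yy - cyp) / ryp) ** 2 <= 1.0
        if not mask.any():
            raise ValueError(f"matrix too small to place muscle {name}")
        if np.any(label_map[mask] != 0):  # pragma: no cover - by construction
            raise ValueError("muscle regions overlap; reduce jitter or grow matrix")
        label_map[mask] = MUSCLE_LABELS[name]
    return label_map


def polynomial_field(
    matrix: tuple[int, int],
    amplitude: float,
    seed: int = 0,
    offset: float = 0.0,
) -> np.ndarray:
    """Smooth low-order 2-D polynomial field, |field − offset| ≤ amplitude.

    Emulates shim-error morphology: a random quadratic in normalised
    coordinates, rescaled so its extreme magnitude equals `amplitude`.
    """
    nx, ny = matrix
    rng = np.random.default_rng(seed)
    u = np.linspace(-1.0, 1.0, nx)[:, None]
    v = np.linspace(-1.0, 1.0, ny)[None, :]
    coeffs = rng.uniform(-1.0, 1.0, size=6)
    f = (
        coeffs[0]
        + coeffs[1] * u
        + coeffs[2] * v
        + coeffs[3] * u * v
        + coeffs[4] * u**2
        + coeffs[5] * v**2
    )
    peak = np.abs(f).max()
    if peak > 0 and amplitude > 0:
        f = f * (amplitude / peak)
    else:
        f = np.zeros((nx, ny))
    return offset + f


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class MuscleKinetics:
    """Ground-truth creatine kinetics of one muscle."""

    rest_asym_pct: float
    delta_asym_pct: float
    tau_s: float

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.rest_asym_pct < 0:
            raise ValueError("rest_asym_pct must be non-negative")


#: Default per-muscle kinetics: healthy-adult medians (resting
#: CrCEST %, ΔCrCEST %, τCr s) for LG, MG and soleus.
DEFAULT_KINETICS = {
    "LG": MuscleKinetics(6.2, 8.9, 138.0),
    "MG": MuscleKinetics(5.9, 5.0, 184.0),
    "Sol": MuscleKinetics(6.6, 3.4, 254.0),
}


@dataclass
class TissuePhantom:
    """Ground-truth anatomy, pool parameters and kinetics for the simulator."""

    label_map: np.ndarray
    kinetics: dict[str, MuscleKinetics] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    water_amp: float = DEFAULT_WATER_AMP
    water_width_ppm: float = DEFAULT_WATER_WIDTH_PPM
    cr_center_ppm: float = DEFAULT_CR_CENTER_PPM
    cr_width_ppm: float = DEFAULT_CR_WIDTH_PPM
    b0_map_ppm: np.ndarray | None = None
    b1_rel_map: np.ndarray | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        shape = self.label_map.shape
        if self.b0_map_ppm is None:
            self.b0_map_ppm = np.zeros(shape)
        if self.b1_rel_map is None:
            self.b1_rel_map = np.ones(shape)
        self.b0_map_ppm = np.asarray(self.b0_map_ppm, dtype=float)
        self.b1_rel_map = np.asarray(self.b1_rel_map, dtype=float)
        if self.b0_map_ppm.shape != shape or self.b1_rel_map.shape != shape:
            raise ValueError("field maps must match label_map shape")
        if np.any(self.b1_rel_map <= 0):
            raise ValueError("b1_rel_map must be positive everywhere")
        for name in self.kinetics:
            if name not in MUSCLE_LABELS:
                raise ValueError(f"unknown muscle label {name!r}")

    @classmethod
    def default(
        cls,
        matrix: int | tuple[int, int] = (128, 128),
        seed: int = 0,
        b0_amplitude_ppm: float = 0.1,
        b1_range: tuple[float, float] = (0.9, 1.1),
        noise_sd: float = 0.0,
        kinetics: dict[str, MuscleKinetics] | None = None,
    ) -> "TissuePhantom":
        """Phantom with jittered anatomy and smooth polynomial B0/B1 fields."""
        label_map = make_anatomy(matrix, seed=seed)
        shape = label_map.shape
        b0 = polynomial_field(shape, b0_amplitude_ppm, seed=seed + 101)
        b1_half = 0.5 * (b1_range[1] - b1_range[0])
        b1_mid = 0.5 * (b1_range[1] + b1_range[0])
        b1 = polynomial_field(shape, b1_half, seed=seed + 202, offset=b1_mid)
        return cls(
            label_map=label_map,
            kinetics=dict(kinetics or DEFAULT_KINETICS),
            b0_map_ppm=b0,
            b1_rel_map=b1,
            noise_sd=noise_sd,
        )


@dataclass
class CestStack:
    """4-D CEST acquisition: (x, y, offset index, frame index) signal fractions."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    frame_times_s: np.ndarray
    offsets_ppm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.offsets_ppm is None:
            self.offsets_ppm = self.protocol.sorted_offsets
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("CestStack data must be 4-D (x, y, offset, frame)")
        if self.data.shape[2] != self.offsets_ppm.size:
            raise ValueError("offset axis inconsistent with offsets_ppm")
        if self.data.shape[3] != self.frame_times_s.size:
            raise ValueError("frame axis inconsistent with frame_times_s")
        dts = np.diff(self.frame_times_s)
        if np.any(dts <= 0):
            raise ValueError("frame_times_s must be strictly increasing")


@dataclass
class WassrStack:
    """Finely sampled water-reference z-spectrum: (x, y, fine offset index)."""

    data: np.ndarray
    offsets_ppm: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.offsets_ppm.size:
            raise ValueError("WassrStack data must be (x, y, n_offsets)")
        if self.offsets_ppm.size < 11:
            raise ValueError("WASSR needs at least 11 offsets")
        if not np.allclose(np.sort(self.offsets_ppm), -np.sort(-self.offsets_ppm)[::-1]):
            raise ValueError("WASSR offsets must be symmetric about 0")


@dataclass
class SimulatedSession:
    """One synthetic scan session plus its generating ground truth."""

    cest: CestStack
    wassr: WassrStack
    b1_rel_map: np.ndarray
    label_map: np.ndarray
    ground_truth: dict


DEFAULT_WASSR_OFFSETS = np.linspace(-1.0, 1.0, 21)


def simulate_acquisition(
    phantom: TissuePhantom,
    protocol: AcquisitionProtocol | None = None,
    seed: int = 0,
    wassr_offsets_ppm: np.ndarray | None = None,
) -> SimulatedSession:
    """Simulate one CrCEST exercise session from a phantom.

    Every voxel's z-spectrum follows the two-pool forward model with the
    voxel's B0/B1 and its muscle's creatine time course; the WASSR stack is
    the water-only reference (creatine amplitude 0) on a fine offset grid.
    Additive Gaussian noise of sd `phantom.noise_sd` (as a fraction of the
    unsaturated signal) is applied to both stacks; `seed` makes the session
    bit-reproducible.
    """
    protocol = protocol or AcquisitionProtocol()
    if wassr_offsets_ppm is None:
        wassr_offsets_ppm = DEFAULT_WASSR_OFFSETS
    wassr_offsets_ppm = np.asarray(wassr_offsets_ppm, dtype=float)
    rng = np.random.default_rng(seed)

    label = phantom.label_map
    nx, ny = label.shape
    offsets = protocol.sorted_offsets
    times = protocol.frame_times_s
    n_off, n_frames = offsets.size, times.size

    # per-voxel, per-frame creatine amplitude from the muscle time courses
    amp = np.zeros((nx, ny, n_frames))
    truth_kinetics = {}
    for name, kin in phantom.kinetics.items():
        code = MUSCLE_LABELS[name]
        mask = label == code
        if not mask.any():
            continue
        course_pct = cr_time_course(
            kin.rest_asym_pct, kin.delta_asym_pct, kin.tau_s, protocol
        )
        course_amp = calibrate_cr_amplitude(
            course_pct,
            water_width_ppm=phantom.water_width_ppm,
            cr_center_ppm=phantom.cr_center_ppm,
            water_amp=phantom.water_amp,
            cr_width_ppm=phantom.cr_width_ppm,
        )
        amp[mask, :] = np.asarray(course_amp)[None, :]
        truth_kinetics[name] = {
            "rest_asym_pct": kin.rest_asym_pct,
            "delta_asym_pct": kin.delta_asym_pct,
            "tau_s": kin.tau_s,
        }

    b0 = phantom.b0_map_ppm[:, :, None, None]
    b1 = phantom.b1_rel_map[:, :, None, None]
    cest_data = zspectrum_forward(
        offsets[None, None, :, None],
        water_width_ppm=phantom.water_width_ppm,
        cr_amplitude=amp[:, :, None, :],
        cr_center_ppm=phantom.cr_center_ppm,
        b0_ppm=b0,
        b1_rel=b1,
        water_amp=phantom.water_amp,
        cr_width_ppm=phantom.cr_width_ppm,
    )

    wassr_data = zspectrum_forward(
        wassr_offsets_ppm[None, None, :],
        water_width_ppm=phantom.water_width_ppm,
        cr_amplitude=0.0,
        cr_center_ppm=phantom.cr_center_ppm,
        b0_ppm=phantom.b0_map_ppm[:, :, None],
        b1_rel=phantom.b1_rel_map[:, :, None],
        water_amp=phantom.water_amp,
        cr_width_ppm=phantom.cr_width_ppm,
    )

    if phantom.noise_sd > 0:
        cest_data = np.clip(
            cest_data + rng.normal(0.0, phantom.noise_sd, cest_data.shape), 0.0, 1.0
        )
        wassr_data = np.clip(
            wassr_data + rng.normal(0.0, phantom.noise_sd, wassr_data.shape), 0.0, 1.0
        )

    ground_truth = {
        "seed": int(seed),
        "noise_sd": float(phantom.noise_sd),
        "water_amp": float(phantom.water_amp),
        "water_width_ppm": float(phantom.water_width_ppm),
        "cr_center_ppm": float(phantom.cr_center_ppm),
        "cr_width_ppm": float(phantom.cr_width_ppm),
        "kinetics": truth_kinetics,
        "protocol": protocol.to_dict(),
        "wassr_offsets_ppm": wassr_offsets_ppm.tolist(),
    }

    cest = CestStack(
        data=cest_data,
        protocol=protocol,
        frame_times_s=times,
        offsets_ppm=offsets,
    )
    wassr = WassrStack(data=wassr_data, offsets_ppm=wassr_offsets_ppm)
    return SimulatedSession(
        cest=cest,
        wassr=wassr,
        b1_rel_map=phantom.b1_rel_map.copy(),
        label_map=label.copy(),
        ground_truth=ground_truth,
    )
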