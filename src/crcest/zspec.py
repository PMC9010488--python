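"""Per-voxel field correction and MTR_asym computation.

Stages:

1. :func:`wassr_b0_map` — water-centre (B0) estimation from the WASSR
   stack by the maximum-symmetry method: the centre c minimising the
   reflection residual Σ_ω (Ẑ(ω) − Ẑ(2c − ω))² over the monotone-cubic
   interpolated spectrum, searched on a coarse grid and refined to
   1e-3 ppm.
2. :func:`correct_b0` — per-side quadratic resampling of the ±1.5/1.8/2.1
   ppm acquisitions at the voxel's true ±1.8 ppm position.
3. :func:`mtr_asym_map` — MTR_asym(%) = 100·(S(−Δω) − S(+Δω))/S(−Δω).
4. :func:`b1_correction` — divide by the saturation-efficiency curve
   normalised to unity at nominal B1.

The asymmetry denominator convention (S(−Δω) rather than the unsaturated
S0) is recorded in :class:`AsymMapSeries` metadata and switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from crcest.phantom import CestStack, WassrStack, saturation_efficiency

__all__ = [
    "FieldMaps",
    "AsymMapSeries",
    "wassr_b0_map",
    "correct_b0",
    "b1_correction",
    "mtr_asym_map",
    "compute_asym_series",
]

#: voxels whose |B0| exceeds this cannot be resampled inside the ±0.3 ppm
#: support of the three-per-side offset set and are flagged out
B0_INTERP_LIMIT_PPM = 0.3

#: valid relative-B1 window for correction
B1_VALID_RANGE = (0.5, 1.5)

#: minimum reference-side signal for a stable asymmetry ratio
MIN_REFERENCE_SIGNAL = 0.05

#: minimum WASSR dip depth below which a spectrum is considered flat
MIN_WASSR_DIP = 0.05


@dataclass
class FieldMaps:
    """Per-voxel B0 (ppm) and relative-B1 maps with a validity mask."""

    b0_ppm: np.ndarray
    b1_rel: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.b0_ppm = np.asarray(self.b0_ppm, dtype=float)
        self.b1_rel = np.asarray(self.b1_rel, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class AsymMapSeries:
    """MTR_asym maps over frames with per-voxel QC flags.

    `maps` is (x, y, frame) in % units; `qc_valid` marks voxels that
    survived the B0-range, B1-range and denominator checks.
    """

    maps: np.ndarray
    frame_times_s: np.ndarray
    qc_valid: np.ndarray
    offset_ppm: float = 1.8
    denominator: str = "S_neg"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.qc_valid = np.asarray(self.qc_valid, dtype=bool)
        if self.maps.ndim != 3:
            raise ValueError("maps must be 3-D (x, y, frame)")
        if self.maps.shape[2] != self.frame_times_s.size:
            raise ValueError("frame axis inconsistent with frame_times_s")
        if self.qc_valid.shape != self.maps.shape[:2]:
            raise ValueError("qc_valid must be a per-voxel 2-D mask")


def _reflection_residual_grid(
    z_dense: np.ndarray,
    grid0: float,
    step: float,
    offsets: np.ndarray,
    centers: np.ndarray,
) -> np.ndarray:
    """Mean squared reflection residual at per-voxel candidate centres.

    `z_dense` is (n_grid, n_vox); `centers` is (n_cand, n_vox) or
    (n_cand, 1) of candidate centre frequencies.  Offsets whose reflection
    2c − ω falls outside the sampled grid are excluded; the residual is the
    mean over the remaining (ω, 2c−ω) pairs.
    """
    n_grid, n_vox = z_dense.shape
    n_cand = centers.shape[0]
    vox_idx = np.arange(n_vox)
    total = np.zeros((n_cand, n_vox))
    count = np.zeros((n_cand, n_vox))
    for omega in offsets:
        i_omega = int(round((omega - grid0) / step))
        z_at = z_dense[i_omega]  # (n_vox,)
        refl = 2.0 * centers - omega  # (n_cand, n_vox) or (n_cand, 1)
        idx = np.round((refl - grid0) / step).astype(int)
        ok = (idx >= 0) & (idx < n_grid)
        idx_c = np.clip(idx, 0, n_grid - 1)
        if idx_c.shape[1] == 1:
            z_ref = z_dense[idx_c[:, 0], :]
        else:
            z_ref = z_dense[idx_c, vox_idx[None, :]]
        diff = np.where(ok, z_at[None, :] - z_ref, 0.0)
        total += diff * diff
        count += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        msr = total / count
    msr[count == 0] = np.inf
    return msr


def wassr_b0_map(
    wassr: WassrStack,
    mask: np.ndarray | None = None,
    search_ppm: float = 0.5,
    coarse_step_ppm: float = 0.01,
    fine_step_ppm: float = 1e-3,
) -> FieldMaps:
    """Per-voxel water-centre shift by maximum-symmetry search.

    Spectra are interpolated with a monotone cubic (PCHIP) onto a dense
    grid; the centre is found on a coarse grid (default 0.01 ppm) over
    ±`search_ppm` and refined on a 1e-3 ppm grid around the coarse
    minimum.  Voxels with a flat spectrum (water dip shallower than
    ``MIN_WASSR_DIP``) are flagged invalid and carry NaN.
    """
    offsets = np.asarray(wassr.offsets_ppm, dtype=float)
    order = np.argsort(offsets)
    offsets = offsets[order]
    nx, ny, _ = wassr.data.shape
    if mask is None:
        mask = np.ones((nx, ny), dtype=bool)
    spectra = wassr.data[..., order][mask]  # (n_vox, n_off)
    n_vox = spectra.shape[0]

    b0_flat = np.full(n_vox, np.nan)
    dip = spectra.max(axis=1) - spectra.min(axis=1)
    usable = dip >= MIN_WASSR_DIP

    if usable.any():
        spec_u = spectra[usable]
        omax = offsets.max()
        step = fine_step_ppm
        n_grid = int(round(2 * omax / step)) + 1
        grid = np.linspace(-omax, omax, n_grid)  # exact endpoints
        interp = PchipInterpolator(offsets, spec_u.T, axis=0)
        z_dense = interp(grid)  # (n_grid, n_vox_u)

        coarse = np.arange(-search_ppm, search_ppm + coarse_step_ppm / 2,
                           coarse_step_ppm)
        msr = _reflection_residual_grid(
            z_dense, grid[0], step, offsets, coarse[:, None]
        )
        c0 = coarse[np.argmin(msr, axis=0)]  # (n_vox_u,)

        refine = np.arange(-coarse_step_ppm, coarse_step_ppm + step / 2, step)
        cand = c0[None, :] + refine[:, None]  # (n_ref, n_vox_u)
        msr_f = _reflection_residual_grid(z_dense, grid[0], step, offsets, cand)
        best = np.argmin(msr_f, axis=0)
        b0_u = cand[best, np.arange(cand.shape[1])]
        b0_flat[usable] = b0_u

    b0_map = np.full((nx, ny), np.nan)
    valid = np.zeros((nx, ny), dtype=bool)
    b0_map[mask] = b0_flat
    tmp = np.zeros(n_vox, dtype=bool)
    tmp[:] = usable
    valid[mask] = tmp
    return FieldMaps(b0_ppm=b0_map, b1_rel=np.ones((nx, ny)), valid=valid)


def _quadratic_resample(side_signals: np.ndarray, side_offsets: np.ndarray,
                        eval_at: np.ndarray) -> np.ndarray:
    """Lagrange quadratic through three per-side points, per voxel/frame.

    `side_signals` is (..., 3); `eval_at` broadcasts over the leading axes.
    """
    x0, x1, x2 = side_offsets
    t = eval_at
    w0 = (t - x1) * (t - x2) / ((x0 - x1) * (x0 - x2))
    w1 = (t - x0) * (t - x2) / ((x1 - x0) * (x1 - x2))
    w2 = (t - x0) * (t - x1) / ((x2 - x0) * (x2 - x1))
    return (
        w0 * side_signals[..., 0]
        + w1 * side_signals[..., 1]
        + w2 * side_signals[..., 2]
    )


def _linear_two_point(side_signals: np.ndarray, side_offsets: np.ndarray,
                      eval_at: np.ndarray, keep: tuple[int, int]) -> np.ndarray:
    i, j = keep
    xi, xj = side_offsets[i], side_offsets[j]
    w = (eval_at - xi) / (xj - xi)
    return (1.0 - w) * side_signals[..., i] + w * side_signals[..., j]


def _resample_side(side_signals: np.ndarray, side_offsets: np.ndarray,
                   eval_at: np.ndarray) -> np.ndarray:
    """Quadratic resampling with linear fallback when one point is flagged.

    An entry with exactly one non-finite acquired point falls back to the
    line through the remaining two; with fewer than two finite points the
    output is NaN.
    """
    out = _quadratic_resample(side_signals, side_offsets, eval_at)
    finite = np.isfinite(side_signals)
    n_ok = finite.sum(axis=-1)
    if np.all(n_ok == 3):
        return out
    ev = np.broadcast_to(eval_at, out.shape)
    for drop, keep in ((0, (1, 2)), (1, (0, 2)), (2, (0, 1))):
        sel = (n_ok == 2) & ~finite[..., drop]
        if sel.any():
            out[sel] = _linear_two_point(
                side_signals[sel], side_offsets, ev[sel], keep
            )
    out[n_ok < 2] = np.nan
    return out


def correct_b0(
    stack: CestStack,
    b0_ppm: np.ndarray,
    eval_offset_ppm: float = 1.8,
    limit_ppm: float = B0_INTERP_LIMIT_PPM,
) -> tuple[CestStack, np.ndarray]:
    """Resample each voxel's two sides at its true ±`eval_offset_ppm`.

    The measured spectrum is the ideal one shifted by the voxel's b0, so
    the ideal value at ±1.8 ppm sits at nominal offset ±1.8 + b0; each side
    is interpolated quadratically through its three acquired offsets and
    evaluated there.  Returns a two-offset stack (−1.8, +1.8) and a boolean
    validity mask; voxels with |b0| > `limit_ppm` (outside the three-point
    support) or non-finite b0 are flagged False and carry NaN.
    """
    offsets = stack.offsets_ppm
    neg = np.sort(offsets[offsets < 0])
    pos = np.sort(offsets[offsets > 0])
    if neg.size < 3 or pos.size < 3:
        raise ValueError("B0 correction needs at least 3 offsets per side")
    b0 = np.asarray(b0_ppm, dtype=float)
    if b0.shape != stack.data.shape[:2]:
        raise ValueError("b0 map shape must match stack")

    valid = np.isfinite(b0) & (np.abs(b0) <= limit_ppm)
    b0_safe = np.where(valid, b0, 0.0)

    neg_idx = [int(np.where(offsets == o)[0][0]) for o in neg[-3:]]
    pos_idx = [int(np.where(offsets == o)[0][0]) for o in pos[:3]]
    sig_neg = stack.data[:, :, neg_idx, :]  # (x, y, 3, f)
    sig_pos = stack.data[:, :, pos_idx, :]

    eval_neg = (-eval_offset_ppm + b0_safe)[:, :, None]
    eval_pos = (eval_offset_ppm + b0_safe)[:, :, None]
    s_neg = _resample_side(np.moveaxis(sig_neg, 2, -1), neg[-3:], eval_neg)
    s_pos = _resample_side(np.moveaxis(sig_pos, 2, -1), pos[:3], eval_pos)

    out = np.stack([s_neg, s_pos], axis=2)  # (x, y, 2, f)
    out[~valid] = np.nan
    corrected = CestStack(
        data=out,
        protocol=stack.protocol,
        frame_times_s=stack.frame_times_s,
        offsets_ppm=np.array([-eval_offset_ppm, eval_offset_ppm]),
    )
    return corrected, valid


def mtr_asym_map(
    corrected: CestStack,
    valid: np.ndarray | None = None,
    denominator: str = "S_neg",
    min_reference: float = MIN_REFERENCE_SIGNAL,
) -> AsymMapSeries:
    """MTR_asym(%) maps from a two-offset (−Δω, +Δω) corrected stack.

    Voxels whose reference signal S(−Δω) drops to ≤ `min_reference` in any
    frame are flagged (division instability).  The `denominator` switch
    selects S(−Δω) (default) or the unsaturated signal S0 = 1.
    """
    if corrected.data.shape[2] != 2:
        raise ValueError("expected a two-offset (−Δω, +Δω) corrected stack")
    s_neg = corrected.data[:, :, 0, :]
    s_pos = corrected.data[:, :, 1, :]
    if denominator == "S_neg":
        denom = s_neg
    elif denominator == "S0":
        denom = np.ones_like(s_neg)
    else:
        raise ValueError("denominator must be 'S_neg' or 'S0'")
    with np.errstate(invalid="ignore", divide="ignore"):
        maps = 100.0 * (s_neg - s_pos) / denom
    finite = np.isfinite(s_neg).all(axis=2)
    stable = np.where(
        np.isfinite(s_neg), s_neg > min_reference, True
    ).all(axis=2)
    qc = finite & stable
    if valid is not None:
        qc = qc & np.asarray(valid, dtype=bool)
    return AsymMapSeries(
        maps=maps,
        frame_times_s=corrected.frame_times_s,
        qc_valid=qc,
        offset_ppm=float(abs(corrected.offsets_ppm[1])),
        denominator=denominator,
    )


def b1_correction(
    asym: AsymMapSeries,
    b1_rel: np.ndarray,
    valid_range: tuple[float, float] = B1_VALID_RANGE,
) -> AsymMapSeries:
    """Divide MTR_asym by the normalised saturation-efficiency curve.

    ŝ(b1) = s(b1)/s(1) with s the generator's efficiency curve; voxels
    with b1 outside `valid_range` are flagged invalid.
    """
    b1 = np.asarray(b1_rel, dtype=float)
    if b1.shape != asym.maps.shape[:2]:
        raise ValueError("b1 map shape must match asym maps")
    in_range = (b1 > valid_range[0]) & (b1 < valid_range[1])
    eff = saturation_efficiency(np.where(in_range, b1, 1.0))
    corrected = asym.maps / eff[:, :, None]
    corrected[~in_range] = np.nan
    return AsymMapSeries(
        maps=corrected,
        frame_times_s=asym.frame_times_s,
        qc_valid=asym.qc_valid & in_range,
        offset_ppm=asym.offset_ppm,
        denominator=asym.denominator,
        meta={**asym.meta, "b1_corrected": True},
    )


def compute_asym_series(
    cest: CestStack,
    wassr: WassrStack,
    b1_rel_map: np.ndarray,
    mask: np.ndarray | None = None,
    apply_b1: bool = True,
    denominator: str = "S_neg",
) -> tuple[AsymMapSeries, FieldMaps]:
    """Full field-corrected MTR_asym pipeline for one session.

    Chains WASSR B0 mapping, B0-corrected resampling at ±1.8 ppm,
    asymmetry computation and (optionally) B1 correction.  `mask`
    restricts the B0 search to foreground voxels.
    """
    fields = wassr_b0_map(wassr, mask=mask)
    corrected, b0_ok = correct_b0(cest, fields.b0_ppm)
    asym = mtr_asym_map(corrected, valid=b0_ok & fields.valid,
                        denominator=denominator)
    if apply_b1:
        asym = b1_correction(asym, b1_rel_map)
    fields.b1_rel = np.asarray(b1_rel_map, dtype=float)
    return asym, fields
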