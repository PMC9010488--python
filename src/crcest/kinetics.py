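"""Muscle-ROI time series and creatine recovery kinetics.

Endpoints per muscle:

* resting CrCEST — mean MTR_asym over the pre-exercise baseline frames,
  an index of free creatine concentration at rest;
* ΔCrCEST — first post-exercise value minus resting, the exercise-induced
  creatine release;
* τCr — time constant of the mono-exponential post-exercise decline,
  v(t) = asymptote + amp·exp(−t/τ), the index of muscle OXPHOS capacity.

Fitted τCr values shorter than one inter-scan interval (24 s) or longer
than 1000 s are flagged implausible (`excluded_low` / `excluded_high`) but
reported, so exclusions are auditable.  The recovery fit is presented
statsmodels-style: :class:`CrRecoveryModel` holds the series, ``fit()``
returns a :class:`KineticsFit` results object with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from crcest.phantom import MUSCLE_LABELS
from crcest.zspec import AsymMapSeries

__all__ = [
    "RoiTimeSeries",
    "KineticsFit",
    "CrRecoveryModel",
    "roi_timeseries",
    "resting_crcest",
    "delta_crcest",
    "fit_tau",
    "apply_plausibility_filter",
    "analyze_roi",
    "TAU_PLAUSIBLE_LO_S",
    "TAU_PLAUSIBLE_HI_S",
    "TAU_FIT_BOUNDS_S",
]

#: plausibility bounds on fitted τCr: below one inter-scan interval the
#: temporal resolution cannot support the estimate; above 1000 s the value
#: exceeds the post-exercise scan window and indicates an insufficient
#: exercise response
TAU_PLAUSIBLE_LO_S = 24.0
TAU_PLAUSIBLE_HI_S = 1000.0

#: hard optimisation bounds on τ during fitting (wider than plausibility,
#: so implausible estimates are still produced and then flagged)
TAU_FIT_BOUNDS_S = (1.0, 5000.0)


@dataclass
class RoiTimeSeries:
    """Mean MTR_asym of one muscle over frames."""

    muscle: str
    times_s: np.ndarray
    values_pct: np.ndarray
    n_voxels: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values_pct = np.asarray(self.values_pct, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if not (self.times_s.size == self.values_pct.size == self.n_voxels.size):
            raise ValueError("times, values and counts must align")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if not np.all(np.isfinite(self.values_pct)):
            raise ValueError("values_pct must be finite for retained frames")

    @property
    def baseline(self) -> np.ndarray:
        return self.values_pct[self.times_s < 0]

    @property
    def post(self) -> tuple[np.ndarray, np.ndarray]:
        sel = self.times_s >= 0
        return self.times_s[sel], self.values_pct[sel]


@dataclass(frozen=True)
class KineticsFit:
    """Results of the recovery analysis for one muscle ROI.

    `status` is one of ``ok``, ``excluded_low``, ``excluded_high`` or
    ``fit_failed``; plausibility-excluded fits keep their τ so exclusion
    accounting stays visible.
    """

    muscle: str
    resting_pct: float
    delta_pct: float
    tau_s: float
    amp_pct: float
    asymptote_pct: float
    rss: float
    status: str
    n_post_frames: int = 0
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"CrCEST recovery fit — {self.muscle}",
            f"  resting CrCEST : {self.resting_pct:8.3f} %",
            f"  ΔCrCEST        : {self.delta_pct:8.3f} %",
            f"  τCr            : {self.tau_s:8.1f} s",
            f"  amplitude      : {self.amp_pct:8.3f} %",
            f"  asymptote      : {self.asymptote_pct:8.3f} %",
            f"  RSS            : {self.rss:10.4g}",
            f"  post frames    : {self.n_post_frames}",
            f"  status         : {self.status}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "muscle": self.muscle,
            "resting_pct": self.resting_pct,
            "delta_pct": self.delta_pct,
            "tau_s": self.tau_s,
            "amp_pct": self.amp_pct,
            "asymptote_pct": self.asymptote_pct,
            "rss": self.rss,
            "status": self.status,
            "n_post_frames": self.n_post_frames,
        }


def roi_timeseries(
    maps: AsymMapSeries,
    label_map: np.ndarray,
    muscle: str,
) -> RoiTimeSeries:
    """Per-frame mean MTR_asym over the unflagged voxels of one muscle.

    Frames in which every muscle voxel is flagged or non-finite are
    dropped (recorded in the returned counts implicitly by their absence).
    """
    if muscle not in MUSCLE_LABELS:
        raise ValueError(f"unknown muscle {muscle!r}")
    code = MUSCLE_LABELS[muscle]
    label_map = np.asarray(label_map)
    if label_map.shape != maps.maps.shape[:2]:
        raise ValueError("mask misaligned with asymmetry maps")
    sel = (label_map == code) & maps.qc_valid
    if not (label_map == code).any():
        raise ValueError(f"muscle mask {muscle!r} is empty")
    vox = maps.maps[sel]  # (n_vox, n_frames)
    finite = np.isfinite(vox)
    n = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(finite, vox, 0.0), axis=0), np.nan)
        mean = mean / np.where(n > 0, n, 1)
    keep = n > 0
    return RoiTimeSeries(
        muscle=muscle,
        times_s=maps.frame_times_s[keep],
        values_pct=mean[keep],
        n_voxels=n[keep],
    )


def resting_crcest(series: RoiTimeSeries, n_baseline: int = 5) -> float:
    """Mean CrCEST over the pre-exercise baseline frames."""
    baseline = series.baseline
    if baseline.size < n_baseline:
        raise ValueError(
            f"need {n_baseline} baseline frames, found {baseline.size}"
        )
    return float(np.mean(baseline[-n_baseline:]))


def delta_crcest(series: RoiTimeSeries, resting_pct: float) -> float:
    """CrCEST at the first post-exercise frame minus the resting level.

    Raises if the first post-exercise frame (t = 0) was dropped by QC: the
    exercise jump is defined at that frame and no silent substitute exists.
    """
    times, values = series.post
    if times.size == 0:
        raise ValueError("no post-exercise frames in series")
    # the first post-exercise frame is at t = 0 by convention
    if not np.isclose(times[0], 0.0, atol=1e-9):
        raise ValueError(
            "first post-exercise frame (t = 0) missing; ΔCrCEST undefined"
        )
    return float(values[0] - resting_pct)


def _initial_guess(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    asymptote = float(np.mean(values[-3:]))
    amp = float(values[0] - asymptote)
    tau = 100.0
    resid = values - asymptote
    pos = resid > 0
    if pos.sum() >= 2:
        # log-linear regression of log(v − asymptote) on t
        slope = np.polyfit(times[pos], np.log(resid[pos]), 1)[0]
        if slope < 0:
            tau = -1.0 / slope
    tau = float(np.clip(tau, *TAU_FIT_BOUNDS_S))
    return np.array([asymptote, amp, tau])


def fit_tau(series: RoiTimeSeries, muscle: str | None = None) -> KineticsFit:
    """Bounded least-squares fit of the post-exercise exponential decline.

    Only post-exercise frames enter the objective; dropped frames are
    simply absent (gaps are tolerated).  Returns status ``fit_failed``
    when the optimiser does not converge or the fitted amplitude is not
    positive; otherwise status ``ok`` (plausibility is applied separately
    by :func:`apply_plausibility_filter`).
    """
    times, values = series.post
    if times.size < 4:
        raise ValueError("need at least 4 post-exercise frames to fit τ")

    x0 = _initial_guess(times, values)

    def residual(p):
        asymptote, amp, tau = p
        return asymptote + amp * np.exp(-times / tau) - values

    lo = np.array([-np.inf, -np.inf, TAU_FIT_BOUNDS_S[0]])
    hi = np.array([np.inf, np.inf, TAU_FIT_BOUNDS_S[1]])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
    try:
        sol = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-12,
                            ftol=1e-12, gtol=1e-12)
    except Exception as exc:  # pragma: no cover - scipy failure path
        return KineticsFit(
            muscle=muscle or series.muscle,
            resting_pct=np.nan, delta_pct=np.nan, tau_s=np.nan,
            amp_pct=np.nan, asymptote_pct=np.nan, rss=np.nan,
            status="fit_failed", n_post_frames=int(times.size),
            diagnostics={"error": str(exc)},
        )
    asymptote, amp, tau = sol.x
    rss = float(np.sum(sol.fun**2))
    status = "ok"
    diagnostics = {"optimizer_status": int(sol.status),
                   "optimizer_message": sol.message}
    if not sol.success or amp <= 0:
        status = "fit_failed"
        diagnostics["reason"] = (
            "non-convergence" if not sol.success else "non-positive amplitude"
        )
    return KineticsFit(
        muscle=muscle or series.muscle,
        resting_pct=np.nan,
        delta_pct=np.nan,
        tau_s=float(tau),
        amp_pct=float(amp),
        asymptote_pct=float(asymptote),
        rss=rss,
        status=status,
        n_post_frames=int(times.size),
        diagnostics=diagnostics,
    )


def apply_plausibility_filter(
    fit: KineticsFit,
    lo_s: float = TAU_PLAUSIBLE_LO_S,
    hi_s: float = TAU_PLAUSIBLE_HI_S,
) -> KineticsFit:
    """Flag implausible τCr estimates; retained fits pass unchanged.

    Idempotent: re-applying with the same bounds never changes the status
    of an already-classified fit.
    """
    if lo_s >= hi_s:
        raise ValueError("plausibility bounds must satisfy lo < hi")
    if fit.status == "fit_failed":
        return fit
    if fit.tau_s < lo_s:
        status = "excluded_low"
    elif fit.tau_s > hi_s:
        status = "excluded_high"
    else:
        status = "ok"
    return replace(fit, status=status)


def analyze_roi(
    series: RoiTimeSeries,
    n_baseline: int = 5,
    lo_s: float = TAU_PLAUSIBLE_LO_S,
    hi_s: float = TAU_PLAUSIBLE_HI_S,
) -> KineticsFit:
    """All three endpoints plus plausibility status for one ROI series."""
    resting = resting_crcest(series, n_baseline)
    delta = delta_crcest(series, resting)
    fit = fit_tau(series)
    fit = apply_plausibility_filter(fit, lo_s, hi_s)
    return replace(fit, resting_pct=resting, delta_pct=delta)


class CrRecoveryModel:
    """Statsmodels-style wrapper: recovery model for one ROI series.

    Examples
    --------
    >>> model = CrRecoveryModel(series, n_baseline=5)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, series: RoiTimeSeries, n_baseline: int = 5,
                 plausibility_s: tuple[float, float] = (TAU_PLAUSIBLE_LO_S,
                                                        TAU_PLAUSIBLE_HI_S)):
        self.series = series
        self.n_baseline = n_baseline
        self.plausibility_s = plausibility_s

    def fit(self) -> KineticsFit:
        return analyze_roi(self.series, self.n_baseline, *self.plausibility_s)

    def predict(self, fit: KineticsFit, times_s: np.ndarray) -> np.ndarray:
        """Model curve at arbitrary post-exercise times."""
        t = np.asarray(times_s, dtype=float)
        return fit.asymptote_pct + fit.amp_pct * np.exp(-t / fit.tau_s)
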