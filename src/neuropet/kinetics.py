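"""Dynamic PET tracer-kinetic modelling for an irreversibly trapped tracer.

Three routes to the net irreversible uptake rate are implemented, matching
how short-chain fatty-acid PET data are analysed at region level:

* standard Patlak graphical analysis — OLS on the transformed coordinates
  ``x = int_0^t Cp / Cp`` and ``y = C_t / Cp`` for frames past ``t*``, whose
  slope is Ki;
* a generalized (Patlak–Blasberg) regression adding an efflux/loss
  regressor, the "modified Patlak" variant;
* full nonlinear fitting of the irreversible two-tissue compartment model
  (rate constants K1, k2, k3; k4 = 0; fractional blood volume vb), whose
  macro constant is ``Ki = K1 k3 / (k2 + k3)``.

The plasma input is a population-shaped curve scaled to an image-derived
whole-blood curve from the superior sagittal sinus; the blood-volume term
multiplies whole blood, modelling signal contamination of the tissue voxel.
Estimators follow scikit-learn conventions (``fit`` + trailing-underscore
attributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .imaging import FrameSchedule, TimeActivityCurve

__all__ = [
    "InputFunction",
    "scale_population_input",
    "two_tissue_curve",
    "frame_average",
    "PatlakModel",
    "TwoTissueModel",
    "patlak_standard",
    "patlak_modified",
    "fit_2tcm",
]


@dataclass
class InputFunction:
    """Blood/plasma tracer concentration on a fine time grid (minutes).

    ``cp`` is the plasma concentration driving the compartment model and
    ``cb`` the whole-blood concentration contaminating the tissue voxel;
    they are related by a single configurable plasma-to-whole-blood ratio.
    """

    time_min: np.ndarray
    cb: np.ndarray
    plasma_to_blood_ratio: float = 1.0
    provenance: str = "synthetic"

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        if self.time_min.shape != self.cb.shape:
            raise ValueError("time and cb must have equal length")
        if np.any(self.cb < -1e-12):
            raise ValueError("blood curve must be nonnegative")

    @property
    def cp(self) -> np.ndarray:
        return self.cb * self.plasma_to_blood_ratio

    def cb_at(self, t) -> np.ndarray:
        return np.interp(t, self.time_min, self.cb, left=0.0)

    def cp_at(self, t) -> np.ndarray:
        return np.interp(t, self.time_min, self.cp, left=0.0)

    def cumulative_cp(self, t) -> np.ndarray:
        """``int_0^t Cp dtau`` by trapezoid on the fine grid, interpolated."""
        from scipy.integrate import cumulative_trapezoid

        cum = cumulative_trapezoid(self.cp, self.time_min, initial=0.0)
        return np.interp(t, self.time_min, cum)


def scale_population_input(
    population: InputFunction,
    blood_tac: TimeActivityCurve,
    window: tuple = (0.0, np.inf),
) -> InputFunction:
    """Scale a population input shape to an image-derived blood TAC.

    A single multiplicative factor matches the trapezoidal AUC of the
    population shape to the AUC of the measured sagittal-sinus curve over
    ``window`` (minutes).
    """
    lo, hi = window
    sel = (blood_tac.time_min >= lo) & (blood_tac.time_min <= hi)
    if sel.sum() < 2:
        raise ValueError("normalisation window contains fewer than 2 samples")
    t = blood_tac.time_min[sel]
    auc_blood = np.trapezoid(blood_tac.value[sel], t)
    auc_pop = np.trapezoid(population.cb_at(t), t)
    if auc_pop <= 0 or auc_blood <= 0:
        raise ValueError("zero AUC in normalisation window")
    scale = auc_blood / auc_pop
    return InputFunction(
        population.time_min,
        population.cb * scale,
        plasma_to_blood_ratio=population.plasma_to_blood_ratio,
        provenance="population-scaled",
    )


# ---------------------------------------------------------------------------
# Forward model


def two_tissue_curve(
    t_fine: np.ndarray,
    cp_fine: np.ndarray,
    cb_fine: np.ndarray,
    k1: float,
    k2: float,
    k3: float,
    vb: float,
) -> np.ndarray:
    """Irreversible 2TCM tissue curve on a fine uniform grid.

    ``C_t = (1 - vb) * h(t) (*) Cp + vb * Cb`` with impulse response
    ``h(t) = K1 [k3/(k2+k3) + k2/(k2+k3) exp(-(k2+k3) t)]`` (k4 = 0).
    """
    if min(k1, k2, k3) < 0 or vb < 0:
        raise ValueError("rate constants and vb must be nonnegative")
    from scipy.signal import fftconvolve

    dt = t_fine[1] - t_fine[0]
    s = k2 + k3
    if s > 0:
        h = k1 * (k3 / s + (k2 / s) * np.exp(-s * t_fine))
    else:
        h = np.full_like(t_fine, k1)
    # trapezoid-weighted discrete convolution (half weights at both ends)
    tissue = (fftconvolve(h, cp_fine)[: t_fine.size]
              - 0.5 * (h[0] * cp_fine + cp_fine[0] * h)) * dt
    return (1.0 - vb) * tissue + vb * cb_fine


def frame_average(t_fine: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval of the schedule.

    Uses the cumulative trapezoidal integral of the fine-grid curve, so the
    average over ``[a, b]`` is ``(F(b) - F(a)) / (b - a)`` with ``F``
    linearly interpolated between grid nodes.
    """
    from scipy.integrate import cumulative_trapezoid

    start = schedule.frame_start / 60.0
    end = (schedule.frame_start + schedule.frame_duration) / 60.0
    cum = cumulative_trapezoid(curve, t_fine, initial=0.0)
    fa = np.interp(start, t_fine, cum)
    fb = np.interp(end, t_fine, cum)
    return (fb - fa) / (end - start)


def _fine_grid(end_min: float, dt_min: float) -> np.ndarray:
    n = int(round(end_min / dt_min)) + 1
    return np.arange(n) * dt_min


# ---------------------------------------------------------------------------
# Patlak graphical analysis


@dataclass
class PatlakResult:
    ki: float
    v0: float
    t_star: float
    r_squared: float
    variant: str
    k_loss: float = 0.0
    n_points: int = 0


class PatlakModel(BaseEstimator):
    """Patlak graphical analysis of an irreversibly trapped tracer.

    Parameters
    ----------
    t_star : float
        Equilibration time in minutes; only frames with mid-time >= t_star
        enter the regression.
    variant : {"standard", "modified"}
        ``standard`` fits ``y = ki x + v0``; ``modified`` adds the
        Patlak–Blasberg efflux regressor ``-int_0^t C_t / Cp`` whose
        coefficient is the loss rate ``k_loss``.
    vb : float
        Whole-blood correction: when a blood-volume fraction is known (or
        assumed), the blood contribution is removed first,
        ``C_corr = (C_t - vb Cb) / (1 - vb)``, so the slope estimates Ki
        itself rather than ``(1 - vb) Ki``.  Default 0 (no correction).
    """

    def __init__(self, t_star: float = 20.0, variant: str = "standard",
                 vb: float = 0.0):
        self.t_star = t_star
        self.variant = variant
        self.vb = vb

    def fit(self, tac: TimeActivityCurve, input_function: InputFunction):
        if self.variant not in ("standard", "modified"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0 <= self.vb < 1:
            raise ValueError("vb must be in [0, 1)")
        t = tac.time_min
        ct = tac.value
        if self.vb > 0:
            ct = (ct - self.vb * input_function.cb_at(t)) / (1.0 - self.vb)
        if not np.all(np.isfinite(ct)):
            raise ValueError("TAC contains non-finite values")
        sel = t >= self.t_star
        if sel.sum() < 3:
            raise ValueError("need at least 3 frames past t_star")
        t_sel, ct_sel = t[sel], ct[sel]
        cp = input_function.cp_at(t_sel)
        if np.any(cp <= 0):
            raise ValueError("plasma input is zero at an included frame")
        x = input_function.cumulative_cp(t_sel) / cp
        y = ct_sel / cp
        if self.variant == "standard":
            design = np.column_stack([x, np.ones_like(x)])
        else:
            from scipy.integrate import cumulative_trapezoid

            # integral of the tissue curve from time zero, on the frame grid
            cum_ct = cumulative_trapezoid(
                np.concatenate([[0.0], ct]), np.concatenate([[0.0], t]), initial=0.0
            )[1:]
            design = np.column_stack([x, np.ones_like(x), -cum_ct[sel] / cp])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        self.collinear_ = rank < design.shape[1]
        resid = y - design @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        self.ki_ = float(coef[0])
        self.v0_ = float(coef[1])
        self.k_loss_ = float(coef[2]) if self.variant == "modified" else 0.0
        self.r_squared_ = float(min(max(r2, 0.0), 1.0))
        self.n_points_ = int(sel.sum())
        self.result_ = PatlakResult(
            self.ki_, self.v0_, self.t_star, self.r_squared_, self.variant,
            self.k_loss_, self.n_points_,
        )
        return self


def patlak_standard(tac, input_function, t_star: float = 20.0) -> PatlakResult:
    return PatlakModel(t_star=t_star, variant="standard").fit(tac, input_function).result_


def patlak_modified(tac, input_function, t_star: float = 20.0) -> PatlakResult:
    return PatlakModel(t_star=t_star, variant="modified").fit(tac, input_function).result_


# ---------------------------------------------------------------------------
# Irreversible two-tissue compartment model


@dataclass
class TcmResult:
    k1: float
    k2: float
    k3: float
    vb: float
    ki_macro: float
    residual_norm: float
    converged: bool


#: Documented multi-start lattice (K1, k2, k3, vb).
DEFAULT_STARTS = (
    (0.05, 0.10, 0.01, 0.03),
    (0.01, 0.05, 0.005, 0.01),
    (0.20, 0.30, 0.05, 0.05),
    (0.10, 0.50, 0.10, 0.02),
    (0.50, 1.00, 0.02, 0.10),
)


class TwoTissueModel(BaseEstimator):
    """Nonlinear fit of the irreversible 2TCM to a frame-averaged TAC.

    Bounds: K1, k2, k3 in [0, 5]; vb in [0, 0.2].  Five documented starting
    points are tried and the best-residual solution kept.  The model
    prediction is frame-averaged over each frame interval when a schedule
    is supplied, matching how reconstructed PET frames integrate activity.
    """

    def __init__(self, dt_min: float = 1.0 / 60.0, starts=DEFAULT_STARTS,
                 bounds=((0.0, 0.0, 0.0, 0.0), (5.0, 5.0, 5.0, 0.2))):
        self.dt_min = dt_min
        self.starts = starts
        self.bounds = bounds

    def fit(self, tac: TimeActivityCurve, input_function: InputFunction,
            schedule: FrameSchedule | None = None):
        ct = tac.value
        if not np.all(np.isfinite(ct)):
            raise ValueError("TAC contains non-finite values")
        end = schedule.end_time_min if schedule is not None else tac.time_min[-1]
        t_fine = _fine_grid(end, self.dt_min)
        cp_fine = input_function.cp_at(t_fine)
        cb_fine = input_function.cb_at(t_fine)

        def predict(params):
            curve = two_tissue_curve(t_fine, cp_fine, cb_fine, *params)
            if schedule is not None:
                return frame_average(t_fine, curve, schedule)
            return np.interp(tac.time_min, t_fine, curve)

        def residuals(params):
            return predict(params) - ct

        best = None
        any_ok = False
        for start in self.starts:
            x0 = np.clip(start, self.bounds[0], self.bounds[1])
            try:
                sol = least_squares(residuals, x0, bounds=self.bounds,
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            any_ok = any_ok or sol.success
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimisation starts failed")
        k1, k2, k3, vb = best.x
        self.k1_, self.k2_, self.k3_, self.vb_ = map(float, (k1, k2, k3, vb))
        self.ki_macro_ = float(k1 * k3 / (k2 + k3)) if (k2 + k3) > 0 else 0.0
        self.residual_norm_ = float(np.sqrt(2.0 * best.cost))
        self.converged_ = bool(any_ok)
        self.result_ = TcmResult(
            self.k1_, self.k2_, self.k3_, self.vb_, self.ki_macro_,
            self.residual_norm_, self.converged_,
        )
        return self

    def predict(self, tac, input_function, schedule=None) -> np.ndarray:
        end = schedule.end_time_min if schedule is not None else tac.time_min[-1]
        t_fine = _fine_grid(end, self.dt_min)
        curve = two_tissue_curve(
            t_fine, input_function.cp_at(t_fine), input_function.cb_at(t_fine),
            self.k1_, self.k2_, self.k3_, self.vb_,
        )
        if schedule is not None:
            return frame_average(t_fine, curve, schedule)
        return np.interp(tac.time_min, t_fine, curve)


def fit_2tcm(tac, input_function, schedule=None, **kwargs) -> TcmResult:
    return TwoTissueModel(**kwargs).fit(tac, input_function, schedule).result_
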