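"""Irreversible two-tissue compartment model (2TCM) for FDG.

The model has a free-tracer compartment C1 and a trapped (phosphorylated)
compartment C2::

    dC1/dt = K1*Cp - (k2 + k3)*C1
    dC2/dt = k3*C1

with plasma input Cp and rate constants K1 (influx, mL·min⁻¹·mL⁻¹),
k2 (efflux, min⁻¹) and k3 (phosphorylation, min⁻¹); dephosphorylation is
neglected (k4 = 0).  The measured concentration is
``Cmodel = (1 - vB)*(C1 + C2) + vB*Cp`` with blood-volume fraction vB.

The net metabolic flux (influx macro-parameter) is
``Ki = K1*k3/(k2 + k3)`` — the model-based analogue of the Patlak slope.

The forward solution is evaluated through the analytic impulse response

    h(t) = (K1/(k2 + k3)) * [k3 + k2*exp(-(k2 + k3)*t)]

convolved with Cp on a uniform fine grid (default 0.5 s) using exact
piecewise-linear integration of the input, then averaged over the
acquisition frames.  All rate constants are per minute; frame schedules are
in seconds (see :mod:`epikinet.acquisition`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .acquisition import SECONDS_PER_MINUTE, FrameSchedule

__all__ = [
    "TwoTCMParams",
    "PlasmaInput",
    "TissueTAC",
    "FitResult",
    "FitConfig",
    "compute_ki",
    "forward_2tcm",
    "fit_2tcm",
]

DEFAULT_GRID_STEP_S = 0.5


def compute_ki(K1: float, k2: float, k3: float) -> float:
    """Net metabolic flux Ki = K1*k3/(k2 + k3).

    Defined as 0 when k2 + k3 == 0 (no exchange, limit choice).  Negative
    rate constants are a domain error.
    """
    if K1 < 0 or k2 < 0 or k3 < 0:
        raise ValueError("rate constants must be nonnegative")
    denom = k2 + k3
    if denom == 0:
        return 0.0
    return K1 * k3 / denom


@dataclass(frozen=True)
class TwoTCMParams:
    """Micro-parameters of the irreversible 2TCM; Ki is derived."""

    K1: float  # mL·min⁻¹·mL⁻¹
    k2: float  # min⁻¹
    k3: float  # min⁻¹
    vB: float = 0.0  # blood-volume fraction, [0, 1)

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate constants must be nonnegative")
        if not 0 <= self.vB < 1:
            raise ValueError("vB must be in [0, 1)")

    @property
    def Ki(self) -> float:
        return compute_ki(self.K1, self.k2, self.k3)

    def as_dict(self) -> dict[str, float]:
        return {"K1": self.K1, "k2": self.k2, "k3": self.k3, "vB": self.vB, "Ki": self.Ki}


@dataclass(frozen=True)
class PlasmaInput:
    """Metabolite-free plasma input curve.

    Piecewise-linear between samples, zero before the first sample, constant
    beyond the last (the hold only matters within the final half frame when
    the curve comes from frame-based carotid sampling).

    Parameters
    ----------
    times_min
        Sample times in minutes, strictly increasing.
    values
        Concentrations in kBq/mL, nonnegative.
    """

    times_min: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or len(t) < 2:
            raise ValueError("need matching 1-D time/value arrays with >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("concentrations must be finite")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t_min) -> np.ndarray:
        return np.interp(t_min, self.times_min, self.values, left=0.0, right=self.values[-1])

    @classmethod
    def from_function(cls, fn, t_end_min: float, step_min: float = DEFAULT_GRID_STEP_S / 60.0) -> "PlasmaInput":
        """Sample a continuous curve densely onto an input object."""
        t = np.arange(0.0, t_end_min + step_min / 2, step_min)
        return cls(times_min=t, values=np.asarray(fn(t), dtype=float))

    def covers(self, schedule: FrameSchedule) -> bool:
        return self.times_min[-1] >= schedule.mids_min[-1] - 1e-9

    def scaled(self, a: float) -> "PlasmaInput":
        return PlasmaInput(self.times_min, self.values * a)


@dataclass(frozen=True)
class TissueTAC:
    """Frame-averaged activity concentration for one VOI."""

    schedule: FrameSchedule
    values: np.ndarray
    voi_id: str = ""
    side: str = ""  # ipsilateral | contralateral | left | right

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != self.schedule.n_frames:
            raise ValueError("value count does not match the frame schedule")
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC values must be finite")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _fine_grid_min(schedule: FrameSchedule, grid_step_s: float) -> np.ndarray:
    h = grid_step_s / SECONDS_PER_MINUTE
    t_end = schedule.total_duration / SECONDS_PER_MINUTE
    n = int(round(t_end / h))
    return np.linspace(0.0, n * h, n + 1)


def _convolve_2tcm(K1: float, k2: float, k3: float, cp: np.ndarray, h_min: float,
                   with_cumulative: bool = False):
    """C1(t) + C2(t) for piecewise-linear Cp sampled at uniform step h_min.

    Exact for a piecewise-linear input: the running input integral Q is the
    trapezoid (exact), and the exponential convolution
    ``y(t) = int Cp(s) exp(-beta*(t-s)) ds`` uses the closed-form segment
    integral propagated by the one-step recursion
    ``y[i+1] = exp(-beta*h)*y[i] + increment[i]`` (evaluated by lfilter).

    With ``with_cumulative`` also returns the exact running integrals of Cp
    and of C1+C2, from which frame averages follow without quadrature error:
    the cumulative of Q is per-segment quadratic (closed form) and
    ``int_0^t y = (Q(t) - y(t))/beta`` by integrating y's own ODE.
    """
    beta = k2 + k3
    seg = (cp[:-1] + cp[1:]) * (h_min / 2.0)
    Q = np.concatenate([[0.0], np.cumsum(seg)])
    if with_cumulative:
        # cumulative integral of the piecewise-quadratic Q
        segR = Q[:-1] * h_min + h_min ** 2 * (2.0 * cp[:-1] + cp[1:]) / 6.0
        R = np.concatenate([[0.0], np.cumsum(segR)])
    if beta < 1e-8:
        # k2 = k3 = 0 limit: pure accumulation of influx
        return (K1 * Q, K1 * R, Q) if with_cumulative else K1 * Q
    x = beta * h_min
    E = np.exp(-x)
    if x > 1e-4:
        I0 = -np.expm1(-x) / beta
        I1h = (1.0 / beta) * (1.0 - (1.0 - E) / x)
    else:  # series to avoid cancellation at tiny beta*h
        I0 = h_min * (1.0 - x / 2.0 + x * x / 6.0 - x ** 3 / 24.0)
        I1h = h_min * (0.5 - x / 6.0 + x * x / 24.0)
    b = cp[:-1] * (I0 - I1h) + cp[1:] * I1h
    y = np.empty_like(cp)
    y[0] = 0.0
    y[1:] = lfilter([1.0], [1.0, -E], b)
    tissue = K1 * ((k3 / beta) * Q + (k2 / beta) * y)
    if not with_cumulative:
        return tissue
    S = K1 * ((k3 / beta) * R + (k2 / beta) * (Q - y) / beta)
    return tissue, S, Q


def _model_frame_values(K1: float, k2: float, k3: float, vB: float,
                        cp: np.ndarray, t_min: np.ndarray,
                        schedule: FrameSchedule) -> np.ndarray:
    """Exact frame averages of (1-vB)*(C1+C2) + vB*Cp for piecewise-linear Cp."""
    h = t_min[1] - t_min[0]
    _, S, Q = _convolve_2tcm(K1, k2, k3, cp, h, with_cumulative=True)
    M = (1.0 - vB) * S + vB * Q
    starts = schedule.starts_min
    ends = starts + schedule.durations_min
    return (np.interp(ends, t_min, M) - np.interp(starts, t_min, M)) / schedule.durations_min


def _frame_average_fine(curve: np.ndarray, t_min: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a piecewise-linear fine-grid curve over each frame.

    The cumulative trapezoid is exact for a piecewise-linear curve, which is
    the representation contract of sampled input functions.
    """
    h = t_min[1] - t_min[0]
    Q = np.concatenate([[0.0], np.cumsum((curve[:-1] + curve[1:]) * (h / 2.0))])
    starts = schedule.starts_min
    ends = starts + schedule.durations_min
    q_start = np.interp(starts, t_min, Q)
    q_end = np.interp(ends, t_min, Q)
    return (q_end - q_start) / schedule.durations_min


def forward_2tcm(
    params: TwoTCMParams,
    input_fn: PlasmaInput,
    schedule: FrameSchedule,
    grid_step_s: float = DEFAULT_GRID_STEP_S,
    voi_id: str = "",
    side: str = "",
) -> TissueTAC:
    """Frame-averaged model TAC for the given parameters and input."""
    if not input_fn.covers(schedule):
        raise ValueError("plasma input does not cover the frame schedule")
    t = _fine_grid_min(schedule, grid_step_s)
    cp = input_fn(t)
    values = _model_frame_values(params.K1, params.k2, params.k3, params.vB,
                                 cp, t, schedule)
    return TissueTAC(schedule=schedule, values=values, voi_id=voi_id, side=side)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Settings of the bounded weighted nonlinear least-squares fit.

    Bounds are physiological FDG ranges; the weighting default (frame
    duration) approximates uniform variance rate across the scan.  vB is
    fixed at 0 by default (the classic three-parameter brain fit) and can be
    freed with ``fit_vb=True``.
    """

    bounds_K1: tuple[float, float] = (0.0, 1.0)
    bounds_k2: tuple[float, float] = (0.0, 2.0)
    bounds_k3: tuple[float, float] = (0.0, 1.0)
    bounds_vB: tuple[float, float] = (0.0, 0.2)
    fit_vb: bool = False
    vb_fixed: float = 0.0
    weights: str = "duration"  # duration | uniform | duration_sq_over_activity
    n_starts: int = 5
    seed: int = 0
    grid_step_s: float = DEFAULT_GRID_STEP_S


@dataclass(frozen=True)
class FitResult:
    params: TwoTCMParams
    wrss: float
    stderr: dict[str, float]
    converged: bool
    n_restarts_used: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "wrss": self.wrss,
            "stderr": self.stderr,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "degenerate": self.degenerate,
        }


def _fit_weights(tac: TissueTAC, scheme: str) -> np.ndarray:
    d = tac.schedule.durations
    if scheme == "uniform":
        w = np.ones_like(d)
    elif scheme == "duration":
        w = d / d.mean()
    elif scheme == "duration_sq_over_activity":
        act = np.maximum(np.abs(tac.values), 1e-3 * np.abs(tac.values).max() + 1e-12)
        w = d ** 2 / act
        w = w / w.mean()
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return w


def fit_2tcm(tac: TissueTAC, input_fn: PlasmaInput, config: FitConfig | None = None) -> FitResult:
    """Fit (K1, k2, k3[, vB]) to a frame-averaged TAC.

    Minimizes the duration-weighted residual sum of squares with bounded
    trust-region least squares and seeded multi-starts; deterministic given
    ``config.seed``.  Non-convergence is flagged, never silent.
    """
    cfg = config or FitConfig()
    if tac.schedule.n_frames < 8:
        raise ValueError("need at least 8 frames to fit the 2TCM")
    if not input_fn.covers(tac.schedule):
        raise ValueError("plasma input does not cover the frame schedule")

    names = ["K1", "k2", "k3"] + (["vB"] if cfg.fit_vb else [])
    lo = np.array([cfg.bounds_K1[0], cfg.bounds_k2[0], cfg.bounds_k3[0]] +
                  ([cfg.bounds_vB[0]] if cfg.fit_vb else []))
    hi = np.array([cfg.bounds_K1[1], cfg.bounds_k2[1], cfg.bounds_k3[1]] +
                  ([cfg.bounds_vB[1]] if cfg.fit_vb else []))

    w = _fit_weights(tac, cfg.weights)
    sqrt_w = np.sqrt(w)

    t = _fine_grid_min(tac.schedule, cfg.grid_step_s)
    cp = input_fn(t)
    h = t[1] - t[0]

    def model_frames(x: np.ndarray) -> np.ndarray:
        vB = x[3] if cfg.fit_vb else cfg.vb_fixed
        return _model_frame_values(x[0], x[1], x[2], vB, cp, t, tac.schedule)

    def residuals(x: np.ndarray) -> np.ndarray:
        return sqrt_w * (tac.values - model_frames(x))

    if np.allclose(tac.values, 0.0):
        params = TwoTCMParams(K1=lo[0], k2=lo[1], k3=lo[2],
                              vB=(lo[3] if cfg.fit_vb else cfg.vb_fixed))
        return FitResult(params=params, wrss=float(np.sum(residuals(lo) ** 2)),
                         stderr={n: float("nan") for n in names},
                         converged=True, n_restarts_used=0, degenerate=True)

    rng = np.random.default_rng(cfg.seed)
    # heuristic first start in the physiological interior, then seeded draws
    starts = [np.array([0.1, 0.12, 0.06] + ([0.03] if cfg.fit_vb else []))]
    for _ in range(max(cfg.n_starts - 1, 0)):
        starts.append(lo + (hi - lo) * rng.uniform(0.05, 0.6, size=len(lo)))

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                            method="trf", x_scale=np.maximum(np.abs(x0), 1e-3),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        if best is None or res.cost < best.cost - 1e-15:
            best = res

    x = best.x
    vB = x[3] if cfg.fit_vb else cfg.vb_fixed
    params = TwoTCMParams(K1=float(x[0]), k2=float(x[1]), k3=float(x[2]), vB=float(vB))
    wrss = float(2.0 * best.cost)

    # standard errors from the Gauss-Newton curvature at the optimum
    stderr = {n: float("nan") for n in names}
    dof = tac.schedule.n_frames - len(x)
    if dof > 0:
        try:
            JTJ = best.jac.T @ best.jac
            cov = np.linalg.inv(JTJ) * (wrss / dof)
            for i, n in enumerate(names):
                stderr[n] = float(np.sqrt(max(cov[i, i], 0.0)))
        except np.linalg.LinAlgError:
            pass

    return FitResult(params=params, wrss=wrss, stderr=stderr,
                     converged=bool(best.success), n_restarts_used=n_used)
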