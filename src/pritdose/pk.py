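"""One-phase exponential-decay kinetics for tissue time-activity curves.

Tumor activity after a pretargeted radiohapten injection follows a one-phase
decay: an initial washout toward a sustained plateau of specifically bound
tracer,

    A(t) = (A0 - P) * exp(-lambda_b * t) + P,      lambda_b = ln2 / T_half_bio

with A0 the back-extrapolated %ID/g at t = 0, P the plateau (%ID/g) and
T_half_bio the biological half-life (hours).  Normal tissues are modelled as
the plateau-free special case (mono-exponential washout).  All values here
are decay-corrected, i.e. purely biological; physical decay of the nuclide is
applied analytically in the dosimetry layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .biodist import GroupSummary
from .errors import FitError, InsufficientDataError, UndefinedStatisticError, ValidationError

LN2 = math.log(2.0)

#: Relative parameter-change convergence tolerance of the fitter.
FIT_XTOL = 1e-10


@dataclass(frozen=True)
class OnePhaseDecayFit:
    """Fitted (or assumed) one-phase-decay kinetic parameters for one tissue.

    A0 is span + plateau, i.e. the curve value at t = 0.  For washout curves
    A0 >= plateau >= 0 holds; r_squared is 1 - SSres/SStot on the fitted
    observations and is None for parameter sets that were not fitted to data.
    """

    A0: float
    plateau: float
    t_half_bio_h: float
    r_squared: float | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if self.plateau < 0:
            raise ValidationError(f"plateau must be >= 0, got {self.plateau}")
        if self.t_half_bio_h <= 0:
            raise ValidationError(f"t_half_bio_h must be > 0, got {self.t_half_bio_h}")

    @property
    def lambda_bio_per_h(self) -> float:
        return LN2 / self.t_half_bio_h

    @property
    def span(self) -> float:
        return self.A0 - self.plateau

    def __call__(self, t_h: float | np.ndarray) -> float | np.ndarray:
        return predict(self, t_h)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OnePhaseDecayFit":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "OnePhaseDecayFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


def exp_washout(A0: float, t_half_bio_h: float) -> OnePhaseDecayFit:
    """Mono-exponential washout: a one-phase decay with plateau fixed at 0."""
    return OnePhaseDecayFit(A0=A0, plateau=0.0, t_half_bio_h=t_half_bio_h)


def predict(fit: OnePhaseDecayFit, t_h: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the one-phase decay curve at t_h >= 0 hours."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t_h must be >= 0")
    out = (fit.A0 - fit.plateau) * np.exp(-fit.lambda_bio_per_h * t) + fit.plateau
    return float(out) if np.isscalar(t_h) or t.ndim == 0 else out


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    Convention for constant observations (SStot = 0): R^2 = 1 when the
    residuals are also zero (perfect fit of a constant), otherwise the
    statistic is undefined and :class:`UndefinedStatisticError` is raised.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise InsufficientDataError("observed and predicted must have equal length >= 2")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        if ss_res <= 1e-24 * max(1.0, float(np.sum(obs**2))):
            return 1.0
        raise UndefinedStatisticError("R^2 undefined: constant observations with nonzero residuals")
    return 1.0 - ss_res / ss_tot


def _as_points(
    data: Sequence[GroupSummary] | tuple[Sequence[float], Sequence[float]],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        t, y = np.asarray(data[0], float), np.asarray(data[1], float)
    else:
        t = np.array([s.time_h for s in data], float)
        y = np.array([s.mean_pct_id_g for s in data], float)
    order = np.argsort(t, kind="stable")
    return t[order], y[order]


def _initial_guesses(t: np.ndarray, y: np.ndarray, plateau_candidates: Sequence[float]):
    """Deterministic multi-start schedule: A0 = first observation, plateau in
    {0, last observation}, T_half from a log-linear regression of (y - P)."""
    guesses = []
    a0 = float(y[0])
    for p in plateau_candidates:
        resid = y - p
        mask = resid > 0
        if mask.sum() >= 2:
            slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
            t_half = LN2 / -slope if slope < 0 else float(t[-1] - t[0])
        else:
            t_half = float(t[-1] - t[0])
        t_half = min(max(t_half, 1e-3), 1e6)
        guesses.append((max(a0, p + 1e-9), p, t_half))
    return guesses


def fit_one_phase_decay(
    data: Sequence[GroupSummary] | tuple[Sequence[float], Sequence[float]],
    *,
    fix_plateau: float | None = None,
) -> OnePhaseDecayFit:
    """Least-squares fit of the one-phase decay model to (time, %ID/g) points.

    ``data`` is either a sequence of GroupSummary (fit on per-timepoint means,
    the default study usage) or a ``(times, values)`` pair of raw points.
    Constraints plateau >= 0 and T_half_bio > 0 are enforced via bounds; a
    deterministic multi-start schedule guards against local minima on sparse
    4-point designs.  ``fix_plateau`` pins the plateau (e.g. 0 for a pure
    washout).  Raises :class:`InsufficientDataError` with fewer distinct
    timepoints than parameters, :class:`FitError` on non-convergence.
    """
    t, y = _as_points(data)
    n_distinct = np.unique(t).size
    n_params = 2 if fix_plateau is not None else 3
    if n_distinct < max(n_params, 3):
        raise InsufficientDataError(
            f"need >= {max(n_params, 3)} distinct timepoints, got {n_distinct}"
        )

    # Constant data: span ~ 0, plateau at the common value.
    if np.allclose(y, y[0], rtol=0, atol=1e-12 * max(1.0, abs(float(y[0])))):
        plateau = float(y[0]) if fix_plateau is None else fix_plateau
        pred = np.full_like(y, plateau)
        ss_res = float(np.sum((y - pred) ** 2))
        r2 = 1.0 if ss_res == 0.0 else None
        return OnePhaseDecayFit(
            A0=float(y[0]), plateau=plateau, t_half_bio_h=float(t[-1] - t[0]) or 1.0,
            r_squared=r2, n_points=int(y.size),
        )

    if fix_plateau is not None:
        plateau_candidates = [fix_plateau]
    else:
        plateau_candidates = [0.0, float(y[-1])]

    scale = max(float(np.max(np.abs(y))), 1e-12)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a0, p, t_half = theta
        lam = LN2 / t_half
        return (a0 - p) * np.exp(-lam * t) + p - y

    best = None
    for a0_0, p_0, th_0 in _initial_guesses(t, y, plateau_candidates):
        if fix_plateau is not None:
            def resid2(theta: np.ndarray) -> np.ndarray:
                return residuals(np.array([theta[0], fix_plateau, theta[1]]))

            sol = least_squares(
                resid2, x0=[a0_0, th_0],
                bounds=([0.0, 1e-9], [np.inf, np.inf]),
                xtol=FIT_XTOL, ftol=1e-15, gtol=1e-15,
            )
            theta = np.array([sol.x[0], fix_plateau, sol.x[1]])
        else:
            sol = least_squares(
                residuals, x0=[a0_0, p_0, th_0],
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                xtol=FIT_XTOL, ftol=1e-15, gtol=1e-15,
            )
            theta = sol.x
        cost = float(np.sum(residuals(theta) ** 2))
        if best is None or cost < best[0]:
            best = (cost, theta, sol.success)

    assert best is not None
    cost, theta, success = best
    if not success and cost > (1e-3 * scale) ** 2 * y.size:
        raise FitError("one-phase decay fit did not converge", best_residual=cost)

    a0, p, t_half = (float(v) for v in theta)
    pred = (a0 - p) * np.exp(-LN2 / t_half * t) + p
    try:
        r2 = r_squared(y, pred)
    except UndefinedStatisticError:
        r2 = None
    return OnePhaseDecayFit(
        A0=a0, plateau=p, t_half_bio_h=t_half, r_squared=r2, n_points=int(y.size)
    )
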