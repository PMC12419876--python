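"""Fitting the stiffness ratio β and sensitivity sweeps.

The only unmeasured mechanical parameter of the beam model is the
pedicle-to-base stiffness ratio β = Ep/Eb.  Given the measured force
ratios Fap/Fas and Fan/Fas (positive and negative pulls against straight),
β is fitted by least squares in log10 space — the two ratios differ by an
order of magnitude, and log-space keeps them on an equal footing.  The
optimiser is deterministic: a coarse log-spaced grid over the search
interval followed by golden-section refinement.

Sensitivity sweeps vary the pedicle radius c or the attachment-site radius
r (with the width tied as w = 1.6·r) and track the directional asymmetry
ratio Fap/Fan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .beam_mechanics import PullScenario, force_ratio_approx
from .section_geometry import MorphParams

__all__ = [
    "ExperimentalRatios",
    "PredictedRatios",
    "FitResult",
    "predict_ratios",
    "fit_beta",
    "sweep_parameter",
    "propagate_errors",
]

#: Width-to-radius scaling used in the r sensitivity sweep.
W_OVER_R = 1.6


@dataclass(frozen=True)
class ExperimentalRatios:
    """Measured abscission-force ratios (medians of force populations)."""

    fap_fas: float = 0.005
    fan_fas: float = 0.03
    source: str = "sideways pull experiment medians"

    def __post_init__(self) -> None:
        if not (self.fap_fas > 0 and self.fan_fas > 0):
            raise ValueError("force ratios must be positive")


@dataclass(frozen=True)
class PredictedRatios:
    """Model force ratios at one parameter set, with validity warnings."""

    fap_fas: float
    fan_fas: float
    fap_fan: float
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "fap_fas": self.fap_fas,
            "fan_fas": self.fan_fas,
            "fap_fan": self.fap_fan,
        }


@dataclass(frozen=True)
class FitResult:
    """Best-fit stiffness ratio β* and the model predictions there."""

    beta_star: float
    objective: float
    predicted: PredictedRatios
    at_boundary: bool = False
    errors: dict[str, float] = field(default_factory=dict)


def predict_ratios(
    params: MorphParams,
    theta_pos: float = 15.0,
    theta_neg: float = 35.0,
    theta1: float = 90.0,
) -> PredictedRatios:
    """Model force ratios for positive and negative pulls at ``params.beta``.

    Evaluates the bending-dominated ratio for each direction at its
    abscission angle θ2 (``theta_pos``/``theta_neg``, degrees) and forms
    Fap/Fan = (Fap/Fas)/(Fan/Fas).  Validity-flag failures are attached as
    warnings (prefixed with the direction), never raised.
    """
    pos = force_ratio_approx(params, PullScenario("positive", theta1, theta_pos))
    neg = force_ratio_approx(params, PullScenario("negative", theta1, theta_neg))
    warnings = tuple(f"positive:{w}" for w in pos.warnings) + tuple(
        f"negative:{w}" for w in neg.warnings
    )
    return PredictedRatios(
        fap_fas=pos.ratio,
        fan_fas=neg.ratio,
        fap_fan=pos.ratio / neg.ratio,
        warnings=warnings,
    )


def _log_objective(beta: float, target: ExperimentalRatios, params: MorphParams) -> float:
    pred = predict_ratios(params.replace(beta=beta))
    return (math.log10(pred.fap_fas) - math.log10(target.fap_fas)) ** 2 + (
        math.log10(pred.fan_fas) - math.log10(target.fan_fas)
    ) ** 2


def fit_beta(
    target: ExperimentalRatios,
    params: MorphParams,
    bounds: tuple[float, float] = (1.0, 1000.0),
    *,
    n_grid: int = 400,
    rel_tol: float = 1e-4,
) -> FitResult:
    """Fit β to experimental ratios by log-space least squares.

    Deterministic two-stage search over β ∈ ``bounds``: an ``n_grid``-point
    log-spaced grid locates the basin, then golden-section refinement (in
    log10 β) narrows it to relative tolerance ``rel_tol``.  An optimum that
    sticks to either bound is flagged ``at_boundary`` — with unreachable
    targets (e.g. both ratios above every model value) the objective is
    monotone and the fit degenerates to the nearer bound.
    """
    lo, hi = bounds
    if not (1.0 <= lo < hi <= 1000.0):
        raise ValueError("bounds must satisfy 1 <= lo < hi <= 1000")

    grid = np.logspace(math.log10(lo), math.log10(hi), n_grid)
    values = np.array([_log_objective(b, target, params) for b in grid])
    i = int(np.argmin(values))

    # Golden-section refinement on the bracketing grid interval, in log space.
    left = math.log10(grid[max(i - 1, 0)])
    right = math.log10(grid[min(i + 1, n_grid - 1)])
    if right > left:
        res = optimize.minimize_scalar(
            lambda t: _log_objective(10.0**t, target, params),
            bounds=(left, right),
            method="bounded",
            options={"xatol": rel_tol * math.log10(math.e)},
        )
        beta_star = float(10.0**res.x)
        objective = float(res.fun)
    else:  # pragma: no cover - degenerate single-point bracket
        beta_star, objective = float(grid[i]), float(values[i])

    # Keep the grid optimum if refinement did not improve on it.
    if values[i] < objective:
        beta_star, objective = float(grid[i]), float(values[i])

    at_boundary = i == 0 or i == n_grid - 1
    if at_boundary:
        beta_star = float(grid[i])
        objective = float(values[i])
    return FitResult(
        beta_star=beta_star,
        objective=objective,
        predicted=predict_ratios(params.replace(beta=beta_star)),
        at_boundary=at_boundary,
    )


def sweep_parameter(
    params: MorphParams,
    which: str,
    grid: "np.ndarray | list[float]",
) -> pd.DataFrame:
    """Sweep the asymmetry ratio Fap/Fan over pedicle radius c or site radius r.

    For an r sweep the attachment-site width is re-derived as w = 1.6·r at
    every grid point.  Points whose y_max validity flag fails (in either
    direction) are kept in the output but marked ``valid=False``.

    Returns a DataFrame with columns ``param_value_um``, ``fap_fan``,
    ``valid``.
    """
    if which not in ("c", "r"):
        raise ValueError("which must be 'c' or 'r'")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid is empty")
    if not (np.all(grid > 0) and np.all(np.diff(grid) > 0)):
        raise ValueError("sweep grid must be positive and strictly ascending")

    rows = []
    for value in grid:
        if which == "c":
            p = params.replace(c=value)
        else:
            p = params.replace(r=value, w=W_OVER_R * value)
        pred = predict_ratios(p)
        valid = not any(w.endswith("y_max_in_pedicle") for w in pred.warnings)
        rows.append((value, pred.fap_fan, valid))
    return pd.DataFrame(rows, columns=["param_value_um", "fap_fan", "valid"])


def propagate_errors(
    param_samples: "list[MorphParams]",
    beta: float,
) -> dict[str, float]:
    """Half-widths of the central 95% interval of each predicted ratio.

    Evaluates :func:`predict_ratios` on every morphology draw (all at the
    same β) and returns ``(P97.5 − P2.5)/2`` per ratio — the propagated
    parameter uncertainty of the predictions.
    """
    if len(param_samples) < 2:
        raise ValueError("need at least two parameter samples")
    preds = [predict_ratios(p.replace(beta=beta)) for p in param_samples]
    out = {}
    for key in ("fap_fas", "fan_fas", "fap_fan"):
        vals = np.array([getattr(p, key) for p in preds])
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[key] = float((hi - lo) / 2.0)
    return out
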