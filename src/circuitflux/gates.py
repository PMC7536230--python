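"""Gate response functions: unit conversions, Hill evaluation and fitting.

The repression response y(x) = y_min + (y_max - y_min) * K^n / (K^n + x^n)
is evaluated either in flux space (x and K in RNAP/s) or in protein space
(x = repressor count, K replaced by the binding constant k).  K and n are
fitted by Poisson regression with a negative log-likelihood loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize

from .profiles import CalibrationConstants

__all__ = [
    "GateResponse",
    "ResponsePoint",
    "HillFit",
    "rpu_from_fluorescence",
    "rpu_to_flux",
    "hill",
    "hill_response",
    "fit_hill",
    "k_from_K",
]


@dataclass
class GateResponse:
    """Response-function parameters of one repressor gate."""

    name: str
    y_min: float
    y_max: float
    K: float = float("nan")  # half-repression input flux, RNAP/s
    n: float = float("nan")  # cooperativity
    k: float = float("nan")  # repressor binding constant, protein count
    alpha: float = float("nan")  # TE of the gate's RBS
    eta: float = float("nan")  # CE of the gate's ribozyme

    def __post_init__(self) -> None:
        if not 0 <= self.y_min < self.y_max:
            raise ValueError("require 0 <= y_min < y_max")


class ResponsePoint(NamedTuple):
    x: float
    y: float
    state: str = ""
    outlier: bool = False


class HillFit(NamedTuple):
    K: float
    n: float
    converged: bool
    nll: float


def rpu_from_fluorescence(yfp: float, yfp_ref: float, yfp_auto: float) -> float:
    """Median-fluorescence conversion to relative promoter units.

    RPU = (<YFP> - <YFP>_0) / (<YFP>_RPU - <YFP>_0).  A value below the
    autofluorescence gives a negative RPU, returned as-is.
    """
    denom = yfp_ref - yfp_auto
    if denom <= 0:
        raise ValueError("reference fluorescence must exceed autofluorescence")
    return (yfp - yfp_auto) / denom


def rpu_to_flux(
    rpu: float,
    consts: CalibrationConstants = CalibrationConstants(),
    total: bool = False,
) -> float:
    """RPU to RNAP/s, per promoter or total over all plasmid copies."""
    if rpu < 0:
        raise ValueError("RPU must be nonnegative")
    flux = consts.rpu_to_rnaps * rpu
    if total:
        flux *= consts.n_circuit_copies
    return flux


def hill(x, y_min: float, y_max: float, K: float, n: float):
    """Repression Hill function; monotone nonincreasing in x."""
    x = np.asarray(x, dtype=float)
    out = y_min + (y_max - y_min) * K**n / (K**n + x**n)
    return out if out.ndim else float(out)


def hill_response(x, gate: GateResponse, space: str = "flux"):
    """Evaluate a gate's response in flux space (K) or protein space (k)."""
    if space == "flux":
        return hill(x, gate.y_min, gate.y_max, gate.K, gate.n)
    if space == "protein":
        return hill(x, gate.y_min, gate.y_max, gate.k, gate.n)
    raise ValueError(f"unknown space {space!r}")


def _poisson_nll(y_obs: np.ndarray, y_model: np.ndarray, exposure: float) -> float:
    mu = np.clip(y_model * exposure, 1e-300, None)
    counts = y_obs * exposure
    return float(np.sum(mu - counts * np.log(mu)))


def fit_hill(
    points: Sequence[ResponsePoint],
    y_min: float,
    y_max: float,
    exposure: float = 1e6,
    xatol: float = 1e-12,
    fatol: float = 1e-10,
) -> HillFit:
    """Fit (K, n) of the repression Hill function by Poisson regression.

    ``y_min``/``y_max`` are fixed from the observed extremes, not fitted.
    Observed outputs are rescaled by ``exposure`` to pseudo-counts before
    the negative log-likelihood is evaluated.  Optimization is
    derivative-free (Nelder-Mead in log-parameter space) with a multistart
    grid: K at the quartiles of the inputs, n in {1, 2, 4}.  Points with
    ``outlier=True`` are excluded.

    Raises
    ------
    ValueError
        Fewer than three usable points, or a degenerate (constant-y) set.
    RuntimeError
        No start converged.
    """
    pts = [p for p in points if not p.outlier]
    if len(pts) < 3:
        raise ValueError("need at least 3 non-outlier points")
    x = np.array([p.x for p in pts], dtype=float)
    y = np.array([p.y for p in pts], dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("all outputs identical; (K, n) not identifiable")

    def objective(theta: np.ndarray) -> float:
        K, n = np.exp(theta)
        return _poisson_nll(y, hill(x, y_min, y_max, K, n), exposure)

    positive_x = x[x > 0]
    if positive_x.size == 0:
        raise ValueError("need at least one positive input value")
    k_starts = np.percentile(positive_x, [25, 50, 75])
    best = None
    any_converged = False
    for K0 in k_starts:
        for n0 in (1.0, 2.0, 4.0):
            res = minimize(
                objective,
                x0=np.log([K0, n0]),
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxiter": 5000},
            )
            any_converged |= bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
    if not any_converged or best is None:
        raise RuntimeError(
            f"Hill fit failed to converge from all starts (last status: {best})"
        )
    K, n = np.exp(best.x)
    return HillFit(K=float(K), n=float(n), converged=bool(best.success), nll=float(best.fun))


def k_from_K(
    K: float,
    alpha: float,
    eta: float,
    gamma: float = 0.0067,
    mu: float = 0.00026,
    b: float = 2.0,
) -> float:
    """Convert a flux-space binding constant K to protein-number space.

    k = alpha * K / (gamma * mu * (eta*(1-b) + b)); with b = 2 the
    denominator factor is (2 - eta).
    """
    if min(alpha, gamma, mu) <= 0:
        raise ValueError("alpha, gamma and mu must be positive")
    return alpha * K / (gamma * mu * (eta * (1.0 - b) + b))
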