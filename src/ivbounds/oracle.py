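"""Response-type linear-programming oracle for sharp binary-IV bounds.

A unit's counterfactual behaviour is summarised by its response type
``(a0, a1, y0, y1)`` with ``a_z = A(z)`` and ``y_a = Y(a)``: 16 types for
binary instrument, exposure and outcome.  Any distribution ``q`` over types
(together with instrument randomisation) induces the observable cell
probabilities ``P(Y=y, A=a | Z=z)``, and the sharp bounds on the average
treatment effect are the optima of the linear programs

    min / max  sum_q q(a0,a1,y0,y1) * (y1 - y0)
    s.t.       observables(q) = pi,  q >= 0,  sum q = 1.

This module solves those LPs directly (scipy HiGHS) and serves as the
independent correctness oracle for the closed-form component tables in
`ivbounds.bound_core`, as well as the exact-truth engine for discrete
test designs.  It deliberately shares no code with the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import linprog

from .bound_core import PI_INDEX, PiPair, theta_lower, theta_upper

__all__ = [
    "RESPONSE_TYPES",
    "IVIncompatibleError",
    "ResponseTypeDist",
    "DiscreteIVDistribution",
    "observables_from_types",
    "type_ate",
    "lp_bounds",
    "true_bounds",
    "merge_strata",
]

#: The 16 response types in binary-counting order (a0, a1, y0, y1).
RESPONSE_TYPES: tuple[tuple[int, int, int, int], ...] = tuple(
    product((0, 1), repeat=4)
)


class IVIncompatibleError(ValueError):
    """Observable cell probabilities admit no response-type distribution."""


@dataclass(frozen=True)
class ResponseTypeDist:
    """Probability vector over the 16 response types."""

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (16,):
            raise ValueError("q must be a 16-vector")
        if q.min() < -1e-12 or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("q must be a probability vector")
        object.__setattr__(self, "q", q)


def _constraint_matrix() -> np.ndarray:
    """Rows: the 8 observable cells (z, (y, a)); columns: the 16 types."""
    A = np.zeros((8, 16))
    for col, (a0, a1, y0, y1) in enumerate(RESPONSE_TYPES):
        for z in (0, 1):
            a = (a0, a1)[z]
            y = (y0, y1)[a]
            row = 4 * z + PI_INDEX.index((y, a))
            A[row, col] = 1.0
    return A

_A_OBS = _constraint_matrix()
_C_ATE = np.array([y1 - y0 for (_, _, y0, y1) in RESPONSE_TYPES], dtype=float)


def observables_from_types(q: ResponseTypeDist | np.ndarray) -> PiPair:
    """Map a response-type distribution to the observable `PiPair`."""
    qv = q.q if isinstance(q, ResponseTypeDist) else ResponseTypeDist(np.asarray(q)).q
    cells = _A_OBS @ qv
    return PiPair(pi_z0=cells[:4], pi_z1=cells[4:])


def type_ate(q: ResponseTypeDist | np.ndarray) -> float:
    """Average treatment effect E[Y(1) - Y(0)] implied by the type law."""
    qv = q.q if isinstance(q, ResponseTypeDist) else np.asarray(q, dtype=float)
    return float(_C_ATE @ qv)


def lp_bounds(pi: PiPair, tol: float = 1e-10) -> tuple[float, float]:
    """Sharp ATE bounds for one covariate stratum by linear programming.

    Equality constraints are relaxed to ``+/- tol`` to absorb floating-point
    noise in the supplied probabilities.  Raises `IVIncompatibleError` when
    the cells are not achievable by any response-type distribution (possible
    for arbitrary simplex pairs, never for ones generated from types).
    """
    arr = pi.as_array() if isinstance(pi, PiPair) else PiPair(pi[0], pi[1]).as_array()
    b = arr.reshape(8)
    A_ub = np.vstack([_A_OBS, -_A_OBS])
    b_ub = np.concatenate([b + tol, -(b - tol)])
    A_eq = np.ones((1, 16))
    out = []
    for sign in (1.0, -1.0):
        res = linprog(
            sign * _C_ATE, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
            bounds=(0, 1), method="highs",
        )
        if res.status == 2:
            raise IVIncompatibleError(
                "cell probabilities are incompatible with the binary IV model"
            )
        if not res.success:  # pragma: no cover - solver failure, not infeasibility
            raise RuntimeError(f"LP solver failed: {res.message}")
        out.append(sign * res.fun)
    return out[0], out[1]


@dataclass(frozen=True)
class DiscreteIVDistribution:
    """Exact stratum-level law: masses, per-stratum cells, instrument propensity.

    ``strata`` is a list of ``(mass, PiPair)``; ``lambda1`` is P(Z=1 | stratum),
    a scalar (instrument independent of the stratum) or one value per stratum.
    """

    strata: tuple[tuple[float, PiPair], ...]
    lambda1: float | np.ndarray = 0.5

    def __post_init__(self):
        strata = tuple((float(m), p if isinstance(p, PiPair) else PiPair(*p))
                       for m, p in self.strata)
        masses = np.array([m for m, _ in strata])
        if masses.min() < -1e-12 or abs(masses.sum() - 1.0) > 1e-9:
            raise ValueError("stratum masses must form a probability vector")
        lam = np.broadcast_to(np.asarray(self.lambda1, dtype=float), (len(strata),))
        if lam.min() <= 0 or lam.max() >= 1:
            raise ValueError("lambda1 must lie strictly in (0, 1)")
        object.__setattr__(self, "strata", strata)
        object.__setattr__(self, "lambda1", np.array(lam))

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.strata])

    @property
    def pis(self) -> np.ndarray:
        """Stacked (S, 2, 4) cell array."""
        return np.stack([p.as_array() for _, p in self.strata])


def true_bounds(
    dist: DiscreteIVDistribution, use: str = "closed_form", check_tol: float = 1e-8
) -> tuple[float, float]:
    """Mass-weighted sharp ATE bounds over a discrete covariate law.

    ``use`` selects the engine: ``"closed_form"`` (component tables),
    ``"lp"`` (response-type LP), or ``"both"`` which runs the two and
    requires agreement within ``check_tol``.
    """
    if use not in ("closed_form", "lp", "both"):
        raise ValueError("use must be 'closed_form', 'lp', or 'both'")
    masses = dist.masses
    results = {}
    if use in ("closed_form", "both"):
        pis = dist.pis
        gl = theta_lower(pis).max(axis=1)
        gu = theta_upper(pis).min(axis=1)
        results["closed_form"] = (float(masses @ gl), float(masses @ gu))
    if use in ("lp", "both"):
        lo = hi = 0.0
        for m, p in dist.strata:
            l, u = lp_bounds(p)
            lo += m * l
            hi += m * u
        results["lp"] = (lo, hi)
    if use == "both":
        cf, lp_ = results["closed_form"], results["lp"]
        if max(abs(cf[0] - lp_[0]), abs(cf[1] - lp_[1])) > check_tol:
            raise AssertionError(
                f"closed-form {cf} and LP {lp_} bounds disagree beyond {check_tol}"
            )
        return cf
    return results[use]


def merge_strata(dist: DiscreteIVDistribution) -> PiPair:
    """Collapse strata to the unadjusted observable cells.

    Within arm z the merged cells are the stratum cells mixed with weights
    proportional to ``mass * P(Z=z | stratum)``; with a constant instrument
    propensity this is the plain mass-weighted mixture.
    """
    masses, lam, pis = dist.masses, dist.lambda1, dist.pis
    merged = np.empty((2, 4))
    for z in (0, 1):
        wz = masses * (lam if z == 1 else 1.0 - lam)
        merged[z] = (wz / wz.sum()) @ pis[:, z, :]
    return PiPair(pi_z0=merged[0], pi_z1=merged[1])
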