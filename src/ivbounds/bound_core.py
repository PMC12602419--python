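"""Balke-Pearl bound functions, their extrema, and log-sum-exp smoothings.

Everything in this module is a pure, deterministic function of conditional
probability tables ``pi[z, (y, a)] = P(Y=y, A=a | X, Z=z)``.  The eight lower
bound components ``theta_l`` and eight upper bound components ``theta_u`` are
signed sums of these probabilities (plus a constant); the conditional average
treatment effect given X lies in ``[max_j theta_l_j, min_j theta_u_j]``.

The component formulas are kept as a literal text table (`THETA_LOWER_TERMS`,
`THETA_UPPER_TERMS`) and parsed once into coefficient arrays, so that a single
transcription drives both the bound evaluation and the influence-function
correction terms built from the same linear combinations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PI_INDEX",
    "THETA_LOWER_TERMS",
    "THETA_UPPER_TERMS",
    "PiPair",
    "ThetaBounds",
    "LSEConfig",
    "SimplexError",
    "check_pi",
    "theta_lower",
    "theta_upper",
    "theta_from_coefs",
    "gamma_and_argext",
    "lse",
    "lse_min",
    "lse_gradient",
    "margin_gaps",
    "margin_summary",
]

#: Order of the (y, a) cells within each instrument arm z.
PI_INDEX: tuple[tuple[int, int], ...] = ((1, 1), (0, 1), (1, 0), (0, 0))

# Literal transcription of the eight lower / eight upper bound components.
# "p11.1" means P(Y=1, A=1 | X, Z=1).  Kept as text to prevent drift between
# the published formulas and the coefficient arrays used in computation.
THETA_LOWER_TERMS: tuple[str, ...] = (
    "p11.1 + p00.0 - 1",
    "p11.0 + p00.1 - 1",
    "- p01.1 - p10.1",
    "- p01.0 - p10.0",
    "p11.0 - p11.1 - p10.1 - p01.0 - p10.0",
    "p11.1 - p11.0 - p10.0 - p01.1 - p10.1",
    "p00.1 - p01.1 - p10.1 - p01.0 - p00.0",
    "p00.0 - p01.0 - p10.0 - p01.1 - p00.1",
)

THETA_UPPER_TERMS: tuple[str, ...] = (
    "1 - p01.1 - p10.0",
    "1 - p01.0 - p10.1",
    "p11.1 + p00.1",
    "p11.0 + p00.0",
    "- p01.0 + p01.1 + p00.1 + p11.0 + p00.0",
    "- p01.1 + p11.1 + p00.1 + p01.0 + p00.0",
    "- p10.1 + p11.1 + p00.1 + p11.0 + p10.0",
    "- p10.0 + p11.0 + p00.0 + p11.1 + p10.1",
)

_TERM_RE = re.compile(r"([+-]?)\s*(?:p([01])([01])\.([01])|1)")


def _parse_terms(rows: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Parse the literal tables into (coef[8, 2, 4], const[8])."""
    coef = np.zeros((8, 2, 4))
    const = np.zeros(8)
    cell = {ya: k for k, ya in enumerate(PI_INDEX)}
    for j, row in enumerate(rows):
        for sign, y, a, z in _TERM_RE.findall(row):
            s = -1.0 if sign == "-" else 1.0
            if y == "":  # bare constant
                const[j] += s
            else:
                coef[j, int(z), cell[(int(y), int(a))]] += s
    return coef, const

THETA_L_COEF, THETA_L_CONST = _parse_terms(THETA_LOWER_TERMS)
THETA_U_COEF, THETA_U_CONST = _parse_terms(THETA_UPPER_TERMS)


class SimplexError(ValueError):
    """A probability 4-vector is off the simplex beyond tolerance."""


@dataclass(frozen=True)
class PiPair:
    """Conditional cell probabilities for both instrument arms.

    ``pi_z0[k] = P(Y=y, A=a | X, Z=0)`` with ``(y, a)`` in `PI_INDEX` order,
    and similarly ``pi_z1`` for Z=1.  Each arm lies on the probability simplex.
    """

    pi_z0: np.ndarray
    pi_z1: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pi_z0", np.asarray(self.pi_z0, dtype=float))
        object.__setattr__(self, "pi_z1", np.asarray(self.pi_z1, dtype=float))
        check_pi(self.as_array())

    def as_array(self) -> np.ndarray:
        """Return the (2, 4) array indexed [z, (y, a)]."""
        return np.stack([self.pi_z0, self.pi_z1])


def check_pi(pi: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Validate an array of cell probabilities of shape (..., 2, 4).

    Raises `SimplexError` if any entry is outside [0, 1] or an arm does not
    sum to one, beyond ``tol``.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape[-2:] != (2, 4):
        raise ValueError(f"expected trailing shape (2, 4), got {pi.shape}")
    if not np.all(np.isfinite(pi)):
        raise SimplexError("non-finite cell probabilities")
    if pi.min() < -tol or pi.max() > 1 + tol:
        raise SimplexError("cell probabilities outside [0, 1]")
    sums = pi.sum(axis=-1)
    if np.abs(sums - 1.0).max() > tol:
        raise SimplexError("arm probabilities do not sum to 1")
    return pi


def theta_from_coefs(pi: np.ndarray, coef: np.ndarray, const: np.ndarray) -> np.ndarray:
    """Apply one of the component tables: (..., 2, 4) -> (..., 8)."""
    pi = np.asarray(pi, dtype=float)
    return np.einsum("jzk,...zk->...j", coef, pi) + const


def _pi_array(pi) -> np.ndarray:
    arr = pi.as_array() if isinstance(pi, PiPair) else np.asarray(pi, dtype=float)
    return check_pi(arr)


def theta_lower(pi) -> np.ndarray:
    """Eight lower-bound components; input a `PiPair` or array (..., 2, 4)."""
    return theta_from_coefs(_pi_array(pi), THETA_L_COEF, THETA_L_CONST)


def theta_upper(pi) -> np.ndarray:
    """Eight upper-bound components; input a `PiPair` or array (..., 2, 4)."""
    return theta_from_coefs(_pi_array(pi), THETA_U_COEF, THETA_U_CONST)


@dataclass
class ThetaBounds:
    """Per-observation bound components with extrema and arg-extrema.

    ``gamma_l[i] = max_j theta_l[i, j]`` attained at index ``d_l[i]`` (1-based,
    ties to the smallest index), ``gamma_u[i] = min_j theta_u[i, j]`` at
    ``d_u[i]``.  Rows where ``gamma_l > gamma_u`` are flagged: with estimated
    probabilities this signals incompatibility with the binary IV model.
    """

    theta_l: np.ndarray
    theta_u: np.ndarray
    gamma_l: np.ndarray = field(init=False)
    gamma_u: np.ndarray = field(init=False)
    d_l: np.ndarray = field(init=False)
    d_u: np.ndarray = field(init=False)
    incompatible: np.ndarray = field(init=False)

    def __post_init__(self):
        tl = np.atleast_2d(np.asarray(self.theta_l, dtype=float))
        tu = np.atleast_2d(np.asarray(self.theta_u, dtype=float))
        if tl.shape != tu.shape or tl.shape[1] != 8:
            raise ValueError("theta_l and theta_u must both be (n, 8)")
        if not (np.all(np.isfinite(tl)) and np.all(np.isfinite(tu))):
            raise ValueError("non-finite bound components")
        self.theta_l, self.theta_u = tl, tu
        # np.argmax/argmin already break ties by the smallest index
        self.d_l = tl.argmax(axis=1) + 1
        self.d_u = tu.argmin(axis=1) + 1
        self.gamma_l = tl.max(axis=1)
        self.gamma_u = tu.min(axis=1)
        # strict crossings only; exact-tie strata differ by float noise
        self.incompatible = self.gamma_l > self.gamma_u + 1e-9

    @property
    def n(self) -> int:
        return self.theta_l.shape[0]

    @property
    def incompatible_fraction(self) -> float:
        return float(self.incompatible.mean())


def gamma_and_argext(theta_l: np.ndarray, theta_u: np.ndarray) -> ThetaBounds:
    """Bundle component matrices into a `ThetaBounds` (extrema + indices)."""
    return ThetaBounds(theta_l, theta_u)


@dataclass(frozen=True)
class LSEConfig:
    """Temperature ``t`` and component count ``k`` for log-sum-exp smoothing."""

    t: float
    k: int = 8

    def __post_init__(self):
        if not (np.isfinite(self.t) and self.t > 0):
            raise ValueError(f"LSE temperature must be positive, got {self.t}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _t_of(cfg) -> float:
    t = cfg.t if isinstance(cfg, LSEConfig) else float(cfg)
    if not (np.isfinite(t) and t > 0):
        raise ValueError(f"LSE temperature must be positive, got {t}")
    return t


def lse(v: np.ndarray, cfg) -> np.ndarray:
    """Smooth maximum g_t(v) = t^{-1} log sum_j exp(t v_j) over the last axis.

    Computed with max-subtraction so it is stable for temperatures in the
    hundreds (t is ~740 at n=3,010 under the t = 100 n^{1/4} default).
    Satisfies max(v) < g_t(v) <= max(v) + log(k)/t.
    """
    t = _t_of(cfg)
    v = np.asarray(v, dtype=float)
    m = v.max(axis=-1, keepdims=True)
    out = m[..., 0] + np.log(np.exp(t * (v - m)).sum(axis=-1)) / t
    return out if out.ndim else float(out)


def lse_min(v: np.ndarray, cfg) -> np.ndarray:
    """Smooth minimum h_t(v) = g_{-t}(v) = -g_t(-v) over the last axis."""
    t = _t_of(cfg)
    return -lse(-np.asarray(v, dtype=float), t)


def lse_gradient(v: np.ndarray, cfg, direction: str = "max") -> np.ndarray:
    """Softmax (direction='max') or softmin ('min') weights of g_t / h_t.

    Nonnegative, sum to one along the last axis; shift-stable.
    """
    t = _t_of(cfg)
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    v = np.asarray(v, dtype=float)
    s = t if direction == "max" else -t
    z = np.exp(s * (v - (v.max(axis=-1, keepdims=True) if s > 0
                         else v.min(axis=-1, keepdims=True))))
    return z / z.sum(axis=-1, keepdims=True)


def margin_gaps(tb: ThetaBounds) -> tuple[np.ndarray, np.ndarray]:
    """Per-row margins between the extremum and the runner-up component.

    Returns ``(lower_gaps, upper_gaps)`` where
    ``lower_gaps[i] = min_{j != d_l} (theta_l[i, d_l] - theta_l[i, j])`` and
    ``upper_gaps[i] = min_{j != d_u} (theta_u[i, j] - theta_u[i, d_u])``.
    Both are nonnegative; zeros are exact ties (margin-condition violations
    at the estimated probabilities).
    """
    tl_sorted = np.sort(tb.theta_l, axis=1)
    tu_sorted = np.sort(tb.theta_u, axis=1)
    lower = tl_sorted[:, -1] - tl_sorted[:, -2]
    upper = tu_sorted[:, 1] - tu_sorted[:, 0]
    return lower, upper


def margin_summary(
    tb: ThetaBounds, thresholds: tuple[float, ...] = (0.01, 0.05, 0.1)
) -> dict:
    """Quantiles of the margin gaps and near-tie fractions at thresholds."""
    lower, upper = margin_gaps(tb)
    qs = (0.0, 0.05, 0.25, 0.5)

    def side(g: np.ndarray) -> dict:
        return {
            "quantiles": {f"q{int(100 * q):02d}": float(np.quantile(g, q)) for q in qs},
            "near_tie_fraction": {str(h): float((g < h).mean()) for h in thresholds},
        }

    return {
        "lower": side(lower),
        "upper": side(upper),
        "argext_hist_lower": np.bincount(tb.d_l, minlength=9)[1:].tolist(),
        "argext_hist_upper": np.bincount(tb.d_u, minlength=9)[1:].tolist(),
        "incompatible_fraction": tb.incompatible_fraction,
    }
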