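"""Influence-function-based direct estimation of the marginal bounds.

Targets L(P) = E[gamma_l(X)] and U(P) = E[gamma_u(X)] under a margin
condition (the arg-extremum among the eight bound components is almost surely
unique and well separated).  For each observation the uncentred influence
function of the lower bound is

    phi_l(O) = sum_j 1{d_l(X) = j} (L_j(O) + theta_l_j(X)),

where L_j replaces each cell probability in the j-th component by the
weighted residual psi_{ya.z}(O) = 1(Z=z)/lambda_z(X) * (1(Y=y, A=a) -
pi_{ya.z}(X)) and drops additive constants; the upper bound is analogous with
the arg-minimum and U_j.  Estimates are weighted empirical means of phi,
variances are weighted centred second moments, and the ATE interval is the
plain Wald construction (lower endpoint from L-hat, upper from U-hat),
clipped to [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .bound_core import (
    THETA_L_COEF, THETA_L_CONST, THETA_U_COEF, THETA_U_CONST,
    ThetaBounds, margin_summary, theta_from_coefs,
)
from .nuisance import CrossFitNuisances, IVSample, wmean

__all__ = [
    "BoundEstimate",
    "psi_terms",
    "correction_terms",
    "theta_hat",
    "estimate_direct",
    "margin_report",
]


def psi_terms(sample: IVSample, nuis: CrossFitNuisances) -> np.ndarray:
    """Weighted cell residuals psi_{ya.z}(O_i), shape (n, 2, 4).

    Entries for the arm not observed (z != Z_i) are exactly zero, because the
    indicator prefactor 1(Z_i = z) is zero.
    """
    lam1 = nuis.lambda1
    if lam1.min() <= 0 or lam1.max() >= 1:
        raise ValueError("lambda estimates must lie strictly in (0, 1)")
    n = sample.n
    onehot = np.zeros((n, 4))
    onehot[np.arange(n), sample.pi_class()] = 1.0
    lam = np.stack([1.0 - lam1, lam1], axis=1)             # (n, 2)
    pref = (sample.Z[:, None] == np.arange(2)[None, :]) / lam
    return pref[:, :, None] * (onehot[:, None, :] - nuis.pi)


def correction_terms(psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Component corrections (Lmat, Umat), each (n, 8), linear in psi.

    L_j / U_j apply the same signed-sum tables as theta_l_j / theta_u_j with
    the cell probabilities replaced by psi and the constants dropped.
    """
    psi = np.asarray(psi, dtype=float)
    Lmat = theta_from_coefs(psi, THETA_L_COEF, np.zeros(8))
    Umat = theta_from_coefs(psi, THETA_U_COEF, np.zeros(8))
    return Lmat, Umat


def theta_hat(nuis: CrossFitNuisances) -> ThetaBounds:
    """Estimated bound components and extrema from cross-fitted cells."""
    tl = theta_from_coefs(nuis.pi, THETA_L_COEF, THETA_L_CONST)
    tu = theta_from_coefs(nuis.pi, THETA_U_COEF, THETA_U_CONST)
    return ThetaBounds(tl, tu)


@dataclass
class BoundEstimate:
    """Estimated ATE bounds with influence-function inference.

    ``ate_ci`` is the Wald interval for the treatment effect (covering the
    whole identified set, hence conservative for the ATE); ``bound_cis`` are
    per-bound Wald intervals.  ``method`` is "direct" or "lse" (then ``t`` and
    the log(8)/t ``correction`` are recorded).  ``warnings`` flags
    finite-sample bound crossing (lower > upper, reported unmodified) and the
    fraction of rows whose estimated cells are incompatible with the IV model.
    """

    lower: float
    upper: float
    if_lower: np.ndarray
    if_upper: np.ndarray
    var_lower: float
    var_upper: float
    ci_level: float
    ate_ci: tuple[float, float]
    bound_cis: dict
    method: str
    n: int
    t: float | None = None
    correction: float = 0.0
    diagnostics: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)

    def to_dict(self, include_if: bool = False) -> dict:
        out = {
            "method": self.method,
            "lower": self.lower,
            "upper": self.upper,
            "var_lower": self.var_lower,
            "var_upper": self.var_upper,
            "se_lower": float(np.sqrt(self.var_lower / self.n)),
            "se_upper": float(np.sqrt(self.var_upper / self.n)),
            "ci_level": self.ci_level,
            "ate_ci": list(self.ate_ci),
            "bound_cis": {k: list(v) for k, v in self.bound_cis.items()},
            "n": self.n,
            "t": self.t,
            "correction": self.correction,
            "diagnostics": self.diagnostics,
            "warnings": self.warnings,
        }
        if include_if:
            out["if_lower"] = self.if_lower.tolist()
            out["if_upper"] = self.if_upper.tolist()
        return out


def _assemble(
    sample: IVSample, phi_l: np.ndarray, phi_u: np.ndarray, ci_level: float,
    method: str, tb: ThetaBounds, t: float | None = None, correction: float = 0.0,
) -> BoundEstimate:
    """Weighted means, variances, Wald intervals and warning flags."""
    if not (0 < ci_level < 1):
        raise ValueError("ci_level must lie in (0, 1)")
    if not (np.all(np.isfinite(phi_l)) and np.all(np.isfinite(phi_u))):
        raise ValueError("non-finite influence-function values")
    w, n = sample.w, sample.n
    L = float(wmean(phi_l, w))
    U = float(wmean(phi_u, w))
    V = float(wmean((phi_l - L) ** 2, w))
    W = float(wmean((phi_u - U) ** 2, w))
    z = norm.ppf(0.5 + ci_level / 2)
    se_l, se_u = np.sqrt(V / n), np.sqrt(W / n)
    # correction is the log(8)/t smoothing slack (0 for the direct method)
    ate_ci = (
        float(np.clip(L - correction - z * se_l, -1, 1)),
        float(np.clip(U + correction + z * se_u, -1, 1)),
    )
    bound_cis = {
        "lower": (float(L - z * se_l), float(L + z * se_l)),
        "upper": (float(U - z * se_u), float(U + z * se_u)),
    }
    flags = {
        "bound_crossing": bool(L > U),
        "iv_incompatible_fraction": tb.incompatible_fraction,
    }
    if flags["bound_crossing"]:
        warnings.warn(
            f"estimated lower bound {L:.4f} exceeds upper bound {U:.4f}; "
            "reported unmodified (possible IV-model incompatibility)",
            stacklevel=3,
        )
    if tb.incompatible_fraction > 0:
        warnings.warn(
            f"{100 * tb.incompatible_fraction:.2f}% of rows have estimated "
            "gamma_l > gamma_u (IV-incompatible cells)", stacklevel=3,
        )
    return BoundEstimate(
        lower=L, upper=U, if_lower=phi_l, if_upper=phi_u,
        var_lower=V, var_upper=W, ci_level=ci_level, ate_ci=ate_ci,
        bound_cis=bound_cis, method=method, n=n, t=t, correction=correction,
        warnings=flags,
    )


def estimate_direct(
    sample: IVSample, nuis: CrossFitNuisances, ci_level: float = 0.95
) -> BoundEstimate:
    """Direct (margin-condition) estimator of the marginal bounds.

    The arg-extrema are plugged in from the estimated components; phi is
    evaluated with out-of-fold nuisances and averaged over all observations.
    """
    if sample.n != nuis.n:
        raise ValueError("sample and nuisances have different lengths")
    tb = theta_hat(nuis)
    Lmat, Umat = correction_terms(psi_terms(sample, nuis))
    rows = np.arange(sample.n)
    phi_l = Lmat[rows, tb.d_l - 1] + tb.gamma_l
    phi_u = Umat[rows, tb.d_u - 1] + tb.gamma_u
    est = _assemble(sample, phi_l, phi_u, ci_level, "direct", tb)
    est.diagnostics["margin"] = margin_summary(tb)
    return est


def margin_report(sample: IVSample, nuis: CrossFitNuisances) -> dict:
    """Margin-condition diagnostics on the estimated bound components.

    Reports gap quantiles, near-tie fractions at 0.01/0.05/0.1, the
    arg-extremum histograms, and a plausibility statement: when the estimated
    gaps are bounded away from zero the margin condition plausibly holds with
    exponent alpha = 1 (gap density bounded near zero).
    """
    tb = theta_hat(nuis)
    report = margin_summary(tb)
    q05 = min(report["lower"]["quantiles"]["q05"],
              report["upper"]["quantiles"]["q05"])
    report["margin_plausible_alpha1"] = bool(q05 > 0.01)
    report["n"] = sample.n
    return report
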