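"""Cross-fitted nuisance estimation for the binary-IV bound estimators.

Two nuisance functions feed the influence-function machinery: the instrument
propensity ``lambda_1(X) = P(Z=1 | X)`` and the joint outcome-exposure cell
probabilities ``pi_{ya.z}(X) = P(Y=y, A=a | X, Z=z)``.  Each is predicted
out-of-fold (K-fold cross-fitting), so the prediction for observation i never
comes from a model trained on i's fold.

The cells are estimated with ONE 4-class probability model per instrument arm
(classes in the `bound_core.PI_INDEX` order), which guarantees simplex-valued
predictions up to learner calibration; a Euclidean simplex projection is
applied as a safety net.  Learners are pluggable through a small registry
("logistic", "tree", "forest", "spline", "freq", "ensemble") or by passing
any scikit-learn-style classifier factory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import nnls
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .bound_core import PI_INDEX, check_pi

__all__ = [
    "IVSample",
    "CrossFitNuisances",
    "NuisanceSpec",
    "LEARNERS",
    "make_learner",
    "assign_folds",
    "project_to_simplex",
    "fit_crossfit_nuisances",
    "oracle_nuisances",
    "FrequencyTableClassifier",
    "StackedEnsembleClassifier",
]


def _binary01(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must be strictly in {{0, 1}}")
    return v.astype(int)


@dataclass
class IVSample:
    """One analysis dataset O = (X, Z, A, Y) with optional sampling weights.

    ``X`` is an (n, d) numeric matrix with d >= 0; ``Z`` and ``A`` are binary;
    ``Y`` is binary, or lies in [0, 1] when ``y_mode="continuous"`` (rescale
    first via `ivbounds.continuous.rescale_outcome`).  Weights default to 1
    and enter every empirical mean as weight-normalised averages.
    """

    X: np.ndarray
    Z: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    w: np.ndarray | None = None
    y_mode: str = "binary"

    def __post_init__(self):
        self.Z = _binary01(self.Z, "Z")
        self.A = _binary01(self.A, "A")
        n = len(self.Z)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1) if self.X.size else self.X.reshape(n, 0)
        if self.X.shape[0] != n and self.X.size == 0:
            self.X = np.empty((n, 0))
        self.Y = np.asarray(self.Y, dtype=float)
        if self.y_mode == "binary":
            self.Y = _binary01(self.Y, "Y")
        elif self.y_mode == "continuous":
            if self.Y.min() < 0 or self.Y.max() > 1:
                raise ValueError("continuous-mode Y must lie in [0, 1]; rescale first")
        else:
            raise ValueError("y_mode must be 'binary' or 'continuous'")
        if self.w is None:
            self.w = np.ones(n)
        self.w = np.asarray(self.w, dtype=float)
        lengths = {len(self.Z), len(self.A), len(self.Y), len(self.w), self.X.shape[0]}
        if lengths != {n}:
            raise ValueError(f"inconsistent column lengths: {lengths}")
        if self.w.min() < 0 or self.w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        if self.Z.min() == self.Z.max():
            raise ValueError("both instrument arms must be present")

    @property
    def n(self) -> int:
        return len(self.Z)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def pi_class(self) -> np.ndarray:
        """4-class joint (Y, A) label in `PI_INDEX` order (binary mode only)."""
        if self.y_mode != "binary":
            raise ValueError("joint class labels require a binary outcome")
        lut = {ya: k for k, ya in enumerate(PI_INDEX)}
        return np.array([lut[(y, a)] for y, a in zip(self.Y, self.A)])

    def replace(self, **kw) -> "IVSample":
        args = dict(X=self.X, Z=self.Z, A=self.A, Y=self.Y, w=self.w,
                    y_mode=self.y_mode)
        args.update(kw)
        return IVSample(**args)


def wmean(v: np.ndarray, w: np.ndarray, axis=0) -> np.ndarray:
    """Weight-normalised average (the weighted empirical measure P_n)."""
    w = np.asarray(w, dtype=float)
    return np.tensordot(w, np.asarray(v, dtype=float), axes=([0], [axis])) / w.sum()


def assign_folds(n: int, K: int, seed: int, strata: np.ndarray | None = None) -> np.ndarray:
    """Deterministic fold labels in 1..K with sizes differing by at most one.

    When ``strata`` is given (e.g. the joint (Z, A, Y) cell), observations are
    shuffled within each stratum and folds dealt cyclically across the
    concatenated strata, so rare cells are spread across folds.
    """
    if not (2 <= K <= n):
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    if strata is None:
        order = rng.permutation(n)
    else:
        strata = np.asarray(strata)
        order = np.concatenate(
            [rng.permutation(np.flatnonzero(strata == s)) for s in np.unique(strata)]
        )
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) % K + 1
    return labels


def project_to_simplex(p: np.ndarray) -> np.ndarray:
    """Euclidean projection of the last axis onto the probability simplex.

    Sort-based algorithm; idempotent and nonexpansive, leaves points already
    on the simplex untouched.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("cannot project non-finite values")
    shape = p.shape
    v = p.reshape(-1, shape[-1])
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ks = np.arange(1, shape[-1] + 1)
    cond = u - css / ks > 0
    rho = shape[-1] - 1 - cond[:, ::-1].argmax(axis=1)
    theta = css[np.arange(len(v)), rho] / (rho + 1)
    out = np.maximum(v - theta[:, None], 0.0)
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# learners


class FrequencyTableClassifier:
    """Weighted class frequencies per distinct covariate row.

    Suited to discrete covariates; unseen rows fall back to the marginal
    class frequencies.  Cheap enough for grid/repetition-heavy pipelines.
    """

    def __init__(self):
        self.table_: dict[tuple, np.ndarray] = {}

    def get_params(self, deep=False):  # clone() support
        return {}

    def set_params(self, **kw):
        return self

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X)
        y = np.asarray(y).astype(int)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight)
        self.classes_ = np.unique(y)
        C = len(self.classes_)
        cls_ix = {c: j for j, c in enumerate(self.classes_)}
        counts: dict[tuple, np.ndarray] = {}
        for row, yi, wi in zip(map(tuple, X), y, w):
            counts.setdefault(row, np.zeros(C))[cls_ix[yi]] += wi
        self.table_ = {k: v / v.sum() for k, v in counts.items() if v.sum() > 0}
        marg = np.zeros(C)
        for v in counts.values():
            marg += v
        self.marginal_ = marg / marg.sum()
        return self

    def predict_proba(self, X):
        X = np.asarray(X)
        return np.stack([self.table_.get(row, self.marginal_) for row in map(tuple, X)])


class StackedEnsembleClassifier:
    """Stacked combination of several probabilistic classifiers.

    Base learners are fit on the full training split; combination weights on
    the probability scale are learned from internal out-of-fold predictions by
    nonnegative least squares against the one-hot labels, then normalised to
    the simplex (a light-weight analogue of SuperLearner-style stacking).
    """

    def __init__(self, base_factories: list[Callable[[], object]] | None = None,
                 inner_folds: int = 3, random_state: int = 0):
        self.base_factories = base_factories
        self.inner_folds = inner_folds
        self.random_state = random_state

    def get_params(self, deep=False):
        return {"base_factories": self.base_factories,
                "inner_folds": self.inner_folds,
                "random_state": self.random_state}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def _factories(self):
        if self.base_factories is not None:
            return self.base_factories
        rs = self.random_state
        return [lambda: make_learner("logistic", rs),
                lambda: make_learner("tree", rs),
                lambda: make_learner("forest", rs),
                lambda: make_learner("spline", rs)]

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X)
        y = np.asarray(y).astype(int)
        n = len(y)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight)
        self.classes_ = np.unique(y)
        C = len(self.classes_)
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        facs = self._factories()
        folds = assign_folds(n, min(self.inner_folds, max(2, n)), self.random_state,
                             strata=y)
        oof = np.zeros((len(facs), n, C))
        for m, fac in enumerate(facs):
            for k in np.unique(folds):
                tr, te = folds != k, folds == k
                est = _FitPredict(fac())
                est.fit(X[tr], y[tr], w[tr], classes=self.classes_)
                oof[m, te] = est.predict_proba(X[te])
        sw = np.sqrt(w / w.sum())[:, None]
        A = np.stack([(oof[m] * sw).ravel() for m in range(len(facs))], axis=1)
        b = (onehot * sw).ravel()
        coef, _ = nnls(A, b)
        if coef.sum() <= 0:
            coef = np.ones(len(facs))
        self.weights_ = coef / coef.sum()
        self.fitted_ = []
        for fac in facs:
            est = _FitPredict(fac())
            est.fit(X, y, w, classes=self.classes_)
            self.fitted_.append(est)
        return self

    def predict_proba(self, X):
        X = np.asarray(X)
        out = np.zeros((len(X), len(self.classes_)))
        for wgt, est in zip(self.weights_, self.fitted_):
            out += wgt * est.predict_proba(X)
        return project_to_simplex(out)


def _logistic():
    return Pipeline([("sc", StandardScaler()),
                     ("clf", LogisticRegression(max_iter=2000))])


LEARNERS: dict[str, Callable[[int], object]] = {
    "logistic": lambda seed: _logistic(),
    # cost-complexity pruning keeps leaf-frequency noise out of the cell
    # estimates (unpruned trees leave ~0.08 systematic error at 40-obs leaves)
    "tree": lambda seed: DecisionTreeClassifier(
        min_samples_leaf=40, ccp_alpha=1e-3, random_state=seed),
    "forest": lambda seed: RandomForestClassifier(
        n_estimators=100, min_samples_leaf=20, random_state=seed, n_jobs=1),
    "spline": lambda seed: Pipeline([
        ("sc", StandardScaler()),
        ("sp", SplineTransformer(n_knots=5, degree=3)),
        ("clf", LogisticRegression(max_iter=2000))]),
    "freq": lambda seed: FrequencyTableClassifier(),
    "ensemble": lambda seed: StackedEnsembleClassifier(random_state=seed),
}


def make_learner(name_or_factory, seed: int = 0):
    """Instantiate a learner from the registry or from a factory callable."""
    if isinstance(name_or_factory, str):
        try:
            return LEARNERS[name_or_factory](seed)
        except KeyError:
            raise KeyError(
                f"unknown learner {name_or_factory!r}; available: {sorted(LEARNERS)}"
            ) from None
    return name_or_factory()


class _FitPredict:
    """Uniform fit/predict facade over scikit-learn-style classifiers.

    Handles sample weights (warns and drops them for learners that do not
    accept them), missing classes in the training split (probability columns
    padded with zeros), and single-class degenerate fits.
    """

    def __init__(self, est):
        self.est = est

    def fit(self, X, y, w, classes: np.ndarray):
        self.classes = np.asarray(classes)
        present = np.unique(y)
        if len(present) < 2:
            self.constant_ = present[0]
            return self
        self.constant_ = None
        est = clone(self.est) if hasattr(self.est, "get_params") else self.est
        try:
            if isinstance(est, Pipeline):
                est.fit(X, y, **{f"{est.steps[-1][0]}__sample_weight": w})
            else:
                est.fit(X, y, sample_weight=w)
        except TypeError:
            if not np.allclose(w, w[0]):
                warnings.warn(
                    f"{type(est).__name__} ignores sample weights", stacklevel=2)
            est.fit(X, y)
        self.est = est
        return self

    def predict_proba(self, X) -> np.ndarray:
        C = len(self.classes)
        if self.constant_ is not None:
            out = np.zeros((len(X), C))
            out[:, np.searchsorted(self.classes, self.constant_)] = 1.0
            return out
        p = self.est.predict_proba(X)
        fitted = np.asarray(self.est.classes_)
        if len(fitted) == C and (fitted == self.classes).all():
            return p
        out = np.zeros((len(X), C))
        out[:, np.searchsorted(self.classes, fitted)] = p
        return out


# ---------------------------------------------------------------------------
# cross-fitting


@dataclass
class CrossFitNuisances:
    """Out-of-fold nuisance predictions aligned with the sample rows.

    ``pi[i, z, k]`` estimates P(Y=y, A=a | X_i, Z=z) with k indexing
    `PI_INDEX`; each (i, z) slice lies on the simplex.  ``lambda1`` is
    truncated to [eps, 1-eps] unless a known constant propensity was supplied
    (randomised instrument), in which case it is used verbatim.
    """

    fold: np.ndarray
    lambda1: np.ndarray
    pi: np.ndarray
    eps: float = 0.01
    known_lambda: float | None = None

    def __post_init__(self):
        self.fold = np.asarray(self.fold, dtype=int)
        self.lambda1 = np.asarray(self.lambda1, dtype=float)
        self.pi = check_pi(np.asarray(self.pi, dtype=float))
        n = len(self.fold)
        if self.pi.shape != (n, 2, 4) or len(self.lambda1) != n:
            raise ValueError("inconsistent nuisance shapes")
        if self.known_lambda is None:
            if self.lambda1.min() < self.eps - 1e-12 or \
               self.lambda1.max() > 1 - self.eps + 1e-12:
                raise ValueError("lambda1 not truncated to [eps, 1-eps]")
        elif self.lambda1.min() <= 0 or self.lambda1.max() >= 1:
            raise ValueError("known lambda must lie in (0, 1)")

    @property
    def n(self) -> int:
        return len(self.fold)


def _empirical_nuisances(sample: IVSample, known_lambda, eps) -> CrossFitNuisances:
    """d = 0: weighted arm-wise empirical cell frequencies, no cross-fitting."""
    pi = np.empty((2, 4))
    cls = sample.pi_class()
    for z in (0, 1):
        mz = sample.Z == z
        pi[z] = np.bincount(cls[mz], weights=sample.w[mz], minlength=4)
        pi[z] /= pi[z].sum()
    lam = known_lambda if known_lambda is not None else \
        float(np.clip(wmean(sample.Z, sample.w), eps, 1 - eps))
    return CrossFitNuisances(
        fold=np.ones(sample.n, dtype=int),
        lambda1=np.full(sample.n, lam),
        pi=np.broadcast_to(pi, (sample.n, 2, 4)).copy(),
        eps=eps, known_lambda=known_lambda,
    )


def fit_crossfit_nuisances(
    sample: IVSample,
    pi_learner="logistic",
    lambda_learner="logistic",
    K: int = 5,
    eps: float = 0.01,
    seed: int = 0,
    known_lambda: float | None = None,
    folds: np.ndarray | None = None,
    lambda1: np.ndarray | None = None,
) -> CrossFitNuisances:
    """K-fold cross-fitted nuisance predictions for every observation.

    For each fold k: the instrument model (Z ~ X) and, within each arm z, a
    4-class model for the joint (Y, A) cell are trained on the observations
    outside k and predicted on fold k.  Folds are stratified on the joint
    (Z, A, Y) cell to protect rare cells.  ``known_lambda`` short-circuits the
    instrument model (randomised instrument).  ``folds``/``lambda1`` allow
    reuse of a fold map and instrument fit across repeated calls whose outcome
    changes but whose instrument does not (the continuous-outcome pipeline).
    """
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    if sample.y_mode != "binary":
        raise ValueError("nuisances are fit on a binary-outcome sample")
    if sample.d == 0:
        return _empirical_nuisances(sample, known_lambda, eps)

    cls = sample.pi_class()
    if folds is None:
        strata = sample.Z * 4 + cls
        folds = assign_folds(sample.n, K, seed, strata=strata)
    folds = np.asarray(folds, dtype=int)

    pi = np.empty((sample.n, 2, 4))
    fit_lambda = known_lambda is None and lambda1 is None
    lam = np.empty(sample.n) if fit_lambda else lambda1
    for k in np.unique(folds):
        tr, te = folds != k, folds == k
        if fit_lambda:
            est = _FitPredict(make_learner(lambda_learner, seed + 1000 + k))
            est.fit(sample.X[tr], sample.Z[tr], sample.w[tr], classes=np.array([0, 1]))
            lam[te] = est.predict_proba(sample.X[te])[:, 1]
        for z in (0, 1):
            trz = tr & (sample.Z == z)
            if not trz.any():
                raise ValueError(
                    f"instrument arm z={z} absent from training split of fold {k}"
                )
            est = _FitPredict(make_learner(pi_learner, seed + 2000 + 2 * k + z))
            est.fit(sample.X[trz], cls[trz], sample.w[trz], classes=np.arange(4))
            pi[te, z, :] = est.predict_proba(sample.X[te])
    if known_lambda is not None:
        lam = np.full(sample.n, float(known_lambda))
    elif lambda1 is None:
        lam = np.clip(lam, eps, 1 - eps)
    return CrossFitNuisances(
        fold=folds, lambda1=np.asarray(lam, dtype=float),
        pi=project_to_simplex(pi), eps=eps, known_lambda=known_lambda,
    )


def oracle_nuisances(
    sample: IVSample, pi_truth: Callable[[np.ndarray], np.ndarray],
    lambda_truth: float | Callable[[np.ndarray], np.ndarray] = 0.5,
) -> CrossFitNuisances:
    """Truth-injected nuisances for oracle / infeasible-estimator studies.

    ``pi_truth(X)`` must return the exact (n, 2, 4) cell array; the resulting
    estimator equals the infeasible influence-function estimator exactly.
    """
    pi = np.asarray(pi_truth(sample.X), dtype=float)
    lam = (np.full(sample.n, float(lambda_truth)) if np.isscalar(lambda_truth)
           else np.asarray(lambda_truth(sample.X), dtype=float))
    known = float(lam[0]) if np.ptp(lam) == 0 else None
    return CrossFitNuisances(
        fold=np.ones(sample.n, dtype=int), lambda1=lam, pi=pi,
        eps=min(0.01, float(lam.min())), known_lambda=known,
    )


@dataclass
class NuisanceSpec:
    """Recipe for fitting nuisances, used by pipelines that refit internally."""

    pi_learner: object = "logistic"
    lambda_learner: object = "logistic"
    K: int = 5
    eps: float = 0.01
    known_lambda: float | None = None

    def fit(self, sample: IVSample, seed: int, folds=None, lambda1=None
            ) -> CrossFitNuisances:
        return fit_crossfit_nuisances(
            sample, self.pi_learner, self.lambda_learner, K=self.K, eps=self.eps,
            seed=seed, known_lambda=self.known_lambda, folds=folds, lambda1=lambda1,
        )
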