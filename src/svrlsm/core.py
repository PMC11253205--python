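"""Support-vector-regression lesion-symptom mapping: the model core.

The central computation maps a binary lesion matrix X (subjects x voxels)
and a one-vs-rest subtype outcome y to a voxelwise beta map:

1. lesion-volume correction: every column of X and the outcome y are
   replaced by their residuals from an OLS regression on [1, volume], so
   sheer tumor size cannot masquerade as location signal;
2. epsilon-SVR with an RBF kernel k(a, b) = exp(-gamma * ||a - b||^2) is
   fit in the dual; the kernel-space weight vector is backprojected onto
   voxel axes as beta_j = sum_i alpha_i * X'_ij over support rows (for a
   linear kernel this is exactly the primal weight vector);
3. hyperparameters (C, gamma) are chosen by Bayesian optimization of the
   cross-validated squared error over a log-scaled box;
4. the SVR is refit across k stratified folds (k = 5 by convention) and
   the per-fold beta maps averaged; the averaged map is standardized
   across retained voxels into a z map.

Because permutation inference refits the same design thousands of times
with only the outcome shuffled, the RBF Gram matrix is computed once per
(X', gamma) through :class:`KernelCache` and sliced per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVR

__all__ = [
    "SvrLsmConfig",
    "SubtypeContrast",
    "SvrModel",
    "BetaMap",
    "KernelCache",
    "residualize_volume",
    "fit_svr",
    "beta_map",
    "optimize_hyperparameters",
    "crossval_beta",
    "zscore_map",
    "make_contrast",
    "toy_config",
]


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SvrLsmConfig:
    """All analysis knobs in one place.

    Defaults follow full-scale convention: minimum overlap 10, 5-fold CV,
    200 Bayesian-optimization iterations, 10 000 permutations at a
    voxelwise threshold of P < .005, and a 100-voxel cluster extent at
    26-connectivity.  ``C``/``gamma`` may be fixed positive reals or the
    string ``"optimize"``.
    """

    kernel: str = "rbf"
    C: float | str = "optimize"
    gamma: float | str = "optimize"
    epsilon: float = 0.1
    hyperopt_iterations: int = 200
    hyperopt_bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (1e-3, 1e3),
        (1e-3, 1e3),
    )
    cv_folds: int = 5
    n_permutations: int = 10_000
    p_threshold: float = 0.005
    min_cluster_voxels: int = 100
    connectivity: int = 26
    min_overlap: int = 10
    seed: int = 0
    tail: str = "two_sided"

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        for name in ("C", "gamma"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "optimize":
                    raise ValueError(f"{name} must be positive or 'optimize'")
            elif v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.hyperopt_iterations < 10:
            raise ValueError("hyperopt_iterations must be >= 10")
        for lo, hi in self.hyperopt_bounds:
            if not (0 < lo < hi):
                raise ValueError("hyperopt bounds must satisfy 0 < lo < hi")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.tail not in ("two_sided", "one_sided_negative", "one_sided_positive"):
            raise ValueError("invalid tail")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hyperopt_bounds"] = [list(b) for b in self.hyperopt_bounds]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SvrLsmConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "hyperopt_bounds" in d:
            d["hyperopt_bounds"] = tuple(tuple(b) for b in d["hyperopt_bounds"])
        return cls(**d)


def toy_config(**overrides) -> SvrLsmConfig:
    """Desk-scale defaults for small synthetic grids.

    Hyperparameters are fixed at the toolbox-conventional (C=30, gamma=5)
    rather than optimized: the CV-error optimum favors a heavily smoothed
    near-linear kernel whose beta maps have poor voxelwise contrast (see
    the methods note), and desk-scale simulations want map power.
    """
    base = dict(
        C=30.0,
        gamma=5.0,
        min_overlap=5,
        hyperopt_iterations=20,
        n_permutations=500,
        min_cluster_voxels=30,
    )
    base.update(overrides)
    return SvrLsmConfig(**base)


@dataclass
class SubtypeContrast:
    """One-vs-rest outcome: +1 for the target subtype, 0 for the rest."""

    y: np.ndarray
    target_name: str

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        vals = np.unique(self.y)
        if len(vals) != 2:
            raise ValueError("contrast outcome must take exactly two values")
        if not (self.y == 1.0).any():
            raise ValueError(f"target group {self.target_name!r} is empty")


def make_contrast(subtypes: np.ndarray, target_name: str) -> SubtypeContrast:
    subtypes = np.asarray(subtypes, dtype=object)
    if not (subtypes == target_name).any():
        raise ValueError(f"subtype {target_name!r} not present in cohort")
    y = (subtypes == target_name).astype(float)
    return SubtypeContrast(y=y, target_name=target_name)


# ---------------------------------------------------------------------------
# Lesion-volume residualization


def residualize_volume(
    X: np.ndarray, y: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Regress total lesion volume out of the design and the outcome.

    Each column of X and the outcome y are replaced by OLS residuals on
    the design [1, v].  Residuals have exactly zero sample covariance with
    v, and the operation is idempotent.  A constant v degenerates to
    mean-centering (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(v)
    if X.shape[0] != n or y.shape[0] != n:
        raise ValueError("X, y and v must agree on the number of subjects")
    if (v <= 0).any():
        raise ValueError("lesion volumes must be strictly positive")
    if np.ptp(v) == 0:
        warnings.warn("constant lesion volume: falling back to mean-centering")
        return X - X.mean(axis=0), y - y.mean()
    D = np.column_stack([np.ones(n), v])
    # hat residual operator applied via least squares (rank-2 design)
    coef_X, *_ = np.linalg.lstsq(D, X, rcond=None)
    coef_y, *_ = np.linalg.lstsq(D, y, rcond=None)
    return X - D @ coef_X, y - D @ coef_y


# ---------------------------------------------------------------------------
# SVR fit and backprojection


@dataclass
class SvrModel:
    """A fitted epsilon-SVR in dual form.

    ``alpha`` holds the signed dual coefficients at ``support`` rows of the
    training matrix; prediction is f(x) = sum_i alpha_i k(x_i, x) + bias.
    """

    support: np.ndarray
    alpha: np.ndarray
    bias: float
    X_support: np.ndarray
    kernel: str
    gamma: float | None
    C: float
    epsilon: float
    dual_objective: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if len(self.support) == 0:
            return np.full(X.shape[0], self.bias)
        if self.kernel == "linear":
            K = X @ self.X_support.T
        else:
            d2 = (
                (X**2).sum(axis=1)[:, None]
                + (self.X_support**2).sum(axis=1)[None, :]
                - 2.0 * X @ self.X_support.T
            )
            K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.alpha + self.bias


def resolve_gamma(gamma, X: np.ndarray) -> float:
    """Resolve 'scale' to 1 / (n_features * var(X)), else pass through."""
    if gamma == "scale":
        var = X.var()
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return float(gamma)


class KernelCache:
    """Pairwise squared distances of a fixed design, Gram matrices on demand.

    Permutation inference refits the same X' thousands of times with only
    y shuffled; the Gram matrix depends on X' and gamma alone, so it is
    computed once and sliced per fold.
    """

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        sq = (self.X**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (self.X @ self.X.T)
        np.maximum(d2, 0.0, out=d2)
        self._d2 = d2
        self._gram: dict[tuple[str, float], np.ndarray] = {}

    def gram(self, kernel: str, gamma: float | None) -> np.ndarray:
        key = (kernel, float(gamma) if gamma is not None else 0.0)
        if key not in self._gram:
            if kernel == "linear":
                self._gram[key] = self.X @ self.X.T
            else:
                self._gram[key] = np.exp(-gamma * self._d2)
        return self._gram[key]


def _dual_objective(alpha_full, K, y, epsilon) -> float:
    return float(
        y @ alpha_full
        - 0.5 * alpha_full @ K @ alpha_full
        - epsilon * np.abs(alpha_full).sum()
    )


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float | None = None,
    epsilon: float = 0.1,
    kernel: str = "rbf",
    gram: np.ndarray | None = None,
    tol: float = 1e-6,
) -> SvrModel:
    """Fit an epsilon-SVR in the dual and return signed dual coefficients.

    With ``gram`` supplied, the solver runs on the precomputed Gram matrix
    (rows of X are still needed for backprojection).  The attained dual
    objective is stored for diagnostics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in SVR inputs")
    if kernel == "rbf" and gamma is None and gram is None:
        raise ValueError("gamma required for the RBF kernel")
    if gram is not None:
        if not np.isfinite(gram).all():
            raise ValueError("non-finite kernel values")
        svr = SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol)
        svr.fit(gram, y)
        K = gram
    elif kernel == "linear":
        svr = SVR(kernel="linear", C=C, epsilon=epsilon, tol=tol)
        svr.fit(X, y)
        K = X @ X.T
    else:
        svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon, tol=tol)
        svr.fit(X, y)
        K = None
    support = svr.support_.astype(np.int64)
    alpha = svr.dual_coef_.ravel().astype(float)
    if K is None:
        cache = KernelCache(X)
        K = cache.gram("rbf", gamma)
    alpha_full = np.zeros(X.shape[0])
    alpha_full[support] = alpha
    return SvrModel(
        support=support,
        alpha=alpha,
        bias=float(svr.intercept_[0]),
        X_support=X[support],
        kernel=kernel,
        gamma=gamma,
        C=C,
        epsilon=epsilon,
        dual_objective=_dual_objective(alpha_full, K, y, epsilon),
    )


def beta_map(model: SvrModel, X: np.ndarray | None = None) -> np.ndarray:
    """Backproject the kernel-space weight vector onto voxel axes.

    beta_j = sum_i alpha_i X'_ij over support rows.  For a linear kernel
    this equals the primal weight vector exactly; for the RBF kernel it is
    the standard sensitivity-map projection used in multivariate
    lesion-symptom mapping.
    """
    Xs = model.X_support if X is None else np.asarray(X, dtype=float)[model.support]
    if len(model.alpha) == 0:
        ncol = Xs.shape[1] if Xs.ndim == 2 else 0
        return np.zeros(ncol)
    return Xs.T @ model.alpha


# ---------------------------------------------------------------------------
# Hyperparameter optimization (GP + expected improvement)


@dataclass
class OptimizationTrace:
    points: np.ndarray  # (n, 2) log10(C), log10(gamma)
    losses: np.ndarray
    best_index: int


def _cv_mse(
    X, y, C, gamma, epsilon, folds, cache: KernelCache, kernel: str
) -> float:
    K = cache.gram(kernel, gamma)
    err = 0.0
    n = len(y)
    for train, test in folds:
        svr = SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=1e-6)
        svr.fit(K[np.ix_(train, train)], y[train])
        pred = svr.predict(K[np.ix_(test, train)])
        err += ((pred - y[test]) ** 2).sum()
    return err / n


def _make_folds(n, cv_folds, seed, strata=None):
    idx = np.arange(n)
    if strata is not None:
        strata = np.asarray(strata)
        _, counts = np.unique(strata, return_counts=True)
        if counts.min() >= cv_folds:
            kf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            return [(tr, te) for tr, te in kf.split(idx, strata)]
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(idx)]


def _expected_improvement(mu, sd, best) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return sd * (z * stats.norm.cdf(z) + stats.norm.pdf(z))


def optimize_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    iterations: int = 200,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-3, 1e3), (1e-3, 1e3)),
    seed: int = 0,
    cv_folds: int = 5,
    epsilon: float = 0.1,
    strata: np.ndarray | None = None,
    kernel: str = "rbf",
    cache: KernelCache | None = None,
    return_trace: bool = False,
):
    """Bayesian optimization of (C, gamma) over a log-scaled box.

    The objective is the k-fold cross-validated mean squared prediction
    error (folds fixed across evaluations).  A Gaussian process with a
    Matern-5/2 kernel is fit to the observed (log10 C, log10 gamma) ->
    loss surface and the next point maximizes expected improvement over a
    seeded candidate cloud.  Deterministic given the seed; returns the
    best observed point.
    """
    if iterations < 10:
        raise ValueError("iterations must be >= 10")
    (c_lo, c_hi), (g_lo, g_hi) = bounds
    if not (0 < c_lo < c_hi and 0 < g_lo < g_hi):
        raise ValueError("degenerate hyperparameter bounds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng([0x68796F70, seed])  # component-tagged stream
    lo = np.log10([c_lo, g_lo])
    hi = np.log10([c_hi, g_hi])
    folds = _make_folds(len(y), cv_folds, seed, strata)
    if cache is None:
        cache = KernelCache(X)

    def objective(theta):
        C = 10.0 ** theta[0]
        gamma = 10.0 ** theta[1] if kernel == "rbf" else None
        return _cv_mse(X, y, C, gamma, epsilon, folds, cache, kernel)

    n_initial = min(max(5, iterations // 4), 10, iterations)
    points = list(lo + (hi - lo) * rng.random((n_initial, 2)))
    losses = [objective(p) for p in points]

    gp_kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=[1.0, 1.0], length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-6, (1e-12, 1e1))
    while len(points) < iterations:
        gp = GaussianProcessRegressor(
            kernel=gp_kernel, normalize_y=True, random_state=0, alpha=1e-10
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(points), np.asarray(losses))
        cand = lo + (hi - lo) * rng.random((256, 2))
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, float(np.min(losses)))
        theta = cand[int(np.argmax(ei))]
        points.append(theta)
        losses.append(objective(theta))

    points = np.asarray(points)
    losses = np.asarray(losses)
    best = int(np.argmin(losses))
    C_star = float(10.0 ** points[best, 0])
    gamma_star = float(10.0 ** points[best, 1]) if kernel == "rbf" else None
    if return_trace:
        return (C_star, gamma_star), OptimizationTrace(points, losses, best)
    return C_star, gamma_star


# ---------------------------------------------------------------------------
# Cross-validated beta map


@dataclass
class BetaMap:
    """Averaged voxelwise beta map with its standardized z map.

    ``z`` is (beta - mean) / SD across retained voxels (population SD);
    the display convention negates z so that stronger subtype association
    reads as lower z (see :meth:`display_z`).
    """

    beta: np.ndarray
    z: np.ndarray
    voxel_index: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None
    fold_betas: np.ndarray | None = None

    def display_z(self) -> np.ndarray:
        return -self.z


def zscore_map(beta: np.ndarray) -> np.ndarray:
    """Standardize a beta map across retained voxels (population SD).

    A constant map maps to all zeros.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size < 2:
        raise ValueError("need at least 2 retained voxels")
    sd = beta.std(ddof=1)
    if sd == 0:
        return np.zeros_like(beta)
    return (beta - beta.mean()) / sd


def crossval_beta(
    X: np.ndarray,
    y: np.ndarray,
    config: SvrLsmConfig,
    C: float,
    gamma: float | None,
    strata: np.ndarray | None = None,
    cache: KernelCache | None = None,
    fold_seed: int | None = None,
    voxel_index: np.ndarray | None = None,
    grid_shape=None,
    keep_folds: bool = False,
) -> BetaMap:
    """Fold-averaged beta map: fit on each training fold, average the maps.

    Folds are seeded and stratified by ``strata`` (the raw outcome group)
    when every class has at least ``cv_folds`` members.  Each fold's beta
    map is backprojected from its training fit only; the fold maps are
    averaged arithmetically and standardized into z.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < config.cv_folds:
        raise ValueError("need at least cv_folds subjects")
    seed = config.seed if fold_seed is None else fold_seed
    folds = _make_folds(n, config.cv_folds, seed, strata)
    if strata is not None:
        strata_arr = np.asarray(strata)
        for attempt in range(2):
            bad = any(len(np.unique(strata_arr[tr])) < 2 for tr, _ in folds)
            if not bad:
                break
            if attempt == 0:
                warnings.warn("single-class training fold; reshuffling once")
                folds = _make_folds(n, config.cv_folds, seed + 1, strata)
            else:
                raise ValueError("could not build folds with both outcome classes")
    if cache is None:
        cache = KernelCache(X)
    K = cache.gram(config.kernel, gamma)
    fold_betas = np.empty((len(folds), X.shape[1]))
    for f, (train, _test) in enumerate(folds):
        model = fit_svr(
            X[train],
            y[train],
            C=C,
            gamma=gamma,
            epsilon=config.epsilon,
            kernel=config.kernel,
            gram=K[np.ix_(train, train)],
        )
        sup = train[model.support]
        fold_betas[f] = X[sup].T @ model.alpha if len(sup) else 0.0
    beta = fold_betas.mean(axis=0)
    return BetaMap(
        beta=beta,
        z=zscore_map(beta),
        voxel_index=voxel_index,
        grid_shape=tuple(grid_shape) if grid_shape is not None else None,
        fold_betas=fold_betas if keep_folds else None,
    )
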