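"""Genomic prediction: ridge-regression BLUP, support-vector regression,
and replicated cross-validated accuracy estimation.

Ridge-regression BLUP fits the mixed model y = 1 mu + Z u + e with all
marker effects u random and a common variance; the shrinkage parameter
lambda = sigma_e^2 / sigma_u^2 is estimated by REML using the spectrum of
the marker cross-product, after which (mu, u) solve the ridge normal
equations.  SVR is epsilon-insensitive support-vector regression with a
radial-basis kernel (cost 1, gamma 1/m, epsilon 0.1 by default; these match
the defaults of the standard libsvm interface).

Accuracy at one design point is the mean, over independently simulated
genotype/phenotype data sets and independent random 80/20 train/test
splits, of the Pearson correlation between held-out phenotypes and their
predictions.  BLUP and SVR consume identical data sets and splits so the
difference response can be computed replicate-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.svm import SVR

from .errors import ConfigurationError, ConstraintViolation
from .population import GenomeSpec, place_qtl, simulate_dh_genotypes
from .trait_model import simulate_trait

__all__ = [
    "DesignPoint",
    "SVRConfig",
    "PredictionResult",
    "AccuracyEstimate",
    "AccuracyComparison",
    "fit_rrblup",
    "fit_svr",
    "make_cv_splits",
    "estimate_accuracy",
]

LAMBDA_FLOOR = 1e-8


@dataclass(frozen=True)
class DesignPoint:
    """One factor combination of the five simulation factors."""

    n_individuals: int
    n_markers: int
    n_qtl: int
    epi_proportion: float
    heritability: float

    def __post_init__(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ConstraintViolation("qtl must not exceed the number of markers")
        if self.n_individuals < 5:
            raise ConfigurationError("need at least 5 individuals for an 80/20 split")
        if not 0.0 <= self.epi_proportion <= 1.0:
            raise ConfigurationError("epi_proportion must lie in [0, 1]")
        if not 0.0 < self.heritability <= 1.0:
            raise ConfigurationError("heritability must lie in (0, 1]")

    def as_dict(self) -> dict:
        return {
            "ind": self.n_individuals,
            "m": self.n_markers,
            "qtl": self.n_qtl,
            "epi": self.epi_proportion,
            "h": self.heritability,
        }


@dataclass(frozen=True)
class SVRConfig:
    kernel: str = "rbf"
    cost: float = 1.0
    gamma: float | None = None  # None -> 1/m
    epsilon: float = 0.1


@dataclass
class PredictionResult:
    predictions: np.ndarray
    method: str
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class AccuracyEstimate:
    """Replicated cross-validated accuracies for one predictor at one point."""

    mean_r: float
    per_replicate_r: np.ndarray
    method: str
    n_datasets: int
    n_splits_per_dataset: int
    design_point: DesignPoint | None = None
    n_degenerate: int = 0

    @property
    def sd_r(self) -> float:
        return float(np.std(self.per_replicate_r, ddof=1)) if len(self.per_replicate_r) > 1 else 0.0

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate_r)


@dataclass
class AccuracyComparison:
    """Paired BLUP/SVM accuracies on shared data sets and splits."""

    blup: AccuracyEstimate
    svm: AccuracyEstimate

    @property
    def per_replicate_diff(self) -> np.ndarray:
        return self.svm.per_replicate_r - self.blup.per_replicate_r

    @property
    def mean_diff(self) -> float:
        return float(np.mean(self.per_replicate_diff))


def _profile_criterion(Zc: np.ndarray, yc: np.ndarray):
    """Negative restricted profile likelihood of log(lambda), up to a constant.

    Works in the spectrum of the marker cross-product: eigenvalues xi_i of
    Zc' Zc (equivalently the nonzero eigenvalues of Zc Zc') together with the
    squared projections of y onto the corresponding directions reduce the
    restricted likelihood to a cheap one-dimensional profile.
    """
    n, m = Zc.shape
    if m <= n:
        G = Zc.T @ Zc
        w, V = np.linalg.eigh(G)
        proj = V.T @ (Zc.T @ yc)
        pos = w > max(w.max(), 1.0) * 1e-12
        xi = w[pos]
        eta2 = proj[pos] ** 2 / xi
    else:
        K = Zc @ Zc.T
        w, U = np.linalg.eigh(K)
        pos = w > max(w.max(), 1.0) * 1e-12
        xi = w[pos]
        eta2 = (U[:, pos].T @ yc) ** 2
    ssnull = max(float(yc @ yc) - float(eta2.sum()), 0.0)
    df = n - 1  # one fixed effect (the intercept) is projected out
    r = len(xi)

    def neg_restricted_ll(loglam: float) -> float:
        lam = np.exp(loglam)
        s2 = (np.sum(eta2 / (xi + lam)) + ssnull / lam) / df
        return df * np.log(s2) + np.sum(np.log(xi + lam)) + (df - r) * np.log(lam)

    return neg_restricted_ll


def _reml_lambda(Zc: np.ndarray, yc: np.ndarray) -> float:
    """REML estimate of lambda = sigma_e^2 / sigma_u^2."""
    crit = _profile_criterion(Zc, yc)
    res = minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded")
    return max(float(np.exp(res.x)), LAMBDA_FLOOR)


def fit_rrblup(
    train_genotypes: np.ndarray,
    train_phenotypes: np.ndarray,
    test_genotypes: np.ndarray,
    lam: float | None = None,
) -> PredictionResult:
    """Ridge-regression BLUP predictions for the test lines.

    With ``lam`` given, the (mu, u) solution of the ridge normal equations

        [[n, 1'Z], [Z'1, Z'Z + lam I]] (mu, u) = (1'y, Z'y)

    is computed directly; otherwise ``lam`` is first estimated by REML.
    Constant training phenotypes fall back to mean prediction with a warning.
    """
    Z = np.asarray(train_genotypes, dtype=float)
    y = np.asarray(train_phenotypes, dtype=float)
    Zt = np.asarray(test_genotypes, dtype=float)
    n, m = Z.shape
    if n < 2:
        raise ConfigurationError("need at least 2 training lines")
    if Zt.shape[1] != m:
        raise ConfigurationError("train and test marker columns differ")
    if np.ptp(y) == 0.0:
        warnings.warn("constant training phenotypes; falling back to mean prediction")
        return PredictionResult(
            np.full(Zt.shape[0], y[0]), "BLUP", {"lambda": None, "degenerate": True}
        )
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    yc = y - y.mean()
    if lam is None:
        lam = _reml_lambda(Zc, yc)
    A = Zc.T @ Zc + lam * np.eye(m)
    u = np.linalg.solve(A, Zc.T @ yc)
    mu = float(y.mean())
    preds = mu + (Zt - zbar) @ u
    return PredictionResult(preds, "BLUP", {"lambda": float(lam), "mu": mu})


def fit_svr(
    train_genotypes: np.ndarray,
    train_phenotypes: np.ndarray,
    test_genotypes: np.ndarray,
    kernel_config: SVRConfig | None = None,
) -> PredictionResult:
    """Epsilon-insensitive SVR predictions for the test lines."""
    cfg = kernel_config or SVRConfig()
    Z = np.asarray(train_genotypes, dtype=float)
    y = np.asarray(train_phenotypes, dtype=float)
    Zt = np.asarray(test_genotypes, dtype=float)
    if Z.shape[0] < 2:
        raise ConfigurationError("need at least 2 training lines")
    gamma = cfg.gamma if cfg.gamma is not None else 1.0 / Z.shape[1]
    model = SVR(kernel=cfg.kernel, C=cfg.cost, gamma=gamma, epsilon=cfg.epsilon, cache_size=500)
    model.fit(Z, y)
    preds = model.predict(Zt)
    return PredictionResult(
        preds, "SVM", {"kernel": cfg.kernel, "cost": cfg.cost, "gamma": gamma, "epsilon": cfg.epsilon}
    )


def make_cv_splits(
    n: int,
    test_fraction: float = 0.2,
    n_splits: int = 25,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent random train/test partitions (not a rotation-fold scheme).

    Each split assigns round(test_fraction * n) lines to the test set.
    """
    n_test = round(test_fraction * n)
    if n < 5 or n_test < 1 or n_test >= n:
        raise ConfigurationError(f"cannot build a {test_fraction:.0%} test set from n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        splits.append((perm[n_test:], perm[:n_test]))
    return splits


def _pearson(y: np.ndarray, yhat: np.ndarray) -> tuple[float, bool]:
    """Pearson r, with zero-variance cases recorded as 0 and flagged."""
    if np.ptp(y) == 0.0 or np.ptp(yhat) == 0.0:
        return 0.0, True
    return float(np.corrcoef(y, yhat)[0, 1]), False


def estimate_accuracy(
    design_point: DesignPoint,
    method: str = "both",
    n_datasets: int = 20,
    n_splits: int = 25,
    seed: int = 0,
    test_fraction: float = 0.2,
    genome: GenomeSpec | None = None,
    svr_config: SVRConfig | None = None,
    pairing: str = "disjoint",
    qtl_rule: str = "evenly_spaced",
    fixed_lambda: float | None = None,
    predictor=None,
):
    """Replicated cross-validated accuracy at one design point.

    For each of ``n_datasets`` independently simulated genotype/phenotype
    data sets, ``n_splits`` random train/test splits are drawn and each
    requested predictor is fit on the training lines and scored by the
    Pearson correlation between held-out phenotypes and predictions
    (20 x 25 = 500 replicates by default).  Returns an
    :class:`AccuracyEstimate` for ``method`` in {"blup", "svm"} and an
    :class:`AccuracyComparison` (shared data and splits) for ``"both"``.
    ``predictor`` may be a callable ``f(Ztrain, ytrain, Ztest) -> preds``
    to score a custom prediction rule.
    """
    if method not in ("blup", "svm", "both") and predictor is None:
        raise ConfigurationError(f"unknown method {method!r}")
    dp = design_point
    spec = genome or GenomeSpec(
        n_markers=dp.n_markers,
        remainder_policy="strict" if dp.n_markers % 10 == 0 else "spread",
    )
    want_blup = predictor is None and method in ("blup", "both")
    want_svm = predictor is None and method in ("svm", "both")
    r_blup, r_svm, r_custom = [], [], []
    deg_blup = deg_svm = deg_custom = 0
    for d in range(n_datasets):
        sim_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(d, 0)))
        split_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(d, 1)))
        pop = simulate_dh_genotypes(spec, dp.n_individuals, sim_rng)
        pop = place_qtl(pop, dp.n_qtl, rule=qtl_rule, seed=sim_rng)
        phen, _ = simulate_trait(
            pop, dp.epi_proportion, dp.heritability, seed=sim_rng, pairing=pairing
        )
        G, y = pop.genotypes, phen.values
        for tr, te in make_cv_splits(dp.n_individuals, test_fraction, n_splits, split_rng):
            if want_blup:
                pr = fit_rrblup(G[tr], y[tr], G[te], lam=fixed_lambda)
                r, deg = _pearson(y[te], pr.predictions)
                r_blup.append(r)
                deg_blup += deg
            if want_svm:
                pr = fit_svr(G[tr], y[tr], G[te], svr_config)
                r, deg = _pearson(y[te], pr.predictions)
                r_svm.append(r)
                deg_svm += deg
            if predictor is not None:
                r, deg = _pearson(y[te], np.asarray(predictor(G[tr], y[tr], G[te])))
                r_custom.append(r)
                deg_custom += deg

    def _estimate(rs, name, ndeg):
        rs = np.asarray(rs)
        return AccuracyEstimate(
            mean_r=float(rs.mean()),
            per_replicate_r=rs,
            method=name,
            n_datasets=n_datasets,
            n_splits_per_dataset=n_splits,
            design_point=dp,
            n_degenerate=ndeg,
        )

    if predictor is not None:
        return _estimate(r_custom, "custom", deg_custom)
    if method == "blup":
        return _estimate(r_blup, "BLUP", deg_blup)
    if method == "svm":
        return _estimate(r_svm, "SVM", deg_svm)
    return AccuracyComparison(
        blup=_estimate(r_blup, "BLUP", deg_blup), svm=_estimate(r_svm, "SVM", deg_svm)
    )
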