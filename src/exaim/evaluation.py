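"""Panel evaluation: PCA of encoded genotypes, per-population Gaussians,
and Monte Carlo misclassification probabilities.

Genotypes are encoded numerically (0|0 = 0, 0|1 or 1|0 = 1, 1|1 = 2,
missing = NA), imputed, centered and (by default) unit-variance scaled, and
projected onto the top d = 3 principal components.  Each population's score
cloud is modelled as a multivariate normal (mu_k, Sigma_k).  The probability
of misclassifying a sample of population i into population j is

    P_m(i, j) = integral over {x : f_i(x) < f_j(x)} of f_i(x)

estimated by Monte Carlo from f_i with a binomial standard error; the
overall panel score P_AIM sums P_m over all ordered pairs, so a smaller
P_AIM means farther-separated populations.  Density comparison uses
log-densities; with the strict inequality, identical Gaussians give
P_m = 0 by construction (degenerate case, kept as documented).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, multivariate_normal

from .io_formats import GenotypeMatrix, VariantKey

__all__ = [
    "NumericGenotypeTable",
    "PcaModel",
    "PopulationGaussian",
    "MisclassificationReport",
    "ConfidenceEllipse",
    "encode_genotypes",
    "impute_missing",
    "fit_pca",
    "project_pca",
    "fit_population_gaussians",
    "misclassification_probability",
    "panel_misclassification",
    "confidence_ellipse",
    "plot_scores",
]


@dataclass
class NumericGenotypeTable:
    samples: list[str]
    variants: list[VariantKey]
    values: np.ndarray  # (n, m), {0,1,2} or NaN
    provenance: str = "dosage-encoded"

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def encode_genotypes(g: GenotypeMatrix) -> NumericGenotypeTable:
    """Numeric encoding of biallelic genotypes (identity on dosages)."""
    if g.multiallelic.any():
        bad = [str(g.variants[i]) for i in np.flatnonzero(g.multiallelic)[:5]]
        raise ValueError(f"multi-allelic markers present, filter first: {bad}")
    return NumericGenotypeTable(
        samples=list(g.samples),
        variants=list(g.variants),
        values=g.dosages.copy(),
    )


def impute_missing(
    t: NumericGenotypeTable,
    method: str = "column_mean",
    rank: int = 3,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> NumericGenotypeTable:
    """Fill missing genotype entries before PCA.

    ``column_mean`` (default) replaces each hole with the marker's observed
    mean.  ``iterative`` alternates a rank-``rank`` SVD reconstruction with
    re-filling the holes until the largest change is below ``tol`` (low-rank
    matrix completion; exact on noiseless low-rank input).
    """
    X = t.values.copy()
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        bad = [str(t.variants[i]) for i in np.flatnonzero(miss.all(axis=0))[:5]]
        raise ValueError(f"fully missing markers cannot be imputed: {bad}")
    col_mean = np.nanmean(t.values, axis=0)
    X[miss] = np.take(col_mean, np.where(miss)[1])
    if method == "column_mean" or not miss.any():
        pass
    elif method == "iterative":
        for _ in range(max_iter):
            U, S, Vt = np.linalg.svd(X, full_matrices=False)
            low = (U[:, :rank] * S[:rank]) @ Vt[:rank]
            delta = np.max(np.abs(low[miss] - X[miss])) if miss.any() else 0.0
            X[miss] = low[miss]
            if delta < tol:
                break
    else:
        raise ValueError("method must be 'column_mean' or 'iterative'")
    return NumericGenotypeTable(
        samples=list(t.samples), variants=list(t.variants), values=X,
        provenance=f"{t.provenance}+imputed({method})",
    )


@dataclass
class PcaModel:
    """Stored PCA transform: centering, scaling and orthonormal loadings."""

    variants: list[VariantKey]  # markers retained by the fit (zero-variance dropped)
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (m_kept, d), columns orthonormal
    scores: np.ndarray  # (n_train, d)
    explained_variance: np.ndarray
    input_variants: list[VariantKey] = field(default_factory=list)
    kept: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def d(self) -> int:
        return self.loadings.shape[1]


def fit_pca(t: NumericGenotypeTable, d: int = 3, scale: bool = True) -> PcaModel:
    """PCA of an imputed genotype table.

    Markers are centered and, when ``scale`` (default), divided by their
    standard deviation; zero-variance markers are dropped with a warning.
    Sign convention: each loading's largest-magnitude entry is positive.
    """
    X = np.asarray(t.values, dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing values before PCA")
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    std = X.std(axis=0)
    kept = np.flatnonzero(std > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} zero-variance markers", stacklevel=2
        )
    Xk = X[:, kept]
    means = Xk.mean(axis=0)
    scales = Xk.std(axis=0) if scale else np.ones(kept.size)
    Z = (Xk - means) / scales
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if d > rank:
        raise ValueError(f"d={d} exceeds matrix rank {rank}")
    loadings = Vt[:d].T  # (m, d)
    # deterministic sign: largest-|entry| of each loading positive
    for c in range(d):
        i = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[i, c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = Z @ loadings
    ev = (S[:d] ** 2) / max(X.shape[0] - 1, 1)
    return PcaModel(
        variants=[t.variants[i] for i in kept],
        means=means,
        scales=scales,
        loadings=loadings,
        scores=scores,
        explained_variance=ev,
        input_variants=list(t.variants),
        kept=kept,
    )


def project_pca(model: PcaModel, t: NumericGenotypeTable) -> np.ndarray:
    """Project a table onto a fitted PCA (same markers, same order); never refits."""
    if [v.sort_key for v in t.variants] != [v.sort_key for v in model.input_variants]:
        raise ValueError("marker list does not match the fitted PCA model")
    X = np.asarray(t.values, dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing values before projection")
    Z = (X[:, model.kept] - model.means) / model.scales
    return Z @ model.loadings


@dataclass
class PopulationGaussian:
    label: str
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape mismatch")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")


def fit_population_gaussians(
    scores: np.ndarray, labels: Sequence[str], ridge: float = 1e-9
) -> dict[str, PopulationGaussian]:
    """Fit mu_k and unbiased Sigma_k per population from PC scores.

    A numerically singular covariance gets ``ridge * I`` added with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    d = scores.shape[1]
    out: dict[str, PopulationGaussian] = {}
    for pop in sorted(set(labels.tolist())):
        pts = scores[labels == pop]
        if pts.shape[0] < d + 1:
            raise ValueError(
                f"population {pop!r} has {pts.shape[0]} samples, needs >= {d + 1}"
            )
        mu = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        if np.linalg.eigvalsh(cov).min() < 1e-12:
            warnings.warn(f"singular covariance for {pop!r}; adding ridge", stacklevel=2)
            cov = cov + ridge * np.eye(d)
        out[pop] = PopulationGaussian(label=pop, mean=mu, cov=cov)
    return out


def misclassification_probability(
    fi: PopulationGaussian,
    fj: PopulationGaussian,
    n_mc: int = 1_000_000,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[float, float]:
    """Monte Carlo estimate of P_m(i, j) with its binomial standard error.

    Draws ``n_mc`` points from f_i and returns the fraction where
    log f_i(x) < log f_j(x) strictly.
    """
    if fi.mean.size != fj.mean.size:
        raise ValueError("dimension mismatch between Gaussians")
    for gk in (fi, fj):
        if np.linalg.eigvalsh(gk.cov).min() < 0:
            raise ValueError(f"covariance of {gk.label!r} is not PSD")
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(fi.mean, fi.cov, size=n_mc, method="cholesky")
    li = multivariate_normal(fi.mean, fi.cov, allow_singular=True).logpdf(x)
    lj = multivariate_normal(fj.mean, fj.cov, allow_singular=True).logpdf(x)
    p = float(np.mean(li < lj))
    se = float(np.sqrt(p * (1.0 - p) / n_mc))
    return p, se


@dataclass
class MisclassificationReport:
    populations: list[str]
    pm: dict[tuple[str, str], float]  # ordered pairs i != j
    se: dict[tuple[str, str], float]
    p_aim: float
    n_mc: int
    seed: int | None


def panel_misclassification(
    gaussians: Mapping[str, PopulationGaussian],
    n_mc: int = 1_000_000,
    seed: int | None = None,
) -> MisclassificationReport:
    """P_m(i, j) for every ordered pair and the panel score P_AIM = sum of all."""
    pops = sorted(gaussians)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    pairs = [(i, j) for i in pops for j in pops if i != j]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs))
    pm: dict[tuple[str, str], float] = {}
    se: dict[tuple[str, str], float] = {}
    for (i, j), child in zip(pairs, children):
        pm[(i, j)], se[(i, j)] = misclassification_probability(
            gaussians[i], gaussians[j], n_mc=n_mc, seed=child
        )
    return MisclassificationReport(
        populations=pops, pm=pm, se=se, p_aim=float(sum(pm.values())),
        n_mc=n_mc, seed=seed,
    )


@dataclass
class ConfidenceEllipse:
    center: np.ndarray
    semi_axes: np.ndarray  # descending
    rotation_rad: float  # angle of the major axis
    level: float


def confidence_ellipse(
    gk: PopulationGaussian, level: float = 0.95, dims: tuple[int, int] = (0, 1)
) -> ConfidenceEllipse:
    """Equal-density contour of the 2-D marginal Gaussian enclosing ``level``.

    The squared Mahalanobis radius is the chi-square(2) quantile of ``level``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    i, j = dims
    cov2 = gk.cov[np.ix_([i, j], [i, j])]
    center = gk.mean[[i, j]]
    evals, evecs = np.linalg.eigh(cov2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r2 = chi2.ppf(level, df=2)
    semi = np.sqrt(np.clip(evals, 0.0, None) * r2)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(center=center, semi_axes=semi, rotation_rad=angle,
                             level=level)


def plot_scores(
    scores: np.ndarray,
    labels: Sequence[str],
    gaussians: Mapping[str, PopulationGaussian] | None = None,
    levels: Sequence[float] = (0.95, 0.99),
    path: str | None = None,
):
    """Convenience scatter of PC1/PC2 scores with optional confidence ellipses."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(labels)
    for pop in sorted(set(labels.tolist())):
        pts = scores[labels == pop]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, label=pop, alpha=0.6)
    if gaussians:
        for pop, gk in gaussians.items():
            for lev, ls in zip(levels, ("-", "--")):
                e = confidence_ellipse(gk, level=lev)
                ax.add_patch(MplEllipse(
                    e.center, 2 * e.semi_axes[0], 2 * e.semi_axes[1],
                    angle=np.degrees(e.rotation_rad), fill=False, ls=ls, lw=1,
                ))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
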