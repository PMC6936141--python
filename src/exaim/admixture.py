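"""Supervised ancestry-proportion estimation from fixed reference frequencies.

The model: a diploid individual with ancestry vector q (on the K-simplex)
carries, at marker j, an alternate allele with probability
pi_j = sum_k q_k p_kj, where p_kj is the reference alternate-allele frequency
of population k.  Unlinked markers give the binomial log-likelihood

    L(q) = sum_j [ g_j ln(pi_j) + (2 - g_j) ln(1 - pi_j) ]

over non-missing genotypes g_j in {0, 1, 2}.  This is the likelihood that
model-based structure tools optimize in supervised mode; with reference
frequencies held fixed it is concave in q, so a single EM run from the
uniform start suffices (random restarts are available for robustness
checks).  Missing genotypes are dropped per marker, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io_formats import GenotypeMatrix, VariantKey
from .popgen_stats import FrequencyTable

__all__ = [
    "ReferencePanel",
    "AdmixtureResult",
    "AccuracyReport",
    "ClassifiedSample",
    "build_reference_panel",
    "admixture_loglik",
    "estimate_admixture_em",
    "estimate_cohort",
    "classify_sample",
    "error_rate",
    "concordance_correlation",
    "write_q_matrix",
]

_SIMPLEX_TOL = 1e-6


@dataclass
class ReferencePanel:
    """Per-population alternate-allele frequencies at panel markers.

    Frequencies are clamped into [epsilon, 1 - epsilon] so that likelihoods
    stay finite at fixed alleles.
    """

    variants: list[VariantKey]
    populations: list[str]
    freqs: np.ndarray  # (K, M), clamped
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.populations), len(self.variants)):
            raise ValueError("frequency matrix shape mismatch")
        if len({v.sort_key for v in self.variants}) != len(self.variants):
            raise ValueError("duplicate markers in reference panel")
        if np.isnan(self.freqs).any():
            raise ValueError("reference panel has undefined frequencies")
        self.freqs = np.clip(self.freqs, self.epsilon, 1.0 - self.epsilon)

    @property
    def K(self) -> int:
        return len(self.populations)

    @property
    def n_markers(self) -> int:
        return len(self.variants)

    @classmethod
    def from_tsv(cls, path, epsilon: float = 1e-6) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        ft = FrequencyTable.from_frame(df)
        return build_reference_panel(ft, epsilon=epsilon)


def build_reference_panel(
    freqs: FrequencyTable, populations: Sequence[str] | None = None,
    epsilon: float = 1e-6,
) -> ReferencePanel:
    """Build a clamped reference panel from an allele-frequency table."""
    pops = list(populations) if populations is not None else list(freqs.populations)
    idx = [freqs.populations.index(p) for p in pops]
    mat = freqs.pop_freq[idx, :]
    if np.isnan(mat).any():
        bad = [str(freqs.variants[m]) for m in np.flatnonzero(np.isnan(mat).any(axis=0))]
        raise ValueError(f"undefined reference frequency at markers: {bad[:5]}")
    return ReferencePanel(
        variants=list(freqs.variants), populations=pops, freqs=mat, epsilon=epsilon
    )


@dataclass
class AdmixtureResult:
    q: np.ndarray  # (K,), on the simplex
    populations: list[str]
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


class ClassifiedSample(NamedTuple):
    label: str
    tie: bool


def _check_simplex(q: np.ndarray, K: int) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (K,):
        raise ValueError(f"q must have length {K}")
    if (q < -_SIMPLEX_TOL).any() or abs(q.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError(f"q is off the simplex: {q}")
    return np.clip(q, 0.0, None)


def admixture_loglik(g: np.ndarray, q: np.ndarray, ref: ReferencePanel) -> float:
    """Binomial admixture log-likelihood; missing markers contribute 0."""
    g = np.asarray(g, dtype=float)
    if g.shape != (ref.n_markers,):
        raise ValueError("genotype vector length != marker count")
    q = _check_simplex(q, ref.K)
    m = ~np.isnan(g)
    if not m.any():
        return 0.0
    pi = q @ ref.freqs[:, m]
    gv = g[m]
    return float(np.sum(gv * np.log(pi) + (2.0 - gv) * np.log(1.0 - pi)))


def estimate_admixture_em(
    g: np.ndarray,
    ref: ReferencePanel,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> AdmixtureResult:
    """Maximum-likelihood ancestry vector by EM with fixed reference frequencies.

    Each iteration attributes the 2M observed alleles to source populations
    in proportion to q_k p_kj / pi_j (alternate) and q_k (1-p_kj) / (1-pi_j)
    (reference), then renormalizes.  The log-likelihood is non-decreasing;
    iteration stops when its improvement drops below ``tol``.
    """
    g = np.asarray(g, dtype=float)
    if g.shape != (ref.n_markers,):
        raise ValueError("genotype vector length != marker count")
    mask = ~np.isnan(g)
    M = int(mask.sum())
    if M == 0:
        raise ValueError("no non-missing genotypes to estimate from")
    P = ref.freqs[:, mask]  # (K, M)
    gv = g[mask]
    K = ref.K
    if K == 1:
        q = np.array([1.0])
        ll = admixture_loglik(g, q, ref)
        return AdmixtureResult(q=q, populations=list(ref.populations), loglik=ll,
                               n_iter=0, converged=True, loglik_trace=np.array([ll]))
    q = (
        np.full(K, 1.0 / K)
        if init is None
        else _check_simplex(init, K).clip(1e-12, None)
    )
    q = q / q.sum()

    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = q @ P  # (M,)
        ll = float(np.sum(gv * np.log(pi) + (2.0 - gv) * np.log(1.0 - pi)))
        trace.append(ll)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        alt_share = q[:, None] * P / pi  # (K, M) responsibility per alt allele
        ref_share = q[:, None] * (1.0 - P) / (1.0 - pi)
        q = (alt_share @ gv + ref_share @ (2.0 - gv)) / (2.0 * M)
        q = np.clip(q, 0.0, None)
        q = q / q.sum()

    final_ll = trace[-1]
    return AdmixtureResult(
        q=q,
        populations=list(ref.populations),
        loglik=final_ll,
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


def estimate_cohort(
    g: GenotypeMatrix,
    ref: ReferencePanel,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> list[AdmixtureResult]:
    """Estimate q for every sample of a matrix aligned with the reference panel."""
    if [v.sort_key for v in g.variants] != [v.sort_key for v in ref.variants]:
        raise ValueError("genotype matrix markers do not match reference panel")
    return [
        estimate_admixture_em(g.dosages[i], ref, tol=tol, max_iter=max_iter)
        for i in range(g.n_samples)
    ]


def classify_sample(res: AdmixtureResult) -> ClassifiedSample:
    """Assign the population with the maximum ancestry proportion.

    Ties break by population order and are flagged.
    """
    q = res.q
    best = int(np.argmax(q))
    tie = bool(np.sum(np.isclose(q, q[best], rtol=0.0, atol=1e-12)) > 1)
    return ClassifiedSample(label=res.populations[best], tie=tie)


@dataclass
class AccuracyReport:
    """Per-population estimation error e_k = mean over samples assigned to k
    of (1 - q_k), and the accuracy 1 - e_k."""

    populations: list[str]
    error: dict[str, float]  # NaN when no sample assigned
    accuracy: dict[str, float]
    n_assigned: dict[str, int]
    assigned: list[str]


def error_rate(
    results: Sequence[AdmixtureResult], assigned: Sequence[str]
) -> AccuracyReport:
    """Estimation error per population from assigned samples.

    ``assigned`` gives each sample's classification label; for population k,
    e_k averages (1 - q_k) over the samples assigned to k.  A population with
    no assigned samples gets NaN (reported missing, not an error).
    """
    if len(results) != len(assigned):
        raise ValueError("every sample needs an assignment")
    if not results:
        raise ValueError("no samples")
    pops = list(results[0].populations)
    err: dict[str, float] = {}
    n: dict[str, int] = {}
    for k, pop in enumerate(pops):
        vals = [
            1.0 - res.q[k] for res, a in zip(results, assigned) if a == pop
        ]
        n[pop] = len(vals)
        err[pop] = float(np.mean(vals)) if vals else float("nan")
    acc = {p: 1.0 - e for p, e in err.items()}
    return AccuracyReport(
        populations=pops, error=err, accuracy=acc, n_assigned=n,
        assigned=list(assigned),
    )


def concordance_correlation(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p-value) of one population's
    proportion across samples in two analyses.

    Returns (NaN, NaN) for fewer than 3 samples or zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("proportion vectors differ in length")
    if a.size < 3 or a.std() == 0.0 or b.std() == 0.0:
        return (float("nan"), float("nan"))
    r, p = sp_stats.pearsonr(a, b)
    return (float(r), float(p))


def write_q_matrix(
    results: Sequence[AdmixtureResult], samples: Sequence[str], path
) -> None:
    """Write ancestry proportions as a headered Q-matrix TSV."""
    if len(results) != len(samples):
        raise ValueError("results/samples length mismatch")
    pops = list(results[0].populations)
    rows = []
    for s, res in zip(samples, results):
        row = {"sample_id": s}
        row.update({p: res.q[k] for k, p in enumerate(pops)})
        row["loglik"] = res.loglik
        row["converged"] = res.converged
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
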