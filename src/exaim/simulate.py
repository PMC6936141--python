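"""Synthetic cohorts: drifted ancestral populations plus admixed individuals.

Population allele frequencies follow the Balding–Nichols model: for each
marker an ancestral frequency p is drawn (uniform on [0.05, 0.95] by
default) and each population k drifts to

    p_k ~ Beta( p (1 - F_k) / F_k , (1 - p)(1 - F_k) / F_k ),

whose mean is p and whose variance F_k p (1 - p) grows with the drift
parameter F_k (an F_ST analogue).  F = 0.15 produces continental-scale
differentiation for a three-population stand-in of the AFR/EAS/EUR
reference design, with admixed individuals (the AMR analogue) receiving
Dirichlet-distributed ancestry vectors.  Genotypes are unlinked binomial
draws, dosage ~ Binomial(2, sum_k q_k p_kj); an optional block-copy mode
duplicates markers with noise to create LD for exercising the pruning
stages.  Everything is driven by one seed and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, SampleMap, VariantKey, write_vcf

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "draw_population_frequencies",
    "draw_admixture_proportions",
    "simulate_genotypes",
    "simulate_cohort",
    "add_ld_copies",
    "write_synthetic_vcf",
]

ADMIXED_LABEL = "ADMIXED"


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the validation design the package is tested under:
    three reference populations at F = 0.15, 100 reference individuals per
    population, and 100 admixed individuals with Dirichlet(1, 1, 1)
    ancestry vectors.
    """

    populations: Sequence[str] = ("AFR", "EAS", "EUR")
    n_markers: int = 1000
    fst: Sequence[float] | float = 0.15
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    n_ref: int = 100  # per reference population
    n_admixed: int = 100
    alpha: Sequence[float] | float = 1.0
    missing_rate: float = 0.0
    seed: int | None = None
    position_gap_bp: int = 200_000
    markers_per_chrom: int = 200

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("population labels must be unique")
        for f in self.fst_vector():
            if not 0.0 < f < 1.0:
                raise ValueError("each F must lie in (0, 1)")
        if any(a <= 0 for a in self.alpha_vector()):
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.n_markers, self.n_ref, self.n_admixed) < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.ancestral_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("invalid ancestral frequency range")

    @property
    def K(self) -> int:
        return len(self.populations)

    @classmethod
    def exome_scale(cls, seed: int | None = None, **overrides) -> "SimulationConfig":
        """The validation study conditions for panel design at exome scale.

        A 100,000-marker pool (the order of magnitude an exome-wide SNP set
        retains after LD and MAF filtering), three reference populations at
        continental differentiation F = 0.15 with 100 individuals each, and
        100 admixed individuals with Dirichlet(1, 1, 1) ancestry.  A 250-AIM
        panel then sits in the extreme tail of the differentiation
        distribution, as it does in real exome-wide design.
        """
        params = dict(
            populations=("AFR", "EAS", "EUR"),
            n_markers=100_000,
            fst=0.15,
            n_ref=100,
            n_admixed=100,
            alpha=1.0,
            missing_rate=0.0,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def fst_vector(self) -> np.ndarray:
        f = np.asarray(self.fst, dtype=float)
        return np.full(self.K, float(f)) if f.ndim == 0 else f

    def alpha_vector(self) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=float)
        return np.full(self.K, float(a)) if a.ndim == 0 else a


@dataclass
class SimulatedCohort:
    """Genotypes plus the ground truth that generated them."""

    genotypes: GenotypeMatrix
    sample_map: SampleMap
    pop_freqs: np.ndarray  # (K, M) true per-population frequencies
    ancestral_freqs: np.ndarray  # (M,)
    true_q: np.ndarray  # (n_total, K); one-hot for reference samples
    config: SimulationConfig

    @property
    def reference_samples(self) -> list[str]:
        return [
            s
            for s in self.genotypes.samples
            if self.sample_map.populations[s] != ADMIXED_LABEL
        ]

    @property
    def admixed_samples(self) -> list[str]:
        return [
            s
            for s in self.genotypes.samples
            if self.sample_map.populations[s] == ADMIXED_LABEL
        ]

    def admixed_true_q(self) -> np.ndarray:
        idx = [
            i
            for i, s in enumerate(self.genotypes.samples)
            if self.sample_map.populations[s] == ADMIXED_LABEL
        ]
        return self.true_q[idx]


def draw_population_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral frequencies and Balding–Nichols drifted population frequencies.

    Returns ``(ancestral (M,), pop_freq (K, M))``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.ancestral_range
    p = rng.uniform(lo, hi, size=cfg.n_markers)
    fst = cfg.fst_vector()
    pop = np.empty((cfg.K, cfg.n_markers))
    for k in range(cfg.K):
        scale = (1.0 - fst[k]) / fst[k]
        pop[k] = rng.beta(p * scale, (1.0 - p) * scale)
    return p, pop


def draw_admixture_proportions(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """i.i.d. Dirichlet(alpha) ancestry vectors for the admixed individuals."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.n_admixed == 0:
        return np.empty((0, cfg.K))
    return rng.dirichlet(cfg.alpha_vector(), size=cfg.n_admixed)


def _marker_keys(cfg: SimulationConfig) -> list[VariantKey]:
    keys = []
    for j in range(cfg.n_markers):
        chrom = str(j // cfg.markers_per_chrom + 1)
        pos = 1 + (j % cfg.markers_per_chrom) * cfg.position_gap_bp
        keys.append(VariantKey(chrom=chrom, pos=pos, ref="A", alt="G", id=f"snp{j}"))
    return keys


def simulate_genotypes(
    pop_freqs: np.ndarray,
    q: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    ancestral_freqs: np.ndarray | None = None,
) -> SimulatedCohort:
    """Binomial genotypes for reference (one-hot q) plus admixed individuals.

    ``q`` holds the admixed individuals' ancestry vectors; reference
    individuals are appended first, one-hot per population, ``cfg.n_ref``
    each.  Dosage_ij ~ Binomial(2, sum_k q_ik p_kj); missing calls are
    injected i.i.d. at ``cfg.missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    q = np.asarray(q, dtype=float)
    if pop_freqs.shape != (cfg.K, cfg.n_markers):
        raise ValueError("pop_freqs shape mismatch")
    if q.ndim != 2 or q.shape[1] != cfg.K:
        raise ValueError("q shape mismatch")

    names: list[str] = []
    pops: dict[str, str] = {}
    q_rows: list[np.ndarray] = []
    for k, pop in enumerate(cfg.populations):
        onehot = np.eye(cfg.K)[k]
        for i in range(cfg.n_ref):
            name = f"{pop}_{i:04d}"
            names.append(name)
            pops[name] = str(pop)
            q_rows.append(onehot)
    for i in range(q.shape[0]):
        name = f"ADM_{i:04d}"
        names.append(name)
        pops[name] = ADMIXED_LABEL
        q_rows.append(q[i])
    q_full = np.vstack(q_rows) if q_rows else np.empty((0, cfg.K))

    pi = q_full @ pop_freqs  # (n, M)
    dosages = rng.binomial(2, pi).astype(float)
    if cfg.missing_rate > 0:
        dosages[rng.random(dosages.shape) < cfg.missing_rate] = np.nan

    g = GenotypeMatrix(
        samples=names,
        variants=_marker_keys(cfg),
        dosages=dosages,
        multiallelic=np.zeros(cfg.n_markers, dtype=bool),
    )
    anc = (
        np.asarray(ancestral_freqs, dtype=float)
        if ancestral_freqs is not None
        else np.full(cfg.n_markers, np.nan)
    )
    return SimulatedCohort(
        genotypes=g,
        sample_map=SampleMap(populations=pops),
        pop_freqs=pop_freqs,
        ancestral_freqs=anc,
        true_q=q_full,
        config=cfg,
    )


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """One-call cohort simulation: frequencies, ancestry vectors, genotypes."""
    rng = np.random.default_rng(cfg.seed)
    anc, pop = draw_population_frequencies(cfg, rng)
    q = draw_admixture_proportions(cfg, rng)
    return simulate_genotypes(pop, q, cfg, rng, ancestral_freqs=anc)


def add_ld_copies(
    cohort: SimulatedCohort,
    n_copies: int = 1,
    resample_prob: float = 0.05,
    offset_bp: int = 1_000,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Append noisy duplicates of each marker to create local LD.

    Each copy keeps the original dosage except that, independently per
    genotype with probability ``resample_prob``, the call is redrawn from
    Binomial(2, pi).  Copies sit ``offset_bp`` apart just after the original
    so windowed pruning sees them.
    """
    rng = np.random.default_rng(cohort.config.seed) if rng is None else rng
    if n_copies < 1:
        return cohort
    if (n_copies * offset_bp) >= cohort.config.position_gap_bp:
        raise ValueError("copies would overrun the inter-marker gap")
    g = cohort.genotypes
    pi = cohort.true_q @ cohort.pop_freqs

    new_keys: list[VariantKey] = []
    new_cols: list[np.ndarray] = []
    new_freq_cols: list[np.ndarray] = []
    new_anc: list[float] = []
    for j, v in enumerate(g.variants):
        new_keys.append(v)
        new_cols.append(g.dosages[:, j])
        new_freq_cols.append(cohort.pop_freqs[:, j])
        new_anc.append(cohort.ancestral_freqs[j])
        for c in range(1, n_copies + 1):
            col = g.dosages[:, j].copy()
            redraw = rng.random(col.shape) < resample_prob
            col[redraw] = rng.binomial(2, pi[redraw, j]).astype(float)
            new_keys.append(
                VariantKey(chrom=v.chrom, pos=v.pos + c * offset_bp,
                           ref=v.ref, alt=v.alt, id=f"{v.id}_ld{c}")
            )
            new_cols.append(col)
            new_freq_cols.append(cohort.pop_freqs[:, j])
            new_anc.append(cohort.ancestral_freqs[j])

    g2 = GenotypeMatrix(
        samples=list(g.samples),
        variants=new_keys,
        dosages=np.column_stack(new_cols),
        multiallelic=np.zeros(len(new_keys), dtype=bool),
    )
    return SimulatedCohort(
        genotypes=g2,
        sample_map=cohort.sample_map,
        pop_freqs=np.column_stack(new_freq_cols),
        ancestral_freqs=np.asarray(new_anc),
        true_q=cohort.true_q,
        config=cohort.config,
    )


def write_synthetic_vcf(cohort: SimulatedCohort, prefix: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF plus truth tables (ancestry q, frequencies).

    Produces ``<prefix>.vcf``, ``<prefix>.samples.tsv``, ``<prefix>.true_q.tsv``
    and ``<prefix>.pop_freqs.tsv``; returns the paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "samples": Path(f"{prefix}.samples.tsv"),
        "true_q": Path(f"{prefix}.true_q.tsv"),
        "pop_freqs": Path(f"{prefix}.pop_freqs.tsv"),
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    cohort.sample_map.to_tsv(paths["samples"])
    qdf = pd.DataFrame(
        cohort.true_q, columns=list(cohort.config.populations),
        index=pd.Index(cohort.genotypes.samples, name="sample_id"),
    )
    qdf.to_csv(paths["true_q"], sep="\t", float_format="%.6f")
    fdf = pd.DataFrame(
        cohort.pop_freqs.T,
        columns=[f"af_{p}" for p in cohort.config.populations],
    )
    fdf.insert(0, "chrom", [v.chrom for v in cohort.genotypes.variants])
    fdf.insert(1, "pos", [v.pos for v in cohort.genotypes.variants])
    fdf.insert(2, "id", [v.id for v in cohort.genotypes.variants])
    fdf.insert(3, "ref", [v.ref for v in cohort.genotypes.variants])
    fdf.insert(4, "alt", [v.alt for v in cohort.genotypes.variants])
    fdf.to_csv(paths["pop_freqs"], sep="\t", index=False, float_format="%.6f")
    return paths
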