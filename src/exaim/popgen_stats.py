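"""Population-genetic statistics: allele frequencies, MAF, LD and Rosenberg's I_n.

The informativeness statistic for a marker over K populations is

    I_n = -(p_A ln p_A + p_a ln p_a)
          + (1/K) sum_i [ p_iA ln p_iA + p_ia ln p_ia ]

with the entropy convention 0 ln 0 = 0.  I_n is 0 when the allele is equally
distributed among the populations and reaches ln K for a population-private
fixed allele.  The "overall" frequency p_A defaults to the unweighted mean of
the K population frequencies, which makes I_n independent of reference-panel
sample-size imbalance; ``overall="pooled"`` instead pools allele counts
across all individuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .io_formats import GenotypeMatrix, SampleMap, VariantKey

__all__ = [
    "FrequencyTable",
    "compute_allele_frequencies",
    "minor_allele_frequency",
    "maf_mask",
    "genotype_r2",
    "max_group_r2",
    "ld_prune_window",
    "rosenberg_in",
    "rosenberg_in_vector",
    "informativeness_table",
]

_IN_ZERO_SNAP = 1e-12  # |I_n| below this is floating-point residue of an exact 0


@dataclass
class FrequencyTable:
    """Per-variant, per-population alternate-allele frequencies.

    ``pop_freq`` is (K, M) with NaN where a population has no called sample;
    ``pop_called`` is the number of called alleles (2 x non-missing samples).
    """

    variants: list[VariantKey]
    populations: list[str]
    pop_freq: np.ndarray
    pop_called: np.ndarray
    overall: np.ndarray
    overall_method: str = "mean"

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def defined_mask(self) -> np.ndarray:
        """Variants with a defined frequency in every population."""
        return ~np.isnan(self.pop_freq).any(axis=0)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "chrom": [v.chrom for v in self.variants],
            "pos": [v.pos for v in self.variants],
            "id": [v.id for v in self.variants],
            "ref": [v.ref for v in self.variants],
            "alt": [v.alt for v in self.variants],
        }
        for k, pop in enumerate(self.populations):
            data[f"af_{pop}"] = self.pop_freq[k]
        data["af_overall"] = self.overall
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, overall_method: str = "mean") -> "FrequencyTable":
        pops = [c[3:] for c in df.columns if c.startswith("af_") and c != "af_overall"]
        variants = [
            VariantKey(chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref),
                       alt=str(r.alt), id=str(getattr(r, "id", ".")))
            for r in df.itertuples(index=False)
        ]
        freq = np.vstack([df[f"af_{p}"].to_numpy(dtype=float) for p in pops])
        overall = (
            df["af_overall"].to_numpy(dtype=float)
            if "af_overall" in df.columns
            else freq.mean(axis=0)
        )
        called = np.zeros_like(freq, dtype=int)
        return cls(variants=variants, populations=pops, pop_freq=freq,
                   pop_called=called, overall=overall, overall_method=overall_method)


def compute_allele_frequencies(
    g: GenotypeMatrix,
    sample_map: SampleMap,
    populations: list[str] | None = None,
    overall: str = "mean",
) -> FrequencyTable:
    """Per-population alternate-allele frequencies from dosages.

    ``populations`` restricts (and orders) the population columns; samples
    belonging to other populations are ignored.  Samples absent from the map
    raise an error listing the offending ids.
    """
    if overall not in ("mean", "pooled"):
        raise ValueError("overall must be 'mean' or 'pooled'")
    unlabeled = [s for s in g.samples if s not in sample_map.populations]
    if unlabeled:
        raise ValueError(f"samples without population label: {unlabeled}")
    if populations is None:
        labels = [sample_map.populations[s] for s in g.samples]
        populations = sorted(set(labels))

    K, M = len(populations), g.n_variants
    freq = np.full((K, M), np.nan)
    called = np.zeros((K, M), dtype=int)
    alt_sum = np.zeros((K, M))
    for k, pop in enumerate(populations):
        rows = [i for i, s in enumerate(g.samples) if sample_map.populations[s] == pop]
        sub = g.dosages[rows, :] if rows else np.empty((0, M))
        obs = ~np.isnan(sub)
        called[k] = 2 * obs.sum(axis=0)
        alt_sum[k] = np.nansum(sub, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(called[k] > 0, alt_sum[k] / np.maximum(called[k], 1), np.nan)

    if overall == "mean":
        overall_freq = freq.mean(axis=0)  # NaN propagates when any pop undefined
    else:
        tot_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            overall_freq = np.where(
                tot_called > 0, alt_sum.sum(axis=0) / np.maximum(tot_called, 1), np.nan
            )
    return FrequencyTable(
        variants=list(g.variants),
        populations=list(populations),
        pop_freq=freq,
        pop_called=called,
        overall=overall_freq,
        overall_method=overall,
    )


def minor_allele_frequency(p: float | np.ndarray) -> float | np.ndarray:
    """min(p, 1-p); raises on undefined (NaN) input."""
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("MAF undefined for NaN allele frequency")
    return np.minimum(arr, 1.0 - arr) if arr.ndim else float(min(arr, 1.0 - arr))


def maf_mask(
    ft: FrequencyTable, threshold: float = 0.01, scope: str = "overall"
) -> np.ndarray:
    """Boolean mask of variants kept by the MAF filter (drop iff MAF < threshold).

    ``scope="per-population"`` keeps a variant only if every population's MAF
    passes.  Variants with undefined frequencies are dropped.
    """
    defined = ft.defined_mask() & ~np.isnan(ft.overall)
    keep = defined.copy()
    if scope == "overall":
        with np.errstate(invalid="ignore"):
            maf = np.minimum(ft.overall, 1.0 - ft.overall)
        keep &= maf >= threshold
    elif scope == "per-population":
        with np.errstate(invalid="ignore"):
            maf = np.minimum(ft.pop_freq, 1.0 - ft.pop_freq)
        keep &= (maf >= threshold).all(axis=0)
    else:
        raise ValueError("scope must be 'overall' or 'per-population'")
    return keep


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are pairwise-deleted.  A constant vector makes r^2
    undefined and returns NaN (callers treat the pair as unlinked); fewer
    than 2 complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    m = ~np.isnan(x) & ~np.isnan(y)
    if m.sum() < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    xs, ys = x[m], y[m]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
    return min(r * r, 1.0)


def max_group_r2(
    x: np.ndarray, y: np.ndarray, groups: Sequence[np.ndarray] | None = None
) -> float:
    """r^2 of two dosage vectors, optionally as the max over sample groups.

    Pooling samples from differentiated populations inflates genotype
    correlation at physically unlinked loci (allele-frequency structure, not
    linkage), so LD screens in the design path evaluate r^2 within each
    population and compare the maximum to the threshold.  Groups with fewer
    than 2 complete pairs or a constant vector are skipped; if nothing is
    evaluable the result is NaN (treated as unlinked).
    """
    if groups is None:
        return genotype_r2(x, y)
    best = float("nan")
    for rows in groups:
        xs, ys = np.asarray(x)[rows], np.asarray(y)[rows]
        if (~np.isnan(xs) & ~np.isnan(ys)).sum() < 2:
            continue
        r2 = genotype_r2(xs, ys)
        if not np.isnan(r2) and not (r2 <= best):  # best may be NaN
            best = r2
    return best


def ld_prune_window(
    g: GenotypeMatrix,
    r2_max: float = 0.2,
    window_bp: int = 100_000,
    groups: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Greedy left-to-right LD pruning within a physical window.

    A variant is removed iff its r^2 with an already-retained variant on the
    same chromosome within ``window_bp`` is >= ``r2_max``.  Input must be
    position-sorted (no silent sorting).  ``groups`` switches the r^2 to the
    within-group maximum (see :func:`max_group_r2`).  Returns the integer
    indices of the retained columns, in order.
    """
    if not g.is_position_sorted():
        raise ValueError("variants must be sorted by (chrom, pos) before LD pruning")
    retained: list[int] = []
    window: list[int] = []  # retained indices on the current chromosome
    cur_chrom: str | None = None
    for j, v in enumerate(g.variants):
        if v.chrom != cur_chrom:
            cur_chrom = v.chrom
            window = []
        # drop retained markers that fell out of the bp window
        window = [k for k in window if v.pos - g.variants[k].pos <= window_bp]
        conflict = False
        for k in window:
            r2 = max_group_r2(g.dosages[:, j], g.dosages[:, k], groups)
            if not np.isnan(r2) and r2 >= r2_max:
                conflict = True
                break
        if not conflict:
            retained.append(j)
            window.append(j)
    return np.asarray(retained, dtype=int)


def rosenberg_in(
    pop_freqs: np.ndarray, overall: float | None = None
) -> float:
    """Rosenberg informativeness I_n for one marker over K >= 2 populations.

    ``pop_freqs`` holds the per-population alternate-allele frequencies;
    ``overall`` defaults to their unweighted mean.  Result is clamped to
    [0, ln K] and snapped to exactly 0 when within numerical residue of it.
    """
    p = np.asarray(pop_freqs, dtype=float)
    K = p.size
    if K < 2:
        raise ValueError("I_n requires at least 2 populations")
    if np.isnan(p).any():
        raise ValueError("I_n undefined: NaN population frequency")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("frequencies must lie in [0, 1]")
    pA = float(p.mean()) if overall is None else float(overall)
    term_overall = -(xlogy(pA, pA) + xlogy(1.0 - pA, 1.0 - pA))
    term_pops = float(np.mean(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)))
    value = float(term_overall + term_pops)
    if abs(value) < _IN_ZERO_SNAP:
        return 0.0
    return float(np.clip(value, 0.0, np.log(K)))


def rosenberg_in_vector(
    pop_freqs: np.ndarray, overall: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized I_n over markers: ``pop_freqs`` is (K, M).

    NaN columns give NaN.  Same zero-snap and [0, ln K] clamp as the scalar
    form.
    """
    p = np.asarray(pop_freqs, dtype=float)
    K = p.shape[0]
    if K < 2:
        raise ValueError("I_n requires at least 2 populations")
    pA = p.mean(axis=0) if overall is None else np.asarray(overall, dtype=float)
    term_overall = -(xlogy(pA, pA) + xlogy(1.0 - pA, 1.0 - pA))
    term_pops = (xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)).mean(axis=0)
    value = term_overall + term_pops
    value = np.where(np.abs(value) < _IN_ZERO_SNAP, 0.0, value)
    with np.errstate(invalid="ignore"):
        return np.clip(value, 0.0, np.log(K))


def _pair_overall(ft: FrequencyTable, i: int, j: int) -> np.ndarray:
    if ft.overall_method == "pooled" and ft.pop_called.sum() > 0:
        called = ft.pop_called[i] + ft.pop_called[j]
        alt = (
            np.nan_to_num(ft.pop_freq[i]) * ft.pop_called[i]
            + np.nan_to_num(ft.pop_freq[j]) * ft.pop_called[j]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    return (ft.pop_freq[i] + ft.pop_freq[j]) / 2.0


def informativeness_table(ft: FrequencyTable) -> pd.DataFrame:
    """I_n over the full population set and every unordered pair, per variant.

    Columns: variant key fields, ``in_overall`` and ``in_<popA>_<popB>``.
    Variants with undefined frequencies get NaN statistics.
    """
    if len(ft.populations) < 2:
        raise ValueError("informativeness requires K >= 2 populations")
    defined = ft.defined_mask()
    M = ft.n_variants
    out = ft.to_frame()[["chrom", "pos", "id", "ref", "alt"]].copy()

    ov = None if ft.overall_method == "mean" else ft.overall
    in_overall = rosenberg_in_vector(ft.pop_freq, overall=ov)
    in_overall[~defined] = np.nan
    out["in_overall"] = in_overall

    for i, j in itertools.combinations(range(len(ft.populations)), 2):
        pair_ov = None if ft.overall_method == "mean" else _pair_overall(ft, i, j)
        col = rosenberg_in_vector(ft.pop_freq[[i, j]], overall=pair_ov)
        col[~defined] = np.nan
        out[f"in_{ft.populations[i]}_{ft.populations[j]}"] = col
    return out
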