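"""Balanced AIM panel selection from filtered genotype data.

Candidates survive a MAF filter and windowed LD pruning, are ranked by
overall I_n, and assigned to the population whose allele frequency deviates
most from the mean of the others (the "dominant" population).  Panels are
then drawn by a deterministic round-robin over populations so that the
design stays balanced: each population in turn contributes its most
informative remaining candidate that respects the minimum physical distance
and the between-AIM LD ceiling.  Larger panels are generated independently,
so they need not contain the markers of smaller ones.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, SampleMap, VariantKey
from .popgen_stats import (
    FrequencyTable,
    compute_allele_frequencies,
    genotype_r2,
    informativeness_table,
    ld_prune_window,
    maf_mask,
    max_group_r2,
)

__all__ = [
    "DesignConfig",
    "AimCandidate",
    "AimPanel",
    "UninformativePoolError",
    "build_candidates",
    "assign_dominant_population",
    "select_balanced_panel",
    "nested_panel_series",
    "choose_optimal_size",
]


class UninformativePoolError(ValueError):
    """Raised when every candidate marker carries zero informativeness."""


@dataclass
class DesignConfig:
    """Design parameters for AIM panel construction.

    Defaults follow the published pipeline settings: background LD pruning at
    r^2 < 0.2 in 100 kb windows, MAF >= 0.01, between-AIM LD <= 0.1, minimum
    inter-AIM distance 100 kb, and a 5000-candidate pool.
    """

    populations: Sequence[str]
    ld_prune_r2: float = 0.2
    maf_min: float = 0.01
    aim_ld_max: float = 0.1
    min_distance_bp: int = 100_000
    ld_window_bp: int = 100_000
    panel_sizes: Sequence[int] = ()
    candidate_pool_size: int = 5000
    rank_by: str = "overall"  # or "pairwise_sum"
    overall_freq: str = "mean"  # I_n overall-frequency convention

    def __post_init__(self) -> None:
        if len(set(self.populations)) < 2:
            raise ValueError("design requires K >= 2 distinct populations")
        if not (0.0 < self.aim_ld_max <= self.ld_prune_r2 <= 1.0):
            raise ValueError("need 0 < aim_ld_max <= ld_prune_r2 <= 1")
        if self.min_distance_bp < 0:
            raise ValueError("min_distance_bp must be >= 0")
        sizes = list(self.panel_sizes)
        if any(s <= 0 for s in sizes) or sizes != sorted(sizes):
            raise ValueError("panel_sizes must be positive and ascending")
        if self.rank_by not in ("overall", "pairwise_sum"):
            raise ValueError("rank_by must be 'overall' or 'pairwise_sum'")


@dataclass
class AimCandidate:
    key: VariantKey
    freqs: np.ndarray  # per-population alt-allele frequency, config order
    in_overall: float
    in_pairwise: dict[tuple[str, str], float]
    dominant: str
    dosages: np.ndarray  # per-sample dosage, for between-AIM LD checks
    uninformative: bool = False
    # row indices per population (shared across a pool); between-AIM LD is
    # evaluated within populations so that allele-frequency structure does
    # not masquerade as linkage
    pop_rows: tuple[np.ndarray, ...] | None = None

    @property
    def rank_value(self) -> float:
        return self.in_overall


@dataclass
class AimPanel:
    """An ordered AIM marker list with its design-config snapshot."""

    markers: list[AimCandidate]
    populations: list[str]
    config: DesignConfig

    @property
    def size(self) -> int:
        return len(self.markers)

    @property
    def variant_keys(self) -> list[VariantKey]:
        return [m.key for m in self.markers]

    @property
    def dominant_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in self.populations}
        for m in self.markers:
            counts[m.dominant] += 1
        return counts

    def validate(self) -> None:
        """Re-check the panel's own distance and LD invariants post hoc."""
        for a in range(self.size):
            for b in range(a + 1, self.size):
                ka, kb = self.markers[a].key, self.markers[b].key
                if ka.chrom == kb.chrom and abs(ka.pos - kb.pos) < self.config.min_distance_bp:
                    raise AssertionError(
                        f"panel markers {ka} and {kb} violate min distance"
                    )
                r2 = max_group_r2(
                    self.markers[a].dosages,
                    self.markers[b].dosages,
                    self.markers[a].pop_rows,
                )
                if not np.isnan(r2) and r2 > self.config.aim_ld_max + 1e-12:
                    raise AssertionError(f"panel markers {ka} and {kb} violate LD cap")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.markers:
            row = {
                "chrom": m.key.chrom,
                "pos": m.key.pos,
                "id": m.key.id,
                "ref": m.key.ref,
                "alt": m.key.alt,
            }
            for pop, f in zip(self.populations, m.freqs):
                row[f"af_{pop}"] = f
            row["in_overall"] = m.in_overall
            for (a, b), v in m.in_pairwise.items():
                row[f"in_{a}_{b}"] = v
            row["dominant_pop"] = m.dominant
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def assign_dominant_population(
    freqs: np.ndarray, populations: Sequence[str]
) -> str:
    """Population whose frequency deviates most from the mean of the others.

    Ties break by population order (deterministic); a fully degenerate tie
    (all frequencies equal) therefore yields the first label.
    """
    p = np.asarray(freqs, dtype=float)
    K = p.size
    if K != len(populations):
        raise ValueError("frequency/population length mismatch")
    if np.isnan(p).any():
        raise ValueError("dominant population undefined for NaN frequencies")
    best, best_dev = 0, -1.0
    for i in range(K):
        others = np.delete(p, i)
        dev = abs(p[i] - others.mean())
        if dev > best_dev + 1e-15:
            best, best_dev = i, dev
    return str(populations[best])


def _candidate_sort_key(c: AimCandidate):
    return (-c.in_overall, c.key.chrom, c.key.pos, c.key.ref, c.key.alt)


def build_candidates(
    g: GenotypeMatrix, sample_map: SampleMap, cfg: DesignConfig
) -> list[AimCandidate]:
    """MAF-filter, LD-prune and rank candidate AIMs from a genotype matrix.

    ``g`` is expected to be region-filtered and biallelic-only already.
    Returns candidates sorted by descending overall I_n (ties by position),
    truncated to ``cfg.candidate_pool_size``.
    """
    pop_rows = tuple(
        np.array(
            [i for i, s in enumerate(g.samples) if sample_map.populations[s] == pop],
            dtype=int,
        )
        for pop in cfg.populations
    )
    freqs = compute_allele_frequencies(
        g, sample_map, populations=list(cfg.populations), overall=cfg.overall_freq
    )
    keep = maf_mask(freqs, threshold=cfg.maf_min, scope="overall")
    g1 = g.take_variants(np.flatnonzero(keep))
    retained = ld_prune_window(
        g1, r2_max=cfg.ld_prune_r2, window_bp=cfg.ld_window_bp, groups=pop_rows
    )
    g2 = g1.take_variants(retained)

    ft = compute_allele_frequencies(
        g2, sample_map, populations=list(cfg.populations), overall=cfg.overall_freq
    )
    stats = informativeness_table(ft)
    pops = list(cfg.populations)
    pop_pairs = list(itertools.combinations(ft.populations, 2))

    defined = ft.defined_mask()
    order = sorted(
        np.flatnonzero(defined),
        key=lambda m: (
            -float(stats["in_overall"].iloc[m]),
            ft.variants[m].chrom,
            ft.variants[m].pos,
            ft.variants[m].ref,
            ft.variants[m].alt,
        ),
    )[: cfg.candidate_pool_size]

    candidates: list[AimCandidate] = []
    for m in order:
        p = ft.pop_freq[:, m]
        in_overall = float(stats["in_overall"].iloc[m])
        pairwise = {
            (a, b): float(stats[f"in_{a}_{b}"].iloc[m]) for a, b in pop_pairs
        }
        candidates.append(
            AimCandidate(
                key=ft.variants[m],
                freqs=p.copy(),
                in_overall=in_overall,
                in_pairwise=pairwise,
                dominant=assign_dominant_population(p, pops),
                dosages=g2.dosages[:, m].copy(),
                uninformative=in_overall == 0.0,
                pop_rows=pop_rows,
            )
        )
    if cfg.panel_sizes:
        largest = max(cfg.panel_sizes)
        if len(candidates) < largest:
            raise ValueError(
                f"only {len(candidates)} candidates survive filtering but the "
                f"largest requested panel needs {largest}"
            )
    return candidates


def _rank(c: AimCandidate, cfg: DesignConfig) -> float:
    if cfg.rank_by == "pairwise_sum":
        return sum(c.in_pairwise.values())
    return c.in_overall


def select_balanced_panel(
    candidates: list[AimCandidate], size: int, cfg: DesignConfig
) -> AimPanel:
    """Round-robin greedy selection of a population-balanced panel.

    Populations take turns in config order; each turn picks the highest-ranked
    unselected candidate dominated by that population that keeps (a) every
    same-chromosome pair at >= ``min_distance_bp`` and (b) every pairwise r^2
    at <= ``aim_ld_max``.  An exhausted population's turn falls to the best
    remaining candidate of any population.  Deterministic for fixed input.
    """
    if size > len(candidates):
        raise ValueError(f"panel size {size} exceeds candidate pool {len(candidates)}")
    if size > 0 and all(c.in_overall == 0.0 for c in candidates):
        raise UninformativePoolError(
            "uninformative pool: all candidates have I_n = 0"
        )
    pool = sorted(candidates, key=lambda c: (-_rank(c, cfg), *_candidate_sort_key(c)[1:]))
    selected: list[AimCandidate] = []
    selected_idx: list[int] = []
    taken = [False] * len(pool)
    pops = list(cfg.populations)

    # fast r^2 path: with complete data, within-group r is a dot product of
    # group-standardized dosage columns; falls back to pairwise deletion
    # whenever missing calls are present
    D = np.column_stack([c.dosages for c in pool]) if pool else np.empty((0, 0))
    groups = pool[0].pop_rows if pool and pool[0].pop_rows is not None else None
    use_fast = D.size > 0 and not np.isnan(D).any()
    zscores: list[np.ndarray] = []
    if use_fast:
        group_rows = groups if groups is not None else (np.arange(D.shape[0]),)
        for rows in group_rows:
            sub = D[rows, :]
            mu = sub.mean(axis=0)
            sd = sub.std(axis=0)
            z = (sub - mu) / np.where(sd > 0, sd, 1.0)
            z[:, sd == 0] = 0.0  # constant in group: treated as unlinked
            zscores.append(z / np.sqrt(len(rows)))

    def pair_r2(ci: int, si: int) -> float:
        if use_fast:
            worst = 0.0
            for z in zscores:
                r = float(z[:, ci] @ z[:, si])
                worst = max(worst, r * r)
            return worst
        r2 = max_group_r2(pool[ci].dosages, pool[si].dosages, pool[ci].pop_rows)
        return 0.0 if np.isnan(r2) else r2

    def feasible(ci: int) -> bool:
        c = pool[ci]
        for s in selected:
            if (
                c.key.chrom == s.key.chrom
                and abs(c.key.pos - s.key.pos) < cfg.min_distance_bp
            ):
                return False
        return all(pair_r2(ci, si) <= cfg.aim_ld_max for si in selected_idx)

    turn = 0
    while len(selected) < size:
        pop = pops[turn % len(pops)]
        pick = None
        for i, c in enumerate(pool):
            if not taken[i] and c.dominant == pop and feasible(i):
                pick = i
                break
        if pick is None:  # population exhausted: best remaining of any population
            for i, c in enumerate(pool):
                if not taken[i] and feasible(i):
                    pick = i
                    break
        if pick is None:
            raise ValueError(
                f"constraints make panel size {size} unreachable; "
                f"achieved {len(selected)}"
            )
        taken[pick] = True
        selected.append(pool[pick])
        selected_idx.append(pick)
        turn += 1
    return AimPanel(markers=selected, populations=pops, config=cfg)


def nested_panel_series(
    candidates: list[AimCandidate], sizes: Sequence[int], cfg: DesignConfig
) -> dict[int, AimPanel]:
    """One panel per requested size, each selected independently.

    The subset property is explicitly not guaranteed: balancing can swap
    markers between sizes.
    """
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("sizes must be ascending")
    return {s: select_balanced_panel(candidates, s, cfg) for s in sizes}


def choose_optimal_size(
    accuracy_by_size: Mapping[int, Mapping[str, float] | float],
    tol: float = 0.001,
) -> int:
    """Smallest panel size past which accuracy stops improving by ``tol``.

    Returns the smallest size s such that no population's accuracy improves
    by ``tol`` or more at any larger evaluated size.  If accuracy keeps
    improving, returns the largest size with a warning.
    """
    if not accuracy_by_size:
        raise ValueError("no accuracies supplied")
    if len(accuracy_by_size) < 2:
        raise ValueError("need accuracies for at least 2 sizes")

    def as_vector(v) -> np.ndarray:
        if isinstance(v, Mapping):
            return np.array([v[k] for k in sorted(v)])
        return np.atleast_1d(np.asarray(v, dtype=float))

    sizes = sorted(accuracy_by_size)
    acc = {s: as_vector(accuracy_by_size[s]) for s in sizes}
    for i, s in enumerate(sizes[:-1]):
        if all(
            float(np.max(acc[s2] - acc[s])) < tol for s2 in sizes[i + 1 :]
        ):
            return s
    warnings.warn(
        "accuracy still improving at the largest evaluated size", stacklevel=2
    )
    return sizes[-1]
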