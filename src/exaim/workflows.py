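"""Convenience glue chaining the pipeline stages.

These helpers keep the bookkeeping (marker alignment between a designed
panel, a reference frequency table and a genotype matrix) in one place; all
the science lives in the stage modules.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .admixture import AdmixtureResult, ReferencePanel, estimate_cohort
from .io_formats import GenotypeMatrix, SampleMap
from .panel_design import AimPanel, DesignConfig, build_candidates, select_balanced_panel
from .popgen_stats import FrequencyTable, compute_allele_frequencies
from .simulate import ADMIXED_LABEL, SimulatedCohort

__all__ = [
    "subset_to_panel",
    "reference_panel_from_genotypes",
    "design_panel",
    "estimate_panel_admixture",
]


def subset_to_panel(g: GenotypeMatrix, panel: AimPanel) -> GenotypeMatrix:
    """Columns of ``g`` at the panel's markers, in panel order."""
    index = {v.sort_key: i for i, v in enumerate(g.variants)}
    missing = [str(k) for k in panel.variant_keys if k.sort_key not in index]
    if missing:
        raise ValueError(f"panel markers absent from matrix: {missing[:5]}")
    return g.take_variants([index[k.sort_key] for k in panel.variant_keys])


def reference_panel_from_genotypes(
    g_ref: GenotypeMatrix,
    sample_map: SampleMap,
    panel: AimPanel,
    populations: Sequence[str],
    epsilon: float = 1e-6,
) -> ReferencePanel:
    """Reference allele frequencies at panel markers, from reference samples."""
    g_sub = subset_to_panel(g_ref, panel)
    ft = compute_allele_frequencies(g_sub, sample_map, populations=list(populations))
    if np.isnan(ft.pop_freq).any():
        raise ValueError("undefined reference frequency at a panel marker")
    return ReferencePanel(
        variants=list(ft.variants),
        populations=list(populations),
        freqs=ft.pop_freq,
        epsilon=epsilon,
    )


def design_panel(
    g_ref: GenotypeMatrix, sample_map: SampleMap, cfg: DesignConfig, size: int
) -> AimPanel:
    """Candidates plus balanced selection in one call."""
    candidates = build_candidates(g_ref, sample_map, cfg)
    return select_balanced_panel(candidates, size, cfg)


def estimate_panel_admixture(
    g: GenotypeMatrix,
    ref: ReferencePanel,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> list[AdmixtureResult]:
    """Ancestry estimation for a matrix that may hold extra markers."""
    index = {v.sort_key: i for i, v in enumerate(g.variants)}
    cols = [index[v.sort_key] for v in ref.variants]
    return estimate_cohort(g.take_variants(cols), ref, tol=tol, max_iter=max_iter)


def split_cohort(
    cohort: SimulatedCohort,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """(reference samples, admixed samples) genotype matrices of a simulation."""
    g = cohort.genotypes
    refs = [s for s in g.samples if cohort.sample_map.populations[s] != ADMIXED_LABEL]
    adm = [s for s in g.samples if cohort.sample_map.populations[s] == ADMIXED_LABEL]
    return g.take_samples(refs), g.take_samples(adm)
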