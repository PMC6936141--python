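"""Shared fixtures: small hand-written VCFs and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from exaim.io_formats import GenotypeMatrix, SampleMap, VariantKey
from exaim.simulate import SimulationConfig, simulate_cohort


VCF_SMALL = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|0\t0|1\t1|1
1\t250000\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t.|.\t0/.
1\t500000\trs3\tG\tA,T\t.\t.\t.\tGT\t0/1\t1/2\t0/0
2\t100\trs4\tT\tC\t.\t.\t.\tGT\t1/1\t1|0\t0/0
"""


@pytest.fixture
def small_vcf(tmp_path):
    path = tmp_path / "small.vcf"
    path.write_text(VCF_SMALL)
    return path


@pytest.fixture
def toy_matrix():
    """3 samples x 4 variants with a missing call and a multi-allelic flag."""
    variants = [
        VariantKey("1", 100, "A", "G", "rs1"),
        VariantKey("1", 250_000, "C", "T", "rs2"),
        VariantKey("1", 500_000, "G", "A,T", "rs3"),
        VariantKey("2", 100, "T", "C", "rs4"),
    ]
    dosages = np.array(
        [
            [0.0, 1.0, 1.0, 2.0],
            [1.0, np.nan, 2.0, 1.0],
            [2.0, np.nan, 0.0, 0.0],
        ]
    )
    return GenotypeMatrix(
        samples=["S1", "S2", "S3"],
        variants=variants,
        dosages=dosages,
        multiallelic=np.array([False, False, True, False]),
    )


@pytest.fixture
def two_pop_map():
    return SampleMap(populations={"S1": "AFR", "S2": "AFR", "S3": "EUR"})


@pytest.fixture(scope="session")
def small_cohort():
    """Three drifted populations plus admixed samples, modest marker count."""
    cfg = SimulationConfig(
        n_markers=600, fst=0.2, n_ref=60, n_admixed=40, seed=11
    )
    return simulate_cohort(cfg)
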