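"""Candidate construction, dominant-population assignment and balanced selection."""

import numpy as np
import pytest

from exaim.io_formats import GenotypeMatrix, SampleMap, VariantKey
from exaim.panel_design import (
    AimCandidate,
    DesignConfig,
    UninformativePoolError,
    assign_dominant_population,
    build_candidates,
    choose_optimal_size,
    nested_panel_series,
    select_balanced_panel,
)
from exaim.simulate import SimulationConfig, simulate_cohort
from exaim.workflows import split_cohort

POPS = ["AFR", "EAS", "EUR"]


def make_candidate(chrom, pos, in_overall, dominant, dosages=None, rng=None):
    if dosages is None:
        seed = int(chrom) * 100_003 + pos % 100_003  # stable across processes
        rng = rng or np.random.default_rng(seed)
        dosages = rng.integers(0, 3, 30).astype(float)
    return AimCandidate(
        key=VariantKey(chrom, pos, "A", "G"),
        freqs=np.array([0.5, 0.5, 0.5]),
        in_overall=in_overall,
        in_pairwise={},
        dominant=dominant,
        dosages=np.asarray(dosages, float),
    )


class TestDesignConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            DesignConfig(populations=POPS, aim_ld_max=0.5, ld_prune_r2=0.2)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            DesignConfig(populations=["AFR"])

    def test_sizes_must_ascend(self):
        with pytest.raises(ValueError):
            DesignConfig(populations=POPS, panel_sizes=[100, 50])


class TestDominantPopulation:
    def test_single_deviating_population(self):
        assert assign_dominant_population([0.9, 0.1, 0.1], POPS) == "AFR"

    def test_low_outlier_beats_high_pair(self):
        # |0.2 - 0.8| = 0.6 for AFR beats |0.8 - 0.5| = 0.3 for the others
        assert assign_dominant_population([0.2, 0.8, 0.8], POPS) == "AFR"

    def test_degenerate_tie_takes_first_label(self):
        assert assign_dominant_population([0.5, 0.5, 0.5], POPS) == "AFR"

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            assign_dominant_population([np.nan, 0.5, 0.5], POPS)


class TestBuildCandidates:
    def make_toy(self):
        """5 variants: v0 informative; v1 fails MAF; v2 duplicates v0 (pruned);
        v3 fails MAF; v4 informative."""
        rng = np.random.default_rng(4)
        n_per = 10
        pops = {}
        samples = []
        for pop in POPS:
            for i in range(n_per):
                s = f"{pop}{i}"
                samples.append(s)
                pops[s] = pop
        # informative but polymorphic within AFR so the duplicate is prunable
        v0 = np.array([2, 1, 2, 1, 2, 2, 2, 2, 2, 2] + [0.0] * (2 * n_per))
        v1 = np.zeros(30)  # monomorphic: MAF 0
        v2 = v0.copy()  # same chromosome, 50 kb away, within-pop r2 = 1
        v3 = np.zeros(30)
        v3[0] = 1.0  # MAF = 1/60 < 0.05 threshold below
        v4 = np.array([0.0] * n_per + [2.0] * n_per + [0.0] * n_per)
        g = GenotypeMatrix(
            samples=samples,
            variants=[
                VariantKey("1", 1, "A", "G"),
                VariantKey("1", 20_000, "A", "G"),
                VariantKey("1", 50_000, "A", "G"),
                VariantKey("1", 70_000, "A", "G"),
                VariantKey("1", 200_000, "A", "G"),
            ],
            dosages=np.column_stack([v0, v1, v2, v3, v4]),
            multiallelic=np.zeros(5, bool),
        )
        return g, SampleMap(populations=pops)

    def test_two_filters_leave_two_candidates(self):
        g, smap = self.make_toy()
        cfg = DesignConfig(populations=POPS, maf_min=0.05)
        cands = build_candidates(g, smap, cfg)
        assert len(cands) == 2
        assert {c.key.pos for c in cands} == {1, 200_000}
        # sorted by In descending and each assigned to its deviating population
        assert cands[0].in_overall >= cands[1].in_overall
        assert {c.dominant for c in cands} == {"AFR", "EAS"}

    def test_uninformative_pool_aborts_selection(self):
        n = 12
        pops = {f"s{i}": POPS[i % 3] for i in range(n)}
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, n).astype(float)
        # identical distribution across populations: replicate one column
        g = GenotypeMatrix(
            samples=list(pops),
            variants=[VariantKey("1", 1 + j * 200_000, "A", "G") for j in range(3)],
            dosages=np.column_stack([col, col, col]),
            multiallelic=np.zeros(3, bool),
        )
        # make frequencies exactly equal across pops: constant dosage 1
        g.dosages[:] = 1.0
        cfg = DesignConfig(populations=POPS, maf_min=0.0)
        cands = build_candidates(g, smap := SampleMap(populations=pops), cfg)
        assert all(c.uninformative for c in cands)
        with pytest.raises(UninformativePoolError):
            select_balanced_panel(cands, 1, cfg)

    def test_insufficient_pool_for_requested_size(self):
        g, smap = self.make_toy()
        cfg = DesignConfig(populations=POPS, maf_min=0.05, panel_sizes=[4])
        with pytest.raises(ValueError, match="candidates"):
            build_candidates(g, smap, cfg)


class TestBalancedSelection:
    def make_pool(self):
        """9 candidates, 3 per dominant population, far apart, uncorrelated."""
        rng = np.random.default_rng(7)
        pool = []
        for i in range(9):
            pool.append(
                make_candidate(
                    chrom=str(i + 1),
                    pos=1_000_000,
                    in_overall=0.5 - 0.01 * i,
                    dominant=POPS[i % 3],
                    dosages=rng.integers(0, 3, 40).astype(float),
                )
            )
        return pool

    def test_round_robin_balances_counts(self):
        cfg = DesignConfig(populations=POPS)
        panel = select_balanced_panel(self.make_pool(), 6, cfg)
        assert panel.dominant_counts == {"AFR": 2, "EAS": 2, "EUR": 2}
        panel.validate()

    def test_distance_constraint_blocks_close_pair(self):
        cfg = DesignConfig(populations=POPS, min_distance_bp=100_000)
        a = make_candidate("1", 1_000_000, 0.6, "AFR")
        b = make_candidate("1", 1_050_000, 0.59, "EAS")  # 50 kb from a
        c = make_candidate("2", 1, 0.3, "EAS")
        d = make_candidate("3", 1, 0.29, "EUR")
        panel = select_balanced_panel([a, b, c, d], 3, cfg)
        positions = {(m.key.chrom, m.key.pos) for m in panel.markers}
        assert ("1", 1_000_000) in positions
        assert ("1", 1_050_000) not in positions

    def test_exhausted_population_falls_to_global_best(self):
        cfg = DesignConfig(populations=POPS)
        pool = [
            make_candidate(str(i + 1), 1, 0.5 - 0.01 * i, "AFR") for i in range(4)
        ] + [make_candidate("9", 1, 0.3, "EAS")]
        panel = select_balanced_panel(pool, 4, cfg)
        assert panel.dominant_counts == {"AFR": 3, "EAS": 1, "EUR": 0}

    def test_selection_is_deterministic(self):
        cfg = DesignConfig(populations=POPS)
        p1 = select_balanced_panel(self.make_pool(), 6, cfg)
        p2 = select_balanced_panel(self.make_pool(), 6, cfg)
        assert [m.key.sort_key for m in p1.markers] == [
            m.key.sort_key for m in p2.markers
        ]

    def test_size_larger_than_pool_rejected(self):
        cfg = DesignConfig(populations=POPS)
        with pytest.raises(ValueError):
            select_balanced_panel(self.make_pool(), 10, cfg)

    def test_unreachable_size_reports_achieved(self):
        cfg = DesignConfig(populations=POPS, min_distance_bp=100_000)
        pool = [
            make_candidate("1", 1_000 + i, 0.5 - 0.01 * i, POPS[i % 3])
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="achieved 1"):
            select_balanced_panel(pool, 3, cfg)

    def test_balanced_beats_naive_on_skewed_pool(self):
        # one population's markers strictly more informative: naive top-In
        # takes them all, balanced keeps every population represented
        cfg = DesignConfig(populations=POPS)
        pool = (
            [make_candidate(str(i + 1), 1, 0.9 - 0.001 * i, "AFR") for i in range(6)]
            + [make_candidate(str(i + 10), 1, 0.3, "EAS") for i in range(3)]
            + [make_candidate(str(i + 20), 1, 0.2, "EUR") for i in range(3)]
        )
        panel = select_balanced_panel(pool, 6, cfg)
        counts = panel.dominant_counts
        naive = sorted(pool, key=lambda c: -c.in_overall)[:6]
        naive_min = min(
            sum(1 for c in naive if c.dominant == p) for p in POPS
        )
        assert min(counts.values()) == 2  # maximal possible for size 6, K = 3
        assert naive_min == 0


class TestOnSimulatedPool:
    def test_unconstrained_counts_differ_by_at_most_one(self, small_cohort):
        gref, _ = split_cohort(small_cohort)
        cfg = DesignConfig(populations=list(small_cohort.config.populations))
        cands = build_candidates(gref, small_cohort.sample_map, cfg)
        panel = select_balanced_panel(cands, 30, cfg)
        counts = list(panel.dominant_counts.values())
        assert max(counts) - min(counts) <= 1
        panel.validate()

    def test_nested_series_sizes(self, small_cohort):
        gref, _ = split_cohort(small_cohort)
        cfg = DesignConfig(populations=list(small_cohort.config.populations))
        cands = build_candidates(gref, small_cohort.sample_map, cfg)
        panels = nested_panel_series(cands, [6, 9], cfg)
        assert panels[6].size == 6 and panels[9].size == 9

    def test_panel_table_roundtrip(self, small_cohort, tmp_path):
        from exaim.io_formats import read_panel_table

        gref, _ = split_cohort(small_cohort)
        cfg = DesignConfig(populations=list(small_cohort.config.populations))
        cands = build_candidates(gref, small_cohort.sample_map, cfg)
        panel = select_balanced_panel(cands, 12, cfg)
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        df = read_panel_table(path)
        assert len(df) == 12
        assert {"in_overall", "dominant_pop", "af_AFR"}.issubset(df.columns)


class TestChooseOptimalSize:
    def test_first_plateau(self):
        acc = {50: 0.97, 100: 0.99, 250: 0.995, 500: 0.995}
        assert choose_optimal_size(acc, tol=0.001) == 250

    def test_flat_curve_takes_smallest(self):
        assert choose_optimal_size({10: 0.99, 50: 0.99}, tol=0.001) == 10

    def test_strictly_increasing_warns_and_takes_largest(self):
        with pytest.warns(UserWarning):
            s = choose_optimal_size({10: 0.9, 50: 0.95, 100: 0.99}, tol=0.001)
        assert s == 100

    def test_per_population_minimum_gain(self):
        acc = {
            10: {"AFR": 0.90, "EAS": 0.99},
            50: {"AFR": 0.99, "EAS": 0.99},  # AFR still improving at 10
            100: {"AFR": 0.99, "EAS": 0.99},
        }
        assert choose_optimal_size(acc, tol=0.001) == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choose_optimal_size({}, tol=0.01)
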