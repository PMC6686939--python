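"""Synthetic population and pooled-count generator."""

import math

import numpy as np
import pytest

from tillseq import (
    CoverageModel,
    Zygosity,
    build_design,
    make_fixture,
    simulate_pool_counts,
    simulate_population,
    synthetic_panel,
)
from tillseq.simulate import BASES, MutationSet


@pytest.fixture(scope="module")
def panel30k():
    # ~30 kb panel for Poisson-count checks
    return synthetic_panel(24, (1200, 1300), (0.4, 0.6), seed=3)


class TestSimulatePopulation:
    def test_deterministic_given_seed(self, small_panel, design_3x4):
        a = simulate_population(small_panel, design_3x4, 1e-3, seed=5)
        b = simulate_population(small_panel, design_3x4, 1e-3, seed=5)
        assert a == b

    def test_seeds_differ(self, small_panel, design_3x4):
        a = simulate_population(small_panel, design_3x4, 1e-2, seed=5)
        b = simulate_population(small_panel, design_3x4, 1e-2, seed=6)
        assert a.mutations != b.mutations

    def test_total_count_near_poisson_mean(self, panel30k):
        design = build_design(3, 16)
        density = 1.0 / 150_000.0
        ms = simulate_population(panel30k, design, density, seed=1)
        mean = design.n_samples * panel30k.total_bp * density
        assert abs(len(ms) - mean) < 3.0 * math.sqrt(mean)

    def test_ref_bases_match_panel(self, small_panel, design_3x4):
        ms = simulate_population(small_panel, design_3x4, 5e-3, seed=2)
        assert len(ms) > 0
        for m in ms:
            assert small_panel[m.amplicon].sequence[m.position - 1] == m.ref_base
            assert m.alt_base != m.ref_base
            assert 0 <= m.sample < design_3x4.n_samples

    def test_het_fraction_extremes(self, small_panel, design_3x4):
        all_het = simulate_population(small_panel, design_3x4, 5e-3, het_fraction=1.0, seed=2)
        assert {m.zygosity for m in all_het} == {Zygosity.HETEROZYGOUS}
        all_hom = simulate_population(small_panel, design_3x4, 5e-3, het_fraction=0.0, seed=2)
        assert {m.zygosity for m in all_hom} == {Zygosity.HOMOZYGOUS}

    def test_ems_bias_forces_transitions_at_gc_sites(self, small_panel, design_3x4):
        ms = simulate_population(
            small_panel, design_3x4, 5e-3, seed=4, ems_bias=True
        )
        for m in ms:
            if m.ref_base == "G":
                assert m.alt_base == "A"
            elif m.ref_base == "C":
                assert m.alt_base == "T"

    @pytest.mark.parametrize("density", [0.0, -1e-4, 1.0])
    def test_bad_density_rejected(self, small_panel, design_3x4, density):
        with pytest.raises(ValueError):
            simulate_population(small_panel, design_3x4, density)

    def test_truth_tsv_round_trip(self, small_panel, design_3x4, tmp_path):
        ms = simulate_population(small_panel, design_3x4, 5e-3, seed=2)
        path = tmp_path / "truth.tsv"
        ms.write_tsv(path)
        again = MutationSet.read_tsv(path)
        assert again.mutations == ms.mutations


class TestSimulatePoolCounts:
    def test_no_mutations_no_errors_pure_reference(self, small_panel, design_3x4):
        empty = MutationSet(mutations=(), density_per_bp=1e-9, seed=0)
        model = CoverageModel(log_mean=math.log(500), log_sd=0.0, seed=1)
        counts = simulate_pool_counts(
            empty, small_panel, design_3x4, model, error_rate=0.0, seed=1
        )
        for (pool, amp), arr in counts.counts.items():
            codes = counts.ref_codes[amp]
            depth = arr.sum(axis=0)
            assert (arr[codes, np.arange(arr.shape[1])] == depth).all()

    def test_conservation_base_counts_sum_to_depth(self, toy_fixture):
        for (pool, amp), arr in toy_fixture.counts.counts.items():
            depth = toy_fixture.counts.depth(pool, amp)
            assert (arr.sum(axis=0) == depth).all()
            assert (arr >= 0).all()

    def test_het_alt_count_matches_binomial_mean(self, design_3x16):
        # one het carrier in a pool of 256: expected alt = depth / 512
        panel = synthetic_panel(1, (100, 100), (0.5, 0.5), seed=9)
        mut = MutationSet(
            mutations=(
                _mutation_at(panel, sample=0, position=50),
            ),
            density_per_bp=1e-9,
            seed=0,
        )
        depth = 512_000
        model = CoverageModel(log_mean=math.log(depth), log_sd=0.0, seed=1)
        counts = simulate_pool_counts(mut, panel, design_3x16, model, error_rate=0.0, seed=3)
        frac = 1.0 / 512.0
        expected = depth * frac
        sd = math.sqrt(depth * frac * (1 - frac))
        for pool in design_3x16.pool_ids_for_sample(0):
            arr = counts.counts[(pool, panel.names[0])]
            alt = arr[BASES.index(mut.mutations[0].alt_base), 49]
            assert abs(alt - expected) < 3.0 * sd

    def test_hom_roughly_twice_het(self, design_3x4):
        panel = synthetic_panel(1, (100, 100), (0.5, 0.5), seed=9)
        depth = 200_000
        model = CoverageModel(log_mean=math.log(depth), log_sd=0.0, seed=1)
        het = MutationSet(
            (_mutation_at(panel, 0, 10, Zygosity.HETEROZYGOUS),), 1e-9, 0
        )
        hom = MutationSet(
            (_mutation_at(panel, 0, 10, Zygosity.HOMOZYGOUS),), 1e-9, 0
        )
        totals = []
        for ms in (het, hom):
            counts = simulate_pool_counts(ms, panel, design_3x4, model, error_rate=0.0, seed=4)
            alt_code = BASES.index(ms.mutations[0].alt_base)
            totals.append(
                sum(
                    counts.counts[(p, panel.names[0])][alt_code, 9]
                    for p in design_3x4.pool_ids_for_sample(0)
                )
            )
        het_total, hom_total = totals
        # hom_total - 2*het_total has variance var(hom) + 4 var(het)
        f_het, f_hom = 1 / 32, 1 / 16
        var = 3 * depth * f_hom * (1 - f_hom) + 4 * 3 * depth * f_het * (1 - f_het)
        assert abs(hom_total - 2 * het_total) < 4 * math.sqrt(var)

    def test_error_rate_bounds(self, small_panel, design_3x4):
        empty = MutationSet((), 1e-9, 0)
        model = CoverageModel(log_mean=5.0, log_sd=0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_pool_counts(empty, small_panel, design_3x4, model, error_rate=0.3)

    def test_counts_tsv_round_trip(self, toy_fixture, tmp_path):
        path = tmp_path / "counts.tsv"
        toy_fixture.counts.write_tsv(path)
        from tillseq import PoolAlleleCounts

        again = PoolAlleleCounts.read_tsv(path)
        assert set(again.counts) == set(toy_fixture.counts.counts)
        for key, arr in toy_fixture.counts.counts.items():
            assert (again.counts[key] == arr).all()


def _mutation_at(panel, sample, position, zygosity=Zygosity.HETEROZYGOUS):
    from tillseq import Mutation

    amp = panel.amplicons[0]
    ref = amp.sequence[position - 1]
    alt = next(b for b in BASES if b != ref)
    return Mutation(
        sample=sample, amplicon=amp.name, position=position,
        ref_base=ref, alt_base=alt, zygosity=zygosity,
    )


class TestMakeFixture:
    def test_toy_shape(self, toy_fixture):
        assert toy_fixture.design.n_pools == 12
        assert toy_fixture.design.n_samples == 64
        assert len(toy_fixture.panel) == 4

    def test_paper_scale_shape(self, paper_scale_fixture):
        f = paper_scale_fixture
        assert f.design.n_pools == 48
        assert f.design.n_samples == 4096
        assert len(f.panel) == 32
        assert len(f.counts.counts) == 1536  # 32 amplicons x 48 pools
        for amp in f.panel:
            assert 670 <= amp.length_bp <= 1513

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("huge", seed=0)

    def test_same_seed_identical_truth_tsv(self, tmp_path):
        a = make_fixture("toy", seed=3, out_dir=tmp_path / "a")
        b = make_fixture("toy", seed=3, out_dir=tmp_path / "b")
        assert a.truth_path.read_bytes() == b.truth_path.read_bytes()
        assert set(a.counts.counts) == set(b.counts.counts)
        for key in a.counts.counts:
            assert (a.counts.counts[key] == b.counts.counts[key]).all()

    def test_different_seed_different_mutations(self):
        a = make_fixture("toy", seed=3)
        b = make_fixture("toy", seed=4)
        assert a.mutations.mutations != b.mutations.mutations
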