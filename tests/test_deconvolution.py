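"""Pool-to-individual deconvolution: uniqueness, intersection, rescue."""

import random

import pytest

from tillseq import (
    CandidateVariant,
    ZygosityEstimate,
    build_design,
    classify_zygosity,
    deconvolve,
    make_fixture,
)
from tillseq.calling import call_pool_variants, filter_common, scaled_af_max
from tillseq.deconvolution import (
    VariantKey,
    group_by_dimension,
    intersect_dimensions,
    rescue,
    unique_in_dimension,
)


def cand(pool_id, amplicon="AMP", position=10, ref="A", alt="T", alt_count=8, depth=2048):
    return CandidateVariant(
        pool_id=pool_id, amplicon=amplicon, position=position,
        ref_base=ref, alt_base=alt, alt_count=alt_count, depth=depth,
    )


@pytest.fixture
def d34():
    return build_design(3, 4)


class TestUniqueInDimension:
    def test_single_pool_key_kept(self, d34):
        by_dim = group_by_dimension([cand(pool_id=2)], d34)
        uniques = unique_in_dimension(by_dim, d34)
        key = VariantKey("AMP", 10, "A", "T")
        assert key in uniques[0]
        coord, pool, af = uniques[0][key]
        assert (coord, pool) == (1, 2)

    def test_key_in_two_pools_dropped(self, d34):
        by_dim = group_by_dimension([cand(2), cand(3)], d34)
        uniques = unique_in_dimension(by_dim, d34)
        assert uniques[0] == {}

    def test_empty_dimension_empty_output(self, d34):
        uniques = unique_in_dimension({}, d34)
        assert all(uniques[d] == {} for d in range(3))

    def test_unknown_pool_raises(self, d34):
        with pytest.raises(ValueError, match="pool id 99"):
            group_by_dimension([cand(99)], d34)


class TestIntersectDimensions:
    def test_key_in_all_dims_yields_one_record(self, d34):
        # pools 2 (dim1), 5 (dim2), 9 (dim3) -> coords (1, 0, 0)
        by_dim = group_by_dimension([cand(2), cand(5), cand(9)], d34)
        uniques = unique_in_dimension(by_dim, d34)
        records = intersect_dimensions(uniques)
        assert len(records) == 1
        key, coords, pool_ids, afs = records[0]
        assert coords == (1, 0, 0)
        assert pool_ids == (2, 5, 9)

    def test_key_missing_a_dimension_absent(self, d34):
        by_dim = group_by_dimension([cand(2), cand(5)], d34)
        uniques = unique_in_dimension(by_dim, d34)
        assert intersect_dimensions(uniques) == []

    def test_two_keys_order_independent(self, d34):
        cands = [
            cand(2), cand(5), cand(9),
            cand(3, position=20), cand(6, position=20), cand(10, position=20),
        ]
        records_fwd = intersect_dimensions(
            unique_in_dimension(group_by_dimension(cands, d34), d34)
        )
        records_rev = intersect_dimensions(
            unique_in_dimension(group_by_dimension(cands[::-1], d34), d34)
        )
        assert records_fwd == records_rev
        assert len(records_fwd) == 2


class TestRescue:
    def test_single_raw_pool_completes_call(self, d34):
        strict = [cand(5), cand(9)]  # dims 2 and 3 only
        raw = strict + [cand(2, alt_count=1, depth=2048)]
        uniques = unique_in_dimension(group_by_dimension(strict, d34), d34)
        rescued = rescue(uniques, group_by_dimension(raw, d34), d34)
        assert len(rescued) == 1
        key, coords, pool_ids, afs = rescued[0]
        assert pool_ids == (2, 5, 9)

    def test_absent_from_raw_reported_unresolved(self, d34):
        from tillseq import DeconvolutionReport

        strict = [cand(5), cand(9)]
        uniques = unique_in_dimension(group_by_dimension(strict, d34), d34)
        report = DeconvolutionReport()
        rescued = rescue(
            uniques, group_by_dimension(strict, d34), d34, report=report
        )
        assert rescued == []
        assert len(report.unresolved) == 1
        assert "absent" in report.unresolved[0][2]

    def test_ambiguous_raw_pools_reported(self, d34):
        from tillseq import DeconvolutionReport

        strict = [cand(5), cand(9)]
        raw = strict + [cand(1, alt_count=1), cand(2, alt_count=1)]
        uniques = unique_in_dimension(group_by_dimension(strict, d34), d34)
        report = DeconvolutionReport()
        rescued = rescue(uniques, group_by_dimension(raw, d34), d34, report=report)
        assert rescued == []
        assert "ambiguous" in report.unresolved[0][2]

    def test_key_missing_two_dimensions_never_called(self, d34):
        from tillseq import DeconvolutionReport

        strict = [cand(5)]  # dim 2 only
        raw = strict + [cand(2, alt_count=1), cand(9, alt_count=1)]
        uniques = unique_in_dimension(group_by_dimension(strict, d34), d34)
        report = DeconvolutionReport()
        assert rescue(uniques, group_by_dimension(raw, d34), d34, report=report) == []
        assert report.unresolved


class TestClassifyZygosity:
    def test_study_control_frequencies_classify_homozygous(self):
        # observed 0.0078 / 0.0103 / 0.0117 in three pools of 256:
        # nearer to the hom expectation 0.0039 than the het 0.00195
        assert (
            classify_zygosity([0.0078, 0.0103, 0.0117], 256)
            is ZygosityEstimate.HOMOZYGOUS
        )

    def test_exact_het_expectation(self):
        assert classify_zygosity([0.00195], 256) is ZygosityEstimate.HETEROZYGOUS

    def test_far_above_hom_is_ambiguous(self):
        assert classify_zygosity([0.05], 256) is ZygosityEstimate.AMBIGUOUS

    def test_far_below_het_is_ambiguous(self):
        assert classify_zygosity([0.0001], 256) is ZygosityEstimate.AMBIGUOUS

    def test_requires_an_observation(self):
        with pytest.raises(ValueError):
            classify_zygosity([], 256)


class TestDeconvolve:
    def _pipeline(self, fixture):
        af_max = scaled_af_max(fixture.design.samples_per_pool)
        cands = filter_common(
            call_pool_variants(fixture.counts, error_rate=0.0), af_max
        )
        return deconvolve(cands, fixture.design)

    def test_toy_truth_recovered_with_zygosity(self, toy_fixture):
        result = self._pipeline(toy_fixture)
        truth = {
            (m.sample, m.amplicon, m.position, m.alt_base): m.zygosity.value
            for m in toy_fixture.mutations
        }
        # non-colliding keys: variant key carried by exactly one sample
        by_key = {}
        for m in toy_fixture.mutations:
            by_key.setdefault((m.amplicon, m.position, m.alt_base), []).append(m)
        got = {
            (c.sample, c.key.amplicon, c.key.position, c.key.alt_base): c
            for c in result.calls
        }
        for tkey, zyg in truth.items():
            sample, amp, pos, alt = tkey
            if len(by_key[(amp, pos, alt)]) > 1:
                continue
            assert tkey in got
            assert got[tkey].zygosity_estimate.value == zyg
        # soundness: nothing that is not planted
        assert set(got) <= set(truth)

    def test_resolved_sample_matches_coordinates(self, toy_fixture):
        result = self._pipeline(toy_fixture)
        for call in result.calls:
            assert toy_fixture.design.sample_at(call.coords) == call.sample
            assert call.pool_ids == tuple(
                toy_fixture.design.pool_id(d, c) for d, c in enumerate(call.coords)
            )

    def test_input_order_irrelevant(self, toy_fixture):
        af_max = scaled_af_max(toy_fixture.design.samples_per_pool)
        cands = filter_common(
            call_pool_variants(toy_fixture.counts, error_rate=0.0), af_max
        )
        shuffled = cands[:]
        random.Random(0).shuffle(shuffled)
        a = deconvolve(cands, toy_fixture.design)
        b = deconvolve(shuffled, toy_fixture.design)
        assert a.calls == b.calls

    def test_planted_collision_dropped_and_reported(self, d34):
        # samples 0 (coords 0,0,0) and 21 (coords 1,1,1) share a key:
        # every dimension sees two pools -> dropped everywhere
        pools_a = (1, 5, 9)
        pools_b = (2, 6, 10)
        cands = [cand(p) for p in pools_a + pools_b]
        result = deconvolve(cands, d34)
        assert result.calls == []
        assert len(result.report.dropped_multi_pool) == 3

    def test_empty_input_empty_result(self, d34):
        result = deconvolve([], d34)
        assert result.calls == []
        assert result.report.dropped_multi_pool == []
        assert result.report.unresolved == []

    def test_position_only_matching_merges_alleles(self, d34):
        # same position, different alt base in different dimensions:
        # allele-aware matching keeps them apart, position-only merges
        cands = [cand(2, alt="T"), cand(5, alt="G"), cand(9, alt="T")]
        strict = deconvolve(cands, d34, match_alleles=True)
        assert strict.calls == []
        loose = deconvolve(cands, d34, match_alleles=False)
        assert len(loose.calls) == 1

    def test_calls_tsv_columns(self, toy_fixture, tmp_path):
        result = self._pipeline(toy_fixture)
        path = tmp_path / "calls.tsv"
        result.write_tsv(path)
        header = path.read_text().split("\n")[0].split("\t")
        assert header == [
            "amplicon", "position", "ref", "alt", "sample_index",
            "pool_d1", "pool_d2", "pool_d3",
            "af_d1", "af_d2", "af_d3", "zygosity", "status",
        ]
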