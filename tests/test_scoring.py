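"""Both parts of the scoring system, the consensus rule and the protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decmscore.morphometry import FeatureVector
from decmscore.scoring import (CONTAMINATION_SUSPECT, DECELLULARIZED, IMPURITY,
                               NUCLEUS, RESIDUAL_NUCLEI, DimensionWeights,
                               SamplingProtocol, SectionCounts, build_benchmark,
                               calibrate_threshold, classify_point,
                               consensus_sample_decision, score_parameter,
                               score_point, score_section, stratified_sample)


def _fv(area=100, perimeter=40, feret=20, minferet=8, ratio=2.5, gray=110):
    return FeatureVector(area=area, perimeter=perimeter, feret=feret,
                         minferet=minferet, feret_ratio=ratio, avg_gray=gray)


def _benchmark(sds=5.0):
    base = _fv()
    jitter = _fv(area=100 + sds, perimeter=40 + sds, feret=20 + sds,
                 minferet=8 + sds, ratio=2.5 + sds, gray=110 + sds)
    low = _fv(area=100 - sds, perimeter=40 - sds, feret=20 - sds,
              minferet=8 - sds, ratio=max(1.0, 2.5 - sds), gray=110 - sds)
    return build_benchmark([base, jitter, low], "he", "nucleus_1")


class TestScoreParameter:
    @pytest.mark.parametrize("x, expected", [
        (100, 3),   # at the mean
        (110, 3),   # exactly 1 sigma: closed toward the better score
        (115, 2),
        (125, 1),   # between 2 and 3 sigma
        (130, 1),
        (140, 0),   # outside 3 sigma
    ])
    def test_sigma_intervals(self, x, expected):
        assert score_parameter(x, mu=100, sigma=10) == expected

    def test_degenerate_sigma(self):
        assert score_parameter(5.0, 5.0, 0.0) == 3
        assert score_parameter(5.1, 5.0, 0.0) == 0

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
           st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_score_in_range_and_monotone_in_distance(self, x, mu, sigma):
        s = score_parameter(x, mu, sigma)
        assert s in (0, 1, 2, 3)
        closer = mu + 0.5 * (x - mu)
        assert score_parameter(closer, mu, sigma) >= s


class TestBenchmark:
    def test_identical_vectors_have_zero_sd(self):
        bench = build_benchmark([_fv()] * 25, "he", "nucleus_1")
        assert bench.n == 25
        assert all(v == 0 for v in bench.sds.values())
        assert bench.means["area"] == 100

    def test_sample_sd_uses_n_minus_1(self):
        vectors = [_fv(area=a) for a in (90, 100, 110)]
        bench = build_benchmark(vectors, "feulgen", "nucleus_2")
        assert bench.means["area"] == pytest.approx(100.0)
        assert bench.sds["area"] == pytest.approx(10.0)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            build_benchmark([_fv()], "he", "nucleus_1")


class TestScorePoint:
    def test_point_at_benchmark_means_is_maximal(self):
        score = score_point(_fv(), _benchmark())
        assert (score.size, score.shape, score.color) == (3.0, 3.0, 3.0)
        assert score.total == 9.0
        assert classify_point(score) == NUCLEUS

    def test_dimension_averaging_and_weighted_sum(self):
        # parameter scores: area 3, perimeter 2, feret 3, minferet 3, ratio 0, gray 3
        bench = _benchmark(sds=5.0)
        fv = _fv(perimeter=40 + 7.5, ratio=2.5 + 40)
        score = score_point(fv, bench)
        assert score.parameter_scores == {
            "area": 3, "perimeter": 2, "feret": 3, "minferet": 3,
            "feret_ratio": 0, "avg_gray": 3}
        assert score.size == pytest.approx(2.5)
        assert score.shape == pytest.approx(2.0)
        assert score.color == pytest.approx(3.0)
        assert score.total == pytest.approx(7.5)

    def test_everything_beyond_three_sigma_scores_zero(self):
        fv = _fv(area=1e5, perimeter=1e4, feret=1e4, minferet=900,
                 ratio=50, gray=255)
        score = score_point(fv, _benchmark())
        assert score.total == 0.0
        assert classify_point(score, threshold=1.0) == IMPURITY

    def test_weights_scale_dimensions(self):
        weights = DimensionWeights(2.0, 1.0, 0.5)
        score = score_point(_fv(), _benchmark(), weights)
        assert score.total == pytest.approx(3 * (2.0 + 1.0 + 0.5))
        assert score.max_total == pytest.approx(10.5)

    def test_moving_one_parameter_toward_mean_never_lowers_total(self):
        bench = _benchmark(sds=5.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            area = float(rng.uniform(80, 130))
            fv = _fv(area=area)
            closer = _fv(area=100 + 0.5 * (area - 100))
            assert (score_point(closer, bench).total
                    >= score_point(fv, bench).total)

    def test_calibrated_threshold_separates_well_separated_totals(self):
        nuc = [9.0, 8.5, 8.0, 7.5, 9.0]
        dust = [1.0, 0.5, 2.0, 1.5, 0.0]
        t = calibrate_threshold(nuc, dust)
        assert all(v >= t for v in nuc)
        assert all(v < t for v in dust)


class TestScoreSection:
    @pytest.mark.parametrize("counts, components, total", [
        ((0, 0, 0), (0, 0, 0), 0),
        ((60, 11, 25), (4, 4, 4), 16),
        ((12, 3, 7), (2, 2, 2), 8),
        ((10, 2, 5), (1, 1, 1), 4),     # printed endpoints go to the lower bin
        ((11, 3, 6), (2, 2, 2), 8),
    ])
    def test_table_lookup_with_nucleus_double_weight(self, counts, components, total):
        sc = score_section(SectionCounts(*counts))
        assert (sc.s_overall, sc.s_nucleus, sc.s_ecm) == components
        assert sc.total == total

    def test_bins_partition_counts_exhaustively(self):
        """Every count 0..1000 lands in exactly one 0-4 category, with no gaps,
        no overlaps, and component jumps of at most one."""
        component_of = {
            "overall": lambda c: score_section(SectionCounts(c, 0, 0)).s_overall,
            "nucleus": lambda c: score_section(SectionCounts(c, c, 0)).s_nucleus,
            "ecm": lambda c: score_section(SectionCounts(c, 0, c)).s_ecm,
        }
        for name, score_of in component_of.items():
            scores = [score_of(c) for c in range(1001)]
            assert all(s in (0, 1, 2, 3, 4) for s in scores), name
            assert scores == sorted(scores), name              # no overlaps
            jumps = {b - a for a, b in zip(scores, scores[1:])}
            assert jumps <= {0, 1}, name                       # no gaps
            assert scores[0] == 0 and scores[-1] == 4, name

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SectionCounts(-1, 0, 0)
        with pytest.raises(ValueError):
            SectionCounts(2, 5, 0)


class TestConsensus:
    def test_all_quiet_is_decellularized(self):
        d = consensus_sample_decision({"he": 0, "feulgen": 1, "acetocarmine": 0,
                                       "dapi": 0})
        assert d.decision == DECELLULARIZED
        assert not d.insufficient_stains

    def test_single_alarm_is_contamination_suspect(self):
        # dust mimics nuclei under HE but not under DNA-specific stains
        d = consensus_sample_decision({"he": 9, "feulgen": 2, "acetocarmine": 1,
                                       "dapi": 0})
        assert d.decision == CONTAMINATION_SUSPECT

    def test_multiple_alarms_mean_residual_nuclei(self):
        d = consensus_sample_decision({"he": 9, "feulgen": 8, "acetocarmine": 12,
                                       "dapi": 2})
        assert d.decision == RESIDUAL_NUCLEI
        assert d.alarms == {"he": True, "feulgen": True,
                            "acetocarmine": True, "dapi": False}

    def test_single_stain_is_flagged_insufficient(self):
        d = consensus_sample_decision({"he": 9})
        assert d.insufficient_stains
        assert d.decision == CONTAMINATION_SUSPECT


def _sections(n_sections=15, nuclei=8, dust=7):
    return [([f"n{i}_{j}" for j in range(nuclei)],
             [f"d{i}_{j}" for j in range(dust)]) for i in range(n_sections)]


class TestStratifiedSampling:
    def test_default_protocol_yields_25_plus_25(self, rng):
        nuclei, dust = stratified_sample(_sections(), rng=rng)
        assert len(nuclei) == 25
        assert len(dust) == 25
        assert len(set(nuclei)) == 25  # without replacement
        assert len(set(dust)) == 25

    def test_same_seed_same_selection(self):
        a = stratified_sample(_sections(), rng=np.random.default_rng(5))
        b = stratified_sample(_sections(), rng=np.random.default_rng(5))
        assert a == b

    def test_insufficient_sections_rejected(self, rng):
        sections = _sections(n_sections=4)
        with pytest.raises(ValueError, match="qualify"):
            stratified_sample(sections, rng=rng)

    def test_sections_without_enough_objects_are_skipped(self, rng):
        sections = _sections(n_sections=5) + [(["n"], ["d"])] * 10
        nuclei, dust = stratified_sample(sections, rng=rng)
        assert len(nuclei) == 25 and len(dust) == 25
        assert not any(x in ("n", "d") for x in nuclei + dust)

    def test_full_design_totals_300(self, rng):
        """25 samples per class per stain: 4 stains x 3 classes x 25 = 300."""
        total = 0
        protocol = SamplingProtocol()
        for _stain in ("he", "feulgen", "acetocarmine", "dapi"):
            for _nucleus_type in ("nucleus_1", "nucleus_2"):
                nuclei, _ = stratified_sample(_sections(), protocol, rng)
                total += len(nuclei)
            _, dust = stratified_sample(_sections(), protocol, rng)
            total += len(dust)
        assert total == 300
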