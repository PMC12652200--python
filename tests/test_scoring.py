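import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathprio import (
    LiteratureSummary,
    PathwayEvidence,
    PathwayRef,
    ThresholdConfig,
    ValidationError,
    bin_protein_coverage,
    bp_coverage_score,
    phi_coverage_score,
    protein_coverage,
    score_all,
    score_pathway,
)
from pathprio.literature import breadth_coefficient

CFG = ThresholdConfig()


def _lit(n, mean):
    g = breadth_coefficient(n)
    return LiteratureSummary("x", n, mean, g, mean * g)


def _evidence(pathway_id="ko04010", name="MAPK signaling pathway",
              ko_total=100, gene_count=60, n_bp=54, n_phi=40, lit=None):
    return PathwayEvidence(
        pathway=PathwayRef(pathway_id, name, ko_total),
        gene_count=gene_count,
        n_bp=n_bp,
        n_phi=n_phi,
        literature=lit or LiteratureSummary.empty(name),
    )


class TestProteinCoverage:
    def test_direct_ratio(self):
        assert protein_coverage(60, 100) == 0.6

    def test_over_unity_coverage_representable(self):
        assert protein_coverage(150, 100) == 1.5

    def test_zero_denominator_warns_and_is_zero(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert protein_coverage(5, 0) == 0.0
        assert "coverage" in caplog.text

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            protein_coverage(-1, 10)


class TestBoundarySemantics:
    """Each band is closed on the left of its upper edge (>=) and open below."""

    @pytest.mark.parametrize(
        "cov, expected",
        [(0.5, 2), (0.50001, 2), (0.49999, 1), (0.2, 1), (0.19999, 0),
         (0.0, 0), (1.5, 2)],
    )
    def test_protein_edges(self, cov, expected):
        assert bin_protein_coverage(cov, CFG) == expected

    @pytest.mark.parametrize(
        "n_bp, n_total, expected_cov, expected_score",
        [(8, 10, 0.8, 2), (79999, 100000, 0.79999, 1), (4, 10, 0.4, 1),
         (39999, 100000, 0.39999, 0), (0, 0, 0.0, 0), (10, 10, 1.0, 2)],
    )
    def test_bp_edges(self, n_bp, n_total, expected_cov, expected_score):
        assert bp_coverage_score(n_bp, n_total, CFG) == (
            pytest.approx(expected_cov),
            expected_score,
        )

    @pytest.mark.parametrize(
        "n_phi, n_total, expected_cov, expected_score",
        [(6, 10, 0.6, 3), (59999, 100000, 0.59999, 2), (3, 10, 0.3, 2),
         (29999, 100000, 0.29999, 1), (1, 10, 0.1, 1), (0, 10, 0.0, 0),
         (0, 0, 0.0, 0)],
    )
    def test_phi_edges(self, n_phi, n_total, expected_cov, expected_score):
        assert phi_coverage_score(n_phi, n_total, CFG) == (
            pytest.approx(expected_cov),
            expected_score,
        )

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValidationError):
            bp_coverage_score(11, 10, CFG)
        with pytest.raises(ValidationError):
            phi_coverage_score(11, 10, CFG)


def _brute_band(cov, bands):
    """Linear scan over (lower_edge_inclusive, score) bands, highest first."""
    for lower, score in bands:
        if cov >= lower:
            return score
    return 0


class TestBinningMonotonicity:
    @settings(max_examples=150, deadline=None)
    @given(st.floats(0, 3, allow_nan=False))
    def test_protein_binning_matches_brute_force(self, cov):
        assert bin_protein_coverage(cov, CFG) == _brute_band(
            cov, [(0.5, 2), (0.2, 1)]
        )

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50))
    def test_bp_binning_matches_brute_force(self, a, b):
        n_bp, n_total = min(a, b), max(a, b)
        cov, score = bp_coverage_score(n_bp, n_total, CFG)
        assert score == _brute_band(cov, [(0.8, 2), (0.4, 1)])

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50))
    def test_phi_binning_matches_brute_force(self, a, b):
        n_phi, n_total = min(a, b), max(a, b)
        cov, score = phi_coverage_score(n_phi, n_total, CFG)
        expected = _brute_band(cov, [(0.6, 3), (0.3, 2)])
        if expected == 0 and cov > 0:
            expected = 1
        assert score == expected

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 2), st.floats(0, 1))
    def test_step_functions_non_decreasing(self, cov, delta):
        assert bin_protein_coverage(cov + delta, CFG) >= bin_protein_coverage(
            cov, CFG
        )


class TestScorePathway:
    def test_composite_example(self):
        # 60/100 -> 0.6 -> 2; 54/60 = 0.9 -> 2; 40/60 = 0.667 >= 0.6 -> 3;
        # literature 2.5 x G(26)=1.0 -> 2.5
        scores = score_pathway(_evidence(lit=_lit(26, 2.5)), CFG)
        assert (
            scores.protein_score,
            scores.bp_score,
            scores.phi_score,
            scores.literature_score,
        ) == (2, 2, 3, 2.5)
        assert scores.total == pytest.approx(9.5)

    def test_composite_example_mid_phi_band(self):
        scores = score_pathway(_evidence(n_phi=30, lit=_lit(26, 2.5)), CFG)
        assert scores.phi_score == 2
        assert scores.total == pytest.approx(8.5)

    def test_all_zero_evidence(self):
        scores = score_pathway(
            _evidence(gene_count=0, n_bp=0, n_phi=0, ko_total=100), CFG
        )
        assert scores.total == 0

    def test_maximal_evidence_totals_ten(self):
        scores = score_pathway(
            _evidence(gene_count=100, ko_total=100, n_bp=100, n_phi=100,
                      lit=_lit(12, 3.0)),
            CFG,
        )
        assert scores.total == 10

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValidationError):
            _evidence(gene_count=10, n_bp=11, n_phi=0)
        with pytest.raises(ValidationError):
            _evidence(gene_count=10, n_bp=0, n_phi=11)


class TestScoreAll:
    def test_duplicate_pathway_rejected(self):
        rows = [_evidence(), _evidence(name="other")]
        with pytest.raises(ValidationError, match="ko04010"):
            score_all(rows, CFG)

    def test_empty_table(self):
        assert score_all([], CFG) == []

    def test_order_independence(self):
        rows = [
            _evidence(pathway_id=f"ko0401{i}", gene_count=10 * i,
                      n_bp=5 * i, n_phi=2 * i, lit=_lit(i, 1.5))
            for i in range(1, 5)
        ]
        forward = score_all(rows, CFG)
        backward = score_all(list(reversed(rows)), CFG)
        assert sorted(forward, key=lambda s: s.pathway_id) == sorted(
            backward, key=lambda s: s.pathway_id
        )


@st.composite
def _evidence_pair(draw):
    """An evidence row plus a strictly-weaker version of it."""
    gene_count = draw(st.integers(1, 40))
    ko_total = draw(st.integers(1, 80))
    n_bp = draw(st.integers(0, gene_count))
    n_phi = draw(st.integers(0, gene_count))
    n_pub = draw(st.integers(0, 15))
    mean = draw(st.sampled_from([0.0, 1.0, 1.5, 2.0, 2.5, 3.0]))
    if n_pub == 0:
        mean = 0.0
    strong = _evidence(gene_count=gene_count, ko_total=ko_total, n_bp=n_bp,
                       n_phi=n_phi, lit=_lit(n_pub, mean))
    weak = _evidence(
        gene_count=gene_count,
        ko_total=ko_total,
        n_bp=draw(st.integers(0, n_bp)),
        n_phi=draw(st.integers(0, n_phi)),
        lit=_lit(*(lambda n, m: (n, 0.0 if n == 0 else m))(
            draw(st.integers(0, n_pub)), draw(st.sampled_from(
                [m for m in (0.0, 1.0, 1.5, 2.0, 2.5, 3.0) if m <= mean]
                or [0.0]
            ))
        )),
    )
    return strong, weak


class TestTotalBoundsAndMonotonicity:
    @settings(max_examples=200, deadline=None)
    @given(_evidence_pair())
    def test_removing_evidence_never_increases_total(self, pair):
        strong, weak = pair
        s, w = score_pathway(strong, CFG), score_pathway(weak, CFG)
        assert 0.0 <= w.total <= s.total <= 10.0
        assert s.total == pytest.approx(
            s.protein_score + s.bp_score + s.phi_score + s.literature_score
        )

    def test_custom_threshold_config_applies(self):
        cfg = ThresholdConfig(protein_edges=(0.1, 0.9))
        assert bin_protein_coverage(0.5, cfg) == 1
        with pytest.raises(ValidationError):
            ThresholdConfig(protein_edges=(0.5, 0.2))

    def test_threshold_yaml_round_trip(self, tmp_path):
        path = tmp_path / "thresholds.yaml"
        path.write_text("protein_edges: [0.1, 0.9]\nphi_edges: [0.25, 0.75]\n")
        cfg = ThresholdConfig.from_yaml(path)
        assert cfg.protein_edges == (0.1, 0.9)
        assert cfg.phi_edges == (0.25, 0.75)
        assert cfg.bp_edges == (0.4, 0.8)
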