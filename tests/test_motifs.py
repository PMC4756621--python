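"""PWM parsing, log-odds scanning, empirical-null calibration, filtering."""

import numpy as np
import pandas as pd
import pytest

from regkit.intervals import GenomicInterval, Peak, overlap_length
from regkit.methylation import Thresholds
from regkit.motifs import (
    EmpiricalNull,
    MotifMatch,
    PWM,
    associate,
    associate_pwm_to_gene,
    build_empirical_null,
    column_information,
    empirical_pvalue,
    filter_matches,
    read_jaspar,
    reverse_complement,
    scan,
    score_ratio,
    to_log_odds,
    within_peaks,
    write_jaspar,
)
from regkit.simulate import plant_motifs, random_pwm, simulate_genome

NO_PSEUDO = Thresholds(pseudocount=0.0)


class TestJasparIO:
    def test_bracketed_dialect(self):
        text = ">MA0001.1 AGL3\nA [ 4 19 0 ]\nC [ 1 0 5 ]\nG [ 3 2 2 ]\nT [ 2 0 3 ]\n"
        (pwm,) = read_jaspar(text)
        assert pwm.id == "MA0001.1" and pwm.name == "AGL3"
        assert pwm.counts.shape == (3, 4)
        assert pwm.counts[:, 0].tolist() == [4, 19, 0]  # A row -> column 0

    def test_plain_dialect_matches_bracketed(self):
        plain = ">M1 X\n4 19 0\n1 0 5\n3 2 2\n2 0 3\n"
        bracketed = ">M1 X\nA [ 4 19 0 ]\nC [ 1 0 5 ]\nG [ 3 2 2 ]\nT [ 2 0 3 ]\n"
        a, b = read_jaspar(plain)[0], read_jaspar(bracketed)[0]
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_single_column_matrix(self):
        (pwm,) = read_jaspar(">M1 X\nA [ 10 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n")
        assert len(pwm) == 1 and pwm.consensus() == "A"

    def test_empty_input(self):
        assert read_jaspar("") == []

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="M1"):
            read_jaspar(">M1 X\nA [ 4 19 ]\nC [ 1 0 5 ]\nG [ 3 2 2 ]\nT [ 2 0 3 ]\n")

    def test_round_trip(self, tmp_path):
        pwms = [random_pwm(L, seed=s) for s, L in enumerate([1, 5, 12])]
        path = tmp_path / "m.jaspar"
        write_jaspar(pwms, path)
        back = read_jaspar(path)
        assert [p.id for p in back] == [p.id for p in pwms]
        for a, b in zip(back, pwms):
            np.testing.assert_array_equal(a.counts, b.counts)


class TestLogOdds:
    def test_uniform_column_scores_zero(self):
        pwm = PWM(id="U", name="U", counts=np.array([[25, 25, 25, 25]]))
        sm = to_log_odds(pwm)
        np.testing.assert_allclose(sm.logodds, 0.0, atol=1e-12)

    def test_max_score_is_sum_of_column_maxima(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        assert sm.max_score == pytest.approx(sm.logodds.max(axis=1).sum())
        assert sm.min_score == pytest.approx(sm.logodds.min(axis=1).sum())

    def test_consensus_scores_max_under_scan(self):
        for seed in range(5):
            pwm = random_pwm(9, seed=seed)
            sm = to_log_odds(pwm)
            hits = scan(pwm.consensus(), sm, threshold=sm.min_score - 1,
                        both_strands=False)
            assert hits[0].score == pytest.approx(sm.max_score)

    def test_zero_column_rejected(self):
        pwm = PWM(id="Z", name="Z", counts=np.array([[0, 0, 0, 0]]))
        with pytest.raises(ValueError, match="zero column"):
            to_log_odds(pwm)


class TestScan:
    def test_planted_consensus_found_at_max_score(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        seq = simulate_genome(5000, seed=8)
        seq, positions = plant_motifs(seq, simple_pwm, 6, seed=9)
        hits = scan(seq, sm, threshold=sm.max_score - 1e-9)
        plus = [m.interval.start for m in hits if m.interval.strand == "+"]
        assert set(positions) <= set(plus)
        for m in hits:
            if m.interval.start in positions and m.interval.strand == "+":
                assert m.score == pytest.approx(sm.max_score)

    def test_threshold_above_max_gives_nothing(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        assert scan("ACGTACGT" * 20, sm, threshold=sm.max_score + 1) == []

    def test_reverse_complement_plant_reported_on_minus(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        seq = simulate_genome(300, seed=10)
        plant = reverse_complement(simple_pwm.consensus())
        seq = seq[:100] + plant + seq[100 + len(plant):]
        hits = [m for m in scan(seq, sm, threshold=sm.max_score - 1e-9)
                if m.interval.start == 100]
        assert any(m.interval.strand == "-" for m in hits)
        assert all(m.interval.end == 100 + len(simple_pwm) for m in hits)

    def test_strand_symmetry(self, simple_pwm):
        """Scanning the reverse complement mirrors the match set."""
        sm = to_log_odds(simple_pwm)
        seq = simulate_genome(2000, seed=12)
        fwd = scan(seq, sm, threshold=0.5 * sm.max_score)
        rev = scan(reverse_complement(seq), sm, threshold=0.5 * sm.max_score)
        L, N = len(simple_pwm), len(seq)
        mirror = {
            (N - m.interval.end, "+-"[m.interval.strand == "+"], round(m.score, 6))
            for m in fwd
        }
        got = {
            (m.interval.start, m.interval.strand, round(m.score, 6)) for m in rev
        }
        assert got == mirror

    def test_windows_with_n_are_skipped(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        seq = simple_pwm.consensus()
        assert scan(seq, sm, threshold=sm.min_score - 1) != []
        assert scan(seq[:-1] + "N", sm, threshold=sm.min_score - 1) == []

    def test_short_sequence_gives_empty(self, simple_pwm):
        assert scan("ACG", to_log_odds(simple_pwm), threshold=-100) == []


class TestEmpiricalNull:
    def test_same_seed_reproduces_null(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        a = build_empirical_null(sm, n_samples=2000, seed=5)
        b = build_empirical_null(sm, n_samples=2000, seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_degenerate_matrix_gives_constant_null(self):
        pwm = PWM(id="U", name="U", counts=np.full((4, 4), 25))
        null = build_empirical_null(to_log_odds(pwm), n_samples=1000, seed=1)
        assert np.allclose(null.scores, null.scores[0])

    def test_null_mean_matches_closed_form(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        comp = np.array([0.2, 0.3, 0.3, 0.2])
        null = build_empirical_null(sm, comp, n_samples=100_000, seed=6)
        expected = (sm.logodds * comp).sum()
        sd = np.sqrt(((sm.logodds**2 * comp).sum(axis=1)
                      - (sm.logodds * comp).sum(axis=1) ** 2).sum())
        assert abs(null.scores.mean() - expected) < 4 * sd / np.sqrt(100_000)

    def test_too_few_samples_rejected(self, simple_pwm):
        with pytest.raises(ValueError):
            build_empirical_null(to_log_odds(simple_pwm), n_samples=10, seed=0)


class TestEmpiricalPvalue:
    def test_extreme_scores(self):
        null = EmpiricalNull(pwm_id="X", scores=np.arange(999.0))
        assert empirical_pvalue(1e9, null) == pytest.approx(1 / 1000)
        assert empirical_pvalue(-1e9, null) == 1.0

    def test_median_score_gives_half(self):
        rng = np.random.default_rng(20)
        scores = rng.normal(size=99_999)
        null = EmpiricalNull(pwm_id="X", scores=scores)
        p = empirical_pvalue(float(np.median(scores)), null)
        assert p == pytest.approx(0.5, abs=0.001)

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(21)
        null = EmpiricalNull(pwm_id="X", scores=rng.normal(size=5000))
        grid = np.linspace(-4, 4, 200)
        ps = empirical_pvalue(grid, null)
        assert (np.diff(ps) <= 0).all()

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(22)
        scores = rng.normal(size=3000)
        null = EmpiricalNull(pwm_id="X", scores=scores)
        for s in rng.normal(size=50):
            expected = (1 + (scores >= s).sum()) / (len(scores) + 1)
            assert empirical_pvalue(s, null) == pytest.approx(expected)


class TestFilterMatches:
    def make_match(self, start, score, pwm_id="TST0001"):
        return MotifMatch(
            interval=GenomicInterval("c", start, start + 8), pwm_id=pwm_id, score=score
        )

    def test_consensus_retained_with_tiny_p(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        null = build_empirical_null(sm, n_samples=5000, seed=7)
        kept = filter_matches([self.make_match(0, sm.max_score)], null)
        assert len(kept) == 1
        assert kept[0].p_emp == pytest.approx(1 / 5001)

    def test_empty_input(self, simple_pwm):
        null = build_empirical_null(to_log_odds(simple_pwm), n_samples=1000, seed=7)
        assert filter_matches([], null) == []

    def test_mismatched_pwm_id_rejected(self, simple_pwm):
        null = build_empirical_null(to_log_odds(simple_pwm), n_samples=1000, seed=7)
        with pytest.raises(ValueError):
            filter_matches([self.make_match(0, 1.0, pwm_id="OTHER")], null)

    def test_null_calibration_retains_p_max_fraction(self, simple_pwm):
        """Scoring background windows against a null from the same
        composition keeps ~5% of windows."""
        sm = to_log_odds(simple_pwm)
        null = build_empirical_null(sm, n_samples=20_000, seed=30)
        seq = simulate_genome(20_000 + len(simple_pwm) - 1, seed=31)
        matches = scan(seq, sm, threshold=sm.min_score - 1, both_strands=False)
        kept = filter_matches(matches, null)
        frac = len(kept) / len(matches)
        assert frac == pytest.approx(0.05, abs=0.01)


class TestPeakContainment:
    def peak(self, start, end):
        return Peak(GenomicInterval("c", start, end), "cellA", "TF1")

    def test_contained_kept_straddling_dropped(self):
        peaks = [self.peak(0, 100)]
        inside = MotifMatch(GenomicInterval("c", 10, 18), "P", 1.0)
        straddle = MotifMatch(GenomicInterval("c", 95, 103), "P", 1.0)
        assert within_peaks([inside, straddle], peaks) == [inside]

    def test_matches_quadratic_containment_oracle(self):
        rng = np.random.default_rng(33)
        peaks = [
            Peak(GenomicInterval("c", s, s + int(rng.integers(20, 80))), "x", "TF")
            for s in rng.integers(0, 2000, size=30)
        ]
        matches = [
            MotifMatch(GenomicInterval("c", s, s + 8), "P", 0.0)
            for s in rng.integers(0, 2000, size=200)
        ]
        expected = [
            m for m in matches
            if any(p.interval.contains(m.interval) for p in peaks)
        ]
        assert within_peaks(matches, peaks) == expected

    def test_association_by_single_base_overlap(self):
        rng = np.random.default_rng(34)
        feats = [
            Peak(GenomicInterval("c", s, s + int(rng.integers(5, 60))), "x", f"TF{i}")
            for i, s in enumerate(rng.integers(0, 1000, size=20))
        ]
        matches = [
            MotifMatch(GenomicInterval("c", s, s + 8), "P", 0.0)
            for s in rng.integers(0, 1000, size=50)
        ]
        mapping = associate(matches, feats)
        for m in matches:
            expected = [
                f.feature_type for f in feats
                if overlap_length(m.interval, f.interval) >= 1
            ]
            assert mapping[m] == expected


class TestInformationContent:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([1, 0, 0, 0], 2.0),
            ([25, 25, 25, 25], 0.0),
            ([50, 50, 0, 0], 1.0),
        ],
    )
    def test_closed_forms_without_pseudocount(self, column, expected):
        pwm = PWM(id="X", name="X", counts=np.array([column]))
        assert column_information(pwm, 0, NO_PSEUDO) == pytest.approx(expected)

    def test_bounded_in_zero_two(self):
        rng = np.random.default_rng(35)
        for seed in range(20):
            pwm = random_pwm(6, seed=seed)
            for i in range(6):
                assert 0.0 <= column_information(pwm, i) <= 2.0

    def test_out_of_range_column_rejected(self, simple_pwm):
        with pytest.raises(IndexError):
            column_information(simple_pwm, len(simple_pwm))


class TestScoreRatio:
    def test_consensus_is_one(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        m = MotifMatch(GenomicInterval("c", 0, 8), "TST0001", sm.max_score)
        assert score_ratio(m, sm) == pytest.approx(1.0)

    def test_simple_fraction(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        m = MotifMatch(GenomicInterval("c", 0, 8), "TST0001", 0.75 * sm.max_score)
        assert score_ratio(m, sm) == pytest.approx(0.75)

    def test_rescanned_scores_are_consistent(self, simple_pwm):
        sm = to_log_odds(simple_pwm)
        seq = simulate_genome(500, seed=36)
        for m in scan(seq, sm, threshold=0.4 * sm.max_score, both_strands=False):
            window = seq[m.interval.start : m.interval.end]
            rescore = sum(
                sm.logodds[i, "ACGT".index(b)] for i, b in enumerate(window)
            )
            assert score_ratio(m, sm) == pytest.approx(rescore / sm.max_score)


class TestPwmGeneAssociation:
    def test_priority_and_fallback(self):
        xrefs = {"MA1": "GENE_X", "MA2": "GENE_Y"}
        besthits = {"MA2": "GENE_Z", "MA3": "GENE_W"}
        mapping = associate_pwm_to_gene(xrefs, besthits)
        assert mapping == {"MA1": "GENE_X", "MA2": "GENE_Y", "MA3": "GENE_W"}

    def test_unmapped_pwm_absent(self):
        assert "MA9" not in associate_pwm_to_gene({}, {"MA3": "G"})

    def test_conflicting_xrefs_rejected(self):
        xrefs = pd.DataFrame({"pwm": ["MA1", "MA1"], "gene": ["G1", "G2"]})
        with pytest.raises(ValueError, match="MA1"):
            associate_pwm_to_gene(xrefs, {})
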