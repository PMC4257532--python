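"""PWM scoring, matrix building, promoter scanning, and module detection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synergyscan.io import PromoterSet
from synergyscan.motifs import (
    BASES,
    PWM,
    BindingSiteHit,
    TFClass,
    annotate_promoters,
    build_pwm,
    column_information_weight,
    core_similarity,
    default_class_pwms,
    detect_modules,
    matrix_similarity,
    pwm_from_consensus,
    read_pwms,
    reverse_complement,
    scan_promoters,
    write_pwms,
)
from synergyscan.simulate import PlantSpec, simulate_promoters


def brute_force_score(pwm: PWM, window: str, positions=None) -> float:
    """Direct formula evaluation: raw = sum ci * f(base), min-max normalized."""
    idx = range(len(pwm)) if positions is None else positions
    raw = raw_min = raw_max = 0.0
    for i in idx:
        b = BASES.index(window[i])
        raw += pwm.ci[i] * pwm.freq[i, b]
        raw_min += pwm.ci[i] * pwm.freq[i].min()
        raw_max += pwm.ci[i] * pwm.freq[i].max()
    if raw_max - raw_min <= 1e-12:
        return 1.0
    return (raw - raw_min) / (raw_max - raw_min)


class TestInformationWeight:
    def test_uniform_is_zero(self):
        assert column_information_weight([0.25] * 4) == pytest.approx(0.0)

    def test_degenerate_is_one(self):
        assert column_information_weight([1, 0, 0, 0]) == pytest.approx(1.0)

    def test_half_half_closed_form(self):
        # ln(2)/ln(4) = 1/2
        assert column_information_weight([0.5, 0.5, 0, 0]) == pytest.approx(0.5)

    @given(st.lists(st.floats(0.001, 1), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_bounded_in_unit_interval(self, raw):
        f = np.array(raw) / np.sum(raw)
        ci = column_information_weight(f)
        assert -1e-12 <= ci <= 1 + 1e-12


class TestMatrixSimilarity:
    @pytest.fixture
    def pwm(self):
        return pwm_from_consensus("stat", TFClass.STAT, "TTCCCGGAA", strength=0.7)

    def test_consensus_scores_one(self, pwm):
        assert matrix_similarity(pwm, pwm.consensus) == pytest.approx(1.0)

    def test_anti_consensus_scores_zero(self):
        freq = np.tile([0.7, 0.1, 0.1, 0.1], (4, 1))
        pwm = PWM("t", TFClass.OTHER, freq)
        assert matrix_similarity(pwm, "CCCC") == pytest.approx(0.0)

    def test_two_position_hand_case(self):
        pwm = PWM("t", TFClass.OTHER, np.array([[1, 0, 0, 0], [0.5, 0.5, 0, 0]]))
        scores = {
            "".join(w): matrix_similarity(pwm, "".join(w))
            for w in itertools.product(BASES, repeat=2)
        }
        top = {w for w, s in scores.items() if s == max(scores.values())}
        assert top == {"AA", "AC"}
        assert scores["AA"] == pytest.approx(1.0)

    def test_core_separates_from_full_matrix(self):
        pwm = pwm_from_consensus("t", TFClass.OTHER, "AAAACCCC", strength=0.9)
        window = pwm.consensus[:4] + "GGGG"  # match only the leading positions
        core_first = PWM("t", TFClass.OTHER, pwm.freq, core_size=4)
        # symmetric ci: leftmost 4 positions are the core
        assert core_first.core_positions == (0, 1, 2, 3)
        assert core_similarity(core_first, window) == pytest.approx(1.0)
        assert matrix_similarity(core_first, window) < 1.0

    def test_uniform_matrix_guard(self):
        pwm = PWM("u", TFClass.OTHER, np.full((5, 4), 0.25))
        assert core_similarity(pwm, "ACGTA") == pytest.approx(1.0)
        assert matrix_similarity(pwm, "ACGTA") == pytest.approx(1.0)

    def test_core_positions_match_exhaustive_argmax(self):
        rng = np.random.default_rng(5)
        raw = rng.dirichlet([0.5] * 4, size=6)
        pwm = PWM("t", TFClass.OTHER, raw, core_size=4)
        sums = [pwm.ci[i : i + 4].sum() for i in range(3)]
        assert pwm.core_positions[0] == int(np.argmax(sums))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_scores_bounded_and_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pwm = PWM("t", TFClass.OTHER, rng.dirichlet([1] * 4, size=5))
        window = "".join(rng.choice(list(BASES), size=5))
        score = matrix_similarity(pwm, window)
        assert 0 - 1e-9 <= score <= 1 + 1e-9
        assert score == pytest.approx(brute_force_score(pwm, window), abs=1e-9)
        core = core_similarity(pwm, window)
        assert core == pytest.approx(
            brute_force_score(pwm, window, pwm.core_positions), abs=1e-9
        )


class TestScanPromoters:
    def test_hit_sets_equal_brute_force_for_short_pwms(self):
        rng = np.random.default_rng(11)
        proms, _ = simulate_promoters(3, length=120, window=(-100, 20), seed=11)
        pwms = [
            PWM(f"p{i}", TFClass.OTHER, rng.dirichlet([0.4] * 4, size=L))
            for i, L in enumerate((4, 5, 6))
        ]
        hits = scan_promoters(proms, pwms, min_core=0.7, min_mss=0.6)
        got = {(h.gene_id, h.pwm_name, h.strand, h.start) for h in hits}
        expected = set()
        for gene, seq in proms:
            for pwm in pwms:
                L = len(pwm)
                for strand in "+-":
                    s = seq if strand == "+" else reverse_complement(seq)
                    for j in range(len(s) - L + 1):
                        w = s[j : j + L]
                        if (
                            brute_force_score(pwm, w, pwm.core_positions) >= 0.7
                            and brute_force_score(pwm, w) >= 0.6
                        ):
                            plus = j if strand == "+" else len(s) - j - L
                            expected.add(
                                (gene, pwm.name, strand, proms.window_start + plus)
                            )
        assert got == expected

    def test_minus_strand_planted_site_coordinates(self):
        pwm = pwm_from_consensus("nfkb", TFClass.NFKB, "GGGACTTTCC", strength=0.95)
        background = "A" * 200
        planted_at = 50  # 0-based position in the sequence
        seq = (
            background[:planted_at]
            + reverse_complement(pwm.consensus)
            + background[planted_at + 10 :]
        )
        proms = PromoterSet({"g": seq}, window_start=-150, window_end=50)
        hits = [
            h
            for h in scan_promoters(proms, [pwm], min_core=0.99, min_mss=0.99)
            if h.pwm_name == "nfkb"
        ]
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].start == -150 + planted_at
        assert hits[0].end == hits[0].start + 10

    def test_random_sequence_no_hits_at_strict_threshold(self):
        proms, _ = simulate_promoters(10, length=500, window=(-400, 100), seed=3)
        pwm = pwm_from_consensus("isre", TFClass.ISRE, "GGAAAGTGAAAC", strength=0.97)
        hits = scan_promoters(proms, [pwm], min_core=0.99, min_mss=0.99)
        assert hits == []

    def test_zero_thresholds_emit_every_window(self):
        proms = PromoterSet({"g": "ACGT" * 10}, window_start=0, window_end=40)
        pwm = pwm_from_consensus("x", TFClass.OTHER, "ACGTA", strength=0.9)
        hits = scan_promoters(proms, [pwm], min_core=0.0, min_mss=0.0)
        assert len(hits) == 2 * (40 - 5 + 1)

    def test_strand_symmetry(self):
        proms, _ = simulate_promoters(
            5, length=300, window=(-250, 50),
            planted=[PlantSpec(TFClass.STAT)], seed=9,
        )
        flipped = PromoterSet(
            {g: reverse_complement(s) for g, s in proms},
            proms.window_start, proms.window_end,
        )
        pwms = default_class_pwms()
        fwd = scan_promoters(proms, pwms)
        rev = scan_promoters(flipped, pwms)
        n = proms.length

        def key(h):
            # mirror: + strand start s of width L maps to n-1-(s+L-1) offset
            L = h.end - h.start
            mirrored = proms.window_start + (
                n - (h.start - proms.window_start) - L
            )
            return (h.gene_id, h.pwm_name, mirrored, round(h.mat_sim, 9))

        assert {key(h) for h in fwd} == {
            (h.gene_id, h.pwm_name, h.start, round(h.mat_sim, 9)) for h in rev
        }


class TestBuildPWM:
    def test_identical_embedded_motif_recovered(self):
        rng = np.random.default_rng(21)
        motif = "GGAAAGTGAAAC"
        sites = []
        for _ in range(20):
            left = "".join(rng.choice(list(BASES), size=6))
            right = "".join(rng.choice(list(BASES), size=6))
            sites.append(left + motif + right)
        res = build_pwm(sites, tuple_size=8)
        consensus = res.pwm.consensus
        assert motif in consensus or reverse_complement(motif) in consensus
        assert len(res.included) == 20

    def test_mutated_sites_mostly_included(self):
        proms, truth = simulate_promoters(
            50, length=40, window=(0, 40),
            planted=[PlantSpec(TFClass.ISRE, position=14)],
            mutation_rate=0.10, seed=42,
        )
        sites = [seq for _, seq in proms]
        res = build_pwm(sites, tuple_size=8, min_tuple_frac=0.60, mss_inclusion=0.90)
        assert len(res.included) >= 45  # >= 90% of 50 planted sites

    def test_random_sites_without_common_tuple_rejected(self):
        rng = np.random.default_rng(1)
        sites = ["".join(rng.choice(list(BASES), size=30)) for _ in range(20)]
        with pytest.raises(ValueError, match="tuple"):
            build_pwm(sites, tuple_size=8)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="5 sites"):
            build_pwm(["ACGTACGTACGT"] * 4)


class TestModules:
    def _hit(self, cls, start, end, gene="g", strand="+"):
        return BindingSiteHit(gene, cls.value, cls, strand, start, end, 0.95, 0.99)

    def test_stat_nfkb_module_with_gap(self):
        hits = [
            self._hit(TFClass.STAT, -200, -185),
            self._hit(TFClass.NFKB, -150, -140),
        ]
        calls = detect_modules(hits, max_gap=100)
        assert len(calls) == 1
        assert calls[0].module_type == "STAT_NFKB"
        assert calls[0].gap == 35

    def test_gap_above_threshold_no_module(self):
        hits = [
            self._hit(TFClass.STAT, -200, -185),
            self._hit(TFClass.NFKB, -150, -140),
        ]
        assert detect_modules(hits, max_gap=20) == []

    def test_overlapping_hits_gap_zero(self):
        hits = [
            self._hit(TFClass.ISRE, -100, -88),
            self._hit(TFClass.NFKB, -95, -85),
        ]
        calls = detect_modules(hits)
        assert calls[0].gap == 0
        assert calls[0].module_type == "IRF_NFKB"

    def test_both_module_types_called_independently(self):
        hits = [
            self._hit(TFClass.STAT, -300, -291),
            self._hit(TFClass.ISRE, -280, -268),
            self._hit(TFClass.NFKB, -260, -250),
        ]
        types = {c.module_type for c in detect_modules(hits)}
        assert types == {"STAT_NFKB", "IRF_NFKB"}


class TestAnnotatePromoters:
    def test_module_consumes_singleton_columns(self):
        proms, _ = simulate_promoters(
            4, length=400, window=(-300, 100),
            planted=[
                PlantSpec(TFClass.STAT, position=-200, strand="+"),
                PlantSpec(TFClass.NFKB, position=-150, strand="+"),
            ],
            seed=13,
        )
        table, hits, modules = annotate_promoters(
            proms, default_class_pwms(), min_mss=0.95
        )
        assert table["STAT_NFKB"].all()
        assert not table["STAT"].any()
        assert not table["NFKB"].any()
        assert len(modules) >= len(proms)

    def test_lone_isre_only_sets_isre_column(self):
        proms, _ = simulate_promoters(
            3, length=400, window=(-300, 100),
            planted=[PlantSpec(TFClass.ISRE, position=-100, strand="+")],
            seed=14,
        )
        table, _, _ = annotate_promoters(proms, default_class_pwms(), min_mss=0.95)
        assert table["ISRE"].all()
        for col in ("STAT_NFKB", "IRF_NFKB", "STAT", "NFKB"):
            assert not table[col].any()

    def test_empty_promoter_all_false(self):
        proms = PromoterSet({"g": "A" * 300}, window_start=-200, window_end=100)
        table, hits, modules = annotate_promoters(proms, default_class_pwms())
        assert not table.loc["g"].any()
        assert hits == [] and modules == []


class TestSerialization:
    def test_pwm_roundtrip(self, tmp_path):
        pwms = default_class_pwms()
        path = tmp_path / "matrices.txt"
        write_pwms(pwms, path)
        back = read_pwms(path)
        assert [p.name for p in back] == [p.name for p in pwms]
        for a, b in zip(pwms, back):
            assert a.tf_class == b.tf_class
            np.testing.assert_allclose(a.freq, b.freq, atol=1e-6)
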