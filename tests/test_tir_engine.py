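"""The element screen: consensus building, scanning, pairing, validation."""

import random

import pytest

from mulescan import (
    MuElement,
    ScreenConfig,
    Sequence,
    StructuralClass,
    TirHit,
    TirModel,
    build_tir_model,
    check_terminal_motifs,
    classify_structure,
    detect_tsd,
    pair_tirs,
    revcomp,
    scan_tirs,
    screen_elements,
    tir_pair_identity,
)
from mulescan.tir_engine import InconsistencyError

from conftest import random_dna


def _mutate(rng: random.Random, s: str, n: int) -> str:
    out = list(s)
    for i in rng.sample(range(len(s)), n):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


@pytest.fixture
def template(rng) -> str:
    return "GAGATA" + random_dna(rng, 214)


class TestBuildTirModel:
    def test_single_tir_is_its_own_consensus(self, template):
        model = build_tir_model([Sequence("t1", template)])
        assert model.consensus.residues == template

    def test_majority_vote_restores_original(self, rng, template):
        # three copies, each with one substitution at a distinct position
        tirs = []
        positions = rng.sample(range(220), 3)
        for k, pos in enumerate(positions):
            out = list(template)
            out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
            tirs.append(Sequence(f"t{k}", "".join(out)))
        model = build_tir_model(tirs)
        assert model.consensus.residues == template

    def test_ties_broken_alphabetically(self):
        a = "GAGATA" + "A" * 194
        b = "GAGATA" + "A" * 193 + "C"
        model = build_tir_model([Sequence("a", a), Sequence("b", b)])
        assert model.consensus.residues[-1] == "A"  # A < C on a 1-1 tie

    def test_rejects_out_of_range_lengths(self):
        with pytest.raises(ValueError):
            build_tir_model([Sequence("short", "ACGT" * 10)])
        with pytest.raises(ValueError):
            build_tir_model([])


class TestScanTirs:
    def test_genome_equal_to_consensus(self, template):
        model = TirModel(Sequence("c", template))
        hits = scan_tirs(Sequence("g", template), model)
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.end, h.orientation) == (0, 220, "forward")
        assert h.identity_pct == 100.0

    def test_planted_inverted_pair_found_exactly(self, rng, template):
        model = TirModel(Sequence("c", template))
        left = random_dna(rng, 500)
        mid = random_dna(rng, 1000)
        right = random_dna(rng, 500)
        genome = Sequence("g", left + template + mid + revcomp(template) + right)
        hits = scan_tirs(genome, model)
        assert [(h.start, h.end, h.orientation, h.identity_pct) for h in hits] == [
            (500, 720, "forward", 100.0),
            (1720, 1940, "reverse", 100.0),
        ]

    def test_heavily_mutated_tir_not_hit(self, rng, template):
        model = TirModel(Sequence("c", template))
        decayed = _mutate(rng, template, 44)  # 20% of 220 -> 80% identity
        genome = Sequence("g", random_dna(rng, 300) + decayed + random_dna(rng, 300))
        assert scan_tirs(genome, model) == []

    def test_lowering_threshold_never_loses_hits(self, rng, template):
        model = TirModel(Sequence("c", template))
        mild = _mutate(rng, template, 22)  # 90% identity
        genome = Sequence(
            "g", random_dna(rng, 300) + template + random_dna(rng, 400) + mild
        )
        strict_hits = scan_tirs(genome, model, min_identity_pct=95)
        loose_hits = scan_tirs(genome, model, min_identity_pct=80)
        strict_set = {(h.start, h.end, h.orientation) for h in strict_hits}
        loose_set = {(h.start, h.end, h.orientation) for h in loose_hits}
        assert strict_set <= loose_set
        assert len(loose_set) > len(strict_set)

    def test_all_n_genome_yields_nothing(self, template):
        model = TirModel(Sequence("c", template))
        assert scan_tirs(Sequence("g", "N" * 5000), model) == []


def _hit(start, end, orientation="forward", ident=100.0):
    return TirHit("g", start, end, orientation, ident, float(end - start))


class TestPairTirs:
    def test_forward_reverse_pair_within_span(self):
        hits = [_hit(0, 220), _hit(1274, 1494, "reverse")]
        elements = pair_tirs(hits)
        paired = [e for e in elements if not e.is_solo]
        assert len(paired) == 1
        assert paired[0].interval == (0, 1494)  # the Mu13 span scale

    def test_two_forward_hits_become_solos(self):
        elements = pair_tirs([_hit(0, 220), _hit(1000, 1220)])
        assert all(e.is_solo for e in elements)
        assert len(elements) == 2

    def test_span_beyond_max_excluded(self):
        elements = pair_tirs([_hit(0, 220), _hit(9780, 10000, "reverse")])
        assert all(e.is_solo for e in elements)


class TestTerminalMotifs:
    def test_perfect_ends(self, rng):
        inner = random_dna(rng, 500)
        g = Sequence("g", "CCC" + "GAGATA" + inner + "TATCTC" + "CCC")
        e = MuElement("g", 3, 3 + 512, _hit(3, 223))
        assert check_terminal_motifs(g, e) is True

    def test_single_terminal_mismatch_fails(self, rng):
        inner = random_dna(rng, 500)
        g = Sequence("g", "CCC" + "GAGATA" + inner + "TATCTG" + "CCC")
        e = MuElement("g", 3, 3 + 512, _hit(3, 223))
        assert check_terminal_motifs(g, e) is False

    def test_too_short_element_rejected(self):
        g = Sequence("g", "GAGATATCTC")
        e = MuElement("g", 0, 10, _hit(0, 10))
        assert check_terminal_motifs(g, e) is False

    def test_out_of_bounds_raises(self):
        g = Sequence("g", "ACGT" * 10)
        e = MuElement("g", 0, 100, _hit(0, 100))
        with pytest.raises(IndexError):
            check_terminal_motifs(g, e)


class TestDetectTsd:
    def test_planted_duplication_detected(self, rng):
        tsd = "ACGTACGTA"
        element = "GAGATA" + random_dna(rng, 488) + "TATCTC"
        g = Sequence("g", random_dna(rng, 100) + tsd + element + tsd + random_dna(rng, 100))
        e = MuElement("g", 109, 109 + 500, _hit(109, 209))
        res = detect_tsd(g, e)
        assert res.present is True
        assert res.mismatches == 0
        assert res.left_copy == res.right_copy == tsd

    def test_mismatch_threshold_semantics(self, rng):
        left = "ACGTACGTA"
        right = "ACGTACGTC"
        element = random_dna(rng, 500)
        g = Sequence("g", random_dna(rng, 50) + left + element + right + random_dna(rng, 50))
        e = MuElement("g", 59, 559, _hit(59, 159))
        assert detect_tsd(g, e).present is False
        assert detect_tsd(g, e, max_mismatch=1).present is True

    def test_short_flank_is_indeterminate(self, rng):
        g = Sequence("g", random_dna(rng, 520))
        e = MuElement("g", 3, 503, _hit(3, 103))
        res = detect_tsd(g, e)
        assert res.present is None
        assert res.indeterminate


class TestTirPairIdentity:
    def test_identical_inverted_tirs(self, rng, template):
        internal = random_dna(rng, 800)
        g = Sequence("g", template + internal + revcomp(template))
        e = MuElement(
            "g", 0, len(g),
            _hit(0, 220),
            _hit(len(g) - 220, len(g), "reverse"),
        )
        assert tir_pair_identity(g, e) == 100.0

    def test_two_substitutions_over_200(self, rng):
        left = random_dna(rng, 200)
        right_fwd = _mutate(rng, left, 2)
        g = Sequence("g", left + random_dna(rng, 600) + revcomp(right_fwd))
        e = MuElement("g", 0, 1000, _hit(0, 200), _hit(800, 1000, "reverse"))
        assert tir_pair_identity(g, e) == pytest.approx(99.0)

    def test_solo_raises(self):
        g = Sequence("g", "ACGT" * 100)
        with pytest.raises(ValueError):
            tir_pair_identity(g, MuElement("g", 0, 100, _hit(0, 100)))


class TestClassifyStructure:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ((0, 223), (1271, 1490), StructuralClass.FULL_FULL),
            ((0, 215), (1400, 1490), StructuralClass.LONG_SHORT),
            ((0, 100), (1390, 1490), StructuralClass.SHORT_SHORT),
        ],
    )
    def test_tir_length_classes(self, left, right, expected):
        e = MuElement(
            "g", left[0], right[1],
            _hit(*left),
            _hit(right[0], right[1], "reverse"),
        )
        assert classify_structure(e) is expected

    def test_single_tir_is_solo(self):
        e = MuElement("g", 0, 220, _hit(0, 220))
        assert classify_structure(e) is StructuralClass.SOLO

    def test_impossibly_short_tir_raises(self):
        e = MuElement("g", 0, 1000, _hit(0, 30), _hit(900, 1000, "reverse"))
        with pytest.raises(InconsistencyError):
            classify_structure(e)


class TestScreenElements:
    def test_perfect_planted_elements_all_strict(self, small_sim):
        cfg, genome, truth, model = small_sim
        res = screen_elements(genome, model, ScreenConfig(min_tir_len=60))
        full = truth.by_class(StructuralClass.FULL_FULL)
        strict_ivals = sorted(e.interval for e in res.strict)
        assert strict_ivals == sorted(t.interval for t in full)

    def test_element_without_tsd_reported_but_not_strict(self, rng, template):
        internal = random_dna(rng, 1000)
        element = template + internal + revcomp(template)
        g = Sequence("g", random_dna(rng, 400) + element + random_dna(rng, 400))
        model = TirModel(Sequence("c", template))
        res = screen_elements(g, model)
        assert len(res.elements) == 1
        e = res.elements[0]
        assert e.tsd.present is False
        assert e.terminal_motifs_ok is True
        assert res.strict == []

    def test_all_n_genome_empty_result(self, template):
        model = TirModel(Sequence("c", template))
        res = screen_elements(Sequence("g", "N" * 3000), model)
        assert res.elements == [] and res.strict == []

    def test_element_sequence_starts_and_ends_on_tirs(self, small_sim):
        cfg, genome, truth, model = small_sim
        res = screen_elements(genome, model, ScreenConfig(min_tir_len=60))
        for e in res.elements:
            assert e.start == e.left_tir.start
            if not e.is_solo:
                assert e.end == e.right_tir.end
            lo, hi = e.internal_interval
            assert e.start <= lo <= hi <= e.end
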