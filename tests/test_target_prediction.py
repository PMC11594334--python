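"""Seed-site scanning on circular sequences, against a naive windowed oracle."""

import numpy as np
import pytest

from cernaforge.target_prediction import (
    InteractionSet,
    circ_mir_interactions,
    circularize,
    expressed_mirnas,
    mir_mrna_interactions,
    reverse_complement,
    scan_mre,
)

from conftest import make_matrix

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_scan(circ: str, mirna: str):
    """Independent oracle: classify every rotation window of the circle
    directly from the site definitions, using modular indexing."""
    s = circ.upper().replace("U", "T")
    mi = mirna.upper().replace("U", "T")
    L = len(s)
    seed = mi[1:7]
    sites = []
    for j in range(L):  # j = seed-match start on the circle
        window = "".join(s[(j + k) % L] for k in range(6))
        if window != "".join(_COMP[b] for b in reversed(seed)):
            continue
        m8 = s[(j - 1) % L] == _COMP[mi[7]]
        a1 = s[(j + 6) % L] == "A"
        if m8 and a1:
            t, start, ln = "8mer", (j - 1) % L, 8
        elif m8:
            t, start, ln = "7mer-m8", (j - 1) % L, 7
        elif a1:
            t, start, ln = "7mer-A1", j, 7
        else:
            t, start, ln = "6mer", j, 6
        sites.append((t, start, start + ln > L))
    return sorted(set(sites), key=lambda x: (x[1], x[0]))


def _make_site(mirna: str, kind: str) -> str:
    """Target-strand sequence for one site of the requested grade."""
    mi = mirna.upper().replace("U", "T")
    seed_rc = reverse_complement(mi[1:7])
    m8c = _COMP[mi[7]]
    if kind == "8mer":
        return m8c + seed_rc + "A"
    if kind == "7mer-m8":
        return m8c + seed_rc + "C"  # A1 slot deliberately not 'A'
    if kind == "7mer-A1":
        other = "C" if m8c != "C" else "G"
        return other + seed_rc + "A"
    return "C" + seed_rc + "C" if m8c != "C" else "G" + seed_rc + "G"


MIRNA = "UAGCUUAUCAGACUGAUGUUGA"  # 22 nt, miR-21-like


class TestCircularize:
    def test_definition(self):
        assert circularize("ACGTACGT", 3) == "ACGTACGTACG"

    def test_zero_overhang_identity(self):
        assert circularize("ACGT", 0) == "ACGT"

    def test_overhang_too_long(self):
        with pytest.raises(ValueError, match="overhang"):
            circularize("ACGT", 4)


class TestScanMre:
    def test_constructed_8mer_at_offset_zero(self):
        circ = _make_site(MIRNA, "8mer") + "CCGGCCGGCCGG"
        sites = scan_mre(circ, MIRNA)
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert sites[0].start == 0
        assert not sites[0].spans_bsj

    def test_no_complementarity_empty(self):
        assert scan_mre("A" * 60, MIRNA) == []

    @pytest.mark.parametrize("kind", ["8mer", "7mer-m8", "7mer-A1", "6mer"])
    def test_each_site_class_detected(self, kind):
        circ = "CCGG" * 5 + _make_site(MIRNA, kind) + "GGCC" * 5
        sites = scan_mre(circ, MIRNA)
        assert [s.site_type for s in sites] == [kind]

    def test_three_planted_7mer_m8_found_exactly(self):
        rng = np.random.default_rng(10)
        site = _make_site(MIRNA, "7mer-m8")
        while True:
            seq = list("".join(rng.choice(list("ACGT"), 500)))
            base = "".join(seq)
            if naive_scan(base, MIRNA):  # avoid coincidental background sites
                continue
            for pos in (40, 200, 420):
                seq[pos:pos + len(site)] = site
            cand = "".join(seq)
            got = scan_mre(cand, MIRNA)
            expected = naive_scan(cand, MIRNA)
            assert [(s.site_type, s.start, s.spans_bsj) for s in got] == expected
            assert sum(s.site_type == "7mer-m8" for s in got) == 3
            break

    def test_junction_spanning_site_needs_circularization(self):
        """A site straddling position 0 of a 60-nt circle is found with the
        default overhang and missed when the overhang is zero."""
        site = _make_site(MIRNA, "8mer")
        rot = site[4:] + "C" * (60 - len(site)) + site[:4]
        while naive_scan("C" * 4 + rot[4:], MIRNA):  # safety: no stray sites
            raise AssertionError("background produced an accidental site")
        found = scan_mre(rot, MIRNA)
        assert len(found) == 1
        assert found[0].spans_bsj
        assert found[0].site_type == "8mer"
        assert scan_mre(rot, MIRNA, overhang=0) == []

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            L = int(rng.integers(20, 101))
            circ = "".join(rng.choice(list("ACGT"), L))
            mirna = "".join(rng.choice(list("ACGT"), int(rng.integers(18, 24))))
            got = [(s.site_type, s.start, s.spans_bsj) for s in scan_mre(circ, mirna)]
            assert got == naive_scan(circ, mirna)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        circ = "".join(rng.choice(list("ACGT"), 120))
        base = {(s.site_type, s.spans_bsj is not None) for s in scan_mre(circ, MIRNA)}
        base_types = sorted(s.site_type for s in scan_mre(circ, MIRNA))
        for shift in (1, 17, 60, 119):
            rot = circ[shift:] + circ[:shift]
            assert sorted(s.site_type for s in scan_mre(rot, MIRNA)) == base_types

    def test_u_and_t_interchangeable(self):
        circ = _make_site(MIRNA, "8mer") + "CCGGCCGG"
        assert scan_mre(circ.replace("T", "U"), MIRNA) == scan_mre(circ, MIRNA)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            scan_mre("ACGTNNN" * 3, MIRNA)

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            scan_mre("ACGT" * 10, "ACGUACG")


class TestInteractions:
    def test_threshold_hierarchy(self):
        sites_8 = scan_mre(_make_site(MIRNA, "8mer") + "CC", MIRNA, "c1", "mi1")
        sites_6 = scan_mre(_make_site(MIRNA, "6mer") + "CC", MIRNA, "c2", "mi1")
        assert circ_mir_interactions(sites_8) == {("c1", "mi1")}
        assert circ_mir_interactions(sites_6) == set()
        assert circ_mir_interactions(sites_6, min_site_type="6mer") == {("c2", "mi1")}

    def test_mir_mrna_filter_and_dedup(self):
        table = [("mi1", "g1"), ("mi1", "g1"), ("mi2", "g2"), ("mi3", "g3")]
        assert mir_mrna_interactions(table, {"g1", "g2"}) == {("mi1", "g1"), ("mi2", "g2")}
        assert mir_mrna_interactions(table, set()) == set()

    def test_malformed_row_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            mir_mrna_interactions([("mi1",)], {"g1"})

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self"):
            InteractionSet(frozenset({("x", "x")}), frozenset())


class TestExpressedMirnas:
    def test_expression_rule(self):
        m = make_matrix(np.array([
            [5, 3, 2, 0, 0, 0],   # 3 of 6 samples -> expressed
            [0, 0, 0, 0, 0, 0],   # never expressed
            [9, 9, 0, 0, 0, 0],   # 2 of 6 -> not expressed
        ]), feature_ids=["mi1", "mi2", "mi3"])
        assert expressed_mirnas(m) == {"mi1"}

    def test_raising_min_count_shrinks(self):
        rng = np.random.default_rng(12)
        m = make_matrix(rng.poisson(4, size=(30, 6)))
        assert expressed_mirnas(m, min_count=10) <= expressed_mirnas(m, min_count=1)
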