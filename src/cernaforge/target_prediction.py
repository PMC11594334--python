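"""miRNA-response-element (MRE) discovery on circular sequences.

circRNA-miRNA interactions are predicted by canonical seed matching in the
TargetScan site hierarchy. The seed is miRNA positions 2-7; a target site is
a Watson-Crick match to the reverse complement of the seed, graded by two
flanking features:

* ``8mer``     seed match + match to miRNA position 8 + 'A' opposite position 1
* ``7mer-m8``  seed match + match to miRNA position 8
* ``7mer-A1``  seed match + 'A' opposite miRNA position 1
* ``6mer``     seed match only

Because a circRNA is covalently closed, a site may straddle the back-spliced
junction; sequences are therefore scanned after appending the first
``overhang`` bases (default 7 = longest site length - 1, the minimum that
guarantees junction-spanning discovery), and hits are de-duplicated by their
start position modulo the circle length, keeping exactly one classification
per modular site. T and U are interchangeable on input.

miRNA-mRNA interactions are not predicted de novo; an external
TargetScan-like table is filtered to the DE mRNA set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .expression_io import CountMatrix, filter_by_junction_reads

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")  # weakest -> strongest
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}
_SITE_LEN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class MreSite:
    circ_id: str
    mirna_id: str
    site_type: str
    start: int  # 0-based offset of the site's 5'-most base on the circle
    spans_bsj: bool


@dataclass(frozen=True)
class InteractionSet:
    """Typed edge sets feeding network assembly."""

    circ_mir: frozenset[tuple[str, str]]
    mir_mrna: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for pair_set in (self.circ_mir, self.mir_mrna):
            for a, b in pair_set:
                if not a or not b:
                    raise ValueError("interaction with an empty identifier")
                if a == b:
                    raise ValueError(f"self-interaction {a!r}")


def normalize_nucleotides(seq: str, what: str = "sequence") -> str:
    """Uppercase, U->T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"invalid {what} alphabet characters {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def circularize(seq: str, overhang: int = 7) -> str:
    """Append the first ``overhang`` bases, emulating the closed circle."""
    if overhang >= len(seq):
        raise ValueError(f"overhang {overhang} must be < sequence length {len(seq)}")
    if overhang < 0:
        raise ValueError("overhang must be >= 0")
    return seq + seq[:overhang]


def scan_mre(
    circ_seq: str,
    mirna_seq: str,
    circ_id: str = "circ",
    mirna_id: str = "mirna",
    overhang: int = 7,
) -> list[MreSite]:
    """All canonical seed sites for one miRNA on one circular sequence.

    Every reported site carries exactly one type, the strongest applicable.
    Flanking positions (the m8 match and the A1 adduct) are evaluated with
    modular indexing on the circle, so classification does not depend on
    where the back-spliced junction falls. Sites are sorted by start.
    """
    s = normalize_nucleotides(circ_seq, "circRNA")
    mi = normalize_nucleotides(mirna_seq, "miRNA")
    if len(mi) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    L = len(s)
    eff_overhang = min(overhang, L - 1)
    ext = circularize(s, eff_overhang)

    seed_rc = reverse_complement(mi[1:7])  # miRNA positions 2-7
    m8_comp = _COMPLEMENT[mi[7]]  # base pairing miRNA position 8

    seen: set[int] = set()
    sites: list[MreSite] = []
    i = ext.find(seed_rc)
    while i != -1:
        j = i % L  # seed start on the circle
        if j not in seen:
            seen.add(j)
            has_m8 = s[(j - 1) % L] == m8_comp
            has_a1 = s[(j + 6) % L] == "A"
            if has_m8 and has_a1:
                site_type = "8mer"
            elif has_m8:
                site_type = "7mer-m8"
            elif has_a1:
                site_type = "7mer-A1"
            else:
                site_type = "6mer"
            start = (j - 1) % L if has_m8 else j
            spans = start + _SITE_LEN[site_type] > L
            sites.append(MreSite(circ_id, mirna_id, site_type, start, spans))
        i = ext.find(seed_rc, i + 1)
    sites.sort(key=lambda st: (st.start, st.site_type))
    return sites


def circ_mir_interactions(
    sites: Iterable[MreSite], min_site_type: str = "7mer-A1"
) -> set[tuple[str, str]]:
    """(circRNA, miRNA) pairs with at least one site of the given grade or better."""
    if min_site_type not in _SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}")
    floor = _SITE_RANK[min_site_type]
    return {
        (st.circ_id, st.mirna_id)
        for st in sites
        if _SITE_RANK[st.site_type] >= floor
    }


def mir_mrna_interactions(
    target_table: Iterable[tuple[str, str]], de_mrna: Iterable[str]
) -> set[tuple[str, str]]:
    """Filter an external (miRNA, gene) table to the DE mRNA set."""
    de = set(de_mrna)
    out = set()
    for row in target_table:
        try:
            mi, g = row
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed target-table row {row!r}") from exc
        if not mi or not g:
            raise ValueError(f"malformed target-table row {row!r}")
        if g in de:
            out.add((mi, g))
    return out


def expressed_mirnas(
    m: CountMatrix, min_count: int = 1, min_sample_fraction: float = 0.5
) -> set[str]:
    """miRNAs passing the expression rule (>= min_count in >= half the samples)."""
    kept = filter_by_junction_reads(m, min_reads=min_count, min_sample_fraction=min_sample_fraction)
    return set(kept.feature_ids)


def sites_to_rows(sites: Sequence[MreSite]) -> list[tuple[str, str, str, int, bool]]:
    return [(s.circ_id, s.mirna_id, s.site_type, s.start, s.spans_bsj) for s in sites]


def scan_all(
    circ_seqs: Mapping[str, str],
    mirna_seqs: Mapping[str, str],
    overhang: int = 7,
) -> list[MreSite]:
    """Scan every circRNA against every miRNA (convenience for the pipeline)."""
    sites: list[MreSite] = []
    for cid, cseq in circ_seqs.items():
        for mid, mseq in mirna_seqs.items():
            sites.extend(scan_mre(cseq, mseq, circ_id=cid, mirna_id=mid, overhang=overhang))
    return sites
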