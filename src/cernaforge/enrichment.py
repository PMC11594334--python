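"""Exact enrichment statistics: 2x2 Fisher test and hypergeometric ORA.

The sponge/disease cross-tabulation asks whether the miRNAs predicted to be
sponged by DE circRNAs are over-represented among disease-associated miRNAs,
relative to all miRNAs expressed in the cell line. The one-sided (greater)
Fisher exact p-value is the upper tail of the hypergeometric distribution
evaluated in log space, exact for all table sizes in scope.

Over-representation analysis (ORA) applies the same tail per annotation
term over a flat term -> gene mapping, with Benjamini-Hochberg adjustment
across terms. No GO-DAG propagation is performed; annotations are taken as
given.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .diff_expr import bh_adjust


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells in the column-major order of R's ``matrix(c(a, b, c, d), 2, 2)``:

    a = sponged & associated, b = sponged & not associated,
    c = not sponged & associated, d = not sponged & not associated.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if isinstance(v, bool) or v != int(v) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))  # accept numpy integers

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        """(associated, not associated) margins."""
        return (self.a + self.c, self.b + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        """(sponged, not sponged) margins."""
        return (self.a + self.b, self.c + self.d)


def fisher_exact_greater(t: ContingencyTable2x2) -> float:
    """P(X >= a) for X ~ Hypergeometric(N=total, K=a+c, n=a+b).

    This is the one-sided "greater" alternative of Fisher's exact test on
    the sponged x associated table; a = 0 degenerates to p = 1.
    """
    if t.total < 1:
        raise ValueError("grand total must be >= 1")
    N = t.total
    K = t.a + t.c  # associated
    n = t.a + t.b  # sponged
    return float(hypergeom.sf(t.a - 1, N, K, n))


def build_sponge_table(
    sponged: Iterable[str], associated: Iterable[str], universe: Iterable[str]
) -> ContingencyTable2x2:
    """Cross-tabulate sponged x disease-associated miRNAs over a universe."""
    sponged = set(sponged)
    associated = set(associated)
    universe = set(universe)
    if not sponged <= universe:
        raise ValueError(
            f"sponged set not a subset of the universe: {sorted(sponged - universe)[:5]}"
        )
    if not associated <= universe:
        raise ValueError(
            f"associated set not a subset of the universe: {sorted(associated - universe)[:5]}"
        )
    a = len(sponged & associated)
    b = len(sponged - associated)
    c = len(associated - sponged)
    d = len(universe - (sponged | associated))
    return ContingencyTable2x2(a, b, c, d)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    overlap_k: int
    term_size_K: int
    query_size_n: int
    universe_N: int
    p_value: float
    fdr: float


def hypergeom_ora(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """One-tailed hypergeometric over-representation over a flat annotation.

    ``universe`` defaults to the union of all annotated genes. Every
    annotated gene must lie in the universe and the query must be a subset
    of it. Terms with no annotated gene in the universe are dropped; BH is
    computed across the tested terms; results are sorted by (p, term).
    """
    ann = {t: set(gs) for t, gs in annotation.items()}
    if universe is None:
        universe = set().union(*ann.values()) if ann else set()
    else:
        universe = set(universe)
        stray = {g for gs in ann.values() for g in gs} - universe
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError(f"query genes outside the universe: {sorted(query - universe)[:5]}")

    N, n = len(universe), len(query)
    rows = []
    for term in sorted(ann):
        genes = ann[term] & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    fdrs = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term, k, K, n, N, p, float(q))
        for (term, k, K, p), q in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


# -- annotation I/O --------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: term<TAB>description<TAB>gene1<TAB>gene2..."""
    ann: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise ValueError(f"{path}:{ln}: GMT row needs term, description, >=1 gene")
        ann[cols[0]] = {g for g in cols[2:] if g}
    return ann


def read_term_table(path: str | Path) -> dict[str, set[str]]:
    """Two-column (term_id, gene_id) TSV; a header row is skipped if present."""
    ann: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if ln == 1 and cols[0].lower() in {"term_id", "term"}:
            continue
        if len(cols) != 2:
            raise ValueError(f"{path}:{ln}: expected two columns")
        ann.setdefault(cols[0], set()).add(cols[1])
    return ann


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.overlap_k, r.term_size_K, r.query_size_n, r.universe_N, r.p_value, r.fdr)
            for r in results
        ],
        columns=["term_id", "overlap_k", "term_size_K", "query_size_n", "universe_N", "p_value", "fdr"],
    )
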