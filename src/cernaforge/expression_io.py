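"""Readers, writers, and filters for expression-level inputs.

Everything downstream of read alignment enters the pipeline through this
module: back-spliced-junction (BSJ) count matrices for circRNAs, gene-level
mRNA count matrices, mature-miRNA count matrices, FASTA sequence files,
two-column miRNA->gene target tables, and one-ID-per-line annotation lists.

A circRNA is identified by its back-spliced junction, written
``chrom:start|end`` with 1-based inclusive coordinates (the CIRI/CIRIquant
convention). Strand is not part of the identity; if a count table carries a
``strand`` column it is preserved as feature metadata and otherwise ignored.

The junction-read confidence filter implemented here keeps a circRNA only if
it has at least ``min_reads`` junction reads in at least half of the samples
(rounding up), which removes the long tail of single-read BSJ artefacts that
back-splice detectors emit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TREATED = "treated"
CONTROL = "control"
GROUP_LABELS = frozenset({TREATED, CONTROL})


class CircIdError(ValueError):
    """Raised when a back-spliced-junction identifier cannot be parsed."""


# coordinates must be canonical integers (no leading zeros) so that
# parse -> format is byte-for-byte
_CIRC_ID_RE = re.compile(
    r"^(?P<chrom>[^:|\s]+):(?P<start>0|[1-9][0-9]*)\|(?P<end>0|[1-9][0-9]*)$"
)


@dataclass(frozen=True, order=True)
class CircId:
    """A back-spliced junction: chromosome plus 1-based inclusive start/end."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise CircIdError("empty chromosome name")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise CircIdError("coordinates must be integers")
        if self.start > self.end:
            raise CircIdError(
                f"start > end in '{self.chromosome}:{self.start}|{self.end}'"
            )

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}|{self.end}"


def parse_circ_id(text: str) -> CircId:
    """Parse ``chrom:start|end`` into a :class:`CircId`.

    Formatting the result reproduces the input exactly; malformed input
    raises :class:`CircIdError` naming the offending token.
    """
    m = _CIRC_ID_RE.match(text)
    if m is None:
        # produce a targeted message for the common failure modes
        if ":" not in text:
            raise CircIdError(f"missing ':' separator in {text!r}")
        chrom, _, rest = text.partition(":")
        if not chrom:
            raise CircIdError(f"empty chromosome in {text!r}")
        if "|" not in rest:
            raise CircIdError(f"missing '|' separator in {text!r}")
        start_s, _, end_s = rest.partition("|")
        for token, name in ((start_s, "start"), (end_s, "end")):
            if not re.fullmatch(r"0|[1-9][0-9]*", token):
                raise CircIdError(f"non-integer {name} coordinate {token!r} in {text!r}")
        raise CircIdError(f"malformed circRNA identifier {text!r}")
    return CircId(m.group("chrom"), int(m.group("start")), int(m.group("end")))


@dataclass(frozen=True)
class AnnotationList:
    """A labelled set of feature identifiers (e.g. disease-associated miRNAs)."""

    ids: frozenset[str]
    label: str = "annotation"

    def __post_init__(self) -> None:
        if any(not i for i in self.ids):
            raise ValueError("annotation list contains an empty identifier")

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self.ids


@dataclass
class CountMatrix:
    """Non-negative integer feature x sample table with treatment labels.

    ``counts`` rows are features, columns are samples; ``groups`` maps each
    sample to ``"treated"`` or ``"control"``. ``feature_meta`` carries
    pass-through per-feature columns (e.g. a strand column) untouched.
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts are not allowed")
        if set(self.groups) != set(self.counts.columns):
            raise ValueError("groups must label exactly the samples in the matrix")
        bad = {g for g in self.groups.values()} - GROUP_LABELS
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; use treated/control")
        self.counts = self.counts.astype("int64")

    # -- views -------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == label]

    def subset_features(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        meta = self.feature_meta.loc[keep] if self.feature_meta is not None else None
        return CountMatrix(self.counts.loc[keep].copy(), dict(self.groups), meta)


def read_count_matrix(path: str | Path, group_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count table (features in rows, header row of sample IDs).

    ``group_map`` assigns every sample column to treated/control; a sample in
    ``group_map`` missing from the header is an error. Gzip input is handled
    by file extension. A ``strand`` column, if present, is carried through as
    feature metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.name is None and df.shape[1] == 0:
        raise ValueError(f"{path}: not a TSV count table")
    df.index = df.index.astype(str)

    meta = None
    if "strand" in df.columns:
        meta = df[["strand"]].copy()
        df = df.drop(columns=["strand"])

    missing = [s for s in group_map if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: samples in group map absent from header: {missing}")
    df = df[list(group_map)]

    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count entry ({exc})") from exc
    if numeric.isna().values.any():
        raise ValueError(f"{path}: missing values in count table")
    if (numeric.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    if not (numeric.values == numeric.values.astype("int64")).all():
        raise ValueError(f"{path}: non-integer counts")
    return CountMatrix(numeric.astype("int64"), dict(group_map), meta)


def write_count_matrix(m: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = m.counts.copy()
    out.index.name = "feature_id"
    if m.feature_meta is not None:
        out = m.feature_meta.join(out)  # strand column re-emitted first
        out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    return path


def filter_by_junction_reads(
    m: CountMatrix, min_reads: int = 2, min_sample_fraction: float = 0.5
) -> CountMatrix:
    """Keep features with >= ``min_reads`` counts in at least
    ``ceil(min_sample_fraction * n_samples)`` samples.

    With the defaults and six samples this is the "minimum of two junction
    reads in at least half of the samples" confidence rule. Treated and
    control samples are pooled for the sample-count rule. Sample set and
    feature order are preserved; the filter is idempotent.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if not (0 < min_sample_fraction <= 1):
        raise ValueError("min_sample_fraction must be in (0, 1]")
    if m.counts.shape[0] == 0:
        raise ValueError("cannot filter an empty count matrix")
    needed = math.ceil(min_sample_fraction * m.n_samples)
    ok = (m.counts.values >= min_reads).sum(axis=1) >= needed
    return m.subset_features([f for f, k in zip(m.feature_ids, ok) if k])


# -- sequences and simple tables ------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` dict (uppercased)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence ID {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path),
        "fasta",
    )
    return path


def read_annotation_list(path: str | Path, label: str = "annotation") -> AnnotationList:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return AnnotationList(frozenset(ids), label=label)


def write_annotation_list(ann: AnnotationList, path: str | Path) -> Path:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ann.ids)))
    return Path(path)


def read_target_table(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column (miRNA, gene) TSV into a set of pairs.

    A single header line starting with ``mirna``/``miRNA`` or ``#`` is
    skipped; rows with a column count other than two are an error.
    """
    pairs: set[tuple[str, str]] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if ln == 1 and (cols[0].lower().startswith("mirna") or cols[0].startswith("#")):
            continue
        if len(cols) != 2 or not cols[0] or not cols[1]:
            raise ValueError(f"{path}:{ln}: malformed target-table row {line!r}")
        pairs.add((cols[0], cols[1]))
    return pairs


def write_target_table(pairs: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for mi, g in sorted(pairs):
            fh.write(f"{mi}\t{g}\n")
    return path
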