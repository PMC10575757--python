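"""Annotated VHH repertoires: container types, table/FASTA I/O and CDR extraction.

A repertoire is a collection of unique CDR1/CDR2/CDR3 triplets, each carrying
per-FACS-round read counts.  Because the display library uses a fixed
(humanized) framework, all sequence variation lives in the CDRs and the
triplet is the identity key: rows with identical triplets are merged on read
by summing their counts.

CDR extraction from full-length VHH sequences is done by exact framework
anchor matching (FR1..FR4 must each occur exactly once and in order); this
replaces numbering-scheme annotation, which a fixed-framework library does
not need.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

SOURCE_NGS = "ngs"
SOURCE_SAMPLED = "sampled"


class RepertoireError(ValueError):
    """Raised for malformed repertoire inputs."""


def validate_cdr(seq: str, label: str = "sequence") -> str:
    """Check that ``seq`` uses only the 20 canonical upper-case residues."""
    for ch in seq:
        if ch not in _AA_SET:
            raise RepertoireError(
                f"{label} {seq!r} contains non-amino-acid character {ch!r}"
            )
    return seq


@dataclass
class AnnotatedVHH:
    """One unique CDR triplet with per-round read counts.

    counts maps round index (0 = pre-sort baseline) to a read count.
    source distinguishes NGS-observed sequences from model-sampled ones.
    """

    seq_id: str
    cdr1: str
    cdr2: str
    cdr3: str
    counts: dict[int, int] = field(default_factory=dict)
    source: str = SOURCE_NGS

    def __post_init__(self) -> None:
        for region, label in ((self.cdr1, "cdr1"), (self.cdr2, "cdr2"), (self.cdr3, "cdr3")):
            validate_cdr(region, f"{label} of {self.seq_id}")
        if not (self.cdr1 or self.cdr2 or self.cdr3):
            raise RepertoireError(f"{self.seq_id}: all three CDRs empty")
        for r, c in self.counts.items():
            if r < 0 or c < 0:
                raise RepertoireError(f"{self.seq_id}: negative round index or count")
        if self.source not in (SOURCE_NGS, SOURCE_SAMPLED):
            raise RepertoireError(f"{self.seq_id}: unknown source {self.source!r}")

    @property
    def triplet(self) -> tuple[str, str, str]:
        return (self.cdr1, self.cdr2, self.cdr3)

    @property
    def concatenated(self) -> str:
        return self.cdr1 + self.cdr2 + self.cdr3

    def count(self, round_index: int) -> int:
        return self.counts.get(round_index, 0)

    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class RepertoireRound:
    """Per-round summary: total reads over all member sequences."""

    round_index: int
    total_reads: int


@dataclass(frozen=True)
class FrameworkAnchors:
    """The four fixed framework segments flanking CDR1-3."""

    fr1: str
    fr2: str
    fr3: str
    fr4: str

    def __post_init__(self) -> None:
        for name in ("fr1", "fr2", "fr3", "fr4"):
            seg = getattr(self, name)
            if not seg:
                raise RepertoireError(f"anchor {name} is empty")
            validate_cdr(seg, f"anchor {name}")


DEFAULT_SCHEMA: dict[str, str] = {
    "seq_id": "seq_id",
    "cdr1": "cdr1",
    "cdr2": "cdr2",
    "cdr3": "cdr3",
}
#: count columns are discovered by this prefix, e.g. count_r0, count_r1, ...
COUNT_PREFIX = "count_r"


def round_summaries(sequences: Iterable[AnnotatedVHH]) -> list[RepertoireRound]:
    totals: dict[int, int] = {}
    for s in sequences:
        for r, c in s.counts.items():
            totals[r] = totals.get(r, 0) + c
    return [RepertoireRound(r, totals[r]) for r in sorted(totals)]


def _dialect_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_repertoire(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[AnnotatedVHH], list[RepertoireRound]]:
    """Read a CSV/TSV repertoire table.

    Duplicate CDR triplets are merged by summing counts; the first seq_id and
    source seen for a triplet are kept.  Returns the merged sequences plus
    per-round totals.
    """
    path = Path(path)
    if not path.exists():
        raise RepertoireError(f"no such file: {path}")
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    merged: dict[tuple[str, str, str], AnnotatedVHH] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_dialect_delimiter(path))
        if reader.fieldnames is None:
            raise RepertoireError(f"{path}: empty file (header row required)")
        for col in ("cdr1", "cdr2", "cdr3"):
            if colmap[col] not in reader.fieldnames:
                raise RepertoireError(f"{path}: missing column {colmap[col]!r}")
        count_cols = sorted(
            (c for c in reader.fieldnames if c.startswith(COUNT_PREFIX)),
            key=lambda c: int(c[len(COUNT_PREFIX):]),
        )
        for lineno, row in enumerate(reader, start=2):
            try:
                counts = {
                    int(c[len(COUNT_PREFIX):]): int(row[c] or 0) for c in count_cols
                }
                seq = AnnotatedVHH(
                    seq_id=row.get(colmap["seq_id"], "") or f"row{lineno}",
                    cdr1=(row[colmap["cdr1"]] or "").strip(),
                    cdr2=(row[colmap["cdr2"]] or "").strip(),
                    cdr3=(row[colmap["cdr3"]] or "").strip(),
                    counts=counts,
                    source=row.get("source", SOURCE_NGS) or SOURCE_NGS,
                )
            except RepertoireError:
                raise
            except (KeyError, TypeError, ValueError) as exc:
                raise RepertoireError(f"{path}: malformed row {lineno}: {exc}") from exc
            key = seq.triplet
            if key in merged:
                tgt = merged[key].counts
                for r, c in seq.counts.items():
                    tgt[r] = tgt.get(r, 0) + c
            else:
                merged[key] = seq
    sequences = list(merged.values())
    return sequences, round_summaries(sequences)


def write_repertoire(
    path: str | Path,
    sequences: Sequence[AnnotatedVHH],
) -> None:
    """Write sequences back in the same table format (inverse of read)."""
    path = Path(path)
    rounds = sorted({r for s in sequences for r in s.counts})
    header = ["seq_id", "cdr1", "cdr2", "cdr3"] + [
        f"{COUNT_PREFIX}{r}" for r in rounds
    ] + ["source"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_dialect_delimiter(path))
        writer.writerow(header)
        for s in sequences:
            writer.writerow(
                [s.seq_id, s.cdr1, s.cdr2, s.cdr3]
                + [s.count(r) for r in rounds]
                + [s.source]
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def extract_cdrs(full_sequence: str, anchors: FrameworkAnchors) -> tuple[str, str, str]:
    """Extract (cdr1, cdr2, cdr3) between exact framework anchor matches.

    Each anchor must occur exactly once and in order; a repeated anchor is
    treated as corrupt input rather than resolved by first-match.
    """
    validate_cdr(full_sequence, "full sequence")
    positions: list[tuple[int, int]] = []
    cursor_check = -1
    for name in ("fr1", "fr2", "fr3", "fr4"):
        seg = getattr(anchors, name)
        first = full_sequence.find(seg)
        if first < 0:
            raise RepertoireError(f"{name} not found")
        if full_sequence.find(seg, first + 1) >= 0:
            raise RepertoireError(f"ambiguous anchor {name}")
        if first <= cursor_check:
            raise RepertoireError(f"anchor {name} out of order")
        cursor_check = first
        positions.append((first, first + len(seg)))
    (s1, e1), (s2, e2), (s3, e3), (s4, _) = positions
    if not (e1 <= s2 and e2 <= s3 and e3 <= s4):
        raise RepertoireError("anchors overlap or are out of order")
    return (
        full_sequence[e1:s2],
        full_sequence[e2:s3],
        full_sequence[e3:s4],
    )
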