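"""Readers and writers for the formats the pipeline touches.

Internally every coordinate is 0-based half-open on the forward strand of the
containing sequence; all files emitted here use 1-based inclusive coordinates.
Supported inputs: FASTA (via Biopython), gene annotations as a minimal GFF3
CDS subset or a 5-column TSV, and 3-column conserved-domain hit tables
(``orf_id  domain_id  e_value``, an ``-outfmt 6``-style reduction).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .dna import sanitize


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError("SeqRecord sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval on a genome or fragment.

    ``start``/``end`` are 0-based half-open on the forward strand; ``strand``
    is '+' or '-'.  ``is_truth_tis`` marks starts trusted for TIS training.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    is_truth_tis: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid annotation interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class DomainHit:
    orf_id: str
    domain_id: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"negative e-value {self.e_value}")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, in file order.

    Lower-case letters are upper-cased and characters outside {A,C,G,T,N}
    become N.  A file with no FASTA records raises :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        records = [
            SeqRecord(id=rec.id, sequence=sanitize(str(rec.seq)))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_gff3_line(line: str) -> GeneAnnotation | None:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 8:
        raise FormatError(f"malformed GFF3 line: {line!r}")
    if cols[2] != "CDS":
        return None
    start_1b, end_1b = int(cols[3]), int(cols[4])
    return GeneAnnotation(
        seq_id=cols[0], start=start_1b - 1, end=end_1b, strand=cols[6]
    )


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (CDS features) or a 5-column TSV.

    The dialect is auto-detected: a ``##gff-version`` header or 9-column rows
    select GFF3 (1-based inclusive, converted on input); otherwise rows are
    ``seq_id  start  end  strand  is_truth_tis`` already in the internal
    0-based half-open convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = path.read_text().lstrip()
    is_gff = header.startswith("##gff-version") or (
        lines and len(lines[0].split("\t")) >= 8
    )
    out: list[GeneAnnotation] = []
    for ln in lines:
        if is_gff:
            ann = _parse_gff3_line(ln)
            if ann is not None:
                out.append(ann)
        else:
            cols = ln.split()
            if len(cols) < 4:
                raise FormatError(f"malformed annotation row: {ln!r}")
            # tolerate a textual header row on the TSV dialect
            if cols[1].lstrip("-").isdigit() is False:
                continue
            flag = bool(int(cols[4])) if len(cols) > 4 else True
            out.append(
                GeneAnnotation(
                    seq_id=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[3],
                    is_truth_tis=flag,
                )
            )
    return out


def write_annotations_tsv(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write annotations in the 5-column TSV dialect (internal 0-based
    half-open coordinates, as :func:`read_annotations` expects back)."""
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.seq_id}\t{a.start}\t{a.end}\t{a.strand}\t{int(a.is_truth_tis)}\n"
            )


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a 3-column tab-separated conserved-domain hit table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[DomainHit] = []
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) < 3:
            raise FormatError(f"malformed domain-hit row: {ln!r}")
        try:
            e_value = float(cols[2])
        except ValueError as exc:
            raise FormatError(f"non-numeric e-value in row {ln!r}") from exc
        hits.append(DomainHit(orf_id=cols[0], domain_id=cols[1], e_value=e_value))
    return hits


PREDICTION_COLUMNS = (
    "fragment_id",
    "start",
    "end",
    "strand",
    "frame",
    "complete5",
    "complete3",
    "p_universal",
    "p_novel",
    "predicted_tis",
)


def write_predictions(predictions: Sequence, path: str | Path) -> None:
    """Write prediction records as a deterministic, sorted TSV.

    Coordinates are emitted 1-based inclusive on the fragment's forward
    strand, sorted by (fragment id, start).  ``predicted_tis`` is the 1-based
    forward position of the first base of the relocated start codon, or
    ``edge`` when the true start was judged to lie off the fragment, or ``.``
    when no relocation was possible.
    """
    rows = []
    for p in predictions:
        a, b = p.forward_interval()
        tis = p.tis_forward()
        rows.append(
            (
                p.fragment_id,
                a + 1,
                b,
                p.strand,
                p.frame,
                int(p.complete5),
                int(p.complete3),
                f"{p.p_universal:.4f}",
                (f"{p.p_novel:.4f}" if p.p_novel is not None else "."),
                ("edge" if tis == "edge" else "." if tis is None else str(tis + 1)),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    buf = _io.StringIO()
    buf.write("\t".join(PREDICTION_COLUMNS) + "\n")
    for row in rows:
        buf.write("\t".join(str(x) for x in row) + "\n")
    Path(path).write_text(buf.getvalue())
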