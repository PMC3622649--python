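"""Six-frame ORF enumeration on metagenomic fragments.

An ORF here is a maximal stop-free in-frame codon run bounded by in-frame
stop codons or by the fragment edges.  Because fragments are short, many runs
leave one or both edges: a run touching the left (5') oriented edge is
5'-incomplete — its true start may lie off the fragment even when internal
start codons exist — and a run touching the right edge is 3'-incomplete.
Coordinates of an :class:`OrfCandidate` are 0-based half-open on the oriented
sequence (the fragment itself for '+', its reverse complement for '-').
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dna import START_CODONS, STOP_CODONS, revcomp
from .io import SeqRecord

DEFAULT_MIN_ORF_LEN = 60


@dataclass(frozen=True)
class TisCandidate:
    """A candidate start codon within an ORF.

    ``position`` is the 0-based offset of the codon's first base on the
    oriented sequence; ``upstream_available`` is how many bases lie 5' of it
    within the fragment (equal to ``position``).
    """

    position: int
    codon: str
    upstream_available: int


@dataclass(frozen=True)
class OrfCandidate:
    fragment_id: str
    strand: str  # '+' or '-'
    frame: int  # codon-grid offset 0..2 on the oriented sequence
    start: int  # 0-based half-open extent on the oriented sequence
    end: int
    complete5: bool  # extent begins at a start codon, run does not leave the 5' edge
    complete3: bool  # extent ends with an in-frame stop codon
    tis_candidates: tuple[TisCandidate, ...] = field(default=())

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def orf_id(self) -> str:
        return f"{self.fragment_id}|{self.strand}{self.frame}:{self.start}-{self.end}"

    def forward_interval(self, fragment_length: int) -> tuple[int, int]:
        """Extent mapped onto the fragment's forward strand (0-based half-open)."""
        if self.strand == "+":
            return self.start, self.end
        return fragment_length - self.end, fragment_length - self.start


def oriented_sequence(fragment: SeqRecord, strand: str) -> str:
    return fragment.sequence if strand == "+" else revcomp(fragment.sequence)


def _runs_in_frame(seq: str, frame: int) -> list[tuple[int, int, bool, bool]]:
    """Maximal stop-free codon runs for one frame of an oriented sequence.

    Returns ``(codon_start_index, codon_end_index_exclusive, left_edge,
    has_stop)`` tuples over the codon grid ``frame, frame+3, ...``; the stop
    codon itself is excluded from the index range.
    """
    n_codons = (len(seq) - frame) // 3
    runs = []
    run_start = 0
    left_edge = True
    for c in range(n_codons):
        codon = seq[frame + 3 * c : frame + 3 * c + 3]
        if codon in STOP_CODONS:
            runs.append((run_start, c, left_edge, True))
            run_start = c + 1
            left_edge = False
    if run_start < n_codons:
        runs.append((run_start, n_codons, left_edge, False))
    return runs


def extract_orfs(
    fragment: SeqRecord, min_len: int = DEFAULT_MIN_ORF_LEN
) -> list[OrfCandidate]:
    """Enumerate complete and incomplete candidate ORFs in all six frames.

    For each of the 3 frames per strand, every maximal stop-free codon run
    yields at most one candidate:

    * run bounded on the left by an in-frame stop: requires an in-frame start
      codon; the extent begins at the 5'-most start and the ORF is
      5'-complete;
    * run touching the left oriented edge: 5'-incomplete; the extent begins
      on the edge codon grid and any internal starts are kept as TIS
      candidates (the true start may be off-fragment — decided later by the
      TIS relocation step);
    * run touching the right edge: 3'-incomplete, extent ends at the last
      full codon; otherwise the terminating stop codon is included.

    Runs whose extent is shorter than ``min_len`` bases are discarded.
    Fragments shorter than ``min_len`` yield an empty list.
    """
    out: list[OrfCandidate] = []
    if len(fragment) < min_len:
        return out
    for strand in "+-":
        seq = oriented_sequence(fragment, strand)
        for frame in range(3):
            for c_start, c_end, left_edge, has_stop in _runs_in_frame(seq, frame):
                starts = [
                    frame + 3 * c
                    for c in range(c_start, c_end)
                    if seq[frame + 3 * c : frame + 3 * c + 3] in START_CODONS
                ]
                if left_edge:
                    complete5 = False
                    orf_start = frame
                else:
                    if not starts:
                        continue
                    complete5 = True
                    orf_start = starts[0]
                orf_end = frame + 3 * (c_end + (1 if has_stop else 0))
                if orf_end - orf_start < min_len:
                    continue
                cands = tuple(
                    TisCandidate(
                        position=p,
                        codon=seq[p : p + 3],
                        upstream_available=p,
                    )
                    for p in starts
                    if p >= orf_start
                )
                out.append(
                    OrfCandidate(
                        fragment_id=fragment.id,
                        strand=strand,
                        frame=frame,
                        start=orf_start,
                        end=orf_end,
                        complete5=complete5,
                        complete3=has_stop,
                        tis_candidates=cands,
                    )
                )
    return out


def enumerate_tis_candidates(
    orf: OrfCandidate, fragment: SeqRecord
) -> list[TisCandidate]:
    """All in-frame {ATG,GTG,TTG} codons of an ORF, ordered 5'→3'.

    Candidates run from the ORF's 5' boundary up to (but excluding) the stop
    codon when the ORF is 3'-complete.
    """
    seq = oriented_sequence(fragment, orf.strand)
    limit = orf.end - 3 if orf.complete3 else orf.end
    cands = []
    for p in range(orf.start, limit, 3):
        codon = seq[p : p + 3]
        if codon in START_CODONS:
            cands.append(
                TisCandidate(position=p, codon=codon, upstream_available=p)
            )
    return cands
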