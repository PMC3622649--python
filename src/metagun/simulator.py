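"""Synthetic annotated genomes, shotgun fragment sampling, and evaluation.

The generator emulates the statistical features the predictor exploits in
real prokaryotic genomes: protein-coding genes with a genome-specific biased
codon usage (drawn from a Dirichlet over the 61 sense codons), gene lengths
from a gamma distribution with mean ~950 bp, Shine-Dalgarno-like AGGAGG
motifs planted at -12..-7 of a configurable fraction of starts, and i.i.d.
intergenic background at a target GC.  Fragments are sampled uniformly on
both strands until a target coverage is reached, error-free, with either a
fixed length or lengths uniform on a range; each fragment carries a truth
map of its projected genes.

Evaluation follows the standard fragment benchmark: a prediction is a true
positive when its 3' end exactly matches an annotated gene's 3' end, or,
when the truth 3' end runs off the fragment, when it matches the gene's
strand and reading frame.  Sn and Sp are the true-positive fractions of
annotated and of predicted genes, combined by the harmonic mean
Hm = 2*Sn*Sp/(Sn+Sp).  TIS accuracy is assessed on true-positive genes only,
split into internal starts (inside the fragment; correct iff predicted
exactly) and external starts (off the fragment; correct iff the prediction
reports the edge sentinel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .dna import SENSE_CODONS, START_CODONS, STOP_CODONS, revcomp
from .io import GeneAnnotation, SeqRecord
from .tis_model import EDGE

MEAN_GENE_LENGTH = 950.0  # bp, matching typical complete-genome averages
MIN_TRUTH_OVERLAP = 60  # bp of coding overlap below which a truth gene is dropped


@dataclass
class GenomeConfig:
    length: int = 100_000
    gene_density: float = 0.9
    codon_dirichlet_alpha: float = 0.2
    codon_usage: np.ndarray | None = None  # explicit 61-dim usage overrides alpha
    sd_motif: str = "AGGAGG"
    sd_fraction: float = 0.8
    gc: float = 0.5
    genome_id: str = "synth"
    genus: str = "Synthgenus"
    domain: str = "Bacteria"
    min_gene_length: int = 90
    min_intergenic: int = 20
    gamma_shape: float = 2.5  # gene-length gamma; scale set to hit the mean


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    genus: str
    domain: str
    annotations: list[GeneAnnotation]
    config: GenomeConfig | None = None
    codon_usage: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def as_seqrecord(self) -> SeqRecord:
        return SeqRecord(id=self.id, sequence=self.sequence)


@dataclass(frozen=True)
class TruthGene:
    """A genome gene projected onto one fragment.

    ``start``/``end`` are the clipped interval on the fragment's forward
    strand (0-based half-open); ``strand`` is the gene's strand on the
    fragment.  ``frame_key`` identifies the reading frame from the unclipped
    projection, ``three_prime`` is the forward index of the last base of the
    gene (stop included) when the 3' end is inside the fragment, and
    ``tis_forward`` the forward index of the first base of the start codon
    when the start is internal.
    """

    fragment_id: str
    fragment_length: int
    strand: str
    frame_key: int
    start: int
    end: int
    complete5: bool
    complete3: bool
    three_prime: int | None
    tis_forward: int | None

    @property
    def tis_internal(self) -> bool:
        return self.complete5


@dataclass
class EvalResult:
    sn: float
    sp: float
    hm: float
    tp: int
    fp: int
    fn: int


@dataclass
class TisEvalResult:
    total: float | None
    internal: float | None
    external: float | None
    n_internal: int
    n_external: int
    correct_internal: int
    correct_external: int


def harmonic_mean(sn: float, sp: float) -> float:
    """Hm = 2*Sn*Sp/(Sn+Sp), zero when both are zero."""
    if sn + sp == 0:
        return 0.0
    return 2.0 * sn * sp / (sn + sp)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _gene_sequence(rng: np.random.Generator, length: int, usage: np.ndarray) -> str:
    """A gene of ``length`` bp (divisible by 3): start codon, sense-codon
    interior drawn from ``usage``, stop codon.  Stop-free in frame by
    construction."""
    n_interior = length // 3 - 2
    start = rng.choice(list(START_CODONS), p=[0.8, 0.15, 0.05])
    interior = rng.choice(len(SENSE_CODONS), size=n_interior, p=usage)
    stop = rng.choice(list(STOP_CODONS), p=[0.6, 0.15, 0.25])
    return start + "".join(SENSE_CODONS[i] for i in interior) + stop


def generate_genome(config: GenomeConfig | None = None, seed: int = 0, **kwargs) -> GenomeRecord:
    """Generate a synthetic annotated genome.

    Genes are placed non-overlapping on both strands, left to right with
    intergenic gaps, until the target density of coding bases is met.  Raises
    ``ValueError`` when the requested density is infeasible given the minimum
    intergenic spacing.
    """
    if config is None:
        config = GenomeConfig(**kwargs)
    elif kwargs:
        config = replace(config, **kwargs)
    if config.length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if not (0 < config.gene_density < 1):
        raise ValueError("gene density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    usage = (
        np.asarray(config.codon_usage, dtype=float)
        if config.codon_usage is not None
        else rng.dirichlet(np.full(len(SENSE_CODONS), config.codon_dirichlet_alpha))
    )
    usage = usage / usage.sum()

    target_coding = config.gene_density * config.length
    scale = (MEAN_GENE_LENGTH - config.min_gene_length) / config.gamma_shape
    lengths: list[int] = []
    total = 0
    while total < target_coding:
        raw = config.min_gene_length + rng.gamma(config.gamma_shape, scale)
        glen = max(config.min_gene_length, 3 * int(round(raw / 3)))
        lengths.append(glen)
        total += glen
    n_genes = len(lengths)
    noncoding = config.length - total
    min_gap_total = (n_genes + 1) * config.min_intergenic
    if noncoding < min_gap_total:
        raise ValueError(
            f"infeasible density {config.gene_density}: {noncoding} noncoding bp "
            f"cannot host {n_genes + 1} gaps of >= {config.min_intergenic} bp"
        )
    gap_extra = rng.multinomial(noncoding - min_gap_total, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    gaps = gap_extra + config.min_intergenic

    seq = _random_bases(rng, config.length, config.gc)
    annotations: list[GeneAnnotation] = []
    cursor = 0
    motif = np.array(list(config.sd_motif))
    for glen, gap in zip(lengths, gaps[:-1]):
        cursor += int(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _gene_sequence(rng, glen, usage)
        if strand == "+":
            seq[cursor : cursor + glen] = list(gene)
            if rng.random() < config.sd_fraction:
                seq[cursor - 12 : cursor - 6] = motif
        else:
            seq[cursor : cursor + glen] = list(revcomp(gene))
            if rng.random() < config.sd_fraction:
                seq[cursor + glen + 6 : cursor + glen + 12] = np.array(
                    list(revcomp(config.sd_motif))
                )
        annotations.append(
            GeneAnnotation(
                seq_id=config.genome_id,
                start=cursor,
                end=cursor + glen,
                strand=strand,
                is_truth_tis=True,
            )
        )
        cursor += glen
    return GenomeRecord(
        id=config.genome_id,
        sequence="".join(seq),
        genus=config.genus,
        domain=config.domain,
        annotations=annotations,
        config=config,
        codon_usage=usage,
    )


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------


def _project_gene(
    ann: GeneAnnotation,
    frag_id: str,
    frag_start: int,
    frag_len: int,
    orientation: str,
) -> TruthGene | None:
    """Project one genome gene onto a sampled fragment, or None when the
    coding overlap is below ``MIN_TRUTH_OVERLAP``."""
    a_raw = ann.start - frag_start
    b_raw = ann.end - frag_start
    a, b = max(a_raw, 0), min(b_raw, frag_len)
    if b - a < MIN_TRUTH_OVERLAP:
        return None
    strand = ann.strand
    if orientation == "-":
        a_raw, b_raw = frag_len - b_raw, frag_len - a_raw
        a, b = frag_len - b, frag_len - a
        strand = "+" if strand == "-" else "-"
    clipped5 = (a_raw < 0) if strand == "+" else (b_raw > frag_len)
    clipped3 = (b_raw > frag_len) if strand == "+" else (a_raw < 0)
    frame_key = a_raw % 3 if strand == "+" else b_raw % 3
    three_prime = None if clipped3 else (b - 1 if strand == "+" else a)
    tis_forward = None if clipped5 else (a if strand == "+" else b - 1)
    return TruthGene(
        fragment_id=frag_id,
        fragment_length=frag_len,
        strand=strand,
        frame_key=frame_key,
        start=a,
        end=b,
        complete5=not clipped5,
        complete3=not clipped3,
        three_prime=three_prime,
        tis_forward=tis_forward,
    )


def sample_fragments(
    genome: GenomeRecord,
    coverage: float = 3.0,
    length_spec: int | tuple[int, int] = (60, 1500),
    seed: int = 0,
) -> tuple[list[SeqRecord], dict[str, list[TruthGene]]]:
    """Random error-free shotgun fragments plus their truth maps.

    ``length_spec`` is either a fixed length or an inclusive (min, max) range
    sampled uniformly.  Fragment start positions are uniform, strands random;
    sampling stops once the summed fragment length reaches
    ``coverage * len(genome)``.
    """
    rng = np.random.default_rng(seed)
    glen = len(genome.sequence)
    max_len = length_spec if isinstance(length_spec, int) else length_spec[1]
    if glen <= max_len:
        raise ValueError("genome must be longer than the maximum fragment length")
    fragments: list[SeqRecord] = []
    truth: dict[str, list[TruthGene]] = {}
    total = 0
    i = 0
    target = coverage * glen
    while total < target:
        flen = (
            length_spec
            if isinstance(length_spec, int)
            else int(rng.integers(length_spec[0], length_spec[1] + 1))
        )
        start = int(rng.integers(0, glen - flen + 1))
        orientation = "+" if rng.random() < 0.5 else "-"
        sub = genome.sequence[start : start + flen]
        if orientation == "-":
            sub = revcomp(sub)
        frag_id = f"{genome.id}_frag{i}"
        fragments.append(SeqRecord(id=frag_id, sequence=sub))
        genes = []
        for ann in genome.annotations:
            if ann.end <= start or ann.start >= start + flen:
                continue
            tg = _project_gene(ann, frag_id, start, flen, orientation)
            if tg is not None:
                genes.append(tg)
        truth[frag_id] = genes
        total += flen
        i += 1
    return fragments, truth


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _prediction_match(pred, gene: TruthGene) -> bool:
    if pred.strand != gene.strand:
        return False
    a, b = pred.forward_interval()
    if gene.complete3:
        if not pred.complete3:
            return False
        pred_3p = b - 1 if pred.strand == "+" else a
        return pred_3p == gene.three_prime
    if pred.complete3:
        return False
    pred_frame = a % 3 if pred.strand == "+" else b % 3
    return pred_frame == gene.frame_key and min(b, gene.end) > max(a, gene.start)


def evaluate_gene_predictions(
    predictions: Sequence, truth: dict[str, list[TruthGene]]
) -> EvalResult:
    """Sensitivity/specificity/harmonic mean of gene calls against truth.

    A truth gene matched by at least one prediction counts one TP;
    Sn = 100*TP/|truth genes| and Sp = 100*TP/|predictions|.
    """
    by_frag: dict[str, list] = {}
    for p in predictions:
        by_frag.setdefault(p.fragment_id, []).append(p)
    n_truth = sum(len(v) for v in truth.values())
    if n_truth == 0:
        raise ValueError("empty truth set: sensitivity undefined")
    tp = 0
    matched_preds: set[int] = set()
    for frag_id, genes in truth.items():
        preds = by_frag.get(frag_id, [])
        for gene in genes:
            hit = False
            for p in preds:
                if _prediction_match(p, gene):
                    hit = True
                    matched_preds.add(id(p))
            if hit:
                tp += 1
    n_pred = len(predictions)
    sn = 100.0 * tp / n_truth
    sp = 100.0 * tp / n_pred if n_pred else 0.0
    return EvalResult(
        sn=sn,
        sp=sp,
        hm=harmonic_mean(sn, sp),
        tp=tp,
        fp=n_pred - len(matched_preds),
        fn=n_truth - tp,
    )


def evaluate_tis_accuracy(
    predictions: Sequence, truth: dict[str, list[TruthGene]]
) -> TisEvalResult:
    """TIS accuracy over true-positive genes (Hyatt-style internal/external).

    For each matched truth gene the matching prediction with the highest
    coding probability is assessed: an internal truth start must be predicted
    at exactly its position; an external truth start is correct iff the
    prediction reports the edge sentinel.
    """
    by_frag: dict[str, list] = {}
    for p in predictions:
        by_frag.setdefault(p.fragment_id, []).append(p)
    n_int = n_ext = c_int = c_ext = 0
    for frag_id, genes in truth.items():
        preds = by_frag.get(frag_id, [])
        for gene in genes:
            matches = [p for p in preds if _prediction_match(p, gene)]
            if not matches:
                continue
            best = max(matches, key=lambda p: max(p.p_universal, p.p_novel or 0.0))
            tis = best.tis_forward()
            if gene.tis_internal:
                n_int += 1
                if tis is not None and tis != EDGE and tis == gene.tis_forward:
                    c_int += 1
            else:
                n_ext += 1
                if tis == EDGE:
                    c_ext += 1
    total_n = n_int + n_ext
    return TisEvalResult(
        total=100.0 * (c_int + c_ext) / total_n if total_n else None,
        internal=100.0 * c_int / n_int if n_int else None,
        external=100.0 * c_ext / n_ext if n_ext else None,
        n_internal=n_int,
        n_external=n_ext,
        correct_internal=c_int,
        correct_external=c_ext,
    )


# ---------------------------------------------------------------------------
# truth-table round trip (for the simulate/evaluate CLI)
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = (
    "fragment_id",
    "fragment_length",
    "strand",
    "frame_key",
    "start",
    "end",
    "complete5",
    "complete3",
    "three_prime",
    "tis_forward",
)


def write_truth(truth: dict[str, list[TruthGene]], path) -> None:
    """Truth map as a TSV; coordinates 0-based half-open (repo convention,
    documented in the header comment of the file)."""
    lines = ["#" + "\t".join(TRUTH_COLUMNS)]
    for frag_id in sorted(truth):
        for g in truth[frag_id]:
            lines.append(
                "\t".join(
                    str(x)
                    for x in (
                        g.fragment_id,
                        g.fragment_length,
                        g.strand,
                        g.frame_key,
                        g.start,
                        g.end,
                        int(g.complete5),
                        int(g.complete3),
                        "." if g.three_prime is None else g.three_prime,
                        "." if g.tis_forward is None else g.tis_forward,
                    )
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth(path) -> dict[str, list[TruthGene]]:
    truth: dict[str, list[TruthGene]] = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            c = ln.rstrip("\n").split("\t")
            g = TruthGene(
                fragment_id=c[0],
                fragment_length=int(c[1]),
                strand=c[2],
                frame_key=int(c[3]),
                start=int(c[4]),
                end=int(c[5]),
                complete5=bool(int(c[6])),
                complete3=bool(int(c[7])),
                three_prime=None if c[8] == "." else int(c[8]),
                tis_forward=None if c[9] == "." else int(c[9]),
            )
            truth.setdefault(g.fragment_id, []).append(g)
    return truth
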