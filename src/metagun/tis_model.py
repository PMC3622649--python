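"""Three-class translation initiation site (TIS) model and start relocation.

Every candidate start codon of an ORF is scored with a posterior triplet:
the probability of being the true TIS (Pt), a false start in non-coding
sequence upstream of the gene (Pnc), and a false start inside coding
sequence (Pco).  Each class is modelled by a positional Markov chain (order
<= 2, add-one smoothing) over up to 50 bases upstream of the candidate,
a start-codon usage distribution over {ATG, GTG, TTG}, and an empirical
class prior; the three log-likelihoods are softmax-normalised.

Relocation of a predicted gene's start follows the modified MetaTISA rules:
candidates need at least 10 bp of upstream context to be scored; for a
5'-complete ORF the candidate with the highest Pt wins (ties go to the
5'-most); for a 5'-incomplete ORF the 5'-most candidate is first tested
against the training distribution of Pco at coding-interior starts — if its
Pco falls inside the central 95% mass the candidate looks like it sits
within coding sequence, the true start is deemed to run off the fragment
edge, and the :data:`EDGE` sentinel is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .dna import BASE_INDEX, START_CODONS, STOP_CODONS, revcomp
from .io import GeneAnnotation, SeqRecord
from .orf import OrfCandidate, TisCandidate, oriented_sequence

#: sentinel returned by :func:`relocate_tis` when the true start is judged
#: to lie off the 5' edge of the fragment
EDGE = "edge"

WINDOW_UPSTREAM = 50  # bases of upstream context modelled
MIN_UPSTREAM = 10  # minimal requisite upstream length for scoring
MIN_TRAINING_STARTS = 30

CLASS_NAMES = ("true", "upstream_false", "downstream_false")


class InsufficientDataError(ValueError):
    """Raised when a genome has too few annotated starts for TIS training."""


@dataclass(frozen=True)
class TisScores:
    p_true: float
    p_upstream_false: float
    p_downstream_false: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_true, self.p_upstream_false, self.p_downstream_false)


NEUTRAL_TIS_SCORES = TisScores(1 / 3, 1 / 3, 1 / 3)


@dataclass
class TisParameterSet:
    """Trained TIS scoring parameters for one genus (or pooled group).

    ``tables[cls][q]`` holds positional conditional counts of shape
    ``(WINDOW_UPSTREAM, 4**q, 4)``: row r describes the base at offset
    -(r+1) from the start codon given its q immediately-upstream bases.
    Truncated windows fall back to the highest order available inside the
    window, which is why all orders 0..m are kept.
    """

    genus_id: str
    order: int
    priors: np.ndarray  # (3,)
    codon_usage: np.ndarray  # (3 classes, 3 start codons), probabilities
    tables: list[list[np.ndarray]]  # [class][order] count arrays
    pco_reference: np.ndarray  # sorted Pco values at coding-interior starts
    n_training_starts: int = 0
    _logp: list | None = field(default=None, repr=False, compare=False)

    def log_prob(self, cls: int, q: int, row: int, ctx: int, base: int) -> float:
        return float(self.logp()[cls][q][row, ctx, base])

    def logp(self) -> list:
        """Interpolated positional log-probabilities (cached).

        Order 0 uses add-one smoothing; each higher order shrinks toward the
        next-lower order with a pseudo-count mass of 4, so sparsely observed
        contexts fall back to the better-estimated shorter context instead of
        amplifying sampling noise (the per-offset tables see only as many
        windows as the genome has training starts).
        """
        if self._logp is None:
            out = []
            for per_cls in self.tables:
                probs: list[np.ndarray] = []
                for q, t in enumerate(per_cls):
                    totals = t.sum(axis=2, keepdims=True)
                    if q == 0:
                        p = (t + 1.0) / (totals + 4.0)
                    else:
                        # parent context drops the oldest (highest-digit) base
                        parent = probs[q - 1][:, np.arange(t.shape[1]) % (t.shape[1] // 4), :]
                        p = (t + 4.0 * parent) / (totals + 4.0)
                    probs.append(p)
                out.append([np.log(p) for p in probs])
            self._logp = out
        return self._logp

    # -- serialization (JSON, text-only artifact) --

    def to_dict(self) -> dict:
        return {
            "genus_id": self.genus_id,
            "order": self.order,
            "priors": self.priors.tolist(),
            "codon_usage": self.codon_usage.tolist(),
            "tables": [[t.tolist() for t in per_cls] for per_cls in self.tables],
            "pco_reference": self.pco_reference.tolist(),
            "n_training_starts": self.n_training_starts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TisParameterSet":
        return cls(
            genus_id=d["genus_id"],
            order=d["order"],
            priors=np.array(d["priors"]),
            codon_usage=np.array(d["codon_usage"]),
            tables=[[np.array(t) for t in per_cls] for per_cls in d["tables"]],
            pco_reference=np.array(d["pco_reference"]),
            n_training_starts=d.get("n_training_starts", 0),
        )


@dataclass
class TisParameterBank:
    """Genus-keyed parameter sets with domain-pooled fallbacks."""

    by_genus: dict = field(default_factory=dict)
    by_domain: dict = field(default_factory=dict)

    def lookup(self, genus: str | None, domain: str | None) -> TisParameterSet | None:
        if genus is not None and genus in self.by_genus:
            return self.by_genus[genus]
        if domain is not None and domain in self.by_domain:
            return self.by_domain[domain]
        return None

    def save(self, path: str | Path) -> None:
        payload = {
            "by_genus": {g: p.to_dict() for g, p in self.by_genus.items()},
            "by_domain": {d: p.to_dict() for d, p in self.by_domain.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TisParameterBank":
        payload = json.loads(Path(path).read_text())
        return cls(
            by_genus={
                g: TisParameterSet.from_dict(p) for g, p in payload["by_genus"].items()
            },
            by_domain={
                d: TisParameterSet.from_dict(p) for d, p in payload["by_domain"].items()
            },
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _collect_instances(
    sequence: str, annotations: list[GeneAnnotation]
) -> tuple[list[list[tuple[str, str]]], int]:
    """Gather (upstream window, start codon) instances for the three classes.

    True instances come from annotated starts; upstream-false instances from
    in-frame start codons 5' of the annotated start, walking upstream until
    the first in-frame stop — the same stop-free-run geometry a candidate
    list has on a fragment, so contexts overlapping a neighbouring gene in a
    different frame (non-coding in the candidate's own frame) are
    represented; downstream-false from in-frame start codons inside the
    annotated coding region.
    """
    length = len(sequence)
    rc = revcomp(sequence)
    instances: list[list[tuple[str, str]]] = [[], [], []]
    n_starts = 0
    for ann in annotations:
        if not ann.is_truth_tis:
            continue
        if ann.strand == "+":
            seq, pos = sequence, ann.start
        else:
            seq, pos = rc, length - ann.end
        glen = ann.end - ann.start
        codon = seq[pos : pos + 3]
        if codon not in START_CODONS or pos < MIN_UPSTREAM:
            continue
        n_starts += 1
        u = min(WINDOW_UPSTREAM, pos)
        instances[0].append((seq[pos - u : pos], codon))
        # upstream false starts: walk 5' in frame until an in-frame stop
        for j in range(1, 51):
            p = pos - 3 * j
            if p < 0:
                break
            cod = seq[p : p + 3]
            if cod in STOP_CODONS:
                break
            if cod in START_CODONS and p >= MIN_UPSTREAM:
                uu = min(WINDOW_UPSTREAM, p)
                instances[1].append((seq[p - uu : p], cod))
        # downstream false starts: in-frame starts inside the coding region
        for p in range(pos + 3, pos + glen - 3, 3):
            cod = seq[p : p + 3]
            if cod in START_CODONS and p >= MIN_UPSTREAM:
                uu = min(WINDOW_UPSTREAM, p)
                instances[2].append((seq[p - uu : p], cod))
    return instances, n_starts


def _fit_instances(
    instances: list[list[tuple[str, str]]], order: int, genus_id: str, n_starts: int
) -> TisParameterSet:
    tables = [
        [np.zeros((WINDOW_UPSTREAM, 4**q, 4), dtype=np.float64) for q in range(order + 1)]
        for _ in range(3)
    ]
    # epsilon-smoothed start-codon usage (empirical frequencies; the tiny
    # floor only guards log(0) for codons a class never emits)
    codon_counts = np.full((3, 3), 1e-6, dtype=np.float64)
    start_index = {c: i for i, c in enumerate(START_CODONS)}
    for cls, inst in enumerate(instances):
        for window, codon in inst:
            codon_counts[cls, start_index[codon]] += 1
            u = len(window)
            codes = [BASE_INDEX.get(b, -1) for b in window]
            for r in range(u):
                base = codes[u - 1 - r]
                if base < 0:
                    continue
                for q in range(order + 1):
                    lo = u - 1 - r - q
                    if lo < 0:
                        break
                    ctx_codes = codes[lo : u - 1 - r]
                    if any(c < 0 for c in ctx_codes):
                        continue
                    ctx = 0
                    for c in ctx_codes:
                        ctx = ctx * 4 + c
                    tables[cls][q][r, ctx, base] += 1
    totals = np.array([max(len(i), 0) for i in instances], dtype=np.float64)
    priors = (totals + 1.0) / (totals.sum() + 3.0)
    params = TisParameterSet(
        genus_id=genus_id,
        order=order,
        priors=priors,
        codon_usage=codon_counts / codon_counts.sum(axis=1, keepdims=True),
        tables=tables,
        pco_reference=np.array([]),
        n_training_starts=n_starts,
    )
    # empirical Pco distribution at coding-interior starts, used by the
    # 95%-confidence edge test during relocation.  Windows are re-scored at
    # the truncated upstream lengths that occur on real fragments (candidates
    # near the 5' edge see 10..50 bp of context), so the reference matches
    # prediction-time conditions rather than only full 50 bp windows.
    pco = []
    for window, codon in instances[2]:
        for u in (10, 20, 30, 40, WINDOW_UPSTREAM):
            if u <= len(window):
                pco.append(
                    _score_window(params, window[len(window) - u :], codon).p_downstream_false
                )
    params.pco_reference = np.sort(np.array(pco))
    return params


def train_tis_parameters(
    genome,
    annotations: list[GeneAnnotation] | None = None,
    order: int = 2,
    genus_id: str | None = None,
) -> TisParameterSet:
    """Train a :class:`TisParameterSet` from one annotated genome.

    ``genome`` may be any object with ``id`` and ``sequence`` attributes
    (e.g. :class:`~metagun.io.SeqRecord` or a simulator genome); annotations
    default to ``genome.annotations``.  Requires at least 30 usable annotated
    starts and a Markov order in {0, 1, 2}.
    """
    if order not in (0, 1, 2):
        raise ValueError(f"Markov order must be 0..2, got {order}")
    if annotations is None:
        annotations = getattr(genome, "annotations", None)
        if annotations is None:
            raise ValueError("no annotations provided")
    instances, n_starts = _collect_instances(genome.sequence, list(annotations))
    if n_starts < MIN_TRAINING_STARTS:
        raise InsufficientDataError(
            f"{genome.id}: {n_starts} usable annotated starts (< {MIN_TRAINING_STARTS})"
        )
    gid = genus_id if genus_id is not None else getattr(genome, "genus", genome.id)
    return _fit_instances(instances, order, gid, n_starts)


def train_tis_parameter_bank(genomes, order: int = 2) -> TisParameterBank:
    """Pool training genomes into genus-level and domain-level parameter sets."""
    pools: dict[tuple[str, str], list] = {}
    for g in genomes:
        inst, n = _collect_instances(g.sequence, list(g.annotations))
        pools.setdefault(("genus", g.genus), [[[], [], []], 0])
        pools.setdefault(("domain", g.domain), [[[], [], []], 0])
        for key in (("genus", g.genus), ("domain", g.domain)):
            for cls in range(3):
                pools[key][0][cls].extend(inst[cls])
            pools[key][1] += n
    bank = TisParameterBank()
    for (kind, name), (inst, n) in pools.items():
        if n < MIN_TRAINING_STARTS:
            continue
        params = _fit_instances(inst, order, name, n)
        if kind == "genus":
            bank.by_genus[name] = params
        else:
            bank.by_domain[name] = params
    return bank


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


_START_INDEX = {c: i for i, c in enumerate(START_CODONS)}


def _score_window(params: TisParameterSet, window: str, codon: str) -> TisScores:
    u = len(window)
    codes = np.array([BASE_INDEX.get(b, -1) for b in window], dtype=np.int64)
    lls = np.log(params.priors) + np.log(params.codon_usage[:, _START_INDEX[codon]])
    logp = params.logp()
    # window index i holds the base at offset -(u - i); table row r = u - 1 - i
    rows_all, qs, ctxs, bases = [], [], [], []
    for r in range(u):
        i = u - 1 - r
        base = codes[i]
        if base < 0:
            continue
        q = min(params.order, i)
        ctx_codes = codes[i - q : i]
        if (ctx_codes < 0).any():
            q, ctx = 0, 0
        else:
            ctx = 0
            for c in ctx_codes:
                ctx = ctx * 4 + int(c)
        rows_all.append(r)
        qs.append(q)
        ctxs.append(ctx)
        bases.append(int(base))
    rows_a = np.array(rows_all)
    qs_a = np.array(qs)
    ctxs_a = np.array(ctxs)
    bases_a = np.array(bases)
    for cls in range(3):
        total = 0.0
        for q in np.unique(qs_a):
            m = qs_a == q
            total += logp[cls][q][rows_a[m], ctxs_a[m], bases_a[m]].sum()
        lls[cls] += total
    post = np.exp(lls - logsumexp(lls))
    return TisScores(*post)


def score_tis_candidate(
    params: TisParameterSet,
    candidate: TisCandidate,
    fragment: SeqRecord,
    strand: str = "+",
) -> TisScores | None:
    """Posterior (Pt, Pnc, Pco) for one candidate start, or None (skip) when
    fewer than 10 bp of upstream sequence are available."""
    if candidate.upstream_available < MIN_UPSTREAM:
        return None
    seq = oriented_sequence(fragment, strand)
    u = min(WINDOW_UPSTREAM, candidate.upstream_available)
    window = seq[candidate.position - u : candidate.position]
    return _score_window(params, window, candidate.codon)


def select_tis(
    scored: list[tuple[TisCandidate, TisScores]]
) -> tuple[TisCandidate, TisScores]:
    """Candidate with the highest Pt; ties go to the 5'-most position."""
    if not scored:
        raise ValueError("select_tis requires a non-empty candidate list")
    ordered = sorted(scored, key=lambda cs: cs[0].position)
    best = ordered[0]
    for cand, sc in ordered[1:]:
        if sc.p_true > best[1].p_true:
            best = (cand, sc)
    return best


def _scored_eligible(
    params: TisParameterSet, orf: OrfCandidate, fragment: SeqRecord
) -> list[tuple[TisCandidate, TisScores]]:
    out = []
    for cand in orf.tis_candidates:
        sc = score_tis_candidate(params, cand, fragment, strand=orf.strand)
        if sc is not None:
            out.append((cand, sc))
    return out


def tis_scores_for_features(
    params: TisParameterSet, orf: OrfCandidate, fragment: SeqRecord
) -> TisScores | None:
    """TIS score triplet entering the ORF's feature vector.

    Absent for 5'-incomplete ORFs and when no candidate passes the 10 bp
    upstream rule; otherwise the triplet of the highest-Pt candidate.
    """
    if not orf.complete5:
        return None
    scored = _scored_eligible(params, orf, fragment)
    if not scored:
        return None
    return select_tis(scored)[1]


def relocate_tis(
    orf: OrfCandidate,
    params: TisParameterSet,
    fragment: SeqRecord,
    confidence: float = 0.95,
):
    """Final start assignment for an ORF classified as coding.

    Returns the chosen :class:`~metagun.orf.TisCandidate`, or :data:`EDGE`
    when the true start is judged to lie off the fragment (5'-incomplete ORF
    whose 5'-most eligible candidate scores like a coding-interior start at
    the given two-sided confidence level, or no eligible candidate at all).
    """
    scored = _scored_eligible(params, orf, fragment)
    if not scored:
        return EDGE
    if orf.complete5:
        return select_tis(scored)[0]
    scored.sort(key=lambda cs: cs[0].position)
    pco = scored[0][1].p_downstream_false
    ref = params.pco_reference
    if ref.size:
        lo, hi = np.quantile(ref, [(1 - confidence) / 2, (1 + confidence) / 2])
        if lo <= pco <= hi:
            return EDGE
    return select_tis(scored)[0]
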