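"""Three-stage prediction: bin -> classify -> relocate starts.

Stage 1 assigns each fragment to a source genome (hence genus and domain) by
naive-Bayes k-mer binning.  Stage 2 extracts every candidate ORF, builds its
EDP/TIS/length feature vector, and scores it with the domain's universal
(and, when present, novel) SVM; ORFs whose best probability strictly exceeds
the threshold are called coding.  Stage 3 relocates the start of every
coding call with the modified MetaTISA rules, using the TIS parameters of
the fragment's genus (falling back to the domain-pooled set, then skipping
relocation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .binning import BinningModel, assign_groups
from .classifier import DEFAULT_CODING_THRESHOLD, ModelBank, decide_coding, predict_coding_probability
from .features import orf_feature_vector
from .io import SeqRecord
from .orf import OrfCandidate, extract_orfs
from .tis_model import EDGE, TisParameterBank, relocate_tis, tis_scores_for_features

log = logging.getLogger(__name__)


@dataclass
class PredictionRecord:
    """One predicted gene on one fragment.

    ``start``/``end`` are the ORF extent, 0-based half-open on the oriented
    sequence (the fragment for '+', its reverse complement for '-');
    ``tis`` is the relocated start position in the same coordinates, the
    :data:`~metagun.tis_model.EDGE` sentinel when the true start is judged to
    run off the fragment, or None when relocation was skipped.
    """

    fragment_id: str
    fragment_length: int
    strand: str
    frame: int
    start: int
    end: int
    complete5: bool
    complete3: bool
    p_universal: float
    p_novel: float | None
    source_module: str
    tis: int | str | None
    genome_id: str | None = None
    genus: str | None = None
    domain: str = "Bacteria"

    def forward_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.start, self.end
        return self.fragment_length - self.end, self.fragment_length - self.start

    def tis_forward(self):
        """Relocated TIS as a forward-strand 0-based position of the start
        codon's first base (or EDGE / None)."""
        if self.tis is None or self.tis == EDGE:
            return self.tis
        if self.strand == "+":
            return self.tis
        return self.fragment_length - 1 - self.tis


def run_predict(
    fragments: Sequence[SeqRecord],
    binning_model: BinningModel,
    model_bank: ModelBank,
    tis_bank: TisParameterBank,
    threshold: float = DEFAULT_CODING_THRESHOLD,
    seed: int = 0,
    confidence: float = 0.95,
    min_orf_len: int = 60,
    forced_assignments: dict | None = None,
) -> list[PredictionRecord]:
    """Predict genes on a set of fragments (deterministic given inputs).

    ``forced_assignments`` bypasses stage 1 for testing stage isolation.
    Fragments whose assigned domain has no universal model are skipped with a
    logged error.
    """
    assignments = (
        forced_assignments
        if forced_assignments is not None
        else assign_groups(binning_model, fragments)
    )
    predictions: list[PredictionRecord] = []
    for frag in fragments:
        assign = assignments[frag.id]
        domain = assign.domain
        if not model_bank.has_universal(domain):
            log.error("no universal model for domain %s; fragment %s skipped", domain, frag.id)
            continue
        params = tis_bank.lookup(assign.genus, domain)
        for orf in extract_orfs(frag, min_len=min_orf_len):
            tis_scores = (
                tis_scores_for_features(params, orf, frag) if params is not None else None
            )
            try:
                fv = orf_feature_vector(orf, frag, tis_scores, domain)
            except Exception:
                continue
            uni = model_bank.get("universal", domain, orf.complete5)
            p_uni = predict_coding_probability(uni, fv)
            novel = model_bank.get("novel", domain, orf.complete5)
            p_nov = predict_coding_probability(novel, fv) if novel is not None else None
            if not decide_coding(p_uni, p_nov, threshold):
                continue
            source = "universal" if p_uni >= (p_nov or 0.0) else "novel"
            if p_nov is not None and p_nov > threshold >= p_uni:
                source = "novel"
            tis = relocate_tis(orf, params, frag, confidence) if params is not None else None
            predictions.append(
                PredictionRecord(
                    fragment_id=frag.id,
                    fragment_length=len(frag),
                    strand=orf.strand,
                    frame=orf.frame,
                    start=orf.start,
                    end=orf.end,
                    complete5=orf.complete5,
                    complete3=orf.complete3,
                    p_universal=p_uni,
                    p_novel=p_nov,
                    source_module=source,
                    tis=(tis.position if hasattr(tis, "position") else tis),
                    genome_id=assign.genome_id,
                    genus=assign.genus,
                    domain=domain,
                )
            )
    return predictions
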