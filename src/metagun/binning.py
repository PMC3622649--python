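"""Naive-Bayes k-mer binning of fragments to source genomes.

The binning model holds, per training genome, a smoothed probability table
over all 4^k k-mers counted on both strands of the genome (pooling strands
makes the model strand-symmetric, so a fragment's sequencing orientation is
irrelevant).  A fragment is scored by the sum of log k-mer probabilities of
its (n-k+1) overlapping k-mers plus a uniform log-prior, and assigned to the
genome with the highest posterior; genome -> genus and genome -> domain maps
then give the genus used for TIS-parameter selection and the domain used for
SVM-model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
from scipy.special import logsumexp

from .dna import encode, revcomp
from .io import SeqRecord

DEFAULT_K = 8
#: domain assigned to unclassifiable fragments (shorter than k or all-N)
DEFAULT_DOMAIN = "Bacteria"


class GroupAssignment(NamedTuple):
    genome_id: str | None
    genus: str | None
    domain: str


@dataclass
class BinningModel:
    k: int
    genome_ids: list[str]  # sorted lexicographically (deterministic tie-break)
    log_probs: np.ndarray  # (n_genomes, 4**k) log k-mer probabilities
    genus_map: dict
    domain_map: dict

    def save(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "genome_ids": self.genome_ids,
            "log_probs": [row.tolist() for row in self.log_probs],
            "genus_map": self.genus_map,
            "domain_map": self.domain_map,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BinningModel":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            genome_ids=d["genome_ids"],
            log_probs=np.array(d["log_probs"]),
            genus_map=d["genus_map"],
            domain_map=d["domain_map"],
        )


def _kmer_indices(seq: str, k: int) -> np.ndarray:
    """Base-4 integer codes of all overlapping k-mers; windows containing N
    are dropped."""
    codes = encode(seq).astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col >= 0
        idx = idx * 4 + np.where(col >= 0, col, 0)
    return idx[valid]


def count_kmers_both_strands(sequence: str, k: int) -> np.ndarray:
    counts = np.zeros(4**k, dtype=np.int64)
    for s in (sequence, revcomp(sequence)):
        idx = _kmer_indices(s, k)
        if idx.size:
            counts += np.bincount(idx, minlength=4**k)
    return counts


def train_binning_model(genomes: Iterable, k: int = DEFAULT_K) -> BinningModel:
    """Train per-genome k-mer tables with add-one smoothing.

    ``genomes`` are objects with ``id``, ``sequence``, ``genus`` and
    ``domain`` attributes (e.g. simulator :class:`GenomeRecord`).
    """
    if not (1 <= k <= 12):
        raise ValueError(f"k must be in 1..12, got {k}")
    genomes = sorted(genomes, key=lambda g: g.id)
    if not genomes:
        raise ValueError("at least one training genome required")
    log_probs = np.zeros((len(genomes), 4**k))
    for i, g in enumerate(genomes):
        counts = count_kmers_both_strands(g.sequence, k) + 1  # add-one smoothing
        log_probs[i] = np.log(counts / counts.sum())
    return BinningModel(
        k=k,
        genome_ids=[g.id for g in genomes],
        log_probs=log_probs,
        genus_map={g.id: g.genus for g in genomes},
        domain_map={g.id: g.domain for g in genomes},
    )


def fragment_log_scores(model: BinningModel, fragment: SeqRecord) -> np.ndarray | None:
    """Per-genome log score (log-likelihood + log uniform prior), or None for
    unclassifiable fragments."""
    idx = _kmer_indices(fragment.sequence, model.k)
    if idx.size == 0:
        return None
    log_prior = -np.log(len(model.genome_ids))
    return model.log_probs[:, idx].sum(axis=1) + log_prior


def classify_fragment(
    model: BinningModel, fragment: SeqRecord
) -> tuple[str | None, float]:
    """(genome_id, posterior) of the best genome; (None, 0.0) when the
    fragment is shorter than k or contains no N-free k-mer."""
    scores = fragment_log_scores(model, fragment)
    if scores is None:
        return None, 0.0
    post = np.exp(scores - logsumexp(scores))
    best = int(np.argmax(post))  # genome_ids sorted, so argmax ties break lexicographically
    return model.genome_ids[best], float(post[best])


def assign_groups(model: BinningModel, fragments: Iterable[SeqRecord]) -> dict:
    """Map fragment_id -> (genome_id, genus, domain); unclassifiable
    fragments fall back to (None, None, Bacteria)."""
    out = {}
    for frag in fragments:
        gid, _ = classify_fragment(model, frag)
        if gid is None:
            out[frag.id] = GroupAssignment(None, None, DEFAULT_DOMAIN)
        else:
            out[frag.id] = GroupAssignment(
                gid, model.genus_map[gid], model.domain_map[gid]
            )
    return out
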