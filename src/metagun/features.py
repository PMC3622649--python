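"""SVM input features for candidate ORFs.

Three blocks describe an ORF's coding potential:

1. the 61-dimensional entropy density profile (EDP) of codon usage,

       s_i = -(1/H) c_i log c_i,   H = -sum_i c_i log c_i,

   where c_i is the relative abundance of sense codon i (stop codons are
   never counted).  The EDP is invariant to the logarithm base and to
   rescaling of counts, and sums to 1 whenever H > 0;
2. the (Pt, Pnc, Pco) TIS score triplet of the best candidate start —
   present only for 5'-complete ORFs;
3. two ORF-length features, one used for complete ORFs and one for
   incomplete ones, the unused slot set to zero.

The numeric layout is fixed: 61 EDP values, then 3 TIS scores (5'-complete
ORFs only), then the 2 length features divided by ``LENGTH_SCALE`` (the
1500 bp maximum training fragment length) and capped at 1.0 — 66 dimensions
for 5'-complete ORFs, 63 for 5'-incomplete ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dna import SENSE_INDEX, STOP_CODONS
from .io import SeqRecord
from .orf import OrfCandidate, oriented_sequence

N_SENSE_CODONS = 61
#: divisor applied to raw bp lengths before they enter the Gaussian kernel
LENGTH_SCALE = 1500.0


class DegenerateOrfError(ValueError):
    """Raised when an ORF has too few countable codons to be profiled."""


@dataclass(frozen=True)
class FeatureVector:
    edp: np.ndarray  # 61 floats
    tis: "TisScores | None"  # present iff complete5
    len_complete: int
    len_incomplete: int
    complete5: bool
    domain: str

    def __post_init__(self) -> None:
        if (self.tis is not None) != self.complete5:
            raise ValueError("TIS scores must be present iff the ORF is 5'-complete")
        if self.len_complete and self.len_incomplete:
            raise ValueError("exactly one length feature may be nonzero")

    @property
    def n_dims(self) -> int:
        return 66 if self.complete5 else 63

    def to_array(self) -> np.ndarray:
        parts = [self.edp]
        if self.complete5:
            parts.append(
                np.array(
                    [self.tis.p_true, self.tis.p_upstream_false, self.tis.p_downstream_false]
                )
            )
        parts.append(
            np.minimum(
                np.array([self.len_complete, self.len_incomplete]) / LENGTH_SCALE, 1.0
            )
        )
        return np.concatenate(parts)


def count_codons(orf: OrfCandidate, fragment: SeqRecord) -> np.ndarray:
    """In-frame sense-codon counts over the ORF extent.

    The terminal stop codon of a 3'-complete ORF is excluded; stop codons and
    codons containing N are never counted.  Fewer than two countable codons
    raises :class:`DegenerateOrfError`.
    """
    seq = oriented_sequence(fragment, orf.strand)
    end = orf.end - 3 if orf.complete3 else orf.end
    counts = np.zeros(N_SENSE_CODONS, dtype=np.int64)
    for p in range(orf.start, end, 3):
        codon = seq[p : p + 3]
        idx = SENSE_INDEX.get(codon)
        if idx is not None:
            counts[idx] += 1
        elif codon not in STOP_CODONS and "N" not in codon:
            raise AssertionError(f"unexpected codon {codon!r}")
    if counts.sum() < 2:
        raise DegenerateOrfError(
            f"ORF {orf.orf_id} has {int(counts.sum())} countable codons"
        )
    return counts


def compute_edp(counts: np.ndarray) -> np.ndarray:
    """Entropy density profile of a codon-count vector.

    With a single distinct codon the Shannon entropy H is zero and the EDP is
    defined as the one-hot limit (equal to the abundance vector itself).
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise DegenerateOrfError("all-zero codon counts")
    c = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(c > 0, -c * np.log(c), 0.0)
    h = terms.sum()
    if h == 0.0:
        return c.copy()
    return terms / h


def compute_length_features(orf: OrfCandidate) -> tuple[int, int]:
    """(complete length, incomplete length); the inapplicable one is zero."""
    if orf.complete5 and orf.complete3:
        return orf.length, 0
    return 0, orf.length


def assemble_feature_vector(
    edp: np.ndarray,
    tis: "TisScores | None",
    lengths: tuple[int, int],
    complete5: bool,
    domain: str,
) -> FeatureVector:
    """Bundle the three feature blocks; see the module docstring for layout."""
    return FeatureVector(
        edp=np.asarray(edp, dtype=np.float64),
        tis=tis,
        len_complete=lengths[0],
        len_incomplete=lengths[1],
        complete5=complete5,
        domain=domain,
    )


def orf_feature_vector(
    orf: OrfCandidate,
    fragment: SeqRecord,
    tis: "TisScores | None",
    domain: str,
) -> FeatureVector:
    """Convenience: full feature vector for one ORF.

    A 5'-complete ORF whose candidates were all skipped by the 10 bp upstream
    rule has no TIS triplet; the uninformative (1/3, 1/3, 1/3) fill keeps the
    66-dimension layout.
    """
    if orf.complete5 and tis is None:
        from .tis_model import NEUTRAL_TIS_SCORES

        tis = NEUTRAL_TIS_SCORES
    edp = compute_edp(count_codons(orf, fragment))
    return assemble_feature_vector(
        edp, tis if orf.complete5 else None, compute_length_features(orf), orf.complete5, domain
    )
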