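"""Universal and novel SVM gene-classification modules.

Each module holds Gaussian-kernel SVM classifiers keyed by (domain,
5'-completeness): the universal module is trained on fragments sampled from
annotated reference genomes, the sample-specific novel module on ORFs
carrying significant conserved-domain hits (e-value < 1e-40) as positives
and 'shadow' ORFs (overlapping a positive by more than 90 bp in a different
reading frame) as negatives.  Training subsamples to at most 1.6 M vectors,
grid-searches the RBF width gamma and penalty C by 5-fold cross-validation
(ties broken toward smaller C, then smaller gamma), and calibrates distances
from the separating hyperplane into probabilities (Platt scaling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureVector, orf_feature_vector
from .io import DomainHit, SeqRecord
from .orf import OrfCandidate, extract_orfs
from .simulator import GenomeRecord, sample_fragments
from .tis_model import TisParameterBank, train_tis_parameter_bank, tis_scores_for_features

log = logging.getLogger(__name__)

TRAINING_CAP = 1_600_000
DOMAIN_HIT_E_THRESHOLD = 1e-40
SHADOW_MIN_OVERLAP = 90
DEFAULT_CODING_THRESHOLD = 0.5

#: spec grid: gamma = 2^-15 .. 2^3 step 2^2, C = 2^-5 .. 2^15 step 2^2
DEFAULT_GAMMA_RANGE = tuple(2.0**e for e in range(-15, 4, 2))
DEFAULT_C_RANGE = tuple(2.0**e for e in range(-5, 16, 2))
#: vectors used for the cross-validated grid search (final fit uses all)
GRID_SUBSAMPLE = 2000


class TrainingError(ValueError):
    pass


@dataclass
class SvmModel:
    gamma: float
    C: float
    estimator: CalibratedClassifierCV
    n_features: int  # 66 (5'-complete) or 63 (5'-incomplete) layout tag
    cv_accuracy: float
    n_training: int = 0
    length_scale: float = 1500.0

    def predict_proba_coding(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature layout mismatch: model expects {self.n_features} dims, got {x.shape[1]}"
            )
        coding_col = list(self.estimator.classes_).index(1)
        return self.estimator.predict_proba(x)[:, coding_col]


@dataclass
class ModelBank:
    """(module, domain, complete5) -> SvmModel; 'novel' entries optional."""

    models: dict = field(default_factory=dict)

    def add(self, module: str, domain: str, complete5: bool, model: SvmModel) -> None:
        self.models[(module, domain, complete5)] = model

    def get(self, module: str, domain: str, complete5: bool) -> SvmModel | None:
        return self.models.get((module, domain, complete5))

    def has_universal(self, domain: str) -> bool:
        return all(("universal", domain, c) in self.models for c in (True, False))

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBank":
        return joblib.load(path)


def _as_matrix(vectors: Sequence) -> np.ndarray:
    rows = [
        v.to_array() if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
        for v in vectors
    ]
    dims = {r.shape[0] for r in rows}
    if len(dims) != 1:
        raise TrainingError(f"mixed feature layouts in one training set: {sorted(dims)}")
    return np.vstack(rows)


def _as_labels(labels: Sequence) -> np.ndarray:
    out = []
    for l in labels:
        if isinstance(l, str):
            out.append(1 if l == "coding" else 0)
        else:
            out.append(int(bool(l)))
    return np.array(out, dtype=int)


def train_svm(
    vectors: Sequence,
    labels: Sequence,
    grid: tuple[Iterable[float], Iterable[float]] | None = None,
    cap: int = TRAINING_CAP,
    seed: int = 0,
    cv: int = 5,
    grid_subsample: int = GRID_SUBSAMPLE,
) -> SvmModel:
    """Grid-searched, probability-calibrated Gaussian-kernel SVM.

    When the training set exceeds ``cap`` a uniformly random (seeded) subset
    of ``cap`` vectors is retained.  The (gamma, C) pair maximising mean
    5-fold CV accuracy is selected, ties resolved toward smaller C then
    smaller gamma; the CV search runs on a seeded stratified subsample of at
    most ``grid_subsample`` vectors, the final probability-calibrated model
    is fit on all retained vectors.
    """
    x = _as_matrix(vectors)
    y = _as_labels(labels)
    if len(np.unique(y)) < 2:
        raise TrainingError("both coding and non-coding classes are required")
    rng = np.random.default_rng(seed)
    if x.shape[0] > cap:
        keep = rng.choice(x.shape[0], size=cap, replace=False)
        x, y = x[keep], y[keep]
    xs, ys = x, y
    if grid_subsample and x.shape[0] > grid_subsample:
        idx = _stratified_subsample(y, grid_subsample, rng)
        xs, ys = x[idx], y[idx]
    gammas, cs = grid if grid is not None else (DEFAULT_GAMMA_RANGE, DEFAULT_C_RANGE)
    n_splits = min(cv, int(np.bincount(ys).min()))
    if n_splits < 2:
        raise TrainingError("too few examples per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(xs, ys))
    best = None  # (accuracy, C, gamma)
    for c_val in sorted(cs):
        for g_val in sorted(gammas):
            accs = []
            for tr, te in folds:
                clf = SVC(kernel="rbf", C=c_val, gamma=g_val)
                clf.fit(xs[tr], ys[tr])
                accs.append(float(np.mean(clf.predict(xs[te]) == ys[te])))
            acc = float(np.mean(accs))
            if best is None or acc > best[0]:
                best = (acc, c_val, g_val)
    cv_acc, c_best, g_best = best
    # Platt scaling of hyperplane distances into probabilities, fit on an
    # internal split of the retained training data
    n_cal = min(5, int(np.bincount(y).min()))
    final = CalibratedClassifierCV(
        SVC(kernel="rbf", C=c_best, gamma=g_best),
        method="sigmoid",
        cv=max(n_cal, 2),
        ensemble=False,
    )
    final.fit(x, y)
    return SvmModel(
        gamma=g_best,
        C=c_best,
        estimator=final,
        n_features=x.shape[1],
        cv_accuracy=cv_acc,
        n_training=x.shape[0],
    )


def _stratified_subsample(y: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    idx = []
    classes, counts = np.unique(y, return_counts=True)
    frac = n / y.shape[0]
    for cls in classes:
        members = np.flatnonzero(y == cls)
        take = max(2, int(round(frac * members.size)))
        idx.append(rng.choice(members, size=min(take, members.size), replace=False))
    return np.sort(np.concatenate(idx))


def predict_coding_probability(model: SvmModel, fv: FeatureVector | np.ndarray) -> float:
    """Calibrated probability that one ORF is protein-coding."""
    x = fv.to_array() if isinstance(fv, FeatureVector) else np.asarray(fv, float)
    return float(model.predict_proba_coding(x.reshape(1, -1))[0])


def decide_coding(
    p_universal: float,
    p_novel: float | None = None,
    threshold: float = DEFAULT_CODING_THRESHOLD,
) -> bool:
    """Coding iff either module's probability strictly exceeds the threshold."""
    p = p_universal if p_novel is None else max(p_universal, p_novel)
    return p > threshold


# ---------------------------------------------------------------------------
# universal module
# ---------------------------------------------------------------------------


def _orf_is_coding(orf: OrfCandidate, genes, fragment_length: int) -> bool:
    """Training label: does this ORF originate from an annotated gene?

    3'-complete ORFs must share the gene's exact 3' end; 3'-incomplete ORFs
    must overlap a 3'-incomplete gene in the same strand and frame (the
    mirror of the evaluation TP rule).
    """
    a, b = orf.forward_interval(fragment_length)
    for g in genes:
        if g.strand != orf.strand:
            continue
        if orf.complete3 != g.complete3:
            continue
        if orf.complete3:
            orf_3p = b - 1 if orf.strand == "+" else a
            if orf_3p == g.three_prime:
                return True
        else:
            frame = a % 3 if orf.strand == "+" else b % 3
            if frame == g.frame_key and min(b, g.end) > max(a, g.start):
                return True
    return False


def build_universal_module(
    genomes: Sequence[GenomeRecord],
    sampler_config: dict | None = None,
    seed: int = 0,
    tis_bank: TisParameterBank | None = None,
    cap: int = TRAINING_CAP,
    grid: tuple | None = None,
    min_orf_len: int = 60,
    model_bank: ModelBank | None = None,
) -> ModelBank:
    """Train the universal prediction module from annotated genomes.

    Fragments are sampled at 3x coverage with lengths uniform on 60-1500 bp
    (overridable via ``sampler_config``), all ORFs >= 60 bp extracted and
    labelled coding when they originate from an annotated gene; vectors are
    pooled per domain and split by 5'-completeness into four classifiers.
    TIS parameters are trained from the same genomes when not supplied.
    """
    if not genomes:
        raise TrainingError("at least one annotated training genome required")
    if any(not g.annotations for g in genomes):
        raise TrainingError("every training genome must carry annotations")
    cfg = {"coverage": 3.0, "length_spec": (60, 1500)}
    if sampler_config:
        cfg.update(sampler_config)
    if tis_bank is None:
        tis_bank = train_tis_parameter_bank(genomes)
    buckets: dict[tuple[str, bool], tuple[list, list]] = {}
    for gi, genome in enumerate(genomes):
        frags, truth = sample_fragments(
            genome, coverage=cfg["coverage"], length_spec=cfg["length_spec"], seed=seed + 1000 * gi
        )
        params = tis_bank.lookup(genome.genus, genome.domain)
        for frag in frags:
            genes = truth[frag.id]
            for orf in extract_orfs(frag, min_len=min_orf_len):
                tis = (
                    tis_scores_for_features(params, orf, frag)
                    if params is not None
                    else None
                )
                try:
                    fv = orf_feature_vector(orf, frag, tis, genome.domain)
                except Exception:
                    continue
                label = _orf_is_coding(orf, genes, len(frag))
                xs, ys = buckets.setdefault(
                    (genome.domain, orf.complete5), ([], [])
                )
                xs.append(fv)
                ys.append(int(label))
    bank = model_bank if model_bank is not None else ModelBank()
    domains = {g.domain for g in genomes}
    for domain in sorted(domains):
        for complete5 in (True, False):
            key = (domain, complete5)
            if key not in buckets:
                warnings.warn(f"no training ORFs for {key}; model absent")
                continue
            xs, ys = buckets[key]
            try:
                model = train_svm(xs, ys, grid=grid, cap=cap, seed=seed)
            except TrainingError as exc:
                warnings.warn(f"universal model {key} not trained: {exc}")
                continue
            bank.add("universal", domain, complete5, model)
            log.info(
                "universal %s complete5=%s: n=%d gamma=%g C=%g cv=%.3f",
                domain, complete5, len(ys), model.gamma, model.C, model.cv_accuracy,
            )
    return bank


# ---------------------------------------------------------------------------
# novel module
# ---------------------------------------------------------------------------


def label_by_domain_hits(
    orfs: Sequence[OrfCandidate],
    hits: Sequence[DomainHit],
    e_threshold: float = DOMAIN_HIT_E_THRESHOLD,
) -> set[str]:
    """ORF ids with at least one conserved-domain hit at e-value strictly
    below the threshold."""
    known = {o.orf_id for o in orfs}
    return {
        h.orf_id for h in hits if h.e_value < e_threshold and h.orf_id in known
    }


def shadow_negatives(
    orfs: Sequence[OrfCandidate],
    positives: set[str],
    min_overlap: int = SHADOW_MIN_OVERLAP,
    fragment_lengths: dict[str, int] | None = None,
) -> set[str]:
    """'Shadow' rule: ORFs overlapping a positive ORF on the same fragment by
    strictly more than ``min_overlap`` bp in a different reading frame."""
    by_frag: dict[str, list[OrfCandidate]] = {}
    for o in orfs:
        by_frag.setdefault(o.fragment_id, []).append(o)
    out: set[str] = set()
    for frag_id, group in by_frag.items():
        flen = (
            fragment_lengths[frag_id]
            if fragment_lengths
            else max(o.end for o in group)
        )
        pos = [o for o in group if o.orf_id in positives]
        for o in group:
            if o.orf_id in positives:
                continue
            a, b = o.forward_interval(flen)
            for p in pos:
                if (o.strand, o.frame) == (p.strand, p.frame):
                    continue
                pa, pb = p.forward_interval(flen)
                if min(b, pb) - max(a, pa) > min_overlap:
                    out.add(o.orf_id)
                    break
    return out


def build_novel_module(
    fragments: Sequence[SeqRecord],
    hits: Sequence[DomainHit],
    group_assignments: dict,
    seed: int = 0,
    tis_bank: TisParameterBank | None = None,
    cap: int = TRAINING_CAP,
    grid: tuple | None = None,
    min_orf_len: int = 60,
    model_bank: ModelBank | None = None,
) -> ModelBank:
    """Train the sample-specific novel module from conserved-domain evidence.

    Positives are ORFs with hits at e < 1e-40; negatives come from the shadow
    rule; vectors are split by the fragment's binning domain and by
    5'-completeness.  Cells missing a class are skipped with a warning; with
    no positives at all the module is absent.
    """
    frag_index = {f.id: f for f in fragments}
    all_orfs: list[OrfCandidate] = []
    for f in fragments:
        all_orfs.extend(extract_orfs(f, min_len=min_orf_len))
    positives = label_by_domain_hits(all_orfs, hits)
    bank = model_bank if model_bank is not None else ModelBank()
    if not positives:
        warnings.warn("no significant domain hits: novel module absent")
        return bank
    negatives = shadow_negatives(
        all_orfs, positives, fragment_lengths={f.id: len(f) for f in fragments}
    )
    buckets: dict[tuple[str, bool], tuple[list, list]] = {}
    for orf in all_orfs:
        if orf.orf_id in positives:
            label = 1
        elif orf.orf_id in negatives:
            label = 0
        else:
            continue
        frag = frag_index[orf.fragment_id]
        assign = group_assignments.get(orf.fragment_id)
        domain = assign.domain if assign else "Bacteria"
        genus = assign.genus if assign else None
        params = tis_bank.lookup(genus, domain) if tis_bank else None
        tis = (
            tis_scores_for_features(params, orf, frag) if params is not None else None
        )
        try:
            fv = orf_feature_vector(orf, frag, tis, domain)
        except Exception:
            continue
        xs, ys = buckets.setdefault((domain, orf.complete5), ([], []))
        xs.append(fv)
        ys.append(label)
    for (domain, complete5), (xs, ys) in sorted(buckets.items()):
        try:
            model = train_svm(xs, ys, grid=grid, cap=cap, seed=seed)
        except TrainingError as exc:
            warnings.warn(f"novel model ({domain}, {complete5}) skipped: {exc}")
            continue
        bank.add("novel", domain, complete5, model)
    return bank
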