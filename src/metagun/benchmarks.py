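"""Reproducible study benchmarks run at package scale.

Each function generates its own inputs from a single seed, runs the relevant
part of the pipeline, and returns measured quantities.  They define the
package's reference study conditions:

* binning self-assignment: 4 composition-distinct synthetic genomes
  (Dirichlet alpha 0.2 codon bias, 100 kb each), 500 fragments of 870 bp;
* classifier parameter recovery: 2,000 coding + 2,000 non-coding codon-usage
  profiles (biased vs uniform), default (gamma, C) grid, 25% held out;
* end-to-end prediction: universal module trained on 2 genomes per domain
  (50 kb, SD motif at every start), tested on a held-out genome of the same
  family at 3x coverage / 870 bp fragments.
"""

from __future__ import annotations

import numpy as np

from .binning import classify_fragment, train_binning_model
from .classifier import build_universal_module, train_svm
from .features import LENGTH_SCALE
from .pipeline import run_predict
from .simulator import (
    evaluate_gene_predictions,
    evaluate_tis_accuracy,
    generate_genome,
    sample_fragments,
)
from .tis_model import train_tis_parameter_bank


def related_codon_usages(
    rng: np.random.Generator, n: int, alpha: float = 0.2, tau: float = 50.0
) -> list[np.ndarray]:
    """Codon usages for a family of related genomes: independent Dirichlet
    draws concentrated (mass ``tau``) around one shared base distribution."""
    base = rng.dirichlet(np.full(61, alpha))
    out = []
    for _ in range(n):
        u = rng.dirichlet(base * tau + 0.1)
        out.append(u / u.sum())
    return out


def binning_self_assignment(
    seed: int = 1,
    n_genomes: int = 4,
    genome_length: int = 100_000,
    n_fragments: int = 500,
    fragment_length: int = 870,
    alpha: float = 0.2,
    k: int = 8,
) -> dict:
    """Fraction of fragments binned back to their source genome (percent)."""
    genomes = [
        generate_genome(
            length=genome_length,
            genome_id=f"genome{i}",
            genus=f"genus{i}",
            domain="Bacteria",
            codon_dirichlet_alpha=alpha,
            seed=seed * 100 + i,
        )
        for i in range(n_genomes)
    ]
    model = train_binning_model(genomes, k=k)
    per_genome = n_fragments // n_genomes
    correct = total = 0
    for i, g in enumerate(genomes):
        frags, _ = sample_fragments(
            g,
            coverage=per_genome * fragment_length / genome_length + 0.1,
            length_spec=fragment_length,
            seed=seed * 100 + 50 + i,
        )
        for f in frags[:per_genome]:
            gid, _ = classify_fragment(model, f)
            correct += gid == g.id
            total += 1
    return {"accuracy_pct": 100.0 * correct / total, "n": total}


def classifier_parameter_recovery(
    seed: int = 1, n_per_class: int = 2000, holdout_fraction: float = 0.25
) -> dict:
    """Held-out accuracy recovering the coding/non-coding separation.

    Coding profiles are multinomial codon counts from genome-specific
    Dirichlet(0.2)-biased usages; non-coding profiles draw codons uniformly.
    Both classes share the ORF-length distribution, so the entropy density
    profile carries the entire signal.
    """
    rng = np.random.default_rng(seed)
    usages = [rng.dirichlet(np.full(61, 0.2)) for _ in range(10)]
    uniform = np.full(61, 1 / 61)

    def profile(p):
        n_codons = int(rng.integers(20, 400))
        counts = rng.multinomial(n_codons, p)
        c = counts / counts.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(c > 0, -c * np.log(c), 0.0)
        edp = t / t.sum() if t.sum() > 0 else c
        length = min(3 * n_codons / LENGTH_SCALE, 1.0)
        return np.concatenate([edp, [0.0, length]])

    x = np.array(
        [profile(usages[i % len(usages)]) for i in range(n_per_class)]
        + [profile(uniform) for _ in range(n_per_class)]
    )
    y = np.array([1] * n_per_class + [0] * n_per_class)
    perm = rng.permutation(len(y))
    x, y = x[perm], y[perm]
    n_test = int(holdout_fraction * len(y))
    model = train_svm(x[n_test:], y[n_test:], seed=seed)
    acc = float(np.mean((model.predict_proba_coding(x[:n_test]) > 0.5) == (y[:n_test] == 1)))
    return {
        "accuracy_pct": 100.0 * acc,
        "n": n_test,
        "gamma": model.gamma,
        "C": model.C,
    }


def end_to_end_benchmark(
    seed: int = 1,
    genome_length: int = 50_000,
    fragment_length: int = 870,
    coverage: float = 3.0,
    grid=None,
) -> dict:
    """Train on 2 genomes per domain, predict on a held-out same-family
    genome, and score 3'-end Sn/Sp/Hm plus internal/external TIS accuracy."""
    rng = np.random.default_rng(seed)
    usages_b = related_codon_usages(rng, 3)
    usages_a = related_codon_usages(rng, 2)
    spec = [
        ("b1", "Escherichia", "Bacteria", usages_b[0]),
        ("b2", "Bacillus", "Bacteria", usages_b[1]),
        ("a1", "Sulfolobus", "Archaea", usages_a[0]),
        ("a2", "Methanococcus", "Archaea", usages_a[1]),
    ]
    genomes = [
        generate_genome(
            length=genome_length, genome_id=gid, genus=genus, domain=domain,
            codon_usage=usage, sd_fraction=1.0, seed=seed * 10 + i,
        )
        for i, (gid, genus, domain, usage) in enumerate(spec, start=1)
    ]
    held_out = generate_genome(
        length=genome_length, genome_id="held_out", genus="Vibrio",
        domain="Bacteria", codon_usage=usages_b[2], sd_fraction=1.0,
        seed=seed * 10 + 5,
    )
    tis_bank = train_tis_parameter_bank(genomes)
    binning_model = train_binning_model(genomes)
    model_bank = build_universal_module(
        genomes,
        sampler_config={"coverage": coverage, "length_spec": fragment_length},
        seed=seed,
        tis_bank=tis_bank,
        grid=grid,
    )
    fragments, truth = sample_fragments(
        held_out, coverage=coverage, length_spec=fragment_length, seed=seed + 11
    )
    predictions = run_predict(fragments, binning_model, model_bank, tis_bank)
    res = evaluate_gene_predictions(predictions, truth)
    tis = evaluate_tis_accuracy(predictions, truth)
    return {
        "sn_pct": res.sn,
        "sp_pct": res.sp,
        "hm_pct": res.hm,
        "tp": res.tp,
        "fp": res.fp,
        "fn": res.fn,
        "tis_internal_pct": tis.internal,
        "tis_external_pct": tis.external,
        "tis_total_pct": tis.total,
        "n_fragments": len(fragments),
        "n_truth_genes": sum(len(v) for v in truth.values()),
    }
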