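"""Shared fixtures: small synthetic genomes and a fast-trained model bank."""

from __future__ import annotations

import numpy as np
import pytest

import metagun as mg
from metagun.binning import train_binning_model
from metagun.classifier import build_universal_module
from metagun.benchmarks import related_codon_usages
from metagun.tis_model import train_tis_parameter_bank

#: a tiny (gamma, C) grid for tests that exercise plumbing, not model choice
TOY_GRID = ((2.0**-7, 2.0**-3), (1.0, 8.0))


@pytest.fixture(scope="session")
def small_genome():
    return mg.generate_genome(
        length=50_000, genome_id="gsmall", genus="Smallus", domain="Bacteria",
        sd_fraction=1.0, seed=11,
    )


@pytest.fixture(scope="session")
def trained_setup():
    """A compact trained pipeline: 1 genome per domain, toy SVM grid.

    Session-scoped because SVM training dominates test runtime; tests using
    it must not mutate the returned objects.
    """
    rng = np.random.default_rng(5)
    ub, ua = related_codon_usages(rng, 1), related_codon_usages(rng, 1)
    genomes = [
        mg.generate_genome(
            length=40_000, genome_id="bact0", genus="Bactus", domain="Bacteria",
            codon_usage=ub[0], sd_fraction=1.0, seed=21,
        ),
        mg.generate_genome(
            length=40_000, genome_id="arch0", genus="Archus", domain="Archaea",
            codon_usage=ua[0], sd_fraction=1.0, seed=22,
        ),
    ]
    tis_bank = train_tis_parameter_bank(genomes)
    bin_model = train_binning_model(genomes)
    bank = build_universal_module(
        genomes,
        sampler_config={"coverage": 1.5, "length_spec": 870},
        seed=3,
        tis_bank=tis_bank,
        grid=TOY_GRID,
    )
    return {
        "genomes": genomes,
        "tis_bank": tis_bank,
        "binning_model": bin_model,
        "model_bank": bank,
    }
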