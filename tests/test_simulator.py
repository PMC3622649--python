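"""Synthetic-genome generator contracts, fragment sampling, and the
Sn/Sp/harmonic-mean and TIS evaluation metrics."""

import numpy as np
import pytest

import metagun as mg
from metagun.dna import START_CODONS, STOP_CODONS, revcomp
from metagun.pipeline import PredictionRecord
from metagun.simulator import (
    TruthGene,
    evaluate_gene_predictions,
    evaluate_tis_accuracy,
    harmonic_mean,
    read_truth,
    write_truth,
)
from metagun.tis_model import EDGE


class TestGenerateGenome:
    def test_determinism(self):
        a = mg.generate_genome(length=20_000, genome_id="g", seed=3)
        b = mg.generate_genome(length=20_000, genome_id="g", seed=3)
        assert a.sequence == b.sequence and a.annotations == b.annotations

    def test_coding_density_near_target(self):
        g = mg.generate_genome(length=100_000, gene_density=0.9, genome_id="g", seed=1)
        coding = sum(a.end - a.start for a in g.annotations)
        assert 0.85 <= coding / len(g.sequence) <= 0.95

    def test_annotated_genes_are_valid_orfs(self):
        g = mg.generate_genome(length=30_000, genome_id="g", seed=9)
        for a in g.annotations:
            gene = g.sequence[a.start : a.end]
            if a.strand == "-":
                gene = revcomp(gene)
            assert len(gene) % 3 == 0
            assert gene[:3] in START_CODONS
            assert gene[-3:] in STOP_CODONS
            interior = [gene[i : i + 3] for i in range(3, len(gene) - 3, 3)]
            assert not any(c in STOP_CODONS for c in interior)

    def test_sd_motif_planted_upstream(self):
        g = mg.generate_genome(length=30_000, genome_id="g", sd_fraction=1.0, seed=9)
        for a in g.annotations:
            if a.strand == "+":
                assert g.sequence[a.start - 12 : a.start - 6] == "AGGAGG"
            else:
                assert g.sequence[a.end + 6 : a.end + 12] == "CCTCCT"

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError):
            mg.generate_genome(length=10_000, gene_density=0.999, genome_id="g", seed=0)


class TestSampleFragments:
    def test_fragment_count_at_fixed_length(self):
        """coverage 3 at fixed 870 bp on an 87 kb genome: 3*87000/870 = 300
        fragments exactly (counting oracle)."""
        g = mg.generate_genome(length=87_000, genome_id="g", seed=2)
        frags, _ = mg.sample_fragments(g, coverage=3.0, length_spec=870, seed=0)
        assert len(frags) == 300

    def test_fixed_length_120(self):
        g = mg.generate_genome(length=20_000, genome_id="g", seed=2)
        frags, _ = mg.sample_fragments(g, coverage=0.5, length_spec=120, seed=0)
        assert frags and all(len(f) == 120 for f in frags)

    def test_coverage_bound(self):
        g = mg.generate_genome(length=40_000, genome_id="g", seed=4)
        frags, _ = mg.sample_fragments(g, coverage=2.0, length_spec=(60, 1500), seed=1)
        total = sum(len(f) for f in frags)
        assert 2.0 <= total / len(g.sequence) <= 2.0 + 1500 / len(g.sequence)

    def test_determinism(self):
        g = mg.generate_genome(length=20_000, genome_id="g", seed=2)
        f1, t1 = mg.sample_fragments(g, coverage=1.0, length_spec=535, seed=8)
        f2, t2 = mg.sample_fragments(g, coverage=1.0, length_spec=535, seed=8)
        assert [(f.id, f.sequence) for f in f1] == [(f.id, f.sequence) for f in f2]
        assert t1 == t2

    def test_truth_projection_oracle(self):
        """Every projected truth gene is recoverable from the genome
        annotation by interval arithmetic on the fragment's sampling window."""
        g = mg.generate_genome(length=30_000, genome_id="g", seed=5)
        frags, truth = mg.sample_fragments(g, coverage=1.0, length_spec=870, seed=6)
        by_pos = {}
        for f in frags:
            fwd = f.sequence
            rev = revcomp(f.sequence)
            # locate the fragment on the genome (unique for 870-mers here)
            start = g.sequence.find(fwd)
            orientation = "+"
            if start < 0:
                start = g.sequence.find(rev)
                orientation = "-"
            assert start >= 0
            expected = []
            for a in g.annotations:
                ov = min(a.end, start + len(f)) - max(a.start, start)
                if ov >= 60:
                    expected.append((a.start, a.end, a.strand))
            got = truth[f.id]
            assert len(got) == len(expected)
            for tg in got:
                # map the clipped fragment interval back to genome coords
                if orientation == "+":
                    ga, gb = start + tg.start, start + tg.end
                    strand = tg.strand
                else:
                    ga, gb = start + len(f) - tg.end, start + len(f) - tg.start
                    strand = "+" if tg.strand == "-" else "-"
                match = [
                    (a0, b0, s0)
                    for (a0, b0, s0) in expected
                    if s0 == strand and max(a0, ga) < min(b0, gb)
                ]
                assert match, (tg, expected)

    def test_five_prime_clipped_gene_is_external_tis(self):
        g = mg.generate_genome(length=30_000, genome_id="g", seed=7)
        frags, truth = mg.sample_fragments(g, coverage=2.0, length_spec=535, seed=3)
        clipped = [
            tg for genes in truth.values() for tg in genes if not tg.complete5
        ]
        assert clipped
        for tg in clipped:
            assert tg.tis_forward is None and not tg.tis_internal


class TestHarmonicMean:
    @pytest.mark.parametrize(
        "sn,sp,hm",
        [
            (98.0, 95.2, 96.6),  # high-accuracy long-fragment regime
            (97.5, 93.6, 95.5),
            (96.9, 95.4, 96.1),
            (82.0, 76.4, 79.1),  # short-fragment regime
        ],
    )
    def test_published_style_pairs_round_to_tenth(self, sn, sp, hm):
        assert round(harmonic_mean(sn, sp), 1) == hm

    def test_degenerate_zero(self):
        assert harmonic_mean(0.0, 0.0) == 0.0

    def test_between_min_and_max(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            sn, sp = rng.uniform(0, 100, 2)
            hm = harmonic_mean(sn, sp)
            assert min(sn, sp) - 1e-9 <= hm <= max(sn, sp) + 1e-9


def _truth(frag="f", flen=300, strand="+", start=30, end=150, c5=True, c3=True):
    three_prime = (end - 1 if strand == "+" else start) if c3 else None
    tis = (start if strand == "+" else end - 1) if c5 else None
    frame = start % 3 if strand == "+" else end % 3
    return TruthGene(
        fragment_id=frag, fragment_length=flen, strand=strand, frame_key=frame,
        start=start, end=end, complete5=c5, complete3=c3,
        three_prime=three_prime, tis_forward=tis,
    )


def _pred(frag="f", flen=300, strand="+", start=30, end=150, c5=True, c3=True,
          tis=None, p=0.9):
    if strand == "-":
        start, end = flen - end, flen - start
    return PredictionRecord(
        fragment_id=frag, fragment_length=flen, strand=strand, frame=start % 3,
        start=start, end=end, complete5=c5, complete3=c3, p_universal=p,
        p_novel=None, source_module="universal", tis=tis,
    )


class TestEvaluateGenePredictions:
    def test_perfect_prediction(self):
        truth = {"f": [_truth()]}
        res = evaluate_gene_predictions([_pred()], truth)
        assert (res.sn, res.sp, res.hm) == (100.0, 100.0, 100.0)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_exact_three_prime_rule(self):
        truth = {"f": [_truth(start=30, end=150)]}
        off = _pred(start=33, end=153)  # same frame, different stop
        res = evaluate_gene_predictions([off], truth)
        assert res.tp == 0 and res.fp == 1

    def test_frame_match_when_three_prime_missing(self):
        """A 3'-incomplete truth gene is matched by any same-strand,
        same-frame overlapping 3'-incomplete prediction."""
        truth = {"f": [_truth(start=30, end=300, c3=False)]}
        pred = _pred(start=120, end=300, c3=False, c5=False)
        res = evaluate_gene_predictions([pred], truth)
        assert res.tp == 1

    def test_multiple_predictions_count_one_tp(self):
        truth = {"f": [_truth(start=30, end=150)]}
        preds = [_pred(start=30, end=150), _pred(start=33, end=150, c5=True)]
        res = evaluate_gene_predictions(preds, truth)
        assert res.tp == 1
        assert res.sp == pytest.approx(100.0 * 1 / 2)

    def test_empty_truth_flagged(self):
        with pytest.raises(ValueError):
            evaluate_gene_predictions([_pred()], {"f": []})


class TestEvaluateTisAccuracy:
    def test_exact_internal_match(self):
        truth = {"f": [_truth(start=30, end=150)]}
        res = evaluate_tis_accuracy([_pred(tis=30)], truth)
        assert res.internal == 100.0 and res.total == 100.0

    def test_internal_off_by_21_incorrect(self):
        truth = {"f": [_truth(start=30, end=150)]}
        res = evaluate_tis_accuracy([_pred(tis=51)], truth)
        assert res.internal == 0.0

    def test_external_edge_sentinel_correct(self):
        truth = {"f": [_truth(start=0, end=300, c5=False, c3=False)]}
        pred = _pred(start=0, end=300, c5=False, c3=False, tis=EDGE)
        res = evaluate_tis_accuracy([pred], truth)
        assert res.external == 100.0 and res.n_internal == 0

    def test_external_positional_call_incorrect(self):
        truth = {"f": [_truth(start=0, end=300, c5=False, c3=False)]}
        pred = _pred(start=0, end=300, c5=False, c3=False, tis=12)
        res = evaluate_tis_accuracy([pred], truth)
        assert res.external == 0.0

    def test_reverse_strand_internal_match(self):
        truth = {"f": [_truth(strand="-", start=30, end=150)]}
        # oriented position of the '-' start codon base: flen-1 - (end-1)
        pred = _pred(strand="-", start=30, end=150, tis=300 - 1 - 149)
        res = evaluate_tis_accuracy([pred], truth)
        assert res.internal == 100.0


class TestTruthRoundTrip:
    def test_write_then_read(self, tmp_path):
        g = mg.generate_genome(length=20_000, genome_id="g", seed=12)
        _, truth = mg.sample_fragments(g, coverage=0.3, length_spec=870, seed=1)
        p = tmp_path / "truth.tsv"
        write_truth(truth, p)
        back = read_truth(p)
        nonempty = {k: v for k, v in truth.items() if v}
        assert {k: v for k, v in back.items()} == nonempty
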