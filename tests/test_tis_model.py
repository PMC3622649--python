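"""Three-class TIS model: training contracts, scoring, selection and
relocation, including the planted-SD-motif recovery benchmark."""

import numpy as np
import pytest

import metagun as mg
from metagun.io import SeqRecord
from metagun.orf import TisCandidate, extract_orfs
from metagun.simulator import _prediction_match
from metagun.tis_model import (
    EDGE,
    InsufficientDataError,
    TisParameterBank,
    TisScores,
    relocate_tis,
    score_tis_candidate,
    select_tis,
    tis_scores_for_features,
    train_tis_parameter_bank,
    train_tis_parameters,
)


@pytest.fixture(scope="module")
def sd_genome():
    return mg.generate_genome(
        length=50_000, genome_id="sdg", genus="SDgen", domain="Bacteria",
        sd_fraction=1.0, seed=31,
    )


@pytest.fixture(scope="module")
def sd_params(sd_genome):
    return train_tis_parameters(sd_genome)


class TestTraining:
    def test_determinism(self, sd_genome):
        a = train_tis_parameters(sd_genome)
        b = train_tis_parameters(sd_genome)
        assert np.array_equal(a.priors, b.priors)
        assert np.array_equal(a.codon_usage, b.codon_usage)
        for ta, tb in zip(a.tables, b.tables):
            for qa, qb in zip(ta, tb):
                assert np.array_equal(qa, qb)
        assert np.array_equal(a.pco_reference, b.pco_reference)

    def test_order_three_rejected(self, sd_genome):
        with pytest.raises(ValueError):
            train_tis_parameters(sd_genome, order=3)

    def test_insufficient_starts_rejected(self):
        g = mg.generate_genome(length=12_000, genome_id="tiny", seed=5)
        assert len(g.annotations) < 30
        with pytest.raises(InsufficientDataError):
            train_tis_parameters(g)

    def test_all_atg_genome_codon_usage(self):
        """A genome whose every gene starts with ATG trains to true-class
        start-codon usage ~ (1, 0, 0)."""
        rng = np.random.default_rng(8)
        g = mg.generate_genome(length=40_000, genome_id="atg", seed=77)
        # rewrite every annotated start codon to ATG on its own strand
        seq = list(g.sequence)
        for a in g.annotations:
            if a.strand == "+":
                seq[a.start : a.start + 3] = "ATG"
            else:
                seq[a.end - 3 : a.end] = list("CAT")
        g.sequence = "".join(seq)
        params = train_tis_parameters(g)
        assert params.codon_usage[0, 0] == pytest.approx(1.0, abs=1e-5)
        assert params.codon_usage[0, 1:].max() < 1e-5


class TestScoring:
    def test_triplet_sums_to_one(self, sd_params, sd_genome):
        frag = SeqRecord("f", sd_genome.sequence[1000:1870])
        for orf in extract_orfs(frag):
            for cand in orf.tis_candidates:
                sc = score_tis_candidate(sd_params, cand, frag, strand=orf.strand)
                if sc is not None:
                    assert sum(sc.as_tuple()) == pytest.approx(1.0, abs=1e-9)

    def test_candidate_with_nine_bp_upstream_skipped(self, sd_params):
        frag = SeqRecord("f", "C" * 9 + "ATG" + "CAC" * 30)
        cand = TisCandidate(position=9, codon="ATG", upstream_available=9)
        assert score_tis_candidate(sd_params, cand, frag) is None

    def test_sd_window_scores_as_true(self, sd_params, sd_genome):
        """The annotated start of an SD-led gene outscores Pnc/Pco."""
        ann = next(a for a in sd_genome.annotations if a.strand == "+" and a.start > 100)
        frag = SeqRecord("f", sd_genome.sequence[ann.start - 50 : ann.start + 100])
        cand = TisCandidate(position=50, codon=sd_genome.sequence[ann.start : ann.start + 3],
                            upstream_available=50)
        sc = score_tis_candidate(sd_params, cand, frag)
        assert sc.p_true > sc.p_upstream_false and sc.p_true > sc.p_downstream_false


class TestSelectTis:
    def _cand(self, pos):
        return TisCandidate(position=pos, codon="ATG", upstream_available=pos)

    def test_highest_pt_wins(self):
        scored = [
            (self._cand(0), TisScores(0.2, 0.5, 0.3)),
            (self._cand(30), TisScores(0.9, 0.05, 0.05)),
            (self._cand(60), TisScores(0.3, 0.4, 0.3)),
        ]
        assert select_tis(scored)[0].position == 30

    def test_tie_goes_to_five_prime_most(self):
        scored = [
            (self._cand(30), TisScores(0.5, 0.25, 0.25)),
            (self._cand(0), TisScores(0.5, 0.25, 0.25)),
        ]
        assert select_tis(scored)[0].position == 0

    def test_single_candidate(self):
        scored = [(self._cand(12), TisScores(0.1, 0.6, 0.3))]
        assert select_tis(scored)[0].position == 12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_tis([])


class TestScoresForFeatures:
    def test_absent_for_five_prime_incomplete(self, sd_params):
        frag = SeqRecord("f", "CAC" * 40)
        (orf,) = [o for o in extract_orfs(frag) if o.strand == "+" and o.frame == 0]
        assert not orf.complete5
        assert tis_scores_for_features(sd_params, orf, frag) is None

    def test_absent_when_all_candidates_lack_upstream(self, sd_params):
        frag = SeqRecord("f", "TAATAA" + "ATG" + "CAC" * 20 + "TAA" + "CAC" * 10)
        (orf,) = [o for o in extract_orfs(frag)
                  if o.strand == "+" and o.frame == 0 and o.complete5]
        assert [c.upstream_available for c in orf.tis_candidates] == [6]
        assert tis_scores_for_features(sd_params, orf, frag) is None


class TestRelocation:
    def test_no_candidates_gives_edge(self, sd_params):
        frag = SeqRecord("f", "CAC" * 40)
        (orf,) = [o for o in extract_orfs(frag) if o.strand == "+" and o.frame == 0]
        assert orf.tis_candidates == ()
        assert relocate_tis(orf, sd_params, frag) == EDGE

    def test_confidence_monotonicity(self, sd_params, sd_genome):
        """Raising the confidence level never reduces edge calls."""
        frags, _ = mg.sample_fragments(sd_genome, coverage=0.3, length_spec=535, seed=9)
        orfs = [
            (o, f) for f in frags for o in extract_orfs(f) if not o.complete5
        ]
        n_edge = {
            conf: sum(relocate_tis(o, sd_params, f, confidence=conf) == EDGE for o, f in orfs)
            for conf in (0.95, 0.99)
        }
        assert n_edge[0.99] >= n_edge[0.95]
        assert n_edge[0.95] > 0

    def test_determinism(self, sd_params, sd_genome):
        frags, _ = mg.sample_fragments(sd_genome, coverage=0.1, length_spec=870, seed=2)
        for f in frags:
            for o in extract_orfs(f):
                assert relocate_tis(o, sd_params, f) == relocate_tis(o, sd_params, f)


class TestSdRecoveryBenchmark:
    def test_internal_tis_recovery_beats_leftmost_baseline(self, sd_genome, sd_params):
        self_usage = lambda: sd_genome.codon_usage
        """With AGGAGG planted at -12..-7 of every true start, relocation
        recovers >= 90% of internal TISs of identified genes and strictly
        beats the 5'-most-candidate baseline."""
        # a fresh genome of the same genus family: parameters are selected
        # at genus level by binning, so the codon usage is shared while the
        # sequence itself is an independent realization
        test_genome = mg.generate_genome(
            length=50_000, genome_id="sdt", genus="SDtest", domain="Bacteria",
            sd_fraction=1.0, codon_usage=self_usage(), seed=32,
        )
        frags, truth = mg.sample_fragments(test_genome, coverage=3.0, length_spec=870, seed=4)
        n = ok = ok_leftmost = 0
        for f in frags:
            orfs = extract_orfs(f)
            for gene in truth[f.id]:
                if not gene.tis_internal:
                    continue
                match = None
                for o in orfs:

                    class P:
                        fragment_id = f.id
                        strand = o.strand
                        complete3 = o.complete3

                        def forward_interval(self, _o=o, _f=f):
                            return _o.forward_interval(len(_f))

                    if _prediction_match(P(), gene):
                        match = o
                        break
                if match is None or not match.tis_candidates:
                    continue
                n += 1
                truth_pos = (
                    gene.tis_forward
                    if match.strand == "+"
                    else len(f) - 1 - gene.tis_forward
                )
                r = relocate_tis(match, sd_params, f)
                ok += r != EDGE and r.position == truth_pos
                ok_leftmost += match.tis_candidates[0].position == truth_pos
        assert n > 100
        assert ok / n >= 0.90
        assert ok > ok_leftmost


class TestBankAndSerialization:
    def test_bank_pools_and_falls_back(self, sd_genome):
        bank = train_tis_parameter_bank([sd_genome])
        assert "SDgen" in bank.by_genus and "Bacteria" in bank.by_domain
        assert bank.lookup("SDgen", "Bacteria").genus_id == "SDgen"
        assert bank.lookup("Unknown", "Bacteria").genus_id == "Bacteria"
        assert bank.lookup(None, "Archaea") is None

    def test_json_round_trip(self, sd_genome, tmp_path):
        bank = train_tis_parameter_bank([sd_genome])
        p = tmp_path / "tis.json"
        bank.save(p)
        back = TisParameterBank.load(p)
        a, b = bank.by_genus["SDgen"], back.by_genus["SDgen"]
        frag = SeqRecord("f", sd_genome.sequence[500:1500])
        cand = TisCandidate(position=300, codon=sd_genome.sequence[800:803], upstream_available=300)
        if cand.codon in ("ATG", "GTG", "TTG"):
            sa = score_tis_candidate(a, cand, frag)
            sb = score_tis_candidate(b, cand, frag)
            assert sa.as_tuple() == pytest.approx(sb.as_tuple(), abs=1e-12)
        assert np.allclose(a.pco_reference, b.pco_reference)
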