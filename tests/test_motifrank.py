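"""PWM scanning, re-centering, recovery AUC and NES."""

import io

import numpy as np
import pytest

from regland.intervals import GenomicInterval
from regland.motifrank import (
    PWM,
    MotifHit,
    enrich,
    nes_scores,
    read_clusterbuster,
    read_jaspar,
    recenter_on_motif,
    recovery_auc,
    recovery_curve,
    scan_best_hit,
)
from regland.simgen import SimConfig, simulate_regions, simulate_sequences
from .conftest import decoy_pwm

RC = str.maketrans("ACGT", "TGCA")


class TestPWM:
    def test_rejects_non_probability_columns(self):
        with pytest.raises(ValueError):
            PWM("bad", np.ones((6, 4)))

    def test_jaspar_parsing(self):
        text = """>MA0000.1 test
A [ 10  0  0 ]
C [  0 10  0 ]
G [  0  0 10 ]
T [  0  0  0 ]
"""
        pwm = read_jaspar(io.StringIO(text))[0]
        assert pwm.length == 3
        assert pwm.consensus == "ACG"

    def test_clusterbuster_parsing(self):
        text = ">mot1\n10 0 0 0\n0 10 0 0\n0 0 0 10\n>mot2\n5 5 0 0\n0 0 5 5\n"
        pwms = read_clusterbuster(text.splitlines())
        assert [p.id for p in pwms] == ["mot1", "mot2"]
        assert pwms[0].consensus == "ACT"
        assert pwms[1].length == 2


class TestScan:
    def test_consensus_scores_closed_form(self, sharp_pwm, rng):
        cons = sharp_pwm.consensus
        bg = "".join(rng.choice(list("ACGT"), size=60))
        seq = bg[:10] + cons + bg[10:]
        hit = scan_best_hit(seq, sharp_pwm, threshold_bits=7.0)
        assert hit is not None and hit.offset == 10 and hit.strand == "+"
        lo = sharp_pwm.log_odds
        expected = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(cons))
        assert hit.score == pytest.approx(expected, abs=1e-9)

    def test_all_n_scores_zero_and_misses_threshold(self, sharp_pwm):
        assert scan_best_hit("N" * 40, sharp_pwm, threshold_bits=7.0) is None
        hit = scan_best_hit("N" * 40, sharp_pwm, threshold_bits=-1.0)
        assert hit is not None and hit.score == 0.0

    def test_reverse_complement_same_score_minus_strand(self, sharp_pwm, rng):
        bg = "".join(rng.choice(list("ACGT"), size=50))
        seq = bg[:15] + sharp_pwm.consensus + bg[15:]
        rc = seq.translate(RC)[::-1]
        fwd = scan_best_hit(seq, sharp_pwm, 7.0)
        rev = scan_best_hit(rc, sharp_pwm, 7.0)
        assert rev is not None
        assert rev.score == pytest.approx(fwd.score, abs=1e-9)
        assert rev.strand == "-"
        assert rev.offset == len(seq) - fwd.offset - sharp_pwm.length

    def test_short_sequence_returns_none(self, sharp_pwm):
        assert scan_best_hit("ACGT", sharp_pwm, 0.0) is None

    def test_strand_symmetry_of_best_score(self, sharp_pwm, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            a = scan_best_hit(seq, sharp_pwm, -np.inf)
            b = scan_best_hit(seq.translate(RC)[::-1], sharp_pwm, -np.inf)
            assert a.score == pytest.approx(b.score, abs=1e-9)


class TestRecenter:
    def test_window_arithmetic(self):
        regions = [GenomicInterval("chr1", 1000, 1500, name="r")]
        hits = [MotifHit("r", 240, "+", 10.0)]
        out = recenter_on_motif(regions, hits, window=250, motif_length=20)
        assert (out[0].start, out[0].end) == (1000, 1501)
        assert out[0].strand == "+"

    def test_minus_hit_orientation_kept(self):
        regions = [GenomicInterval("chr1", 1000, 1500, name="r")]
        out = recenter_on_motif(regions, [MotifHit("r", 100, "-", 9.0)], 50, 10)
        assert out[0].strand == "-"

    def test_region_without_hit_dropped(self):
        regions = [GenomicInterval("chr1", 0, 100, name="a"), GenomicInterval("chr1", 200, 300, name="b")]
        out = recenter_on_motif(regions, [MotifHit("a", 10, "+", 9.0)], 20, 10)
        assert [o.name for o in out] == ["a"]

    def test_clipping_warns(self):
        regions = [GenomicInterval("chr1", 0, 100, name="a")]
        with pytest.warns(UserWarning, match="clipped"):
            out = recenter_on_motif(regions, [MotifHit("a", 0, "+", 9.0)], 50, 10)
        assert out[0].start == 0


class TestRecovery:
    def test_toy_auc_top_ranks(self):
        ranking = [f"r{i}" for i in range(10)]
        assert recovery_auc(ranking, {"r0", "r1"}, 5) == pytest.approx(0.9)

    def test_input_below_threshold_gives_zero(self):
        ranking = [f"r{i}" for i in range(10)]
        assert recovery_auc(ranking, {"r8", "r9"}, 5) == 0.0

    def test_toy_auc_late_ranks(self):
        ranking = [f"r{i}" for i in range(10)]
        assert recovery_auc(ranking, {"r3", "r4"}, 5) == pytest.approx(0.3)

    def test_matches_brute_force_definition(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            ranking = [f"r{i}" for i in rng.permutation(n)]
            k = int(rng.integers(1, n // 2 + 1))
            input_set = set(rng.choice(ranking, size=k, replace=False))
            T = int(rng.integers(1, n + 1))
            brute = np.mean([
                sum(rid in input_set for rid in ranking[:i]) / k
                for i in range(1, T + 1)
            ])
            assert recovery_auc(ranking, input_set, T) == pytest.approx(brute)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            recovery_auc(["a"], set(), 1)


class TestNES:
    def test_mean_auc_maps_to_zero(self):
        nes = nes_scores({"a": 0.1, "b": 0.2, "c": 0.3})
        assert nes["b"] == pytest.approx(0.0)

    def test_hand_computed_population_z(self):
        nes = nes_scores({"a": 0.1, "b": 0.2, "c": 0.3})
        assert nes["c"] == pytest.approx(1.2247, abs=1e-4)

    def test_location_invariance(self, rng):
        aucs = {f"m{i}": float(rng.uniform(0, 0.5)) for i in range(10)}
        shifted = {k: v + 0.17 for k, v in aucs.items()}
        a, b = nes_scores(aucs), nes_scores(shifted)
        for k in aucs:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nes_scores({"a": 0.2, "b": 0.2, "c": 0.2})


class TestEnrich:
    @pytest.fixture(scope="class")
    def planted_study(self, sharp_pwm):
        """1000-region database; 100-region input of which 80 carry the
        planted motif; 19 shuffled decoys compete."""
        from regland.motifrank import rank_database

        cfg = SimConfig(seed=9, n_regions=1000, chrom_length=300_000)
        regions = simulate_regions(cfg)
        bearing = {r.name for r in regions[:80]}
        seqs, truth = simulate_sequences(cfg, sharp_pwm, bearing, regions=regions)
        pwms = [sharp_pwm] + [decoy_pwm(sharp_pwm, k) for k in range(19)]
        rankings = {p.id: rank_database(seqs, p) for p in pwms}
        input_ids = [r.name for r in regions[:100]]
        return regions, truth, rankings, input_ids

    def test_planted_motif_ranks_first_above_cutoff(self, planted_study, sharp_pwm):
        _, _, rankings, input_ids = planted_study
        results = enrich(input_ids, rankings, rank_threshold=100, nes_cutoff=2.5)
        assert results[0].motif == sharp_pwm.id
        assert results[0].nes > 2.5

    def test_candidate_targets_recover_planted_regions(self, planted_study, sharp_pwm):
        _, truth, rankings, input_ids = planted_study
        results = enrich(input_ids, rankings, rank_threshold=100, nes_cutoff=2.5)
        top = next(r for r in results if r.motif == sharp_pwm.id)
        planted = set(truth.motif_bearing) & set(input_ids)
        assert len(set(top.targets) & planted) >= 0.9 * len(planted)

    def test_random_input_rarely_clears_cutoff(self, planted_study):
        regions, _, rankings, _ = planted_study
        all_ids = [r.name for r in regions]
        r = np.random.default_rng(7)
        exceed = 0
        for _ in range(50):
            ids = set(r.choice(all_ids, size=100, replace=False))
            nes = nes_scores({m: recovery_auc(rk, ids, 100) for m, rk in rankings.items()})
            if max(nes.values()) > 2.5:
                exceed += 1
        assert exceed <= 5  # at most 10% of null trials

    def test_best_motif_per_tf_kept(self, planted_study):
        _, _, rankings, input_ids = planted_study
        tf_of = {m: "TF1" for m in rankings}
        results = enrich(input_ids, rankings, rank_threshold=100, tf_of=tf_of)
        assert len(results) == 1
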