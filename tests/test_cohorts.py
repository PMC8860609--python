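"""Cohort construction: context, uORF distance, folding, codons, motifs."""

import numpy as np
import pytest

from tcpscan import cohorts, features
from tcpscan.cohorts import (
    AnchorGroup,
    group_by_context,
    group_by_downstream_folding,
    group_by_stop_distance,
    group_codon_anchors,
    group_main_starts,
    group_motif_windows,
    run_cohort,
    stop_distance,
)
from tcpscan.features import ContextPSSM, MotifPSSM
from tcpscan.folding import ConstantBackend, GCProxyBackend
from tcpscan.profiles import TranscriptAnnotation


def _gene(gid, utr, cds="ATG" + "C" * 87, mrna=1.0):
    return TranscriptAnnotation(gid, utr, cds, mrna)


def _pssm_favoring_A():
    probs = np.full((9, 4), 0.1)
    probs[:, 0] = 0.7
    return ContextPSSM(probs)


class TestContextGroups:
    def test_planted_classes_recovered_exactly(self):
        # one uAUG per gene, AUG-free elsewhere; q = 0.5 partitions all
        genes = []
        for i in range(15):   # high class: A-rich flanks
            utr = "C" * 10 + "AAAAAA" + "ATG" + "AAA" + "C" * 10
            genes.append(_gene(f"hi{i:02d}", utr))
        for i in range(15):   # low class: C-rich flanks
            utr = "C" * 10 + "CCCCCC" + "ATG" + "CCC" + "C" * 10
            genes.append(_gene(f"lo{i:02d}", utr))
        hi, lo = group_by_context(genes, _pssm_favoring_A(), q=0.5)
        assert {g for g, _ in hi.anchors} == {f"hi{i:02d}" for i in range(15)}
        assert {g for g, _ in lo.anchors} == {f"lo{i:02d}" for i in range(15)}

    def test_half_quantile_partitions_with_ties_high(self):
        genes = [_gene(f"g{i}", "C" * 8 + "ATG" + "C" * 10) for i in range(5)]
        hi, lo = group_by_context(genes, _pssm_favoring_A(), q=0.5)
        assert len(hi) + len(lo) == 5
        assert len(hi) == 3 and len(lo) == 2

    def test_isolation_removes_clustered_augs(self):
        utr = "C" * 10 + "ATG" + "CC" + "ATG" + "C" * 30   # gap < 50
        genes = [_gene("g", utr)]
        genes += [_gene(f"f{i}", "C" * 20 + "ATG" + "C" * 40) for i in range(3)]
        hi, lo = group_by_context(genes, _pssm_favoring_A(), q=0.5,
                                  isolation=True)
        kept = {g for g, _ in hi.anchors} | {g for g, _ in lo.anchors}
        assert "g" not in kept

    def test_no_uaugs_raises(self):
        genes = [_gene("g", "C" * 30)]
        with pytest.raises(ValueError):
            group_by_context(genes, _pssm_favoring_A())


class TestMainStarts:
    def test_sample_size_equal_to_population(self):
        genes = [_gene(f"g{i}", "C" * 20) for i in range(10)]
        grp = group_main_starts(genes, sample_size=10, seed=0)
        assert len(grp) == 10
        assert all(pos == 20 for _, pos in grp.anchors)

    def test_seeding(self):
        genes = [_gene(f"g{i}", "C" * 20) for i in range(30)]
        a = group_main_starts(genes, sample_size=10, seed=1)
        b = group_main_starts(genes, sample_size=10, seed=1)
        c = group_main_starts(genes, sample_size=10, seed=2)
        assert a.anchors == b.anchors
        assert a.anchors != c.anchors

    def test_oversized_sample_uses_all(self):
        genes = [_gene(f"g{i}", "C" * 20) for i in range(5)]
        grp = group_main_starts(genes, sample_size=50, seed=0)
        assert len(grp) == 5


class TestStopDistance:
    def test_adjacent_stop_frame0(self):
        g = _gene("g", "CC" + "ATG" + "TAA" + "C" * 20)
        assert stop_distance(g, 2, frame=0) == 3

    def test_frame_shifts_by_direct_scan(self):
        g = _gene("g", "C" + "ATGAAATAA" + "C" * 30)
        assert stop_distance(g, 1, frame=0) == 6
        # frame 1: codons at positions p+4, p+7, ... - scan directly
        t = g.transcript
        expected = None
        for s in range(1 + 4, len(t) - 2, 3):
            if t[s : s + 3] in cohorts.STOP_CODONS:
                expected = s - 1
                break
        assert stop_distance(g, 1, frame=1) == expected

    def test_no_stop_returns_none(self):
        g = _gene("g", "CC" + "ATG" + "C" * 10, cds="ATG" + "C" * 87)
        assert stop_distance(g, 2, frame=0) is None

    def test_planted_uorf_lengths_recovered(self):
        # short uORFs: stop right after the AUG; long: stop ~90 nt away
        genes = []
        for i in range(10):
            genes.append(_gene(f"s{i}", "C" * 10 + "ATGTAA" + "C" * 100))
        for i in range(10):
            genes.append(_gene(f"l{i}", "C" * 10 + "ATG" + "CAC" * 30 + "TAA" + "C" * 10))
        short, long_ = group_by_stop_distance(genes, q=0.5, frame=0)
        assert {g for g, _ in short.anchors} == {f"s{i}" for i in range(10)}
        assert {g for g, _ in long_.anchors} == {f"l{i}" for i in range(10)}

    def test_consistency_identity_across_frames(self):
        # distance in frame k equals frame-0 distance on the k-shifted lattice
        rng = np.random.default_rng(0)
        utr = "C" * 5 + "ATG" + "".join(rng.choice(list("ACGT"), size=120))
        g = _gene("g", utr)
        for k in (1, 2):
            d = stop_distance(g, 5, frame=k)
            t = g.transcript
            manual = None
            for s in range(5 + 3 + k, len(t) - 2, 3):
                if t[s : s + 3] in cohorts.STOP_CODONS:
                    manual = s - 5
                    break
            assert d == manual


class TestDownstreamFolding:
    def test_constant_backend_flagged_degenerate(self):
        genes = [_gene(f"g{i}", "C" * 10 + "ATG" + "C" * 60) for i in range(6)]
        stable, unstable = group_by_downstream_folding(
            genes, ConstantBackend(-1.0), q=0.5)
        assert stable.metadata["degenerate"]

    def test_gc_rich_downstream_lands_in_stable_group(self):
        lo_gc = _gene("weak", "T" * 10 + "ATG" + "AT" * 30 + "T" * 10)
        hi_gc = _gene("strong", "T" * 10 + "ATG" + "GC" * 30 + "T" * 10)
        stable, unstable = group_by_downstream_folding(
            [lo_gc, hi_gc], GCProxyBackend(0.1), q=0.5)
        assert ("strong", 10) in stable.anchors
        assert ("weak", 10) in unstable.anchors

    def test_mean_over_windows_matches_enumeration(self):
        # AUG-free downstream alphabet so the gene holds exactly one uAUG
        rng = np.random.default_rng(1)
        down = "".join(rng.choice(list("ACG"), size=80))
        g = _gene("g", "T" * 8 + "ATG" + down)
        backend = GCProxyBackend(0.1)
        stable, unstable = group_by_downstream_folding([g], backend, q=0.5)
        t = g.transcript
        expected = np.mean(
            [backend.mfe(t[8 + 3 + j : 8 + 3 + j + 30]) for j in range(1, 21)])
        assert stable.metadata["mean_energy"][("g", 8)] == pytest.approx(
            expected, abs=1e-12)


class TestCodonAnchors:
    def test_aug_codon_equals_uaug_scan(self):
        genes = [_gene("g", "CCATGCCATGCC")]
        grp = group_codon_anchors(genes, "AUG")
        assert grp.anchors == [("g", 2), ("g", 7)]

    def test_tandem_codons(self):
        genes = [_gene("g", "CTGCTGAAAA")]
        grp = group_codon_anchors(genes, "CUG")
        assert grp.anchors == [("g", 0), ("g", 3)]

    def test_all_codons_match_string_search(self, small_dataset):
        ann, _, _ = small_dataset
        ann = ann[:10]
        import itertools
        for codon in ["".join(c) for c in itertools.product("ACGT", repeat=3)][:16]:
            grp = group_codon_anchors(ann, codon)
            expected = []
            for a in ann:
                expected += [(a.gene_id, p) for p in range(a.utr5_len - 2)
                             if a.transcript[p : p + 3] == codon]
            assert grp.anchors == expected


class TestMotifWindows:
    def test_planted_motif_recovered_in_high_group(self):
        rng = np.random.default_rng(2)
        motif_seq = "TGACGCAA"
        probs = np.full((8, 4), 0.04)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i, b in enumerate(motif_seq):
            probs[i, idx[b]] = 0.88
        motif = MotifPSSM("cebp", probs / probs.sum(axis=1, keepdims=True))
        genes = []
        planted = []
        for i in range(30):
            utr = list("".join(rng.choice(list("ACGT"), size=60)))
            s = int(rng.integers(0, 50))
            utr[s : s + 8] = list(motif_seq)
            genes.append(_gene(f"g{i:02d}", "".join(utr)))
            planted.append((f"g{i:02d}", s))
        hi, lo = group_motif_windows(genes, motif, q=0.02)
        hits = sum(site in hi.anchors for site in planted)
        assert hits / len(planted) >= 0.95

    def test_uniform_pssm_degenerate(self):
        motif = MotifPSSM("u", np.full((4, 4), 0.25))
        genes = [_gene("g", "ACGT" * 10)]
        hi, lo = group_motif_windows(genes, motif, q=0.5)
        assert hi.metadata["degenerate"]

    def test_group_sizes_near_quantile(self):
        rng = np.random.default_rng(3)
        motif = MotifPSSM("m", rng.dirichlet(np.ones(4), size=5))
        genes = [_gene(f"g{i}", "".join(rng.choice(list("ACGT"), size=100)))
                 for i in range(20)]
        q = 0.05
        hi, lo = group_motif_windows(genes, motif, q=q)
        N = hi.metadata["n_scored"]
        assert abs(len(lo) - int(np.floor(q * N))) <= 1
        assert abs(len(hi) - int(np.floor(q * N))) <= 1


class TestRunCohort:
    def test_identical_groups_identical_rows(self, small_profiles):
        genes = sorted(small_profiles)[:15]
        anchors = [(g, 10) for g in genes]
        a = AnchorGroup("a", anchors)
        b = AnchorGroup("b", list(anchors))
        df = run_cohort([a, b], small_profiles, mode="mean")
        assert df.loc[0, "mic"] == df.loc[1, "mic"]
        assert df.loc[0, "n_points"] == df.loc[1, "n_points"]

    def test_empty_group_flagged_not_dropped(self, small_profiles):
        genes = sorted(small_profiles)[:10]
        a = AnchorGroup("a", [(g, 10) for g in genes])
        empty = AnchorGroup("none", [])
        df = run_cohort([a, empty], small_profiles, mode="mean")
        assert list(df["label"]) == ["a", "none"]
        assert np.isnan(df.loc[1, "mic"])

    def test_report_schema(self, small_profiles):
        genes = sorted(small_profiles)[:10]
        df = run_cohort([AnchorGroup("a", [(g, 5) for g in genes])],
                        small_profiles, mode="mean")
        assert list(df.columns) == cohorts.REPORT_COLUMNS

    def test_equalization_aligns_point_counts(self, small_profiles):
        genes = sorted(small_profiles)
        a = AnchorGroup("a", [(g, 10) for g in genes[:20]])
        b = AnchorGroup("b", [(g, 30) for g in genes[:8]])
        df = run_cohort([a, b], small_profiles, mode="mean")
        assert df["n_points"].max() <= df["n_points"].min() + df["n_points"].min() * 0.05 + 5
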