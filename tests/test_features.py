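"""Feature engine: PSSMs, context scores, folding, composition, motifs."""

import itertools
import math

import numpy as np
import pytest

from tcpscan import features
from tcpscan.features import (
    ContextPSSM,
    MotifPSSM,
    aug_features,
    assemble_feature_table,
    build_context_pssm,
    composition_features,
    context_score,
    feature_registry,
    folding_features,
    motif_score,
    read_homer_motifs,
)
from tcpscan.profiles import TranscriptAnnotation


def _gene(gid, utr, cds, mrna=1.0):
    return TranscriptAnnotation(gid, utr, cds, mrna_level=mrna)


class TestContextPssm:
    def _identical_context_genes(self, n):
        # context AAAAAA|AUG|AAA for every gene
        return [_gene(f"g{i}", "CCCCCC" + "AAAAAA", "ATG" + "AAA" + "C" * 24,
                      mrna=float(i + 1)) for i in range(n)]

    def test_identical_contexts_give_smoothing_formula(self):
        n = 30
        pssm = build_context_pssm(self._identical_context_genes(n),
                                  top_fraction=1.0, pseudocount=1.0)
        # every position observed 'A' n times: p(A) = (n+1)/(n+4)
        assert pssm.probs[:, 0] == pytest.approx(np.full(9, (n + 1) / (n + 4)))
        assert pssm.probs[:, 1] == pytest.approx(np.full(9, 1 / (n + 4)))

    def test_two_contexts_split_position(self):
        genes = []
        for i in range(20):
            up = "AAAAAA" if i % 2 == 0 else "CAAAAA"   # differ at position -6
            genes.append(_gene(f"g{i}", "TTTTTT" + up, "ATGAAA" + "C" * 24,
                               mrna=1.0))
        pssm = build_context_pssm(genes, top_fraction=1.0, pseudocount=1.0)
        # direct tally: 10 A, 10 C (+1 each) at position 0
        assert pssm.probs[0, 0] == pytest.approx(11 / 24)
        assert pssm.probs[0, 1] == pytest.approx(11 / 24)
        assert pssm.probs.sum(axis=1) == pytest.approx(np.ones(9))

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            build_context_pssm(self._identical_context_genes(5))

    def test_deterministic_tie_break_by_gene_id(self):
        genes = self._identical_context_genes(25)
        for g in genes:
            g.mrna_level = 2.0
        a = build_context_pssm(genes, top_fraction=0.2)
        b = build_context_pssm(list(reversed(genes)), top_fraction=0.2)
        assert np.array_equal(a.probs, b.probs)


class TestContextScore:
    def test_fully_missing_context_is_nine_log_quarter(self, uniform_pssm):
        assert context_score("NNNNNNNNN", uniform_pssm) == pytest.approx(
            9 * math.log(0.25), abs=1e-12)

    def test_degenerate_pssm_scores_zero(self):
        probs = np.full((9, 4), 1e-9)
        probs[:, 0] = 1 - 3e-9
        pssm = ContextPSSM(probs / probs.sum(axis=1, keepdims=True))
        assert context_score("AAAAAAAAA", pssm) == pytest.approx(0.0, abs=1e-6)

    def test_matches_manual_log_sum(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=9)
        pssm = ContextPSSM(probs)
        ctx = "ACGTACGTA"
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = sum(math.log(probs[i, idx[b]]) for i, b in enumerate(ctx))
        assert context_score(ctx, pssm) == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_characters(self, uniform_pssm):
        with pytest.raises(ValueError):
            context_score("AXGTACGTA", uniform_pssm)


class TestAugFeatures:
    def test_window_without_aug_gets_sentinels(self, uniform_pssm):
        g = _gene("g", "C" * 40, "ATG" + "C" * 27)
        out = aug_features(g, 0, uniform_pssm)
        assert out["n_aug"] == 0 and out["has_aug"] == 0
        assert out["mean_dist_to_main_aug"] == features.DIST_SENTINEL
        assert out["mean_cs"] == uniform_pssm.score_sentinel

    def test_counts_multiple_augs(self, uniform_pssm):
        g = _gene("g", "CCCATGCCCCCCATGCCCCCCCCCCCCCCCCCCCCCCCC", "ATG" + "A" * 27)
        out = aug_features(g, 0, uniform_pssm)
        assert out["n_aug"] == 2 and out["has_aug"] == 1

    def test_planted_distance_recovered(self, uniform_pssm):
        utr = "C" * 40
        d = 25  # uAUG first nt is d upstream of the main AUG
        utr = utr[: 40 - d] + "ATG" + utr[40 - d + 3 :]
        g = _gene("g", utr, "ATG" + "A" * 27)
        # window [10, 40) holds the planted uAUG but not the main start
        out = aug_features(g, 10, uniform_pssm)
        assert out["mean_dist_to_main_aug"] == d


class TestFoldingFeatures:
    def test_constant_backend_gives_constant_features(self, ):
        from tcpscan.folding import ConstantBackend
        out = folding_features("A" * 100, 10, ConstantBackend(-3.0))
        assert all(v == -3.0 for v in out.values())

    def test_pairing_free_sequence_scores_zero(self, nussinov_backend):
        out = folding_features("A" * 100, 0, nussinov_backend)
        assert all(v == 0.0 for v in out.values())

    def test_matches_brute_force_enumeration(self, gc_backend):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=70))
        out = folding_features(seq, 0, gc_backend)
        fe = [gc_backend.mfe(seq[o : o + 30]) for o in range(31)
              if o + 30 <= len(seq)]
        assert out["fe_pos1"] == fe[0]
        assert out["fe_pos31"] == fe[30]
        assert out["fe_mean_1_30"] == pytest.approx(np.mean(fe[0:30]))
        assert out["fe_min_1_30"] == min(fe[0:30])
        assert out["fe_mean_15_30"] == pytest.approx(np.mean(fe[14:30]))
        assert out["fe_min_20_30"] == min(fe[19:30])

    def test_no_window_at_offset_zero_raises(self, gc_backend):
        with pytest.raises(ValueError):
            folding_features("ACGT", 0, gc_backend)


class TestComposition:
    def test_homopolymer(self):
        out = composition_features("G" * 30)
        assert out["gc"] == 1.0
        assert out["mono_G"] == 1.0
        assert out["di_GG"] == 1.0
        assert out["tri_GGG"] == 1.0

    def test_alternating_dinucleotides(self):
        out = composition_features("AC" * 15)
        assert out["di_AC"] == pytest.approx(15 / 29)
        assert out["di_CA"] == pytest.approx(14 / 29)

    def test_blocks_sum_to_one_and_match_nested_loop(self):
        rng = np.random.default_rng(2)
        w = "".join(rng.choice(list("ACGT"), size=30))
        out = composition_features(w)
        for prefix, k in [("mono_", 1), ("di_", 2), ("tri_", 3)]:
            block = {n: v for n, v in out.items() if n.startswith(prefix)}
            assert sum(block.values()) == pytest.approx(1.0, abs=1e-9)
            for kmer in map("".join, itertools.product("ACGT", repeat=k)):
                count = sum(w[i : i + k] == kmer for i in range(30 - k + 1))
                assert block[prefix + kmer] == pytest.approx(count / (31 - k))


class TestMotifScore:
    def test_full_width_motif_single_offset(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(4), size=30)
        m = MotifPSSM("m", probs)
        w = "".join(rng.choice(list("ACGT"), size=30))
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = sum(math.log(probs[i, idx[b]]) for i, b in enumerate(w))
        assert motif_score(w, m) == pytest.approx(expected, abs=1e-12)

    def test_uniform_motif_is_sequence_independent(self):
        m = MotifPSSM("u", np.full((8, 4), 0.25))
        assert motif_score("ACGTACGTACGTACGTACGTACGTACGTAC", m) == pytest.approx(
            8 * math.log(0.25))

    def test_max_contract_vs_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for _ in range(25):
            probs = rng.dirichlet(np.ones(4), size=4)
            m = MotifPSSM("m", probs)
            w = "".join(rng.choice(list("ACGT"), size=30))
            scores = [
                sum(math.log(probs[i, idx[w[o + i]]]) for i in range(4))
                for o in range(27)
            ]
            assert motif_score(w, m) == pytest.approx(max(scores), abs=1e-12)
            assert all(motif_score(w, m) >= s - 1e-12 for s in scores)

    def test_too_wide_motif_rejected(self):
        m = MotifPSSM("m", np.full((30, 4), 0.25))
        with pytest.raises(ValueError):
            motif_score("ACGT", m)


class TestHomerFormat:
    def test_parse_and_floor(self, tmp_path):
        path = tmp_path / "motifs.txt"
        path.write_text(
            ">ACGTACGTAC\tmotif-1\t6.5\n"
            + "\n".join(["0.97\t0.01\t0.01\t0.01"] * 5)
            + "\n1\t0\t0\t0\n"
            + ">GG\tmotif-2\t3.2\n0.1 0.1 0.7 0.1\n0.2 0.2 0.4 0.2\n"
        )
        motifs = read_homer_motifs(path)
        assert [m.name for m in motifs] == ["motif-1", "motif-2"]
        assert motifs[0].width == 6
        # already-normalized row kept, hard zeros floored
        assert motifs[0].probs[0] == pytest.approx([0.97, 0.01, 0.01, 0.01])
        assert (motifs[0].probs[5] > 0).all()
        assert motifs[0].probs[5].sum() == pytest.approx(1.0)

    def test_wrong_arity_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(">AC\tm\t1.0\n0.5 0.5\n")
        with pytest.raises(ValueError, match="2"):
            read_homer_motifs(path)


class TestAssembly:
    def test_registry_arithmetic(self):
        assert len(feature_registry([])) == 102
        fake = [MotifPSSM(f"m{i}", np.full((4, 4), 0.25)) for i in range(293)]
        assert len(feature_registry(fake)) == 395

    def test_table_has_no_unexpected_missing_values(self, gc_backend, uniform_pssm):
        g = _gene("g", "ACGTACGTAC" * 4, "ATG" + "ACGTAC" * 12)
        windows = [("g", s) for s in range(5)]
        table = assemble_feature_table(windows, [g], uniform_pssm, [], gc_backend)
        assert table.shape == (5, 102)
        assert not table.isna().any().any()

    def test_recomputation_is_bit_identical(self, gc_backend, uniform_pssm):
        g = _gene("g", "ACGTACGTAC" * 4, "ATG" + "ACGTAC" * 12)
        windows = [("g", s) for s in range(3)]
        a = assemble_feature_table(windows, [g], uniform_pssm, [], gc_backend)
        b = assemble_feature_table(windows, [g], uniform_pssm, [], gc_backend)
        assert a.equals(b)
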