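"""Two-stage pipeline post-processing: triplets, cis/trans, merging, hotspots."""

import numpy as np
import pandas as pd
import pytest

from structmap.datatypes import CoefficientMatrix, Hyperparams
from structmap.networks import TraitNetwork
from structmap.threeway import (
    assemble_triplets,
    classify_cis_trans,
    detect_hotspots,
    merge_nearby_snps,
    run_two_stage,
)


def coeffs(B, row_prefix="snp", col_prefix="gene"):
    J, K = B.shape
    return CoefficientMatrix.from_dense(
        B, [f"{row_prefix}{j}" for j in range(J)],
        [f"{col_prefix}{k}" for k in range(K)]
    )


def random_maps(rng, snp_ids, gene_ids, n_chrom=3, span=50_000_000):
    snp_map = pd.DataFrame({
        "chromosome": rng.choice([str(c) for c in range(1, n_chrom + 1)],
                                 size=len(snp_ids)),
        "position": rng.integers(1, span, size=len(snp_ids)),
    }, index=pd.Index(snp_ids, name="snp_id"))
    gene_map = pd.DataFrame({
        "chromosome": rng.choice([str(c) for c in range(1, n_chrom + 1)],
                                 size=len(gene_ids)),
        "tx_start": rng.integers(1, span, size=len(gene_ids)),
    }, index=pd.Index(gene_ids, name="trait_id"))
    return snp_map, gene_map


class TestTriplets:
    def test_single_chain_single_triplet(self):
        B = np.zeros((3, 4))
        B[1, 2] = 0.5
        A = np.zeros((4, 2))
        A[2, 0] = -0.3
        ts = assemble_triplets(coeffs(B), coeffs(A, "gene", "trait"))
        assert len(ts) == 1
        rec = ts.records.iloc[0]
        assert (rec.snp_id, rec.gene_id, rec.trait_id) == ("snp1", "gene2", "trait0")
        assert rec.beta_sg == 0.5 and rec.beta_gt == -0.3

    def test_empty_b_empty_triplets(self):
        ts = assemble_triplets(coeffs(np.zeros((3, 4))),
                               coeffs(np.ones((4, 2)), "gene", "trait"))
        assert len(ts) == 0

    def test_count_is_support_product(self, rng):
        B = (rng.random((6, 5)) < 0.3) * rng.normal(size=(6, 5))
        A = (rng.random((5, 4)) < 0.3) * rng.normal(size=(5, 4))
        ts = assemble_triplets(coeffs(B), coeffs(A, "gene", "trait"))
        expect = sum(int((B[:, m] != 0).sum()) * int((A[m] != 0).sum())
                     for m in range(5))
        assert len(ts) == expect


class TestCisTrans:
    def test_window_boundary(self):
        B = np.zeros((2, 1))
        B[0, 0] = 1.0
        B[1, 0] = 1.0
        snp_map = pd.DataFrame({"chromosome": ["1", "1"],
                                "position": [10_000_000, 21_000_000]},
                               index=pd.Index(["snp0", "snp1"], name="snp_id"))
        gene_map = pd.DataFrame({"chromosome": ["1"], "tx_start": [19_999_999]},
                                index=pd.Index(["gene0"], name="trait_id"))
        out = classify_cis_trans(coeffs(B), snp_map, gene_map)
        # 9,999,999 bp away -> cis ; 1,000,001 bp away -> cis too;
        by_snp = dict(zip(out.snp_id, out.label))
        assert by_snp["snp0"] == "cis"  # distance 9,999,999 <= 10 Mb
        assert by_snp["snp1"] == "cis"

    def test_different_chromosomes_always_trans(self):
        B = np.ones((1, 1))
        snp_map = pd.DataFrame({"chromosome": ["2"], "position": [5]},
                               index=pd.Index(["snp0"], name="snp_id"))
        gene_map = pd.DataFrame({"chromosome": ["1"], "tx_start": [5]},
                                index=pd.Index(["gene0"], name="trait_id"))
        out = classify_cis_trans(coeffs(B), snp_map, gene_map)
        assert out.label.iloc[0] == "trans"

    def test_unmapped_id_labeled_unknown(self, rng):
        B = np.ones((2, 1))
        snp_map = pd.DataFrame({"chromosome": ["1"], "position": [100]},
                               index=pd.Index(["snp0"], name="snp_id"))
        gene_map = pd.DataFrame({"chromosome": ["1"], "tx_start": [100]},
                                index=pd.Index(["gene0"], name="trait_id"))
        with pytest.warns(UserWarning, match="unmapped"):
            out = classify_cis_trans(coeffs(B), snp_map, gene_map)
        assert set(out.label) == {"cis", "unknown"}

    def test_matches_brute_force_on_random_maps(self, rng):
        for _ in range(20):
            J, K = 12, 6
            B = (rng.random((J, K)) < 0.4) * 1.0
            snp_map, gene_map = random_maps(rng, [f"snp{j}" for j in range(J)],
                                            [f"gene{k}" for k in range(K)])
            out = classify_cis_trans(coeffs(B), snp_map, gene_map)
            for rec in out.itertuples(index=False):
                s, g = snp_map.loc[rec.snp_id], gene_map.loc[rec.gene_id]
                expect = ("cis" if s.chromosome == g.chromosome
                          and abs(int(s.position) - int(g.tx_start)) <= 10_000_000
                          else "trans")
                assert rec.label == expect


class TestMergeNearbySnps:
    def _map(self, positions, chrom="1"):
        return pd.DataFrame(
            {"chromosome": [chrom] * len(positions), "position": positions},
            index=pd.Index([f"snp{j}" for j in range(len(positions))],
                           name="snp_id"))

    def test_one_mb_apart_merge(self):
        B = np.array([[0.5], [0.9]])
        out = merge_nearby_snps(coeffs(B), self._map([1_000_000, 2_000_000]))
        assert len(out) == 1
        assert out.iloc[0].snp_id == "snp1"  # strongest |beta| representative
        assert out.iloc[0].n_snps_merged == 2

    def test_three_mb_apart_stay_separate(self):
        B = np.array([[0.5], [0.9]])
        out = merge_nearby_snps(coeffs(B), self._map([1_000_000, 4_000_001]))
        assert len(out) == 2

    def test_matches_brute_force_chaining(self, rng):
        for _ in range(20):
            J = 15
            B = (rng.random((J, 3)) < 0.5) * rng.normal(size=(J, 3))
            positions = np.sort(rng.integers(1, 30_000_000, size=J))
            snp_map = self._map(positions.tolist())
            out = merge_nearby_snps(coeffs(B), snp_map)
            for k in range(3):
                sel = np.nonzero(B[:, k])[0]
                if len(sel) == 0:
                    continue
                # brute-force single-linkage chains
                chains = 1
                pos = positions[sel]
                for a, b in zip(pos, pos[1:]):
                    if b - a > 2_000_000:
                        chains += 1
                got = out[out.gene_id == f"gene{k}"]
                assert len(got) == chains
                assert got.n_snps_merged.sum() == len(sel)


class TestHotspots:
    def test_row_above_threshold_flagged(self):
        B = np.zeros((3, 30))
        B[1, :25] = 1.0
        rep = detect_hotspots(coeffs(B), min_genes=20)
        assert rep.hotspots == ["snp1"]
        assert rep.gene_counts["snp1"] == 25

    def test_empty_matrix_no_hotspots(self):
        rep = detect_hotspots(coeffs(np.zeros((4, 25))))
        assert rep.hotspots == []

    def test_threshold_is_strict(self):
        B = np.zeros((1, 25))
        B[0, :20] = 1.0
        assert detect_hotspots(coeffs(B), min_genes=20).hotspots == []


class TestRunTwoStage:
    def test_wires_stages_and_assembles(self, rng):
        from structmap.preprocess import standardize

        n = 60
        X, _ = standardize((rng.random((n, 5)) < 0.5) * 1.0)
        Y = np.column_stack([X[:, 1] * 1.5 + 0.2 * rng.normal(size=n),
                             rng.normal(size=n)])
        Ys, _ = standardize(Y)
        Z = (Ys[:, 0] * 1.2 + 0.2 * rng.normal(size=n))[:, None]
        Zs, _ = standardize(Z)
        gn = TraitNetwork.from_edges(["gene0", "gene1"], [])
        tn = TraitNetwork.from_edges(["trait0"], [])
        hyper = Hyperparams(lam=3.0, gamma=0.0, tol=1e-8)
        B, A, triplets = run_two_stage(X, Ys, Zs, gn, tn, hyper,
                                       snp_ids=[f"snp{j}" for j in range(5)],
                                       gene_ids=["gene0", "gene1"],
                                       trait_ids=["trait0"])
        assert B.toarray()[1, 0] != 0
        assert A.toarray()[0, 0] != 0
        recs = triplets.records
        assert (("snp1", "gene0", "trait0") in
                set(zip(recs.snp_id, recs.gene_id, recs.trait_id)))

    def test_sample_mismatch_rejected(self, rng):
        gn = TraitNetwork.from_edges(["g"], [])
        with pytest.raises(ValueError, match="sample"):
            run_two_stage(np.zeros((5, 2)), np.zeros((5, 1)), np.zeros((4, 1)),
                          gn, gn, Hyperparams())
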