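import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wprskit.datatypes import MISSING, GenotypeMatrix
from wprskit.qc import (
    GenotypePCA,
    QCThresholds,
    apply_qc,
    call_rate,
    genotype_pca,
    hwe_exact_p,
    ld_prune,
    ld_r2,
    maf,
)

from _oracles import hwe_oracle, pearson_r2
from conftest import make_matrix, random_matrix


class TestCallRateAndMaf:
    def test_call_rate_complete_and_partial(self):
        gm = make_matrix([[0], [1], [2], [1], [0], [2], [1], [0], [1], [MISSING]])
        assert call_rate(gm, "rs0") == 0.9
        gm_full = make_matrix([[0], [1], [2]])
        assert call_rate(gm_full, "rs0") == 1.0

    def test_call_rate_matches_direct_count(self, rng):
        gm = random_matrix(rng, n=50, m=8, missing_rate=0.3)
        for vid in gm.vids:
            col = gm.column(vid)
            assert call_rate(gm, vid) == sum(1 for g in col if g != MISSING) / 50

    @pytest.mark.parametrize(
        "dosages, expected",
        [([[0], [0], [0], [0]], 0.0), ([[2], [2], [2], [2]], 0.0), ([[0], [1], [1], [2]], 0.5)],
    )
    def test_maf_definition(self, dosages, expected):
        assert maf(make_matrix(dosages), "rs0") == expected

    def test_maf_all_missing_errors(self):
        gm = make_matrix([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="missing"):
            maf(gm, "rs0")

    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_maf_invariant_under_allele_relabeling(self, dosages):
        if all(d == MISSING for d in dosages):
            return
        gm = make_matrix([[d] for d in dosages])
        swapped = [[MISSING if d == MISSING else 2 - d] for d in dosages]
        assert maf(gm, "rs0") == pytest.approx(maf(make_matrix(swapped), "rs0"), abs=1e-15)


class TestHweExact:
    def test_modal_configuration_gives_one(self):
        # 50 hets with 100/100 alleles is the modal state: every term counts
        assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_is_degenerate(self):
        assert hwe_exact_p(0, 0, 10) == 1.0

    def test_no_hets_against_enumeration(self):
        assert hwe_exact_p(10, 0, 10) == pytest.approx(hwe_oracle(10, 0, 10), abs=1e-12)

    def test_exhaustive_grid_small_totals(self):
        for n in range(1, 26):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    assert hwe_exact_p(n_aa, n_ab, n_bb) == pytest.approx(
                        hwe_oracle(n_aa, n_ab, n_bb), abs=1e-12
                    ), (n_aa, n_ab, n_bb)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)


class TestLdR2:
    def test_identical_vectors(self):
        gm = make_matrix([[0, 0], [1, 1], [2, 2], [1, 1]])
        assert ld_r2(gm, "rs0", "rs1") == pytest.approx(1.0)

    def test_complement_vector(self):
        gm = make_matrix([[0, 2], [1, 1], [2, 0], [1, 1]])
        assert ld_r2(gm, "rs0", "rs1") == pytest.approx(1.0)

    def test_random_pair_matches_textbook_formula(self, rng):
        gm = random_matrix(rng, n=60, m=2, missing_rate=0.1)
        a, b = gm.column("rs0"), gm.column("rs1")
        ok = (a != MISSING) & (b != MISSING)
        expected = pearson_r2(a[ok], b[ok])
        assert ld_r2(gm, "rs0", "rs1") == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_errors(self):
        gm = make_matrix([[0, 0], [0, 1], [0, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(gm, "rs0", "rs1")


class TestApplyQc:
    def _fixture(self):
        # 6 variants x 20 samples: rs0/rs1 fail call rate (<0.95),
        # rs2 fails MAF (<0.05 threshold), rs3 fails HWE (all hets),
        # rs4/rs5 clean
        n = 20
        cols = {
            "rs0": [MISSING] * 2 + [0, 1] * 9,
            "rs1": [MISSING] * 3 + [1, 2] * 8 + [0],
            "rs2": [0] * 19 + [1],
            "rs3": [1] * 20,
            "rs4": [0, 1, 2, 1] * 5,
            "rs5": [2, 1, 0, 1] * 5,
        }
        return make_matrix(np.array(list(cols.values())).T)

    def test_constructed_failures_counted_by_hand(self):
        gm = self._fixture()
        thr = QCThresholds(min_call_rate=0.95, min_maf=0.05, min_hwe_p=1e-4)
        out, report = apply_qc(gm, thr)
        assert out.vids == ["rs4", "rs5"]
        reasons = report.set_index("vid")["fail_reason"].to_dict()
        assert reasons["rs0"] == "call_rate" and reasons["rs1"] == "call_rate"
        assert reasons["rs2"] == "maf" and reasons["rs3"] == "hwe"

    def test_zero_thresholds_keep_everything(self):
        gm = self._fixture()
        out, _ = apply_qc(gm, QCThresholds(0.0, 0.0, 0.0))
        assert out.vids == gm.vids

    def test_impossible_maf_threshold_empties_output(self, rng):
        gm = random_matrix(rng, n=15, m=4, missing_rate=0.0)
        with pytest.warns(UserWarning, match="failed QC"):
            out, _ = apply_qc(gm, QCThresholds(0.0, 0.51, 0.0))
        assert out.n_variants == 0

    def test_survivors_independent_of_variant_order(self, rng):
        gm = self._fixture()
        perm = rng.permutation(gm.n_variants)
        shuffled = GenotypeMatrix(
            gm.dosages[:, perm], [gm.variants[j] for j in perm], gm.sample_ids
        )
        thr = QCThresholds(min_call_rate=0.95, min_maf=0.05, min_hwe_p=1e-4)
        assert set(apply_qc(gm, thr)[0].vids) == set(apply_qc(shuffled, thr)[0].vids)

    def test_hwe_restricted_to_mask(self):
        gm = self._fixture()
        mask = np.zeros(20, bool)
        mask[:10] = True
        _, report = apply_qc(gm, QCThresholds(0, 0, 0), hwe_sample_mask=mask)
        col = gm.column("rs4")[:10]
        expected = hwe_oracle(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        assert report.set_index("vid").loc["rs4", "hwe_p"] == pytest.approx(expected)


class TestLdPrune:
    def test_duplicate_variant_dropped(self):
        gm = make_matrix([[0, 0], [1, 1], [2, 2], [1, 1]])
        assert ld_prune(gm, max_r2=0.8) == ["rs0"]

    def test_independent_sites_all_kept(self, rng):
        gm = random_matrix(rng, n=400, m=20, missing_rate=0.0)
        assert ld_prune(gm, max_r2=0.8) == gm.vids

    def test_kept_pairs_verified_exhaustively(self, rng):
        # correlated blocks: duplicate some columns with noise
        base = random_matrix(rng, n=120, m=8, missing_rate=0.0)
        dup = base.dosages[:, [0, 0, 1, 2, 3, 4, 5, 6, 7, 1]].copy()
        flip = rng.random(dup.shape) < 0.05
        dup[flip] = np.clip(2 - dup[flip], 0, 2)
        gm = make_matrix(dup)
        kept = ld_prune(gm, max_r2=0.5)
        for i, v1 in enumerate(kept):
            for v2 in kept[i + 1:]:
                assert ld_r2(gm, v1, v2) <= 0.5

    def test_prune_at_one_keeps_all_polymorphic(self, rng):
        gm = random_matrix(rng, n=50, m=10, missing_rate=0.0)
        assert ld_prune(gm, max_r2=1.0) == gm.vids

    def test_different_chromosomes_never_compared(self, rng):
        col = np.tile([0, 1, 2, 1], 10)[:, None]
        gm1 = make_matrix(np.hstack([col, col]), chrom="1")
        # same duplicated data but on two chromosomes -> both kept
        from wprskit.datatypes import VariantMeta
        v2 = [gm1.variants[0],
              VariantMeta("2", 100, "rs1", gm1.variants[1].allele_counted,
                          gm1.variants[1].allele_other)]
        gm2 = GenotypeMatrix(gm1.dosages, v2, gm1.sample_ids)
        assert ld_prune(gm2, max_r2=0.5) == ["rs0", "rs1"]


class TestGenotypePca:
    def test_separated_subpopulations(self, rng):
        m = 40
        maf_a = rng.uniform(0.1, 0.3, m)
        maf_b = np.clip(maf_a + 0.35, 0, 0.95)
        ga = rng.binomial(2, maf_a, size=(60, m))
        gb = rng.binomial(2, maf_b, size=(60, m))
        gm = make_matrix(np.vstack([ga, gb]).astype(np.int8))
        scores = genotype_pca(gm, k=2)
        pc1_a, pc1_b = scores[:60, 0], scores[60:, 0]
        pooled_sd = np.sqrt((pc1_a.var(ddof=1) + pc1_b.var(ddof=1)) / 2)
        assert abs(pc1_a.mean() - pc1_b.mean()) > 4 * pooled_sd
        assert max(pc1_a.max(), pc1_b.max()) > min(pc1_a.min(), pc1_b.min())  # sanity
        # zero overlap between the groups along PC1
        lo, hi = (pc1_a, pc1_b) if pc1_a.mean() < pc1_b.mean() else (pc1_b, pc1_a)
        assert lo.max() < hi.min()

    def test_k_zero_empty(self, rng):
        gm = random_matrix(rng, n=10, m=5)
        assert genotype_pca(gm, k=0).shape == (10, 0)

    def test_reconstruction_matches_svd_oracle(self, rng):
        gm = random_matrix(rng, n=30, m=12, missing_rate=0.0)
        k = 3
        pca = GenotypePCA(n_components=k).fit(gm)
        scores = pca.transform(gm)
        Z = (gm.dosages.astype(float) - pca.mean_) / pca.scale_
        approx = scores @ pca.components_
        # oracle: best rank-k approximation from a direct SVD
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        best = U[:, :k] @ np.diag(s[:k]) @ Vt[:k]
        assert np.linalg.norm(Z - approx) == pytest.approx(np.linalg.norm(Z - best), rel=1e-9)

    def test_sign_convention_fixed(self, rng):
        gm = random_matrix(rng, n=25, m=8, missing_rate=0.0)
        pca = GenotypePCA(n_components=2).fit(gm)
        for comp in pca.components_:
            assert comp[np.abs(comp).argmax()] > 0

    def test_k_too_large_rejected(self, rng):
        gm = random_matrix(rng, n=5, m=3)
        with pytest.raises(ValueError, match="n_components"):
            GenotypePCA(n_components=4).fit(gm)
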