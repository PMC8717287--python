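import numpy as np
import pytest
from scipy.stats import spearmanr

from mimicline.snp_filter import MISSING, SNPMatrix, quality_filter, structural_filter
from mimicline.structure import (
    DistanceMatrix,
    StructureError,
    TreeNode,
    genotype_distance,
    ld_prune,
    neighbor_joining,
    nmf_admixture,
    nuclear_cline_input,
    pca,
)
from mimicline.synthetic_data import SimulationConfig, simulate_snp_matrix


def _matrix(genotypes, pos=None, contig=None, samples=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = genotypes.shape
    return SNPMatrix(
        contig=np.asarray(contig if contig is not None else ["c1"] * n_sites),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_sites + 1)),
        ref=np.array(["A"] * n_sites),
        alt=np.array(["T"] * n_sites),
        biallelic=np.ones(n_sites, dtype=bool),
        samples=samples or [f"s{i}" for i in range(n_samples)],
        genotypes=genotypes,
        depth=np.full((n_sites, n_samples), 30),
        gq=np.full((n_sites, n_samples), 99),
        contig_lengths={"c1": 50_000},
    )


class TestGenotypeDistance:
    def test_identical_zero(self):
        d = genotype_distance(_matrix([[0, 0], [2, 2]]))
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_max(self):
        d = genotype_distance(_matrix([[0, 2], [0, 2]]))
        assert d.values[0, 1] == 1.0

    def test_het_dosage_half(self):
        d = genotype_distance(_matrix([[0, 1], [0, 1]]))
        assert d.values[0, 1] == 0.5

    def test_no_shared_sites_rejected(self):
        with pytest.raises(StructureError):
            genotype_distance(_matrix([[0, MISSING], [MISSING, 2]]))


class TestNeighborJoining:
    def _additive_tree_distances(self):
        # ((A:2,B:3):1,(C:4,D:5)) with internal edge 1
        d = {
            ("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
            ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9,
        }
        ids = ["A", "B", "C", "D"]
        m = np.zeros((4, 4))
        for (a, b), v in d.items():
            i, j = ids.index(a), ids.index(b)
            m[i, j] = m[j, i] = v
        return DistanceMatrix(ids=ids, values=m)

    def test_additive_four_taxon_recovery(self):
        tree = neighbor_joining(self._additive_tree_distances())
        tips = tree.tip_distances()
        assert tips["A"]["B"] == pytest.approx(5)
        assert tips["A"]["C"] == pytest.approx(7)
        assert tips["C"]["D"] == pytest.approx(9)
        assert tips["B"]["D"] == pytest.approx(9)

    def test_three_taxa_star(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids=["a", "b", "c"], values=m))
        tips = tree.tip_distances()
        assert tips["a"]["b"] == pytest.approx(3)
        assert tips["a"]["c"] == pytest.approx(4)
        assert tips["b"]["c"] == pytest.approx(5)

    def test_random_additive_trees_recovered(self):
        # oracle: distances generated from a random additive tree must be
        # reproduced exactly by the NJ reconstruction
        rng = np.random.default_rng(3)
        for rep in range(5):
            n = int(rng.integers(5, 11))
            ids = [f"t{i}" for i in range(n)]
            # build a random tree by sequential attachment
            root = TreeNode(children=[
                (TreeNode(name=ids[0]), float(rng.uniform(0.5, 3))),
                (TreeNode(name=ids[1]), float(rng.uniform(0.5, 3))),
                (TreeNode(name=ids[2]), float(rng.uniform(0.5, 3))),
            ])
            internals = [root]
            for leaf in ids[3:]:
                parent = internals[int(rng.integers(len(internals)))]
                ci = int(rng.integers(len(parent.children)))
                child, bl = parent.children[ci]
                split = TreeNode(children=[
                    (child, bl / 2),
                    (TreeNode(name=leaf), float(rng.uniform(0.5, 3))),
                ])
                parent.children[ci] = (split, bl / 2)
                internals.append(split)
            tips = root.tip_distances()
            m = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    m[i, j] = m[j, i] = tips[ids[i]][ids[j]]
            rebuilt = neighbor_joining(DistanceMatrix(ids=ids, values=m))
            tips2 = rebuilt.tip_distances()
            for i in range(n):
                for j in range(i + 1, n):
                    assert tips2[ids[i]][ids[j]] == pytest.approx(m[i, j], abs=1e-8)

    def test_matches_scikit_bio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        dm = self._additive_tree_distances()
        ours = neighbor_joining(dm).tip_distances()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.ids))
        for a in dm.ids:
            for b in dm.ids:
                if a < b:
                    assert ours[a][b] == pytest.approx(
                        sk_tree.find(a).distance(sk_tree.find(b))
                    )

    def test_order_invariance(self):
        dm = self._additive_tree_distances()
        perm = [2, 0, 3, 1]
        dm_p = DistanceMatrix(
            ids=[dm.ids[i] for i in perm], values=dm.values[np.ix_(perm, perm)]
        )
        t1 = neighbor_joining(dm).tip_distances()
        t2 = neighbor_joining(dm_p).tip_distances()
        for a in dm.ids:
            for b in dm.ids:
                if a != b:
                    assert t1[a][b] == pytest.approx(t2[a][b])

    def test_outgroup_first_child(self):
        tree = neighbor_joining(self._additive_tree_distances(), outgroup="D")
        assert "D" in tree.children[0][0].leaf_names()

    def test_too_few_samples_rejected(self):
        with pytest.raises(StructureError):
            neighbor_joining(DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2))))


class TestLdPrune:
    def test_duplicate_column_dropped(self):
        g = np.array([[0, 1, 2, 0], [0, 1, 2, 0]], dtype=np.int8)
        m = _matrix(g, pos=[100, 1100])
        out = ld_prune(m)
        assert list(out.pos) == [100]

    def test_r2_boundary_exactly_half_kept(self):
        # dosage columns with r^2 = 0.5 exactly: strict > keeps both
        a = np.array([0, 0, 2, 2], dtype=np.int8)
        b = np.array([0, 1, 1, 2], dtype=np.int8)
        assert np.corrcoef(a, b)[0, 1] ** 2 == pytest.approx(0.5, abs=1e-12)
        m = _matrix(np.vstack([a, b]), pos=[100, 200])
        out = ld_prune(m)
        assert out.n_sites == 2

    def test_outside_window_kept(self):
        g = np.array([[0, 1, 2, 0], [0, 1, 2, 0]], dtype=np.int8)
        m = _matrix(g, pos=[100, 5101])
        out = ld_prune(m)
        assert out.n_sites == 2

    def test_no_violating_pairs_remain(self, snp_data):
        m, _, _ = snp_data
        m2 = structural_filter(quality_filter(m))
        out = ld_prune(m2)
        assert out.n_sites <= m2.n_sites
        g = out.genotypes.astype(float)
        for i in range(out.n_sites):
            for j in range(i + 1, out.n_sites):
                if out.contig[i] != out.contig[j]:
                    continue
                if out.pos[j] - out.pos[i] > 5000:
                    continue
                if np.std(g[i]) == 0 or np.std(g[j]) == 0:
                    continue
                r2 = np.corrcoef(g[i], g[j])[0, 1] ** 2
                assert r2 <= 0.5 + 1e-9


class TestPca:
    def test_two_clusters_on_pc1(self):
        g = np.zeros((20, 10), dtype=np.int8)
        g[:, 5:] = 2
        m = _matrix(g)
        res = pca(m, 1)
        side = res.scores[:5, 0]
        other = res.scores[5:, 0]
        assert np.all(np.sign(side) != np.sign(other))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self, clean_snp_config):
        m, _, _ = simulate_snp_matrix(clean_snp_config)
        m = structural_filter(quality_filter(m))
        full_rank = m.n_samples - 1
        res = pca(m, full_rank)
        x = m.genotypes.T.astype(float)
        x = x - x.mean(axis=0)
        recon = res.scores @ res.loadings.T
        assert np.allclose(recon, x, atol=1e-8)

    def test_variances_non_increasing_and_sum(self, clean_snp_config):
        m, _, _ = simulate_snp_matrix(clean_snp_config)
        m = structural_filter(quality_filter(m))
        res = pca(m, m.n_samples - 1)
        ev = res.explained_variance
        assert np.all(ev >= 0)
        assert np.all(np.diff(ev) <= 1e-9)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_sign_determinism(self, clean_snp_config):
        m, _, _ = simulate_snp_matrix(clean_snp_config)
        m = structural_filter(quality_filter(m))
        r1, r2 = pca(m, 2), pca(m, 2)
        assert np.array_equal(r1.scores, r2.scores)

    def test_excess_components_rejected(self):
        m = _matrix(np.zeros((5, 4), dtype=np.int8))
        with pytest.raises(StructureError):
            pca(m, 4)


class TestNmfAdmixture:
    def test_two_pure_populations_one_hot(self):
        rng = np.random.default_rng(0)
        fa = rng.uniform(0.05, 0.3, 300)
        fb = rng.uniform(0.7, 0.95, 300)
        g = np.empty((300, 16), dtype=np.int8)
        g[:, :8] = rng.binomial(2, fa[:, None], (300, 8))
        g[:, 8:] = rng.binomial(2, fb[:, None], (300, 8))
        m = _matrix(g)
        res = nmf_admixture(m, [1, 2, 3], seed=4, n_restarts=5)
        assert res.selected_K == 2
        assert np.all(res.Q.max(axis=1) > 0.9)
        assert np.allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)

    def test_k1_degenerate(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, (100, 10)).astype(np.int8)
        res = nmf_admixture(_matrix(g), [1], seed=2, n_restarts=2)
        assert np.allclose(res.Q, 1.0)

    def test_gradient_recovered_along_transect(self):
        # rank-correlation of the ancestry coefficient with the planted
        # admixture gradient; at 20 samples x ~500 sites the per-sample
        # precision limits the attainable correlation, so assert on the
        # median across generator seeds
        rhos = []
        for seed in (2, 3, 4, 5, 6):
            cfg = SimulationConfig(
                seed=seed, n_snps=500, low_quality_call_fraction=0.0,
                non_biallelic_fraction=0.0, n_ancestry_fixed_snps=0,
                n_numt_intervals=0,
            )
            m, _, truth = simulate_snp_matrix(cfg)
            m = structural_filter(quality_filter(m))
            res = nmf_admixture(m, [2], seed=7, n_restarts=5)
            rho = spearmanr(truth["admixture_north"], res.Q[:, 0]).statistic
            rhos.append(abs(rho))
        assert np.median(rhos) > 0.8
        assert min(rhos) > 0.5

    def test_k_exceeding_samples_rejected(self):
        m = _matrix(np.zeros((10, 4), dtype=np.int8))
        with pytest.raises(StructureError):
            nmf_admixture(m, [6], seed=0)


class TestNuclearClineInput:
    def test_pairs_match_specimens(self, specimen_table):
        from mimicline.structure import AncestryResult

        ids = [r.id for r in specimen_table.records[:6]]
        q = np.array([[0.3, 0.7]] * 6)
        res = AncestryResult(K=2, Q=q, G=np.zeros((2, 5)),
                             cross_entropy={2: 0.5}, selected_K=2, sample_ids=ids)
        x, qq = nuclear_cline_input(res, specimen_table, cluster=1)
        assert len(x) == 6
        assert np.all(qq == 0.7)

    def test_unmapped_sample_rejected(self, specimen_table):
        from mimicline.structure import AncestryResult

        res = AncestryResult(K=2, Q=np.array([[1.0, 0.0]]), G=np.zeros((2, 2)),
                             cross_entropy={2: 0.5}, selected_K=2,
                             sample_ids=["ghost"])
        with pytest.raises(StructureError):
            nuclear_cline_input(res, specimen_table, cluster=0)
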