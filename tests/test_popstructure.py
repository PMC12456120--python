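"""LD pruning, PCA, admixture EM, distances and neighbour joining."""

import numpy as np
import pytest

from conftest import one_hot_gl
from glpop import glcore, popstructure, simdata


class TestLdPrune:
    def test_duplicate_sites_collapse_to_one(self):
        rng = np.random.default_rng(0)
        d = rng.random((5, 30))
        d = np.vstack([d, d[2:3]])  # exact duplicate of site 2
        kept = popstructure.ld_prune(d)
        assert len(kept) == 5
        assert 2 in kept and 5 not in kept  # lowest index kept

    def test_independent_sites_all_kept(self):
        rng = np.random.default_rng(1)
        d = rng.random((50, 200))
        kept = popstructure.ld_prune(d)
        assert len(kept) == 50

    def test_planted_block_leaves_one_survivor(self):
        rng = np.random.default_rng(2)
        indep = rng.random((500, 100))
        block = np.tile(rng.random((1, 100)), (20, 1))
        d = np.vstack([indep[:250], block, indep[250:]])
        kept = popstructure.ld_prune(d)
        in_block = [k for k in kept if 250 <= k < 270]
        assert len(in_block) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        base = rng.random((40, 60))
        noisy = np.repeat(base, 3, axis=0) + 0.05 * rng.random((120, 60))
        kept = popstructure.ld_prune(noisy)
        again = popstructure.ld_prune(noisy[kept])
        assert len(again) == len(kept)


class TestPCA:
    def test_identical_individuals_zero_covariance(self):
        gl = np.tile(glcore.gl_from_counts(2, 2, 0.01), (50, 8, 1))
        f = np.full(50, 0.5)
        C, vals, _ = popstructure.pca_covariance(gl, f)
        assert np.abs(C).max() < 1e-6

    def test_pc1_separates_differentiated_morphs(self, two_morph_highdepth):
        sim = two_morph_highdepth
        f, _, _ = glcore.estimate_maf_em(sim.gl)
        _, _, scores = popstructure.pca_covariance(sim.gl, f)
        pc1 = scores[:, 0]
        a = pc1[sim.group_indices(morph="m1")]
        b = pc1[sim.group_indices(morph="m2")]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert a.max() < b.min() or b.max() < a.min()  # zero overlap

    def test_eigenvalue_sum_equals_trace(self, two_morph_highdepth):
        sim = two_morph_highdepth
        f, _, _ = glcore.estimate_maf_em(sim.gl)
        C, vals, _ = popstructure.pca_covariance(sim.gl, f)
        assert vals.sum() == pytest.approx(np.trace(C), abs=1e-8)

    def test_site_permutation_invariance(self, two_morph_highdepth):
        sim = two_morph_highdepth
        f, _, _ = glcore.estimate_maf_em(sim.gl)
        _, _, s1 = popstructure.pca_covariance(sim.gl, f)
        perm = np.random.default_rng(0).permutation(len(f))
        _, _, s2 = popstructure.pca_covariance(sim.gl[perm], f[perm])
        # deterministic sign fixing makes scores identical, not just up to sign
        assert np.allclose(s1[:, :3], s2[:, :3], atol=1e-8)

    def test_monomorphic_rejected(self):
        gl = one_hot_gl(np.zeros((10, 5), dtype=int))
        with pytest.raises(glcore.EstimationError):
            popstructure.pca_covariance(gl, np.zeros(10))


class TestAdmixture:
    def test_k1_is_pooled_frequency_model(self, two_morph_highdepth):
        sim = two_morph_highdepth
        fit = popstructure.admixture_em(sim.gl[:100], K=1, seed=0, n_restarts=1)
        assert np.allclose(fit.Q, 1.0)
        f, _, _ = glcore.estimate_maf_em(sim.gl[:100])
        assert np.allclose(fit.F[:, 0], f, atol=5e-3)

    def test_q_rows_sum_to_one_and_loglik_monotone(self, two_morph_highdepth):
        sim = two_morph_highdepth
        fit = popstructure.admixture_em(sim.gl[:200], K=2, seed=1, n_restarts=1)
        assert np.allclose(fit.Q.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(np.diff(fit.loglik_path) >= -1e-6)

    def test_recovers_two_diverged_populations(self):
        cfg = simdata.SimConfig(
            lakes=[
                simdata.LakeSpec("l", 0.0, [
                    simdata.MorphSpec("a", 15, 0.5), simdata.MorphSpec("b", 15, 0.5),
                ])
            ],
            n_sites=400, scaffold_length=200_000,
            depth_mean=20.0, depth_sd=2.0, seed=21,
        )
        sim = simdata.simulate_dataset(cfg)
        fit = popstructure.admixture_em(sim.gl, K=2, seed=0)
        q1 = fit.Q[sim.group_indices(morph="a"), 0]
        # orient: cluster 0 is whichever morph a loads on
        if q1.mean() < 0.5:
            q1 = 1 - q1
        q2 = fit.Q[sim.group_indices(morph="b"), 0]
        if q2.mean() > 0.5:
            q2 = 1 - q2
        assert np.max(np.abs(1 - q1)) < 0.05
        assert np.max(np.abs(q2)) < 0.05

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(glcore.ParameterError):
            popstructure.admixture_em(np.ones((5, 3, 3)), K=4)


class TestDistances:
    def test_identical_frequencies_zero_nei(self):
        p = np.array([[0.2, 0.8, 0.5], [0.2, 0.8, 0.5]])
        D = popstructure.distance_matrix(p, "nei_groups")
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_frequencies_capped(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning):
            D = popstructure.distance_matrix(p, "nei_groups")
        assert D[0, 1] == popstructure.NEI_DISTANCE_CAP

    def test_covariance_distance_valid(self, two_morph_highdepth):
        sim = two_morph_highdepth
        f, _, _ = glcore.estimate_maf_em(sim.gl)
        C, _, _ = popstructure.pca_covariance(sim.gl, f)
        D = popstructure.distance_matrix(C, "covariance_individuals")
        assert np.all(D >= 0)
        assert np.allclose(np.diag(D), 0)
        assert np.allclose(D, D.T)


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 2, 3], [2, 0, 4], [3, 4, 0]])
        tree = popstructure.nj_tree(D, ["a", "b", "c"])
        nwk = tree.to_newick()
        assert nwk == "(a:0.5,b:1.5,c:2.5);"

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1.5,c:3,d:4): additive distances
        D = np.array(
            [
                [0.0, 3.0, 5.5, 6.5],
                [3.0, 0.0, 6.5, 7.5],
                [5.5, 6.5, 0.0, 7.0],
                [6.5, 7.5, 7.0, 0.0],
            ]
        )
        tree = popstructure.nj_tree(D, ["a", "b", "c", "d"])
        import dendropy

        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        labels = ["a", "b", "c", "d"]
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[li], taxa[lj]) == pytest.approx(D[i, j])

    def test_equal_distances_star_no_crash(self):
        D = np.ones((5, 5)) - np.eye(5)
        tree = popstructure.nj_tree(D, list("abcde"))
        assert sorted(tree.leaves()) == list("abcde")

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(glcore.ParameterError):
            popstructure.nj_tree(D, list("abc"))

    def test_matches_external_nj_on_additive_matrix(self):
        """Independent oracle: scikit-bio's NJ gives the same path lengths."""
        import io

        import dendropy
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        # random additive tree on 6 taxa via random split metric
        base = rng.random((6, 2)) * 5
        D = np.abs(base[:, 0][:, None] - base[:, 0][None, :]) + np.abs(
            base[:, 1][:, None] - base[:, 1][None, :]
        )
        labels = list("abcdef")
        ours = popstructure.nj_tree(D, labels).to_newick()
        theirs = skbio_nj(DistanceMatrix(D, labels)).write(io.StringIO()).getvalue()
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0


def test_nj_groups_by_lake_before_morph():
    """With between-lake drift >> within-lake drift, individuals cluster by
    lake in the NJ tree (checked through covariance distances)."""
    cfg = simdata.SimConfig(
        lakes=[
            simdata.LakeSpec("L1", 0.3, [simdata.MorphSpec("x", 8, 0.03),
                                         simdata.MorphSpec("y", 8, 0.03)]),
            simdata.LakeSpec("L2", 0.3, [simdata.MorphSpec("x", 8, 0.03),
                                         simdata.MorphSpec("y", 8, 0.03)]),
        ],
        n_sites=600, scaffold_length=300_000, depth_mean=10.0, depth_sd=1.0, seed=33,
    )
    sim = simdata.simulate_dataset(cfg)
    f, _, _ = glcore.estimate_maf_em(sim.gl)
    C, _, _ = popstructure.pca_covariance(sim.gl, f)
    D = popstructure.distance_matrix(C, "covariance_individuals")
    lakes = sim.samples["lake"].to_numpy()
    same = D[lakes[:, None] == lakes[None, :]]
    diff = D[lakes[:, None] != lakes[None, :]]
    assert np.median(same[same > 0]) < np.median(diff)

    import dendropy

    nwk = popstructure.nj_tree(D, list(sim.samples["sample"])).to_newick()
    t = dendropy.Tree.get(data=nwk, schema="newick")
    # the deepest bipartition splits the two lakes exactly
    pdm = t.phylogenetic_distance_matrix()
    # dendropy renders underscores in unquoted labels as spaces
    taxa = {x.label.replace(" ", "_"): x for x in t.taxon_namespace}
    names = list(sim.samples["sample"])
    within, between = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = pdm.distance(taxa[a], taxa[b])
            (within if a.split("_")[0] == b.split("_")[0] else between).append(d)
    assert np.median(within) < np.median(between)
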