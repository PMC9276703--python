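import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from nephroscan.coexpression import (
    GREY,
    MetacellMatrix,
    NetworkConfig,
    build_metacells,
    build_network,
    detect_modules,
    hub_genes,
    kme,
    module_eigengene,
    module_group_specificity,
    signed_adjacency,
    topological_overlap,
)


def _metacells(X, groups=None, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(X.shape[1])]
    idx = [f"mc{i}" for i in range(X.shape[0])]
    expr = pd.DataFrame(X, index=idx, columns=genes)
    prov = pd.DataFrame(
        {
            "cell_type": "PT",
            "group": groups if groups is not None else ["g0"] * X.shape[0],
            "k": 10,
            "members": "",
        },
        index=expr.index,
    )
    return MetacellMatrix(expr, prov)


def _planted_blocks(n_mc=60, n_noise=80, block=60, seed=0):
    """Two orthogonal latent blocks plus noise genes; block 2 tracks the
    IRI_long group."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["Control", "IRI_short", "IRI_long"], n_mc // 3)
    latent1 = rng.normal(size=n_mc)
    latent2 = (groups == "IRI_long") * 2.0 + rng.normal(size=n_mc) * 0.3
    X = rng.normal(size=(n_mc, 2 * block + n_noise))
    X[:, :block] += latent1[:, None] * 2
    X[:, block: 2 * block] += latent2[:, None] * 2
    return _metacells(X, groups=list(groups)), block


class TestBuildMetacells:
    @pytest.fixture(scope="class")
    def adata(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 30)) + 1.0
        obs = pd.DataFrame(
            {
                "cell_type": np.repeat(["PT", "Immune"], 60),
                "condition": list(np.tile(np.repeat(["Control", "IRI"], 30), 2)),
            },
            index=[f"c{i}" for i in range(120)],
        )
        return AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=[f"g{i}" for i in range(30)]))

    def test_k1_resamples_single_cells(self, adata):
        mc = build_metacells(adata, k=1, n_metacells_per_stratum=5, seed=2)
        X = np.asarray(adata.X)
        for row in mc.expr.to_numpy():
            assert any(np.allclose(row, X[i]) for i in range(adata.n_obs))

    def test_identical_cells_reproduced_exactly(self):
        X = np.tile(np.arange(5.0), (20, 1))
        obs = pd.DataFrame({"cell_type": "PT", "condition": "Control"},
                           index=[f"c{i}" for i in range(20)])
        adata = AnnData(X=X, obs=obs,
                        var=pd.DataFrame(index=[f"g{i}" for i in range(5)]))
        mc = build_metacells(adata, k=7, n_metacells_per_stratum=3, seed=0)
        np.testing.assert_allclose(
            mc.expr.to_numpy(), np.tile(np.arange(5.0), (3, 1))
        )

    def test_variance_reduction(self, adata):
        mc = build_metacells(adata, k=20, n_metacells_per_stratum=30, seed=3)
        single_var = np.asarray(adata.X).var(axis=0).mean()
        meta_var = mc.expr.to_numpy().var(axis=0).mean()
        assert meta_var < single_var

    def test_strata_pure_and_deterministic(self, adata):
        mc1 = build_metacells(adata, k=5, n_metacells_per_stratum=4, seed=4)
        mc2 = build_metacells(adata, k=5, n_metacells_per_stratum=4, seed=4)
        pd.testing.assert_frame_equal(mc1.expr, mc2.expr)
        assert set(zip(mc1.provenance["cell_type"], mc1.provenance["group"])) == {
            ("PT", "Control"), ("PT", "IRI"), ("Immune", "Control"),
            ("Immune", "IRI"),
        }


class TestSignedAdjacency:
    def test_correlation_endpoints(self):
        t = np.linspace(-1, 1, 10)
        X = np.column_stack([t, t, -t])
        adj = signed_adjacency(_metacells(X), NetworkConfig(beta=6))
        assert adj.iloc[0, 1] == pytest.approx(1.0)
        assert adj.iloc[0, 2] == pytest.approx(0.0)

    def test_zero_correlation_value(self):
        # two exactly orthogonal profiles: a = 0.5^beta
        X = np.column_stack([[1, -1, 1, -1], [1, 1, -1, -1]]).astype(float)
        adj = signed_adjacency(_metacells(X), NetworkConfig(beta=12))
        assert adj.iloc[0, 1] == pytest.approx(0.5**12, rel=1e-10)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 20))
        adj = signed_adjacency(_metacells(X), NetworkConfig(beta=12))
        expected = ((1 + np.corrcoef(X.T)) / 2) ** 12
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(adj.to_numpy(), expected, atol=1e-10)

    def test_too_few_metacells_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(_metacells(np.ones((2, 4))))


class TestTopologicalOverlap:
    def test_diagonal_only_adjacency(self):
        adj = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        tom = topological_overlap(adj)
        assert np.allclose(tom.to_numpy()[~np.eye(5, dtype=bool)], 0.0)
        assert np.allclose(np.diag(tom), 1.0)

    def test_three_node_closed_form(self):
        a = 0.4
        A = np.full((3, 3), a)
        np.fill_diagonal(A, 1.0)
        adj = pd.DataFrame(A, index=list("xyz"), columns=list("xyz"))
        tom = topological_overlap(adj)
        expected = (a**2 + a) / (2 * a + 1 - a)
        assert tom.iloc[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_matches_naive_triple_loop(self):
        rng = np.random.default_rng(6)
        A = rng.random((30, 30))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        genes = [f"g{i}" for i in range(30)]
        tom = topological_overlap(pd.DataFrame(A, index=genes, columns=genes))
        n = 30
        naive = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                num = sum(A[i, u] * A[u, j] for u in range(n))
                num += -A[i, i] * A[i, j] - A[i, j] * A[j, j] + A[i, j]
                ki = sum(A[i, u] for u in range(n) if u != i)
                kj = sum(A[j, u] for u in range(n) if u != j)
                naive[i, j] = num / (min(ki, kj) + 1 - A[i, j])
        np.fill_diagonal(naive, 1.0)
        np.testing.assert_allclose(tom.to_numpy(), naive, atol=1e-10)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 40))
        adj = signed_adjacency(_metacells(X), NetworkConfig(beta=6))
        tom = topological_overlap(adj)
        T = tom.to_numpy()
        assert np.abs(T - T.T).max() < 1e-12
        assert T.min() >= 0 and T.max() <= 1 + 1e-12


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        mc, block = _planted_blocks(seed=8)
        cfg = NetworkConfig(min_module_size=50)
        net = build_network(mc, cfg)
        mods = net.modules
        non_grey = [m for m in mods.unique() if m != GREY]
        assert len(non_grey) == 2
        for start in (0, block):
            block_mods = mods.iloc[start: start + block]
            top = block_mods.mode()[0]
            assert top != GREY
            assert (block_mods == top).mean() >= 0.9

    def test_undersized_block_goes_grey(self):
        rng = np.random.default_rng(9)
        latent = rng.normal(size=40)
        X = rng.normal(size=(40, 120))
        X[:, :30] += latent[:, None] * 3  # coherent but below min size 50
        mods = detect_modules(
            topological_overlap(signed_adjacency(_metacells(X))),
            NetworkConfig(min_module_size=50),
        )
        assert (mods.iloc[:30] == GREY).all()

    def test_highly_correlated_blocks_merged(self):
        """Two blocks driven by near-identical latents (r ~ 0.95) merge
        under the > 0.8 eigengene-correlation rule."""
        rng = np.random.default_rng(10)
        n = 60
        latent = rng.normal(size=n)
        l1 = latent + rng.normal(scale=0.18, size=n)
        l2 = latent + rng.normal(scale=0.18, size=n)
        X = rng.normal(scale=0.2, size=(n, 140))
        X[:, :60] += l1[:, None]
        X[:, 60:120] += l2[:, None]
        mc = _metacells(X)
        cfg = NetworkConfig(min_module_size=50, merge_me_correlation=0.8)
        adj = signed_adjacency(mc, cfg)
        tom = topological_overlap(adj)
        merged = detect_modules(tom, cfg, expr=mc.expr)
        merged_mods = set(merged.iloc[:120]) - {GREY}
        assert len(merged_mods) == 1

    def test_eigengene_merge_fixpoint(self):
        """Blocks that the dendrogram cut separates (hand-built TOM with zero
        cross-overlap) still merge when their eigengenes correlate > 0.8."""
        rng = np.random.default_rng(21)
        n_genes, n_mc = 120, 40
        T = np.zeros((n_genes, n_genes))
        T[:60, :60] = 0.6
        T[60:, 60:] = 0.6
        np.fill_diagonal(T, 1.0)
        genes = [f"g{i:03d}" for i in range(n_genes)]
        tom = pd.DataFrame(T, index=genes, columns=genes)
        latent = rng.normal(size=n_mc)
        expr = pd.DataFrame(
            latent[:, None] + rng.normal(scale=0.1, size=(n_mc, n_genes)),
            index=[f"mc{i}" for i in range(n_mc)], columns=genes,
        )
        cfg = NetworkConfig(min_module_size=50, merge_me_correlation=0.8)
        merged = detect_modules(tom, cfg, expr=expr)
        assert len(set(merged) - {GREY}) == 1
        unmerged = detect_modules(
            tom, NetworkConfig(min_module_size=50, merge_me_correlation=1.0),
            expr=expr,
        )
        assert len(set(unmerged) - {GREY}) == 2

    def test_gene_order_invariance(self):
        mc, _ = _planted_blocks(seed=11)
        net = build_network(mc, NetworkConfig(min_module_size=50))
        perm = np.random.default_rng(12).permutation(mc.expr.shape[1])
        mc_perm = MetacellMatrix(mc.expr.iloc[:, perm], mc.provenance)
        net_perm = build_network(mc_perm, NetworkConfig(min_module_size=50))
        aligned = net_perm.modules.reindex(net.modules.index)
        assert (aligned == net.modules).all()


class TestEigengenesAndKME:
    def test_identical_genes_give_their_profile(self):
        rng = np.random.default_rng(13)
        profile = rng.normal(size=30)
        X = np.tile(profile[:, None], (1, 4)) + rng.normal(scale=1e-9, size=(30, 4))
        mc = _metacells(X)
        mods = pd.Series(["m"] * 4, index=mc.expr.columns)
        me = module_eigengene(mc, mods)
        r = np.corrcoef(me["m"], profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)
        assert me["m"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(25, 8))
        mc = _metacells(X)
        mods = pd.Series(["m"] * 8, index=mc.expr.columns)
        me = module_eigengene(mc, mods)["m"].to_numpy()
        std = (X - X.mean(axis=0)) / X.std(axis=0)
        u, s, _ = np.linalg.svd(std, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        pc1 = pc1 / pc1.std()
        agree = min(np.abs(me - pc1).max(), np.abs(me + pc1).max())
        assert agree < 1e-8

    def test_kme_bounds_and_self_correlation(self):
        mc, block = _planted_blocks(seed=15)
        net = build_network(mc, NetworkConfig(min_module_size=50))
        K = net.kme.to_numpy()
        assert (K >= -1 - 1e-9).all() and (K <= 1 + 1e-9).all()
        # a gene identical to its ME has kME 1
        me = net.eigengenes.iloc[:, 0]
        expr2 = mc.expr.copy()
        expr2["clone"] = me.to_numpy()
        k2 = kme(expr2, net.eigengenes)
        assert k2.loc["clone", net.eigengenes.columns[0]] == pytest.approx(1.0)

    def test_noise_gene_kme_small(self):
        mc, block = _planted_blocks(n_mc=90, seed=16)
        net = build_network(mc, NetworkConfig(min_module_size=50))
        noise_genes = net.kme.index[2 * block:]
        bound = 3 / np.sqrt(mc.expr.shape[0])
        frac_small = (net.kme.loc[noise_genes].abs() <= bound).to_numpy().mean()
        assert frac_small > 0.95

    def test_hub_is_argmax_with_tie_by_id(self):
        kme_table = pd.DataFrame(
            {"m": [0.9, 0.9, 0.5]}, index=["gB", "gA", "gC"]
        )
        mods = pd.Series(["m", "m", "m"], index=["gB", "gA", "gC"])
        assert hub_genes(mods, kme_table) == {"m": "gA"}


class TestGroupSpecificity:
    def test_group_specific_block_recovered(self):
        """Full-stack check mirroring a hub-gene result: the group-driven
        block is one module, its top-kME gene is a designated hub, and its
        mean eigengene peaks in the driving group."""
        mc, block = _planted_blocks(seed=17)
        net = build_network(mc, NetworkConfig(min_module_size=50))
        block2 = net.modules.index[block: 2 * block]
        module = net.modules.loc[block2].mode()[0]
        assert module != GREY
        mean_me, ind_corr = module_group_specificity(
            net.eigengenes, net.provenance if hasattr(net, "provenance")
            else mc.provenance
        )
        assert mean_me.loc[module].idxmax() == "IRI_long"
        assert ind_corr.loc[module, "IRI_long"] > 0.8
        assert net.hubs[module] in set(block2)

    def test_weighted_mean_me_is_zero(self):
        mc, _ = _planted_blocks(seed=18)
        net = build_network(mc, NetworkConfig(min_module_size=50))
        mean_me, _ = module_group_specificity(net.eigengenes, mc.provenance)
        sizes = mc.provenance["group"].value_counts()
        weighted = (mean_me * sizes[mean_me.columns]).sum(axis=1) / sizes.sum()
        np.testing.assert_allclose(weighted.to_numpy(), 0.0, atol=1e-9)
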