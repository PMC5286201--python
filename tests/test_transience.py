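import heapq

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from pombesv import (
    ParameterError,
    branch_length_association,
    copy_number_distance,
    extract_flank_snps,
    nj_tree,
    relative_transience,
    snp_distance,
    total_branch_length,
)
from pombesv.transience import normalize_to_max


def random_additive_case(rng, n):
    """Random binary tree with random edge lengths; returns (adjacency,
    leaf names, path-distance matrix, total edge length)."""
    leaves = [f"t{i}" for i in range(n)]
    edges = {}

    def add(a, b, l):
        edges.setdefault(a, {})[b] = l
        edges.setdefault(b, {})[a] = l

    for leaf in leaves[:3]:
        add(leaf, "x0", float(rng.uniform(0.1, 2.0)))
    internal = 1
    for leaf in leaves[3:]:
        pairs = [(a, b) for a in edges for b in edges[a] if str(a) < str(b)]
        a, b = pairs[int(rng.integers(0, len(pairs)))]
        l = edges[a][b]
        x = f"x{internal}"
        internal += 1
        f = float(rng.uniform(0.2, 0.8))
        del edges[a][b], edges[b][a]
        add(a, x, l * f)
        add(x, b, l * (1 - f))
        add(leaf, x, float(rng.uniform(0.1, 2.0)))

    def dist(a, b):
        seen = {a: 0.0}
        q = [(0.0, a)]
        while q:
            d, u = heapq.heappop(q)
            if u == b:
                return d
            for v, l in edges[u].items():
                nd = d + l
                if v not in seen or nd < seen[v]:
                    seen[v] = nd
                    heapq.heappush(q, (nd, v))

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(leaves[i], leaves[j])
    total = sum(edges[a][b] for a in edges for b in edges[a] if str(a) < str(b))
    return leaves, D, total


class TestNjTree:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix([[0.0, 0.4], [0.4, 0.0]], ids=["a", "b"])
        tree = nj_tree(dm)
        assert total_branch_length(tree) == pytest.approx(0.4)

    def test_four_taxon_additive_recovered_exactly(self, rng):
        leaves, D, total = random_additive_case(rng, 4)
        tree = nj_tree(DistanceMatrix(D, ids=leaves))
        td = tree.tip_tip_distances()
        for i, a in enumerate(leaves):
            for j in range(i + 1, len(leaves)):
                assert td[a, leaves[j]] == pytest.approx(D[i, j], abs=1e-9)
        assert total_branch_length(tree) == pytest.approx(total)

    def test_random_additive_matrices_recovered(self, rng):
        """Path distances and total length recovered for random 4-8 taxon
        trees; skbio's NJ agrees on the total length."""
        import skbio.tree

        for _ in range(25):
            n = int(rng.integers(4, 9))
            leaves, D, total = random_additive_case(rng, n)
            dm = DistanceMatrix(D, ids=leaves)
            tree = nj_tree(dm)
            td = tree.tip_tip_distances()
            for i in range(n):
                for j in range(i + 1, n):
                    assert td[leaves[i], leaves[j]] == pytest.approx(D[i, j], abs=1e-8)
            assert total_branch_length(tree) == pytest.approx(total, abs=1e-8)
            assert total_branch_length(skbio.tree.nj(dm)) == pytest.approx(total, abs=1e-8)

    def test_equidistant_star_gives_half_terminal_edges(self):
        d = np.full((5, 5), 1.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(d, ids=list("abcde")))
        for tip in tree.tips():
            assert tip.length == pytest.approx(0.5)

    def test_input_order_invariance_of_total_length(self, rng):
        leaves, D, _ = random_additive_case(rng, 6)
        dm = DistanceMatrix(D, ids=leaves)
        perm = list(rng.permutation(len(leaves)))
        D2 = D[np.ix_(perm, perm)]
        dm2 = DistanceMatrix(D2, ids=[leaves[i] for i in perm])
        assert total_branch_length(nj_tree(dm)) == pytest.approx(
            total_branch_length(nj_tree(dm2))
        )

    def test_single_taxon_rejected(self):
        with pytest.raises((ParameterError, Exception)):
            nj_tree(DistanceMatrix([[0.0]], ids=["a"]))

    def test_negative_branches_clamped(self, rng):
        """Non-additive noisy matrices never produce negative edges."""
        for _ in range(10):
            n = 6
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = nj_tree(DistanceMatrix(d, ids=[f"s{i}" for i in range(n)]))
            for node in tree.traverse(include_self=False):
                assert node.length >= 0


class TestDistances:
    def test_snp_distance_trivial_and_oracle(self, rng):
        g = pd.DataFrame(
            [[0, 0, 1, 1, 0, 1, 0, 1, 1, 0],
             [1, 1, 0, 0, 1, 0, 1, 0, 0, 1],
             [0, 0, 1, 1, 0, 1, 0, 1, 1, 0]],
            index=["a", "b", "c"],
        )
        d = snp_distance(g)
        assert d["a", "c"] == 0.0
        assert d["a", "b"] == 1.0  # complementary rows
        # random matrix vs brute-force pair loop
        m = pd.DataFrame(rng.integers(0, 2, size=(6, 40)).astype(float),
                         index=[f"s{i}" for i in range(6)])
        m.iloc[0, :5] = np.nan
        d = snp_distance(m)
        for i in range(6):
            for j in range(i + 1, 6):
                xi, xj = m.iloc[i].to_numpy(), m.iloc[j].to_numpy()
                ok = ~(np.isnan(xi) | np.isnan(xj))
                expect = float((xi[ok] != xj[ok]).sum() / ok.sum())
                assert d[f"s{i}", f"s{j}"] == pytest.approx(expect)

    def test_copy_number_distance_345(self):
        cn = pd.DataFrame([[1.0, 1.0], [4.0, 5.0]], index=["a", "b"])
        assert copy_number_distance(cn)["a", "b"] == pytest.approx(5.0)

    def test_copy_number_distance_matches_oracle(self, rng):
        cn = pd.DataFrame(rng.random((5, 8)), index=[f"s{i}" for i in range(5)])
        d = copy_number_distance(cn)
        for i in range(5):
            for j in range(5):
                expect = np.sqrt(((cn.iloc[i] - cn.iloc[j]) ** 2).sum())
                assert d[f"s{i}", f"s{j}"] == pytest.approx(expect)


class TestFlankSnps:
    def _geno(self):
        cols = [("I", p) for p in [5_000, 29_999, 30_000, 40_000, 50_001, 70_001, 70_002, 95_000]]
        cols += [("II", 45_000)]
        return pd.DataFrame(
            np.zeros((3, len(cols))),
            index=["a", "b", "c"],
            columns=pd.MultiIndex.from_tuples(cols),
        )

    def test_flank_window_boundaries(self):
        # region I:50000-70000 with 20 kb flanks: [30000, 50000) and (70000, 90000]
        out = extract_flank_snps(self._geno(), ("I", 50_000, 70_000), 20_000)
        positions = [p for _, p in out.columns]
        assert positions == [30_000, 40_000, 70_001, 70_002]

    def test_inside_region_excluded(self):
        out = extract_flank_snps(self._geno(), ("I", 50_000, 70_000), 20_000)
        assert 50_001 not in [p for _, p in out.columns]

    def test_zero_flank_empty(self):
        assert extract_flank_snps(self._geno(), ("I", 50_000, 70_000), 0).shape[1] == 0

    def test_no_snps_flagged_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pombesv.transience"):
            out = extract_flank_snps(self._geno(), ("MT", 1, 19_382), 20_000)
        assert out.shape[1] == 0
        assert "no flanking SNPs" in caplog.text


class TestRelativeTransience:
    def test_constant_within_cluster_gives_zero(self):
        cn = pd.DataFrame(
            {"cnv": [2.0, 2.0, 1.0, 4.0, 3.0, 1.0]},
            index=["i1", "i2", "o1", "o2", "o3", "o4"],
        )
        res = relative_transience(cn, "cnv", ["i1", "i2"], "k1")
        assert res.sigma_rc == 0.0

    def test_hand_computed_ratio(self):
        """Inside {1,1,2,2} (SD 0.5774) over outside {1,3,1,3,1,3}
        (SD 1.0954) = 0.527."""
        cn = pd.DataFrame(
            {"cnv": [1.0, 1.0, 2.0, 2.0, 1.0, 3.0, 1.0, 3.0, 1.0, 3.0]},
            index=[f"i{k}" for k in range(4)] + [f"o{k}" for k in range(6)],
        )
        res = relative_transience(cn, "cnv", [f"i{k}" for k in range(4)], "k")
        assert res.sigma_ic == pytest.approx(0.57735, abs=1e-4)
        assert res.sigma_oc == pytest.approx(1.09545, abs=1e-4)
        assert res.sigma_rc == pytest.approx(0.527, abs=1e-3)

    def test_scale_invariance(self):
        cn = pd.DataFrame(
            {"cnv": [1.0, 2.0, 1.0, 4.0, 2.0, 0.0]},
            index=["i1", "i2", "o1", "o2", "o3", "o4"],
        )
        base = relative_transience(cn, "cnv", ["i1", "i2"], "k").sigma_rc
        scaled = relative_transience(cn * 7.0, "cnv", ["i1", "i2"], "k").sigma_rc
        assert scaled == pytest.approx(base)

    def test_zero_outside_sd_flagged_not_infinite(self):
        cn = pd.DataFrame(
            {"cnv": [1.0, 2.0, 3.0, 3.0, 3.0, 3.0]},
            index=["i1", "i2", "o1", "o2", "o3", "o4"],
        )
        res = relative_transience(cn, "cnv", ["i1", "i2"], "k")
        assert not res.defined
        assert res.sigma_rc is None

    def test_matched_distributions_give_ratio_near_one(self, rng):
        """With inside and outside drawn from the same distribution, sigma_rc
        sits near 1 (groups large enough to tame the SD-ratio bias)."""
        vals = []
        for s in range(200):
            r = np.random.default_rng(s)
            cn = pd.DataFrame(
                {"c": r.normal(2.0, 0.5, size=50)},
                index=[f"i{k}" for k in range(25)] + [f"o{k}" for k in range(25)],
            )
            res = relative_transience(cn, "c", [f"i{k}" for k in range(25)], "k")
            vals.append(res.sigma_rc)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)


class TestBranchLengthTools:
    def test_normalizer(self):
        assert normalize_to_max([2.0, 4.0, 8.0]) == pytest.approx([0.25, 0.5, 1.0])

    def test_spearman_association_trivial(self):
        rho, _ = branch_length_association([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = branch_length_association([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_sd_drives_tree_length(self, rng):
        """Across synthetic CNVs with varying spread, per-CNV copy-number SD
        and NJ tree total branch length are strongly rank-correlated."""
        n_strains, n_cnvs = 20, 50
        sds = np.exp(rng.uniform(np.log(0.05), np.log(2.0), size=n_cnvs))
        strains = [f"s{i}" for i in range(n_strains)]
        lengths, true_sds = [], []
        for k in range(n_cnvs):
            col = 1.0 + rng.normal(0.0, sds[k], size=n_strains)
            cn = pd.DataFrame({"c": col}, index=strains)
            dm = copy_number_distance(cn)
            lengths.append(total_branch_length(nj_tree(dm)))
            true_sds.append(col.std(ddof=1))
        rho, p = branch_length_association(lengths, true_sds)
        assert rho >= 0.8
        assert p < 0.001
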