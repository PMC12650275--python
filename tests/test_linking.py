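"""Network/module/eigenvector/Mantel machinery with enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score
from skbio import DistanceMatrix
import skbio.stats.distance

from gutlink import linking, synthetic
from gutlink.containers import PhenotypeMatrix


def _df(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestSpearmanAdjacency:
    def test_monotone_pair_always_connected(self):
        ab = _df([[1, 2], [2, 4], [3, 9], [4, 16], [5, 25]])
        net = linking.spearman_adjacency(ab, 1.0)
        assert net.graph.has_edge("f0", "f1")
        assert net.graph["f0"]["f1"]["sign"] == 1

    def test_constant_column_excluded_with_warning(self, caplog):
        ab = _df([[1, 7], [2, 7], [3, 7], [4, 7]])
        with caplog.at_level("WARNING"):
            net = linking.spearman_adjacency(ab, 0.5)
        assert "f1" not in net.graph.nodes
        assert any("constant" in r.message for r in caplog.records)

    def test_rho_matches_rank_formula_with_ties(self):
        """Tied 6-point vectors: edge weight equals Pearson on average ranks."""
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 6.0])
        expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        net = linking.spearman_adjacency(_df(np.c_[x, y]), threshold=0.1)
        assert net.graph["f0"]["f1"]["weight"] == pytest.approx(expected)

    def test_anticorrelated_pair_gets_negative_sign(self):
        ab = _df([[1, 5], [2, 4], [3, 3], [4, 2], [5, 1]])
        net = linking.spearman_adjacency(ab, 0.9)
        assert net.graph["f0"]["f1"]["sign"] == -1


class TestDetectModules:
    def _clique_frame(self, seed=0):
        """Two independent latent factors, 4 followers each + 3 noise columns."""
        rng = np.random.default_rng(seed)
        f1, f2 = rng.standard_normal((2, 30))
        cols = (
            [f1 + 0.05 * rng.standard_normal(30) for _ in range(4)]
            + [f2 + 0.05 * rng.standard_normal(30) for _ in range(4)]
            + [rng.standard_normal(30) for _ in range(3)]
        )
        return _df(np.column_stack(cols))

    def test_two_blocks_found_as_two_modules(self):
        ab = self._clique_frame()
        labels = linking.detect_modules(linking.spearman_adjacency(ab, 0.7), min_size=3)
        mods = {m for m in labels.values() if m != linking.UNASSIGNED}
        assert len(mods) == 2
        assert labels["f0"] == labels["f3"] != labels["f4"] == labels["f7"]

    def test_small_modules_pooled_as_unassigned(self):
        # a 4-ring at threshold 0: every adjacent pair correlated weakly
        rng = np.random.default_rng(1)
        ab = _df(rng.standard_normal((10, 4)))
        labels = linking.detect_modules(linking.spearman_adjacency(ab, 0.0), min_size=5)
        assert set(labels.values()) == {linking.UNASSIGNED}

    def test_planted_partition_recovery_ari(self):
        """Planted 3-block structure recovered at ARI >= 0.9 in >=90% of seeds."""
        good = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            factors = rng.standard_normal((3, 24))
            cols, truth = [], []
            for b in range(3):
                for _ in range(5):
                    cols.append(factors[b] + 0.2 * rng.standard_normal(24))
                    truth.append(b)
            ab = _df(np.column_stack(cols))
            labels = linking.detect_modules(
                linking.spearman_adjacency(ab, 0.7), min_size=3
            )
            pred = [labels[f"f{j}"] for j in range(15)]
            good += adjusted_rand_score(truth, pred) >= 0.9
        assert good >= 18

    def test_deterministic_under_rerun(self):
        ab = self._clique_frame(3)
        net = linking.spearman_adjacency(ab, 0.6)
        assert linking.detect_modules(net) == linking.detect_modules(net)


class TestModuleEigenvector:
    def test_identical_columns_give_unit_variance_explained(self):
        col = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        ab = _df(np.column_stack([col, col, col]))
        me = linking.module_eigenvector(ab, ["f0", "f1", "f2"])
        assert me.variance_explained == pytest.approx(1.0)
        z = (col - col.mean()) / col.std()
        # sign convention orients the score along the (positive) members
        assert me.score.to_numpy() == pytest.approx(z / np.linalg.norm(z))

    def test_two_member_closed_form(self):
        """PC1 share of a standardized 2-column matrix is (1+|r|)/2."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        y = 0.6 * x + 0.8 * rng.standard_normal(40)
        ab = _df(np.column_stack([x, y]))
        r = np.corrcoef(x, y)[0, 1]
        me = linking.module_eigenvector(ab, ["f0", "f1"])
        assert me.variance_explained == pytest.approx((1 + abs(r)) / 2)

    def test_sign_convention_is_deterministic_and_equivariant(self):
        """Flipping every member column flips the oriented score exactly.

        The orientation (mean member-correlation >= 0) removes the arbitrary
        SVD sign, so the result is a deterministic, antisymmetric function of
        the member columns.
        """
        rng = np.random.default_rng(5)
        base = rng.standard_normal((20, 3))
        a = linking.module_eigenvector(_df(base), ["f0", "f1", "f2"])
        b = linking.module_eigenvector(_df(-base), ["f0", "f1", "f2"])
        assert a.score.to_numpy() == pytest.approx(-b.score.to_numpy())
        again = linking.module_eigenvector(_df(base), ["f0", "f1", "f2"])
        assert a.score.to_numpy() == pytest.approx(again.score.to_numpy())

    def test_zero_variance_member_dropped(self, caplog):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(10)
        ab = _df(np.column_stack([x, x * 2, np.full(10, 3.0)]))
        with caplog.at_level("WARNING"):
            me = linking.module_eigenvector(ab, ["f0", "f1", "f2"])
        assert list(me.loadings.index) == ["f0", "f1"]


class TestPhenotypeModules:
    def _phen(self, values, cats=None):
        frame = _df(values, prefix="t")
        cats = cats or {c: "Gut health" for c in frame.columns}
        return PhenotypeMatrix(frame, pd.Series(cats))

    def test_perfect_pairs_recovered(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 15))
        phen = self._phen(np.column_stack([a, a * 2 + 1, b, -b]))
        blocks = linking.phenotype_modules(phen, 2)
        got = {frozenset(blk.traits) for blk in blocks}
        assert got == {frozenset({"t0", "t1"}), frozenset({"t2", "t3"})}

    def test_single_block_is_global_pc(self):
        rng = np.random.default_rng(1)
        phen = self._phen(rng.standard_normal((12, 4)))
        blocks = linking.phenotype_modules(phen, 1)
        assert len(blocks) == 1
        me = linking.module_eigenvector(phen.values, phen.trait_ids)
        assert blocks[0].score.to_numpy() == pytest.approx(me.score.to_numpy())

    def test_too_many_blocks_rejected(self):
        rng = np.random.default_rng(2)
        phen = self._phen(rng.standard_normal((8, 3)))
        with pytest.raises(ValueError):
            linking.phenotype_modules(phen, 4)

    def test_planted_trait_blocks_recovered(self):
        """Generator blocks recovered at ARI >= 0.9."""
        hits = 0
        for s in range(10):
            cfg = synthetic.SynthConfig(seed=s, n_asvs=100, n_diff_asvs=0,
                                        n_modules=2, module_size=4, n_unlinked_blocks=2)
            _, _, truth = synthetic.generate_asv_table(cfg)
            phen = synthetic.generate_phenotypes(truth, cfg)
            blocks = linking.phenotype_modules(phen, 4)
            truth_labels = ["_".join(t.split("_trait")[:1]) for t in phen.trait_ids]
            pred = {t: blk.block_id for blk in blocks for t in blk.traits}
            hits += adjusted_rand_score(
                truth_labels, [pred[t] for t in phen.trait_ids]
            ) >= 0.9
        assert hits >= 9

    def test_category_by_majority(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(15)
        phen = self._phen(
            np.column_stack([a, a + 0.01 * rng.standard_normal(15), rng.standard_normal(15)]),
            cats={"t0": "Gut health", "t1": "Gut health", "t2": "Gut development"},
        )
        blocks = linking.phenotype_modules(phen, 2)
        by_traits = {frozenset(b.traits): b.category for b in blocks}
        assert by_traits[frozenset({"t0", "t1"})] == "Gut health"


def _random_dm(rng, n):
    pts = rng.standard_normal((n, 2))
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(n)])


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _random_dm(np.random.default_rng(0), 6)
        r, p = linking.mantel(d, d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_exact_enumeration_matches_brute_force_oracle(self):
        """n=4: p over all 24 label permutations, recomputed independently."""
        rng = np.random.default_rng(3)
        d1, d2 = _random_dm(rng, 4), _random_dm(rng, 4)
        r_obs, p = linking.mantel(d1, d2, exact=True)

        def spearman_condensed(a, b):
            iu = np.triu_indices(4, 1)
            return np.corrcoef(sps.rankdata(a[iu]), sps.rankdata(b[iu]))[0, 1]

        m1, m2 = np.asarray(d1.data), np.asarray(d2.data)
        assert r_obs == pytest.approx(spearman_condensed(m1, m2))
        hits = 0
        for sigma in itertools.permutations(range(4)):
            perm = m2[np.ix_(sigma, sigma)]
            hits += spearman_condensed(m1, perm) >= r_obs - 1e-12
        assert p == pytest.approx(hits / 24)

    def test_matches_reference_mantel_r(self):
        rng = np.random.default_rng(9)
        d1, d2 = _random_dm(rng, 10), _random_dm(rng, 10)
        r, _ = linking.mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            d1, d2, method="spearman", permutations=0
        )
        assert r == pytest.approx(float(r_ref), abs=1e-10)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        d1 = _random_dm(rng, 5)
        d2 = DistanceMatrix(np.asarray(d1.data), ids=list("abcde"))
        with pytest.raises(ValueError):
            linking.mantel(d1, d2)

    def test_null_pvalues_uniform(self):
        """Independent matrices: p ~ U(0,1) (KS at alpha=0.01 over 200 seeds)."""
        from gutlink import benchmarks

        ps = benchmarks.mantel_null_pvalues(n_seeds=200)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestLinkModules:
    def test_block_equal_to_module_eigenvector_links_significantly(self):
        rng = np.random.default_rng(4)
        ab = _df(np.column_stack([rng.standard_normal(12)] * 2) + 0.01 * rng.standard_normal((12, 2)))
        me = linking.module_eigenvector(ab, ["f0", "f1"])
        pe = linking.PhenotypeEigengene(
            block_id=1, label="b1", traits=["t"], score=me.score.copy(),
            category="Gut health", variance_explained=1.0,
        )
        report = linking.link_modules([me], [pe], n_perm=199, seed=0)
        row = report.pairs.iloc[0]
        assert row["mantel_r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_planted_link_recovered_with_planted_drivers_on_top(self):
        from gutlink import benchmarks

        out = benchmarks.link_recovery_trial(seed=1, module_phenotype_r=0.9)
        assert out["sole_planted_link"]
        assert out["biomarkers_planted"] >= 3

    def test_independent_blocks_mostly_silent(self):
        from gutlink import benchmarks

        assert benchmarks.link_null_rate(n_seeds=10, seed0=500) >= 0.9


class TestSensitivity:
    def test_identical_partitions_full_jaccard(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(30)
        cols = [f + 0.02 * rng.standard_normal(30) for _ in range(5)]
        cols += [rng.standard_normal(30) for _ in range(4)]
        ab = _df(np.column_stack(cols))
        rep = linking.sensitivity_check(ab, 0.7, 0.8)
        assert (rep.table["jaccard"] == 1.0).all()
        assert rep.table["recovered"].all()

    def test_strong_module_survives_stricter_threshold(self):
        cfg = synthetic.SynthConfig(
            seed=8, n_asvs=150, n_diff_asvs=0, n_modules=1, module_size=8,
            module_noise_sd=0.15, n_linked_modules=1,
        )
        table, _, truth = synthetic.generate_asv_table(cfg)
        from gutlink import profiles

        rel = profiles.relative_abundance(table)
        keep = sorted(truth.module_membership) + [
            a for a in table.asv_ids
            if a not in truth.module_membership and (table.counts[a] > 0).sum() >= 10
        ][:15]
        ab = np.log2(rel[keep] + 1e-6)
        rep = linking.sensitivity_check(ab, 0.7, 0.8)
        planted_rows = rep.table[rep.table["jaccard"] > 0]
        assert rep.table["recovered"].any()

    def test_invalid_threshold_order_rejected(self):
        rng = np.random.default_rng(1)
        ab = _df(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError):
            linking.sensitivity_check(ab, 0.8, 0.7)
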