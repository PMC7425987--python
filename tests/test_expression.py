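"""Normalization, sphericity, correlation PCA, gene selection, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from clonalrhythm import (
    CountMatrix,
    ExpressionSimConfig,
    bartlett_sphericity,
    broken_stick_proportions,
    correlation_pca,
    generate_expression_panel,
    hierarchical_cluster,
    nanostring_normalize,
    optimal_k_scan,
    select_top_genes,
    spread_clone_panel,
)
from clonalrhythm.simulate import expected_log2_expression


def tiny_count_matrix(endogenous: dict[str, list[int]],
                      pos=None, neg=None, hk=None) -> CountMatrix:
    n = len(next(iter(endogenous.values())))
    pos = pos or {"POS_A": [1000] * n, "POS_B": [4000] * n}
    neg = neg or {"NEG_A": [20] * n, "NEG_B": [24] * n}
    hk = hk or {"HK_1": [2000] * n, "HK_2": [3000] * n}
    counts = pd.DataFrame({**endogenous, **pos, **neg, **hk})
    classes = pd.Series(
        ["endogenous"] * len(endogenous) + ["positive"] * len(pos)
        + ["negative"] * len(neg) + ["housekeeping"] * len(hk),
        index=list(endogenous) + list(pos) + list(neg) + list(hk),
    )
    return CountMatrix(counts=counts, probe_class=classes)


class TestNormalization:
    def test_pure_technical_scale_is_removed(self):
        cm = tiny_count_matrix(
            {"G1": [800, 1600], "G2": [300, 600]},
            pos={"POS_A": [1000, 2000], "POS_B": [4000, 8000]},
            neg={"NEG_A": [20, 20], "NEG_B": [24, 24]},
            hk={"HK_1": [2000, 4000], "HK_2": [3000, 6000]},
        )
        norm = nanostring_normalize(cm)
        np.testing.assert_allclose(
            norm.log2.iloc[0].to_numpy(), norm.log2.iloc[1].to_numpy(), atol=0.05
        )

    def test_background_floor_yields_log2_zero(self):
        # endogenous counts equal to background are floored to 1 count
        cm = tiny_count_matrix(
            {"G1": [22, 22]},
            neg={"NEG_A": [20, 20], "NEG_B": [24, 24]},
            hk={"HK_1": [1000, 1000], "HK_2": [1000, 1000]},
        )
        norm = nanostring_normalize(cm)
        np.testing.assert_allclose(norm.log2["G1"].to_numpy(), 0.0, atol=1e-9)

    def test_round_trip_recovers_generator_relative_means(self):
        """Normalized log2 differences track the generator's true means."""
        clones = spread_clone_panel(30)
        cfg = ExpressionSimConfig()
        cm = generate_expression_panel(clones, cfg, seed=5)
        norm = nanostring_normalize(cm)
        for gene, arch in (("ARNTL2", "linear_pos"), ("DBP", "linear_neg"),
                           ("CLOCK", "inverted_U")):
            observed = norm.log2[gene].to_numpy()
            expected = np.array(
                [expected_log2_expression(arch, c.realized_period, cfg)
                 for c in clones]
            )
            # shared offsets cancel in centred comparison
            resid = (observed - observed.mean()) - (expected - expected.mean())
            assert np.abs(resid).mean() < 2 * cfg.dispersion

    def test_idempotence_after_resetting_controls(self):
        # feed normalized endogenous counts back in with neutral controls
        # (identical across samples, zero background): a second pass must
        # change nothing beyond count rounding
        clones = spread_clone_panel(10)
        cm = generate_expression_panel(clones, ExpressionSimConfig(), seed=8)
        first = nanostring_normalize(cm)
        n = len(first.log2)
        endo = (2.0 ** first.log2).round().clip(lower=0).astype(int)
        neutral = {"POS_A": [1000] * n, "POS_B": [4000] * n,
                   "NEG_A": [0] * n, "NEG_B": [0] * n,
                   "HK_1": [2000] * n, "HK_2": [2000] * n}
        counts = pd.concat([endo.reset_index(drop=True),
                            pd.DataFrame(neutral)], axis=1)
        classes = pd.Series(
            ["endogenous"] * endo.shape[1] + ["positive"] * 2
            + ["negative"] * 2 + ["housekeeping"] * 2,
            index=list(endo.columns) + list(neutral),
        )
        renorm = nanostring_normalize(
            CountMatrix(counts=counts, probe_class=classes)
        )
        assert np.abs(
            renorm.log2.to_numpy() - first.log2.to_numpy()
        ).max() < 0.05

    def test_dropped_probe_excluded(self, expression_panel):
        norm = nanostring_normalize(expression_panel, drop_probes=["ARNTL2"])
        assert "ARNTL2" not in norm.log2.columns
        assert norm.dropped_probes == ["ARNTL2"]


class TestBartlettSphericity:
    def test_independent_variables_accept_sphericity(self, rng):
        x = pd.DataFrame(rng.normal(size=(500, 5)))
        res = bartlett_sphericity(x)
        assert res.p_value > 0.01 and not res.singular

    def test_perfect_collinearity_flags_singular(self, rng):
        a = rng.normal(size=200)
        x = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=200)})
        res = bartlett_sphericity(x)
        assert res.singular

    def test_matches_hand_formula_on_fixture(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 3)))
        x["2"] = x[1] * 0.6 + x[2] * 0.8
        x = x.iloc[:, :3]
        res = bartlett_sphericity(x)
        n, p = x.shape
        r = np.corrcoef(x.to_numpy(), rowvar=False)
        chi2 = -(n - 1 - (2 * p + 5) / 6) * math.log(np.linalg.det(r))
        assert res.chi2 == pytest.approx(chi2, rel=1e-9)
        assert res.df == p * (p - 1) // 2


class TestCorrelationPCA:
    def test_eigenvalue_sum_equals_gene_count(self, expression_panel):
        pca = correlation_pca(nanostring_normalize(expression_panel).log2)
        assert pca.eigenvalues.sum() == pytest.approx(19.0, abs=1e-9)
        assert pca.proportion.sum() == pytest.approx(1.0)

    def test_two_perfectly_correlated_genes_give_single_pc(self, rng):
        a = rng.normal(size=50)
        x = pd.DataFrame({"g1": a, "g2": 3 * a + 1})
        pca = correlation_pca(x)
        assert pca.proportion[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_eigendecomposition(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 6)))
        pca = correlation_pca(x)
        r = np.corrcoef(x.to_numpy(), rowvar=False)
        oracle = np.sort(np.linalg.eigvalsh(r))[::-1]
        np.testing.assert_allclose(pca.eigenvalues, oracle, atol=1e-9)

    def test_scores_covariance_is_diagonal_eigenvalues(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 5)))
        x["4"] = x[0] * 0.5 + x[4]
        pca = correlation_pca(x)
        cov = np.cov(pca.scores.to_numpy(), rowvar=False)
        np.testing.assert_allclose(np.diag(cov), pca.eigenvalues, atol=1e-9)
        off = cov - np.diag(np.diag(cov))
        np.testing.assert_allclose(off, 0.0, atol=1e-9)

    def test_contributions_sum_to_100_per_pc(self, expression_panel):
        pca = correlation_pca(nanostring_normalize(expression_panel).log2)
        np.testing.assert_allclose(
            pca.contributions.sum(axis=0).to_numpy(), 100.0, atol=1e-9
        )

    def test_loading_sign_convention(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 4)))
        pca = correlation_pca(x)
        for col in pca.loadings.columns:
            v = pca.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] >= 0

    def test_missing_values_rejected(self):
        x = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            correlation_pca(x)


class TestBrokenStick:
    def test_p3_harmonic_values(self):
        np.testing.assert_allclose(
            broken_stick_proportions(3),
            [11 / 18, 5 / 18, 2 / 18],
            atol=1e-12,
        )

    def test_equal_eigenvalues_retain_single_pc_with_warning(self, rng):
        # independent genes: all proportions ~ 1/p < b_1 -> keep PC1, warn
        x = pd.DataFrame(rng.normal(size=(2000, 5)))
        pca = correlation_pca(x)
        assert pca.n_retained == 1
        assert "broken-stick" in pca.retention_warning

    def test_strong_two_factor_panel_retains_two_pcs(self):
        # panel dominated by one linear and one inverted-U expression factor
        cfg = ExpressionSimConfig(
            gene_archetypes={
                "L1": "linear_pos", "L2": "linear_pos", "L3": "linear_neg",
                "L4": "linear_neg", "L5": "linear_pos",
                "U1": "inverted_U", "U2": "inverted_U", "U3": "inverted_U",
                "U4": "inverted_U", "U5": "inverted_U",
            },
            dispersion=0.08,
        )
        cm = generate_expression_panel(spread_clone_panel(25), cfg, seed=13)
        pca = correlation_pca(nanostring_normalize(cm).log2)
        assert pca.n_retained == 2


class TestSelectTopGenes:
    def test_quarter_of_nineteen_is_five(self, expression_panel):
        pca = correlation_pca(nanostring_normalize(expression_panel).log2)
        assert len(select_top_genes(pca, pc=1, fraction=0.25)) == 5

    def test_fraction_one_returns_all_ordered(self, expression_panel):
        pca = correlation_pca(nanostring_normalize(expression_panel).log2)
        top = select_top_genes(pca, pc=1, fraction=1.0)
        assert len(top) == 19
        contribs = [pca.contributions.loc[g, "PC1"] for g in top]
        assert contribs == sorted(contribs, reverse=True)

    def test_invalid_fraction_rejected(self, expression_panel):
        pca = correlation_pca(nanostring_normalize(expression_panel).log2)
        with pytest.raises(ValueError):
            select_top_genes(pca, pc=1, fraction=1.5)

    def test_signal_genes_top_the_period_pc(self):
        """When 5 of 19 genes carry the period signal, they top the PC."""
        signal = {"S1", "S2", "S3", "S4", "S5"}
        arch = {g: ("linear_pos" if i % 2 else "linear_neg")
                for i, g in enumerate(sorted(signal))}
        arch.update({f"F{i:02d}": "flat" for i in range(14)})
        cfg = ExpressionSimConfig(gene_archetypes=arch)
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            cm = generate_expression_panel(
                spread_clone_panel(25), cfg, seed=300 + rep
            )
            pca = correlation_pca(nanostring_normalize(cm).log2)
            # the period-separating PC: scores correlate most with period
            periods = cm.periods.to_numpy()
            rho = [
                abs(np.corrcoef(pca.scores[f"PC{k}"].to_numpy(), periods)[0, 1])
                for k in range(1, 4)
            ]
            pc = int(np.argmax(rho)) + 1
            hits += set(select_top_genes(pca, pc=pc, fraction=0.25)) == signal
        assert hits / n_rep >= 0.95

    def test_archetype_blocks_split_across_leading_pcs(self):
        """Linear and inverted-U genes load on different leading PCs."""
        cm = generate_expression_panel(
            spread_clone_panel(25), ExpressionSimConfig(), seed=41
        )
        pca = correlation_pca(nanostring_normalize(cm).log2)
        linear = {"ARNTL2", "BHLHE40", "DBP", "NR1D2", "PER2"}
        inverted = {"NR1D1", "CLOCK", "CSNK1D", "CIPC", "NFIL3"}
        top1 = set(select_top_genes(pca, pc=1, fraction=0.25))
        top2 = set(select_top_genes(pca, pc=2, fraction=0.25))
        # each leading PC is dominated by one archetype block
        assert (len(top1 & linear) >= 3 and len(top2 & inverted) >= 3) or (
            len(top1 & inverted) >= 3 and len(top2 & linear) >= 3
        )


class TestHierarchicalClustering:
    def test_three_period_groups_recovered(self):
        # well-separated short/intermediate/long period groups
        taus = [22.2] * 8 + [25.0] * 9 + [27.9] * 8
        from clonalrhythm import CloneRecord

        clones = [CloneRecord(f"c{i:02d}", 0, None, t, t)
                  for i, t in enumerate(taus)]
        cfg = ExpressionSimConfig(dispersion=0.08)
        cm = generate_expression_panel(clones, cfg, seed=17)
        norm = nanostring_normalize(cm)
        pca = correlation_pca(norm.log2)
        periods = cm.periods.to_numpy()
        rho = [abs(np.corrcoef(pca.scores[f"PC{k}"], periods)[0, 1])
               for k in (1, 2)]
        genes = select_top_genes(pca, pc=int(np.argmax(rho)) + 1)
        dendro = hierarchical_cluster(norm.log2, genes=genes, n_clusters=3)
        labels = dendro.labels.to_numpy()
        truth = np.array([0] * 8 + [1] * 9 + [2] * 8)
        # cluster labels match the period groups up to permutation
        from scipy.stats import mode

        remap = {}
        for c in np.unique(labels):
            remap[c] = mode(truth[labels == c]).mode
        mapped = np.array([remap[c] for c in labels])
        assert (mapped == truth).mean() >= 0.9

    def test_duplicate_samples_merge_at_height_zero(self):
        x = pd.DataFrame(
            [[1.0, 2.0, 0.5], [1.0, 2.0, 0.5], [5.0, 1.0, 2.0],
             [4.0, 0.0, 9.0]],
            index=["a", "a2", "b", "c"],
        )
        dendro = hierarchical_cluster(x, n_clusters=2, standardize=False)
        assert dendro.linkage[0, 2] == pytest.approx(0.0)
        assert dendro.labels["a"] == dendro.labels["a2"]

    def test_four_point_planar_fixture_matches_hand_dendrogram(self):
        # points on a line: 0, 1, 10, 12 -> merges at 1, 2, then 12
        x = pd.DataFrame({"u": [0.0, 1.0, 10.0, 12.0],
                          "v": [0.0, 0.0, 0.0, 0.0]},
                         index=list("abcd"))
        dendro = hierarchical_cluster(x, n_clusters=2, standardize=False)
        heights = sorted(dendro.linkage[:, 2])
        np.testing.assert_allclose(heights, [1.0, 2.0, 12.0])

    def test_newick_serialization_contains_all_samples(self):
        x = pd.DataFrame(np.eye(4) * 3.0, index=list("wxyz"))
        nwk = hierarchical_cluster(x, n_clusters=2, standardize=False).newick()
        for name in "wxyz":
            assert name in nwk
        assert nwk.endswith(";")

    def test_too_many_clusters_rejected(self):
        x = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            hierarchical_cluster(x, n_clusters=5)


class TestOptimalKScan:
    def test_two_separated_blobs_agree_on_k2(self, rng):
        a = rng.normal(0, 0.3, size=(20, 3))
        b = rng.normal(5, 0.3, size=(20, 3))
        x = pd.DataFrame(np.vstack([a, b]))
        report = optimal_k_scan(x, k_range=range(1, 7), standardize=False,
                                seed=0)
        assert report.optimal["silhouette"] == 2
        assert report.optimal["CH"] == 2
        assert report.optimal["gap"] == 2
        assert report.consensus_k == 2

    def test_single_gaussian_gap_chooses_k1(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 2)))
        report = optimal_k_scan(x, k_range=range(1, 7), standardize=False,
                                seed=0)
        assert report.optimal["gap"] == 1

    def test_wss_nonincreasing_and_zero_at_n(self, rng):
        x = pd.DataFrame(rng.normal(size=(12, 2)))
        report = optimal_k_scan(x, k_range=range(1, 13), standardize=False,
                                seed=0)
        wss = [report.wss[k] for k in report.k_range]
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))
        assert report.wss[12] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_identical_points_reports_k1(self):
        x = pd.DataFrame(np.ones((10, 3)))
        report = optimal_k_scan(x, standardize=False, seed=0)
        assert report.degenerate and report.consensus_k == 1
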