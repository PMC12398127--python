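import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hs

from celiarank.de import (
    DEConfig,
    bh_adjust,
    build_design,
    compute_cpm,
    compute_fpkm,
    ebayes_moderate,
    estimate_variance_prior,
    filter_low_expression,
    fit_weighted_lm,
    run_comparison,
    run_tissue_comparisons,
    tmm_norm_factors,
    voom_transform,
)
from celiarank.simulate import CohortConfig, EffectConfig, simulate_cohort
from celiarank.types import CountMatrix, ValidationError

from conftest import make_metadata


def _cm(array, genes=None, samples=None):
    array = np.asarray(array)
    genes = genes or [f"G{i}" for i in range(array.shape[0])]
    samples = samples or [f"S{j}" for j in range(array.shape[1])]
    return CountMatrix(pd.DataFrame(array, index=genes, columns=samples))


class TestFilter:
    def test_min_cpm_zero_is_identity(self, tiny_counts):
        out = filter_low_expression(tiny_counts, min_cpm=0.0, min_samples=1)
        assert list(out.gene_ids) == list(tiny_counts.gene_ids)

    def test_all_zero_gene_removed(self):
        cm = _cm([[0, 0, 0], [5, 5, 5]])
        out = filter_low_expression(cm, min_cpm=1.0, min_samples=1)
        assert list(out.gene_ids) == ["G1"]

    def test_matches_brute_force_scan(self, two_group_cohort):
        _, _, counts = two_group_cohort
        out = filter_low_expression(counts, min_cpm=1.0, min_samples=6)
        # independent two-loop scan
        y = counts.counts.to_numpy(float)
        lib = y.sum(axis=0)
        kept = []
        for g in range(y.shape[0]):
            n_ok = 0
            for j in range(y.shape[1]):
                if y[g, j] / lib[j] * 1e6 >= 1.0:
                    n_ok += 1
            if n_ok >= 6:
                kept.append(counts.gene_ids[g])
        assert list(out.gene_ids) == kept

    def test_filter_removing_everything_raises(self):
        cm = _cm([[1, 1], [1, 1]])
        with pytest.raises(ValidationError, match="filter"):
            filter_low_expression(cm, min_cpm=1e9, min_samples=1)


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        col = np.array([10, 200, 30, 4000, 50])
        cm = _cm(np.tile(col[:, None], (1, 4)))
        f = tmm_norm_factors(cm)
        assert np.allclose(f, 1.0)

    def test_depth_scaling_leaves_factor_unit(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 2000, size=300)
        cm = _cm(np.column_stack([base, base * 2, base]))
        f = tmm_norm_factors(cm)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_direct_formula_on_toy_matrix(self):
        rng = np.random.default_rng(42)
        y = rng.integers(1, 500, size=(40, 3)).astype(float)
        cm = _cm(y.astype(int))
        f = tmm_norm_factors(cm).to_numpy()

        # brute-force transcription of the trimmed weighted-mean formula
        lib = y.sum(axis=0)
        uq = np.quantile(y, 0.75, axis=0) / lib
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        expected = np.ones(3)
        for k in range(3):
            m = np.log2((y[:, k] / lib[k]) / (y[:, ref] / lib[ref]))
            a = 0.5 * np.log2((y[:, k] / lib[k]) * (y[:, ref] / lib[ref]))
            w = (lib[k] - y[:, k]) / (lib[k] * y[:, k]) + (lib[ref] - y[:, ref]) / (
                lib[ref] * y[:, ref]
            )
            if np.max(np.abs(m)) < 1e-6:
                expected[k] = 1.0
                continue
            n = len(m)
            import scipy.stats as st

            rm, ra = st.rankdata(m), st.rankdata(a)
            lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
            keep = (
                (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
            )
            expected[k] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f, expected, rtol=1e-12)

    def test_all_zero_sample_rejected_by_name(self):
        cm = _cm([[1, 0], [2, 0]], samples=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            tmm_norm_factors(cm)


class TestCPMFPKM:
    def test_cpm_unit_case(self):
        cm = _cm([[10], [10**6 - 10]])
        out = compute_cpm(cm)
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_log_cpm_finite_on_zero_count(self):
        cm = _cm([[0, 5], [100, 100]])
        out = compute_cpm(cm, log=True)
        assert np.isfinite(out.to_numpy()).all()

    def test_cpm_column_sums_equal_million(self):
        rng = np.random.default_rng(1)
        cm = _cm(rng.integers(0, 100, size=(50, 4)))
        out = compute_cpm(cm)
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_fpkm_unit_case(self):
        counts = pd.DataFrame({"S1": [100, 10**6 - 100]}, index=["GA", "GB"])
        cm = CountMatrix(counts, pd.Series([1000, 1000], index=["GA", "GB"]))
        out = compute_fpkm(cm)
        assert out.loc["GA", "S1"] == pytest.approx(100.0)

    def test_fpkm_halves_when_length_doubles(self, tiny_counts):
        out1 = compute_fpkm(tiny_counts)
        doubled = CountMatrix(tiny_counts.counts, tiny_counts.gene_lengths * 2)
        out2 = compute_fpkm(doubled)
        assert np.allclose(out2.to_numpy(), out1.to_numpy() / 2)

    def test_fpkm_matches_elementwise_oracle(self, tiny_counts):
        out = compute_fpkm(tiny_counts)
        y = tiny_counts.counts.to_numpy(float)
        lib = y.sum(axis=0)
        for g in range(y.shape[0]):
            for j in range(y.shape[1]):
                expected = y[g, j] / (
                    tiny_counts.gene_lengths.iloc[g] / 1e3 * lib[j] / 1e6
                )
                assert out.iloc[g, j] == pytest.approx(expected)

    def test_fpkm_requires_lengths(self):
        cm = _cm([[1, 2], [3, 4]])
        with pytest.raises(ValidationError, match="length"):
            compute_fpkm(cm)


class TestVoom:
    def test_weights_strictly_positive(self, two_group_cohort):
        meta, _, counts = two_group_cohort
        f = tmm_norm_factors(counts)
        design = build_design(meta)
        v = voom_transform(counts, f, design)
        assert (v.weights.to_numpy() > 0).all()
        assert np.isfinite(v.weights.to_numpy()).all()

    def test_flat_variance_data_gives_flat_weights(self):
        # deeply sequenced counts with shared dispersion: log-scale variance
        # ~ 1/mu + phi ~ phi for all genes, so the trend is flat and the
        # weights nearly equal despite a spread of means
        cfg = CohortConfig(
            n_genes=2000,
            group_sizes={"biopsy": {"control": 40}},
            n_patients={"control": 40},
            baseline_log_sd=0.5,
            library_size_range=(2e7, 2e7),
            dispersion_median=0.1,
            dispersion_log_sd=0.0,
            covariate_effect_sd=0.0,
            effect_config=EffectConfig(proportion_de=0.0),
        )
        meta, truth, counts = simulate_cohort(cfg, 5)
        f = tmm_norm_factors(counts)
        design = build_design(meta)
        v = voom_transform(counts, f, design)
        w = v.weights.to_numpy()
        assert w.max() / w.min() < 1.5

    def test_nb_variance_trend_gives_increasing_weights(self):
        # Poisson-like counts: sd of log-CPM falls with abundance, so
        # weight should rise with fitted log-count
        cfg = CohortConfig(
            n_genes=2000,
            group_sizes={"biopsy": {"control": 40}},
            n_patients={"control": 40},
            dispersion_median=0.0,
            covariate_effect_sd=0.0,
            effect_config=EffectConfig(proportion_de=0.0),
        )
        meta, truth, counts = simulate_cohort(cfg, 6)
        f = tmm_norm_factors(counts)
        v = voom_transform(counts, f, build_design(meta))
        ty = v.trend_points[:, 1]
        assert ty[0] > ty[-1]  # sqrt-sd decreases with abundance
        # weight is a steep convex transform of the trend, so check the
        # ordering: per-gene mean weight rises with average abundance
        import scipy.stats as st

        mean_w = v.weights.mean(axis=1).to_numpy()
        rho = st.spearmanr(v.amean.to_numpy(), mean_w).statistic
        assert rho > 0.8

    def test_too_few_genes_rejected(self, two_group_cohort):
        meta, _, counts = two_group_cohort
        small = counts.subset_genes(counts.gene_ids[:5])
        with pytest.raises(ValidationError, match="few genes"):
            voom_transform(small, tmm_norm_factors(small), build_design(meta))


class TestWeightedLM:
    @staticmethod
    def _unit_voom(y, samples):
        from celiarank.de import VoomFit

        genes = [f"G{i}" for i in range(y.shape[0])]
        ones = np.ones_like(y)
        return VoomFit(
            logcpm=pd.DataFrame(y, index=genes, columns=samples),
            weights=pd.DataFrame(ones, index=genes, columns=samples),
            trend_points=np.array([[0.0, 1.0], [1.0, 1.0]]),
            amean=pd.Series(y.mean(axis=1), index=genes),
        )

    def test_unit_weights_two_group_equals_mean_difference(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(30, 10))
        samples = [f"S{j}" for j in range(10)]
        design = pd.DataFrame(
            {"intercept": np.ones(10), "group": [0] * 5 + [1] * 5}, index=samples
        )
        fit = fit_weighted_lm(self._unit_voom(y, samples), design)
        expected = y[:, 5:].mean(axis=1) - y[:, :5].mean(axis=1)
        assert np.allclose(fit.coefficients["group"], expected)

    def test_weight_scale_invariance(self, two_group_cohort):
        meta, _, counts = two_group_cohort
        f = tmm_norm_factors(counts)
        design = build_design(meta)
        v = voom_transform(counts, f, design)
        fit1 = fit_weighted_lm(v, design)
        from celiarank.de import VoomFit

        v2 = VoomFit(v.logcpm, v.weights * 2.0, v.trend_points, v.amean)
        fit2 = fit_weighted_lm(v2, design)
        assert np.allclose(
            fit1.coefficients.to_numpy(), fit2.coefficients.to_numpy()
        )

    def test_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(7)
        n, p, G = 12, 3, 8
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        Y = rng.normal(size=(G, n))
        W = rng.uniform(0.5, 2.0, size=(G, n))
        samples = [f"S{j}" for j in range(n)]
        from celiarank.de import VoomFit

        design = pd.DataFrame(X, index=samples, columns=["intercept", "x1", "x2"])
        genes = [f"G{i}" for i in range(G)]
        v = VoomFit(
            pd.DataFrame(Y, index=genes, columns=samples),
            pd.DataFrame(W, index=genes, columns=samples),
            np.array([[0.0, 1.0], [1.0, 1.0]]),
            pd.Series(Y.mean(axis=1), index=genes),
        )
        fit = fit_weighted_lm(v, design)
        for g in range(G):
            Wg = np.diag(W[g])
            beta = np.linalg.solve(X.T @ Wg @ X, X.T @ Wg @ Y[g])
            assert np.allclose(fit.coefficients.iloc[g].to_numpy(), beta)
            r = Y[g] - X @ beta
            s2 = (W[g] * r**2).sum() / (n - X.shape[1])
            assert fit.sigma.iloc[g] ** 2 == pytest.approx(s2)

    def test_rank_deficiency_names_columns(self):
        n = 8
        samples = [f"S{j}" for j in range(n)]
        X = pd.DataFrame(
            {"intercept": np.ones(n), "a": np.arange(n), "b": 2.0 * np.arange(n)},
            index=samples,
        )
        y = np.random.default_rng(0).normal(size=(12, n))
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_weighted_lm(self._unit_voom(y, samples), X)


class TestModeration:
    def test_posterior_variance_between_prior_and_observed(self, two_group_cohort):
        meta, _, counts = two_group_cohort
        f = tmm_norm_factors(counts)
        design = build_design(meta)
        fit = fit_weighted_lm(voom_transform(counts, f, design), design)
        mod = ebayes_moderate(fit, {"pheno_a-CD": 1.0})
        s2 = fit.sigma.to_numpy() ** 2
        lo = np.minimum(s2, mod.s2_prior)
        hi = np.maximum(s2, mod.s2_prior)
        post = mod.s2_post.to_numpy()
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_homoscedastic_variances_give_large_prior_df(self):
        rng = np.random.default_rng(3)
        d = 20
        s2 = rng.chisquare(d, size=2000) / d * 0.7  # one shared true variance
        d0, s0 = estimate_variance_prior(s2, d)
        assert d0 > 50
        assert s0 == pytest.approx(0.7, rel=0.1)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            estimate_variance_prior(np.zeros(100), 10)


class TestBH:
    def test_hand_step_up_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @given(
        hs.lists(hs.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_brute_force_and_contract(self, pvals):
        p = np.asarray(pvals)
        out = bh_adjust(p)
        # brute-force step-up: sort, p*m/rank, cumulative min from the top
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = p[order] * m / np.arange(1, m + 1)
        for i in range(m - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(out, expected)
        assert np.all(out >= p - 1e-15) and np.all(out <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestRunComparison:
    def test_group_swap_negates_log2fc_exactly(self):
        cfg = CohortConfig(
            n_genes=300,
            group_sizes={"biopsy": {"a-CD": 10, "control": 10}},
            n_patients={"a-CD": 10, "control": 10},
        )
        meta, truth, counts = simulate_cohort(cfg, 4)
        res = run_comparison(counts, meta, "aCD_vs_ctrl", DEConfig(mode="subset"))
        swapped = meta.table.copy()
        swapped["phenotype"] = swapped["phenotype"].map(
            {"a-CD": "control", "control": "a-CD"}
        )
        from celiarank.types import SampleMetadata

        res2 = run_comparison(
            counts, SampleMetadata(swapped), "aCD_vs_ctrl", DEConfig(mode="subset")
        )
        a = res.set_index("gene")
        b = res2.set_index("gene").loc[a.index]
        assert np.allclose(a["log2FC"], -b["log2FC"])
        assert np.allclose(a["p"], b["p"])

    def test_depth_scaling_leaves_log2fc_invariant(self, two_group_cohort):
        meta, _, counts = two_group_cohort
        res1 = run_comparison(counts, meta, "aCD_vs_ctrl")
        scaled = CountMatrix(counts.counts * 3)
        res2 = run_comparison(scaled, meta, "aCD_vs_ctrl")
        a = res1.set_index("gene")["log2FC"]
        b = res2.set_index("gene")["log2FC"].reindex(a.index)
        # invariance is exact up to the 0.5 prior offset, which matters
        # only for near-zero counts
        assert np.corrcoef(a, b)[0, 1] > 0.999
        assert np.median(np.abs(a - b)) < 0.02
        assert np.max(np.abs(a - b)) < 0.2

    def test_power_increases_with_effect_size(self):
        rates = []
        for lfc in (0.5, 1.0, 2.0):
            cfg = CohortConfig(
                n_genes=800,
                group_sizes={"biopsy": {"a-CD": 15, "control": 15}},
                n_patients={"a-CD": 15, "control": 15},
                effect_config=EffectConfig(
                    proportion_de=0.2, lfc_magnitude=lfc, lfc_magnitude_sd=0.0
                ),
            )
            meta, truth, counts = simulate_cohort(cfg, 19)
            res = run_comparison(counts, meta, "aCD_vs_ctrl").set_index("gene")
            nn = truth["lfc_aCD"] != 0
            rates.append((res.loc[nn[nn].index, "adjP"] < 0.05).mean())
        assert rates[0] < rates[1] < rates[2]

    def test_small_group_rejected(self):
        meta = make_metadata({"a-CD": 1, "control": 10})
        cfg = CohortConfig(n_genes=50, group_sizes={"biopsy": {"a-CD": 1, "control": 10}},
                           n_patients={"a-CD": 1, "control": 10})
        truth = simulate_truth_for(meta, cfg)
        with pytest.raises(ValidationError, match="a-CD"):
            run_comparison(truth, meta, "aCD_vs_ctrl")

    def test_joint_and_subset_modes_agree_on_direction(self, table1_cohort):
        _, meta, truth, counts = table1_cohort
        mt = meta.for_tissue("biopsy")
        cm = counts.subset_samples(mt.sample_ids)
        joint = run_comparison(cm, mt, "aCD_vs_ctrl", DEConfig(mode="joint"))
        sub = run_comparison(cm, mt, "aCD_vs_ctrl", DEConfig(mode="subset"))
        a = joint.set_index("gene")["log2FC"]
        b = sub.set_index("gene")["log2FC"]
        common = a.index.intersection(b.index)
        assert np.corrcoef(a.loc[common], b.loc[common])[0, 1] > 0.95


def simulate_truth_for(meta, cfg):
    from celiarank.simulate import simulate_counts, simulate_truth

    truth = simulate_truth(cfg, 0)
    return simulate_counts(truth, meta, cfg, 0)
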