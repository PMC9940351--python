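"""Size factors, NB contrasts, interaction test, categories, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soluseq.core_io import CountMatrix
from soluseq import differential as diff

from oracles import brute_bh, brute_size_factors


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [3, 10, 7], "b": [3, 10, 7]})
        np.testing.assert_allclose(diff.size_factors_median_ratio(counts), 1.0)

    def test_hand_computed_two_by_two(self):
        counts = pd.DataFrame([[2, 4], [8, 16]], columns=["a", "b"])
        sf = diff.size_factors_median_ratio(counts)
        np.testing.assert_allclose(sf, [0.70710678, 1.41421356], rtol=1e-6)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, (20, 4)))
        perm = counts.sample(frac=1, random_state=2)
        pd.testing.assert_series_equal(
            diff.size_factors_median_ratio(counts),
            diff.size_factors_median_ratio(perm),
        )

    def test_matches_brute_force_with_zeros(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 60, (30, 5))
        counts = pd.DataFrame(arr)
        sf = diff.size_factors_median_ratio(counts)
        np.testing.assert_allclose(sf.to_numpy(), brute_size_factors(arr))

    def test_matches_deseq2_reference_implementation(self):
        """Median-of-ratios factors agree with pyDESeq2's estimateSizeFactors."""
        pydeseq2 = pytest.importorskip("pydeseq2.dds")
        rng = np.random.default_rng(10)
        depth = rng.uniform(0.5, 2.0, 6)
        mu = rng.lognormal(np.log(300), 0.6, (40, 1)) * depth
        counts = pd.DataFrame(
            rng.poisson(mu), index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3},
                            index=counts.columns)
        dds = pydeseq2.DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        np.testing.assert_allclose(
            diff.size_factors_median_ratio(counts).to_numpy(),
            dds.obs["size_factors"].to_numpy(),
            rtol=1e-4,
        )

    def test_all_zero_rows_fail(self):
        counts = pd.DataFrame([[0, 1], [2, 0]])
        with pytest.raises(ValueError):
            diff.size_factors_median_ratio(counts)


class TestNbContrast:
    def _sf(self, n):
        return pd.Series(1.0, index=range(n))

    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(100, (50, 3)))
        res = diff.nb_contrast(counts, counts.copy(), self._sf(3), self._sf(3))
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["pvalue"], 1.0)

    def test_all_zero_gene_gets_na(self):
        counts_a = pd.DataFrame([[0, 0, 0], [100, 110, 90]])
        counts_b = pd.DataFrame([[0, 0, 0], [210, 190, 200]])
        res = diff.nb_contrast(counts_a, counts_b, self._sf(3), self._sf(3))
        assert np.isnan(res.loc[0, "pvalue"])
        assert np.isfinite(res.loc[1, "log2fc"])

    def test_lfc_recovery_at_known_effect(self):
        """True log2FC = 1 at mean 200, dispersion 0.05: median estimate
        within +-0.1."""
        rng = np.random.default_rng(5)
        mu = rng.lognormal(np.log(200), 0.5, 2000)
        def nb(m):
            return rng.poisson(rng.gamma(20.0, m / 20.0, size=(2000, 3)))
        a = pd.DataFrame(nb(mu[:, None]))
        b = pd.DataFrame(nb(2 * mu[:, None]))
        res = diff.nb_contrast(a, b, self._sf(3), self._sf(3))
        assert abs(res["log2fc"].median() - 1.0) < 0.1


def _matrix_from_means(means: dict, samples_meta, rng, dispersion=0.0):
    cols = {}
    for sid, mu in means.items():
        mu = np.asarray(mu, dtype=float)
        if dispersion > 0:
            mu = rng.gamma(1 / dispersion, mu * dispersion)
        cols[sid] = rng.poisson(mu)
    genes = [f"g{i}" for i in range(len(next(iter(means.values()))))]
    counts = pd.DataFrame(cols, index=genes)
    species = pd.Series("target", index=genes)
    species.iloc[-4:] = "spike"
    return CountMatrix(counts, samples_meta, species)


def _meta(rows):
    df = pd.DataFrame(
        rows, columns=["sample", "condition", "fraction", "assay", "replicate"]
    )
    return df.set_index("sample")


class TestSolubility:
    def _make(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        base = rng.lognormal(np.log(400), 0.4, n)
        s = rng.uniform(0.2, 0.8, n)
        s[-4:] = 1.0  # spike
        means = {}
        rows = []
        for rep in (1, 2, 3):
            means[f"sol{rep}"] = base * s
            means[f"tot{rep}"] = base
            rows.append((f"sol{rep}", "WT", "soluble", "RNA", rep))
            rows.append((f"tot{rep}", "WT", "total", "RNA", rep))
        return _matrix_from_means(means, _meta(rows), rng), s

    def test_equal_fractions_give_zero_lfc(self):
        rng = np.random.default_rng(1)
        rows = []
        means = {}
        base = np.full(40, 500.0)
        for rep in (1, 2):
            for frac in ("soluble", "total"):
                sid = f"{frac}{rep}"
                means[sid] = base
                rows.append((sid, "WT", frac, "RNA", rep))
        m = _matrix_from_means(means, _meta(rows), rng)
        res = diff.solubility(m, "WT")
        assert res["log2fc"].abs().median() < 0.1

    def test_fraction_swap_negates_lfc_exactly(self):
        m, _ = self._make(seed=2)
        res = diff.solubility(m, "WT")
        swapped_meta = m.samples.copy()
        swapped_meta["fraction"] = swapped_meta["fraction"].map(
            {"soluble": "total", "total": "soluble"}
        )
        m2 = CountMatrix(m.counts, swapped_meta, m.species)
        res2 = diff.solubility(m2, "WT")
        np.testing.assert_allclose(res2["log2fc"], -res["log2fc"], atol=1e-12)

    def test_estimates_track_true_solubility(self):
        m, s = self._make(seed=3)
        res = diff.solubility(m, "WT")
        rho = sps.spearmanr(res["log2fc"], np.log2(s[:-4])).statistic
        assert rho > 0.9


class TestRelativeDegradation:
    def _make(self, rng, deg=2.0):
        n = 50
        base = np.full(n, 500.0)
        d = np.ones(n)
        d[:10] = deg
        d[-4:] = 1.0
        means, rows = {}, []
        for rep in (1, 2, 3):
            means[f"rna{rep}"] = base
            means[f"fp{rep}"] = base * d
            rows.append((f"rna{rep}", "WT", "total", "RNA", rep))
            rows.append((f"fp{rep}", "WT", "total", "5P", rep))
        return _matrix_from_means(means, _meta(rows), rng), d

    def test_degradation_factor_recovered(self):
        rng = np.random.default_rng(6)
        m, d = self._make(rng, deg=2.0)
        res = diff.relative_degradation(m, "WT", "total")
        delta = res["log2fc"].iloc[:10].mean() - res["log2fc"].iloc[10:-4].mean()
        assert abs(delta - 1.0) < 0.15

    def test_doubling_target_only_shifts_by_one(self):
        rng = np.random.default_rng(7)
        m, _ = self._make(rng)
        res = diff.relative_degradation(m, "WT", "total")
        doubled = m.counts.copy()
        fp_cols = m.samples.index[m.samples["assay"] == "5P"]
        target = m.species == "target"
        doubled.loc[target, fp_cols] *= 2
        res2 = diff.relative_degradation(
            CountMatrix(doubled, m.samples, m.species), "WT", "total"
        )
        shift = (res2["log2fc"] - res["log2fc"]).dropna()
        np.testing.assert_allclose(shift, 1.0, atol=0.05)

    def test_doubling_target_and_spike_cancels(self):
        rng = np.random.default_rng(8)
        m, _ = self._make(rng)
        res = diff.relative_degradation(m, "WT", "total")
        doubled = m.counts.copy()
        fp_cols = m.samples.index[m.samples["assay"] == "5P"]
        doubled.loc[:, fp_cols] *= 2
        res2 = diff.relative_degradation(
            CountMatrix(doubled, m.samples, m.species), "WT", "total"
        )
        shift = (res2["log2fc"] - res["log2fc"]).dropna()
        np.testing.assert_allclose(shift, 0.0, atol=0.02)


class TestRatioOfRatios:
    def _res(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        return pd.DataFrame(
            {
                "log2fc": rng.normal(0, 1, 30),
                "se": rng.uniform(0.1, 0.3, 30),
                "pvalue": rng.uniform(0, 1, 30),
                "fdr": rng.uniform(0, 1, 30),
            },
            index=genes,
        )

    def test_identical_inputs_are_null(self):
        a = self._res(1)
        out = diff.ratio_of_ratios(a, a.copy())
        np.testing.assert_allclose(out["estimate"], 0.0)
        np.testing.assert_allclose(out["pvalue"], 1.0)

    def test_antisymmetric_under_swap(self):
        a, b = self._res(2), self._res(3)
        ab = diff.ratio_of_ratios(a, b)
        ba = diff.ratio_of_ratios(b, a)
        np.testing.assert_allclose(ab["estimate"], -ba["estimate"])
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"])


class TestCategories:
    def _inputs(self, d1, d4, fdr):
        genes = ["g1"]
        mk = lambda v: pd.DataFrame({"estimate": [v], "se": [0.1]}, index=genes)
        inter = pd.DataFrame({"fdr": [fdr]}, index=genes)
        return mk(d1), mk(d4), inter

    @pytest.mark.parametrize(
        "d1,d4,fdr,expected",
        [
            (-0.6, 0.6, 0.01, "red"),
            (0.6, -0.6, 0.01, "green"),
            (0.3, 0.3, 0.4, "orange"),
            (-0.3, -0.3, 0.4, "blue"),
            (-0.6, 0.6, 0.2, "none"),   # opposite but not significant
            (-0.3, 0.6, 0.01, "none"),  # significant but below cutoff
        ],
    )
    def test_rules(self, d1, d4, fdr, expected):
        a, b, inter = self._inputs(d1, d4, fdr)
        out = diff.classify_categories(a, b, inter)
        assert out.loc["g1", "category"] == expected

    def test_missing_gene_flagged_none(self):
        a, b, inter = self._inputs(-0.6, 0.6, 0.01)
        b2 = b.drop(index=["g1"])
        b2.loc["g2"] = [0.5, 0.1]
        out = diff.classify_categories(a, b2, inter)
        assert out.loc["g1", "category"] == "none"
        assert not out.loc["g1", "complete"]


class TestSolubilityFlags:
    @pytest.mark.parametrize(
        "lfc,p,fdr,expected",
        [
            (0.5, 0.001, 0.01, "high"),
            (1.2, 0.03, 0.2, "high"),
            (0.5, 0.2, 0.5, "neither"),
            (-0.5, 0.001, 0.01, "low"),
            (-1.2, 0.03, 0.2, "low"),
        ],
    )
    def test_legend_rules(self, lfc, p, fdr, expected):
        res = pd.DataFrame(
            {"log2fc": [lfc], "pvalue": [p], "fdr": [fdr]}, index=["g"]
        )
        assert diff.solubility_flags(res)["g"] == expected


class TestEnrichment:
    def test_zero_overlap_p_is_one(self):
        out = diff.hypergeometric_enrichment(
            ["a", "b"], {"s": {"c", "d"}}, ["a", "b", "c", "d", "e"]
        )
        assert out.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_exact_complete_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        hits = universe[:5]
        out = diff.hypergeometric_enrichment(hits, {"s": set(hits)}, universe)
        assert out.loc["s", "pvalue"] == pytest.approx(1 / 15504, rel=1e-6)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            diff.hypergeometric_enrichment(["a", "a"], {}, ["a", "b"])


class TestBH:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(
            diff.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            p = rng.uniform(0, 1, 200)
            np.testing.assert_allclose(diff.bh_fdr(p), brute_bh(p))
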