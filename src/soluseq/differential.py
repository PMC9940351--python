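"""Differential statistics on CDS count matrices.

This module defines the two central per-gene quantities of the analysis and
the tests built on them:

* **solubility** — log2 fold change of RNA-Seq counts, soluble fraction over
  total fraction within a condition, under within-species (library)
  median-of-ratios normalization;
* **relative degradation** — log2 fold change of 5'P-Seq over RNA-Seq counts
  for the same condition and fraction, normalized by median-of-ratios size
  factors computed on the spike-in species only, so that global shifts in
  the degradome are preserved rather than normalized away.

Fold changes and Wald-type significance come from a minimal negative-
binomial contrast: median-of-ratios size factors, a method-of-moments
dispersion stabilized by a mean-dispersion trend fitted across genes, a
delta-method standard error, and Benjamini-Hochberg FDR.  The interaction
("ratio-of-ratios") test is the z-contrast of two independent log fold
changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import CountMatrix, split_spike
from .stats import bh_fdr

LN2 = np.log(2.0)

RESULT_COLUMNS = ["base_mean", "log2fc", "se", "pvalue", "fdr"]


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample/column).

    For every gene with all-positive counts, each sample's count is divided
    by the gene's geometric mean across samples; a sample's factor is the
    median of these ratios.  Genes containing any zero are excluded from the
    reference, as in the standard RNA-Seq formulation.
    """
    arr = counts.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if usable.sum() < 1:
        raise ValueError("no gene with all-positive counts; cannot estimate size factors")
    sub = arr[usable]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor")
    return pd.Series(factors, index=counts.columns)


def _trend_dispersion(norm: np.ndarray, groups: list[np.ndarray],
                      floor: float) -> np.ndarray:
    """Per-gene NB dispersion from a mean-dispersion trend a0 + a1/mu.

    Gene-wise method-of-moments estimates at 2-3 replicates are far too
    noisy to calibrate a Wald test, so the gene-wise values are used only to
    fit the trend, and every gene is assigned its fitted value (floored).
    """
    n_genes = norm.shape[0]
    ss = np.zeros(n_genes)
    lin = np.zeros(n_genes)
    sq = np.zeros(n_genes)
    grand = np.zeros(n_genes)
    n_total = 0
    for idx in groups:
        sub = norm[:, idx]
        n = sub.shape[1]
        n_total += n
        m = sub.mean(axis=1)
        grand += m * n
        if n > 1:
            ss += ((sub - m[:, None]) ** 2).sum(axis=1)
            lin += (n - 1) * m
            sq += (n - 1) * m**2
    grand /= n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = (ss - lin) / sq
    ok = np.isfinite(alpha_gene) & (grand > 0)
    mu = np.maximum(grand, 1e-8)
    if ok.sum() >= 10:
        # least squares of alpha on [1, 1/mu]; mean-unbiased for the trend
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_gene[ok], rcond=None)
        a0, a1 = coef
        fitted = a0 + np.maximum(a1, 0.0) / mu
    elif ok.sum() > 0:
        fitted = np.full(n_genes, np.mean(alpha_gene[ok]))
    else:
        fitted = np.zeros(n_genes)
    return np.maximum(fitted, floor)


def nb_contrast(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    size_factors_a: pd.Series,
    size_factors_b: pd.Series,
    count_floor: float = 10.0,
    pseudocount: float = 0.5,
    dispersion_floor: float = 0.01,
) -> pd.DataFrame:
    """Negative-binomial Wald contrast of condition B over condition A.

    Returns a per-gene frame with base_mean (mean normalized count),
    log2fc = log2((mean_B + pc) / (mean_A + pc)), a delta-method standard
    error, a normal Wald p-value and BH FDR.  The normal reference is
    justified because the dispersion entering the SE is the trend fitted
    across all genes rather than a noisy per-gene estimate.  Genes whose
    summed normalized counts fall below ``count_floor`` are reported with
    NA statistics.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count frames must share the same gene index")
    na, nb = counts_a.shape[1], counts_b.shape[1]
    if na < 1 or nb < 1:
        raise ValueError("each side needs at least one sample")
    norm_a = counts_a.to_numpy(dtype=float) / np.asarray(size_factors_a, dtype=float)
    norm_b = counts_b.to_numpy(dtype=float) / np.asarray(size_factors_b, dtype=float)
    norm = np.concatenate([norm_a, norm_b], axis=1)
    groups = [np.arange(na), np.arange(na, na + nb)]
    alpha = _trend_dispersion(norm, groups, dispersion_floor)

    m_a = norm_a.mean(axis=1)
    m_b = norm_b.mean(axis=1)
    lfc = np.log2(m_b + pseudocount) - np.log2(m_a + pseudocount)
    var_log = (1.0 / (m_a + pseudocount) + alpha) / na + (
        1.0 / (m_b + pseudocount) + alpha
    ) / nb
    se = np.sqrt(var_log) / LN2  # log2 scale

    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    pvalue = 2.0 * sps.norm.sf(np.abs(z))

    low = norm.sum(axis=1) < count_floor
    res = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
            "se": se,
            "pvalue": pvalue,
        },
        index=counts_a.index,
    )
    res.loc[low, ["log2fc", "se", "pvalue"]] = np.nan
    res["fdr"] = bh_fdr(res["pvalue"].to_numpy())
    res.index.name = "gene"
    return res


def _joint_size_factors(matrix: CountMatrix, reference: str) -> pd.Series:
    """Size factors across all samples of ``matrix`` from one species' genes."""
    target, spike = split_spike(matrix)
    ref = spike if reference == "spike" else target
    return size_factors_median_ratio(ref.counts)


def solubility(
    matrix: CountMatrix,
    condition: str,
    normalization: str = "library",
    **contrast_kwargs,
) -> pd.DataFrame:
    """Per-gene solubility: log2FC of soluble over total RNA-Seq counts.

    Solubility is a within-species compositional ratio, so by default the
    contrast is normalized with library (target-gene) median-of-ratios
    factors; set ``normalization='spike'`` to use spike-in factors instead.
    Only target-species genes are reported.
    """
    sel = matrix.select(assay="RNA", condition=condition)
    if sel.counts.shape[1] == 0:
        raise ValueError(f"no RNA samples for condition {condition!r}")
    sf = _joint_size_factors(sel, normalization)
    target, _ = split_spike(sel)
    tot = target.select(fraction="total")
    sol = target.select(fraction="soluble")
    return nb_contrast(
        tot.counts, sol.counts, sf[tot.counts.columns], sf[sol.counts.columns],
        **contrast_kwargs,
    )


def relative_degradation(
    matrix: CountMatrix,
    condition: str,
    fraction: str,
    **contrast_kwargs,
) -> pd.DataFrame:
    """Per-gene relative degradation: log2FC of 5'P over RNA-Seq counts.

    Normalized with median-of-ratios size factors computed on the spike-in
    species across the paired 5'P and RNA libraries, so that genome-wide
    changes in degradome abundance are retained.  Only target genes are
    reported.
    """
    sel = matrix.select(condition=condition, fraction=fraction)
    if sel.counts.shape[1] == 0:
        raise ValueError(f"no samples for {condition}/{fraction}")
    sf = _joint_size_factors(sel, "spike")
    target, _ = split_spike(sel)
    rna = target.select(assay="RNA")
    fivep = target.select(assay="5P")
    if rna.counts.shape[1] == 0 or fivep.counts.shape[1] == 0:
        raise ValueError("both 5P and RNA samples are required")
    return nb_contrast(
        rna.counts, fivep.counts, sf[rna.counts.columns], sf[fivep.counts.columns],
        **contrast_kwargs,
    )


def ratio_of_ratios(result_a: pd.DataFrame, result_b: pd.DataFrame) -> pd.DataFrame:
    """Interaction ('ratio-of-ratios') test: difference of two independent LFCs.

    estimate = log2fc_A - log2fc_B with SE = sqrt(SE_A^2 + SE_B^2), a normal
    z-test and BH FDR.  Rows are the intersection of the two gene sets; NA
    statistics propagate.
    """
    genes = result_a.index.intersection(result_b.index)
    a = result_a.loc[genes]
    b = result_b.loc[genes]
    est = a["log2fc"] - b["log2fc"]
    se = np.sqrt(a["se"] ** 2 + b["se"] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame({"estimate": est, "se": se, "pvalue": p}, index=genes)
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    out.index.name = "gene"
    return out


CATEGORIES = ("red", "green", "orange", "blue", "none")


def classify_categories(
    delta_sol_not1: pd.DataFrame,
    delta_sol_not4: pd.DataFrame,
    interaction: pd.DataFrame,
    alpha: float = 0.05,
    lfc_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Assign solubility-change categories from the not1d/not4d contrasts.

    red:    interaction FDR < alpha, solubility change not1d/WT < -cutoff
            and not4d/WT > +cutoff (solubilized by Not1, opposed by Not4);
    green:  the mirror image;
    orange: interaction not significant, both changes > 0;
    blue:   interaction not significant, both changes < 0;
    none:   everything else, including genes missing from any input
            (flagged ``complete=False``).
    """
    genes = delta_sol_not1.index.union(delta_sol_not4.index).union(interaction.index)
    d1 = delta_sol_not1["estimate" if "estimate" in delta_sol_not1 else "log2fc"]
    d4 = delta_sol_not4["estimate" if "estimate" in delta_sol_not4 else "log2fc"]
    d1 = d1.reindex(genes)
    d4 = d4.reindex(genes)
    ifdr = interaction["fdr"].reindex(genes)
    complete = d1.notna() & d4.notna() & ifdr.notna()

    category = pd.Series("none", index=genes, dtype=object)
    sig = complete & (ifdr < alpha)
    category[sig & (d1 < -lfc_cutoff) & (d4 > lfc_cutoff)] = "red"
    category[sig & (d1 > lfc_cutoff) & (d4 < -lfc_cutoff)] = "green"
    nonsig = complete & ~(ifdr < alpha)
    category[nonsig & (d1 > 0) & (d4 > 0)] = "orange"
    category[nonsig & (d1 < 0) & (d4 < 0)] = "blue"

    out = pd.DataFrame(
        {
            "delta_sol_not1": d1,
            "delta_sol_not4": d4,
            "interaction_fdr": ifdr,
            "category": category,
            "complete": complete,
        }
    )
    out.index.name = "gene"
    return out


def solubility_flags(
    result: pd.DataFrame,
    fdr_alpha: float = 0.05,
    p_alpha: float = 0.05,
    strong_lfc: float = 1.0,
) -> pd.Series:
    """Flag genes as high / low / neither solubility.

    high: (log2FC > 0 and FDR < 0.05) or (log2FC > 1 and p < 0.05);
    low:  (log2FC < 0 and FDR < 0.05) or (log2FC < -1 and p < 0.05).
    """
    lfc = result["log2fc"]
    p = result["pvalue"]
    fdr = result["fdr"]
    high = ((lfc > 0) & (fdr < fdr_alpha)) | ((lfc > strong_lfc) & (p < p_alpha))
    low = ((lfc < 0) & (fdr < fdr_alpha)) | ((lfc < -strong_lfc) & (p < p_alpha))
    flags = pd.Series("neither", index=result.index, dtype=object)
    flags[high.fillna(False)] = "high"
    flags[low.fillna(False)] = "low"
    flags.name = "solubility_flag"
    return flags


def hypergeometric_enrichment(
    hits, gene_sets: dict[str, set], universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``hits`` in each set.

    p = P(overlap >= observed) drawing len(hits) genes from the universe;
    BH adjustment across sets.  Duplicate ids in hits or universe are
    rejected.
    """
    universe = list(universe)
    hits = list(hits)
    if len(set(universe)) != len(universe):
        raise ValueError("duplicate gene ids in universe")
    if len(set(hits)) != len(hits):
        raise ValueError("duplicate gene ids in hits")
    uni = set(universe)
    if not set(hits) <= uni:
        raise ValueError("hits must be a subset of the universe")
    M, n = len(uni), len(hits)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & uni)
        k = len(set(members) & set(hits))
        p = float(sps.hypergeom.sf(k - 1, M, K, n))
        expected = n * K / M if M else np.nan
        fold = (k / expected) if expected > 0 else np.nan
        rows.append((name, K, k, fold, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "fold", "pvalue"])
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    return out.set_index("set")
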