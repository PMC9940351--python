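"""PAR-CLIP cross-linking density and ChEC promoter signal.

PAR-CLIP cross-link sites read out as T->C transitions; comparable
densities across regions require normalizing the transition count to the
number of T bases in the region and to the sequencing depth (per million
transitions).  The Not4-vs-RNAPII comparison asks which mRNAs deviate at
least twofold from the global linear relation between the two factors'
log densities.

ChEC maps MNase-fusion cleavage around promoters: counts in a window 400 bp
upstream to 100 bp downstream of the +1 nucleosome are converted to RPKM,
compared with the free-MNase control as a log2 fold change, and
mode-centered so that the unbound bulk sits at zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def parclip_density(table: pd.DataFrame, transitions_col: str = "transitions",
                    t_col: str = "t_count") -> pd.Series:
    """Normalized cross-linking density per region.

    density = (transitions / T_count) * 1e6 / total transitions in the
    sample.  Regions with T_count = 0 get NA.
    """
    transitions = table[transitions_col].astype(float)
    t_count = table[t_col].astype(float)
    if (transitions < 0).any() or (t_count < 0).any():
        raise ValueError("negative counts")
    total = transitions.sum()
    if total == 0:
        raise ValueError("no transitions in sample")
    with np.errstate(divide="ignore", invalid="ignore"):
        density = transitions / t_count * 1e6 / total
    density[t_count == 0] = np.nan
    density.name = "density"
    return density


def relative_crosslink(
    not4_density: pd.Series,
    rnapii_density: pd.Series,
    fold_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Classify regions by Not4 cross-linking relative to the RNAPII trend.

    A least-squares line of log2 Not4 density on log2 RNAPII density is fit
    over regions where both densities are positive; regions whose residual
    exceeds +log2(fold_cutoff) are 'higher', below -log2(fold_cutoff)
    'lower', otherwise 'expected'.
    """
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must be > 1")
    joined = pd.concat(
        [not4_density.rename("not4"), rnapii_density.rename("rnapii")], axis=1
    )
    usable = (joined["not4"] > 0) & (joined["rnapii"] > 0)
    sub = joined[usable]
    if len(sub) < 3:
        raise ValueError("too few regions with positive densities")
    x = np.log2(sub["rnapii"].to_numpy())
    y = np.log2(sub["not4"].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    residual = y - (slope * x + intercept)
    thr = np.log2(fold_cutoff)
    cls = np.where(residual > thr, "higher", np.where(residual < -thr, "lower", "expected"))
    out = pd.DataFrame(
        {"log2_residual": pd.Series(residual, index=sub.index), "crosslink_class": cls},
        index=sub.index,
    )
    out = out.reindex(joined.index)
    out["crosslink_class"] = out["crosslink_class"].fillna("undefined")
    out.attrs["slope"] = float(slope)
    out.attrs["intercept"] = float(intercept)
    return out


def promoter_windows(
    plus1: pd.DataFrame,
    contig_lengths: dict[str, int],
    upstream: int = 400,
    downstream: int = 100,
) -> pd.DataFrame:
    """Promoter windows around +1 nucleosome positions (strand-aware).

    ``plus1`` needs columns gene, chrom, pos (0-based), strand.  For a plus-
    strand gene the window runs ``upstream`` bp 5' of the +1 position to
    ``downstream`` bp 3' of it (inclusive of the position itself, so 501 bp
    by default); minus-strand windows are mirrored.  Windows are clipped at
    contig bounds and flagged.
    """
    rows = []
    for rec in plus1.itertuples(index=False):
        length = contig_lengths[rec.chrom]
        if rec.strand == "+":
            start, end = rec.pos - upstream, rec.pos + downstream + 1
        elif rec.strand == "-":
            start, end = rec.pos - downstream, rec.pos + upstream + 1
        else:
            raise ValueError(f"bad strand {rec.strand!r} for {rec.gene}")
        cstart, cend = max(0, start), min(length, end)
        rows.append((rec.gene, rec.chrom, cstart, cend, rec.strand,
                     cstart != start or cend != end))
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "strand", "clipped"]
    ).set_index("gene")


def estimate_mode(values, method: str = "lognormal") -> float:
    """Mode of a distribution of log2 fold changes.

    'lognormal' (default): fit a log-normal to 2**values (strictly positive
    by construction) and return log2 of the fitted mode exp(mu - sigma^2).
    'kde': argmax of a Gaussian kernel density on the log2 scale.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite values")
    if np.ptp(v) == 0:
        return float(v[0])
    if method == "lognormal":
        ratios = np.exp2(v)
        shape, loc, scale = sps.lognorm.fit(ratios, floc=0)
        mode = scale * np.exp(-(shape**2))  # exp(mu - sigma^2)
        return float(np.log2(mode))
    if method == "kde":
        kde = sps.gaussian_kde(v)
        grid = np.linspace(v.min(), v.max(), 2048)
        return float(grid[np.argmax(kde(grid))])
    raise ValueError("method must be 'lognormal' or 'kde'")


def chec_signal(
    sample_counts: pd.Series,
    control_counts: pd.Series,
    regions: pd.DataFrame,
    sample_library: float | None = None,
    control_library: float | None = None,
    pseudocount: float = 0.5,
    mode_method: str = "lognormal",
) -> pd.DataFrame:
    """Promoter-window ChEC signal over the free-MNase control.

    Counts are converted to RPKM (window kb x library millions), the log2
    fold change sample/control taken with an RPKM pseudocount, and the LFC
    distribution centered on its estimated mode so the unbound bulk sits at
    zero.  ``regions`` must carry start/end columns aligned to the counts.
    """
    idx = regions.index
    s = sample_counts.reindex(idx).astype(float)
    c = control_counts.reindex(idx).astype(float)
    if s.isna().any() or c.isna().any():
        raise ValueError("counts missing for some promoters")
    lib_s = float(sample_library if sample_library is not None else s.sum())
    lib_c = float(control_library if control_library is not None else c.sum())
    if lib_s <= 0 or lib_c <= 0:
        raise ValueError("zero-size library")
    kb = (regions["end"] - regions["start"]).astype(float) / 1e3
    rpkm_s = s / kb / (lib_s / 1e6)
    rpkm_c = c / kb / (lib_c / 1e6)
    lfc = np.log2(rpkm_s + pseudocount) - np.log2(rpkm_c + pseudocount)
    mode = estimate_mode(lfc.to_numpy(), method=mode_method)
    out = pd.DataFrame(
        {
            "rpkm_sample": rpkm_s,
            "rpkm_control": rpkm_c,
            "lfc": lfc,
            "centered_lfc": lfc - mode,
        },
        index=idx,
    )
    out.attrs["mode"] = mode
    return out
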