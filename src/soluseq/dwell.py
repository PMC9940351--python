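"""Codon dwelling occupancy and positional profiles from 5'P ends.

During co-translational 5'->3' decay the exonuclease trails the last
translating ribosome, leaving 5'P ends ~17 nt upstream of the ribosome
A-site.  The depth of 5' ends 17 nt upstream of each codon type therefore
reads out relative ribosome dwelling on that codon (5'P-RDO).  This module
computes RDO tables and their differentials, the tAI correlation analysis,
start/stop-anchored and CDS-scaled metagene profiles, windowed read
proportions along the CDS, and reading-frame periodicity.

Frame convention: position 0 is the A of ATG, frame k means
(transcript position mod 3) == k.  Since codon starts are = 0 (mod 3) and
-17 = 1 (mod 3), ribosome-protected 5'P ends fall in frame 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FivePrimeTrackSet, TranscriptCatalog
from .stats import pearson_test, wilcoxon_rank_sum

A_SITE_OFFSET = 17

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "TCAG"
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


def load_tai(path=None) -> pd.Series:
    """Load a codon -> tAI table (TSV with columns codon, tai).

    Without a path, the bundled gene-copy tAI table for budding yeast is
    used.  All 61 sense codons must be present with positive values.
    """
    if path is None:
        ref = importlib.resources.files("soluseq.data").joinpath("tai_yeast.tsv")
        with importlib.resources.as_file(ref) as p:
            tab = pd.read_csv(p, sep="\t")
    else:
        tab = pd.read_csv(path, sep="\t")
    tai = tab.set_index("codon")["tai"].astype(float)
    missing = set(SENSE_CODONS) - set(tai.index)
    if missing:
        raise ValueError(f"tAI table missing codons: {sorted(missing)[:5]} ...")
    if (tai.loc[list(SENSE_CODONS)] <= 0).any():
        raise ValueError("tAI values must be positive")
    return tai.loc[list(SENSE_CODONS)]


@dataclass
class RDOTable:
    """Normalized per-codon dwelling occupancy.

    ``occupancy`` is the mean 5'P depth ``offset`` nt upstream of each
    codon type, divided by the same mean over all codons; the position-
    weighted mean of occupancies is 1 by construction.
    """

    occupancy: pd.Series
    n_positions: pd.Series
    sample_id: str = ""
    offset: int = A_SITE_OFFSET

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"occupancy": self.occupancy, "n_positions": self.n_positions}
        ).rename_axis("codon")


@dataclass
class MetageneProfile:
    axis: np.ndarray
    values: np.ndarray
    anchor: str
    shift: int = 0
    n_transcripts: int = 0

    def to_frame(self) -> pd.DataFrame:
        key = "bin" if self.anchor == "scaled" else "offset"
        return pd.DataFrame({key: self.axis, "value": self.values})


def _eligible(transcript, filter_window, offset):
    """Codon indices contributing to the RDO under an optional CDS window.

    ``filter_window`` is a fractional (lo, hi) interval of the CDS; both the
    codon start and the upstream position it reads from must fall inside.
    The stop codon and codons whose upstream position precedes the CDS are
    always excluded.
    """
    L = transcript.cds_length
    n_codons = L // 3 - 1  # sense codons only; last codon is the stop
    k = np.arange(n_codons)
    p = 3 * k
    keep = p >= offset
    if filter_window is not None:
        lo, hi = filter_window
        lo_nt, hi_nt = lo * L, hi * L
        keep &= (p >= lo_nt) & (p < hi_nt) & (p - offset >= lo_nt)
    return k[keep]


def rdo(
    trackset: FivePrimeTrackSet,
    catalog: TranscriptCatalog,
    offset: int = A_SITE_OFFSET,
    transcripts=None,
    cds_window: tuple[float, float] | None = None,
) -> RDOTable:
    """Per-codon 5'P ribosome dwelling occupancy.

    For each sense codon type, the mean 5'-end depth ``offset`` nt upstream
    of its occurrences is computed over all eligible CDS positions and
    divided by the same mean taken over all codons, so the position-weighted
    mean occupancy is 1.  ``transcripts`` restricts the gene set;
    ``cds_window`` restricts codons to a fractional CDS interval.  Codons
    with no eligible position get NA.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if transcripts is not None:
        catalog = catalog.subset(transcripts)
    if len(catalog) == 0:
        raise ValueError("empty transcript filter")
    depth_sum = {c: 0.0 for c in SENSE_CODONS}
    n_pos = {c: 0 for c in SENSE_CODONS}
    for t in catalog:
        if t.id not in trackset.tracks:
            continue
        track = trackset.tracks[t.id]
        codons = t.codons()
        for k in _eligible(t, cds_window, offset):
            c = codons[k]
            if c not in depth_sum:  # internal stop / ambiguous base
                continue
            depth_sum[c] += float(track[3 * k - offset])
            n_pos[c] += 1
    n = pd.Series(n_pos, dtype=float).loc[list(SENSE_CODONS)]
    s = pd.Series(depth_sum, dtype=float).loc[list(SENSE_CODONS)]
    total_n = n.sum()
    if total_n == 0:
        raise ValueError("no eligible codon positions under this filter")
    overall_mean = s.sum() / total_n
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = (s / n) / overall_mean if overall_mean > 0 else s / n
    occ[n == 0] = np.nan
    return RDOTable(
        occupancy=occ, n_positions=n.astype(int),
        sample_id=trackset.sample_id, offset=offset,
    )


def differential_rdo(rdo_a: RDOTable, rdo_b: RDOTable) -> pd.Series:
    """log2 fold change of normalized occupancy, B over A; NA propagates."""
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2(rdo_b.occupancy / rdo_a.occupancy)
    out.name = "log2fc_rdo"
    return out


def tai_analysis(
    diff_rdo: pd.Series, tai: pd.Series, n_extreme: int = 15
) -> dict:
    """Relate differential RDO to codon optimality (tAI).

    Returns the Pearson correlation of the differential RDO with tAI over
    all codons with data, plus a one-sided Wilcoxon rank-sum test that the
    ``n_extreme`` least-optimal codons (lowest tAI) have *greater*
    differential RDO than the ``n_extreme`` most-optimal ones.
    """
    joined = pd.concat([diff_rdo.rename("d"), tai.rename("tai")], axis=1).dropna()
    if len(joined) < 2 * n_extreme:
        raise ValueError("not enough codons with data")
    pear = pearson_test(joined["d"], joined["tai"], min_n=30)
    ranked = joined.sort_values("tai")
    nonopt = ranked["d"].iloc[:n_extreme]
    opt = ranked["d"].iloc[-n_extreme:]
    wil = wilcoxon_rank_sum(nonopt, opt, alternative="greater")
    return {
        "pearson_r": pear.statistic,
        "pearson_p": pear.pvalue,
        "wilcoxon_p": wil.pvalue,
        "n_codons": len(joined),
        "optimal_codons": list(ranked.index[-n_extreme:]),
        "nonoptimal_codons": list(ranked.index[:n_extreme]),
    }


def metagene_anchored(
    trackset: FivePrimeTrackSet,
    catalog: TranscriptCatalog,
    anchor: str = "start",
    shift: int = A_SITE_OFFSET,
    flank: tuple[int, int] = (-50, 250),
) -> MetageneProfile:
    """Aggregate 5'-end depth around the start or stop codon.

    5' ends are shifted ``shift`` nt downstream (A-site equivalence) before
    aggregation; offsets are relative to the first nucleotide of the start
    codon (anchor='start') or of the stop codon (anchor='stop').  The summed
    depth is scaled per million mapped 5' ends of the library.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    lo, hi = flank
    axis = np.arange(lo, hi + 1)
    values = np.zeros(len(axis), dtype=float)
    n_used = 0
    for t in catalog:
        if t.id not in trackset.tracks:
            continue
        track = trackset.tracks[t.id]
        if track.sum() == 0:
            continue
        n_used += 1
        anchor_pos = 0 if anchor == "start" else t.cds_length - 3
        pos = np.flatnonzero(track)
        offs = pos + shift - anchor_pos
        ok = (offs >= lo) & (offs <= hi)
        np.add.at(values, offs[ok] - lo, track[pos[ok]])
    scale = trackset.library_size / 1e6 if trackset.library_size else 1.0
    return MetageneProfile(axis, values / scale, anchor, shift, n_used)


def metagene_scaled(
    trackset: FivePrimeTrackSet,
    catalog: TranscriptCatalog,
    n_bins: int = 100,
    transcripts=None,
) -> MetageneProfile:
    """CDS-scaled metagene: mean depth per fractional CDS bin.

    Every CDS is split into ``n_bins`` equal bins; bin means are averaged
    across transcripts and divided by the mean depth over all nucleotides of
    the transcript group, so a uniform library gives a flat profile of 1.
    """
    if transcripts is not None:
        catalog = catalog.subset(transcripts)
    sums = np.zeros(n_bins)
    total_depth = 0.0
    total_nt = 0
    n_used = 0
    for t in catalog:
        if t.id not in trackset.tracks:
            continue
        track = trackset.tracks[t.id].astype(float)
        L = len(track)
        if L < n_bins:
            continue
        edges = (np.arange(n_bins + 1) * L) // n_bins
        binmeans = np.array(
            [track[edges[j] : edges[j + 1]].mean() for j in range(n_bins)]
        )
        sums += binmeans
        total_depth += track.sum()
        total_nt += L
        n_used += 1
    if n_used == 0:
        raise ValueError("no transcripts usable for scaled metagene")
    profile = sums / n_used
    group_mean = total_depth / total_nt
    if group_mean > 0:
        profile = profile / group_mean
    return MetageneProfile(np.arange(1, n_bins + 1), profile, "scaled", 0, n_used)


DEFAULT_WINDOWS = ((0.1, 0.3), (0.4, 0.6), (0.7, 0.9))


def window_ratio(
    trackset_soluble: FivePrimeTrackSet,
    trackset_total: FivePrimeTrackSet,
    catalog: TranscriptCatalog,
    windows=DEFAULT_WINDOWS,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Proportions of 5'P reads in fractional CDS windows, soluble vs total.

    Windows are half-open intervals in fraction-of-CDS space.  A transcript
    is included only if its CDS carries at least ``min_reads`` 5'P reads in
    *both* the soluble and the total library.  Proportions are relative to
    all CDS reads of that gene in that library; the log2 ratio
    total/soluble is reported per window.
    """
    rows = []
    for t in catalog:
        tid = t.id
        if tid not in trackset_soluble.tracks or tid not in trackset_total.tracks:
            continue
        sol = trackset_soluble.tracks[tid]
        tot = trackset_total.tracks[tid]
        n_sol, n_tot = int(sol.sum()), int(tot.sum())
        if n_sol < min_reads or n_tot < min_reads:
            continue
        L = t.cds_length
        frac = np.arange(L) / L
        for lo, hi in windows:
            mask = (frac >= lo) & (frac < hi)
            p_sol = sol[mask].sum() / n_sol
            p_tot = tot[mask].sum() / n_tot
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.log2(p_tot / p_sol) if p_sol > 0 and p_tot > 0 else np.nan
            rows.append((tid, f"{int(lo*100)}-{int(hi*100)}%", p_sol, p_tot, ratio))
    return pd.DataFrame(
        rows, columns=["gene", "window", "prop_soluble", "prop_total", "log2_tot_vs_sol"]
    )


def frame_fractions(
    trackset: FivePrimeTrackSet, catalog: TranscriptCatalog
) -> tuple[float, float, float]:
    """Percentage of unshifted 5'P ends in each reading frame (f0, f1, f2)."""
    counts = np.zeros(3, dtype=np.int64)
    for t in catalog:
        if t.id not in trackset.tracks:
            continue
        track = trackset.tracks[t.id]
        for k in range(3):
            counts[k] += int(track[k::3].sum())
    total = counts.sum()
    if total == 0:
        return (np.nan, np.nan, np.nan)
    f = 100.0 * counts / total
    return (float(f[0]), float(f[1]), float(f[2]))
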