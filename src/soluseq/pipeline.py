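"""End-to-end report: from a directory of samples to per-figure tables.

``run_report`` consumes the file layout written by
:func:`soluseq.simulate.simulate_experiment` (or an equivalently organized
real dataset: annotation + per-sample bedGraph tracks + counts) and writes
every analysis table: solubility and relative-degradation contrasts,
interaction test and category calls, per-codon dwelling occupancy with the
tAI comparison, metagene/frame/window profiles, ChEC promoter signal and
PAR-CLIP cross-link classification.  The analysis itself is deterministic;
given byte-identical inputs the report is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosslink, differential, dwell
from .core_io import (
    CONDITIONS,
    FRACTIONS,
    FivePrimeTrackSet,
    TranscriptCatalog,
    load_annotation,
    read_bedgraph,
    read_counts_tsv,
)

FLOAT_FMT = "%.6g"


def pool_tracks(
    tracksets: dict[str, FivePrimeTrackSet], sample_ids, pooled_id: str
) -> FivePrimeTrackSet:
    """Sum replicate tracks into one pooled trackset."""
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("no samples to pool")
    first = tracksets[sample_ids[0]]
    tracks = {tid: arr.copy() for tid, arr in first.tracks.items()}
    lib = first.library_size
    for sid in sample_ids[1:]:
        ts = tracksets[sid]
        for tid, arr in ts.tracks.items():
            tracks[tid] = tracks.get(tid, 0) + arr
        lib += ts.library_size
    return FivePrimeTrackSet(sample_id=pooled_id, tracks=tracks, library_size=lib)


def load_experiment(data_dir):
    """Load annotation, counts and tracks from an experiment directory."""
    data_dir = Path(data_dir)
    catalog = load_annotation(
        data_dir / "annotation.gff3", data_dir / "genome.fa", spike_prefix="SPIKE_"
    )
    matrix = read_counts_tsv(data_dir / "counts.tsv", data_dir / "samples.tsv")
    tracksets = {}
    for path in sorted((data_dir / "tracks").glob("*.bedgraph")):
        ts = read_bedgraph(path, catalog)
        tracksets[ts.sample_id] = ts
    return catalog, matrix, tracksets


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def run_report(data_dir, out_dir, alpha: float = 0.05, lfc_cutoff: float = 0.5,
               tai_path=None) -> dict:
    """Run every analysis stage and write TSVs under ``out_dir``.

    Returns a summary dict (also written as report_summary.json) with the
    headline numbers: category sizes, tAI correlation of the differential
    RDO, frame-1 percentages, ChEC mode, and PAR-CLIP class counts.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog, matrix, tracksets = load_experiment(data_dir)
    samples = matrix.samples
    summary: dict = {}

    # --- solubility per condition, with high/low flags -----------------
    sol = {}
    for cond in CONDITIONS:
        res = differential.solubility(matrix, cond)
        res["flag"] = differential.solubility_flags(res)
        sol[cond] = res
        _write(res, out_dir / f"solubility_{cond}.tsv")

    # --- relative degradation per condition x fraction -----------------
    for cond in CONDITIONS:
        for frac in FRACTIONS:
            res = differential.relative_degradation(matrix, cond, frac)
            _write(res, out_dir / f"relative_degradation_{cond}_{frac}.tsv")

    # --- interaction and categories -------------------------------------
    dsol1 = differential.ratio_of_ratios(sol["not1d"], sol["WT"])
    dsol4 = differential.ratio_of_ratios(sol["not4d"], sol["WT"])
    inter = differential.ratio_of_ratios(sol["not1d"], sol["not4d"])
    _write(dsol1, out_dir / "delta_solubility_not1d.tsv")
    _write(dsol4, out_dir / "delta_solubility_not4d.tsv")
    _write(inter, out_dir / "interaction_not1d_vs_not4d.tsv")
    cats = differential.classify_categories(
        dsol1, dsol4, inter, alpha=alpha, lfc_cutoff=lfc_cutoff
    )
    _write(cats, out_dir / "categories.tsv")
    summary["category_counts"] = cats["category"].value_counts().to_dict()

    # --- pooled 5'P tracks per condition x fraction ---------------------
    pooled = {}
    for cond in CONDITIONS:
        for frac in FRACTIONS:
            ids = samples.index[
                (samples["condition"] == cond)
                & (samples["fraction"] == frac)
                & (samples["assay"] == "5P")
            ]
            pooled[(cond, frac)] = pool_tracks(tracksets, ids, f"{cond}_{frac}_5P")
    target_catalog = catalog.target

    # --- RDO tables, differential RDO total vs soluble, tAI test --------
    tai = dwell.load_tai(tai_path)
    rdo_frames = []
    rdo_tables = {}
    for (cond, frac), ts in pooled.items():
        table = dwell.rdo(ts, target_catalog)
        rdo_tables[(cond, frac)] = table
        frame = table.to_frame()
        frame.insert(0, "condition", cond)
        frame.insert(1, "fraction", frac)
        rdo_frames.append(frame.reset_index())
    _write(pd.concat(rdo_frames).set_index("codon"), out_dir / "rdo.tsv")
    diff = dwell.differential_rdo(rdo_tables[("WT", "soluble")],
                                  rdo_tables[("WT", "total")])
    tai_res = dwell.tai_analysis(diff, tai)
    diff_frame = pd.DataFrame({"log2fc_rdo_total_vs_soluble": diff, "tai": tai})
    _write(diff_frame, out_dir / "differential_rdo_wt.tsv")
    summary["tai_pearson_r"] = tai_res["pearson_r"]
    summary["tai_wilcoxon_p"] = tai_res["wilcoxon_p"]

    # --- metagenes, frames, windows -------------------------------------
    scaled = []
    frames_rows = []
    for (cond, frac), ts in pooled.items():
        prof = dwell.metagene_scaled(ts, target_catalog, n_bins=20)
        f = prof.to_frame()
        f.insert(0, "condition", cond)
        f.insert(1, "fraction", frac)
        scaled.append(f)
        f0, f1, f2 = dwell.frame_fractions(ts, target_catalog)
        frames_rows.append((cond, frac, f0, f1, f2))
    _write(pd.concat(scaled).set_index("condition"), out_dir / "metagene_scaled20.tsv")
    frames = pd.DataFrame(
        frames_rows, columns=["condition", "fraction", "frame0", "frame1", "frame2"]
    ).set_index("condition")
    _write(frames, out_dir / "frame_fractions.tsv")
    summary["frame1_wt_total"] = float(
        frames.loc[
            (frames.index == "WT") & (frames["fraction"] == "total"), "frame1"
        ].iloc[0]
    )
    for anchor in ("start", "stop"):
        prof = dwell.metagene_anchored(pooled[("WT", "total")], target_catalog,
                                       anchor=anchor)
        _write(prof.to_frame().set_index("offset"),
               out_dir / f"metagene_{anchor}_wt_total.tsv")
    windows = dwell.window_ratio(
        pooled[("WT", "soluble")], pooled[("WT", "total")], target_catalog
    )
    _write(windows.set_index("gene"), out_dir / "window_proportions_wt.tsv")
    summary["n_genes_windowed"] = int(windows["gene"].nunique())

    # --- ChEC ------------------------------------------------------------
    chec_path = data_dir / "chec_counts.tsv"
    if chec_path.exists():
        chec_counts = pd.read_csv(chec_path, sep="\t", index_col="gene")
        contig_len = int(chec_counts["pos"].max() + 10_000)
        regions = crosslink.promoter_windows(
            chec_counts.reset_index()[["gene", "chrom", "pos", "strand"]],
            {"chec_contig": contig_len},
        )
        sig = crosslink.chec_signal(
            chec_counts["count_sample"], chec_counts["count_control"], regions
        )
        _write(sig, out_dir / "chec_signal.tsv")
        summary["chec_mode"] = float(sig.attrs["mode"])

    # --- PAR-CLIP --------------------------------------------------------
    par_path = data_dir / "parclip_counts.tsv"
    if par_path.exists():
        par = pd.read_csv(par_path, sep="\t", index_col="region")
        d4 = crosslink.parclip_density(par, "transitions_not4")
        dp = crosslink.parclip_density(par, "transitions_rnapii")
        cls = crosslink.relative_crosslink(d4, dp)
        out = pd.concat(
            [d4.rename("density_not4"), dp.rename("density_rnapii"), cls], axis=1
        )
        _write(out, out_dir / "parclip_classes.tsv")
        summary["parclip_class_counts"] = (
            cls["crosslink_class"].value_counts().to_dict()
        )

    with open(out_dir / "report_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return summary


def digest_outputs(out_dir) -> dict[str, str]:
    """sha256 of every TSV/JSON under ``out_dir`` (determinism check)."""
    out = {}
    for path in sorted(Path(out_dir).rglob("*")):
        if path.is_file() and path.suffix in (".tsv", ".json", ".bedgraph"):
            out[str(path.relative_to(out_dir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return out
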