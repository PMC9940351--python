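"""Ground-truth simulator for solubility-resolved 5'P degradome experiments.

The generator emits a complete multi-condition experiment — a two-species
transcriptome (target + spike-in), 5'P-Seq and RNA-Seq 5'-end tracks and
CDS counts for WT and three depletion conditions (not1d, not4d, not5d) in
soluble and total fractions with replicates, plus ChEC promoter counts and
PAR-CLIP transition tables — together with the ground truth every
downstream estimator is supposed to recover.

Generative model, per gene g and library:

* expression ``e_g`` is log-normal; spike genes are condition-invariant.
* the *total* pool contains all molecules; the *soluble* pool is a
  binomial thinning by the gene's solubility fraction ``s_g``; condition
  effects shift ``s_g`` multiplicatively on the log2 scale.
* 5'P decay-intermediate counts scale with a per-condition/fraction
  degradation factor ``d``; each intermediate places its 5' end, with
  probability pi (the periodic fraction), 17 nt upstream of a codon drawn
  proportionally to a per-codon dwell multiplier exp(-a * tAI) times a
  linear positional ramp (decay-onset delay), and uniformly otherwise.
* RNA-Seq counts are negative-binomial around the expression means with
  uniform 5'-end placement; both assays share the NB replicate dispersion.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    CONDITIONS,
    FRACTIONS,
    CountMatrix,
    FivePrimeTrackSet,
    Transcript,
    TranscriptCatalog,
    reverse_complement,
    write_bedgraph,
    write_counts_tsv,
)
from .dwell import A_SITE_OFFSET, SENSE_CODONS, load_tai

SPIKE_PREFIX = "SPIKE_"
_FLANK = 50  # nt of random sequence around each simulated CDS


def _default_deg_factors() -> dict:
    # Direction of the condition effects on relative degradation: the
    # soluble degradome drops on Not1 depletion, rises on Not4 and (less)
    # Not5 depletion; the total pool rises slightly in all depletions.
    return {
        ("WT", "soluble"): 1.0,
        ("not1d", "soluble"): 0.6,
        ("not4d", "soluble"): 1.5,
        ("not5d", "soluble"): 1.2,
        ("WT", "total"): 1.0,
        ("not1d", "total"): 1.15,
        ("not4d", "total"): 1.15,
        ("not5d", "total"): 1.1,
    }


@dataclass
class SimulationConfig:
    """Parameters of the simulated experiment (defaults = study conditions)."""

    n_genes_target: int = 300
    n_genes_spike: int = 40
    cds_length_range: tuple[int, int] = (300, 1500)
    codon_usage: dict | None = None  # codon -> prob; default uniform over 61
    # --- 5'P placement ---
    dwell_strength: float = 3.0  # a in dwell = exp(-a * tAI)
    fraction_dwell_scale: dict = field(
        default_factory=lambda: {"soluble": 0.5, "total": 1.0}
    )
    condition_dwell_scale: dict = field(
        default_factory=lambda: {c: 1.0 for c in CONDITIONS}
    )
    periodic_fraction: dict = field(
        default_factory=lambda: {"soluble": 0.55, "total": 0.75}
    )
    positional_trend: dict = field(
        default_factory=lambda: {"soluble": 0.0, "total": 1.0}
    )  # ramp slope: weight 1 at CDS start -> 1 + slope at the end
    # --- abundance ---
    expression_sigma: float = 0.8  # log-normal spread of expression
    mean_count: float = 300.0  # mean CDS count per gene and library
    depth_5p: int | None = None  # override: total 5'P ends per library
    depth_rna: int | None = None
    # Replicate-level NB dispersion.  The emulated design splits one lysate
    # into fractions and spikes each library identically, so replicates are
    # technical-quality (cv ~7%); biological replication would be 0.02-0.05.
    nb_dispersion: float = 0.005
    n_replicates: int = 3
    # --- solubility ground truth ---
    solubility_range: tuple[float, float] = (0.2, 0.8)
    frac_red: float = 0.1  # less soluble in not1d, more in not4d
    frac_green: float = 0.1
    planted_solubility: float = 0.4
    sol_shift_log2: float = 1.0  # |Delta solubility LFC| for planted genes
    not5d_shift_log2: float = 0.2  # mild, same direction as not4d
    deg_factors: dict = field(default_factory=_default_deg_factors)
    # --- ChEC ---
    n_promoters: int = 1000
    chec_mean_count: float = 200.0
    chec_enriched_fraction: float = 0.1
    chec_enrichment: float = 4.0
    # --- PAR-CLIP ---
    n_parclip_regions: int = 1000
    parclip_t_range: tuple[int, int] = (200, 2000)
    parclip_rate: float = 0.05  # mean transitions per T
    parclip_rate_sigma: float = 0.5
    parclip_frac_higher: float = 0.1
    parclip_frac_lower: float = 0.05
    parclip_ratio: float = 4.0  # planted Not4/RNAPII rate ratio (>= 2x class)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cds_length_range
        if lo < 60 or hi < lo:
            raise ValueError("cds_length_range must be (lo, hi) with lo >= 60")
        for frac in FRACTIONS:
            if not 0.0 <= self.periodic_fraction[frac] <= 1.0:
                raise ValueError("periodic_fraction must be in [0, 1]")
        s0, s1 = self.solubility_range
        if not (0 < s0 <= s1 < 1):
            raise ValueError("solubility_range must lie inside (0, 1)")
        if self.frac_red + self.frac_green > 1:
            raise ValueError("planted fractions exceed 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_genes_target + self.n_genes_spike

    def resolved_depth(self, assay: str) -> int:
        override = self.depth_5p if assay == "5P" else self.depth_rna
        if override is not None:
            return int(override)
        return int(round(self.mean_count * self.n_genes))

    def codon_probs(self) -> pd.Series:
        if self.codon_usage is None:
            p = pd.Series(1.0, index=list(SENSE_CODONS))
        else:
            p = pd.Series(self.codon_usage, dtype=float).reindex(
                list(SENSE_CODONS), fill_value=0.0
            )
        if (p < 0).any() or p.sum() <= 0:
            raise ValueError("invalid codon usage")
        return p / p.sum()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deg_factors"] = {f"{c}/{f}": v for (c, f), v in self.deg_factors.items()}
        return d


@dataclass
class GroundTruth:
    """True parameter values aligned to the emitted gene/codon/region ids."""

    genes: pd.DataFrame  # expression, solubility per condition, category, deg LFCs
    dwell: pd.DataFrame  # codon, tai, dwell multiplier per fraction
    chec: pd.DataFrame | None = None
    parclip: pd.DataFrame | None = None

    def write(self, outdir: Path) -> list[Path]:
        outdir = Path(outdir)
        paths = []
        for name, frame in [
            ("ground_truth_genes.tsv", self.genes),
            ("ground_truth_dwell.tsv", self.dwell),
            ("ground_truth_chec.tsv", self.chec),
            ("ground_truth_parclip.tsv", self.parclip),
        ]:
            if frame is None:
                continue
            p = outdir / name
            frame.to_csv(p, sep="\t", float_format="%.6g")
            paths.append(p)
        return paths


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def generate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> TranscriptCatalog:
    """Random two-species transcript catalog.

    Each gene sits on its own contig with random flanks; CDSs start with
    ATG, end with a single TAA stop, and draw internal codons from the
    configured codon usage.  Strands alternate so both orientations are
    exercised; spike-in contigs carry the ``SPIKE_`` prefix.
    """
    rng = _as_rng(rng, config, "transcriptome")
    probs = config.codon_probs()
    codons = np.array(probs.index)
    lo, hi = config.cds_length_range
    entries = []
    for i in range(config.n_genes):
        spike = i >= config.n_genes_target
        gid = f"spk{i - config.n_genes_target + 1:04d}" if spike else f"g{i + 1:04d}"
        chrom = (SPIKE_PREFIX if spike else "chr_") + gid
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        internal = rng.choice(codons, size=n_codons - 2, p=probs.to_numpy())
        seq = "ATG" + "".join(internal) + "TAA"
        strand = "+" if i % 2 == 0 else "-"
        start = _FLANK
        entries.append(
            Transcript(
                id=gid,
                chrom=chrom,
                strand=strand,
                segments=[(start, start + len(seq))],
                cds_sequence=seq,
                species="spike" if spike else "target",
            )
        )
    return TranscriptCatalog(entries)


def write_annotation(catalog: TranscriptCatalog, fasta_path, gff_path,
                     rng: np.random.Generator | None = None) -> None:
    """Write the simulated genome FASTA and GFF3 for the catalog."""
    rng = np.random.default_rng(0) if rng is None else rng
    bases = np.array(list("ACGT"))
    with open(fasta_path, "w") as fa, open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for t in catalog:
            flank5 = "".join(rng.choice(bases, _FLANK))
            flank3 = "".join(rng.choice(bases, _FLANK))
            body = t.cds_sequence if t.strand == "+" else reverse_complement(
                t.cds_sequence
            )
            contig = flank5 + body + flank3
            fa.write(f">{t.chrom}\n")
            for j in range(0, len(contig), 70):
                fa.write(contig[j : j + 70] + "\n")
            s, e = t.segments[0]
            gff.write(
                f"{t.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                f"ID=gene:{t.id}\n"
            )
            gff.write(
                f"{t.chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                f"ID=tx:{t.id};Parent=gene:{t.id}\n"
            )
            gff.write(
                f"{t.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t"
                f"ID=cds:{t.id};Parent=tx:{t.id};gene_id={t.id}\n"
            )


# ---------------------------------------------------------------------------
# per-gene parameters
# ---------------------------------------------------------------------------

def draw_gene_parameters(
    catalog: TranscriptCatalog, config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Expression, solubility fractions per condition, and category labels."""
    rng = _as_rng(rng, config, "genes")
    genes = [t.id for t in catalog]
    species = pd.Series({t.id: t.species for t in catalog})
    n = len(genes)
    expr = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=n)

    target_ids = [g for g in genes if species[g] == "target"]
    n_target = len(target_ids)
    n_red = int(round(config.frac_red * n_target))
    n_green = int(round(config.frac_green * n_target))
    category = pd.Series("none", index=genes, dtype=object)
    category[target_ids[:n_red]] = "red"
    category[target_ids[n_red : n_red + n_green]] = "green"

    s0, s1 = config.solubility_range
    s_wt = pd.Series(rng.uniform(s0, s1, size=n), index=genes)
    planted = category != "none"
    s_wt[planted] = config.planted_solubility
    s_wt[species == "spike"] = 1.0  # spike-in added per library, not fractionated

    shift = config.sol_shift_log2
    mild = config.not5d_shift_log2
    sol = {"WT": s_wt.copy()}
    for cond, scale in [("not1d", shift), ("not4d", shift), ("not5d", mild)]:
        delta = pd.Series(0.0, index=genes)
        if cond == "not1d":
            delta[category == "red"] = -scale
            delta[category == "green"] = +scale
        else:  # not4d direction; not5d mildly resembles not4d
            delta[category == "red"] = +scale
            delta[category == "green"] = -scale
        s = np.clip(s_wt * np.exp2(delta), 0.01, 0.99)
        s[species == "spike"] = 1.0
        sol[cond] = s

    out = pd.DataFrame({"species": species, "expression": expr, "category": category})
    median_s = {c: float(np.median(sol[c][species == "target"])) for c in CONDITIONS}
    for cond in CONDITIONS:
        out[f"s_{cond}"] = sol[cond]
        # centered true solubility LFC: what a library-normalized soluble
        # vs total contrast estimates for this gene
        out[f"sol_lfc_{cond}"] = np.log2(sol[cond] / median_s[cond])
        out[f"dsol_{cond}"] = np.log2(sol[cond] / sol["WT"])
    for (cond, frac), d in config.deg_factors.items():
        out[f"deg_lfc_{cond}_{frac}"] = np.log2(
            d / config.deg_factors[("WT", frac)]
        )
    out.index.name = "gene"
    return out


def dwell_multipliers(config: SimulationConfig, tai: pd.Series,
                      condition: str = "WT") -> dict[str, pd.Series]:
    """Per-codon dwell weight exp(-a * tAI) per fraction for a condition."""
    out = {}
    for frac in FRACTIONS:
        a = (
            config.dwell_strength
            * config.fraction_dwell_scale[frac]
            * config.condition_dwell_scale[condition]
        )
        w = np.exp(-a * tai.loc[list(SENSE_CODONS)])
        out[frac] = w / w.mean()
    return out


# ---------------------------------------------------------------------------
# libraries
# ---------------------------------------------------------------------------

def _as_rng(rng, config: SimulationConfig | None = None, label: str = "") -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        base = 0 if config is None else config.seed
        digest = hashlib.sha256(f"{base}:{label}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:4], "little"))
    return np.random.default_rng(int(rng))


def _position_probs(
    transcript: Transcript, dwell: pd.Series, pi: float, trend_slope: float,
    offset: int = A_SITE_OFFSET,
) -> np.ndarray:
    """5'-end placement distribution over CDS positions for one gene."""
    L = transcript.cds_length
    p = np.full(L, (1.0 - pi) / L)
    if pi > 0:
        codons = transcript.codons()[:-1]  # exclude the stop codon
        starts = 3 * np.arange(len(codons))
        keep = starts >= offset
        w = np.array(
            [dwell.get(c, 0.0) for c in codons], dtype=float
        ) * (1.0 + trend_slope * starts / max(L - 1, 1))
        w[~keep] = 0.0
        total = w.sum()
        if total > 0:
            p[starts[keep] - offset] += pi * w[keep] / total
        else:  # no eligible codon: fall back to uniform
            p += pi / L
    return p


def _expected_weights(
    catalog: TranscriptCatalog, params: pd.DataFrame, config: SimulationConfig,
    condition: str, fraction: str, assay: str,
) -> pd.Series:
    """Unnormalized expected abundance per gene for one library."""
    w = params["expression"].copy()
    target = params["species"] == "target"
    # soluble pool: binomial thinning by the solubility fraction
    if fraction == "soluble":
        w[target] *= params.loc[target, f"s_{condition}"]
    if assay == "5P":
        w[target] *= config.deg_factors[(condition, fraction)]
    return w


def simulate_5p_sample(
    catalog: TranscriptCatalog,
    config: SimulationConfig,
    condition: str = "WT",
    fraction: str = "total",
    seed=None,
    params: pd.DataFrame | None = None,
    tai: pd.Series | None = None,
    sample_id: str | None = None,
) -> FivePrimeTrackSet:
    """One 5'P-Seq library: per-transcript 5'-end tracks.

    Per gene, the number of decay intermediates is negative-binomial around
    ``expression x degradation x fraction-weight x depth``; each 5' end is
    either ribosome-delimited (probability pi: placed 17 nt upstream of a
    codon drawn by dwell x positional ramp) or background (uniform over the
    CDS).  Spike-in genes are condition-invariant with uniform ends.
    """
    rng = _as_rng(seed, config, f"5P:{condition}:{fraction}")
    if params is None:
        params = draw_gene_parameters(catalog, config)
    if tai is None:
        tai = load_tai()
    dwell = dwell_multipliers(config, tai, condition)[fraction]
    pi = config.periodic_fraction[fraction]
    trend = config.positional_trend[fraction]
    depth = config.resolved_depth("5P")
    weights = _expected_weights(catalog, params, config, condition, fraction, "5P")
    lam = depth * weights / weights.sum()
    tracks = {}
    for t in catalog:
        mu = float(lam[t.id])
        mu = _nb_mean(rng, mu, config.nb_dispersion)
        n = int(rng.poisson(mu))
        if t.species == "spike":
            p = np.full(t.cds_length, 1.0 / t.cds_length)
        else:
            p = _position_probs(t, dwell, pi, trend)
        tracks[t.id] = rng.multinomial(n, p).astype(np.int64)
    sid = sample_id or f"{condition}_{fraction}_5P"
    return FivePrimeTrackSet(sample_id=sid, tracks=tracks)


def _nb_mean(rng: np.random.Generator, mu: float, dispersion: float) -> float:
    """Gamma-distributed replicate mean giving NB(mu, dispersion) counts."""
    if dispersion <= 0 or mu <= 0:
        return mu
    shape = 1.0 / dispersion
    return float(rng.gamma(shape, mu / shape))


def simulate_rna_sample(
    catalog: TranscriptCatalog,
    config: SimulationConfig,
    condition: str = "WT",
    fraction: str = "total",
    seed=None,
    params: pd.DataFrame | None = None,
    sample_id: str | None = None,
) -> tuple[FivePrimeTrackSet, pd.Series]:
    """One RNA-Seq library: NB counts per gene, 5' ends uniform over the CDS."""
    rng = _as_rng(seed, config, f"RNA:{condition}:{fraction}")
    if params is None:
        params = draw_gene_parameters(catalog, config)
    depth = config.resolved_depth("RNA")
    weights = _expected_weights(catalog, params, config, condition, fraction, "RNA")
    lam = depth * weights / weights.sum()
    tracks = {}
    counts = {}
    for t in catalog:
        mu = _nb_mean(rng, float(lam[t.id]), config.nb_dispersion)
        n = int(rng.poisson(mu))
        counts[t.id] = n
        p = np.full(t.cds_length, 1.0 / t.cds_length)
        tracks[t.id] = rng.multinomial(n, p).astype(np.int64)
    sid = sample_id or f"{condition}_{fraction}_RNA"
    ts = FivePrimeTrackSet(sample_id=sid, tracks=tracks)
    return ts, pd.Series(counts, dtype=np.int64)


def simulate_count_matrix(
    config: SimulationConfig,
    conditions=CONDITIONS,
    assays=("5P", "RNA"),
    params: pd.DataFrame | None = None,
    catalog: TranscriptCatalog | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """CDS count matrix only, skipping positional 5'-end placement.

    Same abundance model as the full track simulation (NB counts around
    expression x solubility x degradation means), but drawing the CDS total
    per gene directly; orders of magnitude faster when only count-level
    statistics (solubility, relative degradation, categories) are needed.
    Returns (matrix, gene parameter table).
    """
    if catalog is None:
        catalog = generate_transcriptome(config)
    if params is None:
        params = draw_gene_parameters(catalog, config)
    samples = sample_table(config)
    keep = samples["condition"].isin(conditions) & samples["assay"].isin(assays)
    samples = samples[keep]
    seeds = np.random.SeedSequence(config.seed).spawn(8)[7].spawn(len(samples))
    data = {}
    for (sid, meta), sseq in zip(samples.iterrows(), seeds):
        rng = np.random.default_rng(sseq)
        depth = config.resolved_depth(meta["assay"])
        w = _expected_weights(
            catalog, params, config, meta["condition"], meta["fraction"],
            meta["assay"],
        )
        mu = depth * w.to_numpy() / w.sum()
        if config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            mu = rng.gamma(shape, mu / shape)
        data[sid] = rng.poisson(mu).astype(np.int64)
    counts = pd.DataFrame(data, index=params.index)
    matrix = CountMatrix(counts, samples, params["species"])
    return matrix, params


# ---------------------------------------------------------------------------
# ChEC and PAR-CLIP
# ---------------------------------------------------------------------------

def simulate_chec(
    config: SimulationConfig, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter-window counts for the MNase fusion vs free MNase.

    Counts are Poisson with a length-proportional background; a configured
    subset of promoters is enriched ``chec_enrichment``-fold in the fusion
    sample.  Returns (counts table, ground truth).
    """
    rng = _as_rng(seed, config, "chec")
    n = config.n_promoters
    ids = [f"prom{i + 1:04d}" for i in range(n)]
    length = np.full(n, 501)
    n_enriched = int(round(config.chec_enriched_fraction * n))
    enrichment = np.ones(n)
    enrichment[:n_enriched] = config.chec_enrichment
    base = config.chec_mean_count * length / 501
    counts_control = rng.poisson(base)
    counts_sample = rng.poisson(base * enrichment)
    pos = 2000 + 1000 * np.arange(n)
    table = pd.DataFrame(
        {
            "chrom": "chec_contig",
            "pos": pos,
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
            "count_sample": counts_sample,
            "count_control": counts_control,
        },
        index=pd.Index(ids, name="gene"),
    )
    truth = pd.DataFrame(
        {"enrichment": enrichment, "true_lfc": np.log2(enrichment)},
        index=pd.Index(ids, name="gene"),
    )
    return table, truth


def simulate_parclip(
    config: SimulationConfig, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region T->C transition counts for Not4 and RNAPII.

    Both factors share a log-normal per-region cross-link rate; a planted
    subset deviates ``parclip_ratio``-fold up (class 'higher') or down
    ('lower') in Not4.  Transitions are Poisson(T_count x rate).
    """
    rng = _as_rng(seed, config, "parclip")
    n = config.n_parclip_regions
    ids = [f"region{i + 1:04d}" for i in range(n)]
    t_lo, t_hi = config.parclip_t_range
    t_count = rng.integers(t_lo, t_hi + 1, size=n)
    rate = config.parclip_rate * rng.lognormal(
        -0.5 * config.parclip_rate_sigma**2, config.parclip_rate_sigma, size=n
    )
    n_hi = int(round(config.parclip_frac_higher * n))
    n_lo = int(round(config.parclip_frac_lower * n))
    ratio = np.ones(n)
    ratio[:n_hi] = config.parclip_ratio
    ratio[n_hi : n_hi + n_lo] = 1.0 / config.parclip_ratio
    label = np.array(["expected"] * n, dtype=object)
    label[:n_hi] = "higher"
    label[n_hi : n_hi + n_lo] = "lower"
    transitions_rnapii = rng.poisson(t_count * rate)
    transitions_not4 = rng.poisson(t_count * rate * ratio)
    table = pd.DataFrame(
        {
            "t_count": t_count,
            "transitions_not4": transitions_not4,
            "transitions_rnapii": transitions_rnapii,
        },
        index=pd.Index(ids, name="region"),
    )
    truth = pd.DataFrame(
        {"rate_ratio": ratio, "true_class": label},
        index=pd.Index(ids, name="region"),
    )
    return table, truth


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def sample_table(config: SimulationConfig) -> pd.DataFrame:
    """The 4 conditions x 2 fractions x 2 assays x replicates design."""
    rows = []
    for cond in CONDITIONS:
        for frac in FRACTIONS:
            for assay in ("5P", "RNA"):
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{cond}_{frac}_{assay}_r{rep}"
                    rows.append((sid, cond, frac, assay, rep))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "fraction", "assay", "replicate"]
    ).set_index("sample")


def simulate_experiment(
    config: SimulationConfig, outdir=None, tai: pd.Series | None = None
):
    """Run the full generator; optionally write everything under ``outdir``.

    Returns (catalog, tracksets, count matrix, ground truth, manifest).
    The manifest records the config, the library list and sha256 digests of
    every written file, so two runs with the same config are comparable
    byte for byte.
    """
    if tai is None:
        tai = load_tai()
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rng_tx, rng_genes, rng_libs, rng_chec, rng_par, rng_fasta = (
        np.random.default_rng(s) for s in seeds
    )
    catalog = generate_transcriptome(config, rng_tx)
    params = draw_gene_parameters(catalog, config, rng_genes)
    samples = sample_table(config)

    tracksets: dict[str, FivePrimeTrackSet] = {}
    lib_seed = np.random.SeedSequence(config.seed).spawn(7)[6].spawn(len(samples))
    for (sid, meta), sseq in zip(samples.iterrows(), lib_seed):
        rng = np.random.default_rng(sseq)
        if meta["assay"] == "5P":
            ts = simulate_5p_sample(
                catalog, config, meta["condition"], meta["fraction"],
                seed=rng, params=params, tai=tai, sample_id=sid,
            )
        else:
            ts, _ = simulate_rna_sample(
                catalog, config, meta["condition"], meta["fraction"],
                seed=rng, params=params, sample_id=sid,
            )
        tracksets[sid] = ts

    counts = pd.DataFrame(
        {sid: {g: int(ts.tracks[g].sum()) for g in (t.id for t in catalog)}
         for sid, ts in tracksets.items()}
    ).loc[[t.id for t in catalog], samples.index]
    matrix = CountMatrix(counts, samples, pd.Series({t.id: t.species for t in catalog}))

    dwell_wt = dwell_multipliers(config, tai, "WT")
    dwell_truth = pd.DataFrame(
        {
            "tai": tai.loc[list(SENSE_CODONS)],
            "dwell_soluble": dwell_wt["soluble"],
            "dwell_total": dwell_wt["total"],
        }
    )
    dwell_truth.index.name = "codon"
    chec_table, chec_truth = simulate_chec(config, rng_chec)
    par_table, par_truth = simulate_parclip(config, rng_par)
    truth = GroundTruth(
        genes=params, dwell=dwell_truth, chec=chec_truth, parclip=par_truth
    )

    manifest = {
        "config": config.to_dict(),
        "n_libraries": int(len(samples)),
        "libraries": list(samples.index),
        "files": {},
    }
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "tracks").mkdir(parents=True, exist_ok=True)
        write_annotation(catalog, outdir / "genome.fa", outdir / "annotation.gff3",
                         rng=rng_fasta)
        for sid, ts in tracksets.items():
            write_bedgraph(ts, outdir / "tracks" / f"{sid}.bedgraph")
        write_counts_tsv(matrix, outdir / "counts.tsv", outdir / "samples.tsv")
        chec_table.to_csv(outdir / "chec_counts.tsv", sep="\t")
        par_table.to_csv(outdir / "parclip_counts.tsv", sep="\t")
        truth.write(outdir)
        for path in sorted(outdir.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                rel = str(path.relative_to(outdir))
                manifest["files"][rel] = hashlib.sha256(
                    path.read_bytes()
                ).hexdigest()
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return catalog, tracksets, matrix, truth, manifest
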