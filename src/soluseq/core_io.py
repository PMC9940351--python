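"""Annotation, sequence and 5'-end track handling.

Everything downstream of alignment starts here: a :class:`TranscriptCatalog`
built from GFF3 + FASTA gives every protein-coding gene a spliced CDS
sequence in transcript coordinates (0-based, 0 = first nucleotide of the
start codon), and per-sample :class:`FivePrimeTrackSet` objects hold the
number of read 5' ends at each CDS nucleotide.  Counts aggregated over the
CDS go into a :class:`CountMatrix` whose genes carry a species tag so that
spike-in (foreign species) genes can be split off for normalization.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based,
closed) is converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

CONDITIONS = ("WT", "not1d", "not4d", "not5d")
FRACTIONS = ("soluble", "total")
ASSAYS = ("5P", "RNA")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    """A protein-coding gene reduced to its (spliced) CDS.

    ``segments`` are genomic half-open intervals in transcript order
    (5'->3' of the mRNA); for minus-strand genes the first segment is the
    rightmost one.  ``cds_sequence`` always reads 5'->3'.
    """

    id: str
    chrom: str
    strand: str
    segments: list[tuple[int, int]]
    cds_sequence: str
    species: str = "target"

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def cds_start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def cds_end(self) -> int:
        return max(e for _, e in self.segments)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to a CDS coordinate, or None if outside."""
        offset = 0
        for s, e in self.segments:
            if s <= gpos < e:
                if self.strand == "+":
                    return offset + (gpos - s)
                return offset + (e - 1 - gpos)
            offset += e - s
        return None

    def codons(self) -> list[str]:
        seq = self.cds_sequence
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@dataclass
class TranscriptCatalog:
    entries: list[Transcript]
    skipped: int = 0

    def __post_init__(self) -> None:
        self._by_id = {t.id: t for t in self.entries}
        if len(self._by_id) != len(self.entries):
            raise ValueError("duplicate transcript ids in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, tid: str) -> Transcript:
        return self._by_id[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_id

    def subset(self, ids) -> "TranscriptCatalog":
        ids = set(ids)
        return TranscriptCatalog([t for t in self.entries if t.id in ids])

    @property
    def target(self) -> "TranscriptCatalog":
        return TranscriptCatalog([t for t in self.entries if t.species == "target"])

    @property
    def spike(self) -> "TranscriptCatalog":
        return TranscriptCatalog([t for t in self.entries if t.species == "spike"])


@dataclass
class FivePrimeTrackSet:
    """Per-transcript 5'-end depth in transcript coordinates for one sample."""

    sample_id: str
    tracks: dict[str, np.ndarray]
    library_size: int = 0

    def __post_init__(self) -> None:
        for tid, arr in self.tracks.items():
            arr = np.asarray(arr, dtype=np.int64)
            if (arr < 0).any():
                raise ValueError(f"negative counts in track {tid}")
            self.tracks[tid] = arr
        total = int(sum(int(a.sum()) for a in self.tracks.values()))
        if self.library_size == 0:
            self.library_size = total
        elif total > self.library_size:
            raise ValueError("track counts exceed declared library size")

    def total_ends(self) -> int:
        return int(sum(int(a.sum()) for a in self.tracks.values()))


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample metadata and species tags.

    ``samples`` must carry columns condition / fraction / assay / replicate;
    ``species`` maps every gene to 'target' or 'spike'.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    species: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = {"condition", "fraction", "assay", "replicate"} - set(
            self.samples.columns
        )
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if list(self.samples.index) != list(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")
        self.species = self.species.reindex(self.counts.index)
        if self.species.isna().any():
            raise ValueError("species tag missing for some genes")

    def select(self, **criteria) -> "CountMatrix":
        """Subset samples by metadata equality, e.g. select(assay='RNA')."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            vals = value if isinstance(value, (list, tuple, set)) else [value]
            mask &= self.samples[key].isin(list(vals))
        cols = self.samples.index[mask]
        return CountMatrix(self.counts[cols], self.samples.loc[cols], self.species)


def load_annotation(
    gff3_path, fasta_path, spike_prefix: str = "SPIKE_"
) -> TranscriptCatalog:
    """Build a transcript catalog from a GFF3 and genome FASTA.

    One transcript per protein-coding gene (the longest CDS wins when a gene
    has several mRNAs); CDS segments are spliced in transcript order and
    minus-strand sequences reverse-complemented so that ``cds_sequence``
    reads 5'->3'.  Genes whose spliced CDS length is not a positive multiple
    of 3 are skipped with a warning (tallied in ``catalog.skipped``).
    Chromosomes whose name starts with ``spike_prefix`` are tagged as
    spike-in species.
    """
    import gffutils

    fasta = Fasta(str(fasta_path), rebuild=False)
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    # Group CDS features by their parent attribute (mRNA/transcript id or,
    # failing that, the gene id).
    groups: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        attr = cds.attributes
        parent = (attr.get("Parent") or attr.get("ID") or attr.get("gene_id"))
        if not parent:
            continue
        parent = parent[0]
        gene = (attr.get("gene_id") or [parent])[0]
        g = groups.setdefault(
            parent,
            {"chrom": cds.seqid, "strand": cds.strand, "gene": gene, "segs": []},
        )
        g["segs"].append((cds.start - 1, cds.end))  # GFF3 1-closed -> half-open

    # Reduce to one transcript per gene: longest spliced CDS wins.
    by_gene: dict[str, dict] = {}
    for parent, g in groups.items():
        g["length"] = sum(e - s for s, e in g["segs"])
        g["parent"] = parent
        prev = by_gene.get(g["gene"])
        if prev is None or g["length"] > prev["length"]:
            by_gene[g["gene"]] = g

    entries: list[Transcript] = []
    skipped = 0
    for gene, g in sorted(by_gene.items()):
        if g["length"] % 3 != 0 or g["length"] == 0:
            logger.warning(
                "skipping %s: CDS length %d not a positive multiple of 3",
                gene,
                g["length"],
            )
            skipped += 1
            continue
        chrom = g["chrom"]
        if chrom not in fasta:
            raise ValueError(f"chromosome {chrom!r} missing from FASTA")
        segs = sorted(g["segs"])
        if g["strand"] == "-":
            segs = segs[::-1]
        parts = []
        for s, e in segs:
            piece = str(fasta[chrom][s:e])
            parts.append(reverse_complement(piece) if g["strand"] == "-" else piece)
        seq = "".join(parts).upper()
        entries.append(
            Transcript(
                id=gene,
                chrom=chrom,
                strand=g["strand"],
                segments=segs,
                cds_sequence=seq,
                species="spike" if chrom.startswith(spike_prefix) else "target",
            )
        )
    return TranscriptCatalog(entries, skipped=skipped)


def _read_bed_reads(bed_path):
    """Yield (chrom, start, end, strand) aligned-read intervals from 6-col BED."""
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            cols = line.split()
            yield cols[0], int(cols[1]), int(cols[2]), cols[5]


def _read_bam_reads(bam_path):
    import pysam

    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            yield (
                read.reference_name,
                read.reference_start,
                read.reference_end,
                "-" if read.is_reverse else "+",
            )


def iter_reads(path):
    """Iterate aligned reads from a BAM or a 6-column BED file."""
    path = str(path)
    if path.endswith((".bam", ".sam", ".cram")):
        yield from _read_bam_reads(path)
    else:
        yield from _read_bed_reads(path)


class _SegmentIndex:
    """Genomic position -> (transcript, CDS coordinate) lookup."""

    def __init__(self, catalog: TranscriptCatalog):
        self._per_chrom: dict[str, list] = {}
        for t in catalog:
            offset = 0
            for s, e in t.segments:
                self._per_chrom.setdefault(t.chrom, []).append((s, e, t, offset))
                offset += e - s
        for segs in self._per_chrom.values():
            segs.sort(key=lambda x: x[0])

    def hits(self, chrom: str, gpos: int, strand: str):
        """All (transcript, transcript_coordinate) pairs covering gpos, sense only."""
        out = []
        for s, e, t, offset in self._per_chrom.get(chrom, ()):
            if s <= gpos < e and t.strand == strand:
                tpos = offset + (gpos - s if strand == "+" else e - 1 - gpos)
                out.append((t, tpos))
        return out

    def overlapping(self, chrom: str, start: int, end: int, strand: str):
        """Transcripts whose CDS overlaps [start, end) on the given strand."""
        out = set()
        for s, e, t, _ in self._per_chrom.get(chrom, ()):
            if s < end and start < e and t.strand == strand:
                out.add(t.id)
        return out


def build_5p_tracks(
    alignments, catalog: TranscriptCatalog, sample_id: str = "sample"
) -> FivePrimeTrackSet:
    """Count read 5' ends per CDS nucleotide in transcript coordinates.

    ``alignments`` is a BAM/BED path or an iterable of
    (chrom, start, end, strand) tuples.  The 5' end of a plus-strand read is
    its leftmost aligned base; of a minus-strand read its rightmost.
    Antisense reads are ignored; a 5' end inside two overlapping CDSs counts
    toward both.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = iter_reads(alignments)
    index = _SegmentIndex(catalog)
    tracks = {t.id: np.zeros(t.cds_length, dtype=np.int64) for t in catalog}
    n_reads = 0
    for chrom, start, end, strand in alignments:
        n_reads += 1
        gpos = start if strand == "+" else end - 1
        for t, tpos in index.hits(chrom, gpos, strand):
            tracks[t.id][tpos] += 1
    return FivePrimeTrackSet(sample_id=sample_id, tracks=tracks, library_size=n_reads)


def count_cds_overlaps(alignments, catalog: TranscriptCatalog) -> pd.Series:
    """RNA-Seq style counting: reads overlapping a CDS by >= 1 nt."""
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = iter_reads(alignments)
    index = _SegmentIndex(catalog)
    counts = {t.id: 0 for t in catalog}
    for chrom, start, end, strand in alignments:
        for tid in index.overlapping(chrom, start, end, strand):
            counts[tid] += 1
    return pd.Series(counts, dtype=np.int64)


def aggregate_counts(
    tracksets: dict[str, FivePrimeTrackSet],
    catalog: TranscriptCatalog,
    samples: pd.DataFrame,
) -> CountMatrix:
    """Sum 5'-end tracks over the CDS into a gene x sample count matrix.

    ``samples`` is indexed by sample id with condition/fraction/assay/replicate
    columns; every sample id must have a trackset.  Samples with zero
    target-species counts are rejected.
    """
    genes = [t.id for t in catalog]
    data = {}
    target_ids = {t.id for t in catalog if t.species == "target"}
    for sid in samples.index:
        ts = tracksets[sid]
        col = np.array(
            [int(ts.tracks[g].sum()) if g in ts.tracks else 0 for g in genes],
            dtype=np.int64,
        )
        if sum(c for g, c in zip(genes, col) if g in target_ids) == 0:
            raise ValueError(f"sample {sid!r} has zero target-species reads")
        data[sid] = col
    counts = pd.DataFrame(data, index=genes)
    species = pd.Series({t.id: t.species for t in catalog})
    return CountMatrix(counts, samples.copy(), species)


def split_spike(matrix: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    """Partition a count matrix into (target, spike) by species tag."""
    is_spike = matrix.species == "spike"
    if not is_spike.any():
        raise ValueError("spike-in required for relative degradation: no spike genes")
    if is_spike.all():
        raise ValueError("no target genes in matrix")
    target = CountMatrix(
        matrix.counts.loc[~is_spike], matrix.samples, matrix.species[~is_spike]
    )
    spike = CountMatrix(
        matrix.counts.loc[is_spike], matrix.samples, matrix.species[is_spike]
    )
    return target, spike


def write_bedgraph(trackset: FivePrimeTrackSet, path) -> None:
    """Write 5'-end depth as bedGraph in transcript coordinates.

    The chrom field holds the transcript id; runs of equal depth are merged.
    A track line records the sample id and library size so the file round
    trips through :func:`read_bedgraph`.
    """
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{trackset.sample_id}" '
            f"library_size={trackset.library_size}\n"
        )
        for tid in sorted(trackset.tracks):
            arr = trackset.tracks[tid]
            if len(arr) == 0:
                continue
            # run-length encode, keeping zero runs implicit
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v != 0:
                    fh.write(f"{tid}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path, catalog: TranscriptCatalog) -> FivePrimeTrackSet:
    """Read a transcript-coordinate bedGraph written by :func:`write_bedgraph`."""
    tracks = {t.id: np.zeros(t.cds_length, dtype=np.int64) for t in catalog}
    sample_id, library_size = "sample", 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("track"):
                for token in line.split():
                    if token.startswith("name="):
                        sample_id = token.split("=", 1)[1].strip('"')
                    elif token.startswith("library_size="):
                        library_size = int(token.split("=", 1)[1])
                continue
            tid, s, e, v = line.split()
            if tid in tracks:
                tracks[tid][int(s) : int(e)] = int(v)
    return FivePrimeTrackSet(
        sample_id=sample_id, tracks=tracks, library_size=library_size
    )


def write_counts_tsv(matrix: CountMatrix, counts_path, samples_path=None) -> None:
    out = matrix.counts.copy()
    out.insert(0, "species", matrix.species)
    out.to_csv(counts_path, sep="\t", index_label="gene")
    if samples_path is not None:
        matrix.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_counts_tsv(counts_path, samples_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="gene")
    species = df.pop("species")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    samples.index = samples.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df, samples, species)
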