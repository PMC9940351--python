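"""Independent brute-force reference implementations.

Deliberately naive per-read / per-position Python loops, kept free of any
code path from the package so they can serve as oracles for the vectorized
implementations.
"""

import numpy as np


def brute_count_5p_ends(reads, catalog):
    """Per-read tally of 5' ends into transcript coordinates."""
    tracks = {t.id: np.zeros(t.cds_length, dtype=np.int64) for t in catalog}
    for chrom, start, end, strand in reads:
        gpos = start if strand == "+" else end - 1
        for t in catalog:
            if t.chrom != chrom or t.strand != strand:
                continue
            tpos = t.genomic_to_transcript(gpos)
            if tpos is not None:
                tracks[t.id][tpos] += 1
    return tracks


def brute_rdo(tracks, catalog, offset=17):
    """Exhaustive per-position codon occupancy."""
    depth = {}
    npos = {}
    for t in catalog:
        track = tracks[t.id]
        seq = t.cds_sequence
        n_codons = len(seq) // 3 - 1  # stop excluded
        for k in range(n_codons):
            p = 3 * k
            if p < offset:
                continue
            codon = seq[p : p + 3]
            depth.setdefault(codon, []).append(float(track[p - offset]))
            npos[codon] = npos.get(codon, 0) + 1
    all_vals = [v for vals in depth.values() for v in vals]
    overall = sum(all_vals) / len(all_vals)
    occ = {}
    for codon, vals in depth.items():
        occ[codon] = (sum(vals) / len(vals)) / overall if overall > 0 else np.nan
    return occ, npos


def brute_scaled_metagene(tracks, catalog, n_bins):
    profiles = []
    total_depth = 0.0
    total_nt = 0
    for t in catalog:
        track = tracks[t.id]
        L = len(track)
        if L < n_bins:
            continue
        means = []
        for j in range(n_bins):
            lo = (j * L) // n_bins
            hi = ((j + 1) * L) // n_bins
            means.append(sum(track[lo:hi]) / (hi - lo))
        profiles.append(means)
        total_depth += float(sum(track))
        total_nt += L
    avg = np.mean(profiles, axis=0)
    group_mean = total_depth / total_nt
    return avg / group_mean if group_mean > 0 else avg


def brute_anchored_metagene(tracks, catalog, library_size, anchor, shift, lo, hi):
    values = np.zeros(hi - lo + 1)
    for t in catalog:
        track = tracks[t.id]
        if sum(track) == 0:
            continue
        anchor_pos = 0 if anchor == "start" else t.cds_length - 3
        for p in range(len(track)):
            off = p + shift - anchor_pos
            if lo <= off <= hi:
                values[off - lo] += track[p]
    return values / (library_size / 1e6)


def brute_frame_fractions(tracks, catalog):
    counts = [0, 0, 0]
    for t in catalog:
        track = tracks[t.id]
        for p in range(len(track)):
            counts[p % 3] += int(track[p])
    total = sum(counts)
    return tuple(100.0 * c / total for c in counts)


def brute_window_props(track, L, windows):
    total = int(sum(track))
    props = []
    for lo, hi in windows:
        n = sum(int(track[p]) for p in range(L) if lo <= p / L < hi)
        props.append(n / total)
    return props


def brute_size_factors(counts):
    """counts: 2-D list genes x samples."""
    counts = np.asarray(counts, dtype=float)
    usable = [g for g in range(counts.shape[0]) if all(counts[g] > 0)]
    factors = []
    for j in range(counts.shape[1]):
        ratios = []
        for g in usable:
            geo = np.exp(np.mean([np.log(c) for c in counts[g]]))
            ratios.append(counts[g, j] / geo)
        factors.append(float(np.median(ratios)))
    return factors


def brute_bh(pvalues):
    """min over j >= i of m * p_(j) / j, capped at 1."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def brute_welch(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df
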