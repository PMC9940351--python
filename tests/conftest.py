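import numpy as np
import pandas as pd
import pytest

from soluseq.core_io import FivePrimeTrackSet, Transcript, TranscriptCatalog
from soluseq.simulate import SimulationConfig, simulate_experiment


def _random_cds(rng, n_codons):
    sense = [
        a + b + c
        for a in "TCAG"
        for b in "TCAG"
        for c in "TCAG"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    internal = "".join(rng.choice(sense) for _ in range(n_codons - 2))
    return "ATG" + internal + "TAA"


@pytest.fixture(scope="session")
def toy_catalog():
    """Three-gene in-memory catalog (two target, one spike), fixed sequences."""
    rng = np.random.default_rng(42)
    seqs = [_random_cds(rng, n) for n in (30, 40, 25)]
    entries = [
        Transcript("gA", "chr1", "+", [(100, 100 + 90)], seqs[0], "target"),
        Transcript("gB", "chr1", "-", [(400, 400 + 120)], seqs[1], "target"),
        Transcript("gS", "SPIKE_1", "+", [(50, 50 + 75)], seqs[2], "spike"),
    ]
    return TranscriptCatalog(entries)


@pytest.fixture()
def toy_trackset(toy_catalog):
    """Deterministic non-uniform 5'-end tracks on the toy catalog."""
    rng = np.random.default_rng(7)
    tracks = {
        t.id: rng.poisson(2.0, size=t.cds_length).astype(np.int64)
        for t in toy_catalog
    }
    return FivePrimeTrackSet(sample_id="toy", tracks=tracks)


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A small full simulated experiment, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(
        n_genes_target=40,
        n_genes_spike=10,
        cds_length_range=(150, 600),
        mean_count=200.0,
        n_replicates=2,
        n_promoters=300,
        n_parclip_regions=300,
        seed=123,
    )
    catalog, tracksets, matrix, truth, manifest = simulate_experiment(config, outdir)
    return {
        "config": config,
        "catalog": catalog,
        "tracksets": tracksets,
        "matrix": matrix,
        "truth": truth,
        "manifest": manifest,
        "dir": outdir,
    }
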