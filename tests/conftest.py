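import numpy as np
import pandas as pd
import pytest

from prophasetx import pausing, runon
from prophasetx.sim import (
    SimConfig,
    generate_annotation,
    simulate_peaks,
    simulate_runon_table,
    simulate_stage_tracks,
)
from prophasetx.tracks import SignalTrack


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(seed=7, n_chroms=2, chrom_length=200_000, n_genes=12)


@pytest.fixture(scope="session")
def dataset(cfg):
    """One simulated dataset shared across read-only tests."""
    genes, sizes = generate_annotation(cfg)
    tracks = simulate_stage_tracks(cfg, genes, sizes)
    samples, standards = simulate_runon_table(cfg)
    peaks = simulate_peaks(cfg, genes, sizes)
    return {
        "cfg": cfg,
        "genes": genes,
        "sizes": sizes,
        "tracks": tracks,
        "runon_samples": samples,
        "runon_standards": standards,
        "peaks": peaks,
    }


@pytest.fixture(scope="session")
def pi_table(dataset):
    return pausing.pausing_index_table(
        dataset["tracks"], dataset["genes"], dataset["sizes"]
    )


@pytest.fixture
def uniform_track():
    """Value 2.0 over [0, 100) on a single 1 kb chromosome."""
    track = SignalTrack({"chr1": 1000}, strand="+")
    track.set_intervals("chr1", [0], [100], [2.0])
    return track


def make_track(dense_by_chrom, sizes, strand="+"):
    return SignalTrack.from_dense(
        {c: np.asarray(a, dtype=float) for c, a in dense_by_chrom.items()},
        sizes,
        strand=strand,
    )


@pytest.fixture
def hand_gene_track():
    """A plus-strand gene [0, 2250) with planted window counts.

    10 reads in the pause window (250 bp), 40 in the body (2000 bp), 25 in
    the 5 kb post-PAS window: pausing index 2.0, retention index 4.0.
    """
    sizes = {"chr1": 10_000}
    dense = np.zeros(10_000)
    dense[5] = 10.0
    dense[300] = 40.0
    dense[3000] = 25.0
    gene = pd.DataFrame(
        [("chr1", 0, 2250, "g1", 0, "+")],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    plus = make_track({"chr1": dense}, sizes, "+")
    minus = SignalTrack(sizes, strand="-")
    return {"tracks": {"+": plus, "-": minus}, "genes": gene, "sizes": sizes}
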