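"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import a3gscan as a3g
from a3gscan.io import Alignment

SMALL_ANNOTATIONS = [("transcribed", 10, 5_000), ("repeat", 10, 500)]


def small_config(**overrides):
    defaults = dict(genome_length=200_000, annotation_spec=SMALL_ANNOTATIONS, seed=11)
    defaults.update(overrides)
    return a3g.SimulationConfig(**defaults)


def cluster_set_from_sim(sim, p_threshold=None, masks=()):
    aln = Alignment(sim.chrom, sim.sequences)
    muts, callable_length = a3g.call_mutations(aln, masks)
    return a3g.build_cluster_set(muts, callable_length, p_threshold=p_threshold), muts


def mutation_frame(positions, anc="C", der="T", chrom="chr1", windows=None):
    """Minimal hand-built mutation table for clustering tests."""
    n = len(positions)
    anc = [anc] * n if isinstance(anc, str) else list(anc)
    der = [der] * n if isinstance(der, str) else list(der)
    df = pd.DataFrame({
        "chrom": chrom, "pos0": np.asarray(positions, dtype=np.int64),
        "anc": anc, "der": der, "lineage": "target",
    })
    df["window"] = windows if windows is not None else ["NNN" + a + "NNN" for a in anc]
    df["context"] = df["window"].str[2:5]
    return df.sort_values(["chrom", "pos0"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def planted_sim():
    """Baseline planted scenario scaled to 200 kb (~30 events)."""
    return a3g.simulate(small_config())


@pytest.fixture(scope="session")
def null_sim():
    """No planted events, no CpG hypermutation: pure background."""
    return a3g.simulate(small_config(a3g_event_rate=0.0, seed=12))


@pytest.fixture(scope="session")
def planted_cluster_set(planted_sim):
    cs, _ = cluster_set_from_sim(planted_sim)
    return cs


@pytest.fixture(scope="session")
def null_cluster_set(null_sim):
    cs, _ = cluster_set_from_sim(null_sim)
    return cs
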