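"""Block-bootstrap standard errors for position-indexed statistics.

The genome is tiled with contiguous equal-sized blocks (default ~90 kb;
the last block of a chromosome may be short).  Each bootstrap replicate
samples blocks with replacement, pools the rows they contain and
recomputes the statistic; the standard deviation across replicates is the
standard error, with a percentile confidence interval alongside.
Resampling blocks rather than rows respects local correlation along the
chromosome.  The production default is 10,000 replicates; tests use a few
hundred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ArgumentError, UndefinedStatisticError


@dataclass
class BlockScheme:
    blocks: pd.DataFrame  # chrom, start, end
    block_size: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def make_blocks(
    genome_extents: Mapping[str, int] | pd.DataFrame, block_size: int = 90_000,
) -> BlockScheme:
    """Tile each chromosome with ceil(length / block_size) blocks."""
    if block_size <= 0:
        raise ArgumentError("block_size must be positive")
    if isinstance(genome_extents, pd.DataFrame):
        extents = dict(zip(genome_extents["chrom"],
                           genome_extents["end"] - genome_extents.get("start", 0)))
    else:
        extents = dict(genome_extents)
    if not extents:
        raise ArgumentError("genome extents are empty")
    rows = []
    for chrom, length in extents.items():
        starts = np.arange(0, length, block_size, dtype=np.int64)
        ends = np.minimum(starts + block_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return BlockScheme(pd.concat(rows, ignore_index=True), block_size)


def assign_blocks(scheme: BlockScheme, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Block index per (chrom, pos); -1 for positions outside all blocks."""
    out = np.full(len(pos), -1, dtype=np.int64)
    pos = np.asarray(pos)
    chrom = np.asarray(chrom)
    for c, sub in scheme.blocks.groupby("chrom", sort=False):
        sel = chrom == c
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (i >= 0) & (pos[sel] < ends[np.clip(i, 0, len(ends) - 1)])
        idx = sub.index.to_numpy()
        out[np.flatnonzero(sel)[ok]] = idx[i[ok]]
    return out


@dataclass
class BootstrapResult:
    se: float
    ci_low: float
    ci_high: float
    n_boot: int
    estimate: float
    replicates: np.ndarray


def block_bootstrap(
    data: pd.DataFrame,
    scheme: BlockScheme,
    statistic: Callable[[pd.DataFrame], float],
    n_boot: int = 10_000,
    seed: int = 0,
    max_undefined: float = 0.01,
) -> BootstrapResult:
    """SE and 95% percentile CI of ``statistic(data)`` under block
    resampling.  *data* needs ``chrom`` and ``pos0`` columns.  Replicates
    on which the statistic raises :class:`UndefinedStatisticError` or
    returns NaN are tolerated up to ``max_undefined`` of n_boot."""
    if scheme.n_blocks < 2:
        raise ArgumentError("need at least 2 blocks to bootstrap")
    rng = np.random.default_rng(seed)
    block_of = assign_blocks(scheme, data["chrom"].to_numpy(), data["pos0"].to_numpy())
    groups = {b: np.flatnonzero(block_of == b) for b in range(scheme.n_blocks)}
    n = scheme.n_blocks
    try:
        estimate = float(statistic(data))
    except UndefinedStatisticError:
        estimate = float("nan")
    reps = np.empty(n_boot)
    bad = 0
    for r in range(n_boot):
        draw = rng.integers(0, n, size=n)
        idx = np.concatenate([groups[b] for b in draw]) if len(data) else np.array([], int)
        sample = data.iloc[idx]
        try:
            v = float(statistic(sample))
        except UndefinedStatisticError:
            v = np.nan
        reps[r] = v
        if not np.isfinite(v):
            bad += 1
    if bad > max_undefined * n_boot:
        raise UndefinedStatisticError(
            f"statistic undefined on {bad}/{n_boot} bootstrap replicates")
    good = reps[np.isfinite(reps)]
    lo, hi = np.percentile(good, [2.5, 97.5])
    # a constant statistic has SE exactly zero (avoid fp cancellation dust)
    se = 0.0 if np.ptp(good) == 0 else float(np.std(good))
    return BootstrapResult(se, float(lo), float(hi), n_boot, estimate, reps)


def bootstrap_enrichment_se(
    cluster_set,
    background: float,
    scheme: BlockScheme,
    motif=None,
    n_boot: int = 200,
    seed: int = 0,
    cpg_filter: bool = False,
) -> BootstrapResult:
    """Block-bootstrap SE of E for one motif with the background held
    fixed: clustered C/G mutations are resampled by block and the motif
    fraction recomputed on each replicate.  ``cpg_filter`` drops mutations
    whose mutated base sits in a CpG, matching the CpG-controlled
    analysis."""
    from .motifs import A3G_CCC, _is_cpg_mutation, window_matches

    motif = A3G_CCC if motif is None else motif
    m = cluster_set.mutations
    types = cluster_set.clusters.set_index("cluster_id")["type"]
    mm = m[m["cluster_id"] >= 0].copy()
    ctype = mm["cluster_id"].map(types)
    frames = []
    for t, strand in (("C", "+"), ("G", "-")):
        grp = mm[(ctype == t).to_numpy()].copy()
        if cpg_filter and len(grp):
            grp = grp[~_is_cpg_mutation(grp["window"], strand)]
        if len(grp):
            grp["_match"] = window_matches(grp["window"], motif, strand)
            frames.append(grp)
    if not frames:
        raise UndefinedStatisticError("no coordinated clustered mutations")
    pooled = pd.concat(frames)[["chrom", "pos0", "_match"]]
    if background <= 0:
        raise ArgumentError("fixed background must be positive")

    def stat(df: pd.DataFrame) -> float:
        if len(df) == 0:
            raise UndefinedStatisticError("empty replicate")
        return df["_match"].mean() / background

    return block_bootstrap(pooled, scheme, stat, n_boot=n_boot, seed=seed)
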