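"""Parsimony calling of lineage-specific substitutions.

The ancestral state of the target/sister common ancestor is taken to be
the sister allele whenever it is confirmed by at least one of the two
outgroups; a substitution is called wherever the target allele differs
from that inferred state.  Columns with missing target or sister alleles,
with both outgroups missing, or overlapping an exclusion mask are removed
first, and the number of surviving columns is the callable length used as
the denominator of the genome-wide mutation probability downstream.

This simple parsimony deliberately still calls sites where the target
matches an outgroup but not the sister (possible homoplasy); with the
low per-branch rates the screen assumes, such sites are rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import array_to_seq, is_base
from .errors import ConsistencyError, FormatError
from .io import Alignment

WINDOW_FLANK = 3  # 7-mer windows accommodate motifs up to 4 bp at any register


@dataclass
class AlignmentColumn:
    """One alignment column on target coordinates.  ``None`` marks a
    missing allele (gap, N, unaligned)."""

    chrom: str
    pos: int
    target: str | None
    sister: str | None
    outgroup1: str | None
    outgroup2: str | None
    masked: bool = False


def infer_ancestral_state(column: AlignmentColumn) -> str | None:
    """Sister allele when confirmed by either outgroup, else missing."""
    s = column.sister
    if s is None:
        return None
    if s == column.outgroup1 or s == column.outgroup2:
        return s
    return None


def masks_to_bool(masks: Iterable[pd.DataFrame], chrom: str, length: int) -> np.ndarray:
    """Union of BED interval sets as a boolean exclusion array."""
    out = np.zeros(length, dtype=bool)
    for df in masks:
        sub = df[df["chrom"] == chrom] if "chrom" in df else df
        for start, end in zip(sub["start"], sub["end"]):
            if start > end:
                raise FormatError(f"malformed interval {start} > {end}")
            out[max(0, int(start)):min(length, int(end))] = True
    return out


def apply_masks(
    aln: Alignment, masks: Sequence[pd.DataFrame] = (),
) -> tuple[np.ndarray, int]:
    """Columns that survive the positional filters.

    Returns a boolean keep-mask over target positions and the callable
    length (its sum).  A column survives when the target and sister alleles
    are concrete bases, at least one outgroup allele is, and no exclusion
    mask covers it.
    """
    t = is_base(aln.species["target"])
    s = is_base(aln.species["sister"])
    o = is_base(aln.species["outgroup1"]) | is_base(aln.species["outgroup2"])
    keep = t & s & o
    if masks:
        keep &= ~masks_to_bool(masks, aln.chrom, aln.length)
    return keep, int(keep.sum())


def call_mutations(
    aln: Alignment,
    masks: Sequence[pd.DataFrame] = (),
    lineage: str = "target",
    context_mode: str = "ancestral",
) -> tuple[pd.DataFrame, int]:
    """Call target-branch substitutions from a four-species alignment.

    Returns ``(mutations, callable_length)``.  The mutation frame carries
    ``chrom, pos0, anc, der, lineage, context, window`` where ``context``
    is the ancestral-strand trinucleotide centred on the site and
    ``window`` a 7-mer used for motif matching.  With the default
    ``context_mode="ancestral"`` flanking bases are read from the target
    sequence with the inferred ancestral allele substituted at *every*
    called site, so contexts describe the pre-mutation haplotype;
    ``context_mode="reference"`` substitutes only at the focal site.
    """
    if context_mode not in ("ancestral", "reference"):
        raise FormatError(f"unknown context_mode {context_mode!r}")
    tgt = aln.species["target"]
    sis = aln.species["sister"]
    o1 = aln.species["outgroup1"]
    o2 = aln.species["outgroup2"]

    keep, callable_length = apply_masks(aln, masks)
    confirmed = is_base(sis) & (((sis == o1) & is_base(o1)) | ((sis == o2) & is_base(o2)))
    called = keep & confirmed & (tgt != sis)
    pos = np.flatnonzero(called)

    corrected = tgt.copy()
    if context_mode == "ancestral":
        corrected[pos] = sis[pos]
    windows = _windows(corrected, pos, tgt, sis, context_mode)

    anc = sis[pos]
    muts = pd.DataFrame({
        "chrom": aln.chrom,
        "pos0": pos.astype(np.int64),
        "anc": [chr(b) for b in anc],
        "der": [chr(b) for b in tgt[pos]],
        "lineage": lineage,
        "window": pd.Series(windows, dtype=str),
    })
    muts["context"] = muts["window"].str[WINDOW_FLANK - 1:WINDOW_FLANK + 2]
    return muts, callable_length


def _windows(corrected, pos, tgt, sis, context_mode) -> list[str]:
    L = corrected.size
    f = WINDOW_FLANK
    padded = np.full(L + 2 * f, ord("N"), dtype=np.uint8)
    padded[f:f + L] = corrected
    if context_mode == "reference":
        # focal substitution only; neighbours keep the reference allele
        out = []
        for p in pos:
            w = padded[p:p + 2 * f + 1].copy()
            w[f] = sis[p]
            out.append(array_to_seq(w))
        return out
    idx = pos[:, None] + np.arange(2 * f + 1)[None, :]
    rows = padded[idx]
    return [r.tobytes().decode("ascii") for r in rows]


def partition_by_lineage(
    muts: pd.DataFrame, allele_tracks: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each mutation to a descendant branch from allele tracks.

    A mutation carried (derived) in every tracked lineage is ``common``;
    carried in exactly one lineage, that lineage's label; carried in a
    strict subset, or with any missing track allele, ``unassigned``.
    Returns a copy of *muts* with the ``lineage`` column replaced.
    """
    lineages = sorted(allele_tracks["lineage"].unique())
    wide = allele_tracks.pivot_table(
        index=["chrom", "pos0"], columns="lineage", values="allele", aggfunc="first")
    out = muts.copy()
    key = pd.MultiIndex.from_frame(muts[["chrom", "pos0"]])
    missing_rows = ~key.isin(wide.index)
    if missing_rows.any():
        p = muts.loc[missing_rows, "pos0"].iloc[0]
        raise ConsistencyError(f"allele tracks lack position {p}")
    sub = wide.loc[key]

    carried = np.zeros((len(muts), len(lineages)), dtype=bool)
    known = np.zeros_like(carried)
    der = muts["der"].to_numpy()
    for j, lin in enumerate(lineages):
        alleles = sub[lin].to_numpy(dtype=object)
        known[:, j] = pd.Series(alleles).isin(list("ACGT")).to_numpy()
        carried[:, j] = alleles == der
    n_carried = carried.sum(axis=1)
    all_known = known.all(axis=1)

    label = np.full(len(muts), "unassigned", dtype=object)
    label[all_known & (n_carried == len(lineages))] = "common"
    one = all_known & (n_carried == 1)
    if one.any():
        which = carried[one].argmax(axis=1)
        label[one] = np.array(lineages, dtype=object)[which]
    out["lineage"] = label
    return out
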