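"""Genomic-region enrichment of the enzyme-induced mutation set.

The A3G-induced set (mutations inside significant C/G-coordinated
clusters carrying at least one CCC mutation) is compared against the
control set of all other mutations.  The per-region fold change is

    (a3g_in / a3g_total) / (control_in / control_total)

with a two-tailed exact test on the 2x2 count table and Bonferroni (or
Benjamini-Hochberg) correction across the region panel.  A mutation falls
in a region when its single-base position lies in the half-open interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError, UndefinedStatisticError


@dataclass
class RegionSet:
    """Sorted, non-overlapping labelled intervals; overlaps are merged on
    construction with length-weighted levels."""

    label: str
    intervals: pd.DataFrame  # chrom, start, end[, level]

    def __post_init__(self):
        df = self.intervals.copy()
        if (df["start"] >= df["end"]).any():
            raise ArgumentError(f"{self.label}: intervals need start < end")
        if "level" not in df:
            df["level"] = np.nan
        self.intervals = _merge(df)

    @property
    def total_length(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean membership per position (vectorised per chromosome)."""
        pos = np.asarray(pos)
        chrom = np.asarray(chrom)
        out = np.zeros(pos.size, dtype=bool)
        for c, sub in self.intervals.groupby("chrom"):
            sel = chrom == c
            if not sel.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            i = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = (i >= 0) & (pos[sel] < ends[np.clip(i, 0, len(ends) - 1)])
            out[np.flatnonzero(sel)[ok]] = True
        return out


def _merge(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom"):
        cur = None
        for _, iv in sub.iterrows():
            if cur is None:
                cur = [chrom, iv.start, iv.end, iv.level * (iv.end - iv.start)]
            elif iv.start <= cur[2]:
                new_end = max(cur[2], iv.end)
                cur[3] += iv.level * (iv.end - iv.start)
                cur[2] = new_end
            else:
                rows.append(cur)
                cur = [chrom, iv.start, iv.end, iv.level * (iv.end - iv.start)]
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "_wl"])
    out["level"] = out["_wl"] / (out["end"] - out["start"])
    out = out.drop(columns="_wl")
    out[["start", "end"]] = out[["start", "end"]].astype(np.int64)
    return out.reset_index(drop=True)


@dataclass
class FoldChangeResult:
    region: str
    a3g_in: int
    a3g_total: int
    control_in: int
    control_total: int
    fold_change: float      # inf flags a zero control fraction
    p: float
    q: float | None = None
    se: float | None = None


def region_fold_change(
    a3g_set: pd.DataFrame,
    control_set: pd.DataFrame,
    regions: RegionSet,
) -> FoldChangeResult:
    """Fold change of in-region fractions, A3G set vs control set."""
    if len(a3g_set) == 0 or len(control_set) == 0:
        raise UndefinedStatisticError("both mutation sets must be nonempty")
    a_in = int(regions.contains(a3g_set["chrom"].to_numpy(),
                                a3g_set["pos0"].to_numpy()).sum())
    c_in = int(regions.contains(control_set["chrom"].to_numpy(),
                                control_set["pos0"].to_numpy()).sum())
    a_tot, c_tot = len(a3g_set), len(control_set)
    c_frac = c_in / c_tot
    fc = float("inf") if c_frac == 0 else (a_in / a_tot) / c_frac
    p = float(stats.fisher_exact(
        [[a_in, a_tot - a_in], [c_in, c_tot - c_in]], alternative="two-sided")[1])
    return FoldChangeResult(regions.label, a_in, a_tot, c_in, c_tot, fc, p)


def region_panel(
    a3g_set: pd.DataFrame,
    control_set: pd.DataFrame,
    region_sets: Sequence[RegionSet],
    method: str = "bonferroni",
) -> list[FoldChangeResult]:
    results = [region_fold_change(a3g_set, control_set, rs) for rs in region_sets]
    if results:
        _, q, _, _ = multipletests([r.p for r in results], method=method)
        for r, qv in zip(results, q):
            r.q = float(qv)
    return results


@dataclass
class DecileReport:
    table: pd.DataFrame     # decile, mean_level, bases, a3g_in, control_in, fold_change
    r: float                # Pearson r over the first nine deciles
    p: float
    top_decile_fold_change: float


def expression_decile_correlation(
    a3g_set: pd.DataFrame,
    control_set: pd.DataFrame,
    expression_regions: RegionSet,
    n_deciles: int = 10,
) -> DecileReport:
    """Fold change per expression decile and its correlation with level.

    Bases of the expression intervals are ranked by interval level and cut
    into ``n_deciles`` equal-base groups (length-weighted deciles).  The
    Pearson correlation of fold change against mean level is taken over
    the first nine deciles; the top decile is reported separately since
    highly transcribed regions are expected to behave differently under
    selection.
    """
    iv = expression_regions.intervals
    if iv["level"].isna().any():
        raise ArgumentError("expression regions need a level column")
    if iv["level"].nunique() < n_deciles:
        raise ArgumentError(
            f"need at least {n_deciles} distinct levels to form deciles")
    iv = iv.sort_values("level", kind="stable").reset_index(drop=True)
    lengths = (iv["end"] - iv["start"]).to_numpy()
    cum = np.cumsum(lengths)
    total = cum[-1]
    # decile of an interval = decile of its base midpoint in the ranking
    mid = cum - lengths / 2
    decile = np.minimum((mid / total * n_deciles).astype(int), n_deciles - 1)

    rows = []
    a_tot, c_tot = len(a3g_set), len(control_set)
    for d in range(n_deciles):
        sub = RegionSet(f"decile{d + 1}", iv[decile == d][["chrom", "start", "end", "level"]])
        a_in = int(sub.contains(a3g_set["chrom"].to_numpy(), a3g_set["pos0"].to_numpy()).sum())
        c_in = int(sub.contains(control_set["chrom"].to_numpy(), control_set["pos0"].to_numpy()).sum())
        w = lengths[decile == d]
        lv = iv.loc[decile == d, "level"].to_numpy()
        fc = (a_in / a_tot) / (c_in / c_tot) if c_in else float("nan")
        rows.append({"decile": d + 1, "mean_level": float(np.average(lv, weights=w)),
                     "bases": int(w.sum()), "a3g_in": a_in, "control_in": c_in,
                     "fold_change": fc})
    table = pd.DataFrame(rows)
    first_nine = table.iloc[:n_deciles - 1]
    fc = first_nine["fold_change"].to_numpy()
    if np.any(~np.isfinite(fc)) or np.ptp(fc) == 0:
        raise UndefinedStatisticError("fold change undefined or constant across deciles")
    r, p = stats.pearsonr(first_nine["mean_level"], fc)
    return DecileReport(table, float(r), float(p),
                        float(table["fold_change"].iloc[-1]))


def branch_comparison(
    region_families: Mapping[str, RegionSet],
    a3g_by_branch: Mapping[str, pd.DataFrame],
    control_by_branch: Mapping[str, pd.DataFrame],
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Differential enzyme-mutation accumulation between two branches.

    For each region family, computes the fold change in each branch and a
    two-tailed exact test comparing in-region A3G vs control counts
    between the branches.  Families with no mutations in either branch
    are skipped.  Returns a frame with per-branch fold changes, nominal p
    and FDR-adjusted q, plus the direction (branch with higher fold
    change).
    """
    (br_a, a3g_a), (br_b, a3g_b) = list(a3g_by_branch.items())
    ctrl_a, ctrl_b = control_by_branch[br_a], control_by_branch[br_b]
    rows = []
    for fam, rs in region_families.items():
        fa = region_fold_change(a3g_a, ctrl_a, rs)
        fb = region_fold_change(a3g_b, ctrl_b, rs)
        if fa.a3g_in + fb.a3g_in == 0:
            continue  # no enzyme-set mutations hit this family in either branch
        table = [[fa.a3g_in, fa.control_in], [fb.a3g_in, fb.control_in]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append({
            "family": fam,
            f"fold_change_{br_a}": fa.fold_change,
            f"fold_change_{br_b}": fb.fold_change,
            "direction": br_a if fa.fold_change >= fb.fold_change else br_b,
            "p": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p"], method=method)
        out["q"] = q
    return out
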