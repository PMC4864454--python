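"""Deaminase motif signals, backgrounds and enrichment statistics.

The motif signal is the fraction of clustered mutations sitting at the
mutated position of a motif, pooling C-coordinated clusters (matched on
the plus strand) with G-coordinated clusters (matched via the motif's
reverse complement).  Enrichment E = signal / background is computed
against four backgrounds:

* ``genomic`` — motif occurrences over C+G occurrences genome-wide;
* ``random_mutations`` — mean motif fraction among clustered mutations of
  randomised mutation sets (each mutation relocated to a random
  matching-base callable position, then re-clustered with identical
  parameters);
* ``random_clusters`` — mean motif fraction at randomly relocated clusters
  that preserve length, internal offsets and mutation types;
* ``local_context`` — motif over ancestral-base occurrences inside the
  10-kb windows centred on cluster midpoints.

One-tailed exact tests compare mutation counts in/out of the motif
against the background counts, Bonferroni-corrected within the motif
panel of one invocation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import (C, G, IUPAC, is_base, iupac_match, pattern_positions,
                   pattern_positions_minus, revcomp)
from .calling import WINDOW_FLANK
from .clusters import ClusterSet, build_cluster_set, filter_by_pvalue
from .errors import ArgumentError, UndefinedStatisticError


@dataclass(frozen=True)
class Motif:
    """IUPAC pattern with the deaminated (mutated) position marked."""

    pattern: str
    mutated_index: int
    label: str

    def __post_init__(self):
        if not 2 <= len(self.pattern) <= 4:
            raise ArgumentError(f"{self.label}: pattern length must be 2-4")
        for sym in self.pattern:
            if sym not in IUPAC:
                raise ArgumentError(f"{self.label}: unsupported symbol {sym!r}")
        if not 0 <= self.mutated_index < len(self.pattern):
            raise ArgumentError(f"{self.label}: mutated_index outside pattern")
        if "C" not in IUPAC[self.pattern[self.mutated_index]]:
            raise ArgumentError(f"{self.label}: mutated position cannot be a C")


# mutated positions follow the deaminase signature literature:
# 3'-most C for CC/CCC/TTC/WRC/TYC, the C of TC, the middle C of TCW
A3G_CC = Motif("CC", 1, "A3G-CC")
A3G_CCC = Motif("CCC", 2, "A3G-CCC")
A3B_TC = Motif("TC", 1, "A3B-TC")
A3B_TCW = Motif("TCW", 1, "A3B-TCW")
A3F_TTC = Motif("TTC", 2, "A3F-TTC")
AID_WRC = Motif("WRC", 2, "AID-WRC")
MOUSE_TYC = Motif("TYC", 2, "mouseA3-TYC")

DEFAULT_PANEL: tuple[Motif, ...] = (A3G_CC, A3G_CCC, A3B_TC, A3B_TCW, A3F_TTC, AID_WRC)


def parse_motif(spec: str) -> Motif:
    """Parse a ``PATTERN:INDEX:LABEL`` command-line motif specification."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ArgumentError(f"motif spec {spec!r} is not PATTERN:INDEX:LABEL")
    pattern, idx, label = parts
    try:
        idx = int(idx)
    except ValueError:
        raise ArgumentError(f"motif spec {spec!r}: index must be an integer") from None
    return Motif(pattern.upper(), idx, label)


@dataclass(frozen=True)
class Counts:
    n_match: int
    n_total: int

    @property
    def ratio(self) -> float:
        if self.n_total == 0:
            raise UndefinedStatisticError("ratio undefined on an empty set")
        return self.n_match / self.n_total

    def __add__(self, other: "Counts") -> "Counts":
        return Counts(self.n_match + other.n_match, self.n_total + other.n_total)


@dataclass
class EnrichmentResult:
    motif: str
    background_mode: str
    n_motif_mutations: int
    n_total_mutations: int
    signal: float
    background: float
    enrichment: float          # inf when background is zero (flag, not error)
    fisher_p: float
    q: float | None = None
    se: float | None = None
    cpg: bool | None = None

    @property
    def infinite(self) -> bool:
        return math.isinf(self.enrichment)


def match_motif(context_window: str, motif: Motif, strand: str = "+") -> bool:
    """Does the motif occur with its mutated base at the centre of an
    odd-length window?  The minus strand tests the reverse complement."""
    if len(context_window) % 2 != 1:
        raise ArgumentError("context window must have odd length")
    center = len(context_window) // 2
    if strand == "+":
        pattern, idx = motif.pattern, motif.mutated_index
    elif strand == "-":
        pattern = revcomp(motif.pattern)
        idx = len(motif.pattern) - 1 - motif.mutated_index
    else:
        raise ArgumentError(f"strand must be '+' or '-', got {strand!r}")
    start = center - idx
    if start < 0 or start + len(pattern) > len(context_window):
        raise ArgumentError("context window shorter than the pattern requires")
    return all(context_window[start + j].upper() in IUPAC[sym]
               for j, sym in enumerate(pattern))


def window_matches(windows: Iterable[str], motif: Motif, strand: str = "+") -> np.ndarray:
    """Vectorised :func:`match_motif` over equal-length windows."""
    windows = list(windows)
    if not windows:
        return np.zeros(0, dtype=bool)
    w = len(windows[0])
    if w % 2 != 1:
        raise ArgumentError("context windows must have odd length")
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(-1, w)
    center = w // 2
    if strand == "-":
        pattern = revcomp(motif.pattern)
        idx = len(motif.pattern) - 1 - motif.mutated_index
    else:
        pattern, idx = motif.pattern, motif.mutated_index
    start = center - idx
    if start < 0 or start + len(pattern) > w:
        raise ArgumentError("context window shorter than the pattern requires")
    out = np.ones(arr.shape[0], dtype=bool)
    for j, sym in enumerate(pattern):
        out &= iupac_match(arr[:, start + j], sym)
    return out


def _is_cpg_mutation(windows: pd.Series, strand: str) -> np.ndarray:
    """Mutated C immediately 5' of G on its own strand."""
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(
        len(windows), -1)
    c = arr.shape[1] // 2
    if strand == "+":
        return arr[:, c + 1] == G
    return arr[:, c - 1] == C


def signal(
    cluster_set: ClusterSet,
    motif: Motif,
    which: str = "clustered",
    cpg_filter: bool = False,
    exclude_cccg: bool = False,
) -> Counts:
    """Pooled motif-mutation counts.

    ``which="clustered"`` uses mutations in C-coordinated (plus strand)
    and G-coordinated (minus strand) clusters; ``which="nonclustered"``
    uses unclustered mutations with ancestral C (plus) or G (minus).
    ``cpg_filter`` drops mutations whose mutated base sits in a CpG on its
    strand; ``exclude_cccg`` drops mutations in a CCCG context.
    """
    m = cluster_set.mutations
    if which == "clustered":
        types = cluster_set.clusters.set_index("cluster_id")["type"]
        mm = m[m["cluster_id"] >= 0]
        ctype = mm["cluster_id"].map(types)
        groups = [(mm[(ctype == "C").to_numpy()], "+"),
                  (mm[(ctype == "G").to_numpy()], "-")]
    elif which == "nonclustered":
        mm = m[m["cluster_id"] < 0]
        groups = [(mm[mm["anc"] == "C"], "+"), (mm[mm["anc"] == "G"], "-")]
    else:
        raise ArgumentError(f"unknown mutation subset {which!r}")

    n_match = n_total = 0
    for grp, strand in groups:
        if len(grp) == 0:
            continue
        keep = np.ones(len(grp), dtype=bool)
        if cpg_filter:
            keep &= ~_is_cpg_mutation(grp["window"], strand)
        if exclude_cccg:
            keep &= ~(window_matches(grp["window"], A3G_CCC, strand)
                      & _is_cpg_mutation(grp["window"], strand))
        grp = grp[keep]
        n_total += len(grp)
        n_match += int(window_matches(grp["window"], motif, strand).sum())
    if n_total == 0:
        raise UndefinedStatisticError("motif signal undefined: no mutations in set")
    return Counts(n_match, n_total)


def _occurrence_masks(genome: np.ndarray, motif: Motif) -> tuple[np.ndarray, np.ndarray]:
    plus = pattern_positions(genome, motif.pattern, motif.mutated_index)
    minus = pattern_positions_minus(genome, motif.pattern, motif.mutated_index)
    return plus, minus


def _cpg_site_masks(genome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = genome.size
    cpg_c = np.zeros(L, bool)
    cpg_c[:-1] = (genome[:-1] == C) & (genome[1:] == G)
    cpg_g = np.zeros(L, bool)
    cpg_g[1:] = cpg_c[:-1]
    return cpg_c, cpg_g


def genomic_background(
    genome: np.ndarray,
    motif: Motif,
    cpg_masked: bool = False,
    exclude_cccg: bool = False,
    region_mask: np.ndarray | None = None,
) -> Counts:
    """Motif occurrences (both strands) over C+G occurrences.

    ``cpg_masked`` removes CpG cytosines/guanines from both counts;
    ``exclude_cccg`` removes CCCG occurrences from the motif count;
    ``region_mask`` restricts counting to a boolean subset of positions.
    """
    plus, minus = _occurrence_masks(genome, motif)
    c_sites = genome == C
    g_sites = genome == G
    if not (c_sites.any() or g_sites.any()):
        raise UndefinedStatisticError("genome contains no C or G")
    if cpg_masked:
        cpg_c, cpg_g = _cpg_site_masks(genome)
        c_sites, g_sites = c_sites & ~cpg_c, g_sites & ~cpg_g
        plus, minus = plus & ~cpg_c, minus & ~cpg_g
    if exclude_cccg:
        cccg_plus = pattern_positions(genome, "CCCG", 2)
        cccg_minus = pattern_positions_minus(genome, "CCCG", 2)
        plus, minus = plus & ~cccg_plus, minus & ~cccg_minus
    if region_mask is not None:
        plus, minus = plus & region_mask, minus & region_mask
        c_sites, g_sites = c_sites & region_mask, g_sites & region_mask
    return Counts(int(plus.sum() + minus.sum()),
                  int(c_sites.sum() + g_sites.sum()))


def local_context_background(
    cluster_set: ClusterSet, genome: np.ndarray, motif: Motif,
    window: int = 10_000,
) -> Counts:
    """Genomic-style counts restricted to the union of ``window``-bp
    regions centred on cluster midpoints, clipped at chromosome ends."""
    cl = cluster_set.coordinated()
    mask = np.zeros(genome.size, dtype=bool)
    half = window // 2
    mid = ((cl["start"] + cl["end"]) // 2).to_numpy()
    for m in mid:
        mask[max(0, m - half):min(genome.size, m + half)] = True
    return genomic_background(genome, motif, region_mask=mask)


def randomized_mutation_sets(
    cluster_set: ClusterSet,
    genome: np.ndarray,
    callable_mask: np.ndarray | None = None,
    n_sets: int = 100,
    seed: int = 0,
    base_matched: bool = True,
):
    """Yield clustered-mutation frames of randomised mutation sets.

    Each replicate relocates every mutation uniformly over callable
    positions carrying the same ancestral base (``base_matched=False``
    relaxes this to any callable base position), then re-runs clustering
    with the parameters and p-value threshold of the observed set.
    """
    rng = np.random.default_rng(seed)
    if callable_mask is None:
        callable_mask = is_base(genome)
    m = cluster_set.mutations
    chrom = m["chrom"].iloc[0] if len(m) else "chr?"
    counts = m["anc"].value_counts().to_dict()
    pools = {}
    for base in counts:
        pool = (np.flatnonzero(callable_mask & (genome == ord(base)))
                if base_matched else np.flatnonzero(callable_mask))
        if pool.size == 0:
            raise ArgumentError(f"no callable positions with base {base} to relocate to")
        pools[base] = pool
    f = WINDOW_FLANK
    padded = np.full(genome.size + 2 * f, ord("N"), dtype=np.uint8)
    padded[f:f + genome.size] = genome
    for _ in range(n_sets):
        frames = []
        for base, n in counts.items():
            pos = rng.choice(pools[base], size=n, replace=True)
            frames.append(pd.DataFrame({"pos0": pos, "anc": base}))
        rand = pd.concat(frames, ignore_index=True)
        rand = rand.drop_duplicates("pos0").sort_values("pos0").reset_index(drop=True)
        rand["chrom"] = chrom
        idx = rand["pos0"].to_numpy()[:, None] + np.arange(2 * f + 1)[None, :]
        rand["window"] = [r.tobytes().decode() for r in padded[idx]]
        cs = build_cluster_set(
            rand, cluster_set.callable_length, cluster_set.max_spacing,
            cluster_set.min_spacing_complex, p_threshold=cluster_set.p_threshold)
        yield cs


def random_mutation_background(
    cluster_set: ClusterSet,
    genome: np.ndarray,
    motif: Motif,
    callable_mask: np.ndarray | None = None,
    n_sets: int = 100,
    seed: int = 0,
    base_matched: bool = True,
) -> Counts:
    """Pooled motif counts among clustered mutations of randomised sets."""
    total = Counts(0, 0)
    for cs in randomized_mutation_sets(cluster_set, genome, callable_mask,
                                       n_sets, seed, base_matched):
        try:
            total = total + signal(cs, motif)
        except UndefinedStatisticError:
            continue  # replicate produced no coordinated clusters
    if total.n_total == 0:
        raise UndefinedStatisticError(
            "no randomised replicate produced coordinated clusters")
    return total


def random_cluster_background(
    cluster_set: ClusterSet,
    genome: np.ndarray,
    motif: Motif,
    n_sets: int = 100,
    seed: int = 0,
) -> Counts:
    """Pooled motif counts at relocated clusters.

    Each replicate moves every coordinated cluster to a uniform random
    locus on the same chromosome, preserving span, internal offsets and
    mutation types; counts pool relocated positions that carry the
    cluster's ancestral base, matching the signal's per-base definition.
    """
    rng = np.random.default_rng(seed)
    cl = cluster_set.coordinated()
    if len(cl) == 0:
        raise UndefinedStatisticError("no coordinated clusters to relocate")
    m = cluster_set.mutations
    plus_occ, minus_occ = _occurrence_masks(genome, motif)
    L = genome.size
    offsets, types, spans = [], [], []
    for cid, t, start, span in zip(cl["cluster_id"], cl["type"], cl["start"], cl["span"]):
        mem = m.loc[m["cluster_id"] == cid, "pos0"].to_numpy() - start
        if span > L:
            raise ArgumentError("cluster longer than the chromosome")
        offsets.append(mem)
        types.append(t)
        spans.append(int(span))
    n_match = n_total = 0
    for _ in range(n_sets):
        for off, t, span in zip(offsets, types, spans):
            new_start = rng.integers(0, L - span + 1)
            pos = off + new_start
            base, occ = (C, plus_occ) if t == "C" else (G, minus_occ)
            on_base = genome[pos] == base
            n_total += int(on_base.sum())
            n_match += int(occ[pos[on_base]].sum())
    if n_total == 0:
        raise UndefinedStatisticError("relocated clusters never landed on the base")
    return Counts(n_match, n_total)


def enrichment(
    sig: Counts, bg: Counts, motif_label: str = "", background_mode: str = "genomic",
    alternative: str = "greater",
) -> EnrichmentResult:
    """E = signal/background plus a one-tailed exact test on the 2x2
    table (mutations in/out of motif vs background positions in/out)."""
    s = sig.ratio
    b = bg.n_match / bg.n_total if bg.n_total else float("nan")
    e = float("inf") if b == 0 else s / b
    table = [[sig.n_match, sig.n_total - sig.n_match],
             [bg.n_match, bg.n_total - bg.n_match]]
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    return EnrichmentResult(motif_label, background_mode, sig.n_match, sig.n_total,
                            s, b, e, p)


def _bonferroni(results: Sequence[EnrichmentResult]) -> None:
    n = len(results)
    for r in results:
        r.q = min(1.0, r.fisher_p * n)


def motif_panel_enrichment(
    cluster_set: ClusterSet,
    genome: np.ndarray,
    motifs: Sequence[Motif] = DEFAULT_PANEL,
    background: str = "genomic",
    callable_mask: np.ndarray | None = None,
    n_sets: int = 100,
    seed: int = 0,
    p_threshold: float | None = None,
) -> list[EnrichmentResult]:
    """Enrichment of a motif panel under one background mode, with
    Bonferroni correction across the panel."""
    cs = cluster_set
    if p_threshold is not None:
        cs = filter_by_pvalue(cs, p_threshold)
    rand_sets = None
    if background == "random_mutations":
        rand_sets = list(randomized_mutation_sets(
            cs, genome, callable_mask, n_sets, seed))
    results = []
    for motif in motifs:
        sig = signal(cs, motif)
        if background == "genomic":
            bg = genomic_background(genome, motif)
        elif background == "local_context":
            bg = local_context_background(cs, genome, motif)
        elif background == "random_mutations":
            bg = Counts(0, 0)
            for rs in rand_sets:
                try:
                    bg = bg + signal(rs, motif)
                except UndefinedStatisticError:
                    continue
            if bg.n_total == 0:
                raise UndefinedStatisticError(
                    "no randomised replicate produced coordinated clusters")
        elif background == "random_clusters":
            bg = random_cluster_background(cs, genome, motif, n_sets, seed)
        else:
            raise ArgumentError(f"unknown background mode {background!r}")
        results.append(enrichment(sig, bg, motif.label, background))
    _bonferroni(results)
    return results


def trinucleotide_motifs() -> list[Motif]:
    """The 48 triplet motifs: every trinucleotide with a C at each of the
    three positions (16 patterns per mutated position)."""
    out = []
    bases = "ACGT"
    for idx in range(3):
        for b1 in bases:
            for b2 in bases:
                pat = list("...")
                pat[idx] = "C"
                rest = [i for i in range(3) if i != idx]
                pat[rest[0]], pat[rest[1]] = b1, b2
                pat = "".join(pat)
                out.append(Motif(pat, idx, f"{pat}@{idx}"))
    return out


def trinucleotide_scan(
    cluster_set: ClusterSet, genome: np.ndarray,
) -> pd.DataFrame:
    """Enrichment of all 48 mutated-cytosine triplets against the genomic
    background, Bonferroni-corrected across the 48; CpG-containing
    triplets are flagged."""
    results = []
    for motif in trinucleotide_motifs():
        sig = signal(cluster_set, motif)
        bg = genomic_background(genome, motif)
        r = enrichment(sig, bg, motif.label)
        r.cpg = "CG" in motif.pattern
        results.append(r)
    _bonferroni(results)
    return pd.DataFrame([{
        "pattern": r.motif.split("@")[0],
        "mutated_index": int(r.motif.split("@")[1]),
        "cpg": r.cpg,
        "n_motif_mutations": r.n_motif_mutations,
        "n_total_mutations": r.n_total_mutations,
        "signal": r.signal,
        "background": r.background,
        "enrichment": r.enrichment,
        "fisher_p": r.fisher_p,
        "q": r.q,
    } for r in results])


def cpg_controls(cluster_set: ClusterSet, genome: np.ndarray) -> dict:
    """Controls separating enzymatic CCC enrichment from CpG deamination.

    Returns ``cpg_masked`` (CpG-filtered mutations vs CpG-masked genome),
    ``cccg_excluded`` (CCCG contexts dropped from signal and background)
    and ``additivity`` (per-stratum mutation rates at CCC-only, CpG-only,
    CCC&CpG and neither sites; a CCCG mutation belongs to both the CCC and
    CpG strata, so it appears in the intersection stratum).
    """
    masked = enrichment(
        signal(cluster_set, A3G_CCC, cpg_filter=True),
        genomic_background(genome, A3G_CCC, cpg_masked=True),
        A3G_CCC.label, "genomic-cpg-masked")
    no_cccg = enrichment(
        signal(cluster_set, A3G_CCC, exclude_cccg=True),
        genomic_background(genome, A3G_CCC, exclude_cccg=True),
        A3G_CCC.label, "genomic-cccg-excluded")

    plus_ccc, minus_ccc = _occurrence_masks(genome, A3G_CCC)
    cpg_c, cpg_g = _cpg_site_masks(genome)
    site_masks = {"site_is_ccc": plus_ccc | minus_ccc,
                  "site_is_cpg": (cpg_c & (genome == C)) | (cpg_g & (genome == G))}
    cg_sites = (genome == C) | (genome == G)

    m = cluster_set.mutations
    types = cluster_set.clusters.set_index("cluster_id")["type"]
    mm = m[m["cluster_id"] >= 0]
    ctype = mm["cluster_id"].map(types)
    pos_list, ccc_mut, cpg_mut = [], [], []
    for t, strand in (("C", "+"), ("G", "-")):
        grp = mm[(ctype == t).to_numpy()]
        if len(grp) == 0:
            continue
        pos_list.append(grp["pos0"].to_numpy())
        ccc_mut.append(window_matches(grp["window"], A3G_CCC, strand))
        cpg_mut.append(_is_cpg_mutation(grp["window"], strand))
    if pos_list:
        is_ccc = np.concatenate(ccc_mut)
        is_cpg = np.concatenate(cpg_mut)
    else:
        is_ccc = is_cpg = np.zeros(0, dtype=bool)

    rows = []
    for name, mut_sel, site_sel in [
        ("ccc_only", is_ccc & ~is_cpg, site_masks["site_is_ccc"] & ~site_masks["site_is_cpg"]),
        ("cpg_only", ~is_ccc & is_cpg, ~site_masks["site_is_ccc"] & site_masks["site_is_cpg"]),
        ("ccc_and_cpg", is_ccc & is_cpg, site_masks["site_is_ccc"] & site_masks["site_is_cpg"]),
        ("neither", ~is_ccc & ~is_cpg, cg_sites & ~site_masks["site_is_ccc"] & ~site_masks["site_is_cpg"]),
    ]:
        n_sites = int((site_sel & cg_sites).sum())
        n_mut = int(mut_sel.sum())
        rows.append({"stratum": name, "n_sites": n_sites, "n_mutations": n_mut,
                     "rate": n_mut / n_sites if n_sites else float("nan")})
    additivity = pd.DataFrame(rows).set_index("stratum")
    rate = additivity["rate"]
    additive_prediction = rate["ccc_only"] + rate["cpg_only"] - rate["neither"]
    return {"cpg_masked": masked, "cccg_excluded": no_cccg,
            "additivity": additivity.reset_index(),
            "additive_prediction": float(additive_prediction)}


@dataclass
class ConfidenceCorrelation:
    table: pd.DataFrame
    r: float | None           # None flags zero variance in E
    p: float | None


def enrichment_vs_confidence(
    cluster_set: ClusterSet,
    genome: np.ndarray,
    thresholds: Sequence[float],
    motif: Motif = A3G_CCC,
) -> ConfidenceCorrelation:
    """E at each cluster p-value threshold and the Pearson correlation of
    E against -log10(threshold)."""
    if len(thresholds) < 3:
        raise ArgumentError("need at least 3 thresholds for a correlation")
    bg = genomic_background(genome, motif)
    rows = []
    for t in sorted(thresholds, reverse=True):
        cs = filter_by_pvalue(cluster_set, t)
        sig = signal(cs, motif)
        r = enrichment(sig, bg, motif.label)
        rows.append({"threshold": t, "neg_log10_threshold": -math.log10(t),
                     "n_clusters": len(cs.coordinated()),
                     "n_mutations": sig.n_total, "enrichment": r.enrichment})
    table = pd.DataFrame(rows)
    e = table["enrichment"].to_numpy()
    if np.ptp(e) == 0 or np.any(~np.isfinite(e)):
        return ConfidenceCorrelation(table, None, None)
    r, p = stats.pearsonr(table["neg_log10_threshold"], e)
    return ConfidenceCorrelation(table, float(r), float(p))


def subset_enrichment(
    cluster_set: ClusterSet,
    genome: np.ndarray,
    regions: pd.DataFrame | None = None,
    motif: Motif = A3G_CCC,
    which: str = "clustered",
) -> EnrichmentResult:
    """E restricted to mutations inside *regions* (chrom/start/end frame);
    ``regions=None`` uses everything.  ``which="nonclustered"`` supports
    the clustered-vs-single-mutation contrast."""
    cs = cluster_set
    if regions is not None:
        from .regions import RegionSet
        rs = regions if isinstance(regions, RegionSet) else RegionSet("subset", regions)
        m = cs.mutations
        inside = rs.contains(m["chrom"].to_numpy(), m["pos0"].to_numpy())
        sub = m[inside]
        cs = ClusterSet(sub, cs.clusters, cs.callable_length, cs.pi,
                        cs.max_spacing, cs.min_spacing_complex, cs.p_threshold)
    sig = signal(cs, motif, which=which)
    bg = genomic_background(genome, motif)
    return enrichment(sig, bg, motif.label)
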