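"""Synthetic four-taxon alignments with planted deaminase cluster events.

The generator emulates the data a comparative screen for APOBEC3G (A3G)
germline mutagenesis operates on: a short ancestral chromosome with
controllable GC and CpG composition, independent background substitutions
on each branch of the ``((target, sister), outgroup1, outgroup2)`` tree,
clustered multi-mutation A3G events planted at CC/CCC motifs on the target
branch, per-lineage allele tracks for three descendant lineages, and BED
annotation tracks with known structure.  A ground-truth table records every
target-branch change so each downstream stage can be validated exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import A, C, G, T, array_to_seq, is_base
from .errors import ArgumentError, ConfigError, InsufficientMotifsError

BRANCHES = ("target", "sister", "outgroup1", "outgroup2", "internal")
#: descendant lineages of the target branch (generic labels for the
#: modern/archaic three-way split scenario)
DESCENDANT_LINEAGES = ("modern", "neandertal", "denisovan")

_DEFAULT_BRANCH_RATES = {
    "target": 1e-3, "sister": 1e-3, "internal": 1e-3,
    "outgroup1": 5e-3, "outgroup2": 1e-2,
}
# truncated geometric(1/2) on 2..5: a modelling choice for the unknown
# in-vivo distribution of mutations per deamination event
_DEFAULT_EVENT_SIZES = {2: 8 / 15, 3: 4 / 15, 4: 2 / 15, 5: 1 / 15}
_DEFAULT_LINEAGES = {"common": 0.4, "modern": 0.2, "neandertal": 0.2, "denisovan": 0.2}
_DEFAULT_ANNOTATIONS = (("transcribed", 40, 20_000), ("repeat", 60, 1_000))

#: fraction of CpG-process mutations that are transitions (C->T / G->A)
CPG_TRANSITION_FRACTION = 0.9


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults correspond to the baseline scenario used throughout the test
    suite: a 2 Mb chromosome at human-like 41% GC, background substitution
    probability 1e-3/bp on the target branch, and ~300 planted A3G events
    (rate 1.5e-4/bp) of 2-5 mutations each placed at the 3' C of CCC
    contexts with probability ``motif_fidelity`` (otherwise at a plain CC).
    """

    genome_length: int = 2_000_000
    gc_fraction: float = 0.41
    cpg_enrichment: float = 1.0
    branch_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BRANCH_RATES))
    a3g_event_rate: float = 1.5e-4
    a3g_event_size: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_EVENT_SIZES))
    a3g_span: int = 50
    a3g_min_gap: int = 11          # > 10 so planted events survive complex exclusion
    a3g_c_to_t_fraction: float = 0.7
    motif_fidelity: float = 0.8
    reverse_strand_fraction: float = 0.5
    cpg_hypermutation_multiplier: float = 1.0
    a3g_placement: str = "uniform"  # or "by_level:<annotation label>"
    lineage_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LINEAGES))
    annotation_spec: Sequence[tuple[str, int, int]] = _DEFAULT_ANNOTATIONS
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ConfigError("genome_length must be >= 1000")
        for name in ("gc_fraction", "a3g_c_to_t_fraction", "motif_fidelity",
                     "reverse_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.cpg_enrichment < 0:
            raise ConfigError("cpg_enrichment must be >= 0")
        for br, rate in self.branch_rates.items():
            if br not in BRANCHES:
                raise ConfigError(f"branch_rates: unknown branch {br!r}")
            if not 0.0 <= rate <= 0.1:
                raise ConfigError(
                    f"branch_rates[{br!r}] must lie in [0, 0.1] "
                    "(higher rates violate the low-homoplasy assumption)")
        if self.a3g_event_rate < 0:
            raise ConfigError("a3g_event_rate must be >= 0")
        sizes = set(self.a3g_event_size)
        if not sizes or not sizes <= set(range(2, 11)):
            raise ConfigError("a3g_event_size support must be a subset of {2,...,10}")
        if any(w < 0 for w in self.a3g_event_size.values()):
            raise ConfigError("a3g_event_size weights must be >= 0")
        if not 1 <= self.a3g_min_gap <= self.a3g_span:
            raise ConfigError("a3g_min_gap must lie in [1, a3g_span]")
        if self.cpg_hypermutation_multiplier < 0:
            raise ConfigError("cpg_hypermutation_multiplier must be >= 0")
        total = sum(self.lineage_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("lineage_fractions must sum to 1")
        if self.a3g_placement != "uniform" and not self.a3g_placement.startswith("by_level:"):
            raise ConfigError("a3g_placement must be 'uniform' or 'by_level:<label>'")
        for label, count, length in self.annotation_spec:
            if count < 1 or length < 1:
                raise ConfigError(f"annotation_spec[{label!r}] needs count, length >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["branch_rates"] = dict(d["branch_rates"])
        d["a3g_event_size"] = {int(k): float(v) for k, v in d["a3g_event_size"].items()}
        d["annotation_spec"] = [list(t) for t in d["annotation_spec"]]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "a3g_event_size" in d:
            d["a3g_event_size"] = {int(k): float(v) for k, v in d["a3g_event_size"].items()}
        if "annotation_spec" in d:
            d["annotation_spec"] = [tuple(t) for t in d["annotation_spec"]]
        return cls(**d)


def generate_ancestral_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[str, pd.DataFrame]]:
    """Sample the ancestral chromosome and annotation tracks.

    Bases are drawn i.i.d. with P(C)=P(G)=gc/2.  CpG enrichment != 1 is then
    imposed by swapping GC dinucleotides to CG (enrichment) or CG to GC
    (depletion), which rescales the CG dinucleotide count while leaving the
    mononucleotide composition untouched.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L, gc = config.genome_length, config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = np.array([A, C, G, T], dtype=np.uint8)[
        rng.choice(4, size=L, p=probs)]

    m = config.cpg_enrichment
    if m != 1.0 and gc > 0:
        _rescale_cpg(arr, m, rng)

    annotations = _make_annotations(config, rng)
    return arr, annotations


def _dinuc_starts(arr: np.ndarray, first: int, second: int) -> np.ndarray:
    return np.flatnonzero((arr[:-1] == first) & (arr[1:] == second))


def _rescale_cpg(arr: np.ndarray, multiplier: float, rng: np.random.Generator) -> None:
    """Swap dinucleotides in place so the CG count becomes ~multiplier x
    its current value; composition is exactly preserved."""
    target = int(round(multiplier * _dinuc_starts(arr, C, G).size))
    tol = max(1, target // 200)
    # each transposition moves one base between two distant loci, so the
    # composition is exactly preserved; flank conditions make the CG count
    # change by exactly +/-1 per transposition, up to rare collisions the
    # recount loop absorbs
    for _ in range(50):
        cur = _dinuc_starts(arr, C, G).size
        raise_count = multiplier >= 1.0
        need = (target - cur) if raise_count else (cur - target)
        if need <= tol:
            return
        inner = arr[1:-1]
        if raise_count:
            # C followed by A/T: receives a G; donor G with prev != C
            sites = 1 + np.flatnonzero((inner == C) & ((arr[2:] == A) | (arr[2:] == T)))
            donors = 1 + np.flatnonzero((inner == G) & (arr[:-2] != C))
        else:
            # CG pairs lose their G to a distant A/T locus with prev != C
            sites = 1 + np.flatnonzero((inner == C) & (arr[2:] == G))
            donors = 1 + np.flatnonzero(((inner == A) | (inner == T)) & (arr[:-2] != C))
        sites = _thin_adjacent(sites, rng)
        if sites.size == 0 or donors.size == 0:
            raise InsufficientMotifsError(
                f"cannot reach CpG count {target}: transposition pools empty")
        k = min(need, sites.size, donors.size)
        s = rng.choice(sites, size=k, replace=False)
        d = rng.choice(donors, size=k, replace=False)
        ok = ~np.isin(d, np.concatenate([s, s + 1, s + 2]))
        s, d = s[ok], d[ok]
        arr[s + 1], arr[d] = arr[d], arr[s + 1].copy()
    raise InsufficientMotifsError(f"CpG rescaling did not converge to {target}")


def _thin_adjacent(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Drop positions closer than 2 bp apart so dinucleotide swaps cannot
    interact."""
    if pos.size == 0:
        return pos
    keep = np.ones(pos.size, dtype=bool)
    last = pos[0]
    for i in range(1, pos.size):
        if pos[i] - last < 2:
            keep[i] = False
        else:
            last = pos[i]
    return pos[keep]


def _make_annotations(
    config: SimulationConfig, rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Place `count` non-overlapping intervals of `length` bp per track by
    sampling one interval uniformly inside each of `count` equal slots.
    Interval levels are a random permutation of 1..count (used as
    expression levels by tests and the level-weighted planting mode)."""
    L = config.genome_length
    out: dict[str, pd.DataFrame] = {}
    for label, count, length in config.annotation_spec:
        slot = L // count
        if length > slot:
            raise ConfigError(
                f"annotation_spec[{label!r}]: {count} intervals of {length} bp "
                f"do not fit in {L} bp")
        starts = np.arange(count) * slot + rng.integers(0, slot - length + 1, size=count)
        levels = rng.permutation(count) + 1
        out[label] = pd.DataFrame({
            "chrom": config.chrom,
            "start": starts.astype(np.int64),
            "end": (starts + length).astype(np.int64),
            "level": levels.astype(float),
        })
    return out


def simulate_branch_mutations(
    sequence: np.ndarray,
    rate: float,
    cpg_hypermutation_multiplier: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw independent per-site substitutions for one branch.

    CpG cytosines (C of CG, and the paired G) mutate at ``multiplier x
    rate`` and are biased toward transitions, emulating spontaneous
    deamination of methylated CpG.  Returns a frame with columns
    ``pos, anc, der, is_cpg`` sorted by position; no site is mutated twice.
    """
    if not 0.0 <= rate <= 0.1:
        raise ArgumentError(f"branch rate must lie in [0, 0.1], got {rate}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    L = sequence.size
    cpg_c = np.zeros(L, dtype=bool)
    cpg_g = np.zeros(L, dtype=bool)
    cpg_c[:-1] = (sequence[:-1] == C) & (sequence[1:] == G)
    cpg_g[1:] = cpg_c[:-1]
    p = np.full(L, rate)
    mult = cpg_hypermutation_multiplier
    p[cpg_c | cpg_g] = min(rate * mult, 0.75)
    hit = np.flatnonzero((rng.random(L) < p) & is_base(sequence))
    anc = sequence[hit]

    # uniform among the three alternatives, then override the CpG bias
    alt = np.array([[C, G, T], [A, G, T], [A, C, T], [A, C, G]], dtype=np.uint8)
    base_idx = np.searchsorted(np.array([A, C, G, T], dtype=np.uint8), anc)
    der = alt[base_idx, rng.integers(0, 3, size=hit.size)]
    at_cpg = cpg_c[hit] | cpg_g[hit]
    ts = at_cpg & (rng.random(hit.size) < CPG_TRANSITION_FRACTION)
    der[ts & (anc == C)] = T
    der[ts & (anc == G)] = A
    # the non-transition remainder at CpG: keep the uniform draw unless it
    # happens to be the transition (redraw it as a transversion)
    rem = at_cpg & ~ts
    fix_c = rem & (anc == C) & (der == T)
    der[fix_c] = np.where(rng.random(int(fix_c.sum())) < 0.5, A, G).astype(np.uint8)
    fix_g = rem & (anc == G) & (der == A)
    der[fix_g] = np.where(rng.random(int(fix_g.sum())) < 0.5, C, T).astype(np.uint8)

    return pd.DataFrame({
        "pos": hit.astype(np.int64),
        "anc": anc,
        "der": der,
        "is_cpg": at_cpg,
    })


def apply_mutations(sequence: np.ndarray, muts: pd.DataFrame) -> np.ndarray:
    out = sequence.copy()
    out[muts["pos"].to_numpy()] = muts["der"].to_numpy()
    return out


class _MotifPools:
    """Sorted eligible plant sites per (strand, motif class), with a blocked
    zone around already-used positions.  Anchors are drawn by rejection
    sampling (optionally weighted), so cost stays logarithmic in pool size
    even with thousands of events."""

    def __init__(self, node: np.ndarray, available: np.ndarray, block: int,
                 weights: np.ndarray | None = None):
        L = node.size
        ok = available & is_base(node)
        cc = np.zeros(L, bool)
        cc[1:] = (node[1:] == C) & (node[:-1] == C)
        ccc = np.zeros(L, bool)
        ccc[2:] = cc[2:] & (node[:-2] == C)
        gg = np.zeros(L, bool)
        gg[:-1] = (node[:-1] == G) & (node[1:] == G)
        ggg = np.zeros(L, bool)
        ggg[:-2] = gg[:-2] & (node[2:] == G)
        self.pools = {
            ("+", "ccc"): np.flatnonzero(ccc & ok),
            ("+", "cc"): np.flatnonzero(cc & ~ccc & ok),
            ("-", "ccc"): np.flatnonzero(ggg & ok),
            ("-", "cc"): np.flatnonzero(gg & ~ggg & ok),
        }
        self.blocked = np.zeros(L, bool)
        self.block = block
        self.L = L
        self.weights = weights
        self.cumw = {}
        for key, pool in self.pools.items():
            self.cumw[key] = (np.cumsum(weights[pool])
                              if weights is not None else None)

    def mark_used(self, pos: int) -> None:
        lo = max(0, pos - self.block)
        self.blocked[lo:pos + self.block + 1] = True

    def in_window(self, key, lo: int, hi: int) -> np.ndarray:
        pool = self.pools[key]
        i, j = np.searchsorted(pool, [lo, hi + 1])
        cand = pool[i:j]
        return cand[~self.blocked[cand]]

    def sample_anchor(self, key, rng) -> int | None:
        pool = self.pools[key]
        if pool.size == 0:
            return None
        cw = self.cumw[key]
        for _ in range(200):
            if cw is None:
                p = int(pool[rng.integers(pool.size)])
            else:
                total = cw[-1]
                if total <= 0:
                    return None
                p = int(pool[np.searchsorted(cw, rng.random() * total)])
            if not self.blocked[p]:
                return p
        return None


def plant_a3g_events(
    node_sequence: np.ndarray,
    target_sequence: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    position_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Plant multi-mutation deamination events on the target branch.

    Each event picks a strand (reverse with probability
    ``reverse_strand_fraction``), a size from ``a3g_event_size`` and a chain
    of same-strand cytosines (guanines on the reverse strand read as C on
    their own strand) spaced ``a3g_min_gap..a3g_span`` bp apart.  Each
    mutation sits at the 3' C of a CCC context with probability
    ``motif_fidelity``, otherwise at a CC that is not CCC.  Derived alleles
    are C->T with probability ``a3g_c_to_t_fraction``, the remainder split
    C->G / C->A (complemented on the reverse strand).

    Returns the mutated target sequence and an event table
    ``(event_id, pos, anc, der, strand, motif_class)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    L = node_sequence.size
    n_events = rng.poisson(config.a3g_event_rate * L)
    available = target_sequence == node_sequence
    # block zone = the complex-mutation spacing so separate events cannot
    # merge into a complex pair
    pools = _MotifPools(node_sequence, available,
                        block=max(10, config.a3g_min_gap - 1),
                        weights=position_weights)

    sizes = np.array(sorted(config.a3g_event_size))
    size_w = np.array([config.a3g_event_size[s] for s in sizes], dtype=float)
    size_w = size_w / size_w.sum()

    if n_events and min(pools.pools[("+", "cc")].size + pools.pools[("+", "ccc")].size,
                        1) == 0:
        raise InsufficientMotifsError("genome contains no CC motifs to plant events")

    rows: list[tuple] = []
    out = target_sequence.copy()
    planted = 0
    fid = config.motif_fidelity
    for event_id in range(n_events):
        size = int(rng.choice(sizes, p=size_w))
        # commit the motif class of every mutation slot before searching
        # for positions: re-anchoring on placement failure then cannot
        # bias realised motif fractions away from motif_fidelity
        classes = ["ccc" if rng.random() < fid else "cc" for _ in range(size)]
        positions = None
        strand = "+"
        for _attempt in range(1000):
            strand = "-" if rng.random() < config.reverse_strand_fraction else "+"
            positions = _build_chain(pools, strand, classes, config, rng)
            if positions is not None:
                break
        if positions is None:
            # rare class sequences (e.g. long all-CCC chains) defeat
            # rejection sampling; the exact search settles whether any
            # placement exists at all
            for strand in ("-", "+") if rng.random() < 0.5 else ("+", "-"):
                positions = _exact_chain(pools, strand, classes, config, rng)
                if positions is not None:
                    break
        if positions is None:
            raise InsufficientMotifsError(
                f"could not place event {event_id} of size {size}; "
                f"achieved {planted} of {n_events} requested events")
        for pos, mclass in zip(positions, classes):
            anc = node_sequence[pos]
            der = _a3g_derived(anc, strand, config.a3g_c_to_t_fraction, rng)
            out[pos] = der
            pools.mark_used(pos)
            rows.append((event_id, pos, anc, der, strand, mclass))
        planted += 1

    events = pd.DataFrame(
        rows, columns=["event_id", "pos", "anc", "der", "strand", "motif_class"])
    if len(events):
        events = events.sort_values("pos", kind="stable").reset_index(drop=True)
    return out, events


def _exact_chain(pools, strand, classes, config, rng):
    """Deterministic viability search: finds a chain honouring the given
    class sequence whenever one exists.  A backward sweep keeps, per slot,
    the pool positions from which the remainder of the chain can be
    completed; the forward pass then samples uniformly (anchor optionally
    weighted) among viable candidates only."""
    lo_gap, hi_gap = config.a3g_min_gap, config.a3g_span
    viable: list[np.ndarray] = [None] * len(classes)
    nxt = None
    for k in range(len(classes) - 1, -1, -1):
        pool = pools.pools[(strand, classes[k])]
        cur = pool[~pools.blocked[pool]]
        if nxt is not None and cur.size:
            lo = np.searchsorted(nxt, cur + lo_gap)
            hi = np.searchsorted(nxt, cur + hi_gap + 1)
            cur = cur[hi > lo]
        if cur.size == 0:
            return None
        viable[k] = cur
        nxt = cur
    anchors = viable[0]
    if pools.weights is not None:
        w = pools.weights[anchors]
        total = w.sum()
        if total <= 0:
            # weighted mass exhausted; fall back to uniform viable anchors
            cur = int(anchors[rng.integers(anchors.size)])
        else:
            cur = int(anchors[np.searchsorted(np.cumsum(w), rng.random() * total)])
    else:
        cur = int(anchors[rng.integers(anchors.size)])
    positions = [cur]
    for k in range(1, len(classes)):
        cand = viable[k]
        i, j = np.searchsorted(cand, [cur + lo_gap, cur + hi_gap + 1])
        cur = int(cand[i + rng.integers(j - i)])
        positions.append(cur)
    return positions


def _build_chain(pools, strand, classes, config, rng):
    cur = pools.sample_anchor((strand, classes[0]), rng)
    if cur is None:
        return None
    positions = [cur]
    for mclass in classes[1:]:
        lo, hi = cur + config.a3g_min_gap, cur + config.a3g_span
        cand = pools.in_window((strand, mclass), lo, hi)
        if cand.size == 0:
            return None
        cur = int(cand[rng.integers(cand.size)])
        positions.append(cur)
    return positions


def _a3g_derived(anc: int, strand: str, c_to_t: float, rng) -> int:
    if strand == "+":
        assert anc == C
        if rng.random() < c_to_t:
            return T
        return G if rng.random() < 0.5 else A
    assert anc == G
    if rng.random() < c_to_t:
        return A
    return C if rng.random() < 0.5 else T


@dataclass
class Simulation:
    """All artefacts of one synthetic run."""

    config: SimulationConfig
    ancestor: np.ndarray
    node: np.ndarray                      # target/sister common ancestor
    sequences: dict[str, np.ndarray]      # target, sister, outgroup1, outgroup2
    annotations: dict[str, pd.DataFrame]
    truth: pd.DataFrame                   # chrom,pos0,lineage,anc,der,event_id,event_class
    allele_tracks: pd.DataFrame           # chrom,pos0,lineage,allele

    @property
    def chrom(self) -> str:
        return self.config.chrom

    def sequence_str(self, name: str) -> str:
        return array_to_seq(self.sequences[name])


def simulate(config: SimulationConfig) -> Simulation:
    """Run the full generator: ancestral genome, branch substitutions,
    planted events, lineage assignment."""
    rng = np.random.default_rng(config.seed)
    ancestor, annotations = generate_ancestral_genome(config, rng)
    rates = {**_DEFAULT_BRANCH_RATES, **config.branch_rates}
    mult = config.cpg_hypermutation_multiplier

    internal_muts = simulate_branch_mutations(ancestor, rates["internal"], mult, rng)
    node = apply_mutations(ancestor, internal_muts)
    target_bg = simulate_branch_mutations(node, rates["target"], mult, rng)
    target0 = apply_mutations(node, target_bg)
    sister = apply_mutations(node, simulate_branch_mutations(node, rates["sister"], mult, rng))
    out1 = apply_mutations(ancestor, simulate_branch_mutations(ancestor, rates["outgroup1"], mult, rng))
    out2 = apply_mutations(ancestor, simulate_branch_mutations(ancestor, rates["outgroup2"], mult, rng))

    weights = None
    if config.a3g_placement.startswith("by_level:"):
        label = config.a3g_placement.split(":", 1)[1]
        if label not in annotations:
            raise ConfigError(f"a3g_placement references unknown annotation {label!r}")
        weights = np.zeros(config.genome_length)
        for _, iv in annotations[label].iterrows():
            weights[int(iv.start):int(iv.end)] = iv.level

    target, events = plant_a3g_events(node, target0, config, rng, weights)

    truth = _build_truth(config, target_bg, events, rng)
    tracks = _build_tracks(truth)
    sequences = {"target": target, "sister": sister,
                 "outgroup1": out1, "outgroup2": out2}
    return Simulation(config, ancestor, node, sequences, annotations, truth, tracks)


def _build_truth(config, target_bg: pd.DataFrame, events: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    labels = list(config.lineage_fractions)
    probs = np.array([config.lineage_fractions[k] for k in labels])

    bg = target_bg.copy()
    bg["event_id"] = -1
    bg["event_class"] = np.where(bg.pop("is_cpg"), "cpg", "background")
    bg["lineage"] = np.array(labels)[rng.choice(len(labels), size=len(bg), p=probs)]

    ev = events.rename(columns={})[["event_id", "pos", "anc", "der"]].copy()
    ev["event_class"] = "a3g"
    # a whole event happens in a single generation on a single sub-branch
    per_event = {eid: labels[rng.choice(len(labels), p=probs)]
                 for eid in sorted(events["event_id"].unique())} if len(events) else {}
    ev["lineage"] = ev["event_id"].map(per_event)

    truth = pd.concat([bg, ev], ignore_index=True)
    truth["chrom"] = config.chrom
    truth = truth.rename(columns={"pos": "pos0"})
    truth["anc"] = truth["anc"].map(chr)
    truth["der"] = truth["der"].map(chr)
    truth = truth[["chrom", "pos0", "lineage", "anc", "der", "event_id", "event_class"]]
    return truth.sort_values("pos0", kind="stable").reset_index(drop=True)


def _build_tracks(truth: pd.DataFrame) -> pd.DataFrame:
    """Allele of each descendant lineage at every target-branch mutation:
    derived where the lineage carries the mutation (assigned to 'common' or
    to that lineage), ancestral otherwise."""
    rows = []
    for lin in DESCENDANT_LINEAGES:
        carried = (truth["lineage"] == "common") | (truth["lineage"] == lin)
        rows.append(pd.DataFrame({
            "chrom": truth["chrom"],
            "pos0": truth["pos0"],
            "lineage": lin,
            "allele": np.where(carried, truth["der"], truth["anc"]),
        }))
    return pd.concat(rows, ignore_index=True)
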