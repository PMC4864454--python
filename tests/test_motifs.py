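"""Motif matching, the four backgrounds, exact tests and scan behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import a3gscan as a3g
from a3gscan._seq import revcomp, seq_to_array
from a3gscan.clusters import build_cluster_set
from a3gscan.errors import ArgumentError, UndefinedStatisticError
from a3gscan.motifs import (A3B_TCW, A3G_CC, A3G_CCC, Counts, Motif,
                            enrichment, enrichment_vs_confidence,
                            genomic_background, local_context_background,
                            match_motif, motif_panel_enrichment, parse_motif,
                            random_cluster_background,
                            random_mutation_background, signal,
                            subset_enrichment, trinucleotide_motifs,
                            trinucleotide_scan)

from conftest import cluster_set_from_sim, mutation_frame, small_config


# --- matching -----------------------------------------------------------------

@pytest.mark.parametrize("window,motif,strand,expected", [
    ("ACCCGNN", A3G_CCC, "+", True),    # mutated 3'-most C at centre
    ("NNCGGGT", A3G_CCC, "-", True),    # 5'-most G is the mutated base
    ("NNTCCNN", A3B_TCW, "+", False),   # W excludes C
    ("NNTCANN", A3B_TCW, "+", True),
    ("NNACANN", A3G_CCC, "+", False),
])
def test_match_motif_cases(window, motif, strand, expected):
    assert match_motif(window, motif, strand) is expected


def test_match_motif_window_too_short():
    with pytest.raises(ArgumentError):
        match_motif("CCC", Motif("NCCC", 3, "x"), "+")


def test_motif_validation():
    with pytest.raises(ArgumentError):
        Motif("CCT", 2, "bad")  # mutated position is a T
    with pytest.raises(ArgumentError):
        parse_motif("CCC:2")
    m = parse_motif("TYC:2:mouse")
    assert m.pattern == "TYC" and m.mutated_index == 2


# --- signal -------------------------------------------------------------------

def _cluster_set_with_windows(windows, anc="C"):
    pos = [100 + 30 * i for i in range(len(windows))]
    muts = mutation_frame(pos, anc=anc, windows=windows)
    return build_cluster_set(muts, callable_length=100_000)


def test_signal_counts_fixture():
    windows = ["NCCCCNN"] * 30 + ["NNACANN"] * 70
    cs = _cluster_set_with_windows(windows)
    sig = signal(cs, A3G_CCC)
    assert (sig.n_match, sig.n_total) == (30, 100)
    assert sig.ratio == pytest.approx(0.30)


def test_signal_saturation_and_zero():
    assert signal(_cluster_set_with_windows(["NCCCCNN"] * 4), A3G_CCC).ratio == 1.0
    assert signal(_cluster_set_with_windows(["NNACANN"] * 4), A3G_CCC).ratio == 0.0


def test_signal_empty_set_is_an_error():
    muts = mutation_frame([100])  # a single mutation cannot cluster
    cs = build_cluster_set(muts, callable_length=10_000)
    with pytest.raises(UndefinedStatisticError):
        signal(cs, A3G_CCC)


# --- genomic background -------------------------------------------------------

def test_genomic_background_saturates_on_ccc_repeat():
    genome = seq_to_array("CCC" * 2000)
    bg = genomic_background(genome, A3G_CCC)
    assert bg.ratio == pytest.approx(1.0, abs=1e-3)  # edge effects O(1/L)


def test_genomic_background_needs_c_or_g():
    with pytest.raises(UndefinedStatisticError):
        genomic_background(seq_to_array("ATAT" * 100), A3G_CCC)


def naive_background_scan(seq: str, motif: Motif) -> Counts:
    """Position-by-position brute force on both strands."""
    rc = revcomp(motif.pattern)
    rc_idx = len(motif.pattern) - 1 - motif.mutated_index
    n_match = 0
    for p in range(len(seq)):
        for pat, idx in ((motif.pattern, motif.mutated_index), (rc, rc_idx)):
            start = p - idx
            if start < 0 or start + len(pat) > len(seq):
                continue
            from a3gscan._seq import IUPAC
            if all(seq[start + j] in IUPAC[sym] for j, sym in enumerate(pat)):
                n_match += 1
    return Counts(n_match, seq.count("C") + seq.count("G"))


@pytest.mark.parametrize("motif", [A3G_CCC, A3G_CC, A3B_TCW])
def test_genomic_background_matches_naive_scan(motif):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=5_000))
    fast = genomic_background(seq_to_array(seq), motif)
    slow = naive_background_scan(seq, motif)
    assert (fast.n_match, fast.n_total) == (slow.n_match, slow.n_total)


# --- randomised backgrounds ---------------------------------------------------

@pytest.fixture(scope="module")
def null_run():
    """1 Mb null at an elevated rate so coordinated clusters are plentiful."""
    cfg = small_config(
        a3g_event_rate=0.0, seed=17, genome_length=1_000_000,
        branch_rates={"target": 2e-3, "sister": 1e-3, "outgroup1": 5e-3,
                      "outgroup2": 1e-2, "internal": 1e-3},
        annotation_spec=[("transcribed", 10, 20_000), ("repeat", 10, 1_000)])
    sim = a3g.simulate(cfg)
    cs, _ = cluster_set_from_sim(sim)
    return sim, cs


def test_random_mutation_background_null_consistency(null_run):
    """A randomised set treated as the observation lies inside the
    4-sigma binomial band of the randomised background: E ~ 1."""
    from a3gscan.motifs import randomized_mutation_sets
    sim, cs = null_run
    genome = sim.sequences["target"]
    bg = random_mutation_background(cs, genome, A3G_CCC, n_sets=20, seed=1)
    bg2 = random_mutation_background(cs, genome, A3G_CCC, n_sets=20, seed=1)
    assert (bg.n_match, bg.n_total) == (bg2.n_match, bg2.n_total)  # seeded
    pseudo = next(iter(randomized_mutation_sets(cs, genome, n_sets=1, seed=99)))
    sig = signal(pseudo, A3G_CCC)
    sigma = np.sqrt(bg.ratio * (1 - bg.ratio) / sig.n_total)
    assert abs(sig.ratio - bg.ratio) <= 4 * sigma


def test_random_cluster_background_agrees_with_genomic(null_run):
    sim, cs = null_run
    genome = sim.sequences["target"]
    bg = random_cluster_background(cs, genome, A3G_CCC, n_sets=50, seed=2)
    gbg = genomic_background(genome, A3G_CCC)
    # two estimators of the same null quantity: binomial 4-sigma band
    sigma = np.sqrt(gbg.ratio * (1 - gbg.ratio) / bg.n_total)
    assert abs(bg.ratio - gbg.ratio) < 4 * sigma


def test_random_cluster_background_all_c_genome():
    muts = mutation_frame([100, 130], anc=["C", "C"])
    cs = build_cluster_set(muts, callable_length=5_000)
    genome = seq_to_array("C" * 5_000)
    bg = random_cluster_background(cs, genome, A3G_CC, n_sets=10, seed=0)
    assert bg.ratio == pytest.approx(1.0)


def test_local_context_background_homogeneous_equals_genomic(null_run):
    sim, cs = null_run
    genome = sim.sequences["target"]
    local = local_context_background(cs, genome, A3G_CCC)
    glob = genomic_background(genome, A3G_CCC)
    sigma = np.sqrt(glob.ratio * (1 - glob.ratio) / local.n_total)
    assert abs(local.ratio - glob.ratio) < 4 * sigma


def test_local_context_window_clipped_at_chromosome_start():
    muts = mutation_frame([100, 130], anc=["C", "C"])
    cs = build_cluster_set(muts, callable_length=3_000)
    genome = seq_to_array("ACGT" * 750)
    bg = local_context_background(cs, genome, A3G_CC, window=10_000)
    full = genomic_background(genome, A3G_CC)
    assert bg.n_total == full.n_total  # window covers the whole 3 kb sequence


def test_local_background_tracks_gc_gradient():
    """Clusters in the GC-rich half see a higher CCC local background."""
    rng = np.random.default_rng(9)
    poor = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=100_000))
    rich = "".join(rng.choice(list("ACGT"), p=[0.1, 0.4, 0.4, 0.1], size=100_000))
    genome = seq_to_array(poor + rich)
    in_rich = build_cluster_set(
        mutation_frame([150_000, 150_030], anc=["C", "C"]), callable_length=200_000)
    local = local_context_background(in_rich, genome, A3G_CCC)
    glob = genomic_background(genome, A3G_CCC)
    assert local.ratio > glob.ratio


# --- enrichment statistics ----------------------------------------------------

def test_enrichment_arithmetic_and_null():
    r = enrichment(Counts(30, 100), Counts(1500, 10_000))
    assert r.enrichment == pytest.approx(2.0)
    same = enrichment(Counts(15, 100), Counts(1500, 10_000))
    assert same.enrichment == pytest.approx(1.0)
    assert same.fisher_p >= 0.5


def test_enrichment_zero_background_flags_infinite():
    r = enrichment(Counts(5, 100), Counts(0, 10_000))
    assert r.infinite


def test_fisher_p_equals_hypergeometric_tail():
    sig, bg = Counts(30, 100), Counts(1500, 10_000)
    r = enrichment(sig, bg)
    M = sig.n_total + bg.n_total
    n_motif = sig.n_match + bg.n_match
    expect = stats.hypergeom.sf(sig.n_match - 1, M, n_motif, sig.n_total)
    assert r.fisher_p == pytest.approx(expect, rel=1e-9)


def test_strand_symmetry_of_enrichment(planted_sim):
    """Reverse-complementing genome and alignment swaps C- and
    G-coordinated clusters but leaves every E unchanged."""
    from a3gscan.io import Alignment
    aln = Alignment(planted_sim.chrom, planted_sim.sequences)
    fwd_cs, _ = cluster_set_from_sim(planted_sim)
    muts, n = a3g.call_mutations(aln.reverse_complement())
    rev_cs = build_cluster_set(muts, n)
    genome = planted_sim.sequences["target"]
    rc_genome = seq_to_array(revcomp(genome.tobytes().decode()))
    for motif in (A3G_CCC, A3G_CC):
        ef = enrichment(signal(fwd_cs, motif), genomic_background(genome, motif))
        er = enrichment(signal(rev_cs, motif), genomic_background(rc_genome, motif))
        assert ef.enrichment == pytest.approx(er.enrichment, rel=1e-12)
        c_fwd = (fwd_cs.clusters["type"] == "C").sum()
        g_rev = (rev_cs.clusters["type"] == "G").sum()
        assert c_fwd == g_rev


def test_panel_bonferroni_within_invocation(planted_sim):
    cs, _ = cluster_set_from_sim(planted_sim)
    genome = planted_sim.sequences["target"]
    results = motif_panel_enrichment(cs, genome)
    n = len(results)
    for r in results:
        assert r.q == pytest.approx(min(1.0, r.fisher_p * n))


# --- trinucleotide scan -------------------------------------------------------

def test_scan_emits_48_results(null_run):
    sim, cs = null_run
    scan = trinucleotide_scan(cs, sim.sequences["target"])
    assert len(scan) == 48
    assert len(trinucleotide_motifs()) == 48
    assert scan.groupby("mutated_index").size().tolist() == [16, 16, 16]


def test_scan_ccc_row_matches_dedicated_motif_run(planted_sim):
    cs, _ = cluster_set_from_sim(planted_sim)
    genome = planted_sim.sequences["target"]
    scan = trinucleotide_scan(cs, genome)
    row = scan[(scan["pattern"] == "CCC") & (scan["mutated_index"] == 2)].iloc[0]
    direct = enrichment(signal(cs, A3G_CCC), genomic_background(genome, A3G_CCC))
    assert row["enrichment"] == pytest.approx(direct.enrichment)
    assert row["fisher_p"] == pytest.approx(direct.fisher_p)


def test_scan_flags_cpg_triplets(null_run):
    sim, cs = null_run
    scan = trinucleotide_scan(cs, sim.sequences["target"])
    assert bool(scan.loc[(scan["pattern"] == "ACG") & (scan["mutated_index"] == 1),
                         "cpg"].iloc[0])
    assert not bool(scan.loc[(scan["pattern"] == "CCC") & (scan["mutated_index"] == 2),
                             "cpg"].iloc[0])


# --- confidence correlation & subsets ----------------------------------------

def test_confidence_correlation_argument_checks(planted_sim):
    cs, _ = cluster_set_from_sim(planted_sim)
    genome = planted_sim.sequences["target"]
    with pytest.raises(ArgumentError):
        enrichment_vs_confidence(cs, genome, [0.5, 0.1])


def test_confidence_correlation_positive_on_planted_signal(planted_sim):
    cs, _ = cluster_set_from_sim(planted_sim)
    genome = planted_sim.sequences["target"]
    res = enrichment_vs_confidence(cs, genome, [0.5, 0.1, 0.01, 0.001])
    assert res.r is not None and len(res.table) == 4


def test_subset_enrichment_whole_genome_is_identity(planted_sim):
    cs, _ = cluster_set_from_sim(planted_sim)
    genome = planted_sim.sequences["target"]
    whole = pd.DataFrame({"chrom": [planted_sim.chrom], "start": [0],
                          "end": [genome.size]})
    sub = subset_enrichment(cs, genome, whole)
    free = subset_enrichment(cs, genome, None)
    assert sub.enrichment == pytest.approx(free.enrichment)


def test_subset_enrichment_empty_region_errors(planted_sim):
    cs, _ = cluster_set_from_sim(planted_sim)
    genome = planted_sim.sequences["target"]
    empty = pd.DataFrame({"chrom": ["nowhere"], "start": [0], "end": [10]})
    with pytest.raises(UndefinedStatisticError):
        subset_enrichment(cs, genome, empty)


def test_clustered_exceed_nonclustered_enrichment(planted_sim):
    """Planted events only ever land in clusters, so clustered mutations
    carry more motif signal than single point mutations."""
    cs, _ = cluster_set_from_sim(planted_sim)
    genome = planted_sim.sequences["target"]
    clustered = subset_enrichment(cs, genome, None, which="clustered")
    single = subset_enrichment(cs, genome, None, which="nonclustered")
    assert clustered.enrichment > single.enrichment
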