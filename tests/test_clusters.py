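"""Cluster chaining vs a brute-force oracle, exclusion and typing rules,
and the negative-binomial cluster score against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from a3gscan.clusters import (build_cluster_set, cluster_pvalue,
                              define_a3g_clusters, detect_clusters,
                              exclude_complex, expected_a3g_clusters,
                              expected_same_ancestor_clusters, filter_by_pvalue)
from a3gscan.errors import ArgumentError

from conftest import mutation_frame


def oracle_clusters(positions, ancs, max_spacing=50, min_size=2, min_spacing=None):
    """Independent all-pairs windowing oracle: union-find over every pair
    within max_spacing, then size filter, complex exclusion and typing."""
    pos = np.asarray(positions)
    n = pos.size
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        near = np.flatnonzero(np.abs(pos - pos[i]) <= max_spacing)
        for j in near:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        if len(members) < min_size:
            continue
        p = sorted(pos[m] for m in members)
        gaps = [b - a for a, b in zip(p, p[1:])]
        if min_spacing is not None and any(g <= min_spacing for g in gaps):
            continue
        a = {ancs[m] for m in members}
        ctype = a.pop() if len(a) == 1 else "N"
        out.append((tuple(p), ctype))
    return sorted(out)


def package_clusters(muts, max_spacing=50, min_spacing=None):
    mm, cl = detect_clusters(muts, max_spacing)
    if min_spacing is not None:
        mm, cl, _ = exclude_complex(mm, cl, min_spacing)
    from a3gscan.clusters import classify_clusters
    cl = classify_clusters(mm, cl)
    out = []
    for cid, t in zip(cl["cluster_id"], cl["type"]):
        p = tuple(sorted(mm.loc[mm["cluster_id"] == cid, "pos0"]))
        out.append((p, t))
    return sorted(out)


def test_detect_simple_chain_and_boundary():
    mm, cl = detect_clusters(mutation_frame([100, 140, 190]))
    assert len(cl) == 1 and cl.iloc[0].k == 3 and cl.iloc[0].span == 91
    mm, cl = detect_clusters(mutation_frame([100, 151]))
    assert len(cl) == 0


def test_detect_requires_sorted_unique_positions():
    df = mutation_frame([100, 90])
    df = df.iloc[::-1].reset_index(drop=True)  # deliberately unsorted
    with pytest.raises(ArgumentError):
        detect_clusters(df)


def test_chains_split_across_chromosomes():
    df = pd.concat([mutation_frame([100, 120], chrom="chr1"),
                    mutation_frame([130, 150], chrom="chr2")], ignore_index=True)
    _, cl = detect_clusters(df)
    assert len(cl) == 2 and set(cl["chrom"]) == {"chr1", "chr2"}


@pytest.mark.parametrize("spacing", [50, 100, 300, 1000])
def test_detection_matches_oracle_on_random_instances(spacing):
    rng = np.random.default_rng(spacing)
    for _ in range(5):
        pos = np.sort(rng.choice(200_000, size=400, replace=False))
        ancs = rng.choice(list("ACGT"), size=400)
        muts = mutation_frame(pos, anc=list(ancs))
        assert (package_clusters(muts, spacing, 10)
                == oracle_clusters(pos, list(ancs), spacing, 2, 10))


def test_exclude_complex_rules():
    mm, cl = detect_clusters(mutation_frame([100, 105, 140]))
    _, kept, removed = exclude_complex(mm, cl)
    assert len(kept) == 0 and len(removed) == 1  # gap 5 <= 10
    mm, cl = detect_clusters(mutation_frame([100, 111, 150]))
    _, kept, removed = exclude_complex(mm, cl)
    assert len(kept) == 1 and len(removed) == 0  # min gap 11


def test_planted_complex_events_are_all_removed():
    """Events generated with spacing <= 10 bp are complex by definition
    and must never survive the exclusion."""
    import a3gscan as a3g
    from conftest import small_config, cluster_set_from_sim
    # loose-motif planting: the tight 6 bp windows rarely contain a CCC
    cfg = small_config(a3g_min_gap=5, a3g_span=10, motif_fidelity=0.0, seed=41)
    sim = a3g.simulate(cfg)
    cs, _ = cluster_set_from_sim(sim)
    planted = set(sim.truth.loc[sim.truth["event_class"] == "a3g", "pos0"])
    clustered = cs.mutations[cs.mutations["cluster_id"] >= 0]
    assert not planted & set(clustered["pos0"])


@pytest.mark.parametrize("ancs,expected", [
    (["C", "C", "C"], "C"), (["C", "G"], "N"), (["A", "A"], "A")])
def test_cluster_typing(ancs, expected):
    pos = [100 + 20 * i for i in range(len(ancs))]
    muts = mutation_frame(pos, anc=ancs)
    assert package_clusters(muts)[0][1] == expected


def test_typing_invariant_to_mutation_order():
    a = package_clusters(mutation_frame([100, 120], anc=["C", "G"]))
    b = package_clusters(mutation_frame([100, 120], anc=["G", "C"]))
    assert a[0][1] == b[0][1] == "N"


# --- negative-binomial cluster score -----------------------------------------

def nb_pvalue_bruteforce(k, x, pi):
    """Term-by-term evaluation of the printed sum."""
    return sum(math.comb(k - 2 + j, j) * (1 - pi) ** j * pi ** (k - 1)
               for j in range(0, x - k + 1))


def test_pvalue_minimal_span_equals_pi():
    assert cluster_pvalue(2, 2, 0.001) == pytest.approx(0.001, abs=1e-15)


def test_pvalue_matches_k2_closed_form():
    for x in (2, 10, 51, 200):
        assert cluster_pvalue(2, x, 1e-3) == pytest.approx(
            1 - (1 - 1e-3) ** (x - 1), abs=1e-13)


@pytest.mark.parametrize("k,x,pi", [(2, 51, 1e-3), (3, 52, 1e-3), (4, 30, 1e-2),
                                    (5, 120, 5e-3), (2, 2, 0.5)])
def test_pvalue_matches_bruteforce_sum(k, x, pi):
    assert cluster_pvalue(k, x, pi) == pytest.approx(
        nb_pvalue_bruteforce(k, x, pi), abs=1e-12)


@given(st.integers(2, 8), st.integers(0, 300), st.floats(1e-5, 0.5))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_pvalue_monotonicity(k, extra, pi):
    x = k + extra
    p = cluster_pvalue(k, x, pi)
    assert 0 < p <= 1
    assert cluster_pvalue(k, x + 10, pi) >= p          # wider span, larger p
    if x >= k + 1:
        assert cluster_pvalue(k + 1, x + 1, pi) <= cluster_pvalue(k, x + 1, pi)


def test_pvalue_tends_to_one_for_huge_spans():
    assert cluster_pvalue(3, 100_000, 1e-3) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("k,x,pi", [(0, 5, 0.1), (2, 1, 0.1), (2, 5, 0.0), (2, 5, 1.0)])
def test_pvalue_domain_violations(k, x, pi):
    with pytest.raises(ArgumentError):
        cluster_pvalue(k, x, pi)


def test_pvalue_filter_monotone_nesting():
    rng = np.random.default_rng(3)
    pos = np.sort(rng.choice(100_000, size=600, replace=False))
    cs = build_cluster_set(mutation_frame(pos), callable_length=100_000)
    full = filter_by_pvalue(cs, 1.0)
    assert len(full.clusters) == len(cs.clusters)  # threshold 1 is identity
    loose = filter_by_pvalue(cs, 0.05)
    strict = filter_by_pvalue(cs, 0.001)
    assert set(strict.clusters["cluster_id"]) <= set(loose.clusters["cluster_id"])
    with pytest.raises(ArgumentError):
        filter_by_pvalue(cs, 0.0)


# --- expected-count formulas --------------------------------------------------

def test_expected_same_ancestor_identities():
    assert expected_same_ancestor_clusters({2: 10, 3: 5}, 1.0) == 15
    assert expected_same_ancestor_clusters({2: 10}, 0.25) == pytest.approx(0.625)


def test_expected_a3g_identities():
    assert expected_a3g_clusters({2: 10}, 0.0) == 0.0
    assert expected_a3g_clusters({2: 10}, 0.5) == pytest.approx(7.5)


def test_expected_a3g_equals_binomial_sum():
    p = 0.137
    for i in range(2, 11):
        closed = 1 - (1 - p) ** i
        binom_sum = sum(math.comb(i, j) * p ** j * (1 - p) ** (i - j)
                        for j in range(1, i + 1))
        assert closed == pytest.approx(binom_sum, abs=1e-12)
        assert expected_a3g_clusters({i: 1}, p) == pytest.approx(binom_sum, abs=1e-12)


# --- putative enzyme-cluster definition --------------------------------------

def test_a3g_cluster_requires_a_stringent_motif_mutation():
    windows_in = ["NNACANN", "NCCCCNN"]   # second mutation in CCC context
    windows_out = ["NNACANN", "NNTCANN"]
    for windows, expect in ((windows_in, 1), (windows_out, 0)):
        muts = mutation_frame([100, 130], anc=["C", "C"], windows=windows)
        cs = build_cluster_set(muts, callable_length=10_000)
        a3g = define_a3g_clusters(cs)
        assert len(a3g.clusters) == expect


def test_g_cluster_matched_through_reverse_complement():
    muts = mutation_frame([100, 130], anc=["G", "G"],
                          windows=["NNNGGGN", "NNNGNNN"])
    cs = build_cluster_set(muts, callable_length=10_000)
    assert len(define_a3g_clusters(cs).clusters) == 1
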