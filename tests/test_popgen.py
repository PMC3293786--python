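"""Unit and property tests for sequence statistics, AMOVA and networks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloniche import popgen as pg


def align(*seqs):
    return pg.Alignment.from_pairs((f"s{i}", s) for i, s in enumerate(seqs))


# ---------------------------------------------------------------------------
# containers


def test_alignment_rejects_ragged_and_duplicate_ids():
    with pytest.raises(ValueError, match="ragged"):
        pg.Alignment(("a", "b"), ("AAA", "AA"))
    with pytest.raises(ValueError, match="duplicate"):
        pg.Alignment(("a", "a"), ("AAA", "AAA"))
    with pytest.raises(ValueError, match="empty"):
        pg.Alignment((), ())


def test_structure_requires_group_for_every_population():
    with pytest.raises(ValueError, match="without group"):
        pg.PopulationStructure({"i1": "p1"}, {})


# ---------------------------------------------------------------------------
# haplotype collapsing


def test_collapse_identical_and_distinct():
    h = pg.collapse_haplotypes(align("AAA", "AAA", "AAA", "AAA"))
    assert h.n_haplotypes == 1 and h.counts == (4,)
    h = pg.collapse_haplotypes(align("AAA", "AAT", "ATA", "TAA"))
    assert h.n_haplotypes == 4 and h.counts == (1, 1, 1, 1)


def test_collapse_merges_ambiguous_sites_under_pairwise_deletion():
    a = align("ANA", "ATA", "AAA")
    merged = pg.collapse_haplotypes(a, merge_ambiguous=True)
    # ANA is compatible with both ATA and AAA; first-occurrence greedy
    # assigns ATA and AAA to the ANA class
    assert merged.n_haplotypes == 1
    strict = pg.collapse_haplotypes(a, merge_ambiguous=False)
    assert strict.n_haplotypes == 3


def test_collapse_order_is_first_occurrence():
    h = pg.collapse_haplotypes(align("TTT", "AAA", "TTT"))
    assert h.sequences == ("TTT", "AAA")
    assert h.counts == (2, 1)
    assert h.individual_haplotype == {"s0": 0, "s1": 1, "s2": 0}


# ---------------------------------------------------------------------------
# diversity


@pytest.mark.parametrize(
    "seqs, expected",
    [
        (("ACGT", "ACGT", "ACGT"), 0.0),
        (("AAA", "AAT", "ATA", "TAA"), 0.5),  # 9 diffs / 6 pairs / 3 sites
        (("AAAA", "TTTT"), 1.0),
    ],
)
def test_nucleotide_diversity_examples(seqs, expected):
    assert pg.nucleotide_diversity(align(*seqs)) == pytest.approx(expected)


def test_haplotype_diversity_examples():
    assert pg.haplotype_diversity(
        pg.collapse_haplotypes(align("AAA", "AAA"))
    ) == pytest.approx(0.0)
    assert pg.haplotype_diversity(
        pg.collapse_haplotypes(align("AAA", "AAT", "ATA", "TAA"))
    ) == pytest.approx(1.0)
    # counts (2, 1, 1): (4/3)(1 - 6/16)
    assert pg.haplotype_diversity(
        pg.collapse_haplotypes(align("AAA", "AAA", "AAT", "ATA"))
    ) == pytest.approx(0.83333333)


def test_diversity_requires_two_sequences():
    with pytest.raises(ValueError):
        pg.nucleotide_diversity(align("AAA"))


# ---------------------------------------------------------------------------
# neutrality tests


def test_tajimas_d_undefined_without_segregating_sites():
    assert math.isnan(pg.tajimas_d(align("AAA", "AAA", "AAA")))


def test_tajimas_d_four_sequence_example():
    # hand derivation: pi = 1.5, S = 3, a1 = 11/6, theta_W = 18/11
    assert pg.tajimas_d(align("AAA", "AAT", "ATA", "TAA")) == pytest.approx(
        -0.754, abs=5e-4
    )


def test_stirling_numbers_match_exact_enumeration():
    # |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)| in exact integer arithmetic
    exact = {1: [0, 1]}
    for n in range(1, 8):
        prev = exact[n]
        nxt = [0] * (n + 2)
        for k in range(1, n + 2):
            nxt[k] = n * (prev[k] if k <= n else 0) + prev[k - 1]
        exact[n + 1] = nxt
    for n in range(2, 9):
        ours = pg.log_stirling_first_unsigned(n)
        for k in range(1, n + 1):
            assert ours[k] == pytest.approx(math.log(exact[n][k]), rel=1e-12)


def test_ewens_distribution_n3_theta1():
    p = pg.ewens_k_distribution(3, 1.0)
    assert p == pytest.approx([2 / 6, 3 / 6, 1 / 6])


def test_fus_fs_matches_ewens_exceedance():
    a = align("AAAA", "AATA", "AATT", "TATT")
    theta = pg.mean_pairwise_differences(a)
    k = pg.collapse_haplotypes(a).n_haplotypes
    s_prime = pg.ewens_k_distribution(a.n, theta)[k - 1 :].sum()
    assert pg.fus_fs(a) == pytest.approx(math.log(s_prime / (1 - s_prime)))


def test_fus_fs_edge_cases():
    assert math.isnan(pg.fus_fs(align("AAA", "AAA")))  # pi = 0
    # merged haplotypes (k=1) with nonzero pi via ambiguous sites: deficit
    # of haplotypes maps to +inf
    assert pg.fus_fs(align("AN", "AT", "AA")) == math.inf


# ---------------------------------------------------------------------------
# distances


def test_distances_zero_for_identical_pairs():
    a = align("ACGTACGT", "ACGTACGT")
    for model in ("p", "JC69", "TN93"):
        d = pg.pairwise_distance(a, pg.DistanceModelConfig(model=model))
        assert d[0, 1] == pytest.approx(0.0)


def test_jc69_closed_form():
    d = pg.pairwise_distance(align("AAT", "AAA"), pg.DistanceModelConfig(model="JC69"))
    assert d[0, 1] == pytest.approx(-0.75 * math.log(5 / 9), rel=1e-9)


def test_jc69_domain_violation_is_nan():
    d = pg.pairwise_distance(align("ACGT", "CATG"), pg.DistanceModelConfig("JC69"))
    assert math.isnan(d[0, 1])  # p = 1 >= 3/4


def test_tn93_collapses_to_jc69_with_equal_frequencies_and_rates():
    # equal base composition in both sequences; transitions == transversions
    # per class: P1 (A<->G), P2 (C<->T) and Q chosen so the TN93 terms match
    # the single JC69 term
    s1 = "AACCGGTT" * 6
    # substitutions: 2 A->G, 2 C->T, 2 A->C, 2 G->T keep composition balanced
    s2 = list(s1)
    s2[0] = "G"; s2[8] = "G"        # A->G transitions
    s2[2] = "T"; s2[10] = "T"       # C->T transitions
    s2[16] = "C"; s2[24] = "C"      # A->C transversions
    s2[4] = "T"; s2[12] = "T"       # G->T transversions
    s2 = "".join(s2)
    a = align(s1, s2)
    jc = pg.pairwise_distance(a, pg.DistanceModelConfig("JC69"))[0, 1]
    tn = pg.pairwise_distance(a, pg.DistanceModelConfig("TN93"))[0, 1]
    assert tn == pytest.approx(jc, abs=5e-3)


def test_distance_matrix_symmetry_and_nonnegativity(rng):
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, 40)]) for _ in range(6)]
    for model in ("p", "JC69", "TN93"):
        d = pg.pairwise_distance(align(*seqs), pg.DistanceModelConfig(model))
        assert np.allclose(d, d.T, equal_nan=True)
        assert np.all(d[~np.isnan(d)] >= 0)
        assert np.all(np.diag(d) == 0)


def test_gamma_correction_increases_distance():
    a = align("AAAAATTTTT", "AAAAATTTAA")
    plain = pg.pairwise_distance(a, pg.DistanceModelConfig("JC69"))[0, 1]
    gamma = pg.pairwise_distance(
        a, pg.DistanceModelConfig("JC69", gamma_alpha=0.5)
    )[0, 1]
    assert gamma > plain


# ---------------------------------------------------------------------------
# AMOVA


def _brute_force_components(d2, pop_of, group_of_pop):
    """Direct evaluation of the sums-of-squares identities."""
    n = len(pop_of)
    pops = np.unique(pop_of)
    groups = np.unique(group_of_pop)

    def ss(idx):
        return sum(
            d2[i, j] for i, j in itertools.combinations(idx, 2)
        ) / len(idx)

    ss_total = ss(range(n))
    ss_wp = sum(ss([i for i in range(n) if pop_of[i] == p]) for p in pops)
    ss_wg = sum(
        ss([i for i in range(n) if group_of_pop[pop_of[i]] == g]) for g in groups
    )
    df_ag, df_ap, df_wp = len(groups) - 1, len(pops) - len(groups), n - len(pops)
    pop_sizes = {p: np.sum(pop_of == p) for p in pops}
    group_sizes = {g: sum(pop_sizes[p] for p in pops if group_of_pop[p] == g)
                   for g in groups}
    sum_np2_ng = sum(
        sum(pop_sizes[p] ** 2 for p in pops if group_of_pop[p] == g) / group_sizes[g]
        for g in groups
    )
    n1 = (n - sum_np2_ng) / df_ap
    n2 = (sum_np2_ng - sum(v**2 for v in pop_sizes.values()) / n) / df_ag
    n3 = (n - sum(v**2 for v in group_sizes.values()) / n) / df_ag
    sc = ss_wp / df_wp
    sb = ((ss_wg - ss_wp) / df_ap - sc) / n1
    sa = ((ss_total - ss_wg) / df_ag - sc - n2 * sb) / n3
    return sa, sb, sc


def test_amova_phi_st_one_for_fixed_differences(two_level_structure):
    # two monomorphic populations in one group, fixed differences between
    ind_pop = {f"A_{i}": "A" for i in range(3)} | {f"B_{i}": "B" for i in range(3)}
    s = pg.PopulationStructure(ind_pop, {"A": "G", "B": "G"})
    ids = list(ind_pop)
    d = np.zeros((6, 6))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if a[0] != b[0]:
                d[i, j] = 4.0
    res = pg.amova(d, ids, s, n_permutations=0)
    assert res.phi_st == pytest.approx(1.0)


def test_amova_all_identical_gives_undefined_phis(two_level_structure):
    ids = list(two_level_structure.individual_population)
    res = pg.amova(np.zeros((12, 12)), ids, two_level_structure, n_permutations=0)
    assert all(math.isnan(v) for v in (res.phi_st, res.phi_sc, res.phi_ct))
    assert res.sigma2 == (0.0, 0.0, 0.0)


def test_amova_components_match_brute_force_oracle(two_level_structure, rng):
    ids = list(two_level_structure.individual_population)
    x = rng.normal(size=(12, 4))
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    res = pg.amova(d2, ids, two_level_structure, n_permutations=0)
    pop_names = two_level_structure.populations
    pop_of = np.array(
        [pop_names.index(two_level_structure.individual_population[i]) for i in ids]
    )
    group_names = two_level_structure.groups
    group_of_pop = np.array(
        [group_names.index(two_level_structure.population_group[p]) for p in pop_names]
    )
    oracle = _brute_force_components(d2, pop_of, group_of_pop)
    assert res.sigma2 == pytest.approx(oracle, abs=1e-10)


def test_amova_phi_identity_and_pvalue_range(two_level_structure, rng):
    ids = list(two_level_structure.individual_population)
    x = rng.normal(size=(12, 3))
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    res = pg.amova(d2, ids, two_level_structure, n_permutations=99, seed=1)
    assert (1 - res.phi_ct) * (1 - res.phi_sc) == pytest.approx(
        1 - res.phi_st, abs=1e-10
    )
    for p in (res.p_phi_ct, res.p_phi_sc, res.p_phi_st):
        assert 1 / 100 <= p <= 1


def test_amova_permutations_are_seed_deterministic(two_level_structure, rng):
    ids = list(two_level_structure.individual_population)
    x = rng.normal(size=(12, 2))
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    r1 = pg.amova(d2, ids, two_level_structure, n_permutations=50, seed=42)
    r2 = pg.amova(d2, ids, two_level_structure, n_permutations=50, seed=42)
    assert r1.p_phi_st == r2.p_phi_st


def test_amova_flags_degenerate_designs():
    ind_pop = {"a": "A", "b": "B", "c": "B", "d": "B"}
    s = pg.PopulationStructure(ind_pop, {"A": "G1", "B": "G2"})
    d = np.ones((4, 4)) - np.eye(4)
    res = pg.amova(d, list(ind_pop), s, n_permutations=0)
    assert "singleton_population" in res.flags
    assert "single_population_group" in res.flags


def test_indicator_distance_is_frequency_only():
    h = pg.collapse_haplotypes(align("AAA", "AAA", "TTT"))
    d = pg.indicator_distance(h, ["s0", "s1", "s2"])
    assert d[0, 1] == 0 and d[0, 2] == 1 and d[1, 2] == 1


# ---------------------------------------------------------------------------
# minimum-spanning network


def _brute_force_mst_weight(D):
    n = D.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = math.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(D[i, j] for i, j in combo))
    return best


def test_mst_trivial_cases():
    single = pg.collapse_haplotypes(align("AAAA"))
    net = pg.min_spanning_network(single)
    assert net.edges == () and net.n_nodes == 1
    tri = pg.collapse_haplotypes(align("AAA", "AAT", "ATT"))
    net = pg.min_spanning_network(tri)
    assert net.total_weight == 2  # chain via the two unit edges


def test_mst_weight_matches_brute_force(rng):
    bases = np.array(list("ACGT"))
    for _ in range(25):
        k = rng.integers(3, 7)
        seqs = {"".join(bases[rng.integers(0, 4, 8)]) for _ in range(k)}
        h = pg.collapse_haplotypes(align(*sorted(seqs)))
        net = pg.min_spanning_network(h)
        D = pg.hamming_distance_matrix(h)
        assert net.total_weight == _brute_force_mst_weight(D)


def test_mst_alternative_edges_close_equal_weight_cycles():
    # square: four haplotypes at unit steps around a cycle
    h = pg.collapse_haplotypes(align("AA", "AT", "TT", "TA"))
    net = pg.min_spanning_network(h)
    assert len(net.edges) == 3
    assert net.total_weight == 3
    # the unused side of the square ties the tree path it would close
    assert len(net.alternative_edges) == 1
    i, j, w = net.alternative_edges[0]
    assert w == 1


# ---------------------------------------------------------------------------
# north/south split and Holm


def test_split_north_south_boundary_and_partition():
    ind_pop = {"a": "P1", "b": "P2", "c": "P3"}
    s = pg.PopulationStructure(
        ind_pop,
        {"P1": "X", "P2": "X", "P3": "X"},
        {"P1": 41.0, "P2": 40.0, "P3": 39.0},
    )
    ns = pg.split_north_south(s)
    assert ns.population_group == {"P1": "N", "P2": "S", "P3": "S"}
    with pytest.raises(ValueError, match="latitude"):
        pg.split_north_south(pg.PopulationStructure(ind_pop, {p: "X" for p in ("P1", "P2", "P3")}))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
def test_holm_is_monotone_capped_and_bounded(ps):
    from phyloniche.stats import holm_adjust

    adj = holm_adjust(ps)
    assert all(0 <= a <= 1 for a in adj)
    assert all(a >= p for a, p in zip(adj, ps))
    order = np.argsort(ps)
    assert all(
        adj[order[i]] <= adj[order[i + 1]] + 1e-12 for i in range(len(ps) - 1)
    )


def test_holm_hand_example():
    from phyloniche.stats import holm_adjust

    assert holm_adjust([0.01, 0.03, 0.04]) == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == [0.2]
    assert holm_adjust([1.0, 1.0]) == [1.0, 1.0]
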