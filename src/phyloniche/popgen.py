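"""Sequence-based phylogeography statistics.

Diversity indices (nucleotide and haplotype diversity), neutrality tests
(Tajima's D, Fu's Fs), nucleotide distances (p, JC69, TN93 with optional
gamma rate heterogeneity), hierarchical AMOVA with permutation tests, and
minimum-spanning haplotype networks.

Missing data (``N``) and alignment gaps (``-``) are handled by pairwise
deletion by default: a site enters a pairwise comparison only when both
sequences carry an unambiguous base there. Complete deletion (drop every
column containing any ambiguous character) is available where it matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

VALID_BASES = frozenset("ACGT")
#: sentinel for statistics that are undefined on the given data (e.g. D at S=0)
UNDEFINED = float("nan")

# ---------------------------------------------------------------------------
# core containers


@dataclass(frozen=True)
class Alignment:
    """Equal-length nucleotide sequences over {A,C,G,T,N,-} with unique ids."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        if len(self.ids) == 0:
            raise ValueError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        bad = set("".join(self.sequences)) - set("ACGTN-")
        if bad:
            raise ValueError(f"invalid characters in alignment: {sorted(bad)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = zip(*((i, s.upper()) for i, s in pairs))
        return cls(tuple(ids), tuple(seqs))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class PopulationStructure:
    """Two-level sampling design: individuals within populations within groups.

    Latitude/longitude are per population (decimal degrees) and optional; the
    north/south relabelling requires latitude.
    """

    individual_population: dict[str, str]
    population_group: dict[str, str]
    population_latitude: dict[str, float] = field(default_factory=dict)
    population_longitude: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.individual_population.values()) - set(self.population_group)
        if missing:
            raise ValueError(f"populations without group assignment: {sorted(missing)}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.individual_population.values():
            seen.setdefault(p, None)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(self.population_group[p], None)
        return list(seen)

    def individuals_of(self, population: str) -> list[str]:
        return [i for i, p in self.individual_population.items() if p == population]

    def populations_of(self, group: str) -> list[str]:
        return [p for p in self.populations if self.population_group[p] == group]


@dataclass(frozen=True)
class HaplotypeSet:
    """Unique haplotype sequences, their counts, and the individual mapping."""

    sequences: tuple[str, ...]
    counts: tuple[int, ...]
    individual_haplotype: dict[str, int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class DistanceModelConfig:
    """Nucleotide substitution model for pairwise distances.

    model: "p", "JC69" or "TN93"; gamma_alpha: gamma shape for rate
    heterogeneity (None = no correction); pairwise_deletion: drop ambiguous
    sites per pair (True) or globally (False).
    """

    model: str = "p"
    gamma_alpha: float | None = None
    pairwise_deletion: bool = True

    def __post_init__(self):
        if self.model not in ("p", "JC69", "TN93"):
            raise ValueError(f"unknown distance model {self.model!r}")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be > 0")


@dataclass(frozen=True)
class NeutralityResult:
    n: int
    S: int
    pi_per_site: float
    pi_per_locus: float
    haplotype_diversity: float
    tajimas_d: float
    fus_fs: float


@dataclass(frozen=True)
class AmovaResult:
    """Hierarchical variance decomposition with Φ-statistics.

    sigma2: (among groups, among populations within groups, within
    populations); percent: same order, summing to 100; p-values are
    permutation (b+1)/(B+1) or NaN when not tested.
    """

    sigma2: tuple[float, float, float]
    percent: tuple[float, float, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    df: tuple[int, int, int]
    ss: tuple[int, int, int] | tuple[float, float, float]
    p_phi_ct: float = UNDEFINED
    p_phi_sc: float = UNDEFINED
    p_phi_st: float = UNDEFINED
    n_permutations: int = 0
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class HaplotypeNetwork:
    """Minimum spanning tree over haplotype mutational distances.

    ``edges`` is the tree core; ``alternative_edges`` are non-tree edges that
    would close a cycle whose maximum tree-edge weight equals their own weight
    (equally parsimonious connections).
    """

    n_nodes: int
    frequencies: tuple[int, ...]
    edges: tuple[tuple[int, int, int], ...]
    alternative_edges: tuple[tuple[int, int, int], ...]

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


# ---------------------------------------------------------------------------
# haplotype collapsing


def collapse_haplotypes(a: Alignment, merge_ambiguous: bool = True) -> HaplotypeSet:
    """Collapse an alignment to unique haplotypes, ordered by first occurrence.

    With ``merge_ambiguous`` (default), a sequence joins the first earlier
    haplotype it is compatible with: equal at every site where both carry an
    unambiguous base (pairwise deletion of N/- sites). Otherwise haplotypes
    are exact string classes.
    """
    reps: list[str] = []
    counts: list[int] = []
    mapping: dict[str, int] = {}
    for ind, seq in zip(a.ids, a.sequences):
        hit = None
        for k, rep in enumerate(reps):
            if seq == rep or (merge_ambiguous and _compatible(seq, rep)):
                hit = k
                break
        if hit is None:
            reps.append(seq)
            counts.append(1)
            mapping[ind] = len(reps) - 1
        else:
            counts[hit] += 1
            mapping[ind] = hit
    return HaplotypeSet(tuple(reps), tuple(counts), mapping)


def _compatible(s1: str, s2: str) -> bool:
    return all(
        c1 == c2 or c1 not in VALID_BASES or c2 not in VALID_BASES
        for c1, c2 in zip(s1, s2)
    )


# ---------------------------------------------------------------------------
# diversity


_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _k, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _k


def _encode(a: Alignment) -> np.ndarray:
    """(n, L) uint8 matrix; A,C,G,T -> 0..3, anything else -> 255."""
    flat = np.frombuffer("".join(a.sequences).encode(), dtype=np.uint8)
    return _ENCODE_TABLE[flat].reshape(a.n, a.length)


def _pair_diff_valid(s1: str, s2: str) -> tuple[int, int]:
    """(differences, comparable sites) under pairwise deletion."""
    diff = valid = 0
    for c1, c2 in zip(s1, s2):
        if c1 in VALID_BASES and c2 in VALID_BASES:
            valid += 1
            if c1 != c2:
                diff += 1
    return diff, valid


def _pairwise_counts(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(diffs, comparable-sites) matrices over all sequence pairs."""
    n = x.shape[0]
    ok = x < 4
    D = np.zeros((n, n))
    V = np.zeros((n, n))
    for i in range(n - 1):
        both = ok[i] & ok[i + 1 :]
        diff = (x[i] != x[i + 1 :]) & both
        D[i, i + 1 :] = diff.sum(axis=1)
        V[i, i + 1 :] = both.sum(axis=1)
    return D + D.T, V + V.T


def mean_pairwise_differences(a: Alignment) -> float:
    """Mean number of pairwise differences per locus (π in per-locus units)."""
    if a.n < 2:
        raise ValueError("need at least 2 sequences")
    D, _ = _pairwise_counts(_encode(a))
    return float(np.sum(np.triu(D, 1))) / (a.n * (a.n - 1) / 2)


def nucleotide_diversity(a: Alignment) -> float:
    """π per site: mean pairwise proportion of differing sites.

    Each pair is normalized by its own number of comparable sites (pairwise
    deletion), so π = mean over pairs of d_ij / L_ij.
    """
    if a.n < 2:
        raise ValueError("need at least 2 sequences")
    D, V = _pairwise_counts(_encode(a))
    iu = np.triu_indices(a.n, 1)
    d, v = D[iu], V[iu]
    frac = np.where(v > 0, d / np.maximum(v, 1), 0.0)
    return float(frac.sum()) / len(d)


def haplotype_diversity(h: HaplotypeSet) -> float:
    """Hd = n/(n−1) · (1 − Σ p_i²): probability two sampled haplotypes differ."""
    n = h.n
    if n < 2:
        raise ValueError("need at least 2 individuals")
    p = np.asarray(h.counts, dtype=float) / n
    return n / (n - 1) * (1.0 - float(np.sum(p**2)))


def segregating_sites(a: Alignment) -> int:
    """Number of polymorphic sites, ignoring N/- characters per column."""
    x = _encode(a)
    present = np.stack([(x == b).any(axis=0) for b in range(4)])
    return int(np.sum(present.sum(axis=0) > 1))


# ---------------------------------------------------------------------------
# neutrality tests


def tajimas_d(a: Alignment) -> float:
    """Tajima's D: normalized difference between π (per locus) and S/a1.

    Returns NaN (undefined) when S = 0. Negative values indicate an excess of
    rare variants, the signature of population expansion.
    """
    n = a.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    S = segregating_sites(a)
    if S == 0:
        return UNDEFINED
    pi = mean_pairwise_differences(a)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return UNDEFINED
    return (pi - S / a1) / math.sqrt(var)


def log_stirling_first_unsigned(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n by the additive recurrence, in log space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    prev = np.full(2, -np.inf)
    prev[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        cur = np.full(m + 2, -np.inf)
        # |s(m+1,k)| = m·|s(m,k)| + |s(m,k-1)|
        cur[1 : m + 1] = np.logaddexp(math.log(m) + prev[1 : m + 1], prev[0:m])
        cur[m + 1] = prev[m]
        prev = cur
    return prev


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k), k = 1..n, under the Ewens sampling formula at θ."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    log_s = log_stirling_first_unsigned(n)[1:]
    k = np.arange(1, n + 1)
    log_num = log_s + k * math.log(theta)
    log_den = sum(math.log(theta + i) for i in range(n))
    p = np.exp(log_num - log_den)
    return p / p.sum()  # guard rounding


def fus_fs(a: Alignment, haplotypes: HaplotypeSet | None = None) -> float:
    """Fu's Fs: log-odds of seeing ≥ k_obs haplotypes under Ewens at θ̂ = π.

    θ̂ is the mean number of pairwise differences (per locus). Returns NaN when
    π = 0 and +inf (deficit of haplotypes is maximal evidence *against*
    expansion) when the exceedance probability S′ = 1 exactly, i.e. k_obs = 1.
    Strongly negative Fs indicates an excess of haplotypes (expansion).
    """
    h = haplotypes if haplotypes is not None else collapse_haplotypes(a)
    n = a.n
    theta = mean_pairwise_differences(a)
    if theta <= 0:
        return UNDEFINED
    k_obs = h.n_haplotypes
    p = ewens_k_distribution(n, theta)
    s_prime = float(p[k_obs - 1 :].sum())
    if s_prime >= 1.0:
        return float("inf")
    if s_prime <= 0.0:
        return float("-inf")
    return math.log(s_prime / (1.0 - s_prime))


def neutrality_summary(a: Alignment) -> NeutralityResult:
    h = collapse_haplotypes(a)
    return NeutralityResult(
        n=a.n,
        S=segregating_sites(a),
        pi_per_site=nucleotide_diversity(a),
        pi_per_locus=mean_pairwise_differences(a),
        haplotype_diversity=haplotype_diversity(h),
        tajimas_d=tajimas_d(a),
        fus_fs=fus_fs(a, h),
    )


# ---------------------------------------------------------------------------
# distances


def _gamma_correct(p_expr: float, alpha: float) -> float:
    """Replace −ln(w) by α(w^{−1/α} − 1) for gamma-distributed rates."""
    return alpha * (p_expr ** (-1.0 / alpha) - 1.0)


def pairwise_distance(a: Alignment, cfg: DistanceModelConfig | None = None) -> np.ndarray:
    """Symmetric pairwise distance matrix under the configured model.

    Entries where the model's formula leaves its domain (e.g. p ≥ 3/4 under
    JC69) are NaN. With complete deletion, columns containing any N/- are
    removed once for all pairs.
    """
    cfg = cfg or DistanceModelConfig()
    x = _encode(a)
    if not cfg.pairwise_deletion:
        keep = (x < 4).all(axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed all columns")
        x = x[:, keep]
    n = x.shape[0]
    D = np.zeros((n, n))
    if cfg.model in ("p", "JC69"):
        Dc, V = _pairwise_counts(x)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(V > 0, Dc / np.maximum(V, 1), np.nan)
        if cfg.model == "p":
            D = P
        else:
            w = 1.0 - 4.0 * P / 3.0
            with np.errstate(invalid="ignore", divide="ignore"):
                if cfg.gamma_alpha is None:
                    D = np.where(w > 0, -0.75 * np.log(np.maximum(w, 1e-300)), np.nan)
                else:
                    al = cfg.gamma_alpha
                    D = np.where(
                        w > 0,
                        0.75 * al * (np.maximum(w, 1e-300) ** (-1.0 / al) - 1.0),
                        np.nan,
                    )
        np.fill_diagonal(D, 0.0)
        return D
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _tn93_distance(x[i], x[j], cfg.gamma_alpha)
    return D


def _tn93_distance(x1: np.ndarray, x2: np.ndarray, alpha: float | None) -> float:
    """Tamura–Nei (1993) distance from one encoded sequence pair.

    Base frequencies are averaged over both sequences at comparable sites;
    transitions are split into purine (A↔G) and pyrimidine (C↔T) classes.
    """
    ok = (x1 < 4) & (x2 < 4)
    L = int(ok.sum())
    if L == 0:
        return UNDEFINED
    a, b = x1[ok], x2[ok]
    diff = a != b
    lo = np.minimum(a, b)[diff]
    hi = np.maximum(a, b)[diff]
    # encoding: A=0, C=1, G=2, T=3
    p1 = int(np.sum((lo == 0) & (hi == 2)))  # A<->G
    p2 = int(np.sum((lo == 1) & (hi == 3)))  # C<->T
    q = int(diff.sum()) - p1 - p2
    counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    gA, gC, gG, gT = counts / (2.0 * L)
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / L, p2 / L, q / L
    if gR <= 0 or gY <= 0:
        return UNDEFINED
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR) if k1 > 0 else 1.0
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY) if k2 > 0 else 1.0
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return UNDEFINED
    if alpha is None:
        d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    else:
        d = (
            k1 * _gamma_correct(w1, alpha)
            + k2 * _gamma_correct(w2, alpha)
            + k3 * _gamma_correct(w3, alpha)
        )
    return max(d, 0.0)


# ---------------------------------------------------------------------------
# AMOVA


def _amova_components(
    d2: np.ndarray,
    pop_of: np.ndarray,
    group_of_pop: np.ndarray,
) -> tuple[tuple[float, float, float], tuple[int, int, int], tuple[float, float, float]]:
    """Excoffier sums-of-squares decomposition from a squared-distance matrix.

    pop_of: population index per individual; group_of_pop: group index per
    population. Returns (σ²_a, σ²_b, σ²_c), dfs, SSs.
    """
    n_total = len(pop_of)
    n_pops = int(group_of_pop.shape[0])
    groups = np.unique(group_of_pop)
    n_groups = len(groups)

    def ss_within(idx: np.ndarray) -> float:
        if len(idx) == 0:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return float(np.sum(np.triu(sub, 1))) / len(idx)

    all_idx = np.arange(n_total)
    ss_total = ss_within(all_idx)
    pop_sizes = np.array([np.sum(pop_of == p) for p in range(n_pops)], dtype=float)
    ss_wp = sum(ss_within(np.flatnonzero(pop_of == p)) for p in range(n_pops))
    ss_groups = 0.0
    for g in groups:
        idx = np.flatnonzero(group_of_pop[pop_of] == g)
        ss_groups += ss_within(idx)
    ss_ag = ss_total - ss_groups
    ss_ap_wg = ss_groups - ss_wp

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_total - n_pops

    group_sizes = np.array(
        [pop_sizes[group_of_pop == g].sum() for g in groups], dtype=float
    )
    sum_np2_over_ng = sum(
        float(np.sum(pop_sizes[group_of_pop == g] ** 2)) / group_sizes[i]
        for i, g in enumerate(groups)
    )
    n_prime = (n_total - sum_np2_over_ng) / df_ap if df_ap > 0 else 0.0
    n_dprime = (
        (sum_np2_over_ng - float(np.sum(pop_sizes**2)) / n_total) / df_ag
        if df_ag > 0
        else 0.0
    )
    n_tprime = (
        (n_total - float(np.sum(group_sizes**2)) / n_total) / df_ag
        if df_ag > 0
        else 0.0
    )

    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp
    sigma_b = (
        (ss_ap_wg / df_ap - sigma_c) / n_prime if df_ap > 0 and n_prime > 0 else 0.0
    )
    sigma_a = (
        (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
        if df_ag > 0 and n_tprime > 0
        else 0.0
    )
    return (
        (sigma_a, sigma_b, sigma_c),
        (df_ag, df_ap, df_wp),
        (ss_ag, ss_ap_wg, ss_wp),
    )


def _phis(sigma: tuple[float, float, float]) -> tuple[float, float, float]:
    sa, sb, sc = sigma
    st = sa + sb + sc
    phi_ct = sa / st if st != 0 else UNDEFINED
    phi_sc = sb / (sb + sc) if (sb + sc) != 0 else UNDEFINED
    phi_st = (sa + sb) / st if st != 0 else UNDEFINED
    return phi_ct, phi_sc, phi_st


def amova(
    dist: np.ndarray,
    ids: Sequence[str],
    structure: PopulationStructure,
    n_permutations: int = 20_000,
    seed: int | None = None,
    squared: bool = True,
    permute: tuple[str, ...] = ("phi_ct", "phi_sc", "phi_st"),
) -> AmovaResult:
    """Hierarchical AMOVA (groups ⊃ populations ⊃ individuals) with permutations.

    ``dist`` is indexed by ``ids``; entries are squared distances (Arlequin
    convention — the count of pairwise differences acts as a squared Euclidean
    distance). Pass ``squared=False`` to square the entries first.

    Permutation schemes (all one-sided, p = (b+1)/(B+1)):
    Φ_ST — individuals permuted among populations across the whole sample;
    Φ_SC — individuals permuted among populations within their group;
    Φ_CT — whole populations permuted among groups.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix does not match ids")
    d2 = dist if squared else dist**2

    pops = structure.populations
    pop_index = {p: k for k, p in enumerate(pops)}
    groups = structure.groups
    group_index = {g: k for k, g in enumerate(groups)}
    pop_of = np.array(
        [pop_index[structure.individual_population[i]] for i in ids], dtype=int
    )
    group_of_pop = np.array(
        [group_index[structure.population_group[p]] for p in pops], dtype=int
    )

    flags = []
    pop_sizes = np.bincount(pop_of, minlength=len(pops))
    if np.any(pop_sizes == 1):
        flags.append("singleton_population")
    if any(np.sum(group_of_pop == g) == 1 for g in range(len(groups))):
        flags.append("single_population_group")

    sigma, df, ss = _amova_components(d2, pop_of, group_of_pop)
    phi_ct, phi_sc, phi_st = _phis(sigma)
    total = sum(sigma)
    percent = tuple(100.0 * s / total if total != 0 else UNDEFINED for s in sigma)

    p_ct = p_sc = p_st = UNDEFINED
    if n_permutations > 0 and total != 0:
        rng = np.random.default_rng(seed)
        b_st = b_sc = b_ct = 0
        n_ok_st = n_ok_sc = n_ok_ct = 0
        for _ in range(n_permutations):
            if "phi_st" in permute:
                # Φ_ST: individuals among populations, whole sample
                perm = rng.permutation(pop_of)
                s = _amova_components(d2, perm, group_of_pop)[0]
                stat = _phis(s)[2]
                if not math.isnan(stat):
                    n_ok_st += 1
                    if stat >= phi_st - 1e-12:
                        b_st += 1
            if "phi_sc" in permute:
                # Φ_SC: individuals among populations within groups
                perm2 = pop_of.copy()
                for g in range(len(groups)):
                    mask = group_of_pop[pop_of] == g
                    perm2[mask] = rng.permutation(pop_of[mask])
                s = _amova_components(d2, perm2, group_of_pop)[0]
                stat = _phis(s)[1]
                if not math.isnan(stat):
                    n_ok_sc += 1
                    if stat >= phi_sc - 1e-12:
                        b_sc += 1
            if "phi_ct" in permute:
                # Φ_CT: whole populations among groups
                s = _amova_components(d2, pop_of, rng.permutation(group_of_pop))[0]
                stat = _phis(s)[0]
                if not math.isnan(stat):
                    n_ok_ct += 1
                    if stat >= phi_ct - 1e-12:
                        b_ct += 1
        if "phi_st" in permute:
            p_st = (b_st + 1) / (n_ok_st + 1)
        if "phi_sc" in permute:
            p_sc = (b_sc + 1) / (n_ok_sc + 1)
        if "phi_ct" in permute:
            p_ct = (b_ct + 1) / (n_ok_ct + 1)

    return AmovaResult(
        sigma2=sigma,
        percent=percent,  # type: ignore[arg-type]
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        df=df,
        ss=ss,
        p_phi_ct=p_ct,
        p_phi_sc=p_sc,
        p_phi_st=p_st,
        n_permutations=n_permutations,
        flags=tuple(flags),
    )


def indicator_distance(h: HaplotypeSet, ids: Sequence[str]) -> np.ndarray:
    """0/1 distance matrix (same haplotype or not), for frequency-only AMOVA."""
    idx = np.array([h.individual_haplotype[i] for i in ids])
    return (idx[:, None] != idx[None, :]).astype(float)


# ---------------------------------------------------------------------------
# minimum-spanning haplotype network


def hamming_distance_matrix(h: HaplotypeSet) -> np.ndarray:
    """Integer mutational-step (Hamming) distances between haplotypes."""
    k = h.n_haplotypes
    D = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d, _ = _pair_diff_valid(h.sequences[i], h.sequences[j])
            D[i, j] = D[j, i] = d
    return D


def min_spanning_network(h: HaplotypeSet) -> HaplotypeNetwork:
    """Minimum spanning tree over Hamming distances, plus alternative edges.

    Kruskal with deterministic tie-break: edges sorted by (weight, i, j).
    A non-tree edge is an alternative connection when its weight equals the
    maximum edge weight on the tree path between its endpoints.
    """
    k = h.n_haplotypes
    D = hamming_distance_matrix(h)
    edges = sorted(
        ((int(D[i, j]), i, j) for i in range(k) for j in range(i + 1, k))
    )
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[int, int, int]] = []
    rest: list[tuple[int, int, int]] = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j, w))
        else:
            rest.append((i, j, w))

    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i, j, w in tree:
        g.add_edge(i, j, weight=w)
    alt = []
    for i, j, w in rest:
        path = nx.shortest_path(g, i, j)
        mx = max(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        if w == mx:
            alt.append((i, j, w))
    return HaplotypeNetwork(
        n_nodes=k,
        frequencies=h.counts,
        edges=tuple(tree),
        alternative_edges=tuple(alt),
    )


# ---------------------------------------------------------------------------
# north/south split


def split_north_south(
    s: PopulationStructure, latitude_threshold: float = 40.0
) -> PopulationStructure:
    """Relabel groups by latitude: strictly above the threshold → "N", else "S".

    A population exactly at the threshold is southern (closed lower bound).
    """
    missing = [p for p in s.populations if p not in s.population_latitude]
    if missing:
        raise ValueError(f"missing latitude for populations: {missing}")
    new_groups = {
        p: ("N" if s.population_latitude[p] > latitude_threshold else "S")
        for p in s.populations
    }
    return PopulationStructure(
        individual_population=dict(s.individual_population),
        population_group=new_groups,
        population_latitude=dict(s.population_latitude),
        population_longitude=dict(s.population_longitude),
    )
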