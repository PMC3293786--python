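"""Synthetic haplotype samples and raster landscapes with known ground truth.

The haplotype generator draws a Kingman coalescent genealogy per population
and sprinkles infinite-sites mutations at rate θ/2 per lineage per unit of
coalescent time; a "star" genealogy mode attaches every tip directly to the
root, producing the excess of singletons (negative Tajima's D / Fu's Fs)
expected after a population expansion. Groups are separated by a fixed
number of private diagnostic columns, giving the hierarchical AMOVA a known
among-group signal.

The landscape generator builds smoothed-white-noise layers (moving-average
low pass) with a nodata border, and presences are drawn without replacement
with probability proportional to a product-Gaussian niche kernel, recording
the true optimum for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .popgen import Alignment, PopulationStructure
from .raster import PresenceSet, RasterStack

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class HaplotypeSimConfig:
    """Sampling design and mutation parameters for the haplotype simulator.

    theta is the scaled mutation rate per locus (θ = 2Nμ for mtDNA);
    divergence_mutations is the number of fixed diagnostic columns private to
    each group after the first; genealogy is "neutral-coalescent" or "star".
    """

    n_groups: int = 2
    pops_per_group: int = 2
    n_per_pop: int = 10
    theta: float = 5.0
    divergence_mutations: int = 10
    genealogy: str = "neutral-coalescent"
    seq_length: int = 600
    seed: int = 0

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.divergence_mutations > self.seq_length:
            raise ValueError("divergence_mutations cannot exceed seq_length")
        if self.genealogy not in ("neutral-coalescent", "star"):
            raise ValueError(f"unknown genealogy {self.genealogy!r}")


class _ColumnPool:
    """Distinct mutation columns drawn uniformly; exhausting them is an error."""

    def __init__(self, length: int, rng: np.random.Generator):
        self._cols = list(rng.permutation(length))

    def draw(self) -> int:
        if not self._cols:
            raise ValueError(
                "seq_length too small to hold the requested mutations "
                "(infinite-sites columns exhausted)"
            )
        return int(self._cols.pop())


def _coalescent_intervals(
    n: int, rng: np.random.Generator
) -> list[tuple[list[frozenset[int]], float]]:
    """(active lineages as tip sets, interval length) per coalescent epoch."""
    lineages: list[set[int]] = [{i} for i in range(n)]
    out = []
    k = n
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        out.append(([frozenset(s) for s in lineages], t))
        i, j = rng.choice(k, size=2, replace=False)
        merged = lineages[i] | lineages[j]
        lineages = [s for idx, s in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        k -= 1
    return out

def _mutate(
    seq_rows: np.ndarray,
    tips: frozenset[int],
    pool: _ColumnPool,
    rng: np.random.Generator,
) -> None:
    col = pool.draw()
    current = seq_rows[next(iter(tips)), col]
    alternatives = [b for b in range(4) if b != current]
    derived = alternatives[rng.integers(3)]
    seq_rows[list(tips), col] = derived


def simulate_haplotypes(
    config: HaplotypeSimConfig,
) -> tuple[Alignment, PopulationStructure]:
    """Simulate a two-level (groups ⊃ populations) haplotype sample.

    Populations within a group share the group-ancestral sequence; groups
    after the first differ from it by ``divergence_mutations`` private fixed
    columns. Within each population, mutations are Poisson(θ·ℓ/2) per branch
    of length ℓ. The star genealogy uses tip branches of length 2·a1(n)/n so
    the expected number of segregating sites matches the neutral case while
    the frequency spectrum is pushed toward singletons. Deterministic under
    the config seed.

    Populations alternate between southern (latitude 38°) and northern
    (latitude 42°) positions so a 40°N split bisects each group.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    ancestral = rng.integers(0, 4, size=L)
    pool = _ColumnPool(L, rng)

    ids: list[str] = []
    seqs: list[str] = []
    ind_pop: dict[str, str] = {}
    pop_group: dict[str, str] = {}
    pop_lat: dict[str, float] = {}
    pop_lon: dict[str, float] = {}

    for g in range(config.n_groups):
        group_anc = ancestral.copy()
        for _ in range(config.divergence_mutations if g > 0 else 0):
            col = pool.draw()
            group_anc[col] = (group_anc[col] + 1 + rng.integers(3)) % 4
        group_name = f"G{g + 1}"
        for p in range(config.pops_per_group):
            pop_name = f"{group_name}P{p + 1}"
            pop_group[pop_name] = group_name
            pop_lat[pop_name] = 38.0 if p % 2 == 0 else 42.0
            pop_lon[pop_name] = -7.0 + 2.0 * g + 0.25 * p
            n = config.n_per_pop
            rows = np.tile(group_anc, (n, 1))
            if config.theta > 0 and n > 1:
                if config.genealogy == "neutral-coalescent":
                    for lineage_sets, t in _coalescent_intervals(n, rng):
                        for tips in lineage_sets:
                            for _ in range(rng.poisson(config.theta * t / 2.0)):
                                _mutate(rows, tips, pool, rng)
                else:  # star: each tip hangs off the root
                    a1 = sum(1.0 / i for i in range(1, n))
                    tip_len = 2.0 * a1 / n
                    for tip in range(n):
                        for _ in range(rng.poisson(config.theta * tip_len / 2.0)):
                            _mutate(rows, frozenset([tip]), pool, rng)
            for i in range(n):
                ind = f"{pop_name}_{i + 1}"
                ids.append(ind)
                seqs.append("".join(_BASES[rows[i]]))
                ind_pop[ind] = pop_name

    alignment = Alignment(tuple(ids), tuple(seqs))
    structure = PopulationStructure(
        individual_population=ind_pop,
        population_group=pop_group,
        population_latitude=pop_lat,
        population_longitude=pop_lon,
    )
    return alignment, structure


# ---------------------------------------------------------------------------
# landscapes


@dataclass(frozen=True)
class LandscapeSimConfig:
    """Smoothed-noise landscape: p layers on a rows×cols grid.

    smoothness is the moving-average radius in cells (0 = white noise);
    layer_correlation optionally imposes a common pairwise Pearson r between
    layers; border_width cells around the edge are flagged nodata.
    """

    n_layers: int = 5
    rows: int = 200
    cols: int = 200
    smoothness: int = 5
    layer_correlation: float = 0.0
    border_width: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.rows < 20 or self.cols < 20:
            raise ValueError("grid must be at least 20 x 20")
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        if not (0.0 <= self.layer_correlation <= 1.0):
            raise ValueError("layer_correlation must be in [0, 1]")


def simulate_landscape(config: LandscapeSimConfig) -> RasterStack:
    """Each layer is moving-average-smoothed white noise rescaled to mean 0,
    SD 1 over valid cells; layers are independent unless a correlation is
    requested."""
    rng = np.random.default_rng(config.seed)
    p, r, c = config.n_layers, config.rows, config.cols
    raw = rng.standard_normal((p, r, c))
    if config.layer_correlation > 0:
        rho = config.layer_correlation
        corr = np.full((p, p), rho) + (1 - rho) * np.eye(p)
        # eigendecomposition square root tolerates the singular rho = 1 case
        vals, vecs = np.linalg.eigh(corr)
        root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None))) @ vecs.T
        raw = np.einsum("ij,jrc->irc", root, raw)
    if config.smoothness > 0:
        size = 2 * config.smoothness + 1
        raw = np.stack([uniform_filter(x, size=size, mode="wrap") for x in raw])
    mask = np.zeros((r, c), dtype=bool)
    b = config.border_width
    mask[b : r - b, b : c - b] = True
    data = np.empty_like(raw)
    for k in range(p):
        vals = raw[k][mask]
        data[k] = (raw[k] - vals.mean()) / vals.std()
        data[k][~mask] = np.nan
    return RasterStack(
        names=[f"env{k + 1}" for k in range(p)],
        data=data,
        mask=mask,
    )


def simulate_presences(
    stack: RasterStack,
    optimum: np.ndarray,
    breadth: np.ndarray,
    n: int,
    seed: int,
    lineage: str = "sim",
) -> PresenceSet:
    """Draw n distinct cells with probability ∝ ∏_j exp(−(x_j−o_j)²/(2 b_j²)).

    One presence per cell (sampling without replacement). The true optimum
    and breadth are recorded in the metadata for recovery tests.
    """
    optimum = np.asarray(optimum, dtype=float)
    breadth = np.asarray(breadth, dtype=float)
    if optimum.shape != (stack.n_layers,) or breadth.shape != (stack.n_layers,):
        raise ValueError("optimum/breadth must have one entry per layer")
    if np.any(breadth <= 0):
        raise ValueError("breadth must be strictly positive")
    valid_idx = np.flatnonzero(stack.mask.ravel())
    if n > len(valid_idx):
        raise ValueError(f"n={n} exceeds the {len(valid_idx)} valid cells")
    X = stack.valid_values()
    logw = -0.5 * np.sum(((X - optimum) / breadth) ** 2, axis=1)
    rng = np.random.default_rng(seed)
    # Gumbel top-k: equivalent to sequential weighted sampling without
    # replacement, and gives common-random-number pairing across scenarios
    # that share a seed (the Gumbel field depends on the seed only)
    gumbel = rng.gumbel(size=len(valid_idx))
    chosen = np.argsort(logw + gumbel)[::-1][:n]
    flat = valid_idx[chosen]
    rows, cols = np.unravel_index(flat, stack.shape)
    cells = list(zip(rows.tolist(), cols.tolist()))
    coords = [stack.center_of(r_, c_) for r_, c_ in cells]
    return PresenceSet(
        lineage=lineage,
        cells=cells,
        coordinates=coords,
        metadata={"true_optimum": optimum.tolist(), "true_breadth": breadth.tolist()},
    )


def simulate_lineage_scenario(
    mode: str,
    stack: RasterStack,
    n_per_lineage: int,
    seed: int,
    breadth: float = 0.35,
    background_breadth: float = 3.0,
    n_niche_axes: int = 2,
    base_marginality: float = 1.0,
    offset: float = 3.0,
) -> tuple[PresenceSet, PresenceSet]:
    """Paired presence sets under a conserved or divergent niche scenario.

    Both lineages are specialists on the first ``n_niche_axes`` layers
    (niche breadth ``breadth`` global SDs there, ``background_breadth``
    elsewhere), so most of the extractable variation is concentrated in the
    leading factors, and both share a marginal optimum ``base_marginality``
    SDs from the global mean on layer 1. Under "conserved" the optima
    coincide; under "divergent" they are separated by offset × breadth along
    the diagonal of the specialist layers. The two lineages sample
    independently (seeds ``seed`` and ``seed + 1``).
    """
    if mode not in ("conserved", "divergent"):
        raise ValueError(f"unknown scenario mode {mode!r}")
    p = stack.n_layers
    if p < n_niche_axes:
        raise ValueError("stack has fewer layers than niche axes")
    b = np.full(p, background_breadth)
    b[:n_niche_axes] = breadth
    base = np.zeros(p)
    base[0] = base_marginality
    if mode == "conserved":
        opt_a = opt_b = base
    else:
        delta = np.zeros(p)
        delta[:n_niche_axes] = offset * breadth / (2.0 * np.sqrt(n_niche_axes))
        opt_a, opt_b = base - delta, base + delta
    pa = simulate_presences(stack, opt_a, b, n_per_lineage, seed, lineage="A")
    pb = simulate_presences(stack, opt_b, b, n_per_lineage, seed + 1, lineage="B")
    return pa, pb
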