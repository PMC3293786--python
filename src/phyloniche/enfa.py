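"""Ecological Niche Factor Analysis (ENFA) for presence-only modelling.

ENFA contrasts the environmental conditions at a taxon's presence cells with
the conditions over the whole study area. In the standardized (z-score)
environmental space it extracts:

* one **marginality axis** — the direction from the global mean environment
  to the presence mean ``m``; the overall marginality ``M = ||m|| / 1.96``
  is ~1 when the taxon's optimum sits 1.96 global SDs from the global mean;
* ``p − 1`` **specialization axes** — directions maximizing the ratio of
  global to presence variance, orthogonal to the marginality direction in
  the presence-covariance metric. Their eigenvalues λ measure how much
  narrower than the background the niche is along each axis (λ ≈ 1 means
  no specialization).

Habitat suitability (HS, 0–100) is computed with the median algorithm: a
cell scores high on a factor when many presence cells lie as far or farther
from the presence median on the same side.

Covariances use the population denominator n (matching the z-space
standardization); a small ridge is always added to the presence covariance
before inversion and is reported in the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .raster import PresenceSet, RasterStack


@dataclass
class BoxCoxParams:
    name: str
    lam: float
    shift: float
    constant: bool = False


def boxcox_transform(stack: RasterStack) -> tuple[RasterStack, list[BoxCoxParams]]:
    """Per-layer maximum-likelihood Box-Cox transform over masked cells.

    Layers with non-positive values are shifted by (1 − min) first. Constant
    layers are returned unchanged and flagged.
    """
    out = stack.data.copy()
    params: list[BoxCoxParams] = []
    for k, name in enumerate(stack.names):
        vals = stack.data[k][stack.mask]
        if np.ptp(vals) == 0:
            warnings.warn(f"layer {name!r} is constant; Box-Cox skipped")
            params.append(BoxCoxParams(name, 1.0, 0.0, constant=True))
            continue
        shift = 1.0 - vals.min() if vals.min() <= 0 else 0.0
        transformed, lam = sps.boxcox(vals + shift)
        out[k][stack.mask] = transformed
        params.append(BoxCoxParams(name, float(lam), float(shift)))
    return (
        RasterStack(
            names=list(stack.names), data=out, mask=stack.mask.copy(),
            cellsize=stack.cellsize, xllcorner=stack.xllcorner,
            yllcorner=stack.yllcorner, units=dict(stack.units),
        ),
        params,
    )


def collinearity_filter(
    stack: RasterStack, r_threshold: float = 0.90
) -> tuple[RasterStack, list[tuple[str, str, float]]]:
    """Greedy collinearity pruning in input order.

    A layer is dropped when its |Pearson r| with any already-retained layer
    exceeds the threshold. Returns the reduced stack and the dropped
    (dropped_layer, correlated_with, r) report.
    """
    vals = stack.valid_values()
    retained: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(stack.n_layers):
        hit = None
        for i in retained:
            r = float(np.corrcoef(vals[:, i], vals[:, j])[0, 1])
            if abs(r) > r_threshold:
                hit = (stack.names[j], stack.names[i], r)
                break
        if hit is None:
            retained.append(j)
        else:
            dropped.append(hit)
    return stack.select([stack.names[i] for i in retained]), dropped


# ---------------------------------------------------------------------------
# model


@dataclass
class EnfaModel:
    """Fitted ENFA factorization.

    axes: (p, p) matrix, columns are unit-norm factor axes in z-space with
    column 0 the marginality direction; eigenvalues[k] is the specialization
    along axes[:, k] (index 0 = yᵀWy for the marginality axis); retained is
    the broken-stick selection (always includes 0).
    """

    layer_names: list[str]
    global_mean: np.ndarray
    global_sd: np.ndarray
    marginality_vector: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray
    retained: list[int]
    presence_scores: np.ndarray
    presence_weights: np.ndarray
    ridge: float
    global_covariance: np.ndarray | None = None
    presence_covariance: np.ndarray | None = None
    flags: tuple[str, ...] = ()

    @property
    def p(self) -> int:
        return len(self.layer_names)

    @property
    def marginality(self) -> float:
        """Overall marginality M = ||m|| / 1.96."""
        return float(np.linalg.norm(self.marginality_vector)) / 1.96


@dataclass
class SuitabilityMap:
    """HS grid on [0, 100]; NaN outside the valid mask."""

    hs: np.ndarray
    mask: np.ndarray
    factor_weights: dict[int, float]
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0


@dataclass
class BinaryMap:
    suitable: np.ndarray
    mask: np.ndarray
    threshold: float
    rule: str = "minimum-training-presence"

    @property
    def area(self) -> int:
        """Number of suitable cells."""
        return int(self.suitable.sum())


def _sym_inv_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if np.any(vals <= 0):
        raise np.linalg.LinAlgError("matrix not positive definite")
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude coefficient of each axis positive."""
    out = axes.copy()
    for k in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, k])))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def fit_enfa(
    stack: RasterStack, pres: PresenceSet, ridge: float = 1e-8
) -> EnfaModel:
    """Fit the ENFA factorization of presence vs. global environment.

    Steps: z-standardize with global (masked-cell) mean/SD; presence mean m
    (weighted); global and presence covariances R_g, R_s (population
    denominator, ridge added to R_s); W = R_s^{-1/2} R_g R_s^{-1/2};
    y ∝ R_s^{-1/2} m; specialization axes are eigenvectors of
    (I − yyᵀ) W (I − yyᵀ) back-transformed by R_s^{-1/2}; the marginality
    axis is m/||m|| with specialization yᵀWy.
    """
    pres.validate_against(stack)
    X = stack.valid_values()  # (n_cells, p)
    p = stack.n_layers
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population denominator
    if np.any(sd == 0):
        bad = [stack.names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant layers cannot enter ENFA: {bad}")
    Z = (X - mean) / sd

    w = pres.weights / pres.weights.sum()
    Zp = (stack.values_at(pres.cells) - mean) / sd
    m = w @ Zp

    Rg = np.cov(Z, rowvar=False, bias=True)
    Rg = np.atleast_2d(Rg)
    centered = Zp - m
    Rs = (centered * w[:, None]).T @ centered
    Rs = np.atleast_2d(Rs)
    if np.trace(Rs) < 1e-12:
        raise ValueError(
            "presence cells are environmentally identical: presence covariance "
            "is singular beyond the ridge"
        )
    Rs = Rs + ridge * np.eye(p)

    Rs_inv_half = _sym_inv_sqrt(Rs)
    W = Rs_inv_half @ Rg @ Rs_inv_half

    flags: list[str] = []
    norm_m = float(np.linalg.norm(m))
    if norm_m < 1e-12:
        flags.append("zero_marginality")
        axis1 = np.zeros(p)
        axis1[0] = 1.0
        y = Rs_inv_half @ axis1
    else:
        axis1 = m / norm_m
        y = Rs_inv_half @ m
    y = y / np.linalg.norm(y)

    proj = np.eye(p) - np.outer(y, y)
    H = proj @ W @ proj
    vals, vecs = np.linalg.eigh(H)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # H has rank ≤ p − 1: the direction y carries a structurally zero
    # eigenvalue, dropped by keeping the p − 1 largest
    spec_vals = vals[: p - 1]
    spec_vecs = vecs[:, : p - 1]
    spec_axes = Rs_inv_half @ spec_vecs
    norms = np.linalg.norm(spec_axes, axis=0)
    spec_axes = spec_axes / norms

    lam1 = float(y @ W @ y)
    axes = np.column_stack([axis1, spec_axes])
    axes = _fix_signs(axes)
    eigenvalues = np.concatenate([[lam1], np.maximum(spec_vals, 0.0)])

    presence_scores = Zp @ axes
    retained = broken_stick_retention(eigenvalues)

    return EnfaModel(
        layer_names=list(stack.names),
        global_mean=mean,
        global_sd=sd,
        marginality_vector=m,
        axes=axes,
        eigenvalues=eigenvalues,
        retained=retained,
        presence_scores=presence_scores,
        presence_weights=pres.weights.copy(),
        ridge=ridge,
        global_covariance=Rg,
        presence_covariance=Rs,
        flags=tuple(flags),
    )


def broken_stick_values(p: int) -> np.ndarray:
    """MacArthur broken-stick expected proportions b_k = (1/p) Σ_{i=k}^p 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_retention(eigenvalues: np.ndarray) -> list[int]:
    """Indices of factors whose eigenvalue share exceeds the broken stick.

    Strict inequality; the marginality factor (index 0) is always retained.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    total = lam.sum()
    if total <= 0:
        return [0]
    b = broken_stick_values(p)
    props = lam / total
    retained = [k for k in range(p) if props[k] > b[k]]
    if 0 not in retained:
        retained = [0] + retained
    return retained


def factor_scores(model: EnfaModel, values: np.ndarray) -> np.ndarray:
    """Project raw layer values (n, p) onto the model's factor axes."""
    z = (np.asarray(values, dtype=float) - model.global_mean) / model.global_sd
    return z @ model.axes


def _median_algorithm_h(
    presence: np.ndarray, cells: np.ndarray
) -> np.ndarray:
    """Per-cell suitability on one factor by the median algorithm.

    H = min(1, 2·#{presences on the cell's side of the presence median, at
    least as far from it}/N). Cells at the median score 1; cells beyond all
    presences score 0.
    """
    med = float(np.median(presence))
    n = len(presence)
    dev_p = presence - med
    dev_c = cells - med
    h = np.zeros(len(cells))
    for side in (-1.0, 1.0):
        p_side = np.sort(np.abs(dev_p[np.sign(dev_p) == side]))
        sel = np.sign(dev_c) == side
        if not np.any(sel):
            continue
        absdev = np.abs(dev_c[sel])
        count = len(p_side) - np.searchsorted(p_side, absdev, side="left")
        h[sel] = 2.0 * count / n
    h[dev_c == 0] = 1.0
    return np.minimum(h, 1.0)


def habitat_suitability(
    model: EnfaModel,
    stack: RasterStack,
    weights: str = "eigenvalue",
) -> SuitabilityMap:
    """HS map (0–100): eigenvalue-weighted mean of per-factor median-algorithm
    scores over the retained factors.

    ``weights``: "eigenvalue" (w_k = λ_k, marginality axis included) or
    "equal".
    """
    if not model.retained:
        raise ValueError("model has no retained factors")
    if weights == "eigenvalue":
        w = {k: float(model.eigenvalues[k]) for k in model.retained}
        if sum(w.values()) <= 0:
            w = {k: 1.0 for k in model.retained}
    elif weights == "equal":
        w = {k: 1.0 for k in model.retained}
    else:
        raise ValueError(f"unknown weighting scheme {weights!r}")

    cell_scores = factor_scores(model, stack.valid_values())
    total = sum(w.values())
    hs_valid = np.zeros(cell_scores.shape[0])
    for k in model.retained:
        h = _median_algorithm_h(model.presence_scores[:, k], cell_scores[:, k])
        hs_valid += w[k] * h
    hs_valid = np.clip(100.0 * hs_valid / total, 0.0, 100.0)

    hs = np.full(stack.shape, np.nan)
    hs[stack.mask] = hs_valid
    return SuitabilityMap(
        hs=hs, mask=stack.mask.copy(), factor_weights=w,
        cellsize=stack.cellsize, xllcorner=stack.xllcorner,
        yllcorner=stack.yllcorner,
    )


def suitability_at(
    model: EnfaModel,
    stack: RasterStack,
    cells: list[tuple[int, int]],
    weights: str = "eigenvalue",
) -> np.ndarray:
    """HS evaluated only at the given cells (no full map)."""
    if weights == "eigenvalue":
        w = {k: float(model.eigenvalues[k]) for k in model.retained}
        if sum(w.values()) <= 0:
            w = {k: 1.0 for k in model.retained}
    else:
        w = {k: 1.0 for k in model.retained}
    scores = factor_scores(model, stack.values_at(cells))
    total = sum(w.values())
    hs = np.zeros(len(cells))
    for k in model.retained:
        hs += w[k] * _median_algorithm_h(model.presence_scores[:, k], scores[:, k])
    return np.clip(100.0 * hs / total, 0.0, 100.0)


def binarize(hs_map: SuitabilityMap, pres: PresenceSet) -> BinaryMap:
    """Threshold at the minimum training presence.

    Suitable ⇔ HS ≥ t and HS > 0, with t the lowest HS among the taxon's own
    presence cells; the HS > 0 guard reproduces the "scores bigger than zero"
    reading when t = 0.
    """
    rows = np.array([c[0] for c in pres.cells])
    cols = np.array([c[1] for c in pres.cells])
    hs_pres = hs_map.hs[rows, cols]
    if np.any(np.isnan(hs_pres)):
        raise ValueError("presence cell has no HS value (outside mask?)")
    t = float(hs_pres.min())
    with np.errstate(invalid="ignore"):
        suitable = (hs_map.hs >= t) & (hs_map.hs > 0) & hs_map.mask
    return BinaryMap(suitable=suitable, mask=hs_map.mask.copy(), threshold=t)


def predictor_relevance(model: EnfaModel, top_k: int = 2) -> dict[str, float]:
    """Per-predictor max |axis coefficient| over the top_k leading factors.

    Factor order: marginality first, then specialization by decreasing
    eigenvalue (the model's column order).
    """
    if top_k > model.p:
        raise ValueError(f"top_k={top_k} exceeds the number of factors {model.p}")
    coef = np.abs(model.axes[:, :top_k])
    scores = coef.max(axis=1)
    return dict(zip(model.layer_names, map(float, scores)))


def variance_captured(model: EnfaModel, k: int = 2) -> float:
    """Percentage of explained variation in the first k factors (λ shares,
    marginality axis included)."""
    lam = model.eigenvalues
    total = float(lam.sum())
    if total <= 0:
        return 100.0
    return 100.0 * float(lam[:k].sum()) / total
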