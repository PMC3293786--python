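"""Niche-divergence assessment and model evaluation.

Implements the evaluation and divergence suite around presence-only niche
models: omission error against independent presences, leave-one-out
(jackknife) population representativeness, interpredictivity across
lineages, lumped-vs-split model overprediction and false-positive rates,
binary-map overlap, minimum-convex-polygon contact zones, and per-predictor
environmental ANOVAs.

Conventions that the source method leaves open are explicit and recorded in
the result objects: overprediction is normalized by the split-union area,
overlap by the union, and each model is binarized with its own
minimum-training-presence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from . import stats as pstats
from .enfa import BinaryMap, EnfaModel, binarize, fit_enfa, habitat_suitability, suitability_at
from .raster import PresenceSet, RasterStack

NAN = float("nan")


# ---------------------------------------------------------------------------
# evaluation


def omission_error(bin_map: BinaryMap, presences: PresenceSet) -> float:
    """% of independent presence cells predicted unsuitable."""
    if presences.n == 0:
        raise ValueError("empty presence set")
    rows = np.array([c[0] for c in presences.cells])
    cols = np.array([c[1] for c in presences.cells])
    missed = np.sum(~bin_map.suitable[rows, cols])
    return 100.0 * float(missed) / presences.n


@dataclass
class JackknifeReport:
    """Leave-one-population-out proportional prediction differences.

    differences[lineage] aligns with the lineage's presence cells; the
    ANOVA compares per-lineage mean differences (sampling-bias check).
    """

    differences: dict[str, np.ndarray]
    lineage_means: dict[str, float]
    anova: pstats.AnovaResult | None


def jackknife_representativeness(
    stack: RasterStack,
    presence_sets: Mapping[str, PresenceSet],
    ridge: float = 1e-8,
    weights: str = "eigenvalue",
) -> JackknifeReport:
    """For each population (presence record): refit the lineage model without
    it and evaluate (HS_full − HS_reduced)/HS_full at that population's cell.

    HS_full = 0 at an evaluation cell yields NaN (undefined) for that
    population. Lineages need ≥3 populations.
    """
    diffs: dict[str, np.ndarray] = {}
    for lineage, pres in presence_sets.items():
        if pres.n < 3:
            raise ValueError(f"lineage {lineage!r} has fewer than 3 populations")
        model_full = fit_enfa(stack, pres, ridge=ridge)
        hs_full = suitability_at(model_full, stack, pres.cells, weights=weights)
        out = np.empty(pres.n)
        for i in range(pres.n):
            reduced = PresenceSet(
                lineage=pres.lineage,
                cells=[c for j, c in enumerate(pres.cells) if j != i],
                weights=np.delete(pres.weights, i),
            )
            model_red = fit_enfa(stack, reduced, ridge=ridge)
            hs_red = suitability_at(model_red, stack, [pres.cells[i]], weights=weights)[0]
            out[i] = (
                (hs_full[i] - hs_red) / hs_full[i] if hs_full[i] != 0 else NAN
            )
        diffs[lineage] = out
    means = {k: float(np.nanmean(v)) for k, v in diffs.items()}
    anova = None
    groups = [v[~np.isnan(v)] for v in diffs.values()]
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        anova = pstats.one_way_anova(groups)
    return JackknifeReport(differences=diffs, lineage_means=means, anova=anova)


# ---------------------------------------------------------------------------
# interpredictivity


@dataclass
class InterpredictivityResult:
    """HS of one lineage's model at every lineage's populations.

    hs_by_lineage: evaluated-lineage → HS values; angular: same after
    arcsin-sqrt transform; anova/tukey compare across evaluated lineages;
    excluded lists lineages with <2 populations (left out of the ANOVA).
    """

    model_lineage: str
    hs_by_lineage: dict[str, np.ndarray]
    angular_by_lineage: dict[str, np.ndarray]
    anova: pstats.AnovaResult | None
    tukey: pstats.TukeyResult | None
    excluded: tuple[str, ...] = ()


def interpredictivity(
    models: Mapping[str, EnfaModel],
    presence_sets: Mapping[str, PresenceSet],
    stack: RasterStack,
    weights: str = "eigenvalue",
) -> dict[str, InterpredictivityResult]:
    """Cross-prediction matrix: each lineage's model scored at all lineages'
    population cells, compared by one-way ANOVA on angularly transformed HS
    with Tukey HSD post-hoc tests."""
    if len(presence_sets) < 2:
        raise ValueError("need at least 2 lineages")
    out: dict[str, InterpredictivityResult] = {}
    for model_lineage, model in models.items():
        hs_by = {
            lin: suitability_at(model, stack, pres.cells, weights=weights)
            for lin, pres in presence_sets.items()
        }
        ang_by = {lin: np.asarray(pstats.angular_transform(v)) for lin, v in hs_by.items()}
        usable = {lin: v for lin, v in ang_by.items() if len(v) >= 2}
        excluded = tuple(sorted(set(ang_by) - set(usable)))
        anova = tukey = None
        if len(usable) >= 2:
            labels = list(usable)
            groups = [usable[l] for l in labels]
            anova = pstats.one_way_anova(groups)
            if all(len(g) >= 2 for g in groups):
                tukey = pstats.tukey_hsd(groups, labels)
        out[model_lineage] = InterpredictivityResult(
            model_lineage=model_lineage,
            hs_by_lineage=hs_by,
            angular_by_lineage=ang_by,
            anova=anova,
            tukey=tukey,
            excluded=excluded,
        )
    return out


# ---------------------------------------------------------------------------
# lumped vs split


@dataclass
class LumpedSplitResult:
    """Lumped-vs-split comparison for one lineage pair.

    Areas are suitable-cell counts. overprediction_pct =
    100·(area_lumped − area_split_union)/area_split_union. FPRs (in %) need a
    reference truth grid; fpr_difference = FPR_lumped − FPR_split_union.
    """

    pair: tuple[str, str]
    area_lumped: int
    area_split_a: int
    area_split_b: int
    area_split_union: int
    overprediction_pct: float
    fpr_lumped: float = NAN
    fpr_split_union: float = NAN
    fpr_difference: float = NAN
    denominator: str = "split-union"


def _false_positive_rate(
    suitable: np.ndarray,
    truth_presence: np.ndarray,
    mask: np.ndarray,
    exclusion: np.ndarray | None = None,
) -> float:
    """100 · (suitable ∩ true-absence) / true-absence, over valid cells.

    ``exclusion`` removes cells from the evaluation (e.g. reference records
    inside the other lineage's MCP)."""
    consider = mask.copy()
    if exclusion is not None:
        consider &= ~exclusion
    absence = consider & ~truth_presence
    n_abs = int(absence.sum())
    if n_abs == 0:
        return NAN
    return 100.0 * float(np.sum(suitable & absence)) / n_abs


def lumped_split_overprediction(
    stack: RasterStack,
    pres_a: PresenceSet,
    pres_b: PresenceSet,
    reference_truth: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
    ridge: float = 1e-8,
    weights: str = "eigenvalue",
) -> LumpedSplitResult:
    """Fit split models on each lineage and a lumped model on the pooled
    presences; binarize each at its own minimum training presence; compare
    predicted areas and (optionally) false-positive rates against a truth
    presence/absence grid."""
    def _bin(pres: PresenceSet) -> BinaryMap:
        model = fit_enfa(stack, pres, ridge=ridge)
        return binarize(habitat_suitability(model, stack, weights=weights), pres)

    lumped_pres = PresenceSet(
        lineage=f"{pres_a.lineage}+{pres_b.lineage}",
        cells=list(pres_a.cells) + [c for c in pres_b.cells if c not in set(pres_a.cells)],
    )
    bin_a = _bin(pres_a)
    bin_b = _bin(pres_b)
    bin_l = _bin(lumped_pres)
    union = bin_a.suitable | bin_b.suitable
    area_union = int(union.sum())
    over = (
        100.0 * (bin_l.area - area_union) / area_union if area_union > 0 else NAN
    )
    fpr_l = fpr_u = fpr_diff = NAN
    if reference_truth is not None:
        truth = np.asarray(reference_truth, dtype=bool)
        if truth.shape != stack.shape:
            raise ValueError("reference truth grid shape mismatch")
        fpr_l = _false_positive_rate(bin_l.suitable, truth, stack.mask, exclusion_mask)
        fpr_u = _false_positive_rate(union, truth, stack.mask, exclusion_mask)
        fpr_diff = fpr_l - fpr_u
    return LumpedSplitResult(
        pair=(pres_a.lineage, pres_b.lineage),
        area_lumped=bin_l.area,
        area_split_a=bin_a.area,
        area_split_b=bin_b.area,
        area_split_union=area_union,
        overprediction_pct=over,
        fpr_lumped=fpr_l,
        fpr_split_union=fpr_u,
        fpr_difference=fpr_diff,
    )


def summarize_lumped_split(
    overprediction: Mapping[frozenset, float],
    fpr_difference: Mapping[frozenset, float] | None = None,
) -> pd.DataFrame:
    """Per-lineage aggregation of pairwise lumped-vs-split results.

    For each lineage: the mean % overprediction over the pairs containing it,
    and the excess of that mean over the remaining pair's value (defined when
    exactly one pair omits the lineage, i.e. for three lineages); same
    aggregation for false-positive-rate differences.
    """
    pairs = list(overprediction)
    if len(pairs) < 2:
        raise ValueError("need at least 2 lineage pairs")
    lineages = sorted(set().union(*pairs))
    rows = []
    for lin in lineages:
        containing = [p for p in pairs if lin in p]
        others = [p for p in pairs if lin not in p]
        mean_over = float(np.mean([overprediction[p] for p in containing]))
        excess = (
            mean_over - overprediction[others[0]] if len(others) == 1 else NAN
        )
        row = {
            "lineage": lin,
            "mean_overprediction_pct": mean_over,
            "overprediction_excess_vs_remaining_pair": excess,
        }
        if fpr_difference is not None:
            mean_fpr = float(np.mean([fpr_difference[p] for p in containing]))
            row["mean_fpr_difference"] = mean_fpr
            row["fpr_excess_vs_remaining_pair"] = (
                mean_fpr - fpr_difference[others[0]] if len(others) == 1 else NAN
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("lineage")


# ---------------------------------------------------------------------------
# overlap and contact zones


@dataclass
class OverlapResult:
    overlap_pct: float
    intersection: np.ndarray
    denominator: str
    n_intersection: int
    n_denominator: int


def suitable_overlap(
    bin_a: BinaryMap, bin_b: BinaryMap, denominator: str = "union"
) -> OverlapResult:
    """% of overlap between two binary suitability maps.

    denominator: "union" (default, symmetric), "a", "b", or "valid" (all
    valid cells). The convention is recorded in the result.
    """
    if bin_a.suitable.shape != bin_b.suitable.shape:
        raise ValueError("binary maps are on different grids")
    inter = bin_a.suitable & bin_b.suitable
    if denominator == "union":
        denom = bin_a.suitable | bin_b.suitable
    elif denominator == "a":
        denom = bin_a.suitable
    elif denominator == "b":
        denom = bin_b.suitable
    elif denominator == "valid":
        denom = bin_a.mask & bin_b.mask
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    n_den = int(denom.sum())
    pct = 100.0 * int(inter.sum()) / n_den if n_den > 0 else NAN
    return OverlapResult(
        overlap_pct=pct,
        intersection=inter,
        denominator=denominator,
        n_intersection=int(inter.sum()),
        n_denominator=n_den,
    )


@dataclass
class ContactZones:
    """Minimum convex polygons per lineage and their pairwise intersections."""

    hulls: dict[str, Polygon]
    intersections: dict[frozenset, Polygon]
    degenerate: tuple[str, ...] = ()

    def contact_area(self, a: str, b: str) -> float:
        poly = self.intersections.get(frozenset((a, b)))
        return float(poly.area) if poly is not None else 0.0


def minimum_convex_polygons(
    coordinates: Mapping[str, Sequence[tuple[float, float]]],
) -> ContactZones:
    """Convex hull of each lineage's occurrence coordinates; areas where two
    hulls overlap are potential contact zones. Lineages with <3 points or
    collinear points get a degenerate-hull flag and no polygon."""
    hulls: dict[str, Polygon] = {}
    degenerate: list[str] = []
    for lin, pts in coordinates.items():
        hull = MultiPoint(list(pts)).convex_hull
        if not isinstance(hull, Polygon) or hull.area == 0:
            degenerate.append(lin)
        else:
            hulls[lin] = hull
    inter: dict[frozenset, Polygon] = {}
    names = sorted(hulls)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x = hulls[a].intersection(hulls[b])
            if not x.is_empty and x.area > 0:
                inter[frozenset((a, b))] = x
    return ContactZones(hulls=hulls, intersections=inter, degenerate=tuple(degenerate))


# ---------------------------------------------------------------------------
# environmental ANOVAs


@dataclass
class PredictorAnova:
    predictor: str
    anova: pstats.AnovaResult | None
    contrasts: dict[tuple[str, str], float]
    contrasts_adjusted: dict[tuple[str, str], float]
    flag: str | None = None


def environment_anova(
    values: pd.DataFrame, lineage: Sequence[str]
) -> list[PredictorAnova]:
    """One-way ANOVA per environmental predictor across lineages.

    ``values``: populations × predictors; ``lineage``: label per population.
    Pairwise contrasts are Welch t-tests, Holm-adjusted across the contrasts
    of each predictor. Predictors with zero within-group variance everywhere
    are flagged rather than tested.
    """
    from scipy import stats as sps

    lineage = np.asarray(lineage)
    labels = sorted(set(lineage))
    if len(labels) < 2:
        raise ValueError("need at least 2 lineages")
    for lab in labels:
        if np.sum(lineage == lab) < 2:
            raise ValueError(f"lineage {lab!r} has fewer than 2 populations")
    out: list[PredictorAnova] = []
    for col in values.columns:
        groups = [values.loc[lineage == lab, col].to_numpy(float) for lab in labels]
        if all(np.ptp(g) == 0 for g in groups):
            out.append(
                PredictorAnova(col, None, {}, {}, flag="zero_within_group_variance")
            )
            continue
        anova = pstats.one_way_anova(groups)
        raw: dict[tuple[str, str], float] = {}
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                t = sps.ttest_ind(groups[i], groups[j], equal_var=False)
                raw[(labels[i], labels[j])] = float(t.pvalue)
        adj = dict(zip(raw, pstats.holm_adjust(list(raw.values()))))
        out.append(PredictorAnova(col, anova, raw, adj))
    return out
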