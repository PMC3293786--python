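"""Shared statistical utilities: ANOVA, Tukey HSD, Holm correction,
angular transform, Pearson chi-square."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise Tukey-HSD comparisons: (label_i, label_j) → adjusted p."""

    pairs: tuple[tuple[str, str], ...]
    p_adjusted: tuple[float, ...]
    mean_differences: tuple[float, ...]

    def p_of(self, a: str, b: str) -> float:
        for (x, y), p in zip(self.pairs, self.p_adjusted):
            if {x, y} == {a, b}:
                return p
        raise KeyError((a, b))


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over ≥2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("empty group")
    k = len(groups)
    n = sum(len(g) for g in groups)
    f, p = sps.f_oneway(*groups)
    return AnovaResult(f=float(f), df_between=k - 1, df_within=n - k, p=float(p))


def tukey_hsd(groups: Sequence[np.ndarray], labels: Sequence[str]) -> TukeyResult:
    """Tukey honestly-significant-difference post-hoc comparisons."""
    if len(groups) != len(labels):
        raise ValueError("labels must match groups")
    res = sps.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    pairs, ps, diffs = [], [], []
    means = [float(np.mean(g)) for g in groups]
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairs.append((labels[i], labels[j]))
            ps.append(float(res.pvalue[i, j]))
            diffs.append(means[i] - means[j])
    return TukeyResult(tuple(pairs), tuple(ps), tuple(diffs))


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Step-down Holm (sequential Bonferroni) adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def angular_transform(hs: np.ndarray | float) -> np.ndarray | float:
    """arcsin-square-root transform mapping percentages [0,100] → [0, π/2]."""
    x = np.asarray(hs, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("values must lie in [0, 100]")
    out = np.arcsin(np.sqrt(x / 100.0))
    return float(out) if np.isscalar(hs) else out


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray


def pearson_chi_square(table: np.ndarray) -> ChiSquareResult:
    """Pearson χ² = Σ(O−E)²/E on an r×c contingency table, df=(r−1)(c−1).

    No continuity correction. Fails loudly when any expected count is zero
    (a row or column of zeros makes the statistic undefined).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero expected counts: empty row or column")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p), expected=expected)
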