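"""Asset-based socioeconomic scoring via multiple correspondence analysis.

A household wealth score is the first dimension of a correspondence
analysis of the disjunctive (indicator) coding of categorical asset and
service variables: form the proportion matrix, remove the rank-one
expectation under row/column independence, scale by inverse square roots
of the row and column masses, and take the leading singular vector.  The
score is split into weighted tertiles (low / middle / high SES), and a
local cohort's score distribution can be projected onto the national one
by carrying the national tertile cutoffs through their percentile ranks
in a reference subset.

Convention notes: MCA itself is unweighted by default (survey weights
enter the tertile cutoffs); the score's sign is oriented so that it
correlates positively with the number of assets owned; records exactly at
a cutoff go to the lower group; weighted quantiles use the inverse of the
left-continuous weighted empirical CDF throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RARE_CATEGORY_MASS = 0.01


@dataclass
class SesAssignment:
    """Scores, tertile cutoffs and low/middle/high labels per record."""

    score: np.ndarray
    cutoffs: tuple[float, float]
    label: np.ndarray
    degenerate: bool = False


def _merge_rare_categories(col: pd.Series) -> pd.Series:
    """Merge categories with <1% mass into the nearest (sorted) neighbour.

    Applied only to variables with more than two categories; collapsing a
    binary indicator would make it constant.
    """
    counts = col.value_counts(normalize=True)
    if len(counts) <= 2 or (counts >= RARE_CATEGORY_MASS).all():
        return col
    cats = sorted(counts.index, key=str)
    mapping = {}
    for i, cat in enumerate(cats):
        if counts[cat] < RARE_CATEGORY_MASS:
            neighbours = [c for c in cats if c != cat and counts[c] >= RARE_CATEGORY_MASS]
            if not neighbours:
                return col
            j = min(
                range(len(neighbours)),
                key=lambda k: abs(cats.index(neighbours[k]) - i),
            )
            mapping[cat] = neighbours[j]
    return col.replace(mapping) if mapping else col


def mca_score(
    records: pd.DataFrame, weights: np.ndarray | None = None
) -> np.ndarray:
    """First-dimension row coordinates of the indicator-matrix CA.

    ``records`` holds categorical asset/service indicators (one column per
    item).  Optional nonnegative row weights become the row masses; by
    default all rows weigh equally.  The returned scores are centred
    (weighted mean zero) and oriented to correlate positively with the
    count of assets owned.
    """
    if records.shape[0] < 1:
        raise ValueError("empty asset matrix")
    n = records.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive total")

    cols = []
    ownership = np.zeros(n)
    for name in records.columns:
        col = _merge_rare_categories(records[name].astype(str))
        cats = sorted(col.unique())
        if len(cats) < 2:
            raise ValueError(
                f"indicator {name!r} has a single observed category; "
                "remove constant indicators before scoring"
            )
        dummies = pd.get_dummies(col)[cats].to_numpy(float)
        cols.append(dummies)
        # ordinal code of the sorted categories: monotone proxy for "owned"
        codes = {c: i for i, c in enumerate(cats)}
        ownership += col.map(codes).to_numpy(float)
    z = np.hstack(cols)
    if records.shape[0] < z.shape[1]:
        raise ValueError("fewer records than indicator categories")

    # correspondence analysis of the disjunctive matrix
    zw = z * w[:, None]
    total = zw.sum()
    p = zw / total
    r = p.sum(axis=1)  # row masses (equal when weights uniform)
    c = p.sum(axis=0)  # column masses
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, _vt = np.linalg.svd(s, full_matrices=False)
    # leading non-trivial dimension (the trivial dimension is removed by
    # the rank-one subtraction; numerical zeros may still lead)
    k = int(np.argmax(sv > 1e-12 * sv[0])) if sv[0] > 0 else 0
    # equal-inertia leading dimensions leave the axis ill-defined; break
    # the tie with the combination most correlated with asset count
    group = [k]
    for j in range(k + 1, len(sv)):
        if abs(sv[j] - sv[k]) <= 1e-9 * sv[k]:
            group.append(j)
    coords = u[:, group] * sv[group] / np.sqrt(r)[:, None]
    own_c = ownership - np.average(ownership, weights=w)
    alpha = coords.T @ (w * own_c)
    norm = np.linalg.norm(alpha)
    if norm < 1e-12 * max(np.abs(coords).max(), 1.0):
        alpha = np.zeros(len(group))
        alpha[0] = 1.0
    else:
        alpha = alpha / norm
    scores = coords @ alpha

    # orientation: positive correlation with asset-ownership count
    cov = float(np.sum(w * own_c * scores))
    if cov < 0:
        scores = -scores
    return scores


def weighted_quantile(
    values: np.ndarray, q: float, weights: np.ndarray | None = None
) -> float:
    """Cutoff convention used package-wide: the largest observed value
    whose weighted empirical CDF does not exceed q (so a record exactly
    at the cutoff falls in the lower group, and an atom carrying more
    than the remaining mass lands above it).  When even the smallest
    value exceeds rank q the returned cutoff lies strictly below the
    observed range."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cdf, q + 1e-12, side="left")) - 1
    if idx < 0:
        return float(v[0]) - max(1.0, abs(float(v[0])))
    return float(v[min(idx, len(v) - 1)])


def weighted_cdf_at(
    values: np.ndarray, x: float, weights: np.ndarray | None = None
) -> float:
    """P(X <= x) under the weighted empirical distribution."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    return float(weights[values <= x].sum() / weights.sum())


def tertile_split(
    scores: np.ndarray, weights: np.ndarray | None = None
) -> SesAssignment:
    """Split scores at the weighted 33.33rd/66.67th percentiles.

    Records with score exactly equal to a cutoff go to the lower group.
    A constant score vector yields a single (low) group flagged degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 records for a tertile split")
    c1 = weighted_quantile(scores, 1.0 / 3.0, weights)
    c2 = weighted_quantile(scores, 2.0 / 3.0, weights)
    label = np.where(scores <= c1, "low", np.where(scores <= c2, "middle", "high"))
    degenerate = bool(np.all(scores == scores[0]))
    if degenerate:
        warnings.warn("all scores identical; tertile split is degenerate")
    return SesAssignment(
        score=scores, cutoffs=(c1, c2), label=label, degenerate=degenerate
    )


def labels_from_cutoffs(scores: np.ndarray, cutoffs: tuple[float, float]) -> np.ndarray:
    c1, c2 = cutoffs
    scores = np.asarray(scores, dtype=float)
    return np.where(scores <= c1, "low", np.where(scores <= c2, "middle", "high"))


def project_cutoffs(
    reference_scores: np.ndarray,
    reference_weights: np.ndarray | None,
    national_cutoffs: tuple[float, float],
    target_scores: np.ndarray,
    target_weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Carry national tertile cutoffs onto a local score distribution.

    The national cutoffs are converted to percentile ranks within the
    reference (e.g. rural/periurban) subset of the national data, and the
    target distribution's quantiles at those ranks become the cutoffs for
    the local cohort.  Ranks are clamped to [0, 1] with a warning when a
    national cutoff lies outside the reference range.
    """
    reference_scores = np.asarray(reference_scores, dtype=float)
    if reference_scores.size == 0:
        raise ValueError("empty reference subset")
    c1, c2 = national_cutoffs
    if c2 < c1:
        raise ValueError("national cutoffs must be ordered")
    ranks = []
    for c in (c1, c2):
        rank = weighted_cdf_at(reference_scores, c, reference_weights)
        if c < reference_scores.min() or c > reference_scores.max():
            warnings.warn(
                f"national cutoff {c:g} outside reference score range; rank clamped"
            )
        ranks.append(min(max(rank, 0.0), 1.0))
    out = tuple(
        weighted_quantile(np.asarray(target_scores, float), r, target_weights)
        for r in ranks
    )
    return out  # type: ignore[return-value]
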