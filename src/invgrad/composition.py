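"""Compositional similarity across the invasion gradient.

Group-pairwise Sørensen similarity matrices and rank-based analysis of
similarity (ANOSIM) with seeded permutation inference and per-group
dissimilarity-rank summaries (the numbers behind ANOSIM boxplots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import DataModelError, GROUP_LABELS, PlotSample, StudyDataset

logger = logging.getLogger(__name__)


def sorensen(presence_a: Iterable[str], presence_b: Iterable[str]) -> float:
    """Sørensen similarity CC = 2a / (2a + b + c) on two presence sets."""
    a_set, b_set = frozenset(presence_a), frozenset(presence_b)
    if not a_set and not b_set:
        raise DataModelError("Sørensen undefined for two empty sets")
    a = len(a_set & b_set)
    b = len(a_set - b_set)
    c = len(b_set - a_set)
    return 2.0 * a / (2.0 * a + b + c)


def group_sorensen_matrix(dataset: StudyDataset) -> pd.DataFrame:
    """5x5 Sørensen matrix over pooled per-group presence sets.

    Each group's presence set is the union of species with cover > 0
    over all its plots; the diagonal is 1 by definition.
    """
    pooled: dict[str, frozenset[str]] = {}
    for g in GROUP_LABELS:
        plots = dataset.plots_in_group(g)
        present: set[str] = set()
        for p in plots:
            present.update(p.species_present())
        if not present:
            raise DataModelError(f"group {g} has an empty pooled species set")
        pooled[g] = frozenset(present)
    mat = pd.DataFrame(
        np.eye(len(GROUP_LABELS)), index=GROUP_LABELS, columns=GROUP_LABELS
    )
    for i, gi in enumerate(GROUP_LABELS):
        for gj in GROUP_LABELS[i + 1:]:
            s = sorensen(pooled[gi], pooled[gj])
            mat.loc[gi, gj] = s
            mat.loc[gj, gi] = s
    return mat


def dissimilarity_matrix(
    plots: Sequence[PlotSample], metric: str = "sorensen_binary"
) -> pd.DataFrame:
    """Plot x plot dissimilarities.

    ``sorensen_binary`` (default): 1 - Sørensen on presence sets.
    ``bray_curtis``: cover-weighted 1 - 2*sum(min)/(sum_a + sum_b).
    Plots with an empty community are excluded with a warning.
    """
    if metric not in {"sorensen_binary", "bray_curtis"}:
        raise DataModelError(f"unknown metric {metric!r}")
    kept = [p for p in plots if p.species_present()]
    dropped = [p.plot_id for p in plots if not p.species_present()]
    if dropped:
        logger.warning("excluding %d empty plot(s): %s", len(dropped), dropped)
    if len(kept) < 2:
        raise DataModelError("need at least 2 non-empty plots")
    ids = [p.plot_id for p in kept]
    n = len(kept)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "sorensen_binary":
                dij = 1.0 - sorensen(kept[i].species_present(), kept[j].species_present())
            else:
                a, b = kept[i].cover, kept[j].cover
                shared = set(a) | set(b)
                mins = sum(min(a.get(s, 0.0), b.get(s, 0.0)) for s in shared)
                tot = sum(a.values()) + sum(b.values())
                dij = 1.0 - 2.0 * mins / tot
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass(frozen=True)
class RankSummary:
    """Five-number summary of a dissimilarity-rank distribution, with
    whiskers at 1.5x IQR and points beyond flagged as outliers."""

    label: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    group_rank_summary: tuple[RankSummary, ...]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": s.label,
                    "n": s.n,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "whisker_low": s.whisker_low,
                    "whisker_high": s.whisker_high,
                    "n_outliers": len(s.outliers),
                }
                for s in self.group_rank_summary
            ]
        )


def _rank_summary(label: str, ranks: np.ndarray) -> RankSummary:
    q1, med, q3 = np.percentile(ranks, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = ranks[(ranks >= lo_fence) & (ranks <= hi_fence)]
    outliers = ranks[(ranks < lo_fence) | (ranks > hi_fence)]
    return RankSummary(
        label=label,
        n=int(ranks.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(o) for o in np.sort(outliers)),
    )


def _anosim_r(ranks_condensed: np.ndarray, same_group: np.ndarray) -> float:
    m = ranks_condensed.size
    r_within = ranks_condensed[same_group].mean()
    r_between = ranks_condensed[~same_group].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    dissim: pd.DataFrame | np.ndarray,
    groups: Mapping[str, str] | Sequence[str],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarity on a plot x plot dissimilarity matrix.

    All n(n-1)/2 dissimilarities are ranked (average ranks for ties);
    R = (mean between-group rank - mean within-group rank) / (M/2), in
    [-1, 1].  The one-sided permutation p-value uses the add-one
    convention p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations) under
    random relabelling preserving group sizes, so p >= 1/(n_perm + 1).
    """
    if isinstance(dissim, pd.DataFrame):
        labels = [groups[i] if isinstance(groups, Mapping) else groups[k]
                  for k, i in enumerate(dissim.index)]
        d = dissim.to_numpy()
    else:
        if isinstance(groups, Mapping):
            raise DataModelError("mapping groups require a labelled DataFrame")
        labels = list(groups)
        d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if len(labels) != n:
        raise DataModelError("group labels do not match matrix size")
    if n_permutations < 1:
        raise DataModelError("n_permutations must be >= 1")
    lab = np.asarray(labels)
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        raise DataModelError("need at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise DataModelError(f"group(s) {list(small)} have fewer than 2 plots")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])  # average ranks for ties
    same = lab[iu[0]] == lab[iu[1]]
    r_obs = _anosim_r(ranks, same)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, same_p) >= r_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)

    summaries = [_rank_summary("Between", ranks[~same])]
    for g in uniq:
        mask = (lab[iu[0]] == g) & (lab[iu[1]] == g)
        summaries.append(_rank_summary(str(g), ranks[mask]))
    return AnosimResult(
        r_statistic=r_obs,
        p_value=float(p),
        n_permutations=int(n_permutations),
        group_rank_summary=tuple(summaries),
    )


def anosim_study(
    dataset: StudyDataset,
    metric: str = "sorensen_binary",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> AnosimResult:
    """ANOSIM of gradient groups A-E on a study's plot dissimilarities."""
    d = dissimilarity_matrix(dataset.plots, metric=metric)
    group_of = {p.plot_id: p.group for p in dataset.plots}
    return anosim(d, group_of, n_permutations=n_permutations, seed=seed)
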