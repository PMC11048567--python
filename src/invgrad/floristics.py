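"""Per-plot and per-group floristic metrics.

Relative abundance, native richness, floristic quality index (FQI),
50/20 dominance, Rényi diversity profiles, and species accumulation
curves — the community-property summaries used to compare plot groups
along an invasion gradient.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from math import comb

from .datamodel import DataModelError, GROUP_LABELS, PlotSample, StudyDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbundanceVector:
    """Relative abundances p_i over a plot set, summing to 1."""

    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.proportions:
            raise DataModelError("empty community has no abundance vector")
        vals = list(self.proportions.values())
        if any(v < 0 for v in vals):
            raise DataModelError("relative abundances must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise DataModelError("relative abundances must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.proportions), dtype=float)


def relative_abundance(
    plots: Sequence[PlotSample], dataset: StudyDataset | None = None
) -> AbundanceVector:
    """p_i = summed cover of species i over the plots / total summed cover."""
    if not plots:
        raise DataModelError("plot set is empty")
    totals: dict[str, float] = {}
    for p in plots:
        for sp, c in p.cover.items():
            if c > 0:
                totals[sp] = totals.get(sp, 0.0) + c
    grand = sum(totals.values())
    if grand == 0:
        raise DataModelError("all covers are zero; community undefined")
    return AbundanceVector({sp: c / grand for sp, c in totals.items()})


def mean_native_richness(
    plots: Sequence[PlotSample], dataset: StudyDataset
) -> float:
    """Mean per-plot count of native species (target invader and all
    non-natives excluded; presence means cover > 0)."""
    if not plots:
        raise DataModelError("plot set is empty")
    return float(np.mean([dataset.native_richness(p) for p in plots]))


def fqi(
    plots: Sequence[PlotSample],
    dataset: StudyDataset,
    native_only: bool = True,
) -> float:
    """Floristic quality index over the pooled plot set: FQI = C̄ * sqrt(S).

    C̄ is the mean coefficient of conservatism over the S qualifying
    species present anywhere in the plot set.  With ``native_only`` (the
    default) only native species qualify; species lacking a C-value are
    excluded from both C̄ and S and logged.
    """
    present: set[str] = set()
    for p in plots:
        present.update(p.species_present())
    qualifying: list[int] = []
    skipped: list[str] = []
    for sp in sorted(present):
        attr = dataset.species[sp]
        if native_only and not attr.native:
            continue
        if attr.c_value is None:
            skipped.append(sp)
            continue
        qualifying.append(attr.c_value)
    if skipped:
        logger.info("FQI: %d species lack C-values and were excluded: %s",
                    len(skipped), ", ".join(skipped[:10]))
    if not qualifying:
        logger.warning("FQI: no qualifying species in plot set; returning 0")
        return 0.0
    s = len(qualifying)
    return float(np.mean(qualifying) * math.sqrt(s))


def mean_plot_fqi(
    plots: Sequence[PlotSample],
    dataset: StudyDataset,
    native_only: bool = True,
) -> float:
    """Mean of per-plot FQI values, the alternative to pooling.

    Pooled :func:`fqi` scores the plot set as one community; this form
    scores each plot separately and averages, so it is sensitive to
    within-plot (rather than pooled) richness.  The two agree only when
    every plot holds the same community.
    """
    if not plots:
        raise DataModelError("mean_plot_fqi needs at least one plot")
    return float(np.mean([fqi([p], dataset, native_only) for p in plots]))


def dominants_50_20(abund: AbundanceVector) -> list[str]:
    """Dominant species by the 50/20 rule.

    Species are sorted by descending relative abundance (ties broken by
    name); dominants are the minimal prefix whose cumulative abundance
    reaches 50%, plus every species with >= 20% individually.
    """
    items = sorted(abund.proportions.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[str] = []
    cum = 0.0
    for sp, p in items:
        if cum < 0.5 - 1e-12:
            out.append(sp)
            cum += p
        elif p >= 0.2 - 1e-12:
            out.append(sp)
    return out


@dataclass(frozen=True)
class RenyiProfile:
    """Rényi entropies H_alpha (natural-log units) over a set of scales.

    H_0 = ln(richness); H_1 = Shannon entropy; H_2 = -ln(Simpson
    concentration); H_inf = -ln(max p_i).  The profile is non-increasing
    in alpha, and flat exactly for a perfectly even community.
    """

    alphas: tuple[float, ...]
    values: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha": self.alphas, "H": self.values})


DEFAULT_ALPHAS: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, math.inf)


def renyi_profile(
    abund: AbundanceVector, alphas: Iterable[float] = DEFAULT_ALPHAS
) -> RenyiProfile:
    """H_alpha = ln(sum p_i^alpha) / (1 - alpha), with the closed-form
    limits at alpha = 1 (Shannon) and alpha = inf (dominance)."""
    p = np.array([v for v in abund.proportions.values() if v > 0], dtype=float)
    alphas = tuple(float(a) for a in alphas)
    values = []
    for a in alphas:
        if a < 0:
            raise DataModelError(f"Rényi scale alpha={a} must be >= 0")
        if math.isinf(a):
            values.append(float(-np.log(p.max())))
        elif a == 1.0:
            values.append(float(-np.sum(p * np.log(p))))
        else:
            values.append(float(np.log(np.sum(p**a)) / (1.0 - a)))
    return RenyiProfile(alphas=alphas, values=tuple(values))


@dataclass(frozen=True)
class AccumulationCurve:
    """Expected species richness in random subsets of 1..N plots."""

    n_plots: tuple[int, ...]
    expected_richness: tuple[float, ...]
    spread: tuple[float, ...]  # per-size standard deviation
    method: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_plots": self.n_plots,
                "expected_richness": self.expected_richness,
                "sd": self.spread,
            }
        )


def _incidence(plots: Sequence[PlotSample]) -> list[frozenset[int]]:
    """Per-species sets of occupied plot indices."""
    occ: dict[str, set[int]] = {}
    for i, p in enumerate(plots):
        for sp in p.species_present():
            occ.setdefault(sp, set()).add(i)
    return [frozenset(v) for v in occ.values()]


def species_accumulation(
    plots: Sequence[PlotSample],
    method: str = "exact",
    n_perm: int = 1000,
    seed: int | None = None,
) -> AccumulationCurve:
    """Sample-based species accumulation curve.

    ``exact`` uses the analytic mean over all equally likely subsets of
    each size (hypergeometric occupancy form), with the matching analytic
    standard deviation.  ``permutation`` estimates the same curve from
    ``n_perm`` random plot orderings (seeded), the classic randomized
    workflow.
    """
    if not plots:
        raise DataModelError("need at least one plot")
    if method not in {"exact", "permutation"}:
        raise DataModelError(f"unknown accumulation method {method!r}")
    n = len(plots)
    occ = _incidence(plots)
    sizes = tuple(range(1, n + 1))

    if method == "permutation":
        if n_perm < 1:
            raise DataModelError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        counts = np.zeros((n_perm, n))
        present = [p.species_present() for p in plots]
        for r in range(n_perm):
            order = rng.permutation(n)
            seen: set[str] = set()
            for j, idx in enumerate(order):
                seen |= present[idx]
                counts[r, j] = len(seen)
        return AccumulationCurve(
            n_plots=sizes,
            expected_richness=tuple(counts.mean(axis=0)),
            spread=tuple(counts.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n)),
            method="permutation",
        )

    # exact: P(species i absent from a size-k subset) = C(n - n_i, k)/C(n, k)
    n_i = np.array([len(s) for s in occ])
    exp_vals: list[float] = []
    sd_vals: list[float] = []
    for k in sizes:
        denom = comb(n, k)
        p_abs = np.array([comb(n - ni, k) / denom if n - ni >= k else 0.0 for ni in n_i])
        a = 1.0 - p_abs  # per-species presence probability
        mean_k = float(a.sum())
        # Var = sum a_i(1-a_i) + 2 sum_{i<j} [P(both) - a_i a_j]
        var = float(np.sum(a * (1.0 - a)))
        for i, j in itertools.combinations(range(len(occ)), 2):
            u = len(occ[i] | occ[j])
            p_none = comb(n - u, k) / denom if n - u >= k else 0.0
            p_both = 1.0 - p_abs[i] - p_abs[j] + p_none
            var += 2.0 * (p_both - a[i] * a[j])
        exp_vals.append(mean_k)
        sd_vals.append(math.sqrt(max(var, 0.0)))
    return AccumulationCurve(
        n_plots=sizes,
        expected_richness=tuple(exp_vals),
        spread=tuple(sd_vals),
        method="exact",
    )


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean_native_richness: float
    fqi: float
    invader_relabund: float  # percent


def group_summaries(
    dataset: StudyDataset,
    invaders: Iterable[str] | None = None,
    pooled_invader_abundance: bool = False,
) -> pd.DataFrame:
    """Per-group summary table (groups A-E as columns).

    Rows: mean native species richness, FQI (pooled over the group's
    plots), and mean invader relative abundance.  By default the invader
    abundance is computed per plot then averaged; ``pooled_invader_abundance``
    instead pools covers over the whole group before dividing.
    """
    names = frozenset(invaders) if invaders is not None else dataset.target_invader
    rows: dict[str, dict[str, float]] = {
        "mean_native_richness": {},
        "fqi": {},
        "invader_relabund": {},
    }
    for g in GROUP_LABELS:
        plots = dataset.plots_in_group(g)
        if not plots:
            raise DataModelError(f"group {g} has no plots")
        rows["mean_native_richness"][g] = mean_native_richness(plots, dataset)
        rows["fqi"][g] = fqi(plots, dataset)
        if pooled_invader_abundance:
            abund = relative_abundance(plots)
            rows["invader_relabund"][g] = 100.0 * sum(
                p for sp, p in abund.proportions.items() if sp in names
            )
        else:
            rows["invader_relabund"][g] = float(
                np.mean([dataset.invader_relative_abundance(p, names) for p in plots])
            )
    return pd.DataFrame(rows).T[list(GROUP_LABELS)]
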