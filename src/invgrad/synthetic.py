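"""Synthetic invasion-gradient communities.

Generates :class:`~invgrad.datamodel.StudyDataset` objects with the
statistical structure the downstream analysis assumes:

* transects of five plots spanning an invader relative-abundance
  gradient from dominant (group A, >20%) to uninvaded (group E, <5%);
* native richness that is a unimodal ("hump-shaped") function of
  invader relative abundance, peaking at moderate invasion;
* covers recorded on the modified Daubenmire class scale and averaged
  over four subplots, exactly as a field crew would record them.

The generator is the test bed for the whole pipeline: the richness hump
is planted at a known invader abundance, so the threshold-detection
procedure has a ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    GROUP_LABELS,
    CoverClassScale,
    DataModelError,
    PlotSample,
    SpeciesAttributes,
    StudyDataset,
    plot_cover_from_subplots,
)

#: Group-mean invader relative abundances (%), A..E.  Chosen inside the
#: ranges observed across target invaders in comparable field studies
#: (A roughly 48-66, B 23-44, C 3-14, D 0-3, E 0-0.4).
DEFAULT_GROUP_MEANS: dict[str, float] = {"A": 60.0, "B": 26.0, "C": 7.0, "D": 1.0, "E": 0.0}

DEFAULT_INVADER = "Invasor dominans"


@dataclass(frozen=True)
class RichnessCurve:
    """Unimodal expected native richness vs invader relative abundance.

    An offset-lognormal bump: ``floor + (peak_richness - floor) *
    exp(-(ln((x+offset)/(peak_abundance+offset)))^2 / (2*width^2))``.
    The maximum sits exactly at ``peak_abundance`` with value
    ``peak_richness``; the curve falls toward ``floor`` at heavy
    invasion and sits below the peak at zero invasion, matching the
    moderate-invasion richness hump seen on mitigation sites.
    """

    peak_abundance: float = 10.0  # x*, % relative abundance
    peak_richness: float = 12.0   # S*, species/plot at the peak
    floor: float = 3.0
    offset: float = 5.0
    width: float = 1.0

    def __call__(self, invader_relabund: float) -> float:
        if not (0.0 <= invader_relabund <= 100.0):
            raise DataModelError("invader relative abundance outside [0, 100]")
        z = math.log(
            (invader_relabund + self.offset) / (self.peak_abundance + self.offset)
        )
        return self.floor + (self.peak_richness - self.floor) * math.exp(
            -(z * z) / (2.0 * self.width**2)
        )


@dataclass(frozen=True)
class SpeciesPool:
    """Fixed pool of taxa to draw from, with a rank-lognormal abundance
    profile (common species are sampled and weighted more heavily)."""

    attributes: tuple[SpeciesAttributes, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.attributes) != len(self.weights):
            raise DataModelError("pool attributes and weights differ in length")

    @property
    def native_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes if a.native and not a.invader)

    @classmethod
    def default(
        cls,
        n_native: int = 120,
        n_nonnative: int = 8,
        invader_name: str = DEFAULT_INVADER,
        rank_sigma: float = 1.0,
        seed: int = 20240913,
    ) -> "SpeciesPool":
        """A synthetic regional flora: ``n_native`` natives with C-values
        drawn to average ~4 (typical of a mid-Atlantic flora), a handful
        of non-native non-target taxa, and one target invader."""
        rng = np.random.default_rng(seed)
        attrs: list[SpeciesAttributes] = []
        for i in range(n_native):
            attrs.append(
                SpeciesAttributes(
                    name=f"Nativus sp{i + 1:03d}",
                    native=True,
                    c_value=int(rng.binomial(10, 0.4)),
                )
            )
        for i in range(n_nonnative):
            attrs.append(
                SpeciesAttributes(name=f"Alienus sp{i + 1:02d}", native=False, c_value=0)
            )
        attrs.append(
            SpeciesAttributes(name=invader_name, native=False, c_value=0, invader=True)
        )
        # rank-lognormal weights over the whole pool (invader weight unused)
        n = len(attrs)
        quantiles = (np.arange(n) + 0.5) / n
        from scipy.stats import norm

        weights = np.exp(rank_sigma * norm.ppf(1.0 - quantiles))
        return cls(attributes=tuple(attrs), weights=tuple(float(w) for w in weights))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe the field design being emulated: >=10 five-plot
    transects, group invader abundances stepping down A->E across the
    dominant (>20%) to uninvaded (<5%) endpoints, Poisson richness noise
    around the unimodal richness curve, and multiplicative lognormal
    noise on subplot covers before Daubenmire discretization.
    """

    n_transects: int = 10
    group_invader_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS)
    )
    richness_curve: RichnessCurve = field(default_factory=RichnessCurve)
    pool: SpeciesPool = field(default_factory=SpeciesPool.default)
    abundance_cv: float = 0.3      # CV of the truncated-normal invader target draw
    cover_sigma: float = 0.4       # lognormal sigma on subplot covers
    richness_noise: bool = True    # Poisson (truncated >=1) around the curve
    #: summed raw native cover (%) on an uninvaded plot; the invader
    #: displaces cover share, so natives hold this times (100 - t)/100
    native_total_cover: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        means = [self.group_invader_mean[g] for g in GROUP_LABELS]
        if any(m2 > m1 for m1, m2 in zip(means, means[1:])):
            raise DataModelError("group invader means must be non-increasing A->E")
        if not (means[0] > 20.0):
            raise DataModelError("group A mean must exceed 20% (dominant endpoint)")
        if not (means[-1] < 5.0):
            raise DataModelError("group E mean must be below 5% (uninvaded endpoint)")
        if self.n_transects < 2:
            raise DataModelError("need at least 2 transects")

    @property
    def invader_name(self) -> str:
        for a in self.pool.attributes:
            if a.invader:
                return a.name
        raise DataModelError("pool has no invader-flagged species")


def expected_richness(invader_relabund: float, cfg: GeneratorConfig) -> float:
    """Expected native richness (species/plot) at a given invader
    relative abundance, under the configured unimodal curve."""
    return cfg.richness_curve(invader_relabund)


def _invader_subplot_midpoints(
    target_cover: float, scale: CoverClassScale
) -> tuple[int, int, int, int]:
    """Four subplot class midpoints whose mean best approximates
    ``target_cover``, using the two midpoints bracketing it.

    Field crews record whole classes per subplot; averaging four of them
    is what gives plot covers finer granularity than the class midpoints
    themselves.
    """
    if target_cover <= 0:
        return (0, 0, 0, 0)
    mids = [0, *scale.midpoints]
    hi_idx = next((i for i, m in enumerate(mids) if m >= target_cover), len(mids) - 1)
    if mids[hi_idx] == target_cover or hi_idx == 0:
        m = mids[hi_idx]
        return (m, m, m, m)
    m_lo, m_hi = mids[hi_idx - 1], mids[hi_idx]
    if target_cover > mids[-1]:
        m = mids[-1]
        return (m, m, m, m)
    n_hi = round(4.0 * (target_cover - m_lo) / (m_hi - m_lo))
    return tuple([m_hi] * n_hi + [m_lo] * (4 - n_hi))  # type: ignore[return-value]


def _draw_plot(
    cfg: GeneratorConfig,
    group: str,
    rng: np.random.Generator,
    scale: CoverClassScale,
) -> tuple[dict[str, float], float]:
    """Simulate one plot; returns (cover map, target invader relabund %)."""
    mean = float(cfg.group_invader_mean[group])
    if mean <= 0 or cfg.abundance_cv == 0:
        target = mean
    else:
        target = float(rng.normal(mean, cfg.abundance_cv * mean))
    target = min(max(target, 0.0), 95.0)

    mu = expected_richness(target, cfg)
    if cfg.richness_noise:
        k = max(1, int(rng.poisson(mu)))
    else:
        k = max(1, round(mu))
    natives = cfg.pool.native_names
    if k > len(natives):
        raise DataModelError(
            f"requested richness {k} exceeds native pool size {len(natives)}"
        )
    w = np.array(
        [cfg.pool.weights[i] for i, a in enumerate(cfg.pool.attributes)
         if a.native and not a.invader]
    )
    chosen_idx = rng.choice(len(natives), size=k, replace=False, p=w / w.sum())
    chosen = [natives[i] for i in chosen_idx]
    raw = w[chosen_idx]
    native_budget = cfg.native_total_cover * (100.0 - target) / 100.0
    raw = native_budget * raw / raw.sum()

    # natives: noisy raw subplot covers, snapped to Daubenmire midpoints
    subplots: list[dict[str, float]] = [dict() for _ in range(4)]
    for sp, c in zip(chosen, raw):
        for sub in subplots:
            if cfg.cover_sigma > 0:
                noise = rng.lognormal(-0.5 * cfg.cover_sigma**2, cfg.cover_sigma)
            else:
                noise = 1.0
            sub[sp] = float(scale.snap(min(c * noise, 100.0)))
    cover = plot_cover_from_subplots(subplots)

    # invader: subplot classes matched to the post-discretization native
    # total so the realized relative abundance tracks the target
    if target > 0:
        c_nat = sum(cover.values())
        desired = target / (100.0 - target) * c_nat
        mids = _invader_subplot_midpoints(min(desired, 98.0), scale)
        inv_cover = sum(mids) / 4.0
        if inv_cover > 0:
            cover[cfg.invader_name] = inv_cover
    return cover, target


def generate_transect(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    transect_id: str = "T01",
    scale: CoverClassScale | None = None,
) -> tuple[PlotSample, ...]:
    """Five plots A-E along one transect of the invasion gradient."""
    scale = scale or CoverClassScale.modified_daubenmire()
    plots = []
    for group in GROUP_LABELS:
        cover, _ = _draw_plot(cfg, group, rng, scale)
        plots.append(
            PlotSample(
                plot_id=f"{transect_id}-{group}",
                transect_id=transect_id,
                group=group,
                cover=cover,
            )
        )
    return tuple(plots)


def generate_study(cfg: GeneratorConfig) -> StudyDataset:
    """A full synthetic study: ``n_transects`` transects x 5 plots.

    A single seed drives a splittable per-transect stream, so increasing
    ``n_transects`` extends the study without reshuffling earlier
    transects.
    """
    scale = CoverClassScale.modified_daubenmire()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_transects)
    plots: list[PlotSample] = []
    for t, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        tid = f"T{t + 1:02d}"
        plots.extend(generate_transect(cfg, rng, transect_id=tid, scale=scale))
    species = {a.name: a for a in cfg.pool.attributes}
    return StudyDataset(
        plots=tuple(plots),
        species=species,
        target_invader=frozenset({cfg.invader_name}),
    )
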