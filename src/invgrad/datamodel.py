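"""Core data model for invasion-gradient vegetation studies.

A study samples vegetation along transects that span an invasion
gradient.  Each transect carries five plots labelled A (completely
invaded, >20% relative cover of the target invader) through E
(uninvaded, <5%).  Cover of every species is recorded in a modified
Daubenmire cover-class scale in four 1 m^2 subplots per plot; the class
midpoints, averaged over the four subplots, are the per-plot cover
values used in all downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

GROUP_LABELS = ("A", "B", "C", "D", "E")


class DataModelError(ValueError):
    """Raised when an input violates a structural or domain invariant."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CoverClassScale:
    """An ordered, contiguous cover-class scale over [0, 100]%.

    Each class is a ``(lower, upper, midpoint)`` triple.  The midpoint is
    the arithmetic mean of the bounds rounded half-up to the nearest whole
    integer, e.g. the 25-50% class has midpoint 38.  Classes are half-open
    ``(lower, upper]`` except the first, which is closed at 0, so a value
    on a shared boundary belongs to the class it terminates; each class
    midpoint therefore maps back to its own class.
    """

    classes: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise DataModelError("scale needs at least one class")
        prev_upper = 0.0
        prev_mid = -1
        for lo, hi, mid in self.classes:
            if lo != prev_upper:
                raise DataModelError(
                    f"classes must tile [0,100] contiguously; gap at {lo}"
                )
            if hi <= lo:
                raise DataModelError(f"empty class ({lo}, {hi})")
            if mid != _round_half_up((lo + hi) / 2.0):
                raise DataModelError(
                    f"midpoint {mid} is not round((lo+hi)/2) for ({lo}, {hi})"
                )
            if mid <= prev_mid:
                raise DataModelError("midpoints must strictly increase")
            prev_upper, prev_mid = hi, mid
        if prev_upper != 100.0:
            raise DataModelError("scale must end at 100%")

    @classmethod
    def from_bounds(cls, bounds: Sequence[tuple[float, float]]) -> "CoverClassScale":
        """Build a scale from (lower, upper) pairs; midpoints are derived."""
        return cls(
            tuple((lo, hi, _round_half_up((lo + hi) / 2.0)) for lo, hi in bounds)
        )

    @classmethod
    def modified_daubenmire(cls) -> "CoverClassScale":
        """The seven-class modified Daubenmire scale used in wetland and
        stream monitoring: 0-1, 1-5, 5-25, 25-50, 50-75, 75-95, 95-100%,
        with integer midpoints 1, 3, 15, 38, 63, 85, 98."""
        return cls.from_bounds(
            [(0, 1), (1, 5), (5, 25), (25, 50), (50, 75), (75, 95), (95, 100)]
        )

    @property
    def midpoints(self) -> tuple[int, ...]:
        return tuple(mid for _, _, mid in self.classes)

    def class_of(self, cover_value: float) -> int:
        """Index of the class containing ``cover_value``.

        A boundary value belongs to the lower of the two classes sharing
        it (intervals are (lower, upper]; the first includes 0), so 1%
        falls in the 0-1% class and 100% in the last class.
        """
        if not (0.0 <= cover_value <= 100.0):
            raise DataModelError(f"cover value {cover_value} outside [0, 100]")
        for i, (lo, hi, _) in enumerate(self.classes):
            if lo < cover_value <= hi:
                return i
        return 0  # cover_value == 0

    def midpoint_of(self, class_index: int) -> int:
        if not (0 <= class_index < len(self.classes)):
            raise DataModelError(f"no cover class with index {class_index}")
        return self.classes[class_index][2]

    def snap(self, cover_value: float) -> int:
        """Midpoint of the class containing ``cover_value`` (field recording)."""
        return self.midpoint_of(self.class_of(cover_value))


def cover_class_of(cover_value: float, scale: CoverClassScale | None = None) -> int:
    scale = scale or CoverClassScale.modified_daubenmire()
    return scale.class_of(cover_value)


def midpoint_of(class_index: int, scale: CoverClassScale | None = None) -> int:
    scale = scale or CoverClassScale.modified_daubenmire()
    return scale.midpoint_of(class_index)


def plot_cover_from_subplots(
    subplot_covers: Sequence[Mapping[str, float]],
) -> dict[str, float]:
    """Average four subplot class-midpoint maps into one per-plot cover map.

    A species absent from a subplot contributes 0 to its mean, so a
    species present in one subplot at midpoint 38 has plot cover 9.5.
    """
    if len(subplot_covers) != 4:
        raise DataModelError(
            f"expected exactly 4 subplot cover maps, got {len(subplot_covers)}"
        )
    species: set[str] = set()
    for sub in subplot_covers:
        species.update(sub)
    out: dict[str, float] = {}
    for sp in species:
        total = sum(sub.get(sp, 0.0) for sub in subplot_covers)
        if total > 0:
            out[sp] = total / 4.0
    return out


@dataclass(frozen=True)
class SpeciesAttributes:
    """Floristic attributes of one taxon.

    ``c_value`` is the coefficient of conservatism (0-10, or None when the
    regional flora assigns none).  ``invader`` marks membership in the
    study's target-invader set; a species may be native yet regulated as
    invasive (e.g. Typha spp. on mitigation sites), so ``invader`` does not
    imply ``native`` is False.
    """

    name: str
    native: bool
    c_value: int | None = None
    invader: bool = False

    def __post_init__(self) -> None:
        if self.c_value is not None and not (0 <= self.c_value <= 10):
            raise DataModelError(
                f"{self.name}: C-value {self.c_value} outside [0, 10]"
            )


@dataclass(frozen=True)
class PlotSample:
    """One 4 m^2 plot: subplot-averaged midpoint cover per species.

    Cover values are percentages and need not sum to 100 (canopies
    overlap).  ``group`` is the plot's position on the invasion gradient.
    """

    plot_id: str
    transect_id: str
    group: str
    cover: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise DataModelError(
                f"plot {self.plot_id}: group {self.group!r} not in {GROUP_LABELS}"
            )
        for sp, c in self.cover.items():
            if c < 0:
                raise DataModelError(f"plot {self.plot_id}: negative cover for {sp}")

    @property
    def total_cover(self) -> float:
        return float(sum(self.cover.values()))

    def species_present(self) -> frozenset[str]:
        return frozenset(sp for sp, c in self.cover.items() if c > 0)


@dataclass(frozen=True)
class StudyDataset:
    """A complete study: plots, species attributes, and the target invader(s).

    ``target_invader`` is a set of species names because aggregated genera
    (e.g. the Typha complex) are analyzed as one taxon set.
    """

    plots: tuple[PlotSample, ...]
    species: Mapping[str, SpeciesAttributes]
    target_invader: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "plots", tuple(self.plots))
        object.__setattr__(self, "target_invader", frozenset(self.target_invader))
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        by_transect: dict[str, list[str]] = {}
        for p in self.plots:
            key = (p.transect_id, p.plot_id)
            if key in seen:
                raise DataModelError(f"duplicate plot id {p.plot_id} on {p.transect_id}")
            seen.add(key)
            by_transect.setdefault(p.transect_id, []).append(p.group)
            for sp in p.cover:
                if sp not in self.species:
                    raise DataModelError(
                        f"species {sp!r} in plot {p.plot_id} has no attributes row"
                    )
        for tid, groups in by_transect.items():
            if sorted(groups) != list(GROUP_LABELS):
                raise DataModelError(
                    f"transect {tid} does not have exactly one plot per group "
                    f"A-E (found {sorted(groups)})"
                )
        for inv in self.target_invader:
            if inv not in self.species:
                raise DataModelError(f"target invader {inv!r} not in attributes")
            if not self.species[inv].invader:
                raise DataModelError(f"target invader {inv!r} lacks invader flag")

    # ---- convenience accessors used throughout the pipeline ----

    @property
    def transect_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.plots:
            seen.setdefault(p.transect_id)
        return tuple(seen)

    @property
    def n_transects(self) -> int:
        return len(self.transect_ids)

    def plots_in_group(self, group: str) -> tuple[PlotSample, ...]:
        if group not in GROUP_LABELS:
            raise DataModelError(f"unknown group {group!r}")
        return tuple(p for p in self.plots if p.group == group)

    def is_native(self, name: str) -> bool:
        return self.species[name].native

    def native_richness(self, plot: PlotSample) -> int:
        """Count of native, non-invader species with cover > 0 in the plot."""
        return sum(
            1
            for sp, c in plot.cover.items()
            if c > 0 and self.species[sp].native and not self.species[sp].invader
        )

    def invader_relative_abundance(
        self, plot: PlotSample, invaders: Iterable[str] | None = None
    ) -> float:
        """Invader cover as a percentage of the plot's total cover.

        Returns 0 for a plot where the invader is absent; a plot with no
        vegetation at all also scores 0 (nothing to invade).
        """
        names = frozenset(invaders) if invaders is not None else self.target_invader
        total = plot.total_cover
        if total == 0:
            return 0.0
        inv = sum(c for sp, c in plot.cover.items() if sp in names)
        return 100.0 * inv / total

    def with_plots(self, plots: Iterable[PlotSample]) -> "StudyDataset":
        return replace(self, plots=tuple(plots))
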