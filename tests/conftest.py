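"""Shared fixtures: small hand-built studies and the default synthetic study."""

from __future__ import annotations

import pytest

from invgrad import (
    GeneratorConfig,
    PlotSample,
    SpeciesAttributes,
    StudyDataset,
    generate_study,
)
from invgrad.datamodel import GROUP_LABELS

INVADER = "Invader alpha"


def make_attributes(names, *, natives=None, c_values=None, invaders=(INVADER,)):
    natives = natives or {}
    c_values = c_values or {}
    return {
        n: SpeciesAttributes(
            name=n,
            native=natives.get(n, n != INVADER),
            c_value=c_values.get(n, 4),
            invader=n in invaders,
        )
        for n in names
    }


def make_dataset(plot_covers, *, natives=None, c_values=None, invaders=(INVADER,)):
    """Build a 1..k-transect dataset from a list of per-transect dicts
    mapping group label -> cover map."""
    plots = []
    names: set[str] = set()
    for t, groups in enumerate(plot_covers):
        tid = f"T{t + 1:02d}"
        for g in GROUP_LABELS:
            cover = groups.get(g, {})
            names.update(cover)
            plots.append(
                PlotSample(plot_id=f"{tid}-{g}", transect_id=tid, group=g, cover=cover)
            )
    names.update(invaders)
    species = make_attributes(sorted(names), natives=natives, c_values=c_values,
                              invaders=invaders)
    return StudyDataset(plots=tuple(plots), species=species,
                        target_invader=frozenset(invaders))


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: 10 transects, planted richness peak."""
    return generate_study(GeneratorConfig(n_transects=10, seed=42))


@pytest.fixture()
def tiny_dataset():
    """One transect, a handful of species, invader declining A -> E."""
    return make_dataset(
        [
            {
                "A": {INVADER: 63.0, "sp1": 15.0, "sp2": 3.0},
                "B": {INVADER: 15.0, "sp1": 15.0, "sp2": 15.0, "sp3": 3.0},
                "C": {INVADER: 3.0, "sp1": 15.0, "sp2": 15.0, "sp3": 15.0, "sp4": 3.0},
                "D": {INVADER: 1.0, "sp1": 15.0, "sp2": 15.0, "sp3": 3.0},
                "E": {"sp1": 15.0, "sp2": 15.0, "sp3": 3.0},
            }
        ]
    )
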