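"""Readers and writers for community and species-attribute tables.

Canonical on-disk form is a pair of UTF-8 comma-delimited files:

* community table, long form: ``plot_id, transect_id, group, species,
  cover_pct`` (one row per plot x species occurrence).  A wide form with
  the first three columns ``plot_id, transect_id, group`` and one column
  per species is accepted read-only.
* attributes table: ``species, native, c_value, invader`` with blank
  ``c_value`` for taxa lacking a coefficient of conservatism.

An optional config (YAML mapping or dict) may supply species aliases
(e.g. folding the Typha complex into one analysis taxon) and the target
invader name(s).
"""

from __future__ import annotations

import math
from os import PathLike
from typing import Any, Mapping

import pandas as pd
import yaml

from .datamodel import (
    DataModelError,
    PlotSample,
    SpeciesAttributes,
    StudyDataset,
)

LONG_COLUMNS = ["plot_id", "transect_id", "group", "species", "cover_pct"]
META_COLUMNS = ["plot_id", "transect_id", "group"]


def load_config(source: str | PathLike | Mapping[str, Any] | None) -> dict[str, Any]:
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    with open(source, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise DataModelError("config must be a mapping")
    return loaded


def _parse_bool(value: Any, context: str) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "t", "yes", "1"}:
        return True
    if s in {"false", "f", "no", "0"}:
        return False
    raise DataModelError(f"{context}: cannot parse boolean from {value!r}")


def read_attributes(path: str | PathLike) -> dict[str, SpeciesAttributes]:
    df = pd.read_csv(path, dtype={"species": str})
    missing = {"species", "native", "invader"} - set(df.columns)
    if missing:
        raise DataModelError(f"attributes table missing columns {sorted(missing)}")
    out: dict[str, SpeciesAttributes] = {}
    for i, row in df.iterrows():
        name = str(row["species"]).strip()
        if name in out:
            raise DataModelError(f"duplicate attributes row for species {name!r}")
        c_raw = row.get("c_value")
        if c_raw is None or (isinstance(c_raw, float) and math.isnan(c_raw)):
            c_value = None
        else:
            c_value = int(c_raw)
        out[name] = SpeciesAttributes(
            name=name,
            native=_parse_bool(row["native"], f"attributes row {i}"),
            c_value=c_value,
            invader=_parse_bool(row["invader"], f"attributes row {i}"),
        )
    return out


def _community_long(df: pd.DataFrame, aliases: Mapping[str, str]) -> pd.DataFrame:
    df = df.copy()
    df["species"] = df["species"].map(lambda s: aliases.get(s, s))
    bad = df[pd.to_numeric(df["cover_pct"], errors="coerce").isna()]
    if len(bad):
        raise DataModelError(
            f"non-numeric cover at row(s) {list(bad.index[:5])} of community table"
        )
    df["cover_pct"] = df["cover_pct"].astype(float)
    # aliased taxa may now collide within a plot: covers add
    df = (
        df.groupby(["plot_id", "transect_id", "group", "species"], as_index=False, sort=False)
        .agg(cover_pct=("cover_pct", "sum"))
    )
    return df[LONG_COLUMNS]


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    species_cols = [c for c in df.columns if c not in META_COLUMNS]
    long = df.melt(
        id_vars=META_COLUMNS, value_vars=species_cols,
        var_name="species", value_name="cover_pct",
    )
    long["cover_pct"] = pd.to_numeric(long["cover_pct"], errors="coerce").fillna(0.0)
    return long[long["cover_pct"] > 0].reset_index(drop=True)


def read_study(
    community_path: str | PathLike,
    attributes_path: str | PathLike,
    config: str | PathLike | Mapping[str, Any] | None = None,
) -> StudyDataset:
    """Read and validate a study from community + attributes tables.

    The community table's shape (long vs wide) is detected from its
    header.  Unknown species, duplicate (plot, species) rows, and
    transects missing a gradient label all raise :class:`DataModelError`.
    """
    cfg = load_config(config)
    aliases: dict[str, str] = dict(cfg.get("aliases", {}))

    df = pd.read_csv(community_path, dtype={"plot_id": str, "transect_id": str})
    if set(LONG_COLUMNS).issubset(df.columns):
        dup = df.duplicated(subset=["plot_id", "species"], keep=False)
        if dup.any():
            first = df[dup].iloc[0]
            raise DataModelError(
                f"duplicate row for plot {first['plot_id']!r} / "
                f"species {first['species']!r}"
            )
        long = _community_long(df[LONG_COLUMNS], aliases)
    elif set(META_COLUMNS).issubset(df.columns):
        long = _community_long(_wide_to_long(df), aliases)
    else:
        raise DataModelError(
            "community table must be long (plot_id, transect_id, group, species,"
            " cover_pct) or wide (plot_id, transect_id, group, <species...>)"
        )

    species = read_attributes(attributes_path)
    for old, new in aliases.items():
        if old in species and new not in species:
            species[new] = SpeciesAttributes(
                name=new,
                native=species[old].native,
                c_value=species[old].c_value,
                invader=species[old].invader,
            )
        species.pop(old, None)

    plots: list[PlotSample] = []
    meta = long[META_COLUMNS].drop_duplicates()
    grouped = dict(list(long.groupby("plot_id", sort=False)))
    for _, row in meta.iterrows():
        sub = grouped[row["plot_id"]]
        cover = dict(zip(sub["species"], sub["cover_pct"]))
        plots.append(
            PlotSample(
                plot_id=str(row["plot_id"]),
                transect_id=str(row["transect_id"]),
                group=str(row["group"]),
                cover=cover,
            )
        )

    target = cfg.get("target_invader")
    if target is None:
        invaders = frozenset(n for n, a in species.items() if a.invader)
    elif isinstance(target, str):
        invaders = frozenset({aliases.get(target, target)})
    else:
        invaders = frozenset(aliases.get(t, t) for t in target)
    return StudyDataset(plots=tuple(plots), species=species, target_invader=invaders)


def write_study(
    dataset: StudyDataset,
    community_path: str | PathLike,
    attributes_path: str | PathLike,
) -> None:
    """Write a dataset to the canonical long-form community + attributes CSVs."""
    rows = [
        {
            "plot_id": p.plot_id,
            "transect_id": p.transect_id,
            "group": p.group,
            "species": sp,
            "cover_pct": c,
        }
        for p in dataset.plots
        for sp, c in sorted(p.cover.items())
        if c > 0
    ]
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(community_path, index=False)

    attr_rows = [
        {
            "species": a.name,
            "native": a.native,
            "c_value": "" if a.c_value is None else a.c_value,
            "invader": a.invader,
        }
        for a in sorted(dataset.species.values(), key=lambda a: a.name)
    ]
    pd.DataFrame(attr_rows, columns=["species", "native", "c_value", "invader"]).to_csv(
        attributes_path, index=False
    )
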