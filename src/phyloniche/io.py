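"""File formats: FASTA alignments, structure/presence CSV, JSON reports.

All readers validate eagerly and raise with file context; writers
round-trip (read ∘ write = identity on content). Raster I/O lives in
:mod:`phyloniche.raster`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .popgen import Alignment, PopulationStructure
from .raster import PresenceSet, RasterStack


def read_fasta(path: str | Path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    try:
        return Alignment.from_pairs((r.id, str(r.seq)) for r in records)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_fasta(path: str | Path, alignment: Alignment) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(alignment.ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


STRUCTURE_COLUMNS = ["individual", "population", "group", "lat", "lon"]


def read_structure_csv(path: str | Path) -> PopulationStructure:
    """CSV columns: individual, population, group, lat, lon (lat/lon optional)."""
    df = pd.read_csv(path)
    for col in ("individual", "population", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    ind_pop = dict(zip(df["individual"].astype(str), df["population"].astype(str)))
    if len(ind_pop) != len(df):
        raise ValueError(f"{path}: duplicate individual ids")
    pop_rows = df.drop_duplicates("population")
    pop_group = dict(zip(pop_rows["population"].astype(str), pop_rows["group"].astype(str)))
    conflicting = (
        df.groupby("population")["group"].nunique(dropna=False).loc[lambda s: s > 1]
    )
    if len(conflicting):
        raise ValueError(
            f"{path}: populations in more than one group: {list(conflicting.index)}"
        )
    lat = lon = {}
    if "lat" in df.columns:
        lat = dict(zip(pop_rows["population"].astype(str), pop_rows["lat"].astype(float)))
    if "lon" in df.columns:
        lon = dict(zip(pop_rows["population"].astype(str), pop_rows["lon"].astype(float)))
    return PopulationStructure(ind_pop, pop_group, lat, lon)


def write_structure_csv(path: str | Path, s: PopulationStructure) -> None:
    rows = []
    for ind, pop in s.individual_population.items():
        rows.append(
            {
                "individual": ind,
                "population": pop,
                "group": s.population_group[pop],
                "lat": s.population_latitude.get(pop, ""),
                "lon": s.population_longitude.get(pop, ""),
            }
        )
    pd.DataFrame(rows, columns=STRUCTURE_COLUMNS).to_csv(path, index=False)


def read_presence_csv(
    path: str | Path, stack: RasterStack
) -> dict[str, PresenceSet]:
    """CSV columns: id, lineage, x, y[, population]; returns one PresenceSet
    per lineage with coordinates resolved to grid cells."""
    df = pd.read_csv(path)
    for col in ("id", "lineage", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: dict[str, PresenceSet] = {}
    for lineage, sub in df.groupby("lineage", sort=False):
        cells, coords = [], []
        for _, row in sub.iterrows():
            x, y = float(row["x"]), float(row["y"])
            try:
                cells.append(stack.cell_of(x, y))
            except ValueError as e:
                raise ValueError(f"{path}: record {row['id']!r}: {e}") from e
            coords.append((x, y))
        out[str(lineage)] = PresenceSet(
            lineage=str(lineage), cells=cells, coordinates=coords
        )
    return out


def write_presence_csv(
    path: str | Path, presence_sets: Mapping[str, PresenceSet]
) -> None:
    rows = []
    for lineage, pres in presence_sets.items():
        coords = pres.coordinates or [(float(c[1]), float(c[0])) for c in pres.cells]
        for k, (x, y) in enumerate(coords):
            rows.append({"id": f"{lineage}_{k + 1}", "lineage": lineage, "x": x, "y": y})
    pd.DataFrame(rows, columns=["id", "lineage", "x", "y"]).to_csv(path, index=False)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_report(path: str | Path, report: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_ReportEncoder)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
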