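"""Station-wise mean degree centrality and grid aggregation.

Degree centrality of a species is its total number of feeding links
(prey + predators) in the meta-web. For a survey station, the mean degree
of the species recorded there (restricted to a focal taxon list, e.g.
fish) summarizes how generalist the local community is; aggregating the
station values on a regular km grid yields the spatial degree field.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FoodWeb, SpeciesSet

EARTH_RADIUS_KM = 6371.0


@dataclass
class Station:
    station: str
    lon: float
    lat: float
    species: set[str] = field(default_factory=set)


@dataclass
class StationTable:
    stations: list[Station]

    def __len__(self):
        return len(self.stations)

    @classmethod
    def read_csv(cls, path: str | Path) -> "StationTable":
        """Long-format CSV: header ``station,lon,lat,species``."""
        by_id: dict[str, Station] = {}
        with Path(path).open(newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                sid = row["station"].strip()
                st = by_id.setdefault(
                    sid, Station(sid, float(row["lon"]), float(row["lat"]))
                )
                if row["species"].strip():
                    st.species.add(row["species"].strip())
        return cls(list(by_id.values()))

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["station", "lon", "lat", "species"])
            for st in self.stations:
                for sp in sorted(st.species):
                    writer.writerow([st.station, st.lon, st.lat, sp])


@dataclass
class DegreeField:
    """Per-cell mean of station values on a regular km grid.

    Cells with no stations are absent from the table (missing, never 0).
    """

    cell_km: float
    cells: pd.DataFrame  # columns: x_km, y_km, mean_value, n_stations
    origin_lon: float
    origin_lat: float


def station_mean_degree(
    stations: StationTable,
    meta: FoodWeb,
    taxa_filter: SpeciesSet | None = None,
) -> dict[str, float]:
    """Mean meta-web degree of the focal species present at each station.

    Stations with no qualifying species map to NaN; species unknown to the
    meta-web are excluded with a warning.
    """
    focal = set(taxa_filter.members) if taxa_filter is not None else meta.nodes
    unknown = focal - meta.nodes
    if unknown:
        raise ValueError(f"taxa filter not in meta-web: {sorted(unknown)}")
    degree = {sp: meta.degree_of(sp) for sp in focal}
    out: dict[str, float] = {}
    for st in stations.stations:
        strange = st.species - meta.nodes
        if strange:
            warnings.warn(
                f"station {st.station}: unknown species excluded: {sorted(strange)}"
            )
        present = (st.species & focal) - strange
        out[st.station] = (
            float(np.mean([degree[sp] for sp in present])) if present else float("nan")
        )
    return out


def grid_aggregate(
    stations: StationTable,
    values: dict[str, float],
    cell_km: float = 50.0,
) -> DegreeField:
    """Aggregate station values on a regular ``cell_km`` x ``cell_km`` grid.

    Coordinates are projected to km with a local equirectangular projection
    about the stations' centroid; each occupied cell carries the mean of
    the station values inside it (NaN station values are dropped first).
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    usable = sorted(
        (
            st for st in stations.stations
            if st.station in values and math.isfinite(values[st.station])
        ),
        key=lambda st: st.station,
    )
    lon0 = float(np.mean([st.lon for st in usable])) if usable else 0.0
    lat0 = float(np.mean([st.lat for st in usable])) if usable else 0.0
    coslat = math.cos(math.radians(lat0))
    pts = []
    for st in usable:
        x = EARTH_RADIUS_KM * math.radians(st.lon - lon0) * coslat
        y = EARTH_RADIUS_KM * math.radians(st.lat - lat0)
        pts.append((x, y, values[st.station]))
    # grid anchored at the minimum coordinates (order-independent)
    if pts:
        xmin = min(p[0] for p in pts)
        ymin = min(p[1] for p in pts)
        rows = [
            (math.floor((x - xmin) / cell_km), math.floor((y - ymin) / cell_km), v)
            for x, y, v in pts
        ]
        df = pd.DataFrame(rows, columns=["ix", "iy", "value"])
        agg = (
            df.groupby(["ix", "iy"])["value"]
            .agg(["mean", "count"])
            .reset_index()
            .rename(columns={"mean": "mean_value", "count": "n_stations"})
        )
        agg["x_km"] = xmin + (agg.pop("ix") + 0.5) * cell_km
        agg["y_km"] = ymin + (agg.pop("iy") + 0.5) * cell_km
        agg = agg[["x_km", "y_km", "mean_value", "n_stations"]].sort_values(
            ["x_km", "y_km"], ignore_index=True
        )
    else:
        agg = pd.DataFrame(columns=["x_km", "y_km", "mean_value", "n_stations"])
    return DegreeField(cell_km=cell_km, cells=agg, origin_lon=lon0, origin_lat=lat0)
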