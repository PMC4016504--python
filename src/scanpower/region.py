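"""Study regions, spatial units and circular cluster collections.

A study region is a set of spatial units (SUs) — ZIP-code-like areas — each
carrying a projected planar centroid and an at-risk population (e.g. mean
annual live births).  Simulated "true" clusters are built exhaustively: every
SU is in turn the center of one approximately circular cluster made of that
SU and its ``s - 1`` nearest neighbors by Euclidean centroid distance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "SpatialUnit",
    "Region",
    "Cluster",
    "load_region",
    "build_cluster_collection",
    "cluster_population",
    "export_cluster_collection",
]


@dataclass(frozen=True)
class SpatialUnit:
    """One spatial unit: identifier, planar centroid and at-risk population."""

    su_id: str
    x: float
    y: float
    population: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"SU {self.su_id!r}: centroid coordinates must be finite")
        if not np.isfinite(self.population) or self.population < 0:
            raise ValueError(f"SU {self.su_id!r}: population must be finite and >= 0")


class Region:
    """An ordered collection of spatial units.

    Units are stored sorted by ``su_id`` so that identical inputs always
    yield the identical region, whatever the input row order.  Optional
    shapely geometries (one polygon per SU, same order) are kept for
    choropleth rendering and GeoJSON export.
    """

    def __init__(
        self,
        units: Iterable[SpatialUnit],
        geometries: Mapping[str, BaseGeometry] | None = None,
    ) -> None:
        units = sorted(units, key=lambda u: u.su_id)
        ids = [u.su_id for u in units]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate su_id(s): {dup}")
        if len(units) < 2:
            raise ValueError("a region needs at least 2 spatial units")
        self.units: tuple[SpatialUnit, ...] = tuple(units)
        self.su_ids: tuple[str, ...] = tuple(ids)
        self._index = {sid: k for k, sid in enumerate(self.su_ids)}
        self.centroids = np.array([[u.x, u.y] for u in units], dtype=float)
        self.populations = np.array([u.population for u in units], dtype=float)
        if self.populations.sum() <= 0:
            raise ValueError("total population must be > 0")
        self.geometries: tuple[BaseGeometry, ...] | None = None
        if geometries is not None:
            missing = set(self.su_ids) - set(geometries)
            if missing:
                raise ValueError(f"geometries missing for SU(s): {sorted(missing)}")
            self.geometries = tuple(geometries[sid] for sid in self.su_ids)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def total_population(self) -> float:
        return float(self.populations.sum())

    def index(self, su_id: str) -> int:
        try:
            return self._index[su_id]
        except KeyError:
            raise KeyError(f"unknown su_id {su_id!r}") from None

    def neighbor_order(self, center: int) -> np.ndarray:
        """Indices of all SUs ordered by increasing distance from ``center``.

        The center itself comes first (distance 0).  Distance ties are broken
        by ascending ``su_id`` — a documented, deterministic rule.
        """
        d = np.linalg.norm(self.centroids - self.centroids[center], axis=1)
        # lexsort's last key is primary: distance first, then su_id rank
        return np.lexsort((np.arange(self.n_units), d))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_field: str = "su_id") -> "Region":
        req = {id_field, "x", "y", "population"}
        if not req <= set(df.columns):
            raise ValueError(f"dataframe must have columns {sorted(req)}")
        units = [
            SpatialUnit(str(r[id_field]), float(r["x"]), float(r["y"]), float(r["population"]))
            for _, r in df.iterrows()
        ]
        return cls(units)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "su_id": self.su_ids,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "population": self.populations,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Region(n_units={self.n_units}, total_population={self.total_population:g})"


@dataclass(frozen=True)
class Cluster:
    """A simulated true cluster: a center SU plus its nearest neighbors."""

    center_su: str
    members: frozenset[str]
    size: int
    population: float = field(compare=False, default=0.0)

    def __post_init__(self) -> None:
        if len(self.members) != self.size:
            raise ValueError("cluster size must equal the number of members")
        if self.center_su not in self.members:
            raise ValueError("cluster center must be a member")


def _looks_geographic(coords: np.ndarray) -> bool:
    """Heuristic: coordinates that all fit in lon/lat ranges are suspect."""
    x, y = coords[:, 0], coords[:, 1]
    return bool(np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0))


def _read_population_table(population_table, id_field: str) -> dict[str, float]:
    if isinstance(population_table, pd.DataFrame):
        df = population_table
    else:
        df = pd.read_csv(population_table, dtype={id_field: str})
    if id_field not in df.columns or "population" not in df.columns:
        raise ValueError(f"population table needs columns {id_field!r} and 'population'")
    ids = df[id_field].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate population record(s) for su_id(s): {sorted(set(dup))}")
    return dict(zip(ids, df["population"].astype(float)))


def load_region(
    geometry_source,
    population_table,
    id_field: str = "su_id",
    assume_projected: bool = False,
) -> Region:
    """Load a region from a GeoJSON of SU polygons/points or a centroid CSV.

    Parameters
    ----------
    geometry_source
        Path to a GeoJSON FeatureCollection (polygons or points, each feature
        carrying ``id_field`` in its properties) or to a CSV with columns
        ``id_field, x, y``.
    population_table
        Path to a CSV with columns ``id_field, population`` (or a DataFrame).
    assume_projected
        Coordinates that all fit within lon/lat ranges are rejected — the
        Euclidean distances the cluster model relies on would be meaningless
        on geographic coordinates.  Pass True to override for genuinely
        projected regions that happen to sit near the origin.
    """
    pops = _read_population_table(population_table, id_field)
    path = Path(geometry_source)
    geometries: dict[str, BaseGeometry] | None = None
    if path.suffix.lower() in {".json", ".geojson"}:
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") != "FeatureCollection":
            raise ValueError("GeoJSON must be a FeatureCollection")
        rows = []
        geometries = {}
        for feat in gj["features"]:
            props = feat.get("properties") or {}
            if id_field not in props:
                raise ValueError(f"feature missing {id_field!r} property")
            sid = str(props[id_field])
            geom = _shapely_shape(feat["geometry"])
            geometries[sid] = geom
            c = geom.centroid  # area-weighted for polygons
            rows.append((sid, c.x, c.y))
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype={id_field: str})
        need = {id_field, "x", "y"}
        if not need <= set(df.columns):
            raise ValueError(f"centroid CSV needs columns {sorted(need)}")
        rows = [(str(r[id_field]), float(r["x"]), float(r["y"])) for _, r in df.iterrows()]
    else:
        raise ValueError(
            f"unsupported geometry source {path.name!r}: expected .geojson/.json or .csv"
        )

    ids = [r[0] for r in rows]
    missing = [i for i in ids if i not in pops]
    if missing:
        raise ValueError(f"no population record for su_id(s): {sorted(set(missing))}")
    extra = sorted(set(pops) - set(ids))
    if extra:
        raise ValueError(f"population record(s) without geometry: {extra}")

    coords = np.array([[r[1], r[2]] for r in rows], dtype=float)
    if not assume_projected and _looks_geographic(coords):
        raise ValueError(
            "coordinates look geographic (lon/lat); project them to a planar "
            "CRS first, or pass assume_projected=True if they really are planar"
        )
    units = [SpatialUnit(sid, x, y, pops[sid]) for (sid, x, y) in rows]
    return Region(units, geometries=geometries)


def build_cluster_collection(region: Region, cluster_size: int) -> list[Cluster]:
    """Exhaustive collection of ``s``-SU clusters, one centered on every SU.

    Each cluster is the center SU plus its ``s - 1`` nearest neighbors by
    Euclidean centroid distance (ties broken by ascending su_id).  The list
    is ordered by center su_id.
    """
    s = int(cluster_size)
    if not 2 <= s <= region.n_units:
        raise ValueError(f"cluster_size must be in [2, {region.n_units}], got {s}")
    out = []
    for k, sid in enumerate(region.su_ids):
        order = region.neighbor_order(k)[:s]
        members = frozenset(region.su_ids[i] for i in order)
        pop = float(region.populations[order].sum())
        out.append(Cluster(center_su=sid, members=members, size=s, population=pop))
    return out


def cluster_population(region: Region, cluster: Cluster) -> float:
    """Total at-risk population of a cluster's member SUs."""
    idx = [region.index(m) for m in cluster.members]
    return float(region.populations[idx].sum())


def export_cluster_collection(clusters: Sequence[Cluster], path) -> None:
    """Write a cluster collection as CSV (center, members, size, population)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["center_su", "member_sus", "size", "population"])
        for c in clusters:
            w.writerow([c.center_su, ";".join(sorted(c.members)), c.size, repr(c.population)])
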