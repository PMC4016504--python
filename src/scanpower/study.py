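"""Performance mapping: run the full simulation experiment and map AUC_EP.

For every cluster in an exhaustive collection and every risk scenario, the
study simulates replicate datasets, scans each with the Poisson spatial
scan, classifies the detection against the true cluster, tallies by
(l, s*) and scores the tally with AUC_EP.  Each cluster's score is then
assigned to its central SU, giving one choropleth performance map per
scenario.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as _shapely_mapping

from .power import DetectionTally, auc_ep, classify_detection, extended_power
from .region import Cluster, Region
from .scan import KulldorffScan, ZoneSystem
from .simulate import RiskScenario, child_seed, simulate_dataset

__all__ = [
    "ScanConfig",
    "PerformanceRecord",
    "PerformanceMap",
    "PerformanceStudy",
    "PerformanceResults",
    "run_experiment",
    "assign_to_map",
    "summarize_by_population",
    "render_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Scan-statistic settings shared by every analysis in a study."""

    max_population_fraction: float = 0.5
    max_zone_size: int | None = None
    mc_replicates: int = 999
    alpha: float = 0.05
    lambda_mode: str = "estimated"
    fixed_lambda: float | None = None
    null: str = "conditional"


@dataclass
class PerformanceRecord:
    """AUC_EP of one (cluster, scenario) cell, assigned to the center SU."""

    center_su: str
    cluster: Cluster
    scenario: str
    auc_ep: float
    ep_intercept: float
    n_datasets: int
    cluster_population: float
    tally: DetectionTally | None = None


@dataclass
class PerformanceMap:
    """Per-SU AUC_EP values for one scenario, ready to render."""

    region: Region
    scenario: str
    values: np.ndarray  # aligned with region.su_ids
    class_breaks: np.ndarray

    def to_geojson(self, path) -> None:
        if self.region.geometries is None:
            raise ValueError("region carries no geometries; cannot write GeoJSON")
        feats = []
        for sid, geom, v in zip(self.region.su_ids, self.region.geometries, self.values):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": _shapely_mapping(geom),
                    "properties": {"su_id": sid, "auc_ep": float(v)},
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


class PerformanceStudy:
    """The full mapping experiment for one region.

    Parameters
    ----------
    region : Region
    scenarios : mapping of name -> RiskScenario
        Scenario ``cluster`` fields are ignored; each scenario is re-applied
        to every cluster of the collection in turn.
    cluster_collection : sequence of Cluster, optional
        Defaults to the exhaustive collection of ``cluster_size``-SU
        clusters centered on every SU.
    cluster_size : int
        True-cluster size s (default 4 SUs: a center and its 3 nearest
        neighbors).
    n_datasets : int
        Replicate datasets per (cluster, scenario).
    max_detected_size : int
        Size cap L above which a significant detection is discarded.
    scan : ScanConfig
    checkpoint_dir : path, optional
        One tally CSV per (cluster, scenario); existing files are loaded
        instead of recomputed, so interrupted runs resume and tallies can be
        re-scored later with a different q grid.
    """

    def __init__(
        self,
        region: Region,
        scenarios: Mapping[str, RiskScenario],
        cluster_collection: Sequence[Cluster] | None = None,
        cluster_size: int = 4,
        n_datasets: int = 1000,
        max_detected_size: int = 30,
        scan: ScanConfig = ScanConfig(),
        checkpoint_dir=None,
    ) -> None:
        from .region import build_cluster_collection

        if n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        self.region = region
        self.scenarios = dict(scenarios)
        self.clusters = (
            list(cluster_collection)
            if cluster_collection is not None
            else build_cluster_collection(region, cluster_size)
        )
        self.n_datasets = n_datasets
        self.L = max_detected_size
        self.scan = scan
        self.checkpoint_dir = Path(checkpoint_dir) if checkpoint_dir else None
        self.zone_system = ZoneSystem(
            region, scan.max_population_fraction, scan.max_zone_size
        )

    def config(self) -> dict:
        return {
            "n_units": self.region.n_units,
            "n_clusters": len(self.clusters),
            "scenarios": sorted(self.scenarios),
            "n_datasets": self.n_datasets,
            "max_detected_size": self.L,
            "scan": vars(self.scan) | {},
        }

    def _tally_path(self, scenario: str, center: str) -> Path | None:
        if self.checkpoint_dir is None:
            return None
        return self.checkpoint_dir / f"tally_{scenario}_{center}.csv"

    def _run_cell(
        self, ci: int, cluster: Cluster, si: int, scenario: RiskScenario, master_seed: int
    ) -> DetectionTally:
        tally = DetectionTally(true_cluster_size=cluster.size, max_size=self.L)
        sc = RiskScenario(
            incidence=scenario.incidence,
            relative_risk=scenario.relative_risk,
            cluster=cluster,
            years=scenario.years,
            name=scenario.name,
        )
        for r in range(self.n_datasets):
            ds = simulate_dataset(
                self.region, sc, rng=child_seed(master_seed, ci, si, r, 0), replicate=r
            )
            res = KulldorffScan(
                ds,
                zones=self.zone_system,
                lambda_mode=self.scan.lambda_mode,
                fixed_lambda=self.scan.fixed_lambda,
                null=self.scan.null,
            ).fit(
                mc_replicates=self.scan.mc_replicates,
                alpha=self.scan.alpha,
                seed=child_seed(master_seed, ci, si, r, 1),
            )
            tally.add(classify_detection(res, cluster, self.L))
        return tally

    def fit(self, master_seed: int = 0, keep_tallies: bool = False) -> "PerformanceResults":
        """Run every (cluster, scenario) cell; fully reproducible from the
        master seed (each cell, even each replicate, has its own derived
        seed, so checkpoint resumption does not shift the stream)."""
        logger.info("performance study config: %s", self.config())
        if self.checkpoint_dir is not None:
            self.checkpoint_dir.mkdir(parents=True, exist_ok=True)
            with open(self.checkpoint_dir / "config.json", "w") as fh:
                json.dump(self.config() | {"master_seed": master_seed}, fh, indent=2)
        records = []
        scen_names = sorted(self.scenarios)
        for si, name in enumerate(scen_names):
            scenario = self.scenarios[name]
            for ci, cluster in enumerate(self.clusters):
                path = self._tally_path(name, cluster.center_su)
                if path is not None and path.exists():
                    tally = DetectionTally.from_csv(path)
                else:
                    tally = self._run_cell(ci, cluster, si, scenario, master_seed)
                    if path is not None:
                        tally.to_csv(path)
                records.append(
                    PerformanceRecord(
                        center_su=cluster.center_su,
                        cluster=cluster,
                        scenario=name,
                        auc_ep=auc_ep(tally),
                        ep_intercept=extended_power(tally, 0.0),
                        n_datasets=tally.n_datasets,
                        cluster_population=cluster.population,
                        tally=tally if keep_tallies else None,
                    )
                )
            logger.info("scenario %s done (%d clusters)", name, len(self.clusters))
        return PerformanceResults(self.region, records)

    run = fit  # orchestration alias


class PerformanceResults:
    """Per-cluster AUC_EP records with summaries and map construction."""

    def __init__(self, region: Region, records: list[PerformanceRecord]) -> None:
        self.region = region
        self.records = records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_su": [r.center_su for r in self.records],
                "scenario": [r.scenario for r in self.records],
                "auc_ep": [r.auc_ep for r in self.records],
                "ep_intercept": [r.ep_intercept for r in self.records],
                "cluster_population": [r.cluster_population for r in self.records],
                "n_datasets": [r.n_datasets for r in self.records],
            }
        )

    def scenario_means(self) -> pd.Series:
        return self.to_frame().groupby("scenario")["auc_ep"].mean()

    def summary(self, breaks="quartiles") -> pd.DataFrame:
        return summarize_by_population(self.records, breaks)

    def to_map(self, scenario: str, assign: str = "center") -> PerformanceMap:
        recs = [r for r in self.records if r.scenario == scenario]
        if not recs:
            raise ValueError(f"no records for scenario {scenario!r}")
        return assign_to_map(recs, scenario, region=self.region, assign=assign)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_experiment(
    region: Region,
    cluster_collection: Sequence[Cluster],
    scenarios: Mapping[str, RiskScenario],
    n_datasets: int,
    scan_config: ScanConfig,
    L: int,
    master_seed: int,
    checkpoint_dir=None,
) -> list[PerformanceRecord]:
    """Functional wrapper around :class:`PerformanceStudy`."""
    study = PerformanceStudy(
        region,
        scenarios,
        cluster_collection=cluster_collection,
        n_datasets=n_datasets,
        max_detected_size=L,
        scan=scan_config,
        checkpoint_dir=checkpoint_dir,
    )
    return study.fit(master_seed).records


def assign_to_map(
    records: Sequence[PerformanceRecord],
    scenario: str,
    region: Region | None = None,
    assign: str = "center",
    class_breaks: np.ndarray | None = None,
) -> PerformanceMap:
    """Build the per-SU AUC_EP map for one scenario.

    ``assign='center'`` gives each SU the score of the cluster centered on
    it (requires exactly one record per SU); ``assign='members-mean'``
    averages over every cluster the SU belongs to.
    """
    recs = [r for r in records if r.scenario == scenario]
    if region is None:
        if not recs:
            raise ValueError("no records supplied")
        raise ValueError("a Region is required to order map values")
    if class_breaks is None:
        class_breaks = np.linspace(0.0, 1.0, 11)  # deciles of [0, 1]
    if assign == "center":
        by_center: dict[str, float] = {}
        for r in recs:
            if r.center_su in by_center:
                raise ValueError(f"duplicate record for center SU {r.center_su!r}")
            by_center[r.center_su] = r.auc_ep
        missing = [sid for sid in region.su_ids if sid not in by_center]
        if missing:
            raise ValueError(f"no record for center SU(s): {missing}")
        values = np.array([by_center[sid] for sid in region.su_ids])
    elif assign == "members-mean":
        sums = {sid: 0.0 for sid in region.su_ids}
        cnts = {sid: 0 for sid in region.su_ids}
        for r in recs:
            for m in r.cluster.members:
                sums[m] += r.auc_ep
                cnts[m] += 1
        missing = [sid for sid in region.su_ids if cnts[sid] == 0]
        if missing:
            raise ValueError(f"SU(s) in no cluster: {missing}")
        values = np.array([sums[sid] / cnts[sid] for sid in region.su_ids])
    else:
        raise ValueError("assign must be 'center' or 'members-mean'")
    return PerformanceMap(region=region, scenario=scenario, values=values, class_breaks=np.asarray(class_breaks))


def summarize_by_population(
    records: Sequence[PerformanceRecord], breaks="quartiles"
) -> pd.DataFrame:
    """Mean/SD/min/max of AUC_EP per at-risk-population class per scenario.

    Classes come from quartiles of the cluster populations by default, or
    from explicit ascending boundary values.  Empty classes are absent from
    the table, not reported as zero.
    """
    if not records:
        raise ValueError("no records to summarize")
    pops = np.array([r.cluster_population for r in records])
    if isinstance(breaks, str):
        if breaks != "quartiles":
            raise ValueError("breaks must be 'quartiles' or explicit boundaries")
        bounds = np.unique(np.quantile(np.unique(pops), [0.25, 0.5, 0.75]))
    else:
        bounds = np.asarray(sorted(breaks), dtype=float)
    edges = np.concatenate(([-np.inf], bounds, [np.inf]))
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == -np.inf:
            labels.append(f"<= {hi:g}")
        elif hi == np.inf:
            labels.append(f"> {lo:g}")
        else:
            labels.append(f"({lo:g}, {hi:g}]")
    df = pd.DataFrame(
        {
            "scenario": [r.scenario for r in records],
            "population": pops,
            "auc_ep": [r.auc_ep for r in records],
        }
    )
    df["pop_class"] = pd.cut(df["population"], edges, labels=labels)
    rows = []
    for (scen, cls), g in df.groupby(["scenario", "pop_class"], observed=True):
        rows.append(
            {
                "scenario": scen,
                "pop_class": str(cls),
                "n": len(g),
                "mean": g["auc_ep"].mean(),
                "sd": g["auc_ep"].std(ddof=1) if len(g) > 1 else float("nan"),
                "min": g["auc_ep"].min(),
                "max": g["auc_ep"].max(),
            }
        )
    return pd.DataFrame(rows)


def render_map(
    pmap: PerformanceMap,
    output_path,
    geojson_path=None,
    cmap: str = "viridis",
    ax=None,
):
    """Render the choropleth (PNG) and optionally the attributed GeoJSON.

    All scenario maps share one color scale over [0, 1] (the fixed class
    breaks) so maps are directly comparable.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.colors import BoundaryNorm
    from matplotlib.patches import Polygon as MplPolygon

    region = pmap.region
    if region.geometries is None:
        raise ValueError("region carries no geometries; cannot render a map")
    norm = BoundaryNorm(pmap.class_breaks, ncolors=256)
    patches = []
    for geom in region.geometries:
        if geom.geom_type == "Polygon":
            polys = [geom]
        elif geom.geom_type == "MultiPolygon":
            polys = list(geom.geoms)
        else:
            raise ValueError(f"cannot render geometry type {geom.geom_type}")
        for p in polys:
            patches.append(MplPolygon(np.asarray(p.exterior.coords)))
    # repeat values for multi-part geometries
    vals = []
    for geom, v in zip(region.geometries, pmap.values):
        k = 1 if geom.geom_type == "Polygon" else len(geom.geoms)
        vals.extend([v] * k)
    owns_fig = ax is None
    if owns_fig:
        fig, ax = plt.subplots(figsize=(7, 6))
    coll = PatchCollection(patches, cmap=cmap, norm=norm, edgecolor="0.4", linewidth=0.3)
    coll.set_array(np.asarray(vals))
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_title(f"AUC_EP — {pmap.scenario}")
    if owns_fig:
        fig.colorbar(coll, ax=ax, label="AUC_EP")
        fig.savefig(output_path, dpi=150)
        plt.close(fig)
    if geojson_path is not None:
        pmap.to_geojson(geojson_path)
    return ax
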