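"""Readers and writers for the interchange formats.

Spatial entities travel as GeoJSON (RFC 7946) FeatureCollections of Points
in a planar CRS (coordinates in meters); the distance matrix as CSV with
center ids in the first column and site ids in the header; run settings as
YAML.  An optional road network (edge list plus node coordinates) can stand
in for the matrix: centers and sites are snapped to their nearest node and
shortest paths are computed with intersection-dwell correction.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    CandidateSite,
    CostParameters,
    FacilityConfiguration,
    PopulationCenter,
    ProblemInstance,
    allocate_nearest,
    build_instance,
    clamp_distances,
)

__all__ = [
    "ConfigError",
    "DataError",
    "write_centers",
    "read_centers",
    "write_sites",
    "read_sites",
    "write_existing",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_scenario",
    "read_inputs",
    "load_config",
    "write_plan_geojson",
]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


class DataError(ValueError):
    """Malformed or inconsistent input data files."""


def _point_feature(obj_id: str, xy, props: dict[str, Any]) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [float(xy[0]), float(xy[1])]},
        "properties": {"id": obj_id, **props},
    }


def _write_collection(path: Path, features: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def _read_collection(path: Path) -> list[dict]:
    try:
        data = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read GeoJSON {path}: {exc}") from exc
    if data.get("type") != "FeatureCollection":
        raise DataError(f"{path}: expected a FeatureCollection")
    return data["features"]


def write_centers(path, centers) -> None:
    _write_collection(
        Path(path),
        [
            _point_feature(c.id, c.location, {"elderly": c.elderly, "demand": c.demand})
            for c in centers
        ],
    )


def read_centers(path) -> list[PopulationCenter]:
    out = []
    for feat in _read_collection(path):
        props = feat["properties"]
        xy = feat["geometry"]["coordinates"]
        try:
            out.append(
                PopulationCenter(
                    str(props["id"]), (float(xy[0]), float(xy[1])),
                    int(props["elderly"]), int(props["demand"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise DataError(f"{path}: bad center feature: {exc}") from exc
    return out


def write_sites(path, sites) -> None:
    _write_collection(
        Path(path),
        [_point_feature(s.id, s.location, {"max_beds": s.max_beds}) for s in sites],
    )


def read_sites(path) -> list[CandidateSite]:
    out = []
    for feat in _read_collection(path):
        props = feat["properties"]
        xy = feat["geometry"]["coordinates"]
        try:
            out.append(
                CandidateSite(
                    str(props["id"]), (float(xy[0]), float(xy[1])),
                    int(props["max_beds"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise DataError(f"{path}: bad site feature: {exc}") from exc
    return out


def write_existing(path, instance: ProblemInstance, config: FacilityConfiguration) -> None:
    feats = [
        _point_feature(
            instance.sites[j].id,
            instance.sites[j].location,
            {"beds": int(config.beds[j])},
        )
        for j in config.open_sites
    ]
    _write_collection(Path(path), feats)


def write_distance_matrix(path, instance: ProblemInstance) -> None:
    df = pd.DataFrame(
        instance.distances,
        index=[c.id for c in instance.centers],
        columns=[s.id for s in instance.sites],
    )
    df.index.name = "center_id"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.17g")  # exact double round-trip


def read_distance_matrix(path, centers, sites) -> np.ndarray:
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except (OSError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot read distance CSV {path}: {exc}") from exc
    center_ids = [c.id for c in centers]
    site_ids = [s.id for s in sites]
    missing_c = set(center_ids) - set(df.index.astype(str))
    missing_s = set(site_ids) - set(df.columns.astype(str))
    if missing_c or missing_s:
        raise DataError(
            f"{path}: id mismatch (missing centers {sorted(missing_c)[:3]}, "
            f"missing sites {sorted(missing_s)[:3]})"
        )
    df.index = df.index.astype(str)
    return df.loc[center_ids, site_ids].to_numpy(dtype=float)


def _road_network_distances(nodes_path, edges_path, centers, sites) -> np.ndarray:
    import networkx as nx

    from .core import effective_distance

    try:
        nodes = pd.read_csv(nodes_path)
        edges = pd.read_csv(edges_path)
    except (OSError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot read road network: {exc}") from exc
    for col in ("node_id", "x", "y"):
        if col not in nodes.columns:
            raise DataError(f"{nodes_path}: missing column {col!r}")
    for col in ("node_u", "node_v", "length_m", "speed_m_s", "dwell_s"):
        if col not in edges.columns:
            raise DataError(f"{edges_path}: missing column {col!r}")
    g = nx.Graph()
    for row in edges.itertuples():
        g.add_edge(
            row.node_u, row.node_v,
            weight=effective_distance(row.length_m, [row.dwell_s], row.speed_m_s),
        )
    xy = nodes[["x", "y"]].to_numpy(dtype=float)
    ids = nodes["node_id"].to_list()

    def snap(point):
        return ids[int(np.argmin(((xy - np.asarray(point)) ** 2).sum(axis=1)))]

    c_nodes = [snap(c.location) for c in centers]
    s_nodes = [snap(s.location) for s in sites]
    d = np.empty((len(centers), len(sites)))
    for i, cn in enumerate(c_nodes):
        lengths = nx.single_source_dijkstra_path_length(g, cn, weight="weight")
        for j, sn in enumerate(s_nodes):
            if sn not in lengths:
                raise DataError(f"road network disconnects center {centers[i].id}")
            d[i, j] = lengths[sn]
    return clamp_distances(d)


def write_scenario(out_dir, instance: ProblemInstance, config: FacilityConfiguration) -> dict:
    """Write a full input set (centers/sites/existing GeoJSON + distances CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "centers": out / "centers.geojson",
        "sites": out / "sites.geojson",
        "existing": out / "existing.geojson",
        "distances": out / "distances.csv",
    }
    write_centers(paths["centers"], instance.centers)
    write_sites(paths["sites"], instance.sites)
    write_existing(paths["existing"], instance, config)
    write_distance_matrix(paths["distances"], instance)
    return {k: str(v) for k, v in paths.items()}


def load_config(path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {"inputs", "objectives", "mia", "workflow", "output", "seed", "verbosity"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return raw


def read_inputs(config: dict, base_dir: Path | str = ".") -> tuple[ProblemInstance, FacilityConfiguration | None]:
    """Build a validated instance (and existing configuration) from config paths.

    A distance matrix takes precedence over a road network when both are
    given.  The existing-facility layer is optional.
    """
    base = Path(base_dir)
    inputs = config.get("inputs", {})
    for key in ("centers", "sites"):
        if key not in inputs:
            raise ConfigError(f"config inputs missing {key!r}")
        if not (base / inputs[key]).exists():
            raise DataError(f"input file not found: {inputs[key]}")
    centers = read_centers(base / inputs["centers"])
    sites = read_sites(base / inputs["sites"])
    if "distances" in inputs and (base / inputs["distances"]).exists():
        d = read_distance_matrix(base / inputs["distances"], centers, sites)
    elif "road_nodes" in inputs and "road_edges" in inputs:
        d = _road_network_distances(
            base / inputs["road_nodes"], base / inputs["road_edges"], centers, sites
        )
    else:
        raise ConfigError("config must name either a distance matrix or a road network")
    obj = config.get("objectives", {})
    try:
        instance = build_instance(
            centers, sites, d,
            beta=float(obj.get("beta", 1.0)),
            costs=CostParameters(
                charge=float(obj.get("charge", 2050.0)),
                cost=float(obj.get("cost", 1250.0)),
            ),
        )
    except ValueError as exc:
        raise DataError(str(exc)) from exc

    existing = None
    if "existing" in inputs:
        path = base / inputs["existing"]
        if not path.exists():
            raise DataError(f"input file not found: {inputs['existing']}")
        site_ids = {s.id: j for j, s in enumerate(instance.sites)}
        beds = np.zeros(instance.n_sites)
        y = np.zeros(instance.n_sites, dtype=int)
        for feat in _read_collection(path):
            props = feat["properties"]
            sid = str(props.get("id"))
            if sid not in site_ids:
                raise DataError(f"existing facility id {sid!r} is not a candidate site")
            j = site_ids[sid]
            y[j] = 1
            beds[j] = float(props.get("beds", 0))
        open_idx = np.flatnonzero(y)
        if open_idx.size:
            z = allocate_nearest(instance, open_idx)
            existing = FacilityConfiguration(
                open=y, beds=beds, allocation=z, p=int(open_idx.size)
            )
    return instance, existing


def write_plan_geojson(path, instance: ProblemInstance, site_indices, beds) -> None:
    """New facilities of a plan as a GeoJSON point layer with bed counts."""
    feats = [
        _point_feature(
            instance.sites[int(j)].id,
            instance.sites[int(j)].location,
            {"beds": int(b)},
        )
        for j, b in zip(site_indices, beds)
    ]
    _write_collection(Path(path), feats)
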