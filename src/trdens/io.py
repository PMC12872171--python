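"""File I/O: delimited-text tables, edge lists, GeoJSON polygons, fit results.

All tabular formats are comma-delimited UTF-8 text with a header row;
files written by the package carry ``#``-prefixed comment headers recording
the package version, seed and config digest so every output is traceable to
its run.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import shape

from . import __version__
from .model import FitResult, ModelSpec

__all__ = [
    "read_tract_table",
    "write_tract_table",
    "read_adjacency",
    "write_adjacency",
    "read_geojson_polygons",
    "write_fit_result",
    "read_fit_result",
    "write_table",
]

TABLE_COLUMNS = [
    "tract_id",
    "year",
    "population",
    "pct_african_american",
    "pct_hispanic",
    "pct_under18",
    "pct_poverty",
    "nchs_level",
    "high_aa",
    "high_hisp",
    "high_children",
    "high_poverty",
    "rurality",
    "licensing",
    "retailer_count",
]
_PCT_COLS = ["pct_african_american", "pct_hispanic", "pct_under18", "pct_poverty"]
_FLAG_COLS = ["high_aa", "high_hisp", "high_children", "high_poverty", "licensing"]


def _header_lines(seed=None, config_digest=None, extra: dict | None = None) -> str:
    fields = {"package": f"trdens {__version__}"}
    if seed is not None:
        fields["seed"] = seed
    if config_digest is not None:
        fields["config_digest"] = config_digest
    if extra:
        fields.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in fields.items())


def write_table(df: pd.DataFrame, path, seed=None, config_digest=None) -> None:
    """Write any DataFrame as commented-header CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(seed, config_digest))
        df.to_csv(fh, index=False)


def write_tract_table(table: pd.DataFrame, path, seed=None, config_digest=None) -> None:
    df = table.copy()
    for col in _FLAG_COLS:
        if col in df.columns:
            # nullable boolean -> Int64 keeps missing poverty flags round-trippable
            df[col] = df[col].astype("boolean").astype("Int64")
    cols = [c for c in TABLE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    write_table(df[cols], path, seed, config_digest)


def read_tract_table(path, column_mapping: dict | None = None) -> pd.DataFrame:
    """Read and validate a tract-year table.

    ``column_mapping`` maps file column names to the canonical names (for
    externally produced files).  Validation failures name the offending
    rows; duplicate (tract, year) pairs, out-of-range percentages, negative
    populations or counts, and 2017 licensing flags are all rejected.
    """
    df = pd.read_csv(path, comment="#")
    if column_mapping:
        df = df.rename(columns=dict(column_mapping))
    required = {"tract_id", "year", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    df["tract_id"] = df["tract_id"].astype(str)
    dup = df.duplicated(["tract_id", "year"], keep=False)
    if dup.any():
        tracts = sorted(df.loc[dup, "tract_id"].unique())
        raise ValueError(f"{path}: duplicated (tract_id, year) rows for tracts {tracts[:5]}")
    for col in _PCT_COLS:
        if col in df.columns:
            bad = df.index[(df[col] < 0) | (df[col] > 100)].tolist()
            if bad:
                raise ValueError(f"{path}: {col} outside [0, 100] at rows {bad[:5]}")
    if (df["population"] < 0).any():
        raise ValueError(f"{path}: negative population")
    if "retailer_count" in df.columns and (df["retailer_count"].fillna(0) < 0).any():
        raise ValueError(f"{path}: negative retailer_count")
    for col in _FLAG_COLS:
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    if "licensing" in df.columns:
        bad = df[(df["year"] == 2017) & (df["licensing"].fillna(False))]
        if len(bad):
            raise ValueError(
                f"{path}: licensing flagged in 2017 for tracts "
                f"{sorted(bad['tract_id'].unique())[:5]} (no policy existed at baseline)"
            )
        df["licensing"] = df["licensing"].fillna(False).astype(bool)
    for col in ("high_aa", "high_hisp", "high_children"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_adjacency(graph: nx.Graph, path, seed=None, config_digest=None) -> None:
    edges = pd.DataFrame(sorted((min(u, v), max(u, v)) for u, v in graph.edges),
                         columns=["tract_id_a", "tract_id_b"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(seed, config_digest, {"id_space": "tract_id"}))
        edges.to_csv(fh, index=False)


def read_adjacency(path, tract_ids=None) -> nx.Graph:
    """Read a two-column edge list into a symmetric graph.

    Self-loops are rejected; if ``tract_ids`` is given, edges naming
    unknown tracts raise, and isolated tracts are added as nodes.
    """
    edges = pd.read_csv(path, comment="#", dtype=str)
    if edges.shape[1] < 2:
        raise ValueError(f"{path}: expected a two-column edge list")
    a, b = edges.columns[:2]
    g = nx.Graph()
    if tract_ids is not None:
        g.add_nodes_from(tract_ids)
        known = set(map(str, tract_ids))
    else:
        known = None
    for u, v in edges[[a, b]].itertuples(index=False):
        if u == v:
            raise ValueError(f"{path}: self-loop on tract {u!r}")
        if known is not None and (u not in known or v not in known):
            raise ValueError(f"{path}: edge ({u!r}, {v!r}) names a tract absent from the table")
        g.add_edge(u, v)
    return g


def read_geojson_polygons(path) -> dict:
    """Read a GeoJSON FeatureCollection into {id: shapely geometry}.

    Feature ids come from the ``id`` member or an ``id``/``tract_id``/
    ``name`` property.  Coordinates are taken as planar; no CRS handling.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = {}
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        pid = feat.get("id", props.get("id", props.get("tract_id", props.get("name", str(k)))))
        polys[str(pid)] = shape(feat["geometry"])
    return polys


def write_fit_result(fit: FitResult, path) -> None:
    payload = {
        "columns": list(fit.columns),
        "beta": fit.beta.tolist(),
        "cov": fit.cov.tolist(),
        "alpha": fit.alpha,
        "gamma": fit.gamma,
        "phi": fit.phi,
        "n_iterations": fit.n_iterations,
        "converged": fit.converged,
        "n_tracts": fit.n_tracts,
        "spec": {
            "terms": list(fit.spec.terms),
            "interaction_candidates": list(fit.spec.interaction_candidates),
            "licensing": fit.spec.licensing,
        },
        "package": f"trdens {__version__}",
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_fit_result(path) -> FitResult:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    spec = ModelSpec(
        terms=tuple(payload["spec"]["terms"]),
        interaction_candidates=tuple(payload["spec"]["interaction_candidates"]),
        licensing=payload["spec"]["licensing"],
    )
    return FitResult(
        spec=spec,
        columns=tuple(payload["columns"]),
        beta=np.asarray(payload["beta"]),
        cov=np.asarray(payload["cov"]),
        alpha=payload["alpha"],
        gamma=payload["gamma"],
        phi=payload["phi"],
        n_iterations=payload["n_iterations"],
        converged=payload["converged"],
        n_tracts=payload["n_tracts"],
    )
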