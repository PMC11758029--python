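"""File round-tripping: snapshot TSV/CSV (+ provenance sidecar), edge
lists, lifetimes, score records, and model/benchmark configs.

On-disk conventions: species indices are 0-based everywhere; snapshot
files are TSV with a header of species labels and integer cells (CSV
accepted by extension, gzip transparently by ``.gz`` suffix); provenance
travels in a ``<file>.meta.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models as _models
from .infer import PairScore
from .models import NetworkModel
from .simulate import SnapshotMatrix

__all__ = ["write_snapshots", "read_snapshots", "write_edges", "read_edges",
           "write_taus", "read_taus", "write_scores", "read_scores",
           "load_model_config", "model_from_config"]


def _sep(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return "," if name.endswith(".csv") else "\t"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_snapshots(snapshots: SnapshotMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(snapshots.data, columns=snapshots.labels)
    df.to_csv(path, sep=_sep(path), index=False)
    _meta_path(path).write_text(json.dumps(snapshots.provenance, indent=1))


def read_snapshots(path) -> SnapshotMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        bad = np.argwhere(arr != np.floor(arr))
        if len(bad):
            r, c = bad[0]
            raise ValueError(
                f"non-integer snapshot cell at row {r}, column {df.columns[c]!r}")
        arr = arr.astype(np.int64)
    prov = {}
    mp = _meta_path(path)
    if mp.exists():
        prov = json.loads(mp.read_text())
    return SnapshotMatrix(arr, [str(c) for c in df.columns], prov)


def write_edges(edges, path) -> None:
    """Directed edge list ``j -> i`` written as rows ``source<TAB>target``."""
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(
        Path(path), sep="\t", index=False)


def read_edges(path) -> list[tuple[int, int]]:
    df = pd.read_csv(Path(path), sep="\t")
    return [(int(s), int(t)) for s, t in zip(df["source"], df["target"])]


def adjacency_from_edges(edges, V: int) -> np.ndarray:
    G = np.zeros((V, V), dtype=np.int8)
    for j, i in edges:
        G[i, j] = 1
    return _models.validate_adjacency(G)


def write_taus(taus, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps([float(t) for t in taus]))
    else:
        pd.DataFrame({"species": np.arange(len(taus)), "tau": taus}).to_csv(
            path, sep="\t", index=False)


def read_taus(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".json":
        return np.asarray(json.loads(path.read_text()), dtype=float)
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("species")["tau"].to_numpy(dtype=float)


def write_scores(scores: list[PairScore], path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in scores], indent=1))


def read_scores(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def load_model_config(path) -> dict:
    """JSON or YAML config with keys ``family`` (mm | goodwin | ecoli),
    ``params``, ``lifetimes``, ``seed``, ``network_file`` / ``V``/``E``."""
    path = Path(path)
    text = path.read_text()
    cfg = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
           else json.loads(text))
    if "family" not in cfg:
        raise ValueError("model config needs a 'family' key")
    return cfg


def model_from_config(cfg: dict, base_dir=None) -> NetworkModel:
    family = cfg["family"]
    params = cfg.get("params") or {}
    if family == "ecoli":
        return _models.build_ecoli(
            _models.EcoliParams(**params) if params else None)
    if cfg.get("network_file"):
        p = Path(cfg["network_file"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        edges = read_edges(p)
        V = cfg.get("V") or (max(max(e) for e in edges) + 1)
        G = adjacency_from_edges(edges, int(V))
    elif "V" in cfg and "E" in cfg:
        G = _models.build_er_network(int(cfg["V"]), int(cfg["E"]),
                                     seed=int(cfg.get("seed", 0)))
    else:
        raise ValueError(
            f"{family} model config needs 'network_file' or 'V' and 'E'")
    if family == "mm":
        return _models.build_michaelis_menten(
            G, _models.MMParams(**params) if params else None,
            lifetimes=cfg.get("lifetimes"))
    if family == "goodwin":
        return _models.build_goodwin(
            G, _models.GoodwinParams(**params) if params else None)
    raise ValueError(f"unknown model family {family!r}")
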