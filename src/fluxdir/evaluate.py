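"""Benchmark harness: ROC/AUC over edge ensembles, determinant
stratification (dispersion, degree, lifetime ratio), and the seven-gene
E. coli case study.

The direction-classification task is framed exactly as in the benchmark
experiments: the undirected topology is taken as given, and for every
true edge both orientations enter the candidate set (the true one labeled
1, its reverse 0).  Sweeping a threshold over the pooled normalized
scores yields the ROC curve; non-edges are deliberately excluded so that
direction inference is not conflated with topology detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from . import models as _models
from .infer import score_pair
from .simulate import SnapshotMatrix, sample_snapshots, subsample

__all__ = ["ROCResult", "EdgeRecord", "roc_auc", "index_of_dispersion",
           "score_true_edges", "benchmark_auc_vs_n", "stratify_performance",
           "ecoli_case_study", "ECOLI_TRUE_EDGES"]


@dataclass
class ROCResult:
    """Threshold sweep of a binary score: FPR/TPR arrays and the area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC of ``scores`` against binary ``labels``.

    Equal scores are grouped at a single threshold; the curve runs from
    (0, 0) to (1, 1) and the area is the trapezoid-rule integral
    (equivalently the normalized Mann-Whitney U statistic).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, thr = _skm.roc_curve(labels, scores)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr,
                     auc=float(_skm.auc(fpr, tpr)))


def index_of_dispersion(snapshots: SnapshotMatrix, i: int) -> float:
    """Variance-to-mean ratio of column ``i`` (Fano factor).

    ``D ~ 1`` marks a Poisson-like species whose dynamics depend only
    weakly on the rest of the network; undefined (NaN) for a zero-mean
    column.
    """
    x = snapshots.column(i).astype(float)
    m = x.mean()
    if m == 0:
        return np.nan
    return float(x.var(ddof=1) / m)


@dataclass
class EdgeRecord:
    """One scored true edge j -> i with the node covariates used by the
    determinant analyses, all computed from the same snapshot matrix."""

    network_id: int
    source: int            # true regulator j
    target: int            # true target i
    s_true: float          # normalized score of the true direction
    s_rev: float           # normalized score of the reverse direction
    correct: bool          # arg-max call equals truth (undetermined = False)
    undetermined: bool
    D_target: float
    D_source: float
    in_degree_source: int
    in_degree_target: int
    lifetime_ratio: float  # tau_source / tau_target
    N: int

    def covariate(self, by: str) -> float:
        if by == "dispersion":
            return self.D_target
        if by == "in_degree":
            return float(self.in_degree_source)
        if by == "lifetime_ratio":
            return self.lifetime_ratio
        raise ValueError(f"unknown stratifier {by!r}")


def score_true_edges(
    snapshots: SnapshotMatrix,
    adjacency: np.ndarray,
    lifetimes,
    network_id: int = 0,
    pairs: list[tuple[int, int]] | None = None,
    method: str = "balance",
) -> list[EdgeRecord]:
    """Score both orientations of every true edge of ``adjacency``.

    ``pairs`` optionally maps node indices of the adjacency to snapshot
    columns (used by the Goodwin benchmark, where only the coupling
    species of each oscillator is scored).
    """
    G = np.asarray(adjacency)
    tau = np.asarray(lifetimes, dtype=float)
    recs: list[EdgeRecord] = []
    for i in range(G.shape[0]):
        for j in np.flatnonzero(G[i]):
            j = int(j)
            ci = i if pairs is None else pairs[i][0]
            cj = j if pairs is None else pairs[j][0]
            ps = score_pair(snapshots, ci, cj, tau[ci], tau[cj], method=method)
            recs.append(EdgeRecord(
                network_id=network_id, source=j, target=i,
                s_true=ps.s_ij, s_rev=ps.s_ji,
                correct=(ps.orientation == "j->i"),
                undetermined=(ps.orientation == "undetermined"),
                D_target=index_of_dispersion(snapshots, ci),
                D_source=index_of_dispersion(snapshots, cj),
                in_degree_source=int(G[j].sum()),
                in_degree_target=int(G[i].sum()),
                lifetime_ratio=float(tau[cj] / tau[ci]),
                N=snapshots.N,
            ))
    return recs


def _pooled_roc(records: list[EdgeRecord]) -> float:
    scores, labels = [], []
    for r in records:
        if np.isfinite(r.s_true):
            scores.append(r.s_true); labels.append(1)
        if np.isfinite(r.s_rev):
            scores.append(r.s_rev); labels.append(0)
    if len(set(labels)) < 2:
        return np.nan
    return roc_auc(scores, labels).auc


def _build_family(family: str, seed: int, V: int, E: int,
                  lifetime_range: tuple[float, float] | None,
                  rng: np.random.Generator):
    """One random benchmark instance: (model, adjacency-for-truth, column
    map, lifetimes-per-column)."""
    if family == "mm":
        G = _models.build_er_network(V, E, seed=seed)
        tau = (np.ones(V) if lifetime_range is None else
               np.exp(rng.uniform(*np.log(lifetime_range), V)))
        model = _models.build_michaelis_menten(G, lifetimes=tau)
        return model, G, None
    if family == "goodwin":
        G = _models.build_er_network(V, E, seed=seed)
        model = _models.build_goodwin(G)
        y = model.metadata["y_species"]
        return model, G, [(int(s),) for s in y]
    raise ValueError(f"unknown benchmark family {family!r}")


def benchmark_auc_vs_n(
    family: str = "mm",
    n_networks: int = 20,
    N_grid=(100, 1000, 10000),
    seed: int = 0,
    V: int = 10,
    E: int = 10,
    lifetime_range: tuple[float, float] | None = None,
    method: str = "balance",
    collect_records: bool = False,
):
    """Direction-classification AUC as a function of the snapshot count.

    Each random network is simulated once at ``max(N_grid)`` and
    subsampled down the grid, so the N-sweep measures pure sampling error
    on a common stationary ensemble.  Returns a table with the pooled AUC
    per N and the across-network standard deviation (and optionally the
    raw edge records).
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks for an across-network sd")
    N_grid = sorted(int(n) for n in N_grid)
    rng = np.random.default_rng(seed)
    all_records: dict[int, list[EdgeRecord]] = {n: [] for n in N_grid}
    per_net: dict[int, list[float]] = {n: [] for n in N_grid}
    for g in range(n_networks):
        net_seed = int(rng.integers(2**31 - 1))
        model, G, pairs = _build_family(family, net_seed, V, E,
                                        lifetime_range, rng)
        snap = sample_snapshots(model, max(N_grid),
                                seed=int(rng.integers(2**31 - 1)))
        for n in N_grid:
            sub = (snap if n == max(N_grid)
                   else subsample(snap, n, seed=int(rng.integers(2**31 - 1))))
            recs = score_true_edges(sub, G, model.tau, network_id=g,
                                    pairs=pairs, method=method)
            all_records[n].extend(recs)
            auc = _pooled_roc(recs)
            if np.isfinite(auc):
                per_net[n].append(auc)
    rows = [{"N": n,
             "auc": _pooled_roc(all_records[n]),
             "sd": float(np.std(per_net[n], ddof=1)) if len(per_net[n]) > 1 else np.nan,
             "n_networks": len(per_net[n]),
             "n_edges": len(all_records[n])}
            for n in N_grid]
    table = pd.DataFrame(rows)
    if collect_records:
        return table, [r for n in N_grid for r in all_records[n]]
    return table


def stratify_performance(
    records: list[EdgeRecord], by: str, bins
) -> pd.DataFrame:
    """Empirical success probability per covariate bin.

    Success means the arg-max orientation equals the true direction;
    undetermined calls count as failures (strictest reading).  Records
    with an undefined covariate are dropped.  The sd column is the
    binomial standard error; empty bins are reported with n = 0.
    """
    if not records:
        raise ValueError("no records to stratify")
    bins = np.asarray(bins, dtype=float)
    cov = np.array([r.covariate(by) for r in records])
    ok = np.array([r.correct for r in records], dtype=float)
    keep = np.isfinite(cov)
    cov, ok = cov[keep], ok[keep]
    idx = np.digitize(cov, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        sel = idx == b
        n = int(sel.sum())
        p = float(ok[sel].mean()) if n else np.nan
        sd = float(np.sqrt(p * (1 - p) / n)) if n else np.nan
        rows.append({"bin_lo": bins[b], "bin_hi": bins[b + 1],
                     "success_rate": p, "sd": sd, "n": n})
    return pd.DataFrame(rows)


#: true directed edges of the seven-gene model, 0-based (source, target)
ECOLI_TRUE_EDGES = [(0, 1), (2, 1), (6, 1), (0, 2), (1, 2), (4, 2), (6, 2),
                    (0, 3), (1, 4), (3, 6), (5, 6)]


def ecoli_case_study(
    N: int = 10000, seed: int = 0,
    params: "_models.EcoliParams | None" = None,
    burn_in: float | None = None, spacing: float | None = None,
) -> pd.DataFrame:
    """Orient every true edge of the E. coli model from one snapshot run.

    Returns a per-edge table (threshold 0: the arg-max direction is always
    called when defined) with node covariates: lifetimes ``1 / gamma``,
    in-degrees, and the index of dispersion of both endpoints.
    """
    model = _models.build_ecoli(params)
    snap = sample_snapshots(model, N, burn_in=burn_in, spacing=spacing,
                            seed=seed)
    rows = []
    for j, i in ECOLI_TRUE_EDGES:
        ps = score_pair(snap, i, j, model.tau[i], model.tau[j])
        rows.append({
            "source": j + 1, "target": i + 1,
            "label": f"{model.labels[j]}->{model.labels[i]}",
            "s_true": ps.s_ij, "s_rev": ps.s_ji,
            "orientation": ps.orientation,
            "correct": ps.orientation == "j->i",
            "tau_source": model.tau[j], "tau_target": model.tau[i],
            "in_degree_source": model.in_degree(j),
            "in_degree_target": model.in_degree(i),
            "D_source": index_of_dispersion(snap, j),
            "D_target": index_of_dispersion(snap, i),
        })
    return pd.DataFrame(rows)
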