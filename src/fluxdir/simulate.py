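"""Stationary snapshot sampling (Gillespie SSA) and an exact
truncated master-equation stationary solver used as a brute-force oracle.

Snapshots are independent-looking draws from the stationary law: a single
trajectory is burnt in for ``20 * max(tau)`` time units and then recorded
every ``10 * max(tau)``, which makes serial correlation negligible
(``exp(-spacing / tau) ~ 5e-5``).  An ``independent`` mode that burns in a
fresh trajectory per snapshot is available for paranoia at ~20x the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _ssa
from .models import NetworkModel

__all__ = ["SnapshotMatrix", "ExactDistribution", "sample_snapshots",
           "solve_stationary", "subsample"]


@dataclass
class SnapshotMatrix:
    """N x V matrix of stationary molecule counts, one row per snapshot."""

    data: np.ndarray
    labels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("snapshot data must be a 2-D matrix")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("snapshot entries must be integers")
            self.data = self.data.astype(np.int64)
        if (self.data < 0).any():
            raise ValueError("snapshot entries must be non-negative")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("need one label per column")

    @property
    def N(self) -> int:
        return self.data.shape[0]

    @property
    def V(self) -> int:
        return self.data.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.data[:, i]


def _default_times(model: NetworkModel, burn_in, spacing) -> tuple[float, float]:
    tau_max = float(np.max(model.tau))
    if burn_in is None:
        burn_in = 20.0 * tau_max
    if spacing is None:
        spacing = 10.0 * tau_max
    if burn_in < 0 or spacing < 0:
        raise ValueError("burn_in and spacing must be non-negative")
    return float(burn_in), float(spacing)


def sample_snapshots(
    model: NetworkModel,
    N: int,
    burn_in: float | None = None,
    spacing: float | None = None,
    seed: int = 0,
    independent: bool = False,
) -> SnapshotMatrix:
    """Exact stochastic simulation of ``model`` from the zero state,
    recording ``N`` snapshots of all copy numbers.

    The first snapshot is taken at ``t = burn_in`` and subsequent ones every
    ``spacing`` time units.  Identical arguments give bit-identical output.
    """
    if N < 1:
        raise ValueError("need at least one snapshot")
    burn_in, spacing = _default_times(model, burn_in, spacing)
    args = (model.V, model.n_latent, model.term_target, model.term_source,
            model.term_kind, model.term_a, model.term_k, model.term_n,
            model.birth_scale, model.conc_scale, model.tau,
            model.latent_rate)
    if independent:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s) % (2**32) for s in ss.generate_state(N)]
        rows = [_ssa.ssa_sample(*args, 1, burn_in, spacing, s)[0] for s in seeds]
        data = np.stack(rows)
    else:
        data = _ssa.ssa_sample(*args, N, burn_in, spacing, int(seed) % (2**32))
    prov = {
        "family": model.metadata.get("family"),
        "params": model.metadata.get("params"),
        "seed": int(seed),
        "burn_in": burn_in,
        "spacing": spacing,
        "independent": bool(independent),
        "lifetimes": model.tau.tolist(),
    }
    return SnapshotMatrix(data=data, labels=list(model.labels), provenance=prov)


def _ssa_python(model: NetworkModel, N: int, burn_in: float, spacing: float,
                seed: int) -> np.ndarray:
    """Reference Python SSA over the generic channel view (slow; used to
    cross-validate the compiled kernel on tiny models)."""
    rng = np.random.default_rng(seed)
    ns = model.V + model.n_latent
    x = np.zeros(ns)
    for l in range(model.n_latent):
        x[model.V + l] = rng.random()
    out = np.zeros((N, model.V), dtype=np.int64)
    t, t_next, rec = 0.0, burn_in, 0
    while rec < N:
        births = model.birth_rates(x)
        deaths = x[: model.V] / model.tau
        props = np.concatenate(
            [births, deaths, np.full(model.n_latent, model.latent_rate)])
        total = props.sum()
        if total <= 0:
            out[rec:] = x[: model.V].astype(np.int64)
            break
        dt = rng.exponential(1.0 / total)
        while rec < N and t_next <= t + dt:
            out[rec] = x[: model.V].astype(np.int64)
            rec += 1
            t_next += spacing
        if rec >= N:
            break
        t += dt
        ch = rng.choice(len(props), p=props / total)
        if ch < model.V:
            x[ch] += 1
        elif ch < 2 * model.V:
            x[ch - model.V] -= 1
        else:
            x[ch - model.V] = rng.random()
    return out


def subsample(snapshots: SnapshotMatrix, n: int, seed: int = 0) -> SnapshotMatrix:
    """Uniform random subset of ``n`` rows without replacement."""
    if not 1 <= n <= snapshots.N:
        raise ValueError(f"cannot draw {n} rows from {snapshots.N}")
    rng = np.random.default_rng(seed)
    rows = rng.choice(snapshots.N, size=n, replace=False)
    prov = dict(snapshots.provenance)
    prov["subsampled"] = {"n": int(n), "seed": int(seed)}
    return SnapshotMatrix(snapshots.data[rows], list(snapshots.labels), prov)


# ----------------------------------------------------------------------
# Exact stationary oracle
# ----------------------------------------------------------------------

@dataclass
class ExactDistribution:
    """Stationary probabilities on the truncated lattice
    ``{0..caps[0]} x ... x {0..caps[V-1]}`` (reflecting truncation).

    ``truncated_mass`` is the probability on the outer boundary (any
    component at its cap) -- a diagnostic for how much of the true law the
    truncation might be missing.
    """

    caps: np.ndarray
    P: np.ndarray
    truncated_mass: float
    labels: list[str]

    def marginal(self, i: int) -> np.ndarray:
        axes = tuple(a for a in range(self.P.ndim) if a != i)
        return self.P.sum(axis=axes)

    def joint(self, i: int, j: int) -> np.ndarray:
        """P(x_i, x_j) with x_i on axis 0 and x_j on axis 1."""
        if i == j:
            raise ValueError("need two distinct species")
        axes = tuple(a for a in range(self.P.ndim) if a not in (i, j))
        out = self.P.sum(axis=axes)
        return out if i < j else out.T

    def mean(self, i: int) -> float:
        p = self.marginal(i)
        return float(np.arange(len(p)) @ p)


def _pilot_caps(model: NetworkModel, safety: float = 8.0) -> np.ndarray:
    pilot = sample_snapshots(model, 200, seed=0)
    mean = pilot.data.mean(axis=0)
    caps = np.ceil(mean + safety * np.sqrt(np.maximum(mean, 1.0)))
    return np.maximum(caps, pilot.data.max(axis=0) + 2).astype(np.int64)


def solve_stationary(
    model: NetworkModel, caps: Sequence[int] | None = None
) -> ExactDistribution:
    """Solve the stationary master equation exactly on a truncated lattice.

    Scope: models with at most 3 species, no latent inputs, and at most
    10^6 truncated states.  Production out of the cap is suppressed
    (reflecting truncation); the returned law is normalized.
    """
    if model.n_latent:
        raise ValueError("exact solver does not support latent inputs")
    if model.V > 3:
        raise ValueError("exact solver limited to <= 3 species")
    caps = _pilot_caps(model) if caps is None else np.asarray(caps, dtype=np.int64)
    if caps.shape != (model.V,) or (caps < 1).any():
        raise ValueError("need one positive cap per species")
    sizes = caps + 1
    S = int(np.prod(sizes))
    if S > 10**6:
        raise ValueError(f"truncated state space too large ({S} states)")

    states = np.array(list(product(*[range(s) for s in sizes])), dtype=np.int64)
    strides = np.ones(model.V, dtype=np.int64)
    for i in range(model.V - 2, -1, -1):
        strides[i] = strides[i + 1] * sizes[i + 1]

    births = np.stack([model.birth_rates(x) for x in states])  # (S, V)
    idx = np.arange(S)
    rows, cols, data = [], [], []
    for i in range(model.V):
        up = states[:, i] < caps[i]
        rows.append(idx[up] + strides[i]); cols.append(idx[up])
        data.append(births[up, i])
        rows.append(idx[up]); cols.append(idx[up]); data.append(-births[up, i])
        down = states[:, i] > 0
        drate = states[down, i] / model.tau[i]
        rows.append(idx[down] - strides[i]); cols.append(idx[down]); data.append(drate)
        rows.append(idx[down]); cols.append(idx[down]); data.append(-drate)
    A = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(S, S),
    )
    # replace one balance equation by the normalization constraint
    B = sp.vstack([sp.csr_matrix(np.ones((1, S))), A[1:]]).tocsc()
    rhs = np.zeros(S)
    rhs[0] = 1.0
    p = spla.spsolve(B, rhs)
    if not np.all(np.isfinite(p)):
        raise ArithmeticError("stationary system is singular on this truncation")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    P = p.reshape(sizes)
    boundary = np.zeros(sizes, dtype=bool)
    for i in range(model.V):
        sl = [slice(None)] * model.V
        sl[i] = -1
        boundary[tuple(sl)] = True
    return ExactDistribution(
        caps=caps, P=P, truncated_mass=float(P[boundary].sum()),
        labels=list(model.labels),
    )
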