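"""Reaction-network data model and benchmark model families.

Every model is a collection of unit-jump birth--death channels: species
``i`` is produced at a state-dependent propensity and degrades with
per-molecule rate ``1/tau_i`` (propensity ``x_i / tau_i``).  Which species
appear in which production rates is recorded in a binary adjacency matrix
``G`` with ``G[i, j] = 1`` meaning *j regulates i* (an edge ``j -> i``).

Production rates are stored as a table of elementary terms (constant,
linear, Michaelis--Menten activation/repression, Hill repression) so that
the stochastic simulator can evaluate them in compiled code; the same
table backs the plain-Python :class:`ReactionChannel` view used by the
exact stationary solver and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TERM_CONST",
    "TERM_LINEAR",
    "TERM_MM_ACT",
    "TERM_MM_REP",
    "TERM_HILL_REP",
    "ConfigurationError",
    "ReactionChannel",
    "MMParams",
    "GoodwinParams",
    "EcoliParams",
    "NetworkModel",
    "build_er_network",
    "build_michaelis_menten",
    "build_goodwin",
    "build_ecoli",
    "validate_adjacency",
]

# Elementary production-rate term kinds.  With u = x[source] / conc_scale:
TERM_CONST = 0      # a
TERM_LINEAR = 1     # a * u
TERM_MM_ACT = 2     # a * u / (K + u)
TERM_MM_REP = 3     # a / (K + u)
TERM_HILL_REP = 4   # a / ((u / K)**n + 1)


class ConfigurationError(ValueError):
    """A model is mis-specified (bad sizes, non-positive parameters, ...)."""


@dataclass
class ReactionChannel:
    """A single reaction ``x_i -> x_i + d`` with propensity ``rate(x)``.

    ``rate`` takes the full (possibly latent-extended) state vector and
    returns a non-negative propensity.  ``d`` is +1 for production and -1
    for degradation; degradation propensities are always ``x_i / tau_i``.
    """

    species: int
    d: int
    rate: Callable[[np.ndarray], float]

    def __post_init__(self) -> None:
        if self.d not in (+1, -1):
            raise ConfigurationError(f"jump must be +1 or -1, got {self.d}")


@dataclass(frozen=True)
class MMParams:
    """Michaelis–Menten regulation parameters.

    ``lam`` is the maximal production rate per incoming edge (events/time),
    ``k`` the abundance at half-maximal rate (molecules), and ``basal`` the
    constant production rate given to nodes with no regulators.
    """

    lam: float = 100.0
    k: float = 100.0
    basal: float = 30.0

    def __post_init__(self) -> None:
        if min(self.lam, self.k, self.basal) <= 0:
            raise ConfigurationError("MM parameters must be positive")


@dataclass(frozen=True)
class GoodwinParams:
    """Goodwin oscillator parameters (x -> y -> z --| x negative feedback).

    The x species is produced at ``lam_x / ((z/k)**n + 1)``, y at
    ``lam_y * x`` plus ``coupling * y_j`` for each incoming oscillator
    edge, z at ``lam_z * y``; all species decay with lifetime ``tau``.

    ``coupling`` must keep the linear y-subsystem dissipative: along a
    directed cycle of oscillators each y feeds the next with gain
    ``coupling * tau``, so ``coupling * tau >= 1`` makes mean abundances
    grow without bound on cyclic coupling graphs.
    """

    lam_x: float = 150.0
    lam_y: float = 1.0
    lam_z: float = 1.0
    k: float = 50.0
    n: float = 10.0
    tau: float = 1.0
    coupling: float = 0.5

    def __post_init__(self) -> None:
        if min(self.lam_x, self.lam_y, self.lam_z, self.k, self.tau,
               self.coupling) <= 0:
            raise ConfigurationError("Goodwin parameters must be positive")
        if self.n < 1:
            raise ConfigurationError("Hill exponent n must be >= 1")


# Catalytic constants k0[m], Michaelis constants KM[m] (m = 1..13) and
# degradation rates gamma[i] (i = 1..7) of the seven-gene E. coli
# regulatory subnetwork (DREAM in-silico challenge parameterization).
_ECOLI_K0 = (0.0362, 1.0106, 0.3550, 0.7472, 2.4007, 0.8511, 2.8247,
             0.6081, 0.0903, 0.5264, 0.6541, 0.0090, 1.1236)
_ECOLI_KM = (0.1259, 1.7937, 1.2069, 1.2858, 0.8218, 1.7099, 1.6656,
             0.0202, 0.069, 0.9600, 1.0891, 0.5191, 0.4986)
_ECOLI_GAMMA = (0.4060, 2.1362, 3.8740, 0.7256, 0.7466, 0.4525, 0.9473)


@dataclass(frozen=True)
class EcoliParams:
    """Parameters of the seven-gene E. coli regulatory network model.

    Rates are written in concentration units ``x~ = x / omega``; the
    copy-number scale ``omega`` converts them to discrete propensities
    (production ``omega * r+(x~)``, degradation ``gamma_i * x_i``, hence
    lifetimes ``tau_i = 1 / gamma_i``).  The latent inputs D and U are
    piecewise-constant Uniform[0, 1] disturbances redrawn at exponential
    times with rate ``disturbance_rate``.
    """

    k0: tuple[float, ...] = _ECOLI_K0
    km: tuple[float, ...] = _ECOLI_KM
    gamma: tuple[float, ...] = _ECOLI_GAMMA
    omega: float = 100.0
    disturbance_rate: float = 1.0

    def __post_init__(self) -> None:
        if len(self.k0) != 13 or len(self.km) != 13 or len(self.gamma) != 7:
            raise ConfigurationError("need 13 (k0, KM) pairs and 7 gamma values")
        if min(min(self.k0), min(self.km), min(self.gamma)) <= 0:
            raise ConfigurationError("all rate parameters must be positive")
        if self.omega <= 0 or self.disturbance_rate <= 0:
            raise ConfigurationError("omega and disturbance_rate must be positive")


def validate_adjacency(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ConfigurationError(f"adjacency must be square, got shape {G.shape}")
    if not np.isin(G, (0, 1)).all():
        raise ConfigurationError("adjacency entries must be 0/1")
    if np.diag(G).any():
        raise ConfigurationError("adjacency must have a zero diagonal (no self-edges)")
    return G.astype(np.int8)


@dataclass
class NetworkModel:
    """A stochastic birth--death reaction network.

    State is a vector of ``V`` non-negative integer copy numbers, optionally
    extended by ``n_latent`` continuous latent inputs (appended at indices
    ``V ..``).  Production propensities are sums of elementary terms over the
    extended state; degradation of species ``i`` has propensity
    ``x_i / tau[i]``.
    """

    V: int
    tau: np.ndarray
    adjacency: np.ndarray
    labels: list[str]
    term_target: np.ndarray   # int64, production-rate term -> species index
    term_source: np.ndarray   # int64, extended-state index or -1 (constant)
    term_kind: np.ndarray     # int64, TERM_* code
    term_a: np.ndarray        # float64, amplitude
    term_k: np.ndarray        # float64, MM / Hill constant
    term_n: np.ndarray        # float64, Hill exponent
    birth_scale: np.ndarray   # float64 (V,), propensity = birth_scale * sum(terms)
    conc_scale: np.ndarray    # float64 (V + n_latent,), u = x / conc_scale
    n_latent: int = 0
    latent_rate: float = 0.0  # redraw rate of each latent input (per time)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.shape != (self.V,) or (self.tau <= 0).any():
            raise ConfigurationError("lifetimes must be positive, one per species")
        self.adjacency = validate_adjacency(self.adjacency)
        if self.adjacency.shape != (self.V, self.V):
            raise ConfigurationError("adjacency dimension does not match species count")
        for name in ("term_target", "term_source", "term_kind"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("term_a", "term_k", "term_n", "birth_scale", "conc_scale"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.labels) != self.V:
            raise ConfigurationError("need one label per species")

    # ------------------------------------------------------------------
    # Rate evaluation (reference Python path; the SSA uses a compiled twin)
    # ------------------------------------------------------------------
    def _term_value(self, m: int, x_ext: np.ndarray) -> float:
        s = self.term_source[m]
        u = 0.0 if s < 0 else float(x_ext[s]) / self.conc_scale[s]
        kind = self.term_kind[m]
        a = self.term_a[m]
        if kind == TERM_CONST:
            return a
        if kind == TERM_LINEAR:
            return a * u
        if kind == TERM_MM_ACT:
            return a * u / (self.term_k[m] + u)
        if kind == TERM_MM_REP:
            return a / (self.term_k[m] + u)
        if kind == TERM_HILL_REP:
            return a / ((u / self.term_k[m]) ** self.term_n[m] + 1.0)
        raise ConfigurationError(f"unknown term kind {kind}")

    def birth_rates(self, x_ext: Sequence[float]) -> np.ndarray:
        """Production propensities of all species at extended state ``x_ext``."""
        x_ext = np.asarray(x_ext, dtype=float)
        out = np.zeros(self.V)
        for m in range(len(self.term_target)):
            out[self.term_target[m]] += self._term_value(m, x_ext)
        return out * self.birth_scale

    def birth_rate(self, i: int, x_ext: Sequence[float]) -> float:
        return float(self.birth_rates(x_ext)[i])

    def death_rates(self, x_ext: Sequence[float]) -> np.ndarray:
        x = np.asarray(x_ext, dtype=float)[: self.V]
        return x / self.tau

    @property
    def channels(self) -> list[ReactionChannel]:
        """All reaction channels as (species, jump, propensity-callable)."""
        chans: list[ReactionChannel] = []
        for i in range(self.V):
            chans.append(ReactionChannel(i, +1, lambda x, i=i: self.birth_rate(i, x)))
            chans.append(
                ReactionChannel(i, -1, lambda x, i=i: float(x[i]) / self.tau[i])
            )
        return chans

    def in_degree(self, i: int) -> int:
        return int(self.adjacency[i].sum())

    def out_degree(self, j: int) -> int:
        return int(self.adjacency[:, j].sum())


def _adjacency_from_terms(V, term_target, term_source) -> np.ndarray:
    G = np.zeros((V, V), dtype=np.int8)
    for i, j in zip(term_target, term_source):
        if 0 <= j < V and j != i:
            G[i, j] = 1
    return G


# ----------------------------------------------------------------------
# Builders
# ----------------------------------------------------------------------

def build_er_network(V: int, E: int, seed: int) -> np.ndarray:
    """Random directed graph: E unordered pairs drawn uniformly, each edge
    assigned one uniformly random direction.

    At most one of ``G[i, j]``, ``G[j, i]`` is set for any pair, so each
    edge has a unique ground-truth direction.
    """
    if V < 2:
        raise ConfigurationError("need at least 2 nodes")
    n_pairs = V * (V - 1) // 2
    if not 0 <= E <= n_pairs:
        raise ConfigurationError(
            f"cannot place {E} edges among {n_pairs} unordered pairs of {V} nodes"
        )
    rng = np.random.default_rng(seed)
    pairs = [(a, b) for a in range(V) for b in range(a + 1, V)]
    chosen = rng.choice(n_pairs, size=E, replace=False)
    G = np.zeros((V, V), dtype=np.int8)
    for idx in chosen:
        a, b = pairs[idx]
        if rng.random() < 0.5:
            a, b = b, a
        G[b, a] = 1  # a -> b: state of a affects node b
    return G


def build_michaelis_menten(
    G: np.ndarray,
    params: MMParams | None = None,
    lifetimes: Sequence[float] | None = None,
) -> NetworkModel:
    """Gene-regulatory benchmark: each edge j -> i contributes a saturating
    production term ``lam * x_j / (x_j + k)`` to node i; nodes without
    regulators produce at the constant basal rate; every node degrades with
    its lifetime."""
    params = params or MMParams()
    G = validate_adjacency(G)
    V = G.shape[0]
    tau = np.ones(V) if lifetimes is None else np.asarray(lifetimes, dtype=float)
    if tau.shape != (V,):
        raise ConfigurationError("lifetimes length must equal the species count")

    tt, ts, tk, ta, tK, tn = [], [], [], [], [], []
    for i in range(V):
        parents = np.flatnonzero(G[i])
        if len(parents) == 0:
            tt.append(i); ts.append(-1); tk.append(TERM_CONST)
            ta.append(params.basal); tK.append(1.0); tn.append(1.0)
        for j in parents:
            tt.append(i); ts.append(int(j)); tk.append(TERM_MM_ACT)
            ta.append(params.lam); tK.append(params.k); tn.append(1.0)

    return NetworkModel(
        V=V, tau=tau, adjacency=G, labels=[f"x{i}" for i in range(V)],
        term_target=tt, term_source=ts, term_kind=tk,
        term_a=ta, term_k=tK, term_n=tn,
        birth_scale=np.ones(V), conc_scale=np.ones(V),
        metadata={"family": "mm", "params": params.__dict__.copy()},
    )


def build_goodwin(G: np.ndarray, params: GoodwinParams | None = None) -> NetworkModel:
    """Coupled Goodwin oscillators.

    ``G`` is the coupling graph over oscillators (triplets), not species:
    an oscillator edge j -> i adds the linear term ``y_j`` to the
    production rate of ``y_i``.  The returned model has ``3 * n_osc``
    species ordered (x_0, y_0, z_0, x_1, ...); metadata records the
    triplet -> species index map.
    """
    params = params or GoodwinParams()
    G = validate_adjacency(G)
    n_osc = G.shape[0]
    V = 3 * n_osc
    x_of, y_of, z_of = (lambda i: 3 * i), (lambda i: 3 * i + 1), (lambda i: 3 * i + 2)

    tt, ts, tk, ta, tK, tn = [], [], [], [], [], []
    for i in range(n_osc):
        # x_i: Hill-repressed by z_i
        tt.append(x_of(i)); ts.append(z_of(i)); tk.append(TERM_HILL_REP)
        ta.append(params.lam_x); tK.append(params.k); tn.append(params.n)
        # y_i: driven by x_i plus incoming coupling y_j
        tt.append(y_of(i)); ts.append(x_of(i)); tk.append(TERM_LINEAR)
        ta.append(params.lam_y); tK.append(1.0); tn.append(1.0)
        for j in np.flatnonzero(G[i]):
            tt.append(y_of(i)); ts.append(y_of(int(j))); tk.append(TERM_LINEAR)
            ta.append(params.coupling); tK.append(1.0); tn.append(1.0)
        # z_i: driven by y_i
        tt.append(z_of(i)); ts.append(y_of(i)); tk.append(TERM_LINEAR)
        ta.append(params.lam_z); tK.append(1.0); tn.append(1.0)

    labels = []
    for i in range(n_osc):
        labels += [f"x{i}", f"y{i}", f"z{i}"]
    adj = _adjacency_from_terms(V, tt, ts)
    return NetworkModel(
        V=V, tau=np.full(V, params.tau), adjacency=adj, labels=labels,
        term_target=tt, term_source=ts, term_kind=tk,
        term_a=ta, term_k=tK, term_n=tn,
        birth_scale=np.ones(V), conc_scale=np.ones(V),
        metadata={
            "family": "goodwin",
            "params": params.__dict__.copy(),
            "oscillator_graph": G.tolist(),
            "y_species": [y_of(i) for i in range(n_osc)],
        },
    )


# Production-rate term table of the seven-gene model: one row per
# Michaelis-Menten term (target gene 0-based, source 0-based or 7/8 for
# the latent disturbances D/U, kind, k0 index 0-based).
_ECOLI_TERMS = (
    (0, 7, TERM_MM_REP, 0),    # gene 1 repressed by disturbance D
    (1, 0, TERM_MM_REP, 1),    # gene 2 repressed by gene 1
    (1, 2, TERM_MM_ACT, 2),    # gene 2 activated by gene 3
    (1, 6, TERM_MM_ACT, 3),    # gene 2 activated by gene 7
    (2, 0, TERM_MM_ACT, 4),    # gene 3 activated by gene 1
    (2, 1, TERM_MM_REP, 5),    # gene 3 repressed by gene 2
    (2, 4, TERM_MM_ACT, 6),    # gene 3 activated by gene 5
    (2, 6, TERM_MM_ACT, 7),    # gene 3 activated by gene 7
    (3, 0, TERM_MM_REP, 8),    # gene 4 repressed by gene 1
    (4, 1, TERM_MM_REP, 9),    # gene 5 repressed by gene 2
    (5, 8, TERM_MM_ACT, 10),   # gene 6 activated by disturbance U
    (6, 3, TERM_MM_ACT, 11),   # gene 7 activated by gene 4
    (6, 5, TERM_MM_ACT, 12),   # gene 7 activated by gene 6
)


def build_ecoli(params: EcoliParams | None = None) -> NetworkModel:
    """Seven-gene E. coli regulatory subnetwork (DREAM in-silico model).

    Propensities: production ``omega * r_i+(x~, D, U)`` with
    ``x~ = x / omega``; degradation ``gamma_i * x_i`` (lifetime
    ``1 / gamma_i``).  D and U are piecewise-constant Uniform[0, 1]
    latent inputs carried as extended-state components 7 and 8.
    """
    params = params or EcoliParams()
    V = 7
    tt = [t[0] for t in _ECOLI_TERMS]
    ts = [t[1] for t in _ECOLI_TERMS]
    tk = [t[2] for t in _ECOLI_TERMS]
    ta = [params.k0[t[3]] for t in _ECOLI_TERMS]
    tK = [params.km[t[3]] for t in _ECOLI_TERMS]
    tn = [1.0] * len(_ECOLI_TERMS)
    conc_scale = np.concatenate([np.full(V, params.omega), np.ones(2)])
    adj = _adjacency_from_terms(V, tt, ts)
    return NetworkModel(
        V=V, tau=1.0 / np.asarray(params.gamma), adjacency=adj,
        labels=[f"gene{i + 1}" for i in range(V)],
        term_target=tt, term_source=ts, term_kind=tk,
        term_a=ta, term_k=tK, term_n=tn,
        birth_scale=np.full(V, params.omega), conc_scale=conc_scale,
        n_latent=2, latent_rate=params.disturbance_rate,
        metadata={"family": "ecoli", "params": {
            "omega": params.omega, "disturbance_rate": params.disturbance_rate}},
    )
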