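"""Direction inference from two-node joint snapshot distributions.

The stationary master equation of a unit-jump birth--death species obeys,
for every abundance level, a flux-balance relation: the mean production
rate at level ``x_i`` times ``P(x_i)`` equals the degradation flux
``(x_i + 1) P(x_i + 1) / tau_i``.  Conditioning the relation on the
abundance of a putative regulator ``x_j`` lets one *invert* the observed
joint law ``P(x_i, x_j)`` into an estimated conditional production-rate
profile ``r^(x_j)``.  The direction of an undirected edge (i, j) is then
called by comparing the local sensitivity (slope near the most probable
abundance) of the two inverted profiles: the steeper, suitably
normalized, slope wins.

Rate-inversion estimators
-------------------------
``balance`` (default)
    Full pairwise flux-balance inversion::

        r^(v) = m_v / tau_i
                + [ v (m_v - m_{v-1})
                    + (v+1) (m_v - m_{v+1}) P(v+1)/P(v) ] / tau_j

    with ``m_v = E[x_i | x_j = v]``.  Derived by multiplying the
    pair-marginalized stationary master equation by ``x_i`` and summing,
    eliminating the regulator's (unobserved) production rate through its
    own marginal balance plus a conditional-independence closure.  Exact
    when the regulator's production rate does not depend on unobserved
    variables correlated with ``x_i`` (e.g. a constitutive upstream node).

``moment``
    ``r^(v) = m_v / tau_i``.  Low variance, but the profile is a
    lifetime-filtered (smoothed) version of the true rate: its slope is
    attenuated by roughly ``tau_j / (tau_i + tau_j)``.

``recursion``
    Level-by-level ratio ``(x_i+1) P(x_i+1|v) / (tau_i P(x_i|v))``
    averaged over ``x_i`` with weights ``P(x_i|v)``; a consistent variant
    of ``moment``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulate import SnapshotMatrix

__all__ = ["JointHistogram", "RateProfile", "SensitivityFit", "PairScore",
           "joint_histogram", "joint_from_probabilities", "balance_residual",
           "invert_rate", "local_sensitivity", "score_pair", "orient_edges"]

#: minimum number of snapshots in an abundance bin for the bin to count
N_MIN_DEFAULT = 5


@dataclass
class JointHistogram:
    """Contingency counts of a species pair: ``counts[x_i, x_j]``.

    ``counts`` may hold probabilities instead of integers (``N_total`` is
    then the total mass, 1); all estimators work on either.
    """

    i: int
    j: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("joint counts must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def N_total(self) -> float:
        return float(self.counts.sum())

    @property
    def marginal_i(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def marginal_j(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "JointHistogram":
        return JointHistogram(self.j, self.i, self.counts.T)


def joint_histogram(snapshots: SnapshotMatrix, i: int, j: int) -> JointHistogram:
    """Exact (unsmoothed) contingency counts of columns ``i`` and ``j``."""
    if i == j:
        raise ValueError("need two distinct species")
    xi, xj = snapshots.column(i), snapshots.column(j)
    counts = np.zeros((int(xi.max()) + 1, int(xj.max()) + 1))
    np.add.at(counts, (xi, xj), 1.0)
    return JointHistogram(i, j, counts)


def joint_from_probabilities(P: np.ndarray, i: int, j: int) -> JointHistogram:
    """Wrap an exact joint law (e.g. from the stationary solver) so that the
    same estimators apply; pass ``n_min=0`` downstream."""
    return JointHistogram(i, j, np.asarray(P, dtype=float))


@dataclass
class RateProfile:
    """Estimated conditional production rate of ``target`` vs regulator level."""

    target: int
    regulator: int
    support: np.ndarray    # regulator abundance values
    rate_hat: np.ndarray   # estimated production rate (events/time)
    weight: np.ndarray     # snapshot count (or probability mass) per bin
    valid: np.ndarray      # bins with enough data for the estimate
    method: str = "balance"


def balance_residual(
    dist: Sequence[float], birth_profile: Sequence[float], tau_i: float
) -> np.ndarray:
    """Flux-balance residual ``r(x) P(x) - (x+1) P(x+1) / tau`` per level.

    Zero (to numerical precision) for any exact stationary marginal paired
    with its true mean conditional production rate; a self-consistency
    test for stationarity of observed data.
    """
    p = np.asarray(dist, dtype=float)
    r = np.asarray(birth_profile, dtype=float)
    if p.shape != r.shape:
        raise ValueError("profile must be defined on the distribution support")
    x = np.arange(len(p))
    up = np.append(p[1:], 0.0)
    return r * p - (x + 1) * up / tau_i


def _conditional_means(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = counts.sum(axis=0)
    xi = np.arange(counts.shape[0], dtype=float)
    with np.errstate(invalid="ignore"):
        m = (xi @ counts) / np.where(w > 0, w, np.nan)
    return m, w


def invert_rate(
    joint: JointHistogram,
    tau_i: float,
    method: str = "balance",
    tau_j: float | None = None,
    n_min: float = N_MIN_DEFAULT,
) -> RateProfile:
    """Invert a pair joint law into the conditional production-rate profile
    of species ``joint.i`` as a function of the level of ``joint.j``.

    ``tau_j`` is required for the default ``balance`` method (the
    regulator's flux terms enter the correction).  Bins holding fewer than
    ``n_min`` snapshots are masked invalid, never extrapolated.
    """
    if tau_i <= 0:
        raise ValueError("tau_i must be positive")
    if joint.N_total == 0:
        raise ValueError("empty joint histogram")
    c = joint.counts
    m, w = _conditional_means(c)
    v = np.arange(c.shape[1], dtype=float)
    defined = w > 0

    if method == "moment":
        rate = m / tau_i
    elif method == "recursion":
        xi = np.arange(c.shape[0], dtype=float)
        num = (xi[:-1] + 1.0) @ c[1:, :]   # sum over x_i of (x_i+1) c[x_i+1, v]
        with np.errstate(invalid="ignore"):
            rate = num / np.where(w > 0, w, np.nan) / tau_i
    elif method == "balance":
        if tau_j is None or tau_j <= 0:
            raise ValueError("balance inversion needs the regulator lifetime tau_j")
        m_filled = np.where(defined, m, 0.0)
        # neighbour conditional means; fall back to m_v where a neighbour
        # bin is unobserved (zero contribution to the difference terms)
        m_lo = np.where(np.roll(defined, 1), np.roll(m_filled, 1), m_filled)
        m_lo[0] = m_filled[0]
        m_hi = np.where(np.roll(defined, -1), np.roll(m_filled, -1), m_filled)
        m_hi[-1] = m_filled[-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.append(w[1:], 0.0) / np.where(w > 0, w, np.nan)
        corr = (v * (m_filled - m_lo) + (v + 1.0) * (m_filled - m_hi) * rho)
        rate = m / tau_i + corr / tau_j
    else:
        raise ValueError(f"unknown inversion method {method!r}")

    valid = defined & (w >= max(n_min, np.finfo(float).tiny)) & np.isfinite(rate)
    rate = np.where(valid, np.clip(rate, 0.0, None), np.nan)
    return RateProfile(
        target=joint.i, regulator=joint.j, support=v.astype(np.int64),
        rate_hat=rate, weight=w, valid=valid, method=method,
    )


@dataclass
class SensitivityFit:
    """Weighted local slope of a rate profile near the probable abundance."""

    J: float                    # rate change per regulator molecule; NaN if undefined
    window: tuple[int, int]     # inclusive regulator-level window used
    n_bins: int                 # valid bins inside the window
    mode: int                   # most probable regulator level

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.J))


def _empirical_mode(weights: np.ndarray) -> int:
    """Arg-max bin; ties broken toward the weighted mean (then downward)."""
    w = np.asarray(weights, dtype=float)
    peak = w.max()
    cand = np.flatnonzero(w == peak)
    if len(cand) == 1:
        return int(cand[0])
    mean = float(np.arange(len(w)) @ w) / w.sum()
    return int(cand[np.argmin(np.abs(cand - mean))])


def local_sensitivity(
    profile: RateProfile,
    marginal_j: Sequence[float] | None = None,
    min_bins: int = 3,
) -> SensitivityFit:
    """Slope of a weighted least-squares line through the rate profile over
    a window centred at the empirical mode of the regulator's marginal.

    The window spans one weighted standard deviation either side of the
    mode and widens symmetrically until it holds at least ``min_bins``
    valid bins (or the support is exhausted); with fewer than ``min_bins``
    valid bins overall the sensitivity is undefined (NaN), never an error.
    """
    w_j = profile.weight if marginal_j is None else np.asarray(marginal_j, float)
    if len(w_j) != len(profile.support) or w_j.sum() <= 0:
        raise ValueError("marginal must live on the profile support")
    x = profile.support.astype(float)
    mode = _empirical_mode(w_j)
    mean = float(x @ w_j) / w_j.sum()
    sd = float(np.sqrt(np.maximum(((x - mean) ** 2) @ w_j / w_j.sum(), 0.0)))

    half = max(sd, 1.0)
    lo, hi = mode - half, mode + half
    while True:
        sel = profile.valid & (x >= lo) & (x <= hi)
        if sel.sum() >= min_bins or (lo <= x[0] and hi >= x[-1]):
            break
        lo -= 1.0
        hi += 1.0
    n = int(sel.sum())
    if n < min_bins:
        return SensitivityFit(np.nan, (int(max(lo, x[0])), int(min(hi, x[-1]))), n, mode)

    xs, ys, ws = x[sel], profile.rate_hat[sel], profile.weight[sel]
    wsum = ws.sum()
    xb, yb = (xs @ ws) / wsum, (ys @ ws) / wsum
    den = ((xs - xb) ** 2) @ ws
    J = float(((xs - xb) * (ys - yb)) @ ws / den) if den > 0 else np.nan
    return SensitivityFit(J, (int(xs.min()), int(xs.max())), n, mode)


@dataclass
class PairScore:
    """Direction scores for one candidate pair.

    ``s_ij`` is the normalized evidence for the edge j -> i (j regulates
    i) and ``s_ji`` for i -> j; ``orientation`` is the arg-max call, or
    ``"undetermined"`` on ties and undefined scores.
    """

    i: int
    j: int
    J_ij: float
    J_ji: float
    s_ij: float
    s_ji: float
    orientation: str
    diagnostics: dict = field(default_factory=dict)

    def winning_score(self) -> float:
        if self.orientation == "undetermined":
            return np.nan
        return self.s_ij if self.orientation == "j->i" else self.s_ji

    def to_dict(self) -> dict:
        out = {"i": self.i, "j": self.j, "J_ij": self.J_ij, "J_ji": self.J_ji,
               "s_ij": self.s_ij, "s_ji": self.s_ji,
               "orientation": self.orientation}
        out.update(self.diagnostics)
        return out


def _directional_sensitivity(
    joint: JointHistogram, tau_tgt: float, tau_reg: float,
    method: str, n_min: float,
) -> SensitivityFit:
    """Sensitivity of the target's production rate to the regulator level.

    For the default ``balance`` method the slope is evaluated through its
    linear-response identity ``J = (1 + tau_tgt / tau_reg) *
    slope(<x_tgt | x_reg>) / tau_tgt``: under local linearity this equals
    the slope of the pointwise balance-inverted profile, but it inherits
    only the (low) variance of the conditional-mean slope instead of the
    noise-amplified level-by-level correction terms.
    """
    if method == "balance":
        prof = invert_rate(joint, tau_tgt, method="moment", n_min=n_min)
        fit = local_sensitivity(prof, joint.marginal_j)
        return SensitivityFit(fit.J * (1.0 + tau_tgt / tau_reg),
                              fit.window, fit.n_bins, fit.mode)
    prof = invert_rate(joint, tau_tgt, method=method, tau_j=tau_reg, n_min=n_min)
    return local_sensitivity(prof, joint.marginal_j)


def score_pair(
    snapshots: SnapshotMatrix,
    i: int,
    j: int,
    tau_i: float,
    tau_j: float,
    method: str = "balance",
    n_min: float = N_MIN_DEFAULT,
) -> PairScore:
    """Score both orientations of the pair (i, j) from snapshot columns
    ``i`` and ``j`` alone.

    The sensitivities are made comparable across pairs by weighting each
    with the *regulator's* abundance scale and persistence time::

        s_ij = |J_ij| * (mean(x_j) + 1) * tau_j

    ``|J| * mean(x_j)`` is the production-rate modulation of the target
    attributable to the regulator (its share of the production flux, for
    a near-linear coupling), and ``tau_j`` is the time over which a
    regulator fluctuation persists to be sensed -- so the score is the
    number of target molecules the regulator's standing abundance drives
    per regulator lifetime, an interaction flux.  The ``+1`` guards
    zero-mean columns.  A constant (zero-variance) column leaves that
    direction's score undefined (NaN), never raises.
    """
    joint = joint_histogram(snapshots, i, j)
    fit_ij = _directional_sensitivity(joint, tau_i, tau_j, method, n_min)
    fit_ji = _directional_sensitivity(joint.transpose(), tau_j, tau_i,
                                      method, n_min)

    xi, xj = snapshots.column(i).astype(float), snapshots.column(j).astype(float)
    sd_i = float(xi.std(ddof=1)) if len(xi) > 1 else 0.0
    sd_j = float(xj.std(ddof=1)) if len(xj) > 1 else 0.0
    s_ij = (abs(fit_ij.J) * (xj.mean() + 1.0) * tau_j
            if np.isfinite(fit_ij.J) and sd_j > 0 else np.nan)
    s_ji = (abs(fit_ji.J) * (xi.mean() + 1.0) * tau_i
            if np.isfinite(fit_ji.J) and sd_i > 0 else np.nan)

    if np.isfinite(s_ij) and np.isfinite(s_ji) and s_ij != s_ji:
        orientation = "j->i" if s_ij > s_ji else "i->j"
    else:
        orientation = "undetermined"
    diag = {
        "n_used": snapshots.N,
        "window_ij": fit_ij.window, "window_ji": fit_ji.window,
        "bins_ij": fit_ij.n_bins, "bins_ji": fit_ji.n_bins,
        "method": method,
    }
    return PairScore(i=i, j=j, J_ij=fit_ij.J, J_ji=fit_ji.J,
                     s_ij=s_ij, s_ji=s_ji, orientation=orientation,
                     diagnostics=diag)


def orient_edges(
    snapshots: SnapshotMatrix,
    edges: Sequence[tuple[int, int]],
    lifetimes: Sequence[float],
    threshold: float = 0.0,
    method: str = "balance",
    n_min: float = N_MIN_DEFAULT,
) -> tuple[list[PairScore], list[tuple[int, int, float]]]:
    """Resolve a list of undirected pairs independently.

    Returns per-pair scores and the emitted arrows ``(source, target,
    score)``: the winning direction of a pair produces an arrow iff its
    normalized score reaches ``threshold``.
    """
    tau = np.asarray(lifetimes, dtype=float)
    if tau.shape != (snapshots.V,) or (tau <= 0).any():
        raise ValueError("need one positive lifetime per species")
    scores: list[PairScore] = []
    arrows: list[tuple[int, int, float]] = []
    for a, b in edges:
        ps = score_pair(snapshots, int(a), int(b), tau[a], tau[b],
                        method=method, n_min=n_min)
        scores.append(ps)
        s = ps.winning_score()
        if np.isfinite(s) and s >= threshold:
            if ps.orientation == "j->i":
                arrows.append((int(b), int(a), float(s)))
            else:
                arrows.append((int(a), int(b), float(s)))
    return scores, arrows
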