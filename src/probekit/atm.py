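"""Automated threshold mapping (ATM).

Locates the knee of a retention curve and returns a suggested cut-off
``x_atm`` together with a target interval (fuzzy boundary between the first
two clusters) and a wider tolerance interval (hotspot anchored at the two
cluster membership maxima).

Pipeline: project each curve point onto a chosen subspace (default: the
retained-probe-set axis), cluster the projected values with fuzzy c-means,
decode the hotspot from the first two clusters (descending-centroid order,
so cluster 1 is the plateau side), extract the fuzzy boundary, and invert
the monotone retained-set component at the boundary mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from probekit.errors import AtmError
from probekit.retention import RetentionCurve

__all__ = [
    "DEFAULT_BASIS",
    "FuzzyPartition",
    "ATMResult",
    "AtmConfig",
    "projector",
    "project",
    "fcm",
    "fcm_best",
    "fukuyama_sugeno",
    "partition_entropy",
    "select_c",
    "hotspot_interval",
    "fuzzy_boundary",
    "interpolate_xatm",
    "run_atm",
    "percent_relative_difference",
]

#: Project (x, pairs, sets) onto the retained-probe-set coordinate.
DEFAULT_BASIS = np.array([[0.0], [0.0], [1.0]])


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def projector(basis: np.ndarray) -> np.ndarray:
    """Orthogonal projector P = B (B^T B)^-1 B^T onto the column space of B."""
    B = np.atleast_2d(np.asarray(basis, dtype=float))
    if B.ndim != 2:
        raise AtmError("basis must be a 2-D matrix")
    gram = B.T @ B
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise AtmError("basis columns are linearly dependent")
    return B @ np.linalg.solve(gram, B.T)


def project(
    curve: RetentionCurve, basis: np.ndarray | None = None
) -> np.ndarray:
    """Map each curve point (x, y1, y2) to its coordinates in the basis.

    Returns an (n,) array for a rank-1 basis (the default), else (n, r).
    With the default basis the learning set equals the retained-probe-set
    column of the curve.
    """
    B = DEFAULT_BASIS if basis is None else np.atleast_2d(
        np.asarray(basis, dtype=float)
    )
    if B.shape[0] != 3:
        B = B.T
    if B.shape[0] != 3:
        raise AtmError("basis must have 3 rows (threshold, pairs, sets)")
    projector(B)  # validates rank
    V = np.column_stack(
        [curve.thresholds, curve.retained_pairs, curve.retained_sets]
    ).astype(float)
    coords = np.linalg.solve(B.T @ B, B.T @ V.T).T  # (n, r)
    if coords.shape[1] == 1:
        return coords[:, 0]
    return coords


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class FuzzyPartition:
    c: int
    q: float
    memberships: np.ndarray  # (c, n); columns sum to 1
    centroids: np.ndarray  # (c,)
    objective: float
    n_iter: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.memberships.shape[1]


def _fcm_memberships(data: np.ndarray, centroids: np.ndarray, q: float) -> np.ndarray:
    d = np.abs(data[None, :] - centroids[:, None])  # (c, n)
    zero = d < 1e-12
    m = np.empty_like(d)
    power = 2.0 / (q - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-power)
        m = inv / inv.sum(axis=0, keepdims=True)
    # a point coinciding with one or more centroids: split membership there
    any_zero = zero.any(axis=0)
    if np.any(any_zero):
        cols = np.where(any_zero)[0]
        m[:, cols] = 0.0
        for j in cols:
            hits = np.where(zero[:, j])[0]
            m[hits, j] = 1.0 / hits.size
    return m


def fcm(
    data: np.ndarray,
    c: int,
    q: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | np.random.Generator | None = None,
) -> FuzzyPartition:
    """Fuzzy c-means on 1-D data via alternating optimization.

    Iterates membership and centroid updates until the largest centroid
    shift falls below ``tol``.  Clusters are relabelled in descending
    centroid order, so cluster index 0 is the plateau side of a retention
    curve.  Non-convergence is flagged on the result, not fatal.
    """
    data = np.asarray(data, dtype=float).ravel()
    n = data.size
    if not n > c:
        raise AtmError(f"need more data points ({n}) than clusters ({c})")
    if c < 2:
        raise AtmError("c must be at least 2")
    if q <= 1.0:
        raise AtmError("fuzzifier q must be > 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    uniq = np.unique(data)
    if uniq.size >= c:
        centroids = rng.choice(uniq, size=c, replace=False).astype(float)
    else:  # degenerate data: jitter around the existing values
        centroids = rng.choice(data, size=c, replace=True).astype(float)
        centroids = centroids + rng.normal(0.0, 1e-9, size=c)

    history: list[float] = []
    converged = False
    n_iter = 0
    m = _fcm_memberships(data, centroids, q)
    for n_iter in range(1, max_iter + 1):
        mq = m ** q
        weights = mq.sum(axis=1)
        weights = np.where(weights < 1e-300, 1e-300, weights)
        new_centroids = (mq @ data) / weights
        m = _fcm_memberships(data, new_centroids, q)
        d2 = (data[None, :] - new_centroids[:, None]) ** 2
        history.append(float(((m ** q) * d2).sum()))
        shift = float(np.max(np.abs(new_centroids - centroids)))
        centroids = new_centroids
        if shift < tol:
            converged = True
            break

    order = np.argsort(-centroids, kind="stable")
    return FuzzyPartition(
        c=c,
        q=q,
        memberships=m[order],
        centroids=centroids[order],
        objective=history[-1],
        n_iter=n_iter,
        converged=converged,
        objective_history=history,
    )


def fcm_best(
    data: np.ndarray,
    c: int,
    q: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
    n_restarts: int = 10,
) -> FuzzyPartition:
    """Best of ``n_restarts`` seeded runs by lowest objective."""
    rng = np.random.default_rng(seed)
    best: FuzzyPartition | None = None
    for _ in range(max(1, n_restarts)):
        part = fcm(data, c, q=q, tol=tol, max_iter=max_iter, seed=rng)
        if best is None or part.objective < best.objective:
            best = part
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# cluster validity
# ---------------------------------------------------------------------------

def fukuyama_sugeno(partition: FuzzyPartition, data: np.ndarray) -> float:
    """Compactness-minus-separation index; lower is better."""
    data = np.asarray(data, dtype=float).ravel()
    grand = data.mean()
    d2 = (data[None, :] - partition.centroids[:, None]) ** 2
    sep = (partition.centroids - grand) ** 2
    mq = partition.memberships ** partition.q
    return float((mq * (d2 - sep[:, None])).sum())


def partition_entropy(partition: FuzzyPartition) -> float:
    """PE = -(1/n) sum_j sum_i m_ij ln m_ij; lower is better (0 = crisp)."""
    m = partition.memberships
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(m > 0, m * np.log(m), 0.0)
    return float(-terms.sum() / partition.n)


_INDEX_FUNCS = {
    "fs": lambda part, data: fukuyama_sugeno(part, data),
    "pe": lambda part, data: partition_entropy(part),
}


def select_c(
    data: np.ndarray,
    c_range: Sequence[int] = range(2, 7),
    index_name: str = "fs",
    q: float = 2.0,
    seed: int | None = None,
    n_restarts: int = 10,
) -> int:
    """Pick the cluster count minimizing a validity index over ``c_range``."""
    if index_name not in _INDEX_FUNCS:
        raise AtmError(f"unknown validity index {index_name!r} (use fs|pe)")
    data = np.asarray(data, dtype=float).ravel()
    best_c: int | None = None
    best_score = np.inf
    for c in c_range:
        part = fcm_best(data, c, q=q, seed=seed, n_restarts=n_restarts)
        score = _INDEX_FUNCS[index_name](part, data)
        if score < best_score:
            best_score = score
            best_c = c
    if best_c is None:
        raise AtmError("empty c_range")
    return best_c


# ---------------------------------------------------------------------------
# hotspot, boundary, interpolation
# ---------------------------------------------------------------------------

def hotspot_interval(
    partition: FuzzyPartition, curve: RetentionCurve
) -> tuple[tuple[float, float], np.ndarray]:
    """Tolerance interval from the first two clusters' membership maxima.

    The anchors are the curve points with maximal membership in the plateau
    cluster and in the second (early-drop) cluster; the hotspot index set J
    runs between them.
    """
    if partition.n != len(curve):
        raise AtmError("partition and curve lengths differ")
    m1, m2 = partition.memberships[0], partition.memberships[1]
    j_inf = int(np.argmax(m1))
    j_sup = int(np.argmax(m2))
    if j_inf > j_sup:
        raise AtmError(
            "membership maxima out of order (plateau anchor after drop "
            "anchor); try a different c or fuzzifier q"
        )
    J = np.arange(j_inf, j_sup + 1)
    interval = (
        float(curve.thresholds[j_inf]),
        float(curve.thresholds[j_sup]),
    )
    return interval, J


def fuzzy_boundary(
    partition: FuzzyPartition,
    epsilon: float = 0.1,
    eps_min: float = 1e-3,
) -> tuple[np.ndarray, int, int, float]:
    """Indices belonging to both of the first two clusters at level epsilon.

    Returns ``(indices, l, k, epsilon_used)`` where ``l``/``k`` are the
    smallest/largest boundary index.  If no element reaches ``epsilon`` the
    level is halved down to ``eps_min`` before giving up.
    """
    m1, m2 = partition.memberships[0], partition.memberships[1]
    overlap = np.minimum(m1, m2)
    eps = float(epsilon)
    while eps >= eps_min:
        idx = np.where(overlap >= eps)[0]
        if idx.size:
            return idx, int(idx.min()), int(idx.max()), eps
        eps /= 2.0
    raise AtmError(
        f"no fuzzy boundary found down to epsilon={eps_min}; the first two "
        "clusters do not overlap"
    )


def _invert_monotone(
    x: np.ndarray, y: np.ndarray, target: float
) -> float:
    """Piecewise-linear inverse of a non-increasing sequence.

    An exact flat run equal to ``target`` maps to the midpoint of the run.
    ``target`` must lie within [y.min(), y.max()].
    """
    hits = np.where(y == target)[0]
    if hits.size:
        return float(0.5 * (x[hits.min()] + x[hits.max()]))
    for i in range(len(y) - 1):
        if y[i] > target > y[i + 1]:
            frac = (y[i] - target) / (y[i] - y[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    raise AtmError("target not bracketed by curve values")


def _lagrange_inverse(x: np.ndarray, y: np.ndarray, target: float) -> float:
    """Quadratic (degree <= 2) inverse through the bracketing knots."""
    for i in range(len(y) - 1):
        if y[i] >= target >= y[i + 1] and y[i] > y[i + 1]:
            lo = max(0, i - 1)
            hi = min(len(y), i + 2)
            ys = y[lo:hi].astype(float)
            xs = x[lo:hi].astype(float)
            uniq_mask = np.concatenate(([True], np.diff(ys) != 0))
            ys, xs = ys[uniq_mask], xs[uniq_mask]
            if ys.size < 2:
                return float(xs[0])
            deg = min(2, ys.size - 1)
            coeffs = np.polyfit(ys, xs, deg)
            return float(np.polyval(coeffs, target))
    return _invert_monotone(x, y, target)


def interpolate_xatm(
    curve: RetentionCurve,
    boundary_idx: np.ndarray,
    projected: np.ndarray,
    method: str = "linear",
) -> tuple[float, float]:
    """Suggested threshold from the boundary mean of projected values.

    ``u_bar`` is the arithmetic mean of the projected values over the
    boundary set; ``x_atm`` is the piecewise-linear (or Lagrange) inverse of
    the projected component over the span of the boundary.  Returns
    ``(x_atm, u_bar)``.  A mean outside the local range is clamped to the
    nearest boundary endpoint with a warning.
    """
    boundary_idx = np.asarray(boundary_idx, dtype=int)
    if boundary_idx.size == 0:
        raise AtmError("empty boundary set")
    u_bar = float(np.mean(projected[boundary_idx]))
    lo, hi = int(boundary_idx.min()), int(boundary_idx.max())
    xs = curve.thresholds[lo:hi + 1]
    ys = np.asarray(projected[lo:hi + 1], dtype=float)
    if u_bar > ys.max():
        warnings.warn("boundary mean above local curve range; clamping",
                      stacklevel=2)
        return float(xs[0]), u_bar
    if u_bar < ys.min():
        warnings.warn("boundary mean below local curve range; clamping",
                      stacklevel=2)
        return float(xs[-1]), u_bar
    if method == "lagrange":
        return _lagrange_inverse(xs, ys, u_bar), u_bar
    return _invert_monotone(xs, ys, u_bar), u_bar


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class AtmConfig:
    c: int = 3
    auto_c: bool = False
    c_range: Sequence[int] = tuple(range(2, 7))
    q: float = 2.0
    epsilon: float = 0.1
    index_name: str = "fs"
    seed: int | None = 0
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 300
    basis: np.ndarray | None = None
    normalize: bool = True
    interp: str = "linear"


@dataclass
class ATMResult:
    x_atm: float
    target_interval: tuple[float, float]  # [x_l, x_k]
    tolerance_interval: tuple[float, float]  # [x_inf(J), x_sup(J)]
    boundary_l: int
    boundary_k: int
    hotspot_J: np.ndarray
    boundary_mean: float
    epsilon_used: float
    index_name: str
    index_value: float
    c: int
    low_confidence: bool
    partition: FuzzyPartition

    def to_dict(self) -> dict:
        return {
            "x_atm": self.x_atm,
            "target_interval": list(self.target_interval),
            "tolerance_interval": list(self.tolerance_interval),
            "index": self.index_name,
            "index_value": self.index_value,
            "c": self.c,
            "epsilon_used": self.epsilon_used,
            "low_confidence": self.low_confidence,
        }


def run_atm(curve: RetentionCurve, config: AtmConfig | None = None) -> ATMResult:
    """Full threshold-mapping pipeline on a retention curve.

    Deterministic given ``config.seed``.  Curve values are rescaled to
    [0, 1] before clustering so the result is invariant to chip size;
    intervals are reported in original threshold units.
    """
    cfg = config or AtmConfig()
    data = project(curve, cfg.basis)
    if data.ndim != 1:
        raise AtmError("run_atm requires a rank-1 basis")
    span = data.max() - data.min()
    if span <= 0:
        raise AtmError("projected curve is constant; no knee to map")
    learn = (data - data.min()) / span if cfg.normalize else data.copy()

    c = cfg.c
    if cfg.auto_c:
        c = select_c(
            learn,
            cfg.c_range,
            index_name=cfg.index_name,
            q=cfg.q,
            seed=cfg.seed,
            n_restarts=cfg.n_restarts,
        )
    partition = fcm_best(
        learn,
        c,
        q=cfg.q,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
        n_restarts=cfg.n_restarts,
    )
    index_value = _INDEX_FUNCS[cfg.index_name](partition, learn)

    tol_interval, J = hotspot_interval(partition, curve)
    idx, l, k, eps_used = fuzzy_boundary(partition, cfg.epsilon)
    # keep the boundary inside the hotspot so x_atm ∈ I' ⊆ I holds
    idx = idx[(idx >= J[0]) & (idx <= J[-1])]
    if idx.size == 0:
        raise AtmError(
            "fuzzy boundary lies outside the hotspot; try a different c or q"
        )
    l, k = int(idx.min()), int(idx.max())
    target_interval = (
        float(curve.thresholds[l]),
        float(curve.thresholds[k]),
    )
    x_atm, u_bar = interpolate_xatm(curve, idx, learn, method=cfg.interp)
    x_atm = float(np.clip(x_atm, target_interval[0], target_interval[1]))

    thr_span = curve.thresholds[-1] - curve.thresholds[0]
    wide = (tol_interval[1] - tol_interval[0]) > 0.5 * thr_span
    # a real knee curve has a plateau: a long run of near-maximal values.
    norm = (data - data.min()) / span
    run = best_run = 0
    for v in norm:
        run = run + 1 if v >= 0.98 else 0
        best_run = max(best_run, run)
    no_plateau = best_run < 0.1 * norm.size
    low_confidence = bool(wide or no_plateau or not partition.converged)

    return ATMResult(
        x_atm=x_atm,
        target_interval=target_interval,
        tolerance_interval=tol_interval,
        boundary_l=l,
        boundary_k=k,
        hotspot_J=J,
        boundary_mean=u_bar,
        epsilon_used=eps_used,
        index_name=cfg.index_name,
        index_value=index_value,
        c=c,
        low_confidence=low_confidence,
        partition=partition,
    )


def percent_relative_difference(selected: float, suggested: float) -> float:
    """100 * |selected - suggested| / selected."""
    if selected == 0:
        raise ValueError("selected cut-off must be nonzero")
    return 100.0 * abs(selected - suggested) / abs(selected)
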