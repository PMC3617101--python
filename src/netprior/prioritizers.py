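"""The four node-scoring algorithms plus exact linear-solve oracles.

Two local methods and two global methods rank every network object by its
proximity to the differentially expressed genes (the seed set):

* **Neighborhood scoring** — a node's score depends half on its own fold
  change and half on the average fold change of its direct neighbors.
* **Interconnectivity** — sums, over all DEGs, a pairwise score combining
  direct adjacency and the shared-neighbor count, normalized by the
  geometric mean of the two degrees.
* **Random walk with restart** — steady-state visitation probabilities of a
  walk on the column-stochastic adjacency that restarts at the seeds with
  probability alpha each step.
* **Network propagation** — flow smoothing of the binary seed indicator on
  the symmetrically degree-normalized adjacency.

Scorer classes follow the fit/transform idiom: ``fit`` binds and
preprocesses a network, ``transform`` maps a :class:`~netprior.signature.NodeSignal`
to a score vector aligned with the network's node order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .network import (InteractionNetwork, build_adjacency,
                      normalize_stochastic, normalize_symmetric)
from .signature import NodeSignal

__all__ = [
    "DiffusionConfig",
    "ConvergenceError",
    "NeighborhoodScorer",
    "InterconnectivityScorer",
    "RandomWalkScorer",
    "NetworkPropagationScorer",
    "neighborhood_score",
    "interconnectivity_pair",
    "interconnectivity_score",
    "random_walk",
    "network_propagation",
    "diffusion_exact",
    "METHODS",
]

METHODS = ("propagation", "random_walk", "interconnectivity", "neighborhood")


@dataclass
class DiffusionConfig:
    """Shared knobs of the two diffusion methods.

    alpha is the restart probability of the random walk and the smoothing
    weight of network propagation (both default 0.5); iteration stops when
    the L1 change drops below ``tol`` (1e-6).
    """

    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class ConvergenceError(RuntimeError):
    """Diffusion failed to converge within max_iter iterations."""

    def __init__(self, method: str, residual: float, max_iter: int):
        super().__init__(
            f"{method} did not converge within {max_iter} iterations "
            f"(last L1 residual {residual:.3e})")
        self.residual = residual


def _seed_indicator(net: InteractionNetwork, deg_nodes: Iterable[str]) -> np.ndarray:
    deg_nodes = set(deg_nodes)
    if not deg_nodes:
        raise ValueError("seed set (DEG nodes) must be non-empty")
    idx = net.index()
    unknown = deg_nodes - set(idx)
    if unknown:
        raise ValueError(f"seed nodes not in network: {sorted(unknown)[:5]}")
    ind = np.zeros(net.n_nodes)
    for n in deg_nodes:
        ind[idx[n]] = 1.0
    return ind


class _NetworkScorer(BaseEstimator):
    """Base class: ``fit`` binds a network, ``transform`` scores a signal."""

    method: str = ""

    def fit(self, net: InteractionNetwork, y=None) -> "_NetworkScorer":
        self.net_ = net
        self.adjacency_ = build_adjacency(net)
        self.degrees_ = np.asarray(self.adjacency_.sum(axis=0)).ravel()
        self._prepare()
        return self

    def _prepare(self) -> None:  # pragma: no cover - overridden
        pass

    def transform(self, signal: NodeSignal) -> np.ndarray:
        raise NotImplementedError

    def fit_transform(self, net: InteractionNetwork,
                      signal: NodeSignal) -> np.ndarray:
        return self.fit(net).transform(signal)

    def _check_signal(self, signal: NodeSignal) -> None:
        if len(signal.weights) != self.net_.n_nodes:
            raise ValueError("signal is not aligned with the fitted network")


class NeighborhoodScorer(_NetworkScorer):
    """score(i) = 0.5*FC(i) + 0.5 * mean over neighbors of FC(n).

    Nodes with zero fold change and no differentially expressed neighbor
    score exactly 0; an empty neighborhood contributes 0 to the second term.
    """

    method = "neighborhood"

    def transform(self, signal: NodeSignal) -> np.ndarray:
        self._check_signal(signal)
        w = np.asarray(signal.weights, dtype=float)
        neighbor_sum = self.adjacency_ @ w
        with np.errstate(invalid="ignore", divide="ignore"):
            neighbor_mean = np.where(self.degrees_ > 0,
                                     neighbor_sum / np.maximum(self.degrees_, 1),
                                     0.0)
        return 0.5 * w + 0.5 * neighbor_mean


class InterconnectivityScorer(BaseEstimator):
    """Sum of pairwise interconnectivity to every DEG.

    ICN(i,j) = (e(i,j) + |N(i) ∩ N(j)|) / norm(i,j) with the geometric-mean
    degree normalization sqrt(deg(i)*deg(j)) by default
    (``normalization="geometric"``) or 2/(deg(i)+deg(j)) with
    ``normalization="harmonic"``. Shared-neighbor counts are the off-diagonal
    entries of A², computed sparsely and restricted to DEG columns so large
    networks stay tractable.
    """

    method = "interconnectivity"

    def __init__(self, normalization: str = "geometric"):
        self.normalization = normalization

    def fit(self, net: InteractionNetwork, y=None) -> "InterconnectivityScorer":
        if self.normalization not in ("geometric", "harmonic"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.net_ = net
        self.adjacency_ = build_adjacency(net)
        self.degrees_ = np.asarray(self.adjacency_.sum(axis=0)).ravel()
        return self

    def pair(self, i: str, j: str) -> float:
        """ICN for a single node pair (0 if either node is isolated)."""
        if i == j:
            raise ValueError("interconnectivity of a node with itself is undefined")
        idx = self.net_.index()
        ii, jj = idx[i], idx[j]
        di, dj = self.degrees_[ii], self.degrees_[jj]
        if di == 0 or dj == 0:
            return 0.0
        shared = len(self.net_.neighbors(i) & self.net_.neighbors(j))
        e = 1.0 if self.net_.has_edge(i, j) else 0.0
        return (e + shared) / self._norm(di, dj)

    def _norm(self, di: np.ndarray, dj: np.ndarray):
        if self.normalization == "geometric":
            return np.sqrt(di * dj)
        return (di + dj) / 2.0

    def transform(self, signal: NodeSignal) -> np.ndarray:
        deg_nodes = signal.deg_nodes
        if not deg_nodes:
            raise ValueError("seed set (DEG nodes) must be non-empty")
        idx = self.net_.index()
        cols = np.array(sorted(idx[d] for d in deg_nodes), dtype=int)
        A = self.adjacency_
        sub = A[:, cols]                       # direct edges to DEGs
        shared = A @ sub                       # A² restricted: shared neighbors
        numer = (sub + shared).toarray()
        # remove the self term: A²[i,i] = deg(i) and e(i,i)=0
        for k, c in enumerate(cols):
            numer[c, k] = 0.0
        di = self.degrees_[:, None]
        dj = self.degrees_[cols][None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = self._norm(di, dj)
            icn = np.where((di > 0) & (dj > 0), numer / denom, 0.0)
        return icn.sum(axis=1)

    def fit_transform(self, net: InteractionNetwork,
                      signal: NodeSignal) -> np.ndarray:
        return self.fit(net).transform(signal)


class RandomWalkScorer(_NetworkScorer):
    """Random walk with restart on the column-stochastic adjacency.

    P_{t+1} = (1-alpha) A' P_t + alpha P_0, P_0 uniform over the seed set.
    Mass sitting on dangling (degree-0) columns is redirected to the restart
    vector each iteration so the update stays stochastic; the returned
    vector sums to 1.
    """

    method = "random_walk"

    def __init__(self, alpha: float = 0.5, tol: float = 1e-6,
                 max_iter: int = 10000):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def _prepare(self) -> None:
        self._cfg = DiffusionConfig(self.alpha, self.tol, self.max_iter)
        norm = normalize_stochastic(self.adjacency_)
        self._A = norm.matrix
        self._dangling = norm.dangling

    def transform(self, signal: NodeSignal, callback=None) -> np.ndarray:
        """Iterate to the stationary vector; ``callback(p)`` is invoked with
        the probability vector after every update (used to monitor mass
        conservation)."""
        self._check_signal(signal)
        p0 = _seed_indicator(self.net_, signal.deg_nodes)
        p0 /= p0.sum()
        alpha = self._cfg.alpha
        p = p0.copy()
        for _ in range(self._cfg.max_iter):
            dangling_mass = p[self._dangling].sum()
            p_next = ((1 - alpha) * (self._A @ p)
                      + (alpha + (1 - alpha) * dangling_mass) * p0)
            residual = np.abs(p_next - p).sum()
            p = p_next
            if callback is not None:
                callback(p)
            if residual < self._cfg.tol:
                return p
        raise ConvergenceError("random_walk", residual, self._cfg.max_iter)


class NetworkPropagationScorer(_NetworkScorer):
    """Flow propagation on the symmetric degree-normalized adjacency.

    F_0 is 1 on seed nodes and 0 elsewhere; F_{t+1} = alpha A' F_t +
    (1-alpha) F_0, stopped when the L1 change drops below tol (1e-6).
    """

    method = "propagation"

    def __init__(self, alpha: float = 0.5, tol: float = 1e-6,
                 max_iter: int = 10000):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def _prepare(self) -> None:
        self._cfg = DiffusionConfig(self.alpha, self.tol, self.max_iter)
        self._A = normalize_symmetric(self.adjacency_).matrix

    def transform(self, signal: NodeSignal) -> np.ndarray:
        self._check_signal(signal)
        f0 = _seed_indicator(self.net_, signal.deg_nodes)
        alpha = self._cfg.alpha
        f = f0.copy()
        for _ in range(self._cfg.max_iter):
            f_next = alpha * (self._A @ f) + (1 - alpha) * f0
            residual = np.abs(f_next - f).sum()
            f = f_next
            if residual < self._cfg.tol:
                return f
        raise ConvergenceError("network_propagation", residual,
                               self._cfg.max_iter)


# -- functional wrappers ----------------------------------------------

def neighborhood_score(net: InteractionNetwork,
                       signal: NodeSignal) -> np.ndarray:
    return NeighborhoodScorer().fit_transform(net, signal)


def interconnectivity_pair(net: InteractionNetwork, i: str, j: str,
                           normalization: str = "geometric") -> float:
    return InterconnectivityScorer(normalization).fit(net).pair(i, j)


def interconnectivity_score(net: InteractionNetwork,
                            deg_nodes: Iterable[str],
                            normalization: str = "geometric") -> np.ndarray:
    signal = NodeSignal(weights=np.zeros(net.n_nodes),
                        deg_nodes=set(deg_nodes), nodes=net.nodes)
    return InterconnectivityScorer(normalization).fit(net).transform(signal)


def _as_signal(net: InteractionNetwork,
               deg_nodes: Iterable[str]) -> NodeSignal:
    return NodeSignal(weights=np.zeros(net.n_nodes),
                      deg_nodes=set(deg_nodes), nodes=net.nodes)


def random_walk(net: InteractionNetwork, deg_nodes: Iterable[str],
                cfg: DiffusionConfig | None = None) -> np.ndarray:
    cfg = cfg or DiffusionConfig()
    scorer = RandomWalkScorer(cfg.alpha, cfg.tol, cfg.max_iter)
    return scorer.fit_transform(net, _as_signal(net, deg_nodes))


def network_propagation(net: InteractionNetwork, deg_nodes: Iterable[str],
                        cfg: DiffusionConfig | None = None) -> np.ndarray:
    cfg = cfg or DiffusionConfig()
    scorer = NetworkPropagationScorer(cfg.alpha, cfg.tol, cfg.max_iter)
    return scorer.fit_transform(net, _as_signal(net, deg_nodes))


def diffusion_exact(net: InteractionNetwork, deg_nodes: Iterable[str],
                    alpha: float = 0.5, method: str = "random_walk",
                    _guard: int = 5000) -> np.ndarray:
    """Exact fixed point of either diffusion via a dense linear solve.

    Test oracle for the iterative methods; guarded to small networks.
    For the random walk the dangling-mass redirection is folded into the
    system matrix so the oracle matches the iteration on graphs with
    isolated nodes too.
    """
    if net.n_nodes > _guard:
        raise ValueError(f"dense solve guarded to <= {_guard} nodes")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    adj = build_adjacency(net)
    seed = _seed_indicator(net, deg_nodes)
    n = net.n_nodes
    eye = np.eye(n)
    if method == "random_walk":
        norm = normalize_stochastic(adj)
        A = norm.matrix.toarray()
        p0 = seed / seed.sum()
        d = norm.dangling.astype(float)
        # P = (1-a)(A' + p0 d^T) P + a p0  (dangling mass restarts)
        system = eye - (1 - alpha) * (A + np.outer(p0, d))
        sol = np.linalg.solve(system, alpha * p0)
    elif method == "propagation":
        A = normalize_symmetric(adj).matrix.toarray()
        system = eye - alpha * A
        sol = np.linalg.solve(system, (1 - alpha) * seed)
    else:
        raise ValueError(f"unknown diffusion method {method!r}")
    assert np.all(np.isfinite(sol)), "singular diffusion system"
    return sol
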