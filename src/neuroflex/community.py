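"""Multilayer modularity and generalized Louvain community detection.

The temporal network couples each node to itself in ordinally adjacent
windows with weight ``omega``; intralayer weights are the thresholded
correlation layers.  The quality of a partition g of all node-layer copies is

    Q = (1 / 2mu) * sum_{ijsr} [ (A_ijs - gamma * k_is k_js / 2m_s) d_sr
                                 + d_ij * C_jsr ] * d(g_is, g_jr)

with C_jsr = omega for |s - r| = 1 and 2mu the total node-layer strength
including the coupling.  With a single layer this reduces to Newman-Girvan
modularity at resolution gamma.

Optimization follows the generalized Louvain scheme: a sparse modularity
matrix B over all node-layer copies is built once, then greedy move sweeps
(in seeded random order, strictly positive gains only) alternate with
aggregation of communities into super-nodes until the quality stops
improving.  The move sweep is a numba kernel over the CSR arrays of B, which
keeps repeated detection across many subjects and seeds affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .connectivity import LayerStack
from .errors import ConfigurationError, UndefinedQualityError

__all__ = [
    "MultilayerNetwork",
    "CommunityAssignment",
    "multilayer_modularity",
    "generalized_louvain",
    "repeated_detection",
]

_TOL = 1e-10


@dataclass
class MultilayerNetwork:
    """Layer stack plus the two multilayer parameters.

    Parameters
    ----------
    layers
        A :class:`~neuroflex.connectivity.LayerStack` or a raw ``(W, R, R)``
        array of symmetric zero-diagonal weight matrices.
    omega
        Interlayer coupling weight (>= 0) between each node and itself in
        adjacent layers.  Larger values favour temporally persistent labels.
    gamma
        Intralayer resolution (> 0).  Larger values favour smaller modules.
    """

    layers: LayerStack | np.ndarray
    omega: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        arr = self.layers.layers if isinstance(self.layers, LayerStack) else self.layers
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ValueError("layers must have shape (W, R, R)")
        if self.omega < 0:
            raise ConfigurationError("omega must be nonnegative")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        self._arr = arr

    @property
    def n_layers(self) -> int:
        return self._arr.shape[0]

    @property
    def n_nodes(self) -> int:
        return self._arr.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return self._arr


@dataclass
class CommunityAssignment:
    """One detection run: integer labels of shape (R, W) plus its quality."""

    labels: np.ndarray
    quality: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be an R x W matrix")


class _DetectionContext:
    """Precomputed structures shared by every detection run on one network.

    ``blocks`` holds the dense intralayer modularity blocks
    A_s - gamma * k k' / 2m_s (layer s occupies node-layer indices
    s * R .. s * R + R - 1); the COO arrays describe the same matrix plus the
    interlayer coupling, and are reused for aggregation and exact quality
    evaluation.
    """

    def __init__(self, net: MultilayerNetwork) -> None:
        arr = net.weights
        w, r, _ = arr.shape
        blocks = np.empty_like(arr)
        two_mu = 0.0
        for s in range(w):
            a = arr[s]
            k = a.sum(axis=1)
            two_m = k.sum()
            blocks[s] = a
            if two_m > 0:
                blocks[s] = a - net.gamma * np.outer(k, k) / two_m
            two_mu += two_m
        two_mu += 2.0 * net.omega * r * (w - 1)
        if two_mu <= 0:
            raise UndefinedQualityError(
                "all layers have zero weight and omega = 0: modularity undefined"
            )
        self.n_layers = w
        self.n_nodes = r
        self.blocks = np.ascontiguousarray(blocks)
        self.omega = float(net.omega) if w > 1 else 0.0
        self.two_mu = two_mu
        n = w * r
        # COO of the full matrix: intralayer blocks then coupling diagonals
        grid = np.arange(r)
        brow = np.broadcast_to(np.arange(n)[:, None], (n, r)).ravel()
        bcol = (
            (np.arange(w)[:, None, None] * r + grid[None, None, :])
            .repeat(r, axis=1)
            .ravel()
        )
        rows = [brow]
        cols = [bcol]
        data = [self.blocks.ravel()]
        if self.omega > 0:
            upper = np.arange(n - r)
            rows += [upper, upper + r]
            cols += [upper + r, upper]
            data += [np.full(n - r, self.omega)] * 2
        self.coo_row = np.concatenate(rows).astype(np.int32)
        self.coo_col = np.concatenate(cols).astype(np.int32)
        self.coo_data = np.concatenate(data)

    def quality(self, flat: np.ndarray) -> float:
        num = _coo_quality_numerator(
            self.coo_row, self.coo_col, self.coo_data,
            np.ascontiguousarray(flat, dtype=np.int32),
        )
        return float(num / self.two_mu)

    def singleton_quality(self) -> float:
        diag = self.blocks[:, np.arange(self.n_nodes), np.arange(self.n_nodes)]
        return float(diag.sum()) / self.two_mu

    def aggregate(self, labels: np.ndarray, n_comms: int) -> "_CsrView":
        return _aggregate_coo(
            self.coo_row, self.coo_col, self.coo_data, labels, n_comms
        )


def _flatten_labels(labels: np.ndarray, w: int, r: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (r, w):
        raise ValueError(f"labels must have shape ({r}, {w})")
    return labels.T.reshape(-1)  # node-layer index s * R + i


def multilayer_modularity(net: MultilayerNetwork, labels: np.ndarray) -> float:
    """Quality Q of an (R, W) label matrix under the multilayer null model.

    Invariant under community relabeling; equals single-layer Newman-Girvan
    modularity (at resolution gamma) when W = 1.
    """
    ctx = _DetectionContext(net)
    flat = _flatten_labels(labels, net.n_layers, net.n_nodes)
    return ctx.quality(flat)


@njit(cache=True)
def _sweep(indptr, indices, data, labels, order, comm_w, touched):
    """One greedy pass over all node-layer copies.

    Moving copy i from its community to community c changes the quality
    numerator by 2 * (w(i -> c) - w(i -> own)); moves happen only on strictly
    positive gain, ties keep the first-encountered candidate.  ``comm_w``
    must arrive filled with -inf (the untouched sentinel) and is restored
    before returning.  Returns the move count and the total numerator gain.
    """
    n_moves = 0
    total_gain = 0.0
    neg_inf = -np.inf
    for t in range(order.shape[0]):
        i = order[t]
        ci = labels[i]
        nt = 0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if j == i:
                continue
            cj = labels[j]
            v = comm_w[cj]
            if v == neg_inf:
                touched[nt] = cj
                nt += 1
                v = 0.0
            comm_w[cj] = v + data[p]
        base = comm_w[ci]
        if base == neg_inf:  # no neighbour shares i's community
            base = 0.0
        best_c = ci
        best_gain = 0.0
        for q in range(nt):
            c = touched[q]
            if c == ci:
                continue
            gain = comm_w[c] - base
            if gain > best_gain:
                best_gain = gain
                best_c = c
        if best_c != ci:
            labels[i] = best_c
            n_moves += 1
            total_gain += 2.0 * best_gain
        for q in range(nt):
            comm_w[touched[q]] = neg_inf
    return n_moves, total_gain


@njit(cache=True)
def _sweep_blocks(blocks, omega, labels, order, comm_w, touched):
    """Greedy pass over node-layer copies using the dense block structure.

    Equivalent to :func:`_sweep` on the assembled sparse matrix but walks the
    contiguous same-layer block row plus the (at most two) coupling
    neighbours directly, which avoids index indirection on the dominant first
    Louvain level.
    """
    w, r, _ = blocks.shape
    n = w * r
    n_moves = 0
    total_gain = 0.0
    for t in range(order.shape[0]):
        i = order[t]
        s = i // r
        iloc = i - s * r
        ci = labels[i]
        nt = 0
        row = blocks[s, iloc]
        base_j = s * r
        neg_inf = -np.inf
        for jloc in range(r):
            j = base_j + jloc
            if j == i:
                continue
            cj = labels[j]
            v = comm_w[cj]
            if v == neg_inf:
                touched[nt] = cj
                nt += 1
                v = 0.0
            comm_w[cj] = v + row[jloc]
        if omega > 0.0:
            if s > 0:
                cj = labels[i - r]
                v = comm_w[cj]
                if v == neg_inf:
                    touched[nt] = cj
                    nt += 1
                    v = 0.0
                comm_w[cj] = v + omega
            if s < w - 1:
                cj = labels[i + r]
                v = comm_w[cj]
                if v == neg_inf:
                    touched[nt] = cj
                    nt += 1
                    v = 0.0
                comm_w[cj] = v + omega
        base = comm_w[ci]
        if base == neg_inf:
            base = 0.0
        best_c = ci
        best_gain = 0.0
        for q in range(nt):
            c = touched[q]
            if c == ci:
                continue
            gain = comm_w[c] - base
            if gain > best_gain:
                best_gain = gain
                best_c = c
        if best_c != ci:
            labels[i] = best_c
            n_moves += 1
            total_gain += 2.0 * best_gain
        for q in range(nt):
            comm_w[touched[q]] = neg_inf
    return n_moves, total_gain


@njit(cache=True)
def _coo_quality_numerator(row, col, data, flat):
    total = 0.0
    for p in range(row.shape[0]):
        if flat[row[p]] == flat[col[p]]:
            total += data[p]
    return total


@njit(cache=True)
def _group_rows(row, col, data, labels, n_comms):
    """Counting-sort relabelled COO triplets into CSR arrays, no dedup.

    Duplicate (row, col) entries are left in place: the sweep kernel sums
    them naturally and later aggregations re-sum them, so an explicit
    sum-duplicates pass (with its sort) is unnecessary.
    """
    nnz = row.shape[0]
    indptr = np.zeros(n_comms + 1, dtype=np.int64)
    for p in range(nnz):
        indptr[labels[row[p]] + 1] += 1
    for c in range(n_comms):
        indptr[c + 1] += indptr[c]
    indices = np.empty(nnz, dtype=np.int32)
    out = np.empty(nnz)
    pos = indptr[:-1].copy()
    for p in range(nnz):
        r = labels[row[p]]
        q = pos[r]
        indices[q] = labels[col[p]]
        out[q] = data[p]
        pos[r] += 1
    return indptr, indices, out


class _CsrView:
    """Minimal CSR triplet container for the sweep kernel."""

    __slots__ = ("indptr", "indices", "data", "shape")

    def __init__(self, indptr, indices, data, n):
        self.indptr = indptr
        self.indices = indices
        self.data = data
        self.shape = (n, n)

    def tocoo_arrays(self):
        row = np.repeat(
            np.arange(self.shape[0], dtype=np.int32), np.diff(self.indptr)
        )
        return row, self.indices, self.data


def _aggregate_coo(row, col, data, labels, n_comms: int) -> "_CsrView":
    """Collapse communities into super-nodes, summing all weights."""
    if n_comms <= 512:  # dense accumulation also dedupes; cheap when small
        flat = labels.astype(np.int64)[row] * n_comms + labels.astype(np.int64)[col]
        dense = np.bincount(flat, weights=data, minlength=n_comms * n_comms)
        mat = sp.csr_matrix(dense.reshape(n_comms, n_comms))
        return _CsrView(
            mat.indptr.astype(np.int64), mat.indices.astype(np.int32),
            mat.data, n_comms,
        )
    indptr, indices, out = _group_rows(row, col, data, labels, n_comms)
    return _CsrView(indptr, indices, out, n_comms)


def _louvain(ctx: _DetectionContext, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Two-phase generalized Louvain on a prebuilt detection context.

    The running quality is tracked from the summed move gains (each accepted
    move raises the quality numerator by exactly twice its gain); the
    returned value is re-evaluated on the original matrix so it equals
    :func:`multilayer_modularity` on the returned labels exactly.
    """
    n0 = ctx.n_layers * ctx.n_nodes
    mapping = np.arange(n0)
    q_best = ctx.singleton_quality()
    cur: _CsrView | None = None  # None = first level, use block kernel
    while True:
        n = n0 if cur is None else cur.shape[0]
        labels = np.arange(n, dtype=np.int32)
        comm_w = np.full(n, -np.inf)
        touched = np.empty(n, dtype=np.int32)
        level_gain = 0.0
        moved_any = False
        while True:
            order = rng.permutation(n).astype(np.int32)
            if cur is None:
                moves, gain = _sweep_blocks(
                    ctx.blocks, ctx.omega, labels, order, comm_w, touched
                )
            else:
                moves, gain = _sweep(
                    cur.indptr, cur.indices, cur.data, labels, order,
                    comm_w, touched,
                )
            if gain < 0:  # greedy moves must never lose quality
                raise AssertionError("modularity decreased within a Louvain sweep")
            level_gain += gain
            if moves == 0:
                break
            moved_any = True
        if not moved_any:
            break
        _, labels = np.unique(labels, return_inverse=True)
        labels = labels.astype(np.int32)
        mapping = labels[mapping]
        improvement = level_gain / ctx.two_mu
        q_best += improvement
        if improvement < _TOL:
            break
        n_comms = int(labels.max()) + 1
        if n_comms == n:
            break
        if cur is None:
            cur = ctx.aggregate(mapping, n_comms)
        else:
            row, col, data = cur.tocoo_arrays()
            cur = _aggregate_coo(row, col, data, labels, n_comms)
    _, mapping = np.unique(mapping, return_inverse=True)
    return mapping, ctx.quality(mapping)


def generalized_louvain(net: MultilayerNetwork, seed: int) -> CommunityAssignment:
    """Greedy multilayer modularity maximization from one seed.

    Deterministic given ``seed``: the node sweep order is reshuffled with the
    seeded generator on every pass.  The returned ``quality`` equals
    :func:`multilayer_modularity` evaluated on the returned labels.
    """
    ctx = _DetectionContext(net)
    flat, quality = _louvain(ctx, np.random.default_rng(seed))
    labels = flat.reshape(net.n_layers, net.n_nodes).T
    return CommunityAssignment(labels=labels, quality=quality, seed=int(seed))


def repeated_detection(
    net: MultilayerNetwork, n_reps: int = 100, master_seed: int = 0
) -> list[CommunityAssignment]:
    """Independent detection runs with seeds derived from ``master_seed``.

    The community-detection heuristic is stochastic; downstream metrics are
    averaged across the returned repetitions.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    ctx = _DetectionContext(net)
    seeds = np.random.SeedSequence(master_seed).generate_state(n_reps, np.uint32)
    out = []
    for s in seeds:
        flat, quality = _louvain(ctx, np.random.default_rng(int(s)))
        labels = flat.reshape(net.n_layers, net.n_nodes).T
        out.append(CommunityAssignment(labels=labels, quality=quality, seed=int(s)))
    return out
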