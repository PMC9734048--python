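"""Sliding-window dynamic functional connectivity.

One subject's parcellated ROI time series (T timepoints x R regions) is
converted into a stack of windowed Pearson-correlation matrices.  Within each
window every unique region pair is tested against zero correlation and only
edges surviving a Benjamini-Hochberg false-discovery-rate threshold are
retained; the surviving matrices become the intralayer weights of the
multilayer network analysed downstream.

The defaults mirror the common resting-state convention: a window of 30
volumes advanced by 1 volume, and FDR control at q < 0.05 within each window
across all R(R-1)/2 region pairs (34,716 pairs for a 264-node parcellation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .errors import InsufficientDataError

__all__ = [
    "RoiTimeSeries",
    "LayerStack",
    "sliding_windows",
    "window_correlation",
    "correlation_pvalue",
    "bh_fdr",
    "build_layer_stack",
]


@dataclass
class RoiTimeSeries:
    """A single subject's T x R region-of-interest signal matrix.

    Parameters
    ----------
    values
        Array of shape ``(T, R)``; arbitrary signal units, no missing values.
    node_ids
        R unique region labels, one per column.
    subject_id
        Identifier carried through every downstream output.
    """

    values: np.ndarray
    node_ids: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x R) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing or non-finite values")
        self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) != self.values.shape[1]:
            raise ValueError("node_ids length must equal the number of columns")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class LayerStack:
    """W thresholded correlation matrices from one subject.

    ``layers`` is ``(W, R, R)``: symmetric, zero diagonal, entries are the
    retained correlation coefficients (zero where an edge was not retained).
    ``retained`` marks the edges that survived thresholding *and* the
    negative-weight policy, so ``layers[w][~retained[w]] == 0`` always holds.
    """

    layers: np.ndarray
    retained: np.ndarray
    window_width: int
    step: int
    alpha: float
    negatives: str = "zero"
    node_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValueError("layers must have shape (W, R, R)")
        if self.retained.shape != self.layers.shape:
            raise ValueError("retained mask must match layers shape")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_regions(self) -> int:
        return self.layers.shape[1]


def sliding_windows(n_timepoints: int, width: int = 30, step: int = 1) -> list[tuple[int, int]]:
    """Half-open index ranges ``[s, s + width)`` covering the series.

    Windows start at ``0, step, 2*step, ...``; the number of windows is
    ``floor((T - width) / step) + 1``.
    """
    if width < 2:
        raise ValueError("window width must be at least 2")
    if step < 1:
        raise ValueError("step must be at least 1")
    if n_timepoints < width:
        raise InsufficientDataError(
            f"series of length {n_timepoints} is shorter than the window width {width}"
        )
    n_windows = (n_timepoints - width) // step + 1
    return [(s * step, s * step + width) for s in range(n_windows)]


def window_correlation(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix of one window (width x R).

    Returns ``(corr, valid)`` where ``valid`` flags columns with nonzero
    variance inside the window.  Rows/columns of constant regions are set to
    zero off-diagonal (their correlations are undefined and are treated as
    non-retained by :func:`build_layer_stack`); the diagonal is always 1.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 2:
        raise ValueError("window must be 2-D with at least two rows")
    sd = window.std(axis=0)
    valid = sd > 0
    r = window.shape[1]
    corr = np.zeros((r, r))
    if valid.any():
        sub = np.corrcoef(window[:, valid], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(valid)
        corr[np.ix_(idx, idx)] = sub
    np.fill_diagonal(corr, 1.0)
    # numerical guard: clip tiny excursions outside [-1, 1]
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr, valid


def correlation_pvalue(r, n: int):
    """Two-sided p-value for a Pearson correlation of ``n`` samples.

    Uses the exact-t reference: t = r * sqrt((n - 2) / (1 - r^2)) on n - 2
    degrees of freedom.  |r| = 1 maps to p = 0.  Accepts scalars or arrays.
    """
    if n < 3:
        raise InsufficientDataError("need at least 3 samples for a correlation p-value")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    p = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    t = r[interior] * np.sqrt((n - 2) / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * _sps.t.sf(np.abs(t), df=n - 2)
    return p if p.ndim else float(p)


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Rejects the k smallest p-values where k is the largest i with
    p_(i) <= i * alpha / m; returns ``(reject, qvals)`` with the monotone
    step-up adjusted q-values clipped to [0, 1].  Empty input yields empty
    outputs.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((ranked * m / ranks)[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    passed = ranked <= ranks * alpha / m
    k = np.max(np.flatnonzero(passed)) + 1 if passed.any() else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    reject = np.zeros(m, dtype=bool)
    qvals = np.zeros(m)
    reject[order] = reject_sorted
    qvals[order] = q_sorted
    return reject, qvals


def build_layer_stack(
    ts: RoiTimeSeries,
    width: int = 30,
    step: int = 1,
    alpha: float = 0.05,
    negatives: str = "zero",
) -> LayerStack:
    """Windowed, FDR-thresholded correlation layers for one subject.

    Per window: Pearson correlations for all R(R-1)/2 unique pairs, exact-t
    two-sided p-values, BH-FDR within the window at level ``alpha``;
    non-retained entries are zeroed.  Edges touching a constant column are
    treated as non-retained rather than fatal.

    ``negatives`` controls significant negative correlations: ``"zero"``
    (default) removes them before community detection, since the intralayer
    null model assumes nonnegative weights; ``"retain"`` keeps them as
    negative weights.
    """
    if negatives not in ("zero", "retain"):
        raise ValueError("negatives must be 'zero' or 'retain'")
    windows = sliding_windows(ts.n_timepoints, width=width, step=step)
    r = ts.n_regions
    iu = np.triu_indices(r, k=1)
    n_win = len(windows)
    # batched window correlations: (W, R, width) views -> cross-products
    view = np.lib.stride_tricks.sliding_window_view(ts.values, width, axis=0)
    view = view[:: step][:n_win]  # (W, R, width)
    centered = view - view.mean(axis=2, keepdims=True)
    cross = np.einsum("wrt,wst->wrs", centered, centered, optimize=True)
    var = np.einsum("wrr->wr", cross)
    valid_all = (view.max(axis=2) - view.min(axis=2)) > 0  # non-constant columns
    sd = np.sqrt(np.where(var > 0, var, 1.0))
    corr_all = cross / (sd[:, :, None] * sd[:, None, :])
    np.clip(corr_all, -1.0, 1.0, out=corr_all)
    pair_r_all = corr_all[:, iu[0], iu[1]]  # (W, P)
    pair_p_all = np.asarray(correlation_pvalue(pair_r_all.ravel(), width))
    pair_p_all = pair_p_all.reshape(n_win, -1)
    layers = np.zeros((n_win, r, r))
    retained = np.zeros((n_win, r, r), dtype=bool)
    for w in range(n_win):
        pair_r = pair_r_all[w]
        pair_p = pair_p_all[w].copy()
        valid = valid_all[w]
        pair_valid = valid[iu[0]] & valid[iu[1]]
        pair_p[~pair_valid] = 1.0  # undefined correlations are never retained
        keep, _ = bh_fdr(pair_p, alpha=alpha)
        keep &= pair_valid
        if negatives == "zero":
            keep &= pair_r > 0
        vals = np.where(keep, pair_r, 0.0)
        layers[w][iu] = vals
        layers[w].T[iu] = vals
        retained[w][iu] = keep
        retained[w].T[iu] = keep
    return LayerStack(
        layers=layers,
        retained=retained,
        window_width=width,
        step=step,
        alpha=alpha,
        negatives=negatives,
        node_ids=list(ts.node_ids),
        subject_id=ts.subject_id,
    )
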