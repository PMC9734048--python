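"""Neural flexibility: how often nodes change community allegiance.

For one detection run with labels g_i(w) over W windows, node flexibility is
f_i = n_i / N where n_i counts the adjacent-window label changes of node i
and N = W - 1 is the number of possible changes.  Profiles average f over
detection repetitions at the node level, then aggregate to functional-system
means and a whole-brain mean; stability is reported as 1 - flexibility at
every level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = [
    "FlexibilityProfile",
    "node_flexibility",
    "mean_over_reps",
    "aggregate_flexibility",
    "profile_from_assignments",
]


@dataclass
class FlexibilityProfile:
    """Per-node, per-system and whole-brain flexibility for one subject."""

    node_flexibility: pd.Series  # indexed by node_id, values in [0, 1]
    system_flexibility: pd.Series  # indexed by system label
    whole_brain: float
    n_reps: int = 1
    subject_id: str = ""

    @property
    def node_stability(self) -> pd.Series:
        return 1.0 - self.node_flexibility

    @property
    def system_stability(self) -> pd.Series:
        return 1.0 - self.system_flexibility

    @property
    def whole_brain_stability(self) -> float:
        return 1.0 - self.whole_brain

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: one row per (level, unit) value."""
        rows = [
            {"subject_id": self.subject_id, "level": "whole_brain", "unit": "whole_brain",
             "value": self.whole_brain}
        ]
        rows += [
            {"subject_id": self.subject_id, "level": "system", "unit": s, "value": v}
            for s, v in self.system_flexibility.items()
        ]
        rows += [
            {"subject_id": self.subject_id, "level": "node", "unit": n, "value": v}
            for n, v in self.node_flexibility.items()
        ]
        return pd.DataFrame(rows)


def node_flexibility(labels: np.ndarray) -> np.ndarray:
    """Fraction of the W - 1 window boundaries at which each node switches.

    ``labels`` is the (R, W) community matrix of one detection run.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be an R x W matrix")
    w = labels.shape[1]
    if w < 2:
        raise InsufficientDataError("flexibility needs at least 2 layers")
    changes = labels[:, 1:] != labels[:, :-1]
    return changes.sum(axis=1) / (w - 1)


def mean_over_reps(vectors) -> np.ndarray:
    """Elementwise mean of per-repetition node vectors."""
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("need at least one repetition")
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1:
        raise ValueError("repetition vectors must all have the same shape")
    return np.mean(np.stack(vectors), axis=0)


def aggregate_flexibility(
    node_values: np.ndarray,
    atlas: pd.DataFrame,
    subject_id: str = "",
    n_reps: int = 1,
) -> FlexibilityProfile:
    """System means (unweighted over member nodes) and the whole-brain mean.

    ``atlas`` must have columns ``node_id`` and ``system`` covering every
    node, in node order matching ``node_values``.
    """
    node_values = np.asarray(node_values, dtype=float)
    if {"node_id", "system"} - set(atlas.columns):
        raise ValueError("atlas needs 'node_id' and 'system' columns")
    if len(atlas) != node_values.size:
        raise ValueError("atlas must label exactly one system per node")
    if atlas["system"].isna().any():
        raise ValueError("every node needs a system label")
    node = pd.Series(node_values, index=atlas["node_id"].to_numpy(), name="flexibility")
    by_system = node.groupby(atlas["system"].to_numpy(), sort=False).mean()
    return FlexibilityProfile(
        node_flexibility=node,
        system_flexibility=by_system,
        whole_brain=float(node.mean()),
        n_reps=n_reps,
        subject_id=subject_id,
    )


def profile_from_assignments(
    assignments, atlas: pd.DataFrame, subject_id: str = ""
) -> FlexibilityProfile:
    """Average node flexibility over detection repetitions, then aggregate."""
    vecs = [node_flexibility(a.labels) for a in assignments]
    mean_vec = mean_over_reps(vecs)
    return aggregate_flexibility(
        mean_vec, atlas, subject_id=subject_id, n_reps=len(vecs)
    )
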