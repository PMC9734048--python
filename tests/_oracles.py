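"""Independent brute-force references used by the oracle tests."""

import numpy as np


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_to_labels(partition, n_nodes, n_layers):
    """Flat node-layer partition -> (R, W) label matrix (index = s*R + i)."""
    n = n_nodes * n_layers
    flat = np.empty(n, dtype=int)
    for k, block in enumerate(partition):
        for idx in block:
            flat[idx] = k
    return flat.reshape(n_layers, n_nodes).T


def exhaustive_best_quality(net, quality_fn):
    """Maximum multilayer modularity over every partition of all copies."""
    n = net.n_nodes * net.n_layers
    best = -np.inf
    best_labels = None
    for part in set_partitions(list(range(n))):
        labels = partition_to_labels(part, net.n_nodes, net.n_layers)
        q = quality_fn(net, labels)
        if q > best:
            best = q
            best_labels = labels
    return best, best_labels


def bh_stepup_reference(pvals, alpha):
    """Literal step-up definition: largest i with p_(i) <= i*alpha/m."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def ols_normal_equations(y, x):
    """(beta, se, t) for every coefficient via explicit normal equations."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = y.size - x.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * s2)
    return beta, se, beta / se, df
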