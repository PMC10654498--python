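"""Numpy implementation of the PNA-style message-passing regressor.

The network follows the principal-neighborhood-aggregation design: each
message-passing layer transforms (sender state, receiver state, edge feature)
triples into messages, aggregates incoming messages per node with four
aggregators (mean, min, max, std) scaled by three degree-dependent scalers
(identity, amplification log(d+1)/delta, attenuation delta/log(d+1)), and
updates the node state from the concatenation of the previous state and the
twelve scaled aggregates.  Node states are mean-pooled per graph and fed to a
fully connected head ending in a single scalar output.

Forward and backward passes are written by hand against numpy scatter
primitives; gradients are validated by finite differences in the test suite.
All computation is float64 and fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_STD_EPS = 1e-5  # inside the sqrt of the std aggregator


@dataclass
class GraphBatch:
    """A disjoint union of molecular graphs."""

    x: np.ndarray  # (N, F_node)
    edge_index: np.ndarray  # (2, E) directed; both directions present
    edge_attr: np.ndarray  # (E, F_edge)
    graph_id: np.ndarray  # (N,) int
    n_graphs: int
    targets: np.ndarray | None = None  # (G,)


def build_batch(graphs, targets=None) -> GraphBatch:
    """Concatenate :class:`~gapdesign.featurize.MoleculeGraph` objects."""
    xs, eis, eas, gids = [], [], [], []
    offset = 0
    for gid, g in enumerate(graphs):
        xs.append(g.node_features)
        eis.append(g.edge_index + offset)
        eas.append(g.edge_features)
        gids.append(np.full(g.n_nodes, gid, dtype=np.int64))
        offset += g.n_nodes
    return GraphBatch(
        x=np.concatenate(xs, axis=0),
        edge_index=np.concatenate(eis, axis=1),
        edge_attr=np.concatenate(eas, axis=0),
        graph_id=np.concatenate(gids),
        n_graphs=len(graphs),
        targets=None if targets is None else np.asarray(targets, dtype=np.float64),
    )


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(
    rng: np.random.Generator,
    node_dim: int,
    edge_dim: int,
    hidden: int,
    n_layers: int,
    fc_dims: list[int],
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {
        "W_in": glorot(rng, node_dim, hidden),
        "b_in": np.zeros(hidden),
    }
    for layer in range(n_layers):
        params[f"W_msg{layer}"] = glorot(rng, 2 * hidden + edge_dim, hidden)
        params[f"b_msg{layer}"] = np.zeros(hidden)
        params[f"W_upd{layer}"] = glorot(rng, 13 * hidden, hidden)
        params[f"b_upd{layer}"] = np.zeros(hidden)
    dims = [hidden] + list(fc_dims) + [1]
    for k in range(len(dims) - 1):
        params[f"W_fc{k}"] = glorot(rng, dims[k], dims[k + 1])
        params[f"b_fc{k}"] = np.zeros(dims[k + 1])
    return params


def mean_log_degree(batches) -> float:
    """The PNA normalization constant delta: avg log(1+in-degree) over training nodes."""
    total, count = 0.0, 0
    for batch in batches:
        deg = np.bincount(batch.edge_index[1], minlength=batch.x.shape[0])
        total += np.log1p(deg).sum()
        count += deg.size
    if count == 0 or total == 0.0:
        return 1.0
    return total / count


def _degree_scalers(deg: np.ndarray, delta: float):
    """Identity / amplification / attenuation scalers; zero for isolated nodes."""
    logd = np.log1p(deg.astype(np.float64))
    has = deg > 0
    s_amp = np.where(has, logd / delta, 0.0)
    with np.errstate(divide="ignore"):
        s_att = np.where(has, delta / np.where(has, logd, 1.0), 0.0)
    s_id = has.astype(np.float64)
    return s_id, s_amp, s_att


def forward(params: dict, batch: GraphBatch, n_layers: int, delta: float):
    """Forward pass; returns (predictions (G,), cache for backward)."""
    src, dst = batch.edge_index
    n_nodes = batch.x.shape[0]
    hidden = params["b_in"].size

    cache: dict = {"layers": []}
    h_pre = batch.x @ params["W_in"] + params["b_in"]
    h = np.maximum(h_pre, 0.0)
    cache["h_in_pre"] = h_pre

    deg = np.bincount(dst, minlength=n_nodes).astype(np.int64)
    n_safe = np.maximum(deg, 1).astype(np.float64)
    scalers = _degree_scalers(deg, delta)
    cache["deg"], cache["n_safe"], cache["scalers"] = deg, n_safe, scalers

    for layer in range(n_layers):
        z = np.concatenate([h[src], h[dst], batch.edge_attr], axis=1)
        m_pre = z @ params[f"W_msg{layer}"] + params[f"b_msg{layer}"]
        m = np.maximum(m_pre, 0.0)

        agg_sum = np.zeros((n_nodes, hidden))
        np.add.at(agg_sum, dst, m)
        agg_sumsq = np.zeros((n_nodes, hidden))
        np.add.at(agg_sumsq, dst, m * m)
        mean = agg_sum / n_safe[:, None]
        var_pre = agg_sumsq / n_safe[:, None] - mean**2
        var = np.maximum(var_pre, 0.0)
        std = np.sqrt(var + _STD_EPS)
        std = np.where(deg[:, None] > 0, std, 0.0)

        mx = np.full((n_nodes, hidden), -np.inf)
        np.maximum.at(mx, dst, m)
        mx = np.where(deg[:, None] > 0, mx, 0.0)
        mn = np.full((n_nodes, hidden), np.inf)
        np.minimum.at(mn, dst, m)
        mn = np.where(deg[:, None] > 0, mn, 0.0)

        aggs = (mean, mn, mx, std)
        blocks = [a * s[:, None] for a in aggs for s in scalers]
        u = np.concatenate([h] + blocks, axis=1)
        h_out_pre = u @ params[f"W_upd{layer}"] + params[f"b_upd{layer}"]
        h_new = np.maximum(h_out_pre, 0.0)

        cache["layers"].append(
            {
                "h": h, "z": z, "m_pre": m_pre, "m": m, "mean": mean,
                "var_pre": var_pre, "std": std, "mx": mx, "mn": mn,
                "u": u, "h_out_pre": h_out_pre,
            }
        )
        h = h_new

    # mean pooling per graph
    n_per_graph = np.bincount(batch.graph_id, minlength=batch.n_graphs).astype(np.float64)
    pooled = np.zeros((batch.n_graphs, hidden))
    np.add.at(pooled, batch.graph_id, h)
    pooled /= n_per_graph[:, None]
    cache["h_final"] = h
    cache["n_per_graph"] = n_per_graph

    a = pooled
    cache["fc"] = []
    n_fc = sum(1 for k in params if k.startswith("W_fc"))
    for k in range(n_fc):
        a_pre = a @ params[f"W_fc{k}"] + params[f"b_fc{k}"]
        cache["fc"].append({"a_in": a, "a_pre": a_pre})
        a = np.maximum(a_pre, 0.0) if k < n_fc - 1 else a_pre
    preds = a[:, 0]
    return preds, cache


def backward(
    params: dict,
    batch: GraphBatch,
    cache: dict,
    d_preds: np.ndarray,
    n_layers: int,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every parameter, given dL/d preds."""
    src, dst = batch.edge_index
    hidden = params["b_in"].size
    n_safe = cache["n_safe"]
    deg = cache["deg"]
    scalers = cache["scalers"]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    # fully connected head
    da = d_preds[:, None]
    n_fc = len(cache["fc"])
    for k in range(n_fc - 1, -1, -1):
        fc = cache["fc"][k]
        d_pre = da if k == n_fc - 1 else da * (fc["a_pre"] > 0)
        grads[f"W_fc{k}"] = fc["a_in"].T @ d_pre
        grads[f"b_fc{k}"] = d_pre.sum(axis=0)
        da = d_pre @ params[f"W_fc{k}"].T

    # un-pool
    d_h = da[batch.graph_id] / cache["n_per_graph"][batch.graph_id][:, None]

    for layer in range(n_layers - 1, -1, -1):
        lc = cache["layers"][layer]
        d_out_pre = d_h * (lc["h_out_pre"] > 0)
        grads[f"W_upd{layer}"] = lc["u"].T @ d_out_pre
        grads[f"b_upd{layer}"] = d_out_pre.sum(axis=0)
        d_u = d_out_pre @ params[f"W_upd{layer}"].T

        d_h_self = d_u[:, :hidden].copy()
        d_aggs = []
        for a_idx in range(4):
            acc = np.zeros((d_h.shape[0], hidden))
            for s_idx in range(3):
                start = hidden * (1 + a_idx * 3 + s_idx)
                acc += d_u[:, start : start + hidden] * scalers[s_idx][:, None]
            d_aggs.append(acc)
        d_mean, d_mn, d_mx, d_std = d_aggs

        m, mean, std = lc["m"], lc["mean"], lc["std"]
        d_m = d_mean[dst] / n_safe[dst, None]

        # min/max route gradients to the extremal messages, split across ties
        for d_ext, ext in ((d_mx, lc["mx"]), (d_mn, lc["mn"])):
            is_ext = (m == ext[dst]).astype(np.float64)
            cnt = np.zeros_like(ext)
            np.add.at(cnt, dst, is_ext)
            cnt = np.maximum(cnt, 1.0)
            d_m += is_ext * d_ext[dst] / cnt[dst]

        # std: d std/d m_e = (m_e - mean)/(n * std) where the variance is positive
        safe_std = np.where(std > 0, std, 1.0)
        d_var = d_std * 0.5 / safe_std
        d_var = np.where((lc["var_pre"] > 0) & (deg[:, None] > 0), d_var, 0.0)
        d_m += 2.0 * d_var[dst] * (m - mean[dst]) / n_safe[dst, None]

        d_m_pre = d_m * (lc["m_pre"] > 0)
        grads[f"W_msg{layer}"] = lc["z"].T @ d_m_pre
        grads[f"b_msg{layer}"] = d_m_pre.sum(axis=0)
        d_z = d_m_pre @ params[f"W_msg{layer}"].T

        d_h = d_h_self
        np.add.at(d_h, src, d_z[:, :hidden])
        np.add.at(d_h, dst, d_z[:, hidden : 2 * hidden])

    d_in_pre = d_h * (cache["h_in_pre"] > 0)
    grads["W_in"] = batch.x.T @ d_in_pre
    grads["b_in"] = d_in_pre.sum(axis=0)
    return grads


class AdamW:
    """Decoupled weight-decay Adam; decay applies to weight matrices only."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for key, p in params.items():
            g = grads[key]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            update = (self.m[key] / bc1) / (np.sqrt(self.v[key] / bc2) + self.eps)
            if key.startswith("W"):
                update = update + self.wd * p
            p -= self.lr * update
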