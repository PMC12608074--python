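"""Comparison estimators: single-tree BM, composite-over-trees dispersal,
averaging-up locations, and the alternate midpoint recombination model.

These are the reference methods the ARG likelihood is judged against:

* ``tree_fit``            — classic phylogenetic-BM GLS on one local tree.
* ``composite_dispersal`` — unweighted average of per-tree ML dispersal
  rates over the first n local trees (each tree fit with its own root).
* ``averaging_up``        — each internal node at the unweighted mean of its
  children's locations, on the simplified ARG; ignores branch lengths and
  provides no uncertainty.
* ``midpoint_fit``        — Brownian motion with independent edge
  displacements where a recombination node sits at the exact midpoint of
  its two parents' arrival points (weights 1/2 each, no span weighting).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import solve_spd
from .arg import ARG, locations_array
from .estimators import SpatialFit, fit as _arg_fit


def _tree_arg(arg: ARG, tree_index: int | None, position: float | None) -> ARG:
    intervals = arg.tree_intervals()
    if position is not None:
        tree_index = next(
            i for i, (l, r) in enumerate(intervals) if l <= position < r
        )
    elif tree_index is None:
        tree_index = 0
    left, right = intervals[tree_index]
    if (left, right) == (0.0, arg.sequence_length):
        return arg
    return arg.restrict(left, right)


def tree_fit(
    arg: ARG,
    locations,
    tree_index: int | None = None,
    position: float | None = None,
    cutoff: float | None = None,
) -> SpatialFit:
    """Classic Brownian-motion GLS fit on a single local tree.

    Same code path as the ARG fit applied to a one-tree ARG (for a tree the
    sample matrix and path matrix coincide).
    """
    return _arg_fit(_tree_arg(arg, tree_index, position), locations, cutoff=cutoff)


def composite_dispersal(arg: ARG, locations, n_trees: int):
    """Average of per-tree ML dispersal rates over the first ``n_trees``
    local trees (composite likelihood over marginal trees, no importance
    sampling; between-tree correlations are ignored)."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    n = min(n_trees, len(arg.tree_intervals()))
    disps = [tree_fit(arg, locations, tree_index=i).dispersal for i in range(n)]
    if np.ndim(disps[0]) == 0:
        return float(np.mean(disps))
    return np.mean(disps, axis=0)


def averaging_up(simplified_arg: ARG, locations) -> pd.DataFrame:
    """Averaging-up node locations on a simplified ARG.

    Nodes are processed in increasing time order; each internal node's
    location is the unweighted mean of its (distinct) children's locations.
    Deterministic point estimates with no uncertainty, unaffected by node
    times or branch lengths.
    """
    arg = simplified_arg
    loc = locations_array(arg, locations)
    d = loc.shape[1]
    located: dict[int, np.ndarray] = {
        int(s): loc[i] for i, s in enumerate(arg.samples)
    }
    internal = sorted(
        (n for n in arg._children if n not in located),
        key=lambda n: arg.node_times[n],
    )
    for n in internal:
        child_locs = [located[c] for c in arg.children(n) if c in located]
        if not child_locs:
            raise ValueError(f"node {n} has no located child (malformed ARG)")
        located[n] = np.mean(child_locs, axis=0)
    rows = sorted(located)
    out = {
        "node_id": rows,
        "time": [arg.node_times[n] for n in rows],
        "x": [located[n][0] for n in rows],
    }
    if d > 1:
        out["y"] = [located[n][1] for n in rows]
    return pd.DataFrame(out)


@dataclass
class MidpointModel:
    """Brownian motion on an ARG with recombination nodes at parent midpoints.

    Node locations are built from independent per-edge displacements: a
    single-parent node is its parent's location plus the edge displacement;
    a recombination node is the average of its two parents' arrival points
    (each parent's location plus the displacement along its own edge).  The
    implied node covariance is ``dispersal × W T W^T`` with ``W`` the
    accumulated weight matrix over edges and ``T`` the diagonal of edge
    durations.  Root locations and the dispersal rate are estimated by GLS
    exactly as in the main model.
    """

    arg: ARG
    W: np.ndarray = field(init=False, repr=False)
    root_design: np.ndarray = field(init=False, repr=False)
    node_ids: list[int] = field(init=False)

    def __post_init__(self):
        arg = self.arg
        nodes = sorted(
            set(arg.roots)
            | set(int(s) for s in arg.samples)
            | {n for e in arg.graph_edges for n in e}
        )
        pos = {n: i for i, n in enumerate(nodes)}
        n_e = len(arg.graph_edges)
        w = np.zeros((len(nodes), n_e))
        m = np.zeros((len(nodes), len(arg.roots)))
        root_pos = {int(r): i for i, r in enumerate(arg.roots)}
        for n in sorted(nodes, key=lambda u: -arg.node_times[u]):
            parents = arg.parents(n)
            if not parents:
                m[pos[n], root_pos[n]] = 1.0
                continue
            share = 1.0 / len(parents)
            for p in parents:
                w[pos[n]] += share * w[pos[p]]
                m[pos[n]] += share * m[pos[p]]
                w[pos[n], arg.edge_index[(n, p)]] += share
        self.W = w
        self.root_design = m
        self.node_ids = nodes

    def _pos(self, node: int) -> int:
        return self.node_ids.index(int(node))

    def node_covariance(self) -> np.ndarray:
        """Covariance factor ``W T W^T`` over all nodes (× dispersal)."""
        c = self.W @ (self.arg.edge_durations[:, None] * self.W.T)
        return (c + c.T) / 2.0

    def node_variance_factors(self) -> dict[int, float]:
        c = self.node_covariance()
        return {n: float(c[i, i]) for i, n in enumerate(self.node_ids)}

    def fit(self, locations) -> "MidpointModel":
        arg = self.arg
        loc = locations_array(arg, locations)
        idx = [self._pos(s) for s in arg.samples]
        c = self.node_covariance()
        self._cov_full = c
        cs = c[np.ix_(idx, idx)]
        x = self.root_design[idx]
        cinv_x = solve_spd(cs, x, "midpoint sample covariance")
        self.root_locations_ = solve_spd(x.T @ cinv_x, x.T @ solve_spd(cs, loc),
                                         "midpoint root normal matrix")
        resid = loc - x @ self.root_locations_
        q = resid.T @ solve_spd(cs, resid) / len(idx)
        q = (q + q.T) / 2.0
        self.dispersal_ = float(q[0, 0]) if q.shape == (1, 1) else q
        d = loc.shape[1]
        disp = np.atleast_2d(np.asarray(self.dispersal_))
        sign, logdet_c = np.linalg.slogdet(cs)
        _, logdet_disp = np.linalg.slogdet(disp)
        ns = len(idx)
        self.log_likelihood_ = float(
            -0.5
            * (
                d * ns * np.log(2 * np.pi)
                + ns * logdet_disp
                + d * logdet_c
                + np.trace(np.linalg.solve(disp, q)) * ns / 1.0
            )
        ) if np.all(np.linalg.eigvalsh(disp) > 0) else -np.inf
        self._sample_idx = idx
        self._locations = loc
        self.result_ = SpatialFit(
            mu_hat=self.root_locations_, dispersal=self.dispersal_,
            loglik=self.log_likelihood_, n_roots=len(arg.roots),
            n_samples=len(idx), n_paths=len(arg.samples),
            roots=arg.roots.copy(), samples=arg.samples.copy(),
        )
        return self

    def locate(self, node: int, dispersal=None):
        """Conditional (mean, variance factor) of a node's location given the
        sample locations, with the fitted roots plugged in.  Root-location
        uncertainty is not propagated here (point-estimate analogue)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("call fit() first")
        c = self._cov_full
        i = self._pos(node)
        idx = self._sample_idx
        cs = c[np.ix_(idx, idx)]
        cas = c[i, idx]
        x = self.root_design[idx]
        mean_nodes = self.root_design @ self.root_locations_
        resid = self._locations - x @ self.root_locations_
        mean = mean_nodes[i] + cas @ solve_spd(cs, resid)
        v = float(c[i, i] - cas @ solve_spd(cs, cas[:, None])[:, 0])
        return np.asarray(mean), max(v, 0.0)


def midpoint_fit(arg: ARG, locations) -> SpatialFit:
    """GLS fit of root locations and dispersal under the midpoint model."""
    return MidpointModel(arg).fit(locations).result_
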