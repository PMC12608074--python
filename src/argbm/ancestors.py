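"""Location distributions of genetic ancestors.

An ancestor is addressed by (sample, genome position, time): the lineage of
that sample at that position, followed back to the requested time.  Given a
fitted spatial model, its location is Gaussian with mean

    E[La] = μ̂_ra + sa^T Sp^g- (P ℓ* - R μ̂)

and variance ``dispersal × V`` where

    V = ta - sa^T Sp^g- sa                                   (Brownian motion)
      + (e_ra - R^T Sp^g- sa)^T (R^T Sp^g- R)^{-1} (...)    (root uncertainty)

with ``sa`` the vector of shared times between an (arbitrary) root path of
the ancestor and the minimal basis paths, ``ta`` its time to the root, and
``ra`` that root's index.  The estimate does not depend on which root path
is chosen.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._linalg import psd_pinv, solve_spd
from .arg import ARG, locations_array
from .paths import PathBasis, shared_time_with_paths


@dataclass(frozen=True)
class AncestorQuery:
    """Identifies the ancestor of ``sample_id`` at ``position`` (bp) and
    ``time`` (generations into the past)."""

    sample_id: int
    position: float
    time: float


@dataclass
class ResolvedAncestor:
    """An ancestral lineage point and its shared-time geometry.

    ``node`` is set when the point coincides with an ARG node; otherwise
    ``edge=(child, parent)`` holds the edge the point sits on at ``time``.
    """

    time: float
    node: int | None
    edge: tuple[int, int] | None
    root: int
    root_index: int
    ta: float
    sa: np.ndarray


@dataclass
class AncestorEstimate:
    """Gaussian location estimate for one ancestor query."""

    query: AncestorQuery
    point: ResolvedAncestor
    mean: np.ndarray
    V: float
    V_bm: float
    V_root: float
    covariance: np.ndarray
    level: float
    # 1D: (lo, hi); 2D: chi-squared ellipse half-axes and orientation
    interval: tuple[float, float] | None = None
    ellipse: dict | None = field(default=None, repr=False)


def _walk_to_time(arg: ARG, sample_id: int, position: float, time: float):
    """Follow the local tree at ``position`` from the sample up to ``time``.

    Returns ``(node, edge)``: one of them is None depending on whether the
    query time lands exactly on a node.
    """
    if sample_id not in set(int(s) for s in arg.samples):
        raise ValueError(f"{sample_id} is not a sample node")
    if not (0 <= position < arg.sequence_length):
        raise ValueError("position outside the sequence")
    t0 = arg.node_times[sample_id]
    if time < t0:
        raise ValueError("query time is more recent than the sample")
    tree = arg.ts.at(position)
    node = int(sample_id)
    while True:
        if np.isclose(arg.node_times[node], time):
            return node, None
        parent = tree.parent(node)
        if parent == -1:
            raise ValueError(
                f"query time {time} is older than the local root at "
                f"position {position}"
            )
        if arg.node_times[parent] > time:
            return None, (node, int(parent))
        node = int(parent)


def _root_path_edges(
    arg: ARG,
    node: int | None,
    edge: tuple[int, int] | None,
    time: float,
    root_path: tuple[int, ...] | None = None,
):
    """((child, parent), duration) pairs of a path from the point to a root.

    By default the canonical-parent rule picks the path; ``root_path`` (node
    ids from the first full node at/above the point up to a root) overrides
    it — any valid choice gives identical estimates.
    """
    edges: list[tuple[tuple[int, int], float]] = []
    if edge is not None:
        c, p = edge
        edges.append(((c, p), arg.node_times[p] - time))
        start = p
    else:
        start = node
    path = arg.canonical_path(start) if root_path is None else tuple(root_path)
    if path[0] != start:
        raise ValueError("root_path must start at the point's upper node")
    for c, p in zip(path[:-1], path[1:]):
        if (c, p) not in arg.edge_index:
            raise ValueError(f"{c}->{p} is not an edge of the ARG")
        edges.append(((c, p), arg.node_times[p] - arg.node_times[c]))
    return edges, int(path[-1])


def resolve_query(
    arg: ARG,
    q: AncestorQuery,
    basis: PathBasis,
    root_path: tuple[int, ...] | None = None,
) -> ResolvedAncestor:
    """Resolve a (sample, position, time) query against a path basis."""
    node, edge = _walk_to_time(arg, q.sample_id, q.position, q.time)
    edges, root = _root_path_edges(arg, node, edge, q.time, root_path)
    root_index = int(np.searchsorted(basis.roots, root))
    if root_index >= len(basis.roots) or basis.roots[root_index] != root:
        raise ValueError(f"node {root} is not a root of the basis")
    sa = shared_time_with_paths(arg, edges, basis)
    ta = float(arg.node_times[root] - q.time)
    return ResolvedAncestor(
        time=q.time, node=node, edge=edge, root=root,
        root_index=root_index, ta=ta, sa=sa,
    )


def locate(
    arg: ARG,
    locations,
    model,
    q: AncestorQuery,
    level: float = 0.95,
    dispersal=None,
    root_path: tuple[int, ...] | None = None,
) -> AncestorEstimate:
    """Location distribution of the queried ancestor under a fitted model.

    ``model`` is a fitted :class:`~argbm.estimators.BrownianDispersal`.
    ``dispersal`` optionally overrides the fitted rate (e.g. to use a known
    true rate when judging uncertainties separately from dispersal bias).
    """
    basis: PathBasis = model.basis_
    sp = model.shared_times_
    mu = model.root_locations_
    loc = locations_array(arg, locations)
    point = resolve_query(arg, q, basis, root_path=root_path)

    g, _, _ = psd_pinv(sp)
    resid = basis.P @ loc - basis.R @ mu
    mean = mu[point.root_index] + point.sa @ g @ resid

    v_bm = float(point.ta - point.sa @ g @ point.sa)
    e_ra = np.zeros(len(basis.roots))
    e_ra[point.root_index] = 1.0
    w = e_ra - basis.R.T @ g @ point.sa
    v_root = float(w @ solve_spd(basis.R.T @ g @ basis.R, w, "R^T Sp^g- R"))
    tol = 1e-9 * max(1.0, point.ta)
    if v_bm < -tol or v_root < -tol:
        raise AssertionError("negative variance component")
    v_bm, v_root = max(v_bm, 0.0), max(v_root, 0.0)
    v = v_bm + v_root

    disp = (
        model.result_.dispersal_matrix()
        if dispersal is None
        else np.atleast_2d(np.asarray(dispersal, dtype=float))
    )
    cov = disp * v
    d = cov.shape[0]
    interval = None
    ellipse = None
    if d == 1:
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(cov[0, 0], 0.0))
        interval = (float(mean[0] - half), float(mean[0] + half))
    else:
        # chi-squared confidence ellipse in 2D
        evals, evecs = np.linalg.eigh(cov)
        r2 = stats.chi2.ppf(level, df=2)
        ellipse = {
            "half_axes": np.sqrt(np.maximum(evals, 0.0) * r2),
            "axes": evecs,
            "angle_deg": float(
                np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1]))
            ),
        }
    return AncestorEstimate(
        query=q, point=point, mean=np.asarray(mean, dtype=float),
        V=v, V_bm=v_bm, V_root=v_root, covariance=cov, level=level,
        interval=interval, ellipse=ellipse,
    )


def locate_track(
    arg: ARG,
    locations,
    model,
    sample_id: int,
    position: float,
    times,
    level: float = 0.95,
    dispersal=None,
) -> list[AncestorEstimate]:
    """Lineage track: ancestor estimates at an increasing grid of times."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("time grid must be non-decreasing")
    return [
        locate(
            arg, locations, model,
            AncestorQuery(sample_id=sample_id, position=position, time=float(t)),
            level=level, dispersal=dispersal,
        )
        for t in times
    ]


def track_frame(track: list[AncestorEstimate]):
    """Tidy DataFrame of a lineage track (one row per time point)."""
    import pandas as pd

    rows = []
    for est in track:
        row = {
            "sample_id": est.query.sample_id,
            "position": est.query.position,
            "time": est.query.time,
            "V": est.V,
            "V_bm": est.V_bm,
            "V_root": est.V_root,
            "level": est.level,
        }
        if len(est.mean) == 1:
            row.update(x=est.mean[0], lo=est.interval[0], hi=est.interval[1])
        else:
            row.update(
                x=est.mean[0], y=est.mean[1],
                var_x=est.covariance[0, 0], var_y=est.covariance[1, 1],
                cov_xy=est.covariance[0, 1],
            )
        rows.append(row)
    return pd.DataFrame(rows)
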