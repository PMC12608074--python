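"""Sample-path bases and shared-time matrices.

Under Brownian motion down an ARG, the covariance between the locations of
path tips is proportional to the time the paths spend on common edges.  A
full enumeration of sample-to-root paths grows super-linearly with the number
of recombination events, but a *minimal* basis of ``ns + n_recomb`` paths
carries the same information: one canonical path per sample (taking the
lowest-id parent at every recombination node) plus, for each recombination
node, one extra path that deviates there by taking the other parent.

The shared-time matrix ``Sp`` of a path set, the path-to-sample indicator
``P`` and the path-to-root indicator ``R`` feed all downstream likelihood
computations; the sample covariance structure is ``S = (P^T Sp^g- P)^{-1}``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import PSD_RTOL, psd_pinv
from .arg import ARG


@dataclass
class PathBasis:
    """A set of sample-to-root paths with its indicator matrices.

    Attributes
    ----------
    paths : list of tuple
        Node-id sequences, each from a sample (first) to a root (last).
    samples, roots : ndarray
        Column orderings of ``P`` and ``R``.
    P : ndarray, shape (np, ns)
        0/1 matrix; entry (i, j) is 1 iff path i starts at sample j.
    R : ndarray, shape (np, nr)
        0/1 matrix; entry (i, j) is 1 iff path i ends at root j.
    """

    paths: list[tuple[int, ...]]
    samples: np.ndarray
    roots: np.ndarray
    P: np.ndarray = field(repr=False, default=None)
    R: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        ns, nr = len(self.samples), len(self.roots)
        s_ix = {int(s): j for j, s in enumerate(self.samples)}
        r_ix = {int(r): j for j, r in enumerate(self.roots)}
        n_p = len(self.paths)
        self.P = np.zeros((n_p, ns))
        self.R = np.zeros((n_p, nr))
        for i, path in enumerate(self.paths):
            if path[0] not in s_ix:
                raise ValueError(f"path {i} does not start at a sample")
            if path[-1] not in r_ix:
                raise ValueError(f"path {i} does not end at a root")
            self.P[i, s_ix[path[0]]] = 1.0
            self.R[i, r_ix[path[-1]]] = 1.0

    def __len__(self) -> int:
        return len(self.paths)

    @property
    def labels(self) -> list[str]:
        """Path labels of the form ``sample{X}_via{parent-ids}``."""
        return [
            f"sample{p[0]}_via" + "-".join(str(n) for n in p[1:])
            for p in self.paths
        ]


def _descend_to_sample(arg: ARG, top: int) -> list[int]:
    """A route (sample .. top) from a designated sample up to ``top``.

    Prefers descent through canonical edges only, choosing the oldest
    reachable sample (ties broken by lowest id); falls back to any downward
    route if the canonical sub-forest below ``top`` contains no sample.
    Any valid choice yields an equivalent basis (basis independence).
    """
    sample_set = set(int(s) for s in arg.samples)
    for canonical_only in (True, False):
        pred: dict[int, int] = {}
        found: list[int] = []
        stack = [top]
        seen = {top}
        while stack:
            u = stack.pop()
            if u in sample_set:
                found.append(u)
            for c in arg.children(u):
                if c in seen:
                    continue
                if canonical_only and arg.canonical_parents[c] != u:
                    continue
                seen.add(c)
                pred[c] = u
                stack.append(c)
        if found:
            best = max(found, key=lambda s: (arg.node_times[s], -s))
            route = [best]
            while route[-1] != top:
                route.append(pred[route[-1]])
            return route
    raise ValueError(f"node {top} has no descendant sample (malformed ARG)")


def enumerate_minimal_paths(arg: ARG) -> PathBasis:
    """Minimal sample-path basis in a single tip-to-root style traversal.

    Exactly ``ns + n_recomb`` paths for a full ARG (for each node with k >= 2
    distinct parents, one extra path per non-canonical parent): the canonical
    path of every sample, plus for each recombination node an extra path that
    is canonical below it for a designated descendant sample, takes the
    non-canonical parent at the node, and is canonical above.
    """
    if arg.num_samples == 0:
        raise ValueError("ARG has no sample nodes")
    paths: list[tuple[int, ...]] = [
        arg.canonical_path(int(s)) for s in arg.samples
    ]
    for v in arg.recombination_nodes:
        v = int(v)
        below = _descend_to_sample(arg, v)
        for parent in arg.parents(v):
            if parent == arg.canonical_parents[v]:
                continue
            paths.append(tuple(below) + arg.canonical_path(parent))
    return PathBasis(paths=paths, samples=arg.samples, roots=arg.roots)


def enumerate_all_paths(arg: ARG, max_paths: int = 200_000) -> PathBasis:
    """Every sample-to-root path (oracle-scale; grows super-linearly)."""
    paths: list[tuple[int, ...]] = []
    for s in arg.samples:
        stack: list[list[int]] = [[int(s)]]
        while stack:
            cur = stack.pop()
            ps = arg.parents(cur[-1])
            if not ps:
                paths.append(tuple(cur))
            else:
                for p in ps:
                    stack.append(cur + [p])
            if len(paths) > max_paths:
                raise ValueError("too many paths to enumerate")
    return PathBasis(paths=paths, samples=arg.samples, roots=arg.roots)


def path_incidence(arg: ARG, paths: list[tuple[int, ...]]) -> np.ndarray:
    """0/1 incidence of paths over the distinct graph edges, shape (np, E)."""
    m = np.zeros((len(paths), len(arg.graph_edges)))
    for i, path in enumerate(paths):
        for c, p in zip(path[:-1], path[1:]):
            m[i, arg.edge_index[(c, p)]] = 1.0
    return m


def shared_times(arg: ARG, basis: PathBasis | list[tuple[int, ...]]) -> np.ndarray:
    """Shared-time matrix ``Sp`` of a path set (generations).

    Diagonal entry i is the elapsed time from path i's root down to its
    sample; off-diagonal (i, j) is the total duration of edges common to
    paths i and j.  Symmetric PSD.  Paths ending at different roots share
    zero time when their subtrees are disjoint; if a chop severs a
    recombination loop, a sample's paths end at different roots yet still
    share the edges below the recombination node.
    """
    paths = basis.paths if isinstance(basis, PathBasis) else basis
    m = path_incidence(arg, paths)
    return m @ (arg.edge_durations[:, None] * m.T)


def shared_time_with_paths(
    arg: ARG,
    point_path_edges: list[tuple[tuple[int, int], float]],
    basis: PathBasis,
) -> np.ndarray:
    """Shared times between one (possibly partial-edge) root path and every
    basis path.

    ``point_path_edges`` lists ``((child, parent), duration)`` pairs; the
    first entry may carry a partial duration when the path starts mid-edge.
    """
    sa = np.zeros(len(basis))
    edge_sets = [
        {(c, p) for c, p in zip(path[:-1], path[1:])} for path in basis.paths
    ]
    for (c, p), dur in point_path_edges:
        for i, es in enumerate(edge_sets):
            if (c, p) in es:
                sa[i] += dur
    return sa


def sample_matrix(
    Sp: np.ndarray, P: np.ndarray, rtol: float = PSD_RTOL
) -> np.ndarray:
    """Sample covariance structure ``S = (P^T Sp^g- P)^{-1}``.

    ``σ² S`` is the covariance of sample locations after imposing that all
    paths of a sample end at the same location.  For a tree, ``S == Sp``.
    """
    g, _, _ = psd_pinv(Sp, rtol=rtol)
    inner = P.T @ g @ P
    try:
        s = np.linalg.inv(inner)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "P^T Sp^g- P is singular: the path set is redundant or does not "
            "connect every sample to a root"
        ) from err
    return (s + s.T) / 2.0


def basis_to_frame(arg: ARG, basis: PathBasis):
    """Sp with path labels as a DataFrame (CSV-exportable)."""
    import pandas as pd

    sp = shared_times(arg, basis)
    labels = basis.labels
    return pd.DataFrame(sp, index=labels, columns=labels)
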