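"""ARG container and transformations (load, chop, simplify, window).

An ancestral recombination graph (ARG) is held as a tskit ``TreeSequence``
plus derived graph structure: distinct child->parent adjacencies ("graph
edges", collapsing per-span edge table rows), node roles, and the canonical
parent used to break ties at recombination nodes.  Node times increase into
the past; genomic spans are half-open ``[left, right)`` in 0-based
coordinates, following the tree-sequence standard.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tskit


class ARG:
    """A validated ancestral recombination graph.

    Parameters
    ----------
    ts : tskit.TreeSequence
        Tree sequence with node times and flagged sample nodes.  Every edge
        must have strictly positive duration (``time(parent) > time(child)``).

    Attributes
    ----------
    ts : tskit.TreeSequence
        The underlying tree sequence.
    samples : ndarray
        Sorted ids of flagged sample nodes.
    roots : ndarray
        Sorted ids of nodes with no parent edges (that are referenced by an
        edge or are samples).
    recombination_nodes : ndarray
        Sorted ids of nodes with two (or more) distinct parents; their parent
        edges carry complementary genomic spans.
    """

    def __init__(self, ts: tskit.TreeSequence):
        self.ts = ts
        self._build()

    # -- construction -----------------------------------------------------

    def _build(self) -> None:
        ts = self.ts
        times = ts.tables.nodes.time
        parents: dict[int, dict[int, list[tuple[float, float]]]] = {}
        children: dict[int, set[int]] = {}
        referenced: set[int] = set()
        for e in ts.edges():
            if times[e.parent] <= times[e.child]:
                raise ValueError(
                    f"edge {e.child}->{e.parent} has non-positive duration"
                )
            parents.setdefault(e.child, {}).setdefault(e.parent, []).append(
                (e.left, e.right)
            )
            children.setdefault(e.parent, set()).add(e.child)
            referenced.add(e.parent)
            referenced.add(e.child)

        self.node_times = np.asarray(times, dtype=float)
        self.samples = np.asarray(sorted(ts.samples()), dtype=int)
        self._parents = {c: tuple(sorted(ps)) for c, ps in parents.items()}
        self._spans = {
            (c, p): sorted(sp) for c, ps in parents.items() for p, sp in ps.items()
        }
        self._children = {p: tuple(sorted(cs)) for p, cs in children.items()}
        active = referenced | set(self.samples)
        self.roots = np.asarray(
            sorted(n for n in active if n not in self._parents), dtype=int
        )
        self.recombination_nodes = np.asarray(
            sorted(c for c, ps in self._parents.items() if len(ps) >= 2), dtype=int
        )
        # canonical parent: deterministic tie-break (lowest node id)
        self.canonical_parents = {c: ps[0] for c, ps in self._parents.items()}

        # distinct child->parent adjacencies, indexed for incidence algebra
        self.graph_edges: list[tuple[int, int]] = sorted(self._spans)
        self.edge_index = {e: i for i, e in enumerate(self.graph_edges)}
        self.edge_durations = np.array(
            [times[p] - times[c] for c, p in self.graph_edges], dtype=float
        )

    # -- basic queries -----------------------------------------------------

    @property
    def num_samples(self) -> int:
        return len(self.samples)

    @property
    def num_recombination_nodes(self) -> int:
        return len(self.recombination_nodes)

    @property
    def sequence_length(self) -> float:
        return self.ts.sequence_length

    def parents(self, node: int) -> tuple[int, ...]:
        return self._parents.get(node, ())

    def children(self, node: int) -> tuple[int, ...]:
        return self._children.get(node, ())

    def edge_spans(self, child: int, parent: int) -> list[tuple[float, float]]:
        return self._spans[(child, parent)]

    def is_sample(self, node: int) -> bool:
        return bool(self.ts.node(node).is_sample())

    def roles(self, node: int) -> set[str]:
        """Role flags for ``node``: sample / recombination / coalescent /
        common_ancestor / root.

        A node is *coalescent* if it has at least two children at some genome
        position (i.e. in some local tree); a non-sample internal node that is
        never coalescent and not a recombination node is a *common ancestor*
        (unary) node.
        """
        out: set[str] = set()
        if node in set(self.samples):
            out.add("sample")
        if node in self._parents and len(self._parents[node]) >= 2:
            out.add("recombination")
        if node not in self._parents and (
            node in self._children or node in set(self.samples)
        ):
            out.add("root")
        if node in self._children:
            events: list[tuple[float, int]] = []
            for c in self._children[node]:
                for left, right in self._spans[(c, node)]:
                    events.append((left, 1))
                    events.append((right, -1))
            depth = 0
            coal = False
            for _, step in sorted(events):
                depth += step
                if depth >= 2:
                    coal = True
                    break
            if coal:
                out.add("coalescent")
            elif "sample" not in out and "recombination" not in out:
                out.add("common_ancestor")
        return out

    def canonical_path(self, node: int) -> tuple[int, ...]:
        """Path from ``node`` to a root, taking the canonical (lowest-id)
        parent at every recombination node."""
        path = [node]
        while path[-1] in self.canonical_parents:
            path.append(self.canonical_parents[path[-1]])
        return tuple(path)

    def tree_intervals(self) -> list[tuple[float, float]]:
        """Intervals of non-empty local trees, in genome order."""
        return [
            tuple(t.interval) for t in self.ts.trees() if t.num_edges > 0
        ]

    # -- IO ----------------------------------------------------------------

    @classmethod
    def load(cls, path) -> "ARG":
        try:
            ts = tskit.load(str(path))
        except Exception as err:
            raise ValueError(f"could not parse tree-sequence file {path}: {err}")
        return cls(ts)

    def dump(self, path) -> None:
        self.ts.dump(str(path))

    @classmethod
    def from_structure(
        cls,
        node_times: Sequence[float],
        samples: Iterable[int],
        edges: Iterable[tuple[int, int, float, float]],
        sequence_length: float,
    ) -> "ARG":
        """Build an ARG from explicit structure.

        ``edges`` are ``(child, parent, left, right)`` tuples with half-open
        genomic spans.  Convenient for small hand-specified graphs.
        """
        tables = tskit.TableCollection(sequence_length=float(sequence_length))
        sample_set = set(samples)
        for i, t in enumerate(node_times):
            flags = tskit.NODE_IS_SAMPLE if i in sample_set else 0
            tables.nodes.add_row(time=float(t), flags=flags)
        for child, parent, left, right in edges:
            if node_times[parent] <= node_times[child]:
                raise ValueError(
                    f"edge {child}->{parent} has non-positive duration"
                )
            tables.edges.add_row(
                left=float(left), right=float(right), parent=int(parent),
                child=int(child),
            )
        tables.sort()
        return cls(tables.tree_sequence())

    # -- transformations ---------------------------------------------------

    def chop(self, cutoff: float) -> "ARG":
        """Truncate the ARG at ``cutoff`` generations in the past.

        Every edge crossing the cutoff is cut there, with a fresh root node
        inserted at ``time = cutoff`` for each crossing child->parent
        adjacency (no merging: the resulting roots are treated as mutually
        independent).  Strictly older nodes and edges are dropped.
        """
        if cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        times = self.node_times
        if any(times[s] >= cutoff for s in self.samples):
            raise ValueError("cutoff is not older than every sample")
        crossing = any(
            times[e.parent] > cutoff for e in self.ts.edges()
        )
        if not crossing:
            warnings.warn(
                "cutoff is older than the oldest edge; chop is a no-op",
                stacklevel=2,
            )
            return ARG(self.ts)

        tables = self.ts.dump_tables()
        tables.edges.clear()
        new_roots: dict[tuple[int, int], int] = {}
        for e in self.ts.edges():
            tp, tc = times[e.parent], times[e.child]
            if tp <= cutoff:
                tables.edges.add_row(
                    left=e.left, right=e.right, parent=e.parent, child=e.child
                )
            elif tc >= cutoff:
                continue  # entirely above the cutoff (or zero-length stub)
            else:
                key = (e.child, e.parent)
                if key not in new_roots:
                    new_roots[key] = tables.nodes.add_row(time=float(cutoff))
                tables.edges.add_row(
                    left=e.left, right=e.right, parent=new_roots[key],
                    child=e.child,
                )
        tables.sort()
        return ARG(tables.tree_sequence())

    def simplify(self) -> "ARG":
        """Reduce to the simplified ARG: sample nodes plus nodes that are
        coalescent in at least one local tree; edges re-spliced across the
        removed unary (recombination / common-ancestor) nodes.  Node ids are
        preserved.  Used by the averaging-up baseline."""
        ts = self.ts.simplify(filter_nodes=False, filter_sites=True)
        return ARG(ts)

    def restrict(self, left: float, right: float) -> "ARG":
        """ARG restricted to the genomic interval ``[left, right)``."""
        if not (0 <= left < right <= self.sequence_length):
            raise ValueError("invalid genomic interval")
        ts = self.ts.keep_intervals([[left, right]], simplify=False)
        return ARG(ts)

    def window(self, focal_position: float, k_trees_each_side: int) -> "ARG":
        """ARG of the local tree at ``focal_position`` plus ``k`` trees on
        each side (fewer at chromosome ends)."""
        if k_trees_each_side < 0:
            raise ValueError("k_trees_each_side must be >= 0")
        if not (0 <= focal_position < self.sequence_length):
            raise ValueError("focal position outside the sequence")
        intervals = self.tree_intervals()
        focal = next(
            i for i, (l, r) in enumerate(intervals) if l <= focal_position < r
        )
        lo = max(0, focal - k_trees_each_side)
        hi = min(len(intervals) - 1, focal + k_trees_each_side)
        left, right = intervals[lo][0], intervals[hi][1]
        if left == 0 and right == self.sequence_length:
            return ARG(self.ts)
        return self.restrict(left, right)

    def first_trees(self, n_trees: int) -> "ARG":
        """ARG of the first ``n_trees`` local trees from the sequence start."""
        intervals = self.tree_intervals()
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        n = min(n_trees, len(intervals))
        right = intervals[n - 1][1]
        if intervals[0][0] == 0 and right == self.sequence_length:
            return ARG(self.ts)
        return self.restrict(intervals[0][0], right)


# -- module-level convenience wrappers -------------------------------------


def load_arg(path) -> ARG:
    """Load an ARG from a ``.trees`` tree-sequence file."""
    return ARG.load(path)


def chop_arg(arg: ARG, cutoff: float) -> ARG:
    return arg.chop(cutoff)


def simplify_arg(arg: ARG) -> ARG:
    return arg.simplify()


def window_arg(arg: ARG, focal_position: float, k_trees_each_side: int) -> ARG:
    return arg.window(focal_position, k_trees_each_side)


def load_locations(path) -> pd.DataFrame:
    """Read sample coordinates from CSV with header ``sample_id,x[,y]``."""
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns or "x" not in df.columns:
        raise ValueError("locations CSV must have columns sample_id,x[,y]")
    cols = ["sample_id", "x"] + (["y"] if "y" in df.columns else [])
    df = df[cols]
    if df.isna().any().any():
        raise ValueError("missing coordinates in locations table")
    return df


def save_locations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def locations_array(arg: ARG, locations: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Coordinates as an ``(ns, d)`` array aligned with ``arg.samples``.

    Accepts a DataFrame with ``sample_id`` plus coordinate columns, or an
    array already in ``arg.samples`` order.
    """
    if isinstance(locations, pd.DataFrame):
        df = locations.set_index("sample_id")
        missing = [s for s in arg.samples if s not in df.index]
        if missing:
            raise ValueError(f"samples without coordinates: {missing}")
        coord_cols = [c for c in ("x", "y") if c in df.columns]
        arr = df.loc[arg.samples, coord_cols].to_numpy(dtype=float)
    else:
        arr = np.asarray(locations, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != arg.num_samples:
            raise ValueError("locations array does not match number of samples")
    if np.isnan(arr).any():
        raise ValueError("missing coordinates in locations")
    if arr.shape[1] not in (1, 2):
        raise ValueError("only 1D or 2D habitats are supported")
    return arr
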