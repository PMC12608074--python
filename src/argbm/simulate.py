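"""Synthetic data: coalescent full ARGs and Brownian-motion location samplers.

ARG topologies come from msprime's Hudson coalescent with recombination,
recording the full ARG (coalescent, recombination, and common-ancestor
nodes).  Sample and node locations are then drawn under three forward
models, all starting from fixed root locations:

* ``conditioned``  — edge displacements are jointly Gaussian and conditioned
  on every recombination loop closing (both parental lineages meeting at the
  recombination node).  This is the process the ARG likelihood assumes; its
  sample covariance is exactly ``σ² S``.
* ``unconditioned`` — independent edge displacements; each *sample path* gets
  its own tip location (covariance ``σ² Sp``); a sample's paths generally end
  at different points.
* ``midpoint``     — independent edge displacements, but each recombination
  node is placed at the average of its two parents' arrival points.

Every draw records the true node locations, so parameter-recovery, coverage
and bias experiments can compare estimates to the truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import msprime

from scipy import linalg

from .arg import ARG, locations_array
from .paths import PathBasis, enumerate_minimal_paths, path_incidence


@dataclass
class SimConfig:
    """Study conditions for a synthetic dataset.

    Times are generations, lengths base pairs, coordinates habitat units.
    ``dispersal`` is the per-generation variance of offspring displacement
    (scalar, applied isotropically in ``dims`` dimensions, or a full matrix).
    """

    n_samples: int = 50
    sequence_length: float = 1e5
    recombination_rate: float = 1e-8
    population_size: float = 1e4
    dispersal: float | np.ndarray = 1.0
    dims: int = 1
    cutoff: float | None = None
    seed: int = 1

    def dispersal_matrix(self) -> np.ndarray:
        d = np.atleast_2d(np.asarray(self.dispersal, dtype=float))
        if d.shape == (1, 1) and self.dims > 1:
            return np.eye(self.dims) * float(d[0, 0])
        return d


def _msprime_seed(seed: int, stream: int = 0) -> int:
    # msprime needs a seed in [1, 2^32); keep derived seeds below 2^31
    return (int(seed) * 7919 + stream * 104729) % (2**31 - 1) + 1


def simulate_arg(cfg: SimConfig) -> ARG:
    """Full-ARG Hudson coalescent-with-recombination simulation.

    Deterministic given ``cfg`` (including its seed); every local tree is a
    valid coalescent tree.  Nodes are haploid genomes (``ploidy=1``).
    """
    ts = msprime.sim_ancestry(
        samples=cfg.n_samples,
        ploidy=1,
        population_size=cfg.population_size,
        sequence_length=cfg.sequence_length,
        recombination_rate=cfg.recombination_rate,
        record_full_arg=True,
        random_seed=_msprime_seed(cfg.seed),
    )
    arg = ARG(ts)
    return arg.chop(cfg.cutoff) if cfg.cutoff is not None else arg


# -- graph machinery for the location samplers -----------------------------


class _GraphOps:
    """Edge-displacement algebra of an ARG: canonical-path incidence, loop
    constraints, and root bookkeeping."""

    def __init__(self, arg: ARG):
        self.arg = arg
        self.nodes = sorted(
            set(arg.roots)
            | set(int(s) for s in arg.samples)
            | {n for e in arg.graph_edges for n in e}
        )
        self.node_pos = {n: i for i, n in enumerate(self.nodes)}
        n_e = len(arg.graph_edges)
        self.T = arg.edge_durations
        # canonical-path incidence: row n = edges on n's canonical root path
        b = np.zeros((len(self.nodes), n_e))
        root_of = {}
        for n in sorted(self.nodes, key=lambda u: -arg.node_times[u]):
            cp = arg.canonical_parents.get(n)
            if cp is None:
                root_of[n] = n
                continue
            b[self.node_pos[n]] = b[self.node_pos[cp]]
            b[self.node_pos[n], arg.edge_index[(n, cp)]] = 1.0
            root_of[n] = root_of[cp]
        self.B = b
        self.root_of = root_of
        self.root_pos = {int(r): i for i, r in enumerate(arg.roots)}
        # one loop-closure constraint per non-canonical parent edge
        rows, pairs = [], []
        for v in arg.recombination_nodes:
            v = int(v)
            for w in arg.parents(v):
                if w == arg.canonical_parents[v]:
                    continue
                a = b[self.node_pos[v]] - b[self.node_pos[w]]
                a[arg.edge_index[(v, w)]] -= 1.0
                rows.append(a)
                pairs.append((v, w))
        self.A = np.array(rows) if rows else np.zeros((0, n_e))
        self.constraint_pairs = pairs

    def root_location_matrix(self, root_locations: np.ndarray) -> np.ndarray:
        """Per-node canonical-root location, shape (n_nodes, d)."""
        return np.stack(
            [root_locations[self.root_pos[self.root_of[n]]] for n in self.nodes]
        )

    def constraint_offsets(self, root_locations: np.ndarray) -> np.ndarray:
        """Right-hand sides b of A D = b (nonzero only for loops cut across
        different roots), shape (n_constraints, d)."""
        if not self.constraint_pairs:
            return np.zeros((0, root_locations.shape[1]))
        return np.stack(
            [
                root_locations[self.root_pos[self.root_of[w]]]
                - root_locations[self.root_pos[self.root_of[v]]]
                for v, w in self.constraint_pairs
            ]
        )


def _as_root_locations(arg: ARG, root_locations, d: int) -> np.ndarray:
    if root_locations is None:
        return np.zeros((len(arg.roots), d))
    if isinstance(root_locations, dict):
        return np.array(
            [np.broadcast_to(root_locations[int(r)], (d,)) for r in arg.roots],
            dtype=float,
        )
    rl = np.asarray(root_locations, dtype=float)
    if rl.ndim == 1:
        rl = rl[:, None] if d == 1 else np.broadcast_to(rl, (len(arg.roots), d))
    if rl.shape != (len(arg.roots), d):
        raise ValueError("root_locations must be (n_roots, d)")
    return rl


def _dispersal_chol(dispersal, d: int) -> np.ndarray:
    m = np.atleast_2d(np.asarray(dispersal, dtype=float))
    if m.shape == (1, 1) and d > 1:
        m = np.eye(d) * float(m[0, 0])
    if m.shape != (d, d):
        raise ValueError("dispersal has wrong dimension")
    return np.linalg.cholesky(m)


def _draw_edge_displacements(ops: _GraphOps, chol, rng, n_reps: int) -> np.ndarray:
    """Independent edge displacements, shape (E, n_reps, d)."""
    n_e = len(ops.T)
    d = chol.shape[0]
    z = rng.standard_normal((n_e, n_reps, d))
    return np.sqrt(ops.T)[:, None, None] * (z @ chol.T)


def _condition_on_loops(ops: _GraphOps, d0: np.ndarray, offsets: np.ndarray):
    """Project independent displacements onto the loop-closure constraints.

    Linear-Gaussian conditioning of D ~ N(0, Σ ⊗ T) on A D = b; the
    projection ``T A^T (A T A^T)^{-1}`` does not depend on the dispersal.
    """
    if ops.A.shape[0] == 0:
        return d0
    k = ops.A @ (ops.T[:, None] * ops.A.T)
    factor = linalg.cho_factor(k)
    resid = offsets[:, None, :] - np.tensordot(ops.A, d0, axes=(1, 0))
    corr = linalg.cho_solve(factor, resid.reshape(len(ops.A), -1)).reshape(
        resid.shape
    )
    return d0 + ops.T[:, None, None] * np.tensordot(ops.A.T, corr, axes=(1, 0))


@dataclass
class BMDraw:
    """Locations drawn down an ARG, with recorded truth.

    ``node_locations`` has shape ``(n_reps, n_nodes, d)`` in the order of
    ``node_ids``; ``displacements`` (if kept) has shape ``(n_reps, E, d)``
    in ``arg.graph_edges`` order.
    """

    arg: ARG
    node_ids: list[int]
    node_locations: np.ndarray
    dispersal: float | np.ndarray
    displacements: np.ndarray | None = field(default=None, repr=False)
    model: str = "conditioned"

    def _pos(self, node: int) -> int:
        return self.node_ids.index(int(node))

    def locations_of(self, nodes, rep: int = 0) -> np.ndarray:
        return np.stack([self.node_locations[rep, self._pos(n)] for n in nodes])

    def sample_locations(self, rep: int = 0) -> pd.DataFrame:
        arr = self.locations_of(self.arg.samples, rep=rep)
        cols = {"sample_id": self.arg.samples, "x": arr[:, 0]}
        if arr.shape[1] > 1:
            cols["y"] = arr[:, 1]
        return pd.DataFrame(cols)

    def truth_table(self, rep: int = 0) -> pd.DataFrame:
        arr = self.node_locations[rep]
        cols = {
            "node_id": self.node_ids,
            "time": [self.arg.node_times[n] for n in self.node_ids],
            "x": arr[:, 0],
        }
        if arr.shape[1] > 1:
            cols["y"] = arr[:, 1]
        return pd.DataFrame(cols)


def simulate_conditioned_bm(
    arg: ARG,
    dispersal=1.0,
    root_locations=None,
    seed: int | np.random.Generator = 0,
    n_reps: int = 1,
    dims: int | None = None,
    keep_displacements: bool | None = None,
) -> BMDraw:
    """Brownian motion down the full ARG, conditioned on loop closure.

    All edge displacements are drawn jointly Gaussian and conditioned on the
    linear loop constraints (the displacement sums around the two halves of
    every recombination loop agree), so both parents of every recombination
    node land at exactly the same point.  Node locations are accumulated
    from the root locations (default: all roots at the origin).
    """
    d = dims or (np.atleast_2d(np.asarray(dispersal)).shape[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ops = _GraphOps(arg)
    rl = _as_root_locations(arg, root_locations, d)
    chol = _dispersal_chol(dispersal, d)
    d0 = _draw_edge_displacements(ops, chol, rng, n_reps)
    dd = _condition_on_loops(ops, d0, ops.constraint_offsets(rl))
    locs = ops.root_location_matrix(rl)[None, :, :] + np.tensordot(
        ops.B, dd, axes=(1, 0)
    ).transpose(1, 0, 2)
    if keep_displacements is None:
        keep_displacements = n_reps == 1
    return BMDraw(
        arg=arg, node_ids=list(ops.nodes), node_locations=locs,
        dispersal=dispersal, model="conditioned",
        displacements=dd.transpose(1, 0, 2) if keep_displacements else None,
    )


def simulate_unconditioned_bm(
    arg: ARG,
    dispersal=1.0,
    root_locations=None,
    seed: int | np.random.Generator = 0,
    n_reps: int = 1,
    dims: int | None = None,
    basis: PathBasis | None = None,
):
    """Independent Brownian motion along every edge: per-path tip locations.

    Returns ``(tips, basis)`` where ``tips`` has shape ``(n_reps, np, d)``;
    the paths of one sample generally end at different locations, and the
    tip covariance is ``σ² Sp``.
    """
    d = dims or (np.atleast_2d(np.asarray(dispersal)).shape[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if basis is None:
        basis = enumerate_minimal_paths(arg)
    ops = _GraphOps(arg)
    rl = _as_root_locations(arg, root_locations, d)
    chol = _dispersal_chol(dispersal, d)
    d0 = _draw_edge_displacements(ops, chol, rng, n_reps)
    m = path_incidence(arg, basis.paths)
    tips = np.tensordot(m, d0, axes=(1, 0)).transpose(1, 0, 2)
    tips += (basis.R @ rl)[None, :, :]
    return tips, basis


def simulate_midpoint_bm(
    arg: ARG,
    dispersal=1.0,
    root_locations=None,
    seed: int | np.random.Generator = 0,
    n_reps: int = 1,
    dims: int | None = None,
    keep_displacements: bool | None = None,
) -> BMDraw:
    """Alternate recombination model: independent edge displacements, with
    each recombination node placed at the average of its parents' arrival
    points before propagating to its children."""
    d = dims or (np.atleast_2d(np.asarray(dispersal)).shape[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ops = _GraphOps(arg)
    rl = _as_root_locations(arg, root_locations, d)
    chol = _dispersal_chol(dispersal, d)
    d0 = _draw_edge_displacements(ops, chol, rng, n_reps)
    arg_ = arg
    locs = np.zeros((len(ops.nodes), n_reps, d))
    for n in sorted(ops.nodes, key=lambda u: -arg_.node_times[u]):
        i = ops.node_pos[n]
        parents = arg_.parents(n)
        if not parents:
            locs[i] = rl[ops.root_pos[n]]
            continue
        arrivals = [
            locs[ops.node_pos[p]] + d0[arg_.edge_index[(n, p)]] for p in parents
        ]
        locs[i] = np.mean(arrivals, axis=0)
    if keep_displacements is None:
        keep_displacements = n_reps == 1
    return BMDraw(
        arg=arg, node_ids=list(ops.nodes),
        node_locations=locs.transpose(1, 0, 2), dispersal=dispersal,
        model="midpoint",
        displacements=d0.transpose(1, 0, 2) if keep_displacements else None,
    )


def conditioned_location_covariance(arg: ARG):
    """Exact node-location covariance factor under the conditioned model.

    Returns ``(node_ids, V)`` with ``Cov(locations) = dispersal × V`` given
    fixed root locations; computed from the conditioned Gaussian in closed
    form (no sampling).  On a single-loop ARG the diagonal entry of the
    recombination node is half the arm time (the Brownian-bridge value).
    """
    ops = _GraphOps(arg)
    t = ops.T
    cov_d = np.diag(t)
    if ops.A.shape[0] > 0:
        k = ops.A @ (t[:, None] * ops.A.T)
        ta = t[:, None] * ops.A.T
        cov_d = cov_d - ta @ linalg.cho_solve(linalg.cho_factor(k), ta.T)
    v = ops.B @ cov_d @ ops.B.T
    return list(ops.nodes), (v + v.T) / 2.0


SAMPLERS = {
    "conditioned": simulate_conditioned_bm,
    "midpoint": simulate_midpoint_bm,
}


def _simulate_arg_with_trees(cfg: SimConfig, min_trees: int, max_tries: int = 50) -> ARG:
    for attempt in range(max_tries):
        arg = simulate_arg(replace(cfg, seed=cfg.seed + 1_000_003 * attempt))
        if len(arg.tree_intervals()) >= min_trees:
            return arg
    raise RuntimeError(
        f"could not simulate an ARG with >= {min_trees} trees in {max_tries} tries; "
        "increase sequence_length or recombination_rate"
    )


def bias_experiment(
    cfg: SimConfig,
    tree_counts: list[int],
    n_reps: int,
    data_model: str = "midpoint",
    methods: tuple[str, ...] = ("arg", "composite"),
    design: str | None = None,
) -> pd.DataFrame:
    """Dispersal estimates as a function of the number of trees used.

    For each replicate an ARG is simulated and sample locations are drawn
    under ``data_model``; each estimator is then run on the ARG restricted
    to the first ``k`` trees for every ``k`` in ``tree_counts``.

    ``design='nested'`` draws one set of sample locations on the full
    (chopped) ARG and re-fits nested windows of it — the model-misspecified
    setting in which the ARG estimate climbs with the number of trees.
    ``design='redraw'`` draws fresh locations on each windowed ARG, so the
    ``conditioned`` data model is exactly the process the ARG likelihood
    assumes at every window size (the well-specified control).  The default
    picks ``nested`` for midpoint data and ``redraw`` for conditioned data.
    """
    from . import baselines
    from .estimators import fit as arg_fit

    if data_model not in SAMPLERS:
        raise ValueError(f"unknown data model {data_model!r}")
    if design is None:
        design = "redraw" if data_model == "conditioned" else "nested"
    if design not in ("nested", "redraw"):
        raise ValueError("design must be 'nested' or 'redraw'")
    sampler = SAMPLERS[data_model]
    k_max = max(tree_counts)
    rows = []
    for rep in range(n_reps):
        rep_cfg = replace(cfg, seed=cfg.seed + 7 * rep + 1)
        arg = _simulate_arg_with_trees(rep_cfg, min_trees=k_max)
        rng = np.random.default_rng(rep_cfg.seed)
        if design == "nested":
            full = arg.first_trees(k_max)
            draw = sampler(
                full, dispersal=cfg.dispersal, seed=rng,
                n_reps=1, dims=cfg.dims, keep_displacements=False,
            )
            loc_df = draw.sample_locations()
        for k in sorted(tree_counts):
            sub = arg.first_trees(k)
            if design == "redraw":
                draw = sampler(
                    sub, dispersal=cfg.dispersal, seed=rng,
                    n_reps=1, dims=cfg.dims, keep_displacements=False,
                )
                loc_df = draw.sample_locations()
            for method in methods:
                if method == "arg":
                    res = arg_fit(sub, loc_df)
                    disp, n_paths = res.dispersal, res.n_paths
                elif method == "composite":
                    disp = baselines.composite_dispersal(sub, loc_df, k)
                    n_paths = np.nan
                elif method == "midpoint":
                    res = baselines.midpoint_fit(sub, loc_df)
                    disp, n_paths = res.dispersal, np.nan
                else:
                    raise ValueError(f"unknown method {method!r}")
                sigma2 = (
                    float(disp)
                    if np.ndim(disp) == 0
                    else float(np.trace(np.atleast_2d(disp)) / cfg.dims)
                )
                rows.append(
                    {
                        "rep": rep,
                        "n_trees": k,
                        "method": method,
                        "sigma2_hat": sigma2,
                        "n_recomb": sub.num_recombination_nodes,
                        "n_paths": n_paths,
                    }
                )
    return pd.DataFrame(rows)
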