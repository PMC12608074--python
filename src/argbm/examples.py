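"""Small hand-built ARGs used in the documentation and tests.

All are full ARGs (with recombination and unary nodes) specified directly
from node times and edges; coordinates of spans are base pairs, times are
generations.
"""
from __future__ import annotations

from .arg import ARG


def two_sample_loop_arg() -> ARG:
    """Two samples below a single recombination loop.

    Samples A(0) and B(1) coalesce at C(2, t=1); that lineage recombines at
    E(3, t=2) whose parents are F(4, t=3) over [0, 1) and the root G(5, t=4)
    over [1, 2); F's lineage rejoins G, closing the loop G->F->E / G->E.
    A and B each have two sample paths; the minimal basis has 3.
    """
    return ARG.from_structure(
        node_times=[0, 0, 1, 2, 3, 4],
        samples=[0, 1],
        edges=[
            (0, 2, 0, 2),  # A -> C
            (1, 2, 0, 2),  # B -> C
            (2, 3, 0, 2),  # C -> E
            (3, 4, 0, 1),  # E -> F (left span)
            (3, 5, 1, 2),  # E -> G (right span)
            (4, 5, 0, 2),  # F -> G
        ],
        sequence_length=2,
    )


def single_loop_arg(arm_time: float = 2.0) -> ARG:
    """A single symmetric recombination loop with a sample under each arm.

    Sample X(0) hangs below the recombination node E(2); sample Y(1) hangs
    below F(3), the midpoint of one arm.  Both arms of the loop from the
    root G(4) down to E last ``arm_time`` generations, so under the
    conditioned model Var(E) = dispersal * arm_time / 2 while the midpoint
    model leaves Var(F) = dispersal * (arm_time / 2) un-reduced.
    """
    t = float(arm_time)
    return ARG.from_structure(
        node_times=[0, 0, t, 1.5 * t, 2 * t],
        samples=[0, 1],
        edges=[
            (0, 2, 0, 2),  # X -> E
            (1, 3, 0, 2),  # Y -> F
            (2, 3, 0, 1),  # E -> F (left arm, lower half)
            (2, 4, 1, 2),  # E -> G (right arm)
            (3, 4, 0, 2),  # F -> G (left arm, upper half)
        ],
        sequence_length=2,
    )


def two_tree_arg(
    t_f: float = 1.0, t_h: float = 2.0, t_e: float = 3.0,
    t_g: float = 4.0, t_q: float = 5.0,
) -> ARG:
    """A two-tree ARG with four samples, used to probe ancestor locations.

    Samples A(0), B(1), C(2), D(3).  C's lineage recombines at F(4); A and B
    coalesce at H(5); in tree 1 F joins the coalescent node E(6), in tree 2
    it attaches directly to G(7), where the recombination loop closes; the
    root is Q(8).  Node H is the ancestor whose estimated location is
    tracked as node times move: deepening the loop-closing node G gives C's
    lineage more time to wander from the loop, pulling the estimate of H
    towards A and B.
    """
    return ARG.from_structure(
        node_times=[0, 0, 0, 0, t_f, t_h, t_e, t_g, t_q],
        samples=[0, 1, 2, 3],
        edges=[
            (0, 5, 0, 2),  # A -> H
            (1, 5, 0, 2),  # B -> H
            (2, 4, 0, 2),  # C -> F
            (4, 6, 0, 1),  # F -> E (tree 1)
            (4, 7, 1, 2),  # F -> G (tree 2): loop F->E->G / F->G
            (5, 6, 0, 2),  # H -> E
            (6, 7, 0, 2),  # E -> G
            (7, 8, 0, 2),  # G -> Q
            (3, 8, 0, 2),  # D -> Q
        ],
        sequence_length=2,
    )


def three_sample_tree() -> ARG:
    """A plain 3-leaf tree (an ARG with no recombination nodes)."""
    return ARG.from_structure(
        node_times=[0, 0, 0, 1, 2],
        samples=[0, 1, 2],
        edges=[
            (0, 3, 0, 1),
            (1, 3, 0, 1),
            (3, 4, 0, 1),
            (2, 4, 0, 1),
        ],
        sequence_length=1,
    )
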