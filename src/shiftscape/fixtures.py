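"""Synthetic trees, run summaries and independent checking oracles.

These make the validation experiments self-contained: a caterpillar ("comb")
tree whose spine provides discrete generations, a pure-birth tree as a
realistically shaped phylogeny, per-depth substitution summaries, and the
matrix-exponential transition-probability oracle used to cross-check the
event loop against the analytic law of the fixed-landscape chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .landscape_core import RateMatrix
from .engine import SimulationResult
from .phylogeny import Tree, TreeNode

__all__ = [
    "make_comb_tree",
    "make_single_branch_tree",
    "make_birth_death_tree",
    "ValidationSummary",
    "summarize",
    "transition_probability_oracle",
]


def make_comb_tree(depth: int, branch_length: float = 1.0) -> Tree:
    """A caterpillar tree of ``depth`` generations, all branches equal.

    Every internal node has two children, one of which is a leaf; the spine
    runs root -> S1 -> ... and ends in a cherry, so the deepest leaves sit at
    global time ``depth * branch_length``.  A comb of depth d has d internal
    nodes (the root included), d+1 leaves and 2d branches.
    """
    if depth < 1:
        raise ValueError("comb depth must be >= 1")
    if branch_length <= 0:
        raise ValueError("branch length must be > 0")
    root = TreeNode("S0")
    spine = root
    for d in range(1, depth):
        leaf = TreeNode(f"L{d - 1}", branch_length)
        nxt = TreeNode(f"S{d}", branch_length)
        spine.add_child(nxt)
        spine.add_child(leaf)
        spine = nxt
    spine.add_child(TreeNode(f"L{depth - 1}", branch_length))
    spine.add_child(TreeNode(f"L{depth - 1}b", branch_length))
    return Tree(root)


def make_single_branch_tree(length: float, name: str = "A") -> Tree:
    """A root with one child at distance ``length`` (the minimal phylogeny)."""
    root = TreeNode("root")
    root.add_child(TreeNode(name, length))
    return Tree(root)


def make_birth_death_tree(n_leaves: int, rate: float, rng: np.random.Generator) -> Tree:
    """A pure-birth (Yule) tree with ``n_leaves`` extant species.

    Lineages split at total rate ``rate * k`` when ``k`` are alive; after the
    last split the clock runs one further exponential waiting time and all
    leaves are cut contemporaneously.  Used as a realistically shaped fixture
    only; no numeric claim rests on its branch lengths.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if rate <= 0:
        raise ValueError("birth rate must be > 0")
    root = TreeNode("")
    t = 0.0
    active: list[tuple[TreeNode, float]] = []  # (node, birth time)
    for _ in range(2):
        child = TreeNode("")
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / (rate * len(active)))
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.branch_length = t - birth
        for _ in range(2):
            child = TreeNode("")
            node.add_child(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / (rate * len(active)))
    leaf_no = 1
    for node, birth in active:
        node.branch_length = t_end - birth
        node.name = f"T{leaf_no}"
        leaf_no += 1
    return Tree(root)


@dataclass
class ValidationSummary:
    """Replicate-level summaries of a batch of simulation results."""

    change_count_mean: float
    change_count_sd: float
    per_depth_substituted_fraction: dict[int, float]
    leaf_allele_frequencies: dict[str, float]

    def __post_init__(self):
        if self.change_count_sd < 0:
            raise ValueError("standard deviation cannot be negative")
        for d, f in self.per_depth_substituted_fraction.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"substituted fraction at depth {d} outside [0, 1]: {f}")


def summarize(results: Sequence[SimulationResult], tree: Tree) -> ValidationSummary:
    """Pool change counts, per-depth substitution fractions and leaf frequencies.

    The per-depth fraction at depth ``d`` is the fraction of positions whose
    symbol differs between a node at ``d`` edges from the root and its
    parent, averaged over all such nodes and all results.  Leaf allele
    frequencies are pooled over every leaf and position.
    """
    if not results:
        raise ValueError("no results to summarize")
    node_names = set(results[0].node_sequences)
    for res in results[1:]:
        if set(res.node_sequences) != node_names:
            raise ValueError("results were produced on different trees")
    counts = np.array([res.n_changes for res in results], dtype=float)
    diff_by_depth: dict[int, list[float]] = {}
    symbol_counts: dict[str, int] = {}
    total_leaf_positions = 0
    for res in results:
        for node in tree.bfs():
            seq = res.node_sequences[node.name]
            if node.parent is not None and len(seq) > 0:
                pseq = res.node_sequences[node.parent.name]
                frac = sum(a != b for a, b in zip(seq, pseq)) / len(seq)
                diff_by_depth.setdefault(tree.depth[node.name], []).append(frac)
            if node.is_leaf:
                for c in seq:
                    symbol_counts[c] = symbol_counts.get(c, 0) + 1
                total_leaf_positions += len(seq)
    per_depth = {d: float(np.mean(v)) for d, v in sorted(diff_by_depth.items())}
    freqs = (
        {s: c / total_leaf_positions for s, c in sorted(symbol_counts.items())}
        if total_leaf_positions
        else {}
    )
    return ValidationSummary(
        change_count_mean=float(counts.mean()),
        change_count_sd=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        per_depth_substituted_fraction=per_depth,
        leaf_allele_frequencies=freqs,
    )


def transition_probability_oracle(Q: RateMatrix, t: float) -> np.ndarray:
    """Allele transition probabilities over time ``t``: ``expm(Q t)``.

    Computed by scaling-and-squaring, entirely outside the event loop, so it
    serves as an independent check of simulated transition frequencies.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    P = expm(Q.rates * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)
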