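"""Sankoff parsimony reconstruction of ancestral diploid numbers on a tree.

The character is the diploid chromosome number 2n over a finite grid of even
states; the transition cost between two states is the minimal number of
rearrangement events separating them (|delta 2n| / 2 translocations or
fissions, optionally with asymmetric weights). A dynamic program over the
rooted tree (Sankoff's algorithm) yields, for every node, the set of states
attained by at least one globally minimal-cost labeling, via a standard
inside (leaves-to-root) and outside (root-to-leaves) pass. A brute-force
enumerator over all internal labelings serves as an independent oracle for
small trees.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import dendropy
import numpy as np

from .rearrangements import EventCount, count_translocations_fissions

logger = logging.getLogger(__name__)

DEFAULT_STATE_SET: tuple[int, ...] = tuple(range(40, 65, 2))

LABELING_POLICIES = ("prefer-ancestral-max", "prefer-ancestral-min", "all-optimal")


class TreeNode:
    """A node of a rooted phylogeny (polytomies permitted)."""

    __slots__ = ("name", "children", "parent", "edge_length", "uncertain")

    def __init__(
        self,
        name: str | None = None,
        edge_length: float | None = None,
        uncertain: bool = False,
    ):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.edge_length = edge_length
        self.uncertain = uncertain

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {self.name!r} {kind}>"


class PhyloTree:
    """A rooted tree with uniquely labeled tips.

    Branches may carry an ``uncertain`` flag (serialized as a ``[&uncertain]``
    Newick comment) marking relationships the source phylogeny leaves dashed;
    :meth:`collapse_uncertain` turns those branches into polytomies for
    sensitivity analyses.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [t.name for t in self.tips()]
        if not labels:
            raise ValueError("tree has no tips")
        if any(lbl is None for lbl in labels):
            raise ValueError("every tip must be labeled")
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise ValueError(f"duplicate tip labels: {sorted(dup)}")

    # -- traversal -----------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for c in node.children:
                yield from walk(c)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tips()]  # type: ignore[misc]

    def find(self, name: str) -> TreeNode | None:
        for n in self.postorder():
            if n.name == name:
                return n
        return None

    def n_internal(self) -> int:
        return sum(1 for n in self.postorder() if not n.is_tip)

    # -- edits ---------------------------------------------------------------

    def prune_tips(self, labels: set[str]) -> "PhyloTree":
        """Return a copy with the given tips removed (unary nodes contracted)."""

        def copy(node: TreeNode) -> TreeNode | None:
            if node.is_tip:
                if node.name in labels:
                    return None
                clone = TreeNode(node.name, node.edge_length, node.uncertain)
                return clone
            kids = [c for c in (copy(c) for c in node.children) if c is not None]
            if not kids:
                return None
            if len(kids) == 1 and node.parent is not None:
                # contract the unary node, summing branch lengths when present
                child = kids[0]
                if node.edge_length is not None and child.edge_length is not None:
                    child.edge_length += node.edge_length
                elif child.edge_length is None:
                    child.edge_length = node.edge_length
                child.uncertain = child.uncertain or node.uncertain
                return child
            clone = TreeNode(node.name, node.edge_length, node.uncertain)
            for k in kids:
                clone.add_child(k)
            return clone

        new_root = copy(self.root)
        if new_root is None:
            raise ValueError("pruning removed every tip")
        return PhyloTree(new_root)

    def collapse_uncertain(self) -> "PhyloTree":
        """Return a copy in which uncertain internal branches are collapsed."""

        def copy(node: TreeNode) -> TreeNode:
            clone = TreeNode(node.name, node.edge_length, node.uncertain)
            for c in node.children:
                cc = copy(c)
                if cc.uncertain and not cc.is_tip:
                    for gc in cc.children:
                        clone.add_child(gc)
                else:
                    clone.add_child(cc)
            return clone

        return PhyloTree(copy(self.root))

    # -- Newick I/O (via dendropy) -------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        """Parse a rooted Newick tree; a path or a Newick string is accepted."""
        looks_like_data = isinstance(source, str) and (
            "(" in source or source.rstrip().endswith(";")
        )
        text = str(source) if looks_like_data else Path(source).read_text()
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:  # normalise dendropy's reader exceptions
            if "Duplicate" in str(exc) or "duplicate" in str(exc):
                raise ValueError(f"duplicate tip labels in Newick input: {exc}") from exc
            raise ValueError(f"could not parse Newick input: {exc}") from exc

        def convert(dnode: dendropy.Node) -> TreeNode:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            else:
                name = dnode.label
            uncertain = any("uncertain" in (c or "") for c in dnode.comments)
            node = TreeNode(name, dnode.edge.length, uncertain)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self, annotations: Mapping[int, str] | None = None) -> str:
        """Serialize to Newick. ``annotations`` maps ``id(node)`` to a comment
        string appended after the node label."""

        def quote(name: str | None) -> str:
            if not name:
                return ""
            if any(ch in name for ch in " (),:;[]'"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def write(node: TreeNode) -> str:
            if node.is_tip:
                s = quote(node.name)
            else:
                s = "(" + ",".join(write(c) for c in node.children) + ")"
                s += quote(node.name)
            if node.uncertain:
                s += "[&uncertain]"
            if annotations and id(node) in annotations:
                s += f"[&{annotations[id(node)]}]"
            if node.edge_length is not None:
                s += f":{node.edge_length:g}"
            return s

        return write(self.root) + ";"


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostModel:
    """Transition costs between diploid numbers, in rearrangement events.

    ``cost(a, b)`` is the event count on a branch from ancestral state ``a``
    to descendant ``b``: ``w_T`` per translocation (2n decrease of 2) and
    ``w_F`` per fission (2n increase of 2).
    """

    state_set: tuple[int, ...] = DEFAULT_STATE_SET
    w_T: float = 1.0
    w_F: float = 1.0

    def __post_init__(self) -> None:
        states = tuple(sorted(int(s) for s in self.state_set))
        if not states:
            raise ValueError("state set is empty")
        if any(s % 2 for s in states):
            raise ValueError("diploid states must be even")
        if self.w_T < 0 or self.w_F < 0:
            raise ValueError("event weights must be non-negative")
        object.__setattr__(self, "state_set", states)

    def cost(self, ancestral: int, descendant: int) -> float:
        steps = (ancestral - descendant) // 2
        return self.w_T * steps if steps >= 0 else -self.w_F * steps

    def cost_matrix(self) -> np.ndarray:
        """Matrix C[i, j] = cost(state_i -> state_j)."""
        s = np.asarray(self.state_set)
        delta = (s[:, None] - s[None, :]) // 2
        return np.where(delta >= 0, self.w_T * delta, -self.w_F * delta).astype(float)


@dataclass
class ReconstructionResult:
    """Outcome of an ancestral-state reconstruction.

    ``node_costs[node]`` holds the minimal subtree (inside) cost per state;
    ``optimal_states[node]`` the states attained by at least one globally
    optimal labeling. Ties are reported as sets and never broken silently.
    """

    tree: PhyloTree
    cost_model: CostModel
    tip_states: dict[str, int]
    node_costs: dict[int, np.ndarray]
    optimal_states: dict[int, frozenset[int]]
    total_cost: float
    pruned_tips: tuple[str, ...] = ()
    branch_events: dict[int, EventCount] = field(default_factory=dict)

    @property
    def root_states(self) -> frozenset[int]:
        return self.optimal_states[id(self.tree.root)]

    def states_of(self, name: str) -> frozenset[int]:
        node = self.tree.find(name)
        if node is None:
            raise KeyError(f"no node named {name!r}")
        return self.optimal_states[id(node)]


def _prepare(
    tree: PhyloTree,
    tip_states: Mapping[str, int],
    cost_model: CostModel,
    prune_missing: bool,
) -> tuple[PhyloTree, dict[str, int], tuple[str, ...]]:
    labels = set(tree.tip_labels())
    missing = labels - set(tip_states)
    states = {l: int(tip_states[l]) for l in labels & set(tip_states)}
    for lbl, s in states.items():
        if s not in cost_model.state_set:
            raise ValueError(
                f"tip {lbl!r} has state {s} outside the state set "
                f"[{cost_model.state_set[0]}..{cost_model.state_set[-1]}]"
            )
    if missing:
        if not prune_missing:
            raise ValueError(f"tips lacking states: {sorted(missing)}")
        logger.warning("pruning %d tip(s) lacking states: %s", len(missing), sorted(missing))
        if missing == labels:
            raise ValueError("no tip has an observed state")
        tree = tree.prune_tips(missing)
    return tree, states, tuple(sorted(missing))


def sankoff_reconstruct(
    tree: PhyloTree,
    tip_states: Mapping[str, int],
    cost_model: CostModel | None = None,
    prune_missing: bool = True,
) -> ReconstructionResult:
    """Minimal-cost ancestral diploid numbers by Sankoff's dynamic program.

    The inside pass computes, leaves to root, each node's minimal subtree cost
    per candidate state; the outside pass propagates the cost of the rest of
    the tree back down, so that every node's reported state set is exactly the
    set of states occurring in at least one globally optimal labeling.
    Tips without an entry in ``tip_states`` are pruned with a logged warning
    (or rejected when ``prune_missing=False``).
    """
    cm = cost_model or CostModel()
    tree, states, pruned = _prepare(tree, tip_states, cm, prune_missing)
    S = np.asarray(cm.state_set)
    C = cm.cost_matrix()
    k = len(S)

    inside: dict[int, np.ndarray] = {}
    # trans_in[child] = per-parent-state min over child states of C + inside
    trans_in: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            vec = np.full(k, np.inf)
            vec[int(np.searchsorted(S, states[node.name]))] = 0.0
        else:
            vec = np.zeros(k)
            for child in node.children:
                t = np.min(C + inside[id(child)][None, :], axis=1)
                trans_in[id(child)] = t
                vec = vec + t
        inside[id(node)] = vec

    root_vec = inside[id(tree.root)]
    total = float(np.min(root_vec))

    # outside pass: cost of everything outside each node's subtree, per state
    outside: dict[int, np.ndarray] = {id(tree.root): np.zeros(k)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        for child in node.children:
            # parent context excluding this child's subtree
            ctx = outside[id(node)] + inside[id(node)] - trans_in[id(child)]
            outside[id(child)] = np.min(ctx[:, None] + C, axis=0)

    optimal: dict[int, frozenset[int]] = {}
    for node in tree.postorder():
        tot = inside[id(node)] + outside[id(node)]
        opt = frozenset(int(s) for s in S[np.isclose(tot, total)])
        optimal[id(node)] = opt

    for t in tree.tips():
        assert optimal[id(t)] == frozenset({states[t.name]})

    return ReconstructionResult(
        tree=tree,
        cost_model=cm,
        tip_states=states,
        node_costs=inside,
        optimal_states=optimal,
        total_cost=total,
        pruned_tips=pruned,
    )


MAX_BRUTE_FORCE_INTERNAL = 8


def brute_force_reconstruct(
    tree: PhyloTree,
    tip_states: Mapping[str, int],
    cost_model: CostModel | None = None,
    prune_missing: bool = True,
) -> ReconstructionResult:
    """Exhaustive-enumeration oracle: identical contract to
    :func:`sankoff_reconstruct`, restricted to small trees."""
    cm = cost_model or CostModel()
    tree, states, pruned = _prepare(tree, tip_states, cm, prune_missing)
    internal = [n for n in tree.postorder() if not n.is_tip]
    if len(internal) > MAX_BRUTE_FORCE_INTERNAL:
        raise ValueError(
            f"brute force refused: {len(internal)} internal nodes exceed the "
            f"limit of {MAX_BRUTE_FORCE_INTERNAL}"
        )
    if not internal:  # single-tip degenerate tree
        only = tree.root
        s = states[only.name]
        k = len(cm.state_set)
        vec = np.full(k, np.inf)
        vec[cm.state_set.index(s)] = 0.0
        return ReconstructionResult(
            tree=tree,
            cost_model=cm,
            tip_states=states,
            node_costs={id(only): vec},
            optimal_states={id(only): frozenset({s})},
            total_cost=0.0,
            pruned_tips=pruned,
        )

    best = np.inf
    opt_states: dict[int, set[int]] = {id(n): set() for n in tree.postorder()}
    for assignment in itertools.product(cm.state_set, repeat=len(internal)):
        label = {id(n): s for n, s in zip(internal, assignment)}
        for t in tree.tips():
            label[id(t)] = states[t.name]
        cost = 0.0
        for node in tree.postorder():
            for child in node.children:
                cost += cm.cost(label[id(node)], label[id(child)])
        if cost < best - 1e-9:
            best = cost
            opt_states = {k_: set() for k_ in opt_states}
        if cost < best + 1e-9:
            for node in tree.postorder():
                opt_states[id(node)].add(label[id(node)])

    return ReconstructionResult(
        tree=tree,
        cost_model=cm,
        tip_states=states,
        node_costs={},
        optimal_states={k_: frozenset(v) for k_, v in opt_states.items()},
        total_cost=float(best),
        pruned_tips=pruned,
    )


def annotate_branch_events(
    result: ReconstructionResult,
    labeling_policy: str = "prefer-ancestral-max",
) -> dict[int, EventCount]:
    """Per-branch translocation/fission counts under one optimal labeling.

    ``labeling_policy`` resolves ties top-down: ``prefer-ancestral-max`` (the
    default) picks the largest optimal state at each node given its parent's
    chosen state, ``prefer-ancestral-min`` the smallest. ``all-optimal``
    instead returns, per branch, the event counts of every (parent, child)
    state pair realised by some optimal labeling, as a frozenset.

    The returned mapping is keyed by ``id(child_node)`` on ``result.tree``;
    summing one labeling's counts reproduces ``result.total_cost`` (for unit
    weights).
    """
    if labeling_policy not in LABELING_POLICIES:
        raise ValueError(
            f"unknown labeling policy {labeling_policy!r}; "
            f"choose from {LABELING_POLICIES}"
        )
    tree, cm = result.tree, result.cost_model
    if not result.node_costs:
        raise ValueError("result lacks cost vectors (use sankoff_reconstruct)")
    S = np.asarray(cm.state_set)
    pick = max if labeling_policy == "prefer-ancestral-max" else min

    if labeling_policy == "all-optimal":
        out: dict[int, frozenset[EventCount]] = {}
        for node in tree.preorder():
            for child in node.children:
                pairs = set()
                for a in result.optimal_states[id(node)]:
                    for b in result.optimal_states[id(child)]:
                        if _pair_feasible(result, node, child, a, b):
                            pairs.add(count_translocations_fissions(a, b))
                out[id(child)] = frozenset(pairs)
        result.branch_events = out  # type: ignore[assignment]
        return out  # type: ignore[return-value]

    chosen: dict[int, int] = {id(tree.root): pick(result.root_states)}
    events: dict[int, EventCount] = {}
    for node in tree.preorder():
        a = chosen[id(node)]
        for child in node.children:
            vec = result.node_costs[id(child)]
            totals = np.array([cm.cost(a, int(s)) for s in S]) + vec
            m = float(np.min(totals))
            cands = [int(s) for s in S[np.isclose(totals, m)]]
            b = pick(cands)
            chosen[id(child)] = b
            events[id(child)] = count_translocations_fissions(a, b)
    result.branch_events = events
    return events


def _pair_feasible(
    result: ReconstructionResult, node: TreeNode, child: TreeNode, a: int, b: int
) -> bool:
    """True if some globally optimal labeling sets (node=a, child=b)."""
    cm = result.cost_model
    S = list(cm.state_set)
    ia = S.index(a)
    inside_child = result.node_costs[id(child)]
    # inside cost of node at a, excluding child's subtree
    C = cm.cost_matrix()
    trans = float(np.min(C[ia] + inside_child))
    inside_node = result.node_costs[id(node)][ia]
    excl = inside_node - trans
    # outside cost of node at state a = total when node=a minus inside at a
    # recover via the identity total(node, a) >= total_cost with equality iff optimal
    outside_node = _outside_cost(result, node, ia)
    total = outside_node + excl + cm.cost(a, b) + inside_child[S.index(b)]
    return bool(np.isclose(total, result.total_cost))


def _outside_cost(result: ReconstructionResult, node: TreeNode, state_idx: int) -> float:
    """Outside cost (everything except node's subtree) at the given state."""
    tree, cm = result.tree, result.cost_model
    C = cm.cost_matrix()
    # recompute outside vectors on demand (cached on the result)
    cache = getattr(result, "_outside_cache", None)
    if cache is None:
        k = len(cm.state_set)
        cache = {id(tree.root): np.zeros(k)}
        for n in tree.preorder():
            if n.is_tip:
                continue
            for ch in n.children:
                trans = np.min(C + result.node_costs[id(ch)][None, :], axis=1)
                ctx = cache[id(n)] + result.node_costs[id(n)] - trans
                cache[id(ch)] = np.min(ctx[:, None] + C, axis=0)
        object.__setattr__(result, "_outside_cache", cache)
    return float(cache[id(node)][state_idx])
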