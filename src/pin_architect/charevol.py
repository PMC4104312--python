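"""Character evolution on the clade tree: origins of noncanonical structure.

Noncanonical PIN structure is scattered across the family tree, and under
the inference that the last common ancestor of land plants carried a single
canonical PIN, the scatter implies repeated independent origins.  The
minimum number of 0 -> 1 (canonical -> noncanonical) transitions is found
by a Sankoff-style dynamic program with the root fixed at canonical:
total state changes are minimised first, and among minimum-change
labelings, the count of 0 -> 1 edges is minimised secondarily (reversals
are allowed at equal cost).  On the bundled reference cladogram with the
published state assignments the answer is seven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import dendropy

CANONICAL, NONCANONICAL = 0, 1

# lexicographic (total changes, origins) packed into one integer; ORIGIN_BASE
# caps the origin count far above any realistic tree size
_ORIGIN_BASE = 1 << 20
_INF = 1 << 60


@dataclass
class CladeTree:
    """A rooted clade-level tree with binary structural states on the tips.

    ``states`` maps tip label -> 0 (canonical) or 1 (noncanonical or
    semicanonical; both depart from the canonical template).
    """

    tree: dendropy.Tree
    states: Dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_newick(cls, newick: str, states: Optional[Mapping[str, int]] = None
                    ) -> "CladeTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        tree.is_rooted = True
        return cls(tree=tree, states=dict(states or {}))

    def tip_labels(self) -> List[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def prune(self, exclude: Set[str]) -> "CladeTree":
        """Return a copy with the named tips removed."""
        keep = [lab for lab in self.tip_labels() if lab not in exclude]
        newtree = self.tree.extract_tree_with_taxa_labels(labels=keep)
        newtree.is_rooted = True
        states = {k: v for k, v in self.states.items() if k in set(keep)}
        return CladeTree(tree=newtree, states=states)


def min_origins(clade_tree: CladeTree, root_state: int = CANONICAL,
                allow_reversals: bool = False) -> Tuple[int, Dict[str, int]]:
    """Minimum independent 0 -> 1 origins with the root state fixed.

    By default the gain of noncanonical structure is treated as
    irreversible (a noncanonical protein cannot regain the entire canonical
    modular loop), so the statistic is the minimum number of 0 -> 1 edges
    over labelings with no 1 -> 0 edge.  With ``allow_reversals=True``,
    reversals cost the same as gains: total state changes are minimised
    first and, among minimum-change labelings, the 0 -> 1 edge count is
    minimised secondarily.  Returns the origin count and one optimal
    labeling (node label / tip label -> state; internal nodes get synthetic
    labels ``node<i>`` when unnamed).
    """
    tree = clade_tree.tree
    states = clade_tree.states
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in states:
            raise ValueError(f"tip {leaf.taxon.label!r} has no structural state")

    def edge_cost(parent: int, child: int) -> int:
        if parent == child:
            return 0
        if (parent, child) == (0, 1):
            return _ORIGIN_BASE + 1
        return _ORIGIN_BASE if allow_reversals else _INF

    cost: Dict[dendropy.Node, List[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            cost[node] = [0 if t == s else _INF for t in (0, 1)]
            continue
        vec = [0, 0]
        for t in (0, 1):
            total = 0
            for child in node.child_nodes():
                best = _INF
                for c in (0, 1):
                    best = min(best, cost[child][c] + edge_cost(t, c))
                total += min(best, _INF)
            vec[t] = min(total, _INF)
        cost[node] = vec

    root = tree.seed_node
    packed = cost[root][root_state]
    if packed >= _INF:
        raise ValueError("no labeling consistent with the fixed root state")
    origins = packed % _ORIGIN_BASE

    # backtrack one optimal labeling (ties prefer the canonical state)
    labeling: Dict[str, int] = {}
    counter = [0]

    def node_label(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        if node.label:
            return node.label
        counter[0] += 1
        return f"node{counter[0]}"

    def assign(node: dendropy.Node, state: int) -> None:
        labeling[node_label(node)] = state
        for child in node.child_nodes():
            best_c, best_cost = None, _INF + 1
            for c in (0, 1):
                cand = cost[child][c] + edge_cost(state, c)
                if cand < best_cost or (cand == best_cost and c == 0 and best_c != 0):
                    best_c, best_cost = c, cand
            assign(child, best_c)

    assign(root, root_state)
    return int(origins), labeling


def long_branch_clades(
    tree: dendropy.Tree,
    clade_map: Optional[Mapping[str, str]] = None,
    ratio: float = 2.0,
) -> Set[str]:
    """Flag clades whose within-clade root-to-tip paths are anomalously long.

    For every clade (tips grouped by ``clade_map``; each tip its own clade
    when the map is None) the score is the median path length from the
    clade root to its tips, the clade root being the tips' MRCA for
    multi-tip clades and the tip's parent for singletons.  A clade is
    flagged when its score exceeds ``ratio`` times the median of the same
    tip-level measure over all tips.  Missing branch lengths are an error.
    """
    leaves = list(tree.leaf_node_iter())
    if clade_map is None:
        clade_map = {leaf.taxon.label: leaf.taxon.label for leaf in leaves}

    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("missing branch length on tree")

    by_clade: Dict[str, List[dendropy.Node]] = {}
    for leaf in leaves:
        clade = clade_map.get(leaf.taxon.label)
        if clade is not None:
            by_clade.setdefault(clade, []).append(leaf)

    def _median(values: List[float]) -> float:
        vs = sorted(values)
        n = len(vs)
        mid = n // 2
        return vs[mid] if n % 2 else 0.5 * (vs[mid - 1] + vs[mid])

    depths: Dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)

    tip_measures: List[float] = []
    clade_scores: Dict[str, float] = {}
    for clade, tips in by_clade.items():
        if len(tips) == 1:
            root_depth = depths[tips[0].parent_node]
        else:
            mrca = tree.mrca(taxa=[t.taxon for t in tips])
            root_depth = depths[mrca]
        paths = [depths[t] - root_depth for t in tips]
        clade_scores[clade] = _median(paths)
        tip_measures.extend(paths)

    baseline = _median(tip_measures)
    if baseline <= 0:
        return set()
    return {clade for clade, score in clade_scores.items()
            if score > ratio * baseline}


# ---------------------------------------------------------------------------
# The bundled reference cladogram


def reference_cladogram() -> CladeTree:
    """The clade-level reference cladogram with published structural states.

    Encodes the major-clade arrangement of the family tree: a bryophyte
    canonical outgroup; the two independently derived bryophyte
    noncanonical lineages; the lycophyte pair; and the three euphyllophyte
    lineages Eu1 {PIN5, PIN12, PINI}, Eu2 {PINK, PINL, PINM, PINN, PIN6}
    and Eu3 {PINJ, PINE, PINF, PING, PINH, PIN1, PIN9, PIN11, PIN2, PIN3,
    PIN8}, with each noncanonical angiosperm clade sister to a canonical
    clade and PIN9 arising within the PIN1 clade.
    """
    nwk = resources.files("pin_architect.data").joinpath("reference_clades.nwk").read_text()
    states = reference_clade_states()
    return CladeTree.from_newick(nwk, states=states)


def reference_clade_states() -> Dict[str, int]:
    """Published structural states for the reference cladogram tips."""
    text = resources.files("pin_architect.data").joinpath(
        "reference_clade_states.tsv").read_text()
    states: Dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("clade\t"):
            continue
        clade, label = line.split("\t")
        states[clade] = NONCANONICAL if label in {"noncanonical", "semicanonical"} \
            else CANONICAL
    return states
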