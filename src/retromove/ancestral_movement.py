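"""Ancestral Muller-element reconstruction and movement classification.

Given a gene's per-species element states, the direction of a relocation is
read primarily from the copy-type markup (the intronless copy is the derived,
retroposed one; the intron-bearing copy marks the ancestral location).  When
no markup is available, a small-parsimony reconstruction on the rooted
species tree supplies the ancestral (root) state instead.

Minimum change counts, per-node MPR state sets and the set of branches that
carry a change in at least one most-parsimonious reconstruction are computed
with a unit-cost Sankoff up/down dynamic program, which generalizes the
classic Fitch pass to multifurcations and polymorphic (ambiguity-set) tips
while returning the same minimum.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from .types import (
    AUTOSOMAL,
    X_LINKED,
    FitchResult,
    InferenceError,
    LocationMatrix,
    MovementEvent,
    MullerMap,
)

_INF = 10**9


def node_label(node: dendropy.Node) -> str:
    """Leaf taxon label, or ``(leaf,leaf,...)`` for internal nodes."""
    if node.is_leaf():
        return node.taxon.label.replace(" ", "_")
    leaves = sorted(
        l.taxon.label.replace(" ", "_") for l in node.leaf_iter()
    )
    return "(" + ",".join(leaves) + ")"


def fitch_reconstruct(
    tree: dendropy.Tree, tip_states: Mapping[str, Iterable[str]]
) -> FitchResult:
    """Small-parsimony reconstruction of discrete states on a rooted tree.

    ``tip_states`` maps leaf labels to non-empty state collections
    (ambiguity sets allowed); leaves absent from the mapping are treated as
    uninformative wildcards.  Returns the minimum change count, per-node MPR
    state sets, and the branches on which some MPR places a change.
    """
    tips = {k: frozenset(v) for k, v in tip_states.items()}
    if any(not v for v in tips.values()):
        raise InferenceError("empty tip state set")
    if len(tips) < 2:
        raise InferenceError("need at least 2 leaves with data")
    alphabet = sorted(set().union(*tips.values()))
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}

    down: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
            if label in tips:
                down[node] = [0 if s in tips[label] else _INF for s in alphabet]
            else:
                down[node] = [0] * k
        else:
            cost = [0] * k
            for child in node.child_nodes():
                dc = down[child]
                best = min(dc)
                for i in range(k):
                    cost[i] += min(best + 1, dc[i])
            down[node] = cost

    root = tree.seed_node
    min_changes = min(down[root])

    # out[u][a]: min cost of the whole tree outside u's subtree with u's
    # parent fixed to state a; up[u][s] = min_a out[u][a] + [a != s].
    up: dict[dendropy.Node, list[int]] = {root: [0] * k}
    out: dict[dendropy.Node, list[int]] = {}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        for child in children:
            o = []
            for a in range(k):
                total = up[node][a]
                for sib in children:
                    if sib is child:
                        continue
                    ds = down[sib]
                    total += min(min(ds) + 1, ds[a])
                o.append(total)
            out[child] = o
            up[child] = [
                min(o[a] + (0 if a == s else 1) for a in range(k))
                for s in range(k)
            ]

    node_states: dict[str, frozenset[str]] = {}
    for node in tree.preorder_node_iter():
        total = [down[node][s] + up[node][s] for s in range(k)]
        node_states[node_label(node)] = frozenset(
            alphabet[s] for s in range(k) if total[s] == min_changes
        )

    mpr_edges = set()
    for node in tree.preorder_node_iter():
        if node is root or k < 2:
            continue
        o, d = out[node], down[node]
        change_cost = min(
            o[a] + 1 + d[b]
            for a in range(k)
            for b in range(k)
            if a != b and o[a] < _INF and d[b] < _INF
        )
        if change_cost == min_changes:
            mpr_edges.add(node_label(node))

    observed = set().union(*tips.values())
    return FitchResult(
        node_states=node_states,
        min_changes=min_changes,
        mpr_edges=frozenset(mpr_edges),
        root_states=node_states[node_label(root)],
        multi_origin_flagged=min_changes > max(len(observed) - 1, 0),
    )


def canonical_event_branch(
    tree: dendropy.Tree, mpr_edges: frozenset[str]
) -> Optional[str]:
    """The MPR change branch closest to the root (fewest edges above the
    child node); ties broken lexicographically on the branch label."""
    if not mpr_edges:
        return None
    depth = {}
    for node in tree.preorder_node_iter():
        lbl = node_label(node)
        if lbl in mpr_edges:
            d, p = 0, node
            while p.parent_node is not None:
                d += 1
                p = p.parent_node
            depth[lbl] = d
    return min(mpr_edges, key=lambda e: (depth[e], e))


# ---------------------------------------------------------------------------
# event inference from a location-matrix row


def _resolve_cell_states(
    states: Sequence[str], species: str, muller_map: MullerMap
) -> tuple[tuple[str, ...], bool]:
    """Map a cell's symbols to Muller elements.  The literal ``X`` marker
    resolves to that species' X-linked element(s); returns the resolved
    element tuple and whether it must be excluded from consensus voting
    (an X marker ambiguous between elements, as on the obscura neo-X)."""
    resolved: list[str] = []
    x_ambiguous = False
    for s in states:
        if s == "X":
            xs = sorted(muller_map.x_elements(species))
            resolved.extend(e for e in xs if e not in resolved)
            if len(xs) > 1:
                x_ambiguous = True
        elif s not in resolved:
            resolved.append(s)
    return tuple(resolved), x_ambiguous


def _consensus(cells: list[tuple[str, tuple[str, ...]]]) -> tuple[str, bool]:
    """Consensus element over (species, element-tuple) cells.

    Every cell votes for each element it allows.  A unique plurality wins;
    ties prefer the element backed by more unambiguous (singleton) cells,
    then alphabetical order, and mark the result ambiguous.  Cells with an
    ambiguity set mark the result ambiguous even when the winner is unique.
    """
    votes: Counter[str] = Counter()
    singleton: Counter[str] = Counter()
    any_ambiguous = False
    for _, els in cells:
        if len(els) == 1:
            singleton[els[0]] += 1
        else:
            any_ambiguous = True
        for e in els:
            votes[e] += 1
    if not votes:
        raise InferenceError("no informative cells for consensus")
    top = max(votes.values())
    leaders = sorted(e for e, v in votes.items() if v == top)
    if len(leaders) == 1:
        return leaders[0], any_ambiguous
    leaders.sort(key=lambda e: (-singleton[e], e))
    return leaders[0], True


def infer_event(
    matrix: LocationMatrix,
    gene: str,
    tree: dendropy.Tree,
    muller_map: MullerMap,
    include_degraded: bool = False,
) -> MovementEvent:
    """Infer the relocation event for one gene.

    Primary basis uses the copy-type markup: the source element is the
    consensus over parental (intron-bearing) species, the target the
    consensus over retro-flagged species.  Without markup, the parsimony
    fallback takes the unique root MPR state as the source and the derived
    state below the canonical change branch as the target.  Degraded-copy
    cells and secondary-copy annotations are excluded by default.
    """
    row = matrix.row(gene)
    usable: dict[str, tuple[tuple[str, ...], bool, bool]] = {}
    for sp, cell in row.items():
        if cell.missing or (cell.degraded and not include_degraded):
            continue
        els, x_amb = _resolve_cell_states(cell.states, sp, muller_map)
        usable[sp] = (els, x_amb, cell.retro)
    if len(usable) < 2:
        raise InferenceError(f"{gene}: fewer than 2 informative species")

    tip_states = {sp: els for sp, (els, _, _) in usable.items()}
    fitch = fitch_reconstruct(tree, tip_states)
    if fitch.min_changes == 0:
        raise InferenceError(f"{gene}: no relocation (all states equal)")
    branch = canonical_event_branch(tree, fitch.mpr_edges)
    single_origin = fitch.min_changes == 1

    retro_cells = [
        (sp, els) for sp, (els, x_amb, r) in usable.items() if r and not x_amb
    ]
    parental_cells = [
        (sp, els) for sp, (els, x_amb, r) in usable.items() if not r and not x_amb
    ]
    has_flags = any(r for _, (_, _, r) in usable.items())

    if has_flags and retro_cells and parental_cells:
        source, amb_s = _consensus(parental_cells)
        target, amb_t = _consensus(retro_cells)
        if source == target:
            raise InferenceError(f"{gene}: no relocation (source == target)")
        context = tuple(sorted(sp for sp, (_, _, r) in usable.items() if r))
        # the flags polarize the reconstruction: among the MPR change
        # branches, the event branch is the one leading only to species
        # carrying the derived (retro) copy
        derived_edges = [
            e for e in fitch.mpr_edges
            if set(_leaves_below(tree, e)) <= set(context)
        ]
        branch_amb = True
        if len(derived_edges) == 1:
            branch = derived_edges[0]
            branch_amb = False
        elif fitch.mpr_edges:
            branch_amb = len(fitch.mpr_edges) > 1
        ambiguous = amb_s or amb_t or branch_amb
        return MovementEvent(
            gene=gene, source=source, target=target,
            event_branch=branch or "ambiguous",
            single_origin=single_origin, basis="copy-type flags",
            context_species=context, ambiguous=ambiguous,
        )

    # parsimony fallback
    if len(fitch.root_states) != 1:
        raise InferenceError(
            f"{gene}: no unique ancestral state (root MPR {sorted(fitch.root_states)})"
        )
    source = next(iter(fitch.root_states))
    if branch is None:
        raise InferenceError(f"{gene}: no change branch found")
    child_states = fitch.node_states[branch] - {source}
    if len(child_states) != 1:
        raise InferenceError(f"{gene}: ambiguous derived state")
    target = next(iter(child_states))
    context = _leaves_below(tree, branch)
    return MovementEvent(
        gene=gene, source=source, target=target, event_branch=branch,
        single_origin=single_origin, basis="parsimony-root",
        context_species=tuple(sorted(context)),
        ambiguous=len(fitch.mpr_edges) > 1,
    )


def _leaves_below(tree: dendropy.Tree, branch_label: str) -> list[str]:
    for node in tree.preorder_node_iter():
        if node_label(node) == branch_label:
            return [l.taxon.label.replace(" ", "_") for l in node.leaf_iter()]
    raise InferenceError(f"branch {branch_label} not found")


def classify_movement(
    event: MovementEvent,
    muller_map: MullerMap,
    context_species: Optional[Iterable[str]] = None,
) -> str:
    """Movement class under the Muller map of the species carrying the
    derived copy (so element D is autosomal for an event observed in
    D. ananassae but X-linked for the obscura neo-X).  Inconsistent linkage
    across context species falls back to majority rule."""
    context = tuple(context_species or event.context_species)
    if not context:
        raise InferenceError(f"{event.gene}: no context species")
    votes: Counter[str] = Counter()
    for sp in context:
        src = "X" if muller_map.linkage_of(sp, event.source) == X_LINKED else "A"
        tgt = "X" if muller_map.linkage_of(sp, event.target) == X_LINKED else "A"
        votes[f"{src}->{tgt}"] += 1
    ranked = votes.most_common()
    return ranked[0][0]


def count_movements(
    events: Iterable[MovementEvent], muller_map: MullerMap
) -> dict[str, int]:
    """Movement counts per class; zero classes are reported explicitly."""
    counts = {"X->A": 0, "A->X": 0, "A->A": 0, "X->X": 0}
    for ev in events:
        counts[classify_movement(ev, muller_map)] += 1
    return counts


def infer_all_events(
    matrix: LocationMatrix,
    tree: dendropy.Tree,
    muller_map: MullerMap,
    include_degraded: bool = False,
) -> tuple[list[MovementEvent], dict[str, str]]:
    """Infer events for every gene; returns (events, rejected-with-reason)."""
    events, rejected = [], {}
    for gene in matrix.genes:
        try:
            events.append(
                infer_event(matrix, gene, tree, muller_map, include_degraded)
            )
        except InferenceError as exc:
            rejected[gene] = str(exc)
    return events, rejected
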