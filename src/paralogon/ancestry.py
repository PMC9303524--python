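"""Gene-architecture character matrices and ancestral-state reconstruction.

Gene models are flattened into binary presence/absence characters (exons,
motifs, isoform classes) and reconstructed on a rooted paralog tree with
unordered-parsimony dynamic programming: for every character the exact
minimal change count and, per node, the full set of states attainable in
some most-parsimonious reconstruction (MPR), with polytomies and unknown
leaf states handled exactly.  A single-gain (Dollo) alternative is
available for complex motif characters whose convergent gain is
implausible; it is off by default and only consulted by the merged
pre-WGD model report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .model import GeneModel, ParalogTree, ValidationError

__all__ = [
    "CHARACTERS",
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "AMBIGUOUS",
    "PLACEMENT_DEPENDENT",
    "FeatureMatrix",
    "AncestralStateMap",
    "extract_features",
    "fitch_reconstruct",
    "dollo_states",
    "scenario_report",
    "ScenarioReport",
    "prewgd_model",
    "PreWgdModel",
    "DEFAULT_PLACEMENTS",
]

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"
AMBIGUOUS = "ambiguous"
PLACEMENT_DEPENDENT = "placement_dependent"

#: Characters extracted from gene models, in matrix order.
CHARACTERS = (
    "EXON_IV",
    "LVPQ",
    "SXXSS",
    "CTBP",
    "EXON_XII_CRARF",
    "EXON_XIIp_CRALF",
    "EXON_XIII",
    "DELTA_N_ISOFORM",
    "ALT_SPLICE_EXON_VII",
    "ISOFORM_B",
    "ISOFORM_E",
    "ISOFORM_N",
    "EXON_X_XI_INTRON",
    "C_CLAMP",
    "EXON_III_MET",
)

_GAIN_TIEBREAK = 1e-6  # secondary cost steering canonical labelings to fewest gains


@dataclass
class FeatureMatrix:
    """Rectangular taxon x character matrix over {present, absent, unknown}."""

    taxa: tuple[str, ...]
    characters: tuple[str, ...]
    states: dict  # (taxon, character) -> state

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.characters = tuple(self.characters)
        for taxon in self.taxa:
            for character in self.characters:
                state = self.states.get((taxon, character))
                if state not in (PRESENT, ABSENT, UNKNOWN):
                    raise ValidationError(f"missing or invalid state for ({taxon}, {character}): {state!r}")

    def state(self, taxon: str, character: str) -> str:
        return self.states[(taxon, character)]

    def column(self, character: str) -> dict:
        return {t: self.states[(t, character)] for t in self.taxa}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: [self.states[(t, c)] for t in self.taxa] for c in self.characters},
            index=list(self.taxa),
        )

    def with_character(self, name: str, column: Mapping[str, str]) -> "FeatureMatrix":
        states = dict(self.states)
        for taxon in self.taxa:
            states[(taxon, name)] = column.get(taxon, UNKNOWN)
        return FeatureMatrix(self.taxa, self.characters + (name,), states)

    def without_characters(self, names: Sequence[str]) -> "FeatureMatrix":
        drop = set(names)
        keep = tuple(c for c in self.characters if c not in drop)
        states = {(t, c): self.states[(t, c)] for t in self.taxa for c in keep}
        return FeatureMatrix(self.taxa, keep, states)


# ---------------------------------------------------------------------------
# Feature extraction from gene models
# ---------------------------------------------------------------------------


def _components(label: str) -> tuple[str, ...]:
    return tuple(label.split("-"))


def _exon_with(model: GeneModel, component: str):
    for exon in model.exons:
        if component in _components(exon.label):
            return exon
    return None


def _path_has(model: GeneModel, path: Sequence[str], component: str) -> bool:
    return any(component in _components(lab) for lab in path)


def _bool_state(value: bool) -> str:
    return PRESENT if value else ABSENT


def _extract_one(model: GeneModel) -> dict:
    motifs = model.motifs()
    first = model.exons[0].label
    order = {e.label: i for i, e in enumerate(model.exons)}

    def exists_iso(pred) -> bool:
        return any(pred(iso) for iso in model.isoforms)

    crarf_exon = next(
        (e for e in model.exons if "CRARF" in e.motifs and "XII" in _components(e.label) and "XII'" not in _components(e.label)),
        None,
    )
    # fused labels such as XI-XII also carry the CRARF exon
    if crarf_exon is None:
        crarf_exon = next((e for e in model.exons if "CRARF" in e.motifs), None)
    hmg_idx = [order[e.label] for e in model.exons if "HMG" in e.motifs]

    def complete_clamp(iso) -> bool:
        if crarf_exon is None:
            return False
        return crarf_exon.label in iso.splice_path and _path_has(model, iso.splice_path, "XIV")

    def b_like(iso) -> bool:
        return (
            _path_has(model, iso.splice_path, "XIV")
            and not _path_has(model, iso.splice_path, "XII")
            and not _path_has(model, iso.splice_path, "XII'")
        )

    def truncated_before_hmg(iso) -> bool:
        if not hmg_idx:
            return False
        return max(order[lab] for lab in iso.splice_path) < min(hmg_idx)

    def alt_vii() -> bool:
        vii = _exon_with(model, "VII")
        if vii is None:
            return False
        with_vii = [i for i in model.isoforms if vii.label in i.splice_path]
        without = [
            i
            for i in model.isoforms
            if vii.label not in i.splice_path
            and any(order[lab] > order[vii.label] for lab in i.splice_path)
            and any(order[lab] < order[vii.label] for lab in i.splice_path)
        ]
        return bool(with_vii) and bool(without)

    x_exon = _exon_with(model, "X")
    xi_exon = _exon_with(model, "XI")
    separate_x_xi = (
        x_exon is not None and xi_exon is not None and x_exon.label != xi_exon.label
    )

    states = {
        "EXON_IV": _bool_state(_exon_with(model, "IV") is not None),
        "LVPQ": _bool_state("LVPQ" in motifs),
        "SXXSS": _bool_state("SXXSS" in motifs),
        "CTBP": _bool_state("CTBP" in motifs),
        "EXON_XII_CRARF": _bool_state(crarf_exon is not None),
        "EXON_XIIp_CRALF": _bool_state(
            any("CRALF" in e.motifs and "XII'" in _components(e.label) for e in model.exons)
        ),
        "EXON_XIII": _bool_state(_exon_with(model, "XIII") is not None),
        "DELTA_N_ISOFORM": _bool_state(exists_iso(lambda i: i.start_exon != first)),
        "ALT_SPLICE_EXON_VII": _bool_state(alt_vii()),
        "ISOFORM_B": _bool_state(exists_iso(b_like)),
        "ISOFORM_E": _bool_state(exists_iso(complete_clamp)),
        "ISOFORM_N": _bool_state(exists_iso(truncated_before_hmg)),
        "EXON_X_XI_INTRON": _bool_state(separate_x_xi),
        "C_CLAMP": _bool_state(exists_iso(complete_clamp)),
    }
    met = model.flags.get("met33")
    states["EXON_III_MET"] = UNKNOWN if met is None else _bool_state(bool(met))
    for character in model.unknown_features:
        if character not in CHARACTERS:
            raise ValidationError(f"{model.gene_id}: unknown_features names unknown character {character}")
        states[character] = UNKNOWN
    return states


def extract_features(models: Sequence[GeneModel]) -> FeatureMatrix:
    """Deterministically flatten gene models into the binary character matrix.

    Isoform-class characters are coded structurally: a B-like terminus is a
    splice path reaching exon XIV without passing any exon XII/XII' (no
    C-clamp); an E-like terminus joins the CRARF-bearing exon XII to exon
    XIV (complete C-clamp); an N-type isoform truncates before the first
    HMG-box exon.
    """
    taxa = tuple(m.gene_id for m in models)
    states: dict = {}
    for model in models:
        per = _extract_one(model)
        for character in CHARACTERS:
            states[(model.gene_id, character)] = per[character]
    return FeatureMatrix(taxa, CHARACTERS if models else (), states)


# ---------------------------------------------------------------------------
# Parsimony reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AncestralStateMap:
    """Exact parsimony reconstruction over all characters of a matrix.

    ``node_states[node][character]`` is present/absent when every
    most-parsimonious reconstruction agrees, else ambiguous.  ``events``
    come from one canonical MP labeling (ties resolved toward the fewest
    gains, then the parental state) whose change count equals the
    parsimony score, character by character.
    """

    node_states: dict  # node label -> {character -> PRESENT/ABSENT/AMBIGUOUS}
    scores: dict  # character -> minimal change count
    min_gains: dict  # character -> gains in the fewest-gain MP labeling
    events: list  # (character, parent_label, child_label, "gain"/"loss")
    canonical: dict  # node label -> {character -> 0/1}
    tree: ParalogTree

    def root_state(self, character: str, node: str) -> str:
        return self.node_states[node][character]

    def states_frame(self) -> pd.DataFrame:
        nodes = list(self.node_states)
        chars = list(self.scores)
        return pd.DataFrame(
            {c: [self.node_states[n][c] for n in nodes] for c in chars}, index=nodes
        )


def _node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _leaf_costs(state: str) -> np.ndarray:
    if state == PRESENT:
        return np.array([math.inf, 0.0])
    if state == ABSENT:
        return np.array([0.0, math.inf])
    return np.array([0.0, 0.0])  # unknown: wildcard


def _reconstruct_character(
    tree: ParalogTree, leaf_states: Mapping[str, str]
) -> tuple[dict, int, int, dict]:
    """Exact MPR sets, score, min gains and canonical labeling for one character."""
    w = np.array([[0.0, 1.0], [1.0, 0.0]])
    wg = np.array([[0.0, 1.0 + _GAIN_TIEBREAK], [1.0, 0.0]])  # gains slightly dearer
    down: dict[int, np.ndarray] = {}
    downg: dict[int, np.ndarray] = {}
    nodes = list(tree.tree.postorder_node_iter())
    for node in nodes:
        nid = id(node)
        if node.is_leaf():
            down[nid] = _leaf_costs(leaf_states[node.taxon.label])
            downg[nid] = down[nid].copy()
        else:
            cost = np.zeros(2)
            costg = np.zeros(2)
            for child in node.child_nodes():
                cid = id(child)
                cost += np.min(down[cid][None, :] + w, axis=1)
                costg += np.min(downg[cid][None, :] + wg, axis=1)
            down[nid] = cost
            downg[nid] = costg
    root = tree.tree.seed_node
    score = float(np.min(down[id(root)]))

    # upward pass for exact MPR membership
    up: dict[int, np.ndarray] = {id(root): np.zeros(2)}
    for node in tree.tree.preorder_node_iter():
        nid = id(node)
        children = node.child_nodes()
        if not children:
            continue
        # contribution of each child to its parent's per-state cost
        contrib = {id(c): np.min(down[id(c)][None, :] + w, axis=1) for c in children}
        for child in children:
            cid = id(child)
            rest = up[nid] + down[nid] - contrib[cid]  # parent-state cost excluding this child
            up[cid] = np.min(rest[:, None] + w, axis=0)
    mpr: dict[str, set[int]] = {}
    for node in nodes:
        nid = id(node)
        total = down[nid] + up[nid]
        mpr[_node_label(node)] = {s for s in (0, 1) if total[s] <= score + 1e-9}

    # canonical labeling: weighted backtrack, ties toward parent state then absent
    canonical: dict[str, int] = {}
    gains = 0
    events: list[tuple[str, str, int, int]] = []
    rootg = downg[id(root)]
    root_state = int(np.argmin(rootg))  # argmin prefers 0 (absent) on exact ties
    canonical[_node_label(root)] = root_state
    stack = [(root, root_state)]
    while stack:
        node, state = stack.pop()
        for child in node.child_nodes():
            cid = id(child)
            options = downg[cid] + wg[state]
            best = float(np.min(options))
            choice = state if options[state] <= best + 1e-12 else int(np.argmin(options))
            canonical[_node_label(child)] = choice
            if choice != state:
                if choice == 1:
                    gains += 1
                events.append((_node_label(node), _node_label(child), state, choice))
            stack.append((child, choice))
    return mpr, int(round(score)) if math.isfinite(score) else 0, gains, {
        "canonical": canonical,
        "events": events,
    }


def fitch_reconstruct(matrix: FeatureMatrix, tree: ParalogTree) -> AncestralStateMap:
    """Unordered binary parsimony over every character of ``matrix``.

    Matrix taxa must all be tree leaves; tree leaves without matrix rows
    are treated as entirely unknown.  Nodes whose MPR state set is not a
    singleton are reported ambiguous.
    """
    leaves = set(tree.leaf_labels)
    missing = [t for t in matrix.taxa if t not in leaves]
    if missing:
        raise ValidationError(f"matrix taxa missing from tree: {missing}")
    node_states: dict[str, dict[str, str]] = {}
    scores: dict[str, int] = {}
    min_gains: dict[str, int] = {}
    events: list[tuple[str, str, str, str]] = []
    canonical: dict[str, dict[str, int]] = {}
    for character in matrix.characters:
        column = matrix.column(character)
        leaf_states = {leaf: column.get(leaf, UNKNOWN) for leaf in leaves}
        mpr, score, gains, canon = _reconstruct_character(tree, leaf_states)
        scores[character] = score
        min_gains[character] = gains
        for label, states in mpr.items():
            verdict = AMBIGUOUS if len(states) == 2 else (PRESENT if 1 in states else ABSENT)
            node_states.setdefault(label, {})[character] = verdict
        for label, state in canon["canonical"].items():
            canonical.setdefault(label, {})[character] = state
        for parent, child, s_from, s_to in canon["events"]:
            events.append((character, parent, child, "gain" if s_to == 1 else "loss"))
    return AncestralStateMap(
        node_states=node_states,
        scores=scores,
        min_gains=min_gains,
        events=events,
        canonical=canonical,
        tree=tree,
    )


def dollo_states(tree: ParalogTree, leaf_states: Mapping[str, str]) -> dict:
    """Single-gain (Dollo) reconstruction of one binary character.

    The character arises exactly once, on the edge above the most recent
    common ancestor of all present leaves, and may be lost any number of
    times afterwards.  A node is present iff it sits in that ancestor's
    subtree and still has a present descendant.  Unknown leaves are
    ignored when locating the gain.
    """
    present_leaves = {l for l, s in leaf_states.items() if s == PRESENT}
    states: dict[str, str] = {}
    if not present_leaves:
        for node in tree.tree.preorder_node_iter():
            states[_node_label(node)] = ABSENT
        return states
    mrca: dict[int, bool] = {}
    below: dict[int, set[str]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = {node.taxon.label}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.child_nodes()))
    lca = None
    for node in tree.tree.postorder_node_iter():
        if present_leaves <= below[id(node)]:
            lca = node
            break
    in_subtree: set[int] = set()
    stack = [lca]
    while stack:
        node = stack.pop()
        in_subtree.add(id(node))
        stack.extend(node.child_nodes())
    for node in tree.tree.preorder_node_iter():
        has_present = bool(below[id(node)] & present_leaves)
        states[_node_label(node)] = (
            PRESENT if id(node) in in_subtree and has_present else ABSENT
        )
    for leaf, state in leaf_states.items():
        if state == PRESENT:
            states[leaf] = PRESENT
        elif state == ABSENT:
            states[leaf] = ABSENT
    return states


@dataclass
class ScenarioReport:
    """Branch-ordered gain/loss narrative plus question-marked characters."""

    events: pd.DataFrame  # branch order follows a preorder traversal
    ambiguous: pd.DataFrame

    def narrative(self) -> str:
        lines = []
        for _, row in self.events.iterrows():
            lines.append(
                f"{row['parent']} -> {row['child']}: {row['event']} of {row['character']}"
            )
        for _, row in self.ambiguous.iterrows():
            lines.append(f"{row['node']}: {row['character']} state uncertain (?)")
        return "\n".join(lines)


def scenario_report(states: AncestralStateMap, tree: ParalogTree) -> ScenarioReport:
    """Order reconstruction events along the tree and list uncertain states."""
    order: dict[str, int] = {}
    for i, node in enumerate(tree.tree.preorder_node_iter()):
        order[_node_label(node)] = i
    rows = [
        {"parent": p, "child": c, "character": char, "event": kind}
        for (char, p, c, kind) in states.events
    ]
    events = pd.DataFrame(rows, columns=["parent", "child", "character", "event"])
    if not events.empty:
        events = events.sort_values(
            by=["child", "character"], key=lambda s: s.map(order).fillna(0) if s.name == "child" else s
        ).reset_index(drop=True)
    amb_rows = [
        {"node": node, "character": char}
        for node, per in states.node_states.items()
        for char, verdict in per.items()
        if verdict == AMBIGUOUS and node not in set(tree.leaf_labels)
    ]
    ambiguous = pd.DataFrame(amb_rows, columns=["node", "character"])
    if not ambiguous.empty:
        ambiguous = ambiguous.sort_values(
            by=["node", "character"], key=lambda s: s.map(order).fillna(0) if s.name == "node" else s
        ).reset_index(drop=True)
    return ScenarioReport(events=events, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# Merged pre-WGD model under alternative cyclostome placements
# ---------------------------------------------------------------------------

#: attachment points for the cyclostome polytomy: the vertebrate root
#: (pre-1R divergence) or either post-1R ohnolog stem.
DEFAULT_PLACEMENTS = {
    "vertebrate_root": ("preWGD", False),
    "tcf7l1_l2_stem": ("tcf7l1_l2", True),
    "tcf7_lef1_stem": ("tcf7_lef1", True),
}


@dataclass
class PreWgdModel:
    """Merged ancestral gene model at the pre-WGD node.

    ``states[character]`` is present/absent when every placement and, for
    multi-gain characters, the single-gain alternative all agree; else
    ``placement_dependent`` (placements disagree) or ``ambiguous``
    (reconstructions within a placement disagree).  ``detail`` keeps the
    per-placement evidence for audit.
    """

    focal_node: str
    states: dict
    detail: pd.DataFrame

    def question_marked(self) -> tuple[str, ...]:
        return tuple(
            c for c, v in self.states.items() if v in (AMBIGUOUS, PLACEMENT_DEPENDENT)
        )


def prewgd_model(
    matrix: FeatureMatrix,
    tree: ParalogTree,
    cyclostome_taxa: Sequence[str] = (),
    focal_node: str = "preWGD",
    placements: Optional[Mapping[str, tuple[str, bool]]] = None,
    dollo_when_gains_ge: int = 2,
) -> PreWgdModel:
    """Reconstruct the pre-WGD ancestral gene model across placements.

    Cyclostome taxa attach as a polytomy at each configured placement in
    turn.  For characters whose most-parsimonious reconstruction demands
    two or more independent gains of the same complex feature, the
    single-gain (Dollo) alternative is also evaluated - convergent gain of
    a motif is biologically implausible, so parsimony and Dollo
    disagreement is reported as a question mark rather than forced either
    way.
    """
    if placements is None:
        placements = DEFAULT_PLACEMENTS if cyclostome_taxa else {"base": (focal_node, False)}
    rows = []
    verdict_sets: dict[str, set[str]] = {c: set() for c in matrix.characters}
    fitch_by_placement: dict[str, dict[str, str]] = {}
    for name, (at, on_stem) in placements.items():
        placed = tree.attach_polytomy(cyclostome_taxa, at, on_stem) if cyclostome_taxa else tree
        recon = fitch_reconstruct(matrix, placed)
        fitch_by_placement[name] = {}
        for character in matrix.characters:
            fitch_state = recon.node_states[focal_node][character]
            fitch_by_placement[name][character] = fitch_state
            dollo_state = None
            if recon.min_gains[character] >= dollo_when_gains_ge:
                leaf_states = {
                    leaf: matrix.column(character).get(leaf, UNKNOWN)
                    for leaf in placed.leaf_labels
                }
                dollo_state = dollo_states(placed, leaf_states)[focal_node]
            verdict_sets[character].add(fitch_state)
            if dollo_state is not None:
                verdict_sets[character].add(dollo_state)
            rows.append(
                {
                    "character": character,
                    "placement": name,
                    "fitch": fitch_state,
                    "min_gains": recon.min_gains[character],
                    "dollo": dollo_state if dollo_state is not None else "",
                }
            )
    states: dict[str, str] = {}
    for character in matrix.characters:
        verdicts = verdict_sets[character]
        if verdicts <= {PRESENT} or verdicts <= {ABSENT}:
            states[character] = next(iter(verdicts))
        else:
            fitch_states = {fitch_by_placement[p][character] for p in fitch_by_placement}
            if AMBIGUOUS not in fitch_states and len(fitch_states) > 1:
                states[character] = PLACEMENT_DEPENDENT
            else:
                states[character] = AMBIGUOUS
    detail = pd.DataFrame(rows, columns=["character", "placement", "fitch", "min_gains", "dollo"])
    return PreWgdModel(focal_node=focal_node, states=states, detail=detail)
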