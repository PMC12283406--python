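"""Colony phylogeny: construction, ancestral states, clock scaling, bulk placement.

The tree is built from the binary colony x mutation genotype matrix by
perfect-phylogeny / maximum-parsimony reasoning: mutations sharing a
carrier set define a candidate clade; compatible carrier sets form a
laminar family and therefore a unique rooted tree, with the all-reference
hypothetical zygote as outgroup root. Carrier sets that conflict with
better-supported ones (possible only with genotyping noise) do not shape
the topology; their mutations are placed on the branch subtending the
carriers' most recent common ancestor and flagged.

Branch lengths come in three flavors: molecular (all assigned mutations),
clock (mutations attributed to the clock-like signatures after excluding
treatment-related ones), and time (years, after ultrametric scaling of
cumulative clock counts to the donor's age).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

from . import signatures as sigmod
from .tree import TreeNode

logger = logging.getLogger(__name__)

CLOCK_SIGNATURES = ("SBS1", "SBS5")


@dataclass
class PhyloTree:
    """Rooted colony tree with per-branch mutation assignments."""
    root: TreeNode
    colonies: list[str]
    site_to_branch: dict[str, int]      # site key -> node_id
    conflicting_sites: list[str] = field(default_factory=list)
    dropped_sites: list[str] = field(default_factory=list)

    def nodes(self) -> list[TreeNode]:
        return list(self.root.preorder())

    def node_by_id(self, node_id: int) -> TreeNode:
        for node in self.root.preorder():
            if node.node_id == node_id:
                return node
        raise KeyError(node_id)

    def n_assigned_mutations(self) -> int:
        return sum(len(n.mutations) for n in self.root.preorder())


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------

class _SetNode:
    __slots__ = ("colonies", "children", "sites")

    def __init__(self, colonies: frozenset):
        self.colonies = colonies
        self.children: list["_SetNode"] = []
        self.sites: list[str] = []


def build_tree(genotype_matrix: pd.DataFrame) -> PhyloTree:
    """Infer the rooted colony tree from a {0,1,missing} genotype matrix.

    Rows are colonies, columns mutation site keys; missing genotypes
    (NaN) are treated as absence for carrier-set formation. On a
    conflict-free matrix this returns the unique perfect phylogeny, with
    every mutation assigned to the branch subtending exactly its carrier
    set. All-missing or carrier-free columns are dropped with a warning.
    """
    colonies = list(genotype_matrix.index)
    if len(colonies) < 2:
        raise ValueError("need at least two colonies to build a tree")
    M = genotype_matrix.to_numpy(dtype=float)

    groups: dict[frozenset, list[str]] = {}
    dropped: list[str] = []
    for j, site in enumerate(genotype_matrix.columns):
        col = M[:, j]
        carriers = frozenset(colonies[i] for i in np.flatnonzero(col == 1.0))
        if not carriers:
            dropped.append(str(site))
            continue
        groups.setdefault(carriers, []).append(str(site))
    if dropped:
        logger.warning("dropped %d carrier-free/all-missing mutation columns",
                       len(dropped))

    full = frozenset(colonies)
    root_set = _SetNode(full)
    ordered = sorted(groups.items(),
                     key=lambda kv: (-len(kv[0]), -len(kv[1]), sorted(kv[0])))
    conflicts: list[tuple[frozenset, list[str]]] = []
    for S, sites in ordered:
        if S == full:
            root_set.sites.extend(sites)
            continue
        node = root_set
        placed = False
        while not placed:
            inside = [c for c in node.children if S <= c.colonies]
            if inside:
                node = inside[0]
                continue
            partial = [c for c in node.children
                       if (c.colonies & S) and not (c.colonies <= S)]
            if partial:
                conflicts.append((S, sites))
                placed = True
                continue
            new = _SetNode(S)
            new.sites = list(sites)
            subsumed = [c for c in node.children if c.colonies <= S]
            for c in subsumed:
                node.children.remove(c)
                new.children.append(c)
            node.children.append(new)
            placed = True

    # convert the laminar set family to a TreeNode tree under a zygote root
    root = TreeNode("zygote", time=0.0)

    def build(set_node: _SetNode, parent: TreeNode) -> TreeNode:
        covered = frozenset().union(*(c.colonies for c in set_node.children)) \
            if set_node.children else frozenset()
        if len(set_node.colonies) == 1 and not set_node.children:
            (colony,) = set_node.colonies
            tn = TreeNode(colony)
        else:
            tn = TreeNode()
            for child in set_node.children:
                build(child, tn)
            for colony in sorted(set_node.colonies - covered):
                tn.add_child(TreeNode(colony))
        tn.mutations = list(set_node.sites)
        parent.add_child(tn)
        return tn

    mrca = build(root_set, root)
    # if the root carrier set itself had no mutations and only one child,
    # keep it anyway: the zygote -> MRCA branch carries the full-set sites.
    del mrca
    root.assign_ids()

    site_to_branch: dict[str, int] = {}
    for node in root.preorder():
        for s in node.mutations:
            site_to_branch[s] = node.node_id

    # conflicting carrier sets: place mutations on the MRCA branch of carriers
    conflict_sites: list[str] = []
    if conflicts:
        tipmap = {n.name: n for n in root.leaves()}
        for S, sites in conflicts:
            nodes_paths = [tipmap[c].path_from_root() for c in sorted(S)]
            depth = min(len(p) for p in nodes_paths)
            mrca_node = root
            for d in range(depth):
                candidates = {id(p[d]) for p in nodes_paths}
                if len(candidates) == 1:
                    mrca_node = nodes_paths[0][d]
                else:
                    break
            mrca_node.mutations.extend(sites)
            for s in sites:
                site_to_branch[s] = mrca_node.node_id
            conflict_sites.extend(sites)
        logger.warning("%d mutations had conflicting carrier sets; placed at "
                       "carrier MRCAs", len(conflict_sites))

    return PhyloTree(root, colonies, site_to_branch, conflict_sites, dropped)


# ----------------------------------------------------------------------
# ancestral states (Fitch parsimony)
# ----------------------------------------------------------------------

@dataclass
class AncestralStates:
    """Fitch states per node (rows follow ``sites``) and parsimony scores."""
    sites: list[str]
    states: dict[int, np.ndarray]       # node_id -> {0,1} per site
    changes: np.ndarray                 # parsimony score per site

    @property
    def total_changes(self) -> int:
        return int(self.changes.sum())


def reconstruct_ancestral(tree: PhyloTree,
                          genotype_matrix: pd.DataFrame) -> AncestralStates:
    """Minimum-change (small-parsimony) ancestral presence/absence.

    Sankoff dynamic programming over the two states with unit change
    cost, exact on multifurcating nodes; the root is forced to absent
    (the zygote carries no somatic mutations). Missing tip genotypes are
    uninformative. The total implied changes per site equal the
    parsimony score under the fixed all-reference root.
    """
    sites = [str(s) for s in genotype_matrix.columns]
    m = len(sites)
    tips = {n.name: n for n in tree.root.leaves()}
    missing_tips = set(genotype_matrix.index) - set(tips)
    if missing_tips:
        raise ValueError(f"colonies absent from tree: {sorted(missing_tips)}")

    BIG = np.float64(1e12)
    cost: dict[int, tuple[np.ndarray, np.ndarray]] = {}   # id -> (cost0, cost1)
    for node in tree.root.postorder():
        if node.is_leaf:
            c0 = np.zeros(m)
            c1 = np.zeros(m)
            if node.name in genotype_matrix.index:
                col = genotype_matrix.loc[node.name].to_numpy(dtype=float)
                c0[col == 1.0] = BIG
                c1[col == 0.0] = BIG
            cost[id(node)] = (c0, c1)
        else:
            c0 = np.zeros(m)
            c1 = np.zeros(m)
            for child in node.children:
                k0, k1 = cost[id(child)]
                c0 += np.minimum(k0, k1 + 1.0)
                c1 += np.minimum(k1, k0 + 1.0)
            cost[id(node)] = (c0, c1)

    r0, _r1 = cost[id(tree.root)]
    changes = r0.astype(np.int64)       # root forced to state 0

    states: dict[int, np.ndarray] = {}
    for node in tree.root.preorder():
        if node.parent is None:
            states[node.node_id] = np.zeros(m, dtype=np.int8)
            continue
        pst = states[node.parent.node_id]
        c0, c1 = cost[id(node)]
        total0 = c0 + (pst == 1)        # +1 change if parent is present
        total1 = c1 + (pst == 0)
        states[node.node_id] = (total1 < total0).astype(np.int8)
    return AncestralStates(sites, states, changes)


# ----------------------------------------------------------------------
# per-node exposures and branch signature counts
# ----------------------------------------------------------------------

def node_exposures(tree: PhyloTree, mutation_table: pd.DataFrame,
                   reference_set: pd.DataFrame,
                   min_exposure: float = 1.0) -> dict[int, pd.Series]:
    """Refit signature exposures on each node's implied mutation set.

    The implied set of a node is the union of mutations assigned to the
    branches on its root path (the ancestral genome's somatic content).
    ``mutation_table`` is indexed by site key with ref/alt/context columns.
    Nodes with empty sets get all-zero exposures.
    """
    zero = pd.Series(0.0, index=reference_set.columns)
    out: dict[int, pd.Series] = {}
    spectra: dict[int, pd.Series] = {}
    for node in tree.root.preorder():
        own = sigmod.count_contexts(mutation_table.loc[
            [s for s in node.mutations if s in mutation_table.index]])
        if node.parent is None:
            spectra[node.node_id] = own
        else:
            spectra[node.node_id] = spectra[node.parent.node_id] + own
    for node_id, spec in spectra.items():
        if spec.sum() <= 0:
            out[node_id] = zero.copy()
        else:
            out[node_id], _ = sigmod.fit_exposures(spec, reference_set,
                                                   min_exposure=min_exposure)
    return out


class NegativeCountFlag(NamedTuple):
    value: float
    flagged: bool


def handle_negative_counts(diff: float, branch_total: float) -> NegativeCountFlag:
    """Resolve a negative child-minus-parent signature count.

    A negative difference is an artifact (set to 0) iff it lies in
    [-1, 0) or its magnitude is below 5% of the branch's total signature
    count; otherwise it is flagged as a genuine inconsistency and left
    for the caller to surface (the value is still clamped to 0 so that
    downstream lengths remain usable).
    """
    if diff >= 0:
        return NegativeCountFlag(float(diff), False)
    if -1.0 <= diff < 0.0:
        return NegativeCountFlag(0.0, False)
    if abs(diff) < 0.05 * branch_total:
        return NegativeCountFlag(0.0, False)
    return NegativeCountFlag(0.0, True)


def branch_signature_counts(tree: PhyloTree,
                            exposures: dict[int, pd.Series]) -> pd.DataFrame:
    """Per-branch signature counts as child-minus-parent exposure differences.

    Negative differences are resolved by :func:`handle_negative_counts`;
    the returned frame has one row per non-root node (indexed by node_id)
    with one column per signature plus a ``flagged`` column.
    """
    rows = {}
    for node in tree.root.preorder():
        if node.parent is None:
            continue
        child = exposures[node.node_id]
        parent = exposures[node.parent.node_id]
        diff = child - parent
        total = float(diff.clip(lower=0.0).sum())
        adj = {}
        flagged = False
        for name, d in diff.items():
            res = handle_negative_counts(float(d), total)
            adj[name] = res.value
            flagged |= res.flagged
        adj["flagged"] = flagged
        rows[node.node_id] = adj
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "node_id"
    return out


# ----------------------------------------------------------------------
# clock lengths and ultrametric scaling
# ----------------------------------------------------------------------

def exclude_signature_mutations(tree: PhyloTree,
                                attribution: pd.DataFrame,
                                signature: str = "SBSC",
                                posterior_threshold: float = 0.5) -> PhyloTree:
    """Set per-branch clock counts excluding a (treatment-related) signature.

    ``attribution`` is indexed by site key with ``assigned_signature`` and
    ``assigned_probability`` columns (see ``signatures.attribute_mutations``).
    A mutation is excluded from the clock count iff its maximum-posterior
    signature equals ``signature`` with posterior >= threshold. Topology
    and molecular lengths are untouched.
    """
    assigned = attribution["assigned_signature"]
    prob = attribution["assigned_probability"]
    for node in tree.root.preorder():
        count = 0
        for s in node.mutations:
            if s in assigned.index and assigned[s] == signature \
                    and prob[s] >= posterior_threshold:
                continue
            count += 1
        node.clock_count = float(count)
    return tree


def set_clock_counts_from_branch_signatures(tree: PhyloTree,
                                            branch_counts: pd.DataFrame,
                                            clock_signatures: Iterable[str] = CLOCK_SIGNATURES,
                                            ) -> PhyloTree:
    """Clock length = fitted SBS1+SBS5 counts per branch (alternative route)."""
    cols = [c for c in clock_signatures if c in branch_counts.columns]
    for node in tree.root.preorder():
        if node.parent is None:
            node.clock_count = 0.0
        else:
            node.clock_count = float(branch_counts.loc[node.node_id, cols].sum())
    return tree


def make_ultrametric(tree: PhyloTree, donor_age: float) -> PhyloTree:
    """Scale cumulative clock counts to years so all tips end at donor_age.

    Each tip defines a linear scaling (donor_age / its root-to-tip clock
    count); an internal node's time is the mean of the times implied by
    its descendant tips, then a top-down pass enforces monotonicity
    (parent time <= child time). Root stays at 0; topology and tip set
    are preserved.
    """
    if donor_age <= 0:
        raise ValueError("donor_age must be > 0")
    root = tree.root
    cum: dict[int, float] = {}
    for node in root.preorder():
        c = node.clock_count if node.clock_count is not None else len(node.mutations)
        cum[id(node)] = (cum[id(node.parent)] if node.parent else 0.0) + float(c)

    scale: dict[int, float] = {}
    for tip in root.leaves():
        total = cum[id(tip)]
        scale[id(tip)] = donor_age / total if total > 0 else 0.0

    def tip_times(node: TreeNode) -> list[float]:
        return [cum[id(node)] * scale[id(t)] if scale[id(t)] > 0 else donor_age
                for t in ([node] if node.is_leaf else node.leaves())]

    for node in root.preorder():
        if node.parent is None:
            node.time = 0.0
        elif node.is_leaf:
            node.time = donor_age
        else:
            node.time = float(np.mean(tip_times(node)))
    for node in root.preorder():
        if node.parent is not None and node.time < node.parent.time:
            node.time = node.parent.time
    return tree


# ----------------------------------------------------------------------
# bulk sample placement
# ----------------------------------------------------------------------

@dataclass
class MRCAResult:
    """Placement of a bulk genome's most recent common ancestor on the tree."""
    status: str                      # "placed" | "no_mrca"
    branch_node_id: Optional[int]
    shared_sites: list[str]
    unshared_path_sites: list[str]   # detected mutations off the chosen path
    n_path_mutations: int

    @property
    def found(self) -> bool:
        return self.status == "placed"


def place_bulk_sample(tree: PhyloTree, bulk: pd.DataFrame,
                      min_vaf: float = 0.05, min_alt: int = 2) -> MRCAResult:
    """Find the deepest branch whose entire root path is detected in bulk.

    A tree mutation is detected if the bulk sample shows it at
    VAF >= min_vaf with >= min_alt reads. The MRCA branch is the deepest
    branch such that every mutation on its root path is detected; ties
    are broken toward more path mutations, then preorder. Detected
    mutations not on the chosen path are reported as unshared. With no
    detected overlap at all the result is "no_mrca" (the bulk clone
    diverged below the resolution of the sampled colonies).
    """
    det = bulk[(bulk["vaf"] >= min_vaf) & (bulk["alt_depth"] >= min_alt)]
    detected = {f"{c}:{p}:{r}>{a}" for c, p, r, a in
                zip(det["chrom"], det["pos"], det["ref"], det["alt"])}
    tree_sites = set(tree.site_to_branch)
    shared_all = detected & tree_sites
    if not shared_all:
        return MRCAResult("no_mrca", None, [], [], 0)

    best: Optional[TreeNode] = None
    best_depth = -1

    def walk(node: TreeNode, path_ok: bool, depth: int):
        nonlocal best, best_depth
        if node.parent is not None:
            branch_detected = [s for s in node.mutations if s in detected]
            path_ok = path_ok and len(branch_detected) == len(node.mutations)
            depth += len(node.mutations)
            if path_ok and depth > best_depth:
                best, best_depth = node, depth
        for child in node.children:
            walk(child, path_ok, depth)

    walk(tree.root, True, 0)
    if best is None or best_depth == 0:
        return MRCAResult("no_mrca", None, sorted(shared_all), [], 0)

    path_sites = [s for anc in best.path_from_root() for s in anc.mutations]
    unshared = sorted(shared_all - set(path_sites))
    return MRCAResult("placed", best.node_id, sorted(set(path_sites) & detected),
                      unshared, len(path_sites))
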