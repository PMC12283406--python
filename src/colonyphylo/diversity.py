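"""Clonal diversity statistics: clade definition, evenness, Shannon, subsampling.

A clade partition cuts the colony tree at a fixed distance from the root
(years on an ultrametric tree, or mutations on a molecular/clock tree):
every lineage crossing the cut founds one clade containing its descendant
tips. Simpson's evenness divides the inverse Simpson index by the number
of clades, so perfectly even clade sizes score 1 regardless of clade
count; the Shannon index is the usual -sum p ln p on clone proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylogeny import PhyloTree
from .tree import TreeNode

DEFAULT_CUT_MOLECULAR = 100.0   # mutations from the root
EXPANDED_CLADE_MIN_COLONIES = 3


@dataclass
class CladePartition:
    """Assignment of every colony to exactly one clade at a given cut."""
    cut: float
    length_type: str
    assignments: dict[str, int]     # colony -> clade id
    clade_sizes: list[int]

    @property
    def n_clades(self) -> int:
        return len(self.clade_sizes)

    def expanded_clades(self, min_colonies: int = EXPANDED_CLADE_MIN_COLONIES
                        ) -> list[int]:
        return [i for i, s in enumerate(self.clade_sizes) if s >= min_colonies]

    def metadata(self) -> dict:
        return {"cut": self.cut, "length_type": self.length_type,
                "n_clades": self.n_clades}


def define_clades(tree: PhyloTree | TreeNode,
                  cut: float = DEFAULT_CUT_MOLECULAR,
                  length_type: str = "molecular") -> CladePartition:
    """Cut the tree at a fixed root distance; crossing lineages found clades.

    ``length_type`` selects the branch-length flavor ("molecular",
    "clock" or "time"). A tip whose total root distance is below the cut
    forms its own clade.
    """
    root = tree.root if isinstance(tree, PhyloTree) else tree
    if cut < 0:
        raise ValueError("cut must be >= 0")
    assignments: dict[str, int] = {}
    sizes: list[int] = []

    def cum_len(node: TreeNode, acc: float):
        nonlocal sizes
        below = acc + node.branch_length(length_type)
        if node.parent is not None and below >= cut and acc < cut:
            clade_id = len(sizes)
            tips = node.leaf_names() if not node.is_leaf else [node.name]
            for t in tips:
                assignments[t] = clade_id
            sizes.append(len(tips))
            return
        if node.is_leaf:
            clade_id = len(sizes)
            assignments[node.name] = clade_id
            sizes.append(1)
            return
        for child in node.children:
            cum_len(child, below)

    cum_len(root, -root.branch_length(length_type))  # root branch has no length
    return CladePartition(cut, length_type, assignments, sizes)


def simpson_evenness(clade_sizes) -> float:
    """E = (1 / sum p_i^2) / S: inverse Simpson over clade count, in (0, 1]."""
    sizes = np.asarray([s for s in clade_sizes if s > 0], dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one non-empty clade")
    p = sizes / sizes.sum()
    return float(1.0 / np.sum(p ** 2) / sizes.size)


def shannon_index(clone_sizes) -> float:
    """H = -sum p_i ln p_i over non-empty clones (0 ln 0 := 0)."""
    sizes = np.asarray([s for s in clone_sizes if s > 0], dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one non-empty clone")
    p = sizes / sizes.sum()
    return float(-np.sum(p * np.log(p)))


def simpson_index(clone_sizes) -> float:
    """Inverse Simpson diversity 1 / sum p_i^2."""
    sizes = np.asarray([s for s in clone_sizes if s > 0], dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one non-empty clone")
    p = sizes / sizes.sum()
    return float(1.0 / np.sum(p ** 2))


def subsample_diversity(clone_labels, sample_size: int, reps: int,
                        seed: int, index: str = "shannon") -> np.ndarray:
    """Distribution of a diversity index under random subsampling.

    Draws ``reps`` independent uniform without-replacement samples of
    ``sample_size`` cells from the labeled population and returns the
    per-replicate index values ("shannon", "simpson" or
    "simpson_evenness" on the sampled clone sizes).
    """
    labels = np.asarray(clone_labels)
    if not 0 < sample_size <= labels.size:
        raise ValueError("sample_size must lie in [1, population size]")
    fn = {"shannon": shannon_index, "simpson": simpson_index,
          "simpson_evenness": simpson_evenness}[index]
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for r in range(reps):
        take = rng.choice(labels.size, size=sample_size, replace=False)
        _uniq, counts = np.unique(labels[take], return_counts=True)
        out[r] = fn(counts)
    return out


def clade_table(partition: CladePartition) -> pd.DataFrame:
    """Per-colony clade assignment with the cut parameters as metadata columns."""
    df = pd.DataFrame({
        "colony": list(partition.assignments),
        "clade": [partition.assignments[c] for c in partition.assignments],
    }).set_index("colony")
    df["cut"] = partition.cut
    df["length_type"] = partition.length_type
    return df
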