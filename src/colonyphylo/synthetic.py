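"""Synthetic single-HSPC-colony cohorts with known ground truth.

Generates every input the analysis pipeline consumes: a colony genealogy
with Poisson clock-like mutation accumulation (default 17.2 SNVs/year),
embedded germline variants (population VAF 0.5 in every colony),
in-culture subclonal mutations (within-colony VAF 0.1-0.25), recurrent
low-VAF artifact sites, driver-bearing expanded clades, an optional
late-life melphalan-like mutation burst, read-count tables at a target
sequencing depth, and a bulk myeloid-neoplasm sample descending from a
chosen colony lineage.

The genealogy model is a coalescent-like random binary tree in units of
years: background lineages coalesce early in life (by default within the
first five years, when the adult HSPC pool is established), while each
driver clade is forced to coalesce at its stated origin age. Every
stochastic operation takes an explicit seed; identical seeds give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import signatures as sigmod
from .tree import TreeNode

NORMAL_CLOCK_RATE = 17.2  # SNVs per year in normal HSPCs

CHROM_SIZES = {str(c): 120_000_000 for c in range(1, 23)}


def make_site_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic donor/patient cohort."""

    n_colonies: int
    donor_age: float = 60.0
    clock_rate: float = NORMAL_CLOCK_RATE
    driver_clades: Sequence[tuple[float, str, float]] = ()  # (fraction, label, origin_age)
    melphalan_exposure: Optional[tuple[float, float]] = None  # (age, extra SNVs/colony)
    germline_count: int = 300
    inculture_rate: float = 2.0        # in-culture mutations per colony
    artifact_count: int = 30
    mean_depth: float = 30.0
    early_coalescence_age: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_colonies < 2:
            raise ValueError("n_colonies must be >= 2")
        if self.donor_age <= 0 or self.clock_rate < 0:
            raise ValueError("donor_age must be > 0 and clock_rate >= 0")
        if min(self.germline_count, self.artifact_count) < 0 or self.inculture_rate < 0:
            raise ValueError("contaminant counts must be >= 0")
        total = 0.0
        for frac, _label, origin in self.driver_clades:
            if not 0 < frac <= 1:
                raise ValueError("clade size fractions must lie in (0, 1]")
            if not 0 < origin <= self.donor_age:
                raise ValueError("driver origin ages must lie in (0, donor_age]")
            total += frac
        if total > 1.0 + 1e-9:
            raise ValueError("clade size fractions must sum to at most 1")
        if self.melphalan_exposure is not None:
            age, extra = self.melphalan_exposure
            if not 0 <= age < self.donor_age or extra < 0:
                raise ValueError("melphalan exposure age must precede donor_age")


@dataclass
class GroundTruth:
    """Simulated cohort with complete labels for every site and colony."""

    config: CohortConfig
    tree: TreeNode                      # root = zygote at time 0
    colonies: list[str]
    mutations: pd.DataFrame             # indexed by integer mut_id
    carrier_sets: dict[int, tuple[str, ...]]
    colony_clade_labels: dict[str, str]

    def node_by_id(self, node_id: int) -> TreeNode:
        for node in self.tree.preorder():
            if node.node_id == node_id:
                return node
        raise KeyError(node_id)

    def site_keys(self) -> pd.Series:
        m = self.mutations
        if m["ref"].isna().any():
            raise ValueError("run simulate_spectra before requesting site keys")
        return pd.Series(
            [make_site_key(c, p, r, a)
             for c, p, r, a in zip(m["chrom"], m["pos"], m["ref"], m["alt"])],
            index=m.index,
        )


# ----------------------------------------------------------------------
# genealogy
# ----------------------------------------------------------------------

def _join_lineages(lineages: list[TreeNode], times: np.ndarray,
                   rng: np.random.Generator) -> TreeNode:
    """Coalesce lineages pairwise at the given times (processed latest first)."""
    times = np.sort(np.asarray(times, dtype=float))[::-1]
    active = list(lineages)
    for t in times:
        i, j = rng.choice(len(active), size=2, replace=False)
        i, j = (i, j) if i < j else (j, i)
        parent = TreeNode(time=float(t))
        parent.add_child(active[i])
        parent.add_child(active[j])
        active[i] = parent
        del active[j]
    assert len(active) == 1
    return active[0]


def simulate_genealogy(config: CohortConfig) -> GroundTruth:
    """Simulate the colony genealogy and all true mutation labels.

    Somatic mutation counts are Poisson along branches at ``clock_rate``
    per year (plus the melphalan burst, if configured, spread uniformly
    between exposure age and sampling); driver clades coalesce at their
    origin ages and carry a labeled driver mutation on their stem.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_colonies
    names = [f"C{i:03d}" for i in range(n)]

    # ---- partition colonies into driver clades + background
    order = rng.permutation(n)
    clade_members: list[tuple[list[int], str, float]] = []
    cursor = 0
    for frac, label, origin in config.driver_clades:
        size = max(1, int(round(frac * n)))
        members = list(order[cursor:cursor + size])
        if not members:
            raise ValueError("driver clade received no colonies")
        cursor += size
        clade_members.append((members, label, origin))
    background = list(order[cursor:])

    # ---- build clade subtrees rooted at their origin ages
    units: list[TreeNode] = []
    clade_roots: list[tuple[TreeNode, str]] = []
    labels = {name: "background" for name in names}
    for members, label, origin in clade_members:
        tips = [TreeNode(names[i], time=config.donor_age) for i in members]
        for i in members:
            labels[names[i]] = label
        if len(tips) == 1:
            clade_root = tips[0]
        else:
            times = np.concatenate([
                [origin],
                rng.uniform(origin, config.donor_age, size=len(tips) - 2),
            ]) if len(tips) > 2 else np.array([origin])
            clade_root = _join_lineages(tips, times, rng)
        units.append(clade_root)
        clade_roots.append((clade_root, label))
    units.extend(TreeNode(names[i], time=config.donor_age) for i in background)

    # ---- early coalescence of background lineages and clade stems
    early_max = min([config.early_coalescence_age]
                    + [origin for _m, _l, origin in clade_members]
                    + [config.donor_age])
    if len(units) == 1:
        root = TreeNode("zygote", time=0.0)
        root.add_child(units[0])
    elif len(units) == 2:
        root = TreeNode("zygote", time=0.0)
        root.add_child(units[0])
        root.add_child(units[1])
    else:
        times = np.concatenate([[0.0], rng.uniform(0.0, early_max, size=len(units) - 2)])
        root = _join_lineages(units, times, rng)
        root.name = "zygote"
    root.assign_ids()

    # ---- Poisson clock mutations along branches
    records = []
    carrier_sets: dict[int, tuple[str, ...]] = {}
    mut_id = 0
    exposure = config.melphalan_exposure
    tip_cache = {id(node): tuple(sorted(node.leaf_names())) for node in root.preorder()}
    for node in root.preorder():
        if node.parent is None:
            continue
        t0, t1 = node.parent.time, node.time
        carriers = tip_cache[id(node)]
        k = rng.poisson(config.clock_rate * (t1 - t0))
        for age in rng.uniform(t0, t1, size=k):
            records.append((mut_id, "somatic", "clock", node.node_id, float(age), ""))
            carrier_sets[mut_id] = carriers
            mut_id += 1
        if exposure is not None:
            age_e, extra = exposure
            span = config.donor_age - age_e
            lo, hi = max(t0, age_e), min(t1, config.donor_age)
            if span > 0 and hi > lo and extra > 0:
                kx = rng.poisson(extra / span * (hi - lo))
                for age in rng.uniform(lo, hi, size=kx):
                    records.append((mut_id, "somatic", "exposure", node.node_id,
                                    float(age), ""))
                    carrier_sets[mut_id] = carriers
                    mut_id += 1

    # ---- driver mutation on each clade stem
    for clade_root, label in clade_roots:
        records.append((mut_id, "somatic", "clock", clade_root.node_id,
                        float(clade_root.time), label))
        carrier_sets[mut_id] = tip_cache[id(clade_root)]
        clade_root.mutations.append(mut_id)
        mut_id += 1

    # attach clock/exposure mutation ids to branches (drivers already attached)
    by_branch: dict[int, list[int]] = {}
    for mid, _cls, _origin, branch, _age, gene in records:
        if gene == "":
            by_branch.setdefault(branch, []).append(mid)
    for node in root.preorder():
        if node.node_id in by_branch:
            node.mutations.extend(by_branch[node.node_id])

    # ---- germline variants (carried by every colony)
    all_names = tuple(names)
    for _ in range(config.germline_count):
        records.append((mut_id, "germline", None, -1, np.nan, ""))
        carrier_sets[mut_id] = all_names
        mut_id += 1

    # ---- in-culture subclonal mutations, private to one colony
    n_inculture = rng.poisson(config.inculture_rate, size=n)
    aux_vaf: dict[int, float] = {}
    for ci, k in enumerate(n_inculture):
        for _ in range(k):
            records.append((mut_id, "in_culture", None, -1, np.nan, ""))
            carrier_sets[mut_id] = (names[ci],)
            aux_vaf[mut_id] = float(rng.uniform(0.10, 0.25))
            mut_id += 1

    # ---- recurrent low-VAF artifact sites
    for _ in range(config.artifact_count):
        frac = rng.uniform(0.12, 0.25)
        k = max(int(np.ceil(frac * n)), int(np.floor(0.1 * n)) + 1)
        cols = rng.choice(n, size=min(k, n), replace=False)
        records.append((mut_id, "artifact", None, -1, np.nan, ""))
        carrier_sets[mut_id] = tuple(sorted(names[i] for i in cols))
        aux_vaf[mut_id] = 0.05
        mut_id += 1

    df = pd.DataFrame(records, columns=["mut_id", "mut_class", "origin",
                                        "branch_id", "age", "gene"])
    df = df.set_index("mut_id").sort_index()

    # ---- genomic coordinates, unique per (chrom, pos)
    chroms = np.array(list(CHROM_SIZES), dtype=object)
    m = len(df)
    chrom = rng.choice(chroms, size=m)
    pos = rng.integers(1, 120_000_000, size=m)
    key = pd.Series(chrom.astype(str)) + ":" + pd.Series(pos).astype(str)
    while key.duplicated().any():
        dup = key.duplicated().to_numpy()
        pos[dup] = rng.integers(1, 120_000_000, size=int(dup.sum()))
        key = pd.Series(chrom.astype(str)) + ":" + pd.Series(pos).astype(str)
    df["chrom"] = chrom
    df["pos"] = pos
    df["ref"] = pd.Series([None] * m, index=df.index, dtype=object)
    df["alt"] = pd.Series([None] * m, index=df.index, dtype=object)
    df["trinucleotide_context"] = pd.Series([None] * m, index=df.index, dtype=object)
    df["true_signature"] = pd.Series([None] * m, index=df.index, dtype=object)
    df["aux_vaf"] = pd.Series(aux_vaf, dtype=float).reindex(df.index)

    return GroundTruth(
        config=config,
        tree=root,
        colonies=names,
        mutations=df,
        carrier_sets=carrier_sets,
        colony_clade_labels=labels,
    )


# ----------------------------------------------------------------------
# spectra
# ----------------------------------------------------------------------

def default_exposure_schedule(config: CohortConfig) -> list[tuple[float, float, dict]]:
    """Constant clock-like mixture across life (SBS1 30% / SBS5 70%)."""
    return [(0.0, config.donor_age, {"SBS1": 0.3, "SBS5": 0.7})]


def simulate_spectra(
    truth: GroundTruth,
    signature_set: Optional[pd.DataFrame] = None,
    exposure_schedule: Optional[list[tuple[float, float, dict]]] = None,
    seed: Optional[int] = None,
) -> GroundTruth:
    """Assign each mutation a trinucleotide channel drawn from its signature.

    Clock mutations sample a signature from the schedule interval covering
    their age; melphalan-burst mutations always draw from the melphalan-like
    signature (``SBSC``); germline/in-culture/artifact sites draw from SBS5.
    Updates ``truth.mutations`` in place (ref/alt/context/true_signature)
    and returns the same object.
    """
    if signature_set is None:
        signature_set = sigmod.default_reference_signatures()
    if exposure_schedule is None:
        exposure_schedule = default_exposure_schedule(truth.config)
    for lo, hi, weights in exposure_schedule:
        total = sum(weights.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("schedule exposure weights must sum to 1")
        if hi <= lo:
            raise ValueError("schedule intervals must have positive length")
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None else seed)

    df = truth.mutations
    sig_of = np.empty(len(df), dtype=object)
    ages = df["age"].to_numpy()
    classes = df["mut_class"].to_numpy()
    origins = df["origin"].to_numpy()
    for i in range(len(df)):
        if classes[i] != "somatic":
            sig_of[i] = "SBS5"
        elif origins[i] == "exposure":
            sig_of[i] = "SBSC"
        else:
            weights = None
            for lo, hi, wts in exposure_schedule:
                if lo <= ages[i] <= hi:
                    weights = wts
                    break
            if weights is None:
                raise ValueError(f"no schedule interval covers age {ages[i]:.2f}")
            names = list(weights)
            sig_of[i] = names[rng.choice(len(names), p=[weights[k] for k in names])]

    channels = np.empty(len(df), dtype=object)
    for name in pd.unique(sig_of):
        mask = sig_of == name
        pmf = signature_set[name].to_numpy()
        draws = rng.choice(96, size=int(mask.sum()), p=pmf / pmf.sum())
        channels[mask] = [sigmod.CHANNELS_96[j] for j in draws]

    decoded = [sigmod.decode_channel(ch) for ch in channels]
    df["ref"] = [d[0] for d in decoded]
    df["alt"] = [d[1] for d in decoded]
    df["trinucleotide_context"] = [d[2] for d in decoded]
    df["true_signature"] = sig_of
    return truth


# ----------------------------------------------------------------------
# read counts
# ----------------------------------------------------------------------

def simulate_read_counts(
    truth: GroundTruth,
    mean_depth: Optional[float] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-site, per-colony alt/total read depths (the VariantCallTable).

    Depth is Poisson(mean_depth) per site and colony. Alt reads are
    Binomial(depth, v) with v = 0.5 for true carriers (somatic and
    germline), the drawn subclonal VAF for in-culture sites, and a low
    error rate for artifact sites in their recurrent colonies.
    """
    if mean_depth is None:
        mean_depth = truth.config.mean_depth
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(truth.config.seed + 2 if seed is None else seed)

    df = truth.mutations
    if len(df) and df["ref"].isna().any():
        raise ValueError("run simulate_spectra before simulate_read_counts")
    names = truth.colonies
    col_index = {c: j for j, c in enumerate(names)}
    m, n = len(df), len(names)

    vaf = np.zeros((m, n))
    aux = df["aux_vaf"].to_numpy()
    for i, (mid, cls) in enumerate(zip(df.index, df["mut_class"])):
        cols = [col_index[c] for c in truth.carrier_sets[mid]]
        vaf[i, cols] = 0.5 if cls in ("somatic", "germline") else aux[i]

    depth = rng.poisson(mean_depth, size=(m, n))
    alt = np.zeros((m, n), dtype=np.int64)
    nz = vaf > 0          # mutant reads arise only where a variant is present
    alt[nz] = rng.binomial(depth[nz], vaf[nz])

    meta = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(),
        "pos": df["pos"].to_numpy(),
        "ref": df["ref"].to_numpy(),
        "alt": df["alt"].to_numpy(),
        "trinucleotide_context": df["trinucleotide_context"].to_numpy(),
    })
    numeric = np.empty((m, 2 * n), dtype=np.int64)
    numeric[:, 0::2] = alt
    numeric[:, 1::2] = depth
    names_interleaved = [f"{c}_{suffix}" for c in names for suffix in ("alt", "dp")]
    counts = pd.DataFrame(numeric, columns=names_interleaved)
    return pd.concat([meta, counts], axis=1)


def true_genotype_matrix(truth: GroundTruth) -> pd.DataFrame:
    """Noise-free colony x somatic-mutation binary matrix (a perfect phylogeny)."""
    df = truth.mutations
    somatic = df.index[df["mut_class"] == "somatic"]
    keys = truth.site_keys()
    col_index = {c: i for i, c in enumerate(truth.colonies)}
    M = np.zeros((len(truth.colonies), len(somatic)), dtype=np.int64)
    for j, mid in enumerate(somatic):
        M[[col_index[c] for c in truth.carrier_sets[mid]], j] = 1
    return pd.DataFrame(M, index=truth.colonies,
                        columns=[keys[mid] for mid in somatic])


# ----------------------------------------------------------------------
# bulk t-MN sample
# ----------------------------------------------------------------------

def simulate_bulk_tmn(
    truth: GroundTruth,
    origin_branch: int | TreeNode,
    n_private: int = 100,
    purity: float = 0.8,
    mean_depth: float = 60.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Bulk tumor sample descending from one branch of the true genealogy.

    Contains every mutation on the root-to-origin path at expected VAF
    purity/2 plus ``n_private`` novel heterozygous mutations; mutations on
    branches disjoint from the path are absent.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    rng = np.random.default_rng(truth.config.seed + 3 if seed is None else seed)
    node = origin_branch if isinstance(origin_branch, TreeNode) \
        else truth.node_by_id(origin_branch)

    path_ids: list[int] = []
    for anc in node.path_from_root():
        path_ids.extend(anc.mutations)
    df = truth.mutations
    rows = []
    for mid in path_ids:
        rec = df.loc[mid]
        dp = int(rng.poisson(mean_depth))
        a = int(rng.binomial(dp, purity / 2)) if dp > 0 else 0
        rows.append((rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"],
                     a / dp if dp else 0.0, a, dp))
    for _ in range(n_private):
        chrom = rng.choice(list(CHROM_SIZES))
        pos = int(rng.integers(1, 120_000_000))
        ch = sigmod.CHANNELS_96[rng.integers(96)]
        ref, alt, _ctx = sigmod.decode_channel(ch)
        dp = int(rng.poisson(mean_depth))
        a = int(rng.binomial(dp, purity / 2)) if dp > 0 else 0
        rows.append((chrom, pos, ref, alt, a / dp if dp else 0.0, a, dp))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "vaf", "alt_depth", "total_depth"])


# ----------------------------------------------------------------------
# convenience
# ----------------------------------------------------------------------

def simulate_cohort(config: CohortConfig,
                    signature_set: Optional[pd.DataFrame] = None,
                    exposure_schedule: Optional[list] = None,
                    ) -> tuple[GroundTruth, pd.DataFrame]:
    """Genealogy + spectra + read counts in one call.

    Returns (ground truth, variant call table).
    """
    truth = simulate_genealogy(config)
    simulate_spectra(truth, signature_set, exposure_schedule)
    table = simulate_read_counts(truth)
    return truth, table


def write_ground_truth(truth: GroundTruth, newick_path, labels_path) -> None:
    """True tree as Newick (time lengths) and colony labels as TSV."""
    with open(newick_path, "w") as fh:
        fh.write(truth.tree.to_newick("time") + "\n")
    pd.Series(truth.colony_clade_labels, name="clade_label") \
        .rename_axis("colony").to_frame().to_csv(labels_path, sep="\t")
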