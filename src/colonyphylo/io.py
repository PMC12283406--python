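"""File formats, run configuration and the end-to-end pipeline report.

All tables are plain TSV; trees are Newick; the run report is JSON. Every
output carries the SHA-256 hash of the producing configuration so stages
can be audited and resumed from on-disk artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import diversity as divmod_
from . import filtering, phylogeny, signatures, synthetic
from .tree import TreeNode, parse_newick

logger = logging.getLogger("colonyphylo")

VARIANT_META_COLUMNS = ["chrom", "pos", "ref", "alt", "trinucleotide_context"]


def read_variant_table(path) -> pd.DataFrame:
    """Read and validate a variant call table TSV.

    Expected columns: chrom, pos (1-based), ref, alt,
    trinucleotide_context, then ``<colony>_alt`` / ``<colony>_dp`` pairs.
    Malformed rows raise with their (1-based, header-inclusive) line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    alt_cols = [c for c in df.columns if c.endswith("_alt")]
    dp_cols = [c for c in df.columns if c.endswith("_dp")]
    colonies = [c[:-4] for c in alt_cols]
    if sorted(colonies) != sorted(c[:-3] for c in dp_cols):
        raise ValueError(f"{path}: colony _alt/_dp columns do not pair up")
    for c in alt_cols + dp_cols:
        bad = df.index[(df[c] < 0) | df[c].isna()]
        if len(bad):
            raise ValueError(f"{path}: negative or missing depth in column {c}, "
                             f"line {bad[0] + 2}")
    for colony in colonies:
        bad = df.index[df[f"{colony}_alt"] > df[f"{colony}_dp"]]
        if len(bad):
            raise ValueError(f"{path}: alt_depth > total_depth for colony "
                             f"{colony}, line {bad[0] + 2}")
    return df


def write_variant_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_genotype_matrix(gm: pd.DataFrame, path) -> None:
    """Colonies x mutations as TSV with 0/1/NA."""
    gm.to_csv(path, sep="\t", na_rep="NA", index_label="colony")


def read_genotype_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="colony", na_values="NA")


def read_bulk_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "pos", "ref", "alt", "vaf", "alt_depth", "total_depth"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
        raise ValueError(f"{path}: VAF outside [0, 1]")
    return df


def read_driver_list(path) -> list[str]:
    """One gene symbol per line; '#' comments and blanks ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


NEWICK_LENGTH_TYPES = ("molecular", "clock", "time", "none")


def write_newick(tree, length_type: str = "molecular") -> str:
    """Render a tree (PhyloTree or TreeNode) as Newick text."""
    if length_type not in NEWICK_LENGTH_TYPES:
        raise ValueError(f"unknown length_type {length_type!r}; "
                         f"choose from {NEWICK_LENGTH_TYPES}")
    root = tree.root if hasattr(tree, "root") else tree
    lt = None if length_type == "none" else length_type
    return root.to_newick(lt)


def read_newick(path_or_text) -> TreeNode:
    text = str(path_or_text)
    if not text.strip().endswith(";"):
        text = Path(path_or_text).read_text()
    return parse_newick(text)


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (strict: unknown keys rejected)."""
    seed: int = 0
    sex: str = "female"
    donor_age: float = 60.0
    n_colonies: int = 40
    clock_rate: float = synthetic.NORMAL_CLOCK_RATE
    mean_depth: float = 30.0
    germline_count: int = 300
    inculture_rate: float = 2.0
    artifact_count: int = 30
    driver_clades: tuple = ()
    melphalan_exposure: Optional[tuple] = None
    variant_table: Optional[str] = None     # skip simulation if given
    bulk_table: Optional[str] = None
    driver_list: Optional[str] = None
    signature_table: Optional[str] = None
    excluded_signature: str = "SBSC"
    clade_cut: float = divmod_.DEFAULT_CUT_MOLECULAR
    clade_cut_length_type: str = "molecular"
    min_bulk_vaf: float = 0.05
    min_bulk_alt: int = 2
    output_dir: str = "colonyphylo_run"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("driver_clades",):
            if key in data and data[key] is not None:
                data[key] = tuple(tuple(x) for x in data[key])
        if data.get("melphalan_exposure") is not None:
            data["melphalan_exposure"] = tuple(data["melphalan_exposure"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Simulate (optional) -> filter -> signatures -> tree -> clock ->
    diversity -> bulk placement; returns a machine-readable report."""
    report: dict[str, Any] = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "stages": {},
    }
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs
    truth = None
    if config.variant_table is not None:
        table = read_variant_table(config.variant_table)
        report["stages"]["input"] = {"status": "ok", "n_sites": len(table),
                                     "source": str(config.variant_table)}
    else:
        cohort = synthetic.CohortConfig(
            n_colonies=config.n_colonies, donor_age=config.donor_age,
            clock_rate=config.clock_rate, driver_clades=config.driver_clades,
            melphalan_exposure=config.melphalan_exposure,
            germline_count=config.germline_count,
            inculture_rate=config.inculture_rate,
            artifact_count=config.artifact_count,
            mean_depth=config.mean_depth, seed=config.seed)
        truth, table = synthetic.simulate_cohort(cohort)
        report["stages"]["simulate"] = {
            "status": "ok", "n_sites": len(table),
            "n_colonies": config.n_colonies, "seed": config.seed}
        if write_outputs:
            write_variant_table(table, outdir / "variant_table.tsv")
            synthetic.write_ground_truth(truth, outdir / "true_tree.nwk",
                                         outdir / "true_labels.tsv")
    logger.info("[input] %d candidate sites, %d colonies", len(table),
                sum(1 for c in table.columns if c.endswith("_alt")))

    # --- filtering
    result = filtering.run_filter_pipeline(table, sex=config.sex)
    counts = result.report["status"].value_counts().to_dict()
    report["stages"]["filter"] = {"status": "ok", "site_status_counts": counts,
                                  "n_kept": int(len(result.kept_sites)),
                                  "n_colonies_qc_fail":
                                      int((result.colony_qc["status"] == "fail").sum())}
    logger.info("[filter] kept %d sites", len(result.kept_sites))
    if write_outputs:
        result.report.to_csv(outdir / "filter_report.tsv", sep="\t")
        write_genotype_matrix(result.genotype_matrix, outdir / "genotype_matrix.tsv")

    # --- signatures
    ref = (signatures.read_signature_table(config.signature_table)
           if config.signature_table else signatures.default_reference_signatures())
    kept = result.kept_sites
    meta = table[VARIANT_META_COLUMNS].copy()
    meta.index = pd.Index([synthetic.make_site_key(c, p, r, a) for c, p, r, a in
                           zip(meta["chrom"], meta["pos"], meta["ref"], meta["alt"])])
    kept_meta = meta.loc[[k for k in kept if k in meta.index]]
    spectrum = signatures.count_contexts(kept_meta)
    exposures, residual = signatures.fit_exposures(spectrum, ref)
    attribution = signatures.attribute_mutations(kept_meta, exposures, ref)
    report["stages"]["signatures"] = {
        "status": "ok",
        "exposures": {k: float(v) for k, v in exposures.items()},
        "residual": residual}
    if write_outputs:
        attribution.to_csv(outdir / "mutation_signatures.tsv", sep="\t")

    # --- tree + clock scaling
    tree = phylogeny.build_tree(result.genotype_matrix)
    phylogeny.exclude_signature_mutations(tree, attribution,
                                          signature=config.excluded_signature)
    phylogeny.make_ultrametric(tree, config.donor_age)
    report["stages"]["tree"] = {
        "status": "ok",
        "n_assigned": tree.n_assigned_mutations(),
        "n_conflicting": len(tree.conflicting_sites),
        "n_dropped": len(tree.dropped_sites)}
    if write_outputs:
        for lt in ("molecular", "clock", "time"):
            (outdir / f"tree_{lt}.nwk").write_text(write_newick(tree, lt) + "\n")

    # --- drivers
    if config.driver_list is not None:
        genes = read_driver_list(config.driver_list)
        flags = filtering.annotate_drivers(
            kept_meta.assign(gene=""), genes)
        report["stages"]["drivers"] = {"status": "ok",
                                       "n_flagged": int(flags.sum())}

    # --- diversity
    partition = divmod_.define_clades(tree, config.clade_cut,
                                      config.clade_cut_length_type)
    report["stages"]["diversity"] = {
        "status": "ok",
        "clade_sizes": partition.clade_sizes,
        "simpson_evenness": divmod_.simpson_evenness(partition.clade_sizes),
        "shannon": divmod_.shannon_index(partition.clade_sizes),
        **partition.metadata()}
    if write_outputs:
        divmod_.clade_table(partition).to_csv(outdir / "clades.tsv", sep="\t")

    # --- bulk placement
    if config.bulk_table is not None:
        bulk = read_bulk_table(config.bulk_table)
        mrca = phylogeny.place_bulk_sample(tree, bulk, config.min_bulk_vaf,
                                           config.min_bulk_alt)
        report["stages"]["bulk"] = {
            "status": "ok", "mrca_status": mrca.status,
            "branch_node_id": mrca.branch_node_id,
            "n_shared": len(mrca.shared_sites)}
    else:
        report["stages"]["bulk"] = {"status": "skipped",
                                    "reason": "no bulk sample configured"}

    # --- truth evaluation (synthetic runs only)
    if truth is not None:
        keys = truth.site_keys()
        classes = truth.mutations.set_index(keys)["mut_class"]
        kept_set = set(result.kept_sites)
        by_class = {}
        for cls in ("somatic", "germline", "in_culture", "artifact"):
            sites = classes.index[classes == cls]
            if len(sites):
                kept_frac = float(np.mean([s in kept_set for s in sites]))
                by_class[cls] = {"n": int(len(sites)), "kept_fraction": kept_frac}
        report["truth_evaluation"] = by_class

    if write_outputs:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def write_trajectory(traj, path) -> None:
    traj.data.assign(scenario=traj.scenario).to_csv(path, sep="\t", index=False)
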