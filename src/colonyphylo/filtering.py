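"""Post-caller somatic mutation filters and colony clonality QC.

Candidate variants from single-colony whole-genome sequencing are refined
with a fixed sequence of filters before phylogeny construction:

1. germline classification — an exact one-sided (lower-tail) binomial test
   on alt/total depths pooled across all colonies of the patient, null
   VAF 0.5 (0.95 on sex chromosomes in males); sites with p > 1e-10 are
   germline (their pooled VAF is consistent with a constitutive variant);
2. proximity — pairs of sites within 10 bp on a chromosome are removed
   (clustered calls are typically alignment artifacts);
3. coverage "NA" — genotypes at depth < 5 (autosomes; X in females) or
   < 3 (X/Y in males) are set to missing, and sites missing in more than
   five colonies are dropped;
4. mean VAF — sites whose mean VAF across mutant-read-bearing colonies is
   0.3 or less are removed (in-culture subclonal mutations);
5. recurrent low VAF — sites with 0 < VAF < 0.1 in over 10% of colonies
   are removed (recurrent sequencing artifacts).

Colony QC then excludes colonies whose somatic-VAF histogram lacks a
single peak near 0.5 (likely merged colonies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GERMLINE_P_THRESHOLD = 1e-10
PROXIMITY_BP = 10
MIN_DEPTH_AUTOSOME = 5
MIN_DEPTH_SEX_MALE = 3
MAX_NA_COLONIES = 5
MEAN_VAF_CUTOFF = 0.3
LOW_VAF_CUTOFF = 0.1
LOW_VAF_FRACTION = 0.10

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class FilterParams:
    """Tunable constants of the filter pipeline (defaults follow the text above)."""
    germline_p: float = GERMLINE_P_THRESHOLD
    proximity_bp: int = PROXIMITY_BP
    min_depth_autosome: int = MIN_DEPTH_AUTOSOME
    min_depth_sex_male: int = MIN_DEPTH_SEX_MALE
    max_na_colonies: int = MAX_NA_COLONIES
    mean_vaf_cutoff: float = MEAN_VAF_CUTOFF
    low_vaf_cutoff: float = LOW_VAF_CUTOFF
    low_vaf_fraction: float = LOW_VAF_FRACTION
    min_alt_reads: int = 2          # alt reads required to call a genotype 1
    qc_min_sites: int = 30
    qc_bin_width: float = 0.05
    qc_mode_fraction: float = 0.25
    qc_peak_window: tuple[float, float] = (0.4, 0.6)
    qc_smooth: bool = True      # 1-2-1 histogram smoothing before mode search


def null_vaf(chrom: str, sex: str) -> float:
    """Null VAF for the germline test: 0.5, or 0.95 on male sex chromosomes."""
    if sex.lower().startswith("m") and str(chrom) in SEX_CHROMS:
        return 0.95
    return 0.5


def germline_binomial_test(alt_sum: int, depth_sum: int,
                           p0: float = 0.5,
                           threshold: float = GERMLINE_P_THRESHOLD,
                           ) -> tuple[float, str]:
    """Exact one-sided (lower-tail) binomial test for germline status.

    Pools alt and total depths across all colonies of a patient and asks
    whether the pooled VAF is too low to be a constitutive variant:
    p = P(X <= alt_sum | depth_sum, p0). Sites with p > threshold are
    classified germline; far-below-null sites are somatic candidates.
    """
    if depth_sum <= 0:
        raise ValueError("site has zero pooled depth; classification undefined")
    p = float(stats.binom.cdf(alt_sum, depth_sum, p0))
    return p, ("germline" if p > threshold else "somatic")


def proximity_filter(sites: pd.DataFrame, max_bp: int = PROXIMITY_BP) -> np.ndarray:
    """Boolean mask of sites removed for having a neighbor within ``max_bp``.

    Any pair on the same chromosome at distance <= max_bp removes *both*
    sites. ``sites`` needs ``chrom`` and ``pos`` columns.
    """
    removed = np.zeros(len(sites), dtype=bool)
    if not len(sites):
        return removed
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].astype(str).to_numpy()))
    chrom = sites["chrom"].astype(str).to_numpy()[order]
    pos = sites["pos"].to_numpy()[order]
    close = (chrom[1:] == chrom[:-1]) & (np.abs(pos[1:] - pos[:-1]) <= max_bp)
    hit = np.zeros(len(sites), dtype=bool)
    hit[:-1] |= close
    hit[1:] |= close
    removed[order] = hit
    return removed


def coverage_na_filter(depths: np.ndarray, chroms: Sequence[str], sex: str,
                       params: FilterParams = FilterParams(),
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Missing-genotype flags and site exclusions from low coverage.

    Returns (na_mask of shape sites x colonies, excluded site mask).
    A genotype is missing below 5 reads (autosomes; X in females) or below
    3 reads (sex chromosomes in males); a site missing in more than
    ``max_na_colonies`` colonies is excluded entirely.
    """
    chroms = np.asarray([str(c) for c in chroms], dtype=object)
    male = sex.lower().startswith("m")
    min_depth = np.where(
        male & np.isin(chroms, list(SEX_CHROMS)),
        params.min_depth_sex_male,
        params.min_depth_autosome,
    )
    na = depths < min_depth[:, None]
    excluded = na.sum(axis=1) > params.max_na_colonies
    return na, excluded


def mean_vaf_filter(alt: np.ndarray, depth: np.ndarray,
                    cutoff: float = MEAN_VAF_CUTOFF) -> bool:
    """True (remove) iff the mean VAF over mutant-read-bearing colonies is <= cutoff."""
    carrier = alt > 0
    if not carrier.any():
        return False
    vaf = alt[carrier] / np.maximum(depth[carrier], 1)
    return bool(vaf.mean() <= cutoff)


def recurrent_low_vaf_filter(alt: np.ndarray, depth: np.ndarray,
                             n_colonies: Optional[int] = None,
                             cutoff: float = LOW_VAF_CUTOFF,
                             fraction: float = LOW_VAF_FRACTION) -> bool:
    """True (remove) iff 0 < VAF < cutoff in more than ``fraction`` of colonies."""
    if n_colonies is None:
        n_colonies = len(alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    low = (alt > 0) & (vaf < cutoff)
    return bool(low.sum() / n_colonies > fraction)


class QCResult(NamedTuple):
    status: str                 # "pass" | "fail" | "indeterminate"
    n_modes: int
    mode_centers: tuple[float, ...]
    reason: str


def colony_clonality_qc(colony_vafs: Sequence[float],
                        params: FilterParams = FilterParams()) -> QCResult:
    """Single-cell-origin QC from a colony's somatic VAF histogram.

    A clonal (single-cell-derived) colony shows one VAF mode near 0.5;
    merged colonies show a shifted or multimodal histogram. Modes are
    local maxima of a fixed-width histogram exceeding
    ``qc_mode_fraction`` of the tallest bin; the colony passes iff there
    is exactly one mode and it falls inside ``qc_peak_window``. Fewer
    than ``qc_min_sites`` informative sites give an indeterminate result.
    """
    vafs = np.asarray([v for v in colony_vafs if np.isfinite(v) and v > 0])
    if len(vafs) < params.qc_min_sites:
        return QCResult("indeterminate", 0, (),
                        f"only {len(vafs)} sites (<{params.qc_min_sites})")
    edges = np.arange(0.0, 1.0 + params.qc_bin_width, params.qc_bin_width)
    hist, _ = np.histogram(vafs, bins=edges)
    h = hist.astype(float)
    if params.qc_smooth:
        # VAFs are ratios of small integers; a 1-2-1 kernel removes the
        # sawtooth that depth discreteness imprints on fixed-width bins
        h = np.convolve(h, [0.25, 0.5, 0.25], mode="same")
    thresh = params.qc_mode_fraction * h.max()
    centers = (edges[:-1] + edges[1:]) / 2
    modes = []
    for i in range(len(h)):
        left = h[i - 1] if i > 0 else 0.0
        right = h[i + 1] if i + 1 < len(h) else 0.0
        if h[i] > thresh and h[i] >= left and h[i] >= right:
            modes.append(centers[i])
    # adjacent equal-height bins count as one mode
    merged: list[float] = []
    for c in modes:
        if merged and abs(c - merged[-1]) <= params.qc_bin_width + 1e-9:
            merged[-1] = (merged[-1] + c) / 2
        else:
            merged.append(c)
    lo, hi = params.qc_peak_window
    if len(merged) == 1 and lo <= merged[0] <= hi:
        return QCResult("pass", 1, tuple(merged), "single mode near 0.5")
    if len(merged) != 1:
        return QCResult("fail", len(merged), tuple(merged),
                        f"{len(merged)} VAF modes")
    return QCResult("fail", 1, tuple(merged),
                    f"mode at {merged[0]:.2f} outside [{lo}, {hi}]")


def annotate_drivers(kept_sites: pd.DataFrame,
                     driver_list: Sequence[str]) -> pd.Series:
    """Case-insensitive driver flags from a user-supplied gene list.

    ``kept_sites`` needs a ``gene`` column; returns a boolean Series.
    """
    drivers = {g.upper() for g in driver_list}
    if "gene" not in kept_sites.columns or not drivers:
        return pd.Series(False, index=kept_sites.index)
    return kept_sites["gene"].fillna("").astype(str).str.upper().isin(drivers)


@dataclass
class FilterResult:
    """Output of the filter pipeline."""
    genotype_matrix: pd.DataFrame       # colonies x kept sites, {0,1,NaN}
    report: pd.DataFrame                # per input site: status, p_germline
    colony_qc: pd.DataFrame             # per colony: status, reason
    params: FilterParams = field(default_factory=FilterParams)

    @property
    def kept_sites(self) -> pd.Index:
        return self.report.index[self.report["status"] == "kept"]


def split_variant_table(table: pd.DataFrame
                        ) -> tuple[pd.DataFrame, list[str], np.ndarray, np.ndarray]:
    """Split a variant call table into site info, colony ids, alt and depth arrays."""
    meta_cols = [c for c in table.columns if not c.endswith(("_alt", "_dp"))]
    colonies = [c[:-4] for c in table.columns if c.endswith("_alt")]
    alt = table[[f"{c}_alt" for c in colonies]].to_numpy(dtype=np.int64)
    depth = table[[f"{c}_dp" for c in colonies]].to_numpy(dtype=np.int64)
    if (alt > depth).any() or (alt < 0).any() or (depth < 0).any():
        raise ValueError("alt depths must satisfy 0 <= alt <= total")
    return table[meta_cols].copy(), colonies, alt, depth


def run_filter_pipeline(table: pd.DataFrame, sex: str = "female",
                        params: FilterParams = FilterParams()) -> FilterResult:
    """Apply germline, proximity, coverage, VAF filters and colony QC.

    Filters run in the fixed order germline -> proximity -> coverage-NA ->
    mean-VAF -> recurrent-low-VAF; each site receives exactly one status
    (its first failure, or "kept"). Deterministic and idempotent on its
    kept output.
    """
    meta, colonies, alt, depth = split_variant_table(table)
    m, n = alt.shape if len(table) else (0, len(table.columns))
    keys = pd.Index(
        [f"{c}:{p}:{r}>{a}" for c, p, r, a in
         zip(meta.get("chrom", []), meta.get("pos", []),
             meta.get("ref", []), meta.get("alt", []))],
        name="site",
    )
    status = np.array(["kept"] * m, dtype=object)

    if m == 0:
        empty_gm = pd.DataFrame(index=colonies)
        report = pd.DataFrame({"status": status, "p_germline": []}, index=keys)
        qc = pd.DataFrame(columns=["status", "n_sites", "reason"], index=colonies)
        return FilterResult(empty_gm, report, qc, params)

    # 0) germline classification on pooled depths
    chroms = meta["chrom"].astype(str).to_numpy()
    p0 = np.array([null_vaf(c, sex) for c in chroms])
    alt_sum = alt.sum(axis=1)
    depth_sum = depth.sum(axis=1)
    if (depth_sum == 0).any():
        raise ValueError("sites with zero pooled depth cannot be classified")
    p_germ = stats.binom.cdf(alt_sum, depth_sum, p0)
    status[p_germ > params.germline_p] = "germline"
    active = status == "kept"

    # 1) proximity (assessed among non-germline candidates)
    prox = proximity_filter(meta.loc[active, ["chrom", "pos"]],
                            params.proximity_bp)
    idx_active = np.flatnonzero(active)
    status[idx_active[prox]] = "proximity"
    active = status == "kept"

    # 2) coverage NA
    na, excluded = coverage_na_filter(depth, chroms, sex, params)
    status[active & excluded] = "na_excluded"
    active = status == "kept"

    # 3) mean VAF over mutant-read colonies
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    carrier = alt > 0
    carrier_n = carrier.sum(axis=1)
    mean_vaf = np.where(
        carrier_n > 0,
        np.where(carrier, vaf, 0.0).sum(axis=1) / np.maximum(carrier_n, 1),
        1.0,
    )
    status[active & (carrier_n > 0) & (mean_vaf <= params.mean_vaf_cutoff)] = "low_mean_vaf"
    active = status == "kept"

    # 4) recurrent low VAF
    low = carrier & (vaf < params.low_vaf_cutoff)
    status[active & (low.sum(axis=1) / n > params.low_vaf_fraction)] = "recurrent_low_vaf"
    active = status == "kept"

    # genotype matrix on kept sites
    kept_idx = np.flatnonzero(active)
    geno = np.where(alt[kept_idx] >= params.min_alt_reads, 1.0, 0.0)
    geno[na[kept_idx]] = np.nan
    gm = pd.DataFrame(geno.T, index=colonies, columns=keys[kept_idx])

    # colony QC on each colony's own kept mutations
    qc_rows = {}
    for j, colony in enumerate(colonies):
        mask = (geno[:, j] == 1.0)
        vafs = vaf[kept_idx[mask], j]
        res = colony_clonality_qc(vafs, params)
        qc_rows[colony] = {"status": res.status, "n_sites": int(mask.sum()),
                           "reason": res.reason}
    qc = pd.DataFrame.from_dict(qc_rows, orient="index")
    qc.index.name = "colony"

    failed = qc.index[qc["status"] == "fail"]
    gm = gm.drop(index=failed)

    report = pd.DataFrame({"status": status, "p_germline": p_germ}, index=keys)
    return FilterResult(gm, report, qc, params)
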