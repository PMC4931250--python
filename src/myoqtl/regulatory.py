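"""Stretch/typical enhancer classification and matched-null SNP enrichment.

Enhancer-state runs are maximal blocks of contiguous intervals whose state
belongs to the enhancer label set. Runs >= 3 kb are "stretch" enhancers,
runs <= 800 bp "typical" (the median enhancer size in reference
segmentations), and everything between is "intermediate". A run is
tissue-specific when at most a configured fraction of its bases is active
(enhancer or promoter states) in every other tissue.

Enrichment of a SNP set in an interval feature set is measured against
matched null SNP sets: each test SNP is matched on MAF bin, log10
TSS-distance bin and LD-neighbour-count bin (r^2 >= 0.8 proxies within 1 Mb),
and each null set draws one matched candidate per test SNP. The fold is the
observed overlap count over the mean null overlap, with an empirical p-value
``(1 + #{null >= observed}) / (n_null + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ACTIVE_STATES,
    CHROMATIN_STATES,
    ENHANCER_STATES,
    ChromatinSegmentation,
    GeneAnnotation,
    GenotypeMatrix,
)

__all__ = [
    "merge_enhancer_runs",
    "classify_enhancers",
    "tissue_specific_filter",
    "ld_neighbour_count",
    "annotate_universe",
    "matched_null_enrichment",
    "stratified_enrichment",
    "EnrichmentResult",
]

STRETCH_MIN_BP = 3_000
TYPICAL_MAX_BP = 800


def merge_enhancer_runs(
    segmentation: ChromatinSegmentation,
    enhancer_states: frozenset[str] | set[str] = ENHANCER_STATES,
) -> pd.DataFrame:
    """Maximal runs of contiguous enhancer-state intervals per chromosome.

    Adjacent intervals (end == next start) with enhancer states merge; any
    gap or non-enhancer state breaks the run.
    """
    unknown = set(enhancer_states) - set(CHROMATIN_STATES)
    if unknown:
        raise ValueError(
            f"unknown states {sorted(unknown)}; vocabulary: {list(CHROMATIN_STATES)}"
        )
    iv = segmentation.intervals
    enh = iv[iv["state"].isin(enhancer_states)]
    runs = []
    for chrom, grp in enh.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if len(grp) == 0:
            continue
        run_start = starts[0]
        run_end = ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s == run_end:
                run_end = e
            else:
                runs.append((chrom, run_start, run_end))
                run_start, run_end = s, e
        runs.append((chrom, run_start, run_end))
    out = pd.DataFrame(runs, columns=["chrom", "start", "end"])
    out["length"] = out["end"] - out["start"]
    return out


def classify_enhancers(
    runs: pd.DataFrame,
    stretch_min_bp: int = STRETCH_MIN_BP,
    typical_max_bp: int = TYPICAL_MAX_BP,
    stretch_quantile: float | None = None,
) -> pd.DataFrame:
    """Label runs stretch (>= 3 kb), typical (<= 800 bp) or intermediate.

    ``stretch_quantile`` overrides the absolute threshold with a length
    quantile (e.g. 0.9 calls the longest 10% stretch).
    """
    out = runs.copy()
    if stretch_quantile is not None:
        stretch_min_bp = float(np.quantile(out["length"], stretch_quantile))
    cls = np.where(
        out["length"] >= stretch_min_bp,
        "stretch",
        np.where(out["length"] <= typical_max_bp, "typical", "intermediate"),
    )
    out["class"] = cls
    return out


def _interval_overlap_bp(
    chrom: str, start: int, end: int, other: pd.DataFrame
) -> int:
    """Bases of [start, end) covered by intervals of ``other`` on ``chrom``."""
    grp = other[other["chrom"] == chrom]
    if not len(grp):
        return 0
    s = np.maximum(grp["start"].to_numpy(), start)
    e = np.minimum(grp["end"].to_numpy(), end)
    return int(np.maximum(e - s, 0).sum())


def tissue_specific_filter(
    enhancers: pd.DataFrame,
    other_segmentations: list[ChromatinSegmentation],
    max_shared_fraction: float = 0.1,
    active_states: frozenset[str] | set[str] = ACTIVE_STATES,
) -> pd.DataFrame:
    """Flag runs whose active-chromatin overlap in EVERY other tissue is small.

    A run is tissue-specific when, for each other tissue, the fraction of its
    bases overlapping active (enhancer/promoter) states is <= the threshold.
    """
    if not other_segmentations:
        raise ValueError("need at least one other tissue")
    actives = [
        seg.intervals[seg.intervals["state"].isin(active_states)]
        for seg in other_segmentations
    ]
    flags = []
    for row in enhancers.itertuples():
        length = row.end - row.start
        specific = True
        for act in actives:
            shared = _interval_overlap_bp(row.chrom, row.start, row.end, act)
            if shared / length > max_shared_fraction:
                specific = False
                break
        flags.append(specific)
    out = enhancers.copy()
    out["tissue_specific"] = flags
    return out


def ld_neighbour_count(
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
) -> np.ndarray:
    """Per-variant count of r^2 >= threshold proxies within +/- window (self excluded)."""
    var = genotypes.variants
    dos = genotypes.dosages
    n_var = len(var)
    counts = np.zeros(n_var, dtype=int)
    sd = dos.std(axis=1)
    for chrom, grp in var.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        ok = sd[idx] > 0
        sub = idx[ok]
        if sub.size == 0:
            continue
        X = dos[sub]
        Xc = (X - X.mean(axis=1, keepdims=True)) / (
            sd[sub][:, None] * np.sqrt(dos.shape[1])
        )
        r2 = (Xc @ Xc.T) ** 2
        in_window = np.abs(pos[ok][:, None] - pos[ok][None, :]) <= window_bp
        hits = (r2 >= r2_threshold) & in_window
        np.fill_diagonal(hits, False)
        counts[sub] = hits.sum(axis=1)
    return counts


_LD_BIN_EDGES = (1, 5, 20, 100)  # bins {0}, 1-4, 5-19, 20-99, >=100


def annotate_universe(
    genotypes: GenotypeMatrix,
    genes: GeneAnnotation,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
    maf_bin_width: float = 0.02,
    tss_log_bin_width: float = 0.5,
) -> pd.DataFrame:
    """Annotate every variant with the three matching-bin coordinates.

    Columns: variant_id, maf, tss_distance, ld_neighbours and the binned
    versions used for matching.
    """
    var = genotypes.variants
    maf = genotypes.maf
    # distance to nearest TSS per chromosome
    tss_by_chrom: dict[str, np.ndarray] = {}
    for row in genes.genes.itertuples():
        tss_by_chrom.setdefault(row.chrom, [])
        tss_by_chrom[row.chrom].extend(row.tss_list)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    dist = np.empty(len(var))
    for chrom, grp in var.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        tss = tss_by_chrom.get(chrom)
        if tss is None or tss.size == 0:
            dist[grp.index.to_numpy()] = np.inf
            continue
        j = np.searchsorted(tss, pos)
        left = np.abs(pos - tss[np.clip(j - 1, 0, tss.size - 1)])
        right = np.abs(tss[np.clip(j, 0, tss.size - 1)] - pos)
        dist[grp.index.to_numpy()] = np.minimum(left, right)
    ld = ld_neighbour_count(genotypes, r2_threshold, window_bp)
    out = pd.DataFrame(
        {
            "variant_id": var["id"].to_numpy(),
            "chrom": var["chrom"].to_numpy(),
            "pos": var["pos"].to_numpy(),
            "maf": maf,
            "tss_distance": dist,
            "ld_neighbours": ld,
        }
    )
    out["maf_bin"] = np.floor(out["maf"] / maf_bin_width).astype(int)
    logd = np.log10(np.maximum(out["tss_distance"], 1.0))
    out["tss_bin"] = np.floor(logd / tss_log_bin_width).astype(int)
    out["ld_bin"] = np.searchsorted(_LD_BIN_EDGES, out["ld_neighbours"], side="right")
    return out


def _overlap_flags(
    universe: pd.DataFrame, features: pd.DataFrame
) -> np.ndarray:
    """Boolean per universe variant: does its position fall in a feature?

    Features are 0-based half-open; variant positions are 1-based.
    """
    flags = np.zeros(len(universe), dtype=bool)
    feats = features.sort_values(["chrom", "start"], kind="stable")
    for chrom, grp in feats.groupby("chrom", sort=False):
        sel = universe["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        pos0 = universe.loc[sel, "pos"].to_numpy() - 1  # to 0-based
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        j = np.searchsorted(starts, pos0, side="right") - 1
        inside = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        flags[np.where(sel)[0]] = inside
    return flags


@dataclass
class EnrichmentResult:
    feature_set_id: str
    stratum: str
    n_test_snps: int
    n_observed: int
    null_mean: float
    fold: float
    empirical_p: float
    n_null_sets: int
    low_power: bool = False


def matched_null_enrichment(
    test_variant_ids,
    features: pd.DataFrame,
    universe: pd.DataFrame,
    n_null_sets: int = 1000,
    min_pool: int = 500,
    seed: int = 0,
    feature_set_id: str = "features",
    stratum: str = "all",
) -> EnrichmentResult:
    """Count-based enrichment of test SNPs in features vs matched null sets.

    Each test SNP's candidate pool shares its (maf_bin, tss_bin, ld_bin);
    pools below ``min_pool`` are widened by dropping first the LD bin, then
    the TSS bin, then falling back to the whole universe (logged via the
    result). Null sets sample one candidate per test SNP without replacement
    within a set.
    """
    rng = np.random.default_rng(seed)
    uni = universe.reset_index(drop=True)
    overlap = _overlap_flags(uni, features)
    uni_idx = pd.Index(uni["variant_id"])
    test_pos = uni_idx.get_indexer(np.asarray(test_variant_ids))
    if (test_pos < 0).any():
        raise KeyError("test SNP absent from universe annotation")

    key_full = ["maf_bin", "tss_bin", "ld_bin"]
    groups_full = uni.groupby(key_full).indices
    groups_mt = uni.groupby(["maf_bin", "tss_bin"]).indices
    groups_m = uni.groupby(["maf_bin"]).indices

    pools = []
    for ti in test_pos:
        row = uni.iloc[ti]
        key = (row["maf_bin"], row["tss_bin"], row["ld_bin"])
        pool = groups_full.get(key, np.array([], dtype=int))
        if pool.size < min_pool:
            pool = groups_mt.get((row["maf_bin"], row["tss_bin"]), pool)
        if pool.size < min_pool:
            pool = groups_m.get(row["maf_bin"], pool)
        if pool.size < min_pool:
            pool = np.arange(len(uni))
        if pool.size == 0:
            raise ValueError(f"empty matching pool for {row['variant_id']}")
        pools.append(np.asarray(pool))

    observed = int(overlap[test_pos].sum())
    null_counts = np.empty(n_null_sets, dtype=int)
    for s in range(n_null_sets):
        used: set[int] = set()
        count = 0
        for pool in pools:
            for _ in range(10):
                cand = int(pool[rng.integers(0, pool.size)])
                if cand not in used:
                    break
            used.add(cand)
            count += int(overlap[cand])
        null_counts[s] = count
    null_mean = float(null_counts.mean())
    fold = observed / null_mean if null_mean > 0 else np.inf if observed else 0.0
    emp_p = float((1 + (null_counts >= observed).sum()) / (n_null_sets + 1))
    return EnrichmentResult(
        feature_set_id=feature_set_id,
        stratum=stratum,
        n_test_snps=len(test_pos),
        n_observed=observed,
        null_mean=null_mean,
        fold=fold,
        empirical_p=emp_p,
        n_null_sets=n_null_sets,
    )


def stratified_enrichment(
    best_eqtls: pd.DataFrame,
    deciles: pd.Series,
    feature_sets: dict[str, pd.DataFrame],
    universe: pd.DataFrame,
    n_null_sets: int = 1000,
    min_pool: int = 500,
    seed: int = 0,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Matched-null enrichment per (specificity decile x feature class).

    ``best_eqtls`` must hold one SNP per gene (best_per_gene output);
    ``feature_sets`` maps class name (e.g. stretch/typical) to interval
    frames. Deciles with fewer than ``min_snps`` SNPs carry a low-power flag.
    """
    rows = []
    dec = deciles.reindex(best_eqtls["gene_id"]).to_numpy()
    for d in range(1, 11):
        sel = best_eqtls.loc[dec == d, "variant_id"].to_numpy()
        for fsid, feats in feature_sets.items():
            if len(sel) == 0:
                rows.append(
                    EnrichmentResult(fsid, f"decile_{d}", 0, 0, np.nan, np.nan, 1.0, 0, True)
                )
                continue
            res = matched_null_enrichment(
                sel,
                feats,
                universe,
                n_null_sets=n_null_sets,
                min_pool=min_pool,
                seed=seed + d,
                feature_set_id=fsid,
                stratum=f"decile_{d}",
            )
            res.low_power = len(sel) < min_snps
            rows.append(res)
    return pd.DataFrame([r.__dict__ for r in rows])
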