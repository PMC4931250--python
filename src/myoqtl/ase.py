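"""Allele-specific expression: filtering, expectation, exact tests, combination.

The workflow mirrors standard allelic-imbalance practice on RNA-seq read
counts at heterozygous transcribed SNPs:

1. ``apply_filters`` removes sites susceptible to mapping artifacts: a
   read-mapping simulation coverage outside the accepted band [193, 202]
   (for 101-bp paired-end reads), blacklisted regions, proximity to indels,
   and sites without both alleles represented (0.01 < fracRef < 0.99).
2. Forward/reverse strand rows are merged before any statistics.
3. ``expected_fracref`` estimates, per sample and ordered allele pair
   (A>G distinct from G>A), the null reference-read fraction: the pooled
   ref/total ratio over the group's SNPs, where SNPs above the sample's 75th
   coverage percentile are first down-sampled to 30x (seeded hypergeometric
   thinning, which preserves the expectation) so single high-coverage sites
   cannot dominate.
4. ``binomial_ase_test`` is an exact two-sided binomial test of each site's
   ref count against the group expectation (minimum-likelihood two-sidedness
   by default, central 2*min-tail optional).
5. Per-variant evidence is combined across samples with Fisher's method when
   a variant is testable in >= 10 samples; significance is judged by Storey
   q-values at q <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, storey_qvalues

__all__ = [
    "apply_filters",
    "merge_strands",
    "expected_fracref",
    "binomial_ase_test",
    "fisher_combine",
    "combine_across_samples",
    "ase_qvalues",
    "run_ase",
]

SIM_COVERAGE_BAND = (193, 202)
FRACREF_BOUNDS = (0.01, 0.99)


def apply_filters(
    counts: pd.DataFrame,
    mask: pd.DataFrame,
    sim_coverage_band: tuple[int, int] = SIM_COVERAGE_BAND,
    fracref_bounds: tuple[float, float] = FRACREF_BOUNDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter allelic count rows; returns (retained rows, removal log).

    Every variant in ``counts`` must appear in ``mask`` (columns variant_id,
    simulated_coverage, blacklisted, near_indel); silent pass-through of
    unmasked variants is forbidden.
    """
    mask_idx = mask.set_index("variant_id")
    missing = set(counts["variant_id"]) - set(mask_idx.index)
    if missing:
        raise ValueError(
            f"{len(missing)} variants missing from mappability mask, "
            f"e.g. {sorted(missing)[:3]}"
        )
    m = mask_idx.reindex(counts["variant_id"])
    total = counts["ref_count"].to_numpy() + counts["alt_count"].to_numpy()
    with np.errstate(invalid="ignore"):
        fracref = np.where(total > 0, counts["ref_count"].to_numpy() / total, np.nan)
    lo, hi = sim_coverage_band
    flo, fhi = fracref_bounds
    reasons = np.full(len(counts), "", dtype=object)
    sim = m["simulated_coverage"].to_numpy()
    bad_sim = (sim < lo) | (sim > hi)
    reasons[bad_sim] = "simulated_coverage outside band"
    bl = m["blacklisted"].to_numpy(dtype=bool) & (reasons == "")
    reasons[bl] = "blacklisted region"
    ni = m["near_indel"].to_numpy(dtype=bool) & (reasons == "")
    reasons[ni] = "near indel"
    zero = (total == 0) & (reasons == "")
    reasons[zero] = "zero total count"
    with np.errstate(invalid="ignore"):
        bad_frac = (
            ((fracref <= flo) | (fracref >= fhi)) & (total > 0) & (reasons == "")
        )
    reasons[bad_frac] = "fracRef outside bounds"
    removed = counts[reasons != ""].copy()
    removed["reason"] = reasons[reasons != ""]
    retained = counts[reasons == ""].reset_index(drop=True)
    return retained, removed.reset_index(drop=True)


def merge_strands(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum forward/reverse strand rows per (sample, variant)."""
    keys = ["sample_id", "variant_id", "chrom", "pos", "ref", "alt"]
    merged = (
        counts.groupby(keys, sort=False, as_index=False)[["ref_count", "alt_count"]]
        .sum()
    )
    merged["allele_pair"] = merged["ref"] + ">" + merged["alt"]
    return merged


def _thin_hypergeom(
    ref: int, alt: int, target_total: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw ``target_total`` reads without replacement from the ref/alt pool."""
    total = ref + alt
    if total <= target_total:
        return ref, alt
    new_ref = int(rng.hypergeometric(ref, alt, target_total))
    return new_ref, target_total - new_ref


def expected_fracref(
    merged: pd.DataFrame,
    downsample_cov: int = 30,
    pct: float = 75.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (sample, allele_pair) expected fracRef with coverage down-sampling.

    Within each sample, SNPs with total coverage strictly above the sample's
    ``pct`` coverage percentile are thinned to ``downsample_cov`` reads by a
    seeded hypergeometric draw; the group expectation is the pooled thinned
    ref count over the pooled thinned total.
    """
    rng = np.random.default_rng(seed)
    df = merged.copy()
    df["total"] = df["ref_count"] + df["alt_count"]
    out_rows = []
    for sample, sgrp in df.groupby("sample_id", sort=True):
        cutoff = np.percentile(sgrp["total"].to_numpy(), pct)
        for pair, grp in sgrp.groupby("allele_pair", sort=True):
            sum_ref = 0
            sum_tot = 0
            for row in grp.itertuples():
                r, a = row.ref_count, row.alt_count
                if row.total > cutoff:
                    r, a = _thin_hypergeom(r, a, downsample_cov, rng)
                sum_ref += r
                sum_tot += r + a
            if sum_tot > 0:
                out_rows.append(
                    {
                        "sample_id": sample,
                        "allele_pair": pair,
                        "expected_fracref": sum_ref / sum_tot,
                        "n_snps": len(grp),
                    }
                )
    return pd.DataFrame(
        out_rows, columns=["sample_id", "allele_pair", "expected_fracref", "n_snps"]
    )


def binomial_ase_test(
    ref_count: int,
    total: int,
    expected: float,
    method: str = "minlike",
) -> float:
    """Exact two-sided binomial p-value of ref_count successes in total trials.

    ``minlike``: sum of P(X=k) over all k whose probability does not exceed
    the observed outcome's (the minimum-likelihood two-sided test).
    ``central``: twice the smaller tail, capped at 1.
    """
    if not (0 < expected < 1):
        raise ValueError("expected fracRef must lie strictly inside (0, 1)")
    if total < 1:
        raise ValueError("total must be >= 1")
    if method == "minlike":
        k = np.arange(total + 1)
        pmf = sps.binom.pmf(k, total, expected)
        p_obs = pmf[ref_count]
        # small relative tolerance guards against float noise on equal masses
        p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
        return float(min(p, 1.0))
    if method == "central":
        lower = sps.binom.cdf(ref_count, total, expected)
        upper = sps.binom.sf(ref_count - 1, total, expected)
        return float(min(1.0, 2 * min(lower, upper)))
    raise ValueError(f"unknown two-sided method: {method!r}")


def fisher_combine(p_values) -> float:
    """Fisher's combined probability: chi-square upper tail of -2 sum(ln p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x, df=2 * p.size))


def per_sample_tests(
    merged: pd.DataFrame,
    expectations: pd.DataFrame,
    method: str = "minlike",
) -> pd.DataFrame:
    """Exact test per (sample, variant) against its group expectation.

    Groups whose expectation is degenerate (0 or 1) are skipped.
    """
    exp = expectations.set_index(["sample_id", "allele_pair"])["expected_fracref"]
    rows = []
    for row in merged.itertuples():
        key = (row.sample_id, row.allele_pair)
        if key not in exp.index:
            continue
        e = exp.loc[key]
        if not (0 < e < 1):
            continue
        total = row.ref_count + row.alt_count
        p = binomial_ase_test(row.ref_count, total, e, method=method)
        rows.append(
            {
                "sample_id": row.sample_id,
                "variant_id": row.variant_id,
                "allele_pair": row.allele_pair,
                "ref_count": row.ref_count,
                "total": total,
                "expected_fracref": e,
                "binomial_p": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "variant_id",
            "allele_pair",
            "ref_count",
            "total",
            "expected_fracref",
            "binomial_p",
        ],
    )


def combine_across_samples(
    per_sample: pd.DataFrame, min_samples: int = 10
) -> pd.DataFrame:
    """Fisher-combine per-sample p-values per variant (>= min_samples only)."""
    rows = []
    for vid, grp in per_sample.groupby("variant_id", sort=True):
        n = len(grp)
        if n < min_samples:
            continue
        rows.append(
            {
                "variant_id": vid,
                "combined_p": fisher_combine(grp["binomial_p"].to_numpy()),
                "n_samples_tested": n,
                "mean_fracref": (grp["ref_count"] / grp["total"]).mean(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "combined_p", "n_samples_tested", "mean_fracref"],
    )


def ase_qvalues(pvalues: np.ndarray, min_m_for_storey: int = 100) -> np.ndarray:
    """Storey q-values (BH fallback for small collections)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < min_m_for_storey:
        return bh_fdr(p)
    return storey_qvalues(p)


def run_ase(
    counts: pd.DataFrame,
    mask: pd.DataFrame,
    min_samples: int = 10,
    downsample_cov: int = 30,
    pct: float = 75.0,
    method: str = "minlike",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full ASE pipeline; returns (per-sample table with q, per-variant table with q)."""
    retained, _ = apply_filters(counts, mask)
    merged = merge_strands(retained)
    # merged rows can violate the fracRef bounds even when strand rows passed
    total = merged["ref_count"] + merged["alt_count"]
    frac = merged["ref_count"] / total
    merged = merged[
        (total > 0) & (frac > FRACREF_BOUNDS[0]) & (frac < FRACREF_BOUNDS[1])
    ].reset_index(drop=True)
    expectations = expected_fracref(
        merged, downsample_cov=downsample_cov, pct=pct, seed=seed
    )
    per_sample = per_sample_tests(merged, expectations, method=method)
    if len(per_sample):
        per_sample = per_sample.copy()
        per_sample["q"] = ase_qvalues(per_sample["binomial_p"].to_numpy())
    combined = combine_across_samples(per_sample, min_samples=min_samples)
    if len(combined):
        combined["q"] = ase_qvalues(combined["combined_p"].to_numpy())
    return per_sample, combined
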