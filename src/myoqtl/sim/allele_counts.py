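"""Allelic read-count simulation with planted imbalance and mapping-bias SNPs.

A subset of variants acts as transcribed heterozygous sites. For every
heterozygous sample x site cell, total coverage is negative-binomial
(mean ``coverage_mean``, dispersion ``coverage_dispersion``) and the
reference-allele count is binomial at the site's true fracRef. Null sites
inherit a small ordered-allele-pair baseline (emulating systematic
reference-mapping preference by allele pair); planted sites use a configured
imbalance value. Counts are emitted split across forward/reverse strand rows.

Mapping-bias SNPs are planted with a distorted fracRef and a simulated
read-mapping coverage value outside the accepted band, so the coverage filter
must remove them; clean sites receive values inside the band. The mask table
also carries a few planted blacklist / near-indel flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import GenotypeMatrix
from .config import SimConfig

SIM_COVERAGE_BAND = (193, 202)


def simulate_allele_counts(
    genotypes: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample allelic counts at heterozygous transcribed sites.

    Returns ``(counts, mask, ase_truth, bias_snp_truth)``:
    counts has one row per (sample, site, strand) with ref/alt read counts;
    mask has one row per site with simulated_coverage, blacklisted and
    near_indel flags.
    """
    if config.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    var = genotypes.variants
    n_sites = max(1, int(round(config.frac_ase_sites * genotypes.n_variants)))
    site_idx = np.sort(rng.choice(genotypes.n_variants, size=n_sites, replace=False))

    # ordered allele-pair baselines near 0.5 (systematic mapping preference)
    pairs = sorted(
        {f"{r}>{a}" for r, a in zip(var["ref"], var["alt"])}
    )
    pair_base = {p: rng.uniform(0.47, 0.53) for p in pairs}

    n_ase = int(round(config.frac_ase_effects * n_sites))
    n_bias = int(round(config.frac_bias_snps * n_sites))
    special = rng.choice(n_sites, size=n_ase + n_bias, replace=False)
    ase_pos, bias_pos = special[:n_ase], special[n_ase:]

    true_fracref = np.empty(n_sites)
    for j in range(n_sites):
        vid = site_idx[j]
        pair = f"{var['ref'].iloc[vid]}>{var['alt'].iloc[vid]}"
        true_fracref[j] = pair_base[pair]
    effect_grid = np.asarray(config.ase_effect_fracrefs)
    true_fracref[ase_pos] = effect_grid[np.arange(n_ase) % effect_grid.size]
    # mapping-bias SNPs look strongly imbalanced but must be filtered out
    true_fracref[bias_pos] = np.where(rng.random(n_bias) < 0.5, 0.9, 0.1)

    lo, hi = SIM_COVERAGE_BAND
    sim_cov = rng.integers(lo, hi + 1, size=n_sites)
    bias_low = rng.integers(120, lo, size=n_bias)
    bias_high = rng.integers(hi + 1, 280, size=n_bias)
    sim_cov[bias_pos] = np.where(rng.random(n_bias) < 0.5, bias_low, bias_high)

    blacklisted = np.zeros(n_sites, dtype=bool)
    near_indel = np.zeros(n_sites, dtype=bool)
    n_flag = max(1, n_sites // 50)
    blacklisted[rng.choice(n_sites, size=n_flag, replace=False)] = True
    near_indel[rng.choice(n_sites, size=n_flag, replace=False)] = True

    # negative binomial via gamma-Poisson: mean m, dispersion a -> var m + a m^2
    a = config.coverage_dispersion
    m = config.coverage_mean
    sample_ids = np.array(genotypes.sample_ids)
    parts = []
    for j, vid in enumerate(site_idx):
        het = np.where(np.rint(genotypes.dosages[vid]) == 1)[0]
        if het.size == 0:
            continue
        lam = rng.gamma(shape=1.0 / a, scale=m * a, size=het.size)
        totals = rng.poisson(lam)
        keep = totals > 0
        het, totals = het[keep], totals[keep]
        if het.size == 0:
            continue
        refs = rng.binomial(totals, true_fracref[j])
        ref_fwd = rng.binomial(refs, 0.5)
        alt_fwd = rng.binomial(totals - refs, 0.5)
        k = het.size
        parts.append(
            pd.DataFrame(
                {
                    "sample_id": np.tile(sample_ids[het], 2),
                    "chrom": var["chrom"].iloc[vid],
                    "pos": int(var["pos"].iloc[vid]),
                    "ref": var["ref"].iloc[vid],
                    "alt": var["alt"].iloc[vid],
                    "variant_id": var["id"].iloc[vid],
                    "strand": np.repeat(["+", "-"], k),
                    "ref_count": np.concatenate([ref_fwd, refs - ref_fwd]),
                    "alt_count": np.concatenate(
                        [alt_fwd, totals - refs - alt_fwd]
                    ),
                }
            )
        )
    cols = [
        "sample_id",
        "chrom",
        "pos",
        "ref",
        "alt",
        "variant_id",
        "strand",
        "ref_count",
        "alt_count",
    ]
    counts = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=cols)
    )
    mask = pd.DataFrame(
        {
            "variant_id": var["id"].to_numpy()[site_idx],
            "simulated_coverage": sim_cov,
            "blacklisted": blacklisted,
            "near_indel": near_indel,
        }
    )
    ase_truth = pd.DataFrame(
        {
            "variant_id": var["id"].to_numpy()[site_idx[ase_pos]],
            "true_fracref": true_fracref[ase_pos],
        }
    )
    bias_snp_truth = pd.DataFrame(
        {"variant_id": var["id"].to_numpy()[site_idx[bias_pos]]}
    )
    return counts, mask, ase_truth, bias_snp_truth
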