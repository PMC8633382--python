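"""Genome-scan driver and post-GWAS summaries.

``run_scan`` streams variant blocks through QC, genotype centering, grouped
GLS and the sequential Wald stages, producing one row per variant (or a skip
record). Significant SNPs are then merged into non-overlapping genomic
regions (single-linkage on base-pair distance below a gap threshold, 1 Mbp by
default) and summarised as pairwise trait-sharing tables.

Trait attribution per SNP uses marginal single-trait p-values; that rule is a
reporting convention of this package, labelled as such in output headers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plink_io, preprocess
from .gls_engine import (
    SnpSkipped,
    accumulate_group_stats,
    center_genotype,
    gls_fit,
    precompute_group_weights,
)
from .preprocess import AdjustedPhenotypeMatrix, PatternGroup
from .sequential import declared_order, sequential_pvalues

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    maf_min: float = 0.001
    call_rate_min: float = 0.95
    min_group_size: int = 1
    early_stop_p: float = 1.0
    max_stage: int | None = None
    chunk_size: int = 10_000
    transforms: dict[str, str] | None = None
    alpha: float = 1e-8  # genome-wide significance, strict inequality
    gap_bp: int = 1_000_000


@dataclass
class PleiotropyRegion:
    """Merged interval of significant SNPs (1-based closed bp coordinates)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    lead_snp: str
    min_p: float
    stage: int
    trait_mask: np.ndarray


def scan_block(
    dosage: np.ndarray,
    variants: list[plink_io.VariantRecord],
    adjusted: AdjustedPhenotypeMatrix,
    groups: list[PatternGroup],
    weights,
    analyzed_idx: np.ndarray,
    config: ScanConfig,
) -> tuple[list[dict], list[dict]]:
    """Test one decoded block (variants x samples); returns result rows and
    skip records."""
    p = adjusted.n_traits
    max_stage = config.max_stage or p
    freq, call_rate = preprocess.variant_qc(dosage[:, analyzed_idx])
    keep = preprocess.filter_variants(freq, call_rate, config.maf_min, config.call_rate_min)
    rows, skips = [], []
    for i, variant in enumerate(variants):
        if not keep[i]:
            skips.append(
                {
                    "id": variant.id,
                    "reason": f"filtered (freq={freq[i]:.4g}, call_rate={call_rate[i]:.4g})",
                }
            )
            continue
        try:
            x, n_imputed = center_genotype(dosage[i], analyzed_idx)
            stats = accumulate_group_stats(x, adjusted, groups)
            est = gls_fit(stats, weights=weights)
            res = sequential_pvalues(
                est.beta_hat, est.cov_beta, max_stage=max_stage, early_stop_p=config.early_stop_p
            )
        except SnpSkipped as exc:
            skips.append({"id": variant.id, "reason": exc.reason})
            continue
        row = {
            "id": variant.id,
            "chrom": variant.chrom,
            "bp": variant.bp,
            "n_used": est.n_used,
            "n_geno_imputed": n_imputed,
        }
        se = np.sqrt(np.diag(est.cov_beta))
        for j, name in enumerate(adjusted.trait_names):
            row[f"beta_{name}"] = est.beta_hat[j]
            row[f"se_{name}"] = se[j]
        for s in range(1, max_stage + 1):
            row[f"p_stage{s}"] = res.stage_p[s - 1]
            row[f"neglog10_stage{s}"] = res.stage_neglog10[s - 1]
        for j, name in enumerate(adjusted.trait_names):
            row[f"p_marginal_{name}"] = res.marginal_p[j]
        rows.append(row)
    return rows, skips


def run_scan(
    bed_path,
    bim_path,
    fam_path,
    pheno_path,
    covar_path=None,
    config: ScanConfig | None = None,
    out_prefix: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Whole-file scan: read inputs, adjust phenotypes, estimate S once,
    then stream variant chunks. Returns (results, skips, run_log)."""
    config = config or ScanConfig()
    variants = plink_io.read_bim(bim_path)
    samples = plink_io.read_fam(fam_path)
    bed = plink_io.BedFile(bed_path, n_samples=len(samples), n_variants=len(variants))

    pheno = plink_io.read_table(pheno_path, samples)
    covar = plink_io.read_table(covar_path, samples) if covar_path else None
    adjusted = preprocess.adjust_phenotypes(pheno, covar, transforms=config.transforms)
    groups, n_dropped = preprocess.find_missing_patterns(
        adjusted.observed, min_group_size=config.min_group_size
    )
    errcov = preprocess.estimate_error_covariance(adjusted)
    weights = precompute_group_weights(errcov.S, groups)
    analyzed_idx = np.sort(np.concatenate([g.member_indices for g in groups]))

    all_rows, all_skips = [], []
    for start in range(0, len(variants), config.chunk_size):
        stop = min(start + config.chunk_size, len(variants))
        block = bed.read_block(range(start, stop))
        rows, skips = scan_block(
            block.dosage, variants[start:stop], adjusted, groups, weights, analyzed_idx, config
        )
        all_rows.extend(rows)
        all_skips.extend(skips)

    results = pd.DataFrame(all_rows)
    skips = pd.DataFrame(all_skips, columns=["id", "reason"])
    run_log = {
        "n_samples": len(samples),
        "n_samples_analyzed": int(analyzed_idx.size),
        "n_samples_dropped_small_groups": int(n_dropped),
        "n_variants": len(variants),
        "n_tested": int(len(results)),
        "n_skipped": int(len(skips)),
        "n_pattern_groups": len(groups),
        "covariance_repaired": errcov.repaired,
        "config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in vars(config).items()
        },
        "trait_names": adjusted.trait_names,
    }
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        results.to_csv(f"{out_prefix}.results.tsv", sep="\t", index=False)
        skips.to_csv(f"{out_prefix}.skipped.tsv", sep="\t", index=False)
        with open(f"{out_prefix}.runlog.json", "w") as fh:
            json.dump(run_log, fh, indent=2, default=str)
    return results, skips, run_log


def add_declared_order(results: pd.DataFrame, alpha: float = 1e-8) -> pd.DataFrame:
    """Append the declared pleiotropy order (largest s with all stage-1..s
    p-values below alpha, strict) to a scan results table."""
    stage_cols = sorted(
        (c for c in results.columns if c.startswith("p_stage")),
        key=lambda c: int(c.removeprefix("p_stage")),
    )
    orders = [
        declared_order([row[c] if pd.notna(row[c]) else None for c in stage_cols], alpha)
        for _, row in results.iterrows()
    ]
    out = results.copy()
    out["declared_order"] = orders
    return out


def attribute_traits(
    marginal_p: np.ndarray, order: int, trait_alpha: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Flag traits with marginal p below trait_alpha; if fewer than the
    declared order are flagged, flag the ``order`` smallest marginal p-values
    instead and mark the attribution as forced."""
    marginal_p = np.asarray(marginal_p, dtype=np.float64)
    mask = marginal_p < trait_alpha
    forced = False
    if mask.sum() < order:
        mask = np.zeros_like(mask)
        mask[np.argsort(marginal_p, kind="stable")[:order]] = True
        forced = True
    return mask, forced


def group_regions(
    snps: pd.DataFrame,
    gap_bp: int = 1_000_000,
    orders: np.ndarray | None = None,
    trait_masks: np.ndarray | None = None,
) -> list[PleiotropyRegion]:
    """Merge significant SNPs into non-overlapping regions per chromosome.

    SNPs whose base-pair distance to the nearest member of a growing region
    is smaller than ``gap_bp`` join it (transitive, single-linkage), so two
    regions are always separated by at least ``gap_bp``. ``snps`` needs
    columns chrom, bp, id, p; ``orders``/``trait_masks`` are optional arrays
    aligned to its rows.
    """
    n = len(snps)
    if orders is None:
        orders = np.ones(n, dtype=int)
    if trait_masks is None:
        trait_masks = np.zeros((n, 0), dtype=bool)
    orders = np.asarray(orders)
    trait_masks = np.asarray(trait_masks, dtype=bool)

    regions: list[PleiotropyRegion] = []
    df = snps.reset_index(drop=True)
    df["_row"] = np.arange(n)
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["bp", "id"], kind="stable")
        bps = sub["bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(bps) >= gap_bp)
        bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = sub.iloc[a:b]
            rows = members["_row"].to_numpy()
            pvals = members["p"].to_numpy(dtype=np.float64)
            best = np.lexsort((members["bp"].to_numpy(), pvals))[0]
            mask = (
                trait_masks[rows].any(axis=0)
                if trait_masks.size
                else np.zeros(0, dtype=bool)
            )
            regions.append(
                PleiotropyRegion(
                    chrom=str(chrom),
                    start_bp=int(members["bp"].min()),
                    end_bp=int(members["bp"].max()),
                    n_snps=len(members),
                    lead_snp=str(members.iloc[best]["id"]),
                    min_p=float(pvals.min()),
                    stage=int(orders[rows].max()),
                    trait_mask=mask,
                )
            )
    return regions


def pairwise_region_table(regions: list[PleiotropyRegion]) -> dict[str, np.ndarray]:
    """Counts of regions and member SNPs shared per trait pair: cell (j, k) is
    the number of regions (SNPs) whose trait mask contains both j and k.
    Symmetric with an empty diagonal; per-trait totals count each region once."""
    if not regions:
        return {
            "regions": np.zeros((0, 0), dtype=int),
            "snps": np.zeros((0, 0), dtype=int),
            "trait_total_regions": np.zeros(0, dtype=int),
            "trait_total_snps": np.zeros(0, dtype=int),
        }
    p = len(regions[0].trait_mask)
    reg = np.zeros((p, p), dtype=int)
    snp = np.zeros((p, p), dtype=int)
    tot_r = np.zeros(p, dtype=int)
    tot_s = np.zeros(p, dtype=int)
    for r in regions:
        idx = np.flatnonzero(r.trait_mask)
        for a in idx:
            if len(idx) > 1:
                tot_r[a] += 1
                tot_s[a] += r.n_snps
            for b in idx:
                if a < b:
                    reg[a, b] += 1
                    reg[b, a] += 1
                    snp[a, b] += r.n_snps
                    snp[b, a] += r.n_snps
    return {
        "regions": reg,
        "snps": snp,
        "trait_total_regions": tot_r,
        "trait_total_snps": tot_s,
    }


def summarize_regions(
    results: pd.DataFrame,
    trait_names: list[str],
    alpha: float = 1e-8,
    gap_bp: int = 1_000_000,
    min_order: int = 2,
    trait_alpha: float | None = None,
) -> tuple[list[PleiotropyRegion], pd.DataFrame]:
    """End-to-end: declared orders -> significant SNPs of at least
    ``min_order`` -> trait attribution -> merged regions + region table."""
    trait_alpha = alpha if trait_alpha is None else trait_alpha
    annotated = add_declared_order(results, alpha)
    sig = annotated[annotated["declared_order"] >= min_order].reset_index(drop=True)
    if sig.empty:
        return [], pd.DataFrame()
    masks = np.zeros((len(sig), len(trait_names)), dtype=bool)
    for i, (_, row) in enumerate(sig.iterrows()):
        marg = np.array([row[f"p_marginal_{t}"] for t in trait_names])
        masks[i], _ = attribute_traits(marg, int(row["declared_order"]), trait_alpha)
    stage_col = f"p_stage{min_order}"
    snps = sig[["chrom", "bp", "id"]].copy()
    snps["p"] = sig[stage_col].astype(float)
    regions = group_regions(
        snps, gap_bp=gap_bp, orders=sig["declared_order"].to_numpy(), trait_masks=masks
    )
    table = pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_snps": r.n_snps,
                "lead_snp": r.lead_snp,
                "min_p": r.min_p,
                "order": r.stage,
                # marginal-p attribution; package convention, not a test output
                "traits": ",".join(
                    t for t, m in zip(trait_names, r.trait_mask) if m
                ),
            }
            for r in regions
        ]
    )
    return regions, table
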