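"""Genome-wide POE scan: QC, per-variant testing, and multiplicity rules.

Each variant passing QC gets the covariance-equality test on the adjusted
traits; variants reaching the Bonferroni genome-wide threshold optionally
get the post hoc AA-vs-BB interaction test, whose own Bonferroni screen
(alpha over the number of significant variants) separates POE-consistent
hits from interaction-suspect ones.  Per-variant computations are pure, so
block-parallel execution reproduces the serial result exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .io import VariantRecord
from .preprocess import QCThresholds, variant_qc
from .stat_core import MISSING, TestStatus, poirot_test, posthoc_interaction_test
from .univariate import univariate_poe_test

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "genome_scan", "bonferroni_threshold", "posthoc_screen",
           "qq_table", "manhattan_table"]

#: Fixed column order of the scan result table.
SCAN_COLUMNS = [
    "id", "chrom", "pos", "ref", "alt", "maf", "hwe_pvalue", "missing_rate",
    "n_AA", "n_AB", "n_BB", "t2", "df1", "df2", "pvalue", "status",
]


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of a genome scan (QC thresholds, level, post hoc, parallelism)."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    alpha: float = 0.05
    posthoc: bool = False
    univariate: bool = False
    n_blocks: int = 1
    min_group: int | None = None


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _scan_one(variant: VariantRecord, Y: np.ndarray, config: ScanConfig) -> dict:
    g = variant.genotypes
    qc = variant_qc(g, config.qc)
    row = {
        "id": variant.id, "chrom": variant.chrom, "pos": variant.pos,
        "ref": variant.ref, "alt": variant.alt,
        "maf": qc.maf, "hwe_pvalue": qc.hwe_pvalue, "missing_rate": qc.missing_rate,
        "qc_pass": qc.passed,
        "n_AA": int((g == 0).sum()), "n_AB": int((g == 1).sum()),
        "n_BB": int((g == 2).sum()),
    }
    if not qc.passed:
        return row
    res = poirot_test(Y, g, min_group=config.min_group)
    row.update(t2=res.t2, df1=res.df1, df2=res.df2, pvalue=res.pvalue,
               status=res.status.value)
    if config.univariate and res.status == TestStatus.OK:
        keep = g != MISSING
        uni = univariate_poe_test(Y[keep], g[keep])
        for k, p in enumerate(uni.pvalues):
            row[f"uni_pvalue_{k}"] = p
        row["uni_min_pvalue"] = uni.min_pvalue
        row["K_eff"] = uni.K_eff
    return row


def _scan_block(variants, idx, Y, config) -> list[dict]:
    return [_scan_one(variants[i], Y, config) for i in idx]


def genome_scan(variants, Y_adjusted, config: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Run the POE scan over an iterable of variants.

    Returns one row per variant passing QC, ordered by (chrom, pos);
    failures inside the test surface as ``status`` flags, never silent
    drops.  When ``config.posthoc`` is set, variants significant at the
    Bonferroni threshold (``config.alpha`` over the number of tested
    variants) additionally carry the post hoc interaction p-value.
    """
    Y = np.asarray(Y_adjusted, dtype=float)
    variants = list(variants)
    for v in variants:
        if len(v.genotypes) != Y.shape[0]:
            raise ValueError(
                f"variant {v.id}: {len(v.genotypes)} genotypes but {Y.shape[0]} phenotype rows; "
                "join samples explicitly before scanning"
            )
    if config.n_blocks > 1:
        blocks = np.array_split(np.arange(len(variants)), config.n_blocks)
        results = Parallel(n_jobs=min(config.n_blocks, 4), prefer="threads")(
            delayed(_scan_block)(variants, b, Y, config) for b in blocks
        )
        rows = [r for block in results for r in block]
    else:
        rows = [_scan_one(v, Y, config) for v in variants]

    n_failed = sum(1 for r in rows if not r["qc_pass"])
    if n_failed:
        logger.info("%d of %d variants failed QC", n_failed, len(rows))
    rows = [r for r in rows if r["qc_pass"]]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.drop(columns=["qc_pass"])
    df["pos"] = df["pos"].astype(int)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    if config.posthoc and len(df):
        cutoff = bonferroni_threshold(len(df), config.alpha)
        df["posthoc_pvalue"] = np.nan
        sig = df.index[(df["status"] == "ok") & (df["pvalue"] < cutoff)]
        by_id = {v.id: v for v in variants}
        for i in sig:
            res = posthoc_interaction_test(
                Y, by_id[df.at[i, "id"]].genotypes, min_group=config.min_group
            )
            if res.status == TestStatus.OK:
                df.at[i, "posthoc_pvalue"] = res.pvalue
    return df


def posthoc_screen(scan: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label genome-wide-significant variants by the post hoc test.

    Among the m variants significant at ``alpha / n_variants``, a variant
    is "POE-consistent" when its post hoc p-value exceeds alpha/m (the two
    homozygote groups look alike) and "interaction-suspect" otherwise.
    """
    df = scan.copy()
    if "posthoc_pvalue" not in df.columns:
        df["posthoc_pvalue"] = np.nan
    cutoff = bonferroni_threshold(len(df), alpha)
    sig = (df["status"] == "ok") & (df["pvalue"] < cutoff)
    m = int(sig.sum())
    df["significant"] = sig
    df["posthoc_label"] = ""
    if m:
        per_variant = alpha / m
        post = df.loc[sig, "posthoc_pvalue"]
        df.loc[sig, "posthoc_label"] = np.where(
            post > per_variant, "POE-consistent", "interaction-suspect"
        )
        df.loc[sig & post.reindex(df.index).isna(), "posthoc_label"] = "no-posthoc"
    return df


def qq_table(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p, ready for a QQ plot."""
    p = np.sort(np.asarray(pvalues, float))
    p = p[np.isfinite(p)]
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(np.clip(p, 1e-300, None)),
    })


def manhattan_table(scan: pd.DataFrame) -> pd.DataFrame:
    """Chromosome/position/-log10 p columns for a Manhattan plot."""
    ok = scan[scan["status"] == "ok"]
    return pd.DataFrame({
        "chrom": ok["chrom"], "pos": ok["pos"],
        "neglog10_pvalue": -np.log10(np.clip(ok["pvalue"], 1e-300, None)),
    })
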