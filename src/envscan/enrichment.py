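"""Genic/non-synonymous SNP enrichment across Q^2 bins, with moving block
bootstrap (MBB) confidence intervals.

The Q^2 axis is cut into fixed-width bins (default 0.125, starting at 0;
negative Q^2 pools into the lowest bin); bins holding fewer than 100 SNPs
are merged into the immediately lower bin. Within bin b the enrichment of a
SNP class is

    e_b = (n_class,b / n_b) / (n_class / n),

so the SNP-count-weighted mean of e_b over bins is exactly 1. Confidence
intervals come from resampling blocks of contiguous SNPs (circular moving
block bootstrap, per chromosome), which respects linkage disequilibrium
among neighbouring loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.125
MIN_BIN_SNPS = 100
DEFAULT_BLOCK_SIZE = 40
DEFAULT_N_BOOTSTRAP = 1000
DEFAULT_CI_LEVEL = 0.90


@dataclass
class EnrichmentCurve:
    """Per-bin enrichment of one SNP class with bootstrap bands."""

    target_class: str
    bin_edges: np.ndarray          # merged edges, length n_bins + 1
    n_snps: np.ndarray             # SNPs per merged bin
    enrichment: np.ndarray
    boot_median: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    ci_level: float = DEFAULT_CI_LEVEL
    block_size: int = 0
    n_bootstrap: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "class": self.target_class,
            "n": self.n_snps,
            "enrichment": self.enrichment,
        })
        if self.boot_median is not None:
            df["boot_median"] = self.boot_median
            df["ci_lo"] = self.ci_low
            df["ci_hi"] = self.ci_high
        return df


def make_bins(q2: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH,
              min_snps: int = MIN_BIN_SNPS) -> np.ndarray:
    """Merged bin edges for a Q^2 vector.

    Fixed-width bins from 0 up (negatives pool into the lowest bin, whose
    lower edge is -inf); working from the top down, any bin with fewer than
    ``min_snps`` SNPs is merged into the bin below it.
    """
    q2 = np.asarray(q2, float)
    top = max(float(q2.max()), bin_width)
    n_bins = int(math.ceil(top / bin_width + 1e-9))
    edges = np.concatenate([[-np.inf], np.arange(1, n_bins + 1) * bin_width])
    edges[-1] = max(edges[-1], top + 1e-12)
    counts, _ = np.histogram(q2, edges)
    # merge sparse bins downward; the lowest bin absorbs everything left
    keep = [0]
    acc = 0
    for b in range(n_bins - 1, 0, -1):
        acc += counts[b]
        if acc >= min_snps:
            keep.append(b)
            acc = 0
    keep = np.array(sorted(set(keep)))
    merged = np.append(edges[keep], edges[-1])
    # if the lowest merged bin is still sparse, fold it into the next one
    c, _ = np.histogram(q2, merged)
    while len(merged) > 2 and c[0] < min_snps:
        merged = np.delete(merged, 1)
        c, _ = np.histogram(q2, merged)
    return merged


def enrichment_statistic(
    q2: np.ndarray,
    classes: np.ndarray,
    bin_edges: np.ndarray,
    target_class: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed per-bin enrichment ratios. Returns (enrichment, n per bin)."""
    q2 = np.asarray(q2, float)
    is_target = np.asarray(classes) == target_class
    n = q2.size
    n_target = int(is_target.sum())
    if n_target == 0:
        raise ValueError(f"no SNPs of class {target_class!r}")
    n_b, _ = np.histogram(q2, bin_edges)
    n_tb, _ = np.histogram(q2[is_target], bin_edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        enr = (n_tb / n_b) / (n_target / n)
    return enr, n_b


def _chrom_block_indices(n: int, b: int, n_reps: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Resampled SNP indices for one chromosome: ceil(n/b) circular blocks
    of length b per replicate (whole chromosome as one block if n < b)."""
    if n < b:
        logger.debug("chromosome shorter than block (%d < %d): single block", n, b)
        return np.tile(np.arange(n), (n_reps, 1))
    k = math.ceil(n / b)
    starts = rng.integers(0, n, size=(n_reps, k))
    offs = np.arange(b)
    return (starts[:, :, None] + offs[None, None, :]).reshape(n_reps, k * b) % n


def mbb_bootstrap(
    df: pd.DataFrame,
    bin_edges: np.ndarray,
    target_class: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_reps: int = DEFAULT_N_BOOTSTRAP,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Bootstrap distribution of the per-bin enrichment statistic.

    ``df`` must carry columns ``chrom, pos, q2, snp_class`` and is resampled
    per chromosome in blocks of ``block_size`` SNPs ordered by position;
    replicates are concatenated across chromosomes and the enrichment is
    recomputed per replicate on the fixed merged ``bin_edges``.

    Returns an (n_reps, n_bins) array.
    """
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = df.sort_values(["chrom", "pos"], kind="stable")
    q2 = df["q2"].to_numpy(float)
    is_target = (df["snp_class"] == target_class).to_numpy()
    chrom = df["chrom"].to_numpy()

    parts = []
    offset = 0
    for c in pd.unique(chrom):
        n_c = int((chrom == c).sum())
        parts.append(offset + _chrom_block_indices(n_c, block_size, n_reps, rng))
        offset += n_c
    idx = np.concatenate(parts, axis=1)

    n_bins = len(bin_edges) - 1
    out = np.empty((n_reps, n_bins))
    for r in range(n_reps):
        take = idx[r]
        qq = q2[take]
        tt = is_target[take]
        n_b, _ = np.histogram(qq, bin_edges)
        n_tb, _ = np.histogram(qq[tt], bin_edges)
        frac = tt.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            out[r] = (n_tb / n_b) / frac
    return out


def enrichment_curve(
    df: pd.DataFrame,
    target_class: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_snps: int = MIN_BIN_SNPS,
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_reps: int = DEFAULT_N_BOOTSTRAP,
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: int | np.random.Generator = 0,
) -> EnrichmentCurve:
    """Observed enrichment curve with MBB bootstrap median and CI."""
    finite = df["q2"].notna()
    if not finite.all():
        logger.info("dropping %d SNPs without a finite Q^2", (~finite).sum())
        df = df[finite]
    edges = make_bins(df["q2"].to_numpy(float), bin_width, min_snps)
    enr, n_b = enrichment_statistic(df["q2"].to_numpy(float),
                                    df["snp_class"].to_numpy(),
                                    edges, target_class)
    boots = mbb_bootstrap(df, edges, target_class, block_size, n_reps, seed)
    alpha = (1.0 - ci_level) / 2.0
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(boots, axis=0)
        lo = np.nanquantile(boots, alpha, axis=0)
        hi = np.nanquantile(boots, 1.0 - alpha, axis=0)
    return EnrichmentCurve(target_class, edges, n_b, enr, med, lo, hi,
                           ci_level, block_size, n_reps)


def stratified_enrichment(
    df: pd.DataFrame,
    strata: pd.Series,
    target_class: str,
    min_stratum_snps: int = 300,
    **kwargs,
) -> dict[object, EnrichmentCurve]:
    """Enrichment curves computed independently inside covariate classes.

    ``strata`` assigns each SNP a covariate class (e.g. MAF quartile);
    strata with fewer than ``min_stratum_snps`` SNPs, or without both the
    target class and its complement, are skipped with a warning.
    """
    curves: dict[object, EnrichmentCurve] = {}
    for label in sorted(pd.unique(strata)):
        sub = df[strata.reindex(df.index) == label]
        if len(sub) < min_stratum_snps:
            logger.warning("stratum %r has %d SNPs (< %d); skipped",
                           label, len(sub), min_stratum_snps)
            continue
        if (sub["snp_class"] == target_class).sum() == 0:
            logger.warning("stratum %r lacks class %r; skipped", label, target_class)
            continue
        curves[label] = enrichment_curve(sub, target_class, **kwargs)
    return curves
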