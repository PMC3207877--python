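"""SNP classification, Weir-Cockerham F_ST, and covariate stratification.

A SNP is *genic* if it lies inside a transcript or no more than 500 bp
upstream of its transcription start site; it is *intergenic* if it lies in
a gene-free interval longer than 100 kb. SNPs matching neither rule are
labeled *other* and excluded from genic/intergenic contrasts. Where a gene
has multiple isoforms, only the longest transcript is kept.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UPSTREAM_BP = 500
INTERGENIC_MIN_GAP_BP = 100_000


def longest_transcript(genes: pd.DataFrame) -> pd.DataFrame:
    """Keep one interval per gene: the longest transcript.

    ``genes`` has columns ``gene_id, chrom, start, end, strand`` with
    1-based inclusive coordinates. Ties broken by (start, end) order.
    """
    g = genes.copy()
    if (g["start"] > g["end"]).any():
        bad = g[g["start"] > g["end"]]
        raise ValueError(f"degenerate gene intervals: {bad['gene_id'].tolist()}")
    g["_len"] = g["end"] - g["start"] + 1
    g = g.sort_values(["gene_id", "_len", "start", "end"],
                      ascending=[True, False, True, True])
    return g.drop_duplicates("gene_id", keep="first").drop(columns="_len") \
            .reset_index(drop=True)


def classify_snps(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    upstream_bp: int = UPSTREAM_BP,
    min_gap_bp: int = INTERGENIC_MIN_GAP_BP,
    strand_aware: bool = True,
) -> pd.Series:
    """Classify SNP positions as genic / intergenic / other.

    Parameters
    ----------
    snps : DataFrame with columns ``chrom, pos`` (1-based), indexed by snp_id.
    genes : gene intervals (``gene_id, chrom, start, end, strand``); multiple
        isoforms per gene are reduced to the longest transcript.
    strand_aware : if True, "upstream" is taken on the 5' side of the
        transcript (interval end for minus-strand genes); if False, upstream
        means before the interval start regardless of strand.

    Returns a Series of class labels. Genic takes precedence where both
    rules match. SNPs on chromosomes absent from the annotation are labeled
    "other" with a warning.
    """
    genes = longest_transcript(genes)
    labels = pd.Series("other", index=snps.index, dtype=object)

    for chrom, snp_grp in snps.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            logger.warning("chromosome %s absent from gene annotation; "
                           "%d SNPs labeled 'other'", chrom, len(snp_grp))
            continue
        pos = snp_grp["pos"].to_numpy()

        # genic: inside the transcript, or within upstream_bp 5' of the TSS
        start = g["start"].to_numpy(float)
        end = g["end"].to_numpy(float)
        if strand_aware:
            minus = (g["strand"] == "-").to_numpy()
            lo = np.where(minus, start, start - upstream_bp)
            hi = np.where(minus, end + upstream_bp, end)
        else:
            lo, hi = start - upstream_bp, end
        genic = np.zeros(pos.size, dtype=bool)
        for l, h in zip(lo, hi):
            genic |= (pos >= l) & (pos <= h)

        # intergenic: the maximal gene-free interval containing the SNP
        # exceeds min_gap_bp. Chromosome-flank gaps are treated as unbounded.
        order = np.argsort(start)
        s_sorted, e_sorted = start[order], end[order]
        # merge overlapping gene intervals
        ms, me = [], []
        for s, e in zip(s_sorted, e_sorted):
            if ms and s <= me[-1] + 1:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        ms_arr, me_arr = np.asarray(ms), np.asarray(me)
        # gap i spans (me[i-1], ms[i]); flanks are infinite
        gap_lo = np.concatenate([[-np.inf], me_arr])
        gap_hi = np.concatenate([ms_arr, [np.inf]])
        gap_len = gap_hi - gap_lo - 1  # bases strictly between genes
        idx = np.searchsorted(ms_arr, pos, side="right")
        in_gap = (pos > gap_lo[idx]) & (pos < gap_hi[idx])
        intergenic = in_gap & (gap_len[idx] > min_gap_bp)

        lab = np.where(genic, "genic", np.where(intergenic, "intergenic", "other"))
        labels.loc[snp_grp.index] = lab
    return labels


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST

def weir_fst(freqs: np.ndarray, sizes: np.ndarray) -> float:
    """Weir-Cockerham theta for one biallelic locus from allele frequencies.

    ``freqs`` are per-population allele frequencies, ``sizes`` diploid
    sample sizes. Heterozygosity is taken at its Hardy-Weinberg expectation
    2p(1-p) since only frequencies are observed. May be negative. Returns
    NaN when the locus is monomorphic across all populations.
    """
    a, b, c = _wc_components(np.asarray(freqs, float), np.asarray(sizes, float))
    denom = a + b + c
    if denom == 0.0 or not np.isfinite(denom):
        return float("nan")
    return float(a / denom)


def weir_fst_multi(freqs: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Per-locus theta for a SNP x population frequency matrix (ratio of
    per-locus components; NaN for monomorphic loci)."""
    out = np.empty(freqs.shape[0])
    for i in range(freqs.shape[0]):
        out[i] = weir_fst(freqs[i], sizes)
    return out


def _wc_components(p: np.ndarray, n: np.ndarray) -> tuple[float, float, float]:
    """Variance components (a, b, c) of Weir & Cockerham (1984) for a
    biallelic locus, with HWE heterozygosity."""
    if p.size < 2 or np.any(n < 1):
        raise ValueError("need >= 2 populations with sample size >= 1")
    r = p.size
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    h = 2.0 * p * (1.0 - p)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def weir_fst_overall(freqs: np.ndarray, sizes: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham estimator: ratio of summed components."""
    A = B = C = 0.0
    for i in range(freqs.shape[0]):
        a, b, c = _wc_components(np.asarray(freqs[i], float), np.asarray(sizes, float))
        A += a
        B += b
        C += c
    tot = A + B + C
    return float("nan") if tot == 0 else float(A / tot)


# ---------------------------------------------------------------------------
# Covariate stratification

def stratify(covariate: pd.Series, n_classes: int) -> pd.Series:
    """Quantile-based classes of near-equal size.

    SNPs are ordered by covariate with ties broken by input order (stable
    sort), then split into ``n_classes`` contiguous rank chunks. If there
    are fewer distinct values than classes the effective number of classes
    shrinks (logged).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if covariate.isna().any():
        raise ValueError("covariate missing for some SNPs")
    n_distinct = covariate.nunique()
    if n_classes > n_distinct:
        logger.warning("n_classes=%d exceeds %d distinct covariate values; "
                       "using %d classes", n_classes, n_distinct, n_distinct)
        n_classes = n_distinct
    order = np.argsort(covariate.to_numpy(), kind="stable")
    bounds = np.round(np.linspace(0, len(covariate), n_classes + 1)).astype(int)
    labels = np.empty(len(covariate), dtype=int)
    for k in range(n_classes):
        labels[order[bounds[k]:bounds[k + 1]]] = k
    return pd.Series(labels, index=covariate.index, name=f"{covariate.name}_class")


def annotate_covariates(ft, n_classes: int = 4) -> pd.DataFrame:
    """Per-SNP covariates (mean folded MAF, F_ST, recombination proxy) and
    their quantile class labels, for stratified enrichment."""
    freqs = ft.freqs.to_numpy()
    sizes = ft.sample_sizes.to_numpy(float)
    out = pd.DataFrame(index=ft.snp_ids)
    out["maf"] = freqs.mean(axis=1)
    out["fst"] = weir_fst_multi(freqs, sizes)
    if "recomb" in ft.annotations.columns:
        out["recomb"] = ft.annotations["recomb"]
    for col in [c for c in ("maf", "fst", "recomb") if c in out.columns]:
        filled = out[col].fillna(out[col].median())
        out[f"{col}_class"] = stratify(filled.rename(col), n_classes)
    return out
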