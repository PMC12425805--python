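"""Overlap-based enrichment statistics.

Covers three cross-referencing analyses: AMP enrichment in the 3-kb
upstream promoters of allele-specifically expressed (ASE) genes
(hypergeometric test at gene level), enrichment of bQTL within +/-100
bp of GWAS hits relative to matched background SNP sets, and pairwise
linkage disequilibrium (r^2) between markers; plus the allele-specific
RNA read-counting rule (each read counted once per gene regardless of
how many informative SNPs it spans).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import hypergeom_enrichment_p

PROMOTER_BP = 3000
GWAS_WINDOW_BP = 100


def promoter_window(tss: int, strand: str, promoter_bp: int = PROMOTER_BP):
    """Closed [lo, hi] window covering ``promoter_bp`` bp upstream of the TSS."""
    if strand == "+":
        return tss - promoter_bp, tss
    if strand == "-":
        return tss, tss + promoter_bp
    raise ValueError(f"invalid strand {strand!r}")


def amp_positive_genes(
    genes: pd.DataFrame, amp_positions, promoter_bp: int = PROMOTER_BP
) -> pd.Series:
    """Flag genes with >=1 AMP in their strand-aware upstream promoter."""
    amps = np.sort(np.asarray(amp_positions, dtype=np.int64))
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"]).astype(np.int64)
    flags = []
    for t, s in zip(tss, genes["strand"]):
        lo, hi = promoter_window(int(t), s, promoter_bp)
        left = np.searchsorted(amps, lo, side="left")
        right = np.searchsorted(amps, hi, side="right")
        flags.append(right > left)
    return pd.Series(flags, index=genes.index, name="amp_positive")


def promoter_ase_enrichment(
    genes: pd.DataFrame,
    amp_positions,
    ase_class: str = "ASE",
    background_class: str | None = None,
    promoter_bp: int = PROMOTER_BP,
) -> dict:
    """Hypergeometric enrichment of AMP-positive promoters in a gene class.

    ``genes`` columns: start, end, strand, ase_class.  The universe is
    every gene (or the ``background_class`` subset plus the tested
    class); enrichment is the ratio of AMP-positive fractions, with
    exact upper- and lower-tail hypergeometric p-values.
    """
    if (genes["ase_class"] == ase_class).sum() == 0:
        raise ValueError(f"gene class {ase_class!r} is empty")
    universe = genes
    if background_class is not None:
        universe = genes[genes["ase_class"].isin([ase_class, background_class])]
        if (universe["ase_class"] == background_class).sum() == 0:
            raise ValueError(f"gene class {background_class!r} is empty")
    pos = amp_positive_genes(universe, amp_positions, promoter_bp)
    in_class = universe["ase_class"] == ase_class
    n_pop, n_marked = len(universe), int(pos.sum())
    n_draw, k = int(in_class.sum()), int((pos & in_class).sum())
    p_upper, p_lower = hypergeom_enrichment_p(n_pop, n_marked, n_draw, k)
    class_frac = k / n_draw
    bg_frac = n_marked / n_pop
    return {
        "n_genes": n_pop,
        "n_amp_positive": n_marked,
        "n_class": n_draw,
        "n_class_amp_positive": k,
        "enrichment": class_frac / bg_frac if bg_frac > 0 else np.nan,
        "p_enriched": p_upper,
        "p_depleted": p_lower,
    }


def _count_near(positions: np.ndarray, hits: np.ndarray, window: int) -> int:
    """How many positions lie within +/-window (inclusive) of any hit."""
    hits = np.sort(hits)
    left = np.searchsorted(hits, positions - window, side="left")
    right = np.searchsorted(hits, positions + window, side="right")
    return int((right > left).sum())


def gwas_hit_enrichment(
    bqtl: pd.DataFrame,
    gwas_hits,
    matched_bg_sets: list[pd.DataFrame],
    window_bp: int = GWAS_WINDOW_BP,
    strata: str | None = None,
) -> pd.DataFrame:
    """Fold enrichment of bQTL near GWAS hits vs matched backgrounds.

    Observed = number of bQTL within +/-``window_bp`` of any hit;
    expected = the mean of that count over the background sets.  When
    ``strata`` names a column shared by the bQTL and background tables
    (e.g. a distance-to-gene bin), per-stratum folds are reported
    alongside the overall one.  An empirical percentile of the observed
    count within the background distribution accompanies each fold.
    """
    if not matched_bg_sets:
        raise ValueError("need at least one matched background set")
    hits = np.asarray(gwas_hits, dtype=np.int64)

    def _one(frame_sets, bq):
        obs = _count_near(bq["pos"].to_numpy(np.int64), hits, window_bp)
        counts = np.array(
            [_count_near(s["pos"].to_numpy(np.int64), hits, window_bp) for s in frame_sets]
        )
        expected = counts.mean()
        fold = obs / expected if expected > 0 else np.nan
        pct = float((counts < obs).mean() + 0.5 * (counts == obs).mean())
        return obs, expected, fold, pct

    rows = []
    obs, exp, fold, pct = _one(matched_bg_sets, bqtl)
    rows.append({"stratum": "all", "observed": obs, "expected": exp,
                 "fold": fold, "percentile": pct})
    if strata is not None:
        for level in sorted(bqtl[strata].unique()):
            sub_bg = [s[s[strata] == level] for s in matched_bg_sets]
            obs, exp, fold, pct = _one(sub_bg, bqtl[bqtl[strata] == level])
            rows.append({"stratum": level, "observed": obs, "expected": exp,
                         "fold": fold, "percentile": pct})
    return pd.DataFrame(rows)


def ld_r2(genotype_a, genotype_b) -> float:
    """Squared Pearson correlation of two marker vectors.

    Pairs with a missing call in either marker are dropped; zero
    variance in either vector gives a missing value.
    """
    a = np.asarray(genotype_a, dtype=float)
    b = np.asarray(genotype_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("marker vectors must cover the same individuals")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ase_read_counting(read_snp_overlaps: pd.DataFrame) -> pd.DataFrame:
    """Allele-specific read counts per gene from read-SNP assignments.

    ``read_snp_overlaps`` columns: replicate, gene_id, allele, snp_id,
    read_id.  SNPs without reads on both alleles are dropped first
    (they cannot be confirmed to lie inside the gene on both
    haplotypes); then each distinct read counts once per
    (replicate, gene, allele) no matter how many retained SNPs it
    spans.  Genes without informative SNPs are absent from the output.
    """
    overlaps = read_snp_overlaps.copy()
    informative = (
        overlaps.groupby("snp_id")["allele"].nunique().loc[lambda s: s >= 2].index
    )
    kept = overlaps[overlaps["snp_id"].isin(informative)]
    if kept.empty:
        return pd.DataFrame(columns=["replicate", "gene_id", "allele", "count"])
    counts = (
        kept.groupby(["replicate", "gene_id", "allele"])["read_id"]
        .nunique()
        .rename("count")
        .reset_index()
    )
    return counts
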