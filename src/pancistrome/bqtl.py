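"""Local association mapping of binding QTL.

For every variant site that is an MP in at least two lines of the F1
panel, the binding frequency is regressed across lines on each of five
predictors separately and jointly:

    MP ~ mCHH        MP ~ mCG        MP ~ mCHG
    MP ~ GT_i        MP ~ GT_i + mCG + mCHG + mCHH

with GT_i the paternal-allele genotype code (0 = identical to the
reference, 1 = alternative) and mC* the between-allele methylation
difference of the +/-20 bp window means.  Significance is controlled by
Benjamini-Hochberg per model at 5% FDR, sites are classified as
genotype-driven / methylation-driven / both, and significant sites
within 65 bp are clumped into linkage groups led by the lowest p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

MODEL_COLUMNS = ("p_geno", "p_mcg", "p_mchg", "p_mchh")
FULL_COLUMNS = ("p_full_geno", "p_full_mcg", "p_full_mchg", "p_full_mchh")
CLUMP_BP = 65


def _ols_slope_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided t-test p-value for the slope of y ~ 1 + x."""
    n = x.size
    if n < 3:
        return np.nan
    xm = x - x.mean()
    sxx = float(xm @ xm)
    if sxx <= 0:
        return np.nan
    beta = float(xm @ y) / sxx
    resid = y - y.mean() - beta * xm
    rss = float(resid @ resid)
    dof = n - 2
    if rss <= 1e-300 * max(1.0, float(y @ y)):
        return np.nan  # zero residual variance: inestimable
    se = np.sqrt(rss / dof / sxx)
    t = beta / se
    return float(2.0 * sps.t.sf(abs(t), dof))


def _ols_multi_p(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficient p-values (excluding intercept) of y ~ [1, X]."""
    n, k = X.shape
    keep = X.std(axis=0) > 0
    p_out = np.full(k, np.nan)
    Xk = X[:, keep]
    q = Xk.shape[1]
    dof = n - q - 1
    if q == 0 or dof < 1:
        return p_out
    D = np.column_stack([np.ones(n), Xk])
    XtX = D.T @ D
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return p_out
    beta = XtX_inv @ (D.T @ y)
    resid = y - D @ beta
    rss = float(resid @ resid)
    if rss <= 1e-300 * max(1.0, float(y @ y)):
        return p_out
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    p_out[keep] = p[1:]
    return p_out


def fit_local_models(
    gt, mcg, mchg, mchh, response, min_lines: int = 2
) -> dict[str, float]:
    """Five OLS fits of binding frequency across lines at one site.

    Lines with a missing response are excluded; predictors with zero
    variance yield a missing p-value.  Returns the four marginal
    p-values plus the full-model coefficient p-values.
    """
    arrs = [np.asarray(a, dtype=float) for a in (gt, mcg, mchg, mchh, response)]
    y = arrs[4]
    mask = np.isfinite(y)
    for a in arrs[:4]:
        mask &= np.isfinite(a)
    out = {c: np.nan for c in MODEL_COLUMNS + FULL_COLUMNS}
    out["n_lines"] = int(mask.sum())
    if mask.sum() < max(min_lines, 3):
        return out
    gt_, mcg_, mchg_, mchh_, y_ = (a[mask] for a in arrs)
    out["p_geno"] = _ols_slope_p(gt_, y_)
    out["p_mcg"] = _ols_slope_p(mcg_, y_)
    out["p_mchg"] = _ols_slope_p(mchg_, y_)
    out["p_mchh"] = _ols_slope_p(mchh_, y_)
    full = _ols_multi_p(np.column_stack([gt_, mcg_, mchg_, mchh_]), y_)
    for name, val in zip(FULL_COLUMNS, full):
        out[name] = val
    return out


def fit_local_models_table(predictors: pd.DataFrame, min_lines: int = 2) -> pd.DataFrame:
    """Apply :func:`fit_local_models` per site of a long predictor table.

    ``predictors`` columns: site_id, line, gt, mcg, mchg, mchh,
    binding_frequency (missing where the site had no reads in a line).
    """
    records = []
    for site_id, grp in predictors.groupby("site_id", sort=True):
        rec = fit_local_models(
            grp["gt"], grp["mcg"], grp["mchg"], grp["mchh"],
            grp["binding_frequency"], min_lines=min_lines,
        )
        rec["site_id"] = site_id
        records.append(rec)
    cols = ["site_id", "n_lines", *MODEL_COLUMNS, *FULL_COLUMNS]
    return pd.DataFrame.from_records(records)[cols]


def assemble_predictors(
    mps: pd.DataFrame, genotypes: pd.DataFrame, methylomes: pd.DataFrame
) -> pd.DataFrame:
    """Join binding frequencies, genotypes and methylation differences.

    ``mps`` must carry one row per site x line with ``binding_frequency``
    (e.g. pooled MP records for one condition); the methylation
    predictors are the paternal-minus-reference window-mean differences.
    """
    wide = methylomes.pivot_table(
        index=["site_id", "line"], columns="allele",
        values=["mCG", "mCHG", "mCHH"],
    )
    diff = pd.DataFrame(
        {
            "mcg": wide[("mCG", "pat")] - wide[("mCG", "ref")],
            "mchg": wide[("mCHG", "pat")] - wide[("mCHG", "ref")],
            "mchh": wide[("mCHH", "pat")] - wide[("mCHH", "ref")],
        }
    ).reset_index()
    gt_long = (
        genotypes.stack().rename("gt").reset_index()
        .rename(columns={"level_1": "line"})
    )
    out = mps[["site_id", "line", "binding_frequency"]].merge(
        gt_long, on=["site_id", "line"], how="left"
    )
    return out.merge(diff, on=["site_id", "line"], how="left")


def select_significant(
    records: pd.DataFrame, fdr: float = 0.05, meth_rule: str = "any_single"
) -> pd.DataFrame:
    """BH correction per model and genotype/methylation attribution.

    A site is genotype-associated when the GT model passes the FDR
    threshold; methylation-associated when any single-context model
    passes (``meth_rule='any_single'``, the default) or when
    additionally any full-model methylation coefficient passes
    (``meth_rule='any'``).
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    if meth_rule not in ("any_single", "any"):
        raise ValueError(f"unknown meth_rule {meth_rule!r}")
    out = records.copy()
    for col in MODEL_COLUMNS + FULL_COLUMNS:
        if col in out.columns:
            out["q" + col[1:]] = bh_adjust(out[col])
    sig = lambda col: (out[col] < fdr).fillna(False).to_numpy()  # noqa: E731
    out["geno_sig"] = sig("q_geno")
    meth = sig("q_mcg") | sig("q_mchg") | sig("q_mchh")
    if meth_rule == "any":
        meth |= sig("q_full_mcg") | sig("q_full_mchg") | sig("q_full_mchh")
    out["meth_sig"] = meth
    out["sig_class"] = classify_bqtl(out["geno_sig"], out["meth_sig"])
    return out


def classify_bqtl(geno_sig, meth_sig) -> np.ndarray:
    """Partition significant sites into geno_only / meth_only / both."""
    geno = np.asarray(geno_sig, dtype=bool)
    meth = np.asarray(meth_sig, dtype=bool)
    out = np.full(geno.shape, "none", dtype=object)
    out[geno & ~meth] = "geno_only"
    out[~geno & meth] = "meth_only"
    out[geno & meth] = "both"
    return out


def clump_linkage_groups(
    significant: pd.DataFrame, max_gap: int = CLUMP_BP
) -> pd.DataFrame:
    """Chain significant sites within ``max_gap`` bp into linkage groups.

    Grouping is transitive over consecutive positions (a gap of exactly
    ``max_gap`` still joins).  The lead of a group is the member with
    the lowest lead-defining p-value (``p_lead``: the minimum p over a
    site's significant models); ties break to the leftmost position.
    """
    out = significant.copy()
    if out.empty:
        out["group_id"] = pd.Series(dtype=int)
        out["is_lead"] = pd.Series(dtype=bool)
        return out
    if "chrom" not in out.columns:
        out["chrom"] = "chr1"
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    new_chrom = out["chrom"].ne(out["chrom"].shift())
    gap = out["pos"].diff()
    new_group = new_chrom | (gap > max_gap)
    out["group_id"] = new_group.cumsum().astype(int)
    out["is_lead"] = False
    for _, idx in out.groupby("group_id").groups.items():
        grp = out.loc[idx]
        best = grp.sort_values(["p_lead", "pos"], kind="mergesort").index[0]
        out.loc[best, "is_lead"] = True
    return out


def lead_pvalue(records: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Lead-defining p per site: min p over that site's significant models."""
    ps = []
    for col in MODEL_COLUMNS:
        qcol = "q" + col[1:]
        p = records[col].where(records[qcol] < fdr)
        ps.append(p)
    return pd.concat(ps, axis=1).min(axis=1)


def map_bqtl(
    predictors: pd.DataFrame,
    positions: pd.Series,
    fdr: float = 0.05,
    clump_bp: int = CLUMP_BP,
    min_lines: int = 2,
) -> pd.DataFrame:
    """End-to-end bQTL mapping: fit, select, classify and clump."""
    records = fit_local_models_table(predictors, min_lines=min_lines)
    records = select_significant(records, fdr=fdr)
    records["pos"] = positions.reindex(records["site_id"]).to_numpy()
    records["p_lead"] = lead_pvalue(records, fdr=fdr)
    sig = records[records["sig_class"] != "none"].copy()
    clumped = clump_linkage_groups(sig, max_gap=clump_bp)
    keep = ["site_id", "group_id", "is_lead"]
    return records.merge(clumped[keep], on="site_id", how="left")
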