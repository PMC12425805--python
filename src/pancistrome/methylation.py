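"""Windowed DNA-methylation summaries and occupancy concordance.

Methylation at a variant site is the arithmetic mean of per-cytosine
levels within +/-20 bp (closed window), separately per sequence context
(CG, CHG, CHH) and allele.  Alleles are differentially methylated when
one is <10% and the other >70% methylated; strictly equally methylated
when both are <10% or both >70%.  Concordance statistics relate these
classes to allele-specific footprint occupancy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HALFWIDTH = 20
DIFF_LOW = 0.10
DIFF_HIGH = 0.70
CONTEXTS = ("CG", "CHG", "CHH")


def windowed_methylation(
    cytosines: pd.DataFrame, site_pos: int, halfwidth: int = HALFWIDTH
) -> dict[str, float]:
    """Mean methylation per context within [site-hw, site+hw] (closed).

    ``cytosines`` columns: pos, context, level.  Contexts without any
    cytosine in the window are missing (NaN).
    """
    lo, hi = site_pos - halfwidth, site_pos + halfwidth
    win = cytosines[(cytosines["pos"] >= lo) & (cytosines["pos"] <= hi)]
    out = {}
    for ctx in CONTEXTS:
        levels = win.loc[win["context"] == ctx, "level"]
        out[f"m{ctx}"] = float(levels.mean()) if len(levels) else np.nan
    return out


def windowed_methylation_table(
    cytosines: pd.DataFrame, sites: pd.DataFrame, halfwidth: int = HALFWIDTH
) -> pd.DataFrame:
    """Window means for many sites, per line and allele.

    ``cytosines`` columns: line, allele, pos, context, level.
    Returns long-form rows (site_id, line, allele, mCG, mCHG, mCHH).
    """
    records = []
    for (line, allele), grp in cytosines.groupby(["line", "allele"]):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        for _, site in sites.iterrows():
            lo = np.searchsorted(pos, site["pos"] - halfwidth, side="left")
            hi = np.searchsorted(pos, site["pos"] + halfwidth, side="right")
            win = grp.iloc[lo:hi]
            rec = {"site_id": site["site_id"], "line": line, "allele": allele}
            for ctx in CONTEXTS:
                levels = win.loc[win["context"] == ctx, "level"]
                rec[f"m{ctx}"] = float(levels.mean()) if len(levels) else np.nan
            records.append(rec)
    return pd.DataFrame.from_records(records)


def classify_differential(m_ref, m_pat, low: float = DIFF_LOW, high: float = DIFF_HIGH):
    """Differential-methylation class per allele pair.

    ``ref_hypo`` iff m_ref < low and m_pat > high; ``pat_hypo``
    symmetrically; otherwise ``not_differential``.  Missing inputs give
    a missing class (None).
    """
    ref = np.asarray(m_ref, dtype=float)
    pat = np.asarray(m_pat, dtype=float)
    out = np.full(ref.shape, "not_differential", dtype=object)
    out[(ref < low) & (pat > high)] = "ref_hypo"
    out[(pat < low) & (ref > high)] = "pat_hypo"
    out[~(np.isfinite(ref) & np.isfinite(pat))] = None
    return out if out.ndim else out.item()


def classify_equal_strict(m_ref, m_pat, low: float = DIFF_LOW, high: float = DIFF_HIGH):
    """Strict equal methylation: both alleles < low or both > high."""
    ref = np.asarray(m_ref, dtype=float)
    pat = np.asarray(m_pat, dtype=float)
    out = ((ref < low) & (pat < low)) | ((ref > high) & (pat > high))
    return out if out.ndim else bool(out)


def combine_context_classes(classes_by_context: pd.DataFrame) -> pd.Series:
    """Reduce per-context differential classes to one per pair.

    A pair is differential if any supplied context (CG and/or CHG by
    default upstream) is differential; conflicting directions across
    contexts yield ``not_differential``.
    """
    def _reduce(row):
        vals = {v for v in row if v in ("ref_hypo", "pat_hypo")}
        if len(vals) == 1:
            return vals.pop()
        if len(vals) > 1:
            return "not_differential"
        if row.isna().all():
            return None
        return "not_differential"

    return classes_by_context.apply(_reduce, axis=1)


def differential_class_table(
    methylomes: pd.DataFrame, contexts: tuple[str, ...] = ("CG", "CHG")
) -> pd.DataFrame:
    """Per site x line differential/equal classification.

    Uses CG and CHG by default (these carry effectively all allelic
    methylation differences); CHH is retained only as a covariate for
    association mapping.
    """
    wide = methylomes.pivot_table(
        index=["site_id", "line"], columns="allele",
        values=[f"m{c}" for c in contexts],
    )
    per_ctx = {}
    equal_any = None
    for c in contexts:
        ref, pat = wide[(f"m{c}", "ref")], wide[(f"m{c}", "pat")]
        per_ctx[c] = pd.Series(
            classify_differential(ref.to_numpy(), pat.to_numpy()), index=wide.index
        )
        eq = pd.Series(
            classify_equal_strict(ref.to_numpy(), pat.to_numpy()), index=wide.index
        )
        equal_any = eq if equal_any is None else (equal_any & eq)
    cls = combine_context_classes(pd.DataFrame(per_ctx))
    out = pd.DataFrame({"diff_class": cls, "equal_strict": equal_any})
    out["is_differential"] = out["diff_class"].isin(["ref_hypo", "pat_hypo"])
    return out.reset_index()


def bias_concordance(amps: pd.DataFrame) -> dict:
    """Fraction of differential AMPs biased toward the hypomethylated allele.

    ``amps`` columns: binding_frequency (toward the reference allele)
    and diff_class in {ref_hypo, pat_hypo}.  Records with frequency
    exactly 0.5 carry no direction and are dropped.
    """
    d = amps[amps["diff_class"].isin(["ref_hypo", "pat_hypo"])].copy()
    d = d[np.isfinite(d["binding_frequency"]) & (d["binding_frequency"] != 0.5)]
    if d.empty:
        return {"n": 0, "n_concordant": 0, "fraction": np.nan}
    toward_ref = d["binding_frequency"] > 0.5
    concordant = np.where(d["diff_class"] == "ref_hypo", toward_ref, ~toward_ref)
    return {
        "n": int(len(d)),
        "n_concordant": int(concordant.sum()),
        "fraction": float(concordant.mean()),
    }


def shared_site_partition(
    per_line: pd.DataFrame,
    min_diff: int = 2,
    min_eq: int = 2,
    min_amp: int = 1,
) -> pd.DataFrame:
    """Per-site AMP fractions among differential vs equally methylated lines.

    ``per_line`` columns: site_id, line, is_differential, equal_strict,
    is_amp.  A site is eligible when >= ``min_diff`` lines are
    differentially methylated, >= ``min_eq`` strictly equally methylated
    and >= ``min_amp`` lines carry an AMP.  Returns one row per
    eligible site with the two fractions.
    """
    records = []
    for site_id, grp in per_line.groupby("site_id"):
        n_diff = int(grp["is_differential"].sum())
        n_eq = int(grp["equal_strict"].sum())
        n_amp = int(grp["is_amp"].sum())
        if n_diff < min_diff or n_eq < min_eq or n_amp < min_amp:
            continue
        frac_diff = grp.loc[grp["is_differential"], "is_amp"].mean()
        frac_eq = grp.loc[grp["equal_strict"], "is_amp"].mean()
        records.append(
            {
                "site_id": site_id,
                "n_differential": n_diff,
                "n_equal": n_eq,
                "amp_fraction_differential": float(frac_diff),
                "amp_fraction_equal": float(frac_eq),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "site_id", "n_differential", "n_equal",
            "amp_fraction_differential", "amp_fraction_equal",
        ],
    )
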