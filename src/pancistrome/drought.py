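"""Condition-response classification of allele-specific sites.

Sites with significant allelic bias (AMP) in at least one of two
conditions fall into four response groups:

    I    detected in exactly one condition (below the coverage
         detection limit in the other);
    II   detected in both with >=60% bias toward the same allele;
    III  detected in both with >=60% bias toward opposite alleles;
    IV   significant bias in one condition, near-balanced occupancy
         (frequency strictly between 40% and 60%) in the other.

The 60% rule replaces a second statistical cut-off in the second
condition.  A separate selector picks high-confidence drought candidate
loci: bQTL near AMPs in significantly responsive regions, recurring in
at least two lines, close to genes with haplotype-specific and
drought-responsive transcripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BIAS_CUT = 0.60
NO_BIAS_BAND = (0.40, 0.60)
UPSTREAM_BP = 5000
DOWNSTREAM_BP = 1000
OVERLAP_BP = 65


def _bias_dir(f: float, cut: float) -> int:
    """+1 ref-biased (f >= cut), -1 pat-biased (f <= 1-cut), 0 neither."""
    if f >= cut:
        return 1
    if f <= 1.0 - cut:
        return -1
    return 0


def classify_condition_amps(pair, bias_cut: float = BIAS_CUT) -> str:
    """Assign a response group to one site x line condition pair.

    ``pair`` (mapping or Series) fields: detected_a, detected_b (peak
    signal above the MP detection threshold), f_a, f_b (binding
    frequencies), amp_a, amp_b.  Requires an AMP call in at least one
    condition; raises ``ValueError`` otherwise.
    """
    amp_a, amp_b = bool(pair["amp_a"]), bool(pair["amp_b"])
    if not (amp_a or amp_b):
        raise ValueError("pair is not eligible: AMP in neither condition")
    det_a, det_b = bool(pair["detected_a"]), bool(pair["detected_b"])
    if det_a != det_b:
        return "I"
    if not (det_a and det_b):
        return "unclassified"
    f_a, f_b = float(pair["f_a"]), float(pair["f_b"])
    d_a, d_b = _bias_dir(f_a, bias_cut), _bias_dir(f_b, bias_cut)
    if d_a != 0 and d_b != 0:
        return "II" if d_a == d_b else "III"
    lo, hi = NO_BIAS_BAND
    if amp_a and d_a != 0 and lo < f_b < hi:
        return "IV"
    if amp_b and d_b != 0 and lo < f_a < hi:
        return "IV"
    return "unclassified"


def classify_condition_amps_table(
    pairs: pd.DataFrame, bias_cut: float = BIAS_CUT
) -> pd.Series:
    """Vector version of :func:`classify_condition_amps` (eligible rows only)."""
    return pairs.apply(lambda row: classify_condition_amps(row, bias_cut), axis=1)


def condition_pairs_from_records(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> pd.DataFrame:
    """Build condition pairs from two per-condition MP/AMP tables.

    Each input needs site_id, line, is_mp, is_amp, binding_frequency.
    Detection = the MP coverage criterion in that condition.  Only
    pairs with an AMP in at least one condition are returned.
    """
    key = ["site_id", "line"]
    a = records_a.set_index(key)
    b = records_b.set_index(key)
    idx = a.index.union(b.index)
    pairs = pd.DataFrame(index=idx)
    pairs["detected_a"] = a["is_mp"].reindex(idx).fillna(False).astype(bool)
    pairs["detected_b"] = b["is_mp"].reindex(idx).fillna(False).astype(bool)
    pairs["f_a"] = a["binding_frequency"].reindex(idx)
    pairs["f_b"] = b["binding_frequency"].reindex(idx)
    pairs["amp_a"] = a["is_amp"].reindex(idx).fillna(False).astype(bool)
    pairs["amp_b"] = b["is_amp"].reindex(idx).fillna(False).astype(bool)
    return pairs[pairs["amp_a"] | pairs["amp_b"]].reset_index()


def gene_flank_window(gene, up: int = UPSTREAM_BP, down: int = DOWNSTREAM_BP):
    """Strand-aware [lo, hi] window: ``up`` bp upstream of the TSS
    through ``down`` bp downstream of the TTS (closed bounds)."""
    strand = gene["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene.get('gene_id', '?')} lacks a valid strand")
    if strand == "+":
        return int(gene["start"]) - up, int(gene["end"]) + down
    return int(gene["start"]) - down, int(gene["end"]) + up


def select_drought_candidates(
    bqtl: pd.DataFrame,
    amps: pd.DataFrame,
    responsive_regions: pd.DataFrame,
    genes: pd.DataFrame,
    transcript_flags: pd.DataFrame,
    up: int = UPSTREAM_BP,
    down: int = DOWNSTREAM_BP,
    min_lines: int = 2,
    window: int = OVERLAP_BP,
) -> pd.DataFrame:
    """High-confidence drought-responsive candidate loci.

    A bQTL (columns site_id, pos) is retained when (1) AMPs
    (columns pos, line) lying inside significantly responsive regions
    (columns start, end, direction, significant) fall within ``window``
    bp of it in at least ``min_lines`` distinct lines, and (2) it lies
    within ``up`` bp upstream or ``down`` bp downstream (strand-aware)
    of a gene whose transcripts are flagged both haplotype-specific
    (``ase``) and drought-responsive (``drought_responsive``).
    """
    if genes["strand"].isna().any():
        raise ValueError("every gene needs a strand for the flank windows")
    regions = responsive_regions[responsive_regions["significant"].astype(bool)]
    amp_ok = amps.copy()
    in_region = np.zeros(len(amp_ok), dtype=bool)
    dirs = np.full(len(amp_ok), None, dtype=object)
    for _, reg in regions.iterrows():
        m = (amp_ok["pos"] >= reg["start"]) & (amp_ok["pos"] < reg["end"])
        if "line" in reg.index and pd.notna(reg.get("line")):
            m &= amp_ok["line"] == reg["line"]
        dirs[m.to_numpy()] = reg["direction"]
        in_region |= m.to_numpy()
    amp_ok = amp_ok[in_region].assign(direction=dirs[in_region])

    flagged = transcript_flags[
        transcript_flags["ase"].astype(bool)
        & transcript_flags["drought_responsive"].astype(bool)
    ]
    flag_genes = genes[genes["gene_id"].isin(flagged["gene_id"])]

    records = []
    for _, row in bqtl.iterrows():
        near = amp_ok[(amp_ok["pos"] - row["pos"]).abs() <= window]
        n_lines = near["line"].nunique()
        if n_lines < min_lines:
            continue
        for _, gene in flag_genes.iterrows():
            lo, hi = gene_flank_window(gene, up=up, down=down)
            if lo <= row["pos"] <= hi:
                records.append(
                    {
                        "site_id": row["site_id"],
                        "pos": int(row["pos"]),
                        "gene_id": gene["gene_id"],
                        "n_responsive_lines": int(n_lines),
                        "direction": near["direction"].mode().iat[0]
                        if not near["direction"].mode().empty
                        else None,
                    }
                )
                break
    return pd.DataFrame.from_records(
        records,
        columns=["site_id", "pos", "gene_id", "n_responsive_lines", "direction"],
    )
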