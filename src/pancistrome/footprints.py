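"""Allele-specific footprint occupancy at variant sites.

Quantifies MNase footprint coverage per haplotype, computes binding
frequencies, calls MPs (variants inside footprint peaks passing
coverage thresholds) and AMPs (MPs with significant allelic imbalance),
applies the WGS-control percentile filter, summarises coverage at small
INDELs, and tests footprint regions for a condition response.

Binomial testing is performed on read numbers, never on normalised
RPGC values; RPGC is only used for the detection threshold.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_adjust, binom_two_sided_p_vec, welch_t_test

FOOTPRINT_BP = 20  # each read collapses to a 20-bp fragment-center window
MP_RPGC_MIN = 7.0  # detection threshold: > 7 RPGC (~ >25 reads) on one allele


@dataclass
class CoverageTrack:
    """Per-base scaled coverage (RPGC units) on one chromosome."""

    chrom: str
    values: np.ndarray
    scale: float
    effective_genome_size: float = np.nan
    n_mapped: int = 0

    @property
    def values_array(self) -> np.ndarray:  # used by io.write_fixtures
        return self.values

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())


def fragment_center_track(
    read_intervals,
    genome_length: int,
    effective_genome_size: float,
    n_mapped: int | None = None,
    rng: np.random.Generator | None = None,
    chrom: str = "chr1",
) -> CoverageTrack:
    """Collapse reads to 20-bp fragment-center windows and RPGC-scale.

    Each read [start, end) contributes a 20-bp window centred on its
    middle base: for odd lengths the window is ``[m-10, m+10)`` with
    ``m`` the middle base; for even lengths one of the two middle bases
    is chosen at random.  Coverage is scaled by
    ``effective_genome_size / n_mapped``.
    """
    reads = np.asarray(read_intervals, dtype=np.int64).reshape(-1, 2)
    if reads.size and (reads[:, 1] <= reads[:, 0]).any():
        raise ValueError("read intervals must have positive length")
    if n_mapped is None:
        n_mapped = reads.shape[0]
    if n_mapped <= 0 and reads.size:
        raise ValueError("n_mapped must be > 0")
    scale = effective_genome_size / n_mapped if n_mapped else 0.0
    values = np.zeros(genome_length)
    if reads.size:
        if rng is None:
            rng = np.random.default_rng()
        length = reads[:, 1] - reads[:, 0]
        mid = reads[:, 0] + length // 2
        even = length % 2 == 0
        # for even reads the middle bases are len/2-1 and len/2; pick one
        mid = mid - even.astype(np.int64) * rng.integers(0, 2, size=reads.shape[0])
        half = FOOTPRINT_BP // 2
        for m in mid:
            lo = max(int(m) - half, 0)
            hi = min(int(m) + half, genome_length)
            values[lo:hi] += scale
    return CoverageTrack(
        chrom=chrom,
        values=values,
        scale=scale,
        effective_genome_size=effective_genome_size,
        n_mapped=int(n_mapped),
    )


def binding_frequency(rpgc_ref, rpgc_pat):
    """Fraction of scaled coverage on the reference allele.

    Returns NaN (missing) where both alleles have zero coverage, per
    the convention that binding frequency at loci with no reads is NA.
    """
    ref = np.asarray(rpgc_ref, dtype=float)
    pat = np.asarray(rpgc_pat, dtype=float)
    if (ref < 0).any() or (pat < 0).any():
        raise ValueError("coverage must be non-negative")
    total = ref + pat
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, ref / np.where(total > 0, total, 1.0), np.nan)
    return out if out.ndim else float(out)


def rpgc_to_reads(rpgc, scale: float):
    """Back-convert RPGC to read counts: round half away from zero."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    x = np.asarray(rpgc, dtype=float) / scale
    out = np.floor(x + 0.5).astype(np.int64)
    return out if out.ndim else int(out)


def pool_replicates(coverage: pd.DataFrame) -> pd.DataFrame:
    """Sum reads and RPGC over replicates per site x line x condition."""
    return (
        coverage.groupby(["site_id", "line", "condition"], as_index=False)[
            ["reads_ref", "reads_pat", "rpgc_ref", "rpgc_pat"]
        ].sum()
    )


def call_mps(
    coverage: pd.DataFrame,
    in_peak: pd.Series,
    rpgc_min: float = MP_RPGC_MIN,
    min_other_reads: int = 1,
) -> pd.DataFrame:
    """Call MPs on pooled allele-specific coverage.

    A site x line x condition record is an MP iff the site lies inside
    a footprint peak, the better-covered allele exceeds ``rpgc_min``
    RPGC, and the other allele carries at least ``min_other_reads``
    read(s) so the allelic test is well defined.
    """
    missing = set(coverage["site_id"]) - set(in_peak.index)
    if missing:
        raise ValueError(f"{len(missing)} sites lack peak annotation")
    out = coverage.copy()
    out["in_peak"] = in_peak.reindex(out["site_id"]).to_numpy()
    hi_rpgc = np.maximum(out["rpgc_ref"], out["rpgc_pat"])
    other_reads = np.where(
        out["rpgc_ref"] >= out["rpgc_pat"], out["reads_pat"], out["reads_ref"]
    )
    out["binding_frequency"] = binding_frequency(
        out["rpgc_ref"].to_numpy(), out["rpgc_pat"].to_numpy()
    )
    out["is_mp"] = out["in_peak"] & (hi_rpgc > rpgc_min) & (other_reads >= min_other_reads)
    out["is_amp"] = False
    return out


def call_amps(mps: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Exact binomial test of allelic balance with BH correction.

    A two-sided exact binomial test of ``reads_ref`` out of the total
    against p = 0.5 is applied to every MP; Benjamini-Hochberg q-values
    are computed within each line x condition MP set and ``is_amp`` is
    ``q < fdr``.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    out = mps.copy()
    out["p_binomial"] = np.nan
    out["q_fdr"] = np.nan
    mp_mask = out["is_mp"].to_numpy()
    k = out.loc[mp_mask, "reads_ref"].to_numpy()
    n = k + out.loc[mp_mask, "reads_pat"].to_numpy()
    out.loc[mp_mask, "p_binomial"] = binom_two_sided_p_vec(k, n)
    for _, idx in out[mp_mask].groupby(["line", "condition"]).groups.items():
        out.loc[idx, "q_fdr"] = bh_adjust(out.loc[idx, "p_binomial"])
    out["is_amp"] = mp_mask & (out["q_fdr"] < fdr)
    return out


def wgs_control_filter(
    amps: pd.DataFrame,
    wgs_ratio: pd.Series,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> pd.DataFrame:
    """Drop AMPs whose WGS control ratio is extreme among all MPs.

    Thresholds are the 5th and 95th percentile (linear interpolation)
    of the WGS allelic ratio over every MP; AMPs outside (lo, hi) are
    flagged ``wgs_excluded`` and lose their AMP status.
    """
    out = amps.copy()
    out["wgs_ratio"] = wgs_ratio.reindex(out["site_id"]).to_numpy()
    mp_ratios = out.loc[out["is_mp"], "wgs_ratio"].dropna().to_numpy()
    if mp_ratios.size < 20:
        warnings.warn(
            f"only {mp_ratios.size} MPs available; WGS percentile thresholds "
            "are unreliable",
            stacklevel=2,
        )
    if mp_ratios.size == 0:
        out["wgs_excluded"] = False
        return out
    lo, hi = np.percentile(mp_ratios, [lower_pct, upper_pct])
    out["wgs_excluded"] = out["is_amp"] & ((out["wgs_ratio"] < lo) | (out["wgs_ratio"] > hi))
    out.loc[out["wgs_excluded"], "is_amp"] = False
    return out


# ---------------------------------------------------------------------------
# INDELs

INDEL_MIN_LEN = 2
INDEL_MAX_LEN = 50
_DEL_FLANK = 3


def filter_indels(indels: pd.DataFrame) -> pd.DataFrame:
    """Retain biallelic INDELs of length 2-50 bp present in >=2 lines."""
    keep = indels["length"].between(INDEL_MIN_LEN, INDEL_MAX_LEN)
    if "alt_count" in indels.columns:
        keep &= indels["alt_count"] >= 2
    return indels[keep].reset_index(drop=True)


def indel_allele_coverage(track: CoverageTrack, start: int, end: int, kind: str) -> float:
    """Mean RPGC for one INDEL allele.

    ``insertion``: mean over the inserted span [start, end) on the
    genome that carries it.  ``deletion``: mean over the 3 bp before
    ``start`` plus the 3 bp after ``end`` (6 bases; ``start == end``
    for the point locus on the genome lacking the sequence).
    Zero-coverage bases count toward the average.
    """
    v = track.values
    if kind == "insertion":
        if end <= start:
            raise ValueError("insertion span must be non-empty")
        window = v[start:end]
        return float(window.sum() / (end - start))
    if kind == "deletion":
        lo = max(start - _DEL_FLANK, 0)
        hi = min(end + _DEL_FLANK, v.size)
        total = v[lo:start].sum() + v[end:hi].sum()
        return float(total / (2 * _DEL_FLANK))
    raise ValueError(f"kind must be 'insertion' or 'deletion', got {kind!r}")


def indel_site_coverage(
    indel: pd.Series | dict,
    track_ref: CoverageTrack,
    track_pat: CoverageTrack,
    scale: float | None = None,
) -> dict:
    """Allele-specific coverage at one small INDEL.

    ``indel`` needs: ``carrier`` ('ref' or 'pat', the allele carrying
    the inserted sequence), ``ins_start``/``ins_end`` (span on the
    carrier genome) and ``del_pos`` (position on the other genome).
    RPGC means are back-converted to read counts using ``scale``
    (default: the carrier track's scale).
    """
    carrier = indel["carrier"]
    if carrier not in ("ref", "pat"):
        raise ValueError("carrier must be 'ref' or 'pat'")
    tracks = {"ref": track_ref, "pat": track_pat}
    other = "pat" if carrier == "ref" else "ref"
    rpgc_carrier = indel_allele_coverage(
        tracks[carrier], int(indel["ins_start"]), int(indel["ins_end"]), "insertion"
    )
    rpgc_other = indel_allele_coverage(
        tracks[other], int(indel["del_pos"]), int(indel["del_pos"]), "deletion"
    )
    rpgc = {carrier: rpgc_carrier, other: rpgc_other}
    if scale is None:
        scale = tracks[carrier].scale
    return {
        "rpgc_ref": rpgc["ref"],
        "rpgc_pat": rpgc["pat"],
        "reads_ref": rpgc_to_reads(rpgc["ref"], scale),
        "reads_pat": rpgc_to_reads(rpgc["pat"], scale),
    }


# ---------------------------------------------------------------------------
# condition response

TreatmentResponse = namedtuple(
    "TreatmentResponse", ["direction", "statistic", "pvalue", "significant"]
)


def treatment_response_test(
    coverage_ww, coverage_ds, alpha: float = 0.05
) -> TreatmentResponse:
    """Welch t-test of replicate coverages between conditions.

    ``direction`` is the sign of mean(DS) - mean(WW): +1 for increased
    occupancy under drought, -1 for decreased.
    """
    ww = np.asarray(coverage_ww, dtype=float)
    ds = np.asarray(coverage_ds, dtype=float)
    t, p = welch_t_test(ds, ww)
    direction = int(np.sign(ds.mean() - ww.mean()))
    return TreatmentResponse(direction, t, p, bool(p < alpha))
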