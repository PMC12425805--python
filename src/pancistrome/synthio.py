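"""Synthetic F1-hybrid panel generator.

Emulates the inputs of a haplotype-specific footprint-occupancy study:
a panel of F1 hybrids sharing one reference mother (B73-like), biallelic
variant sites segregating in the paternal genomes, bimodal allelic DNA
methylation, overdispersed allele-specific footprint read counts in two
watering conditions, whole-genome-sequencing control allelic ratios, and
a linear-genome gene/peak annotation.

The generator records its ground truth (per-site causal class, true
binding frequencies, condition-specific depth multipliers) so that every
downstream caller can be benchmarked for recovery.

All randomness flows from ``SimConfig.seed`` through named substreams,
so an identical configuration yields byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import write_fixtures  # noqa: F401  (re-exported for convenience)

CAUSAL_CLASSES = ("geno", "meth", "both", "null")

#: order defines the substream layout; never reorder, only append
_STREAMS = (
    "genotypes",
    "annotations",
    "classes",
    "methylomes",
    "binding",
    "counts_WW",
    "counts_DS",
    "wgs",
    "traits",
    "background",
)


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the synthetic study.

    Defaults mirror the study design being emulated: 25 F1 hybrids with
    a shared reference parent, variants retained only when the paternal
    allele occurs in >=2 lines, methylation modes at ~2% / ~85% so the
    <10% / >70% differential rule separates them cleanly, footprint
    peaks covering ~2% of the genome, an RPGC scale of 0.3 so that ~25
    reads correspond to ~7.5 RPGC, and well-watered (WW) vs
    drought-stress (DS) conditions with three biological replicates.
    """

    n_lines: int = 25
    n_sites: int = 2000
    n_genes: int = 120
    genome_size: int = 1_000_000
    read_depth_mean: float = 50.0
    depth_dispersion: float = 0.3
    frac_cis_effect: float = 0.10
    effect_size_delta: float = 0.25
    frac_meth_effect: float = 0.10
    frac_both_effect: float = 0.05
    meth_high_level: float = 0.85
    meth_low_level: float = 0.02
    conditions: tuple[str, ...] = ("WW", "DS")
    drought_effect_frac: float = 0.10
    n_replicates: int = 3
    rpgc_scale: float = 0.3
    peak_fraction: float = 0.02
    peak_width: int = 200
    frac_sites_in_peak: float = 0.5
    n_gwas_hits: int = 50
    wgs_artifact_frac: float = 0.02
    wgs_concentration: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.read_depth_mean <= 0:
            raise ValueError("read_depth_mean must be > 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if not 0 <= self.effect_size_delta < 0.5:
            raise ValueError("effect_size_delta must be in [0, 0.5)")
        for name in (
            "frac_cis_effect",
            "frac_meth_effect",
            "frac_both_effect",
            "meth_high_level",
            "meth_low_level",
            "drought_effect_frac",
            "peak_fraction",
            "frac_sites_in_peak",
            "wgs_artifact_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_cis_effect + self.frac_meth_effect + self.frac_both_effect > 1:
            raise ValueError("causal fractions must sum to <= 1")
        if self.rpgc_scale <= 0:
            raise ValueError("rpgc_scale must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the master seed."""
        idx = _STREAMS.index(stream)
        child = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[idx]
        return np.random.default_rng(child)

    @property
    def line_names(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_lines)]


@dataclass
class Annotations:
    genes: pd.DataFrame  # chrom, start, end, strand, gene_id
    peaks: pd.DataFrame  # chrom, start, end
    gwas_hits: pd.DataFrame  # chrom, pos


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    freq: pd.DataFrame  # site x line true binding frequency (toward ref)
    classes: pd.Series  # site -> {geno, meth, both, null}
    hypo_allele: pd.Series  # site -> {ref, pat} for meth/both sites, NA else
    diff_lines: pd.DataFrame  # site x line: allele-differential methylation
    depth_mult: pd.DataFrame  # site x condition depth multiplier


@dataclass
class SimulatedData:
    cfg: SimConfig
    annotations: Annotations
    sites: pd.DataFrame
    genotypes: pd.DataFrame
    methylomes: pd.DataFrame
    truth: SyntheticTruth
    coverage: dict[str, pd.DataFrame]
    wgs_ratio: pd.Series


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(cfg: SimConfig) -> Annotations:
    """Non-overlapping genes, footprint peaks and GWAS hit positions.

    Peaks are laid out as ``n = round(peak_fraction * genome / width)``
    fixed-width non-overlapping intervals, so the covered genome
    fraction equals the requested fraction up to a single-peak rounding
    error.
    """
    cfg.validate()
    rng = cfg.rng("annotations")
    genes = _place_intervals(
        rng, cfg.genome_size, lengths=rng.integers(1000, 5001, size=cfg.n_genes)
    )
    genes["strand"] = rng.choice(["+", "-"], size=len(genes))
    genes["gene_id"] = [f"g{i + 1:04d}" for i in range(len(genes))]
    genes["chrom"] = "chr1"
    genes = genes[["chrom", "start", "end", "strand", "gene_id"]]

    n_peaks = int(round(cfg.peak_fraction * cfg.genome_size / cfg.peak_width))
    peaks = _place_intervals(
        rng, cfg.genome_size, lengths=np.full(max(n_peaks, 1), cfg.peak_width)
    )
    peaks["chrom"] = "chr1"
    peaks = peaks[["chrom", "start", "end"]]

    hits = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.sort(rng.choice(cfg.genome_size, size=cfg.n_gwas_hits, replace=False)),
        }
    )
    return Annotations(genes=genes, peaks=peaks, gwas_hits=hits)


def _place_intervals(rng, genome_size: int, lengths: np.ndarray) -> pd.DataFrame:
    """Place intervals without overlap by distributing the free space."""
    lengths = np.asarray(lengths, dtype=np.int64)
    free = genome_size - int(lengths.sum())
    if free <= 0:
        raise ValueError("intervals do not fit in the genome")
    gaps = rng.multinomial(free, np.full(lengths.size + 1, 1.0 / (lengths.size + 1)))
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    return pd.DataFrame({"start": starts, "end": starts + lengths})


def annotate_sites(
    sites: pd.DataFrame, genes: pd.DataFrame, peaks: pd.DataFrame
) -> pd.DataFrame:
    """Attach distance-to-nearest-gene and in-peak membership.

    Distance is to the nearest gene interval edge (0 when the site lies
    inside a gene), matching ``bedtools closest -d`` semantics.
    """
    out = sites.copy()
    out["dist_to_gene"] = distance_to_intervals(
        out["pos"].to_numpy(), genes["start"].to_numpy(), genes["end"].to_numpy()
    )
    out["in_peak"] = in_intervals(
        out["pos"].to_numpy(), peaks["start"].to_numpy(), peaks["end"].to_numpy()
    )
    return out


def distance_to_intervals(pos, starts, ends) -> np.ndarray:
    """Distance from each position to the nearest [start, end) interval."""
    pos = np.asarray(pos, dtype=np.int64)
    order = np.argsort(starts)
    starts = np.asarray(starts, dtype=np.int64)[order]
    ends = np.asarray(ends, dtype=np.int64)[order]
    if starts.size == 0:
        return np.full(pos.shape, np.iinfo(np.int64).max)
    i = np.searchsorted(starts, pos, side="right") - 1
    dist = np.full(pos.shape, np.iinfo(np.int64).max)
    # gap to the interval at or before the position
    has_prev = i >= 0
    prev_end = np.where(has_prev, ends[np.clip(i, 0, None)], 0)
    inside = has_prev & (pos < prev_end)
    dist = np.where(has_prev, np.maximum(pos - prev_end + 1, 0), dist)
    # gap to the next interval
    j = np.clip(i + 1, 0, starts.size - 1)
    has_next = i + 1 < starts.size
    next_gap = np.where(has_next, np.maximum(starts[j] - pos, 0), np.iinfo(np.int64).max)
    dist = np.minimum(dist, next_gap)
    dist = np.where(inside, 0, dist)
    return dist


def in_intervals(pos, starts, ends) -> np.ndarray:
    """Membership of positions in a set of [start, end) intervals."""
    pos = np.asarray(pos, dtype=np.int64)
    order = np.argsort(starts)
    starts = np.asarray(starts, dtype=np.int64)[order]
    ends = np.asarray(ends, dtype=np.int64)[order]
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    return ok & (pos < ends[np.clip(i, 0, None)])


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    cfg: SimConfig, annotations: Annotations | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biallelic variant sites and the paternal genotype matrix.

    Sites whose non-reference allele occurs in fewer than two lines are
    discarded, reproducing the study's retention rule (hence a minimum
    minor allele frequency of 2 / n_lines).
    """
    cfg.validate()
    if annotations is None:
        annotations = simulate_annotations(cfg)
    rng = cfg.rng("genotypes")

    rows: list[np.ndarray] = []
    while len(rows) < cfg.n_sites:
        n_draw = 2 * (cfg.n_sites - len(rows)) + 16
        p = rng.uniform(0.05, 0.9, size=n_draw)
        g = (rng.random((n_draw, cfg.n_lines)) < p[:, None]).astype(np.int8)
        keep = g.sum(axis=1) >= 2
        rows.extend(g[keep])
    geno = np.vstack(rows[: cfg.n_sites])

    # place a realistic share of variants inside footprint peaks: the
    # analysis concerns variants at occupied loci, so a uniform layout
    # would leave almost nothing past the in-peak filter
    peaks = annotations.peaks
    in_peak_mask = rng.random(cfg.n_sites) < cfg.frac_sites_in_peak
    pos = np.empty(cfg.n_sites, dtype=np.int64)
    pos[~in_peak_mask] = rng.choice(cfg.genome_size, size=(~in_peak_mask).sum(),
                                    replace=False)
    if in_peak_mask.any() and len(peaks):
        pk = rng.integers(0, len(peaks), size=in_peak_mask.sum())
        offset = rng.integers(0, (peaks["end"] - peaks["start"]).to_numpy()[pk])
        pos[in_peak_mask] = peaks["start"].to_numpy()[pk] + offset
    # de-duplicate while keeping the site count fixed
    while np.unique(pos).size < pos.size:
        seen: set[int] = set()
        for i, p in enumerate(pos):
            while int(pos[i]) in seen:
                pos[i] += 1
            seen.add(int(pos[i]))
    pos = np.sort(pos)
    site_ids = [f"s{i + 1:06d}" for i in range(cfg.n_sites)]
    sites = pd.DataFrame({"site_id": site_ids, "chrom": "chr1", "pos": pos})
    sites = annotate_sites(sites, annotations.genes, annotations.peaks)
    sites["alt_count"] = geno.sum(axis=1)
    sites["allele_freq"] = sites["alt_count"] / cfg.n_lines
    genotypes = pd.DataFrame(geno, index=pd.Index(site_ids, name="site_id"),
                             columns=cfg.line_names)
    return sites, genotypes


def assign_causal_classes(cfg: SimConfig) -> pd.Series:
    """Mutually exclusive causal labels over {geno, meth, both, null}."""
    rng = cfg.rng("classes")
    n = cfg.n_sites
    labels = np.array(["null"] * n, dtype=object)
    k_g = int(round(cfg.frac_cis_effect * n))
    k_m = int(round(cfg.frac_meth_effect * n))
    k_b = int(round(cfg.frac_both_effect * n))
    chosen = rng.choice(n, size=min(k_g + k_m + k_b, n), replace=False)
    labels[chosen[:k_g]] = "geno"
    labels[chosen[k_g : k_g + k_m]] = "meth"
    labels[chosen[k_g + k_m :]] = "both"
    ids = [f"s{i + 1:06d}" for i in range(n)]
    return pd.Series(labels, index=pd.Index(ids, name="site_id"), name="causal_class")


# ---------------------------------------------------------------------------
# methylomes


def _beta_around(rng, mean: float, conc: float, size) -> np.ndarray:
    a = mean * conc
    b = (1.0 - mean) * conc
    return rng.beta(a, b, size=size)


def simulate_methylomes(
    sites: pd.DataFrame,
    cfg: SimConfig,
    classes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Per-line, per-allele methylation windows with a bimodal mixture.

    CG and CHG levels sit in a low mode (near ``meth_low_level``) or a
    high mode (near ``meth_high_level``); CHH is kept uniformly low so
    that effectively all between-allele differences come from CG/CHG.
    At methylation-causal sites one allele is hypomethylated in a random
    subset of lines (>=2 differential and >=2 equal lines enforced).

    Returns ``(methylomes, hypo_allele, diff_lines)`` where
    ``methylomes`` is long-form (site_id, line, allele, mCG, mCHG, mCHH).
    """
    cfg.validate()
    if classes is None:
        classes = assign_causal_classes(cfg)
    classes = classes.reindex(sites["site_id"])
    rng = cfg.rng("methylomes")
    conc = 150.0
    n_sites = len(sites)
    n_lines = cfg.n_lines
    differential = classes.isin(["meth", "both"]).to_numpy()

    # site-level choices
    hypo = np.where(rng.random(n_sites) < 0.5, "ref", "pat")
    hypo = np.where(differential, hypo, None)
    base_high = rng.random(n_sites) < 0.3  # shared mode at non-differential sites

    # line-level differential membership at causal sites
    diff_lines = rng.random((n_sites, n_lines)) < 0.5
    for i in np.flatnonzero(differential):
        while diff_lines[i].sum() < 2 or (~diff_lines[i]).sum() < 2:
            diff_lines[i] = rng.random(n_lines) < 0.5
    diff_lines[~differential] = False

    shape = (n_sites, n_lines)
    low = {a: _beta_around(rng, cfg.meth_low_level, conc, shape) for a in ("ref", "pat")}
    high = {a: _beta_around(rng, cfg.meth_high_level, conc, shape) for a in ("ref", "pat")}
    # independent second context draws
    low2 = {a: _beta_around(rng, cfg.meth_low_level, conc, shape) for a in ("ref", "pat")}
    high2 = {a: _beta_around(rng, cfg.meth_high_level, conc, shape) for a in ("ref", "pat")}
    chh = {a: _beta_around(rng, cfg.meth_low_level, conc, shape) for a in ("ref", "pat")}

    frames = []
    for allele in ("ref", "pat"):
        # high-mode mask for this allele, per site x line
        is_hypo_allele = (hypo == allele)[:, None]
        hi_mask = np.where(
            diff_lines,
            ~is_hypo_allele,  # differential line: hypo allele low, other high
            np.broadcast_to(base_high[:, None], shape),
        )
        mcg = np.where(hi_mask, high[allele], low[allele])
        mchg = np.where(hi_mask, high2[allele], low2[allele])
        df = pd.DataFrame(
            {
                "site_id": np.repeat(sites["site_id"].to_numpy(), n_lines),
                "line": np.tile(cfg.line_names, n_sites),
                "allele": allele,
                "mCG": mcg.ravel(),
                "mCHG": mchg.ravel(),
                "mCHH": chh[allele].ravel(),
            }
        )
        frames.append(df)
    meth = pd.concat(frames, ignore_index=True)
    hypo_s = pd.Series(hypo, index=pd.Index(sites["site_id"], name="site_id"),
                       name="hypo_allele", dtype=object)
    diff_df = pd.DataFrame(diff_lines, index=pd.Index(sites["site_id"], name="site_id"),
                           columns=cfg.line_names)
    return meth, hypo_s, diff_df


# ---------------------------------------------------------------------------
# binding model and counts


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def simulate_binding_model(
    sites: pd.DataFrame,
    genotypes: pd.DataFrame,
    methylomes: pd.DataFrame,
    cfg: SimConfig,
    classes: pd.Series | None = None,
    hypo_allele: pd.Series | None = None,
    diff_lines: pd.DataFrame | None = None,
) -> SyntheticTruth:
    """True binding frequencies from a logistic effect model.

    ``f = expit(beta_G * GT + beta_M * dM)`` with ``dM`` the scaled
    paternal-minus-reference CG/CHG methylation difference, and both
    betas chosen so a full effect shifts the frequency from 0.5 to
    ``0.5 + effect_size_delta``.  A hypomethylated allele therefore
    never has lower expected occupancy when only methylation differs.
    """
    cfg.validate()
    if classes is None:
        classes = assign_causal_classes(cfg)
    if hypo_allele is None or diff_lines is None:
        raise ValueError("pass hypo_allele and diff_lines from simulate_methylomes")
    beta = _logit(0.5 + cfg.effect_size_delta)
    classes = classes.reindex(sites["site_id"])
    geno_on = classes.isin(["geno", "both"]).to_numpy()[:, None]
    meth_on = classes.isin(["meth", "both"]).to_numpy()[:, None]

    g = genotypes.reindex(sites["site_id"]).to_numpy(dtype=float)

    wide = methylomes.pivot_table(
        index=["site_id", "line"], columns="allele", values=["mCG", "mCHG"]
    )
    dm = (
        (wide[("mCG", "pat")] - wide[("mCG", "ref")])
        + (wide[("mCHG", "pat")] - wide[("mCHG", "ref")])
    ) / 2.0
    dm = dm.unstack("line").reindex(index=sites["site_id"], columns=genotypes.columns)
    span = cfg.meth_high_level - cfg.meth_low_level
    dm_scaled = dm.to_numpy() / span if span > 0 else dm.to_numpy() * 0.0

    eta = beta * g * geno_on + beta * np.clip(dm_scaled, -1, 1) * meth_on
    freq = 1.0 / (1.0 + np.exp(-eta))
    freq_df = pd.DataFrame(freq, index=pd.Index(sites["site_id"], name="site_id"),
                           columns=genotypes.columns)

    rng = cfg.rng("binding")
    mult = pd.DataFrame(
        1.0, index=freq_df.index, columns=list(cfg.conditions)
    )
    if "DS" in cfg.conditions and cfg.drought_effect_frac > 0:
        affected = rng.random(len(freq_df)) < cfg.drought_effect_frac
        direction = rng.random(len(freq_df)) < 0.5
        ds = np.where(affected, np.where(direction, 2.0, 0.05), 1.0)
        mult["DS"] = ds
    return SyntheticTruth(
        freq=freq_df,
        classes=classes.set_axis(freq_df.index),
        hypo_allele=hypo_allele,
        diff_lines=diff_lines,
        depth_mult=mult,
    )


def simulate_moa_counts(
    truth: SyntheticTruth,
    cfg: SimConfig,
    condition: str = "WW",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-replicate allele-specific footprint counts and RPGC values.

    Total depth per site x line x replicate is gamma-Poisson
    (negative-binomial-like; ``var = mu + dispersion * mu^2``), the
    reference-allele count is binomial at the true binding frequency,
    and RPGC = reads x ``rpgc_scale``.
    """
    cfg.validate()
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if rng is None:
        rng = cfg.rng(f"counts_{condition}")
    freq = truth.freq.to_numpy()
    n_sites, n_lines = freq.shape
    mult = truth.depth_mult[condition].to_numpy()[:, None, None]
    shape = (n_sites, n_lines, cfg.n_replicates)
    mu = cfg.read_depth_mean * np.broadcast_to(mult, shape)
    if cfg.depth_dispersion > 0:
        lam = rng.gamma(1.0 / cfg.depth_dispersion, cfg.depth_dispersion * mu)
    else:
        lam = mu
    depth = rng.poisson(lam)
    reads_ref = rng.binomial(depth, freq[:, :, None])
    reads_pat = depth - reads_ref

    idx_site = np.repeat(truth.freq.index.to_numpy(), n_lines * cfg.n_replicates)
    idx_line = np.tile(np.repeat(truth.freq.columns.to_numpy(), cfg.n_replicates), n_sites)
    idx_rep = np.tile(np.arange(1, cfg.n_replicates + 1), n_sites * n_lines)
    return pd.DataFrame(
        {
            "site_id": idx_site,
            "line": idx_line,
            "condition": condition,
            "replicate": idx_rep,
            "reads_ref": reads_ref.ravel(),
            "reads_pat": reads_pat.ravel(),
            "rpgc_ref": reads_ref.ravel() * cfg.rpgc_scale,
            "rpgc_pat": reads_pat.ravel() * cfg.rpgc_scale,
        }
    )


def simulate_wgs_controls(sites: pd.DataFrame, cfg: SimConfig) -> pd.Series:
    """Per-site WGS control allelic ratios.

    Ratios concentrate around 0.5; a configured fraction of
    mapping-artifact sites receives extreme ratios (near 0 or 1).
    """
    cfg.validate()
    rng = cfg.rng("wgs")
    n = len(sites)
    c = cfg.wgs_concentration
    ratio = rng.beta(0.5 * c, 0.5 * c, size=n)
    artifact = rng.random(n) < cfg.wgs_artifact_frac
    extreme = rng.uniform(0.0, 0.02, size=n)
    hi_side = rng.random(n) < 0.5
    ratio = np.where(artifact, np.where(hi_side, 1.0 - extreme, extreme), ratio)
    return pd.Series(ratio, index=pd.Index(sites["site_id"], name="site_id"),
                     name="wgs_ratio")


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(cfg: SimConfig) -> SimulatedData:
    """Run every generator stage with a consistent substream layout."""
    cfg.validate()
    ann = simulate_annotations(cfg)
    sites, genotypes = simulate_genotypes(cfg, annotations=ann)
    classes = assign_causal_classes(cfg)
    meth, hypo, diff = simulate_methylomes(sites, cfg, classes=classes)
    truth = simulate_binding_model(
        sites, genotypes, meth, cfg, classes=classes, hypo_allele=hypo, diff_lines=diff
    )
    coverage = {c: simulate_moa_counts(truth, cfg, condition=c) for c in cfg.conditions}
    wgs = simulate_wgs_controls(sites, cfg)
    return SimulatedData(
        cfg=cfg,
        annotations=ann,
        sites=sites,
        genotypes=genotypes,
        methylomes=meth,
        truth=truth,
        coverage=coverage,
        wgs_ratio=wgs,
    )


def dataset_tables(data: SimulatedData) -> dict[str, object]:
    """Flatten a simulated dataset into named tables for fixture I/O."""
    tables: dict[str, object] = {
        "sites": data.sites,
        "genotypes": data.genotypes.reset_index(),
        "methylomes": data.methylomes,
        "genes": data.annotations.genes,
        "peaks": data.annotations.peaks,
        "gwas_hits": data.annotations.gwas_hits,
        "wgs_ratio": data.wgs_ratio.reset_index(),
        "truth_freq": data.truth.freq.reset_index(),
        "truth_classes": data.truth.classes.reset_index(),
    }
    for cond, cov in data.coverage.items():
        tables[f"coverage_{cond}"] = cov
    return tables
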