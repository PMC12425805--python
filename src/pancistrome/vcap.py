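"""Variance-component partitioning of trait heritability (VCAP).

Additive genetic variance of a trait is split across SNP sets -- the
bQTL set, a matched background set (equal allele-frequency and
distance-to-gene composition), and the rest of the genome -- by fitting

    y = Xb + sum_k u_k + e,   u_k ~ N(0, s2_k K_k),   e ~ N(0, s2_e I)

with restricted maximum likelihood.  K_k are centred-cross-product
genomic relatedness matrices scaled to mean diagonal 1.  The REML
solver uses average-information updates with an EM fallback and a
non-negativity constraint on every component.  Background SNP sets are
resampled per permutation (the bQTL set is fixed), giving a
distribution of estimates per trait.  The trait simulator draws each
trait as a sum of zero-mean multivariate normals whose covariances are
the kinship matrices (plus the identity for residual variation) scaled
by the target heritabilities -- the study's own validation design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

AF_BIN = 0.1
DIST_BIN_EDGES = tuple(range(0, 10_001, 1_000))  # 0-1 kb ... 9-10 kb


# ---------------------------------------------------------------------------
# kinship


def build_kinship(genotypes: np.ndarray) -> np.ndarray:
    """Centred cross-product GRM scaled to mean diagonal 1.

    ``genotypes`` is individuals x markers (0/1 inbred coding or
    0/1/2).  K = Z Z' / c with Z the column-centred matrix and c chosen
    so mean(diag K) = 1.  Identical genotype vectors give identical
    rows/columns.  Raises when no marker varies.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need an individuals x markers matrix with >=1 marker")
    Z = X - X.mean(axis=0)
    K = Z @ Z.T
    c = np.trace(K) / K.shape[0]
    if c <= 0:
        raise ValueError("all markers have zero variance; kinship undefined")
    return K / c


# ---------------------------------------------------------------------------
# matched background sampling


def af_bin(af) -> np.ndarray:
    """Allele-frequency bin index with 0.1 bin size ([0.1k, 0.1k+0.1))."""
    af = np.asarray(af, dtype=float)
    return np.minimum((af / AF_BIN).astype(int), int(1 / AF_BIN) - 1)


def distance_bin(dist) -> np.ndarray:
    """Distance-to-gene bin: 0 = intragenic, 1..10 = 0-1 kb .. 9-10 kb,
    11 = >10 kb."""
    d = np.asarray(dist, dtype=np.int64)
    out = np.searchsorted(np.asarray(DIST_BIN_EDGES[1:]), d, side="left") + 1
    out = np.where(d == 0, 0, out)
    return np.minimum(out, len(DIST_BIN_EDGES))


def matching_cells(sites: pd.DataFrame) -> pd.Series:
    """(AF bin, distance bin) cell label per site."""
    return pd.Series(
        list(zip(af_bin(sites["allele_freq"]), distance_bin(sites["dist_to_gene"]))),
        index=sites.index,
    )


def sample_matched_background(
    bqtl_sites: pd.DataFrame,
    all_sites: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.Index:
    """One matched non-bQTL site per bQTL, without replacement.

    Sites are matched on the (allele-frequency bin x distance-to-gene
    bin) cell.  When a cell has too few non-bQTL sites, the shortfall
    is drawn from the nearest non-empty distance bin at the same AF bin
    (with a warning) -- the documented fallback.
    """
    bqtl_ids = set(bqtl_sites["site_id"])
    pool = all_sites[~all_sites["site_id"].isin(bqtl_ids)].reset_index(drop=True)
    pool_cells = matching_cells(pool)
    bqtl_cells = matching_cells(bqtl_sites.reset_index(drop=True))
    chosen: list[str] = []
    taken = np.zeros(len(pool), dtype=bool)
    for (a_bin, d_bin), count in bqtl_cells.value_counts().items():
        avail = np.flatnonzero(
            (~taken)
            & (pool_cells.map(lambda c: c[0]).to_numpy() == a_bin)
            & (pool_cells.map(lambda c: c[1]).to_numpy() == d_bin)
        )
        take = min(count, avail.size)
        if take:
            pick = rng.choice(avail, size=take, replace=False)
            taken[pick] = True
            chosen.extend(pool.loc[pick, "site_id"])
        short = count - take
        if short:
            warnings.warn(
                f"cell (af_bin={a_bin}, dist_bin={d_bin}) short by {short}; "
                "falling back to the nearest non-empty distance bin",
                stacklevel=2,
            )
            for off in range(1, len(DIST_BIN_EDGES) + 2):
                for nb in (d_bin - off, d_bin + off):
                    if short == 0 or not 0 <= nb <= len(DIST_BIN_EDGES):
                        continue
                    avail = np.flatnonzero(
                        (~taken)
                        & (pool_cells.map(lambda c: c[0]).to_numpy() == a_bin)
                        & (pool_cells.map(lambda c: c[1]).to_numpy() == nb)
                    )
                    take = min(short, avail.size)
                    if take:
                        pick = rng.choice(avail, size=take, replace=False)
                        taken[pick] = True
                        chosen.extend(pool.loc[pick, "site_id"])
                        short -= take
                if short == 0:
                    break
            if short:
                raise ValueError("background pool exhausted at this AF bin")
    return pd.Index(chosen, name="site_id")


# ---------------------------------------------------------------------------
# REML


@dataclass
class VarCompEstimate:
    """REML variance components for one trait."""

    variances: np.ndarray  # per kinship component
    residual: float
    loglik: float
    converged: bool
    iterations: int

    @property
    def total(self) -> float:
        return float(self.variances.sum() + self.residual)

    @property
    def proportions(self) -> np.ndarray:
        """Per-component proportion of phenotypic variance."""
        return self.variances / self.total

    @property
    def residual_proportion(self) -> float:
        return self.residual / self.total


def reml_loglik(sig2: np.ndarray, y: np.ndarray, comps: list[np.ndarray]) -> float:
    """Restricted log-likelihood at the given variance components
    (intercept-only fixed effect); the last component is the residual."""
    n = y.size
    V = sum(s * C for s, C in zip(sig2, comps))
    c, low = cho_factor(V, lower=True)
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = cho_solve((c, low), y)
    ones = np.ones(n)
    Vi_1 = cho_solve((c, low), ones)
    xvx = float(ones @ Vi_1)
    Py = Vi_y - Vi_1 * (float(ones @ Vi_y) / xvx)
    return -0.5 * (logdetV + np.log(xvx) + float(y @ Py))


def reml_fit(
    trait,
    kinships: list[np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarCompEstimate:
    """AI-REML with EM fallback and non-negativity constraints.

    Individuals with a missing trait value are dropped (the kinships
    are subset accordingly).  The first iteration is an EM step; later
    iterations use the average-information update, falling back to EM
    with step halving whenever the likelihood would decrease or a
    component would go negative beyond the boundary clamp.
    """
    y = np.asarray(trait, dtype=float)
    mask = np.isfinite(y)
    y = y[mask]
    n = y.size
    if n < 2:
        raise ValueError("need >=2 non-missing individuals")
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("trait has zero variance")
    comps = [np.asarray(K, dtype=float)[np.ix_(mask, mask)] for K in kinships]
    comps.append(np.eye(n))
    m = len(comps)
    floor = 1e-8 * vary
    sig2 = np.full(m, vary / m)
    ones = np.ones(n)

    def _state(s):
        V = sum(si * C for si, C in zip(s, comps))
        c, low = cho_factor(V, lower=True)
        Vi = cho_solve((c, low), np.eye(n))
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        Vi1 = Vi @ ones
        xvx = float(ones @ Vi1)
        P = Vi - np.outer(Vi1, Vi1) / xvx
        Py = P @ y
        ll = -0.5 * (logdetV + np.log(xvx) + float(y @ Py))
        return P, Py, ll

    P, Py, ll = _state(sig2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        KPy = [C @ Py for C in comps]
        trPK = np.array([float((P * C).sum()) for C in comps])
        yPKPy = np.array([float(Py @ w) for w in KPy])
        score = -0.5 * (trPK - yPKPy)
        if it == 1:
            new = sig2 + sig2**2 * (yPKPy - trPK) / n  # EM warm-up step
        else:
            W = np.column_stack(KPy)
            AI = 0.5 * (W.T @ P @ W)
            try:
                step = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                step = sig2**2 * (yPKPy - trPK) / n
            new = sig2 + step
        new = np.maximum(new, floor)
        P_new, Py_new, ll_new = _state(new)
        if ll_new < ll - 1e-10:
            # AI overshoot: fall back to the (monotone) EM update
            new = np.maximum(sig2 + sig2**2 * (yPKPy - trPK) / n, floor)
            P_new, Py_new, ll_new = _state(new)
        delta = abs(ll_new - ll)
        sig2, P, Py = new, P_new, Py_new
        if delta < tol * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return VarCompEstimate(
        variances=sig2[:-1].copy(),
        residual=float(sig2[-1]),
        loglik=float(ll),
        converged=converged,
        iterations=it,
    )


# ---------------------------------------------------------------------------
# trait simulation and recovery


def _psd_cholesky(K: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(K)
        if w.min() < -1e-8 * max(1.0, w.max()):
            # genuinely indefinite, not just rank-deficient to machine precision
            warnings.warn("kinship not PSD; clipping negative eigenvalues", stacklevel=2)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_traits(
    kinships: list[np.ndarray],
    h2,
    n_traits: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Traits as sums of MVN draws with kinship covariances.

    ``h2`` holds one heritability per kinship plus the residual share;
    entries must be >= 0 and sum to <= 1 (any remainder is added to the
    residual so the total expected variance is 1).
    """
    h2 = np.asarray(h2, dtype=float)
    if (h2 < 0).any():
        raise ValueError("heritabilities must be >= 0")
    if h2.size == len(kinships):
        h2 = np.append(h2, 0.0)
    if h2.size != len(kinships) + 1:
        raise ValueError("h2 must have one entry per kinship plus residual")
    if h2.sum() > 1 + 1e-9:
        raise ValueError("heritabilities must sum to <= 1")
    h2 = h2.copy()
    h2[-1] += 1.0 - h2.sum()
    n = kinships[0].shape[0]
    roots = [_psd_cholesky(K) for K in kinships]
    traits = np.zeros((n, n_traits))
    for k, L in enumerate(roots):
        traits += np.sqrt(h2[k]) * (L @ rng.standard_normal((n, n_traits)))
    traits += np.sqrt(h2[-1]) * rng.standard_normal((n, n_traits))
    return pd.DataFrame(traits, columns=[f"trait{j + 1:02d}" for j in range(n_traits)])


def recovery_experiment(
    kinships: list[np.ndarray],
    h2_sets,
    n_traits_per_set: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate traits at known heritabilities and re-estimate them.

    For each heritability set, ``n_traits_per_set`` traits are drawn
    and fitted; the report carries the mean and spread of the estimated
    proportions next to the truth, per component.
    """
    if rng is None:
        rng = np.random.default_rng()
    records = []
    for set_idx, h2 in enumerate(h2_sets):
        traits = simulate_traits(kinships, h2, n_traits_per_set, rng)
        ests = [reml_fit(traits[c], kinships) for c in traits.columns]
        props = np.array([np.append(e.proportions, e.residual_proportion) for e in ests])
        h2_full = np.asarray(h2, dtype=float)
        if h2_full.size == len(kinships):
            h2_full = np.append(h2_full, 1.0 - h2_full.sum())
        for k in range(len(kinships) + 1):
            name = f"K{k + 1}" if k < len(kinships) else "residual"
            records.append(
                {
                    "h2_set": set_idx,
                    "component": name,
                    "truth": float(h2_full[k]),
                    "mean_estimate": float(props[:, k].mean()),
                    "sd_estimate": float(props[:, k].std(ddof=1)),
                    "bias": float(props[:, k].mean() - h2_full[k]),
                }
            )
    return pd.DataFrame.from_records(records)


def vcap_permutations(
    bqtl_sites: pd.DataFrame,
    all_sites: pd.DataFrame,
    genotypes: pd.DataFrame,
    traits: pd.DataFrame,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Refit the three-component model over background permutations.

    ``genotypes`` is sites x individuals (rows indexed by site_id).
    The bQTL kinship is built once and reused; per permutation the
    background set is resampled, the background and rest-of-genome
    kinships rebuilt, and every trait refitted.  Returns a long table
    (permutation, trait, component, variance, proportion).
    """
    if rng is None:
        rng = np.random.default_rng()
    bqtl_ids = pd.Index(bqtl_sites["site_id"])
    K_bqtl = build_kinship(genotypes.loc[bqtl_ids].to_numpy().T)
    records = []
    for perm in range(n_perm):
        bg_ids = sample_matched_background(bqtl_sites, all_sites, rng)
        rest_ids = genotypes.index.difference(bqtl_ids.union(bg_ids))
        K_bg = build_kinship(genotypes.loc[bg_ids].to_numpy().T)
        K_rest = build_kinship(genotypes.loc[rest_ids].to_numpy().T)
        for trait_name in traits.columns:
            est = reml_fit(traits[trait_name], [K_bqtl, K_bg, K_rest])
            props = np.append(est.proportions, est.residual_proportion)
            variances = np.append(est.variances, est.residual)
            for comp, v, p in zip(("bqtl", "background", "rest", "residual"),
                                  variances, props):
                records.append(
                    {
                        "permutation": perm,
                        "trait": trait_name,
                        "component": comp,
                        "variance": float(v),
                        "proportion": float(p),
                        "converged": est.converged,
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# structured genotype generator for validation designs


def simulate_structured_genotypes(
    n_individuals: int,
    n_markers: int,
    rng: np.random.Generator,
    n_clusters: int = 25,
    fst: float = 0.15,
) -> np.ndarray:
    """Balding-Nichols structured 0/1 genotypes (inbred coding).

    Individuals are assigned to clusters (default 25, the family count
    of a nested association mapping panel); marker frequencies drift
    per cluster with divergence ``fst``.  The resulting kinship departs
    from the identity, which makes distinct marker sets mutually
    distinguishable in variance-component fits -- mirroring the
    structured mapping populations such partitions are used on.
    """
    clusters = rng.integers(0, n_clusters, size=n_individuals)
    p0 = rng.uniform(0.1, 0.9, size=n_markers)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    p_cluster = rng.beta(a, b, size=(n_clusters, n_markers))
    u = rng.random((n_individuals, n_markers))
    return (u < p_cluster[clusters]).astype(np.int8)
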