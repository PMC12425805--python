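"""End-to-end orchestration of the synthetic pan-cistrome analysis.

Composes the stages in dependency order -- simulate, footprint MP/AMP
calling with the WGS filter, methylation classification, bQTL mapping
in both conditions, drought-response classification, variance-component
partitioning and promoter/GWAS enrichment -- and records a run manifest
(config snapshot, seed, stage record counts, output digests) so a rerun
with the same manifest reproduces the outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bqtl as bqtl_mod
from . import drought as drought_mod
from . import enrichment as enrich_mod
from . import footprints as fp
from . import methylation as meth_mod
from . import vcap as vcap_mod
from .io import write_fixtures
from .synthio import SimConfig, SimulatedData, dataset_tables, simulate_dataset


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    fdr_amp: float = 0.01
    fdr_bqtl: float = 0.05
    clump_bp: int = 65
    n_perm: int = 3
    n_traits: int = 3
    h2: tuple[float, ...] = (0.4, 0.2, 0.2)

    def validate(self) -> None:
        self.sim.validate()
        for name in ("fdr_amp", "fdr_bqtl"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"config field '{name}' must be in (0, 1), got {v}")
        if self.clump_bp < 0:
            raise ValueError(f"config field 'clump_bp' must be >= 0, got {self.clump_bp}")
        if self.n_perm < 1:
            raise ValueError(f"config field 'n_perm' must be >= 1, got {self.n_perm}")
        if self.n_traits < 1:
            raise ValueError(f"config field 'n_traits' must be >= 1, got {self.n_traits}")
        if any(h < 0 for h in self.h2) or sum(self.h2) > 1:
            raise ValueError("config field 'h2' must be non-negative and sum to <= 1")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


@dataclass
class PipelineResult:
    data: SimulatedData
    mp_records: dict[str, pd.DataFrame]
    meth_classes: pd.DataFrame
    bqtl_records: dict[str, pd.DataFrame]
    condition_groups: pd.Series
    vcap_estimates: pd.DataFrame
    promoter_enrichment: dict
    manifest: RunManifest


def _amp_stage(data: SimulatedData, condition: str, fdr: float) -> pd.DataFrame:
    pooled = fp.pool_replicates(data.coverage[condition])
    in_peak = data.sites.set_index("site_id")["in_peak"]
    mps = fp.call_mps(pooled, in_peak)
    amps = fp.call_amps(mps, fdr=fdr)
    return fp.wgs_control_filter(amps, data.wgs_ratio)


def run_pipeline(config: PipelineConfig | SimConfig | None = None,
                 out_dir=None) -> PipelineResult:
    """Run every stage on a synthetic dataset; optionally write fixtures."""
    if config is None:
        config = PipelineConfig()
    if isinstance(config, SimConfig):
        config = PipelineConfig(sim=config)
    config.validate()
    cfg = config.sim
    data = simulate_dataset(cfg)

    mp_records = {c: _amp_stage(data, c, config.fdr_amp) for c in cfg.conditions}
    meth_classes = meth_mod.differential_class_table(data.methylomes)

    positions = data.sites.set_index("site_id")["pos"]
    bqtl_records = {}
    for cond, recs in mp_records.items():
        preds = bqtl_mod.assemble_predictors(
            recs[recs["is_mp"]], data.genotypes, data.methylomes
        )
        bqtl_records[cond] = bqtl_mod.map_bqtl(
            preds, positions, fdr=config.fdr_bqtl, clump_bp=config.clump_bp
        )

    if set(cfg.conditions) >= {"WW", "DS"}:
        pairs = drought_mod.condition_pairs_from_records(
            mp_records["WW"], mp_records["DS"]
        )
        groups = drought_mod.classify_condition_amps_table(pairs) if len(pairs) else pd.Series(dtype=object)
    else:
        groups = pd.Series(dtype=object)

    # variance partitioning on the line panel (individuals = F1 lines)
    cond0 = cfg.conditions[0]
    sig = bqtl_records[cond0]
    bqtl_ids = sig.loc[sig["sig_class"] != "none", "site_id"]
    rng = cfg.rng("traits")
    if len(bqtl_ids) >= 5:
        bqtl_sites = data.sites[data.sites["site_id"].isin(bqtl_ids)]
        K_sets = [
            vcap_mod.build_kinship(data.genotypes.loc[bqtl_ids].to_numpy().T),
        ]
        bg_rng = cfg.rng("background")
        bg_ids = vcap_mod.sample_matched_background(bqtl_sites, data.sites, bg_rng)
        rest_ids = data.genotypes.index.difference(
            pd.Index(bqtl_ids).union(bg_ids)
        )
        K_sets.append(vcap_mod.build_kinship(data.genotypes.loc[bg_ids].to_numpy().T))
        K_sets.append(vcap_mod.build_kinship(data.genotypes.loc[rest_ids].to_numpy().T))
        traits = vcap_mod.simulate_traits(K_sets, config.h2, config.n_traits, rng)
        records = []
        for name in traits.columns:
            est = vcap_mod.reml_fit(traits[name], K_sets)
            for comp, p in zip(("bqtl", "background", "rest", "residual"),
                               np.append(est.proportions, est.residual_proportion)):
                records.append({"trait": name, "component": comp,
                                "proportion": float(p), "converged": est.converged})
        vcap_estimates = pd.DataFrame.from_records(records)
    else:
        vcap_estimates = pd.DataFrame(columns=["trait", "component", "proportion", "converged"])

    genes = data.annotations.genes.copy()
    amp_pos = positions.reindex(
        mp_records[cond0].loc[mp_records[cond0]["is_amp"], "site_id"].unique()
    ).to_numpy()
    gene_rng = cfg.rng("annotations")
    genes["ase_class"] = np.where(
        gene_rng.random(len(genes)) < 0.3, "ASE", "non_ASE"
    )
    promoter = enrich_mod.promoter_ase_enrichment(genes, amp_pos)

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=cfg.seed,
        stage_counts={
            "sites": len(data.sites),
            "mps": int(mp_records[cond0]["is_mp"].sum()),
            "amps": int(mp_records[cond0]["is_amp"].sum()),
            "bqtl": int((bqtl_records[cond0]["sig_class"] != "none").sum()),
            "linkage_groups": int(bqtl_records[cond0]["group_id"].nunique()),
            "condition_pairs": int(len(groups)),
        },
    )

    result = PipelineResult(
        data=data,
        mp_records=mp_records,
        meth_classes=meth_classes,
        bqtl_records=bqtl_records,
        condition_groups=groups,
        vcap_estimates=vcap_estimates,
        promoter_enrichment=promoter,
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        tables = dataset_tables(data)
        for cond, recs in mp_records.items():
            tables[f"mp_records_{cond}"] = recs
        for cond, recs in bqtl_records.items():
            tables[f"bqtl_{cond}"] = recs
        tables["vcap_estimates"] = vcap_estimates
        paths = write_fixtures(tables, out)
        for p in paths:
            manifest.output_digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        (out / "manifest.json").write_text(manifest.to_json())
    return result
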