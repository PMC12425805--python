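"""Call MPs and AMPs on one condition of a synthetic panel.

An MP is a variant inside a footprint peak with >7 RPGC on one allele
and at least one read on the other; an AMP is an MP whose allelic read
ratio deviates from 1:1 (exact binomial test, 1% FDR), surviving the
WGS-control percentile filter.
"""

from pancistrome import SimConfig, call_amps, call_mps, simulate_dataset, wgs_control_filter
from pancistrome.footprints import pool_replicates

cfg = SimConfig(n_sites=1_000, seed=42)
data = simulate_dataset(cfg)

pooled = pool_replicates(data.coverage["WW"])
in_peak = data.sites.set_index("site_id")["in_peak"]
mps = call_mps(pooled, in_peak)
amps = call_amps(mps, fdr=0.01)
filtered = wgs_control_filter(amps, data.wgs_ratio)

n_mp = int(filtered["is_mp"].sum())
n_amp = int(filtered["is_amp"].sum())
n_excl = int(filtered["wgs_excluded"].sum())
print(f"site x line records: {len(filtered)}")
print(f"MPs: {n_mp}, AMPs: {n_amp} ({100 * n_amp / n_mp:.1f}% of MPs)")
print(f"AMPs removed by the WGS control filter: {n_excl}")
print()
print("The AMP rate reflects the simulated fraction of causal variants;")
print("the WGS filter removes sites whose control allelic ratio is in the")
print("extreme 5% tails, i.e. likely mapping artifacts.")
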