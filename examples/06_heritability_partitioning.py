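"""Partition trait variance across bQTL / background / rest SNP sets.

Traits are simulated with known heritabilities from three kinship
matrices (the study's own validation design) and re-estimated with
multi-component REML.
"""

import numpy as np

from pancistrome import build_kinship, reml_fit, simulate_traits
from pancistrome.vcap import simulate_structured_genotypes

rng = np.random.default_rng(1)
kinships = [
    build_kinship(simulate_structured_genotypes(400, 1_000, rng))
    for _ in range(3)
]
truth = (0.4, 0.2, 0.2)  # bQTL, background, rest; residual 0.2
traits = simulate_traits(kinships, truth, 10, rng)

props = np.array(
    [
        np.append(e.proportions, e.residual_proportion)
        for e in (reml_fit(traits[c], kinships) for c in traits.columns)
    ]
)
names = ("bQTL", "background", "rest", "residual")
full_truth = (*truth, 1 - sum(truth))
print(f"{'component':>10}  truth  mean estimate  sd")
for j, name in enumerate(names):
    print(f"{name:>10}  {full_truth[j]:.2f}   {props[:, j].mean():.3f}        "
          f"{props[:, j].std(ddof=1):.3f}")
print()
print("Mean estimated proportions track the simulated heritabilities,")
print("validating the REML partitioning before it is applied to traits")
print("whose true architecture is unknown.")
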