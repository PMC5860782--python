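"""Is an observed copy-number vector significantly balanced?

Compares the distance from observed to balanced copies against the same
distance for random copy-number vectors drawn from a genome-wide abundance
distribution.  A small p-value means the observed copies are closer to
balance than chance expects.
"""

import numpy as np

from stoichbal import AbundanceDistribution, balance_significance
from stoichbal.fixtures import chain_network, chain_copies_balanced

net = chain_network()
dist = AbundanceDistribution(mode="lognormal", mu=np.log(80.0), sigma=0.8)

report = balance_significance(
    net, chain_copies_balanced(), dist, alpha=1.0, n_rand=500, seed=0
)
print(f"chi-square distance (observed) : {report.csd_real:.4g}")
print(f"Jensen-Shannon divergence      : {report.jsd_real:.4g}")
print(f"p-value (CSD) = {report.p_csd:.4g}, p-value (JSD) = {report.p_jsd:.4g}")

# A perfectly balanced input has distance 0, so its p-value is the
# smallest achievable with this null sample: 1/(n_rand+1).
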