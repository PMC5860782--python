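"""Balance a small interface-resolved network.

Builds a competitive three-protein chain A-B-C (B binds both partners
through one interface, so balance requires B = A + C), perturbs the middle
protein's copies, and solves for the nearest balanced copy numbers.
"""

from stoichbal import build_system, solve_balance, protein_copies, expression_ratio
from stoichbal.fixtures import chain_network

net = chain_network()
observed = {"A": 50.0, "B": 160.0, "C": 50.0}   # 60 leftover copies of B

system = build_system(net, observed, alpha=1.0)
result = solve_balance(system)
balanced = protein_copies(result)
ratios = expression_ratio(observed, balanced)

print("desired complexes per edge:", [round(float(x), 2) for x in result.x_min])
print("balanced copies:", {k: round(v, 1) for k, v in balanced.items()})
print("observed/balanced ratio:", {k: round(v, 2) for k, v in ratios.items()})

# The optimizer splits the imbalance between raising the partners and
# lowering B: a ratio above 1 flags overexpression (B here), below 1
# underexpression.  With balanced input (50/100/50) the solver returns the
# input unchanged at any alpha.
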