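# Methods

## The balance program

An interface-interaction network (IIN) refines a protein-protein
interaction network by recording which binding interface carries each
interaction. With A the interface-by-edge incidence matrix (entries 1, or
2 for a self-interaction, so every column sums to 2) and x ≥ 0 the vector
of desired pairwise complexes, a balanced assignment of interface copies
is C = A x. Given observed copies C₀ the package minimizes

    α (A x − C₀)ᵀ Z (A x − C₀) + (A x)ᵀ H (A x),   x ≥ 0.

Choices made where the formulation was open:

* **H as a per-protein complete-graph Laplacian.** Any PSD matrix whose
  kernel is exactly the per-protein-equal vectors yields the same
  balanced solutions; the Laplacian is the canonical such matrix and
  makes objective values reproducible. Scaling differences against other
  valid H choices shift objective values by constants but not minimizers.
* **Exact solve by NNLS.** Both terms are squared seminorms of linear
  images of x, so the QP stacks into one nonnegative least-squares
  problem solved by the Lawson–Hanson active-set method
  (`scipy.optimize.nnls`): deterministic, exact for this convex class, no
  iterative tolerance to tune. Degeneracy (a nontrivial null space of the
  Hessian 2αAᵀZA + 2AᵀHA) is detected by an eigenvalue check and flagged
  on the result; the active-set solution is a deterministic vertex of the
  optimal face rather than the minimum-norm point.
* **α defaults to 1**, the headline setting; the useful sweep range is
  0.01–2. Raising α weights fidelity to C₀ more, which provably does not
  increase the Z-weighted distance term and empirically raises
  intra-protein interface variance ("noise", population σ²/μ² per
  protein; single-interface proteins report 0, zero-mean-with-variance
  reports infinity).
* **x ≥ 0 exactly.** No positive floor is imposed; a floor can be
  emulated by adding a constant to C₀ but is deliberately not a solver
  option.

Protein-level balanced copies are the arithmetic means of each protein's
interface copies; over/underexpression is the ratio observed/balanced
(NaN when balanced copies are zero and observed are not).

## Balance significance

Distances between observed and balanced protein copies: chi-square
distance Σ(Xᵢ−Yᵢ)²/(Xᵢ+Yᵢ) (terms with zero denominator contribute 0) and
the Jensen–Shannon divergence in natural log (after normalizing both
vectors; bounded by ln 2; the divergence, not its square root). Distances
are computed on protein-level copies since over/underexpression is
reported per protein.

The null model draws random copy vectors (empirical resampling from an
abundance pool, parametric log-normal, or permutation of the observed
vector) and solves the same balance program for each. The one-sided
p-value uses the (r+1)/(n+1) estimator, which is super-uniform under the
null at finite n and never exactly zero. Null draws that fail to solve
are counted and excluded.

The default parametric null is log-normal with median 1000 copies and
σ(log) = 1.5 — a reasonable stand-in for a yeast whole-proteome abundance
distribution, which spans a few copies to over a million with a heavy
right tail. Real analyses should pass their own genome-wide pool in
empirical mode.

## Binary misinteraction engine

Competitive binary binding A_i + A_j ⇌ C_ij with every unordered species
pair classified specific, nonspecific, or absent. K_D values are molar
and converted to copy units through an effective volume chosen so 50
copies ≈ 1 µM; the absolute volume shifts only the free fraction, while
cost ratios are governed by the K_D ratio. koff is 1 s⁻¹ for every pair
(kon = koff/K_D), so equilibria depend on K_D alone. The direct Gillespie
method runs in time windows of 10/koff; steady state is declared when the
windowed mean total occupancy drifts < 1% between consecutive windows,
and reported occupancies are time averages over the final window. Default
replicate counts: 1000 for surfaces, 5000 for single-point estimates;
tests and examples use fewer.

Two numerical details: copy numbers are rounded to whole molecules on
model construction (the stochastic simulator counts discrete molecules;
balanced projections are real-valued), and the steady-state drift
criterion uses an absolute floor of √(total copies) so that weakly bound
systems, whose windowed occupancy fluctuates on that scale, terminate.

Misinteraction cost is N_ns/(N_s + N_free) in complex counts, or
2N_ns/(2N_s + N_free) in protein counts (used for the large-network
study); 0/0 is 0. Motif cost surfaces vary two proteins' copies with the
rest fixed at 50, axes normalized by the fixed abundance. Sensitivity to
imbalance is the percent cost increase along the first principal
component of the lowest-decile (lowest-cost) grid points, interpolated
through the optimum; the optimum can be overridden for motifs (the chain)
whose global minimum is a trivial edge of the grid.

Large-network studies use the static-model generator: node i carries
weight i^(−γ), edges are drawn with probability proportional to the
weight product and rejected until unique, one interface per protein.
γ = 0 gives binomial degrees; γ → 1 approaches scale-free. The
topology optimizer performs greedy edge swaps that reduce
chains + triangles − squares − hubs (unit weights) while preserving edge
count and connectivity class. Balanced copies for single-interface
networks come either from an equal-complex assignment (copies
proportional to degree) or the projection min ‖Ax − C₀‖², x ≥ 0. Per-edge
affinities default to the fixed gap K_D,specific = 100 nM,
K_D,nonspecific = 100 µM; a per-pair table can be supplied.

## Network-free rule engine

Molecules are typed site-graphs; repeated site names declare equivalent
instances of one site class (a triskelion's three legs). Rules bind two
site classes; propensities aggregate per rule over global free-site
counts, split by compartment. A sampled pair inside one complex fires as
a null event — an exact thinning of the chain, as in network-free
simulators generally. Bond dissociation is per-bond at the rule's koff.
Complex splits are detected by bidirectional search from the severed
endpoints.

Membrane: a complex is membrane-associated iff it contains a lipid
(membrane-resident molecule). When both partners are membrane-associated,
kon is multiplied by Vol_CP/(SA_PM·2σ) ≈ 246 for the default geometry
(37.2 µm³, 75.7 µm², σ = 1 nm) — the copy-unit form of
K_D²ᴰ = K_D³ᴰ/2σ. Doubling σ halves the enhancement exactly. There is no
other spatial resolution, and no steric hindrance: aggregates can grow
arbitrarily, which is the known reason adaptor loads per vesicle are
physically implausible (≈ 16.5 nm² of membrane per adaptor on a 100 nm
vesicle carrying 1900 of them).

Cooperative ring closure, when enabled, immediately closes a specific
bond between two molecules already held together through one shared
neighbor (a trimer held by two bonds gets its third "at an arbitrarily
high rate"). Distant intra-complex pairs still require a bimolecular
encounter. Closure is off in the clathrin module.

## ARP2/3 assembly model

Seven subunits; the core subunit ARC19 binds five others; peripheral
contacts follow the crystal-structure contact map (ARP2–ARP3, ARP3–ARC18,
ARC40–ARC35) and are configurable. Core bonds are 10-fold stronger than
peripheral bonds. Copies: 250 per subunit balanced; core-depleted
("observed-like") sets ARC19 to 50, the ~5-fold underexpression seen in
yeast proteomics. Yield is N_desired/(N_desired + N_undesired) over
proteins in complexes, free monomers ignored; a complex is complete when
it holds exactly one of each subunit with every topology edge bonded.

**Rate convention.** The sweep holds kon at a diffusion-limited
10⁶ M⁻¹s⁻¹ and varies koff = kon·K_D ("fixed-kon"), so strong binders
have long-lived bonds. This matters: obligate-complex interfaces are
effectively permanent on assembly timescales, and misassembled
intermediates (two cores bridged through peripheral bonds, peripheral
dimers) persist rather than annealing away. Under the alternative
fixed-koff convention every sweep point relaxes equally fast and yields
climb toward complete annealing, erasing the copy-number dependence the
model exists to measure. The default sweep spans peripheral K_D = 10 nM
to 0.1 nM (core 10× stronger), t_end = 60 s, a few replicates per point;
reported is the maximum mean yield over the sweep. Typical outcomes:
balanced ≈ 41–45%, core-depleted ≈ 14–16%, insensitive to the absolute
copy scale between 100 and 1000 per subunit.

## Clathrin vesicle module

Nine proteins plus the membrane lipid. Heavy chains enter pre-trimerized
(3 leg + 3 light-chain + 3 adaptor sites); ENT1/2 are merged. All
affinities, copies, geometry and rates are the literature values carried
in `CME_PARAMS`; koff = 1 s⁻¹ throughout. ENT and the two YAP paralogs
compete for the triskelion's three adaptor sites; SLA2 reaches clathrin
through the light chain. Lipids are a finite membrane population (density
× area ≈ 1.9 M sites); lipid binding defines membrane association.
Table-row fidelity: YAP1801 carries the lipid-binding site, YAP1802 the
EDE1-binding site, each printed affinity applied exactly as labeled.

Any membrane complex containing ≥ 100 full triskelia (heavy-chain trimer
with all three light chains bound) is a vesicle: deleted at
k_dump = 1000 s⁻¹, members re-injected one at a time at k_recyc = 1000 s⁻¹
(proteins to the cytosol, lipids to the membrane), conserving every
molecule type. Each triskelion's first entry into a membrane-associated
complex is attributed to the bond that caused it: clathrin–clathrin
polymerization versus any adaptor/scaffold-mediated bond.

Generated misinteractions add a nonspecific rule for every *protein* site
pair lacking a specific rule at K_D = f·√(K_D,mean,1·K_D,mean,2), each
site's mean being the geometric mean of its specific K_Ds (the arithmetic
mean of binding energies); f = 10⁴ is an energy gap of ln 10⁴ ≈ 9.21 kBT,
f = 10³ ≈ 6.91 kBT. The lipid head-group is excluded: with ~1.9 M lipids
even mM-scale nonspecific lipid binding would swamp the system, and the
misinteraction model concerns protein interfaces.

A `scale` switch multiplies all copies with volume and membrane area
co-scaled, preserving every concentration, for fast exploratory runs; the
vesicle threshold stays at 100 triskelia. Baseline full-scale runs give
≈ 18–19 adaptor/scaffold proteins per full triskelion and ≈ 96% of
triskelia first membrane-bound through an adaptor; with f = 10³
misinteractions the per-vesicle adaptor load roughly triples because
misbonds sequester light chains (fewer full triskelia per aggregate) and
glue extra adaptors in — the qualitative signature expected of strong
misinteractions, though the magnitude of the ratio is sensitive to the
exact site structure assumed for the adaptor competition.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the study sizes: 1000 Gillespie replicates for
the triangle endpoint, the clathrin module at full literature scale (five
baseline vesicles; three with misinteractions), and 6 replicates per
sweep point for ARP2/3. The pytest suite checks the same endpoints at
reduced replicate counts (hundreds of runs, 3–4 vesicles) with
statistical tolerances widened by the correspondingly larger standard
errors, plus brute-force oracles (grid search for the QP, subgraph
enumeration for motifs, birth–death closed forms for equilibria) at
problem sizes where exhaustive computation is exact.

## Known limitations

* No steric hindrance or excluded volume: adaptor aggregates and vesicle
  compositions are upper bounds on physical ones.
* Two compartments only; no membrane mechanics, scission, cargo, or
  cytoskeleton.
* The synthetic abundance null is log-normal, not a measured proteome;
  significance against it demonstrates the machinery, not a biological
  claim.
* The balance metric ignores binding affinities and temporal expression;
  strongly and weakly bound partners weigh equally in C₀ demand.
* Interface-reassignment rewiring preserves the parent protein graph and
  interface counts but is one member of the family of such null models;
  conclusions about competitive-vs-noncompetitive structure should be
  checked against alternatives.
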