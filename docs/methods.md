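# Methods

This note documents the models implemented in `tetra`, the defaults and
numerical choices behind them, and what the synthetic-data suite does and
does not establish about real data.

## Cross-link restraints

A detected cross-link is a residue pair bridged by a linker of known span.
For DSS (disuccinimidyl suberate, lysine-reactive) the conventional
residue-level window is 3–24 Å, applied here between **Cβ anchor atoms**,
falling back to Cα for glycine. Cβ is chosen because DSS bridges side
chains and 24 Å is the usual Cβ–Cβ cap for this linker; the anchor rule is
configurable to Cα–Cα, and both bounds can be overridden per restraint set.

Cross-links involving a homodimeric molecule are intrinsically ambiguous —
the peptide evidence cannot distinguish the two chemically identical
chains. A link touching a protein with k assigned chains on one side and m
on the other expands into a k×m OR-group; the group counts as satisfied
when any member's anchor distance falls inside the window. This mirrors
the ambiguous-interaction-restraint convention of docking engines, and the
HADDOCK-dialect export renders each group as one CNS `assign` statement
with `or` alternatives (distance d, minus-correction d−lower, plus 0).
Export output is sorted by chain and residue and is byte-deterministic.

The domain-pair contact matrix buckets each link by the domains of its two
residues and counts it once under the lexicographically sorted label pair,
so the matrix total equals the number of links. The catalytic subunit's
architecture is built in (activation peptide 1–37, β-sandwich 38–183,
catalytic core 184–515, β-barrel-1 516–627, β-barrel-2 628–731, 1-based
inclusive); the carrier subunit's ten ~60-residue sushi domains have no
published residue boundaries, so sushi maps are user-supplied
(`uniform_domain_map` builds equal-length approximations).

Residue numbering is preserved from the source PDB. `renumber_continuum`
merges chains into one continuously numbered chain (chain k offset by the
cumulative maximum residue index of its predecessors) for docking servers
that only accept bimolecular input, and returns the bijection needed to
map results back.

## AFM topograph simulation and envelope docking

A topograph is a height grid h(x, y) in nm over a flat substrate (h = 0).
The simulator uses hard-sphere tip dilation: an atom of radius r at height
z_a probed by a spherical tip of radius R contributes
z_a + sqrt((r+R)² − d²) − R at lateral distance d wherever the root is
real. The model is grounded so the lowest atom sphere touches the
substrate, and its centroid is placed on the center pixel's center. The
commensurate placement matters: the rigid search below samples centroid
positions at pixel centers only, and an incommensurate simulated placement
would be unreachable by construction — near the steep dilated rim the
nearest reachable pose can then protrude past the clash tolerance and the
self-recovery property would fail for purely geometric reasons.

Docking is an exhaustive search over a rotation grid (default: z-axis
rotations in 30° steps, appropriate for flat adsorbates; a full Euler grid
is available) times every integer-pixel lateral placement. Each pose is
grounded (lowest atom center at z = 0) and scored by the number of atoms
inside the favorable layer — the shell of thickness t (default 1.0 nm)
just beneath the envelope: favorable iff h − t ≤ z ≤ h at the atom's
pixel. The score maps to a pseudo-energy E = −N_favorable, the simplest
monotone mapping under which the best score is the lowest energy. Any atom
more than the clash tolerance (default 0.3 nm) above the envelope
invalidates the pose, because the envelope is a physical upper bound on
where matter can be; a soft mode (energy penalty per protruding atom) is
available behind a flag for exploration. Neither the layer thickness nor
the clash tolerance has a published value; both are explicit parameters
recorded in the result diagnostics.

Up to `keep` poses (default 10⁵) are retained, ranked by energy with a
deterministic tie-break (angle, then grid row, then column). The result
reports the four standard statistics: minimum energy, mean energy of the
top 10, mean pairwise Cα RMSD of the top 3 placements **without
superposition** (docked poses live in a common frame, so superposing would
erase exactly the differences of interest), and the lateral offset of the
best pose's centroid from the grid center. The per-rotation scoring is
vectorized by noting that with centroids on pixel centers every atom falls
in a fixed integer-offset pixel, so all placements for one rotation are
scored with shifted array slices; the same pose scored in isolation
(`score_pose`) reproduces the search result exactly, which the tests
exploit against a brute-force enumeration oracle.

## Titration calorimetry forward model

Stepwise (sequential) schemes M + A ⇌ MA ⇌ MA₂ (⇌ MA₃) are parameterized
by per-step dissociation constants and molar enthalpies. Ligation-state
populations follow the binding polynomial Φ([A]) = 1 + Σ_j β_j[A]^j with
β_j = Π_{i≤j} 1/K_{d,i}; the free-ligand concentration solves the mass
balance A_tot = [A] + M_tot·ν([A]), whose left side is strictly increasing
in [A], so the root is unique and bracketed by [0, A_tot]. It is found by
Brent's method at machine tolerance. The classic single-set-of-sites model
(n identical independent sites) is also provided; with n = 1 it is
identical to a one-step sequential scheme (verified to 1e-12 in the
tests), and its state decomposition for integer n follows binomial site
filling.

The injection model is the displacement (perfusion) convention for
overfilled cells: injecting volume v into cell volume V₀ expels the
fraction v/V₀ of the current contents, so prior totals scale by (1 − v/V₀)
while the injectant adds c_syr·v/V₀. The cell heat content is
H = V₀·Σ_j ΔH_j·[states with ≥ j ligands]; injection i releases
q_i = H_i − H_{i−1}(1 − v_i/V₀), reported per mole of injected titrant. A
no-displacement mode exists for cross-checks against closed forms (total
saturated heat V₀·M₀·ΣΔH; the Wiseman inflection value at finite c). A
constant per-injection offset models the heat of dilution (default 0 for
synthetic data, standing in for blank subtraction).

Defaults the experiments leave unstated, chosen once as instrument-typical
for a MicroCal-class calorimeter and used throughout: cell volume 200 µL;
schedule 0.4 µL + 19 × 2 µL; association temperature 298.15 K
(dissociation experiments are at 303.15 K, which is stated). Free energies
use the 1 M standard state, ΔG = RT ln(K_d/1 M) with R = 8.314 J/(mol·K),
and −TΔS = ΔG − ΔH, so positive −TΔS denotes entropically unfavorable
binding. Heats are kJ/mol throughout.

## Fitting

The fit minimizes Σ w_i (q_obs,i − q_model,i)² with unit weights by
default (no published error model; 1/σ² weights can be supplied when an
isotherm carries noise metadata). K_d parameters are optimized as log₁₀
values — they span nM to mM, and the log scale keeps positivity without
constrained solvers — while enthalpies are linear. Bounded trust-region
least squares (scipy `least_squares`, trf) runs from a deterministic
multistart: the declared initial point plus seven seeded perturbations
(±1 decade on log-K_d, ±50% on enthalpies), keeping the best-RSS solution.
This replaces the interactive iterate-until-stable loops of commercial ITC
software with a reproducible, seed-logged procedure. Parameters may be
held fixed (e.g., a first calcium event pinned to the literature
K_d = 100 µM); with everything fixed the forward-model RSS is returned
without optimization. The first injection is excluded by default (the
standard small-purge anomaly convention).

Identifiability is governed by the Wiseman c-value, c = M₀/K_d per step.
Steps with c > 1000 produce near-vertical transitions whose K_d the data
only bound; these are flagged `bounded_only` in the diagnostics rather
than reported as point estimates. At the other extreme (c near 1) the
K_d–ΔH pair of a shallow step is strongly correlated: sums of adjacent
step enthalpies are determined much more tightly than their split, and
under noise the individual estimates have heavy-tailed sampling
distributions even when the fit finds the global minimum. The noisy
recovery tests show this concretely: with 0.5% noise the three-step
calcium scheme recovers event-1 ΔH to fractions of a percent, Kds of the
identifiable steps within a factor of two, while the event-2/event-3
enthalpy split scatters tens of percent around the truth — a property of
the experiment design, not of the optimizer.

Uncertainty comes from a residual-resampling bootstrap (2.5/97.5
percentile intervals, seed-reproducible, refits started from the base
estimate); model selection uses small-sample AICc,
n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), ranked ascending with stable ties.

## Synthetic data

Generators are pure functions of (parameters, seed). The atomic toys
(helix or bead chains with Cα/Cβ anchors, ≥2 Å self-avoidance, optional
planted glycines) and the bipartite particle (a compact ball plus a thin
low-lying arm, emulating a compact body with filamentous extensions) are
geometric stand-ins: they carry no real sequence, no sushi-domain
topology, and no side-chain chemistry. Cross-link sets plant an exact
fraction of in-window anchor distances, so restraint bookkeeping can be
checked against construction; isotherm and topograph noise is iid
Gaussian (heights clipped at the substrate, clip count recorded), the
simplest model consistent with integrated-heat and height-map errors.

Passing tests therefore demonstrate that the computations are correct and
self-consistent — restraint satisfaction matches brute-force distances,
docking matches exhaustive enumeration and recovers planted placements,
fits recover generating parameters at the stated tolerances — not that
real micrograph heights or calorimetric traces are reproduced. Published
field maxima from real topographs (a few to ~20 nm depending on the
species) depend on instrument data and adsorption effects that are out of
scope here.

## Problem sizes

The default test and acceptance runs use 20-injection titrations,
topographs of order 10–60 pixels per side with a few hundred atoms, and
20-seed noise ensembles; these sizes make every oracle comparison exact
and keep full runs fast while exercising each code path at the same
parameter values the analyses use.

## Known limitations

* PDB only (wwPDB v3.3 fixed-width); no mmCIF, no insertion codes, no
  hydrogens, no energy minimization.
* Sequential schemes support one to three steps; cooperative or
  site-specific models beyond single-set and sequential are not included.
* Raw thermogram integration (power vs time) and peptide-spectrum
  identification are upstream of this package; inputs are integrated
  per-injection heats and residue-pair tables.
* The rigid AFM search samples z-axis rotations by default; fully
  unconstrained orientation search is available but scales with the cube
  of the angular resolution.
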