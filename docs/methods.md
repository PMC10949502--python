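# Methods

## Scope and model

`glutaflux` performs constraint-based analysis for strain design on a
curated central-carbon core network of *Corynebacterium glutamicum*
(74 reactions, 62 species, single cytosolic compartment plus boundary
species). The network covers PTS and PTS-independent glucose uptake,
glycolysis/gluconeogenesis (including fbp), the oxidative and non-oxidative
pentose phosphate pathway, pyruvate dehydrogenase, the complete TCA cycle,
the glyoxylate shunt (aceA/aceB), both C4 anaplerotic carboxylases (pyc,
ppc) plus PEP carboxykinase and malic enzyme, fermentative and
transamination drains (ldh, alaT, alaD, gdh), the branched-chain pathways
to L-valine and L-leucine, acetate activation (pta/ackA), a lumped
respiratory chain, a lumped biomass pseudo-reaction and an ATP-maintenance
pseudo-reaction. An optional augmentation adds the two bifunctional
phosphoketolase reactions (F6P + Pi → E4P + AcP; X5P + Pi → G3P + AcP) of
the bifido shunt. The full inventory with equations, bounds, gene tags and
subsystems is in `core_model_reactions.tsv`.

All fluxes are mmol gCDW⁻¹ h⁻¹. The steady-state assumption is purely
stoichiometric: S·v = 0 with box bounds per reaction; no thermodynamic,
kinetic or regulatory constraints, and the gene field is an annotation only
(no GPR logic).

### Elemental bookkeeping

Metabolite formulas track carbon and nitrogen only. Cofactors carry their
real C/N (NAD(P)(H) C21N7, ATP/ADP C10N5, CoA C21N7) so paired conversions
cancel; species without carbon or nitrogen (O2, Pi, H2O) carry an
explicitly empty composition. `check_mass_balance` verifies every
non-pseudo internal reaction over whatever elements are present; the
generated model always audits clean, and the test suite enforces it.
Biomass, maintenance and the two demand probes are flagged pseudo and
exempt.

### Deliberate simplifications

* **Succinate dehydrogenase** transfers electrons to the NAD pool (the FAD
  step is lumped into the single redox currency).
* **Respiration** is one lumped reaction, NADH + ½O2 + 2 ADP + 2 Pi →
  NAD + 2 ATP (P/O = 2). Oxygen uptake is unrestricted.
* **PTS-independent uptake** (IolT permease + polyphosphate glucokinase)
  phosphorylates glucose without drawing on the ATP pool; the proton motive
  force and the poly-P reservoir that pay for it in vivo are outside the
  model boundary. Without this route a PTS-only network cannot realise the
  full phosphoketolase ceiling (pure bifido-shunt flux generates no
  NADH/ATP to regenerate PEP from the PTS-released pyruvate).
* **NADPH** is supplied by zwf/gnd, icd and the malic-enzyme cycle
  (pyc + mdh + malE), the ATP-driven, carbon-neutral transhydrogenase-like
  cycle this organism actually uses. Without a carbon-free NADPH source the
  valine ceiling would drop from 1.00 to 6/7 mol/mol.
* **Biomass composition** is an invented convention on the standard
  precursor-demand scale (mmol per gCDW: pyruvate 2.8, oxaloacetate 1.8,
  2-oxoglutarate 1.1, acetyl-CoA 3.7, E4P 0.4, R5P 0.9, NH4 10, ATP 40,
  NADPH 16). Absolute growth rates are therefore conventions of this model;
  only zero/nonzero growth and orderings are meaningful, and no test
  asserts a growth-rate value.
* **Maintenance ATP** defaults to 2.0 mmol gCDW⁻¹ h⁻¹ in growth
  simulations and is switched off inside theoretical-yield calculations,
  which are stoichiometric ceilings by definition.

## Solvers

All three solvers sit on one LP contract (`solve_lp`), backed by scipy's
HiGHS with fixed options, so repeated runs are deterministic.

* **FBA** maximises the objective under S·v = 0, bounds and the substrate
  cap (imposed as lower bound −4.67 on the glucose exchange; uptake is
  negative by the standard sign convention).
* **FVA** holds the objective at a fraction of its optimum (multiplicative
  for a nonzero optimum, threshold 0 for a zero optimum, avoiding the
  degenerate fraction-of-zero) and min/maximises each reaction: 2N LPs.
* **Geometric FBA** returns a unique central point of the optimal face:
  iterate FVA at fraction 1.0, L1-project onto the interval midpoints,
  shrink the box halfway toward the midpoints (widened, if necessary, to
  retain the projection point — this keeps every iterate provably
  feasible), and stop when the widest interval is below
  √(lp_tolerance) ≈ 3×10⁻⁵ or after 30 iterations, raising an error that
  carries the last iterate on non-convergence. Downstream comparisons of
  flux states always use geometric FBA; raw FBA vertices of degenerate
  optima are never compared.

The solvers are certified in the test suite against an independent
brute-force oracle: exhaustive vertex enumeration (basis fixing + linear
solves) on ≤6-reaction random networks over 100 seeds, for both the FBA
optimum and FVA interval ends. cobrapy serves as a second, independent
cross-check on the bundled SBML file.

## Design workflow

* **Essentiality classification** runs FVA on the model with the biomass
  floor installed (biomass ≥ f·μmax, default f = 0.2) and the production
  objective left free. Intervals excluding zero (after ε-rounding,
  ε = 10⁻⁶) are *essential* — a deliberate widening of the narrower
  "min = max ≠ 0" reading, so that required-but-variable reactions are not
  dropped from the partition; identically-zero intervals are *blocked*;
  everything else is *substitutable*. Pinning the production objective at
  its optimum instead would collapse every pure drain to blocked (at a
  carbon-limited production optimum no flux can be wasted), which
  contradicts the known substitutability of the ldh/alaT drains; the
  floor-only constraint is therefore the implemented reading.
* **Regulation modes** compare the geometric-FBA growth state with the
  biomass-constrained production state: U when production flux magnitude
  exceeds growth, D when it falls short *and* the reaction is essential,
  KO for substitutable/blocked reactions carrying no production flux,
  none otherwise.
* **Theoretical yield** fixes substrate uptake at 1, disables maintenance,
  leaves biomass at its natural zero and maximises product export; yield is
  export/uptake in mol/mol.
* **Attenuation sweep**: the control is the geometric-FBA *growth* state of
  the production-configured model with glucose uptake fixed at the cap
  (the native flux through the target). Each row caps the target's flux
  magnitude at r × control (an upper bound, not an equality — a cap is the
  natural reading of "decreased flux" and cannot manufacture spurious
  infeasibility; an equality variant is available behind a flag) and
  re-solves growth by geometric FBA. Fixing the uptake keeps the carbon
  budget identical across rows, so attenuating the TCA entry forces the
  surplus into the product pathway — the r = 1.0 row is the control itself
  by definition, and infeasible rows are recorded rather than raised.
  Relative fluxes are reported as flux/control with 0/0 → 1 ("no change").

## Genotype presets

* `leucine_producer`: ldh/alaT/alaD deleted, lactate/alanine/valine/acetate
  secretion closed — surplus pyruvate can only leave through the leucine
  pathway.
* `LEU-28`: producer + Δpyc Δppc with the glyoxylate shunt closed; no route
  to oxaloacetate remains and maximal biomass is exactly zero.
* `LEU-29`: LEU-28 with isocitrate-dehydrogenase capacity scaled to 20%
  (the icd R543S lesion, ≈80% activity loss, modelled purely as a bound
  scaling — no kinetics) and the glyoxylate shunt opened; C4 supply and
  growth return. With the default ±1000 bounds the 0.2 scaling is
  non-binding; it is retained for fidelity to the genotype, and the rescue
  is driven by the shunt opening.
* `acetate_media`: glucose closed, acetate uptake 1, glyoxylate shunt open
  (acetate induces aceBA). The shunt is closed in glucose-grown wild type,
  reflecting its transcriptional repression, and presets open it rather
  than any regulatory model.

## sRNA design

Window coordinates use biological numbering with no position 0 (−1 abuts
+1; the A of ATG is +1). The default binding window is +1..+24, giving the
24-nt antisense residue; the statement "spanning AUG to +21" conflicts with
the stated 24-bp length under this rule (+1..+21 is 21 nt), and the length
is taken as authoritative. The wider −4..+48 GFP window gives 52 nt.
Cassettes are assembled binding–scaffold–terminator. The bundled scaffold
and terminator sequences are deterministic synthetic stand-ins (labelled so
in filename and FASTA headers) — they fix lengths for testing and must be
replaced with validated scaffold sequences, via user FASTA, before any
construct design. Folding-energy optimisation is delegated to external
folding software and intentionally absent.

## What the synthetic network does and does not show

The generator is the study's data source: there is no public
machine-readable model to load, so the core network re-creates the pathway
scheme at reduced scale with exact elemental bookkeeping. Stoichiometric
ceilings (yields, shunt ratios) are genuine properties of the pathway
chemistry and transfer to any correctly-curated larger model; absolute
fluxes, growth rates and the constrained-yield pairs of a genome-scale
reconstruction depend on its biomass equation and maintenance values and
are *not* reproduced here. Passing tests certify solver correctness,
classification logic and pathway stoichiometry — not fermentation
performance.

## Numerical choices

LP feasibility/optimality tolerance 10⁻⁹ (HiGHS defaults are tighter than
the tolerances asserted anywhere in the tests); classification ε 10⁻⁶;
geometric-FBA convergence width √(lp_tolerance); "unbounded" flux magnitude
1000. Exported tables format floats to 12 significant digits, making
repeated pipeline runs byte-identical on one host. Degenerate optima are
handled exclusively through FVA intervals or geometric FBA. Problem sizes
throughout (74-reaction core model, ≤6-reaction oracle networks, 100 oracle
seeds, 10 sweep rows) keep any single analysis under a minute on one CPU.
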