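# glutaflux

Constraint-based strain design on a *Corynebacterium glutamicum*
central-carbon core model: flux balance analysis (FBA), flux variability
analysis (FVA) and geometric FBA; reaction-essentiality classification;
regulation-mode recommendation; theoretical product yields; flux-attenuation
sweeps; the phosphoketolase ("bifido shunt") augmentation; and antisense
sRNA cassette design.

## The problem

Pyruvate-derived amino acids (L-alanine, L-valine, L-leucine) compete with
biomass formation for carbon. Model-guided design asks, for every reaction
in central metabolism: is it *essential* for growth-coupled production
(its feasible flux interval excludes zero), *substitutable* (the interval
spans zero — a candidate for deletion), or *blocked*? Essential reactions
that carry less flux in the production state than in the growth state are
attenuation targets (downregulate, e.g. with antisense sRNA); substitutable
drains with no production flux are knockout targets.

The package computes these calls on a curated 74-reaction core network of
*C. glutamicum* glucose metabolism (glycolysis, PPP, PDH, TCA, glyoxylate
shunt, pyc/ppc anaplerosis, ldh/alaT/alaD drains, valine/leucine pathways,
lumped respiration and biomass), generated from code with exact carbon and
nitrogen bookkeeping. Everything is an LP over S·v = 0 with flux bounds:
FBA maximises an objective flux, FVA brackets each reaction at a fixed
objective level, and geometric FBA selects the unique central optimum so
that flux states can be compared at all. See `docs/methods.md` for the
model and algorithms, `docs/core_model_reactions.tsv` for the full
reaction inventory, and `docs/model_schema.md` for the file formats.

## Worked example

```python
import glutaflux as gf

model = gf.build_core_model()
config = gf.SimulationConfig()          # glucose cap 4.67, 20% biomass floor

for exchange, name in [("EX_ala__L_e", "L-alanine"),
                       ("EX_val__L_e", "L-valine"),
                       ("EX_leu__L_e", "L-leucine")]:
    report = gf.max_theoretical_yield(model, config, exchange)
    print(f"{name:10s} {report.yield_mol_per_mol:.3f} mol/mol glucose")

records = gf.essentiality_analysis(model, config, "EX_leu__L_e")
by = {r.reaction_id: r.essentiality for r in records}
print("ldh:", by["LDH"], "| alaT:", by["ALATA"], "| acn:", by["ACONT"])

leu28 = gf.apply_genotype(gf.build_core_model(), "LEU-28")
leu29 = gf.apply_genotype(gf.build_core_model(), "LEU-29")
print("max growth  LEU-28:", gf.fba(leu28, config).objective_value,
      " LEU-29: %.3f" % gf.fba(leu29, config).objective_value)
```

prints

```
L-alanine  2.000 mol/mol glucose
L-valine   1.000 mol/mol glucose
L-leucine  0.667 mol/mol glucose
ldh: substitutable | alaT: substitutable | acn: essential
max growth  LEU-28: -0.0  LEU-29: 0.521
```

The yields are the stoichiometric ceilings of the pathways (glucose → 2
pyruvate → 2 alanine; 2 pyruvate + 2 NADPH → 1 valine; 3 pyruvate → 1
leucine with 3 CO2 released, hence 2/3). The lactate and alanine drains
classify substitutable under leucine production (deletion candidates) while
aconitase is growth-essential (attenuation target). The Δpyc Δppc strain
(LEU-28) cannot form oxaloacetate and its maximal growth is exactly zero;
attenuating isocitrate dehydrogenase and opening the glyoxylate shunt
(LEU-29) restores it.

## Command line

Each analysis maps to a subcommand:

```sh
glutaflux build-model --out core.json
glutaflux yield core.json --product EX_val__L_e
glutaflux classify core.json --product EX_leu__L_e --out essentiality.tsv
glutaflux sweep core.json --target ACONT --out sweep.tsv
glutaflux design-srna targets.fasta --out designs.tsv
glutaflux run config.yaml            # full declarative pipeline + manifest
```

Bundled pipeline configs live in `src/glutaflux/data/configs/`:
`fig1a.yaml` (classification + regulation modes + yields), `fig1e.yaml`
(aconitase attenuation sweep on the leucine-producer background) and
`fig3a.yaml` (acetyl-CoA ceiling without/with the bifido shunt).

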