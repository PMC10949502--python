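# Native JSON model dialect

The native, loss-free exchange format for `glutaflux` models. UTF-8, fixed
key ordering, floats round-trip to full precision.

```json
{
 "id": "cglutamicum_core",
 "objective": {"reaction": "BIOMASS", "sense": "maximize"},
 "annotations": {"organism": "Corynebacterium glutamicum"},
 "metabolites": [
  {
   "id": "pyr",
   "name": "pyruvate",
   "compartment": "c",
   "formula": {"C": 3}
  }
 ],
 "reactions": [
  {
   "id": "PDH",
   "name": "pyruvate dehydrogenase complex",
   "stoichiometry": {"pyr": -1, "coa": -1, "nad": -1,
                     "accoa": 1, "co2": 1, "nadh": 1},
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene": "aceE",
   "subsystem": "PDH",
   "is_exchange": false,
   "is_pseudo": false
  }
 ]
}
```

Field semantics:

| field | type | notes |
|---|---|---|
| `id` | string | model identifier |
| `objective.reaction` | string | must name a reaction |
| `objective.sense` | `maximize`/`minimize` | |
| `annotations` | object of strings | free-form |
| `metabolites[].formula` | object element→int, or `null` | `null` = unknown (lumped species, skipped by the balance checker); `{}` = explicitly devoid of tracked elements |
| `reactions[].stoichiometry` | object metabolite-id→signed number | negative = consumed; non-empty; ids must resolve |
| `reactions[].lower_bound`/`upper_bound` | number | mmol/gCDW/h, `lb <= ub` |
| `reactions[].is_exchange` | bool | exchange reactions touch exactly one metabolite; uptake is negative flux |
| `reactions[].is_pseudo` | bool | biomass/maintenance/demands; exempt from elemental balance |

## TSV import format

Import-only. Optional `# metabolites` section (columns `id`, `name`,
`compartment`, `formula` — formula as `C6N1`-style strings, `-` or empty for
unknown), then a `# reactions` section (columns `id`, `equation`, `lb`,
`ub`, `gene`, `subsystem`). Equations are written `2 A + B -> C` with `->`
or `<=>` arrows (bounds are authoritative for reversibility). A trailing
`# objective <reaction-id>` line selects the objective. When a metabolites
section is present, every species cited by an equation must be declared in
it. Single-species equations are treated as exchanges.

## SBML

SBML Level 3 + FBC version 2, strict. Species/reaction ids are prefixed
`M_`/`R_`; formulas map to `fbc:chemicalFormula`; bounds are shared
value-keyed parameters; gene, subsystem and the exchange/pseudo flags
travel in reaction notes (`<p>key: value</p>`). One lossy corner: an
explicitly empty formula (`{}`) has no FBC representation and reads back as
absent. The bundled `cglutamicum_core.xml` re-imports in cobrapy, which
reproduces the same biomass optimum (cross-checked in the test suite).
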