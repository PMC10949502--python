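"""Curated *Corynebacterium glutamicum* central-carbon core model.

This module generates, from code, a compact (~60 reaction) stoichiometric
model of glucose-grown *C. glutamicum* central metabolism: PTS uptake,
glycolysis/gluconeogenesis, the pentose phosphate pathway, pyruvate
dehydrogenase, the full TCA cycle, the glyoxylate shunt, both C4 anaplerotic
routes (pyc, ppc) plus malic enzyme, fermentative/transamination drains
(ldh, alaT, alaD, gdh), the branched-chain amino-acid pathways to L-valine
and L-leucine, acetate activation (pta/ackA), lumped respiration, a lumped
biomass pseudo-reaction and an ATP-maintenance pseudo-reaction.  An optional
augmentation adds the bifunctional phosphoketolase ("bifido shunt")
reactions F6P -> E4P + AcP and X5P -> G3P + AcP.

Every non-pseudo internal reaction is elementally balanced in carbon and
nitrogen (metabolite formulas track C and N; redox/energy cofactors carry
their real C/N so that paired conversions cancel).  Genotype presets encode
the strain scenarios studied on this network: anaplerosis double knockout
(growth abolition), IDH attenuation + glyoxylate-shunt opening (growth
rescue), and an engineered leucine-producer background.

Flux unit: mmol/gCDW/h.  Biomass flux is a growth-rate proxy on an invented
(documented) precursor composition; absolute growth rates are conventions of
this core model, not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import DEFAULT_BOUND, Metabolite, MetabolicModel, Reaction

__all__ = [
    "CoreModelOptions",
    "GenotypePreset",
    "GENOTYPE_PRESETS",
    "build_core_model",
    "apply_genotype",
    "augment_with_bifido_shunt",
    "build_toy_network",
    "GLUCOSE_EXCHANGE",
    "BIOMASS_ID",
]

GLUCOSE_EXCHANGE = "EX_glc__D_e"
BIOMASS_ID = "BIOMASS"
ATPM_ID = "ATPM"

#: lumped biomass precursor demand, mmol per gCDW (standard bacterial
#: precursor-demand scale); the composition is a documented convention.
BIOMASS_DEMAND = {
    "pyr": 2.8,
    "oaa": 1.8,
    "akg": 1.1,
    "accoa": 3.7,
    "e4p": 0.4,
    "r5p": 0.9,
    "nh4": 10.0,
    "atp": 40.0,
    "nadph": 16.0,
}


@dataclass
class CoreModelOptions:
    """Scenario knobs for the generated core model.

    The glyoxylate shunt is present but closed (bounds 0) by default: it is
    transcriptionally off in glucose-grown wild type and is opened by the
    rescue/acetate presets.  ``maintenance_atp`` is the non-growth ATP demand
    (lower bound on the ATP hydrolysis pseudo-reaction).
    """

    include_glyoxylate_shunt: bool = True
    glyoxylate_open: bool = False
    include_bifido_shunt: bool = False
    maintenance_atp: float = 2.0
    genotype: Optional[str] = None


@dataclass
class GenotypePreset:
    """A named strain scenario: knockouts, capacity scalings, bound opens."""

    name: str
    knockouts: List[str] = field(default_factory=list)
    bound_scalings: Dict[str, float] = field(default_factory=dict)
    opens: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    notes: str = ""

    def validate(self) -> None:
        for rid, f in self.bound_scalings.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"preset {self.name!r}: scaling for {rid!r} must be in [0,1]"
                )


#: engineered leucine-producer background: fermentative/transamination drains
#: deleted and the competing export routes closed
_PRODUCER_KO = ["LDH", "ALATA", "ALAD", "EX_lac__L_e", "EX_ala__L_e",
                "EX_val__L_e", "EX_ac_e"]

GENOTYPE_PRESETS: Dict[str, GenotypePreset] = {
    "wild_type": GenotypePreset("wild_type", notes="unmodified core model"),
    "leucine_producer": GenotypePreset(
        "leucine_producer",
        knockouts=list(_PRODUCER_KO),
        notes=(
            "engineered leucine-overproducer background: ldh/alaT/alaD deleted "
            "and lactate/alanine/valine/acetate secretion closed so surplus "
            "pyruvate drains into the leucine pathway"
        ),
    ),
    "LEU-28": GenotypePreset(
        "LEU-28",
        knockouts=list(_PRODUCER_KO) + ["PC", "PPC"],
        notes=(
            "leucine producer with both C4 anaplerotic routes (pyc, ppc) "
            "deleted and the glyoxylate shunt closed; no route to oxaloacetate "
            "remains, so aerobic growth on glucose is abolished"
        ),
    ),
    "LEU-29": GenotypePreset(
        "LEU-29",
        knockouts=list(_PRODUCER_KO) + ["PC", "PPC"],
        bound_scalings={"ICDHx": 0.2},
        opens={"ICL": (0.0, DEFAULT_BOUND), "MALS": (0.0, DEFAULT_BOUND)},
        notes=(
            "evolved rescue of LEU-28: IDH capacity reduced to 20% (icd "
            "R543S, ~80% activity loss) and the glyoxylate shunt opened, "
            "restoring C4 supply and growth"
        ),
    ),
    "acetate_media": GenotypePreset(
        "acetate_media",
        opens={
            "ICL": (0.0, DEFAULT_BOUND),
            "MALS": (0.0, DEFAULT_BOUND),
            "EX_ac_e": (-1.0, DEFAULT_BOUND),
        },
        bound_scalings={GLUCOSE_EXCHANGE: 0.0},
        notes=(
            "acetate-fed medium: glucose closed, acetate uptake 1 mmol/gCDW/h, "
            "glyoxylate shunt active (acetate induces aceBA)"
        ),
    ),
}


# ---------------------------------------------------------------------------
# metabolite and reaction tables
# ---------------------------------------------------------------------------

def _metabolites() -> List[Metabolite]:
    # formula maps track C and N only; {} means "carbon- and nitrogen-free"
    spec = [
        # id, name, compartment, C, N
        ("glc__D_e", "D-glucose (extracellular)", "e", 6, 0),
        ("o2_e", "oxygen (extracellular)", "e", 0, 0),
        ("co2_e", "carbon dioxide (extracellular)", "e", 1, 0),
        ("nh4_e", "ammonium (extracellular)", "e", 0, 1),
        ("pi_e", "phosphate (extracellular)", "e", 0, 0),
        ("h2o_e", "water (extracellular)", "e", 0, 0),
        ("ac_e", "acetate (extracellular)", "e", 2, 0),
        ("lac__L_e", "L-lactate (extracellular)", "e", 3, 0),
        ("ala__L_e", "L-alanine (extracellular)", "e", 3, 1),
        ("val__L_e", "L-valine (extracellular)", "e", 5, 1),
        ("leu__L_e", "L-leucine (extracellular)", "e", 6, 1),
        ("glc__D", "D-glucose", "c", 6, 0),
        ("g6p", "glucose 6-phosphate", "c", 6, 0),
        ("f6p", "fructose 6-phosphate", "c", 6, 0),
        ("fdp", "fructose 1,6-bisphosphate", "c", 6, 0),
        ("dhap", "dihydroxyacetone phosphate", "c", 3, 0),
        ("g3p", "glyceraldehyde 3-phosphate", "c", 3, 0),
        ("13dpg", "1,3-bisphosphoglycerate", "c", 3, 0),
        ("3pg", "3-phosphoglycerate", "c", 3, 0),
        ("2pg", "2-phosphoglycerate", "c", 3, 0),
        ("pep", "phosphoenolpyruvate", "c", 3, 0),
        ("pyr", "pyruvate", "c", 3, 0),
        ("6pgc", "6-phosphogluconate", "c", 6, 0),
        ("ru5p__D", "ribulose 5-phosphate", "c", 5, 0),
        ("xu5p__D", "xylulose 5-phosphate", "c", 5, 0),
        ("r5p", "ribose 5-phosphate", "c", 5, 0),
        ("s7p", "sedoheptulose 7-phosphate", "c", 7, 0),
        ("e4p", "erythrose 4-phosphate", "c", 4, 0),
        ("accoa", "acetyl-CoA", "c", 23, 7),
        ("coa", "coenzyme A", "c", 21, 7),
        ("actp", "acetyl phosphate", "c", 2, 0),
        ("cit", "citrate", "c", 6, 0),
        ("icit", "isocitrate", "c", 6, 0),
        ("akg", "2-oxoglutarate", "c", 5, 0),
        ("succoa", "succinyl-CoA", "c", 25, 7),
        ("succ", "succinate", "c", 4, 0),
        ("fum", "fumarate", "c", 4, 0),
        ("mal__L", "L-malate", "c", 4, 0),
        ("oaa", "oxaloacetate", "c", 4, 0),
        ("glx", "glyoxylate", "c", 2, 0),
        ("lac__L", "L-lactate", "c", 3, 0),
        ("ac", "acetate", "c", 2, 0),
        ("ala__L", "L-alanine", "c", 3, 1),
        ("val__L", "L-valine", "c", 5, 1),
        ("leu__L", "L-leucine", "c", 6, 1),
        ("glu__L", "L-glutamate", "c", 5, 1),
        ("alac__S", "(S)-2-acetolactate", "c", 5, 0),
        ("23dhmb", "2,3-dihydroxy-3-methylbutanoate", "c", 5, 0),
        ("3mob", "2-ketoisovalerate", "c", 5, 0),
        ("3c3hmp", "2-isopropylmalate", "c", 7, 0),
        ("4mop", "2-ketoisocaproate", "c", 6, 0),
        ("nh4", "ammonium", "c", 0, 1),
        ("co2", "carbon dioxide", "c", 1, 0),
        ("o2", "oxygen", "c", 0, 0),
        ("pi", "phosphate", "c", 0, 0),
        ("h2o", "water", "c", 0, 0),
        ("nad", "NAD+", "c", 21, 7),
        ("nadh", "NADH", "c", 21, 7),
        ("nadp", "NADP+", "c", 21, 7),
        ("nadph", "NADPH", "c", 21, 7),
        ("atp", "ATP", "c", 10, 5),
        ("adp", "ADP", "c", 10, 5),
    ]
    mets = []
    for mid, name, comp, c, n in spec:
        formula: Dict[str, int] = {}
        if c:
            formula["C"] = c
        if n:
            formula["N"] = n
        mets.append(Metabolite(id=mid, name=name, compartment=comp, formula=formula))
    return mets


def _rxn(rid, stoich, lb, ub, name="", gene=None, subsystem=None,
         exchange=False, pseudo=False) -> Reaction:
    return Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=lb,
                    upper_bound=ub, name=name, gene=gene, subsystem=subsystem,
                    is_exchange=exchange, is_pseudo=pseudo)


def _reactions(options: CoreModelOptions) -> List[Reaction]:
    B = DEFAULT_BOUND
    glyox_ub = B if (options.include_glyoxylate_shunt and options.glyoxylate_open) else 0.0
    rxns = [
        # --- exchanges (export positive; uptake negative) ---
        _rxn(GLUCOSE_EXCHANGE, {"glc__D_e": -1}, -4.67, 0.0,
             "D-glucose exchange", subsystem="exchange", exchange=True),
        _rxn("EX_o2_e", {"o2_e": -1}, -B, B, "O2 exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_co2_e", {"co2_e": -1}, 0.0, B, "CO2 exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_nh4_e", {"nh4_e": -1}, -B, B, "NH4 exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_pi_e", {"pi_e": -1}, -B, B, "phosphate exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_h2o_e", {"h2o_e": -1}, -B, B, "water exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_ac_e", {"ac_e": -1}, 0.0, B, "acetate exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_lac__L_e", {"lac__L_e": -1}, 0.0, B, "L-lactate exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_ala__L_e", {"ala__L_e": -1}, 0.0, B, "L-alanine exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_val__L_e", {"val__L_e": -1}, 0.0, B, "L-valine exchange",
             subsystem="exchange", exchange=True),
        _rxn("EX_leu__L_e", {"leu__L_e": -1}, 0.0, B, "L-leucine exchange",
             subsystem="exchange", exchange=True),
        # --- transport ---
        _rxn("O2t", {"o2_e": -1, "o2": 1}, -B, B, "O2 diffusion",
             subsystem="transport"),
        _rxn("CO2t", {"co2": -1, "co2_e": 1}, -B, B, "CO2 diffusion",
             subsystem="transport"),
        _rxn("NH4t", {"nh4_e": -1, "nh4": 1}, -B, B, "ammonium transport",
             subsystem="transport"),
        _rxn("PIt", {"pi_e": -1, "pi": 1}, -B, B, "phosphate transport",
             subsystem="transport"),
        _rxn("H2Ot", {"h2o": -1, "h2o_e": 1}, -B, B, "water diffusion",
             subsystem="transport"),
        _rxn("ACt", {"ac": -1, "ac_e": 1}, -B, B, "acetate transport",
             subsystem="transport"),
        _rxn("LACt", {"lac__L": -1, "lac__L_e": 1}, 0.0, B,
             "L-lactate export", subsystem="transport"),
        _rxn("ALAt", {"ala__L": -1, "ala__L_e": 1}, 0.0, B,
             "L-alanine export", subsystem="transport"),
        _rxn("VALt", {"val__L": -1, "val__L_e": 1}, 0.0, B,
             "L-valine export", subsystem="transport"),
        _rxn("LEUt", {"leu__L": -1, "leu__L_e": 1}, 0.0, B,
             "L-leucine export", subsystem="transport"),
        # --- glycolysis / gluconeogenesis ---
        _rxn("PTS", {"glc__D_e": -1, "pep": -1, "g6p": 1, "pyr": 1}, 0.0, B,
             "glucose PTS uptake", gene="ptsG", subsystem="glycolysis"),
        _rxn("GLCperm", {"glc__D_e": -1, "glc__D": 1}, 0.0, B,
             "PTS-independent glucose permease (IolT; PMF cost out of scope)",
             gene="iolT1", subsystem="glycolysis"),
        _rxn("PPGK", {"glc__D": -1, "pi": -1, "g6p": 1}, 0.0, B,
             "polyphosphate glucokinase (poly-P pool out of scope)",
             gene="ppgK", subsystem="glycolysis"),
        _rxn("PGI", {"g6p": -1, "f6p": 1}, -B, B,
             "glucose-6-phosphate isomerase", gene="pgi", subsystem="glycolysis"),
        _rxn("PFK", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1}, 0.0, B,
             "phosphofructokinase", gene="pfkA", subsystem="glycolysis"),
        _rxn("FBP", {"fdp": -1, "h2o": -1, "f6p": 1, "pi": 1}, 0.0, B,
             "fructose-1,6-bisphosphatase", gene="fbp", subsystem="gluconeogenesis"),
        _rxn("FBA", {"fdp": -1, "dhap": 1, "g3p": 1}, -B, B,
             "fructose-bisphosphate aldolase", gene="fba", subsystem="glycolysis"),
        _rxn("TPI", {"dhap": -1, "g3p": 1}, -B, B,
             "triose-phosphate isomerase", gene="tpi", subsystem="glycolysis"),
        _rxn("GAPD", {"g3p": -1, "nad": -1, "pi": -1, "13dpg": 1, "nadh": 1},
             -B, B, "glyceraldehyde-3-phosphate dehydrogenase", gene="gap",
             subsystem="glycolysis"),
        _rxn("PGK", {"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1}, -B, B,
             "phosphoglycerate kinase", gene="pgk", subsystem="glycolysis"),
        _rxn("PGM", {"3pg": -1, "2pg": 1}, -B, B,
             "phosphoglycerate mutase", gene="pgm", subsystem="glycolysis"),
        _rxn("ENO", {"2pg": -1, "pep": 1, "h2o": 1}, -B, B,
             "enolase", gene="eno", subsystem="glycolysis"),
        _rxn("PYK", {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, 0.0, B,
             "pyruvate kinase", gene="pyk", subsystem="glycolysis"),
        # --- pentose phosphate pathway ---
        _rxn("G6PDH", {"g6p": -1, "nadp": -1, "6pgc": 1, "nadph": 1}, 0.0, B,
             "glucose-6-phosphate dehydrogenase (lumped with lactonase)",
             gene="zwf", subsystem="PPP"),
        _rxn("GND", {"6pgc": -1, "nadp": -1, "ru5p__D": 1, "co2": 1, "nadph": 1},
             0.0, B, "6-phosphogluconate dehydrogenase", gene="gnd",
             subsystem="PPP"),
        _rxn("RPE", {"ru5p__D": -1, "xu5p__D": 1}, -B, B,
             "ribulose-5-phosphate epimerase", gene="rpe", subsystem="PPP"),
        _rxn("RPI", {"ru5p__D": -1, "r5p": 1}, -B, B,
             "ribose-5-phosphate isomerase", gene="rpi", subsystem="PPP"),
        _rxn("TKT1", {"xu5p__D": -1, "r5p": -1, "s7p": 1, "g3p": 1}, -B, B,
             "transketolase 1", gene="tkt", subsystem="PPP"),
        _rxn("TALA", {"s7p": -1, "g3p": -1, "e4p": 1, "f6p": 1}, -B, B,
             "transaldolase", gene="tal", subsystem="PPP"),
        _rxn("TKT2", {"xu5p__D": -1, "e4p": -1, "f6p": 1, "g3p": 1}, -B, B,
             "transketolase 2", gene="tkt", subsystem="PPP"),
        # --- pyruvate dehydrogenase ---
        _rxn("PDH", {"pyr": -1, "coa": -1, "nad": -1,
                     "accoa": 1, "co2": 1, "nadh": 1}, 0.0, B,
             "pyruvate dehydrogenase complex", gene="aceE", subsystem="PDH"),
        # --- TCA cycle ---
        _rxn("CS", {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1},
             0.0, B, "citrate synthase", gene="gltA", subsystem="TCA"),
        _rxn("ACONT", {"cit": -1, "icit": 1}, -B, B,
             "aconitase", gene="acn", subsystem="TCA"),
        _rxn("ICDHx", {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1},
             0.0, B, "isocitrate dehydrogenase (NADP)", gene="icd",
             subsystem="TCA"),
        _rxn("AKGDH", {"akg": -1, "coa": -1, "nad": -1,
                       "succoa": 1, "co2": 1, "nadh": 1}, 0.0, B,
             "2-oxoglutarate dehydrogenase", gene="odhA", subsystem="TCA"),
        _rxn("SUCOAS", {"succoa": -1, "adp": -1, "pi": -1,
                        "succ": 1, "coa": 1, "atp": 1}, -B, B,
             "succinyl-CoA synthetase", gene="sucCD", subsystem="TCA"),
        _rxn("SUCD", {"succ": -1, "nad": -1, "fum": 1, "nadh": 1}, 0.0, B,
             "succinate dehydrogenase (FAD lumped into NAD pool)",
             gene="sdh", subsystem="TCA"),
        _rxn("FUM", {"fum": -1, "h2o": -1, "mal__L": 1}, -B, B,
             "fumarase", gene="fum", subsystem="TCA"),
        _rxn("MDH", {"mal__L": -1, "nad": -1, "oaa": 1, "nadh": 1}, -B, B,
             "malate dehydrogenase", gene="mdh", subsystem="TCA"),
        # --- glyoxylate shunt (closed in glucose-grown wild type) ---
        _rxn("ICL", {"icit": -1, "succ": 1, "glx": 1}, 0.0, glyox_ub,
             "isocitrate lyase", gene="aceA", subsystem="glyoxylate"),
        _rxn("MALS", {"glx": -1, "accoa": -1, "h2o": -1, "mal__L": 1, "coa": 1},
             0.0, glyox_ub, "malate synthase", gene="aceB",
             subsystem="glyoxylate"),
        # --- anaplerosis and NADPH-generating malic enzyme cycle ---
        _rxn("PC", {"pyr": -1, "atp": -1, "co2": -1,
                    "oaa": 1, "adp": 1, "pi": 1}, 0.0, B,
             "pyruvate carboxylase", gene="pyc", subsystem="anaplerosis"),
        _rxn("PPC", {"pep": -1, "co2": -1, "oaa": 1, "pi": 1}, 0.0, B,
             "PEP carboxylase", gene="ppc", subsystem="anaplerosis"),
        _rxn("PCK", {"oaa": -1, "atp": -1, "pep": 1, "co2": 1, "adp": 1},
             0.0, B, "PEP carboxykinase", gene="pck", subsystem="anaplerosis"),
        _rxn("ME", {"mal__L": -1, "nadp": -1, "pyr": 1, "co2": 1, "nadph": 1},
             0.0, B, "malic enzyme (NADP)", gene="malE",
             subsystem="anaplerosis"),
        # --- fermentative drains and nitrogen assimilation ---
        _rxn("LDH", {"pyr": -1, "nadh": -1, "lac__L": 1, "nad": 1}, -B, B,
             "lactate dehydrogenase", gene="ldh", subsystem="fermentation"),
        _rxn("GDH", {"akg": -1, "nh4": -1, "nadph": -1,
                     "glu__L": 1, "nadp": 1, "h2o": 1}, -B, B,
             "glutamate dehydrogenase (NADPH)", gene="gdh",
             subsystem="nitrogen"),
        _rxn("ALATA", {"pyr": -1, "glu__L": -1, "ala__L": 1, "akg": 1}, -B, B,
             "alanine transaminase", gene="alaT", subsystem="fermentation"),
        _rxn("ALAD", {"pyr": -1, "nh4": -1, "nadh": -1,
                      "ala__L": 1, "nad": 1, "h2o": 1}, -B, B,
             "alanine dehydrogenase (NADH)", gene="alaD",
             subsystem="fermentation"),
        # --- branched-chain amino acids ---
        _rxn("ACLS", {"pyr": -2, "alac__S": 1, "co2": 1}, 0.0, B,
             "acetolactate synthase", gene="ilvBN", subsystem="BCAA"),
        _rxn("KARA", {"alac__S": -1, "nadph": -1, "23dhmb": 1, "nadp": 1},
             0.0, B, "ketol-acid reductoisomerase", gene="ilvC",
             subsystem="BCAA"),
        _rxn("DHAD", {"23dhmb": -1, "3mob": 1, "h2o": 1}, 0.0, B,
             "dihydroxy-acid dehydratase", gene="ilvD", subsystem="BCAA"),
        _rxn("VALTA", {"3mob": -1, "glu__L": -1, "val__L": 1, "akg": 1},
             -B, B, "valine transaminase", gene="ilvE", subsystem="BCAA"),
        _rxn("IPPS", {"3mob": -1, "accoa": -1, "h2o": -1,
                      "3c3hmp": 1, "coa": 1}, 0.0, B,
             "2-isopropylmalate synthase", gene="leuA", subsystem="BCAA"),
        _rxn("IPMD", {"3c3hmp": -1, "nad": -1, "4mop": 1, "co2": 1, "nadh": 1},
             0.0, B, "isopropylmalate isomerase/dehydrogenase (lumped leuCD+leuB)",
             gene="leuB", subsystem="BCAA"),
        _rxn("LEUTA", {"4mop": -1, "glu__L": -1, "leu__L": 1, "akg": 1},
             -B, B, "leucine transaminase", gene="ilvE", subsystem="BCAA"),
        # --- acetate metabolism ---
        _rxn("ACK", {"ac": -1, "atp": -1, "actp": 1, "adp": 1}, -B, B,
             "acetate kinase", gene="ackA", subsystem="acetate"),
        _rxn("PTA", {"accoa": -1, "pi": -1, "actp": 1, "coa": 1}, -B, B,
             "phosphotransacetylase", gene="pta", subsystem="acetate"),
        # --- energy metabolism ---
        _rxn("NADHOX", {"nadh": -1, "o2": -0.5, "adp": -2, "pi": -2,
                        "nad": 1, "atp": 2, "h2o": 1}, 0.0, B,
             "lumped respiratory chain (P/O = 2)", subsystem="energy"),
        _rxn(ATPM_ID, {"atp": -1, "h2o": -1, "adp": 1, "pi": 1},
             max(0.0, options.maintenance_atp), B,
             "non-growth ATP maintenance", subsystem="energy", pseudo=True),
        # --- pseudo demands (closed; opened by specific analyses) ---
        _rxn("DM_accoa", {"accoa": -1, "coa": 1}, 0.0, 0.0,
             "acetyl-CoA demand (yield probe)", subsystem="demand", pseudo=True),
        _rxn("DM_mal__L", {"mal__L": -1}, 0.0, 0.0,
             "malate demand (yield probe)", subsystem="demand", pseudo=True),
        # --- biomass ---
        _rxn(BIOMASS_ID,
             {
                 "pyr": -BIOMASS_DEMAND["pyr"],
                 "oaa": -BIOMASS_DEMAND["oaa"],
                 "akg": -BIOMASS_DEMAND["akg"],
                 "accoa": -BIOMASS_DEMAND["accoa"],
                 "e4p": -BIOMASS_DEMAND["e4p"],
                 "r5p": -BIOMASS_DEMAND["r5p"],
                 "nh4": -BIOMASS_DEMAND["nh4"],
                 "atp": -BIOMASS_DEMAND["atp"],
                 "nadph": -BIOMASS_DEMAND["nadph"],
                 "coa": BIOMASS_DEMAND["accoa"],
                 "adp": BIOMASS_DEMAND["atp"],
                 "pi": BIOMASS_DEMAND["atp"],
                 "nadp": BIOMASS_DEMAND["nadph"],
             },
             0.0, B, "lumped biomass formation (growth-rate proxy)",
             subsystem="biomass", pseudo=True),
    ]
    if not options.include_glyoxylate_shunt:
        rxns = [r for r in rxns if r.id not in ("ICL", "MALS")]
    return rxns


def build_core_model(options: Optional[CoreModelOptions] = None) -> MetabolicModel:
    """Generate the central-carbon core model.

    The returned model has the biomass pseudo-reaction as its objective and
    glucose uptake bounded at 4.67 mmol/gCDW/h on the exchange.  Genotype
    presets (see :data:`GENOTYPE_PRESETS`) are applied last.
    """
    opts = options or CoreModelOptions()
    model = MetabolicModel(
        id="cglutamicum_core",
        metabolites=_metabolites(),
        reactions=_reactions(opts),
        objective_id=BIOMASS_ID,
        objective_sense="maximize",
        annotations={
            "organism": "Corynebacterium glutamicum",
            "description": "central-carbon core model for constraint-based "
                           "strain design",
        },
    )
    if opts.include_bifido_shunt:
        model = augment_with_bifido_shunt(model)
    if opts.genotype is not None:
        model = apply_genotype(model, opts.genotype)
    model.validate()
    return model


def apply_genotype(model: MetabolicModel, genotype: str) -> MetabolicModel:
    """Apply a named genotype preset; returns a modified copy."""
    if genotype not in GENOTYPE_PRESETS:
        raise KeyError(
            f"unknown genotype preset {genotype!r}; known presets: "
            + ", ".join(sorted(GENOTYPE_PRESETS))
        )
    preset = GENOTYPE_PRESETS[genotype]
    preset.validate()
    out = model.copy()
    for rid, (lb, ub) in preset.opens.items():
        out.set_bounds(rid, lb, ub)
    for rid in preset.knockouts:
        out.set_bounds(rid, 0.0, 0.0)
    for rid, factor in preset.bound_scalings.items():
        rxn = out.reaction(rid)
        rxn.lower_bound *= factor
        rxn.upper_bound *= factor
    out.annotations["genotype"] = genotype
    return out


def augment_with_bifido_shunt(model: MetabolicModel) -> MetabolicModel:
    """Add the phosphoketolase (FxpK) reactions of the bifido shunt.

    FXPK1: F6P + Pi -> E4P + AcP; FXPK2: X5P + Pi -> G3P + AcP, both
    irreversible forward; the existing pta link converts AcP to acetyl-CoA.
    Raises on re-augmentation.
    """
    if model.has_reaction("FXPK1") or model.has_reaction("FXPK2"):
        raise ValueError("model already carries the bifido-shunt reactions")
    for required in ("f6p", "xu5p__D", "e4p", "g3p", "actp", "pi"):
        model.metabolite(required)  # KeyError if the host model lacks it
    out = model.copy()
    out.reactions.append(_rxn(
        "FXPK1", {"f6p": -1, "pi": -1, "e4p": 1, "actp": 1}, 0.0, DEFAULT_BOUND,
        "phosphoketolase (F6P)", gene="fxpK", subsystem="bifido_shunt"))
    out.reactions.append(_rxn(
        "FXPK2", {"xu5p__D": -1, "pi": -1, "g3p": 1, "actp": 1}, 0.0, DEFAULT_BOUND,
        "phosphoketolase (X5P)", gene="fxpK", subsystem="bifido_shunt"))
    out.annotations["bifido_shunt"] = "present"
    out.validate()
    return out


# ---------------------------------------------------------------------------
# toy fixtures for solver oracles
# ---------------------------------------------------------------------------

def build_toy_network(kind: str, seed: int = 0, size: int = 5) -> MetabolicModel:
    """Small fixed/random networks for exercising the LP solvers.

    ``chain``: uptake(<=10) -> A -> B -> export, objective export (optimum 10).
    ``diamond``: two parallel branches of capacity 10 each carrying a total
    demand of 10 (optimum 10, branch split degenerate).
    ``random``: a connected chain with random extra shortcut reactions and
    random finite bounds; always feasible with a positive optimum.
    """
    if kind == "chain":
        mets = [Metabolite("A", compartment="c", formula={"C": 1}),
                Metabolite("B", compartment="c", formula={"C": 1})]
        rxns = [
            _rxn("R_in", {"A": 1}, 0.0, 10.0, "uptake", exchange=True),
            _rxn("R_ab", {"A": -1, "B": 1}, 0.0, 1000.0, "conversion"),
            _rxn("R_out", {"B": -1}, 0.0, 1000.0, "export", exchange=True),
        ]
        m = MetabolicModel("toy_chain", mets, rxns, objective_id="R_out")
        m.validate()
        return m
    if kind == "diamond":
        mets = [Metabolite("A", compartment="c", formula={"C": 1}),
                Metabolite("B", compartment="c", formula={"C": 1})]
        rxns = [
            _rxn("R_in", {"A": 1}, 0.0, 10.0, "uptake", exchange=True),
            _rxn("R_top", {"A": -1, "B": 1}, 0.0, 10.0, "upper branch"),
            _rxn("R_bot", {"A": -1, "B": 1}, 0.0, 10.0, "lower branch"),
            _rxn("R_out", {"B": -1}, 0.0, 10.0, "export", exchange=True),
        ]
        m = MetabolicModel("toy_diamond", mets, rxns, objective_id="R_out")
        m.validate()
        return m
    if kind == "random":
        if size > 12:
            raise ValueError("random toy networks are capped at size 12")
        return _random_toy(seed, size)
    raise ValueError(f"unknown toy network kind {kind!r}")


def _random_toy(seed: int, size: int) -> MetabolicModel:
    """Connected random network: a metabolite chain with shortcut reactions.

    Reaction count equals ``size``; feasibility with positive optimum is
    guaranteed by construction (the chain itself is open end to end), so no
    retry loop is needed.
    """
    rng = np.random.default_rng(seed)
    n_chain = max(2, min(size - 1, 1 + int(rng.integers(1, max(2, size - 1)))))
    n_mets = n_chain  # chain metabolites M0..M{n-1}
    mets = [Metabolite(f"M{i}", compartment="c") for i in range(n_mets)]
    cap_in = float(rng.uniform(2.0, 10.0))
    rxns = [_rxn("R_in", {"M0": 1}, 0.0, cap_in, "uptake", exchange=True)]
    for i in range(n_mets - 1):
        cap = float(rng.uniform(5.0, 20.0))
        lb = 0.0 if rng.random() < 0.7 else -float(rng.uniform(0.0, 5.0))
        rxns.append(_rxn(f"R_{i}_{i+1}", {f"M{i}": -1, f"M{i+1}": 1}, lb, cap,
                         "chain step"))
    rxns.append(_rxn("R_out", {f"M{n_mets-1}": -1}, 0.0,
                     float(rng.uniform(5.0, 20.0)), "export", exchange=True))
    k = 0
    while len(rxns) < size + 2 and k < 2 * size:
        k += 1
        i, j = rng.integers(0, n_mets, size=2)
        if i == j:
            continue
        rid = f"S{k}_{i}_{j}"
        cap = float(rng.uniform(0.0, 15.0))
        rxns.append(_rxn(rid, {f"M{i}": -1, f"M{j}": 1}, 0.0, cap, "shortcut"))
    m = MetabolicModel(f"toy_random_{seed}", mets, rxns, objective_id="R_out")
    m.validate()
    return m
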