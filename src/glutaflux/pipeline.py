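"""Declarative pipeline runs: config in, artifacts + manifest out.

A run config (YAML or JSON) names a model source (the generated core model
or a file), a genotype preset, simulation knobs and a list of stages.  Each
stage writes its table under the output directory with fixed 12-significant-
digit float formatting, so repeated runs on the same host are byte-identical;
the manifest records the config snapshot, input digests, package version and
per-stage status.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple, Union

import yaml

from . import __version__
from .coremodel import (
    CoreModelOptions,
    apply_genotype,
    augment_with_bifido_shunt,
    build_core_model,
)
from .design import (
    DesignRecommendation,
    EssentialityRecord,
    SweepResult,
    YieldReport,
    essentiality_analysis,
    max_theoretical_yield,
    recommend_regulation,
    simulate_production,
    sweep_relative_flux,
)
from .io import load_model, write_model
from .model import MetabolicModel, SimulationConfig
from .solvers import FluxDistribution, fba, fva, geometric_fba

__all__ = [
    "RunManifest",
    "run_pipeline",
    "load_config",
    "fmt",
    "export_essentiality_tsv",
    "export_recommendations_tsv",
    "export_sweep_tsv",
    "export_flux_json",
]

KNOWN_STAGES = (
    "build_model", "fba", "gfba", "fva", "classify", "recommend",
    "yields", "production", "sweep", "bifido_compare",
)


def fmt(x: float) -> str:
    """Fixed float formatting for all exported tables (12 significant digits)."""
    return f"{float(x):.12g}"


@dataclass
class RunManifest:
    run_id: str
    config: Dict[str, Any]
    input_digests: Dict[str, str]
    tool_version: str
    stages: List[Dict[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages)

    def to_json(self) -> str:
        return json.dumps(
            {
                "run_id": self.run_id,
                "tool_version": self.tool_version,
                "config": self.config,
                "input_digests": self.input_digests,
                "stages": self.stages,
            },
            indent=1,
            sort_keys=True,
        ) + "\n"


def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_model_from_config(cfg: Dict[str, Any], digests: Dict[str, str]) -> MetabolicModel:
    mcfg = cfg.get("model", {})
    source = mcfg.get("source", "core")
    if source == "core":
        opts = CoreModelOptions(
            glyoxylate_open=bool(mcfg.get("glyoxylate_open", False)),
            include_bifido_shunt=bool(mcfg.get("bifido", False)),
            maintenance_atp=float(mcfg.get("maintenance_atp", 2.0)),
        )
        model = build_core_model(opts)
    else:
        path = Path(source)
        digests[str(path)] = _sha256(path)
        model = load_model(path, mcfg.get("format"))
        if mcfg.get("bifido", False):
            model = augment_with_bifido_shunt(model)
    genotype = mcfg.get("genotype")
    if genotype and genotype != "wild_type":
        model = apply_genotype(model, genotype)
    for rid in mcfg.get("knockouts", []) or []:
        model.set_bounds(rid, 0.0, 0.0)
    return model


def _sim_config(cfg: Dict[str, Any]) -> SimulationConfig:
    scfg = cfg.get("simulation", {})
    sim = SimulationConfig(
        substrate_exchange_id=scfg.get("substrate_exchange", "EX_glc__D_e"),
        substrate_uptake_max=float(scfg.get("substrate_uptake_max", 4.67)),
        biomass_reaction_id=scfg.get("biomass_reaction", "BIOMASS"),
        biomass_fraction=float(scfg.get("biomass_fraction", 0.2)),
    )
    if "sweep_fractions" in scfg:
        sim.sweep_fractions = tuple(float(f) for f in scfg["sweep_fractions"])
    sim.validate()
    return sim


# ---------------------------------------------------------------------------
# exporters (fixed formatting)
# ---------------------------------------------------------------------------

def export_essentiality_tsv(records: Sequence[EssentialityRecord], path: Path) -> None:
    lines = ["reaction_id\tclass\tv_min\tv_max"]
    for rec in records:
        lines.append(
            f"{rec.reaction_id}\t{rec.essentiality}\t{fmt(rec.v_min)}\t{fmt(rec.v_max)}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_recommendations_tsv(recs: Sequence[DesignRecommendation], path: Path) -> None:
    lines = ["reaction_id\tmode\tgrowth_flux\tproduction_flux"]
    for rec in recs:
        lines.append(
            f"{rec.reaction_id}\t{rec.mode}\t{fmt(rec.growth_flux)}\t{fmt(rec.production_flux)}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_sweep_tsv(sweep: SweepResult, path: Path) -> None:
    """Fraction x reaction matrix of relative fluxes (flux / control, 0/0 -> 1)."""
    matrix = sweep.relative_flux_matrix()
    rxn_ids = sorted(sweep.control_state.fluxes)
    lines = ["fraction\tstatus\t" + "\t".join(rxn_ids)]
    for frac, dist in sweep.rows:
        if not dist.optimal:
            lines.append(f"{fmt(frac)}\t{dist.status}\t" + "\t".join([""] * len(rxn_ids)))
            continue
        row = matrix[frac]
        lines.append(
            f"{fmt(frac)}\toptimal\t" + "\t".join(fmt(row[r]) for r in rxn_ids)
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_flux_json(dist: FluxDistribution, path: Path) -> None:
    doc = {
        "status": dist.status,
        "objective_value": None if dist.status != "optimal" else float(fmt(dist.objective_value)),
        "fluxes": {k: float(fmt(v)) for k, v in sorted(dist.fluxes.items())},
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def _yield_doc(report: YieldReport) -> Dict[str, Any]:
    return {
        "product": report.product_id,
        "substrate": report.substrate_id,
        "yield_mol_per_mol": (None if report.status != "optimal"
                              else float(fmt(report.yield_mol_per_mol))),
        "biomass_fraction_used": report.biomass_fraction_used,
        "status": report.status,
    }


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config_path: Union[str, Path], output_dir: Optional[Union[str, Path]] = None) -> RunManifest:
    """Execute the configured stages in order, writing artifacts + manifest.

    A stage failure is recorded and aborts the stages that depend on it;
    the manifest is always written.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    digests = {str(config_path): _sha256(config_path)}
    run_id = cfg.get("run_id", config_path.stem)
    out_dir = Path(output_dir or cfg.get("output_dir", f"results/{run_id}"))
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(run_id=run_id, config=cfg, input_digests=digests,
                           tool_version=__version__)
    stages: List[str] = list(cfg.get("stages", ["classify", "yields"]))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; known: {KNOWN_STAGES}")

    model = _build_model_from_config(cfg, digests)
    sim = _sim_config(cfg)
    product = cfg.get("simulation", {}).get("product_exchange", "EX_leu__L_e")

    failed = False
    for stage in stages:
        if failed:
            manifest.stages.append({"name": stage, "status": "skipped",
                                    "detail": "earlier stage failed"})
            continue
        try:
            detail = _run_stage(stage, model, sim, product, cfg, out_dir)
            manifest.stages.append({"name": stage, "status": "ok", "detail": detail})
        except Exception as exc:  # recorded, not raised: manifest must land
            manifest.stages.append({"name": stage, "status": "error",
                                    "detail": f"{type(exc).__name__}: {exc}"})
            failed = True

    (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def _run_stage(
    stage: str,
    model: MetabolicModel,
    sim: SimulationConfig,
    product: str,
    cfg: Dict[str, Any],
    out_dir: Path,
) -> str:
    if stage == "build_model":
        write_model(model, out_dir / "model.json", "json")
        write_model(model, out_dir / "model.xml", "sbml")
        return "model.json, model.xml"
    if stage == "fba":
        export_flux_json(fba(model, sim), out_dir / "fba.json")
        return "fba.json"
    if stage == "gfba":
        export_flux_json(geometric_fba(model, sim), out_dir / "gfba.json")
        return "gfba.json"
    if stage == "fva":
        frac = float(cfg.get("simulation", {}).get("fva_fraction", 1.0))
        result = fva(model, sim, objective_fraction=frac)
        lines = ["reaction_id\tv_min\tv_max"]
        for rid in sorted(result.intervals):
            lo, hi = result.intervals[rid]
            lines.append(f"{rid}\t{fmt(lo)}\t{fmt(hi)}")
        (out_dir / "fva.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        return "fva.tsv"
    if stage == "classify":
        records = essentiality_analysis(model, sim, product)
        export_essentiality_tsv(records, out_dir / "essentiality.tsv")
        return "essentiality.tsv"
    if stage == "recommend":
        growth = geometric_fba(model, sim)
        production = simulate_production(model, sim, product)
        records = essentiality_analysis(model, sim, product)
        recs = recommend_regulation(growth, production, records,
                                    sim.classification_tolerance)
        export_recommendations_tsv(recs, out_dir / "recommendations.tsv")
        return "recommendations.tsv"
    if stage == "yields":
        products = cfg.get("simulation", {}).get(
            "yield_products", ["EX_ala__L_e", "EX_val__L_e", "EX_leu__L_e"])
        doc = [_yield_doc(max_theoretical_yield(model, sim, p)) for p in products]
        (out_dir / "yields.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return "yields.json"
    if stage == "production":
        export_flux_json(simulate_production(model, sim, product),
                         out_dir / "production.json")
        return "production.json"
    if stage == "sweep":
        target = cfg.get("simulation", {}).get("sweep_target", "ACONT")
        sweep = sweep_relative_flux(model, sim, target)
        export_sweep_tsv(sweep, out_dir / "sweep.tsv")
        return "sweep.tsv"
    if stage == "bifido_compare":
        probe = cfg.get("simulation", {}).get("bifido_probe", "DM_accoa")
        plain = model.copy()
        plain.set_bounds(probe, 0.0, 1000.0)
        augmented = augment_with_bifido_shunt(plain)
        doc = {
            "probe": probe,
            "without_bifido": _yield_doc(max_theoretical_yield(plain, sim, probe)),
            "with_bifido": _yield_doc(max_theoretical_yield(augmented, sim, probe)),
        }
        (out_dir / "bifido_compare.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return "bifido_compare.json"
    raise AssertionError(f"unreachable stage {stage!r}")
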