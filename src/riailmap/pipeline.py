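"""End-to-end orchestration: simulate -> map -> eQTL -> hotspots -> mediate.

A :class:`PipelineConfig` either points at genotype/phenotype/expression TSV
files or requests a fully synthetic study; :func:`run_pipeline` validates the
whole configuration up front, runs the stages in order, writes every stage's
output as TSV into the output directory, and records a JSON manifest with
parameters, seeds and row counts.  Reruns with the same config and master
seed reproduce all outputs bit-exactly.

The master seed expands into independent per-stage seeds through a
counter-based scheme (one fixed counter per stage), so adding a stage never
perturbs the random streams of earlier stages.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from riailmap import eqtl as eqtl_mod
from riailmap import io as rio
from riailmap import linkage, mediation, sim

_STAGE_COUNTERS = {
    "simulate_genotypes": 0,
    "simulate_expression": 1,
    "simulate_trait": 2,
    "map_threshold": 3,
    "eqtl_fdr": 4,
    "hotspot_check": 5,
    "mediation": 6,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and a fixed stage counter."""
    counter = _STAGE_COUNTERS[stage]
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Parameters for one end-to-end run.

    Leave the file paths as ``None`` to simulate the inputs; otherwise
    ``genotypes/marker_map/phenotypes`` (and ``expression`` +
    ``probe_positions`` when eQTL/mediation stages run) must all exist.
    """

    # input files (all-or-none with simulation)
    genotypes: str | None = None
    marker_map: str | None = None
    phenotypes: str | None = None
    expression: str | None = None
    probe_positions: str | None = None
    trait: str = "drug_trait"
    # simulation parameters
    n_lines: int = 300
    n_chromosomes: int = 6
    markers_per_chromosome: int = 100
    chrom_length_cm: float = 50.0
    map_expansion: float = 4.0
    n_probes: int = 500
    local_fraction: float = 0.3
    n_hotspot_genes: int = 50
    eqtl_effect_size: float = 1.5
    mediation_a: float = 0.8
    mediation_b: float = 0.5
    mediation_c_prime: float = 0.2
    # stage parameters
    n_perm: int = 1000
    alpha: float = 0.05
    max_qtl: int = 10
    eqtl_n_perm: int = 10
    fdr: float = 0.05
    bin_cm: float = 5.0
    hotspot_percentile: float = 0.99
    lod_floor: float | None = None
    n_boot: int = 1000
    run_eqtl: bool = True
    run_mediation: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        file_fields = [self.genotypes, self.marker_map, self.phenotypes]
        provided = [f for f in file_fields if f is not None]
        if provided and len(provided) != 3:
            raise ValueError(
                "provide genotypes, marker_map and phenotypes together, or none to simulate"
            )
        for f in provided:
            if not Path(f).exists():
                raise FileNotFoundError(f"input file not found: {f}")
        if provided and (self.run_eqtl or self.run_mediation):
            for name, f in (("expression", self.expression), ("probe_positions", self.probe_positions)):
                if f is None:
                    raise ValueError(f"{name} file required when eQTL/mediation stages run")
                if not Path(f).exists():
                    raise FileNotFoundError(f"input file not found: {f}")
        if self.run_mediation and not self.run_eqtl:
            raise ValueError("mediation requires the eQTL stage (candidate probes)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.bin_cm <= 0 or self.n_perm < 1 or self.eqtl_n_perm < 1 or self.n_boot < 1:
            raise ValueError("stage parameters must be positive")

    @property
    def simulated(self) -> bool:
        return self.genotypes is None


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all configured stages and write results under ``outdir``.

    Returns a result bundle dict with the in-memory tables
    (``qtl, eqtl, hotspots, mediation``) and the manifest.  Raises before
    any compute when the configuration is invalid.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)

    manifest: dict = {"stages": {}, "seed": config.seed, "parameters": asdict(config)}
    t0 = time.time()

    truth = None
    mediator_probe = None
    if config.simulated:
        mmap = sim.generate_marker_map(
            config.n_chromosomes, config.markers_per_chromosome, config.chrom_length_cm
        )
        panel = sim.simulate_riail_genotypes(
            mmap,
            config.n_lines,
            map_expansion=config.map_expansion,
            seed=stage_seed(config.seed, "simulate_genotypes"),
        )
        hotspot_locus = mmap.iloc[len(mmap) // 2]["marker"]
        expression, probe_positions, truth = sim.simulate_expression_panel(
            panel,
            config.n_probes,
            local_fraction=config.local_fraction,
            hotspot_locus=hotspot_locus,
            n_hotspot_genes=config.n_hotspot_genes,
            effect_size=config.eqtl_effect_size,
            seed=stage_seed(config.seed, "simulate_expression"),
        )
        mediator_probe = truth.loc[truth["cls"] == "hotspot", "probe"].iloc[0]
        phenotype, _ = sim.simulate_mediated_trait(
            panel,
            hotspot_locus,
            a=config.mediation_a,
            b=config.mediation_b,
            c_prime=config.mediation_c_prime,
            mediator=expression[mediator_probe],
            seed=stage_seed(config.seed, "simulate_trait"),
        )
        phenotype.name = config.trait
        phenotypes = phenotype.to_frame()
        rio.write_genotypes(panel, outdir / "genotypes.tsv", outdir / "marker_map.tsv")
        rio.write_traits(phenotypes, outdir / "phenotypes.tsv")
        rio.write_traits(expression, outdir / "expression.tsv")
        rio.write_probe_positions(probe_positions, outdir / "probe_positions.tsv")
        rio.write_table(truth, outdir / "simulation_truth.tsv")
        manifest["stages"]["simulate"] = {
            "n_lines": panel.n_lines,
            "n_markers": panel.n_markers,
            "n_probes": config.n_probes,
            "hotspot_locus": str(hotspot_locus),
            "mediator_probe": str(mediator_probe),
        }
    else:
        panel = rio.read_genotypes(config.genotypes, config.marker_map)
        phenotypes = rio.read_traits(config.phenotypes)
        if config.trait not in phenotypes.columns:
            raise ValueError(f"trait {config.trait!r} not in phenotype table")
        phenotype = phenotypes[config.trait]
        if config.run_eqtl:
            expression = rio.read_traits(config.expression)
            probe_positions = rio.read_probe_positions(config.probe_positions)

    # --- linkage mapping of the focal trait ---------------------------------
    qtl = linkage.forward_search(
        panel,
        phenotype,
        n_perm=config.n_perm,
        alpha=config.alpha,
        max_qtl=config.max_qtl,
        seed=stage_seed(config.seed, "map_threshold"),
    )
    qtl_table = pd.DataFrame([vars(q) for q in qtl])
    rio.write_table(qtl_table, outdir / "qtl.tsv")
    manifest["stages"]["linkage"] = {"n_qtl": len(qtl_table), "trait": config.trait}

    eqtl_table = pd.DataFrame(columns=list(eqtl_mod.EQTL_COLUMNS))
    hotspot_table = pd.DataFrame()
    mediation_table = pd.DataFrame()
    if config.run_eqtl:
        threshold = eqtl_mod.permutation_fdr_threshold(
            panel,
            expression,
            n_perm=config.eqtl_n_perm,
            target_fdr=config.fdr,
            seed=stage_seed(config.seed, "eqtl_fdr"),
        )
        if np.isnan(threshold):
            raise RuntimeError("eQTL stage: no grid threshold controls the FDR target")
        eqtl_table = eqtl_mod.map_expression_panel(panel, expression, probe_positions, threshold)
        rio.write_table(eqtl_table, outdir / "eqtl.tsv")
        hotspots = eqtl_mod.detect_hotspots(
            eqtl_table,
            panel.marker_map,
            bin_cm=config.bin_cm,
            percentile=config.hotspot_percentile,
            lod_floor=config.lod_floor,
        )
        hotspot_table = hotspots.bins
        rio.write_table(hotspot_table, outdir / "hotspots.tsv")
        manifest["stages"]["eqtl"] = {
            "threshold": threshold,
            "n_eqtl": len(eqtl_table),
            "n_local": int((eqtl_table["classification"] == "local").sum()),
            "n_distant": int((eqtl_table["classification"] == "distant").sum()),
            "lambda": hotspots.lam,
            "critical_count": hotspots.critical_count,
            "n_hotspots": int(hotspot_table["significant"].sum()),
        }

    if config.run_mediation:
        if qtl_table.empty:
            manifest["stages"]["mediation"] = {"skipped": "no QTL detected for the trait"}
        else:
            sig = hotspot_table[hotspot_table["significant"]]
            if sig.empty:
                manifest["stages"]["mediation"] = {"skipped": "no significant hotspot"}
            else:
                top_bin = sig.loc[sig["count"].idxmax()]
                in_bin = eqtl_table[
                    (eqtl_table["peak_chrom"] == top_bin["chrom"])
                    & (eqtl_table["peak_cm"] >= top_bin["start_cm"])
                    & (eqtl_table["peak_cm"] < top_bin["end_cm"])
                ]
                candidates = sorted(in_bin["probe"].unique())
                qtl_marker = qtl_table.iloc[0]["peak_marker"]
                mediation_table = mediation.mediate_panel(
                    panel,
                    qtl_marker,
                    expression,
                    candidates,
                    phenotype,
                    n_boot=config.n_boot,
                    seed=stage_seed(config.seed, "mediation"),
                )
                rio.write_table(mediation_table, outdir / "mediation.tsv")
                manifest["stages"]["mediation"] = {
                    "qtl_marker": str(qtl_marker),
                    "n_candidates": len(candidates),
                    "top_probe": str(mediation_table.iloc[0]["probe"]),
                }
                if mediator_probe is not None:
                    manifest["stages"]["mediation"]["planted_mediator"] = str(mediator_probe)

    manifest["runtime_s"] = round(time.time() - t0, 3)
    manifest["row_counts"] = {
        "qtl": len(qtl_table),
        "eqtl": len(eqtl_table),
        "hotspot_bins": len(hotspot_table),
        "mediation": len(mediation_table),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "qtl": qtl_table,
        "eqtl": eqtl_table,
        "hotspots": hotspot_table,
        "mediation": mediation_table,
        "manifest": manifest,
        "truth": truth,
    }
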