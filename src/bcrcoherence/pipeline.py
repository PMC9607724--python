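"""End-to-end pipeline: ingest -> alleles -> classify -> clonotype ->
coherence -> groups -> junctions, with a machine-readable JSON summary.

A :class:`PipelineConfig` fully serializes a run (inputs, every stage
parameter, seeds, output directory); two runs with the same config produce
byte-identical summaries. Stages fail fast with the stage name in the
error message and partial outputs are left on disk flagged by the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from . import classify as _classify
from . import coherence as _coherence
from . import groups as _groups
from . import junctions as _junctions
from .alleles import infer_alleles
from .errors import ConfigurationError
from .repio import (
    CellRecord,
    GermlineReference,
    assemble_cells,
    read_airr_rearrangements,
    read_germline_fasta,
    read_per_cell_table,
    write_per_cell_table,
)
from .synthetic import SimulationConfig, PublicPlan, simulate_repertoire

logger = logging.getLogger("bcrcoherence")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    outdir: str
    seed: int = 0
    # exactly one input source: simulate, airr_paths(+germline), per_cell(+germline)
    simulate: Optional[SimulationConfig] = None
    airr_paths: Sequence[str] = ()
    per_cell_table: Optional[str] = None
    germline_fasta: Optional[str] = None
    # stage parameters
    min_count: int = 4
    min_fraction: float = 0.25
    tail_exclusion: int = 15
    cdr3_nt_identity: float = 0.85
    merge_paralogs: bool = True
    group_identity_threshold: float = 90.0
    n_permutations: int = 200
    contingency_n_mc: int = 2000
    junction_max_cells: int = 2000
    classes: Sequence[str] = ("memory", "naive")
    run_permutation: bool = True
    run_groups: bool = True
    run_junctions: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        config = cls(**raw)
        if sim is not None:
            public = sim.pop("public", None)
            sim_config = SimulationConfig(**sim)
            if public is not None:
                sim_config.public = PublicPlan(**public)
            config.simulate = sim_config
        return config

    def validate(self) -> None:
        sources = [
            self.simulate is not None,
            bool(self.airr_paths),
            self.per_cell_table is not None,
        ]
        if sum(sources) != 1:
            raise ConfigurationError(
                "exactly one of 'simulate', 'airr_paths' or 'per_cell_table' "
                "must be set"
            )
        if self.simulate is None and not self.germline_fasta:
            raise ConfigurationError(
                "'germline_fasta' is required when not simulating"
            )
        for path in list(self.airr_paths) + (
            [self.germline_fasta] if self.germline_fasta else []
        ) + ([self.per_cell_table] if self.per_cell_table else []):
            if path and not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")


@dataclass
class PipelineResult:
    summary: Dict[str, object]
    cells: List[CellRecord]
    reference: GermlineReference
    paths: Dict[str, str] = field(default_factory=dict)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _curve_record(curve: _coherence.CoherenceCurve) -> dict:
    return {
        "label": curve.label,
        "bins": list(curve.bins),
        "pair_count": curve.pair_count.tolist(),
        "coherent_count": curve.coherent_count.tolist(),
        "fraction": [None if np.isnan(f) else round(float(f), 6)
                     for f in curve.fraction()],
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and write the report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    summary: Dict[str, object] = {"seed": config.seed}
    paths: Dict[str, str] = {}
    stage = "ingest"
    try:
        cells, reference = _stage_ingest(config, summary)
        logger.info("ingest: %d cells", len(cells))

        stage = "alleles"
        allele_table = infer_alleles(
            cells, reference, min_count=config.min_count,
            min_fraction=config.min_fraction,
            tail_exclusion=config.tail_exclusion,
        )
        allele_table.to_tsv(outdir / "alleles.tsv")
        paths["alleles"] = str(outdir / "alleles.tsv")
        summary["alleles"] = {"n_variants": allele_table.n_variants()}
        logger.info("alleles: %d variants", allele_table.n_variants())

        stage = "classify"
        _classify.classify_cells(cells, allele_table, reference)
        n_naive = sum(c.cell_class == "naive" for c in cells)
        summary["classify"] = {
            "n_cells": len(cells),
            "n_naive": n_naive,
            "n_memory": len(cells) - n_naive,
        }
        logger.info("classify: %d naive / %d memory", n_naive, len(cells) - n_naive)

        stage = "clonotype"
        assignment = _classify.compute_clonotypes(
            cells, cdr3_nt_identity=config.cdr3_nt_identity
        )
        assignment.to_tsv(outdir / "clonotypes.tsv")
        paths["clonotypes"] = str(outdir / "clonotypes.tsv")
        summary["clonotype"] = {"n_clonotypes": assignment.n_clonotypes}
        write_per_cell_table(cells, outdir / "per_cell.tsv")
        paths["per_cell"] = str(outdir / "per_cell.tsv")

        stage = "coherence"
        summary["coherence"] = _stage_coherence(
            config, cells, assignment, reference, outdir, paths
        )

        if config.run_groups:
            stage = "groups"
            summary["groups"] = _stage_groups(config, cells, assignment, outdir, paths)

        if config.run_junctions:
            stage = "junctions"
            summary["junctions"] = _stage_junctions(
                config, cells, reference, outdir, paths
            )
    except Exception as exc:  # noqa: BLE001
        logger.error("stage %s failed: %s", stage, exc)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = str(summary_path)
    return PipelineResult(summary=summary, cells=cells, reference=reference,
                          paths=paths)


def _stage_ingest(config: PipelineConfig, summary: dict):
    if config.simulate is not None:
        sim = simulate_repertoire(config.simulate)
        summary["ingest"] = {"source": "simulate", "n_cells": len(sim.cells)}
        return sim.cells, sim.reference
    reference = read_germline_fasta(config.germline_fasta)
    if config.per_cell_table is not None:
        cells = read_per_cell_table(config.per_cell_table)
        summary["ingest"] = {"source": "per_cell_table", "n_cells": len(cells)}
        return cells, reference
    cells = []
    dropped_total: Dict[str, int] = {}
    for path in config.airr_paths:
        result = read_airr_rearrangements(path)
        batch, dropped = assemble_cells(result)
        cells.extend(batch)
        for k, v in dropped.items():
            dropped_total[k] = dropped_total.get(k, 0) + v
    summary["ingest"] = {
        "source": "airr",
        "n_cells": len(cells),
        "dropped": dropped_total,
    }
    return cells, reference


def _stage_coherence(config, cells, assignment, reference, outdir, paths) -> dict:
    out: Dict[str, object] = {}
    curve_rows = []
    for cls in config.classes:
        cross = _coherence.enumerate_pairs(cells, "cross_donor", cls)
        curves = _coherence.coherence_curve(
            cross, stratify_by=None, merge_paralogs=config.merge_paralogs
        )
        pooled = curves.get("all", _coherence.CoherenceCurve(label="all"))
        n100, c100 = pooled.at_bin(100)
        out[cls] = {
            "n_pairs": len(cross),
            "bin100_pairs": n100,
            "bin100_coherence": c100 / n100 if n100 else None,
            "curve": _curve_record(pooled),
        }
        for label, curve in _coherence.coherence_curve(
            cross, stratify_by="donor_pair", merge_paralogs=config.merge_paralogs
        ).items():
            for b, n, c in zip(curve.bins, curve.pair_count, curve.coherent_count):
                curve_rows.append(
                    {"class": cls, "stratum": label, "bin": b,
                     "pair_count": int(n), "coherent_count": int(c)}
                )
        same = _coherence.enumerate_pairs(
            cells, "same_donor", cls, assignment=assignment, reference=reference
        )
        s100 = [p for p in same if p.identity_bin == 100]
        out[cls]["same_donor"] = {
            "n_pairs": len(same),
            "bin100_pairs": len(s100),
            "bin100_coherence": (
                _coherence.light_chain_coherence(s100, config.merge_paralogs)
                if s100 else None
            ),
        }

    if config.run_permutation:
        null = _coherence.permute_light_chains(
            cells, n_perm=config.n_permutations, seed=config.seed,
            assignment=assignment, merge_paralogs=config.merge_paralogs,
        )
        out["permutation_null"] = {
            "n_perm": null.n_perm,
            "n_pairs": null.n_pairs,
            "overall_mean": null.overall_mean,
            "overall_sem": null.overall_sem,
            "analytic_match_probability": null.analytic,
        }

    memory = [c for c in cells if c.cell_class == "memory"]
    if memory:
        vh, vl = _coherence.clonotype_vh_vl_labels(
            memory, assignment, config.merge_paralogs
        )
        if len(set(vh)) > 1 and len(set(vl)) > 1:
            result = _coherence.vh_vl_contingency_test(
                vh, vl, n_mc=config.contingency_n_mc, seed=config.seed
            )
            out["vh_vl_contingency"] = {
                "statistic": result.statistic,
                "p": result.p,
                "n_mc": result.n_mc,
                "n_clonotypes": result.n_observations,
            }

    for cls in config.classes:
        rec = _coherence.count_recurrences(cells, cell_class=cls)
        out.setdefault("recurrences", {})[cls] = {
            "n_recurrent_cells": rec.n_recurrent_cells,
            "n_recurrent_keys": rec.n_recurrent_keys,
            "mean_cdrh3_length": rec.mean_cdrh3_length,
        }

    import pandas as pd

    pd.DataFrame(curve_rows).to_csv(outdir / "coherence_curves.csv", index=False)
    paths["coherence_curves"] = str(outdir / "coherence_curves.csv")
    return out


def _stage_groups(config, cells, assignment, outdir, paths) -> dict:
    built = _groups.build_transitive_groups(
        cells, config.group_identity_threshold, assignment
    )
    cells_by_id = {c.cell_id: c for c in cells}
    import pandas as pd

    rows = [
        {"group_id": g.group_id, "cell_id": cid}
        for g in built
        for cid in g.cell_ids
    ]
    pd.DataFrame(rows, columns=["group_id", "cell_id"]).to_csv(
        outdir / "groups.tsv", sep="\t", index=False
    )
    paths["groups"] = str(outdir / "groups.tsv")
    multi = [g for g in built if len(g.donors) >= 2]
    coherences = [
        _groups.group_coherence(g, cells_by_id, config.merge_paralogs).pair_coherence
        for g in multi
    ]
    coherences = [c for c in coherences if not np.isnan(c)]
    return {
        "identity_threshold": config.group_identity_threshold,
        "n_groups": len(built),
        "n_multi_donor_groups": len(multi),
        "mean_cross_donor_coherence": (
            float(np.mean(coherences)) if coherences else None
        ),
        "largest_group_size": max((g.size for g in built), default=0),
    }


def _stage_junctions(config, cells, reference, outdir, paths) -> dict:
    selected = sorted(cells, key=lambda c: c.cell_id)[: config.junction_max_cells]
    decomps = _junctions.decompose_cells(selected, reference)
    import pandas as pd

    rows = [
        {
            "cell_id": cid,
            "topology": d.topology,
            "d_genes": "+".join(d.d_genes),
            "inserted": d.inserted_bases,
            "deleted": d.deleted_bases,
            "substitutions": d.substitutions,
            "aligned": d.aligned_bases,
            "rate": round(d.substitution_rate, 6),
        }
        for cid, d in sorted(decomps.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    paths["junctions"] = str(outdir / "junctions.tsv")
    ins = [d.inserted_bases for d in decomps.values()]
    return {
        "n_decomposed": len(decomps),
        "mean_inserted_bases": float(np.mean(ins)) if ins else None,
        "vddj_rate": float(np.mean([d.topology == "VDDJ" for d in decomps.values()]))
        if decomps else None,
        "zero_insertion_fraction": float(np.mean([i == 0 for i in ins]))
        if ins else None,
    }
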