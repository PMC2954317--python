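"""End-to-end orchestration: simulate -> quantify -> gate -> noise -> DE -> enrichment.

Stages communicate only through files under the output directory, so each
stage can also be run standalone on user-supplied data; the bundle is
deterministic under the configured seed and carries a machine-readable
manifest (seed, thresholds, SHA-256 digests of every emitted table).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_expr, enrichment, qpcr_panel, synthdata, variability
from . import junction_quant as jq

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """All thresholds and sizes of one pipeline run.

    Defaults are the study thresholds: gene fold-change bounds 4 / 0.25 and
    variant bounds 2 / 0.5 at p < 0.01, expressed variants at >= 5 pooled
    counts, detection floors 0.1 RPM and Ct < 32, CV strata cut at 1 and 10
    RPM, consensus targets from >= 2 algorithms.
    """

    seed: int = 0
    fc_hi: float = 4.0
    fc_lo: float = 0.25
    variant_fc_hi: float = 2.0
    variant_fc_lo: float = 0.5
    alpha: float = 0.01
    min_counts: int = 5
    rpm_floor: float = 0.1
    ct_threshold: float = 32.0
    strata: tuple[float, float] = (1.0, 10.0)
    min_algorithms: int = 2
    n_genes: int = 2000
    n_mirnas: int = 60
    mirna_universe: int = 10_000
    input_files: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return validate_config(cls(**raw))


def validate_config(config: RunConfig) -> RunConfig:
    """Check threshold ranges and referenced files; inject a default seed."""
    errors = []
    if config.seed is None:
        config = dataclasses.replace(config, seed=0)
        logger.info("no seed given; defaulting to 0")
    if not config.fc_lo < config.fc_hi:
        errors.append("fc_lo must be < fc_hi")
    if not config.variant_fc_lo < config.variant_fc_hi:
        errors.append("variant_fc_lo must be < variant_fc_hi")
    if not 0 < config.alpha <= 1:
        errors.append("alpha must be in (0, 1]")
    if config.min_counts < 0:
        errors.append("min_counts must be >= 0")
    if config.rpm_floor <= 0:
        errors.append("rpm_floor must be > 0")
    if not 0 < config.ct_threshold <= 40:
        errors.append("ct_threshold must be in (0, 40]")
    if not config.strata[0] < config.strata[1]:
        errors.append("strata bounds must be increasing")
    if config.min_algorithms < 1:
        errors.append("min_algorithms must be >= 1")
    for f in config.input_files:
        if not Path(f).exists():
            errors.append(f"missing input file: {f}")
    if errors:
        raise ValueError("; ".join(errors))
    return config


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir) -> dict:
    """Run the full synthetic pipeline; returns the summary dict.

    Emits per-stage tables, ``summary.json`` and ``manifest.json`` under
    ``out_dir``.  Any stage failure aborts with the stage name attached.
    """
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "simulate"
    try:
        # --- simulate staged population -------------------------------
        pop_config, truth = synthdata.default_config(
            seed=config.seed, n_genes=config.n_genes
        )
        cm, truth = synthdata.generate_counts(pop_config, truth)
        cm.to_tsv(out / "counts.tsv")
        cm.library_size.to_frame("library_size").join(cm.stage).to_csv(
            out / "cells.tsv", sep="\t"
        )
        rpm = cm.rpm

        # --- junction quantification on a toy two-isoform locus -------
        stage = "junction_quant"
        models = synthdata.random_gene_models(n_genes=2, seed=config.seed + 1)
        abundances = pd.DataFrame(
            {"ICM": [88, 35, 20, 5], "ESC": [13, 142, 20, 40]},
            index=[m.variant_id for m in models],
        )
        reads, reference, jx_truth = synthdata.generate_junction_reads(
            models, abundances, mismatch_rate=0.01, seed=config.seed + 2
        )
        synthdata.write_reads_fasta(reads, out / "junction_reads.fasta")
        reference.to_fasta(out / "junctions.fasta")
        reference.to_map_tsv(out / "junctions.map.tsv")
        table = jq.match_reads(reads, reference)
        _write(table.counts, out / "junction_counts.tsv")
        _write(table.rpm, out / "junction_rpm.tsv")
        _write(table.stats, out / "junction_stats.tsv")

        # --- qPCR gating ----------------------------------------------
        stage = "qpcr_gate"
        ctm = synthdata.generate_ct_matrix(
            synthdata.default_ct_design(), seed=config.seed + 3
        )
        ctm.to_csv(out / "ct_matrix.csv")
        gate = qpcr_panel.gate_pluripotency(ctm, threshold=config.ct_threshold)
        _write(gate.fractions, out / "gate_fractions.tsv")

        # --- variability ----------------------------------------------
        stage = "variability"
        esc_cells = cm.cells_of("ESC")
        profile = variability.cv_profile(
            rpm[esc_cells], detect_rpm=config.rpm_floor, bounds=config.strata
        )
        _write(profile.set_index("feature"), out / "cv_profile_esc.tsv")
        _write(variability.stratum_summary(profile), out / "cv_strata_esc.tsv")
        coords, evr = variability.embed(rpm)
        _write(coords.join(cm.stage), out / "embedding.tsv")
        summary["embedding_explained_variance"] = [round(float(v), 6) for v in evr]

        # --- differential expression ----------------------------------
        stage = "diff_expr"
        icm_cells = cm.cells_of("ICM")
        gde = diff_expr.gene_de(
            rpm, esc_cells, icm_cells, "ESC", "ICM",
            fc_hi=config.fc_hi, fc_lo=config.fc_lo, alpha=config.alpha,
            floor=config.rpm_floor,
        )
        _write(gde.set_index("feature"), out / "gene_de.tsv")
        summary["gene_de"] = diff_expr.summarize_de(gde)

        vde = diff_expr.variant_de(
            table, reference, "ESC", "ICM",
            fc_hi=config.variant_fc_hi, fc_lo=config.variant_fc_lo,
            alpha=config.alpha, min_counts=config.min_counts,
            floor=config.rpm_floor,
        )
        _write(vde.set_index("feature"), out / "variant_de.tsv")
        summary["variant_de"] = diff_expr.summarize_de(vde)

        # epigenetic-regulator style panel: planted up/down genes
        panel = [g for g, f in truth.planted_de_genes.items()][:60]
        ps = diff_expr.panel_summary(
            gde, panel, "planted_panel", change_fold=2.0, alpha=config.alpha
        )
        summary["panel"] = dataclasses.asdict(ps) | {
            "percent_changed": ps.percent_changed
        }

        day5 = cm.cells_of("Day5_Oct4pos", "Day5_Oct4neg")
        r = diff_expr.pluripotency_correlation(rpm[day5])
        r.to_frame().to_csv(out / "pluripotency_r.tsv", sep="\t", float_format=_FLOAT_FMT)
        summary["anticorrelated_recovered"] = int(
            (r[list(truth.anticorrelated_genes)] < -0.6).sum()
        )

        # --- miRNA ----------------------------------------------------
        stage = "enrichment"
        profile_tbl, targets, mtruth = synthdata.generate_mirna_fixture(
            n_mirnas=config.n_mirnas,
            n_genes=config.mirna_universe,
            seed=config.seed + 4,
            planted_folds=synthdata.default_mirna_folds(
                n_differential=12, seed=config.seed + 5
            ),
        )
        _write(profile_tbl, out / "mirna_profile.tsv")
        targets.to_csv(out / "mirna_targets.tsv", sep="\t", index=False)
        consensus = enrichment.consensus_targets(targets, config.min_algorithms)
        planted = list(mtruth.planted_mirna_targets)[:10]
        universe = [f"G{i:05d}" for i in range(config.mirna_universe)]
        enr = enrichment.mirna_class_enrichment(
            planted, consensus, mtruth.mirna_class_genes, universe
        )
        summary["mirna_enrichment"] = dataclasses.asdict(enr)
        groups = {
            "ICM": [c for c in profile_tbl.columns if c.startswith("ICM")],
            "ESC": [c for c in profile_tbl.columns if c.startswith("ESC")],
        }
        mde = enrichment.mirna_de(profile_tbl, groups, "ESC", "ICM", alpha=config.alpha)
        _write(mde.set_index("mirna"), out / "mirna_de.tsv")
        summary["mirna_de"] = {
            "n_up": int((mde["call"] == "up").sum()),
            "n_down": int((mde["call"] == "down").sum()),
        }
    except Exception as exc:  # attach the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- report bundle ------------------------------------------------
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "package": "sctrace",
        "version": _version(),
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "files": {
            p.name: _digest(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary


def _version() -> str:
    from . import __version__

    return __version__
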