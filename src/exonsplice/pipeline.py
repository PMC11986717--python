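"""End-to-end orchestration: configuration, staged execution, artifacts.

``analyze`` runs the whole analysis in memory and returns a state object;
``run_pipeline`` additionally writes every artifact (filter ledger, presence
tables, DE/AS tables, fold changes, enrichment tables, run log) into the
output directory.  A rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova_core, chip_model, enrichment, preprocess, presence_summary, summarize_filter
from .chip_model import GroupDesign, IntensityMatrix
from .errors import ExonSpliceError, InputError
from .synthetic_data import SimConfig, simulate_chip, recovery_metrics

log = logging.getLogger(__name__)

_SCHEMA: dict[str, dict] = {
    "inputs": {
        "intensity": None, "annotation": None, "background": None,
        "sample_sheet": None, "gene_sets": None,
    },
    "simulate": {f.name: None for f in dataclasses.fields(SimConfig)},
    "gc": {"min": 6, "max": 17},
    "log": {"offset": 0.1, "base": 2.0},
    "presence": {
        "require": "any", "pvar": "literal", "n0": "standardized",
        "probeset_alpha": 0.001, "gene_alpha": 0.01,
    },
    "alpha": {"anova": 0.01, "fc_ttest": 0.05},
    "fc": {"reference": None},
    "cluster": {"min_sets": 4, "max_sets": 200},
    "invariance": {"q": 0.10, "reference": "median"},
    "enrichment": {"alpha": 0.01, "bh": False},
}


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (defaults documented in _SCHEMA)."""

    outdir: str | None = None
    inputs: dict = field(default_factory=dict)
    simulate: dict | None = None
    gc: dict = field(default_factory=lambda: dict(_SCHEMA["gc"]))
    log: dict = field(default_factory=lambda: dict(_SCHEMA["log"]))
    presence: dict = field(default_factory=lambda: dict(_SCHEMA["presence"]))
    alpha: dict = field(default_factory=lambda: dict(_SCHEMA["alpha"]))
    fc: dict = field(default_factory=lambda: dict(_SCHEMA["fc"]))
    cluster: dict = field(default_factory=lambda: dict(_SCHEMA["cluster"]))
    invariance: dict = field(default_factory=lambda: dict(_SCHEMA["invariance"]))
    enrichment: dict = field(default_factory=lambda: dict(_SCHEMA["enrichment"]))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_SCHEMA) - {"outdir"}
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(outdir=raw.get("outdir"))
        for section, defaults in _SCHEMA.items():
            user = raw.get(section)
            if user is None:
                continue
            if not isinstance(user, dict):
                raise InputError(f"config section {section!r} must be a mapping")
            bad = set(user) - set(defaults)
            if bad:
                raise InputError(f"unknown config key(s) in {section!r}: {sorted(bad)}")
            merged = dict(getattr(cfg, section) or {})
            merged.update(user)
            setattr(cfg, section, merged)
        if cfg.simulate is not None and "seed" not in cfg.simulate:
            raise InputError("simulate block requires a seed")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


@dataclass
class PipelineState:
    """Everything the analysis computed, stage by stage."""

    design: GroupDesign
    annotation: chip_model.ChipAnnotation
    corrected: IntensityMatrix
    background_model: preprocess.BackgroundModel
    cascade: summarize_filter.CascadeResult
    gene_presence: pd.DataFrame
    coexpression: presence_summary.CoexpressionTable
    differential: anova_core.DifferentialResult
    fold_changes: pd.DataFrame
    enrichment_table: pd.DataFrame | None
    truth: pd.DataFrame | None  # only for simulated inputs
    recovery: dict | None


def _stage(name: str):
    """Decorator-ish context: re-raise package errors with the stage name."""

    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ExonSpliceError):
                raise type(exc)(f"[stage {name}] {exc}") from None
            return False

    return _Ctx()


def analyze(cfg: PipelineConfig) -> PipelineState:
    """Run the full analysis and return the in-memory state."""
    truth = None
    catalog = None
    if cfg.simulate is not None:
        with _stage("simulate"):
            sim = simulate_chip(SimConfig(**cfg.simulate))
            m, ann, bg, design, truth = (
                sim.intensity, sim.annotation, sim.background, sim.design, sim.truth,
            )
    else:
        with _stage("load-inputs"):
            req = ["intensity", "annotation", "background", "sample_sheet"]
            missing = [k for k in req if not cfg.inputs.get(k)]
            if missing:
                raise InputError(f"missing input path(s): {missing}")
            m = chip_model.read_intensity_matrix(cfg.inputs["intensity"])
            ann = chip_model.read_annotation(cfg.inputs["annotation"])
            with _stage("background"):
                bg = chip_model.read_background(cfg.inputs["background"])
            design = chip_model.read_sample_sheet(cfg.inputs["sample_sheet"])
            design.validate_against(m)
    if cfg.inputs.get("gene_sets"):
        with _stage("load-gene-sets"):
            catalog = chip_model.read_gene_sets(cfg.inputs["gene_sets"])

    with _stage("normalize"):
        m = preprocess.quantile_normalize(m)
    with _stage("transform"):
        m = preprocess.log_transform(m, offset=cfg.log["offset"], base=cfg.log["base"])
        gc_mask = preprocess.filter_probes_by_gc(ann, cfg.gc["min"], cfg.gc["max"])
    with _stage("background"):
        bg.check_disjoint(ann)
        model = preprocess.fit_background_model(m, bg, design)
        corrected = preprocess.subtract_gc_background(m, model, ann)
    with _stage("filter-cascade"):
        cascade = summarize_filter.run_filter_cascade(
            corrected, ann, model, design, gc_mask,
            presence_alpha=cfg.presence["probeset_alpha"],
            presence_require=cfg.presence["require"],
            pvar_mode=cfg.presence["pvar"],
            invariance_q=cfg.invariance["q"],
            invariance_reference=cfg.invariance["reference"],
            min_sets=cfg.cluster["min_sets"],
            max_sets=cfg.cluster["max_sets"],
        )
    with _stage("gene-presence"):
        gp = presence_summary.gene_presence(
            corrected, model, ann, design,
            alpha=cfg.presence["gene_alpha"],
            probes=cascade.passing_probes,
            clusters=cascade.clusters,
            mode=cfg.presence["n0"],
        )
        coex = presence_summary.coexpression_summary(gp, design)
    with _stage("anova"):
        diff = anova_core.run_differential_analysis(
            cascade.probe_sets, design,
            alpha=cfg.alpha["anova"], gene_presence=gp,
        )
    with _stage("fold-change"):
        fc = anova_core.fold_change_and_ttest(
            cascade.probe_sets, design,
            offset=cfg.log["offset"], base=cfg.log["base"],
            reference=cfg.fc["reference"],
        )
    enr = None
    if catalog is not None:
        with _stage("enrichment"):
            enr = enrichment.enrich_catalog(
                set(diff.de_genes), set(diff.as_genes),
                set(cascade.clusters), catalog,
                alpha=cfg.enrichment["alpha"], bh_column=cfg.enrichment["bh"],
            )
    recovery = None
    if truth is not None:
        tested = set(cascade.clusters)
        recovery = {
            "de": recovery_metrics(diff.de_genes, truth, "de", universe=tested),
            "as": recovery_metrics(diff.as_genes, truth, "as", universe=tested),
        }
    return PipelineState(
        design, ann, corrected, model, cascade, gp, coex, diff, fc, enr, truth, recovery
    )


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the analysis and write all artifacts into ``cfg.outdir``."""
    if not cfg.outdir:
        raise InputError("config must set an output directory (outdir)")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("exonsplice")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        state = analyze(cfg)
        (outdir / "config_resolved.yaml").write_text(cfg.to_yaml(), encoding="utf-8")
        state.cascade.ledger.to_tsv(outdir / "filter_ledger.tsv")
        state.cascade.ledger.to_tsv(outdir / "filter_ledger_paper.tsv", paper_style=True)
        state.gene_presence.to_csv(
            outdir / "gene_presence.tsv", sep="\t", index=False, lineterminator="\n"
        )
        (outdir / "coexpression.txt").write_text(state.coexpression.render(), encoding="utf-8")
        t = state.differential.table.sort_values("p_group_adj", kind="mergesort")
        t.to_csv(outdir / "anova_table.tsv", sep="\t", index=False, lineterminator="\n")
        de = t[t["transcript_cluster_id"].isin(set(state.differential.de_genes))]
        de.to_csv(outdir / "de_table.tsv", sep="\t", index=False, lineterminator="\n")
        a = state.differential.table.sort_values("p_interaction_adj", kind="mergesort")
        asg = a[a["transcript_cluster_id"].isin(set(state.differential.as_genes))]
        asg.to_csv(outdir / "as_table.tsv", sep="\t", index=False, lineterminator="\n")
        fc = state.fold_changes.merge(
            state.differential.table[["transcript_cluster_id", "p_group", "p_group_adj"]],
            on="transcript_cluster_id", how="left",
        )
        fc.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False, lineterminator="\n")
        hist, edges = np.histogram(
            state.differential.table["p_interaction"].dropna(), bins=20, range=(0, 1)
        )
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}).to_csv(
            outdir / "pvalue_histogram.tsv", sep="\t", index=False, lineterminator="\n"
        )
        if state.enrichment_table is not None:
            state.enrichment_table.to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False, lineterminator="\n"
            )
            for cls, text in enrichment.render_paper_style(state.enrichment_table).items():
                (outdir / f"enrichment_{cls}.txt").write_text(text, encoding="utf-8")
        if state.truth is not None:
            state.truth.to_csv(outdir / "truth.tsv", sep="\t", lineterminator="\n")
            rec = pd.DataFrame(state.recovery).T
            rec.to_csv(outdir / "recovery.tsv", sep="\t", lineterminator="\n")
        log.info("wrote artifacts to %s", outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
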