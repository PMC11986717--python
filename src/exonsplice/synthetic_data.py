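"""Synthetic probe-level exon-array data with known truth.

The generator emulates the statistical structure the pipeline assumes:
transcript clusters of several probe sets of ~4 probes each, GC-dependent
probe affinity shared with a population of antigenomic background probes,
array (hybridization) effects nested in treatment group, and optional
spiked group effects (differential expression) and single-exon group x exon
effects (alternative splicing).  Effects are additive on the log2 scale and
therefore exactly multiplicative on the raw intensity scale.

Every gene draws from its own counter-keyed random stream, so enlarging the
simulation does not perturb earlier genes' values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chip_model import (
    BackgroundProbeTable,
    ChipAnnotation,
    GeneSetCatalog,
    GroupDesign,
    IntensityMatrix,
    Stage,
    write_annotation,
    write_background,
    write_gene_sets,
    write_intensity_matrix,
    write_sample_sheet,
)
from .errors import InputError

log = logging.getLogger(__name__)

# spawn keys for the shared (non-gene) streams
_KEY_BACKGROUND = 1_000_000
_KEY_ARRAYS = 1_000_001
_KEY_CATALOG = 1_000_002


@dataclass
class SimConfig:
    """Study conditions of a simulated chip experiment.

    Defaults model a two-group liver study (non-genotoxic vs genotoxic arm)
    with 3 hybridizations per group, genes of 4-12 probe sets of 4 probes,
    a unimodal probe GC distribution centred at 12 (support 3..25), 200
    background probes per GC bin, and log2-scale effect sizes.
    """

    seed: int
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 12)
    probes_per_set: int = 4
    gc_range: tuple[int, int] = (3, 25)
    groups: tuple[str, ...] = ("bht-1-mf", "ndea-1-mf")
    arrays_per_group: int = 3
    bg_probes_per_bin: int = 200
    baseline_mean: float = 7.0  # log2 probe-set baseline (mu0)
    baseline_sd: float = 1.0
    background_mean: float = 4.0  # log2 level of antigenomic probes
    beta_gc: float = 0.05  # GC affinity slope per GC unit around 12
    sigma_array: float = 0.1  # hybridization (array) effect SD
    sigma_resid: float = 0.25  # residual probe noise SD
    f_de: float = 0.0  # fraction of genes with a group shift
    f_as: float = 0.0  # fraction of genes with a one-exon group x exon shift
    delta_de: float = 1.0  # log2 units
    delta_as: float = 2.0  # log2 units
    extended_fraction: float = 0.0  # fraction of probe sets annotated Extended

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("SimConfig.seed is mandatory")
        if self.n_genes < 1 or self.arrays_per_group < 1 or len(self.groups) < 1:
            raise InputError("need >= 1 gene, >= 1 array per group, >= 1 group")
        for s in (self.baseline_sd, self.sigma_array, self.sigma_resid):
            if s < 0:
                raise InputError("standard deviations must be >= 0")
        for f in (self.f_de, self.f_as, self.extended_fraction):
            if not 0.0 <= f <= 1.0:
                raise InputError("fractions must lie in [0, 1]")
        if round(self.f_de * self.n_genes) + round(self.f_as * self.n_genes) > self.n_genes:
            raise InputError("f_de + f_as spike more genes than exist")


@dataclass
class SimulatedChip:
    """Raw intensities, annotation, background table, design and truth."""

    intensity: IntensityMatrix
    annotation: ChipAnnotation
    background: BackgroundProbeTable
    design: GroupDesign
    truth: pd.DataFrame  # index cluster: is_de, is_as, affected_exon, delta_de, delta_as, n_exons
    config: SimConfig


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_chip(cfg: SimConfig) -> SimulatedChip:
    """Generate one chip experiment; deterministic given ``cfg.seed``."""
    groups = list(cfg.groups)
    array_ids = [f"{g}_a{j + 1}" for g in groups for j in range(cfg.arrays_per_group)]
    n_arrays = len(array_ids)
    group_of_array = np.repeat(np.arange(len(groups)), cfg.arrays_per_group)

    rng_arr = _gene_rng(cfg.seed, _KEY_ARRAYS)
    array_eff = rng_arr.normal(0.0, cfg.sigma_array, n_arrays)

    n_de = round(cfg.f_de * cfg.n_genes)
    n_as = round(cfg.f_as * cfg.n_genes)
    lo, hi = cfg.exons_per_gene
    gmin, gmax = cfg.gc_range
    span = gmax - gmin
    p_gc = (12 - gmin) / span  # unimodal around 12

    probe_ids: list[str] = []
    ann_rows: list[tuple] = []
    blocks: list[np.ndarray] = []
    truth_rows = []
    # treatment arm receiving the spike: the last group (vs the first as reference)
    spike_group = len(groups) - 1

    for i in range(cfg.n_genes):
        rng = _gene_rng(cfg.seed, i)
        cluster = f"TC{i:05d}"
        n_exons = int(rng.integers(lo, hi + 1))
        baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_exons)
        gcs = rng.binomial(span, p_gc, n_exons * cfg.probes_per_set) + gmin
        affected = int(rng.integers(n_exons))
        is_de = i < n_de
        is_as = n_de <= i < n_de + n_as
        noise = rng.normal(0.0, cfg.sigma_resid, (n_exons * cfg.probes_per_set, n_arrays))
        levels = rng.random(n_exons) < cfg.extended_fraction

        exon_idx = np.repeat(np.arange(n_exons), cfg.probes_per_set)
        logv = (
            baselines[exon_idx][:, None]
            + cfg.beta_gc * (gcs - 12)[:, None]
            + array_eff[None, :]
            + noise
        )
        if is_de:
            logv += cfg.delta_de * (group_of_array == spike_group)[None, :]
        if is_as:
            mask = (exon_idx == affected)[:, None] & (group_of_array == spike_group)[None, :]
            logv += cfg.delta_as * mask
        blocks.append(logv)

        for j, (e, gc) in enumerate(zip(exon_idx, gcs)):
            ps_id = f"{cluster}_PS{e:02d}"
            probe_id = f"{ps_id}_p{j % cfg.probes_per_set}"
            level = "Extended" if levels[e] else "Core"
            probe_ids.append(probe_id)
            ann_rows.append((probe_id, int(gc), ps_id, cluster, level))
        truth_rows.append(
            {
                "transcript_cluster_id": cluster,
                "is_de": is_de,
                "is_as": is_as,
                "affected_exon": affected if is_as else -1,
                "delta_de": cfg.delta_de if is_de else 0.0,
                "delta_as": cfg.delta_as if is_as else 0.0,
                "n_exons": n_exons,
            }
        )

    # antigenomic background probes, sharing GC affinity and noise structure
    rng_bg = _gene_rng(cfg.seed, _KEY_BACKGROUND)
    bg_ids, bg_gc, bg_blocks = [], [], []
    for gc in range(gmin, gmax + 1):
        vals = (
            cfg.background_mean
            + cfg.beta_gc * (gc - 12)
            + array_eff[None, :]
            + rng_bg.normal(0.0, cfg.sigma_resid, (cfg.bg_probes_per_bin, n_arrays))
        )
        bg_blocks.append(vals)
        bg_ids.extend(f"BG{gc:02d}_{j}" for j in range(cfg.bg_probes_per_bin))
        bg_gc.extend([gc] * cfg.bg_probes_per_bin)

    log_matrix = np.concatenate(blocks + bg_blocks, axis=0)
    all_ids = probe_ids + bg_ids
    raw = pd.DataFrame(
        np.power(2.0, log_matrix), index=pd.Index(all_ids, name="probe_id"), columns=array_ids
    )
    intensity = IntensityMatrix(raw, Stage.RAW)

    ann_df = pd.DataFrame(
        ann_rows,
        columns=["probe_id", "gc_count", "probe_set_id", "transcript_cluster_id", "annotation_level"],
    )
    probes = ann_df.set_index("probe_id")[["gc_count", "probe_set_id"]]
    probe_sets = (
        ann_df[["probe_set_id", "transcript_cluster_id", "annotation_level"]]
        .drop_duplicates()
        .set_index("probe_set_id")
    )
    annotation = ChipAnnotation(probes, probe_sets, max_probe_length=max(25, gmax))
    background = BackgroundProbeTable(
        pd.DataFrame({"gc_count": bg_gc}, index=pd.Index(bg_ids, name="probe_id"))
    )
    design = GroupDesign(
        pd.Series(
            [groups[g] for g in group_of_array], index=pd.Index(array_ids, name="array_id")
        ),
        groups=tuple(groups),
    )
    truth = pd.DataFrame(truth_rows).set_index("transcript_cluster_id")
    log.info(
        "simulated chip: %d genes (%d DE, %d AS spiked), %d probes, %d background probes, %d arrays",
        cfg.n_genes, n_de, n_as, len(probe_ids), len(bg_ids), n_arrays,
    )
    return SimulatedChip(intensity, annotation, background, design, truth, cfg)


def simulate_catalog(
    cluster_ids,
    seed: int,
    terms_per_class: int = 15,
    size_range: tuple[int, int] = (5, 40),
) -> GeneSetCatalog:
    """Random flat gene-set catalog over the given clusters (for pipeline runs)."""
    from .chip_model import GENE_SET_CLASSES

    rng = _gene_rng(seed, _KEY_CATALOG)
    ids = np.asarray(list(cluster_ids))
    rows = []
    for cls in GENE_SET_CLASSES:
        for t in range(terms_per_class):
            size = int(rng.integers(size_range[0], min(size_range[1], len(ids)) + 1))
            members = frozenset(rng.choice(ids, size=size, replace=False))
            rows.append(
                {
                    "class": cls,
                    "term_id": f"{cls}:{t:04d}",
                    "term_name": f"synthetic term {t} ({cls})",
                    "members": members,
                }
            )
    return GeneSetCatalog(pd.DataFrame(rows))


def recovery_metrics(
    called,
    truth: pd.DataFrame,
    kind: str = "as",
    universe=None,
) -> dict:
    """Confusion-matrix rates of a call set against the simulation truth.

    ``kind`` selects the truth column (``de`` or ``as``); ``universe`` is the
    set of genes actually tested (defaults to every simulated gene).  With an
    empty call set the FDR is reported as 0 with ``fdr_defined`` False.
    """
    col = {"de": "is_de", "as": "is_as"}.get(kind)
    if col is None:
        raise InputError(f"kind must be 'de' or 'as', got {kind!r}")
    universe = set(truth.index) if universe is None else set(universe)
    called = set(called)
    stray = called - universe
    if stray:
        raise InputError(f"called gene(s) outside the tested universe: {sorted(stray)[:3]}")
    positives = {g for g in universe if bool(truth.loc[g, col])}
    negatives = universe - positives
    tp = len(called & positives)
    fp = len(called & negatives)
    fn = len(positives - called)
    tn = len(negatives - called)
    power = tp / (tp + fn) if (tp + fn) else 0.0
    fdr_defined = (tp + fp) > 0
    fdr = fp / (tp + fp) if fdr_defined else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "power": power, "fdr": fdr, "fdr_defined": fdr_defined,
        "specificity": specificity,
        "n_positives": len(positives), "n_tested": len(universe),
    }


def write_simulated(sim: SimulatedChip, outdir: str | Path) -> dict[str, Path]:
    """Write the five standard TSVs plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensity": outdir / "intensity.tsv",
        "annotation": outdir / "annotation.tsv",
        "background": outdir / "background.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_intensity_matrix(sim.intensity, paths["intensity"])
    write_annotation(sim.annotation, paths["annotation"])
    write_background(sim.background, paths["background"])
    write_sample_sheet(sim.design, paths["sample_sheet"])
    sim.truth.to_csv(paths["truth"], sep="\t", lineterminator="\n")
    return paths
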