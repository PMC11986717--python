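"""Probe-set summarization and the five-step filter cascade.

The cascade mirrors the chip-level filter ledger: (0) totals on chip,
(1) Core probe sets only, (2) GC-passing probes with >=3 passing probes per
probe set, (3) probe sets expressed above background, (4) a named no-op
(no absolute-score filter), (5) the chi-square invariance filter; the final
analysis gene list is the transcript clusters left with 4..200 passing probe
sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chip_model import ChipAnnotation, GroupDesign, IntensityMatrix, Stage
from .errors import InputError, NumericalError
from .preprocess import BackgroundModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class ProbeSetMatrix:
    """Probe-set x array score matrix plus per-set metadata.

    ``scores`` is indexed by probe_set_id with array columns; ``meta`` carries
    ``n_probes`` (count of passing probes summarized) and
    ``transcript_cluster_id``; ``probes`` is the passing-probe table
    (index probe_id, columns probe_set_id and gc_count) used for the
    GC-composition of presence statistics.  Matrices produced by
    :func:`summarize_probe_sets` are guaranteed to have >= 3 passing probes
    per retained set.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise InputError("non-finite probe-set score")
        if not self.scores.index.equals(self.meta.index):
            raise InputError("scores/meta index mismatch")

    @property
    def probe_set_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def array_ids(self) -> pd.Index:
        return self.scores.columns

    def clusters(self) -> pd.Series:
        return self.meta["transcript_cluster_id"]

    def restrict(self, probe_set_ids) -> "ProbeSetMatrix":
        ids = self.scores.index.intersection(pd.Index(probe_set_ids))
        probes = self.probes[self.probes["probe_set_id"].isin(set(ids))]
        return ProbeSetMatrix(self.scores.loc[ids], self.meta.loc[ids], probes)


@dataclass
class FilterLedger:
    """Machine-readable record of the filter cascade (one row per step)."""

    rows: list[dict] = field(default_factory=list)

    def append(
        self,
        step: int,
        description: str,
        probes: int | None,
        probe_sets: int | None,
        clusters: int | None,
    ) -> None:
        self.rows.append(
            {
                "step": step,
                "filter": description,
                "probes": probes,
                "probe_sets": probe_sets,
                "transcript_clusters": clusters,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def validate_monotone(self) -> None:
        """Counts never increase down the cascade (where the column applies)."""
        for col in ("probes", "probe_sets", "transcript_clusters"):
            prev = None
            for row in self.rows:
                v = row[col]
                if v is None:
                    continue
                if prev is not None and v > prev:
                    raise NumericalError(
                        f"ledger column {col} increased at step {row['step']}"
                    )
                prev = v

    def to_tsv(self, path, paper_style: bool = False) -> None:
        df = self.to_frame()
        if paper_style:
            df = df.copy()
            df["probe_sets"] = [
                "" if v is None else (f"{v:,} (**)" if s >= 2 else f"{v:,}")
                for s, v in zip(df["step"], df["probe_sets"])
            ]
            df["transcript_clusters"] = [
                "" if v is None else (f"{v:,} (*)" if s >= 1 else f"{v:,}")
                for s, v in zip(df["step"], df["transcript_clusters"])
            ]
            df["probes"] = [("" if v is None else f"{v:,}") for v in df["probes"]]
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def filter_core(ann: ChipAnnotation) -> pd.Index:
    """Probe sets at the Core annotation level (the only level analyzed)."""
    mask = ann.probe_sets["annotation_level"] == "Core"
    if not mask.any():
        warnings.warn("no Core probe sets on this chip", stacklevel=2)
    return ann.probe_sets.index[mask]


def summarize_probe_sets(
    m: IntensityMatrix,
    ann: ChipAnnotation,
    probe_mask: pd.Series,
    min_probes: int = 3,
) -> ProbeSetMatrix:
    """Median-summarize passing probes into probe-set scores.

    ``probe_mask`` is a boolean Series over annotated probes (GC filter and
    any probe-set level restriction already combined).  Probe sets with fewer
    than ``min_probes`` passing probes are dropped for all arrays, so the
    design stays balanced.
    """
    if m.stage is not Stage.BACKGROUND_CORRECTED:
        raise InputError(
            f"summarize_probe_sets expects background_corrected stage, got {m.stage.value}"
        )
    passing = probe_mask.index[probe_mask].intersection(m.probe_ids)
    probes = ann.probes.loc[passing, ["probe_set_id", "gc_count"]]
    counts = probes.groupby("probe_set_id").size()
    keep_sets = counts.index[counts >= min_probes]
    probes = probes[probes["probe_set_id"].isin(set(keep_sets))]

    sub = m.values.loc[probes.index]
    scores = sub.groupby(probes["probe_set_id"]).median()
    scores = scores.loc[keep_sets]
    meta = pd.DataFrame(
        {
            "n_probes": counts.loc[keep_sets],
            "transcript_cluster_id": ann.probe_sets.loc[keep_sets, "transcript_cluster_id"],
        }
    )
    meta.index.name = "probe_set_id"
    return ProbeSetMatrix(scores, meta, probes)


def probe_set_presence(
    ps: ProbeSetMatrix,
    model: BackgroundModel,
    design: GroupDesign,
    alpha: float = 0.001,
    pvar_mode: str = "literal",
) -> pd.DataFrame:
    """Detection-above-background call per (probe set, group).

    T is the mean probe-set score over the group's arrays; P the GC-weighted
    mean background level on the corrected scale (bin mean minus bin median,
    averaged over the set's passing probes); Pvar the total background
    variance divided by the squared probe count (``literal``) or by the probe
    count (``mean_variance``).  The set is called expressed when the upper
    normal tail at T0 = sqrt(GroupSize) * (T - P) / sqrt(Pvar) is <= alpha.
    """
    if pvar_mode not in ("literal", "mean_variance"):
        raise InputError(f"unknown pvar mode {pvar_mode!r}")
    if model.total_var <= 0:
        raise NumericalError("background total variance is zero; Pvar undefined")

    per_set_gc = ps.probes.groupby("probe_set_id")["gc_count"]
    p_bg = per_set_gc.apply(lambda g: float(np.mean(model.corrected_mean_for(g))))
    k = ps.meta["n_probes"].astype(float)
    denom = k**2 if pvar_mode == "literal" else k
    pvar = model.total_var / denom

    rows = []
    for group in design.groups:
        arrays = [a for a in design.arrays_in(group) if a in ps.scores.columns]
        gsize = len(arrays)
        if gsize == 0:
            raise InputError(f"group {group!r} has no arrays in the score matrix")
        T = ps.scores[arrays].mean(axis=1)
        t0 = np.sqrt(gsize) * (T - p_bg.loc[T.index]) / np.sqrt(pvar.loc[T.index])
        pval = stats.norm.sf(t0)
        rows.append(
            pd.DataFrame(
                {
                    "probe_set_id": T.index,
                    "group": group,
                    "group_size": gsize,
                    "n_probes": k.loc[T.index].astype(int).to_numpy(),
                    "T": T.to_numpy(),
                    "P": p_bg.loc[T.index].to_numpy(),
                    "pvar": pvar.loc[T.index].to_numpy(),
                    "t0": np.asarray(t0),
                    "p_value": pval,
                    "expressed": pval <= alpha,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def filter_expressed(
    presence: pd.DataFrame,
    groups: list[str] | None = None,
    require: str = "any",
) -> pd.Index:
    """Probe sets expressed above background in the analysis groups.

    ``require='any'`` keeps sets expressed in at least one listed group (the
    default: a set silent in every group carries no signal), ``'all'``
    demands expression in every listed group.
    """
    if require not in ("any", "all"):
        raise InputError(f"presence.require must be 'any' or 'all', got {require!r}")
    sub = presence if groups is None else presence[presence["group"].isin(groups)]
    agg = sub.groupby("probe_set_id")["expressed"].agg("any" if require == "any" else "all")
    return agg.index[agg]


def filter_invariant(
    ps: ProbeSetMatrix, n_arrays: int, q: float = 0.10, reference: str = "median"
) -> pd.Index:
    """Drop probe sets whose across-array variance is implausibly low.

    A set is dropped when (N-1) * s2_set / s2bar_gene falls below the lower
    ``q`` quantile of chi-square with N-1 degrees of freedom, where
    s2bar_gene is a per-cluster reference variance: the median probe-set
    variance of the transcript cluster by default, or its mean
    (``reference='mean'``).  The mean reference lets a single high-variance
    (e.g. genuinely spliced) exon inflate the cluster scale and mask every
    sibling exon as "invariant"; the median is robust to that.
    Single-set clusters are always kept (the statistic degenerates to N-1).
    """
    if n_arrays < 2:
        raise InputError("invariance filter needs >= 2 arrays")
    if reference not in ("median", "mean"):
        raise InputError(f"invariance reference must be 'median' or 'mean', got {reference!r}")
    s2 = ps.scores.var(axis=1, ddof=1)
    cluster = ps.clusters()
    s2bar = s2.groupby(cluster).transform(reference)
    n_sets = s2.groupby(cluster).transform("size")

    cut = stats.chi2.ppf(q, n_arrays - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (n_arrays - 1) * s2 / s2bar
    stat = stat.where(s2bar > 0, 0.0)
    stat = stat.mask(n_sets == 1, float(n_arrays - 1))  # single-set clusters kept
    return ps.scores.index[stat >= cut]


def filter_clusters(
    probe_set_ids: pd.Index,
    ann: ChipAnnotation,
    min_sets: int = 4,
    max_sets: int = 200,
) -> pd.Index:
    """Transcript clusters with min_sets..max_sets surviving probe sets."""
    clusters = ann.probe_sets.loc[probe_set_ids, "transcript_cluster_id"]
    counts = clusters.value_counts()
    return counts.index[(counts >= min_sets) & (counts <= max_sets)]


# ---------------------------------------------------------------------------
# Cascade orchestration
# ---------------------------------------------------------------------------


@dataclass
class CascadeResult:
    """Everything the filter cascade produces."""

    probe_sets: ProbeSetMatrix  # analysis-ready matrix (sets in kept clusters)
    clusters: pd.Index  # analysis gene list
    ledger: FilterLedger
    presence: pd.DataFrame  # probe-set level presence statistics
    passing_probes: pd.Index  # probes behind the final probe sets


def run_filter_cascade(
    corrected: IntensityMatrix,
    ann: ChipAnnotation,
    model: BackgroundModel,
    design: GroupDesign,
    gc_mask: pd.Series,
    presence_alpha: float = 0.001,
    presence_require: str = "any",
    pvar_mode: str = "literal",
    invariance_q: float = 0.10,
    invariance_reference: str = "median",
    min_sets: int = 4,
    max_sets: int = 200,
    min_probes: int = 3,
) -> CascadeResult:
    """Run the full five-step cascade and assemble the ledger."""
    ledger = FilterLedger()

    def cluster_count(set_ids: pd.Index) -> int:
        return len(filter_clusters(set_ids, ann, min_sets, max_sets))

    ledger.append(0, "Total on Chip", ann.n_probes, ann.n_probe_sets, ann.n_clusters)

    core_sets = filter_core(ann)
    core_probes = ann.probes.index[ann.probes["probe_set_id"].isin(set(core_sets))]
    ledger.append(1, "Core Probe Sets", len(core_probes), len(core_sets), cluster_count(core_sets))

    mask = gc_mask & ann.probes["probe_set_id"].isin(set(core_sets))
    ps = summarize_probe_sets(corrected, ann, mask, min_probes=min_probes)
    ledger.append(
        2,
        "Pass Filter 1 and Probes with GC Counts in Range",
        int(ps.meta["n_probes"].sum()),
        len(ps.probe_set_ids),
        None,
    )

    presence = probe_set_presence(ps, model, design, alpha=presence_alpha, pvar_mode=pvar_mode)
    expressed_sets = filter_expressed(presence, list(design.groups), require=presence_require)
    ps_expr = ps.restrict(expressed_sets)
    ledger.append(
        3,
        "Pass Filters 1 and 2 and Probe Sets Expressed Above the Background",
        int(ps_expr.meta["n_probes"].sum()),
        len(ps_expr.probe_set_ids),
        None,
    )

    # step 4 is a named no-op so ledgers align with the chip-level report
    ledger.append(
        4,
        "No AbsoluteScore Filter Used",
        int(ps_expr.meta["n_probes"].sum()),
        len(ps_expr.probe_set_ids),
        None,
    )

    kept = filter_invariant(
        ps_expr, n_arrays=len(ps_expr.array_ids), q=invariance_q,
        reference=invariance_reference,
    )
    ps_kept = ps_expr.restrict(kept)
    clusters = filter_clusters(ps_kept.probe_set_ids, ann, min_sets, max_sets)
    ledger.append(
        5,
        "Pass Filters 1-4 and the Invariance (Chi-Square) Filter",
        int(ps_kept.meta["n_probes"].sum()),
        len(ps_kept.probe_set_ids),
        len(clusters),
    )
    ledger.validate_monotone()

    final_sets = ps_kept.meta.index[ps_kept.clusters().isin(set(clusters))]
    final = ps_kept.restrict(final_sets)
    log.info(
        "filter cascade: %d probe sets in %d transcript clusters enter the analysis",
        len(final.probe_set_ids), len(clusters),
    )
    return CascadeResult(final, clusters, ledger, presence, final.probes.index)
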