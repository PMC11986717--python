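"""Per-gene mixed-model nested ANOVA, FDR control and reporting statistics.

The model for one transcript cluster is

    y_gae = mu + group_g + array_a(g) + exon_e + (group x exon)_ge + eps

with arrays (hybridizations) a random factor nested in treatment group and
group/exon fixed.  Because the filter cascade removes probe sets for all
arrays at once, every cluster is balanced (each array scores each passing
probe set exactly once) and the expected-mean-squares F tests are exact:

    F_group       = MS_group / MS_array(group)
    F_exon        = MS_exon / MS_residual
    F_interaction = MS_(group x exon) / MS_residual

A significant interaction is the operational signature of alternative
splicing; a significant group effect is differential gene expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chip_model import GroupDesign
from .errors import InputError, NumericalError
from .summarize_filter import ProbeSetMatrix

log = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    """F statistics, degrees of freedom and p-values for one cluster."""

    cluster_id: str
    n_groups: int
    n_arrays: int
    n_exons: int
    f_group: float
    p_group: float
    df_group: tuple[int, int]
    f_exon: float
    p_exon: float
    df_exon: tuple[int, int]
    f_interaction: float
    p_interaction: float
    df_interaction: tuple[int, int]
    flags: tuple[str, ...] = ()


def fit_nested_anova(
    scores: pd.DataFrame, design: GroupDesign, cluster_id: str = ""
) -> AnovaResult:
    """Fit the nested mixed model on one cluster's probe-set x array scores.

    ``scores`` must contain every design array as a column (balance within
    the cluster); >= 2 groups, >= 2 arrays per group and >= 2 probe sets
    (exons) are required.  Unequal group sizes are supported; exons are
    crossed with every array so the sums of squares stay orthogonal.
    """
    groups = list(design.groups)
    if len(groups) < 2:
        raise InputError("nested ANOVA needs >= 2 groups")
    arrays_by_group = {g: design.arrays_in(g) for g in groups}
    for g, arrs in arrays_by_group.items():
        if len(arrs) < 2:
            raise InputError(f"group {g!r} has < 2 arrays")
        missing = [a for a in arrs if a not in scores.columns]
        if missing:
            raise InputError(f"cluster {cluster_id!r} unbalanced: missing arrays {missing}")
    E = len(scores)
    if E < 2:
        raise InputError(f"cluster {cluster_id!r} has < 2 probe sets")

    blocks = [scores[arrays_by_group[g]].to_numpy(dtype=float) for g in groups]  # (E, n_g)
    n_g = np.array([b.shape[1] for b in blocks])
    N_a = int(n_g.sum())
    Y = np.concatenate(blocks, axis=1)  # (E, N_a)

    grand = Y.mean()
    exon_means = Y.mean(axis=1)  # over all arrays
    group_means = np.array([b.mean() for b in blocks])
    array_means = Y.mean(axis=0)  # per array, over exons

    ss_group = E * float(np.sum(n_g * (group_means - grand) ** 2))
    ss_exon = N_a * float(np.sum((exon_means - grand) ** 2))
    ss_array = 0.0
    ss_int = 0.0
    for g, b in enumerate(blocks):
        ss_array += E * float(np.sum((b.mean(axis=0) - group_means[g]) ** 2))
        cell = b.mean(axis=1)  # group x exon cell means
        dev = cell - group_means[g] - exon_means + grand
        ss_int += n_g[g] * float(np.sum(dev**2))
    ss_tot = float(np.sum((Y - grand) ** 2))
    ss_resid = ss_tot - ss_group - ss_array - ss_exon - ss_int

    df_group = len(groups) - 1
    df_array = int(np.sum(n_g - 1))
    df_exon = E - 1
    df_int = df_group * df_exon
    df_resid = df_array * df_exon

    # absolute tolerance below which a sum of squares is numerically zero
    tol = Y.size * (np.abs(Y).max() + 1.0) ** 2 * 1e-26
    flags: list[str] = []

    def f_test(ss_num, df_num, ss_den, df_den, label):
        if df_den <= 0:
            flags.append(f"{label}:zero_denominator_df")
            return np.nan, np.nan
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den
        if ss_num <= tol:
            return 0.0, 1.0
        if ms_den <= tol:
            flags.append(f"{label}:zero_denominator_ms")
            return np.inf, 0.0
        f = ms_num / ms_den
        return f, float(stats.f.sf(f, df_num, df_den))

    f_g, p_g = f_test(ss_group, df_group, ss_array, df_array, "group")
    f_e, p_e = f_test(ss_exon, df_exon, max(ss_resid, 0.0), df_resid, "exon")
    f_i, p_i = f_test(ss_int, df_int, max(ss_resid, 0.0), df_resid, "interaction")

    return AnovaResult(
        cluster_id=cluster_id,
        n_groups=len(groups),
        n_arrays=N_a,
        n_exons=E,
        f_group=f_g, p_group=p_g, df_group=(df_group, df_array),
        f_exon=f_e, p_exon=p_e, df_exon=(df_exon, df_resid),
        f_interaction=f_i, p_interaction=p_i, df_interaction=(df_int, df_resid),
        flags=tuple(flags),
    )


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_i = min_{j >= rank(i)} p_(j) * N / j, capped at 1; the
    adjustment preserves the ordering of the raw p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise InputError("NaN p-value passed to bh_fdr")
    if (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def splicing_fp_filter(
    as_calls, gene_presence: pd.DataFrame, min_groups: int = 2
) -> tuple[list[str], dict[str, str]]:
    """Drop splicing calls for genes near background in all but one group.

    When a gene is expressed above background in fewer than ``min_groups``
    groups, an apparent exon-group interaction can be a dynamic-range
    artifact ("non-parallel" dampening), so the call is excluded and flagged
    ``near_background``.
    """
    expressed_groups = (
        gene_presence[gene_presence["expressed"]]
        .groupby("transcript_cluster_id")["group"]
        .nunique()
    )
    kept, flags = [], {}
    for gene in as_calls:
        if int(expressed_groups.get(gene, 0)) >= min_groups:
            kept.append(gene)
        else:
            flags[gene] = "near_background"
    return kept, flags


@dataclass
class DifferentialResult:
    """Gene-level DE/AS analysis output."""

    table: pd.DataFrame  # per-cluster F/p/adjusted-p columns
    de_genes: list[str]
    as_genes: list[str]
    both: list[str]
    as_flags: dict[str, str] = field(default_factory=dict)


def run_differential_analysis(
    ps: ProbeSetMatrix,
    design: GroupDesign,
    alpha: float = 0.01,
    gene_presence: pd.DataFrame | None = None,
    fp_min_groups: int = 2,
) -> DifferentialResult:
    """Fit the nested ANOVA per cluster, BH-adjust, and call DE / AS genes.

    DE genes have adjusted group p < alpha; AS genes have adjusted
    interaction p < alpha and survive the near-background splicing filter
    when gene-level presence calls are supplied.
    """
    results = []
    for cluster, sets in ps.clusters().groupby(ps.clusters()):
        ids = sets.index
        if len(ids) < 2:
            continue
        results.append(fit_nested_anova(ps.scores.loc[ids], design, cluster_id=str(cluster)))
    if not results:
        raise InputError("no cluster with >= 2 probe sets to test")

    table = pd.DataFrame(
        {
            "transcript_cluster_id": [r.cluster_id for r in results],
            "n_exons": [r.n_exons for r in results],
            "f_group": [r.f_group for r in results],
            "p_group": [r.p_group for r in results],
            "f_exon": [r.f_exon for r in results],
            "p_exon": [r.p_exon for r in results],
            "f_interaction": [r.f_interaction for r in results],
            "p_interaction": [r.p_interaction for r in results],
        }
    )
    table["p_group_adj"] = bh_fdr(table["p_group"].to_numpy())
    table["p_interaction_adj"] = bh_fdr(table["p_interaction"].to_numpy())

    de = list(table.loc[table["p_group_adj"] < alpha, "transcript_cluster_id"])
    as_raw = list(table.loc[table["p_interaction_adj"] < alpha, "transcript_cluster_id"])
    if gene_presence is not None:
        as_genes, flags = splicing_fp_filter(as_raw, gene_presence, min_groups=fp_min_groups)
    else:
        as_genes, flags = as_raw, {}
    both = sorted(set(de) & set(as_genes))
    log.info(
        "differential analysis: %d clusters tested, %d DE, %d AS, %d both (alpha=%g)",
        len(table), len(de), len(as_genes), len(both), alpha,
    )
    return DifferentialResult(table, de, as_genes, both, flags)


def fold_change_and_ttest(
    ps: ProbeSetMatrix,
    design: GroupDesign,
    offset: float = 0.1,
    base: float = 2.0,
    floor: float = 1e-9,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene fold change on the normalized untransformed scale + t-test.

    The gene's per-array score is the mean of its probe-set scores
    (log scale), back-transformed as base**score - offset and guarded at a
    small positive floor.  The fold change r = mean(other)/mean(reference)
    is reported with the signed convention (+r if r >= 1 else -1/r); the
    p-value is a classical two-sided pooled-variance Student t-test between
    the two groups' per-array gene values.
    """
    groups = list(design.groups)
    if len(groups) != 2:
        raise InputError("fold_change_and_ttest expects exactly 2 groups")
    if reference is None:
        reference = groups[0]
    if reference not in groups:
        raise InputError(f"reference group {reference!r} not in design")
    other = [g for g in groups if g != reference][0]

    gene_log = ps.scores.groupby(ps.clusters()).mean()
    raw = np.power(base, gene_log) - offset
    flagged = (raw.to_numpy() <= floor).any(axis=1)
    raw = raw.clip(lower=floor)

    ref_arrays = [a for a in design.arrays_in(reference) if a in raw.columns]
    oth_arrays = [a for a in design.arrays_in(other) if a in raw.columns]
    m_ref = raw[ref_arrays].mean(axis=1)
    m_oth = raw[oth_arrays].mean(axis=1)
    ratio = m_oth / m_ref
    signed = np.where(ratio >= 1, ratio, -1.0 / ratio)

    t_res = stats.ttest_ind(
        raw[oth_arrays], raw[ref_arrays], axis=1, equal_var=True
    )
    t_stat = np.asarray(t_res.statistic, dtype=float)
    p_val = np.asarray(t_res.pvalue, dtype=float)
    # zero-variance, equal-mean genes: t = 0/0; define t = 0, p = 1
    degenerate = ~np.isfinite(t_stat)
    equal = np.isclose(m_oth.to_numpy(), m_ref.to_numpy())
    t_stat[degenerate & equal] = 0.0
    p_val[degenerate & equal] = 1.0
    t_stat[degenerate & ~equal] = np.inf
    p_val[degenerate & ~equal] = 0.0

    return pd.DataFrame(
        {
            "transcript_cluster_id": raw.index,
            "fold_change": signed,
            "ratio": ratio.to_numpy(),
            "t": t_stat,
            "p_value": p_val,
            "floored": flagged,
        }
    ).reset_index(drop=True)
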