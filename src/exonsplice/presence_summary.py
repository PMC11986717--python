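"""Gene-level expressed-above-background calls and co-expression accounting.

A transcript cluster is called expressed in a group when the standardized
sum of its background-corrected probe scores over the group's arrays exceeds
the upper-tail normal threshold (default p < 0.01).  The co-expression
summary reports per-group totals, pairwise shared counts and per-group
exclusive counts with the inclusion-exclusion identity holding exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .chip_model import ChipAnnotation, GroupDesign, IntensityMatrix, Stage
from .errors import InputError, NumericalError
from .preprocess import BackgroundModel

log = logging.getLogger(__name__)


def gene_presence(
    m: IntensityMatrix,
    model: BackgroundModel,
    ann: ChipAnnotation,
    design: GroupDesign,
    alpha: float = 0.01,
    probes: pd.Index | None = None,
    clusters: pd.Index | None = None,
    mode: str = "standardized",
) -> pd.DataFrame:
    """Per (transcript cluster, group) presence call.

    N0 sums the corrected probe scores of the gene's passing probes over the
    group's arrays.  In the default ``standardized`` mode the sum is divided
    by sqrt(K * Var) (K = number of summed values, Var = average background
    variance) so N0 is standard normal under the null; ``literal`` divides by
    Var alone.  Genes with no passing probes are reported absent with an
    ``undefined`` flag.
    """
    if m.stage is not Stage.BACKGROUND_CORRECTED:
        raise InputError(
            f"gene_presence expects background_corrected stage, got {m.stage.value}"
        )
    if mode not in ("standardized", "literal"):
        raise InputError(f"unknown N0 mode {mode!r}")
    if model.var_avg <= 0:
        raise NumericalError("average background variance is zero; N0 undefined")

    table = ann.probe_table()
    if probes is not None:
        table = table.loc[table.index.intersection(probes)]
    table = table.loc[table.index.intersection(m.probe_ids)]
    if clusters is None:
        clusters = pd.Index(table["transcript_cluster_id"].unique())

    sub = m.values.loc[table.index]
    by_cluster = sub.groupby(table["transcript_cluster_id"]).agg(["sum", "count"])
    # per-cluster, per-array sums and probe counts
    sums = by_cluster.xs("sum", axis=1, level=1)
    n_probes = sub.groupby(table["transcript_cluster_id"]).size()

    rows = []
    for group in design.groups:
        arrays = [a for a in design.arrays_in(group) if a in m.array_ids]
        gsize = len(arrays)
        for cl in clusters:
            if cl in sums.index:
                s = float(sums.loc[cl, arrays].sum())
                k = int(n_probes.loc[cl]) * gsize
            else:
                s, k = 0.0, 0
            if k == 0:
                rows.append((cl, group, 0, np.nan, np.nan, False, True))
                continue
            if mode == "standardized":
                n0 = s / np.sqrt(k * model.var_avg)
            else:
                n0 = s / model.var_avg
            p = float(stats.norm.sf(n0))
            rows.append((cl, group, k, n0, p, p < alpha, False))
    return pd.DataFrame(
        rows,
        columns=["transcript_cluster_id", "group", "k", "n0", "p_value", "expressed", "undefined"],
    )


def expressed_percentage(expressed_count: int, tested_count: int) -> float:
    """100 * expressed/tested, rounded half-up to one decimal place."""
    if tested_count <= 0:
        raise InputError("tested_count must be positive")
    if expressed_count < 0 or expressed_count > tested_count:
        raise InputError("expressed_count must be in [0, tested_count]")
    pct = Decimal(100) * Decimal(expressed_count) / Decimal(tested_count)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CoexpressionTable:
    """Totals, pairwise shared counts and exclusives of gene presence calls."""

    groups: tuple[str, ...]
    tested: int
    totals: dict[str, int]
    percentages: dict[str, float]
    shared: dict[tuple[str, str], int]
    exclusives: dict[str, int]

    def __post_init__(self) -> None:
        for g in self.groups:
            if self.totals[g] < 0 or self.exclusives[g] < 0:
                raise NumericalError("negative presence count")
        if len(self.groups) == 2:
            g1, g2 = self.groups
            s = self.shared[(g1, g2)]
            if self.exclusives[g1] != self.totals[g1] - s or (
                self.exclusives[g2] != self.totals[g2] - s
            ):
                raise NumericalError("exclusivity identity violated")

    def render(self) -> str:
        """Results-style report: totals, pairwise matrix, exclusivity rows."""
        lines = ["Group\tExpressed\t% of genes tested"]
        for g in self.groups:
            lines.append(f"{g}\t{self.totals[g]:,}\t{self.percentages[g]}%")
        lines.append("")
        header = "\t" + "\t".join(self.groups)
        lines.append(header)
        for i, g1 in enumerate(self.groups):
            cells = []
            for j, g2 in enumerate(self.groups):
                if j < i:
                    cells.append("-")
                elif i == j:
                    cells.append(f"{self.totals[g1]:,} ({self.exclusives[g1]:,})")
                else:
                    key = (g1, g2) if (g1, g2) in self.shared else (g2, g1)
                    cells.append(f"{self.shared[key]:,}")
            lines.append(g1 + "\t" + "\t".join(cells))
        lines.append("")
        for (g1, g2), s in self.shared.items():
            lines.append(f"{g1} vs. {g2}\t{s:,}")
        for g in self.groups:
            lines.append(f"{g}\t{self.exclusives[g]:,}")
        return "\n".join(lines) + "\n"


def coexpression_summary(presence: pd.DataFrame, design: GroupDesign) -> CoexpressionTable:
    """Build the co-expression table from gene-level presence calls."""
    groups = tuple(design.groups)
    if len(groups) < 2:
        raise InputError("co-expression needs >= 2 groups")
    wide = presence.pivot_table(
        index="transcript_cluster_id", columns="group", values="expressed", aggfunc="first"
    ).fillna(False).astype(bool)
    for g in groups:
        if g not in wide.columns:
            wide[g] = False
    tested = len(wide)
    totals = {g: int(wide[g].sum()) for g in groups}
    percentages = {g: expressed_percentage(totals[g], tested) for g in groups}
    shared = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            shared[(g1, g2)] = int((wide[g1] & wide[g2]).sum())
    exclusives = {}
    for g in groups:
        others = [h for h in groups if h != g]
        exclusives[g] = int((wide[g] & ~wide[others].any(axis=1)).sum())
    return CoexpressionTable(groups, tested, totals, percentages, shared, exclusives)
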