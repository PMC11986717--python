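"""Array-level normalization and probe-level transforms.

Order of operations in the pipeline: complete quantile normalization of the
raw intensities, exclusion of probes with extreme GC counts (default keep
6..17), log transform (log2 of value + 0.1 by default), fitting of the
GC-binned background model on the antigenomic probes, and subtraction of the
GC-matched background median from every annotated probe score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip_model import (
    BackgroundProbeTable,
    ChipAnnotation,
    GroupDesign,
    IntensityMatrix,
    Stage,
)
from .errors import InputError, NumericalError

log = logging.getLogger(__name__)


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Complete quantile normalization.

    Every array's value at rank r is replaced by the across-array mean of the
    r-th order statistics, so all arrays end up with an identical value
    multiset.  Ties within an array receive the mean of the reference values
    over their tied rank span, which makes the map deterministic and
    order-independent; the transform is idempotent.
    """
    if m.stage is not Stage.RAW:
        raise InputError(f"quantile_normalize expects raw stage, got {m.stage.value}")
    X = m.values.to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        warnings.warn("single array: quantile normalization is the identity", stacklevel=2)
        return m.advanced(m.values.astype(float).copy(), Stage.NORMALIZED)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average the reference values across tied rank spans
        tied = pd.Series(assigned).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.advanced(values, Stage.NORMALIZED)


def filter_probes_by_gc(
    ann: ChipAnnotation, gc_min: int = 6, gc_max: int = 17
) -> pd.Series:
    """Boolean mask over annotated probes keeping gc_min <= gc_count <= gc_max."""
    gc = ann.probes["gc_count"]
    return (gc >= gc_min) & (gc <= gc_max)


def log_transform(
    m: IntensityMatrix, offset: float = 0.1, base: float = 2.0
) -> IntensityMatrix:
    """value -> log_base(value + offset); requires value + offset > 0 everywhere."""
    if m.stage is not Stage.NORMALIZED:
        raise InputError(f"log_transform expects normalized stage, got {m.stage.value}")
    shifted = m.values.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        r, c = np.argwhere(shifted <= 0)[0]
        raise NumericalError(
            f"value + offset <= 0 at probe {m.probe_ids[r]!r}, array {m.array_ids[c]!r}"
        )
    values = pd.DataFrame(
        np.log(shifted) / np.log(base), index=m.values.index, columns=m.values.columns
    )
    return m.advanced(values, Stage.TRANSFORMED)


@dataclass
class BackgroundModel:
    """GC-binned summary of the antigenomic (background) probe scores.

    Fitted on transformed-stage values, pooled across all arrays:

    * ``bins``: per GC bin — median (the "GC Background" subtracted from every
      annotated probe), mean, variance (ddof=1) and count.
    * ``var_avg``: average of the per-bin variances; the ``Var`` term of the
      gene-level presence statistic.
    * ``total_var``: variance of all background values after removing their
      bin median, i.e. the total background variance on the corrected scale;
      feeds the probe-set presence ``Pvar`` term.
    * ``group_bin_means``: per (group, GC bin) mean, retained for per-group
      presence diagnostics.
    """

    bins: pd.DataFrame
    var_avg: float
    total_var: float
    group_bin_means: pd.DataFrame

    def require_bins(self, gcs) -> None:
        missing = sorted(set(np.asarray(gcs, dtype=int)) - set(self.bins.index))
        if missing:
            raise InputError(f"GC bin(s) missing from background model: {missing}")

    def median_for(self, gcs) -> np.ndarray:
        self.require_bins(gcs)
        return self.bins["median"].loc[np.asarray(gcs, dtype=int)].to_numpy()

    def corrected_mean_for(self, gcs) -> np.ndarray:
        """Per-GC mean of background values on the background-corrected scale."""
        self.require_bins(gcs)
        b = self.bins.loc[np.asarray(gcs, dtype=int)]
        return (b["mean"] - b["median"]).to_numpy()


def fit_background_model(
    m: IntensityMatrix, bg: BackgroundProbeTable, design: GroupDesign
) -> BackgroundModel:
    """Fit per-GC-bin medians/means/variances of background probes.

    Values are pooled across all arrays within each bin; per-group bin means
    are retained as well.  Degenerate single-value bins get variance 0 with a
    warning.
    """
    if m.stage is not Stage.TRANSFORMED:
        raise InputError(f"fit_background_model expects transformed stage, got {m.stage.value}")
    missing = bg.probe_ids.difference(m.probe_ids)
    if len(missing):
        raise InputError(
            f"{len(missing)} background probe(s) absent from matrix, e.g. {missing[0]}"
        )
    sub = m.values.loc[bg.probe_ids]
    gc = bg.probes["gc_count"]
    long = sub.stack().rename("value").reset_index()
    long.columns = ["probe_id", "array_id", "value"]
    long["gc"] = long["probe_id"].map(gc)

    grouped = long.groupby("gc")["value"]
    bins = pd.DataFrame(
        {
            "median": grouped.median(),
            "mean": grouped.mean(),
            "var": grouped.var(ddof=1),
            "n": grouped.size(),
        }
    )
    single = bins["n"] == 1
    if single.any():
        warnings.warn(
            f"background GC bin(s) {list(bins.index[single])} hold a single value; "
            "variance set to 0",
            stacklevel=2,
        )
        bins.loc[single, "var"] = 0.0
    if (bins["var"] < 0).any():  # pragma: no cover - numerically impossible
        raise NumericalError("negative background variance")

    centred = long["value"] - long["gc"].map(bins["median"])
    total_var = float(centred.var(ddof=1))
    var_avg = float(bins["var"].mean())

    long["group"] = long["array_id"].map(design.assignments)
    gbm = long.dropna(subset=["group"]).groupby(["group", "gc"])["value"].mean()
    log.info(
        "background model: %d GC bins, Var=%.4g, total corrected variance=%.4g",
        len(bins), var_avg, total_var,
    )
    return BackgroundModel(bins, var_avg, total_var, gbm.to_frame("mean"))


def subtract_gc_background(
    m: IntensityMatrix, model: BackgroundModel, ann: ChipAnnotation
) -> IntensityMatrix:
    """Subtract each probe's GC-bin background median from its score.

    Only annotated probes are carried forward (background probes have served
    their purpose once the model is fitted).  Negative corrected scores are
    permitted.
    """
    if m.stage is not Stage.TRANSFORMED:
        raise InputError(f"subtract_gc_background expects transformed stage, got {m.stage.value}")
    keep = ann.probes.index.intersection(m.probe_ids)
    sub = m.values.loc[keep]
    gcs = ann.probes.loc[keep, "gc_count"]
    medians = model.median_for(gcs)
    values = sub.sub(pd.Series(medians, index=keep), axis=0)
    return m.advanced(values, Stage.BACKGROUND_CORRECTED)
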