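"""Domain types and TSV readers/writers for the exon-array chip model.

The chip is purely hierarchical: probes belong to exactly one probe set,
probe sets to exactly one transcript cluster ("gene").  There are no genomic
coordinates anywhere in the pipeline; all identifiers are opaque strings.

All on-disk formats are UTF-8, tab-separated, Unix newlines; lines starting
with ``#`` are comments.  The five input tables are:

* intensity matrix   ``probe_id<TAB>arr1<TAB>arr2...`` (numeric cells)
* chip annotation    ``probe_id  gc_count  probe_set_id  transcript_cluster_id  annotation_level``
* background probes  ``probe_id  gc_count``
* sample sheet       ``array_id  group``
* gene-set catalog   ``class  term_id  term_name  comma_separated_members``
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)


class Stage(str, Enum):
    """Processing stage of an intensity matrix; transitions only move forward."""

    RAW = "raw"
    NORMALIZED = "normalized"
    TRANSFORMED = "transformed"
    BACKGROUND_CORRECTED = "background_corrected"


_STAGE_ORDER = [Stage.RAW, Stage.NORMALIZED, Stage.TRANSFORMED, Stage.BACKGROUND_CORRECTED]

ANNOTATION_LEVELS = ("Core", "Extended", "Complete")
# Vendor files spell the reliability level inconsistently; "full" is the
# historical alias of the all-inclusive level.
_LEVEL_ALIASES = {
    "core": "Core",
    "extended": "Extended",
    "complete": "Complete",
    "full": "Complete",
}

GENE_SET_CLASSES = ("GOMolFn", "GOProcess", "GOCellLoc", "Pathway")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class IntensityMatrix:
    """Probe x array matrix of fluorescence intensities (or transformed scores).

    ``values`` is a DataFrame indexed by probe id with array-id columns.
    ``stage`` records where in the pipeline the values sit; raw intensities
    must be non-negative, every stage must be finite, and missing values are
    not supported.
    """

    values: pd.DataFrame
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise InputError(f"duplicate probe id {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise InputError(f"duplicate array id {dup}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise InputError(
                f"non-finite value at probe {idx[bad[0]]!r}, array {cols[bad[1]]!r}"
            )
        if self.stage is Stage.RAW and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise InputError(
                f"negative raw intensity at probe {idx[bad[0]]!r}, array {cols[bad[1]]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def array_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def advanced(self, values: pd.DataFrame, stage: Stage) -> "IntensityMatrix":
        """Return a new matrix at ``stage``, enforcing forward-only transitions."""
        stage = Stage(stage)
        if _STAGE_ORDER.index(stage) != _STAGE_ORDER.index(self.stage) + 1:
            raise InputError(
                f"illegal stage transition {self.stage.value} -> {stage.value}"
            )
        return IntensityMatrix(values, stage)


@dataclass
class ChipAnnotation:
    """Probe -> probe set -> transcript cluster hierarchy with GC counts.

    ``probes``: DataFrame indexed by probe_id with columns ``gc_count``
    (int >= 0) and ``probe_set_id``.  ``probe_sets``: DataFrame indexed by
    probe_set_id with columns ``transcript_cluster_id`` and
    ``annotation_level`` (one of Core/Extended/Complete).
    """

    probes: pd.DataFrame
    probe_sets: pd.DataFrame
    max_probe_length: int = 25

    def __post_init__(self) -> None:
        if self.probes.index.has_duplicates:
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise InputError(f"probe {dup} mapped to more than one probe set")
        if self.probe_sets.index.has_duplicates:
            dup = self.probe_sets.index[self.probe_sets.index.duplicated()][0]
            raise InputError(f"probe set {dup} defined more than once")
        gc = self.probes["gc_count"]
        if (gc < 0).any() or (gc > self.max_probe_length).any():
            raise InputError(
                f"gc_count outside [0, {self.max_probe_length}] for some probes"
            )
        unknown = set(self.probe_sets["annotation_level"]) - set(ANNOTATION_LEVELS)
        if unknown:
            raise InputError(f"unknown annotation level(s): {sorted(unknown)}")
        missing = set(self.probes["probe_set_id"]) - set(self.probe_sets.index)
        if missing:
            raise InputError(
                f"{len(missing)} probe(s) reference undefined probe sets, e.g. "
                f"{sorted(missing)[:3]}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_probe_sets(self) -> int:
        return len(self.probe_sets)

    @property
    def n_clusters(self) -> int:
        return self.probe_sets["transcript_cluster_id"].nunique()

    def cluster_of(self) -> pd.Series:
        """probe_set_id -> transcript_cluster_id."""
        return self.probe_sets["transcript_cluster_id"]

    def probe_table(self) -> pd.DataFrame:
        """Flat probe table with probe_set_id, gc_count and transcript_cluster_id."""
        t = self.probes.copy()
        t["transcript_cluster_id"] = t["probe_set_id"].map(
            self.probe_sets["transcript_cluster_id"]
        )
        return t


@dataclass
class BackgroundProbeTable:
    """Antigenomic (background) probes keyed by probe id, with GC counts."""

    probes: pd.DataFrame  # index probe_id, column gc_count

    def __post_init__(self) -> None:
        if self.probes.index.has_duplicates:
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise InputError(f"duplicate background probe id {dup}")
        if (self.probes["gc_count"] < 0).any():
            raise InputError("negative gc_count in background table")

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    def gc_bins(self) -> pd.Index:
        return pd.Index(sorted(self.probes["gc_count"].unique()))

    def check_disjoint(self, ann: ChipAnnotation) -> None:
        overlap = self.probes.index.intersection(ann.probes.index)
        if len(overlap):
            raise InputError(
                f"background probes overlap annotated probes, e.g. {overlap[0]}"
            )


@dataclass
class GroupDesign:
    """array_id -> treatment group assignment with a stable group order."""

    assignments: pd.Series  # index array_id, values group label
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.assignments.index.has_duplicates:
            dup = self.assignments.index[self.assignments.index.duplicated()][0]
            raise InputError(f"array {dup} assigned to more than one group")
        if not self.groups:
            seen: list[str] = []
            for g in self.assignments:
                if g not in seen:
                    seen.append(g)
            self.groups = tuple(seen)
        for g, n in self.group_sizes.items():
            if n < 2:
                warnings.warn(
                    f"group {g!r} has a single array; presence statistics are degenerate",
                    stacklevel=2,
                )

    @property
    def array_ids(self) -> pd.Index:
        return self.assignments.index

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.assignments.value_counts()
        return {g: int(counts.get(g, 0)) for g in self.groups}

    def arrays_in(self, group: str) -> list[str]:
        return list(self.assignments.index[self.assignments == group])

    def validate_against(self, m: IntensityMatrix) -> None:
        missing = self.array_ids.difference(m.array_ids)
        if len(missing):
            raise InputError(
                f"array(s) in sample sheet absent from intensity matrix: {list(missing)}"
            )


@dataclass
class GeneSetCatalog:
    """Flat gene-set catalog: class / term -> member transcript clusters."""

    terms: pd.DataFrame  # columns: class, term_id, term_name, members (frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.terms["class"]) - set(GENE_SET_CLASSES)
        if unknown:
            raise InputError(f"unknown gene-set class(es): {sorted(unknown)}")
        dup = self.terms.duplicated(subset=["class", "term_id"])
        if dup.any():
            row = self.terms[dup].iloc[0]
            raise InputError(
                f"term {row['term_id']} duplicated within class {row['class']}"
            )

    def __len__(self) -> int:
        return len(self.terms)

    def intersect(self, tested: set[str]) -> "GeneSetCatalog":
        """Restrict every term's members to the tested-gene universe."""
        t = self.terms.copy()
        t["members"] = t["members"].map(lambda s: frozenset(s) & set(tested))
        return GeneSetCatalog(t)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, expected_cols: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, header=0, skip_blank_lines=True
        )
    except pd.errors.ParserError as exc:  # ragged rows etc., message names the line
        raise InputError(f"{path}: parse error: {exc}") from exc
    if expected_cols is not None:
        missing = [c for c in expected_cols if c not in df.columns]
        if missing:
            raise InputError(f"{path}: missing column(s) {missing}")
    return df


def read_intensity_matrix(path: str | Path, stage: Stage | None = None) -> IntensityMatrix:
    """Read a probe x array intensity TSV.

    The first column holds probe ids, the header row array ids.  A
    ``# stage: <name>`` comment, if present, sets the matrix stage; otherwise
    the matrix is taken as raw.
    """
    path = Path(path)
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: intensity matrix needs a probe column and >=1 array")
    probe_col = df.columns[0]
    probes = df[probe_col]
    if probes.duplicated().any():
        raise InputError(f"duplicate probe id {probes[probes.duplicated()].iloc[0]}")
    values = df.drop(columns=[probe_col])
    missing = values.isna()
    if missing.any().any():
        r, c = np.argwhere(missing.to_numpy())[0]
        raise InputError(
            f"{path}: missing value at probe {probes.iloc[r]!r}, "
            f"array {values.columns[c]!r} (data row {r + 1})"
        )
    cols = {}
    for c, name in enumerate(values.columns):
        raw = values[name].to_numpy()
        try:
            # numpy's parser is correctly rounded, so write/read round-trips
            cols[name] = raw.astype(np.float64)
        except ValueError:
            for r, cell in enumerate(raw):
                try:
                    float(cell)
                except ValueError:
                    raise InputError(
                        f"{path}: non-numeric cell {cell!r} at probe "
                        f"{probes.iloc[r]!r}, array {name!r} (data row {r + 1})"
                    ) from None
            raise
    numeric = pd.DataFrame(cols, index=pd.Index(probes, name="probe_id"))
    if stage is None:
        stage = _sniff_stage(path)
    return IntensityMatrix(numeric, stage)


def _sniff_stage(path: Path) -> Stage:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# stage:"):
                return Stage(line.split(":", 1)[1].strip())
    return Stage.RAW


def read_annotation(path: str | Path, max_probe_length: int = 25) -> ChipAnnotation:
    """Read the chip annotation TSV and build the probe/probe-set hierarchy."""
    cols = ["probe_id", "gc_count", "probe_set_id", "transcript_cluster_id", "annotation_level"]
    df = _read_tsv(path, cols)
    df = df.drop_duplicates()
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise InputError(f"probe {dup} mapped to more than one probe set")
    level = df["annotation_level"].str.lower().map(_LEVEL_ALIASES)
    if level.isna().any():
        bad = df["annotation_level"][level.isna()].iloc[0]
        raise InputError(f"unknown annotation level token {bad!r}")
    df = df.assign(annotation_level=level, gc_count=pd.to_numeric(df["gc_count"]).astype(int))

    sets = df[["probe_set_id", "transcript_cluster_id", "annotation_level"]].drop_duplicates()
    if sets["probe_set_id"].duplicated().any():
        dup = sets["probe_set_id"][sets["probe_set_id"].duplicated()].iloc[0]
        raise InputError(f"probe set {dup} has conflicting cluster or annotation level")
    probes = df.set_index("probe_id")[["gc_count", "probe_set_id"]]
    probe_sets = sets.set_index("probe_set_id")
    ann = ChipAnnotation(probes, probe_sets, max_probe_length=max_probe_length)
    log.info(
        "annotation: %d probes, %d probe sets, %d transcript clusters",
        ann.n_probes, ann.n_probe_sets, ann.n_clusters,
    )
    return ann


def read_background(path: str | Path) -> BackgroundProbeTable:
    df = _read_tsv(path, ["probe_id", "gc_count"])
    df = df.assign(gc_count=pd.to_numeric(df["gc_count"]).astype(int))
    return BackgroundProbeTable(df.set_index("probe_id")[["gc_count"]])


def read_sample_sheet(path: str | Path) -> GroupDesign:
    df = _read_tsv(path, ["array_id", "group"])
    return GroupDesign(df.set_index("array_id")["group"])


def read_gene_sets(path: str | Path) -> GeneSetCatalog:
    df = _read_tsv(path, ["class", "term_id", "term_name", "members"])
    members = df["members"].fillna("").map(
        lambda s: frozenset(x for x in str(s).split(",") if x)
    )
    return GeneSetCatalog(df.assign(members=members))


# ---------------------------------------------------------------------------
# Writers (canonical forms; writing then reading round-trips byte-identically)
# ---------------------------------------------------------------------------


def write_intensity_matrix(m: IntensityMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# stage: {m.stage.value}\n")
        m.values.to_csv(fh, sep="\t", index_label="probe_id", lineterminator="\n")


def write_annotation(ann: ChipAnnotation, path: str | Path) -> None:
    t = ann.probe_table()
    t["annotation_level"] = t["probe_set_id"].map(ann.probe_sets["annotation_level"])
    out = t.reset_index()[
        ["probe_id", "gc_count", "probe_set_id", "transcript_cluster_id", "annotation_level"]
    ]
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_background(bg: BackgroundProbeTable, path: str | Path) -> None:
    bg.probes.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_sample_sheet(design: GroupDesign, path: str | Path) -> None:
    design.assignments.rename("group").to_csv(
        path, sep="\t", index_label="array_id", lineterminator="\n"
    )


def write_gene_sets(catalog: GeneSetCatalog, path: str | Path) -> None:
    t = catalog.terms.copy()
    t["members"] = t["members"].map(lambda s: ",".join(sorted(s)))
    t[["class", "term_id", "term_name", "members"]].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
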