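"""Domain types and file I/O shared by every analysis stage.

The substrate of the pipeline is an :class:`ExpressionCohort` — a probes ×
samples matrix of already-normalized log2 intensities (e.g. RMA output from an
Affymetrix platform).  Values are assumed to be on the log2 scale throughout;
no transform is applied (``ASSUME_LOG2`` documents this contract).  Missing
entries are permitted and propagate as NaN; downstream correlations use
pairwise-complete observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSUME_LOG2 = True

GROUPS = ("tumor", "control")

_NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "None"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCohort:
    """Probes × samples log2 intensity matrix with ordered identifier registries.

    Parameters
    ----------
    probe_ids : list of str
        Row identifiers, unique, order preserved from the source file.
    sample_ids : list of str
        Column identifiers, unique.
    values : ndarray of shape (n_probes, n_samples)
        Log2-scale intensities; NaN marks a missing entry.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p).strip() for p in self.probe_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        present = self.values[~np.isnan(self.values)]
        if present.size and not np.isfinite(present).all():
            raise ValueError("expression matrix contains non-finite values (inf)")

    # -- accessors ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    @property
    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def probe_values(self, probe_id: str) -> np.ndarray:
        """Row vector of one probe across all samples."""
        try:
            return self.values[self.probe_index[probe_id]]
        except KeyError:
            raise KeyError(f"probe {probe_id!r} not in cohort") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionCohort":
        idx = self.sample_index
        cols = [idx[s] for s in sample_ids]
        return ExpressionCohort(list(self.probe_ids), list(sample_ids), self.values[:, cols])

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionCohort":
        idx = self.probe_index
        missing = [p for p in probe_ids if p not in idx]
        if missing:
            raise KeyError(f"probes not in cohort: {missing}")
        rows = [idx[p] for p in probe_ids]
        return ExpressionCohort(list(probe_ids), list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample clinical annotation.

    ``survival_months`` and ``event`` are present together or not at all:
    a follow-up time without an event indicator (1 = death/event, 0 =
    censored) is not interpretable.
    """

    sample_id: str
    group: str
    cohort_label: str | None = None
    stage: str | None = None
    survival_months: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        self.sample_id = str(self.sample_id).strip()
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if (self.survival_months is None) != (self.event is None):
            raise ValueError(
                f"sample {self.sample_id!r}: survival_months and event must be "
                "present together"
            )
        if self.survival_months is not None:
            if self.survival_months < 0:
                raise ValueError(f"sample {self.sample_id!r}: negative survival time")
            if self.event not in (0, 1):
                raise ValueError(f"sample {self.sample_id!r}: event must be 0 or 1")


@dataclass
class ProbeAnnotation:
    """Mapping of one probe to its gene symbol, title, and category labels."""

    probe_id: str
    gene_symbol: str
    gene_title: str | None = None
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.probe_id = str(self.probe_id).strip()
        self.gene_symbol = str(self.gene_symbol).strip()
        self.categories = frozenset(str(c).strip() for c in self.categories if str(c).strip())


@dataclass
class CategoryUniverse:
    """Flat category → member sets over a declared platform background.

    ``level`` records whether members are probe ids or gene symbols;
    enrichment refuses to mix levels without an explicit bridge.
    """

    categories: dict[str, frozenset[str]]
    universe_size: int
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        self.categories = {k: frozenset(v) for k, v in self.categories.items()}
        for name, members in self.categories.items():
            if len(members) > self.universe_size:
                raise ValueError(
                    f"category {name!r} has {len(members)} members, exceeding "
                    f"universe_size={self.universe_size}"
                )

    def members(self, category: str) -> frozenset[str]:
        try:
            return self.categories[category]
        except KeyError:
            raise KeyError(f"unknown category {category!r}") from None


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionCohort:
    """Read a probes × samples expression table.

    The header row holds sample ids; the first column holds probe ids.  Empty
    cells and NA tokens become missing entries.  Duplicate identifiers and
    non-numeric cells are hard errors naming the offender.
    """
    sep = _sep(dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    # pandas renames duplicate header fields, so check the raw header first
    _check_unique([h.strip() for h in header[1:]], "sample id")
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str, keep_default_na=False)
    sample_ids = [str(c).strip() for c in df.columns]
    probe_ids = [str(p).strip() for p in df.index]
    _check_unique(sample_ids, "sample id")
    _check_unique(probe_ids, "probe id")
    values = np.full(df.shape, np.nan)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell in _NA_TOKENS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at probe {probe_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    return ExpressionCohort(probe_ids, sample_ids, values)


def write_expression_matrix(
    cohort: ExpressionCohort, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a cohort back to disk (floats at 6 significant digits, NaN as empty)."""
    cohort.to_frame().to_csv(
        path, sep=_sep(dialect), float_format="%.6g", na_rep="", lineterminator="\n"
    )


_SAMPLE_COLUMNS = {"sample_id", "group", "cohort_label", "stage", "survival_months", "event"}


def read_sample_table(
    path: str | Path, stage_order: Sequence[str] | None = None
) -> list[SampleMetadata]:
    """Read per-sample metadata from a TSV.

    Required columns: ``sample_id``, ``group``.  Optional: ``cohort_label``,
    ``stage``, ``survival_months``, ``event``.  Unknown columns are ignored
    with a warning.  A ``survival_months`` column without an ``event`` column
    (or vice versa) is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = set(df.columns)
    for required in ("sample_id", "group"):
        if required not in cols:
            raise ValueError(f"sample table missing required column {required!r}")
    unknown = cols - _SAMPLE_COLUMNS
    if unknown:
        logger.warning("sample table: ignoring unknown columns %s", sorted(unknown))
    if ("survival_months" in cols) != ("event" in cols):
        raise ValueError("survival_months and event columns must be present together")

    records: list[SampleMetadata] = []
    for _, row in df.iterrows():
        months_raw = str(row.get("survival_months", "")).strip()
        event_raw = str(row.get("event", "")).strip()
        months = None if months_raw in _NA_TOKENS else float(months_raw)
        event = None if event_raw in _NA_TOKENS else int(float(event_raw))
        stage = str(row.get("stage", "")).strip() or None
        if stage is not None and stage_order is not None and stage not in stage_order:
            raise ValueError(f"stage {stage!r} not in declared order {list(stage_order)}")
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                group=str(row["group"]).strip(),
                cohort_label=str(row.get("cohort_label", "")).strip() or None,
                stage=stage,
                survival_months=months,
                event=event,
            )
        )
    _check_unique([r.sample_id for r in records], "sample id")
    return records


def write_sample_table(records: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "cohort_label": r.cohort_label if r.cohort_label is not None else "",
                "stage": r.stage if r.stage is not None else "",
                "survival_months": "" if r.survival_months is None else f"{r.survival_months:.1f}",
                "event": "" if r.event is None else str(r.event),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_probe_annotation(path: str | Path) -> dict[str, ProbeAnnotation]:
    """Read probe annotation: probe_id, gene_symbol, gene_title?, categories?.

    Categories are a semicolon-separated list in one column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for required in ("probe_id", "gene_symbol"):
        if required not in df.columns:
            raise ValueError(f"probe annotation missing required column {required!r}")
    out: dict[str, ProbeAnnotation] = {}
    for _, row in df.iterrows():
        cats = str(row.get("categories", "")).strip()
        ann = ProbeAnnotation(
            probe_id=row["probe_id"],
            gene_symbol=row["gene_symbol"],
            gene_title=str(row.get("gene_title", "")).strip() or None,
            categories=frozenset(c for c in cats.split(";") if c.strip()),
        )
        if ann.probe_id in out:
            raise ValueError(f"duplicate probe id in annotation: {ann.probe_id!r}")
        out[ann.probe_id] = ann
    return out


def write_probe_annotation(
    annotation: Mapping[str, ProbeAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "probe_id": a.probe_id,
            "gene_symbol": a.gene_symbol,
            "gene_title": a.gene_title or "",
            "categories": ";".join(sorted(a.categories)),
        }
        for a in annotation.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_categories(
    path: str | Path, dialect: str, level: str, universe_size: int
) -> CategoryUniverse:
    """Read category membership from GMT or a two-column member↦category TSV.

    GMT lines are ``name <tab> description <tab> member ...``; duplicate
    members within a category are deduplicated (sets).
    """
    categories: dict[str, set[str]] = {}
    if dialect == "gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0].strip():
                    continue
                name = parts[0].strip()
                members = {m.strip() for m in parts[2:] if m.strip()}
                categories.setdefault(name, set()).update(members)
    elif dialect == "two_column_tsv":
        with open(path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\n").split("\t")]
                if len(parts) < 2 or not parts[0]:
                    continue
                member, name = parts[0], parts[1]
                categories.setdefault(name, set()).add(member)
    else:
        raise ValueError(f"unknown category dialect {dialect!r}")
    return CategoryUniverse(
        {k: frozenset(v) for k, v in categories.items()}, universe_size, level
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def align_cohort(
    cohort: ExpressionCohort, metadata: Iterable[SampleMetadata]
) -> tuple[ExpressionCohort, dict[str, list[str]]]:
    """Restrict a cohort to annotated samples and partition by group.

    Samples absent from the metadata are dropped (count logged).  Returns the
    restricted cohort (column order preserved) and the group partition
    ``{"tumor": [...], "control": [...]}``.  Idempotent.
    """
    by_id = {m.sample_id: m for m in metadata}
    kept = [s for s in cohort.sample_ids if s in by_id]
    if not kept:
        raise ValueError("no cohort sample appears in the metadata")
    dropped = len(cohort.sample_ids) - len(kept)
    if dropped:
        logger.warning("align_cohort: dropped %d samples without metadata", dropped)
    aligned = cohort.subset_samples(kept)
    groups = {g: [s for s in kept if by_id[s].group == g] for g in GROUPS}
    return aligned, groups
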