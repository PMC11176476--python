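"""Ingestion and harmonization of monotherapy cytotoxicity screens.

A screen is a long-format table of (drug, cell line, AUC) records, where AUC
is the area under the monotherapy dose-response curve on the dataset's native
scale (lower = more sensitive).  Several public screens of this shape exist
(CTRP, GDSC, PRISM); this module reads any delimited export of that layout
and applies the standard preparation steps before cross-dataset analysis:

1. collapse duplicate (drug, cell line) measurements to their mean AUC;
2. drop cell lines whose lineage is excluded (hematological by default);
3. drop drugs observed in only one dataset, since recurrence across
   independent screens is the unit of evidence downstream.

AUC scales are deliberately left on each dataset's native scale: every
downstream statistic is rank-based within a dataset, so cross-dataset
harmonization of the response variable is unnecessary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: default lineage names treated as excluded
DEFAULT_EXCLUDED_LINEAGES = frozenset({"hematological"})


@dataclass
class AUCTable:
    """One dataset's monotherapy response records.

    ``df`` has columns ``drug``, ``cell_line``, ``auc``.  After
    :func:`prepare_datasets` the (drug, cell_line) key is unique.
    """

    dataset_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"drug", "cell_line", "auc"} - set(self.df.columns)
        if missing:
            raise FormatError(
                f"AUCTable {self.dataset_id!r}: missing columns {sorted(missing)}"
            )

    @property
    def drugs(self) -> set[str]:
        return set(self.df["drug"].unique())

    @property
    def cell_lines(self) -> set[str]:
        return set(self.df["cell_line"].unique())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def counts(self) -> dict[str, int]:
        """Per-table summary mirroring a screens-overview table layout."""
        return {
            "dataset": self.dataset_id,  # type: ignore[dict-item]
            "cell_lines": len(self.cell_lines),
            "drugs": len(self.drugs),
            "combinations": self.n_records,
        }


@dataclass
class LineageMap:
    """Cell line -> lineage assignments plus the set of excluded lineages."""

    entries: dict[str, str] = field(default_factory=dict)
    excluded_lineages: frozenset[str] = DEFAULT_EXCLUDED_LINEAGES

    def is_excluded(self, cell_line: str) -> bool:
        return self.entries.get(cell_line) in self.excluded_lineages

    def unmapped(self, cell_lines: set[str]) -> set[str]:
        return cell_lines - self.entries.keys()


def _clean_id(value: object, *, case_fold: bool, strip: bool) -> str:
    s = str(value)
    if strip:
        s = s.strip()
    if case_fold:
        s = s.casefold()
    return s


def read_auc_table(
    path,
    dataset_id: str,
    *,
    drug_col: str = "drug",
    cell_line_col: str = "cell_line",
    auc_col: str = "auc",
    sep: str | None = None,
    case_fold: bool = False,
    strip: bool = True,
) -> AUCTable:
    """Read a delimited monotherapy screen export.

    Column names are configurable; the delimiter is sniffed when ``sep`` is
    None.  Identifier matching downstream is exact-string after the optional
    case-folding and whitespace trim applied here — no fuzzy name resolution.

    Raises
    ------
    FormatError
        if a required column is absent.
    ValidationError
        if any AUC value is non-numeric or non-finite; the message names the
        offending rows (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for col in (drug_col, cell_line_col, auc_col):
        if col not in df.columns:
            raise FormatError(
                f"{path}: required column {col!r} not found "
                f"(available: {list(df.columns)})"
            )
    out = pd.DataFrame(
        {
            "drug": [
                _clean_id(v, case_fold=case_fold, strip=strip) for v in df[drug_col]
            ],
            "cell_line": [
                _clean_id(v, case_fold=case_fold, strip=strip)
                for v in df[cell_line_col]
            ],
            "auc": pd.to_numeric(df[auc_col], errors="coerce"),
        }
    )
    bad = out.index[~np.isfinite(out["auc"].to_numpy(dtype=float, na_value=np.nan))]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:20])
        raise ValidationError(
            f"{path}: non-numeric or non-finite AUC in row(s) {rows}"
            + (" ..." if len(bad) > 20 else "")
        )
    empty = out.index[(out["drug"] == "") | (out["cell_line"] == "")]
    if len(empty):
        raise ValidationError(f"{path}: empty drug or cell-line id in row(s) "
                              + ", ".join(str(i + 1) for i in empty[:20]))
    logger.info("read %d records from %s as dataset %s", len(out), path, dataset_id)
    return AUCTable(dataset_id=dataset_id, df=out)


def read_lineage_map(path, *, excluded_lineages=DEFAULT_EXCLUDED_LINEAGES) -> LineageMap:
    """Read a two-column (cell_line, lineage) CSV into a :class:`LineageMap`."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: lineage map needs two columns (cell_line, lineage)")
    cl_col, lin_col = df.columns[:2]
    entries = {
        str(c).strip(): str(lin).strip() for c, lin in zip(df[cl_col], df[lin_col])
    }
    return LineageMap(entries=entries, excluded_lineages=frozenset(excluded_lineages))


def prepare_datasets(
    tables: list[AUCTable], lineages: LineageMap
) -> list[AUCTable]:
    """Harmonize raw screens into analysis-ready per-dataset tables.

    Deduplication (mean AUC), excluded-lineage removal, and removal of drugs
    unique to a dataset, in that order.  Unmapped cell lines are retained
    with a warning.  The operation is idempotent.
    """
    if len(tables) < 2:
        raise ConfigurationError(
            f"preparation requires >=2 datasets, got {len(tables)}"
        )
    deduped: list[tuple[str, pd.DataFrame]] = []
    for t in tables:
        df = (
            t.df.groupby(["drug", "cell_line"], as_index=False, sort=True)["auc"]
            .mean()
        )
        unmapped = lineages.unmapped(set(df["cell_line"]))
        if unmapped:
            logger.warning(
                "dataset %s: %d cell line(s) without lineage annotation retained "
                "(e.g. %s)",
                t.dataset_id,
                len(unmapped),
                sorted(unmapped)[:5],
            )
        keep = ~df["cell_line"].map(lineages.is_excluded)
        df = df.loc[keep].reset_index(drop=True)
        deduped.append((t.dataset_id, df))

    drug_presence = Counter()
    for _, df in deduped:
        drug_presence.update(set(df["drug"]))
    shared = {d for d, c in drug_presence.items() if c >= 2}

    prepared = []
    for dataset_id, df in deduped:
        df = df[df["drug"].isin(shared)].reset_index(drop=True)
        table = AUCTable(dataset_id=dataset_id, df=df)
        if table.n_records == 0:
            logger.warning("dataset %s is empty after preparation", dataset_id)
        logger.info(
            "prepared %s: %d drugs, %d cell lines, %d combinations",
            dataset_id,
            len(table.drugs),
            len(table.cell_lines),
            table.n_records,
        )
        prepared.append(table)
    return prepared


def write_auc_table(table: AUCTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
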