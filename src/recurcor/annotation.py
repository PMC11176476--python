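"""Drug-class annotation.

Drugs are mapped to Anatomical Therapeutic Chemical (ATC) class codes, used
throughout as a surrogate identifier for mechanism of action.  Codes are
arbitrary strings: real screens contain compounds without an official ATC
code, so curated maps routinely include non-canonical codes, and no ontology
validation is attempted.  Catch-all "miscellaneous-type" codes (e.g. L01XX
"other antineoplastics") group drugs by *not* fitting elsewhere, so class
pairs containing them are flagged and later excluded from final reporting.

A drug pair maps to a canonical class-pair key "CODE1-CODE2" with the codes
lexicographically sorted, so the key is independent of input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .correlation import PairSummary
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: catch-all class codes excluded from final enrichment reports
DEFAULT_MISC_CODES = frozenset(
    {"D01AE", "L01AX", "L01CX", "L01DC", "L01EX", "L01XX"}
)


@dataclass
class ClassMap:
    """Drug -> class-code assignments plus per-code metadata.

    ``class_flags`` carries optional curation flags per code (``targeted``,
    ``pathway_group``) used only for user-driven prioritization filters.
    """

    assignments: dict[str, str]
    misc_codes: frozenset[str] = DEFAULT_MISC_CODES
    class_labels: dict[str, str] = field(default_factory=dict)
    class_flags: dict[str, dict] = field(default_factory=dict)

    def code_of(self, drug: str) -> str:
        try:
            return self.assignments[drug]
        except KeyError:
            raise ValidationError(f"drug {drug!r} has no class assignment") from None

    def label(self, code: str) -> str:
        return self.class_labels.get(code, code)


@dataclass(frozen=True)
class ClassPair:
    key: str
    same_class: bool
    contains_misc: bool

    @property
    def codes(self) -> tuple[str, str]:
        a, b = self.key.split("-", 1)
        return a, b


def class_pair_key(
    code_a: str, code_b: str, class_map: ClassMap | None = None
) -> ClassPair:
    """Canonical order-independent class-pair key.

    e.g. (L01EG, L01EF) -> "L01EF-L01EG".
    """
    if not code_a or not code_b:
        raise ValidationError("class codes must be non-empty")
    lo, hi = sorted((code_a, code_b))
    misc = DEFAULT_MISC_CODES if class_map is None else class_map.misc_codes
    return ClassPair(
        key=f"{lo}-{hi}",
        same_class=lo == hi,
        contains_misc=lo in misc or hi in misc,
    )


_TRUTHY = {"1", "true", "yes", "y", "t"}


def _as_bool(v) -> bool:
    return str(v).strip().casefold() in _TRUTHY


def load_class_map(path, *, misc_codes=DEFAULT_MISC_CODES) -> ClassMap:
    """Read a drug->class CSV (columns: drug, code[, label, misc, targeted,
    pathway_group]).  Unknown columns are ignored with a warning.

    A drug listed twice with conflicting codes is an error; repeated
    consistent rows are tolerated.  Codes flagged ``misc`` are added to the
    default miscellaneous registry.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: class map needs at least (drug, code) columns")
    cols = {c.strip().casefold(): c for c in df.columns}
    drug_col = cols.get("drug", df.columns[0])
    code_col = cols.get("code", cols.get("atc_code", df.columns[1]))
    known = {"drug", "code", "atc_code", "label", "misc", "targeted", "pathway_group"}
    unknown = [c for c in df.columns if c.strip().casefold() not in known]
    if unknown:
        logger.warning("%s: ignoring unrecognized columns %s", path, unknown)

    assignments: dict[str, str] = {}
    labels: dict[str, str] = {}
    flags: dict[str, dict] = {}
    misc = set(misc_codes)
    for i, row in df.iterrows():
        drug = str(row[drug_col]).strip()
        code = "" if pd.isna(row[code_col]) else str(row[code_col]).strip()
        if not code:
            raise ValidationError(f"{path}: empty class code for drug {drug!r}")
        if drug in assignments and assignments[drug] != code:
            raise ValidationError(
                f"{path}: drug {drug!r} assigned to both "
                f"{assignments[drug]!r} and {code!r}"
            )
        assignments[drug] = code
        if "label" in cols and pd.notna(row[cols["label"]]):
            labels[code] = str(row[cols["label"]]).strip()
        if "misc" in cols and _as_bool(row[cols["misc"]]):
            misc.add(code)
        entry = flags.setdefault(code, {})
        if "targeted" in cols and pd.notna(row[cols["targeted"]]):
            entry["targeted"] = _as_bool(row[cols["targeted"]])
        if "pathway_group" in cols and pd.notna(row[cols["pathway_group"]]):
            entry["pathway_group"] = str(row[cols["pathway_group"]]).strip()
    return ClassMap(
        assignments=assignments,
        misc_codes=frozenset(misc),
        class_labels=labels,
        class_flags={k: v for k, v in flags.items() if v},
    )


def annotate_pair_sets(
    summaries: list[PairSummary], class_map: ClassMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate the tested background and the DCSCAD foreground with class
    pairs and integer weights.

    Background weight = number of datasets the pair was tested in;
    foreground weight = number of datasets the pair was correlated in.  The
    weighting compensates for pairs tested in three screens being tested (and
    thus correlatable) more often than pairs tested in two.

    Every drug must have a class assignment; otherwise a
    :class:`ValidationError` lists the complete set of missing drugs.
    """
    drugs = sorted({d for s in summaries for d in s.pair})
    missing = [d for d in drugs if d not in class_map.assignments]
    if missing:
        raise ValidationError(
            f"{len(missing)} drug(s) without class assignment: {missing}"
        )

    def rows(subset, weight_of):
        recs = []
        for s in subset:
            cp = class_pair_key(
                class_map.code_of(s.pair[0]), class_map.code_of(s.pair[1]), class_map
            )
            recs.append(
                {
                    "drug_a": s.pair[0],
                    "drug_b": s.pair[1],
                    "class_key": cp.key,
                    "same_class": cp.same_class,
                    "contains_misc": cp.contains_misc,
                    "weight": weight_of(s),
                }
            )
        return pd.DataFrame(
            recs,
            columns=[
                "drug_a",
                "drug_b",
                "class_key",
                "same_class",
                "contains_misc",
                "weight",
            ],
        )

    background = rows(summaries, lambda s: len(s.datasets_tested))
    foreground = rows(
        [s for s in summaries if s.in_dcscad],
        lambda s: len(s.datasets_correlated),
    )
    return background, foreground
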