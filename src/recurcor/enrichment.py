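"""Weighted hypergeometric class-combination enrichment.

Each class combination present in the DCSCAD is tested for overrepresentation
against the background of all class combinations tested for correlation,
using dataset-count weights (an urn of N weighted background instances of
which K carry the class pair; n weighted DCSCAD draws of which k carry it).
The enrichment p-value is the upper tail P(X >= k).

Order of operations, which matters for the multiple-testing family:

1. same-class combinations are removed *before* FDR adjustment — they are
   enriched by construction (same targets) and would distort the family;
2. Benjamini-Hochberg is applied across the remaining tested combinations,
   miscellaneous-containing ones included;
3. miscellaneous-containing combinations are excluded *after* FDR, since
   their class labels do not describe a shared mechanism of action.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import ClassPair
from .errors import ValidationError

logger = logging.getLogger(__name__)

STATUS_TESTED = "tested"
STATUS_SAME_CLASS = "removed_same_class"
STATUS_MISC = "excluded_misc"


@dataclass
class EnrichmentRecord:
    class_pair: ClassPair
    k: int  # foreground weighted count of this class pair
    n: int  # total foreground weight
    K: int  # background weighted count of this class pair
    N: int  # total background weight
    p_raw: float
    p_fdr: float | None
    status: str


def weighted_class_counts(
    background: pd.DataFrame, foreground: pd.DataFrame
) -> tuple[dict[str, int], dict[str, int], int, int]:
    """Sum integer weights per class-pair key.

    Returns (foreground counts, background counts, n, N).  Every foreground
    class pair must appear in the background — a DCSCAD pair is by
    definition a tested pair.
    """
    bg = background.groupby("class_key")["weight"].sum().astype(int).to_dict()
    fg = (
        foreground.groupby("class_key")["weight"].sum().astype(int).to_dict()
        if len(foreground)
        else {}
    )
    orphans = set(fg) - set(bg)
    if orphans:
        raise ValidationError(
            f"foreground class pairs absent from background: {sorted(orphans)}"
        )
    n = int(sum(fg.values()))
    N = int(sum(bg.values()))
    return fg, bg, n, N


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Includes the observed value in the tail (the standard overrepresentation
    convention) and is evaluated via the survival function, which works in
    log space internally and stays stable for large counts.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(
            f"count k={k} outside [0, min(n={n}, K={K})] for N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with the
    input and capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def run_enrichment(
    background: pd.DataFrame,
    foreground: pd.DataFrame,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every class combination present in the DCSCAD.

    ``background``/``foreground`` are the annotated instance tables from
    :func:`recurcor.annotation.annotate_pair_sets`.  Records come back for
    all tested combinations with status ``tested``, ``removed_same_class``
    (no adjusted p) or ``excluded_misc`` (adjusted p retained but excluded
    from the final report).  Use :func:`significant` for the final list.
    """
    fg, bg, n, N = weighted_class_counts(background, foreground)
    if not fg:
        logger.warning("empty DCSCAD: no class combinations to test")
        return []

    flag_rows = (
        pd.concat([background, foreground])
        .drop_duplicates("class_key")
        .set_index("class_key")
    )
    records: list[EnrichmentRecord] = []
    for key in sorted(fg):
        row = flag_rows.loc[key]
        cp = ClassPair(
            key=key,
            same_class=bool(row["same_class"]),
            contains_misc=bool(row["contains_misc"]),
        )
        k, K = fg[key], bg[key]
        records.append(
            EnrichmentRecord(
                class_pair=cp,
                k=k,
                n=n,
                K=K,
                N=N,
                p_raw=hypergeom_upper_tail(k, K, n, N),
                p_fdr=None,
                status=STATUS_SAME_CLASS if cp.same_class else STATUS_TESTED,
            )
        )

    family = [r for r in records if r.status == STATUS_TESTED]
    if family:
        adjusted = bh_adjust([r.p_raw for r in family])
        for r, p in zip(family, adjusted):
            r.p_fdr = float(p)
    for r in family:
        if r.class_pair.contains_misc:
            r.status = STATUS_MISC
    logger.info(
        "enrichment: %d tested, %d same-class removed, FDR family %d, "
        "%d misc-excluded",
        len(records),
        sum(r.status == STATUS_SAME_CLASS for r in records),
        len(family),
        sum(r.status == STATUS_MISC for r in records),
    )
    return records


def significant(
    records: list[EnrichmentRecord], alpha: float = 0.05
) -> list[EnrichmentRecord]:
    """Final report: tested, FDR-significant combinations, most significant
    first (ties broken lexicographically by class-pair key)."""
    hits = [
        r
        for r in records
        if r.status == STATUS_TESTED and r.p_fdr is not None and r.p_fdr < alpha
    ]
    return sorted(hits, key=lambda r: (r.p_fdr, r.class_pair.key))


def enrichment_frame(records: list[EnrichmentRecord], class_map=None) -> pd.DataFrame:
    """Flat TSV-ready table of all enrichment records."""
    rows = []
    for r in sorted(records, key=lambda r: r.class_pair.key):
        a, b = r.class_pair.codes
        rows.append(
            {
                "class_key": r.class_pair.key,
                "label_a": class_map.label(a) if class_map else a,
                "label_b": class_map.label(b) if class_map else b,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "status": r.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "class_key", "label_a", "label_b",
            "k", "K", "n", "N", "p_raw", "p_fdr", "status",
        ],
    )


def prioritized(
    records: list[EnrichmentRecord],
    class_map,
    alpha: float = 0.05,
    *,
    distinct_pathways: bool = False,
    targeted_only: bool = False,
) -> list[EnrichmentRecord]:
    """Apply the user-curated prioritization filters to the significant set.

    ``distinct_pathways`` keeps combinations whose two classes carry
    different ``pathway_group`` flags; ``targeted_only`` keeps combinations
    where both classes are flagged targeted.  Both filters rely on curation
    supplied in the class map — nothing is inferred.
    """
    out = []
    for r in significant(records, alpha):
        a, b = r.class_pair.codes
        fa = class_map.class_flags.get(a, {})
        fb = class_map.class_flags.get(b, {})
        if distinct_pathways:
            ga, gb = fa.get("pathway_group"), fb.get("pathway_group")
            if ga is None or gb is None or ga == gb:
                continue
        if targeted_only and not (fa.get("targeted") and fb.get("targeted")):
            continue
        out.append(r)
    return out
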