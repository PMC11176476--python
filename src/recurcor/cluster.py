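"""Class-by-class matrix assembly, pruning, clustering, and export.

Enrichment results are reshaped into a square symmetric matrix of adjusted
p-values over individual drug classes.  Class pairs never tested for
correlation in any dataset are *missing* (masked); class pairs that were
tested but never entered the DCSCAD — and the diagonal — are set to 1.0, the
value of "no evidence of enrichment", so that a complete matrix suitable for
Euclidean distances can be formed.

Because panel overlap is sparse, some classes participate in many missing
cells; the pruning step removes offender classes (greedy most-missing-first,
with a manual override list) until the matrix is complete, after which the
classes are hierarchically clustered (complete linkage, Euclidean distance on
rows of adjusted p-values) for heatmap display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .annotation import ClassMap, class_pair_key
from .correlation import PairSummary
from .enrichment import EnrichmentRecord
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClassPValueMatrix:
    """Square symmetric matrix of adjusted enrichment p-values.

    ``missing_mask`` is True where the class pair was never tested for
    correlation in any dataset (absent from the background).
    """

    classes: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    @property
    def n_missing_cells(self) -> int:
        """Unordered off-diagonal missing cells."""
        return int(np.triu(self.missing_mask, k=1).sum())

    @property
    def n_class_pairs(self) -> int:
        m = len(self.classes)
        return m * (m - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.classes, columns=self.classes)
        return df.mask(self.missing_mask)


def build_class_pvalue_matrix(
    records: list[EnrichmentRecord], background_keys
) -> ClassPValueMatrix:
    """Assemble the matrix from enrichment records and the background keys.

    Entry conventions: adjusted p where an adjusted p exists; 1.0 where the
    class pair is in the background but carries no adjusted p (not in the
    DCSCAD, or removed as same-class); the diagonal is 1.0; masked where the
    class pair is absent from the background entirely.
    """
    background_keys = set(background_keys)
    classes = sorted({c for key in background_keys for c in key.split("-", 1)})
    idx = {c: i for i, c in enumerate(classes)}
    m = len(classes)
    values = np.ones((m, m))
    mask = np.ones((m, m), dtype=bool)
    np.fill_diagonal(mask, False)

    for key in background_keys:
        a, b = key.split("-", 1)
        i, j = idx[a], idx[b]
        mask[i, j] = mask[j, i] = False

    for r in records:
        if r.p_fdr is None:
            continue
        a, b = r.class_pair.codes
        if a not in idx or b not in idx:
            continue
        i, j = idx[a], idx[b]
        values[i, j] = values[j, i] = r.p_fdr
    values[mask] = np.nan
    return ClassPValueMatrix(classes=classes, values=values, missing_mask=mask)


def prune_to_complete(
    matrix: ClassPValueMatrix, drop_classes=()
) -> ClassPValueMatrix:
    """Remove classes until no off-diagonal cell is missing.

    Classes in ``drop_classes`` are removed first (manual override, mirroring
    a curator's choice of offender classes); the remainder are removed
    greedily, always the class in the most missing cells, ties broken
    lexicographically.  Each greedy step strictly reduces the missing count,
    so termination is guaranteed.
    """
    classes = list(matrix.classes)
    values = matrix.values.copy()
    mask = matrix.missing_mask.copy()

    def drop(name: str):
        nonlocal classes, values, mask
        i = classes.index(name)
        keep = [j for j in range(len(classes)) if j != i]
        classes = [classes[j] for j in keep]
        values = values[np.ix_(keep, keep)]
        mask = mask[np.ix_(keep, keep)]

    removed = []
    for name in drop_classes:
        if name in classes:
            drop(name)
            removed.append(name)

    while mask.any():
        per_class = mask.sum(axis=1)
        worst = int(np.lexsort((np.array(classes, dtype=str), -per_class))[0])
        name = classes[worst]
        drop(name)
        removed.append(name)

    if len(classes) < 2:
        raise ValidationError(
            f"pruning left {len(classes)} class(es); matrix unusable"
        )
    if removed:
        logger.info("pruned %d class(es): %s", len(removed), removed)
    return ClassPValueMatrix(classes=classes, values=values, missing_mask=mask)


def _canonical_leaf_order(Z: np.ndarray, labels: list[str]) -> list[int]:
    """Leaf order determined by the merge tree with subtrees ordered by their
    lexicographically smallest label, so the order is invariant to the input
    row permutation (for matrices without tied merge heights)."""
    n = len(labels)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    key: dict[int, str] = {i: labels[i] for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        first, second = (a, b) if key[a] <= key[b] else (b, a)
        node = n + step
        members[node] = members[first] + members[second]
        key[node] = min(key[first], key[second])
    return members[2 * n - 2] if n > 1 else [0]


def hierarchical_order(
    matrix: ClassPValueMatrix,
    method: str = "complete",
    metric: str = "euclidean",
) -> tuple[list[str], np.ndarray]:
    """Cluster class rows and return (ordered class labels, linkage matrix).

    The feature vector for a class is its row of adjusted p-values.  The
    returned leaf order is deterministic and permutation-invariant (see
    :func:`_canonical_leaf_order`).
    """
    if matrix.missing_mask.any():
        raise ValidationError("matrix has missing cells; prune before clustering")
    if len(matrix.classes) < 2:
        return list(matrix.classes), np.empty((0, 4))
    Z = linkage(pdist(matrix.values, metric=metric), method=method)
    order = _canonical_leaf_order(Z, matrix.classes)
    return [matrix.classes[i] for i in order], Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a merge tree as a Newick string with merge heights as
    branch lengths."""
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"
    node_height = {i: 0.0 for i in range(n)}
    text = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = (h - node_height[a]) / 2
        lb = (h - node_height[b]) / 2
        node = n + step
        text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
        node_height[node] = h
    return text[2 * n - 2] + ";"


def fraction_correlated_matrix(
    summaries: list[PairSummary],
    drugs: list[str],
    class_map: ClassMap,
    dcscad_threshold: float = 0.66,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug-level view of recurrence: fraction of datasets correlated.

    Returns ``(fractions, qualifies)``: a drug x drug DataFrame of
    fraction-correlated values (NaN for untested and same-class cells, both
    displayed gray in figures) and a boolean DataFrame marking cells whose
    fraction exceeds ``dcscad_threshold`` — i.e. correlated in >2/3 of the
    (2 or 3) datasets tested.  Drugs are grouped by class in the output
    order.
    """
    by_pair = {s.pair: s for s in summaries}
    unknown = [d for d in drugs if d not in class_map.assignments]
    if unknown:
        raise ValidationError(f"drugs without class assignment: {unknown}")
    ordered = sorted(drugs, key=lambda d: (class_map.code_of(d), d))
    frac = pd.DataFrame(np.nan, index=ordered, columns=ordered)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if class_map.code_of(a) == class_map.code_of(b):
                continue  # same-class cells stay unavailable
            s = by_pair.get((a, b) if a < b else (b, a))
            if s is None:
                logger.debug("pair %s-%s never tested", a, b)
                continue
            frac.loc[a, b] = frac.loc[b, a] = s.fraction_correlated
    qualifies = frac > dcscad_threshold
    return frac, qualifies


def export_heatmap(
    matrix: ClassPValueMatrix,
    ordering: list[str],
    path_prefix,
    *,
    missing_sentinel: str = "NA",
) -> dict[str, str]:
    """Write the ordered matrix as TSV and a raster heatmap.

    Smaller adjusted p-values map to hotter colors; masked cells get the
    sentinel in the TSV and a distinct gray in the image.  Returns the paths
    written.  Re-export of identical input is byte-identical for the TSV.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.to_frame().loc[ordering, ordering]
    tsv_path = f"{path_prefix}.tsv"
    png_path = f"{path_prefix}.png"
    df.to_csv(tsv_path, sep="\t", na_rep=missing_sentinel, float_format="%.6g")

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(ordering)), max(4, 0.25 * len(ordering)))
    )
    cmap = plt.get_cmap("inferno_r").copy()
    cmap.set_bad("0.7")
    with np.errstate(divide="ignore"):
        shown = -np.log10(np.clip(df.to_numpy(dtype=float), 1e-300, 1.0))
    im = ax.imshow(np.ma.masked_invalid(shown), cmap=cmap, interpolation="nearest")
    ax.set_xticks(range(len(ordering)), ordering, rotation=90, fontsize=6)
    ax.set_yticks(range(len(ordering)), ordering, fontsize=6)
    fig.colorbar(im, ax=ax, label="-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return {"tsv": tsv_path, "png": png_path}
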