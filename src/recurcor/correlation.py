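"""Pairwise drug-drug correlation and cross-dataset recurrence.

The central object is the set of "drug combinations significantly correlated
across datasets" (DCSCAD): unordered drug pairs whose monotherapy AUC
profiles show |Spearman rho| at or above a magnitude cutoff in at least two
independent screens, with the same correlation sign everywhere the magnitude
criterion is met.

Eligibility comes first: a pair is tested in a dataset only when the two
drugs share at least ``min_shared`` cell lines there, and only pairs meeting
that bar in at least ``min_datasets`` datasets are tested at all.  Spearman
p-values play no role in pruning — sample sizes and panel overlaps vary
between pairs, so the p-values are not exchangeable across tests and cannot
be jointly adjusted; the magnitude + recurrence + sign-consistency rule is
the whole filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .io import AUCTable

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

#: magnitude cutoff on |rho| for a pair to count as correlated in a dataset
DEFAULT_RHO_MIN = 0.25
#: minimum shared cell lines for a pair to be testable in a dataset
DEFAULT_MIN_SHARED = 10
#: minimum datasets for eligibility and for DCSCAD recurrence
DEFAULT_MIN_DATASETS = 2


def canonical_pair(drug_a: str, drug_b: str) -> Pair:
    """Unordered pair key: lexicographically sorted, applied before any join."""
    if drug_a == drug_b:
        raise ValueError(f"pair members must be distinct, got {drug_a!r} twice")
    return (drug_a, drug_b) if drug_a < drug_b else (drug_b, drug_a)


@dataclass(frozen=True)
class PairCorrelation:
    pair: Pair
    dataset_id: str
    rho: float
    n_shared: int


@dataclass
class PairSummary:
    """Cross-dataset recurrence summary for one drug pair."""

    pair: Pair
    datasets_tested: frozenset[str]
    datasets_correlated: frozenset[str]
    signs: dict[str, int]  # dataset -> +1/-1, correlated datasets only
    in_dcscad: bool
    sign_conflict: bool

    @property
    def fraction_correlated(self) -> float:
        return len(self.datasets_correlated) / len(self.datasets_tested)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Equivalent to the Pearson correlation of the mid-ranked vectors.  Returns
    NaN (the undefined-correlation sentinel) when either vector has zero rank
    variance; no p-value is computed or used anywhere in this package.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def enumerate_eligible_pairs(
    tables: list[AUCTable],
    min_shared: int = DEFAULT_MIN_SHARED,
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> dict[str, list[Pair]]:
    """Pairs with >= ``min_shared`` shared cell lines in >= ``min_datasets``
    datasets, listed under every dataset where the shared-lines bar is met.

    Uses a drugs x cell-lines indicator matrix per dataset so the shared-line
    counts come from one integer matrix product.
    """
    if min_shared < 2:
        raise ConfigurationError("min_shared must be >= 2")
    per_dataset_ok: dict[str, set[Pair]] = {}
    for t in tables:
        drugs = sorted(t.drugs)
        cells = {c: j for j, c in enumerate(sorted(t.cell_lines))}
        m = np.zeros((len(drugs), len(cells)), dtype=np.int32)
        di = {d: i for i, d in enumerate(drugs)}
        for d, c in zip(t.df["drug"], t.df["cell_line"]):
            m[di[d], cells[c]] = 1
        shared = m @ m.T
        ii, jj = np.nonzero(np.triu(shared >= min_shared, k=1))
        per_dataset_ok[t.dataset_id] = {(drugs[i], drugs[j]) for i, j in zip(ii, jj)}

    counts: dict[Pair, int] = {}
    for ok in per_dataset_ok.values():
        for p in ok:
            counts[p] = counts.get(p, 0) + 1
    eligible = {p for p, c in counts.items() if c >= min_datasets}
    result = {
        ds: sorted(ok & eligible) for ds, ok in per_dataset_ok.items()
    }
    for ds, pairs in result.items():
        logger.info("dataset %s: %d eligible pairs", ds, len(pairs))
    return result


def correlate_all(
    tables: list[AUCTable], eligible: dict[str, list[Pair]]
) -> list[PairCorrelation]:
    """One Spearman rho per (eligible pair, dataset), computed on the cell
    lines where both drugs were measured in that dataset.

    Pairs with degenerate rank variance in a dataset are omitted for that
    dataset (logged); the result is deterministic given the inputs.
    """
    by_id = {t.dataset_id: t for t in tables}
    out: list[PairCorrelation] = []
    n_skipped = 0
    for dataset_id, pairs in sorted(eligible.items()):
        table = by_id[dataset_id]
        wide = table.df.pivot(index="cell_line", columns="drug", values="auc")
        arr = {d: wide[d].to_numpy() for d in wide.columns}
        for a, b in pairs:
            xa, xb = arr[a], arr[b]
            mask = ~(np.isnan(xa) | np.isnan(xb))
            n_shared = int(mask.sum())
            if n_shared < 2:
                continue
            rho = spearman_rho(xa[mask], xb[mask])
            if math.isnan(rho):
                n_skipped += 1
                logger.debug(
                    "pair %s-%s in %s skipped: zero rank variance", a, b, dataset_id
                )
                continue
            out.append(
                PairCorrelation(
                    pair=(a, b), dataset_id=dataset_id, rho=rho, n_shared=n_shared
                )
            )
    if n_skipped:
        logger.info("skipped %d pair/dataset entries with undefined rho", n_skipped)
    return out


def build_dcscad(
    correlations: list[PairCorrelation],
    rho_min: float = DEFAULT_RHO_MIN,
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> list[PairSummary]:
    """Assemble per-pair recurrence summaries and DCSCAD membership.

    A pair enters the DCSCAD when |rho| >= ``rho_min`` (inclusive) in at
    least ``min_datasets`` datasets and the sign of rho agrees across all of
    those datasets.  Sign-conflicted pairs are retained in the output with
    ``in_dcscad=False`` and ``sign_conflict=True`` — they stay part of the
    tested background downstream.
    """
    if not 0 < rho_min <= 1:
        raise ConfigurationError("rho_min must be in (0, 1]")
    grouped: dict[Pair, list[PairCorrelation]] = {}
    for c in correlations:
        grouped.setdefault(c.pair, []).append(c)

    summaries = []
    for pair in sorted(grouped):
        entries = grouped[pair]
        tested = frozenset(e.dataset_id for e in entries)
        corr = {e.dataset_id: e.rho for e in entries if abs(e.rho) >= rho_min}
        signs = {ds: (1 if rho > 0 else -1) for ds, rho in corr.items()}
        recurrent = len(corr) >= min_datasets
        consistent = len(set(signs.values())) <= 1
        summaries.append(
            PairSummary(
                pair=pair,
                datasets_tested=tested,
                datasets_correlated=frozenset(corr),
                signs=signs,
                in_dcscad=recurrent and consistent,
                sign_conflict=recurrent and not consistent,
            )
        )
    n_in = sum(s.in_dcscad for s in summaries)
    logger.info(
        "DCSCAD: %d of %d tested pairs (%d sign conflicts removed)",
        n_in,
        len(summaries),
        sum(s.sign_conflict for s in summaries),
    )
    return summaries


def correlations_frame(correlations: list[PairCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug_a": [c.pair[0] for c in correlations],
            "drug_b": [c.pair[1] for c in correlations],
            "dataset": [c.dataset_id for c in correlations],
            "rho": [c.rho for c in correlations],
            "n_shared": [c.n_shared for c in correlations],
        }
    )


def summaries_frame(summaries: list[PairSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug_a": [s.pair[0] for s in summaries],
            "drug_b": [s.pair[1] for s in summaries],
            "n_tested": [len(s.datasets_tested) for s in summaries],
            "n_correlated": [len(s.datasets_correlated) for s in summaries],
            "fraction_correlated": [s.fraction_correlated for s in summaries],
            "in_dcscad": [s.in_dcscad for s in summaries],
            "sign_conflict": [s.sign_conflict for s in summaries],
        }
    )
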