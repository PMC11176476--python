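"""Synergy validation: combinatorial-screen calls and dose-matrix metrics.

Two layers of validation are supported.

*Screen-level*: given a public combinatorial screen of Loewe synergy scores
per (drug pair, cell line), a synergy cutoff is set at a percentile of all
scores (90th by default), a drug pair is called synergistic when it exceeds
the cutoff in at least one cell line, and a class combination is called
synergistic when at least one member pair is.  The fraction of
enrichment-identified class combinations that receive a synergistic call is
the headline validation number.

*Dose-matrix level*: an a x b checkerboard of combination treatments with
single-agent edges is scored against three references:

- **Loewe additivity** — the combination behaves as a drug combined with
  itself: the expected effect y at doses (d_a, d_b) solves
  d_a/D_a(y) + d_b/D_b(y) = 1, with D(.) the inverse four-parameter-logistic
  dose functions of the two single agents.
- **HSA** (highest single agent) — expected effect is the better of the two
  single agents at the corresponding doses.
- **Chou-Talalay combination index** — CI = d_a/D_a(fa) + d_b/D_b(fa) with
  D from median-effect fits (fa/fu = (D/Dm)^m); reported at the 75% effect
  level.

Loewe and HSA scores are the mean observed-minus-expected effect over the
matrix in percentage points; scores > 10 are called synergistic, while CI
< 0.3 at EC75 is the strong-synergy call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .annotation import ClassMap, class_pair_key
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

LOEWE_SYNERGY_THRESHOLD = 10.0
HSA_SYNERGY_THRESHOLD = 10.0
CI_SYNERGY_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# screen-level validation
# ---------------------------------------------------------------------------

@dataclass
class ComboScreenTable:
    """Long-format combinatorial screen: one Loewe score per (pair, line)."""

    df: pd.DataFrame  # columns drug_a, drug_b, cell_line, loewe_score

    def __post_init__(self) -> None:
        need = {"drug_a", "drug_b", "cell_line", "loewe_score"}
        if not need <= set(self.df.columns):
            raise ValidationError(f"combo screen needs columns {sorted(need)}")
        if not np.isfinite(self.df["loewe_score"].to_numpy(dtype=float)).all():
            raise ValidationError("combo screen contains non-finite scores")
        # canonicalize the unordered pair
        a = self.df["drug_a"].astype(str)
        b = self.df["drug_b"].astype(str)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        self.df = self.df.assign(drug_a=lo, drug_b=hi)

    @property
    def scores(self) -> np.ndarray:
        return self.df["loewe_score"].to_numpy(dtype=float)


def read_combo_screen(path) -> ComboScreenTable:
    return ComboScreenTable(pd.read_csv(path, sep=None, engine="python"))


def percentile_cutoff(scores, percentile: float = 90.0) -> float:
    """Linear-interpolation percentile of all scores considered, used as the
    synergy cutoff (comparison downstream is strict >)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("cannot take a percentile of zero scores")
    if not 0 <= percentile <= 100:
        raise ConfigurationError("percentile must be in [0, 100]")
    return float(np.percentile(scores, percentile, method="linear"))


@dataclass
class ValidationCalls:
    cutoff: float
    pair_calls: pd.DataFrame      # drug_a, drug_b, class_key, max_score, synergistic
    class_calls: dict[str, bool]  # class_key -> call over member pairs
    evaluated_class_pairs: list[str] = field(default_factory=list)
    fraction_synergistic: float | None = None


def call_synergy(
    screen: ComboScreenTable,
    cutoff: float,
    class_map: ClassMap,
    identified_class_pairs=None,
) -> ValidationCalls:
    """Combination- and class-level synergy calls at a fixed cutoff.

    A pair is synergistic when its score strictly exceeds the cutoff in at
    least one cell line; a class combination when at least one member pair
    is.  If ``identified_class_pairs`` is given, the fraction of those class
    pairs (restricted to pairs evaluable in the screen) receiving a call is
    reported.  Pairs with an unannotated drug are excluded with a warning.
    """
    rows = []
    for (a, b), sub in screen.df.groupby(["drug_a", "drug_b"], sort=True):
        if a not in class_map.assignments or b not in class_map.assignments:
            logger.warning("screen pair %s-%s has unannotated drug(s); excluded", a, b)
            continue
        cp = class_pair_key(class_map.code_of(a), class_map.code_of(b), class_map)
        mx = float(sub["loewe_score"].max())
        rows.append(
            {
                "drug_a": a,
                "drug_b": b,
                "class_key": cp.key,
                "max_score": mx,
                "synergistic": mx > cutoff,
            }
        )
    pair_calls = pd.DataFrame(
        rows, columns=["drug_a", "drug_b", "class_key", "max_score", "synergistic"]
    )
    class_calls = (
        pair_calls.groupby("class_key")["synergistic"].any().to_dict()
        if len(pair_calls)
        else {}
    )

    evaluated: list[str] = []
    fraction = None
    if identified_class_pairs is not None:
        evaluated = sorted(k for k in identified_class_pairs if k in class_calls)
        if evaluated:
            fraction = sum(class_calls[k] for k in evaluated) / len(evaluated)
    return ValidationCalls(
        cutoff=cutoff,
        pair_calls=pair_calls,
        class_calls=class_calls,
        evaluated_class_pairs=evaluated,
        fraction_synergistic=fraction,
    )


# ---------------------------------------------------------------------------
# dose-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseMatrix:
    """Checkerboard viability data as fraction affected relative to vehicle.

    ``inhibition[i, j]`` is the combination effect at (conc_a[i], conc_b[j]);
    ``mono_a``/``mono_b`` are the single-agent effects along each edge.
    Concentrations are molar, strictly positive and ascending.
    """

    conc_a: np.ndarray
    conc_b: np.ndarray
    inhibition: np.ndarray
    mono_a: np.ndarray
    mono_b: np.ndarray

    def __post_init__(self) -> None:
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        self.mono_a = np.asarray(self.mono_a, dtype=float)
        self.mono_b = np.asarray(self.mono_b, dtype=float)
        for conc in (self.conc_a, self.conc_b):
            if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
                raise ValidationError(
                    "concentrations must be strictly positive and ascending"
                )
        if self.inhibition.shape != (len(self.conc_a), len(self.conc_b)):
            raise ValidationError("inhibition matrix shape mismatch")
        if not np.isfinite(self.inhibition).all():
            raise ValidationError("inhibition values must be finite")


@dataclass
class FourPLFit:
    """Four-parameter logistic: y = bottom + (top-bottom)/(1+(ec50/D)^hill)."""

    bottom: float
    top: float
    ec50: float
    hill: float
    converged: bool = True
    message: str = ""

    def predict(self, conc) -> np.ndarray:
        d = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1 + (self.ec50 / d) ** self.hill)

    def inverse(self, y: float) -> float:
        """Dose giving effect ``y``; inf/0 outside the attainable range."""
        if y >= self.top:
            return math.inf
        if y <= self.bottom:
            return 0.0
        r = (self.top - y) / (y - self.bottom)
        return self.ec50 * r ** (-1.0 / self.hill)


def fit_four_parameter_logistic(conc, response) -> FourPLFit:
    """Variable-slope 4PL fit of effect vs log-concentration.

    Initialization is deterministic: bottom/top from the response extremes,
    EC50 by interpolating the concentration at mid-response, hill = 1.
    Flat responses yield a flagged degenerate fit (EC50 unidentifiable)
    rather than an exception; non-convergence is likewise flagged.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValidationError("need >= 4 distinct concentrations for a 4PL fit")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be positive")

    lo, hi = float(response.min()), float(response.max())
    if hi - lo < 1e-9:
        return FourPLFit(
            bottom=lo, top=hi, ec50=float(np.median(conc)), hill=1.0,
            converged=False, message="flat response: EC50 unidentifiable",
        )
    mid = (lo + hi) / 2
    order = np.argsort(conc)
    c_sorted, r_sorted = conc[order], response[order]
    ec50_0 = float(np.interp(mid, np.sort(r_sorted), c_sorted[np.argsort(r_sorted)]))
    ec50_0 = min(max(ec50_0, c_sorted[0]), c_sorted[-1])

    def model(logc, bottom, top, log_ec50, hill):
        return bottom + (top - bottom) / (1 + 10 ** ((log_ec50 - logc) * hill))

    try:
        popt, _ = curve_fit(
            model,
            np.log10(conc),
            response,
            p0=[lo, hi, math.log10(ec50_0), 1.0],
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        return FourPLFit(
            bottom=lo, top=hi, ec50=ec50_0, hill=1.0,
            converged=False, message=f"non-convergence: {exc}",
        )
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    if bottom > top:
        bottom, top = top, bottom
        hill = -hill
    return FourPLFit(bottom=bottom, top=top, ec50=10 ** log_ec50, hill=hill)


@dataclass
class MedianEffectFit:
    """Median-effect line: log(fa/fu) = m (log D - log Dm)."""

    m: float
    dm: float

    def dose_at(self, fa: float) -> float:
        if not 0 < fa < 1:
            raise ValidationError("effect level must lie strictly in (0, 1)")
        return self.dm * (fa / (1 - fa)) ** (1.0 / self.m)


def median_effect_fit(conc, fa) -> MedianEffectFit:
    """Least-squares median-effect fit over points with 0 < fa < 1."""
    conc = np.asarray(conc, dtype=float)
    fa = np.asarray(fa, dtype=float)
    keep = (fa > 0) & (fa < 1)
    if keep.sum() < 2:
        raise ValidationError(
            "median-effect fit needs >= 2 points with 0 < fa < 1"
        )
    x = np.log(conc[keep])
    y = np.log(fa[keep] / (1 - fa[keep]))
    m, intercept = np.polyfit(x, y, 1)
    return MedianEffectFit(m=float(m), dm=float(math.exp(-intercept / m)))


def hsa_score(matrix: DoseResponseMatrix) -> float:
    """Mean excess over the highest single agent, in percentage points."""
    ref = np.maximum.outer(matrix.mono_a, matrix.mono_b)
    return float((matrix.inhibition - ref).mean() * 100)


def loewe_expected(
    conc_a: float, conc_b: float, fit_a: FourPLFit, fit_b: FourPLFit,
    tol: float = 1e-8,
) -> float:
    """Loewe-additive expected effect at a dose pair.

    Solves d_a/D_a(y) + d_b/D_b(y) = 1 by bracketed root finding on the
    effect range both fits can attain; dose pairs beyond that range are
    clipped to its edge.
    """
    lo = max(fit_a.bottom, fit_b.bottom)
    hi = min(fit_a.top, fit_b.top)
    if hi <= lo:
        raise ValidationError("single-agent fits have no common effect range")
    eps = (hi - lo) * 1e-12

    def g(y: float) -> float:
        da, db = fit_a.inverse(y), fit_b.inverse(y)
        return conc_a / da + conc_b / db - 1.0

    y_lo, y_hi = lo + eps, hi - eps
    if g(y_hi) > 0:   # doses exceed the attainable range: clip to ceiling
        return y_hi
    if g(y_lo) < 0:   # doses below the attainable floor
        return y_lo
    return float(brentq(g, y_lo, y_hi, xtol=tol))


def loewe_score(
    matrix: DoseResponseMatrix, fit_a: FourPLFit, fit_b: FourPLFit
) -> float:
    """Mean observed-minus-Loewe-expected effect, in percentage points.

    Cells where the additive reference is unattainable are excluded with a
    warning rather than failing the whole matrix.
    """
    excess = []
    n_excluded = 0
    for i, ca in enumerate(matrix.conc_a):
        for j, cb in enumerate(matrix.conc_b):
            try:
                expected = loewe_expected(ca, cb, fit_a, fit_b)
            except (ValidationError, ValueError):
                n_excluded += 1
                continue
            excess.append(matrix.inhibition[i, j] - expected)
    if n_excluded:
        logger.warning("Loewe reference unattainable for %d cell(s)", n_excluded)
    if not excess:
        raise ValidationError("no cells with an attainable Loewe reference")
    return float(np.mean(excess) * 100)


def combination_index_at_effect(
    matrix: DoseResponseMatrix,
    effect: float = 0.75,
    fit_a: MedianEffectFit | None = None,
    fit_b: MedianEffectFit | None = None,
) -> tuple[float, bool]:
    """Chou-Talalay combination index interpolated at an effect level.

    Median-effect fits come from the single-agent edges unless supplied.
    Each matrix cell with 0 < fa < 1 yields CI(fa) = d_a/D_a(fa) +
    d_b/D_b(fa); CI values are then interpolated against observed fa at the
    requested ``effect`` (EC75 by default).  Returns ``(ci, extrapolated)``
    — when no observed fa brackets the effect level, the CI of the nearest
    fa is returned and flagged.
    """
    if fit_a is None:
        fit_a = median_effect_fit(matrix.conc_a, matrix.mono_a)
    if fit_b is None:
        fit_b = median_effect_fit(matrix.conc_b, matrix.mono_b)

    fas, cis = [], []
    for i, ca in enumerate(matrix.conc_a):
        for j, cb in enumerate(matrix.conc_b):
            fa = matrix.inhibition[i, j]
            if not 0 < fa < 1:
                continue
            ci = ca / fit_a.dose_at(fa) + cb / fit_b.dose_at(fa)
            fas.append(fa)
            cis.append(ci)
    if not fas:
        raise ValidationError("no matrix cells with 0 < fa < 1")
    df = pd.DataFrame({"fa": fas, "ci": cis}).groupby("fa")["ci"].mean()
    fa_grid = df.index.to_numpy()
    ci_grid = df.to_numpy()
    if effect < fa_grid[0] or effect > fa_grid[-1]:
        nearest = int(np.argmin(np.abs(fa_grid - effect)))
        logger.warning(
            "effect level %.2f outside observed fa range [%.3f, %.3f]; "
            "returning nearest-fa CI",
            effect, fa_grid[0], fa_grid[-1],
        )
        return float(ci_grid[nearest]), True
    return float(np.interp(effect, fa_grid, ci_grid)), False


@dataclass
class SynergyReport:
    loewe_score: float
    hsa_score: float
    ci_at_75: float
    ci_extrapolated: bool
    calls: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "loewe_score": self.loewe_score,
            "hsa_score": self.hsa_score,
            "ci_at_75": self.ci_at_75,
            "ci_extrapolated": self.ci_extrapolated,
            **{f"synergistic_{k}": v for k, v in self.calls.items()},
        }


def score_matrix(
    matrix: DoseResponseMatrix,
    fit_a: FourPLFit | None = None,
    fit_b: FourPLFit | None = None,
) -> SynergyReport:
    """All three metrics plus threshold calls for one dose matrix.

    4PL fits of the single-agent edges are computed here unless supplied.
    """
    if fit_a is None:
        fit_a = fit_four_parameter_logistic(matrix.conc_a, matrix.mono_a)
    if fit_b is None:
        fit_b = fit_four_parameter_logistic(matrix.conc_b, matrix.mono_b)
    loewe = loewe_score(matrix, fit_a, fit_b)
    hsa = hsa_score(matrix)
    ci, extrapolated = combination_index_at_effect(matrix)
    return SynergyReport(
        loewe_score=loewe,
        hsa_score=hsa,
        ci_at_75=ci,
        ci_extrapolated=extrapolated,
        calls={
            "loewe": loewe > LOEWE_SYNERGY_THRESHOLD,
            "hsa": hsa > HSA_SYNERGY_THRESHOLD,
            "ci": ci < CI_SYNERGY_THRESHOLD,
        },
    )


def read_dose_matrix(path) -> DoseResponseMatrix:
    """Read a checkerboard CSV: first row/column hold molar concentrations,
    with a zero-dose row and column carrying the single-agent edges; the
    (0, 0) cell is the vehicle control (must be 0)."""
    raw = pd.read_csv(path, header=None).to_numpy(dtype=float)
    conc_a = raw[1:, 0]
    conc_b = raw[0, 1:]
    body = raw[1:, 1:]
    if conc_a[0] != 0 or conc_b[0] != 0:
        raise ValidationError(
            f"{path}: dose matrix must include a zero-dose row and column "
            "holding the single-agent edges"
        )
    return DoseResponseMatrix(
        conc_a=conc_a[1:],
        conc_b=conc_b[1:],
        inhibition=body[1:, 1:],
        mono_a=body[1:, 0],
        mono_b=body[0, 1:],
    )


def write_dose_matrix(matrix: DoseResponseMatrix, path) -> None:
    a, b = len(matrix.conc_a), len(matrix.conc_b)
    grid = np.zeros((a + 2, b + 2))
    grid[2:, 0] = matrix.conc_a
    grid[0, 2:] = matrix.conc_b
    grid[2:, 1] = matrix.mono_a
    grid[1, 2:] = matrix.mono_b
    grid[2:, 2:] = matrix.inhibition
    pd.DataFrame(grid).to_csv(path, header=False, index=False)
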