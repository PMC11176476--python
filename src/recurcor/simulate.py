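"""Synthetic multi-dataset screens with planted shared-vulnerability structure.

The generator emulates the shape of the public monotherapy screens this
package consumes: several datasets with overlapping but non-identical
cell-line panels, each reporting AUC on its own native scale, with drugs
organized into mechanism classes.  Cell lines carry latent *vulnerability
factors*; a drug's AUC is

    AUC(drug, line) = baseline(drug) - loading * factor(class(drug), line)
                      + Gaussian noise,

so drugs whose classes load on a common factor have correlated responses
across lines (the planted "shared vulnerability"), while classes on
independent factors are null.  Lower AUC means more sensitive, so the factor
enters negatively for vulnerable lines; rank statistics downstream are
unaffected by the sign or by the per-dataset affine rescaling applied to
emulate native AUC scales.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import ClassMap, class_pair_key
from .errors import ConfigurationError
from .io import AUCTable, LineageMap
from .synergy import (
    ComboScreenTable,
    DoseResponseMatrix,
    FourPLFit,
    loewe_expected,
)

_LINEAGES = ("lung", "breast", "prostate", "colon", "skin")


@dataclass(frozen=True)
class ClassSpec:
    """One drug class in the simulation: code, size, latent factor, loading."""

    code: str
    n_drugs: int = 5
    factor: str = "independent"
    loading: float = 1.0


def default_classes() -> list[ClassSpec]:
    """Six classes of five drugs: a PARPi-like / AurKi-like pair planted on a
    shared vulnerability factor, plus four null classes on private factors."""
    return [
        ClassSpec("L01XK", 5, "shared_1", 1.0),   # PARP-inhibitor-like
        ClassSpec("L01EZ", 5, "shared_1", 1.0),   # Aurora-kinase-like (non-canonical code)
        ClassSpec("L01EA", 5, "f_L01EA", 1.0),
        ClassSpec("L01EB", 5, "f_L01EB", 1.0),
        ClassSpec("L01EF", 5, "f_L01EF", 1.0),
        ClassSpec("L01EG", 5, "f_L01EG", 1.0),
    ]


@dataclass
class SimConfig:
    """Study conditions for one simulated multi-screen experiment.

    Defaults: 3 datasets of 40 cell lines drawn from a common pool with 75%
    panel overlap, 6 classes of 5 drugs with the planted pair loading on one
    shared factor at loading 1, and response noise of 0.3 on the factor
    scale.
    """

    n_datasets: int = 3
    classes: list[ClassSpec] = field(default_factory=default_classes)
    n_cell_lines: int = 40
    panel_overlap: float = 0.75
    noise_sd: float = 0.3
    n_hematological: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 2:
            raise ConfigurationError("need >= 2 datasets")
        if not 0 <= self.panel_overlap <= 1:
            raise ConfigurationError("panel_overlap must be in [0, 1]")
        if self.n_cell_lines < 2 or any(c.n_drugs < 1 for c in self.classes):
            raise ConfigurationError("counts must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def shared_factor_pairs(self) -> list[str]:
        """Ground-truth cross-class pairs whose classes share a factor."""
        keys = set()
        for i, a in enumerate(self.classes):
            for b in self.classes[i + 1 :]:
                if a.factor == b.factor:
                    keys.add(class_pair_key(a.code, b.code).key)
        return sorted(keys)


@dataclass
class SimTruth:
    planted_class_pairs: list[str]
    drug_factors: dict[str, str]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def generate_monotherapy_datasets(
    config: SimConfig,
) -> tuple[list[AUCTable], ClassMap, LineageMap, SimTruth]:
    """Draw one multi-dataset screen under the configured conditions.

    The cell-line pool size is ``n_cell_lines * (1 + (1-overlap)*(k-1))``
    and each dataset samples its panel from the pool without replacement, so
    overlap 1 gives identical panels and overlap 0 near-disjoint ones.
    Hematological lines, if requested, are appended to the pool so that the
    preparation step has something to remove.
    """
    rng = np.random.default_rng(config.seed)
    pool_n = max(
        config.n_cell_lines,
        round(
            config.n_cell_lines
            * (1 + (1 - config.panel_overlap) * (config.n_datasets - 1))
        ),
    )
    if pool_n < config.n_cell_lines:
        raise ConfigurationError("infeasible overlap/panel size")
    pool = [f"CL{i:04d}" for i in range(pool_n + config.n_hematological)]
    lineages = {
        cl: (
            "hematological"
            if i >= pool_n
            else _LINEAGES[i % len(_LINEAGES)]
        )
        for i, cl in enumerate(pool)
    }

    factor_ids = sorted({c.factor for c in config.classes})
    factors = {f: rng.standard_normal(len(pool)) for f in factor_ids}

    drugs: list[tuple[str, ClassSpec]] = []
    for spec in config.classes:
        for i in range(spec.n_drugs):
            drugs.append((f"{spec.code}_d{i + 1}", spec))
    baselines = {name: rng.uniform(4.0, 8.0) for name, _ in drugs}

    cell_index = {cl: i for i, cl in enumerate(pool)}
    tables = []
    for d in range(config.n_datasets):
        panel = sorted(
            rng.choice(pool, size=config.n_cell_lines, replace=False).tolist()
        )
        # per-dataset affine rescaling emulates native AUC scales; it is
        # rank-preserving so downstream statistics are unchanged
        scale = 1.0 + 0.3 * d
        offset = 0.5 * d
        rows = []
        for name, spec in drugs:
            fvals = factors[spec.factor]
            for cl in panel:
                raw = (
                    baselines[name]
                    - spec.loading * fvals[cell_index[cl]]
                    + rng.normal(0.0, config.noise_sd)
                )
                rows.append((name, cl, offset + scale * raw))
        df = pd.DataFrame(rows, columns=["drug", "cell_line", "auc"])
        tables.append(AUCTable(dataset_id=f"DS{d + 1}", df=df))

    class_map = ClassMap(
        assignments={name: spec.code for name, spec in drugs},
        class_labels={c.code: f"simulated class {c.code}" for c in config.classes},
        class_flags={
            c.code: {"targeted": True, "pathway_group": c.code}
            for c in config.classes
        },
    )
    truth = SimTruth(
        planted_class_pairs=config.shared_factor_pairs,
        drug_factors={name: spec.factor for name, spec in drugs},
        seed=config.seed,
    )
    return tables, class_map, LineageMap(entries=lineages), truth


def generate_dose_matrix(
    fit_a: FourPLFit,
    fit_b: FourPLFit,
    model: str = "loewe_additive",
    conc_a=None,
    conc_b=None,
    noise_sd: float = 0.0,
    boost: float = 0.0,
    seed: int | None = None,
) -> DoseResponseMatrix:
    """Checkerboard surface generated under a named reference model.

    ``model`` is ``loewe_additive`` (the Loewe equation applied to the two
    fits) or ``hsa_null`` (the better single agent); ``boost`` adds a
    constant excess to every combination cell, giving surfaces with known
    synergy scores.  Default grids follow an 8 x 5 checkerboard of 1:5
    serial dilutions from 8 uM and 1.6 uM tops.
    """
    if conc_a is None:
        conc_a = 8e-6 / 5.0 ** np.arange(7, -1, -1)
    if conc_b is None:
        conc_b = 1.6e-6 / 5.0 ** np.arange(4, -1, -1)
    conc_a = np.asarray(conc_a, dtype=float)
    conc_b = np.asarray(conc_b, dtype=float)

    mono_a = fit_a.predict(conc_a)
    mono_b = fit_b.predict(conc_b)
    inhibition = np.empty((len(conc_a), len(conc_b)))
    for i, ca in enumerate(conc_a):
        for j, cb in enumerate(conc_b):
            if model == "loewe_additive":
                inhibition[i, j] = loewe_expected(ca, cb, fit_a, fit_b)
            elif model == "hsa_null":
                inhibition[i, j] = max(mono_a[i], mono_b[j])
            else:
                raise ConfigurationError(f"unknown reference model {model!r}")
    inhibition += boost
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inhibition = inhibition + rng.normal(0.0, noise_sd, inhibition.shape)
    return DoseResponseMatrix(
        conc_a=conc_a,
        conc_b=conc_b,
        inhibition=inhibition,
        mono_a=mono_a,
        mono_b=mono_b,
    )


def generate_combo_screen(
    class_map: ClassMap,
    synergistic_class_pairs,
    n_cell_lines: int = 10,
    score_sd: float = 3.0,
    synergy_excess: float = 15.0,
    seed: int = 0,
) -> ComboScreenTable:
    """Combinatorial-screen table with planted class-level synergy.

    Every cross-class drug pair from the class map is scored in every cell
    line with Gaussian null scores; pairs belonging to
    ``synergistic_class_pairs`` get ``synergy_excess`` added in one cell
    line, so they exceed a high percentile cutoff while null pairs rarely
    do.
    """
    rng = np.random.default_rng(seed)
    synergistic = set(synergistic_class_pairs)
    drugs = sorted(class_map.assignments)
    lines = [f"VCL{i:02d}" for i in range(n_cell_lines)]
    rows = []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1 :]:
            ca, cb = class_map.code_of(a), class_map.code_of(b)
            if ca == cb:
                continue
            key = class_pair_key(ca, cb, class_map).key
            scores = rng.normal(0.0, score_sd, n_cell_lines)
            if key in synergistic:
                scores[rng.integers(n_cell_lines)] += synergy_excess
            rows.extend(
                (a, b, cl, s) for cl, s in zip(lines, scores)
            )
    return ComboScreenTable(
        pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line", "loewe_score"])
    )
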