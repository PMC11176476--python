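"""End-to-end orchestration: prepare -> correlate -> recurrence -> annotate
-> enrich -> prune/cluster -> export, plus the screen-level validation
workflow.

The analytical pipeline is fully deterministic: identical inputs and
parameters produce identical artifacts, and the run manifest records the
parameters, per-stage counts and artifact checksums needed to verify that.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation import ClassMap, annotate_pair_sets
from .cluster import (
    build_class_pvalue_matrix,
    export_heatmap,
    fraction_correlated_matrix,
    hierarchical_order,
    linkage_to_newick,
    prune_to_complete,
)
from .correlation import (
    DEFAULT_MIN_DATASETS,
    DEFAULT_MIN_SHARED,
    DEFAULT_RHO_MIN,
    build_dcscad,
    correlate_all,
    correlations_frame,
    enumerate_eligible_pairs,
    summaries_frame,
)
from .enrichment import enrichment_frame, run_enrichment, significant
from .errors import RecurcorError, ValidationError
from .io import AUCTable, LineageMap, prepare_datasets
from .synergy import ComboScreenTable, call_synergy, percentile_cutoff

logger = logging.getLogger(__name__)


@dataclass
class RunParameters:
    rho_min: float = DEFAULT_RHO_MIN
    min_shared: int = DEFAULT_MIN_SHARED
    min_datasets: int = DEFAULT_MIN_DATASETS
    alpha: float = 0.05
    drop_classes: tuple[str, ...] = ()


@dataclass
class AnalysisResult:
    """In-memory artifacts of one full run."""

    parameters: RunParameters
    prepared: list
    eligible: dict
    correlations: list
    summaries: list
    background: object
    foreground: object
    records: list
    matrix: object
    pruned: object
    ordering: list
    linkage: object
    manifest: dict = field(default_factory=dict)

    @property
    def significant(self):
        return significant(self.records, self.parameters.alpha)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, RecurcorError):
                exc.args = (f"[stage {name}] {exc.args[0]}",) + exc.args[1:]
            return False

    return _ctx()


def run_analysis(
    tables: list[AUCTable],
    class_map: ClassMap,
    lineage_map: LineageMap,
    parameters: RunParameters | None = None,
) -> AnalysisResult:
    """Execute all analysis stages on in-memory tables.

    Stage errors propagate annotated with the stage name.  A threshold that
    empties the recurrent set yields an empty (but well-formed) result, not
    an error.
    """
    p = parameters or RunParameters()
    with _stage("prepare"):
        prepared = prepare_datasets(tables, lineage_map)
    with _stage("eligibility"):
        eligible = enumerate_eligible_pairs(
            prepared, min_shared=p.min_shared, min_datasets=p.min_datasets
        )
    with _stage("correlate"):
        correlations = correlate_all(prepared, eligible)
    with _stage("recurrence"):
        summaries = build_dcscad(
            correlations, rho_min=p.rho_min, min_datasets=p.min_datasets
        )
    with _stage("annotate"):
        background, foreground = annotate_pair_sets(summaries, class_map)
    with _stage("enrich"):
        records = run_enrichment(background, foreground, alpha=p.alpha)
    with _stage("cluster"):
        matrix = build_class_pvalue_matrix(records, set(background["class_key"]))
        if len(matrix.classes) >= 2:
            pruned = prune_to_complete(matrix, drop_classes=p.drop_classes)
            ordering, Z = hierarchical_order(pruned)
        else:
            pruned, ordering, Z = matrix, list(matrix.classes), None

    result = AnalysisResult(
        parameters=p,
        prepared=prepared,
        eligible=eligible,
        correlations=correlations,
        summaries=summaries,
        background=background,
        foreground=foreground,
        records=records,
        matrix=matrix,
        pruned=pruned,
        ordering=ordering,
        linkage=Z,
    )
    result.manifest = _build_manifest(result)
    return result


def _build_manifest(result: AnalysisResult) -> dict:
    p = result.parameters
    return {
        "version": __version__,
        "parameters": {
            "rho_min": p.rho_min,
            "min_shared": p.min_shared,
            "min_datasets": p.min_datasets,
            "alpha": p.alpha,
            "drop_classes": list(p.drop_classes),
        },
        "stages": {
            "datasets": len(result.prepared),
            "prepared_counts": [t.counts() for t in result.prepared],
            "eligible_pairs": {k: len(v) for k, v in sorted(result.eligible.items())},
            "correlations": len(result.correlations),
            "pairs_tested": len(result.summaries),
            "dcscad_size": sum(s.in_dcscad for s in result.summaries),
            "sign_conflicts": sum(s.sign_conflict for s in result.summaries),
            "class_pairs_tested": len(result.records),
            "significant": len(result.significant),
            "matrix_classes": len(result.matrix.classes),
            "pruned_classes": len(result.pruned.classes),
        },
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_artifacts(result: AnalysisResult, outdir, class_map: ClassMap) -> dict:
    """Write all tables, the heatmap and the manifest under ``outdir``.

    Returns the manifest (also written as ``manifest.json``) including
    sha256 checksums of every text artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    correlations_frame(result.correlations).to_csv(
        outdir / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    paths["correlations"] = outdir / "correlations.tsv"
    summaries_frame(result.summaries).to_csv(
        outdir / "pair_summaries.tsv", sep="\t", index=False, float_format="%.6g"
    )
    paths["pair_summaries"] = outdir / "pair_summaries.tsv"
    enrichment_frame(result.records, class_map).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )
    paths["enrichment"] = outdir / "enrichment.tsv"

    if len(result.pruned.classes) >= 2:
        exported = export_heatmap(
            result.pruned, result.ordering, outdir / "class_matrix"
        )
        paths["class_matrix"] = Path(exported["tsv"])
        if result.linkage is not None:
            (outdir / "class_dendrogram.nwk").write_text(
                linkage_to_newick(result.linkage, result.pruned.classes) + "\n"
            )
            paths["class_dendrogram"] = outdir / "class_dendrogram.nwk"

    dcscad_drugs = sorted({d for s in result.summaries if s.in_dcscad for d in s.pair})
    if dcscad_drugs:
        frac, _ = fraction_correlated_matrix(result.summaries, dcscad_drugs, class_map)
        frac.to_csv(outdir / "fraction_correlated.tsv", sep="\t", na_rep="NA",
                    float_format="%.6g")
        paths["fraction_correlated"] = outdir / "fraction_correlated.tsv"

    manifest = dict(result.manifest)
    manifest["artifacts"] = {
        name: {"path": str(p.name), "sha256": _sha256(p)} for name, p in paths.items()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


@dataclass
class ValidationReport:
    cutoff: float
    n_screen_pairs: int
    n_evaluated_class_pairs: int
    n_synergistic_class_pairs: int
    fraction_synergistic: float | None
    per_class: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_screen_pairs": self.n_screen_pairs,
            "n_evaluated_class_pairs": self.n_evaluated_class_pairs,
            "n_synergistic_class_pairs": self.n_synergistic_class_pairs,
            "fraction_synergistic": self.fraction_synergistic,
            "per_class": self.per_class,
        }


def run_validation(
    screen: ComboScreenTable,
    class_map: ClassMap,
    identified_class_pairs,
    percentile: float = 90.0,
) -> ValidationReport:
    """Screen-level validation of identified class combinations.

    The synergy cutoff is the given percentile of all screen scores; class
    combinations among ``identified_class_pairs`` that are evaluable in the
    screen are called synergistic when any member pair exceeds the cutoff in
    any cell line.
    """
    screen_drugs = set(screen.df["drug_a"]) | set(screen.df["drug_b"])
    if not screen_drugs & set(class_map.assignments):
        raise ValidationError(
            "no overlap between screen drugs and annotated drug universe"
        )
    cutoff = percentile_cutoff(screen.scores, percentile)
    calls = call_synergy(screen, cutoff, class_map, identified_class_pairs)
    evaluated = calls.evaluated_class_pairs
    per_class = {k: bool(calls.class_calls[k]) for k in evaluated}
    return ValidationReport(
        cutoff=cutoff,
        n_screen_pairs=int(len(calls.pair_calls)),
        n_evaluated_class_pairs=len(evaluated),
        n_synergistic_class_pairs=int(sum(per_class.values())),
        fraction_synergistic=calls.fraction_synergistic,
        per_class=per_class,
    )
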