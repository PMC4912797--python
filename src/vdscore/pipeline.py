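"""End-to-end analysis of a cohort CSV.

Runs, in order: the descriptive stratified summary, LOWESS curves of each
severity index against 25OHD, the two multivariable logistic models, the five
prediction scores' ROC/AUC (DCCI, DCCI + 25OHD, APACHE II, APACHE II + 25OHD,
and the 25OHD category sub-score alone), the five pairwise AUC equality tests
of interest, and the Youden-optimal cut-point for every score. Results are
returned as one structured report and optionally serialized to JSON plus TSV
tables.

The "25OHD alone" predictor is the category sub-score (0-3 under the initial
assignment), not the raw level: the score is the object being evaluated, and
its cut-points live on the sub-score scale (a cutoff of >=3 means
"25OHD < 10 ng/mL"). AUC comparisons are reported unadjusted for
multiplicity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort  # noqa: F401 (re-export)
from .cutpoint import CutpointResult, optimal_cutpoint
from .errors import DegenerateInputError, PipelineError
from .lowess import LowessFit, lowess_fit
from .logistic import APACHE_SPEC, DCCI_SPEC, fit, or_table
from .roc_delong import AUCResult, PairedAUCTest, auc, delong_compare
from .score_augment import (
    COLLAPSED_ASSIGNMENT,
    INITIAL_ASSIGNMENT,
    ScoreAssignment,
    augment_scores,
    search_best,
)
from .synthetic_cohort import CohortSummary, summarize_cohort

log = logging.getLogger(__name__)

ASSIGNMENT_MODES = ("initial_0123", "collapsed_0113", "search")

#: Score names in report order.
SCORE_NAMES = ("dcci", "dcci_25ohd", "apache_ii", "apache_25ohd", "vitd_25ohd_subscore")

#: The pairwise AUC equality tests reported by the analysis.
COMPARISONS = (
    ("dcci", "dcci_25ohd"),
    ("apache_ii", "apache_25ohd"),
    ("dcci_25ohd", "apache_25ohd"),
    ("dcci_25ohd", "apache_ii"),
    ("vitd_25ohd_subscore", "dcci_25ohd"),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run."""

    cohort_path: str
    assignment_mode: str = "initial_0123"
    max_sub: int = 6
    anchor_top_zero: bool = True
    monotone: bool = True
    lowess_span: float = 2.0 / 3.0
    lowess_robust_iter: int = 3
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.assignment_mode not in ASSIGNMENT_MODES:
            raise ValueError(
                f"assignment_mode must be one of {ASSIGNMENT_MODES}, "
                f"got {self.assignment_mode!r}"
            )


@dataclass
class AnalysisReport:
    summary: CohortSummary
    or_tables: dict                 # model name -> DataFrame
    assignments: dict               # base score -> ScoreAssignment used
    search_results: dict            # base score -> AugmentationSearchResult (search mode)
    aucs: dict                      # score name -> AUCResult
    comparisons: dict               # "a_vs_b" -> PairedAUCTest
    cutpoints: dict                 # score name -> CutpointResult
    lowess: dict                    # index name -> LowessFit
    provenance: dict = field(default_factory=dict)


def _stage(name):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with the stage label
                raise PipelineError(name, exc) from exc
        return wrapped
    return decorator


def _resolve_assignments(cohort, mode, max_sub, anchor, monotone):
    if mode == "initial_0123":
        a = INITIAL_ASSIGNMENT
        return {"dcci": a, "apache_ii": a, "vitd_25ohd_subscore": a}, {}
    if mode == "collapsed_0113":
        a = COLLAPSED_ASSIGNMENT
        return {"dcci": a, "apache_ii": a, "vitd_25ohd_subscore": a}, {}
    # exhaustive search per base index; the standalone 25OHD sub-score keeps
    # the initial categorical scale
    labels = cohort.column("death90")
    levels = cohort.column("vitd_25ohd")
    results = {}
    assignments = {"vitd_25ohd_subscore": INITIAL_ASSIGNMENT}
    for base in ("dcci", "apache_ii"):
        results[base] = search_best(
            cohort.column(base), levels, labels,
            max_sub=max_sub, anchor_top_zero=anchor, monotone=monotone,
        )
        assignments[base] = results[base].best_assignment
    return assignments, results


def analyze_cohort(
    cohort: Cohort,
    assignment_mode: str = "initial_0123",
    max_sub: int = 6,
    anchor_top_zero: bool = True,
    monotone: bool = True,
    lowess_span: float = 2.0 / 3.0,
    lowess_robust_iter: int = 3,
    seed: int = 0,
) -> AnalysisReport:
    """Run the full analysis on an in-memory cohort.

    Deterministic given (cohort, arguments): nothing downstream of the
    cohort draws randomness; ``seed`` is recorded in the provenance block
    for resampling diagnostics run by callers.
    """
    labels = cohort.column("death90")
    if len(cohort) == 0 or labels.sum() in (0, len(cohort)):
        raise PipelineError("input", DegenerateInputError(
            "cohort must contain both survivors and non-survivors"))

    summary = _stage("summary")(summarize_cohort)(cohort)

    levels = cohort.column("vitd_25ohd")

    @_stage("lowess")
    def _lowess():
        return {
            "dcci": lowess_fit(levels, cohort.column("dcci"),
                               span=lowess_span, robust_iter=lowess_robust_iter),
            "apache_ii": lowess_fit(levels, cohort.column("apache_ii"),
                                    span=lowess_span, robust_iter=lowess_robust_iter),
        }

    lowess_curves = _lowess()

    @_stage("logistic")
    def _logistic():
        return {
            "dcci_model": or_table(fit(DCCI_SPEC, cohort)),
            "apache_model": or_table(fit(APACHE_SPEC, cohort)),
        }

    or_tables = _logistic()

    @_stage("augmentation")
    def _assignments():
        return _resolve_assignments(cohort, assignment_mode, max_sub,
                                    anchor_top_zero, monotone)

    assignments, search_results = _assignments()

    @_stage("roc")
    def _scores_and_aucs():
        scores = {
            "dcci": cohort.column("dcci").astype(float),
            "apache_ii": cohort.column("apache_ii").astype(float),
            "dcci_25ohd": augment_scores(cohort.column("dcci"), levels,
                                         assignments["dcci"]).astype(float),
            "apache_25ohd": augment_scores(cohort.column("apache_ii"), levels,
                                           assignments["apache_ii"]).astype(float),
            "vitd_25ohd_subscore": augment_scores(
                np.zeros(len(cohort), dtype=int), levels,
                assignments["vitd_25ohd_subscore"]).astype(float),
        }
        aucs = {name: auc(scores[name], labels) for name in SCORE_NAMES}
        return scores, aucs

    scores, aucs = _scores_and_aucs()

    @_stage("auc_comparison")
    def _comparisons():
        out = {}
        for a, b in COMPARISONS:
            out[f"{a}_vs_{b}"] = delong_compare(scores[a], scores[b], labels)
        return out

    comparisons = _comparisons()

    cutpoints = _stage("cutpoint")(
        lambda: {name: optimal_cutpoint(scores[name], labels) for name in SCORE_NAMES}
    )()

    provenance = {
        "package": "vdscore",
        "version": __version__,
        "seed": seed,
        "cohort_label": cohort.label,
        "n": len(cohort),
        "dropped_rows": cohort.dropped_rows,
        "assignment_mode": assignment_mode,
        "max_sub": max_sub,
        "anchor_top_zero": anchor_top_zero,
        "monotone": monotone,
        "lowess_span": lowess_span,
        "lowess_robust_iter": lowess_robust_iter,
        "note": "AUC comparisons are unadjusted for multiplicity",
    }
    return AnalysisReport(
        summary=summary,
        or_tables=or_tables,
        assignments=assignments,
        search_results=search_results,
        aucs=aucs,
        comparisons=comparisons,
        cutpoints=cutpoints,
        lowess=lowess_curves,
        provenance=provenance,
    )


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Read the cohort CSV, analyze it, and (optionally) write the outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cohort = _stage("read_cohort")(read_cohort)(config.cohort_path)
    report = analyze_cohort(
        cohort,
        assignment_mode=config.assignment_mode,
        max_sub=config.max_sub,
        anchor_top_zero=config.anchor_top_zero,
        monotone=config.monotone,
        lowess_span=config.lowess_span,
        lowess_robust_iter=config.lowess_robust_iter,
        seed=config.seed,
    )
    report.provenance["config"] = dataclasses.asdict(config)
    if config.out_dir is not None:
        _stage("write_outputs")(write_report)(report, config.out_dir)
    return report


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def report_to_dict(report: AnalysisReport) -> dict:
    """JSON-safe nested dict of the full report (deterministic layout)."""

    def auc_d(r: AUCResult):
        return {"auc": r.auc, "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high}

    def test_d(t: PairedAUCTest):
        return {"auc_a": t.auc_a, "auc_b": t.auc_b, "delta": t.delta,
                "chi2": t.chi2, "df": t.df, "p": t.p}

    def cut_d(c: CutpointResult):
        return {"cutoff": c.cutoff, "sensitivity": c.sensitivity,
                "specificity": c.specificity, "accuracy": c.accuracy,
                "youden_sum": c.youden_sum}

    out = {
        "provenance": report.provenance,
        "summary": report.summary.to_frame().to_dict(orient="records"),
        "or_tables": {k: v.to_dict(orient="records") for k, v in report.or_tables.items()},
        "assignments": {k: list(v.sub_scores) for k, v in report.assignments.items()},
        "aucs": {k: auc_d(v) for k, v in report.aucs.items()},
        "comparisons": {k: test_d(v) for k, v in report.comparisons.items()},
        "cutpoints": {k: cut_d(v) for k, v in report.cutpoints.items()},
    }
    if report.search_results:
        out["search"] = {
            base: {
                "best_assignment": list(r.best_assignment.sub_scores),
                "best_auc": auc_d(r.best_auc),
                "n_evaluated": r.n_evaluated,
            }
            for base, r in report.search_results.items()
        }
    return out


def write_report(report: AnalysisReport, out_dir) -> None:
    """Write report.json plus TSV tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
    )
    report.summary.to_frame().to_csv(out / "table1.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"model": k, **vars(v)} for k, v in report.aucs.items()]
    ).to_csv(out / "auc.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"model": k, **vars(v)} for k, v in report.cutpoints.items()]
    ).to_csv(out / "cutpoints.tsv", sep="\t", index=False)
    for base, fname in (("dcci", "lowess_dcci.tsv"), ("apache_ii", "lowess_apache.tsv")):
        curve: LowessFit = report.lowess[base]
        pd.DataFrame({"vitd_25ohd": curve.x_sorted, "fitted": curve.fitted}).to_csv(
            out / fname, sep="\t", index=False
        )
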