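"""Scoring enrichment results against the known knocked-out pathway.

In each knockout scenario the knocked-out ("target") pathway is a true
positive if significantly enriched (p <= alpha) and a false negative
otherwise; under ORA a non-testable target is kept apart as "not run"
rather than being folded into the FNs.  Every other pathway of the tested
universe is a false positive if significant and a true negative otherwise
(non-testable non-targets count as TN: they were not detected as enriched).

Aggregation follows the benchmark's conventions: TPR / FNR / not-run rate
are proportions of scenarios (they sum to 1 exactly), while FPR and TNR are
the *average counts* of FP and TN pathways per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrich import ORA, EnrichmentResult

__all__ = [
    "ScenarioOutcome",
    "EvaluationSummary",
    "classify_scenario",
    "aggregate",
    "conditional_tpr",
    "TP", "FN", "NOT_RUN",
]

TP = "TP"
FN = "FN"
NOT_RUN = "not_run"


@dataclass(frozen=True)
class ScenarioOutcome:
    scenario: str
    method: str
    target_label: str  # TP | FN | not_run
    fp_count: int
    tn_count: int
    tested_pathway_count: int


@dataclass(frozen=True)
class EvaluationSummary:
    method: str
    n_scenarios: int
    tpr: float
    fnr: float
    not_run_rate: float
    fpr: float  # mean FP count per scenario
    tnr: float  # mean TN count per scenario


def classify_scenario(
    scenario: str, result: EnrichmentResult, alpha: float = 0.05
) -> ScenarioOutcome:
    """Label the target pathway and count FP/TN among the others."""
    if scenario not in result.per_pathway:
        raise KeyError(f"target pathway {scenario!r} absent from result universe")
    target = result.per_pathway[scenario]
    if not target.testable:
        # ORA's min-hits filter keeps the target out of the test entirely;
        # for GSEA an untestable target simply cannot be detected.
        label = NOT_RUN if result.method == ORA else FN
    elif target.p_value <= alpha:
        label = TP
    else:
        label = FN
    fp = tn = 0
    for pid, rec in result.per_pathway.items():
        if pid == scenario:
            continue
        if rec.testable and rec.p_value is not None and rec.p_value <= alpha:
            fp += 1
        else:
            tn += 1
    return ScenarioOutcome(
        scenario=scenario,
        method=result.method,
        target_label=label,
        fp_count=fp,
        tn_count=tn,
        tested_pathway_count=len(result.per_pathway),
    )


def aggregate(outcomes: list[ScenarioOutcome]) -> EvaluationSummary:
    """Average the per-scenario outcomes of one method into summary rates."""
    if not outcomes:
        raise ValueError("no outcomes to aggregate")
    methods = {o.method for o in outcomes}
    if len(methods) > 1:
        raise ValueError(f"mixed methods in outcomes: {sorted(methods)}")
    n = len(outcomes)
    labels = [o.target_label for o in outcomes]
    return EvaluationSummary(
        method=methods.pop(),
        n_scenarios=n,
        tpr=labels.count(TP) / n,
        fnr=labels.count(FN) / n,
        not_run_rate=labels.count(NOT_RUN) / n,
        fpr=float(np.mean([o.fp_count for o in outcomes])),
        tnr=float(np.mean([o.tn_count for o in outcomes])),
    )


def conditional_tpr(outcomes: list[ScenarioOutcome]) -> float | None:
    """TP / (TP + FN) over the scenarios whose target test actually ran."""
    tp = sum(o.target_label == TP for o in outcomes)
    fn = sum(o.target_label == FN for o in outcomes)
    if tp + fn == 0:
        return None
    return tp / (tp + fn)
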