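"""Growth/no-growth validation and gene essentiality screening.

Model predictions are binarized (growth iff the FBA optimum exceeds a
small threshold) and compared against observed growth conditions in a
confusion matrix.  Both plain accuracy and the geometric mean of
sensitivity and specificity are reported, together with Matthews'
correlation coefficient and the F-score.

Single-gene essentiality follows the GPR logic: deleting a gene disables
every reaction whose boolean rule evaluates false, and the knockout
growth rate is re-computed by FBA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .core import Medium, MetabolicModel, ModelError
from .fba import STATUS_OPTIMAL, FluxSolution, solve_fba

#: Growth rates above this (1/h) count as growth.
GROWTH_THRESHOLD = 1e-6


@dataclass
class GrowthCondition:
    condition_id: str
    medium: Medium
    observed_growth: bool
    description: str = ""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EssentialityResult:
    gene_id: str
    wild_type_growth: float
    knockout_growth: float
    classification: str  # "essential", "growth_reducing", "non_essential"


def classify_growth(mu: Optional[float], threshold: float = GROWTH_THRESHOLD,
                    status: str = STATUS_OPTIMAL) -> bool:
    """Binarize a growth simulation: growth iff optimal and mu > threshold."""
    if status != STATUS_OPTIMAL or mu is None:
        return False
    return mu > threshold


def evaluate_conditions(
    model: MetabolicModel,
    conditions: Sequence[GrowthCondition],
    threshold: float = GROWTH_THRESHOLD,
) -> Tuple[ConfusionMatrix, pd.DataFrame]:
    """FBA per condition, tallied against observations.

    Conditions whose medium references a missing exchange are recorded as
    evaluation errors and excluded from the tally (with a warning).
    """
    if not conditions:
        raise ValueError("no conditions given")
    rows = []
    tp = tn = fp = fn = 0
    for cond in conditions:
        try:
            sol = solve_fba(model, medium=cond.medium)
        except ModelError as exc:
            warnings.warn(
                f"condition {cond.condition_id}: {exc}; excluded from tally",
                stacklevel=2,
            )
            rows.append({
                "condition_id": cond.condition_id, "observed": cond.observed_growth,
                "predicted": None, "mu": math.nan, "error": str(exc),
            })
            continue
        predicted = classify_growth(
            sol.objective_value if sol.is_optimal else None,
            threshold, sol.status,
        )
        mu = sol.objective_value if sol.is_optimal else math.nan
        rows.append({
            "condition_id": cond.condition_id, "observed": cond.observed_growth,
            "predicted": predicted, "mu": mu, "error": "",
        })
        if predicted and cond.observed_growth:
            tp += 1
        elif predicted and not cond.observed_growth:
            fp += 1
        elif not predicted and cond.observed_growth:
            fn += 1
        else:
            tn += 1
    table = pd.DataFrame(rows, columns=["condition_id", "observed", "predicted",
                                        "mu", "error"])
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn), table


def confusion_metrics(cm: ConfusionMatrix) -> Dict[str, float]:
    """Accuracy, geometric mean, MCC and F1 from a confusion matrix.

    Undefined ratios (zero denominators) are reported as 0.0 and flagged
    in the ``undefined`` entry.
    """
    if cm.total <= 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def safe_div(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = safe_div(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = safe_div(cm.tn, cm.tn + cm.fp, "specificity")
    gmean = math.sqrt(sensitivity * specificity)
    mcc_den = math.sqrt(
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = safe_div(cm.tp * cm.tn - cm.fp * cm.fn, mcc_den, "mcc")
    f1 = safe_div(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")
    return {
        "accuracy": accuracy,
        "gmean": gmean,
        "mcc": mcc,
        "f1": f1,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "undefined": undefined,
    }


def knockout_growth(
    model: MetabolicModel, medium: Optional[Medium],
    deleted_genes: Iterable[str],
) -> FluxSolution:
    """FBA after disabling all reactions inactivated by a gene deletion set."""
    ko = model.copy()
    for rid in ko.inactive_reactions(deleted_genes):
        ko.set_bounds(rid, 0.0, 0.0)
    return solve_fba(ko, medium=medium)


def essentiality_screen(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    threshold_fraction: float = 0.01,
    genes: Optional[Sequence[str]] = None,
) -> List[EssentialityResult]:
    """Single-gene deletion screen.

    A gene is *essential* if knockout growth falls below
    ``threshold_fraction`` of wild type, *growth_reducing* if it falls
    below ``(1 - threshold_fraction)`` of wild type but above the
    essentiality cut, and *non_essential* otherwise.  The three classes
    partition the gene set.
    """
    wt = solve_fba(model, medium=medium)
    if not wt.is_optimal or wt.objective_value <= GROWTH_THRESHOLD:
        raise ValueError("wild type does not grow under the given medium")
    mu_wt = wt.objective_value
    results = []
    for gene in (genes if genes is not None else model.genes):
        sol = knockout_growth(model, medium, {gene})
        mu_ko = sol.objective_value if sol.is_optimal else 0.0
        mu_ko = max(mu_ko, 0.0)
        if mu_ko < threshold_fraction * mu_wt:
            label = "essential"
        elif mu_ko < (1.0 - threshold_fraction) * mu_wt:
            label = "growth_reducing"
        else:
            label = "non_essential"
        results.append(EssentialityResult(
            gene_id=gene, wild_type_growth=mu_wt, knockout_growth=mu_ko,
            classification=label,
        ))
    return results


def essentiality_summary(results: Sequence[EssentialityResult]) -> Dict[str, int]:
    counts = {"essential": 0, "growth_reducing": 0, "non_essential": 0}
    for r in results:
        counts[r.classification] += 1
    return counts
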