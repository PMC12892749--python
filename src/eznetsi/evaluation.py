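"""Diagnostic evaluation of localization against the resection/Engel
reference standard.

A patient is a true positive when the predicted epileptogenic set overlaps
the resected regions *and* the outcome is Engel class I (seizure freedom);
a false positive when it overlaps without seizure freedom; a false negative
when it misses the resection despite seizure freedom; and a true negative
when it misses the resection and the outcome is unfavorable.

Six statistics are reported: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/total, PLR = sens/(1-spec),
NLR = (1-sens)/spec and DOR = (TP*TN)/(FP*FN).  Proportions carry Wilson
score 95% CIs; ratio statistics carry log-normal (Woolf-type) intervals
with a Haldane 0.5 continuity correction when any cell is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io_formats import ClinicalRecord

logger = logging.getLogger(__name__)

__all__ = ["ContingencyTable", "DiagnosticReport", "classify_patient",
           "build_contingency", "diagnostics", "wilson_ci", "compare_metrics",
           "engel_summary", "printed_contingency_tables"]


@dataclass
class ContingencyTable:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticReport:
    sensitivity: float
    specificity: float
    accuracy: float
    plr: float
    nlr: float
    dor: float
    ci_95: dict = field(default_factory=dict)
    method_notes: str = ""

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "plr": self.plr,
            "nlr": self.nlr,
            "dor": self.dor,
            "ci_95": {k: list(v) for k, v in self.ci_95.items()},
            "method_notes": self.method_notes,
        }


def classify_patient(predicted: set[int], clinical: ClinicalRecord) -> str:
    """One of "TP", "FP", "TN", "FN" per the resection/outcome rules."""
    predicted = set(int(r) for r in predicted)
    if not predicted.issubset(range(1, 69)):
        raise ValueError("predicted regions must be ids in 1..68")
    if not predicted:
        logger.warning("empty prediction for patient %s treated as no-overlap",
                       clinical.patient_id)
    overlap = bool(predicted & clinical.resected_regions)
    favorable = clinical.favorable
    if overlap and favorable:
        return "TP"
    if overlap and not favorable:
        return "FP"
    if not overlap and favorable:
        return "FN"
    return "TN"


def build_contingency(predictions: dict[str, set[int]],
                      records: list[ClinicalRecord]) -> ContingencyTable:
    """Tally patient classifications for one metric's predictions."""
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for rec in records:
        counts[classify_patient(predictions.get(rec.patient_id, set()), rec)] += 1
    return ContingencyTable(tp=counts["TP"], fp=counts["FP"],
                            tn=counts["TN"], fn=counts["FN"])


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid successes/trials ({k}/{n})")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def _log_ratio_ci(ratio: float, se_log: float, z: float) -> tuple[float, float]:
    if ratio <= 0 or not np.isfinite(ratio):
        return (0.0, np.inf)
    log_r = np.log(ratio)
    return (float(np.exp(log_r - z * se_log)), float(np.exp(log_r + z * se_log)))


def diagnostics(ct: ContingencyTable, level: float = 0.95) -> DiagnosticReport:
    """All six printed statistics with 95% CIs.

    Wilson score intervals for the three proportions; log-normal intervals
    for PLR/NLR/DOR.  Zero cells trigger the Haldane 0.5 correction for the
    ratio statistics only, flagged in ``method_notes``.
    """
    if ct.total == 0:
        raise ValueError("empty contingency table")
    tp, fp, tn, fn = ct.tp, ct.fp, ct.tn, ct.fn
    pos, neg = tp + fn, tn + fp

    sens = tp / pos if pos else float("nan")
    spec = tn / neg if neg else float("nan")
    acc = (tp + tn) / ct.total

    notes = ["Wilson score CIs for proportions; "
             "log-normal (Woolf-type) CIs for PLR/NLR/DOR."]
    cells = np.array([tp, fp, tn, fn], float)
    if np.any(cells == 0):
        cells = cells + 0.5
        notes.append("Haldane 0.5 correction applied to ratio statistics "
                     "(zero cell present).")
    htp, hfp, htn, hfn = cells
    hsens = htp / (htp + hfn)
    hspec = htn / (htn + hfp)

    # ratio point estimates use raw counts unless a zero cell forces Haldane
    if fp and fn and pos and neg:
        plr = sens / (1 - spec) if spec < 1 else float("inf")
        nlr = (1 - sens) / spec if spec > 0 else float("inf")
        dor = (tp * tn) / (fp * fn)
    else:
        plr = hsens / (1 - hspec)
        nlr = (1 - hsens) / hspec
        dor = (htp * htn) / (hfp * hfn)

    z = stats.norm.ppf(0.5 + level / 2.0)
    ci: dict[str, tuple[float, float]] = {}
    if pos:
        ci["sensitivity"] = wilson_ci(tp, pos, level)
    if neg:
        ci["specificity"] = wilson_ci(tn, neg, level)
    ci["accuracy"] = wilson_ci(tp + tn, ct.total, level)
    se_plr = np.sqrt((1 - hsens) / htp + hspec / hfp)
    se_nlr = np.sqrt(hsens / hfn + (1 - hspec) / htn)
    se_dor = np.sqrt(1 / htp + 1 / hfp + 1 / htn + 1 / hfn)
    ci["plr"] = _log_ratio_ci(plr, se_plr, z)
    ci["nlr"] = _log_ratio_ci(nlr, se_nlr, z)
    ci["dor"] = _log_ratio_ci(dor, se_dor, z)

    return DiagnosticReport(sensitivity=sens, specificity=spec, accuracy=acc,
                            plr=plr, nlr=nlr, dor=dor, ci_95=ci,
                            method_notes=" ".join(notes))


def compare_metrics(ct_a: ContingencyTable, ct_b: ContingencyTable,
                    test: str = "auto") -> tuple[float, float, str]:
    """Correct-vs-incorrect comparison of two metrics on the same cohort.

    Builds the 2x2 table [[correct_a, incorrect_a], [correct_b,
    incorrect_b]] (correct = TP + TN).  With ``test="auto"`` Pearson
    chi-square is applied when all expected counts are >= 5, otherwise
    Fisher's exact test (two-sided, point-probability rule); either test
    can also be forced.  Returns (statistic, p, test_name).
    """
    table = np.array([
        [ct_a.tp + ct_a.tn, ct_a.fp + ct_a.fn],
        [ct_b.tp + ct_b.tn, ct_b.fp + ct_b.fn],
    ])
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        return 0.0, 1.0, "degenerate (zero margin)"
    if test == "auto":
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        test = "chi-square" if np.all(expected >= 5) else "fisher"
    if test == "chi-square":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p), "chi-square"
    if test == "fisher":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p), "fisher"
    raise ValueError(f"unknown test {test!r}")


def engel_summary(records: list[ClinicalRecord]) -> dict:
    """Engel-class counts and the favorable (class I) proportion."""
    if not records:
        raise ValueError("no clinical records")
    counts = {c: 0 for c in ("I", "II", "III", "IV")}
    for rec in records:
        counts[rec.engel_class] += 1
    favorable = counts["I"] / len(records)
    return {"counts": counts, "n": len(records),
            "favorable_fraction": favorable}


def printed_contingency_tables() -> dict[str, ContingencyTable]:
    """Packaged per-metric TP/FP/TN/FN counts for the 15-patient cohort,
    recovered algebraically from the published summary statistics
    (derived-from-printed-values fixture)."""
    import json

    with resources.files("eznetsi.data").joinpath(
            "printed_contingency.json").open() as fh:
        raw = json.load(fh)
    return {
        key: ContingencyTable(**val)
        for key, val in raw.items()
        if isinstance(val, dict) and "tp" in val
    }
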