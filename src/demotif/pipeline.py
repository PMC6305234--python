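"""End-to-end orchestration: scan -> features -> 16 hypothesis cases ->
logistic regressions -> a-posteriori case ranking -> contingency / LIR /
extreme-feature reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .context_features import (DEFAULT_HALF_WIDTH, annotate_dataset,
                               contexts_by_protein)
from .core_model import Dataset
from .hypothesis_engine import (build_design_matrix, enumerate_cases,
                                extreme_features)
from .motif_scan import lir_contiguity_summary
from .stats_inference import (RegressionResult, fit_logistic,
                              phospho_contingency_by_group)


@dataclass
class RunConfig:
    half_width: int = DEFAULT_HALF_WIDTH
    histidine_charge: float = 0.0
    lir_mode: str = "core"
    lir_max_gap: int = 0
    phospho_kinds: tuple[str, ...] | None = None
    per_group: bool = True
    ridge: float = 0.0

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    case_results: list[RegressionResult]
    best_case: int | None
    best_case_tied: bool
    excluded_cases: list[int]
    extremes: pd.DataFrame
    phospho: dict
    lir: dict
    group_reports: dict[str, "RunReport"] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    status: str = "ok"

    def per_case_frame(self) -> pd.DataFrame:
        rows = []
        n_cases = max(len(self.case_results), 1)
        for r in self.case_results:
            row = {"case_id": r.case_id, "n": r.n, "loglik": r.loglik,
                   "lrt_p": r.lrt_p,
                   "lrt_p_bonferroni": min(1.0, r.lrt_p * n_cases),
                   "converged": r.converged,
                   "separation": r.separation_detected}
            for name, coef, p, orr in zip(r.names, r.coefficients,
                                          r.wald_p, r.odds_ratios):
                row[f"coef_{name}"] = coef
                row[f"wald_p_{name}"] = p
                row[f"or_{name}"] = orr
            rows.append(row)
        return pd.DataFrame(rows)


def _rank_cases(results: list[RegressionResult]
                ) -> tuple[int | None, bool, list[int]]:
    """Best case by lowest model LRT p among converged, non-separated
    fits; ties broken by lowest case_id and flagged."""
    eligible = [r for r in results
                if r.converged and not r.separation_detected]
    excluded = [r.case_id for r in results if r not in eligible]
    if not eligible:
        return None, False, excluded
    best_p = min(r.lrt_p for r in eligible)
    tied = [r.case_id for r in eligible
            if np.isclose(r.lrt_p, best_p, rtol=0, atol=1e-12)]
    return min(tied), len(tied) > 1, excluded


def compare_groups_extremes(dataset: Dataset, contexts=None,
                            half_width: int = DEFAULT_HALF_WIDTH,
                            histidine_charge: float = 0.0) -> pd.DataFrame:
    """Per-label distributions (median, quartiles) of per-protein extreme
    charge/hydrophobicity, with a rank-sum p-value as a descriptive aid.

    When a label class is empty or has a single protein, the test is
    skipped (p = NaN) but the summary is still emitted.
    """
    if contexts is None:
        contexts = annotate_dataset(dataset, half_width=half_width,
                                    histidine_charge=histidine_charge)
    grouped = contexts_by_protein(contexts)
    feats = {}
    for rec in dataset:
        if rec.id in grouped:
            feats[rec.id] = extreme_features(grouped[rec.id])
    labels = {rec.id: rec.label for rec in dataset}
    rows = []
    for feature in ("min_charge", "max_charge", "min_hydro", "max_hydro"):
        per_label = {}
        for pid, ef in feats.items():
            per_label.setdefault(labels[pid], []).append(
                getattr(ef, feature))
        sec = per_label.get("secretory", [])
        non = per_label.get("non_secretory", [])
        if len(sec) >= 2 and len(non) >= 2:
            p = float(sps.mannwhitneyu(sec, non,
                                       alternative="two-sided").pvalue)
        else:
            p = float("nan")
        for label, values in sorted(per_label.items()):
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            rows.append({"feature": feature, "label": label,
                         "n": len(values), "q1": q1, "median": med,
                         "q3": q3, "ranksum_p": p})
    return pd.DataFrame(rows)


def run_full_analysis(dataset: Dataset,
                      config: RunConfig | None = None,
                      _top_level: bool = True) -> RunReport:
    """Run all 16 case regressions plus the contingency, LIR and
    extreme-feature reports; rank cases a posteriori by model LRT p."""
    config = config or RunConfig()
    counts = dataset.label_counts()
    n_binary = sum(counts.get(l, 0) for l in ("secretory", "non_secretory"))
    if counts.get("secretory", 0) == 0 or counts.get("non_secretory", 0) == 0:
        raise ValueError(
            f"both label classes required for regression, got {counts}")

    contexts = annotate_dataset(dataset, half_width=config.half_width,
                                histidine_charge=config.histidine_charge)
    results: list[RegressionResult] = []
    import warnings as _warnings
    for case in enumerate_cases():
        rows = build_design_matrix(dataset, contexts, case)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            results.append(fit_logistic(rows, case_id=case.case_id,
                                        ridge=config.ridge))
    best, tied, excluded = _rank_cases(results)

    report = RunReport(
        case_results=results,
        best_case=best,
        best_case_tied=tied,
        excluded_cases=excluded,
        extremes=compare_groups_extremes(dataset, contexts),
        phospho=phospho_contingency_by_group(dataset, config.phospho_kinds),
        lir=lir_contiguity_summary(dataset, config.lir_mode,
                                   config.lir_max_gap),
        provenance={
            "config_hash": config.digest(),
            "n_proteins": len(dataset),
            "n_binary_labels": n_binary,
            "n_excluded_no_de": dataset.n_excluded_no_de,
            "version": __version__,
        },
        status="ok" if best is not None else "no rankable case",
    )
    if config.per_group and _top_level:
        for group in dataset.groups():
            sub = dataset.subset(group=group)
            sub_counts = sub.label_counts()
            if (sub_counts.get("secretory", 0) < 2
                    or sub_counts.get("non_secretory", 0) < 2):
                continue
            report.group_reports[group] = run_full_analysis(
                sub, config, _top_level=False)
    return report


def report_to_json(report: RunReport) -> dict:
    """JSON-serializable view of a run report (deterministic key order)."""
    return {
        "status": report.status,
        "best_case": report.best_case,
        "best_case_tied": report.best_case_tied,
        "excluded_cases": report.excluded_cases,
        "cases": report.per_case_frame().to_dict(orient="records"),
        "extremes": report.extremes.to_dict(orient="records"),
        "phospho": {
            key: {"table": list(res.table), "odds_ratio": res.odds_ratio,
                  "or_ci_95": list(res.or_ci_95),
                  "fisher_p": res.fisher_p_two_sided,
                  "correction_applied": res.correction_applied}
            for key, res in report.phospho.items()},
        "lir": {f"{g}|{l}": bins for (g, l), bins in report.lir.items()},
        "groups": {g: report_to_json(r)
                   for g, r in report.group_reports.items()},
        "provenance": report.provenance,
    }
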