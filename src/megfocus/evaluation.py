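"""Diagnostic-performance statistics over surgical case sets.

Computes, from per-case concordance labels and Engel seizure outcomes:
subgroup concordance rates, Fisher's exact test comparing the two
localization methods, diagnostic odds ratios with Woolf (log-normal) 95%
confidence intervals, and sensitivity/specificity/PPV/NPV of concordance
as a predictor of good (Engel I) vs. poor (Engel II-III) outcome.

A 19-case table with the published per-case labels ships with the
package (``data/cases_tables_1_2.csv``); the same functions apply to
simulated case sets produced by the benchmark.

Printing conventions: percentages to 1 decimal, odds ratios and CIs to
3 significant figures, p-values to 3 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

VALID_ENGEL = ("I", "II", "III", "IV")
Subgroup = Literal["all", "engel_I", "engel_II_III", "deep"]
Method = Literal["cds", "ecd"]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CaseRecord:
    """One surgical case: concordance labels, depth flag, outcome."""

    case_id: str
    deep_seated: bool
    engel: str
    cds_concordant: bool
    ecd_concordant: bool
    n_ied: int
    sex_age: str = ""
    cds_region: str = ""
    ecd_region: str = ""

    def __post_init__(self) -> None:
        if self.engel not in VALID_ENGEL:
            raise ValueError(f"case {self.case_id}: invalid Engel class {self.engel!r}")
        if self.n_ied < 3:
            raise ValueError(
                f"case {self.case_id}: {self.n_ied} IEDs — cases with one or two "
                "IEDs are excluded from analysis"
            )

    def concordant(self, method: Method) -> bool:
        return self.cds_concordant if method == "cds" else self.ecd_concordant


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of non-negative counts, [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class DiagnosticStats:
    """Outcome-prediction statistics of one method, in printed units (%)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def round_pct(x: float) -> float:
    return round(x, 1)


def round_3sf(x: float) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + 2)


def round_p(x: float) -> float:
    return round(x, 3)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "case_id",
    "deep_seated",
    "engel",
    "cds_concordant",
    "ecd_concordant",
    "n_ied",
)


def load_case_table(path: str | Path | None = None) -> list[CaseRecord]:
    """Load a case table CSV; without a path, the packaged 19-case table."""
    if path is None:
        with resources.as_file(
            resources.files("megfocus.data") / "cases_tables_1_2.csv"
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"case table missing column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            CaseRecord(
                case_id=str(row["case_id"]),
                deep_seated=bool(int(row["deep_seated"])),
                engel=str(row["engel"]),
                cds_concordant=bool(int(row["cds_concordant"])),
                ecd_concordant=bool(int(row["ecd_concordant"])),
                n_ied=int(row["n_ied"]),
                sex_age=str(row.get("sex_age", "")),
                cds_region=str(row.get("cds_region", "")),
                ecd_region=str(row.get("ecd_region", "")),
            )
        )
    return records


def _subset(records: Sequence[CaseRecord], subgroup: Subgroup) -> list[CaseRecord]:
    if subgroup == "all":
        sel = list(records)
    elif subgroup == "engel_I":
        sel = [r for r in records if r.engel == "I"]
    elif subgroup == "engel_II_III":
        sel = [r for r in records if r.engel in ("II", "III")]
    elif subgroup == "deep":
        sel = [r for r in records if r.deep_seated]
    else:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    if not sel:
        raise ValueError(f"subgroup {subgroup!r} is empty")
    return sel


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def concordance_rate(
    records: Sequence[CaseRecord], method: Method, subgroup: Subgroup = "all"
) -> float:
    """Percent of cases whose diagnosed region lay in the resected area."""
    sel = _subset(records, subgroup)
    n_conc = sum(r.concordant(method) for r in sel)
    return round_pct(100.0 * n_conc / len(sel))


def methods_table(records: Sequence[CaseRecord], subgroup: Subgroup = "all") -> ContingencyTable:
    """Rows = method (cDS, ECD), columns = (concordant, discordant)."""
    sel = _subset(records, subgroup)
    a = sum(r.cds_concordant for r in sel)
    c = sum(r.ecd_concordant for r in sel)
    return ContingencyTable(a, len(sel) - a, c, len(sel) - c)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (probability-ordering convention)."""
    return float(_scipy_fisher(table.as_array(), alternative="two-sided")[1])


def diagnostic_odds_ratio(
    table: ContingencyTable,
) -> tuple[float, tuple[float, float], bool]:
    """DOR = ad/bc with Woolf log-normal 95% CI.

    Any zero cell triggers the 0.5 continuity correction applied to all
    four cells; the returned flag reports whether it fired.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    dor = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(dor) - Z_95 * se)
    hi = math.exp(math.log(dor) + Z_95 * se)
    return dor, (lo, hi), corrected


def outcome_table(records: Sequence[CaseRecord], method: Method) -> ContingencyTable:
    """Rows = (concordant, discordant), columns = (Engel I, Engel II-III)."""
    recs = list(records)
    tp = sum(r.concordant(method) and r.engel == "I" for r in recs)
    fp = sum(r.concordant(method) and r.engel in ("II", "III") for r in recs)
    fn = sum((not r.concordant(method)) and r.engel == "I" for r in recs)
    tn = sum((not r.concordant(method)) and r.engel in ("II", "III") for r in recs)
    return ContingencyTable(tp, fp, fn, tn)


def diagnostic_performance(records: Sequence[CaseRecord], method: Method) -> DiagnosticStats:
    """Sens/spec/PPV/NPV of concordance predicting good (Engel I) outcome.

    A zero denominator makes the corresponding statistic not computable,
    reported as None rather than zero.
    """
    t = outcome_table(records, method)
    tp, fp, fn, tn = t.a, t.b, t.c, t.d
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("records must contain both good and poor outcomes")

    def _pct(num: int, den: int) -> float | None:
        return None if den == 0 else round_pct(100.0 * num / den)

    return DiagnosticStats(
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
        ppv=_pct(tp, tp + fp),
        npv=_pct(tn, tn + fn),
    )


def results_report(records: Sequence[CaseRecord]) -> dict:
    """Every concordance/outcome statistic of a case set, printed precision.

    Keys: per-subgroup rates (``cds_all`` ... ``ecd_deep``), Fisher
    p-values (``all_p``, ``engel1_p``, ``engel23_p``, ``deep_p``),
    diagnostic odds ratios with CIs, and both methods' outcome-prediction
    statistics.
    """
    report: dict = {}
    subgroup_keys = {
        "all": "all",
        "engel_I": "engel1",
        "engel_II_III": "engel23",
        "deep": "deep",
    }
    for subgroup, key in subgroup_keys.items():
        report[f"cds_{key}"] = concordance_rate(records, "cds", subgroup)
        report[f"ecd_{key}"] = concordance_rate(records, "ecd", subgroup)
        table = methods_table(records, subgroup)
        report[f"{key}_p"] = round_p(fisher_exact(table))
        dor, (lo, hi), corrected = diagnostic_odds_ratio(table)
        report[f"dor_{key}"] = round_3sf(dor)
        report[f"dor_{key}_ci"] = (round_3sf(lo), round_3sf(hi))
        if corrected:
            report[f"dor_{key}_continuity_corrected"] = True
    for method in ("cds", "ecd"):
        perf = diagnostic_performance(records, method)
        report[f"{method}_sensitivity"] = perf.sensitivity
        report[f"{method}_specificity"] = perf.specificity
        report[f"{method}_ppv"] = perf.ppv
        report[f"{method}_npv"] = perf.npv
    report["n_cases"] = len(list(records))
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`results_report` output."""
    lines = [
        f"Cases analyzed: {report['n_cases']}",
        "",
        f"{'subgroup':<14}{'cDS %':>8}{'ECD %':>8}{'Fisher p':>10}{'DOR':>8}  95% CI",
    ]
    for key, label in (
        ("all", "all"),
        ("engel1", "Engel I"),
        ("engel23", "Engel II-III"),
        ("deep", "deep-seated"),
    ):
        lo, hi = report[f"dor_{key}_ci"]
        lines.append(
            f"{label:<14}{report[f'cds_{key}']:>8}{report[f'ecd_{key}']:>8}"
            f"{report[f'{key}_p']:>10}{report[f'dor_{key}']:>8}  ({lo}-{hi})"
        )
    lines.append("")
    for method in ("cds", "ecd"):
        lines.append(
            f"{method.upper()}: sensitivity {report[f'{method}_sensitivity']}%, "
            f"specificity {report[f'{method}_specificity']}%, "
            f"PPV {report[f'{method}_ppv']}%, NPV {report[f'{method}_npv']}%"
        )
    return "\n".join(lines)
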