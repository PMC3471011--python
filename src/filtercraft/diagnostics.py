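"""Diagnostic-accuracy statistics for filter evaluation.

A filter applied to a labeled corpus yields the classic 2x2 table

                        relevant    not relevant
    retrieved              a             b
    not retrieved          c             d

from which sensitivity a/(a+c), specificity d/(b+d), precision a/(a+b) and
accuracy (a+d)/n are computed, each with a Wald (default) or Wilson
confidence interval.  Cohen's kappa quantifies two-reader agreement when
building the reference standard.  The inversion utilities recover the
prevalence implied by a published (sensitivity, specificity, precision)
triple and from it the implied accuracy — a consistency check applicable to
printed performance tables without the underlying corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # relevant, retrieved
    b: int  # not relevant, retrieved
    c: int  # relevant, missed
    d: int  # not relevant, missed

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in {cells}")
        if sum(cells) < 1:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def prevalence(self) -> float:
        return (self.a + self.c) / self.n


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its confidence interval."""

    point: float
    lo: float
    hi: float
    degenerate: bool = False  # Wald interval collapsed at p in {0, 1}

    def as_percent(self) -> str:
        return (
            f"{format_percent(self.point)} "
            f"({format_percent(self.lo)}-{format_percent(self.hi)})"
        )


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    precision: MetricEstimate | None
    accuracy: MetricEstimate | None
    table: ContingencyTable
    ci_method: str = "wald"
    level: float = 0.95

    def youden(self) -> float:
        if self.sensitivity is None or self.specificity is None:
            raise ValueError("Youden index undefined for this table")
        return self.sensitivity.point + self.specificity.point - 1.0

    def to_dict(self) -> dict:
        out = {
            "a": self.table.a, "b": self.table.b,
            "c": self.table.c, "d": self.table.d,
            "ci_method": self.ci_method, "level": self.level,
        }
        for name in ("sensitivity", "specificity", "precision", "accuracy"):
            m = getattr(self, name)
            if m is None:
                out[name] = None
            else:
                out[name] = {"point": m.point, "lo": m.lo, "hi": m.hi}
        return out


def format_percent(p: float) -> str:
    """Percent to one decimal, rounding half away from zero (table style)."""
    return str(Decimal(p * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def contingency(retrieved, corpus) -> ContingencyTable:
    """Cross the retrieved uid set against the corpus's consensus labels."""
    retrieved = set(retrieved)
    unknown = retrieved - corpus.uids
    if unknown:
        raise ValueError(f"retrieved uids not in corpus: {sorted(unknown)[:5]}")
    relevant = corpus.relevant_uids
    a = len(retrieved & relevant)
    b = len(retrieved) - a
    c = len(relevant) - a
    d = len(corpus) - a - b - c
    return ContingencyTable(a, b, c, d)


def _estimate(count: int, nobs: int, ci_method: str, level: float):
    if nobs == 0:
        return None
    p = count / nobs
    method = {"wald": "normal", "wilson": "wilson"}[ci_method]
    lo, hi = proportion_confint(count, nobs, alpha=1 - level, method=method)
    degenerate = ci_method == "wald" and p in (0.0, 1.0)
    return MetricEstimate(point=p, lo=float(lo), hi=float(hi), degenerate=degenerate)


def performance(
    table: ContingencyTable, ci_method: str = "wald", level: float = 0.95
) -> DiagnosticPerformance:
    """The four accuracy metrics with confidence intervals.

    A metric whose denominator is zero (e.g. precision when nothing is
    retrieved) is reported as None — undefined, not zero.
    """
    if ci_method not in ("wald", "wilson"):
        raise ValueError(f"unknown CI method {ci_method!r}")
    return DiagnosticPerformance(
        sensitivity=_estimate(table.a, table.a + table.c, ci_method, level),
        specificity=_estimate(table.d, table.b + table.d, ci_method, level),
        precision=_estimate(table.a, table.a + table.b, ci_method, level),
        accuracy=_estimate(table.a + table.d, table.n, ci_method, level),
        table=table,
        ci_method=ci_method,
        level=level,
    )


def cohen_kappa(labels_1, labels_2) -> float | None:
    """Two-rater, two-category chance-corrected agreement.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected agreement.
    Returns None when p_e = 1 (both raters constant and identical), where
    kappa is undefined.
    """
    labels_1 = [bool(x) for x in labels_1]
    labels_2 = [bool(x) for x in labels_2]
    if len(labels_1) != len(labels_2) or not labels_1:
        raise ValueError("label lists must be paired and non-empty")
    n = len(labels_1)
    p_o = sum(x == y for x, y in zip(labels_1, labels_2)) / n
    p1 = sum(labels_1) / n
    p2 = sum(labels_2) / n
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if math.isclose(p_e, 1.0):
        return None
    return (p_o - p_e) / (1 - p_e)


def invert_to_prevalence(se: float, sp: float, ppv: float) -> float:
    """The unique prevalence p at which a test with the given sensitivity and
    specificity has positive predictive value ``ppv``:

        ppv = se*p / (se*p + (1-sp)*(1-p))
        =>  p = ppv*(1-sp) / (se*(1-ppv) + ppv*(1-sp))
    """
    for name, v in (("se", se), ("sp", sp), ("ppv", ppv)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if se == 1.0 and sp == 1.0:
        raise ValueError(
            "a perfect test (se=sp=1) has ppv=1 at every prevalence; "
            "ppv carries no prevalence information"
        )
    num = ppv * (1.0 - sp)
    den = se * (1.0 - ppv) + num
    if den == 0.0:
        raise ValueError(f"degenerate (se={se}, sp={sp}, ppv={ppv})")
    return num / den


def implied_accuracy(se: float, sp: float, ppv: float) -> float:
    """Accuracy implied by a printed (sensitivity, specificity, precision)
    triple: se*p + sp*(1-p) at the prevalence those values imply."""
    p = invert_to_prevalence(se, sp, ppv)
    return se * p + sp * (1.0 - p)


def performance_report_row(source_text: str, perf: DiagnosticPerformance) -> dict:
    """One machine-readable report row (the TSV/JSON analogue of a published
    performance-table row)."""
    row = {"filter": source_text}
    row.update(perf.to_dict())
    return row
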