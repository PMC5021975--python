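"""Publication-style outputs: replication summary tables, Manhattan-plot data,
risk-curve overlays with external monthly covariates, and demographics
comparisons between institutions.

All operations here assemble plot-ready *tables*; rendering is left to the
caller so the numeric surface stays testable without graphics.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .assoc import ConditionAssociation
from .ingest import PatientRecord
from .replication import ReplicationResult, RiskCurve

logger = logging.getLogger(__name__)

#: category labels pooled into a single "unknown" bucket before demographics
#: comparison (institutions encode missingness differently)
UNKNOWN_LABELS = frozenset({"unknown", "unidentified", "declined", "other/unidentified",
                            "unidentified/unknown"})

SUMMARY_COLUMNS = [
    "condition_code", "condition_label",
    "low_month_a", "high_month_a", "low_month_b", "high_month_b",
    "max_rr_a", "max_rr_b", "p_fdr_a", "p_fdr_b", "p_replication_display",
]


@dataclass(frozen=True)
class MonthlyCovariateSeries:
    """An external monthly series (e.g. flu peak-month counts, serum vitamin D)."""

    name: str
    values: tuple[float, ...]
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (12,):
            raise ValueError(f"covariate {self.name!r} must have exactly 12 monthly values")
        object.__setattr__(self, "values", tuple(float(x) for x in v))


@dataclass(frozen=True)
class SummaryRow:
    """One condition's two-institution replication summary."""

    condition_code: str
    condition_label: str
    low_month_a: int
    high_month_a: int
    low_month_b: int
    high_month_b: int
    max_rr_a: float
    max_rr_b: float
    p_fdr_a: float
    p_fdr_b: float
    p_replication_display: str


def build_summary_table(
    scan_a: list[ConditionAssociation],
    scan_b: list[ConditionAssociation],
    replication: list[ReplicationResult],
) -> list[SummaryRow]:
    """One row per replicated condition, sorted by replication p ascending.

    Low/high risk months are the arg-min/arg-max of each institution's RR
    curve. The condition set of ``replication`` must be present in both scans.
    """
    by_a = {r.condition_code: r for r in scan_a}
    by_b = {r.condition_code: r for r in scan_b}
    missing = sorted(
        {r.condition_code for r in replication} - (set(by_a) & set(by_b))
    )
    if missing:
        raise ValueError(f"replication conditions absent from a scan: {missing}")

    ordered = sorted(replication, key=lambda r: (r.p_empirical, r.condition_code))
    rows = []
    for rep in ordered:
        a, b = by_a[rep.condition_code], by_b[rep.condition_code]
        rows.append(
            SummaryRow(
                condition_code=rep.condition_code,
                condition_label=a.condition_label,
                low_month_a=a.min_rr_month, high_month_a=a.max_rr_month,
                low_month_b=b.min_rr_month, high_month_b=b.max_rr_month,
                max_rr_a=a.max_rr, max_rr_b=b.max_rr,
                p_fdr_a=a.p_fdr, p_fdr_b=b.p_fdr,
                p_replication_display=rep.display_p,
            )
        )
    return rows


def summary_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows], columns=SUMMARY_COLUMNS)


def manhattan_data(
    scan: list[ConditionAssociation],
    grouping: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Plot-ready Manhattan table: chapter group, -log10(FDR p), significance flag.

    The significance flag uses strict ``p_fdr < alpha``. Adjusted p-values of
    exactly zero are clipped to the smallest positive float so the y-value
    stays finite (with a logged note).
    """
    if not scan:
        raise ValueError("scan is empty")
    rows = []
    for r in scan:
        p = r.p_fdr
        if p == 0.0:
            p = np.nextafter(0.0, 1.0)
            logger.info("condition %s: p_fdr == 0 clipped to %.3g for plotting",
                        r.condition_code, p)
        rows.append(
            {
                "condition_code": r.condition_code,
                "chapter": (grouping or {}).get(r.condition_code, "unassigned"),
                "p_fdr": r.p_fdr,
                "neg_log10_p_fdr": float(-np.log10(p)),
                "significant": bool(r.p_fdr < alpha),
            }
        )
    return pd.DataFrame(rows)


def overlay_table(
    curve: RiskCurve, covariates: list[MonthlyCovariateSeries]
) -> pd.DataFrame:
    """12-row table aligning a risk curve with external monthly covariates.

    Purely descriptive — no statistic is computed on the overlay.
    """
    data = {"month": list(range(1, 13)), "rr": list(curve.rr)}
    for cov in covariates:
        if len(cov.values) != 12:
            raise ValueError(f"covariate {cov.name!r} must have 12 values")
        data[cov.name] = list(cov.values)
    return pd.DataFrame(data)


def demographic_counts(patients: list[PatientRecord]) -> dict[str, Counter]:
    """Category counts per demographic attribute for a patient list."""
    out: dict[str, Counter] = {}
    for p in patients:
        for attr, value in p.demographics.items():
            out.setdefault(attr, Counter())[str(value)] += 1
    return out


def _align_categories(
    counts_a: dict[str, int], counts_b: dict[str, int]
) -> tuple[list[str], list[int], list[int]]:
    """Case-insensitive label alignment, pooling unknown-like and one-sided
    categories into a single "unknown" bucket."""
    def normalize(counts):
        norm: dict[str, int] = {}
        for label, count in counts.items():
            key = str(label).strip().lower()
            if key in UNKNOWN_LABELS:
                key = "unknown"
            norm[key] = norm.get(key, 0) + int(count)
        return norm

    na, nb = normalize(counts_a), normalize(counts_b)
    shared = (set(na) & set(nb)) - {"unknown"}

    def bucketed(norm):
        out = {label: norm[label] for label in shared}
        out["unknown"] = sum(v for k, v in norm.items() if k not in shared)
        return out

    ba, bb = bucketed(na), bucketed(nb)
    labels = sorted(shared) + ["unknown"]
    a = [ba[label] for label in labels]
    b = [bb[label] for label in labels]
    # drop categories empty at both sites (zero expected counts)
    keep = [i for i in range(len(labels)) if a[i] + b[i] > 0]
    return [labels[i] for i in keep], [a[i] for i in keep], [b[i] for i in keep]


def compare_demographics(
    table_a: dict[str, dict[str, int]], table_b: dict[str, dict[str, int]]
) -> dict[str, tuple[float, int, float]]:
    """Per-attribute chi-squared comparison of category counts between sites.

    Categories are matched case-insensitively; unknown-like labels and
    categories recorded at only one site are pooled into an "unknown" bucket.
    Attributes with fewer than two usable categories are skipped with a
    logged reason. Returns ``{attribute: (chi2, df, p)}``.
    """
    results: dict[str, tuple[float, int, float]] = {}
    for attr in sorted(set(table_a) & set(table_b)):
        labels, a, b = _align_categories(table_a[attr], table_b[attr])
        if len(labels) < 2:
            logger.warning(
                "attribute %r skipped: fewer than 2 shared categories after alignment",
                attr,
            )
            continue
        chi2, p, df, _ = scipy.stats.chi2_contingency(
            np.array([a, b]), correction=False
        )
        results[attr] = (float(chi2), int(df), float(p))
    return results


def demographics_frame(results: dict[str, tuple[float, int, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"attribute": k, "chi2": v[0], "df": v[1], "p": v[2]} for k, v in results.items()],
        columns=["attribute", "chi2", "df", "p"],
    )
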