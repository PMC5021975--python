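"""The season-wide association scan.

For every diagnosis code with enough carriers, test whether carriers' birth
months are distributed differently from the cohort's, and summarise the
association as a 12-point birth-month relative-risk curve.

Statistical choices
-------------------
* Relative risk for month m compares risk among those born in m against
  everyone born in any other month:
  ``RR_m = (c_m / n_m) / ((C - c_m) / (N - n_m))``.
  Confidence intervals use the Katz log method; months with a zero cell get
  the Haldane–Anscombe 0.5 correction (applied to that month only) so curves
  stay finite for downstream permutation use.
* The omnibus association test is the Pearson chi-squared test on the
  2 x 12 (case status x birth month) table, df = 11; months with zero
  population are dropped with df reduced accordingly.
* Multiplicity is controlled with Benjamini–Hochberg FDR across exactly the
  set of conditions passing the inclusion threshold in this scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .ingest import MonthlyCaseCounts, PatientRecord, condition_case_counts

logger = logging.getLogger(__name__)

_RR_COLS = [f"rr_{m}" for m in range(1, 13)]
_LO_COLS = [f"ci_low_{m}" for m in range(1, 13)]
_HI_COLS = [f"ci_high_{m}" for m in range(1, 13)]

SCAN_COLUMNS = [
    "condition_code", "label", "n_cases", "chi2", "df", "p_raw", "p_fdr",
    "max_rr", "max_rr_month", "min_rr_month", *_RR_COLS, *_LO_COLS, *_HI_COLS,
]


@dataclass(frozen=True)
class MonthlyContingency:
    """Case and population counts by birth month (January first).

    ``cases_by_month[m-1]`` counts patients with the condition born in month
    m; ``population_by_month[m-1]`` counts all cohort patients born in m.
    """

    cases_by_month: tuple[int, ...]
    population_by_month: tuple[int, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.cases_by_month, dtype=np.int64)
        n = np.asarray(self.population_by_month, dtype=np.int64)
        if c.shape != (12,) or n.shape != (12,):
            raise ValueError("cases_by_month and population_by_month must have length 12")
        if (c < 0).any() or (n < 0).any():
            raise ValueError("counts must be non-negative")
        if (c > n).any():
            bad = [m + 1 for m in np.flatnonzero(c > n)]
            raise ValueError(f"cases exceed population in months {bad}")
        object.__setattr__(self, "cases_by_month", tuple(int(x) for x in c))
        object.__setattr__(self, "population_by_month", tuple(int(x) for x in n))

    @property
    def total_cases(self) -> int:
        return int(sum(self.cases_by_month))

    @property
    def total_population(self) -> int:
        return int(sum(self.population_by_month))


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: inclusion threshold, FDR level, CI coverage."""

    min_patients_per_condition: int = 1000
    fdr_alpha: float = 0.05
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.min_patients_per_condition < 1:
            raise ValueError("min_patients_per_condition must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class ConditionAssociation:
    """One condition's birth-month association: RR curve, CIs, test, FDR-adjusted p."""

    condition_code: str
    condition_label: str
    n_cases: int
    rr: np.ndarray
    rr_ci_low: np.ndarray
    rr_ci_high: np.ndarray
    chi2_stat: float
    df: int
    p_raw: float
    p_fdr: float
    max_rr: float
    max_rr_month: int
    min_rr_month: int
    contingency: MonthlyContingency | None = field(default=None, repr=False)


def monthly_relative_risk(
    t: MonthlyContingency, ci_level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Birth-month relative-risk curve with Katz log-method confidence intervals.

    For each month m, risk among those born in m is compared with risk among
    those born in any other month. Months where either the in-month or
    out-of-month case count is zero get a 0.5 continuity correction added to
    all four cells of that month's 2x2 table (that month only).

    Returns ``(rr, ci_low, ci_high)``, three length-12 arrays.
    """
    c = np.asarray(t.cases_by_month, dtype=float)
    n = np.asarray(t.population_by_month, dtype=float)
    if (n == 0).any():
        bad = [m + 1 for m in np.flatnonzero(n == 0)]
        raise ValueError(f"no population in months {bad}; relative risk undefined")
    C, N = t.total_cases, t.total_population
    if C <= 0:
        raise ValueError("no cases; relative risk undefined")
    if N <= C:
        raise ValueError("cases must be a proper subset of the population")

    a, n1 = c, n                      # in-month cases / population
    b, n2 = C - c, N - n              # out-of-month cases / population
    adjust = (a == 0) | (b == 0)      # Haldane–Anscombe, per affected month
    a = a + 0.5 * adjust
    b = b + 0.5 * adjust
    n1 = n1 + 1.0 * adjust
    n2 = n2 + 1.0 * adjust

    rr = (a / n1) / (b / n2)
    z = scipy.stats.norm.ppf(0.5 + ci_level / 2.0)
    se_log = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n2)
    ci_low = rr * np.exp(-z * se_log)
    ci_high = rr * np.exp(z * se_log)
    return rr, ci_low, ci_high


def birth_month_association_test(t: MonthlyContingency) -> tuple[float, int, float]:
    """Pearson chi-squared test of case status against birth month.

    The 2 x 12 table (cases / non-cases by month) gives df = 11; months with
    zero population are dropped, reducing df. Returns ``(chi2, df, p)``.
    """
    c = np.asarray(t.cases_by_month, dtype=np.int64)
    n = np.asarray(t.population_by_month, dtype=np.int64)
    keep = n > 0
    if keep.sum() < 2:
        raise ValueError("association test needs at least 2 months with population")
    C, N = t.total_cases, t.total_population
    if C == 0 or C == N:
        raise ValueError("case status is constant; chi-squared test undefined")
    observed = np.vstack([c[keep], (n - c)[keep]])
    chi2, p, df, _ = scipy.stats.chi2_contingency(observed, correction=False)
    return float(chi2), int(df), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input's order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    bad = np.flatnonzero(~((p >= 0) & (p <= 1)))
    if bad.size:
        raise ValueError(f"p-value out of [0, 1] at index {int(bad[0])}: {p[bad[0]]!r}")
    return multipletests(p, method="fdr_bh")[1]


def run_scan(
    patients: list[PatientRecord] | MonthlyCaseCounts,
    cfg: ScanConfig = ScanConfig(),
    labels: dict[str, str] | None = None,
) -> list[ConditionAssociation]:
    """Scan every condition meeting the inclusion threshold, FDR-adjusted jointly.

    ``patients`` may be a patient list or precomputed
    :class:`~seawas.ingest.MonthlyCaseCounts`. Conditions with at least
    ``cfg.min_patients_per_condition`` cases (threshold inclusive) are tested;
    the BH adjustment spans exactly this tested set. Results are ordered by
    condition code. Arg-extrema month ties break toward the earliest calendar
    month.
    """
    counts = patients if isinstance(patients, MonthlyCaseCounts) else condition_case_counts(patients)
    tested = sorted(
        code for code, tot in counts.totals.items()
        if tot >= cfg.min_patients_per_condition
    )
    if not tested:
        logger.warning("no condition reached %d cases; scan is empty",
                       cfg.min_patients_per_condition)
        return []

    population = tuple(int(x) for x in counts.population_by_month)
    results: list[ConditionAssociation] = []
    p_raws = np.empty(len(tested))
    for i, code in enumerate(tested):
        t = MonthlyContingency(tuple(int(x) for x in counts.cases[code]), population)
        rr, lo, hi = monthly_relative_risk(t, cfg.ci_level)
        chi2, df, p = birth_month_association_test(t)
        p_raws[i] = p
        results.append(
            ConditionAssociation(
                condition_code=code,
                condition_label=(labels or {}).get(code, code),
                n_cases=t.total_cases,
                rr=rr, rr_ci_low=lo, rr_ci_high=hi,
                chi2_stat=chi2, df=df, p_raw=p, p_fdr=np.nan,
                max_rr=float(rr.max()),
                max_rr_month=int(np.argmax(rr)) + 1,   # argmax -> earliest tie
                min_rr_month=int(np.argmin(rr)) + 1,
                contingency=t,
            )
        )
    p_fdr = benjamini_hochberg(p_raws)
    for res, q in zip(results, p_fdr):
        res.p_fdr = float(q)
    return results


def shared_condition_set(
    scan_a: list[ConditionAssociation],
    scan_b: list[ConditionAssociation],
    threshold: int = 1000,
) -> list[str]:
    """Condition codes with at least ``threshold`` cases at both institutions, sorted."""
    a = {r.condition_code for r in scan_a if r.n_cases >= threshold}
    b = {r.condition_code for r in scan_b if r.n_cases >= threshold}
    return sorted(a & b)


def write_scan_results(results: list[ConditionAssociation], path) -> None:
    """Write scan results as tab-delimited text (full float precision)."""
    rows = []
    for r in results:
        row = {
            "condition_code": r.condition_code, "label": r.condition_label,
            "n_cases": r.n_cases, "chi2": r.chi2_stat, "df": r.df,
            "p_raw": r.p_raw, "p_fdr": r.p_fdr, "max_rr": r.max_rr,
            "max_rr_month": r.max_rr_month, "min_rr_month": r.min_rr_month,
        }
        row.update({col: float(v) for col, v in zip(_RR_COLS, r.rr)})
        row.update({col: float(v) for col, v in zip(_LO_COLS, r.rr_ci_low)})
        row.update({col: float(v) for col, v in zip(_HI_COLS, r.rr_ci_high)})
        rows.append(row)
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_scan_results(path) -> list[ConditionAssociation]:
    """Read a scan-results table written by :func:`write_scan_results`.

    The per-month contingency is not stored in the file, so ``contingency``
    is ``None`` on the returned objects.
    """
    df = pd.read_csv(path, sep="\t", dtype={"condition_code": str, "label": str})
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: scan results missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            ConditionAssociation(
                condition_code=d["condition_code"],
                condition_label=d["label"],
                n_cases=int(d["n_cases"]),
                rr=np.array([d[c] for c in _RR_COLS]),
                rr_ci_low=np.array([d[c] for c in _LO_COLS]),
                rr_ci_high=np.array([d[c] for c in _HI_COLS]),
                chi2_stat=float(d["chi2"]),
                df=int(d["df"]),
                p_raw=float(d["p_raw"]),
                p_fdr=float(d["p_fdr"]),
                max_rr=float(d["max_rr"]),
                max_rr_month=int(d["max_rr_month"]),
                min_rr_month=int(d["min_rr_month"]),
            )
        )
    return out
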