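"""Cross-institution replication of birth-month risk-curve patterns.

Two institutions that share an underlying seasonal mechanism should show
similar 12-point birth-month relative-risk curves for the same condition,
even when the single peak month differs. Similarity is measured with the
Pearson correlation between the two month-ordered curves, and significance
with an empirical permutation null: one curve is held fixed, the 12 entries
of the other are shuffled as a block (sampled without replacement), and the
empirical p-value is the proportion of shuffled correlations strictly greater
than the observed one. A zero count at B = 1000 is displayed as "p < 0.001".

Within :func:`permutation_null` the observed correlation and the permuted
correlations are computed with the same product-moment formula, so the
identity permutation can never spuriously count as an exceedance under the
strict inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._util import derive_seed
from .assoc import ConditionAssociation

logger = logging.getLogger(__name__)

REPLICATION_COLUMNS = [
    "condition_code", "r_observed", "B", "n_exceeding", "p_empirical",
    "display_p", "seed",
]


class ZeroVarianceError(ValueError):
    """A risk curve is constant, so its Pearson correlation is undefined."""


@dataclass(frozen=True)
class RiskCurve:
    """A condition's 12 monthly relative risks (January first) at one institution."""

    condition_code: str
    institution_label: str
    rr: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.rr, dtype=float)
        if arr.shape != (12,):
            raise ValueError("risk curve must have exactly 12 entries")
        if not np.all(np.isfinite(arr)) or (arr <= 0).any():
            raise ValueError("risk curve entries must be finite and positive")
        object.__setattr__(self, "rr", tuple(float(x) for x in arr))


@dataclass(frozen=True)
class ReplicationResult:
    """Observed correlation, permutation count, and empirical p for one condition."""

    condition_code: str
    r_observed: float
    n_permutations: int
    n_exceeding: int
    p_empirical: float
    display_p: str
    seed: int


def curve_from_association(assoc: ConditionAssociation, institution_label: str) -> RiskCurve:
    """Extract the relative-risk curve of a scanned condition."""
    return RiskCurve(assoc.condition_code, institution_label, tuple(float(x) for x in assoc.rr))


def _check_variance(v: np.ndarray, name: str) -> None:
    if np.ptp(v) == 0:
        raise ZeroVarianceError(f"{name} is constant; Pearson correlation undefined")


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises :class:`ZeroVarianceError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-d vectors of length >= 3")
    _check_variance(x, "x")
    _check_variance(y, "y")
    return float(scipy.stats.pearsonr(x, y).statistic)


def _correlations_against(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of Y against x (rows must be non-constant).

    Uses per-row elementwise reductions rather than a matrix product: BLAS
    matmul rounds differently depending on matrix shape, which would break
    the bit-exact tie between the observed curve and the identity permutation
    that the strict exceedance rule relies on.
    """
    xc = x - x.mean()
    xn = np.sqrt((xc**2).sum())
    Yc = Y - Y.mean(axis=1, keepdims=True)
    return (Yc * xc).sum(axis=1) / (np.sqrt((Yc**2).sum(axis=1)) * xn)


def permutation_pvalue(
    fixed, shuffled, n_permutations: int, seed: int
) -> tuple[float, int]:
    """Permutation exceedance count for the correlation of two vectors.

    Holds ``fixed`` fixed, draws ``n_permutations`` uniform random
    permutations of ``shuffled`` (its entries shuffled as a block, without
    replacement), and counts permuted correlations strictly greater than the
    observed one. Returns ``(r_observed, n_exceeding)``. Works for any common
    length >= 3 (the 12-month case is the production path; short vectors are
    useful for exhaustive cross-checks).
    """
    x = np.asarray(fixed, dtype=float)
    y = np.asarray(shuffled, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-d vectors of length >= 3")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    _check_variance(x, "fixed curve")
    _check_variance(y, "shuffled curve")
    r_obs = float(_correlations_against(x, y[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n_permutations, 1)), axis=1)
    r_null = _correlations_against(x, perms)
    return r_obs, int(np.sum(r_null > r_obs))


def format_display_p(n_exceeding: int, n_permutations: int, p_empirical: float) -> str:
    """Reporting convention: an exact zero at B = 1000 prints as ``p < 0.001``."""
    if n_exceeding == 0 and n_permutations == 1000:
        return "p < 0.001"
    return f"{p_empirical:g}"


def permutation_null(
    curve_fixed: RiskCurve,
    curve_shuffled: RiskCurve,
    n_permutations: int = 1000,
    seed: int = 0,
    add_one: bool = False,
) -> ReplicationResult:
    """Empirical permutation test of pattern similarity between two risk curves.

    ``p_empirical = n_exceeding / B`` with a strict ">" exceedance rule. With
    ``add_one=True`` the ``(b + 1) / (B + 1)`` convention is used instead (and
    the display string is always numeric, since an exact zero cannot occur).
    """
    r_obs, n_exc = permutation_pvalue(
        curve_fixed.rr, curve_shuffled.rr, n_permutations, seed
    )
    if add_one:
        p = (n_exc + 1) / (n_permutations + 1)
        display = f"{p:g}"
    else:
        p = n_exc / n_permutations
        display = format_display_p(n_exc, n_permutations, p)
    return ReplicationResult(
        condition_code=curve_fixed.condition_code,
        r_observed=r_obs,
        n_permutations=n_permutations,
        n_exceeding=n_exc,
        p_empirical=p,
        display_p=display,
        seed=seed,
    )


def replicate_all(
    scan_a: list[ConditionAssociation],
    scan_b: list[ConditionAssociation],
    shared: list[str],
    n_permutations: int = 1000,
    seed: int = 0,
    add_one: bool = False,
    fixed: str = "a",
) -> list[ReplicationResult]:
    """Run the permutation replication test for every shared condition.

    By default institution A's curve is held fixed and institution B's curve
    is randomized; pass ``fixed="b"`` for the opposite direction (run both for
    a symmetric report). Each condition uses a sub-seed derived from
    ``(seed, condition_code)``, so results do not depend on the order of
    ``shared``. Conditions whose curve is constant are skipped with a logged
    reason.
    """
    if fixed not in ("a", "b"):
        raise ValueError('fixed must be "a" or "b"')
    by_code_a = {r.condition_code: r for r in scan_a}
    by_code_b = {r.condition_code: r for r in scan_b}
    missing = [c for c in shared if c not in by_code_a or c not in by_code_b]
    if missing:
        raise ValueError(f"conditions missing from one of the scans: {missing}")

    results = []
    for code in shared:
        curve_a = curve_from_association(by_code_a[code], "a")
        curve_b = curve_from_association(by_code_b[code], "b")
        held, randomized = (curve_a, curve_b) if fixed == "a" else (curve_b, curve_a)
        sub_seed = derive_seed(seed, code)
        try:
            results.append(
                permutation_null(held, randomized, n_permutations, sub_seed, add_one)
            )
        except ZeroVarianceError as exc:
            logger.warning("condition %s excluded from replication: %s", code, exc)
    return results


def write_replication_results(results: list[ReplicationResult], path) -> None:
    """Write replication results as tab-delimited text."""
    rows = [
        {
            "condition_code": r.condition_code, "r_observed": r.r_observed,
            "B": r.n_permutations, "n_exceeding": r.n_exceeding,
            "p_empirical": r.p_empirical, "display_p": r.display_p, "seed": r.seed,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=REPLICATION_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_replication_results(path) -> list[ReplicationResult]:
    """Read a replication-results table written by :func:`write_replication_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"condition_code": str, "display_p": str})
    missing = [c for c in REPLICATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: replication results missing columns {missing}")
    return [
        ReplicationResult(
            condition_code=row.condition_code,
            r_observed=float(row.r_observed),
            n_permutations=int(row.B),
            n_exceeding=int(row.n_exceeding),
            p_empirical=float(row.p_empirical),
            display_p=str(row.display_p),
            seed=int(row.seed),
        )
        for row in df.itertuples(index=False)
    ]
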