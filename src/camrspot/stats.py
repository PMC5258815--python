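"""Exact contingency statistics, confusion metrics, rank tests, outliers.

Two-sided exact tests use the probability-mass criterion: the p-value sums
the (generalized) hypergeometric probabilities of every margin-consistent
table whose probability does not exceed that of the observed table (within
a relative tolerance of 1e-7).  This is the convention of R's
``fisher.test``.  The 2×2 case is delegated to scipy; the R×C
generalization (Freeman–Halton) is implemented here by exact enumeration
with a Monte-Carlo fallback for large tables.

Diagnostic-test percentages are rounded half-up to the nearest integer and
the raw fractions are always retained alongside.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .errors import CapabilityError, InsufficientDataError
from .records import AntigenClass, CohortTables, PhenotypeCall, TimePoint

#: Relative tolerance for the "probability <= observed" comparison.
PROB_RTOL = 1e-7

#: DSA positivity threshold (mean fluorescence intensity).
DSA_MFI_THRESHOLD = 1000.0

#: Proteinuria threshold (urinary protein-to-creatinine ratio).
PCR_THRESHOLD = 50.0


class TestMethod(str, enum.Enum):
    FISHER_2X2 = "fisher_2x2"
    FISHER_RXC = "fisher_rxc"
    FISHER_RXC_MC = "fisher_rxc_monte_carlo"
    MANN_WHITNEY = "mann_whitney"
    KRUSKAL_WALLIS = "kruskal_wallis"
    T_TEST = "t_test"


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: TestMethod
    statistic: Optional[float] = None
    degenerate: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()
    positive_row: int = 0
    positive_col: int = 0

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("table must be at least 2x2")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _as_array(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.array
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test for a 2×2 table (probability-mass rule)."""
    arr = _as_array(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return TestResult(p_value=1.0, method=TestMethod.FISHER_2X2, degenerate=True)
    odds, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        p_value=float(min(p, 1.0)), method=TestMethod.FISHER_2X2,
        statistic=float(odds) if math.isfinite(odds) else None,
    )


def _log_table_prob(const: float, flat: np.ndarray, lfact: np.ndarray) -> float:
    return const - lfact[flat].sum()


def _enumerate_log_probs(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Log probabilities of every table with the given margins."""
    n = int(rows.sum())
    lfact = scipy.special.gammaln(np.arange(n + 1) + 1)
    const = lfact[rows].sum() + lfact[cols].sum() - lfact[n]
    out: list[float] = []
    ncols = len(cols)

    def recurse(row_idx: int, remaining_cols: np.ndarray, acc: float) -> None:
        if row_idx == len(rows) - 1:
            # last row forced by the column margins
            if (remaining_cols <= n).all():
                out.append(const + acc - lfact[remaining_cols].sum())
            return
        r = rows[row_idx]

        def fill(col_idx: int, left: int, rem: np.ndarray, acc2: float) -> None:
            if col_idx == ncols - 1:
                if left <= rem[col_idx]:
                    new_rem = rem.copy()
                    new_rem[col_idx] -= left
                    recurse(row_idx + 1, new_rem, acc2 - lfact[left])
                return
            for v in range(min(left, rem[col_idx]) + 1):
                new_rem = rem.copy()
                new_rem[col_idx] -= v
                fill(col_idx + 1, left - v, new_rem, acc2 - lfact[v])

        fill(0, int(r), remaining_cols, acc)

    recurse(0, cols.copy(), 0.0)
    return np.array(out)


def fisher_exact_rxc(
    table,
    max_n: int = 200,
    monte_carlo: bool = False,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Freeman–Halton exact test for an R×C table with fixed margins.

    Exact enumeration up to total ``max_n``; beyond that a seeded
    Monte-Carlo estimate over ``n_draws`` margin-preserving tables is
    available via ``monte_carlo=True``.
    """
    arr = _as_array(table)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    # drop empty margins — they carry no information
    arr = arr[rows > 0][:, cols > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return TestResult(p_value=1.0, method=TestMethod.FISHER_RXC, degenerate=True)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())

    lfact = scipy.special.gammaln(np.arange(n + 1) + 1)
    const = lfact[rows].sum() + lfact[cols].sum() - lfact[n]
    log_p_obs = const - lfact[arr.ravel()].sum()

    if n > max_n:
        if not monte_carlo:
            raise CapabilityError(
                f"table total {n} exceeds exact-enumeration guard {max_n}; "
                "pass monte_carlo=True for a seeded estimate"
            )
        rng = np.random.default_rng(seed)
        dist = scipy.stats.random_table(rows, cols)
        draws = dist.rvs(n_draws, random_state=rng).astype(np.int64)
        logps = const - lfact[draws.reshape(n_draws, -1)].sum(axis=1)
        hits = int((logps <= log_p_obs + math.log1p(PROB_RTOL)).sum())
        p = (hits + 1) / (n_draws + 1)
        return TestResult(
            p_value=min(p, 1.0), method=TestMethod.FISHER_RXC_MC, statistic=None
        )

    logps = _enumerate_log_probs(rows, cols)
    mask = logps <= log_p_obs + math.log1p(PROB_RTOL)
    p = float(np.exp(logps[mask]).sum())
    return TestResult(p_value=min(p, 1.0), method=TestMethod.FISHER_RXC)


def exact_pvalue_cdf_terms(table) -> tuple[float, float]:
    """Null CDF terms of the exact p-value, conditional on the margins.

    Returns (P(P < p_obs), P(P = p_obs)) under the generalized
    hypergeometric null.  For a valid exact test the *randomized* p-value
    ``P(P < p_obs) + U·P(P = p_obs)`` with U ~ Uniform(0,1) is exactly
    uniform, which is the right calibration check for a test whose raw
    p-values are super-uniform by discreteness.
    """
    arr = _as_array(table)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    arr = arr[rows > 0][:, cols > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 0.0, 1.0
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())
    lfact = scipy.special.gammaln(np.arange(n + 1) + 1)
    const = lfact[rows].sum() + lfact[cols].sum() - lfact[n]
    log_p_obs = const - lfact[arr.ravel()].sum()
    logps = _enumerate_log_probs(rows, cols)
    tol = math.log1p(PROB_RTOL)
    p_obs = float(np.exp(logps[logps <= log_p_obs + tol]).sum())
    # p-value of each margin-consistent table, by the same criterion
    order = np.argsort(logps)
    sorted_probs = np.exp(logps[order])
    cum = np.cumsum(sorted_probs)
    # tables sharing (within tolerance) a probability share a p-value
    pvals = np.empty_like(cum)
    i = 0
    while i < len(cum):
        j = i
        while j + 1 < len(cum) and logps[order[j + 1]] <= logps[order[i]] + tol:
            j += 1
        pvals[i : j + 1] = cum[j]
        i = j + 1
    p_less = float(sorted_probs[pvals < p_obs * (1 - PROB_RTOL)].sum())
    p_equal = max(min(p_obs - p_less, 1.0), 0.0)
    return p_less, p_equal


def _percent_half_up(num: int, den: int) -> int:
    """num/den as a percentage, rounded half-up (87.5 → 88)."""
    return (200 * num + den) // (2 * den)


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: Optional[int]
    specificity: Optional[int]
    ppv: Optional[int]
    npv: Optional[int]
    fractions: Mapping[str, Optional[Fraction]] = field(default_factory=dict)


def confusion_metrics(
    table, positive_row: int = 0, positive_col: int = 0
) -> ConfusionMetrics:
    """Diagnostic-test metrics from a 2×2 table with declared orientation.

    ``positive_row`` indexes the test-positive row, ``positive_col`` the
    outcome-positive column.  Metrics with a zero denominator are reported
    absent rather than 0.
    """
    if isinstance(table, ContingencyTable):
        positive_row, positive_col = table.positive_row, table.positive_col
    arr = _as_array(table)
    if arr.shape != (2, 2):
        raise ValueError("confusion_metrics requires a 2x2 table")
    tp = int(arr[positive_row, positive_col])
    fp = int(arr[positive_row, 1 - positive_col])
    fn = int(arr[1 - positive_row, positive_col])
    tn = int(arr[1 - positive_row, 1 - positive_col])

    def metric(num, den):
        return (Fraction(num, den), _percent_half_up(num, den)) if den else (None, None)

    sens_f, sens = metric(tp, tp + fn)
    spec_f, spec = metric(tn, tn + fp)
    ppv_f, ppv = metric(tp, tp + fp)
    npv_f, npv = metric(tn, tn + fn)
    return ConfusionMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        fractions={"sensitivity": sens_f, "specificity": spec_f,
                   "ppv": ppv_f, "npv": npv_f},
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the smaller sample has ≤8 observations and
    there are no ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = 1.0 if math.isnan(res.pvalue) else float(min(res.pvalue, 1.0))
    return TestResult(
        p_value=p, method=TestMethod.MANN_WHITNEY, statistic=float(res.statistic)
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test (chi-square approximation, tie-corrected)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 nonempty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return TestResult(
            p_value=1.0, method=TestMethod.KRUSKAL_WALLIS, statistic=0.0,
            degenerate=True,
        )
    stat, p = scipy.stats.kruskal(*groups)
    return TestResult(
        p_value=float(min(p, 1.0)), method=TestMethod.KRUSKAL_WALLIS,
        statistic=float(stat),
    )


class OutlierFlag(str, enum.Enum):
    INLIER = "inlier"
    MILD = "mild"
    EXTREME = "extreme"


def iqr_outliers(values: Sequence[float]) -> list[OutlierFlag]:
    """Tukey fences: mild beyond 1.5×IQR, extreme beyond 3×IQR.

    Quartiles use the linear-interpolation convention.  Requires n ≥ 4.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise InsufficientDataError("need >=4 values for IQR fences")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    flags = []
    for v in arr:
        if v < q1 - 3.0 * iqr or v > q3 + 3.0 * iqr:
            flags.append(OutlierFlag.EXTREME)
        elif v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr:
            flags.append(OutlierFlag.MILD)
        else:
            flags.append(OutlierFlag.INLIER)
    return flags


# ---------------------------------------------------------------------------
# Association report


def _donor_call(
    calls: Mapping[tuple, PhenotypeCall], pid: str, tp: TimePoint
) -> Optional[PhenotypeCall]:
    call = calls.get((pid, tp, AntigenClass.DONOR))
    if call is not None and call.interpretable:
        return call
    return None


def _predictor_values(
    cohort: CohortTables,
    calls: Mapping[tuple, PhenotypeCall],
    dsa_threshold: float,
    pcr_threshold: float,
) -> dict[str, dict[str, Optional[bool]]]:
    """Per-predictor {patient_id: True/False/None (missing)} maps."""
    from .trajectory import label_transition, BdepChange, DsrChange

    preds: dict[str, dict[str, Optional[bool]]] = {}
    for p in cohort.patients:
        pid = p.patient_id
        t1 = _donor_call(calls, pid, TimePoint.T1)
        t2 = _donor_call(calls, pid, TimePoint.T2)
        values: dict[str, Optional[bool]] = {
            "pcr_gt_50": None if p.pcr is None else p.pcr > pcr_threshold,
            "banff_g_ge1": p.banff_g >= 1,
            "banff_ptc_ge1": p.banff_ptc >= 1,
            "banff_cg_ge1": p.banff_cg >= 1,
            "banff_cv_ge1": p.banff_cv >= 1,
            "c4d_ptc": p.c4d_ptc,
            "c4d_glom": p.c4d_glom,
            "dsa_gt_1000_t1": None if p.dsa_mfi_t1 is None
            else p.dsa_mfi_t1 > dsa_threshold,
            "dsa_gt_1000_t2": None if p.dsa_mfi_t2 is None
            else p.dsa_mfi_t2 > dsa_threshold,
            "dsr_t1": None if t1 is None else t1.dsr,
            "dsr_t2": None if t2 is None else t2.dsr,
            "bdep_t1": None if t1 is None else t1.b_dependent,
            "bdep_t2": None if t2 is None else t2.b_dependent,
        }
        if t1 is not None and t2 is not None:
            trans = label_transition(t1, t2)
            values["change_to_or_maintain_dsr"] = trans.dsr_change in (
                DsrChange.TO_DSR, DsrChange.MAINTAIN_DSR,
            )
            values["change_to_or_maintain_bdep"] = trans.bdep_change in (
                BdepChange.TO_B, BdepChange.MAINTAIN_B,
            )
        else:
            values["change_to_or_maintain_dsr"] = None
            values["change_to_or_maintain_bdep"] = None
        for name, val in values.items():
            preds.setdefault(name, {})[pid] = val
    return preds


def association_report(
    cohort: CohortTables,
    calls: Mapping[tuple, PhenotypeCall],
    outcome_labels: Iterable,
    dsa_threshold: float = DSA_MFI_THRESHOLD,
    pcr_threshold: float = PCR_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """2×2 associations of every predictor with graft failure and ΔeGFR class.

    Returns one DataFrame per outcome with columns
    predictor, a, b, c, d (TP/FP/FN/TN), fisher_p and the four confusion
    metrics.  Predictors with a single observed level are skipped.
    """
    from .trajectory import Outcome

    labels = {l.patient_id: l.label for l in outcome_labels}
    outcomes = {
        "graft_failure": {
            p.patient_id: p.graft_failed for p in cohort.patients
        },
        "deteriorating": {
            pid: lab is Outcome.DETERIORATING for pid, lab in labels.items()
        },
    }
    preds = _predictor_values(cohort, calls, dsa_threshold, pcr_threshold)

    reports = {}
    for outcome_name, outcome_map in outcomes.items():
        rows = []
        for pred_name, pred_map in preds.items():
            pids = [
                pid
                for pid in pred_map
                if pred_map[pid] is not None and pid in outcome_map
            ]
            if not pids:
                continue
            pred_vals = [pred_map[pid] for pid in pids]
            out_vals = [outcome_map[pid] for pid in pids]
            if len(set(pred_vals)) < 2 or len(set(out_vals)) < 2:
                warnings.warn(
                    f"skipping {pred_name} vs {outcome_name}: single level",
                    stacklevel=2,
                )
                continue
            a = sum(1 for p, o in zip(pred_vals, out_vals) if p and o)
            b = sum(1 for p, o in zip(pred_vals, out_vals) if p and not o)
            c = sum(1 for p, o in zip(pred_vals, out_vals) if not p and o)
            d = sum(1 for p, o in zip(pred_vals, out_vals) if not p and not o)
            fisher = fisher_exact_2x2([[a, b], [c, d]])
            cm = confusion_metrics([[a, b], [c, d]])
            rows.append(
                {
                    "predictor": pred_name, "a": a, "b": b, "c": c, "d": d,
                    "fisher_p": fisher.p_value,
                    "sens": cm.sensitivity, "spec": cm.specificity,
                    "ppv": cm.ppv, "npv": cm.npv,
                }
            )
        reports[outcome_name] = pd.DataFrame(
            rows,
            columns=["predictor", "a", "b", "c", "d", "fisher_p",
                     "sens", "spec", "ppv", "npv"],
        )
    return reports
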