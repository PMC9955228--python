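"""Statistical validation battery for head-deviation measurements.

Implements the comparisons used to validate a new severity score against
clinical comparators on a control/torticollis cohort:

* inter-method / inter-rater reliability via the two-way mixed single-measure
  intraclass correlation ICC(3,1) (Shrout–Fleiss), with F-based 95% CI and
  p-value, and the absolute-agreement variant ICC(2,1) behind a flag;
* Pearson product-moment correlation;
* the Mann–Whitney U test (exact by enumeration for small samples, normal
  approximation with tie and continuity corrections otherwise);
* empirical ROC analysis with the cut-off placed where the sensitivity and
  specificity curves cross (linear interpolation between thresholds);
* per-group summaries of absolute values (measurements are signed by
  direction, so group moments are reported on magnitudes);
* minimum per-group sample size for a two-sample t test at a given effect
  size, via the noncentral t power function.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, StatsError

__all__ = [
    "ICCResult",
    "ROCResult",
    "ValidationSpec",
    "absolute_summary",
    "icc_3_1",
    "pearson_r",
    "mann_whitney_u",
    "roc_analysis",
    "sample_size_t",
    "validate_cohort_table",
    "run_validation",
    "report_markdown",
]

CONTROL, TORTICOLLIS = "control", "torticollis"


# ---------------------------------------------------------------------------
# elementary summaries

def absolute_summary(values) -> tuple[float, float]:
    """Mean and sample SD (n−1 denominator) of the absolute values.

    Signed angle measurements point left or right depending on the affected
    side; group-level moments are therefore taken on magnitudes.
    """
    v = np.abs(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise StatsError("absolute_summary of an empty sample")
    if v.size < 2:
        raise StatsError("sample SD needs at least two values")
    return float(v.mean()), float(v.std(ddof=1))


# ---------------------------------------------------------------------------
# reliability

@dataclass
class ICCResult:
    icc: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def icc_3_1(data, absolute_agreement: bool = False) -> ICCResult:
    """Single-measure intraclass correlation from an n×k subjects-by-raters matrix.

    Default is the two-way mixed consistency coefficient ICC(3,1) =
    (MSR − MSE) / (MSR + (k−1)·MSE); ``absolute_agreement=True`` gives the
    two-way random absolute-agreement ICC(2,1). The 95% CI comes from the F
    bounds on MSR/MSE and the p-value from the F test of MSR against MSE
    (null: no subject effect, ICC = 0).

    With zero total variance the coefficient is defined as 1 (identical
    constant columns agree perfectly) with a degenerate CI.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise StatsError("ICC needs a 2D subjects-by-raters matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise StatsError(f"ICC needs at least 3 subjects and 2 raters, got {n}x{k}")
    if not np.all(np.isfinite(X)):
        raise StatsError("ICC matrix has missing or non-finite cells")

    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ssr = k * float(((row_m - grand) ** 2).sum())        # subjects
    ssc = n * float(((col_m - grand) ** 2).sum())        # raters
    sse = float(((X - row_m[:, None] - col_m[None, :] + grand) ** 2).sum())  # residual
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if ssr + ssc + sse < 1e-24:
        return ICCResult(1.0, float("nan"), float("nan"), float("nan"), n, k, degenerate=True)

    if absolute_agreement:  # ICC(2,1)
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom
    else:  # ICC(3,1)
        icc = (msr - mse) / (msr + (k - 1) * mse)

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0.0:
        return ICCResult(float(icc), float(icc), float(icc), 0.0, n, k, degenerate=True)
    F = msr / mse
    p = float(stats.f.sf(F, df1, df2))
    # F-distribution CI for the consistency coefficient (Shrout & Fleiss)
    fl = F / stats.f.ppf(0.975, df1, df2)
    fu = F * stats.f.ppf(0.975, df2, df1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(lo), float(hi), p, n, k)


# ---------------------------------------------------------------------------
# correlation

def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise StatsError("pearson_r needs equal-length samples")
    if x.size < 3:
        raise StatsError("pearson_r needs at least 3 pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise StatsError("pearson_r is undefined for a constant sample")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Mann–Whitney U

_EXACT_LIMIT = 12  # combined size up to which the permutation null is enumerated


def _u_min(pooled_ranks: np.ndarray, idx_a, n1: int, n2: int) -> float:
    r1 = float(pooled_ranks[list(idx_a)].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return min(u1, n1 * n2 - u1)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann–Whitney U with a two-sided p-value.

    U is the smaller of the two rank-sum statistics (midranks for ties).
    For combined samples of at most 12 observations the p-value is exact:
    every C(n1+n2, n1) group labeling of the pooled values is enumerated and
    p = P(min-U ≤ observed). Larger samples use the normal approximation
    with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise StatsError("mann_whitney_u needs two non-empty samples")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_min(ranks, range(n1), n1, n2)

    N = n1 + n2
    if N <= _EXACT_LIMIT:
        count = sum(
            1
            for idx in itertools.combinations(range(N), n1)
            if _u_min(ranks, idx, n1, n2) <= u_obs + 1e-12
        )
        p = count / math.comb(N, n1)
        return u_obs, float(p)

    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var == 0.0:  # all values identical
        return u_obs, 1.0
    z = (u_obs - mean + 0.5) / math.sqrt(var)  # U ≤ mean by construction
    p = min(1.0, 2.0 * float(stats.norm.cdf(z)))
    return u_obs, p


# ---------------------------------------------------------------------------
# ROC

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC of a severity score against binary disease labels.

    A case is called positive when its score is ≥ the threshold. Thresholds
    are the distinct observed scores (ascending) plus one sentinel above the
    maximum, so sensitivity runs from 1 down to 0 and specificity from 0 up
    to 1. AUC is computed by pair counting with ties worth 0.5 — identical
    to U/(n1·n2). The cut-off is the threshold where the piecewise-linear
    sensitivity and specificity curves cross, by linear interpolation
    between adjacent thresholds, so sensitivity = specificity there.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.size != y.size:
        raise StatsError("scores and labels must be equal length")
    if set(np.unique(y)) - {0, 1}:
        raise StatsError("labels must be 0 (control) or 1 (case)")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise StatsError("ROC needs both classes present")

    uniq = np.unique(s)
    sentinel = uniq[-1] + max(1.0, uniq[-1] - uniq[0])
    thr = np.append(uniq, sentinel)
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])

    # AUC by pair counting: P(pos > neg) + 0.5 P(pos = neg)
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    auc = (gt + 0.5 * eq) / (pos.size * neg.size)

    d = sens - spec  # starts at +1 (t below min), ends at −1
    cutoff = sens_c = spec_c = None
    for i in range(len(thr) - 1):
        if d[i] == 0.0:
            cutoff, sens_c, spec_c = thr[i], sens[i], spec[i]
            break
        if d[i] > 0 >= d[i + 1]:
            w = d[i] / (d[i] - d[i + 1])
            cutoff = thr[i] + w * (thr[i + 1] - thr[i])
            sens_c = sens[i] + w * (sens[i + 1] - sens[i])
            spec_c = spec[i] + w * (spec[i + 1] - spec[i])
            break
    if cutoff is None:  # d is +1 then jumps to −1 at the sentinel edge
        cutoff, sens_c, spec_c = thr[-1], sens[-1], spec[-1]
    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        cutoff=float(cutoff),
        sens_at_cutoff=float(sens_c),
        spec_at_cutoff=float(spec_c),
    )


# ---------------------------------------------------------------------------
# sample size

def sample_size_t(
    effect_size_d: float, alpha: float = 0.05, power: float = 0.80, tails: int = 1
) -> int:
    """Smallest per-group n for a two-sample t test to reach the given power.

    Iterates n upward, evaluating achieved power from the noncentral t
    distribution with noncentrality d·sqrt(n/2) and 2n−2 degrees of freedom.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise StatsError("alpha and power must lie in (0, 1)")
    if effect_size_d <= 0:
        raise StatsError("effect size must be positive")
    if tails not in (1, 2):
        raise StatsError("tails must be 1 or 2")

    def achieved(n: int) -> float:
        df = 2 * n - 2
        nc = effect_size_d * math.sqrt(n / 2.0)
        if tails == 1:
            tcrit = stats.t.ppf(1 - alpha, df)
            return float(1 - stats.nct.cdf(tcrit, df, nc))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))

    for n in range(2, 1_000_000):
        if achieved(n) >= power:
            return n
    raise StatsError("requested power unreachable")


# ---------------------------------------------------------------------------
# cohort-level driver

def validate_cohort_table(table: pd.DataFrame, group_column: str = "group") -> None:
    if "subject_id" not in table.columns or group_column not in table.columns:
        raise SchemaError("cohort table needs subject_id and group columns")
    if table["subject_id"].duplicated().any():
        raise SchemaError("subject_ids must be unique")
    if table[group_column].isna().any():
        raise SchemaError("every row needs a group label")
    bad = set(table[group_column].unique()) - {CONTROL, TORTICOLLIS}
    if bad:
        raise SchemaError(f"unknown group labels: {sorted(bad)}")
    value_cols = [c for c in table.columns if c not in ("subject_id", group_column)]
    if not value_cols:
        raise SchemaError("cohort table needs at least one measurement column")


@dataclass
class ValidationSpec:
    """Which column comparisons the validation report runs.

    Defaults mirror the clinical study design: reliability between the two
    goniometer raters, each rater vs still photography, each rater vs the
    scanner roll angle; correlation of each comparator with the 3D angle;
    group difference per measurement column; ROC on the 3D angle.
    """

    icc_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("goniometer_1", "goniometer_2"),
            ("goniometer_1", "still_photo"),
            ("goniometer_2", "still_photo"),
            ("goniometer_1", "roll"),
            ("goniometer_2", "roll"),
        ]
    )
    pearson_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("goniometer_1", "angle3d"),
            ("goniometer_2", "angle3d"),
            ("still_photo", "angle3d"),
        ]
    )
    roc_column: str = "angle3d"
    group_column: str = "group"
    positive_group: str = TORTICOLLIS
    correlation_rows: str = "all"  # "all" or one group label


def run_validation(cohort: pd.DataFrame, spec: ValidationSpec | None = None) -> dict:
    """Run the full battery on a cohort table; returns a JSON-serializable dict.

    All comparisons run on absolute values, matching how signed clinical
    angles are summarized. The ROC treats the configured positive group as
    cases. A single-group cohort gets an explicit error entry in the ROC
    section instead of a result.
    """
    spec = spec or ValidationSpec()
    validate_cohort_table(cohort, spec.group_column)
    needed = {c for p in spec.icc_pairs + spec.pearson_pairs for c in p} | {spec.roc_column}
    missing = sorted(needed - set(cohort.columns))
    if missing:
        raise SchemaError(f"cohort table is missing columns: {', '.join(missing)}")

    absd = cohort.copy()
    value_cols = [c for c in cohort.columns if c not in ("subject_id", spec.group_column)]
    absd[value_cols] = absd[value_cols].abs()

    report: dict = {"n_rows": int(len(cohort))}

    report["icc"] = {}
    for a, b in spec.icc_pairs:
        r = icc_3_1(absd[[a, b]].to_numpy())
        report["icc"][f"{a}|{b}"] = {
            "icc": r.icc, "ci95_low": r.ci95_low, "ci95_high": r.ci95_high,
            "p_value": r.p_value, "n_subjects": r.n_subjects,
        }

    rows = absd if spec.correlation_rows == "all" else absd[absd[spec.group_column] == spec.correlation_rows]
    report["pearson"] = {}
    for a, b in spec.pearson_pairs:
        r, p = pearson_r(rows[a], rows[b])
        report["pearson"][f"{a}|{b}"] = {"r": r, "p_value": p, "n": int(len(rows))}

    groups = absd.groupby(spec.group_column)
    report["group_summary"] = {
        g: {c: dict(zip(("abs_mean", "abs_sd"), absolute_summary(sub[c]))) for c in value_cols}
        for g, sub in groups
    }

    report["mann_whitney"] = {}
    labels = set(absd[spec.group_column].unique())
    if len(labels) == 2:
        pos = absd[absd[spec.group_column] == spec.positive_group]
        negg = absd[absd[spec.group_column] != spec.positive_group]
        for c in value_cols:
            u, p = mann_whitney_u(pos[c], negg[c])
            report["mann_whitney"][c] = {"U": u, "p_value": p}
        roc = roc_analysis(
            absd[spec.roc_column],
            (absd[spec.group_column] == spec.positive_group).astype(int),
        )
        report["roc"] = {
            "column": spec.roc_column,
            "auc": roc.auc,
            "cutoff": roc.cutoff,
            "sens_at_cutoff": roc.sens_at_cutoff,
            "spec_at_cutoff": roc.spec_at_cutoff,
        }
    else:
        report["roc"] = {"error": "ROC and group tests need both groups present"}
    return report


def _fmt_p(p: float) -> str:
    if p != p:
        return "n/a"
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    return f"{p:.3f}"


def report_markdown(report: dict) -> str:
    """Human-readable rendering of a run_validation report."""
    lines = ["# Cohort validation report", ""]
    lines += ["## Reliability (ICC 3,1)", "", "| pair | ICC | 95% CI | p |", "|---|---|---|---|"]
    for pair, r in report["icc"].items():
        lines.append(
            f"| {pair} | {r['icc']:.3f} | {r['ci95_low']:.3f}-{r['ci95_high']:.3f} | {_fmt_p(r['p_value'])} |"
        )
    lines += ["", "## Correlation (Pearson, absolute values)", "", "| pair | r | p |", "|---|---|---|"]
    for pair, r in report["pearson"].items():
        lines.append(f"| {pair} | {r['r']:.3f} | {_fmt_p(r['p_value'])} |")
    lines += ["", "## Group summary (mean ± SD of absolute values, degrees)", ""]
    header = sorted({c for g in report["group_summary"].values() for c in g})
    lines += ["| group | " + " | ".join(header) + " |", "|" + "---|" * (len(header) + 1)]
    for g, cols in report["group_summary"].items():
        cells = [f"{cols[c]['abs_mean']:.2f} ± {cols[c]['abs_sd']:.2f}" for c in header]
        lines.append(f"| {g} | " + " | ".join(cells) + " |")
    lines += ["", "## Group difference (Mann–Whitney U)", "", "| measurement | U | p |", "|---|---|---|"]
    for c, r in report.get("mann_whitney", {}).items():
        lines.append(f"| {c} | {r['U']:.1f} | {_fmt_p(r['p_value'])} |")
    lines += ["", "## ROC", ""]
    roc = report["roc"]
    if "error" in roc:
        lines.append(f"ROC not computed: {roc['error']}")
    else:
        lines += [
            f"Score column: {roc['column']}",
            f"AUC = {roc['auc']:.3f}; cut-off = {roc['cutoff']:.3f} deg "
            f"(score ≥ cut-off called positive); sensitivity = {roc['sens_at_cutoff']:.3f}, "
            f"specificity = {roc['spec_at_cutoff']:.3f}",
        ]
    return "\n".join(lines) + "\n"
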