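"""Group comparisons and ROC/Youden classification of vibratory parameters.

The workflow reproduces a standard clinical-study analysis:

1. **Normality routing.**  Shapiro-Wilk per group at ``alpha``; if every
   group looks Gaussian the comparison is parametric (two-sample t test /
   one-way ANOVA), otherwise non-parametric (Mann-Whitney U /
   Kruskal-Wallis).  A single failing group routes the whole comparison
   non-parametric.
2. **Post hoc tests** after a three-group omnibus: Fisher's least
   significant difference (LSD) on the parametric route, Dunn's rank-based
   test with Bonferroni adjustment on the non-parametric route.
3. **ROC analysis** in two variants — normophonic vs any organic lesion,
   and benign vs malignant — for every parameter.  Each parameter is
   oriented as a *booster* (values rise with disease risk) or *inhibitor*
   (values fall with risk) so that the reported AUC is always >= 0.5.
   AUC confidence intervals and the p-value against AUC = 0.5 use DeLong's
   covariance method.
4. **Youden cut-points.**  The operating threshold maximizes
   ``J = sensitivity + specificity - 1`` over all candidate thresholds
   (midpoints between consecutive distinct values plus the infinities).

Sensitivities and specificities are reported as fractions in [0, 1];
formatting as percentages is left to rendering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "TestResult",
    "ROCResult",
    "CutPoint",
    "StudyReport",
    "compare_groups",
    "posthoc_pairwise",
    "roc_analysis",
    "youden_cutpoint",
    "youden_index",
    "run_study",
]


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------

@dataclass
class TestResult:
    """Outcome of one hypothesis test on one parameter."""

    parameter: str
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    n: dict[str, int]
    means: dict[str, float]
    medians: dict[str, float]
    route: str  # "parametric" | "nonparametric"
    adjusted_p: float | None = None


def _group_values(
    table: pd.DataFrame, parameter: str, groups: tuple[str, ...]
) -> dict[str, np.ndarray]:
    if parameter not in table.columns:
        raise ValidationError(f"parameter {parameter!r} not in table")
    out = {}
    for g in groups:
        vals = table.loc[table["diagnosis"] == g, parameter].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValidationError(f"group {g!r} is empty for {parameter!r}")
        out[g] = vals
    return out


def _route(samples: list[np.ndarray], alpha: float) -> str:
    """Shapiro-Wilk routing: any non-Gaussian group -> nonparametric."""
    for x in samples:
        if len(x) < 3:
            raise ValidationError("Shapiro-Wilk needs n >= 3 per group")
        if np.ptp(x) == 0:  # constant sample: W undefined, clearly non-Gaussian
            return "nonparametric"
        if sps.shapiro(x).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    groups: tuple[str, ...],
    alpha: float = 0.05,
) -> TestResult:
    """Normality-routed two- or three-group comparison of one parameter.

    Two groups: t test (parametric) or Mann-Whitney U.  Three or more:
    one-way ANOVA or Kruskal-Wallis.  The result records which route the
    Shapiro-Wilk screening selected.
    """
    data = _group_values(table, parameter, tuple(groups))
    samples = list(data.values())
    route = _route(samples, alpha)
    if len(samples) == 2:
        if route == "parametric":
            res = sps.ttest_ind(*samples)
            name = "T"
        else:
            res = sps.mannwhitneyu(*samples, alternative="two-sided")
            name = "U Mann-Whitney"
    else:
        if route == "parametric":
            res = sps.f_oneway(*samples)
            name = "one-way ANOVA"
        else:
            res = sps.kruskal(*samples)
            name = "Kruskal-Wallis"
    return TestResult(
        parameter=parameter,
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=tuple(groups),
        n={g: len(v) for g, v in data.items()},
        means={g: float(v.mean()) for g, v in data.items()},
        medians={g: float(np.median(v)) for g, v in data.items()},
        route=route,
    )


def _fisher_lsd(samples: dict[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Pairwise t tests on the pooled ANOVA error term (unadjusted)."""
    groups = list(samples)
    n_total = sum(len(v) for v in samples.values())
    k = len(groups)
    mse = sum(
        ((v - v.mean()) ** 2).sum() for v in samples.values()
    ) / (n_total - k)
    df = n_total - k
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[groups[i]], samples[groups[j]]
            se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
            t = (a.mean() - b.mean()) / se
            p = 2.0 * sps.t.sf(abs(t), df)
            out.append((groups[i], groups[j], float(t), float(p)))
    return out


def _dunn(samples: dict[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Dunn's rank-based multiple comparison z tests (unadjusted p)."""
    groups = list(samples)
    all_vals = np.concatenate([samples[g] for g in groups])
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in groups:
        m = len(samples[g])
        mean_ranks[g] = ranks[start : start + m].mean()
        sizes[g] = m
        start += m
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            out.append((a, b, float(z), float(p)))
    return out


def posthoc_pairwise(
    table: pd.DataFrame,
    parameter: str,
    groups: tuple[str, ...],
    route: str,
    omnibus_p: float | None = None,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Pairwise post hoc comparisons after a three-group omnibus test.

    Parametric route: Fisher LSD (unadjusted pairwise t tests on the pooled
    error term, valid after a significant ANOVA).  Non-parametric route:
    Dunn's test with Bonferroni adjustment.  Running post hocs after a
    non-significant omnibus only triggers a warning.
    """
    if len(groups) < 3:
        raise ValidationError("post hoc tests require at least 3 groups")
    if omnibus_p is not None and omnibus_p >= alpha:
        warnings.warn(
            f"post hoc tests run although omnibus p={omnibus_p:.3g} >= {alpha}",
            stacklevel=2,
        )
    data = _group_values(table, parameter, tuple(groups))
    if route == "parametric":
        pairs = _fisher_lsd(data)
        name = "Fisher LSD"
        n_comp = 1  # LSD is by construction unadjusted
    else:
        pairs = _dunn(data)
        name = "Dunn"
        n_comp = len(pairs)
    results = []
    for a, b, stat, p in pairs:
        results.append(
            TestResult(
                parameter=parameter,
                test=name,
                statistic=stat,
                p_value=p,
                groups=(a, b),
                n={g: len(data[g]) for g in (a, b)},
                means={g: float(data[g].mean()) for g in (a, b)},
                medians={g: float(np.median(data[g])) for g in (a, b)},
                route=route,
                adjusted_p=min(p * n_comp, 1.0),
            )
        )
    return results


# --------------------------------------------------------------------------
# ROC / Youden
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Oriented ROC curve of one parameter for one study variant."""

    parameter: str
    variant: str
    orientation: str  # "booster" | "inhibitor"
    auc: float
    ci: tuple[float, float]
    p_value: float
    thresholds: np.ndarray  # raw parameter units
    sensitivity: np.ndarray
    specificity: np.ndarray


@dataclass
class CutPoint:
    """Youden-optimal operating point."""

    threshold: float
    j: float
    sensitivity: float
    specificity: float


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance for cases (positive) vs controls."""
    m, n = len(cases), len(controls)
    all_vals = np.concatenate([cases, controls])
    tx = _midrank(cases)
    ty = _midrank(controls)
    tz = _midrank(all_vals)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over cases
    v10 = 1.0 - (tz[m:] - ty) / m  # over controls
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_analysis(
    values: np.ndarray,
    labels: np.ndarray,
    positive_label,
    parameter: str = "",
    variant: str = "",
) -> ROCResult:
    """Oriented empirical ROC curve with DeLong CI and p-value vs 0.5.

    The orientation is chosen so the reported AUC is >= 0.5: *booster* when
    higher values indicate the positive class, *inhibitor* when lower
    values do.  Candidate thresholds are midpoints between consecutive
    distinct observed values plus the two infinities; for a booster the
    decision rule is ``value >= threshold -> positive``, for an inhibitor
    ``value <= threshold -> positive``.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if np.any(~np.isfinite(values)):
        raise ValidationError("missing values in ROC input")
    pos = labels == positive_label
    if pos.all() or not pos.any():
        raise ValidationError("ROC needs both classes present")

    cases, controls = values[pos], values[~pos]

    def oriented_curve(sign: float):
        """Empirical ROC in the given direction; value*sign >= thr -> positive."""
        distinct = np.unique(sign * values)
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        thr = np.concatenate([[-np.inf], mids, [np.inf]])
        case_sorted = np.sort(sign * cases)
        ctrl_sorted = np.sort(sign * controls)
        tp = len(cases) - np.searchsorted(case_sorted, thr, side="left")
        fp = len(controls) - np.searchsorted(ctrl_sorted, thr, side="left")
        sens = tp / len(cases)
        spec = 1.0 - fp / len(controls)
        # thresholds ascend, so TPR/FPR descend: integrate in ascending FPR
        auc = float(np.trapezoid(sens[::-1], 1.0 - spec[::-1]))
        return thr, sens, spec, auc

    thr_oriented, sens, spec, auc = oriented_curve(1.0)
    orientation = "booster"
    sign = 1.0
    if auc < 0.5:
        orientation = "inhibitor"
        sign = -1.0
        thr_oriented, sens, spec, auc = oriented_curve(-1.0)

    _, var = _delong_variance(sign * cases, sign * controls)

    if var > 0:
        se = np.sqrt(var)
        z = (auc - 0.5) / se
        p = 2.0 * sps.norm.sf(abs(z))
        ci = (max(auc - 1.959963984540054 * se, 0.0), min(auc + 1.959963984540054 * se, 1.0))
    else:  # degenerate (e.g. perfect separation on tiny n)
        p = 0.0 if auc != 0.5 else 1.0
        ci = (auc, auc)

    return ROCResult(
        parameter=parameter,
        variant=variant,
        orientation=orientation,
        auc=float(auc),
        ci=ci,
        p_value=float(p),
        thresholds=sign * thr_oriented,
        sensitivity=sens,
        specificity=spec,
    )


def youden_cutpoint(roc: ROCResult) -> CutPoint:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Among ties the smallest threshold in oriented units is chosen (smallest
    raw threshold for a booster, largest for an inhibitor), which makes the
    cut-point deterministic.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = j.max()
    tie = np.nonzero(j >= best - 1e-12)[0]
    sign = 1.0 if roc.orientation == "booster" else -1.0
    k = tie[np.argmin(sign * roc.thresholds[tie])]
    return CutPoint(
        threshold=float(roc.thresholds[k]),
        j=float(j[k]),
        sensitivity=float(roc.sensitivity[k]),
        specificity=float(roc.specificity[k]),
    )


# --------------------------------------------------------------------------
# Full study
# --------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Ordered results of the complete statistical workflow."""

    omnibus: list[TestResult]
    posthoc: dict[str, list[TestResult]]
    involved_vs_healthy: list[TestResult]
    roc: dict[str, list[tuple[ROCResult, CutPoint]]] = field(default_factory=dict)

    def roc_table(self, variant: str) -> pd.DataFrame:
        rows = []
        for roc, cut in self.roc[variant]:
            rows.append(
                {
                    "Parameter": roc.parameter,
                    "Booster/Inhibitor": roc.orientation,
                    "AUC": roc.auc,
                    "AUC lower 95%": roc.ci[0],
                    "AUC upper 95%": roc.ci[1],
                    "p value": roc.p_value,
                    "Youden index": cut.j,
                    "Cutting point": cut.threshold,
                    "Sensitivity": cut.sensitivity,
                    "Specificity": cut.specificity,
                }
            )
        return pd.DataFrame(rows)

    def omnibus_table(self) -> pd.DataFrame:
        rows = []
        for res in self.omnibus:
            for g in res.groups:
                rows.append(
                    {
                        "Parameter": res.parameter,
                        "Diagnosis": g,
                        "n": res.n[g],
                        "Mean": res.means[g],
                        "Median": res.medians[g],
                        "Test": res.test,
                        "p": res.p_value,
                    }
                )
        return pd.DataFrame(rows)


ROC_VARIANTS = {
    "norm_vs_lesion": (("norm",), ("benign", "malignant")),
    "benign_vs_malignant": (("benign",), ("malignant",)),
}


def run_study(
    table: pd.DataFrame,
    alpha: float = 0.05,
    parameters: tuple[str, ...] | None = None,
) -> StudyReport:
    """Run the full statistical workflow on a cohort parameter table.

    ``table`` needs a ``diagnosis`` column with labels ``norm`` / ``benign``
    / ``malignant`` plus one column per parameter.  For every parameter:
    three-group omnibus comparison and post hoc pairs; involved-vs-healthy
    amplitude comparisons within the benign and malignant groups; and both
    ROC variants with Youden cut-points, sorted by descending AUC.
    Parameters unavailable for a variant (per-fold amplitudes are undefined
    for normophonic subjects) are skipped in that variant.
    """
    if "diagnosis" not in table.columns:
        raise ValidationError("cohort table lacks a 'diagnosis' column")
    if parameters is None:
        from .stv import PARAMETER_NAMES

        parameters = tuple(p for p in PARAMETER_NAMES if p in table.columns)

    three = ("norm", "benign", "malignant")
    per_fold = {"AmpInvolvedAvg", "AmpHealthyAvg"}

    omnibus: list[TestResult] = []
    posthoc: dict[str, list[TestResult]] = {}
    for param in parameters:
        groups = ("benign", "malignant") if param in per_fold else three
        res = compare_groups(table, param, groups, alpha=alpha)
        omnibus.append(res)
        if len(groups) == 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                posthoc[param] = posthoc_pairwise(
                    table, param, groups, res.route, omnibus_p=res.p_value, alpha=alpha
                )

    involved_vs_healthy: list[TestResult] = []
    for group in ("benign", "malignant"):
        sub = table[table["diagnosis"] == group]
        if {"AmpInvolvedAvg", "AmpHealthyAvg"} <= set(sub.columns) and len(sub) >= 3:
            long = pd.DataFrame(
                {
                    "diagnosis": ["involved"] * len(sub) + ["healthy"] * len(sub),
                    "amplitude": np.concatenate(
                        [sub["AmpInvolvedAvg"].to_numpy(), sub["AmpHealthyAvg"].to_numpy()]
                    ),
                }
            )
            res = compare_groups(long, "amplitude", ("involved", "healthy"), alpha=alpha)
            res.parameter = f"AmpInvolvedAvg vs AmpHealthyAvg ({group})"
            involved_vs_healthy.append(res)

    roc: dict[str, list[tuple[ROCResult, CutPoint]]] = {}
    for variant, (neg_groups, pos_groups) in ROC_VARIANTS.items():
        mask = table["diagnosis"].isin(neg_groups + pos_groups)
        labels = np.where(table.loc[mask, "diagnosis"].isin(pos_groups), 1, 0)
        results = []
        for param in parameters:
            vals = table.loc[mask, param].to_numpy(float)
            if np.any(~np.isfinite(vals)):
                continue
            r = roc_analysis(vals, labels, 1, parameter=param, variant=variant)
            results.append((r, youden_cutpoint(r)))
        results.sort(key=lambda rc: rc[0].auc, reverse=True)
        roc[variant] = results

    return StudyReport(
        omnibus=omnibus,
        posthoc=posthoc,
        involved_vs_healthy=involved_vs_healthy,
        roc=roc,
    )
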