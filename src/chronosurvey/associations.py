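"""Statistical battery over the merged subject table.

Covers the analyses run against chronotype scores: Pearson correlations for
continuous covariates, Student t tests for binary factors, one-way ANOVA
with Tukey HSD post-hoc contrasts for multi-level factors, equal-count
binned trend profiles with polynomial fits, and the lipid-biomarker
contrasts across extreme-chronotype categories.

Conventions
-----------
* "Student t test" is the pooled-variance two-sample t; Welch is available
  behind ``equal_var=False``.
* Tukey HSD uses the studentized-range distribution with the Tukey-Kramer
  unequal-n adjustment (statsmodels).
* No multiple-testing correction is applied across the battery; every
  p value is reported as-is.
* Missing data are handled complete-case per analysis, and every analysis
  reports the rows it used so exclusion counts always reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .normalization import CATEGORY_EARLY, CATEGORY_LATE, CATEGORY_NON_EXTREME

__all__ = [
    "TestResult",
    "pearson",
    "group_compare",
    "binned_profile",
    "biomarker_contrast",
    "AssociationBattery",
    "BatteryResults",
]


@dataclass
class TestResult:
    """Outcome of one statistical comparison.

    ``estimate`` is the Pearson r for correlations, or the difference in
    group means (first listed group minus second) for two-group contrasts.
    ``pairwise`` holds the Tukey HSD table for ANOVA contrasts.
    """

    kind: str
    statistic: float
    p_value: float
    estimate: float
    n: dict
    groups: tuple = ()
    pairwise: Optional[pd.DataFrame] = None
    notes: str = ""

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p value out of range: {self.p_value}")


def _complete(*cols):
    arrs = [np.asarray(c, dtype=float) for c in cols]
    mask = np.logical_and.reduce([np.isfinite(a) for a in arrs])
    return [a[mask] for a in arrs], int(mask.sum())


def pearson(x, y) -> TestResult:
    """Pearson correlation with a two-sided p from the t transform.

    Computed from the product-moment definition:
    ``r = cov(x, y) / (sd(x) * sd(y))`` over complete pairs, then
    ``t = r * sqrt((n-2) / (1-r^2))`` referred to a t distribution with
    n - 2 degrees of freedom.
    """
    (xa, ya), n = _complete(x, y)
    if n < 3:
        raise ValueError(f"Pearson correlation needs >= 3 complete pairs, got {n}")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return TestResult("pearson", statistic=r, p_value=float(p), estimate=r, n={"pairs": n})


def group_compare(values, groups, method: str = "ttest",
                  equal_var: bool = True) -> TestResult:
    """Compare a response across groups.

    ``method="ttest"`` runs the two-sample Student t (pooled variance by
    default; ``equal_var=False`` switches to Welch) and reports the mean
    difference (first group label in sorted order minus second).
    ``method="anova_tukey"`` runs one-way ANOVA plus a Tukey HSD pairwise
    matrix with family-wise error control.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    mask = np.isfinite(values) & pd.notna(groups)
    values, groups = values[mask], groups[mask]
    labels = sorted(set(groups), key=str)
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("each of >= 2 groups needs at least 2 observations")
    ns = {str(g): int(len(s)) for g, s in zip(labels, samples)}
    notes = ""
    if any(s.std(ddof=1) == 0 and len(s) == 2 for s in samples):
        notes = "zero-variance group with n=2"

    if method == "ttest":
        if len(labels) != 2:
            raise ValueError(f"ttest needs exactly 2 groups, got {len(labels)}")
        stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        est = float(samples[0].mean() - samples[1].mean())
        return TestResult("ttest", float(stat), float(p), est, ns,
                          groups=tuple(labels), notes=notes)
    if method == "anova_tukey":
        stat, p = stats.f_oneway(*samples)
        tukey = pairwise_tukeyhsd(values, groups.astype(str))
        pw = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
        grand = [s.mean() for s in samples]
        return TestResult("anova_tukey", float(stat), float(p),
                          float(max(grand) - min(grand)), ns,
                          groups=tuple(labels), pairwise=pw, notes=notes)
    raise ValueError(f"unknown method: {method}")


def binned_profile(x, y, n_bins: int = 16, poly_order: int = 4):
    """Equal-count binned mean +/- SD profile plus a polynomial trend.

    Bins contain (as nearly as possible) equal numbers of points, ordered by
    ``x``; the polynomial (default order 4) is least-squares fitted through
    the raw points, not the bin summaries.

    Returns ``(profile, coeffs)`` where ``profile`` is a DataFrame with
    columns ``bin_centre`` (mean of x in the bin), ``mean``, ``sd``, ``n``
    and ``coeffs`` are polynomial coefficients, highest order first.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    (xa, ya), n = _complete(x, y)
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} complete pairs, got {n}")
    order = np.argsort(xa, kind="stable")
    idx = np.array_split(order, n_bins)
    rows = [
        {
            "bin_centre": float(xa[i].mean()),
            "mean": float(ya[i].mean()),
            "sd": float(ya[i].std(ddof=1)) if len(i) > 1 else 0.0,
            "n": int(len(i)),
        }
        for i in idx
    ]
    coeffs = np.polyfit(xa, ya, deg=poly_order)
    return pd.DataFrame(rows), coeffs


def biomarker_contrast(table: pd.DataFrame, category_col: str = "category",
                       log: Optional[list] = None) -> dict:
    """Lipid-biomarker contrasts across extreme-chronotype categories.

    Runs, on the subjects with biomarker values:

    * one-way ANOVA + Tukey of HDL and of LDL across the three chronotype
      categories;
    * Student t of the LDL/HDL ratio between extremely early and extremely
      late subjects;
    * sex-stratified extreme (either tail) vs non-extreme t tests of HDL.

    Strata with fewer than 2 observations are skipped with a log entry.
    """
    log = log if log is not None else []
    out: dict[str, TestResult] = {}
    df = table.copy()
    df["ldl_hdl_ratio"] = df["ldl"] / df["hdl"]

    def _try(name, fn):
        try:
            out[name] = fn()
        except ValueError as exc:
            log.append(f"{name}: skipped ({exc})")

    for marker in ("hdl", "ldl"):
        sub = df.dropna(subset=[marker, category_col])
        _try(f"{marker}_by_category",
             lambda s=sub, m=marker: group_compare(s[m], s[category_col], "anova_tukey"))

    extremes = df[df[category_col].isin([CATEGORY_EARLY, CATEGORY_LATE])]
    sub = extremes.dropna(subset=["ldl_hdl_ratio", category_col])
    _try("ldl_hdl_ratio_early_vs_late",
         lambda s=sub: group_compare(s["ldl_hdl_ratio"], s[category_col], "ttest"))

    df["is_extreme"] = np.where(
        df[category_col].isin([CATEGORY_EARLY, CATEGORY_LATE]), "extreme",
        np.where(df[category_col] == CATEGORY_NON_EXTREME, "non_extreme", None),
    )
    for sex in ("men", "women"):
        sub = df[(df["sex"] == sex)].dropna(subset=["hdl", "is_extreme"])
        _try(f"hdl_extreme_vs_non_extreme_{sex}",
             lambda s=sub: group_compare(s["hdl"], s["is_extreme"], "ttest"))
    return out


#: (analysis name, response column, covariate column, kind, expected sign)
BATTERY_PLAN = [
    ("latitude_msfsc", "msfsc", "latitude", "pearson", +1),
    ("longitude_msfsc", "msfsc", "longitude", "pearson", -1),
    ("settlement_msfsc", "msfsc", "log10_settlement", "pearson", +1),
    ("outdoor_msfsc", "msfsc", "outdoor_hours_week", "pearson", -1),
    ("age_msfsc", "msfsc", "age", "pearson", -1),
    ("children_msfsc", "msfsc", "has_children_0_17", "binary", -1),
    ("partner_msfsc", "msfsc", "partner", "binary", -1),
    ("dog_msfsc", "msfsc", "dog_owner", "binary", +1),
    ("smoking_msfsc", "msfsc", "smoking_cat", "binary", +1),
    ("alcohol_msfsc", "msfsc", "alcohol_cat", "binary", +1),
    ("fruitveg_msfsc", "msfsc", "fruitveg_cat", "binary", +1),
    ("bmi_msfsasc_women", "bmi", "msfsasc", "pearson_women", +1),
]

#: Category level coded 1 in each binary contrast (the "exposed" level).
BINARY_POSITIVE = {
    "has_children_0_17": 1,
    "partner": 1,
    "dog_owner": 1,
    "smoking_cat": "smokers",
    "alcohol_cat": "high",
    "fruitveg_cat": "rarely",
}


class AssociationBattery:
    """The full set of chronotype-association analyses over a subject table.

    Construct from a merged per-subject DataFrame (scores, demographics,
    covariates, biomarkers) and call :meth:`run`.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table.copy()
        if "settlement_size" in self.table and "log10_settlement" not in self.table:
            self.table["log10_settlement"] = np.log10(self.table["settlement_size"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AssociationBattery":
        return cls(df)

    def run(self, include_biomarkers: bool = True) -> "BatteryResults":
        results: dict[str, TestResult] = {}
        log: list[str] = []
        df = self.table
        for name, resp, cov, kind, sign in BATTERY_PLAN:
            if resp not in df or cov not in df:
                log.append(f"{name}: skipped (missing column)")
                continue
            try:
                if kind == "pearson":
                    results[name] = pearson(df[cov], df[resp])
                elif kind == "pearson_women":
                    w = df[df["sex"] == "women"]
                    results[name] = pearson(w[cov], w[resp])
                elif kind == "binary":
                    positive = BINARY_POSITIVE[cov]
                    coded = np.where(df[cov] == positive, "exposed", "reference")
                    coded = np.where(pd.isna(df[cov]), None, coded)
                    res = group_compare(df[resp], coded, "ttest")
                    # estimate = exposed - reference mean difference
                    if res.groups == ("exposed", "reference"):
                        results[name] = res
                    else:
                        res.estimate = -res.estimate
                        res.groups = tuple(reversed(res.groups))
                        results[name] = res
            except ValueError as exc:
                log.append(f"{name}: skipped ({exc})")

        if "settlement_band" in df:
            try:
                results["settlement_band_msfsc"] = group_compare(
                    df["msfsc"], df["settlement_band"], "anova_tukey")
            except ValueError as exc:
                log.append(f"settlement_band_msfsc: skipped ({exc})")

        biomarkers = {}
        if include_biomarkers and {"hdl", "ldl", "category", "sex"} <= set(df.columns):
            biomarkers = biomarker_contrast(df, log=log)
        results.update(biomarkers)
        return BatteryResults(results, log, expected_signs={
            name: sign for name, *_rest, sign in BATTERY_PLAN})


class BatteryResults:
    """Results container for :class:`AssociationBattery`."""

    def __init__(self, results: dict, log: list, expected_signs: dict):
        self.results = results
        self.log = log
        self.expected_signs = expected_signs

    def __getitem__(self, name: str) -> TestResult:
        return self.results[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.results.items():
            rows.append({
                "analysis": name,
                "kind": res.kind,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "estimate": res.estimate,
                "n": sum(res.n.values()),
                "expected_sign": self.expected_signs.get(name, np.nan),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Chronotype association battery",
                 f"  analyses: {len(df)}, skipped: {len(self.log)}"]
        for _, row in df.iterrows():
            lines.append(
                f"  {row['analysis']:<34} {row['kind']:<12} "
                f"est={row['estimate']:+.4f}  p={row['p_value']:.3g}  n={row['n']}"
            )
        return "\n".join(lines)
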