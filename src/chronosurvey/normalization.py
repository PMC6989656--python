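"""Age/sex normalization of chronotype via sex-specific exponential decay.

Population chronotype (mid-sleep MSFsc) is latest around age 18-20 and
advances steadily through adulthood toward a plateau.  This module models
that trajectory per sex with a one-phase exponential decay

    MSFsc(age) = (Y0 - Plateau) * exp(-K * age) + Plateau

and uses it to normalize each subject's chronotype to a *hypothetical
chronotype at age 30* (MSFsasc), removing both the age trend and the sex
offset so that extreme chronotypes can be compared across demography.

`ChronotypeDecayModel` follows the Model/Results convention: build the
model from (age, msfsc) data, call :meth:`~ChronotypeDecayModel.fit`, and
read estimates, standard errors and diagnostics off the returned
:class:`DecayResults`.

Bundled default constants (per sex) are the published reference values for
the surveyed population:

====== ====== ======== ======
sex    Y0     Plateau  K
====== ====== ======== ======
men    9.62   2.829    0.067
women  10.69  2.947    0.089
====== ====== ======== ======
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DecayCurve",
    "DEFAULT_CURVES",
    "ChronotypeDecayModel",
    "DecayResults",
    "msfsasc",
    "categorize_deciles",
    "build_curves_from_yaml",
    "curves_to_yaml",
    "REFERENCE_AGE",
]

REFERENCE_AGE = 30.0

K_BOUNDS = (1e-4, 1.0)
PLATEAU_BOUNDS = (-12.0, 12.0)
#: Multi-start grids for the nonlinear fit.
Y0_STARTS = (6.0, 9.0, 12.0)
K_STARTS = (0.03, 0.07, 0.15)
FIT_TOL = 1e-8

CATEGORY_EARLY = "extremely_early"
CATEGORY_LATE = "extremely_late"
CATEGORY_NON_EXTREME = "non_extreme"


@dataclass(frozen=True)
class DecayCurve:
    """One-phase exponential decay of chronotype with age.

    ``y0`` is the (extrapolated) value at age 0, ``plateau`` the late-life
    asymptote, both in hours centred on midnight; ``k`` is the decay rate
    per year of age.
    """

    y0: float
    plateau: float
    k: float
    sex: str = ""

    def predict(self, age):
        """Expected chronotype (hours centred on midnight) at ``age`` years."""
        age = np.asarray(age, dtype=float)
        out = (self.y0 - self.plateau) * np.exp(-self.k * age) + self.plateau
        return out if out.ndim else float(out)


#: Published reference decay constants per sex.
DEFAULT_CURVES: Mapping[str, DecayCurve] = {
    "men": DecayCurve(9.62, 2.829, 0.067, sex="men"),
    "women": DecayCurve(10.69, 2.947, 0.089, sex="women"),
}


class ChronotypeDecayModel:
    """Nonlinear least-squares model for the chronotype-age decay.

    Parameters
    ----------
    age : array-like
        Subject ages in years (adults; >= 18 expected).
    msfsc : array-like
        Sleep-debt corrected mid-sleep, hours centred on midnight.
    sex : str
        Label carried through to the fitted curve (e.g. ``"men"``).

    The model requires at least 30 observations spanning at least 20 years
    of age, otherwise the three parameters are not jointly identifiable in
    practice.
    """

    MIN_N = 30
    MIN_AGE_SPAN = 20.0

    def __init__(self, age, msfsc, sex: str = ""):
        age = np.asarray(age, dtype=float)
        msfsc = np.asarray(msfsc, dtype=float)
        mask = np.isfinite(age) & np.isfinite(msfsc)
        self.age = age[mask]
        self.msfsc = msfsc[mask]
        self.sex = sex
        if self.age.size < self.MIN_N:
            raise ValueError(f"need >= {self.MIN_N} (age, msfsc) pairs, got {self.age.size}")
        if np.ptp(self.age) < self.MIN_AGE_SPAN:
            raise ValueError(
                f"ages span {np.ptp(self.age):.1f} y; >= {self.MIN_AGE_SPAN} y required"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_col: str = "age",
                       msfsc_col: str = "msfsc", sex: str = "") -> "ChronotypeDecayModel":
        return cls(df[age_col], df[msfsc_col], sex=sex)

    # -- fitting ---------------------------------------------------------

    def _starts(self):
        oldest = self.age >= np.quantile(self.age, 0.9)
        plateau0 = float(np.quantile(self.msfsc[oldest], 0.10))
        for y0 in Y0_STARTS:
            for k in K_STARTS:
                yield np.array([y0, plateau0, k])

    def fit(self) -> "DecayResults":
        """Fit (Y0, Plateau, K) by multi-start bounded least squares.

        Raises :class:`RuntimeError` (carrying the best residual norm) when
        no start converges, e.g. for constant data where K is
        unidentifiable.
        """
        if np.ptp(self.msfsc) < 1e-12:
            raise RuntimeError(
                f"constant response (plateau = {self.msfsc[0]:.4g}): "
                "decay rate K is unidentifiable"
            )
        lo = [-24.0, PLATEAU_BOUNDS[0], K_BOUNDS[0]]
        hi = [24.0, PLATEAU_BOUNDS[1], K_BOUNDS[1]]

        def resid(theta):
            y0, plateau, k = theta
            return (y0 - plateau) * np.exp(-k * self.age) + plateau - self.msfsc

        best = None
        for x0 in self._starts():
            try:
                sol = optimize.least_squares(
                    resid, x0, bounds=(lo, hi), xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL
                )
            except Exception:  # pragma: no cover - scipy internal failure
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError("decay fit did not converge from any start")

        # K pinned at its lower bound means the decay is unidentifiable
        # (e.g. constant response): refuse to report a sham rate.
        if best.x[2] <= K_BOUNDS[0] * (1 + 1e-6):
            raise RuntimeError(
                "decay rate K unidentifiable (pinned at lower bound); "
                f"best residual norm {np.sqrt(2 * best.cost):.4g}"
            )

        n, p = self.age.size, 3
        dof = n - p
        resid_vec = best.fun
        sigma2 = float(resid_vec @ resid_vec) / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = sigma2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        return DecayResults(self, best.x, cov, resid_vec, dof)


class DecayResults:
    """Fit results for :class:`ChronotypeDecayModel`.

    Attributes
    ----------
    params : ndarray
        Fitted ``[y0, plateau, k]``.
    bse : ndarray
        Asymptotic standard errors from the Gauss-Newton covariance.
    curve : DecayCurve
        The fitted curve, usable directly for prediction/normalization.
    """

    param_names = ("y0", "plateau", "k")

    def __init__(self, model, params, cov, resid, dof):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = np.asarray(cov, dtype=float)
        self.resid = np.asarray(resid, dtype=float)
        self.df_resid = dof
        self.bse = np.sqrt(np.diag(self.cov_params))
        self.curve = DecayCurve(*self.params, sex=model.sex)

    @property
    def nobs(self) -> int:
        return self.model.age.size

    def predict(self, age):
        return self.curve.predict(age)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald confidence intervals, rows ordered (y0, plateau, k)."""
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Chronotype-age exponential decay fit"
            + (f" ({self.model.sex})" if self.model.sex else ""),
            f"  n = {self.nobs}, residual SD = {np.sqrt(self.resid @ self.resid / self.df_resid):.4f} h",
            f"  {'param':<8}{'estimate':>10}{'std err':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        for name, est, se, (lo, hi) in zip(self.param_names, self.params, self.bse, ci):
            lines.append(f"  {name:<8}{est:>10.4f}{se:>10.4f}{lo:>10.4f}{hi:>10.4f}")
        return "\n".join(lines)


def msfsasc(msfsc, age, sex, curves: Optional[Mapping[str, DecayCurve]] = None,
            reference: str = "pooled"):
    """Normalize chronotype to the hypothetical value at age 30.

    Each subject's expected chronotype given age and sex is subtracted and
    replaced by a common reference level at age 30::

        MSFsasc = MSFsc - predict(sex, age) + ref30

    With ``reference="pooled"`` (default) ``ref30`` is the mean of the men
    and women curve predictions at 30, so both the age trend and the sex
    offset are removed; ``reference="per_sex"`` keeps each sex on its own
    curve at 30 (removing age only).

    Accepts scalars or aligned arrays; ``sex`` entries must be keys of
    ``curves`` (default: the bundled reference curves, keys ``"men"`` /
    ``"women"``).
    """
    curves = DEFAULT_CURVES if curves is None else curves
    msfsc = np.asarray(msfsc, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_arr = np.asarray(sex, dtype=object)
    scalar = msfsc.ndim == 0
    msfsc, age, sex_arr = np.atleast_1d(msfsc), np.atleast_1d(age), np.atleast_1d(sex_arr)
    if np.any(age < 18):
        raise ValueError("normalization is defined for adults (age >= 18)")

    ref_pooled = float(np.mean([c.predict(REFERENCE_AGE) for c in curves.values()]))
    out = np.empty_like(msfsc)
    for label, curve in curves.items():
        m = sex_arr == label
        ref = curve.predict(REFERENCE_AGE) if reference == "per_sex" else ref_pooled
        out[m] = msfsc[m] - curve.predict(age[m]) + ref
    unknown = ~np.isin(sex_arr, list(curves))
    if np.any(unknown):
        raise ValueError(f"unknown sex labels: {set(sex_arr[unknown])}")
    return float(out[0]) if scalar else out


def build_curves_from_yaml(path) -> dict:
    """Load per-sex decay constants from a YAML model file.

    Expected layout: ``{sex: {y0: ..., plateau: ..., k: ...}, ...}``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        sex: DecayCurve(float(c["y0"]), float(c["plateau"]), float(c["k"]), sex=sex)
        for sex, c in raw.items()
    }


def curves_to_yaml(curves: Mapping[str, DecayCurve], path) -> None:
    """Write per-sex decay constants to a YAML model file."""
    import yaml

    data = {
        sex: {"y0": float(c.y0), "plateau": float(c.plateau), "k": float(c.k)}
        for sex, c in curves.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def categorize_deciles(values: Sequence[float]) -> np.ndarray:
    """Label the lowest and highest deciles as extreme chronotypes.

    Rank-based (average ranks for ties): ranks <= n/10 are
    ``extremely_early``, ranks > 9n/10 are ``extremely_late``, the middle
    eight deciles are ``non_extreme``.  Requires n >= 10.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < 10:
        raise ValueError(f"decile categorization needs n >= 10, got {n}")
    ranks = stats.rankdata(vals, method="average")
    out = np.full(n, CATEGORY_NON_EXTREME, dtype=object)
    out[ranks <= n / 10.0] = CATEGORY_EARLY
    out[ranks > 9.0 * n / 10.0] = CATEGORY_LATE
    return out
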