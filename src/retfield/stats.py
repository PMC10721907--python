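"""Electrode-level statistical models of perceptual threshold.

Per-electrode measurement tables (electrode–retina distance, retinal
thickness, fibrotic tissue thickness, impedance, perceptual threshold)
are filtered by a visibility + safe-amplitude rule, then modelled with
per-covariate simple regressions and one multiple regression, reporting
R² and p-values at α = 0.05 — the layout of the clinical analysis this
package emulates.  The safe-charge-density computation for a disc
electrode is provided alongside.

`ThresholdRegression` wraps the workflow statsmodels-style: build the
model from a table, `.fit()` it, read `.summary()` off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geometry import ElectrodeMeasurement, measurements_to_frame

__all__ = ["THRESHOLD_CAP_UA", "RegressionResult", "max_safe_amplitude",
           "charge_density", "inclusion_filter", "ols",
           "ThresholdRegression", "ThresholdRegressionResults",
           "mixed_effects_model"]

# operational inclusion cutoff (µA) used by the clinical analysis; the
# direct computation from the 1.0 mC/cm²/phase limit gives 698 µA — see
# docs/methods.md for the discrepancy
THRESHOLD_CAP_UA = 677.0
ALPHA = 0.05

COVARIATES = ["distance_mm", "thickness_mm", "impedance_kohm", "fibrosis_mm"]


@dataclass
class RegressionResult:
    """One fitted linear model (single- or multi-covariate)."""

    covariates: list[str]
    slopes: np.ndarray
    intercept: float
    r_squared: float
    p_values: np.ndarray          # two-sided t-test per covariate
    p_overall: float              # F-test (equals the t p for one covariate)
    stderr: np.ndarray
    n: int

    @property
    def significant(self) -> bool:
        return self.p_overall < ALPHA


def max_safe_amplitude(charge_density_limit_mc_cm2: float = 1.0,
                       pulse_width_ms: float = 0.45,
                       diameter_um: float = 200.0) -> float:
    """Maximum amplitude (µA) within a per-phase charge-density limit.

    I = limit · π(d/2)² / pulse width; the defaults give ≈ 698 µA for a
    200 µm disc at 0.45 ms/phase and 1.0 mC/cm²/phase.
    """
    if min(charge_density_limit_mc_cm2, pulse_width_ms, diameter_um) <= 0:
        raise ValueError("all inputs must be positive")
    area_cm2 = np.pi * (diameter_um * 1e-4 / 2.0) ** 2
    return charge_density_limit_mc_cm2 * area_cm2 / pulse_width_ms * 1e6


def charge_density(amplitude_uA: float, pulse_width_ms: float = 0.45,
                   diameter_um: float = 200.0) -> float:
    """Charge density (mC/cm²/phase) of a rectangular phase on a disc."""
    area_cm2 = np.pi * (diameter_um * 1e-4 / 2.0) ** 2
    return amplitude_uA * 1e-6 * pulse_width_ms / area_cm2


def inclusion_filter(measurements: list[ElectrodeMeasurement],
                     threshold_cap_uA: float = THRESHOLD_CAP_UA
                     ) -> tuple[list[ElectrodeMeasurement], dict[str, int]]:
    """Keep visible electrodes with threshold strictly below the cap.

    Returns the retained measurements and counts of exclusions by reason.
    """
    retained, counts = [], {"not_visible": 0, "over_cap": 0, "retained": 0}
    for m in measurements:
        if not m.visible:
            counts["not_visible"] += 1
        elif not (m.threshold_uA < threshold_cap_uA):
            counts["over_cap"] += 1
        else:
            retained.append(m)
            counts["retained"] += 1
    return retained, counts


def ols(x, y, names: list[str] | None = None) -> RegressionResult:
    """Least-squares linear fit of thresholds on one or more covariates.

    ``x`` is (n,) or (n, p); p-values are two-sided t-tests per slope and
    an overall F-test.  Rank-deficient design matrices raise ``ValueError``
    naming the collinear covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    names = names or [f"x{i}" for i in range(p)]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    X = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        bad = [names[i] for i in range(p)
               if np.ptp(x[:, i]) == 0
               or (p > 1 and np.any(np.abs(np.delete(corr[i], i)) > 1 - 1e-12))]
        raise ValueError(f"rank-deficient design; collinear covariates: {bad or names}")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(covariates=list(names),
                            slopes=np.asarray(fit.params[1:]),
                            intercept=float(fit.params[0]),
                            r_squared=float(fit.rsquared),
                            p_values=np.asarray(fit.pvalues[1:]),
                            p_overall=float(fit.f_pvalue),
                            stderr=np.asarray(fit.bse[1:]),
                            n=n)


class ThresholdRegression:
    """Statistical threshold model for one participant's electrode table.

    Parameters
    ----------
    data : DataFrame
        One row per electrode with the measurement columns; typically from
        :func:`retfield.geometry.measurements_to_frame`.
    covariates : list of str
        Explanatory variables; defaults to distance, thickness, impedance
        and fibrosis where present (all-NaN columns are dropped, matching
        participants without fibrotic growth).
    """

    def __init__(self, data: pd.DataFrame, covariates: list[str] | None = None,
                 threshold_cap_uA: float = THRESHOLD_CAP_UA):
        df = data.copy()
        if "visible" in df:
            df = df[df["visible"].astype(bool)]
        df = df[df["threshold_uA"] < threshold_cap_uA]
        cov = covariates or [c for c in COVARIATES if c in df]
        # degenerate covariates (all NaN, or no spread beyond numerical
        # noise) cannot enter a regression — e.g. fibrosis for a patient
        # without fibrotic growth, or constant fields of a flat phantom
        def varies(col):
            v = df[col].dropna()
            return len(v) > 1 and np.ptp(v) > 1e-9 * max(1.0, np.abs(v).max())
        cov = [c for c in cov if not df[c].isna().all() and varies(c)]
        self.data = df.dropna(subset=cov + ["threshold_uA"])
        self.covariates = cov

    @classmethod
    def from_measurements(cls, measurements: list[ElectrodeMeasurement],
                          **kwargs) -> "ThresholdRegression":
        return cls(measurements_to_frame(measurements), **kwargs)

    def fit(self) -> "ThresholdRegressionResults":
        y = self.data["threshold_uA"].to_numpy()
        singles = {c: ols(self.data[c].to_numpy(), y, names=[c])
                   for c in self.covariates}
        multiple = (ols(self.data[self.covariates].to_numpy(), y,
                        names=self.covariates)
                    if len(self.covariates) > 1 else None)
        return ThresholdRegressionResults(self, singles, multiple)


@dataclass
class ThresholdRegressionResults:
    model: ThresholdRegression
    singles: dict[str, RegressionResult]
    multiple: RegressionResult | None

    def summary(self) -> pd.DataFrame:
        """Per-covariate and multiple-regression R²/p table."""
        rows = []
        for name, r in self.singles.items():
            rows.append({"model": name, "R2": r.r_squared, "p": r.p_overall,
                         "slope": r.slopes[0], "n": r.n,
                         "significant": r.significant})
        if self.multiple is not None:
            rows.append({"model": "multiple", "R2": self.multiple.r_squared,
                         "p": self.multiple.p_overall, "slope": np.nan,
                         "n": self.multiple.n,
                         "significant": self.multiple.significant})
        return pd.DataFrame(rows).set_index("model")


def mixed_effects_model(df: pd.DataFrame, covariate: str,
                        group: str = "participant",
                        response: str = "threshold_uA"):
    """Random-intercept-and-slope mixed model across participants.

    Thin delegation to ``statsmodels`` MixedLM; returns the fitted results
    object (fixed-effect estimate under ``fe_params``).
    """
    model = sm.MixedLM.from_formula(f"{response} ~ {covariate}", groups=group,
                                    re_formula=f"~{covariate}", data=df)
    return model.fit(method="lbfgs", reml=True)
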