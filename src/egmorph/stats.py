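"""Condition comparison and dose-response modelling.

Two small model classes in the statsmodels idiom:

* :class:`ConditionComparison` — built from a long-format per-beat feature
  table with ``BL`` and ``CBX`` conditions; ``fit()`` returns a
  :class:`ConditionComparisonResults` whose ``table`` holds, per feature,
  the condition means and SDs, a two-sided t statistic and p value, the
  percent change from baseline and a significance flag at alpha = 0.05.
* :class:`DoseResponse` — built from per-dose latency means (and optional
  SDs); ``fit()`` performs a multi-start weighted least-squares fit of a
  four-parameter logistic (4PL) and returns a :class:`DoseResponseResults`.

The 4PL is parameterized so the zero-dose point is exactly the lower
asymptote:

    L(d) = A + (B - A) / (1 + (d50 / d)^h),   L(0) = A,

with A, B the baseline and saturating latencies (ms), d50 the half-effect
dose and h the Hill slope.

By default condition comparisons pool all beats (Welch unequal-variance,
unpaired, two-sided); Student and paired variants plus per-heart pooling
and Benjamini-Hochberg correction are available as options but off by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from .errors import EmptyConditionError, FitError
from .io import ALL_FEATURE_COLUMNS, StudyTable

__all__ = [
    "summarize",
    "percent_change",
    "welch_t_test",
    "compare_table",
    "ConditionComparison",
    "ConditionComparisonResults",
    "DoseResponse",
    "DoseResponseResults",
    "four_param_logistic",
]


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def _as_frame(table: StudyTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, StudyTable) else table


def summarize(table: StudyTable | pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-feature mean and sample SD (n-1) over all beats in a condition.

    NaN (undefined-marker) entries are excluded feature-wise.  Raises
    :class:`EmptyConditionError` for conditions with fewer than two beats.
    """
    df = _as_frame(table)
    sub = df[df["condition"] == condition]
    if len(sub) < 2:
        raise EmptyConditionError(
            f"condition {condition!r} has {len(sub)} beat(s); need >= 2"
        )
    cols = [c for c in ALL_FEATURE_COLUMNS if c in sub.columns]
    out = pd.DataFrame(
        {
            "mean": sub[cols].mean(skipna=True),
            "sd": sub[cols].std(ddof=1, skipna=True),
            "n": sub[cols].count(),
        }
    )
    out.index.name = "feature"
    return out


def percent_change(bl_mean: float, cbx_mean: float) -> float:
    """Percent change from baseline: 100 * (cbx - bl) / |bl|.

    The absolute-value denominator keeps the sign meaningful for
    negative-baseline features (a deepening S wave is a negative change).
    Returns NaN when the baseline mean is zero.
    """
    if bl_mean == 0 or not np.isfinite(bl_mean):
        return float("nan")
    return 100.0 * (cbx_mean - bl_mean) / abs(bl_mean)


def welch_t_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sided Welch unequal-variance t-test: returns (t, df, p).

    Degenerate inputs follow fixed conventions: two zero-variance samples
    with equal means give (0, nan, 1); zero-variance samples with unequal
    means give (+/-inf, nan, 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise EmptyConditionError("each sample needs n >= 2 finite values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float("nan"), 1.0
        warnings.warn(
            "zero-variance samples with unequal means: p -> 0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.sign(x.mean() - y.mean()) * np.inf), float("nan"), 0.0
    res = sstats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _student_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = sstats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(x.size + y.size - 2), float(res.pvalue)


# --------------------------------------------------------------------------
# condition comparison model
# --------------------------------------------------------------------------

class ConditionComparison:
    """Baseline-vs-drug comparison of per-beat EGM features.

    Parameters
    ----------
    table:
        A :class:`~egmorph.io.StudyTable` (or equivalent DataFrame) holding
        beats from both conditions.
    features:
        Feature columns to compare; defaults to the canonical 19 + latency,
        in table order.
    """

    def __init__(
        self,
        table: StudyTable | pd.DataFrame,
        features: Sequence[str] | None = None,
    ):
        df = _as_frame(table)
        present = set(df["condition"].unique())
        missing = {"BL", "CBX"} - present
        if missing:
            raise EmptyConditionError(f"condition(s) {sorted(missing)} absent")
        if features is None:
            features = [c for c in ALL_FEATURE_COLUMNS if c in df.columns]
        else:
            absent = [f for f in features if f not in df.columns]
            if absent:
                raise EmptyConditionError(f"feature column(s) {absent} absent")
        self.df = df
        self.features = list(features)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "ConditionComparison":
        return cls(df, **kw)

    def _samples(self, feature: str, condition: str, pooling: str) -> np.ndarray:
        sub = self.df[self.df["condition"] == condition]
        if pooling == "beats":
            v = sub[feature].to_numpy(dtype=float)
        elif pooling == "hearts":
            v = sub.groupby("heart_id")[feature].mean().to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        return v[np.isfinite(v)]

    def fit(
        self,
        method: str = "welch",
        pooling: str = "beats",
        alpha: float = 0.05,
        fdr: bool = False,
    ) -> "ConditionComparisonResults":
        """Run per-feature tests and assemble the comparison table.

        method: ``welch`` (default), ``student`` or ``paired`` (pairs beats
        by site/channel/beat key).  ``fdr=True`` applies Benjamini-Hochberg
        before flagging significance.
        """
        rows = []
        for feat in self.features:
            x = self._samples(feat, "BL", pooling)
            y = self._samples(feat, "CBX", pooling)
            if x.size < 2 or y.size < 2:
                raise EmptyConditionError(
                    f"feature {feat!r}: need >= 2 finite values per condition"
                )
            if method == "welch":
                t, dof, p = welch_t_test(x, y)
            elif method == "student":
                t, dof, p = _student_t_test(x, y)
            elif method == "paired":
                t, dof, p = self._paired_test(feat)
            else:
                raise ValueError(f"unknown method {method!r}")
            bl_m, cbx_m = float(x.mean()), float(y.mean())
            rows.append(
                {
                    "feature": feat,
                    "bl_mean": bl_m,
                    "bl_sd": float(x.std(ddof=1)),
                    "cbx_mean": cbx_m,
                    "cbx_sd": float(y.std(ddof=1)),
                    "t_stat": t,
                    "p_value": p,
                    "percent_change": percent_change(bl_m, cbx_m),
                }
            )
        table = pd.DataFrame(rows)
        pvals = table["p_value"].to_numpy()
        if fdr:
            adj = sstats.false_discovery_control(np.clip(pvals, 0.0, 1.0))
            table["p_adjusted"] = adj
            table["significant"] = adj < alpha
        else:
            table["significant"] = pvals < alpha
        return ConditionComparisonResults(
            table=table, method=method, pooling=pooling, alpha=alpha, fdr=fdr
        )

    def _paired_test(self, feature: str) -> tuple[float, float, float]:
        keys = ["heart_id", "site_index", "channel", "beat_index"]
        bl = self.df[self.df["condition"] == "BL"].set_index(keys)[feature]
        cbx = self.df[self.df["condition"] == "CBX"].set_index(keys)[feature]
        joined = pd.concat([bl, cbx], axis=1, join="inner", keys=["bl", "cbx"]).dropna()
        if len(joined) < 2:
            raise EmptyConditionError(f"feature {feature!r}: no paired beats")
        res = sstats.ttest_rel(joined["bl"], joined["cbx"])
        return float(res.statistic), float(len(joined) - 1), float(res.pvalue)


@dataclass
class ConditionComparisonResults:
    """Comparison table plus the options used to produce it."""

    table: pd.DataFrame
    method: str = "welch"
    pooling: str = "beats"
    alpha: float = 0.05
    fdr: bool = False

    def row(self, feature: str) -> pd.Series:
        sub = self.table[self.table["feature"] == feature]
        if len(sub) != 1:
            raise KeyError(feature)
        return sub.iloc[0]

    def summary(self) -> str:
        """Human-readable comparison table (percent change to 2 dp)."""
        lines = [
            "Condition comparison (BL vs CBX)",
            f"  test: {self.method}, pooling: {self.pooling}, "
            f"alpha: {self.alpha}, fdr: {self.fdr}",
            "",
            f"{'feature':<26}{'BL mean (SD)':>20}{'CBX mean (SD)':>20}"
            f"{'p':>10}{'change %':>10}",
        ]
        for _, r in self.table.iterrows():
            pc = r["percent_change"]
            lines.append(
                f"{r['feature']:<26}"
                f"{r['bl_mean']:>11.2f} ({r['bl_sd']:.2f}){'':<1}"
                f"{r['cbx_mean']:>11.2f} ({r['cbx_sd']:.2f})"
                f"{r['p_value']:>10.4f}"
                f"{pc:>9.2f}{'*' if r['significant'] else ''}"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_table(
    table: StudyTable | pd.DataFrame, **fit_kw
) -> pd.DataFrame:
    """One-call wrapper: ConditionComparison(table).fit(**fit_kw).table."""
    return ConditionComparison(table).fit(**fit_kw).table


# --------------------------------------------------------------------------
# dose-response model
# --------------------------------------------------------------------------

def four_param_logistic(
    d: np.ndarray | float, a: float, b: float, d50: float, h: float
) -> np.ndarray:
    """4PL sigmoid with L(0) = a exactly."""
    d = np.asarray(d, dtype=float)
    out = np.full(d.shape, a, dtype=float)
    pos = d > 0
    with np.errstate(over="ignore"):
        out[pos] = a + (b - a) / (1.0 + (d50 / d[pos]) ** h)
    return out


class DoseResponse:
    """Latency-vs-dose sigmoid model.

    Parameters
    ----------
    doses:
        Increasing, non-negative doses (ml).
    latency_mean, latency_sd:
        Per-dose mean latency (ms) and optional SD used as inverse-variance
        weights.
    """

    def __init__(
        self,
        doses: Sequence[float],
        latency_mean: Sequence[float],
        latency_sd: Sequence[float] | None = None,
    ):
        self.doses = np.asarray(doses, dtype=float)
        self.latency_mean = np.asarray(latency_mean, dtype=float)
        if self.doses.size != self.latency_mean.size:
            raise ValueError("doses and latency_mean must have equal length")
        if self.doses.size < 5:
            raise ValueError("dose-response fit needs >= 5 dose points")
        if np.any(np.diff(self.doses) <= 0) or np.any(self.doses < 0):
            raise ValueError("doses must be non-negative and increasing")
        if latency_sd is not None:
            sd = np.asarray(latency_sd, dtype=float)
            if sd.size != self.doses.size:
                raise ValueError("latency_sd length mismatch")
            self.latency_sd = sd
        else:
            self.latency_sd = None

    def fit(
        self,
        weighted: bool = True,
        d50_grid: Sequence[float] | None = None,
        h_grid: Sequence[float] = (0.5, 1.0, 2.0, 3.0, 5.0),
    ) -> "DoseResponseResults":
        """Multi-start least-squares 4PL fit.

        Starts span a grid of d50 (dose quantiles by default) and Hill
        slopes; the best converged start wins.  Raises :class:`FitError` if
        every start fails.
        """
        y = self.latency_mean
        d = self.doses
        if weighted and self.latency_sd is not None and np.all(self.latency_sd > 0):
            w = 1.0 / self.latency_sd
        else:
            w = np.ones_like(y)

        pos = d[d > 0]
        if d50_grid is None:
            d50_grid = np.quantile(pos, [0.2, 0.4, 0.6, 0.8])

        span = float(y.max() - y.min())
        a0, b0 = float(y[0]), float(y[-1])

        def residuals(p: np.ndarray) -> np.ndarray:
            a, b, log_d50, log_h = p
            return w * (four_param_logistic(d, a, b, np.exp(log_d50), np.exp(log_h)) - y)

        best = None
        for d50_0 in d50_grid:
            for h0 in h_grid:
                x0 = np.array([a0, b0, np.log(d50_0), np.log(h0)])
                try:
                    sol = optimize.least_squares(
                        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=20000,
                    )
                except Exception:
                    continue
                if not np.all(np.isfinite(sol.x)):
                    continue
                if best is None or sol.cost < best.cost - 1e-30:
                    best = sol
        if best is None:
            raise FitError(
                "4PL fit failed from every start "
                f"(d50 grid {list(d50_grid)}, h grid {list(h_grid)})"
            )
        a, b, log_d50, log_h = best.x
        pred = four_param_logistic(d, a, b, np.exp(log_d50), np.exp(log_h))
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        return DoseResponseResults(
            doses=d,
            latency_mean=y,
            latency_sd=self.latency_sd,
            lower=float(a),
            upper=float(b),
            d50=float(np.exp(log_d50)),
            hill=float(np.exp(log_h)),
            rmse=rmse,
        )


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters, with the data they were fitted to."""

    doses: np.ndarray
    latency_mean: np.ndarray
    latency_sd: np.ndarray | None
    lower: float   # A, baseline asymptote (ms)
    upper: float   # B, saturating asymptote (ms)
    d50: float     # half-effect dose (ml)
    hill: float    # Hill slope
    rmse: float    # ms

    def predict(self, d: np.ndarray | float) -> np.ndarray:
        return four_param_logistic(d, self.lower, self.upper, self.d50, self.hill)

    @property
    def params(self) -> dict[str, float]:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "d50": self.d50,
            "hill": self.hill,
        }

    def summary(self) -> str:
        return (
            "Dose-response 4PL fit\n"
            f"  lower asymptote A : {self.lower:8.3f} ms\n"
            f"  upper asymptote B : {self.upper:8.3f} ms\n"
            f"  half-effect d50   : {self.d50:8.3f} ml\n"
            f"  Hill slope h      : {self.hill:8.3f}\n"
            f"  rmse              : {self.rmse:8.4f} ms\n"
            f"  doses             : {np.array2string(self.doses, precision=1)}"
        )
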