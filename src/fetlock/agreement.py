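"""Agreement and variability statistics for the two measurement channels.

Two model objects carry the statistical layer:

* :class:`MethodAgreement` — built from an aligned pair of angle traces;
  ``fit()`` returns RMSE, Pearson correlation, a two-directional Granger
  temporal-agreement test and Bland–Altman bias / limits of agreement.
* :class:`RomVariabilityAnova` — built from a table of left–right range-of-
  motion coefficients of variation; ``fit()`` runs the three-way main-effects
  ANOVA (lameness × gait × limb pair) and partitions the percent of total
  variation per factor.

The plain functions (:func:`rmse`, :func:`pcc`, :func:`cv_percent`,
:func:`granger_agreement`, :func:`bland_altman_rm`,
:func:`anova3_partition`) are the underlying computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .series import AngleSeries

FACTORS = ("lameness", "gait", "limb_pair")


# ---------------------------------------------------------------- primitives

def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(getattr(x, "values", x), dtype=float)
    y = np.asarray(getattr(y, "values", y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be one-dimensional and of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def rmse(x, y) -> float:
    """Root mean square error sqrt(Σ(xᵢ−yᵢ)²/n) between two equal-length traces."""
    x, y = _pair(x, y)
    if x.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def pcc(x, y) -> tuple[float, float]:
    """Pearson product–moment correlation and its two-sided p-value."""
    x, y = _pair(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def cv_percent(values) -> float:
    """Coefficient of variation, sample SD (n−1) over the mean, in percent."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a CV")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(np.std(v, ddof=1) / mean * 100.0)


# ------------------------------------------------------------------- Granger

@dataclass
class GrangerReport:
    """Two-directional Granger temporal-agreement verdict at level ``alpha``."""

    lag_order: int
    p_fwd: float       # does x help predict y
    p_rev: float       # does y help predict x
    alpha: float
    rule: str          # 'either' or 'both'

    @property
    def agree(self) -> bool:
        if self.rule == "both":
            return self.p_fwd < self.alpha and self.p_rev < self.alpha
        return self.p_fwd < self.alpha or self.p_rev < self.alpha


def _granger_pvalue(target: np.ndarray, source: np.ndarray, lag: int) -> float:
    from statsmodels.tsa.stattools import grangercausalitytests

    data = np.column_stack([target, source])
    with warnings.catch_warnings():
        # deprecated verbose param; rank warnings on near-deterministic traces
        warnings.simplefilter("ignore")
        res = grangercausalitytests(data, maxlag=[lag], verbose=False)
    return float(res[lag][0]["ssr_ftest"][1])


def granger_agreement(x, y, max_lag: int = 20, alpha: float = 0.01,
                      difference: bool = True, rule: str = "either",
                      lag_order: int | None = None) -> GrangerReport:
    """Granger temporal-agreement test between two traces.

    Both series are first-differenced by default (the traces are strongly
    trending within strides), the lag order is selected by BIC up to
    ``max_lag`` on the bivariate autoregression, and the F-test of the
    restricted vs. unrestricted regression is run in each direction.  The
    channels are declared in temporal agreement when the null of no
    predictive content is rejected at ``alpha`` in at least one direction
    (``rule='either'``, default) or in both (``rule='both'``).
    """
    from statsmodels.tsa.api import VAR

    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    x, y = _pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Granger test undefined for a constant series")
    if difference:
        x, y = np.diff(x), np.diff(y)
    if x.size <= 10 * max_lag:
        raise ValueError(f"need more than {10 * max_lag} samples for max_lag={max_lag}")
    if lag_order is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = VAR(np.column_stack([x, y])).select_order(maxlags=max_lag)
        lag_order = max(1, int(sel.bic))
    p_fwd = _granger_pvalue(y, x, lag_order)
    p_rev = _granger_pvalue(x, y, lag_order)
    return GrangerReport(lag_order=int(lag_order), p_fwd=p_fwd, p_rev=p_rev,
                         alpha=alpha, rule=rule)


# -------------------------------------------------------------- Bland–Altman

@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    method: str        # 'pooled' or 'rm_corrected'
    sd: float          # SD entering the limits of agreement
    n: int

    def __post_init__(self) -> None:
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman_rm(x, y, subject=None, method: str = "rm_corrected",
                    z: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman bias and limits of agreement, difference taken as x − y.

    ``pooled`` treats all pairs as independent: LoA = bias ± z·SD(d).
    ``rm_corrected`` accounts for repeated measures per subject: the
    difference variance is decomposed by a one-way analysis of the
    differences by subject, the between-subject component is estimated from
    the subject-means mean square, and LoA = bias ± z·sqrt(between + within).
    With fewer than two subjects, or any subject contributing fewer than two
    pairs, the pooled estimate is used with a warning.
    """
    x, y = _pair(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    if method not in ("pooled", "rm_corrected"):
        raise ValueError("method must be 'pooled' or 'rm_corrected'")

    use_rm = method == "rm_corrected"
    groups: list[np.ndarray] = []
    if use_rm:
        if subject is None:
            raise ValueError("rm_corrected requires subject labels")
        subject = np.asarray(subject)
        if subject.shape != d.shape:
            raise ValueError("subject labels must match the pairs")
        groups = [d[subject == s] for s in pd.unique(subject)]
        if len(groups) < 2 or any(g.size < 2 for g in groups):
            warnings.warn("repeated-measures correction needs ≥2 subjects with "
                          "≥2 pairs each; falling back to the pooled estimate")
            use_rm = False

    if not use_rm:
        sd = float(np.std(d, ddof=1))
        return BlandAltmanResult(bias, bias - z * sd, bias + z * sd,
                                 "pooled", sd, int(d.size))

    k = len(groups)
    counts = np.array([g.size for g in groups], dtype=float)
    n_tot = counts.sum()
    means = np.array([g.mean() for g in groups])
    msb = float(np.sum(counts * (means - bias) ** 2) / (k - 1))
    msw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups) / (n_tot - k))
    m0 = (n_tot - np.sum(counts**2) / n_tot) / (k - 1)
    var_between = max(0.0, (msb - msw) / m0)
    sd = float(np.sqrt(var_between + msw))
    return BlandAltmanResult(bias, bias - z * sd, bias + z * sd,
                             "rm_corrected", sd, int(n_tot))


# --------------------------------------------------------------------- ANOVA

@dataclass
class AnovaPartition:
    """Main-effects ANOVA table with the percent-of-total-variation split.

    ``percent_of_total`` for a factor is its sum of squares over the total
    (corrected) sum of squares × 100.  The residual share is reported as the
    remainder to 100, which on balanced designs equals the residual SS share.
    """

    table: pd.DataFrame            # index: factors + 'residual'; SS, df, F, p, percent
    total_ss: float
    shapiro_p: float
    alpha: float
    dropped_factors: tuple[str, ...] = ()

    @property
    def percent_of_total(self) -> dict[str, float]:
        return self.table["percent_of_total"].to_dict()

    def significant_factors(self) -> list[str]:
        p = self.table["p"].drop("residual")
        return list(p.index[p < self.alpha])


def anova3_partition(records: pd.DataFrame, response: str = "cv_percent",
                     alpha: float = 0.05, typ: int = 2) -> AnovaPartition:
    """Three-way main-effects ANOVA of left–right CV on lameness, gait and
    limb pair, with the percent-of-total-variation partition.

    The horse is deliberately not a clustering variable.  Residual normality
    is screened with a Shapiro–Wilk test first (a warning, not a rejection).
    Factors with a single observed level are dropped with a warning.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = records.copy()
    if response not in df.columns:
        raise ValueError(f"records lack a {response!r} column")
    present, dropped = [], []
    for f in FACTORS:
        if f in df.columns and df[f].nunique() >= 2:
            present.append(f)
        else:
            dropped.append(f)
            warnings.warn(f"factor {f!r} has fewer than two levels; dropped")
    if not present:
        raise ValueError("no factor has two levels; nothing to analyse")

    y = df[response].to_numpy(dtype=float)
    n_params = 1 + sum(df[f].nunique() - 1 for f in present)
    if len(df) <= n_params:
        raise ValueError(f"{len(df)} records cannot support {n_params} model "
                         "parameters; enlarge the cohort or drop factors")
    total_ss = float(np.sum((y - y.mean()) ** 2))
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in present)
    fit = smf.ols(formula, data=df).fit()

    resid = fit.resid.to_numpy()
    degenerate = np.ptp(resid) < 1e-9 * max(1.0, np.ptp(y))
    shapiro_p = 1.0 if degenerate else float(sps.shapiro(resid)[1])
    if shapiro_p < alpha:
        warnings.warn(f"Shapiro–Wilk rejects residual normality (p={shapiro_p:.3g})")

    if total_ss == 0:
        rows = {f: dict(sum_sq=0.0, df=float(df[f].nunique() - 1),
                        F=np.nan, p=np.nan, percent_of_total=0.0) for f in present}
        rows["residual"] = dict(sum_sq=0.0, df=float(len(df) - 1 - len(present)),
                                F=np.nan, p=np.nan, percent_of_total=0.0)
        return AnovaPartition(pd.DataFrame(rows).T, 0.0, shapiro_p, alpha,
                              tuple(dropped))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = anova_lm(fit, typ=typ)
    rows = {}
    pct_sum = 0.0
    for f in present:
        row = anova.loc[f"C({f})"]
        pct = float(row["sum_sq"]) / total_ss * 100.0
        pct_sum += pct
        rows[f] = dict(sum_sq=float(row["sum_sq"]), df=float(row["df"]),
                       F=float(row["F"]), p=float(row["PR(>F)"]),
                       percent_of_total=pct)
    res = anova.loc["Residual"]
    rows["residual"] = dict(sum_sq=float(res["sum_sq"]), df=float(res["df"]),
                            F=np.nan, p=np.nan,
                            percent_of_total=100.0 - pct_sum)
    table = pd.DataFrame(rows).T
    return AnovaPartition(table, total_ss, shapiro_p, alpha, tuple(dropped))


# ------------------------------------------------------- model-style objects

@dataclass
class MethodAgreementResults:
    """Agreement estimates for one aligned IMU/OMC trace pair."""

    rmse_deg: float
    pcc: float
    pcc_p: float
    granger: GrangerReport
    bland_altman: BlandAltmanResult
    n: int
    meta: dict = field(default_factory=dict)

    def summary(self) -> str:
        g, ba = self.granger, self.bland_altman
        lines = [
            "Method agreement (IMU vs OMC)",
            "=" * 46,
            f"samples                 {self.n}",
            f"RMSE [deg]              {self.rmse_deg:.3f}",
            f"PCC                     {self.pcc:.4f} (p={self.pcc_p:.3g})",
            f"Granger lag order       {g.lag_order}",
            f"Granger p (x->y, y->x)  {g.p_fwd:.3g}, {g.p_rev:.3g}",
            f"temporal agreement      {g.agree} (alpha={g.alpha}, rule={g.rule})",
            f"Bland-Altman bias [deg] {ba.bias:.3f}",
            f"limits of agreement     [{ba.loa_low:.3f}, {ba.loa_high:.3f}] ({ba.method})",
        ]
        return "\n".join(lines)

    def plot_bland_altman(self, x, y, ax=None):
        """Classic Bland–Altman scatter for the pair this result came from."""
        import matplotlib.pyplot as plt

        x = np.asarray(getattr(x, "values", x), float)
        y = np.asarray(getattr(y, "values", y), float)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter((x + y) / 2.0, x - y, s=4, alpha=0.4)
        for val, style in ((self.bland_altman.bias, "-"),
                           (self.bland_altman.loa_low, "--"),
                           (self.bland_altman.loa_high, "--")):
            ax.axhline(val, color="k", linestyle=style, linewidth=1)
        ax.set_xlabel("mean of methods [deg]")
        ax.set_ylabel("difference IMU − OMC [deg]")
        return ax


class MethodAgreement:
    """Agreement model for one synchronized, vertically aligned trace pair.

    Parameters
    ----------
    imu, omc : AngleSeries or array-like
        The two angle traces on the common 200 Hz grid, already synchronised
        (see :func:`fetlock.pipeline.synchronize_and_align`).
    subject : array-like, optional
        Per-sample subject labels for the repeated-measures Bland–Altman
        correction; without labels the pooled estimate is used.
    """

    def __init__(self, imu, omc, subject=None):
        self.imu, self.omc = _pair(imu, omc)
        self.subject = subject
        self.meta = dict(getattr(imu, "meta", {}) or {})

    @classmethod
    def from_series(cls, imu: AngleSeries, omc: AngleSeries, **kw) -> "MethodAgreement":
        return cls(imu, omc, **kw)

    def fit(self, max_lag: int = 20, alpha: float = 0.01,
            granger_rule: str = "either", granger_decimate: int = 4,
            ba_method: str | None = None) -> MethodAgreementResults:
        """Fit all agreement statistics.

        The Granger regressions are run on the traces decimated by
        ``granger_decimate`` (50 Hz at the native 200 Hz): the 10 Hz
        band-limited traces are heavily oversampled at 200 Hz, where a
        series' own 100 ms history predicts it almost perfectly and the test
        has no power; decimation is alias-free after the 10 Hz low-pass.
        ``max_lag`` is expressed at the native rate and scaled accordingly,
        preserving the 100 ms history window.
        """
        if ba_method is None:
            ba_method = "rm_corrected" if self.subject is not None else "pooled"
        r, p = pcc(self.imu, self.omc)
        n = self.imu.size
        dec = max(1, int(granger_decimate))
        x, y = self.imu[::dec], self.omc[::dec]
        lag = max(1, min(max_lag // dec, (x.size - 2) // 10 - 1))
        return MethodAgreementResults(
            rmse_deg=rmse(self.imu, self.omc),
            pcc=r, pcc_p=p,
            granger=granger_agreement(x, y, max_lag=lag,
                                      alpha=alpha, rule=granger_rule),
            bland_altman=bland_altman_rm(self.imu, self.omc, self.subject,
                                         method=ba_method),
            n=n, meta=self.meta)


@dataclass
class RomVariabilityResults:
    """Fitted three-way ANOVA of left–right FJROM variability."""

    partition: AnovaPartition
    records: pd.DataFrame

    @property
    def dominant_factor(self) -> str:
        pct = self.partition.table["percent_of_total"].drop("residual")
        return str(pct.idxmax())

    def summary(self) -> str:
        t = self.partition.table
        lines = [
            "Left-right FJROM variability: three-way ANOVA",
            "=" * 58,
            f"records: {len(self.records)}   total SS: {self.partition.total_ss:.3f}"
            f"   Shapiro-Wilk p: {self.partition.shapiro_p:.3g}",
            f"{'factor':<12}{'SS':>10}{'df':>5}{'F':>9}{'p':>12}{'% total':>9}",
        ]
        for name, row in t.iterrows():
            fstr = "" if np.isnan(row["F"]) else f"{row['F']:.2f}"
            pstr = "" if np.isnan(row["p"]) else f"{row['p']:.2e}"
            lines.append(f"{name:<12}{row['sum_sq']:>10.3f}{row['df']:>5.0f}"
                         f"{fstr:>9}{pstr:>12}{row['percent_of_total']:>9.2f}")
        if self.partition.dropped_factors:
            lines.append(f"dropped factors: {', '.join(self.partition.dropped_factors)}")
        return "\n".join(lines)

    def plot_partition(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pct = self.partition.table["percent_of_total"]
        ax.bar(pct.index.astype(str), pct.to_numpy())
        ax.set_ylabel("% of total variation")
        return ax


class RomVariabilityAnova:
    """Three-way ANOVA model of left–right FJROM coefficients of variation.

    Expects one row per horse × gait × limb pair with columns ``horse_id``,
    ``gait`` (walk/trot), ``limb_pair`` (front/hind), ``lameness``
    (sound/lame) and ``cv_percent``.
    """

    def __init__(self, records: pd.DataFrame):
        required = {"cv_percent"}
        if not required.issubset(records.columns):
            raise ValueError(f"records must carry columns {sorted(required)}")
        if (records["cv_percent"] < 0).any():
            raise ValueError("cv_percent must be non-negative")
        self.records = records.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RomVariabilityAnova":
        return cls(df)

    def fit(self, alpha: float = 0.05, typ: int = 2) -> RomVariabilityResults:
        part = anova3_partition(self.records, alpha=alpha, typ=typ)
        return RomVariabilityResults(partition=part, records=self.records)
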