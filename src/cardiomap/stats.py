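"""Study-level statistics for microtissue AP metrics.

Covers the analyses a screening study runs on top of the per-tissue
metrics: the nested variability decomposition across
beat/tissue/mold/batch replicate levels, KS normality, paired dose
tests, power-based sample sizing, ECDFs, restitution summaries,
sigma-shift dose-response maps, normalized mean-difference signature
maps, and the triangulation-vs-APD_MxR slope comparison with a
slope-equality Z-test.

The variability decomposition deliberately follows the plain
sequential-SD scheme (SDs of means at each nesting level, reported
mean +/- SD across batches) rather than a REML mixed model: the
components it reports are the directly interpretable replicate SDs a
screening lab quotes, at the cost of upward contamination of each level
by the levels below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VarianceComponents",
    "DoseResponseTable",
    "ShiftMap",
    "SignatureMap",
    "SlopeComparison",
    "variance_components",
    "ks_normality",
    "paired_metric_test",
    "sample_size_for_change",
    "sigma_shift_map",
    "mean_difference_signature",
    "ecdf",
    "restitution_curve",
    "tri_vs_mxr_slopes",
]


# --------------------------------------------------------------------------
# variability decomposition
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    """Replicate SDs at each nesting level, in ms.

    ``*_sd_ms`` is the mean across batches and ``*_sd_sd_ms`` its SD
    across batches; the batch-level SD is a single number (there is only
    one set of batch means, so it carries no dispersion). NaN marks a
    level with too few units to estimate.
    """

    beat_sd_ms: float
    beat_sd_sd_ms: float
    tissue_sd_ms: float
    tissue_sd_sd_ms: float
    mold_sd_ms: float
    mold_sd_sd_ms: float
    batch_sd_ms: float


def variance_components(data: pd.DataFrame) -> VarianceComponents:
    """Sequential-SD decomposition of a nested APD dataset.

    Expects columns ``batch``, ``mold``, ``tissue``, ``beat``, ``apd_ms``
    (tissue ids unique within mold, molds within batch). Levels:

    - beat: per-tissue SD across beats, averaged within batch, reported
      mean +/- SD across batches (technical replicates);
    - tissue: SD of tissue means within each mold, averaged per batch,
      mean +/- SD across batches (biological replicates);
    - mold: SD of mold means within each batch, mean +/- SD across
      batches;
    - batch: SD of the batch means (single value).

    Invariant to record order and to adding a constant; scaling the APDs
    by ``c`` scales every component by ``|c|``.
    """
    required = {"batch", "mold", "tissue", "beat", "apd_ms"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if data["apd_ms"].isna().any():
        raise ValueError("apd_ms contains missing values")
    # canonical order: output must be independent of record order
    data = data.sort_values(["batch", "mold", "tissue", "beat"], kind="mergesort")

    # beat level: SD across beats within each tissue
    beat_sd = (
        data.groupby(["batch", "mold", "tissue"])["apd_ms"]
        .std(ddof=1)
        .reset_index(name="sd")
    )
    beat_by_batch = beat_sd.groupby("batch")["sd"].mean().dropna()

    # tissue level: SD of tissue means within each mold
    tissue_means = (
        data.groupby(["batch", "mold", "tissue"])["apd_ms"].mean().reset_index()
    )
    tissue_sd = (
        tissue_means.groupby(["batch", "mold"])["apd_ms"].std(ddof=1).reset_index(name="sd")
    )
    tissue_by_batch = tissue_sd.groupby("batch")["sd"].mean().dropna()

    # mold level: SD of mold means within each batch
    mold_means = data.groupby(["batch", "mold"])["apd_ms"].mean().reset_index()
    mold_by_batch = mold_means.groupby("batch")["apd_ms"].std(ddof=1).dropna()

    # batch level: SD of batch means
    batch_means = data.groupby("batch")["apd_ms"].mean()
    batch_sd = float(batch_means.std(ddof=1)) if len(batch_means) >= 2 else math.nan

    def mean_sd(series: pd.Series) -> tuple[float, float]:
        if len(series) == 0:
            return math.nan, math.nan
        m = float(series.mean())
        s = float(series.std(ddof=1)) if len(series) >= 2 else math.nan
        return m, s

    b_m, b_s = mean_sd(beat_by_batch)
    t_m, t_s = mean_sd(tissue_by_batch)
    m_m, m_s = mean_sd(mold_by_batch)
    return VarianceComponents(
        beat_sd_ms=b_m,
        beat_sd_sd_ms=b_s,
        tissue_sd_ms=t_m,
        tissue_sd_sd_ms=t_s,
        mold_sd_ms=m_m,
        mold_sd_sd_ms=m_s,
        batch_sd_ms=batch_sd,
    )


# --------------------------------------------------------------------------
# hypothesis tests and power
# --------------------------------------------------------------------------


def ks_normality(values, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample mean and SD.

    The plain KS p-value (default) treats the fitted parameters as known,
    the convention of most screening reports; set ``lilliefors=True`` for
    the estimated-parameter correction.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise ValueError("ks_normality requires n >= 8")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input has no defined normality statistic")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def paired_metric_test(
    before, after, paired: bool = True
) -> tuple[float, float, float]:
    """Two-tailed Student t-test; returns ``(t, p, mean_diff)``.

    ``mean_diff`` is mean(after) - mean(before), the quantity entering
    the signature maps. A paired comparison with identically zero
    difference variance is degenerate and raises.
    """
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        if len(a) < 2:
            raise ValueError("need n >= 2")
        d = b - a
        if np.allclose(d, d[0]) and d[0] != 0:
            raise ValueError("zero variance of nonzero differences: degenerate t")
        t, p = sps.ttest_rel(b, a)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per group")
        t, p = sps.ttest_ind(b, a)
    return float(t), float(p), float(b.mean() - a.mean())


def sample_size_for_change(
    mean: float,
    sd: float,
    rel_change: float,
    alpha: float = 0.05,
    power: float = 0.80,
    design: str = "one_sample",
    n_max: int = 10_000,
) -> int:
    """Smallest n detecting a relative change with a two-sided t-test.

    The effect is ``delta = rel_change * mean``; for the ``one_sample``
    and ``paired`` designs (a paired test is a one-sample test on
    differences) power is computed exactly from the noncentral t
    distribution and n is increased until the requested power is
    reached. A minimum of n = 2 is enforced — one observation cannot
    estimate a variance.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if not (0 < rel_change <= 1):
        raise ValueError("rel_change must be in (0, 1]")
    if design not in ("one_sample", "paired"):
        raise ValueError("design must be 'one_sample' or 'paired'")
    delta = rel_change * mean
    d = abs(delta) / sd  # standardized effect
    if d == 0:
        raise ValueError("effect size is zero: undetectable")
    for n in range(2, n_max + 1):
        if _one_sample_t_power(d, n, alpha) >= power:
            return n
    raise ValueError(f"required n exceeds {n_max}")


def _one_sample_t_power(d: float, n: int, alpha: float) -> float:
    df = n - 1
    nc = d * math.sqrt(n)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


# --------------------------------------------------------------------------
# dose-response tables, shift and signature maps
# --------------------------------------------------------------------------


@dataclass
class DoseResponseTable:
    """Tissue x dose x metric observations with a designated control dose.

    ``data`` is long-form with columns ``tissue``, ``dose``, ``metric``,
    ``value`` and a boolean ``excitable``; a tissue that loses
    excitability at a dose has ``excitable == False`` there and its
    metric values are ignored (when excitability is lost, the other
    metrics cannot be measured).
    """

    data: pd.DataFrame
    control_dose: object

    def __post_init__(self) -> None:
        required = {"tissue", "dose", "metric", "value", "excitable"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.control_dose not in set(self.data["dose"]):
            raise ValueError("control dose absent from table")

    @property
    def doses(self) -> list:
        doses = sorted(set(self.data["dose"]))
        return doses

    @property
    def metrics(self) -> list[str]:
        return sorted(set(self.data["metric"]))


@dataclass
class ShiftMap:
    """Per-tissue metric shifts in control-SD units.

    ``values`` is indexed by tissue with (metric, dose) columns; NaN
    marks unavailable cells (non-excitable tissue at that dose — the
    cells rendered black on a heatmap).
    """

    values: pd.DataFrame
    control_dose: object
    flagged_metrics: tuple[str, ...] = ()


@dataclass
class SignatureMap:
    """Mean paired dose-control differences, normalized by control SD.

    ``values`` and ``pvalues`` are (metric x dose) frames; the control
    column is exactly 0 and non-significant. ``significant`` is the
    p < alpha mask; the sign of ``values`` encodes the direction of the
    dose response.
    """

    values: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    control_dose: object
    alpha: float = 0.05


def sigma_shift_map(table: DoseResponseTable) -> ShiftMap:
    """Shift of every (tissue, metric, dose) cell from the control mean,
    in units of the control SD of that metric.

    Control statistics are computed over excitable control tissues;
    metrics with fewer than 2 such tissues, or zero control SD, are
    flagged and their columns left NaN. By construction the control
    columns have mean 0 and SD 1 per metric.
    """
    df = table.data
    flagged = []
    pieces = {}
    for metric in table.metrics:
        sub = df[df["metric"] == metric]
        ctrl = sub[(sub["dose"] == table.control_dose) & sub["excitable"]]
        if len(ctrl) < 2 or ctrl["value"].std(ddof=1) == 0:
            flagged.append(metric)
            mu, sd = math.nan, math.nan
        else:
            mu = ctrl["value"].mean()
            sd = ctrl["value"].std(ddof=1)
        for dose in table.doses:
            cell = sub[sub["dose"] == dose].set_index("tissue")
            shifted = (cell["value"] - mu) / sd
            shifted[~cell["excitable"]] = math.nan
            pieces[(metric, dose)] = shifted
    values = pd.DataFrame(pieces)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["metric", "dose"])
    return ShiftMap(
        values=values, control_dose=table.control_dose, flagged_metrics=tuple(flagged)
    )


def mean_difference_signature(table: DoseResponseTable, alpha: float = 0.05) -> SignatureMap:
    """Normalized mean paired difference of each metric at each dose.

    For every (metric, dose), tissues excitable at both the dose and the
    control are paired; the mean difference is divided by the metric's
    control SD and significance comes from the two-tailed paired t-test.
    Cells with fewer than 3 pairs are NaN. The control column is exactly
    zero by construction.
    """
    df = table.data
    metrics = table.metrics
    doses = table.doses
    values = pd.DataFrame(index=metrics, columns=doses, dtype=float)
    pvals = pd.DataFrame(index=metrics, columns=doses, dtype=float)
    for metric in metrics:
        sub = df[df["metric"] == metric]
        ctrl = (
            sub[(sub["dose"] == table.control_dose) & sub["excitable"]]
            .set_index("tissue")["value"]
        )
        sd_ctr = ctrl.std(ddof=1)
        for dose in doses:
            if dose == table.control_dose:
                values.loc[metric, dose] = 0.0
                pvals.loc[metric, dose] = 1.0
                continue
            cell = sub[(sub["dose"] == dose) & sub["excitable"]].set_index("tissue")[
                "value"
            ]
            common = ctrl.index.intersection(cell.index)
            if len(common) < 3 or not np.isfinite(sd_ctr) or sd_ctr == 0:
                continue
            try:
                t, p, mean_diff = paired_metric_test(ctrl.loc[common], cell.loc[common])
            except ValueError:
                # exactly constant nonzero differences: direction is known
                # but the t statistic is degenerate; leave p unavailable
                mean_diff = float(cell.loc[common].mean() - ctrl.loc[common].mean())
                p = math.nan
            values.loc[metric, dose] = mean_diff / sd_ctr
            pvals.loc[metric, dose] = p
    return SignatureMap(
        values=values,
        pvalues=pvals,
        significant=pvals < alpha,
        control_dose=table.control_dose,
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# curves
# --------------------------------------------------------------------------


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: returns (sorted x, F(x))."""
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) == 0:
        raise ValueError("ecdf requires at least one value")
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


def restitution_curve(apds_by_cl: dict[float, "np.ndarray | list"]) -> pd.DataFrame:
    """Per-cycle-length APD summary, ordered by cycle length.

    Input maps pacing cycle length (ms) to the APD observations recorded
    at that rate; output has columns ``cycle_length_ms``, ``mean_ms``,
    ``sd_ms``, ``n``.
    """
    rows = []
    for cl in sorted(apds_by_cl):
        vals = np.asarray(apds_by_cl[cl], dtype=float)
        rows.append(
            dict(
                cycle_length_ms=float(cl),
                mean_ms=float(vals.mean()),
                sd_ms=float(vals.std(ddof=1)) if len(vals) >= 2 else math.nan,
                n=len(vals),
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# slope comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseSlope:
    dose: object
    slope: float
    intercept: float
    stderr: float
    n: int
    z_vs_control: float
    p_vs_control: float


@dataclass
class SlopeComparison:
    """OLS fits of APD_tri on APD_MxR per dose, compared against control.

    The equality of two regression coefficients is tested with
    Z = (b_d - b_ctrl) / sqrt(SE_d^2 + SE_ctrl^2) against the standard
    normal (two-sided).
    """

    control_dose: object
    slopes: list[DoseSlope]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.slopes])


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(x) == 0:
        raise ValueError("degenerate x variance: slope unavailable")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.stderr)


def tri_vs_mxr_slopes(
    points_by_dose: dict[object, np.ndarray], control_dose: object
) -> SlopeComparison:
    """Per-dose slope of APD_tri vs APD_MxR with slope-equality Z-tests.

    ``points_by_dose`` maps dose label to an (n, 2) array of per-tissue
    (apd_mxr, apd_tri) pairs, n >= 3 per dose. The control compares to
    itself with Z = 0, p = 1.
    """
    if control_dose not in points_by_dose:
        raise ValueError("control dose missing")
    fits = {}
    for dose, pts in points_by_dose.items():
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError(f"dose {dose!r}: need an (n>=3, 2) point array")
        fits[dose] = (*_ols_slope(pts[:, 0], pts[:, 1]), pts.shape[0])

    b0, _, se0, _ = fits[control_dose]
    slopes = []
    for dose, (b, a, se, n) in fits.items():
        if dose == control_dose:
            z, p = 0.0, 1.0
        else:
            z = (b - b0) / math.hypot(se, se0)
            p = float(2 * sps.norm.sf(abs(z)))
        slopes.append(
            DoseSlope(
                dose=dose, slope=b, intercept=a, stderr=se, n=n,
                z_vs_control=float(z), p_vs_control=p,
            )
        )
    return SlopeComparison(control_dose=control_dose, slopes=slopes)
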