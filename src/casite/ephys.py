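"""Curve fitting and statistics for two-electrode voltage-clamp peak tables.

The module covers the standard ASIC analysis chain: normalization of peak
currents, Hill fits of the pH dependence of activation and of steady-state
desensitization (SSD), inhibition (dose-response) fits, single-exponential
recovery/onset kinetics, per-oocyte paired midpoint shifts and tau ratios,
and the group comparisons (paired t, one-way ANOVA with Dunnett or Tukey).

Model forms:

    activation / SSD:  I = Imax / (1 + (10^-pH50 / 10^-pH)^nH)
                         = Imax / (1 + 10^(s * nH * (pH - pH50)))
                       with s = +1 for activation (response grows with
                       acidity) and s = -1 for SSD (availability falls with
                       acidic conditioning); nH is reported positive and the
                       SSD midpoint is called pHD50.
    inhibition:        I = NonIn + (Imax - NonIn) / (1 + (x / IC50)^nH)
    recovery:          I = Imax * (1 - exp(-t / tau))
    onset of SSD:      I = NonDes + (Imax - NonDes) * exp(-t / tau)

Fits minimize unweighted least squares with a 5-point multistart on the
midpoint parameter and bounds pH50 in [3, 9], nH in (0, 10], IC50 in
(1e-4, 1e3] mM.  Inward currents are stored signed (negative nA); all
fitting is done on magnitudes of normalized responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateSeriesError,
    DegenerateTestError,
    DomainError,
    FitError,
    InsufficientPairsError,
    UnidentifiableError,
)

PEAK_COLUMNS = [
    "oocyte_id",
    "construct",
    "protocol",
    "divalent",
    "conc_mM",
    "stimulus",
    "peak_nA",
]

PH50_BOUNDS = (3.0, 9.0)
NH_BOUNDS = (1e-6, 10.0)
IC50_BOUNDS = (1e-4, 1e3)
FIT_TOL = 1e-10


# ---------------------------------------------------------------------------
# model curves


def hill_curve(ph, imax, ph50, nh, kind="activation"):
    """Hill pH-dependence curve; `kind` selects activation or SSD orientation."""
    s = 1.0 if kind == "activation" else -1.0
    return imax / (1.0 + 10.0 ** (s * nh * (np.asarray(ph, float) - ph50)))


def inhibition_curve(x, imax, non_in, ic50, nh):
    return non_in + (imax - non_in) / (1.0 + (np.asarray(x, float) / ic50) ** nh)


def recovery_curve(t, imax, tau):
    return imax * (1.0 - np.exp(-np.asarray(t, float) / tau))


def onset_curve(t, imax, non_des, tau):
    return non_des + (imax - non_des) * np.exp(-np.asarray(t, float) / tau)


# ---------------------------------------------------------------------------
# fit result containers


@dataclass
class HillFit:
    imax: float
    ph50: float  # pHD50 when kind == "ssd"
    nh: float
    se: dict[str, float]
    kind: str
    sse: float
    n_points: int
    converged: bool = True

    @property
    def phd50(self) -> float:
        return self.ph50


@dataclass
class InhibitionFit:
    imax: float
    non_in: float
    ic50: float
    nh: float
    se: dict[str, float]
    sse: float
    n_points: int
    converged: bool = True


@dataclass
class ExponentialFit:
    imax: float
    tau: float
    non_des: float | None
    se: dict[str, float]
    kind: str  # recovery or onset
    sse: float
    n_points: int
    converged: bool = True


@dataclass
class PairedShift:
    deltas: dict[str, float]  # oocyte -> low-arm minus high-arm midpoint
    mean: float
    sd: float
    n: int
    n_dropped: int = 0


@dataclass
class TauRatio:
    ratios: dict[str, float]
    mean: float
    sd: float
    n: int
    protocol: str


@dataclass
class StatsResult:
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value out of [0,1]: {self.p_value}")


# ---------------------------------------------------------------------------
# normalization


def normalize_series(records: pd.DataFrame) -> pd.DataFrame:
    """Return the series with a `response` column of normalized magnitudes.

    Activation/SSD series are divided by the maximal peak magnitude of the
    series (the normalized maximum is exactly 1).  Recovery/onset series are
    divided by the control response, encoded as rows with an empty
    ``stimulus`` field; control rows are dropped from the output.
    """
    if records.empty:
        raise DegenerateSeriesError("empty peak series")
    protocols = records["protocol"].unique()
    if len(protocols) != 1:
        raise DomainError(f"normalize_series expects one protocol, got {protocols}")
    protocol = protocols[0]
    out = records.copy()
    mag = out["peak_nA"].abs()
    if protocol in ("activation", "ssd", "inhibition"):
        denom = mag.max()
        if not denom > 0:
            raise DegenerateSeriesError("maximal peak amplitude is zero")
        out["response"] = mag / denom
        return out
    if protocol in ("recovery", "onset"):
        is_control = out["stimulus"].isna()
        if not is_control.any():
            raise DegenerateSeriesError(
                f"{protocol} series has no control row (empty stimulus)"
            )
        denom = mag[is_control].mean()
        if not denom > 0:
            raise DegenerateSeriesError("control amplitude is zero")
        out = out.loc[~is_control].copy()
        out["response"] = out["peak_nA"].abs() / denom
        return out
    raise DomainError(f"unknown protocol {protocol!r}")


# ---------------------------------------------------------------------------
# generic multistart least squares


def _multistart_curve_fit(model, x, y, starts, bounds, names):
    best = None
    best_sse = np.inf
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model,
                x,
                y,
                p0=p0,
                bounds=bounds,
                maxfev=20000,
                xtol=FIT_TOL,
                ftol=FIT_TOL,
                gtol=FIT_TOL,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(x, *popt) - y) ** 2))
        if sse < best_sse:
            best_sse = sse
            best = (popt, pcov)
    if best is None:
        raise FitError(
            "no multistart converged", residuals=np.asarray(y, float)
        )
    popt, pcov = best
    with np.errstate(invalid="ignore"):
        se_vals = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(
            len(popt), np.nan
        )
    se = dict(zip(names, (float(s) for s in se_vals)))
    return popt, se, best_sse


def _check_series(x, y, min_distinct, what):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise DomainError("stimulus and response lengths differ")
    if len(np.unique(x)) < min_distinct:
        raise FitError(
            f"{what} needs >= {min_distinct} distinct stimulus values",
            residuals=y,
        )
    return x, y


# ---------------------------------------------------------------------------
# fits


def fit_hill(series, kind: str = "activation") -> HillFit:
    """Least-squares Hill fit of a normalized pH-dependence series.

    `series` is (pH values, responses) or a DataFrame with `stimulus` and
    `response` columns.  `kind` is "activation" or "ssd".
    """
    if kind not in ("activation", "ssd"):
        raise DomainError(f"kind must be activation or ssd, got {kind!r}")
    if isinstance(series, pd.DataFrame):
        x, y = series["stimulus"].to_numpy(float), series["response"].to_numpy(float)
    else:
        x, y = series
    x, y = _check_series(x, y, 4, "Hill fit")

    def model(ph, imax, ph50, nh):
        return hill_curve(ph, imax, ph50, nh, kind=kind)

    lo = max(PH50_BOUNDS[0], x.min() - 1.0)
    hi = min(PH50_BOUNDS[1], x.max() + 1.0)
    mid_starts = np.linspace(lo, hi, 5)
    imax0 = max(y.max(), 1e-3)
    nh0 = 1.5 if kind == "activation" else 3.0
    starts = [(imax0, m, nh0) for m in mid_starts]
    bounds = ([1e-6, PH50_BOUNDS[0], NH_BOUNDS[0]], [10.0, PH50_BOUNDS[1], NH_BOUNDS[1]])
    popt, se, sse = _multistart_curve_fit(model, x, y, starts, bounds,
                                          ("imax", "ph50", "nh"))
    return HillFit(
        imax=float(popt[0]), ph50=float(popt[1]), nh=float(popt[2]),
        se=se, kind=kind, sse=sse, n_points=len(x),
    )


def fit_inhibition(series) -> InhibitionFit:
    """Fit of the inhibition equation to response-vs-concentration data.

    Also usable with fitted pH50 values as the "response" to estimate the
    apparent affinity of the midpoint-vs-concentration relation.
    """
    if isinstance(series, pd.DataFrame):
        x, y = series["stimulus"].to_numpy(float), series["response"].to_numpy(float)
    else:
        x, y = series
    x, y = _check_series(x, y, 4, "inhibition fit")
    if np.allclose(y, y[0]):
        raise UnidentifiableError("all responses equal; IC50 unidentifiable")

    def model(c, imax, non_in, ic50, nh):
        return inhibition_curve(c, imax, non_in, ic50, nh)

    span = y.max() - y.min()
    xpos = x[x > 0]
    log_lo = np.log10(max(xpos.min(), IC50_BOUNDS[0])) if len(xpos) else -2
    log_hi = np.log10(min(x.max() if x.max() > 0 else 10.0, IC50_BOUNDS[1]))
    ic50_starts = 10.0 ** np.linspace(log_lo, log_hi, 5)
    starts = [(y.max(), y.min(), c0, 1.0) for c0 in ic50_starts]
    ymin, ymax = float(y.min()), float(y.max())
    pad = max(span, 1e-6)
    bounds = (
        [ymin - pad, ymin - pad, IC50_BOUNDS[0], NH_BOUNDS[0]],
        [ymax + pad, ymax + pad, IC50_BOUNDS[1], NH_BOUNDS[1]],
    )
    popt, se, sse = _multistart_curve_fit(
        model, x, y, starts, bounds, ("imax", "non_in", "ic50", "nh")
    )
    imax, non_in, ic50, nh = (float(v) for v in popt)
    if non_in > imax:  # keep the 0 <= NonIn <= Imax orientation
        imax, non_in = non_in, imax
    return InhibitionFit(
        imax=imax, non_in=non_in, ic50=ic50, nh=nh, se=se, sse=sse, n_points=len(x)
    )


def _fit_exponential(x, y, kind):
    x, y = _check_series(x, y, 4, f"{kind} fit")
    if np.allclose(y, y[0]):
        raise UnidentifiableError(f"constant series; {kind} tau unidentifiable")
    tau_starts = np.geomspace(max(x[x > 0].min(), 1e-3), max(x.max(), 1e-2), 5)
    if kind == "recovery":
        def model(t, imax, tau):
            return recovery_curve(t, imax, tau)
        starts = [(max(y.max(), 1e-3), t0) for t0 in tau_starts]
        bounds = ([1e-6, 1e-6], [10.0, 1e5])
        names = ("imax", "tau")
    else:
        def model(t, imax, non_des, tau):
            return onset_curve(t, imax, non_des, tau)
        starts = [(max(y.max(), 1e-3), max(y.min(), 0.0), t0) for t0 in tau_starts]
        bounds = ([1e-6, 0.0, 1e-6], [10.0, 10.0, 1e5])
        names = ("imax", "non_des", "tau")
    popt, se, sse = _multistart_curve_fit(model, x, y, starts, bounds, names)
    if kind == "recovery":
        imax, tau = (float(v) for v in popt)
        non_des = None
    else:
        imax, non_des, tau = (float(v) for v in popt)
    if not tau > 0:
        raise FitError(f"non-positive fitted tau: {tau}", residuals=y)
    return ExponentialFit(
        imax=imax, tau=tau, non_des=non_des, se=se, kind=kind,
        sse=sse, n_points=len(x),
    )


def fit_recovery(series) -> ExponentialFit:
    """Single-exponential rise fit of recovery from desensitization."""
    if isinstance(series, pd.DataFrame):
        x, y = series["stimulus"].to_numpy(float), series["response"].to_numpy(float)
    else:
        x, y = series
    return _fit_exponential(np.asarray(x, float), np.asarray(y, float), "recovery")


def fit_onset(series) -> ExponentialFit:
    """Single-exponential decay-to-plateau fit of SSD onset."""
    if isinstance(series, pd.DataFrame):
        x, y = series["stimulus"].to_numpy(float), series["response"].to_numpy(float)
    else:
        x, y = series
    return _fit_exponential(np.asarray(x, float), np.asarray(y, float), "onset")


# ---------------------------------------------------------------------------
# paired summaries


def _midpoint(v) -> float:
    if isinstance(v, HillFit):
        return v.ph50
    return float(v)


def paired_shift(fits_low: Mapping, fits_high: Mapping) -> PairedShift:
    """Per-oocyte midpoint shift, low-divalent arm minus high-divalent arm."""
    common = sorted(set(fits_low) & set(fits_high))
    dropped = len(set(fits_low) ^ set(fits_high))
    if len(common) < 2:
        raise InsufficientPairsError(
            f"need >= 2 oocytes present in both arms, have {len(common)}"
        )
    deltas = {k: _midpoint(fits_low[k]) - _midpoint(fits_high[k]) for k in common}
    vals = np.array(list(deltas.values()))
    return PairedShift(
        deltas=deltas,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n=len(common),
        n_dropped=dropped,
    )


def _tau(v) -> float:
    if isinstance(v, ExponentialFit):
        return v.tau
    return float(v)


def tau_ratio(fits_low: Mapping, fits_high: Mapping, protocol: str) -> TauRatio:
    """Per-oocyte tau ratio: recovery low/high, onset high/low."""
    if protocol not in ("recovery", "onset"):
        raise DomainError(f"protocol must be recovery or onset, got {protocol!r}")
    common = sorted(set(fits_low) & set(fits_high))
    if len(common) < 2:
        raise InsufficientPairsError(
            f"need >= 2 oocytes present in both arms, have {len(common)}"
        )
    ratios = {}
    for k in common:
        lo, hi = _tau(fits_low[k]), _tau(fits_high[k])
        if lo <= 0 or hi <= 0:
            raise DomainError(f"non-positive tau for oocyte {k}")
        ratios[k] = lo / hi if protocol == "recovery" else hi / lo
    vals = np.array(list(ratios.values()))
    return TauRatio(
        ratios=ratios,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n=len(common),
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# group statistics


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    test: str,
    control: str | None = None,
) -> list[StatsResult]:
    """Paired t, or one-way ANOVA followed by Dunnett/Tukey multiple comparisons.

    ``test`` is "paired-t" (exactly two groups, paired by position),
    "anova-dunnett" (``control`` names the reference group) or "anova-tukey".
    Two-sided throughout.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], float) for k in names]
    if test == "paired-t":
        if len(arrays) != 2:
            raise DomainError("paired-t needs exactly two groups")
        a, b = arrays
        if len(a) != len(b) or len(a) < 2:
            raise DomainError("paired-t needs >= 2 pairs of equal length")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            if np.allclose(diffs, 0.0):
                return [StatsResult("paired-t", 0.0, 1.0, tuple(names))]
            raise DegenerateTestError("zero variance of nonzero paired differences")
        res = stats.ttest_rel(a, b)
        return [StatsResult("paired-t", float(res.statistic), float(res.pvalue),
                            tuple(names))]
    if test in ("anova-dunnett", "anova-tukey"):
        if len(arrays) < 3:
            raise DomainError("ANOVA needs >= 3 groups")
        f = stats.f_oneway(*arrays)
        out = [StatsResult("anova", float(f.statistic), float(f.pvalue), tuple(names))]
        if test == "anova-dunnett":
            if control is None or control not in groups:
                raise DomainError("anova-dunnett needs a valid control group name")
            treat_names = [k for k in names if k != control]
            res = stats.dunnett(
                *[np.asarray(groups[k], float) for k in treat_names],
                control=np.asarray(groups[control], float),
            )
            for k, s, p in zip(treat_names, res.statistic, res.pvalue):
                out.append(
                    StatsResult("dunnett", float(s), float(min(p, 1.0)), (k, control))
                )
        else:
            res = stats.tukey_hsd(*arrays)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    out.append(
                        StatsResult(
                            "tukey",
                            float(res.statistic[i, j]),
                            float(min(res.pvalue[i, j], 1.0)),
                            (names[i], names[j]),
                        )
                    )
        return out
    raise DomainError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# per-oocyte fitting over a peak table


def fit_peak_table(records: pd.DataFrame) -> pd.DataFrame:
    """Fit every (oocyte, protocol, divalent, conc) series of a peak table.

    Returns one row per series with the fitted parameters; the fit family is
    chosen by the protocol (Hill for activation/ssd, inhibition, exponential
    for recovery/onset).
    """
    rows = []
    keys = ["oocyte_id", "construct", "protocol", "divalent", "conc_mM"]
    for (oo, construct, protocol, divalent, conc), sub in records.groupby(
        keys, sort=True, dropna=False
    ):
        norm = normalize_series(sub)
        row = {
            "oocyte_id": oo, "construct": construct, "protocol": protocol,
            "divalent": divalent, "conc_mM": conc, "n_points": len(norm),
        }
        if protocol in ("activation", "ssd"):
            fit = fit_hill(norm, kind=protocol)
            row.update(
                midpoint=fit.ph50, nh=fit.nh, imax=fit.imax,
                midpoint_se=fit.se.get("ph50", math.nan),
            )
        elif protocol == "inhibition":
            fit = fit_inhibition(norm)
            row.update(ic50=fit.ic50, nh=fit.nh, imax=fit.imax, non_in=fit.non_in)
        elif protocol == "recovery":
            fit = fit_recovery(norm)
            row.update(tau=fit.tau, imax=fit.imax)
        elif protocol == "onset":
            fit = fit_onset(norm)
            row.update(tau=fit.tau, imax=fit.imax, non_des=fit.non_des)
        else:
            raise DomainError(f"unknown protocol {protocol!r}")
        rows.append(row)
    return pd.DataFrame(rows)
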