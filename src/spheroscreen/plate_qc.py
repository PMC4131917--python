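"""HTS assay-quality statistics for spheroid screening plates.

Implements the screening-window coefficient (Z-factor / Z'), signal window,
coefficient of variation, plate-uniformity assessment (robust FDR-based
outlier removal, D'Agostino-Pearson K2 normality, t-test detection power),
growth-increase and drug-washout dilution arithmetic, and the two viability
normalisation schemes (assay-validation and cytotoxicity anchoring).

Acceptance criteria follow the usual HTS guidance: an assay condition passes
when Z > 0.4, SW > 2 and CV < 20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_cli import PlateReading, WellRole

Z_PASS = 0.4
SW_PASS = 2.0
CV_PASS = 20.0


@dataclass
class SummaryStats:
    """Mean, SD and count of a group of well readings."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStats":
        v = np.asarray(values, dtype=float)
        return cls(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=v.size)


@dataclass
class QCStats:
    z_factor: float
    signal_window: float
    cv_percent: float

    @property
    def passes(self) -> bool:
        return (self.z_factor > Z_PASS and self.signal_window > SW_PASS
                and self.cv_percent < CV_PASS)


def z_factor(sample: SummaryStats, control: SummaryStats) -> float:
    """Screening-window coefficient Z = 1 - 3(sd_s + sd_c)/|mean_s - mean_c|.

    Z' is the same quantity computed between positive and negative controls.
    Z <= 1 always, with equality only when both SDs vanish.
    """
    sep = abs(sample.mean - control.mean)
    if sep == 0:
        raise ValueError("Z-factor undefined: sample and control means are equal")
    return 1.0 - 3.0 * (sample.sd + control.sd) / sep


def signal_window(high: SummaryStats, low: SummaryStats) -> float:
    """Signal window SW = (|mean_h - mean_l| - 3(sd_h + sd_l)) / sd_h."""
    if high.sd <= 0:
        raise ValueError("signal window undefined for zero high-signal SD")
    return (abs(high.mean - low.mean) - 3.0 * (high.sd + low.sd)) / high.sd


def cv_percent(s: SummaryStats) -> float:
    """Coefficient of variation, 100 * sd / mean."""
    if s.mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * s.sd / abs(s.mean)


def qc_stats(sample: SummaryStats, control: SummaryStats) -> QCStats:
    return QCStats(z_factor=z_factor(sample, control),
                   signal_window=signal_window(sample, control),
                   cv_percent=cv_percent(sample))


def growth_increase(v_day1: float, v_day7: float) -> float:
    """Spheroid volume increase %, 100 * (V_day7 - V_day1) / V_day1."""
    if not v_day1 > 0:
        raise ValueError("day-1 volume must be positive")
    return (v_day7 - v_day1) * 100.0 / v_day1


def residual_fraction(well_volume: float, exchanged_volume: float,
                      n_exchanges: int) -> float:
    """Drug fraction left after partial media exchanges.

    Each exchange keeps (well - exchanged)/well of the dissolved drug; the
    fractions multiply.  Two 150 ul exchanges in a 200 ul well leave 1/16.
    """
    if not 0 < exchanged_volume <= well_volume:
        raise ValueError("exchanged volume must be in (0, well volume]")
    if n_exchanges < 0:
        raise ValueError("n_exchanges must be >= 0")
    return ((well_volume - exchanged_volume) / well_volume) ** n_exchanges


# ---------------------------------------------------------------------------
# Outliers and normality
# ---------------------------------------------------------------------------

def detect_outliers_robust(values: Sequence[float], q_percent: float = 1.0
                           ) -> list[int]:
    """Robust FDR-controlled outlier flagging for a single group of values.

    Location-only variant of the robust-regression-plus-FDR (ROUT) idea:
    residuals from the median are scaled by the robust SD (the 68.27th
    percentile of absolute residuals, with a small-sample correction
    n/(n-1)), converted to two-sided t p-values, and flagged by a
    Benjamini-Hochberg step at rate Q.  Returns indices of flagged values,
    most extreme first; constant data flags nothing.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 5:
        raise ValueError("robust outlier detection needs at least 5 values")
    if q_percent <= 0:
        raise ValueError("Q must be positive")
    resid = v - np.median(v)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        return []
    t = np.abs(resid) / rsdr
    p = 2.0 * stats.t.sf(t, df=n - 1)
    order = np.argsort(p)
    q = q_percent / 100.0
    thresh = q * (np.arange(1, n + 1)) / n
    passing = p[order] <= thresh
    k = int(np.max(np.nonzero(passing)[0]) + 1) if passing.any() else 0
    return [int(i) for i in order[:k]]


def dagostino_k2(values: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K2 normality test.

    K2 is the sum of the squared normal-transformed sample skewness and
    kurtosis; under normality K2 ~ chi-square with 2 df.  Requires n >= 20
    (the kurtosis transformation breaks down below that).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20:
        raise ValueError("K2 test requires n >= 20")
    k2, p = stats.normaltest(v)
    return float(k2), float(p)


def detection_power(drop_percent: float, cv_percent: float, n_per_group: int,
                    alpha: float = 0.05, tails: str = "one",
                    design: str = "two-sample") -> float:
    """Power of a t-test to detect a viability drop at a given well CV.

    The control group has mean 100 and SD equal to the CV; the treated group
    has mean ``100 - drop_percent`` and SD scaled with its mean (both groups
    carry the same relative variability).  Power is computed from the
    noncentral t distribution with the pooled-SD noncentrality

        ncp = drop / (sd_pooled * sqrt(2/n)),   sd_pooled^2 = (sd_c^2 + sd_t^2)/2

    and df = 2n - 2.  ``design='one-sample'`` instead tests the treated
    sample of n wells against the fixed plate mean of 100 (df = n - 1).
    """
    if not 0 < drop_percent < 100:
        raise ValueError("drop_percent must be in (0, 100)")
    if cv_percent <= 0:
        raise ValueError("cv_percent must be positive")
    if n_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")

    sd_c = cv_percent
    sd_t = cv_percent * (100.0 - drop_percent) / 100.0
    if design == "two-sample":
        df = 2 * n_per_group - 2
        sd_pooled = math.sqrt((sd_c ** 2 + sd_t ** 2) / 2.0)
        ncp = drop_percent / (sd_pooled * math.sqrt(2.0 / n_per_group))
    elif design == "one-sample":
        df = n_per_group - 1
        ncp = drop_percent / (sd_t / math.sqrt(n_per_group))
    else:
        raise ValueError("design must be 'two-sample' or 'one-sample'")
    a = alpha if tails == "one" else alpha / 2.0
    tcrit = stats.t.ppf(1.0 - a, df)
    return float(stats.nct.sf(tcrit, df, ncp))


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def anchor_normalize(values: Sequence[float] | float, low_mean: float,
                     high_mean: float) -> np.ndarray | float:
    """Linear map sending ``low_mean`` to 0% and ``high_mean`` to 100%.

    Values outside [0, 100] are allowed (never clipped).
    """
    if high_mean == low_mean:
        raise ValueError("anchor means are equal; normalisation undefined")
    scalar = np.isscalar(values)
    v = np.asarray(values, dtype=float)
    out = (v - low_mean) * 100.0 / (high_mean - low_mean)
    return float(out) if scalar else out


def _role_mean(readings: Sequence[PlateReading], role: WellRole) -> float:
    vals = [r.value for r in readings if r.role == role]
    if not vals:
        raise ValueError(f"no {role.value} wells present; cannot anchor")
    return float(np.mean(vals))


def normalize_readings(readings: Sequence[PlateReading], scheme: str
                       ) -> pd.DataFrame:
    """Normalise raw readings of one run to the % scale.

    ``scheme='validation'``: the highest reading maps to 100% and the mean
    of the cell-free media wells to 0%.  ``scheme='cytotoxicity'``: the
    negative (vehicle) control mean maps to 100% viability and the positive
    (25% DMSO) control mean to 0%.

    Returns a DataFrame with the original reading fields plus
    ``viability_pct``, sample wells only.
    """
    if scheme == "validation":
        low = _role_mean(readings, WellRole.MEDIA_ONLY)
        high = float(max(r.value for r in readings))
    elif scheme == "cytotoxicity":
        low = _role_mean(readings, WellRole.POSITIVE_CONTROL)
        high = _role_mean(readings, WellRole.NEGATIVE_CONTROL)
    else:
        raise ValueError("scheme must be 'validation' or 'cytotoxicity'")
    rows = []
    for r in readings:
        if r.role != WellRole.SAMPLE:
            continue
        rows.append({
            "run_id": r.run_id, "well": r.well, "assay": r.assay,
            "condition": r.condition, "concentration_uM": r.concentration_uM,
            "viability_pct": anchor_normalize(r.value, low, high),
        })
    return pd.DataFrame(rows)


# public alias used by the CLI fit command
def normalized_points(readings: Sequence[PlateReading],
                      scheme: str = "cytotoxicity") -> pd.DataFrame:
    return normalize_readings(readings, scheme)


# ---------------------------------------------------------------------------
# Plate-level reports
# ---------------------------------------------------------------------------

@dataclass
class UniformityReport:
    """Whole-plate spheroid-size uniformity summary."""

    n_wells: int
    mean_diameter: float
    cv_percent: float
    outlier_ids: list = field(default_factory=list)
    k2_statistic: float = math.nan
    k2_p: float = math.nan
    power_1_minus_beta: float = math.nan


def uniformity_report(diameters: Sequence[float],
                      ids: Sequence | None = None,
                      q_percent: float = 1.0,
                      drop_percent: float = 20.0,
                      n_per_group: int = 6,
                      alpha: float = 0.05) -> UniformityReport:
    """Assess plate uniformity of spheroid diameters.

    Outliers are removed by the robust FDR procedure, the cleaned values are
    tested for normality (K2, when n >= 20), and the detection power of a
    one-tailed t-test for a ``drop_percent`` viability drop at the plate's
    CV is reported.
    """
    d = np.asarray(diameters, dtype=float)
    ids = list(ids) if ids is not None else list(range(d.size))
    out_idx = detect_outliers_robust(d, q_percent)
    keep = np.ones(d.size, dtype=bool)
    keep[out_idx] = False
    clean = d[keep]
    s = SummaryStats.from_values(clean)
    cv = cv_percent(s)
    k2 = p = math.nan
    if clean.size >= 20:
        k2, p = dagostino_k2(clean)
    power = detection_power(drop_percent, cv, n_per_group, alpha, tails="one")
    return UniformityReport(
        n_wells=int(d.size), mean_diameter=s.mean, cv_percent=cv,
        outlier_ids=[ids[i] for i in out_idx],
        k2_statistic=k2, k2_p=p, power_1_minus_beta=power,
    )


def qc_table(readings: Sequence[PlateReading]) -> pd.DataFrame:
    """Per-condition Z'/SW/CV table against the positive-control baseline.

    Each (assay, condition/concentration) sample group is compared with the
    positive-control wells of the same assay; the negative-control group row
    reports the classic Z' between negative and positive controls.
    """
    df = pd.DataFrame([{
        "run_id": r.run_id, "assay": r.assay, "role": r.role.value,
        "condition": r.condition, "concentration_uM": r.concentration_uM,
        "value": r.value} for r in readings])
    rows = []
    for (run_id, assay), g in df.groupby(["run_id", "assay"], sort=True):
        pos = g[g.role == WellRole.POSITIVE_CONTROL.value]["value"]
        if len(pos) < 2:
            continue
        control = SummaryStats.from_values(pos)
        groups = [("negative_control", None,
                   g[g.role == WellRole.NEGATIVE_CONTROL.value]["value"])]
        samples = g[g.role == WellRole.SAMPLE.value]
        for (cond, conc), sg in samples.groupby(["condition", "concentration_uM"],
                                                sort=True, dropna=False):
            groups.append((cond, conc, sg["value"]))
        for cond, conc, vals in groups:
            if len(vals) < 2:
                continue
            s = SummaryStats.from_values(vals)
            try:
                q = qc_stats(s, control)
            except ValueError:
                continue
            rows.append({
                "run_id": run_id, "assay": assay, "condition": cond,
                "concentration_uM": conc, "n": s.n, "mean": s.mean,
                "sd": s.sd, "z_factor": q.z_factor,
                "signal_window": q.signal_window, "cv_percent": q.cv_percent,
                "passes": q.passes,
            })
    return pd.DataFrame(rows)
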