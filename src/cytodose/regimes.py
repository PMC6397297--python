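"""Dose-response curves and variance-ratio regime segmentation.

Per-cell records are sorted by total-GFP expression and pooled into
consecutive equal-count bins to form a dose-response curve (DRC).  A
ratio-of-variances statistic

    RoV_i = var(d_{i+1..i+N}) / var(d_{i-N..i-1})

(sample variances over two N-sized windows flanking each interior bin i)
flags transitions between response regimes: entering a dose-response
stretch from a flat no-effect regime the leading window's variance jumps
(RoV >> 1), and entering the saturation plateau it collapses (RoV << 1).
Peaks of |log RoV| above a prominence threshold become candidate
expression thresholds; candidates pooled across descriptors yield two
global thresholds G1 < G2 that sort individual cells into the no-effect,
dose-response and saturation regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gmean, gstd

from .morphometrics import CellRecord

POOLINGS = ("gmean", "mean", "median")

REGIMES = ("no_effect", "dose_response", "saturation")


@dataclass
class DoseResponseCurve:
    """Ordered expression bins with a pooled descriptor statistic.

    ``expression`` holds the geometric mean total-GFP of each bin's
    members; ``stat`` the pooled descriptor value (geometric mean,
    arithmetic mean or median per configuration); ``disp_low``/``disp_high``
    the dispersion band (geometric SD, SD or Q1-Q3); ``n`` the member
    counts.
    """

    descriptor: str
    pooling: str
    expression: np.ndarray
    stat: np.ndarray
    disp_low: np.ndarray
    disp_high: np.ndarray
    n: np.ndarray

    def __len__(self) -> int:
        return len(self.expression)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "expression": self.expression, "stat": self.stat,
            "disp_low": self.disp_low, "disp_high": self.disp_high,
            "n": self.n,
        })


@dataclass
class RoVSeries:
    """Ratio-of-variances values aligned with the DRC bins.

    ``values[i]`` is NaN outside the interior range or where the trailing
    window has zero variance (flagged undefined rather than infinite);
    ``log_scale`` records whether variances were taken on log-transformed
    bin statistics.
    """

    values: np.ndarray
    window: int
    log_scale: bool
    var_lead: Optional[np.ndarray] = None
    var_trail: Optional[np.ndarray] = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class Candidate:
    """One candidate regime-transition threshold on a single curve."""

    expression: float
    index: int
    direction: str      # "up": variance increases ahead (dose-response
                        # onset); "down": variance collapses (saturation)
    magnitude: float    # |log RoV| at the peak


@dataclass
class RegimeSegmentation:
    g1: float
    g2: float
    labels: np.ndarray
    counts: dict


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.to_dict() if isinstance(r, CellRecord) else r
                         for r in records])


def build_drc(records, descriptor: str, n_min: int = 100,
              pooling: str = "gmean") -> DoseResponseCurve:
    """Pool per-cell records into an expression-ordered dose-response curve.

    Records with positive total_gfp and a finite descriptor value are
    sorted by total_gfp and cut into consecutive equal-count bins of at
    least ``n_min`` members (``len // n_min`` bins, sizes differing by at
    most one).  ``pooling`` selects the bin statistic and its dispersion:
    ``gmean`` (geometric mean / geometric SD band), ``mean`` (mean / SD) or
    ``median`` (median / Q1-Q3).
    """
    if pooling not in POOLINGS:
        raise ValueError(f"pooling must be one of {POOLINGS}")
    df = _records_frame(records)
    ok = np.isfinite(df[descriptor]) & (df["total_gfp"] > 0)
    if pooling == "gmean":
        # geometric statistics are defined on positive values only
        ok &= df[descriptor] > 0
    df = df.loc[ok].sort_values("total_gfp", kind="mergesort")
    n = len(df)
    if n < 2 * n_min:
        raise ValueError(
            f"need at least {2 * n_min} usable records for n_min={n_min}, "
            f"got {n} ({2 * n_min - n} short)")
    n_bins = n // n_min
    expr_bins = np.array_split(df["total_gfp"].to_numpy(), n_bins)
    val_bins = np.array_split(df[descriptor].to_numpy(), n_bins)

    expression, stat, lo, hi, counts = [], [], [], [], []
    for e, v in zip(expr_bins, val_bins):
        expression.append(gmean(e))
        if pooling == "gmean":
            g = gmean(v)
            s = gstd(v) if len(v) > 1 and np.ptp(v) > 0 else 1.0
            stat.append(g)
            lo.append(g / s)
            hi.append(g * s)
        elif pooling == "mean":
            m = float(np.mean(v))
            s = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            stat.append(m)
            lo.append(m - s)
            hi.append(m + s)
        else:
            stat.append(float(np.median(v)))
            lo.append(float(np.quantile(v, 0.25)))
            hi.append(float(np.quantile(v, 0.75)))
        counts.append(len(v))
    return DoseResponseCurve(
        descriptor=descriptor, pooling=pooling,
        expression=np.asarray(expression), stat=np.asarray(stat),
        disp_low=np.asarray(lo), disp_high=np.asarray(hi),
        n=np.asarray(counts))


def rov_series(d: Sequence[float], N: int = 3,
               log: bool = True) -> RoVSeries:
    """Ratio of variances in two N-sized windows flanking each point.

    For each interior index i the leading window is ``d[i+1 .. i+N]`` and
    the trailing window ``d[i-N .. i-1]``; both variances are sample
    variances (denominator N-1).  With ``log=True`` (appropriate for
    positive-valued descriptors spanning decades) variances are computed
    on log-transformed values.  Indices whose trailing window has zero
    variance are flagged NaN rather than infinite.
    """
    d = np.asarray(d, dtype=float)
    if N < 2:
        raise ValueError("window size N must be >= 2")
    if len(d) < 2 * N + 1:
        raise ValueError(
            f"series of length {len(d)} too short for N={N} "
            f"(need >= {2 * N + 1})")
    if log:
        if np.any(d <= 0):
            raise ValueError("log-scale RoV requires positive values")
        x = np.log(d)
    else:
        x = d
    out = np.full(len(d), np.nan)
    var_lead = np.full(len(d), np.nan)
    var_trail = np.full(len(d), np.nan)
    for i in range(N, len(d) - N):
        lead = x[i + 1:i + N + 1]
        trail = x[i - N:i]
        var_lead[i] = np.var(lead, ddof=1)
        var_trail[i] = np.var(trail, ddof=1)
        if var_trail[i] == 0:
            continue
        out[i] = var_lead[i] / var_trail[i]
    return RoVSeries(values=out, window=N, log_scale=log,
                     var_lead=var_lead, var_trail=var_trail)


DEFAULT_MIN_LOG_RATIO = 3.0
EPS_QUANTILE = 0.35


def regularized_log_rov(rov: RoVSeries, smooth: int = 1) -> np.ndarray:
    """Stabilised peak-detection score derived from the RoV windows.

    The raw variance ratio is F-distributed with few degrees of freedom
    under the null, so isolated near-zero denominators produce huge
    spurious ratios on perfectly flat curves.  Both window variances are
    therefore regularised by a low quantile of the window variances of the
    whole series (an estimate of the noise floor that tolerates up to
    ~2/3 of the curve being trend-dominated) before taking the log ratio,
    and the result is smoothed with a centred moving mean over
    ``2*smooth+1`` bins: a genuine regime transition elevates several
    consecutive windows coherently, a noise spike does not.
    """
    if rov.var_lead is None or rov.var_trail is None:
        raise ValueError("RoVSeries lacks window variances")
    valid = np.isfinite(rov.var_lead)
    if not valid.any():
        return np.full(len(rov.values), np.nan)
    eps = float(np.quantile(np.concatenate(
        [rov.var_lead[valid], rov.var_trail[valid]]), EPS_QUANTILE))
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log((rov.var_lead + eps) / (rov.var_trail + eps))
    n = len(lr)
    out = np.full(n, np.nan)
    for i in range(n):
        w = lr[max(0, i - smooth):i + smooth + 1]
        w = w[np.isfinite(w)]
        if len(w) == 2 * smooth + 1:
            out[i] = w.mean()
    return out


def detect_thresholds(rov: RoVSeries,
                      curve: Optional[DoseResponseCurve] = None,
                      min_log_ratio: float = DEFAULT_MIN_LOG_RATIO,
                      smooth: int = 1) -> List[Candidate]:
    """Candidate regime transitions from peaks in the RoV series.

    Local maxima of the magnitude of the regularised, smoothed log-RoV
    score (see :func:`regularized_log_rov`) exceeding ``min_log_ratio``
    are ranked by magnitude; the two most prominent, reordered by
    expression, become the curve's candidate thresholds.  Zero, one or
    two candidates may be returned.  Each candidate's direction records
    whether variance rose ("up", a dose-response onset) or collapsed
    ("down", a saturation onset) across the transition.
    """
    score = regularized_log_rov(rov, smooth=smooth)
    mag = np.where(np.isfinite(score), np.abs(score), 0.0)
    peaks, _ = find_peaks(mag, height=min_log_ratio)
    if peaks.size == 0:
        return []
    order = np.argsort(mag[peaks])[::-1][:2]
    chosen = np.sort(peaks[order])
    out = []
    for idx in chosen:
        expr = float(curve.expression[idx]) if curve is not None else float(idx)
        out.append(Candidate(
            expression=expr, index=int(idx),
            direction="up" if score[idx] > 0 else "down",
            magnitude=float(mag[idx])))
    return out


def global_thresholds(candidates: Iterable[Sequence[Candidate]]
                      ) -> tuple[float, float]:
    """Pool per-curve candidates into two global expression thresholds.

    "Up" candidates (variance increasing: dose-response onset) contribute
    to the lower threshold G1 and "down" candidates (saturation onset) to
    G2; each is the geometric mean of its contributors, appropriate for an
    expression axis spanning decades.  Raises ``ValueError`` when either
    side has no contributors or the pooled thresholds cross.
    """
    lowers, uppers = [], []
    for curve_candidates in candidates:
        for c in curve_candidates:
            (lowers if c.direction == "up" else uppers).append(c.expression)
    if not lowers or not uppers:
        raise ValueError(
            f"need at least one lower and one upper candidate "
            f"(got {len(lowers)} lower, {len(uppers)} upper)")
    g1 = float(gmean(lowers))
    g2 = float(gmean(uppers))
    if g1 >= g2:
        raise ValueError(f"crossed global thresholds: G1={g1:g} >= G2={g2:g}")
    return g1, g2


def assign_regimes(records, g1: float, g2: float) -> RegimeSegmentation:
    """Label each cell by thresholding total_gfp at the global thresholds.

    Half-open convention: expression in [0, G1) -> no_effect, [G1, G2) ->
    dose_response, [G2, inf) -> saturation.
    """
    if not g1 < g2:
        raise ValueError("require G1 < G2")
    expr = _records_frame(records)["total_gfp"].to_numpy()
    labels = np.where(expr < g1, "no_effect",
                      np.where(expr < g2, "dose_response", "saturation"))
    counts = {k: int(np.sum(labels == k)) for k in REGIMES}
    return RegimeSegmentation(g1=g1, g2=g2, labels=labels, counts=counts)
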