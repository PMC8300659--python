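"""Per-well alkylation kinetics: from fluorescence time series to k_obs.

The monobromobimane (MBB) assay follows probe incorporation into the single
cysteine of vimentin by fluorescence.  Each well yields a time series
``F_t``; the analysis (i) fits a logistic curve in time to extract the
bottom plateau ``F_o`` (signal of the initially non-alkylated protein),
(ii) linearizes the early phase as ``ln(F_t / F_o)`` whose slope is the
pseudo-first-order rate constant ``k_obs`` (min^-1), and (iii) aggregates
replicate wells per pH with background correction into a titration curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "SigmoidFit",
    "RateEstimate",
    "fit_time_sigmoid",
    "estimate_kobs",
    "analyze_trace",
    "build_titration_curve",
    "absorbance_to_concentration",
    "traces_to_frame",
    "frame_to_traces",
]

KINETICS_COLUMNS = [
    "well_id", "role", "variant", "ph_nominal", "ph_final",
    "replicate", "time_min", "fluorescence_au",
]


@dataclass
class KineticTrace:
    """One well's fluorescence time series with pH and role metadata."""

    well_id: str
    role: str  # sample | background | positive_control
    variant: str
    ph_nominal: float
    ph_final: float
    replicate: int
    times: np.ndarray  # min, strictly increasing
    fluorescence: np.ndarray  # AU

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size < 5:
            raise ValueError(
                f"well {self.well_id!r}: need >=5 time points, got {self.times.size}"
            )
        if self.times.size != self.fluorescence.size:
            raise ValueError(f"well {self.well_id!r}: times/fluorescence length mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"well {self.well_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError(f"well {self.well_id!r}: non-finite fluorescence")


@dataclass
class SigmoidFit:
    """Logistic-in-time fit of one trace; ``bottom`` is the F_o estimate."""

    bottom: float  # AU, curve value at the first sampled time
    top: float  # AU, upper plateau
    rate: float  # min^-1
    midpoint: float  # min, time of half-maximal signal
    r_squared: float
    residual_sd: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class RateEstimate:
    """k_obs from the early-phase ln(F_t/F_o) slope of one well."""

    kobs: float  # min^-1, clipped at 0 for reporting
    slope: float  # min^-1, raw OLS slope (may be negative under noise)
    stderr: float
    window: tuple[int, int]  # [start, stop) indices used
    r_squared: float
    ph_final: float
    warnings: list[str] = field(default_factory=list)


def _logistic(t: np.ndarray, top: float, rate: float, mid: float) -> np.ndarray:
    z = np.clip(-rate * (t - mid), -500.0, 500.0)
    return top / (1.0 + np.exp(z))


def _logistic_jac(t: np.ndarray, top: float, rate: float, mid: float) -> np.ndarray:
    z = np.clip(-rate * (t - mid), -500.0, 500.0)
    s = 1.0 / (1.0 + np.exp(z))
    core = top * s * (1.0 - s)
    return np.column_stack((s, core * (t - mid), -core * rate))


def fit_time_sigmoid(trace: KineticTrace) -> SigmoidFit:
    """Fit a logistic growth curve in time and extract the plateaus.

    The curve family is ``F(t) = top / (1 + exp(-rate (t - mid)))``; the
    reported ``bottom`` is the fitted curve evaluated at the first sampled
    time, i.e. the fluorescence of the still-unmodified protein when the
    reaction starts.  Flat traces degenerate to ``bottom = top = mean``.
    """
    t, F = trace.times, trace.fluorescence
    if np.ptp(F) == 0.0:
        m = float(F[0])
        return SigmoidFit(bottom=m, top=m, rate=0.0, midpoint=math.nan,
                          r_squared=1.0, residual_sd=0.0)

    # no statistically significant rise -> degenerate flat fit
    lin = stats.linregress(t, F)
    if not (lin.slope > 0 and lin.pvalue < 0.01):
        m = float(F.mean())
        return SigmoidFit(bottom=m, top=m, rate=0.0, midpoint=math.nan,
                          r_squared=0.0, residual_sd=float(F.std(ddof=1)),
                          warnings=["no significant rise; flat fit"])

    span = t[-1] - t[0]
    top0 = float(max(F.max(), 1e-12)) * 1.05
    # data-driven midpoint guess: first time the signal crosses half-max
    half = top0 / 2.0
    above = np.nonzero(F >= half)[0]
    mid0 = float(t[above[0]]) if above.size else float(t[-1] * 2.0)
    # crude rate guess from the overall fractional rise
    rise = max((F[-1] - F[0]) / max(top0, 1e-12), 1e-3)
    rate0 = max(rise / span, 0.1 / span)
    starts = [
        (top0, rate0, mid0),
        (top0, 4.0 / span, t[len(t) // 2]),
        (top0 * 10.0, 0.02 / span, t[-1] * 3.0),
    ]
    def _try_lm(p0):
        # plain LM on (top, rate, mid); a solver stopped by the eval cap
        # still returns its best point, which matters on the top->inf
        # ridge of slow, plateau-free traces
        try:
            x, _, _, _, ier = optimize.leastsq(
                lambda p: _logistic(t, *p) - F, p0,
                Dfun=lambda p: _logistic_jac(t, *p), maxfev=400,
                full_output=True)
        except Exception:
            return None
        if ier in (1, 2, 3, 4, 5) and np.all(np.isfinite(x)) \
                and x[0] > 0 and x[1] > 0:
            return x
        return None

    def _try_lm_log(p0):
        # positivity-preserving reparameterization (log top, log rate, mid)
        def resid(p):
            return _logistic(t, np.exp(np.clip(p[0], -50, 50)),
                             np.exp(np.clip(p[1], -50, 50)), p[2]) - F
        try:
            x, _, _, _, ier = optimize.leastsq(
                resid, (np.log(p0[0]), np.log(p0[1]), p0[2]),
                maxfev=400, full_output=True)
        except Exception:
            return None
        if ier in (1, 2, 3, 4, 5) and np.all(np.isfinite(x)):
            return np.array([np.exp(np.clip(x[0], -50, 50)),
                             np.exp(np.clip(x[1], -50, 50)), x[2]])
        return None

    best = None
    for p0 in starts:
        popt = _try_lm(p0)
        alt = _try_lm_log(p0) if popt is None else None
        popt = popt if popt is not None else alt
        if popt is None:
            continue
        ssr = float(np.sum((F - _logistic(t, *popt)) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
        if ssr <= 1e-14 * max(1.0, float(np.sum(F ** 2))):
            break  # numerically exact; skip remaining starts

    notes: list[str] = []
    if best is None:
        # Multistart failed entirely: fall back to robust plateau guesses.
        q = np.sort(F)
        bottom = float(np.mean(q[: max(1, len(q) // 4)]))
        top = float(F.max())
        notes.append("logistic fit did not converge; first-quartile bottom fallback")
        resid = F - np.clip(F, bottom, top)
        return SigmoidFit(bottom=bottom, top=top, rate=math.nan, midpoint=math.nan,
                          r_squared=math.nan, residual_sd=float(np.std(resid)),
                          warnings=notes)

    (top, rate, mid), ssr = best
    fitted = _logistic(t, top, rate, mid)
    tss = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - ssr / tss if tss > 0 else 1.0
    bottom = float(_logistic(np.array([t[0]]), top, rate, mid)[0])
    return SigmoidFit(
        bottom=bottom, top=float(top), rate=float(rate), midpoint=float(mid),
        r_squared=r2, residual_sd=float(np.sqrt(ssr / max(1, len(F) - 3))),
        warnings=notes,
    )


def estimate_kobs(
    trace: KineticTrace,
    f0: float,
    top: float | None = None,
    window_frac: float = 0.3,
    min_points: int = 4,
) -> RateEstimate:
    """OLS slope of ln(F_t / F_o) over the early-phase window.

    The window keeps points with ``F_t <= f0 + window_frac * (top - f0)``
    (where ln-linearity of the logistic holds to good approximation); when
    the threshold leaves fewer than ``min_points`` it expands to the first
    six points.  Non-positive fluorescence points are dropped with a
    warning.  The raw slope is retained for background subtraction; the
    reported ``kobs`` is clipped at zero.
    """
    if not (f0 > 0):
        raise ValueError(f"well {trace.well_id!r}: f0 must be positive, got {f0}")
    t, F = trace.times, trace.fluorescence
    notes: list[str] = []

    if top is not None and top > f0:
        thr = f0 + window_frac * (top - f0)
        # contiguous early-phase prefix below the threshold
        stop = 0
        while stop < len(F) and F[stop] <= thr:
            stop += 1
        if stop < min_points:
            stop = min(6, len(F))
            notes.append("early-phase threshold left <4 points; using first 6 points")
    else:
        stop = len(F)

    idx = np.arange(stop)
    pos = F[idx] > 0
    if not np.all(pos):
        notes.append(f"dropped {int((~pos).sum())} non-positive fluorescence point(s)")
    idx = idx[pos]
    if idx.size < min_points:
        raise ValueError(
            f"well {trace.well_id!r}: only {idx.size} usable points in the early window"
        )

    y = np.log(F[idx] / f0)
    res = stats.linregress(t[idx], y)
    slope = float(res.slope)
    if slope < 0:
        notes.append("negative fitted slope clipped to 0")
    return RateEstimate(
        kobs=max(slope, 0.0), slope=slope, stderr=float(res.stderr),
        window=(int(idx[0]), int(idx[-1]) + 1),
        r_squared=float(res.rvalue) ** 2, ph_final=trace.ph_final, warnings=notes,
    )


def analyze_trace(trace: KineticTrace, window_frac: float = 0.3) -> RateEstimate:
    """Convenience: sigmoid fit for F_o, then the early-phase slope.

    A trace whose fitted rise does not clear five residual SDs is treated
    as flat (no detectable reaction); its slope then uses the full time
    range, which keeps background-well slope estimates from collapsing
    onto a handful of noisy early points.
    """
    sig = fit_time_sigmoid(trace)
    f0 = sig.bottom if sig.bottom > 0 else float(np.median(trace.fluorescence))
    flat = (not math.isfinite(sig.rate)) or \
        (sig.top - sig.bottom) <= 5.0 * sig.residual_sd
    top = None if flat else sig.top
    return estimate_kobs(trace, f0=f0, top=top, window_frac=window_frac)


def build_titration_curve(traces, window_frac: float = 0.3):
    """Aggregate per-well k_obs into a background-corrected k_obs vs pH curve.

    Wells are grouped by nominal pH; within a group the background (no
    protein) raw slope mean is subtracted from every sample slope.  Points
    are keyed by the measured final pH (mean over the group's sample
    wells).  Duplicated wells (same well_id and role) are ignored.
    Returns a :class:`vimcys.titration.TitrationCurve`.
    """
    from .titration import TitrationCurve, TitrationPoint

    seen: set[tuple[str, str]] = set()
    unique = []
    for tr in traces:
        key = (tr.well_id, tr.role)
        if key not in seen:
            seen.add(key)
            unique.append(tr)

    by_ph: dict[float, dict[str, list[KineticTrace]]] = {}
    for tr in unique:
        by_ph.setdefault(round(tr.ph_nominal, 6), {"sample": [], "background": []})
        if tr.role in ("sample", "background"):
            by_ph[round(tr.ph_nominal, 6)][tr.role].append(tr)

    points = []
    for ph_nom in sorted(by_ph):
        grp = by_ph[ph_nom]
        samples = sorted(grp["sample"], key=lambda tr: (tr.replicate, tr.well_id))
        if not samples:
            continue
        bg_slopes, bg_stderrs = [], []
        for tr in sorted(grp["background"], key=lambda tr: tr.well_id):
            try:
                est = analyze_trace(tr, window_frac)
            except ValueError as exc:
                warnings.warn(f"background well skipped: {exc}")
                continue
            bg_slopes.append(est.slope)
            bg_stderrs.append(est.stderr)
        bg = float(np.mean(bg_slopes)) if bg_slopes else 0.0
        if len(bg_slopes) > 1:
            bg_se = float(np.std(bg_slopes, ddof=1) / np.sqrt(len(bg_slopes)))
        elif bg_slopes:
            bg_se = float(bg_stderrs[0])  # single well: its OLS slope SE
        else:
            bg_se = 0.0

        corrected = []
        for tr in samples:
            try:
                est = analyze_trace(tr, window_frac)
            except ValueError as exc:
                warnings.warn(f"sample well skipped: {exc}")
                continue
            corrected.append(est.slope - bg)
        if not corrected:
            warnings.warn(f"pH {ph_nom}: no usable replicates; point excluded")
            continue
        arr = np.asarray(corrected)
        ph_final = float(np.mean([tr.ph_final for tr in samples]))
        rep_sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        # the background slope error is shared by every replicate at this
        # pH, so it propagates into the point SEM as a systematic term
        sem = float(np.hypot(rep_sem, bg_se))
        points.append(TitrationPoint(
            ph_final=ph_final, kobs_mean=float(arr.mean()), sem=sem, n=int(arr.size),
        ))
    points.sort(key=lambda p: p.ph_final)
    return TitrationCurve(points=points)


def absorbance_to_concentration(a280: float, path_cm: float = 1.0,
                                epsilon: float = 22450.0) -> float:
    """Beer-Lambert protein concentration in uM from A280.

    The default molar absorptivity is vimentin's (22,450 M^-1 cm^-1).
    """
    if a280 < 0:
        raise ValueError("absorbance must be non-negative")
    if not (path_cm > 0 and epsilon > 0):
        raise ValueError("path length and extinction coefficient must be positive")
    return a280 / (epsilon * path_cm) * 1e6


def traces_to_frame(traces) -> pd.DataFrame:
    """Long-format kinetics table (one row per time point)."""
    rows = []
    for tr in traces:
        for t, f in zip(tr.times, tr.fluorescence):
            rows.append((tr.well_id, tr.role, tr.variant, tr.ph_nominal,
                         tr.ph_final, tr.replicate, t, f))
    return pd.DataFrame(rows, columns=KINETICS_COLUMNS)


def frame_to_traces(df: pd.DataFrame) -> list[KineticTrace]:
    traces = []
    keys = ["well_id", "role", "variant", "ph_nominal", "ph_final", "replicate"]
    for key, sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("time_min")
        traces.append(KineticTrace(
            well_id=key[0], role=key[1], variant=key[2], ph_nominal=float(key[3]),
            ph_final=float(key[4]), replicate=int(key[5]),
            times=sub["time_min"].to_numpy(), fluorescence=sub["fluorescence_au"].to_numpy(),
        ))
    return traces
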