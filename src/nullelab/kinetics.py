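"""Aggregation-kinetics analysis: half-times, dose-response, Hill fit, KIC50.

An aggregation time course (e.g. a ThT fluorescence trace of seeded
alpha-synuclein aggregation) is normalized between its pre-transition
baseline and post-transition plateau; the aggregation half-time t1/2 is the
time of the first upward 0.5 crossing.  The approximate overall rate is
1/t1/2, rescaled so the compound-free control maps to 100.  Rates across a
concentration series are fitted to a Hill curve

    R(c) = bottom + (top - bottom) / (1 + (c / m)^h)

and the kinetic inhibitory constant KIC50 — the compound concentration at
which t1/2 is increased by 50% relative to the negative control,
equivalently where the normalized rate falls to 100 * 2/3 — is obtained by
numerically inverting the fitted curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

KIC50_RATE_TARGET = 100.0 * 2.0 / 3.0  # rate at which t1/2 is up 50% vs control


class NoTransitionError(ValueError):
    """Trace has no discernible baseline-to-plateau transition."""


@dataclass(frozen=True)
class KineticTrace:
    """One aggregation time course.

    times are in hours (strictly increasing, >= 5 points); signal in
    arbitrary fluorescence units; concentration in uM (0 for the control).
    """

    times: np.ndarray
    signal: np.ndarray
    condition: str = ""
    concentration_um: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        if t.size < 5:
            raise ValueError("a kinetic trace needs at least 5 points")
        if t.size != y.size:
            raise ValueError("times and signal must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.concentration_um < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class HalfTimeResult:
    t_half: float                 # hours; a lower bound when censored == "end"
    method: str = "interpolation"
    censored: str | None = None   # None, "start", or "end"
    baseline: float | None = None
    plateau: float | None = None

    @property
    def defined(self) -> bool:
        return self.censored is None


@dataclass(frozen=True)
class DoseResponse:
    """Approximate rates (1/t1/2, control = 100) across a concentration series."""

    concentrations: np.ndarray    # uM, includes 0 for the control
    rates: np.ndarray             # dimensionless, control = 100 by construction
    control_t_half: float
    excluded: tuple[float, ...] = ()   # concentrations dropped for censoring
    t_half_sd: np.ndarray | None = None  # per-concentration replicate spread

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, float))
        object.__setattr__(self, "rates", np.asarray(self.rates, float))
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class HillFit:
    midpoint: float               # m, uM
    slope: float                  # h
    top: float
    bottom: float
    rss: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.midpoint <= 0:
                raise ValueError("midpoint must be positive")
            if self.top < self.bottom:
                raise ValueError("top must be >= bottom")

    def rate(self, c: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(c, dtype=float)
        out = self.bottom + (self.top - self.bottom) / (1.0 + (c / self.midpoint) ** self.slope)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Kic50Result:
    kic50: float | None           # uM; None when undefined
    extrapolated: bool
    control_t_half: float
    reason: str = ""

    @property
    def defined(self) -> bool:
        return self.kic50 is not None


# ---------------------------------------------------------------------------
# Trace normalization and half-time extraction
# ---------------------------------------------------------------------------

def _plateau_windows(trace: KineticTrace, head_frac: float, tail_frac: float):
    n = trace.times.size
    n_head = max(3, int(math.ceil(head_frac * n)))
    n_tail = max(3, int(math.ceil(tail_frac * n)))
    head = trace.signal[:n_head]
    tail = trace.signal[-n_tail:]
    return float(head.mean()), float(tail.mean()), float(head.std(ddof=0))


def normalize_trace(
    trace: KineticTrace,
    head_frac: float = 0.05,
    tail_frac: float = 0.05,
    min_transition_snr: float = 3.0,
) -> KineticTrace:
    """Rescale signal to [0, 1] between baseline and plateau estimates.

    Baseline and plateau are the means of the head and tail windows (each at
    least 3 points).  If the plateau-baseline difference is below
    ``min_transition_snr`` times the head-window noise (with an absolute
    floor), the trace is flagged by raising :class:`NoTransitionError`.
    Idempotent on already-normalized traces; invariant to affine transforms
    of the signal.
    """
    baseline, plateau, noise = _plateau_windows(trace, head_frac, tail_frac)
    span = plateau - baseline
    floor = 1e-12 * max(abs(baseline), abs(plateau), 1.0)
    if span <= max(min_transition_snr * noise, floor):
        raise NoTransitionError(
            f"no transition: plateau - baseline = {span:.3g} "
            f"(head noise {noise:.3g})"
        )
    return KineticTrace(
        times=trace.times,
        signal=(trace.signal - baseline) / span,
        condition=trace.condition,
        concentration_um=trace.concentration_um,
        replicate=trace.replicate,
    )


def half_time(trace: KineticTrace) -> HalfTimeResult:
    """Time of the first upward 0.5 crossing of a normalized trace.

    Uses monotone linear interpolation between the bracketing samples.
    Returns a censored result when the trace starts above 0.5 ("start") or
    never crosses within the observed range ("end", with the last time point
    as a lower bound on t1/2).
    """
    t, y = trace.times, trace.signal
    if y[0] >= 0.5:
        return HalfTimeResult(t_half=float(t[0]), censored="start")
    above = np.nonzero(y >= 0.5)[0]
    if above.size == 0:
        return HalfTimeResult(t_half=float(t[-1]), censored="end")
    i = int(above[0])
    t_half = t[i - 1] + (0.5 - y[i - 1]) * (t[i] - t[i - 1]) / (y[i] - y[i - 1])
    return HalfTimeResult(t_half=float(t_half))


def extract_half_time(trace: KineticTrace, **norm_kwargs) -> HalfTimeResult:
    """Normalize a raw trace and extract its half-time."""
    baseline, plateau, _ = _plateau_windows(
        trace, norm_kwargs.get("head_frac", 0.05), norm_kwargs.get("tail_frac", 0.05)
    )
    norm = normalize_trace(trace, **norm_kwargs)
    res = half_time(norm)
    return HalfTimeResult(
        t_half=res.t_half,
        method=res.method,
        censored=res.censored,
        baseline=baseline,
        plateau=plateau,
    )


class CensoredHalfTimeError(ValueError):
    """Operation requires an uncensored half-time."""


def normalized_half_time(sample: HalfTimeResult, control: HalfTimeResult) -> float:
    """sample t1/2 / control t1/2 (dimensionless; > 1 indicates inhibition)."""
    if not sample.defined or not control.defined:
        raise CensoredHalfTimeError("normalized half-time undefined for censored inputs")
    return sample.t_half / control.t_half


# ---------------------------------------------------------------------------
# Dose-response assembly
# ---------------------------------------------------------------------------

def dose_response(traces: list[KineticTrace], control: KineticTrace | None = None) -> DoseResponse:
    """Build the normalized-rate dose-response from raw traces.

    Traces are grouped by concentration; replicates are reduced to the mean
    t1/2 (spread reported).  The control (concentration 0) anchors the rate
    scale at exactly 100; any concentration whose half-time is censored is
    excluded from the series and reported in ``excluded``.
    """
    all_traces = list(traces)
    if control is not None:
        all_traces.append(control)
    controls = [tr for tr in all_traces if tr.concentration_um == 0]
    if not controls:
        raise ValueError("dose_response requires a control trace at concentration 0")

    groups: dict[float, list[KineticTrace]] = {}
    for tr in all_traces:
        groups.setdefault(float(tr.concentration_um), []).append(tr)

    concs, rates, sds, excluded = [], [], [], []
    control_results = [extract_half_time(tr) for tr in groups[0.0]]
    if any(not r.defined for r in control_results):
        raise CensoredHalfTimeError("control half-time is censored")
    control_t_half = float(np.mean([r.t_half for r in control_results]))

    for c in sorted(groups):
        try:
            results = [extract_half_time(tr) for tr in groups[c]]
        except NoTransitionError:
            excluded.append(c)
            continue
        if any(not r.defined for r in results):
            excluded.append(c)
            continue
        th = float(np.mean([r.t_half for r in results]))
        sds.append(float(np.std([r.t_half for r in results], ddof=0)))
        concs.append(c)
        rates.append((control_t_half / th) * 100.0)

    return DoseResponse(
        concentrations=np.array(concs),
        rates=np.array(rates),
        control_t_half=control_t_half,
        excluded=tuple(excluded),
        t_half_sd=np.array(sds),
    )


# ---------------------------------------------------------------------------
# Hill fit and KIC50
# ---------------------------------------------------------------------------

def _hill(c, top, bottom, m, h):
    return bottom + (top - bottom) / (1.0 + (c / m) ** h)


def hill_fit(dr: DoseResponse, rate_spread_tol: float = 1.0) -> HillFit:
    """Least-squares Hill fit of the dose-response.

    top is initialized at 100 and bottom bounded >= 0.  A series whose rates
    span less than ``rate_spread_tol`` (no effect) yields a degenerate,
    non-converged fit; downstream KIC50 then refuses.
    """
    mask = dr.concentrations > 0
    if int(mask.sum()) < 4 or len(set(dr.concentrations[mask])) < 4:
        raise ValueError("hill_fit requires >= 4 distinct non-zero concentrations")
    c, r = dr.concentrations, dr.rates
    if float(r.max() - r.min()) < rate_spread_tol:
        return HillFit(1.0, 1.0, float(r.mean()), float(r.mean()), 0.0, False,
                       "degenerate: rates show no dose effect")
    pos = c[mask]
    p0 = [100.0, max(float(r.min()), 0.0), float(np.exp(np.mean(np.log(pos)))), 1.0]
    bounds = ([0.0, 0.0, 1e-9, 0.05], [1e4, 1e4, 1e9, 20.0])
    try:
        popt, _ = curve_fit(_hill, c, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        return HillFit(1.0, 1.0, 100.0, 0.0, math.inf, False, f"non-convergence: {exc}")
    top, bottom, m, h = (float(v) for v in popt)
    if top < bottom:
        top, bottom = bottom, top  # symmetric in the model with h -> -h; keep top >= bottom
    rss = float(np.sum((_hill(c, top, bottom, m, h) - r) ** 2))
    return HillFit(midpoint=m, slope=h, top=top, bottom=bottom, rss=rss, converged=True)


def kic50(fit: HillFit, dr: DoseResponse) -> Kic50Result:
    """Invert the fitted Hill curve at the 50%-t1/2-increase rate (100 * 2/3).

    Root-finding is numeric (bracketing bisection on the fitted curve); the
    ``extrapolated`` flag is set when the solution lies outside the tested
    concentration range.
    """
    if not fit.converged:
        return Kic50Result(None, False, dr.control_t_half,
                           reason=f"fit not converged ({fit.message})")
    target = KIC50_RATE_TARGET
    if not (fit.bottom < target < fit.top):
        return Kic50Result(None, False, dr.control_t_half,
                           reason="no inhibition: fitted curve never reaches 2/3 of control")
    lo, hi = fit.midpoint * 1e-9, fit.midpoint * 1e9
    f = lambda c: fit.rate(c) - target
    if f(lo) * f(hi) > 0:
        return Kic50Result(None, False, dr.control_t_half,
                           reason="target rate not bracketed by fitted curve")
    root = float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))
    tested = dr.concentrations[dr.concentrations > 0]
    extrapolated = bool(tested.size == 0 or root < tested.min() or root > tested.max())
    return Kic50Result(kic50=root, extrapolated=extrapolated, control_t_half=dr.control_t_half)


# ---------------------------------------------------------------------------
# Long-format CSV I/O
# ---------------------------------------------------------------------------

def read_traces_csv(path) -> list[KineticTrace]:
    """Read traces from long-format CSV (time_h, signal, condition, concentration_uM, replicate)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"time_h", "signal", "condition", "concentration_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    traces = []
    for (cond, conc, rep), g in df.groupby(["condition", "concentration_uM", "replicate"]):
        g = g.sort_values("time_h")
        traces.append(
            KineticTrace(
                times=g["time_h"].to_numpy(),
                signal=g["signal"].to_numpy(),
                condition=str(cond),
                concentration_um=float(conc),
                replicate=int(rep),
            )
        )
    return traces


def write_traces_csv(path, traces: list[KineticTrace]) -> None:
    import pandas as pd

    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": tr.times,
                    "signal": tr.signal,
                    "condition": tr.condition,
                    "concentration_uM": tr.concentration_um,
                    "replicate": tr.replicate,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def analyze_dose_series(traces: list[KineticTrace]) -> dict:
    """Full kinetics analysis: t1/2 table, dose-response, Hill fit, KIC50."""
    dr = dose_response(traces)
    fit = hill_fit(dr)
    res = kic50(fit, dr)
    return {
        "control_t_half_h": dr.control_t_half,
        "concentrations_uM": dr.concentrations.tolist(),
        "rates": dr.rates.tolist(),
        "excluded_concentrations_uM": list(dr.excluded),
        "hill": {
            "midpoint_uM": fit.midpoint,
            "slope": fit.slope,
            "top": fit.top,
            "bottom": fit.bottom,
            "rss": fit.rss,
            "converged": fit.converged,
            "message": fit.message,
        },
        "kic50_uM": res.kic50,
        "kic50_extrapolated": res.extrapolated,
        "kic50_reason": res.reason,
    }
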