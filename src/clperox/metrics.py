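"""Derived peroxidation metrics: rates, flux, chain length, lag, stoichiometry.

The analysis follows classical inhibited-autoxidation bookkeeping:

* the uninhibited oxidation rate R_ox is the slope of the diene trace
  over an early window (default: the first 25 min after initiation);
* the radical generation rate Ri is calibrated from a reference
  antioxidant of known stoichiometry, Ri = n [AH] / tau
  (alpha-tocopherol: n = 2);
* chain propagation length nu = R_ox / Ri (tails oxidized per radical);
* inhibition efficiency = R_uninhibited / R_inhibited;
* inhibition duration tau is the intersection of the plateau line with
  the post-lag (uninhibited-slope) line;
* stoichiometric factor n = Ri tau / [AH].

Units: concentrations in M, times in minutes, rates in M/min throughout
this module; nM/min appears only in printed tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .antioxidants import AntioxidantSpec
from .errors import ConfigurationError, DomainError, InsufficientDataError
from .spectra import KineticTrace

#: Sentinel duration returned when no post-lag rise is detected.
INHIBITION_ONGOING = math.inf

#: Sentinel efficiency when the inhibited rate is indistinguishable from 0.
COMPLETE_INHIBITION = math.inf

#: Local-slope threshold (fraction of the uninhibited rate) separating the
#: inhibited plateau from the post-lag rise.
PLATEAU_SLOPE_FRACTION = 0.25

#: Default uninhibited-rate fit window, minutes after initiation.
DEFAULT_RATE_WINDOW_MIN = 25.0


@dataclass
class RateEstimate:
    """OLS slope of a concentration trace over a time window."""

    rate: float  # M/min
    window: tuple[float, float]  # minutes
    residual_rms: float  # M
    n_points: int
    intercept: float = 0.0  # M, at t = 0


@dataclass
class RadicalFlux:
    """Radical generation rate calibrated from a reference antioxidant."""

    Ri: float  # M/min
    reference: str = ""
    reference_conc: float = float("nan")  # M
    reference_lag: float = float("nan")  # min
    stoichiometry: float = float("nan")

    def __post_init__(self) -> None:
        if not self.Ri > 0:
            raise DomainError(f"radical flux must be > 0, got {self.Ri}")


@dataclass
class PeroxidationMetrics:
    """One summary-table row for a single antioxidant (or pure lipid)."""

    antioxidant: str
    oxidation_rate_nM_min: float
    oxidation_rate_sd: float
    chain_length: float
    inhibition_efficiency: float | None  # None for the uninhibited row
    inhibition_duration_min: float | None
    inhibition_duration_sd: float | None
    stoichiometric_factor: float | None
    n_replicates: int


@dataclass
class ReplicateStats:
    mean: float
    sd: float
    n: int
    low_n: bool = False


@dataclass
class LagAnalysis:
    """Full result of the plateau/terminal line-intersection construction."""

    duration_min: float  # minutes after t_addition; inf if inhibition ongoing
    plateau: RateEstimate
    terminal: RateEstimate | None
    t_addition: float


# ---------------------------------------------------------------------------
# Elementary estimators
# ---------------------------------------------------------------------------

def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and RMS residual of y vs t."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return float(slope), float(intercept), float(np.sqrt(np.mean(resid**2)))


def fit_oxidation_rate(trace: KineticTrace, window: tuple[float, float] | None = None) -> RateEstimate:
    """OLS slope of concentration vs time over ``window`` (minutes).

    A two-point window reduces exactly to the difference quotient
    (c(t2) - c(t1)) / (t2 - t1).
    """
    if window is None:
        t0 = float(trace.times[0]) if trace.times.size else 0.0
        window = (t0, t0 + DEFAULT_RATE_WINDOW_MIN)
    sub = trace.window(*window)
    if sub.times.size < 2:
        raise InsufficientDataError(
            f"need >= 2 points in window {window}, found {sub.times.size}"
        )
    slope, intercept, rms = _ols_line(sub.times, sub.values)
    return RateEstimate(slope, window, rms, sub.times.size, intercept)


def radical_flux(reference_conc: float, inhibition_duration: float, stoichiometry: float) -> RadicalFlux:
    """Calibrate the radical generation rate Ri = n [AH] / tau.

    Parameters are the reference antioxidant concentration (M), its
    measured inhibition duration (min) and its radical-trapping
    stoichiometry.  All must be positive.
    """
    if not inhibition_duration > 0:
        raise DomainError(f"inhibition duration must be > 0, got {inhibition_duration}")
    if not reference_conc > 0:
        raise DomainError(f"reference concentration must be > 0, got {reference_conc}")
    if not stoichiometry > 0:
        raise DomainError(f"stoichiometry must be > 0, got {stoichiometry}")
    return RadicalFlux(
        Ri=stoichiometry * reference_conc / inhibition_duration,
        reference_conc=reference_conc,
        reference_lag=inhibition_duration,
        stoichiometry=stoichiometry,
    )


def chain_propagation_length(oxidation_rate: float, flux: RadicalFlux) -> float:
    """Tails oxidized per initiating radical: R_ox / Ri."""
    if oxidation_rate < 0:
        raise DomainError(f"oxidation rate must be >= 0, got {oxidation_rate}")
    return oxidation_rate / flux.Ri


def inhibition_efficiency(uninhibited_rate: float, inhibited_rate: float) -> float:
    """Ratio of uninhibited to inhibited oxidation rates.

    A non-positive inhibited rate (below the noise floor) yields the
    :data:`COMPLETE_INHIBITION` sentinel rather than a number.
    """
    if inhibited_rate <= 0:
        return COMPLETE_INHIBITION
    return uninhibited_rate / inhibited_rate


def stoichiometric_factor(flux: RadicalFlux, lag: float, antioxidant_conc: float) -> float:
    """Radicals trapped per antioxidant molecule: n = Ri tau / [AH]."""
    if lag < 0:
        raise DomainError(f"lag must be >= 0, got {lag}")
    if not antioxidant_conc > 0:
        raise DomainError(f"antioxidant concentration must be > 0, got {antioxidant_conc}")
    return flux.Ri * lag / antioxidant_conc


def replicate_stats(values) -> ReplicateStats:
    """Mean and sample (n-1) standard deviation of replicate values.

    n = 1 yields sd = 0; groups with n < 3 are flagged low-n.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise InsufficientDataError("no replicate values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return ReplicateStats(mean, sd, int(values.size), low_n=values.size < 3)


# ---------------------------------------------------------------------------
# Inhibition duration (line-intersection construction)
# ---------------------------------------------------------------------------

def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in a boolean array."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def lag_analysis(
    inhibited_trace: KineticTrace,
    uninhibited_rate: float,
    t_addition: float = 0.0,
) -> LagAnalysis:
    """Plateau/terminal line fits and their intersection.

    The plateau line L1 is fit to the longest contiguous run of points
    (from ``t_addition`` on) whose local slope stays below
    ``PLATEAU_SLOPE_FRACTION`` of the uninhibited rate.  The terminal line
    L2 is fit to the last 20% of points or the maximal-slope contiguous
    window of the same length, whichever fits with lower residual.  The
    inhibition duration is the intersection time minus ``t_addition``.
    """
    if not uninhibited_rate > 0:
        raise DomainError("uninhibited rate must be > 0")
    m = inhibited_trace.times >= t_addition
    t = inhibited_trace.times[m]
    y = inhibited_trace.values[m]
    if t.size < 4:
        raise InsufficientDataError("need >= 4 points after t_addition")
    slope_local = np.gradient(y, t)
    below = slope_local < PLATEAU_SLOPE_FRACTION * uninhibited_rate

    runs = _runs_of(below)
    if not runs:
        # trace indistinguishable from the uninhibited line: no lag
        zero = RateEstimate(uninhibited_rate, (float(t[0]), float(t[-1])), 0.0, t.size)
        return LagAnalysis(0.0, zero, None, t_addition)
    runs = [r for r in runs if r[1] - r[0] >= 2]
    if not runs:
        zero = RateEstimate(uninhibited_rate, (float(t[0]), float(t[-1])), 0.0, t.size)
        return LagAnalysis(0.0, zero, None, t_addition)
    p0, p1 = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    m1, b1, rms1 = _ols_line(t[p0:p1], y[p0:p1])
    plateau = RateEstimate(m1, (float(t[p0]), float(t[p1 - 1])), rms1, p1 - p0, b1)

    # Terminal line: the first points after the plateau, where the resumed
    # oxidation still runs at its full pace.  Later windows systematically
    # underestimate both slope and intersection because substrate depletion
    # bends the curve; fall back to the trailing 20% only when the plateau
    # reaches the end of the record.
    k = max(2, math.ceil(0.2 * t.size))
    if t.size - p1 >= 2:
        a, b = p1, min(p1 + k, t.size)
    else:
        a, b = t.size - k, t.size
    m2, b2, rms2 = _ols_line(t[a:b], y[a:b])
    terminal = RateEstimate(m2, (float(t[a]), float(t[b - 1])), rms2, b - a, b2)

    if m2 < PLATEAU_SLOPE_FRACTION * uninhibited_rate:
        return LagAnalysis(INHIBITION_ONGOING, plateau, terminal, t_addition)
    t_star = (b1 - b2) / (m2 - m1)
    return LagAnalysis(float(t_star - t_addition), plateau, terminal, t_addition)


def inhibition_duration(
    inhibited_trace: KineticTrace,
    uninhibited_rate: float,
    t_addition: float = 0.0,
) -> float:
    """Inhibition duration in minutes (see :func:`lag_analysis`).

    Returns :data:`INHIBITION_ONGOING` (inf) when the trace never resumes
    uninhibited-like growth (terminal slope < 25% of the uninhibited rate).
    """
    return lag_analysis(inhibited_trace, uninhibited_rate, t_addition).duration_min


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class RunGroup:
    """Replicate measurements for one sample composition."""

    name: str
    rates: list  # M/min, one per replicate
    durations: list | None = None  # minutes, one per replicate (None if N.A.)
    antioxidant: AntioxidantSpec | None = None
    concentration: float = 0.0  # M
    uninhibited: bool = False
    reference: bool = False
    addition_min: float = 0.0
    notes: str = ""


def build_metrics_table(
    groups: list[RunGroup],
    flux: RadicalFlux,
    rounded: bool = True,
) -> list[PeroxidationMetrics]:
    """Assemble per-antioxidant summary rows from grouped replicate runs.

    Requires exactly one uninhibited (pure lipid) group, whose mean rate
    anchors the efficiency column.  Rounding policy: rates to 3
    significant figures, chain length and stoichiometric factor to 2,
    efficiency to the nearest integer.  Durations of inf (inhibition
    ongoing) or None (not measurable) propagate as None.
    """
    unin = [g for g in groups if g.uninhibited]
    if len(unin) != 1:
        raise ConfigurationError(
            f"expected exactly one uninhibited group, found {len(unin)}"
        )
    r_unin = replicate_stats(unin[0].rates).mean

    def _r3(x):
        return round_sig(x, 3) if rounded else x

    def _r2(x):
        return round_sig(x, 2) if rounded else x

    rows = []
    for g in groups:
        rs = replicate_stats(g.rates)
        if rs.low_n and rs.n > 1:
            warnings.warn(f"group {g.name!r}: only {rs.n} replicates", stacklevel=2)
        chain = chain_propagation_length(max(rs.mean, 0.0), flux)
        if g.uninhibited:
            eff = dur = dur_sd = n_fac = None
        else:
            e = inhibition_efficiency(r_unin, rs.mean)
            eff = (round(e) if rounded else e) if math.isfinite(e) else None
            finite = [d for d in (g.durations or []) if math.isfinite(d)]
            if finite:
                ds = replicate_stats(finite)
                dur, dur_sd = ds.mean, ds.sd
                n_fac = stoichiometric_factor(flux, ds.mean, g.concentration) if g.concentration > 0 else None
                if rounded:
                    dur, dur_sd = _r3(dur), _r2(dur_sd)
                    n_fac = _r2(n_fac) if n_fac is not None else None
            else:
                dur = dur_sd = n_fac = None
        rows.append(
            PeroxidationMetrics(
                antioxidant=g.name,
                oxidation_rate_nM_min=_r3(rs.mean * 1e9),
                oxidation_rate_sd=_r3(rs.sd * 1e9),
                chain_length=_r2(chain),
                inhibition_efficiency=eff,
                inhibition_duration_min=dur,
                inhibition_duration_sd=dur_sd,
                stoichiometric_factor=n_fac,
                n_replicates=rs.n,
            )
        )
    return rows
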