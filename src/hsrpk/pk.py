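"""Closed-form one-compartment concentration-time machinery.

Murine subcutaneous dosing is modelled as first-order absorption into a
single compartment with first-order elimination; human comparator profiles
use the zero-order (constant-rate) infusion closed form.  Multi-dose
regimens are handled by superposition of time-shifted single-dose terms,
and indefinitely repeated (q8h-style) dosing by geometric accumulation of
the exponential terms, which yields the periodic steady state exactly.

Every profile is represented as a list of terms of the form

    coef * (t - onset)**power * exp(-rate * (t - onset)),   t >= onset

so that evaluation, integration (AUC) and steady-state accumulation are
all analytic.  Units are fixed throughout: time in hours, doses in mg/kg,
volumes in L/kg, concentrations in mg/L.  Per-kg dosing removes body
weight from all formulas; bioavailability of subcutaneous doses is taken
as 1 (the fitted volumes are apparent volumes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import special

MATRICES = ("plasma", "ELF")
ROUTES = ("subcutaneous_bolus", "iv_infusion")

#: relative |ka - kel| below which the equal-rate limit form is used
EQUAL_RATE_RTOL = 1e-9

#: default dense-grid step for grid views, hours
DEFAULT_GRID_STEP = 0.001


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation (e.g. t < 0)."""


class ValidationError(ValueError):
    """Structurally invalid object (non-positive parameter, bad regimen...)."""


@dataclass(frozen=True)
class PKParameters:
    """One-compartment first-order-absorption parameters for one matrix.

    Parameters
    ----------
    volume : apparent volume of distribution, L/kg (> 0)
    ka : first-order absorption rate constant, 1/h (> 0)
    kel : first-order elimination rate constant, 1/h (> 0)
    matrix : "plasma" or "ELF"

    ka and kel may be in either order: flip-flop kinetics (absorption
    slower than elimination, so the terminal slope is the absorption rate)
    are permitted and occur for meropenem in murine plasma.
    """

    volume: float
    ka: float
    kel: float
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        if not (self.volume > 0 and self.ka > 0 and self.kel > 0):
            raise ValidationError(
                f"PK parameters must be strictly positive, got "
                f"V={self.volume}, ka={self.ka}, kel={self.kel}"
            )
        if self.matrix not in MATRICES:
            raise ValidationError(f"matrix must be one of {MATRICES}, got {self.matrix!r}")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: time (h), amount (mg/kg), route."""

    time: float
    amount: float
    route: str = "subcutaneous_bolus"
    infusion_duration: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"dose time must be >= 0, got {self.time}")
        if not self.amount > 0:
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")
        if self.route not in ROUTES:
            raise ValidationError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.route == "iv_infusion":
            if self.infusion_duration is None or not self.infusion_duration > 0:
                raise ValidationError("iv_infusion requires infusion_duration > 0")
        elif self.infusion_duration is not None:
            raise ValidationError("infusion_duration only valid for iv_infusion")


@dataclass(frozen=True)
class Regimen:
    """An ordered dose schedule, optionally repeated every ``repeat_interval`` h.

    ``horizon`` bounds repeat expansion and the default evaluation window.
    When ``repeat_interval`` is set, all event times must lie within one
    interval (strictly below ``repeat_interval``).
    """

    events: tuple[DoseEvent, ...]
    repeat_interval: float | None = None
    horizon: float = 24.0

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.time))
        object.__setattr__(self, "events", events)
        if self.repeat_interval is not None:
            if not self.repeat_interval > 0:
                raise ValidationError("repeat_interval must be > 0")
            if any(e.time >= self.repeat_interval for e in events):
                raise ValidationError(
                    "all event times must be < repeat_interval when repeating"
                )
        if events and self.horizon < events[-1].time:
            raise ValidationError(
                f"horizon {self.horizon} h is shorter than the last event "
                f"at {events[-1].time} h"
            )

    @property
    def total_dose_per_course(self) -> float:
        """Sum of event amounts over one course/interval, mg/kg."""
        return sum(e.amount for e in self.events)

    def materialize(self) -> tuple[DoseEvent, ...]:
        """Expand repeats into explicit events at times < horizon."""
        if self.repeat_interval is None:
            return self.events
        out: list[DoseEvent] = []
        k = 0
        while k * self.repeat_interval < self.horizon:
            for e in self.events:
                t = e.time + k * self.repeat_interval
                if t < self.horizon:
                    out.append(replace(e, time=t))
            k += 1
        return tuple(sorted(out, key=lambda e: e.time))

    def scaled(self, factor: float) -> "Regimen":
        """Regimen with every dose amount multiplied by ``factor``."""
        return Regimen(
            tuple(replace(e, amount=e.amount * factor) for e in self.events),
            repeat_interval=self.repeat_interval,
            horizon=self.horizon,
        )


@dataclass(frozen=True)
class Term:
    """One analytic profile term: coef * (t-onset)^power * exp(-rate*(t-onset))."""

    onset: float
    coef: float
    rate: float
    power: int = 0


def _term_eval(term: Term, t: np.ndarray) -> np.ndarray:
    u = t - term.onset
    out = np.zeros_like(u)
    m = u >= 0
    um = u[m]
    v = term.coef * np.exp(-term.rate * um)
    if term.power:
        v = v * um**term.power
    out[m] = v
    return out


def _term_integral(term: Term, a: float, b: float) -> float:
    """Exact integral of one term over [a, b] (b >= a)."""
    a = max(a, term.onset)
    if b <= a:
        return 0.0
    u0, u1 = a - term.onset, b - term.onset
    lam, p = term.rate, term.power
    if lam == 0.0:
        return term.coef * (u1 ** (p + 1) - u0 ** (p + 1)) / (p + 1)
    # int u^p e^{-lam u} du = p!/lam^{p+1} * P(p+1, lam*u), P = regularized
    # lower incomplete gamma
    g = special.gammainc(p + 1, lam * u1) - special.gammainc(p + 1, lam * u0)
    return float(term.coef * math.gamma(p + 1) / lam ** (p + 1) * g)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Evaluable concentration-time curve on a window, as an analytic term list.

    The closed form is the source of truth; :meth:`grid` provides a dense
    view for plotting and bracketing.  ``binding_state`` records whether the
    term coefficients already include an unbound-fraction correction.
    """

    terms: tuple[Term, ...]
    window: tuple[float, float]
    matrix: str = "plasma"
    binding_state: str = "total"
    unbound_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.window[1] < self.window[0]:
            raise ValidationError(f"reversed window {self.window}")
        if not (0 < self.unbound_fraction <= 1):
            raise ValidationError("unbound_fraction must be in (0, 1]")

    def __call__(self, t):
        arr = np.atleast_1d(np.asarray(t, dtype=float))
        c = np.zeros_like(arr)
        for term in self.terms:
            c += _term_eval(term, arr)
        # tiny negative values can arise from cancellation at term onsets
        np.clip(c, 0.0, None, out=c)
        return float(c[0]) if np.isscalar(t) or np.ndim(t) == 0 else c

    def grid(self, step: float = DEFAULT_GRID_STEP):
        """Dense (t, C(t)) view over the window at the given step."""
        t0, t1 = self.window
        n = max(2, int(round((t1 - t0) / step)) + 1)
        t = np.linspace(t0, t1, n)
        return t, self(t)

    def onsets_within(self, a: float, b: float) -> list[float]:
        """Distinct term onsets in (a, b) — the inter-dose segment breaks."""
        return sorted({tm.onset for tm in self.terms if a < tm.onset < b})

    def scaled(self, factor: float) -> "ConcentrationProfile":
        return replace(
            self, terms=tuple(replace(tm, coef=tm.coef * factor) for tm in self.terms)
        )

    def integral(self, a: float, b: float) -> float:
        """Exact analytic integral over [a, b], mg*h/L."""
        if b < a:
            raise DomainError(f"reversed integration window [{a}, {b}]")
        return sum(_term_integral(tm, a, b) for tm in self.terms)


# ---------------------------------------------------------------------------
# single-dose building blocks


def single_dose_concentration(params: PKParameters, dose: float, t) -> float | np.ndarray:
    """Concentration after one subcutaneous dose at t=0 (mg/L).

    C(t) = (D/V) * ka/(ka-kel) * (exp(-kel t) - exp(-ka t)); the ka==kel
    limit form (D/V) * ka * t * exp(-ka t) is used when the rates are equal
    to within ``EQUAL_RATE_RTOL``.  The curve is unchanged under the
    flip-flop reparameterization (V, ka, kel) -> (V*kel/ka, kel, ka), so
    absorption- and elimination-limited kinetics are observationally
    equivalent; the peak time ln(ka/kel)/(ka-kel) is symmetric in the rates.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise DomainError("negative time")
    if dose <= 0:
        raise ValidationError("dose must be > 0")
    V, ka, kel = params.volume, params.ka, params.kel
    if abs(ka - kel) / ka < EQUAL_RATE_RTOL:
        c = (dose / V) * ka * arr * np.exp(-ka * arr)
    else:
        A = (dose / V) * ka / (ka - kel)
        c = A * (np.exp(-kel * arr) - np.exp(-ka * arr))
    return float(c) if np.ndim(t) == 0 else c


def infusion_concentration(
    volume: float, kel: float, dose: float, duration: float, t
) -> float | np.ndarray:
    """One-compartment concentration under a zero-order infusion at t=0.

    Rises as (R0/(V*kel)) * (1 - exp(-kel t)) during the infusion
    (R0 = dose/duration) and decays monoexponentially afterwards;
    continuous at t = duration.
    """
    if not duration > 0:
        raise ValidationError("duration must be > 0")
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise DomainError("negative time")
    plateau = (dose / duration) / (volume * kel)
    during = plateau * (1.0 - np.exp(-kel * np.minimum(arr, duration)))
    c = during * np.exp(-kel * np.maximum(arr - duration, 0.0))
    return float(c) if np.ndim(t) == 0 else c


def _bolus_terms(params: PKParameters, dose: float, onset: float) -> list[Term]:
    V, ka, kel = params.volume, params.ka, params.kel
    if abs(ka - kel) / ka < EQUAL_RATE_RTOL:
        return [Term(onset, (dose / V) * ka, ka, power=1)]
    A = (dose / V) * ka / (ka - kel)
    return [Term(onset, A, kel), Term(onset, -A, ka)]


def _infusion_terms(
    volume: float, kel: float, dose: float, duration: float, onset: float
) -> list[Term]:
    # a finite infusion is the difference of two step responses
    K = (dose / duration) / (volume * kel)
    return [
        Term(onset, K, 0.0),
        Term(onset, -K, kel),
        Term(onset + duration, -K, 0.0),
        Term(onset + duration, K, kel),
    ]


def _event_terms(params: PKParameters, event: DoseEvent) -> list[Term]:
    if event.route == "subcutaneous_bolus":
        return _bolus_terms(params, event.amount, event.time)
    return _infusion_terms(
        params.volume, params.kel, event.amount, event.infusion_duration, event.time
    )


# ---------------------------------------------------------------------------
# regimens


def simulate_regimen(
    params: PKParameters,
    regimen: Regimen,
    unbound_fraction: float | None = None,
) -> ConcentrationProfile:
    """Superpose single-dose profiles for every (materialized) dose event.

    ``unbound_fraction`` in (0, 1] multiplies the whole profile and tags it
    "unbound" (the fitted parameters describe total concentrations; binding
    correction is post hoc).  ``None`` leaves a total-concentration profile.
    The profile is linear in every dose amount.
    """
    fu = 1.0 if unbound_fraction is None else unbound_fraction
    if not (0 < fu <= 1):
        raise ValidationError("unbound_fraction must be in (0, 1]")
    terms: list[Term] = []
    for event in regimen.materialize():
        for tm in _event_terms(params, event):
            terms.append(replace(tm, coef=tm.coef * fu))
    return ConcentrationProfile(
        terms=tuple(terms),
        window=(0.0, regimen.horizon),
        matrix=params.matrix,
        binding_state="total" if unbound_fraction is None else "unbound",
        unbound_fraction=fu,
    )


def _periodic_carry_terms(term: Term, interval: float) -> list[Term]:
    """Terms (onset 0) for the sum of all earlier-interval copies of ``term``.

    For A*(u)^p e^{-lam u}, u = t - onset, summed over shifts u + k*T, k>=1,
    the geometric series gives closed forms for p = 0 and p = 1.
    """
    lam, p, A, tau = term.rate, term.power, term.coef, term.onset
    T = interval
    if lam == 0.0:
        raise ValidationError(
            "rate-0 terms cannot accumulate under repeated dosing "
            "(unbounded); infusion step pairs must cancel"
        )
    E = math.exp(-lam * T)
    f = 1.0 / (1.0 - E)
    shift = math.exp(-lam * (T - tau))  # e^{-lam * v0}, v0 = t=0 offset
    if p == 0:
        return [Term(0.0, A * shift * f, lam)]
    if p == 1:
        # sum_{j>=0} (v + jT) e^{-lam(v+jT)} with v = t + (T - tau)
        return [
            Term(0.0, A * f * shift, lam, power=1),
            Term(0.0, A * f * shift * ((T - tau) + T * E * f), lam, power=0),
        ]
    raise NotImplementedError(f"periodic accumulation for power {p}")


def periodic_steady_state(
    params: PKParameters,
    regimen: Regimen,
    unbound_fraction: float | None = None,
    method: str = "geometric",
    rel_tol: float = 1e-6,
    max_intervals: int = 10_000,
) -> ConcentrationProfile:
    """Limiting within-interval profile under indefinitely repeated dosing.

    ``method="geometric"`` accumulates each exponential term's earlier-interval
    copies in closed form; ``method="simulate"`` repeats intervals until the
    interval-start concentration changes by < ``rel_tol`` relative and shifts
    the final interval back to [0, T].  The two agree to ~1e-6 relative.
    """
    if regimen.repeat_interval is None:
        raise ValidationError("periodic steady state requires repeat_interval")
    T = regimen.repeat_interval
    fu = 1.0 if unbound_fraction is None else unbound_fraction
    if not (0 < fu <= 1):
        raise ValidationError("unbound_fraction must be in (0, 1]")
    binding = "total" if unbound_fraction is None else "unbound"

    base_terms: list[Term] = []
    for event in regimen.events:
        for tm in _event_terms(params, event):
            base_terms.append(replace(tm, coef=tm.coef * fu))

    if method == "geometric":
        zero_rate_net = sum(tm.coef for tm in base_terms if tm.rate == 0.0)
        if abs(zero_rate_net) > 1e-9:
            raise ValidationError("unbalanced zero-rate (infusion) terms in interval")
        terms = list(base_terms)
        for tm in base_terms:
            if tm.rate == 0.0:
                continue  # step pairs cancel across earlier intervals
            terms.extend(_periodic_carry_terms(tm, T))
        return ConcentrationProfile(
            tuple(terms), (0.0, T), params.matrix, binding, fu
        )

    if method == "simulate":
        terms: list[Term] = []
        prev_start = None
        for k in range(max_intervals):
            for tm in base_terms:
                terms.append(replace(tm, onset=tm.onset + k * T))
            start = sum(_term_eval(tm, np.array([(k + 1) * T]))[0] for tm in terms)
            if prev_start is not None and start > 0:
                if abs(start - prev_start) / start < rel_tol:
                    shifted = tuple(
                        replace(tm, onset=tm.onset - k * T) for tm in terms
                    )
                    return ConcentrationProfile(
                        shifted, (0.0, T), params.matrix, binding, fu
                    )
            prev_start = start
        raise RuntimeError("steady state not reached within max_intervals")

    raise ValidationError(f"unknown method {method!r}")
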