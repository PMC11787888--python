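"""PK/PD exposure indices computed from analytic concentration profiles.

The indices are the standard pharmacodynamic drivers: %fT>MIC (fraction of
the evaluation window with free concentration above a threshold, the driver
for beta-lactams), fCmax and fAUC (the drivers for aminoglycosides), each
tabulated across the MIC doubling-dilution ladder 1, 2, 4, ... 128 mg/L.

Threshold crossings are located by bracketing on a dense grid of the closed
form and refining with bisection, so %fT>MIC is reproducible to well below
0.01 percentage points; AUC uses the exact analytic integral of the
exponential-term list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .pk import ConcentrationProfile, DomainError, ValidationError, DEFAULT_GRID_STEP

DOUBLING_GRID = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)

#: bisection tolerance for threshold-crossing times, hours
CROSSING_XTOL = 1e-6


@dataclass(frozen=True)
class ExposureSummary:
    """fCmax, fAUC and %fT>MIC over a window for one matrix and species."""

    fcmax: float
    tmax: float
    fauc: float
    window: tuple[float, float]
    ft_above: dict[float, float] = field(default_factory=dict)
    matrix: str = "plasma"
    species: str = "mouse"

    def __post_init__(self) -> None:
        if self.fauc < 0:
            raise ValidationError("fauc must be >= 0")
        mics = list(self.ft_above)
        if mics != sorted(mics):
            raise ValidationError("ft_above grid must be increasing")
        pcts = list(self.ft_above.values())
        if any(not (0 <= p <= 100) for p in pcts):
            raise ValidationError("percentages must be in [0, 100]")
        if any(b > a + 1e-9 for a, b in zip(pcts, pcts[1:])):
            raise ValidationError("%fT>MIC must be non-increasing in MIC")


def _check_window(profile: ConcentrationProfile, window):
    if window is None:
        return profile.window
    a, b = window
    if b < a:
        raise DomainError(f"reversed window {window}")
    p0, p1 = profile.window
    if a < p0 - 1e-12 or b > p1 + 1e-12:
        raise DomainError(f"window {window} outside profile window {profile.window}")
    return (float(a), float(b))


def cmax(profile: ConcentrationProfile, window=None) -> tuple[float, float]:
    """Global maximum concentration over the window and its time, (mg/L, h).

    The window maximum lies either at a window endpoint or inside an
    inter-dose segment; the dense-grid argmax is refined by bounded scalar
    maximisation of the closed form within its bracketing cell.
    """
    a, b = _check_window(profile, window)
    if b == a:
        return profile(a), a
    breaks = [a] + profile.onsets_within(a, b) + [b]
    step = min(DEFAULT_GRID_STEP, (b - a) / 10)
    t = np.unique(np.concatenate([np.arange(a, b, step), np.asarray(breaks)]))
    c = profile(t)
    i = int(np.argmax(c))
    lo = t[max(i - 1, 0)]
    hi = t[min(i + 1, len(t) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda x: -profile(x), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun >= c[i]:
            return float(-res.fun), float(res.x)
    return float(c[i]), float(t[i])


def auc(profile: ConcentrationProfile, window=None) -> float:
    """Exact analytic area under the curve over the window, mg*h/L."""
    a, b = _check_window(profile, window)
    return profile.integral(a, b)


def fraction_time_above(
    profile: ConcentrationProfile,
    threshold: float,
    window=None,
    grid_step: float = DEFAULT_GRID_STEP,
) -> float:
    """Percent of the window during which C(t) > threshold.

    Sign changes of C - threshold are bracketed on a <= ``grid_step`` grid
    (with all dose onsets included) and each crossing is bisected to
    ``CROSSING_XTOL`` hours on the closed form.
    """
    if not threshold > 0:
        raise DomainError("threshold must be > 0")
    a, b = _check_window(profile, window)
    if b == a:
        return 0.0
    breaks = profile.onsets_within(a, b)
    t = np.unique(np.concatenate([
        np.arange(a, b, min(grid_step, (b - a) / 10)), np.asarray([b] + breaks),
    ]))
    d = profile(t) - threshold
    crossings: list[float] = []
    sign = np.sign(d)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        x = optimize.brentq(
            lambda x: profile(x) - threshold, t[i], t[i + 1], xtol=CROSSING_XTOL
        )
        crossings.append(float(x))
    # exact-zero grid nodes act as crossings as well
    crossings.extend(float(x) for x in t[sign == 0])
    edges = np.unique(np.concatenate([[a, b], crossings]))
    above = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if profile(0.5 * (lo + hi)) > threshold:
            above += hi - lo
    return 100.0 * above / (b - a)


def doubling_grid_summary(
    profile: ConcentrationProfile,
    window=None,
    mic_grid=DOUBLING_GRID,
    species: str = "mouse",
) -> ExposureSummary:
    """Assemble fCmax, fAUC and the %fT>MIC ladder into one summary."""
    grid = [float(m) for m in mic_grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("mic_grid must be strictly increasing")
    a, b = _check_window(profile, window)
    peak, tpeak = cmax(profile, (a, b))
    ft = {}
    running_min = 100.0
    for mic in grid:
        pct = 0.0 if mic >= peak else fraction_time_above(profile, mic, (a, b))
        running_min = min(running_min, pct)  # monotone by construction
        ft[mic] = running_min
    return ExposureSummary(
        fcmax=peak,
        tmax=tpeak,
        fauc=auc(profile, (a, b)),
        window=(a, b),
        ft_above=ft,
        matrix=profile.matrix,
        species=species,
    )


def compare_exposures(mouse: ExposureSummary, human: ExposureSummary) -> pd.DataFrame:
    """Per-index mouse - human differences (absolute and relative).

    The two summaries must share the MIC grid and evaluation-window length;
    no judgement thresholds are applied — the table reports differences only.
    """
    if list(mouse.ft_above) != list(human.ft_above):
        raise ValidationError("MIC grids differ between summaries")
    if abs((mouse.window[1] - mouse.window[0]) - (human.window[1] - human.window[0])) > 1e-9:
        raise ValidationError("window lengths differ between summaries")
    rows = []

    def _row(index, m, h):
        rel = (m - h) / h if h != 0 else np.nan
        rows.append({
            "index": index, "mouse": m, "human": h,
            "abs_diff": m - h, "rel_diff": rel,
        })

    _row("fcmax_mg_L", mouse.fcmax, human.fcmax)
    _row("fauc_mg_h_L", mouse.fauc, human.fauc)
    for mic in mouse.ft_above:
        _row(f"ft_above_{mic:g}", mouse.ft_above[mic], human.ft_above[mic])
    return pd.DataFrame(rows)
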