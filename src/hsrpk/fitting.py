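"""Naive-pooled nonlinear least-squares PK estimation from sparse data.

Destructive murine sampling (each animal contributes at most three samples)
rules out individual-level fits, so all observations are pooled onto one
curve per analyte and matrix.  The pipeline is:

1. statistical outlier removal per timepoint by the interquartile-range
   method (single pass, 1.5*IQR fences, quartiles by linear interpolation;
   groups with fewer than 4 values pass through unfiltered);
2. weighted least squares on the one-compartment first-order-absorption
   closed form (or a two-compartment candidate for model comparison),
   with multi-start initialisation in log-parameter space seeded from the
   curve geometry (terminal slope, back-extrapolated intercept);
3. model selection by the least-squares Akaike information criterion
   n*ln(RSS/n) + 2k, ties resolved toward fewer parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .pk import (
    DoseEvent,
    PKParameters,
    Regimen,
    ValidationError,
    simulate_regimen,
)

OBS_COLUMNS = ["subject_id", "time_h", "matrix", "analyte", "conc_mg_L"]

MODELS = ("one_compartment_foabs", "two_compartment_foabs")
WEIGHTINGS = ("none", "1/y", "1/y2")


@dataclass
class StudyDataset:
    """Pooled sparse concentration observations plus design metadata.

    ``observations`` columns: subject_id, time_h, matrix, analyte,
    conc_mg_L.  ``metadata`` carries the administered regimen (required
    for fitting), the sampling design, and — for synthetic datasets —
    the generating truth and outlier flags.
    """

    observations: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.observations.columns]
        if missing:
            raise ValidationError(f"observations missing columns {missing}")
        if (self.observations["time_h"] < 0).any():
            raise ValidationError("negative observation times")
        if (self.observations["conc_mg_L"] < 0).any():
            raise ValidationError("negative concentrations")


@dataclass
class FitResult:
    """One candidate model's naive-pooled fit."""

    model: str
    params: dict[str, float]
    rss: float
    n_obs: int
    k_params: int
    aic: float
    residuals: np.ndarray
    converged: bool
    weighting: str = "none"
    n_starts: int = 0

    @property
    def parameters(self) -> PKParameters | None:
        """One-compartment parameters, when applicable."""
        if self.model != "one_compartment_foabs":
            return None
        return PKParameters(
            volume=self.params["volume"], ka=self.params["ka"],
            kel=self.params["kel"], matrix=self.params.get("matrix", "plasma"),
        )


def flip_flop_alternative(params: PKParameters) -> PKParameters:
    """The observationally equivalent fit with absorption/elimination swapped.

    The first-order-absorption curve is invariant under
    (V, ka, kel) -> (V*kel/ka, kel, ka), so concentration data alone cannot
    say which rate constant is absorption; naive-pooled fits may converge to
    either representation and recovery must be scored on the pair.
    """
    return PKParameters(
        volume=params.volume * params.kel / params.ka,
        ka=params.kel, kel=params.ka, matrix=params.matrix,
    )


def iqr_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass interquartile-range outlier screen on one group.

    Values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are excluded; quartiles use
    linear interpolation between order statistics.  Groups with n < 4 pass
    through unfiltered (quartiles are not meaningful).
    Returns (kept, excluded) arrays in input order.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        return v, np.empty(0)
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def filter_dataset(
    dataset: StudyDataset,
    group_cols: Sequence[str] = ("time_h", "analyte", "matrix"),
) -> tuple[StudyDataset, pd.DataFrame]:
    """Apply the IQR screen per timepoint x analyte x matrix group.

    Returns the filtered dataset and a per-matrix exclusion report with
    counts in the conventional "excluded/total (pct%)" form.
    """
    obs = dataset.observations
    keep_mask = np.ones(len(obs), dtype=bool)
    for _, idx in obs.groupby(list(group_cols)).groups.items():
        vals = obs.loc[idx, "conc_mg_L"].to_numpy()
        if vals.size < 4:
            continue
        q1, q3 = np.percentile(vals, [25, 75], method="linear")
        iqr = q3 - q1
        bad = (vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)
        keep_mask[obs.index.get_indexer(idx)] &= ~bad
    report_rows = []
    for matrix, sub in obs.groupby("matrix"):
        sub_keep = keep_mask[obs.index.get_indexer(sub.index)]
        n, nex = len(sub), int((~sub_keep).sum())
        pct = 100.0 * nex / n if n else 0.0
        report_rows.append({
            "matrix": matrix, "n_total": n, "n_excluded": nex,
            "summary": f"{nex}/{n} ({pct:.1f}%)",
        })
    filtered = StudyDataset(
        observations=obs[keep_mask].reset_index(drop=True),
        metadata={**dataset.metadata,
                  "iqr_excluded": int((~keep_mask).sum())},
    )
    return filtered, pd.DataFrame(report_rows)


def aic(n_obs: int, rss: float, k_params: int) -> float:
    """Least-squares AIC: n*ln(RSS/n) + 2k."""
    if n_obs <= 0:
        raise ValidationError("n_obs must be > 0")
    if rss < 0:
        raise ValidationError("rss must be >= 0")
    if rss == 0:
        warnings.warn("rss = 0: AIC is -inf (perfect fit)", stacklevel=2)
        return float("-inf")
    return n_obs * math.log(rss / n_obs) + 2 * k_params


# ---------------------------------------------------------------------------
# model predictions


def _predict_one_compartment(logp: np.ndarray, regimen: Regimen, t: np.ndarray) -> np.ndarray:
    V, ka, kel = np.exp(np.clip(logp, -30.0, 30.0))  # keep rates finite
    params = PKParameters(volume=V, ka=ka, kel=kel)
    return simulate_regimen(params, regimen)(t)


def two_compartment_concentration(
    volume: float, ka: float, k10: float, k12: float, k21: float,
    dose: float, t,
) -> np.ndarray:
    """Two-compartment first-order-absorption closed form (central conc).

    Tri-exponential with macro rate constants alpha, beta from
    s^2 - (k10+k12+k21) s + k10*k21 = 0.  Used only as the richer AIC
    candidate; near-coincident rates are nudged apart for stability.
    """
    raw = np.asarray(t, dtype=float)
    arr = np.maximum(raw, 0.0)  # pre-dose times contribute zero
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
    rates = [alpha, beta, ka]
    for i in range(1, 3):  # separate coincident exponents
        for j in range(i):
            if abs(rates[i] - rates[j]) < 1e-9 * max(rates[i], 1e-12):
                rates[i] *= 1.0 + 1e-7
    alpha, beta, ka = rates
    pref = ka * dose / volume
    c = (
        pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha)) * np.exp(-alpha * arr)
        + pref * (k21 - beta) / ((ka - beta) * (alpha - beta)) * np.exp(-beta * arr)
        + pref * (k21 - ka) / ((alpha - ka) * (beta - ka)) * np.exp(-ka * arr)
    )
    return np.where(raw >= 0, c, 0.0)


def _predict_two_compartment(logp: np.ndarray, regimen: Regimen, t: np.ndarray) -> np.ndarray:
    V, ka, k10, k12, k21 = np.exp(np.clip(logp, -30.0, 30.0))
    c = np.zeros_like(t, dtype=float)
    for e in regimen.materialize():
        c += two_compartment_concentration(V, ka, k10, k12, k21, e.amount, t - e.time)
    return c


_PREDICTORS = {
    "one_compartment_foabs": (_predict_one_compartment, 3),
    "two_compartment_foabs": (_predict_two_compartment, 5),
}


def _initial_guesses(t: np.ndarray, y: np.ndarray, dose_total: float, model: str):
    """Multi-start grid from curve geometry.

    The terminal slope of log-concentration estimates the slower rate
    constant; because of possible flip-flop it may be either ka or kel, so
    both assignments are tried against a log-spaced grid for the partner
    rate.  V is back-extrapolated from the observed peak.
    """
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    pos = ys > 0
    lam_z = 1.0
    if pos.sum() >= 3:
        tt, ly = ts[pos], np.log(ys[pos])
        tail = max(3, len(tt) // 3)
        slope = np.polyfit(tt[-tail:], ly[-tail:], 1)[0]
        if slope < -1e-6:
            lam_z = -slope
    cmax_obs = float(ys.max()) if ys.size else 1.0
    v0 = max(dose_total / max(cmax_obs, 1e-6), 1e-3)
    partner_grid = np.array([0.1, 1.0, 5.0, 30.0])
    starts = []
    for partner in partner_grid:
        if abs(partner - lam_z) / lam_z < 0.05:
            partner *= 1.5
        if model == "one_compartment_foabs":
            starts.append(np.log([v0, partner, lam_z]))  # absorption fast
            starts.append(np.log([v0, lam_z, partner]))  # flip-flop
        else:
            starts.append(np.log([v0, partner, lam_z, 0.5, 0.5]))
            starts.append(np.log([v0, lam_z, partner, 0.5, 0.5]))
    return starts


def fit_pk(
    data: StudyDataset,
    model: str = "one_compartment_foabs",
    weighting: str = "none",
    lloq: float | None = None,
    regimen: Regimen | None = None,
    matrix: str | None = None,
    analyte: str | None = None,
) -> FitResult:
    """Naive-pooled weighted NLS fit of a compartment model.

    The administered regimen is taken from ``data.metadata["regimen"]``
    unless passed explicitly.  Observations below ``lloq`` are dropped
    (no imputation).  Weighting options: "none", "1/y", "1/y2" (weights
    computed from observed concentrations).  Multi-start initialisation is
    deterministic, so the fit is reproducible given the data.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    if weighting not in WEIGHTINGS:
        raise ValidationError(f"unknown weighting {weighting!r}")
    regimen = regimen or data.metadata.get("regimen")
    if regimen is None:
        raise ValidationError("no regimen in metadata and none provided")
    obs = data.observations
    if matrix is not None:
        obs = obs[obs["matrix"] == matrix]
    if analyte is not None:
        obs = obs[obs["analyte"] == analyte]
    if lloq is not None:
        obs = obs[obs["conc_mg_L"] >= lloq]
    t = obs["time_h"].to_numpy(dtype=float)
    y = obs["conc_mg_L"].to_numpy(dtype=float)
    predictor, k = _PREDICTORS[model]
    if np.unique(t).size < k + 1:
        raise ValidationError(
            f"need >= {k + 1} distinct timepoints for {model}, "
            f"got {np.unique(t).size}"
        )
    if weighting == "none":
        w = np.ones_like(y)
    elif weighting == "1/y":
        w = 1.0 / np.maximum(y, 1e-9)
    else:
        w = 1.0 / np.maximum(y, 1e-9) ** 2
    sw = np.sqrt(w)

    def residual(logp):
        return sw * (predictor(logp, regimen, t) - y)

    best = None
    n_ok = 0
    starts = _initial_guesses(t, y, regimen.total_dose_per_course, model)
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residual, x0, method="trf", x_scale="jac", max_nfev=400,
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    converged = best is not None and n_ok > 0 and best.success
    if best is None:
        return FitResult(model, {}, float("inf"), len(y), k, float("inf"),
                         np.empty(0), False, weighting, len(starts))
    res = best.fun / sw  # unweighted residuals
    rss = float(np.sum(best.fun**2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        crit = aic(len(y), rss, k)
    p = np.exp(best.x)
    if model == "one_compartment_foabs":
        names = ["volume", "ka", "kel"]
    else:
        names = ["volume", "ka", "k10", "k12", "k21"]
    params = dict(zip(names, (float(x) for x in p)))
    if matrix is not None:
        params["matrix"] = matrix
    return FitResult(
        model=model, params=params, rss=rss, n_obs=len(y), k_params=k,
        aic=crit, residuals=res, converged=converged,
        weighting=weighting, n_starts=len(starts),
    )


def select_model(fits: list[FitResult]) -> FitResult:
    """Lowest-AIC converged fit; exact ties go to the simpler model."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValidationError("no converged fits to select from")
    return min(ok, key=lambda f: (f.aic, f.k_params))
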