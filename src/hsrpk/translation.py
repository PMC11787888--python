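"""Matrix corrections between plasma, BAL fluid and epithelial lining fluid.

Three translations connect the measured matrices to the pharmacologically
relevant ones:

* ultrafiltration free fraction — unbound fraction fu estimated per
  replicate as C_ultrafiltrate / C_total, pooled across dose groups;
* BAL urea-dilution correction — lavage dilutes ELF by an unknown factor;
  urea equilibrates freely between plasma and ELF, so
  C_ELF = C_BAL * (urea_plasma / urea_BAL) recovers the ELF concentration;
* plasma-to-ELF penetration — a linear-in-time penetration ratio
  C_ELF(t) = C_plasma(t) * (slope * t + intercept) fitted to single-point
  penetration estimates, used to construct a plausible human ELF profile
  and its AUC_ELF/AUC_plasma ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .pk import ConcentrationProfile, DomainError, Term, ValidationError


@dataclass(frozen=True)
class BindingRecord:
    """One ultrafiltration replicate: paired total and ultrafiltrate conc."""

    dose_group: float
    replicate: int
    total_concentration: float
    ultrafiltrate_concentration: float


@dataclass(frozen=True)
class BALRecord:
    """One mouse's pooled BAL sample with paired plasma/BAL urea (mg/dL).

    Only the urea ratio matters, so any consistent urea unit is accepted.
    """

    mouse_id: str
    bal_concentration: float
    urea_plasma: float
    urea_bal: float
    time_h: float | None = None

    def __post_init__(self) -> None:
        if self.urea_plasma <= 0:
            raise ValidationError("urea_plasma must be > 0")
        if self.urea_bal > self.urea_plasma:
            warnings.warn(
                f"mouse {self.mouse_id}: urea_BAL ({self.urea_bal}) exceeds "
                f"urea_plasma ({self.urea_plasma}); lavage should dilute urea",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PenetrationModel:
    """Linear-in-time plasma-to-ELF penetration ratio: slope*t + intercept."""

    slope: float
    intercept: float
    r_squared: float = float("nan")
    time_range: tuple[float, float] = (0.5, 8.0)

    def predict(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.intercept


@dataclass(frozen=True)
class FreeFractionResult:
    per_replicate: pd.DataFrame  # dose_group, replicate, fraction
    per_dose: pd.Series  # dose_group -> mean fraction
    pooled: float  # unweighted mean of dose-group means
    n_capped: int
    n_dropped: int


def free_fraction(records: list[BindingRecord]) -> FreeFractionResult:
    """Unbound fraction per replicate, per dose group, and pooled.

    fraction = ultrafiltrate / total per replicate; dose-group means are
    averaged with equal weight into the pooled estimate (binding is treated
    as exposure-independent over the studied dose range).  Fractions above
    1 (assay noise) are capped at 1 with a warning; records with
    non-positive totals are dropped with a warning.
    """
    rows = []
    n_capped = n_dropped = 0
    for r in records:
        if r.total_concentration <= 0:
            warnings.warn(
                f"dropping replicate {r.replicate} of dose {r.dose_group}: "
                f"non-positive total concentration", stacklevel=2,
            )
            n_dropped += 1
            continue
        frac = r.ultrafiltrate_concentration / r.total_concentration
        if frac > 1:
            warnings.warn(
                f"capping fraction {frac:.3f} at 1 for replicate "
                f"{r.replicate} of dose {r.dose_group}", stacklevel=2,
            )
            frac = 1.0
            n_capped += 1
        rows.append({"dose_group": r.dose_group, "replicate": r.replicate,
                     "fraction": frac})
    if not rows:
        raise ValidationError("no usable binding records")
    df = pd.DataFrame(rows)
    per_dose = df.groupby("dose_group")["fraction"].mean()
    return FreeFractionResult(
        per_replicate=df,
        per_dose=per_dose,
        pooled=float(per_dose.mean()),
        n_capped=n_capped,
        n_dropped=n_dropped,
    )


def elf_from_bal(record: BALRecord) -> float:
    """ELF concentration from a BAL measurement via the urea-dilution ratio.

    Returns C_BAL * urea_plasma / urea_BAL (mg/L); the result is an unbound
    concentration (BAL fluid lacks albumin, so ELF drug is considered free).
    """
    if record.urea_bal <= 0:
        raise DomainError("urea_bal must be > 0")
    return record.bal_concentration * record.urea_plasma / record.urea_bal


def elf_from_bal_table(records: list[BALRecord]) -> pd.DataFrame:
    """Tabulate the urea-dilution correction for a list of BAL records."""
    return pd.DataFrame(
        {
            "mouse_id": r.mouse_id,
            "time_h": r.time_h,
            "bal_mg_L": r.bal_concentration,
            "dilution_factor": r.urea_bal / r.urea_plasma,
            "elf_mg_L": elf_from_bal(r),
        }
        for r in records
    )


def fit_penetration_model(times, ratios) -> PenetrationModel:
    """Ordinary least-squares line through (time, penetration ratio) points."""
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.size != r.size or t.size < 2:
        raise ValidationError("need >= 2 paired (time, ratio) points")
    if np.unique(t).size < 2:
        raise ValidationError("degenerate design: all times identical")
    fit = stats.linregress(t, r)
    return PenetrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        time_range=(float(t.min()), float(t.max())),
    )


def apply_penetration(
    profile_plasma: ConcentrationProfile,
    model: PenetrationModel,
    extrapolate: bool = False,
) -> tuple[ConcentrationProfile, float]:
    """Scale a plasma profile by the time-varying penetration ratio.

    C_ELF(t) = C_plasma(t) * (slope*t + intercept).  Because the ratio is
    linear in t, each term coef*(t-tau)^p*exp(...) maps exactly onto terms
    of power p and p+1, keeping the ELF profile analytic.  Returns the ELF
    profile and AUC_ELF/AUC_plasma over the profile window.

    By default the profile window must lie within the model's fitted time
    range; pass ``extrapolate=True`` to apply the line outside it (e.g.
    over a full 24 h interval).
    """
    a, b = profile_plasma.window
    lo = model.intercept + model.slope * (a if model.slope > 0 else b)
    if lo < 0:
        bad_end = a if model.slope > 0 else b
        raise DomainError(
            f"penetration ratio negative near t={bad_end:g} h within "
            f"window [{a:g}, {b:g}]"
        )
    if not extrapolate and (a < model.time_range[0] - 1e-9 or b > model.time_range[1] + 1e-9):
        raise ValidationError(
            f"window [{a:g}, {b:g}] outside fitted range {model.time_range}; "
            "pass extrapolate=True to allow"
        )
    terms = []
    for tm in profile_plasma.terms:
        # (intercept + slope*t) = (intercept + slope*tau) + slope*(t - tau)
        terms.append(replace(tm, coef=tm.coef * (model.intercept + model.slope * tm.onset)))
        terms.append(Term(tm.onset, tm.coef * model.slope, tm.rate, tm.power + 1))
    elf = ConcentrationProfile(
        terms=tuple(terms),
        window=profile_plasma.window,
        matrix="ELF",
        binding_state="unbound",
        unbound_fraction=profile_plasma.unbound_fraction,
    )
    denom = profile_plasma.integral(a, b)
    ratio = elf.integral(a, b) / denom if denom > 0 else float("nan")
    return elf, ratio
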