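"""Seeded generators of realistic murine PK study datasets.

Murine PK sampling is destructive and sparse: groups of six mice per
timepoint, each mouse contributing at most two retro-orbital samples plus
one terminal (cardiac puncture) sample, at which BAL fluid may also be
collected.  The generators emulate that structure — proportional assay
noise, per-mouse lavage dilution with paired urea, ultrafiltration
replicate pairs, and optional multiplicative outliers — so every pipeline
stage (IQR filtering, naive-pooled fitting, urea correction, binding
estimation) can be exercised and validated against a known truth without
any external data.  All randomness flows from one explicit seed and the
generating truth is recorded in the dataset metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import OBS_COLUMNS, StudyDataset
from .pk import ConcentrationProfile, PKParameters, Regimen, ValidationError, simulate_regimen
from .translation import BALRecord, BindingRecord


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: proportional CV, additive SD, outlier process.

    The default 20% proportional CV sits below the ~30% parameter-level
    variability typical of antibiotic PK in mice.  Proportional errors are
    Normal(0, cv) truncated at -0.99 so concentrations stay positive.
    """

    cv: float = 0.20
    additive_sd: float = 0.0
    outlier_prob: float = 0.0
    outlier_multipliers: tuple[float, ...] = (5.0, 10.0)

    def __post_init__(self) -> None:
        if self.cv < 0 or self.additive_sd < 0:
            raise ValidationError("noise magnitudes must be >= 0")
        if not (0 <= self.outlier_prob <= 1):
            raise ValidationError("outlier_prob must be in [0, 1]")

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.normal(0.0, self.cv, size=values.shape) if self.cv > 0 else 0.0
        eps = np.maximum(eps, -0.99)
        out = values * (1.0 + eps)
        if self.additive_sd > 0:
            out = out + rng.normal(0.0, self.additive_sd, size=values.shape)
        return np.maximum(out, 0.0)


@dataclass(frozen=True)
class SamplingDesign:
    """Destructive sparse sampling scheme: timepoints, group size, per-mouse cap."""

    timepoints: tuple[float, ...]
    mice_per_timepoint: int = 6
    samples_per_mouse: int = 3

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise ValidationError("need at least one timepoint")
        if any(t < 0 for t in self.timepoints):
            raise ValidationError("timepoints must be >= 0")
        if self.mice_per_timepoint <= 0 or not (1 <= self.samples_per_mouse <= 3):
            raise ValidationError("counts must be positive; samples_per_mouse <= 3")

    def schedule(self) -> list[tuple[str, float]]:
        """(mouse id, time) pairs: cohorts of mice span consecutive timepoints.

        Each cohort of ``mice_per_timepoint`` mice is bled at up to
        ``samples_per_mouse`` consecutive timepoints, the last of which is
        terminal, giving exactly ``mice_per_timepoint`` samples per timepoint.
        """
        times = sorted(self.timepoints)
        pairs: list[tuple[str, float]] = []
        span = self.samples_per_mouse
        for c, start in enumerate(range(0, len(times), span)):
            block = times[start:start + span]
            for m in range(self.mice_per_timepoint):
                mouse = f"c{c}m{m}"
                pairs.extend((mouse, t) for t in block)
        return pairs


def generate_pk_study(
    truth: PKParameters,
    regimen: Regimen,
    design: SamplingDesign,
    noise: NoiseModel,
    seed: int,
    matrix: str | None = None,
    analyte: str = "drug",
) -> StudyDataset:
    """Simulate a destructive-sampling PK study from known parameters.

    Observation = closed-form concentration x (1 + eps); deterministic given
    the seed.  Truth, design and regimen are recorded in the metadata so
    recovery tests can score the fit.
    """
    rng = np.random.default_rng(seed)
    matrix = matrix or truth.matrix
    profile = simulate_regimen(truth, regimen)
    pairs = design.schedule()
    t = np.array([p[1] for p in pairs])
    true_c = profile(t)
    obs_c = noise.perturb(true_c, rng)
    obs = pd.DataFrame({
        "subject_id": [p[0] for p in pairs],
        "time_h": t,
        "matrix": matrix,
        "analyte": analyte,
        "conc_mg_L": obs_c,
    })[OBS_COLUMNS]
    ds = StudyDataset(
        observations=obs,
        metadata={
            "regimen": regimen, "design": design, "noise": noise, "seed": seed,
            "truth": truth, "true_conc": true_c,
        },
    )
    if noise.outlier_prob > 0:
        ds = inject_outliers(ds, noise.outlier_prob, noise.outlier_multipliers,
                             seed=rng.integers(2**31))
    return ds


def generate_bal_study(
    truth_elf_profile: ConcentrationProfile,
    urea_plasma: float,
    timepoints,
    n_per_timepoint: int,
    noise: NoiseModel,
    seed: int,
    dilution_range: tuple[float, float] = (0.01, 0.10),
) -> tuple[list[BALRecord], dict]:
    """Simulate BAL sampling: per-mouse lavage dilution with paired urea.

    Each mouse draws a dilution d ~ Uniform(dilution_range); both the drug
    and urea channels see the same d (urea equilibrates into ELF at the
    plasma level) with independent proportional noise, so the urea-ratio
    correction inverts the dilution exactly when the noise is zero.
    """
    if not (0 < dilution_range[0] < dilution_range[1] < 1):
        raise ValidationError("dilution support must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    records: list[BALRecord] = []
    truth: dict[str, float] = {}
    for t in timepoints:
        elf_true = truth_elf_profile(float(t))
        for m in range(n_per_timepoint):
            d = rng.uniform(*dilution_range)
            bal = float(noise.perturb(np.array([elf_true * d]), rng)[0])
            urea_bal = float(noise.perturb(np.array([urea_plasma * d]), rng)[0])
            mouse = f"t{t:g}m{m}"
            records.append(BALRecord(
                mouse_id=mouse, bal_concentration=bal,
                urea_plasma=urea_plasma, urea_bal=urea_bal, time_h=float(t),
            ))
            truth[mouse] = elf_true
    return records, {"true_elf": truth, "seed": seed, "urea_plasma": urea_plasma}


def generate_binding_study(
    true_fraction: float,
    dose_groups,
    replicates: int,
    noise: NoiseModel,
    seed: int,
    concentration_per_dose: float = 1.0,
) -> list[BindingRecord]:
    """Simulate ultrafiltration replicate pairs at escalating doses.

    Total plasma concentration is taken proportional to dose
    (``concentration_per_dose`` mg/L per mg/kg, the 1 h post-dose level);
    the ultrafiltrate is total x true_fraction with proportional noise on
    both channels.  The free-fraction estimator recovers ``true_fraction``
    exactly at zero noise.
    """
    if not (0 < true_fraction <= 1):
        raise ValidationError("true_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    records: list[BindingRecord] = []
    for dose in dose_groups:
        for rep in range(replicates):
            total = float(noise.perturb(
                np.array([dose * concentration_per_dose]), rng)[0])
            uf = float(noise.perturb(np.array([total * true_fraction]), rng)[0])
            records.append(BindingRecord(
                dose_group=float(dose), replicate=rep,
                total_concentration=total, ultrafiltrate_concentration=uf,
            ))
    return records


def inject_outliers(
    dataset: StudyDataset,
    probability: float,
    multipliers: tuple[float, ...] = (5.0, 10.0),
    seed: int = 0,
) -> StudyDataset:
    """Multiply a random subset of observations by an outlier factor.

    Flags are recorded in ``metadata["outlier_flags"]`` so filter
    operating characteristics (hit rate, false exclusions) can be scored.
    """
    if not (0 <= probability <= 1):
        raise ValidationError("probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    obs = dataset.observations.copy()
    flags = rng.random(len(obs)) < probability
    if flags.any():
        mult = rng.choice(np.asarray(multipliers, dtype=float), size=int(flags.sum()))
        obs.loc[flags, "conc_mg_L"] = obs.loc[flags, "conc_mg_L"].to_numpy() * mult
    return StudyDataset(
        observations=obs,
        metadata={**dataset.metadata, "outlier_flags": flags,
                  "outlier_seed": seed},
    )
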