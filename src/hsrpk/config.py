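"""Drug/regimen configuration: schema-validated JSON fixtures and loaders.

The shipped ``data/drugs.json`` encodes the study fixtures for the three
reference antibiotics (meropenem, cefiderocol, tobramycin): fitted
one-compartment parameters per matrix, the confirmed human-simulated
regimens, murine and human unbound fractions, and the human reference
exposures (%fT>MIC ladders for the beta-lactams; fCmax/fAUC for
tobramycin).  Human reference values are literature inputs, never
computed here.  Unknown keys are rejected so a typo cannot silently
change a study condition.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .exposure import ExposureSummary
from .pk import DoseEvent, PKParameters, Regimen, ValidationError
from .translation import PenetrationModel


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DoseEventConfig(_Strict):
    time_h: float = Field(ge=0)
    amount_mg_per_kg: float = Field(gt=0)


class RegimenConfig(_Strict):
    events: list[DoseEventConfig]
    repeat_interval_h: float | None = Field(default=None, gt=0)
    horizon_h: float = 24.0

    def to_regimen(self) -> Regimen:
        return Regimen(
            tuple(DoseEvent(e.time_h, e.amount_mg_per_kg) for e in self.events),
            repeat_interval=self.repeat_interval_h,
            horizon=self.horizon_h,
        )


class MatrixConfig(_Strict):
    volume_L_per_kg: float = Field(gt=0)
    ka_per_h: float = Field(gt=0)
    kel_per_h: float = Field(gt=0)
    regimen: RegimenConfig
    human_ft_above_pct: dict[float, float] | None = None

    @field_validator("human_ft_above_pct")
    @classmethod
    def _check_row(cls, v):
        if v is not None:
            if any(not (0 <= p <= 100) for p in v.values()):
                raise ValueError("percentages must lie in [0, 100]")
        return v


class HumanIndices(_Strict):
    fcmax_mg_L: float = Field(gt=0)
    fauc_mg_h_L: float = Field(gt=0)


class PenetrationConfig(_Strict):
    slope_per_h: float
    intercept: float
    r_squared: float
    time_range_h: tuple[float, float]
    literature_auc_ratio: float

    def to_model(self) -> PenetrationModel:
        return PenetrationModel(
            slope=self.slope_per_h, intercept=self.intercept,
            r_squared=self.r_squared, time_range=self.time_range_h,
        )


class DrugConfig(_Strict):
    drug_class: str
    human_regimen_label: str
    unbound_fraction_mouse: float = Field(gt=0, le=1)
    unbound_fraction_human: float = Field(gt=0, le=1)
    matrices: dict[str, MatrixConfig]
    human_reference_indices: dict[str, HumanIndices] | None = None
    penetration: PenetrationConfig | None = None
    murine_binding_pct_by_dose: dict[float, float] | None = None

    def pk_parameters(self, matrix: str) -> PKParameters:
        m = self.matrices[matrix]
        return PKParameters(m.volume_L_per_kg, m.ka_per_h, m.kel_per_h, matrix)

    def regimen(self, matrix: str) -> Regimen:
        return self.matrices[matrix].regimen.to_regimen()

    def unbound_fraction(self, matrix: str) -> float:
        """Murine unbound fraction applied to a matrix's profile.

        ELF concentrations are treated as fully unbound (BAL fluid lacks
        albumin), so only plasma receives a binding correction.
        """
        return self.unbound_fraction_mouse if matrix == "plasma" else 1.0

    def human_summary(self, matrix: str, window=(0.0, 8.0)) -> ExposureSummary | None:
        """Human reference exposures as a literature-fixture summary."""
        m = self.matrices[matrix]
        idx = (self.human_reference_indices or {}).get(matrix)
        if m.human_ft_above_pct is None and idx is None:
            return None
        ft = dict(sorted((m.human_ft_above_pct or {}).items()))
        return ExposureSummary(
            fcmax=idx.fcmax_mg_L if idx else float("nan"),
            tmax=float("nan"),
            fauc=idx.fauc_mg_h_L if idx else float("nan"),
            window=window,
            ft_above=ft,
            matrix=matrix,
            species="human",
        )


class ConfigFile(_Strict):
    schema_version: int
    drugs: dict[str, DrugConfig]


def default_config_path() -> Path:
    return Path(resources.files("hsrpk") / "data" / "drugs.json")


def load_config(path: str | Path | None = None) -> dict[str, DrugConfig]:
    """Load and schema-validate a drug configuration file.

    Defaults to the shipped fixture set.  Raises a validation error naming
    the offending field on any schema violation; unknown keys are rejected.
    """
    p = Path(path) if path is not None else default_config_path()
    if not p.exists():
        raise FileNotFoundError(p)
    with open(p) as fh:
        raw = json.load(fh)
    try:
        cfg = ConfigFile.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError carries field names
        raise ValidationError(f"invalid drug config {p}: {exc}") from exc
    return cfg.drugs


def config_digest(path: str | Path | None = None) -> str:
    """SHA-256 of the raw config file, for provenance headers."""
    import hashlib

    p = Path(path) if path is not None else default_config_path()
    return hashlib.sha256(p.read_bytes()).hexdigest()[:16]
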