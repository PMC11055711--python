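"""Configuration models for the synthetic cohort and the pipeline.

All randomness in a run flows from the single integer ``seed`` through one
:class:`numpy.random.Generator`; there is no global RNG state anywhere in
the package.
"""

from __future__ import annotations

import math
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import defaults
from .registry import IMPAIRMENT_THRESHOLD, RCI_THRESHOLD, load_registry


class ConfigError(ValueError):
    """A cohort or pipeline configuration is invalid; message names the field."""


class _ValidatedModel(BaseModel):
    """Surface validation failures as ConfigError (field named in message)."""

    def __init__(self, **data):
        from pydantic import ValidationError

        try:
            super().__init__(**data)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc


class CohortConfig(_ValidatedModel):
    """Generating conditions for one synthetic control + patient cohort."""

    model_config = ConfigDict(validate_assignment=True)

    n_controls: int = 96
    n_patients: int = 348
    seed: int = 0

    group_mix: dict[str, float] = Field(
        default_factory=lambda: dict(defaults.GROUP_MIX)
    )
    domain_effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in defaults.DOMAIN_EFFECTS.items()}
    )
    #: per-domain shift added to every group's effects at follow-up
    followup_drift: float = defaults.FOLLOWUP_DRIFT
    #: optional full override of follow-up effects (group -> domain -> shift)
    domain_effects_followup: dict[str, dict[str, float]] | None = None

    practice_effect: dict[str, float] = Field(
        default_factory=lambda: dict(defaults.PRACTICE_EFFECT)
    )
    test_retest_r: dict[str, float] | float = defaults.TEST_RETEST_R
    test_models: dict[str, tuple[float, float, float, float, float]] = Field(
        default_factory=lambda: dict(defaults.TEST_MODELS)
    )

    #: correlation of the latent domain scores across domains
    cross_domain_r: float = 0.45
    #: SD of the (mean-centred) within-domain sub-score deviations
    within_domain_sd: float = 0.6

    retention: float = defaults.RETENTION
    followup_years: tuple[float, float] = defaults.FOLLOWUP_YEARS

    mri_params: dict[str, dict] = Field(
        default_factory=lambda: {g: dict(v) for g, v in defaults.MRI_PARAMS.items()}
    )
    mri_cog_slopes: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {m: dict(v) for m, v in defaults.MRI_COG_SLOPES.items()}
    )
    #: cross-measure correlations keyed "measure_a|measure_b"
    mri_corr: dict[str, float] = Field(
        default_factory=lambda: {f"{a}|{b}": r for (a, b), r in defaults.MRI_CORR.items()}
    )
    cortical_lesion_available: float = defaults.CORTICAL_LESION_AVAILABLE

    @field_validator("n_controls")
    @classmethod
    def _n_controls(cls, v: int) -> int:
        if v < 20:
            raise ConfigError(f"n_controls must be >= 20 to fit norms, got {v}")
        return v

    @field_validator("n_patients")
    @classmethod
    def _n_patients(cls, v: int) -> int:
        if v < 1:
            raise ConfigError(f"n_patients must be positive, got {v}")
        return v

    @field_validator("retention", "cortical_lesion_available")
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"fraction must lie in [0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        known = set(defaults.GROUPS)
        unknown = set(self.group_mix) - known
        if unknown:
            raise ConfigError(
                f"group_mix references unknown group(s) {sorted(unknown)}; "
                f"known groups: {sorted(known)}"
            )
        total = sum(self.group_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"group_mix must sum to 1 (got {total!r})")
        unknown = set(self.domain_effects) - known
        if unknown:
            raise ConfigError(f"domain_effects references unknown group(s) {sorted(unknown)}")
        for name, r in self.retest_by_test().items():
            if not 0.0 < r < 1.0:
                raise ConfigError(f"test_retest_r[{name}] must lie in (0, 1), got {r}")
        for name, (_, sd, *_rest) in self.test_models.items():
            if sd <= 0:
                raise ConfigError(f"test_models[{name}] residual SD must be > 0, got {sd}")
        for group, params in self.mri_params.items():
            for key, val in params.items():
                if isinstance(val, tuple) and len(val) == 2 and val[1] is not None:
                    if val[1] <= 0:
                        raise ConfigError(f"mri_params[{group}][{key}] SD must be > 0")
        return self

    def retest_by_test(self) -> dict[str, float]:
        """Per-test test-retest correlation (scalar broadcast over the battery)."""
        names = list(self.test_models)
        if isinstance(self.test_retest_r, dict):
            return {n: self.test_retest_r.get(n, defaults.TEST_RETEST_R) for n in names}
        return {n: float(self.test_retest_r) for n in names}

    def followup_effects(self) -> dict[str, dict[str, float]]:
        if self.domain_effects_followup is not None:
            return self.domain_effects_followup
        return {
            g: {d: v + self.followup_drift for d, v in eff.items()}
            for g, eff in self.domain_effects.items()
        }


class PipelineConfig(_ValidatedModel):
    """End-to-end run settings; constants default to the published rules."""

    model_config = ConfigDict(validate_assignment=True)

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    seed: int = 0

    impairment_threshold: float = IMPAIRMENT_THRESHOLD
    rci_threshold: float = RCI_THRESHOLD
    sed_estimator: Literal["jacobson_truax", "sd_of_differences"] = "jacobson_truax"
    rci_gated: bool = False
    #: count every multidomain->multidomain follow-up as declining (printed
    #: cross-tabulation accounting) instead of count-based labelling
    multidomain_declines: bool = False
    entry_alpha: float = 0.05
    multiplicity: Literal["bonferroni", "none"] = "bonferroni"
    screen_alpha: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        for name in ("impairment_threshold", "rci_threshold", "entry_alpha", "screen_alpha"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigError(f"{name} must be finite, got {v}")
        if self.rci_threshold < 0:
            raise ConfigError("rci_threshold must be non-negative")
        self.cohort.seed = self.seed
        return self

    def resolved_yaml(self) -> str:
        import yaml

        payload = self.model_dump(mode="json")
        return yaml.safe_dump(payload, sort_keys=True)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]


def validate_registry_names(names) -> None:
    """Raise ConfigError if any score name is outside the registry."""
    reg = load_registry()
    allowed = set(reg.all_raw_names) | set(reg.scored)
    unknown = sorted(set(names) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown sub-score name(s) {unknown}; registry knows {sorted(allowed)}"
        )
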