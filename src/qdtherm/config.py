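"""Run configuration for the thermometry analysis.

All tunable constants of the pipeline live in :class:`RunConfig` so that a
run is fully described by (input tables, config).  Defaults reflect the
assay geometry (readings every 5 s for 2 min, quadratic initial-rate fit
over the full window) and the replicate QC convention (single-pass 1-SD
rule after negative-rate removal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class RunConfig:
    """Tunable parameters of the analysis pipeline.

    Parameters
    ----------
    poly_degree
        Degree of the polynomial fitted to each relative fluorescence
        trace; the initial decay rate is minus the linear coefficient.
        A "negative hyperbolic" decay is locally quadratic, so degree 2
        gives an interpretable t = 0 derivative without chasing the noisy
        tail of the trace.
    sampling_interval_s
        Expected spacing of kinetic readings, seconds.
    interval_tolerance
        Allowed relative deviation of each time step from
        ``sampling_interval_s`` (plate readers jitter slightly).
    window_end_s
        End of the regression window, seconds; points beyond it are
        dropped before fitting.
    sd_multiplier
        Width of the replicate exclusion band in sample standard
        deviations (the assay convention is 1.0).
    iia_stratify_threshold
        MyHC type IIa fraction above which a preparation is assigned to
        the high-IIa stratum and kept out of the main group comparison.
    a280_factor_mg_per_ml_per_AU
        Conversion from blank-corrected A280 absorbance to mg/mL.  The
        generic-protein convention is 1.0; the factor cancels in any
        within-study comparison because every sample shares it.
    bsa_recovery_tolerance
        Allowed relative deviation of a BSA internal control's measured
        concentration from its nominal value before the batch is flagged.
    cv_warn_threshold
        Reading CV above which a protein quantification gets a QC note
        (not an exclusion).
    dilution_rate_tolerance
        Relative band below the fastest net rate within which a dilution
        still counts as "fastest" when picking the optimal concentration.
    weighted_fit
        If True, weight the polynomial fit by the inverse noise variance
        of the two noise regimes (early window clean, late window noisy).
        Off by default: the reference procedure is plain OLS.
    noise_boundary_s
        Boundary between the two noise regimes, seconds.
    weight_late_relative_sd
        Assumed late/early noise-SD ratio used only when ``weighted_fit``.
    exclude_whole_animal_high_iia
        If True, an animal with any high-IIa preparation is removed from
        the main-group statistic entirely; default stratifies per
        preparation.
    missing_composition_policy
        "exclude" (default: drop the preparation from stratified group
        statistics, with a warning note) or "main" (assume main stratum).
    random_seed
        Seed for any stochastic step (none in the core pipeline; kept for
        provenance and CLI symmetry with the simulator).
    """

    poly_degree: int = 2
    sampling_interval_s: float = 5.0
    interval_tolerance: float = 0.10
    window_end_s: float = 120.0
    sd_multiplier: float = 1.0
    iia_stratify_threshold: float = 0.10
    a280_factor_mg_per_ml_per_AU: float = 1.0
    bsa_recovery_tolerance: float = 0.10
    cv_warn_threshold: float = 0.10
    dilution_rate_tolerance: float = 0.05
    weighted_fit: bool = False
    noise_boundary_s: float = 20.0
    weight_late_relative_sd: float = 5.0
    exclude_whole_animal_high_iia: bool = False
    missing_composition_policy: str = "exclude"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.poly_degree < 1:
            raise ConfigError("poly_degree must be >= 1")
        for name in (
            "sampling_interval_s",
            "window_end_s",
            "sd_multiplier",
            "a280_factor_mg_per_ml_per_AU",
            "weight_late_relative_sd",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.iia_stratify_threshold <= 1.0:
            raise ConfigError("iia_stratify_threshold must be in [0, 1]")
        for name in ("bsa_recovery_tolerance", "dilution_rate_tolerance",
                     "interval_tolerance"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.missing_composition_policy not in ("exclude", "main"):
            raise ConfigError(
                "missing_composition_policy must be 'exclude' or 'main'")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config file must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **overrides: Any) -> "RunConfig":
        data = self.to_dict()
        data.update(overrides)
        return RunConfig.from_dict(data)
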