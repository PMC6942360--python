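"""Run configuration: YAML round-trip with strict key validation."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .experiment import PAPER_COVERS, PAPER_DYNAMISMS, ScenarioGrid
from .species import build_virtual_species_set

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    seed: int = 0
    output_dir: str = "results"
    figures: bool = True
    verbosity: str = "info"
    # landscape
    side_m: float = 3163.0
    mean_area_ha: float = 0.5
    sd_area_ha: float = 0.2
    min_dist_m: float = 10.0
    initial_age_mode: str = "uniform0_100"
    # grid
    species_ids: list[int] | None = None  #: None = all 54
    species_b: float = 1.0
    covers: list[float] = field(default_factory=lambda: list(PAPER_COVERS))
    dynamisms: list[float] = field(default_factory=lambda: list(PAPER_DYNAMISMS))
    iterations: int = 100
    steps: int = 100
    init_occupancy: float = 0.5
    fresh_landscape_per_iteration: bool = True
    colonization_rule: str = "product"
    extinction_rule: str = "product"
    ci_method: str = "normal"
    workers: int = 1

    def validate(self) -> None:
        checks = [
            (self.side_m > 0, "side_m must be positive"),
            (self.mean_area_ha > 0, "mean_area_ha must be positive"),
            (self.sd_area_ha >= 0, "sd_area_ha must be non-negative"),
            (self.min_dist_m >= 0, "min_dist_m must be non-negative"),
            (self.iterations >= 1, "iterations must be >= 1"),
            (self.steps >= 1, "steps must be >= 1"),
            (0 <= self.init_occupancy <= 1, "init_occupancy must be in [0, 1]"),
            (self.initial_age_mode in ("uniform0_100", "zero"),
             f"initial_age_mode: unknown mode {self.initial_age_mode!r}"),
            (self.ci_method in ("normal", "bootstrap"),
             f"ci_method: unknown method {self.ci_method!r}"),
            (self.colonization_rule in ("product", "or"),
             f"colonization_rule: unknown rule {self.colonization_rule!r}"),
            (self.extinction_rule in ("product", "or"),
             f"extinction_rule: unknown rule {self.extinction_rule!r}"),
            (self.workers >= 1, "workers must be >= 1"),
        ]
        for cover in self.covers:
            checks.append((0 < cover < 1, f"covers: value {cover} not in (0, 1)"))
        for dyn in self.dynamisms:
            checks.append((0 <= dyn <= 1, f"dynamisms: value {dyn} not in [0, 1]"))
        if self.species_ids is not None:
            for sid in self.species_ids:
                checks.append(
                    (1 <= sid <= 54, f"species_ids: id {sid} outside 1..54")
                )
        errors = [msg for ok, msg in checks if not ok]
        if errors:
            raise ConfigError("; ".join(errors))

    def to_grid(self) -> ScenarioGrid:
        self.validate()
        all_species = build_virtual_species_set(b=self.species_b)
        if self.species_ids is None:
            species = tuple(all_species)
        else:
            by_id = {s.species_id: s for s in all_species}
            species = tuple(by_id[i] for i in self.species_ids)
        return ScenarioGrid(
            species=species,
            covers=tuple(self.covers),
            dynamisms=tuple(self.dynamisms),
            iterations=self.iterations,
            steps=self.steps,
            init_occupancy=self.init_occupancy,
            base_seed=self.seed,
            side=self.side_m,
            mean_area=self.mean_area_ha,
            sd_area=self.sd_area_ha,
            min_dist=self.min_dist_m,
            initial_age_mode=self.initial_age_mode,
            fresh_landscape_per_iteration=self.fresh_landscape_per_iteration,
            colonization_rule=self.colonization_rule,
            extinction_rule=self.extinction_rule,
            ci_method=self.ci_method,
        )

    def content_hash(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys with their names."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    cfg = RunConfig(**raw)
    try:
        cfg.validate()
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
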