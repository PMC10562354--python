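"""Experiment configuration: YAML schema, validation, defaults.

The configuration mirrors the pipeline stages: a ``landscape`` block with the
synthetic-generator parameters and ``seed``, a ``prioritization`` block with
the benefit-function settings, and an ``evaluation`` block with the analysis
resolutions and top fractions.  Unknown keys are rejected by name so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .landscape import DDWParams, DEFAULT_SITE_SHARES, SPECIES, SpeciesParams, DEFAULT_SPECIES_PARAMS
from .pyramid import DEFAULT_RESOLUTIONS


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated parameters of one six-resolution prioritization experiment."""

    extent_x: float = 960.0
    extent_y: float = 960.0
    cell_size: float = 16.0
    site_shares: tuple[float, float, float, float] = DEFAULT_SITE_SHARES
    smoothness: float = 80.0
    species: dict[str, SpeciesParams] = field(default_factory=lambda: dict(DEFAULT_SPECIES_PARAMS))
    ddw: DDWParams = field(default_factory=DDWParams)
    stack_path: str | None = None  # load a user stack instead of simulating
    z: float = 0.25
    weights: float = 1.0
    warp: int = 1
    tie_rule: str = "lexicographic"
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS
    top_fractions: tuple[float, ...] = (0.02, 0.10)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.z <= 1:
            raise ValueError("z must satisfy 0 < z <= 1")
        if self.warp < 1:
            raise ValueError("warp must be >= 1")
        if self.tie_rule not in ("lexicographic", "random"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")
        for p in self.top_fractions:
            if not 0 < p <= 1:
                raise ValueError(f"top fraction {p} not in (0, 1]")
        for res in self.resolutions:
            ratio = res / self.cell_size
            if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
                raise ValueError(
                    f"resolution {res} is not an integer multiple of the "
                    f"baseline cell size {self.cell_size}"
                )
            for name, extent in (("extent_x", self.extent_x), ("extent_y", self.extent_y)):
                if abs(extent / res - round(extent / res)) > 1e-9:
                    raise ValueError(f"{name}={extent} is not divisible by resolution {res}")

    def to_dict(self) -> dict:
        d = {
            "landscape": {
                "extent_x": self.extent_x,
                "extent_y": self.extent_y,
                "cell_size": self.cell_size,
                "site_shares": list(self.site_shares),
                "smoothness": self.smoothness,
                "species": {sp: dataclasses.asdict(p) for sp, p in self.species.items()},
                "ddw": dataclasses.asdict(self.ddw),
                "stack_path": self.stack_path,
            },
            "prioritization": {
                "z": self.z,
                "weights": self.weights,
                "warp": self.warp,
                "tie_rule": self.tie_rule,
            },
            "evaluation": {
                "resolutions": list(self.resolutions),
                "top_fractions": list(self.top_fractions),
            },
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        return d

    def config_hash(self) -> str:
        """Stable hash of the scientific parameter set, recorded in every output.

        The output directory is excluded: where results land does not change
        what they are.
        """
        d = self.to_dict()
        d.pop("out_dir")
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


_TOP_KEYS = {"landscape", "prioritization", "evaluation", "seed", "out_dir"}
_LANDSCAPE_KEYS = {
    "extent_x",
    "extent_y",
    "cell_size",
    "site_shares",
    "smoothness",
    "species",
    "ddw",
    "stack_path",
}
_PRIORITIZATION_KEYS = {"z", "weights", "warp", "tie_rule"}
_EVALUATION_KEYS = {"resolutions", "top_fractions"}


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def config_from_dict(raw: dict | None) -> ExperimentConfig:
    """Build a validated config from a (possibly empty) parsed YAML mapping."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    kw: dict = {}
    land = raw.get("landscape") or {}
    _reject_unknown(land, _LANDSCAPE_KEYS, "landscape")
    for key in ("extent_x", "extent_y", "cell_size", "smoothness", "stack_path"):
        if key in land:
            kw[key] = land[key]
    if "site_shares" in land:
        kw["site_shares"] = tuple(land["site_shares"])
    if "species" in land:
        species = dict(DEFAULT_SPECIES_PARAMS)
        for sp, overrides in land["species"].items():
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r} in landscape.species")
            base = species[sp]
            bad = set(overrides) - {f.name for f in dataclasses.fields(SpeciesParams)}
            if bad:
                raise ValueError(f"unknown config key(s) in landscape.species.{sp}: {sorted(bad)}")
            species[sp] = base.replace(
                **{
                    k: tuple(v) if k == "intensity_per_ha" else v
                    for k, v in overrides.items()
                }
            )
        kw["species"] = species
    if "ddw" in land:
        bad = set(land["ddw"]) - {f.name for f in dataclasses.fields(DDWParams)}
        if bad:
            raise ValueError(f"unknown config key(s) in landscape.ddw: {sorted(bad)}")
        kw["ddw"] = DDWParams(**land["ddw"])
    prio = raw.get("prioritization") or {}
    _reject_unknown(prio, _PRIORITIZATION_KEYS, "prioritization")
    kw.update(prio)
    ev = raw.get("evaluation") or {}
    _reject_unknown(ev, _EVALUATION_KEYS, "evaluation")
    if "resolutions" in ev:
        kw["resolutions"] = tuple(ev["resolutions"])
    if "top_fractions" in ev:
        kw["top_fractions"] = tuple(ev["top_fractions"])
    if "seed" in raw and raw["seed"] is not None:
        kw["seed"] = int(raw["seed"])
    if "out_dir" in raw:
        kw["out_dir"] = raw["out_dir"]
    return ExperimentConfig(**kw)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML config file; an empty file means all defaults."""
    text = Path(path).read_text()
    return config_from_dict(yaml.safe_load(text))
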