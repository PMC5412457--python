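"""Run configuration, model serialization and result writers.

Model configurations are plain YAML documents with ``species``, ``reactions``
and ``moieties`` blocks; the shipped files under ``thermoglyc/configs/``
reproduce the published parameter tables bit-exactly (round-tripping through
:func:`dump_model` / :func:`load_model` is the identity).

CSV output uses a fixed 12-significant-digit float format so that identical
runs produce byte-identical files, and every CLI run writes a provenance
record (config hash, seed, package version) next to its results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError
from .pathway import PathwayModel, ReactionSpec, SpeciesState

__all__ = [
    "RunConfig",
    "parse_config",
    "serialize_config",
    "load_model",
    "dump_model",
    "load_shipped_model",
    "apply_overrides",
    "write_csv",
    "write_json",
    "provenance_record",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"

_SCENARIOS = ("hyp1", "hyp2", "hyp3", "phosphate", "thermo", "steady",
              "mca", "scan")
_FORMATS = ("csv", "json")
_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    scenario: str
    organism: str = "sulfolobus"
    variant: str = "base"
    overrides: dict = field(default_factory=dict)  # dotted path -> value
    out_dir: str = "results"
    formats: tuple = ("csv", "json")
    seed: int = 1
    log_level: str = "INFO"
    condition: str = "catabolic"  # hyp3 only
    k_deg: float = 1.058  # hyp2/scan only
    with_gapn: bool = False  # hyp2/scan only

    def __post_init__(self):
        problems = []
        if self.scenario not in _SCENARIOS:
            problems.append(f"scenario={self.scenario!r} "
                            f"(valid: {_SCENARIOS})")
        for fmt in self.formats:
            if fmt not in _FORMATS:
                problems.append(f"formats entry {fmt!r} (valid: {_FORMATS})")
        if self.log_level not in _LOG_LEVELS:
            problems.append(f"log_level={self.log_level!r} "
                            f"(valid: {_LOG_LEVELS})")
        if problems:
            raise ConfigurationError(
                "invalid run configuration: " + "; ".join(problems))


def parse_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(
            f"run config {path} must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration keys {unknown}; valid keys: "
            f"{sorted(known)}")
    if "scenario" not in raw:
        raise ConfigurationError("configuration must name a 'scenario'")
    if "formats" in raw:
        raw["formats"] = tuple(raw["formats"])
    return RunConfig(**raw)


def serialize_config(config: RunConfig) -> str:
    """Normalized YAML form of a run configuration (round-trip stable)."""
    data = dataclasses.asdict(config)
    data["formats"] = list(data["formats"])
    return yaml.safe_dump(data, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(serialize_config(config).encode()).hexdigest()


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def dump_model(model: PathwayModel) -> str:
    """YAML document describing a model bit-exactly (floats via repr)."""
    doc = {
        "name": model.name,
        "organism": model.organism,
        "temperature_C": model.temperature_label,
        "species": [
            {"name": s.name, "initial_mM": s.concentration,
             "boundary": s.is_boundary}
            for s in model.species
        ],
        "reactions": [
            {"name": r.name,
             "rate_law": r.rate_law_id,
             "stoichiometry": dict(r.stoichiometry),
             "parameters": {k: ("inf" if math.isinf(v) else v)
                            for k, v in r.parameters.items()},
             **({"species_map": dict(r.species_map)}
                if r.species_map else {})}
            for r in model.reactions
        ],
        "moieties": [
            {"species": sorted(members), "total_mM": total}
            for members, total in model.moieties
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_model(source) -> PathwayModel:
    """Build a PathwayModel from a YAML document (path or string)."""
    text = source if "\n" in str(source) else Path(source).read_text()
    doc = yaml.safe_load(text)
    try:
        species = [SpeciesState(s["name"], float(s["initial_mM"]),
                                bool(s.get("boundary", False)))
                   for s in doc["species"]]
        reactions = [
            ReactionSpec(
                r["name"],
                {k: int(v) for k, v in r["stoichiometry"].items()},
                r["rate_law"],
                {k: (math.inf if v == "inf" else float(v))
                 for k, v in r["parameters"].items()},
                species_map=r.get("species_map"))
            for r in doc["reactions"]
        ]
        moieties = [(frozenset(m["species"]), float(m["total_mM"]))
                    for m in doc.get("moieties", [])]
        model = PathwayModel(
            organism=doc["organism"],
            species=species,
            reactions=reactions,
            moieties=moieties,
            temperature_label=doc.get("temperature_C"),
            name=doc.get("name", ""),
        )
    except (KeyError, TypeError, ValueError) as err:
        raise ConfigurationError(f"malformed model document: {err}") from err
    return model.validate()


def load_shipped_model(name: str) -> PathwayModel:
    """Load one of the model configs shipped with the package.

    ``name`` is e.g. ``sulfolobus_with_gapn`` (see ``thermoglyc/configs``).
    """
    ref = resources.files("thermoglyc") / "configs" / f"{name}.yaml"
    if not ref.is_file():
        available = sorted(
            p.name.removesuffix(".yaml")
            for p in (resources.files("thermoglyc") / "configs").iterdir())
        raise ConfigurationError(
            f"no shipped model {name!r}; available: {available}")
    return load_model(ref.read_text())


def apply_overrides(model: PathwayModel, overrides: dict) -> PathwayModel:
    """Apply dotted-path overrides, e.g. ``reactions.GAPDH.Vm: 66000``.

    Supported paths: ``reactions.<name>.<symbol>`` for rate-law parameters
    and ``species.<name>.concentration`` for boundary concentrations.
    """
    for path, value in overrides.items():
        parts = path.split(".")
        if len(parts) != 3:
            raise ConfigurationError(
                f"override path {path!r} must have three dot-separated "
                "components")
        kind, name, attr = parts
        if kind == "reactions":
            model = model.with_parameter(name, attr, float(value))
        elif kind == "species" and attr == "concentration":
            model = model.with_boundary(name, float(value))
        else:
            raise ConfigurationError(
                f"override path {path!r} not recognised; use "
                "reactions.<name>.<param> or species.<name>.concentration")
    return model


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def write_csv(frame, path) -> Path:
    """Write a DataFrame with fixed float formatting (stable diffs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, float_format=FLOAT_FORMAT)
    return path


def write_json(payload, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")
    return path


def _json_default(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def provenance_record(config: RunConfig | None, seed: int) -> dict:
    return {
        "package": "thermoglyc",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash(config) if config else None,
    }
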