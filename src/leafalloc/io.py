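"""Tabular readers/writers, structured configs and run manifests.

Delimited tables are comma-separated UTF-8 with one header row; numeric
columns carry their units in the column name. Observation tables prepend
``#``-prefixed metadata lines declaring the kinetic convention. Config
files are YAML with ``traits:`` and ``environment:`` sections; packaged
fixtures reproduce the built-in trait/environment tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .calibration import ObservationSet
from .kinetics import COLLATZ, KineticConstants
from .photosynthesis import Environment
from .traits import PlantTraits

__all__ = [
    "ConfigError",
    "read_observation_table",
    "write_observation_table",
    "read_trait_env_config",
    "load_fixture_config",
    "list_fixtures",
    "read_pft_table",
    "RunManifest",
    "write_manifest",
]

#: Named kinetic conventions an observation table may declare.
KINETIC_CONVENTIONS: dict[str, KineticConstants] = {"collatz91": COLLATZ}

_OBS_COLUMNS = {
    "leaf_n_g_per_g": "leaf_n",
    "vcmax25_umol_m2_s": "vcmax25",
    "jmax25_umol_m2_s": "jmax25",
    "measurement_t_c": "measurement_t",
}
_OBS_REQUIRED = ("leaf_n_g_per_g", "vcmax25_umol_m2_s")


class ConfigError(ValueError):
    """A configuration or table failed validation; lists every problem."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def write_observation_table(obs: ObservationSet, path) -> None:
    """Write an observation set as CSV with unit-bearing headers and a
    kinetic-convention metadata line."""
    convention = next(
        (k for k, v in KINETIC_CONVENTIONS.items() if v == obs.kinetics), None
    )
    if convention is None:
        raise ValueError("observation set uses an unnamed kinetic convention")
    inverse = {v: k for k, v in _OBS_COLUMNS.items()}
    table = obs.table.rename(columns=inverse)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kinetic_convention: {convention}\n")
        table.to_csv(fh, index=False, lineterminator="\n")


def read_observation_table(
    path, traits: PlantTraits | None = None, env: Environment | None = None
) -> ObservationSet:
    """Read a delimited observation table into an :class:`ObservationSet`.

    The header must name the units (``leaf_n_g_per_g``,
    ``vcmax25_umol_m2_s``) and a ``# kinetic_convention:`` line must
    declare a known convention. Problems are reported all at once.
    """
    problems: list[str] = []
    convention = None
    with open(path, "r", encoding="utf-8") as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
            else:
                break
    for line in header_lines:
        if line.startswith("kinetic_convention:"):
            convention = line.split(":", 1)[1].strip()
    if convention is None:
        problems.append("missing '# kinetic_convention:' metadata line")
    elif convention not in KINETIC_CONVENTIONS:
        problems.append(
            f"unknown kinetic convention {convention!r}; supported: "
            f"{sorted(KINETIC_CONVENTIONS)}"
        )

    table = pd.read_csv(path, comment="#")
    for col in _OBS_REQUIRED:
        if col not in table.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise ConfigError(problems)

    table = table.rename(columns=_OBS_COLUMNS)
    table = table[[c for c in _OBS_COLUMNS.values() if c in table.columns]]
    if (table["leaf_n"] <= 0).any():
        problems.append("leaf_n_g_per_g must be strictly positive in every row")
    if problems:
        raise ConfigError(problems)
    return ObservationSet(
        table=table, traits=traits, env=env,
        kinetics=KINETIC_CONVENTIONS[convention],
    )


_TRAIT_KEYS = {
    "lma", "leaf_n", "fnc_m", "f_s", "f_r", "d_ns", "f_cleaf",
    "structural_n", "nonleaf_n_ratio", "carbon_frac",
}
_ENV_KEYS = {
    "par", "co2_ppm", "day_temp", "night_temp", "rh", "day_hours", "ci_ratio",
}


def _build_section(cls, raw: dict, allowed: set[str], section: str, problems: list):
    unknown = set(raw) - allowed
    for key in sorted(unknown):
        problems.append(f"{section}: unknown key {key!r}")
    kwargs = {k: v for k, v in raw.items() if k in allowed}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        problems.append(f"{section}: {exc}")
        return None


def read_trait_env_config(path) -> tuple[PlantTraits, Environment]:
    """Read a YAML config with ``traits:`` and ``environment:`` sections."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _parse_trait_env(raw, str(path))


def _parse_trait_env(raw, source: str) -> tuple[PlantTraits, Environment]:
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError([f"{source}: config must be a mapping"])
    for section in ("traits", "environment"):
        if section not in raw:
            problems.append(f"{source}: missing {section!r} section")
    if problems:
        raise ConfigError(problems)
    traits = _build_section(
        PlantTraits, raw["traits"], _TRAIT_KEYS, "traits", problems
    )
    env = _build_section(
        Environment, raw["environment"], _ENV_KEYS, "environment", problems
    )
    if problems:
        raise ConfigError(problems)
    return traits, env


def list_fixtures() -> list[str]:
    """Names of the packaged trait/environment fixture configs."""
    pkg = resources.files("leafalloc") / "data"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir()
                  if p.name.endswith(".yaml"))


def load_fixture_config(name: str) -> tuple[PlantTraits, Environment]:
    """Load a packaged fixture (e.g. ``table3_herbaceous``) by name."""
    pkg = resources.files("leafalloc") / "data" / f"{name}.yaml"
    try:
        text = pkg.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise KeyError(
            f"no packaged fixture {name!r}; available: {list_fixtures()}"
        ) from None
    return _parse_trait_env(yaml.safe_load(text), f"fixture {name}")


def read_pft_table(path) -> dict[str, PlantTraits]:
    """Read a CSV of trait rows (one per plant functional type).

    Requires a ``name`` column; remaining columns are :class:`PlantTraits`
    fields.
    """
    table = pd.read_csv(path, comment="#")
    problems: list[str] = []
    if "name" not in table.columns:
        raise ConfigError(["pft table: missing required column 'name'"])
    unknown = set(table.columns) - _TRAIT_KEYS - {"name"}
    for key in sorted(unknown):
        problems.append(f"pft table: unknown column {key!r}")
    if problems:
        raise ConfigError(problems)
    out: dict[str, PlantTraits] = {}
    for _, row in table.iterrows():
        kwargs = {
            k: float(v) for k, v in row.items()
            if k != "name" and pd.notna(v)
        }
        try:
            out[str(row["name"])] = PlantTraits(**kwargs)
        except (TypeError, ValueError) as exc:
            problems.append(f"pft table row {row['name']!r}: {exc}")
    if problems:
        raise ConfigError(problems)
    return out


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record sufficient to re-execute a deterministic command."""

    command: str
    config: dict
    package_version: str
    seed: int | None
    timestamp_utc: str
    input_digests: dict[str, str]


def write_manifest(
    path,
    command: str,
    config: dict,
    seed: int | None = None,
    inputs: list | None = None,
) -> RunManifest:
    """Write a JSON run manifest next to a command's outputs."""
    from . import __version__

    manifest = RunManifest(
        command=command,
        config=config,
        package_version=__version__,
        seed=seed,
        timestamp_utc=datetime.now(timezone.utc).isoformat(),
        input_digests={
            str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
    )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
        fh.write("\n")
    return manifest
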