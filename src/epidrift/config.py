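"""Scenario configuration: presets, validation, echoing, hashing.

A run is fully described by a :class:`ScenarioSpec`: the preset (which
aging scenario), the genome recipe, parameter overrides, run length and
seed.  ``load_config`` validates a YAML/JSON file exhaustively (all errors
reported at once) and resolves it against the preset defaults; the fully
resolved parameter set is echoed alongside every run for provenance.

Presets
-------
``no-arp-isolated``
    Age-independent phenotype, no exchange between niche and omega
    (P_alpha = P_omega = 0): the niche is an isolated, quiescent control.
``no-arp-exchange``
    Age-independent phenotype with exchange on: neutral clonal
    competition extends to both environments (clone number decays ~1/t).
``low-differentiation``
    Aged cells differentiate at q0 / 3: a dominant, positively selected
    age-related phenotype.
``low-proliferation``
    Aged cells proliferate at 4/5 R: a recessive phenotype that coexists
    with young cells for long times.
``hsc``
    The hematopoietic stem-cell scenario: aged cells have 4.0-fold niche
    inflow and 0.25-fold niche exit, so they accumulate in the niche and
    push young cells out.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cells import ARPDefinition
from .genome import Genome, generate_genome, make_fixture_genome, read_genome
from .population import EnvironmentParams, Trajectory, run_scenario
from .regulation import RegulationParams

__all__ = [
    "PRESETS",
    "DEFAULT_GENOME_NH",
    "DEFAULT_MARKERS",
    "ScenarioSpec",
    "ConfigError",
    "load_config",
    "default_genome",
    "run_from_spec",
]

#: nucleosome counts of the default (fixture) simulation genome; spans all
#: gene classes: C3 (0), C2 (2-6) and C1/C1a (8).
DEFAULT_GENOME_NH = (0, 0, 2, 4, 4, 6, 8, 8, 8, 8)
#: the three bistable genes whose mean expression defines the ARP
DEFAULT_MARKERS = (7, 8, 9)

PRESETS: dict[str, dict] = {
    "no-arp-isolated": {
        "arp": {"enabled": False},
        "env": {"rho_alpha": 0.0, "rho_omega": 0.0},
    },
    "no-arp-exchange": {
        "arp": {"enabled": False},
    },
    "low-differentiation": {
        "arp": {"enabled": True, "q0_mult": 1.0 / 3.0},
    },
    "low-proliferation": {
        "arp": {"enabled": True, "r_mult": 0.8},
    },
    "hsc": {
        "arp": {"enabled": True, "rho_omega_mult": 4.0, "rho_alpha_mult": 0.25},
    },
}


class ConfigError(ValueError):
    """Invalid configuration; the message lists every problem found."""


@dataclass
class ScenarioSpec:
    """A fully resolved scenario description."""

    preset: str = "no-arp-exchange"
    seed: int = 0
    steps: int = 6000
    burn_in: int = 0
    record_every: int = 50
    n_initial: tuple[int, int] = (10, 10)
    n_clones: int | None = None
    force_phenotype: str | None = None
    genome: dict = field(default_factory=lambda: {"kind": "fixture"})
    params: dict = field(default_factory=dict)
    env: dict = field(default_factory=dict)
    arp: dict = field(default_factory=dict)

    def resolved(self) -> "ScenarioSpec":
        """Merge preset defaults under the user's explicit overrides."""
        preset = PRESETS[self.preset]
        merged_env = {**preset.get("env", {}), **self.env}
        merged_arp = {**{"enabled": True}, **preset.get("arp", {}), **self.arp}
        return dataclasses.replace(self, env=merged_env, arp=merged_arp)

    # -- builders ----------------------------------------------------------

    def build_genome(self) -> Genome:
        g = dict(self.genome)
        kind = g.pop("kind", "fixture")
        if kind == "fixture":
            return make_fixture_genome(
                n_h=list(g.get("n_h", DEFAULT_GENOME_NH)),
                n_cpg=g.get("n_cpg"),
                seed=int(g.get("seed", 0)),
            )
        if kind == "random":
            return generate_genome(
                length=int(g.get("length", 400_000)),
                promoter_motif=g.get("promoter_motif", "010101"),
                seed=int(g.get("seed", 0)),
            )
        if kind == "files":
            return read_genome(g["fasta"], g["gff"])
        raise ConfigError(f"unknown genome kind {kind!r}")

    def build_params(self) -> RegulationParams:
        return RegulationParams(**self.params)

    def build_env(self) -> EnvironmentParams:
        return EnvironmentParams(**self.env)

    def build_arp(self) -> ARPDefinition | None:
        a = dict(self.arp)
        if not a.pop("enabled", True):
            return None
        markers = tuple(a.pop("marker_gene_ids", DEFAULT_MARKERS))
        return ARPDefinition(marker_gene_ids=markers, **a)

    # -- provenance --------------------------------------------------------

    def echo(self) -> dict:
        """The fully resolved configuration, defaults included."""
        spec = self.resolved()
        out = dataclasses.asdict(spec)
        out["params"] = dataclasses.asdict(spec.build_params())
        out["env"] = dataclasses.asdict(spec.build_env())
        arp = spec.build_arp()
        out["arp"] = (
            {"enabled": False} if arp is None
            else {"enabled": True, **dataclasses.asdict(arp)}
        )
        out["update_order"] = (
            "step_cells,evaluate_phenotype,alpha_exits,omega_entries,"
            "divisions,differentiation"
        )
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.echo(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_KNOWN_KEYS = {f.name for f in dataclasses.fields(ScenarioSpec)}

_PARAM_RANGES = {
    "d_main": (0.0, 1.0),
    "d_novo0": (0.0, 1.0),
    "k_m": (0.0, 1.0),
    "k_d": (0.0, 1.0),
    "delta": (0.0, None),
    "p_max": (0.0, None),
}


def _validate_raw(raw: dict) -> list[str]:
    errors = []
    if not isinstance(raw, dict):
        return ["configuration root must be a mapping"]
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown key {key!r}")
    preset = raw.get("preset", "no-arp-exchange")
    if preset not in PRESETS:
        errors.append(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    for key in ("steps", "burn_in", "record_every", "seed"):
        if key in raw and (not isinstance(raw[key], int) or raw[key] < 0):
            errors.append(f"{key} must be a non-negative integer")
    fp = raw.get("force_phenotype")
    if fp not in (None, "young", "aged"):
        errors.append("force_phenotype must be null, 'young' or 'aged'")
    for name, value in (raw.get("params") or {}).items():
        lo_hi = _PARAM_RANGES.get(name)
        if lo_hi is None:
            continue
        lo, hi = lo_hi
        if (lo is not None and value < lo) or (hi is not None and value > hi):
            bound = f">= {lo}" if hi is None else f"in [{lo}, {hi}]"
            errors.append(f"params.{name} = {value} out of range (must be {bound})")
    for name, value in (raw.get("env") or {}).items():
        if isinstance(value, (int, float)) and value < 0:
            errors.append(f"env.{name} must be non-negative")
    return errors


def load_config(path: str | Path) -> ScenarioSpec:
    """Load + validate a YAML/JSON scenario config.

    Every problem found is reported in a single :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    errors = _validate_raw(raw)
    if errors:
        raise ConfigError("; ".join(errors))
    if "n_initial" in raw:
        raw["n_initial"] = tuple(raw["n_initial"])
    spec = ScenarioSpec(**raw).resolved()
    try:  # constructor-level range checks (reported together)
        spec.build_params()
        spec.build_env()
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return spec


def default_genome(seed: int = 0) -> Genome:
    """The default fixture genome used by all presets."""
    return make_fixture_genome(n_h=list(DEFAULT_GENOME_NH), seed=seed)


def run_from_spec(spec: ScenarioSpec, seed: int | None = None) -> Trajectory:
    """Build everything a spec describes and execute the scenario."""
    spec = spec.resolved()
    genome = spec.build_genome()
    return run_scenario(
        genome,
        spec.build_params(),
        spec.build_env(),
        spec.build_arp(),
        steps=spec.steps,
        burn_in=spec.burn_in,
        record_every=spec.record_every,
        seed=spec.seed if seed is None else seed,
        n_initial=tuple(spec.n_initial),
        n_clones=spec.n_clones,
        force_phenotype=spec.force_phenotype,
        config_echo=spec.echo(),
    )
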