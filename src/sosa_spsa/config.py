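"""Run configuration: JSON loading, validation and the bundled fixture.

A run configuration is a JSON document with a ``schema_version`` field.
Unknown keys are rejected rather than ignored, and validation failures are
enumerated in full instead of being silently corrected.

The package ships ``hill2010_fhs.json``: the ten contagion rates estimated
by Hill et al. (2010) from the Framingham Heart Study social network,
together with the near-uniform initial split O=626, P=626, S=628 of a
population of N=1880.  This is the reference scenario for the modified
model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .model import (
    RATE_NAMES,
    ModelParameters,
    PopulationState,
    validate_parameters,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "ConfigParseError",
    "ConfigValidationError",
    "load_config",
    "save_config",
    "fixture_path",
    "load_fhs_config",
]

SCHEMA_VERSION = 1
MODELS = ("sisa", "sosa_spsa", "modified")
DEFAULT_T_END = 2000.0
DEFAULT_N_POINTS = 400

_TOP_KEYS = {
    "schema_version", "model", "params", "initial", "N",
    "t_end", "n_points", "seed", "output_path",
}
_PARAM_KEYS = set(RATE_NAMES) | {"contact_scaling"}
_SISA_PARAM_KEYS = {"alpha", "beta", "g", "contact_scaling"}


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigParseError(ConfigError):
    """The file is not valid JSON."""


class ConfigValidationError(ConfigError):
    """The document parsed but violates the schema; lists every problem."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid run configuration:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class RunConfig:
    """A fully validated simulation run description."""

    model: str                      # "sisa" | "sosa_spsa" | "modified"
    params: ModelParameters
    initial: PopulationState
    N: float
    t_end: float = DEFAULT_T_END
    n_points: int = DEFAULT_N_POINTS
    seed: int | None = None
    output_path: str | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "schema_version": SCHEMA_VERSION,
            "model": self.model,
            "params": dataclasses.asdict(self.params),
            "initial": {"S": self.initial.S, "O": self.initial.O, "P": self.initial.P},
            "N": self.N,
            "t_end": self.t_end,
            "n_points": self.n_points,
        }
        if self.seed is not None:
            d["seed"] = self.seed
        if self.output_path is not None:
            d["output_path"] = self.output_path
        return d


def _build(doc: dict) -> RunConfig:
    problems: list[str] = []
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level keys: {sorted(unknown)}")
    if doc.get("schema_version") != SCHEMA_VERSION:
        problems.append(
            f"schema_version must be {SCHEMA_VERSION}, got {doc.get('schema_version')!r}"
        )
    model = doc.get("model", "modified")
    if model not in MODELS:
        problems.append(f"model must be one of {MODELS}, got {model!r}")

    raw_params = doc.get("params")
    params: ModelParameters | None = None
    if not isinstance(raw_params, dict):
        problems.append("params must be a mapping of rate names to numbers")
    elif model == "sisa":
        # one alpha/beta/g triple, carried on the O channel; P channel inert
        unknown_p = set(raw_params) - _SISA_PARAM_KEYS
        missing = {"alpha", "beta", "g"} - set(raw_params)
        if unknown_p:
            problems.append(f"sisa params accept only alpha/beta/g: unknown {sorted(unknown_p)}")
        if missing:
            problems.append(f"sisa params missing {sorted(missing)}")
        if not unknown_p and not missing:
            params = ModelParameters(
                alpha_O=raw_params["alpha"], beta_O=raw_params["beta"], g_O=raw_params["g"],
                alpha_P=0.0, beta_P=0.0, g_P=0.0,
                contact_scaling=raw_params.get("contact_scaling", "frequency"),
            )
    else:
        unknown_p = set(raw_params) - _PARAM_KEYS
        missing = {"alpha_O", "beta_O", "g_O", "alpha_P", "beta_P", "g_P"} - set(raw_params)
        if unknown_p:
            problems.append(f"unknown parameter keys: {sorted(unknown_p)}")
        if missing:
            problems.append(f"params missing required rates {sorted(missing)}")
        if not unknown_p and not missing:
            params = ModelParameters(**raw_params)
            if model == "sosa_spsa":
                nonzero = [
                    k for k in ("l1", "l2", "m1", "m2") if getattr(params, k) != 0
                ]
                if nonzero:
                    problems.append(
                        "model 'sosa_spsa' has no optimist-pessimist interaction: "
                        f"nonzero {nonzero}"
                    )
    if params is not None:
        problems.extend(validate_parameters(params).violations)

    raw_initial = doc.get("initial")
    initial: PopulationState | None = None
    if not isinstance(raw_initial, dict):
        problems.append("initial must be a mapping with S, O, P (or S, I for sisa)")
    else:
        keys = set(raw_initial)
        if model == "sisa" and keys == {"S", "I"}:
            initial = PopulationState(S=raw_initial["S"], O=raw_initial["I"], P=0.0)
        elif keys == {"S", "O", "P"}:
            initial = PopulationState(**raw_initial)
        else:
            problems.append(f"initial must have keys S, O, P (or S, I for sisa), got {sorted(keys)}")
        if initial is not None and min(initial.S, initial.O, initial.P) < 0:
            problems.append(f"negative initial compartment: {raw_initial}")

    N = doc.get("N")
    if not isinstance(N, (int, float)) or N <= 0:
        problems.append(f"N must be a positive number, got {N!r}")
    elif initial is not None and abs(initial.total - N) > 1e-9 * N:
        problems.append(f"initial state sums to {initial.total}, which breaks S+O+P = N = {N}")

    t_end = doc.get("t_end", DEFAULT_T_END)
    n_points = doc.get("n_points", DEFAULT_N_POINTS)
    if not isinstance(t_end, (int, float)) or t_end <= 0:
        problems.append(f"t_end must be positive, got {t_end!r}")
    if not isinstance(n_points, int) or n_points < 2:
        problems.append(f"n_points must be an integer >= 2, got {n_points!r}")
    seed = doc.get("seed")
    if seed is not None and not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")

    if problems:
        raise ConfigValidationError(problems)
    assert params is not None and initial is not None
    return RunConfig(
        model=model, params=params, initial=initial, N=float(N),
        t_end=float(t_end), n_points=n_points, seed=seed,
        output_path=doc.get("output_path"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration from a JSON file.

    A bare file name that does not exist on disk is also looked up among
    the bundled fixtures, so ``load_config("hill2010_fhs.json")`` works
    from anywhere.
    """
    p = Path(path)
    if not p.exists():
        candidate = fixture_path(p.name) if p.name == str(path) else None
        if candidate is None or not candidate.exists():
            raise FileNotFoundError(f"no such config file: {path}")
        p = candidate
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigParseError(f"{p}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigValidationError([f"{p}: top level must be a JSON object"])
    return _build(doc)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to JSON (round-trips through load)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def fixture_path(name: str = "hill2010_fhs.json") -> Path:
    """Filesystem path of a bundled fixture config."""
    return Path(str(resources.files("sosa_spsa").joinpath("data", name)))


def load_fhs_config() -> RunConfig:
    """The bundled Framingham-rates reference scenario."""
    return load_config(fixture_path())
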