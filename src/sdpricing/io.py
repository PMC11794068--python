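"""Serialization: JSON model files, tidy CSV writers, run configurations.

The model dialect is a versioned JSON document with one record per variable
(``name``, ``kind`` and the kind's fields) and one record per term
(``coefficient``, ``kind`` and the kind's fields). Files are written with
sorted keys and shortest round-trip float formatting, so writing is
deterministic and ``read_model(write_model(spec))`` reproduces ``spec``
exactly. Unknown fields or kinds are rejected with a diagnostic naming the
offending path.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .core import Delay1Spec, ModelError, ModelSpec, SimConfig, Term, Trajectory, VariableSpec

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "RunConfig",
    "read_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
    "load_builtin_model",
    "write_trajectory",
    "read_run_config",
]

SCHEMA_VERSION = "1"


class SchemaError(ModelError):
    """A model file does not conform to the dialect."""


# ---------------------------------------------------------------------------
# model <-> dict


def _term_to_dict(t: Term) -> dict[str, Any]:
    d: dict[str, Any] = {"coefficient": t.coefficient, "kind": t.kind}
    if t.kind == "literal":
        d["literal"] = t.literal_value
    elif t.kind == "ref":
        d["source"] = t.source
    else:
        d["source"] = t.source
        d["delay_time"] = t.delay.delay_time
        d["init_policy"] = t.delay.init_policy
        if t.delay.init_value is not None:
            d["init_value"] = t.delay.init_value
    return d


def _variable_to_dict(v: VariableSpec) -> dict[str, Any]:
    d: dict[str, Any] = {"name": v.name, "kind": v.kind}
    if v.kind == "constant":
        d["value"] = v.value
    elif v.kind == "auxiliary":
        d["terms"] = [_term_to_dict(t) for t in v.terms]
    else:
        d["inflow"] = v.inflow
        d["initial"] = v.initial
    return d


def model_to_dict(spec: ModelSpec) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "metadata": dict(spec.metadata),
        "variables": [_variable_to_dict(v) for v in spec.variables],
    }


_TERM_FIELDS = {
    "literal": {"coefficient", "kind", "literal"},
    "ref": {"coefficient", "kind", "source"},
    "delay1": {"coefficient", "kind", "source", "delay_time", "init_policy", "init_value"},
}
_VAR_FIELDS = {
    "constant": {"name", "kind", "value"},
    "auxiliary": {"name", "kind", "terms"},
    "stock": {"name", "kind", "inflow", "initial"},
}


def _check_fields(record: dict, allowed: set[str], required: set[str], path: str) -> None:
    unknown = set(record) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown field(s) {sorted(unknown)}")
    missing = required - set(record)
    if missing:
        raise SchemaError(f"{path}: missing field(s) {sorted(missing)}")


def _term_from_dict(d: Any, path: str) -> Term:
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: term must be an object")
    kind = d.get("kind")
    if kind not in _TERM_FIELDS:
        raise SchemaError(f"{path}: unknown term kind {kind!r}")
    required = {"coefficient", "kind"} | ({"literal"} if kind == "literal" else {"source"})
    if kind == "delay1":
        required |= {"delay_time"}
    _check_fields(d, _TERM_FIELDS[kind], required, path)
    try:
        if kind == "literal":
            return Term.lit(d["literal"], d["coefficient"])
        if kind == "ref":
            return Term.ref(d["source"], d["coefficient"])
        return Term.delay1(
            d["source"],
            d["delay_time"],
            d["coefficient"],
            init_policy=d.get("init_policy", "auto"),
            init_value=d.get("init_value"),
        )
    except ModelError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def _variable_from_dict(d: Any, path: str) -> VariableSpec:
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: variable must be an object")
    name = d.get("name", "<unnamed>")
    kind = d.get("kind")
    if kind not in _VAR_FIELDS:
        raise SchemaError(f"{path} ({name!r}): unknown variable kind {kind!r}")
    _check_fields(d, _VAR_FIELDS[kind], _VAR_FIELDS[kind], f"{path} ({name!r})")
    try:
        if kind == "constant":
            return VariableSpec.constant(name, d["value"])
        if kind == "auxiliary":
            terms = d["terms"]
            if not isinstance(terms, list):
                raise SchemaError(f"{path} ({name!r}).terms: must be a list")
            return VariableSpec.auxiliary(
                name,
                [_term_from_dict(t, f"{path} ({name!r}).terms[{i}]") for i, t in enumerate(terms)],
            )
        return VariableSpec.stock(name, d["inflow"], d["initial"])
    except ModelError as exc:
        raise SchemaError(f"{path} ({name!r}): {exc}") from exc


def model_from_dict(doc: Any) -> ModelSpec:
    if not isinstance(doc, dict):
        raise SchemaError("$: document must be an object")
    _check_fields(doc, {"schema_version", "metadata", "variables"}, {"schema_version", "variables"}, "$")
    version = doc["schema_version"]
    if version != SCHEMA_VERSION:
        raise SchemaError(f"$.schema_version: unsupported version {version!r} (expected {SCHEMA_VERSION!r})")
    variables = doc["variables"]
    if not isinstance(variables, list):
        raise SchemaError("$.variables: must be a list")
    return ModelSpec(
        variables=[_variable_from_dict(v, f"$.variables[{i}]") for i, v in enumerate(variables)],
        metadata=dict(doc.get("metadata") or {}),
    )


# ---------------------------------------------------------------------------
# files


def write_model(spec: ModelSpec, path: str | Path) -> None:
    """Write a model file; output is deterministic (sorted keys, shortest
    round-trip float formatting, trailing newline)."""
    text = json.dumps(model_to_dict(spec), indent=2, sort_keys=True)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_model(path: str | Path) -> ModelSpec:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    return model_from_dict(doc)


def load_builtin_model(name: str = "japan") -> ModelSpec:
    """Load a bundled model by name (currently only "japan")."""
    resource = importlib.resources.files("sdpricing.data").joinpath(f"{name}_model.json")
    if not resource.is_file():
        raise SchemaError(f"no builtin model named {name!r}")
    return model_from_dict(json.loads(resource.read_text(encoding="utf-8")))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a tidy CSV: columns ``time,variable,value``, time-major with
    variables in declaration order; byte-identical across re-runs."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["time", "variable", "value"])
        names = list(traj.series)
        for i, t in enumerate(traj.times):
            for name in names:
                writer.writerow([repr(float(t)), name, repr(float(traj.series[name][i]))])


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated settings for a full experiment run."""

    simulation: SimConfig
    step_sizes: list[float]
    parameters: list[str]
    scale: float
    delay_init: str | None
    output_dir: Path
    seed: int | None

    @staticmethod
    def from_dict(doc: dict[str, Any]) -> "RunConfig":
        allowed = {
            "t_start", "t_end", "dt", "save_every", "step_sizes",
            "parameters", "scale", "delay_init", "output_dir", "seed",
        }
        unknown = set(doc) - allowed
        if unknown:
            raise SchemaError(f"run config: unknown field(s) {sorted(unknown)}")
        sim = SimConfig(
            t_start=float(doc.get("t_start", 0.0)),
            t_end=float(doc.get("t_end", 50.0)),
            dt=float(doc.get("dt", 1.0)),
            save_every=int(doc.get("save_every", 1)),
        )
        delay_init = doc.get("delay_init")
        if delay_init not in (None, "zero", "equilibrium"):
            raise SchemaError(f"run config: delay_init must be null, 'zero' or 'equilibrium', got {delay_init!r}")
        scale = float(doc.get("scale", 1.8))
        if not scale > 0:
            raise SchemaError("run config: scale must be positive")
        return RunConfig(
            simulation=sim,
            step_sizes=[float(x) for x in doc.get("step_sizes", [1.0, 0.5, 0.125])],
            parameters=[str(p) for p in doc.get("parameters", [])],
            scale=scale,
            delay_init=delay_init,
            output_dir=Path(doc.get("output_dir", ".")),
            seed=None if doc.get("seed") is None else int(doc["seed"]),
        )


def read_run_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration; all settings are validated
    before any run starts."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if doc is None:
        doc = {}
    return RunConfig.from_dict(doc)
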