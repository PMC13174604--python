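"""Run configuration: YAML/JSON parsing, validation, defaults.

Defaults mirror the analysis as the assay ran it: input filter at 10 counts,
IP pseudocount 1e-6, assignment budget of 2 mismatches, exact adapter matching
for merged reads and a 7% adapter error rate for pairs, CrPV as the activity
threshold and ``control`` as the normalization reference.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

_PATH = (str, type(None))

# schema: leaf -> (allowed types, default); nested dict -> sub-schema
_SCHEMA = {
    "reference_fasta": (_PATH, None),
    "sample_sheet": (_PATH, None),
    "structure_file": (_PATH, None),
    "design_manifest": (_PATH, None),
    "outdir": (str, "results"),
    "seed": (int, 1),
    "parameters": {
        "min_input": (int, 10),
        "pseudocount": (float, 1e-6),
        "max_mismatches": (int, 2),
        "min_overlap": (int, 10),
        "max_mismatch_rate": (float, 0.1),
        "error_rate_single": (float, 0.0),
        "error_rate_paired": (float, 0.07),
        "threshold_construct": (str, "CrPV"),
        "reference_condition": (str, "control"),
    },
    "simulate": {
        "n_constructs": (int, 50),
        "utr_length": (int, 150),
        "n_reads": (int, 50000),
        "epsilon": (float, 0.001),
        "te_log2_range": (list, [-5.0, 5.0]),
        "duplication_mean": (float, 1.5),
        "abundance_sigma": (float, 1.0),
        "spike_ratio": (list, [0.01, 0.1, 1.0]),
        "spike_fraction": (float, 0.01),
        "n_bio_rep": (int, 1),
        "n_tech_rep": (int, 1),
        "conditions": (dict, {"control": {}}),
    },
}


class ConfigError(ValueError):
    """Validation failure with a path-addressed message."""


def _validate(data: dict, schema: dict, path: str) -> dict:
    out = {}
    unknown = set(data) - set(schema)
    if unknown:
        raise ConfigError(f"unknown key(s) at {path or 'top level'}: {sorted(unknown)}")
    for key, spec in schema.items():
        loc = f"{path}.{key}" if path else key
        if isinstance(spec, dict):
            sub = data.get(key, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"{loc} must be a mapping, got {type(sub).__name__}")
            out[key] = _validate(sub, spec, loc)
            continue
        types, default = spec
        if key not in data or data[key] is None:
            out[key] = copy.deepcopy(default)
            continue
        val = data[key]
        if float in (types if isinstance(types, tuple) else (types,)) and isinstance(
            val, int
        ) and not isinstance(val, bool):
            val = float(val)
        ok_types = types if isinstance(types, tuple) else (types,)
        if not isinstance(val, ok_types) or isinstance(val, bool) and bool not in ok_types:
            want = "/".join(t.__name__ for t in ok_types if t is not type(None))
            raise ConfigError(f"type error at {loc}: expected {want}, got {val!r}")
        out[key] = val
    return out


def _check_semantics(cfg: dict) -> None:
    p = cfg["parameters"]
    if p["pseudocount"] <= 0:
        raise ConfigError("parameters.pseudocount must be > 0")
    if p["min_input"] < 0:
        raise ConfigError("parameters.min_input must be >= 0")
    if not 0 <= p["max_mismatch_rate"] <= 1:
        raise ConfigError("parameters.max_mismatch_rate must be in [0, 1]")
    s = cfg["simulate"]
    if len(s["te_log2_range"]) != 2:
        raise ConfigError("simulate.te_log2_range must be [low, high]")
    if len(s["spike_ratio"]) != 3:
        raise ConfigError("simulate.spike_ratio must have three entries")
    if not 0 <= s["epsilon"] <= 0.1:
        raise ConfigError("simulate.epsilon must be in [0, 0.1]")


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted run configuration."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]

    @property
    def parameters(self) -> dict:
        return self.data["parameters"]

    @property
    def simulate(self) -> dict:
        return self.data["simulate"]

    @property
    def outdir(self) -> Path:
        return Path(self.data["outdir"])

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)


def validate_config(source) -> RunConfig:
    """Validate a config mapping, YAML/JSON path or text; fill defaults.

    Unknown keys are rejected and type errors name the offending key path
    (e.g. ``parameters.min_input``). An empty config is valid and yields all
    defaults.
    """
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    cfg = _validate(raw, _SCHEMA, "")
    _check_semantics(cfg)
    return RunConfig(cfg)
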