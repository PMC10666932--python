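"""Plain-text run configuration (INI ``key = value`` sections).

Unknown sections or keys are errors; the resolved configuration (with every
default filled in) can be echoed back and hashed, so a run is reproducible
from its logged config.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json

from .synthetic import CohortSpec


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad value, bad combination)."""


_DEFAULTS = {
    "run": {"seed": 0, "log_level": "INFO", "jobs": 1},
    "paths": {"container": "cohort.h5", "report_prefix": "report"},
    "alignment": {
        "method": "cha",
        "steps": 3,
        "alignment_radius_mm": 15.0,
        "source_movie": "A",
        "target_movie": "A",
    },
    "predict": {"mode": "timeseries", "categories": "", "baseline_aa": True},
    "evaluate": {"searchlight_radius_mm": 15.0},
}

_COHORT_FIELDS = {f.name: f for f in dataclasses.fields(CohortSpec)}


def _coerce(value: str, like):
    if isinstance(like, bool):
        if str(value).lower() in ("1", "true", "yes", "on"):
            return True
        if str(value).lower() in ("0", "false", "no", "off"):
            return False
        raise ConfigError(f"expected a boolean, got {value!r}")
    if isinstance(like, int):
        return int(value)
    if isinstance(like, float):
        return float(value)
    if isinstance(like, tuple):
        return tuple(v.strip() for v in str(value).split(",") if v.strip())
    return str(value)


@dataclasses.dataclass
class RunConfig:
    """Fully resolved configuration for a pipeline run."""

    run: dict
    paths: dict
    alignment: dict
    predict: dict
    evaluate: dict
    cohort: CohortSpec

    def resolved(self) -> dict:
        d = {
            "run": self.run,
            "paths": self.paths,
            "alignment": self.alignment,
            "predict": self.predict,
            "evaluate": self.evaluate,
            "cohort": dataclasses.asdict(self.cohort),
        }
        d["cohort"]["categories"] = list(d["cohort"]["categories"])
        d["cohort"]["movie_ids"] = list(d["cohort"]["movie_ids"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate(self) -> None:
        if self.alignment["method"] not in ("cha", "rha", "aa"):
            raise ConfigError(f"unknown alignment method {self.alignment['method']!r}")
        if self.predict["mode"] not in ("timeseries", "contrast_map"):
            raise ConfigError(f"unknown prediction mode {self.predict['mode']!r}")
        if self.alignment["method"] == "rha" and (
            self.alignment["source_movie"] != self.alignment["target_movie"]
        ):
            raise ConfigError(
                "RHA requires the same stimulus for all subjects (response "
                "patterns are matched timepoint by timepoint); cross-movie "
                "alignment needs method = cha"
            )


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Parse an INI config file; every key must belong to a known section."""
    sections = {k: dict(v) for k, v in _DEFAULTS.items()}
    cohort_kwargs: dict = {}
    if path is not None:
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise ConfigError(f"config file {path} not found or unreadable")
        for section in parser.sections():
            if section == "cohort":
                for key, value in parser.items(section):
                    if key not in _COHORT_FIELDS:
                        raise ConfigError(f"unknown cohort key {key!r}")
                    fld = _COHORT_FIELDS[key]
                    default = fld.default
                    cohort_kwargs[key] = _coerce(value, default)
                continue
            if section not in sections:
                raise ConfigError(f"unknown config section [{section}]")
            for key, value in parser.items(section):
                if key not in sections[section]:
                    raise ConfigError(f"unknown key {key!r} in section [{section}]")
                sections[section][key] = _coerce(value, sections[section][key])
    for dotted, value in (overrides or {}).items():
        section, key = dotted.split(".", 1)
        if section == "cohort":
            cohort_kwargs[key] = value
        elif section in sections and key in sections[section]:
            sections[section][key] = value
        else:
            raise ConfigError(f"unknown override {dotted!r}")
    cfg = RunConfig(cohort=CohortSpec(**cohort_kwargs), **sections)
    cfg.validate()
    return cfg
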