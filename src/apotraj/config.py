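"""Configuration for the synthetic-cohort generator.

The packaged default (``data/default_sim.yaml``) holds the full
calibration: covariate marginals, woman-level APO prevalence targets,
frailty loadings, the observation process, and the ground-truth group
mean curves.  User configs are YAML files with the same structure;
missing keys fall back to the defaults.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Any

import yaml

from .exceptions import ConfigError

OUTCOMES = ("sbp", "dbp", "bmi", "total_chol", "hdl_chol", "glucose")
COUNT_GROUPS = ("0", "1", "2", "3+")

#: APO flags carried per pregnancy.
APO_FLAGS = (
    "gestational_hypertension",
    "preeclampsia",
    "gestational_diabetes",
    "ptb_spontaneous",
    "ptb_indicated",
    "sga",
    "lga",
    "congenital_anomaly",
)
#: Flags underivable without hospital-episode linkage.
HES_FLAGS = ("ptb_spontaneous", "ptb_indicated", "sga", "lga")


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


class SimConfig:
    """Validated view over the nested simulation-config mapping."""

    def __init__(self, raw: dict[str, Any]):
        self.raw = raw
        self._validate()

    # -- block accessors -------------------------------------------------
    @property
    def cohort(self) -> dict:
        return self.raw["cohort"]

    @property
    def covariates(self) -> dict:
        return self.raw["covariates"]

    @property
    def apo(self) -> dict:
        return self.raw["apo"]

    @property
    def timing(self) -> dict:
        return self.raw["pregnancy_timing"]

    @property
    def observation(self) -> dict:
        return self.raw["observation"]

    @property
    def truth(self) -> dict:
        return self.raw["truth"]

    @property
    def window(self) -> tuple[float, float]:
        lo, hi = self.observation["window"]
        return float(lo), float(hi)

    @property
    def townsend_probs(self) -> list[float]:
        """Quintile probabilities renormalised over the non-missing mass."""
        probs = [float(p) for p in self.covariates["townsend_quintile"]["probs"]]
        total = sum(probs)
        return [p / total for p in probs]

    @property
    def townsend_missing(self) -> float:
        return float(self.covariates["townsend_quintile"]["missing"])

    @property
    def parity_support(self) -> tuple[list[int], list[float]]:
        probs = self.covariates["parity"]["probs"]
        levels = sorted(int(k) for k in probs)
        weights = [float(probs[k] if k in probs else probs[str(k)]) for k in levels]
        total = sum(weights)
        return levels, [w / total for w in weights]

    def noise_sd(self, outcome: str) -> tuple[float, float]:
        scale = float(self.truth.get("noise_scale", 1.0))
        block = self.truth["noise"][outcome]
        return scale * float(block["intercept_sd"]), scale * float(block["residual_sd"])

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        for block in ("cohort", "covariates", "apo", "pregnancy_timing", "observation", "truth"):
            if block not in self.raw:
                raise ConfigError(f"missing config block '{block}'")
        for name, prob in self.apo["prevalence"].items():
            if not 0.0 <= float(prob) <= 1.0:
                raise ConfigError(f"prevalence for {name} outside [0, 1]: {prob}")
        misc = self.apo["miscarriage"]
        if not 0.0 <= float(misc["any"]) <= 1.0 or not 0.0 <= float(misc["multiple"]) <= 1.0:
            raise ConfigError("miscarriage prevalences must lie in [0, 1]")
        if float(misc["multiple"]) > float(misc["any"]):
            raise ConfigError("multiple-miscarriage prevalence exceeds any-miscarriage prevalence")
        probs = self.covariates["townsend_quintile"]["probs"]
        if abs(sum(float(p) for p in probs) - 1.0) > 0.02:
            raise ConfigError(f"townsend quintile probabilities must sum to ~1, got {sum(probs):.4f}")
        _, parity_w = self.parity_support
        if any(w < 0 for w in parity_w):
            raise ConfigError("parity probabilities must be non-negative")
        eth = self.covariates["ethnicity"]
        if abs(sum(float(v) for v in eth.values()) - 1.0) > 0.01:
            raise ConfigError("ethnicity probabilities must sum to 1")
        lo, hi = self.window
        if hi <= lo:
            raise ConfigError("observation window must be increasing")
        for outcome, groups in self.truth["anchors"].items():
            if outcome not in OUTCOMES:
                raise ConfigError(f"unknown outcome '{outcome}' in truth anchors")
            for group, anchors in groups.items():
                if str(group) not in COUNT_GROUPS:
                    raise ConfigError(f"unknown APO-count group '{group}'")
                times = sorted(float(t) for t in anchors)
                if times[0] > lo or times[-1] < hi:
                    raise ConfigError(
                        f"truth anchors for {outcome}/{group} must cover the window {self.window}"
                    )
        for outcome in OUTCOMES:
            su, se = self.noise_sd(outcome)
            if su < 0 or se < 0:
                raise ConfigError(f"noise SDs for {outcome} must be non-negative")

    # -- construction ----------------------------------------------------
    @classmethod
    def default(cls) -> "SimConfig":
        return cls(_load_default_dict())

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            overrides = yaml.safe_load(fh) or {}
        raw = _deep_update(_load_default_dict(), overrides)
        return cls(raw)

    def updated(self, overrides: dict) -> "SimConfig":
        """A copy with nested ``overrides`` merged in."""
        raw = _deep_update(copy.deepcopy(self.raw), copy.deepcopy(overrides))
        return SimConfig(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)


def _load_default_dict() -> dict:
    text = resources.files("apotraj.data").joinpath("default_sim.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


def default_config() -> SimConfig:
    return SimConfig.default()
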