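"""Grid configuration: YAML parsing, validation and Cartesian expansion.

A config file mirrors the Scenario fields; list values expand into a grid::

    design: cohort
    n_cohort: [5000, 10000]
    raf: 0.10
    hr: [1.1, 1.2, 1.5, 2.0]
    incidence: [0.05, 0.10, 0.15]
    censoring: [complete, survey, random]
    n_replicates: 1000
    seed: 20170503

Defaults: alpha 0.05, max_follow_up 20 years, primary calibration, 1000
replicates, and the stand-in nuisance parameters lam / beta_age of the
event-time model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import yaml

from .cohort import DEFAULT_BETA_AGE, DEFAULT_LAMBDA, Scenario

__all__ = ["GridConfig", "ConfigError", "expand_grid", "load_config"]

_LIST_KEYS = (
    "design",
    "n_cohort",
    "sampling_fraction",
    "raf",
    "hr",
    "incidence",
    "censoring",
)
_SCALAR_KEYS = {
    "calibration_mode": "primary",
    "max_follow_up": 20.0,
    "alpha": 0.05,
    "n_replicates": 1000,
    "seed": 0,
    "lam": DEFAULT_LAMBDA,
    "beta_age": DEFAULT_BETA_AGE,
}
_REQUIRED = ("design", "n_cohort", "raf", "hr", "incidence", "censoring")


class ConfigError(ValueError):
    """Raised with every validation problem found in a config, joined together."""


@dataclass
class GridConfig:
    design: list[str]
    n_cohort: list[int]
    raf: list[float]
    hr: list[float]
    incidence: list[float]
    censoring: list[str]
    sampling_fraction: list[float] = field(default_factory=list)
    calibration_mode: str = "primary"
    max_follow_up: float = 20.0
    alpha: float = 0.05
    n_replicates: int = 1000
    seed: int = 0
    lam: float = DEFAULT_LAMBDA
    beta_age: float = DEFAULT_BETA_AGE

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "n_cohort": self.n_cohort,
            "raf": self.raf,
            "hr": self.hr,
            "incidence": self.incidence,
            "censoring": self.censoring,
            "sampling_fraction": self.sampling_fraction,
            "calibration_mode": self.calibration_mode,
            "max_follow_up": self.max_follow_up,
            "alpha": self.alpha,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "lam": self.lam,
            "beta_age": self.beta_age,
        }


def _as_list(value):
    if isinstance(value, (list, tuple)):
        return list(value)
    return [value]


def load_config(path) -> GridConfig:
    """Read and validate a YAML grid config, reporting all violations at once."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping of keys to values")

    errors: list[str] = []
    known = set(_LIST_KEYS) | set(_SCALAR_KEYS)
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    for key in _REQUIRED:
        if key not in raw:
            errors.append(f"missing required key {key!r}")

    values = {k: _as_list(raw[k]) for k in _LIST_KEYS if k in raw}
    scalars = {k: raw.get(k, default) for k, default in _SCALAR_KEYS.items()}

    for design in values.get("design", []):
        if design not in ("cohort", "case_cohort"):
            errors.append(f"design: {design!r} is not 'cohort' or 'case_cohort'")
    for cen in values.get("censoring", []):
        if cen not in ("complete", "survey", "random"):
            errors.append(f"censoring: {cen!r} is not complete/survey/random")
    for raf in values.get("raf", []):
        if not 0 < raf < 1:
            errors.append(f"raf: {raf} is outside (0, 1)")
    for inc in values.get("incidence", []):
        if not 0 < inc < 1:
            errors.append(f"incidence: {inc} is outside (0, 1)")
    for hr in values.get("hr", []):
        if hr <= 0:
            errors.append(f"hr: {hr} must be > 0")
    for n in values.get("n_cohort", []):
        if not isinstance(n, (int, np.integer)) or n < 1:
            errors.append(f"n_cohort: {n!r} must be a positive integer")
    for f in values.get("sampling_fraction", []):
        if not 0 < f < 1:
            errors.append(f"sampling_fraction: {f} is outside (0, 1)")
    if "case_cohort" in values.get("design", []) and not values.get("sampling_fraction"):
        errors.append("case_cohort design requires sampling_fraction")
    if scalars["calibration_mode"] not in ("primary", "secondary"):
        errors.append(f"calibration_mode: {scalars['calibration_mode']!r}")
    if not 0 < scalars["alpha"] < 1:
        errors.append(f"alpha: {scalars['alpha']} is outside (0, 1)")
    if scalars["n_replicates"] < 1:
        errors.append("n_replicates must be >= 1")
    if scalars["max_follow_up"] <= 0:
        errors.append("max_follow_up must be > 0")
    if scalars["lam"] <= 0:
        errors.append("lam must be > 0")
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))

    return GridConfig(
        design=values["design"],
        n_cohort=[int(n) for n in values["n_cohort"]],
        raf=[float(v) for v in values["raf"]],
        hr=[float(v) for v in values["hr"]],
        incidence=[float(v) for v in values["incidence"]],
        censoring=values["censoring"],
        sampling_fraction=[float(v) for v in values.get("sampling_fraction", [])],
        calibration_mode=scalars["calibration_mode"],
        max_follow_up=float(scalars["max_follow_up"]),
        alpha=float(scalars["alpha"]),
        n_replicates=int(scalars["n_replicates"]),
        seed=int(scalars["seed"]),
        lam=float(scalars["lam"]),
        beta_age=float(scalars["beta_age"]),
    )


def expand_grid(config: GridConfig) -> list[Scenario]:
    """Cartesian expansion into scenarios, with deterministic per-scenario seeds.

    Seeds are drawn from ``SeedSequence(config.seed)`` in grid order, so a
    scenario's results do not depend on how the grid is parallelised.
    """
    cells = []
    for design in config.design:
        fractions = config.sampling_fraction if design == "case_cohort" else [None]
        for n, frac, cen, inc, hr, raf in product(
            config.n_cohort, fractions, config.censoring, config.incidence, config.hr, config.raf
        ):
            cells.append((design, n, frac, cen, inc, hr, raf))
    seeds = np.random.SeedSequence(config.seed).generate_state(max(len(cells), 1)) % (2**31)
    scenarios = []
    for seed, (design, n, frac, cen, inc, hr, raf) in zip(seeds, cells):
        scenarios.append(
            Scenario(
                design=design,
                n_cohort=n,
                raf=raf,
                hr=hr,
                incidence=inc,
                censoring=cen,
                sampling_fraction=frac,
                calibration_mode=config.calibration_mode,
                max_follow_up=config.max_follow_up,
                alpha=config.alpha,
                n_replicates=config.n_replicates,
                seed=int(seed),
            )
        )
    return scenarios
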