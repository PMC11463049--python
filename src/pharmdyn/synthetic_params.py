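"""Seeded synthetic parameter sets emulating a multi-pharmacy survey.

The original calibration data — interviews and documents from 16 inpatient
hospital pharmacies — were never published, so cohort-level analyses here run
on synthetic parameter sets: every field of
:class:`~pharmdyn.pharmacy_model.ParameterSet` is drawn independently from a
documented plausible range around the reference calibration (log-uniform for
strictly positive scale parameters, uniform for fractions and indices).  The
ranges are entirely synthetic and versioned in ``data/parameter_ranges.json``;
they are labelled as such and fit no real survey.

Sub-seeds for cohort members are derived from the master seed with a
splitmix64-style hash, so cohorts are reproducible and stable across
versions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .pharmacy_model import ParameterSet, build_pharmacy_model, reference_parameters
from .sd_engine import SimConfig, simulate
from .validation_patterns import REFERENCE_PATTERNS, classify_trend

__all__ = [
    "Range",
    "default_parameter_ranges",
    "load_parameter_ranges",
    "derive_subseed",
    "sample_parameter_set",
    "sample_cohort",
    "PatternPrevalence",
    "ensemble_patterns",
    "cohort_to_frame",
]

_MASK64 = (1 << 64) - 1

#: fields sampled uniformly (fractions, indices, counts); everything else is
#: a strictly positive scale parameter and sampled log-uniformly
_UNIFORM_FIELDS = {
    "profit_margin_low",
    "profit_margin_high",
    "share_high_consumption",
    "demand_seasonal_amplitude",
    "workforce_competence",
    "response_speed_base",
    "pharmacists_in_team",
    "staff_count",
    "expiry_fraction",
    "transfer_rate_coeff",
    "initial_profit",
}


@dataclass(frozen=True)
class Range:
    dist: str  # "uniform" or "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if not self.low < self.high:
            raise ValueError(f"need low < high, got [{self.low}, {self.high}]")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("loguniform range must be strictly positive")


def default_parameter_ranges() -> dict[str, Range]:
    """The packaged synthetic survey ranges (versioned data file)."""
    raw = json.loads(
        (resources.files("pharmdyn") / "data" / "parameter_ranges.json").read_text()
    )
    return {
        name: Range(dist=spec["dist"], low=spec["low"], high=spec["high"])
        for name, spec in raw.items()
    }


def load_parameter_ranges(path) -> dict[str, Range]:
    """Read ranges from a JSON/YAML file keyed ``<field>: {dist, low, high}``."""
    from pathlib import Path

    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    ranges = {
        name: Range(dist=spec["dist"], low=float(spec["low"]), high=float(spec["high"]))
        for name, spec in raw.items()
    }
    unknown = sorted(set(ranges) - set(ParameterSet.field_names()))
    if unknown:
        raise ValueError(f"ranges file names unknown parameters: {unknown}")
    return ranges


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def derive_subseed(master_seed: int, index: int) -> int:
    """Stable splitmix64-style sub-seed for cohort member ``index``."""
    return _splitmix64(_splitmix64(master_seed & _MASK64) ^ (index & _MASK64)) % (2**31)


def sample_parameter_set(
    seed: int, ranges: Mapping[str, Range] | None = None
) -> ParameterSet:
    """Draw one validated :class:`ParameterSet`, deterministically in ``seed``.

    Fields are drawn independently, in declared field order, from their
    declared distribution; fields without a range keep the reference value.
    """
    ranges = dict(ranges) if ranges is not None else default_parameter_ranges()
    rng = np.random.default_rng(seed)
    ref = reference_parameters().to_dict()
    values: dict[str, float] = {}
    for name in ParameterSet.field_names():
        if name not in ranges:
            values[name] = ref[name]
            continue
        r = ranges[name]
        if r.dist == "uniform":
            values[name] = float(rng.uniform(r.low, r.high))
        else:
            values[name] = float(np.exp(rng.uniform(np.log(r.low), np.log(r.high))))
    return ParameterSet.from_dict(values)


def sample_cohort(
    n: int, seed: int, ranges: Mapping[str, Range] | None = None
) -> list[ParameterSet]:
    """Sample ``n`` pharmacies from splitmix-derived sub-seeds of ``seed``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    return [
        sample_parameter_set(derive_subseed(seed, i), ranges) for i in range(n)
    ]


def cohort_to_frame(cohort: Sequence[ParameterSet]):
    """One row per pharmacy, one column per parameter (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([p.to_dict() for p in cohort])


@dataclass
class PatternPrevalence:
    """Fraction of cohort runs exhibiting each reference pattern."""

    fractions: dict[str, float]
    n_samples: int
    n_failed: int
    seed: int | None = None
    failures: list[str] = None  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions,
            "n_samples": self.n_samples,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "failures": self.failures or [],
        }


def ensemble_patterns(
    cohort: Sequence[ParameterSet],
    config: SimConfig | None = None,
    seed: int | None = None,
) -> PatternPrevalence:
    """Run every cohort member through the pharmacy model and classify.

    For each pattern required of the reference run (e.g. ``increasing`` total
    disposed medicines) the returned fractions give the share of successful
    runs exhibiting it.  Integration failures are recorded and excluded from
    the denominators.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must not be empty")
    config = config or SimConfig()
    counts: dict[str, int] = {}
    keys: list[str] = []
    for var, required in REFERENCE_PATTERNS.items():
        for label in sorted(required):
            keys.append(f"{var}:{label}")
            counts[f"{var}:{label}"] = 0
    failures: list[str] = []
    n_ok = 0
    for i, params in enumerate(cohort):
        try:
            traj = simulate(build_pharmacy_model(params), params.to_dict(), config)
        except Exception as exc:  # noqa: BLE001 - per-set failures are data
            failures.append(f"member {i}: {type(exc).__name__}: {exc}")
            continue
        n_ok += 1
        for var, required in REFERENCE_PATTERNS.items():
            labels = classify_trend(traj[var], traj.times)
            for label in sorted(required):
                if label in labels:
                    counts[f"{var}:{label}"] += 1
    fractions = {
        k: (counts[k] / n_ok if n_ok else float("nan")) for k in keys
    }
    return PatternPrevalence(
        fractions=fractions,
        n_samples=len(cohort),
        n_failed=len(failures),
        seed=seed,
        failures=failures,
    )
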