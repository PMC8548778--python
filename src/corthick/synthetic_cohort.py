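"""Synthetic lifespan cohorts with realistic cortical-thickness structure.

The generator emulates a pooled cross-sectional sample of ~1,100 healthy
subjects aged 5-96 years with mean thickness (mm) in 62 cortical regions.
Each region follows one of six smooth trajectory archetypes:

* ``change25`` / ``change40`` / ``change50`` / ``change70`` — a gentle
  lifelong decline with one abrupt transition (a tanh step of ~6-year
  width) centred at the named age;
* ``multi`` — two localized thickness bumps, peaking near ages 35 and 62,
  on top of the same slow decline;
* ``constant`` — a near-linear steady decline with only mild curvature.

Templates are sums of scaled tanh sigmoids plus a linear drift, so they are
everywhere differentiable and live in the same function family as the
tanh networks fitted downstream.  Observed thickness is the template value
plus independent Gaussian noise, truncated to the physiologically plausible
band (1.0-4.5 mm by default).

Per-region defaults derive from the bundled 4-subject reference table:
baseline = the region's mean thickness there, amplitude = 10% of baseline,
noise SD = 6% of baseline (~0.15 mm for a typical 2.5 mm region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import regions as _regions

ARCHETYPES = ("change25", "change40", "change50", "change70", "multi", "constant")

_TRANSITION_AGE = {
    "change25": 25.0,
    "change40": 40.0,
    "change50": 50.0,
    "change70": 70.0,
}
_STEP_WIDTH = 6.0  # years; width of the tanh transition
_DRIFT_SPAN = 180.0  # years; drift loses amplitude/180 mm per year
_MULTI_PEAKS = ((35.0, 0.8), (62.0, 0.6))
_BUMP_HALF = 6.0

METADATA_COLUMNS = ("subject_id", "age", "sex", "source")
SOURCE_TAGS = ("IXI", "MMRR", "NKI", "OASIS")


def _bump(age: np.ndarray, center: float) -> np.ndarray:
    """Smooth unit-height bump: difference of two tanh steps, peak at center."""
    u = (age - center) / _BUMP_HALF
    return (np.tanh(u + 1.0) - np.tanh(u - 1.0)) / (2.0 * math.tanh(1.0))


def _bump_derivative(age: np.ndarray, center: float) -> np.ndarray:
    u = (age - center) / _BUMP_HALF
    sech2 = lambda v: 1.0 - np.tanh(v) ** 2  # noqa: E731
    return (sech2(u + 1.0) - sech2(u - 1.0)) / (2.0 * math.tanh(1.0) * _BUMP_HALF)


def trajectory_template(archetype: str, age, baseline: float, amplitude: float):
    """Noise-free thickness (mm) of an archetype at the given age(s)."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be nonnegative")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    drift = amplitude * (a - 50.0) / _DRIFT_SPAN
    if archetype in _TRANSITION_AGE:
        t = _TRANSITION_AGE[archetype]
        val = baseline - amplitude * np.tanh((a - t) / _STEP_WIDTH) - drift
    elif archetype == "multi":
        bumps = sum(w * _bump(a, c) for c, w in _MULTI_PEAKS)
        val = baseline + amplitude * bumps - drift
    elif archetype == "constant":
        val = baseline - amplitude * (
            (a - 50.0) / 35.0 + 0.25 * np.tanh((a - 50.0) / 40.0)
        )
    else:
        raise ValueError(f"unknown archetype: {archetype!r}")
    return float(val) if val.ndim == 0 else val


def template_derivative(archetype: str, age, baseline: float, amplitude: float):
    """Analytic d(thickness)/d(age) in mm/year of :func:`trajectory_template`."""
    a = np.asarray(age, dtype=float)
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    sech2 = lambda v: 1.0 - np.tanh(v) ** 2  # noqa: E731
    if archetype in _TRANSITION_AGE:
        t = _TRANSITION_AGE[archetype]
        val = (
            -amplitude * sech2((a - t) / _STEP_WIDTH) / _STEP_WIDTH
            - amplitude / _DRIFT_SPAN
        )
    elif archetype == "multi":
        val = (
            amplitude * sum(w * _bump_derivative(a, c) for c, w in _MULTI_PEAKS)
            - amplitude / _DRIFT_SPAN
        )
    elif archetype == "constant":
        val = -amplitude * (
            1.0 / 35.0 + 0.25 * sech2((a - 50.0) / 40.0) / 40.0
        ) * np.ones_like(a)
    else:
        raise ValueError(f"unknown archetype: {archetype!r}")
    val = np.asarray(val, dtype=float)
    return float(val) if val.ndim == 0 else val


@dataclass(frozen=True)
class RegionSpec:
    """Generative settings for one region of one hemisphere."""

    name: str
    hemisphere: str
    archetype: str
    baseline: float  # mm
    amplitude: float  # mm
    noise_sd: float  # mm

    def __post_init__(self) -> None:
        if self.hemisphere not in _regions.HEMISPHERES:
            raise ValueError(f"unknown hemisphere: {self.hemisphere!r}")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype: {self.archetype!r}")
        if not (1.0 <= self.baseline <= 4.5):
            raise ValueError("baseline must lie in [1.0, 4.5] mm")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be nonnegative")

    @property
    def column(self) -> str:
        return f"{self.name}_{self.hemisphere}"


@dataclass
class CohortConfig:
    n_subjects: int = 1100
    age_min: float = 5.0
    age_max: float = 96.0
    regions: Sequence[RegionSpec] = field(default_factory=lambda: default_regions())
    seed: int = 0
    thickness_min: float = 1.0
    thickness_max: float = 4.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.age_min < self.age_max:
            raise ValueError("need age_min < age_max")
        cols = [r.column for r in self.regions]
        if len(set(cols)) != len(cols):
            raise ValueError("region names must be unique per hemisphere")


@dataclass
class Cohort:
    """A cross-sectional cohort: subject metadata plus a thickness matrix."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns: {missing}")
        thick = self.frame[self.region_columns]
        if not all(np.issubdtype(dt, np.number) for dt in thick.dtypes):
            raise ValueError("non-numeric thickness column")
        if (thick.to_numpy() <= 0).any():
            raise ValueError("thickness values must be positive")

    @property
    def region_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in METADATA_COLUMNS]

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    @property
    def thickness(self) -> pd.DataFrame:
        return self.frame[self.region_columns]

    def column(self, region: str, hemisphere: str) -> np.ndarray:
        return self.frame[f"{region}_{hemisphere}"].to_numpy(dtype=float)

    def region_means(self, hemisphere: Optional[str] = None) -> pd.Series:
        """Mean thickness per region column, optionally one hemisphere only."""
        cols = self.region_columns
        if hemisphere is not None:
            cols = [c for c in cols if c.endswith(f"_{hemisphere}")]
        return self.frame[cols].mean()


def default_regions(
    amplitude_fraction: float = 0.10, noise_fraction: float = 0.06
) -> list[RegionSpec]:
    """The 62-region default: baselines from the bundled reference table.

    Amplitude and noise SD scale with each region's baseline so thin and
    thick cortex get proportionally sized trajectories and scatter.
    """
    fixture = load_table1_fixture()
    means = fixture.region_means()
    specs = []
    for hemi in _regions.HEMISPHERES:
        for name in _regions.REGION_NAMES:
            base = float(means[f"{name}_{hemi}"])
            specs.append(
                RegionSpec(
                    name=name,
                    hemisphere=hemi,
                    archetype=_regions.DEFAULT_ARCHETYPES[(name, hemi)],
                    baseline=base,
                    amplitude=amplitude_fraction * base,
                    noise_sd=noise_fraction * base,
                )
            )
    return specs


def generate_cohort(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> Cohort:
    """Draw a seeded cohort: uniform ages, template thickness + Gaussian noise.

    Noise is truncated to the config's physiological thickness band.  The
    same (config, seed) always yields a bit-identical cohort.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ages = rng.uniform(config.age_min, config.age_max, size=n)
    sex = rng.choice(["M", "F"], size=n)
    source = rng.choice(SOURCE_TAGS, size=n)
    data = {
        "subject_id": [f"s{i:05d}" for i in range(n)],
        "age": ages,
        "sex": sex,
        "source": source,
    }
    for spec in config.regions:
        clean = trajectory_template(spec.archetype, ages, spec.baseline, spec.amplitude)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=n)
        data[spec.column] = np.clip(noisy, config.thickness_min, config.thickness_max)
    return Cohort(pd.DataFrame(data))


class CohortParseError(ValueError):
    """Malformed cohort CSV."""


def write_cohort(cohort: Cohort, path) -> None:
    cohort.frame.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header[: len(METADATA_COLUMNS)] != list(METADATA_COLUMNS):
        raise CohortParseError(
            f"{path}: header must start with {','.join(METADATA_COLUMNS)}"
        )
    dup = {c for c in header if header.count(c) > 1}
    if dup:
        raise CohortParseError(f"{path}: duplicate columns {sorted(dup)}")
    frame = pd.read_csv(path)
    for col in frame.columns:
        if col in METADATA_COLUMNS:
            continue
        if not np.issubdtype(frame[col].dtype, np.number):
            raise CohortParseError(f"{path}: non-numeric thickness column {col!r}")
    bad_sex = set(frame["sex"].astype(str)) - {"M", "F", "U"}
    if bad_sex:
        raise CohortParseError(f"{path}: unexpected sex codes {sorted(bad_sex)}")
    return Cohort(frame)


def load_table1_fixture() -> Cohort:
    """The bundled 4-subject reference table (one subject per source study)."""
    return read_cohort(_regions.fixture_path())
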