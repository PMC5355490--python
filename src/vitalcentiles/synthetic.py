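"""Synthetic bedside-monitor cohorts with ground-truth labels.

Real critical-care monitor streams carry statistical structure the analysis
must survive: per-age value distributions that range from near-Gaussian
(heart rate, systolic pressure) to right-skewed and heavy-tailed (mean and
diastolic arterial pressure), wildly heterogeneous lengths of stay, stretches
of electrically paced heart rate that do not reflect intrinsic rate,
occasional impossible values from sensor dropouts, and a "sawtooth" digit
preference imprinted by the monitor's rate algorithm.  This module generates
cohorts with exactly those features, each sample labeled with its ground
truth, so every downstream stage can be tested without patient data.

Values are emitted as integers (rounding half away from zero): monitors
report integers, and the sawtooth structure only exists on integer bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import VALUE_BINS, ValueHistogram, VARIABLES

DEFAULT_SAMPLING_INTERVAL_S = 5
SECONDS_PER_DAY = 86_400

#: ground-truth sample labels
LABEL_CLEAN = "clean"
LABEL_IMPLAUSIBLE = "implausible_artifact"
LABEL_PACED = "paced"

_EPOCH = np.datetime64("2014-01-01T00:00:00", "s")


class ConfigurationError(ValueError):
    """Invalid cohort or artifact configuration."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (monitor convention)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass(frozen=True)
class TrueDistribution:
    """Generative law of one variable at one age.

    Families
    --------
    gaussian / logistic : location, scale in the variable's units.
    sinh-arcsinh        : X = loc + scale * sinh((asinh(Z) + skew) / tailweight);
                          skew > 0 gives right skew, tailweight < 1 heavier
                          tails (leptokurtic) — the mean/diastolic BP shape.
    boxcox-normal       : location = median M, scale = coefficient of
                          variation S, skew = Box-Cox power L.
    """

    family: str
    location: float
    scale: float
    skew: float = 0.0
    tailweight: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError(f"scale must be positive, got {self.scale}")
        if self.family not in ("gaussian", "logistic", "sinh-arcsinh", "boxcox-normal"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.family == "sinh-arcsinh" and self.tailweight <= 0:
            raise ConfigurationError("tailweight must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return _sample_family(
            self.family, rng,
            np.full(size, self.location), np.full(size, self.scale),
            np.full(size, self.skew), np.full(size, self.tailweight),
        )


def _sample_family(family, rng, loc, scale, skew, tail):
    z = rng.standard_normal(loc.shape[0])
    if family == "gaussian":
        x = loc + scale * z
    elif family == "logistic":
        u = rng.uniform(1e-12, 1 - 1e-12, loc.shape[0])
        x = loc + scale * np.log(u / (1 - u))
    elif family == "sinh-arcsinh":
        x = loc + scale * np.sinh((np.arcsinh(z) + skew) / tail)
    elif family == "boxcox-normal":
        L, M, S = skew, loc, scale
        small = np.abs(L) < 1e-8
        arg = np.where(small, 1.0, 1.0 + L * S * z)
        arg = np.maximum(arg, 1e-12)  # truncate the unreachable Box-Cox branch
        with np.errstate(divide="ignore"):
            x = np.where(
                small, M * np.exp(S * z), M * np.power(arg, np.where(small, 1.0, 1.0 / L))
            )
    else:  # pragma: no cover - guarded in TrueDistribution
        raise ConfigurationError(f"unknown family {family!r}")
    return round_half_away(x)


@dataclass(frozen=True)
class AgeInterpolatedTruth:
    """Age-dependent TrueDistribution: parameters interpolated over age anchors.

    ``anchors_days`` must be ascending; each parameter is linearly
    interpolated between anchors (constant beyond the ends).
    """

    family: str
    anchors_days: tuple[float, ...]
    location: tuple[float, ...]
    scale: tuple[float, ...]
    skew: tuple[float, ...] = ()
    tailweight: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.anchors_days)
        if a.size == 0 or np.any(np.diff(a) < 0):
            raise ConfigurationError("anchors must be a non-empty ascending sequence")
        if min(self.scale) <= 0:
            raise ConfigurationError("scale must be positive at every anchor")

    def params_at(self, age_days: np.ndarray):
        a = np.asarray(self.anchors_days, dtype=float)
        loc = np.interp(age_days, a, self.location)
        scale = np.interp(age_days, a, self.scale)
        skew = (
            np.interp(age_days, a, self.skew)
            if self.skew else np.zeros_like(loc)
        )
        tail = (
            np.interp(age_days, a, self.tailweight)
            if self.tailweight else np.ones_like(loc)
        )
        return loc, scale, skew, tail

    def at(self, age_days: float) -> TrueDistribution:
        loc, scale, skew, tail = self.params_at(np.array([age_days]))
        return TrueDistribution(
            family=self.family, location=float(loc[0]), scale=float(scale[0]),
            skew=float(skew[0]), tailweight=float(tail[0]),
        )

    def quantile(self, age_days: float, q: float) -> float:
        """Analytic quantile of the continuous (pre-rounding) law at an age."""
        from scipy import stats

        d = self.at(age_days)
        z = stats.norm.ppf(q)
        if d.family == "gaussian":
            return d.location + d.scale * z
        if d.family == "logistic":
            return d.location + d.scale * math.log(q / (1 - q))
        if d.family == "sinh-arcsinh":
            return d.location + d.scale * math.sinh((math.asinh(z) + d.skew) / d.tailweight)
        if d.family == "boxcox-normal":
            L, M, S = d.skew, d.location, d.scale
            if abs(L) < 1e-8:
                return M * math.exp(S * z)
            return M * (1.0 + L * S * z) ** (1.0 / L)
        raise ConfigurationError(f"unknown family {d.family!r}")


def default_truth() -> dict[str, AgeInterpolatedTruth]:
    """Age trends emulating the critical-care vital-sign shapes.

    Heart rate and systolic pressure are near-Gaussian (mesokurtic); mean
    and diastolic arterial pressure are right-skewed and leptokurtic
    (sinh-arcsinh with positive skew and tailweight < 1).  Locations follow
    the familiar pediatric trends: HR falls and BP rises with age.
    """
    anchors = (0.0, 30.0, 365.25, 2 * 365.25, 6 * 365.25, 12 * 365.25, 18 * 365.25)
    return {
        "HR": AgeInterpolatedTruth(
            family="gaussian",
            anchors_days=anchors,
            location=(145.0, 150.0, 135.0, 120.0, 105.0, 92.0, 82.0),
            scale=(18.0, 18.0, 18.0, 17.0, 16.0, 15.0, 14.0),
        ),
        "SBP": AgeInterpolatedTruth(
            family="gaussian",
            anchors_days=anchors,
            location=(62.0, 70.0, 85.0, 92.0, 100.0, 110.0, 118.0),
            scale=(10.0, 10.0, 11.0, 12.0, 12.0, 13.0, 13.0),
        ),
        "MBP": AgeInterpolatedTruth(
            family="sinh-arcsinh",
            anchors_days=anchors,
            location=(45.0, 50.0, 58.0, 62.0, 68.0, 74.0, 80.0),
            scale=(6.0, 6.0, 7.0, 7.0, 8.0, 8.0, 9.0),
            skew=(0.6,) * 7,
            tailweight=(0.55,) * 7,
        ),
        "DBP": AgeInterpolatedTruth(
            family="sinh-arcsinh",
            anchors_days=anchors,
            location=(32.0, 36.0, 42.0, 46.0, 52.0, 58.0, 62.0),
            scale=(5.0, 5.0, 6.0, 6.0, 7.0, 7.0, 8.0),
            skew=(0.5,) * 7,
            tailweight=(0.6,) * 7,
        ),
    }


def lognormal_stay_sampler(
    median_hours: float = 48.0, sigma: float = 1.0
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Length-of-stay sampler (hours): log-normal, heavy right tail.

    ICU stays are dominated by short admissions with a long tail of
    multi-week patients; a log-normal with median ~2 days and sigma 1
    reproduces that heterogeneity.
    """

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return median_hours * np.exp(sigma * rng.standard_normal(n))

    return sample


def loguniform_age_sampler(
    min_days: float = 0.25, max_days: float = 18 * 365.25
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Age-at-admission sampler (days): log-uniform.

    Admissions to pediatric/cardiac ICUs skew heavily toward infancy; a
    log-uniform age fills the day-level neonatal groups and the coarse
    groups alike.
    """

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(min_days), np.log(max_days), n))

    return sample


@dataclass
class CohortConfig:
    """Everything needed to simulate a cohort deterministically."""

    n_patients: int
    seed: int
    age_sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        default_factory=loguniform_age_sampler
    )
    stay_sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        default_factory=lognormal_stay_sampler
    )
    variables: tuple[str, ...] = ("HR", "SBP", "MBP", "DBP")
    truth: Mapping[str, AgeInterpolatedTruth] = field(default_factory=default_truth)
    sampling_interval: int = DEFAULT_SAMPLING_INTERVAL_S

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be positive")
        unknown = set(self.variables) - set(VARIABLES)
        if unknown:
            raise ConfigurationError(f"unknown variables {sorted(unknown)}")
        for v in self.variables:
            if v not in self.truth:
                raise ConfigurationError(f"no true distribution configured for {v}")


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates and shapes of the injected artifacts."""

    implausible_rate: float = 0.0
    paced_fraction: float = 0.0
    paced_rate: float = 80.0
    paced_jitter: float = 0.5
    digit_preference: Optional[Mapping[int, float]] = None

    def __post_init__(self) -> None:
        for name in ("implausible_rate", "paced_fraction"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {r}")


@dataclass
class LabeledStream:
    """Observations plus index-aligned ground-truth labels.

    ``observations`` columns: patient_id, time (datetime64[s]), variable,
    value (int).  ``labels``: one of {clean, implausible_artifact, paced}
    per row.
    """

    observations: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.observations) != len(self.labels):
            raise ValueError("labels must align with observations")

    @property
    def n_samples(self) -> int:
        return len(self.observations)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, LabeledStream]:
    """Simulate a clean cohort: metadata plus an all-clean labeled stream.

    Each patient receives an admission time within a 30-month window, a
    date of birth consistent with the sampled age at admission, and
    ``floor(stay_seconds / interval)`` samples per variable at exactly the
    sampling interval.  Age advances during the stay, so long-stay patients
    can cross age-group boundaries.  Byte-identical output under a fixed
    seed.
    """
    rng = np.random.default_rng(config.seed)
    meta_rows = []
    pid_parts, time_parts, var_parts, val_parts = [], [], [], []
    if config.n_patients > 0:
        ages = config.age_sampler(rng, config.n_patients)
        stays = config.stay_sampler(rng, config.n_patients)
        window_s = int(30 * 30.44 * SECONDS_PER_DAY)  # ~30-month admission window
        admit_offsets = rng.integers(0, window_s, config.n_patients)
        for i in range(config.n_patients):
            pid = f"P{i:05d}"
            admission = _EPOCH + np.timedelta64(int(admit_offsets[i]), "s")
            dob = admission - np.timedelta64(int(round(ages[i] * SECONDS_PER_DAY)), "s")
            n = int(stays[i] * 3600 // config.sampling_interval)
            meta_rows.append(
                {
                    "patient_id": pid,
                    "dob": dob,
                    "sex": "M" if rng.uniform() < 0.55 else "F",
                }
            )
            if n == 0:
                continue
            offsets = np.arange(n, dtype=np.int64) * config.sampling_interval
            times = admission + offsets.astype("timedelta64[s]")
            age_at_sample = ages[i] + offsets / SECONDS_PER_DAY
            for var in config.variables:
                truth = config.truth[var]
                loc, scale, skew, tail = truth.params_at(age_at_sample)
                values = _sample_family(truth.family, rng, loc, scale, skew, tail)
                pid_parts.append(np.full(n, pid, dtype=object))
                time_parts.append(times)
                var_parts.append(np.full(n, var, dtype=object))
                val_parts.append(values.astype(np.int64))
    metadata = pd.DataFrame(meta_rows, columns=["patient_id", "dob", "sex"])
    if pid_parts:
        obs = pd.DataFrame(
            {
                "patient_id": np.concatenate(pid_parts),
                "time": np.concatenate(time_parts),
                "variable": np.concatenate(var_parts),
                "value": np.concatenate(val_parts),
            }
        )
    else:
        obs = pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "time": pd.Series(dtype="datetime64[s]"),
                "variable": pd.Series(dtype=str),
                "value": pd.Series(dtype=np.int64),
            }
        )
    labels = np.full(len(obs), LABEL_CLEAN, dtype=object)
    return metadata, LabeledStream(observations=obs, labels=labels)


def inject_artifacts(
    stream: LabeledStream, spec: ArtifactSpec, seed: int
) -> LabeledStream:
    """Overwrite samples with artifacts and update ground-truth labels.

    Paced episodes (HR only) are contiguous runs of near-constant rate;
    implausible values (<= 0 or >= 300) are scattered uniformly over the
    remaining samples.  The input stream must be all-clean; the original
    clean values are destroyed, recoverable only through the labels.
    """
    if not np.all(stream.labels == LABEL_CLEAN):
        raise ConfigurationError("inject_artifacts expects an all-clean stream")
    rng = np.random.default_rng(seed)
    obs = stream.observations.copy()
    labels = stream.labels.copy()
    values = obs["value"].to_numpy().copy()

    if spec.paced_fraction > 0:
        hr_mask = (obs["variable"] == "HR").to_numpy()
        if not hr_mask.any():
            raise ConfigurationError("paced_fraction > 0 but the stream has no HR samples")
        for pid, idx in obs.index[hr_mask].to_series().groupby(
            obs.loc[hr_mask, "patient_id"]
        ):
            pos = idx.to_numpy()
            n = pos.size
            target = int(round(spec.paced_fraction * n))
            if target == 0:
                continue
            n_episodes = 1 if target < 40 else int(rng.integers(1, 4))
            cuts = np.sort(rng.integers(0, target + 1, n_episodes - 1))
            lengths = np.diff(np.concatenate([[0], cuts, [target]]))
            start_floor = 0
            for length in lengths:
                length = int(length)
                if length == 0:
                    continue
                hi = n - length
                if start_floor > hi:
                    break
                start = int(rng.integers(start_floor, hi + 1))
                sl = pos[start : start + length]
                values[sl] = round_half_away(
                    rng.normal(spec.paced_rate, spec.paced_jitter, length)
                ).astype(np.int64)
                labels[sl] = LABEL_PACED
                start_floor = start + length

    if spec.implausible_rate > 0:
        candidates = np.nonzero(labels == LABEL_CLEAN)[0]
        hit = candidates[rng.uniform(size=candidates.size) < spec.implausible_rate]
        low = rng.uniform(size=hit.size) < 0.5
        bad = np.where(
            low, rng.integers(-20, 1, hit.size), rng.integers(300, 331, hit.size)
        )
        values[hit] = bad
        labels[hit] = LABEL_IMPLAUSIBLE

    obs["value"] = values
    return LabeledStream(observations=obs, labels=labels)


def apply_digit_preference(
    histogram: ValueHistogram, preference: Mapping[int, float]
) -> ValueHistogram:
    """Impose monitor digit preference on a pmf: multiply preferred bins'
    mass by their excess factor, then renormalize.

    Used to build sawtooth fixtures for the smoothing tests; an empty map
    is the identity.
    """
    pmf = histogram.pmf.copy()
    for value, excess in preference.items():
        if excess < 0:
            raise ConfigurationError(f"negative excess {excess} for value {value}")
        if not (1 <= value <= 299):
            raise ConfigurationError(f"preferred value {value} outside support 1..299")
        pmf[value - 1] *= excess
    total = pmf.sum()
    if total <= 0:
        raise ConfigurationError("digit preference annihilated the pmf")
    return ValueHistogram(
        variable=histogram.variable, pmf=pmf / total, n_obs=histogram.n_obs
    )


def sawtooth_preference(
    period: int = 5, excess: float = 1.5, support: Sequence[int] = range(1, 300)
) -> dict[int, float]:
    """Digit-preference map boosting every ``period``-th value (monitor-style)."""
    return {v: excess for v in support if v % period == 0}
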