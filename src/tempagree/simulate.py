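"""Synthetic repeated temperature measurements with known ground truth.

The generative model mirrors the structure assumed by the repeated-measures
agreement analysis: reading for participant i, device k at time point j is

    y_ijk = baseline_i + time_effect_j + device_bias_k + u_ik + e_ijk

with ``baseline_i ~ N(baseline_mean, baseline_sd^2)`` drawn once per
participant, ``e_ijk ~ N(0, device_noise_sd_k^2)`` independent measurement
noise, and an optional participant-by-device random intercept
``u_ik ~ N(0, person_device_sd^2)``. Under the pure model (person_device_sd
= 0) the participant baseline cancels exactly in a same-person difference,
forcing the between-participant variance of differences to zero; the u_ik
term is an extension that lets differences cluster by participant the way
real device comparisons do. Short person-specific temperature trends are
folded into the residual noise rather than modelled parametrically.

After the structural draw, each reading is independently corrupted:
replaced by an implausibly low value (emulating sensor artefacts caught by
the <= 34 degC plausibility filter) with probability ``erroneous_prob``, or
dropped entirely with probability ``missing_prob``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import DEFAULT_DEVICES, MeasurementTable
from .exceptions import ConfigurationError

#: Default device biases (degC) relative to the heat-flux reference, sized so
#: the heat-flux comparisons have biases of roughly -0.5 and -0.4 degC.
DEFAULT_DEVICE_BIASES = {"heat_flux": 0.0, "oral": 0.5, "infrared": 0.4}

#: Default per-device residual SDs (degC); chosen so paired-difference SDs
#: are of order 0.8-1.1 degC, i.e. 95% limits of agreement of order +-2 degC.
DEFAULT_DEVICE_NOISE_SD = {"heat_flux": 0.6, "oral": 0.5, "infrared": 0.7}


@dataclass
class SyntheticConfig:
    """Full parameterization of the generative model.

    Defaults describe a cohort of 166 parturients measured at 0/10/20/30
    minutes after spinal anaesthesia with a gentle cooling trajectory
    (36.6 degC mean baseline, -0.6 degC by 30 min) — plausible physiology
    for this setting, producing a within-30-min hypothermia (<36 degC)
    prevalence of the same order as observational reports.
    """

    n_participants: int = 166
    time_points: tuple[int, ...] = (0, 10, 20, 30)
    devices: tuple[str, ...] = DEFAULT_DEVICES
    baseline_mean: float = 36.6
    baseline_sd: float = 0.4
    time_effects: tuple[float, ...] = (0.0, -0.3, -0.5, -0.6)
    device_biases: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEVICE_BIASES)
    )
    device_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEVICE_NOISE_SD)
    )
    person_device_sd: float = 0.3
    missing_prob: float = 0.02
    erroneous_prob: float = 0.01
    erroneous_value_range: tuple[float, float] = (30.0, 34.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_points = tuple(int(t) for t in self.time_points)
        self.time_effects = tuple(float(x) for x in self.time_effects)
        self.devices = tuple(self.devices)
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if len(self.time_effects) != len(self.time_points):
            raise ConfigurationError(
                "time_effects must have one entry per time point "
                f"({len(self.time_effects)} != {len(self.time_points)})"
            )
        if len(set(self.time_points)) != len(self.time_points):
            raise ConfigurationError("time_points must be distinct")
        if set(self.device_biases) != set(self.devices) or set(
            self.device_noise_sd
        ) != set(self.devices):
            raise ConfigurationError(
                "device_biases and device_noise_sd must cover exactly the device set"
            )
        for name, val in [
            ("baseline_sd", self.baseline_sd),
            ("person_device_sd", self.person_device_sd),
            *[(f"device_noise_sd[{k}]", v) for k, v in self.device_noise_sd.items()],
        ]:
            if val < 0 or not math.isfinite(val):
                raise ConfigurationError(f"{name} must be a finite SD >= 0")
        for name, p in [
            ("missing_prob", self.missing_prob),
            ("erroneous_prob", self.erroneous_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.erroneous_value_range
        if not lo < hi:
            raise ConfigurationError("erroneous_value_range must be (low, high)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("time_points", "time_effects", "devices", "erroneous_value_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthRecord:
    """Latent draws and configuration behind one synthetic table."""

    config: SyntheticConfig
    baselines: dict[str, float]
    person_device_effects: dict[str, dict[str, float]]

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "baselines": self.baselines,
            "person_device_effects": self.person_device_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _participant_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_table(config: SyntheticConfig) -> tuple[MeasurementTable, TruthRecord]:
    """Draw one measurement table from the generative model.

    Identical config (including seed) gives byte-identical output. Separate
    random sub-streams, derived deterministically from the master seed, feed
    the structural draws and the corruption step so that e.g. switching
    corruption off does not change the structural readings.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_corrupt = [np.random.default_rng(s) for s in ss.spawn(2)]

    n, times, devices = config.n_participants, config.time_points, config.devices
    pids = _participant_ids(n)
    baselines = rng_struct.normal(config.baseline_mean, config.baseline_sd, size=n)
    pd_effects = rng_struct.normal(
        0.0, config.person_device_sd, size=(n, len(devices))
    )

    rows = []
    for i, pid in enumerate(pids):
        for k, dev in enumerate(devices):
            noise = rng_struct.normal(0.0, config.device_noise_sd[dev], size=len(times))
            for j, t in enumerate(times):
                temp = (
                    baselines[i]
                    + config.time_effects[j]
                    + config.device_biases[dev]
                    + pd_effects[i, k]
                    + noise[j]
                )
                rows.append((pid, dev, t, temp))
    df = pd.DataFrame(rows, columns=["participant_id", "device", "time_min", "temp_c"])

    # corruption: erroneous replacement then missingness, independent per reading
    m = len(df)
    u_err = rng_corrupt.uniform(size=m)
    err_vals = rng_corrupt.uniform(*config.erroneous_value_range, size=m)
    u_miss = rng_corrupt.uniform(size=m)
    is_err = u_err < config.erroneous_prob
    df.loc[is_err, "temp_c"] = err_vals[is_err]
    df.loc[u_miss < config.missing_prob, "temp_c"] = np.nan

    table = MeasurementTable(
        df, devices=devices, provenance=f"synthetic(seed={config.seed})"
    )
    truth = TruthRecord(
        config=config,
        baselines={pid: float(b) for pid, b in zip(pids, baselines)},
        person_device_effects={
            pid: {dev: float(pd_effects[i, k]) for k, dev in enumerate(devices)}
            for i, pid in enumerate(pids)
        },
    )
    return table, truth


def true_pair_parameters(
    config: SyntheticConfig, device_a: str, device_b: str
) -> tuple[float, float, float]:
    """Closed-form agreement truth for a device pair under the model.

    Returns ``(true_bias, true_between_sd, true_within_sd)`` of the
    same-person difference a - b: the participant baseline and time effects
    cancel, so the bias is the bias difference, the between-participant SD
    comes only from the participant-by-device effects
    (``person_device_sd * sqrt(2)``) and the within SD is the quadrature sum
    of the two devices' noise SDs.
    """
    for dev in (device_a, device_b):
        if dev not in config.devices:
            raise ConfigurationError(f"unknown device {dev!r}")
    bias = config.device_biases[device_a] - config.device_biases[device_b]
    between = config.person_device_sd * math.sqrt(2.0)
    within = math.hypot(
        config.device_noise_sd[device_a], config.device_noise_sd[device_b]
    )
    return bias, between, within
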