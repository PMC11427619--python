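"""Study-level orchestration: run every device comparison, the clinical
summaries, and the sensitivity variants, and render report tables."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .clinical import ErrorGridRules, error_grid_summary, hypothermia_summary
from .data import (
    DEFAULT_DEVICES,
    MeasurementTable,
    apply_plausibility_filter,
    drop_time_point,
    pair_differences,
)
from .exceptions import ConfigurationError, TempAgreeError
from .model import analyze_pair, per_timepoint_agreement

#: Pair order of the main comparison table.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("heat_flux", "oral"),
    ("heat_flux", "infrared"),
    ("infrared", "oral"),
)


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    devices: tuple[str, ...] = DEFAULT_DEVICES
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    margin: float = 0.5
    level: float = 0.95
    plausibility_threshold: float = 34.0
    hypo_threshold: float = 36.0
    hyper_threshold: float = 38.0
    hypo_window: tuple[int, int] = (0, 30)
    n_boot: int = 2000
    seed: int | None = None
    include_implausible: bool = False
    drop_t0: bool = False
    per_timepoint: bool = False

    def __post_init__(self):
        self.devices = tuple(self.devices)
        self.pairs = tuple((a, b) for a, b in self.pairs)
        for a, b in self.pairs:
            if a not in self.devices or b not in self.devices:
                raise ConfigurationError(f"pair ({a}, {b}) outside device list")
        if self.n_boot and self.n_boot > 0 and self.seed is None:
            raise ConfigurationError("a seed is required when the bootstrap is enabled")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["devices"] = list(self.devices)
        d["pairs"] = [list(p) for p in self.pairs]
        d["hypo_window"] = list(self.hypo_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "pairs" in d:
            d["pairs"] = tuple(tuple(p) for p in d["pairs"])
        for key in ("devices", "hypo_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StudyReport:
    """Everything one analysis run produced."""

    config: AnalysisConfig
    agreement: dict[str, dict]
    error_grid: dict[str, dict]
    hypothermia: dict[str, dict]
    variants: dict[str, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "agreement": self.agreement,
            "error_grid": self.error_grid,
            "hypothermia": self.hypothermia,
            "variants": self.variants,
            "metadata": self.metadata,
        }

    def to_json(self, path=None, indent: int = 2):
        payload = json.loads(json.dumps(self.to_dict(), default=_jsonable))
        if path is None:
            return json.dumps(payload, indent=indent)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=indent)
        return None


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _pair_label(a: str, b: str) -> str:
    return f"{a} vs {b}"


def _analyse_table(table: MeasurementTable, config: AnalysisConfig,
                   stage: str) -> tuple[dict, dict]:
    rules = ErrorGridRules(margin=config.margin,
                           hypo_threshold=config.hypo_threshold,
                           hyper_threshold=config.hyper_threshold)
    agreement, grids = {}, {}
    for a, b in config.pairs:
        label = _pair_label(a, b)
        try:
            pairs = pair_differences(table, a, b)
            agreement[label] = analyze_pair(
                pairs, margin=config.margin, level=config.level,
                n_boot=config.n_boot, seed=_pair_seed(config.seed, stage, label),
            )
            grids[label] = error_grid_summary(pairs, rules).to_dict()
        except TempAgreeError as exc:
            raise type(exc)(f"[{stage} / {label}] {exc}") from exc
    return agreement, grids


def _pair_seed(master: int | None, stage: str, label: str) -> int | None:
    """Deterministic per-(stage, pair) sub-seed below 2**31."""
    if master is None:
        return None
    h = np.random.SeedSequence(
        [int(master)] + [ord(c) for c in stage + "/" + label]
    )
    return int(h.generate_state(1)[0] % (2**31))


def run_analysis(table: MeasurementTable, config: AnalysisConfig | None = None) -> StudyReport:
    """Run the full agreement pipeline on a measurement table.

    The main analysis removes implausible readings (<= threshold) and uses
    all time points. Enabled sensitivity variants rerun the whole chain:
    ``include_implausible`` (no plausibility filter), ``drop_t0`` (without
    the baseline time point), and ``per_timepoint`` (classical Bland-Altman
    and correlation per time slice).
    """
    if config is None:
        config = AnalysisConfig(n_boot=0)
    filtered, n_removed = apply_plausibility_filter(
        table, config.plausibility_threshold
    )

    agreement, grids = _analyse_table(filtered, config, "main")
    hypo = {}
    for dev in config.devices:
        hypo[dev] = hypothermia_summary(
            filtered, dev, threshold=config.hypo_threshold,
            window=config.hypo_window, level=config.level,
        ).to_dict()

    variants: dict[str, dict] = {}
    if config.include_implausible:
        agr, grd = _analyse_table(table, config, "include_implausible")
        variants["include_implausible"] = {"agreement": agr, "error_grid": grd}
    if config.drop_t0:
        t0 = min(table.time_points)
        agr, grd = _analyse_table(
            drop_time_point(filtered, t0), config, "drop_t0"
        )
        variants["drop_t0"] = {"agreement": agr, "error_grid": grd,
                               "dropped_time_min": int(t0)}
    if config.per_timepoint:
        per_tp = {}
        for a, b in config.pairs:
            tbl = per_timepoint_agreement(filtered, a, b, level=config.level)
            per_tp[_pair_label(a, b)] = tbl.to_dict(orient="records")
        variants["per_timepoint"] = per_tp

    times = table.time_points
    metadata = {
        "tempagree_version": __version__,
        "seed": config.seed,
        "time_min_range": [int(times[0]), int(times[-1])] if times else None,
        "n_implausible_removed": int(n_removed),
        "n_records": table.n_records,
        "n_participants": len(table.participants),
        "provenance": table.provenance,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return StudyReport(config=config, agreement=agreement, error_grid=grids,
                       hypothermia=hypo, variants=variants, metadata=metadata)


def render_table1(report: StudyReport, decimals: int = 1) -> pd.DataFrame:
    """Main comparison table: one row per device pair with bias, SE of the
    bias, mean LOA (halfwidth) and both LOA boundaries, rounded to the
    reporting precision (one decimal by default)."""
    rows = []
    for (a, b) in report.config.pairs:
        res = report.agreement[_pair_label(a, b)]
        rows.append({
            "Monitor Comparison": f"{_label(a)} vs. {_label(b)}",
            "Duration": _duration_label(report),
            "Mean Bias": round(res["bias"], decimals),
            "Standard error of the bias": round(res["bias_se"], decimals),
            "Mean LOA": round(res["loa_halfwidth"], decimals),
            "Lower boundary of the LOA": round(res["loa_lower"], decimals),
            "Upper boundary of the LOA": round(res["loa_upper"], decimals),
        })
    return pd.DataFrame(rows)


def _label(device: str) -> str:
    return {"heat_flux": "Heat flux", "oral": "Oral", "infrared": "IR"}.get(
        device, device
    )


def _duration_label(report: StudyReport) -> str:
    rng = report.metadata.get("time_min_range")
    if rng:
        return f"T{rng[0]} – T{rng[1]}"
    return "T0 – T30"
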