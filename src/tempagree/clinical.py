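"""Clinical error grid and hypothermia-detection summaries.

Paired readings are classified by the clinical consequence of their
disagreement rather than its raw size. Two readings agree clinically
(green) when they are within a margin of each other, or when both imply
the same clinical action — both below the hypothermia threshold or both
above the hyperthermia threshold. A disagreement beyond the margin is
relevant but not actionable (yellow) when neither reading crosses an action
threshold, and clinically significant (red) when the readings imply
different actions: exactly one is actionable, or the two are actionable in
opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .data import MeasurementTable, PairedDifferenceSet
from .exceptions import ConfigurationError, UndefinedInputError

ZONES = ("green", "yellow", "red")

#: Core-temperature action thresholds (degC): thermoregulatory disturbance
#: is a core temperature < 36.0 or > 38.0.
HYPOTHERMIA_C = 36.0
HYPERTHERMIA_C = 38.0


@dataclass(frozen=True)
class ErrorGridRules:
    """Zone rules: agreement margin and clinical action thresholds (degC)."""

    margin: float = 0.5
    hypo_threshold: float = HYPOTHERMIA_C
    hyper_threshold: float = HYPERTHERMIA_C

    def __post_init__(self):
        if not self.margin > 0:
            raise ConfigurationError("margin must be positive")
        if not self.hypo_threshold < self.hyper_threshold:
            raise ConfigurationError("hypo_threshold must be below hyper_threshold")


DEFAULT_RULES = ErrorGridRules()


@dataclass
class ErrorGridSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    n_pairs: int

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "fractions": dict(self.fractions),
                "n_pairs": self.n_pairs}


@dataclass
class HypothermiaSummary:
    """Per-device detection of hypothermia within a time window."""

    device: str
    n_detected: int
    n_participants: int
    n_excluded: int
    proportion: float
    ci_lower: float
    ci_upper: float
    level: float
    threshold: float
    window: tuple[int, int]
    method: str

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["window"] = list(self.window)
        return d


# ---------------------------------------------------------------------------
# zone classification
# ---------------------------------------------------------------------------

def classify_pairs(value_a, value_b, rules: ErrorGridRules = DEFAULT_RULES) -> np.ndarray:
    """Vectorised zone classification; returns an array of zone labels."""
    a = np.asarray(value_a, dtype=float)
    b = np.asarray(value_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("value arrays must have equal shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise UndefinedInputError("zone classification requires both readings present")
    lo, hi, m = rules.hypo_threshold, rules.hyper_threshold, rules.margin

    within = np.abs(a - b) <= m
    same_action = ((a < lo) & (b < lo)) | ((a > hi) & (b > hi))
    green = within | same_action
    a_actionable = (a < lo) | (a > hi)
    b_actionable = (b < lo) | (b > hi)
    red = ~green & (a_actionable | b_actionable)

    out = np.full(a.shape, "yellow", dtype=object)
    out[green] = "green"
    out[red] = "red"
    return out


def classify_pair(value_a: float, value_b: float,
                  rules: ErrorGridRules = DEFAULT_RULES) -> str:
    """Zone for one pair of readings: 'green', 'yellow' or 'red'."""
    return str(classify_pairs(np.array([value_a]), np.array([value_b]), rules)[0])


def error_grid_summary(pairs: PairedDifferenceSet,
                       rules: ErrorGridRules = DEFAULT_RULES) -> ErrorGridSummary:
    """Zone counts and fractions over all complete pairs."""
    if pairs.n_pairs == 0:
        raise UndefinedInputError("no complete pairs to classify")
    zones = classify_pairs(pairs.data["value_a"], pairs.data["value_b"], rules)
    counts = {z: int(np.sum(zones == z)) for z in ZONES}
    n = pairs.n_pairs
    fractions = {z: counts[z] / n for z in ZONES}
    return ErrorGridSummary(counts=counts, fractions=fractions, n_pairs=n)


# ---------------------------------------------------------------------------
# hypothermia detection
# ---------------------------------------------------------------------------

def detect_hypothermia(table: MeasurementTable, device: str,
                       threshold: float = HYPOTHERMIA_C,
                       window: tuple[int, int] = (0, 30)):
    """Per-participant flag: any reading by ``device`` in the window below
    ``threshold`` (strict). Participants with no readings by that device in
    the window are excluded from the result.

    The table should already be plausibility-filtered; implausible readings
    would otherwise count as detections.

    Returns
    -------
    flags : pandas.Series of bool indexed by participant_id
    n_excluded : int
    """
    if device not in table.devices:
        raise ConfigurationError(f"unknown device {device!r}")
    t0, t1 = window
    df = table.data
    sub = df[(df["device"] == device)
             & (df["time_min"] >= t0) & (df["time_min"] <= t1)
             & df["temp_c"].notna()]
    flags = sub.groupby("participant_id")["temp_c"].agg(lambda v: bool((v < threshold).any()))
    all_participants = set(df["participant_id"].unique())
    n_excluded = len(all_participants) - len(flags)
    return flags.sort_index(), n_excluded


def proportion_with_ci(k: int, n: int, level: float = 0.95,
                       method: str = "exact") -> tuple[float, float, float]:
    """Binomial proportion with confidence interval.

    ``method``: 'exact' (Clopper-Pearson, default), 'wilson', or 'wald'.
    """
    if n < 1 or not 0 <= k <= n:
        raise ConfigurationError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ConfigurationError("level must lie in (0, 1)")
    sm_method = {"exact": "beta", "wilson": "wilson", "wald": "normal"}.get(method)
    if sm_method is None:
        raise ConfigurationError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    return k / n, float(lo), float(hi)


def hypothermia_summary(table: MeasurementTable, device: str,
                        threshold: float = HYPOTHERMIA_C,
                        window: tuple[int, int] = (0, 30),
                        level: float = 0.95,
                        method: str = "exact") -> HypothermiaSummary:
    """Proportion of participants in whom ``device`` detected hypothermia
    within the window, with a binomial CI (Clopper-Pearson by default)."""
    flags, n_excluded = detect_hypothermia(table, device, threshold, window)
    n = len(flags)
    if n == 0:
        raise UndefinedInputError(f"no participants with {device} readings in window")
    k = int(flags.sum())
    p, lo, hi = proportion_with_ci(k, n, level=level, method=method)
    return HypothermiaSummary(
        device=device, n_detected=k, n_participants=n, n_excluded=n_excluded,
        proportion=p, ci_lower=lo, ci_upper=hi, level=level,
        threshold=threshold, window=(int(window[0]), int(window[1])), method=method,
    )
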