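"""Repeated-measures Bland-Altman agreement model.

Classical Bland-Altman limits of agreement (mean difference +- 1.96 SD)
assume one independent difference per participant. With repeated readings
per participant the naive analysis understates uncertainty and over-weights
participants with more readings. The model here treats the paired
differences d_ij (participant i, reading j) as

    d_ij = mu_d + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2)

and estimates (mu_d, sigma_b, sigma_w) by restricted maximum likelihood.
The 95% limits of agreement are mu_d +- z * sigma_total with
sigma_total = sqrt(sigma_b^2 + sigma_w^2): a 95% prediction interval for a
single future difference on a new participant. The mean bias carries a
standard error that respects the clustering, Var(mu_hat) =
1 / sum_i n_i / (sigma_w^2 + n_i sigma_b^2).

The random-intercept REML fit is computed by profiling: for a fixed
variance ratio rho = sigma_b^2 / sigma_w^2 both the GLS mean and sigma_w^2
have closed forms, leaving a one-dimensional criterion in rho that is
minimised numerically. Boundary estimates sigma_b = 0 are allowed. With
exactly one difference per participant the variance components are not
separately identified and the fit collapses, deliberately and exactly, to
the classical Bland-Altman estimate (flagged ``components_identified =
False``).

Uncertainty for the limits of agreement comes from an *unconditional*
parametric bootstrap: each replicate simulates a whole dataset from the
fitted model — fresh random intercepts, fresh residuals, identical
participant/reading structure — refits it and recomputes the limits;
confidence intervals are percentile quantiles across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import MeasurementTable, PairedDifferenceSet, pair_differences
from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    UndefinedInputError,
)

__all__ = [
    "AgreementModel",
    "AgreementResults",
    "LoaBootstrap",
    "fit_variance_components",
    "limits_of_agreement",
    "bootstrap_loa",
    "agreement_probability",
    "empirical_within_margin",
    "empirical_loa_coverage",
    "cluster_bootstrap_correlation",
    "per_timepoint_agreement",
    "analyze_pair",
]


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ConfigurationError("coverage level must lie strictly in (0, 1)")
    return float(stats.norm.ppf(0.5 + level / 2.0))


# ---------------------------------------------------------------------------
# profiled REML for the one-way random-intercept model
# ---------------------------------------------------------------------------

def _reml_random_intercept(y: np.ndarray, codes: np.ndarray, n_groups: int):
    """REML fit of y_ij = mu + b_i + e_ij via 1-D profiling over
    rho = sigma_b^2 / sigma_w^2. Returns (mu, se_mu, sigma_b, sigma_w)."""
    N = y.size
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.bincount(codes, weights=y, minlength=n_groups)
    gmeans = sums / counts
    # within-group sum of squares, invariant in rho
    ssw = float(np.sum((y - gmeans[codes]) ** 2))

    def profile(rho: float):
        w = counts / (1.0 + counts * rho)
        sw = w.sum()
        mu = float(np.dot(w, gmeans) / sw)
        rss = ssw + float(np.dot(w, (gmeans - mu) ** 2))
        sigma2 = rss / (N - 1)
        crit = (
            (N - 1) * np.log(sigma2)
            + float(np.sum(np.log1p(counts * rho)))
            + np.log(sw)
        )
        return crit, mu, sigma2, sw

    def crit(log_rho: float) -> float:
        return profile(np.exp(log_rho))[0]

    # bracket in log-rho; include the sigma_b = 0 boundary explicitly
    res = optimize.minimize_scalar(
        crit, bounds=(-14.0, 10.0), method="bounded",
        options={"xatol": 1e-10},
    )
    rho_hat = float(np.exp(res.x))
    c_hat = profile(rho_hat)[0]
    c_zero = profile(0.0)[0]
    if c_zero <= c_hat:
        rho_hat = 0.0
    _, mu, sigma2, sw = profile(rho_hat)
    sigma_w = float(np.sqrt(sigma2))
    sigma_b = float(np.sqrt(rho_hat * sigma2))
    se_mu = float(np.sqrt(sigma2 / sw))
    return mu, se_mu, sigma_b, sigma_w


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class AgreementModel:
    """Random-intercept model for paired device differences.

    Parameters
    ----------
    diff : array-like
        Paired differences (device A minus device B), degC.
    participant : array-like
        Participant label per difference; differences sharing a label share
        a random intercept.
    time : array-like, optional
        Time point (minutes) per difference; required when
        ``include_time_effect`` is on.
    include_time_effect : bool
        Add fixed offsets per time point; the reported bias is then the
        average of the per-time means over observed time points. Default off
        (a constant device bias over time).
    """

    def __init__(self, diff, participant, time=None, include_time_effect=False,
                 device_a: str | None = None, device_b: str | None = None):
        self.diff = np.asarray(diff, dtype=float)
        participant = np.asarray(participant)
        if self.diff.ndim != 1 or participant.shape != self.diff.shape:
            raise ConfigurationError("diff and participant must be equal-length 1-D")
        if not np.all(np.isfinite(self.diff)):
            raise UndefinedInputError("differences must be finite (complete pairs only)")
        self.groups, self.codes = np.unique(participant, return_inverse=True)
        self.time = None if time is None else np.asarray(time)
        self.include_time_effect = bool(include_time_effect)
        if self.include_time_effect and self.time is None:
            raise ConfigurationError("include_time_effect requires time values")
        self.device_a = device_a
        self.device_b = device_b

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: PairedDifferenceSet, include_time_effect=False):
        df = pairs.data
        return cls(
            df["diff"].to_numpy(),
            df["participant_id"].to_numpy(),
            time=df["time_min"].to_numpy(),
            include_time_effect=include_time_effect,
            device_a=pairs.device_a,
            device_b=pairs.device_b,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, diff_col="diff",
                       participant_col="participant_id", time_col=None,
                       include_time_effect=False):
        time = df[time_col].to_numpy() if time_col else None
        return cls(df[diff_col].to_numpy(), df[participant_col].to_numpy(),
                   time=time, include_time_effect=include_time_effect)

    # -- estimation --------------------------------------------------------
    def fit(self) -> "AgreementResults":
        y, codes = self.diff, self.codes
        n_grp = len(self.groups)
        n = y.size
        if n_grp < 2:
            raise DegenerateDataError(
                "at least 2 participants are required to respect clustering"
            )
        if n < 3:
            raise DegenerateDataError("at least 3 paired differences are required")
        if np.ptp(y) == 0.0:
            raise DegenerateDataError(
                "all differences identical: residual variance would be zero"
            )

        max_per_group = int(np.bincount(codes).max())
        if self.include_time_effect:
            mu, se, sigma_b, sigma_w, time_means = self._fit_time_effect()
            method = "reml+time"
            identified = True
        elif max_per_group == 1:
            # one difference per participant: classical Bland-Altman
            mu = float(np.mean(y))
            sd = float(np.std(y, ddof=1))
            se = sd / np.sqrt(n)
            sigma_b, sigma_w = 0.0, sd
            time_means = None
            method = "classical"
            identified = False
        else:
            mu, se, sigma_b, sigma_w = _reml_random_intercept(y, codes, n_grp)
            time_means = None
            method = "reml"
            identified = True

        return AgreementResults(
            model=self,
            bias=mu,
            bias_se=se,
            sigma_b=sigma_b,
            sigma_w=sigma_w,
            n_participants=n_grp,
            n_pairs=n,
            method=method,
            components_identified=identified,
            time_effect_means=time_means,
        )

    def _fit_time_effect(self):
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        df = pd.DataFrame({
            "diff": self.diff,
            "participant": self.groups[self.codes],
            "time_min": self.time,
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            md = sm.MixedLM.from_formula(
                "diff ~ C(time_min)", groups="participant", data=df
            )
            fit = md.fit(reml=True)
        fe = fit.fe_params
        names = list(fe.index)
        times = sorted(pd.unique(self.time))
        # averaging contrast over observed time points
        c = np.zeros(len(names))
        c[names.index("Intercept")] = 1.0
        k = len(times)
        for nm in names:
            if nm != "Intercept":
                c[names.index(nm)] = 1.0 / k
        mu = float(c @ fe.to_numpy())
        cov = fit.cov_params().loc[names, names].to_numpy()
        se = float(np.sqrt(c @ cov @ c))
        sigma_b = float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))
        sigma_w = float(np.sqrt(fit.scale))
        time_means = {}
        for t in times:
            key = f"C(time_min)[T.{t}]"
            off = float(fe[key]) if key in fe.index else 0.0
            time_means[int(t)] = float(fe["Intercept"]) + off
        return mu, se, sigma_b, sigma_w, time_means


@dataclass
class LoaBootstrap:
    """Percentile bootstrap intervals for the limits of agreement."""

    ci_halfwidth: tuple[float, float]
    ci_lower_bound: tuple[float, float]
    ci_upper_bound: tuple[float, float]
    ci_bias: tuple[float, float]
    n_boot: int
    n_dropped: int
    seed: int | None
    level: float
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "ci_halfwidth": list(self.ci_halfwidth),
            "ci_lower_bound": list(self.ci_lower_bound),
            "ci_upper_bound": list(self.ci_upper_bound),
            "ci_bias": list(self.ci_bias),
            "n_boot": self.n_boot,
            "n_dropped": self.n_dropped,
            "seed": self.seed,
            "level": self.level,
            "warning": self.warning,
        }


@dataclass
class AgreementResults:
    """Fitted variance components and the agreement statistics they imply.

    Attributes
    ----------
    bias : float
        Mean difference mu_d (device A minus device B), degC.
    bias_se : float
        Standard error of the bias, accounting for participant clustering.
    sigma_b, sigma_w : float
        Between-participant and within-participant (residual) SDs of the
        differences, degC. ``sigma_total = sqrt(sigma_b^2 + sigma_w^2)``.
    components_identified : bool
        False when only one difference per participant was available, in
        which case sigma_b/sigma_w are not separately identified and the
        total SD is the classical sample SD.
    """

    model: AgreementModel
    bias: float
    bias_se: float
    sigma_b: float
    sigma_w: float
    n_participants: int
    n_pairs: int
    method: str
    components_identified: bool = True
    time_effect_means: dict | None = None

    @property
    def sigma_total(self) -> float:
        return float(np.hypot(self.sigma_b, self.sigma_w))

    # -- limits of agreement ------------------------------------------------
    def loa_halfwidth(self, level: float = 0.95) -> float:
        """z * sigma_total: the 'mean LOA', half the prediction interval."""
        return _z(level) * self.sigma_total

    def loa(self, level: float = 0.95) -> tuple[float, float]:
        """Limits of agreement: a ``level`` prediction interval for one
        future difference on a new participant."""
        h = self.loa_halfwidth(level)
        return (self.bias - h, self.bias + h)

    # -- agreement probabilities ---------------------------------------------
    def agreement_probability(self, margin: float = 0.5) -> float:
        """Model probability that a future difference lies within +-margin:
        Phi((margin - mu_d)/sigma_total) - Phi((-margin - mu_d)/sigma_total)."""
        if margin <= 0:
            raise ConfigurationError("margin must be positive")
        s = self.sigma_total
        return float(
            stats.norm.cdf((margin - self.bias) / s)
            - stats.norm.cdf((-margin - self.bias) / s)
        )

    def prob_within(self, lower: float, upper: float) -> float:
        """Model probability that a future difference lies in [lower, upper]."""
        if not lower < upper:
            raise ConfigurationError("need lower < upper")
        s = self.sigma_total
        return float(
            stats.norm.cdf((upper - self.bias) / s)
            - stats.norm.cdf((lower - self.bias) / s)
        )

    # -- simulation -----------------------------------------------------------
    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one dataset from the fitted model (fresh random intercepts and
        residuals) on the observed participant/reading structure."""
        m = self.model
        b = rng.normal(0.0, self.sigma_b, size=self.n_participants)
        e = rng.normal(0.0, self.sigma_w, size=self.n_pairs)
        if self.time_effect_means is not None:
            means = np.array([self.time_effect_means[int(t)] for t in m.time])
        else:
            means = self.bias
        return means + b[m.codes] + e

    # -- bootstrap -------------------------------------------------------------
    def bootstrap_loa(self, n_boot: int = 2000, seed: int | None = None,
                      level: float = 0.95) -> LoaBootstrap:
        """Unconditional parametric bootstrap percentile CIs for the LOA.

        Each replicate simulates a full dataset from the fitted model,
        refits, and recomputes bias, halfwidth and both bounds. Replicates
        whose refit fails are dropped and counted; if more than 5% drop a
        warning is recorded in the result.
        """
        if n_boot < 100:
            raise ConfigurationError("n_boot must be >= 100")
        rng = np.random.default_rng(seed)
        m = self.model
        stats_rows = np.empty((n_boot, 4))
        n_dropped = 0
        kept = 0
        for _ in range(n_boot):
            y = self.simulate(rng)
            try:
                res = AgreementModel(
                    y, m.groups[m.codes], time=m.time,
                    include_time_effect=m.include_time_effect,
                ).fit()
            except Exception:
                n_dropped += 1
                continue
            h = res.loa_halfwidth(level)
            lo, hi = res.loa(level)
            stats_rows[kept] = (res.bias, h, lo, hi)
            kept += 1
        if kept == 0:
            raise DegenerateDataError("every bootstrap replicate failed to refit")
        stats_rows = stats_rows[:kept]
        alpha = (1.0 - level) / 2.0
        q = np.quantile(stats_rows, [alpha, 1.0 - alpha], axis=0)
        warning = None
        if n_dropped > 0.05 * n_boot:
            warning = f"{n_dropped}/{n_boot} bootstrap replicates dropped"
        return LoaBootstrap(
            ci_bias=(float(q[0, 0]), float(q[1, 0])),
            ci_halfwidth=(float(q[0, 1]), float(q[1, 1])),
            ci_lower_bound=(float(q[0, 2]), float(q[1, 2])),
            ci_upper_bound=(float(q[0, 3]), float(q[1, 3])),
            n_boot=n_boot,
            n_dropped=n_dropped,
            seed=seed,
            level=level,
        )

    # -- reporting --------------------------------------------------------------
    def summary(self, level: float = 0.95, margin: float = 0.5) -> str:
        lo, hi = self.loa(level)
        pair = ""
        if self.model.device_a and self.model.device_b:
            pair = f" [{self.model.device_a} - {self.model.device_b}]"
        lines = [
            f"Repeated-measures Bland-Altman agreement{pair}",
            "=" * 58,
            f"  participants: {self.n_participants:>6d}    paired readings: {self.n_pairs:>6d}",
            f"  estimation:   {self.method}"
            + ("" if self.components_identified else "  (components not identified)"),
            "-" * 58,
            f"  mean bias                 {self.bias:+8.3f}  (SE {self.bias_se:.3f}) degC",
            f"  between-participant SD    {self.sigma_b:8.3f}  degC",
            f"  within-participant SD     {self.sigma_w:8.3f}  degC",
            f"  total SD                  {self.sigma_total:8.3f}  degC",
            f"  {level:.0%} limits of agreement  [{lo:+.3f}, {hi:+.3f}] degC"
            f"  (halfwidth {self.loa_halfwidth(level):.3f})",
            f"  P(|future diff| <= {margin:.1f})   "
            f"{self.agreement_probability(margin):8.3f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "device_a": self.model.device_a,
            "device_b": self.model.device_b,
            "bias": self.bias,
            "bias_se": self.bias_se,
            "sigma_b": self.sigma_b,
            "sigma_w": self.sigma_w,
            "sigma_total": self.sigma_total,
            "n_participants": self.n_participants,
            "n_pairs": self.n_pairs,
            "method": self.method,
            "components_identified": self.components_identified,
        }


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_variance_components(
    pairs: PairedDifferenceSet, include_time_effect: bool = False
) -> AgreementResults:
    """Fit the random-intercept difference model to a device pair."""
    return AgreementModel.from_pairs(pairs, include_time_effect=include_time_effect).fit()


def limits_of_agreement(
    fit: AgreementResults, level: float = 0.95
) -> tuple[float, float, float]:
    """(lower, upper, halfwidth) of the level-prediction interval."""
    lo, hi = fit.loa(level)
    return lo, hi, fit.loa_halfwidth(level)


def bootstrap_loa(pairs_or_fit, fit: AgreementResults | None = None,
                  n_boot: int = 2000, seed: int | None = None,
                  level: float = 0.95) -> LoaBootstrap:
    """Parametric-bootstrap percentile CIs for the limits of agreement."""
    res = fit if fit is not None else (
        pairs_or_fit if isinstance(pairs_or_fit, AgreementResults)
        else fit_variance_components(pairs_or_fit)
    )
    return res.bootstrap_loa(n_boot=n_boot, seed=seed, level=level)


def agreement_probability(fit: AgreementResults, margin: float = 0.5) -> float:
    """Model probability that a future difference is within +-margin degC."""
    return fit.agreement_probability(margin)


def empirical_within_margin(pairs: PairedDifferenceSet, margin: float = 0.5) -> float:
    """Observed fraction of paired readings with |diff| <= margin (inclusive)."""
    d = pairs.diff
    if d.size == 0:
        raise UndefinedInputError("no complete pairs")
    return float(np.mean(np.abs(d) <= margin))


def empirical_loa_coverage(
    pairs: PairedDifferenceSet, loa_lower: float, loa_upper: float
) -> float:
    """Observed fraction of differences inside [loa_lower, loa_upper]."""
    if not loa_lower < loa_upper:
        raise ConfigurationError("need loa_lower < loa_upper")
    d = pairs.diff
    if d.size == 0:
        raise UndefinedInputError("no complete pairs")
    return float(np.mean((d >= loa_lower) & (d <= loa_upper)))


def cluster_bootstrap_correlation(
    pairs: PairedDifferenceSet, n_boot: int = 2000, seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float, float, dict]:
    """Pearson correlation with a participant-level non-parametric bootstrap.

    r is the plain correlation of (value_a, value_b) over all rows — no
    repeated-measures adjustment. The percentile CI resamples *participants*
    with replacement so all of a participant's readings move together.
    Degenerate replicates (zero variance after resampling) are dropped and
    counted in the returned metadata.
    """
    df = pairs.data
    a = df["value_a"].to_numpy()
    b = df["value_b"].to_numpy()
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise DegenerateDataError("zero variance in one device's readings")
    groups, codes = np.unique(df["participant_id"].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise DegenerateDataError("need >= 2 participants for the cluster bootstrap")
    r = float(stats.pearsonr(a, b).statistic)

    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(len(groups)))
    ends = np.searchsorted(sorted_codes, np.arange(len(groups)) + 1)
    row_idx = [order[s:e] for s, e in zip(starts, ends)]

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    kept = 0
    n_dropped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(groups), size=len(groups))
        idx = np.concatenate([row_idx[g] for g in pick])
        aa, bb = a[idx], b[idx]
        sa, sb = aa.std(), bb.std()
        if sa == 0.0 or sb == 0.0:
            n_dropped += 1
            continue
        reps[kept] = np.corrcoef(aa, bb)[0, 1]
        kept += 1
    if kept == 0:
        raise DegenerateDataError("every correlation bootstrap replicate degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps[:kept], [alpha, 1.0 - alpha])
    meta = {"n_boot": n_boot, "n_dropped": n_dropped, "seed": seed, "level": level}
    return r, float(lo), float(hi), meta


def per_timepoint_agreement(
    table: MeasurementTable, device_a: str, device_b: str,
    level: float = 0.95, min_pairs: int = 3,
) -> pd.DataFrame:
    """Classical single-measurement Bland-Altman and Pearson r per time slice.

    Each time point holds at most one pair per participant, so the classical
    analysis (mean +- z*SD of the differences) is valid within a slice. Slices
    with fewer than ``min_pairs`` complete pairs are flagged insufficient.
    """
    pairs = pair_differences(table, device_a, device_b)
    z = _z(level)
    rows = []
    for t, grp in pairs.data.groupby("time_min", sort=True):
        d = grp["diff"].to_numpy()
        n = d.size
        if n < min_pairs or np.ptp(d) == 0.0:
            rows.append((int(t), n, np.nan, np.nan, np.nan, np.nan, False))
            continue
        mu = float(d.mean())
        sd = float(d.std(ddof=1))
        if grp["value_a"].std() == 0.0 or grp["value_b"].std() == 0.0:
            r = np.nan
        else:
            r = float(stats.pearsonr(grp["value_a"], grp["value_b"]).statistic)
        rows.append((int(t), n, mu, mu - z * sd, mu + z * sd, r, True))
    return pd.DataFrame(
        rows,
        columns=["time_min", "n_pairs", "bias", "loa_lower", "loa_upper",
                 "pearson_r", "sufficient"],
    )


def analyze_pair(
    pairs: PairedDifferenceSet,
    margin: float = 0.5,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
    include_time_effect: bool = False,
) -> dict:
    """Full agreement analysis for one device pair, as a plain dict.

    Bundles the variance-components fit, limits of agreement with parametric
    bootstrap CIs, model and empirical within-margin agreement, empirical LOA
    coverage, and the cluster-bootstrap correlation. ``n_boot = 0`` skips both
    bootstraps.
    """
    res = fit_variance_components(pairs, include_time_effect=include_time_effect)
    lo, hi = res.loa(level)
    out = res.to_dict()
    out.update({
        "level": level,
        "margin": margin,
        "loa_halfwidth": res.loa_halfwidth(level),
        "loa_lower": lo,
        "loa_upper": hi,
        "prob_within_margin": res.agreement_probability(margin),
        "empirical_within_margin": empirical_within_margin(pairs, margin),
        "empirical_loa_coverage": empirical_loa_coverage(pairs, lo, hi),
    })
    if n_boot and n_boot > 0:
        ss = np.random.SeedSequence(seed)
        s_loa, s_corr = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        out["loa_bootstrap"] = res.bootstrap_loa(
            n_boot=n_boot, seed=s_loa, level=level
        ).to_dict()
        r, rlo, rhi, meta = cluster_bootstrap_correlation(
            pairs, n_boot=n_boot, seed=s_corr, level=level
        )
        out["correlation"] = r
        out["correlation_ci"] = [rlo, rhi]
        out["correlation_meta"] = meta
    else:
        a = pairs.data["value_a"]
        b = pairs.data["value_b"]
        if a.std() > 0 and b.std() > 0:
            out["correlation"] = float(stats.pearsonr(a, b).statistic)
        else:
            out["correlation"] = None
        out["correlation_ci"] = None
    out["n_boot"] = n_boot
    out["seed"] = seed
    return out
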