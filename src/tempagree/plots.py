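"""Bland-Altman and scatter panels with clinical error-grid shading.

The Bland-Altman panel shows diff vs pair mean with horizontal lines at the
bias and both limits of agreement; the scatter panel shows device A vs
device B with the identity line. Both are shaded by the error-grid zone of
the underlying reading pair. In (mean, diff) coordinates the implied
readings are a = mean + diff/2 and b = mean - diff/2, so the shading is the
exact geometric translation of the pairwise zone rules.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

from .clinical import DEFAULT_RULES, ErrorGridRules, classify_pairs
from .data import PairedDifferenceSet

_ZONE_COLORS = {"green": "#cdebc9", "yellow": "#fdf3c0", "red": "#f6c9c4"}
_ZONE_INDEX = {"green": 0, "yellow": 1, "red": 2}


def _zone_mesh(a_grid: np.ndarray, b_grid: np.ndarray, rules: ErrorGridRules):
    zones = classify_pairs(a_grid.ravel(), b_grid.ravel(), rules)
    return np.vectorize(_ZONE_INDEX.get)(zones).reshape(a_grid.shape)


def _zone_cmap():
    from matplotlib.colors import ListedColormap

    return ListedColormap([_ZONE_COLORS["green"], _ZONE_COLORS["yellow"],
                           _ZONE_COLORS["red"]])


def bland_altman_panel(ax, pairs: PairedDifferenceSet, result,
                       rules: ErrorGridRules = DEFAULT_RULES,
                       level: float = 0.95, shade: bool = True,
                       n_grid: int = 301):
    """Diff-vs-mean panel with bias/LOA lines and zone shading."""
    mean = pairs.pair_mean
    diff = pairs.diff
    xm = (mean.min() - 0.5, mean.max() + 0.5)
    ym_abs = max(np.abs(diff).max(), abs(result.loa(level)[0]),
                 abs(result.loa(level)[1])) + 0.4
    if shade:
        x = np.linspace(*xm, n_grid)
        y = np.linspace(-ym_abs, ym_abs, n_grid)
        X, Y = np.meshgrid(x, y)
        A, B = X + Y / 2.0, X - Y / 2.0
        Z = _zone_mesh(A, B, rules)
        ax.pcolormesh(X, Y, Z, cmap=_zone_cmap(), vmin=0, vmax=2,
                      shading="nearest", zorder=0)
    ax.scatter(mean, diff, s=12, color="#333333", alpha=0.7, zorder=2)
    lo, hi = result.loa(level)
    ax.axhline(result.bias, color="#1f4e9c", lw=1.5, label="bias", zorder=3)
    ax.axhline(lo, color="#1f4e9c", lw=1.2, ls="--", label="LOA", zorder=3)
    ax.axhline(hi, color="#1f4e9c", lw=1.2, ls="--", zorder=3)
    ax.set_xlim(*xm)
    ax.set_ylim(-ym_abs, ym_abs)
    ax.set_xlabel("pair mean (degC)")
    ax.set_ylabel(f"{pairs.device_a} − {pairs.device_b} (degC)")
    ax.set_title(f"Bland-Altman: {pairs.label}")
    return ax


def scatter_panel(ax, pairs: PairedDifferenceSet,
                  rules: ErrorGridRules = DEFAULT_RULES,
                  shade: bool = True, n_grid: int = 301):
    """Device-vs-device scatter with identity line and zone shading."""
    a = pairs.data["value_a"].to_numpy()
    b = pairs.data["value_b"].to_numpy()
    lo = min(a.min(), b.min()) - 0.5
    hi = max(a.max(), b.max()) + 0.5
    if shade:
        x = np.linspace(lo, hi, n_grid)
        X, Y = np.meshgrid(x, x)
        Z = _zone_mesh(Y, X, rules)  # rows: value_a on y-axis
        ax.pcolormesh(X, Y, Z, cmap=_zone_cmap(), vmin=0, vmax=2,
                      shading="nearest", zorder=0)
    ax.plot([lo, hi], [lo, hi], color="#666666", lw=1.0, ls=":", zorder=1)
    ax.scatter(b, a, s=12, color="#333333", alpha=0.7, zorder=2)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel(f"{pairs.device_b} (degC)")
    ax.set_ylabel(f"{pairs.device_a} (degC)")
    ax.set_title(f"Scatter: {pairs.label}")
    ax.set_aspect("equal")
    return ax


def render_pair_figure(pairs: PairedDifferenceSet, result,
                       rules: ErrorGridRules = DEFAULT_RULES,
                       level: float = 0.95):
    """One figure per pair: Bland-Altman panel (left), scatter (right)."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    bland_altman_panel(axes[0], pairs, result, rules=rules, level=level)
    scatter_panel(axes[1], pairs, rules=rules)
    fig.tight_layout()
    return fig


def render_plots(pair_sets: dict[str, PairedDifferenceSet],
                 results: dict[str, object], outdir,
                 rules: ErrorGridRules = DEFAULT_RULES,
                 level: float = 0.95,
                 formats: tuple[str, ...] = ("png", "svg")) -> list[Path]:
    """Write one agreement figure per device pair; returns the file paths.

    Empty pair sets are skipped with a warning on stderr.
    """
    import sys

    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for label, pairs in pair_sets.items():
        if pairs.n_pairs == 0:
            print(f"warning: no complete pairs for {label}; panel skipped",
                  file=sys.stderr)
            continue
        fig = render_pair_figure(pairs, results[label], rules=rules, level=level)
        stem = label.replace(" ", "_")
        for ext in formats:
            path = outdir / f"agreement_{stem}.{ext}"
            fig.savefig(path, dpi=150)
            written.append(path)
        plt.close(fig)
    return written
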