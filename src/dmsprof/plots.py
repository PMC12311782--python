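"""Declarative plot data and export.

Each of the nine plot kinds is built as a :class:`PlotData` object whose
numeric content comes entirely from the statistics layer — plotting is a pure
presentation layer on top of :mod:`dmsprof.stats` and :mod:`dmsprof.screen`.
Exports: tidy CSV (bit-identical to the series arrays), PNG (matplotlib), or
a standalone HTML page embedding the rendered image.

Base colors follow the probing-community convention used throughout:
A orange, C purple, T light blue, G yellow.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import screen as screen_mod
from . import stats
from .errors import CardinalityError, ValidationError
from .selection import SelectionSpec, select
from .study import Study

PLOT_KINDS = (
    "aligned_reads_freq",
    "base_coverage",
    "mut_per_read",
    "mutation_fraction",
    "compare_profiles",
    "fraction_identity",
    "variable_across_samples",
    "fraction_delta",
    "correlation_by_reference",
)

BASE_COLORS = {"A": "orange", "C": "purple", "T": "lightblue", "G": "yellow"}


@dataclass
class PlotSeries:
    label: str
    x: np.ndarray
    y: np.ndarray
    style: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y)
        if len(self.x) != len(self.y):
            raise ValidationError(
                f"series {self.label!r}: x and y lengths differ "
                f"({len(self.x)} vs {len(self.y)})"
            )


@dataclass
class PlotData:
    kind: str
    series: list[PlotSeries]
    annotations: dict[str, Any] = field(default_factory=dict)
    base_colors: dict[str, str] = field(default_factory=lambda: dict(BASE_COLORS))
    frame: pd.DataFrame | None = None  # tidy CSV payload
    title: str = ""

    def to_frame(self) -> pd.DataFrame:
        if self.frame is not None:
            return self.frame.copy()
        parts = []
        for s in self.series:
            parts.append(pd.DataFrame({"label": s.label, "x": s.x, "y": s.y}))
        return pd.concat(parts, ignore_index=True)


def _require_rows(kind: str, got: int, want: int, at_least: bool = False) -> None:
    ok = got >= want if at_least else got == want
    if not ok:
        req = f"at least {want}" if at_least else f"exactly {want}"
        raise CardinalityError(
            f"plot kind {kind!r} requires {req} selected row(s), got {got}"
        )


def build_plot(
    kind: str, study: Study, spec: SelectionSpec, **extra
) -> PlotData:
    """Build the named plot kind from a data selection.

    ``extra`` carries kind-specific options: ``n_bins`` (aligned_reads_freq),
    ``position``/``variable`` (variable_across_samples), ``config`` (a
    ScreenConfig for correlation_by_reference), ``normalization`` (method for
    compare/delta kinds, default none).
    """
    if kind not in PLOT_KINDS:
        raise ValidationError(f"unknown plot kind {kind!r}; expected one of {PLOT_KINDS}")
    return _BUILDERS[kind](study, spec, **extra)


def _views_pair(study, spec, normalization="none"):
    views = select(study, spec)
    _require_rows("compare", len(views), 2)
    v1, v2 = views
    if normalization != "none":
        v2 = stats.normalize_profiles(v1, v2, method=normalization).normalized
    return v1, v2


def _plot_aligned_reads_freq(study, spec, n_bins: int = 30, **_):
    samples = spec.samples or tuple(study.samples)
    _require_rows("aligned_reads_freq", len(samples), 1)
    rec = study.samples[samples[0]]
    counts, edges = stats.reads_per_reference_distribution(rec, n_bins=n_bins)
    frame = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return PlotData(
        kind="aligned_reads_freq",
        series=[PlotSeries(samples[0], edges[:-1], counts, {"draw": "bar"})],
        annotations={"bin_edges": edges},
        frame=frame,
        title=f"Aligned reads per reference — {samples[0]}",
    )


def _single_view(study, spec, kind):
    views = select(study, spec)
    _require_rows(kind, len(views), 1)
    return views[0]


def _plot_base_coverage(study, spec, **_):
    v = _single_view(study, spec, "base_coverage")
    y = v.coverage.astype(float).copy()
    y[~v.unmasked] = np.nan
    keep = v.unmasked
    frame = pd.DataFrame(
        {"position": v.positions[keep], "base": v.base[keep], "coverage": v.coverage[keep]}
    )
    return PlotData(
        kind="base_coverage",
        series=[PlotSeries(v.sample, v.positions, y,
                           {"draw": "line", "bases": v.base})],
        frame=frame,
        title=f"Base coverage — {v.sample} / {v.reference} / {v.section.name}",
    )


def _plot_mut_per_read(study, spec, **_):
    samples = spec.samples or tuple(study.samples)
    refs = spec.references or tuple(study.references)
    _require_rows("mut_per_read", len(samples) * len(refs), 1)
    sample, ref = samples[0], refs[0]
    hist = study.samples[sample].read_hists.get(ref)
    if hist is None:
        raise ValidationError(
            f"sample {sample!r} has no mutations-per-read histogram for {ref!r}"
        )
    frame = pd.DataFrame(
        {"bin_left": hist.bin_edges[:-1], "bin_right": hist.bin_edges[1:],
         "count": hist.counts}
    )
    return PlotData(
        kind="mut_per_read",
        series=[PlotSeries(f"{sample}/{ref}", hist.bin_edges[:-1], hist.counts,
                           {"draw": "bar"})],
        annotations={"total_reads": hist.total_reads},
        frame=frame,
        title=f"Mutations per read — {sample} / {ref}",
    )


def _plot_mutation_fraction(study, spec, **_):
    v = _single_view(study, spec, "mutation_fraction")
    keep = v.unmasked
    frame = pd.DataFrame(
        {"position": v.positions[keep], "base": v.base[keep],
         "fraction": v.fraction[keep]}
    )
    return PlotData(
        kind="mutation_fraction",
        series=[PlotSeries(v.sample, v.positions, v.fraction,
                           {"draw": "bar", "bases": v.base})],
        frame=frame,
        title=f"Mutation fraction — {v.sample} / {v.reference} / {v.section.name}",
    )


def _plot_compare_profiles(study, spec, normalization="none", **_):
    v1, v2 = _views_pair(study, spec, normalization)
    res = stats.compare_profiles(v1, v2)
    frame = res.pairs.copy()
    return PlotData(
        kind="compare_profiles",
        series=[PlotSeries(f"{v1.sample} vs {v2.sample}",
                           frame["x"].to_numpy(), frame["y"].to_numpy(),
                           {"draw": "scatter", "bases": frame["base"].to_numpy()})],
        annotations={
            "identity_line": "x = y",
            "best_fit": {"slope": res.slope, "intercept": res.intercept},
            "n": res.n, "pearson_r": res.pearson_r, "r_squared": res.r_squared,
            "rmse": res.rmse,
        },
        frame=frame,
        title=f"Compare profiles — {v1.sample} vs {v2.sample} / {v1.reference}",
    )


def _plot_fraction_identity(study, spec, **_):
    v = _single_view(study, spec, "fraction_identity")
    frame = stats.fraction_identity(v)
    keep = v.unmasked
    frame = frame[keep].reset_index(drop=True)
    series = [
        PlotSeries(f"to_{b}", frame["position"].to_numpy(),
                   frame[f"frac_to_{b}"].to_numpy(),
                   {"draw": "stacked-bar", "color": BASE_COLORS[b]})
        for b in "ACGT"
    ]
    return PlotData(
        kind="fraction_identity",
        series=series,
        frame=frame,
        title=f"Mutation fraction identity — {v.sample} / {v.reference}",
    )


def _plot_variable_across_samples(study, spec, position=None, variable=None, **_):
    if position is None or variable is None:
        raise ValidationError(
            "variable_across_samples requires 'position' and 'variable' options"
        )
    refs = spec.references or tuple(study.references)
    _require_rows("variable_across_samples", len(refs), 1)
    frame = stats.variable_series(
        study, refs[0], position, variable,
        section=spec.section or "full",
        samples=list(spec.samples) if spec.samples else None,
    )
    return PlotData(
        kind="variable_across_samples",
        series=[PlotSeries(variable, frame["value"].to_numpy(),
                           frame["fraction"].to_numpy(),
                           {"draw": "scatter-line"})],
        annotations={"position": position, "reference": refs[0]},
        frame=frame,
        title=f"{variable} across samples — {refs[0]} position {position}",
    )


def _plot_fraction_delta(study, spec, normalization="none", **_):
    v1, v2 = _views_pair(study, spec, normalization)
    delta = stats.delta_profile(v1, v2)
    frame = delta.to_frame(drop_masked=True)
    return PlotData(
        kind="fraction_delta",
        series=[PlotSeries(f"{v1.sample} - {v2.sample}", delta.positions, delta.delta,
                           {"draw": "bar", "bases": delta.base})],
        frame=frame,
        title=f"Mutation fraction delta — {v1.sample} − {v2.sample} / {v1.reference}",
    )


def _plot_correlation_by_reference(study, spec, config=None, **_):
    samples = spec.samples or tuple(study.samples)
    _require_rows("correlation_by_reference", len(samples), 2)
    config = config or screen_mod.ScreenConfig(bases=spec.bases)
    result = screen_mod.per_reference_correlation(study, samples[0], samples[1], config)
    passing = result.table[result.table["pass_qc"]].reset_index(drop=True)
    frame = passing[["rank", "reference", "r_squared", "n", "responder"]].copy()
    return PlotData(
        kind="correlation_by_reference",
        series=[PlotSeries(f"{samples[0]} vs {samples[1]}",
                           passing["rank"].to_numpy(),
                           passing["r_squared"].to_numpy(),
                           {"draw": "scatter", "names": passing["reference"].to_numpy()})],
        annotations={"threshold": result.threshold_r2},
        frame=frame,
        title=f"Correlation by reference — {samples[0]} vs {samples[1]}",
    )


_BUILDERS = {
    "aligned_reads_freq": _plot_aligned_reads_freq,
    "base_coverage": _plot_base_coverage,
    "mut_per_read": _plot_mut_per_read,
    "mutation_fraction": _plot_mutation_fraction,
    "compare_profiles": _plot_compare_profiles,
    "fraction_identity": _plot_fraction_identity,
    "variable_across_samples": _plot_variable_across_samples,
    "fraction_delta": _plot_fraction_delta,
    "correlation_by_reference": _plot_correlation_by_reference,
}


# ---------------------------------------------------------------------------
# Rendering and export
# ---------------------------------------------------------------------------

def _render(plot: PlotData):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    bottom = None
    for s in plot.series:
        draw = s.style.get("draw", "line")
        x = np.asarray(s.x, dtype=float)
        y = np.asarray(s.y, dtype=float)
        if draw == "bar":
            bases = s.style.get("bases")
            colors = (
                [plot.base_colors.get(b, "gray") for b in bases]
                if bases is not None
                else None
            )
            ax.bar(x, y, color=colors, width=0.8, label=s.label)
        elif draw == "stacked-bar":
            if bottom is None:
                bottom = np.zeros(len(y))
            yy = np.nan_to_num(y)
            ax.bar(x, yy, bottom=bottom, color=s.style.get("color"), label=s.label)
            bottom = bottom + yy
        elif draw == "scatter":
            ax.scatter(x, y, s=18, label=s.label)
        elif draw == "scatter-line":
            ax.plot(x, y, marker="o", label=s.label)
        else:
            ax.plot(x, y, label=s.label)
    if "identity_line" in plot.annotations:
        finite = [
            v
            for s in plot.series
            for v in np.concatenate([s.x.astype(float), s.y.astype(float)])
            if np.isfinite(v)
        ]
        hi = max(finite) if finite else 1.0
        ax.plot([0, hi], [0, hi], "k--", lw=1, label="x = y")
        fit = plot.annotations.get("best_fit")
        if fit and np.isfinite(fit["slope"]):
            ax.plot([0, hi], [fit["intercept"], fit["intercept"] + fit["slope"] * hi],
                    "r-", lw=1, label="fit")
    if "threshold" in plot.annotations:
        ax.axhline(plot.annotations["threshold"], color="red", ls="--", lw=1)
    ax.set_title(plot.title)
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    return fig


def export_plot(plot: PlotData, format: str, path: str | Path) -> Path:
    """Export a plot as csv (tidy data, bit-identical to the PlotData
    arrays), png, or a standalone html page."""
    path = Path(path)
    if format == "csv":
        plot.to_frame().to_csv(path, index=False)
    elif format == "png":
        fig = _render(plot)
        fig.savefig(path, dpi=120)
        import matplotlib.pyplot as plt

        plt.close(fig)
    elif format == "html":
        fig = _render(plot)
        buf = io.BytesIO()
        fig.savefig(buf, format="png", dpi=120)
        import matplotlib.pyplot as plt

        plt.close(fig)
        payload = base64.b64encode(buf.getvalue()).decode("ascii")
        path.write_text(
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{plot.title or plot.kind}</title></head><body>"
            f"<h1>{plot.title or plot.kind}</h1>"
            f"<img alt='{plot.kind}' src='data:image/png;base64,{payload}'/>"
            "</body></html>\n"
        )
    else:
        raise ValidationError(
            f"unknown export format {format!r}; expected csv, png or html"
        )
    return path


def plot_filename(sample: str, reference: str, section: str, kind: str, ext: str) -> str:
    """Canonical output name: <sample>__<reference>__<section>__<kind>.<ext>."""
    return f"{sample}__{reference}__{section}__{kind}.{ext}"
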