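"""Statistics over mutation profiles.

The per-position reactivity signal of a MaP experiment is the mutation
fraction, mutated reads / covering reads. This module provides the
distributional summaries (aligned-reads and mutations-per-read histograms)
and the paired-profile statistics used to compare samples:

* :func:`compare_profiles` — Pearson r, R^2 (= r^2), RMSE and an ordinary
  least-squares fit of sample-1 fractions (y) on sample-2 fractions (x),
  computed only over positions unmasked in *both* inputs;
* :func:`delta_profile` — per-position difference sample1 − sample2;
* :func:`normalize_profiles` — a single positive scale factor bringing
  sample 2 onto sample 1, by default the least-squares scaling through the
  origin k = Σxy / Σy² over shared unmasked positions.

Degenerate inputs (constant vectors) leave r undefined: it is reported as a
masked statistic with a reason string, never coerced to 0.

Every result exports as a tidy DataFrame (one row per position or pair) for
CSV download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UnavailableError, ValidationError
from .selection import ProfileView
from .study import (
    BASES,
    PositionProfile,
    ReadMutHistogram,
    SampleRecord,
    Study,
    mutation_fraction,
)

__all__ = [
    "mutation_fraction",
    "ComparisonResult",
    "DeltaProfile",
    "NormalizationResult",
    "compare_profiles",
    "delta_profile",
    "normalize_profiles",
    "fraction_identity",
    "variable_series",
    "reads_per_reference_distribution",
    "mutations_per_read_histogram",
]


def _check_same_slice(p1: ProfileView, p2: ProfileView) -> None:
    if p1.reference != p2.reference:
        raise ValidationError(
            f"profiles are for different references: {p1.reference!r} vs "
            f"{p2.reference!r}"
        )
    if p1.section.name != p2.section.name or not np.array_equal(p1.positions, p2.positions):
        raise ValidationError(
            f"profiles cover different sections/positions "
            f"({p1.section.name!r} vs {p2.section.name!r})"
        )


@dataclass
class ComparisonResult:
    """Paired-profile statistics over shared unmasked positions.

    ``pearson_r`` (and hence ``r_squared``, ``slope``, ``intercept``) may be
    NaN with ``reason`` set when a vector has zero variance.
    """

    n: int
    pearson_r: float
    r_squared: float
    rmse: float
    slope: float
    intercept: float
    pairs: pd.DataFrame
    reason: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.pairs.copy()


def compare_profiles(p1: ProfileView, p2: ProfileView, min_n: int = 2) -> ComparisonResult:
    """Compare two profile views of the same reference/section.

    x = sample-2 fractions, y = sample-1 fractions (so ``slope`` matches the
    convention of plotting sample 1 on the vertical axis with the best-fit
    regression line of y on x). RMSE is the root-mean-square of (y − x).
    """
    _check_same_slice(p1, p2)
    shared = p1.unmasked & p2.unmasked
    n = int(shared.sum())
    if n < min_n:
        raise InsufficientDataError(
            f"only {n} shared unmasked position(s) between {p1.sample!r} and "
            f"{p2.sample!r} for {p1.reference!r}/{p1.section.name!r}; need >= {min_n}"
        )
    y = p1.fraction[shared]
    x = p2.fraction[shared]
    pairs = pd.DataFrame(
        {
            "position": p1.positions[shared],
            "base": p1.base[shared],
            "x": x,
            "y": y,
        }
    )
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    reason = None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = slope = intercept = np.nan
        reason = "degenerate-variance"
        if np.ptp(x) > 0:  # y constant: OLS still defined, flat line
            slope, intercept = 0.0, float(y[0])
    else:
        # centered sums: numerically stable on fraction-scale data
        dx = x - x.mean()
        dy = y - y.mean()
        sxx = float(np.sum(dx * dx))
        syy = float(np.sum(dy * dy))
        sxy = float(np.sum(dx * dy))
        r = sxy / np.sqrt(sxx * syy)
        slope = sxy / sxx
        intercept = float(y.mean() - slope * x.mean())
    return ComparisonResult(
        n=n,
        pearson_r=r,
        r_squared=r * r if np.isfinite(r) else np.nan,
        rmse=rmse,
        slope=slope,
        intercept=intercept,
        pairs=pairs,
        reason=reason,
    )


@dataclass
class DeltaProfile:
    """Per-position fraction difference, sample1 − sample2; NaN where either
    input is masked."""

    reference: str
    section_name: str
    positions: np.ndarray
    base: np.ndarray
    delta: np.ndarray

    def to_frame(self, drop_masked: bool = True) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"position": self.positions, "base": self.base, "delta": self.delta}
        )
        if drop_masked:
            frame = frame[np.isfinite(self.delta)].reset_index(drop=True)
        return frame


def delta_profile(p1: ProfileView, p2: ProfileView) -> DeltaProfile:
    """Change in mutation fraction, sample 1 − sample 2, masked where either
    input is masked."""
    _check_same_slice(p1, p2)
    return DeltaProfile(
        reference=p1.reference,
        section_name=p1.section.name,
        positions=p1.positions.copy(),
        base=p1.base.copy(),
        delta=p1.fraction - p2.fraction,
    )


@dataclass
class NormalizationResult:
    """A single positive scale factor applied to sample-2 fractions."""

    factor: float
    method: str
    normalized: ProfileView
    n_clipped: int = 0


def normalize_profiles(
    p1: ProfileView, p2: ProfileView, method: str = "ls_origin"
) -> NormalizationResult:
    """Scale sample 2 onto sample 1 with one factor.

    Methods: ``ls_origin`` (default) minimizes Σ(x − k·y)² over shared
    unmasked positions, giving k = Σxy/Σy²; ``median_ratio`` takes the median
    of x/y over shared positions with y > 0; ``none`` applies factor 1.
    Scaled fractions above 1 are clipped, with the count reported.
    """
    _check_same_slice(p1, p2)
    shared = p1.unmasked & p2.unmasked
    n = int(shared.sum())
    if n < 2:
        raise InsufficientDataError(
            f"only {n} shared unmasked position(s); need >= 2 to normalize"
        )
    x = p1.fraction[shared]
    y = p2.fraction[shared]
    if method == "ls_origin":
        denom = float(np.sum(y * y))
        if denom == 0:
            raise ValidationError(
                "normalization factor undefined: sample-2 fractions are all zero "
                "on shared positions"
            )
        factor = float(np.sum(x * y)) / denom
    elif method == "median_ratio":
        ok = y > 0
        if not np.any(ok):
            raise ValidationError(
                "normalization factor undefined: sample-2 fractions are all zero "
                "on shared positions"
            )
        factor = float(np.median(x[ok] / y[ok]))
    elif method == "none":
        factor = 1.0
    else:
        raise ValidationError(
            f"unknown normalization method {method!r}; expected 'ls_origin', "
            f"'median_ratio' or 'none'"
        )
    if factor <= 0:
        raise ValidationError(f"normalization factor {factor:.3g} is not positive")
    scaled = p2.fraction * factor
    n_clipped = int(np.nansum(scaled > 1.0))
    if n_clipped:
        warnings.warn(
            f"normalization clipped {n_clipped} scaled fraction(s) above 1",
            stacklevel=2,
        )
        scaled = np.minimum(scaled, 1.0)
    return NormalizationResult(
        factor=factor, method=method, normalized=p2.with_fraction(scaled),
        n_clipped=n_clipped
    )


def fraction_identity(profile: PositionProfile | ProfileView) -> pd.DataFrame:
    """Per-position fraction mutated to each target base (stacked-bar data).

    Requires a substitution breakdown; converted third-party data without one
    raises :class:`UnavailableError` rather than reporting zeros. Because
    deletions count toward ``mutated`` but not toward ``sub_counts``, the
    stack sum at a position is <= the mutation fraction there.
    """
    if profile.sub_counts is None:
        raise UnavailableError(
            "substitution breakdown (sub_counts) unavailable for "
            f"{profile.reference!r} — identity fractions cannot be computed"
        )
    cov = np.asarray(profile.coverage, dtype=float)
    data = {"position": profile.positions, "base": profile.base}
    for b in BASES:
        counts = profile.sub_counts.get(b, np.zeros_like(profile.coverage))
        frac = np.full(len(cov), np.nan)
        np.divide(counts, cov, out=frac, where=cov > 0)
        data[f"frac_to_{b}"] = frac
    return pd.DataFrame(data)


def variable_series(
    study: Study,
    reference: str,
    position: int,
    variable: str,
    section: str = "full",
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Mutation fraction at one position as a function of an experimental
    variable, across samples, sorted ascending by the variable's value.

    Samples lacking the variable (or with a non-numeric value) are excluded
    with a warning. Raises :class:`InsufficientDataError` if the position is
    masked in every sample that has the variable.
    """
    rows = []
    names = samples if samples is not None else sorted(study.samples)
    for sname in names:
        rec = study.samples[sname]
        var = rec.variables.get(variable)
        value = var.get("value") if isinstance(var, dict) else var
        if value is None or not isinstance(value, (int, float)) or isinstance(value, bool):
            warnings.warn(
                f"sample {sname!r} lacks a numeric value for variable "
                f"{variable!r}; excluded",
                stacklevel=2,
            )
            continue
        prof = study.get_profile(sname, reference, section)
        idx = np.flatnonzero(prof.positions == position)
        if len(idx) == 0:
            raise ValidationError(
                f"position {position} outside section {section!r} of {reference!r}"
            )
        frac = float(prof.fraction[idx[0]])
        unit = var.get("unit") if isinstance(var, dict) else None
        rows.append(
            {"sample": sname, "value": float(value), "unit": unit, "fraction": frac}
        )
    frame = pd.DataFrame(rows, columns=["sample", "value", "unit", "fraction"])
    frame = frame[np.isfinite(frame["fraction"])].reset_index(drop=True)
    if frame.empty:
        raise InsufficientDataError(
            f"position {position} of {reference!r} is masked in every sample with "
            f"variable {variable!r}"
        )
    return frame.sort_values(["value", "sample"], kind="stable").reset_index(drop=True)


def reads_per_reference_distribution(
    sample: SampleRecord, n_bins: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency distribution of per-reference aligned-read counts for one
    sample. Returns (counts, bin_edges); empty input yields empty arrays."""
    values = np.array(sorted(sample.aligned_reads.values()), dtype=float)
    if len(values) == 0:
        return np.array([], dtype=int), np.array([], dtype=float)
    counts, edges = np.histogram(values, bins=n_bins)
    return counts.astype(int), edges


def mutations_per_read_histogram(
    read_counts, bin_width: int = 1, cap: int = 10
) -> ReadMutHistogram:
    """Histogram of mutations per read: contiguous integer bins from 0 of
    width ``bin_width``, with a final overflow bin for counts >= ``cap``."""
    read_counts = np.asarray(read_counts, dtype=int)
    if np.any(read_counts < 0):
        raise ValidationError("mutations-per-read counts must be >= 0")
    edges = list(range(0, cap + 1, bin_width))
    top = int(read_counts.max()) + 1 if len(read_counts) else cap + 1
    edges.append(max(cap + 1, top))
    counts, _ = np.histogram(read_counts, bins=edges)
    return ReadMutHistogram(
        bin_edges=np.asarray(edges), counts=counts, total_reads=int(len(read_counts))
    )
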