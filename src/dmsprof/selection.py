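"""Data selection and quality-control filters.

A :class:`SelectionSpec` describes a subset of a study — samples, references,
one section, a base subset (default A and C, the DMS-reactive bases), an
optional position range and a per-position coverage floor. Applying it yields
:class:`ProfileView` objects: position-parallel views in which excluded
positions are *masked* (NaN fraction), never dropped, so the position axis is
preserved and views from different samples stay alignable.

The QC gate used by the screen requires, per reference and per sample, a
minimum median coverage over the region of interest and a minimum number of
informative (unmasked A/C) positions. The thresholds are package defaults —
1000x median coverage as the community floor for stable MaP fractions, and
10 informative positions — and are overridable everywhere they are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SelectionError, ValidationError
from .study import PositionProfile, SectionAnnotation, Study

DEFAULT_BASES = frozenset({"A", "C"})
ALL_BASES = frozenset({"A", "C", "G", "T"})


@dataclass(frozen=True)
class SelectionSpec:
    """Composable data-selection filters (all optional)."""

    samples: tuple[str, ...] | None = None
    references: tuple[str, ...] | None = None
    section: str | None = None
    bases: frozenset[str] = DEFAULT_BASES
    position_range: tuple[int, int] | None = None
    min_coverage: int = 0

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValidationError("SelectionSpec.bases must be non-empty")
        object.__setattr__(self, "bases", frozenset(b.upper() for b in self.bases))
        unknown = self.bases - ALL_BASES
        if unknown:
            raise ValidationError(f"SelectionSpec.bases: unknown bases {sorted(unknown)}")


@dataclass(frozen=True)
class QcSpec:
    """Quality-control thresholds for the per-reference gate."""

    min_median_coverage: int = 1000
    min_informative_positions: int = 10

    def __post_init__(self) -> None:
        if self.min_median_coverage < 0 or self.min_informative_positions < 0:
            raise ValidationError("QC thresholds must be >= 0")


@dataclass
class ProfileView:
    """A masked, position-parallel view of one profile for one sample.

    ``fraction`` carries NaN at masked positions (zero coverage, excluded
    base, out-of-range, or below the coverage floor); the underlying counts
    are exposed unchanged.
    """

    sample: str
    reference: str
    section: SectionAnnotation
    positions: np.ndarray
    base: np.ndarray
    coverage: np.ndarray
    mutated: np.ndarray
    fraction: np.ndarray
    sub_counts: dict[str, np.ndarray] | None = None

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean array, True where the view exposes a usable fraction."""
        return np.isfinite(self.fraction)

    @property
    def n_unmasked(self) -> int:
        return int(self.unmasked.sum())

    def with_fraction(self, fraction: np.ndarray) -> "ProfileView":
        return replace(self, fraction=np.asarray(fraction, dtype=float))


def make_view(
    profile: PositionProfile,
    sample: str,
    bases: Iterable[str] = ALL_BASES,
    position_range: tuple[int, int] | None = None,
    min_coverage: int = 0,
) -> ProfileView:
    """Build a ProfileView with the given masking applied.

    The coverage floor is inclusive: a position with coverage exactly equal
    to ``min_coverage`` is kept.
    """
    bases = frozenset(b.upper() for b in bases)
    fraction = profile.fraction.copy()
    mask = ~np.isin(profile.base, sorted(bases))
    if position_range is not None:
        lo, hi = position_range
        if lo > hi:
            raise ValidationError(f"position range {lo}..{hi}: start exceeds end")
        if lo < profile.section.start or hi > profile.section.end:
            raise ValidationError(
                f"position range {lo}..{hi} outside section "
                f"{profile.section.name!r} ({profile.section.start}.."
                f"{profile.section.end})"
            )
        mask |= (profile.positions < lo) | (profile.positions > hi)
    if min_coverage > 0:
        mask |= profile.coverage < min_coverage
    fraction[mask] = np.nan
    return ProfileView(
        sample=sample,
        reference=profile.reference,
        section=profile.section,
        positions=profile.positions,
        base=profile.base,
        coverage=profile.coverage,
        mutated=profile.mutated,
        fraction=fraction,
        sub_counts=profile.sub_counts,
    )


def _resolve_names(
    requested: tuple[str, ...] | None, available: Iterable[str], what: str
) -> list[str]:
    available = list(available)
    if requested is None:
        return available
    unknown = [r for r in requested if r not in available]
    if unknown:
        raise SelectionError(
            f"unknown {what} {unknown}; available: {sorted(available)}"
        )
    return list(requested)


def select(study: Study, spec: SelectionSpec) -> list[ProfileView]:
    """Apply a SelectionSpec to a study, returning one view per selected
    (sample, reference) pair.

    The section defaults to ``full``. References lacking the requested
    section in a sample are skipped when references were not explicitly
    requested; explicitly requested combinations that do not exist raise
    :class:`SelectionError`.
    """
    samples = _resolve_names(spec.samples, study.samples.keys(), "sample(s)")
    section = spec.section or "full"
    views: list[ProfileView] = []
    for sname in samples:
        rec = study.samples[sname]
        refs = _resolve_names(spec.references, study.references.keys(), "reference(s)")
        for ref in refs:
            key = (ref, section)
            if key not in rec.profiles:
                if spec.references is None and spec.section is None:
                    continue
                have = sorted({s for r, s in rec.profiles if r == ref})
                raise SelectionError(
                    f"sample {sname!r} has no profile for reference {ref!r}, "
                    f"section {section!r}; available sections: {have}"
                )
            views.append(
                make_view(
                    rec.profiles[key],
                    sample=sname,
                    bases=spec.bases,
                    position_range=spec.position_range,
                    min_coverage=spec.min_coverage,
                )
            )
    return views


def _roi_section(study: Study, reference: str) -> SectionAnnotation:
    rois = [s for s in study.sections.get(reference, []) if s.role == "roi"]
    if not rois:
        raise ConfigurationError(
            f"reference {reference!r} has no section with role 'roi'; QC and "
            f"screening require one"
        )
    return rois[0]


def roi_view(
    study: Study,
    sample: str,
    reference: str,
    bases: Iterable[str] = DEFAULT_BASES,
    min_coverage: int = 0,
) -> ProfileView:
    """View of the region-of-interest profile for one sample/reference.

    Uses the profile stored for the ROI section if present, otherwise slices
    the full-section profile down to the ROI coordinates via range masking
    applied on a view of the full profile.
    """
    roi = _roi_section(study, reference)
    rec = study.samples[sample]
    if (reference, roi.name) in rec.profiles:
        return make_view(rec.profiles[(reference, roi.name)], sample, bases=bases,
                         min_coverage=min_coverage)
    full = study.get_profile(sample, reference, "full")
    view = make_view(full, sample, bases=bases, position_range=(roi.start, roi.end),
                     min_coverage=min_coverage)
    return view


def qc_filter(
    study: Study, sample_a: str, sample_b: str, spec: QcSpec = QcSpec()
) -> pd.DataFrame:
    """Per-reference QC over a sample pair; symmetric in the two samples.

    A reference passes only if *both* samples reach ``min_median_coverage``
    median coverage over the ROI and expose at least
    ``min_informative_positions`` unmasked A/C positions there. Failures
    carry a reason code (``coverage``, ``positions``, ``coverage+positions``,
    or ``absent`` for references present in only one sample).

    Returns a DataFrame indexed by reference with columns ``passed``,
    ``reason``, and the per-sample medians/counts.
    """
    for s in (sample_a, sample_b):
        if s not in study.samples:
            raise SelectionError(
                f"unknown sample {s!r}; available: {sorted(study.samples)}"
            )
    refs_a = set(study.samples[sample_a].references())
    refs_b = set(study.samples[sample_b].references())
    rows = []
    for ref in sorted(refs_a | refs_b):
        if ref not in refs_a or ref not in refs_b:
            rows.append(
                {"reference": ref, "passed": False, "reason": "absent",
                 "median_coverage_a": np.nan, "median_coverage_b": np.nan,
                 "informative_a": 0, "informative_b": 0}
            )
            continue
        stats = {}
        for tag, sname in (("a", sample_a), ("b", sample_b)):
            view = roi_view(study, sname, ref, bases=DEFAULT_BASES)
            roi_cov = view.coverage
            stats[f"median_coverage_{tag}"] = float(np.median(roi_cov)) if len(roi_cov) else 0.0
            stats[f"informative_{tag}"] = view.n_unmasked
        cov_ok = (
            stats["median_coverage_a"] >= spec.min_median_coverage
            and stats["median_coverage_b"] >= spec.min_median_coverage
        )
        pos_ok = (
            stats["informative_a"] >= spec.min_informative_positions
            and stats["informative_b"] >= spec.min_informative_positions
        )
        reason = ""
        if not cov_ok and not pos_ok:
            reason = "coverage+positions"
        elif not cov_ok:
            reason = "coverage"
        elif not pos_ok:
            reason = "positions"
        rows.append({"reference": ref, "passed": cov_ok and pos_ok, "reason": reason, **stats})
    columns = ["reference", "passed", "reason", "median_coverage_a",
               "median_coverage_b", "informative_a", "informative_b"]
    return pd.DataFrame(rows, columns=columns).set_index("reference")
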