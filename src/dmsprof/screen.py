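"""Riboswitch conformational-switch screen.

A riboswitch that binds its ligand rearranges, so its DMS reactivity profile
with ligand decorrelates from the profile without ligand, while technical
replicates stay highly correlated. The screen therefore computes, for every
reference passing QC, the squared Pearson correlation (R^2) of region-of-
interest A/C mutation fractions between two samples, ranks references by
ascending R^2, and calls *responders* strictly below a threshold (default
R^2 < 0.6). Binding-site protection summaries report the per-position drop
in reactivity at candidate ligand-pocket bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .selection import DEFAULT_BASES, ProfileView, QcSpec, qc_filter, roi_view
from .stats import compare_profiles, normalize_profiles

RESULT_COLUMNS = ["reference", "r_squared", "n", "pass_qc", "reason", "responder", "rank"]


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of the screen.

    ``normalization`` scales sample B onto sample A before correlating
    (method name from :func:`dmsprof.stats.normalize_profiles`); the default
    is ``none``. Switch it on (``ls_origin``) when the two samples differ in
    chemistry (e.g. U vs pseudouridine transcripts) so that global reactivity
    rescaling does not masquerade as structural change.
    """

    threshold_r2: float = 0.6
    bases: frozenset[str] = DEFAULT_BASES
    section_role: str = "roi"
    qc: QcSpec = field(default_factory=QcSpec)
    normalization: str = "none"

    def __post_init__(self) -> None:
        if not (0 < self.threshold_r2 < 1):
            raise ValidationError(
                f"threshold_r2 must lie in (0, 1), got {self.threshold_r2}"
            )


@dataclass
class ScreenResult:
    """Per-reference ranked R^2 with QC flags and responder calls.

    ``table`` has one row per reference (columns ``reference``, ``r_squared``,
    ``n``, ``pass_qc``, ``reason``, ``responder``, ``rank``). Ranks run 1..k
    over the k QC-passing references, ascending in R^2, ties broken
    lexicographically by reference name.
    """

    table: pd.DataFrame
    sample_a: str
    sample_b: str
    threshold_r2: float
    config: ScreenConfig | None = None

    @property
    def responders(self) -> list[str]:
        t = self.table
        return t.loc[t["responder"], "reference"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _ranked(rows: list[dict], threshold: float) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    passing = table[table["pass_qc"]].sort_values(
        ["r_squared", "reference"], kind="stable"
    )
    table["rank"] = np.nan
    table.loc[passing.index, "rank"] = np.arange(1, len(passing) + 1)
    table["responder"] = table["pass_qc"] & (table["r_squared"] < threshold)
    return table.sort_values(
        ["pass_qc", "rank", "reference"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def per_reference_correlation(
    study, sample_a: str, sample_b: str, config: ScreenConfig = ScreenConfig()
) -> ScreenResult:
    """Screen every reference common to two samples.

    For each QC-passing reference, sample A's and sample B's ROI profiles
    (restricted to ``config.bases``) are compared after optional
    normalization of B onto A; the squared Pearson correlation is recorded
    and references are ranked ascending. References present in only one
    sample are reported with reason ``absent``; QC failures carry their
    reason code and no rank.
    """
    qc_table = qc_filter(study, sample_a, sample_b, config.qc)
    common = qc_table.index[qc_table["reason"] != "absent"]
    if len(common) == 0:
        raise ValidationError(
            f"samples {sample_a!r} and {sample_b!r} share no references"
        )
    rows = []
    for ref in qc_table.index:
        qc_row = qc_table.loc[ref]
        row = {
            "reference": ref,
            "r_squared": np.nan,
            "n": 0,
            "pass_qc": bool(qc_row["passed"]),
            "reason": qc_row["reason"],
            "responder": False,
            "rank": np.nan,
        }
        if qc_row["passed"]:
            va = roi_view(study, sample_a, ref, bases=config.bases)
            vb = roi_view(study, sample_b, ref, bases=config.bases)
            if config.normalization != "none":
                vb = normalize_profiles(va, vb, method=config.normalization).normalized
            try:
                cmp_res = compare_profiles(va, vb)
            except InsufficientDataError:
                row["pass_qc"] = False
                row["reason"] = "positions"
            else:
                row["r_squared"] = cmp_res.r_squared
                row["n"] = cmp_res.n
                if not np.isfinite(cmp_res.r_squared):
                    row["pass_qc"] = False
                    row["reason"] = cmp_res.reason or "degenerate"
        rows.append(row)
    return ScreenResult(
        table=_ranked(rows, config.threshold_r2),
        sample_a=sample_a,
        sample_b=sample_b,
        threshold_r2=config.threshold_r2,
        config=config,
    )


def call_responders(result: ScreenResult, threshold: float) -> ScreenResult:
    """Re-flag responders at a new threshold (strict inequality: a reference
    with R^2 exactly at the threshold is not a responder)."""
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    table = result.table.copy()
    table["responder"] = table["pass_qc"] & (table["r_squared"] < threshold)
    return replace(result, table=table, threshold_r2=threshold)


@dataclass
class ProtectionSummary:
    """Ligand-induced protection at candidate binding-site positions.

    ``delta`` is with-ligand minus without-ligand fraction; a position is
    *protected* when the with-ligand fraction is strictly lower.
    """

    reference: str
    table: pd.DataFrame  # columns: position, base, without, with, delta, protected

    @property
    def all_protected(self) -> bool:
        return bool(self.table["protected"].all())

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def binding_site_protection(
    p_minus: ProfileView, p_plus: ProfileView, site: list[int]
) -> ProtectionSummary:
    """Summarize reactivity change at binding-site positions.

    ``p_minus``/``p_plus`` are views without/with ligand. Site positions must
    fall within the section; at least one must be unmasked in both views.
    """
    if p_minus.reference != p_plus.reference:
        raise ValidationError("profiles are for different references")
    site = np.asarray(sorted(site), dtype=int)
    out_of_range = (site < p_minus.section.start) | (site > p_minus.section.end)
    if np.any(out_of_range):
        raise ValidationError(
            f"site position(s) {site[out_of_range].tolist()} outside section "
            f"{p_minus.section.name!r} "
            f"({p_minus.section.start}..{p_minus.section.end})"
        )
    idx = site - p_minus.section.start
    without = p_minus.fraction[idx]
    with_ = p_plus.fraction[idx]
    usable = np.isfinite(without) & np.isfinite(with_)
    if not np.any(usable):
        raise InsufficientDataError(
            "all binding-site positions are masked in one or both profiles"
        )
    table = pd.DataFrame(
        {
            "position": site[usable],
            "base": p_minus.base[idx][usable],
            "without": without[usable],
            "with": with_[usable],
        }
    )
    table["delta"] = table["with"] - table["without"]
    table["protected"] = table["delta"] < 0
    return ProtectionSummary(reference=p_minus.reference, table=table)


def screen_report(
    result_replicate: ScreenResult, result_condition: ScreenResult
) -> pd.DataFrame:
    """Join a replicate screen and a condition screen over one reference
    universe: per reference, replicate R^2, condition R^2, and the condition
    responder call. Raises on disjoint reference sets; a join with no
    QC-passing reference returns an empty table with a notice in
    ``frame.attrs['notice']``.
    """
    rep = result_replicate.table.set_index("reference")
    cond = result_condition.table.set_index("reference")
    shared = rep.index.intersection(cond.index)
    if len(shared) == 0:
        raise ValidationError("replicate and condition screens share no references")
    frame = pd.DataFrame(
        {
            "replicate_r_squared": rep.loc[shared, "r_squared"],
            "condition_r_squared": cond.loc[shared, "r_squared"],
            "pass_qc": rep.loc[shared, "pass_qc"] & cond.loc[shared, "pass_qc"],
            "responder": cond.loc[shared, "responder"],
        }
    )
    frame = frame.sort_values(
        ["condition_r_squared", "replicate_r_squared"], na_position="last"
    )
    frame.index.name = "reference"
    frame = frame.reset_index()
    if not frame["pass_qc"].any():
        frame = frame.iloc[0:0]
        frame.attrs["notice"] = "no reference passed QC in both screens"
    return frame
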