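"""Hierarchical container for chemical-probing mutation profiles.

A *study* holds everything one mutational-profiling (MaP) experiment series
produces after upstream read alignment and mutation calling: reference
sequences, named sections of each reference (primers, barcode, flanks, region
of interest), and per-sample, per-reference, per-section position profiles
(coverage, mutated-read counts, substitution breakdown, mutation fraction)
plus mutations-per-read histograms and aligned-read tallies.

The on-disk form is a JSON dialect (schema_version "1", documented in
``docs/formats.md`` and ``docs/study_schema.json``):

* coordinates are 1-based inclusive throughout;
* arrays are position-parallel; masked fractions are encoded as ``null``;
* unknown top-level keys are preserved under ``provenance`` rather than
  rejected, for forward compatibility with upstream exporters.

A mutation fraction is ``mutated / coverage`` and is *masked* (NaN in memory)
wherever coverage is zero or the reference base is N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

SCHEMA_VERSION = "1"
BASES = ("A", "C", "G", "T")
SECTION_ROLES = ("primer5", "barcode", "flank5", "roi", "flank3", "primer3", "full")


def mutation_fraction(mutated, coverage) -> np.ndarray:
    """Per-position mutation fraction ``mutated / coverage``.

    The single code path used everywhere a fraction is computed (loader,
    converters, simulator). Positions with zero coverage are masked (NaN).

    Raises
    ------
    ValidationError
        If shapes differ, counts are negative, or ``mutated > coverage``
        anywhere.
    """
    mutated = np.asarray(mutated, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if mutated.shape != coverage.shape:
        raise ValidationError(
            f"mutated/coverage shape mismatch: {mutated.shape} vs {coverage.shape}"
        )
    if np.any(mutated < 0) or np.any(coverage < 0):
        raise ValidationError("negative counts are not allowed")
    bad = mutated > coverage
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"mutated > coverage at array index {idx} "
            f"({mutated[idx]:.0f} > {coverage[idx]:.0f})"
        )
    out = np.full(mutated.shape, np.nan)
    ok = coverage > 0
    np.divide(mutated, coverage, out=out, where=ok)
    return out


def _arrays_equal(a: np.ndarray, b: np.ndarray) -> bool:
    if a.shape != b.shape:
        return False
    if a.dtype.kind == "f" or b.dtype.kind == "f":
        return bool(np.array_equal(a.astype(float), b.astype(float), equal_nan=True))
    return bool(np.array_equal(a, b))


@dataclass(frozen=True)
class SectionAnnotation:
    """A named sub-interval of a reference, 1-based inclusive coordinates."""

    name: str
    role: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.role not in SECTION_ROLES:
            raise ValidationError(
                f"section {self.name!r}: unknown role {self.role!r} "
                f"(expected one of {SECTION_ROLES})"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"section {self.name!r}: require 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def validate_against(self, reference: str, sequence: str) -> None:
        if self.end > len(sequence):
            raise ValidationError(
                f"section {self.name!r} of {reference!r}: end={self.end} exceeds "
                f"reference length {len(sequence)}"
            )
        if self.role == "full" and (self.start != 1 or self.end != len(sequence)):
            raise ValidationError(
                f"section {self.name!r} of {reference!r}: role 'full' must span "
                f"the entire reference (1..{len(sequence)})"
            )

    def to_dict(self) -> dict:
        return {"name": self.name, "role": self.role, "start": self.start, "end": self.end}


@dataclass
class PositionProfile:
    """Per-position counts and mutation fractions for one (reference, section).

    All arrays are position-parallel and cover the section's coordinates.
    ``sub_counts`` maps target base -> per-position substitution counts; it is
    ``None`` for data converted from tools that do not report the breakdown.
    """

    reference: str
    section: SectionAnnotation
    positions: np.ndarray
    base: np.ndarray
    coverage: np.ndarray
    mutated: np.ndarray
    sub_counts: dict[str, np.ndarray] | None = None
    fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.base = np.asarray(self.base, dtype="U1")
        self.coverage = np.asarray(self.coverage, dtype=int)
        self.mutated = np.asarray(self.mutated, dtype=int)
        if self.sub_counts is not None:
            self.sub_counts = {
                b: np.asarray(v, dtype=int) for b, v in self.sub_counts.items()
            }
        if self.fraction is None:
            self.fraction = self.compute_fraction()
        else:
            self.fraction = np.asarray(self.fraction, dtype=float)

    def compute_fraction(self) -> np.ndarray:
        """Recompute fractions from counts; N reference bases stay masked."""
        frac = mutation_fraction(self.mutated, self.coverage)
        frac[self.base == "N"] = np.nan
        return frac

    def validate(self, sequence: str | None = None) -> None:
        n = self.section.length
        arrays: dict[str, np.ndarray] = {
            "positions": self.positions,
            "base": self.base,
            "coverage": self.coverage,
            "mutated": self.mutated,
            "fraction": self.fraction,
        }
        if self.sub_counts is not None:
            for b, v in self.sub_counts.items():
                arrays[f"sub_counts[{b}]"] = v
        for name, arr in arrays.items():
            if len(arr) != n:
                raise ValidationError(
                    f"profile {self.reference!r}/{self.section.name!r}: {name} has "
                    f"length {len(arr)}, expected section length {n}"
                )
        expect_pos = np.arange(self.section.start, self.section.end + 1)
        if not np.array_equal(self.positions, expect_pos):
            raise ValidationError(
                f"profile {self.reference!r}/{self.section.name!r}: positions must "
                f"run {self.section.start}..{self.section.end} contiguously"
            )
        bad = self.mutated > self.coverage
        if np.any(bad):
            pos = int(self.positions[np.flatnonzero(bad)[0]])
            raise ValidationError(
                f"profile {self.reference!r}/{self.section.name!r}: mutated > "
                f"coverage at position {pos}"
            )
        if self.sub_counts is not None:
            total_subs = np.sum(list(self.sub_counts.values()), axis=0)
            bad = total_subs > self.mutated
            if np.any(bad):
                pos = int(self.positions[np.flatnonzero(bad)[0]])
                raise ValidationError(
                    f"profile {self.reference!r}/{self.section.name!r}: "
                    f"sum(sub_counts) > mutated at position {pos}"
                )
        expect_frac = self.compute_fraction()
        if not _arrays_equal(np.round(self.fraction, 12), np.round(expect_frac, 12)):
            raise ValidationError(
                f"profile {self.reference!r}/{self.section.name!r}: stored "
                f"fractions disagree with mutated/coverage"
            )
        if sequence is not None:
            sub = np.array(list(sequence[self.section.start - 1 : self.section.end]), dtype="U1")
            if not np.array_equal(self.base, sub):
                raise ValidationError(
                    f"profile {self.reference!r}/{self.section.name!r}: base array "
                    f"disagrees with the reference subsequence"
                )

    def equals(self, other: "PositionProfile") -> bool:
        if self.reference != other.reference or self.section != other.section:
            return False
        if (self.sub_counts is None) != (other.sub_counts is None):
            return False
        pairs = [
            (self.positions, other.positions),
            (self.base, other.base),
            (self.coverage, other.coverage),
            (self.mutated, other.mutated),
            (self.fraction, other.fraction),
        ]
        if self.sub_counts is not None:
            if set(self.sub_counts) != set(other.sub_counts):
                return False
            pairs += [(self.sub_counts[b], other.sub_counts[b]) for b in self.sub_counts]
        return all(_arrays_equal(a, b) for a, b in pairs)

    def to_dict(self) -> dict:
        frac = [None if not np.isfinite(f) else float(f) for f in self.fraction]
        d: dict[str, Any] = {
            "reference": self.reference,
            "section": self.section.name,
            "positions": self.positions.tolist(),
            "base": "".join(self.base),
            "coverage": self.coverage.tolist(),
            "mutated": self.mutated.tolist(),
            "sub_counts": None
            if self.sub_counts is None
            else {b: self.sub_counts[b].tolist() for b in BASES if b in self.sub_counts},
            "fraction": frac,
        }
        return d


@dataclass
class ReadMutHistogram:
    """Frequency distribution of mutations per read, contiguous integer bins.

    ``bin_edges`` has one more entry than ``counts``; bin *i* covers
    ``[bin_edges[i], bin_edges[i+1])``. The final bin may be an overflow bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    total_reads: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        self.total_reads = int(self.total_reads)

    def validate(self) -> None:
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValidationError("histogram: len(bin_edges) must be len(counts)+1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("histogram: bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.total_reads:
            raise ValidationError(
                f"histogram: sum(counts)={int(self.counts.sum())} != "
                f"total_reads={self.total_reads}"
            )

    def equals(self, other: "ReadMutHistogram") -> bool:
        return (
            self.total_reads == other.total_reads
            and _arrays_equal(self.bin_edges, other.bin_edges)
            and _arrays_equal(self.counts, other.counts)
        )

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "total_reads": self.total_reads,
        }


@dataclass
class SampleRecord:
    """One sample: experimental variables plus per-reference profile data."""

    sample: str
    variables: dict[str, dict] = field(default_factory=dict)
    profiles: dict[tuple[str, str], PositionProfile] = field(default_factory=dict)
    read_hists: dict[str, ReadMutHistogram] = field(default_factory=dict)
    aligned_reads: dict[str, int] = field(default_factory=dict)

    def references(self) -> list[str]:
        return sorted({ref for ref, _ in self.profiles})

    def equals(self, other: "SampleRecord") -> bool:
        if self.sample != other.sample or self.variables != other.variables:
            return False
        if set(self.profiles) != set(other.profiles):
            return False
        if any(not self.profiles[k].equals(other.profiles[k]) for k in self.profiles):
            return False
        if set(self.read_hists) != set(other.read_hists):
            return False
        if any(not self.read_hists[k].equals(other.read_hists[k]) for k in self.read_hists):
            return False
        return self.aligned_reads == other.aligned_reads


@dataclass
class Study:
    """Top-level container: references, sections, samples, provenance."""

    schema_version: str = SCHEMA_VERSION
    references: dict[str, str] = field(default_factory=dict)
    sections: dict[str, list[SectionAnnotation]] = field(default_factory=dict)
    samples: dict[str, SampleRecord] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------

    def get_section(self, reference: str, name: str) -> SectionAnnotation:
        for sec in self.sections.get(reference, []):
            if sec.name == name:
                return sec
        available = [s.name for s in self.sections.get(reference, [])]
        raise ValidationError(
            f"reference {reference!r} has no section {name!r}; available: {available}"
        )

    def get_profile(self, sample: str, reference: str, section: str) -> PositionProfile:
        if sample not in self.samples:
            raise ValidationError(
                f"unknown sample {sample!r}; available: {sorted(self.samples)}"
            )
        rec = self.samples[sample]
        key = (reference, section)
        if key not in rec.profiles:
            raise ValidationError(
                f"sample {sample!r} has no profile for {key}; available: "
                f"{sorted(rec.profiles)}"
            )
        return rec.profiles[key]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for ref, secs in self.sections.items():
            if ref not in self.references:
                raise ValidationError(f"sections given for unknown reference {ref!r}")
            names = [s.name for s in secs]
            if len(names) != len(set(names)):
                dup = sorted({n for n in names if names.count(n) > 1})
                raise ValidationError(f"reference {ref!r}: duplicate section names {dup}")
            for sec in secs:
                sec.validate_against(ref, self.references[ref])
        for rec in self.samples.values():
            for (ref, sec_name), prof in rec.profiles.items():
                if ref not in self.references:
                    raise ValidationError(
                        f"sample {rec.sample!r}: profile for unknown reference {ref!r}"
                    )
                sec = self.get_section(ref, sec_name)
                if sec != prof.section:
                    raise ValidationError(
                        f"sample {rec.sample!r}: profile section {sec_name!r} does not "
                        f"match the study annotation for {ref!r}"
                    )
                prof.validate(sequence=self.references[ref])
            for ref, hist in rec.read_hists.items():
                hist.validate()
                aligned = rec.aligned_reads.get(ref)
                if aligned is not None and aligned < hist.total_reads:
                    raise ValidationError(
                        f"sample {rec.sample!r}, reference {ref!r}: aligned_reads="
                        f"{aligned} < histogram total_reads={hist.total_reads}"
                    )

    def equals(self, other: "Study") -> bool:
        if self.schema_version != other.schema_version:
            return False
        if self.references != other.references or self.sections != other.sections:
            return False
        if set(self.samples) != set(other.samples):
            return False
        if any(not self.samples[s].equals(other.samples[s]) for s in self.samples):
            return False
        return self.provenance == other.provenance


# ---------------------------------------------------------------------------
# JSON dialect I/O
# ---------------------------------------------------------------------------

_TOP_KEYS = ("schema_version", "references", "sections", "samples", "provenance")


def write_study(study: Study, path: str | Path) -> Path:
    """Serialize a study to the JSON dialect (schema_version "1").

    Field ordering is fixed (top-level keys in documented order, samples and
    references in insertion order, profile fields in documented order) so that
    writing the same study twice yields identical bytes.
    """
    study.validate()
    doc: dict[str, Any] = {
        "schema_version": study.schema_version,
        "references": dict(study.references),
        "sections": {
            ref: [s.to_dict() for s in secs] for ref, secs in study.sections.items()
        },
        "samples": {},
    }
    for name, rec in study.samples.items():
        doc["samples"][name] = {
            "variables": rec.variables,
            "aligned_reads": dict(rec.aligned_reads),
            "read_hists": {r: h.to_dict() for r, h in rec.read_hists.items()},
            "profiles": [rec.profiles[k].to_dict() for k in sorted(rec.profiles)],
        }
    doc["provenance"] = study.provenance
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
    return path


def _require(doc: Mapping, key: str, context: str) -> Any:
    if key not in doc:
        raise FormatError(f"{context}: missing required key {key!r}")
    return doc[key]


def load_study(path: str | Path) -> Study:
    """Load and validate a study from the JSON dialect.

    Masked fractions (``null``) become NaN; a profile without a ``fraction``
    array gets one recomputed from its counts. Unknown top-level keys are
    preserved under ``provenance['extra_keys']``.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: top level must be a JSON object")

    references = dict(_require(doc, "references", str(path)))
    sections: dict[str, list[SectionAnnotation]] = {}
    for ref, secs in _require(doc, "sections", str(path)).items():
        sections[ref] = [
            SectionAnnotation(
                name=_require(s, "name", f"{path} sections[{ref}]"),
                role=_require(s, "role", f"{path} sections[{ref}]"),
                start=int(_require(s, "start", f"{path} sections[{ref}]")),
                end=int(_require(s, "end", f"{path} sections[{ref}]")),
            )
            for s in secs
        ]

    samples: dict[str, SampleRecord] = {}
    for name, sdoc in _require(doc, "samples", str(path)).items():
        ctx = f"{path} samples[{name}]"
        rec = SampleRecord(
            sample=name,
            variables=dict(sdoc.get("variables", {})),
            aligned_reads={r: int(v) for r, v in sdoc.get("aligned_reads", {}).items()},
        )
        for ref, hdoc in sdoc.get("read_hists", {}).items():
            rec.read_hists[ref] = ReadMutHistogram(
                bin_edges=_require(hdoc, "bin_edges", f"{ctx} read_hists[{ref}]"),
                counts=_require(hdoc, "counts", f"{ctx} read_hists[{ref}]"),
                total_reads=_require(hdoc, "total_reads", f"{ctx} read_hists[{ref}]"),
            )
        for pdoc in sdoc.get("profiles", []):
            ref = _require(pdoc, "reference", ctx)
            sec_name = _require(pdoc, "section", ctx)
            matches = [s for s in sections.get(ref, []) if s.name == sec_name]
            if not matches:
                raise ValidationError(
                    f"{ctx}: profile names section {sec_name!r} of {ref!r}, which is "
                    f"not annotated"
                )
            frac = pdoc.get("fraction")
            if frac is not None:
                frac = np.array([np.nan if f is None else f for f in frac], dtype=float)
            subs = pdoc.get("sub_counts")
            prof = PositionProfile(
                reference=ref,
                section=matches[0],
                positions=_require(pdoc, "positions", ctx),
                base=list(_require(pdoc, "base", ctx)),
                coverage=_require(pdoc, "coverage", ctx),
                mutated=_require(pdoc, "mutated", ctx),
                sub_counts=None if subs is None else {b: subs[b] for b in subs},
                fraction=frac,
            )
            rec.profiles[(ref, sec_name)] = prof
        samples[name] = rec

    provenance = dict(doc.get("provenance", {}))
    extra = {k: doc[k] for k in doc if k not in _TOP_KEYS}
    if extra:
        provenance.setdefault("extra_keys", {}).update(extra)

    study = Study(
        schema_version=str(doc.get("schema_version", SCHEMA_VERSION)),
        references=references,
        sections=sections,
        samples=samples,
        provenance=provenance,
    )
    study.validate()
    return study


# ---------------------------------------------------------------------------
# Sections table and FASTA
# ---------------------------------------------------------------------------

def read_sections_table(
    path: str | Path, references: Mapping[str, str]
) -> dict[str, list[SectionAnnotation]]:
    """Read a sections annotation CSV (columns: reference, section, start,
    end, role; 1-based inclusive coordinates).

    An implicit ``full`` section spanning the whole reference is added for
    every reference that lacks one. References in the table must exist in
    ``references``; coordinates are checked against sequence lengths.
    """
    path = Path(path)
    table = pd.read_csv(path)
    table.columns = [c.strip().lower() for c in table.columns]
    required = {"reference", "section", "start", "end", "role"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(
            f"{path}: missing columns {sorted(missing)}; found {list(table.columns)}"
        )
    out: dict[str, list[SectionAnnotation]] = {ref: [] for ref in references}
    for row in table.itertuples(index=False):
        ref = str(row.reference)
        if ref not in references:
            raise ValidationError(
                f"{path}: row names unknown reference {ref!r}; known: "
                f"{sorted(references)}"
            )
        sec = SectionAnnotation(
            name=str(row.section), role=str(row.role), start=int(row.start), end=int(row.end)
        )
        sec.validate_against(ref, references[ref])
        if any(s.name == sec.name for s in out[ref]):
            raise ValidationError(
                f"{path}: duplicate section name {sec.name!r} for reference {ref!r}"
            )
        out[ref].append(sec)
    for ref, seq in references.items():
        if not any(s.role == "full" for s in out[ref]):
            out[ref].append(SectionAnnotation("full", "full", 1, len(seq)))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read reference sequences from FASTA (wrapped or unwrapped).

    Sequences are uppercased and U is normalized to T (the study model stores
    DNA-alphabet references).
    """
    refs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in refs:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        refs[record.id] = str(record.seq).upper().replace("U", "T")
    if not refs:
        raise FormatError(f"{path}: no FASTA records found")
    return refs


def write_fasta(references: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in references.items():
            fh.write(f">{name}\n{seq}\n")
    return path
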