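"""Harmonize third-party probing outputs into the study model.

Two upstream formats are supported:

* **ShapeMapper2-style profile tables** (``*_profile.txt``): tab-separated,
  one row per nucleotide. Only the modified-channel columns are mandatory
  (``Nucleotide``, ``Sequence``, ``Modified_mutations``,
  ``Modified_effective_depth``; header match is case-insensitive). Untreated/
  denatured channels, if present, are carried along in provenance but unused:
  the study model is count-based DMS-MaPseq data without background
  subtraction.

* **RNA-Framework-style per-transcript count files**, in either of two
  documented dialects (see ``docs/formats.md``): an XML flavor with
  ``<transcript id>``/``<sequence>``/``<count>``/``<coverage>`` elements, or a
  plain-text flavor with four lines per record (``>id``, sequence,
  comma-separated counts, comma-separated coverage). Files carrying only
  normalized reactivities (non-integer values, or ``<reactivity>`` elements)
  are rejected: raw counts are required.

Conversion preserves counts exactly and computes fractions through the same
code path as the study model. Converters never invent a substitution
breakdown; ``sub_counts`` stays ``None`` so identity plots report
"unavailable" rather than zeros.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .study import PositionProfile, SampleRecord, SectionAnnotation, Study

_SM_REQUIRED = ("nucleotide", "sequence", "modified_mutations", "modified_effective_depth")


def _full_section(sequence: str) -> SectionAnnotation:
    return SectionAnnotation("full", "full", 1, len(sequence))


def _check_fasta(reference: str, sequence: str, fasta: Mapping[str, str] | None) -> None:
    if fasta is None:
        return
    if reference not in fasta:
        raise ValidationError(
            f"reference {reference!r} not present in the supplied FASTA "
            f"({sorted(fasta)})"
        )
    if fasta[reference] != sequence:
        raise ValidationError(
            f"reference {reference!r}: sequence in the converted file disagrees "
            f"with the supplied FASTA"
        )


def _assemble(sample: str, profiles: list[PositionProfile], source: dict) -> Study:
    study = Study(provenance={"source": source})
    rec = SampleRecord(sample=sample)
    for prof in profiles:
        seq = "".join(prof.base)
        study.references[prof.reference] = seq
        study.sections[prof.reference] = [prof.section]
        rec.profiles[(prof.reference, prof.section.name)] = prof
    study.samples[sample] = rec
    study.validate()
    return study


def from_shapemapper(
    profile_path: str | Path,
    sample: str,
    reference: str,
    fasta: Mapping[str, str] | None = None,
) -> Study:
    """Convert a ShapeMapper2-style profile table into a one-sample study.

    ``mutated`` is taken from Modified_mutations and ``coverage`` from
    Modified_effective_depth; the reference sequence is rebuilt from the
    Sequence column (U normalized to T). Gaps in the position column are
    filled with N bases at zero coverage; non-monotone positions are an error.
    """
    profile_path = Path(profile_path)
    table = pd.read_csv(profile_path, sep="\t")
    colmap = {c.strip().lower(): c for c in table.columns}
    missing = [c for c in _SM_REQUIRED if c not in colmap]
    if missing:
        raise FormatError(
            f"{profile_path}: missing mandatory column(s) {missing}; found "
            f"{list(table.columns)}"
        )
    pos = table[colmap["nucleotide"]].to_numpy(dtype=int)
    if len(pos) == 0:
        raise FormatError(f"{profile_path}: empty profile table")
    if np.any(np.diff(pos) <= 0):
        raise FormatError(f"{profile_path}: Nucleotide positions must be strictly increasing")
    seq_col = table[colmap["sequence"]].astype(str).str.upper().str.replace("U", "T")
    muts = table[colmap["modified_mutations"]].to_numpy(dtype=int)
    depth = table[colmap["modified_effective_depth"]].to_numpy(dtype=int)

    length = int(pos[-1])
    bases = np.full(length, "N", dtype="U1")
    coverage = np.zeros(length, dtype=int)
    mutated = np.zeros(length, dtype=int)
    bases[pos - 1] = seq_col.to_numpy(dtype="U1")
    coverage[pos - 1] = depth
    mutated[pos - 1] = muts

    sequence = "".join(bases)
    _check_fasta(reference, sequence, fasta)
    prof = PositionProfile(
        reference=reference,
        section=_full_section(sequence),
        positions=np.arange(1, length + 1),
        base=bases,
        coverage=coverage,
        mutated=mutated,
        sub_counts=None,
    )
    extra_cols = [c for c in table.columns if c.strip().lower() not in _SM_REQUIRED]
    source = {
        "tool": "shapemapper2",
        "path": str(profile_path),
        "extra_columns": extra_cols,
    }
    if extra_cols:
        source["extra_data"] = {c: table[c].tolist() for c in extra_cols}
    return _assemble(sample, [prof], source)


# ---------------------------------------------------------------------------
# RNA-Framework-style count files
# ---------------------------------------------------------------------------

def _int_vector(raw: str, context: str) -> np.ndarray:
    vals = [v.strip() for v in raw.strip().split(",") if v.strip() != ""]
    out = np.empty(len(vals), dtype=int)
    for i, v in enumerate(vals):
        f = float(v)
        if f != int(f):
            raise FormatError(
                f"{context}: non-integer value {v!r} — this looks like normalized "
                f"reactivities; raw counts are required"
            )
        out[i] = int(f)
    return out


def _rnaf_records_xml(text: str, context: str):
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise FormatError(f"{context}: XML parse failure ({exc})") from exc
    transcripts = root.findall(".//transcript")
    if root.tag == "transcript":
        transcripts = [root]
    for t in transcripts:
        tid = t.get("id")
        if tid is None:
            raise FormatError(f"{context}: <transcript> without an id attribute")
        if t.find("reactivity") is not None and t.find("count") is None:
            raise FormatError(
                f"{context}: transcript {tid!r} carries only <reactivity> values; "
                f"raw <count>/<coverage> are required"
            )
        seq_el, cnt_el, cov_el = t.find("sequence"), t.find("count"), t.find("coverage")
        for el, name in ((seq_el, "sequence"), (cnt_el, "count"), (cov_el, "coverage")):
            if el is None or el.text is None:
                raise FormatError(f"{context}: transcript {tid!r} lacks <{name}>")
        seq = "".join(seq_el.text.split()).upper().replace("U", "T")
        yield tid, seq, _int_vector(cnt_el.text, f"{context}:{tid}"), _int_vector(
            cov_el.text, f"{context}:{tid}"
        )


def _rnaf_records_text(lines: list[str], context: str):
    block: list[str] = []
    for line in lines + [""]:
        line = line.strip()
        if line:
            block.append(line)
            continue
        if not block:
            continue
        if len(block) != 4 or not block[0].startswith(">"):
            raise FormatError(
                f"{context}: expected 4-line records ('>id', sequence, counts, "
                f"coverage) separated by blank lines"
            )
        tid = block[0][1:].strip()
        seq = block[1].upper().replace("U", "T")
        yield tid, seq, _int_vector(block[2], f"{context}:{tid}"), _int_vector(
            block[3], f"{context}:{tid}"
        )
        block = []


def from_rnaframework(
    counts_path: str | Path,
    sample: str,
    fasta: Mapping[str, str] | None = None,
) -> Study:
    """Convert an RNA-Framework-style per-transcript count file into a study.

    One PositionProfile per transcript; fractions are counts/coverage. An
    empty record list yields an empty (but valid) study.
    """
    counts_path = Path(counts_path)
    text = counts_path.read_text()
    if text.lstrip().startswith("<"):
        records = list(_rnaf_records_xml(text, str(counts_path)))
    else:
        records = list(_rnaf_records_text(text.splitlines(), str(counts_path)))

    profiles = []
    for tid, seq, counts, coverage in records:
        if len(counts) != len(seq) or len(coverage) != len(seq):
            raise ValidationError(
                f"{counts_path}: transcript {tid!r}: sequence length {len(seq)} but "
                f"{len(counts)} counts / {len(coverage)} coverage values"
            )
        _check_fasta(tid, seq, fasta)
        profiles.append(
            PositionProfile(
                reference=tid,
                section=_full_section(seq),
                positions=np.arange(1, len(seq) + 1),
                base=list(seq),
                coverage=coverage,
                mutated=counts,
                sub_counts=None,
            )
        )
    return _assemble(sample, profiles, {"tool": "rnaframework", "path": str(counts_path)})
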