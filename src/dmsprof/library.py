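"""Synthetic amplicon-library design and DMS-MaPseq signal simulation.

The library design follows the standard recipe for pooled structure-probing
libraries of short RNAs: every member shares common forward/reverse primers
(non-biased amplification), carries a member-specific barcode for
demultiplexing (all barcode pairs at Hamming distance >= 4), and is padded to
one common total length (default 170 nt) with unstructured flanking sequences
made only of C and U (emitted as T in DNA context), regenerated whenever a
run of identical bases longer than 3 appears.

The simulator emulates an amplicon DMS-MaPseq experiment at the signal
level — downstream of alignment and mutation calling, which are out of
scope. Each member carries a planted ground truth: a pairing state per
position (from a toy alternating stem/loop generator or user-supplied), a
responder flag, and binding-site positions. Per read, mutation events are
independent per-position Bernoulli draws with probability

* ``p_unpaired`` at unpaired A/C (DMS-accessible),
* ``p_paired`` at paired A/C,
* ``p_background`` at G/U,

each multiplied by a per-position lognormal jitter fixed in the truth (so
replicates share it). With ligand present, a responder adopts its bound
conformation: a fixed member-specific subset of ROI pairing states flips
(the aptamer rearrangement) and binding-site probabilities are multiplied
by the protection factor. Reads are simulated
individually so mutations-per-read histograms are genuine; a fixed share of
mutation events are deletions (counted in ``mutated`` but not in
``sub_counts``), the rest substitutions with a uniformly random non-reference
target base. A chemistry label other than "U" (pseudouridine-like) flips a
random subset of pairing states per affected member and disables ligand
switching, emulating modification-driven structural rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FeasibilityError, ValidationError
from .selection import DEFAULT_BASES
from .stats import mutations_per_read_histogram
from .study import (
    PositionProfile,
    SampleRecord,
    SectionAnnotation,
    Study,
    mutation_fraction,
)

FORWARD_PRIMER = "TTAAACCGGCCAACATACC"
REVERSE_PRIMER = "TCGAAAGGAACGAGTAGCG"
_ALPHABET = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Design primitives
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences."""
    if len(a) != len(b):
        raise ValidationError(
            f"Hamming distance undefined for lengths {len(a)} != {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def _ball_volume(length: int, radius: int) -> int:
    """Number of sequences within Hamming distance `radius` of a fixed one."""
    return sum(comb(length, i) * 3**i for i in range(radius + 1))


def design_barcodes(
    n: int,
    length: int = 8,
    min_hamming: int = 4,
    seed: int = 0,
    max_attempts_per_barcode: int = 2000,
) -> list[str]:
    """Design ``n`` barcodes of ``length`` nt with all pairwise Hamming
    distances >= ``min_hamming`` by seeded rejection sampling.

    Requests violating the sphere-packing or Singleton upper bounds for a
    code with this minimum distance are rejected up front; otherwise a
    rejection-sampling budget guards against the greedy search stalling, with
    the error suggesting longer barcodes.
    """
    if n < 1 or length < 1 or min_hamming < 1:
        raise ValidationError("n, length and min_hamming must all be >= 1")
    if min_hamming > length:
        raise FeasibilityError(
            f"min_hamming={min_hamming} exceeds barcode length {length}"
        )
    # Provable infeasibility: Hamming (sphere-packing) and Singleton bounds.
    packing = 4**length // _ball_volume(length, (min_hamming - 1) // 2)
    singleton = 4 ** (length - min_hamming + 1)
    if n > min(packing, singleton):
        raise FeasibilityError(
            f"no code of {n} barcodes with length {length} and minimum distance "
            f"{min_hamming} can exist (upper bound {min(packing, singleton)}); "
            f"use longer barcodes"
        )
    rng = np.random.default_rng(seed)
    kept = np.empty((0, length), dtype=np.int8)
    attempts = 0
    while len(kept) < n:
        attempts += 1
        if attempts > max_attempts_per_barcode * n:
            raise FeasibilityError(
                f"rejection-sampling budget exhausted after {attempts} attempts "
                f"({len(kept)}/{n} barcodes found); use longer barcodes or a "
                f"smaller minimum distance"
            )
        cand = rng.integers(0, 4, size=length, dtype=np.int8)
        if len(kept) and int((kept != cand).sum(axis=1).min()) < min_hamming:
            continue
        kept = np.vstack([kept, cand])
    return ["".join(_ALPHABET[row]) for row in kept]


def design_flank(
    length: int, max_run: int = 3, seed: int = 0, as_rna: bool = False,
    max_attempts: int = 10000
) -> str:
    """Generate an unstructured flanking sequence of C and U (T in DNA).

    Bases are drawn i.i.d. with equal C/U probability and the whole sequence
    is regenerated whenever it contains a run of identical bases longer than
    ``max_run`` — equivalent, for the stated constraint, to shuffling a fixed
    C/U pool and filtering. The attempt cap only matters for pathological
    length/max_run combinations.
    """
    if length < 0:
        raise ValidationError("flank length must be >= 0")
    if length == 0:
        return ""
    if max_run < 1:
        raise ValidationError("max_run must be >= 1")
    letters = np.array(["C", "U" if as_rna else "T"])
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        draw = rng.integers(0, 2, size=length)
        if max_run_length(draw) <= max_run:
            return "".join(letters[draw])
    raise FeasibilityError(
        f"could not draw a length-{length} flank with max run {max_run} in "
        f"{max_attempts} attempts"
    )


def max_run_length(seq) -> int:
    """Longest run of identical consecutive symbols (0 for empty input)."""
    arr = np.asarray(list(seq) if isinstance(seq, str) else seq)
    if len(arr) == 0:
        return 0
    boundaries = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate([[0], boundaries + 1, [len(arr)]])
    return int(np.diff(starts).max())


# ---------------------------------------------------------------------------
# Library assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryDesignSpec:
    """Design parameters for an equal-length amplicon library."""

    roi_sequences: tuple[tuple[str, str], ...]  # (name, sequence) pairs
    total_length: int = 170
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    barcode_length: int = 8
    min_barcode_hamming: int = 4
    max_cu_run: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_barcode_hamming < 1:
            raise ValidationError("min_barcode_hamming must be >= 1")
        names = [n for n, _ in self.roi_sequences]
        if len(names) != len(set(names)):
            raise ValidationError("ROI names must be unique")


@dataclass
class LibraryMember:
    """One assembled member: full sequence plus its segment layout.

    ``segments`` maps role -> (start, end), 1-based inclusive; zero-length
    segments (e.g. a flank of length 0) are omitted. The segments partition
    the full sequence.
    """

    name: str
    sequence: str
    segments: dict[str, tuple[int, int]]

    def segment_seq(self, role: str) -> str:
        start, end = self.segments[role]
        return self.sequence[start - 1 : end]

    def sections(self) -> list[SectionAnnotation]:
        secs = [
            SectionAnnotation(role, role, start, end)
            for role, (start, end) in self.segments.items()
        ]
        secs.append(SectionAnnotation("full", "full", 1, len(self.sequence)))
        return secs


def assemble_library(spec: LibraryDesignSpec) -> list[LibraryMember]:
    """Assemble the library: per member primer5 + barcode + flank5 + ROI +
    flank3 + primer3, padded with C/U flanks to one common total length.

    The 5' flank takes the larger half when the padding is odd. ROIs too long
    to fit are reported together in one error.
    """
    fixed = (
        len(spec.forward_primer) + len(spec.reverse_primer) + spec.barcode_length
    )
    offenders = [
        (name, len(seq))
        for name, seq in spec.roi_sequences
        if fixed + len(seq) > spec.total_length
    ]
    if offenders:
        raise ValidationError(
            f"ROI(s) too long for total_length={spec.total_length} (fixed "
            f"segments use {fixed} nt): {offenders}"
        )
    rng = np.random.default_rng(spec.seed)
    barcodes = design_barcodes(
        len(spec.roi_sequences),
        length=spec.barcode_length,
        min_hamming=spec.min_barcode_hamming,
        seed=int(rng.integers(2**31 - 1)),
    )
    members = []
    for (name, roi), barcode in zip(spec.roi_sequences, barcodes):
        roi = roi.upper().replace("U", "T")
        pad = spec.total_length - fixed - len(roi)
        flank5_len = pad - pad // 2
        flank3_len = pad // 2
        flank5 = design_flank(
            flank5_len, spec.max_cu_run, seed=int(rng.integers(2**31 - 1))
        )
        flank3 = design_flank(
            flank3_len, spec.max_cu_run, seed=int(rng.integers(2**31 - 1))
        )
        parts = [
            ("primer5", spec.forward_primer),
            ("barcode", barcode),
            ("flank5", flank5),
            ("roi", roi),
            ("flank3", flank3),
            ("primer3", spec.reverse_primer),
        ]
        segments: dict[str, tuple[int, int]] = {}
        cursor = 1
        for role, seq in parts:
            if len(seq) == 0:
                continue
            segments[role] = (cursor, cursor + len(seq) - 1)
            cursor += len(seq)
        members.append(
            LibraryMember(
                name=name,
                sequence="".join(seq for _, seq in parts),
                segments=segments,
            )
        )
    return members


def sections_frame(members: Sequence[LibraryMember]) -> pd.DataFrame:
    """Sections annotation table (CSV-ready) for an assembled library."""
    rows = [
        {"reference": m.name, "section": s.name, "start": s.start, "end": s.end,
         "role": s.role}
        for m in members
        for s in m.sections()
    ]
    return pd.DataFrame(rows, columns=["reference", "section", "start", "end", "role"])


def random_roi_set(
    n: int, length: int = 100, seed: int = 0, prefix: str = "member"
) -> tuple[tuple[str, str], ...]:
    """Random ROI sequences (uniform A/C/G/T) for synthetic studies."""
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n)))
    return tuple(
        (f"{prefix}_{i + 1:0{width}d}",
         "".join(_ALPHABET[rng.integers(0, 4, size=length)]))
        for i in range(n)
    )


# ---------------------------------------------------------------------------
# Simulation ground truth
# ---------------------------------------------------------------------------

def toy_pairing(length: int, stem: int = 4, loop: int = 3, phase: int = 0) -> np.ndarray:
    """Toy alternating stem/loop pairing truth: ``stem`` paired positions,
    then ``loop`` unpaired, repeating. Returns True at unpaired positions."""
    period = stem + loop
    offsets = (np.arange(length) + phase) % period
    return offsets >= stem


@dataclass
class SimulationTruth:
    """Planted ground truth for one member (full-length arrays)."""

    member: str
    unpaired: np.ndarray  # bool per position, True = unpaired
    responder: bool
    binding_site: np.ndarray  # 1-based positions, subset of unpaired A/C
    jitter: np.ndarray  # per-position multiplicative rate jitter
    seed: int
    p_unpaired: float = 0.02
    p_paired: float = 0.002
    p_background: float = 0.001
    protection_factor: float = 0.1
    depth: int = 5000
    deletion_rate: float = 0.1
    switch_flip_frac: float = 0.25
    chemistry_effect_prob: float = 0.6
    chemistry_flip_frac: float = 0.3

    def validate(self, sequence: str) -> None:
        for p in (self.p_unpaired, self.p_paired, self.p_background):
            if not (0 < p < 1):
                raise ValidationError(
                    f"{self.member}: rate parameters must lie in (0, 1)"
                )
        if not (0 < self.protection_factor < 1):
            raise ValidationError(
                f"{self.member}: protection_factor must lie in (0, 1)"
            )
        if len(self.unpaired) != len(sequence):
            raise ValidationError(f"{self.member}: pairing truth length mismatch")
        if self.responder and len(self.binding_site):
            idx = self.binding_site - 1
            bases = np.array(list(sequence))[idx]
            if not (self.unpaired[idx].all() and np.isin(bases, ["A", "C"]).all()):
                raise ValidationError(
                    f"{self.member}: binding site must consist of unpaired A/C "
                    f"positions"
                )

    def rates(self, sequence: str, unpaired: np.ndarray | None = None) -> np.ndarray:
        """Per-position per-read mutation probability for a given pairing
        state (no ligand applied)."""
        if unpaired is None:
            unpaired = self.unpaired
        bases = np.array(list(sequence), dtype="U1")
        is_ac = np.isin(bases, ["A", "C"])
        rates = np.where(
            is_ac,
            np.where(unpaired, self.p_unpaired, self.p_paired),
            self.p_background,
        )
        return np.clip(rates * self.jitter, 1e-6, 0.5)


def make_truth(
    members: Sequence[LibraryMember],
    n_responders: int = 4,
    responders: Sequence[str] | None = None,
    site_size: int = 10,
    rate_jitter_sd: float = 0.25,
    seed: int = 0,
    **params,
) -> dict[str, SimulationTruth]:
    """Build the planted ground truth for a library.

    Pairing comes from :func:`toy_pairing` (random phase per member);
    responders are drawn at random unless given explicitly; each responder's
    binding site is ``site_size`` unpaired A/C positions sampled from its ROI
    (all of them if fewer are available). ``params`` override the
    per-member rate/depth defaults of :class:`SimulationTruth`.
    """
    rng = np.random.default_rng(seed)
    names = [m.name for m in members]
    if responders is None:
        k = min(n_responders, len(names))
        responders = list(rng.choice(names, size=k, replace=False)) if k else []
    unknown = set(responders) - set(names)
    if unknown:
        raise ValidationError(f"responder names not in library: {sorted(unknown)}")
    truth: dict[str, SimulationTruth] = {}
    for m in members:
        length = len(m.sequence)
        member_seed = int(rng.integers(2**31 - 1))
        mrng = np.random.default_rng(member_seed)
        unpaired = toy_pairing(length, phase=int(mrng.integers(7)))
        jitter = np.exp(mrng.normal(0.0, rate_jitter_sd, size=length))
        is_resp = m.name in responders
        site = np.array([], dtype=int)
        if is_resp:
            roi_start, roi_end = m.segments["roi"]
            pos = np.arange(roi_start, roi_end + 1)
            bases = np.array(list(m.segment_seq("roi")), dtype="U1")
            candidates = pos[
                np.isin(bases, ["A", "C"]) & unpaired[roi_start - 1 : roi_end]
            ]
            k = min(site_size, len(candidates))
            if k == 0:
                raise ValidationError(
                    f"{m.name}: no unpaired A/C positions in ROI to plant a "
                    f"binding site"
                )
            site = np.sort(mrng.choice(candidates, size=k, replace=False))
        t = SimulationTruth(
            member=m.name,
            unpaired=unpaired,
            responder=is_resp,
            binding_site=site,
            jitter=jitter,
            seed=member_seed,
            **params,
        )
        t.validate(m.sequence)
        truth[m.name] = t
    return truth


# ---------------------------------------------------------------------------
# Conditions and the simulator
# ---------------------------------------------------------------------------

_CHEMISTRIES = {"U": 0, "psi": 1, "m1psi": 2}


@dataclass(frozen=True)
class Condition:
    """One simulated sample: ligand presence, chemistry, extra variables."""

    name: str
    ligand: bool = False
    ligand_mM: float = 5.0
    chemistry: str = "U"
    variables: Mapping[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chemistry not in _CHEMISTRIES:
            raise ValidationError(
                f"unknown chemistry {self.chemistry!r}; expected one of "
                f"{sorted(_CHEMISTRIES)}"
            )

    def sample_variables(self) -> dict[str, dict]:
        out = {
            "adenine": {"value": self.ligand_mM if self.ligand else 0.0, "unit": "mM"},
            "chemistry": {"value": self.chemistry, "unit": None},
        }
        out.update({k: dict(v) for k, v in self.variables.items()})
        return out


def _chemistry_pairing(truth: SimulationTruth, chemistry: str) -> tuple[np.ndarray, bool]:
    """Pairing truth under a chemistry, and whether switching is enabled.

    Deterministic per (member, chemistry): derived from the member's own
    truth seed so every replicate and condition of the same chemistry sees
    the same perturbed structure.
    """
    if chemistry == "U":
        return truth.unpaired, True
    crng = np.random.default_rng([truth.seed, _CHEMISTRIES[chemistry]])
    unpaired = truth.unpaired.copy()
    if crng.random() < truth.chemistry_effect_prob:
        flip = crng.random(len(unpaired)) < truth.chemistry_flip_frac
        unpaired[flip] = ~unpaired[flip]
    return unpaired, False  # modification disables ligand switching


def _simulate_member(
    member: LibraryMember,
    truth: SimulationTruth,
    condition: Condition,
    rng: np.random.Generator,
) -> tuple[dict[str, PositionProfile], np.ndarray]:
    """Simulate one member under one condition.

    Returns profiles (keyed by section name: full + every annotated segment
    role of interest) and the per-read mutation counts.
    """
    seq = member.sequence
    length = len(seq)
    unpaired, switching = _chemistry_pairing(truth, condition.chemistry)
    if condition.ligand and truth.responder and switching and len(truth.binding_site):
        # Ligand-bound conformation: the aptamer rearranges (a fixed,
        # member-specific subset of ROI pairing states flips — identical in
        # every ligand-bound sample) and binding-site bases are additionally
        # protected from methylation by the bound ligand.
        brng = np.random.default_rng([truth.seed, 3])
        bound = unpaired.copy()
        roi_start, roi_end = member.segments["roi"]
        in_roi = np.zeros(length, dtype=bool)
        in_roi[roi_start - 1 : roi_end] = True
        in_roi[truth.binding_site - 1] = False  # pocket stays unpaired
        flip = in_roi & (brng.random(length) < truth.switch_flip_frac)
        bound[flip] = ~bound[flip]
        rates = truth.rates(seq, unpaired=bound)
        rates[truth.binding_site - 1] *= truth.protection_factor
    else:
        rates = truth.rates(seq, unpaired=unpaired)

    depth = truth.depth
    if depth == 0:
        coverage = np.zeros(length, dtype=int)
        mutated = np.zeros(length, dtype=int)
        per_read = np.array([], dtype=int)
        subs = {b: np.zeros(length, dtype=int) for b in "ACGT"}
    else:
        hits = rng.random((depth, length)) < rates
        coverage = np.full(length, depth, dtype=int)
        mutated = hits.sum(axis=0).astype(int)
        per_read = hits.sum(axis=1).astype(int)
        # Deletions: a fixed share of mutation events; the rest are
        # substitutions with a uniform non-reference target base.
        deletions = rng.binomial(mutated, truth.deletion_rate)
        sub_total = mutated - deletions
        t1 = rng.binomial(sub_total, 1.0 / 3.0)
        t2 = rng.binomial(sub_total - t1, 0.5)
        t3 = sub_total - t1 - t2
        subs = {b: np.zeros(length, dtype=int) for b in "ACGT"}
        bases = np.array(list(seq), dtype="U1")
        for ref_base in "ACGT":
            targets = [b for b in "ACGT" if b != ref_base]
            at = bases == ref_base
            for target, counts in zip(targets, (t1, t2, t3)):
                subs[target][at] = counts[at]

    profiles: dict[str, PositionProfile] = {}
    for sec in member.sections():
        if sec.role not in ("full", "roi"):
            continue
        lo, hi = sec.start - 1, sec.end
        profiles[sec.name] = PositionProfile(
            reference=member.name,
            section=sec,
            positions=np.arange(sec.start, sec.end + 1),
            base=list(seq[lo:hi]),
            coverage=coverage[lo:hi],
            mutated=mutated[lo:hi],
            sub_counts={b: subs[b][lo:hi] for b in "ACGT"},
        )
    return profiles, per_read


def simulate_study(
    members: Sequence[LibraryMember],
    truth: Mapping[str, SimulationTruth],
    conditions: Sequence[Condition],
    seed: int = 0,
) -> Study:
    """Simulate a full study: one sample per condition, one profile pair
    (full + ROI sections) per member, read-level mutation histograms, and
    aligned-read tallies. Bit-identical output for identical arguments."""
    missing = [m.name for m in members if m.name not in truth]
    if missing:
        raise ValidationError(f"no simulation truth for member(s): {missing}")
    names = [c.name for c in conditions]
    if len(names) != len(set(names)):
        raise ValidationError("condition names must be unique")

    study = Study(
        provenance={
            "source": {"tool": "dmsprof-simulator", "seed": seed,
                       "conditions": list(names)}
        }
    )
    for m in members:
        study.references[m.name] = m.sequence
        study.sections[m.name] = m.sections()

    root = np.random.SeedSequence(seed)
    cond_seeds = root.spawn(len(conditions))
    for condition, cseed in zip(conditions, cond_seeds):
        rec = SampleRecord(sample=condition.name, variables=condition.sample_variables())
        member_seeds = cseed.spawn(len(members))
        for member, mseed in zip(members, member_seeds):
            t = truth[member.name]
            t.validate(member.sequence)
            profiles, per_read = _simulate_member(
                member, t, condition, np.random.default_rng(mseed)
            )
            for sec_name, prof in profiles.items():
                rec.profiles[(member.name, sec_name)] = prof
            rec.read_hists[member.name] = mutations_per_read_histogram(per_read)
            rec.aligned_reads[member.name] = int(t.depth)
        study.samples[condition.name] = rec
    study.validate()
    return study
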