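"""Shared fixtures: a small deterministic hand-built study and simulated
studies used across the suite. Everything is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import dmsprof as dp

ROI1 = "ACCAATCCAACATCCA"  # 14 A/C of 16
ROI2 = "CACCATACCTAACGCC"  # 13 A/C of 16
SEQ1 = "GGAC" + ROI1 + "GTGA"
SEQ2 = "TTAC" + ROI2 + "GGTT"


def _profile(ref, seq, section, offset):
    """Deterministic counts: coverage 2000, mutated varies with position."""
    lo, hi = section.start, section.end
    positions = np.arange(lo, hi + 1)
    n = len(positions)
    coverage = np.full(n, 2000)
    mutated = 5 + (positions * 13 + offset) % 50
    deletions = mutated // 10
    subs_total = mutated - deletions
    bases = np.array(list(seq[lo - 1 : hi]), dtype="U1")
    sub_counts = {b: np.zeros(n, dtype=int) for b in "ACGT"}
    for i, ref_base in enumerate(bases):
        targets = [b for b in "ACGT" if b != ref_base]
        t1 = subs_total[i] // 3
        t2 = (subs_total[i] - t1) // 2
        t3 = subs_total[i] - t1 - t2
        for b, c in zip(targets, (t1, t2, t3)):
            sub_counts[b][i] = c
    return dp.PositionProfile(
        reference=ref, section=section, positions=positions, base=bases,
        coverage=coverage, mutated=mutated, sub_counts=sub_counts,
    )


def build_golden_study() -> dp.Study:
    study = dp.Study()
    study.references = {"ref1": SEQ1, "ref2": SEQ2}
    for ref, seq in study.references.items():
        study.sections[ref] = [
            dp.SectionAnnotation("full", "full", 1, len(seq)),
            dp.SectionAnnotation("roi", "roi", 5, 20),
        ]
    for k, (sname, mg) in enumerate([("s0", 0.0), ("s10", 10.0)]):
        rec = dp.SampleRecord(
            sample=sname,
            variables={"MgCl2": {"value": mg, "unit": "mM"}},
        )
        for j, (ref, seq) in enumerate(study.references.items()):
            offset = 7 * k + 19 * j
            for sec in study.sections[ref]:
                rec.profiles[(ref, sec.name)] = _profile(ref, seq, sec, offset)
            reads = np.arange(120) % 7  # deterministic mutations-per-read
            rec.read_hists[ref] = dp.mutations_per_read_histogram(reads)
            rec.aligned_reads[ref] = 2000 + 50 * j + 10 * k
        study.samples[sname] = rec
    study.validate()
    return study


@pytest.fixture(scope="session")
def golden_study() -> dp.Study:
    return build_golden_study()


@pytest.fixture(scope="session")
def sim_library():
    """Small simulated library: 8 members, 2 planted responders."""
    rois = dp.library.random_roi_set(8, 100, seed=5)
    members = dp.assemble_library(dp.LibraryDesignSpec(roi_sequences=rois, seed=5))
    truth = dp.make_truth(members, n_responders=2, seed=5)
    return members, truth


@pytest.fixture(scope="session")
def sim_study(sim_library) -> dp.Study:
    """Three conditions: two no-ligand replicates plus one with ligand."""
    members, truth = sim_library
    conditions = [
        dp.Condition("rep1"),
        dp.Condition("rep2"),
        dp.Condition("plus", ligand=True),
    ]
    return dp.simulate_study(members, truth, conditions, seed=11)
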