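# File formats

## Study JSON dialect (schema_version "1")

The study file is a single JSON object with five top-level keys, written in
this order (see `docs/study_schema.json` for a machine-readable schema):

```json
{
 "schema_version": "1",
 "references": {"ref1": "TTAAACCGG...TAGCG"},
 "sections": {
  "ref1": [
   {"name": "roi", "role": "roi", "start": 40, "end": 112},
   {"name": "full", "role": "full", "start": 1, "end": 170}
  ]
 },
 "samples": {
  "sample_A": {
   "variables": {"MgCl2": {"value": 10.0, "unit": "mM"}},
   "aligned_reads": {"ref1": 5000},
   "read_hists": {
    "ref1": {"bin_edges": [0, 1, 2, 11], "counts": [100, 80, 20], "total_reads": 200}
   },
   "profiles": [
    {
     "reference": "ref1",
     "section": "roi",
     "positions": [40, 41],
     "base": "AC",
     "coverage": [5000, 5000],
     "mutated": [125, 10],
     "sub_counts": {"A": [0, 3], "C": [40, 0], "G": [40, 3], "T": [33, 3]},
     "fraction": [0.025, 0.002]
    }
   ]
  }
 },
 "provenance": {}
}
```

Conventions:

* **Coordinates are 1-based inclusive** everywhere (`start`/`end`,
  `positions`). A section with role `full` must span the whole reference.
* All profile arrays are **position-parallel**; `base` is a string with one
  character per position; `positions` must run contiguously from the
  section's `start` to its `end`.
* `fraction[i]` equals `mutated[i] / coverage[i]`; positions with zero
  coverage (or an `N` reference base) are **masked and encoded as `null`**.
  A profile without a `fraction` array gets one recomputed from counts on
  load; a stored array that disagrees with the counts is rejected.
* `mutated` counts any non-reference call (substitution or deletion);
  `sub_counts` covers substitutions only, so per position
  `sum(sub_counts) <= mutated`. `sub_counts` is `null` for converted data
  without a substitution breakdown.
* Section roles: `primer5`, `barcode`, `flank5`, `roi`, `flank3`, `primer3`,
  `full`.
* Unknown top-level keys are preserved under `provenance.extra_keys`, not
  rejected.
* Writing is deterministic: the same study always serializes to the same
  bytes (top-level key order fixed, profiles sorted by (reference, section)).

## Sections annotation table (CSV)

Columns: `reference, section, start, end, role` (1-based inclusive). One row
per named section. An implicit `full` section is added per reference when
absent. Example:

```
reference,section,start,end,role
ref1,roi,40,112,roi
ref1,bc,20,27,barcode
```

## Reference sequences (FASTA)

Standard FASTA, wrapped or unwrapped (read with Biopython). Sequences are
uppercased and U is normalized to T.

## ShapeMapper2-style profile table

Tab-separated with a header. Mandatory columns (case-insensitive):
`Nucleotide`, `Sequence`, `Modified_mutations`, `Modified_effective_depth`.
Positions must be strictly increasing; gaps are filled with `N` at zero
coverage. All other columns (untreated/denatured channels, reactivities) are
preserved in provenance but unused. The converted profile has
`mutated = Modified_mutations`, `coverage = Modified_effective_depth` and no
substitution breakdown.

## RNA-Framework-style count files

Two dialects, auto-detected:

**XML flavor** (first non-blank character `<`):

```xml
<data>
 <transcript id="tx1">
  <sequence>ACGU</sequence>
  <count>1,0,2,0</count>
  <coverage>100,100,100,0</coverage>
 </transcript>
</data>
```

**Text flavor**: four lines per record, blank-line separated:

```
>tx1
ACGU
1,0,2,0
100,100,100,0
```

Count and coverage vectors must match the sequence length. Files carrying
only normalized reactivities (non-integer values, or `<reactivity>` elements
without `<count>`) are rejected with an explanatory message: the study model
is count-based.
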