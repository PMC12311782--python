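# Methods

## The measurement being modelled

Dimethyl sulfate (DMS) methylates the Watson–Crick–Franklin face of
solvent-exposed, unpaired A and C bases. In mutational profiling (MaP),
reverse transcription converts each methylation adduct into a mutation, so
after sequencing and alignment the per-position **mutation fraction**

    f_i = mutated_i / coverage_i

is the reactivity signal: high at unpaired A/C, low at paired A/C, and near
the error floor at G and U/T, which DMS does not probe on this face. This
package starts downstream of alignment and mutation calling: its unit of
input is the per-position count table, organized as a *study* — samples,
each holding per-reference, per-section profiles (see `docs/formats.md`).

Fractions are masked (NaN in memory, `null` on disk) wherever coverage is
zero or the reference base is N; every statistic in the package is computed
only over positions unmasked in all of its inputs, and the reported `n` is
exactly that count. Selection (base subset, position range, coverage floor)
masks positions rather than dropping them, so views from different samples
always stay position-aligned. The coverage floor is inclusive
(`coverage >= min_coverage` keeps the position).

## Comparison statistics

`compare_profiles(p1, p2)` computes, over shared unmasked positions, with
x = sample-2 fractions and y = sample-1 fractions:

* Pearson r from centered sums, and R² reported as r² (for simple ordinary
  least squares the squared correlation and the regression R² coincide; this
  coincidence is unit-tested against `scipy.stats.linregress`);
* RMSE of (y − x), on raw (or, when requested, normalized) fractions with no
  transformation;
* the OLS slope and intercept of y on x, matching the plotting convention of
  sample 1 on the vertical axis with a best-fit line and the x = y identity
  line as the no-change null.

A constant vector leaves r undefined; it is reported as NaN with reason
`degenerate-variance`, never coerced to 0. Sample-versus-population variance
is immaterial for r (the normalization cancels); centered sums are used for
numerical stability on fraction-scale data.

`normalize_profiles` rescales sample 2 onto sample 1 with a single positive
factor. The default method `ls_origin` minimizes Σ(x − k·y)², giving
k = Σxy/Σy² over shared unmasked positions; `median_ratio` (median of x/y
where y > 0) is available as a robust alternative, and `none` applies factor
1. Scaled fractions above 1 are clipped and counted, with a warning. A
single multiplicative factor is the weakest correction that removes global
reactivity-scale differences (e.g. between chemistry conditions) without
reshaping profiles; it is deliberately not an outlier-trimmed or quantile
normalization.

## Quality control and the riboswitch screen

A reference passes QC for a sample pair only if **both** samples reach a
median region-of-interest (ROI) coverage of at least 1000 reads and expose
at least 10 unmasked A/C positions there. Both thresholds are
package-chosen defaults (1000x is a community floor below which MaP
fractions at the few-percent scale become noisy; 10 points is a minimal
basis for a meaningful correlation) and are overridable in the API and CLI.
Failures carry a reason code (`coverage`, `positions`, or `absent` for
references present in only one sample).

The screen computes, per QC-passing reference, the r² of ROI A/C fractions
between two samples, ranks references ascending (ties broken
lexicographically by name, so ranking is deterministic), and calls
**responders** strictly below the threshold, default r² < 0.6 (a reference
exactly at the threshold is not a responder). Normalization before
correlating is off by default — replicate and ligand comparisons share a
chemistry, where a global scale difference is not expected — and should be
switched on (`ls_origin`) when the samples differ in nucleotide chemistry
(uridine vs pseudouridine transcripts), where global reactivity rescaling
would otherwise masquerade as structural change.

`binding_site_protection` reports, for a supplied list of candidate
ligand-pocket positions, the fraction without ligand, with ligand, their
difference (with − without), and a per-position protected flag
(strictly negative difference).

## The synthetic library and simulator

The library designer reproduces the standard pooled-probing design for
short RNAs, with every member 170 nt:

    primer5 (19 nt) | barcode (8 nt) | flank5 | ROI | flank3 | primer3 (19 nt)

* Common primers `TTAAACCGGCCAACATACC` / `TCGAAAGGAACGAGTAGCG`.
* Barcodes: seeded rejection sampling until all pairwise Hamming distances
  are ≥ 4. Provably impossible requests (violating the sphere-packing or
  Singleton upper bounds) are rejected up front; a per-barcode attempt
  budget guards against the greedy search saturating (empirically it stalls
  near ~190 codes at length 8, distance 4 — use longer barcodes for larger
  libraries).
* Flanks: i.i.d. C/U (T in DNA output) draws, regenerated whole whenever a
  run of identical bases exceeds 3 — equivalent, for that constraint, to
  shuffling a fixed C/U pool and filtering. The 5′ flank takes the larger
  half of an odd padding.

The simulator emulates the experiment at the signal level. Each member
carries a planted truth:

| parameter | default | meaning |
|---|---|---|
| `p_unpaired` | 0.02 | per-read mutation probability, unpaired A/C |
| `p_paired` | 0.002 | per-read mutation probability, paired A/C |
| `p_background` | 0.001 | per-read mutation probability, G/T |
| `rate_jitter_sd` | 0.25 | sd of lognormal per-position rate multiplier |
| `protection_factor` | 0.1 | multiplier on binding-site rates with ligand |
| `switch_flip_frac` | 0.25 | ROI pairing states flipped in the bound state |
| `depth` | 5000 | reads per member per sample |
| `deletion_rate` | 0.1 | share of mutation events that are deletions |
| site size | 10 | binding-site positions per responder |

These magnitudes follow typical amplicon DMS-MaPseq practice: unpaired A/C
signal a few percent, an order of magnitude of paired/unpaired contrast,
G/T near the error floor, and ~10 protected pocket bases as in adenine
aptamers. Pairing truth comes from a toy alternating stem(4)/loop(3)
generator (or user-supplied masks) — deliberately not thermodynamic
folding, so the screen's ground truth is exact. The lognormal jitter is
drawn once per member and shared by all conditions and replicates, giving
profiles realistic position-to-position spread while keeping replicate
correlation driven purely by counting noise.

Reads are simulated individually (per-read Bernoulli at each position), so
mutations-per-read histograms are genuine rather than resampled from
aggregate counts. A responder with ligand adopts its *bound conformation*:
a fixed member-specific 25% of ROI pairing states flips, emulating aptamer
rearrangement, and binding-site rates are additionally multiplied by the
protection factor. Site protection alone would decorrelate the profiles far
less than real riboswitches do (observed replicate-to-ligand r² drops from
~0.98 to ~0.2 in published adenine-aptamer data), and the conformational
component reproduces that magnitude. A chemistry label other than `U`
(pseudouridine-like) flips a random ~30% of pairing states in ~60% of
members — structural rearrangement without ligand — and disables ligand
switching entirely, mirroring the loss of riboswitch function upon
pseudouridylation.

What the simulator does **not** model: reverse-transcription and sequencing
error profiles, read-length or coverage gradients across the amplicon,
correlated co-occurring mutations within a read, partial ligand occupancy,
or thermodynamically realistic ensembles. Passing tests therefore certify
the statistics, formats and screening logic under a clean binomial signal
model — not performance on real libraries with those artifacts.

## Problem sizes used in tests

The acceptance-level checks run the screen on 81-member libraries at depth
5000 over 50 seeds (recovery of 4 planted responders), a 200-reference null
replicate pair at depth 5000 (false-positive behavior), and calibration of
the estimator at depth 100,000 averaged over 20 replicate samples (so the
per-position *bias*, rather than one realization's counting noise, is what
is bounded). Unit tests use 1–10 member libraries at depths 1200–20,000.

## Determinism

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; the simulator spawns per-condition, per-member
child streams, so output studies are bit-identical for identical inputs.
Study serialization is byte-stable, and CLI runs record their full
parameterization in `run_log.json`.

## Known limitations

* The QC thresholds are defaults, not a reproduction of any published
  filter; published pass/fail counts cannot be regenerated from them.
* Converted third-party data lack a substitution breakdown; identity plots
  on such data raise an explicit "unavailable" error rather than showing
  zeros.
* The greedy barcode search is not a coding-theoretic constructor; near its
  saturation point it fails with an actionable error instead of degrading.
* HTML export embeds a static rendering; it is a shareable page, not an
  interactive figure.
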