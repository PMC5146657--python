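# Methods

## Marker model

SSR genotypes are modelled as *allele sets*: the distinct integer
fragment sizes (bp) called for a sample at a marker, with no copy
numbers. This dosage blindness is the central modelling choice — it is
what fragment analysis actually reports, and it is why the screen works
the way it does: a P-ploid can show at most P distinct alleles, and a
single-copy locus in a diploid at most two. Allele identity is exact
integer equality; no stutter/binning tolerance is applied, because the
inputs are already-called discrete alleles, not raw electropherogram
sizes (raw-trace processing is out of scope).

### Pedigree informativeness test

A full-sib family (two diploid parents, n progeny; the reference survey
used six) classifies each marker:

* **Cross type** from the parental allele-sharing pattern: AB × CD
  (both heterozygous, disjoint), AB × BC (one shared allele),
  AB × AB (identical heterozygotes), *uninformative* (a homozygous
  parent), *invalid* (a parent with >2 alleles — not single-copy).
  Only AB × CD and AB × BC make all four offspring classes
  distinguishable.
* **Single-copy verdict**: every progeny call must be explainable as
  one maternal plus one paternal gamete. Three or more alleles flag
  `progeny_extra_allele`; an allele outside the parental union flags
  `progeny_allele_not_parental`; a single-allele progeny is legal only
  when that allele is obtainable from *both* parents (the AB × BC
  cross legitimately yields BB homozygotes) and otherwise flags
  `null_allele_signature`. A two-allele set inside the parental union
  but not decomposable as maternal × paternal (e.g. {A,B} under
  AB × CD) also carries the null flag: a silenced allele plus a
  co-migrating artefact is the usual wet-lab cause, and the enum has no
  separate category for it.

A verdict is issued from a single progeny upward; `n_progeny` is
recorded so callers can impose stricter floors. Detection of null
alleles is necessarily probabilistic — with silencing rate q and six
progeny under AB × CD, the chance that no allele is silenced anywhere
is (1−q)¹², so q = 0.3 is caught ≈ 98.6% of the time — and the test
suite checks this monotonicity by simulation.

### Variability statistics

Allele frequencies are estimated on a diploid panel with one ramet per
clone: each sample contributes two observations, a single-allele call
counting twice (the standard codominant homozygote convention —
treating it as missing would bias frequencies at AB × BC-derived
loci). Samples showing ≥3 alleles must be excluded first; mixing
ploidies makes dosage-blind counts unidentifiable, so the estimator
raises rather than guessing. Clonal deduplication keeps the
lexicographically first member of each clone group (deterministic
tie-break).

PIC uses the Botstein convention,
PIC = 1 − Σp² − (Σp²)² + Σp⁴ (the closed form of the pairwise double
sum); the cited source for the original survey's formula does not print
it, and this convention is the near-universal one for codominant SSRs
and matches the reported 0.34–0.79 scale. Markers observed monomorphic
get PIC exactly 0 and are never diagnostic. Selection keeps markers
with PIC strictly above the threshold (default 0.5), sorted by PIC
descending with marker-id tie-break, honouring a manual exclude list
(the "distinct and easily recordable alleles" judgement a statistic
cannot make).

### Candidate screen and clone detection

A sample's candidate class is determined solely by its maximum allele
count over diagnostic markers (missing cells skipped, never treated as
monomorphic): ≤2 → diploid, 3 → triploid candidate, 4 → tetraploid
candidate, ≥5 → higher candidate, nothing typed → unscorable. The
maximum — not a vote — is used because a single reliable three-allele
genotype at a validated single-copy locus is conclusive; all markers
attaining the maximum are reported so users can demand ≥2 supporting
markers. The error structure is one-sided: classes are never above the
true ploidy, but a polyploid homozygous enough can be missed, which is
why detection power grows with allele count and marker number (checked
by simulation).

Clone detection is exact multilocus identity — equal allele sets at
every co-typed marker, with at least `min_shared_markers` (default 5)
markers in common — closed transitively. No genetic-distance threshold
is used: with ~10 markers of PIC ≈ 0.6, two distinct genets matching at
every locus by chance is vanishingly improbable, and identity is the
defining property of ramets. Output ordering is deterministic
(lexicographic), so results are invariant to input sample order.

## Cytometry model

Ploidy follows from P_s = P_r × M_s / M_r with an internal diploid
reference; all instrument calibration cancels in the ratio.

### Peak detection

The G0/G1 peak finder is this package's own design (vendor software
performed this step in the original survey): histogram the events into
`n_bins` (default 512) equal-width bins over [0, max]; smooth with an
edge-padded moving average (window 5 bins — edge padding matters,
because zero-padding creates artificial boundary dips that lend
baseline ripple spurious prominence); major peaks are local maxima with
prominence ≥ 10% of the global maximum that also stand at least twice
the median bin height above the baseline (the latter rejects flat
streams); the *lowest-position* major peak is G0/G1, which excludes
G2/M nuclei and doublet aggregates at doubled positions. An initial
spread is taken from the full width at half maximum (σ ≈ FWHM/2.355,
floored at one bin width), the raw events are gated at ±2σ, and mean/sd
are recomputed from the gated events with one refinement pass around
the updated moments. CV% = 100·sd/mean. Near-delta streams fall back to
the modal bin when no neighbour-based maximum exists.

### Calling and QC

Ratios are reported rounded to two decimals, half away from zero, in
decimal arithmetic (the printed-precision edge cases 2.0655→2.07 and
0.99506→1.00 round exactly). The ploidy estimate is
reference_ploidy × ratio; the call is the nearest integer, flagged
ambiguous when the estimate sits more than 0.3 from it — the survey's
triploid lands at 2.94 and its most extreme diploid at 1.81, both
comfortably inside, while an exact midpoint (2.50) is flagged.
Replicates (three by default) are pooled by unweighted mean of means —
no weighting scheme is imposed — and QC passes only when *every*
replicate has CV < 5% and enough gated events; failing replicates are
flagged, never dropped. The published-table workflow calls ploidy on
the rounded ratio (matching printed semantics); the event-stream
workflow calls on the raw pooled ratio.

Event input is the canonical one-intensity-per-line CSV; negative
values are rejected with the offending line named. FCS container
ingestion is not implemented; exporting a channel to CSV is assumed.

## Synthetic data

The generator emulates the survey's data shapes, not its biology in
detail:

* **Markers**: distinct integer allele sizes in 150–450 bp (the
  surveyed amplicons ran 168–406 bp), frequencies from a symmetric
  Dirichlet (default concentration 1 in the base config; the bundled
  48-stand study uses concentration 5 and 6 alleles/marker, i.e.
  moderately even frequencies typical of highly variable SSRs).
  Markers are unlinked; nothing in the screening logic uses linkage.
* **Genotypes**: ploidy i.i.d. allele draws, each silenced
  independently at the null-allele rate, then collapsed to a set.
  Hardy–Weinberg proportions therefore hold per locus; inbreeding and
  population structure are not modelled.
* **F1 families**: one uniformly chosen allele per parent per progeny,
  then silencing; true gametes are recorded.
* **Cytometry streams**: mixture of Normal(μ, cv·μ) G0/G1 (μ scaled by
  ploidy/2 from the diploid unit position 10739), Normal(2μ) G2/M
  (default fraction 0.1 — only its doubled position matters, for
  testing the lowest-peak rule), and a zero-truncated exponential
  debris tail with mean μ/3 (default fraction 0.05) — a simple,
  standard stand-in; real debris spectra are instrument- and
  preparation-specific. Default CV 4.5% and 5,000 events per run sit
  at the survey's reported operating point (CV 2.61–4.97%, mean 4.47,
  ≥5,000 particles).

The bundled 48-stand default study mirrors the survey's composition:
one tree species all tetraploid (with a ramet trio), one 8:4
tetraploid:diploid (ramet pair), one shrub species 1 tetraploid : 11
diploid, one 1 triploid : 11 diploid (ramet pair).

What passing synthetic tests shows — and does not. They verify the
*logic*: one-sided screening, Mendelian bookkeeping, null-allele
signatures, peak-ratio arithmetic, clone identity, QC thresholds. They
do not exercise allele-calling noise (stutter, size drift between
runs), linked or structured populations, aneuploidy, endopolyploid
tissue, or instrument drift between sample and reference; real
deployments still need the wet-lab controls the original protocol
prescribes.

## Problem sizes and determinism

Simulation-backed checks use: 200 paired sample/reference cytometry
runs at 5,000 events across CV {2.6, 4.5}% and debris {0, 5, 10}% for
ploidy recovery; three seeds of the full 48-stand study (3 replicates ×
5,000 events per sample) end to end; 1,000 random frequency vectors for
the PIC oracle; and exhaustive enumeration for the Mendelian oracle.
All generators take a `numpy.random.Generator` or an integer seed and
are bit-reproducible; the acceptance script derives every stochastic
component from its single `--seed`.

## Known limitations

* Ploidy from markers is a lower bound by construction; the package
  reports candidate classes, not certainties, and the cytometry stage
  is the arbiter.
* The peak finder assumes the G0/G1 peak is the lowest *major* mode;
  pathological debris distributions with a genuine low-position mode
  above the prominence and baseline thresholds would mislead it.
* Exact-identity clone detection treats any single genotyping
  discrepancy as evidence of distinct genets; allele-calling errors
  therefore split true clone groups rather than merging false ones.
* Aneuploid and >4× samples are classed only coarsely
  (`higher_candidate`; cytometry estimates remain continuous).
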