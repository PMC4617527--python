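# Methods

This note documents the statistical model, the defaults and the open design
choices in `plaquecall`.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Assay model

One animal's mutant plaques (typically 10²–10³) are pooled and amplified in
two independent PCR reactions, each sequenced as a barcoded deep amplicon
library.  The model underlying every stage is that a mutation carried by
*k* of the *n* pooled plaques contributes reads at proportion *k/n*, on top
of three error layers:

- **Positional background** ("false mutation proportion"): each (position,
  event) pair has a characteristic artefact rate that is stable *across*
  libraries (polymerase context errors, alignment artefacts, semiconductor
  homopolymer miscalls).  Because it is shared, the cross-library **median**
  of an event's read proportion estimates it robustly even when a few
  libraries carry the event as a real mutation: with a panel of ≥ 12
  libraries, a mutation private to one animal occupies only 2 of ≥ 12
  values and cannot move the median.  The estimator therefore includes the
  library under test by default (`estimate_noise(..., exclude=)` gives the
  leave-one-out variant; with an even panel the median is the mean of the
  two central order statistics).  Events never observed anywhere get
  background 0 — no pseudocount, so subtraction preserves raw signal and
  the calling threshold provides the guard.
- **Indel excess at homopolymers**: indel background can exceed anything
  seen for substitutions.  Indel events whose background is strictly above
  the *largest substitution background in the panel* (the indel cap) are
  masked from calling entirely; ties at the cap survive.
- **Replicate-specific PCR jackpots**: an early-cycle polymerase error
  propagates to ~2⁻ᶜ of one replicate's reads and can clear any threshold.
  These are uncorrelated between the two replicates, which is why a call
  requires the threshold in **both**.

## Calling

The threshold is `stringency × 1/n_plaques` with stringency 1.0 (default),
0.75 or 0.5.  Comparison is inclusive (≥): the source description says
"above", but ties at machine precision are immaterial at these magnitudes
and the inclusive rule is fixed for determinism.  Calls are per (position,
kind, detail): two alternate bases at one position are two independent
mutations.  Copy counts always divide by the stringency-1.0 expectation
`1/n_plaques` — regardless of calling stringency — so a count always means
"plaques among the pool"; rounding is half-up with floor 1 (the rounding
rule is not specified by the assay description; half-up is required to make
the published worked example (50 − 0.3123)/1.1363 = 43.7 → 44 come out under
either convention, whereas truncation would give 43).

A consequence of the threshold design worth knowing: a single-copy mutation
has *expected* proportion exactly at the stringent threshold, so binomial
sampling puts each replicate above it only about half the time.  Stringent
calling therefore recovers roughly 50–70 % of pooled plaques (multi-copy
mutations are recovered essentially always); the test suite asserts ≥ 50 %
on the default synthetic conditions.  Analyses that need sensitivity more
than specificity (e.g. clonality estimation) can use stringency 0.5, where
recovery is near-complete and the false-call rate is still negligible at
5×10⁴× depth.

## Clonality calibration (LOD/linear model)

Pooled sequencing cannot resolve low copy numbers, and above the resolvable
range the observed count inflates linearly.  Calibration mixtures of known
copy numbers are fit with a piecewise model: observed counts at or below a
limit of detection L collapse to a prediction of one copy; above L,
ordinary least squares of observed on expected.  The objective for a
candidate L is the total squared error — OLS residuals above, and for each
collapsed point the squared gap between its known copy number and 1 (the
below-LOD loss is not defined by the source; scoring the collapsed
prediction against the known truth is this package's choice).  L is
searched over [0, max expected] by a coarse grid refined with step-halving
around the running best until 1000 objective evaluations are spent, and is
reported as the integer count it implies.  When several L values give the
same below/above partition the objective is flat and the smallest such
integer may be returned; the *adjustment* is identical anywhere on the
plateau.  A pure-error lack-of-fit F-test on the above-LOD points is
reported when replicated expected counts allow it (informational, never a
gate).

Counts are inverted through `adjusted = max(1, round((observed −
intercept)/slope))` for observed > L, else 1.  When no calibration data are
supplied, the packaged default model (LOD 4, slope 1.1363, intercept
0.3123) — measured on this assay's own control mixtures — is used.
Clonality is `(total_adjusted − independent)/total_adjusted` per animal
(0 when no calls), and the corrected mutation frequency is
`(mutant_pfu/total_pfu) × (1 − clonality)`; group values are means of
per-animal values, and fold induction is the ratio of group means.

## Spectra and statistics

Substitutions are collapsed over complementary strands into six classes
(G:C→A:T, G:C→T:A, G:C→C:G, A:T→G:C, A:T→T:A, A:T→C:G; the first and
fourth are transitions), insertions and deletions are separate classes.
Spectra use independent mutations (each distinct event per animal weighs 1)
unless copy weighting is requested.  Group spectra are compared with
Pearson's chi-squared test of independence; when any expected cell is
below 5 the p-value is Monte-Carlo under fixed margins (multivariate
hypergeometric draws, 10⁵ by default, fixed seed 20151019 — small expected
counts are routine for rare classes).  Per-class comparisons use 2×2
chi-squared with Holm correction by default; the correction method is
configurable because no canonical choice exists for this assay.  Mutant
frequencies are compared by Poisson regression of mutant pfu with a
log(total pfu) offset and a group indicator (Wald p); a group with zero
mutants falls back to an exact conditional two-sample Poisson test,
flagged in the output.

Hotspots are positions whose independent-mutation count — distinct events
per animal, summed over animals — strictly exceeds a cutoff (default 4).
Homopolymer association counts indel calls inside or within 1 bp of
mononucleotide runs ≥ 3 bp.  The power simulation subsamples k mutants
without replacement from an animal's full mutation list and scores the
fraction of subsamples whose spectrum is *not* significantly different from
the full list (chi-squared goodness of fit, Monte-Carlo p under the
hypergeometric subsampling null); the comparison target and test are a
strategy interface because the original procedure is underspecified — a
callable metric can replace the default.

## Synthetic data generator

The generator defines the study conditions for all tests:

| parameter | default | rationale |
|---|---|---|
| depth per library | 5×10⁴ | the supported assay design sequences ~9×10⁴× per library; 5×10⁴ keeps full-scale simulations fast with the same statistical regime |
| n_plaques per pool | 300 | between the assay's control (~145) and treated (~500) pool sizes |
| clonal_fraction | 0.3 | probability a plaque duplicates an earlier plaque's mutation; yields per-animal clonality in the 30–45 % range typical of bone marrow |
| class probabilities | BaP-like | transitions 0.14, transversions 0.61, indels 0.25, dominated by G:C→T:A (0.38) and G:C→C:G (0.15); a spontaneous-like alternative (0.35/0.49/0.16) is provided |
| substitution noise | log-uniform 1.7×10⁻⁵–2.15×10⁻² | the observed background range for substitutions in this assay |
| indel noise | same range, ×10 at runs ≥ 3 bp | slippage-type errors concentrate at homopolymers; ×10 places roughly a third of homopolymer indel events above the indel cap, matching the fraction removed in practice |
| PCR jackpots | rate 10⁻³ per base per replicate | each at read fraction 2⁻ᶜ, c uniform in 3..11, substitutions; gives the concordance filter true negatives |
| mutant/total pfu | 8.6×10⁻⁵ (control), 701.7×10⁻⁵ (treated) of 5×10⁵ pfu | the assay's observed group mutant frequencies, Poisson-sampled per animal |

Counts are drawn by a per-position multinomial over that position's events
plus the reference remainder, so event counts can never exceed depth, and
the noise field is drawn once per study and shared by every library, while
truth mutations and PCR jackpots are per-sample and per-replicate
respectively.  Indels are generated and keyed left-aligned (one canonical
slippage insertion and deletion per same-base run), so emitted pileup text
re-parses to identical keys.  Fresh mutation draws are redrawn on collision
with an existing event in the same animal, so recurrent copies in the truth
arise from clonal duplication only and `clonal_fraction=0` yields
all-distinct singletons.  Each plaque carries exactly one driving mutation;
optional silent "hitchhiker" co-mutations are off by default.

What the generator does **not** emulate: read-level errors and quality
scores (no FASTQ), flowgram homopolymer signal beyond the rate multiplier,
alignment artefacts, coverage ramps at amplicon ends, plaque-size variation
in pooled studies (available in calibration mixtures as per-plaque weight
multipliers), and multi-nucleotide/complex mutations.  Passing tests
therefore demonstrate that the *statistical machinery* behaves correctly
under the assay's published noise magnitudes, not that any particular real
sequencing run is free of artefacts the model omits.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive on the reporter's coding strand
  throughout; insertions anchor to the position before the inserted bases,
  deletions to their first deleted base, both left-aligned.
- Zero-depth positions keep proportion 0 and are flagged, never dropped, so
  medians stay positionally aligned.
- Protein impacts are classified per single event against the unmutated
  codon (a substitution creating a stop is nonsense even if the codon
  carries another pool mutation); indels are frameshift unless length ≡ 0
  mod 3.
- "CpG stretches" are maximal alternating C/G substrings (no CC/GG inside)
  of length ≥ 5 by default; a stricter tandem-CG definition is selectable,
  since the census definition used in the field is not standardized.
- The Muta™Mouse colony carries a small number of fixed differences from
  the archival *lacZ* reference; `load_reference` applies a user-supplied
  variant list (default empty) and refuses mismatched reference bases.
- Full-scale simulations in the tests use a 3096-bp random toy gene — the
  real *lacZ* sequence is not redistributable here — and 6-sample panels
  (12 libraries), the smallest panel at which the median estimator has its
  intended robustness.

## Known limitations

- Copy counts are rough estimates; between the LOD plateau and rounding,
  per-animal clonality is reliable to roughly ±5–10 percentage points, and
  comparisons are most meaningful *between* groups processed identically.
- Single-copy mutations sit exactly at the stringent threshold, so
  stringent-threshold recovery is intrinsically partial (see Calling);
  spectra are unbiased by this dropout for substitutions, but indels are
  slightly under-represented because of the cap mask.
- The Monte-Carlo chi-squared and the power simulation condition on margins
  and subsampling respectively; they do not model between-animal
  overdispersion of spectra.
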