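# Methods

## Overview

`coopselex` decides, for one transcription factor with per-cycle HT-SELEX
read pools, whether the factor binds DNA as a cooperative homodimer, and if
so at which spacer length and orientation. The decision is a pure
conjunction of three lines of evidence computed on the same dimer model:
a motif screen on the final-cycle pool, an enrichment-rate comparison across
cycles, and a spacer-specificity test pair. Cooperativity strength measured
in vitro (Tau) is handled by an independent module operating on EMSA band
proportions.

## Motif representation and scanning

PWMs are L×4 row-stochastic matrices in A,C,G,T order. Per-column
information content is IC = 2 + Σ_b p_b log₂ p_b bits (0 uniform, 2 fixed
base), with 0·log 0 ≡ 0. Scanning scores windows by natural-log odds
against a uniform 0.25 background — the scale Homer writes into `.motif`
headers, so imported thresholds apply unchanged. A position containing N
contributes an effectively infinite penalty: N never matches. Reverse-strand
hits are reported at the forward-strand coordinate of the match's leftmost
base. Overlapping hits are all reported; deduplication is the caller's
concern, because spacer counting needs every placement.

`consensus_to_pwm` reproduces seq2profile-style semantics: consensus bases
get probability (1−(4−k)ε)/k (k = degenerate-code size), off-consensus bases
ε = 10⁻³, and the match threshold is placed midway between the worst
sequence at ≤m mismatches and the best sequence at m+1, so thresholded
scanning equals Hamming-ball membership exactly (verified exhaustively over
all 256 4-mers in the suite). Default mismatches = 0 throughout the
counting stages; exposed in configuration.

## Dimer-site screen

Core sites are the pair of non-overlapping 4-column windows, ≥2 bp apart,
maximizing the sum of mean per-column IC; ties break to the leftmost first
window, then the smallest spacer. The three criteria:

1. both cores' mean IC > 0.6 bits (mean per-column IC, not summed — the
   0.6 threshold only makes sense on a 0–2 bit per-column scale);
2. each core's mean IC ≥ 1.5× the mean IC of the surrounding columns.
   "Surrounding" defaults to all non-core columns (flanks and spacer
   pooled); `flanks_only` and `spacer_only` are available. A motif whose
   per-column IC is flat — the signature of a few over-amplified sequences
   rather than many independent binders — fails this ratio regardless of
   how strong the cores are;
3. the motif occurs in ≥5% of final-cycle reads, both strands. Motifs
   imported from Homer are scanned at their own log-odds threshold. Motifs
   from internal discovery carry no externally calibrated threshold, so
   occurrence is counted as presence of the dimer configuration itself
   (both core consensus sites at the motif's spacer); a derived whole-PWM
   threshold proved far too permissive on clone-structured pools.

### Internal long-motif discovery

A deliberately lightweight stand-in for a full de-novo motif search, used
only when no Homer motifs are supplied. Gapped 4mer-pair seeds
(word, spacer 2–12, word), canonicalized with their reverse complements,
are counted per read. A seed is kept when (a) it occurs in ≥0.1% of
final-cycle reads, (b) its count exceeds 3× the number predicted by its two
words' independent per-position frequencies and a Poisson tail test at
p < 10⁻⁹ rejects that co-occurrence null (several hundred thousand candidate
seeds make mild fold excesses at small counts routine — and a strongly
selected *monomer* creates chance pairings at every spacer), and (c) its
read frequency is >2× that in the unselected library. For each top seed,
final-cycle reads containing it are aligned on the seed span and stacked
into a 16- or 18-column PWM. Shifted satellites of a strong seed can yield
additional models at neighboring spacers; each is screened and reported
independently, and the factor is called cooperative if any model passes.

## Enrichment factor

Per cycle, three read fractions are counted: reads with ≥1 full dimer
configuration (site1, exact spacer, site2, in the model's orientation; a
configuration and its full reverse complement are one event), and — among
reads with *no* dimer configuration — reads with ≥1 match to site1 and to
site2 respectively (masking; without it every dimer read would also count
as two monomer sites). Fractions rather than raw counts normalize unequal
pool sizes. Fold changes vs cycle 0 are linearized with the natural log; a
pseudocount of 0.5/|pool| guards cycle-0 zeros, which are routine for
15-bp configurations at 50k depth. Slopes come from OLS with free intercept
(PCR-efficiency offsets between cycle 0 and 1 land in the intercept and
cancel between the dimer and monomer fits, which share the treatment), over
all available cycles including cycle 0. EF = dimer slope over the mean of
the two monomer-site slopes; a non-positive mean monomer slope yields NaN,
never a spuriously "cooperative" negative ratio. EF > 2 is the positivity
gate.

## Spacer specificity

For each spacer s in 0–20 and orientation in {FF, FR, RF} (RR is the
reverse complement of FF and folds into it), the number of reads containing
the two-site configuration is tabulated; a read contributes at most once
per cell. Cells whose configuration cannot fit the read length are marked
unobservable and excluded from testing rather than zero-filled — zeros
there would fabricate outlier evidence.

* **Grubbs max test** (one-sided, single maximum): G = (max−mean)/sd with
  p = n·SF_t(τ, n−2), τ² = n(n−2)G²/((n−1)²−nG²). Calibration is exact
  under the Gaussian null (measured rejection 0.052 at α = 0.05 over 20k
  replicates). On strongly right-skewed counts (e.g. iid Poisson with small
  mean) the max-outlier rejection rate inflates to ~0.07 — a property of
  the test, mitigated here by requiring the chi-square test to reject as
  well.
* **Chi-square independence** on the 2×K cycle-by-spacer table, expected
  counts from margins, dof K−1; cells with expected < 1 are pooled into a
  neighbor toward the range center first.

Both tests run per orientation with Bonferroni correction across the
orientations examined; the orientation with the smallest Grubbs p is
reported. A spacer is called — the argmax cell of the final-cycle counts —
only when both corrected p-values are < α = 0.05. Grubbs runs on raw
counts (equivalent to proportions for the outlier decision at fixed total).
The same counting applies unchanged to genomic peak regions
(BED + genome FASTA), where the per-spacer profile of called peaks can be
tested for the same configuration preference.

## Tau from EMSA band proportions

τ = 4[P₂D][D]/[PD]², per binding reaction. Inputs are per-lane band
proportions (or raw intensities with `--normalize`); lanes with [PD] below
0.01 are excluded from summaries (τ diverges) and reported. Group
comparisons use the two-sided unpaired Student t-test, equal-variance by
default with Welch as an option. K_d1 and K_d2 are never estimated; τ is
exactly the fold-facilitation of the second binding event. For independent
per-site occupancy p the proportions are binomial (p², 2p(1−p), (1−p)²) and
τ = 1 identically — the null the suite property-tests across p.

## Synthetic data generators

### SELEX

The generator emulates a random fixed-length oligo library under
binding-probability-weighted selection. Defaults mirror the study
conditions the pipeline is designed for: 50,000 reads per cycle, 20-bp
reads, 4 selection cycles, TAAT cores, planted spacer 7 (the layout of the
canonical cooperative HD dimer site), monomer weight 5, selection
stringency 0.2 (fraction of the pool retained per round), PCR modeled as
multinomial resampling to constant depth.

Each read's selection weight is

    w = 1 + mw·m + mw·ω·d

where d counts planted-spacer configurations and m counts core-site matches
(either strand) as a maximal *non-overlapping* set lying outside any
configuration footprint — overlapping proteins cannot bind simultaneously,
and without this rule tandem TAATTAAT reads pick up a spurious embedded
ATTA match that manufactures a spacer-0 enrichment artifact. ω is defined
as the fold advantage of the paired configuration over a single binding
event: at ω = 1 a dimer-configuration read enriches exactly like a
single-site read, making dimer and monomer ln-fold-change slopes equal in
expectation (EF → 1), and ω ≫ 1 produces the faster dimer enrichment the
pipeline detects. A quadratic dimer term (mw²·ω·d) was considered and
rejected: it makes EF ≈ 1.8 at ω = 1, i.e. "independent" simulations would
not be independent by the pipeline's own measure.

The physical pool is simulated at `population_size` molecules (default
10× the read output) and each cycle's returned pool is a fresh
`library_size` subsample — real libraries carry molecular diversity many
orders beyond sequencing depth, and simulating the physical pool at
sequencing depth produces founder/clone artifacts (jagged spacer counts,
spurious Grubbs outliers, wildly variable EF) that real pools do not show
at the spacer-cell level. Selection uses the Gumbel top-k race, an exact
weighted sampler without replacement.

What the generator does **not** emulate: sequence-dependent PCR bias (a
GC-bias hook exists but is off by default), polymerase error, sequencing
error or quality, read-length mixtures, and protein-concentration changes
across cycles. Passing tests therefore demonstrate correct recovery of the
generative model's signal at desk scale, not robustness to every artifact
of production HT-SELEX.

### EMSA

Equilibrium proportions for a two-site probe: D : PD : P₂D = 1 : 2a : ωa²
with a = [P]/K_d1 and K_d2 = K_d1/ω, normalized per lane; Gaussian noise of
configurable sd is added to proportions, clipped and renormalized.
Noiseless lanes satisfy τ ≡ ω algebraically, which the suite asserts.

## Numerical and engineering choices

* All pool-scale counting runs on an integer-packed word matrix (4-mers as
  0–255 with a never-matching sentinel for N or padding) and 257-entry
  boolean lookup tables; brute-force string scans serve as oracles in the
  tests, never as the production path.
* Every stochastic step draws from one seeded `numpy` Generator recorded in
  the report; pipeline reruns with the same configuration and seed are
  byte-identical (the per-TF subsample of 50,000 reads is drawn
  independently per cycle under that seed).
* Degenerate inputs are errors, not silent results: empty pools, missing
  cycle 0, fewer than 2 cycles, zero-variance Grubbs input (G = 0, p = 1),
  all-zero chi-square margins, τ with no monomer band.
* Problem sizes in the suite: simulation-recovery checks run 20 replicates
  of the full 50,000-read × 4-cycle condition; unit-level simulations use
  5–20k reads, chosen so the expected number of planted-configuration
  founder reads stays well above zero.

## Known limitations

* The internal discovery is a seeded heuristic, not a Homer replacement;
  faithful reproduction runs should import Homer `.motif` files.
* Heterodimers (CAP-SELEX-style pairs of different factors) are out of
  scope; both sites come from one factor's motif.
* The spacer range tested is bounded by read length; 20-bp reads observe
  spacers only up to 12 bp.
* Grubbs on skewed low-count cells is anticonservative (see above); the
  conjunction with chi-square, the Bonferroni across orientations, and the
  unobservable-cell exclusion are the guards.
* Tau assumes three cleanly separated bands; smeared gels or higher-order
  complexes violate the model upstream of this package.
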