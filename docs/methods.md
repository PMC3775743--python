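# Methods

## Repeat enumeration on a circle

The scanner compares the genome with a second copy of itself — identical for
direct repeats (DRs), reverse complemented for inverted repeats (IRs) — and
rolls the copies past each other one base per step. Each relative offset
("rotation state") is a diagonal (DR) or anti-diagonal (IR) of the
self-comparison matrix, and a candidate repeat is a window of consecutive
aligned positions on one diagonal. A full rotation visits every DR twice
(once per arm ordering) and every IR once, with both arms covered
simultaneously; canonical orientation (`arm1_start <= arm2_start`, ties by
arm end) plus coordinate keying removes the double count. All coordinates
are 1-based inclusive and computed modulo the genome length; a repeat arm
may wrap the origin, in which case `end < start`.

### Acceptance rule

For a window of length `l` with `m` mismatches (`i = l − m` matches), under
+1 match / −3 mismatch local scoring:

1. both window ends must be matches;
2. `l >= min_length` (default 2 bp — short repeats matter in aggregate
   because their abundance grows exponentially as length shrinks);
3. **default stringency**: `l >= 4(m+1)` for `m >= 1`. This is the package's
   formalization of "about one mismatch per three matches, but a little
   stricter": it implies a 3-mismatch repeat needs at least 16 bp, and makes
   the total alignment score `i − 3m = l − 4m >= 4` automatically;
4. **relaxed stringency** (`two mismatches per match`): `m <= 2i`, with the
   length budget of rule 3 dropped. Applying both would make the relaxed
   preset identical to the default (the budget already implies `m <= i/3`),
   so the two rules are alternatives, not layers;
5. **low-match valleys**: a maximal run of consecutive mismatches may be
   crossed only if it is at most `low_match_extension` (20) bp long, and a
   run of 4 or more mismatches only if the 4 bases on each side of the run
   match. Four consecutive matches is the break-even run under +1/−3
   scoring. Crossability is evaluated from the run's sequence context, not
   per window, which keeps the rule O(1) per window and symmetric under
   strand reversal.

Rules 3–5 are reconstructions of a verbally described procedure; the exact
formal rule is not derivable from the stated scoring alone, so the package
fixes one self-consistent version and validates its observable consequences
(the 16-bp/3-mismatch threshold, planted-repeat recovery, invariances).

### Maximality, families, arms

* Arms of one repeat may not overlap (for DRs this caps window length at
  `min(d, L−d)` for offset `d`; for IRs at the distance to the reflection
  fixed point of the anti-diagonal).
* A reported repeat is maximal: no acceptable window on any diagonal
  strictly contains both its arms. Containment is filtered within diagonals
  by an interval sweep and across diagonals by a vectorized arm-pair
  containment check (only strictly longer repeats can contain shorter ones).
* Within one diagonal, overlapping surviving windows form a family and only
  the best member (longest; ties broken by the start closest to the family's
  own circular hull start, which keeps the choice rotation-covariant) is
  reported. This collapses the quadratic self-overlap families of
  homopolymer and tandem tracts to one representative.
* `N` bases never match (conservative).

The fast scanner walks from the first match of each match run (plus the few
starts whose leftward extension is blocked by the arm-overlap cap) to the
farthest acceptable end using precomputed mismatch positions and
crossability prefix sums; full-cap sliding windows are swept in vectorized
form. The brute-force enumerator (`brute_force_repeats`, guarded to
genomes ≤ 2000 bp) instead enumerates every (start, end) pair on every
diagonal and applies the identical acceptance predicate and post-filters.
The test suite asserts set equality of the two on random circles of
300–500 bp for both repeat kinds and both stringency presets; the scanner is
O(L²) overall, so a full 16.5-kb mammalian genome takes minutes, while the
few-hundred-bp genomes used throughout the tests take fractions of a second.

### Junction descriptors

`locate_junction_repeat` answers "what repeat sits at this inversion
junction": starting from the junction bases (j1 on the plus strand, j2 on
the minus strand) it extends outward under +1/−3 scoring and returns the
match-terminated extension with the highest running score (ties to the
longer one), or None when the junction bases mismatch or nothing scores
positively. This is deliberately *not* the scan acceptance rule: observed
junctions include 0/0 and 1/1 bp descriptors that no scan would report.

## Mutagenic score

`score(i, l) = (i²/(25·l))^6`. The normalization length 25 bp makes the
longest near-perfect mammalian repeats score ≈ 1; with no mismatches the
weight reduces to `(l/25)^6`; the `i²/l` form penalizes mismatches smoothly
(`i = l` when perfect). The exponent 6 is the slope of the log-log
relationship between repeat length and deletion rate;
`fit_power_exponent` recovers it by weighted least squares on logs, with
default weights ∝ 1/l because short-repeat rate data are the most reliable.
Totals are sums over individual repeats; the headline statistic excludes the
D-loop by keeping only repeats with both arms inside the union of
gene/tRNA/rRNA/CDS annotations (a genome without a D-loop annotation is
scored in full, with a warning).

Stratifications: per repeat length and per match count (both exposed, since
either can serve as the x-axis of a deletion-spectrum comparison); per
spacer (shortest circular gap between the nearest arm ends, the package's
definition where none is standard); per genomic position, re-based so
tRNA-Phe starts at position 1 (the conventional mammalian anchor) with each
arm contributing half the repeat's score at its midpoint — a two-armed
repeat has no single canonical position, so the half-half split is the
package's documented choice.

Abundance subsampling keeps a repeat with `i` matches with probability
`3^(i−12)` (clamped to 1 for `i >= 12`), equalizing expected class counts
with the 12-match class; the base 3 rather than 4 compensates for the
quarter of shorter repeats hidden inside longer ones that maximality
filtering never counts.

## Comparative analysis

All variables are log₁₀-transformed (base 10 chosen for readability; the
statistics are base-invariant). Species with zero repeat score are dropped
at transform time with a logged count. Pearson and Spearman correlations
are two-tailed; Shapiro–Wilk on the residuals of the y-on-x least-squares
fit documents how far the data are from normality.

The taxonomy tree is merged from root-to-species lineage paths
(semicolon-joined in the species TSV; a Newick reader is provided for
interoperability). All branch lengths are 1; internal nodes with a single
child are collapsed so no edge is a non-splitting pass-through. Felsenstein
contrasts are computed post-order with the standard variance bookkeeping.
Polytomies get exactly one contrast: daughters are split into two groups at
the median of the independent variable (MLS), and the 1/v-weighted group
means are contrasted — a deliberate, documented reduction (a degree-d
polytomy therefore adds 1 contrast, not d−1); `polytomy="random"` instead
resolves each polytomy into seeded random cherries with zero-length
internal edges as a sensitivity check. Contrast pairs are polarized so the
MLS contrast is ≥ 0, the headline contrast statistic is Spearman's ρ, and
the secondary Pearson correlation is computed through the origin (standard
for contrasts) with n−1 degrees of freedom.

## qPCR arithmetic

The dilution-series slope is expressed as cycles per two-fold concentration
change (sign-normalized positive; 4X series are converted via log₂), so the
per-cycle amplification factor is `f = 2^(1/slope)`. Relative inversion
concentration: `c = f_m^Ctm / (dilution · f_i^Cti)` with a 20-fold template
dilution by default. For the nested LR-PCR/qPCR experiment, each LR
reaction's Ct is the median of its qPCR replicates; with group means
`M_Ct(B)`, `M_Ct(S)` and sample variances `s²`, `ΔCt = M_Ct(S) − M_Ct(B)`
and `s_ΔCt = (s²_S/n_S + s²_B/n_B)^0.5` (group sizes 12/12/6 are defaults,
not hard-coded). The 95% upper bound `m` uses the normal quantile, matching
the described procedure; a t-quantile option exists but is off by default.
Mean and minimum replication fractions are `f^(−ΔCt)` and `f^(−m)`. Ct
thresholding, baselining and passive-reference normalization are upstream
instrument concerns; inputs are final Ct values.

## Synthetic data generator

The generator provides every input the pipeline consumes, as pure functions
of seed and spec:

* **Genomes**: i.i.d. bases at a chosen GC content (default 0.40, typical
  of mammalian mtDNA), annotated with one synthetic gene covering all but a
  trailing ~10% D-loop so gene-region filtering is always exercised.
* **Planted repeats**: the second arm is written as a (mismatched) copy or
  reverse complement of the first, with mismatches at interior positions
  (≥ 4 bp from the ends where the arm length allows, ≥ 3 otherwise, never
  adjacent) and the diagonal continuation beyond each end overwritten with a
  four-mismatch run, a match, and another mismatch — a pattern the valley
  rule can never cross — so the planted repeat is *exactly* maximal and its
  ground truth is guaranteed recoverable, not just probable.
* **Species panels** (defaults: 60 species in 4 clades with three-species
  genera, MLS log-uniform on 2–100 years, genomes of 1.6 kb): IR content is
  planted greedily (perfect repeats, lengths 25 down to 8) so the realized
  log₁₀ total follows `α − β·log₁₀ MLS + N(0, σ)` with α = 0.5, β = 1,
  σ = 0.15; quantization from discrete planting is below ~0.02 log units,
  small against σ. Two random-length DRs give every species a non-zero,
  lifespan-neutral DR score. Panel sizes and noise were fixed once as
  plausible study conditions: 60 species sits between the published clade
  sizes, and σ = 0.15 leaves the planted relation dominant but not trivial.
* **qPCR plates**: `Ct = −log_f(concentration) + offset + N(0, σ)`, in
  triplicate by default, plus a nested-experiment simulator with known group
  separation.

What the generator does **not** emulate: real mtDNA base composition and
codon structure, tandem-repeat-rich D-loops, sequence evolution along the
tree, or correlated phylogenetic noise in the score–lifespan relation
(noise is i.i.d. across species). Consequently, passing tests demonstrate
that the algorithms are correct and that planted signals of realistic size
survive the full pipeline — not that any particular biological claim holds
in real genomes. Random sequence also carries an irreducible background of
small accepted repeats (on the order of 0.1 score units for a 1-kb genome),
so scanned totals slightly exceed planted totals; tests therefore assert
exact recovery of the planted repeats and their summed score rather than
equality of the full-genome total.

## Numerical and degenerate-input choices

* Tie-break for equally scoring maximal extensions: longer `l`, then
  smaller canonical `arm1_start`, then smaller `arm2_start`.
* Homopolymers (e.g. an all-A circle) are valid input: every diagonal is
  fully matched, and family suppression reports one tandem representative
  per rotation state rather than a quadratic blow-up. An all-A circle has
  no IRs at all (A never pairs with A).
* Spacer 0 (contiguous palindrome) is representable and found; arms
  touching is allowed, overlapping is not.
* Genomes shorter than `2·min_length`, non-ACGTN characters, empty
  sequences, inconsistent lineages, non-monotone bin edges, and empty qPCR
  groups raise errors; missing lifespans, missing D-loops, and non-monotone
  dilution series warn and continue.
* Problem sizes used by the shipped test suite — 50 random circles of
  300–500 bp for oracle equivalence, 100 seeded panels per recovery
  scenario, 500 simulated nested experiments for the coverage check — were
  chosen so the statistical assertions have comfortable margins while the
  whole suite stays fast.

## Known limitations

* The scan is exact but O(L²); full mammalian genomes are minutes, not
  seconds, and no suffix-structure asymptotics are attempted (mtDNA is
  ≤ ~26 kb).
* Gapped (indel-containing) repeats are out of scope.
* The acceptance rule is a reconstruction; where a different formalization
  of the valley rule is wanted, `low_match_extension` and the stringency
  preset are the exposed knobs, but the 4-matches-flank constant is fixed.
* Polytomy handling deliberately under-counts contrasts relative to a fully
  resolved tree; contrast counts are reported alongside the statistics.
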