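# Methods

## The mirror-tree statistic

For two protein families A and B with validated alignments, the analysis
filters both to their common species (normalized `genus_species` labels,
lexicographically sorted), computes each family's pairwise distance matrix
over that subset, vectorizes both strict upper triangles in the same
row-major order, and takes the Pearson product-moment correlation r_AB of
the two vectors. With N common species the vectors have
n = (N² − N)/2 entries.

Distances are **uncorrected p-distances**: mismatches divided by compared
sites. No Poisson/JTT-style multiple-hit correction is applied — the
downstream statistic is a correlation, and the p-distance is the distance
the method is defined on. A `--model` seam exists in the distance layer but
only `"p"` is implemented.

**Gap and ambiguity handling** defaults to *pairwise deletion*: a site
enters a pair's comparison only when both sequences carry one of the 20
canonical residues there (gaps and X excluded). This preserves species with
partial sequences; *complete deletion* (drop a column for all pairs if any
included sequence is non-canonical there) is available via
`gap_policy="complete"`. Which of the two a given legacy analysis used is
rarely stated; the choice can shift individual distances, which is why it is
a flagged, documented option rather than a silent default. Non-canonical
residue codes B/Z/J/U/O are folded into X on input, with a warning.

**min_sites guard.** A pair whose usable-site overlap falls below
`min_sites` (default 50 — about 10% of a short P-type-ATPase domain) raises
rather than returning a distance estimated from almost nothing. Unit tests
and toy examples pass `min_sites=1`.

**Common-species distances** are computed on the common-species *rows* of
each family's full alignment; columns are not re-aligned after filtering.
A pipeline that filters before aligning could produce slightly different
columns; re-alignment is deliberately outside this package's contract
(alignments are inputs).

## Fisher r-to-z comparison and ranking

Significance of a single correlation: t = r·sqrt((n−2)/(1−r²)) on n−2
degrees of freedom, two-tailed. Difference of two correlations:
z_i = atanh(r_i), z_stat = (z₁−z₂)/sqrt(1/(n₁−3)+1/(n₂−3)), referred to the
standard normal, two-tailed, no continuity correction (matching the classic
Vassarstats calculators). `rank_partners` sorts a panel by r_AB descending
and tests the leader against every other member, flagging as ties those the
data cannot separate at the 5% level.

**Sample-size convention.** Both tests take the *pairing count* n, not the
organism count N, as the sample size. This is the convention under which
the published panel p-values (0.002 for PKC θ vs η; 0.05 for Lck vs Yes)
are reproduced exactly — verified against an independent scipy evaluation
before the implementation was written; using N instead gives 0.55 and 0.77
respectively. The statistical caveat is real and worth stating prominently:
the n matrix entries are **not independent** (each species contributes to
N−1 of them), so these p-values are anti-conservative as absolute error
rates. They are used *comparatively*, to rank candidate partners analysed
under the same convention. `AnalysisConfig.sample_size` exposes
`"pairings"` (default) and `"organisms"`.

No multiple-testing correction is applied across a panel's comparisons;
rankings report raw two-tailed p-values.

## Conservation profiling and kinase context

Per-column residue counts are reported in the coordinates of a chosen
reference species (1-based positions at the reference's non-gap columns).
"Conserved" means the modal non-gap residue reaches a threshold fraction
(default 1.0 — strictly conserved across all non-gap species); gap-bearing
species are excluded from the denominator and counted separately. Species
can be grouped into classes through an explicit map (no taxonomy lookup, so
runs are offline and deterministic), giving per-class modal fractions — the
structure needed to say things like "Tyr-7 is conserved in every vertebrate
class except cartilaginous fish".

The kinase-context scan extracts, per species, the ±window ungapped
neighbourhood of the residue aligned to a reference position (windows are
taken in each species' own coordinates, so indels elsewhere in the
alignment cannot distort them; truncation at sequence ends is flagged).
Verdicts operationalize two well-known substrate preferences without
claiming a trained predictor: **src-context** = tyrosine with ≥1 acidic
residue (D/E) in the window (default ±3); **pkc-context** = serine or
threonine with basic residues (K/R) on both sides or ≥2 total in the window
(default ±5). Everything else is "none".

## The synthetic-data generator

The generator produces the statistical structure the mirror-tree method
assumes, with known ground truth:

- **Tree**: Yule pure-birth topology (dendropy's birth–death sampler with
  death rate 0), branch lengths rescaled so the mean root-to-tip path is
  1.0 expected substitution per site at rate 1. Default panel sizes follow
  the input regime of real analyses (tens of common species; 20–100
  supported).
- **Rate heterogeneity**: per-branch multipliers exp(g),
  g ~ Normal(−σ²/2, σ²) i.i.d., so E[multiplier] = 1 exactly. The default
  σ = 0.5 puts most multipliers within 2–3-fold of 1 — substantial but
  realistic lineage effects.
- **Coevolution**: family B's log-rates are g_B = ρ·g_A + sqrt(1−ρ²)·ε with
  ε normal and its mean chosen so g_B keeps the Normal(−σ²/2, σ²) marginal;
  corr(g_A, g_B) = ρ by construction, ρ=1 copies rates exactly, ρ=0 makes
  them independent.
- **Sequences**: root drawn i.i.d. uniform over the 20 residues; each branch
  of effective length b = length × multiplier applies the 20-state
  uniform-exchange (Poisson) transition. The implementation samples each
  site's *final* state from the exact transition law — P(changed) =
  (19/20)(1 − e^{−(20/19)b}), new state uniform over the 19 alternatives —
  which is distributionally identical to simulating individual substitution
  events and gives the closed-form p-distance expectation used as an
  analytic oracle in the tests.
- **Determinism**: every operation is a pure function of (parameters, seed);
  a master seed is split via `numpy.random.SeedSequence` into named
  substreams (tree / ratesA / ratesB / seqA / seqB).

What the simulator does **not** emulate: empirical amino-acid exchange
matrices (JTT/WAG), across-site rate variation, indels (so alignments are
exact by construction), alignment error, biased taxon sampling, or
paralogy/annotation noise in the input families. Passing recovery tests on
this generator therefore shows the statistical machinery behaves as
designed under the model's own assumptions — not that real database-derived
alignments are free of those additional error sources.

**The shared-tree confound, on purpose.** Even at ρ = 0, two families on a
shared phylogeny correlate strongly (r ≈ 0.88 at the default settings)
because both matrices reflect the same species divergence structure. The
test suite asserts this inflation explicitly (shared-tree ρ=0 pairs beat
independent-tree pairs). It is the model-level reason the panel runner
refuses to call candidates from absolute r values and instead bands them
against the largest negative-control correlation observed in the same run
(fallback threshold 0.92 when no negatives are supplied). No correction for
the shared phylogenetic component (e.g. projecting out a species-tree
signal) is implemented — the method correlates raw matrices.

## Numerical and design choices

- Pearson is computed by the direct two-pass sum formula in float64 and
  clamped to [−1, 1]; it agrees with exact rational-arithmetic and scipy
  oracles to 1e-12 in tests. Constant vectors raise rather than return NaN.
- Vectorization order (sorted species, strict upper triangle, row-major) is
  fixed so outputs are reproducible and diffable; Pearson itself is
  order-invariant.
- Duplicate species within one family keep the record with the most non-gap
  residues, ties broken by smallest id — deterministic and favouring
  complete entries.
- Minimum species overlap defaults to 5 (n = 10 pairings); below that a
  correlation is vacuous and the pair is refused (panel runs record it as
  skipped and continue).
- Distance-matrix files round-trip losslessly (full float repr); readers
  reject asymmetry beyond 1e-9 and non-square layouts.
- Panel reports serialize with fixed key order so identical inputs give
  byte-identical JSON.
- Problem sizes in the test suite and acceptance script (40 species ×
  2000 sites × 20 paired replicates for recovery; 100 000 sites for the
  closed-form distance check) are chosen to put Monte-Carlo standard errors
  well inside the asserted tolerances while keeping a full run in the
  tens-of-seconds range.

## Known limitations

- p-values inherit the dependence caveat above; treat them as ranking
  scores, not calibrated error rates.
- No background-phylogeny correction; strongly non-clocklike families can
  inflate or deflate r_AB for reasons unrelated to interaction.
- The conservation verdicts are deliberately coarse motif-context rules,
  not substrate predictors.
- Sequence collection, BLAST filtering and alignment are upstream of this
  package: garbage alignments in, garbage correlations out.
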