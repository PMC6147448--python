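# Methods

## Data model

A sample is an HVRI haplotype — a set of rCRS-relative variant calls over
positions 15997–16409 (1-based rCRS coordinates, as universally printed in
the ancient-mtDNA literature; no 0-based remapping is exposed) — plus a set
of coding-region SNP calls at diagnostic positions, a burial-group code
(`Bain`/`P`/`Bidj` → Early, `S` → Middle, `T` → Late), and optionally a
curated haplogroup label. Variant tokens encode only the derived state
(`16223T`); the reference base is implicit in the rCRS. Parenthesized
tokens are stored with an `uncertain` flag; exactly one such call (an
uncertain 16193 C-insertion) occurs in the bundled series. Coding calls
such as `14766C,7028T` are stored verbatim as observed states, without
interpreting them against an ancestral state.

The bundled table (`tagarmt/data/tagar_series.tsv`) holds 79 individuals
(46 Early, 24 Middle, 9 Late) with 39 distinct HVRI haplotypes. The TSV
with columns `sample_id, stage_code, hvr1, coding, haplogroup` is the
canonical on-disk format for both real and simulated series.

## Haplogroup calling

The caller is intentionally self-contained: a motif table
(`tagarmt/data/motifs.json`) lists, per haplogroup, mandatory coding-region
markers, the HVRI motif expected on that background, a parent link, and the
West/East Eurasian macro-cluster. The bundled table is the *minimal* rule
set consistent with the haplogroups observed in the bundled series (27
labels from A/A8 through U*); it is not, and does not claim to be, a
complete mtDNA phylogeny. Users with broader series supply their own table
in the same JSON schema.

A rule matches a sample when **all** of its coding markers and **all** of
its HVRI motif variants are present (uncertain variants count at full
weight; only one exists in the data and down-weighting a single call would
change nothing while complicating the contract). Among matching rules the
call is the deepest one, with ties broken by motif score
(matched/expected markers) and then lexicographic label. Requiring the full
motif — rather than ranking partially-matched rules by depth — is what makes
backbone haplotypes resolve correctly: a haplotype carrying the T backbone
motif but only part of the T2f7 motif must be called `T`, not dragged to the
deeper partial match. With this rule the caller reproduces all 79 curated
labels, is invariant to rule order, and calling a sample whose variants
complete a child motif can only deepen the assignment.

Paragroup (star) labels `HV*` and `U*` are ordinary rules with empty motifs;
they win exactly when no child rule's motif is complete, which is the
conventional meaning of a star label. Macro-clustering resolves a label in
the table and walks to its root; labels absent from the table fall back to
the longest known root prefix (A/C/D/F/G → East; H/HV/I/J/K/T/U/V/W/X →
West), and unknown roots raise with the list of known roots.

## Distances and F_ST

The pairwise sequence distance is the number of HVRI positions at which two
haplotypes' implied sequences differ (a position carried by one haplotype
differs from reference; a position substituted to different bases in both
counts once). Indels and uncertain calls are excluded by default and can be
switched on. This is an unweighted p-distance on a 413-bp window: no
substitution-model correction (e.g. Tamura–Nei) is applied, because with at
most ~8 differences per pair the correction is second-order relative to
sampling noise; the flags make the distance basis explicit and configurable.

Sequence F_ST is (π_B − π_W)/π_B, with π_W the **unweighted** mean of the
two within-population mean pairwise differences (symmetric in the
populations, conventional for two-group comparisons) and π_B the mean
between-population pairwise difference; 0 when π_B = 0. Frequency F_ST is
the single-locus multi-allelic (H_T − H_S)/H_T with H = 1 − Σp², H_S the
unweighted mean within-population gene diversity and H_T from mean allele
frequencies. Both estimators are clamped to [0, 1] before Slatkin
linearization F_ST/(1 − F_ST), mirroring common practice in population
packages that floor negative variance-component estimates at zero.

Significance is a Monte-Carlo permutation test: individuals are reshuffled
between the two populations preserving sample sizes, and
p = (1 + #{permuted F_ST ≥ observed})/(n + 1), so p is never 0 and has
resolution 1/(n+1). The default is n = 100 interchanges to match the
desk-scale convention for small ancient series; for real inference we
recommend ≥ 9999. Because the statistic is clamped at 0, permutation ties
are common under the null and the test is conservative (sub-uniform
p-values), never anti-conservative; the test suite checks exactly this
validity property.

## Ordination

Classical (Torgerson) metric MDS: double-center −½d², eigendecompose,
scale the top eigenvectors by √eigenvalue. It is deterministic — unlike
stress-minimizing iterative MDS — and recovers Euclidean-embeddable
configurations exactly, which is what makes it testable. Eigenvalues below
a relative tolerance of 1e-12 are treated as zero; if fewer positive
eigenvalues than requested dimensions exist the remaining axes are
zero-padded with a warning. Negative eigenvalue mass (non-Euclidean input,
common for linearized F_ST matrices) is reported as a diagnostic
(`negative_mass`), not silently dropped. Axis orientation is fixed by
pointing each axis's largest-magnitude coordinate positive; orientation and
scale of any published ordination plot are arbitrary and are not a
comparison surface.

## Haplotype sharing

Lineage identity = equality of canonical certain-substitution sets, i.e.
the same basis as the default distance (indels/uncertain calls ignored);
this makes "identical lineages" well-defined in the presence of the one
parenthesized call. Two normalizations are reported, since published
sharing analyses do not always state theirs: the fraction of A's
*individuals* whose haplotype occurs in B (the headline number; it is the
definition under which the bundled series' Middle-in-Early sharing is
exactly 50% and 72% of Early individuals carry lineages absent from the
Middle stage) and the fraction of A's *distinct haplotypes* occurring in B.
The sharing matrix (rows = A, columns = B) is intentionally asymmetric with
a diagonal of 100.

## Detectability

Under a simple binomial model, a cluster at population frequency p is
entirely absent from a sample of N with probability (1 − p)^N; solving
(1 − p)^N = α gives the minimum reliably-detectable frequency
p = 1 − α^(1/N). Default α = 0.05. Full precision is kept internally and
values are rounded to 3 decimals only for display. Note p is decreasing in
both N and α. No finite-population or Bayesian correction is applied — the
model is deliberately the textbook binomial.

## Synthetic series

The generator emulates the structure the analyses assume, not coalescent
realism. Founders are haplogroup-rooted haplotypes (by default one per
motif-table rule: the rule's motif on its coding background). Per stage,
the East share of individuals is binomial around the configured mixture,
founder frequencies within each macro-cluster are symmetric-Dirichlet
(concentration 0.5 by default, giving the skewed, singleton-rich spectra
typical of small ancient series), and each individual receives
Poisson-distributed private substitutions placed uniformly on unoccupied
HVRI positions (infinite-sites within the window). Between stages, founder
frequencies are resampled through a multinomial bottleneck (default 25),
which loses rare founders and so lowers predecessor-in-successor haplotype
sharing as the bottleneck tightens.

Defaults mirror the bundled series' study conditions: stage sizes
(46, 24, 9), East fractions (0.348, 0.458, 0.111), mutation rate 0.3 per
transmitted haplotype. By default new mutations avoid every position used
by any motif in the bundled table, so the haplogroup caller recovers each
record's founder label exactly by construction — the caller-recovery tests
are therefore tests of the caller, not of mutation luck; set
`allow_motif_positions=True` to relax this. All randomness flows from a
single seed through an explicit `numpy` generator that every stochastic
operation accepts.

What the simulator does **not** model: aDNA damage and sequencing error,
heteroplasmy, selection, realistic site-specific mutation-rate
heterogeneity, or coalescent genealogy. Passing simulation-based tests
shows the pipeline's estimators behave correctly under the stated
generative model, not that the bundled series satisfies that model.

## Numerical choices and degenerate inputs

* Empty haplotype ≡ `rCRS`; an empty sample table is readable (with a
  warning) but diversity statistics on it raise.
* F_ST on a population of < 2 individuals raises naming the pair;
  both-monomorphic-same-label frequency F_ST returns 0 with a warning.
* Permutation p-values use the add-one estimator; identical seeds give
  identical p.
* Reproduction checks compare unrounded computed values within declared
  tolerances (0.05 on one-decimal percentages, 5e-4 on three-decimal
  frequencies, exact on counts), stored declaratively in
  `tagarmt/data/reproduction_targets.json` so the reproduction surface is
  auditable rather than hard-coded in test logic.

## Known limitations

* The motif table covers only the haplogroups present in the bundled
  series; calling unrelated series requires a user table.
* Cross-population comparisons against other ancient/modern series require
  user-supplied tables of haplotypes or haplogroup frequencies; none are
  bundled. The F_ST/MDS/sharing machinery accepts them through the same
  TSV interfaces.
* The sequence distance treats the one uncertain insertion as absent by
  default; at most one pairwise difference in the bundled data is affected,
  and flags expose the alternative.
* Problem sizes in the test suite (exhaustive F_ST grids at ≤ 6 individuals
  over ≤ 3 haplotypes, 60-replicate permutation-null checks at 49
  interchanges, 10,000-replicate Monte-Carlo detectability checks,
  simulated series of ≤ 200 records) were chosen as the smallest designs
  at which each property is statistically decidable; all are desk-scale.
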