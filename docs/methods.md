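# Methods

This note documents the models, estimators, rules and numerical choices in
`convrates`, and what the synthetic-data experiments do and do not show.

## The comparative design

All analyses assume a `PairDesign`: an outgroup/reference species and an
ordered list of (mutualist, generalist) sister-lineage pairs — by default
the seven-taxon layout `gracilis` + (`concolor`,`pallidus`),
(`flavicornis`,`PSW54`), (`dendroicus`,`elongatus`).  The default topology
places the `pallidus` lineage sister to the (`flavicornis`,`PSW54`) clade;
because this placement is less certain than the sister pairs themselves,
any newick string can be substituted.  Default branch lengths make the tree
ultrametric with a root-to-tip depth of 0.025 expected substitutions/site,
i.e. about 5% pairwise divergence from the outgroup — the shallow-divergence
regime in which p-distances are nearly linear in branch length and
reference-based alignment is safe.  Terminal branches are deliberately
length-matched within pairs so that, with no rate shift, paired differences
are exchangeable.

## Simulators

**Codon sequences** evolve site-independently over the 61 sense codons of
the standard nuclear code (stops excluded from the state space, so
simulated genes never contain internal stop codons).  The instantaneous
rate from codon i to j is 0 unless they differ at one position, and
otherwise proportional to π_j, times κ for transitions (default 2.0) and ω
for nonsynonymous changes (default 0.2, a typical genome-wide level of
purifying selection).  Each branch's matrix is scaled to mean rate 1 at
stationarity before applying (branch length × ρ), so branch lengths read as
expected substitutions per codon site and the per-branch multiplier ρ
scales realised divergence directly.  Transition matrices come from
`scipy.linalg.expm`; child states are drawn exactly by sampling the
stay/move event first and resolving the (rare) movers against the
renormalised off-diagonal row — an optimisation for the low-divergence
regime, not an approximation.

**Planted convergent sites** are imposed after simulation: at each chosen
column, a residue absent from every species is written into all mutualist
leaves (as a codon of that amino acid) and recorded in the truth table.
This guarantees a known-positive set with an unambiguous background.

**Noncoding sequence** uses the 4-state analogue (Jukes–Cantor by default;
HKY when κ or unequal base frequencies are given), with optional planted
runs of N to exercise window-validity rules.

**Read depth** is per-base Poisson with mean λ·CN/2 (diploid baseline
CN = 2, default λ = 30).  **Mapping populations** follow a heterozygous
queen × haploid father: each diploid offspring is coded by the inherited
maternal allele, with recombination between adjacent markers from the
Haldane map function r = (1 − e^(−2d/100))/2.  **Expression** is i.i.d.
Gamma(2,1) per gene × 29 tissues, with the head column of designated fast
genes multiplied by (1 + head_shift), so head_shift = 0 is an exact null.

What the simulators do *not* emulate: indels, within-scaffold
recombination or topology heterogeneity, alignment error, GC-biased gene
conversion, rate variation among sites, genotyping error in the mapping
family, or correlated expression across tissues.  Passing tests therefore
demonstrate that the estimators and rules recover what they claim under
their own model assumptions — not that those assumptions hold in any real
data set.

## Estimators and rules

**NG86.**  Synonymous site counts use per-position fractions of the three
single-base changes with mutations into stop codons removed from the
denominator, preserving S + N = 3 per codon.  Pairwise difference counts
average over all orderings of the differing positions, discarding pathways
through stops (equal weights); codons whose every pathway is blocked are
skipped and counted.  S and N are averaged between the two sequences; pN
and pS are corrected with d = −(3/4)·ln(1 − (4/3)p), undefined (flagged)
at p ≥ 3/4.  dS = 0 genes have undefined ratios: they are excluded from
ratio means but included in the Σ dN / Σ dS sums, and genes with ratio
≥ 10 are excluded from ratio statistics as likely annotation artefacts.
This counting estimator is the package's headline approximation: it
replaces maximum-likelihood codon-model fitting, trading efficiency for
full auditability (every value is checkable by enumeration).  Rates are
computed species-vs-outgroup to match the window-distance framing; an
all-pairs mode exists for tree building.

**Windows.**  Fixed-size windows at a fixed step, no shorter trailing
window (equal-width statistics); a window is valid only if every species
is known over ≥ half of it.  p-distance counts a site when both sequences
are known; IUPAC ambiguity codes are known, and two sites differ only if
their allele sets are disjoint — so a heterozygote sharing an allele with
the reference is not a difference.  An alternative policy (mask
heterozygous consensus sites to N) is available at consensus-calling time.

**Consensus calling** emits, in order: N at >3-allele sites; the genotype
call when present (IUPAC code for heterozygotes); the reference base when
uncalled but covered ≥ 5×; otherwise N.

**Gene QC** requires all species present, ≥ 300 codons (inclusive), and
< 20% missing data per sequence; any codon column with an in-frame stop in
any species is masked to NNN across all species (stops at these shallow
divergences are overwhelmingly misalignment artefacts).  Gap-containing
codon columns can be dropped wholesale (`drop-gap-columns`), a deliberately
blunt stand-in for alignment-block filtering, switchable off.

**Consistency classification** uses strict inequalities; any tie makes a
unit inconsistent.  This is conservative: at finite window sizes tied
p-distances have non-negligible probability, pushing directional classes
slightly below the 12.5% exchangeable-null value (visible in the null
calibration at 25 kb windows, where fractions sit around 0.10–0.13).

**Statistical choices.**  Two-sided tests throughout; directionality is
read off the sign of the statistic.  Welch's unequal-variance t for
expression contrasts; rank (Spearman) correlations for Nc vs rates;
Benjamini–Hochberg step-up (via statsmodels) for FDR; exact two-sided
binomial for the 1:1 allele-ratio filter at α = 0.05.

**ENC.**  Wright's estimator with family homozygosity
F̂ = (nΣp̂² − 1)/(n − 1): Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, with Met
and Trp as the "+2", Ile the single 3-fold family, and Leu/Ser/Arg as
6-fold.  Families with n < 2 or F̂ ≤ 0 are unusable; a degeneracy class
with no usable family is imputed with the mean of the observed class
means; Nc is capped at 61.  The background-composition-corrected variant
of ENC is intentionally out of scope.

**Convergence scanning.**  Default mode is shared-exclusive (subset of ≥2
foreground lineages shares a residue found in no other species); the
strict mode additionally requires a uniform background and can only reduce
counts.  Both are reported because the genome-wide counting rule behind
published totals of this kind is rarely spelled out; the strict mode
matches the worked site-level examples.  Columns with any gap, stop or X
are excluded from the examined-site denominator.  Positions are 1-based
within the translated gene.

**Screens.**  NuMt hits count at e-value < 1e-20 and ≥ 35% coverage of the
seed sequence (coverage is measured on the query/seed, per the rule's
wording).  Copy number is 2 × region-mean depth / genome-median depth over
unmasked bases — the median normaliser is robust to the planted gains
themselves.  Duplication consistency requires every species of one class
≥ 1.5 copies and ≥ 1.5× every species of the other class.  TE filtering
orders its rules dedupe (80/80, keep longest) → length ≥ 80 → protein
similarity (bit ≥ 100, or ≥50% similarity over ≥50% length), logging the
first rule each removal hits.

**Linkage.**  Marker QC order: queen heterozygous → ≥75% genotyped →
≤2 alleles → 1:1 allele ratio.  Phase doubling duplicates each marker with
mirrored 0/1 coding; grouping is single-linkage closure at recombination
fraction < 0.2, mirrored groups collapsed afterwards.  Marker *ordering*
within groups is out of scope; the grouping is a transparent stand-in for
a full mapping algorithm and is validated only for chromosome membership.

## Problem sizes in the checks

The recovery experiments run at desk scale: neutral dN/dS on 50,000 codons
(10 genes × 5,000); rate-shift recovery on 2,000 windows of 2 kb plus 200
genes × 400 codons with ρ = 1.5 on mutualist terminals; null calibration
on 2,000 non-overlapping 25 kb windows (the larger window keeps tied
distances rare enough for the binomial band around 12.5% to apply) and 20
null replicates of 150 windows for p-value uniformity; convergence recall
on 30 genes with 8 planted sites; the symmetry check on a deep (0.3
substitutions/site) neutral tree, pooling counts over 5 replicates into a
single two-sided binomial test; copy number at 30× over 10 kb regions;
linkage on 3 chromosomes × 5 markers × 48 offspring over 20 replicates.

## Known limitations

* NG86 underestimates rates at high divergence and ignores
  transition/transversion and codon-frequency bias in its site counts; it
  is well calibrated in the <10% divergence regime this package targets.
* The consistency classifier's tie rule makes directional fractions
  window-size dependent under the null.
* The convergence scanner cannot distinguish convergent substitution from
  shared ancestral polymorphism or introgression; it counts patterns, not
  processes.
* The linkage grouper recovers chromosome membership, not marker order or
  map distances.
* Likelihood-based selection tests are consumed only as external p-value
  tables (the reverse-foreground filter operates on their output); the
  package does not fit codon models by maximum likelihood.
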