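# Methods

## Model and statistics

All statistics operate on biallelic sites from four populations on the
rooted species tree `(((P1,P2),P3),O)`, polarized so that 1 means the
derived allele. Per site the package uses the frequency forms

- `d_xy = p_x(1-p_y) + (1-p_x)p_y` — average pairwise difference
  between populations x and y; identical to counting mismatching
  haplotype pairs (tested exhaustively for up to 8 haplotypes a side);
- `pi_x = 2 p_x (1-p_x)` — within-population diversity. No
  `n/(n-1)` small-sample correction is applied by default, keeping the
  estimator consistent with the frequency form of d_xy; an unbiased
  variant is available via a flag.

Over a window of L variant sites, with shared numerator
`N = sum(p2*d13 - p1*d23)`:

| statistic | denominator | notes |
|---|---|---|
| D | `sum(p3*d12)` | ABBA−BABA contrast; detects, overestimates f |
| f_hom | `sum(p3*d13 - p1*pi3)` | assumes P3→P2 direction |
| f_d | `sum(pD*d1D - p1*piD)` | pD = larger of (p2, p3) per site |
| d_f | `sum(p2*d13 + p1*d23)` | includes the BBAA species-tree distance |

d_f is bounded in [−1, 1] whenever defined (its numerator terms are a
subset of the denominator's, both nonnegative), positive for P3⇔P2
gene flow and negative for P3⇔P1. When p2 = p3 at a site, PD is taken
to be P3; the choice cannot change f_d (pD, d1D and piD coincide) and
exists only to make the code path deterministic.

### Degenerate windows

A zero denominator (for example a BBAA-only window for D, or
`p1 = p2 = 0` everywhere for d_f) yields NaN for that statistic and a
flag on the window; scans never raise mid-run. Sites monomorphic
across all four populations are skipped, multi-allelic sites are
dropped with a counter, per-site frequencies use non-missing haplotypes
only, and a site is dropped when any population has zero calls.

### Laplace smoothing

In genome scans the derived-allele frequencies of P1 and P2 are
replaced by `(count+1)/(n+2)` — one derived and one ancestral allele
added — and every distance is recomputed from the smoothed values. P3
and the outgroup are untouched. Smoothing is off by default for
whole-window statistics and on by default in `run_scan`/the `scan`
subcommand, where small windows would otherwise produce extreme values.

### Polarization

The outgroup defines the ancestral state. The default `strict` policy
keeps only sites where the outgroup is fixed (the count of discarded
sites is logged), so p4 = 0 for every retained site and the
`(1-p4)/2` factor of the pattern expressions drops out of all ratios.
The `major` policy instead calls the outgroup's major allele ancestral
and drops only 50/50 ties, where no defensible call exists. Coordinates
are 0-based with half-open windows throughout.

## Coalescent simulator

`simulate_locus` draws genealogies under the classic four-population
history with split times t12 < t123 ≤ t123O in units of 4N generations
and one admixture pulse of fraction f at t_GF (directions P3→P2, P2→P3
or P3→P1, implemented as a backwards-in-time mass migration of the
recipient's lineages into the donor). msprime is the backend; haploid
populations of size 0.5 make one msprime generation equal one
4N-generation unit, so ms-style times, the locus-wide rho and the
branch-scale mutation rate are used without conversion (unit-tested
against closed-form branch-length expectations).

Baseline study conditions (the package defaults): 8 haplotypes per
population, t12/t123/t123O = 1/2/3, f pulse at t_GF = 0.1, rho = 50
over a 5 kb locus, HKY mutations at s = 0.01 substitutions per site per
unit branch length. HKY's transition/transversion ratio and base
frequencies are not part of the study conditions; they default to
kappa = 2 with equal frequencies, are configurable, and the frequency-
based statistics are insensitive to them at biallelic sites. An
infinite-sites binary model at matched density is available when exact
knowledge of the ancestral state is wanted.

Simulated HKY data are polarized through the same strict outgroup path
an empirical pipeline would use — including its known artefacts
(misoriented sites where the outgroup is fixed derived), which real
analyses share. Replicate seeds derive deterministically from a master
seed via `numpy.random.SeedSequence`.

What the simulator does *not* emulate: sequencing error, missing
genotypes, selection, continuous migration, or more than one pulse.
Passing accuracy tests therefore demonstrates estimator behaviour under
clean demographic histories, not robustness to data-quality artefacts.

## Accuracy experiments

`run_accuracy_experiment` simulates (by default) 100 loci for each
introgression fraction f = 0, 0.1, …, 1 and scores each statistic
with:

- **adjusted R²** of an OLS regression of the statistic on the true
  fraction (intercept + slope). An alternative `identity` mode scores
  deviation from the line y = f instead, because "goodness of fit"
  admits both readings; OLS is the default. A constant estimator has
  adjusted R² defined as 0.
- **SSLF/n** — `sum_j n_j (mean_j − f_j)² / n`, the lack-of-fit sum of
  squares divided by the per-fraction sample size; near zero for d_f.
- **SSPE** — `sum_ij (y_ij − mean_j)²`, the pure-error sum of squares,
  reported raw.

Loci with an undefined statistic are excluded with a logged count
rather than imputed. The detection experiment simulates 10,000 neutral
and 1,000 introgressed loci and reports the ROC AUC of each statistic
as a classifier (rank-based, tie-aware).

`dxy_vs_f_curves` computes Monte-Carlo means of the per-bp pairwise
distances d_12, d_13, d_23 against f. Under P3→P2 gene flow the fitted
slope of d_13 on f is ~0 while d_23 falls; the mirror holds for P2→P3
and d_12 — the direction-informative asymmetry the genome scan's sign
conventions rest on.

## Genome scan

`run_scan` tiles the chromosome with half-open windows (50 kb
consecutive windows by default; at least one window is emitted when the
region is shorter than the width), computes the statistics per window
(Laplace-smoothed), and tests each window against a null value — 0
everywhere, or the regional mean inside a user-specified region (the
inside-the-inversion style null).

**Jackknife.** Blocks are the scan windows themselves (configurable).
The pooled region statistic is the ratio of summed numerators to summed
denominators; delete-one-block estimates are formed incrementally from
those sums and the weighted jackknife variance follows Busing et al.
(1999) with block weights proportional to SNP counts (equal weights
reduce to the textbook delete-one formula and are available as a flag).
Each window's standard error is the implied per-block standard
deviation `sqrt(g · var_jack)` scaled by `sqrt(mean_weight/weight_i)`,
so SNP-rich windows receive tighter errors. Consequences worth knowing:
a window's own extremeness inflates the variance it is tested against,
so a lone extreme block among few windows saturates at modest Z — per-
window significance needs many blocks relative to the outlying ones,
which genome-scale scans provide. Zero variance (statistic constant
across blocks) or fewer than two usable blocks yield NaN Z with a
warning, never an exception.

Two-sided p-values come from the normal distribution (the sign of d_f
is meaningful in both directions), are adjusted by Benjamini–Hochberg,
and outlier tables report each significant window at the strictest
level passed (0.05 and 0.01 tiers by default).

## Numerical and testing choices

Monte-Carlo assertions in the test suite use fixed seeds and tolerance
bands of ±3 Monte-Carlo standard errors; oracle comparisons
(pattern-counting D, brute-force delete-one jackknife, hand-computed
BH) are exact to 1e-10 or better. The heavier simulation studies run at
100 replicates per fraction (accuracy panels) and 50 replicates
(gene-flow-time and distance-slope experiments), sizes at which the
pinned reference values are stable to well within their tolerance
bands. Scan tests use a synthetic 500 kb chromosome built from
independent segments with a planted 100 kb tract.

## Known limitations

- The statistics presume the resolved tree (((P1,P2),P3),O); they are
  not applicable to other topologies or to five-taxon systems.
- Direction inference from the d_xy slope asymmetry is exposed only as
  the curve/slope computation, not as an automated classifier.
- The jackknife block size and weight formula are conventions (windows
  as blocks, SNP-count weights); both are parameters, since no single
  canonical choice exists for consecutive-window scans.
- Per-window Z values share one variance scale estimated from the whole
  region; strongly heterogeneous chromosomes may prefer the regional
  mean null or custom blocks.
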