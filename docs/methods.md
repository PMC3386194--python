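# Methods

This note documents the models implemented in `deletometer`, their
assumptions, the parameters that matter, and the design decisions taken
where the protocol was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scientific setting

Bacterial genomes shrink by spontaneous deletion, and reductive genome
evolution can be driven either by drift (bottlenecks, relaxed selection) or
by selection, if carrying superfluous genes is costly. Quantifying the
selective route needs four pieces of machinery, each a module here:

1. a **deletion-rate estimator** for fluctuation assays, with normalization
   by the amount of deletable DNA around the assayed locus;
2. a **junction analyzer** that measures the direct-repeat homology at
   deletion endpoints and classifies the implied recombination mechanism;
3. **fitness estimators** — exponential growth rates from OD600 curves,
   selection coefficients from two-color competitions, and the
   protein-burden prediction for the benefit of shedding unused genes;
4. **take-over models** for how fast a recurrently arising beneficial
   deletion spreads under daily serial passage.

A synthetic-data module generates every input with the statistical
structure the estimators assume, so the whole pipeline is testable without
external data.

## Fluctuation assays and rate estimation

**Model.** Each culture grows from `N0` to `Nt` cells
(`g = log2(Nt/N0)` generations, the last doubling treated as a partial
interval with proportionally fewer births). Mutations arise per doubling as
a Poisson draw with mean `mu x (cells born)`; each mutant founds a lineage
that doubles deterministically at the wild-type rate (no death, no
phenotypic lag, plating efficiency 1 apart from the plating fraction).
Because total births sum to `Nt - N0`, the number of mutations per culture
is Poisson with mean `m = mu (Nt - N0)`, and the zero-count probability is
`exp(-m)` — the identity behind the P0 method. Mutant counts are thinned
binomially by the plating fraction (default 0.9: 900 µl of a 1 ml culture
plated), and the estimators correspondingly divide by
`plating_fraction x (Nt - N0)`, since zero counts and medians describe the
plated sample.

**P0 method.** `m = -ln(P0hat)` with `P0hat` the fraction of zero-count
cultures. SE by the delta method on the binomial SE of `P0hat`; 95% CI by
Clopper-Pearson. All-zero assays give `mu = 0` with a one-sided upper
bound; assays with no zero culture are refused — with nine cultures the
method saturates once `m` exceeds roughly 3–5, because `exp(-m)` leaves no
zero cultures to count. This is a property of the method, not of the
implementation, and the estimator-recovery test documents it at
`mu = 1e-8` (`m ~ 10`).

**Lea–Coulson median method.** Solves `r_median/m - ln(m) = 1.24` by
Brent's method on `(1e-6, 1e6)` to residual `< 1e-9` (the constant 1.24 is
exposed for sensitivity analysis). For even culture counts the median is
the lower middle order statistic: the classical tables assume an observed,
integer count, and the lower statistic is conservative and reproducible.
The SE/CI construction for this estimator is not standardized; we use a
seeded nonparametric bootstrap over cultures (1000 resamples; resamples
with median 0 fall outside the method's domain and are dropped).

**Deletable-window normalization.** Raw rates at a locus scale with how
much flanking DNA is dispensable. With `k` sequenced deletions whose
largest observed extents left/right of the marker are `M1`, `M2` (kbp), and
assuming deletion endpoints fall uniformly in the true deletable extents
`L1`, `L2`:

- point estimate `L_est = M (k+1)/k` (the bias-corrected maximum of a
  uniform sample);
- 95% upper bound `L_hi = M / 0.05^(1/k)` (the `L` for which observing a
  maximum at or below `M` has probability 0.05).

The per-kbp rate divides `mu` by the largest observed deletion; the
intrinsic per-kbp² rate divides by `L1 x L2` — best estimate from `L_est`,
lower bound from `L_hi`, upper bound from `M1 x M2` (the smallest window
consistent with the data). The uniform-endpoint model is this package's
own construction for the window estimate; treat the bounds as
model-dependent.

## Junction microhomology

`homology_bp` is the largest `h <= max_scan` (default 50) with
`genome[start:start+h] == genome[end:end+h]`, case-insensitive over
A/C/G/T; any other base terminates the match. Coordinates are 0-based
half-open (BED); FASTA record names must match BED chrom fields exactly.

*Convention.* The repeat is measured downstream of both endpoints. On
uniform random sequence this gives the clean null `P(h >= x) = 0.25^x`,
which the tests check; scanning both directions and reporting the maximum
(available via `scan_upstream=True`) roughly doubles that tail and is
therefore not the default. Scans truncate at sequence ends unless
`circular=True`, in which case they wrap (bacterial chromosomes are
circular, but endpoints near the origin are rare enough that linear is the
safer default for arbitrary references).

Classification: `>= 25 bp` → `reca_capable` (the approximate minimum for
RecA-mediated strand exchange); `5–24 bp` → `microhomology`
(RecA-independent); `<= 4 bp` → `none_or_low`. Observed junction classes
in sequenced spontaneous deletions cluster at 6–15 bp and <= 4 bp, leaving
5 bp unassigned; it is grouped with microhomology (anything above the
<= 4 class). Matching is exact; mismatch-tolerant scoring is not
implemented.

## Fitness estimation

**Growth curves.** The generator produces logistic trajectories
`OD(t) = K x0 e^{rt} / (K + x0(e^{rt}-1))` sampled every 0.25 h for 16 h
with additive Gaussian noise, clamped at a detection floor of 0.01 OD (a
typical plate-reader blank). The fitted rate is the maximal slope of
`ln(OD)` over any contiguous window of `window_points` readings (default
5) above the floor, earliest window on ties. Two caveats the tests make
explicit: (i) on a logistic curve the ln-slope is `r(1 - OD/K)`, so the fit
recovers `r` only while the window sits deep in exponential phase; (ii)
readings within a few noise SDs of the blank make `ln(OD)` noise-dominated
and the max-slope selection chases noise upward — analyses should raise the
fit floor to ~4 noise SDs above blank (0.02 for 0.005 noise).

**Competitions.** True mutant frequency evolves with a constant
per-generation advantage `(1+s)` across daily cycles of
`log2(1000) ≈ 9.97` generations (a 1:1000 dilution); each timepoint
observes a binomial draw of `events_per_timepoint` cells (default 1e5,
typical of flow-cytometric counting). The estimator is the OLS slope of
`ln(counts_a/counts_b)` against generations, so a noiseless `(1+s)`
advantage yields exactly `ln(1+s)`; the log base is natural by convention
here (a log2 option is provided, since published Δs values do not always
state their base). Timepoints with a zero count are dropped with a logged
warning rather than pseudo-counted: at ~1e5 events a zero means
near-fixation, where the log-linear model fails anyway. Per-replicate
estimates can be pooled by inverse variance.

**Protein burden.** Expressing a non-used protein of length `L` amino
acids at `n` copies per cell costs `s = nL/r0` with `r0 = 1e9` the total
amino acids polymerized into protein per cell; deleting a gene set is
predicted to gain `sum(n_i L_i)/r0`. The model assumes the freed synthesis
capacity is reallocated to growth-limiting protein and the product has no
other phenotype. The constant `FLAGELLAR_ENERGY_COST = 0.045` (fraction of
cellular energy dissipated by flagellar rotation, a literature-derived
figure) is exposed for comparison with motility-gene deletions; its
derivation is not reimplemented.

## Take-over dynamics

**Deterministic model.** `dp/dg = u(1-p) + s p(1-p)` — recurrent mutation
at rate `u` per cell per generation plus logistic selection — integrated
from `p(0) = 1/N` (one pre-existing copy; configurable to 0) with RK45 at
relative tolerance 1e-8; the crossing of the target frequency (0.5 by
default: "take-over" means reaching half the population) is located by
event root-finding. With `u = 0` it reduces to the logistic sweep
`t = ln[(p_t/(1-p_t))/(p0/(1-p0))]/s`, which the tests verify to 1e-6
relative error. An optional flag multiplies the influx by the classical
establishment probability `2s` (off by default). This functional form is a
reconstruction: it is the minimal frequency equation consistent with
take-over time as a function of deletion rate, parameterized by `s` and
`N`.

**Stochastic serial passage.** Growth–mutation–bottleneck cycles. Within a
cycle both classes grow deterministically (mutants at per-generation factor
`2(1+s)`); mutation events arise per generation as Poisson draws with mean
`u x (wild-type divisions)`; the daily bottleneck samples `N0` cells
binomially at the current frequency. Mutations occur during growth only
(they require replication), and each event seeds **both** daughters of the
mutated division — a 2-cell lineage. The 2-cell convention is what makes
the stochastic model's mean-field frequency influx exactly the `u(1-p)`
per generation of the deterministic equation (seeding one cell halves it),
so both models describe the same measured `u`. The default passage regime
is the experimental daily transfer of ~1e6 cells regrown to `N`
(`generations_per_cycle = log2(N/N0)`); at `N = 1e9` this is exactly the
1:1000 daily dilution (~9.97 generations/cycle). For model populations
below 1e7 the bottleneck is capped at `N/10`. Replicates that do not reach
the target within the horizon (default 1e4 generations) are counted and
reported separately, never averaged in.

With `s = 0`, `u = 0` the mutant frequency is a martingale (binomial
sampling preserves its mean), so the probability of hitting a target
frequency before loss is `p0/target` — a property test checks this. The
stochastic mean take-over time approaches the deterministic one when the
surviving mutation supply through the bottleneck is not limiting; at
`N = 1e7`, `u = 1e-7`, `s = 0.05` the two agree within ~11% in our tests.
With a much tighter bottleneck the stochastic model becomes
supply-limited and far slower than the deterministic curve — a real
regime, not an error.

## Synthetic data: what it does and does not emulate

The generators reproduce the sampling distributions the estimators assume:
Luria–Delbrück skew (jackpots) across parallel cultures, conditioned-
uniform deletion endpoints over the deletable window, exact planted direct
repeats at junctions, binomial counting noise at competition timepoints,
and additive OD noise with a detection floor. They deliberately omit:
mutant/wild-type growth-rate differences within fluctuation cultures,
phenotypic lag and partial plating efficiency, sequence-dependent deletion
hotspots (endpoints are uniform), mismatch-containing repeats, day-to-day
environmental variation in competitions, and plate effects in growth
curves. Passing tests therefore validate the estimators under their own
assumptions; they do not show robustness to these real-data violations.

Default generator parameters are the assay conditions the package models:
9 cultures of 1e6 → 1e9 cells, plating fraction 0.9, deletions >= 2 kbp
(the three-marker cassette spans ~2 kbp), deletable windows of order
10 kbp per side, planted homology lengths splitting 19:11 between 6–15 bp
and 0–4 bp across 30 junctions, `s_true = 0.05`, 5 daily cycles of
~9.97 generations with 1e5 events per timepoint, and logistic growth at
1.2/h to K = 1.5 OD with 0.005 OD noise.

## Numerical choices

- Root-finding: Brent on a fixed bracket `(1e-6, 1e6)`; no-root conditions
  raise with the bracket named.
- ODE: RK45, `rtol = 1e-8`, `atol = 1e-18` (initial frequencies can be
  1e-9), event-based crossing detection.
- Randomness: every generator draws from
  `numpy.random.default_rng([stream, seed])` with a fixed per-generator
  stream id, so one root seed fans out to independent, reproducible
  streams; the pipeline derives per-region seeds from the root seed.
- TSV floats are written with `%.17g` and parsed with round-trip
  precision, so write→read→write is byte-identical.
- Ties in the max-slope window fit go to the earliest window; flat curves
  fit slope 0 with r² defined as 1.
- Degenerate deletion windows (minimum size equal to the whole window)
  are produced exactly rather than by rejection, which would almost never
  terminate on integer endpoints.

## Problem sizes in the test suite

Statistical checks run at sizes chosen to make their tolerances
comfortable: 500 assays per estimator-recovery condition, 500 simulated
competitions at the `s = 0.003` sensitivity floor, 1e5 draws for the
endpoint-distribution KS check, 1000 random genomes for the junction null
tail, 100 replicates for stochastic/deterministic agreement, and 1000
replicates for drift controls. These are sample-size choices, not model
parameters.

## Known limitations

- The deletable-window bounds assume uniform endpoints; clustered real
  endpoints (e.g. repeat-mediated hotspots) would bias `L_est` low.
- The median method's bootstrap CI is approximate for n = 9 cultures.
- The take-over models treat a single beneficial class: no clonal
  interference, no multiple-mutation genotypes.
- Junction scoring is exact-match only and reports a single maximal
  repeat; imperfect (mismatch-containing) homeologies are invisible to it.
- The P0 method saturates above `m ≈ 5`; use the median method there, as
  the pipeline does automatically.
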