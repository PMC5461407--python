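# Methods

## The cell-cycle model

The package models an exponentially growing, steady-state culture of a
diploid bacterium. Each generation of length `td` (minutes) contains
one synchronous replication initiation (all origins of both chromosome
sets fire together), one termination of the round due in that
generation, and one division. The replication period `C`, the
termination-to-division period `D`, the ploidy `p` (chromosome sets per
newborn cell, default 2) and the genome length `L` are the full
parameter vector.

Copy-number averages follow from the steady-state age distribution
`φ(a) = (2 ln2/td)·2^(−a/td)` on `[0, td)`:

- mean origins `Ī = p·2^((C+D)/td)`, mean termini `T̄ = p·2^(D/td)`,
  oriC/terC ratio `2^(C/td)`;
- mean DNA content `p·(td/(C ln2))·(2^((C+D)/td) − 2^(D/td))` genome
  equivalents, obtained by integrating the per-age fork tree against
  `φ`; as `C → 0` it tends to `T̄`.

Inversion gives the inference route: `C = ln(I/T)·td/ln2` from the
marker-frequency ratio, then `D = ln(Ī/p)·td/ln2 − C` from the mean
origin count. The printed equation for `D` in the source material has
unbalanced parentheses; the reading adopted here is the unique one that
reproduces the tabulated periods from their tabulated inputs. With
`p = 1` every formula degenerates to the classic monoploid
Cooper–Helmstetter model, which the tests use as an independent oracle
(numerical integration of the per-age state against `φ`).

Event ages within a generation: initiation at `a_i = n·td − (C+D)` with
`n = ceil((C+D)/td)` concurrent rounds, termination at `td − D`. Round
orders above 2 (`C + D > 2·td`) are rejected — they do not occur in the
growth regimes this package targets, and supporting them would
complicate the per-cell fork tree for no measurable case. `D ≥ td` is
likewise rejected (exactly one termination per generation).

Reported periods are rounded to the nearest minute and fork speeds
(`(L/2)/(60·C)` per fork, bidirectional replication) to the nearest
10 bases/s, matching how such values are conventionally tabulated;
all internal arithmetic is unrounded. One knowing deviation: the model
mean `Ī(78, 20, 63) = 5.88` differs from the measured 5.90 used as an
inference input — the measurement is flow cytometry data, not a model
output, so exact agreement is not expected and not forced.

## Population simulator

`popsim.cell_state_at_age` evaluates the deterministic schedule. Within
the supported regimes a chromosome set is, at any age, one of four
configurations; the general bookkeeping is: the set has `leaves = 1`
complete chromosome before this generation's termination and 2 after,
and the `j`-th oldest active round (0-based, replicated fraction
`p_j = elapsed/C`) contributes `2^j · p_j` genome equivalents per leaf
and runs on `leaves·2^j` origin pairs. This makes DNA content exactly
double over one generation for any valid parameters, which is asserted
in the tests.

Runout histograms place the age-CDF mass below `a_i` on the
pre-initiation origin count and the rest on its double; the analytic
mean equals `Ī` exactly. Coverage profiles use the locus-level average
`c(x)/c(ter) = 2^(C(1−x)/td)` at replichore fraction `x`, mapped to a
circular genome with oriC at 0 bp and terC at `L/2`; windowed values
are evaluated at window midpoints (so the first-window value sits
slightly below the exact oriC endpoint — endpoint identities are tested
against the closed form, not the windowed track).

The focus-count observation model: each sister-origin pair created at
this generation's initiation stays one focus until its cohesion time
elapses. Cohesion times default to a gamma distribution with shape 3,
truncated to [5, 80] min, with the scale calibrated (by root finding)
so the *truncated* mean is 36 min — the measured mean and range; the
family is configurable ("uniform", "fixed"). Sister termini merge with
probability 0.5 by default; this is a declared convention (the real
terC colocalization mechanism is spatial, not per-pair Bernoulli), kept
because only the direction of the undercount matters for the analyses
here. Pairs still cohered at division are not tracked across the
division (cross-generation cohesion exists in reality; modelling it
would break the even-segregation bookkeeping for, at these parameters,
a small tail effect).

## qPCR stage

Technical replicates are aggregated by arithmetic mean of Ct per
(sample, marker class) before ΔCt; ratios are `2^−ΔCt`, normalized as
`2^(ΔCt_ref − ΔCt)` against a replication-runout reference sample whose
true ratio is 1 by construction. Normalization cancels marker-specific
offsets; it uses a per-run reference by default. Primer efficiencies
(`E = 10^(−1/slope)` from dilution curves) are reported as a quality
check but do not correct ratios by default; an efficiency-corrected
mode exists. Dispersion is the SD over all (ori, ter) replicate
pairings — exact for triplicates — with a bootstrap alternative.

Because the estimator exponentiates a Gaussian Ct difference it carries
a small convexity bias (≈ `(σ_ΔCt·ln2)²/2` relative); at the default
noise (sd 0.1 cycles, triplicates, noisy reference) the per-run SD of
the ratio is ≈ 0.2 at a true ratio of 2.36. Tests assert unbiasedness
within Monte-Carlo error plus this bias allowance.

## Flow-cytometry stage

Densities are estimated on the log-signal axis by fine histogramming
(2048 bins) under a Gaussian kernel with a Silverman-rule bandwidth —
numerically equivalent to a KDE at O(n + bins) cost. The grid is padded
by four bandwidths so modes can never sit on a grid edge. Gating
thresholds sit at the density minimum between the two highest label
modes; a unimodal label density is an error rather than a guess.
Calibration matches the standard's refined peak positions to
`count · genome_Mb · k` by least squares; the cross-species conversion
(standard 4.22 Mb vs sample 3.21 Mb) assumes fluorescence linear in DNA
mass. Counting assigns nearest integers by default (transparent,
deterministic); at CV ≈ 6% the hard-assignment histogram leaks mass to
neighboring integers, so a constrained-mixture mode (means fixed at
integer multiples, shared CV, EM) reports component *weights*, which
are unbiased where tallies are not. Events below 0.5 chromosome
equivalents are excluded as debris and warned about beyond 5%.

## Demographs and focus statistics

Records are oriented so the brighter pole (old-pole marker) sits at
relative coordinate 0; exact ties are left unflipped and flagged. Rows
are sorted ascending by length and normalized per cell (max = 1 by
default, sum = 1 optional). Focus positions are rendered with a
triangular kernel two bins wide — a point-spread stand-in, width
configurable. Focus counting chains positions closer than
`min_separation` (default 0.1 relative units, a declared convention for
optical resolution, not a measured value) and is monotone
non-increasing in that parameter. The regression stage is plain OLS of
count on length with Pearson r.

## Synthetic-data generator

The generator's defaults are the study conditions: doubling times
63/83/130 min with (C, D) = (78, 20)/(96, 18)/(97, 26) min, ploidy 2,
genome 3.21 Mb; newborn length 2.01 µm, pre-division length 3.94 µm
(SDs 0.2/0.4 µm — chosen as realistic morphological spread, not
measured values); cohesion mean 36 min on [5, 80] min; Ct noise sd 0.1
cycles in triplicate with baseline 20 cycles (the baseline cancels in
every ratio); flow CV 6% with 50,000 events, a {4, 8}-chromosome
4.22 Mb standard at 25% of events, 2% debris, and label-channel modes
separated 100-fold (lognormal sd 0.4) so gating is easy unless
deliberately degraded. Elongation is exponential between newborn and
division length (the organism grows apically; no growth law is
published, linear mode available). Old-pole marker contrast defaults to
2:1 with lognormal noise — a declared convention. Released sister
origins migrate linearly from their pole anchor (0.05/0.95) toward
staggered septum-flanking targets (0.42/0.58, then 0.30/0.70), which
reproduces the observed ~4 origin foci in pre-division cells and the
central terminus band in demographs.

What the generator does *not* emulate: initiation-age jitter and
cell-to-cell period variability (both off by default — the real
culture's 10- and 12-chromosome runout cells require asynchrony the
source data do not quantify, so the synchronous model's runout support
is exactly two counts); spatial point-spread overlap beyond the merge
rules; segmentation errors; non-exponential growth phases. Passing
recovery tests therefore demonstrate estimator correctness under the
stated statistical structure, not robustness to every real-data
artifact.

## Problem sizes and numerics

Monte-Carlo convergence checks use 10^5 cells (tolerance 3/√n);
parameter recovery uses 100 seeds of one qPCR plate plus 50,000 flow
events each, with medians compared at ±2 min (C) and ±3 min (D). These
sizes give comfortable margins relative to the estimator SDs while
keeping the suite quick. Root finding for the truncated-gamma scale
uses Brent's method on a log-scale bracket; truncated sampling is exact
inverse-CDF, so cohesion draws never leave [min, max]. Degenerate
inputs (C → 0, C+D = td, unit ratios, empty inputs) are covered by
explicit limits or errors rather than silent continuation.
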