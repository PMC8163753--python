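# Methods

## Scope and model

`nucruler` quantifies how nucleosome arrays are organized around genomic
"barriers" — DNA-bound general regulatory factors (GRFs) such as Reb1,
double-strand-break (DSB) ends such as BamHI cut sites, or annotated +1
nucleosomes — from MNase-seq-style dyad coverage, and simulates the
*remodeler ruler* mechanism proposed to generate that organization: a
remodeler-intrinsic element that biases nucleosome sliding direction as a
function of the distance to the nearest barrier.

All coordinates are 0-based half-open (BED convention). The nucleosome
core footprint is 147 bp; half-footprint 73 bp.

## Read processing

Each mapped single-end read stands for one nucleosome whose dyad lies 73 bp
3′-ward of the read's 5′ end: plus-strand reads give `dyad = start + 73`,
minus-strand reads `dyad = (end − 1) − 73`. Each dyad is replaced by a
50 bp fragment `[dyad − 25, dyad + 25)`; per-base coverage of these
fragments is the dyad-density track. The 50 bp window is centered (dyad
just left of center) rather than extended directionally, because composite
peak maxima are interpreted as dyad positions; the residual 1 bp asymmetry
of an even window cancels when up- and downstream features are averaged.
Fragments that would leave a chromosome are dropped, not clipped, so total
coverage is exactly 50 × retained fragments — a conservation law the tests
assert.

## Site alignment and composites

Coverage is extracted in a 2001 bp window (offsets −1000..+1000) centered
on each barrier site; minus-strand sites are orientation-flipped so
positive offsets always point downstream of the motif. Sites within
1000 bp of a chromosome end are excluded (not zero-padded) to avoid edge
artifacts. Each row is divided by its own mean ("per-site normalization";
the mean is chosen so every surviving row averages 1 and the composite is a
weighted occupancy shape); all-zero rows are dropped and counted. The
composite profile is the column-wise mean.

Site selection emulates ranking by an external binding track: the score is
the mean of that track's aligned matrix over offsets [−280, −160) — a
120 bp window ending 160 bp upstream of the alignment point — and the top
⌈12.5%⌉ of sites are kept, ties broken by site id so selection is
permutation-invariant. Promoter grouping classifies GRF sites within
400 bp upstream of a TSS: group 1 motif on the downstream gene's sense
strand, group 2 antisense, group 3 bidirectional (divergent genes on both
sides), otherwise "other".

## Peak calling and array features

The composite is smoothed with a centered moving average (default 15 bp,
odd). The first downstream peak is the argmax over offsets
[30, 30 + 250]; each next peak is the argmax over
[previous + 100, previous + 250] (the 100 bp lower bound is below any
physical nucleosome repeat, the 250 bp upper bound above the repeats seen
in practice); calling stops when the search window leaves the profile or
the candidate's height falls below 0.1 × the first peak's height. The
upstream side is mirrored. Tie handling: a contiguous run of tied maxima —
the plateau produced by noise-free boxcar composites — resolves to its
center, rounding away from the alignment point; disconnected tied maxima
resolve to the smallest |offset|. Flatness is judged on the *unsmoothed*
profile within the search region: a constant stretch yields no peaks
rather than a spurious plateau edge. No sub-bp interpolation is applied;
peak offsets are integers and feature estimates consequently carry ±1–2 bp
discretization noise.

Features per side: `distance_to_barrier = |first peak offset| − 73`
(barrier center to the proximal flank of the first nucleosome) and
`linker_i = |peak_{i+1} − peak_i| − 147`. Averaged features are the mean
over the sides on which they could be computed; averaging happens after
per-side feature extraction, not on profiles. Replicate aggregation is the
arithmetic mean per feature, skipping replicates in which a feature could
not be called.

## Synthetic data generator

The generator emulates barrier-anchored phased regular arrays, the study
condition the pipeline is validated against. Defaults: phasing distance
80 bp, linker 60 bp, 3 nucleosomes per side on both sides, 147 bp
footprint, positional jitter sd 15 bp, 50 bp reads at 100 reads per dyad
with balanced strands. Nucleosome k (k = 1..n) downstream of a site has
mean dyad `center + phasing + 73 + (k−1)(147 + linker)`, mirrored
upstream; jitter is drawn independently per nucleosome (so the expected
spacing equals the parameter; a cumulative mode is available behind a
flag), rounded to integer bp; colliding dyads are pushed apart
symmetrically to exactly one footprint, preserving order. Reads place
their 5′ ends 73 bp outside the dyad on each strand — the exact inverse of
the recentering step, which the round-trip tests exploit. The jitter sd of
15 bp is a modeling choice for reconstituted chromatin, not a measured
value.

What the generator does **not** emulate: MNase sequence bias and
over/under-digestion, sequence-dependent nucleosome positioning, occupancy
differences between sites, background (non-array) nucleosomes, and mapping
artifacts. Passing recovery tests therefore demonstrates correctness of
the quantification arithmetic and estimator behavior under positional
noise — not robustness to the full error structure of real MNase-seq.

## Ruler model

A nucleosome on a 1D lattice slides ±1 bp with rates set by the gap d
(free bp) between its flank and the nearest barrier edge on that side —
explicit barriers, or a neighboring nucleosome's flank. With ruler reach
a (region A) and b (region B), reciprocal mode sets
`r_toward = r0(1 − β)`, `r_away = r0(1 + β)` for d < a, the reverse for
a ≤ d < a + b, and `(r0, r0)` beyond. Asymmetric mode modulates only the
toward-rate. Kinetic-release mode is reciprocal with both rates scaled by
(1 − γ) at exactly d = a, making the equilibrium a total-rate minimum
without moving it. The stationary gap distribution peaks at the A/B
boundary; on the discrete chain the detailed-balance ratio across that
boundary is exactly 1, so the mode is the pair {a−1, a}.

Composition with two engagements (e.g. barrier left, neighbor right): each
direction's rate is r0 × toward-multiplier of the movement-direction gap ×
away-multiplier of the opposite gap, each factor 1 when that side is out
of reach. This reduces exactly to (r_toward, r_away) for a single engaged
barrier and contains no joint (d_L, d_R) term beyond the product.

Barriers with footprint w > 0 block a centered interval; footprint 0
(DSB-like) is an infinitely thin wall between positions c−1 and c that
blocks crossing but occupies no bp. A Reb1-like factor can be given
w ≈ 20 bp. Domain ends are reflecting walls without ruler interaction.
"Soft" barriers (partial invasion by the ruler) can only be caricatured by
reducing the effective nucleosome footprint. Steps are 1 bp; multi-bp
stepping is not modeled.

The simulator is exact Gillespie sampling (per-event exponential clocks,
only the moved nucleosome's and its neighbors' rates recomputed), with
*time-weighted* occupancy accumulated after a burn-in. Two independent
oracles validate it: the closed-form birth-death stationary law (single
nucleosome, detailed balance along the dyad coordinate) and a direct
linear solve of the master-equation generator over all enumerated
configurations (multi-nucleosome, reduced footprint; capped at 2×10⁵
states). Steady-state occupancies are converted to array features by the
same peak-calling code used for experimental composites, with the first
search offset clamped to the half-footprint so the exclusion zone next to
the barrier is not mistaken for structure; an unbiased ruler yields a flat
density and an empty peak set.

## Numerical choices and problem sizes

- Gillespie runs in the test and acceptance suites use 10⁶ events for the
  single-nucleosome oracle comparison (L = 500), ~10⁵ time units for the
  clamping scans (L = 2500, up to 14 nucleosomes), chosen to keep total
  variation against the exact law well under 0.05 while the whole suite
  runs in minutes on one core.
- Steady-state runs are initialized at the predicted equilibrium gap; a
  region-C start adds a long unbiased-diffusion transient that only
  inflates burn-in requirements (the stationary law is start-independent).
- With deep wells at two distant barriers (reach 40, bias 0.5) the
  well-exchange probability is ~(1−β)/(1+β) to the power a ≈ 10⁻¹⁴, so no
  finite simulation mixes between wells; symmetry of the dynamics is
  checked exactly via the birth-death law and stochastically in a
  shallow-well configuration where the chain genuinely mixes.
- The master-equation solve replaces one balance row with the
  normalization constraint and clips negative round-off before
  renormalizing (entries ~1e−16).
- Overlap resolution after jitter iterates symmetric pairwise pushes
  (capped, with a left-to-right sweep fallback); at the default linker 60
  and jitter 15 collisions are ~0.2% of neighbor pairs.

## Known limitations

- Per-site (single-locus) nucleosome calling and occupancy/positioning
  deconvolution are out of scope; features describe composite averages.
- Feature estimates are integer bp; differences below ~2 bp are within
  estimator discretization noise at realistic depths.
- The ruler parameterization is a sharp two-level piecewise-constant
  instantiation of a mechanism whose true reach profile is unknown;
  region widths and curve shapes are fully exposed parameters, not fitted
  values.
- The simulator models sliding only: no eviction, assembly, histone
  exchange, or remodeler binding competition.
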