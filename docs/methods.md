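# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, the numerical choices, what the synthetic generators do
and do not emulate, and known limitations.

## matS discovery on circular genomes

**Model.** Candidate signature sites of the replication-terminus
macrodomain are found by two scans over the chromosome: (i) *edit mode* —
every locus whose window (length |p| ± k) is within Levenshtein distance
k of a concrete query p, reporting the per-locus minimum distance; and
(ii) *degenerate mode* — exact matching of a pattern containing N
wildcards. Edit distance is full Levenshtein (substitutions, insertions,
deletions at unit cost); a Hamming-style restriction is obtained by
comparing only |p|-length windows, but indel-aware matching is the
default because candidate sites may differ from the consensus by more
than point substitutions. Circular genomes are scanned across the origin
by extending the text by |p| + k − 1 bases.

**Algorithm.** The scan is pigeonhole seed-and-verify: a window within k
errors of p must contain one of k+1 contiguous pieces of p exactly;
exact piece occurrences (vectorized) nominate candidate starts which are
verified with banded alignments. The result is proven equal to the naive
all-windows dynamic program on random genomes in the test suite.
Overlapping hits (starts closer than |p|) are collapsed to the
minimum-distance, smallest-start representative; palindromic patterns
(equal to their reverse complement, with N self-complementary) are
reported once per forward-strand locus because a palindrome matches both
strands at the same coordinates.

**GC skew.** Per-window skew is (n_G − n_C)/(n_G + n_C), 0 for windows
without G or C; the cumulative curve is its running sum. Following the
leading-strand G-bias convention of cumulative-skew ori/ter prediction,
the terminus is called at the global maximum and the origin at the
global minimum; ties break toward the smaller coordinate, and a flat
curve leaves both calls undefined. Each window is represented by its
(rounded-up) genomic midpoint. Defaults: window = step = 1000 bp
(non-overlapping windows), a standard resolution for bacterial
chromosomes; both are configurable.

**Family ranking.** Families are ranked by the median circular distance
of hit midpoints (start + length/2) to the called terminus, ascending;
ties break lexicographically by pattern. Midpoints rather than starts
are used because the distance of interest is that of the site, not of
its 5′ edge; for 13-mers the difference is 6 bp and never changes a
ranking in practice.

**Global identity.** Needleman–Wunsch with match +1, mismatch 0, linear
gap −1; identity = 100 × matches / alignment columns, counting gap
columns in the denominator. The denominator choice is stated explicitly
because percent-identity values are only comparable under a fixed
convention.

## Gel densitometry and credible intervals

**Background.** A centered moving median with reflected edges estimates
the lane background; the median ignores bands narrower than half the
window. The default window is 3× the widest declared band window —
wide enough that inside a band the majority of window samples are
background. Background-subtracted signal is clamped at 0; band areas are
trapezoidal integrals over declared windows and fractions are normalized
to sum to 1. Fractions are invariant under positive rescaling of the
lane and the background estimate is equivariant under constant offsets
(both property-tested).

**Posterior for replicate efficiencies.** Likelihood xᵢ ~ N(μ, σ²),
prior uniform on μ over a stated box and density ∝ 1/σ² on σ. The σ
integral is analytic: p(μ|x) ∝ (Σ(xᵢ−μ)²)^(−(n+1)/2), evaluated in log
space on a μ grid (default 2001 points) and normalized by trapezoid; a
numeric 2-D marginalization over a truncated log-spaced σ grid
(σ ∈ [10⁻⁴, 10] × data range, ≥ 200 points) is provided as a
cross-check and agrees to 10⁻³ in interval endpoints. Intervals are
equal-tailed (interpolated from the posterior CDF) rather than HPD:
equal-tailed intervals are unambiguous, identical for symmetric
posteriors, and directly comparable against the brute-force oracle. The
posterior mean, posterior sd, and replicate sd are all reported, since
a "± value" can denote either spread.

**Relative signal (entrapment assay).** Per-replicate ratios
xᵢ/mean(reference) form the data; the μ prior is uniform over ±10·|x̄|
with x̄ the ratio sample mean — the only reading of a "±10 μ" prior that
yields a proper finite interval — so weak signals get posteriors
extending below zero. Degenerate all-equal ratios return a point
interval; zero-variance data otherwise raise an error, since σ cannot be
marginalized.

## Cross-link species combinatorics

Sites react independently with their efficiencies pᵢ; a template with k
sites yields 2^k outcomes with probabilities Π pᵢ Π (1−pⱼ).
Independence is a model assumption, not a fact — it is what makes
"expected depletion ratios" arithmetic valid, and deviations from it
would appear as disagreement between implied and directly measured
efficiencies. Covalent species are connected components of the chain
graph under formed-site edges; gel detection keys on the component
containing the reporter (fluorescently tagged) chain. Covalent circles
are the simple cycles of the chain multigraph (every incident vertex of
degree 2, connected; an intra-chain pair forms a one-edge loop), named
against the compartment table ring = {cap, neck, hinge},
clamp = {cap, neck, head}, frame = {head, hinge}. The shipped template
has chains κ-MukB, ν-MukB (reporter type) and MukF; MukE is omitted
because no MukE cysteines are used in the probing scheme. Cycle
detection is exhaustive over edge subsets, which is exact and cheap for
templates of this size (≤ 20 sites enforced).

## Entrapment topology

Catenation is modelled purely by crossing parity: a closed DNA component
is catenated with a circularized compartment iff it crosses any spanning
disk of that compartment an odd number of times. No embedding geometry,
linking-number sign, or knot type is tracked — parity suffices to
reproduce every qualitative retention claim. The frame compartment's
crossings are the per-component sum of ring and clamp crossings, which
enforces frame = ring XOR clamp for single-component configurations
(exhaustively verified for crossings ≤ 5). The shipped candidate set:
double_lock (1,1), ring_only (1,0), clamp_only (0,1), sisters
(1,0)+(0,1), parallel_axis_loop (1,0 with a note — its precise threading
is schematic and the crossing counts are a modelling choice),
pseudo_topological (2,0), non_topological (0,0).

## EMSA equilibrium fitting

The single-equilibrium model P + D ⇌ PD gives the bound fraction as the
physical root of PD² − (P_tot + D_tot + K_d)·PD + P_tot·D_tot = 0.
Ligand depletion is not negligible at a 2 nM probe against candidate
K_d values of similar magnitude, so the quadratic (not the hyperbola) is
the default; the no-depletion hyperbola is available as an option. The
fit is parametrized by (log₁₀ K_d, baseline, asymptote) with k_a an
arbitrary constant fixing the time unit of k_d = K_d·k_a; reported K_d
is invariant under k_a rescaling by construction and verified to 10⁻⁶
over six decades. Optimization: Levenberg–Marquardt least squares with
multi-start over seven K_d decades centered on the top protein
concentration, keeping the lowest residual sum of squares; log-K_d
parametrization keeps the search scale-free. A rate-equation relaxation
d[PD]/dt = k_a(P_tot−PD)(D_tot−PD) − k_d·PD integrated from PD(0) = 0
(LSODA, rtol 10⁻¹¹) provides the independent steady-state check,
agreeing with the algebraic root to 10⁻⁶ when converged; non-converged
calls (relative change per step > 10⁻⁸ at t_end) raise an error rather
than returning a biased value. The protein concentration is the MatP
dimer concentration with 1:1 dimer-to-site stoichiometry; cooperative
and multi-site models are out of scope.

## Structural geometry

Duplex axes are fitted from base-pair midpoints: paired C1′ atoms
(antiparallel pairing by residue index; P fallback) define midpoints
that precess around the true axis at ~2 Å radius; a running mean over
one helical turn (10 bp, the B-DNA default) cancels the precession
before the total-least-squares line fit (SVD), making the fit exact on
ideal helices and debiased on short real duplexes. At least 4 base pairs
are required; below 11 midpoints the raw fit is used. The crossing angle
is arccos|â·b̂| ∈ [0°, 90°] (acute convention, symmetric and
flip-invariant); a signed mode (sign from the triple product with the
inter-axis connector) is provided but flagged experimental because the
sign convention of the plectoneme literature cannot be pinned down from
a single structure.

Minimum backbone VDW distance: min over cross pairs of
‖xᵢ−xⱼ‖ − rᵢ − rⱼ with the attaining pair reported; values < 0 mean
interpenetrating spheres. Backbone atom sets: protein {N, CA, C, O},
nucleic {P, OP1, OP2, O5′, C5′, C4′, C3′, O3′} (chosen per selection by
residue names). Radii default to a Bondi-type table (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, H 1.20 Å), shipped explicitly and swappable
because published values differ at the 0.05 Å level. The computation is
vectorized all-pairs, verified identical to a scalar loop.

Structure I/O is gemmi-backed (PDB and mmCIF); only the first model is
read, and alternate locations resolve to the highest-occupancy conformer
(ties toward altloc A).

## Synthetic data: what it emulates, and what not

Generators are bit-reproducible: streams are keyed by (seed, purpose
tag) so adding a generator never perturbs another's draws.

- *Genomes*: two replichores with P(G)−P(C) = ±a·(P(G)+P(C)) flipping at
  ori/ter (ter diametrically opposite ori), G+C fraction 0.5 by default
  so skew is controlled independently of GC content; A/T fill the
  complement uniformly. Planted sites are substitution-mutated only, so
  recorded positions stay exact. Not emulated: coding structure, repeat
  families, skew heterogeneity, horizontally transferred islands — so a
  perfect ter call here bounds algorithmic error only, not biological
  noise.
- *Lanes*: Gaussian bands (the standard densitometry shape; none is
  dictated by theory) on a polynomial background with white noise. Real
  lanes add smearing, saturation, and lane-to-lane distortion that the
  generator does not model.
- *Titrations*: exact depletion-aware responses, affinely mapped, plus
  white noise; default 2 nM probe, 12-point half-log series 0.5 nM–5 μM
  plus a zero point, K_d 50 nM, 1% noise — a realistic EMSA layout.
  Pipetting error correlated across the series is not modelled.
- *Replicates*: i.i.d. normal draws; real biological triplicates may
  have heavier tails.
- *Helix scenes*: pseudo-atom duplexes (C1′ and P on a cylinder, rise
  3.4 Å, twist 36°/bp) whose axes subtend the requested angle exactly by
  construction; recorded axis directions make the round trip testable
  without a fit. Grooves, sequence-dependent geometry, and bending are
  absent, so angle-recovery tests validate the fit machinery, not its
  robustness to curved DNA.

## Problem sizes

The default verification suite runs entirely on synthetic data:
genomes of 50–200 kb (the discovery round trip in the acceptance script
uses a 200 kb chromosome with the nine-member site family planted around
the terminus, a deliberate scale-down of a multi-Mb chromosome that
preserves the statistical structure of the scan), 1000-px lanes,
13-point titrations, 100-fit recovery ensembles, and 50-seed scene
ensembles. Chance background matches of a 10-concrete-base degenerate
pattern occur at rate ≈ L/4¹⁰, so a 200 kb genome occasionally shows one
extra family locus beyond the planted nine; the planted-site recovery
fraction is the scale-free quantity.

## Known limitations

- The accession-based checks (chromosome scan count, deposited-model
  crossing angle and neck-gate VDW distance, AcpP orthologue identity)
  require the deposited data to be fetched into `data/accessions/`; the
  interface residue ranges for the neck gate are not published as
  machine-readable selections and must be supplied explicitly
  (`selections.json`), as documented in the README.
- Lane-species grouping (which partially cross-linked species co-migrate
  on a given gel) is empirical; the species model exposes raw outcomes
  and leaves grouping to the caller.
- No PWM/probabilistic motif models, no knot/link polynomials, no
  kinetic (time-resolved) binding analysis, no cryo-EM processing or
  model refinement.
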