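# Methods

## Elastic model of forced nucleosomal DNA deformation

DNA is treated as a shearable elastic rod of base-pair steps, each with six
rigid-body degrees of freedom (shift, slide, rise, tilt, roll, twist;
Cambridge convention). Nucleosome formation forces a window of odd length
*L*, centred on the putative dyad, onto the ideal superhelix (radius 41.9 Å,
pitch 25.9 Å). Two linear constraints encode that geometry:

1. the phase-projected roll/tilt sum equals the superhelical curvature α;
2. the phase-projected slide/shift sum equals the screw-axis displacement
   *S* = 41.96 Å.

The torque (force) is assumed uniform along the window, and each step
responds harmonically and independently of its neighbours:
ρ(i) = ρ₀(i) + F_b·cos Ωᵢ / k_roll(i), and likewise tilt with sin Ωᵢ,
slide/shift with F_s. Eliminating F via the constraint yields
E = (α − A₀)²/2C per window (see the README for A₀ and C). This closed form
is exactly the minimiser of the diagonal harmonic energy subject to the
linear constraint; the test suite verifies it against an SLSQP
quadratic-programming oracle to 1e−8 on random toy windows.

**Phase convention.** Roll couples to cos Ω and tilt to sin Ω (slide/shift
analogously). With the complement rules below this makes both energies
exactly strand-symmetric: re-reading a window on the reverse complement maps
step +i to step −i with tilt/shift negated and Ω antisymmetric, leaving every
term of A₀ and C unchanged. An intrinsically bent step placed where cos Ω is
large and positive reduces the residual bend α − A₀ and hence the energy —
the mechanical reading of 10-bp rotational positioning.

**Twist phasing.** Step twists are the table equilibria rescaled by a common
window factor so they sum exactly to (L−1)·Ω̄, with Ω̄ = 34.52° the mean step
twist of the 1kx5 nucleosome crystal structure (~10.4 bp/turn). Ωᵢ is
accumulated at the *centre* of step i: half of the step's own scaled twist
plus the full scaled twists between it and the dyad, so Ω±1 = ±half the first
step's twist. The phases are therefore sequence-dependent, not a fixed
crystallographic ruler.

**Window parameters.** Defaults: L = 129 (the curved central part of the
147-bp core; the two straight 9-bp ends contribute little curvature) with
α = 579°; L = 147 uses α = 600°. For any other L, α must be supplied
explicitly — the printed pair is not linear in L, so no interpolation is
assumed. Energies are reported per step (divided by L−1, the step count) for
bend and shear alike. Windows containing ambiguous bases are flagged invalid
(NaN + mask), never imputed or zeroed.

## Parameter estimation

Equilibrium geometry and force constants per dinucleotide are estimated from
base-pair-step observations (the output dialect of standard DNA-geometry
analysis of protein–DNA crystal structures; this package does not compute
step parameters from coordinates). The pipeline assumes clean ACGT steps —
chemically modified bases are expected to be excluded upstream.

* **Outlier rejection**: one non-iterative pass; a step is dropped if any of
  its six parameters deviates more than 2 sample SDs from its dinucleotide
  type's mean, both computed on the unfiltered input (avoids anharmonic
  tails).
* **Equilibria**: roll/twist/slide are means over the complement-equivalence
  class (partner-strand records sign-flipped on tilt/shift before pooling —
  a no-op for these three). Tilt and shift are computed per strand and
  antisymmetrized, t₀(d) = (t̄(d) − t̄(d′))/2, so complementary values differ
  only in sign; self-complementary dinucleotides (AT, TA, CG, GC) are set to
  zero — tilt has no preferred opening direction there, and the strand
  reading of shift is arbitrary. The antisymmetric part is the minimal
  projection achieving sign symmetry; the symmetric remainder is discarded.
* **Force constants**: per class, the 6×6 sample covariance of deviations
  about the pooled class means is inverted and the diagonal entries for
  roll, tilt, slide, shift reported. Rise participates in the inversion
  (it carries real couplings) but its stiffness is discarded, since rise
  enters no energy term. Cross-couplings are likewise discarded because the
  energy model is diagonal-harmonic. Ill-conditioned covariances
  (condition number > 1e10) raise with the condition number rather than
  falling back to a pseudo-inverse.
* **Once-only counting**: each physical step enters the covariance once.
  Duplicating self-complementary steps onto the complementary strand zeroes
  the tilt/shift means and inflates their variances to mean² + variance
  (≈4-fold when the per-strand mean is √3 times the SD), destroying the
  comparability of force constants across dinucleotides; the test suite
  asserts this pathology on synthetic samples.

The covariance is inverted per pooled complement class (not per strand); the
deviations are taken about the pooled frame-mapped means rather than the
symmetrized equilibria, which matters only when strand sampling is
unbalanced. Units: degrees and Å; force constants in kT/deg² and kT/Å². Any
global energy scale is absorbed by β in the thermodynamic layer.

## Thermodynamic layer

The grand-canonical model treats nucleosomes as hard rods of `footprint` bp
(default 147) on a linear lattice, exchanging with a reservoir at fugacity τ;
a rod starting at i weighs τ·exp(−β·E(i)), where E(i) is the energy profile
value at the rod's dyad (i + (footprint−1)/2). Forward/backward partition
recursions over non-overlapping configurations give exact start
probabilities in O(N); all arithmetic is in log space, so β·E up to 1e4
cannot overflow. Invalid starts carry +∞ energy and exactly zero
probability. No periodic wrap: rods cannot overhang sequence ends. The DP is
verified against exhaustive configuration enumeration on small lattices
(≤14 bp, footprints 3–5) to 1e−10.

The Boltzmann alternative normalises exp(−β·E) over all legal starts of the
sequence with no steric exclusion, and rescales the footprint-window
occupancy to a maximum of one (the exact normalisation is a convention; all
downstream uses are scale-free correlations and rankings). Defaults follow
the occupancy-fitting regime (τ = 0.001, β = 15, shear channel); dyad-
probability work uses τ = 0.35, β = 35 on the bend channel. τ is a
multiplicative fugacity — the minimal embedding of a chemical potential given
that τ and β are the model's only thermodynamic knobs — and adding a constant
c to all energies is exactly equivalent to τ → τ·e^(−βc) (asserted in tests).

Footprints of any positive length are accepted (the exhaustive-enumeration
cross-checks use even toy footprints); dyad re-centring uses
floor((footprint−1)/2).

## Dyad calling and periodicity

Dyads are strict local extrema (minima of bending energy or maxima of dyad
probability); plateaus contribute their central index, and calls closer than
`min_separation` (default 5 bp) are thinned greedily — better score wins,
leftmost wins ties. The published behaviour is unsmoothed; an optional
moving average is deliberately not applied by default. Matching pairs each
reference dyad with its nearest call (ties to the smaller coordinate) and
reports signed offsets, the count within tolerance (default 2 bp) and the
mean absolute offset.

Rotational periodicity is quantified as FFT power in the 9–11.5 bp period
band after mean detrending (segments ≥ 32 bp). The core-vs-flank ratio uses
a direct projection onto band-period harmonics instead of the FFT so that
19-bp flank segments can be scored at all; amplitudes are normalised by n²
so a coherent sinusoid scores independently of segment length.

## Synthetic data: what it emulates and what it does not

The generators plant ~10-bp periodic dinucleotides on an i.i.d. background
of configurable GC content (default 0.39, yeast-like) — the in-phase
AA/TT-class vs out-of-phase GC-class oscillation of real nucleosomal DNA.
The packaged benchmark (10 sequences × 380 bp, 2 planted dyads each, 20
total; fixed seed, SHA-256-checked at load) imposes a dyad-phased roll
signal out to ±60 steps: high-roll dinucleotides (CA/CG/TG) where
cos((|k|−½)·Ω̄) > 0.6, AA/TT below −0.6. Sequence identifiers carry a
`_synth` suffix and the generating code ships in the package; the benchmark
is a constructed stand-in, not experimental data.

Consequently, passing the benchmark shows that the model detects phased
flexibility signals with base-pair precision under its own parameter table —
it does not certify accuracy on real in-vitro reconstitution data, where the
positioning signal is weaker, parameter error matters, and competing
positions overlap. Similarly the synthetic forming/inhibiting classification
(phased signal vs poly(dA:dT)-rich tracts) probes the occupancy machinery's
discrimination, not genome-scale accuracy. Genome-scale evaluation against
experimental occupancy maps requires external downloads and is out of scope
for the shipped test suite; the generic track/FASTA readers and the
`eval` commands support it when such data are available locally.

The packaged default parameter table is synthetic as well: calibrated once
to B-DNA crystallographic survey averages (flexible pyrimidine–purine steps
CA/CG/TA with high positive roll and soft constants, stiff AT-rich steps,
mean twist ≈ 34.4°), satisfying every table invariant. Users with access to
curated crystal-structure step tables should estimate their own table via
`nucdeform params estimate`.

## Numerical choices and limitations

* Profile sizes: the acceptance script uses a 10-kb synthetic genome and
  ~60 classification regions — ample for stable correlations/AUC while
  keeping runs at desk scale.
* Benchmark fixed seed 24133; all other randomness is caller-seeded.
* Tolerances: closed form vs QP 1e−8; DP vs enumeration 1e−10; twist-sum
  1e−9 relative; TSV round trips at 12 significant digits.
* The model omits histone–DNA contact energies, cross-couplings between step
  parameters, tetranucleotide context, multimodal conformational substates,
  and remodeler/barrier effects; it scores intrinsic sequence preference
  only. Bending dominates total energy and carries the dyad signal, while
  the smoother shear channel tracks coarse occupancy better — a consequence
  of footprint-window averaging, reproduced qualitatively in the test suite.
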