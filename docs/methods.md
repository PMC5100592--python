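# Methods

## The two-state equilibrium model

Each base pair of a closed circular duplex is either intact or
separated.  A microstate is a set of `r` disjoint circular runs of
separated base pairs (any two runs separated by at least one intact
pair), totalling `n` open base pairs, with free energy (kcal/mol)

```
g(state) = a_nuc · r + Σ_{i open} b_i + Q(n, α)
```

* `a_nuc · r` — nucleation: each run pays once for creating two
  helix/coil interfaces.  This term is what makes one large bubble
  cheaper than several small ones of the same total size.
* `b_i` — copolymer separation energetics: a single value for every
  A·T pair (`b_at`) and a single larger value for every G·C pair
  (`b_gc`).  No nearest-neighbour refinement is used.
* `Q(n, α)` — torsional term.  The enforced linking difference
  `α = Lk − Lk0` (turns) is partitioned between the interstrand
  helicity `τ` (rad/bp) of the open regions and the residual
  superhelicity `α_r = α + n/A − nτ/2π`, where `A` is the helical
  repeat unwound per separated base pair.  With harmonic energies
  `(c_ss/2)·n·τ² + (K/2)·α_r²` the minimisation over τ is a quadratic
  with the closed form

  ```
  Q(n, α) = K d² / (2 (1 + nK / 4π²c_ss)),    d = α + n/A,   n > 0
  Q(0, α) = K α² / 2
  ```

  `K` is the empirical quadratic supercoiling coefficient
  `2200·R·T/N` per turn² unless overridden.

Boltzmann weighting all states with `r ≤ r_max` and `n ≤ n_max`
(intact state included) at temperature `T` gives the partition
function, per-bp marginal opening probabilities, run-class masses and
two-site joint probabilities.  Bending stress is deliberately outside
the model: it sees topology and pairing thermodynamics only, so
phenomena driven by circle geometry (cooperative antipodal kinking)
appear here only through the synthetic generator's explicit coupling
term, never through the equilibrium model itself.

### Parameters, units, defaults

| parameter | default | unit | role |
|---|---|---|---|
| `a_nuc` | 10.8 | kcal/mol | nucleation cost per open run |
| `b_at`, `b_gc` | 0.55, 1.35 | kcal/mol | separation cost per A·T / G·C pair |
| `helicity_A` | 10.4 | bp/turn | unwinding per separated bp |
| `c_ss` | 2.9 | kcal/(mol·rad²·bp) | interstrand twist stiffness of open DNA |
| `k_res_coeff` | 2200·R·T/N | kcal/(mol·turn²) | residual superhelicity stiffness |
| `temperature_K` | 300 | K | |
| `r_max` | 2 | — | maximum simultaneous runs |
| `n_max` | min(N−2, 50) | bp | maximum total open bp |

The energy constants are literature-informed values appropriate to
300 K and 0.1 M monovalent salt; they are configuration defaults, not
fitted quantities, and every headline behaviour checked by the test
suite (site selection by AT-rich regions, stress-sink behaviour,
single-bubble dominance, monotone stress response) is robust to
moderate changes in them.  `r_max = 2` reflects the physics of
~100-bp circles, where the nucleation penalty makes triple-bubble
states negligible; the enumeration path supports arbitrary `r_max`
for validation.

### Enumeration and numerics

For `r_max ≤ 2` the profile is computed vectorised: single-run
energies from circular prefix sums (O(N·n_max)), two-run sums as
sliding-window correlations over run Boltzmann factors
(O(N·n_max²)), and marginal accumulation by difference arrays.  For
`r_max > 2` an explicit recursive run-placement enumeration is used.
Both paths, and an independent 2^N bitmask oracle in the test suite,
agree to ~1e−15.

All weights are exponentiated relative to a lower bound on the minimum
state energy, so no intermediate overflows; probabilities that
underflow to zero are genuinely negligible.  Argmax ties break to the
lowest 1-based index.  Normalised profiles divide by the per-circle
maximum of `p_raw` (relative, not absolute, probabilities are the
comparable quantity between circles); raw values are always retained.

The accumulation dtype is selectable.  The DESIGNED circle is a
deliberate near-degeneracy: its three contiguous 12-bp A/T motifs are
identical under copolymer energetics except for O(e^{−30}) bridging
states, so their ordering margins (~1e−18 relative to p ~ 1e−5) sit
below float64 summation noise.  `dtype=numpy.longdouble` pushes the
noise floor to ~1e−28 and resolves the ordering deterministically
(the computed margins are bitwise stable under rotation of the
circle).

### Joint profiles

`joint_profile` reuses the explicit enumeration and therefore scales
with the state count; it is intended for small circles or reduced
`n_max`.  Pairs that co-open in no enumerated state carry a NaN
sentinel (written as `NA`), never a large negative number, so band
statistics are not corrupted.

## Trajectory statistics

Open calls use a strict inequality at the 4 Å middle-hydrogen-bond
distance threshold (a pair *exceeding* 4 Å is disrupted) and the
−3.03×10⁻²¹ J hydrogen-bond-energy threshold (less negative = open).
A breathing event is a maximal open episode bounded by closed frames
on both sides lasting at most 1 ns; episodes touching a trajectory end
are discarded because their closure cannot be verified.  Replicate
pooling weights frames equally; across-replicate standard deviations
provide error bars.

Defect classification treats episodes as 4-connected components in
the frame × bp grid (circular in bp): persistent (≥ 10 ns, the
configurable default) multi-bp components are bubbles and single-bp
ones type II kinks; sub-persistence components are wrinkles (or
breathing when single-bp and within the breathing window).  Type I
kinks require the stacking-broken channel with pairing intact at both
flanking pairs, and slips require the pairing-register channel;
missing channels produce warnings and those kinds are skipped, because
deriving stacking or register from 3-D coordinates is out of scope.
"Average twist deviation" is the per-frame mean over steps of
(twist − reference twist); the alternative reading (deviation of the
mean twist) is numerically identical for a fixed step count.

The antipodal statistic is the mean finite log joint probability over
off-diagonal pairs whose circular separation is within a band of N/2,
minus the mean over all other off-diagonal pairs; its null is obtained
by permuting base-pair labels, which preserves the co-opening table
while destroying the circular geometry.

## Synthetic data: what it emulates and what it does not

The open/close generator is Metropolis dynamics on the equilibrium
energy with single-bp flips (moves violating `r ≤ r_max` or
`n ≤ n_max` rejected), recording one frame per sweep.  Detailed
balance makes its long-run marginals equal the restricted-ensemble
equilibrium — verified against the model to within three batch-means
standard errors.  It is *not* a kinetic model: flip attempt ordering,
time scales and pathways carry no physical meaning, only the
stationary law does.  The antipodal coupling (−J when exactly two runs
sit at opposite sides of the circle, within a configurable band)
injects the bending-driven cooperativity that the equilibrium model
lacks, so the detection pipeline can be exercised; it is a caricature,
not a mechanical model.  Distance emission draws closed pairs at
2.0 ± 0.5 Å and open pairs at 6.0 ± 0.5 Å, far from the 4 Å threshold,
so classification noise is negligible by construction — passing tests
therefore validate the statistics pipeline, not robustness to
borderline distances.

Equilibrium-recovery checks run on a 24-bp mixed-sequence circle with
a reduced nucleation barrier (`a_nuc = 3` kcal/mol) and strong stress
(α = −1.2, σ ≈ −0.12 at this size), chosen so opening probabilities
are O(0.1–0.5) and the chain mixes within thousands of sweeps; with
the physical barrier of 10.8 kcal/mol the chain equilibrates far too
slowly for a test-scale run, which is a statement about Metropolis
mixing, not about the model.  Standard errors use 30 batch means with
a binomial floor.

Breathing series are independent per-bp telegraph processes
(`1 − exp(−k·dt)` transition probabilities, stationary initial state).
Default rates give base pairs flanking CA/TA/CG/AT steps a 20-fold
faster opening rate (0.4 vs 0.02 ns⁻¹, closing 2 ns⁻¹), so most
generated events fall at those steps, mirroring the empirical
enrichment of breathing at flexurally soft steps.

The packaged stiffness library is synthetic: plausible means
(including the extreme 29°/42° AG/GA equilibrium twists), larger
angular fluctuations for YpR steps and mild slide–twist / roll–twist
couplings.  It exists so stiffness estimation and elastic-energy
bookkeeping can be exercised end to end; quantitative sequence
comparisons require a real simulation-derived table, supplied as the
documented TSV format.  Likewise `synthetic_random_circle` /
`synthetic_fuse_circle` are labelled stand-ins reproducing only gross
composition (a mixed ~50% AT circle; an 80%-AT 50-bp insert replacing
bp 1–50), not any published sequence — site-level predictions such as
a specific argmax position are only meaningful for the real sequences
read from FASTA.

## Elasticity conventions

Parameter order is fixed package-wide as (shift, slide, rise, tilt,
roll, twist), Å and degrees.  "Correlation matrix" is implemented as
the parameter covariance — the only dimensionally coherent reading of
`A = k_B T C⁻¹` — estimated with the unbiased (n−1) normalisation
because simulation tables are often small.  Covariance matrices must
be symmetric positive definite; singular estimates raise an error
naming the null direction.  Energies are reported in both k_BT and
kcal/mol, and the decomposition (six diagonal terms + one coupling
term) sums to the total exactly by construction.  Circle energies are
evaluated on a single structure (typically the time-averaged one);
mapping over frames and averaging gives the per-frame alternative,
with `mean_structure` provided for the former.

## Design choices and limitations

* 1-based circular coordinates throughout; position N+1 ≡ 1.
* ΔLk is always derived from integer `Lk` and real `Lk0`, never stored,
  because `Lk0` assignment is itself uncertain at these sizes.
* Size correction rounds half to even on the real base-pair count.
* The DESIGNED 106-mer uses a 13-bp leading CG block
  (13+12+15+12+15+12+15+12), the only layout consistent with the motif
  ranges bp14–25/41–52/68–79/95–106; motif phases are (TA)ₙ starting
  T, (AT)ₙ starting A, (CA)ₙ starting C, poly-CG starting C.  The
  108-bp variant grows the leading block by two.
* The stress-sink property (an AT-rich insert suppresses opening
  elsewhere) holds elementwise for all sites distal to the insert; the
  insert's immediate flanks (≲ one helical repeat) can instead gain
  probability because bubbles bridge across the boundary.  This is a
  real feature of the model, not an artefact.
* Known limitations: no bending energetics or writhe in the
  equilibrium model; no temperature/salt recomputation of the
  separation energies; no parsing of binary simulation formats; joint
  profiles are exponential in circle size through the state count.
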