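# Methods

This note documents the models, estimator settings, statistical procedures
and design choices behind `ptenet`, in the order the pipeline runs them.

## Synthetic cohort model

Each subject is an `n_nodes × n_samples` recording. Node signals start as
Gaussian white noise band-passed to 0.5–35 Hz (Butterworth order 4,
zero-phase), the broadband range of cortical source activity the analysis
targets; the default sampling rate is 600 Hz and recordings last 5 minutes.
Directed coupling is linear and delayed: an edge (s → t, w, d) adds
`w · x_s(t − d)` to node t, applied recursively in time order so that
information genuinely propagates along chains and cycles (delays ≥ 1 sample
make the recursion causal and well defined). Rows are standardized to zero
mean and unit variance afterwards, so `w` reads as relative drive. Default
planted delays are 10–30 samples (17–50 ms at 600 Hz), a plausible
cortico-cortical conduction range.

Two groups (patients/controls) are simulated from two coupling
specifications sharing the node set; per-subject seeds are spawned
deterministically from a master seed. Behavioral severity scores with a
target population correlation ρ to any per-subject metric are generated as
`ρ·z(metric) + √(1−ρ²)·ε`, affinely mapped so ±3 SD spans the instrument
range (0–100) and clipped; the noise SD is the closed-form calibration that
makes the population correlation exactly ρ.

**What the generator does not emulate:** volume conduction / source
leakage, 1/f spectra, nonstationarity, artifacts, subject-level
heterogeneity beyond independent noise, and anatomical geometry. Passing
tests therefore demonstrate correctness of the pipeline's inference under
its own assumptions (stationary, linearly delayed couplings in band-limited
noise), not robustness to every property of real MEG source estimates.

## Filtering and epoching

The conditioning chain is a causal Butterworth high-pass at 0.5 Hz
(drift removal on a continuous stream), a second-order IIR notch at 50 Hz
(quality factor 30) applied causally, and a zero-phase (forward–backward)
Butterworth low-pass at 35 Hz. Filter orders default to 4 and are
configurable. All three filters are applied to the continuous recording
*before* epoching: the passband is identical to filtering epochs
individually, and epoch edges see no filter transients.

Epochs (default 8 × 8 s) are drawn pseudo-randomly after excluding the
first minute, by rejection-sampling start indices until a pairwise
non-overlapping draw appears; the draw is deterministic under the seed.

## Phase transfer entropy

Instantaneous phases come from the Hilbert analytic signal, wrapped to
(−π, π]. With embedding length k = 1 and prediction delay δ,

    pTE(x→y) = H(y_t, y_{t+δ}) + H(y_t, x_t) − H(y_t) − H(y_{t+δ}, y_t, x_t),

where every H is a plug-in histogram entropy (natural log, empty cells
contribute 0) over B equal-width bins spanning (−π, π]; values at exactly
−π map to the first bin. Small negative pTE values caused by estimator bias
are kept (no flooring) so the later z-scoring is well defined.

**Prediction delay.** δ is estimated once per epoch as
`round(samples × channels / phase sign flips)`, floored at 1 — the mean
half-period of the pooled phase processes — and shared by all pairs of that
epoch. A per-pair δ is available through `PteParams`.

**Bin count.** Three rules are implemented. `fixed_49` returns 49 bins
(so the three-way joint histogram has 49³ = 117,649 cells) and
`scott_style` returns `round(exp(0.626 + 0.4·ln(n−1)))` (56 at n = 4800);
both are marginal-histogram rules. At 8-s epochs (4800 samples) they leave
the *three-dimensional* joint histogram with far fewer than one observation
per cell, and the sparsity bias of the plug-in entropy then dominates the
directional signal: coupled pairs concentrate their joint histograms and
receive *less* negative bias than independent pairs, which can push their
estimated flow below the independent baseline. The pipeline therefore
defaults to `joint_adequate`, `B = round((n/10)^{1/3})` (B = 8 at 4800
samples), targeting about ten observations per joint cell. The fixed-bin
and Scott-style modes remain available for arithmetic fidelity with the
reference settings.

**Subject reduction.** Per-epoch adjacencies are averaged element-wise into
one matrix per subject, then z-scored over the off-diagonal entries (mean
0, SD 1; the diagonal stays 0). Z-scoring makes subjects comparable but has
a side effect worth knowing: if one group carries extra strong couplings,
its *background* edges shift slightly below those of the other group, so a
"controls > patients" contrast can flag shared background edges. The
scientific contrast of interest is patients > controls.

**Sanity check.** Reversing the time axis of a coupled pair maps an x→y
coupling onto y→x (y's past becomes x's future), so the dominant pTE
direction must flip. Note that reversing only *one* series of a stationary
delayed-coupled pair instead destroys the coupling — the effective lag
becomes time-dependent — and leaves the direction estimate at chance; the
package's check reverses the pair.

## Edge-wise permutation statistics

Within-group networks: per edge, a one-sample t statistic of the subjects'
z-values against zero; the null flips the sign of each subject's values
(default: one flip per subject per permutation, preserving within-subject
edge correlation — the standard exchangeability argument for symmetric
nulls; independent per-cell flips are available, and exhaustive enumeration
of all 2ⁿ patterns for ≤ 16 subjects). Group differences: a pooled-variance
independent-samples t with a group-label permutation null, optionally
combined with sign flipping. Two-sided p-values count permuted |t| ≥
observed |t| with the observed statistic included (add-one rule), so
p ≥ 1/(B+1). Both tests are evaluated in vectorized permutation batches
(sums of squares are permutation-invariant, so each permuted t is a closed
form of the permuted mean), making 10⁵ permutations cheap.

**Permutation count vs FDR level.** The add-one rule bounds attainable
p-values, so Benjamini–Hochberg at level q over m edges can reject k edges
only if `B + 1 ≥ m/(k·q)`. At q = 0.001 over the 380 edges of a 20-node
network, recovering ~10 edges requires B ≥ ~38,000; the analysis scripts
use B = 100,000. The package default stays at 5000 — adequate for lenient
q — and this constraint is the reason, not a performance limit.

FDR thresholding is BH step-up over all off-diagonal ordered pairs
(via `statsmodels.stats.multitest`); surviving edges and their t-values
form the significant network.

## Graph metrics

All metrics treat edge weights (t- or z-values) as connection strengths and
convert to lengths as 1/w for shortest paths (Dijkstra via
`scipy.sparse.csgraph`; a Floyd–Warshall brute force is the test oracle).

- **Node strength**: sum of |weights| of incident edges, in + out.
- **Density**: edges over unordered pairs N(N−1)/2, reported to 4 decimals.
  The unordered denominator (despite directed edges) is what reproduces the
  reported worked values 0.0024 (863 nodes, 892 edges) and 0.0012 (863, 441).
- **Global efficiency**: mean over ordered pairs of 1/distance, 1/∞ = 0.
- **Characteristic path length**: mean *finite* distance over ordered
  pairs; the count of unreachable pairs is available.
- **SWP**: the directed matrix is symmetrized (max of the two directions),
  observed weighted clustering (Onnela geometric-mean triangles, via
  networkx) and path length are compared against a ring-lattice reordering
  of the weight multiset (strongest weights on shortest ring distances) and
  the mean of 50 random placements; ΔC = (C_latt−C_obs)/(C_latt−C_rand)
  and ΔL = (L_obs−L_rand)/(L_latt−L_rand) are clipped to [0, 1] and
  SWP = 1 − √((ΔC²+ΔL²)/2). Degenerate nulls (C_latt ≈ C_rand) raise a
  diagnostic error.

**Per-subject substrate.** Group-level significant networks have no subject
variance, so per-subject metrics are computed on each subject's z-weights
restricted to the union of the group-level significant networks (density
stays group-level). Masked weights below 0.1 (z units) — including negative
ones — are floored at 0.1, capping any single edge length at 10: with a
tiny floor a few near-zero weights dominate every shortest path and CPL
degenerates into a count of weak edges.

**Group comparison / behavior.** Mann–Whitney U (exact for ≤ 8 per group
without ties, tie-corrected normal approximation otherwise), reported both
raw and standardized as (U − n₁n₂/2)/σ_U — reported U values near ±2 in the
literature are on this standardized scale. Brain–behavior associations use
Pearson r with the two-sided t-test p at the supplied n.

## Validation studies (`ptenet.validation`)

- **Direction recovery**: 200 simulated pairs (strength 0.7, delay 20,
  4800 samples at 600 Hz); the fraction with pTE asymmetry along the planted
  edge, plus the time-reversal flip rate among pairs whose asymmetry
  exceeds the 95th percentile of matched uncoupled pairs.
- **Null calibration**: i.i.d. standard-normal edge values, 20 (+20)
  subjects, ~1000 edges, 1000 permutations. A single permutation stream
  shared across edges correlates their rejections and inflates the variance
  of the rejection rate beyond binomial, so the study tests independent
  3-node blocks, each with its own stream, making the binomial band the
  correct reference.
- **Planted recovery**: 10 patient-only couplings at strength 0.6, 20 + 20
  subjects, full pipeline, BH at q = 0.001; precision/recall of the
  recovered directed edges. Planted edges form a node-disjoint matching:
  with chained plantings (x→y→z) the generator genuinely transmits
  information x→z and a correct pipeline detects that edge, which would be
  miscounted as a false positive.
- **Surrogate control**: the same cohort with every epoch replaced by a
  Fourier-amplitude-preserving, phase-randomized surrogate (per node: FFT
  amplitudes kept, positive-frequency phases drawn uniformly, DC/Nyquist
  untouched) must yield no significant group differences even at q = 0.1.
- **Correlation recovery**: a planted metric–score correlation of −0.6 at
  n = 40 recovered from a single draw.

Problem sizes (20 nodes, 20 + 20 subjects, 8 × 8-s epochs) are the
package's chosen synthetic scale: large enough for every stage to operate
in its intended regime, small enough that the whole validation battery runs
in minutes on one core. Node count, cohort size and all estimator settings
are configuration parameters.

## Known limitations

- The histogram pTE estimator remains biased; only its *contrast* across
  directions, epochs and groups is interpreted, never absolute values.
- SWP can saturate at the boundary (exactly 1) on small, dense masked
  networks with strongly bimodal weights, where the ring-lattice null is
  not lattice-like in the weighted sense; saturated values carry no
  subject-level variance (correlations with them are undefined). Large
  sparse networks do not show this.
- Epoch-level direction calls at the fixed 49-bin setting are unreliable
  (see the bin-count discussion); analyses that must use that setting
  should rely on epoch- and subject-level averaging plus group statistics.
- The one-sample "network detection" on z-scored connectomes finds edges
  with *above-average* flow by construction, since z-scoring centers each
  subject's edge distribution at zero.
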