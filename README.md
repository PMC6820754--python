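# ptenet — directed resting-state connectivity with phase transfer entropy

`ptenet` re-implements, as a tested and fully synthetic-data-driven pipeline,
a whole-cortex *directed* functional connectivity analysis of resting-state
source-space recordings: the kind of analysis used to compare the intrinsic
cortical networks of a patient group (e.g. chronic tinnitus) against matched
controls. Because the original MEG cohorts in such studies are rarely public,
the package ships a ground-truth cohort generator, so every stage — estimator,
statistics, graph metrics — is validated against planted truth.

It is aimed at researchers in electrophysiological connectomics who want a
transparent, reproducible reference implementation of this analysis chain,
and at methodologists who want to probe its estimator and statistics under
controlled conditions.

## The analysis

**Phase transfer entropy (pTE).** For signals *x* and *y* with Hilbert
instantaneous phases θx, θy wrapped to (−π, π], the information flow x→y
with embedding length k = 1 and prediction delay δ is

    pTE(x→y) = H(θy_t, θy_{t+δ}) + H(θy_t, θx_t) − H(θy_t) − H(θy_{t+δ}, θy_t, θx_t)

with Shannon entropies (natural log) estimated from histograms over B
equal-width phase bins; δ is estimated per epoch as the mean number of
samples between phase sign flips pooled over channels. pTE is asymmetric —
pTE(x→y) ≠ pTE(y→x) — and the asymmetry carries the direction of coupling.
Time-reversing a coupled pair provably flips the dominant direction, which
the package uses as a built-in sanity check.

**Pipeline** (`ptenet.pipeline.run_pipeline`, or the numbered scripts under
`analysis/`):

1. simulate (or load) per-subject node × sample recordings;
2. filter — causal Butterworth high-pass 0.5 Hz, 50 Hz notch, zero-phase
   low-pass 35 Hz;
3. cut 8 pseudo-random non-overlapping 8-s epochs, excluding the first minute;
4. per epoch: Hilbert phases → shared δ → all-pairs pTE adjacency;
5. per subject: epoch-average, z-score off-diagonal → one directed connectome;
6. within-group networks by one-sample *sign-flip* permutation tests, group
   differences by *label-permutation* t-tests, both thresholded edge-wise
   with Benjamini–Hochberg FDR;
7. weighted graph metrics on the significant networks — node strength,
   density, global efficiency E, characteristic path length CPL, and
   small-worldness propensity SWP = 1 − √((ΔC² + ΔL²)/2) against
   weight-matched lattice and random nulls;
8. Mann–Whitney U group comparisons and Pearson correlations with
   behavioral severity scores, plus BrainNet Viewer `.node`/`.edge` export.

## Worked example

The demo analysis (20 nodes, 10 + 10 subjects, 5-minute recordings at
600 Hz; both groups share 8 background couplings and patients carry 5 extra
couplings at strength ≈ 0.6):

```bash
python analysis/01_simulate_cohort.py   # cohort + ground truth
python analysis/02_connectomes.py       # per-subject z-scored connectomes
python analysis/03_group_networks.py    # significant networks + FDR
python analysis/04_graph_metrics.py     # SWP / E / CPL, group stats, behavior
python analysis/05_surrogate_control.py # phase-randomized negative control
```

Stage 03 prints (seed 11):

```
control network: 9 nodes, 5 edges, density 0.0263
patient network: 19 nodes, 36 edges, density 0.1895
patients > controls: 9 nodes, 5 edges
controls > patients: 7 nodes, 5 edges
```

The patients > controls contrast recovers the 5 planted patient-only
couplings; the patient network is denser than the control network because
of the planted hyper-connectivity. (Edges in the "controls > patients"
direction sit on shared background couplings: per-subject z-scoring pushes
patients' background edges down when their extra couplings pull the mean
up — see `docs/methods.md`.) Stage 04 then prints:

```
group comparison (patients vs controls, Mann-Whitney U):
  swp        patients 1.000 vs controls 0.567 (U = 100.0, standardized +4.038, p = 0.000)
  efficiency patients 0.217 vs controls 0.146 (U = 100.0, standardized +3.780, p = 0.000)
  cpl        patients 17.812 vs controls 20.576 (U = 0.0, standardized -3.780, p = 0.000)
behavioral correlations in patients (planted r = -0.6 on efficiency):
  swp        undefined (constant vector; correlation undefined)
  efficiency r = -0.707, p = 0.022
  cpl        r = +0.453, p = 0.189
```

so planted hyper-connectivity translates into higher efficiency and shorter
path length for patients on this synthetic network, and a severity score
generated with a planted correlation of −0.6 to patient efficiency is
recovered at r = −0.707. Stage 05 reports the negative control:

```
surrogate control at q = 0.001: 0 significant edges
surrogate control at q = 0.05: 0 significant edges
surrogate control at q = 0.1: 0 significant edges
```

— phase-randomized data yield no group differences even at lenient
thresholds.

## Layout

```
src/ptenet/          library: cohort, preprocess, pte, stats, graphs,
                     io, pipeline, validation
analysis/            numbered narrative drivers + config.yaml
scripts/acceptance.py
tests/               pytest suite (unit + end-to-end validation)
docs/methods.md      model, estimator settings, design choices, limitations
```
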