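# solband

Neural-strategy solution bands for lower-limb joint contact forces during
walking.

The human musculoskeletal system is redundant: many more muscles than
degrees of freedom, so infinitely many muscle recruitment strategies can
produce the same observed gait. Which strategy the nervous system picks
changes the loads transmitted across the hip, knee and ankle — a question
that matters for gait retraining, rehabilitation and joint-preservation
programs. `solband` is a Python toolkit for exploring that strategy space:
it resolves the redundancy frame by frame with *weighted static
optimization*, samples thousands of candidate strategies with a seeded
Markov chain, propagates each one to joint contact forces (JCFs), and
summarizes the resulting *solution bands*. It is aimed at biomechanists and
neuromusculoskeletal modellers who want a self-contained, fully testable
implementation of this workflow without an OpenSim installation.

## The model

At every stance frame the muscle activations `a ∈ [0, 1]^m` solve the
convex quadratic program

    minimize    Σᵢ wᵢ aᵢ²
    subject to  Σᵢ R[d,i] · aᵢ · F_max,i = τ_d      for every DOF d

where `R` is the signed moment-arm matrix, `τ` the joint torques, and the
per-muscle weights `wᵢ` encode a *neural strategy*: raising `wᵢ` makes the
optimizer protect muscle *i* and shift load to its synergists. All weights
equal to 1 is standard static optimization. Strategies are sampled on the
lattice `{1, 10, 100}^m` by a Markov chain (single-site uniform re-draw,
every state recorded). For each strategy, joint reaction analysis sums the
intersegmental load and the muscle force vectors crossing each joint; the
resultant, in bodyweights (BW) on a 101-point stance grid, forms one curve
of the band. An *EMG-constrained* variant additionally boxes each measured
muscle's activation within ±δ of its recorded envelope, narrowing the band
toward strategies consistent with the subject's own muscle activity.

Band statistics include the pointwise bandwidth (max − min across
strategies), 10th–90th percentile bounds, the bandwidth ratio
(EMG-constrained / unconstrained), relative area differences (RAD) between
paired curves, impulses, the minimal/maximal-loading strategies and their
cross-joint effects, and an exact Wilcoxon signed-rank test.

A synthetic gait generator closes the loop: it builds smooth moment arms,
ground-truth activations, torques derived as `τ = R(a ∘ F_max)` (so the
truth is exactly feasible), a double-peaked vertical GRF and noisy EMG
envelopes — which makes parameter-recovery and band-narrowing experiments
possible with known ground truth and no experimental data.

## Worked example

```bash
solband synth --seed 7 --out demo/data
solband mcmc  --data demo/data --out demo/band_u --n 500 --mode unconstrained   --seed 7
solband mcmc  --data demo/data --out demo/band_c --n 500 --mode emg_constrained --seed 7
solband analyze --data demo/data --band demo/band_u --band-emg demo/band_c --out demo/analysis
```

`analysis.json` then contains, per joint, entries like (seed 7, 500
strategies):

```json
"knee": {
  "mean_bandwidth_bw": 1.33,
  "peak_bandwidth_bw": [3.44, 0.10],
  "bandwidth_ratio": 0.23,
  "rad_mean_increase_pct": 57.5,
  "rad_n_increase": 500
}
```

Read: across 500 neural strategies the knee JCF curves spread by 1.33 BW on
average over stance (3.44 BW at the first GRF peak); constraining the
simulations with EMG shrinks the inter-peak bandwidth to 23 % of the
unconstrained reference, and every EMG-constrained run carries more area
under the knee JCF curve than its unconstrained twin (mean +57.5 %) —
the optimizer's unconstrained solutions under-predict co-contraction.
The same library calls are available in Python (`make_gait_trial`,
`sample_weight_chain`, `run_band`, `band_summary`, …); `solband report`
renders the band plots.

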