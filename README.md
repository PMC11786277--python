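# vantage

Analysis pipeline for **viewpoint trajectories in non-immersive (desktop)
3D art viewing**. When people inspect a virtual sculpture through an
orbit camera, the camera path *is* the behavioural record: where they
stood still, from which angles they looked, and how far they travelled.
`vantage` turns raw frame-level logs of camera and look-at-target
coordinates into statistical answers about how viewing *mode* —
narrative-, process-, or creator-oriented instructions given before
viewing — changes that behaviour.

It is written for behavioural researchers running (or simulating)
three-condition viewing experiments, and covers the full chain:

* **Preprocessing** — TSV trajectory logs and cohort manifests; the three
  protocol exclusions (camera too far, too little travel, mean logging
  rate < 10 records/s); fixation detection (stationary holds >= 500 ms);
  signed view-angles theta in (-pi, pi], 0 = directly in front.
* **Movement + Likert statistics** — d_total = ln(summed camera travel)
  with the practice-phase analogue d_cov as ANCOVA covariate; Pillai's
  trace MANOVA over the nine Likert dimensions with Bonferroni
  post-hocs; partial eta^2 with noncentral-F confidence bounds.
* **The circular core** — a hierarchical Bayesian von Mises model

      theta_ij ~ VonMises(mu_i, kappa_i)
      mu_i     ~ N(alpha_mu(c_i), sigma_mu)
      kappa_i  ~ N(alpha_kappa(c_i), sigma_kappa), truncated >= 0
      alpha(c) = alpha^n + delta^np [c=1] + delta^nc [c=2]

  fitted by an adaptive Metropolis-within-Gibbs sampler (numba-compiled,
  with hierarchical translation/scale moves), gated on rank-normalised
  split-R-hat, and compared against the null model (all deltas = 0) by
  **bridge-sampling Bayes factors** computed on the group-level marginal
  posterior (participant parameters integrated out by adaptive
  Gauss-Hermite quadrature), with a repeated-refit stability analysis.
* **Dwell-surface mapping** — camera-to-target rays cast against the
  stimulus mesh (vectorised Möller-Trumbore), viewing time accumulated
  per voxel and condition, colored by the p_n : p_p : p_c ratio.
* **A synthetic-cohort simulator** — generates cohorts from the same
  hierarchy (defaults: group sizes 108/110/99 and the fitted group-level
  means), renders them into realistic orbit-camera logs, and records the
  ground truth, so every stage is testable end to end.

See `docs/methods.md` for the model details, priors, numerical choices,
and limitations.

## Worked example

The numbered scripts under `analysis/` walk through a complete study on
a simulated cohort (20 participants per condition):

```sh
python analysis/01_simulate_cohort.py --seed 0 --out scratch/demo_cohort
python analysis/02_preprocess.py      --data scratch/demo_cohort --out scratch/demo_results
python analysis/04_fit_view_angle_model.py --data scratch/demo_cohort --out scratch/demo_results
python analysis/05_bayes_factor_stability.py --data scratch/demo_cohort --out scratch/demo_results --repeats 3
```

which prints (abridged):

```
wrote 60 sessions (467886 frames) to scratch/demo_cohort
input 60 participants; excluded 0 (...); retained 60
1444 fixation events (median dwell 1026 ms)

H1 (max split-R-hat = 1.0313 (ok, gate 1.05)):
                 2.5%   mean  97.5%     sd
sigma_kappa     0.583  0.845  1.255  0.166
alpha_kappa     1.213  1.683  2.097  0.224
delta_kappa_np -1.332 -0.586  0.011  0.340
...
BF10 range: 2.743 .. 2.883; median log BF10 1.05
evidence favours the condition effects model
```

Reading this: the group-level reference concentration `alpha_kappa`
(posterior mean 1.68) and the process-condition shift `delta_kappa_np`
(-0.59) recover the simulator's generating values (1.724 and -0.466) —
the process group looks at the sculpture from a wider range of angles —
and the Bayes factor of ~2.8 favours the condition-effects model even at
this small cohort size. The same commands run on real logs by pointing
`--data` at a directory of per-participant TSVs plus a `manifest.csv`;
`vantage all <data_dir>` runs the entire chain from the command line.

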