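# fcgraph

Resting-state functional-connectome analysis for two-group, two-timepoint
intervention studies — built for neuroimaging researchers who need to ask
"did the intervention change brain network organization, and did that
change track behavior?" on modest pediatric or clinical cohorts, and to
validate the whole analysis end to end on synthetic data with known
ground truth.

The package covers the full path from ROI time series to inference:

1. **QC / motion scrubbing** — per-run volume discard; framewise
   displacement FD(t) = Σ|Δd_i| + 50·Σ|Δθ_i| (mm) and fractional DVARS;
   censoring at FD > 0.8 mm or DVARS > 0.05; censored-frame interpolation,
   polynomial detrending and zero-phase 0.009–0.1 Hz band-pass.
2. **Connectivity** — Fisher-z FC matrices, z = atanh(r), and
   intra-/inter-network block means over a 7-ICN + subcortical partition
   (36 block outcomes).
3. **Graph topology** — proportional density thresholds 15–35% (step 1%);
   nodal strength, Onnela weighted clustering
   C_i = (k_i(k_i−1))⁻¹ Σ (ŵ_ij ŵ_jh ŵ_hi)^{1/3}, harmonic closeness;
   global efficiency, clustering, characteristic path length; and
   small-worldness σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) against degree-preserving
   Maslov–Sneppen rewired nulls; all integrated across densities.
4. **Statistics** — the group-by-time interaction tested as a
   between-group comparison of within-subject change via Freedman–Lane
   permutation (age and scanner as covariates; 5000 permutations by
   default), and covariate-residualized Pearson brain–behavior
   correlations.
5. **Synthetic cohorts** — block-structured multivariate-normal BOLD with
   planted group-by-time effects, exactly recoverable motion spikes, and
   tunable FC–behavior coupling, so every claim the pipeline makes can be
   checked against ground truth.

See `docs/methods.md` for the full model description and the reasoning
behind the defaults.

## Worked example

Simulate a cohort with a planted effect (intra-SVN connectivity rises by
0.15 Fisher-z in the non-intervention group at time 2), run one
permutation test per network block, and correlate the planted block's FC
change with behavior change (`examples/05_interaction_test.py`):

```python
import fcgraph as fg

config = fg.SyntheticConfig(n_per_group=(18, 11), n_frames=240, n_runs=1,
                            roi_count=32, motion_spike_rate=0.0, seed=21)
cohort = fg.simulate_cohort(config)
tables = {s: {t: fg.block_summary(fg.fc_matrix(ts), cohort.partition)
              for t, (ts, _m) in by_t.items()}
          for s, by_t in cohort.sessions.items()}
results = fg.run_interaction_suite(cohort.design, fc_blocks=tables,
                                   n_perms=2000, seed=5)
```

Output:

```
top 5 network-block outcomes by permutation p:
            outcome  statistic  p_value  mean_change_I  mean_change_NI
        fc::SVN-SVN  -7.541009 0.000500      -0.002010        0.155114
     fc::DAN-Visual  -2.845473 0.010495      -0.015675        0.027745
fc::ECN-Subcortical   2.273635 0.029485       0.001374       -0.020968
        fc::ECN-SMN   2.087785 0.047476       0.014175       -0.024284
        fc::SVN-ECN   1.863417 0.078461       0.016334       -0.010762

planted block fc::SVN-SVN p = 0.0005 (group NI increases while group I stays flat)
brain-behavior correlation r = 0.312 (p = 0.114, n = 29); generator coupling was 0.4
```

The planted block dominates the ranking: the non-intervention group's
mean change (+0.155 z) matches the planted +0.15 while the intervention
group stays flat (−0.002), and the permutation p hits the floor for 2000
permutations. The remaining 35 blocks behave like null outcomes (a
couple of ~0.01–0.05 p-values among 35 nulls is exactly what chance
produces). The recovered brain–behavior r of 0.31 estimates the
generator's coupling of 0.4 at n = 29 (single-cohort sampling error at
this n is about ±0.18).

The other scripts in `examples/` each demonstrate one capability:
cohort generation and the bundle format, scrubbing with exact spike
recovery, block summaries, graph topology with σ, and the end-to-end
pipeline driven by a YAML-style config (also available on the command
line via `fcgraph run-all --config cfg.yaml`).

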