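"""Density-thresholded weighted graph topology of one connectome.

Thresholds a simulated FC matrix across the 15-35% density grid, computes
nodal strength/clustering/closeness and global efficiency, clustering,
path length and small-worldness (against 50 degree-preserving rewired
nulls), and integrates each metric across densities.  Sigma near 1 is
random-like; well above 1 is small-world.
"""

import numpy as np

import fcgraph as fg

partition = fg.default_partition(64)
spec = fg.BlockFcSpec.uniform(partition.systems)
cov = fg.build_block_covariance(partition, spec.base)
data = fg.simulate_subject_timeseries(cov.cov, n_frames=400, seed=5)
fc = fg.fc_matrix(fg.RoiTimeSeries(data, tr=2.0,
                                   roi_names=partition.roi_names))

g15 = fg.apply_density_threshold(fc, 0.15)
print(f"graph at 15% density: {g15.n_edges} edges over {g15.n_nodes} nodes")
print(f"  strength: mean {fg.nodal_strength(g15).mean():.3f}")
print(f"  Onnela clustering: mean {fg.nodal_clustering(g15).mean():.3f}")
print(f"  harmonic closeness: mean {fg.nodal_closeness(g15).mean():.3f}")
L, unreachable = fg.characteristic_path_length(g15)
print(f"  characteristic path length {L:.3f} "
      f"({unreachable:.0%} of pairs unreachable)")

profile = fg.metric_profile(fc, n_nulls=50, seed=9)
print("\nintegrated over densities 15-35% (range-normalized trapezoid):")
for name, value in profile.global_integrated.items():
    print(f"  {name}: {value:.3f}")
sig = profile.sigma_details[0]
print(f"\nsigma at 15%: {sig.sigma:.3f} "
      f"(C={sig.clustering:.3f} vs null {sig.null_clustering_mean:.3f}; "
      f"L={sig.path_length:.3f} vs null {sig.null_path_length_mean:.3f})")
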