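"""Validation experiments: calibration, power, and recovery studies.

Each function runs a self-contained simulation study through the package's
own analysis path — generating synthetic cohorts, measuring connectivity,
and applying the permutation machinery — and returns the summary a
methodologist would quote: empirical type-I error of the interaction test,
power to detect a planted block effect (with off-target specificity),
recovery of the behavior-coupling parameter, exactness of motion
scrubbing, and the block-z round trip of the generator.

These studies back the package's validation suite and the reproducibility
script; they are deterministic given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import block_summary, fc_matrix
from .partition import default_partition
from .qc import discard_initial_volumes, make_qc_report
from .stats import permutation_interaction_test, run_interaction_suite, \
    brain_behavior_correlation
from .synthetic import (BlockFcSpec, SyntheticConfig, build_block_covariance,
                        default_effect_spec, simulate_behavior,
                        simulate_cohort, simulate_subject_timeseries,
                        spikes_after_discard)
from .timeseries import RoiTimeSeries


def _seeds(seed: int, n: int, key: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return ss.generate_state(n) % (2 ** 31)


def type_one_error_rate(n_cohorts: int = 500, n_perms: int = 1000,
                        seed: int = 0, n_per_group: tuple[int, int] = (18, 11),
                        roi_count: int = 32, n_frames: int = 120,
                        alpha: float = 0.05) -> float:
    """Empirical type-I error of the group-by-time permutation test.

    Simulates ``n_cohorts`` cohorts with no planted effect, measures one FC
    outcome per cohort (the intra-SVN block change on the clean signal),
    runs the covariate-adjusted permutation test, and returns the fraction
    of cohorts rejected at ``alpha``.
    """
    rejections = 0
    spec = None
    for s in _seeds(seed, n_cohorts, 0):
        cfg = SyntheticConfig(
            n_per_group=n_per_group, n_frames=n_frames, n_runs=1,
            roi_count=roi_count, motion_spike_rate=0.0,
            behavior_coupling=0.0, seed=int(s))
        if spec is None:
            spec = BlockFcSpec.uniform(default_partition(roi_count).systems)
        cohort = simulate_cohort(cfg, spec)
        delta = np.array([cohort.ground_truth["delta_fc"][subj]
                          for subj in cohort.design.subjects])
        res = permutation_interaction_test(
            delta, cohort.design, n_perms=n_perms, seed=int(s) ^ 0x5A5A5A,
            outcome="fc::SVN-SVN")
        rejections += res.p_value < alpha
    return rejections / n_cohorts


@dataclass
class PowerResult:
    planted_rejection_rate: float
    off_target_rejection_rate: float
    n_replicates: int
    planted_block: str


def planted_effect_power(n_replicates: int = 200, n_perms: int = 1000,
                         seed: int = 0, delta_z: float = 0.15,
                         n_per_group: tuple[int, int] = (18, 11),
                         roi_count: int = 32, n_frames: int = 240,
                         alpha: float = 0.05) -> PowerResult:
    """Power and specificity for a planted intra-block group-by-time effect.

    Each replicate cohort carries a ``delta_z`` Fisher-z increase of the
    intra-SVN block in the non-intervention group at time 2 and nothing
    else.  All 36 network-block outcomes are tested; the function returns
    the rejection rate of the planted block and the mean rejection rate of
    the 35 unaffected blocks.
    """
    partition = default_partition(roi_count)
    spec = default_effect_spec(partition.systems, delta_z=delta_z)
    hit_planted = 0
    off_rates = []
    for s in _seeds(seed, n_replicates, 1):
        cfg = SyntheticConfig(
            n_per_group=n_per_group, n_frames=n_frames, n_runs=1,
            roi_count=roi_count, motion_spike_rate=0.0, seed=int(s))
        cohort = simulate_cohort(cfg, spec)
        tables = {
            subj: {sess: block_summary(fc_matrix(ts), partition)
                   for sess, (ts, _mo) in by_sess.items()}
            for subj, by_sess in cohort.sessions.items()}
        results = run_interaction_suite(
            cohort.design, fc_blocks=tables, n_perms=n_perms,
            seed=int(s) ^ 0x3C3C3C, alpha_fc=alpha).set_index("outcome")
        rej = results["p_value"] < alpha
        hit_planted += bool(rej.loc["fc::SVN-SVN"])
        off_rates.append(rej.drop(index="fc::SVN-SVN").mean())
    return PowerResult(
        planted_rejection_rate=hit_planted / n_replicates,
        off_target_rejection_rate=float(np.mean(off_rates)),
        n_replicates=n_replicates, planted_block="fc::SVN-SVN")


def coupling_recovery(n_replicates: int = 500, n_subjects: int = 29,
                      coupling: float = 0.4, seed: int = 0) -> float:
    """Mean recovered brain-behavior correlation across replicates.

    Per replicate: draw per-subject connectivity changes, couple a behavior
    change to them at the configured strength via the generator, then
    estimate the covariate-adjusted Pearson correlation the analysis
    reports.  Returns the mean estimate (to be compared with ``coupling``).
    """
    import pandas as pd

    from .stats import StudyDesign

    rs = []
    for s in _seeds(seed, n_replicates, 2):
        rng = np.random.default_rng(int(s))
        n_i = n_subjects // 2 + 1
        frame = pd.DataFrame({
            "subject": [f"s{i:02d}" for i in range(n_subjects)],
            "group": ["I"] * n_i + ["NI"] * (n_subjects - n_i),
            "age": rng.uniform(7, 12, n_subjects),
            "scanner": (rng.random(n_subjects) < 0.5).astype(float),
        })
        design = StudyDesign(frame, behaviors=())
        delta_fc = rng.normal(size=n_subjects)
        design = simulate_behavior(design, delta_fc, coupling, rng,
                                   behavior="b")
        res = brain_behavior_correlation(
            delta_fc, design.behavior_delta("b"),
            covariates=design.covariates())
        rs.append(res.r)
    return float(np.mean(rs))


@dataclass
class ScrubExactness:
    n_sessions: int
    n_exact: int
    kept_counts_match: bool

    @property
    def all_exact(self) -> bool:
        return self.n_exact == self.n_sessions


def scrub_exactness(config: SyntheticConfig | None = None,
                    n_discard: int = 5) -> ScrubExactness:
    """Check planted motion spikes are exactly the censored frames.

    Simulates a cohort with the given (default: study-dimension) config,
    runs discard + FD/DVARS on every session, and compares the censored
    frame set and surviving frame count against the generator's ground
    truth.
    """
    config = config or SyntheticConfig()
    cohort = simulate_cohort(config)
    n_sessions = n_exact = 0
    counts_ok = True
    for subject, by_sess in cohort.sessions.items():
        for session, (ts, motion) in by_sess.items():
            n_sessions += 1
            ts_d, mo_d = discard_initial_volumes(ts, n_discard, motion=motion)
            report = make_qc_report(ts_d, mo_d,
                                    dvars_divisor=float(ts_d.data.mean()))
            flagged = np.flatnonzero(~report.keep)
            truth = spikes_after_discard(
                np.array(cohort.ground_truth["spike_frames"][subject][session],
                         int),
                ts.run_lengths, n_discard)
            if np.array_equal(flagged, truth):
                n_exact += 1
            if report.n_kept != ts_d.n_frames - len(truth):
                counts_ok = False
    return ScrubExactness(n_sessions=n_sessions, n_exact=n_exact,
                          kept_counts_match=counts_ok)


def fc_roundtrip_error(n_frames: int = 5000, seed: int = 0,
                       roi_count: int = 141) -> float:
    """Max abs deviation of empirical block-mean z from the generating spec."""
    partition = default_partition(roi_count)
    spec = BlockFcSpec.uniform(partition.systems)
    target = spec.block_z("I", "1")
    cov = build_block_covariance(partition, target).cov
    data = simulate_subject_timeseries(cov, n_frames, seed)
    ts = RoiTimeSeries(data, tr=2.0, roi_names=partition.roi_names)
    table = block_summary(fc_matrix(ts), partition).table
    return float((table - target).abs().max().max())


def ring_lattice_weights(n: int, k: int) -> np.ndarray:
    """Ring lattice: each node linked to its k nearest neighbours (unit weights)."""
    w = np.zeros((n, n))
    for off in range(1, k // 2 + 1):
        idx = np.arange(n)
        w[idx, (idx + off) % n] = 1.0
        w[(idx + off) % n, idx] = 1.0
    return w


def watts_strogatz_weights(n: int, k: int, p: float,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Watts-Strogatz small-world topology with unit weights.

    Starts from a ring lattice of degree ``k`` and rewires each edge's far
    endpoint with probability ``p`` to a uniformly chosen node, avoiding
    self-loops and duplicates.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w = ring_lattice_weights(n, k)
    for off in range(1, k // 2 + 1):
        for i in range(n):
            j = (i + off) % n
            if rng.random() < p and w[i, j] > 0:
                candidates = np.flatnonzero((w[i] == 0))
                candidates = candidates[candidates != i]
                if candidates.size == 0:
                    continue
                new_j = int(rng.choice(candidates))
                w[i, j] = w[j, i] = 0.0
                w[i, new_j] = w[new_j, i] = 1.0
    return w


def erdos_renyi_weights(n: int, density: float,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """G(n, m) random graph at the given edge density, unit weights."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    iu = np.triu_indices(n, k=1)
    m = int(round(density * len(iu[0])))
    pick = rng.choice(len(iu[0]), size=m, replace=False)
    w = np.zeros((n, n))
    w[iu[0][pick], iu[1][pick]] = 1.0
    return w + w.T
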