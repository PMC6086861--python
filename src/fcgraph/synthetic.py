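"""Synthetic resting-state cohort generator.

Builds complete input bundles — ROI time series, motion traces, study
design and behavior scores — for a 2-group x 2-timepoint intervention
design, with a controllable block-correlation structure over the 8-system
partition, planted group-by-time connectivity effects, motion spikes that
violate the FD/DVARS scrubbing thresholds, and a tunable coupling between
per-subject connectivity change and behavior change.

Every stage of the analysis pipeline can therefore be exercised end-to-end
with known ground truth and no external data.  The default configuration
mirrors the study dimensions this package targets: groups of 18 and 11
subjects, 246 frames at TR = 2 s acquired as two runs, 141 ROIs over 7
cortical systems plus a subcortical system, an intra-SVN group-by-time
effect of +0.15 Fisher-z in the non-intervention group, and a 0.4 coupling
between connectivity change and internalizing-symptom change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import block_summary, fc_matrix
from .partition import SYSTEMS, NetworkPartition, default_partition
from .stats import StudyDesign
from .timeseries import RoiTimeSeries, write_motion

#: maximum |z| allowed in a block specification
MAX_ABS_Z = 3.0
#: eigenvalue floor for positive-definite repair of block covariances
PD_EIG_FLOOR = 1e-6

# Behavior-score generator defaults: baseline mean/SD per group at time 1
# and per-group mean change, on the two symptom scales of the target study
# population (parent/clinician-rated; improvement = decrease).
BEHAVIOR_DEFAULTS: dict[str, dict] = {
    "inattention": {
        "baseline_mean": {"I": 16.278, "NI": 18.909},
        "baseline_sd": {"I": 4.254, "NI": 5.186},
        "delta_mean": {"I": -3.111, "NI": -1.636},
        "delta_sd": 3.0,
    },
    "internalizing": {
        "baseline_mean": {"I": 7.889, "NI": 12.364},
        "baseline_sd": {"I": 5.086, "NI": 9.553},
        "delta_mean": {"I": -2.500, "NI": -1.818},
        "delta_sd": 3.0,
    },
}

# Scanner mix per group (probability of the older scanner), mirroring the
# markedly unbalanced allocation of the target study.
SCANNER_P_OLD = {"I": 5 / 18, "NI": 9 / 11}


def _check_block_table(df: pd.DataFrame, systems: tuple[str, ...]) -> pd.DataFrame:
    df = df.loc[list(systems), list(systems)].astype(float)
    v = df.to_numpy()
    if not np.allclose(v, v.T, atol=0):
        raise ValueError("block_z table must be symmetric")
    if np.any(np.abs(v) >= MAX_ABS_Z):
        raise ValueError(f"|z| must be < {MAX_ABS_Z}")
    return df


@dataclass(frozen=True)
class BlockFcSpec:
    """Target mean Fisher-z per system pair, optionally per (group, time).

    ``base`` is the 8x8 symmetric table of baseline block z.  ``effects``
    holds additive deltas applied on top of the base for specific
    (group, session) combinations — the planted group-by-time effects.
    Diagonal cells are intra-system blocks (off-diagonal ROI pairs within a
    system), not the unit matrix diagonal.
    """

    systems: tuple[str, ...]
    base: pd.DataFrame
    effects: dict = field(default_factory=dict)  # (group, session) -> DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "base", _check_block_table(self.base, self.systems))
        checked = {}
        for key, df in self.effects.items():
            delta = df.loc[list(self.systems), list(self.systems)].astype(float)
            v = delta.to_numpy()
            if not np.allclose(v, v.T, atol=0):
                raise ValueError(f"effect table for {key} must be symmetric")
            checked[key] = delta
            _check_block_table(self.base + delta, self.systems)
        object.__setattr__(self, "effects", checked)

    @classmethod
    def uniform(cls, systems: tuple[str, ...] = SYSTEMS,
                intra_z: float = 0.3, inter_z: float = 0.1) -> "BlockFcSpec":
        """Homogeneous baseline: one z for intra-, one for inter-system blocks.

        The defaults (intra 0.3, inter 0.1) are plausible resting-state
        magnitudes chosen as documented assumptions, not measured values.
        """
        k = len(systems)
        v = np.full((k, k), float(inter_z))
        np.fill_diagonal(v, float(intra_z))
        return cls(tuple(systems), pd.DataFrame(v, index=systems, columns=systems))

    def with_effect(self, group: str, session: str, system_a: str,
                    system_b: str, delta_z: float) -> "BlockFcSpec":
        """Return a spec with an additive z effect planted on one block."""
        key = (group, str(session))
        k = len(self.systems)
        if key in self.effects:
            d = self.effects[key].copy()
        else:
            d = pd.DataFrame(np.zeros((k, k)), index=self.systems,
                             columns=self.systems)
        d.loc[system_a, system_b] += delta_z
        if system_a != system_b:
            d.loc[system_b, system_a] += delta_z
        effects = dict(self.effects)
        effects[key] = d
        return BlockFcSpec(self.systems, self.base, effects)

    def block_z(self, group: str, session: str) -> pd.DataFrame:
        """Effective 8x8 z table for one (group, session) combination."""
        out = self.base.copy()
        delta = self.effects.get((group, str(session)))
        if delta is not None:
            out = out + delta
        return out


def default_effect_spec(systems: tuple[str, ...] = SYSTEMS,
                        delta_z: float = 0.15,
                        block: tuple[str, str] = ("SVN", "SVN"),
                        group: str = "NI") -> BlockFcSpec:
    """Baseline spec with the canonical planted effect.

    The non-intervention group's intra-SVN connectivity rises by
    ``delta_z`` at the second timepoint while the intervention group stays
    flat — the group-by-time pattern this pipeline is built to detect.
    """
    return BlockFcSpec.uniform(systems).with_effect(group, "2", *block, delta_z)


@dataclass
class SyntheticConfig:
    """Dimensions and effect knobs of a synthetic cohort.

    Defaults reproduce the target study conditions: 18 + 11 subjects, 246
    frames at TR 2 s over two equal runs, 141 ROIs, moderate motion-spike
    contamination, and 0.4 connectivity-behavior coupling on the
    internalizing scale.
    """

    n_per_group: tuple[int, int] = (18, 11)
    n_frames: int = 246
    n_runs: int = 2
    tr_seconds: float = 2.0
    roi_count: int = 141
    noise_sd: float = 0.0
    motion_spike_rate: float = 0.05
    spike_fd_mm: float = 1.6
    dvars_spike_frac: float = 0.1
    behavior_coupling: float = 0.4
    coupling_block: tuple[str, str] = ("SVN", "SVN")
    coupling_behavior: str = "internalizing"
    signal_mean: float = 1000.0
    signal_scale: float = 10.0
    scanner_effect_z: float = 0.0
    spike_guard_frames: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("n_per_group must be >= 2 each")
        if self.n_frames < 64:
            raise ValueError("n_frames must be >= 64")
        if self.roi_count < 16:
            raise ValueError("roi_count must be >= 16")
        if not (0 <= self.motion_spike_rate < 0.5):
            raise ValueError("motion_spike_rate must be in [0, 0.5)")
        if abs(self.behavior_coupling) > 1:
            raise ValueError("|behavior_coupling| must be <= 1")
        if self.signal_mean <= 0:
            raise ValueError("signal_mean must be positive")

    def run_lengths(self) -> tuple[int, ...]:
        base = self.n_frames // self.n_runs
        rem = self.n_frames - base * self.n_runs
        return tuple(base + (1 if i < rem else 0) for i in range(self.n_runs))


@dataclass
class CovarianceResult:
    """Block-structured ROI covariance with its PD-repair record."""

    cov: np.ndarray
    repaired: bool
    min_eigenvalue: float
    repair_method: str = "eigenvalue clip + diagonal rescale"


def build_block_covariance(partition: NetworkPartition,
                           block_z: pd.DataFrame,
                           block_tolerance: float = 0.2) -> CovarianceResult:
    """ROI-by-ROI covariance whose block means realize a target z table.

    The target correlation for every ROI pair in block (a, b) is
    tanh(z_ab); the diagonal is 1.  If the assembled matrix is not positive
    definite it is repaired by clipping eigenvalues at a small positive
    floor and rescaling the diagonal back to 1.  If after repair any block
    mean deviates from its target by more than ``block_tolerance`` the spec
    is declared infeasible with the offending blocks named.
    """
    systems = [s for s in block_z.index]
    v = block_z.to_numpy(float)
    if not np.allclose(v, v.T, atol=0):
        raise ValueError("block_z table must be symmetric")
    labels = partition.label_array()
    unknown = set(labels) - set(systems)
    if unknown:
        raise ValueError(f"partition labels missing from block_z: {sorted(unknown)}")
    r_target = np.tanh(
        block_z.loc[list(labels), list(labels)].to_numpy(float))
    cov = r_target.copy()
    np.fill_diagonal(cov, 1.0)
    eigvals = np.linalg.eigvalsh(cov)
    min_eig = float(eigvals[0])
    repaired = False
    if min_eig < PD_EIG_FLOOR:
        repaired = True
        w, q = np.linalg.eigh(cov)
        w = np.clip(w, PD_EIG_FLOOR, None)
        cov = (q * w) @ q.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        cov = (cov + cov.T) / 2.0
        min_eig = float(np.linalg.eigvalsh(cov)[0])
        # verify the repaired matrix still honors the requested blocks
        bad = []
        for i, a in enumerate(systems):
            ia = partition.indices(a)
            for j in range(i, len(systems)):
                b = systems[j]
                ib = partition.indices(b)
                if a == b:
                    if len(ia) < 2:
                        continue
                    sub = cov[np.ix_(ia, ia)]
                    got = sub[np.triu_indices(len(ia), k=1)].mean()
                else:
                    got = cov[np.ix_(ia, ib)].mean()
                if abs(got - np.tanh(v[i, j])) > block_tolerance:
                    bad.append((a, b))
        if bad:
            raise ValueError(
                f"no positive-definite covariance within tolerance "
                f"{block_tolerance} of the requested blocks; offending "
                f"blocks: {bad}")
    return CovarianceResult(cov=cov, repaired=repaired, min_eigenvalue=min_eig)


def simulate_subject_timeseries(cov: np.ndarray, n_frames: int,
                                seed: int | np.random.Generator) -> np.ndarray:
    """Zero-mean multivariate-normal frames with the given covariance.

    Frames are independent draws (white in time); deterministic for a
    fixed seed.  Raises if ``cov`` is not positive definite.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    cov = np.asarray(cov, float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance matrix is not positive definite") from e
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = rng.standard_normal((n_frames, cov.shape[0]))
    return z @ chol.T


def inject_motion(ts: RoiTimeSeries, spike_rate: float, spike_fd_mm: float,
                  seed: int | np.random.Generator,
                  dvars_spike_frac: float = 0.1,
                  guard_frames: int = 6) -> tuple[RoiTimeSeries, np.ndarray, np.ndarray]:
    """Plant transient motion spikes violating both FD and DVARS thresholds.

    Returns ``(perturbed series, motion trace, spike frame indices)``.  A
    spike is an out-and-back head movement spanning two consecutive frames
    t and t+1: one translation steps by exactly ``spike_fd_mm`` at t and
    back at t+1 (with the smooth baseline increments zeroed at both), so
    FD equals the spike magnitude at both frames to machine precision.
    The signal receives a transient global offset of ``dvars_spike_frac``
    times its grand mean at frame t only, so DVARS exceeds its threshold
    at t (offset on) and t+1 (offset off) and nowhere else — the artifact
    is wholly confined to the two flagged frames.  Both frames of every
    spike are returned/recorded, and ``spike_rate`` is the expected
    fraction of affected frames.

    Spikes are never planted in the first ``guard_frames`` frames of a run,
    keeping them recoverable after the pipeline's initial-volume discard.
    """
    if not (0 <= spike_rate < 0.5):
        raise ValueError("spike_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = ts.n_frames
    # eligible spike-start frames: outside every run's leading guard window
    # and not a run's final frame (the return movement at t+1 must land in
    # the same run, or it would straddle the next run's discard window)
    eligible = np.ones(n, bool)
    start = 0
    for rl in ts.run_lengths:
        eligible[start:start + min(guard_frames, rl)] = False
        eligible[start + rl - 1] = False
        start += rl
    draws = rng.random(n) < spike_rate / 2.0  # two frames per spike
    starts = []
    last = -2
    for t in np.flatnonzero(eligible & draws):
        if t > last + 1:  # keep spikes non-overlapping
            starts.append(int(t))
            last = t + 1
    starts = np.asarray(starts, int)
    spikes = np.sort(np.concatenate([starts, starts + 1])) if starts.size else \
        np.empty(0, int)
    # smooth baseline: small white increments, translations mm / rotations rad
    inc = np.empty((n, 6))
    inc[:, :3] = rng.normal(0.0, 0.01, size=(n, 3))
    inc[:, 3:] = rng.normal(0.0, 0.0002, size=(n, 3))
    inc[0] = 0.0
    inc[spikes] = 0.0
    inc[starts, 0] = spike_fd_mm
    inc[starts + 1, 0] = -spike_fd_mm
    motion = np.cumsum(inc, axis=0)
    data = ts.data.copy()
    if starts.size:
        grand_mean = float(ts.data.mean())
        if grand_mean <= 0:
            raise ValueError("signal must have a positive grand mean to "
                             "plant DVARS-visible spikes")
        offsets = rng.choice([-1.0, 1.0], size=starts.size) * (
            dvars_spike_frac * grand_mean)
        data[starts, :] += offsets[:, None]
    return ts.with_data(data, run_lengths=ts.run_lengths), motion, spikes


def simulate_behavior(design: StudyDesign, true_delta_fc: np.ndarray,
                      coupling: float, seed: int | np.random.Generator,
                      behavior: str = "behavior",
                      baseline_mean: dict[str, float] | float = 0.0,
                      baseline_sd: dict[str, float] | float = 1.0,
                      delta_mean: dict[str, float] | float = 0.0,
                      delta_sd: float = 1.0) -> StudyDesign:
    """Fill time-1/time-2 behavior columns coupled to connectivity change.

    The standardized change score is coupling * standardize(delta_fc) +
    sqrt(1 - coupling^2) * noise, so its population correlation with the
    connectivity change equals ``coupling`` (when group mean offsets are
    equal).  It is then scaled by ``delta_sd`` and shifted by the per-group
    ``delta_mean``; time-1 scores are drawn around the per-group
    ``baseline_mean``.
    """
    if abs(coupling) > 1:
        raise ValueError("|coupling| must be <= 1")
    dfc = np.asarray(true_delta_fc, float)
    n = design.n_subjects
    if dfc.shape[0] != n:
        raise ValueError(f"need one delta-FC value per subject ({n}), "
                         f"got {dfc.shape[0]}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def per_group(param, group):
        return param[group] if isinstance(param, dict) else float(param)

    sd = dfc.std()
    z = (dfc - dfc.mean()) / sd if sd > 0 else np.zeros(n)
    noise = rng.standard_normal(n)
    delta_std = coupling * z + np.sqrt(max(0.0, 1 - coupling ** 2)) * noise
    frame = design.frame.copy()
    groups = frame["group"].to_numpy()
    b_mean = np.array([per_group(baseline_mean, g) for g in groups])
    b_sd = np.array([per_group(baseline_sd, g) for g in groups])
    d_mean = np.array([per_group(delta_mean, g) for g in groups])
    t1 = b_mean + b_sd * rng.standard_normal(n)
    delta = d_mean + delta_sd * delta_std
    frame[f"{behavior}_t1"] = t1
    frame[f"{behavior}_t2"] = t1 + delta
    behaviors = design.behaviors if behavior in design.behaviors else (
        *design.behaviors, behavior)
    return StudyDesign(frame, behaviors=behaviors,
                       covariate_cols=design.covariate_cols)


@dataclass
class SyntheticCohort:
    """A complete synthetic input bundle with its ground truth."""

    config: SyntheticConfig
    spec: BlockFcSpec
    partition: NetworkPartition
    design: StudyDesign
    #: subject -> session ("1"/"2") -> (RoiTimeSeries, motion trace)
    sessions: dict
    ground_truth: dict

    def timeseries(self, subject: str, session: str) -> RoiTimeSeries:
        return self.sessions[subject][session][0]

    def motion(self, subject: str, session: str) -> np.ndarray:
        return self.sessions[subject][session][1]

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle in the pipeline's external formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.partition.to_tsv(out / "partition.tsv")
        self.design.to_tsv(out / "design.tsv")
        for subject, by_session in self.sessions.items():
            for session, (ts, motion) in by_session.items():
                stem = f"{subject}_ses-{session}"
                ts.to_tsv(out / f"{stem}_timeseries.tsv")
                write_motion(out / f"{stem}_motion.txt", motion)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


def spikes_after_discard(spikes: np.ndarray, run_lengths: tuple[int, ...],
                         n_discard: int) -> np.ndarray:
    """Map raw spike frame indices to post-discard frame numbering.

    Spikes falling inside a discarded leading window are dropped (the
    generator's guard window prevents this under default settings).
    """
    spikes = np.asarray(spikes, int)
    bounds = np.cumsum((0,) + tuple(run_lengths))
    out = []
    for s in spikes:
        run = int(np.searchsorted(bounds, s, side="right") - 1)
        within = s - bounds[run]
        if within < n_discard:
            continue
        out.append(s - (run + 1) * n_discard)
    return np.asarray(out, int)


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_cohort(config: SyntheticConfig | None = None,
                    spec: BlockFcSpec | None = None) -> SyntheticCohort:
    """Generate a full 2-group x 2-session cohort with ground truth.

    Fully reproducible from ``config.seed``.  The per-subject connectivity
    change that drives behavior coupling is the empirical Fisher-z change
    of the configured coupling block, measured on the clean (pre-spike)
    signal, recorded in the ground truth.
    """
    config = config or SyntheticConfig()
    partition = default_partition(config.roi_count)
    spec = spec or default_effect_spec(partition.systems)
    n_i, n_ni = config.n_per_group
    subjects = [f"sub-{i + 1:02d}" for i in range(n_i + n_ni)]
    groups = ["I"] * n_i + ["NI"] * n_ni

    rng_design = _rng_for(config.seed, 0)
    age = np.clip(rng_design.normal(9.2, 1.4, size=len(subjects)), 6.0, 13.0)
    scanner = np.array([
        float(rng_design.random() < SCANNER_P_OLD[g]) for g in groups])
    frame = pd.DataFrame({
        "subject": subjects, "group": groups,
        "age": np.round(age, 2), "scanner": scanner,
    })
    design = StudyDesign(frame, behaviors=())

    # covariance per distinct (group, session, scanner) cell
    cov_cache: dict[tuple, CovarianceResult] = {}

    def cov_for(group: str, session: str, scan: float) -> CovarianceResult:
        key = (group, session, scan)
        if key not in cov_cache:
            z = spec.block_z(group, session)
            if config.scanner_effect_z and scan:
                z = z + config.scanner_effect_z
            cov_cache[key] = build_block_covariance(partition, z)
        return cov_cache[key]

    sessions: dict = {}
    spike_record: dict = {}
    delta_fc = np.empty(len(subjects))
    run_lengths = config.run_lengths()
    for si, (subject, group, scan) in enumerate(zip(subjects, groups, scanner)):
        sessions[subject] = {}
        spike_record[subject] = {}
        block_z_obs = {}
        for sess_i, session in enumerate(("1", "2")):
            cov_res = cov_for(group, session, scan)
            rng_ts = _rng_for(config.seed, 1, si, sess_i)
            signal = simulate_subject_timeseries(
                cov_res.cov, config.n_frames, rng_ts)
            if config.noise_sd > 0:
                signal = signal + rng_ts.normal(
                    0.0, config.noise_sd, size=signal.shape)
            ts = RoiTimeSeries(
                config.signal_mean + config.signal_scale * signal,
                tr=config.tr_seconds,
                subject=subject, session=session,
                roi_names=partition.roi_names, run_lengths=run_lengths)
            # empirical coupling-block z on the clean signal
            blocks = block_summary(fc_matrix(ts), partition)
            block_z_obs[session] = blocks.value(*config.coupling_block)
            rng_mo = _rng_for(config.seed, 2, si, sess_i)
            ts, motion, spikes = inject_motion(
                ts, config.motion_spike_rate, config.spike_fd_mm, rng_mo,
                dvars_spike_frac=config.dvars_spike_frac,
                guard_frames=config.spike_guard_frames)
            sessions[subject][session] = (ts, motion)
            spike_record[subject][session] = [int(s) for s in spikes]
        delta_fc[si] = block_z_obs["2"] - block_z_obs["1"]

    for bi, (behavior, params) in enumerate(sorted(BEHAVIOR_DEFAULTS.items())):
        coupling = (config.behavior_coupling
                    if behavior == config.coupling_behavior else 0.0)
        design = simulate_behavior(
            design, delta_fc, coupling, _rng_for(config.seed, 3, bi),
            behavior=behavior, **params)

    ground_truth = {
        "seed": config.seed,
        "n_per_group": list(config.n_per_group),
        "block_z": {f"{g}|{t}": spec.block_z(g, t).round(6).to_dict()
                    for g in ("I", "NI") for t in ("1", "2")},
        "pd_repaired": {f"{k[0]}|{k[1]}|{k[2]}": bool(v.repaired)
                        for k, v in cov_cache.items()},
        "behavior_coupling": config.behavior_coupling,
        "coupling_block": list(config.coupling_block),
        "coupling_behavior": config.coupling_behavior,
        "spike_frames": spike_record,
        "run_lengths": list(run_lengths),
        "delta_fc": {s: float(d) for s, d in zip(subjects, delta_fc)},
    }
    return SyntheticCohort(config=config, spec=spec, partition=partition,
                           design=design, sessions=sessions,
                           ground_truth=ground_truth)
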