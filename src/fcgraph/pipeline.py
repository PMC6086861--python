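"""End-to-end orchestration: simulate -> qc -> connectivity -> graph -> stats.

A run is driven by a :class:`RunConfig` (YAML-serializable, unknown keys
rejected), executes the enabled stages in order on a directory of
standard-format inputs (TSV time series, 6-column motion text, partition
and design tables), and writes every result table as TSV plus a JSON run
manifest with per-stage wall-clock, output hashes and warnings.  All
randomness derives from the master seed via fixed per-stage offsets, so
re-running an identical config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .connectivity import BlockFcTable, ConnectivityMatrix, block_summary, fc_matrix
from .graph import (DEFAULT_DENSITIES, DEFAULT_N_NULLS, DEFAULT_SWAPS_PER_EDGE,
                    GraphMetricProfile, metric_profile)
from .partition import NetworkPartition
from .stats import (DEFAULT_N_PERMS, StudyDesign, brain_behavior_correlation,
                    run_interaction_suite)
from .synthetic import SyntheticConfig, default_effect_spec, simulate_cohort
from .timeseries import RoiTimeSeries, read_motion

STAGES = ("simulate", "qc", "connectivity", "graph", "stats")


@dataclass
class SimulateOptions:
    n_per_group: tuple[int, int] = (18, 11)
    n_frames: int = 246
    n_runs: int = 2
    tr_seconds: float = 2.0
    roi_count: int = 141
    noise_sd: float = 0.0
    motion_spike_rate: float = 0.05
    behavior_coupling: float = 0.4
    effect_delta_z: float = 0.15
    effect_block: tuple[str, str] = ("SVN", "SVN")
    effect_group: str = "NI"


@dataclass
class QcOptions:
    n_discard: int = qc_mod.DEFAULT_N_DISCARD
    low_hz: float = qc_mod.DEFAULT_BAND_HZ[0]
    high_hz: float = qc_mod.DEFAULT_BAND_HZ[1]
    fd_threshold: float = qc_mod.DEFAULT_FD_THRESHOLD_MM
    dvars_threshold: float = qc_mod.DEFAULT_DVARS_THRESHOLD
    head_radius_mm: float = qc_mod.DEFAULT_HEAD_RADIUS_MM
    min_frames: int = qc_mod.DEFAULT_MIN_FRAMES
    flag_rule: str = "union"
    rotations_in_degrees: bool = False
    filter_method: str = "fft"
    dvars_on: str = "raw"  # compute DVARS on raw or band-passed series
    run_lengths: tuple[int, ...] | None = None
    tr_seconds: float = 2.0


@dataclass
class GraphOptions:
    density_min: float = DEFAULT_DENSITIES[0]
    density_max: float = DEFAULT_DENSITIES[-1]
    density_step: float = 0.01
    n_nulls: int = DEFAULT_N_NULLS
    n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
    compute_sigma: bool = True

    def densities(self) -> np.ndarray:
        n = int(round((self.density_max - self.density_min) / self.density_step)) + 1
        return np.round(np.linspace(self.density_min, self.density_max, n), 10)


@dataclass
class StatsOptions:
    n_perms: int = DEFAULT_N_PERMS
    alpha_fc: float = 0.05
    alpha_nodal: float = 0.01
    fdr: bool = False


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    input_dir: str = "data"
    output_dir: str = "results"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulate: SimulateOptions = field(default_factory=SimulateOptions)
    qc: QcOptions = field(default_factory=QcOptions)
    graph: GraphOptions = field(default_factory=GraphOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {"simulate": SimulateOptions, "qc": QcOptions,
                    "graph": GraphOptions, "stats": StatsOptions}
        kwargs = {}
        for key, typ in sections.items():
            sub = dict(d.pop(key, {}))
            valid = set(typ.__dataclass_fields__)
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            kwargs[key] = typ(**sub)
        valid_top = set(cls.__dataclass_fields__) - set(sections)
        unknown = set(d) - valid_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return json.loads(json.dumps(asdict(self)))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed by a fixed offset."""
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(idx,)).generate_state(1)[0] % (2 ** 31))


class ValidationError(ValueError):
    """An input bundle failed cross-validation."""


@dataclass
class LoadedBundle:
    partition: NetworkPartition
    design: StudyDesign
    #: subject -> session -> (RoiTimeSeries, motion)
    sessions: dict


def load_inputs(input_dir: str | Path, tr_seconds: float = 2.0,
                run_lengths: tuple[int, ...] | None = None) -> LoadedBundle:
    """Load and cross-validate a standard input bundle.

    Expects ``partition.tsv``, ``design.tsv`` and per subject-session
    ``<subject>_ses-<s>_timeseries.tsv`` / ``<subject>_ses-<s>_motion.txt``.
    Frame counts must match between series and motion, ROI counts must
    match the partition, and every design subject needs both sessions.
    """
    root = Path(input_dir)
    part_path = root / "partition.tsv"
    design_path = root / "design.tsv"
    if not part_path.exists():
        raise ValidationError(f"missing partition file: {part_path}")
    if not design_path.exists():
        raise ValidationError(f"missing design file: {design_path}")
    partition = NetworkPartition.from_tsv(part_path)
    design = StudyDesign.from_tsv(design_path)
    sessions: dict = {}
    for subject in design.subjects:
        sessions[subject] = {}
        for session in ("1", "2"):
            ts_path = root / f"{subject}_ses-{session}_timeseries.tsv"
            mo_path = root / f"{subject}_ses-{session}_motion.txt"
            if not ts_path.exists():
                raise ValidationError(
                    f"missing time series for {subject} session {session}")
            if not mo_path.exists():
                raise ValidationError(
                    f"missing motion trace for {subject} session {session}")
            ts = RoiTimeSeries.from_tsv(ts_path, tr=tr_seconds, subject=subject,
                                        session=session,
                                        run_lengths=run_lengths or ())
            motion = read_motion(mo_path)
            if motion.shape[0] != ts.n_frames:
                raise ValidationError(
                    f"frame mismatch for {subject} session {session}: "
                    f"{ts.n_frames} signal frames vs {motion.shape[0]} motion frames")
            if ts.n_rois != partition.n_rois:
                raise ValidationError(
                    f"ROI mismatch for {subject} session {session}: series has "
                    f"{ts.n_rois} ROIs, partition covers {partition.n_rois}")
            if tuple(ts.roi_names) != tuple(partition.roi_names):
                raise ValidationError(
                    f"ROI names for {subject} session {session} do not match "
                    "the partition")
            sessions[subject][session] = (ts, motion)
    return LoadedBundle(partition=partition, design=design, sessions=sessions)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    completed_stages: list = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    versions: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order; see module docstring."""
    from . import __version__

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        versions={"fcgraph": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__})

    def finish_stage(name: str, t0: float) -> None:
        manifest.completed_stages.append(name)
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)

    run_lengths = config.qc.run_lengths
    if config.stages.get("simulate", True):
        t0 = time.perf_counter()
        sim = config.simulate
        syn_cfg = SyntheticConfig(
            n_per_group=tuple(sim.n_per_group), n_frames=sim.n_frames,
            n_runs=sim.n_runs, tr_seconds=sim.tr_seconds,
            roi_count=sim.roi_count, noise_sd=sim.noise_sd,
            motion_spike_rate=sim.motion_spike_rate,
            behavior_coupling=sim.behavior_coupling,
            seed=config.stage_seed("simulate"))
        from .partition import default_partition
        spec = default_effect_spec(
            default_partition(sim.roi_count).systems,
            delta_z=sim.effect_delta_z, block=tuple(sim.effect_block),
            group=sim.effect_group)
        cohort = simulate_cohort(syn_cfg, spec)
        cohort.write(config.input_dir)
        run_lengths = syn_cfg.run_lengths()
        finish_stage("simulate", t0)

    bundle = load_inputs(config.input_dir, tr_seconds=config.qc.tr_seconds,
                         run_lengths=run_lengths)
    partition = bundle.partition
    design = bundle.design

    clean: dict = {}       # subject -> session -> scrubbed RoiTimeSeries
    if config.stages.get("qc", True):
        t0 = time.perf_counter()
        q = config.qc
        qc_rows = []
        excluded_subjects = set()
        for subject, by_session in bundle.sessions.items():
            clean[subject] = {}
            for session, (ts, motion) in by_session.items():
                ts_d, motion_d = qc_mod.discard_initial_volumes(
                    ts, q.n_discard, motion=motion)
                raw_mean = float(ts_d.data.mean())
                if q.dvars_on == "raw":
                    report = qc_mod.make_qc_report(
                        ts_d, motion_d, fd_threshold=q.fd_threshold,
                        dvars_threshold=q.dvars_threshold,
                        head_radius_mm=q.head_radius_mm,
                        min_frames=q.min_frames, flag_rule=q.flag_rule,
                        rotations_in_degrees=q.rotations_in_degrees,
                        dvars_divisor=raw_mean)
                    # censored frames are interpolated before filtering so
                    # their artifact does not smear into kept frames
                    filtered = qc_mod.bandpass_detrend(
                        qc_mod.interpolate_censored(ts_d, report.keep),
                        q.low_hz, q.high_hz, method=q.filter_method)
                else:
                    filtered = qc_mod.bandpass_detrend(
                        ts_d, q.low_hz, q.high_hz, method=q.filter_method)
                    report = qc_mod.make_qc_report(
                        filtered, motion_d, fd_threshold=q.fd_threshold,
                        dvars_threshold=q.dvars_threshold,
                        head_radius_mm=q.head_radius_mm,
                        min_frames=q.min_frames, flag_rule=q.flag_rule,
                        rotations_in_degrees=q.rotations_in_degrees,
                        dvars_divisor=raw_mean)
                report.to_frame().to_csv(
                    out_dir / f"{subject}_ses-{session}_qc.tsv", sep="\t",
                    index=False, float_format="%.10g")
                scrubbed, _ = qc_mod.scrub(filtered, report)
                clean[subject][session] = scrubbed
                qc_rows.append(report.summary())
                if report.excluded:
                    excluded_subjects.add(subject)
        pd.DataFrame(qc_rows).to_csv(out_dir / "qc_summary.tsv", sep="\t",
                                     index=False, float_format="%.10g")
        if excluded_subjects:
            manifest.warnings.append(
                f"subjects excluded for < {config.qc.min_frames} surviving "
                f"frames (dropped listwise): {sorted(excluded_subjects)}")
            keep = ~design.frame["subject"].isin(excluded_subjects)
            design = StudyDesign(design.frame[keep].reset_index(drop=True),
                                 behaviors=design.behaviors,
                                 covariate_cols=design.covariate_cols)
            clean = {s: v for s, v in clean.items() if s not in excluded_subjects}
        if not clean:
            raise RuntimeError(
                "every subject fell below the minimum surviving-frame count "
                f"({config.qc.min_frames}); nothing left to analyze")
        finish_stage("qc", t0)
    else:
        clean = {s: {k: ts for k, (ts, _m) in v.items()}
                 for s, v in bundle.sessions.items()}

    fc_tables: dict[str, dict[str, BlockFcTable]] = {}
    fcs: dict[str, dict[str, ConnectivityMatrix]] = {}
    if config.stages.get("connectivity", True):
        t0 = time.perf_counter()
        block_rows = []
        for subject, by_session in clean.items():
            fcs[subject] = {}
            fc_tables[subject] = {}
            for session, ts in by_session.items():
                fc = fc_matrix(ts)
                fc.to_tsv(out_dir / f"{subject}_ses-{session}_fc.tsv")
                blocks = block_summary(fc, partition)
                fcs[subject][session] = fc
                fc_tables[subject][session] = blocks
                long = blocks.to_long()
                long.insert(0, "session", session)
                long.insert(0, "subject", subject)
                block_rows.append(long)
        pd.concat(block_rows, ignore_index=True).to_csv(
            out_dir / "fc_blocks.tsv", sep="\t", index=False,
            float_format="%.10g")
        finish_stage("connectivity", t0)

    profiles: dict[str, dict[str, GraphMetricProfile]] = {}
    if config.stages.get("graph", True):
        if not fcs:
            raise RuntimeError("graph stage requires the connectivity stage")
        t0 = time.perf_counter()
        g = config.graph
        densities = g.densities()
        seed0 = config.stage_seed("graph")
        long_rows, integ_rows = [], []
        for si, (subject, by_session) in enumerate(sorted(fcs.items())):
            profiles[subject] = {}
            for sess_i, (session, fc) in enumerate(sorted(by_session.items())):
                child = int(np.random.SeedSequence(
                    entropy=seed0, spawn_key=(si, sess_i)).generate_state(1)[0]
                    % (2 ** 31))
                prof = metric_profile(
                    fc, densities=densities, n_nulls=g.n_nulls, seed=child,
                    n_swaps_per_edge=g.n_swaps_per_edge,
                    compute_sigma=g.compute_sigma)
                profiles[subject][session] = prof
                long_rows.append(prof.to_long(partition.roi_names))
                integ_rows.append(prof.integrated_frame(partition.roi_names))
        pd.concat(long_rows, ignore_index=True).to_csv(
            out_dir / "graph_metrics.tsv", sep="\t", index=False,
            float_format="%.10g")
        pd.concat(integ_rows, ignore_index=True).to_csv(
            out_dir / "graph_metrics_integrated.tsv", sep="\t", index=False,
            float_format="%.10g")
        finish_stage("graph", t0)

    if config.stages.get("stats", True):
        if not fc_tables and not profiles:
            raise RuntimeError("stats stage requires connectivity and/or graph outputs")
        t0 = time.perf_counter()
        s = config.stats
        results = run_interaction_suite(
            design, fc_blocks=fc_tables or None, profiles=profiles or None,
            n_perms=s.n_perms, seed=config.stage_seed("stats"),
            alpha_fc=s.alpha_fc, alpha_nodal=s.alpha_nodal,
            roi_names=partition.roi_names, fdr=s.fdr)
        results.to_csv(out_dir / "interaction_results.tsv", sep="\t",
                       index=False, float_format="%.10g")
        # brain-behavior correlations for outcomes passing the FC alpha
        bb_rows = []
        sig = results[results["sig_alpha_fc"]]
        covs = design.covariates()
        deltas = _collect_deltas(sig["outcome"], design, fc_tables, profiles,
                                 partition.roi_names)
        for behavior in design.behaviors:
            d_beh = design.behavior_delta(behavior)
            for outcome, d_metric in deltas.items():
                try:
                    bb = brain_behavior_correlation(
                        d_metric, d_beh, covariates=covs, metric=outcome,
                        behavior=behavior)
                except ValueError:
                    continue
                bb_rows.append({"outcome": outcome, "behavior": behavior,
                                "r": bb.r, "p_value": bb.p_value,
                                "n": bb.n, "df": bb.df})
        pd.DataFrame(bb_rows, columns=["outcome", "behavior", "r", "p_value",
                                       "n", "df"]).to_csv(
            out_dir / "brain_behavior.tsv", sep="\t", index=False,
            float_format="%.10g")
        meta = {
            "seed": config.seed, "n_perms": s.n_perms,
            "alpha_fc": s.alpha_fc, "alpha_nodal": s.alpha_nodal,
            "delta_convention": "time2 - time1; improvement = score decrease",
            "n_subjects": design.n_subjects,
        }
        with open(out_dir / "stats_manifest.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        finish_stage("stats", t0)

    for p in sorted(out_dir.glob("*.tsv")) + sorted(out_dir.glob("*.json")):
        if p.name != "run_manifest.json":
            manifest.output_hashes[p.name] = _sha256(p)
    manifest.write(out_dir / "run_manifest.json")
    return manifest


def _collect_deltas(outcomes, design: StudyDesign, fc_tables, profiles,
                    roi_names) -> dict[str, np.ndarray]:
    """Per-subject session-2 minus session-1 change for selected outcomes."""
    out = {}
    for outcome in outcomes:
        vals = np.empty(design.n_subjects)
        ok = True
        for i, subject in enumerate(design.subjects):
            if outcome.startswith("fc::"):
                a, b = outcome[4:].split("-")
                vals[i] = (fc_tables[subject]["2"].value(a, b)
                           - fc_tables[subject]["1"].value(a, b))
            elif outcome.startswith("global::"):
                m = outcome[len("global::"):]
                vals[i] = (profiles[subject]["2"].global_integrated[m]
                           - profiles[subject]["1"].global_integrated[m])
            elif outcome.startswith("nodal::"):
                _, m, name = outcome.split("::")
                ni = list(roi_names).index(name)
                vals[i] = (profiles[subject]["2"].nodal_integrated[m][ni]
                           - profiles[subject]["1"].nodal_integrated[m][ni])
            else:
                ok = False
                break
        if ok:
            out[outcome] = vals
    return out
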