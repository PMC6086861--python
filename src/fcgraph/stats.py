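"""Permutation inference for the 2-group x 2-timepoint design.

In a two-group repeated-measures design with two timepoints, the
group-by-time interaction is exactly the between-group difference in each
subject's within-subject change Delta = time2 - time1, so every outcome
reduces to a two-sample problem on change scores.

Without covariates the test is the classical two-sample permutation test
(pooled-variance t, whole subjects exchanged between groups, exact
enumeration when feasible).  With nuisance covariates (age, scanner) the
Freedman-Lane scheme is used: the reduced (covariates-only) model is
fitted once, and each permutation shuffles its residuals, re-projects
them, and recomputes the partial t of the group indicator — both outcome
and indicator adjusted for the covariates — which stays calibrated even
when a covariate is unbalanced across groups.

Sampled permutation p-values use the add-one estimator
p = (1 + #{|t*| >= |t|}) / (1 + n_perms), two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .connectivity import BlockFcTable
from .graph import GraphMetricProfile

DEFAULT_N_PERMS = 5000
GROUP_LEVELS = ("I", "NI")  # intervention / non-intervention


@dataclass
class StudyDesign:
    """Per-subject design: group, covariates, behavior at both timepoints.

    ``frame`` columns: subject, group (in {"I", "NI"}), age (years),
    scanner (binary label), and per behavior scale two columns
    ``<behavior>_t1`` / ``<behavior>_t2``.
    """

    frame: pd.DataFrame
    behaviors: tuple[str, ...] = ("inattention", "internalizing")
    covariate_cols: tuple[str, ...] = ("age", "scanner")

    def __post_init__(self) -> None:
        df = self.frame
        required = {"subject", "group", *self.covariate_cols}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        if df["subject"].duplicated().any():
            raise ValueError("every subject must appear exactly once")
        bad = set(df["group"]) - set(GROUP_LEVELS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        cov = df[list(self.covariate_cols)].to_numpy(float)
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariates must be finite")

    @property
    def subjects(self) -> list[str]:
        return list(self.frame["subject"])

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def group_mask(self) -> np.ndarray:
        """Boolean mask, True for the intervention group."""
        return (self.frame["group"] == "I").to_numpy()

    def covariates(self) -> np.ndarray:
        return self.frame[list(self.covariate_cols)].to_numpy(float)

    def behavior_delta(self, behavior: str) -> np.ndarray:
        """time2 - time1 change score (improvement = decrease on symptom scales)."""
        t1, t2 = f"{behavior}_t1", f"{behavior}_t2"
        if t1 not in self.frame.columns or t2 not in self.frame.columns:
            raise ValueError(f"behavior columns for {behavior!r} not present")
        return (self.frame[t2] - self.frame[t1]).to_numpy(float)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "StudyDesign":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)


@dataclass
class InteractionTestResult:
    outcome: str
    statistic: float           # two-sample t on adjusted change scores
    f_statistic: float         # t^2
    p_value: float
    n_perms: int
    seed: int | None
    mean_change: dict          # per-group mean Delta
    exact: bool = False        # permutation distribution enumerated exactly

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value out of range")


@dataclass
class BrainBehaviorResult:
    metric: str
    behavior: str
    r: float
    p_value: float
    n: int
    df: int


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``values`` after intercept + covariates.

    With no covariates this is mean-centering.  Rank-deficient covariate
    matrices are rejected.
    """
    y = np.asarray(values, float)
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return y - y.mean(axis=0)
    x = np.asarray(covariates, float)
    if x.ndim == 1:
        x = x[:, None]
    if n <= x.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def pooled_t(values: np.ndarray, group_a: np.ndarray) -> float:
    """Pooled-variance two-sample t (group A minus group B)."""
    a = values[group_a]
    b = values[~group_a]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def _residual_maker(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Projection onto the orthogonal complement of [intercept, covariates]."""
    if covariates is None or covariates.size == 0:
        return np.eye(n) - np.full((n, n), 1.0 / n)
    x = np.asarray(covariates, float)
    if x.ndim == 1:
        x = x[:, None]
    z = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    return np.eye(n) - z @ np.linalg.pinv(z)


def _partial_r(e_rows: np.ndarray, g_tilde: np.ndarray) -> np.ndarray:
    """Partial correlation of covariate-adjusted outcome rows with the
    adjusted group indicator."""
    num = e_rows @ g_tilde
    den = np.linalg.norm(g_tilde) * np.linalg.norm(e_rows, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, 0.0)


def _r_to_t(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r * np.sqrt(df / (1 - r ** 2))


def interaction_statistic(delta: np.ndarray, group_a: np.ndarray,
                          covariates: np.ndarray | None = None) -> float:
    """Group-by-time interaction statistic on change scores.

    Without covariates this is the pooled-variance two-sample t between
    groups.  With covariates it is the partial t of the group indicator
    after adjusting both the change score and the indicator for the
    covariates — identical to the pooled t when the covariates are
    balanced across groups, and correctly calibrated when they are not
    (e.g. an unbalanced scanner mix).  The equivalent F is t^2.
    """
    group_a = np.asarray(group_a, bool)
    if group_a.all() or not group_a.any():
        raise ValueError("both groups must be non-empty")
    delta = np.asarray(delta, float)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return pooled_t(delta, group_a)
    n = delta.shape[0]
    cov = np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    m = _residual_maker(cov, n)
    df = n - cov.shape[1] - 2
    if df < 1:
        raise ValueError("not enough subjects for the covariate count")
    r = _partial_r((m @ delta)[None, :], m @ group_a.astype(float))[0]
    return float(_r_to_t(np.asarray(r), df))


def _perm_t_matrix(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled t for many boolean group-A masks at once (masks: P x n)."""
    n = values.shape[0]
    na = masks.sum(axis=1)
    nb = n - na
    s1 = masks @ values
    s2 = masks @ (values ** 2)
    tot1, tot2 = values.sum(), (values ** 2).sum()
    ma = s1 / na
    mb = (tot1 - s1) / nb
    ssa = s2 - na * ma ** 2
    ssb = (tot2 - s2) - nb * mb ** 2
    sp2 = (ssa + ssb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    return t


def permutation_interaction_test(delta: np.ndarray, design: StudyDesign,
                                 n_perms: int = DEFAULT_N_PERMS,
                                 seed: int = 0,
                                 outcome: str = "outcome",
                                 use_covariates: bool = True) -> InteractionTestResult:
    """Two-sided permutation test for the group-by-time interaction.

    Whole subjects are exchanged between groups (within-subject pairing
    stays intact because the outcome is the per-subject change score).

    Without covariates the group labels are permuted directly, and the
    null distribution is enumerated exactly whenever the number of
    distinct assignments C(n, n_A) is at most ``n_perms``.  With
    covariates the Freedman-Lane scheme is used: the reduced
    (covariates-only) model is fitted once, its residuals are permuted,
    re-projected, and the partial t of the group indicator is recomputed,
    which stays calibrated even when a covariate is unbalanced across
    groups.  Sampled p-values use the add-one estimator, so
    p >= 1/(n_perms + 1).
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    delta = np.asarray(delta, float)
    if delta.shape[0] != design.n_subjects:
        raise ValueError("one change score per subject required")
    group_a = design.group_mask()
    na = int(group_a.sum())
    n = design.n_subjects
    if na < 2 or n - na < 2:
        raise ValueError("each group needs at least 2 subjects")
    cov = design.covariates() if use_covariates else None
    have_cov = cov is not None and cov.size > 0
    mean_change = {
        "I": float(delta[group_a].mean()),
        "NI": float(delta[~group_a].mean()),
    }
    if not have_cov:
        adj = delta - delta.mean()
        obs = pooled_t(adj, group_a)
        n_distinct = comb(n, na)
        if n_distinct <= n_perms:
            masks = np.zeros((n_distinct, n), bool)
            for i, c in enumerate(combinations(range(n), na)):
                masks[i, list(c)] = True
            t_null = _perm_t_matrix(adj, masks)
            p = float(np.mean(np.abs(t_null) >= abs(obs) - 1e-12))
            return InteractionTestResult(
                outcome=outcome, statistic=obs, f_statistic=obs ** 2,
                p_value=p, n_perms=n_distinct, seed=seed,
                mean_change=mean_change, exact=True)
        rng = np.random.default_rng(seed)
        keys = rng.random((n_perms, n))
        idx = np.argpartition(keys, na - 1, axis=1)[:, :na]
        masks = np.zeros((n_perms, n), bool)
        np.put_along_axis(masks, idx, True, axis=1)
        t_null = _perm_t_matrix(adj, masks)
        p = float((1 + np.sum(np.abs(t_null) >= abs(obs) - 1e-12))
                  / (1 + n_perms))
        return InteractionTestResult(
            outcome=outcome, statistic=obs, f_statistic=obs ** 2, p_value=p,
            n_perms=n_perms, seed=seed, mean_change=mean_change, exact=False)
    # Freedman-Lane with nuisance covariates
    cov = np.asarray(cov, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    df = n - cov.shape[1] - 2
    if df < 1:
        raise ValueError("not enough subjects for the covariate count")
    m = _residual_maker(cov, n)
    e = m @ delta
    g_tilde = m @ group_a.astype(float)
    r_obs = float(_partial_r(e[None, :], g_tilde)[0])
    obs = float(_r_to_t(np.asarray(r_obs), df))
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perms, n)), axis=1)
    e_perm = (e[perm_idx]) @ m  # re-project permuted reduced residuals
    r_null = _partial_r(e_perm, g_tilde)
    p = float((1 + np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12))
              / (1 + n_perms))
    return InteractionTestResult(
        outcome=outcome, statistic=obs, f_statistic=obs ** 2, p_value=p,
        n_perms=n_perms, seed=seed, mean_change=mean_change, exact=False)


def brain_behavior_correlation(delta_metric: np.ndarray,
                               delta_behavior: np.ndarray,
                               covariates: np.ndarray | None = None,
                               metric: str = "metric",
                               behavior: str = "behavior") -> BrainBehaviorResult:
    """Pearson correlation between FC/topology change and symptom change.

    Both change vectors are residualized on the covariates first; the
    two-sided p-value uses a t distribution with n - 2 - k degrees of
    freedom, charging one df per covariate regressed out.
    """
    x = np.asarray(delta_metric, float)
    y = np.asarray(delta_behavior, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("change vectors must be 1-D and equal length")
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    k = 0
    x_scale, y_scale = max(1.0, x.std()), max(1.0, y.std())
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        k = cov.shape[1]
        x = residualize(x, cov)
        y = residualize(y, cov)
    if x.std() <= 1e-10 * x_scale or y.std() <= 1e-10 * y_scale:
        raise ValueError("constant vector after residualization")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2 - k
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r ** 2))
        p = float(2 * sstats.t.sf(abs(t), df))
    return BrainBehaviorResult(metric=metric, behavior=behavior, r=r,
                               p_value=p, n=n, df=df)


def _block_delta_table(tables: dict[str, dict[str, BlockFcTable]],
                       design: StudyDesign) -> pd.DataFrame:
    """Per-subject change (session 2 - session 1) for each of the 36 blocks."""
    rows = {}
    for subject in design.subjects:
        t1 = tables[subject]["1"]
        t2 = tables[subject]["2"]
        systems = list(t1.table.index)
        vals = {}
        for i, a in enumerate(systems):
            for b in systems[i:]:
                vals[f"fc::{a}-{b}"] = t2.table.loc[a, b] - t1.table.loc[a, b]
        rows[subject] = vals
    return pd.DataFrame.from_dict(rows, orient="index").loc[design.subjects]


def _metric_delta_table(profiles: dict[str, dict[str, GraphMetricProfile]],
                        design: StudyDesign,
                        roi_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-subject change of integrated global and nodal graph metrics."""
    rows = {}
    for subject in design.subjects:
        p1 = profiles[subject]["1"]
        p2 = profiles[subject]["2"]
        vals = {}
        for m in p1.global_integrated:
            vals[f"global::{m}"] = p2.global_integrated[m] - p1.global_integrated[m]
        for m in p1.nodal_integrated:
            d = p2.nodal_integrated[m] - p1.nodal_integrated[m]
            for ni, v in enumerate(d):
                name = roi_names[ni] if roi_names else f"ROI_{ni + 1:03d}"
                vals[f"nodal::{m}::{name}"] = v
        rows[subject] = vals
    return pd.DataFrame.from_dict(rows, orient="index").loc[design.subjects]


def run_interaction_suite(design: StudyDesign,
                          fc_blocks: dict[str, dict[str, BlockFcTable]] | None = None,
                          profiles: dict[str, dict[str, GraphMetricProfile]] | None = None,
                          n_perms: int = DEFAULT_N_PERMS,
                          seed: int = 0,
                          alpha_fc: float = 0.05,
                          alpha_nodal: float = 0.01,
                          roi_names: tuple[str, ...] | None = None,
                          fdr: bool = False) -> pd.DataFrame:
    """Permutation interaction test for every FC-block and graph outcome.

    ``fc_blocks`` / ``profiles`` map subject -> session ("1"/"2") ->
    per-session summaries.  One permutation test is run per outcome: 36
    network blocks, the integrated global metrics, and the integrated nodal
    metrics per node.  Raw p-values are reported with significance flags at
    both alpha levels; no familywise correction is applied by default (an
    optional Benjamini-Hochberg column can be requested).
    """
    pieces = []
    if fc_blocks is not None:
        pieces.append(_block_delta_table(fc_blocks, design))
    if profiles is not None:
        pieces.append(_metric_delta_table(profiles, design, roi_names))
    if not pieces:
        raise ValueError("provide fc_blocks and/or profiles")
    deltas = pd.concat(pieces, axis=1)
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, outcome in enumerate(deltas.columns):
        d = deltas[outcome].to_numpy(float)
        if np.any(~np.isfinite(d)):
            continue  # undefined block (e.g. <2 ROIs in a system)
        child_seed = int(np.random.SeedSequence(
            entropy=seed, spawn_key=(i,)).generate_state(1)[0] % (2 ** 31))
        res = permutation_interaction_test(
            d, design, n_perms=n_perms, seed=child_seed, outcome=outcome)
        rows.append({
            "outcome": outcome, "statistic": res.statistic,
            "f_statistic": res.f_statistic, "p_value": res.p_value,
            "sig_alpha_fc": res.p_value < alpha_fc,
            "sig_alpha_nodal": res.p_value < alpha_nodal,
            "mean_change_I": res.mean_change["I"],
            "mean_change_NI": res.mean_change["NI"],
            "n_perms": res.n_perms, "exact": res.exact, "seed": child_seed,
        })
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_fdr"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
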