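"""Mixed-design statistical battery and the tidy outcome-table assembler.

The battery mirrors the standard analysis of a 2 (Group: ADHD vs HC) x
3 (Feedback Condition: real/sham/none) x 2 (Phase: DP/NDP) mixed design:

* Mixed ANOVAs (one between-subjects factor, one or two within-subject
  factors) via the univariate sums-of-squares decomposition with subjects
  nested in groups.  Sphericity of within effects with more than two levels
  is handled by Greenhouse-Geisser / Huynh-Feldt epsilons estimated from
  orthonormal-contrast covariance matrices; following common practice the
  Huynh-Feldt correction is applied when the GG estimate exceeds 0.75 and
  Greenhouse-Geisser otherwise.  Effect sizes are partial eta squared.
* Bonferroni-adjusted pairwise post-hoc t-tests.
* Independent/one-sample t-tests with Cohen's d.
* Pearson/Spearman correlation matrices with Benjamini-Hochberg adjusted
  p-values (adjustment across the off-diagonal tests of one matrix).
* Recognition accuracy (proportion correct of 60 old/new judgments).

All tests are two-sided at alpha = .05 by convention of the paradigm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "mixed_anova",
    "mixed_anova_2x3",
    "posthoc_bonferroni",
    "ttest_independent",
    "ttest_one_sample",
    "correlation_matrix",
    "recognition_accuracy",
    "build_outcome_table",
]


@dataclass
class AnovaResult:
    effect: str
    ss: float
    df_num: float
    df_den: float
    ms: float
    F: float
    p: float
    partial_eta_sq: float
    eps_gg: Optional[float] = None
    eps_hf: Optional[float] = None
    correction_applied: str = "none"  # "none" | "GG" | "HF"
    p_corrected: Optional[float] = None

    @property
    def p_final(self) -> float:
        return self.p if self.p_corrected is None else self.p_corrected


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, :i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _epsilons(y: np.ndarray, contrast: np.ndarray, n_groups: int
              ) -> tuple[float, float]:
    """GG and HF sphericity epsilons for contrast-transformed scores.

    ``y`` is the subjects x levels matrix of the within effect (already
    averaged over other factors); ``contrast`` maps levels to the effect's
    orthonormal contrasts.  HF uses the mixed-design small-sample correction
    with subjects-within-groups degrees of freedom.
    """
    z = y @ contrast.T
    s = np.cov(z, rowvar=False)
    s = np.atleast_2d(s)
    d = s.shape[0]
    tr = np.trace(s)
    denom = d * float(np.sum(s * s))
    gg = (tr ** 2) / denom if denom > 0 else 1.0  # constant data: no violation
    gg = float(min(1.0, max(1.0 / d, gg)))
    n = y.shape[0]
    num = n * d * gg - 2.0
    den = d * (n - n_groups) - d * d * gg
    hf = float(min(1.0, num / den)) if den > 0 else 1.0
    hf = max(hf, gg)
    return gg, hf


def _cell_means(df: pd.DataFrame, dv: str, by: list[str]) -> pd.Series:
    return df.groupby(by, observed=True)[dv].mean()


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant",
    between: str = "group",
    within: Sequence[str] = ("condition", "phase"),
) -> pd.DataFrame:
    """Mixed ANOVA with one between factor and 1-2 within factors.

    Requires a balanced, complete design: every subject contributes exactly
    one observation per within-cell.  Returns one row per effect with F,
    degrees of freedom, partial eta squared and — for within effects with
    more than two levels — sphericity epsilons and the corrected p-value
    (HF if the GG estimate exceeds 0.75, GG otherwise).
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ValueError("mixed_anova supports one or two within factors")
    df = data[[subject, between, dv, *within]].copy()
    # completeness check: every subject x within-cell exactly once
    levels = [sorted(df[f].unique()) for f in within]
    grid = pd.MultiIndex.from_product(
        [sorted(df[subject].unique()), *levels], names=[subject, *within])
    counts = df.groupby([subject, *within], observed=True)[dv] \
        .count().reindex(grid, fill_value=0)
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(
            f"unbalanced design: subject cell {bad.index[0]} has "
            f"{int(bad.iloc[0])} observations (expected 1)")
    if df[dv].isna().any():
        bad = df.loc[df[dv].isna(), subject].iloc[0]
        raise ValueError(f"missing dv value for participant {bad!r}")

    subjects = df[subject].unique()
    groups = df.groupby(subject, observed=True)[between].first()
    g_levels = sorted(groups.unique())
    n_g = len(g_levels)
    n_s = len(subjects)
    lv = {f: sorted(df[f].unique()) for f in within}
    k = {f: len(lv[f]) for f in within}
    n_cells = int(np.prod([k[f] for f in within]))

    gm = df[dv].mean()
    ss_total = float(((df[dv] - gm) ** 2).sum())

    subj_mean = df.groupby(subject, observed=True)[dv].mean()
    ss_between_subj = n_cells * float(((subj_mean - gm) ** 2).sum())
    grp_mean = df.groupby(between, observed=True)[dv].mean()
    grp_n = groups.value_counts()
    ss_g = n_cells * float(sum(
        grp_n[g] * (grp_mean[g] - gm) ** 2 for g in g_levels))
    ss_subj_g = ss_between_subj - ss_g
    df_subj_g = n_s - n_g

    results: list[AnovaResult] = []

    def add(effect: str, ss: float, dfn: float, ss_err: float, dfe: float,
            eps: Optional[tuple[float, float]] = None) -> None:
        ss = max(ss, 0.0)
        ss_err = max(ss_err, 0.0)
        ms = ss / dfn if dfn > 0 else np.nan
        mse = ss_err / dfe if dfe > 0 else np.nan
        if ss == 0 and ss_err == 0:
            f_val, p = 0.0, 1.0
        elif mse == 0:
            f_val, p = np.inf, 0.0
        else:
            f_val = ms / mse
            p = float(sps.f.sf(f_val, dfn, dfe))
        pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        res = AnovaResult(effect=effect, ss=ss, df_num=dfn, df_den=dfe,
                          ms=ms, F=float(f_val), p=p, partial_eta_sq=pes)
        if eps is not None and np.isfinite(f_val):
            gg, hf = eps
            use_hf = gg > 0.75
            e = hf if use_hf else gg
            res.eps_gg, res.eps_hf = gg, hf
            res.correction_applied = "HF" if use_hf else "GG"
            res.p_corrected = float(sps.f.sf(f_val, dfn * e, dfe * e))
        results.append(res)

    add(between, ss_g, n_g - 1, ss_subj_g, df_subj_g)

    # pivot: subject x full within-cell grid
    pivot_full = df.pivot_table(index=subject, columns=within, values=dv,
                                observed=True)
    grp_of = groups.loc[pivot_full.index].to_numpy()

    within_error_ss: dict[str, float] = {}
    for f in within:
        other = [w for w in within if w != f]
        kf = k[f]
        mult_f = n_cells // kf  # observations per (subject, level-of-f)
        f_mean = df.groupby(f, observed=True)[dv].mean()
        ss_f = n_s * mult_f * float(((f_mean - gm) ** 2).sum())
        gf_mean = _cell_means(df, dv, [between, f])
        ss_gf = mult_f * float(sum(
            grp_n[g] * (gf_mean[(g, c)] - grp_mean[g] - f_mean[c] + gm) ** 2
            for g in g_levels for c in lv[f]))
        # error: f x subject(group)
        sf_mean = df.groupby([subject, f], observed=True)[dv].mean()
        ss_sf = mult_f * float(sum(
            (sf_mean[(s_, c)] - subj_mean[s_] - gf_mean[(groups[s_], c)]
             + grp_mean[groups[s_]]) ** 2
            for s_ in subjects for c in lv[f]))
        df_err = df_subj_g * (kf - 1)
        within_error_ss[f] = ss_sf
        eps = None
        if kf > 2:
            ymat = df.pivot_table(index=subject, columns=f, values=dv,
                                  observed=True).loc[pivot_full.index]
            eps = _epsilons(ymat.to_numpy(), _orthonormal_contrasts(kf), n_g)
        add(f, ss_f, kf - 1, ss_sf, df_err, eps)
        add(f"{between} * {f}", ss_gf, (n_g - 1) * (kf - 1), ss_sf, df_err,
            eps)

    if len(within) == 2:
        f1, f2 = within
        k1, k2 = k[f1], k[f2]
        m12 = _cell_means(df, dv, [f1, f2])
        f1_mean = df.groupby(f1, observed=True)[dv].mean()
        f2_mean = df.groupby(f2, observed=True)[dv].mean()
        ss_12 = n_s * float(sum(
            (m12[(a, b)] - f1_mean[a] - f2_mean[b] + gm) ** 2
            for a in lv[f1] for b in lv[f2]))
        g12 = _cell_means(df, dv, [between, f1, f2])
        g1 = _cell_means(df, dv, [between, f1])
        g2 = _cell_means(df, dv, [between, f2])
        ss_g12 = float(sum(
            grp_n[g] * (g12[(g, a, b)] - g1[(g, a)] - g2[(g, b)]
                        - m12[(a, b)] + grp_mean[g] + f1_mean[a]
                        + f2_mean[b] - gm) ** 2
            for g in g_levels for a in lv[f1] for b in lv[f2]))
        # residual within error: total minus every named effect and error
        ss_named = (sum(r.ss for r in results) + ss_subj_g
                    + sum(within_error_ss.values()) + ss_12 + ss_g12)
        ss_err12 = ss_total - ss_named
        df_err12 = df_subj_g * (k1 - 1) * (k2 - 1)
        eps = None
        if (k1 - 1) * (k2 - 1) > 1:
            c12 = np.kron(_orthonormal_contrasts(k1),
                          _orthonormal_contrasts(k2))
            cols = [(a, b) for a in lv[f1] for b in lv[f2]]
            ymat = pivot_full.reindex(columns=cols).to_numpy()
            eps = _epsilons(ymat, c12, n_g)
        add(f"{f1} * {f2}", ss_12, (k1 - 1) * (k2 - 1), ss_err12, df_err12,
            eps)
        add(f"{between} * {f1} * {f2}", ss_g12,
            (n_g - 1) * (k1 - 1) * (k2 - 1), ss_err12, df_err12, eps)

    out = pd.DataFrame([vars(r) for r in results])
    out["p_final"] = out["p_corrected"].fillna(out["p"])
    out.attrs["ss_total"] = ss_total
    out.attrs["ss_subjects_within_groups"] = ss_subj_g
    return out


def mixed_anova_2x3(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant",
    between: str = "group",
    within: str = "condition",
) -> pd.DataFrame:
    """2 x k mixed ANOVA (one within factor), e.g. Group x Feedback Condition."""
    return mixed_anova(data, dv, subject=subject, between=between,
                       within=[within])


def posthoc_bonferroni(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "participant",
    paired: bool = True,
) -> pd.DataFrame:
    """Pairwise t-tests over factor levels with Bonferroni adjustment.

    Adjusted p = min(1, m * p_raw) with m = number of level pairs.  Paired
    tests aggregate to one value per subject x level first.
    """
    levels = sorted(data[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    agg = data.groupby([subject, factor], observed=True)[dv].mean().unstack()
    for a, b in pairs:
        if paired:
            x, y = agg[a].to_numpy(), agg[b].to_numpy()
            t, p = sps.ttest_rel(x, y)
            diff = float(np.mean(x - y))
            dof = len(x) - 1
        else:
            x = data.loc[data[factor] == a, dv].to_numpy()
            y = data.loc[data[factor] == b, dv].to_numpy()
            t, p = sps.ttest_ind(x, y)
            diff = float(np.mean(x) - np.mean(y))
            dof = len(x) + len(y) - 2
        rows.append({
            "level_a": a, "level_b": b, "mean_diff": diff, "t": float(t),
            "df": dof, "p_raw": float(p),
            "p_bonferroni": float(min(1.0, m * p)),
        })
    return pd.DataFrame(rows)


def _cohen_d_ind(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                 / (nx + ny - 2))
    return float((np.mean(x) - np.mean(y)) / sp) if sp > 0 else np.nan


def ttest_independent(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided independent-samples t-test with Cohen's d."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per sample")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("zero variance in both samples")
    t, p = sps.ttest_ind(x, y)
    return {"t": float(t), "df": len(x) + len(y) - 2, "p": float(p),
            "cohen_d": _cohen_d_ind(x, y)}


def ttest_one_sample(x: Sequence[float], popmean: float = 0.0) -> dict:
    """Two-sided one-sample t-test against ``popmean`` with Cohen's d."""
    x = np.asarray(x, float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    t, p = sps.ttest_1samp(x, popmean)
    return {"t": float(t), "df": len(x) - 1, "p": float(p),
            "cohen_d": float((np.mean(x) - popmean) / sd)}


def correlation_matrix(
    data: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    method: str = "pearson",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation matrix with BH-adjusted p-values.

    Returns ``(r, p_adjusted)``; the BH step-up correction is applied across
    the upper-triangle tests of this one matrix.  Constant columns yield NaN
    entries with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    cols = list(columns) if columns is not None else [
        c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    raw = []
    pairs = []
    for i, j in combinations(range(k), 2):
        x = data[cols[i]].to_numpy(float)
        y = data[cols[j]].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            warnings.warn(
                f"correlation {cols[i]} ~ {cols[j]}: constant or insufficient "
                f"data; entry set to NaN")
            r.iloc[i, j] = r.iloc[j, i] = np.nan
            p.iloc[i, j] = p.iloc[j, i] = np.nan
            continue
        if method == "pearson":
            rv, pv = sps.pearsonr(x[ok], y[ok])
        else:
            rv, pv = sps.spearmanr(x[ok], y[ok])
        r.iloc[i, j] = r.iloc[j, i] = float(rv)
        raw.append(float(pv))
        pairs.append((i, j))
    if raw:
        _, p_adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
        for (i, j), pv in zip(pairs, p_adj):
            p.iloc[i, j] = p.iloc[j, i] = float(pv)
    return r, p


def recognition_accuracy(judgments: Sequence[bool],
                         ground_truth: Sequence[bool]) -> float:
    """Proportion of correct old/new judgments."""
    judgments = np.asarray(judgments, bool)
    ground_truth = np.asarray(ground_truth, bool)
    if judgments.shape != ground_truth.shape:
        raise ValueError("judgments and ground truth must have equal length")
    if judgments.size == 0:
        raise ValueError("empty judgment vector")
    return float(np.mean(judgments == ground_truth))


# ---------------------------------------------------------------------------
# Outcome assembly: the full multimodal analysis battery over sessions
# ---------------------------------------------------------------------------

def build_outcome_table(
    sessions: Sequence,
    scene=None,
    include_eeg: bool = False,
    include_oculomotor: bool = False,
) -> pd.DataFrame:
    """One row per participant x condition x phase with all outcome columns.

    Runs the analysis battery on each block: CPT scoring split by phase,
    gaze-state dwell percentages and the distractibility score (per
    condition, repeated on both phase rows), head actigraphy, optionally the
    saccade detector and the EEG theta/beta ratio.  Dwell classification
    re-runs the ray-cast pipeline on the stored gaze stream against the
    reconstructed distractor schedule.
    """
    from . import oculomotor as ocu
    from . import physio
    from .cpt import split_performance_by_phase
    from .scene import (apply_schedule_to_scene, classify_gaze_stream,
                        default_scene, dwell_summary, intervals_from_samples)
    from .session import Phase

    rows = []
    for sess in sessions:
        for blk in sess.blocks:
            sched = blk.phase_schedule
            # dwell: classify stored gaze against the block's scene state
            scn = scene if scene is not None else default_scene()
            from .scene import distractor_schedule as dsched
            # distractor windows cannot be recovered from the gaze file alone:
            # prefer explicit activation metadata when the caller provides a
            # pre-configured scene; otherwise rebuild windows generously from
            # the schedule (any distractor active during DP).
            if scene is None:
                for c in scn.colliders:
                    if c.kind == "distractor":
                        c.active_windows = sched.windows(Phase.DP)
            g = blk.gaze
            dirs = np.stack([g.channel("ldx") + g.channel("rdx"),
                             g.channel("ldy") + g.channel("rdy"),
                             g.channel("ldz") + g.channel("rdz")], axis=1)
            norms = np.linalg.norm(dirs, axis=1, keepdims=True)
            dirs = np.divide(dirs, norms, out=np.zeros_like(dirs),
                             where=norms > 0)
            origins = np.stack([g.channel("lx"), g.channel("ly"),
                                g.channel("lz")], axis=1)
            valid = g.validity if g.validity is not None else \
                np.ones(len(g), bool)
            states, _ = classify_gaze_stream(g.timestamps, origins, dirs,
                                             scn, valid=valid)
            ivs = intervals_from_samples(g.timestamps, states,
                                         end_time=sched.end)
            dwell = dwell_summary(ivs, sched.duration)
            acti = physio.head_displacement(blk.head)
            perf = split_performance_by_phase(blk.cpt_block, blk.responses,
                                              sched)
            sac_summary = None
            if include_oculomotor:
                bt = ocu.BinocularTrace(
                    t=g.timestamps,
                    left=np.stack([g.channel("ldx"), g.channel("ldy"),
                                   g.channel("ldz")], axis=1),
                    right=np.stack([g.channel("rdx"), g.channel("rdy"),
                                    g.channel("rdz")], axis=1),
                    valid_left=g.channel("validity_l") > 0,
                    valid_right=g.channel("validity_r") > 0,
                )
                mono = ocu.preprocess(bt)
                saccades, _ = ocu.detect_events(mono)
                sac_summary = ocu.summarize_saccades(saccades, sched)
            for phase in (Phase.DP, Phase.NDP):
                row = {
                    "participant": sess.participant_id,
                    "group": sess.group,
                    "condition": blk.condition.value,
                    "phase": phase.value,
                    "omission_errors": perf[phase].omission_errors,
                    "commission_errors": perf[phase].commission_errors,
                    "mean_rt": perf[phase].mean_rt,
                    "head_movement": acti.mean_displacement * 1000.0,  # mm
                    "n_feedback": len(blk.feedback_events),
                    **dwell.as_dict(),
                }
                for k, v in blk.experience_sampling.items():
                    row[f"es_{k}"] = v
                if sac_summary is not None:
                    row["saccade_count"] = sac_summary[phase]["count"]
                    row["saccade_duration"] = \
                        sac_summary[phase]["mean_duration_ms"]
                if include_eeg and blk.eeg is not None:
                    res = physio.tbr_pipeline(blk.eeg, sched, phase,
                                              condition=blk.condition.value)
                    row["tbr"] = res.tbr
                    row["theta_power"] = res.theta_power
                    row["beta_power"] = res.beta_power
                rows.append(row)
    return pd.DataFrame(rows)
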