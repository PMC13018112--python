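"""Mixed-design (split-plot) ANOVA and simple-effect statistics for IPS.

The design crosses one between-subjects factor (group: treated vs control)
with one within-subjects factor (time: T0, T1, T2). The classical split-plot
decomposition is used:

* between-subjects stratum — group effect tested against
  subjects-within-groups;
* within-subjects stratum — time and group x time tested against the
  time x subjects-within-groups residual.

Sphericity of the within-subject covariance is assessed with Mauchly's test
on the pooled (per-group-centered) covariance matrix; the Greenhouse-Geisser
epsilon rescales the within-stratum degrees of freedom. Both corrected and
uncorrected p-values are always reported; the corrected one is flagged as
primary when Mauchly's p < .05.

Effect sizes are generalized eta-squared (Gn2), computed as
``SS_effect / (SS_effect + SS_subjects_within + SS_within_residual)`` so
values are comparable across the between- and within-subject effects.

Simple effects are within-group paired t-tests across time, with Shaffer's
sequentially rejective adjustment over the three pairwise contrasts, and
paired standardized effect sizes: dz (mean change / SD of change scores)
and the alternative d_av (mean change / mean of the two raw SDs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixedAnova",
    "split_plot_anova",
    "shaffer_adjust",
    "paired_change_summary",
    "simple_effects",
]


class MissingDataError(ValueError):
    """Incomplete participant x time crossing (no imputation is attempted)."""


def _validate_long(data: pd.DataFrame, dv: str) -> tuple[pd.DataFrame, list, list]:
    need = {"participant", "group", "time", dv}
    missing = need - set(data.columns)
    if missing:
        raise ValueError(f"long table missing columns {sorted(missing)}")
    groups = sorted(data["group"].unique())
    times = sorted(data["time"].unique())
    gmap = data.groupby("participant")["group"].nunique()
    if (gmap > 1).any():
        raise ValueError("a participant appears in more than one group")
    counts = data.groupby(["participant", "time"]).size()
    wide = data.pivot_table(index="participant", columns="time", values=dv)
    if (counts != 1).any() or wide.isna().any().any():
        bad = sorted(wide.index[wide.isna().any(axis=1)])
        raise MissingDataError(
            f"incomplete participant x time crossing (e.g. {bad[:5]}); "
            "split-plot ANOVA requires complete data"
        )
    return wide, groups, times


def _gg_epsilon(pooled_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-subject covariance."""
    k = pooled_cov.shape[0]
    # Double-centered covariance: equivalent to C S C' with orthonormal
    # contrasts C, via the eigenvalues of the centered matrix.
    ctr = np.eye(k) - np.ones((k, k)) / k
    s = ctr @ pooled_cov @ ctr
    tr = np.trace(s)
    denom = (k - 1) * np.sum(s * s.T)
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr * tr / denom))


def _mauchly(pooled_cov: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Mauchly's sphericity W and chi-square p on the pooled covariance.

    ``df_resid`` is N - g, the degrees of freedom of the pooled estimate.
    """
    k = pooled_cov.shape[0]
    # Project onto an orthonormal contrast basis (k-1 dims).
    full = np.linalg.qr(np.vstack([np.ones(k), np.eye(k - 1, k)]).T)[0]
    c = full[:, 1:].T
    s = c @ pooled_cov @ c.T
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 0):
        return 0.0, 0.0
    w = float(np.prod(eig) / (np.mean(eig) ** (k - 1)))
    d = k - 1
    f_corr = (2 * d * d + d + 2) / (6.0 * d * df_resid)
    chi2 = -(1.0 - f_corr) * df_resid * np.log(w)
    df = d * (d + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return w, p


def split_plot_anova(
    data: pd.DataFrame, dv: str = "ips", mauchly_alpha: float = 0.05
) -> pd.DataFrame:
    """Split-plot ANOVA table for a 2-group x k-time complete design.

    Returns one row per effect (group, time, group:time) with columns
    SS, df1, df2, MS, F, p, p_gg, df1_gg, df2_gg, gen_eta_sq, epsilon_gg,
    mauchly_w, mauchly_p, sphericity_violated. GG-scaled df and p are
    reported for the within-stratum effects regardless of the Mauchly
    outcome; ``sphericity_violated`` says whether the correction is the
    primary read-out under the configured threshold.
    """
    wide, groups, times = _validate_long(data, dv)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    group_of = data.groupby("participant")["group"].first()
    y = wide[times].to_numpy(float)  # subjects x times
    glab = group_of.loc[wide.index].to_numpy()
    n_sub, k = y.shape
    g = len(groups)
    if min((glab == lab).sum() for lab in groups) < 2:
        raise ValueError("need >= 2 participants per group")

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    group_means = {lab: y[glab == lab].mean() for lab in groups}
    n_g = {lab: int((glab == lab).sum()) for lab in groups}

    # Between-subject stratum (on subject means, scaled by k).
    ss_group = k * sum(n_g[lab] * (group_means[lab] - grand) ** 2 for lab in groups)
    ss_subj = k * sum(
        (subj_mean[glab == lab] - group_means[lab]) @ (subj_mean[glab == lab] - group_means[lab])
        for lab in groups
    )

    # Within-subject stratum on subject-centered scores.
    c = y - subj_mean[:, None]
    tbar = c.mean(axis=0)  # weighted (by subject) time means
    ss_time = n_sub * float(tbar @ tbar)
    ss_inter = 0.0
    ss_err_w = 0.0
    for lab in groups:
        cg = c[glab == lab]
        cell = cg.mean(axis=0)
        ss_inter += n_g[lab] * float((cell - tbar) @ (cell - tbar))
        ss_err_w += float(((cg - cell) ** 2).sum())

    df_group, df_subj = g - 1, n_sub - g
    df_time, df_inter = k - 1, (g - 1) * (k - 1)
    df_err_w = (n_sub - g) * (k - 1)

    # Pooled within-group covariance of the raw time scores.
    pooled = np.zeros((k, k))
    for lab in groups:
        yg = y[glab == lab]
        pooled += (yg - yg.mean(axis=0)).T @ (yg - yg.mean(axis=0))
    pooled /= df_subj
    eps = _gg_epsilon(pooled)
    w, mauchly_p = _mauchly(pooled, df_subj)

    ms_subj = ss_subj / df_subj
    ms_err_w = ss_err_w / df_err_w

    def _row(name, ss, df1, df2, ms_err, within):
        if ms_err == 0.0:
            f = np.nan if ss == 0 else np.inf
            p = np.nan
        else:
            f = (ss / df1) / ms_err
            p = float(stats.f.sf(f, df1, df2))
        ges = ss / (ss + ss_subj + ss_err_w) if (ss + ss_subj + ss_err_w) > 0 else np.nan
        row = {
            "effect": name,
            "SS": ss,
            "df1": df1,
            "df2": df2,
            "MS": ss / df1,
            "F": f,
            "p": p,
            "gen_eta_sq": ges,
            "epsilon_gg": eps if within else np.nan,
            "mauchly_w": w if within else np.nan,
            "mauchly_p": mauchly_p if within else np.nan,
            "sphericity_violated": (mauchly_p < mauchly_alpha) if within else False,
        }
        if within:
            row["df1_gg"] = df1 * eps
            row["df2_gg"] = df2 * eps
            row["p_gg"] = float(stats.f.sf(f, df1 * eps, df2 * eps)) if np.isfinite(f) else np.nan
        else:
            row["df1_gg"] = np.nan
            row["df2_gg"] = np.nan
            row["p_gg"] = np.nan
        return row

    rows = [
        _row("group", ss_group, df_group, df_subj, ms_subj, within=False),
        _row("time", ss_time, df_time, df_err_w, ms_err_w, within=True),
        _row("group:time", ss_inter, df_inter, df_err_w, ms_err_w, within=True),
    ]
    out = pd.DataFrame(rows)
    out.attrs["ss_subjects_within"] = ss_subj
    out.attrs["ss_within_residual"] = ss_err_w
    out.attrs["df_subjects_within"] = df_subj
    out.attrs["df_within_residual"] = df_err_w
    return out


def shaffer_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Shaffer S1 adjustment for the 3 pairwise contrasts among 3 levels.

    With three pairwise hypotheses among three means, rejecting the
    smallest-p hypothesis leaves at most one of the remaining two true, so
    the step-down multipliers are {3, 1, 1} in ascending-p order; a running
    maximum enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.shape != (3,):
        raise ValueError("Shaffer S1 for 3 levels expects exactly 3 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    mult = np.array([3.0, 1.0, 1.0])
    adj_sorted = np.minimum(np.maximum.accumulate(p[order] * mult), 1.0)
    adj = np.empty(3)
    adj[order] = adj_sorted
    return adj


@dataclass(frozen=True)
class PairedChange:
    """Summary of a paired change score between two time points."""

    n: int
    mean_change: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    dz: float  # mean diff / SD of diffs
    d_av: float  # mean diff / mean of the two raw SDs
    degenerate: bool  # True when the change scores have zero variance


def paired_change_summary(
    values_a: Sequence[float], values_b: Sequence[float], ci: float = 0.95
) -> PairedChange:
    """Paired change b - a: mean, t-based CI, paired-t p, dz and d_av."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired sequences with n >= 2")
    d = b - a
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    sd_av = float((a.std(ddof=1) + b.std(ddof=1)) / 2.0)
    if sd == 0.0:
        return PairedChange(n, mean, mean, mean, np.nan, np.nan, np.nan,
                            mean / sd_av if sd_av > 0 else np.nan, True)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci / 2.0, n - 1)
    tstat = mean / se
    p = float(2.0 * stats.t.sf(abs(tstat), n - 1))
    return PairedChange(
        n=n,
        mean_change=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        t=float(tstat),
        p=p,
        dz=mean / sd,
        d_av=mean / sd_av if sd_av > 0 else np.nan,
        degenerate=False,
    )


def simple_effects(
    data: pd.DataFrame, dv: str = "ips", times: Sequence[str] | None = None
) -> pd.DataFrame:
    """Within-group paired contrasts across time with Shaffer adjustment.

    One row per group per pairwise contrast (later - earlier), with the
    paired-t raw p, Shaffer-adjusted p (within each group's three
    contrasts), the 95% CI of the mean change, and both paired effect
    sizes.
    """
    wide, groups, all_times = _validate_long(data, dv)
    times = list(times or all_times)
    group_of = data.groupby("participant")["group"].first()
    rows = []
    for lab in groups:
        sub = wide.loc[group_of.loc[wide.index] == lab]
        contrasts = [(b, a) for a, b in combinations(times, 2)]
        summaries = [paired_change_summary(sub[a], sub[b]) for b, a in contrasts]
        raw = [s.p for s in summaries]
        adj = (
            shaffer_adjust(raw)
            if len(raw) == 3 and np.isfinite(raw).all()
            else np.full(len(raw), np.nan)
        )
        for (later, earlier), s, ap in zip(contrasts, summaries, adj):
            rows.append(
                {
                    "group": lab,
                    "contrast": f"{later}-{earlier}",
                    "n": s.n,
                    "mean_change": s.mean_change,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "raw_p": s.p,
                    "adjusted_p": ap,
                    "dz": s.dz,
                    "d_av": s.d_av,
                    "degenerate": s.degenerate,
                }
            )
    return pd.DataFrame(rows)


class MixedAnova:
    """Split-plot ANOVA estimator for a long participant x time outcome table.

    Parameters
    ----------
    dv : str
        Outcome column in the long table (default "ips").
    mauchly_alpha : float
        Threshold on Mauchly's p below which the Greenhouse-Geisser
        corrected p is flagged as the primary read-out.
    simple_effects_gate : bool
        When True (default), simple effects are computed only after a
        significant interaction (at ``alpha``), mirroring the usual
        reporting convention; set False to always compute them.
    alpha : float
        Two-sided significance level.

    Fitted attributes: ``anova_``, ``epsilon_gg_``, ``mauchly_p_``,
    ``simple_effects_`` (None when gated out), ``interaction_significant_``.
    """

    def __init__(
        self,
        dv: str = "ips",
        mauchly_alpha: float = 0.05,
        simple_effects_gate: bool = True,
        alpha: float = 0.05,
    ):
        self.dv = dv
        self.mauchly_alpha = mauchly_alpha
        self.simple_effects_gate = simple_effects_gate
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {
            "dv": self.dv,
            "mauchly_alpha": self.mauchly_alpha,
            "simple_effects_gate": self.simple_effects_gate,
            "alpha": self.alpha,
        }

    def set_params(self, **params) -> "MixedAnova":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame) -> "MixedAnova":
        self.anova_ = split_plot_anova(data, dv=self.dv, mauchly_alpha=self.mauchly_alpha)
        inter = self.anova_.set_index("effect").loc["group:time"]
        self.epsilon_gg_ = float(inter["epsilon_gg"])
        self.mauchly_p_ = float(inter["mauchly_p"])
        p_primary = inter["p_gg"] if inter["sphericity_violated"] else inter["p"]
        self.interaction_significant_ = bool(p_primary < self.alpha)
        if self.interaction_significant_ or not self.simple_effects_gate:
            self.simple_effects_ = simple_effects(data, dv=self.dv)
        else:
            self.simple_effects_ = None
        return self
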