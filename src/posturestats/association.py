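"""Exploratory brain-behavior correlations.

Spearman rank correlations, computed separately per group, between
connectivity metrics (cluster-mean or single-edge Fisher z, as change
scores or per-session values) and the postural-stability change score
dIPS. Ranks use average-rank tie handling; the two-sided p-value comes
from the t approximation. With fewer than three pairs the correlation is
reported without a p-value. Following the exploratory framing of these
analyses, no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssociationResult", "spearman_assoc", "brainbehavior_report"]


@dataclass(frozen=True)
class AssociationResult:
    group: str
    metric: str
    rs: float
    p: float  # NaN when n < 3 or a variable is constant
    n: int


def spearman_assoc(
    x: Sequence[float], y: Sequence[float], group: str = "", metric: str = ""
) -> AssociationResult:
    """Spearman rank correlation with average-rank ties and t-approx p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(group, metric, np.nan, np.nan, n)
    rs, p = stats.spearmanr(x, y)
    if n < 3:
        p = np.nan
    return AssociationResult(group, metric, float(rs), float(p), n)


def brainbehavior_report(
    cluster_fc: pd.DataFrame,
    changes: pd.DataFrame,
    edge_fc: Mapping[str, pd.DataFrame] | None = None,
    contrast: str = "T1-T0",
    sessions: Sequence[str] = ("T0", "T1"),
) -> pd.DataFrame:
    """Per-group Spearman associations between FC metrics and dIPS.

    Parameters
    ----------
    cluster_fc : frame with participant, group, fc_<session> columns and
        delta_fc (cluster-mean values, from ``cluster_mean_fc``).
    changes : per-participant IPS change table (``ips_changes`` output);
        the rows matching ``contrast`` supply dIPS.
    edge_fc : optional mapping of edge label -> same-shape frame for
        single-edge metrics.
    """
    d_ips = (
        changes[changes["contrast"] == contrast]
        .set_index("participant")[["group", "delta_ips"]]
    )
    frames = {"cluster": cluster_fc}
    frames.update(edge_fc or {})
    rows = []
    for name, fc in frames.items():
        fc = fc.set_index("participant")
        missing = set(d_ips.index) ^ set(fc.index)
        if missing:
            raise ValueError(f"participant keys misaligned for {name}: {sorted(missing)}")
        joined = fc.join(d_ips["delta_ips"], how="inner")
        for group, sub in joined.groupby("group"):
            metrics = {f"dFC_{name}": sub["delta_fc"]}
            for s in sessions:
                metrics[f"FC_{name}@{s}"] = sub[f"fc_{s}"]
            for metric, vals in metrics.items():
                res = spearman_assoc(vals, sub["delta_ips"], group, metric)
                rows.append(
                    {
                        "group": res.group,
                        "metric": res.metric,
                        "rs": res.rs,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)
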