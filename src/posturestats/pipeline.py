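"""End-to-end pipeline: generate a synthetic study and run all analyses.

``run_all`` executes, in order: synthetic-data generation, IPS scoring and
change scores, the split-plot ANOVA with simple effects, the body-part-code
contingency analysis, the TFCE permutation test on edge-wise connectivity
change, and the brain-behavior association report. Every stage writes its
tables under the output directory and the run is fully reproducible from
(config, seed): re-running with the same inputs yields byte-identical
reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .association import brainbehavior_report
from .behavior import MixedAnova
from .coding import CodeContingency, ContingencyResult, chi_square_test
from .config import SimConfig
from .connectome import (
    EdgeInteractionTest,
    cluster_mean_fc,
    delta_fc_by_group,
    fc_table,
)
from .posturography import IpsScorer, ips_records
from .synth import (
    generate_study,
    write_code_table,
    write_cop_table,
    write_roi_series,
)

__all__ = ["run_all", "replicate_bodypart_counts", "RunManifest", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    config_hash: str
    stages: dict = field(default_factory=dict)  # stage -> {"status", "outputs"}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                default=str,
            )


def _hash_config(config: SimConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(
    config: SimConfig,
    out_dir,
    n_perm: int = 1000,
    write_raw: bool = False,
) -> RunManifest:
    """Run every stage on a synthetic study; returns the run manifest.

    ``write_raw`` additionally dumps the raw COP / ROI tables (large);
    analysis tables and the consolidated report are always written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__ as version

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        version=version,
        config_hash=_hash_config(config),
    )

    def _stage(name, fn):
        try:
            outputs = fn()
        except Exception as exc:  # halt, but keep partial outputs on disk
            manifest.stages[name] = {"status": "failed", "error": str(exc)}
            manifest.to_json(out / "manifest.json")
            raise StageError(name, exc) from exc
        manifest.stages[name] = {"status": "ok", "outputs": outputs}
        return outputs

    state: dict = {}

    def synth_stage():
        state["study"] = generate_study(config)
        paths = []
        write_code_table(state["study"].code_table, out / "code_table.csv")
        paths.append("code_table.csv")
        if write_raw:
            write_cop_table(state["study"].cop_trials, out / "cop_trials.csv")
            write_roi_series(state["study"].roi_series, out / "roi_series")
            paths += ["cop_trials.csv", "roi_series/"]
        return paths

    def ips_stage():
        scorer = IpsScorer().fit(state["study"].cop_trials)
        state["ips"] = scorer.records_
        state["changes"] = scorer.changes_
        scorer.records_.to_csv(out / "ips_records.csv", index=False)
        scorer.changes_.to_csv(out / "ips_changes.csv", index=False)
        return ["ips_records.csv", "ips_changes.csv"]

    def anova_stage():
        model = MixedAnova(simple_effects_gate=False).fit(state["ips"])
        state["anova"] = model
        model.anova_.to_csv(out / "anova.csv", index=False)
        model.simple_effects_.to_csv(out / "simple_effects.csv", index=False)
        return ["anova.csv", "simple_effects.csv"]

    def coding_stage():
        model = CodeContingency(groups=config.groups, times=config.code_time_points)
        model.fit(state["study"].code_table)
        state["coding"] = model
        flat = model.counts_.copy()
        flat.columns = [f"{g}_{t}" for g, t in flat.columns]
        flat.to_csv(out / "code_counts.csv")
        rz = model.residuals_.copy()
        rz.columns = flat.columns
        rz.to_csv(out / "code_residuals.csv")
        return ["code_counts.csv", "code_residuals.csv"]

    def connectome_stage():
        fcs = fc_table(state["study"].roi_series)
        state["fcs"] = fcs
        deltas = delta_fc_by_group(fcs, sessions=config.fc_time_points)
        treated, control = config.groups
        est = EdgeInteractionTest(n_perm=n_perm, seed=config.seed).fit(
            deltas[treated], deltas[control], roi_labels=config.roi_labels
        )
        state["edges"] = est
        est.edge_stats_.to_csv(out / "edge_stats.csv", index=False)
        return ["edge_stats.csv"]

    def association_stage():
        est = state["edges"]
        members = (
            est.clusters_[0]["members"]
            if est.clusters_
            else list(state["study"].truth.planted_edges)
        )
        cl = cluster_mean_fc(state["fcs"], members, sessions=config.fc_time_points)
        edge_frames = {
            f"{a}--{b}": cluster_mean_fc(
                state["fcs"], [(a, b)], sessions=config.fc_time_points
            )
            for a, b in members
        }
        assoc = brainbehavior_report(
            cl, state["changes"], edge_fc=edge_frames,
            sessions=config.fc_time_points,
        )
        state["assoc"] = assoc
        cl.to_csv(out / "cluster_fc.csv", index=False)
        assoc.to_csv(out / "associations.csv", index=False)
        return ["cluster_fc.csv", "associations.csv"]

    _stage("synth", synth_stage)
    _stage("posturography", ips_stage)
    _stage("behavior_stats", anova_stage)
    _stage("coding", coding_stage)
    _stage("connectome", connectome_stage)
    _stage("association", association_stage)

    _write_report(out, config, state)
    manifest.stages["report"] = {"status": "ok", "outputs": ["report.json"]}
    manifest.to_json(out / "manifest.json")
    return manifest


def _write_report(out: Path, config: SimConfig, state: dict) -> None:
    est = state["edges"]
    anova = state["anova"].anova_.set_index("effect")
    inter = anova.loc["group:time"]
    treated = config.treated_group
    se = state["anova"].simple_effects_
    se_t = se[(se["group"] == treated) & (se["contrast"] == "T1-T0")].iloc[0]
    report = {
        "seed": config.seed,
        "groups": list(config.groups),
        "n_per_group": list(config.n_per_group),
        "ips": {
            "baseline_mean_by_group": state["ips"][state["ips"].time == "T0"]
            .groupby("group")["ips"]
            .mean()
            .round(6)
            .to_dict(),
            "anova_interaction": {
                "F": round(float(inter["F"]), 6),
                "df1_gg": round(float(inter["df1_gg"]), 4),
                "df2_gg": round(float(inter["df2_gg"]), 4),
                "p_gg": round(float(inter["p_gg"]), 6),
                "gen_eta_sq": round(float(inter["gen_eta_sq"]), 6),
                "epsilon_gg": round(float(inter["epsilon_gg"]), 6),
            },
            "treated_T1_T0": {
                "mean_change": round(float(se_t["mean_change"]), 6),
                "ci": [round(float(se_t["ci_low"]), 6), round(float(se_t["ci_high"]), 6)],
                "adjusted_p": round(float(se_t["adjusted_p"]), 6),
                "dz": round(float(se_t["dz"]), 6),
            },
        },
        "coding": {
            "chi2": round(state["coding"].chi2_, 6),
            "df": state["coding"].df_,
            "p": round(state["coding"].p_, 6),
            "cramers_v": round(state["coding"].cramers_v_, 6),
        },
        "connectome": {
            "n_edges": len(est.edges_),
            "df": est.df_,
            "n_clusters": len(est.clusters_),
            "clusters": [
                {
                    "cluster_id": c["cluster_id"],
                    "members": [f"{a}--{b}" for a, b in c["members"]],
                    "cluster_tfce": round(c["cluster_tfce"], 4),
                    "p_fwe": round(c["p_fwe"], 6),
                }
                for c in est.clusters_
            ],
        },
        "associations": state["assoc"].round(6).to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def replicate_bodypart_counts(counts_path=None) -> ContingencyResult:
    """Contingency analysis of the packaged (or a user-supplied) body-part
    count table: 5 codes x 4 group-time conditions of participant-level
    code presences."""
    if counts_path is None:
        ref = resources.files("posturestats.data") / "bodypart_counts.csv"
        with resources.as_file(ref) as p:
            counts = pd.read_csv(p, index_col=0)
    else:
        counts = pd.read_csv(counts_path, index_col=0)
        if counts.shape[1] < 2 or not np.issubdtype(
            counts.to_numpy().dtype, np.number
        ):
            raise ValueError(
                f"malformed counts file {counts_path}: expected code rows and "
                "numeric condition columns"
            )
    return chi_square_test(counts)


def packaged_expected_stats() -> pd.DataFrame:
    """Published comparison values shipped with the count fixture."""
    ref = resources.files("posturestats.data") / "bodypart_expected_stats.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#")
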