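"""Synthetic study generator.

Emits the three raw-data modalities the analysis pipeline consumes, with
the statistical structure the downstream analyses assume and full
determinism under the configured seed:

* **COP sessions** — five 10-s stance trials per participant per session.
  Each axis follows a discretized Ornstein-Uhlenbeck (OU) process around
  the position's target center, giving stationary, tunable sway.
  Directional trials are centered at participant-specific stability limits
  (log-normal around the population values), so the IPS varies across
  subjects. The treated arm's sway SD is scaled by ``10**(-ips_effect/2)``
  at post-training sessions, which shrinks sway areas by ``10**(-ips_effect)``
  and hence raises the expected IPS by ``ips_effect``.
* **code tables** — per participant-document Bernoulli draws of each
  body-part code, with per group x time probabilities.
* **ROI time series** — 18-ROI multivariate normal series with block
  covariance by network (within- vs between-network correlation), AR(1)
  smoothed to emulate band-limited BOLD signal (lag-0 covariance is
  preserved by the smoothing). For the treated arm at T1 the planted
  edges' correlations are shifted by ``planted_delta_r``, recomposing the
  full covariance so positive definiteness can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ROI_NETWORKS, ConfigError, SimConfig
from .posturography import DIRECTIONAL_POSITIONS, POSITIONS, CopTrial

__all__ = [
    "RoiTimeSeries",
    "SyntheticStudy",
    "gen_cop_session",
    "gen_code_table",
    "gen_roi_timeseries",
    "generate_study",
    "write_cop_table",
    "write_code_table",
    "write_roi_series",
]

# Fixed substream offsets so the three modalities draw from independent,
# individually reproducible streams of the master seed.
_STREAM_COP, _STREAM_CODE, _STREAM_ROI = 1, 2, 3


@dataclass(frozen=True)
class RoiTimeSeries:
    """One participant-session block of denoised ROI signals (ROI x time)."""

    participant: str
    group: str
    session: str
    data: np.ndarray  # (n_rois, n_volumes)
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, float)
        if arr.ndim != 2 or arr.shape[0] != len(self.roi_labels):
            raise ValueError("data must be (n_rois, n_volumes) matching roi_labels")
        if arr.shape[1] < 10:
            raise ValueError("need >= 10 time points")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite values in ROI series")
        object.__setattr__(self, "data", arr)


@dataclass(frozen=True)
class StudyTruth:
    """Planted-effect record; echoes the generating config exactly."""

    ips_effect: float
    planted_edges: tuple[tuple[str, str], ...]
    planted_delta_r: float
    code_probs: Mapping


@dataclass(frozen=True)
class SyntheticStudy:
    config: SimConfig
    cop_trials: list  # list[CopTrial]
    code_table: pd.DataFrame
    roi_series: list  # list[RoiTimeSeries]
    truth: StudyTruth


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# -- COP ----------------------------------------------------------------------


def _ou_trial(
    rng: np.random.Generator,
    center: np.ndarray,
    sd: float,
    theta: float,
    n: int,
    dt: float,
) -> np.ndarray:
    """Exact-discretization stationary OU around ``center``; sd is the
    stationary per-axis SD."""
    if sd == 0.0:
        return np.tile(center, (n, 1))
    a = np.exp(-theta * dt)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    x0 = rng.normal(0.0, sd, size=2)
    steps = rng.normal(0.0, innov_sd, size=(n - 1, 2))
    # x[i] = a * x[i-1] + steps[i-1]: an AR(1) filter over the innovations
    from scipy.signal import lfilter

    drive = np.vstack([x0, steps])
    x = lfilter([1.0], [1.0, -a], drive, axis=0)
    return x + center


def gen_cop_session(config: SimConfig) -> list[CopTrial]:
    """All COP trials: participants x behavioral time points x 5 positions."""
    if config.cop_noise_sd < 0 or config.cop_ou_theta <= 0:
        raise ConfigError("cop_noise_sd must be >= 0 and cop_ou_theta > 0")
    rng = _rng(config, _STREAM_COP)
    n = int(round(config.cop_rate * config.cop_duration))
    dt = 1.0 / config.cop_rate
    trials: list[CopTrial] = []
    for pid, group in config.participants():
        # Participant-specific stability limits and sway scale (log-normal).
        lim_ap = config.stance_limit_ap * np.exp(rng.normal(0.0, config.limit_sigma))
        lim_ml = config.stance_limit_ml * np.exp(rng.normal(0.0, config.limit_sigma))
        sway_mult = np.exp(rng.normal(0.0, config.sway_sigma))
        centers = {
            "center": np.array([0.0, 0.0]),
            "anterior": np.array([lim_ap / 2.0, 0.0]),
            "posterior": np.array([-lim_ap / 2.0, 0.0]),
            "right": np.array([0.0, lim_ml / 2.0]),
            "left": np.array([0.0, -lim_ml / 2.0]),
        }
        treated = group == config.treated_group
        for time in config.time_points:
            post = time != config.time_points[0]
            # Sway-area shrink of 10**(-effect) <=> SD scale 10**(-effect/2).
            scale = 10.0 ** (-config.ips_effect / 2.0) if (treated and post) else 1.0
            sd = config.cop_noise_sd * sway_mult * scale
            for pos in POSITIONS:
                samples = _ou_trial(
                    rng, centers[pos], sd, config.cop_ou_theta, n, dt
                )
                trials.append(
                    CopTrial(
                        participant=pid,
                        group=group,
                        time=time,
                        position=pos,
                        samples=samples,
                        rate=config.cop_rate,
                    )
                )
    return trials


# -- body-part code tables ----------------------------------------------------


def gen_code_table(config: SimConfig) -> pd.DataFrame:
    """Binary participant-document x code presence table.

    One row per participant per interview time; one 0/1 column per code,
    independent Bernoulli draws with the configured probabilities.
    """
    config._validate_code_probs()
    rng = _rng(config, _STREAM_CODE)
    codes = list(config.code_probs)
    rows = []
    for pid, group in config.participants():
        for time in config.code_time_points:
            draws = [
                int(rng.random() < config.code_probs[c][group][time]) for c in codes
            ]
            rows.append([pid, group, time, *draws])
    return pd.DataFrame(rows, columns=["participant", "group", "time", *codes])


# -- ROI time series ----------------------------------------------------------


def _block_correlation(config: SimConfig) -> np.ndarray:
    labels = config.roi_labels
    net = [config.roi_network_map[r] for r in labels]
    p = len(labels)
    sigma = np.full((p, p), config.fc_base_between)
    for i in range(p):
        for j in range(p):
            if net[i] == net[j]:
                sigma[i, j] = config.fc_base_within
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _planted_correlation(config: SimConfig) -> np.ndarray:
    sigma = _block_correlation(config)
    idx = {r: i for i, r in enumerate(config.roi_labels)}
    for a, b in config.planted_edges:
        i, j = idx[a], idx[b]
        sigma[i, j] += config.planted_delta_r
        sigma[j, i] = sigma[i, j]
    return sigma


def _checked_cholesky(sigma: np.ndarray, context: str) -> np.ndarray:
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] <= 1e-10:
        raise ConfigError(
            f"{context}: implied covariance is not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.3e})"
        )
    return np.linalg.cholesky(sigma)


def _mvn_ar1(
    rng: np.random.Generator, chol: np.ndarray, n_t: int, phi: float
) -> np.ndarray:
    """(p, n_t) series with lag-0 covariance chol@chol.T and AR(1) smoothing.

    y_t = phi*y_{t-1} + sqrt(1-phi^2)*x_t with x_t iid MVN leaves the
    instantaneous covariance unchanged, so the block structure survives
    the temporal smoothing exactly.
    """
    p = chol.shape[0]
    x = chol @ rng.standard_normal((p, n_t))
    if phi == 0.0:
        return x
    y = np.empty_like(x)
    y[:, 0] = x[:, 0]
    c = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_t):
        y[:, t] = phi * y[:, t - 1] + c * x[:, t]
    return y


def gen_roi_timeseries(
    config: SimConfig, n_volumes: int | None = None
) -> list[RoiTimeSeries]:
    """ROI x time series for every participant x imaging session.

    ``n_volumes`` overrides the configured length (used by oversampled
    correlation checks).
    """
    n_t = int(n_volumes or config.n_volumes)
    base = _block_correlation(config)
    planted = _planted_correlation(config)
    chol_base = _checked_cholesky(base, "baseline block covariance")
    chol_planted = _checked_cholesky(planted, "planted-effect covariance")
    rng = _rng(config, _STREAM_ROI)
    labels = config.roi_labels
    out = []
    for pid, group in config.participants():
        treated = group == config.treated_group
        for session in config.fc_time_points:
            post = session != config.fc_time_points[0]
            chol = chol_planted if (treated and post) else chol_base
            data = _mvn_ar1(rng, chol, n_t, config.ar_coef)
            out.append(
                RoiTimeSeries(
                    participant=pid,
                    group=group,
                    session=session,
                    data=data,
                    roi_labels=labels,
                )
            )
    return out


# -- whole study --------------------------------------------------------------


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate all three modalities plus the planted-effect truth record."""
    return SyntheticStudy(
        config=config,
        cop_trials=gen_cop_session(config),
        code_table=gen_code_table(config),
        roi_series=gen_roi_timeseries(config),
        truth=StudyTruth(
            ips_effect=config.ips_effect,
            planted_edges=config.planted_edges,
            planted_delta_r=config.planted_delta_r,
            code_probs=config.code_probs,
        ),
    )


# -- tabular writers ----------------------------------------------------------


def write_cop_table(trials: list[CopTrial], path) -> None:
    frames = []
    for t in trials:
        n = len(t.samples)
        frames.append(
            pd.DataFrame(
                {
                    "participant": t.participant,
                    "group": t.group,
                    "time": t.time,
                    "position": t.position,
                    "sample_index": np.arange(n),
                    "ap_cm": t.samples[:, 0],
                    "ml_cm": t.samples[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_code_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_roi_series(series: list[RoiTimeSeries], out_dir) -> None:
    """One matrix file per participant x session, plus an ROI -> network map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net_map = {r: n for n, rois in ROI_NETWORKS.items() for r in rois}
    for s in series:
        df = pd.DataFrame(
            s.data, index=pd.Index(s.roi_labels, name="roi"),
            columns=[f"v{i:03d}" for i in range(s.data.shape[1])],
        )
        df.insert(0, "group", s.group)
        df.to_csv(out / f"roi_{s.participant}_{s.session}.csv")
    pd.DataFrame(
        {"roi": list(net_map), "network": list(net_map.values())}
    ).to_csv(out / "roi_networks.csv", index=False)
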