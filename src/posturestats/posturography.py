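"""Posturographic sway metrics and the Index of Postural Stability (IPS).

A stabilometer records the center of pressure (COP) as a 2-D trajectory
(anteroposterior, mediolateral; cm) at a fixed sampling rate. A session
comprises five 10-s trials: quiet stance at center, plus maximal weight
shifts toward the anterior, posterior, right and left limits of the base of
support. Two areas summarize the session:

* **postural sway area** — for each trial, the rectangle spanned by the
  trajectory's AP and ML extremes; the session value is the mean of the
  five per-position rectangles (cm^2);
* **area of stability limit** — the rectangle spanned by the centers of
  sway of the four directional trials (cm^2).

The IPS combines them on a log scale::

    IPS = log10((limit_area + sway_area) / sway_area)

Higher IPS means a larger usable stability region relative to spontaneous
sway, i.e. better postural stability. Healthy young adults score near 1.7.
Individual change scores (dIPS) are compared against a minimal detectable
change threshold (MDC95 = 0.26) to separate real change from measurement
error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POSITIONS",
    "DIRECTIONAL_POSITIONS",
    "DEFAULT_MDC95",
    "AREA_EPSILON",
    "CopTrial",
    "IpsRecord",
    "ChangeRecord",
    "sway_rectangle_area",
    "postural_sway_area",
    "stability_limit_area",
    "compute_ips",
    "ips_records",
    "ips_changes",
    "IpsScorer",
    "read_cop_table",
    "cop_trials_from_frame",
]

#: The five stance positions of a measurement session.
POSITIONS = ("center", "anterior", "posterior", "right", "left")

#: The four maximal-weight-shift positions defining the stability limit.
DIRECTIONAL_POSITIONS = ("anterior", "posterior", "right", "left")

#: Minimal detectable change (95% confidence) for the IPS in young healthy
#: adults, used as the default individual-change threshold.
DEFAULT_MDC95 = 0.26

#: Floor for degenerate (constant-trajectory) sway rectangles, cm^2.
AREA_EPSILON = 1e-6

#: Change-score contrasts among the three behavioral time points.
CONTRASTS = (("T1", "T0"), ("T2", "T0"), ("T2", "T1"))


class InsufficientDataError(ValueError):
    """Raised when a trial has too few samples for an area."""


class TrialLayoutError(ValueError):
    """Raised when a session is missing or duplicating a stance position."""


@dataclass(frozen=True)
class CopTrial:
    """One COP recording: a stance position held for ~10 s at ``rate`` Hz.

    ``samples`` is an (n, 2) array of (AP, ML) coordinates in cm; AP is
    positive anterior, ML positive right.
    """

    participant: str
    group: str
    time: str
    position: str
    samples: np.ndarray
    rate: float = 20.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("samples must be an (n, 2) array of (ap, ml) cm")
        if arr.shape[0] < 2:
            raise InsufficientDataError(
                f"trial {self.participant}/{self.time}/{self.position}: "
                f"needs >= 2 samples, got {arr.shape[0]}"
            )
        if not np.isfinite(arr).all():
            raise ValueError("samples contain missing/non-finite coordinates")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def center_of_sway(self) -> tuple[float, float]:
        """Mean (AP, ML) of the trajectory, cm."""
        ap, ml = self.samples.mean(axis=0)
        return float(ap), float(ml)


@dataclass(frozen=True)
class IpsRecord:
    """Per participant x time IPS value and its component areas."""

    participant: str
    group: str
    time: str
    sway_area: float  # cm^2
    limit_area: float  # cm^2
    ips: float  # dimensionless

    def __post_init__(self) -> None:
        if self.sway_area <= 0:
            raise ValueError("sway_area must be positive")
        if self.limit_area < 0:
            raise ValueError("limit_area must be non-negative")


@dataclass(frozen=True)
class ChangeRecord:
    """Per participant IPS change score for one time contrast."""

    participant: str
    group: str
    contrast: str  # e.g. "T1-T0"
    delta_ips: float
    exceeds_mdc: bool


def sway_rectangle_area(trial: CopTrial) -> float:
    """Rectangle area (cm^2) spanned by the AP and ML extremes of a trial.

    Degenerate (constant) trajectories are floored at ``AREA_EPSILON`` with
    a warning so the downstream log ratio stays finite.
    """
    ap = trial.samples[:, 0]
    ml = trial.samples[:, 1]
    area = float((ap.max() - ap.min()) * (ml.max() - ml.min()))
    if area < AREA_EPSILON:
        warnings.warn(
            f"degenerate COP trajectory for {trial.participant}/"
            f"{trial.time}/{trial.position}; flooring sway rectangle at "
            f"{AREA_EPSILON} cm^2",
            stacklevel=2,
        )
        return AREA_EPSILON
    return area


def _by_position(trials: Iterable[CopTrial], required: Sequence[str]) -> dict[str, CopTrial]:
    out: dict[str, CopTrial] = {}
    for t in trials:
        if t.position in out:
            raise TrialLayoutError(f"duplicate trial for position {t.position!r}")
        out[t.position] = t
    missing = [p for p in required if p not in out]
    if missing:
        raise TrialLayoutError(f"missing trial(s) for position(s) {missing}")
    extra = [p for p in out if p not in required]
    if extra:
        raise TrialLayoutError(f"unexpected position(s) {extra}")
    return out

def postural_sway_area(trials: Iterable[CopTrial]) -> float:
    """Mean of the five per-position sway rectangles (cm^2)."""
    by_pos = _by_position(trials, POSITIONS)
    return float(np.mean([sway_rectangle_area(by_pos[p]) for p in POSITIONS]))


def stability_limit_area(trials: Iterable[CopTrial]) -> float:
    """Rectangle (cm^2) spanned by the four directional centers of sway.

    The AP side is the distance between the anterior and posterior trial
    centers; the ML side between the right and left trial centers.
    """
    by_pos = _by_position(trials, DIRECTIONAL_POSITIONS)
    ap_side = abs(
        by_pos["anterior"].center_of_sway[0] - by_pos["posterior"].center_of_sway[0]
    )
    ml_side = abs(by_pos["right"].center_of_sway[1] - by_pos["left"].center_of_sway[1])
    return float(ap_side * ml_side)


def compute_ips(limit_area: float, sway_area: float) -> float:
    """IPS = log10((limit_area + sway_area) / sway_area).

    Strictly increasing in ``limit_area`` and decreasing in ``sway_area``;
    zero when the stability limit collapses to a point; invariant under a
    common rescaling of both areas.
    """
    if sway_area <= 0:
        raise ValueError(f"sway_area must be positive, got {sway_area}")
    if limit_area < 0:
        raise ValueError(f"limit_area must be non-negative, got {limit_area}")
    return float(np.log10((limit_area + sway_area) / sway_area))


def _score_session(trials: Sequence[CopTrial]) -> IpsRecord:
    by_pos = _by_position(trials, POSITIONS)
    sway = postural_sway_area(by_pos.values())
    limit = stability_limit_area(by_pos[p] for p in DIRECTIONAL_POSITIONS)
    first = trials[0]
    return IpsRecord(
        participant=first.participant,
        group=first.group,
        time=first.time,
        sway_area=sway,
        limit_area=limit,
        ips=compute_ips(limit, sway),
    )


def ips_records(trials: Iterable[CopTrial]) -> pd.DataFrame:
    """Score every (participant, time) session found in ``trials``.

    Returns a tidy frame with columns participant, group, time, sway_area,
    limit_area, ips.
    """
    sessions: dict[tuple[str, str], list[CopTrial]] = {}
    for t in trials:
        sessions.setdefault((t.participant, t.time), []).append(t)
    rows = []
    for (pid, time), sess in sorted(sessions.items()):
        rec = _score_session(sess)
        rows.append(
            (rec.participant, rec.group, rec.time, rec.sway_area, rec.limit_area, rec.ips)
        )
    return pd.DataFrame(
        rows, columns=["participant", "group", "time", "sway_area", "limit_area", "ips"]
    )


def ips_changes(
    records: pd.DataFrame,
    mdc: float = DEFAULT_MDC95,
    contrasts: Sequence[tuple[str, str]] = CONTRASTS,
) -> pd.DataFrame:
    """Per-participant IPS change scores with the MDC95 exceedance flag.

    ``records`` is an ips_records-style frame. Each contrast (later, earlier)
    yields delta_ips = ips(later) - ips(earlier); exceeds_mdc is True when
    delta_ips > mdc.
    """
    wide = records.pivot_table(index=["participant", "group"], columns="time", values="ips")
    needed = sorted({t for pair in contrasts for t in pair})
    wide = wide.reindex(columns=needed)
    missing = wide.isna().any(axis=1)
    if missing.any():
        bad = list(wide.index[missing].get_level_values("participant"))
        raise ValueError(f"participants missing required time points: {bad}")
    rows = []
    for (pid, group), row in wide.iterrows():
        for later, earlier in contrasts:
            d = float(row[later] - row[earlier])
            rows.append((pid, group, f"{later}-{earlier}", d, d > mdc))
    return pd.DataFrame(
        rows, columns=["participant", "group", "contrast", "delta_ips", "exceeds_mdc"]
    )


class IpsScorer:
    """Transformer from raw COP trials to IPS and change-score tables.

    Parameters
    ----------
    mdc : float
        Minimal-detectable-change threshold applied to individual change
        scores (default 0.26).

    After :meth:`fit`, exposes ``records_`` (participant x time IPS table)
    and ``changes_`` (per-contrast change scores).
    """

    def __init__(self, mdc: float = DEFAULT_MDC95):
        self.mdc = mdc

    def get_params(self, deep: bool = True) -> dict:
        return {"mdc": self.mdc}

    def set_params(self, **params) -> "IpsScorer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trials: Iterable[CopTrial]) -> "IpsScorer":
        self.records_ = ips_records(trials)
        times = set(self.records_["time"])
        usable = [c for c in CONTRASTS if set(c) <= times]
        self.changes_ = ips_changes(self.records_, mdc=self.mdc, contrasts=usable)
        return self

    def transform(self, trials: Iterable[CopTrial]) -> pd.DataFrame:
        return ips_records(trials)

    def fit_transform(self, trials: Iterable[CopTrial]) -> pd.DataFrame:
        return self.fit(trials).records_


# -- tabular I/O --------------------------------------------------------------

COP_COLUMNS = ["participant", "group", "time", "position", "sample_index", "ap_cm", "ml_cm"]


def cop_trials_from_frame(frame: pd.DataFrame, rate: float = 20.0) -> list[CopTrial]:
    """Reassemble CopTrial objects from a long tabular COP recording."""
    missing = [c for c in COP_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"COP table missing columns {missing}")
    trials = []
    keys = ["participant", "group", "time", "position"]
    for (pid, group, time, pos), g in frame.groupby(keys, sort=True):
        g = g.sort_values("sample_index")
        trials.append(
            CopTrial(
                participant=str(pid),
                group=str(group),
                time=str(time),
                position=str(pos),
                samples=g[["ap_cm", "ml_cm"]].to_numpy(float),
                rate=rate,
            )
        )
    return trials


def read_cop_table(path) -> list[CopTrial]:
    """Read COP trials from the tabular text format written by the generator."""
    return cop_trials_from_frame(pd.read_csv(path))
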