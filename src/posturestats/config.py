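"""Study-level simulation configuration.

:class:`SimConfig` freezes every parameter of the synthetic study: sample
sizes, the center-of-pressure (COP) sway model, planted behavioral and
connectivity effects, per-code report probabilities, and the seed. The
defaults describe a two-arm postural-training study — a treated arm (SDE,
sensory discrimination with attentional expansion, n = 25) and an active
control (SDO, sensory discrimination only, n = 23) — measured at baseline
(T0), immediately post-training (T1) and 30 min post-training (T2) for
behavior, and at T0/T1 for resting-state imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import yaml

__all__ = ["SimConfig", "DEFAULT_CODE_PROBS", "ROI_NETWORKS", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete simulation configuration."""


#: Per-code Bernoulli probability of a participant mentioning the body part,
#: by group and time. Values are the observed per-condition report
#: proportions of the study the generator emulates.
DEFAULT_CODE_PROBS: dict[str, dict[str, dict[str, float]]] = {
    "Foot": {"SDE": {"T0": 1.00, "T1": 0.96}, "SDO": {"T0": 0.957, "T1": 0.870}},
    "Lower limb (non-foot)": {
        "SDE": {"T0": 0.28, "T1": 0.48},
        "SDO": {"T0": 0.130, "T1": 0.217},
    },
    "Shoulder": {"SDE": {"T0": 0.00, "T1": 0.80}, "SDO": {"T0": 0.087, "T1": 0.130}},
    "Lumbopelvic region": {
        "SDE": {"T0": 0.36, "T1": 0.56},
        "SDO": {"T0": 0.304, "T1": 0.217},
    },
    "Trunk": {"SDE": {"T0": 0.88, "T1": 0.88}, "SDO": {"T0": 0.826, "T1": 0.652}},
}

#: 18-ROI parcellation grouped into four large-scale networks: salience
#: (SN, 7 ROIs), frontoparietal (FPN, 4), default mode (DMN, 4) and
#: sensorimotor (SMN, 3). Labels follow the CONN default atlas naming.
ROI_NETWORKS: dict[str, tuple[str, ...]] = {
    "SN": (
        "ACC",
        "AInsula (L)",
        "AInsula (R)",
        "RPFC (L)",
        "RPFC (R)",
        "SMG (L)",
        "SMG (R)",
    ),
    "FPN": ("LPFC (L)", "LPFC (R)", "PPC (L)", "PPC (R)"),
    "DMN": ("MPFC", "LP (L)", "LP (R)", "PCC"),
    "SMN": ("SMN Lateral (L)", "SMN Lateral (R)", "SMN Superior"),
}


def _roi_labels() -> tuple[str, ...]:
    return tuple(r for rois in ROI_NETWORKS.values() for r in rois)


@dataclass
class SimConfig:
    """All knobs of the synthetic study.

    Parameters
    ----------
    n_per_group : (int, int)
        Sample sizes (treated, control); defaults (25, 23). An int applies
        to both arms.
    groups : (str, str)
        Labels (treated, control); defaults ("SDE", "SDO").
    time_points : sequence of str
        Behavioral sessions; imaging uses ``fc_time_points``.
    cop_noise_sd : float, cm
        Stationary SD of the Ornstein-Uhlenbeck COP sway per axis. The
        default is calibrated so the baseline IPS distribution is centered
        near 1.7 with between-subject SD near 0.2.
    cop_ou_theta : float, 1/s
        Mean-reversion rate of the sway process.
    stance_limit_ap, stance_limit_ml : float, cm
        Population-typical stability-limit extents (anteroposterior,
        mediolateral). Participant-specific limits are log-normal around
        these.
    limit_sigma, sway_sigma : float
        SDs, on the natural-log scale, of participant-specific multipliers
        on the stability limits and on the sway SD; together they set the
        between-subject spread of IPS.
    ips_effect : float
        Additive IPS shift planted in the treated arm at the post-training
        time points (sway noise is scaled by 10**(-effect/2) so the sway
        area shrinks by 10**(-effect)).
    code_probs : mapping
        code -> group -> time -> Bernoulli probability of a participant's
        transcript containing that body-part code.
    fc_base_within, fc_base_between : float
        Baseline ROI-ROI correlation inside / across network blocks.
    planted_edges : sequence of (str, str)
        ROI label pairs whose coupling changes in the treated arm at T1.
    planted_delta_r : float
        Correlation change applied to the planted edges.
    n_volumes : int
        Usable fMRI volumes per session (240 acquired, first 4 discarded).
    ar_coef : float
        AR(1) smoothing coefficient emulating band-limited BOLD signal.
    seed : int
        Master seed; every generator output is a pure function of
        (config, seed).
    """

    n_per_group: tuple[int, int] = (25, 23)
    groups: tuple[str, str] = ("SDE", "SDO")
    time_points: tuple[str, ...] = ("T0", "T1", "T2")
    fc_time_points: tuple[str, ...] = ("T0", "T1")
    code_time_points: tuple[str, ...] = ("T0", "T1")
    cop_rate: float = 20.0  # Hz
    cop_duration: float = 10.0  # s
    cop_noise_sd: float = 0.31  # cm, stationary per-axis sway SD
    cop_ou_theta: float = 1.0  # 1/s
    stance_limit_ap: float = 10.0  # cm
    stance_limit_ml: float = 8.0  # cm
    limit_sigma: float = 0.25
    sway_sigma: float = 0.15
    ips_effect: float = 0.09
    code_probs: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: DEFAULT_CODE_PROBS
    )
    fc_base_within: float = 0.3
    fc_base_between: float = 0.1
    planted_edges: tuple[tuple[str, str], ...] = (
        ("AInsula (R)", "SMG (R)"),
        ("AInsula (L)", "SMG (R)"),
    )
    planted_delta_r: float = -0.2
    n_volumes: int = 236
    ar_coef: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = (self.n_per_group, self.n_per_group)
        self.n_per_group = tuple(int(n) for n in self.n_per_group)
        self.groups = tuple(self.groups)
        self.time_points = tuple(self.time_points)
        self.fc_time_points = tuple(self.fc_time_points)
        self.code_time_points = tuple(self.code_time_points)
        self.planted_edges = tuple(tuple(e) for e in self.planted_edges)
        self.validate()

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        if len(self.groups) != 2 or len(set(self.groups)) != 2:
            raise ConfigError("groups must be two distinct labels")
        if any(n < 2 for n in self.n_per_group):
            raise ConfigError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if self.cop_noise_sd < 0:
            raise ConfigError("cop_noise_sd must be non-negative")
        if self.cop_ou_theta <= 0:
            raise ConfigError("cop_ou_theta must be positive")
        if self.cop_rate <= 0 or self.cop_duration <= 0:
            raise ConfigError("cop_rate and cop_duration must be positive")
        if min(self.stance_limit_ap, self.stance_limit_ml) <= 0:
            raise ConfigError("stance limits must be positive")
        for r, name in (
            (self.fc_base_within, "fc_base_within"),
            (self.fc_base_between, "fc_base_between"),
        ):
            if not abs(r) < 1:
                raise ConfigError(f"|{name}| must be < 1, got {r}")
        if not abs(self.planted_delta_r) < 2:
            raise ConfigError("planted_delta_r out of range")
        roi_set = set(_roi_labels())
        for a, b in self.planted_edges:
            if a not in roi_set or b not in roi_set:
                raise ConfigError(f"planted edge ({a!r}, {b!r}) names unknown ROI(s)")
            if a == b:
                raise ConfigError("planted edge must join two distinct ROIs")
        if self.n_volumes < 10:
            raise ConfigError("n_volumes must be >= 10")
        if not 0 <= self.ar_coef < 1:
            raise ConfigError("ar_coef must be in [0, 1)")
        self._validate_code_probs()

    def _validate_code_probs(self) -> None:
        for code, by_group in self.code_probs.items():
            for g in self.groups:
                if g not in by_group:
                    raise ConfigError(f"code_probs[{code!r}] missing group {g!r}")
                for t in self.code_time_points:
                    if t not in by_group[g]:
                        raise ConfigError(
                            f"code_probs[{code!r}][{g!r}] missing time {t!r}"
                        )
                    p = by_group[g][t]
                    if not 0 <= p <= 1:
                        raise ConfigError(
                            f"code_probs[{code!r}][{g!r}][{t!r}] = {p} not in [0, 1]"
                        )

    # -- convenience ----------------------------------------------------------

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return _roi_labels()

    @property
    def roi_network_map(self) -> dict[str, str]:
        return {r: net for net, rois in ROI_NETWORKS.items() for r in rois}

    @property
    def treated_group(self) -> str:
        return self.groups[0]

    def participants(self) -> list[tuple[str, str]]:
        """(participant_id, group) pairs, treated arm first."""
        out = []
        for g, n in zip(self.groups, self.n_per_group):
            out.extend((f"{g}{i + 1:02d}", g) for i in range(n))
        return out

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["code_probs"] = {
            c: {g: dict(t) for g, t in bg.items()} for c, bg in self.code_probs.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        # YAML round-trips tuples as lists; from_dict re-tuples them.
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
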