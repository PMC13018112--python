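"""Body-part coding of interview transcripts and contingency statistics.

Participants describe their postural-control strategy in a short interview
at T0 and T1. Each transcript (one document per participant per time) is
coded for the presence of five body-part categories — Foot, Lower limb
(non-foot), Shoulder, Lumbopelvic region, Trunk — via a term-list codebook:
a code is present (1) when any of its terms occurs at least once as an
exact token or contiguous phrase, case-insensitively.

The presence counts are cross-tabulated as 5 codes x 4 (group x time)
conditions and analyzed with Pearson's chi-square (no continuity
correction), Cramer's V, and Haberman adjusted standardized residuals

    z_ij = (O_ij - E_ij) / sqrt(E_ij (1 - rowsum_i/N)(1 - colsum_j/N)),

which are approximately standard normal under independence; |z| >= 1.96
flags over/under-represented cells. Because one participant can carry
several codes, the grid treats code-presences as the counting unit
(multi-response data); within-participant dependence between codes is a
known caveat of this convention, not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "Codebook",
    "default_codebook",
    "apply_codebook",
    "build_contingency",
    "chi_square_test",
    "adjusted_residuals",
    "sentence_level_summary",
    "CodeContingency",
    "ContingencyResult",
]

RESIDUAL_FLAG_Z = 1.96


@dataclass(frozen=True)
class Codebook:
    """code name -> list of terms (single tokens or multi-token phrases)."""

    codes: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        norm = {}
        for code, terms in self.codes.items():
            cleaned = tuple(dict.fromkeys(t.strip().lower() for t in terms if t.strip()))
            if not cleaned:
                raise ValueError(f"code {code!r} has no terms")
            norm[code] = cleaned
        object.__setattr__(self, "codes", norm)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def default_codebook() -> Codebook:
    """The packaged five-code body-part codebook (English term lists)."""
    ref = resources.files("posturestats.data") / "codebook.yaml"
    return Codebook(yaml.safe_load(ref.read_text()))


def _phrase_in(tokens: list[str], phrase: list[str]) -> bool:
    k = len(phrase)
    return any(tokens[i : i + k] == phrase for i in range(len(tokens) - k + 1))


def _presence_vector(tokens: Sequence[str], codebook: Codebook) -> dict[str, int]:
    toks = [t.lower() for t in tokens]
    out = {}
    for code, terms in codebook.codes.items():
        hit = False
        for term in terms:
            phrase = term.split()
            if (phrase[0] in toks) if len(phrase) == 1 else _phrase_in(toks, phrase):
                hit = True
                break
        out[code] = int(hit)
    return out


def apply_codebook(
    documents: Mapping, codebook: Codebook
) -> pd.DataFrame:
    """Binary presence table from tokenized documents.

    ``documents`` maps (participant, group, time) -> token sequence.
    Presence is 1 iff any codebook term occurs at least once in the
    document (exact token or contiguous phrase, case-insensitive).
    """
    if not documents:
        raise ValueError("empty document set")
    rows = []
    for (pid, group, time), tokens in documents.items():
        pres = _presence_vector(list(tokens), codebook)
        rows.append({"participant": pid, "group": group, "time": time, **pres})
    return pd.DataFrame(rows)


def build_contingency(
    table: pd.DataFrame,
    groups: Sequence[str] = ("SDE", "SDO"),
    times: Sequence[str] = ("T0", "T1"),
) -> pd.DataFrame:
    """Codes x (group, time) participant-presence counts.

    Cell = number of participants in that condition whose document carries
    the code. Participants may contribute to several code rows
    (multi-response), so the grand total is the total number of
    code-presences, not of participants.
    """
    codes = [c for c in table.columns if c not in ("participant", "group", "time")]
    bad_g = set(table["group"]) - set(groups)
    bad_t = set(table["time"]) - set(times)
    if bad_g or bad_t:
        raise ValueError(f"unknown group/time label(s): {sorted(bad_g | bad_t)}")
    vals = table[codes]
    if not vals.isin([0, 1]).all().all():
        raise ValueError("presence table must be binary 0/1")
    cols = pd.MultiIndex.from_product([groups, times], names=["group", "time"])
    out = pd.DataFrame(0, index=pd.Index(codes, name="code"), columns=cols)
    for (g, t), sub in table.groupby(["group", "time"]):
        out.loc[:, (g, t)] = sub[codes].sum().to_numpy()
    return out


@dataclass(frozen=True)
class ContingencyResult:
    counts: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    cramers_v: float
    residuals: pd.DataFrame  # adjusted standardized residuals z
    residual_p: pd.DataFrame  # two-sided normal p per cell
    flags: pd.DataFrame  # |z| >= 1.96


def _expected(counts: np.ndarray) -> np.ndarray:
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    n = counts.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate margin: zero row or column sum")
    return row * col / n


def chi_square_test(counts: pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square on an r x c count table, with Cramer's V and
    Haberman adjusted standardized residuals."""
    obs = np.asarray(counts, dtype=float)
    exp = _expected(obs)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(chi2, df))
    n = obs.sum()
    v = float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
    z = adjusted_residuals(counts)
    zp = pd.DataFrame(
        2.0 * stats.norm.sf(np.abs(z.to_numpy())), index=z.index, columns=z.columns
    )
    return ContingencyResult(
        counts=counts,
        expected=pd.DataFrame(exp, index=counts.index, columns=counts.columns),
        chi2=chi2,
        df=df,
        p=p,
        cramers_v=v,
        residuals=z,
        residual_p=zp,
        flags=z.abs() >= RESIDUAL_FLAG_Z,
    )


def adjusted_residuals(counts: pd.DataFrame) -> pd.DataFrame:
    """Haberman adjusted standardized residuals; NaN where a cell's
    variance term vanishes."""
    obs = np.asarray(counts, dtype=float)
    exp = _expected(obs)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    var = exp * (1.0 - row / n) * (1.0 - col / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (obs - exp) / np.sqrt(var), np.nan)
    return pd.DataFrame(z, index=counts.index, columns=counts.columns)


def sentence_level_summary(
    sentences: Mapping, codebook: Codebook
) -> pd.DataFrame:
    """Descriptive sentence-level code frequency per condition.

    ``sentences`` maps (group, time) -> iterable of token sequences (one
    per sentence). Returns, per condition x code, the number and
    percentage of sentences containing the code. Sentences can carry
    several codes, so percentages may sum above 100. Purely descriptive;
    no test is attached. Percentage is NaN for an empty condition.
    """
    rows = []
    for (group, time), sents in sentences.items():
        sents = [list(s) for s in sents]
        n_sent = len(sents)
        hits = {c: 0 for c in codebook.codes}
        for s in sents:
            for code, present in _presence_vector(s, codebook).items():
                hits[code] += present
        for code, h in hits.items():
            rows.append(
                {
                    "group": group,
                    "time": time,
                    "code": code,
                    "n_sentences": n_sent,
                    "n_with_code": h,
                    "pct": 100.0 * h / n_sent if n_sent else np.nan,
                }
            )
    return pd.DataFrame(rows)


class CodeContingency:
    """Contingency-statistics estimator over a binary code-presence table.

    fit() cross-tabulates code presences by group x time and computes the
    omnibus chi-square, Cramer's V, and cell-level adjusted standardized
    residuals.

    Fitted attributes: ``counts_``, ``expected_``, ``chi2_``, ``df_``,
    ``p_``, ``cramers_v_``, ``residuals_``, ``residual_p_``, ``flags_``,
    ``result_``.
    """

    def __init__(
        self,
        groups: Sequence[str] = ("SDE", "SDO"),
        times: Sequence[str] = ("T0", "T1"),
        flag_z: float = RESIDUAL_FLAG_Z,
    ):
        self.groups = tuple(groups)
        self.times = tuple(times)
        self.flag_z = flag_z

    def get_params(self, deep: bool = True) -> dict:
        return {"groups": self.groups, "times": self.times, "flag_z": self.flag_z}

    def set_params(self, **params) -> "CodeContingency":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, presence_table: pd.DataFrame) -> "CodeContingency":
        counts = build_contingency(presence_table, self.groups, self.times)
        if (counts.to_numpy() == 0).all():
            raise ValueError("all-zero contingency table; nothing to test")
        return self.fit_counts(counts)

    def fit_counts(self, counts: pd.DataFrame) -> "CodeContingency":
        """Fit directly from a pre-tabulated count matrix."""
        res = chi_square_test(counts)
        self.result_ = res
        self.counts_ = res.counts
        self.expected_ = res.expected
        self.chi2_ = res.chi2
        self.df_ = res.df
        self.p_ = res.p
        self.cramers_v_ = res.cramers_v
        self.residuals_ = res.residuals
        self.residual_p_ = res.residual_p
        self.flags_ = res.residuals.abs() >= self.flag_z
        return self
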