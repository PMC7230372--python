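"""Rank-agreement statistics for comparing two prioritization settings.

The causal-variant rank of each patient is categorized into five mutually
exclusive bins (Top, 2-5, 6-10, >10, Filtered out/Not prioritized).  Paired
settings are compared through a square contingency table over those bins:
percentage agreement and Cohen's kappa (with the Landis-Koch verbal bands),
the Stuart-Maxwell chi-square test of marginal homogeneity, and the
Wilcoxon signed-rank test on the numeric rank pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "FILTERED_OUT",
    "NOT_PRIORITIZED",
    "RankOutcome",
    "RankBin",
    "ContingencyTable",
    "assign_bin",
    "summarize_ranks",
    "cohens_kappa",
    "landis_koch_label",
    "stuart_maxwell",
    "wilcoxon_signed_rank",
    "compare_settings",
    "read_rank_outcomes",
    "write_rank_outcomes",
]

FILTERED_OUT = "FILTERED_OUT"
NOT_PRIORITIZED = "NOT_PRIORITIZED"


@dataclass(frozen=True)
class RankOutcome:
    """Rank of the correct diagnosed variant(s) for one patient, or a sentinel."""

    patient_id: str
    rank: float | None = None
    sentinel: str | None = None
    gene_rank_if_not_prioritized: float | None = None

    def __post_init__(self) -> None:
        if (self.rank is None) == (self.sentinel is None):
            raise ValueError("exactly one of rank / sentinel must be set")
        if self.sentinel is not None and self.sentinel not in (
            FILTERED_OUT,
            NOT_PRIORITIZED,
        ):
            raise ValueError(f"unknown sentinel: {self.sentinel}")
        if self.rank is not None and self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")


class RankBin(str, Enum):
    TOP = "Top"
    R2_5 = "2-5"
    R6_10 = "6-10"
    GT10 = ">10"
    FILTERED_OR_NOT_PRIORITIZED = "Filtered out/Not prioritized"


BIN_ORDER = tuple(RankBin)


def assign_bin(outcome: RankOutcome) -> RankBin:
    """Bin a rank outcome; tie-averaged ranks bin by numeric value, and the
    Top bin is reserved for rank exactly 1."""
    if outcome.sentinel is not None:
        return RankBin.FILTERED_OR_NOT_PRIORITIZED
    r = outcome.rank
    if r == 1:
        return RankBin.TOP
    if r <= 5:
        return RankBin.R2_5
    if r <= 10:
        return RankBin.R6_10
    return RankBin.GT10


def summarize_ranks(outcomes: Sequence[RankOutcome]) -> dict:
    """Cohort summary: rank statistics on the effective N (sentinels excluded)
    and top-k percentages over the full N."""
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    n = len(outcomes)
    numeric = np.array([o.rank for o in outcomes if o.rank is not None], dtype=float)
    n_sentinel = n - len(numeric)
    summary: dict = {
        "n": n,
        "n_effective": int(len(numeric)),
        "n_sentinel": int(n_sentinel),
        "top1_pct": 100.0 * float(np.sum(numeric == 1)) / n if len(numeric) else 0.0,
        "top5_pct": 100.0 * float(np.sum(numeric <= 5)) / n if len(numeric) else 0.0,
        "top10_pct": 100.0 * float(np.sum(numeric <= 10)) / n if len(numeric) else 0.0,
    }
    if len(numeric) == 0:
        summary.update(mean=None, sd=None, median=None, min=None, max=None)
        return summary
    summary.update(
        mean=float(numeric.mean()),
        sd=float(numeric.std(ddof=1)) if len(numeric) > 1 else 0.0,
        median=float(np.median(numeric)),
        min=float(numeric.min()),
        max=float(numeric.max()),
    )
    return summary


@dataclass(frozen=True)
class ContingencyTable:
    """Square labelled count table of paired categorical outcomes."""

    labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValueError("labels must be distinct")
        mat = np.asarray(self.counts)
        if mat.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (mat < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.astype(int), index=self.labels, columns=self.labels)


def cohens_kappa(table: ContingencyTable) -> dict:
    """Cohen's kappa with observed agreement and its Landis-Koch label.

    kappa = (Po - Pe) / (1 - Pe) with Po the diagonal mass and Pe the
    chance agreement from the marginals.
    """
    mat = table.matrix
    n = mat.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    po = np.trace(mat) / n
    pe = float(np.sum(mat.sum(axis=0) * mat.sum(axis=1)) / n**2)
    if pe == 1.0:
        if po == 1.0:
            kappa = 1.0
        else:
            raise ValueError("degenerate table: chance agreement is 1 but observed < 1")
    else:
        kappa = (po - pe) / (1.0 - pe)
    return {
        "kappa": float(kappa),
        "percent_agreement": float(100.0 * po),
        "label": landis_koch_label(kappa),
    }


def landis_koch_label(kappa: float) -> str:
    if kappa < 0.0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def stuart_maxwell(table: ContingencyTable) -> dict:
    """Stuart-Maxwell chi-square test of marginal homogeneity on a k x k table.

    Uses the first k-1 marginal differences d and their covariance S
    (S_ii = row_i + col_i - 2 t_ii, S_ij = -(t_ij + t_ji)); chi2 = d' S^- d
    with a Moore-Penrose generalized inverse and df = rank(S) when S is
    singular (zero-margin bins).
    """
    mat = table.matrix
    k = mat.shape[0]
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    d = (row - col)[: k - 1]
    if np.allclose(d, 0.0) and np.allclose(row, col):
        return {"chi2": 0.0, "df": k - 1, "p": 1.0}
    s = np.zeros((k - 1, k - 1))
    for i in range(k - 1):
        for j in range(k - 1):
            if i == j:
                s[i, j] = row[i] + col[i] - 2.0 * mat[i, i]
            else:
                s[i, j] = -(mat[i, j] + mat[j, i])
    rank = int(np.linalg.matrix_rank(s))
    sinv = np.linalg.pinv(s)
    chi2_stat = float(d @ sinv @ d)
    df = rank if rank > 0 else k - 1
    p = float(chi2.sf(chi2_stat, df))
    return {"chi2": chi2_stat, "df": df, "p": p}


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating the 2^n sign assignments.

    Implemented as a convolution over doubled (hence integral) midranks, so
    tied absolute differences are handled exactly.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_low = dist[: w2 + 1].sum()
    p_high = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    paired: Sequence[tuple[float, float]], exact_threshold: int = 25
) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; absolute differences receive midranks.
    The null distribution is enumerated exactly up to *exact_threshold*
    informative pairs, and approximated normally (with tie correction)
    beyond it.
    """
    a = np.array([p[0] for p in paired], dtype=float)
    b = np.array([p[1] for p in paired], dtype=float)
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return {"W": 0.0, "p": 1.0, "n": 0, "method": "degenerate"}
    ranks = rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        delta = w_plus - mean
        correction = 0.5 * np.sign(delta)  # continuity correction toward the mean
        z = (delta - correction) / math.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
        method = "normal"
    return {"W": w_plus, "p": min(p, 1.0), "n": n, "method": method}


def build_contingency(
    outcomes_a: Mapping[str, RankOutcome], outcomes_b: Mapping[str, RankOutcome]
) -> ContingencyTable:
    shared = sorted(set(outcomes_a) & set(outcomes_b))
    if not shared:
        raise ValueError("no overlapping patients between the two settings")
    index = {b: i for i, b in enumerate(BIN_ORDER)}
    mat = np.zeros((len(BIN_ORDER), len(BIN_ORDER)), dtype=int)
    for pid in shared:
        i = index[assign_bin(outcomes_a[pid])]
        j = index[assign_bin(outcomes_b[pid])]
        mat[i, j] += 1
    return ContingencyTable(
        labels=tuple(b.value for b in BIN_ORDER),
        counts=tuple(tuple(int(x) for x in row) for row in mat),
    )


def compare_settings(
    outcomes_a: Iterable[RankOutcome], outcomes_b: Iterable[RankOutcome]
) -> dict:
    """Full pairwise report for two settings over the same patients.

    Builds the 5x5 bin contingency table, computes agreement/kappa and the
    Stuart-Maxwell test on it, and runs the Wilcoxon signed-rank test on
    patients with numeric ranks under both settings.  Percent agreement is
    reported both over all shared patients and over the pairwise-numeric
    subset, since the two denominators differ whenever sentinels occur.
    """
    map_a = {o.patient_id: o for o in outcomes_a}
    map_b = {o.patient_id: o for o in outcomes_b}
    table = build_contingency(map_a, map_b)
    kappa = cohens_kappa(table)
    sm = stuart_maxwell(table)
    shared = sorted(set(map_a) & set(map_b))
    pairs = [
        (map_a[p].rank, map_b[p].rank)
        for p in shared
        if map_a[p].rank is not None and map_b[p].rank is not None
    ]
    wlx = wilcoxon_signed_rank(pairs) if pairs else {"W": 0.0, "p": 1.0, "n": 0}
    diag_effective = sum(
        1
        for p in shared
        if map_a[p].rank is not None
        and map_b[p].rank is not None
        and assign_bin(map_a[p]) == assign_bin(map_b[p])
    )
    return {
        "table": table,
        "kappa": kappa,
        "stuart_maxwell": sm,
        "wilcoxon": wlx,
        "n": table.n,
        "percent_agreement_full": kappa["percent_agreement"],
        "percent_agreement_effective": (
            100.0 * diag_effective / len(pairs) if pairs else float("nan")
        ),
    }


def write_rank_outcomes(outcomes: Sequence[RankOutcome], path) -> None:
    with open(path, "w") as fh:
        fh.write("PATIENT_ID\tRANK\tGENE_RANK_IF_NOT_PRIORITIZED\n")
        for o in outcomes:
            value = o.sentinel if o.sentinel is not None else f"{o.rank:g}"
            gr = (
                ""
                if o.gene_rank_if_not_prioritized is None
                else f"{o.gene_rank_if_not_prioritized:g}"
            )
            fh.write(f"{o.patient_id}\t{value}\t{gr}\n")


def read_rank_outcomes(path) -> list[RankOutcome]:
    outcomes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("PATIENT_ID"):
            raise ValueError("rank-outcome TSV must start with a PATIENT_ID header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pid, value = parts[0], parts[1]
            gr = float(parts[2]) if len(parts) > 2 and parts[2] else None
            if value in (FILTERED_OUT, NOT_PRIORITIZED):
                outcomes.append(
                    RankOutcome(pid, sentinel=value, gene_rank_if_not_prioritized=gr)
                )
            else:
                outcomes.append(RankOutcome(pid, rank=float(value)))
    return outcomes
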