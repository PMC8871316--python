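"""Ordinal agreement statistics: contingency tables and weighted Cohen's kappa.

Cross-classifies the same items under two raters (here: the measured-volume
and estimated-volume categorisations) and quantifies chance-corrected
agreement.  Weighted kappa gives partial credit to near-diagonal
disagreement:

    P_o = Σ w_ij n_ij / N
    P_e = Σ w_ij r_i c_j / N²
    κ   = (P_o − P_e) / (1 − P_e)

with r, c the row/column marginals and w the weight scheme.  Three schemes
are supported: ``unweighted`` (identity), ``linear``
(Cicchetti–Allison, w_ij = 1 − |i−j|/(k−1)) and ``quadratic``
(Fleiss–Cohen, w_ij = 1 − (|i−j|/(k−1))²).  Quadratic is the package
default: it is the scheme that reproduces the published agreement values
for these data (see the agreement tests, which confirm this by brute force
against all four published tables and against an independent
implementation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WEIGHT_SCHEMES",
    "DEFAULT_SCHEME",
    "ContingencyTable",
    "KappaResult",
    "build_table",
    "pairs_from_table",
    "weight_matrix",
    "weighted_kappa",
    "percent_agreement",
]

WEIGHT_SCHEMES = ("unweighted", "linear", "quadratic")
DEFAULT_SCHEME = "quadratic"


@dataclass(frozen=True)
class ContingencyTable:
    """k×k cross-classification of two ordinal raters over the same items.

    Rows are rater A (measured volume), columns rater B (estimated volume);
    ``labels`` gives the shared, identically ordered category list.
    """

    labels: tuple[str, ...]
    counts: np.ndarray  # (k, k) non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if k < 2:
            raise ValueError("need at least 2 categories")
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    # -- derived quantities -------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal_sum(self) -> int:
        return int(np.trace(self.counts))

    @property
    def off_diagonal_sum(self) -> int:
        return self.grand_total - self.diagonal_sum

    @property
    def above_diagonal_sum(self) -> int:
        """Items whose column (rater B) category exceeds their row category."""
        return int(np.triu(self.counts, k=1).sum())

    @property
    def below_diagonal_sum(self) -> int:
        return int(np.tril(self.counts, k=-1).sum())

    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.labels, self.counts.T.copy())

    # -- conversion ---------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ContingencyTable":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels must match and share order")
        return cls(tuple(str(x) for x in df.index), df.to_numpy())

    def write_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "category"
        df.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_dataframe(df)


@dataclass(frozen=True)
class KappaResult:
    """Weighted agreement under one weight scheme."""

    scheme: str
    observed_weighted_agreement: float  # P_o
    expected_weighted_agreement: float  # P_e
    kappa: float

    def rounded(self, ndigits: int = 2) -> float:
        """Kappa rounded half-up, the convention used in reports."""
        import decimal

        q = decimal.Decimal(10) ** -ndigits
        return float(
            decimal.Decimal(repr(self.kappa)).quantize(
                q, rounding=decimal.ROUND_HALF_UP
            )
        )


def build_table(
    pairs: Iterable[tuple[object, object]], labels: Sequence[object]
) -> ContingencyTable:
    """Tally (rater A, rater B) category pairs into a contingency table."""
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, b in pairs:
        try:
            counts[index[a], index[b]] += 1
        except KeyError as exc:
            raise ValueError(f"category {exc.args[0]!r} not in labels {labels}") from exc
    str_labels = tuple(getattr(lab, "label", None) or str(lab) for lab in labels)
    return ContingencyTable(str_labels, counts)


def pairs_from_table(table: ContingencyTable) -> list[tuple[str, str]]:
    """Expand a table back into one (row, column) label pair per item."""
    out: list[tuple[str, str]] = []
    for i, a in enumerate(table.labels):
        for j, b in enumerate(table.labels):
            out.extend([(a, b)] * int(table.counts[i, j]))
    return out


def weight_matrix(k: int, scheme: str = DEFAULT_SCHEME) -> np.ndarray:
    """Agreement weights w_ij ∈ [0, 1], symmetric with unit diagonal."""
    if k < 2:
        raise ValueError("k must be >= 2")
    i, j = np.indices((k, k))
    d = np.abs(i - j) / (k - 1)
    if scheme == "unweighted":
        return (i == j).astype(float)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise ValueError(f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")


def weighted_kappa(table: ContingencyTable, scheme: str = DEFAULT_SCHEME) -> KappaResult:
    """Weighted Cohen's kappa of a contingency table under one weight scheme.

    Raises if the table is empty or if chance agreement P_e = 1 (degenerate
    marginals concentrated in a single category), where kappa is undefined.
    """
    n = table.grand_total
    if n == 0:
        raise ValueError("empty table: kappa undefined")
    w = weight_matrix(table.k, scheme)
    counts = table.counts.astype(float)
    p_o = float((w * counts).sum() / n)
    expected = np.outer(table.row_marginals(), table.col_marginals()).astype(float)
    p_e = float((w * expected).sum() / n**2)
    if p_e >= 1.0:
        raise ZeroDivisionError(
            "degenerate marginals: expected agreement is 1, kappa undefined"
        )
    return KappaResult(scheme, p_o, p_e, (p_o - p_e) / (1.0 - p_e))


def percent_agreement(table: ContingencyTable) -> float:
    """Raw proportion of items on the diagonal (identical categories)."""
    n = table.grand_total
    if n == 0:
        raise ValueError("empty table: agreement undefined")
    return table.diagonal_sum / n
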