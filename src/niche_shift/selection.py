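"""Two-stage predictor screening for collinear bioclimatic variables.

Stage 1 (``prescreen``): after a preliminary model run on all candidates,
variables whose contribution rate is exactly zero are dropped.

Stage 2 (``select_variables``): Pearson correlations are computed between the
variables **at the (thinned) presence points** — the environments the model
actually contrasts — and pairs whose |r| exceeds the threshold (default 0.8)
are broken deterministically: offending pairs are processed in decreasing |r|
(ties by name order), and for each pair still wholly retained the member with
the lower contribution rate is dropped (ties: lower permutation importance,
then the larger bioclim index).  Pairs at exactly |r| = threshold are kept —
only strictly larger correlations are resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrelationMatrix", "VariableImportance", "pearson_r",
           "prescreen", "select_variables", "SelectionReport"]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises for constant or too-short vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return max(-1.0, min(1.0, r))


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over named variables."""

    variables: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variables)
        if self.r.shape != (n, n):
            raise ValueError("r must be square over the variables")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(self.r).max() > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "CorrelationMatrix":
        """Correlations between columns of a value table (e.g. presence extracts)."""
        names = list(values.columns)
        n = len(names)
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                r[i, j] = r[j, i] = pearson_r(values.iloc[:, i].to_numpy(),
                                              values.iloc[:, j].to_numpy())
        return cls(variables=names, r=r)

    def get(self, a: str, b: str) -> float:
        return float(self.r[self.variables.index(a), self.variables.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


@dataclass
class VariableImportance:
    """Per-variable contribution rate and permutation importance (each ~100%)."""

    table: pd.DataFrame  # index = variables; columns contribution_pct, permutation_pct

    def __post_init__(self) -> None:
        required = {"contribution_pct", "permutation_pct"}
        if not required <= set(self.table.columns):
            raise ValueError(f"importance table needs columns {sorted(required)}")
        if (self.table[list(required)] < -1e-9).any().any():
            raise ValueError("importance entries must be non-negative")

    @property
    def variables(self) -> list[str]:
        return list(self.table.index)

    def contribution(self, var: str) -> float:
        return float(self.table.loc[var, "contribution_pct"])

    def permutation(self, var: str) -> float:
        return float(self.table.loc[var, "permutation_pct"])


def prescreen(importance: VariableImportance) -> list[str]:
    """Drop variables with a contribution rate of exactly 0 (order preserved)."""
    kept = [v for v in importance.variables if importance.contribution(v) > 0.0]
    if not kept:
        raise ValueError("every variable has zero contribution; nothing to retain")
    return kept


def _bioclim_index(name: str) -> int:
    m = re.search(r"(\d+)$", name)
    return int(m.group(1)) if m else -1


@dataclass
class SelectionReport:
    retained: list[str]
    dropped: list[dict]
    correlation: CorrelationMatrix
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "retained": self.retained,
            "dropped": self.dropped,
            "correlation": {
                "variables": self.correlation.variables,
                "r": self.correlation.r.tolist(),
            },
        }


def select_variables(corr: CorrelationMatrix, importance: VariableImportance,
                     threshold: float = 0.8, *,
                     return_report: bool = False):
    """Resolve |r| > threshold pairs, keeping the more important member.

    Offending pairs are processed in decreasing |r| (ties broken by variable
    name order).  For each pair whose members are both still retained, the one
    with the lower contribution rate is dropped; contribution ties fall to the
    lower permutation importance, and remaining ties to the larger bioclim
    index.  The result has pairwise |r| ≤ threshold.
    """
    variables = list(corr.variables)
    if set(variables) != set(importance.variables):
        raise ValueError("correlation and importance must cover the same variables")

    pairs = []
    for i, a in enumerate(variables):
        for j in range(i + 1, len(variables)):
            b = variables[j]
            r = abs(corr.r[i, j])
            if r > threshold:
                pairs.append((r, tuple(sorted((a, b)))))
    pairs.sort(key=lambda t: (-t[0], t[1]))

    retained = set(variables)
    dropped: list[dict] = []
    for r, (a, b) in pairs:
        if a not in retained or b not in retained:
            continue  # already resolved through an earlier, stronger pair
        ca, cb = importance.contribution(a), importance.contribution(b)
        if ca != cb:
            loser = a if ca < cb else b
            reason = "lower contribution rate"
        else:
            pa, pb = importance.permutation(a), importance.permutation(b)
            if pa != pb:
                loser = a if pa < pb else b
                reason = "lower permutation importance"
            else:
                loser = a if _bioclim_index(a) > _bioclim_index(b) else b
                reason = "larger bioclim index (final tie-break)"
        retained.discard(loser)
        dropped.append({"dropped": loser,
                        "kept": a if loser == b else b,
                        "abs_r": r, "reason": reason})

    result = [v for v in variables if v in retained]
    if return_report:
        return result, SelectionReport(retained=result, dropped=dropped,
                                       correlation=corr, threshold=threshold)
    return result
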