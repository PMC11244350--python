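"""Feature expansion for the maximum-entropy model.

Variables are affinely scaled to [0, 1] using min/max bounds taken from the
background sample, then expanded into the classic presence-background feature
families: linear, quadratic, product (pairwise interactions), hinge and
threshold.  Hinge/threshold knots sit at equally spaced background quantiles.
At prediction time scaled values are clamped into [0, 1] so features never
extrapolate outside the range the model was trained on.

Feature class availability follows the usual presence-count heuristic:
fewer than 10 presences → linear only; 10–14 → + quadratic; 15–79 → + hinge;
80 or more → all classes (adds product and threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["FeatureDef", "FeatureSet", "auto_feature_classes"]

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")

#: Base regularization constants per feature class.
BETA_BASE = {"linear": 0.1, "quadratic": 0.1, "product": 0.1,
             "hinge": 0.5, "threshold": 1.0}


def auto_feature_classes(n_presence: int) -> tuple[str, ...]:
    """Feature classes enabled for a given presence count."""
    if n_presence < 10:
        return ("linear",)
    if n_presence < 15:
        return ("linear", "quadratic")
    if n_presence < 80:
        return ("linear", "quadratic", "hinge")
    return FEATURE_CLASSES


@dataclass(frozen=True)
class FeatureDef:
    """One feature: its class, the variable(s) it reads, and its knot (scaled units)."""

    kind: str
    variables: tuple[str, ...]
    knot: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.kind!r}")
        if self.kind == "product" and len(set(self.variables)) != 2:
            raise ValueError("product features need exactly two distinct variables")
        if self.kind in ("hinge", "threshold"):
            if self.knot is None or not (0.0 <= self.knot < 1.0):
                raise ValueError(f"{self.kind} knot must lie in [0, 1)")

    @property
    def label(self) -> str:
        base = "*".join(self.variables)
        if self.knot is not None:
            return f"{self.kind}({base}, {self.knot:.4g})"
        if self.kind == "quadratic":
            return f"{base}^2"
        return base


class FeatureSet:
    """Scaling bounds plus an ordered list of feature definitions.

    Built from a background sample; ``transform`` maps a raw variable matrix
    (columns in ``self.variables`` order) to the feature matrix.
    """

    def __init__(self, variables: list[str], bounds: dict[str, tuple[float, float]],
                 defs: list[FeatureDef]):
        self.variables = list(variables)
        self.bounds = dict(bounds)
        self.defs = list(defs)
        self._var_idx = {v: i for i, v in enumerate(self.variables)}

    @classmethod
    def from_background(cls, variables: list[str], background: np.ndarray,
                        classes: tuple[str, ...],
                        n_knots: int = 30) -> "FeatureSet":
        """Derive scaling bounds and knots from a background sample.

        Constant variables contribute no features (their bounds would collapse);
        they are silently skipped here and reported by the caller.
        """
        background = np.asarray(background, dtype=float)
        bounds: dict[str, tuple[float, float]] = {}
        usable: list[str] = []
        for i, name in enumerate(variables):
            col = background[:, i]
            lo, hi = float(np.nanmin(col)), float(np.nanmax(col))
            bounds[name] = (lo, hi)
            if hi > lo:
                usable.append(name)

        defs: list[FeatureDef] = []
        for name in usable:
            if "linear" in classes:
                defs.append(FeatureDef("linear", (name,)))
            if "quadratic" in classes:
                defs.append(FeatureDef("quadratic", (name,)))
        if "product" in classes:
            for a, b in combinations(usable, 2):
                defs.append(FeatureDef("product", (a, b)))
        probs = np.arange(1, n_knots + 1) / (n_knots + 1)
        for name in usable:
            lo, hi = bounds[name]
            col = np.clip((background[:, variables.index(name)] - lo) / (hi - lo), 0, 1)
            knots = np.unique(np.round(np.quantile(col, probs), 12))
            knots = knots[(knots >= 0.0) & (knots < 1.0)]
            if "hinge" in classes:
                defs.extend(FeatureDef("hinge", (name,), float(k)) for k in knots)
            if "threshold" in classes:
                defs.extend(FeatureDef("threshold", (name,), float(k))
                            for k in knots if k > 0.0)
        return cls(variables=variables, bounds=bounds, defs=defs)

    def __len__(self) -> int:
        return len(self.defs)

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.defs]

    def scale(self, X: np.ndarray) -> np.ndarray:
        """Scale raw values into [0, 1] by the background bounds (clamped)."""
        X = np.asarray(X, dtype=float)
        Z = np.empty_like(X)
        for j, name in enumerate(self.variables):
            lo, hi = self.bounds[name]
            if hi > lo:
                Z[:, j] = np.clip((X[:, j] - lo) / (hi - lo), 0.0, 1.0)
            else:
                Z[:, j] = 0.0
        return Z

    def transform(self, X: np.ndarray) -> np.ndarray:
        """(n, n_features) feature matrix for raw variable matrix ``X``."""
        Z = self.scale(X)
        F = np.empty((Z.shape[0], len(self.defs)))
        for k, d in enumerate(self.defs):
            i = self._var_idx[d.variables[0]]
            if d.kind == "linear":
                F[:, k] = Z[:, i]
            elif d.kind == "quadratic":
                F[:, k] = Z[:, i] ** 2
            elif d.kind == "product":
                j = self._var_idx[d.variables[1]]
                F[:, k] = Z[:, i] * Z[:, j]
            elif d.kind == "hinge":
                F[:, k] = np.maximum(0.0, Z[:, i] - d.knot) / (1.0 - d.knot)
            else:  # threshold
                F[:, k] = (Z[:, i] > d.knot).astype(float)
        return F

    def variable_shares(self) -> list[dict[str, float]]:
        """Per feature: variable → attribution share (products split 50/50)."""
        shares = []
        for d in self.defs:
            if d.kind == "product":
                shares.append({d.variables[0]: 0.5, d.variables[1]: 0.5})
            else:
                shares.append({d.variables[0]: 1.0})
        return shares

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "defs": [{"kind": d.kind, "variables": list(d.variables), "knot": d.knot}
                     for d in self.defs],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FeatureSet":
        return cls(
            variables=list(data["variables"]),
            bounds={k: (float(v[0]), float(v[1])) for k, v in data["bounds"].items()},
            defs=[FeatureDef(d["kind"], tuple(d["variables"]),
                             None if d["knot"] is None else float(d["knot"]))
                  for d in data["defs"]],
        )
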