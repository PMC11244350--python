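"""Presence-background maximum-entropy model (Gibbs / log-linear over background).

The model estimates a probability distribution q(x) = exp(λ·f(x)) / Z over the
background cells — the maximum-entropy distribution whose feature expectations
match the presence sample, subject to an L1 budget.  Fitting minimizes the
convex objective

    J(λ) = −(1/m) Σ_presence λ·f  +  log Σ_background exp(λ·f)  +  Σ_j β_j |λ_j|

by cyclic coordinate descent: each coordinate takes a soft-thresholded Newton
step (curvature from the current Gibbs variance of the feature), backed off
onto the safe quadratic-bound step (f ∈ [0,1] gives curvature ≤ 1/4) whenever
the trial step fails to decrease J, so the objective is non-increasing by
construction.

Suitability links: ``raw`` is q itself; ``logistic`` p = e^H·q / (1 + e^H·q);
``cloglog`` (default) p = 1 − exp(−e^H·q), with H the entropy of the fitted
distribution over the background.  Both links are monotone in q.

The API follows the model/results convention: build a :class:`MaxEnt` from
presence and background value tables (or ``from_occurrences`` on a raster
stack), call :meth:`MaxEnt.fit`, and read everything else off the returned
:class:`MaxEntResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import BETA_BASE, FeatureSet, auto_feature_classes
from .geo import RasterLayer, RasterStack, extract_values
from .occurrences import OccurrenceSet

__all__ = ["MaxEnt", "MaxEntResults", "SplitConfig", "EvalReport",
           "auc", "split", "DEFAULT_BACKGROUND_SIZE"]

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND_SIZE = 10_000
LINKS = ("raw", "logistic", "cloglog")


# ---------------------------------------------------------------------------
# Train/test split and AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitConfig:
    """Random presence partition; train share defaults to 75%."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def split(occ: OccurrenceSet, config: SplitConfig = SplitConfig()
          ) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Seeded random partition into (train, test).

    The train count is ``floor(fraction·n + 0.5)`` (half rounds up), so 374
    records split 281/93 at the default 75%.
    """
    n = len(occ.records)
    if n < 4:
        raise ValueError(f"need at least 4 records to split, got {n}")
    n_train = int(np.floor(config.train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    mk = lambda idx: OccurrenceSet(records=[occ.records[i] for i in idx],
                                   thinning_min_km=occ.thinning_min_km, seed=occ.seed)
    return mk(train_idx), mk(test_idx)


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann–Whitney AUC: P(presence score > background score), ties count 1/2."""
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pres, bg]))
    r_sum = ranks[:pres.size].sum()
    u = r_sum - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * bg.size))


@dataclass(frozen=True)
class EvalReport:
    auc_train: float
    auc_test: float | None
    threshold: float = 0.8

    @property
    def passed(self) -> bool:
        value = self.auc_test if self.auc_test is not None else self.auc_train
        return value > self.threshold


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def _fit_coordinate_descent(F_pres: np.ndarray, F_bg: np.ndarray, beta: np.ndarray,
                            tol: float, max_iter: int):
    """Cyclic coordinate descent on the L1-penalized maxent objective.

    Returns (lambda, objective_history, update_trace, converged); the trace
    holds one ``(feature_index, unpenalized_gain_increase)`` entry per accepted
    coordinate update, which downstream contribution attribution consumes.
    """
    n_feat = F_pres.shape[1]
    n_bg = F_bg.shape[0]
    lam = np.zeros(n_feat)
    pbar = F_pres.mean(axis=0)

    scores = np.zeros(n_bg)
    log_z = np.log(n_bg)
    mean_pres_score = 0.0
    penalty = 0.0
    obj = -mean_pres_score + log_z + penalty
    history = [obj]
    trace: list[tuple[int, float]] = []
    log_nbg = np.log(n_bg)
    converged = False

    for _sweep in range(max_iter):
        obj_start = obj
        q = np.exp(scores - log_z)
        for j in range(n_feat):
            fj = F_bg[:, j]
            eq = float(q @ fj)
            eq2 = float(q @ (fj * fj))
            grad = pbar[j] - eq                     # ascent direction of gain
            curv = max(eq2 - eq * eq, 1e-10)
            # soft-thresholded Newton proposal
            w = lam[j] + grad / curv
            thr = beta[j] / curv
            w_new = np.sign(w) * max(abs(w) - thr, 0.0)
            delta = w_new - lam[j]
            if delta == 0.0:
                continue
            # safe step from the quadratic bound (curvature 1/4 since f in [0,1])
            w_safe = lam[j] + 4.0 * grad
            w_safe = np.sign(w_safe) * max(abs(w_safe) - 4.0 * beta[j], 0.0)
            delta_safe = w_safe - lam[j]
            accepted = False
            for _bt in range(30):
                trial = scores + delta * fj
                log_z_new = _logsumexp(trial)
                mps_new = mean_pres_score + delta * pbar[j]
                pen_new = penalty + beta[j] * (abs(lam[j] + delta) - abs(lam[j]))
                obj_new = -mps_new + log_z_new + pen_new
                if obj_new <= obj + 1e-12:
                    accepted = True
                    break
                delta = delta_safe if _bt == 0 and delta != delta_safe else delta / 2.0
                if delta == 0.0:
                    break
            if not accepted:
                continue
            gain_old = mean_pres_score - log_z + log_nbg
            scores = trial
            log_z = log_z_new
            mean_pres_score = mps_new
            penalty = pen_new
            lam[j] += delta
            obj = obj_new
            trace.append((j, (mean_pres_score - log_z + log_nbg) - gain_old))
            q = np.exp(scores - log_z)
        history.append(obj)
        if obj_start - obj < tol * max(1.0, abs(obj_start)):
            converged = True
            break
    return lam, history, trace, converged


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class MaxEnt:
    """Presence-background maximum-entropy model (unfitted).

    Parameters
    ----------
    presence, background
        Value tables (rows = samples, columns = environmental variables); the
        two must share columns.  Presence rows are appended to the background
        (the landscape sample should include where the species was seen), and
        feature scaling bounds/knots come from that combined background.
    feature_classes
        Override the presence-count heuristic (tuple drawn from
        ``linear, quadratic, product, hinge, threshold``).
    beta_multiplier
        Global multiplier on the per-feature L1 penalties
        β_j = multiplier · b_class · max(σ_j, 1e-3) / √m with σ_j the feature
        std over presences and b 0.1 (linear/quadratic/product), 0.5 (hinge),
        1.0 (threshold).
    """

    def __init__(self, presence: pd.DataFrame, background: pd.DataFrame, *,
                 feature_classes: tuple[str, ...] | None = None,
                 beta_multiplier: float = 1.0,
                 n_knots: int = 30,
                 add_presence_to_background: bool = True):
        presence = presence.copy()
        background = background[list(presence.columns)].copy()
        if presence.shape[0] < 1 or background.shape[0] < 2:
            raise ValueError("need >= 1 presence and >= 2 background samples")
        self.variables = list(presence.columns)
        self.presence = presence
        if add_presence_to_background:
            background = pd.concat([background, presence], ignore_index=True)
        self.background = background
        self.beta_multiplier = beta_multiplier
        if feature_classes is None:
            feature_classes = auto_feature_classes(len(presence))
        self.feature_classes = tuple(feature_classes)
        self.features = FeatureSet.from_background(
            self.variables, background.to_numpy(), self.feature_classes, n_knots)
        dropped = [v for v in self.variables
                   if self.features.bounds[v][0] == self.features.bounds[v][1]]
        if dropped:
            logger.info("constant variables dropped from features: %s", dropped)
        self._F_pres = self.features.transform(presence.to_numpy())
        self._F_bg = self.features.transform(background.to_numpy())

    @classmethod
    def from_occurrences(cls, occ: OccurrenceSet, stack: RasterStack, *,
                         variables: list[str] | None = None,
                         background_size: int = DEFAULT_BACKGROUND_SIZE,
                         seed: int = 0, **kwargs) -> "MaxEnt":
        """Build from presence points and a raster stack.

        Background cells are sampled uniformly at random (seeded, without
        replacement) from the valid cells, up to ``background_size``; presence
        records on nodata cells are dropped.
        """
        variables = variables or stack.names
        sub = stack.subset(variables)
        table = extract_values(sub, occ.points())
        pres = table.loc[table["valid"], variables]
        n_bad = len(table) - len(pres)
        if n_bad:
            logger.info("dropped %d presence records outside/nodata", n_bad)
        if pres.empty:
            raise ValueError("no presence record falls on a valid cell")

        valid = sub.valid_mask()
        flat = np.flatnonzero(valid.ravel())
        rng = np.random.default_rng(seed)
        take = min(background_size, flat.size)
        chosen = rng.choice(flat, size=take, replace=False)
        cube = sub.to_array().reshape(len(variables), -1)
        bg = pd.DataFrame(cube[:, chosen].T, columns=variables)
        return cls(pres.reset_index(drop=True), bg, **kwargs)

    def _betas(self) -> np.ndarray:
        m = self._F_pres.shape[0]
        sigma = self._F_pres.std(axis=0)
        base = np.array([BETA_BASE[d.kind] for d in self.features.defs])
        return self.beta_multiplier * base * np.maximum(sigma, 1e-3) / np.sqrt(m)

    def fit(self, tol: float = 1e-5, max_iter: int = 500) -> "MaxEntResults":
        beta = self._betas()
        lam, history, trace, converged = _fit_coordinate_descent(
            self._F_pres, self._F_bg, beta, tol, max_iter)
        if not converged:
            grad = np.abs(self._F_pres.mean(axis=0)
                          - _gibbs(self._F_bg, lam) @ self._F_bg)
            warnings.warn(
                f"coordinate descent stopped at max_iter={max_iter} "
                f"(max |gradient| = {grad.max():.3g})", RuntimeWarning, stacklevel=2)
        return MaxEntResults(self, lam, beta, history, trace, converged)


def _gibbs(F_bg: np.ndarray, lam: np.ndarray) -> np.ndarray:
    scores = F_bg @ lam
    scores -= scores.max()
    w = np.exp(scores)
    return w / w.sum()


class MaxEntResults:
    """Fitted maximum-entropy model: weights, entropy, diagnostics, prediction."""

    def __init__(self, model: MaxEnt, params: np.ndarray, beta: np.ndarray,
                 objective_history: list[float], trace: list[tuple[int, float]],
                 converged: bool):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.beta = beta
        self.objective_history = list(objective_history)
        self.trace = list(trace)
        self.converged = converged

        self._q_bg = _gibbs(model._F_bg, self.params)
        scores_bg = model._F_bg @ self.params
        self._log_z = _logsumexp_arr(scores_bg)
        # entropy of the fitted raw distribution over the background
        with np.errstate(divide="ignore", invalid="ignore"):
            logq = np.where(self._q_bg > 0, np.log(self._q_bg), 0.0)
        self.entropy = float(-(self._q_bg * logq).sum())

    # -- core quantities ----------------------------------------------------

    @property
    def gain(self) -> float:
        """Mean presence log-probability improvement over uniform (nats)."""
        scores = self.model._F_pres @ self.params
        n_bg = self.model._F_bg.shape[0]
        return float(scores.mean() - self._log_z + np.log(n_bg))

    def raw_background_probs(self) -> np.ndarray:
        return self._q_bg.copy()

    # -- prediction ---------------------------------------------------------

    def _raw_from_values(self, X: np.ndarray) -> np.ndarray:
        F = self.model.features.transform(X)
        return np.exp(F @ self.params - self._log_z)

    def _apply_link(self, q: np.ndarray, link: str) -> np.ndarray:
        if link == "raw":
            return q
        r = np.exp(self.entropy) * q
        if link == "logistic":
            return r / (1.0 + r)
        if link == "cloglog":
            return 1.0 - np.exp(-r)
        raise ValueError(f"unknown link {link!r}; choose from {LINKS}")

    def predict_values(self, values: pd.DataFrame | np.ndarray,
                       link: str = "cloglog") -> np.ndarray:
        """Suitability for a table of variable values (columns in model order)."""
        if isinstance(values, pd.DataFrame):
            values = values[self.model.variables].to_numpy()
        return self._apply_link(self._raw_from_values(np.asarray(values, float)), link)

    def predict(self, stack: RasterStack, link: str = "cloglog",
                chunk: int = 8192) -> RasterLayer:
        """Suitability map on a raster stack (nodata propagates)."""
        missing = [v for v in self.model.variables if v not in stack]
        if missing:
            raise ValueError(f"stack is missing model variables: {missing}")
        sub = stack.subset(self.model.variables)
        grid = sub.grid
        valid = sub.valid_mask().ravel()
        cube = sub.to_array().reshape(len(self.model.variables), -1)
        out = np.full(grid.n_rows * grid.n_cols, np.nan)
        idx = np.flatnonzero(valid)
        for start in range(0, idx.size, chunk):
            sel = idx[start:start + chunk]
            out[sel] = self.predict_values(cube[:, sel].T, link=link)
        return RasterLayer(grid=grid, name=f"suitability_{link}",
                           values=out.reshape(grid.n_rows, grid.n_cols))

    # -- evaluation ---------------------------------------------------------

    def training_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """(presence, background) raw scores λ·f on the training samples."""
        return (self.model._F_pres @ self.params, self.model._F_bg @ self.params)

    def evaluate(self, test_presence: pd.DataFrame | None = None,
                 threshold: float = 0.8) -> EvalReport:
        """Training AUC, plus test AUC if a held-out presence table is given.

        Both AUCs score presences against the model's training background.
        """
        pres_s, bg_s = self.training_scores()
        auc_train = auc(pres_s, bg_s)
        auc_test = None
        if test_presence is not None:
            X = test_presence[self.model.variables].to_numpy()
            test_s = self.model.features.transform(X) @ self.params
            auc_test = auc(test_s, bg_s)
        return EvalReport(auc_train=auc_train, auc_test=auc_test, threshold=threshold)

    # -- variable importance ------------------------------------------------

    def contribution_rates(self) -> pd.Series:
        """Training-path attribution of gain increases to variables (sums to 100).

        Each accepted coordinate update's unpenalized-gain increase is credited
        to the updated feature's variable (products split 50/50); negative
        variable totals are floored at 0 and the vector normalized to 100.
        The attribution is path-dependent by construction — the sweep order is
        deterministic, so runs are reproducible.
        """
        shares = self.model.features.variable_shares()
        totals = {v: 0.0 for v in self.model.variables}
        for j, dgain in self.trace:
            for var, w in shares[j].items():
                totals[var] += w * dgain
        vec = pd.Series(totals, dtype=float).clip(lower=0.0)
        s = vec.sum()
        return vec * (100.0 / s) if s > 0 else vec

    def permutation_importance(self, seed: int = 0, reps: int = 1) -> pd.Series:
        """Normalized drop in training AUC when each variable is shuffled.

        Shuffles the variable's raw values across the combined presence +
        background sample (seeded), re-scores, and records the AUC drop;
        negative drops floor at 0 and the vector is normalized to sum 100.
        """
        rng = np.random.default_rng(seed)
        model = self.model
        n_pres = model.presence.shape[0]
        X_all = np.vstack([model.presence.to_numpy(), model.background.to_numpy()])
        pres_s, bg_s = self.training_scores()
        base_auc = auc(pres_s, bg_s)
        drops = {}
        for k, var in enumerate(model.variables):
            drop = 0.0
            for _ in range(reps):
                Xp = X_all.copy()
                Xp[:, k] = rng.permutation(Xp[:, k])
                scores = model.features.transform(Xp) @ self.params
                drop += base_auc - auc(scores[:n_pres], scores[n_pres:])
            drops[var] = drop / reps
        vec = pd.Series(drops, dtype=float).clip(lower=0.0)
        s = vec.sum()
        return vec * (100.0 / s) if s > 0 else vec

    def importance(self, seed: int = 0, reps: int = 1) -> pd.DataFrame:
        """Contribution rate and permutation importance side by side (%, each to 100)."""
        return pd.DataFrame({
            "contribution_pct": self.contribution_rates(),
            "permutation_pct": self.permutation_importance(seed=seed, reps=reps),
        })

    def jackknife(self, tol: float = 1e-5, max_iter: int = 500) -> pd.DataFrame:
        """Per-variable training gain with only that variable / without it.

        Refits the model on variable subsets with the same settings; the
        ``without`` column is NaN when the model has a single variable.
        """
        model = self.model
        rows = {}
        for var in model.variables:
            only = MaxEnt(model.presence[[var]], model.background[[var]],
                          feature_classes=model.feature_classes,
                          beta_multiplier=model.beta_multiplier,
                          add_presence_to_background=False).fit(tol, max_iter)
            if len(model.variables) >= 2:
                rest = [v for v in model.variables if v != var]
                without = MaxEnt(model.presence[rest], model.background[rest],
                                 feature_classes=model.feature_classes,
                                 beta_multiplier=model.beta_multiplier,
                                 add_presence_to_background=False).fit(tol, max_iter)
                gain_without = without.gain
            else:
                gain_without = np.nan
            rows[var] = {"gain_only": only.gain, "gain_without": gain_without}
        df = pd.DataFrame(rows).T
        df["gain_full"] = self.gain
        return df

    # -- response curves ----------------------------------------------------

    def response_curve(self, variable: str, n_points: int = 100,
                       link: str = "cloglog") -> pd.DataFrame:
        """Sweep one variable over its background range, others held at their
        presence means; returns columns ``value`` and ``p``."""
        if variable not in self.model.variables:
            raise ValueError(f"{variable!r} is not a model variable")
        lo, hi = self.model.features.bounds[variable]
        sweep = np.linspace(lo, hi, n_points)
        base = self.model.presence.mean(axis=0)
        X = np.tile(base.to_numpy(), (n_points, 1))
        X[:, self.model.variables.index(variable)] = sweep
        p = self.predict_values(X, link=link)
        return pd.DataFrame({"value": sweep, "p": p})

    def plot_response(self, variable: str, n_points: int = 100,
                      link: str = "cloglog", ax=None):
        """Plot a response curve (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        curve = self.response_curve(variable, n_points, link)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["value"], curve["p"])
        ax.set_xlabel(variable)
        ax.set_ylabel(f"suitability ({link})")
        ax.set_ylim(-0.02, 1.02)
        return ax

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        model = self.model
        n_nonzero = int((self.params != 0).sum())
        ev = self.evaluate()
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 45,
            f"presences:          {model.presence.shape[0]}",
            f"background samples: {model.background.shape[0]} (presences included)",
            f"variables:          {len(model.variables)}",
            f"feature classes:    {', '.join(model.feature_classes)}",
            f"features:           {len(model.features)} ({n_nonzero} nonzero weights)",
            f"beta multiplier:    {model.beta_multiplier}",
            f"converged:          {self.converged} "
            f"({len(self.objective_history) - 1} sweeps)",
            f"final objective:    {self.objective_history[-1]:.6f}",
            f"training gain:      {self.gain:.4f} nats",
            f"entropy H:          {self.entropy:.4f}",
            f"training AUC:       {ev.auc_train:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable model state (features, bounds, weights, entropy)."""
        return {
            "variables": self.model.variables,
            "feature_set": self.model.features.to_dict(),
            "params": self.params.tolist(),
            "beta": self.beta.tolist(),
            "log_z": self._log_z,
            "entropy": self.entropy,
            "gain": self.gain,
            "converged": self.converged,
            "n_presence": int(self.model.presence.shape[0]),
            "n_background": int(self.model.background.shape[0]),
            "beta_multiplier": self.model.beta_multiplier,
            "feature_classes": list(self.model.feature_classes),
        }


def _logsumexp_arr(x: np.ndarray) -> float:
    m = float(x.max())
    return m + float(np.log(np.exp(x - m).sum()))


def predict_from_saved(state: dict, stack: RasterStack, link: str = "cloglog",
                       chunk: int = 8192) -> RasterLayer:
    """Predict a suitability map from a serialized model dict (see
    :meth:`MaxEntResults.to_dict`) without the training data."""
    feats = FeatureSet.from_dict(state["feature_set"])
    params = np.asarray(state["params"], dtype=float)
    log_z = float(state["log_z"])
    entropy = float(state["entropy"])
    variables = list(state["variables"])
    missing = [v for v in variables if v not in stack]
    if missing:
        raise ValueError(f"stack is missing model variables: {missing}")
    sub = stack.subset(variables)
    grid = sub.grid
    valid = sub.valid_mask().ravel()
    cube = sub.to_array().reshape(len(variables), -1)
    out = np.full(grid.n_rows * grid.n_cols, np.nan)
    idx = np.flatnonzero(valid)
    for start in range(0, idx.size, chunk):
        sel = idx[start:start + chunk]
        q = np.exp(feats.transform(cube[:, sel].T) @ params - log_z)
        if link == "raw":
            out[sel] = q
        elif link == "logistic":
            r = np.exp(entropy) * q
            out[sel] = r / (1.0 + r)
        elif link == "cloglog":
            out[sel] = 1.0 - np.exp(-np.exp(entropy) * q)
        else:
            raise ValueError(f"unknown link {link!r}; choose from {LINKS}")
    return RasterLayer(grid=grid, name=f"suitability_{link}",
                       values=out.reshape(grid.n_rows, grid.n_cols))
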