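"""Wrapper feature selection by modified simulated annealing.

The selector searches n-feature subsets of an m-feature pool, scoring each
candidate by refitting the Gaussian Bayes classifier on the training rows
and computing the cost

    cost = mean(AUC_train, AUC_test, AUC_validation)
           - sd(AUC_train, AUC_test, AUC_validation)

(sample SD), penalized to exactly 0 whenever any of the six
sensitivity/specificity values over the three sets falls below the
``penalty_threshold`` (default 0.6). Rewarding the mean while subtracting
the spread favours subsets that generalize consistently across the
hold-out sets rather than peaking on one of them.

The annealer follows the classic Metropolis scheme with two modifications:
candidates are fresh uniform n-subsets (a global neighbourhood), and every
evaluated cost is recorded so the returned optimum is the maximum of the
whole cost history, independent of the acceptance trajectory. The default
schedule is T0 = 0.5979, geometric cooling by 0.82 down to Tmin = 0.0232
(17 temperature levels), with an adaptive steady state: round(Lk)
candidate evaluations per level, Lk starting at 30 and growing by the
factor 2 - e^-1 per level.

Two execution modes are provided. ``standard`` (default) is the two-loop
schedule above with per-candidate Metropolis acceptance. ``as_printed``
reproduces the literal single-loop pseudocode in which the temperature
cools every iteration and the candidate cost is replaced by the running
maximum before the acceptance test (making the downhill branch
unreachable); it is retained for comparison, not for use.

The per-dimension sweep starts from an 11-feature solution with prior
evidence of fall-risk association and grows the dimension one feature at a
time, seeding each dimension with the previous optimum plus one random
unused feature, stopping after a fixed number of consecutive dimensions
without improvement of the best cost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bayes import _fit_gaussian, _log_density, _regularize
from .registry import ALL_FEATURES, LABEL_FALL_RISK, SEED_FEATURES

__all__ = [
    "SAConfig",
    "SAResult",
    "SweepResult",
    "CostEvaluator",
    "cost",
    "random_solution",
    "metropolis_accept",
    "anneal",
    "dimension_sweep",
    "search_space_size",
]

#: Per-level growth factor of the steady-state length.
LK_GROWTH = 2.0 - math.exp(-1.0)


@dataclass
class SAConfig:
    """Annealing constants and selection options."""

    t0: float = 0.5979
    tmin: float = 0.0232
    alpha: float = 0.82
    lk0: float = 30.0
    lk_growth: float = LK_GROWTH
    penalty_threshold: float = 0.6
    pool: tuple[str, ...] | None = None
    mode: str = "standard"          # or "as_printed"
    neighborhood: str = "uniform"   # or "swap" (single-exchange local moves)
    seed: int | None = None

    def validate(self) -> None:
        if not 0 < self.tmin < self.t0:
            raise ValueError("need 0 < tmin < t0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lk0 < 1:
            raise ValueError("lk0 must be >= 1")
        if not 0 <= self.penalty_threshold <= 1:
            raise ValueError("penalty_threshold must lie in [0, 1]")
        if self.mode not in ("standard", "as_printed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.neighborhood not in ("uniform", "swap"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")


@dataclass
class SAResult:
    """Outcome of one annealing run at a fixed dimension."""

    n: int
    best_subset: tuple[str, ...]
    best_cost: float
    cost_history: np.ndarray
    n_evals: int
    n_levels: int
    metrics: dict | None = None

    def summary(self) -> dict:
        return {"n": self.n, "best_subset": list(self.best_subset),
                "best_cost": self.best_cost, "n_evals": self.n_evals,
                "n_levels": self.n_levels, "metrics": self.metrics}


@dataclass
class SweepResult:
    """Per-dimension optima and the cross-dimension selection tally."""

    dimensions: dict[int, SAResult]
    feature_frequency: dict[str, int]
    stopped_at: int

    def best_dimension(self) -> int:
        return max(self.dimensions, key=lambda n: self.dimensions[n].best_cost)


class CostEvaluator:
    """Cached cost function: subset -> penalized mean-minus-SD of AUCs.

    Caches the standardized feature columns and split row masks once so the
    annealer can evaluate tens of thousands of candidate subsets cheaply.
    """

    def __init__(self, table: pd.DataFrame, split,
                 penalty_threshold: float = 0.6, prior: float = 0.5):
        self.penalty_threshold = penalty_threshold
        self.prior = prior
        self._cols = {c: table[c].to_numpy(dtype=float)
                      for c in table.columns
                      if c in ALL_FEATURES}
        labels = table["label"].to_numpy()
        pos = labels == LABEL_FALL_RISK
        self._sets = []
        positions = {idx: i for i, idx in enumerate(table.index)}
        for name, idx in split.sets().items():
            rows = np.array([positions[i] for i in idx], dtype=int)
            self._sets.append((name, rows, pos[rows]))
        train_rows = self._sets[0][1]
        self._train_pos = train_rows[pos[train_rows]]

    def _auc(self, scores: np.ndarray, pos: np.ndarray) -> float:
        n_pos = int(pos.sum())
        n_neg = len(scores) - n_pos
        ranks = rankdata(scores)
        return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    def __call__(self, subset) -> float:
        X = np.column_stack([self._cols[f] for f in subset])
        Xfit = X[self._train_pos]
        mu, S = _fit_gaussian(Xfit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S, _ = _regularize(S, len(Xfit) < len(subset) + 2)
        try:
            logp = _log_density(X, mu, S)
        except np.linalg.LinAlgError:
            return 0.0
        pfr = self.prior * np.exp(np.minimum(logp, 700.0))
        aucs = []
        for _, rows, pos in self._sets:
            s = pfr[rows]
            pred_pos = s > 0.5
            n_pos = int(pos.sum())
            n_neg = len(s) - n_pos
            se = (pred_pos & pos).sum() / n_pos
            sp = (~pred_pos & ~pos).sum() / n_neg
            if se < self.penalty_threshold or sp < self.penalty_threshold:
                return 0.0
            aucs.append(self._auc(s, pos))
        aucs = np.asarray(aucs)
        return float(aucs.mean() - aucs.std(ddof=1))

    def metrics(self, subset) -> dict[str, dict[str, float]]:
        """Full per-set metrics of one subset (for reporting)."""
        X = np.column_stack([self._cols[f] for f in subset])
        Xfit = X[self._train_pos]
        mu, S = _fit_gaussian(Xfit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S, _ = _regularize(S, len(Xfit) < len(subset) + 2)
        pfr = self.prior * np.exp(np.minimum(_log_density(X, mu, S), 700.0))
        out = {}
        for name, rows, pos in self._sets:
            s = pfr[rows]
            pred_pos = s > 0.5
            out[name] = {
                "sensitivity": float((pred_pos & pos).sum() / pos.sum()),
                "specificity": float((~pred_pos & ~pos).sum()
                                     / (~pos).sum()),
                "auc": float(self._auc(s, pos)),
            }
        return out


def cost(subset, split, table: pd.DataFrame,
         penalty_threshold: float = 0.6) -> float:
    """Penalized cost of one subset (convenience wrapper over the cache)."""
    return CostEvaluator(table, split, penalty_threshold)(tuple(subset))


def random_solution(pool, n: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Uniformly random n-subset of the pool, without replacement."""
    pool = list(pool)
    if n > len(pool):
        raise ValueError(f"cannot draw {n} features from a pool of {len(pool)}")
    idx = rng.permutation(len(pool))[:n]
    return tuple(pool[i] for i in idx)


def metropolis_accept(delta: float, temperature: float, u: float) -> bool:
    """Accept iff the move improves or exp(delta/T) beats the uniform draw."""
    if delta >= 0:
        return True
    return math.exp(delta / temperature) > u


def _swap_neighbor(current, pool, rng):
    current = list(current)
    outside = [f for f in pool if f not in current]
    if not outside:
        return tuple(current)
    current[rng.integers(len(current))] = outside[rng.integers(len(outside))]
    return tuple(current)


def anneal(n: int, initial_subset, cfg: SAConfig, split=None, table=None,
           cost_fn=None, rng: np.random.Generator | None = None) -> SAResult:
    """Anneal over n-feature subsets, returning the best subset ever evaluated.

    Either pass ``split``/``table`` (the cost is built from the classifier
    pipeline) or a custom ``cost_fn(subset) -> float``.
    """
    cfg.validate()
    initial_subset = tuple(initial_subset)
    if len(initial_subset) != n:
        raise ValueError(f"initial subset has {len(initial_subset)} features, "
                         f"expected {n}")
    if cost_fn is None:
        if split is None or table is None:
            raise ValueError("need either cost_fn or (split, table)")
        cost_fn = CostEvaluator(table, split, cfg.penalty_threshold)
    pool = list(cfg.pool) if cfg.pool is not None else [
        c for c in (table.columns if table is not None else initial_subset)
        if c in ALL_FEATURES]
    if n > len(pool):
        raise ValueError("dimension exceeds pool size")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if cfg.mode == "as_printed":
        return _anneal_as_printed(n, initial_subset, cfg, cost_fn, pool, rng)

    current = initial_subset
    c0 = cost_fn(current)
    history = [c0]
    best_cost, best_subset = c0, current
    t = cfg.t0
    lk = cfg.lk0
    n_levels = 0
    uniform_hood = cfg.neighborhood == "uniform"
    rng_random = rng.random
    while t > cfg.tmin:
        for _ in range(round(lk)):
            cand = (random_solution(pool, n, rng) if uniform_hood
                    else _swap_neighbor(current, pool, rng))
            cp = cost_fn(cand)
            history.append(cp)
            if cp > best_cost:
                best_cost, best_subset = cp, cand
            delta = cp - c0
            if delta >= 0 or math.exp(delta / t) > rng_random():
                c0 = cp
                current = cand
        t *= cfg.alpha
        lk *= cfg.lk_growth
        n_levels += 1
    return SAResult(n=n, best_subset=best_subset, best_cost=best_cost,
                    cost_history=np.asarray(history),
                    n_evals=len(history) - 1, n_levels=n_levels)


def _anneal_as_printed(n, initial_subset, cfg, cost_fn, pool, rng) -> SAResult:
    # Literal pseudocode: T cools every iteration; the candidate cost is
    # replaced by the running maximum before the acceptance test, so the
    # Metropolis branch never fires and every iteration is "accepted".
    c0 = cost_fn(initial_subset)
    history = [c0]
    accepted: dict[int, tuple[str, ...]] = {0: initial_subset}
    t = cfg.t0
    lk = cfg.lk0
    i = 0
    while t > cfg.tmin:
        i += 1
        cand = random_solution(pool, n, rng)
        history.append(cost_fn(cand))
        cp = max(history)
        delta = cp - c0
        if delta >= 0 or math.exp(delta / t) > rng.random():
            c0 = cp
            accepted[i] = cand
        t *= cfg.alpha
        lk *= cfg.lk_growth
    hist = np.asarray(history)
    best_i = int(hist.argmax())
    while best_i not in accepted:  # penalized/rejected index: walk back
        best_i -= 1
    return SAResult(n=n, best_subset=accepted[best_i],
                    best_cost=float(hist.max()), cost_history=hist,
                    n_evals=len(hist) - 1, n_levels=i)


def dimension_sweep(cfg: SAConfig, split, table: pd.DataFrame,
                    n_start: int = 11, stop_patience: int = 3,
                    initial_features=SEED_FEATURES,
                    cost_fn=None, seed: int | None = None) -> SweepResult:
    """Run the annealer over growing dimensions with warm-started solutions.

    Dimension ``n_start`` starts from ``initial_features`` (the 11-feature
    evidence-based solution by default); every later dimension starts from
    the previous optimum plus one random unused feature. The sweep stops
    after ``stop_patience`` consecutive dimensions without improvement of
    the best cost, or when the pool is exhausted.
    """
    cfg.validate()
    pool = list(cfg.pool) if cfg.pool is not None else [
        c for c in table.columns if c in ALL_FEATURES]
    missing = [f for f in initial_features if f not in pool]
    if missing:
        raise ValueError(f"initial features not in the pool: {missing}")
    if cost_fn is None:
        cost_fn = CostEvaluator(table, split, cfg.penalty_threshold)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    results: dict[int, SAResult] = {}
    tally: dict[str, int] = {}
    best_overall = -np.inf
    stale = 0
    prev_best: tuple[str, ...] | None = None
    n = n_start
    run_cfg = SAConfig(**{**cfg.__dict__, "pool": tuple(pool)})
    while n <= len(pool):
        if prev_best is None:
            init = (tuple(initial_features) if len(initial_features) == n
                    else random_solution(pool, n, rng))
        else:
            unused = [f for f in pool if f not in prev_best]
            init = prev_best + (unused[rng.integers(len(unused))],)
        res = anneal(n, init, run_cfg, cost_fn=cost_fn, rng=rng)
        if hasattr(cost_fn, "metrics"):
            res.metrics = cost_fn.metrics(res.best_subset)
        results[n] = res
        for f in res.best_subset:
            tally[f] = tally.get(f, 0) + 1
        if res.best_cost > best_overall:
            best_overall = res.best_cost
            stale = 0
        else:
            stale += 1
        prev_best = res.best_subset
        if stale >= stop_patience:
            break
        n += 1
    return SweepResult(dimensions=results, feature_frequency=tally,
                       stopped_at=max(results))


def search_space_size(m: int, n: int) -> int:
    """Exact number of n-subsets of an m-feature pool: C(m, n)."""
    if n < 0 or m < 0:
        raise ValueError("m and n must be non-negative")
    if n > m:
        raise ValueError(f"cannot choose {n} from {m}")
    return math.comb(m, n)
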