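"""Butterfly Optimization Algorithm (BOA) wrapper feature selection.

Each candidate feature subset is encoded as a butterfly: a point in the
unit hypercube ``[0, 1]^D``, binarized at a threshold into a column
mask.  A butterfly emits a fragrance

    F = s * K ** x

where ``s`` is the sensory modality, ``x`` the power exponent, and the
stimulus intensity ``K`` is tied to the (minimized) cost — here
``K = 1 / (1 + cost)`` so better subsets smell stronger.  Per
iteration, each butterfly draws a random ``d`` in [0, 1] and either
moves toward the incumbent best position (global search, probability
``p``)

    b <- b + (d^2 * c* - b) * F

or toward the gap between itself and a random population member (local
search)

    b <- b + (d^2 * b - b_m) * F,

with every coordinate clamped back into [0, 1].  The power exponent
grows linearly over the run, sharpening fragrance differences late in
the search, and the best mask ever evaluated is never lost (elitism).

Two elements beyond the bare equations make the search effective on the
binarized lattice.  First, a move is accepted for a butterfly only if it
does not worsen that butterfly's cost (the greedy acceptance rule the
original butterfly-algorithm reference code applies).  Second, after
every iteration the best mask proposed in that iteration is refined by
an elitist hill climb over single-bit flips and drop-one/add-one swaps,
budgeted per iteration; any improvement replaces the incumbent.  This
memetic refinement is the package's intensification step: the
continuous dynamics explore subset space globally while the hill climb
resolves the final one- and two-bit differences that separate
neighboring masks under the size penalty.

The wrapper cost of a mask S over D columns is

    cost = alpha * err(S) + (1 - alpha) * |S| / D + gamma * (1 - Hbar(S))

where ``err`` is the 1-nearest-neighbor misclassification rate on a
stratified 70/30 internal holdout fixed per run, the middle term
penalizes subset size, and the optional entropy term (off by default)
rewards columns with high mean normalized Shannon entropy after
equal-width 10-bin discretization.

:func:`exhaustive_select` evaluates every nonempty mask (guarded to
D <= 20) with the same cost and split, serving as an exact oracle for
small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import InvalidArgumentError

__all__ = [
    "BOAConfig",
    "Butterfly",
    "SelectionResult",
    "fragrance",
    "global_search_step",
    "local_search_step",
    "binarize",
    "FitnessEvaluator",
    "fitness",
    "run_boa",
    "exhaustive_select",
]


@dataclass(frozen=True)
class BOAConfig:
    """All BOA hyperparameters.

    Defaults: a population of 10 butterflies run for 100 iterations;
    sensory modality ``s = 0.01``; power exponent growing 0.1 -> 0.3;
    switch probability ``p = 0.8``; binarization threshold 0.5; cost
    weight ``alpha = 0.99`` on classification error (so 0.01 on subset
    size); entropy weight ``gamma = 0`` (term disabled);
    ``refine_budget`` caps the per-iteration hill-climb evaluations
    (0 disables refinement entirely).
    """

    population: int = 10
    max_iter: int = 100
    sensory_modality_s: float = 0.01
    power_exponent_x0: float = 0.1
    power_exponent_x1: float = 0.3
    switch_prob_p: float = 0.8
    binarize_threshold: float = 0.5
    fitness_alpha: float = 0.99
    entropy_gamma: float = 0.0
    refine_budget: int = 512
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.switch_prob_p <= 1.0:
            raise InvalidArgumentError("switch_prob_p must be in [0, 1]")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise InvalidArgumentError("binarize_threshold must be in (0, 1)")
        if not 0.0 <= self.fitness_alpha <= 1.0:
            raise InvalidArgumentError("fitness_alpha must be in [0, 1]")
        if self.population < 2:
            raise InvalidArgumentError("population must be >= 2")
        if self.max_iter < 1:
            raise InvalidArgumentError("max_iter must be >= 1")
        if self.refine_budget < 0:
            raise InvalidArgumentError("refine_budget must be >= 0")


@dataclass
class Butterfly:
    """One candidate: a continuous position with its cost and fragrance."""

    position: np.ndarray
    cost: float = np.inf
    stimulus: float = 0.0
    fragrance: float = 0.0


@dataclass
class SelectionResult:
    mask: np.ndarray
    selected_indices: list[int]
    best_cost_per_iter: np.ndarray
    best_cost: float
    config_echo: BOAConfig

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise InvalidArgumentError("selection mask may not be empty")


def fragrance(K: float, s: float, x: float) -> float:
    """Perceived fragrance ``s * K**x`` (``0**x`` is 0 for x > 0)."""
    if K < 0:
        raise InvalidArgumentError("stimulus intensity K must be >= 0")
    if s < 0 or not 0.0 <= x <= 1.0:
        raise InvalidArgumentError("need s >= 0 and x in [0, 1]")
    if K == 0.0 and x > 0.0:
        return 0.0
    return float(s * K**x)


def _clamp01(v: np.ndarray) -> np.ndarray:
    return np.clip(v, 0.0, 1.0)


def global_search_step(
    b: np.ndarray, c_star: np.ndarray, F: float, d: float
) -> np.ndarray:
    """Move toward the incumbent best: ``clamp01(b + (d^2 c* - b) F)``."""
    b = np.asarray(b, float)
    c_star = np.asarray(c_star, float)
    if b.shape != c_star.shape:
        raise InvalidArgumentError("position length mismatch")
    return _clamp01(b + (d * d * c_star - b) * F)


def local_search_step(
    b: np.ndarray, b_m: np.ndarray, F: float, d: float
) -> np.ndarray:
    """Local move past a random member: ``clamp01(b + (d^2 b - b_m) F)``."""
    b = np.asarray(b, float)
    b_m = np.asarray(b_m, float)
    if b.shape != b_m.shape:
        raise InvalidArgumentError("position length mismatch")
    return _clamp01(b + (d * d * b - b_m) * F)


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Mask of coordinates above threshold; an empty result falls back to
    the single largest coordinate (ties -> lowest index), so every mask
    is nonempty."""
    position = np.asarray(position, float)
    mask = position > threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def _mean_normalized_entropy(x: np.ndarray, bins: int = 10) -> float:
    """Mean over columns of Shannon entropy / log(bins) after equal-width
    binning; 1 means maximally spread columns, 0 means constant ones."""
    ents = []
    for j in range(x.shape[1]):
        col = x[:, j]
        counts, _ = np.histogram(col, bins=bins)
        p = counts[counts > 0] / counts.sum()
        ents.append(float(-(p * np.log(p)).sum() / np.log(bins)))
    return float(np.mean(ents))


def _as_values_labels(table, labels):
    """Accept a FeatureMatrix-like object (with .values/.labels) or a plain
    array plus explicit labels."""
    if hasattr(table, "matrix") and hasattr(table, "labels"):
        vals = np.asarray(table.matrix, float)
        if labels is None:
            labels = table.labels
    elif hasattr(table, "values") and hasattr(table, "labels"):
        vals = np.asarray(table.values, float)
        if labels is None:
            labels = table.labels
    else:
        vals = np.asarray(table, float)
        if labels is None:
            raise InvalidArgumentError("labels required for a plain matrix")
    return vals, np.asarray(labels, int)


class FitnessEvaluator:
    """Memoized wrapper cost on a fixed internal 70/30 stratified holdout.

    The split is drawn once per evaluator from ``cfg.seed``, so every
    mask within one selection run (and the exhaustive oracle sharing
    the config) is scored against the same partition.
    """

    def __init__(self, values: np.ndarray, labels: np.ndarray, cfg: BOAConfig):
        values, labels = _as_values_labels(values, labels)
        if len(np.unique(labels)) < 2:
            raise InvalidArgumentError("need at least two classes")
        counts = np.bincount(labels)
        if counts[counts > 0].min() < 2:
            raise InvalidArgumentError("need >= 2 samples per class")
        self.cfg = cfg
        idx = np.arange(len(labels))
        tr, te = train_test_split(
            idx,
            test_size=0.3,
            stratify=labels,
            random_state=int(cfg.seed) % (2**31),
        )
        self.x_train, self.x_test = values[tr], values[te]
        self.y_train, self.y_test = labels[tr], labels[te]
        self.values = values
        self.d_total = values.shape[1]
        self._cache: dict[bytes, float] = {}

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise InvalidArgumentError("fitness of an empty mask is undefined")
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        err = self._knn_error(mask)
        alpha = self.cfg.fitness_alpha
        cost = alpha * err + (1.0 - alpha) * (mask.sum() / self.d_total)
        if self.cfg.entropy_gamma != 0.0:
            hbar = _mean_normalized_entropy(self.values[:, mask])
            cost += self.cfg.entropy_gamma * (1.0 - hbar)
        cost = float(cost)
        self._cache[key] = cost
        return cost

    def _knn_error(self, mask: np.ndarray) -> float:
        """1-NN misclassification rate on the holdout, selected columns only.

        Euclidean nearest neighbor via the expanded-square distance and
        a BLAS product; distance ties resolve to the lowest train index.
        """
        a = self.x_train[:, mask]
        b = self.x_test[:, mask]
        d2 = (
            (b * b).sum(axis=1)[:, None]
            + (a * a).sum(axis=1)[None, :]
            - 2.0 * (b @ a.T)
        )
        nearest = d2.argmin(axis=1)
        return float(np.mean(self.y_train[nearest] != self.y_test))


def fitness(mask: np.ndarray, table, labels, cfg: BOAConfig) -> float:
    """One-shot cost of a single mask (builds a fresh evaluator)."""
    return FitnessEvaluator(table, labels, cfg)(mask)


def _power_exponent(cfg: BOAConfig, it: int) -> float:
    if cfg.max_iter == 1:
        return cfg.power_exponent_x0
    t = it / (cfg.max_iter - 1)
    return cfg.power_exponent_x0 + t * (cfg.power_exponent_x1 - cfg.power_exponent_x0)


def run_boa(table, labels, cfg: BOAConfig) -> SelectionResult:
    """Run the full BOA loop and return the best mask ever evaluated.

    Deterministic for a fixed ``cfg.seed``: the same seed drives the
    population initialization, all move draws and the internal holdout.
    """
    values, labels = _as_values_labels(table, labels)
    if values.ndim != 2 or values.shape[1] < 1:
        raise InvalidArgumentError("need an N x D matrix with D >= 1")
    evaluator = FitnessEvaluator(values, labels, cfg)
    D = values.shape[1]
    rng = np.random.default_rng(cfg.seed)
    pop = [Butterfly(rng.uniform(size=D)) for _ in range(cfg.population)]

    best_mask = None
    best_cost = np.inf
    best_pos = None
    traj = np.empty(cfg.max_iter)

    def score(bf: Butterfly, x: float) -> np.ndarray:
        nonlocal best_mask, best_cost, best_pos
        mask = binarize(bf.position, cfg.binarize_threshold)
        bf.cost = evaluator(mask)
        bf.stimulus = 1.0 / (1.0 + bf.cost)
        bf.fragrance = fragrance(bf.stimulus, cfg.sensory_modality_s, x)
        if bf.cost < best_cost:
            best_cost = bf.cost
            best_mask = mask
            best_pos = bf.position.copy()
        return mask

    x = _power_exponent(cfg, 0)
    for bf in pop:
        score(bf, x)

    for it in range(cfg.max_iter):
        x = _power_exponent(cfg, it)
        iter_best_cost = np.inf
        iter_best_mask = None
        for bf in pop:
            d = rng.uniform()
            if d < cfg.switch_prob_p:
                new_pos = global_search_step(bf.position, best_pos, bf.fragrance, d)
            else:
                mate = pop[rng.integers(cfg.population)]
                new_pos = local_search_step(bf.position, mate.position, bf.fragrance, d)
            new_mask = binarize(new_pos, cfg.binarize_threshold)
            new_cost = evaluator(new_mask)
            # greedy acceptance: a butterfly keeps a move only if it does
            # not worsen its own cost
            if new_cost <= bf.cost:
                bf.position = new_pos
                bf.cost = new_cost
                bf.stimulus = 1.0 / (1.0 + new_cost)
            bf.fragrance = fragrance(bf.stimulus, cfg.sensory_modality_s, x)
            if new_cost < iter_best_cost:
                iter_best_cost = new_cost
                iter_best_mask = new_mask
            if new_cost < best_cost:
                best_cost = new_cost
                best_mask = new_mask
                best_pos = new_pos.copy()
        if cfg.refine_budget > 0 and iter_best_mask is not None:
            ref_mask, ref_cost = _refine_mask(
                evaluator, iter_best_mask, iter_best_cost, cfg.refine_budget
            )
            if ref_cost < best_cost:
                best_cost = ref_cost
                best_mask = ref_mask
                # continuous echo of the refined mask keeps the attractor
                # consistent with the incumbent
                best_pos = np.where(ref_mask, 0.75, 0.25)
        traj[it] = best_cost

    return SelectionResult(
        mask=best_mask,
        selected_indices=sorted(np.flatnonzero(best_mask).tolist()),
        best_cost_per_iter=traj,
        best_cost=float(best_cost),
        config_echo=cfg,
    )


def _refine_mask(
    evaluator: "FitnessEvaluator",
    mask: np.ndarray,
    cost: float,
    budget: int,
) -> tuple[np.ndarray, float]:
    """Elitist hill climb over bit flips and drop/add swaps of one mask.

    Deterministic sweep order; stops at a local optimum of the combined
    neighborhood or when the evaluation budget is spent.
    """
    D = mask.shape[0]
    mask = mask.copy()
    evals = 0
    improved = True
    while improved and evals < budget:
        improved = False
        for j in range(D):
            if evals >= budget:
                break
            cand = mask.copy()
            cand[j] = ~cand[j]
            if not cand.any():
                continue
            c = evaluator(cand)
            evals += 1
            if c < cost:
                cost, mask, improved = c, cand, True
        on = np.flatnonzero(mask)
        off = np.flatnonzero(~mask)
        for a in on:
            if evals >= budget:
                break
            for b in off:
                if evals >= budget:
                    break
                cand = mask.copy()
                cand[a] = False
                cand[b] = True
                c = evaluator(cand)
                evals += 1
                if c < cost:
                    cost, mask, improved = c, cand, True
    return mask, cost


def exhaustive_select(table, labels, cfg: BOAConfig) -> SelectionResult:
    """Exact arg-min over all nonempty masks (oracle; refuses D > 20).

    Ties are broken toward the smaller subset, then lexicographically
    on the sorted selected-index list (lower column indices preferred).
    """
    values, labels = _as_values_labels(table, labels)
    D = values.shape[1]
    if D > 20:
        raise InvalidArgumentError(f"exhaustive search refused for D = {D} > 20")
    evaluator = FitnessEvaluator(values, labels, cfg)
    best = None
    for bits in itertools.product((False, True), repeat=D):
        mask = np.asarray(bits, bool)
        if not mask.any():
            continue
        cost = evaluator(mask)
        key = (cost, int(mask.sum()), tuple(np.flatnonzero(mask)))
        if best is None or key < best[0]:
            best = (key, mask)
    (cost, _, _), mask = best
    return SelectionResult(
        mask=mask,
        selected_indices=sorted(np.flatnonzero(mask).tolist()),
        best_cost_per_iter=np.array([cost]),
        best_cost=float(cost),
        config_echo=cfg,
    )
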