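"""Wrapper feature selection by differential evolution and particle swarm.

Both selectors search the continuous unit box: a candidate is a length-d real
vector, decoded into a feature subset by thresholding (coordinate j selected
when x_j > threshold, with an argmax fallback so the subset is never empty).
The objective, minimized, is the misclassification rate of a 1-nearest-
neighbour classifier evaluated on the decoded column subset — the classic
"fine KNN" wrapper fitness — so the selected subset size is emergent rather
than fixed in advance.

Differential evolution uses rand/1 mutation ``v = x_{r1} + F (x_{r2} - x_{r3})``,
binomial crossover at rate Cr with a guaranteed j_rand coordinate, and greedy
one-to-one replacement (trial replaces target when its error is <= the
target's).  Particle swarm uses the standard inertia form
``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``, ``x <- x + v`` with a
velocity clamp, personal bests updated on strict improvement and the global
best as the best personal best.

Random-stream contract (relied upon by the replay oracles in the test suite):
each run consumes a single ``numpy.random.Generator`` seeded from the config,
in this documented order —

- DE: init ``rng.random((pop, d))``; then per generation, per target i:
  ``rng.choice(others, 3, replace=False)`` for r1..r3, ``rng.integers(d)``
  for j_rand, ``rng.random(d)`` for the crossover draws.
- PSO: init ``rng.random((pop, d))``; then per step, per particle i:
  ``rng.random(d)`` for the cognitive draw then ``rng.random(d)`` for the
  social draw.

The fitness holdout split is driven by ``FitnessSpec.seed`` only, so selector
streams can be replayed independently of the evaluation scheme.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold, train_test_split

from .dataio import FeatureMatrix


@dataclass
class FitnessSpec:
    """1-NN error-rate fitness configuration.

    ``eval_scheme='holdout'`` evaluates on stratified ``holdout_fraction``
    test splits, averaged over ``repeats`` independent splits (cheap, and the
    averaging damps split noise so the wrapper loop sees a more stable
    objective); ``'kfold'`` averages the error over ``folds`` stratified
    folds.  Columns are z-scored with training-split statistics before
    distances are computed.  Splits depend only on the spec (labels, scheme
    and seed), never on the selector's random stream.
    """

    neighbors: int = 1
    distance: str = "euclidean"
    eval_scheme: Literal["holdout", "kfold"] = "holdout"
    holdout_fraction: float = 0.3
    repeats: int = 3
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neighbors < 1:
            raise ValueError("neighbors must be >= 1")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class DEConfig:
    population: int = 50
    scale_factor: float = 0.2      # F, the differential weight
    crossover_rate: float = 0.7    # Cr
    max_generations: int = 50
    bounds: tuple[float, float] = (0.0, 1.0)
    decode_threshold: float = 0.5
    patience: int | None = None    # early stop after this many stale generations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("DE population must be >= 4 (mutation needs "
                             "3 distinct non-target members)")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.bounds[1] < self.bounds[0]:
            raise ValueError("bounds must satisfy min <= max")


@dataclass
class PSOConfig:
    population: int = 50
    inertia: float = 0.7           # w
    cognitive: float = 2.0         # c1
    social: float = 2.0            # c2
    max_generations: int = 50
    velocity_clamp: float | None = None   # default 0.5 * (max - min)
    bounds: tuple[float, float] = (0.0, 1.0)
    decode_threshold: float = 0.5
    patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("PSO population must be >= 2")
        if self.velocity_clamp is None:
            self.velocity_clamp = 0.5 * (self.bounds[1] - self.bounds[0])
        if self.velocity_clamp <= 0:
            raise ValueError("velocity_clamp must be > 0")


@dataclass
class SelectionMask:
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 1 or self.count < 1:
            raise ValueError("mask must be 1-D with at least one selected column")

    @property
    def count(self) -> int:
        return int(self.selected.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


@dataclass
class SelectionResult:
    mask: SelectionMask
    best_fitness: float
    trace: list[float]
    method: str
    config: dict
    seed: int

    def __post_init__(self) -> None:
        if self.trace and abs(self.best_fitness - self.trace[-1]) > 1e-12:
            raise ValueError("best_fitness must equal the final trace entry")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": self.mask.selected.astype(int).tolist(),
            "count": self.mask.count,
            "best_fitness": self.best_fitness,
            "trace": list(self.trace),
            "config": self.config,
            "seed": self.seed,
        }


def decode_mask(position: np.ndarray, threshold: float = 0.5) -> SelectionMask:
    """Threshold a continuous candidate into a feature subset.

    ``selected[j] = position[j] > threshold``; if nothing clears the
    threshold, the single largest coordinate is selected (first index wins
    ties), guaranteeing a non-empty subset.
    """
    position = np.asarray(position, dtype=float)
    selected = position > threshold
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmax(position))] = True
    return SelectionMask(selected=selected)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def _one_nn_error(X_train: np.ndarray, y_train: np.ndarray,
                  X_test: np.ndarray, y_test: np.ndarray,
                  metric: str) -> float:
    """1-NN misclassification rate; exact ties go to the lowest train index."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    dist = cdist((X_test - mu) / sd, (X_train - mu) / sd, metric=metric)
    nearest = np.argmin(dist, axis=1)  # argmin returns the first minimum
    return float(np.mean(y_train[nearest] != y_test))


_SPLIT_CACHE: dict = {}


def _fitness_splits(y: np.ndarray, spec: FitnessSpec) -> list[tuple]:
    """(train_idx, test_idx) pairs for the spec; cached, label-driven only."""
    key = (tuple(y.tolist()), spec.eval_scheme, spec.holdout_fraction,
           spec.repeats, spec.folds, spec.seed)
    if key in _SPLIT_CACHE:
        return _SPLIT_CACHE[key]
    idx = np.arange(len(y))
    if spec.eval_scheme == "holdout":
        splits = []
        for r in range(spec.repeats):
            tr, te = train_test_split(idx, test_size=spec.holdout_fraction,
                                      stratify=y, random_state=spec.seed + r)
            if len(tr) == 0:
                raise ValueError("holdout left an empty training set")
            splits.append((tr, te))
    else:
        skf = StratifiedKFold(n_splits=spec.folds, shuffle=True,
                              random_state=spec.seed)
        splits = [(tr, te) for tr, te in skf.split(idx, y)]
    if len(_SPLIT_CACHE) > 32:
        _SPLIT_CACHE.clear()
    _SPLIT_CACHE[key] = splits
    return splits


def knn_error_fitness(fm: FeatureMatrix, mask: SelectionMask,
                      spec: FitnessSpec) -> float:
    """Misclassification rate of 1-NN on the masked columns, in [0, 1]."""
    if len(fm.classes) < 2:
        raise ValueError("fitness needs at least 2 classes")
    if mask.count < 1:
        raise ValueError("mask selects no columns")
    X = fm.X[:, mask.selected]
    y = fm.y
    errs = [
        _one_nn_error(X[tr], y[tr], X[te], y[te], spec.distance)
        for tr, te in _fitness_splits(y, spec)
    ]
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# differential evolution
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    position: np.ndarray
    fitness: float | None = None


def de_initialize(d: int, cfg: DEConfig,
                  rng: np.random.Generator) -> list[Candidate]:
    """Uniform initialization within the bounds: ``lo + U(0,1) (hi - lo)``."""
    if d < 1:
        raise ValueError("d must be >= 1")
    lo, hi = cfg.bounds
    positions = lo + rng.random((cfg.population, d)) * (hi - lo)
    return [Candidate(position=p) for p in positions]


def de_mutate(population: list[Candidate], cfg: DEConfig,
              rng: np.random.Generator) -> np.ndarray:
    """rand/1 donors, one per target, clipped to bounds after the arithmetic."""
    pop = len(population)
    d = population[0].position.size
    lo, hi = cfg.bounds
    donors = np.empty((pop, d))
    idx = np.arange(pop)
    for i in range(pop):
        others = idx[idx != i]
        r1, r2, r3 = rng.choice(others, size=3, replace=False)
        donor = (population[r1].position
                 + cfg.scale_factor * (population[r2].position
                                       - population[r3].position))
        donors[i] = np.clip(donor, lo, hi)
    return donors


def de_crossover(target: Candidate, donor: np.ndarray, cfg: DEConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover: donor coordinate when draw <= Cr or j == j_rand."""
    d = target.position.size
    jrand = int(rng.integers(d))
    draws = rng.random(d)
    take_donor = (draws <= cfg.crossover_rate) | (np.arange(d) == jrand)
    return np.where(take_donor, donor, target.position)


def de_run(fm: FeatureMatrix, cfg: DEConfig, spec: FitnessSpec,
           callback=None) -> SelectionResult:
    """Full DE wrapper selection loop with greedy one-to-one replacement.

    The trace records the population-best fitness after each generation
    (entry 0 is the initial population), so it is non-increasing by
    construction.  ``callback(generation, best_fitness)`` is invoked per
    generation when given.
    """
    rng = np.random.default_rng(cfg.seed)
    population = de_initialize(fm.d, cfg, rng)

    def fit(position: np.ndarray) -> float:
        return knn_error_fitness(fm, decode_mask(position, cfg.decode_threshold),
                                 spec)

    for cand in population:
        cand.fitness = fit(cand.position)

    trace = [min(c.fitness for c in population)]
    stale = 0
    for gen in range(cfg.max_generations):
        donors = de_mutate(population, cfg, rng)
        for i, target in enumerate(population):
            trial = de_crossover(target, donors[i], cfg, rng)
            trial_fitness = fit(trial)
            if trial_fitness <= target.fitness:
                population[i] = Candidate(position=trial, fitness=trial_fitness)
        best = min(c.fitness for c in population)
        stale = stale + 1 if best >= trace[-1] else 0
        trace.append(best)
        if callback is not None:
            callback(gen, best)
        if cfg.patience is not None and stale >= cfg.patience:
            break

    best_cand = min(population, key=lambda c: c.fitness)
    return SelectionResult(
        mask=decode_mask(best_cand.position, cfg.decode_threshold),
        best_fitness=trace[-1], trace=trace, method="de",
        config=_config_dict(cfg), seed=cfg.seed)


# ---------------------------------------------------------------------------
# particle swarm
# ---------------------------------------------------------------------------

@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    fitness: float | None = None
    best_position: np.ndarray | None = None
    best_fitness: float | None = None


def pso_initialize(d: int, cfg: PSOConfig,
                   rng: np.random.Generator) -> list[Particle]:
    """Uniform positions in the bounds, zero velocities, personal best unset."""
    if d < 1:
        raise ValueError("d must be >= 1")
    lo, hi = cfg.bounds
    positions = lo + rng.random((cfg.population, d)) * (hi - lo)
    return [Particle(position=p, velocity=np.zeros(d)) for p in positions]


def _evaluate_swarm(swarm: list[Particle], fit) -> None:
    for p in swarm:
        p.fitness = fit(p.position)
        if p.best_fitness is None or p.fitness < p.best_fitness:
            p.best_fitness = p.fitness
            p.best_position = p.position.copy()


def _global_best(swarm: list[Particle]) -> Particle:
    return min(swarm, key=lambda p: p.best_fitness)


def pso_step(swarm: list[Particle], cfg: PSOConfig, spec: FitnessSpec,
             fm: FeatureMatrix, rng: np.random.Generator) -> list[Particle]:
    """One synchronous swarm update.

    All velocities/positions move using the global best from the *previous*
    evaluation; then the swarm is re-evaluated, personal bests update on
    strict improvement, and the global best is re-derived from them.
    """
    gb = _global_best(swarm).best_position
    lo, hi = cfg.bounds
    for p in swarm:
        r1 = rng.random(p.position.size)
        r2 = rng.random(p.position.size)
        v = (cfg.inertia * p.velocity
             + cfg.cognitive * r1 * (p.best_position - p.position)
             + cfg.social * r2 * (gb - p.position))
        p.velocity = np.clip(v, -cfg.velocity_clamp, cfg.velocity_clamp)
        p.position = np.clip(p.position + p.velocity, lo, hi)

    def fit(position: np.ndarray) -> float:
        return knn_error_fitness(fm, decode_mask(position, cfg.decode_threshold),
                                 spec)

    _evaluate_swarm(swarm, fit)
    return swarm


def pso_run(fm: FeatureMatrix, cfg: PSOConfig, spec: FitnessSpec,
            callback=None) -> SelectionResult:
    """Full PSO wrapper selection loop; trace is the global-best error."""
    rng = np.random.default_rng(cfg.seed)
    swarm = pso_initialize(fm.d, cfg, rng)

    def fit(position: np.ndarray) -> float:
        return knn_error_fitness(fm, decode_mask(position, cfg.decode_threshold),
                                 spec)

    _evaluate_swarm(swarm, fit)
    trace = [_global_best(swarm).best_fitness]
    stale = 0
    for gen in range(cfg.max_generations):
        swarm = pso_step(swarm, cfg, spec, fm, rng)
        best = _global_best(swarm).best_fitness
        stale = stale + 1 if best >= trace[-1] else 0
        trace.append(best)
        if callback is not None:
            callback(gen, best)
        if cfg.patience is not None and stale >= cfg.patience:
            break

    gb = _global_best(swarm)
    return SelectionResult(
        mask=decode_mask(gb.best_position, cfg.decode_threshold),
        best_fitness=trace[-1], trace=trace, method="pso",
        config=_config_dict(cfg), seed=cfg.seed)


def _config_dict(cfg) -> dict:
    out = asdict(cfg)
    out["bounds"] = list(out["bounds"])
    return out


def run_selector(fm: FeatureMatrix, method: str, cfg, spec: FitnessSpec,
                 callback=None) -> SelectionResult:
    """Dispatch to :func:`de_run` or :func:`pso_run` by method name."""
    if method == "de":
        return de_run(fm, cfg, spec, callback=callback)
    if method == "pso":
        return pso_run(fm, cfg, spec, callback=callback)
    raise ValueError(f"unknown selection method {method!r}")
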