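"""Binary Harris Hawks optimization over gene-inclusion masks.

Harris Hawks optimization (HHO) is a population metaheuristic mimicking
cooperative hawk hunting.  Each hawk holds a continuous position in
[0, 1]^D; rounding each coordinate yields a binary mask over the D
candidate genes (1 = retained).  The best mask ever seen (the "rabbit")
is elitist.  An escape-energy schedule

    E = 2 * E0 * (1 - t / T),    E0 ~ U(-1, 1) per hawk per iteration,

switches the search between global exploration (|E| >= 1) and four
local "besiege" update rules chosen by |E| and a capture-probability
draw r.  The two progressive-dive rules propose Levy-flight jumps and
accept them greedily.

The objective balances a KNN cross-validation error against subset
size:

    fitness = alpha * (1 - KNN_acc) + (1 - alpha) * f_num / F_num

with alpha = 0.99 by default, f_num the mask popcount and F_num = D.
Lower is better; fitness lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma, pi, sin
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .datatypes import ExpressionDataset, GeneSubset, VehError

__all__ = [
    "HHOConfig",
    "FitnessConfig",
    "EnergyState",
    "HawkPosition",
    "HHOTrace",
    "initialize_population",
    "escape_energy",
    "exploration_update",
    "soft_besiege",
    "hard_besiege",
    "levy_flight",
    "soft_besiege_dive",
    "hard_besiege_dive",
    "binarize",
    "repair_empty_mask",
    "fitness_from_accuracy",
    "make_knn_fitness",
    "evaluate_fitness",
    "hho_minimize",
    "hho_select",
]

MaskFitness = Callable[[np.ndarray], float]


@dataclass
class HHOConfig:
    """Optimizer parameters: 30 hawks, 100 generations, positions in [0, 1].

    ``dive_variant`` selects the hard-dive first candidate: ``"original"``
    aims at the population mean, ``"as_printed"`` reuses the soft-dive
    formula (aiming at the current hawk).
    """

    n_hawks: int = 30
    n_iter: int = 100
    lb: float = 0.0
    ub: float = 1.0
    levy_beta: float = 1.5
    levy_scale: float = 0.01
    seed: int = 0
    dive_variant: str = "original"

    def __post_init__(self) -> None:
        if self.n_hawks < 2:
            raise VehError("need at least 2 hawks")
        if self.n_iter < 1:
            raise VehError("need at least 1 iteration")
        if not self.lb < self.ub:
            raise VehError("lb must be < ub")
        if self.dive_variant not in ("original", "as_printed"):
            raise VehError("dive_variant must be 'original' or 'as_printed'")


@dataclass
class FitnessConfig:
    """KNN-fitness parameters: alpha 0.99, k = 5, stratified 5-fold."""

    alpha: float = 0.99
    knn_k: int = 5
    eval_folds: int = 5
    eval_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise VehError("alpha must lie in [0, 1]")
        if self.knn_k < 1 or self.eval_folds < 2:
            raise VehError("knn_k >= 1 and eval_folds >= 2 required")


@dataclass
class EnergyState:
    """One hawk's random draws for a single update step."""

    E0: float = 0.0
    E: float = 0.0
    r5: float = 0.5
    r: float = 0.5
    q: float = 0.5
    r1: float = 0.5
    r2: float = 0.5
    r3: float = 0.5
    r4: float = 0.5

    @property
    def J(self) -> float:
        """Jump strength, 2 * (1 - r5), in (0, 2)."""
        return 2.0 * (1.0 - self.r5)


@dataclass
class HawkPosition:
    """Continuous position with its derived binary mask and fitness."""

    x: np.ndarray
    mask: np.ndarray
    fitness: float = np.inf


@dataclass
class HHOTrace:
    """Convergence record: elitist best fitness per iteration (length T+1)."""

    best_fitness_per_iter: list[float] = field(default_factory=list)
    best_size_per_iter: list[int] = field(default_factory=list)
    evaluations: int = 0


def initialize_population(
    cfg: HHOConfig, D: int, rng: np.random.Generator | None = None
) -> list[HawkPosition]:
    """Draw the initial flock i.i.d. uniform on [lb, ub]^D.

    Masks are derived by rounding and repaired if empty; fitness is
    left unset.  Deterministic given ``cfg.seed`` (or the passed rng).
    """
    if D < 1:
        raise VehError("dimension must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])
    positions = rng.uniform(cfg.lb, cfg.ub, size=(cfg.n_hawks, D))
    hawks: list[HawkPosition] = []
    for i in range(cfg.n_hawks):
        x = positions[i]
        mask = binarize(x)
        if mask.sum() == 0:
            mask, x = repair_empty_mask(mask, x, rng)
        hawks.append(HawkPosition(x=x, mask=mask))
    return hawks


def escape_energy(E0: float, t: int, T: int) -> float:
    """Escape energy 2 * E0 * (1 - t/T), decaying linearly to 0 at t = T."""
    if T <= 0:
        raise VehError("T must be positive")
    return 2.0 * E0 * (1.0 - t / T)


def _clip(x: np.ndarray, cfg: HHOConfig) -> np.ndarray:
    return np.clip(x, cfg.lb, cfg.ub)


def _check_dims(*vecs: np.ndarray) -> None:
    d = {v.shape for v in vecs}
    if len(d) != 1:
        raise VehError(f"dimension mismatch among update vectors: {d}")


def exploration_update(
    x: np.ndarray,
    x_rand: np.ndarray,
    x_rabbit: np.ndarray,
    x_mean: np.ndarray,
    draws: EnergyState,
    cfg: HHOConfig,
) -> np.ndarray:
    """Global search step used when |E| >= 1.

    With probability q >= 0.5 the hawk perches relative to a random
    flock member, otherwise relative to the rabbit and the flock mean.
    """
    _check_dims(x, x_rand, x_rabbit, x_mean)
    if draws.q >= 0.5:
        new = x_rand - draws.r1 * np.abs(x_rand - 2.0 * draws.r2 * x)
    else:
        new = (x_rabbit - x_mean) - draws.r3 * (
            cfg.lb + draws.r4 * (cfg.ub - cfg.lb)
        )
    return _clip(new, cfg)


def soft_besiege(
    x: np.ndarray,
    x_rabbit: np.ndarray,
    E: float,
    r5: float,
    cfg: HHOConfig | None = None,
) -> np.ndarray:
    """Soft besiege (r >= 0.5, 0.5 <= |E| < 1): encircle a lively prey."""
    cfg = cfg or HHOConfig()
    _check_dims(x, x_rabbit)
    J = 2.0 * (1.0 - r5)
    dist = x_rabbit - x
    return _clip(dist - E * np.abs(J * x_rabbit - x), cfg)


def hard_besiege(
    x: np.ndarray,
    x_rabbit: np.ndarray,
    E: float,
    cfg: HHOConfig | None = None,
) -> np.ndarray:
    """Hard besiege (r >= 0.5, |E| < 0.5): pounce on an exhausted prey."""
    cfg = cfg or HHOConfig()
    _check_dims(x, x_rabbit)
    dist = x_rabbit - x
    return _clip(x_rabbit - E * np.abs(dist), cfg)


def levy_sigma(beta: float) -> float:
    """Mantegna scale factor sigma(beta) for the numerator normal draw."""
    num = gamma(1.0 + beta) * sin(pi * beta / 2.0)
    den = gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_flight(
    D: int, beta: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed step vector via the Mantegna construction.

    Each element is ``scale * u * sigma(beta) / |v|**(1/beta)`` with
    u, v independent standard normals; for beta in (1, 2] the absolute
    steps have a power-law tail with index beta.
    """
    if not 1.0 < beta <= 2.0:
        raise VehError("levy beta must lie in (1, 2]")
    u = rng.standard_normal(D)
    v = rng.standard_normal(D)
    return scale * u * levy_sigma(beta) / np.abs(v) ** (1.0 / beta)


def _dive(
    y_target: np.ndarray,
    x: np.ndarray,
    x_rabbit: np.ndarray,
    E: float,
    draws: EnergyState,
    fitness_fn: MaskFitness,
    cfg: HHOConfig,
    rng: np.random.Generator,
    fx: float | None,
) -> tuple[np.ndarray, float | None]:
    """Shared greedy dive: try Y, then a Levy jump Z, else stay put.

    ``y_target`` is the vector inside the |J*x_rabbit - target| term
    (the hawk itself for the soft dive, the flock mean for the original
    hard dive).  Returns (position, fitness or None if unchanged and
    unknown).
    """
    if fx is None:
        fx = _position_fitness(x, fitness_fn, rng)
    Y = _clip(x_rabbit - E * np.abs(draws.J * x_rabbit - y_target), cfg)
    fY = _position_fitness(Y, fitness_fn, rng)
    if fY < fx:
        return Y, fY
    S = rng.uniform(0.0, 1.0, size=x.shape[0])
    Z = _clip(Y + S * levy_flight(x.shape[0], cfg.levy_beta, cfg.levy_scale, rng), cfg)
    fZ = _position_fitness(Z, fitness_fn, rng)
    if fZ < fx:
        return Z, fZ
    return x.copy(), fx


def soft_besiege_dive(
    x: np.ndarray,
    x_rabbit: np.ndarray,
    x_mean: np.ndarray,
    E: float,
    draws: EnergyState,
    fitness_fn: MaskFitness,
    cfg: HHOConfig,
    rng: np.random.Generator,
    fx: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Soft besiege with progressive rapid dives (r < 0.5, |E| >= 0.5)."""
    _check_dims(x, x_rabbit, x_mean)
    return _dive(x, x, x_rabbit, E, draws, fitness_fn, cfg, rng, fx)


def hard_besiege_dive(
    x: np.ndarray,
    x_rabbit: np.ndarray,
    x_mean: np.ndarray,
    E: float,
    draws: EnergyState,
    fitness_fn: MaskFitness,
    cfg: HHOConfig,
    rng: np.random.Generator,
    fx: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Hard besiege with progressive rapid dives (r < 0.5, |E| < 0.5).

    The ``original`` variant aims the first candidate at the flock mean;
    ``as_printed`` reuses the soft-dive candidate.
    """
    _check_dims(x, x_rabbit, x_mean)
    target = x_mean if cfg.dive_variant == "original" else x
    return _dive(target, x, x_rabbit, E, draws, fitness_fn, cfg, rng, fx)


def binarize(x: np.ndarray) -> np.ndarray:
    """Round each coordinate to a bit: 1 iff x_d >= 0.5 (half rounds up)."""
    x = np.asarray(x, dtype=float)
    if ((x < 0.0) | (x > 1.0)).any():
        raise VehError("binarize expects entries in [0, 1]")
    return (x >= 0.5).astype(np.int8)


def repair_empty_mask(
    mask: np.ndarray, x: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Force one uniformly chosen gene into an all-zero mask.

    The objective is undefined for an empty subset, so a single
    coordinate is set to 1 in the mask and to 1.0 in the continuous
    position; everything else is untouched.
    """
    mask = mask.copy()
    x = x.copy()
    j = int(rng.integers(mask.shape[0]))
    mask[j] = 1
    x[j] = 1.0
    return mask, x


def _position_fitness(
    x: np.ndarray, fitness_fn: MaskFitness, rng: np.random.Generator
) -> float:
    mask = binarize(x)
    if mask.sum() == 0:
        mask, _ = repair_empty_mask(mask, x, rng)
    return fitness_fn(mask)


def fitness_from_accuracy(
    knn_acc: float, f_num: int, F_num: int, alpha: float = 0.99
) -> float:
    """Combine classifier accuracy and subset size into the objective.

    ``alpha * (1 - knn_acc) + (1 - alpha) * f_num / F_num`` — an error
    term dominated (alpha = 0.99) by the cross-validated KNN accuracy,
    plus a small pressure toward fewer genes.  Lies in [0, 1].
    """
    if f_num < 1 or f_num > F_num:
        raise VehError("need 1 <= f_num <= F_num")
    return alpha * (1.0 - knn_acc) + (1.0 - alpha) * f_num / F_num


def make_knn_fitness(
    ds: ExpressionDataset, fcfg: FitnessConfig, cache: bool = True
) -> MaskFitness:
    """Build the KNN + size-penalty objective for a preprocessed dataset.

    The stratified folds are frozen from ``eval_seed`` so every mask in
    a run is scored on identical splits; results are cached by mask.
    """
    if fcfg.knn_k >= ds.n_samples:
        raise VehError("knn_k must be smaller than the sample count")
    splitter = StratifiedKFold(
        n_splits=fcfg.eval_folds, shuffle=True, random_state=fcfg.eval_seed
    )
    folds = list(splitter.split(ds.values, ds.labels))
    X, y = ds.values, ds.labels
    D = ds.n_genes
    memo: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        mask = np.asarray(mask)
        f_num = int(mask.sum())
        if f_num == 0:
            raise VehError("fitness undefined for an empty mask")
        key = mask.astype(np.int8).tobytes()
        if cache and key in memo:
            return memo[key]
        cols = np.where(mask != 0)[0]
        Xm = X[:, cols]
        accs = []
        for train, test in folds:
            knn = KNeighborsClassifier(n_neighbors=fcfg.knn_k)
            knn.fit(Xm[train], y[train])
            accs.append(float(np.mean(knn.predict(Xm[test]) == y[test])))
        acc = float(np.mean(accs))
        value = fitness_from_accuracy(acc, f_num, D, fcfg.alpha)
        if cache:
            memo[key] = value
        return value

    return fitness


def evaluate_fitness(
    mask: np.ndarray, ds: ExpressionDataset, fcfg: FitnessConfig
) -> float:
    """One-shot objective evaluation for a single mask."""
    return make_knn_fitness(ds, fcfg, cache=False)(np.asarray(mask))


def hho_minimize(
    fitness_fn: MaskFitness,
    D: int,
    cfg: HHOConfig | None = None,
) -> tuple[HawkPosition, HHOTrace]:
    """Run the full HHO loop against an arbitrary mask objective.

    Returns the elitist best hawk (first encountered among ties) and a
    convergence trace.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or HHOConfig()
    if D < 1:
        raise VehError("dimension must be >= 1")
    # independent substreams: population init, per-hawk draws, dives/repair
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_init = np.random.default_rng(ss[0])
    rng_hawk = np.random.default_rng(ss[1])
    rng_dive = np.random.default_rng(ss[2])

    trace = HHOTrace()
    n_evals = 0

    def eval_mask(mask: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return fitness_fn(mask)

    hawks = initialize_population(cfg, D, rng_init)
    for hawk in hawks:
        hawk.fitness = eval_mask(hawk.mask)

    best_i = int(np.argmin([h.fitness for h in hawks]))
    rabbit = HawkPosition(
        x=hawks[best_i].x.copy(),
        mask=hawks[best_i].mask.copy(),
        fitness=hawks[best_i].fitness,
    )
    trace.best_fitness_per_iter.append(rabbit.fitness)
    trace.best_size_per_iter.append(int(rabbit.mask.sum()))

    T = cfg.n_iter
    for t in range(1, T + 1):
        x_mean = np.mean([h.x for h in hawks], axis=0)
        for i, hawk in enumerate(hawks):
            draws = EnergyState(
                E0=rng_hawk.uniform(-1.0, 1.0),
                r5=rng_hawk.uniform(),
                r=rng_hawk.uniform(),
                q=rng_hawk.uniform(),
                r1=rng_hawk.uniform(),
                r2=rng_hawk.uniform(),
                r3=rng_hawk.uniform(),
                r4=rng_hawk.uniform(),
            )
            E = escape_energy(draws.E0, t, T)
            draws.E = E
            new_fitness: float | None = None
            if abs(E) >= 1.0:
                x_rand = hawks[int(rng_hawk.integers(cfg.n_hawks))].x
                x_new = exploration_update(
                    hawk.x, x_rand, rabbit.x, x_mean, draws, cfg
                )
            elif draws.r >= 0.5 and abs(E) >= 0.5:
                x_new = soft_besiege(hawk.x, rabbit.x, E, draws.r5, cfg)
            elif draws.r >= 0.5:
                x_new = hard_besiege(hawk.x, rabbit.x, E, cfg)
            elif abs(E) >= 0.5:
                x_new, new_fitness = soft_besiege_dive(
                    hawk.x, rabbit.x, x_mean, E, draws,
                    eval_mask, cfg, rng_dive, fx=hawk.fitness,
                )
            else:
                x_new, new_fitness = hard_besiege_dive(
                    hawk.x, rabbit.x, x_mean, E, draws,
                    eval_mask, cfg, rng_dive, fx=hawk.fitness,
                )
            mask_new = binarize(x_new)
            if mask_new.sum() == 0:
                mask_new, x_new = repair_empty_mask(mask_new, x_new, rng_dive)
                new_fitness = None
            if new_fitness is None:
                new_fitness = eval_mask(mask_new)
            hawk.x, hawk.mask, hawk.fitness = x_new, mask_new, new_fitness
            if hawk.fitness < rabbit.fitness:
                rabbit = HawkPosition(
                    x=hawk.x.copy(), mask=hawk.mask.copy(), fitness=hawk.fitness
                )
        trace.best_fitness_per_iter.append(rabbit.fitness)
        trace.best_size_per_iter.append(int(rabbit.mask.sum()))

    trace.evaluations = n_evals
    return rabbit, trace


def hho_select(
    ds: ExpressionDataset,
    hcfg: HHOConfig | None = None,
    fcfg: FitnessConfig | None = None,
) -> tuple[GeneSubset, HHOTrace]:
    """Select a gene subset of a preprocessed dataset by binary HHO."""
    hcfg = hcfg or HHOConfig()
    fcfg = fcfg or FitnessConfig()
    if ds.n_genes < 1:
        raise VehError("dataset has no genes")
    fitness = make_knn_fitness(ds, fcfg)
    rabbit, trace = hho_minimize(fitness, ds.n_genes, hcfg)
    ids = [ds.feature_ids[j] for j in np.where(rabbit.mask != 0)[0]]
    return GeneSubset(feature_ids=ids, fitness=rabbit.fitness), trace
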