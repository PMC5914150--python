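"""Wrapper feature selection over regional graph metrics.

The selection problem is the binary program

    maximize f(x),   x_k in {0, 1},  k = 1..d,

where x selects a subset of the d regional metric values and f(x) is the
leave-one-subject-out cross-validated accuracy of an RBF C-SVM trained on
the selected features.  It is solved with a Holland-style generational
genetic algorithm: binary chromosomes of length d, tournament selection
(size 4), two-point crossover, bit-flip mutation, and the LOSOCV accuracy
as the fitness.  The conventional baseline selects instead the regions
whose metric increases significantly from the low-load to the high-load
condition (one-sided paired t-test, uncorrected), then classifies on them.

Two statsmodels-style entry points wrap the procedures:
``GAFeatureSelection(table).fit()`` and ``ManualFeatureSelection(table).fit()``
both return results objects carrying the selected mask, the cross-validated
accuracy, the chosen hyperparameters, and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    CVResult,
    DegenerateMaskError,
    HyperGrid,
    SvmHyperparams,
    grid_search,
)
from .graph_metrics import FeatureTable

__all__ = [
    "SelectionMask",
    "GAConfig",
    "GAResult",
    "evaluate_fitness",
    "two_point_crossover",
    "bit_flip_mutation",
    "tournament_select",
    "run_ga",
    "manual_selection",
    "GAFeatureSelection",
    "ManualFeatureSelection",
    "GAFeatureSelectionResults",
    "ManualSelectionResults",
]


@dataclass
class SelectionMask:
    """Binary decision vector x: x_k = 1 keeps region k's metric."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(np.int8)
        if self.bits.ndim != 1:
            raise ValueError("mask must be a 1-D bit vector")
        if not np.all(np.isin(self.bits, (0, 1))):
            raise ValueError("mask entries must be 0/1")

    def __len__(self) -> int:
        return self.bits.size

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def region_names(self, names) -> list[str]:
        return [names[i] for i in self.indices()]

    @classmethod
    def from_indices(cls, indices, d: int) -> "SelectionMask":
        bits = np.zeros(d, dtype=np.int8)
        bits[np.asarray(list(indices), dtype=int)] = 1
        return cls(bits)

    def key(self) -> bytes:
        return self.bits.tobytes()


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 100
    crossover_rate: float = 0.7
    mutation_rate: float = 0.5  # per-individual probability of mutating at all
    per_gene_flip_prob: float | None = None  # defaults to 1/d at run time
    tournament_size: int = 4
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if self.tournament_size < 1 or self.tournament_size > self.population_size:
            raise ValueError("tournament_size must be in [1, population_size]")


@dataclass
class GAResult:
    best_mask: SelectionMask
    best_fitness: float
    fitness_history: pd.DataFrame  # columns: generation, best, mean
    final_cv: CVResult
    rng_seed: int | None
    n_fitness_evaluations: int = 0


def evaluate_fitness(mask: SelectionMask, ft: FeatureTable, grid: HyperGrid) -> float:
    """LOSOCV grid-search accuracy of the masked features; empty mask -> 0."""
    try:
        return grid_search(ft, mask, grid).accuracy
    except DegenerateMaskError:
        return 0.0


def two_point_crossover(
    p1: SelectionMask, p2: SelectionMask, rng: np.random.Generator
) -> tuple[SelectionMask, SelectionMask]:
    """Exchange the segment between two uniform cut points.

    Cut points are slice positions in [0, d]; equal cuts exchange nothing.
    The positionwise multiset of bits over the pair is preserved.
    """
    if len(p1) != len(p2):
        raise ValueError("parents must have equal length")
    d = len(p1)
    lo, hi = sorted(rng.integers(0, d + 1, size=2).tolist())
    c1, c2 = p1.bits.copy(), p2.bits.copy()
    c1[lo:hi], c2[lo:hi] = p2.bits[lo:hi].copy(), p1.bits[lo:hi].copy()
    return SelectionMask(c1), SelectionMask(c2)


def bit_flip_mutation(
    m: SelectionMask, per_gene_flip_prob: float, rng: np.random.Generator
) -> SelectionMask:
    """Flip each bit independently with the given probability."""
    if not 0.0 <= per_gene_flip_prob <= 1.0:
        raise ValueError("per_gene_flip_prob must lie in [0, 1]")
    flips = rng.random(len(m)) < per_gene_flip_prob
    return SelectionMask(np.where(flips, 1 - m.bits, m.bits))


def tournament_select(
    pop: list[SelectionMask],
    fitnesses,
    k: int,
    count: int,
    rng: np.random.Generator,
) -> list[SelectionMask]:
    """Repeat ``count`` times: draw k uniformly with replacement, copy the fittest.

    Ties break toward the earliest-drawn contestant (the convention of the
    usual GA frameworks): deterministic given the generator state, and under
    all-equal fitness the selection reduces to a uniform resample.
    """
    if not pop:
        raise ValueError("empty population")
    if k > len(pop):
        raise ValueError(f"tournament size {k} exceeds population {len(pop)}")
    fitnesses = np.asarray(fitnesses, dtype=float)
    selected = []
    for _ in range(count):
        drawn = rng.integers(0, len(pop), size=k)
        winner = drawn[0]
        for i in drawn[1:]:
            if fitnesses[i] > fitnesses[winner]:
                winner = i
        selected.append(SelectionMask(pop[winner].bits.copy()))
    return selected


def run_ga(
    ft: FeatureTable,
    cfg: GAConfig | None = None,
    grid: HyperGrid | None = None,
    final_grid: HyperGrid | None = None,
    progress: bool = False,
    initial_population: list[SelectionMask] | None = None,
) -> GAResult:
    """Generational GA over selection masks with best-ever tracking.

    The population is initialized with i.i.d. Bernoulli(0.5) bits.  Each
    generation applies tournament selection, pairs consecutive individuals
    of the shuffled selection for two-point crossover (probability
    ``crossover_rate`` per pair), mutates each individual with probability
    ``mutation_rate`` (then flips each gene with ``per_gene_flip_prob``,
    default 1/d), and re-evaluates fitness.  There is no elitism in the
    population itself; the returned optimum is the best individual ever
    evaluated.  Fitness values are cached by mask, and the final result is
    re-scored on ``final_grid`` (the full grid by default).
    """
    cfg = cfg or GAConfig()
    grid = grid or HyperGrid.coarse()
    final_grid = final_grid or HyperGrid.default()
    rng = np.random.default_rng(cfg.rng_seed)
    d = ft.d
    flip_p = cfg.per_gene_flip_prob if cfg.per_gene_flip_prob is not None else 1.0 / d

    cache: dict[bytes, float] = {}
    n_evals = 0

    def fitness(mask: SelectionMask) -> float:
        nonlocal n_evals
        key = mask.key()
        if key not in cache:
            cache[key] = evaluate_fitness(mask, ft, grid)
            n_evals += 1
        return cache[key]

    if initial_population is not None:
        if len(initial_population) != cfg.population_size:
            raise ValueError("initial_population size must equal population_size")
        pop = [SelectionMask(m.bits.copy()) for m in initial_population]
    else:
        pop = [
            SelectionMask(rng.integers(0, 2, size=d))
            for _ in range(cfg.population_size)
        ]
    fits = np.array([fitness(m) for m in pop])
    best_i = int(np.argmax(fits))
    best_mask = SelectionMask(pop[best_i].bits.copy())
    best_fit = float(fits[best_i])
    history = [(0, best_fit, float(fits.mean()))]

    for gen in range(1, cfg.generations + 1):
        selected = tournament_select(
            pop, fits, cfg.tournament_size, cfg.population_size, rng
        )
        order = rng.permutation(len(selected))
        shuffled = [selected[i] for i in order]
        for i in range(0, len(shuffled) - 1, 2):
            if rng.random() < cfg.crossover_rate:
                shuffled[i], shuffled[i + 1] = two_point_crossover(
                    shuffled[i], shuffled[i + 1], rng
                )
        pop = [
            bit_flip_mutation(m, flip_p, rng) if rng.random() < cfg.mutation_rate else m
            for m in shuffled
        ]
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = SelectionMask(pop[gen_best].bits.copy())
        history.append((gen, best_fit, float(fits.mean())))
        if progress:
            print(f"  gen {gen:3d}  best-ever {best_fit:.4f}  mean {fits.mean():.4f}")

    final_cv = grid_search(ft, best_mask, final_grid)
    return GAResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        fitness_history=pd.DataFrame(history, columns=["generation", "best", "mean"]),
        final_cv=final_cv,
        rng_seed=cfg.rng_seed,
        n_fitness_evaluations=n_evals,
    )


def manual_selection(
    ft: FeatureTable, alpha: float = 0.05, grid: HyperGrid | None = None
) -> tuple[SelectionMask, CVResult]:
    """Significance-based baseline: keep regions whose metric increases.

    Per region, a one-sided paired t-test (high-load condition greater than
    low-load, across subjects, uncorrected) selects regions at p < alpha;
    the SVM is then grid-searched on that mask.  If nothing is significant
    the result carries an empty mask and accuracy 0.
    """
    grid = grid or HyperGrid.default()
    diff = ft.paired_difference()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_1samp(diff, 0.0, axis=0, alternative="greater")
        pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    mask = SelectionMask((pvals < alpha).astype(np.int8))
    if mask.n_selected == 0:
        warnings.warn(
            "no region significant at alpha=%g; empty baseline mask" % alpha,
            stacklevel=2,
        )
        cv = CVResult(
            accuracy=0.0,
            per_fold_predictions=np.array([]),
            hyperparams=None,
            true_labels=ft.labels.copy(),
        )
        return mask, cv
    return mask, grid_search(ft, mask, grid)


# ---------------------------------------------------------------------------
# Model / Results layer


class _SelectionResults:
    """Shared result surface: mask, accuracy, hyperparameters, summary."""

    method = "selection"

    def __init__(self, model, mask: SelectionMask, cv: CVResult):
        self.model = model
        self.mask = mask
        self.cv = cv

    @property
    def table(self) -> FeatureTable:
        return self.model.table

    @property
    def accuracy(self) -> float:
        return self.cv.accuracy

    @property
    def hyperparams(self) -> SvmHyperparams | None:
        return self.cv.hyperparams

    @property
    def selected_regions(self) -> list[str]:
        return self.mask.region_names(self.table.region_names)

    def to_dict(self) -> dict:
        hp = self.cv.hyperparams
        return {
            "method": self.method,
            "metric": self.table.metric_name,
            "accuracy": self.accuracy,
            "cost": None if hp is None else hp.C,
            "gamma": None if hp is None else hp.gamma,
            "n_selected": self.mask.n_selected,
            "selected_regions": self.selected_regions,
            "mask": self.mask.bits.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        hp = self.cv.hyperparams
        lines = [
            f"{self.method} feature selection — metric: {self.table.metric_name}",
            "=" * 58,
            f"subjects: {self.table.n_subjects}   regions: {self.table.d}   "
            f"selected: {self.mask.n_selected}",
            f"LOSOCV accuracy: {100 * self.accuracy:.2f}%",
        ]
        if hp is not None:
            lines.append(f"cost C: {hp.C:.3g}   gamma: {hp.gamma:.3g}")
        lines.append("-" * 58)
        lines.append("selected regions:")
        for name in self.selected_regions:
            lines.append(f"  {name}")
        return "\n".join(lines)


class GAFeatureSelectionResults(_SelectionResults):
    method = "ga"

    def __init__(self, model, ga_result: GAResult):
        super().__init__(model, ga_result.best_mask, ga_result.final_cv)
        self.ga_result = ga_result
        self.fitness_history = ga_result.fitness_history
        self.best_fitness = ga_result.best_fitness

    def to_dict(self) -> dict:
        out = super().to_dict()
        out["best_fitness"] = self.best_fitness
        out["rng_seed"] = self.ga_result.rng_seed
        out["n_fitness_evaluations"] = self.ga_result.n_fitness_evaluations
        return out

    def plot_fitness(self, ax=None):
        """Best-ever and mean fitness per generation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.fitness_history
        ax.plot(h["generation"], h["best"], label="best-ever")
        ax.plot(h["generation"], h["mean"], label="population mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("LOSOCV accuracy (fitness)")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


class ManualSelectionResults(_SelectionResults):
    method = "manual"

    def __init__(self, model, mask: SelectionMask, cv: CVResult, alpha: float):
        super().__init__(model, mask, cv)
        self.alpha = alpha

    def to_dict(self) -> dict:
        out = super().to_dict()
        out["alpha"] = self.alpha
        return out


class _SelectionModel:
    def __init__(self, table: FeatureTable):
        self.table = table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(FeatureTable.from_dataframe(df), **kwargs)


class GAFeatureSelection(_SelectionModel):
    """GA wrapper selection model over a feature table.

    Parameters
    ----------
    table : FeatureTable
        Subjects x regions metric values for both conditions.
    config : GAConfig, optional
        GA parameters (population 100, generations 100, crossover 0.7,
        mutation 0.5, tournament 4 by default).
    fitness_grid, final_grid : HyperGrid, optional
        Grids used during fitness evaluation (coarse 3x3 by default) and
        for the final reported cross-validation (full grid by default).
    """

    def __init__(
        self,
        table: FeatureTable,
        config: GAConfig | None = None,
        fitness_grid: HyperGrid | None = None,
        final_grid: HyperGrid | None = None,
    ):
        super().__init__(table)
        self.config = config or GAConfig()
        self.fitness_grid = fitness_grid or HyperGrid.coarse()
        self.final_grid = final_grid or HyperGrid.default()

    def fit(self, seed: int | None = None, progress: bool = False):
        cfg = self.config
        if seed is not None:
            cfg = GAConfig(**{**cfg.__dict__, "rng_seed": seed})
        res = run_ga(self.table, cfg, self.fitness_grid, self.final_grid, progress)
        return GAFeatureSelectionResults(self, res)


class ManualFeatureSelection(_SelectionModel):
    """Significance-based baseline selection model (paired t-test, p < alpha)."""

    def __init__(
        self, table: FeatureTable, alpha: float = 0.05, grid: HyperGrid | None = None
    ):
        super().__init__(table)
        self.alpha = alpha
        self.grid = grid or HyperGrid.default()

    def fit(self):
        mask, cv = manual_selection(self.table, self.alpha, self.grid)
        return ManualSelectionResults(self, mask, cv, self.alpha)
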