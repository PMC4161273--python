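"""Island-model grammatical evolution with balanced-accuracy fitness.

The total population is split into demes (sub-populations).  Each deme
evolves independently — tournament selection, single-point codon crossover,
per-codon reset mutation, elitism — except that every ``migration_interval``
generations the best genome of each deme replaces the worst genome of the
next deme around a ring.  Fitness is the balanced accuracy (mean of
sensitivity and specificity) of the mapped model's predictions on the
training data, which keeps selection honest under heavy class imbalance;
genomes whose derivation fails receive fitness 0 and stay in the population.

Reproducibility: one master seed; every deme draws from its own child
stream spawned deterministically from it, so serial and multi-worker runs
produce identical results.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import yaml
from joblib import Parallel, delayed

from .grammar import (
    CODON_MAX,
    MAX_GENOME_LEN,
    MIN_GENOME_LEN,
    Genome,
    Grammar,
    default_grammar,
    map_genome,
)
from .io import PhenotypeVector
from .model import NetworkModel, raw_output
from .transform import KnowledgeMatrix

__all__ = [
    "EvolutionConfig",
    "ConfusionCounts",
    "FitnessRecord",
    "FitnessEvaluator",
    "balanced_accuracy",
    "confusion_from_predictions",
    "random_valid_genome",
    "initialize_population",
    "evaluate_fitness",
    "evolve_deme",
    "migrate",
    "run_evolution",
    "DESK_CONFIG",
    "FULL_SCALE_CONFIG",
]


@dataclass(frozen=True)
class EvolutionConfig:
    pop_per_deme: int = 150
    n_demes: int = 3
    generations: int = 40
    migration_interval: int = 10
    crossover_prob: float = 0.9
    mutation_prob_per_codon: float = 0.01
    tournament_size: int = 2
    elitism: int = 1
    wrap_limit: int = 2
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        for name in ("pop_per_deme", "n_demes", "generations", "migration_interval",
                     "tournament_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("crossover_prob", "mutation_prob_per_codon"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elitism < 0 or self.elitism > self.pop_per_deme:
            raise ValueError("elitism must be in [0, pop_per_deme]")
        if self.migration_interval > self.generations:
            raise ValueError("migration_interval must be <= generations")
        if self.wrap_limit < 0:
            raise ValueError("wrap_limit must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvolutionConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh, sort_keys=True)


#: small profile used throughout the test battery and analysis scripts
DESK_CONFIG = EvolutionConfig()

#: cluster-sized full-scale run profile (not exercised by tests)
FULL_SCALE_CONFIG = EvolutionConfig(
    pop_per_deme=25_000, n_demes=20, generations=300, migration_interval=15
)


# ---------------------------------------------------------------------------
# fitness


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def balanced_accuracy(c: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2; requires both classes present."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("balanced accuracy needs both classes present")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return (sens + spec) / 2.0


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must align")
    return ConfusionCounts(
        tp=int(np.count_nonzero(y_true & y_pred)),
        fp=int(np.count_nonzero(~y_true & y_pred)),
        tn=int(np.count_nonzero(~y_true & ~y_pred)),
        fn=int(np.count_nonzero(y_true & ~y_pred)),
    )


@dataclass
class FitnessRecord:
    genome: Genome
    model: Optional[NetworkModel]
    fitness: float
    model_text: Optional[str] = None

    @property
    def success(self) -> bool:
        return self.model is not None


class FitnessEvaluator:
    """Maps genomes and scores them on one fixed training matrix.

    Caches genome→phenotype mappings (keyed by a digest of the codons) and
    phenotype→fitness values (keyed by model text), which removes most of
    the cost of re-evaluating elites and converged populations.
    """

    def __init__(
        self,
        matrix: KnowledgeMatrix,
        labels: PhenotypeVector,
        grammar: Optional[Grammar] = None,
    ):
        if matrix.sample_ids != labels.sample_ids:
            raise ValueError("matrix and labels are not sample-aligned")
        if not labels.both_classes_present():
            raise ValueError("training labels must contain both classes")
        self.grammar = grammar or default_grammar(matrix.feature_ids)
        self.columns = matrix.columns()
        self.y = labels.labels.astype(bool)
        self.n_pos = int(self.y.sum())
        self.n_neg = int((~self.y).sum())
        self._map_cache: dict[bytes, Optional[str]] = {}
        self._models: dict[str, NetworkModel] = {}
        self._fit_cache: dict[str, float] = {}

    def _map(self, genome: Genome) -> Optional[str]:
        key = hashlib.blake2b(
            genome.codons.tobytes() + bytes([genome.wrap_limit & 0xFF]),
            digest_size=16,
        ).digest()
        if key in self._map_cache:
            return self._map_cache[key]
        outcome = map_genome(genome, self.grammar)
        text = outcome.text if outcome.success else None
        if text is not None and text not in self._models:
            self._models[text] = outcome.model
        self._map_cache[key] = text
        return text

    def fitness_of_model(self, model: NetworkModel) -> float:
        raw = np.asarray(raw_output(model, self.columns), dtype=float)
        if raw.ndim == 0:
            raw = np.full(self.y.shape, float(raw))
        pred = raw >= 0.0  # logistic(raw) >= 0.5, ties to the positive class
        tp = int(np.count_nonzero(pred & self.y))
        tn = int(np.count_nonzero(~pred & ~self.y))
        return 0.5 * (tp / self.n_pos + tn / self.n_neg)

    def evaluate(self, genome: Genome) -> FitnessRecord:
        text = self._map(genome)
        if text is None:
            return FitnessRecord(genome, None, 0.0)
        fitness = self._fit_cache.get(text)
        model = self._models[text]
        if fitness is None:
            fitness = self.fitness_of_model(model)
            self._fit_cache[text] = fitness
        return FitnessRecord(genome, model, fitness, model_text=text)


def evaluate_fitness(
    genome: Genome,
    grammar: Grammar,
    train: KnowledgeMatrix,
    labels: PhenotypeVector,
) -> FitnessRecord:
    """One-off fitness evaluation (see :class:`FitnessEvaluator` for bulk use)."""
    return FitnessEvaluator(train, labels, grammar).evaluate(genome)


# ---------------------------------------------------------------------------
# initialization: grow a valid derivation, reverse-encode it as codons


def _min_depths(grammar: Grammar) -> dict[str, int]:
    """Minimum derivation depth to a terminal-only string, per nonterminal."""
    depths: dict[str, int] = {}
    changed = True
    while changed:
        changed = False
        for nt, alts in grammar.productions.items():
            best = None
            for alt in alts:
                worst = 0
                ok = True
                for sym in alt:
                    if grammar.is_nonterminal(sym):
                        if sym not in depths:
                            ok = False
                            break
                        worst = max(worst, depths[sym])
                if ok:
                    cand = 1 + worst
                    best = cand if best is None else min(best, cand)
            if best is not None and depths.get(nt) != best:
                depths[nt] = best
                changed = True
    missing = set(grammar.productions) - set(depths)
    if missing:
        raise ValueError(f"nonterminal(s) cannot terminate: {sorted(missing)}")
    return depths


def _grow(
    grammar: Grammar,
    depths: dict[str, int],
    rng: np.random.Generator,
    symbol: str,
    budget: int,
    choices: list[tuple[int, int]],
) -> None:
    if not grammar.is_nonterminal(symbol):
        return
    alts = grammar.alternatives(symbol)
    if len(alts) == 1:
        chosen = 0
    else:
        feasible = [
            i
            for i, alt in enumerate(alts)
            if all(
                not grammar.is_nonterminal(s) or depths[s] <= budget - 1
                for s in alt
            )
        ]
        if not feasible:  # budget exhausted: fall back to a min-depth alternative
            mins = [
                1 + max(
                    (depths[s] for s in alt if grammar.is_nonterminal(s)),
                    default=0,
                )
                for alt in alts
            ]
            feasible = [i for i, m in enumerate(mins) if m == min(mins)]
        chosen = int(feasible[rng.integers(0, len(feasible))])
        choices.append((chosen, len(alts)))
    for sym in alts[chosen]:
        _grow(grammar, depths, rng, sym, budget - 1, choices)


#: symbol-depth budget for grown derivations (≈ five node levels)
_GROW_BUDGET = 11


def random_valid_genome(
    grammar: Grammar,
    rng: np.random.Generator,
    wrap_limit: int = 2,
    max_tries: int = 50,
) -> Genome:
    """Grow a random valid derivation and reverse-encode it as codons.

    Every choice (i of k) becomes a codon congruent to i mod k with a random
    multiple of k added, then the genome is padded with random codons to a
    random length in [MIN_GENOME_LEN, MAX_GENOME_LEN] — so generation-0
    individuals always map to functional networks while their genetic
    material stays diverse.
    """
    depths = _min_depths(grammar)
    encoded: list[int] = []
    for _ in range(max_tries):
        choices: list[tuple[int, int]] = []
        _grow(grammar, depths, rng, grammar.start, _GROW_BUDGET, choices)
        encoded = [
            int(i + k * rng.integers(0, (CODON_MAX - 1 - i) // k + 1))
            for i, k in choices
        ]
        if len(encoded) <= MAX_GENOME_LEN:
            break
    target = int(rng.integers(max(MIN_GENOME_LEN, len(encoded)),
                              max(MAX_GENOME_LEN, len(encoded)) + 1))
    pad = rng.integers(0, CODON_MAX, size=target - len(encoded))
    return Genome(np.concatenate([np.asarray(encoded, dtype=np.int64),
                                  pad.astype(np.int64)]), wrap_limit)


def initialize_population(
    config: EvolutionConfig,
    grammar: Grammar,
    rng: Optional[np.random.Generator] = None,
) -> list[Genome]:
    """pop_per_deme × n_demes genomes, all mapping to functional networks."""
    rng = rng or np.random.default_rng(config.seed)
    return [
        random_valid_genome(grammar, rng, config.wrap_limit)
        for _ in range(config.pop_per_deme * config.n_demes)
    ]


# ---------------------------------------------------------------------------
# variation and migration


def _tournament(
    records: Sequence[FitnessRecord], rng: np.random.Generator, size: int
) -> FitnessRecord:
    idx = rng.integers(0, len(records), size=size)
    best = idx[0]
    for i in idx[1:]:
        if records[i].fitness > records[best].fitness:
            best = i
    return records[int(best)]


def _mutate_inplace(
    codons: np.ndarray, rng: np.random.Generator, prob: float
) -> None:
    if prob <= 0.0:
        return
    mask = rng.random(codons.size) < prob
    n = int(mask.sum())
    if n:
        codons[mask] = rng.integers(0, CODON_MAX, size=n)


def evolve_deme(
    records: Sequence[FitnessRecord],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> list[Genome]:
    """Produce the next generation of one deme.

    Elites are copied unchanged; the rest come from tournament selection,
    aligned single-point crossover and per-codon reset mutation.  Population
    size is preserved.
    """
    n = len(records)
    order = sorted(range(n), key=lambda i: -records[i].fitness)
    nxt: list[Genome] = [records[i].genome for i in order[: config.elitism]]
    while len(nxt) < n:
        p1 = _tournament(records, rng, config.tournament_size)
        p2 = _tournament(records, rng, config.tournament_size)
        g1, g2 = p1.genome.codons, p2.genome.codons
        if rng.random() < config.crossover_prob:
            cut = int(rng.integers(1, min(g1.size, g2.size)))
            c1 = np.concatenate([g1[:cut], g2[cut:]])
            c2 = np.concatenate([g2[:cut], g1[cut:]])
        else:
            c1, c2 = g1.copy(), g2.copy()
        for child in (c1, c2):
            if len(nxt) >= n:
                break
            _mutate_inplace(child, rng, config.mutation_prob_per_codon)
            nxt.append(Genome(child, config.wrap_limit))
    return nxt


def migrate(
    demes: list[list[FitnessRecord]], config: EvolutionConfig
) -> list[list[FitnessRecord]]:
    """Ring migration: deme i's best replaces deme (i+1)'s worst.

    All bests are taken from the pre-migration state, so the global best
    can never decrease across a migration event.  No-op for one deme.
    """
    k = len(demes)
    if k <= 1:
        return [list(d) for d in demes]
    bests = []
    for d in demes:
        bi = max(range(len(d)), key=lambda i: (d[i].fitness, -i))
        bests.append(d[bi])
    out = []
    for j in range(k):
        d = list(demes[j])
        wi = min(range(len(d)), key=lambda i: (d[i].fitness, i))
        d[wi] = bests[(j - 1) % k]
        out.append(d)
    return out


# ---------------------------------------------------------------------------
# main loop


def write_log_tsv(log: list[dict], path: str | Path) -> None:
    """Per-generation, per-deme best/mean fitness as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("generation\tdeme\tbest_fitness\tmean_fitness\n")
        for row in log:
            fh.write(
                f"{row['generation']}\t{row['deme']}\t"
                f"{row['best_fitness']:.6f}\t{row['mean_fitness']:.6f}\n"
            )


def run_evolution(
    train: KnowledgeMatrix,
    labels: PhenotypeVector,
    config: EvolutionConfig,
    grammar: Optional[Grammar] = None,
    log: Optional[list[dict]] = None,
) -> FitnessRecord:
    """Evolve against the training data; return the best-ever record.

    Fully reproducible from ``config.seed``: each deme owns a child random
    stream spawned from the master seed, and cross-deme steps (migration,
    best-ever bookkeeping) run serially, so the result is independent of
    ``n_jobs``.
    """
    if not labels.both_classes_present():
        raise ValueError("labels must contain both classes")
    evaluator = FitnessEvaluator(train, labels, grammar)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_demes)
    rngs = [np.random.default_rng(s) for s in streams]
    pops: list[list[Genome]] = [
        [
            random_valid_genome(evaluator.grammar, rngs[d], config.wrap_limit)
            for _ in range(config.pop_per_deme)
        ]
        for d in range(config.n_demes)
    ]
    best: Optional[FitnessRecord] = None

    def eval_deme(pop: list[Genome]) -> list[FitnessRecord]:
        return [evaluator.evaluate(g) for g in pop]

    parallel = (
        Parallel(n_jobs=config.n_jobs, backend="threading")
        if config.n_jobs > 1
        else None
    )
    for gen in range(config.generations):
        if parallel is not None:
            records = parallel(delayed(eval_deme)(pop) for pop in pops)
        else:
            records = [eval_deme(pop) for pop in pops]
        for d, recs in enumerate(records):
            fits = [r.fitness for r in recs]
            deme_best = max(fits)
            if log is not None:
                log.append(
                    {
                        "generation": gen,
                        "deme": d,
                        "best_fitness": deme_best,
                        "mean_fitness": float(np.mean(fits)),
                    }
                )
            for r in recs:
                if best is None or r.fitness > best.fitness:
                    best = r
        last = gen == config.generations - 1
        if not last and config.n_demes > 1 and (gen + 1) % config.migration_interval == 0:
            records = migrate(records, config)
        if not last:
            pops = [
                evolve_deme(records[d], config, rngs[d])
                for d in range(config.n_demes)
            ]
    assert best is not None
    return best
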