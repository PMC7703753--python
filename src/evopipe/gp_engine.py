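"""Genetic-programming search over pipeline expression trees.

The evolutionary loop follows the scheme of tree-based pipeline
optimisation: a population of random pipelines is evolved through one-point
crossover, operator mutation (insert / remove / substitute / hyperparameter
resample), elitist replacement (the single best pipeline is copied into 10%
of the next generation's slots, protected from variation) and three-way
tournament selection with two-way parsimony (drop the lowest-fitness of
three, keep the less complex of the remaining two).  A Pareto archive of
(balanced accuracy up, complexity down) non-dominated pipelines is
maintained across the whole run.

Because evolutionary search is stochastic, the representative-model
protocol re-runs the search under ``n_seeds`` different seeds and keeps the
run whose best pipeline has the highest mean CV balanced accuracy.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .data_model import LabeledDataset
from .operator_catalog import OperatorCatalog
from .pipeline_tree import (
    CombineNode,
    DataLeaf,
    FitnessRecord,
    OperatorNode,
    PipelineTree,
    _count_ops,
    evaluate_cv,
    iter_nodes,
    random_pipeline,
)

logger = logging.getLogger(__name__)


@dataclass
class GPConfig:
    """Search hyperparameters.

    Defaults follow the study protocol: population 1000, up to 1000
    generations or a wall-clock budget (whichever happens first), 10-fold CV
    balanced accuracy fitness, 10% elitism, three-way tournaments.
    """

    population_size: int = 1000
    max_generations: int = 1000
    time_budget: float | None = 24 * 3600.0  # seconds; None = unlimited
    crossover_rate: float = 0.1
    mutation_rate: float = 0.9
    elite_fraction: float = 0.10
    tournament_size: int = 3
    n_folds: int = 10
    seed: int = 0
    max_operators: int = 10
    redraw_folds: bool = False
    n_jobs: int = 1

    def __post_init__(self):
        if self.population_size < 10:
            raise ValueError("population_size must be >= 10")
        if not (0.0 <= self.crossover_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")

    @property
    def n_elite(self) -> int:
        return max(1, int(np.floor(self.elite_fraction * self.population_size + 0.5)))


@dataclass
class SearchResult:
    """Outcome of one GP run."""

    best_tree: PipelineTree
    best_record: FitnessRecord
    pareto_archive: list  # [(tree, record)] non-dominated
    history: list  # per generation: {"generation", "best", "mean"}
    seed: int
    n_evaluations: int = 0
    evaluations: dict = field(default_factory=dict)  # serialized tree -> record


# ---------------------------------------------------------------------------
# Structural edit helpers
# ---------------------------------------------------------------------------

def _edges(tree: PipelineTree):
    """All (parent, key, node) edges below the root, pre-order."""
    out = []

    def walk(parent, key, node):
        out.append((parent, key, node))
        if isinstance(node, OperatorNode):
            walk(node, "child", node.child)
        elif isinstance(node, CombineNode):
            for i, c in enumerate(node.children):
                walk(node, i, c)

    walk(tree.root, "child", tree.root.child)
    return out


def _set_child(parent, key, node):
    if isinstance(parent, OperatorNode):
        parent.child = node
    else:
        parent.children[key] = node


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def crossover(
    a: PipelineTree,
    b: PipelineTree,
    rng: np.random.Generator,
    max_operators: int | None = None,
):
    """One-point crossover: swap one compatible subtree between two parents.

    A point pair is compatible when exchanging the subtrees leaves both
    offspring valid (the classifier stays unique at each root, and neither
    offspring exceeds ``max_operators``).  If no compatible pair exists the
    parents are returned unchanged.
    """
    a2, b2 = a.clone(), b.clone()
    edges_a = _edges(a2)
    edges_b = _edges(b2)
    ca, cb = a2.complexity(), b2.complexity()
    pairs = []
    for i, (_, _, na) in enumerate(edges_a):
        oa = _count_ops(na)
        for j, (_, _, nb) in enumerate(edges_b):
            ob = _count_ops(nb)
            new_ca = ca - oa + ob
            new_cb = cb - ob + oa
            if new_ca < 1 or new_cb < 1:
                continue
            if max_operators is not None and (new_ca > max_operators or new_cb > max_operators):
                continue
            pairs.append((i, j))
    if not pairs:
        logger.debug("crossover: no compatible point pair; parents unchanged")
        return a.clone(), b.clone()
    i, j = pairs[rng.integers(len(pairs))]
    pa, ka, na = edges_a[i]
    pb, kb, nb = edges_b[j]
    _set_child(pa, ka, nb)
    _set_child(pb, kb, na)
    return a2, b2


def _applicable_moves(tree, catalog, max_operators):
    moves = []
    c = tree.complexity()
    if c < max_operators:
        moves.append("insert")
    op_nodes = [n for n in iter_nodes(tree.root.child) if isinstance(n, OperatorNode)]
    if op_nodes:
        moves.append("remove")
    sub_targets = _substitution_targets(tree, catalog)
    if sub_targets:
        moves.append("substitute")
    if _resample_targets(tree):
        moves.append("resample")
    return moves


def _substitution_targets(tree, catalog):
    targets = []
    if len(catalog.classifiers) > 1:
        targets.append(tree.root)
    for n in iter_nodes(tree.root.child):
        if isinstance(n, OperatorNode):
            same_kind = [
                s
                for s in catalog.preprocessors
                if s.kind == catalog.get(n.name).kind and s.name != n.name
            ]
            if same_kind:
                targets.append(n)
    return targets


def _resample_targets(tree):
    return [
        n
        for n in iter_nodes(tree.root)
        if isinstance(n, OperatorNode) and n.values
    ]


def mutate(
    tree: PipelineTree,
    catalog: OperatorCatalog,
    rng: np.random.Generator,
    max_operators: int = 10,
    return_move: bool = False,
):
    """Apply one mutation move, chosen uniformly among applicable moves.

    Moves: insert a random operator at a random edge; remove a random
    non-classifier operator; substitute an operator (or the classifier when
    alternatives exist) with a random same-kind operator; resample one
    hyperparameter from its domain.  Complexity changes by at most 1.
    With ``return_move`` the applied move name is returned alongside the
    tree (for audits).
    """
    out = tree.clone()
    moves = _applicable_moves(out, catalog, max_operators)
    if not moves:
        return (out, None) if return_move else out
    move = moves[rng.integers(len(moves))]
    if move == "insert":
        edges = _edges(out)
        parent, key, node = edges[rng.integers(len(edges))]
        pre = catalog.preprocessors
        spec = pre[rng.integers(len(pre))]
        _set_child(parent, key, OperatorNode(spec.name, spec.sample_values(rng), node))
    elif move == "remove":
        candidates = [
            (p, k, n) for (p, k, n) in _edges(out) if isinstance(n, OperatorNode)
        ]
        parent, key, node = candidates[rng.integers(len(candidates))]
        _set_child(parent, key, node.child)
    elif move == "substitute":
        targets = _substitution_targets(out, catalog)
        node = targets[rng.integers(len(targets))]
        if node is out.root:
            options = [s for s in catalog.classifiers if s.name != node.name]
        else:
            kind = catalog.get(node.name).kind
            options = [
                s
                for s in catalog.preprocessors
                if s.kind == kind and s.name != node.name
            ]
        spec = options[rng.integers(len(options))]
        node.name = spec.name
        node.values = spec.sample_values(rng)
    else:  # resample
        targets = _resample_targets(out)
        node = targets[rng.integers(len(targets))]
        spec = catalog.get(node.name)
        hp_names = sorted(node.values)
        hp = hp_names[rng.integers(len(hp_names))]
        domain = tuple(spec.hyperparameters[hp])
        node.values[hp] = domain[rng.integers(len(domain))]
    out.validate(catalog, max_operators)
    return (out, move) if return_move else out


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def tournament_select(candidates, rng: np.random.Generator):
    """Three-way tournament with two-way parsimony.

    Drop the lowest-fitness candidate (fitness ties: drop the more complex),
    then of the remaining two return the less complex one (complexity tie:
    higher fitness; full tie: uniform random).
    """
    if len(candidates) != 3:
        raise ValueError("tournament requires exactly 3 candidates")
    cands = list(candidates)
    min_fit = min(rec.fitness for _, rec in cands)
    lowest = [i for i, (_, rec) in enumerate(cands) if rec.fitness == min_fit]
    if len(lowest) > 1:
        max_cx = max(cands[i][1].complexity for i in lowest)
        lowest = [i for i in lowest if cands[i][1].complexity == max_cx]
    drop = lowest[rng.integers(len(lowest))] if len(lowest) > 1 else lowest[0]
    rest = [cands[i] for i in range(3) if i != drop]
    (t1, r1), (t2, r2) = rest
    if r1.complexity != r2.complexity:
        return rest[0] if r1.complexity < r2.complexity else rest[1]
    if r1.fitness != r2.fitness:
        return rest[0] if r1.fitness > r2.fitness else rest[1]
    return rest[int(rng.integers(2))]


def _best_index(records):
    """Index of the highest-fitness record; ties -> smaller complexity."""
    best = None
    for i, rec in enumerate(records):
        key = (rec.fitness, -rec.complexity)
        if best is None or key > best[0]:
            best = (key, i)
    return best[1]


def next_generation(
    population,
    records,
    config: GPConfig,
    rng: np.random.Generator,
    catalog: OperatorCatalog,
):
    """Produce the next population: elitist copies + tournament winners,
    then crossover/mutation applied to the configured fractions of the
    non-elite slots (elite copies are protected from variation)."""
    n = len(population)
    if n != config.population_size or len(records) != n:
        raise ValueError("population/records size mismatch with config")
    if all(not rec.valid for rec in records):
        raise RuntimeError("population collapse: every pipeline is invalid")
    n_elite = config.n_elite
    best_i = _best_index(records)
    new_pop = [population[best_i].clone() for _ in range(n_elite)]
    while len(new_pop) < n:
        idx = rng.integers(n, size=3)
        winner, _ = tournament_select([(population[i], records[i]) for i in idx], rng)
        new_pop.append(winner.clone())

    non_elite = list(range(n_elite, n))
    n_cx = int(np.floor(config.crossover_rate * n + 0.5))
    n_cx = min(n_cx - n_cx % 2, len(non_elite) - len(non_elite) % 2)
    if n_cx >= 2:
        chosen = rng.choice(len(non_elite), size=n_cx, replace=False)
        slots = [non_elite[i] for i in chosen]
        for a_slot, b_slot in zip(slots[0::2], slots[1::2]):
            child_a, child_b = crossover(
                new_pop[a_slot], new_pop[b_slot], rng, config.max_operators
            )
            new_pop[a_slot], new_pop[b_slot] = child_a, child_b
    n_mut = min(int(np.floor(config.mutation_rate * n + 0.5)), len(non_elite))
    if n_mut >= 1:
        chosen = rng.choice(len(non_elite), size=n_mut, replace=False)
        for i in chosen:
            slot = non_elite[i]
            new_pop[slot] = mutate(new_pop[slot], catalog, rng, config.max_operators)
    return new_pop


# ---------------------------------------------------------------------------
# Pareto archive
# ---------------------------------------------------------------------------

def _dominates(a: FitnessRecord, b: FitnessRecord) -> bool:
    """a dominates b in (fitness up, complexity down)."""
    ge = a.fitness >= b.fitness and a.complexity <= b.complexity
    gt = a.fitness > b.fitness or a.complexity < b.complexity
    return ge and gt


def update_pareto_archive(archive, tree, record):
    """Insert (tree, record) keeping the archive a non-dominated set."""
    if not record.valid:
        return archive
    for _, rec in archive:
        if _dominates(rec, record) or (
            rec.fitness == record.fitness and rec.complexity == record.complexity
        ):
            return archive
    kept = [(t, r) for (t, r) in archive if not _dominates(record, r)]
    kept.append((tree.clone(), record))
    return kept


# ---------------------------------------------------------------------------
# Search loop
# ---------------------------------------------------------------------------

def _evaluate_population(population, data, catalog, n_folds, fold_seed, cache, n_jobs):
    keys = [t.serialize() for t in population]
    missing = [(k, t) for k, t in zip(keys, population) if k not in cache]
    # Deduplicate identical trees before evaluating.
    unique = {}
    for k, t in missing:
        unique.setdefault(k, t)
    items = sorted(unique.items())
    if n_jobs != 1 and len(items) > 1:
        results = Parallel(n_jobs=n_jobs)(
            delayed(evaluate_cv)(t, data, catalog, n_folds, fold_seed) for _, t in items
        )
    else:
        results = [evaluate_cv(t, data, catalog, n_folds, fold_seed) for _, t in items]
    for (k, _), rec in zip(items, results):
        cache[k] = rec
    return [cache[k] for k in keys], len(items)


def run_search(
    data: LabeledDataset,
    catalog: OperatorCatalog,
    config: GPConfig,
) -> SearchResult:
    """Run the full GP loop; deterministic for a fixed seed (no time budget)."""
    rng = np.random.default_rng(config.seed)
    start = time.monotonic()
    population = [
        random_pipeline(catalog, rng, config.max_operators)
        for _ in range(config.population_size)
    ]
    cache: dict = {}
    all_evaluations: dict = {}
    archive: list = []
    history = []
    n_evals = 0
    generation = 0
    while True:
        fold_seed = (
            (config.seed * 1315423911 + generation) % (2**31 - 1)
            if config.redraw_folds
            else config.seed % (2**31 - 1)
        )
        if config.redraw_folds:
            cache = {}
        records, new_evals = _evaluate_population(
            population, data, catalog, config.n_folds, fold_seed, cache, config.n_jobs
        )
        n_evals += new_evals
        all_evaluations.update(cache)
        for tree, rec in zip(population, records):
            archive = update_pareto_archive(archive, tree, rec)
        valid = [r.fitness for r in records if r.valid]
        history.append(
            {
                "generation": generation,
                "best": max(valid) if valid else float("-inf"),
                "mean": float(np.mean(valid)) if valid else float("-inf"),
            }
        )
        logger.info(
            "generation %d: best=%.4f mean=%.4f archive=%d",
            generation,
            history[-1]["best"],
            history[-1]["mean"],
            len(archive),
        )
        if generation >= config.max_generations:
            break
        if config.time_budget is not None and time.monotonic() - start > config.time_budget:
            logger.info("time budget reached after generation %d", generation)
            break
        population = next_generation(population, records, config, rng, catalog)
        generation += 1
    if not archive:
        raise RuntimeError("population collapse: no valid pipeline was ever evaluated")
    best_tree, best_record = max(
        archive, key=lambda tr: (tr[1].fitness, -tr[1].complexity)
    )
    return SearchResult(
        best_tree=best_tree.clone(),
        best_record=best_record,
        pareto_archive=archive,
        history=history,
        seed=config.seed,
        n_evaluations=n_evals,
        evaluations=all_evaluations,
    )


def representative_model(
    data: LabeledDataset,
    catalog: OperatorCatalog,
    config: GPConfig,
    n_seeds: int = 50,
) -> SearchResult:
    """Multi-seed protocol: re-run the search under ``n_seeds`` seeds and
    return the run whose best pipeline has the highest mean CV balanced
    accuracy (ties: smaller complexity, then smaller seed)."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    best = None
    for i in range(n_seeds):
        result = run_search(data, catalog, replace(config, seed=config.seed + i))
        key = (
            result.best_record.fitness,
            -result.best_record.complexity,
            -result.seed,
        )
        if best is None or key > best[0]:
            best = (key, result)
    return best[1]
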