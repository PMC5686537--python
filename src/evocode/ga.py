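"""Genetic algorithm over codon tables.

Each individual is a full 64-codon assignment.  Selection keeps the top
``elite_fraction`` of the population; offspring are produced by mutating the
elite cyclically (offspring ``i`` mutates ``elite[i mod n_elite]``).  The
incumbent best individual is carried over unchanged every round, so the best
fitness trace is non-decreasing.  Offspring whose chemical-diversity score
``F_chem`` falls below the best seen so far are rejected and resampled (a
bounded number of times), which ratchets chemical diversity upward alongside
the combined fitness.

Mutation follows the per-codon model: with probability ``mutation_rate`` a
codon takes the product of another randomly chosen codon (the default COPY
operator; an EXCHANGE operator that swaps the two products is available).
COPY can change the multiset of codon counts per residue — required for the
optimizer to flatten the standard code's 1-6 codons-per-residue range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codes import (
    AMINO_ACIDS,
    CODONS,
    CODON_INDEX,
    PRODUCTS,
    STOP,
    ChemicalClassTable,
    GeneticCode,
    count_reassignments,
    normalize_codon,
    standard_code,
)
from .metrics import (
    FitnessReport,
    _class_vector,
    _fast_components,
    _fast_fitness,
    _product_vector,
    combined_fitness,
)

_STOP_I = PRODUCTS.index(STOP)


@dataclass(frozen=True)
class GAConfig:
    """Parameters of one GA run.

    Defaults follow the reference simulation scheme: 2,500 individuals,
    1,000 rounds, 10% per-codon mutation, top-10% cyclical selection with
    elitism.
    """

    population_size: int = 2500
    rounds: int = 1000
    mutation_rate: float = 0.10
    elite_fraction: float = 0.10
    penalty_alpha: float | None = None
    penalty_exponent: int = 1
    frozen_codons: frozenset[str] = frozenset()
    native_restriction: bool = False
    allow_residue_loss: bool = False
    reassignable_codons: frozenset[str] | None = None  # None = all
    stopless_mode: bool = True
    mutation_operator: str = "copy"  # or "exchange"
    distinct_chem: bool = False
    fchem_acceptance: bool = True
    max_retries: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in (0, 1]")
        if not 0.0 < self.elite_fraction <= 1.0:
            raise ValueError("elite_fraction must lie in (0, 1]")
        if self.penalty_alpha is not None and not 0.0 < self.penalty_alpha < 1.0:
            raise ValueError("penalty_alpha must lie in (0, 1)")
        if self.penalty_exponent not in (1, 2):
            raise ValueError("penalty_exponent must be 1 or 2")
        if self.mutation_operator not in ("copy", "exchange"):
            raise ValueError("mutation_operator must be 'copy' or 'exchange'")


@dataclass
class GATrace:
    """Per-round best-fitness history and the final winner."""

    best_fitness: list[float]
    best_code: GeneticCode
    report: FitnessReport
    reassignments: int
    rounds_run: int
    config: GAConfig = field(repr=False, default=None)


def prepare_stopless(code: GeneticCode) -> GeneticCode:
    """Reassign TAG and TGA to asparagine, leaving TAA the sole stop.

    Idempotent; the returned code still encodes all 20 residues.  During
    optimization TAA is additionally frozen so the single stop survives.
    """
    out = code
    for codon in ("TAG", "TGA"):
        if out[codon] == STOP:
            out = out.with_assignment(codon, "N")
    return GeneticCode(
        out.translation, name=f"{code.name}-stopless", reference=code.name
    )


class _Constraints:
    """Vectorized constraint checks shared by mutation and acceptance.

    ``reference`` anchors the native-restriction check; ``anchor`` (default
    the reference) is the code whose products frozen codons must keep —
    for a run started from a prepared code this is the start code itself.
    """

    def __init__(
        self,
        config: GAConfig,
        reference: GeneticCode,
        anchor: GeneticCode | None = None,
    ):
        self.config = config
        self.ref_prod = _product_vector(reference)
        self.anchor_prod = _product_vector(anchor) if anchor is not None else self.ref_prod
        frozen = {CODON_INDEX[normalize_codon(c)] for c in config.frozen_codons}
        if config.stopless_mode:
            frozen.add(CODON_INDEX["TAA"])
        if config.reassignable_codons is not None:
            allowed = {
                CODON_INDEX[normalize_codon(c)] for c in config.reassignable_codons
            }
            frozen |= set(range(64)) - allowed
        self.frozen = np.zeros(64, dtype=bool)
        self.frozen[sorted(frozen)] = True
        self.mutable = ~self.frozen

    def ok(self, prod: np.ndarray) -> bool:
        cfg = self.config
        if (prod[self.frozen] != self.anchor_prod[self.frozen]).any():
            return False
        if not cfg.allow_residue_loss:
            present = np.bincount(prod[prod != _STOP_I], minlength=20) > 0
            if not present.all():
                return False
        if cfg.native_restriction:
            native = prod == self.ref_prod
            for aa in range(20):
                mask = self.ref_prod == aa
                if mask.any() and not native[mask].any():
                    return False
        return True


def _mutate_prod(
    prod: np.ndarray, cons: _Constraints, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """One mutation pass over a product vector (constraints not rechecked)."""
    out = prod.copy()
    hit = (rng.random(64) < config.mutation_rate) & cons.mutable
    for ci in np.nonzero(hit)[0]:
        partner = int(rng.integers(64))
        while partner == ci:
            partner = int(rng.integers(64))
        if config.mutation_operator == "copy":
            out[ci] = out[partner]
        else:  # exchange
            if cons.mutable[partner]:
                out[ci], out[partner] = out[partner], out[ci]
    return out


def mutate_code(
    code: GeneticCode,
    config: GAConfig,
    rng: np.random.Generator,
    reference: GeneticCode | None = None,
) -> GeneticCode:
    """Mutate a code under the config's constraints.

    Violating proposals are resampled up to ``config.max_retries`` times;
    if none validates the input code is returned unchanged.
    """
    reference = reference or code
    cons = _Constraints(config, reference, anchor=code)
    prod = _product_vector(code)
    for _ in range(config.max_retries):
        trial = _mutate_prod(prod, cons, config, rng)
        if cons.ok(trial):
            return _to_code(trial, name=f"{code.name}-mut", reference=code)
    return code


def _to_code(prod: np.ndarray, name: str, reference: GeneticCode) -> GeneticCode:
    translation = "".join(PRODUCTS[i] for i in prod)
    return GeneticCode(
        translation,
        name=name,
        reference=reference.name,
        stopless=STOP not in translation,
        require_all_residues=False,
    )


def evolve(
    start: GeneticCode,
    config: GAConfig,
    classes: ChemicalClassTable | None = None,
    reference: GeneticCode | None = None,
) -> GATrace:
    """Run the select -> mutate -> accept loop from ``start``.

    ``reference`` (default: the standard code) anchors frozen-codon and
    native-restriction checks and the reassignment penalty.
    """
    classes = classes or ChemicalClassTable()
    reference = reference or standard_code()
    cls_vec = _class_vector(classes)
    cons = _Constraints(config, reference, anchor=start)
    rng = np.random.default_rng(config.seed)
    ref_prod = _product_vector(reference)

    start_prod = _product_vector(start)
    if not cons.ok(start_prod):
        raise ValueError("start code violates the configured constraints")

    def score(prod: np.ndarray) -> float:
        f = _fast_fitness(prod, cls_vec, distinct=config.distinct_chem)
        if config.penalty_alpha is not None:
            r = int((prod != ref_prod).sum())
            f *= config.penalty_alpha ** (r ** config.penalty_exponent)
        return f

    if not cons.mutable.any():
        report = combined_fitness(start, classes, reference, distinct_chem=config.distinct_chem)
        return GATrace([report.f_combined], start, report,
                       count_reassignments(start, reference), 0, config)

    n_elite = max(1, int(round(config.population_size * config.elite_fraction)))
    population = [start_prod.copy() for _ in range(config.population_size)]
    fitnesses = np.array([score(p) for p in population])
    best_prod = population[int(fitnesses.argmax())].copy()
    best_fit = float(fitnesses.max())
    best_fchem = _fast_components(best_prod, cls_vec, distinct=config.distinct_chem)[2]
    history: list[float] = []

    for _ in range(config.rounds):
        order = np.argsort(-fitnesses, kind="stable")
        elite = [population[i] for i in order[:n_elite]]
        nxt = [best_prod.copy()]  # elitism: incumbent survives
        nxt_fit = [best_fit]
        while len(nxt) < config.population_size:
            parent = elite[(len(nxt) - 1) % n_elite]
            child = None
            for _try in range(config.max_retries):
                trial = _mutate_prod(parent, cons, config, rng)
                if not cons.ok(trial):
                    continue
                if config.fchem_acceptance:
                    fc = _fast_components(trial, cls_vec, distinct=config.distinct_chem)[2]
                    if fc < best_fchem - 1e-12:
                        continue
                child = trial
                break
            if child is None:
                child = parent.copy()
            nxt.append(child)
            nxt_fit.append(score(child))
        population = nxt
        fitnesses = np.array(nxt_fit)
        i = int(fitnesses.argmax())
        if fitnesses[i] > best_fit:
            best_fit = float(fitnesses[i])
            best_prod = population[i].copy()
            best_fchem = max(
                best_fchem,
                _fast_components(best_prod, cls_vec, distinct=config.distinct_chem)[2],
            )
        history.append(best_fit)

    best_code = _to_code(best_prod, name=f"{start.name}-ga", reference=reference)
    report = combined_fitness(best_code, classes, reference, distinct_chem=config.distinct_chem)
    if config.penalty_alpha is not None:
        from .metrics import penalized_fitness

        report = penalized_fitness(
            best_code, reference, classes,
            alpha=config.penalty_alpha, exponent=config.penalty_exponent,
            distinct_chem=config.distinct_chem,
        )
    return GATrace(history, best_code, report,
                   count_reassignments(best_code, reference), config.rounds, config)


def optimize_free_codons(
    freed: frozenset[str] | set[str],
    classes: ChemicalClassTable | None = None,
    config: GAConfig | None = None,
    *,
    exhaustive_threshold: int = 2,
) -> GATrace:
    """Optimize the products of a small set of freed codons only.

    All other codons keep their standard assignments.  For
    ``len(freed) <= exhaustive_threshold`` the search enumerates all
    product combinations (21 per codon, stop included) and is exact;
    otherwise the GA runs restricted to the freed codons.
    """
    classes = classes or ChemicalClassTable()
    std = standard_code()
    freed_norm = frozenset(normalize_codon(c) for c in freed)
    if not freed_norm:
        report = combined_fitness(std, classes, std)
        return GATrace([report.f_combined], std, report, 0, 0, config)

    base = config or GAConfig(population_size=500, rounds=300)
    cfg = replace(
        base,
        reassignable_codons=freed_norm,
        stopless_mode=False,
        allow_residue_loss=False,
    )
    if len(freed_norm) <= exhaustive_threshold:
        return _exhaustive_free(freed_norm, classes, cfg, std)
    return evolve(std, cfg, classes, reference=std)


def _exhaustive_free(
    freed: frozenset[str], classes: ChemicalClassTable, config: GAConfig,
    std: GeneticCode,
) -> GATrace:
    from itertools import product as iproduct

    cls_vec = _class_vector(classes)
    std_prod = _product_vector(std)
    idx = sorted(CODON_INDEX[c] for c in freed)
    best_fit, best_prod = -np.inf, None
    for combo in iproduct(range(21), repeat=len(idx)):
        trial = std_prod.copy()
        trial[idx] = combo
        present = np.bincount(trial[trial != _STOP_I], minlength=20) > 0
        if not config.allow_residue_loss and not present.all():
            continue
        if _STOP_I not in trial:
            continue
        f = _fast_fitness(trial, cls_vec, distinct=config.distinct_chem)
        if f > best_fit:
            best_fit, best_prod = f, trial.copy()
    best_code = _to_code(best_prod, name="free-codon-optimum", reference=std)
    report = combined_fitness(best_code, classes, std, distinct_chem=config.distinct_chem)
    return GATrace([best_fit], best_code, report,
                   count_reassignments(best_code, std), 0, config)


#: Codons synonymously removed in the 57-codon E. coli genome design; the
#: freed set the restricted-reassignment mode targets by default.
RECODED_57_FREED_CODONS = frozenset(
    {"AGA", "AGG", "AGC", "AGT", "TTA", "TTG", "TAG"}
)
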