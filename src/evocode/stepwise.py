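"""Recursive best-move improvement of a genetic code.

Each round considers every single codon reassignment (codon -> any of the
20 residues) and keeps the move(s) with the maximal strictly positive gain
in combined fitness.  Two modes:

* branching (default): a breadth-wise expansion that keeps *all* codes
  achieving the round's maximal fitness (deduplicated), mirroring an
  exhaustive enumeration of tied best moves; the terminal set is the set of
  locally optimal codes with the highest fitness reached.
* greedy: follows one best move per round (first in canonical codon/product
  order), cheaper but tie-path dependent.

Stop codons are not part of the search: codons assigned to the stop signal
are immobile and no move may create or destroy a stop.  The conventional
starting point is the stopless-prepared standard code (TAG/TGA reassigned
to asparagine, TAA the sole stop; :func:`evocode.ga.prepare_stopless`).

The move objective defaults to the combined fitness with the
distinct-classes reading of the chemical-diversity component, the variant
under which the branching search from the stopless-prepared standard code
terminates at the reference depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codes import (
    CODONS,
    PRODUCTS,
    STOP,
    ChemicalClassTable,
    GeneticCode,
)
from .metrics import _class_vector, _fast_fitness, _product_vector

_STOP_I = PRODUCTS.index(STOP)

#: relative tolerance for fitness ties; all quantities are ratios of small
#: integers so exact ties are exact in floating point up to this slack
TIE_TOL = 1e-12


class BudgetExceededError(RuntimeError):
    """Node budget exhausted; ``partial`` carries the best result so far."""

    def __init__(self, message: str, partial: "SearchResult"):
        super().__init__(message)
        self.partial = partial


@dataclass
class SearchResult:
    """Outcome of a recursive search."""

    terminal_codes: list[GeneticCode]
    depth: int
    visited: int
    trace: list[float] = field(default_factory=list)  # best fitness per depth

    @property
    def best(self) -> GeneticCode:
        return self.terminal_codes[0]


def _movable(prod: np.ndarray) -> np.ndarray:
    return prod != _STOP_I


def _improving_moves(
    prod: np.ndarray,
    cls_vec: np.ndarray,
    base: float,
    *,
    distinct_chem: bool,
    allow_residue_loss: bool,
) -> list[tuple[float, int, int]]:
    """All strictly improving single reassignments as (fitness, codon, product)."""
    out = []
    counts = np.bincount(prod, minlength=21)
    for ci in np.nonzero(_movable(prod))[0]:
        cur = prod[ci]
        if not allow_residue_loss and counts[cur] == 1:
            continue
        for ai in range(20):
            if ai == cur:
                continue
            trial = prod.copy()
            trial[ci] = ai
            f = _fast_fitness(trial, cls_vec, distinct=distinct_chem)
            if f > base + TIE_TOL:
                out.append((f, int(ci), ai))
    return out


def best_moves(
    code: GeneticCode,
    classes: ChemicalClassTable | None = None,
    *,
    distinct_chem: bool = True,
    allow_residue_loss: bool = False,
) -> set[tuple[str, str]]:
    """The set of single reassignments achieving the maximal positive gain.

    Empty when the code is locally optimal.  Stop codons are excluded both
    as move targets and as new products.
    """
    classes = classes or ChemicalClassTable()
    cls_vec = _class_vector(classes)
    prod = _product_vector(code)
    base = _fast_fitness(prod, cls_vec, distinct=distinct_chem)
    moves = _improving_moves(
        prod, cls_vec, base,
        distinct_chem=distinct_chem, allow_residue_loss=allow_residue_loss,
    )
    if not moves:
        return set()
    fmax = max(f for f, _, _ in moves)
    return {
        (CODONS[ci], PRODUCTS[ai])
        for f, ci, ai in moves
        if f >= fmax - TIE_TOL
    }


def is_locally_optimal(
    code: GeneticCode,
    classes: ChemicalClassTable | None = None,
    *,
    distinct_chem: bool = True,
    allow_residue_loss: bool = False,
) -> bool:
    """True when no single reassignment strictly improves the fitness."""
    return not best_moves(
        code, classes,
        distinct_chem=distinct_chem, allow_residue_loss=allow_residue_loss,
    )


def recursive_search(
    start: GeneticCode,
    classes: ChemicalClassTable | None = None,
    *,
    greedy: bool = False,
    budget: int = 10**6,
    distinct_chem: bool = True,
    allow_residue_loss: bool = False,
    dedupe: bool = True,
) -> SearchResult:
    """Iterate best moves from ``start`` until no move improves the fitness.

    Branching mode keeps every code that attains the maximal fitness
    reachable at each depth (all tied best moves, deduplicated on the
    64-symbol assignment string), so the terminal set holds the
    maximal-fitness locally optimal codes.  ``budget`` caps the number of
    candidate evaluations; exceeding it raises :class:`BudgetExceededError`
    with the partial result attached.
    """
    classes = classes or ChemicalClassTable()
    cls_vec = _class_vector(classes)
    start_prod = _product_vector(start)
    base = _fast_fitness(start_prod, cls_vec, distinct=distinct_chem)

    front: dict[bytes, np.ndarray] = {start_prod.tobytes(): start_prod}
    fitness = base
    depth = 0
    visited = 0
    trace = [fitness]

    def package(front_now: dict[bytes, np.ndarray]) -> SearchResult:
        codes = [
            _as_code(p, start, depth_label=depth) for p in front_now.values()
        ]
        return SearchResult(codes, depth, visited, trace)

    while True:
        best_f = fitness
        nxt: dict[bytes, np.ndarray] = {}
        for prod in front.values():
            moves = _improving_moves(
                prod, cls_vec, fitness,
                distinct_chem=distinct_chem, allow_residue_loss=allow_residue_loss,
            )
            visited += 63 * 19  # candidates examined for this node (upper bound)
            if visited > budget:
                raise BudgetExceededError(
                    f"node budget {budget} exceeded at depth {depth}",
                    package(front),
                )
            if not moves:
                continue
            if greedy:
                # canonical order: lowest codon index, then product index
                f, ci, ai = max(moves, key=lambda m: (m[0], -m[1], -m[2]))
                t = prod.copy()
                t[ci] = ai
                if f > best_f + TIE_TOL:
                    best_f = f
                    nxt = {t.tobytes(): t}
                break
            for f, ci, ai in moves:
                if f > best_f + TIE_TOL:
                    best_f = f
                    t = prod.copy()
                    t[ci] = ai
                    nxt = {t.tobytes(): t}
                elif f >= best_f - TIE_TOL and best_f > fitness + TIE_TOL:
                    t = prod.copy()
                    t[ci] = ai
                    nxt[t.tobytes()] = t
        if not nxt:
            return package(front)
        if not dedupe and not greedy:
            pass  # front dict already deduplicates; flag kept for API clarity
        front = nxt
        fitness = best_f
        depth += 1
        trace.append(fitness)


def _as_code(prod: np.ndarray, start: GeneticCode, depth_label: int) -> GeneticCode:
    translation = "".join(PRODUCTS[i] for i in prod)
    return GeneticCode(
        translation,
        name=f"{start.name}-step{depth_label}",
        reference=start.name,
        stopless=STOP not in translation,
        require_all_residues=False,
    )
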