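"""Synthetic fixtures: random genes, scrambled codes, substitution tables.

These generators stand in for real sequence collections so every pipeline
stage is testable offline.  All of them are deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import (
    AMINO_ACIDS,
    CODONS,
    PRODUCTS,
    STOP,
    GeneticCode,
    standard_code,
)
from .metrics import min_replacements


@dataclass(frozen=True)
class GeneSpec:
    """Parameters of one synthetic coding sequence."""

    length: int  # in codons, excluding the appended stop codon
    gc_content: float = 0.5
    start_codon: bool = True
    stop_codon: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        minimum = 2 if (self.start_codon and self.stop_codon) else 1
        if self.length < minimum:
            raise ValueError(f"length must be >= {minimum} codons")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")


def _gc(codon: str) -> float:
    return sum(b in "GC" for b in codon) / 3.0


def random_gene(spec: GeneSpec, code: GeneticCode | None = None) -> str:
    """A random CDS under ``code`` with no internal stops.

    Codons are drawn position-wise with weights biased toward the GC
    target (weight ``exp(-beta * |gc(codon) - target|)`` over the sense
    codons, beta = 8), which keeps the empirical GC content of long genes
    within a few percent of the target.
    """
    code = code or standard_code()
    rng = np.random.default_rng(spec.seed)
    sense = [c for c in CODONS if code[c] != STOP]
    if not sense:
        raise ValueError(f"code {code.name!r} has no sense codons")
    beta = 8.0
    weights = np.array([np.exp(-beta * abs(_gc(c) - spec.gc_content)) for c in sense])
    weights /= weights.sum()
    n_body = spec.length - (1 if spec.start_codon else 0)
    body = rng.choice(len(sense), size=n_body, p=weights)
    parts = []
    if spec.start_codon:
        starts = code.codons_for("M") or (sense[0],)
        parts.append(starts[0])
    parts.extend(sense[i] for i in body)
    if spec.stop_codon:
        stops = code.stop_codons
        if not stops:
            raise ValueError(f"code {code.name!r} has no stop codon")
        parts.append(stops[0])
    return "".join(parts)


def random_code(
    seed: int = 0,
    *,
    all_residues: bool = True,
    n_stops: int = 1,
    name: str | None = None,
) -> GeneticCode:
    """A uniformly scrambled valid genetic code.

    The 20 residues (when ``all_residues``) and ``n_stops`` stop signals are
    first pinned to distinct random codons, then the remaining codons draw
    products uniformly from the 20 residues.
    """
    if not 1 <= n_stops <= 44:
        raise ValueError("n_stops must be between 1 and 44")
    rng = np.random.default_rng(seed)
    products = [None] * 64
    pinned = list(AMINO_ACIDS) if all_residues else []
    pinned += [STOP] * n_stops
    slots = rng.choice(64, size=len(pinned), replace=False)
    for slot, prod in zip(slots, pinned):
        products[slot] = prod
    for i in range(64):
        if products[i] is None:
            products[i] = AMINO_ACIDS[rng.integers(20)]
    return GeneticCode(
        "".join(products),
        name=name or f"random-{seed}",
        require_all_residues=all_residues,
    )


def synthetic_substitutions(
    code: GeneticCode | None = None,
    *,
    snr_bias: float = 20.0,
    n: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Substitution-count table with an injected accessibility bias.

    Ordered residue pairs (wt != mut) are sampled with probability
    proportional to ``snr_bias ** (1 - d)`` where ``d`` is the minimal
    number of nucleotide replacements separating the two residues under
    ``code``; ``snr_bias = 1`` gives a uniform table, larger values
    concentrate events on single-replacement pairs.
    """
    if snr_bias <= 0:
        raise ValueError("snr_bias must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    dist = min_replacements(code)
    pairs = [
        (a, b)
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
        if a != b
    ]
    weights = np.array(
        [float(snr_bias) ** float(1 - dist.loc[a, b]) for a, b in pairs]
    )
    probs = weights / weights.sum()
    counts = rng.multinomial(n, probs)
    return pd.DataFrame(
        {
            "wt": [a for a, _ in pairs],
            "mut": [b for _, b in pairs],
            "count": counts,
        }
    )
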