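"""Accessibility and fitness metrics over genetic codes.

Every metric is built on the single-nucleotide-replacement (SNR)
neighborhood: each codon has exactly 9 neighbors at Hamming distance 1
(3 positions x 3 alternative bases).

The combined fitness of a code is the product of three normalized
components:

* ``F_unique`` — mean number of distinct alternative products (the stop
  signal counts as a product) reachable from a codon by one SNR, averaged
  over all 64 codons.  Theoretical maximum 9.
* ``F_ratio`` — evenness of incoming SNR conversions per encoded residue:
  the minimum over residues of the number of directed SNR events producing
  that residue from a different one, divided by the maximum.  Stop codons do
  not take part.  Maximum 1.
* ``F_chem`` — chemical diversity of SNR outcomes.  The default reading
  counts, per codon, the number of SNRs whose product belongs to a different
  chemical class (with multiplicity; the stop pseudo-class is a class).  A
  distinct-classes variant is available via ``distinct=True``.  Both are
  normalized by 9.

``F = (F_unique/9) * F_ratio * (F_chem/9)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .codes import (
    AMINO_ACIDS,
    BASES,
    CODONS,
    CODON_INDEX,
    PRODUCTS,
    STOP,
    ChemicalClassTable,
    GeneticCode,
    count_reassignments,
    normalize_codon,
)

# ---------------------------------------------------------------------------
# SNR neighborhood machinery

N_CODONS = 64
N_NEIGHBORS = 9
N_EDGES = 288  # 64 * 9 / 2 unordered Hamming-1 pairs


@lru_cache(maxsize=1)
def _neighbor_index() -> np.ndarray:
    """(64, 9) array: row i lists codon indices at Hamming distance 1."""
    rows = []
    for codon in CODONS:
        row = [
            CODON_INDEX[codon[:i] + b + codon[i + 1 :]]
            for i in range(3)
            for b in BASES
            if b != codon[i]
        ]
        rows.append(row)
    return np.asarray(rows, dtype=np.int8)


@lru_cache(maxsize=1)
def _edge_index() -> np.ndarray:
    """(288, 2) array of unordered Hamming-1 codon index pairs."""
    nbr = _neighbor_index()
    pairs = sorted(
        {tuple(sorted((i, int(j)))) for i in range(N_CODONS) for j in nbr[i]}
    )
    return np.asarray(pairs, dtype=np.int8)


_PRODUCT_INDEX = {p: i for i, p in enumerate(PRODUCTS)}
_STOP_I = _PRODUCT_INDEX[STOP]


def _product_vector(code: GeneticCode) -> np.ndarray:
    return np.fromiter(
        (_PRODUCT_INDEX[p] for p in code.translation), dtype=np.int8, count=N_CODONS
    )


def _class_vector(classes: ChemicalClassTable) -> np.ndarray:
    labels = sorted({classes[p] for p in PRODUCTS})
    lab_index = {l: i for i, l in enumerate(labels)}
    return np.fromiter(
        (lab_index[classes[p]] for p in PRODUCTS), dtype=np.int8, count=21
    )


def snr_neighbors(codon: str) -> set[str]:
    """The 9 codons at Hamming distance 1 from ``codon``."""
    c = normalize_codon(codon)
    return {
        c[:i] + b + c[i + 1 :] for i in range(3) for b in BASES if b != c[i]
    }


# ---------------------------------------------------------------------------
# per-codon accessibility

def _unique_access_vector(prod: np.ndarray) -> np.ndarray:
    """Distinct alternative products per codon (length-64 int vector)."""
    P = prod[_neighbor_index()]  # (64, 9) neighbor products
    S = np.sort(P, axis=1)
    distinct = 1 + (np.diff(S, axis=1) != 0).sum(axis=1)
    own_present = (P == prod[:, None]).any(axis=1)
    return (distinct - own_present).astype(np.int64)


def unique_access(code: GeneticCode, codon: str) -> int:
    """Number of distinct products (stop included) reachable from ``codon``
    by one SNR that differ from the codon's own product."""
    own = code[codon]
    return len({code[n] for n in snr_neighbors(codon)} - {own})


def f_unique(code: GeneticCode) -> float:
    """Mean unique SNR accessibility over all 64 codons."""
    return float(_unique_access_vector(_product_vector(code)).mean())


def access_distribution(code: GeneticCode) -> tuple[float, float, int, int]:
    """(mean, population SD, min, max) of the 64 per-codon accessibilities."""
    ua = _unique_access_vector(_product_vector(code))
    return float(ua.mean()), float(ua.std(ddof=0)), int(ua.min()), int(ua.max())


class UndefinedRatioError(ValueError):
    """F_ratio is undefined: no inter-residue SNR conversions exist."""


def _incoming_counts(prod: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directed SNR conversion counts into each residue, and the encoded mask.

    An event is a directed Hamming-1 codon pair (C, C') with different,
    non-stop products; it counts toward the product of C'.
    """
    nbr = _neighbor_index()
    src = np.repeat(prod, N_NEIGHBORS)
    dst = prod[nbr].ravel()
    mask = (src != dst) & (src != _STOP_I) & (dst != _STOP_I)
    incoming = np.bincount(dst[mask], minlength=21)[:20]
    encoded = np.bincount(prod[prod != _STOP_I], minlength=20) > 0
    return incoming, encoded


def f_ratio(code: GeneticCode) -> float:
    """Min/max ratio of incoming SNR conversion counts over encoded residues.

    Residues with zero incoming conversions drive the ratio to 0.  Raises
    :class:`UndefinedRatioError` when no residue receives any conversion
    (e.g. a constant code).
    """
    prod = _product_vector(code)
    incoming, encoded = _incoming_counts(prod)
    if encoded.sum() < 2:
        raise UndefinedRatioError(
            f"code {code.name!r} encodes fewer than 2 residues"
        )
    vals = incoming[encoded]
    if vals.max() == 0:
        raise UndefinedRatioError(
            f"no inter-residue SNR conversions under code {code.name!r}"
        )
    return float(vals.min() / vals.max())


def f_chem(
    code: GeneticCode,
    classes: ChemicalClassTable | None = None,
    *,
    distinct: bool = False,
    count_stop_class: bool = True,
) -> float:
    """Mean chemical-class accessibility per codon.

    Default (calibrated) reading: per codon, the number of SNRs whose
    product falls in a different chemical class than the codon's own
    product, counted with multiplicity.  ``distinct=True`` instead counts
    the distinct classes represented among the non-synonymous accessible
    products.  ``count_stop_class=False`` drops the stop pseudo-class from
    the tally.
    """
    classes = classes or ChemicalClassTable()
    prod = _product_vector(code)
    cls = _class_vector(classes)[prod]  # class id per codon
    nbr = _neighbor_index()
    P = prod[nbr]
    C = cls[nbr]
    stop_cls = _class_vector(classes)[_STOP_I]
    if distinct:
        masked = np.where(P == prod[:, None], 99, C)
        if not count_stop_class:
            masked = np.where(P == _STOP_I, 99, masked)
        S = np.sort(masked, axis=1)
        counts = ((np.diff(S, axis=1) != 0) & (S[:, 1:] != 99)).sum(axis=1) + (
            S[:, 0] != 99
        )
    else:
        changed = C != cls[:, None]
        if not count_stop_class:
            changed &= P != _STOP_I
        counts = changed.sum(axis=1)
    return float(counts.mean())


F_UNIQUE_MAX = 9.0
F_RATIO_MAX = 1.0
F_CHEM_MAX = 9.0


@dataclass(frozen=True)
class FitnessReport:
    """All fitness components of one code, plus bookkeeping."""

    name: str
    f_unique: float
    f_ratio: float
    f_chem: float
    f_combined: float
    reassignments: int | None = None
    penalized_f: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def combined_fitness(
    code: GeneticCode,
    classes: ChemicalClassTable | None = None,
    reference: GeneticCode | None = None,
    *,
    distinct_chem: bool = False,
) -> FitnessReport:
    """Full fitness report: F = (F_unique/9) * F_ratio * (F_chem/9)."""
    fu = f_unique(code)
    fr = f_ratio(code)
    fc = f_chem(code, classes, distinct=distinct_chem)
    f = (fu / F_UNIQUE_MAX) * (fr / F_RATIO_MAX) * (fc / F_CHEM_MAX)
    reassign = count_reassignments(code, reference) if reference is not None else None
    return FitnessReport(
        name=code.name,
        f_unique=fu,
        f_ratio=fr,
        f_chem=fc,
        f_combined=f,
        reassignments=reassign,
    )


def penalized_fitness(
    code: GeneticCode,
    reference: GeneticCode,
    classes: ChemicalClassTable | None = None,
    *,
    alpha: float,
    exponent: int = 1,
    distinct_chem: bool = False,
) -> FitnessReport:
    """Combined fitness discounted by ``alpha ** (R ** exponent)`` where R is
    the reassignment count against ``reference``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"penalty alpha must lie in (0, 1), got {alpha}")
    if exponent not in (1, 2):
        raise ValueError(f"penalty exponent must be 1 or 2, got {exponent}")
    report = combined_fitness(code, classes, reference, distinct_chem=distinct_chem)
    r = report.reassignments
    penalized = report.f_combined * alpha ** (r ** exponent)
    return FitnessReport(
        name=report.name,
        f_unique=report.f_unique,
        f_ratio=report.f_ratio,
        f_chem=report.f_chem,
        f_combined=report.f_combined,
        reassignments=r,
        penalized_f=penalized,
    )


# ---------------------------------------------------------------------------
# fast path for optimizers: fitness straight from a product-index vector

def _fast_components(
    prod: np.ndarray, cls_vec: np.ndarray, *, distinct: bool = False
) -> tuple[float, float, float]:
    """(f_unique, f_ratio, f_chem) from a length-64 product-index vector.

    Mirrors the public metrics; an undefined ratio maps to 0 so optimizer
    intermediates always compare.  ``cls_vec`` is the 21-long class-id
    vector from :func:`_class_vector`.
    """
    nbr = _neighbor_index()
    P = prod[nbr]
    own = prod[:, None]
    S = np.sort(P, axis=1)
    fu = float(
        (1 + (np.diff(S, axis=1) != 0).sum(axis=1) - (P == own).any(axis=1)).mean()
    )
    C = cls_vec[prod]
    if distinct:
        masked = np.where(P == own, 99, cls_vec[P])
        Sm = np.sort(masked, axis=1)
        fc = float(
            (((np.diff(Sm, axis=1) != 0) & (Sm[:, 1:] != 99)).sum(axis=1)
             + (Sm[:, 0] != 99)).mean()
        )
    else:
        fc = float((cls_vec[P] != C[:, None]).sum(axis=1).mean())
    src = np.repeat(prod, N_NEIGHBORS)
    dst = P.ravel()
    mask = (src != dst) & (src != _STOP_I) & (dst != _STOP_I)
    incoming = np.bincount(dst[mask], minlength=21)[:20]
    encoded = np.bincount(prod[prod != _STOP_I], minlength=20) > 0
    vals = incoming[encoded]
    fr = 0.0 if len(vals) == 0 or vals.max() == 0 else float(vals.min() / vals.max())
    return fu, fr, fc


def _fast_fitness(
    prod: np.ndarray, cls_vec: np.ndarray, *, distinct: bool = False
) -> float:
    fu, fr, fc = _fast_components(prod, cls_vec, distinct=distinct)
    return (fu / F_UNIQUE_MAX) * (fr / F_RATIO_MAX) * (fc / F_CHEM_MAX)


# ---------------------------------------------------------------------------
# edge census

@dataclass(frozen=True)
class EdgeCensus:
    """Classification of the 288 Hamming-1 codon pairs of a code.

    ``red_edges`` is the figure-style count of pairs whose products share a
    chemical class: synonymous pairs plus within-class pairs.
    """

    synonymous: int
    within_class: int
    between_class: int
    stop_involving: int

    @property
    def total(self) -> int:
        return self.synonymous + self.within_class + self.between_class + self.stop_involving

    @property
    def red_edges(self) -> int:
        return self.synonymous + self.within_class

    def to_dict(self) -> dict:
        d = asdict(self)
        d["red_edges"] = self.red_edges
        return d


def edge_census(
    code: GeneticCode, classes: ChemicalClassTable | None = None
) -> EdgeCensus:
    """Assign every unordered Hamming-1 codon pair to exactly one category.

    ``stop_involving`` when either product is stop; ``synonymous`` when
    products are equal; ``within_class`` when they differ but share a
    chemical class; ``between_class`` otherwise.
    """
    classes = classes or ChemicalClassTable()
    prod = _product_vector(code)
    cls = _class_vector(classes)[prod]
    edges = _edge_index()
    p, q = prod[edges[:, 0]], prod[edges[:, 1]]
    cp, cq = cls[edges[:, 0]], cls[edges[:, 1]]
    stop = (p == _STOP_I) | (q == _STOP_I)
    syn = (p == q) & ~stop
    within = (p != q) & (cp == cq) & ~stop
    between = ~stop & ~syn & ~within
    return EdgeCensus(
        synonymous=int(syn.sum()),
        within_class=int(within.sum()),
        between_class=int(between.sum()),
        stop_involving=int(stop.sum()),
    )


def edge_list(
    code: GeneticCode, classes: ChemicalClassTable | None = None
) -> pd.DataFrame:
    """Long-form table of all 288 Hamming-1 pairs with their category."""
    classes = classes or ChemicalClassTable()
    rows = []
    for i, j in _edge_index():
        a, b = CODONS[i], CODONS[j]
        p, q = code[a], code[b]
        if p == STOP or q == STOP:
            cat = "stop_involving"
        elif p == q:
            cat = "synonymous"
        elif classes[p] == classes[q]:
            cat = "within_class"
        else:
            cat = "between_class"
        rows.append((a, b, p, q, cat))
    return pd.DataFrame(rows, columns=["codon_a", "codon_b", "product_a", "product_b", "category"])


# ---------------------------------------------------------------------------
# minimum-replacement distance matrix

class UndefinedEntryError(ValueError):
    """A product has no codon under the code, so its distances are undefined."""


def min_replacements(code: GeneticCode) -> pd.DataFrame:
    """21x21 matrix of minimal nucleotide replacements between products.

    Entry (a, b) is the minimum Hamming distance over codon pairs encoding
    a and b.  Diagonal 0, symmetric, off-diagonal values in {1, 2, 3}.
    """
    present = sorted(set(code.translation), key=PRODUCTS.index)
    missing = sorted(set(PRODUCTS) - set(present))
    if missing:
        raise UndefinedEntryError(f"product(s) with no codon: {missing}")
    codon_arrays = {
        p: np.array([[BASES.index(b) for b in c] for c in code.codons_for(p)])
        for p in present
    }
    n = len(present)
    mat = np.zeros((n, n), dtype=int)
    for i, a in enumerate(present):
        for j in range(i + 1, n):
            b = present[j]
            ca, cb = codon_arrays[a], codon_arrays[b]
            d = (ca[:, None, :] != cb[None, :, :]).sum(axis=2).min()
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=present, columns=present)


# ---------------------------------------------------------------------------
# substitution-table analysis

def substitution_analysis(
    observed: pd.DataFrame,
    code: GeneticCode | None = None,
    *,
    exact: bool = False,
) -> tuple[pd.DataFrame, float, float]:
    """Relate observed residue-substitution counts to required replacements.

    Parameters
    ----------
    observed:
        DataFrame with columns ``wt``, ``mut``, ``count`` (non-negative).
    code:
        Code defining the minimum-replacement distances (standard if None).
    exact:
        Use an exact permutation test for the Spearman p-value (small
        tables); default is the large-sample approximation.

    Returns
    -------
    (normalized table, Spearman rho, p-value) where the table gains
    ``frequency`` and ``min_replacements`` columns and the correlation is
    computed between replacement class (1/2/3) and frequency over all
    ordered residue pairs present.
    """
    from .codes import standard_code

    if observed.empty:
        raise ValueError("empty substitution table")
    required = {"wt", "mut", "count"}
    if not required.issubset(observed.columns):
        raise ValueError(f"substitution table needs columns {sorted(required)}")
    if (observed["count"] < 0).any():
        raise ValueError("substitution counts must be non-negative")
    code = code or standard_code()
    dist = min_replacements(code)
    table = observed.copy()
    table["wt"] = table["wt"].str.upper()
    table["mut"] = table["mut"].str.upper()
    bad = (set(table["wt"]) | set(table["mut"])) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residue symbol(s): {sorted(bad)}")
    total = table["count"].sum()
    if total == 0:
        raise ValueError("substitution table has zero total count")
    table["frequency"] = table["count"] / total
    table["min_replacements"] = [
        int(dist.loc[w, m]) for w, m in zip(table["wt"], table["mut"])
    ]
    if exact:
        res = stats.spearmanr(table["min_replacements"], table["frequency"])
        rho = float(res.statistic)
        perm = stats.permutation_test(
            (table["min_replacements"].to_numpy(),),
            lambda x: stats.spearmanr(x, table["frequency"]).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            random_state=0,
        )
        return table, rho, float(perm.pvalue)
    rho, p = stats.spearmanr(table["min_replacements"], table["frequency"])
    return table, float(rho), float(p)


# ---------------------------------------------------------------------------
# gene-level evolvability

def evolvability(gene: str, code: GeneticCode) -> float:
    """Mean per-codon unique SNR accessibility over a coding sequence."""
    seq = gene.strip().upper().replace("U", "T")
    if not seq:
        raise ValueError("empty gene")
    if len(seq) % 3:
        raise ValueError(f"gene length {len(seq)} is not a multiple of 3")
    ua = _unique_access_vector(_product_vector(code))
    idx = [CODON_INDEX[normalize_codon(seq[i : i + 3])] for i in range(0, len(seq), 3)]
    return float(ua[idx].mean())


def mean_evolvability(genes: Iterable[str], code: GeneticCode) -> float:
    """Mean of per-gene evolvability scores."""
    scores = [evolvability(g, code) for g in genes]
    if not scores:
        raise ValueError("no genes supplied")
    return float(np.mean(scores))
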