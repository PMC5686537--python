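"""Synonymous-by-construction gene recoding between genetic codes.

Rewrites a coding sequence so that it translates to the same protein under
a *target* code as the original does under its *source* code, while staying
as close as possible to the wild-type mRNA folding energy and secondary
structure.  The region whose structure matters most for translation
initiation — the 4-nt 5'UTR plus the first 13 codons (39 nt) of the CDS —
is optimized first by sampling a fraction of the Cartesian product of
per-position candidate codons; the remaining CDS is processed left to right
in 30-nt windows at a smaller sampling fraction, each window folded in the
context of the 30 nt preceding it.

Folding backends
----------------
``dp``
    Self-contained base-pair maximization dynamic program (Watson-Crick +
    GU wobble, minimum hairpin loop of 3 unpaired bases); energy is the
    negated pair count.  Deterministic and dependency-free; the default.
``thermo``
    Minimum-free-energy folding through the ViennaRNA Python bindings when
    they are installed; energies in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .codes import GeneticCode

_PAIRS = {("G", "C"), ("C", "G"), ("A", "T"), ("T", "A"), ("G", "T"), ("T", "G")}
_MIN_LOOP = 3


class UnencodableError(ValueError):
    """A residue required by the protein has no codon in the target code."""


@dataclass(frozen=True)
class FoldResult:
    """Secondary structure (dot-bracket) and folding energy of a sequence."""

    structure: str
    energy: float

    def pairs(self) -> frozenset[tuple[int, int]]:
        return _pairs_from_dotbracket(self.structure)


def _pairs_from_dotbracket(structure: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = set()
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced structure: {structure}")
            pairs.add((stack.pop(), i))
    if stack:
        raise ValueError(f"unbalanced structure: {structure}")
    return frozenset(pairs)


def _normalize_seq(sequence: str) -> str:
    s = sequence.strip().upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    bad = sorted(set(s) - set("ACGT"))
    if bad:
        raise ValueError(f"invalid nucleotide(s): {bad}")
    return s


@lru_cache(maxsize=4096)
def _fold_dp(seq: str) -> FoldResult:
    """Base-pair maximization (Nussinov-style) with traceback."""
    n = len(seq)
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j] if i + 1 <= j else 0
            if j - 1 >= i:
                best = max(best, dp[i, j - 1])
            if (seq[i], seq[j]) in _PAIRS and j - i > _MIN_LOOP:
                inner = dp[i + 1, j - 1] if i + 1 <= j - 1 else 0
                best = max(best, inner + 1)
            for k in range(i + 1, j):
                cand = dp[i, k] + dp[k + 1, j]
                if cand > best:
                    best = cand
            dp[i, j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
        elif dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
        elif (
            (seq[i], seq[j]) in _PAIRS
            and j - i > _MIN_LOOP
            and dp[i, j] == (dp[i + 1, j - 1] if i + 1 <= j - 1 else 0) + 1
        ):
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
        else:
            for k in range(i + 1, j):
                if dp[i, j] == dp[i, k] + dp[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    n_pairs = int(dp[0, n - 1]) if n > 1 else 0
    return FoldResult("".join(structure), -float(n_pairs))


def _fold_thermo(seq: str) -> FoldResult:
    try:
        import RNA  # ViennaRNA bindings
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RuntimeError(
            "the 'thermo' backend needs the ViennaRNA Python bindings"
        ) from exc
    structure, mfe = RNA.fold(seq.replace("T", "U"))
    return FoldResult(structure, float(mfe))


_BACKENDS = {"dp": _fold_dp, "thermo": _fold_thermo}


def fold(sequence: str, backend: str = "dp") -> FoldResult:
    """Fold a nucleotide sequence (DNA or RNA alphabet accepted)."""
    if backend not in _BACKENDS:
        raise ValueError(f"unknown folding backend {backend!r}; use {sorted(_BACKENDS)}")
    return _BACKENDS[backend](_normalize_seq(sequence))


def structure_distance(a: FoldResult, b: FoldResult) -> int:
    """Base-pair distance: size of the symmetric difference of pair sets."""
    if len(a.structure) != len(b.structure):
        raise ValueError(
            f"structure lengths differ: {len(a.structure)} vs {len(b.structure)}"
        )
    return len(a.pairs() ^ b.pairs())


# ---------------------------------------------------------------------------
# recoding

@dataclass(frozen=True)
class RecodingConfig:
    """Knobs of the recoding procedure (defaults follow the leader/window
    scheme: 4-nt UTR, 39-nt leader CDS scanned at 1%, 30-nt body windows
    scanned at 0.4%)."""

    utr_length: int = 4
    leader_cds_length: int = 39
    leader_scan_fraction: float = 0.01
    body_window: int = 30
    body_scan_fraction: float = 0.004
    candidate_cap: int = 100_000
    structure_weight: float = 1.0
    backend: str = "dp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leader_cds_length % 3 or self.body_window % 3:
            raise ValueError("leader_cds_length and body_window must be codon-aligned")
        for frac in (self.leader_scan_fraction, self.body_scan_fraction):
            if not 0.0 < frac <= 1.0:
                raise ValueError("scan fractions must lie in (0, 1]")


@dataclass
class RegionDiagnostics:
    region: str
    start: int           # 0-based offset into the CDS
    length: int
    wt_energy: float
    recoded_energy: float
    bp_distance: int
    candidates_scored: int


@dataclass
class RecodedGene:
    """A recoded coding sequence plus per-region folding diagnostics."""

    original: str
    recoded: str
    utr: str
    regions: list[RegionDiagnostics] = field(default_factory=list)
    translation_preserved: bool = True


def _candidate_lists(protein: str, target: GeneticCode, offset_codons: int) -> list[tuple[str, ...]]:
    lists = []
    for k, aa in enumerate(protein):
        codons = target.codons_for(aa)
        if not codons:
            raise UnencodableError(
                f"residue {aa!r} at codon position {offset_codons + k} "
                f"has no codon in code {target.name!r}"
            )
        lists.append(codons)
    return lists


def _sample_assemblies(
    lists: list[tuple[str, ...]],
    fraction: float,
    cap: int,
    rng: np.random.Generator,
    always: str | None = None,
) -> list[str]:
    """Uniform sample (without replacement) of the Cartesian product."""
    radices = [len(l) for l in lists]
    size = math.prod(radices)
    k = min(cap, max(1, math.ceil(fraction * size)))

    def assemble(index: int) -> str:
        parts = []
        for codons, r in zip(reversed(lists), reversed(radices)):
            index, digit = divmod(index, r)
            parts.append(codons[digit])
        return "".join(reversed(parts))

    if size <= max(10 * k, 4096):
        indices = rng.choice(size, size=min(k, size), replace=False)
    else:
        chosen: set[int] = set()
        while len(chosen) < k:
            chosen.update(int(x) for x in rng.integers(size, size=k - len(chosen)))
        indices = sorted(chosen)
    out = [assemble(int(i)) for i in indices]
    if always is not None and always not in out:
        out.append(always)
    return out


def _score(
    candidate: str, wt: FoldResult, weight: float, backend: str
) -> tuple[float, int, FoldResult]:
    f = fold(candidate, backend)
    d = structure_distance(f, wt)
    return abs(f.energy - wt.energy) + weight * d, d, f


def _pick_best(
    prefix: str,
    assemblies: list[str],
    wt: FoldResult,
    config: RecodingConfig,
) -> tuple[str, float, int, FoldResult]:
    best = None
    for cand in assemblies:
        s, d, f = _score(prefix + cand, wt, config.structure_weight, config.backend)
        key = (s, d, cand)
        if best is None or key < best[0]:
            best = (key, cand, s, d, f)
    _, cand, s, d, f = best
    return cand, s, d, f


def recode_leader(
    utr: str,
    cds: str,
    source: GeneticCode,
    target: GeneticCode,
    config: RecodingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, RegionDiagnostics]:
    """Recode the leader CDS (first 13 codons) against the wild-type fold.

    Returns the recoded leader CDS (without the UTR) and its diagnostics.
    The identity assembly is always scored when it is a valid recoding, so
    recoding a gene onto its own code returns the wild-type sequence.
    After the scan, positions where the candidate and wild-type structures
    disagree trigger a repair pass: codons overlapping a disagreement are
    swapped for synonymous alternatives when that strictly improves the
    score.
    """
    config = config or RecodingConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    utr = _normalize_seq(utr) if utr else ""
    cds = _normalize_seq(cds)
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    leader_nt = min(config.leader_cds_length, len(cds))
    if leader_nt % 3:
        raise ValueError("leader region not codon-aligned")
    leader = cds[:leader_nt]
    protein = source.translate(leader)
    lists = _candidate_lists(protein, target, 0)
    identity = leader if target.translate(leader) == protein else None
    assemblies = _sample_assemblies(
        lists, config.leader_scan_fraction, config.candidate_cap, rng, always=identity
    )
    wt = fold(utr + leader, config.backend)
    cand, score, dist, cand_fold = _pick_best(utr, assemblies, wt, config)

    # disparity repair: re-optimize codons overlapping structural disagreements
    if dist > 0:
        cand_list = [cand[i : i + 3] for i in range(0, len(cand), 3)]
        for k, aa in enumerate(protein):
            lo, hi = len(utr) + 3 * k, len(utr) + 3 * k + 3
            disagree = any(
                cand_fold.structure[p] != wt.structure[p] for p in range(lo, hi)
            )
            if not disagree:
                continue
            for alt in target.codons_for(aa):
                if alt == cand_list[k]:
                    continue
                trial = cand_list.copy()
                trial[k] = alt
                s, d, f = _score(
                    utr + "".join(trial), wt, config.structure_weight, config.backend
                )
                if s < score:
                    cand_list, score, dist, cand_fold = trial, s, d, f
        cand = "".join(cand_list)

    diag = RegionDiagnostics(
        region="leader",
        start=0,
        length=leader_nt,
        wt_energy=wt.energy,
        recoded_energy=cand_fold.energy,
        bp_distance=dist,
        candidates_scored=len(assemblies),
    )
    return cand, diag


def recode_gene(
    utr: str,
    gene: str,
    source: GeneticCode,
    target: GeneticCode,
    config: RecodingConfig | None = None,
) -> RecodedGene:
    """Recode a full CDS: leader scan, then tiled 30-nt window scans.

    Each body window is scored in the folding context of the 30 nt that
    precede it (already-recoded sequence vs the wild-type counterpart).
    The final partial window is processed as its own region; there is no
    adjustment pass after the windows.  The returned gene satisfies
    ``target.translate(recoded) == source.translate(original)``.
    """
    config = config or RecodingConfig()
    rng = np.random.default_rng(config.seed)
    gene = _normalize_seq(gene)
    if len(gene) % 3:
        raise ValueError(f"gene length {len(gene)} is not a multiple of 3")
    utr = _normalize_seq(utr) if utr else ""

    leader, leader_diag = recode_leader(utr, gene, source, target, config, rng)
    recoded = leader
    regions = [leader_diag]
    pos = leader_diag.length
    while pos < len(gene):
        window = gene[pos : pos + config.body_window]
        protein = source.translate(window)
        lists = _candidate_lists(protein, target, pos // 3)
        identity = window if target.translate(window) == protein else None
        assemblies = _sample_assemblies(
            lists, config.body_scan_fraction, config.candidate_cap, rng,
            always=identity,
        )
        ctx = 30
        rec_prefix = recoded[-ctx:] if ctx else ""
        wt_prefix = gene[max(0, pos - ctx) : pos]
        wt = fold(wt_prefix + window, config.backend)
        # candidate context uses the recoded upstream sequence; pad to the
        # wild-type context length so structures stay comparable
        rec_prefix = rec_prefix[-len(wt_prefix) :] if wt_prefix else ""
        cand, score, dist, cand_fold = _pick_best(rec_prefix, assemblies, wt, config)
        regions.append(
            RegionDiagnostics(
                region="window",
                start=pos,
                length=len(window),
                wt_energy=wt.energy,
                recoded_energy=cand_fold.energy,
                bp_distance=dist,
                candidates_scored=len(assemblies),
            )
        )
        recoded += cand
        pos += len(window)

    preserved = target.translate(recoded) == source.translate(gene)
    if not preserved:  # pragma: no cover - hard invariant, bug guard
        raise AssertionError("translation not preserved; internal recoding bug")
    return RecodedGene(
        original=gene, recoded=recoded, utr=utr, regions=regions,
        translation_preserved=preserved,
    )
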