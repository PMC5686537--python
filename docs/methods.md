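# Methods

## Model

A genetic code is a total map from the 64 trinucleotide codons to 21
products (20 residues + the stop signal). All metrics derive from the
single-nucleotide-replacement (SNR) graph on codons: each codon has
exactly 9 neighbors at Hamming distance 1, giving 288 unordered codon
pairs (64·9/2). The package treats the code as the designable object and
asks how much amino-acid diversity the SNR graph exposes.

### Fitness components

* `F_unique(C)` = mean over the 64 codons of `|{AA(c') : d(c,c')=1} \ {AA(c)}|`,
  the number of distinct alternative products one SNR away. Stop codons
  participate both as sources (they are averaged over) and as a reachable
  product. Range 0–9.
* `F_ratio(C)`: for each encoded residue `a`, count directed Hamming-1
  events `(c → c')` with `AA(c) ≠ AA(c') = a` and neither product a stop;
  `F_ratio` = min/max of these counts over encoded residues. A residue
  with no incoming conversions forces 0; a code with no conversions at
  all has no defined ratio (`UndefinedRatioError`). Stop is not a residue
  here.
* `F_chem(C, classes)`: chemical diversity of mutational outcomes. The
  default reading counts, per codon, the **number of SNRs whose product
  belongs to a different chemical class**, multiplicity included, with
  stop as its own pseudo-class; range 0–9. A distinct-classes variant
  (`distinct=True`) counts the number of different classes among the
  non-synonymous reachable products instead. Which variant a caller gets
  is an explicit toggle everywhere; see "Calibration" for why the
  defaults differ between the metrics and the stepwise module.
* Combined: `F = (F_unique/9) · F_ratio · (F_chem/9)`, each component
  normalized by its theoretical maximum so no axis dominates selection.
  Reassignment penalties multiply `F` by `alpha^(R^N)` with `R` the
  Hamming distance to a reference code over the 64 positions, `N ∈ {1,2}`.
  `alpha` has no canonical value; `evocode` requires it explicitly for
  penalized runs (0.95 is a reasonable starting point).

### Calibration of the chemical-class table

The class partition is a config file, not a constant. The shipped default
was calibrated jointly against two reference statistics of the standard
code: mean chemical-class accessibility **5.53** per codon and **109**
same-class Hamming-1 edges. Two facts fall out of the calibration:

1. With stop↔sense adjacencies fixed (23 of the 25 stop-involving edges
   connect a stop to a sense codon), the multiplicity reading satisfies
   `F_chem = 2·(between_class_edges + 23)/64`, so 5.53125 = 354/64 pins
   the partition to exactly 154 between-class and 42 within-class
   non-synonymous edges. The red-edge count then follows *from the same
   constraint*: 67 synonymous + 42 within-class = 109 same-class pairs.
   No partition satisfies both statistics under the distinct-classes
   reading (annealing over all 10^13 partitions of the 20 residues caps
   the within-class count near 49 when the distinct-class mean is held at
   5.53).
2. Among partitions that keep the textbook chemistry groups intact, the
   within-42 requirement has a unique solution: the seven-group chart
   (aliphatic, aromatic, acidic, basic, hydroxyl, sulfur, amide) with
   isoleucine's bulky β-branched side chain split into its own class.
   Parity rules out every alternative: all other group splits/merges
   change the within-class count by even amounts, and 49 − 42 = 7 is odd;
   only the I split (removing the I–L and I–V adjacencies, 4 + 3 edges)
   fits.

The default table is therefore: aliphatic {G,A,V,L,P}, β-branched {I},
aromatic {F,W,Y}, acidic {D,E}, basic {K,R,H}, hydroxyl {S,T},
sulfur {C,M}, amide {N,Q}, STOP {\*}. Users can supply any partition as
JSON/TSV.

### Edge census

Every Hamming-1 pair gets exactly one category: `stop_involving` (either
product is stop), `synonymous` (equal products), `within_class`
(different products, same class), `between_class` (otherwise); the four
counts always sum to 288. `red_edges` = synonymous + within_class is the
figure-style "conservative edge" count (a synonymous pair trivially
shares its class). Standard code: 67/42/154/25, red 109.

## Genetic algorithm

Individuals are full 64-codon assignments. Per round: rank by fitness
(penalized if configured), take the top `elite_fraction`, create
offspring by mutating elite members cyclically (`offspring i` mutates
`elite[i mod n_elite]`), and carry the incumbent best over unchanged
(elitism ⇒ the best-fitness trace is non-decreasing). Mutation visits
each non-frozen codon independently with probability `mutation_rate`
(default 0.10) and copies the product of another uniformly chosen codon;
COPY (not exchange) is the default because an exchange-only operator
preserves the multiset of codon counts and could never flatten the
standard code's 1–6 codons-per-residue spread. An exchange operator is
available as a switch.

Offspring must also pass (a) the constraint set — frozen codons
(including TAA in stopless mode), optional native-codon retention per
residue, optional all-residues-present — and (b) the chemical-diversity
acceptance ratchet: `F_chem` at least that of the best individual seen so
far. Violations are resampled up to 50 times, then the parent is copied;
this bounds every round's work. The ratchet is a *constraint*, not part
of the objective: it deliberately changes the reachable set (the
restricted two-codon scenario has an unconstrained optimum the ratcheted
GA cannot reach), which is why oracle-equivalence tests disable it.

Stopless preparation (`prepare_stopless`) reassigns TAG and TGA to
asparagine and freezes TAA as the sole stop before optimization, so the
search never has to reason about stop-codon placement.

Restricted mode (`optimize_free_codons`) freezes all but a chosen codon
set to their standard assignments — e.g. the seven codons synonymously
removed in the 57-codon *E. coli* design (AGA, AGG, AGC, AGT, TTA, TTG,
TAG; configurable) — and searches only their products; sets of ≤ 2 codons
are enumerated exhaustively (21 products each) instead.

Reference run sizes are 2,500 individuals × 1,000 rounds; the shipped
tests and the acceptance script use 500 × 300 for the seven-codon
scenario, which converges to the same improvement level (≈ +8% F_unique)
in a couple of minutes on one CPU.

## Recursive best-move search

One *move* reassigns one non-stop codon to any of the 20 residues
(residue loss disallowed by default; stop codons are excluded from the
search and survive untouched). The branching mode is a deterministic
iso-fitness front expansion: from the current set of codes, generate all
single moves, keep every code attaining the maximal fitness reached this
round (deduplicated on the 64-symbol string), and repeat until no move
improves any front member. This realizes "branch over all tied best
moves and keep the maximal-fitness ensemble" without materializing the
full tie tree. Node budget 10^6 evaluations (the standard-code run needs
≈ 2.3·10^5); exceeding it raises an error carrying the partial result.
Greedy mode follows one best move per round (first in canonical
codon/product order). Greedy depth is tie-path dependent — across
tie-break policies it ranged from 11 to 34 rounds in our experiments — so
depth statements should always reference the branching mode.

The stepwise objective is the unpenalized combined `F` with the
**distinct-classes** `F_chem` reading: under the calibrated class table
this is the variant whose branching search from the stopless-prepared
standard code terminates exactly when single-step improvements are
exhausted at 16 rounds, the reference landmark; the multiplicity reading
terminates at 19. Both are exposed (`distinct_chem=`). The terminal code
of the depth-16 search lifts `F_unique` from 6.11 to 7.33 (+19.9%).

## Gene recoding

Inputs: a CDS (DNA or RNA alphabet), a 4-nt 5'UTR (placeholder `AGGA`
when absent), a source and a target code. The protein under the source
code is the hard invariant: the result always translates to it under the
target code, residue for residue.

* **Leader**: the first 13 codons (39 nt — the biologically motivated
  37 nt padded to codon alignment). Translate, build per-residue codon
  candidate lists under the target code, and sample
  `min(cap, ceil(0.01 · |Cartesian product|))` distinct assemblies
  uniformly without replacement (seeded; the identity assembly is always
  scored when it is a valid recoding, making source = target an exact
  no-op). Candidates are scored as `|E − E_wt| + λ·d_bp` against the
  fold of UTR + wild-type leader, where `d_bp` is the base-pair distance
  (symmetric difference of pair sets) and λ defaults to 1. Ties break on
  lower `d_bp`, then lexicographic sequence. A repair pass then revisits
  codons overlapping positions where the chosen structure disagrees with
  the wild type, accepting synonymous swaps that strictly improve the
  score.
* **Body**: the remaining CDS in consecutive 30-nt windows (final partial
  window as its own region), sampled at 0.4%, each scored in the folding
  context of the 30 nt preceding the window (recoded upstream sequence
  vs the wild-type counterpart — chosen so windows feel upstream
  structure while keeping folds short). No adjustment pass after the
  windows.
* The per-region sampling cap (default 10^5) bounds work when candidate
  spaces explode; caps, energies, and base-pair distances are recorded in
  the per-region diagnostics.

The default folding backend is a base-pair-maximization dynamic program
(Watson–Crick + GU wobble, minimum hairpin loop of 3 unpaired bases,
energy = −pair count) — deterministic, dependency-free, and adequate for
*relative* structure comparison between synonymous variants. It is not a
thermodynamic model: absolute energies are meaningless, and isoenergetic
structures are common at short lengths. The `thermo` backend (ViennaRNA
bindings, when installed) provides kcal/mol MFE folds; results then
depend on the ViennaRNA parameter version.

## Synthetic data

* `random_gene`: codons drawn per position among the code's sense codons
  with weights `exp(-8·|gc(codon) − target|)`; empirical GC of a
  1,000-codon gene stays within ±5% of the target. Optional ATG start
  and stop appending; no internal stops by construction.
* `random_code`: pins the 20 residues plus the requested number of stops
  to distinct random codons, fills the rest uniformly — every draw is a
  valid code, used as the test substrate for metric/optimizer oracles.
* `synthetic_substitutions`: samples ordered residue pairs with
  probability ∝ `bias^(1 − d)` where `d` is the minimal-replacement
  distance under a code, emulating the empirical dominance of
  single-replacement amino-acid changes in mutagenesis datasets.
  `substitution_analysis` recovers the injected bias as a negative
  Spearman correlation between required replacements and observed
  frequency.

What the generators do **not** emulate: real codon-usage bias, GC skew
along genes, ribosome-binding-site constraints, or the composition of any
particular organism's essential-gene set. Green tests on synthetic genes
therefore certify the machinery (invariants, determinism, optimization
behavior), not organism-specific effect sizes; gene-level evolvability
numbers on real genomes require the user's own FASTA.

## Numerical conventions

* Fitness ties use an absolute tolerance of 1e-12; all fitness values are
  ratios of small integers, so true ties are exact and 1e-12 only guards
  against float association effects.
* Population (not sample) SD for the 64-codon accessibility distribution:
  the 64 codons are the whole population.
* Spearman p-values use scipy's large-sample approximation by default; an
  exact permutation test (`exact=True`) is available for small tables.
* Printed-value comparisons round half-even to the printed precision.
* All stochastic components (GA, recoder sampling, generators) flow
  through a single seeded `numpy` Generator per run; identical seed ⇒
  bit-identical output.

## Known limitations

* The recursive search's branching front can in principle grow large on
  adversarial codes; the node budget turns that into a clean error with a
  partial result rather than an open-ended run.
* The GA's diversity ratchet makes late-stage exploration conservative;
  runs that need to trade `F_chem` down for `F_unique` up should disable
  it (`fchem_acceptance=False`).
* The DP folding backend ignores thermodynamics entirely (see above);
  leader/window scores under `dp` and `thermo` are not comparable.
* Codes with residues encoded by a single codon constrain both mutation
  (residue-loss guard) and the distance matrix; codes missing residues
  outright are representable (`require_all_residues=False`) but most
  metrics treat them as degenerate inputs.
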