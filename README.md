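# evocode

Tools for quantifying — and deliberately maximizing — the *evolvability*
of genetic codes: how many distinct amino acids a point mutation can reach.

The standard genetic code is famously robust: a single nucleotide
replacement (SNR) in a codon usually produces the same amino acid or a
chemically similar one. That robustness is a feature for living cells and
a handicap for laboratory evolution, which explores sequence space almost
exclusively through single point mutations. `evocode` treats the 64-codon
table itself as a designable object: it measures how much amino-acid
diversity SNRs can reach under a given code, searches for reassigned codon
tables that maximize that diversity, and rewrites coding sequences under a
new table while preserving the protein and approximating the wild-type
mRNA folding.

## The fitness function

Every codon has 9 SNR neighbors (3 positions × 3 alternative bases). For a
code *C* mapping codons to products (20 residues + stop):

* **F_unique** — the mean, over all 64 codons, of the number of *distinct*
  products reachable by one SNR that differ from the codon's own product
  (stop counts as a product). Standard code: **6.1** (SD 0.69, range 5–7).
* **F_ratio** — evenness of incoming conversions: for each encoded residue
  count the directed SNR events that produce it from a different residue;
  F_ratio = min/max over residues. 1.0 means perfectly even.
* **F_chem** — chemical diversity of SNR outcomes: the mean number of SNRs
  per codon whose product falls in a different chemical class (side-chain
  chemistry partition; a distinct-classes variant is available). Standard
  code: **5.53**.

The combined fitness is the normalized product

```
F = (F_unique / 9) · F_ratio · (F_chem / 9)
```

and may be discounted by `alpha^(R^N)` where R is the number of codon
reassignments against a reference code (N = 1 linear, N = 2 squared), to
search for codes that buy most of the accessibility gain with few changes.

Three optimizers/analyses sit on top:

* a **genetic algorithm** over codon tables (cyclical top-10% selection,
  10%-per-codon reassignment mutation, elitism, and a chemical-diversity
  acceptance ratchet), with constraint flags (frozen codons, native-codon
  retention, residue-loss control, restricted reassignable sets);
* a **recursive best-move search** that repeatedly applies the single
  codon reassignment with the maximal fitness gain, branching over ties,
  until no single move improves the code;
* a **gene recoder** that rewrites a CDS from one code to another,
  sampling synonymous-candidate assemblies for the translation-initiation
  leader (4-nt 5'UTR + first 39 nt, 1% scan) and 30-nt body windows
  (0.4% scan), scored by |ΔMFE| + λ·base-pair distance against the
  wild-type fold (self-contained base-pair-maximization DP by default,
  ViennaRNA backend optional).

## Worked example

```python
>>> from evocode import standard_code, ChemicalClassTable, combined_fitness
>>> from evocode import edge_census, prepare_stopless, recursive_search, f_unique
>>> std = standard_code()
>>> rep = combined_fitness(std)
>>> round(rep.f_unique, 1), round(rep.f_chem, 2), round(rep.f_ratio, 3)
(6.1, 5.53, 0.189)
```

So an average codon can reach 6.1 other products by point mutation, those
mutations cross a chemical-class boundary 5.53 times per codon, and the
most SNR-accessible residue receives 1/0.189 ≈ 5× more incoming
conversions than the least accessible one.

```python
>>> edge_census(std).red_edges          # Hamming-1 pairs sharing a class
109
>>> result = recursive_search(prepare_stopless(std))
>>> result.depth
16
>>> round(f_unique(result.best), 2)     # up from 6.11
7.33
```

Sixteen rounds of single best-move reassignment exhaust all single-step
improvements and lift the mean SNR accessibility from 6.11 to 7.33 amino
acids per codon.

The same machinery is available from the shell:

```
evocode evaluate                       # fitness report for the standard code
evocode edges                          # 288-edge census
evocode stepwise --out runs/step       # recursive search, codes + trace
evocode evolve --pop 500 --rounds 300 --seed 1 --out runs/ga
evocode simulate genes --n 10 --length 200 --seed 1 --out genes.fasta
evocode recode --fasta genes.fasta --to-code runs/ga.code.tsv --seed 1 --out runs/recoded
```

## Layout

| module | contents |
| --- | --- |
| `evocode.codes` | `GeneticCode`, `ChemicalClassTable`, parsing/serialization |
| `evocode.metrics` | SNR neighborhoods, F_unique/F_ratio/F_chem/F, edge census, distance matrix, substitution analysis, gene evolvability |
| `evocode.ga` | genetic algorithm, constraints, free-codon restricted mode |
| `evocode.stepwise` | best-move generation, branching/greedy recursive search |
| `evocode.recode` | folding backends, leader/window structure-preserving recoding |
| `evocode.datagen` | synthetic genes, scrambled codes, biased substitution tables |
| `evocode.io` / `evocode.cli` | FASTA/table IO, code comparison, `evocode` CLI |

See `docs/methods.md` for the model details, calibration of the chemical
class table, numerical conventions, and known limitations.
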