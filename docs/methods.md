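# Methods

## Problem and data model

Bacterial ribosomal protein S1 is a tandem array of one to six ~70-residue
S1 domains (OB-fold RNA-binding repeats) joined by short linkers. Two
questions drive the pipeline: how domain count distributes across bacterial
phyla, and which repeat position is most conserved. A record is a protein
sequence plus annotation: accession, protein and gene name, semicolon
lineage, phylum, the ordered 1-based inclusive (start, end) boundaries of
its S1 domains, and a flag for annotated non-S1 domains. Boundaries must be
sorted, non-overlapping and inside the sequence; conversion to Python
slices happens in exactly one function so off-by-one errors cannot
multiply. `X` is accepted in sequences and flagged, but never counts as an
identity match — not even against another `X`.

## Record selection

The funnel applies five subset rules in a fixed order and logs attrition
per rule: (1) the lowercased protein name must contain one of eight S1
family keywords (substring match — annotation capitalisation varies too
much for exact matching); (2) the gene must fullmatch `rpsA(_\d+)?`
case-insensitively, so numbered analogs pass but `rpsAB` does not; (3)
records whose lineage or phylum contains the stem `candidat` are removed —
the stem deliberately catches both "candidate division ..." and
"Candidatus ...", since neither has standing in nomenclature (the stem is
configurable back to the literal word); (4) records with zero annotated S1
domains are removed; (5) records with extra non-S1 domains are removed. An
optional strict mode additionally keeps only six-character accessions (a
proxy for fully annotated database records); it is off by default because
it is meaningless for synthetic accessions. The first three rules commute
(they are independent predicates); the composition is idempotent, and the
report's chain invariant (`n_out == n_in - dropped`, consecutive rows
chain) is enforced at construction.

## Alignment and identity

Needleman–Wunsch global alignment is implemented from first principles as
a three-state affine recurrence (M / gap-in-b / gap-in-a), filled and
traced back in numba-compiled kernels over int8-encoded residues
(~17k alignments of 70×70 per second on one core, which makes the
quadratic matrix sweeps tractable). A gap of length L costs
`gap_open + (L-1)*gap_extend`; with `gap_open == gap_extend` this is a
linear penalty. Traceback ties prefer diagonal, then gap-in-b, then
gap-in-a, making outputs byte-deterministic. Correctness is checked three
ways: exhaustive recursive enumeration of all global alignments for short
pairs, an LCS cross-check (with all-zero gap penalties and match=1/
mismatch=0 the optimal score equals the longest-common-subsequence
length), and an independent library aligner on random pairs.

**Default scoring: match=1, mismatch=0, gap −1 linear.** A pure
match-count scheme with zero gap penalties looks like the obvious
"standard parameters", but its optimum is the LCS alignment: for 70-residue
domain pairs it inserts many free gaps, and the resulting identity deviates
by ~10 points from the substitution-model expectation (measured: 68.5%
observed vs 81.1% expected at divergence 0.1/0.1). A unit linear gap
penalty keeps the ungapped alignment optimal for equal-length homologous
sequences while still tolerating genuine length differences, and
reproduces the closed form to under one point. BLOSUM62 with affine gaps
(−10/−0.5) and the zero-gap scheme remain available for sensitivity
analysis.

**Identity denominator.** Percent identity divides matching columns (same
non-gap, non-X residue) by the full alignment length, gap columns
included — the most conservative convention, monotone under added gaps.
`shorter` (shorter ungapped sequence) and `aligned_columns` are selectable;
every output header names the denominator used. A zero-length alignment
has identity 0.

## Conservation statistics

For a k-domain group, the identity matrix cell (i, j) with i ≠ j averages
identity between domain-i and domain-j instances over both orientations of
every cross-record pair **plus each record's own internal i–j pair**; the
within-record pairs are included by default because identity "between
domains" of one architecture is part of the question being asked
(configurable to cross-record-only). Diagonal cells average over
cross-record pairs of the same position. Averages are unweighted over
pairs. Groups larger than a record cap (default 500) would cost O(n²)
alignments per cell, so cell averages then use a seeded random subsample
of cross-record pairs; the seed is recorded in the output. Argmax ties
always break toward the lower domain index. Groups with fewer than two
records raise an explicit insufficient-data error; a matrix whose entries
are all equal is flagged degenerate in the summary rather than reporting a
meaningless argmax.

The reference scan aligns each domain of each record against a one-domain
reference (domain versus reference-domain, not versus the full protein)
and records the argmax position per record; the mode of those positions,
its frequency, and the mean identity among the voting records summarise
the group. The multiple-alignment variant of within-position identity is
not reproduced here: within-position conservation is measured as mean
pairwise global-alignment identity, which preserves the ranking of
positions; an externally computed MSA can be ingested through the
aligned-FASTA reading path if column-wise identity is wanted.

## Synthetic families

The generator draws a uniform i.i.d. ancestral domain (default 70
residues), evolves each domain copy independently by substituting each
site with probability d(index) — replacement uniform over the 19 other
residues — and concatenates copies with random linkers (default 10
residues, never inside a boundary). Substitution-only evolution keeps
expected identities in closed form,
`100[(1-d_i)(1-d_j) + d_i d_j / 19]`; there is deliberately no indel
process, no site-rate heterogeneity and no tree structure, so passing
tests demonstrate correct bookkeeping and estimator behaviour under a
clean model, not robustness to real evolutionary noise. Defaults are the
study conditions: divergence vector (0.40, 0.35, 0.15, 0.20, 0.30, 0.40)
planting index 3 as most conserved with a 0.05 contrast to its neighbour,
and a phylum × domain-count profile matching the empirical census shares
(0.8 / 0.6 / 1.9 / 33 / 1.1 / 62 percent for one- to six-domain classes,
the four-domain share split roughly evenly between Actinobacteria and
Firmicutes, weights normalised). Contaminants violating exactly one filter
rule each can be planted by rate or by exact count. Everything derives
from one `numpy` generator seeded by the config, so outputs are
byte-identical across runs.

## Problem sizes and tolerances

The test suite checks the closed-form identity calibration at 200
replicate pairs per divergence cell (tolerance ±3 points, about three
standard errors of the mean at these sizes), planted-index recovery over
100 seeded runs of 50 six-domain records (each locator required in ≥95% of
runs), the filter funnel on 50 records with one planted violation per
rule, and census recovery at n=2000 against binomial 99% confidence
intervals. `scripts/acceptance.py` re-measures the same quantities with 50
recovery runs. Note that at n=2000 the three rarest classes (expected
counts ≈22/16/12) are close enough that their strict ordering flips in an
appreciable fraction of runs; the confidence-interval check, not the tail
ordering, is the statistically meaningful statement at this sample size.

## Known limitations

- Real UniProt-scale inputs (the ~1.4k-record family) are not bundled;
  the pipeline reads them from FASTA + TSV but the packaged evidence is
  synthetic.
- The substitution model is uniform over residues; BLOSUM-like exchange
  preferences would raise off-diagonal identity slightly.
- Percent identity between two diverged copies is not a metric; matrix
  cells are means over pairs and carry no variance estimate beyond the
  recorded pair counts.
- Cross-database domain-count reconciliation (SMART/Pfam/PROSITE/SUPFAM)
  is out of scope; one boundary set per record is taken as given.
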