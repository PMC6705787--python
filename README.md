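# s1census

Tools for a domain-architecture census of bacterial ribosomal protein S1
and for locating its most conserved repeat.

Ribosomal protein S1, encoded by *rpsA*, is a chain of one to six copies of
the ~70-residue S1 domain (an OB-fold RNA-binding repeat). The number of
copies tracks phylogeny — six-domain proteins dominate Proteobacteria,
four-domain proteins Firmicutes and Actinobacteria — and the central
repeats are more conserved than the terminal ones. `s1census` packages
that analysis as a tested pipeline:

1. **records_io** — FASTA sequences + a UniProt-style annotation TSV
   (accession, names, lineage, phylum, 1-based inclusive S1-domain
   boundaries, extra-domain flag) merged into validated records;
2. **filtering** — the five-rule selection funnel (protein-name keyword,
   *rpsA* gene, candidate-taxon removal, at least one S1 domain, no non-S1
   domains) with a per-rule attrition report;
3. **census** — phylum × domain-count occupancy with length statistics;
4. **alignment** — global pairwise alignment implemented from first
   principles, with percent identity;
5. **conservation** — inter-domain identity matrices per domain-count
   group and a reference scan against one-domain S1 proteins (e.g. the S1
   domain of polynucleotide phosphorylase, PNPase);
6. **synthetic_data** — a seeded generator of S1-like families with known
   ground truth, so every stage is testable without downloads.

## The core computation

Pairwise alignment is Needleman–Wunsch with affine gaps, the three-state
recurrence over sequences $a_{1..n}$, $b_{1..m}$:

$$M_{ij} = \max(M_{i-1,j-1}, I^x_{i-1,j-1}, I^y_{i-1,j-1}) + s(a_i, b_j)$$
$$I^x_{ij} = \max(M_{i-1,j} + g_o,\; I^x_{i-1,j} + g_e,\; I^y_{i-1,j} + g_o)$$
$$I^y_{ij} = \max(M_{i,j-1} + g_o,\; I^x_{i,j-1} + g_o,\; I^y_{i,j-1} + g_e)$$

with deterministic traceback (diagonal, then gap-in-b, then gap-in-a on
ties). The default scheme is match = 1, mismatch = 0, and a unit linear
gap penalty ($g_o = g_e = -1$); BLOSUM62 with affine gaps (−10/−0.5) and a
zero-gap (LCS) scheme are selectable. Percent identity is

$$\mathrm{id}(a,b) = 100 \cdot \frac{\#\{\text{columns with the same non-gap, non-X residue}\}}{\text{alignment length}}$$

with the denominator convention stated in every output header. For a
$k$-domain group, cell $(i,j)$ of the identity matrix is the unweighted
mean of $\mathrm{id}$ over all cross-record (and, for $i \ne j$,
within-record) pairs of domain-$i$ and domain-$j$ instances; the reference
scan reports, per record, $\arg\max_i \mathrm{id}(\text{domain}_i,
\text{ref})$ and its mode across the group.

The simulator evolves each domain from a shared ancestor by substituting
each site with probability $d$ (uniform over the 19 other residues), so two
copies at divergences $d_i, d_j$ have expected identity
$100\,[(1-d_i)(1-d_j) + d_i d_j/19]$ — a closed form the test suite checks
by Monte Carlo.

## Worked example

```bash
s1census simulate --seed 7 --n-records 200 --out-dir sim
s1census filter   --fasta sim/family.fasta --meta sim/family.tsv --out-dir filt
s1census census   --fasta filt/filtered.fasta --meta filt/filtered.tsv --out-dir cen
s1census conserve --fasta filt/filtered.fasta --meta filt/filtered.tsv -k 6 --out-dir cons
```

prints (stderr log):

```
INFO s1census: wrote 200 records to sim
INFO s1census: filter funnel: 200 -> 200 records
INFO s1census: 1-domain: 0.5% of records, length 70 (70-70)
INFO s1census: 2-domain: 1.5% of records, length 150 (150-150)
INFO s1census: 3-domain: 3.0% of records, length 230 (230-230)
INFO s1census: 4-domain: 32.0% of records, length 310 (310-310)
INFO s1census: 5-domain: 3.0% of records, length 390 (390-390)
INFO s1census: 6-domain: 60.0% of records, length 470 (470-470)
INFO s1census: k=6: diagonal argmax 3, off-diagonal argmax (3, 4)
```

The census recovers the generator's domain-count profile (six- and
four-domain classes dominate, as in the real family), and the identity
matrix for the six-domain group locates the planted conserved repeat: the
within-position identity peaks at domain 3 (73.5% vs 64.5% for domain 4 and
36–50% elsewhere), the maximal off-diagonal cell is domains 3–4 (68.8%),
and `conserved_summary_k6.json` reports all locators agreeing on the
central domain. A no-contamination run loses nothing in the funnel; planted
contaminants (wrong name, wrong gene, candidate taxon, zero domains, extra
domains) are each dropped at exactly their rule.

Aligning two peptides directly:

```bash
$ s1census align HEAGAWGHEE PAWHEAE
HEAGAWGHEE
---PAWHEAE
score=0 identity=30.00% (denominator=alignment)
```

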