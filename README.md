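# ugtevol

Molecular-evolution analysis of duplicated coding-gene families: how old
are the duplicates, and what selection pressure have they been under?

The package is built for gene families like the plant family-1
UDP-glycosyltransferases (UGTs) — large, heavily duplicated, and marked
by a conserved 44-residue PSPG signature box — and provides, as one
importable toolkit:

* **duplicate calling** — all-vs-all global protein alignment with a
  permutation-calibrated score threshold, reciprocal-best-hit (RBH)
  pair calling, intra-/inter-chromosomal classification and a census;
* **Ka/Ks** — Nei–Gojobori (1986) counting with equal-weight mutational
  pathway averaging, stop-codon exclusion and Jukes–Cantor correction:
  pS = Sd/S, pN = Nd/N, d = −(3/4)·ln(1 − 4p/3), ω = Ka/Ks
  (< 1 purifying, ≈ 1 neutral, > 1 positive), plus the standard
  filtration for dating (drop Ks < 0.001 and Ks > 2);
* **molecular-clock dating** — t = Ks/(2r)/10⁶ MY at
  r = 6.5×10⁻⁹ substitutions per synonymous site per year;
* **PSPG-motif windowing** — position-specific log-odds profile scan
  returning the 44-residue window with flanking context;
* **phylogenetics** — neighbor joining on p-distances, column-resampling
  bootstrap supports, Fitch small-parsimony scoring, newick/PHYLIP I/O;
* **in-silico splicing** — exon fusion of single-intron genes and
  overlap-extension PCR primer design (30-nt junction chimeras);
* **qPCR expression** — Livak 2^−ΔΔCt fold changes;
* **a calibrated codon-evolution simulator** — gene families with known
  duplication times, known ω and a conserved embedded motif, so every
  stage above is testable against ground truth without any external
  data.

## Worked example

Simulate a family whose history is known, then recover it:

```bash
python analysis/01_simulate_family.py
python analysis/02_duplication_rbh.py
python analysis/03_kaks_dating.py
```

The first script duplicates one 500-codon ancestor 40, 15 and 5 million
years ago under purifying selection (ω = 0.3) and prints the truth:

```
simulated 4 genes (500 codons each)
  g1-g2: true divergence 40 MYA (expected Ks 0.520)
  ...
  g3-g4: true divergence 5 MYA (expected Ks 0.065)
```

The third script aligns every pair, runs NG86 and the clock, and
compares against that truth:

```
6 pairs, 6 retained after Ks filtration
  g1-g2: Ks 0.572  Ka/Ks 0.238 (purifying)  estimated 44.0 MYA, true 40 MYA
  g2-g3: Ks 0.209  Ka/Ks 0.225 (purifying)  estimated 16.1 MYA, true 15 MYA
  g3-g4: Ks 0.044  Ka/Ks 0.467 (purifying)  estimated 3.4 MYA, true 5 MYA
  ...
median |relative dating error|: 11.0%
Ks mean 0.364, mode bin midpoint 0.575, 100% of pairs with Ka/Ks < 1 (purifying)
```

Every pair is correctly classified as purifying (true ω = 0.3 < 1), the
youngest duplicates are mutual best hits on different chromosomes
(`02_duplication_rbh.py` reports `('g3', 'g4', 'inter_chromosomal')`
and rejects unrelated decoy genes), and estimated ages track the true
5/15/40 MY history. `analysis/04_motif_phylogeny.py` then recovers the
planted PSPG box at residues 331–374 in all copies and builds the NJ
tree `(g3,g4,(g1,g2)99);` with 99% bootstrap support for the young
sister pair; `analysis/05_splice_qpcr.py` fuses the 678+738 and 643+728
bp exon geometries into 1416- and 1371-bp CDSs (471 and 456 residues)
and demonstrates 2^−ΔΔCt expression profiles.

The same stages are available as a CLI (`ugtevol simulate | mine | dup |
kaks | motif | tree | splice | qpcr | report`) and as one orchestrated,
seeded, byte-reproducible pipeline (`ugtevol report --config run.yaml`).

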