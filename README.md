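# ipcon — intron position conservation for orthology

`ipcon` asks a comparative-genomics question: **do orthologs keep their intron
positions better than merely similar sequences?** If they do, intron position
conservation (IPC) is a usable extra signal when assigning orthology between
two genomes. The package implements the full analysis for researchers in
molecular evolution and orthology benchmarking:

1. **Gene structures → marked proteins.** CDS `join(...)` locations from
   EMBL/GenBank flat files give each intron's coding-nucleotide offset `k`;
   the residue `k // 3` (phase `k % 3`) is written lower-case in a "marked
   FASTA". Redundant gene copies are removed and the longest spliceform kept.
2. **Ortholog clusters.** Bidirectional best hits seed InParanoid-style
   two-species clusters (coverage cutoffs 0.5 / 0.25); sequences scoring at
   least the seed similarity *S* against their own seed join as inparalogs
   with confidence `(sim − S) / (self − S)`. Each **extended cluster** adds,
   per member, the closest non-ortholog (cno, other species) and closest
   non-inparalog (cni, same species) — homologs just outside the cluster that
   act as the similarity-matched control group.
3. **IPC scoring.** Marked residues are projected through a multiple
   alignment; positions count as conserved within the same codon (≤ 2 nt
   slide). For a pair with `n_A`, `n_B` introns of which `shared` coincide:

   `IPC = 2 · shared / (n_A + n_B)`  (Jaccard variant available)

   IPC is undefined for two intronless proteins; scored pairs are
   ortholog–ortholog (o-o), ortholog–cno (o-cno), inparalog–inparalog (i-i)
   and inparalog–cni (i-cni), maximized over spliceforms and with the two
   possible cno (cni) pairs averaged.
4. **Statistics.** Mann-Whitney-Wilcoxon tests between pair types; sequence
   identity binning with combined equal-count boundaries and per-bin
   `log2(mean IPC ratio)` to control for the orthologs' higher identity;
   Spearman correlation of IPC vs identity; agreement between the IPC ranking
   and the seed assignment, split by seed bootstrap support (≥ 90%).
5. **Enrichment.** Genes found only in *inconsistent* clusters (seed pair not
   top-ranked by IPC) are tested for GO/Pfam term enrichment or depletion
   against the consistent background (hypergeometric, BH FDR 1%, oversized
   clusters > 200 genes removed), with an association network that groups
   redundant terms under greedily chosen representatives, Pfam clan rollup
   and repeat collapsing, plus protein-property comparisons (length, introns,
   pseudo-domains).
6. **Simulator.** Two-species gene families with known orthology, intron
   gain/loss histories, rate heterogeneity, outparalogs, planted annotation
   terms and trivially true alignments — every pipeline input format can be
   generated from a seed, so the whole analysis is testable offline.

## Worked example

`examples/04_compare_pair_types.py` simulates 200 families (8 ancestral
introns, loss 0.3/unit time, speciation depth 1, outparalogs at depth 2),
clusters them from the similarity table and runs the comparison:

```
mean IPC per pair type:
  o-o    0.686  (n=366)
  o-cno  0.436  (n=348)
  i-i    0.780  (n=113)
  i-cni  0.454  (n=101)
MWW p (o-o vs o-cno): 1.66e-51
MWW p (i-i vs i-cni): 6.48e-24

identity-binned log2(mean IPC o-o / mean IPC o-cno):
  bin 0: +0.83  (n_oo=2, n_ocno=359)
  ...
  bin 9: +1.25  (n_oo=253, n_ocno=14)
```

Orthologs conserve intron positions roughly 1.6× better than their closest
non-orthologs, inparalogs (youngest pairs) best of all, and the advantage
persists in every sequence-identity bin — so it is not explained by the
orthologs' higher identity. The other examples cover extraction (`01`),
clustering (`02`), per-pair scoring (`03`), enrichment with the planted term
(`05`) and full dataset emission + file-based pipeline (`06`).

A thin CLI wraps the same library calls:

```bash
ipcon simulate --families 50 --seed 1 --out data/
ipcon run-all --config pipeline.yaml
```

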