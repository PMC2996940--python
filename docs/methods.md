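# Methods

## The IPC score

An intron position is described by the codon it precedes or interrupts: from
the exon segments of a CDS, an intron at coding-nucleotide offset `k` marks
protein residue `k // 3` with phase `k % 3` (phase 0 = between codons). Two
introns in different sequences count as the *same* position when their marked
residues occupy the same column of the protein alignment. Because the mark is
codon-level, this is exactly the "same codon" criterion: an intron may slide
up to 2 nt and still count, while a shift of a full codon never does. Two
marks inside one codon (different phases) collapse to a single marked
residue.

For a sequence pair with `n_A` and `n_B` marked residues after alignment
projection, of which `shared` coincide:

```
IPC = 2 * shared / (n_A + n_B)          (default)
IPC = shared / (n_A + n_B - shared)     (formula="jaccard")
```

Both are symmetric, lie in [0, 1] and equal 1 exactly when the mark sets
coincide. The pair score is *undefined* (and excluded from every mean) when
both sequences are intronless; a one-sided intronless pair scores 0. The
default denominator is a declared design choice, not an empirical claim; the
Jaccard form is a configuration switch (`ipc_formula`).

Sequence identity of a pair is matches over co-aligned (both non-gap)
columns, 0 when the sequences share no columns.

## Cluster model

Clusters are two-species, InParanoid-style: seed pairs are bidirectional best
hits among coverage-passing hits (query coverage ≥ 0.5 and longest-segment
coverage ≥ 0.25, both inclusive; best-hit ties broken by lexicographic
subject id), and gene *x* joins as an inparalog when its score to its own
seed is at least the seed-pair score S. The inparalog confidence
`(sim − S)/(self − S)` (clamped to [0, 1]) fixes seeds at 1.0 and threshold
members at 0.0. Where the two directed scores of a seed pair differ, S is
their mean. Instead of the published conflict-resolution machinery, seeds
are processed greedily in descending S with genes removed from the candidate
pool once assigned; this yields disjoint clusters with the same seed and
membership semantics, which is all the downstream analysis needs. Seed
bootstrap values are consumed from the input cluster table, never computed.

Extended clusters attach to each member its closest non-ortholog (best
coverage-passing non-member hit in the other species) and closest
non-inparalog (same, own species). "Non-member" means not in the focal
cluster; a cno may be a member, even a seed, of another cluster.
Mitochondrial clusters are excluded outright (intronless), and the members'
shorter spliceforms are re-attached before scoring.

## Pair types and aggregation

o-o pairs are all cross-species member pairs (not only the seed pair); i-i
pairs all within-species member pairs. When genes have several spliceforms
the combination with the highest IPC is used (ties: higher identity, then
lexicographic ids); maximization applies uniformly to all four pair types to
avoid biasing the comparison. Each o-o (i-i) pair contributes one o-cno
(i-cni) value: the mean over the defined scores of its two members' cno
(cni) pairs. Cluster summaries hold per-type means over defined values; a
multi-cluster is *consistent* when its seed pair attains the maximum o-o IPC
(ties count as agreement; an undefined seed-pair score competes as 0.0, a
degenerate case that only arises for intronless seeds).

## Statistics

* **MWW.** Two-sided Mann-Whitney-Wilcoxon via scipy: exact null for
  combined n ≤ 20 (full permutation enumeration when ties are present),
  asymptotic with tie correction above. By default the test compares
  per-cluster per-type mean IPC values (`mww_mode="cluster_means"`); a
  per-pair mode exists. Note a subtlety of the two-cno averaging: under an
  exchangeable null the averaged o-cno values have half the variance of
  single o-o draws, so the cluster-mean statistic can reject on shape alone.
  The simulation property checks (headline direction, parallel-gain control)
  therefore use the per-pair mode, which is exactly distribution-matched
  under exchangeability.
* **Binning.** Per pair type, equal-count boundaries are midpoints between
  the adjacent order statistics at each k-quantile split (k = 10 by
  default); the combined boundary is the position-wise mean of the two
  types' boundaries, and both types are re-binned by it (right-closed
  intervals; a value on a boundary goes to the lower bin). Per-bin
  `log2(mean IPC ratio)` is flagged undefined — never ±inf — when a bin is
  empty for either type or a mean is 0.
* **Spearman.** IPC vs identity per pair type, average-rank ties,
  t-approximation p; constant input is flagged, not NaN.
* **Agreement by bootstrap.** Among multi-clusters with known seed
  bootstraps, the fraction of consistent clusters is reported separately for
  min(seed bootstraps) ≥ 90 and < 90; unknown-bootstrap clusters are counted
  and excluded.
* **Consistency sets.** Focal-species genes appearing only in consistent /
  only in inconsistent multi-clusters form the background and foreground of
  the enrichment analysis; genes seen on both sides are set aside. Clusters
  with more than 200 genes (strict >) are removed first as likely
  orthology-assignment artifacts.

## Enrichment

Per term: hypergeometric upper tail P(X ≥ k) (enrichment) and lower tail
P(X ≤ k) (depletion); the two-sided p is the doubled smaller tail, capped at
1, and feeds Benjamini-Hochberg step-up control at FDR 1% over the single
joint family (separate families per direction were considered and rejected
as the default because the procedure tests "enriched or depleted" jointly).
No GO ancestor propagation is performed — term interdependence is handled
empirically: term B is *associated* with A when B is significant on the full
data but not after removing all A-annotated genes from universe and
foreground (the full test + FDR is re-run per exclusion). Representatives
are picked greedily: most-linked node first (ties: smallest id), absorbing
its current neighbors. Pfam analyses replace domains by clans where mapped,
and consecutive runs of the same Repeat/Motif-type domain collapse into one
pseudo-domain before counting and in the protein-property comparison
(length, intron count, pseudo-domain count; two-sided MWW plus percent mean
difference).

## The simulator

Each family descends from one ancestral gene of 200 residues with 8
ancestral introns (residues drawn uniformly, phases uniform on {0,1,2}).
The main lineage speciates at depth 1.0 (arbitrary time units); with
probability 0.9 a pre-speciation duplication at depth 2.0 creates an
outparalog lineage that also speciates, providing the cno/cni material; with
probabilities 0.5 / 0.25 a post-speciation duplication at 0.4 creates
inparalogs in species A / B. Per branch of length t, each intron survives
with probability `exp(-loss_rate * t)` (loss 0.3/unit) and gains arrive as a
Poisson count with mean `gain_rate * t * |protosplice sites|` (gain
0.01/site/unit over a per-family 10% protosplice subset, phase 0, never on
an already-marked codon). Sequences evolve indel-free by per-residue
substitution (0.12/unit), so the true family alignment is trivial; shorter
spliceforms (20% of genes, 80% prefix truncations) are padded with trailing
gaps.

Realism knobs and what they are for:

* **Duplicate acceleration** (`duplicate_rate_multiplier` = 1.8): the branch
  below a duplication evolves faster, reflecting relaxed constraint on young
  copies. This is what makes the retained copy genuinely the best
  cross-species match, so BBH seeds and the consistency analysis have a
  meaningful ground truth.
* **Confusable families** (25%): duplication just before the speciation
  (0.95·depth) at the neutral rate, making the seed ranking ambiguous on
  purpose; their emitted seed bootstraps are drawn from the low regime
  (50–89) versus 92–100 otherwise, which is what gives the
  agreement-by-bootstrap table its structure.
* **Rate heterogeneity**: independent per-family lognormal factors on the
  sequence rate (σ = 0.4) and intron-turnover rate (σ = 0.3) spread pair
  identities across the [0.3, 1) range so the identity-controlled binning is
  exercised with overlapping distributions. Because the two factors are
  independent, the within-type IPC-identity correlation is near zero; real
  data show weak positive correlations, so this emulates the "weak at most"
  regime rather than any particular value.
* **Similarity scores**: `scale · exp(-decay · d) · (1 + ε)` with d the
  substitution-weighted path distance and ε uniform in ±2%, symmetric per
  pair; only rank order matters to clustering. An infinitesimal (1e-6)
  deterministic penalty on main-vs-outparalog pairs keeps a copy *exactly*
  equidistant with the seed (root polytomy, below) outside the cluster
  under the inclusive ≥ threshold.
* **Planted annotations**: families whose seed pair does *not* attain the
  top cross-pair IPC — decidable at generation time from the true intron
  histories — carry the planted GO term at 30% versus 6% background (5×),
  so the enrichment stage has a recoverable signal; 5% of families are
  mitochondrial (intronless) to exercise the exclusion rule.

Calibration scenarios (fixed presets, not tuned per run):

* **Pure loss** (`pure_loss_params`): 500 one-to-one families, 20 ancestral
  introns, loss 0.2, no gains/outparalogs/noise/rate-spread. Writing
  s = exp(−loss·t) per branch, E[shared] = n·s² and E[n_A] = n·s, so mean
  o-o IPC ≈ s with a ratio-estimator bias ≈ s(1−s)/(2ns); n = 20 and
  s ≈ 0.82 keep that bias (~0.004) well inside three Monte-Carlo standard
  errors of the 500-family mean, which is the recovery check.
* **Parallel-gain control** (`parallel_gain_control_params`): zero ancestral
  introns, gains only (0.12/site over an 8% protosplice set), and the
  outparalog lineage split exactly at the speciation — a root polytomy, so
  all four tips are exchangeable and any intron sharing is parallel gain.
  Under this null, which copy is called "ortholog" is an arbitrary but fixed
  labeling, and o-o vs o-cno IPC must show no systematic difference.

What the simulator does **not** emulate: indels and alignment error (an
optional external-aligner hook exists, and a gap-padding fallback valid only
for indel-free data), codon-level sequence evolution, intron sliding,
correlated sequence/intron rates, cross-family homology, and BLAST score
statistics (similarity is rank-faithful, not bit-score-calibrated). Passing
tests therefore demonstrate correctness of the pipeline's logic and its
statistical behavior under the stated model, not robustness to annotation or
alignment error in real genomes.

## Problem sizes and determinism

The test suite runs the comparative analysis at 200 families per seed panel
(10 seeds), the pure-loss calibration at 500 families, and the enrichment
recovery at 100 seeded universes of 1,000 genes — sizes chosen so each
property check has clear statistical resolution while the whole suite stays
interactive (~20 s). All randomness flows from explicit
`numpy.random.default_rng` seeds; file emission sorts every collection and
formats floats with `%.6g`, so identical seeds give byte-identical datasets
and reports (pinned by a golden-report test). Undefined quantities are
reported as `None`/flags, never NaN or ±inf.

## Known limitations

* One species pair per run; multi-comparison consistency sets are supported
  at the API level (`gene_consistency_sets`) but the bundled pipeline runs
  one comparison at a time.
* The inparalog rule uses the directed score with the seed as subject; real
  BLAST tables with asymmetric reciprocal scores may classify borderline
  inparalogs differently than the original tool.
* Phase information survives flat-file extraction but not the marked-FASTA
  round trip (the format encodes the marked codon only); IPC is unaffected,
  as the criterion is codon-level.
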