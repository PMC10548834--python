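# Methods

## The decision problem

A patient with several lung lesions may harbor independent primaries (MPLC),
metastatic spread of one clone (IPM), benign nodules, or a single lineage
that switched histology. The observable that separates these is clonal
inheritance: lesions descending from one ancestor share the ancestor's
("trunk") somatic mutations, while independently initiated tumors share
essentially nothing — except recurrent driver hotspots, which arise
convergently. `clonetrace` treats whole-exome evidence as primary and uses
neoantigen sharing and expression structure as corroboration, mirroring how
the genomic, immunopeptidomic and transcriptomic read-outs relate causally:
neoantigens are a function of the mutations, and expression reflects cell
state, which co-varies with lineage but also with histology.

## Somatic retention filter (`variant_io`)

A call is retained iff

* `alt_reads >= 4` and `vaf >= 0.02` — both boundaries inclusive,
* `pop_freq <= 0.01` — exclusion is strictly above 1%, so a call annotated
  at exactly 1% population frequency survives,
* it is not on the (user-supplied) blacklist of recurrent sequencing
  errors.

Keys are normalized before any comparison: shared trailing bases trimmed
first, then shared leading bases (position advancing), each side keeping at
least one base; chromosome names lose a leading `chr`, are uppercased, and
`M` is unified to `MT`. Duplicate keys collapse to the call with maximal
read support. VCF input is read via cyvcf2 (per-sample `AD` preferred,
`AF`+`DP` fallback; population frequency as the max over `POP_AF`,
`MAX_AF`, `AF_1000G`, `AF_EXAC`; synonymous status from a `SYN` flag);
a MAF-like TSV is the round-trippable native format.

## Similarity and phylogeny (`clonality`)

The pairwise gene similarity score is the Jaccard index × 100 over
normalized keys, recorded as `jaccard_pct` in all outputs. The field also
uses likelihood-based clonality statistics; the score here was chosen
because it is parameter-free, auditable from the two reported counts
(`n_shared`, `n_union`), and reproduces the orderings that matter for the
decision rules (high tens of percent for metastatic pairs, ~0–1% for
independent pairs that happen to share a driver). A probability-based
statistic can be substituted at the `PairSimilarity` interface without
touching the caller. By default the score uses **all** retained somatic
calls; trees use non-synonymous calls only. Both toggles are exposed
because either convention is defensible; sensitivity to the choice is
small whenever mutation counts are in the hundreds.

Trees: binary presence matrix → pairwise raw Hamming counts → neighbor
joining (scikit-bio), negative branch lengths clamped to zero, rooted on
the all-zero `normal` column. Raw (unnormalized) Hamming distance makes
branch lengths read directly as mutation counts, so the trunk/branch
structure is visible in the tree. NJ was preferred over parsimony for
determinism and speed; Q-matrix ties are resolved by scikit-bio's stable
ordering of the lexicographically sorted input ids.

## Neoantigens (`neoantigen`)

Windows: all 9-, 10- and 11-mers of the mutant context that contain the
mutated residue (windows without it are wild-type peptides). A full 21-mer
context with the mutation at position 11 yields exactly 9+10+11 = 30
windows. Strong binding is IC50 strictly below 500 nM against any of the
patient's HLA class-I alleles; a tie at exactly 500 is excluded. All strong
windows of one mutation collapse to a single neoantigen, so neoantigen
counts are bounded by non-synonymous mutation counts. "Shared neoantigen"
is defined at the mutation level (same normalized key with ≥ 1 strong
binder in each sample): HLA is constant within a patient, so mutation-level
sharing is well defined; a stricter peptide-string level is available as a
toggle.

The bundled `mock_affinity` predictor is deterministic and pure: peptides
containing `W[ILV]F` score 50 nM, all others 5000 nM. It exists so the
synthetic generator can plant binders whose recovery is exactly checkable;
any real predictor can be plugged in as a callable or ingested from its
tabular output (`TabularPredictor`).

## Expression (`expression`)

Preprocessing is log2(FPKM+1), zero-variance gene removal, per-gene
centering (unit scaling optional). PCA signs are fixed (largest-magnitude
loading positive) for determinism; clustering is complete-linkage on
Euclidean distances over the top-k PC scores, with samples pre-sorted
lexicographically so results are input-order invariant.

The cell-type score is a single-sample weighted-rank enrichment: with genes
sorted by descending expression (ties broken by gene id), the in-set
cumulative distribution weights rank r by `(N - r + 1)^alpha`
(`alpha = 0.25`), the out-of-set distribution is uniform, and the score is
the deviation of maximal magnitude between the two — bounded in [−1, 1] and
dependent only on within-sample ranks, hence invariant under any global
rescaling of FPKM. The full xCell pipeline (64 curated platform-calibrated
signatures, spillover compensation) is deliberately not reproduced; the
testable content here is the scoring and the compartment aggregation.
Signatures come from a GMT file whose description column carries the
compartment (`immune`/`stroma`); a small synthetic set is bundled.
Cell-type scores are floored at 0 before compartment sums, so immune,
stroma and microenvironment scores are non-negative and
`microenvironment = immune + stroma` holds exactly (tested to 1e−9).

## Lineage rules (`lineage`)

Defaults: `t_ipm = 5.0%`, `t_low = 1.0%`, `min_shared_nonhotspot = 3`.
These thresholds are this package's defaults, chosen to order the regimes
the method must separate — metastatic pairs in the tens of percent,
same-lineage progression pairs around ten percent with many shared
non-hotspot mutations, and driver-only coincidences below one percent —
and all are config-exposed. The cascade order (R1 similarity → R2
nothing-shared → R3 driver-coincidence → R4 indeterminate) encodes the
primacy of exome evidence; neoantigen or expression agreement is appended
to the trace as corroboration and can never alone produce an IPM call.
Missing evidence needed by the first applicable rule produces an
`indeterminate` call whose trace names the gap, rather than a guess.
The transformation annotation (EGFR+TP53+RB1 mutated, neuroendocrine
histology, EGFR-TKI flag in the manifest) is deliberately an annotation,
not a label: it marks a hypothesis that needs clinical context.

## Synthetic patients (`synthetic`)

The generator emulates the structure the method exploits, with exact
bookkeeping for recovery tests:

* **Mutations** are unique SNV keys drawn from a synthetic grid
  (chromosomes 1–22, positions 10⁴–10⁸); no reference genome is required.
  Clonal groups share `n_trunk = 150` trunk keys; nested sub-clades (groups
  of 3+) share `n_internal = 30` keys per internal edge of a random binary
  genealogy; every tumor adds `n_private = 50` private keys. The defaults
  give a two-tumor clonal pair a Jaccard similarity of 150/250 = 60%, the
  regime of a clear metastatic pair; recovery tests sweep trunk fractions
  0.2–0.6.
* **Hotspot drivers** (five real lung-cancer hotspots, per-tumor occurrence
  probabilities 0.05–0.10) are drawn independently per tumor, reproducing
  the confound of unrelated tumors sharing a driver.
* **Contaminants**: a patient-level germline set (population frequency
  drawn in (0.011, 0.5); ~10% of raw calls) appears in every sample, and
  ~5% low-support artifacts (alt reads < 4 or VAF < 2%) are planted per
  sample; the retention filter must remove all of them. A benign sample
  contains only contaminants.
* **Contexts**: 21-mers with the mutated residue at position 11; 5% are
  terminus-truncated (1–8 residue flank on one side). Background residues
  are drawn from the 19 non-tryptophan amino acids; a `binder_fraction` of
  30% of non-synonymous mutations gets `W[ILV]F` planted over the mutated
  position. Because tryptophan occurs only in planted motifs, the mock
  predictor's strong binders are exactly the planted ones, and the
  shared-neoantigen count between two tumors equals the planted binder
  count on their shared keys — checked for exact equality.
* **Expression**: per-lineage per-gene centroids `N(3, 1.5)` in log2-FPKM,
  samples scattered with `N(0, 0.3)` noise, 500 genes. At these defaults
  same-lineage samples are far closer than cross-lineage ones, which is
  what the PCA mutual-nearest-neighbor check quantifies.
* 75% of mutations are non-synonymous (exome-typical); read depths are
  drawn in [80, 300) with true VAF in [0.10, 0.60), re-drawn if a somatic
  call would fall below the retention thresholds so that truth sets are
  exact.

What the generator does **not** emulate: mutational signatures, copy-number
events, subclonal cellularity structure, read-level noise, realistic
binding-affinity landscapes, or expression covariance between genes.
Passing recovery tests therefore demonstrates the correctness of the
set-algebraic, combinatorial and decision logic under the stated generative
model — not calling performance on real sequencing data, where upstream
callers and predictor quality dominate.

## Problem sizes and numerical choices

Validation runs use 200 two-tumor patients (pair labels, AUC), 100
four-tumor patients (topology recovery), 100 patients (neoantigen
recovery), and 100 seeds (expression mutual-NN) with ~100–260 mutations per
patient — sizes at which every recovery statistic is stable across seeds
while the full suite runs in well under a minute; the package's own choice
of desk-scale conditions. Determinism throughout: one `numpy`
`default_rng(seed)` per simulation, seed-derived sub-streams in the
acceptance script, deterministic tie-breaks in ranking, clustering and PCA
sign conventions, and JSON reports with sorted keys and no timestamps so
repeated runs are byte-identical.
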