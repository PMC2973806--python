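# Methods

`catnets` ranks the residues of an enzyme family by how likely they are to
be catalytic, combining sequence conservation with the spatial clustering
of coevolving positions around active sites. This note documents the model,
the numerical choices, the synthetic benchmark the package is validated on,
and the limits of what that validation shows.

## Inputs and preprocessing

A family is a multiple sequence alignment (FASTA or Stockholm) with a
designated reference sequence, a single-chain PDB structure matching that
reference, and optionally a set of annotated catalytic residues (chain +
author residue number). Preprocessing is applied once, in this order:

1. columns where the reference has a gap are removed;
2. of the remaining columns, those with more than 50% gaps are removed;
3. sequences whose residues cover less than 50% of the trimmed reference
   length are removed (the reference itself never is).

The trimmed reference is then matched to the structure's one-letter
sequence — exact substring match in either direction first, a global
pairwise alignment as fallback — giving each column a structure residue or
an "unmapped" mark. Unmapped columns still participate in the MI matrix but
receive no proximity or final scores (no coordinates, no neighborhood).
Mapping fails loudly if fewer than half of the reference columns match the
structure sequence.

Redundancy weights follow the classic identity-clustering scheme:
single-linkage clusters at ≥62% pairwise identity (identity counted over
columns where both sequences carry residues), each sequence weighted
1/(cluster size). `X` and other non-standard symbols are treated as gaps
for all counting, never as a 21st state.

## Conservation

Three per-column measures, all in bits and oriented so higher = more
conserved:

* **Max-Freq** — frequency of the most common amino acid;
* **Shannon** — reported as `log2(20) − H` so the orientation matches;
* **KL** — `Σ_a p_a log2(p_a / q_a)` against an amino-acid background `q`.

The bundled background is the UniProtKB/Swiss-Prot amino-acid composition
(renormalized over the 20 standard residues); any 20-line TSV can be
substituted. Each measure runs under four conditions: `raw`, `c`
(clustering weights), `l` (pseudocounts), `cl` (both). The pipeline's
default conservation score is **raw KL**, the best-performing condition;
the other eleven remain available for comparison.

The pseudocount ("low count") correction blends the observed frequencies
with the background, `p' = (n_eff·p + β·q)/(n_eff + β)`, where `n_eff` is
the column's weighted residue count and `β` is the number of sequence
clusters (√n_sequences when unweighted). This is a deliberately simple
background blend rather than a substitution-matrix mixture; since the
default pipeline uses the uncorrected score, the choice only affects the
explicitly requested `l`/`cl` conditions.

## Mutual information

For every column pair, joint amino-acid frequencies are accumulated over
the sequences ungapped at *both* columns (weights renormalized over that
subset), optionally blended with the product-of-background pseudocount
(same `β`), and converted to `MI_ij = Σ_ab p_ab log2(p_ab/(p_a p_b))` with
marginals taken from the joint. The implementation is a one-hot matrix
product over all pairs at once, which is what makes permutation testing
affordable.

Two corrections turn raw MI into a usable coevolution signal:

* **APC** (average product correction):
  `MI_ij − (MI_i· × MI_·j)/MI_··`, with the row means and grand mean taken
  over off-diagonal entries. This removes the rank-one background component
  created by phylogeny and by per-column entropy differences.
* **Permutation Z-scores**: residues are shuffled within each column (gap
  positions stay fixed), the APC-corrected matrix is recomputed per
  permutation (100 by default), and each observed value is standardized.

**Per-pair vs pooled null.** By default each pair is standardized against
its own permutation distribution. A single pooled null per alignment is
available (`per_pair=False`) and is cheaper to describe, but its spread is
dominated by the *between-pair heterogeneity* of the small-sample MI bias
(a pair of diverse 20-state columns has a null mean several tenths of a bit
above a pair of nearly conserved columns). Measured on planted families,
genuinely coevolving pairs with per-pair Z above 100 reach only Z ≈ 4 under
the pooled null — below any sensible working threshold — so the pooled
variant is not the default. The Z-score null uses APC-corrected values;
`null_on="raw"` switches to raw-MI nulls.

A pair whose null has zero spread (e.g. two fully conserved columns) gets a
masked Z and drops out of all downstream sums.

## From MI to per-residue scores

* **cMI** — for each column, the sum of APC-corrected MI over partners with
  `Z ≥ z_thr`. Negative corrected values passing the threshold are summed
  as-is; at the default `z_thr = 5.5` they essentially never occur.
* **distances** — minimum heavy-atom (non-hydrogen) distance between
  residue pairs, model 1 of the PDB file, highest-occupancy altlocs.
* **pMI / pC** — for each structure-mapped residue, the mean cMI
  (respectively mean KL) over neighbors at distance `0 < d ≤ D`, divided by
  the neighbor count (so buried and exposed residues are on the same
  footing), then min-max rescaled to [0, 1] within the family. A residue's
  own value is excluded from its average (`include_self=True` exposed for
  sensitivity analysis); a residue with no neighbors scores 0; a constant
  vector rescales to all zeros. Neighborhoods are closed at the threshold
  (`≤`).

## The combined score and its parameters

```
Cls_r = KL_r + w_mi · pMI_r + w_c · pC_r
```

KL enters unnormalized (bits) with a fixed weight of 1; `w_mi` and `w_c`
are weights relative to it. Only relative weights affect the ranking, so
the anchor is a convention, chosen to make the published optima meaningful.
`--normalize-kl` rescales the KL term to [0, 1] for sensitivity analysis.

Defaults are the published cross-validated optima: `z_thr = 5.5`,
`d_mi = 8.0 Å`, `d_c = 5.6 Å`, `w_mi = 0.6`, `w_c = 0.2`.

Fitting uses brute-force grid search under 5-fold cross validation at the
*family* level (residues within a family are not independent): for each
fold, the grid point maximizing the mean per-family AUC on the training
families is selected and scored on the held-out fold; exact ties break
toward the lexicographically smallest `(z_thr, d_mi, d_c, w_mi, w_c)`. The
default grid spans Z in 4–8 (step 0.5), both distances in 4–12 Å (step
1 Å), both weights in 0–1.5 (step 0.1). Families that cannot be scored
(single-class labels) are skipped with a warning. The expensive,
parameter-independent stages (MI + permutations, distances, KL) are
computed once per family and all ~187k grid points are evaluated on the
cached pieces with a vectorized rank-based AUC, so the full CV fit on 20
synthetic families takes well under a minute.

## Evaluation

Catalytic residues are positives, all other structure-mapped residues
negatives. Per family:

* **AUC** — Mann-Whitney formulation; ties count 1/2.
* **AUC01** — area under the ROC restricted to false-positive rate
  ∈ [0, 0.1] (specificity 1→0.9), trapezoid over the empirical curve with
  linear interpolation at FPR = 0.1, **divided by 0.1** so a perfect
  predictor scores 1.0 and a random one 0.05. The raw (undivided) area is
  available via `normalize=False`. The normalization is stated prominently
  because conventions differ and a random baseline of 0.05 — not 0.5 — is
  the only reading consistent with partial areas reported alongside full
  AUCs of comparable magnitude.
* **Sensitivity at specificity s** — the best sensitivity over all score
  cutoffs achieving specificity ≥ s, together with the cutoff itself,
  reported at s ∈ {0.99, 0.95, 0.90, 0.85}.

## The synthetic benchmark

The generator builds families with planted, analytically known signals.

Sequences: each column draws its consensus residue with probability
`conservation_level`, otherwise from the background. A coevolving pair
`(i, j, s)` replaces both columns by a two-state code (consensus vs an
alternative residue); the partner copies the driving column's state with
probability `s`, so `s = 1` on a 50/50 column plants exactly 1 bit of MI
and `s = 0` none. Phylogenetic redundancy is planted as duplicate clusters
(3 near-copies of a source sequence at 2% point noise), and 2% of residues
in non-reference rows are gapped.

Structure: one Cα-like pseudo-atom per residue (minimum heavy-atom distance
reduces to center distance on fixtures; real PDBs exercise the full
minimum). The site is layered so that, seen from a catalytic residue,
neighborhoods are informative at the contact radius and only there:
catalytic residues sit on a shell ~4.5 Å from the site center, mutually at
least 6 Å apart (so they are not each other's immediate neighbors);
low-cMI "filler" residues line the inside of the site — moderately
conserved (0.45–0.7 in the benchmarks), as the second shell of a real
active site is, which is what gives pC its signal; each coevolving partner
sits in a shell at 0.68–0.95 × `contact_radius` from its coupled residue;
and the remaining chain random-walks (3.8 Å steps, clash distance 3.4 Å)
in a compact shell just outside every catalytic residue's contact sphere,
as in a globular protein, rather than escaping to infinity. Neighborhoods
smaller than the contact radius therefore see mostly filler, the contact
radius captures the coevolving partners, and larger neighborhoods dilute
into ordinary chain — which is what lets the grid search rediscover the
planted distance scale.

Benchmarks: `easy` families have fully conserved catalytic columns, five
mild decoy columns (conservation 0.6) and *no* coevolving pairs (a fully
conserved column cannot covary), with sizes log-spread over 5–600 sequences
to expose the small-alignment failure mode of conservation scores. `hard`
families have catalytic columns at conservation 0.5–0.7, six strong decoys
(0.85–0.95), three coupling-0.8 partners per catalytic column inside the
8 Å sphere, and 300–600 sequences — MI estimation needs hundreds of
effective sequences, so the hard benchmark operates in the regime where the
method is claimed to work. Family sizes there (~40–55 columns) are chosen
so the whole suite runs in minutes on one CPU; the pipeline itself handles
real Pfam-sized inputs, just more slowly.

What passing these benchmarks does **not** show: real families have
phylogenetic structure (not i.i.d. draws plus duplicate clusters),
alignment errors, structural flexibility, multi-chain sites, and
coevolution that is weaker and denser than the planted two-state pairs.
The synthetic results validate the machinery and its statistical
calibration, not field performance on real enzymes.

## Numerical details and degenerate inputs

* Everything is in bits (log base 2).
* MI/APC/Z matrices carry NaN diagonals; masked entries (zero-spread nulls,
  zero joint weight) propagate as NaN/0 and are excluded from sums.
* APC of a matrix with zero grand mean returns the input unchanged.
* Min-max rescaling of a constant vector returns zeros.
* All stochastic steps (permutations, fold assignment, generators) take
  explicit seeds and are deterministic given them.
* Warnings are attached to the prepared family (and echoed into CLI output
  headers): fewer than 10 sequences after trimming (conservation scores
  become unreliable), fewer than 400 sequence clusters (MI estimates become
  unreliable), catalytic annotations not covered by the mapping.

## Known limitations

* mmCIF input is not supported (PDB only).
* Single chain per family; multi-chain active sites are out of scope.
* The pseudocount scheme is a background blend, not a substitution-matrix
  mixture; conclusions about the `l`/`cl` conditions should not be
  over-read.
* The structure generator's one-atom residues cannot test side-chain-level
  distance effects.
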