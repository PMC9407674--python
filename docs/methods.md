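# Methods

## Model

`classdiv` treats an immune repertoire as a frequency distribution
`p_i` over unique CDR3 amino-acid sequences and measures its diversity
with similarity-sensitive Hill numbers. The kernel is multiplicative in
the number of amino-acid differences, `Z_ij = s^m`, on the reasoning
that each substitution independently multiplies the expected Kd ratio of
a reference/variant pair. The per-substitution similarity `s` is the
geometric-mean Kd ratio for one substitution, linked to binding free
energy by `s = exp(−|ΔΔG|/RT)`; the default `s = 0.30` corresponds to a
mean single-substitution effect of 0.71 kcal/mol at R = 1.99×10⁻³
kcal·mol⁻¹·K⁻¹ and T = 298 K (RT ≈ 0.593 kcal/mol).

Assumptions worth keeping in view:

* the Kd ratio for one reference antigen is taken as representative of a
  pair's similarity across antigen space;
* substitutions act multiplicatively and exchangeably — position and
  chemistry enter only through the *average* effect (the bootstrap
  model-selection pipeline exists precisely to test whether richer
  per-substitution models beat this average out of sample);
* any individual `Z_ij` is a noisy estimate; repertoire-scale sums over
  many pairs are what the measure relies on.

## Key parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `s` | 0.30 | — | per-substitution Kd ratio; smaller s → sharper classes |
| `distance` | levenshtein | — | `m` in `s^m`; hamming offered for equal-length analyses |
| `m_cap` | none | substitutions | opt-in distance cap; per-entry truncation error ≤ `s^(m_cap+1)`, always reported |
| `epsilon` | none | — | opt-in similarity floor; zeroes `Z_ij < ε` |
| `q` | — | — | viewpoint; 0 counts classes, ∞ sees only the densest class |
| ΔΔG cutoff | 3.2 | kcal/mol | extreme-value removal before fitting (sensitivity sweep 3.0–3.4 built in) |
| core weight | 0.15 | — | core:noncore mix of the master ΔΔG distribution |

Levenshtein is the default metric so unequal-length CDR3 pairs get a
finite similarity; it is the minimal generalization of "number of
amino-acid differences" across lengths. Exact computation is the
default: weak similarities are many, and silently truncating them would
bias class richness downward, so `m_cap` and `epsilon` are opt-in and
carry explicit error bounds. No solubility-derived lower similarity
limit is applied by default (no principled value is available).

## Computation

The diversity formula needs only the ordinariness vector
`Z_i = Σ_j Z_ij p_j`, never the dense similarity matrix: repertoires up
to 4,000 unique sequences use one dense matrix product, larger ones
stream row by row in O(N²) time and O(N) memory. Distances come from
edlib's banded bit-parallel algorithm; with `m_cap` set, pairs whose
length difference already exceeds the cap are skipped before alignment.
Numerical choices: the q = 1 limit uses the product form evaluated in
log space; |q−1| < 1e-9 is treated as q = 1; q = ∞ is the closed form
`1/max Z_i` over the support (zero-frequency entries are excluded from
all sums); subsampled diversities in rarefaction/ordering reuse the
parent repertoire's similarity matrix by index slicing.

Edit-distance-threshold clustering is included purely as the baseline
class diversity is meant to replace. The greedy variant's outcome
depends on the seeding rule, so it is pinned: seed at the
highest-degree node, ties broken by lexicographically smallest sequence.

## Fitting s (`classdiv.ddg`)

Single-substitution records with both Kd values are parsed from a
SKEMPI-like CSV; region codes map COR → core and RIM/SUP/INT/SUR →
noncore (configurable — the published region scheme is not enumerated in
a machine-readable form, so the mapping is exposed rather than
hard-coded). Core and noncore |ΔΔG| samples are combined 0.15:0.85 by
*weight* (not by record count), |ΔΔG| > 3.2 kcal/mol is removed, and
candidate models are compared by 200 random 2:1 train:test splits,
scoring weighted held-out RMSE. The mean model predicts the weighted
training mean; linear models are OLS on per-substitution differences of
standardized biophysical properties, raw or reduced to five principal
components. Selection prefers the mean model unless a competitor wins
by more than 2 SD of its replicate RMSE. The 95% CI for the implied `s`
is a standard nonparametric bootstrap (resample n records with
replacement, percentile interval of `exp(−mean/RT)`): the spread of 2/3-
subsample training means would understate the full-sample mean's
sampling error by ~√2, so it is not used for the CI.

The bundled property table carries side-chain size, surface, charge,
H-bonding, polarizability, electronegativity, and seven hydrophobicity
scales. The values are approximate compiled literature scales (see the
`load_property_table` docstring); they enter the analysis only as
standardized differences, and no result depends on any individual value
— on synthetic tables with no substitution signal, their whole job is to
*fail* to beat the mean model.

## Synthetic data (`classdiv.simulate`)

The generators emulate the study conditions everything is tested under:

* **Clone networks** — a seed CDR3 (length 17, conserved C/F flanks)
  grows by successive single substitutions into a connected distance-1
  lineage; counts are one dominant ancestor with geometrically decaying
  descendants (decay 0.85), normalized to 752 cells over 34 unique
  sequences. The published reference clone's exact topology and count
  vector are not available, so the shared-count-multiset property — the
  thing the validity test actually needs — is what the generator pins.
* **Validity panel** — one-clone, two-clone, unrelated (all pairs at
  distance ≥ 2), and uniformly random 17-mers, all with the same count
  multiset. The two-clone member relocates half of the one-clone
  lineage via a fixed-point-free residue relabelling, which preserves
  every within-block distance (an isomorphic induced subgraph by
  construction) while placing the blocks ≥ ⌈L/2⌉ apart. For this to
  bound cross-block distances, lineage substitutions are confined to a
  fixed subset of 6 interior positions — a deliberate departure from
  spatially unconstrained hypermutation that also makes the one- vs
  two-clone comparison structural (identical within-block similarity).
* **Clonal repertoires** — unions of independent lineages with seeds
  rejection-sampled to pairwise distance ⌈L/2⌉ + 2·(position budget),
  so cross-clone similarity is provably ≤ `s^(L/2)`.
* **ΔΔG tables** — |ΔΔG| per region is exponential with mean
  `RT·ln(fold)` (core 13-fold, noncore 4-fold), truncated at the 3.2
  kcal/mol cutoff; Kd pairs are reconstructed so parsing recovers the
  generated values exactly. Ground truth (including the truncated
  mixture mean and its implied s ≈ 0.258) is emitted alongside.

What the generators do *not* emulate: V(D)J recombination statistics,
hypermutation hotspots, sequencing error, length variation within a
clone, or the antigen-driven selection that shapes real clone sizes.
Passing tests therefore demonstrate correctness of the measures and
pipelines under controlled structure, not biological findings about real
repertoires.

## Problem sizes

The test suite runs repertoires up to a few hundred unique sequences for
dual-route (optimized vs textbook) equivalence checks, 50,000-element
frequency vectors for the idealized two-block example, 1,328-record
synthetic binding tables (20 independent seeds) for fit recovery, and
12,000-cell clonal repertoires subsampled at 3,000 for ordering
robustness — sizes chosen so each check exercises the real code path
while the whole suite stays fast.

## Known limitations

* `s^m` ignores which residues changed and where; the framework is
  modular (any kernel can populate `Z`), but only the edit-distance
  kernel ships.
* No unseen-species correction is applied to sequence diversity;
  rarefaction reports observed values only, so raw `qD` at small sample
  sizes underestimates richness.
* Hamming mode rejects unequal-length pairs rather than padding.
* The greedy clustering tie-break is a convention, not a claim; other
  seeding rules give other counts (which is the point of the baseline).
* Off-diagonal similarity mass is reported (`off_diagonal_report`) but
  no quantitative "mostly near zero" criterion is imposed.
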