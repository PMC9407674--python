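# classdiv

Similarity-sensitive ("class") diversity for antibody and T cell receptor
CDR3 repertoires.

## The problem

Repertoires are usually summarized by *sequence diversity*: Hill numbers
`qD` over the clone frequencies `p_i` (q = 0 richness, q = 1 the
exponential of Shannon entropy, q = 2 inverse Simpson, q = ∞ inverse
Berger–Parker). Sequence diversity counts genes, not function: a
repertoire of 50,000 unique sequences that all bind the same two antigens
is, functionally, a repertoire of two. `classdiv` measures the *effective
number of binding classes* instead, using the Leinster–Cobbold
similarity-sensitive Hill numbers

```
qD_S = ( Σ_i p_i · Z_i^(q−1) )^(1/(1−q))      q ∉ {1, ∞}
1D_S = Π_i (1/Z_i)^(p_i)                       (Shannon limit)
∞D_S = 1 / max_i Z_i                           (Berger–Parker limit)

Z_i  = Σ_j Z_ij p_j        (the "ordinariness" of sequence i)
```

with a binding-similarity kernel grounded in thermodynamics:

```
Z_ij = s^m,   m = edit distance between CDR3s i and j,
s = exp(−|ΔΔG| / RT) = average Kd ratio per single substitution ≈ 0.30
```

`|ΔΔG| = −RT ln(Kd1/Kd2)` is the change in Gibbs free energy of binding
caused by one amino-acid substitution (R = 1.99×10⁻³ kcal·mol⁻¹·K⁻¹,
T = 298 K). The default `s = 0.30` corresponds to a mean single-
substitution effect of 0.71 kcal/mol, the value implied by large-scale
mutational binding data; the package includes the full fitting pipeline
that produces it, so `s` can be re-derived from any SKEMPI-style table.
With the identity kernel (`Z = I`), `qD_S` reduces exactly to `qD`.

## What's in the box

| module | contents |
| --- | --- |
| `classdiv.repertoire` | `Repertoire` container; AIRR TSV / plain TSV / FASTA I/O |
| `classdiv.similarity` | edit distances, the `s^m` kernel, ΔΔG↔Kd-ratio conversions, ordinariness, edit-distance-threshold clustering baselines |
| `classdiv.diversity` | `qD`, `qD_S`, class BPI, diversity profiles over q |
| `classdiv.ddg` | SKEMPI-like parsing, core/noncore master distribution, extreme-value removal, bootstrap model selection (`SubstitutionEffectModel.fit()` → results with `summary()`) |
| `classdiv.sampling` | subsampling, metarepertoires, rarefaction + discovery rate, ordering robustness |
| `classdiv.simulate` | clonal lineage networks, the four-repertoire validity panel, synthetic ΔΔG tables with ground truth |
| `classdiv.cli` | `classdiv` command with `diversity`, `profile`, `cluster`, `fit-ddg`, `subsample`, `rarefy`, `ordering`, `simulate` |

## Worked example

Simulate a 34-sequence, 752-cell repertoire made of two unrelated
somatically hypermutated clones, then measure it:

```sh
classdiv simulate --kind two-clone --seed 7 --out two_clone.tsv
classdiv diversity --input two_clone.tsv --q 0,1,2,inf
```

```json
{
  "n_unique": 34,
  "total_count": 752,
  "model": {"s": 0.3, "distance": "levenshtein", "m_cap": null},
  "results": [
    {"q": 0.0,   "sequence_diversity": 34.0,  "class_diversity": 16.347},
    {"q": 1.0,   "sequence_diversity": 16.001, "class_diversity": 7.021},
    {"q": 2.0,   "sequence_diversity": 12.063, "class_diversity": 5.599},
    {"q": "inf", "sequence_diversity": 6.596,  "class_diversity": 3.347}
  ]
}
```

Sequence richness says 34 different sequences; class diversity says the
repertoire behaves like ~16 independent binders at q = 0 (two tight
clusters plus intraclone spread), shrinking further as q up-weights the
dominant clones. Refit `s` from a synthetic binding table with known
ground truth (implied s = 0.2579):

```sh
classdiv simulate --kind ddg --seed 7 --out ddg.csv
classdiv fit-ddg --input ddg.csv --models mean --n-reps 200 --seed 7
```

which reports held-out RMSE 0.713 kcal/mol for the mean model and an
implied `s = 0.259` (95% CI 0.244–0.273), covering the generator's truth.

The same objects are available as a library:

```python
from classdiv import Repertoire, SimilarityModel, class_diversity

rep = Repertoire(["CARDYW", "CARDFW"], [1, 1])
class_diversity(rep, q=0, model=SimilarityModel())   # 1.538 = 1/0.65
```

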