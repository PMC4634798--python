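# otufs — feature subset selection for microbiome abundance tables

Comparative microbiome and metagenomic studies routinely ask which OTUs
(operational taxonomic units) or functional features best discriminate
between sample phenotypes — omnivore vs vegetarian diet, IBD vs control,
treatment vs stimulus.  `otufs` answers that question with *feature subset
selection* over a BIOM feature-by-sample count matrix
`X ∈ ℕ₊^{K×M}` and a per-sample phenotype `Y`, without tying the answer to
any particular classifier.  It is aimed at microbial ecologists who already
have a classified abundance table (e.g. from QIIME) plus a mapping file, and
at methods developers who want the selection primitives as a Python library.

Three selection families are implemented:

**Information-theoretic greedy filters.**  Features are scored by the
plug-in mutual information

    I(X;Y) = Σ_y Σ_x p(x,y) log₂ [ p(x,y) / (p(x) p(y)) ]

and selected by greedy forward search maximizing

    J(X, Y, F) = I(X;Y) − α Σ_{X'∈F} I(X;X') + β Σ_{X'∈F} I(X;X'|Y),   α, β ≥ 0,

where `F` is the already-selected set: relevance, minus redundancy, plus
*conditional* redundancy (rewarded, because features that are jointly
informative about `Y` help).  MIM (α=β=0), mRMR (α=1/|F|, β=0) and JMI
(α=β=1/|F|) are instances of this linear form; MIFS, CIFE, CMIM, ICAP, DISR
and CondMI complete a nine-criterion catalog.

**NPFS (Neyman–Pearson Feature Selection).**  Fixed-`k` filters need the
subset size up front; NPFS only needs a guess.  It runs the base selector
("NPFS-SF", e.g. NPFS-MIM) on bootstrap subsamples, counts per-feature
selections, and keeps features whose counts exceed the smallest ζ with
`P(Binomial(n, k/K) > ζ) ≤ α` — so the relevant-set size is data-driven.
The bootstrap is embarrassingly parallel and seeded per replicate, so the
result is identical for any worker count.

**Embedded selection with the lasso.**  On per-sample relative abundances
and a ±1 phenotype coding,

    θ* = argmin_θ (1/2M) ‖y − Xᵀθ‖₂² + λ‖θ‖₁,

with λ chosen by stratified cross-validation over a data-derived grid
anchored at λ_max = (1/M)·max_j |X_j·y| (the smallest penalty whose solution
is exactly zero).  The nonzero coefficients are the selected features.

## Worked example

```python
from otufs import (SyntheticSpec, generate, extract_labels,
                   greedy_select, make_objective)

table, metadata, truth = generate(
    SyntheticSpec(K=100, M=120, n_informative=10, n_redundant=5, seed=7))
table, labels = extract_labels(table, metadata, "class")
result = greedy_select(table, labels, k=12, params=make_objective("jmi"))
for rank, (fid, score) in enumerate(zip(result.feature_ids, result.scores), 1):
    print(rank, fid, round(score, 4))
```

prints (`examples/greedy_filter_selection.py` runs the full version):

```
rank  feature      score(bits)  planted?
   1  OTU_00002      0.2453  yes
   2  OTU_00008      0.6214  yes
   3  OTU_00066      0.5253  no
   4  OTU_00023      0.5301  no
   5  OTU_00004      0.5488  yes
   ...
8/12 selected features are planted signal
```

The first score is the marginal `I(X;Y)` of the best single OTU (0.245
bits); later scores are the full JMI objective at the moment of selection,
so they are not monotone.  Eight of the twelve picks are planted
class-shifted OTUs or their redundant copies.

The same study from the shell (see `examples/biom_cli_workflow.py`):

```sh
otufs --input study.biom --map map.tsv --column class \
      --output ranked.tsv --method mrmr --k 8 --report-differences 5
```

writes `ranked.tsv` (rank, feature ID, taxonomy, score, in selection order)
and `ranked.tsv.diff.tsv`, the selected OTUs sorted by the absolute
difference of their mean relative abundances between the two classes, with
the sign convention stated in the header (negative = higher in the second,
lexicographically later, class).

Other entry points: `examples/npfs_automatic_set_size.py` (NPFS deciding the
number of relevant OTUs from a guessed k) and
`examples/lasso_embedded_selection.py` (cross-validated lasso support).

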