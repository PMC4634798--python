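"""Rank OTUs by information-theoretic relevance with a greedy filter.

Builds a small two-class synthetic study (10 class-shifted OTUs among 100),
then runs JMI — the criterion that balances relevance against redundancy and
rewards jointly-informative features — and prints the selected features with
their per-step objective scores (in bits).
"""

from otufs import SyntheticSpec, extract_labels, generate, greedy_select, make_objective

table, metadata, truth = generate(
    SyntheticSpec(K=100, M=120, n_informative=10, n_redundant=5, seed=7)
)
table, labels = extract_labels(table, metadata, "class")

result = greedy_select(table, labels, k=12, params=make_objective("jmi"))

planted = set(truth["informative"].tolist()) | set(truth["redundant"].tolist())
print(f"JMI selection on {table.n_features} OTUs x {table.n_samples} samples")
print("rank  feature      score(bits)  planted?")
for rank, (idx, fid, score) in enumerate(
    zip(result.feature_indices, result.feature_ids, result.scores), start=1
):
    print(f"{rank:>4}  {fid}  {score:>10.4f}  {'yes' if idx in planted else 'no'}")

hits = sum(i in planted for i in result.feature_indices)
print(
    f"\n{hits}/12 selected features are planted signal; the score is the "
    "greedy objective J = I(X;Y) - (1/|F|) sum I(X;X') + (1/|F|) sum I(X;X'|Y) "
    "at the moment of selection."
)
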