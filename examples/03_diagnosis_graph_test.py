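"""Test whether a diagnosis aggregates non-randomly on the membership graph.

Subjects and centroids form a bipartite graph with edge distance 1 - u.
The average shortest weighted path (ASWP) among diagnosed subjects is
compared with 5000 equally sized random subject sets; a small left-tail
p-value means the diagnosed subjects sit more compactly in profile space
than chance.
"""

import fuzzyprofiles as fp

spec = fp.SyntheticSpec(n_per_cohort={"DISC": 1200}, seed=11)
tables, truth = fp.generate(spec)
table = fp.residualize(tables[0])
X = table.features
X = (X - X.mean()) / X.std(ddof=0)
model, U = fp.fit_fcm(X, 4, seed=11)

graph = fp.build_graph(U, transform="one_minus_u")
pvals = []
for dx in table.schema.diagnoses:
    flags = table.data[dx]
    flags.index = U.row_ids
    res = fp.aswp_permutation_test(graph, flags, B=5000, seed=11, label_name=dx)
    pvals.append(res.p_left)
    print(f"{dx:5s} n={res.n_labeled:4d}  ASWP={res.observed:.3f}  "
          f"p_left={res.p_left:.4f}  p_right={res.p_right:.4f}")

adj, _ = fp.fdr_bh(pvals)
print("FDR-adjusted left-tail p:", [round(p, 4) for p in adj])
print("\nASWP is the mean shortest-path distance over all diagnosed pairs;")
print("p_left < 0.05 after FDR indicates compact, non-random aggregation.")
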