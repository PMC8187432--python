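"""Build the weighted sample-similarity graph for one omics view.

Edges are cosine similarities kept above a threshold eps; eps is set
implicitly by k, the average number of retained pairs per node.  The
retained adjacency is renormalized with self-loops so graph convolutions
stay numerically stable (all eigenvalues in [-1, 1]).
"""

import numpy as np

import mogonet as mg
from mogonet.graph import build_graph, extend_for_test

data, _ = mg.generate_complementary_trio(n=100, c=3, seed=0, n_features=40)
X = data.views[0].values

graph = build_graph(X, k=5)
n = X.shape[0]
retained = (graph.S >= graph.epsilon).sum() / n
print(f"eps = {graph.epsilon:.4f}; average retained pairs/node = {retained:.2f}")

eigs = np.linalg.eigvalsh(graph.A_tilde)
print(f"A_tilde symmetric: {np.allclose(graph.A_tilde, graph.A_tilde.T)}; "
      f"eigenvalues in [{eigs.min():.3f}, {eigs.max():.3f}]")

# a new sample is classified transductively: append it to the training
# graph, compute only its similarity row, and renormalize
x_new = X[:3] * 0.9  # pretend these are unseen samples
A_ext = extend_for_test(X, x_new, graph.epsilon, A_tr=graph.A)
print(f"extended adjacencies: {A_ext.shape} (one (n+1)-node graph per sample)")

# with k=1 no off-diagonal edge survives and the graph collapses to identity
g1 = build_graph(X, k=1)
print(f"k=1 gives identity: {np.array_equal(g1.A_tilde, np.eye(n))}")
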