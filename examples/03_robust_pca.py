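"""Principal component pursuit: split a corrupted matrix into low-rank
plus sparse parts.

A rank-5 matrix with 5% of entries hit by +/-10 spikes is recovered almost
exactly by the convex program min ||L||_* + lambda ||S||_1 s.t. X = L + S.
"""

import numpy as np

from matrixmi import gen_lowrank_sparse, rpca_decompose

X, L0, S0 = gen_lowrank_sparse(m=200, n=200, rank=5, density=0.05,
                               amplitude=10.0, seed=42)
print(f"input: 200x200, true rank {np.linalg.matrix_rank(L0)}, "
      f"{np.count_nonzero(S0)} corrupted entries")

res = rpca_decompose(X)  # default lambda = 1/sqrt(max(m, n))
rel_L = np.linalg.norm(res.L - L0) / np.linalg.norm(L0)
print(f"lambda = {res.lam:.4f}, converged in {res.iterations} iterations "
      f"(feasibility residual {res.primal_residual:.1e})")
print(f"low-rank recovery relative error: {rel_L:.2e}")
print(f"recovered rank: {np.linalg.matrix_rank(res.L)}")
print("an error around 1e-7 means the corruption was removed exactly up to "
      "solver tolerance")
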