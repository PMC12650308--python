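"""Soft-cluster the trajectory shapes: the study design partitions the
features into 16 kinetic clusters, with the fuzzifier m selected by the
Xie-Beni compactness/separation ratio over a grid at that cluster count.
The fitted memberships become each metabolite's quantitative kinetic
label."""

import json
from pathlib import Path

import pandas as pd

from strokemap import fcm

PRE = Path("results/preprocess")
OUT = Path("results/cluster")
SEED = 1
C = 16  # study configuration: sixteen kinetic signatures

X_df = pd.read_csv(PRE / "shape_matrix.csv", index_col=0)
X = X_df.to_numpy()

_, m_star, xb_table = fcm.select_parameters(
    X, c_grid=(C,), m_grid=(1.1, 1.3, 1.5, 2.0), seed=SEED, n_init=3
)
print(f"Xie-Beni fuzzifier selection at c = {C}: m* = {m_star}")
print(xb_table.sort_values("xb").to_string(index=False))

model, U = fcm.fit_fcm(X, c=C, m=m_star, seed=SEED, n_init=10, max_iter=500)
print(f"fit: {model.n_iter} iterations, converged={model.converged}, "
      f"XB = {model.xb:.4f}")

OUT.mkdir(parents=True, exist_ok=True)
xb_table.to_csv(OUT / "xb_grid.csv", index=False)
(OUT / "cluster_model.json").write_text(json.dumps(model.to_dict(), indent=2))
pd.DataFrame(U, index=X_df.index).to_csv(OUT / "memberships_raw.csv")
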