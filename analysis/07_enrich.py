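"""Pathway over-representation of the selected (drowning-corrected) feature
set against a synthetic pathway annotation in which one pathway is
constructed from signature-labelled features (so it should enrich) and the
others are random background draws (so they should not)."""

from pathlib import Path

import numpy as np
import pandas as pd

from strokemap.enrich import fisher_ora

LAB = Path("results/labels")
OUT = Path("results/enrich")
SEED = 1

labels = pd.read_csv(LAB / "labels.csv", index_col=0)
selected = list(labels.index[labels["selected"]])
background = list(labels.index)

rng = np.random.default_rng(SEED)
pathways = {
    # enriched by construction: mostly selected features
    "signature_pathway": set(rng.choice(selected, size=min(15, len(selected)),
                                        replace=False))
    | set(rng.choice(background, size=5, replace=False)),
}
for i in range(8):  # null pathways: random background draws
    pathways[f"null_pathway_{i}"] = set(
        rng.choice(background, size=20, replace=False))

result = fisher_ora(selected, background, pathways, alpha=0.01)
OUT.mkdir(parents=True, exist_ok=True)
result.to_csv(OUT / "enrichment.csv", index=False)

print(f"{len(selected)} selected of {len(background)} background features")
print(result[["pathway", "hits", "pathway_size", "p_value", "pass"]]
      .to_string(index=False))
print(f"{int(result['pass'].sum())} pathway(s) pass Fisher p < 0.01")
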