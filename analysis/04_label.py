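"""Turn memberships into kinetic labels: annotate each cluster centroid by
its dynamics, identify the dominant clusters that absorb most membership
mass, and apply the drowning-effect correction (primary characteristic =
highest-membership cluster outside the dominant set; presentation set =
features with a non-dominant membership above 0.5)."""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from strokemap import labeling
from strokemap.schedule import build_schedule

CLU = Path("results/cluster")
OUT = Path("results/labels")

schedule = build_schedule()
model = json.loads((CLU / "cluster_model.json").read_text())
U_df = pd.read_csv(CLU / "memberships_raw.csv", index_col=0)
U = U_df.to_numpy()

annotations = labeling.annotate_clusters(np.array(model["centroids"]), schedule)
codes = [a.code for a in annotations]
print("cluster annotations (narrative order):")
for a in sorted(annotations, key=lambda a: a.code):
    print(f"  {a.code}: {a.description}")

dominant = labeling.identify_dominant(U, k=4, codes=codes)
print(f"dominant clusters (top-4 membership mass): {sorted(dominant)}")

labels = labeling.assign_labels(U, annotations, dominant, threshold=0.5,
                                feature_ids=U_df.index)
frame = labeling.labels_to_frame(labels)
n_sel = int(frame["selected"].sum())
n_corrected = int((frame["primary"] != frame["masked_primary"]).sum())
print(f"{n_sel} features selected (non-dominant membership > 0.5); "
      f"{n_corrected} rescued from dominant clusters by the correction")

groups, Z = labeling.hca_on_memberships(U, n_groups=len(codes))
OUT.mkdir(parents=True, exist_ok=True)
frame.to_csv(OUT / "labels.csv")
pd.DataFrame(U, index=U_df.index, columns=codes).to_csv(OUT / "memberships.csv")
(OUT / "dendrogram.newick").write_text(
    labeling.linkage_to_newick(Z, U_df.index))
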