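"""Pathway over-representation by one-sided Fisher's exact test.

For each pathway the 2x2 table is::

                    in pathway    not in pathway
    in set             hits       set - hits
    not in set      path - hits   rest

tested one-sided for enrichment.  The pass flag uses the raw p-value at a
strict ``p < alpha`` rule (default 0.01); a Benjamini-Hochberg column is
reported for transparency but does not drive the flag.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


def fisher_ora(
    selected,
    background,
    pathways: dict,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-sided over-representation test of ``selected`` within ``background``.

    ``pathways`` maps pathway id -> iterable of feature ids.  Pathway members
    outside the background are ignored.  Rows are sorted by p-value.
    """
    selected = set(selected)
    background = set(background)
    stray = selected - background
    if stray:
        raise ValueError(
            f"selected features missing from background: {sorted(stray)[:10]}"
        )
    n_bg = len(background)
    n_set = len(selected)
    rows = []
    for pid, members in pathways.items():
        members = set(members) & background
        hits = len(members & selected)
        table = [
            [hits, n_set - hits],
            [len(members) - hits, n_bg - n_set - (len(members) - hits)],
        ]
        p = float(fisher_exact(table, alternative="greater").pvalue)
        rows.append({
            "pathway": pid, "hits": hits, "set_size": n_set,
            "pathway_size": len(members), "background_size": n_bg, "p_value": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["pass"] = out["p_value"] < alpha
        out = out.sort_values(["p_value", "pathway"], kind="stable", ignore_index=True)
    return out


def read_pathway_map(path) -> dict:
    """Two-column CSV (feature id, pathway id) -> {pathway: set of features}."""
    df = pd.read_csv(path)
    feat_col, path_col = df.columns[:2]
    return {
        pid: set(group[feat_col].astype(str))
        for pid, group in df.groupby(path_col)
    }
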