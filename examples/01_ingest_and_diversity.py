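"""Ingest a survey, rarefy it, and compute alpha diversity per cluster.

Generates a synthetic 43-digester survey (16 Cluster-I + 27 Cluster-II
samples, 300 OTUs at depth 2230), round-trips it through TSV, and prints
Chao1/Shannon/Simpson means per cluster — the expected pattern is lower
diversity in the Clostridium-dominated Cluster I.
"""

import tempfile
from pathlib import Path

from digestnet import (
    alpha_diversity,
    generate_community,
    rarefy,
    read_otu_table,
    write_otu_table,
)

comm = generate_community(seed=1)
table = comm.table

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "otu_table.tsv"
    write_otu_table(table, path)
    table = read_otu_table(path)  # round-trip through the on-disk format

# already at uniform depth; re-rarefying to a lower depth is a no-op demo
table = rarefy(table, 2000, seed=1)

profile = alpha_diversity(table)
labels = comm.metadata.frame["cluster"]
for cluster in ("I", "II"):
    sub = profile.loc[labels == cluster]
    print(
        f"Cluster {cluster:<3} n={len(sub):2d}  "
        f"observed={sub.observed_otus.mean():6.1f}  "
        f"chao1={sub.chao1.mean():6.1f}  "
        f"shannon={sub.shannon.mean():5.2f}  simpson={sub.simpson.mean():5.3f}"
    )
print("\nLower Shannon/Simpson in Cluster I reflects its planted dominance "
      "by a few core OTUs; Chao1 estimates total richness including unseen OTUs.")
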