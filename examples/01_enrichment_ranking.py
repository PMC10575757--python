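"""Cluster enrichment factors from multi-round NGS read counts.

Uses the bundled anti-NKp46 campaign table: per-cluster read counts over
FACS rounds 0 (unsorted baseline), 1 and 2, plus the per-round repertoire
totals.  The enrichment factor EF = ((n+1)/(t+1))|sel / ((n+1)/(t+1))|base
flags clusters whose relative abundance grew over sorting — including rare
clusters with almost no baseline reads, which pure frequency ranking would
miss.
"""

from vhhmine import campaign
from vhhmine.enrichment import enrichment_factor

clusters, totals = campaign.cluster_reads()

print("cluster  reads_r0  reads_r2      EF  (rounded)")
for row in clusters.itertuples():
    ef = enrichment_factor(row.count_r2, totals[2], row.count_r0, totals[0])
    print(
        f"{row.cluster_id:>7}  {row.count_r0:>8}  {row.count_r2:>8}"
        f"  {ef:>8.1f}  ({round(ef)})"
    )

print(
    "\nCluster 1 has zero baseline reads yet the largest fold change -- the"
    "\npseudocount keeps its EF finite; frequency ranking alone would put"
    "\ncluster 4 (11,954 round-2 reads) first instead."
)
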