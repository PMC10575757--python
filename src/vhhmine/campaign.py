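"""Bundled reference data from an anti-NKp46 VHH discovery campaign.

The package ships three small tables from a published yeast-surface-display
campaign against the NK-cell receptor NKp46, used throughout the test suite
and the worked examples as real-world anchors:

* per-cluster NGS read counts over FACS rounds 0-2 (plus round totals),
* the most-occurring CDR1-3 sequence of the five most frequent and five
  most enriched CDR3 clusters (eight distinct sequences; two clusters
  appear in both rankings),
* the 37 characterized candidate sequences with their CDR3 cluster group,
  origin (NGS-observed vs. model-sampled) and reported scores.

All sequences share one fixed humanized framework, so only the CDRs are
tabulated.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .repertoire import AnnotatedVHH


def _data_path(name: str):
    return resources.files("vhhmine.data").joinpath(name)


def cluster_reads() -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-cluster NGS reads by FACS round and per-round repertoire totals.

    Returns (clusters, totals) where clusters has columns cluster_id /
    count_r0 / count_r1 / count_r2 and totals maps round index to the full
    repertoire's read total for that round.
    """
    with resources.as_file(_data_path("nkp46_cluster_reads.csv")) as p:
        df = pd.read_csv(p)
    totals_row = df[df["cluster_id"] == "ALL"].iloc[0]
    totals = {
        int(c.removeprefix("count_r")): int(totals_row[c])
        for c in df.columns
        if c.startswith("count_r")
    }
    clusters = df[df["cluster_id"] != "ALL"].copy()
    clusters["cluster_id"] = clusters["cluster_id"].astype(int)
    return clusters.reset_index(drop=True), totals


def top_cluster_sequences() -> pd.DataFrame:
    """CDR triplets of the top-frequency / top-enrichment cluster representatives."""
    with resources.as_file(_data_path("nkp46_top_clusters.csv")) as p:
        return pd.read_csv(p)


def candidate_sequences() -> pd.DataFrame:
    """The 37 characterized candidates with CDR3 cluster group and origin."""
    with resources.as_file(_data_path("nkp46_candidates.csv")) as p:
        return pd.read_csv(p)


def candidates_as_vhh() -> list[AnnotatedVHH]:
    """Candidate table as AnnotatedVHH records (unit counts, ngs/sampled source)."""
    df = candidate_sequences()
    return [
        AnnotatedVHH(
            seq_id=str(row.candidate_id),
            cdr1=row.cdr1,
            cdr2=row.cdr2,
            cdr3=row.cdr3,
            counts={2: 1},
            source=row.source,
        )
        for row in df.itertuples()
    ]


def candidate_groups() -> dict[str, int]:
    """seq_id -> published CDR3 cluster group for the candidate table."""
    df = candidate_sequences()
    return {
        str(r.candidate_id): int(r.cluster_group) for r in df.itertuples()
    }
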