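"""Cluster-level enrichment factors and per-residue frequency/enrichment matrices.

The enrichment factor (fold change) of a cluster between a baseline and a
selected FACS round is the pseudocount-stabilized ratio of relative
abundances::

    EF = ((n_sel + 1) / (t_sel + 1)) / ((n_base + 1) / (t_base + 1))

where n is the cluster's read count and t the round's total read count.  The
+1 pseudocounts keep the ratio finite for clusters absent from the baseline,
which is exactly the regime (rare but strongly improving binders) the
statistic is designed to flag.

Per-residue matrices summarize, for a cluster, either the count-weighted
residue frequency at each position (rows sum to 1) or the ratio of such
frequencies between two rounds (pseudocount-stabilized), over member
sequences whose region length equals the cluster's modal length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterTable
from .repertoire import AA_ALPHABET, AnnotatedVHH

REGIONS = ("cdr1", "cdr2", "cdr3", "concatenated")


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentRecord:
    cluster_id: int
    n_base: int
    t_base: int
    n_sel: int
    t_sel: int
    ef: float

    @property
    def ef_rounded(self) -> int:
        """Nearest-integer EF as printed in summary tables."""
        return int(round(self.ef))


def enrichment_factor(n_sel: int, t_sel: int, n_base: int, t_base: int) -> float:
    for name, n, t in (("selected", n_sel, t_sel), ("baseline", n_base, t_base)):
        if n < 0 or t < 0:
            raise EnrichmentError(f"negative {name} counts")
        if n > t:
            raise EnrichmentError(
                f"{name} cluster reads {n} exceed round total {t}"
            )
    return ((n_sel + 1) / (t_sel + 1)) / ((n_base + 1) / (t_base + 1))


def rank_clusters(
    table: ClusterTable,
    mode: str,
    sel_round: int,
    base_round: int | None = None,
    totals: dict[int, int] | None = None,
) -> list[EnrichmentRecord]:
    """Rank clusters by selected-round frequency or by enrichment factor.

    ``totals`` overrides the per-round totals (defaults to sums over the
    table, which is correct when the table covers the full repertoire).
    """
    if mode not in ("frequency", "enrichment"):
        raise EnrichmentError(f"unknown ranking mode {mode!r}")
    if mode == "enrichment" and base_round is None:
        raise EnrichmentError("enrichment mode needs a baseline round")
    observed = {r for cl in table.clusters for r in cl.per_round_counts}
    for r in (sel_round,) if base_round is None else (sel_round, base_round):
        if totals is None and r not in observed:
            raise EnrichmentError(f"round {r} absent from cluster table")
    if totals is None:
        totals = {}
        for cl in table.clusters:
            for r, c in cl.per_round_counts.items():
                totals[r] = totals.get(r, 0) + c
    records = []
    for cl in table.clusters:
        n_sel = cl.count(sel_round)
        n_base = cl.count(base_round) if base_round is not None else 0
        t_base = totals.get(base_round, 0) if base_round is not None else 0
        ef = (
            enrichment_factor(n_sel, totals[sel_round], n_base, t_base)
            if base_round is not None
            else float("nan")
        )
        records.append(
            EnrichmentRecord(
                cluster_id=cl.cluster_id,
                n_base=n_base,
                t_base=t_base,
                n_sel=n_sel,
                t_sel=totals[sel_round],
                ef=ef,
            )
        )
    if mode == "frequency":
        records.sort(key=lambda r: (-r.n_sel, r.cluster_id))
    else:
        records.sort(key=lambda r: (-r.ef, r.cluster_id))
    return records


def _region_strings(seq: AnnotatedVHH, region: str) -> str:
    if region == "concatenated":
        return seq.concatenated
    if region not in REGIONS:
        raise EnrichmentError(f"unknown region {region!r}")
    return getattr(seq, region)


def _modal_length_members(
    members: Sequence[AnnotatedVHH], round_index: int, region: str
) -> tuple[list[AnnotatedVHH], float]:
    """Members whose region length equals the count-weighted modal length.

    Returns the retained members and the excluded read fraction.
    """
    weights: dict[int, int] = {}
    for s in members:
        weights[len(_region_strings(s, region))] = weights.get(
            len(_region_strings(s, region)), 0
        ) + s.count(round_index)
    total = sum(weights.values())
    if total == 0:
        raise EnrichmentError(f"no reads in round {round_index}")
    modal = max(sorted(weights), key=lambda L: weights[L])
    kept = [
        s
        for s in members
        if len(_region_strings(s, region)) == modal and s.count(round_index) > 0
    ]
    if not kept:
        raise EnrichmentError("no sequences left after modal-length filtering")
    excluded = 1.0 - weights[modal] / total
    return kept, excluded


@dataclass
class PositionalMatrix:
    region: str
    mode: str  # "frequency" | "enrichment"
    values: pd.DataFrame  # positions x 20 residues
    excluded_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode == "frequency":
            rows = self.values.to_numpy().sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                raise EnrichmentError("frequency rows must sum to 1")
            if (self.values.to_numpy() < 0).any():
                raise EnrichmentError("negative frequency entry")
        elif self.mode == "enrichment":
            if (self.values.to_numpy() <= 0).any():
                raise EnrichmentError("enrichment entries must be positive")
        else:
            raise EnrichmentError(f"unknown matrix mode {self.mode!r}")


def positional_frequency(
    members: Sequence[AnnotatedVHH],
    round_index: int,
    region: str = "cdr3",
) -> PositionalMatrix:
    """Count-weighted per-position residue frequencies for one round."""
    kept, excluded = _modal_length_members(members, round_index, region)
    length = len(_region_strings(kept[0], region))
    counts = np.zeros((length, len(AA_ALPHABET)))
    aa_index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for s in kept:
        w = s.count(round_index)
        for pos, aa in enumerate(_region_strings(s, region)):
            counts[pos, aa_index[aa]] += w
    freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, index=range(1, length + 1), columns=list(AA_ALPHABET))
    return PositionalMatrix(
        region=region, mode="frequency", values=df, excluded_fraction=excluded
    )


def positional_enrichment(
    members: Sequence[AnnotatedVHH],
    sel_round: int,
    base_round: int,
    pseudo: float | None = None,
    region: str = "cdr3",
) -> PositionalMatrix:
    """Per-position residue frequency ratio between two rounds.

    entry(i, a) = (f_sel(i, a) + pseudo) / (f_base(i, a) + pseudo).  The
    default pseudocount is 1 / (total reads in the smaller round), shrinking
    ratios where coverage cannot support them.
    """
    f_sel = positional_frequency(members, sel_round, region)
    f_base = positional_frequency(members, base_round, region)
    if f_sel.values.shape != f_base.values.shape:
        raise EnrichmentError(
            "modal region length differs between rounds; "
            "cannot form positional ratios"
        )
    if pseudo is None:
        totals = [
            sum(s.count(r) for s in members) for r in (sel_round, base_round)
        ]
        pseudo = 1.0 / min(totals)
    if pseudo <= 0:
        raise EnrichmentError("pseudocount must be positive")
    ratio = (f_sel.values + pseudo) / (f_base.values + pseudo)
    return PositionalMatrix(
        region=region,
        mode="enrichment",
        values=ratio,
        excluded_fraction=max(f_sel.excluded_fraction, f_base.excluded_fraction),
    )
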