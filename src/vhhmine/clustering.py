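"""Greedy centroid clustering of VHH repertoires at a CDR3 identity threshold.

Identity between two CDR3s is defined from a global alignment with match
score 1, mismatch 0 and linear gap penalty -1: the number of identical
aligned positions in the optimal-score alignment, divided by the longer
sequence length.  Among score-co-optimal alignments the one with the most
identical positions is used, which makes the value well defined.

Clustering is abundance-ordered greedy centroid assignment (CD-HIT style):
candidates are visited in descending total read count (ties broken by
lexicographic CDR3, then seq_id); a sequence joins the first existing
cluster whose centroid identity is >= the threshold, otherwise it founds a
new cluster with its own CDR3 as centroid.  The procedure is deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .repertoire import AnnotatedVHH


class ClusteringError(ValueError):
    pass


def _alignment_matches(a: str, b: str) -> int:
    """Max identical aligned positions among score-optimal global alignments.

    Linear-gap Needleman-Wunsch (match 1 / mismatch 0 / gap -1) tracking, for
    every cell, the best score and the maximum match count achievable at that
    score.
    """
    n, m = len(a), len(b)
    # rows over a, columns over b; python loops are fine at CDR scale
    prev_s = list(range(0, -(m + 1), -1))
    prev_m = [0] * (m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur_s = [-i] + [0] * m
        cur_m = [0] * (m + 1)
        for j in range(1, m + 1):
            match = 1 if ai == b[j - 1] else 0
            s_diag = prev_s[j - 1] + match
            m_diag = prev_m[j - 1] + match
            s_up = prev_s[j] - 1
            s_left = cur_s[j - 1] - 1
            best = s_diag
            best_m = m_diag
            if s_up > best:
                best, best_m = s_up, prev_m[j]
            elif s_up == best and prev_m[j] > best_m:
                best_m = prev_m[j]
            if s_left > best:
                best, best_m = s_left, cur_m[j - 1]
            elif s_left == best and cur_m[j - 1] > best_m:
                best_m = cur_m[j - 1]
            cur_s[j] = best
            cur_m[j] = best_m
        prev_s, prev_m = cur_s, cur_m
    return prev_m[m]


def pairwise_identity(a: str, b: str) -> float:
    """Fractional CDR3 identity in [0, 1]; 1.0 iff the strings are equal."""
    if not a or not b:
        raise ClusteringError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    return _alignment_matches(a, b) / max(len(a), len(b))


def _identity_at_least(a: str, b: str, threshold: float) -> bool:
    """pairwise_identity(a, b) >= threshold, with cheap pre-filters.

    The ungapped match count is a lower bound on the alignment match count,
    and the residue-composition intersection is an upper bound; both avoid
    the DP for most clearly-inside / clearly-outside pairs.
    """
    longer = max(len(a), len(b))
    need = threshold * longer - 1e-12
    if len(a) == len(b):
        hamming_matches = sum(x == y for x, y in zip(a, b))
        if hamming_matches >= need:
            return True
    inter = sum((Counter(a) & Counter(b)).values())
    if inter < need:
        return False
    return _alignment_matches(a, b) >= need


@dataclass
class Cluster:
    cluster_id: int
    centroid_cdr3: str
    member_ids: list[str] = field(default_factory=list)
    per_round_counts: dict[int, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def count(self, round_index: int) -> int:
        return self.per_round_counts.get(round_index, 0)


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    threshold: float

    def assignment(self) -> dict[str, int]:
        """seq_id -> cluster_id map."""
        return {
            sid: cl.cluster_id for cl in self.clusters for sid in cl.member_ids
        }

    def __len__(self) -> int:
        return len(self.clusters)

    def by_id(self, cluster_id: int) -> Cluster:
        for cl in self.clusters:
            if cl.cluster_id == cluster_id:
                return cl
        raise KeyError(cluster_id)


def cluster_by_cdr3(
    sequences: Sequence[AnnotatedVHH],
    threshold: float = 0.5,
) -> ClusterTable:
    """Partition sequences into CDR3-identity clusters (default 50%)."""
    if not sequences:
        raise ClusteringError("cannot cluster an empty collection")
    if not 0.0 < threshold <= 1.0:
        raise ClusteringError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(
        sequences, key=lambda s: (-s.total_count(), s.cdr3, s.seq_id)
    )
    clusters: list[Cluster] = []
    cache: dict[tuple[str, str], bool] = {}
    for seq in order:
        home = None
        for cl in clusters:
            key = (seq.cdr3, cl.centroid_cdr3)
            hit = cache.get(key)
            if hit is None:
                hit = _identity_at_least(seq.cdr3, cl.centroid_cdr3, threshold)
                cache[key] = hit
            if hit:
                home = cl
                break
        if home is None:
            home = Cluster(cluster_id=len(clusters) + 1, centroid_cdr3=seq.cdr3)
            clusters.append(home)
        home.member_ids.append(seq.seq_id)
        for r, c in seq.counts.items():
            home.per_round_counts[r] = home.per_round_counts.get(r, 0) + c
    return ClusterTable(clusters=clusters, threshold=threshold)


def distance_matrix(cdr3s: Sequence[str], ids: Sequence[str] | None = None):
    """Symmetric pairwise distance matrix (1 - identity) over CDR3 strings.

    The export format consumed by external embedding/visualization tools
    (UMAP and the like); rendering is out of scope here.
    """
    import pandas as pd

    ids = list(ids) if ids is not None else [str(i) for i in range(len(cdr3s))]
    n = len(cdr3s)
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(cdr3s[i], cdr3s[j])
            mat[i][j] = mat[j][i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def partition_deviations(
    assignment: dict[str, int],
    reference: dict[str, int],
) -> list[str]:
    """Ids whose reference group is split or merged relative to ``assignment``.

    Returns, for every reference group, the members outside that group's
    majority cluster (and ids co-clustered with a different reference
    group's majority).  Empty list means the partitions agree.
    """
    deviants: list[str] = []
    groups: dict[int, list[str]] = {}
    for sid, g in reference.items():
        groups.setdefault(g, []).append(sid)
    majority: dict[int, int] = {}
    for g, members in groups.items():
        votes = Counter(assignment[sid] for sid in members)
        majority[g] = votes.most_common(1)[0][0]
    if len(set(majority.values())) < len(majority):
        # two reference groups merged: every member of the smaller is deviant
        seen: dict[int, int] = {}
        for g in sorted(majority, key=lambda g: -len(groups[g])):
            cl = majority[g]
            if cl in seen:
                deviants.extend(groups[g])
            else:
                seen[cl] = g
    for g, members in groups.items():
        for sid in members:
            if assignment[sid] != majority[g] and sid not in deviants:
                deviants.append(sid)
    return sorted(deviants)
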