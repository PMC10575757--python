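"""Candidate nomination: pick <= N sequences per cluster for synthesis.

The nomination rules operationalize a hit-triaging strategy over an
NLL-ranked, developability-profiled candidate pool:

1. take the best-NLL sequences passing all hard descriptor cutoffs until a
   minimum quota from the top-ranked window (default 3 from the top 100) is
   met;
2. optionally add the passing sequences nearest each tercile boundary of
   the pool's NLL range, so the synthesized set spans the score range for
   later score-vs-affinity correlation;
3. add passing sequences to cover empty isoelectric-point bins (pI
   diversity de-risks formulation-dependent behavior);
4. if every chosen sequence carries some liability category (moderate/low
   severity), add a passing variant lacking it, mirroring the practice of
   synthesizing liability-free backups;
5. ensure both sequence origins (NGS-observed and model-sampled) are
   represented, swapping in the best passing sequence of a missing origin
   if necessary.

The priority order is fixed to make the selection a deterministic function
of the input; every inclusion carries rationale tags and every exclusion a
reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .developability import DevelopabilityProfile
from .generative import ScoredSequence


class SelectionError(ValueError):
    pass


@dataclass
class SelectionConfig:
    max_per_cluster: int = 10
    min_from_top100: int = 3
    top_rank_window: int = 100
    nll_spread: bool = True
    descriptor_cutoffs: dict[str, float] = field(default_factory=dict)
    pi_bins: tuple[float, ...] = (6.5, 7.5, 8.5)
    require_liability_free_variant: bool = True
    require_both_sources: bool = True

    def __post_init__(self) -> None:
        if self.max_per_cluster < self.min_from_top100:
            raise SelectionError("max_per_cluster must be >= min_from_top100")


@dataclass
class SelectionReport:
    chosen: list[ScoredSequence]
    rationale: dict[tuple[str, str, str], list[str]]
    exclusions: list[tuple[ScoredSequence, str]]

    def tags(self, seq: ScoredSequence) -> list[str]:
        return self.rationale.get(seq.triplet, [])


def _pi_bin(pi: float, boundaries: Sequence[float]) -> int:
    return sum(pi > b for b in boundaries)


def select_candidates(
    ranked: Sequence[tuple[ScoredSequence, DevelopabilityProfile]],
    config: SelectionConfig | None = None,
) -> SelectionReport:
    """Nominate candidates from an NLL-ascending ranked, profiled pool."""
    config = config or SelectionConfig()
    if any(
        ranked[i][0].nll > ranked[i + 1][0].nll for i in range(len(ranked) - 1)
    ):
        raise SelectionError("input must be sorted ascending by NLL")

    exclusions: list[tuple[ScoredSequence, str]] = []
    passing: list[tuple[int, ScoredSequence, DevelopabilityProfile]] = []
    for rank0, (seq, prof) in enumerate(ranked):
        failed = None
        for name, cutoff in config.descriptor_cutoffs.items():
            if prof.descriptor(name) > cutoff:
                failed = name
                break
        if failed is not None:
            exclusions.append((seq, f"descriptor_cutoff:{failed}"))
        else:
            passing.append((rank0 + 1, seq, prof))
    report = SelectionReport(chosen=[], rationale={}, exclusions=exclusions)
    if not passing:
        return report

    chosen_keys: set[tuple[str, str, str]] = set()

    def add(seq: ScoredSequence, tag: str) -> bool:
        if len(report.chosen) >= config.max_per_cluster:
            return False
        if seq.triplet in chosen_keys:
            if tag not in report.rationale[seq.triplet]:
                report.rationale[seq.triplet].append(tag)
            return False
        report.chosen.append(seq)
        report.rationale[seq.triplet] = [tag]
        chosen_keys.add(seq.triplet)
        return True

    # 1. best-NLL quota from the top-ranked window
    quota = 0
    for rank, seq, prof in passing:
        if rank > config.top_rank_window or quota >= config.min_from_top100:
            break
        if add(seq, "top_nll"):
            quota += 1

    # 2. span the NLL range: nearest passing sequence to each tercile boundary
    if config.nll_spread and len(ranked) > 1:
        lo, hi = ranked[0][0].nll, ranked[-1][0].nll
        for boundary in (lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3):
            best = min(passing, key=lambda item: abs(item[1].nll - boundary))
            add(best[1], "nll_spread")

    # 3. cover empty pI bins
    covered = {
        _pi_bin(prof.pI, config.pi_bins)
        for _, seq, prof in passing
        if seq.triplet in chosen_keys
    }
    for _, seq, prof in passing:
        if len(report.chosen) >= config.max_per_cluster:
            break
        b = _pi_bin(prof.pI, config.pi_bins)
        if b not in covered:
            if add(seq, "pi_diversity"):
                covered.add(b)

    # 4. liability-free backup per category carried by every chosen sequence
    if config.require_liability_free_variant:
        prof_of = {seq.triplet: prof for _, seq, prof in passing}
        chosen_profs = [prof_of[s.triplet] for s in report.chosen]
        flagged = {
            f.category
            for p in chosen_profs
            for f in p.flags
            if f.severity in ("moderate", "low")
        }
        for category in sorted(flagged):
            if any(category not in p.flag_categories() for p in chosen_profs):
                continue
            for _, seq, prof in passing:
                if category not in prof.flag_categories():
                    add(seq, "liability_free_variant")
                    break

    # 5. represent both sequence origins
    if config.require_both_sources:
        sources = {s.source for s in report.chosen}
        available = {seq.source for _, seq, _ in passing}
        missing = available - sources
        for source in sorted(missing):
            candidate = next(
                (seq for _, seq, _ in passing if seq.source == source), None
            )
            if candidate is None:
                continue
            if not add(candidate, "source_balance"):
                # full: swap out the worst-NLL chosen sequence that is not
                # needed for the top-window quota
                top_members = [
                    s
                    for s in report.chosen
                    if "top_nll" in report.rationale[s.triplet]
                ]
                removable = sorted(
                    (
                        s
                        for s in report.chosen
                        if s.source != source
                        and (
                            "top_nll" not in report.rationale[s.triplet]
                            or len(top_members) > config.min_from_top100
                        )
                    ),
                    key=lambda s: -s.nll,
                )
                if removable:
                    out = removable[0]
                    report.chosen.remove(out)
                    chosen_keys.discard(out.triplet)
                    del report.rationale[out.triplet]
                    exclusions.append((out, f"swapped_for_source:{source}"))
                    add(candidate, "source_balance")

    report.chosen.sort(key=lambda s: (s.nll, s.triplet))
    return report
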