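"""Developability triage and candidate nomination on published sequences.

Profiles the bundled anti-NKp46 candidates (liability motifs, pI, windowed
hydropathy, CDR positive charge), derives traffic-light reference bands
from the pool itself, and applies the nomination rules (top-NLL quota, NLL
spread, pI diversity, liability-free backups, both origins) to pick <= 10
sequences for one CDR3 family.
"""

from vhhmine import campaign
from vhhmine.developability import ReferenceStats, assess
from vhhmine.generative import ScoredSequence
from vhhmine.selection import SelectionConfig, select_candidates

df = campaign.candidate_sequences()
group = df[df.cluster_group == 1].sort_values("nll")

pairs = []
for row in group.itertuples():
    seq = ScoredSequence(
        cdr1=row.cdr1, cdr2=row.cdr2, cdr3=row.cdr3,
        nll=float(row.nll), source=row.source,
    )
    vhh = campaign.candidates_as_vhh()[row.Index]
    pairs.append((seq, assess(vhh)))

print("candidate profiles (CDR3 family 1):")
print("  nll   source   pI    hydro  charge  flags")
for seq, prof in pairs:
    worst = prof.max_severity() or "-"
    print(
        f"  {seq.nll:4.1f}  {seq.source:7s} {prof.pI:5.2f}  {prof.cdr_hydropathy:5.2f}"
        f"  {prof.cdr_positive_charge:5.1f}  worst={worst}"
    )

ref = ReferenceStats.from_values(
    {
        "cdr_hydropathy": [p.cdr_hydropathy for _, p in pairs],
        "cdr_positive_charge": [p.cdr_positive_charge for _, p in pairs],
    }
)
cutoffs = {k: m + s for k, (m, s) in ref.stats.items()}
report = select_candidates(
    pairs, SelectionConfig(descriptor_cutoffs=cutoffs, min_from_top100=3)
)
print(f"\nnominated {len(report.chosen)} (cutoffs = pool mean + 1 SD):")
for s in report.chosen:
    print(f"  {s.nll:4.1f}  {s.source:7s}  {'|'.join(report.tags(s))}")
print(f"excluded: {[(s.cdr3, r) for s, r in report.exclusions]}")
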