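"""Sequence-level developability triage for VHH candidates.

Descriptors computed per sequence:

* chemical liability / PTM motif flags in the CDRs (Asn deamidation, Asp
  isomerization, Met oxidation, unpaired Cys, N-X-S/T glycosylation
  sequons), tiered by motif susceptibility;
* isoelectric point (Henderson-Hasselbalch net charge, bisection);
* CDR hydropathy: the maximum sliding-window mean under a published residue
  scale (Kyte-Doolittle by default) — a sequence-level stand-in for
  structure-based aggregation scores, preserving their filtering role;
* CDR positive charge: count of Arg + Lys (+0.1 per His) across the CDRs;
* optional framework human-likeness versus a germline sequence.

Descriptors can be traffic-lit against a user-supplied reference set:
green within mean + 1 SD, yellow within mean + 2 SD, red above (for
descriptors where low is good; directions are declared per descriptor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .repertoire import AnnotatedVHH, validate_cdr

CDR_REGIONS = ("cdr1", "cdr2", "cdr3")

#: motif susceptibility tiers; all tables overridable per call
HIGH_DEAMIDATION = frozenset({"NG"})
MODERATE_DEAMIDATION = frozenset({"NS", "NT", "NN", "ND", "NH"})
HIGH_ISOMERIZATION = frozenset({"DG"})
MODERATE_ISOMERIZATION = frozenset({"DS", "DT", "DD"})

#: traffic-light direction: True = lower is better (lit); absent = no light
LIGHT_DESCRIPTORS: dict[str, bool] = {
    "cdr_hydropathy": True,
    "cdr_positive_charge": True,
}


class DevelopabilityError(ValueError):
    pass


def _load_json(name: str) -> dict:
    with resources.as_file(resources.files("vhhmine.data").joinpath(name)) as p:
        return json.loads(p.read_text())


def default_pka_table() -> dict:
    return _load_json("pka_emboss.json")


def default_hydropathy_scale() -> dict[str, float]:
    scale = _load_json("hydropathy_kd.json")
    scale.pop("comment", None)
    return scale


@dataclass(frozen=True)
class LiabilityFlag:
    region: str  # cdr1 | cdr2 | cdr3 | framework
    position: int  # 1-based within region
    motif: str
    category: str  # deamidation | isomerization | oxidation | glycosylation_sequon | unpaired_cysteine
    severity: str  # high | moderate | low

    def __str__(self) -> str:
        return f"{self.region}:{self.position}:{self.motif}:{self.category}:{self.severity}"


def _scan_region(region_name: str, seq: str) -> list[LiabilityFlag]:
    flags: list[LiabilityFlag] = []
    n = len(seq)
    for i, aa in enumerate(seq):
        pos = i + 1
        if aa == "N":
            dipep = seq[i : i + 2]
            if dipep in HIGH_DEAMIDATION:
                sev = "high"
            elif dipep in MODERATE_DEAMIDATION:
                sev = "moderate"
            else:
                sev = "low"
            flags.append(LiabilityFlag(region_name, pos, dipep, "deamidation", sev))
            # N-X-S/T sequon with X != P
            if i + 2 < n and seq[i + 1] != "P" and seq[i + 2] in "ST":
                flags.append(
                    LiabilityFlag(
                        region_name, pos, seq[i : i + 3], "glycosylation_sequon", "high"
                    )
                )
        elif aa == "D":
            dipep = seq[i : i + 2]
            if dipep in HIGH_ISOMERIZATION:
                sev = "high"
            elif dipep in MODERATE_ISOMERIZATION:
                sev = "moderate"
            else:
                sev = "low"
            flags.append(LiabilityFlag(region_name, pos, dipep, "isomerization", sev))
        elif aa == "M":
            flags.append(LiabilityFlag(region_name, pos, "M", "oxidation", "high"))
        elif aa == "C":
            flags.append(
                LiabilityFlag(region_name, pos, "C", "unpaired_cysteine", "high")
            )
    return flags


def detect_liabilities(cdr1: str, cdr2: str, cdr3: str) -> list[LiabilityFlag]:
    """Flag chemically labile residues and PTM motifs in the three CDRs.

    Every CDR Asn/Asp/Met/Cys is flagged; the motif context (the following
    residue, or the N-X-S/T window for sequons) sets the severity tier, so
    weak motifs are still visible rather than silently ignored.
    """
    flags: list[LiabilityFlag] = []
    for name, seq in zip(CDR_REGIONS, (cdr1, cdr2, cdr3)):
        validate_cdr(seq, name)
        flags.extend(_scan_region(name, seq))
    return flags


def net_charge(sequence: str, ph: float, pka_table: Mapping | None = None) -> float:
    """Henderson-Hasselbalch net formal charge at the given pH."""
    pka = pka_table or default_pka_table()
    pos = 1.0 / (1.0 + 10 ** (ph - pka["n_terminus"]))
    neg = -1.0 / (1.0 + 10 ** (pka["c_terminus"] - ph))
    for aa in sequence:
        if aa in pka["basic"]:
            pos += 1.0 / (1.0 + 10 ** (ph - pka["basic"][aa]))
        elif aa in pka["acidic"]:
            neg -= 1.0 / (1.0 + 10 ** (pka["acidic"][aa] - ph))
    return pos + neg


def isoelectric_point(
    sequence: str, pka_table: Mapping | None = None, tol: float = 1e-4
) -> float:
    """pH of zero net charge, by bisection on [0, 14]."""
    validate_cdr(sequence, "sequence")
    pka = pka_table or default_pka_table()
    lo, hi = 0.0, 14.0
    # net charge is strictly decreasing in pH
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def cdr_hydropathy(
    cdr1: str,
    cdr2: str,
    cdr3: str,
    window: int = 5,
    scale: Mapping[str, float] | None = None,
) -> float:
    """Maximum sliding-window mean hydropathy across the three CDRs.

    Windows never span CDR boundaries; a CDR shorter than the window
    contributes its full-length mean.  Higher values mean a more
    hydrophobic (aggregation-prone) patch.
    """
    if window < 1:
        raise DevelopabilityError("window must be >= 1")
    kd = scale or default_hydropathy_scale()
    best = float("-inf")
    for seq in (cdr1, cdr2, cdr3):
        if not seq:
            continue
        validate_cdr(seq)
        vals = [kd[aa] for aa in seq]
        if len(vals) <= window:
            best = max(best, sum(vals) / len(vals))
        else:
            for i in range(len(vals) - window + 1):
                best = max(best, sum(vals[i : i + window]) / window)
    if best == float("-inf"):
        raise DevelopabilityError("all CDRs empty")
    return best


def cdr_positive_charge(cdr1: str, cdr2: str, cdr3: str) -> float:
    """Positive-charge burden of the CDRs: #R + #K + 0.1 * #H."""
    combined = cdr1 + cdr2 + cdr3
    validate_cdr(combined)
    return (
        combined.count("R") + combined.count("K") + 0.1 * combined.count("H")
    )


def framework_identity(framework: str, germline: str) -> float:
    """Percent identical positions over the global alignment length.

    Same alignment scheme as the clustering identity (match 1 / mismatch 0 /
    gap -1) but normalized by alignment columns, the convention used for
    human-likeness percentages.
    """
    if not framework or not germline:
        raise DevelopabilityError("framework_identity requires non-empty sequences")
    _, matches, pairs = _alignment_stats(framework, germline)
    columns = len(framework) + len(germline) - pairs
    return 100.0 * matches / columns


def _alignment_stats(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, aligned residue pairs) of the optimal global alignment,
    maximizing matches then aligned pairs among score-co-optimal alignments."""
    n, m = len(a), len(b)
    prev = [(-j, 0, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(-i, 0, 0)] + [(0, 0, 0)] * m
        for j in range(1, m + 1):
            match = 1 if a[i - 1] == b[j - 1] else 0
            cur[j] = max(
                (prev[j - 1][0] + match, prev[j - 1][1] + match, prev[j - 1][2] + 1),
                (prev[j][0] - 1, prev[j][1], prev[j][2]),
                (cur[j - 1][0] - 1, cur[j - 1][1], cur[j - 1][2]),
            )
        prev = cur
    return prev[m]


@dataclass
class ReferenceStats:
    """Per-descriptor mean and SD over a reference antibody set."""

    stats: dict[str, tuple[float, float]]  # descriptor -> (mean, sd)

    def __post_init__(self) -> None:
        for name, (mean, sd) in self.stats.items():
            if sd <= 0:
                raise DevelopabilityError(f"reference SD for {name} must be > 0")

    @classmethod
    def from_values(cls, values: Mapping[str, Sequence[float]]) -> "ReferenceStats":
        import statistics

        return cls(
            {
                k: (statistics.fmean(v), statistics.stdev(v))
                for k, v in values.items()
                if len(v) >= 2
            }
        )

    @classmethod
    def from_csv(cls, path) -> "ReferenceStats":
        import csv as _csv

        with open(path, newline="") as fh:
            rows = list(_csv.DictReader(fh))
        return cls(
            {r["descriptor"]: (float(r["mean"]), float(r["sd"])) for r in rows}
        )

    def light(self, descriptor: str, value: float) -> str | None:
        if descriptor not in self.stats or descriptor not in LIGHT_DESCRIPTORS:
            return None
        mean, sd = self.stats[descriptor]
        z = (value - mean) / sd if LIGHT_DESCRIPTORS[descriptor] else (mean - value) / sd
        if z <= 1.0:
            return "green"
        if z <= 2.0:
            return "yellow"
        return "red"


@dataclass
class DevelopabilityProfile:
    seq_id: str
    pI: float
    cdr_hydropathy: float
    cdr_positive_charge: float
    framework_identity_pct: float | None
    flags: list[LiabilityFlag] = field(default_factory=list)
    lights: dict[str, str] = field(default_factory=dict)

    def descriptor(self, name: str) -> float:
        return getattr(self, name if name != "pi" else "pI")

    def max_severity(self) -> str | None:
        order = {"low": 0, "moderate": 1, "high": 2}
        if not self.flags:
            return None
        return max(self.flags, key=lambda f: order[f.severity]).severity

    def flag_categories(self) -> set[str]:
        return {f.category for f in self.flags}

    def flags_joined(self) -> str:
        return ";".join(str(f) for f in self.flags)


def assess(
    sequence: AnnotatedVHH,
    reference: ReferenceStats | None = None,
    germline: str | None = None,
    framework: str | None = None,
    hydropathy_window: int = 5,
) -> DevelopabilityProfile:
    """Full sequence-level developability profile for one candidate.

    pI is computed on the concatenated CDRs (plus the framework when
    provided) and reported as an informational diversity axis — it carries
    no traffic light.  Missing reference stats simply omit the lights.
    """
    cdr1, cdr2, cdr3 = sequence.triplet
    pi_seq = (framework or "") + cdr1 + cdr2 + cdr3
    profile = DevelopabilityProfile(
        seq_id=sequence.seq_id,
        pI=isoelectric_point(pi_seq),
        cdr_hydropathy=cdr_hydropathy(cdr1, cdr2, cdr3, window=hydropathy_window),
        cdr_positive_charge=cdr_positive_charge(cdr1, cdr2, cdr3),
        framework_identity_pct=(
            framework_identity(framework, germline) if framework and germline else None
        ),
        flags=detect_liabilities(cdr1, cdr2, cdr3),
    )
    if reference is not None:
        for name in LIGHT_DESCRIPTORS:
            light = reference.light(name, profile.descriptor(name))
            if light is not None:
                profile.lights[name] = light
    return profile
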