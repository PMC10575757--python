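"""One-command orchestration: cluster -> enrich -> train -> sample -> score
-> develop -> select, with a manifest for reproducibility.

A run consumes either a repertoire table or a simulation block, progresses
the union of the top-k most frequent and top-k most enriched CDR3 clusters
(deduplicated), trains one generative model per progressed cluster, samples
and scores new CDR combinations, profiles developability and nominates
candidates.  All stage outputs land in one run directory; the manifest
records parameters, seeds and output checksums, and completed stages are
skipped on resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .clustering import ClusterTable, cluster_by_cdr3
from .developability import ReferenceStats, assess
from .enrichment import rank_clusters
from .generative import (
    GenerativeConfig,
    rank_pool,
    sample_sequences,
    save_model,
    train_generative_model,
)
from .repertoire import AnnotatedVHH, read_repertoire, write_repertoire
from .selection import SelectionConfig, select_candidates
from .simulate import default_config, simulate_repertoire

log = logging.getLogger("vhhmine.pipeline")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    input_table: str | None = None
    simulate: dict[str, Any] | None = None
    threshold: float = 0.5
    sel_round: int = 2
    base_round: int = 0
    top_k_frequency: int = 5
    top_k_enrichment: int = 5
    min_cluster_unique: int = 25  # clusters smaller than this are not modeled
    generative: dict[str, Any] = field(default_factory=dict)
    sample_n: int | None = None
    selection: dict[str, Any] = field(default_factory=dict)
    resume: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def generative_config(self, cluster_seed: int) -> GenerativeConfig:
        return GenerativeConfig(**{**self.generative, "seed": cluster_seed})

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(**self.selection)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, manifest: dict) -> None:
    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def done(stage: str, *files: str) -> bool:
        return config.resume and all((outdir / f).exists() for f in files)

    try:
        # ---- input -------------------------------------------------------
        rep_path = outdir / "repertoire.csv"
        if config.input_table:
            sequences, rounds = read_repertoire(config.input_table)
            write_repertoire(rep_path, sequences)
        elif done("input", "repertoire.csv"):
            sequences, rounds = read_repertoire(rep_path)
        else:
            sim_cfg = default_config(
                **{**(config.simulate or {}), "seed": config.seed}
            )
            sequences, truth = simulate_repertoire(sim_cfg)
            write_repertoire(rep_path, sequences)
            pd.DataFrame(
                {
                    "seq_id": list(truth.cluster_of),
                    "true_cluster": list(truth.cluster_of.values()),
                    "fitness": [truth.fitness_of[s] for s in truth.cluster_of],
                }
            ).to_csv(outdir / "ground_truth.csv", index=False)
        manifest["stages"]["input"] = "ok"
        log.info("input: %d unique sequences", len(sequences))

        # ---- cluster -----------------------------------------------------
        table = cluster_by_cdr3(sequences, threshold=config.threshold)
        assignment = table.assignment()
        pd.DataFrame(
            {"seq_id": list(assignment), "cluster_id": list(assignment.values())}
        ).to_csv(outdir / "assignments.csv", index=False)
        rounds_present = sorted({r for s in sequences for r in s.counts})
        pd.DataFrame(
            [
                {
                    "cluster_id": cl.cluster_id,
                    "centroid_cdr3": cl.centroid_cdr3,
                    "n_members": cl.size,
                    **{f"count_r{r}": cl.count(r) for r in rounds_present},
                }
                for cl in table.clusters
            ]
        ).to_csv(outdir / "clusters.csv", index=False)
        manifest["stages"]["cluster"] = f"{len(table)} clusters"

        # ---- enrich + cluster shortlist -----------------------------------
        by_ef = rank_clusters(
            table, "enrichment", config.sel_round, config.base_round
        )
        by_freq = rank_clusters(table, "frequency", config.sel_round)
        pd.DataFrame(
            [
                {
                    "cluster_id": r.cluster_id,
                    "n_base": r.n_base,
                    "n_sel": r.n_sel,
                    "ef": r.ef,
                    "ef_rounded": r.ef_rounded,
                }
                for r in by_ef
            ]
        ).to_csv(outdir / "enrichment.csv", index=False)
        shortlist: list[int] = []
        for rec in by_freq[: config.top_k_frequency]:
            shortlist.append(rec.cluster_id)
        for rec in by_ef[: config.top_k_enrichment]:
            if rec.cluster_id not in shortlist:
                shortlist.append(rec.cluster_id)
        members_of = {
            cl.cluster_id: [s for s in sequences if assignment[s.seq_id] == cl.cluster_id]
            for cl in table.clusters
        }
        shortlist = [
            cid for cid in shortlist if len(members_of[cid]) >= config.min_cluster_unique
        ]
        manifest["stages"]["enrich"] = {"shortlist": shortlist}
        log.info("shortlisted clusters: %s", shortlist)

        # ---- per-cluster generative design --------------------------------
        selections = {}
        for cid in shortlist:
            members = members_of[cid]
            gcfg = config.generative_config(cluster_seed=config.seed * 1000 + cid)
            model = train_generative_model(members, gcfg, round_index=config.sel_round)
            save_model(model, outdir / f"model_c{cid}.npz")
            n = config.sample_n if config.sample_n is not None else gcfg.sample_n
            sampled, shortfall = sample_sequences(model, n=n)
            if shortfall:
                log.warning("cluster %d: %d samples rejected", cid, shortfall)
            ranked = rank_pool(members, sampled, model)
            pd.DataFrame(
                [
                    {
                        "cdr1": s.cdr1,
                        "cdr2": s.cdr2,
                        "cdr3": s.cdr3,
                        "nll": s.nll,
                        "source": s.source,
                    }
                    for s in ranked
                ]
            ).to_csv(outdir / f"ranked_c{cid}.csv", index=False)

            profiles = [
                assess(
                    AnnotatedVHH(
                        seq_id=f"c{cid}_{i}",
                        cdr1=s.cdr1,
                        cdr2=s.cdr2,
                        cdr3=s.cdr3,
                        counts={},
                        source=s.source,
                    )
                )
                for i, s in enumerate(ranked)
            ]
            pool_ref = ReferenceStats.from_values(
                {
                    "cdr_hydropathy": [p.cdr_hydropathy for p in profiles],
                    "cdr_positive_charge": [p.cdr_positive_charge for p in profiles],
                }
            )
            pd.DataFrame(
                [
                    {
                        "cdr1": s.cdr1,
                        "cdr2": s.cdr2,
                        "cdr3": s.cdr3,
                        "nll": s.nll,
                        "source": s.source,
                        "pI": p.pI,
                        "cdr_hydropathy": p.cdr_hydropathy,
                        "cdr_positive_charge": p.cdr_positive_charge,
                        "flags": p.flags_joined(),
                    }
                    for s, p in zip(ranked, profiles)
                ]
            ).to_csv(outdir / f"developability_c{cid}.csv", index=False)

            scfg = config.selection_config()
            if not scfg.descriptor_cutoffs:
                scfg.descriptor_cutoffs = {
                    name: pool_ref.stats[name][0] + pool_ref.stats[name][1]
                    for name in ("cdr_hydropathy", "cdr_positive_charge")
                    if name in pool_ref.stats
                }
            report = select_candidates(list(zip(ranked, profiles)), scfg)
            selections[cid] = report
            pd.DataFrame(
                [
                    {
                        "cdr1": s.cdr1,
                        "cdr2": s.cdr2,
                        "cdr3": s.cdr3,
                        "nll": s.nll,
                        "source": s.source,
                        "rationale": "|".join(report.tags(s)),
                    }
                    for s in report.chosen
                ]
            ).to_csv(outdir / f"selection_c{cid}.csv", index=False)
            manifest["stages"][f"cluster_{cid}"] = {
                "selected_epoch": model.selected_epoch,
                "n_sampled": len(sampled),
                "n_chosen": len(report.chosen),
                "cutoffs": dict(scfg.descriptor_cutoffs),
            }
        manifest["status"] = "completed"
    except Exception as exc:  # record the failure point, skip downstream
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(outdir, manifest)
        raise
    _write_manifest(outdir, manifest)
    return manifest
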