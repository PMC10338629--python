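"""End-to-end pipeline: simulate/ingest -> preprocess -> DE -> networks ->
consensus -> modules, with a reproducible run report.

Every stage's thresholds and the master seed are recorded in the report;
rerunning with the same configuration and seed reproduces identical artifact
files (the report carries no wall-clock fields for exactly that reason).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .de import phase_partition, run_de
from .io import (
    read_json,
    read_matrix,
    read_pairs,
    read_samples,
    write_edges,
    write_graphml,
    write_json,
    write_matrix,
    write_pairs,
    write_samples,
)
from .modules import enrich_module, extract_modules, read_gmt
from .network import consensus, infer_network, trim_network
from .preprocess import preprocess_proteins
from .priors import PriorSet, build_clinical_prior, build_direct_prior, build_indirect_prior, build_ppi_prior
from .simulate import GroundTruth, MultiOmicDataset, SimulationConfig, generate_priors, simulate_timecourse

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_dataset", "load_dataset"]


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    With ``simulate=True`` the input dataset is generated from ``simulation``;
    otherwise matrices and priors are read from ``indir`` (transcript.tsv,
    protein_raw.tsv, clinical.tsv, samples.tsv, priors_map.tsv,
    priors_ppi.tsv).
    """

    outdir: str = "tolnet_run"
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    indir: str | None = None
    # preprocessing
    min_median_correlation: float = -1.0
    drop_flagged: bool = False
    # differential expression
    fdr: float = 0.05
    fc: float = 1.5
    fc_scale: str = "natural"
    transcript_phase_map: dict[int, str] | None = None
    protein_phase_map: dict[int, str] | None = None
    # network inference
    alpha: float = 0.5
    cv_folds: int = 5
    n_lambdas: int = 50
    lam_min_ratio: float = 0.01
    select_rule: str = "cv_min"
    r2_min: float = 0.1
    beta_min: float = 0.002
    consensus_mode: str = "eligible"
    # modules / enrichment / concordance
    module_radius: int = 1
    gmt_path: str | None = None
    enrich_fdr: float = 0.05
    ortholog_map_path: str | None = None
    external_de_paths: dict[str, str] = field(default_factory=dict)
    concordance_fdr: float = 0.1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("transcript_phase_map", "protein_phase_map"):
            if d.get(key):
                d[key] = {int(k): v for k, v in d[key].items()}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


def write_dataset(dataset: MultiOmicDataset, priors: PriorSet, truth: GroundTruth | None, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.transcript, outdir / "transcript.tsv", "gene_id")
    write_matrix(dataset.protein_raw, outdir / "protein_raw.tsv", "protein_id")
    write_matrix(dataset.clinical, outdir / "clinical.tsv", "variable")
    write_samples(dataset.sample_meta, outdir / "samples.tsv")
    write_pairs(priors.direct_map, outdir / "priors_map.tsv", ("gene_id", "protein_id"))
    write_pairs(priors.ppi, outdir / "priors_ppi.tsv", ("protein_a", "protein_b"))
    if truth is not None:
        write_json(truth.to_dict(), outdir / "truth.json")


def load_dataset(indir) -> tuple[MultiOmicDataset, PriorSet, GroundTruth | None]:
    indir = Path(indir)
    dataset = MultiOmicDataset(
        transcript=read_matrix(indir / "transcript.tsv"),
        protein_raw=read_matrix(indir / "protein_raw.tsv"),
        clinical=read_matrix(indir / "clinical.tsv"),
        sample_meta=read_samples(indir / "samples.tsv"),
    )
    dataset.validate()
    universe = set(dataset.transcript.index) | set(dataset.protein_raw.index) | set(
        dataset.clinical.index
    )
    direct, _ = build_direct_prior(read_pairs(indir / "priors_map.tsv"), universe)
    ppi, _ = build_ppi_prior(read_pairs(indir / "priors_ppi.tsv"), universe)
    priors = PriorSet(direct_map=direct, ppi=ppi, indirect_map=build_indirect_prior(direct, ppi))
    truth = None
    if (indir / "truth.json").exists():
        truth = GroundTruth.from_dict(read_json(indir / "truth.json"))
    return dataset, priors, truth


def _stage(report: dict, name: str, **counts) -> None:
    report["stages"][name] = counts
    logger.info("stage %s: %s", name, counts)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to disk).

    Any stage failure raises with the stage name prefixed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    report: dict = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "artifacts": [],
    }

    def emit(name: str):
        report["artifacts"].append(name)
        return outdir / name

    stage = "ingest"
    try:
        if config.simulate:
            sim = config.simulation
            sim.seed = config.seed
            dataset, truth = simulate_timecourse(sim)
            priors = generate_priors(sim, truth)
            write_dataset(dataset, priors, truth, outdir)
            report["artifacts"] += [
                "transcript.tsv", "protein_raw.tsv", "clinical.tsv", "samples.tsv",
                "priors_map.tsv", "priors_ppi.tsv", "truth.json",
            ]
        else:
            if not config.indir:
                raise ValueError("indir required when simulate=False")
            dataset, priors, truth = load_dataset(config.indir)
        _stage(report, stage,
               n_genes=len(dataset.transcript.index),
               n_proteins=len(dataset.protein_raw.index),
               n_clinical=len(dataset.clinical.index),
               n_samples=len(dataset.samples))

        stage = "preprocess"
        protein_norm, prep_report = preprocess_proteins(
            dataset.protein_raw,
            min_median_correlation=config.min_median_correlation,
            drop_flagged=config.drop_flagged,
        )
        write_matrix(protein_norm, emit("protein_norm.tsv"), "protein_id")
        write_json(prep_report, emit("preprocess_report.json"))
        _stage(report, stage, **{k: v for k, v in prep_report.items() if isinstance(v, int)},
               n_flagged=len(prep_report["flagged_samples"]))

        samples = [s for s in dataset.samples if s in protein_norm.columns]
        transcript = dataset.transcript[samples]
        clinical = dataset.clinical[samples]
        protein_norm = protein_norm[samples]
        meta = dataset.sample_meta[dataset.sample_meta["sample_id"].isin(samples)]

        stage = "de"
        phase_map = config.simulation.phase_map if config.simulate else None
        t_phase_map = config.transcript_phase_map or phase_map
        p_phase_map = config.protein_phase_map or phase_map
        if t_phase_map is None or p_phase_map is None:
            raise ValueError("phase maps are required when running from files")
        de_t, sets_t = run_de(transcript, meta, mode="transcript",
                              fdr=config.fdr, fc=config.fc, fc_scale=config.fc_scale)
        de_p, sets_p = run_de(protein_norm, meta, mode="protein", fdr=config.fdr)
        de_t.table.to_csv(emit("de_transcript.tsv"), sep="\t", index=False)
        de_p.table.to_csv(emit("de_protein.tsv"), sep="\t", index=False)
        phases_t = phase_partition(sets_t, t_phase_map)
        phases_p = phase_partition(sets_p, p_phase_map)
        write_json(
            {
                "transcript": {
                    "phase_sets": {k: sorted(v) for k, v in phases_t.phase_sets.items()},
                    "unique": {k: sorted(v) for k, v in phases_t.unique.items()},
                    "shared": sorted(phases_t.shared),
                    "venn": phases_t.venn_counts(),
                },
                "protein": {
                    "phase_sets": {k: sorted(v) for k, v in phases_p.phase_sets.items()},
                    "unique": {k: sorted(v) for k, v in phases_p.unique.items()},
                    "shared": sorted(phases_p.shared),
                    "venn": phases_p.venn_counts(),
                },
            },
            emit("phase_sets.json"),
        )
        _stage(report, stage,
               n_de_transcript=sum(len(s) for s in sets_t.values()),
               n_de_protein=sum(len(s) for s in sets_p.values()),
               n_tolerance_unique=len(phases_t.unique.get("tolerance", set()))
               + len(phases_p.unique.get("tolerance", set())))

        stage = "infer"
        matrices = {"transcript": transcript, "protein": protein_norm, "clinical": clinical}
        rng = np.random.SeedSequence(config.seed)
        net_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(3)]
        kw = dict(alpha=config.alpha, cv_folds=config.cv_folds, n_lambdas=config.n_lambdas,
                  lam_min_ratio=config.lam_min_ratio, select_rule=config.select_rule)
        net_t = infer_network(matrices, priors, "transcript", seed=net_seeds[0], **kw)
        net_p = infer_network(matrices, priors, "protein", seed=net_seeds[1], **kw)
        priors.clinical_candidates = build_clinical_prior(net_t, net_p, list(clinical.index))
        net_c = infer_network(matrices, priors, "clinical", seed=net_seeds[2], **kw)
        for net in (net_t, net_p, net_c):
            write_edges(net.sorted_edges(), emit(f"network_{net.center}.tsv"))
        _stage(report, stage, transcript_edges=net_t.n_edges, protein_edges=net_p.n_edges,
               clinical_edges=net_c.n_edges)

        stage = "trim"
        trimmed = [trim_network(n, config.r2_min, config.beta_min) for n in (net_t, net_p, net_c)]
        for net in trimmed:
            write_edges(net.sorted_edges(), emit(f"network_{net.center}_trimmed.tsv"))
        _stage(report, stage, **{f"{n.center}_edges": n.n_edges for n in trimmed},
               r2_min=config.r2_min, beta_min=config.beta_min)

        stage = "consensus"
        cons = consensus(trimmed, mode=config.consensus_mode)
        write_edges(cons.sorted_edges(), emit("consensus.tsv"))
        _stage(report, stage, edges=cons.n_edges, nodes=len(cons.nodes),
               mode=config.consensus_mode)

        stage = "modules"
        seeds = set(phases_t.unique.get("tolerance", set())) | set(
            phases_p.unique.get("tolerance", set())
        )
        if seeds:
            mods = extract_modules(cons, seeds, radius=config.module_radius)
        else:
            logger.warning("no tolerance-unique DE features; no modules extracted")
            from .modules import ModuleSet
            mods = ModuleSet(modules=[], singletons=set())
        module_of = {n: i for i, m in enumerate(mods.modules) for n in m.members}
        rows = []
        for i, m in enumerate(mods.modules):
            for node in sorted(m.members):
                rows.append((i, node, cons.nodes.get(node, "?"), m.betweenness.get(node, 0.0),
                             node in seeds))
        pd.DataFrame(rows, columns=["module", "node", "layer", "betweenness", "is_seed"]).to_csv(
            emit("modules.tsv"), sep="\t", index=False
        )
        write_graphml(cons, emit("modules.graphml"), module_of)
        _stage(report, stage, n_seeds=len(seeds), n_modules=mods.n_modules,
               n_module_nodes=mods.n_nodes, n_singletons=len(mods.singletons))

        stage = "enrich"
        if config.gmt_path:
            genesets = read_gmt(config.gmt_path)
            universe = set(transcript.index) | set(protein_norm.index)
            rows = []
            for i, m in enumerate(mods.modules):
                for r in enrich_module(m.members, genesets, universe, module_id=i,
                                       fdr_threshold=config.enrich_fdr):
                    rows.append((r.module_id, r.gene_set, r.overlap, r.set_size,
                                 r.module_size, r.p, r.fdr, r.significant))
            pd.DataFrame(rows, columns=["module", "gene_set", "overlap", "set_size",
                                        "module_size", "p", "fdr", "significant"]).to_csv(
                emit("enrichment.tsv"), sep="\t", index=False
            )
            _stage(report, stage, n_genesets=len(genesets),
                   n_significant=sum(r[-1] for r in rows))

        stage = "concordance"
        if config.ortholog_map_path and config.external_de_paths:
            from .modules import concordance as score_concordance

            omap = pd.read_csv(config.ortholog_map_path, sep="\t", dtype=str)
            mouse = (
                de_t.table.loc[de_t.table["fdr"] < config.fdr]
                .sort_values("fdr")
                .drop_duplicates("feature")[["feature", "log2fc"]]
            )
            frames = []
            for cohort, p in sorted(config.external_de_paths.items()):
                ext = pd.read_csv(p, sep="\t")
                tab = score_concordance(mouse, ext, omap, fdr=config.concordance_fdr)
                tab.insert(0, "cohort", cohort)
                frames.append(tab)
            conc = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            conc.to_csv(emit("concordance.tsv"), sep="\t", index=False)
            _stage(report, stage, n_cohorts=len(frames),
                   n_concordant=int(conc["concordant"].sum()) if len(conc) else 0)

        if truth is not None:
            report["truth_summary"] = {
                "n_true_edges": len(truth.true_edges),
                "n_module_members": len(truth.module_members),
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    write_json(report, outdir / "run_report.json")
    return report
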