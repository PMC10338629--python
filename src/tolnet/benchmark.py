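"""Planted-truth evaluation helpers: run the inference stack on simulated
data and score edge and module recovery against the generator's ground truth.

Scoring conventions:

* Edge recovery is measured on molecular (gene/protein) node pairs against
  the planted edges whose endpoints both survive into the analyzed matrices
  — an edge touching a protein removed by the complete-case filter is not
  recoverable by any method and is excluded from the reference; edges merely
  missing from the priors stay in it (prior incompleteness is part of the
  difficulty).  Clinical pairs are excluded: the generator's clinical ground
  truth is the weight table, not edge membership.
* Module recovery is the Jaccard index between the union of extracted module
  members and the planted tolerance module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import phase_partition, run_de
from .modules import ModuleSet, extract_modules
from .network import MultiOmicNetwork, consensus, infer_network, trim_network
from .preprocess import preprocess_proteins
from .priors import PriorSet, build_clinical_prior, _canon
from .simulate import GroundTruth, MultiOmicDataset, SimulationConfig, generate_priors, simulate_timecourse

__all__ = ["InferenceRun", "run_inference", "edge_recovery", "module_recovery"]


@dataclass
class InferenceRun:
    """Everything one simulated end-to-end inference produced."""

    dataset: MultiOmicDataset
    truth: GroundTruth
    priors: PriorSet
    matrices: dict[str, pd.DataFrame]
    networks: list[MultiOmicNetwork]
    trimmed: list[MultiOmicNetwork]
    consensus: MultiOmicNetwork
    phase_unique: dict[str, set[str]]

    def tolerance_seeds(self) -> set[str]:
        return set(self.phase_unique.get("tolerance", set()))


def run_inference(
    config: SimulationConfig,
    seed: int | None = None,
    r2_min: float = 0.1,
    beta_min: float = 0.002,
    consensus_mode: str = "eligible",
    select_rule: str = "cv_min",
    alpha: float = 0.5,
) -> InferenceRun:
    """Simulate one dataset and run preprocess -> DE -> networks -> consensus."""
    if seed is not None:
        config.seed = seed
    dataset, truth = simulate_timecourse(config)
    priors = generate_priors(config, truth)
    protein_norm, _ = preprocess_proteins(dataset.protein_raw)
    matrices = {
        "transcript": dataset.transcript,
        "protein": protein_norm,
        "clinical": dataset.clinical,
    }

    _, sets_t = run_de(dataset.transcript, dataset.sample_meta, mode="transcript")
    _, sets_p = run_de(protein_norm, dataset.sample_meta, mode="protein")
    phases_t = phase_partition(sets_t, config.phase_map)
    phases_p = phase_partition(sets_p, config.phase_map)
    phase_unique = {
        ph: phases_t.unique.get(ph, set()) | phases_p.unique.get(ph, set())
        for ph in set(phases_t.unique) | set(phases_p.unique)
    }

    ss = np.random.SeedSequence(config.seed)
    net_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    kw = dict(alpha=alpha, select_rule=select_rule)
    net_t = infer_network(matrices, priors, "transcript", seed=net_seeds[0], **kw)
    net_p = infer_network(matrices, priors, "protein", seed=net_seeds[1], **kw)
    priors.clinical_candidates = build_clinical_prior(net_t, net_p, list(dataset.clinical.index))
    net_c = infer_network(matrices, priors, "clinical", seed=net_seeds[2], **kw)
    nets = [net_t, net_p, net_c]
    trimmed = [trim_network(n, r2_min, beta_min) for n in nets]
    cons = consensus(trimmed, mode=consensus_mode)
    return InferenceRun(dataset, truth, priors, matrices, nets, trimmed, cons, phase_unique)


def _molecular_pairs(net: MultiOmicNetwork, layers: dict[str, str]) -> set[tuple[str, str]]:
    return {
        p
        for p in net.pairs()
        if layers.get(p[0]) in ("transcript", "protein")
        and layers.get(p[1]) in ("transcript", "protein")
    }


def edge_recovery(run: InferenceRun, net: MultiOmicNetwork | None = None) -> dict[str, float]:
    """Precision/recall/F1 of a network's molecular pairs vs measurable truth."""
    net = run.consensus if net is None else net
    measured = set(run.matrices["transcript"].index) | set(run.matrices["protein"].index)
    reference = {
        _canon(s, t)
        for s, t, _ in run.truth.true_edges
        if s in measured and t in measured
    }
    layers = {f: l for l, m in run.matrices.items() for f in m.index}
    got = _molecular_pairs(net, layers)
    tp = len(got & reference)
    precision = tp / len(got) if got else 0.0
    recall = tp / len(reference) if reference else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_called": len(got),
        "n_reference": len(reference),
    }


def module_recovery(run: InferenceRun, radius: int = 1) -> dict[str, float]:
    """Jaccard of extracted module members vs the planted tolerance module.

    Scored on molecular nodes (clinical variables legitimately join extracted
    modules but are not part of the planted member set) against the planted
    members that survived into the analyzed matrices.
    """
    seeds = run.tolerance_seeds()
    if not seeds:
        return {"jaccard": 0.0, "n_modules": 0, "n_nodes": 0}
    mods: ModuleSet = extract_modules(run.consensus, seeds, radius=radius)
    layers = {f: l for l, m in run.matrices.items() for f in m.index}
    got = {n for n in mods.all_members() if layers.get(n) in ("transcript", "protein")}
    measured = set(run.matrices["transcript"].index) | set(run.matrices["protein"].index)
    planted = run.truth.module_members & measured
    inter = len(got & planted)
    union = len(got | planted)
    return {
        "jaccard": inter / union if union else 0.0,
        "n_modules": mods.n_modules,
        "n_nodes": mods.n_nodes,
    }
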