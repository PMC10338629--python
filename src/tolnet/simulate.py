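"""Synthetic longitudinal multi-omic datasets with planted ground truth.

The generator emulates a repeated-injury time course: toxin-treated animals
sampled at several weeks (vehicle-treated controls at week zero and the final
week), a transcript layer, a TMT-style protein layer with a pooled reference
channel and intensity-dependent dropout, and a handful of clinical variables.

Planted structure, all recorded in :class:`GroundTruth`:

* phase-specific differentially expressed (DE) genes — a shared set active in
  every treated phase plus disjoint per-phase unique sets, among them the
  designated tolerance-unique set;
* a regulatory network of gene->protein (coding) and protein->protein edges;
  protein values propagate from their realized upstream sources, so the
  regression stage sees an exact linear data-generating model plus noise;
* a tolerance module: the tolerance-unique genes and their direct true-edge
  neighbors — every tolerance-unique gene is guaranteed a coding edge so the
  planted module is connected at the pair level;
* clinical variables as noisy weighted sums of module features.

Expression is simulated on the log2 scale; raw reporter intensities are the
exponentiated values, so the ratio/normalization stage downstream is exercised
for real.  One independent random stream per layer is split from the master
seed, so adding a layer never perturbs another layer's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .priors import PriorSet, build_indirect_prior, _canon

__all__ = ["SimulationConfig", "GroundTruth", "MultiOmicDataset", "simulate_timecourse", "generate_priors"]

PHASES = ("initiation", "progression", "tolerance")

_DEFAULT_PHASE_MAP = {
    0: "control",
    1: "initiation",
    2: "initiation",
    4: "progression",
    6: "progression",
    8: "tolerance",
    10: "tolerance",
}


@dataclass
class SimulationConfig:
    """Study-design and effect parameters of the simulated time course.

    Defaults describe the emulated design: weeks 0-10 with 2-3 animals per
    time point, ~100 genes, ~80 proteins, a few clinical variables, planted
    log2 effects of 2.0 against residual noise of 0.5.
    """

    n_genes: int = 100
    n_proteins: int = 80
    n_clinical: int = 6
    weeks: tuple[int, ...] = (0, 1, 2, 4, 6, 8, 10)
    reps_per_week: int = 3
    phase_map: dict[int, str] = field(default_factory=lambda: dict(_DEFAULT_PHASE_MAP))
    n_de_unique: dict[str, int] = field(
        default_factory=lambda: {"initiation": 8, "progression": 12, "tolerance": 10}
    )
    n_de_shared: int = 10
    effect_size: float = 2.0
    n_true_edges: int = 150
    frac_coding_edges: float = 0.6  # share of true edges that are gene->coding-protein
    prior_coverage: float = 0.9
    decoy_prior_edges: int = 50
    noise_sd: float = 0.5
    edge_weight: float = 0.8
    gene_baseline_mean: float = 7.0
    protein_baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    missingness_steepness: float = 1.5
    missingness_midpoint: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_proteins", "n_clinical", "reps_per_week"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_edges < 0:
            raise ValueError("n_true_edges must be nonnegative")
        if self.reps_per_week < 2:
            raise ValueError("reps_per_week must be >= 2 (variance estimation needs replicates)")
        missing = [w for w in self.weeks if w not in self.phase_map]
        if missing:
            raise ValueError(f"phase_map does not cover weeks {missing}")
        if not 0.0 <= self.prior_coverage <= 1.0:
            raise ValueError(f"prior_coverage must lie in [0, 1], got {self.prior_coverage}")
        if self.decoy_prior_edges < 0:
            raise ValueError("decoy_prior_edges must be nonnegative")
        n_planted = self.n_de_shared + sum(self.n_de_unique.get(p, 0) for p in PHASES)
        if n_planted > self.n_genes:
            raise ValueError("more planted DE genes than genes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weeks"] = list(self.weeks)
        d["phase_map"] = {int(k): v for k, v in self.phase_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "weeks" in d:
            d["weeks"] = tuple(int(w) for w in d["weeks"])
        if "phase_map" in d:
            d["phase_map"] = {int(k): v for k, v in d["phase_map"].items()}
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream recovery scoring."""

    true_edges: set[tuple[str, str, int]]  # (source, target, sign)
    de_sets_by_phase: dict[str, set[str]]
    tolerance_unique: set[str]
    module_members: set[str]
    de_signs: dict[str, int]
    clinical_weights: dict[str, dict[str, float]]

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Undirected canonical pairs of the planted edges."""
        return {_canon(s, t) for s, t, _ in self.true_edges}

    def to_dict(self) -> dict:
        return {
            "true_edges": sorted([list(e) for e in self.true_edges]),
            "de_sets_by_phase": {k: sorted(v) for k, v in self.de_sets_by_phase.items()},
            "tolerance_unique": sorted(self.tolerance_unique),
            "module_members": sorted(self.module_members),
            "de_signs": self.de_signs,
            "clinical_weights": self.clinical_weights,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_edges={(s, t, int(sg)) for s, t, sg in d["true_edges"]},
            de_sets_by_phase={k: set(v) for k, v in d["de_sets_by_phase"].items()},
            tolerance_unique=set(d["tolerance_unique"]),
            module_members=set(d["module_members"]),
            de_signs={k: int(v) for k, v in d["de_signs"].items()},
            clinical_weights={c: dict(w) for c, w in d["clinical_weights"].items()},
        )


@dataclass
class MultiOmicDataset:
    """Aligned transcript/protein/clinical matrices over one sample set.

    ``transcript`` is genes x samples on the log2 scale; ``protein_raw`` is
    proteins x samples of nonnegative reporter intensities (NaN = missing)
    plus a ``REF`` reference-channel column; ``clinical`` is variables x
    samples; ``sample_meta`` has one row per sample (sample_id, week,
    treatment).
    """

    transcript: pd.DataFrame
    protein_raw: pd.DataFrame
    clinical: pd.DataFrame
    sample_meta: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.sample_meta["sample_id"])

    def validate(self) -> None:
        samples = self.samples
        if list(self.transcript.columns) != samples:
            raise ValueError("transcript columns misaligned with sample metadata")
        if [c for c in self.protein_raw.columns if c != "REF"] != samples:
            raise ValueError("protein columns misaligned with sample metadata")
        if list(self.clinical.columns) != samples:
            raise ValueError("clinical columns misaligned with sample metadata")
        vals = self.protein_raw.to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise ValueError("reporter intensities must be nonnegative")


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    final = max(config.weeks)
    for w in config.weeks:
        if w == 0:
            for r in range(config.reps_per_week):
                rows.append((f"w{w:02d}_ctl_{r + 1}", w, "control"))
        else:
            for r in range(config.reps_per_week):
                rows.append((f"w{w:02d}_tox_{r + 1}", w, "toxic"))
    for r in range(config.reps_per_week):
        rows.append((f"w{final:02d}_ctl_{r + 1}", final, "control"))
    return pd.DataFrame(rows, columns=["sample_id", "week", "treatment"])


def _plant_de_sets(config: SimulationConfig, rng: np.random.Generator, genes: list[str]):
    """Shared-across-phases set plus disjoint per-phase unique sets."""
    counts = [config.n_de_shared] + [config.n_de_unique.get(p, 0) for p in PHASES]
    chosen = rng.choice(len(genes), size=sum(counts), replace=False)
    blocks, off = [], 0
    for c in counts:
        blocks.append({genes[i] for i in chosen[off : off + c]})
        off += c
    shared, uniq_i, uniq_p, uniq_t = blocks
    de_sets = {
        "initiation": shared | uniq_i,
        "progression": shared | uniq_p,
        "tolerance": shared | uniq_t,
    }
    return de_sets, uniq_t


def _plant_edges(
    config: SimulationConfig, rng: np.random.Generator, tol_unique: set[str]
) -> set[tuple[str, str, int]]:
    n_code = min(
        int(round(config.frac_coding_edges * config.n_true_edges)),
        min(config.n_genes, config.n_proteins),
    )
    n_ppi = config.n_true_edges - n_code
    max_ppi = config.n_proteins * (config.n_proteins - 1) // 2
    if n_ppi > max_ppi:
        raise ValueError("n_true_edges exceeds the available protein-pair capacity")

    # coding edges G_j -> P_j; tolerance-unique genes are wired first so the
    # planted module has guaranteed protein partners
    tol_idx = sorted(int(g[1:]) for g in tol_unique if int(g[1:]) < config.n_proteins)
    pool = [j for j in range(min(config.n_genes, config.n_proteins)) if j not in set(tol_idx)]
    extra = max(n_code - len(tol_idx), 0)
    rest = rng.choice(len(pool), size=min(extra, len(pool)), replace=False)
    code_idx = tol_idx + [pool[i] for i in rest]

    edges: set[tuple[str, str, int]] = set()
    for j in code_idx:
        sign = 1 if rng.random() < 0.5 else -1
        edges.add((f"G{j:03d}", f"P{j:03d}", sign))

    # protein->protein edges, lower index -> higher index (acyclic propagation)
    seen = set()
    while len(seen) < n_ppi:
        i, j = rng.integers(0, config.n_proteins, size=2)
        if i == j:
            continue
        a, b = (int(min(i, j)), int(max(i, j)))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        sign = 1 if rng.random() < 0.5 else -1
        edges.add((f"P{a:03d}", f"P{b:03d}", sign))
    return edges


def simulate_timecourse(config: SimulationConfig) -> tuple[MultiOmicDataset, GroundTruth]:
    """Draw one dataset + ground truth; bit-identical for identical configs."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_plan, rng_gene, rng_prot, rng_clin, rng_miss, _rng_prior = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    meta = _sample_frame(config)
    samples = list(meta["sample_id"])
    n_s = len(samples)
    genes = [f"G{i:03d}" for i in range(config.n_genes)]
    prots = [f"P{i:03d}" for i in range(config.n_proteins)]
    clins = [f"C{i}" for i in range(config.n_clinical)]

    de_sets, tol_unique = _plant_de_sets(config, rng_plan, genes)
    edges = _plant_edges(config, rng_plan, tol_unique)
    planted = sorted(set().union(*de_sets.values()))
    de_signs = {g: (1 if rng_plan.random() < 0.5 else -1) for g in planted}

    # --- transcript layer (log2) ---
    base_g = config.gene_baseline_mean + config.baseline_sd * rng_gene.standard_normal(config.n_genes)
    shift = np.zeros((config.n_genes, n_s))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for s_i, (w, trt) in enumerate(zip(meta["week"], meta["treatment"])):
        if trt != "toxic":
            continue
        phase = config.phase_map[int(w)]
        for g in de_sets.get(phase, ()):
            shift[gene_pos[g], s_i] = de_signs[g] * config.effect_size
    signal_g = base_g[:, None] + shift
    transcript = signal_g + config.noise_sd * rng_gene.standard_normal((config.n_genes, n_s))

    # --- protein layer: propagate realized upstream values through true edges ---
    base_p = config.protein_baseline_mean + config.baseline_sd * rng_prot.standard_normal(
        config.n_proteins
    )
    prot_pos = {p: i for i, p in enumerate(prots)}
    incoming: dict[str, list[tuple[str, int]]] = {p: [] for p in prots}
    for src, tgt, sign in edges:
        incoming[tgt].append((src, sign))
    noise_p = config.noise_sd * rng_prot.standard_normal((config.n_proteins, n_s))
    prot_log2 = np.zeros((config.n_proteins, n_s))
    prot_signal = np.zeros((config.n_proteins, n_s))  # noiseless, for the REF channel
    for j, p in enumerate(prots):  # index order respects edge direction (acyclic)
        contrib = np.zeros(n_s)
        contrib_signal = np.zeros(n_s)
        for src, sign in sorted(incoming[p]):
            w = sign * config.edge_weight
            if src.startswith("G"):
                gi = gene_pos[src]
                contrib += w * (transcript[gi] - base_g[gi])
                contrib_signal += w * (signal_g[gi] - base_g[gi])
            else:
                si = prot_pos[src]
                contrib += w * (prot_log2[si] - base_p[si])
                contrib_signal += w * (prot_signal[si] - base_p[si])
        prot_signal[j] = base_p[j] + contrib_signal
        prot_log2[j] = base_p[j] + contrib + noise_p[j]

    intensities = np.power(2.0, prot_log2)
    ref = np.power(2.0, prot_signal).mean(axis=1)  # noiseless pooled mean
    p_miss = 1.0 / (
        1.0 + np.exp(config.missingness_steepness * (prot_log2 - config.missingness_midpoint))
    )
    intensities = np.where(rng_miss.random(intensities.shape) < p_miss, np.nan, intensities)

    # --- planted tolerance module: tolerance-unique features + true-edge neighbors ---
    module = set(tol_unique)
    for src, tgt, _ in edges:
        if src in tol_unique:
            module.add(tgt)
        if tgt in tol_unique:
            module.add(src)

    # --- clinical layer: noisy weighted sums of module features ---
    feature_rows = {**{g: transcript[gene_pos[g]] for g in genes},
                    **{p: prot_log2[prot_pos[p]] for p in prots}}
    module_feats = sorted(module)
    clinical_weights: dict[str, dict[str, float]] = {}
    clin_mat = np.zeros((config.n_clinical, n_s))
    for k, c in enumerate(clins):
        n_avail = len(module_feats)
        if n_avail == 0:
            n_feat = 0
        else:
            lo, hi = min(3, n_avail), min(10, n_avail)
            n_feat = int(rng_clin.integers(lo, hi + 1))
        picks = rng_clin.choice(n_avail, size=n_feat, replace=False) if n_feat else []
        weights = {}
        val = np.zeros(n_s)
        for i in picks:
            f = module_feats[i]
            w = float(rng_clin.uniform(0.5, 1.0) * (1 if rng_clin.random() < 0.5 else -1))
            weights[f] = w
            row = feature_rows[f]
            val += w * (row - row.mean())
        clinical_weights[c] = weights
        clin_mat[k] = val + config.noise_sd * rng_clin.standard_normal(n_s)

    protein_raw = pd.DataFrame(intensities, index=prots, columns=samples)
    protein_raw["REF"] = ref
    dataset = MultiOmicDataset(
        transcript=pd.DataFrame(transcript, index=genes, columns=samples),
        protein_raw=protein_raw,
        clinical=pd.DataFrame(clin_mat, index=clins, columns=samples),
        sample_meta=meta,
    )
    dataset.validate()
    truth = GroundTruth(
        true_edges=edges,
        de_sets_by_phase=de_sets,
        tolerance_unique=tol_unique,
        module_members=module,
        de_signs=de_signs,
        clinical_weights=clinical_weights,
    )
    return dataset, truth


def generate_priors(config: SimulationConfig, truth: GroundTruth) -> PriorSet:
    """Prior tables covering a configured fraction of the planted edges.

    Keeps exactly ``round(prior_coverage * n_true)`` true edges (uniformly
    without replacement) and adds ``decoy_prior_edges`` candidate pairs with
    no planted effect, split evenly between the gene-protein map and the PPI.
    Deterministic given the configuration seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    edges = sorted(truth.true_edges)
    n_keep = int(round(config.prior_coverage * len(edges)))
    keep_idx = rng.choice(len(edges), size=n_keep, replace=False) if n_keep else []
    kept = [edges[i] for i in sorted(keep_idx)]

    direct = {(s, t) for s, t, _ in kept if s.startswith("G")}
    ppi = {_canon(s, t) for s, t, _ in kept if s.startswith("P")}

    genes = [f"G{i:03d}" for i in range(config.n_genes)]
    prots = [f"P{i:03d}" for i in range(config.n_proteins)]
    truth_pairs = truth.edge_pairs()
    n_decoy_map = config.decoy_prior_edges // 2
    n_decoy_ppi = config.decoy_prior_edges - n_decoy_map
    guard = 0
    while n_decoy_map > 0 and guard < 100_000:
        guard += 1
        g = genes[rng.integers(0, len(genes))]
        p = prots[rng.integers(0, len(prots))]
        if _canon(g, p) in truth_pairs or (g, p) in direct:
            continue
        direct.add((g, p))
        n_decoy_map -= 1
    guard = 0
    while n_decoy_ppi > 0 and guard < 100_000:
        guard += 1
        i, j = rng.integers(0, len(prots), size=2)
        if i == j:
            continue
        pair = _canon(prots[int(i)], prots[int(j)])
        if pair in truth_pairs or pair in ppi:
            continue
        ppi.add(pair)
        n_decoy_ppi -= 1

    return PriorSet(direct_map=direct, ppi=ppi, indirect_map=build_indirect_prior(direct, ppi))
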