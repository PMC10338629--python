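"""Prior-guided per-node network inference, trimming, and consensus.

Each feature of the centered layer becomes the response of one sparse-group-
lasso regression whose candidate predictors come from the priors (predictors
grouped by omic layer).  The penalty level is chosen per node by K-fold
cross-validated mean squared error with the one-standard-error rule on a
50-point log-spaced grid below the node's lambda_max; the final model is
refit on all samples.  Nonzero coefficients become directed edges
predictor -> target carrying the standardized-scale coefficient and the
node model's R^2.

Three networks are inferred, centered on the transcript, protein, and
clinical layers.  Trimming removes node models with R^2 below 0.1 and effects
with |beta| below 0.002 (both strict).  The consensus keeps a node pair only
when an effect with a consistent sign is present in every centered network
whose target layer can host the pair at all — a gene-protein pair, for
instance, must be found in both the transcript- and the protein-centered
network, while it can never occur in the clinical-centered one (its targets
are clinical variables only).  A strict mode requiring literal presence in
all three networks is also available; over layer-disjoint edge sets it is
empty by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .priors import PriorSet, _canon
from .sgl import lambda_max, sgl_path

logger = logging.getLogger(__name__)

__all__ = [
    "NodeModel",
    "MultiOmicNetwork",
    "fit_node_model",
    "infer_network",
    "trim_network",
    "consensus",
]

EDGE_COLUMNS = ["source", "target", "beta", "r2"]

# predictor layers admissible for each center's targets
PREDICTOR_LAYERS = {
    "transcript": {"protein", "clinical"},
    "protein": {"transcript", "protein", "clinical"},
    "clinical": {"transcript", "protein", "clinical"},
}


@dataclass
class NodeModel:
    """One target's fitted sparse regression."""

    target: str
    predictors: list[str]
    groups: list[str]  # omic layer per predictor
    coef: np.ndarray  # standardized-predictor scale; zeros = not selected
    intercept: float
    lam: float
    alpha: float
    r2: float  # on the fitting data, clamped to [0, 1]

    def selected(self) -> list[tuple[str, float]]:
        return [(p, float(b)) for p, b in zip(self.predictors, self.coef) if b != 0.0]


@dataclass
class MultiOmicNetwork:
    """A centered network: node models flattened to a weighted edge list."""

    center: str
    nodes: dict[str, str]  # feature id -> layer
    edges: pd.DataFrame  # source (predictor), target, beta, r2
    models: dict[str, NodeModel] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.edges.columns)[:4] != EDGE_COLUMNS:
            self.edges = self.edges.reindex(columns=EDGE_COLUMNS)
        if len(self.edges):
            if (self.edges["source"] == self.edges["target"]).any():
                raise ValueError("self-edges are not allowed")
            if not np.isfinite(self.edges["beta"].to_numpy(dtype=float)).all():
                raise ValueError("edge weights must be finite")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        """Undirected canonical node pairs carrying at least one edge."""
        return {_canon(s, t) for s, t in zip(self.edges["source"], self.edges["target"])}

    def to_networkx(self, directed: bool = True) -> "nx.Graph":
        g = nx.DiGraph() if directed else nx.Graph()
        for node, layer in self.nodes.items():
            g.add_node(node, layer=layer)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, beta=float(row.beta), r2=float(row.r2))
        return g

    def sorted_edges(self) -> pd.DataFrame:
        return self.edges.sort_values(["source", "target"]).reset_index(drop=True)


def _lambda_grid(lam_max: float, n_lambdas: int, lam_min_ratio: float) -> np.ndarray:
    if lam_max <= 0:
        return np.zeros(1)
    return np.geomspace(lam_max, lam_max * lam_min_ratio, n_lambdas)


def fit_node_model(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: list[str],
    alpha: float = 0.5,
    cv_folds: int = 5,
    n_lambdas: int = 50,
    lam_min_ratio: float = 0.01,
    seed: int = 0,
    tol: float = 1e-6,
    cv_tol: float = 1e-4,
    select_rule: str = "cv_min",
    target: str = "",
) -> NodeModel:
    """Cross-validated sparse-group-lasso fit for one target feature.

    The penalty grid runs from the node's lambda_max (everything zero) down
    to ``lam_min_ratio`` times it; lambda is chosen by ``cv_folds``-fold CV
    mean squared error, either at the CV minimum (``select_rule="cv_min"``,
    default) or by the one-standard-error rule (``"1se"``); the model is then
    refit on all samples.  A target with no candidates yields an empty model
    with R^2 = 0.
    """
    if select_rule not in ("cv_min", "1se"):
        raise ValueError(f"unknown select_rule {select_rule!r}")
    if X.shape[1] == 0:
        return NodeModel(target, [], [], np.zeros(0), float(np.mean(y)), 0.0, alpha, 0.0)
    n = X.shape[0]
    if n < cv_folds:
        raise ValueError(f"{n} samples cannot support {cv_folds}-fold cross-validation")
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xv - mu) / sd
    yc = np.asarray(y, dtype=float)
    y_mean = yc.mean()
    yc = yc - y_mean
    glabels = pd.factorize(np.asarray(groups))[0]

    lam_max = lambda_max(Xs, yc, glabels, alpha)
    if lam_max <= 0:
        return NodeModel(target, list(X.columns), list(groups), np.zeros(X.shape[1]),
                         float(y_mean), 0.0, alpha, 0.0)
    lams = _lambda_grid(lam_max, n_lambdas, lam_min_ratio)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse = np.zeros((cv_folds, lams.size))
    for k, (tr, te) in enumerate(kf.split(Xs)):
        betas = sgl_path(Xs[tr], yc[tr] - yc[tr].mean(), glabels, lams, alpha, tol=cv_tol)
        pred = (Xs[te] @ betas.T) + yc[tr].mean()
        mse[k] = ((yc[te][:, None] - pred) ** 2).mean(axis=0)
    mean_mse = mse.mean(axis=0)
    se_mse = mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(mean_mse))
    if select_rule == "1se":
        cutoff = mean_mse[i_min] + se_mse[i_min]
        i_sel = int(np.flatnonzero(mean_mse <= cutoff)[0])  # largest lambda within 1 SE
    else:
        # CV minimum, gated on paired evidence of predictive improvement over
        # the empty model: keep the null fit unless the per-fold error drop
        # exceeds its own standard error.
        drop = mse[:, 0] - mse[:, i_min]
        se_drop = drop.std(ddof=1) / np.sqrt(cv_folds)
        i_sel = i_min if (i_min > 0 and drop.mean() > se_drop) else 0

    beta = sgl_path(Xs, yc, glabels, lams[: i_sel + 1], alpha, tol=tol)[-1]
    resid = yc - Xs @ beta
    tss = float((yc**2).sum())
    r2 = float(np.clip(1.0 - (resid**2).sum() / tss, 0.0, 1.0)) if tss > 0 else 0.0
    return NodeModel(
        target=target,
        predictors=list(X.columns),
        groups=list(groups),
        coef=beta,
        intercept=float(y_mean),
        lam=float(lams[i_sel]),
        alpha=alpha,
        r2=r2,
    )


def _candidates(
    target: str,
    center: str,
    priors: PriorSet,
    available: dict[str, str],  # feature -> layer for features with data
) -> list[str]:
    if center == "transcript":
        cand = priors.proteins_of_gene(target) | priors.indirect_of_gene(target)
        cand |= {f for f, l in available.items() if l == "clinical"}
    elif center == "protein":
        cand = priors.genes_of_protein(target) | priors.ppi_partners(target)
        cand |= {f for f, l in available.items() if l == "clinical"}
    elif center == "clinical":
        cand = set(priors.clinical_candidates.get(target, set()))
    else:
        raise ValueError(f"unknown center {center!r}")
    cand.discard(target)
    return sorted(f for f in cand if f in available)


def infer_network(
    matrices: dict[str, pd.DataFrame],
    priors: PriorSet,
    center: str,
    alpha: float = 0.5,
    cv_folds: int = 5,
    n_lambdas: int = 50,
    lam_min_ratio: float = 0.01,
    seed: int = 0,
    tol: float = 1e-6,
    select_rule: str = "cv_min",
) -> MultiOmicNetwork:
    """One sparse regression per feature of the centered layer.

    ``matrices`` maps layer name ("transcript", "protein", "clinical") to a
    complete, preprocessed feature x sample matrix; all layers must share the
    same sample columns in the same order.
    """
    if center not in matrices:
        raise ValueError(f"no matrix for center layer {center!r}")
    samples = list(next(iter(matrices.values())).columns)
    for layer, m in matrices.items():
        if list(m.columns) != samples:
            raise ValueError(f"layer {layer!r} samples misaligned with the other layers")
        if m.isna().to_numpy().any():
            raise ValueError(f"layer {layer!r} contains missing values")

    available: dict[str, str] = {}
    rows: dict[str, np.ndarray] = {}
    for layer, m in matrices.items():
        for f in m.index:
            available[f] = layer
            rows[f] = m.loc[f].to_numpy(dtype=float)

    nodes = dict(available)
    models: dict[str, NodeModel] = {}
    edges = []
    targets = list(matrices[center].index)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(targets))]
    for target, tseed in zip(targets, child_seeds):
        cand = _candidates(target, center, priors, available)
        X = pd.DataFrame({c: rows[c] for c in cand}, index=samples) if cand else pd.DataFrame(index=samples)
        model = fit_node_model(
            rows[target],
            X,
            [available[c] for c in cand],
            alpha=alpha,
            cv_folds=cv_folds,
            n_lambdas=n_lambdas,
            lam_min_ratio=lam_min_ratio,
            seed=tseed,
            tol=tol,
            select_rule=select_rule,
            target=target,
        )
        if not cand:
            logger.debug("target %s has no candidate predictors", target)
        models[target] = model
        for pred, b in model.selected():
            edges.append((pred, target, b, model.r2))
    edge_df = pd.DataFrame(edges, columns=EDGE_COLUMNS)
    return MultiOmicNetwork(center=center, nodes=nodes, edges=edge_df, models=models)


def trim_network(
    net: MultiOmicNetwork, r2_min: float = 0.1, beta_min: float = 0.002
) -> MultiOmicNetwork:
    """Drop weak node models and weak effects (strict thresholds).

    Removes every edge whose target model has R^2 < ``r2_min`` and every edge
    with |beta| < ``beta_min``; nodes left without any edge are dropped.
    """
    e = net.edges
    keep = (e["r2"] >= r2_min) & (e["beta"].abs() >= beta_min)
    edges = e.loc[keep].reset_index(drop=True)
    used = set(edges["source"]) | set(edges["target"])
    nodes = {f: l for f, l in net.nodes.items() if f in used}
    return MultiOmicNetwork(center=net.center, nodes=nodes, edges=edges, models=net.models)


def _pair_signs(net: MultiOmicNetwork) -> dict[tuple[str, str], list[tuple[str, str, float]]]:
    out: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for row in net.edges.itertuples(index=False):
        out.setdefault(_canon(row.source, row.target), []).append(
            (row.source, row.target, float(row.beta))
        )
    return out


def _pair_eligible(layers: tuple[str, str], center: str) -> bool:
    la, lb = layers
    preds = PREDICTOR_LAYERS[center]
    return (la == center and lb in preds) or (lb == center and la in preds)


def consensus(
    nets: list[MultiOmicNetwork], mode: str = "eligible"
) -> MultiOmicNetwork:
    """Node pairs supported consistently across the centered networks.

    mode="eligible" (default): a pair is kept iff it carries a consistently
    signed effect in every input network whose center layer can host the pair
    as a (target, predictor) combination.  mode="strict": literal presence in
    all inputs (the all-three intersection).  In both modes every appearance
    of the pair, in any direction, must agree in sign; the consensus weight
    is the mean beta over the supporting edges.
    """
    if len(nets) < 3:
        raise ValueError(f"consensus needs three networks, got {len(nets)}")
    if mode not in ("eligible", "strict"):
        raise ValueError(f"unknown consensus mode {mode!r}")

    layer_of: dict[str, str] = {}
    for net in nets:
        layer_of.update(net.nodes)
    per_net = [_pair_signs(net) for net in nets]
    all_pairs = set().union(*per_net)

    rows = []
    for pair in sorted(all_pairs):
        support = []
        ok = True
        for net, pmap in zip(nets, per_net):
            present = pair in pmap
            if mode == "strict":
                required = True
            else:
                layers = (layer_of.get(pair[0], "?"), layer_of.get(pair[1], "?"))
                required = (
                    _pair_eligible(layers, net.center) if net.center in PREDICTOR_LAYERS else present
                )
            if required and not present:
                ok = False
                break
            if present:
                support.extend(pmap[pair])
        if not ok or not support:
            continue
        signs = {np.sign(b) for _, _, b in support}
        if len(signs) != 1:
            continue
        betas = [b for _, _, b in support]
        r2s = []
        for net, pmap in zip(nets, per_net):
            for _s, t, _b in pmap.get(pair, []):
                m = net.models.get(t)
                if m is not None:
                    r2s.append(m.r2)
        rows.append((pair[0], pair[1], float(np.mean(betas)), float(np.mean(r2s)) if r2s else np.nan))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    used = set(edges["source"]) | set(edges["target"])
    nodes = {f: l for f, l in layer_of.items() if f in used}
    return MultiOmicNetwork(center="consensus", nodes=nodes, edges=edges)
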