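"""Per-time-point differential expression with moderated statistics.

Every feature is fit with one ordinary-least-squares model over all samples:
an intercept (the pooled vehicle-control mean) plus one dummy variable per
treated week, so each week's coefficient is that week's log2 fold change
against the pooled controls.  Residual variances are shrunk toward a common
prior by empirical Bayes — the prior degrees of freedom d0 and prior variance
s0^2 are estimated by the method of moments on log s^2 — giving moderated
t-statistics with d + d0 degrees of freedom.  P-values are corrected per week
across features with Benjamini-Hochberg, and features are called DE at
adjusted p below the FDR cutoff (transcript mode additionally requires a fold
change beyond the cutoff).  Per-week DE sets are then grouped into the three
response phases and decomposed into unique and shared subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DesignInfo",
    "DEResult",
    "PhaseSets",
    "fit_timepoint_model",
    "moderate_variance",
    "adjust_bh",
    "call_de",
    "phase_partition",
    "run_de",
]


@dataclass
class DesignInfo:
    """Sample-to-week assignment with a pooled control group."""

    sample_weeks: dict[str, int]
    control_samples: list[str]
    treated_weeks: list[int] = field(init=False)

    def __post_init__(self):
        if not self.control_samples:
            raise ValueError("control group is empty")
        treated = {}
        for s, w in self.sample_weeks.items():
            if s in set(self.control_samples):
                continue
            treated.setdefault(int(w), []).append(s)
        for w, samps in treated.items():
            if len(samps) < 2:
                raise ValueError(f"treated week {w} has fewer than 2 samples")
        self.treated_weeks = sorted(treated)
        self._treated = treated

    @classmethod
    def from_sample_meta(cls, meta: pd.DataFrame) -> "DesignInfo":
        ctl = list(meta.loc[meta["treatment"] == "control", "sample_id"])
        weeks = dict(zip(meta["sample_id"], meta["week"].astype(int)))
        return cls(sample_weeks=weeks, control_samples=ctl)

    def design_matrix(self, samples: list[str]) -> tuple[np.ndarray, list[int]]:
        """Intercept + one dummy per treated week, rows ordered as ``samples``."""
        ctl = set(self.control_samples)
        X = np.zeros((len(samples), 1 + len(self.treated_weeks)))
        X[:, 0] = 1.0
        col = {w: j + 1 for j, w in enumerate(self.treated_weeks)}
        for i, s in enumerate(samples):
            if s in ctl:
                continue
            if s not in self.sample_weeks:
                raise ValueError(f"sample {s} missing from the design")
            X[i, col[self.sample_weeks[s]]] = 1.0
        return X, list(self.treated_weeks)


@dataclass
class ModelFits:
    """Per-feature OLS output: coefficients, standard errors, residual variance."""

    features: list[str]
    weeks: list[int]
    coef: np.ndarray  # features x weeks, log2 fold change vs pooled control
    se: np.ndarray  # unmoderated standard errors
    s2: np.ndarray  # residual variance per feature
    df_resid: float


@dataclass
class DEResult:
    """Moderated per-feature, per-week statistics and the calls they support."""

    table: pd.DataFrame  # feature, week, log2fc, se, t, p, fdr
    df_resid: float
    d0: float
    s0_sq: float
    s2: pd.Series
    s2_mod: pd.Series

    def de_sets(self, fdr: float = 0.05, fc: float = 1.5, fc_scale: str = "natural",
                mode: str = "transcript") -> dict[int, set[str]]:
        return call_de(self, fdr=fdr, fc=fc, fc_scale=fc_scale, mode=mode)


def fit_timepoint_model(matrix: pd.DataFrame, design: DesignInfo) -> ModelFits:
    """OLS per feature: each treated week contrasted against pooled controls.

    Because treated weeks share no samples, each week's coefficient equals the
    two-group mean difference (treated week minus pooled control).
    """
    samples = list(matrix.columns)
    X, weeks = design.design_matrix(samples)
    n, k = X.shape
    df = n - np.linalg.matrix_rank(X)
    if df < 2:
        raise ValueError(
            f"only {df} residual degrees of freedom with treated weeks {weeks}; need >= 2"
        )
    Y = matrix.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ (XtX_inv @ X.T).T  # features x k
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / df
    c = np.sqrt(np.diag(XtX_inv))[1:]  # per-week multiplier
    se = np.sqrt(s2)[:, None] * c[None, :]
    return ModelFits(
        features=list(matrix.index),
        weeks=weeks,
        coef=B[:, 1:],
        se=se,
        s2=s2,
        df_resid=float(df),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from the log residual variances.

    Under the scaled-inverse-chi-square prior, z = log s^2 has known mean and
    variance involving digamma/trigamma functions of d/2 and d0/2; matching
    the empirical moments of z yields d0 (via trigamma inversion) and s0^2.
    d0 = inf when the observed spread of log s^2 is no wider than sampling
    noise alone.
    """
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("need at least 10 features with positive residual variance")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(e.mean())
    n = e.size
    evar = float(((e - ebar) ** 2).sum() / (n - 1))
    target = evar - float(polygamma(1, df / 2.0))
    if target <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = float(np.exp(ebar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_variance(
    fits: ModelFits, d0: float | None = None, s0_sq: float | None = None
) -> DEResult:
    """Empirical-Bayes shrinkage of residual variances and moderated tests.

    s2_mod = (d0 * s0^2 + d * s^2) / (d0 + d); the moderated t uses s2_mod in
    place of s^2 and d + d0 degrees of freedom.  ``d0``/``s0_sq`` may be fixed
    by the caller (d0=0 reproduces the ordinary t; d0=inf forces s2_mod=s0^2);
    by default they are estimated by the method of moments.
    """
    s2 = fits.s2
    if d0 is None or s0_sq is None:
        if np.all(s2 == 0):
            logger.warning("all residual variances are zero; falling back to ordinary t")
            d0, s0_sq = 0.0, 0.0
        else:
            est_d0, est_s0 = estimate_prior(s2, fits.df_resid)
            d0 = est_d0 if d0 is None else d0
            s0_sq = est_s0 if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
    else:
        s2_mod = (d0 * s0_sq + fits.df_resid * s2) / (d0 + fits.df_resid)
    df_total = fits.df_resid + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        df_total = np.inf

    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt(np.where(s2 > 0, s2_mod / s2, np.nan))
        se_mod = fits.se * scale[:, None]
        tvals = np.where(se_mod > 0, fits.coef / se_mod, np.sign(fits.coef) * np.inf)
    if np.isinf(df_total):
        from scipy.stats import norm

        pvals = 2.0 * norm.sf(np.abs(tvals))
    else:
        pvals = 2.0 * t_dist.sf(np.abs(tvals), df_total)

    rows = []
    for j, w in enumerate(fits.weeks):
        fdr = adjust_bh(pvals[:, j])
        for i, f in enumerate(fits.features):
            rows.append((f, w, fits.coef[i, j], se_mod[i, j], tvals[i, j], pvals[i, j], fdr[i]))
    table = pd.DataFrame(rows, columns=["feature", "week", "log2fc", "se", "t", "p", "fdr"])
    return DEResult(
        table=table,
        df_resid=fits.df_resid,
        d0=float(d0),
        s0_sq=float(s0_sq),
        s2=pd.Series(s2, index=fits.features),
        s2_mod=pd.Series(s2_mod, index=fits.features),
    )


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, NaN-aware.

    NaN entries are excluded from the test count m and propagated as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_de(
    result: DEResult,
    fdr: float = 0.05,
    fc: float = 1.5,
    fc_scale: str = "natural",
    mode: str = "transcript",
) -> dict[int, set[str]]:
    """Per-week DE sets under the configured thresholds (strict inequalities).

    Transcript mode requires adjusted p < fdr AND |log2FC| beyond the fold
    cutoff; protein mode uses the FDR cutoff alone.  ``fc_scale="natural"``
    reads ``fc`` as a natural-scale fold change (cutoff log2(fc));
    ``"log2"`` reads it directly as a log2 cutoff.
    """
    if mode not in ("transcript", "protein"):
        raise ValueError(f"unknown mode {mode!r}")
    if fc_scale not in ("natural", "log2"):
        raise ValueError(f"unknown fc_scale {fc_scale!r}")
    if mode == "transcript":
        if fc_scale == "natural":
            if fc <= 1:
                raise ValueError("natural-scale fold-change cutoff must exceed 1")
            lfc_cut = np.log2(fc)
        else:
            if fc <= 0:
                raise ValueError("log2 fold-change cutoff must be positive")
            lfc_cut = fc
    t = result.table
    sig = t["fdr"] < fdr
    if mode == "transcript":
        sig = sig & (t["log2fc"].abs() > lfc_cut)
    out: dict[int, set[str]] = {int(w): set() for w in t["week"].unique()}
    for f, w in zip(t.loc[sig, "feature"], t.loc[sig, "week"]):
        out[int(w)].add(f)
    return out


@dataclass
class PhaseSets:
    """Per-phase DE sets with their unique and shared decomposition."""

    phase_sets: dict[str, set[str]]
    unique: dict[str, set[str]]
    shared: set[str]

    def venn_counts(self) -> dict[str, int]:
        """Region sizes of the phase Venn diagram (3 phases -> 7 regions)."""
        phases = sorted(self.phase_sets)
        union = set().union(*self.phase_sets.values()) if self.phase_sets else set()
        counts = {}
        for mask in range(1, 2 ** len(phases)):
            inside = [p for i, p in enumerate(phases) if mask >> i & 1]
            outside = [p for p in phases if p not in inside]
            region = set(union)
            for p in inside:
                region &= self.phase_sets[p]
            for p in outside:
                region -= self.phase_sets[p]
            counts["&".join(inside)] = len(region)
        return counts


def phase_partition(
    de_sets: dict[int, set[str]], phase_map: dict[int, str]
) -> PhaseSets:
    """Union per-week DE sets into phases; decompose into unique/shared.

    A phase's set is the union over its weeks; unique(P) removes every
    feature present in any other phase; shared is the all-phase intersection.
    Weeks labelled "control" are ignored; any other unmapped week is an error.
    """
    phase_sets: dict[str, set[str]] = {}
    for w, feats in de_sets.items():
        if w not in phase_map:
            raise ValueError(f"week {w} is not assigned to a phase")
        phase = phase_map[w]
        if phase == "control":
            continue
        phase_sets.setdefault(phase, set()).update(feats)
    unique = {
        p: s - set().union(*(phase_sets[q] for q in phase_sets if q != p), set())
        for p, s in phase_sets.items()
    }
    shared = set.intersection(*phase_sets.values()) if phase_sets else set()
    return PhaseSets(phase_sets=phase_sets, unique=unique, shared=shared)


def run_de(
    matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    mode: str = "transcript",
    fdr: float = 0.05,
    fc: float = 1.5,
    fc_scale: str = "natural",
) -> tuple[DEResult, dict[int, set[str]]]:
    """Fit, moderate, and call DE for one expression layer."""
    meta = sample_meta[sample_meta["sample_id"].isin(matrix.columns)]
    design = DesignInfo.from_sample_meta(meta)
    fits = fit_timepoint_model(matrix, design)
    result = moderate_variance(fits)
    sets = call_de(result, fdr=fdr, fc=fc, fc_scale=fc_scale, mode=mode)
    return result, sets
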