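"""Topology hypothesis tests: RELL resampling, KH, SH and AU, plus the ranked table.

All tests operate on a matrix of per-site-pattern log-likelihoods, one
row per candidate topology evaluated at that topology's own optimized
parameters.  Resampling follows the RELL idea: bootstrap replicates
re-draw site patterns (with probability proportional to multiplicity)
and re-total the stored per-site log-likelihoods instead of
re-optimizing anything.

* KH: one-sided Kishino-Hasegawa — a tree's observed log-likelihood
  deficit is compared against its replicate deficit distribution
  centered at its own mean.
* SH: Shimodaira-Hasegawa — the null distribution is the maximum of the
  centered replicate deficits over the whole candidate set, which makes
  the test conservative (p_SH >= p_KH always, on the same replicates).
* AU: approximately unbiased — bootstrap proportions are computed at
  several replicate-size scales r (replicate size = round(r * n)); the
  probit-transformed proportions are regressed on d*sqrt(r) + c/sqrt(r)
  by weighted least squares, and p_AU = 1 - Phi(d - c) corrects the
  naive bootstrap proportion for boundary curvature.

The ranked table mirrors the conventional presentation: topologies
sorted ascending by dLogL/SE with the maximum-likelihood tree first and
a "within one standard error" flag (dLogL/SE <= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RellConfig",
    "SiteLogLik",
    "delta_and_se",
    "rell_resample",
    "kh_test",
    "sh_test",
    "au_test",
    "build_table",
    "TABLE_COLUMNS",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))

TABLE_COLUMNS = ["rank", "tree", "delta_logl", "se", "ratio",
                 "p_au", "p_kh", "p_sh", "scenario", "within_1se"]


@dataclass
class RellConfig:
    """Replicate count, resampling scales and RNG seed for all tests."""

    n_replicates: int = 10_000
    scales: tuple = DEFAULT_SCALES
    seed: int = 0

    def __post_init__(self):
        self.scales = tuple(float(s) for s in self.scales)
        if self.n_replicates < 100:
            raise ValueError("need at least 100 replicates")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if not any(abs(s - 1.0) < 1e-12 for s in self.scales):
            raise ValueError("scale 1.0 must be present (KH/SH use it)")

    @property
    def unit_scale_index(self) -> int:
        return next(i for i, s in enumerate(self.scales)
                    if abs(s - 1.0) < 1e-12)


@dataclass
class SiteLogLik:
    """Per-pattern log-likelihoods for a set of candidate topologies.

    ``matrix[i, p]`` is tree i's log-likelihood at pattern p (computed
    at tree i's optimized branch lengths and rate parameters);
    ``counts[p]`` is the pattern multiplicity.  ``trees`` holds one
    identifying Newick/canonical string per row.
    """

    trees: list
    matrix: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.trees):
            raise ValueError("matrix must be (n_trees, n_patterns)")
        if self.matrix.shape[1] != self.counts.shape[0]:
            raise ValueError("counts length must match matrix columns")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite site log-likelihoods")

    @property
    def n_trees(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def totals(self) -> np.ndarray:
        return self.matrix @ self.counts

    def ml_index(self) -> int:
        """Row of the ML tree; exact total-logL ties break on the tree string."""
        totals = self.totals
        best = totals.max()
        tied = np.flatnonzero(totals == best)
        if len(tied) == 1:
            return int(tied[0])
        return int(min(tied, key=lambda i: str(self.trees[i])))

    def to_tsv(self, path):
        """Documented TSV: first row = pattern multiplicities, then one row/tree."""
        with open(path, "w") as fh:
            fh.write("tree\t" + "\t".join(str(int(c)) for c in self.counts) + "\n")
            for t, row in zip(self.trees, self.matrix):
                fh.write(str(t) + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "SiteLogLik":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            counts = np.array([int(c) for c in header[1:]])
            trees, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                trees.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(trees=trees, matrix=np.array(rows), counts=counts)


# ---------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------

def delta_and_se(sl: SiteLogLik):
    """Log-likelihood deficits and their standard errors vs the ML tree.

    delta_i = logL_ML - logL_i >= 0.  SE_i is the usual standard error
    of the total per-site log-likelihood difference,
    sqrt( n/(n-1) * sum_s (d_s - dbar)^2 ), expanded over pattern
    multiplicities; the ML tree's SE is reported as 0.
    """
    if sl.n_trees < 2:
        raise ValueError("need at least two trees to compare")
    ml = sl.ml_index()
    diffs = sl.matrix[ml][None, :] - sl.matrix       # (n_trees, n_pat) per-site d_s
    n = sl.n_sites
    delta = diffs @ sl.counts
    dbar = delta / n
    ssq = ((diffs - dbar[:, None]) ** 2) @ sl.counts
    se = np.sqrt(n / (n - 1) * ssq)
    se[ml] = 0.0
    delta[ml] = 0.0
    return delta, se


def _scale_rng(cfg: RellConfig, scale_index: int) -> np.random.Generator:
    # fixed stream splitting: each scale gets its own child stream, so
    # replicates never depend on which/how many trees are present
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(scale_index,)))


def rell_resample(sl: SiteLogLik, cfg: RellConfig, scale: float) -> np.ndarray:
    """RELL replicate totals at one scale: (n_replicates, n_trees).

    Each replicate draws round(scale * n) sites with replacement
    (pattern probability proportional to multiplicity); the same draws
    are shared by all trees within a replicate.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    try:
        scale_index = next(i for i, s in enumerate(cfg.scales)
                           if abs(s - scale) < 1e-12)
    except StopIteration:
        raise ValueError(f"scale {scale} not in config scales {cfg.scales}")
    rng = _scale_rng(cfg, scale_index)
    n = sl.n_sites
    m = int(round(scale * n))
    prob = sl.counts / n
    draws = rng.multinomial(m, prob, size=cfg.n_replicates)
    return draws.astype(float) @ sl.matrix.T


def _unit_replicates(sl, cfg, rell):
    if rell is None:
        rell = rell_resample(sl, cfg, 1.0)
    return rell


def kh_test(sl: SiteLogLik, cfg: RellConfig, rell: np.ndarray = None) -> np.ndarray:
    """One-sided KH p-value per tree (centered RELL null), vs the ML tree."""
    rep = _unit_replicates(sl, cfg, rell)
    delta, _ = delta_and_se(sl)
    ml = sl.ml_index()
    dstar = rep[:, ml][:, None] - rep                 # replicate deficits
    centered = dstar - dstar.mean(axis=0, keepdims=True)
    return (centered >= delta[None, :]).mean(axis=0)


def sh_test(sl: SiteLogLik, cfg: RellConfig, rell: np.ndarray = None) -> np.ndarray:
    """SH p-value per tree: null is the max over trees of centered replicate gains."""
    rep = _unit_replicates(sl, cfg, rell)
    delta, _ = delta_and_se(sl)
    centered = rep - rep.mean(axis=0, keepdims=True)
    # simulated deficit of tree i in replicate b: max_j R_j(b) - R_i(b)
    null = centered.max(axis=1, keepdims=True) - centered
    return (null >= delta[None, :]).mean(axis=0)


def _bootstrap_proportions(sl: SiteLogLik, cfg: RellConfig):
    """BP[tree, scale]: fraction of replicates where the tree attains the max."""
    b = cfg.n_replicates
    bp = np.zeros((sl.n_trees, len(cfg.scales)))
    for si, scale in enumerate(cfg.scales):
        rep = rell_resample(sl, cfg, scale)
        winners = rep.argmax(axis=1)                  # ties: lowest row index
        cnt = np.bincount(winners, minlength=sl.n_trees)
        bp[:, si] = cnt / b
    return bp


def au_test(sl: SiteLogLik, cfg: RellConfig, return_details: bool = False):
    """AU p-value per tree from the multiscale bootstrap.

    Degenerate trees (BP stuck at 0 or 1 on fewer than two informative
    scales) are assigned p = 0 or 1 by the side their BPs sit on and
    flagged; BPs are clamped to [1/(B+1), 1 - 1/(B+1)] before the
    probit so the regression stays finite.
    """
    if len(cfg.scales) < 3:
        raise ValueError("AU needs at least 3 resampling scales")
    b = cfg.n_replicates
    bp = _bootstrap_proportions(sl, cfg)
    eps = 1.0 / (b + 1)
    r = np.array(cfg.scales)
    x = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])

    p_au = np.empty(sl.n_trees)
    flags = np.zeros(sl.n_trees, dtype=bool)
    coefs = np.zeros((sl.n_trees, 2))
    for i in range(sl.n_trees):
        informative = (bp[i] > eps) & (bp[i] < 1 - eps)
        if informative.sum() < 2:
            flags[i] = True
            p_au[i] = 1.0 if bp[i].mean() > 0.5 else 0.0
            continue
        bpc = np.clip(bp[i], eps, 1 - eps)
        z = norm.ppf(1.0 - bpc)
        # weights: inverse delta-method variance of the probit-transformed BP
        w = b * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(x * sw[:, None], z * sw, rcond=None)
        d, c = beta
        coefs[i] = (d, c)
        p_au[i] = float(norm.sf(d - c))
    if return_details:
        return p_au, {"flags": flags, "bp": bp, "coefs": coefs}
    return p_au


# ---------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------

def build_table(sl: SiteLogLik, cfg: RellConfig,
                scenario_labels=None) -> pd.DataFrame:
    """Ranked results table: one row per topology, sorted by dLogL/SE.

    The ML tree has delta = se = ratio = 0 and rank 1; ties in the sort
    key break deterministically on the tree string.  ``within_1se``
    flags topologies with dLogL/SE <= 1 (the "within one standard
    error of the ML tree" criterion).
    """
    if sl.n_trees == 1:
        # degenerate candidate set: the lone tree is the ML tree
        delta = se = np.zeros(1)
        p_kh = p_sh = p_au = np.ones(1)
        au_info = {"flags": np.array([True])}
    else:
        delta, se = delta_and_se(sl)
        rep1 = rell_resample(sl, cfg, 1.0)
        p_kh = kh_test(sl, cfg, rep1)
        p_sh = sh_test(sl, cfg, rep1)
        p_au, au_info = au_test(sl, cfg, return_details=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta == 0.0, 0.0,
                         np.where(se > 0, delta / np.maximum(se, 1e-300), np.inf))
    if scenario_labels is None:
        scenario_labels = [""] * sl.n_trees
    df = pd.DataFrame({
        "tree": [str(t) for t in sl.trees],
        "delta_logl": delta,
        "se": se,
        "ratio": ratio,
        "p_au": p_au,
        "p_kh": p_kh,
        "p_sh": p_sh,
        "scenario": list(scenario_labels),
        "au_degenerate": au_info["flags"],
        "total_logl": sl.totals,
    })
    df = df.sort_values(["ratio", "delta_logl", "tree"],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["within_1se"] = df["ratio"] <= 1.0
    return df[TABLE_COLUMNS + ["au_degenerate", "total_logl"]]
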