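"""Phylogenetic likelihood under empirical amino-acid models with +I and +Gk.

The model is a reversible CTMC on the 20 amino acids: Q_ij = s_ij * pi_j
(i != j) with symmetric exchangeabilities s and equilibrium frequencies
pi, scaled so the expected rate at equilibrium is 1.  Rate heterogeneity
across sites uses a proportion ``p_inv`` of invariant sites plus ``k``
discrete gamma categories (means of equal-probability bins of
Gamma(alpha, alpha)); the gamma category rates are divided by
(1 - p_inv) so the full mixture keeps mean rate 1.

Per-site likelihoods are computed by Felsenstein pruning over the
compressed site patterns of the alignment; transition kernels come from
the symmetric eigendecomposition of the rate matrix, which also yields
analytic first and second derivatives with respect to a branch length.
Branch-length optimization runs Newton updates per branch on cached
"inside" (subtree) and "outside" (rest-of-tree) partials, interleaved
with bounded quasi-Newton profile optimization of alpha and p_inv.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize as sciopt
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._jtt import AA_ORDER, JTT_FREQS, JTT_LOWER
from .treespace import Tree, TreeError

__all__ = [
    "AA_ORDER",
    "AMBIG_CODE",
    "MSA",
    "SubstModel",
    "discrete_gamma_rates",
    "site_loglik",
    "optimize_tree",
    "OptResult",
    "LikelihoodEngine",
    "PartialLeafData",
    "invariant_class_lik",
    "subtree_partials",
]

AMBIG_CODE = 20  # gap / X / unknown: fully ambiguous observation
_CODE_OF = {aa: i for i, aa in enumerate(AA_ORDER)}
for _ch in "-X?.BZJUO*":
    _CODE_OF[_ch] = AMBIG_CODE

BL_MIN, BL_MAX = 1e-8, 10.0
ALPHA_MIN, ALPHA_MAX = 0.02, 100.0
PINV_MAX = 0.99


# ---------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------

class MSA:
    """Aligned amino-acid matrix with compressed site patterns.

    Rows are sequences (``labels``), columns are sites.  Internally the
    matrix is integer-coded (0..19 amino acids in PAML order, 20 =
    gap/ambiguity) and compressed to distinct site patterns with
    multiplicities; all likelihood machinery works on patterns.
    """

    def __init__(self, labels, codes):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[0] != len(labels):
            raise ValueError("codes must be (n_sequences, n_sites)")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate sequence labels")
        self.labels = list(labels)
        self.codes = codes
        self._patterns = None

    # -- constructors --------------------------------------------------

    @classmethod
    def from_sequences(cls, items) -> "MSA":
        """Build from an iterable of (label, sequence-string) pairs."""
        items = list(items)
        labels = [l for l, _ in items]
        seqs = [s.upper() for _, s in items]
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("sequences have unequal lengths")
        try:
            codes = np.array([[_CODE_OF[c] for c in s] for s in seqs],
                             dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"unknown residue character {exc}") from None
        return cls(labels, codes)

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        from Bio import SeqIO
        items = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not items:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(items)

    def to_fasta(self, path):
        inv = AA_ORDER + "-"
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.codes):
                seq = "".join(inv[c] for c in row)
                fh.write(f">{label}\n{seq}\n")

    # -- queries -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def patterns(self):
        """(pattern_codes (n_seq, n_patterns), multiplicities (n_patterns,))."""
        if self._patterns is None:
            pat, counts = np.unique(self.codes, axis=1, return_counts=True)
            self._patterns = (pat, counts.astype(np.int64))
        return self._patterns

    def __eq__(self, other):
        return (isinstance(other, MSA) and self.labels == other.labels
                and np.array_equal(self.codes, other.codes))


# ---------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Category rates: means of the k equal-probability bins of Gamma(a, a).

    Returned rates average exactly 1.  k=1 collapses to the homogeneous
    model (rate 1) regardless of alpha.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"alpha must be a positive finite number, got {alpha}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    # bin boundaries at quantiles i/k of Gamma(shape=a, scale=1/a)
    q = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    q = np.concatenate([[0.0], q, [np.inf]])
    # E[X; bin] = F_{a+1}(q_hi) - F_{a+1}(q_lo) for mean-1 gamma
    cdf1 = np.where(np.isinf(q), 1.0, gammainc(alpha + 1.0, alpha * q))
    rates = k * np.diff(cdf1)
    return rates / rates.mean()


@dataclass(eq=False)
class SubstModel:
    """Reversible amino-acid substitution model with +I and discrete +G."""

    name: str
    exchange: np.ndarray          # (20, 20) symmetric, zero diagonal
    freqs: np.ndarray             # (20,), sums to 1
    alpha: float = 1.0
    k: int = 4
    p_inv: float = 0.0

    def __post_init__(self):
        self.exchange = np.asarray(self.exchange, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.exchange.shape != (20, 20):
            raise ValueError("exchange must be 20x20")
        if not np.allclose(self.exchange, self.exchange.T):
            raise ValueError("exchange matrix must be symmetric")
        if abs(self.freqs.sum() - 1.0) > 1e-6 or (self.freqs <= 0).any():
            raise ValueError("frequencies must be positive and sum to 1")
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError("alpha must be positive and finite")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self._spectral = None

    # -- constructors --------------------------------------------------

    @classmethod
    def jtt(cls, alpha: float = 1.0, k: int = 4, p_inv: float = 0.0) -> "SubstModel":
        s = np.zeros((20, 20))
        idx = 0
        # column-major lower triangle: (2,1),(3,1),...,(20,1),(3,2),...
        for j in range(19):
            for i in range(j + 1, 20):
                s[i, j] = s[j, i] = JTT_LOWER[idx]
                idx += 1
        f = np.array(JTT_FREQS)
        return cls("JTT", s, f / f.sum(), alpha, k, p_inv)

    @classmethod
    def poisson(cls, alpha: float = 1.0, k: int = 1, p_inv: float = 0.0) -> "SubstModel":
        """Equal rates, equal frequencies: the closed-form-testable model."""
        s = np.ones((20, 20)) - np.eye(20)
        return cls("Poisson", s, np.full(20, 0.05), alpha, k, p_inv)

    def with_rates(self, alpha: float = None, p_inv: float = None) -> "SubstModel":
        m = replace(self,
                    alpha=self.alpha if alpha is None else float(alpha),
                    p_inv=self.p_inv if p_inv is None else float(p_inv))
        m._spectral = self._spectral  # rate matrix unchanged
        return m

    # -- derived quantities --------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        """Q scaled so the expected substitution rate at equilibrium is 1."""
        q = self.exchange * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        return q / mu

    def spectral(self):
        """(eigenvalues, V, Vinv) with P(t) = V @ diag(exp(lam t)) @ Vinv."""
        if self._spectral is None:
            q = self.rate_matrix()
            sq = np.sqrt(self.freqs)
            b = q * (sq[:, None] / sq[None, :])   # similar symmetric matrix
            lam, w = np.linalg.eigh((b + b.T) / 2)
            v = w / sq[:, None]
            vinv = w.T * sq[None, :]
            self._spectral = (lam, v, vinv)
        return self._spectral

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        lam, v, vinv = self.spectral()
        p = (v * np.exp(lam * (t * rate))[None, :]) @ vinv
        return np.clip(p, 0.0, None)

    def category_rates(self) -> np.ndarray:
        """Effective rates of the variable-site categories (mixture mean 1 with +I)."""
        r = discrete_gamma_rates(self.alpha, self.k)
        if self.p_inv > 0:
            r = r / (1.0 - self.p_inv)
        return r


# ---------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------

_LEAF_PARTIAL = np.vstack([np.eye(20), np.ones((1, 20))])  # code -> partial row


class PartialLeafData:
    """Leaf observations given as precomputed conditional-likelihood arrays.

    Used by the OTU-reduced evaluation mode: each "leaf" is a whole OTU
    subtree whose inside partial (one (k, n_patterns, 20) array, at
    fixed within-OTU branch lengths and rates) was extracted from a
    reference fit.  ``counts`` and ``l0`` come from the full alignment,
    so totals equal the full-tree log-likelihood with those subtree
    branch lengths held fixed.
    """

    def __init__(self, partials: dict, counts, l0):
        self.partials = dict(partials)
        self.labels = list(self.partials)
        self.counts = np.asarray(counts)
        self.l0 = np.asarray(l0, dtype=float)
        shapes = {p.shape for p in self.partials.values()}
        if len(shapes) != 1:
            raise ValueError("all leaf partials must share one shape")
        if next(iter(shapes))[1] != self.counts.shape[0]:
            raise ValueError("partial pattern axis must match counts")
        self._cast = {}

    def partials_as(self, dtype) -> dict:
        """Per-dtype cast of the partial arrays, cached (shared by engines)."""
        key = np.dtype(dtype).name
        if key not in self._cast:
            self._cast[key] = {l: np.ascontiguousarray(p, dtype=dtype)
                               for l, p in self.partials.items()}
        return self._cast[key]


class LikelihoodEngine:
    """Pruning likelihood and branch optimization for one topology.

    Nodes are indexed in postorder; the display root (index ``n-1``) has
    no branch.  Branch lengths live in ``self.bl`` indexed by node.
    """

    def __init__(self, tree: Tree, msa, model: SubstModel,
                 default_bl: float = 0.1, opt_dtype=np.float32):
        nodes = tree.postorder()
        labels = set(msa.labels)
        tree_labels = [v.label for v in nodes if v.is_leaf]
        if set(tree_labels) != labels:
            raise TreeError(
                f"tree leaves do not match alignment rows: "
                f"{sorted(set(tree_labels) ^ labels)}")
        self.model = model
        self.n_nodes = len(nodes)
        self.root = self.n_nodes - 1
        self.children = [[] for _ in nodes]
        self.parent = np.full(self.n_nodes, -1)
        index = {id(v): i for i, v in enumerate(nodes)}
        self.bl = np.full(self.n_nodes, float(default_bl))
        self.leaf_of = {}
        for i, v in enumerate(nodes):
            for c in v.children:
                j = index[id(c)]
                self.children[i].append(j)
                self.parent[j] = i
            if v.length is not None:
                self.bl[i] = min(max(v.length, BL_MIN), BL_MAX)
            if v.is_leaf:
                self.leaf_of[i] = v.label
        self._node_order = nodes  # postorder template, reused for export
        if len(self.children[self.root]) < 2:
            raise TreeError("display root must have at least two children")

        if isinstance(msa, MSA):
            pat, counts = msa.patterns
            row = {l: r for r, l in enumerate(msa.labels)}
            self.pat = {i: pat[row[lab]] for i, lab in self.leaf_of.items()}
            self.part = {}
            self.counts = counts.astype(float)
            self.n_pat = pat.shape[1]
            # invariant-class likelihood: sum of pi over states compatible
            # with every (non-ambiguous) observation in the pattern
            allow = np.ones((self.n_pat, 20))
            for i in self.pat:
                allow *= _LEAF_PARTIAL[self.pat[i]]
            self.l0 = allow @ model.freqs
        else:  # PartialLeafData: leaves carry precomputed partial arrays
            self.pat = {}
            self._part_data = msa
            self.part = {i: lab for i, lab in self.leaf_of.items()}
            self.counts = msa.counts.astype(float)
            self.n_pat = int(self.counts.shape[0])
            self.l0 = msa.l0
        self.n_sites = int(self.counts.sum())

        self._down = [None] * self.n_nodes   # inside partials, (k, npat, 20)
        self._msg = [None] * self.n_nodes    # inside message through own branch
        self._leaf_cache = {}
        self._cur_dtype = None
        self.opt_dtype = np.dtype(opt_dtype)
        self._set_rates(model.alpha, model.p_inv)

    # -- model-rate plumbing -------------------------------------------

    def _set_rates(self, alpha, p_inv):
        self.alpha = float(alpha)
        self.p_inv = float(p_inv)
        m = self.model
        r = discrete_gamma_rates(self.alpha, m.k)
        if self.p_inv > 0:
            r = r / (1.0 - self.p_inv)
        self.rates = r
        self.w_var = (1.0 - self.p_inv) / m.k
        self.lam, self.v, self.vinv = m.spectral()
        self.vinv_t = np.ascontiguousarray(self.vinv.T)
        # per-dtype casts of the model constants, cached for the hot loops
        self._const = {}
        for dt in (np.dtype(np.float64), self.opt_dtype):
            self._const[dt] = {
                "v": self.v.astype(dt), "vinv_t": self.vinv_t.astype(dt),
                "freqs": m.freqs.astype(dt), "l0": self.l0.astype(dt),
                "tiny": float(np.finfo(dt).tiny),
            }

    def _pmats_t(self, t: float, dtype=np.float64) -> np.ndarray:
        """Transposed transition kernels P(t)^T for one branch: (k, 20, 20)."""
        e = np.exp(np.outer(self.rates * t, self.lam))
        pt = (self.vinv_t[None, :, :] * e[:, None, :]) @ self.v.T
        pt = np.clip(pt, 0.0, None, out=pt)
        return pt if dtype == np.float64 else pt.astype(dtype)

    def _pmats_t_ext(self, t: float, dtype) -> np.ndarray:
        """P(t)^T with a 21st all-ones row: message of a coded leaf is a
        row gather ``pt_ext[codes]`` (one-hot partials; code 20 = ambiguous,
        whose message is the row sum of P = 1)."""
        pt = self._pmats_t(t, np.float64)
        ext = np.concatenate([pt, np.ones((pt.shape[0], 1, 20))], axis=1)
        return ext if dtype == np.float64 else ext.astype(dtype)

    def _pmats(self, t: float, dtype=np.float64) -> np.ndarray:
        """Transition kernels for one branch, all categories: (k, 20, 20)."""
        e = np.exp(np.outer(self.rates * t, self.lam))
        p = (self.v[None, :, :] * e[:, None, :]) @ self.vinv
        return p if dtype == np.float64 else p.astype(dtype)

    # -- pruning -------------------------------------------------------

    def _leaf_partial(self, i, dtype):
        key = (i, np.dtype(dtype).name)
        if key not in self._leaf_cache:
            k = len(self.rates)
            base = _LEAF_PARTIAL.astype(dtype)[self.pat[i]]
            self._leaf_cache[key] = np.broadcast_to(base, (k, self.n_pat, 20))
        return self._leaf_cache[key]

    def _down_pass(self, dtype=np.float64):
        self._cur_dtype = np.dtype(dtype)
        for i in range(self.n_nodes):
            coded_leaf = i in self.leaf_of and i not in self.part
            if i in self.leaf_of:
                if coded_leaf:
                    self._down[i] = self._leaf_partial(i, dtype)
                else:
                    cast = self._part_data.partials_as(dtype)
                    self._down[i] = cast[self.part[i]]
            else:
                d = None
                for c in self.children[i]:
                    d = self._msg[c] if d is None else d * self._msg[c]
                self._down[i] = d
            if i != self.root:
                if coded_leaf:
                    pt = self._pmats_t_ext(self.bl[i], dtype)
                    self._msg[i] = pt[:, self.pat[i], :]
                else:
                    pt = self._pmats_t(self.bl[i], dtype)
                    self._msg[i] = self._down[i] @ pt

    def _site_lik(self) -> np.ndarray:
        cst = self._const[self._cur_dtype]
        lc = self._down[self.root] @ cst["freqs"]
        s = self.w_var * lc.sum(axis=0)
        if self.p_inv > 0:
            s = s + self.p_inv * cst["l0"]
        return np.clip(s, cst["tiny"], None)

    def site_loglik(self) -> np.ndarray:
        """Per-pattern log-likelihood (float64) at the current lengths/rates."""
        self._down_pass(np.float64)
        return np.log(self._site_lik())

    def loglik(self) -> float:
        return float(self.counts @ self.site_loglik())

    def _sweep_loglik(self) -> float:
        """Total logL in the optimization dtype (cheap, lower precision)."""
        self._down_pass(self.opt_dtype)
        return float(self.counts @ np.log(self._site_lik()))

    # -- branch optimization -------------------------------------------

    def _up_pass(self):
        """Outside partials W[v] (function of the parent state), preorder."""
        k = len(self.rates)
        out = [None] * self.n_nodes
        w = [None] * self.n_nodes
        out[self.root] = np.broadcast_to(
            self._const[self._cur_dtype]["freqs"], (k, self.n_pat, 20))
        for i in range(self.n_nodes - 1, -1, -1):  # preorder = reverse postorder
            if i in self.leaf_of:
                continue
            kids = self.children[i]
            for c in kids:
                acc = out[i]
                for s in kids:
                    if s != c:
                        acc = acc * self._msg[s]
                w[c] = acc
                if c not in self.leaf_of:
                    out[c] = w[c] @ self._pmats(self.bl[c], self._cur_dtype)
        self._up = w

    def _newton_buffers(self, nb, k, dt):
        key = (nb, k, np.dtype(dt).name)
        if getattr(self, "_nbuf_key", None) != key:
            self._nbuf_key = key
            self._nbuf = {
                "a": np.empty((nb, k, self.n_pat, 20), dtype=dt),
                "d": np.empty((nb, k, self.n_pat, 20), dtype=dt),
            }
        return self._nbuf

    def _newton_all_branches(self, idx=None, max_iter: int = 6) -> np.ndarray:
        """One parallel Newton update of the given branches from cached partials.

        All branches are updated from the same inside/outside partials
        (a "stale" parallel sweep); the caller re-checks the total logL
        and damps if the joint step overshoots.  Safeguarded by per-
        branch bisection brackets on [BL_MIN, BL_MAX].
        """
        dt = self._cur_dtype
        cst = self._const[dt]
        if idx is None:
            idx = [i for i in range(self.n_nodes) if i != self.root]
        nb = len(idx)
        k = len(self.rates)
        buf = self._newton_buffers(nb, k, dt)
        for b, i in enumerate(idx):
            np.matmul(self._up[i], cst["v"], out=buf["a"][b])
            np.matmul(self._down[i], cst["vinv_t"], out=buf["d"][b])
        ad = np.multiply(buf["a"], buf["d"], out=buf["a"])  # (b, k, npat, 20)
        g = np.ascontiguousarray(ad.transpose(0, 2, 1, 3).reshape(
            nb, self.n_pat, k * 20))
        rl = (self.rates[:, None] * self.lam[None, :]).reshape(-1)
        rl_dt = rl.astype(dt)
        counts = self.counts.astype(dt)

        t = self.bl[idx].copy()
        lo = np.full(nb, BL_MIN)
        hi = np.full(nb, BL_MAX)
        for _ in range(max_iter):
            e = np.exp(np.multiply.outer(t, rl)).astype(dt)        # (b, 80)
            basis = np.stack([e, e * rl_dt, e * (rl_dt * rl_dt)], axis=2)
            l = g @ basis                                          # (b, npat, 3)
            s = self.w_var * l[..., 0]
            if self.p_inv > 0:
                s = s + self.p_inv * cst["l0"]
            s = np.clip(s, cst["tiny"], None)
            r1 = self.w_var * l[..., 1] / s
            f1 = (r1 @ counts).astype(np.float64)
            f2 = ((self.w_var * l[..., 2] / s - r1 * r1) @ counts
                  ).astype(np.float64)
            lo = np.where(f1 > 0, np.maximum(lo, t), lo)
            hi = np.where(f1 <= 0, np.minimum(hi, t), hi)
            # Newton step where curvature is usable (the per-branch profile
            # is unimodal in practice), clipped into the bisection bracket;
            # a step clipped to BL_MIN resolves boundary collapse in one go
            newton = t - f1 / np.where(f2 < 0, f2, 1.0)
            step = np.where(f2 < 0, np.clip(newton, lo, hi),
                            0.5 * (lo + hi))
            done = np.all(np.abs(step - t) <= 1e-6 * (1.0 + t))
            t = step
            if done:
                break
        out = self.bl.copy()
        out[idx] = np.clip(t, BL_MIN, BL_MAX)
        return out

    def optimize_branch_lengths(self, sweeps: int = 10, tol: float = 1e-4):
        """Cyclic Newton sweeps over all branches; returns the final logL.

        Sweeps run in the engine's optimization dtype (float32 by
        default, enough for branch lengths at the stated tolerances);
        call :meth:`loglik`/:meth:`site_loglik` afterwards for the
        float64 value.  A sweep that lowers the objective (possible
        because all branches update from the same cached partials) is
        damped toward the previous lengths, so the reported logL is
        non-decreasing over sweeps up to the dtype's resolution.
        """
        slack = max(tol * 0.1, float(np.finfo(self.opt_dtype).eps) * 100)
        ll = self._sweep_loglik()
        all_idx = [i for i in range(self.n_nodes) if i != self.root]
        active = all_idx
        for sweep in range(sweeps):
            self._up_pass()
            old_bl = self.bl.copy()
            self.bl = self._newton_all_branches(active)
            # freeze branches that have stopped moving (their remaining
            # logL contribution is below the sweep tolerance); the first
            # two sweeps always update everything
            if sweep >= 1:
                moved = np.abs(self.bl - old_bl) > 1e-4 * (0.01 + old_bl)
                active = [i for i in all_idx if moved[i]] or all_idx
            ll_new = self._sweep_loglik()
            tries = 0
            while ll_new < ll - slack and tries < 5:
                # stale-partial overshoot: damp toward the previous lengths
                self.bl = 0.5 * (self.bl + old_bl)
                ll_new = self._sweep_loglik()
                tries += 1
            if ll_new < ll - slack:
                self.bl = old_bl
                self._down_pass(self.opt_dtype)
                break
            improved = ll_new - ll
            ll = ll_new
            if improved < tol:
                break
        return ll

    # -- rate-parameter optimization -----------------------------------

    def optimize_rates(self, optimize_alpha=True, optimize_pinv=True) -> float:
        m = self.model
        optimize_alpha = optimize_alpha and m.k > 1
        if not (optimize_alpha or optimize_pinv):
            return self.loglik()

        def unpack(x):
            alpha, pinv = self.alpha, self.p_inv
            j = 0
            if optimize_alpha:
                alpha = math.exp(x[j]); j += 1
            if optimize_pinv:
                pinv = x[j]
            return alpha, pinv

        def neg(x):
            alpha, pinv = unpack(x)
            self._set_rates(alpha, pinv)
            return -self.loglik()

        x0, bounds = [], []
        if optimize_alpha:
            x0.append(math.log(self.alpha))
            bounds.append((math.log(ALPHA_MIN), math.log(ALPHA_MAX)))
        if optimize_pinv:
            x0.append(self.p_inv)
            bounds.append((0.0, PINV_MAX))
        res = sciopt.minimize(neg, np.array(x0), method="L-BFGS-B",
                              bounds=bounds,
                              options={"maxiter": 60, "ftol": 1e-9})
        alpha, pinv = unpack(res.x)
        self._set_rates(alpha, pinv)
        return self.loglik()

    # -- export --------------------------------------------------------

    def tree_with_lengths(self) -> Tree:
        t = Tree(self._node_order[-1]).copy()
        for i, v in enumerate(t.postorder()):
            v.length = None if i == self.root else float(self.bl[i])
        return t


@dataclass
class OptResult:
    tree: Tree
    alpha: float
    p_inv: float
    loglik: float
    converged: bool
    n_rounds: int
    site_loglik: np.ndarray = field(repr=False, default=None)
    pattern_counts: np.ndarray = field(repr=False, default=None)


def invariant_class_lik(msa: MSA, model: SubstModel) -> np.ndarray:
    """Per-pattern likelihood of the invariant class: sum of pi over the
    states compatible with every observation (gaps/X are wildcards)."""
    pat, _ = msa.patterns
    allow = np.ones((pat.shape[1], 20))
    for row in pat:
        allow *= _LEAF_PARTIAL[row]
    return allow @ model.freqs


def subtree_partials(root, leaf_codes: dict, model: SubstModel,
                     alpha: float = None, p_inv: float = None) -> np.ndarray:
    """Inside (conditional-likelihood) array of a subtree at its root.

    *root* is a tree node with branch lengths on all its descendants;
    ``leaf_codes`` maps each subtree leaf label to its pattern codes
    (one int8 row over the full pattern axis).  Returns (k, n_pat, 20)
    float64, one slice per rate category.
    """
    rates = discrete_gamma_rates(model.alpha if alpha is None else alpha,
                                 model.k)
    pv = model.p_inv if p_inv is None else p_inv
    if pv > 0:
        rates = rates / (1.0 - pv)
    lam, v, vinv = model.spectral()
    vinv_t = np.ascontiguousarray(vinv.T)

    def down(node):
        if node.is_leaf:
            codes = leaf_codes[node.label]
            d = np.broadcast_to(_LEAF_PARTIAL[codes],
                                (len(rates), codes.shape[0], 20))
        else:
            d = None
            for c in node.children:
                m = msg(c)
                d = m if d is None else d * m
        return d

    def msg(node):
        e = np.exp(np.outer(rates * node.length, lam))
        pt = (vinv_t[None, :, :] * e[:, None, :]) @ v.T
        return down(node) @ np.clip(pt, 0.0, None)

    return np.ascontiguousarray(down(root))


def site_loglik(tree: Tree, msa: MSA, model: SubstModel) -> np.ndarray:
    """Per-pattern log-likelihoods of *msa* on *tree* (lengths required).

    Pattern order matches ``msa.patterns``; the total log-likelihood is
    the dot product with the pattern multiplicities.
    """
    for v in tree.postorder()[:-1]:
        if v.length is None:
            raise TreeError("site_loglik requires branch lengths on every edge")
        if not np.isfinite(v.length) or v.length < 0:
            raise TreeError(f"invalid branch length {v.length}")
    return LikelihoodEngine(tree, msa, model).site_loglik()


def optimize_tree(tree: Tree, msa: MSA, model: SubstModel, *,
                  optimize_alpha: bool = True, optimize_pinv: bool = True,
                  tol: float = 1e-4, max_rounds: int = 20,
                  branch_sweeps: int = 3, default_bl: float = 0.1) -> OptResult:
    """Fit branch lengths (and optionally alpha, p_inv) on a fixed topology.

    Alternates Newton branch-length sweeps with bounded profile
    optimization of the rate parameters until the round-to-round logL
    gain drops below *tol* or *max_rounds* is hit (then the best-so-far
    fit is returned with ``converged=False``).  Deterministic for fixed
    inputs.
    """
    eng = LikelihoodEngine(tree, msa, model, default_bl=default_bl)
    do_rates = (optimize_alpha and model.k > 1) or optimize_pinv
    if not do_rates:
        # pure branch-length fit: one long sweep loop, internal convergence
        ll = eng.optimize_branch_lengths(sweeps=max_rounds * branch_sweeps,
                                         tol=tol)
        sl = eng.site_loglik()
        counts = eng.counts.copy()
        return OptResult(tree=eng.tree_with_lengths(), alpha=eng.alpha,
                         p_inv=eng.p_inv, loglik=float(counts @ sl),
                         converged=True, n_rounds=1,
                         site_loglik=sl, pattern_counts=counts)
    ll = eng.optimize_branch_lengths(sweeps=branch_sweeps, tol=tol)
    converged = False
    rounds = 1
    for rounds in range(1, max_rounds + 1):
        ll_round = ll
        ll = eng.optimize_rates(optimize_alpha, optimize_pinv)
        ll = eng.optimize_branch_lengths(sweeps=branch_sweeps, tol=tol)
        if ll - ll_round < tol:
            converged = True
            break
    sl = eng.site_loglik()
    counts = eng.counts.copy()
    return OptResult(tree=eng.tree_with_lengths(), alpha=eng.alpha,
                     p_inv=eng.p_inv, loglik=float(counts @ sl),
                     converged=converged, n_rounds=rounds,
                     site_loglik=sl, pattern_counts=counts)
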