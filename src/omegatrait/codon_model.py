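"""Codon substitution models, ML fitting, and selection tests.

Implements a GY94-style codon model (kappa for transition/transversion bias,
target-codon frequencies pi, omega = dN/dS on nonsynonymous changes) with a
Felsenstein-pruning likelihood over the 61 sense codons, and the model
hierarchy used to screen for selection on labeled foreground lineages:

* one-ratio: a single omega shared by all branches (null);
* two-ratio: separate foreground / background omega (branch model);
* free-ratio: an independent omega on every branch, from which per-branch
  dN and dS and root-to-tip omega averages are derived;
* branch-site model A: four site classes allowing omega2 >= 1 on the
  foreground only, with naive empirical-Bayes site posteriors.

Likelihood-ratio tests, Benjamini-Hochberg FDR correction and the decision
rules for rapidly evolving genes (REG) and positively selected genes (PSG)
live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests
from Bio.Data import CodonTable

from .trees_io import (
    CodonAlignment,
    PhyloTree,
    SENSE_CODONS,
    BACKGROUND,
    FOREGROUND,
)

# ------------------------------------------------------------ genetic code

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: amino acid encoded by each sense codon (standard code)
CODON_AA: tuple[str, ...] = tuple(_STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS)

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _neighbor_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ordered sense-codon pairs differing at exactly one nucleotide."""
    src, dst, ts, ns = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            src.append(i)
            dst.append(j)
            ts.append(_is_transition(ci[k], cj[k]))
            ns.append(CODON_AA[i] != CODON_AA[j])
    return (
        np.array(src),
        np.array(dst),
        np.array(ts, dtype=bool),
        np.array(ns, dtype=bool),
    )


_NB_SRC, _NB_DST, _NB_TS, _NB_NS = _neighbor_arrays()

# optimizer bounds (natural scale)
KAPPA_BOUNDS = (0.05, 50.0)
OMEGA_BOUNDS = (1e-4, 50.0)
T_BOUNDS = (1e-6, 20.0)
_LNL_TOL = 1e-4


class LikelihoodError(RuntimeError):
    """Non-finite likelihood (underflow or invalid parameters)."""


# ------------------------------------------------------------- rate matrix


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """GY94 generator over the 61 sense codons.

    ``q[i, j] = pi_j * kappa^[transition] * omega^[nonsynonymous]`` for codon
    pairs differing at one nucleotide, zero otherwise; the diagonal makes
    rows sum to zero.  When ``scale`` is set the matrix is rescaled so the
    expected substitution rate at stationarity, ``-sum_i pi_i q_ii``, is 1,
    i.e. branch lengths are in expected substitutions per codon.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (61,):
        raise ValueError("pi must have 61 entries")
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    rates = pi[_NB_DST] * np.where(_NB_TS, kappa, 1.0) * np.where(_NB_NS, omega, 1.0)
    Q = np.zeros((61, 61))
    Q[_NB_SRC, _NB_DST] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -float(pi @ np.diag(Q))
        if mu <= 0:
            raise LikelihoodError("degenerate rate matrix (zero mean rate)")
        Q /= mu
    return Q


class CodonRateModel:
    """A (kappa, omega, pi) rate matrix with cached spectral decomposition.

    The GY94 chain is reversible, so ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``
    is symmetric and transition matrices for any branch length come from a
    single symmetric eigendecomposition.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray) -> None:
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.pi = np.asarray(pi, dtype=float)
        self.Q = build_rate_matrix(kappa, omega, self.pi)
        sqrt_pi = np.sqrt(self.pi)
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        evals, evecs = eigh((B + B.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]      # D^-1/2 U
        self._right = (evecs * sqrt_pi[:, None]).T  # U^T D^1/2

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P


# --------------------------------------------------- codon frequency models


def estimate_pi(aln: CodonAlignment, mode: str = "f3x4") -> np.ndarray:
    """Equilibrium codon frequencies from the alignment.

    ``f3x4`` (default, the codeml convention): product of position-specific
    nucleotide frequencies, renormalized over sense codons.  ``f61``:
    empirical codon frequencies with a half-count pseudocount.  ``uniform``:
    1/61 everywhere.
    """
    if mode == "uniform":
        return np.full(61, 1.0 / 61.0)
    obs = aln.codons[aln.codons >= 0]
    if mode == "f61":
        counts = np.bincount(obs, minlength=61).astype(float) + 0.5
        return counts / counts.sum()
    if mode == "f3x4":
        nuc_counts = np.full((3, 4), 0.25)  # Laplace-style guard against zeros
        nuc_index = {"A": 0, "C": 1, "G": 2, "T": 3}
        codon_nucs = np.array(
            [[nuc_index[c[k]] for k in range(3)] for c in SENSE_CODONS]
        )
        for pos in range(3):
            nuc_counts[pos] += np.bincount(codon_nucs[obs, pos], minlength=4)
        f = nuc_counts / nuc_counts.sum(axis=1, keepdims=True)
        pi = f[0, codon_nucs[:, 0]] * f[1, codon_nucs[:, 1]] * f[2, codon_nucs[:, 2]]
        return pi / pi.sum()
    raise ValueError(f"unknown codon frequency mode {mode!r}")


# ------------------------------------------------------------ params types


@dataclass
class CodonModelParams:
    """Fitted parameterization of a codon model on a tree.

    ``branch_omega`` maps non-root node index -> omega for that branch;
    ``t`` holds expected substitutions per codon for each branch (indexed by
    node; the root entry is unused).
    """

    kappa: float
    pi: np.ndarray
    branch_omega: dict[int, float]
    t: np.ndarray

    def omega_for(self, node: int) -> float:
        return self.branch_omega[node]


@dataclass
class FitResult:
    params: CodonModelParams
    lnL: float
    converged: bool
    model: str
    extras: dict = field(default_factory=dict)

    @property
    def omega(self) -> float:
        """Single omega for one-ratio fits."""
        vals = set(self.params.branch_omega.values())
        if len(vals) != 1:
            raise ValueError("omega is not shared across branches in this fit")
        return next(iter(vals))


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested codon models."""

    lnL0: float
    lnL1: float
    df: int
    stat: float
    p: float
    p_adj: float | None = None


@dataclass
class SiteClassPosterior:
    """Per-codon-site posterior over the four branch-site model A classes.

    ``class_posterior`` has shape (n_sites, 4) in the class order
    (0, 1, 2a, 2b); ``positive`` is the per-site posterior probability of
    the positively selected classes (2a + 2b).
    """

    class_posterior: np.ndarray
    positive: np.ndarray

    def selected_sites(self, threshold: float = 0.8) -> list[int]:
        """1-based codon columns whose positive-class posterior exceeds threshold."""
        return [int(i) + 1 for i in np.flatnonzero(self.positive > threshold)]


# -------------------------------------------------------------- likelihood


def _pattern_compress(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique columns, their multiplicities, and column -> pattern index."""
    patterns, inverse, counts = np.unique(
        aln.codons, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse


def _site_log_likelihoods(
    tree: PhyloTree,
    patterns: np.ndarray,
    taxon_row: dict[int, int],
    P: dict[int, np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    """Felsenstein pruning over unique site patterns with per-node scaling.

    ``P[v]`` is the transition matrix on the branch above node ``v``;
    ``taxon_row[tip_node]`` indexes the pattern matrix row for that tip.
    Returns per-pattern log-likelihoods.
    """
    npat = patterns.shape[1]
    log_scale = np.zeros(npat)
    contrib: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if not tree.children[v]:
            states = patterns[taxon_row[v]]
            up = np.ones((61, npat))
            obs = states >= 0
            up[:, obs] = P[v][:, states[obs]]
            contrib[v] = up
        else:
            partial = np.ones((61, npat))
            for c in tree.children[v]:
                partial *= contrib.pop(c)
            m = partial.max(axis=0)
            if np.any(m <= 0):
                raise LikelihoodError("site likelihood underflow to zero")
            partial /= m
            log_scale += np.log(m)
            if v == tree.root:
                site_L = pi @ partial
                return np.log(site_L) + log_scale
            contrib[v] = P[v] @ partial
    raise AssertionError("tree has no root partial")  # pragma: no cover


def log_likelihood(
    aln: CodonAlignment, tree: PhyloTree, params: CodonModelParams
) -> float:
    """Log-likelihood of the alignment under a fitted codon model."""
    missing = set(aln.taxa) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"alignment taxa not in tree: {sorted(missing)}")
    patterns, weights, _ = _pattern_compress(aln)
    taxon_row = {tree.tip_index(t): r for r, t in enumerate(aln.taxa)}
    models: dict[float, CodonRateModel] = {}
    P: dict[int, np.ndarray] = {}
    for v in tree.branch_indices():
        w = params.branch_omega[v]
        if w not in models:
            models[w] = CodonRateModel(params.kappa, w, params.pi)
        P[v] = models[w].transition_matrix(float(params.t[v]))
    site = _site_log_likelihoods(tree, patterns, taxon_row, P, params.pi)
    lnL = float(weights @ site)
    if not np.isfinite(lnL):
        raise LikelihoodError("non-finite log-likelihood")
    return lnL


# ------------------------------------------------------------------ fitting


class _Problem:
    """Shared state for the optimizers: compressed data and tree indexing.

    Besides the plain pruning likelihood it implements the inside/outside
    two-pass scheme: ``up_pass`` stores the subtree ("inside") partials and
    the per-branch messages, ``down_pass`` the complementary "outside"
    vectors B_v, from which the branch-length gradient dlnL/dt_v =
    sum_s w_s (B_v . Q up_v) / (B_v . up_v) and cheap one-branch parameter
    perturbations follow without re-pruning the whole tree.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree, pi_mode: str):
        self.tree = tree
        self.patterns, self.weights, self.inverse = _pattern_compress(aln)
        self.taxon_row = {tree.tip_index(t): r for r, t in enumerate(aln.taxa)}
        self.pi = estimate_pi(aln, pi_mode)
        self.branches = tree.branch_indices()

    def site_loglik(self, P: dict[int, np.ndarray]) -> np.ndarray:
        return _site_log_likelihoods(self.tree, self.patterns, self.taxon_row, P, self.pi)

    def loglik(self, P: dict[int, np.ndarray]) -> float:
        return float(self.weights @ self.site_loglik(P))

    def _tip_up(self, v: int, P_v: np.ndarray) -> np.ndarray:
        states = self.patterns[self.taxon_row[v]]
        up = np.ones((61, self.patterns.shape[1]))
        obs = states >= 0
        up[:, obs] = P_v[:, states[obs]]
        return up

    def up_pass(self, P: dict[int, np.ndarray]):
        """Inside pass keeping all messages: (site lnL, ups, internal partials)."""
        tree = self.tree
        npat = self.patterns.shape[1]
        log_scale = np.zeros(npat)
        ups: dict[int, np.ndarray] = {}
        partials: dict[int, np.ndarray] = {}
        site_ll = None
        for v in tree.postorder:
            if not tree.children[v]:
                ups[v] = self._tip_up(v, P[v])
            else:
                part = np.ones((61, npat))
                for c in tree.children[v]:
                    part = part * ups[c]
                m = part.max(axis=0)
                if np.any(m <= 0):
                    raise LikelihoodError("site likelihood underflow to zero")
                part /= m
                log_scale += np.log(m)
                partials[v] = part
                if v == tree.root:
                    site_ll = np.log(self.pi @ part) + log_scale
                else:
                    ups[v] = P[v] @ part
        return site_ll, ups, partials

    def down_pass(self, P: dict[int, np.ndarray], ups: dict[int, np.ndarray]):
        """Outside vectors B_v (at the parent-side end of each branch)."""
        tree = self.tree
        B: dict[int, np.ndarray] = {}
        A: dict[int, np.ndarray] = {tree.root: self.pi[:, None]}
        for v in tree.preorder:
            kids = tree.children[v]
            if not kids:
                continue
            k = len(kids)
            # prefix/suffix products of the children's up-messages
            prefix = [None] * k
            acc = None
            for i, c in enumerate(kids):
                prefix[i] = acc
                acc = ups[c] if acc is None else acc * ups[c]
            suffix = None
            for i in range(k - 1, -1, -1):
                c = kids[i]
                other = prefix[i]
                if suffix is not None:
                    other = suffix if other is None else other * suffix
                Bc = A[v] * (other if other is not None else 1.0)
                if other is None:  # single child
                    Bc = A[v] * np.ones_like(ups[c])
                B[c] = Bc
                suffix = ups[c] if suffix is None else suffix * ups[c]
                if tree.children[c]:
                    Ac = P[c].T @ B[c]
                    m = Ac.max(axis=0)
                    m[m <= 0] = 1.0
                    A[c] = Ac / m
        return B


def _log_bounds(bounds: tuple[float, float]) -> tuple[float, float]:
    return (np.log(bounds[0]), np.log(bounds[1]))


def _init_lengths(tree: PhyloTree) -> np.ndarray:
    t0 = np.clip(tree.length, 1e-3, 5.0)
    return t0


def fit_one_ratio(
    aln: CodonAlignment,
    tree: PhyloTree,
    pi_mode: str = "f3x4",
    n_restarts: int = 1,
    seed: int = 0,
    maxiter: int = 500,
) -> FitResult:
    """ML fit of the single-omega model; branch lengths are co-estimated.

    The input tree's branch lengths (clipped to a sensible range) seed the
    optimizer, so passing a tree in expected-substitution units speeds
    convergence.  Additional restarts perturb the starting point.
    """
    prob = _Problem(aln, tree, pi_mode)
    B = prob.branches
    rng = np.random.default_rng(seed)
    t_init = _init_lengths(tree)
    h = 1e-4  # central-difference step for the two global log-parameters

    def value_and_grad(x: np.ndarray):
        kappa, omega = np.exp(x[0]), np.exp(x[1])
        t = np.exp(x[2:])
        model = CodonRateModel(kappa, omega, prob.pi)
        P = {v: model.transition_matrix(t[k]) for k, v in enumerate(B)}
        site_ll, ups, _ = prob.up_pass(P)
        f = float(prob.weights @ site_ll)
        Bout = prob.down_pass(P, ups)
        grad = np.empty_like(x)
        for k, v in enumerate(B):
            denom = (Bout[v] * ups[v]).sum(axis=0)
            numer = (Bout[v] * (model.Q @ ups[v])).sum(axis=0)
            grad[2 + k] = float(prob.weights @ (numer / denom)) * t[k]
        for slot, (kp, wp) in enumerate(
            [((kappa * np.exp(h), omega), (kappa * np.exp(-h), omega)),
             ((kappa, omega * np.exp(h)), (kappa, omega * np.exp(-h)))]
        ):
            mp = CodonRateModel(*kp, prob.pi)
            mm = CodonRateModel(*wp, prob.pi)
            lp = prob.loglik({v: mp.transition_matrix(t[k]) for k, v in enumerate(B)})
            lm = prob.loglik({v: mm.transition_matrix(t[k]) for k, v in enumerate(B)})
            grad[slot] = (lp - lm) / (2 * h)
        return -f, -grad

    bounds = [_log_bounds(KAPPA_BOUNDS), _log_bounds(OMEGA_BOUNDS)] + [
        _log_bounds(T_BOUNDS)
    ] * len(B)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            x0 = np.concatenate(
                [[np.log(2.0), np.log(0.4)], np.log([t_init[v] for v in B])]
            )
        else:
            x0 = np.concatenate(
                [
                    [np.log(rng.uniform(0.5, 5.0)), np.log(rng.uniform(0.05, 2.0))],
                    np.log(np.clip([t_init[v] for v in B] * rng.uniform(0.3, 3.0, len(B)), *T_BOUNDS)),
                ]
            )
        res = minimize(value_and_grad, x0, method="L-BFGS-B", jac=True, bounds=bounds,
                       options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    kappa, omega = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    t = np.zeros(tree.n_nodes)
    for k, v in enumerate(B):
        t[v] = np.exp(best.x[2 + k])
    params = CodonModelParams(kappa, prob.pi, {v: omega for v in B}, t)
    return FitResult(params, -float(best.fun), bool(best.success), "one_ratio")


def fit_two_ratio(
    aln: CodonAlignment,
    tree: PhyloTree,
    one_ratio: FitResult | None = None,
    pi_mode: str = "f3x4",
    reestimate_lengths: bool = False,
    maxiter: int = 300,
) -> FitResult:
    """ML fit of the branch (two-ratio) model on a labeled tree.

    Branch lengths are fixed at the one-ratio MLEs (refit them with
    ``reestimate_lengths``); kappa and the two omegas are re-optimized from
    the one-ratio solution, which guarantees the nested log-likelihood
    ordering lnL_two >= lnL_one.
    """
    if one_ratio is None:
        one_ratio = fit_one_ratio(aln, tree, pi_mode=pi_mode)
    prob = _Problem(aln, tree, pi_mode)
    B = prob.branches
    classes = tree.branch_class
    t_fix = one_ratio.params.t
    w_hat = one_ratio.omega

    def build_P(kappa, w_fg, w_bg, t):
        m_fg = CodonRateModel(kappa, w_fg, prob.pi)
        m_bg = CodonRateModel(kappa, w_bg, prob.pi)
        return {
            v: (m_fg if classes[v] == FOREGROUND else m_bg).transition_matrix(float(t[v]))
            for v in B
        }

    if reestimate_lengths:
        def objective(x):
            t = np.zeros(tree.n_nodes)
            for k, v in enumerate(B):
                t[v] = np.exp(x[3 + k])
            return -prob.loglik(build_P(np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), t))

        x0 = np.concatenate(
            [
                [np.log(one_ratio.params.kappa), np.log(w_hat), np.log(w_hat)],
                np.log(np.clip([t_fix[v] for v in B], *T_BOUNDS)),
            ]
        )
        bounds = (
            [_log_bounds(KAPPA_BOUNDS)] + [_log_bounds(OMEGA_BOUNDS)] * 2
            + [_log_bounds(T_BOUNDS)] * len(B)
        )
    else:
        def objective(x):
            return -prob.loglik(build_P(np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), t_fix))

        x0 = np.array([np.log(one_ratio.params.kappa), np.log(w_hat), np.log(w_hat)])
        bounds = [_log_bounds(KAPPA_BOUNDS)] + [_log_bounds(OMEGA_BOUNDS)] * 2
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter})
    kappa = float(np.exp(res.x[0]))
    w_fg, w_bg = float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    if reestimate_lengths:
        t = np.zeros(tree.n_nodes)
        for k, v in enumerate(B):
            t[v] = np.exp(res.x[3 + k])
    else:
        t = t_fix.copy()
    branch_omega = {v: (w_fg if classes[v] == FOREGROUND else w_bg) for v in B}
    params = CodonModelParams(kappa, prob.pi, branch_omega, t)
    lnL = -float(res.fun)
    if lnL < one_ratio.lnL:  # flat alternative: keep the nested optimum
        lnL = one_ratio.lnL
        params = CodonModelParams(
            one_ratio.params.kappa, prob.pi, {v: w_hat for v in B}, t_fix.copy()
        )
        w_fg = w_bg = w_hat
    return FitResult(
        params, lnL, bool(res.success), "two_ratio",
        extras={"omega_fg": w_fg, "omega_bg": w_bg},
    )


def branch_dn_ds(
    kappa: float, omega: float, pi: np.ndarray, t: float
) -> tuple[float, float]:
    """Per-branch dN and dS from the fitted rate matrix.

    The substitution flux under the fitted matrix splits into nonsynonymous
    and synonymous shares rho_N + rho_S = 1; site proportions p_N, p_S come
    from the same matrix with omega set to 1 (the codeml-like convention).
    Then dN = t * rho_N / (3 p_N) and dS = t * rho_S / (3 p_S).
    """
    if t == 0:
        return 0.0, 0.0
    pi = np.asarray(pi, dtype=float)

    def flux_nonsyn_share(w: float) -> float:
        rates = pi[_NB_DST] * np.where(_NB_TS, kappa, 1.0) * np.where(_NB_NS, w, 1.0)
        flux = pi[_NB_SRC] * rates
        total = flux.sum()
        return float(flux[_NB_NS].sum() / total) if total > 0 else 0.0

    rho_n = flux_nonsyn_share(omega)
    rho_s = 1.0 - rho_n
    p_n = flux_nonsyn_share(1.0)
    p_s = 1.0 - p_n
    dN = t * rho_n / (3.0 * p_n) if p_n > 0 else 0.0
    dS = t * rho_s / (3.0 * p_s) if p_s > 0 else 0.0
    return dN, dS


@dataclass
class BranchRates:
    """Per-branch free-ratio estimates: omega, t, dN, dS.

    ``table`` is indexed by non-root node index with columns
    (omega, t, dN, dS, reliable); branches with near-zero length keep an
    omega estimate but are flagged unreliable.
    """

    table: pd.DataFrame
    kappa: float
    pi: np.ndarray
    lnL: float

    def omega(self, node: int) -> float:
        return float(self.table.loc[node, "omega"])


def fit_free_ratio(
    aln: CodonAlignment,
    tree: PhyloTree,
    one_ratio: FitResult | None = None,
    pi_mode: str = "f3x4",
    maxiter: int = 400,
    min_reliable_t: float = 1e-5,
) -> BranchRates:
    """ML fit of an independent omega on every branch.

    Branch lengths are fixed at the one-ratio MLEs; kappa and all
    per-branch omegas are optimized jointly from that solution.
    """
    if one_ratio is None:
        one_ratio = fit_one_ratio(aln, tree, pi_mode=pi_mode)
    prob = _Problem(aln, tree, pi_mode)
    B = prob.branches
    t_fix = one_ratio.params.t
    h = 1e-4

    def _P_set(kappa: float, omegas: np.ndarray) -> dict[int, np.ndarray]:
        models: dict[float, CodonRateModel] = {}
        P = {}
        for k, v in enumerate(B):
            w = float(omegas[k])
            if w not in models:
                models[w] = CodonRateModel(kappa, w, prob.pi)
            P[v] = models[w].transition_matrix(float(t_fix[v]))
        return P

    def value_and_grad(x: np.ndarray):
        kappa = np.exp(x[0])
        omegas = np.exp(x[1:])
        P = _P_set(kappa, omegas)
        site_ll, ups, partials = prob.up_pass(P)
        f = float(prob.weights @ site_ll)
        Bout = prob.down_pass(P, ups)
        grad = np.empty_like(x)
        # per-branch omega: only that branch's matrix changes, so a local
        # central difference B_v . P'(omega +- h) partial_v suffices
        for k, v in enumerate(B):
            w = float(omegas[k])
            t_v = float(t_fix[v])
            denom = np.log((Bout[v] * ups[v]).sum(axis=0))
            diffs = []
            for sgn in (1.0, -1.0):
                mloc = CodonRateModel(kappa, w * np.exp(sgn * h), prob.pi)
                Ploc = mloc.transition_matrix(t_v)
                if prob.tree.children[v]:
                    up_loc = Ploc @ partials[v]
                else:
                    up_loc = prob._tip_up(v, Ploc)
                diffs.append(np.log((Bout[v] * up_loc).sum(axis=0)) - denom)
            grad[1 + k] = float(prob.weights @ (diffs[0] - diffs[1])) / (2 * h)
        lp = prob.loglik(_P_set(kappa * np.exp(h), omegas))
        lm = prob.loglik(_P_set(kappa * np.exp(-h), omegas))
        grad[0] = (lp - lm) / (2 * h)
        return -f, -grad

    x0 = np.concatenate(
        [[np.log(one_ratio.params.kappa)], np.full(len(B), np.log(one_ratio.omega))]
    )
    bounds = [_log_bounds(KAPPA_BOUNDS)] + [_log_bounds(OMEGA_BOUNDS)] * len(B)
    res = minimize(value_and_grad, x0, method="L-BFGS-B", jac=True, bounds=bounds,
                   options={"maxiter": maxiter})
    kappa = float(np.exp(res.x[0]))
    lnL = -float(res.fun)
    rows = {}
    for k, v in enumerate(B):
        w = float(np.exp(res.x[1 + k]))
        t = float(t_fix[v])
        dN, dS = branch_dn_ds(kappa, w, prob.pi, t)
        rows[v] = {
            "omega": w,
            "t": t,
            "dN": dN,
            "dS": dS,
            "reliable": t >= min_reliable_t,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if lnL < one_ratio.lnL:
        lnL = one_ratio.lnL
    return BranchRates(table=table, kappa=kappa, pi=prob.pi, lnL=lnL)


# ------------------------------------------------------------- branch-site

_BS_CLASSES = ("0", "1", "2a", "2b")


def _bs_proportions(u: float, v: float) -> np.ndarray:
    """(p0, p1, p2a, p2b) from the transformed pair u = p0+p1, v = p0/(p0+p1)."""
    p0, p1 = u * v, u * (1.0 - v)
    p2 = 1.0 - u
    return np.array([p0, p1, p2 * v, p2 * (1.0 - v)])


def fit_branch_site(
    aln: CodonAlignment,
    tree: PhyloTree,
    variant: str = "alternative",
    one_ratio: FitResult | None = None,
    pi_mode: str = "f3x4",
    maxiter: int = 300,
) -> FitResult:
    """Branch-site model A fit (null: omega2 = 1; alternative: omega2 >= 1).

    Site classes 0 (omega0 < 1 everywhere), 1 (neutral everywhere),
    2a (background omega0, foreground omega2) and 2b (background 1,
    foreground omega2), with proportions p0, p1, p2*p0/(p0+p1),
    p2*p1/(p0+p1).  kappa and branch lengths are fixed at the one-ratio
    MLEs.  The returned fit caches per-class site log-likelihoods for
    empirical-Bayes posteriors (:func:`site_posteriors`).
    """
    if variant not in ("null", "alternative"):
        raise ValueError(f"unknown branch-site variant {variant!r}")
    if not np.any(tree.branch_class == FOREGROUND):
        raise ValueError("branch-site model requires at least one foreground branch")
    if one_ratio is None:
        one_ratio = fit_one_ratio(aln, tree, pi_mode=pi_mode)
    prob = _Problem(aln, tree, pi_mode)
    B = prob.branches
    classes = tree.branch_class
    kappa = one_ratio.params.kappa
    t_fix = one_ratio.params.t

    def class_site_logliks(omega0: float, omega2: float) -> np.ndarray:
        """Rows: per-pattern log-likelihood under classes (0, 1, 2a, 2b)."""
        models = {w: CodonRateModel(kappa, w, prob.pi) for w in {omega0, 1.0, omega2}}
        P_cache = {
            (w, v): models[w].transition_matrix(float(t_fix[v]))
            for w in models
            for v in B
        }

        def P_for(bg_w: float, fg_w: float) -> dict[int, np.ndarray]:
            return {
                v: P_cache[(fg_w if classes[v] == FOREGROUND else bg_w, v)] for v in B
            }

        return np.vstack(
            [
                prob.site_loglik(P_for(omega0, omega0)),
                prob.site_loglik(P_for(1.0, 1.0)),
                prob.site_loglik(P_for(omega0, omega2)),
                prob.site_loglik(P_for(1.0, omega2)),
            ]
        )

    is_alt = variant == "alternative"

    def unpack(x):
        u, v = expit(x[0]), expit(x[1])
        omega0 = 1e-4 + (1.0 - 2e-4) * expit(x[2])
        omega2 = 1.0 + np.exp(x[3]) if is_alt else 1.0
        return u, v, omega0, omega2

    def objective(x):
        u, v, omega0, omega2 = unpack(x)
        props = _bs_proportions(u, v)
        ll = class_site_logliks(omega0, omega2)
        site = logsumexp(ll, axis=0, b=props[:, None].clip(1e-300))
        return -float(prob.weights @ site)

    # starting points: mostly-purifying, mostly-neutral, strong-selection
    # and near-boundary (omega2 ~ 1) mixtures
    if is_alt:
        starts = [
            np.array([2.0, 1.4, -2.2, 0.55]),
            np.array([0.4, 0.0, 0.0, -1.0]),
            np.array([1.4, 2.0, -1.4, np.log(3.0)]),
            np.array([2.0, 1.4, -2.2, -6.0]),  # near the omega2 = 1 boundary
        ]
    else:  # 3-parameter constrained fit: two starts suffice
        starts = [np.array([2.0, 1.4, -2.2]), np.array([0.4, 0.0, 0.0])]
    bounds = [(-12, 12), (-12, 12), (-12, 12)] + ([( -12, np.log(49.0))] if is_alt else [])
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    u, v, omega0, omega2 = unpack(best.x if is_alt else np.append(best.x, 0.0))
    props = _bs_proportions(u, v)
    ll = class_site_logliks(omega0, omega2)
    lnL = -float(best.fun)
    branch_omega = {
        x: (omega2 if classes[x] == FOREGROUND else omega0) for x in B
    }  # class-2a view; the mixture is in extras
    params = CodonModelParams(kappa, prob.pi, branch_omega, t_fix.copy())
    return FitResult(
        params,
        lnL,
        bool(best.success),
        f"branch_site_{variant}",
        extras={
            "omega0": omega0,
            "omega2": omega2,
            "proportions": props,
            "class_site_loglik": ll,
            "pattern_inverse": prob.inverse,
            "pattern_weights": prob.weights,
        },
    )


def site_posteriors(fit: FitResult) -> SiteClassPosterior:
    """Naive empirical-Bayes posteriors over branch-site classes at the MLEs."""
    if "class_site_loglik" not in fit.extras:
        raise ValueError("fit does not carry branch-site class likelihoods")
    ll = fit.extras["class_site_loglik"]
    props = np.clip(fit.extras["proportions"], 1e-300, None)
    logpost = np.log(props)[:, None] + ll
    logpost -= logsumexp(logpost, axis=0, keepdims=True)
    post_pat = np.exp(logpost)
    post = post_pat[:, fit.extras["pattern_inverse"]].T  # (n_sites, 4)
    return SiteClassPosterior(class_posterior=post, positive=post[:, 2] + post[:, 3])


# --------------------------------------------------------- tests and rules


def lrt(lnL0: float, lnL1: float, df: int) -> LRTResult:
    """Likelihood-ratio test: stat = 2(lnL1 - lnL0) against chi-square df.

    Negative statistics within optimizer tolerance are clamped to zero; a
    larger deficit raises a warning (the alternative failed to nest).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL1 - lnL0)
    if stat < -_LNL_TOL:
        warnings.warn(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; clamping LRT to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df))
    return LRTResult(lnL0=lnL0, lnL1=lnL1, df=df, stat=stat, p=p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def classify_reg(
    omega_fg: float,
    omega_bg: float,
    p_adj: float,
    alpha: float = 0.05,
    ratio_cutoff: float = 5.0,
    omega_floor: float = 0.5,
) -> tuple[bool, str | None]:
    """Rapidly-evolving-gene call from the two-ratio fit.

    A gene is a REG when the adjusted branch-test p-value is below alpha and
    either omega_fg / omega_bg > 5 (ratio clause; evaluated as +inf when
    omega_bg = 0 and omega_fg > 0) or omega_fg > 0.5 with omega_fg >
    omega_bg (elevated clause).  Both cutoffs are strict inequalities.
    Returns (is_reg, clause) where clause is "ratio", "elevated",
    "ratio+elevated" or None.
    """
    if omega_fg < 0 or omega_bg < 0:
        raise ValueError("omega values must be non-negative")
    ratio_fires = (
        omega_fg / omega_bg > ratio_cutoff if omega_bg > 0 else omega_fg > 0
    )
    elevated_fires = omega_fg > omega_floor and omega_fg > omega_bg
    significant = p_adj < alpha
    fired = []
    if ratio_fires:
        fired.append("ratio")
    if elevated_fires:
        fired.append("elevated")
    is_reg = significant and bool(fired)
    return is_reg, ("+".join(fired) if (is_reg and fired) else None)


def classify_psg(
    p_adj: float,
    posterior: SiteClassPosterior,
    alpha: float = 0.05,
    posterior_threshold: float = 0.8,
) -> tuple[bool, list[int]]:
    """Positively-selected-gene call: significant branch-site LRT (adjusted
    p < alpha) plus at least one codon with positive-class posterior above
    the threshold.  Returns (is_psg, selected 1-based codon columns)."""
    sites = posterior.selected_sites(posterior_threshold)
    return (p_adj < alpha and len(sites) > 0), sites
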