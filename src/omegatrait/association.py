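"""Root-to-tip omega aggregation and phenotype association.

The free-ratio fit gives each branch of a gene tree its own omega; the
root-to-tip omega of a species is the unweighted mean over the branches on
its root-to-tip path, after discarding branches whose dN or dS is below a
floor (default 2e-4) where the ratio is numerically meaningless.  Genes are
then screened for association between root-to-tip omega and the testicular
position encoding with phylogenetic generalized least squares (PGLS) under
Brownian-motion covariance, hardened by a two-step leave-one-species-out
calibration: p.all (all species), p.robust (drop the largest-residual
species), p.max (worst p over all single-species deletions).  A gene is
called significant when both p.all and p.max clear alpha, so no single
species can carry the association.

Group differences in gene-family expansion/contraction counts are tested
with a simulation-based phylogenetic ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import t as t_dist

from .codon_model import BranchRates
from .trees_io import PhyloTree

MIN_SPECIES = 4  # below this a PGLS fit is not attempted

DEFAULT_MIN_RATE = 2e-4  # dN/dS floor for root-to-tip averaging


@dataclass
class PglsFit:
    slope: float
    intercept: float
    t_stat: float
    p: float
    n: int
    residuals: pd.Series  # raw residuals y - X beta, indexed by species


@dataclass
class AssociationResult:
    """PGLS association of one gene's root-to-tip omega with the phenotype."""

    gene: str
    n: int
    slope: float
    t_stat: float
    p_all: float
    p_robust: float
    p_max: float
    significant: bool
    robust_dropped: str | None = None
    max_dropped: str | None = None
    skipped_reason: str | None = None
    loo_pvalues: dict[str, float] = field(default_factory=dict)


def root_to_tip_omega(
    branch_rates: BranchRates,
    tree: PhyloTree,
    min_rate: float = DEFAULT_MIN_RATE,
) -> pd.DataFrame:
    """Per-species mean omega over the root-to-tip path.

    Branches with dN < min_rate or dS < min_rate are excluded before
    averaging; a species whose entire path is filtered gets NaN.  Returns a
    DataFrame indexed by species with columns (omega, n_branches,
    n_excluded).
    """
    rows = {}
    for sp in tree.tip_labels:
        path = tree.root_to_tip_nodes(sp)
        used, excluded = [], 0
        for v in path:
            dN = float(branch_rates.table.loc[v, "dN"])
            dS = float(branch_rates.table.loc[v, "dS"])
            if dN >= min_rate and dS >= min_rate:
                used.append(float(branch_rates.table.loc[v, "omega"]))
            else:
                excluded += 1
        rows[sp] = {
            "omega": float(np.mean(used)) if used else np.nan,
            "n_branches": len(used),
            "n_excluded": excluded,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def pgls_fit(y: pd.Series, x: pd.Series, C: pd.DataFrame) -> PglsFit:
    """Generalized least squares of y on x under covariance C.

    beta = (X' C^-1 X)^-1 X' C^-1 y with an intercept; the slope's two-sided
    t test uses df = n - 2.  Implemented by Cholesky whitening; a singular C
    raises ValueError.
    """
    species = list(y.index)
    if list(x.index) != species or list(C.index) != species:
        x = x.loc[species]
        C = C.loc[species, species]
    n = len(species)
    if n < MIN_SPECIES:
        raise ValueError(f"need at least {MIN_SPECIES} species, got {n}")
    Cm = np.asarray(C, dtype=float)
    try:
        L = cholesky(Cm, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc
    X = np.column_stack([np.ones(n), np.asarray(x, dtype=float)])
    yv = np.asarray(y, dtype=float)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, yv, lower=True)
    XtX = Xw.T @ Xw
    try:
        beta = np.linalg.solve(XtX, Xw.T @ yw)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular design (constant predictor?)") from exc
    resid_w = yw - Xw @ beta
    df = n - 2
    sigma2 = float(resid_w @ resid_w) / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(max(cov_beta[1, 1], 0.0))
    if se == 0.0:
        t_stat = np.inf if beta[1] != 0 else 0.0
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        t_stat = float(beta[1] / se)
        p = float(2.0 * t_dist.sf(abs(t_stat), df))
    residuals = pd.Series(yv - X @ beta, index=species)
    return PglsFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        t_stat=t_stat,
        p=p,
        n=n,
        residuals=residuals,
    )


def calibrated_association(
    gene: str,
    x: pd.Series,
    y: pd.Series,
    C: pd.DataFrame,
    alpha: float = 0.05,
    require_robust: bool = False,
) -> AssociationResult:
    """Two-step calibrated PGLS association for one gene.

    x is the per-species root-to-tip omega (NaN = missing), y the numeric
    phenotype encoding.  p_all uses every usable species; p_robust refits
    after dropping the species with the largest absolute residual; p_max is
    the maximum p over all leave-one-species-out refits.  Significance
    requires p_all < alpha and p_max < alpha (and p_robust < alpha when
    ``require_robust``); refits that fall below the minimum species count
    contribute a conservative p = 1.
    """
    usable = [sp for sp in y.index if sp in x.index and np.isfinite(x.get(sp, np.nan))]
    if len(usable) < MIN_SPECIES:
        return AssociationResult(
            gene=gene, n=len(usable), slope=np.nan, t_stat=np.nan,
            p_all=np.nan, p_robust=np.nan, p_max=np.nan, significant=False,
            skipped_reason=f"only {len(usable)} species with usable omega",
        )
    xs, ys = x.loc[usable], y.loc[usable]
    Cs = C.loc[usable, usable]
    full = pgls_fit(ys, xs, Cs)

    def refit_without(sp: str) -> float:
        keep = [s for s in usable if s != sp]
        if len(keep) < MIN_SPECIES:
            return 1.0
        try:
            return pgls_fit(ys.loc[keep], xs.loc[keep], Cs.loc[keep, keep]).p
        except ValueError:
            return 1.0

    worst_sp = full.residuals.abs().idxmax()
    p_robust = refit_without(worst_sp)
    loo = {sp: refit_without(sp) for sp in usable}
    max_sp = max(loo, key=loo.get)
    p_max = loo[max_sp]
    significant = full.p < alpha and p_max < alpha
    if require_robust:
        significant = significant and p_robust < alpha
    return AssociationResult(
        gene=gene, n=full.n, slope=full.slope, t_stat=full.t_stat,
        p_all=full.p, p_robust=p_robust, p_max=p_max,
        significant=bool(significant),
        robust_dropped=worst_sp, max_dropped=max_sp, loo_pvalues=loo,
    )


def association_screen(
    omega_table: pd.DataFrame,
    y: pd.Series,
    C: pd.DataFrame,
    alpha: float = 0.05,
    require_robust: bool = False,
) -> pd.DataFrame:
    """Calibrated PGLS for every gene (rows of ``omega_table`` = genes,
    columns = species).  Returns a tidy results table."""
    rows = []
    for gene, xrow in omega_table.iterrows():
        res = calibrated_association(
            str(gene), xrow, y, C, alpha=alpha, require_robust=require_robust
        )
        rows.append(
            {
                "gene": res.gene,
                "n": res.n,
                "slope": res.slope,
                "t": res.t_stat,
                "p_all": res.p_all,
                "p_robust": res.p_robust,
                "p_max": res.p_max,
                "significant": res.significant,
                "robust_dropped": res.robust_dropped or "",
                "max_dropped": res.max_dropped or "",
                "skipped_reason": res.skipped_reason or "",
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------ phylogenetic ANOVA


def _anova_f(X: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Vectorized one-way ANOVA F for each row of X (n_sims x n_tips)."""
    k = len(group_idx)
    n = X.shape[1]
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for idx in group_idx:
        gm = X[:, idx].mean(axis=1)
        ssb += len(idx) * (gm - grand) ** 2
        ssw += ((X[:, idx] - gm[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n - k))
    return np.where(np.isfinite(F), F, 0.0)


def phyl_anova(
    tree: PhyloTree,
    values: pd.Series,
    groups: pd.Series,
    nsim: int = 1000,
    seed: int = 0,
    C: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Simulation-based phylogenetic ANOVA (phytools-style).

    The observed F is the ordinary one-way ANOVA statistic on tip values;
    the null distribution comes from ``nsim`` Brownian-motion simulations on
    the tree with rate set to the phylogenetically corrected variance of the
    observed tips.  p = (#{F_sim >= F_obs} + 1) / (nsim + 1).
    """
    species = [sp for sp in values.index if sp in set(groups.index)]
    vals = values.loc[species].astype(float)
    grp = groups.loc[species]
    labels = sorted(grp.unique())
    if len(labels) < 2:
        raise ValueError("phylogenetic ANOVA needs at least 2 groups")
    group_idx = []
    for g in labels:
        idx = np.flatnonzero((grp == g).to_numpy())
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 species")
        group_idx.append(idx)
    if C is None:
        from .trees_io import brownian_covariance

        C = brownian_covariance(tree, labels=species)
    Cm = np.asarray(C.loc[species, species], dtype=float)
    x = vals.to_numpy()
    n = len(x)
    F_obs = float(_anova_f(x[None, :], group_idx)[0])
    # phylogenetically corrected rate: GLS mean, then quadratic form
    cho = cho_factor(Cm, lower=True)
    ones = np.ones(n)
    Cinv_1 = cho_solve(cho, ones)
    mu = float(ones @ cho_solve(cho, x)) / float(ones @ Cinv_1)
    dev = x - mu
    sigma2 = float(dev @ cho_solve(cho, dev)) / (n - 1)
    rng = np.random.default_rng(seed)
    L = cholesky(sigma2 * Cm, lower=True)
    sims = rng.standard_normal((nsim, n)) @ L.T
    F_sim = _anova_f(sims, group_idx)
    p = (np.count_nonzero(F_sim >= F_obs) + 1) / (nsim + 1)
    return F_obs, float(p)
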