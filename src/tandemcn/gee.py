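"""Poisson regression with generalized estimating equations on a phylogeny.

Copy-number estimates of related lineages are not independent: lineages
sharing recent ancestry share repeat history.  When reproductive modes are
also phylogenetically clustered (asexuality arising in a few clades), a naive
regression of copy number on mode mistakes clade effects for mode effects.
The comparative GEE absorbs this by fitting a log-link quasi-Poisson model

    E[y_i] = exp(x_i' beta),   Var(y_i) = phi * mu_i,

with a fixed working correlation R derived from the tree: the covariance of
two tips is the shared root-to-MRCA path length, scaled by the tip depths so
the diagonal is 1.  The working correlation is held fixed across iterations
(the phylogeny is known, not estimated), and the whole cohort forms a single
correlated cluster, so inference uses the model-based covariance
phi * (D' V^{-1} D)^{-1}; a single-cluster sandwich estimate is also reported
for diagnostics but is rank-deficient by construction and is not used for
p-values.

The quasi-score equations are applied to the (non-integer) copy-number
estimates directly -- GEE needs only the mean-variance relationship, not
integer support.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats as sps


@dataclass
class GEEFit:
    """A fitted Poisson GEE: coefficients, uncertainties, diagnostics."""

    params: pd.Series
    se: pd.Series  # model-based standard errors (used for inference)
    se_robust: pd.Series  # single-cluster sandwich, diagnostic only
    zvalues: pd.Series
    pvalues: pd.Series
    dispersion: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        if self.converged:
            if not np.all(np.isfinite(self.params)):
                raise ValueError("converged fit has non-finite coefficients")
            if not np.all(self.se > 0):
                raise ValueError("converged fit has non-positive standard errors")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


def load_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def _tip_depths_and_mrca(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Shared root-to-MRCA path length for every tip pair (the phylo VCV)."""
    tree = tree.clone(depth=1)
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth
        edge = node.edge.length or 0.0
        node._depth = parent_depth + edge
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    # ancestor sets keyed by id; MRCA depth = max depth among shared ancestors
    paths = []
    for lf in leaves:
        anc = {}
        node = lf
        while node is not None:
            anc[id(node)] = node._depth
            node = node.parent_node
        paths.append(anc)
    n = len(leaves)
    cov = np.zeros((n, n))
    for i in range(n):
        cov[i, i] = paths[i][id(leaves[i])]
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            depth = max(paths[i][k] for k in shared)
            cov[i, j] = cov[j, i] = depth
    return labels, cov


def phylo_correlation(
    tree: dendropy.Tree, lineages: Sequence[str] | None = None
) -> pd.DataFrame:
    """Working correlation among lineages implied by shared ancestry.

    Entry (i, j) is the shared root-to-MRCA path length divided by the
    geometric mean of the two root-to-tip depths; the diagonal is exactly 1.
    The matrix is a Gram matrix of root-to-tip paths, hence positive
    semi-definite for any tree with non-negative branch lengths.
    """
    labels, cov = _tip_depths_and_mrca(tree)
    depths = np.diag(cov)
    if np.any(depths <= 0):
        bad = [l for l, d in zip(labels, depths) if d <= 0]
        raise ValueError(f"zero root-to-tip depth for: {bad}")
    denom = np.sqrt(np.outer(depths, depths))
    corr = cov / denom
    np.fill_diagonal(corr, 1.0)
    out = pd.DataFrame(corr, index=labels, columns=labels)
    if lineages is not None:
        missing = set(lineages) - set(labels)
        extra = set(labels) - set(lineages)
        if missing or extra:
            raise ValueError(
                f"tree tips and lineages differ (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        out = out.loc[list(lineages), list(lineages)]
    return out


def fit_poisson_gee(
    response: Sequence[float] | pd.Series,
    design: pd.DataFrame | np.ndarray,
    working_correlation: pd.DataFrame | np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GEEFit:
    """Solve the quasi-score equations for a log-link Poisson-variance GEE.

    With mu = exp(X beta), D = d mu / d beta = diag(mu) X and working
    covariance V = phi A^{1/2} R A^{1/2} (A = diag(mu)), the update is the
    Fisher-scoring step

        beta <- beta + (D' V^- D)^{-1} D' V^- (y - mu).

    phi is the generalized Pearson estimate r' R^{-1} r / (n - p) on the
    Pearson residuals r.  With R = I this reduces exactly to the Poisson
    maximum-likelihood scoring iteration with the ordinary Pearson
    dispersion.  Convergence: max |delta beta| < tol.
    """
    y = np.asarray(response, dtype=float)
    if np.any(y < 0):
        raise ValueError("response must be non-negative")
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    names = (
        list(design.columns)
        if isinstance(design, pd.DataFrame)
        else [f"b{i}" for i in range(X.shape[1])]
    )
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("response/design length mismatch")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix")
    if working_correlation is None:
        R = np.eye(n)
    else:
        R = (
            working_correlation.to_numpy(dtype=float)
            if isinstance(working_correlation, pd.DataFrame)
            else np.asarray(working_correlation, dtype=float)
        )
    if R.shape != (n, n):
        raise ValueError("working correlation has wrong shape")
    # tiny ridge guards exact-PSD trees (duplicated tips, zero branches)
    eigmin = float(np.min(np.linalg.eigvalsh(R)))
    if eigmin < -1e-8:
        raise ValueError("working correlation is not positive semi-definite")
    if eigmin < 1e-10:
        R = R + np.eye(n) * 1e-8

    Rinv = linalg.inv(R)
    mean_y = float(np.mean(y))
    if mean_y <= 0:
        raise ValueError("response mean must be positive for a log link")
    beta = np.zeros(p)
    beta[0] = np.log(mean_y) if names[0] in ("intercept", "b0", "const") else 0.0

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        sqrt_mu = np.sqrt(mu)
        # D'V^-D = X' A^{1/2} R^{-1} A^{1/2} X (phi cancels in the update)
        AX = X * sqrt_mu[:, None]
        info = AX.T @ Rinv @ AX
        resid = (y - mu) / sqrt_mu
        score = AX.T @ Rinv @ resid
        try:
            delta = linalg.solve(info, score, assume_a="sym")
        except linalg.LinAlgError as exc:
            raise ValueError(f"singular quasi-information matrix: {exc}") from None
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    sqrt_mu = np.sqrt(mu)
    pearson = (y - mu) / sqrt_mu
    # generalized Pearson dispersion r' R^{-1} r / (n - p): with correlated
    # observations the diagonal-only sum is far too variable (few effective
    # observations) and makes Wald tests anti-conservative; this reduces to
    # the ordinary Pearson estimate when R = I
    dispersion = float(pearson @ Rinv @ pearson / max(n - p, 1))
    AX = X * sqrt_mu[:, None]
    info = AX.T @ Rinv @ AX
    bread = linalg.inv(info)
    cov_model = dispersion * bread
    u = AX.T @ Rinv @ pearson
    cov_robust = bread @ np.outer(u, u) @ bread

    se = np.sqrt(np.diag(cov_model))
    se_rob = np.sqrt(np.maximum(np.diag(cov_robust), 0.0))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return GEEFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        se_robust=pd.Series(se_rob, index=names),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(pvals, index=names),
        dispersion=dispersion,
        n_iter=it,
        converged=converged,
    )


def fit_mode_gee(
    cn_values: pd.DataFrame,
    metadata: pd.DataFrame,
    tree: dendropy.Tree,
    gene: str = "5.8S",
) -> GEEFit:
    """Fit copy number ~ reproductive mode with the phylogenetic correlation.

    The response is one gene's per-haploid copy-number column; the design is
    an intercept plus an asexual indicator, ordered to match the tree tips.
    """
    meta = metadata.set_index("lineage")
    y = cn_values[gene].dropna()
    lineages = list(y.index)
    R = phylo_correlation(tree, lineages)
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "asexual": (meta.loc[lineages, "mode"] == "asexual").astype(float).to_numpy(),
        },
        index=lineages,
    )
    return fit_poisson_gee(y.to_numpy(), design, R)
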