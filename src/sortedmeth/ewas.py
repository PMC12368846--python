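"""Per-site regression frameworks for cell-sorted EWAS.

Four frameworks share one result schema and are vectorized across sites:

* ``ctlr`` — ordinary least squares within one cell type (one sample per
  individual, so observations are independent).
* ``alllr`` — OLS pooling all cell types with case x cell-type
  interactions and *classical* standard errors. With multiple samples per
  individual and heteroskedastic cell types this is deliberately
  misspecified; its anticonservative behaviour is part of what the
  benchmark harness measures.
* ``mer`` — random-intercept (per individual) mixed model with the same
  fixed effects, fitted by profiled REML over the variance ratio, Wald z
  inference.
* ``crr`` — same OLS point estimates as ``alllr`` with cluster-robust
  (CR1) sandwich standard errors, t reference with G-1 df.

Cell type enters with treatment coding; the reference level defaults to
the alphabetically first label, and interaction estimates are contrasts
against it.

The model-facing surface is :class:`CellSortedEWAS`, whose ``fit()``
returns an :class:`EWASResults` carrying the per-site table, the term
covariances needed for joint tests, and ``summary()`` /
``call_significant()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellSortedEWAS",
    "EWASResults",
    "build_design",
    "fit_ctlr",
    "fit_alllr",
    "fit_mer",
    "fit_crr",
    "call_significant",
]

FRAMEWORKS = ("ctlr", "alllr", "mer", "crr")
CALL_POLICIES = ("any-term", "main-only", "joint-test")


class RankDeficientDesign(ValueError):
    pass


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    sheet: pd.DataFrame,
    covariates=("age", "sex", "brain_bank"),
    cell_type_factor: bool = True,
    reference: str | None = None,
):
    """Build the fixed-effect design matrix from a sample sheet.

    Columns: intercept, case indicator, cell-type dummies and
    case x cell-type interactions (treatment coding against ``reference``,
    default the alphabetically first cell type), then covariates
    (categoricals dummy-coded dropping the first level, numerics
    centered).

    Returns ``(X, names, interaction_cols, case_col, cell_types)``.
    """
    n = len(sheet)
    cols = [np.ones(n)]
    names = ["intercept"]
    case = (sheet["phenotype"] == "case").to_numpy(dtype=float)
    cols.append(case)
    names.append("case")
    case_col = 1

    interaction_cols = []
    cell_levels = []
    if cell_type_factor:
        levels = sorted(sheet["cell_type"].unique())
        ref = reference if reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among cell types")
        cell_levels = [ref] + [l for l in levels if l != ref]
        for lev in cell_levels[1:]:
            d = (sheet["cell_type"] == lev).to_numpy(dtype=float)
            cols.append(d)
            names.append(f"celltype_{lev}")
        for lev in cell_levels[1:]:
            d = (sheet["cell_type"] == lev).to_numpy(dtype=float)
            interaction_cols.append(len(cols))
            cols.append(case * d)
            names.append(f"case_x_{lev}")

    for cov in covariates:
        if cov not in sheet.columns:
            raise ValueError(f"covariate {cov!r} missing from sample sheet")
        col = sheet[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float) - float(col.mean()))
            names.append(cov)
        else:
            for lev in sorted(col.unique())[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{cov}_{lev}")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns greedily
        bad = []
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep):
                bad.append(names[j])
            else:
                keep.append(j)
        raise RankDeficientDesign(
            f"design is rank deficient; collinear columns: {bad}"
        )
    return X, names, interaction_cols, case_col, cell_levels


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class EWASResults:
    """Per-site association results for one fitted framework.

    ``table`` has one row per site. For ``ctlr``: ``main_beta``,
    ``main_se``, ``main_stat``, ``main_p``, ``df``, ``converged``. Pooled
    frameworks add ``int_<celltype>_{beta,se,stat,p}`` per non-reference
    cell type plus ``joint_int_stat`` / ``joint_int_p``.
    """

    framework: str
    table: pd.DataFrame
    reference: str | None = None
    cell_type: str | None = None
    params: dict = field(default_factory=dict)

    @property
    def interaction_terms(self):
        return [c[: -len("_p")] for c in self.table.columns
                if c.startswith("int_") and c.endswith("_p")]

    def call_significant(self, threshold: float, policy: str = "any-term") -> pd.Series:
        return call_significant(self, threshold, policy)

    def min_p(self, term: str = "any") -> float:
        """Smallest p-value across sites for a term family.

        ``term``: 'main', 'interaction', 'joint' or 'any' (main or any
        interaction).
        """
        t = self.table
        if term == "main":
            return float(np.nanmin(t["main_p"].to_numpy()))
        if term == "joint":
            return float(np.nanmin(t["joint_int_p"].to_numpy()))
        cols = [f"{i}_p" for i in self.interaction_terms]
        if term == "interaction":
            return float(np.nanmin(t[cols].to_numpy()))
        return float(np.nanmin(t[["main_p"] + cols].to_numpy()))

    def summary(self, top: int = 10) -> str:
        t = self.table
        n_conv = int(t["converged"].sum())
        lines = [
            f"Cell-sorted EWAS results: framework={self.framework}"
            + (f", cell_type={self.cell_type}" if self.cell_type else "")
            + (f", reference={self.reference}" if self.reference else ""),
            f"sites fitted: {len(t)} (converged: {n_conv})",
            f"min main-effect p: {np.nanmin(t['main_p']):.3e}",
        ]
        show = ["main_beta", "main_se", "main_p"]
        if "joint_int_p" in t.columns:
            show.append("joint_int_p")
        lines.append("")
        lines.append(
            t.nsmallest(top, "main_p")[show].to_string(
                float_format=lambda v: f"{v:.3g}"
            )
        )
        return "\n".join(lines)


def call_significant(result: EWASResults, threshold: float, policy: str = "any-term") -> pd.Series:
    """Per-site significance calls under a term policy.

    ``ctlr`` calls on the case term regardless of policy. For pooled
    frameworks: ``any-term`` calls when the main effect or any interaction
    passes, ``main-only`` on the main effect alone, ``joint-test`` when
    the main effect or the joint interaction test passes.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if policy not in CALL_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {CALL_POLICIES}")
    t = result.table
    main = t["main_p"].to_numpy() < threshold
    if result.framework == "ctlr" or not result.interaction_terms:
        calls = main
    elif policy == "main-only":
        calls = main
    elif policy == "joint-test":
        calls = main | (t["joint_int_p"].to_numpy() < threshold)
    else:
        ints = t[[f"{i}_p" for i in result.interaction_terms]].to_numpy()
        calls = main | (np.nan_to_num(ints, nan=1.0) < threshold).any(axis=1)
    calls = calls & t["converged"].to_numpy()
    return pd.Series(calls, index=t.index, name="significant")


# ---------------------------------------------------------------------------
# OLS machinery
# ---------------------------------------------------------------------------

def _ols(X, Y):
    """Vectorized OLS of every column-site in Y (n x S) on X (n x p)."""
    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    coef = XtXi @ (X.T @ Y)  # p x S
    resid = Y - X @ coef
    rss = np.einsum("ns,ns->s", resid, resid)
    return coef, resid, rss, XtXi


def _site_variable(Y):
    """True where a site varies across samples (n x S input)."""
    return Y.max(axis=0) > Y.min(axis=0)


def _p_from_t(stat, df):
    return 2.0 * stats.t.sf(np.abs(stat), df)


def _finish_table(site_ids, data):
    tab = pd.DataFrame(data, index=pd.Index(site_ids, name="site_id"))
    return tab


def fit_ctlr(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates=("age", "sex", "brain_bank"),
) -> EWASResults:
    """Within-cell-type linear regression, one OLS t-test per site.

    ``beta``/``sheet`` must contain a single cell type with one sample per
    individual. Zero-variance sites are flagged non-converged with missing
    p-values.
    """
    cts = sheet["cell_type"].unique()
    if len(cts) != 1:
        raise ValueError("fit_ctlr expects samples from a single cell type")
    if sheet["individual_id"].duplicated().any():
        raise ValueError("fit_ctlr expects one sample per individual")
    X, names, _, case_col, _ = build_design(
        sheet, covariates=covariates, cell_type_factor=False
    )
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few samples for the design")
    Y = beta.to_numpy(dtype=float).T  # n x S
    coef, resid, rss, XtXi = _ols(X, Y)
    df = n - p
    sigma2 = rss / df
    se = np.sqrt(sigma2 * XtXi[case_col, case_col])
    ok = (se > 0) & _site_variable(Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(ok, coef[case_col] / np.where(ok, se, 1.0), np.nan)
    pvals = np.where(ok, _p_from_t(tstat, df), np.nan)
    tab = _finish_table(
        beta.index,
        {
            "main_beta": coef[case_col],
            "main_se": np.where(ok, se, np.nan),
            "main_stat": tstat,
            "main_p": pvals,
            "df": df,
            "converged": ok,
        },
    )
    return EWASResults("ctlr", tab, cell_type=str(cts[0]),
                       params={"covariates": list(covariates), "df": df})


def _pooled_ols_parts(beta, sheet, covariates, reference):
    X, names, int_cols, case_col, levels = build_design(
        sheet, covariates=covariates, cell_type_factor=True, reference=reference
    )
    Y = beta.to_numpy(dtype=float).T  # n x S
    coef, resid, rss, XtXi = _ols(X, Y)
    return X, names, int_cols, case_col, levels, Y, coef, resid, rss, XtXi


def _assemble_pooled_table(site_ids, names, int_cols, case_col, coef, se_by_col,
                           stat_df, joint_stat, joint_p, ok):
    """Shared layout for allLR / MER / CRR outputs."""
    data = {
        "main_beta": coef[case_col],
        "main_se": se_by_col[case_col],
        "main_stat": coef[case_col] / se_by_col[case_col],
    }
    data["main_p"] = _pvec(data["main_stat"], stat_df)
    for j in int_cols:
        lev = names[j].removeprefix("case_x_")
        b, s = coef[j], se_by_col[j]
        data[f"int_{lev}_beta"] = b
        data[f"int_{lev}_se"] = s
        data[f"int_{lev}_stat"] = b / s
        data[f"int_{lev}_p"] = _pvec(b / s, stat_df)
    data["joint_int_stat"] = joint_stat
    data["joint_int_p"] = joint_p
    data["converged"] = ok
    tab = _finish_table(site_ids, data)
    for c in tab.columns:
        if c != "converged":
            tab.loc[~tab["converged"], c] = np.nan
    return tab


def _pvec(stat, df):
    """Two-sided p; df None means the normal reference."""
    if df is None:
        return 2.0 * stats.norm.sf(np.abs(stat))
    return _p_from_t(stat, df)


def fit_alllr(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates=("age", "sex", "brain_bank"),
    reference: str | None = None,
) -> EWASResults:
    """Pooled OLS across cell types with classical standard errors.

    beta ~ case + celltype + case:celltype + covariates. The classical
    SEs ignore both the within-individual correlation and the
    heteroskedasticity across cell types — by design, so that the bias of
    this framework is reproducible. Joint interaction test: classical
    Wald F.
    """
    if sheet["cell_type"].nunique() < 2:
        raise ValueError("fit_alllr needs at least two cell types")
    X, names, int_cols, case_col, levels, Y, coef, resid, rss, XtXi = (
        _pooled_ols_parts(beta, sheet, covariates, reference)
    )
    n, p = X.shape
    df = n - p
    sigma2 = rss / df
    ok = (sigma2 > 0) & _site_variable(Y)
    se = np.sqrt(np.maximum(sigma2, 0)[None, :] * np.diag(XtXi)[:, None])
    k = len(int_cols)
    Vjj = XtXi[np.ix_(int_cols, int_cols)]
    Vjj_inv = np.linalg.inv(Vjj)
    B = coef[int_cols]  # k x S
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.einsum("ks,kl,ls->s", B, Vjj_inv, B) / np.maximum(sigma2, 1e-300)
        joint_stat = wald / k
        joint_p = stats.f.sf(joint_stat, k, df)
        tab = _assemble_pooled_table(
            beta.index, names, int_cols, case_col, coef, se, df,
            joint_stat, joint_p, ok,
        )
    return EWASResults("alllr", tab, reference=levels[0],
                       params={"covariates": list(covariates), "df": df})


# ---------------------------------------------------------------------------
# cluster-robust regression
# ---------------------------------------------------------------------------

def fit_crr(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates=("age", "sex", "brain_bank"),
    reference: str | None = None,
    cluster: str = "individual_id",
) -> EWASResults:
    """Cluster-robust regression: allLR point estimates, CR1 sandwich SEs.

    The meat sums outer products of within-cluster score vectors; SEs are
    scaled by G/(G-1) * (N-1)/(N-k) (CR1) and referred to a t distribution
    with G-1 df, G the number of clusters (individuals). The joint
    interaction test is a Wald F with (k, G-1) df on the robust
    interaction covariance block.
    """
    clusters = sheet[cluster].to_numpy()
    uniq = pd.unique(clusters)
    G = len(uniq)
    if G < 2:
        raise ValueError("need at least two clusters")
    X, names, int_cols, case_col, levels, Y, coef, resid, rss, XtXi = (
        _pooled_ols_parts(beta, sheet, covariates, reference)
    )
    n, p = X.shape
    S = Y.shape[1]
    # rows of A^{-1} X' we need robust variances for
    sel = [case_col] + list(int_cols)
    C = (XtXi @ X.T)[sel]  # m x n
    m = len(sel)
    V = np.zeros((m, m, S))
    for g in uniq:
        idx = np.flatnonzero(clusters == g)
        s_g = C[:, idx] @ resid[idx]  # m x S
        V += s_g[:, None, :] * s_g[None, :, :]
    scale = (G / (G - 1.0)) * ((n - 1.0) / (n - p))
    V *= scale
    dfr = G - 1
    se_sel = np.sqrt(np.maximum(V[np.arange(m), np.arange(m)], 0.0))
    ok = (rss > 0) & np.all(se_sel > 0, axis=0) & _site_variable(Y)
    se_by_col = np.full((p, S), np.nan)
    for i, j in enumerate(sel):
        se_by_col[j] = se_sel[i]
    k = len(int_cols)
    Vint = V[1:, 1:]  # k x k x S
    B = coef[int_cols]
    Vint_t = np.moveaxis(Vint, -1, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sol = np.linalg.solve(
            np.where(ok[:, None, None], Vint_t, np.eye(k)), B.T[:, :, None]
        )[:, :, 0]
        wald = np.einsum("sk,sk->s", B.T, sol)
        joint_stat = wald / k
        joint_p = stats.f.sf(joint_stat, k, dfr)
        tab = _assemble_pooled_table(
            beta.index, names, int_cols, case_col, coef, se_by_col, dfr,
            joint_stat, joint_p, ok,
        )
    return EWASResults("crr", tab, reference=levels[0],
                       params={"covariates": list(covariates), "df": dfr,
                               "n_clusters": G, "small_sample": "CR1"})


# ---------------------------------------------------------------------------
# random-intercept mixed model, profiled REML
# ---------------------------------------------------------------------------

def _cluster_rotation(clusters):
    """Orthonormal rotation block-diagonalizing the random-intercept
    covariance.

    For each cluster of size m_g the basis holds the scaled mean vector
    (eigenvalue m_g of ZZ') and m_g - 1 orthonormal contrasts (eigenvalue
    0). Returns (Q, d) with Q orthonormal (n x n) and d the per-rotated-row
    eigenvalue of ZZ'.
    """
    n = len(clusters)
    Q = np.zeros((n, n))
    d = np.zeros(n)
    row = 0
    for g in pd.unique(clusters):
        idx = np.flatnonzero(clusters == g)
        mg = len(idx)
        Q[row, idx] = 1.0 / np.sqrt(mg)
        d[row] = mg
        row += 1
        if mg > 1:
            # Helmert contrasts
            for j in range(1, mg):
                v = np.zeros(mg)
                v[:j] = 1.0
                v[j] = -j
                v /= np.linalg.norm(v)
                Q[row, idx] = v
                d[row] = 0.0
                row += 1
    return Q, d


def _reml_neg2_profile(lam, classes, Gmats, H, q, n, p):
    """-2 REML (up to a constant) at variance ratio lam, all sites at once.

    classes: list of (d_value, count); Gmats/H/q: per-class X'X blocks,
    X'y blocks (k x p x S) and y'y (k x S) in the rotated basis.
    """
    w = np.array([1.0 / (1.0 + lam * d) for d, _ in classes])
    A = np.einsum("k,kij->ij", w, Gmats)
    Hs = np.einsum("k,kps->ps", w, H)
    qs = w @ q
    sign, logdetA = np.linalg.slogdet(A)
    b = np.linalg.solve(A, Hs)
    rss = np.maximum(qs - np.einsum("ps,ps->s", Hs, b), 1e-300)
    logdetV = sum(c * np.log1p(lam * d) for d, c in classes)
    return (n - p) * np.log(rss) + logdetV + logdetA, b, rss, A


def fit_mer(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates=("age", "sex", "brain_bank"),
    reference: str | None = None,
    cluster: str = "individual_id",
    n_grid: int = 61,
    max_ratio: float = 100.0,
) -> EWASResults:
    """Random-intercept mixed model per site, profiled REML, Wald z tests.

    The variance ratio lambda = sigma_u^2 / sigma_e^2 is profiled on a log
    grid shared across sites (the rotated design makes each grid point a
    single p x p solve for *all* sites) and refined per site by parabolic
    interpolation of the REML surface in log-lambda. Fixed-effect SEs are
    model-based; p-values use the asymptotic normal reference, the joint
    interaction test a Wald chi-square.
    """
    if sheet["cell_type"].nunique() < 2:
        raise ValueError("fit_mer expects pooled cell types")
    clusters = sheet[cluster].to_numpy()
    X, names, int_cols, case_col, levels = build_design(
        sheet, covariates=covariates, cell_type_factor=True, reference=reference
    )
    n, p = X.shape
    Y = beta.to_numpy(dtype=float).T  # n x S
    S = Y.shape[1]
    Q, d = _cluster_rotation(clusters)
    Xr = Q @ X
    Yr = Q @ Y

    d_vals = np.unique(d)
    classes = [(float(dv), int((d == dv).sum())) for dv in d_vals]
    Gmats = np.stack([Xr[d == dv].T @ Xr[d == dv] for dv, _ in classes])
    H = np.stack([Xr[d == dv].T @ Yr[d == dv] for dv, _ in classes])
    q = np.stack([np.einsum("ns,ns->s", Yr[d == dv], Yr[d == dv])
                  for dv, _ in classes])

    if max_ratio == 0:
        # constrained fit: random-intercept variance fixed at zero (GLS
        # degenerates to the pooled OLS)
        lams = np.array([0.0])
    else:
        lams = np.concatenate([[0.0], np.geomspace(1e-4, max_ratio, n_grid - 1)])
    crit = np.empty((len(lams), S))
    for i, lam in enumerate(lams):
        crit[i], _, _, _ = _reml_neg2_profile(lam, classes, Gmats, H, q, n, p)
    best = np.argmin(crit, axis=0)

    # parabolic refinement in log-lambda for interior optima
    lam_hat = lams[best]
    interior = (best > 1) & (best < len(lams) - 1)
    if np.any(interior):
        i0 = best[interior]
        x0 = np.log(lams[i0 - 1]); x1 = np.log(lams[i0]); x2 = np.log(lams[i0 + 1])
        y0 = crit[i0 - 1, np.flatnonzero(interior)]
        y1 = crit[i0, np.flatnonzero(interior)]
        y2 = crit[i0 + 1, np.flatnonzero(interior)]
        denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
        with np.errstate(divide="ignore", invalid="ignore"):
            xv = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2)
                             - (x1 - x2) ** 2 * (y1 - y0)) / denom
        xv = np.where(np.isfinite(xv) & (xv > x0) & (xv < x2), xv, x1)
        lam_hat[interior] = np.exp(xv)

    # final GLS per site at its own lambda
    w_all = 1.0 / (1.0 + lam_hat[None, :] * d_vals[:, None])  # k x S
    A_s = np.einsum("ks,kij->sij", w_all, Gmats)
    H_s = np.einsum("ks,kps->sp", w_all, H)
    q_s = np.einsum("ks,ks->s", w_all, q)
    b_s = np.linalg.solve(A_s, H_s[:, :, None])[:, :, 0]  # S x p
    rss = np.maximum(q_s - np.einsum("sp,sp->s", H_s, b_s), 0.0)
    dfres = n - p
    sigma2_e = rss / dfres
    sigma2_u = lam_hat * sigma2_e
    Ainv = np.linalg.inv(A_s)
    cov = Ainv * sigma2_e[:, None, None]  # S x p x p
    se_all = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0)).T  # p x S
    coef = b_s.T  # p x S
    ok = ((sigma2_e > 0)
          & np.all(se_all[[case_col] + list(int_cols)] > 0, axis=0)
          & _site_variable(Y))

    k = len(int_cols)
    Vint = cov[:, int_cols][:, :, int_cols]  # S x k x k
    B = coef[int_cols].T  # S x k
    with np.errstate(divide="ignore", invalid="ignore"):
        sol = np.linalg.solve(
            np.where(ok[:, None, None], Vint, np.eye(k)), B[:, :, None]
        )[:, :, 0]
        wald = np.einsum("sk,sk->s", B, sol)
        joint_p = stats.chi2.sf(wald, k)
        tab = _assemble_pooled_table(
            beta.index, names, int_cols, case_col, coef, se_all, None,
            wald, joint_p, ok,
        )
    tab["sigma2_individual"] = sigma2_u
    tab["sigma2_residual"] = sigma2_e
    tab["variance_ratio"] = lam_hat
    res = EWASResults("mer", tab, reference=levels[0],
                      params={"covariates": list(covariates),
                              "inference": "wald-z", "method": "reml"})
    res.params["cov"] = cov  # S x p x p, used by two-stage contrasts
    res.params["coef_names"] = names
    res.params["coef"] = coef
    return res


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class CellSortedEWAS:
    """Cell-sorted EWAS model over a beta matrix and sample sheet.

    Parameters
    ----------
    beta : DataFrame, sites x samples, values in [0, 1]
    sheet : DataFrame with sample_id, individual_id, cell_type, covariates
        and an assigned phenotype
    framework : one of 'ctlr', 'alllr', 'mer', 'crr'
    cell_type : for 'ctlr', which cell type to analyse (defaults to the
        single cell type present)

    ``fit()`` returns :class:`EWASResults`.
    """

    def __init__(self, beta, sheet, framework="ctlr", cell_type=None,
                 covariates=("age", "sex", "brain_bank"), reference=None):
        if framework not in FRAMEWORKS:
            raise ValueError(f"unknown framework {framework!r}")
        if list(beta.columns) != list(sheet["sample_id"]):
            raise ValueError("beta columns must match sheet sample_id order")
        self.beta = beta
        self.sheet = sheet
        self.framework = framework
        self.cell_type = cell_type
        self.covariates = tuple(covariates)
        self.reference = reference

    @classmethod
    def from_files(cls, beta_path, sheet_path, **kw):
        from .io import read_beta, read_sheet
        beta = read_beta(beta_path)
        sheet = read_sheet(sheet_path)
        return cls(beta, sheet.loc[sheet["sample_id"].isin(beta.columns)], **kw)

    def fit(self, **kw) -> EWASResults:
        if self.framework == "ctlr":
            ct = self.cell_type
            if ct is None:
                cts = self.sheet["cell_type"].unique()
                if len(cts) != 1:
                    raise ValueError("specify cell_type for ctlr on pooled data")
                ct = cts[0]
            mask = (self.sheet["cell_type"] == ct).to_numpy()
            return fit_ctlr(self.beta.loc[:, mask], self.sheet.loc[mask],
                            covariates=self.covariates, **kw)
        fitter = {"alllr": fit_alllr, "mer": fit_mer, "crr": fit_crr}[self.framework]
        return fitter(self.beta, self.sheet, covariates=self.covariates,
                      reference=self.reference, **kw)
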