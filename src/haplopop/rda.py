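"""Redundancy analysis (RDA) from first principles, for genotype–environment
association and variance partitioning.

The response is an individuals × allele-dosage matrix (0/1/2 per
microhaplotype allele, mean-imputed, column-centered).  RDA regresses the
response on a constraint matrix (environmental PCs and/or orthogonal
polynomials of coastline distance), then eigen-decomposes the fitted values:
the canonical axes summarize the component of genomic variation explained by
the constraints.  R² is the explained share of total response variance;
adjusted R² applies the Ezekiel correction so that fractions from models
with different numbers of predictors are comparable.  Partial RDA (a
conditioning matrix whose effect is removed first) supports variance
partitioning of two predictor sets into unique and shared fractions by
inclusion–exclusion on adjusted R².  Alleles most strongly associated with
the constraints are flagged by the Mahalanobis distance of their loadings on
the first two canonical axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import EnvTable, GenotypeMatrix, LinkageMap, MISSING

__all__ = [
    "AlleleDosageMatrix", "RdaModel", "VarpartResult", "GeaFlags",
    "code_alleles", "env_pca", "spatial_design", "rda_fit",
    "forward_select", "varpart", "varpart_fractions", "mahalanobis_flags",
]

_RANK_TOL = 1e-9


@dataclass
class AlleleDosageMatrix:
    """Centered allele-dosage response matrix for ordination."""

    matrix: np.ndarray                 # (n_individuals, n_columns), centered
    columns: list[tuple[str, int]]     # (locus_id, allele_index)
    column_means: np.ndarray           # pre-centering means (imputed scale)
    individuals: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def code_alleles(geno: GenotypeMatrix,
                 individual_idx: Optional[Sequence[int]] = None,
                 min_allele_freq: float = 0.02) -> AlleleDosageMatrix:
    """Per-allele dosage coding with mean imputation and column centering.

    A fully observed individual has dosages over a locus's alleles summing
    to 2; missing genotypes receive the across-individual mean dosage of each
    allele column before centering.  Columns for loci with no observed copies
    in the subset are dropped, as are columns whose allele frequency falls
    outside [min_allele_freq, 1 - min_allele_freq]: near-monomorphic columns
    carry no usable association signal but their near-zero variance makes
    loading-based outlier statistics heavy-tailed.  Set ``min_allele_freq=0``
    to keep every column.
    """
    idx = np.arange(geno.n_individuals) if individual_idx is None else np.asarray(individual_idx)
    if len(idx) < 2:
        raise ValueError("need >= 2 individuals")
    blocks = []
    columns: list[tuple[str, int]] = []
    for li, locus in enumerate(geno.loci):
        calls = geno.calls[li, idx]
        observed = (calls != MISSING).all(axis=1)
        if not observed.any():
            continue
        A = locus.n_alleles
        dos = np.zeros((len(idx), A))
        rows = np.nonzero(observed)[0]
        for copy in range(2):
            np.add.at(dos, (rows, calls[rows, copy]), 1.0)
        col_mean = dos[rows].mean(axis=0)
        dos[~observed] = col_mean
        freq = col_mean / 2.0
        keep = (freq >= min_allele_freq) & (freq <= 1.0 - min_allele_freq)
        if not keep.any():
            continue
        blocks.append(dos[:, keep])
        columns.extend((locus.locus_id, a) for a in np.nonzero(keep)[0])
    if not blocks:
        raise ValueError("no observed loci in subset")
    mat = np.concatenate(blocks, axis=1)
    means = mat.mean(axis=0)
    return AlleleDosageMatrix(
        matrix=mat - means, columns=columns, column_means=means,
        individuals=[geno.individuals[i] for i in idx],
    )


@dataclass
class EnvPca:
    scores: pd.DataFrame      # estuary x PC
    loadings: pd.DataFrame    # variable x PC
    percent_variance: np.ndarray
    dropped_variables: list[str]


def env_pca(env: EnvTable) -> EnvPca:
    """PCA of standardized environmental variables across estuaries.

    Variables are centered and unit-scaled across estuaries; scores per
    estuary come from the eigen-decomposition of the correlation structure.
    Zero-variance variables are dropped with a warning.
    """
    df = env.table
    if df.shape[0] < 2:
        raise ValueError("need >= 2 estuaries")
    sd = df.std(axis=0, ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"env_pca: dropping zero-variance variables {dropped}")
        df = df.drop(columns=dropped)
    z = (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    keep = s > _RANK_TOL * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    pcs = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=df.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=df.columns, columns=pcs)
    var = s**2
    return EnvPca(scores=scores, loadings=loadings,
                  percent_variance=100.0 * var / var.sum(),
                  dropped_variables=dropped)


def spatial_design(coastal_distance_km: Sequence[float], degree: int = 3,
                   jitter_sd_km: float = 2.0,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Centered orthogonal-polynomial basis of jittered coastline distance.

    Distances are per individual; Gaussian jitter (sd in km) mimics
    within-estuary variability in sampling location, and the polynomial of
    the given degree captures nonlinear isolation by distance.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(coastal_distance_km, dtype=float)
    if jitter_sd_km > 0:
        x = x + rng.normal(0.0, jitter_sd_km, size=len(x))
    if np.ptp(x) == 0:
        raise ValueError("all distances identical and no jitter: rank-0 design")
    xc = (x - x.mean()) / x.std()
    V = np.vander(xc, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    if np.abs(np.diag(R)).min() < _RANK_TOL:
        raise ValueError("polynomial design is rank-deficient")
    cols = Q[:, 1:]  # drop intercept column
    return cols - cols.mean(axis=0)


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _residualize(A: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, A, rcond=None)
    return A - Z @ coef


@dataclass
class RdaModel:
    n: int
    m: int
    p_cond: int
    eigenvalues: np.ndarray
    R2: float
    adjR2: float
    axis_percent_constrained: np.ndarray
    site_scores: np.ndarray
    allele_loadings: np.ndarray
    pseudo_F: float
    p_perm: float
    columns: list = field(default_factory=list)
    ss_total: float = np.nan
    ss_fitted: float = np.nan


def _constraint_basis(Xw: np.ndarray) -> np.ndarray:
    """Orthonormal basis (n x rank) of the column space of Xw."""
    u, s, _ = np.linalg.svd(Xw, full_matrices=False)
    keep = s > _RANK_TOL * max(s[0], 1.0)
    return u[:, keep]

def _fit_core(Yw: np.ndarray, Xw: np.ndarray) -> tuple[float, int, np.ndarray, np.ndarray, np.ndarray]:
    """(SS_fitted, rank, singular values, U*s site scores, V loadings).

    The fitted values are the projection of Yw onto the column space of Xw,
    so their singular values equal those of the small matrix Ux' Yw — the
    full n x q SVD is never formed.
    """
    Ux = _constraint_basis(Xw)
    small = Ux.T @ Yw
    u, s, vt = np.linalg.svd(small, full_matrices=False)
    keep = s > _RANK_TOL * max(s[0] if len(s) else 1.0, 1.0)
    s = s[keep]
    return (float((small**2).sum()), Ux.shape[1], s,
            (Ux @ u[:, keep]) * s, vt[keep].T)


def rda_fit(Y, X, Z=None, n_perm: int = 1000,
            rng: Optional[np.random.Generator] = None) -> RdaModel:
    """Fit a (partial) redundancy analysis.

    ``Y`` is an :class:`AlleleDosageMatrix` or a centered response matrix;
    ``X`` the constraint matrix; ``Z`` an optional conditioning matrix whose
    least-squares effect is removed from both Y and X first.  R² (and its
    Ezekiel adjustment) is reported against the *total* unconditioned
    response variance, so fractions from partial models are commensurable in
    variance partitioning.  The permutation test shuffles rows of the
    (residualized) response and recomputes the pseudo-F.
    """
    rng = np.random.default_rng() if rng is None else rng
    columns = []
    if isinstance(Y, AlleleDosageMatrix):
        columns = Y.columns
        Y = Y.matrix
    Y = _as_matrix(Y)
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]
    X = _as_matrix(X)
    X = X - X.mean(axis=0)
    ss_total = float((Y**2).sum())
    p_cond = 0
    Yw, Xw = Y, X
    if Z is not None:
        Z = _as_matrix(Z)
        Z = Z - Z.mean(axis=0)
        p_cond = int(np.linalg.matrix_rank(Z, tol=None))
        Yw = _residualize(Y, Z)
        Xw = _residualize(X, Z)
    ss_fit, m, s, site_scores, loadings = _fit_core(Yw, Xw)
    if m == 0:
        raise ValueError("constraint matrix has rank 0")
    eig = s**2 / (n - 1)
    R2 = ss_fit / ss_total
    df_resid = n - m - p_cond - 1
    if df_resid > 0:
        adjR2 = 1.0 - (1.0 - R2) * (n - 1) / df_resid
        ss_resid = float((Yw**2).sum()) - ss_fit
        pseudo_F = (ss_fit / m) / (ss_resid / df_resid)
    else:
        # saturated model: R2 is defined, the F machinery is not
        adjR2 = np.nan
        pseudo_F = np.nan
        n_perm = 0
    p_perm = np.nan
    if n_perm > 0:
        Ux = _constraint_basis(Xw)
        ss_yw = float((Yw**2).sum())
        count = 0
        for _ in range(n_perm):
            Yp = Yw[rng.permutation(n)]
            ss_p = float(((Ux.T @ Yp) ** 2).sum())
            Fp = (ss_p / m) / ((ss_yw - ss_p) / df_resid)
            if Fp >= pseudo_F - 1e-15:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
    return RdaModel(
        n=n, m=m, p_cond=p_cond, eigenvalues=eig, R2=R2, adjR2=adjR2,
        axis_percent_constrained=100.0 * eig / eig.sum(),
        site_scores=site_scores, allele_loadings=loadings,
        pseudo_F=pseudo_F, p_perm=p_perm, columns=columns,
        ss_total=ss_total, ss_fitted=ss_fit,
    )


def forward_select(Y, candidates: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 1000,
                   rng: Optional[np.random.Generator] = None) -> tuple[list[str], pd.DataFrame]:
    """Forward selection of constraint columns with the double stopping rule.

    At each step the candidate giving the largest adjusted-R² increase is
    tested by permutation conditional on the already-selected columns; it is
    kept only if p <= alpha and the cumulative adjusted R² does not exceed
    that of the model with every candidate.  Returns the ordered selection
    and a trace table.  An empty selection is a valid outcome.
    """
    rng = np.random.default_rng() if rng is None else rng
    if isinstance(Y, AlleleDosageMatrix):
        Y = Y.matrix
    Y = _as_matrix(Y)
    names = list(candidates.columns)
    if not names:
        raise ValueError("need >= 1 candidate")
    full = rda_fit(Y, candidates.to_numpy(), n_perm=0, rng=rng)
    cap = full.adjR2
    selected: list[str] = []
    trace_rows = []
    current_adj = 0.0
    remaining = names.copy()
    while remaining:
        best_name, best_adj = None, -np.inf
        for name in remaining:
            cols = selected + [name]
            fit = rda_fit(Y, candidates[cols].to_numpy(), n_perm=0, rng=rng)
            if fit.adjR2 > best_adj:
                best_name, best_adj = name, fit.adjR2
        if best_adj > cap + 1e-12:
            break
        Z = candidates[selected].to_numpy() if selected else None
        test = rda_fit(Y, candidates[[best_name]].to_numpy(), Z=Z,
                       n_perm=n_perm, rng=rng)
        trace_rows.append((best_name, best_adj, test.p_perm, test.p_perm <= alpha))
        if test.p_perm > alpha:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current_adj = best_adj
    trace = pd.DataFrame(trace_rows, columns=["candidate", "cum_adjR2", "p_perm",
                                              "accepted"])
    return selected, trace


@dataclass
class VarpartResult:
    adjR2_env_total: float   # [a+b]
    adjR2_xy_total: float    # [b+c]
    adjR2_full: float        # [a+b+c]
    env_unique: float        # [a]
    xy_unique: float         # [c]
    shared: float            # [b]
    residual: float
    p_env_total: float
    p_xy_total: float
    p_full: float
    p_env_unique: float
    p_xy_unique: float

    def table(self) -> pd.DataFrame:
        rows = [
            ("residuals", self.residual, np.nan),
            ("env + shared", self.adjR2_env_total, self.p_env_total),
            ("env + xy + shared", self.adjR2_full, self.p_full),
            ("shared", self.shared, np.nan),
            ("xy + shared", self.adjR2_xy_total, self.p_xy_total),
            ("env", self.env_unique, self.p_env_unique),
            ("xy", self.xy_unique, self.p_xy_unique),
        ]
        return pd.DataFrame(rows, columns=["partition", "adjR2", "p_perm"])


def varpart_fractions(ab: float, bc: float, abc: float) -> dict[str, float]:
    """Inclusion–exclusion on adjusted R² of the two marginal models and the
    full model: unique and shared fractions (components may be negative)."""
    return {
        "env_unique": abc - bc,
        "xy_unique": abc - ab,
        "shared": ab + bc - abc,
        "residual": 1.0 - abc,
    }


def varpart(Y, X_env, X_xy, n_perm: int = 1000,
            rng: Optional[np.random.Generator] = None) -> VarpartResult:
    """Partition response variance between two predictor sets.

    Fits the two marginal models and the combined model, derives unique and
    shared adjusted-R² fractions by inclusion–exclusion, and permutation-tests
    the marginal, full, and both partial (conditioned) models.
    """
    rng = np.random.default_rng() if rng is None else rng
    if isinstance(Y, AlleleDosageMatrix):
        Y = Y.matrix
    X_env = _as_matrix(X_env)
    X_xy = _as_matrix(X_xy)
    fit_env = rda_fit(Y, X_env, n_perm=n_perm, rng=rng)
    fit_xy = rda_fit(Y, X_xy, n_perm=n_perm, rng=rng)
    fit_full = rda_fit(Y, np.hstack([X_env, X_xy]), n_perm=n_perm, rng=rng)

    def _partial_p(X, Z):
        # degenerate when X lies in the span of Z (fully shared predictors)
        try:
            return rda_fit(Y, X, Z=Z, n_perm=n_perm, rng=rng).p_perm
        except ValueError:
            return np.nan

    p_env_unique = _partial_p(X_env, X_xy)
    p_xy_unique = _partial_p(X_xy, X_env)
    fr = varpart_fractions(fit_env.adjR2, fit_xy.adjR2, fit_full.adjR2)
    return VarpartResult(
        adjR2_env_total=fit_env.adjR2,
        adjR2_xy_total=fit_xy.adjR2,
        adjR2_full=fit_full.adjR2,
        env_unique=fr["env_unique"],
        xy_unique=fr["xy_unique"],
        shared=fr["shared"],
        residual=fr["residual"],
        p_env_total=fit_env.p_perm,
        p_xy_total=fit_xy.p_perm,
        p_full=fit_full.p_perm,
        p_env_unique=p_env_unique,
        p_xy_unique=p_xy_unique,
    )


@dataclass
class GeaFlags:
    table: pd.DataFrame        # locus_id, allele, loading1, loading2, D2, flagged
    flagged_loci: set[str]
    threshold: float
    linkage_counts: Optional[pd.DataFrame] = None


def mahalanobis_flags(model: RdaModel, threshold: float = 25.0,
                      linkage_map: Optional[LinkageMap] = None) -> GeaFlags:
    """Flag alleles far from the loading cloud on the first two canonical axes.

    D²_j = (l_j - l̄)ᵀ Σ̂⁻¹ (l_j - l̄) with the plain empirical mean and
    covariance of the loadings; under approximate bivariate normality
    D² ~ χ²₂, so the default threshold of 25 flags only extreme tails
    (P(χ²₂ > 25) ≈ 3.7e-6).  A locus is flagged when any of its alleles is.
    """
    L = model.allele_loadings
    if L.shape[1] < 2:
        raise ValueError("model has fewer than 2 canonical axes")
    if L.shape[0] < 3:
        raise ValueError("fewer than 3 response columns: covariance is singular")
    pts = L[:, :2]
    mu = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("loading covariance is singular") from exc
    dev = pts - mu
    d2 = np.einsum("ij,jk,ik->i", dev, cov_inv, dev)
    if model.columns:
        locus_ids = [c[0] for c in model.columns]
        alleles = [c[1] for c in model.columns]
    else:
        locus_ids = [str(i) for i in range(len(d2))]
        alleles = [0] * len(d2)
    table = pd.DataFrame({
        "locus_id": locus_ids, "allele": alleles,
        "loading1": pts[:, 0], "loading2": pts[:, 1],
        "mahalanobis_D2": d2, "flagged": d2 > threshold,
    })
    flagged_loci = set(table.loc[table["flagged"], "locus_id"])
    link = None
    if linkage_map is not None:
        lg = linkage_map.group_of()
        counts: dict[int, int] = {}
        for lid in flagged_loci:
            if lid in lg:
                counts[lg[lid]] = counts.get(lg[lid], 0) + 1
        link = pd.DataFrame(sorted(counts.items()),
                            columns=["linkage_group", "flagged_loci"])
    return GeaFlags(table=table, flagged_loci=flagged_loci,
                    threshold=threshold, linkage_counts=link)
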