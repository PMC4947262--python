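"""Structure-aware association mapping for SNPs and expression markers.

SNP association uses the mixed linear model

    y = X beta + u + e,    u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I),

with X holding an intercept, the ancestry (Q) covariates and the tested
marker dosage, and K the kinship matrix absorbing polygenic confounding.
Variance components are REML-estimated on the null model by profiling the
ratio delta = sigma_e^2 / sigma_g^2 on the spectrum of K projected off X
(the EMMA device: a dense grid on log10 delta refined by golden section).
Each marker is then tested by a 1-df F-test under generalised least
squares.  By default the null-model components are reused for every marker
(the P3D shortcut); exact per-marker REML re-estimation is available.

GEM association is the simple per-unigene linear regression of RPKM on the
trait; its two-sided P is a monotone transform of the Pearson correlation,
so response/predictor orientation does not affect significance.  A
unigene's RPKM vector can itself be mapped as a trait against the SNPs
("GEM as trait") to locate the loci controlling its expression.

Outputs are association tables ordered along the pseudomolecule map, with
Bonferroni and Benjamini–Hochberg adjusted columns appended for reference.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .marker_scoring import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "NullModelFit",
    "fit_null_mlm",
    "snp_association",
    "gem_association",
    "gem_as_trait",
    "manhattan_table",
    "manhattan_plot",
    "adjust_pvalues",
    "genomic_inflation",
]


@dataclass
class NullModelFit:
    """REML variance components of the null mixed model, plus spectra.

    ``delta`` is sigma_e^2 / sigma_g^2.  ``U``/``w`` hold the
    eigendecomposition of K used to whiten the data under the fitted
    components; ``boundary`` flags a fit pinned to the delta grid edge.
    """

    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float
    U: np.ndarray
    w: np.ndarray
    X: np.ndarray
    y: np.ndarray
    boundary: bool

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan


def _reml_loglik_factory(y, X, K):
    """Profiled REML log-likelihood in delta, via the projected spectrum."""
    n, p = X.shape
    # orthonormal basis of the complement of col(X)
    Qx, _ = np.linalg.qr(X, mode="complete")
    A = Qx[:, p:]  # n x (n-p)
    M = A.T @ K @ A
    lam, V = np.linalg.eigh((M + M.T) / 2.0)
    eta = V.T @ (A.T @ y)
    df = n - p

    def loglik(delta: float) -> float:
        d = lam + delta
        if np.any(d <= 0):
            return -np.inf
        s = np.sum(eta**2 / d)
        return 0.5 * (
            df * (np.log(df / (2.0 * np.pi)) - 1.0 - np.log(s)) - np.sum(np.log(d))
        )

    def sigma_g2(delta: float) -> float:
        return float(np.sum(eta**2 / (lam + delta)) / df)

    return loglik, sigma_g2


def fit_null_mlm(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    grid: tuple[float, float, int] = (-5.0, 5.0, 61),
    tol: float = 1e-8,
) -> NullModelFit:
    """REML fit of y = X beta + u + e with u ~ N(0, sigma_g^2 K).

    ``covariates`` excludes the intercept (added here); pass None for an
    intercept-only null.  The profiled REML criterion in
    delta = sigma_e^2/sigma_g^2 is evaluated on a log10 grid and refined
    by bounded golden-section search around the best grid point.  A
    maximiser at the grid edge is returned flagged as a boundary fit.
    """
    y = np.asarray(y, float).ravel()
    n = len(y)
    X = np.column_stack([np.ones(n)] + ([np.asarray(covariates, float)] if covariates is not None and np.size(covariates) else []))
    if n < X.shape[1] + 2:
        raise ValueError("too few observations for the null model")
    K = np.asarray(K, float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    wK = np.linalg.eigvalsh(K)
    if wK.min() < -1e-6 * max(1.0, wK.max()):
        raise ValueError("kinship matrix is not positive semi-definite")

    loglik, sigma_g2_of = _reml_loglik_factory(y, X, K)
    lo, hi, npts = grid
    deltas = np.logspace(lo, hi, int(npts))
    vals = np.array([loglik(d) for d in deltas])
    best = int(np.argmax(vals))
    boundary = best in (0, len(deltas) - 1)
    a = deltas[max(best - 1, 0)]
    b = deltas[min(best + 1, len(deltas) - 1)]
    if a < b:
        res = optimize.minimize_scalar(
            lambda d: -loglik(d), bounds=(a, b), method="bounded",
            options={"xatol": tol},
        )
        delta = float(res.x)
        if loglik(delta) < vals[best]:
            delta = float(deltas[best])
    else:
        delta = float(deltas[best])

    sg2 = sigma_g2_of(delta)
    se2 = delta * sg2
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return NullModelFit(
        sigma_g2=sg2,
        sigma_e2=se2,
        delta=delta,
        loglik=float(loglik(delta)),
        U=U,
        w=w,
        X=X,
        y=y,
        boundary=boundary,
    )


def _gls_marker_scan(y, X0, G, U, w, delta):
    """Vectorised 1-df GLS F-tests for all complete-data markers.

    Whitens with V^(-1/2) ~ diag(1/sqrt(w + delta)) U', residualises the
    trait and every marker on the null design, and forms the added-variable
    F statistic per marker.
    """
    d = 1.0 / np.sqrt(w + delta)
    yt = d * (U.T @ y)
    X0t = d[:, None] * (U.T @ X0)
    Gt = d[:, None] * (U.T @ G)
    Q0, _ = np.linalg.qr(X0t)
    yr = yt - Q0 @ (Q0.T @ yt)
    Gr = Gt - Q0 @ (Q0.T @ Gt)
    rss0 = float(yr @ yr)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(gg > 0, gy / gg, np.nan)
    rss1 = rss0 - np.where(gg > 0, gy**2 / gg, 0.0)
    df2 = len(y) - X0.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(gg > 0, (rss0 - rss1) / (rss1 / df2), np.nan)
    F = np.clip(F, 0.0, None)
    P = stats.f.sf(F, 1, df2)
    return beta, F, P, df2


def snp_association(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    q_covariates: pd.DataFrame | None,
    kinship: pd.DataFrame,
    mode: str = "P3D",
    marker_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mixed-model association scan of every SNP against one trait.

    Returns a table with one row per marker: effect (trait units per unit
    dosage), F statistic, P, -log10 P and the sample size used.  Missing
    genotypes drop the accession for that marker only (casewise deletion);
    markers monomorphic among the remaining accessions get a NaN row with
    a warning.  ``mode='P3D'`` reuses the null-model variance components
    for every marker; ``mode='exact'`` re-estimates them per marker.
    """
    if mode not in ("P3D", "exact"):
        raise ValueError("mode must be 'P3D' or 'exact'")
    acc = genotypes.accessions
    y_full = trait.reindex(acc)
    keep = y_full.notna().to_numpy()
    if q_covariates is not None and len(q_covariates.columns) == 0:
        q_covariates = None
    if q_covariates is not None:
        qc = q_covariates.reindex(acc)
        keep &= qc.notna().all(axis=1).to_numpy()
    acc = acc[keep]
    y = y_full[keep].to_numpy(float)
    C = q_covariates.reindex(acc).to_numpy(float) if q_covariates is not None else None
    Kfull = kinship.reindex(index=acc, columns=acc).to_numpy(float)
    G = genotypes.calls.loc[acc].to_numpy(float)
    markers = genotypes.markers

    null = fit_null_mlm(y, C, Kfull)
    X0 = null.X
    n = len(y)

    eff = np.full(len(markers), np.nan)
    Fst = np.full(len(markers), np.nan)
    P = np.full(len(markers), np.nan)
    nused = np.zeros(len(markers), dtype=int)
    df2_col = np.full(len(markers), np.nan)

    complete = np.isfinite(G).all(axis=0)
    poly = np.nanstd(G, axis=0) > 0
    idx_c = np.nonzero(complete & poly)[0]
    if len(idx_c) and mode == "P3D":
        b, F, p, df2 = _gls_marker_scan(
            y, X0, G[:, idx_c], null.U, null.w, null.delta
        )
        eff[idx_c], Fst[idx_c], P[idx_c] = b, F, p
        nused[idx_c] = n
        df2_col[idx_c] = df2

    # markers needing per-marker handling: missing data, or exact mode
    rest = np.nonzero(poly & (~complete | (mode == "exact")))[0]
    for j in rest:
        gj = G[:, j]
        m = np.isfinite(gj)
        if m.sum() < X0.shape[1] + 2 or np.std(gj[m]) == 0:
            continue
        ys, Xs, gs = y[m], X0[m], gj[m]
        Ks = Kfull[np.ix_(m, m)]
        if mode == "exact":
            sub = fit_null_mlm(ys, Xs[:, 1:] if Xs.shape[1] > 1 else None, Ks)
            delta, U, wv = sub.delta, sub.U, sub.w
        else:
            wv, U = np.linalg.eigh((Ks + Ks.T) / 2.0)
            wv = np.clip(wv, 0.0, None)
            delta = null.delta
        b, F, p, df2 = _gls_marker_scan(ys, Xs, gs[:, None], U, wv, delta)
        eff[j], Fst[j], P[j] = b[0], F[0], p[0]
        nused[j] = int(m.sum())
        df2_col[j] = df2

    if np.any(~poly):
        warnings.warn(
            f"{int((~poly).sum())} monomorphic marker(s) reported as NaN rows"
        )

    table = pd.DataFrame(
        {
            "id": markers,
            "effect": eff,
            "stat": Fst,
            "df": df2_col,
            "p": P,
            "neglog10p": -np.log10(np.clip(P, 1e-300, None)),
            "n": nused,
        }
    )
    if "unigene" in genotypes.info.columns:
        table["unigene"] = genotypes.info["unigene"].to_numpy()
    table = adjust_pvalues(table)
    if marker_map is not None:
        table = manhattan_table(table, marker_map)
    return table


def gem_association(
    trait: pd.Series,
    expression: ExpressionMatrix,
    q_covariates: pd.DataFrame | None = None,
    marker_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-unigene linear regression of RPKM on the trait.

    RPKM is the response and the trait the predictor; the reported slope
    sign therefore says whether expression rises or falls with the trait.
    The two-sided P derives from t = r sqrt((n-2)/(1-r^2)).  Optionally
    the trait and expression are first residualised on ancestry covariates.
    """
    R = expression.rpkm
    acc = R.index
    y = trait.reindex(acc).to_numpy(float)
    keep = np.isfinite(y)
    y = y[keep]
    E = R.to_numpy(float)[keep]
    if q_covariates is not None and len(q_covariates.columns):
        C = np.column_stack(
            [np.ones(len(y)), q_covariates.reindex(acc[keep]).to_numpy(float)]
        )
        Qc, _ = np.linalg.qr(C)
        y = y - Qc @ (Qc.T @ y)
        E = E - Qc @ (Qc.T @ E)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    sy = y.std()
    if sy == 0:
        raise ValueError("trait has zero variance")
    Ec = E - E.mean(axis=0)
    se = E.std(axis=0)
    zero = se == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant unigene(s) reported as NaN rows")
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec.T @ yc) / (n * np.where(zero, np.nan, se) * sy)
    r = np.clip(r, -1.0, 1.0)
    slope = r * se / sy
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame(
        {
            "id": R.columns,
            "unigene": R.columns,
            "effect": slope,
            "r": r,
            "stat": t,
            "df": float(n - 2),
            "p": P,
            "neglog10p": -np.log10(np.clip(P, 1e-300, None)),
            "n": n,
        }
    )
    table = adjust_pvalues(table)
    if marker_map is not None:
        table = manhattan_table(table, marker_map)
    return table


def gem_as_trait(
    unigene: str,
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    q_covariates: pd.DataFrame | None,
    kinship: pd.DataFrame,
    mode: str = "P3D",
    marker_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Map one unigene's RPKM vector as the phenotype against all SNPs.

    This is definitionally ``snp_association`` with the expression vector
    as the trait; peaks locate the loci controlling that unigene's
    transcript abundance (cis if they coincide with the unigene itself).
    """
    if unigene not in expression.rpkm.columns:
        raise KeyError(f"unigene {unigene!r} not in the expression matrix")
    vec = expression.rpkm[unigene]
    if vec.std() == 0:
        raise ValueError(f"unigene {unigene!r} has zero expression variance")
    return snp_association(
        vec, genotypes, q_covariates, kinship, mode=mode, marker_map=marker_map
    )


def _natural_chrom_key(label: str) -> tuple:
    m = re.match(r"^(\d+)([A-Za-z]*)$", str(label))
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, 0, str(label))


def manhattan_table(
    assoc: pd.DataFrame, marker_map: pd.DataFrame
) -> pd.DataFrame:
    """Order an association table along the pseudomolecule map.

    ``marker_map`` is indexed by unigene with ``chromosome`` and
    ``position`` columns.  Rows gain chromosome, position and a cumulative
    x coordinate across chromosomes in natural label order (1A, 1B, 1D,
    2A, ...); markers whose unigene is absent from the map are appended in
    an 'unplaced' block with a warning.  Row count is conserved.
    """
    out = assoc.copy()
    key = out["unigene"] if "unigene" in out.columns else out["id"]
    chrom = key.map(marker_map["chromosome"]) if "chromosome" in marker_map else None
    pos = key.map(marker_map["position"])
    out["chromosome"] = chrom
    out["position"] = pos
    unplaced = out["chromosome"].isna()
    if unplaced.any():
        warnings.warn(f"{int(unplaced.sum())} marker(s) not in map: unplaced block")
        out.loc[unplaced, "chromosome"] = "unplaced"
        out.loc[unplaced, "position"] = np.arange(1, unplaced.sum() + 1)
    chroms = sorted(out["chromosome"].unique(), key=_natural_chrom_key)
    chroms = [c for c in chroms if c != "unplaced"] + (
        ["unplaced"] if "unplaced" in chroms else []
    )
    out["_ckey"] = out["chromosome"].map({c: i for i, c in enumerate(chroms)})
    out = out.sort_values(["_ckey", "position", "id"], kind="mergesort").drop(
        columns="_ckey"
    )
    offset = 0
    xs = np.empty(len(out))
    boundaries = {}
    for c in chroms:
        mask = (out["chromosome"] == c).to_numpy()
        pos_c = out.loc[mask, "position"].to_numpy(float)
        xs[mask] = offset + pos_c
        boundaries[c] = (offset, offset + (pos_c.max() if len(pos_c) else 0))
        offset += pos_c.max() if len(pos_c) else 0
    out["x"] = xs
    out.attrs["chromosome_boundaries"] = boundaries
    return out.reset_index(drop=True)


def manhattan_plot(ordered: pd.DataFrame, path, title: str = ""):
    """Render a map-ordered association table as a Manhattan plot PNG.

    ``ordered`` is the output of :func:`manhattan_table` (cumulative ``x``
    and ``neglog10p`` columns); chromosomes alternate shading.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    chroms = ordered["chromosome"].unique()
    for i, c in enumerate(chroms):
        sub = ordered[ordered["chromosome"] == c]
        ax.scatter(sub["x"], sub["neglog10p"], s=6,
                   color="C0" if i % 2 == 0 else "C1")
        ax.annotate(c, ((sub["x"].min() + sub["x"].max()) / 2, 0),
                    xytext=(0, -18), textcoords="offset points",
                    ha="center", fontsize=7)
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.set_xticks([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def adjust_pvalues(assoc: pd.DataFrame) -> pd.DataFrame:
    """Append Bonferroni and Benjamini–Hochberg adjusted P columns.

    NaN rows are excluded from the effective test count m.  These columns
    are informational: peak declaration in this analysis tradition is by
    inspection of the -log10 P profile, not a hard threshold.
    """
    out = assoc.copy()
    p = out["p"].to_numpy(float)
    ok = np.isfinite(p)
    bonf = np.full_like(p, np.nan)
    bh = np.full_like(p, np.nan)
    if ok.any():
        m = int(ok.sum())
        bonf[ok] = np.minimum(1.0, p[ok] * m)
        bh[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out["p_bonferroni"] = bonf
    out["p_bh"] = bh
    return out


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor lambda from association P values.

    Converts each P to a 1-df chi-square quantile and divides the median
    by the theoretical null median 0.456 (chi2(1) at 0.5).  Values near 1
    indicate calibrated tests; >1 signals confounding.
    """
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite P values")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
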