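"""Shared statistical core for all association scans.

The model is the single-kinship linear mixed model

    y = X beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with variance components estimated once per phenotype by REML on the null
model (no marker), then held fixed while every marker is tested by
generalized least squares in the whitened space — the EMMAX approximation.
Phenotypes are quantile-normalized to N(0,1); kinship is VanRaden-type;
population-structure PCs and confounder PCs enter as fixed covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .containers import Locus

__all__ = [
    "quantile_normalize", "QuantileNormalizer", "compute_kinship",
    "structure_pcs", "EmmaNull", "LinearMixedScan", "fit_null_lmm",
    "gls_scan", "permutation_empirical_p", "effective_tests",
    "classify_cis_trans", "merge_lead_loci", "lambda_gc", "marker_r2",
]


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based mapping to standard-normal scores.

    Average ranks for ties, Phi^{-1}(rank / (n + 1)); missing values are
    preserved as NaN. A constant vector maps to all zeros (with warning).
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    x = v[ok]
    if np.ptp(x) == 0:
        warnings.warn("constant vector quantile-normalized to zeros")
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(x, method="average")
    out[ok] = stats.norm.ppf(ranks / (n + 1.0))
    return out


class QuantileNormalizer:
    """Column-wise quantile normalization as an sklearn-style transformer."""

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "QuantileNormalizer":
        return self

    def fit(self, X, y=None) -> "QuantileNormalizer":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return quantile_normalize(X)
        return np.column_stack([quantile_normalize(X[:, j]) for j in range(X.shape[1])])


def _impute_and_center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing marker values; return (imputed, column means)."""
    X = np.asarray(X, dtype=float)
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    out = np.where(np.isfinite(X), X, mu)
    return out, mu


def compute_kinship(markers: np.ndarray) -> np.ndarray:
    """VanRaden kinship K = Z Z' / sum(2 p (1-p)) from an (n_samples x
    n_markers) additive code matrix (SNP dosages or SMP codes alike).

    Missing cells are mean-imputed; monomorphic columns are dropped.
    """
    X, mu = _impute_and_center(markers)
    p = mu / 2.0
    keep = (p > 0) & (p < 1)
    X, p = X[:, keep], p[keep]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic markers for kinship")
    Z = X - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    K = (Z @ Z.T) / denom
    return (K + K.T) / 2.0


def structure_pcs(markers: np.ndarray, n_pcs: int) -> np.ndarray:
    """Leading principal components of the centered marker matrix."""
    if n_pcs == 0:
        return np.empty((markers.shape[0], 0))
    from sklearn.decomposition import PCA

    X, mu = _impute_and_center(markers)
    X = X - mu
    n_pcs = min(n_pcs, min(X.shape) - 1)
    return PCA(n_components=n_pcs, svd_solver="auto", random_state=0).fit_transform(X)


def lambda_gc(pvalues: np.ndarray) -> float:
    """Genomic-control inflation factor from two-sided p-values."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


class EmmaNull:
    """Spectral machinery for the EMMAX null model, shared across phenotypes.

    Precomputes the eigendecomposition of K (for whitening) and of the
    covariate-projected kinship (for the restricted likelihood), so that
    fitting each phenotype is a cheap 1-D optimization.
    """

    def __init__(self, K: np.ndarray, covariates: np.ndarray | None = None,
                 add_intercept: bool = True):
        K = np.asarray(K, dtype=float)
        n = K.shape[0]
        if K.shape != (n, n):
            raise ValueError("K must be square")
        if np.max(np.abs(K - K.T)) > 1e-8:
            raise ValueError("K must be symmetric")
        C = np.ones((n, 1)) if add_intercept else np.empty((n, 0))
        if covariates is not None and np.size(covariates):
            covariates = np.asarray(covariates, dtype=float)
            if covariates.ndim == 1:
                covariates = covariates[:, None]
            C = np.hstack([C, covariates])
        if C.shape[1] == 0:
            raise ValueError("model needs at least an intercept")
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        self.n, self.p = n, C.shape[1]
        self.K, self.C = K, C
        lam, U = np.linalg.eigh(K)
        if lam.min() < -1e-6:
            raise ValueError("kinship matrix is not PSD")
        self.lam = np.maximum(lam, 0.0)
        self.U = U
        # restricted spectrum: eigendecomposition of S K S, S = I - C (C'C)^-1 C'
        Q, _ = np.linalg.qr(C)
        S = np.eye(n) - Q @ Q.T
        xi, Us = np.linalg.eigh(S @ K @ S)
        order = np.argsort(xi)[::-1]
        self.xi = np.maximum(xi[order][: n - self.p], 0.0)
        self.Us = Us[:, order][:, : n - self.p]

    # -- restricted likelihood ------------------------------------------
    def _reml_ll(self, log_delta: float, eta2: np.ndarray) -> float:
        delta = np.exp(log_delta)
        w = self.xi + delta
        nq = self.n - self.p
        return 0.5 * (
            nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(np.sum(eta2 / w)))
            - np.sum(np.log(w))
        )

    def fit(self, y: np.ndarray) -> "FittedNull":
        """REML variance components for one phenotype."""
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("phenotype has missing values; subset first")
        eta = self.Us.T @ y
        eta2 = eta**2
        grid = np.linspace(-10.0, 10.0, 41)
        lls = np.array([self._reml_ll(g, eta2) for g in grid])
        g0 = grid[np.argmax(lls)]
        res = minimize_scalar(
            lambda g: -self._reml_ll(g, eta2),
            bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        log_delta = res.x if -res.fun >= lls.max() else g0
        delta = float(np.exp(log_delta))
        nq = self.n - self.p
        sigma_g2 = float(np.sum(eta2 / (self.xi + delta)) / nq)
        sigma_e2 = delta * sigma_g2
        ols_fallback = log_delta >= 9.5  # variance ratio at the boundary
        return FittedNull(self, y, delta, sigma_g2, sigma_e2, ols_fallback)


@dataclass
class FittedNull:
    """A phenotype's fitted null model plus the whitening transform."""

    null: EmmaNull
    y: np.ndarray
    delta: float
    sigma_g2: float
    sigma_e2: float
    ols_fallback: bool
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def h2(self) -> float:
        return 1.0 / (1.0 + self.delta)

    def _whitened(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(y_resid, Qc, w) with covariates projected out in whitened space."""
        if "wh" not in self._cache:
            w = self.null.lam + self.delta
            sw = 1.0 / np.sqrt(w)
            yt = (self.null.U.T @ self.y) * sw
            Ct = (self.null.U.T @ self.null.C) * sw[:, None]
            Qc, _ = np.linalg.qr(Ct)
            y_res = yt - Qc @ (Qc.T @ yt)
            self._cache["wh"] = (y_res, Qc, sw)
        return self._cache["wh"]

    def whiten_markers(self, G: np.ndarray) -> np.ndarray:
        """Whiten and covariate-residualize an (n x m) marker matrix."""
        G, _ = _impute_and_center(G)
        _, Qc, sw = self._whitened()
        Gt = (self.null.U.T @ G) * sw[:, None]
        return Gt - Qc @ (Qc.T @ Gt)

    def scan(self, G: np.ndarray) -> pd.DataFrame:
        """GLS per-marker test with fixed variance components.

        Returns beta, se, t, p per marker; monomorphic markers get NaN.
        """
        y_res, _, _ = self._whitened()
        Gt = self.whiten_markers(G)
        gg = np.einsum("ij,ij->j", Gt, Gt)
        gy = Gt.T @ y_res
        dof = self.null.n - self.null.p - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = gy / gg
            rss = float(y_res @ y_res) - beta * gy
            se = np.sqrt(rss / dof / gg)
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        bad = gg <= 1e-12
        for arr in (beta, se, tstat):
            arr[bad] = np.nan
        pvals[bad] = np.nan
        return pd.DataFrame({"beta": beta, "se": se, "t": tstat, "p": pvals})


def fit_null_lmm(
    y: np.ndarray, K: np.ndarray, covariates: np.ndarray | None = None
) -> FittedNull:
    """Thin wrapper: REML variance components and whitening transform."""
    return EmmaNull(K, covariates).fit(y)


def gls_scan(fitted: FittedNull, markers: np.ndarray) -> pd.DataFrame:
    """Thin wrapper over :meth:`FittedNull.scan`."""
    return fitted.scan(markers)


class LinearMixedScan:
    """sklearn-style estimator: EMMAX mixed-model association scan.

    Parameters are the kinship and fixed covariates; ``fit(X, y)`` runs
    the null REML then scores every column of X, leaving ``results_``,
    ``h2_``, ``delta_`` and variance components as fitted attributes.
    """

    def __init__(self, kinship: np.ndarray | None = None,
                 covariates: np.ndarray | None = None):
        self.kinship = kinship
        self.covariates = covariates

    def get_params(self, deep: bool = True) -> dict:
        return {"kinship": self.kinship, "covariates": self.covariates}

    def set_params(self, **params) -> "LinearMixedScan":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearMixedScan":
        X = np.asarray(X, dtype=float)
        K = self.kinship if self.kinship is not None else np.eye(X.shape[0])
        null = EmmaNull(K, self.covariates)
        fitted = null.fit(np.asarray(y, dtype=float))
        self.null_ = fitted
        self.delta_ = fitted.delta
        self.h2_ = fitted.h2
        self.sigma_g2_ = fitted.sigma_g2
        self.sigma_e2_ = fitted.sigma_e2
        self.ols_fallback_ = fitted.ols_fallback
        self.results_ = fitted.scan(X)
        return self

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Negative log10 of the strongest association (for model selection)."""
        self.fit(X, y)
        return float(-np.log10(np.nanmin(self.results_["p"])))


def permutation_empirical_p(
    fitted: FittedNull,
    markers: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    beta_approx: bool = True,
) -> dict:
    """Permutation empirical p-value for the lead marker of a window.

    The whitened, covariate-residualized phenotype is permuted (seeded);
    the window is rescanned per permutation and the lead (minimum) p
    compared: empirical p = (1 + #{perm min-p <= observed}) / (1 + B).
    With ``beta_approx`` a Beta distribution is fitted by ML to the
    permutation minima and its CDF at the observed minimum reported too.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse empirical p")
    y_res, _, _ = fitted._whitened()
    Gt = fitted.whiten_markers(markers)
    norms = np.sqrt(np.einsum("ij,ij->j", Gt, Gt))
    ok = norms > 1e-12
    if not ok.any():
        raise ValueError("no polymorphic marker in window")
    Gn = Gt[:, ok] / norms[ok]
    yn = y_res / np.linalg.norm(y_res)
    dof = fitted.null.n - fitted.null.p - 1

    def minp_from_r2(r2_max: np.ndarray) -> np.ndarray:
        r2_max = np.clip(r2_max, 0.0, 1.0 - 1e-15)
        t2 = dof * r2_max / (1.0 - r2_max)
        return 2.0 * stats.t.sf(np.sqrt(t2), dof)

    r_obs = yn @ Gn
    obs_r2 = float(np.max(r_obs**2))
    lead_local = int(np.argmax(r_obs**2))
    lead_idx = int(np.flatnonzero(ok)[lead_local])
    obs_minp = float(minp_from_r2(np.array([obs_r2]))[0])

    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, len(yn)))
    for b in range(n_perm):
        perm[b] = yn[rng.permutation(len(yn))]
    R = perm @ Gn
    perm_minp = minp_from_r2((R**2).max(axis=1))
    p_emp = (1.0 + np.sum(perm_minp <= obs_minp)) / (1.0 + n_perm)
    out = {
        "lead_idx": lead_idx,
        "p_nominal": obs_minp,
        "p_empirical": float(p_emp),
        "n_perm": n_perm,
    }
    if beta_approx:
        eps = 1e-12
        x = np.clip(perm_minp, eps, 1 - eps)
        try:
            a, b_, _, _ = stats.beta.fit(x, floc=0, fscale=1)
            out["p_beta"] = float(stats.beta.cdf(obs_minp, a, b_))
            out["beta_shape"] = (float(a), float(b_))
        except Exception:  # degenerate permutation distribution
            out["p_beta"] = float(p_emp)
    return out


def effective_tests(
    markers: np.ndarray, window: int = 1000, alpha: float = 0.05
) -> tuple[float, float]:
    """Effective number of independent tests (Li–Ji eigenvalue method,
    summed over sliding correlation blocks) and the genome-wide threshold
    alpha / M_eff.

    markers : (n_samples, m) additive codes; missing mean-imputed.
    """
    X, _ = _impute_and_center(markers)
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    m = X.shape[1]
    if m == 0:
        raise ValueError("no polymorphic markers")
    meff = 0.0
    for lo in range(0, m, window):
        block = X[:, lo: lo + window]
        if block.shape[1] == 1:
            meff += 1.0
            continue
        corr = np.corrcoef(block, rowvar=False)
        lam = np.round(np.abs(np.linalg.eigvalsh(corr)), 8)  # guard float fuzz
        meff += float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    return meff, alpha / meff


def classify_cis_trans(
    marker_chrom: str,
    marker_pos: int,
    target_chrom: str,
    anchor_start: int,
    anchor_end: int | None = None,
    window_bp: float = 1_000_000,
) -> tuple[str, int]:
    """cis iff same chromosome and distance <= window_bp (inclusive).

    The anchor may be a point (SMP position, gene midpoint) or an
    interval (gene body); distance is 0 inside the interval. Returns
    (label, distance_bp); distance is -1 across chromosomes.
    """
    if not marker_chrom or not target_chrom:
        raise ValueError("unknown chromosome")
    if marker_chrom != target_chrom:
        return "trans", -1
    if anchor_end is None:
        anchor_end = anchor_start
    if anchor_start <= marker_pos <= anchor_end:
        dist = 0
    else:
        dist = int(min(abs(marker_pos - anchor_start), abs(marker_pos - anchor_end)))
    return ("cis" if dist <= window_bp else "trans"), dist


def marker_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors (pairwise complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def merge_lead_loci(
    results: pd.DataFrame,
    marker_matrix: np.ndarray,
    marker_index: pd.DataFrame,
    r2_threshold: float = 0.1,
    by_target: bool = True,
) -> list[Locus]:
    """Single-linkage merge of significant markers with pairwise r2 >
    threshold into loci (per target by default).

    results : rows with marker_idx (row into marker_matrix/marker_index),
        target_id, p. marker_index supplies chrom/pos per marker.
    The lead is the minimum-p member; ties break to the smaller position.
    Output ordering is by (target, chrom, start) and is invariant to
    input row order.
    """
    if results.empty:
        return []
    req = {"marker_idx", "target_id", "p"}
    if not req.issubset(results.columns):
        raise ValueError(f"results needs columns {sorted(req)}")
    loci: list[Locus] = []
    groups = results.groupby("target_id") if by_target else [(None, results)]
    for target, grp in groups:
        grp = grp.sort_values(["p", "marker_idx"]).drop_duplicates("marker_idx")
        idx = grp["marker_idx"].to_numpy()
        chroms = marker_index["chrom"].to_numpy()[idx]
        pos = marker_index["pos"].to_numpy()[idx]
        k = len(idx)
        parent = list(range(k))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(k):
            for j in range(i + 1, k):
                if chroms[i] != chroms[j]:
                    continue
                r2 = marker_r2(marker_matrix[idx[i]], marker_matrix[idx[j]])
                if np.isfinite(r2) and r2 > r2_threshold:
                    pi, pj = find(i), find(j)
                    if pi != pj:
                        parent[max(pi, pj)] = min(pi, pj)
        clusters: dict[int, list[int]] = {}
        for i in range(k):
            clusters.setdefault(find(i), []).append(i)
        ps = grp["p"].to_numpy()
        for members in clusters.values():
            order = sorted(members, key=lambda i: (ps[i], pos[i]))
            lead = order[0]
            loci.append(Locus(
                lead_marker=str(idx[lead]),
                members=[str(idx[i]) for i in sorted(members, key=lambda i: pos[i])],
                chrom=str(chroms[lead]),
                start=int(pos[members[0]] if len(members) == 1 else min(pos[i] for i in members)),
                end=int(max(pos[i] for i in members)),
                target=str(target),
                lead_p=float(ps[lead]),
                lead_pos=int(pos[lead]),
            ))
    loci.sort(key=lambda L: (L.target, L.chrom, L.start))
    return loci
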