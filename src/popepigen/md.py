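"""Methylation disequilibrium (MD) statistics between SMP pairs.

For two SMPs with epi-alleles M1/U1 and M2/U2 at frequencies p_M1, p_U1,
p_M2, p_U2 and joint epi-haplotype frequency p_M1M2,

    MD  = p_M1M2 - p_M1 * p_M2
    Mr2 = MD^2 / (p_M1 p_U1 p_M2 p_U2)

Unphased epi-genotypes leave the double-heterozygote haplotype assignment
ambiguous; two estimators are provided:

``composite``
    Burrows' composite disequilibrium on 0/1/2 codes. Mr2 is the
    composite r^2 with the Zaykin homozygosity-corrected denominator,
    which equals the squared Pearson correlation of the codes; the
    reported MD is half the composite Delta. Both reduce exactly to the
    haplotype formulas when no accession is heterozygous.

``em_phase``
    Maximum-likelihood haplotype frequencies by EM over the
    double-heterozygote ambiguity; MD and Mr2 then follow the haplotype
    formulas exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, EpiGenotypeMatrix


@dataclass
class PairwiseMD:
    site_a: int
    site_b: int
    distance: int
    p_m1: float
    p_m2: float
    p_m1m2: float
    md: float
    mr2: float
    n_used: int
    method: str


def mr2_from_haplotype_counts(n_mm: int, n_mu: int, n_um: int, n_uu: int) -> PairwiseMD:
    """MD/Mr2 from phased epi-haplotype counts (M1M2, M1U2, U1M2, U1U2)."""
    n = n_mm + n_mu + n_um + n_uu
    if n == 0:
        raise ValueError("no haplotypes")
    p_m1m2 = n_mm / n
    p_m1 = (n_mm + n_mu) / n
    p_m2 = (n_mm + n_um) / n
    md = p_m1m2 - p_m1 * p_m2
    denom = p_m1 * (1 - p_m1) * p_m2 * (1 - p_m2)
    mr2 = md * md / denom if denom > 0 else np.nan
    return PairwiseMD(-1, -1, 0, p_m1, p_m2, p_m1m2, md, mr2, n, "haplotype")


def _joint_codes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = (x != MISSING) & (y != MISSING)
    return x[ok].astype(float), y[ok].astype(float)


def composite_md(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, int]:
    """Composite (Burrows) estimator on additive codes.

    Returns (p_m1, p_m2, MD, Mr2, n). MD = Delta/2; Mr2 = squared Pearson
    correlation of codes (composite r^2 with Zaykin denominator).
    """
    xv, yv = _joint_codes(np.asarray(x), np.asarray(y))
    n = xv.size
    if n == 0:
        return np.nan, np.nan, np.nan, np.nan, 0
    p1, p2 = xv.mean() / 2.0, yv.mean() / 2.0
    delta = (xv * yv).mean() / 2.0 - 2.0 * p1 * p2
    md = delta / 2.0
    vx, vy = xv.var(), yv.var()
    if vx <= 0 or vy <= 0:
        return p1, p2, md, np.nan, n
    cov = (xv * yv).mean() - xv.mean() * yv.mean()
    mr2 = min(1.0, (cov * cov) / (vx * vy))
    return p1, p2, md, mr2, n


def em_haplotype_frequencies(
    x: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 2000
) -> tuple[np.ndarray, int]:
    """EM haplotype frequencies (p_MM, p_MU, p_UM, p_UU) from unphased codes."""
    xv, yv = _joint_codes(np.asarray(x), np.asarray(y))
    n = xv.size
    if n == 0:
        raise ValueError("no jointly called accessions")
    counts = np.zeros((3, 3))
    for gx in range(3):
        for gy in range(3):
            counts[gx, gy] = np.sum((xv == gx) & (yv == gy))
    # unambiguous haplotype contributions
    base = np.zeros(4)  # MM, MU, UM, UU  (first index site a allele)
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    n_dh = counts[1, 1]
    p = np.full(4, 0.25)
    for it in range(max_iter):
        denom = p[0] * p[3] + p[1] * p[2]
        pi = 0.5 if denom <= 0 else p[0] * p[3] / denom
        c = base.copy()
        c[0] += n_dh * pi
        c[3] += n_dh * pi
        c[1] += n_dh * (1 - pi)
        c[2] += n_dh * (1 - pi)
        p_new = c / (2.0 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return p, n


def em_md(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, int]:
    p, n = em_haplotype_frequencies(x, y)
    p_m1 = p[0] + p[1]
    p_m2 = p[0] + p[2]
    md = p[0] - p_m1 * p_m2
    denom = p_m1 * (1 - p_m1) * p_m2 * (1 - p_m2)
    mr2 = min(1.0, md * md / denom) if denom > 0 else np.nan
    return p_m1, p_m2, md, mr2, n


def pairwise_mr2(
    epi: EpiGenotypeMatrix,
    site_a: int,
    site_b: int,
    method: str = "composite",
    n_min: int = 20,
) -> PairwiseMD:
    """MD statistics between two sites of an epi-genotype matrix."""
    x = epi.codes[site_a]
    y = epi.codes[site_b]
    n_joint = int(((x != MISSING) & (y != MISSING)).sum())
    if n_joint < n_min:
        raise ValueError(
            f"only {n_joint} jointly called accessions (< n_min={n_min})"
        )
    if method == "composite":
        p1, p2, md, mr2, n = composite_md(x, y)
    elif method == "em_phase":
        p1, p2, md, mr2, n = em_md(x, y)
    else:
        raise ValueError("method must be 'composite' or 'em_phase'")
    sa, sb = epi.sites.iloc[site_a], epi.sites.iloc[site_b]
    dist = abs(int(sa["pos"]) - int(sb["pos"])) if sa["chrom"] == sb["chrom"] else -1
    p_m1m2 = p1 * p2 + md
    return PairwiseMD(site_a, site_b, dist, p1, p2, p_m1m2, md, mr2, n, method)


def pairwise_r2_codes(
    codes: np.ndarray, ia: np.ndarray, ib: np.ndarray,
    n_min: int = 20, chunk: int = 200_000,
) -> np.ndarray:
    """Vectorized composite Mr2 (squared code correlation) for pair lists.

    codes : (n_sites, n_accessions) int codes with -1 missing.
    """
    X = codes.astype(float)
    M = codes != MISSING
    X = np.where(M, X, 0.0)
    Mf = M.astype(float)
    out = np.empty(len(ia))
    for lo in range(0, len(ia), chunk):
        hi = min(lo + chunk, len(ia))
        a, b = ia[lo:hi], ib[lo:hi]
        mm = Mf[a] * Mf[b]
        n = mm.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = (X[a] * mm).sum(axis=1) / n
            sy = (X[b] * mm).sum(axis=1) / n
            sxx = (X[a] ** 2 * mm).sum(axis=1) / n
            syy = (X[b] ** 2 * mm).sum(axis=1) / n
            sxy = (X[a] * X[b] * mm).sum(axis=1) / n
            vx = sxx - sx * sx
            vy = syy - sy * sy
            cov = sxy - sx * sy
            r2 = cov * cov / (vx * vy)
        r2[(n < n_min) | ~np.isfinite(r2)] = np.nan
        out[lo:hi] = np.minimum(r2, 1.0)
    return out


@dataclass
class DecayProfile:
    """Binned Mr2 decay with distance and its half-decay distance."""

    bins: pd.DataFrame  # left, mid, right, mean_mr2, median_mr2, n_pairs
    half_decay_bp: float
    n_pairs_total: int

    def is_empty(self) -> bool:
        return self.bins.empty


def _half_decay(bins: pd.DataFrame, plateau_fraction: float = 0.25) -> float:
    """Smallest bin midpoint where mean Mr2 <= (max + plateau)/2.

    The plateau is the mean over the farthest ``plateau_fraction`` of
    bins, making the midpoint robust to a non-zero baseline.
    """
    valid = bins[bins["n_pairs"] > 0]
    if len(valid) < 2:
        return np.nan
    means = valid["mean_mr2"].to_numpy()
    k = max(1, int(np.ceil(len(valid) * plateau_fraction)))
    plateau = means[-k:].mean()
    thr = (means.max() + plateau) / 2.0
    below = valid["mid"].to_numpy()[means <= thr]
    return float(below[0]) if below.size else np.nan


def md_decay(
    epi: EpiGenotypeMatrix,
    max_distance: int = 2000,
    bin_width: int = 10,
    context: str | None = None,
    pair_budget: int = 2_000_000,
    n_min: int = 20,
    seed: int = 0,
) -> DecayProfile:
    """Mean/median Mr2 in distance bins over all within-chromosome pairs
    up to ``max_distance`` (seeded subsample above ``pair_budget``)."""
    if max_distance < bin_width:
        raise ValueError("max_distance must be >= bin_width")
    sub = epi
    if context is not None:
        sub = epi.subset_sites((epi.sites["context"] == context).to_numpy())
    maf = sub.maf()
    poly = np.isfinite(maf) & (maf > 0)
    sub = sub.subset_sites(poly)
    edges = np.arange(0, max_distance + bin_width, bin_width)
    empty = pd.DataFrame(
        columns=["left", "mid", "right", "mean_mr2", "median_mr2", "n_pairs"]
    )
    if sub.n_sites < 2:
        return DecayProfile(empty, np.nan, 0)

    ia_all, ib_all = [], []
    pos = sub.sites["pos"].to_numpy()
    chroms = sub.sites["chrom"].to_numpy()
    offset = 0
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        p = pos[sel]
        right = np.searchsorted(p, p + max_distance, side="right")
        for k, i in enumerate(sel):
            j = sel[k + 1: right[k]]
            if j.size:
                ia_all.append(np.full(j.size, i))
                ib_all.append(j)
    if not ia_all:
        return DecayProfile(empty, np.nan, 0)
    ia = np.concatenate(ia_all)
    ib = np.concatenate(ib_all)
    if len(ia) > pair_budget:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(ia), size=pair_budget, replace=False)
        ia, ib = ia[pick], ib[pick]
    dist = np.abs(pos[ib] - pos[ia])
    r2 = pairwise_r2_codes(sub.codes, ia, ib, n_min=n_min)
    ok = np.isfinite(r2)
    dist, r2 = dist[ok], r2[ok]
    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        vals = r2[which == b]
        rows.append({
            "left": edges[b], "mid": (edges[b] + edges[b + 1]) / 2.0,
            "right": edges[b + 1],
            "mean_mr2": float(vals.mean()) if vals.size else np.nan,
            "median_mr2": float(np.median(vals)) if vals.size else np.nan,
            "n_pairs": int(vals.size),
        })
    bins = pd.DataFrame(rows)
    return DecayProfile(bins, _half_decay(bins), int(ok.sum()))


def md_blocks(
    epi: EpiGenotypeMatrix,
    r2_threshold: float = 0.1,
    max_gap: int = 10_000,
    n_min: int = 20,
) -> list[dict]:
    """Greedy chaining of consecutive sites into MD blocks.

    Adjacent sites are joined while their pairwise Mr2 >= r2_threshold and
    the gap <= max_gap; a block records chrom, span and member site indices.
    """
    n = epi.n_sites
    if n == 0:
        return []
    chroms = epi.sites["chrom"].to_numpy()
    pos = epi.sites["pos"].to_numpy()
    if n > 1:
        ia = np.arange(n - 1)
        r2_adj = pairwise_r2_codes(epi.codes, ia, ia + 1, n_min=n_min)
    blocks = []
    members = [0]
    for i in range(1, n):
        joined = (
            chroms[i] == chroms[i - 1]
            and pos[i] - pos[i - 1] <= max_gap
            and np.isfinite(r2_adj[i - 1])
            and r2_adj[i - 1] >= r2_threshold
        )
        if joined:
            members.append(i)
        else:
            blocks.append(members)
            members = [i]
    blocks.append(members)
    return [
        {
            "chrom": chroms[m[0]],
            "start": int(pos[m[0]]),
            "end": int(pos[m[-1]]),
            "sites": m,
            "n_sites": len(m),
        }
        for m in blocks
    ]
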