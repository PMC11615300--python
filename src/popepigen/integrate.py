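"""Multi-omics synthesis on top of the scan results.

Covers: regulatory typing of eQTM genes against meQTL evidence,
EWAS x GWAS co-localization, gene-regulatory-network construction by
LD-block co-localization of trait loci with eQTL/eQTM leads, elite
epi-allele pyramiding, and GBLUP phenotype prediction from SNP- and/or
SMP-derived kinships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import EmmaNull, marker_r2


# ---------------------------------------------------------------------------
# eQTM gene typing (genetic vs epigenetic regulation)

def classify_eqtm_genes(
    eqtm_leads: pd.DataFrame,
    meqtl_results: pd.DataFrame,
    tested_sites: set | None = None,
) -> pd.DataFrame:
    """Type each eQTM gene by the meQTL status of its lead SMP.

    type I   : the SMP has a significant cis-meQTL (genetic & cis-epigenetic)
    type II  : only trans-meQTL evidence (genetic & trans-epigenetic)
    type III : no significant meQTL (epigenetic regulated only)
    unclassified : the SMP was never tested for meQTL

    eqtm_leads needs gene_id and site_idx (the lead SMP row);
    meqtl_results needs site_idx and label in {cis, trans}.
    """
    if "site_idx" not in eqtm_leads.columns:
        raise ValueError("eqtm_leads needs a site_idx column (lead SMP)")
    cis_sites = set(meqtl_results.loc[meqtl_results["label"] == "cis", "site_idx"])
    trans_sites = set(meqtl_results.loc[meqtl_results["label"] == "trans", "site_idx"])
    rows = []
    for _, r in eqtm_leads.iterrows():
        s = int(r["site_idx"])
        if tested_sites is not None and s not in tested_sites:
            cls = "unclassified"
        elif s in cis_sites:
            cls = "I"
        elif s in trans_sites:
            cls = "II"
        else:
            cls = "III"
        rows.append({"gene_id": r["gene_id"], "site_idx": s, "type": cls})
    out = pd.DataFrame(rows, columns=["gene_id", "site_idx", "type"])
    return out


def regulation_type_fractions(typed: pd.DataFrame) -> pd.Series:
    counts = typed["type"].value_counts()
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# EWAS x GWAS co-localization

def colocalize_ewas_gwas(
    ewas_loci: pd.DataFrame,
    gwas_loci: pd.DataFrame,
    distance_bp: int = 20_000,
    meqtl_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Partition EWAS and GWAS loci into shared vs study-specific, with
    the four-way regulatory typing of trait loci.

    An EWAS locus is "shared" iff a same-trait GWAS locus lies within
    ``distance_bp`` (absolute distance of lead positions). Classes:
    epigenetic_only (EWAS not shared), genetic_only (GWAS not shared),
    genetic_cis_epigenetic / genetic_trans_epigenetic (shared, by the
    meQTL evidence at the EWAS lead SMP; shared loci without meQTL
    evidence are genetic_epigenetic_unresolved).

    Both tables need trait, chrom and a lead position column (``pos`` or
    ``lead_pos``). Traits present in one table but not the other raise.
    """
    def _pos(df):
        return df["pos"] if "pos" in df.columns else df["lead_pos"]

    t_e, t_g = set(ewas_loci["trait"]), set(gwas_loci["trait"])
    unmatched = sorted(t_e ^ t_g)
    if unmatched:
        raise ValueError(f"trait names unmatched between locus sets: {unmatched}")
    cis_sites, trans_sites = set(), set()
    if meqtl_results is not None and len(meqtl_results):
        cis_sites = set(meqtl_results.loc[meqtl_results["label"] == "cis", "site_idx"])
        trans_sites = set(meqtl_results.loc[meqtl_results["label"] == "trans", "site_idx"])
    rows = []
    e_pos, g_pos = _pos(ewas_loci).to_numpy(), _pos(gwas_loci).to_numpy()
    for i, e in ewas_loci.reset_index(drop=True).iterrows():
        same = (
            (gwas_loci["trait"] == e["trait"]).to_numpy()
            & (gwas_loci["chrom"] == e["chrom"]).to_numpy()
            & (np.abs(g_pos - e_pos[i]) <= distance_bp)
        )
        shared = bool(same.any())
        if not shared:
            cls = "epigenetic_only"
        else:
            s = int(e["lead_site_idx"]) if "lead_site_idx" in e else None
            if s is not None and s in cis_sites:
                cls = "genetic_cis_epigenetic"
            elif s is not None and s in trans_sites:
                cls = "genetic_trans_epigenetic"
            else:
                cls = "genetic_epigenetic_unresolved"
        rows.append({"source": "EWAS", "trait": e["trait"], "chrom": e["chrom"],
                     "pos": int(e_pos[i]), "shared": shared, "class": cls})
    for j, g in gwas_loci.reset_index(drop=True).iterrows():
        same = (
            (ewas_loci["trait"] == g["trait"]).to_numpy()
            & (ewas_loci["chrom"] == g["chrom"]).to_numpy()
            & (np.abs(e_pos - g_pos[j]) <= distance_bp)
        )
        shared = bool(same.any())
        rows.append({"source": "GWAS", "trait": g["trait"], "chrom": g["chrom"],
                     "pos": int(g_pos[j]), "shared": shared,
                     "class": "shared" if shared else "genetic_only"})
    return pd.DataFrame(rows, columns=["source", "trait", "chrom", "pos",
                                       "shared", "class"])


# ---------------------------------------------------------------------------
# GRN construction by LD-block co-localization

def build_grn(
    trait_loci: pd.DataFrame,
    regulatory_results: pd.DataFrame,
    marker_matrix: np.ndarray,
    r2_threshold: float = 0.1,
) -> pd.DataFrame:
    """Join trait loci (GWAS or EWAS) to regulatory leads (eQTL or eQTM)
    in the same LD/MD block and emit edges to the regulated genes.

    trait_loci : trait, chrom, marker_idx (row into marker_matrix), p.
    regulatory_results : target_id (gene), chrom, marker_idx, p — one row
        per significant marker-gene pair (leads suffice).
    Edge created when the trait-locus marker and the regulatory marker
    are on the same chromosome with r^2 > r2_threshold.
    """
    edges = []
    block = 0
    for _, t in trait_loci.iterrows():
        linked = regulatory_results[regulatory_results["chrom"] == t["chrom"]]
        hit_genes = {}
        for _, r in linked.iterrows():
            r2 = marker_r2(marker_matrix[int(t["marker_idx"])],
                           marker_matrix[int(r["marker_idx"])])
            if np.isfinite(r2) and r2 > r2_threshold:
                prev = hit_genes.get(r["target_id"])
                if prev is None or r["p"] < prev["p"]:
                    hit_genes[r["target_id"]] = r
        if hit_genes:
            for gene, r in sorted(hit_genes.items()):
                edges.append({
                    "source_marker_idx": int(t["marker_idx"]),
                    "trait": t["trait"], "chrom": t["chrom"],
                    "target_gene": gene, "edge_p": float(r["p"]),
                    "block_id": block,
                })
            block += 1
    return pd.DataFrame(edges, columns=["source_marker_idx", "trait", "chrom",
                                        "target_gene", "edge_p", "block_id"])


def network_overlap(edges_a: pd.DataFrame, edges_b: pd.DataFrame) -> dict:
    """Shared regulated genes between two networks (e.g. genetic vs epigenetic)."""
    a = set(edges_a["target_gene"]) if len(edges_a) else set()
    b = set(edges_b["target_gene"]) if len(edges_b) else set()
    return {"n_a": len(a), "n_b": len(b), "n_shared": len(a & b),
            "shared_genes": sorted(a & b)}


def edges_to_graphml(edges: pd.DataFrame, path) -> None:
    """Write the edge list as GraphML (markers and genes as nodes)."""
    import networkx as nx

    g = nx.DiGraph()
    for _, e in edges.iterrows():
        src = f"locus_{e['chrom']}_{e['source_marker_idx']}"
        g.add_node(src, kind="trait_locus", trait=str(e["trait"]))
        g.add_node(str(e["target_gene"]), kind="gene")
        g.add_edge(src, str(e["target_gene"]), p=float(e["edge_p"]),
                   block=int(e["block_id"]))
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Elite epi-allele pyramiding

def jonckheere_terpstra(groups: list[np.ndarray], alternative: str = "increasing"
                        ) -> tuple[float, float]:
    """Jonckheere–Terpstra trend test across ordered groups.

    Normal approximation with mean (N^2 - sum n_i^2)/4 and the no-ties
    variance; ties contribute 1/2 to the pairwise counts. One-sided p for
    the stated direction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        return np.nan, np.nan
    U = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i][:, None], groups[j][None, :]
            U += np.sum(a < b) + 0.5 * np.sum(a == b)
    ns = np.array([len(g) for g in groups])
    N = ns.sum()
    mean = (N * N - np.sum(ns**2)) / 4.0
    var = (N * N * (2 * N + 3) - np.sum(ns**2 * (2 * ns + 3))) / 72.0
    if var <= 0:
        return np.nan, np.nan
    z = (U - mean) / np.sqrt(var)
    if alternative == "decreasing":
        z = -z
    return float(z), float(stats.norm.sf(z))


def pyramiding_analysis(
    ewas_loci: pd.DataFrame,
    epi,
    phenotypes: pd.DataFrame,
    trait_directions: dict,
    het_weight: float = 0.5,
    min_carriers: int = 3,
) -> dict:
    """Count elite epi-alleles per accession and test the trait trend.

    At each trait-associated locus the elite epi-allele is the homozygous
    class (MM or UU) whose carriers show the more favorable mean trait
    (per ``trait_directions``: 'higher' or 'lower' is better).
    Heterozygous MU carriers contribute ``het_weight`` (set 0 for strict
    counting). Loci with only one homozygous class observed are dropped.

    Returns per-trait dicts with the per-accession count, group trait
    means, and a Jonckheere–Terpstra monotone-trend p-value.
    """
    acc = list(epi.accessions)
    pheno = phenotypes.loc[acc]
    out = {}
    for trait, grp in ewas_loci.groupby("trait"):
        if trait not in trait_directions:
            raise ValueError(f"no direction of merit declared for trait {trait}")
        higher_better = trait_directions[trait] == "higher"
        y = pheno[trait].to_numpy(dtype=float)
        counts = np.zeros(len(acc))
        n_used = 0
        elite_classes = {}
        for _, locus in grp.iterrows():
            codes = epi.codes[int(locus["lead_site_idx"])]
            mm, uu = codes == 2, codes == 0
            ok = np.isfinite(y)
            if (mm & ok).sum() < min_carriers or (uu & ok).sum() < min_carriers:
                continue
            mean_mm = float(np.mean(y[mm & ok]))
            mean_uu = float(np.mean(y[uu & ok]))
            mm_elite = (mean_mm > mean_uu) if higher_better else (mean_mm < mean_uu)
            elite = mm if mm_elite else uu
            elite_classes[locus.get("locus_id", n_used)] = "MM" if mm_elite else "UU"
            counts += elite.astype(float) + het_weight * (codes == 1)
            n_used += 1
        groups_lbl = np.round(counts * 2) / 2  # half-steps from het_weight
        levels = np.unique(groups_lbl)
        group_stats = pd.DataFrame({
            "elite_count": levels,
            "n": [int(np.sum(groups_lbl == g)) for g in levels],
            "trait_mean": [float(np.nanmean(y[groups_lbl == g])) for g in levels],
        })
        ordered = [y[(groups_lbl == g) & np.isfinite(y)] for g in levels]
        z, p = jonckheere_terpstra(
            ordered, "increasing" if higher_better else "decreasing")
        out[trait] = {
            "elite_count": pd.Series(counts, index=acc),
            "elite_classes": elite_classes,
            "n_loci_used": n_used,
            "group_summary": group_stats,
            "trend_z": z,
            "trend_p": p,
        }
    return out


# ---------------------------------------------------------------------------
# GBLUP phenotype prediction

class GBLUP:
    """Genomic BLUP with a precomputed kinship (sklearn-style regressor).

    ``fit(K, y)`` takes the train x train kinship; ``predict(K_cross)``
    the test x train kinship block. Variance components by REML on the
    intercept-only mixed model; near-singular systems get a ridge jitter.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def get_params(self, deep: bool = True) -> dict:
        return {"ridge": self.ridge}

    def set_params(self, **params) -> "GBLUP":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, K: np.ndarray, y: np.ndarray) -> "GBLUP":
        K = np.asarray(K, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if K.shape != (n, n):
            raise ValueError("K must be n x n for n phenotypes")
        null = EmmaNull(K)
        fitted = null.fit(y)
        self.delta_ = fitted.delta
        self.sigma_g2_ = fitted.sigma_g2
        self.sigma_e2_ = fitted.sigma_e2
        self.h2_ = fitted.h2
        A = K + (self.delta_ + self.ridge) * np.eye(n)
        try:
            c = np.linalg.solve(A, np.ones(n))
            self.mu_ = float(np.ones(n) @ np.linalg.solve(A, y) / (np.ones(n) @ c))
            self.alpha_ = np.linalg.solve(A, y - self.mu_)
        except np.linalg.LinAlgError:
            A += 1e-4 * np.eye(n)
            c = np.linalg.solve(A, np.ones(n))
            self.mu_ = float(np.ones(n) @ np.linalg.solve(A, y) / (np.ones(n) @ c))
            self.alpha_ = np.linalg.solve(A, y - self.mu_)
        return self

    def predict(self, K_cross: np.ndarray) -> np.ndarray:
        K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
        return self.mu_ + K_cross @ self.alpha_


def combine_kinships(kinships: dict, weights: dict) -> np.ndarray:
    """Weighted kinship sum; weights must be non-negative and sum to 1."""
    w = np.array([weights[k] for k in kinships], dtype=float)
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    out = None
    for (name, K), wi in zip(kinships.items(), w):
        term = wi * np.asarray(K, dtype=float)
        out = term if out is None else out + term
    return out


def exclude_markers_near_loci(
    marker_index: pd.DataFrame, loci: pd.DataFrame, window_bp: int = 0
) -> np.ndarray:
    """Keep-mask for markers not at (or within window_bp of) listed loci —
    the leakage guard used before building prediction kinships."""
    keep = np.ones(len(marker_index), dtype=bool)
    if loci is None or len(loci) == 0:
        return keep
    m_chrom = marker_index["chrom"].to_numpy()
    m_pos = marker_index["pos"].to_numpy()
    for _, l in loci.iterrows():
        pos = l["pos"] if "pos" in l else l["lead_pos"]
        keep &= ~((m_chrom == l["chrom"]) & (np.abs(m_pos - pos) <= window_bp))
    return keep


def gblup_predict(
    kinships: dict,
    weights: dict,
    y: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    ridge: float = 1e-6,
) -> dict:
    """Cross-validated GBLUP accuracy for one trait.

    kinships : name -> full n x n kinship (e.g. {"snp": K1, "smp": K2});
    weights combine them (must sum to 1). Returns out-of-fold
    predictions, fold assignment, and the Pearson correlation between
    predicted and observed values.
    """
    from sklearn.model_selection import KFold

    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    K = combine_kinships(kinships, weights)
    n = len(y)
    if cv_folds < 2:
        raise ValueError("folds must be >= 2")
    preds = np.full(n, np.nan)
    folds = np.full(n, -1)
    idx_ok = np.flatnonzero(ok)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_pcc = []
    for f, (tr, te) in enumerate(kf.split(idx_ok)):
        tr_i, te_i = idx_ok[tr], idx_ok[te]
        model = GBLUP(ridge=ridge).fit(K[np.ix_(tr_i, tr_i)], y[tr_i])
        preds[te_i] = model.predict(K[np.ix_(te_i, tr_i)])
        folds[te_i] = f
        fold_pcc.append(
            float(np.corrcoef(preds[te_i], y[te_i])[0, 1])
            if np.std(preds[te_i]) > 1e-12 else 0.0
        )
    r = np.corrcoef(preds[idx_ok], y[idx_ok])[0, 1]
    # fold-averaged PCC avoids the pooled estimator's negative bias under
    # the null (fold train-means anti-correlate with test-fold means)
    return {"predictions": preds, "folds": folds, "pcc": float(r),
            "pcc_fold_mean": float(np.mean(fold_pcc))}
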