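"""Genotype QC, LD-kNN imputation, kinship and linkage-disequilibrium analysis.

The QC chain removes markers in a fixed order: monomorphic, then call rate,
then minor allele frequency (computed on non-missing calls; the MAF rule is
strict, i.e. "less than" the threshold is removed).  Missing calls are filled
by LD-kNN imputation: for a missing cell, the markers in highest LD with its
marker define a local distance between lines, and the k nearest lines vote
for the genotype with inverse-distance weights.

LD is measured as the squared Pearson correlation of dosage columns.  The
background ("critical") r² is the square of the 95th percentile of sqrt(r²)
over unlinked (inter-chromosomal) pairs, and the decay distance is where the
distance-binned mean intra-chromosomal r² first drops below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .panel import GenotypePanel, KinshipMatrix


class EmptyPanelError(ValueError):
    """All markers were removed by quality control."""


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_filter(
    panel: GenotypePanel, min_call_rate: float = 0.9, min_maf: float = 0.05
) -> tuple[GenotypePanel, dict]:
    """Remove monomorphic, low-call-rate and low-MAF markers, in that order."""
    if not 0.0 < min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in (0, 1]")
    if not 0.0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")

    D = panel.dosage
    n_obs = (~np.isnan(D)).sum(axis=0)
    # monomorphic: fewer than two distinct non-missing values (all-missing
    # markers carry no variation and fall under this rule too)
    with np.errstate(invalid="ignore"):
        col_min = np.nanmin(np.where(np.isnan(D), np.inf, D), axis=0)
        col_max = np.nanmax(np.where(np.isnan(D), -np.inf, D), axis=0)
    mono = (n_obs == 0) | (col_min == col_max)
    keep = ~mono

    call = panel.call_rate()
    low_call = keep & (call < min_call_rate)
    keep = keep & ~low_call

    maf = panel.minor_allele_frequency()
    low_maf = keep & (maf < min_maf)
    keep = keep & ~low_maf

    report = {
        "n_input": panel.n_markers,
        "n_monomorphic": int(mono.sum()),
        "n_low_call_rate": int(low_call.sum()),
        "n_low_maf": int(low_maf.sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        raise EmptyPanelError("quality control removed every marker")
    return panel.subset(marker_idx=np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# pairwise-complete LD helper
# ---------------------------------------------------------------------------

def _pairwise_r2(D: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete.

    Uses indicator algebra so sums run over the rows where both markers are
    observed; monomorphic pairs yield nan.
    """
    M = (~np.isnan(D)).astype(float)
    A = np.where(np.isnan(D), 0.0, D)
    n = M.T @ M
    sx = A.T @ M            # sum of x over common support (A zero off-support)
    sxx = (A * A).T @ M
    sxy = A.T @ A
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        r2 = cov**2 / (varx * varx.T)
        r2[(varx <= 0) | (varx.T <= 0) | (n < 2)] = np.nan
    return np.clip(r2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# LD-kNN imputation
# ---------------------------------------------------------------------------

def ld_knni_impute(
    panel: GenotypePanel, k_neighbors: int = 5, l_markers: int = 30
) -> GenotypePanel:
    """Impute missing dosages by LD-informed k-nearest-neighbour vote.

    For each missing cell (line i, marker m), the ``l_markers`` markers in
    highest r² with m that are observed in line i define an r²-weighted
    Euclidean distance from line i to every line observed at m; the
    ``k_neighbors`` nearest lines vote for {0, 1, 2} with weight
    1/max(distance, 1e-6), ties in distance broken by line index.
    """
    D = panel.dosage
    if panel.n_lines < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 lines")
    miss_li, miss_mi = np.nonzero(np.isnan(D))
    if miss_li.size == 0:
        return panel.copy()
    all_missing = np.flatnonzero(np.isnan(D).all(axis=0))
    if all_missing.size:
        raise ValueError(f"marker {panel.marker_ids[all_missing[0]]} is entirely missing")

    r2 = _pairwise_r2(D)
    np.fill_diagonal(r2, -1.0)
    out = D.copy()
    obs = ~np.isnan(D)
    for m in np.unique(miss_mi):
        lines_missing = miss_li[miss_mi == m]
        donors_all = np.flatnonzero(obs[:, m])
        scores = np.where(np.isnan(r2[:, m]), -1.0, r2[:, m])
        order = np.argsort(-scores, kind="stable")
        for i in lines_missing:
            cand = order[obs[i, order]][:l_markers]
            if cand.size == 0:
                # no informative markers in this line: frequency-rounded fill
                out[i, m] = np.round(np.nanmean(D[:, m]) / 2.0) * 2.0 if set(
                    np.unique(D[obs[:, m], m])
                ) <= {0.0, 2.0} else np.round(np.nanmean(D[:, m]))
                continue
            xi = D[i, cand]
            Xd = D[np.ix_(donors_all, cand)]
            wts = np.clip(scores[cand], 0.0, None)
            diff = Xd - xi[None, :]
            ok = ~np.isnan(diff)
            wsum = (ok * wts[None, :]).sum(axis=1)
            sq = np.where(ok, diff, 0.0) ** 2 * wts[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.sqrt(sq.sum(axis=1) / wsum)
            dist[wsum <= 0] = np.inf
            usable = np.isfinite(dist)
            donors = donors_all[usable]
            dist = dist[usable]
            if donors.size == 0:
                out[i, m] = np.round(np.nanmean(D[:, m]))
                continue
            kk = min(k_neighbors, donors.size)
            pick = np.lexsort((donors, dist))[:kk]
            w = 1.0 / np.maximum(dist[pick], 1e-6)
            votes = np.zeros(3)
            for dn, wt in zip(donors[pick], w):
                votes[int(D[dn, m])] += wt
            out[i, m] = float(np.argmax(votes))
    result = panel.copy()
    result.dosage = out
    result.validate()
    return result


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def ibs_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """Identity-by-state kinship: K_ij = mean_m (1 − |d_im − d_jm| / 2)."""
    D = panel.dosage
    if np.isnan(D).any():
        raise ValueError("IBS kinship requires a complete panel; impute first")
    if panel.n_markers == 0:
        raise ValueError("no markers")
    dist = cdist(D, D, metric="cityblock") / (2.0 * panel.n_markers)
    K = 1.0 - dist
    K = (K + K.T) / 2.0
    return KinshipMatrix(line_ids=list(panel.line_ids), values=K, method="IBS")


def vanraden_grm(panel: GenotypePanel) -> KinshipMatrix:
    """VanRaden genomic relationship: G = WWᵀ / (2 Σ p_j(1−p_j)), W = D − 2p."""
    D = panel.dosage
    if np.isnan(D).any():
        raise ValueError("VanRaden GRM requires a complete panel; impute first")
    p = D.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    W = D - 2.0 * p[None, :]
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return KinshipMatrix(line_ids=list(panel.line_ids), values=G, method="VanRaden")


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDSummary:
    critical_r2: float
    decay_distance_bp: dict  # chromosome -> distance (nan if never crossed)
    decay_distance_genomewide_bp: float
    percentile: float = 95.0


def pairwise_ld(
    panel: GenotypePanel,
    max_distance_bp: int | None = None,
    include_interchromosomal: bool = False,
    inter_cap: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate pairwise r² between markers.

    Intra-chromosomal pairs are limited to ``max_distance_bp`` (all pairs if
    None); inter-chromosomal pairs, used to estimate background LD, are
    subsampled to at most ``inter_cap`` with the given seed.  Monomorphic
    columns are skipped; their pair count is recorded in ``df.attrs``.
    """
    D = panel.dosage
    r2 = _pairwise_r2(D)
    chrom = panel.chromosome
    pos = panel.position_bp
    ids = np.asarray(panel.marker_ids, dtype=object)

    rows = []
    n_skipped = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        ii, jj = np.triu_indices(idx.size, k=1)
        gi, gj = idx[ii], idx[jj]
        dist = np.abs(pos[gj] - pos[gi])
        if max_distance_bp is not None:
            keep = dist <= max_distance_bp
            gi, gj, dist = gi[keep], gj[keep], dist[keep]
        vals = r2[gi, gj]
        good = ~np.isnan(vals)
        n_skipped += int((~good).sum())
        rows.append(
            pd.DataFrame(
                {
                    "marker_i": ids[gi[good]],
                    "marker_j": ids[gj[good]],
                    "chromosome_i": c,
                    "chromosome_j": c,
                    "distance_bp": dist[good].astype(float),
                    "r2": vals[good],
                }
            )
        )

    if include_interchromosomal:
        rng = np.random.default_rng(seed)
        gi, gj = np.triu_indices(panel.n_markers, k=1)
        inter = chrom[gi] != chrom[gj]
        gi, gj = gi[inter], gj[inter]
        if gi.size > inter_cap:
            pick = rng.choice(gi.size, size=inter_cap, replace=False)
            gi, gj = gi[pick], gj[pick]
        vals = r2[gi, gj]
        good = ~np.isnan(vals)
        n_skipped += int((~good).sum())
        rows.append(
            pd.DataFrame(
                {
                    "marker_i": ids[gi[good]],
                    "marker_j": ids[gj[good]],
                    "chromosome_i": chrom[gi[good]],
                    "chromosome_j": chrom[gj[good]],
                    "distance_bp": np.nan,
                    "r2": vals[good],
                }
            )
        )

    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["marker_i", "marker_j", "chromosome_i", "chromosome_j", "distance_bp", "r2"]
    )
    table.attrs["n_skipped_monomorphic_pairs"] = n_skipped
    return table


def ld_summary(
    ld_table: pd.DataFrame, percentile: float = 95.0, bin_width_bp: int = 500
) -> LDSummary:
    """Critical r² from unlinked pairs and LD decay distance from binned means.

    critical_r2 is the square of the ``percentile``-th percentile of sqrt(r²)
    over inter-chromosomal pairs.  The decay distance (per chromosome and
    pooled) is the midpoint of the first distance bin whose mean r² falls
    below critical_r2; nan marks a curve that never crosses.
    """
    unlinked = ld_table[ld_table["distance_bp"].isna()]
    if unlinked.empty:
        raise ValueError("no unlinked (inter-chromosomal) pairs in LD table")
    crit = float(np.percentile(np.sqrt(unlinked["r2"].to_numpy()), percentile) ** 2)

    linked = ld_table[ld_table["distance_bp"].notna()].copy()

    def _decay(sub: pd.DataFrame) -> float:
        if sub.empty:
            return float("nan")
        bins = (sub["distance_bp"] // bin_width_bp).astype(int)
        means = sub.groupby(bins)["r2"].mean().sort_index()
        below = means[means < crit]
        if below.empty:
            return float("nan")
        b = int(below.index[0])
        return (b + 0.5) * bin_width_bp

    per_chrom = {
        str(c): _decay(g) for c, g in linked.groupby("chromosome_i", sort=True)
    }
    return LDSummary(
        critical_r2=crit,
        decay_distance_bp=per_chrom,
        decay_distance_genomewide_bp=_decay(linked),
        percentile=percentile,
    )
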