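"""LD pruning and principal component analysis of population structure.

Pruning is the usual greedy left-to-right window scan: within a sliding
SNP window, whenever a pair's genotype r² reaches the threshold the later
SNP is dropped.  An exhaustive cleanup pass over the survivors (on by
default) then guarantees the postcondition globally — every surviving
pairwise r² is below the threshold, not only within-window ones.

PCA follows the smartpca normalization: each SNP column is centred by
``2 p̂`` and scaled by ``sqrt(2 p̂ (1 - p̂))``; missing dosages are
mean-imputed (zero after centring); monomorphic SNPs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import MISSING, GenotypePanel, PanelError


def genotype_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns.

    Missing entries (sentinel) are handled pairwise-complete.
    """
    d = dosages.astype(np.float64)
    d[dosages == MISSING] = np.nan
    mask = ~np.isnan(d)
    x = np.where(mask, d, 0.0)
    m = mask.astype(np.float64)
    n = m.T @ m
    sx = x.T @ m
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_x = sxx / n - (sx / n) ** 2
        r2 = cov**2 / (var_x * var_x.T)
    r2 = np.where(n >= 2, r2, np.nan)
    return r2


def ld_prune(
    panel: GenotypePanel,
    r2_threshold: float = 0.2,
    window_snps: int = 50,
    step: int = 5,
    exhaustive: bool = True,
) -> tuple[GenotypePanel, np.ndarray]:
    """Greedy LD pruning at a genotype-r² threshold.

    Returns the pruned panel and the indices (into the input panel) of the
    surviving SNPs.  With ``exhaustive=True`` a final global pass removes
    any surviving pair still at or above the threshold, so the advertised
    postcondition holds for *all* pairs.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise PanelError(f"r2_threshold {r2_threshold} outside (0, 1]")
    keep = np.ones(panel.n_snps, dtype=bool)
    chrom = panel.markers["chromosome"].to_numpy()

    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            window = idx[start : start + window_snps]
            live = window[keep[window]]
            if len(live) > 1:
                r2 = genotype_r2_matrix(panel.dosages[:, live])
                for a in range(len(live)):
                    if not keep[live[a]]:
                        continue
                    for b in range(a + 1, len(live)):
                        if keep[live[b]] and r2[a, b] >= r2_threshold:
                            keep[live[b]] = False
            if start + window_snps >= len(idx):
                break
            start += step

    if exhaustive:
        live = np.flatnonzero(keep)
        if len(live) > 1:
            r2 = genotype_r2_matrix(panel.dosages[:, live])
            for a in range(len(live)):
                if not keep[live[a]]:
                    continue
                bad = np.flatnonzero(
                    (r2[a] >= r2_threshold) & keep[live] & (np.arange(len(live)) > a)
                )
                keep[live[bad]] = False

    survivors = np.flatnonzero(keep)
    return panel.take_snps(survivors), survivors


@dataclass
class PcaResult:
    """Top-K PCA of the sample x SNP matrix after smartpca normalization."""

    scores: np.ndarray  # (n_samples, K)
    eigenvalues: np.ndarray  # (K,), non-increasing
    explained: np.ndarray  # fraction of total variance per component
    samples: list[str]
    n_snps_used: int


def pca(panel: GenotypePanel, k: int = 10) -> PcaResult:
    """Smartpca-style PCA: frequency-normalized columns, SVD, top-K scores."""
    if k >= panel.n_samples:
        raise PanelError(f"K={k} must be < n_samples={panel.n_samples}")
    d = panel.dosages.astype(np.float64)
    d[panel.dosages == MISSING] = np.nan
    p_hat = np.nanmean(d, axis=0) / 2.0
    var = 2.0 * p_hat * (1.0 - p_hat)
    poly = np.nan_to_num(var) > 0.0
    if not poly.any():
        raise PanelError("no polymorphic SNPs for PCA")
    x = (d[:, poly] - 2.0 * p_hat[poly]) / np.sqrt(var[poly])
    x = np.nan_to_num(x)  # mean-impute missing after centring

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / x.shape[1]
    total = eigvals.sum()
    scores = u[:, :k] * s[:k]
    return PcaResult(
        scores=scores,
        eigenvalues=eigvals[:k],
        explained=eigvals[:k] / total if total > 0 else np.zeros(k),
        samples=list(panel.samples),
        n_snps_used=int(poly.sum()),
    )
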