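"""Pairwise genotype LD, distance binning, and the Sved hyperbolic decay fit.

r² is the squared Pearson correlation of allele-dosage vectors, computed
for all autosomal SNP pairs within a maximum distance (default 1,000 kb)
after per-analysis MAF (>= 0.10) and missingness (< 0.10) filters.  The
decay of r² with physical distance d is summarized two ways: means over
the study's 19 fixed distance classes, and a one-parameter least-squares
fit of the hyperbola

    E[r²] = 1 / (1 + beta * d)

whose LD extent at threshold t is the distance where the fitted curve
crosses t: ``d_t = (1/t - 1) / beta`` (reported for t = 0.3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .panel import MISSING, GenotypePanel, PanelError, minor_allele_frequencies

#: Distance-class edges in kb, half-open [lo, hi).
BIN_EDGES_KB: tuple[float, ...] = (
    0, 4, 8, 12, 20, 30, 40, 60, 80, 100, 120,
    160, 200, 250, 300, 360, 460, 620, 800, 1000,
)


@dataclass
class SvedFit:
    """Fitted hyperbolic decay coefficient and derived LD extent."""

    beta_per_kb: float
    rss: float
    n_pairs: int
    threshold: float = 0.3

    @property
    def beta_per_bp(self) -> float:
        return self.beta_per_kb / 1000.0

    @property
    def extent_kb(self) -> float:
        """Distance (kb) where the fitted curve crosses the threshold."""
        if self.beta_per_kb <= 0.0:
            return float("inf")
        return (1.0 / self.threshold - 1.0) / self.beta_per_kb

    def predict(self, distance_kb: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 + self.beta_per_kb * np.asarray(distance_kb, dtype=float))


def pairwise_r2(
    panel: GenotypePanel,
    sample_index: np.ndarray | None = None,
    max_distance_bp: int = 1_000_000,
    min_maf: float = 0.10,
    max_missing: float = 0.10,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """All same-chromosome SNP-pair r² within ``max_distance_bp``.

    SNPs failing the MAF / missingness filters (computed within the sample
    subset) are removed first.  Returns columns ``snp_a, snp_b,
    distance_bp, r2``; pairs with a zero-variance dosage vector over the
    pairwise-complete samples are skipped.
    """
    sub = panel if not autosomes_only else panel.autosomal()
    if sample_index is not None:
        sub = sub.take_samples(np.asarray(sample_index))
    if sub.n_samples < 2:
        raise PanelError("need >= 2 samples for LD")

    maf = minor_allele_frequencies(sub)
    miss = (sub.dosages == MISSING).mean(axis=0)
    keep = np.where(np.isnan(maf), False, maf >= min_maf) & (miss < max_missing)
    sub = sub.take_snps(keep)

    d = sub.dosages.astype(np.float64)
    d[sub.dosages == MISSING] = np.nan
    pos = sub.markers["position_bp"].to_numpy()
    chrom = sub.markers["chromosome"].to_numpy()
    snp_ids = sub.markers["snp_id"].to_numpy()
    m = sub.n_snps

    mask = ~np.isnan(d)
    x = np.where(mask, d, 0.0)
    mk = mask.astype(np.float64)

    out_a, out_b, out_d, out_r2 = [], [], [], []
    for k in range(1, m):
        same = chrom[k:] == chrom[:-k]
        dist = pos[k:] - pos[:-k]
        ok = same & (dist > 0) & (dist <= max_distance_bp)
        if not ok.any():
            if not (same & (dist <= max_distance_bp)).any():
                # every within-chromosome gap at this offset already exceeds
                # the cap; larger offsets can only be farther apart
                break
            continue
        idx = np.flatnonzero(ok)
        a, b = idx, idx + k
        n = (mk[:, a] * mk[:, b]).sum(axis=0)
        sx = (x[:, a] * mk[:, b]).sum(axis=0)
        sy = (x[:, b] * mk[:, a]).sum(axis=0)
        sxx = (x[:, a] ** 2 * mk[:, b]).sum(axis=0)
        syy = (x[:, b] ** 2 * mk[:, a]).sum(axis=0)
        sxy = (x[:, a] * x[:, b]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = sxy / n - (sx / n) * (sy / n)
            vx = sxx / n - (sx / n) ** 2
            vy = syy / n - (sy / n) ** 2
            r2 = cov**2 / (vx * vy)
        good = (n >= 2) & (vx > 0) & (vy > 0)
        out_a.append(snp_ids[a[good]])
        out_b.append(snp_ids[b[good]])
        out_d.append((pos[b] - pos[a])[good])
        out_r2.append(np.clip(r2[good], 0.0, 1.0))

    if not out_a:
        return pd.DataFrame(columns=["snp_a", "snp_b", "distance_bp", "r2"])
    return pd.DataFrame(
        {
            "snp_a": np.concatenate(out_a),
            "snp_b": np.concatenate(out_b),
            "distance_bp": np.concatenate(out_d),
            "r2": np.concatenate(out_r2),
        }
    )


def bin_ld(records: pd.DataFrame) -> pd.DataFrame:
    """Mean r² and pair count per fixed distance class ([lo, hi) in kb)."""
    edges = np.asarray(BIN_EDGES_KB, dtype=float)
    dist_kb = records["distance_bp"].to_numpy() / 1000.0
    which = np.digitize(dist_kb, edges, right=False) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append(
            {
                "bin": f"{edges[b]:g}-{edges[b + 1]:g}",
                "lo_kb": edges[b],
                "hi_kb": edges[b + 1],
                "n_pairs": int(sel.sum()),
                "mean_r2": float(records.loc[sel, "r2"].mean()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fit_sved(
    records: pd.DataFrame,
    threshold: float = 0.3,
    use_binned: bool = False,
) -> SvedFit:
    """Least-squares fit of ``r² = 1/(1 + beta d)`` with beta >= 0.

    By default the fit uses the raw pairs; ``use_binned=True`` fits the
    19-class mean curve instead (each class weighted equally).
    """
    if use_binned:
        binned = bin_ld(records)
        binned = binned.dropna(subset=["mean_r2"])
        d_kb = ((binned["lo_kb"] + binned["hi_kb"]) / 2.0).to_numpy()
        y = binned["mean_r2"].to_numpy()
    else:
        d_kb = records["distance_bp"].to_numpy() / 1000.0
        y = records["r2"].to_numpy()
    if np.unique(d_kb).size < 2:
        raise PanelError("need >= 2 distinct distances to fit the decay curve")

    def rss(log_beta: float) -> float:
        beta = np.exp(log_beta)
        return float(np.sum((y - 1.0 / (1.0 + beta * d_kb)) ** 2))

    res = minimize_scalar(rss, bounds=(np.log(1e-8), np.log(1e4)), method="bounded")
    beta = float(np.exp(res.x))
    rss_zero = float(np.sum((y - 1.0) ** 2))  # beta -> 0 limit
    if rss_zero <= res.fun:
        beta = 0.0
    return SvedFit(
        beta_per_kb=beta,
        rss=min(float(res.fun), rss_zero),
        n_pairs=len(y),
        threshold=threshold,
    )


def population_ld_fit(
    panel: GenotypePanel,
    population: str,
    threshold: float = 0.3,
    **r2_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, SvedFit]:
    """Intrapopulation pipeline: records, binned curve, Sved fit."""
    rows = panel.sample_indices(population)
    records = pairwise_r2(panel, rows, **r2_kwargs)
    return records, bin_ld(records), fit_sved(records, threshold=threshold)


def interpopulation_ld(
    panel: GenotypePanel,
    populations: list[str],
    n_per_pop: int,
    seed: int = 0,
    threshold: float = 0.3,
    **r2_kwargs,
) -> tuple[pd.DataFrame, SvedFit]:
    """Pooled LD across populations from a seeded subsample per population.

    Populations smaller than ``n_per_pop`` contribute all their samples.
    Returns the pooled records and the Sved fit.
    """
    rng = np.random.default_rng(seed)
    labels = panel.population_labels
    chosen: list[np.ndarray] = []
    for pop in populations:
        idx = np.flatnonzero(labels == pop)
        if idx.size == 0:
            raise PanelError(f"population {pop!r} absent from panel")
        if idx.size <= n_per_pop:
            chosen.append(idx)
        else:
            chosen.append(rng.choice(idx, size=n_per_pop, replace=False))
    rows = np.sort(np.concatenate(chosen))
    records = pairwise_r2(panel, rows, **r2_kwargs)
    return records, fit_sved(records, threshold=threshold)
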