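"""Within-population diversity: P_N, expected heterozygosity, allelic richness.

* ``P_N`` — proportion of a SNP subset segregating (both alleles observed
  among called genotypes) in a population.
* ``H_E`` — mean plug-in expected heterozygosity ``2 p (1 - p)``.
* ``A_R`` — allelic richness by rarefaction: the expected number of
  distinct alleles in a hypergeometric draw of ``g`` gene copies, averaged
  over SNPs; standardizes allele counts across populations of unequal size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, GenotypePanel, PanelError, allele_frequencies


@dataclass(frozen=True)
class DiversitySummary:
    population: str
    n_snps: int
    p_n: float
    h_e: float
    a_r: float
    rarefaction_g: int


def _population_counts(
    panel: GenotypePanel, population: str, snp_subset: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """(allele2 copies, total called copies) per SNP of the subset."""
    rows = panel.sample_indices(population)
    d = panel.dosages[rows]
    if snp_subset is not None:
        d = d[:, np.asarray(snp_subset)]
    called = d != MISSING
    n_copies = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0, dtype=np.int64)
    return alt, n_copies


def proportion_polymorphic(
    panel: GenotypePanel, population: str, snp_subset: np.ndarray | None = None
) -> float:
    """Fraction of subset SNPs with both alleles observed in the population."""
    alt, n = _population_counts(panel, population, snp_subset)
    if alt.size == 0:
        raise PanelError("empty SNP subset")
    segregating = (alt > 0) & (alt < n)
    return float(segregating.sum() / alt.size)


def expected_heterozygosity(
    panel: GenotypePanel, population: str, snp_subset: np.ndarray | None = None
) -> float:
    """Mean 2p(1-p) over the subset; all-missing SNPs excluded with a warning."""
    rows = panel.sample_indices(population)
    freq, n_called = allele_frequencies(panel, rows)
    if snp_subset is not None:
        idx = np.asarray(snp_subset)
        freq, n_called = freq[idx], n_called[idx]
    if freq.size == 0:
        raise PanelError("empty SNP subset")
    ok = n_called > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} all-missing SNPs excluded from H_E", stacklevel=2
        )
    if not ok.any():
        raise PanelError("no SNP with a called genotype")
    p = freq[ok]
    return float(np.mean(2.0 * p * (1.0 - p)))


def rarefied_allele_count(
    allele_counts: np.ndarray, g: int
) -> np.ndarray:
    """Expected distinct alleles among ``g`` copies drawn without replacement.

    ``allele_counts`` is (n_snps, n_alleles); per SNP the value is
    ``sum_a [1 - C(N - N_a, g) / C(N, g)]`` with ``N = sum_a N_a``.
    Binomial coefficients are evaluated in log space.
    """
    counts = np.asarray(allele_counts, dtype=np.int64)
    n_total = counts.sum(axis=1)
    if np.any(g > n_total):
        bad = int(np.argmax(g > n_total))
        raise PanelError(
            f"rarefaction size g={g} exceeds {n_total[bad]} called copies at SNP {bad}"
        )

    def log_choose(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)

    rest = n_total[:, None] - counts  # copies of the other alleles
    with np.errstate(invalid="ignore"):
        log_absent = log_choose(rest, g) - log_choose(n_total, g)[:, None]
    prob_absent = np.where(rest >= g, np.exp(log_absent), 0.0)
    return (1.0 - prob_absent).sum(axis=1)


def allelic_richness(
    panel: GenotypePanel,
    population: str,
    snp_subset: np.ndarray | None = None,
    g: int | None = None,
) -> tuple[float, int]:
    """Mean rarefied allele count over the subset, and the g used.

    ``g`` defaults to the smallest per-SNP number of called gene copies in
    the population over the subset (the largest depth valid at every SNP).
    """
    alt, n = _population_counts(panel, population, snp_subset)
    if alt.size == 0:
        raise PanelError("empty SNP subset")
    if np.any(n == 0):
        raise PanelError("SNP with zero called copies in rarefaction subset")
    if g is None:
        g = int(n.min())
    counts = np.stack([n - alt, alt], axis=1)
    return float(rarefied_allele_count(counts, g).mean()), g


def diversity_table(
    panel: GenotypePanel,
    snp_subset: np.ndarray | None = None,
    g: int | None = None,
) -> pd.DataFrame:
    """Per-population P_N / H_E / A_R summary (one row per population).

    When ``g`` is None a common rarefaction depth is used: twice the
    smallest per-population called sample size over the subset, so A_R is
    comparable across populations.
    """
    if g is None:
        depths = []
        for pop in panel.population_names():
            _, n = _population_counts(panel, pop, snp_subset)
            depths.append(int(n.min()) if n.size else 0)
        g = max(2, min(depths))
    rows = []
    for pop in panel.population_names():
        a_r, g_used = allelic_richness(panel, pop, snp_subset, g)
        rows.append(
            DiversitySummary(
                population=pop,
                n_snps=panel.n_snps if snp_subset is None else len(np.asarray(snp_subset)),
                p_n=proportion_polymorphic(panel, pop, snp_subset),
                h_e=expected_heterozygosity(panel, pop, snp_subset),
                a_r=a_r,
                rarefaction_g=g_used,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
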