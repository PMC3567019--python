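"""Core data model for diploid biallelic SNP panels.

A :class:`GenotypePanel` holds a sample x SNP matrix of alt-allele dosages
(0/1/2, with ``MISSING = -1`` as the missing sentinel), a marker map
(chromosome, 1-based bp position, allele pair) and a population label per
sample.  All downstream statistics (diversity, distance, F_ST, LD, ROH,
selection scans) operate on this container.

Dosage orientation: the dosage counts copies of the *second* allele of the
marker's allele pair, one consistent orientation for every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Missing-genotype sentinel in dosage matrices (PLINK text "0 0").
MISSING: int = -1

MAP_COLUMNS = ("snp_id", "chromosome", "position_bp", "allele1", "allele2")

#: Chromosome labels excluded by autosome-only analyses (LD, F_ST, ROH).
SEX_CHROMOSOMES = frozenset({"X", "Y", "XY", "MT", "23", "24", "25", "26"})


class PanelError(ValueError):
    """Raised on malformed panels or invalid panel operations."""


@dataclass(frozen=True)
class FilterConfig:
    """SNP QC thresholds: call rate >= ``min_call_rate`` and MAF >= ``min_maf``."""

    min_call_rate: float = 0.90
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise PanelError(f"min_call_rate {self.min_call_rate} outside [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise PanelError(f"min_maf {self.min_maf} outside [0, 0.5]")


def _validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in MAP_COLUMNS if c not in markers.columns]
    if missing_cols:
        raise PanelError(f"marker map lacks columns {missing_cols}")
    if markers["snp_id"].duplicated().any():
        dup = markers.loc[markers["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise PanelError(f"duplicate snp_id {dup!r}")
    if (markers["position_bp"] < 1).any():
        raise PanelError("positions must be 1-based (>= 1)")
    for _, grp in markers.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise PanelError("positions not strictly increasing within a chromosome")
    return markers.reset_index(drop=True)


@dataclass
class GenotypePanel:
    """Sample x SNP dosage matrix with marker map and population labels.

    Parameters
    ----------
    markers : pandas.DataFrame
        One row per SNP with columns ``snp_id, chromosome, position_bp,
        allele1, allele2``; positions strictly increasing within chromosome.
    samples : list of str
        Sample identifiers, unique.
    populations : dict
        sample id -> population label; must cover every sample.
    dosages : ndarray of int8, shape (n_samples, n_snps)
        Count of allele2 copies, ``MISSING`` (-1) where uncalled.
    """

    markers: pd.DataFrame
    samples: list[str]
    populations: dict[str, str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.markers = _validate_markers(self.markers)
        if len(set(self.samples)) != len(self.samples):
            raise PanelError("duplicate sample id")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise PanelError(
                f"dosage matrix shape {self.dosages.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        unlabeled = [s for s in self.samples if s not in self.populations]
        if unlabeled:
            raise PanelError(f"samples without population label: {unlabeled[:5]}")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise PanelError("dosages must be in {0, 1, 2} or the missing sentinel")

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    @property
    def population_labels(self) -> np.ndarray:
        """Per-sample population label, aligned with the dosage rows."""
        return np.array([self.populations[s] for s in self.samples])

    def population_names(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def sample_indices(self, population: str | None = None) -> np.ndarray:
        """Row indices of all samples, or of one population's samples."""
        if population is None:
            return np.arange(self.n_samples)
        labels = self.population_labels
        idx = np.flatnonzero(labels == population)
        if idx.size == 0:
            raise PanelError(f"population {population!r} absent from panel")
        return idx

    def called_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_snps) mask of called genotypes."""
        return self.dosages != MISSING

    # -- subsetting -------------------------------------------------------

    def take_snps(self, index: np.ndarray | Sequence[int]) -> "GenotypePanel":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            markers=self.markers.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            populations=dict(self.populations),
            dosages=self.dosages[:, idx].copy(),
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypePanel":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        samples = [self.samples[i] for i in idx]
        return GenotypePanel(
            markers=self.markers.copy(),
            samples=samples,
            populations={s: self.populations[s] for s in samples},
            dosages=self.dosages[idx].copy(),
        )

    def autosomal(self) -> "GenotypePanel":
        """Drop SNPs on sex/mito chromosomes (labels in SEX_CHROMOSOMES)."""
        keep = ~self.markers["chromosome"].astype(str).str.upper().isin(SEX_CHROMOSOMES)
        return self.take_snps(keep.to_numpy())


# ---------------------------------------------------------------------------
# allele frequencies and QC filters
# ---------------------------------------------------------------------------


def allele_frequencies(
    panel: GenotypePanel, sample_index: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Allele2 frequency and called-individual count for every SNP.

    Frequency is (dosage sum) / (2 x called individuals) over the given
    sample rows (default: all).  SNPs with zero called genotypes get NaN.
    """
    d = panel.dosages if sample_index is None else panel.dosages[sample_index]
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return freq, n_called


def allele_frequency(
    panel: GenotypePanel, snp: int | str, sample_index: np.ndarray | None = None
) -> tuple[float, int]:
    """Allele2 frequency at one SNP (by index or snp_id) plus n_called.

    Raises
    ------
    PanelError
        If every genotype in the subset is missing (distinct from freq 0).
    """
    if isinstance(snp, str):
        hits = np.flatnonzero(panel.markers["snp_id"].to_numpy() == snp)
        if hits.size == 0:
            raise PanelError(f"unknown SNP {snp!r}")
        j = int(hits[0])
    else:
        j = int(snp)
    col = panel.dosages[:, j] if sample_index is None else panel.dosages[sample_index, j]
    called = col != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise PanelError(f"all genotypes missing at SNP index {j}")
    return float(col[called].sum() / (2.0 * n_called)), n_called


def minor_allele_frequencies(
    panel: GenotypePanel, sample_index: np.ndarray | None = None
) -> np.ndarray:
    """Per-SNP MAF = min(p, 1-p) over called genotypes (NaN if none called)."""
    freq, _ = allele_frequencies(panel, sample_index)
    return np.minimum(freq, 1.0 - freq)


def filter_snps(
    panel: GenotypePanel, config: FilterConfig = FilterConfig()
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Apply the chip-QC filters: call rate and MAF thresholds (inclusive >=).

    Returns the filtered panel and a per-SNP report with columns
    ``snp_id, call_rate, maf, kept, reason`` (reason empty when kept; the
    call-rate rule is reported first when both fail).
    """
    called = panel.called_mask()
    call_rate = called.mean(axis=0) if panel.n_samples else np.zeros(panel.n_snps)
    maf = minor_allele_frequencies(panel)
    cr_ok = call_rate >= config.min_call_rate
    maf_ok = np.where(np.isnan(maf), False, maf >= config.min_maf)
    keep = cr_ok & maf_ok
    reason = np.where(keep, "", np.where(~cr_ok, "call_rate", "maf"))
    report = pd.DataFrame(
        {
            "snp_id": panel.markers["snp_id"],
            "call_rate": call_rate,
            "maf": maf,
            "kept": keep,
            "reason": reason,
        }
    )
    return panel.take_snps(keep), report


def maf_subset(
    panel: GenotypePanel,
    groups: Mapping[str, Iterable[str]],
    min_maf: float = 0.2,
) -> GenotypePanel:
    """Retain SNPs with MAF >= ``min_maf`` within *every* super-group.

    ``groups`` maps a super-group name to the population labels it pools
    (e.g. a native and a commercial group); a SNP must clear the threshold
    in each group separately to survive.
    """
    known = set(panel.population_names())
    labels = panel.population_labels
    keep = np.ones(panel.n_snps, dtype=bool)
    for name, pops in groups.items():
        pops = list(pops)
        unknown = sorted(set(pops) - known)
        if unknown:
            raise PanelError(f"group {name!r} has unknown populations {unknown}")
        idx = np.flatnonzero(np.isin(labels, pops))
        maf = minor_allele_frequencies(panel, idx)
        keep &= np.where(np.isnan(maf), False, maf >= min_maf)
    return panel.take_snps(keep)
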