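"""Sliding-window runs-of-homozygosity detection and autozygosity summaries.

The caller follows the classic SNP-array scanning-window scheme.  Windows
are runs of ``window_min_snps`` consecutive SNPs (per chromosome), valid
only when their physical span does not exceed ``window_span_bp`` — a
density guard reconciling the dual span/count constraint.  A window is
*homozygous* when it contains at most ``max_het_per_window`` heterozygous
and at most ``max_missing_per_window`` missing calls, tolerating the
occasional genotyping error or missing call inside an otherwise unbroken
homozygous tract.  Each SNP's hit rate is the fraction of valid covering
windows that are homozygous; SNPs at or above ``window_hit_threshold``
are ROH-eligible, and maximal runs of eligible SNPs spanning at least
``min_roh_length_bp`` are emitted as segments (1-based inclusive
coordinates at the outermost eligible SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError


@dataclass(frozen=True)
class RohConfig:
    window_span_bp: int = 5_000_000
    window_min_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_roh_length_bp: int = 500_000
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if min(
            self.window_span_bp,
            self.window_min_snps,
            self.min_roh_length_bp,
        ) <= 0:
            raise PanelError("ROH config values must be positive")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise PanelError("window_hit_threshold outside (0, 1]")
        if self.min_roh_length_bp > self.window_span_bp:
            raise PanelError("min ROH length exceeds the window span")


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def _eligible_snps(
    dosage: np.ndarray, pos: np.ndarray, config: RohConfig
) -> np.ndarray:
    """Boolean ROH-eligibility per SNP of one chromosome for one sample."""
    m = len(pos)
    w = config.window_min_snps
    eligible = np.zeros(m, dtype=bool)
    if m < w:
        return eligible
    het = (dosage == 1).astype(np.int64)
    mis = (dosage == MISSING).astype(np.int64)
    span = pos[w - 1 :] - pos[: m - w + 1]
    valid = span <= config.window_span_bp
    hom = (
        valid
        & (_sliding_sum(het, w) <= config.max_het_per_window)
        & (_sliding_sum(mis, w) <= config.max_missing_per_window)
    )
    # SNP i is covered by window starts s in [i-w+1, i]
    cover_valid = _cover_count(valid.astype(np.int64), w, m)
    cover_hom = _cover_count(hom.astype(np.int64), w, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(cover_valid > 0, cover_hom / cover_valid, 0.0)
    return rate >= config.window_hit_threshold


def _cover_count(starts_flag: np.ndarray, w: int, m: int) -> np.ndarray:
    """For each SNP, how many flagged window starts cover it."""
    c = np.concatenate([[0], np.cumsum(starts_flag)])
    i = np.arange(m)
    lo = np.maximum(i - w + 1, 0)
    hi = np.minimum(i, len(starts_flag) - 1)
    out = np.where(hi >= lo, c[hi + 1] - c[lo], 0)
    return out


def detect_roh(
    panel: GenotypePanel, sample: int | str, config: RohConfig = RohConfig()
) -> list[RohSegment]:
    """Call ROH segments for one sample across all autosomes."""
    if isinstance(sample, str):
        try:
            row = panel.samples.index(sample)
        except ValueError:
            raise PanelError(f"unknown sample {sample!r}")
    else:
        row = int(sample)
    sid = panel.samples[row]
    auto = panel.autosomal()
    dosage_row = auto.dosages[row]
    chrom = auto.markers["chromosome"].to_numpy()
    pos = auto.markers["position_bp"].to_numpy()

    segments: list[RohSegment] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        if np.any(np.diff(p) <= 0):
            raise PanelError(f"marker map unsorted on chromosome {c}")
        d = dosage_row[idx]
        elig = _eligible_snps(d, p, config)
        # maximal runs of eligible SNPs
        padded = np.concatenate([[False], elig, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
        for s, e in zip(starts, ends):
            start_bp, end_bp = int(p[s]), int(p[e])
            if end_bp - start_bp + 1 < config.min_roh_length_bp:
                continue
            run = d[s : e + 1]
            segments.append(
                RohSegment(
                    sample=sid,
                    chromosome=str(c),
                    start_bp=start_bp,
                    end_bp=end_bp,
                    n_snps=int(len(run)),
                    n_het=int((run == 1).sum()),
                    n_missing=int((run == MISSING).sum()),
                )
            )
    return segments


def detect_roh_all(
    panel: GenotypePanel, config: RohConfig = RohConfig()
) -> pd.DataFrame:
    """ROH segments for every sample, as a table."""
    rows = []
    for i in range(panel.n_samples):
        for seg in detect_roh(panel, i, config):
            rows.append(
                {
                    "sample": seg.sample,
                    "population": panel.populations[seg.sample],
                    "chromosome": seg.chromosome,
                    "start_bp": seg.start_bp,
                    "end_bp": seg.end_bp,
                    "n_snps": seg.n_snps,
                    "n_het": seg.n_het,
                    "n_missing": seg.n_missing,
                    "length_bp": seg.length_bp,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "population", "chromosome", "start_bp", "end_bp",
            "n_snps", "n_het", "n_missing", "length_bp",
        ],
    )


def roh_summary(
    segments: pd.DataFrame,
    panel: GenotypePanel,
    genome_span_bp: int | None = None,
    length_classes_mb: tuple[float, ...] = (0.5, 1, 2, 4, 8, 16, np.inf),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample autozygosity fraction and an ROH length histogram.

    ``genome_span_bp`` defaults to the summed span of the analyzed
    autosomes (first to last SNP per chromosome).
    """
    if genome_span_bp is None:
        auto = panel.autosomal()
        genome_span_bp = int(
            auto.markers.groupby("chromosome")["position_bp"]
            .agg(lambda s: s.max() - s.min() + 1)
            .sum()
        )
    if genome_span_bp <= 0:
        raise PanelError("zero genome span")

    per_sample = []
    for sid in panel.samples:
        seg = segments[segments["sample"] == sid] if len(segments) else segments
        total = int(seg["length_bp"].sum()) if len(seg) else 0
        per_sample.append(
            {
                "sample": sid,
                "population": panel.populations[sid],
                "n_segments": int(len(seg)),
                "roh_bp": total,
                "autozygosity_fraction": total / genome_span_bp,
            }
        )
    sample_table = pd.DataFrame(per_sample)

    edges = [0.0] + [x for x in length_classes_mb]
    lengths_mb = segments["length_bp"].to_numpy() / 1e6 if len(segments) else np.array([])
    hist_rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (lengths_mb >= lo) & (lengths_mb < hi)
        hist_rows.append({"lo_mb": lo, "hi_mb": hi, "n_segments": int(sel.sum())})
    return sample_table, pd.DataFrame(hist_rows)
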