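"""Weir–Cockerham F_ST from a two-level ANOVA on allele frequencies.

Per SNP, with s populations, n_i gene copies (2 x called diploids) and
allele-A frequency p_i in population i:

    p_bar = sum n_i p_i / sum n_i
    MSP   = sum n_i (p_i - p_bar)^2 / (s - 1)          (among populations)
    MSG   = sum n_i p_i (1 - p_i)   / sum (n_i - 1)    (within populations)
    n_c   = (sum n_i - sum n_i^2 / sum n_i) / (s - 1)  (sample-size correction)

    F_ST  = (MSP - MSG) / (MSP + (n_c - 1) MSG)

Negative estimates, which have no biological interpretation, are clamped
to 0 (and, for numerical safety, estimates above 1 to 1).  SNPs where any
group has zero called genotypes, or that are monomorphic over all groups
(0/0 estimate), are flagged invalid and excluded from aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError


@dataclass(frozen=True)
class FstComponents:
    """Per-SNP ANOVA pieces and the clamped estimate."""

    s: int
    n: np.ndarray  # gene copies per group
    p: np.ndarray  # allele-A (allele2) frequency per group
    p_bar: float
    msp: float
    msg: float
    n_c: float
    fst: float


def _group_rows(panel: GenotypePanel, grouping: Mapping[str, str] | None) -> tuple[list[str], list[np.ndarray]]:
    """Resolve a population->group mapping into row-index blocks per group."""
    labels = panel.population_labels
    if grouping is None:
        grouping = {p: p for p in panel.population_names()}
    unknown = sorted(set(grouping) - set(panel.population_names()))
    if unknown:
        raise PanelError(f"grouping references unknown populations {unknown}")
    groups: dict[str, list[str]] = {}
    for pop, grp in grouping.items():
        groups.setdefault(grp, []).append(pop)
    names = list(groups)
    rows = [np.flatnonzero(np.isin(labels, pops)) for pops in groups.values()]
    return names, rows


def _component_arrays(
    panel: GenotypePanel, rows: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """(n_groups, n_snps) gene-copy counts and allele frequencies."""
    n = np.empty((len(rows), panel.n_snps), dtype=np.int64)
    p = np.empty((len(rows), panel.n_snps))
    for g, idx in enumerate(rows):
        d = panel.dosages[idx]
        called = d != MISSING
        n[g] = 2 * called.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p[g] = np.where(called, d, 0).sum(axis=0) / n[g]
    return n, p


def fst_components_table(
    panel: GenotypePanel, grouping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Vectorized per-SNP F_ST with all ANOVA components.

    Columns: snp_id, chromosome, position_bp, p_bar, msp, msg, n_c,
    fst_raw, fst, valid.  ``valid`` is False where a group has no called
    genotype or the estimate is 0/0 (monomorphic everywhere).
    """
    names, rows = _group_rows(panel, grouping)
    s = len(names)
    if s < 2:
        raise PanelError("need >= 2 groups for F_ST")
    n, p = _component_arrays(panel, rows)

    any_empty = (n == 0).any(axis=0)
    n_sum = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_bar = (n * p).sum(axis=0) / n_sum
        msp = (n * (p - p_bar) ** 2).sum(axis=0) / (s - 1)
        msg = (n * p * (1.0 - p)).sum(axis=0) / (n - 1).sum(axis=0)
        n_c = (n_sum - (n**2).sum(axis=0) / n_sum) / (s - 1)
        denom = msp + (n_c - 1.0) * msg
        fst_raw = (msp - msg) / denom
    valid = ~any_empty & (denom > 0)
    fst = np.clip(np.where(valid, fst_raw, np.nan), 0.0, 1.0)

    return pd.DataFrame(
        {
            "snp_id": panel.markers["snp_id"],
            "chromosome": panel.markers["chromosome"],
            "position_bp": panel.markers["position_bp"],
            "p_bar": p_bar,
            "msp": msp,
            "msg": msg,
            "n_c": n_c,
            "fst_raw": fst_raw,
            "fst": fst,
            "valid": valid,
        }
    )


def per_snp_fst(
    panel: GenotypePanel, grouping: Mapping[str, str] | None = None, snp: int | str = 0
) -> FstComponents:
    """ANOVA components and clamped F_ST for a single SNP.

    Raises if any group has zero called genotypes at the SNP.
    """
    if isinstance(snp, str):
        hits = np.flatnonzero(panel.markers["snp_id"].to_numpy() == snp)
        if hits.size == 0:
            raise PanelError(f"unknown SNP {snp!r}")
        j = int(hits[0])
    else:
        j = int(snp)
    names, rows = _group_rows(panel, grouping)
    n, p = _component_arrays(panel, rows)
    n, p = n[:, j], p[:, j]
    if (n == 0).any():
        empty = names[int(np.argmax(n == 0))]
        raise PanelError(f"group {empty!r} has zero called genotypes at SNP {j}")
    return fst_from_counts(n, p)


def fst_from_counts(n: np.ndarray, p: np.ndarray) -> FstComponents:
    """F_ST directly from per-group gene-copy counts and frequencies."""
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    s = len(n)
    if s < 2:
        raise PanelError("need >= 2 groups")
    p_bar = float((n * p).sum() / n.sum())
    msp = float((n * (p - p_bar) ** 2).sum() / (s - 1))
    msg = float((n * p * (1.0 - p)).sum() / (n - 1.0).sum())
    n_c = float((n.sum() - (n**2).sum() / n.sum()) / (s - 1))
    denom = msp + (n_c - 1.0) * msg
    fst = np.nan if denom <= 0 else min(max((msp - msg) / denom, 0.0), 1.0)
    return FstComponents(
        s=s, n=n, p=p, p_bar=p_bar, msp=msp, msg=msg, n_c=n_c, fst=float(fst)
    )


def group_mean_fst(
    panel: GenotypePanel, grouping: Mapping[str, str] | None = None
) -> tuple[float, float, pd.DataFrame]:
    """Arithmetic mean and sd of clamped per-SNP F_ST, plus the per-SNP table.

    Invalid SNPs are excluded (the table's ``valid`` column counts them).
    """
    table = fst_components_table(panel, grouping)
    vals = table.loc[table["valid"], "fst"].to_numpy()
    if vals.size == 0:
        raise PanelError("no SNP with a valid F_ST estimate")
    return float(vals.mean()), float(vals.std(ddof=0)), table


def multilocus_fst(
    panel: GenotypePanel, grouping: Mapping[str, str] | None = None
) -> float:
    """Multilocus F_ST as the ratio of summed variance components.

    ``sum(MSP - MSG) / sum(MSP + (n_c - 1) MSG)`` over valid SNPs — the
    standard Weir–Cockerham combination across loci, which (unlike the
    arithmetic mean of per-SNP ratios) is a consistent estimator of the
    generative divergence.  Clamped to [0, 1].
    """
    table = fst_components_table(panel, grouping)
    t = table[table["valid"]]
    if len(t) == 0:
        raise PanelError("no SNP with a valid F_ST estimate")
    num = (t["msp"] - t["msg"]).sum()
    den = (t["msp"] + (t["n_c"] - 1.0) * t["msg"]).sum()
    return float(min(max(num / den, 0.0), 1.0))


def pairwise_population_fst(panel: GenotypePanel) -> pd.DataFrame:
    """Mean F_ST for every population pair (symmetric, zero diagonal)."""
    pops = panel.population_names()
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            sub = panel.take_samples(
                np.isin(panel.population_labels, [a, b])
            )
            mean, _, _ = group_mean_fst(sub, {a: a, b: b})
            out.loc[a, b] = out.loc[b, a] = mean
    return out
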