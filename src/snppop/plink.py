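"""PLINK text (.ped/.map) reading and writing plus the population file.

The population file is a two-column TSV (sample_id, population).  Genotypes
are encoded as dosage of the marker's second allele; ``0 0`` in the .ped is
the missing genotype.  Alleles are ordered lexicographically when read from
a .ped (an explicit allele table may be supplied instead); a SNP where only
one allele is observed has that allele stored as allele1 (dosage 0).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError

MISSING_ALLELE = "0"


def read_map(map_path: str | Path) -> pd.DataFrame:
    """Read a .map file (chrom, snp_id, cM, bp) into the marker-map frame."""
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PanelError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            rows.append((parts[1], parts[0], int(parts[3])))
    if not rows:
        raise PanelError(f"{map_path}: no markers")
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


def read_populations(pop_path: str | Path) -> dict[str, str]:
    """Read the two-column (sample_id, population) TSV."""
    pops: dict[str, str] = {}
    with open(pop_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise PanelError(f"{pop_path}:{ln}: expected 2 columns")
            if parts[0] in pops:
                raise PanelError(f"{pop_path}:{ln}: duplicate sample id {parts[0]!r}")
            pops[parts[0]] = parts[1]
    return pops


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    pop_path: str | Path | None = None,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> GenotypePanel:
    """Read a whitespace-delimited .ped/.map pair (plus population file).

    Parameters
    ----------
    alleles : optional
        snp_id -> (allele1, allele2) fixing the dosage orientation; without
        it alleles are ordered lexicographically per SNP from the data.

    Raises
    ------
    PanelError
        On ped/map dimension mismatch, >2 alleles at a SNP, duplicate
        sample ids, or alleles absent from the supplied table.
    """
    markers = read_map(map_path)
    m = len(markers)

    sample_ids: list[str] = []
    fams: list[str] = []
    geno_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PanelError(
                    f"{ped_path}:{ln}: {len(parts)} fields, expected {6 + 2 * m} "
                    f"for {m} markers"
                )
            if parts[1] in sample_ids:
                raise PanelError(f"{ped_path}:{ln}: duplicate sample id {parts[1]!r}")
            fams.append(parts[0])
            sample_ids.append(parts[1])
            geno_rows.append(np.array(parts[6:], dtype="U8"))
    if not sample_ids:
        raise PanelError(f"{ped_path}: no samples")

    geno = np.stack(geno_rows)  # (n, 2m)
    a_first = geno[:, 0::2]
    a_second = geno[:, 1::2]

    allele1 = np.empty(m, dtype="U8")
    allele2 = np.empty(m, dtype="U8")
    dosages = np.full((len(sample_ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        col = np.concatenate([a_first[:, j], a_second[:, j]])
        observed = sorted(set(col.tolist()) - {MISSING_ALLELE})
        snp_id = markers["snp_id"].iloc[j]
        if alleles is not None:
            try:
                a1, a2 = alleles[snp_id]
            except KeyError:
                raise PanelError(f"no allele pair supplied for SNP {snp_id!r}")
            extra = set(observed) - {a1, a2}
            if extra:
                raise PanelError(f"SNP {snp_id!r}: unknown alleles {sorted(extra)}")
        else:
            if len(observed) > 2:
                raise PanelError(f"SNP {snp_id!r}: >2 alleles {observed}")
            a1 = observed[0] if observed else "A"
            a2 = observed[1] if len(observed) > 1 else "B"
        allele1[j] = a1
        allele2[j] = a2
        f, s = a_first[:, j], a_second[:, j]
        called = (f != MISSING_ALLELE) & (s != MISSING_ALLELE)
        dosages[called, j] = (f[called] == a2).astype(np.int8) + (
            s[called] == a2
        ).astype(np.int8)

    markers["allele1"] = allele1
    markers["allele2"] = allele2

    if pop_path is not None:
        populations = read_populations(pop_path)
        unlabeled = [s for s in sample_ids if s not in populations]
        if unlabeled:
            raise PanelError(f"samples missing from population file: {unlabeled[:5]}")
    else:
        # fall back on the .ped family column as the population label
        populations = dict(zip(sample_ids, fams))
    populations = {s: populations[s] for s in sample_ids}
    return GenotypePanel(markers, sample_ids, populations, dosages)


def write_plink_text(
    panel: GenotypePanel, prefix: str | Path, write_pop: bool = True
) -> dict[str, Path]:
    """Write ``prefix.ped``, ``prefix.map`` and (optionally) ``prefix.pop``.

    The .ped family column carries the population label; genotype columns
    use the marker allele pair with ``0 0`` for missing.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = Path(f"{prefix}.map")
    ped_path = Path(f"{prefix}.ped")
    pop_path = Path(f"{prefix}.pop")

    mk = panel.markers
    with open(map_path, "w") as fh:
        for _, row in mk.iterrows():
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")

    a1 = mk["allele1"].to_numpy(dtype="U8")
    a2 = mk["allele2"].to_numpy(dtype="U8")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.samples):
            d = panel.dosages[i]
            first = np.where(d >= 1, a2, a1)
            second = np.where(d == 2, a2, a1)
            first = np.where(d == MISSING, MISSING_ALLELE, first)
            second = np.where(d == MISSING, MISSING_ALLELE, second)
            geno = " ".join(f"{x} {y}" for x, y in zip(first, second))
            pop = panel.populations[sid]
            fh.write(f"{pop} {sid} 0 0 0 -9 {geno}\n")

    paths = {"ped": ped_path, "map": map_path}
    if write_pop:
        with open(pop_path, "w") as fh:
            for sid in panel.samples:
                fh.write(f"{sid}\t{panel.populations[sid]}\n")
        paths["pop"] = pop_path
    return paths
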