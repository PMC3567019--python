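"""Synthetic multi-population SNP panels with controllable structure.

The generator emulates a SNP-chip study design: several populations of
diploid individuals typed at thousands of mapped SNPs, with

* between-population divergence under the Balding–Nichols model — each
  population's allele frequency at SNP i is drawn from
  ``Beta(p_i (1-F)/F, (1-p_i)(1-F)/F)`` around an ancestral frequency
  ``p_i``, so frequencies have mean ``p_i`` and variance ``F p_i (1-p_i)``;
* within-population linkage disequilibrium decaying hyperbolically:
  haplotypes are first-order Markov chains along each chromosome whose
  transition probabilities are solved so that (a) every SNP keeps its
  Balding–Nichols population frequency exactly and (b) the allele
  correlation between SNPs at distance d is ``exp(-lambda d / 2)`` within a
  genomic region.  Region-wise decay rates ``lambda ~ Exp(mean beta)``
  (stratified draws) make the *expected* genotype r² at distance d equal
  the Sved hyperbola ``1/(1 + beta d)`` exactly, by the exponential-mixture
  identity ``E[e^(-lambda d)] = 1/(1 + beta d)``;
* planted fully autozygous tracts (one haplotype copied over the other);
* optional admixed populations (each haplotype drawn from one of two
  source populations);
* planted outlier loci whose divergence ``F*`` replaces the population's
  background ``F`` (directional-selection mimics);
* independent random missingness.

Everything is driven by one seeded :class:`numpy.random.Generator`; a fixed
seed reproduces the panel bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: name, diploid sample count, divergence F."""

    name: str
    n_individuals: int
    divergence: float  # Balding-Nichols F in (0, 1)

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise PanelError(f"divergence F={self.divergence} outside (0, 1)")
        if self.n_individuals < 1:
            raise PanelError("n_individuals must be >= 1")


@dataclass(frozen=True)
class AdmixtureSpec:
    """An admixed population drawing haplotypes from two sources.

    Each haplotype independently comes from ``source_a`` with probability
    ``fraction``, else from ``source_b``.
    """

    target: str
    source_a: str
    source_b: str
    fraction: float = 0.5


@dataclass(frozen=True)
class PlantedRoh:
    """A forced autozygous tract for one individual of one population."""

    population: str
    individual: int  # index within the population
    chromosome: str
    start_bp: int
    length_bp: int


@dataclass
class SimulationConfig:
    """Full study design for :func:`simulate_genotypes`.

    Defaults reflect the emulated chip study scaled to desk size: mean
    inter-SNP spacing 55.6 kb, populations of 5–32 diploids, divergence
    F in the 0.1–0.3 range, LD decaying over tens to hundreds of kb.
    """

    seed: int = 0
    n_snps: int = 2000
    snp_spacing_bp: float = 55_600.0
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("POP1", 20, 0.15),
            PopulationSpec("POP2", 20, 0.15),
        ]
    )
    ld_beta_per_kb: float | dict[str, float] = 0.0
    missing_rate: float = 0.0
    n_chromosomes: int = 1
    ld_region_bp: float = 2_500_000.0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    #: sd of the ancestral-frequency random walk per sqrt(kb); frequencies
    #: drift slowly along the chromosome (needed for realistic strong LD:
    #: tightly linked SNPs must have similar frequencies)
    ancestral_walk_sd: float = 0.0015
    admixture: AdmixtureSpec | None = None
    planted_roh: list[PlantedRoh] = field(default_factory=list)
    outlier_loci: dict[int, float] = field(default_factory=dict)  # snp index -> F*

    def beta_for(self, population: str) -> float:
        if isinstance(self.ld_beta_per_kb, dict):
            return float(self.ld_beta_per_kb.get(population, 0.0))
        return float(self.ld_beta_per_kb)

    def to_json(self) -> str:
        d = asdict(self)
        d["outlier_loci"] = {str(k): v for k, v in self.outlier_loci.items()}
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------


def simulate_population_frequencies(
    p: np.ndarray | float, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw Balding–Nichols population frequencies around ancestral ``p``.

    ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` — expectation ``p``, variance
    ``F p (1-p)``.
    """
    if not 0.0 < divergence < 1.0:
        raise PanelError(f"divergence F={divergence} outside (0, 1)")
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise PanelError("ancestral frequencies must lie strictly in (0, 1)")
    scale = (1.0 - divergence) / divergence
    return rng.beta(p * scale, (1.0 - p) * scale)


def _marker_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Jittered uniform positions around the mean spacing, split over chromosomes."""
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    rows = []
    snp = 0
    for c, n_c in enumerate(per_chrom, start=1):
        gaps = rng.uniform(0.5, 1.5, size=n_c) * config.snp_spacing_bp
        pos = np.maximum(1, np.ceil(np.cumsum(gaps))).astype(np.int64)
        pos = np.maximum.accumulate(pos + np.arange(n_c))  # enforce strict increase
        for p in pos:
            rows.append((f"snp{snp:06d}", str(c), int(p), "A", "B"))
            snp += 1
    return pd.DataFrame(
        rows, columns=["snp_id", "chromosome", "position_bp", "allele1", "allele2"]
    )


def _stratified_exponential(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Exponential(mean) draws via shuffled stratified inverse-CDF sampling.

    Keeps the realized mixture close to its nominal distribution even for a
    handful of regions, so the generative decay coefficient is honoured
    without requiring hundreds of regions.
    """
    u = (np.arange(size) + rng.uniform(0.0, 1.0, size=size)) / size
    lam = -mean * np.log1p(-u)
    rng.shuffle(lam)
    return lam


def _chain_haplotypes(
    freqs: np.ndarray,
    delta: np.ndarray,
    n_haplotypes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order binary Markov chain haplotypes with exact marginals.

    ``freqs[j]`` is the target allele frequency at SNP j; ``delta[j]`` the
    regression coefficient of SNP j's allele on SNP j-1's
    (``delta = cov / var_{j-1}``), already clipped to the feasible range.
    Transition probabilities: P(1|1) = p_j + delta q_{j-1},
    P(1|0) = p_j - delta p_{j-1}; both marginals are preserved exactly and
    corr(X_j, X_k) telescopes to the target product.
    """
    m = freqs.shape[0]
    hap = np.empty((n_haplotypes, m), dtype=np.int8)
    u = rng.uniform(size=(n_haplotypes, m))
    hap[:, 0] = u[:, 0] < freqs[0]
    for j in range(1, m):
        p_prev, p_cur, d = freqs[j - 1], freqs[j], delta[j]
        prob = np.where(
            hap[:, j - 1] == 1, p_cur + d * (1.0 - p_prev), p_cur - d * p_prev
        )
        hap[:, j] = u[:, j] < prob
    return hap


def _ancestral_walk(
    markers: pd.DataFrame,
    lo: float,
    hi: float,
    walk_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ancestral frequencies as a reflected Gaussian walk along each chromosome.

    Tightly linked SNPs must carry similar allele frequencies for strong LD
    to be attainable (the correlation of two Bernoulli variables is capped
    by how close their frequencies are), so the ancestral frequency drifts
    with sd ``walk_sd * sqrt(gap in kb)`` instead of being drawn i.i.d.
    """
    pos = markers["position_bp"].to_numpy()
    chrom = markers["chromosome"].to_numpy()
    out = np.empty(len(markers))
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        gaps_kb = np.diff(pos[idx]) / 1000.0
        steps = rng.normal(0.0, walk_sd * np.sqrt(np.maximum(gaps_kb, 0.1)))
        walk = rng.uniform(lo, hi) + np.concatenate([[0.0], np.cumsum(steps)])
        # reflect into [lo, hi]
        width = hi - lo
        folded = np.abs(np.mod(walk - lo, 2.0 * width) - width)
        out[idx] = lo + np.minimum(folded, width)
    return out


def _step_correlations(
    markers: pd.DataFrame,
    beta_per_kb: float,
    region_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-SNP adjacent-haplotype-allele correlation rho targeting Sved decay.

    Each chromosome is partitioned into fixed-span regions; region r gets a
    decay rate lambda_r from a stratified Exponential with mean
    ``beta_per_kb`` (per kb), and the step correlation over a gap d is
    ``exp(-lambda d / 2)`` so that within-region r² = exp(-lambda d).  The
    exponential mixture over regions averages to ``E[r²] = 1/(1 + beta d)``
    exactly.  rho[0] of each chromosome is 0 (chain restart).
    """
    m = len(markers)
    rho = np.zeros(m)
    if beta_per_kb <= 0.0:
        return rho
    pos = markers["position_bp"].to_numpy()
    chrom = markers["chromosome"].to_numpy()
    region_id = np.zeros(m, dtype=np.int64)
    next_region = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        local = (pos[idx] - pos[idx][0]) // int(region_bp)
        region_id[idx] = next_region + local
        next_region = int(region_id[idx].max()) + 1
    lam = _stratified_exponential(beta_per_kb / 1000.0, next_region, rng)

    same_chrom = np.concatenate([[False], chrom[1:] == chrom[:-1]])
    gap = np.concatenate([[0], np.diff(pos)])
    return np.where(same_chrom, np.exp(-lam[region_id] * gap / 2.0), 0.0)


def _copula_bn_frequencies(
    ancestral: np.ndarray,
    divergence: float,
    rho: np.ndarray,
    outlier_f: dict[int, float],
    rng: np.random.Generator,
    outlier_flip: bool = False,
    outlier_u: dict[int, float] | None = None,
) -> np.ndarray:
    """Balding–Nichols frequencies with cross-SNP Gaussian-copula dependence.

    Marginally each SNP's frequency is an exact Balding–Nichols draw
    (Beta with mean ``ancestral`` and variance ``F p (1-p)``); along the
    chromosome the draws share a latent AR(1) field with step correlations
    ``rho``, so the population's deviation from the ancestral frequency
    varies smoothly — as linkage makes it in real genomes — instead of
    jumping SNP to SNP.  Outlier loci use their boosted divergence F*.
    """
    from scipy.stats import beta as beta_dist, norm

    m = ancestral.shape[0]
    z = np.empty(m)
    z[0] = rng.normal()
    eps = rng.normal(size=m)
    for j in range(1, m):
        z[j] = rho[j] * z[j - 1] + np.sqrt(1.0 - rho[j] ** 2) * eps[j]
    u = norm.cdf(z)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)

    f_per_snp = np.full(m, divergence)
    for j, f_star in outlier_f.items():
        if not 0.0 < f_star < 1.0:
            raise PanelError(f"outlier divergence F*={f_star} outside (0, 1)")
        f_per_snp[j] = f_star
        if outlier_u is not None:
            # planted outliers share one latent quantile across populations,
            # antithetic between alternate populations: opposite Beta tails,
            # the directional-contrast pattern a selection scan should flag
            u[j] = 1.0 - outlier_u[j] if outlier_flip else outlier_u[j]
    scale = (1.0 - f_per_snp) / f_per_snp
    return beta_dist.ppf(u, ancestral * scale, (1.0 - ancestral) * scale)


def _chain_delta(freqs: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Feasibility-clipped chain coefficients from the target correlations.

    delta_j = rho_j * sqrt(V_j / V_{j-1}) makes the variance-ratio factors
    telescope so any within-region pair attains corr = prod(rho); the clip
    enforces valid transition probabilities (binary marginals bound the
    achievable correlation).
    """
    var = freqs * (1.0 - freqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.sqrt(np.concatenate([[1.0], var[1:] / var[:-1]]))
    target = rho * ratio
    p_prev = np.concatenate([[0.5], freqs[:-1]])
    p_cur = freqs
    d_max = np.minimum((1.0 - p_cur) / (1.0 - p_prev), p_cur / p_prev)
    return np.clip(target, 0.0, d_max * (1.0 - 1e-9))


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Generate a :class:`GenotypePanel` under the configured study design.

    Raises
    ------
    PanelError
        For impossible planted-tract placements or missing admixture sources.
    """
    rng = np.random.default_rng(config.seed)
    markers = _marker_map(config, rng)
    m = len(markers)
    lo, hi = config.ancestral_freq_range
    ancestral = _ancestral_walk(markers, lo, hi, config.ancestral_walk_sd, rng)

    pop_names = [p.name for p in config.populations]
    if config.admixture is not None:
        adm = config.admixture
        for src in (adm.source_a, adm.source_b):
            if src not in pop_names:
                raise PanelError(f"admixture source {src!r} not among populations")
        if adm.target not in pop_names:
            raise PanelError(f"admixture target {adm.target!r} not among populations")

    for j in config.outlier_loci:
        if not 0 <= j < m:
            raise PanelError(f"outlier SNP index {j} out of range")
        # planted outliers sit at intermediate ancestral frequency so that
        # boosted divergence can realize opposite near-fixation between
        # populations (a skewed ancestral puts both Beta tails at the same
        # boundary, erasing the contrast)
        ancestral[j] = 0.5
    # one shared latent quantile per outlier, drawn from the outer tail so
    # alternate populations land on opposite sides of the ancestral value
    outlier_u = {j: rng.uniform(0.75, 0.995) for j in sorted(config.outlier_loci)}

    # per population: target step correlations, Balding-Nichols frequencies
    # (copula-coupled along the chromosome), and feasible chain coefficients
    pop_freqs: dict[str, np.ndarray] = {}
    deltas: dict[str, np.ndarray] = {}
    for k, spec in enumerate(config.populations):
        rho = _step_correlations(
            markers, config.beta_for(spec.name), config.ld_region_bp, rng
        )
        # the population's frequency deviations decay more slowly than the
        # haplotype correlation itself, keeping linked frequencies similar
        # so the chain coefficients stay feasible (minimal clipping)
        f = _copula_bn_frequencies(
            ancestral, spec.divergence, rho ** 0.25, config.outlier_loci, rng,
            outlier_flip=(k % 2 == 1), outlier_u=outlier_u,
        )
        pop_freqs[spec.name] = np.clip(f, 1e-4, 1.0 - 1e-4)
        deltas[spec.name] = _chain_delta(pop_freqs[spec.name], rho)

    samples: list[str] = []
    populations: dict[str, str] = {}
    dosage_blocks: list[np.ndarray] = []
    hap_store: dict[str, np.ndarray] = {}

    for spec in config.populations:
        n_hap = 2 * spec.n_individuals
        if config.admixture is not None and spec.name == config.admixture.target:
            adm = config.admixture
            src = np.where(
                rng.uniform(size=n_hap) < adm.fraction, adm.source_a, adm.source_b
            )
            hap = np.empty((n_hap, m), dtype=np.int8)
            for source in (adm.source_a, adm.source_b):
                rows = np.flatnonzero(src == source)
                if rows.size:
                    hap[rows] = _chain_haplotypes(
                        pop_freqs[source], deltas[source], rows.size, rng
                    )
        else:
            hap = _chain_haplotypes(
                pop_freqs[spec.name], deltas[spec.name], n_hap, rng
            )
        hap_store[spec.name] = hap
        ids = [f"{spec.name}_{i:03d}" for i in range(spec.n_individuals)]
        samples.extend(ids)
        for sid in ids:
            populations[sid] = spec.name

    # planted autozygosity: copy haplotype 0 over haplotype 1 in the tract
    chrom_arr = markers["chromosome"].to_numpy()
    pos_arr = markers["position_bp"].to_numpy()
    for roh in config.planted_roh:
        if roh.population not in hap_store:
            raise PanelError(f"planted ROH population {roh.population!r} unknown")
        spec = next(p for p in config.populations if p.name == roh.population)
        if not 0 <= roh.individual < spec.n_individuals:
            raise PanelError(f"planted ROH individual {roh.individual} out of range")
        in_tract = (
            (chrom_arr == roh.chromosome)
            & (pos_arr >= roh.start_bp)
            & (pos_arr < roh.start_bp + roh.length_bp)
        )
        if not in_tract.any():
            raise PanelError(
                f"planted ROH at {roh.chromosome}:{roh.start_bp} covers no SNPs"
            )
        hap = hap_store[roh.population]
        h0, h1 = 2 * roh.individual, 2 * roh.individual + 1
        hap[h1, in_tract] = hap[h0, in_tract]

    for spec in config.populations:
        hap = hap_store[spec.name]
        dosage_blocks.append(hap[0::2] + hap[1::2])

    dosages = np.concatenate(dosage_blocks, axis=0).astype(np.int8)
    if config.missing_rate > 0.0:
        mask = rng.uniform(size=dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    return GenotypePanel(markers, samples, populations, dosages)


def roh_sweep_panel(
    lengths_kb: list[int],
    spacing_bp: int = 5_000,
    separation_bp: int = 2_500_000,
    plant_dosage: int = 0,
) -> tuple[GenotypePanel, list[tuple[int, int, int]]]:
    """One-sample synthetic chromosome with planted homozygous tracts.

    The background alternates heterozygous and homozygous calls (50%
    heterozygosity) with the SNP flanking each tract heterozygous, so the
    scanning-window hit rate at tract edges is deterministic: the called
    segment is exactly the planted tract, with no edge erosion or
    extension.  Used to probe the caller's minimum-length rule by sweeping
    planted tract lengths.

    Returns the panel and ``(start_bp, end_bp, length_kb)`` per tract.
    """
    lengths_bp = [int(l * 1000) for l in lengths_kb]
    n_plant_snps = [l // spacing_bp + 1 for l in lengths_bp]
    margin = separation_bp

    pos_blocks: list[np.ndarray] = []
    dos_blocks: list[np.ndarray] = []
    plants: list[tuple[int, int, int]] = []

    def background(start_bp: int, n: int) -> None:
        """n background SNPs alternating het/hom, heterozygous at both ends."""
        pos = start_bp + spacing_bp * np.arange(n)
        i = np.arange(n)
        het = np.minimum(i, n - 1 - i) % 2 == 0
        pos_blocks.append(pos)
        dos_blocks.append(np.where(het, 1, 2).astype(np.int8))

    cursor = 1
    n_bg = margin // spacing_bp
    for length_bp, n_snps in zip(lengths_bp, n_plant_snps):
        background(cursor, n_bg)
        cursor += n_bg * spacing_bp
        pos = cursor + spacing_bp * np.arange(n_snps)
        pos_blocks.append(pos)
        dos_blocks.append(np.full(n_snps, plant_dosage, dtype=np.int8))
        plants.append((int(pos[0]), int(pos[-1]), length_bp // 1000))
        cursor = int(pos[-1]) + spacing_bp
    background(cursor, n_bg)

    positions = np.concatenate(pos_blocks)
    dosages = np.concatenate(dos_blocks)[None, :]
    markers = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(len(positions))],
            "chromosome": "1",
            "position_bp": positions,
            "allele1": "A",
            "allele2": "B",
        }
    )
    panel = GenotypePanel(markers, ["S1"], {"S1": "SWEEP"}, dosages)
    return panel, plants


def write_simulation(
    config: SimulationConfig, prefix: str | Path
) -> GenotypePanel:
    """Simulate, write .ped/.map/.pop plus a JSON echo of the config."""
    from .plink import write_plink_text

    panel = simulate_genotypes(config)
    write_plink_text(panel, prefix)
    Path(f"{prefix}.config.json").write_text(config.to_json())
    return panel
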