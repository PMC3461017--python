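"""Synthetic two-cohort data with the statistical structure the scans assume.

Two generators cover the two nulls the pipeline needs:

* ``simulate_two_pop_drift`` — independent sites; each site's ancestral
  frequency drifts through ``split_generations`` of binomial Wright-Fisher
  resampling separately in two populations of ``N`` diploids, then cohorts
  are drawn under Hardy-Weinberg. The expected per-SNP Fst is
  1 - (1 - 1/2N)^t ~ 1 - exp(-t/2N). This is the differentiation null.

* ``simulate_sweep_panel`` — linked sites; a forward-time diploid
  Wright-Fisher population with Poisson crossovers placed on the genetic
  map evolves a derived allele introduced as a single copy at a focal site
  under additive selection ``s``, rejection-conditioned on the allele
  reaching a target frequency band. The reference population shares the
  founder haplotypes and evolves neutrally for the same number of
  generations. This is the haplotype-statistics alternative.

Default cohort sizes follow the study design the pipeline emulates: 156/110
diploids for the genotype (Fst) cohorts and 143/90 for the phased panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .genomic_io import (
    GeneAnnotation,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    SiteMeta,
)


@dataclass
class SimulationConfig:
    """Knobs for both simulators; all rates per generation.

    ``split_generations`` is the drift time per population in drift mode and
    the cap on sweep duration in sweep mode (the realized duration is in the
    truth record). ``sample_size_*`` count diploid individuals.
    """

    seed: int = 0
    n_sites: int = 1200
    chromosome_length_bp: int = 25_000_000
    recombination_rate_cM_Mb: float = 1.0
    N: int = 500
    split_generations: int = 40
    sample_size_test: int = 156
    sample_size_ref: int = 110
    selection_coefficient: float = 0.05
    sweep_position_bp: int | None = None
    target_band: tuple[float, float] = (0.6, 0.8)
    neutral_duration: int = 100
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    max_retries: int = 200
    max_generations: int = 600
    n_genes: int = 25
    gene_length_bp: tuple[int, int] = (20_000, 100_000)
    genes_over_sweep_bp: int = 0
    pop_test: str = "test"
    pop_ref: str = "ref"
    chromosome: str = "1"

    def __post_init__(self) -> None:
        if self.selection_coefficient < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.recombination_rate_cM_Mb < 0:
            raise ValueError("recombination rate must be >= 0")
        if max(self.sample_size_test, self.sample_size_ref) > self.N:
            raise ValueError("sample sizes cannot exceed N diploids")


@dataclass
class SimulatedCohort:
    """Simulated panels, genotypes, map, annotation and the truth record."""

    panels: dict[str, HaplotypePanel]
    genotypes: GenotypeMatrix
    genetic_map: GeneticMap
    annotation: GeneAnnotation
    truth: dict[str, Any]
    config: SimulationConfig = field(repr=False, default=None)


def _make_sites(
    rng: np.random.Generator, config: SimulationConfig, focal_bp: int | None = None
) -> tuple[list[SiteMeta], int | None]:
    """Random sorted site positions (plus an optional focal site) with cM."""
    pos = rng.choice(
        np.arange(2, config.chromosome_length_bp, dtype=np.int64),
        size=config.n_sites,
        replace=False,
    )
    pos = np.sort(pos)
    focal_idx = None
    if focal_bp is not None:
        pos = pos[pos != focal_bp]
        pos = np.sort(np.append(pos, focal_bp))
        focal_idx = int(np.searchsorted(pos, focal_bp))
    rate = config.recombination_rate_cM_Mb
    sites = [
        SiteMeta(
            snp_id=f"snp{i}",
            chromosome=config.chromosome,
            position_bp=int(p),
            ancestral_allele="A",
            derived_allele="G",
            genetic_pos_cM=float((p - 1) * rate / 1e6),
        )
        for i, p in enumerate(pos)
    ]
    return sites, focal_idx


def _sample_cohorts(
    rng: np.random.Generator,
    config: SimulationConfig,
    sites: list[SiteMeta],
    hap_test: np.ndarray,
    hap_ref: np.ndarray,
) -> tuple[dict[str, HaplotypePanel], GenotypeMatrix]:
    """Draw diploid samples from the two haplotype pools."""
    panels = {}
    blocks = []
    ids: list[str] = []
    labels: list[str] = []
    for pop, pool, n in (
        (config.pop_test, hap_test, config.sample_size_test),
        (config.pop_ref, hap_ref, config.sample_size_ref),
    ):
        ind = rng.choice(pool.shape[0] // 2, size=n, replace=False)
        rows = np.empty(2 * n, dtype=np.int64)
        rows[0::2], rows[1::2] = 2 * ind, 2 * ind + 1
        sample_ids = [f"{pop}{i}" for i in range(n)]
        panels[pop] = HaplotypePanel(
            sites=list(sites), haplotypes=pool[rows], sample_ids=sample_ids
        )
        blocks.append(pool[rows][0::2] + pool[rows][1::2])
        ids.extend(sample_ids)
        labels.extend([pop] * n)
    genotypes = GenotypeMatrix(
        sites=list(sites),
        dosages=np.vstack(blocks).astype(np.int8),
        individual_ids=ids,
        population_labels=labels,
    )
    return panels, genotypes


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GeneAnnotation:
    """Random non-overlapping gene intervals leaving at least 30% of the
    chromosome >= 50 kb away from every gene."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.chromosome_length_bp
    margin = 50_000
    empty = pd.DataFrame(columns=["chromosome", "start_bp", "end_bp", "name"])
    if config.n_genes == 0:
        return GeneAnnotation(intervals=empty)
    for _ in range(50):
        lengths = rng.integers(*config.gene_length_bp, size=config.n_genes)
        starts = np.sort(rng.integers(1, max(2, L - int(lengths.max())), size=config.n_genes))
        intervals = []
        prev_end = 0
        ok = True
        for s, l in zip(starts, lengths):
            e = min(int(s + l - 1), L)
            if s <= prev_end:
                ok = False
                break
            intervals.append((int(s), e))
            prev_end = e
        if not ok:
            continue
        covered = sum(
            min(e + margin, L) - max(s - margin, 1) + 1 for s, e in intervals
        )
        if L - covered >= 0.3 * L:
            df = pd.DataFrame(
                [
                    {
                        "chromosome": config.chromosome,
                        "start_bp": s,
                        "end_bp": e,
                        "name": f"gene{i}",
                    }
                    for i, (s, e) in enumerate(intervals)
                ],
                columns=["chromosome", "start_bp", "end_bp", "name"],
            )
            return GeneAnnotation(intervals=df)
    raise ValueError(
        "could not place non-overlapping genes leaving 30% of the chromosome "
        "intergenic; lower n_genes or gene lengths"
    )


def simulate_two_pop_drift(config: SimulationConfig) -> SimulatedCohort:
    """Independent-sites drift of two populations from a common ancestor."""
    rng = np.random.default_rng(config.seed)
    sites, _ = _make_sites(rng, config)
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=len(sites))
    freqs = {}
    for pop in (config.pop_test, config.pop_ref):
        p = p0.copy()
        for _ in range(config.split_generations):
            p = rng.binomial(2 * config.N, p) / (2 * config.N)
        freqs[pop] = p
    n_hap_t = 2 * config.N
    hap_test = (rng.random((n_hap_t, len(sites))) < freqs[config.pop_test]).astype(np.int8)
    hap_ref = (rng.random((n_hap_t, len(sites))) < freqs[config.pop_ref]).astype(np.int8)
    panels, genotypes = _sample_cohorts(rng, config, sites, hap_test, hap_ref)
    annotation = simulate_annotation(config, rng)
    gmap = GeneticMap.uniform(config.chromosome_length_bp, config.recombination_rate_cM_Mb)
    truth = {
        "mode": "drift",
        "seed": config.seed,
        "N": config.N,
        "split_generations": config.split_generations,
        "expected_fst": 1.0 - (1.0 - 1.0 / (2 * config.N)) ** config.split_generations,
        "sweep_position_bp": None,
        "selection_coefficient": 0.0,
        "final_derived_frequency": None,
    }
    return SimulatedCohort(
        panels=panels, genotypes=genotypes, genetic_map=gmap,
        annotation=annotation, truth=truth, config=config,
    )


def _next_generation(
    rng: np.random.Generator,
    hap: np.ndarray,
    cms: np.ndarray,
    total_morgans: float,
    s: float,
    focal_idx: int | None,
) -> np.ndarray:
    """One diploid Wright-Fisher generation with recombination and selection."""
    n_hap, n_sites = hap.shape
    n_ind = n_hap // 2
    if s > 0 and focal_idx is not None:
        dosage = hap[0::2, focal_idx].astype(float) + hap[1::2, focal_idx]
        w = 1.0 + s * dosage
        prob = w / w.sum()
        parents = rng.choice(n_ind, size=n_hap, p=prob)
    else:
        parents = rng.integers(0, n_ind, size=n_hap)
    n_cross = rng.poisson(total_morgans, size=n_hap)
    start_hap = rng.integers(0, 2, size=n_hap)
    out = np.empty_like(hap)
    plain = n_cross == 0
    out[plain] = hap[2 * parents[plain] + start_hap[plain]]
    # single-crossover gametes (most recombinants): two slice copies each
    single_idx = np.flatnonzero(n_cross == 1)
    if single_idx.size:
        cut_sites = np.searchsorted(cms, rng.uniform(0.0, cms[-1], size=single_idx.size))
        first = 2 * parents[single_idx] + start_hap[single_idx]
        second = 2 * parents[single_idx] + 1 - start_hap[single_idx]
        for k, g in enumerate(single_idx):
            ci = cut_sites[k]
            out[g, :ci] = hap[first[k], :ci]
            out[g, ci:] = hap[second[k], ci:]
    for g in np.flatnonzero(n_cross >= 2):
        cuts = np.sort(rng.uniform(0.0, cms[-1], size=n_cross[g]))
        # copy alternating donor segments between crossover breakpoints
        bounds = np.concatenate([[0], np.searchsorted(cms, cuts), [cms.size]])
        donor = start_hap[g]
        base = 2 * parents[g]
        for k in range(bounds.size - 1):
            lo, hi = bounds[k], bounds[k + 1]
            if lo < hi:
                out[g, lo:hi] = hap[base + donor, lo:hi]
            donor = 1 - donor
    return out


def simulate_sweep_panel(config: SimulationConfig) -> SimulatedCohort:
    """Forward-time linked-sites simulation with a partial sweep in the test
    population.

    With ``selection_coefficient > 0`` the derived allele starts as a single
    copy and the run is rejection-conditioned on it reaching the target
    frequency band (within ``max_generations``); with ``s == 0`` the focal
    allele starts at a standing frequency drawn inside the band and drifts
    for ``neutral_duration`` generations, again conditioned on ending inside
    the band, which provides the frequency-matched neutral control.
    """
    rng = np.random.default_rng(config.seed)
    focal_bp = config.sweep_position_bp or config.chromosome_length_bp // 2
    sites, focal_idx = _make_sites(rng, config, focal_bp=focal_bp)
    cms = np.array([s.genetic_pos_cM for s in sites])
    total_morgans = (cms[-1] - cms[0]) / 100.0
    lo, hi = config.ancestral_freq_range
    band_lo, band_hi = config.target_band
    s_coef = config.selection_coefficient
    n_hap = 2 * config.N

    p0 = rng.uniform(lo, hi, size=len(sites))
    founders = (rng.random((n_hap, len(sites))) < p0).astype(np.int8)
    founders[:, focal_idx] = 0

    attempts = 0
    while True:
        attempts += 1
        if attempts > config.max_retries:
            raise RuntimeError(
                f"sweep did not reach frequency band {config.target_band} "
                f"in {config.max_retries} attempts"
            )
        hap_test = founders.copy()
        if s_coef > 0:
            hap_test[rng.integers(0, n_hap), focal_idx] = 1
        else:
            standing = rng.uniform(band_lo, band_hi)
            hap_test[:, focal_idx] = rng.random(n_hap) < standing
        gens = 0
        success = False
        horizon = config.max_generations if s_coef > 0 else config.neutral_duration
        while gens < horizon:
            hap_test = _next_generation(rng, hap_test, cms, total_morgans, s_coef, focal_idx)
            gens += 1
            freq = hap_test[:, focal_idx].mean()
            if s_coef > 0:
                if freq == 0.0:
                    break
                if band_lo <= freq <= band_hi:
                    success = True
                    break
        if s_coef == 0:
            success = band_lo <= hap_test[:, focal_idx].mean() <= band_hi
        if success:
            break

    hap_ref = founders.copy()
    for _ in range(gens):
        hap_ref = _next_generation(rng, hap_ref, cms, total_morgans, 0.0, None)

    panels, genotypes = _sample_cohorts(rng, config, sites, hap_test, hap_ref)
    annotation = simulate_annotation(config, rng)
    if config.genes_over_sweep_bp > 0:
        # gene-dense swept locus: the intergenic null assumes sweeps are at
        # genes, so hitchhikers inside the sweep footprint are made genic
        half = config.genes_over_sweep_bp
        focal_pos = sites[focal_idx].position_bp
        lo, hi = focal_pos - half, focal_pos + half
        iv = annotation.intervals
        iv = iv[(iv["end_bp"] < lo - 60_000) | (iv["start_bp"] > hi + 60_000)]
        tiles, s = [], lo
        while s < hi:
            tiles.append(
                {
                    "chromosome": config.chromosome,
                    "start_bp": int(max(1, s)),
                    "end_bp": int(min(s + 100_000, hi)),
                    "name": f"sweepgene{len(tiles)}",
                }
            )
            s += 120_000
        annotation = GeneAnnotation(
            intervals=pd.concat([iv, pd.DataFrame(tiles)], ignore_index=True)
        )
    gmap = GeneticMap.uniform(config.chromosome_length_bp, config.recombination_rate_cM_Mb)
    truth = {
        "mode": "sweep",
        "seed": config.seed,
        "N": config.N,
        "split_generations": gens,
        "sweep_position_bp": sites[focal_idx].position_bp,
        "sweep_snp_id": sites[focal_idx].snp_id,
        "focal_index": focal_idx,
        "selection_coefficient": s_coef,
        "final_derived_frequency": float(hap_test[:, focal_idx].mean()),
        "attempts": attempts,
    }
    return SimulatedCohort(
        panels=panels, genotypes=genotypes, genetic_map=gmap,
        annotation=annotation, truth=truth, config=config,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
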