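"""Readers, writers and containers for the formats the scan touches.

All coordinates are 1-based inclusive internally. BED input (0-based,
half-open) is converted on read. Haplotype matrices are coded 0 = ancestral
allele, 1 = derived allele; genotype dosages count the derived (A2) allele
with ``-1`` standing for a missing call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SiteMeta:
    """Metadata for one biallelic SNP."""

    snp_id: str
    chromosome: str
    position_bp: int
    ancestral_allele: str
    derived_allele: str
    genetic_pos_cM: float = 0.0

    def __post_init__(self) -> None:
        if self.ancestral_allele == self.derived_allele:
            raise ValueError(
                f"{self.snp_id}: ancestral and derived alleles are identical"
            )
        if self.genetic_pos_cM < 0:
            raise ValueError(f"{self.snp_id}: negative genetic position")


def _check_sites_sorted(sites: Sequence[SiteMeta]) -> None:
    by_chrom: dict[str, SiteMeta] = {}
    for s in sites:
        prev = by_chrom.get(s.chromosome)
        if prev is not None:
            if s.position_bp <= prev.position_bp:
                raise ValueError(
                    f"sites not strictly increasing on {s.chromosome}: "
                    f"{prev.position_bp} then {s.position_bp}"
                )
            if s.genetic_pos_cM < prev.genetic_pos_cM:
                raise ValueError(
                    f"genetic positions decrease on {s.chromosome} at {s.snp_id}"
                )
        by_chrom[s.chromosome] = s


@dataclass
class HaplotypePanel:
    """Phased haplotype-by-site 0/1 matrix with per-site metadata.

    Rows are haplotypes (two consecutive rows per diploid individual),
    columns are sites in genomic order.
    """

    sites: list[SiteMeta]
    haplotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    allow_odd: bool = False

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError(
                f"{self.haplotypes.shape[1]} haplotype columns for "
                f"{len(self.sites)} sites"
            )
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")
        if self.haplotypes.shape[0] % 2 and not self.allow_odd:
            raise ValueError("odd haplotype count without allow_odd flag")
        _check_sites_sorted(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.sites], dtype=np.int64)

    @property
    def positions_cM(self) -> np.ndarray:
        return np.array([s.genetic_pos_cM for s in self.sites], dtype=float)

    def derived_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def to_genotype_matrix(self, population_label: str) -> "GenotypeMatrix":
        """Collapse consecutive haplotype pairs to 0/1/2 dosages."""
        if self.n_haplotypes % 2:
            raise ValueError("cannot pair an odd number of haplotypes")
        dosages = self.haplotypes[0::2] + self.haplotypes[1::2]
        n_ind = dosages.shape[0]
        ids = self.sample_ids or [f"ind{i}" for i in range(n_ind)]
        return GenotypeMatrix(
            sites=list(self.sites),
            dosages=dosages.astype(np.int8),
            individual_ids=list(ids),
            population_labels=[population_label] * n_ind,
        )


@dataclass
class GenotypeMatrix:
    """Individual-by-site derived-allele dosage matrix with population labels."""

    sites: list[SiteMeta]
    dosages: np.ndarray
    individual_ids: list[str]
    population_labels: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.individual_ids), len(self.sites)):
            raise ValueError("dosage matrix shape mismatch with ids/sites")
        if len(self.population_labels) != len(self.individual_ids):
            raise ValueError("one population label per individual required")
        if self.dosages.size and not np.isin(self.dosages, (0, 1, 2, MISSING)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        if self.n_individuals == 0:
            return np.zeros(self.n_sites)
        return (self.dosages == MISSING).mean(axis=0)

    def subset_population(self, label: str) -> "GenotypeMatrix":
        idx = [i for i, l in enumerate(self.population_labels) if l == label]
        if not idx:
            raise ValueError(f"no individuals labelled {label!r}")
        return GenotypeMatrix(
            sites=list(self.sites),
            dosages=self.dosages[idx],
            individual_ids=[self.individual_ids[i] for i in idx],
            population_labels=[label] * len(idx),
        )

    def allele_counts(self) -> np.ndarray:
        """Per-SNP (derived count, ancestral count) over non-missing calls."""
        obs = self.dosages != MISSING
        derived = np.where(obs, self.dosages, 0).sum(axis=0)
        total = 2 * obs.sum(axis=0)
        return np.stack([derived, total - derived], axis=1)


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map: bp anchor -> cumulative cM."""

    positions_bp: np.ndarray
    rates_cM_per_Mb: np.ndarray
    cumulative_cM: np.ndarray

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.rates_cM_per_Mb = np.asarray(self.rates_cM_per_Mb, dtype=float)
        self.cumulative_cM = np.asarray(self.cumulative_cM, dtype=float)
        order = np.argsort(self.positions_bp, kind="stable")
        self.positions_bp = self.positions_bp[order]
        self.rates_cM_per_Mb = self.rates_cM_per_Mb[order]
        self.cumulative_cM = self.cumulative_cM[order]
        if len(self.positions_bp) == 0:
            raise ValueError("empty genetic map")
        if (np.diff(self.cumulative_cM) < 0).any():
            bad = int(np.flatnonzero(np.diff(self.cumulative_cM) < 0)[0]) + 1
            raise FormatError(
                f"cumulative cM decreases at anchor {bad + 1} "
                f"(position {self.positions_bp[bad]})"
            )
        if (self.rates_cM_per_Mb < 0).any():
            raise FormatError("negative recombination rate in map")

    @classmethod
    def uniform(cls, length_bp: int, rate_cM_per_Mb: float) -> "GeneticMap":
        return cls(
            positions_bp=np.array([1, length_bp]),
            rates_cM_per_Mb=np.array([rate_cM_per_Mb] * 2),
            cumulative_cM=np.array([0.0, (length_bp - 1) * rate_cM_per_Mb / 1e6]),
        )


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive."""

    intervals: pd.DataFrame  # columns: chromosome, start_bp, end_bp, name

    def __post_init__(self) -> None:
        required = {"chromosome", "start_bp", "end_bp", "name"}
        if not required.issubset(self.intervals.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if (self.intervals["start_bp"] > self.intervals["end_bp"]).any():
            raise ValueError("gene interval with start > end")


# ---------------------------------------------------------------------------
# readers


def _read_legend(path: Path) -> list[SiteMeta]:
    sites = []
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 4:
            raise FormatError(f"{path}: legend header needs >=4 columns")
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 columns")
            cM = float(tok[4]) if len(tok) > 4 else 0.0
            sites.append(
                SiteMeta(
                    snp_id=tok[0],
                    chromosome=tok[5] if len(tok) > 5 else "1",
                    position_bp=int(tok[1]),
                    ancestral_allele=tok[2],
                    derived_allele=tok[3],
                    genetic_pos_cM=cM,
                )
            )
    return sites


def _read_hap_legend(hap_path: Path, legend_path: Path) -> HaplotypePanel:
    sites = _read_legend(legend_path)
    rows: list[list[int]] = []
    width = None
    with open(hap_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if width is None:
                width = len(tok)
            elif len(tok) != width:
                raise FormatError(
                    f"{hap_path}:{lineno}: {len(tok)} alleles, expected {width}"
                )
            rows.append([int(t) for t in tok])
    if rows and len(rows) != len(sites):
        raise FormatError(
            f"{hap_path}: {len(rows)} site rows for {len(sites)} legend sites"
        )
    # hap files are site-per-row in IMPUTE convention: transpose
    mat = np.array(rows, dtype=np.int8).T if rows else np.zeros((0, len(sites)), np.int8)
    sample_path = hap_path.with_suffix(".sample")
    sample_ids: list[str] = []
    if sample_path.exists():
        sample_ids = [l.split()[0] for l in sample_path.read_text().splitlines() if l.strip()]
    order = np.argsort([s.position_bp for s in sites], kind="stable")
    sites = [sites[i] for i in order]
    mat = mat[:, order]
    return HaplotypePanel(sites=sites, haplotypes=mat, sample_ids=sample_ids)


def _read_phased_vcf(path: Path) -> HaplotypePanel:
    sites: list[SiteMeta] = []
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            tok = line.split("\t")
            if len(tok) < 10:
                raise FormatError(f"{path}:{lineno}: truncated VCF record")
            chrom, pos, snp_id, ref, alt = tok[0], tok[1], tok[2], tok[3], tok[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                n_skipped += 1
                continue
            fmt = tok[8].split(":")
            if "GT" not in fmt:
                raise FormatError(f"{path}:{lineno}: record without GT field")
            gt_i = fmt.index("GT")
            alleles: list[int] = []
            for cell in tok[9:]:
                gt = cell.split(":")[gt_i]
                if "/" in gt or "." in gt:
                    raise FormatError(
                        f"{path}:{lineno}: unphased or missing genotype {gt!r}"
                    )
                a, _, b = gt.partition("|")
                alleles.extend((int(a), int(b)))
            sites.append(
                SiteMeta(
                    snp_id=snp_id if snp_id != "." else f"{chrom}:{pos}",
                    chromosome=chrom,
                    position_bp=int(pos),
                    ancestral_allele=ref,
                    derived_allele=alt,
                )
            )
            columns.append(np.array(alleles, dtype=np.int8))
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic record(s)", path, n_skipped)
    mat = np.stack(columns, axis=1) if columns else np.zeros((0, 0), np.int8)
    panel = HaplotypePanel(sites=sites, haplotypes=mat, sample_ids=sample_ids)
    panel.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return panel


def read_haplotypes(
    path: str | Path,
    format: str = "impute_hap_legend",
    legend_path: str | Path | None = None,
) -> HaplotypePanel:
    """Read a phased haplotype panel.

    ``format`` is ``impute_hap_legend`` (needs ``legend_path``, defaulting to
    the ``.legend`` sibling of ``path``) or ``phased_vcf``. Non-biallelic VCF
    records are skipped with a logged count; unphased genotypes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "impute_hap_legend":
        legend = Path(legend_path) if legend_path else path.with_suffix(".legend")
        if not legend.exists():
            raise FileNotFoundError(legend)
        return _read_hap_legend(path, legend)
    if format == "phased_vcf":
        return _read_phased_vcf(path)
    raise ValueError(f"unknown haplotype format {format!r}")


def write_haplotypes(
    panel: HaplotypePanel, hap_path: str | Path, legend_path: str | Path | None = None
) -> None:
    """Write IMPUTE-style hap + legend (site-per-row hap file)."""
    hap_path = Path(hap_path)
    legend_path = Path(legend_path) if legend_path else hap_path.with_suffix(".legend")
    with open(legend_path, "w") as fh:
        fh.write("id position a0 a1 cM chrom\n")
        for s in panel.sites:
            fh.write(
                f"{s.snp_id} {s.position_bp} {s.ancestral_allele} "
                f"{s.derived_allele} {s.genetic_pos_cM:.8g} {s.chromosome}\n"
            )
    with open(hap_path, "w") as fh:
        for col in panel.haplotypes.T:
            fh.write(" ".join(str(int(v)) for v in col) + "\n")
    if panel.sample_ids:
        with open(hap_path.with_suffix(".sample"), "w") as fh:
            fh.write("\n".join(panel.sample_ids) + "\n")


def read_genotypes(path: str | Path, labels_path: str | Path) -> GenotypeMatrix:
    """Read a tab-separated dosage matrix plus a two-column (id, population) file.

    The matrix file has one header row of individual ids after the site
    columns ``snp_id chromosome position_bp a0 a1``; entries are 0/1/2 or NA.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["snp_id", "chromosome", "position_bp", "a0", "a1"]
    for c in meta_cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    ind_ids = [c for c in df.columns if c not in meta_cols]
    labels = pd.read_csv(
        labels_path, sep="\t", header=None, names=["id", "population"], dtype=str
    )
    label_map = dict(zip(labels["id"], labels["population"]))
    unlabelled = [i for i in ind_ids if i not in label_map]
    if unlabelled:
        raise ValueError(f"individuals without population label: {unlabelled}")
    sites = [
        SiteMeta(
            snp_id=r.snp_id,
            chromosome=r.chromosome,
            position_bp=int(r.position_bp),
            ancestral_allele=r.a0,
            derived_allele=r.a1,
        )
        for r in df.itertuples()
    ]
    raw = df[ind_ids].to_numpy()  # rows = sites, columns = individuals
    dosages = np.full(raw.shape, MISSING, dtype=np.int8)
    valid = ~pd.isna(raw) & (raw != "NA") & (raw != ".")
    dosages[valid] = raw[valid].astype(np.int8)
    order = sorted(
        range(len(sites)), key=lambda i: (sites[i].chromosome, sites[i].position_bp)
    )
    sites = [sites[i] for i in order]
    dosages = dosages[order].T  # -> individuals x sites
    return GenotypeMatrix(
        sites=sites,
        dosages=dosages,
        individual_ids=ind_ids,
        population_labels=[label_map[i] for i in ind_ids],
    )


def write_genotypes(
    gm: GenotypeMatrix, path: str | Path, labels_path: str | Path
) -> None:
    rows = []
    for j, s in enumerate(gm.sites):
        row = {
            "snp_id": s.snp_id,
            "chromosome": s.chromosome,
            "position_bp": s.position_bp,
            "a0": s.ancestral_allele,
            "a1": s.derived_allele,
        }
        for i, ind in enumerate(gm.individual_ids):
            d = gm.dosages[i, j]
            row[ind] = "NA" if d == MISSING else int(d)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    with open(labels_path, "w") as fh:
        for ind, pop in zip(gm.individual_ids, gm.population_labels):
            fh.write(f"{ind}\t{pop}\n")


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a HapMap-style rate file: position, rate (cM/Mb), cumulative cM."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            try:
                rows.append((int(tok[0]), float(tok[1]), float(tok[2])))
            except (ValueError, IndexError):
                if lineno == 1:  # header line
                    continue
                raise FormatError(f"{path}:{lineno}: bad map row {line.rstrip()!r}")
    if not rows:
        raise FormatError(f"{path}: empty genetic map")
    rows.sort()
    pos, rate, cum = map(np.array, zip(*rows))
    # warn when the cumulative column disagrees with integrating the rates
    recomputed = np.concatenate(
        [[cum[0]], cum[0] + np.cumsum(rate[:-1] * np.diff(pos) / 1e6)]
    )
    if np.abs(recomputed - cum).max() > 1e-6:
        logger.warning(
            "%s: cumulative cM column inconsistent with rate column "
            "(max deviation %.3g cM)", path, float(np.abs(recomputed - cum).max())
        )
    return GeneticMap(positions_bp=pos, rates_cM_per_Mb=rate, cumulative_cM=cum)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\trate_cM_Mb\tcumulative_cM\n")
        for p, r, c in zip(gmap.positions_bp, gmap.rates_cM_per_Mb, gmap.cumulative_cM):
            fh.write(f"{int(p)}\t{r:.8g}\t{c:.10g}\n")


def interpolate_cM(gmap: GeneticMap, position_bp: np.ndarray | int) -> np.ndarray | float:
    """Linear interpolation of cumulative cM; extrapolation at the terminal rate."""
    pos = np.asarray(position_bp, dtype=float)
    cm = np.interp(pos, gmap.positions_bp.astype(float), gmap.cumulative_cM)
    lo, hi = gmap.positions_bp[0], gmap.positions_bp[-1]
    below = pos < lo
    above = pos > hi
    if below.any():
        cm = np.where(
            below,
            gmap.cumulative_cM[0] - (lo - pos) * gmap.rates_cM_per_Mb[0] / 1e6,
            cm,
        )
    if above.any():
        cm = np.where(
            above,
            gmap.cumulative_cM[-1] + (pos - hi) * gmap.rates_cM_per_Mb[-1] / 1e6,
            cm,
        )
    if np.isscalar(position_bp) or np.ndim(position_bp) == 0:
        return float(cm)
    return cm


def read_bed(path: str | Path) -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            tok = line.split()
            if len(tok) < 3:
                raise FormatError(f"{path}:{lineno}: BED row needs >=3 columns")
            name = tok[3] if len(tok) > 3 else f"feature{lineno}"
            rows.append(
                {
                    "chromosome": tok[0],
                    "start_bp": int(tok[1]) + 1,
                    "end_bp": int(tok[2]),
                    "name": name,
                }
            )
    return GeneAnnotation(intervals=pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "name"]))


def write_bed(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ann.intervals.itertuples():
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{r.name}\n")


def classify_intergenic(
    ann: GeneAnnotation,
    sites: Sequence[SiteMeta],
    margin_bp: int = 50_000,
) -> np.ndarray:
    """Flag sites at least ``margin_bp`` from every gene interval.

    A site inside a gene has distance 0; the margin boundary is inclusive
    (a site exactly ``margin_bp`` away counts as intergenic).
    """
    flags = np.ones(len(sites), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in ann.intervals.itertuples():
        by_chrom.setdefault(r.chromosome, []).append((r.start_bp, r.end_bp))
    for i, s in enumerate(sites):
        for start, end in by_chrom.get(s.chromosome, ()):
            if start <= s.position_bp <= end:
                dist = 0
            elif s.position_bp < start:
                dist = start - s.position_bp
            else:
                dist = s.position_bp - end
            if dist < margin_bp:
                flags[i] = False
                break
    return flags
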