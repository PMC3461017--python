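"""From per-SNP tracks to candidate sweep regions.

Significant SNPs are grouped into linkage-disequilibrium clusters (connected
components of the genotype R^2 >= 0.25 graph), clusters are attributed to the
test population when a member SNP has XP-EHH > 3, iHS candidates come from
the top fraction of 50-SNP sliding windows ranked by the share of |iHS| > 2
SNPs, and regions found by two or more metrics are reported as concordant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genomic_io import MISSING, GenotypeMatrix


@dataclass
class LDCluster:
    """Connected component of the thresholded genotype-R^2 graph."""

    snp_ids: list[str]
    chromosome: str
    start_bp: int
    end_bp: int
    max_fst: float = math.nan
    max_abs_ihs: float = math.nan
    max_xpehh: float = math.nan
    n_significant: int = 0
    assigned: bool | None = None

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def genotype_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairwise-complete over individuals with both calls non-missing; requires
    at least three such individuals. Zero variance in either vector gives
    NaN (treated as below any threshold).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 3:
        raise ValueError("need >=3 pairwise-complete individuals")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return math.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_cluster(
    snp_ids: list[str],
    genotypes: GenotypeMatrix,
    r2_min: float = 0.25,
) -> list[LDCluster]:
    """Group candidate SNPs into LD clusters per chromosome.

    Builds, per chromosome, a graph over the candidate SNPs with edges where
    genotype R^2 >= ``r2_min`` and returns its connected components
    (singletons allowed), ordered by leftmost position.
    """
    index = {s.snp_id: j for j, s in enumerate(genotypes.sites)}
    missing = [sid for sid in snp_ids if sid not in index]
    if missing:
        raise KeyError(f"candidate SNPs absent from genotype matrix: {missing[:5]}")
    by_chrom: dict[str, list[str]] = {}
    for sid in snp_ids:
        by_chrom.setdefault(genotypes.sites[index[sid]].chromosome, []).append(sid)
    clusters: list[LDCluster] = []
    for chrom, ids in by_chrom.items():
        g = nx.Graph()
        g.add_nodes_from(ids)
        for i, sid_a in enumerate(ids):
            da = genotypes.dosages[:, index[sid_a]]
            for sid_b in ids[i + 1 :]:
                try:
                    r2 = genotype_r2(da, genotypes.dosages[:, index[sid_b]])
                except ValueError:
                    continue
                if not math.isnan(r2) and r2 >= r2_min:
                    g.add_edge(sid_a, sid_b)
        for comp in nx.connected_components(g):
            members = sorted(comp, key=lambda s: genotypes.sites[index[s]].position_bp)
            positions = [genotypes.sites[index[s]].position_bp for s in members]
            clusters.append(
                LDCluster(
                    snp_ids=members,
                    chromosome=chrom,
                    start_bp=min(positions),
                    end_bp=max(positions),
                )
            )
    clusters.sort(key=lambda c: (c.chromosome, c.start_bp))
    return clusters


def assign_population(
    cluster: LDCluster, xpehh_by_snp: dict[str, float], xpehh_min: float = 3.0
) -> bool | None:
    """Attribute a cluster to the test population when its maximum member
    XP-EHH strictly exceeds ``xpehh_min``; None when no member is scored."""
    scores = [
        xpehh_by_snp[s]
        for s in cluster.snp_ids
        if s in xpehh_by_snp and not math.isnan(xpehh_by_snp[s])
    ]
    if not scores:
        cluster.assigned = None
        return None
    cluster.max_xpehh = max(scores)
    cluster.assigned = cluster.max_xpehh > xpehh_min
    return cluster.assigned


def ihs_window_scan(
    ihs_track: pd.DataFrame,
    window: int = 50,
    score_min: float = 2.0,
    top_fraction: float = 0.0002,
    denominator: str = "all",
) -> tuple[pd.DataFrame, list[str]]:
    """Rank 50-SNP sliding windows by their share of |iHS| > ``score_min`` SNPs.

    Windows slide one SNP at a time within each chromosome. Non-overlapping
    windows are chosen greedily in descending score order (ties to the
    smaller start) until ceil(top_fraction * n) are selected, where n counts
    all scored windows (``denominator='all'``) or only the non-overlapping
    ones that greedy selection could make (``denominator='nonoverlapping'``).
    Returns the selected windows and the |iHS| > ``score_min`` SNP ids inside
    them. Chromosomes with fewer than ``window`` SNPs are skipped.
    """
    track = ihs_track.sort_values(["chromosome", "position_bp"], kind="stable")
    all_windows = []
    for chrom, sub in track.groupby("chromosome", sort=True):
        if len(sub) < window:
            continue
        hits = (sub["ihs_std"].abs() > score_min).to_numpy()
        csum = np.concatenate([[0], np.cumsum(hits)])
        n_win = len(sub) - window + 1
        counts = csum[window:] - csum[:-window]
        pos = sub["position_bp"].to_numpy()
        ids = sub["snp_id"].to_numpy()
        for w in range(n_win):
            all_windows.append(
                {
                    "chromosome": chrom,
                    "start_index": w,
                    "start_bp": int(pos[w]),
                    "end_bp": int(pos[w + window - 1]),
                    "fraction": counts[w] / window,
                    "n_hits": int(counts[w]),
                    "_ids": ids[w : w + window][hits[w : w + window]],
                }
            )
    if not all_windows:
        return pd.DataFrame(
            columns=["chromosome", "start_index", "start_bp", "end_bp", "fraction", "n_hits"]
        ), []
    windows = pd.DataFrame(all_windows)
    order = windows.sort_values(
        ["fraction", "chromosome", "start_index"],
        ascending=[False, True, True],
        kind="stable",
    ).index
    chosen: list[int] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for i in order:
        row = windows.loc[i]
        span = (row["start_index"], row["start_index"] + window - 1)
        if any(
            not (span[1] < s or span[0] > e)
            for s, e in occupied.get(row["chromosome"], [])
        ):
            continue
        chosen.append(i)
        occupied.setdefault(row["chromosome"], []).append(span)
    if denominator == "all":
        n_total = len(windows)
    elif denominator == "nonoverlapping":
        n_total = len(chosen)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    n_keep = math.ceil(top_fraction * n_total)
    keep = chosen[:n_keep]
    selected = windows.loc[keep].copy()
    snp_ids = sorted({sid for lst in selected["_ids"] for sid in lst})
    selected = selected.drop(columns="_ids").reset_index(drop=True)
    return selected, snp_ids


def clusters_to_regions(clusters: list[LDCluster], metric: str) -> pd.DataFrame:
    """Tabulate LD clusters as regions attributed to one metric."""
    rows = [
        {
            "chromosome": c.chromosome,
            "start_bp": c.start_bp,
            "end_bp": c.end_bp,
            "metrics": frozenset([metric]),
            "n_snps": c.size,
            "max_fst": c.max_fst,
            "max_abs_ihs": c.max_abs_ihs,
            "max_xpehh": c.max_xpehh,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start_bp", "end_bp", "metrics",
            "n_snps", "max_fst", "max_abs_ihs", "max_xpehh",
        ],
    )


def merge_overlapping(regions: pd.DataFrame) -> pd.DataFrame:
    """Transitive union of bp-overlapping regions on the same chromosome.

    Metric sets are unioned and SNP counts summed; per-metric maxima are
    taken over the merged members. Idempotent.
    """
    if regions.empty:
        return regions.copy()
    out = []
    for chrom, sub in regions.groupby("chromosome", sort=True):
        sub = sub.sort_values(["start_bp", "end_bp"], kind="stable")
        current = None
        for row in sub.to_dict("records"):
            if current is None or row["start_bp"] > current["end_bp"]:
                if current is not None:
                    out.append(current)
                current = dict(row)
                current["metrics"] = frozenset(row.get("metrics", frozenset()))
            else:
                current["end_bp"] = max(current["end_bp"], row["end_bp"])
                current["metrics"] = current["metrics"] | frozenset(
                    row.get("metrics", frozenset())
                )
                current["n_snps"] = current.get("n_snps", 0) + row.get("n_snps", 0)
                for col in ("max_fst", "max_abs_ihs", "max_xpehh"):
                    if col in row:
                        vals = [
                            v for v in (current.get(col), row[col])
                            if v is not None and v == v
                        ]
                        current[col] = max(vals) if vals else math.nan
        if current is not None:
            out.append(current)
    return pd.DataFrame(out, columns=regions.columns).reset_index(drop=True)


def concordant_regions(
    regions_by_metric: dict[str, pd.DataFrame], min_methods: int = 2
) -> pd.DataFrame:
    """Genomic intervals covered by regions of at least ``min_methods`` metrics.

    An interval-sweep over region endpoints finds every maximal segment where
    the number of distinct covering metrics reaches the threshold; adjacent
    qualifying segments are merged. Each emitted region carries the union of
    contributing metric sets and per-metric SNP counts summed over the
    overlapping source regions.
    """
    events: dict[str, list[tuple[int, int, str, int]]] = {}
    for metric, df in regions_by_metric.items():
        if df is None or df.empty:
            continue
        for row in df.itertuples():
            events.setdefault(row.chromosome, []).append(
                (int(row.start_bp), int(row.end_bp), metric, int(getattr(row, "n_snps", 0)))
            )
    out = []
    for chrom, ivals in sorted(events.items()):
        points = sorted({p for s, e, _, _ in ivals for p in (s, e + 1)})
        qualifying: list[tuple[int, int, frozenset]] = []
        for lo, hi in zip(points[:-1], points[1:]):
            cover = {m for s, e, m, _ in ivals if s <= lo and hi - 1 <= e}
            if len(cover) >= min_methods:
                qualifying.append((lo, hi - 1, frozenset(cover)))
        # merge adjacent/overlapping qualifying segments
        merged: list[list] = []
        for lo, hi, cover in qualifying:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = hi
                merged[-1][2] = merged[-1][2] | cover
            else:
                merged.append([lo, hi, cover])
        for lo, hi, cover in merged:
            counts = {
                m: sum(
                    n for s, e, mm, n in ivals
                    if mm == m and not (e < lo or s > hi)
                )
                for m in sorted(cover)
            }
            out.append(
                {
                    "chromosome": chrom,
                    "start_bp": lo,
                    "end_bp": hi,
                    "metrics": frozenset(cover),
                    "snp_counts": counts,
                }
            )
    return pd.DataFrame(
        out, columns=["chromosome", "start_bp", "end_bp", "metrics", "snp_counts"]
    )
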