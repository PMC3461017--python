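"""Extended haplotype homozygosity statistics: EHH, iHS and XP-EHH.

EHH(x) at a core SNP is the probability that two randomly drawn haplotypes
carrying the core allele are identical at every site between the core and
genetic distance x. iHH integrates EHH over cM (trapezoid, truncated where
EHH drops below a cutoff); iHS is ln(iHH_ancestral / iHH_derived),
standardized to zero mean / unit variance within derived-allele-frequency
bins. XP-EHH compares pooled (site-level) iHH between a test and a reference
population at the same core, standardized genome-wide with Gaussian
two-tailed p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import HaplotypePanel

logger = logging.getLogger(__name__)

ANCESTRAL, DERIVED, POOLED = "ancestral", "derived", "pooled"


class UndefinedEHHError(ValueError):
    """EHH profile undefined (fewer than two carrier haplotypes)."""


class UnboundedEHHError(ValueError):
    """EHH did not decay below the cutoff before the chromosome end."""


@dataclass
class EHHProfile:
    """EHH decay away from a core site, separately leftward and rightward.

    Each side stores genetic distances from the core (ascending, starting at
    0) and the EHH value at each traversed site. For the ancestral/derived
    classes EHH at the core is 1; for the pooled class it is the core-site
    homozygosity (pairs must also match at the core itself).
    """

    core_index: int
    allele_class: str
    n_carriers: int
    left_distances: np.ndarray = field(default_factory=lambda: np.zeros(1))
    left_ehh: np.ndarray = field(default_factory=lambda: np.ones(1))
    right_distances: np.ndarray = field(default_factory=lambda: np.zeros(1))
    right_ehh: np.ndarray = field(default_factory=lambda: np.ones(1))

    def side(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        if which == "left":
            return self.left_distances, self.left_ehh
        return self.right_distances, self.right_ehh


def _ehh_one_side(
    hap: np.ndarray,
    carriers: np.ndarray,
    init_labels: np.ndarray,
    core_index: int,
    step: int,
    cms: np.ndarray,
    stop_below: float | None,
    max_steps: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Walk outward from the core refining the identity partition.

    Haplotypes whose identity class shrinks to a singleton can never pair
    again and are dropped from the working set; the pair denominator stays
    the full carrier count.
    """
    n0 = carriers.size
    denom = n0 * (n0 - 1)
    labels = init_labels.copy()
    active = carriers.copy()
    _, labels, counts = np.unique(labels, return_inverse=True, return_counts=True)
    keep = counts[labels] >= 2
    active, labels = active[keep], labels[keep]
    dists = [0.0]
    ehh = [float((counts * (counts - 1)).sum() / denom)]
    core_cm = cms[core_index]
    n_sites = hap.shape[1]
    j = core_index + step
    steps = 0
    while 0 <= j < n_sites and active.size:
        if max_steps is not None and steps >= max_steps:
            break
        # refine: pairs stay identical only if they also match at site j
        combined = labels * 2 + hap[active, j]
        _, labels, counts = np.unique(combined, return_inverse=True, return_counts=True)
        keep = counts[labels] >= 2
        active, labels = active[keep], labels[keep]
        dists.append(abs(cms[j] - core_cm))
        ehh.append(float((counts[counts >= 2] * (counts[counts >= 2] - 1)).sum() / denom))
        steps += 1
        if stop_below is not None and ehh[-1] < stop_below:
            break
        if ehh[-1] == 0.0:
            break
        j += step
    return np.asarray(dists), np.asarray(ehh)


def ehh_profile(
    panel: HaplotypePanel,
    core_index: int,
    allele_class: str = DERIVED,
    stop_below: float | None = None,
    max_steps_left: int | None = None,
    max_steps_right: int | None = None,
) -> EHHProfile:
    """Compute the EHH decay profile around a core SNP.

    ``stop_below`` truncates the walk once EHH falls under that value (used
    when only the integral down to a cutoff is needed); ``max_steps_*`` cap
    the number of sites traversed per side.
    """
    hap = panel.haplotypes
    core_alleles = hap[:, core_index]
    if allele_class == ANCESTRAL:
        carriers = np.flatnonzero(core_alleles == 0)
        init = np.zeros(carriers.size, dtype=np.int64)
    elif allele_class == DERIVED:
        carriers = np.flatnonzero(core_alleles == 1)
        init = np.zeros(carriers.size, dtype=np.int64)
    elif allele_class == POOLED:
        carriers = np.arange(hap.shape[0])
        init = core_alleles.astype(np.int64)
    else:
        raise ValueError(f"unknown allele class {allele_class!r}")
    if carriers.size < 2:
        raise UndefinedEHHError(
            f"site {core_index}: {carriers.size} carrier(s) of {allele_class} allele"
        )
    cms = panel.positions_cM
    ld, le = _ehh_one_side(hap, carriers, init, core_index, -1, cms, stop_below, max_steps_left)
    rd, re = _ehh_one_side(hap, carriers, init, core_index, +1, cms, stop_below, max_steps_right)
    return EHHProfile(
        core_index=core_index,
        allele_class=allele_class,
        n_carriers=int(carriers.size),
        left_distances=ld,
        left_ehh=le,
        right_distances=rd,
        right_ehh=re,
    )


def _truncate_side(
    dists: np.ndarray, ehh: np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Cut a one-sided profile at the interpolated EHH = cutoff crossing.

    Returns (distances, ehh, crossed). When EHH never drops below the cutoff
    the profile is returned unchanged with crossed = False.
    """
    below = np.flatnonzero(ehh < cutoff)
    if below.size == 0:
        return dists, ehh, False
    i = int(below[0])
    if i == 0:  # already below cutoff at the core
        return dists[:1], ehh[:1], True
    frac = (ehh[i - 1] - cutoff) / (ehh[i - 1] - ehh[i])
    d_star = dists[i - 1] + frac * (dists[i] - dists[i - 1])
    return (
        np.concatenate([dists[:i], [d_star]]),
        np.concatenate([ehh[:i], [cutoff]]),
        True,
    )


def integrate_ihh(profile: EHHProfile, cutoff: float = 0.05) -> float:
    """Trapezoidal integral of EHH over cM, both sides summed.

    Each side is truncated at the first EHH < cutoff crossing (linearly
    interpolated). Raises :class:`UnboundedEHHError` when either side never
    crosses before the chromosome end.
    """
    total = 0.0
    for which in ("left", "right"):
        dists, ehh, crossed = _truncate_side(*profile.side(which), cutoff)
        if not crossed:
            raise UnboundedEHHError(
                f"core {profile.core_index} ({profile.allele_class}): EHH still "
                f">= {cutoff} at the {which} chromosome end"
            )
        total += float(np.trapezoid(ehh, dists))
    return total


def ihs_raw(
    panel: HaplotypePanel,
    core_index: int,
    cutoff: float = 0.05,
    maf: float = 0.10,
) -> dict:
    """Unstandardized iHS at one core: ln(iHH_ancestral / iHH_derived).

    Returns a record dict; ``ihs_raw`` is NaN (with ``flag`` set) for cores
    failing the MAF bound, lacking carriers, or with unbounded EHH.
    """
    daf = float(panel.haplotypes[:, core_index].mean())
    rec = {
        "snp_id": panel.sites[core_index].snp_id,
        "chromosome": panel.sites[core_index].chromosome,
        "position_bp": panel.sites[core_index].position_bp,
        "daf": daf,
        "ihh_a": math.nan,
        "ihh_d": math.nan,
        "ihs_raw": math.nan,
        "flag": "",
    }
    if not (maf <= daf <= 1 - maf):
        rec["flag"] = "maf"
        return rec
    try:
        prof_a = ehh_profile(panel, core_index, ANCESTRAL, stop_below=cutoff)
        prof_d = ehh_profile(panel, core_index, DERIVED, stop_below=cutoff)
        ihh_a = integrate_ihh(prof_a, cutoff)
        ihh_d = integrate_ihh(prof_d, cutoff)
    except UndefinedEHHError:
        rec["flag"] = "carriers"
        return rec
    except UnboundedEHHError:
        rec["flag"] = "unbounded"
        return rec
    if ihh_a <= 0 or ihh_d <= 0:
        rec["flag"] = "zero_integral"
        return rec
    rec.update(ihh_a=ihh_a, ihh_d=ihh_d, ihs_raw=math.log(ihh_a / ihh_d))
    return rec


def _side_profile_from_mismatch(
    first_mm: np.ndarray, mask: np.ndarray, denom: float, c: int,
    cms: np.ndarray, side: str,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided EHH profile from first-mismatch positions of selected pairs."""
    m = first_mm[mask]
    n_sites = cms.size
    if side == "right":
        sites = np.arange(c, n_sites)
        hist = np.bincount(m, minlength=n_sites + 1)
        surv = m.size - np.cumsum(hist)[sites]
        surv[0] = m.size  # the core itself
        dists = cms[sites] - cms[c]
    else:
        sites = np.arange(c, -1, -1)
        hist = np.bincount(m + 1, minlength=n_sites + 2)
        cum = np.cumsum(hist)
        surv = cum[sites]  # pairs with first mismatch < s
        surv[0] = m.size
        dists = cms[c] - cms[sites]
    return dists, surv.astype(float) / denom


def ihs_scan(
    panel: HaplotypePanel, cutoff: float = 0.05, maf: float = 0.10
) -> pd.DataFrame:
    """Raw iHS for every site of a panel (one row per SNP).

    Computes the same quantities as calling :func:`ihs_raw` per site but via
    the pair-based engine, which shares the first-mismatch recurrence across
    cores.
    """
    n = panel.n_haplotypes
    n_sites = panel.n_sites
    cms = panel.positions_cM
    hap_cols = np.ascontiguousarray(panel.haplotypes.T)
    pair_i, pair_j = np.triu_indices(n, k=1)
    dafs = panel.haplotypes.mean(axis=0)

    ihh = {("left", 0): {}, ("left", 1): {}, ("right", 0): {}, ("right", 1): {}}
    flags: dict[int, str] = {}
    derived_counts = panel.haplotypes.sum(axis=0)
    scored_set = set()
    for c in range(n_sites):
        if not (maf <= dafs[c] <= 1 - maf):
            continue
        if min(derived_counts[c], n - derived_counts[c]) < 2:
            flags[c] = "carriers"
        scored_set.add(c)
    for side, order, step in (("right", range(n_sites - 1, -1, -1), 1),
                              ("left", range(n_sites), -1)):
        sentinel = n_sites if side == "right" else -1
        first_mm = np.full(pair_i.size, sentinel, dtype=np.int32)
        for c in order:
            nb = c + step
            if 0 <= nb < n_sites:
                col = hap_cols[nb]
                np.copyto(first_mm, np.int32(nb), where=col[pair_i] != col[pair_j])
            if c not in scored_set or flags.get(c):
                continue
            alleles = hap_cols[c]
            for a in (0, 1):
                mask = (alleles[pair_i] == a) & (alleles[pair_j] == a)
                k = int((alleles == a).sum())
                denom = k * (k - 1) / 2
                dists, ehh_vals = _side_profile_from_mismatch(
                    first_mm, mask, denom, c, cms, side
                )
                d, e, crossed = _truncate_side(dists, ehh_vals, cutoff)
                if not crossed:
                    flags[c] = "unbounded"
                    break
                ihh[(side, a)][c] = float(np.trapezoid(e, d))

    records = []
    for c in range(n_sites):
        site = panel.sites[c]
        rec = {
            "snp_id": site.snp_id,
            "chromosome": site.chromosome,
            "position_bp": site.position_bp,
            "daf": float(dafs[c]),
            "ihh_a": math.nan,
            "ihh_d": math.nan,
            "ihs_raw": math.nan,
            "flag": "",
        }
        if c not in scored_set:
            rec["flag"] = "maf"
        elif c in flags:
            rec["flag"] = flags[c]
        else:
            ihh_a = ihh[("left", 0)].get(c, math.nan) + ihh[("right", 0)].get(c, math.nan)
            ihh_d = ihh[("left", 1)].get(c, math.nan) + ihh[("right", 1)].get(c, math.nan)
            if not (ihh_a > 0 and ihh_d > 0):
                rec["flag"] = "zero_integral"
            else:
                rec.update(ihh_a=ihh_a, ihh_d=ihh_d, ihs_raw=math.log(ihh_a / ihh_d))
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    n_dropped = (df["flag"] == "unbounded").sum()
    if n_dropped:
        logger.info("iHS: %d core(s) dropped with unbounded EHH", n_dropped)
    return df


def standardize_ihs(
    records: pd.DataFrame, n_bins: int = 20, maf: float = 0.10
) -> pd.DataFrame:
    """Standardize raw iHS within equal-width derived-allele-frequency bins.

    Bins partition [maf, 1 - maf]; within each occupied bin the raw scores
    are centred and scaled to unit variance. Bins with fewer than two scored
    records leave their records unstandardized (NaN, flagged).
    """
    df = records.copy()
    edges = np.linspace(maf, 1 - maf, n_bins + 1)
    ok = df["ihs_raw"].notna()
    bin_idx = np.clip(np.searchsorted(edges, df["daf"], side="right") - 1, 0, n_bins - 1)
    df["daf_bin"] = np.where(ok, bin_idx, -1)
    df["ihs_std"] = np.nan
    for b in range(n_bins):
        mask = ok & (df["daf_bin"] == b)
        vals = df.loc[mask, "ihs_raw"]
        if len(vals) < 2 or vals.std(ddof=0) == 0:
            if len(vals):
                df.loc[mask, "flag"] = df.loc[mask, "flag"].where(
                    df.loc[mask, "flag"] != "", "unstandardized"
                )
            continue
        df.loc[mask, "ihs_std"] = (vals - vals.mean()) / vals.std(ddof=0)
    return df


def _combine_panels(
    panel_test: HaplotypePanel, panel_ref: HaplotypePanel
) -> HaplotypePanel:
    if panel_test.n_sites != panel_ref.n_sites:
        raise ValueError("test and reference panels must share the same sites")
    return HaplotypePanel(
        sites=panel_test.sites,
        haplotypes=np.vstack([panel_test.haplotypes, panel_ref.haplotypes]),
        allow_odd=True,
    )


def xpehh(
    panel_test: HaplotypePanel,
    panel_ref: HaplotypePanel,
    core_index: int,
    cutoff: float = 0.05,
    allele_class: str = POOLED,
    _combined: HaplotypePanel | None = None,
) -> dict:
    """Raw XP-EHH at one core: ln(iHH_test / iHH_ref).

    Site-level (pooled) EHH by default. A common truncation distance per
    side is taken from the EHH = cutoff crossing of the pooled
    two-population profile, so both integrals cover the same interval; when
    that profile never crosses before a chromosome end the integrals are
    truncated there and the record flagged ``edge``. Positive values mean
    the test population carries the longer-range haplotypes.
    """
    combined = _combined if _combined is not None else _combine_panels(panel_test, panel_ref)
    site = panel_test.sites[core_index]
    rec = {
        "snp_id": site.snp_id,
        "chromosome": site.chromosome,
        "position_bp": site.position_bp,
        "ihh_test": math.nan,
        "ihh_ref": math.nan,
        "xpehh_raw": math.nan,
        "flag": "",
    }
    try:
        prof_c = ehh_profile(combined, core_index, allele_class, stop_below=cutoff)
    except UndefinedEHHError:
        rec["flag"] = "carriers"
        return rec
    edge = False
    ihh = {"test": 0.0, "ref": 0.0}
    for which in ("left", "right"):
        dists_c, ehh_c, crossed = _truncate_side(*prof_c.side(which), cutoff)
        if not crossed:
            edge = True
        d_star = dists_c[-1]
        n_steps = len(prof_c.side(which)[0]) - 1  # sites traversed by the pooled walk
        kw = {f"max_steps_{which}": n_steps}
        for name, panel in (("test", panel_test), ("ref", panel_ref)):
            try:
                prof = ehh_profile(panel, core_index, allele_class, **kw)
            except UndefinedEHHError:
                rec["flag"] = "carriers"
                return rec
            d, e = prof.side(which)
            ihh[name] += _integral_to(d, e, d_star)
    if ihh["test"] <= 0 or ihh["ref"] <= 0:
        rec["flag"] = "zero_integral"
        return rec
    rec.update(
        ihh_test=ihh["test"],
        ihh_ref=ihh["ref"],
        xpehh_raw=math.log(ihh["test"] / ihh["ref"]),
        flag="edge" if edge else "",
    )
    return rec


def _integral_to(dists: np.ndarray, ehh: np.ndarray, d_star: float) -> float:
    """Trapezoid integral of a one-sided profile from 0 to distance d_star."""
    if d_star <= 0:
        return 0.0
    inside = dists <= d_star
    d, e = dists[inside], ehh[inside]
    if d[-1] < d_star and inside.sum() < dists.size:
        i = int(inside.sum())  # first point beyond d_star
        frac = (d_star - dists[i - 1]) / (dists[i] - dists[i - 1])
        e_star = ehh[i - 1] + frac * (ehh[i] - ehh[i - 1])
        d = np.concatenate([d, [d_star]])
        e = np.concatenate([e, [e_star]])
    return float(np.trapezoid(e, d))


def xpehh_scan(
    panel_test: HaplotypePanel,
    panel_ref: HaplotypePanel,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Raw XP-EHH for every shared site (one row per SNP).

    Same quantities as calling :func:`xpehh` per site, via the shared
    first-mismatch recurrence: one pass over the pooled two-population pair
    set yields, per core, the common truncation distance and both
    populations' integrals.
    """
    combined = _combine_panels(panel_test, panel_ref)
    n_t = panel_test.n_haplotypes
    n_r = panel_ref.n_haplotypes
    n_all = n_t + n_r
    n_sites = combined.n_sites
    cms = panel_test.positions_cM
    hap_cols = np.ascontiguousarray(combined.haplotypes.T)
    pair_i, pair_j = np.triu_indices(n_all, k=1)
    both_test = (pair_i < n_t) & (pair_j < n_t)
    both_ref = (pair_i >= n_t) & (pair_j >= n_t)
    denom_all = n_all * (n_all - 1) / 2
    denom_t = n_t * (n_t - 1) / 2
    denom_r = n_r * (n_r - 1) / 2

    ihh_t = np.zeros(n_sites)
    ihh_r = np.zeros(n_sites)
    edge = np.zeros(n_sites, dtype=bool)
    for side, order, step in (("right", range(n_sites - 1, -1, -1), 1),
                              ("left", range(n_sites), -1)):
        sentinel = n_sites if side == "right" else -1
        first_mm = np.full(pair_i.size, sentinel, dtype=np.int32)
        for c in order:
            nb = c + step
            if 0 <= nb < n_sites:
                col = hap_cols[nb]
                np.copyto(first_mm, np.int32(nb), where=col[pair_i] != col[pair_j])
            alleles = hap_cols[c]
            same_allele = alleles[pair_i] == alleles[pair_j]
            dists, ehh_pool = _side_profile_from_mismatch(
                first_mm, same_allele, denom_all, c, cms, side
            )
            # pooled EHH at the core is the core-site homozygosity
            ehh_pool[0] = same_allele.sum() / denom_all
            dp, ep, crossed = _truncate_side(dists, ehh_pool, cutoff)
            if not crossed:
                edge[c] = True
            d_star = dp[-1]
            for mask, denom, acc in (
                (same_allele & both_test, denom_t, ihh_t),
                (same_allele & both_ref, denom_r, ihh_r),
            ):
                d, e = _side_profile_from_mismatch(first_mm, mask, denom, c, cms, side)
                acc[c] += _integral_to(d, e, d_star)

    records = []
    for c in range(n_sites):
        site = panel_test.sites[c]
        rec = {
            "snp_id": site.snp_id,
            "chromosome": site.chromosome,
            "position_bp": site.position_bp,
            "ihh_test": math.nan,
            "ihh_ref": math.nan,
            "xpehh_raw": math.nan,
            "flag": "edge" if edge[c] else "",
        }
        if ihh_t[c] > 0 and ihh_r[c] > 0:
            rec.update(
                ihh_test=float(ihh_t[c]),
                ihh_ref=float(ihh_r[c]),
                xpehh_raw=math.log(ihh_t[c] / ihh_r[c]),
            )
        else:
            rec["flag"] = "zero_integral"
        records.append(rec)
    return pd.DataFrame.from_records(records)


def normalize_xpehh(records: pd.DataFrame) -> pd.DataFrame:
    """Standardize raw XP-EHH genome-wide and attach two-tailed Gaussian p-values."""
    df = records.copy()
    ok = df["xpehh_raw"].notna()
    if ok.sum() < 30:
        raise ValueError("need >=30 scored records to fit the null Gaussian")
    vals = df.loc[ok, "xpehh_raw"]
    mu, sd = vals.mean(), vals.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate XP-EHH distribution (zero variance)")
    df["xpehh_norm"] = (df["xpehh_raw"] - mu) / sd
    df["p_value"] = 2 * stats.norm.sf(np.abs(df["xpehh_norm"]))
    return df


def xpehh_threshold(m: int, alpha: float = 0.05) -> float:
    """Normalized-score threshold for Bonferroni two-tailed significance.

    Solves 2 * (1 - Phi(z)) = alpha / m for z under a standard normal.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(stats.norm.isf(alpha / (2 * m)))
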