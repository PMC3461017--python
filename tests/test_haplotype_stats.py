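import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    HaplotypePanel,
    ehh_profile,
    ihs_raw,
    ihs_scan,
    integrate_ihh,
    normalize_xpehh,
    standardize_ihs,
    xpehh,
    xpehh_scan,
    xpehh_threshold,
)
from sweepscan.haplotype_stats import (
    EHHProfile,
    UnboundedEHHError,
    UndefinedEHHError,
)

from conftest import make_sites, random_panel


def brute_force_ehh(hap, carriers, core, target):
    """All-pairs identity count over the inclusive site span [core..target]."""
    lo, hi = min(core, target), max(core, target)
    idx = [s for s in range(lo, hi + 1) if s != core]
    same = 0
    for a, b in itertools.combinations(carriers, 2):
        if all(hap[a, s] == hap[b, s] for s in idx):
            same += 1
    n = len(carriers)
    return same / (n * (n - 1) / 2)


class TestEHHProfile:
    def test_identical_carriers_stay_at_one(self):
        hap = np.vstack([np.ones(6, dtype=np.int8)] * 4)
        panel = HaplotypePanel(sites=make_sites(6), haplotypes=hap)
        prof = ehh_profile(panel, 3, "derived")
        assert (prof.left_ehh == 1.0).all() and (prof.right_ehh == 1.0).all()

    def test_partition_2_1_1_gives_one_sixth(self):
        hap = np.array([[1, 0], [1, 0], [1, 1], [0, 1]], dtype=np.int8)
        hap = np.array([[1, 0, 0], [1, 0, 0], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        panel = HaplotypePanel(sites=make_sites(3), haplotypes=hap)
        prof = ehh_profile(panel, 0, "derived")
        assert prof.right_ehh[2] == pytest.approx(1 / 6)

    def test_core_value_is_one_for_allele_classes(self, rng):
        panel = random_panel(rng, n_hap=10, n_sites=8)
        for ac in ("ancestral", "derived"):
            try:
                prof = ehh_profile(panel, 4, ac)
            except UndefinedEHHError:
                continue
            assert prof.left_ehh[0] == 1.0 and prof.right_ehh[0] == 1.0

    def test_fewer_than_two_carriers_raises(self):
        hap = np.zeros((4, 3), dtype=np.int8)
        hap[0, 1] = 1
        panel = HaplotypePanel(sites=make_sites(3), haplotypes=hap)
        with pytest.raises(UndefinedEHHError):
            ehh_profile(panel, 1, "derived")

    def test_monotone_nonincreasing(self, rng):
        for _ in range(20):
            panel = random_panel(rng)
            core = int(rng.integers(0, panel.n_sites))
            for ac in ("ancestral", "derived", "pooled"):
                try:
                    prof = ehh_profile(panel, core, ac)
                except UndefinedEHHError:
                    continue
                assert (np.diff(prof.left_ehh) <= 1e-12).all()
                assert (np.diff(prof.right_ehh) <= 1e-12).all()

    def test_matches_all_pairs_brute_force(self, rng):
        """EHH equals a direct all-pairs identity count at every site."""
        for _ in range(40):
            panel = random_panel(rng, n_hap=2 * int(rng.integers(2, 9)))
            hap = panel.haplotypes
            core = int(rng.integers(0, panel.n_sites))
            for ac, val in (("ancestral", 0), ("derived", 1)):
                carriers = np.flatnonzero(hap[:, core] == val)
                if carriers.size < 2:
                    continue
                prof = ehh_profile(panel, core, ac)
                # the walk stops once EHH reaches 0 (it can never recover)
                for k in range(len(prof.right_ehh)):
                    assert prof.right_ehh[k] == pytest.approx(
                        brute_force_ehh(hap, carriers, core, core + k), abs=1e-12
                    )
                if len(prof.right_ehh) < panel.n_sites - core:
                    assert prof.right_ehh[-1] == 0.0
                for k in range(len(prof.left_ehh)):
                    assert prof.left_ehh[k] == pytest.approx(
                        brute_force_ehh(hap, carriers, core, core - k), abs=1e-12
                    )
                if len(prof.left_ehh) < core + 1:
                    assert prof.left_ehh[-1] == 0.0


class TestIntegrateIHH:
    def test_rectangle_profile(self):
        prof = EHHProfile(
            0, "derived", 4,
            left_distances=np.array([0.0, 0.1, 0.1001]),
            left_ehh=np.array([1.0, 1.0, 0.0]),
            right_distances=np.array([0.0, 0.1, 0.1001]),
            right_ehh=np.array([1.0, 1.0, 0.0]),
        )
        assert integrate_ihh(prof) == pytest.approx(0.2, rel=1e-3)

    def test_piecewise_linear_hand_trapezoid(self):
        # right side: 1 @0, 0.5 @0.1, 0.04 @0.2; crossing at 0.1 + 0.45/0.46*0.1
        prof = EHHProfile(
            0, "derived", 4,
            left_distances=np.array([0.0, 0.05]),
            left_ehh=np.array([1.0, 0.0]),
            right_distances=np.array([0.0, 0.1, 0.2]),
            right_ehh=np.array([1.0, 0.5, 0.04]),
        )
        d_star = 0.1 + (0.45 / 0.46) * 0.1
        right = 0.1 * 0.75 + (d_star - 0.1) * (0.5 + 0.05) / 2
        left = 0.5 * (1.0 + 0.05) * (0.05 * 0.95)  # crossing at 0.0475
        assert integrate_ihh(prof) == pytest.approx(left + right, rel=1e-9)

    def test_unbounded_side_raises(self):
        prof = EHHProfile(
            0, "derived", 4,
            left_distances=np.array([0.0, 0.1]),
            left_ehh=np.array([1.0, 0.5]),
            right_distances=np.array([0.0, 0.1]),
            right_ehh=np.array([1.0, 0.01]),
        )
        with pytest.raises(UnboundedEHHError):
            integrate_ihh(prof)

    def test_symmetric_profiles_give_equal_integrals(self):
        d = np.array([0.0, 0.05, 0.12])
        e = np.array([1.0, 0.4, 0.01])
        p1 = EHHProfile(0, "ancestral", 4, d, e, d, e)
        p2 = EHHProfile(0, "derived", 4, d, e, d, e)
        assert integrate_ihh(p1) == integrate_ihh(p2)


def brute_force_ihs(panel, core, cutoff=0.05):
    """Independent iHS: explicit pair loops + trapezoid with interpolation."""
    hap = panel.haplotypes
    cms = panel.positions_cM
    out = {}
    for name, val in (("A", 0), ("D", 1)):
        carriers = np.flatnonzero(hap[:, core] == val)
        if carriers.size < 2:
            return None
        total = 0.0
        for step in (-1, 1):
            ds, es = [0.0], [1.0]
            s = core + step
            while 0 <= s < panel.n_sites:
                ds.append(abs(cms[s] - cms[core]))
                es.append(brute_force_ehh(hap, carriers, core, s))
                s += step
            crossing = None
            for k in range(1, len(es)):
                if es[k] < cutoff:
                    frac = (es[k - 1] - cutoff) / (es[k - 1] - es[k])
                    crossing = k
                    d_star = ds[k - 1] + frac * (ds[k] - ds[k - 1])
                    break
            if crossing is None:
                return None
            xs = ds[:crossing] + [d_star]
            ys = es[:crossing] + [cutoff]
            total += sum(
                (xs[i + 1] - xs[i]) * (ys[i + 1] + ys[i]) / 2 for i in range(len(xs) - 1)
            )
        out[name] = total
    return math.log(out["A"] / out["D"])


class TestIHS:
    def test_symmetric_classes_give_zero(self):
        # ancestral and derived carrier pairs diverge at mirror-image sites,
        # so iHH_A = iHH_D and the log-ratio is exactly 0
        hap = np.array(
            [
                [0, 0, 1, 0, 0],
                [1, 0, 1, 0, 1],
                [0, 1, 0, 1, 0],
                [1, 1, 0, 1, 1],
            ],
            dtype=np.int8,
        )
        panel = HaplotypePanel(sites=make_sites(5, cm_per_site=0.2), haplotypes=hap)
        rec = ihs_raw(panel, 2, maf=0.0)
        assert rec["flag"] == ""
        assert rec["ihh_a"] == pytest.approx(rec["ihh_d"], abs=1e-12)
        assert rec["ihs_raw"] == pytest.approx(0.0, abs=1e-12)

    def test_maf_bound_excludes_rare_cores(self, rng):
        hap = np.zeros((20, 5), dtype=np.int8)
        hap[0, 2] = 1  # DAF 0.05 < 0.10
        panel = HaplotypePanel(sites=make_sites(5), haplotypes=hap)
        rec = ihs_raw(panel, 2)
        assert rec["flag"] == "maf"

    def test_matches_brute_force_oracle(self, rng):
        checked = 0
        for _ in range(40):
            panel = random_panel(rng, n_hap=8, n_sites=10)
            core = int(rng.integers(2, 8))
            expected = brute_force_ihs(panel, core)
            rec = ihs_raw(panel, core, maf=0.0)
            if expected is None:
                # the oracle bails at the first excluded class; the scan may
                # record a different (equally excluding) reason
                assert rec["flag"] in ("unbounded", "carriers")
            elif rec["flag"] == "":
                assert rec["ihs_raw"] == pytest.approx(expected, abs=1e-10)
                checked += 1
        assert checked >= 5

    def test_scan_matches_per_core_reference(self, rng):
        for _ in range(10):
            panel = random_panel(rng, n_hap=12, n_sites=15)
            fast = ihs_scan(panel, maf=0.0)
            for j in range(panel.n_sites):
                ref = ihs_raw(panel, j, maf=0.0)
                row = fast.iloc[j]
                assert row["flag"] == ref["flag"]
                if ref["flag"] == "":
                    assert row["ihs_raw"] == pytest.approx(ref["ihs_raw"], abs=1e-12)


class TestStandardizeIHS:
    def test_per_bin_mean_zero_sd_one(self, rng):
        df = pd.DataFrame(
            {
                "daf": rng.uniform(0.1, 0.9, size=400),
                "ihs_raw": rng.normal(size=400),
                "flag": "",
            }
        )
        out = standardize_ihs(df)
        for _, grp in out[out.ihs_std.notna()].groupby("daf_bin"):
            if len(grp) >= 2:
                assert grp.ihs_std.mean() == pytest.approx(0.0, abs=1e-10)
                assert grp.ihs_std.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_single_bin_pair(self):
        df = pd.DataFrame({"daf": [0.5, 0.5], "ihs_raw": [-1.0, 1.0], "flag": ""})
        out = standardize_ihs(df, n_bins=1)
        assert sorted(out.ihs_std) == [-1.0, 1.0]

    def test_three_bins_hand_arithmetic(self):
        df = pd.DataFrame(
            {
                "daf": [0.15, 0.15, 0.45, 0.45, 0.45, 0.80, 0.80],
                "ihs_raw": [1.0, 3.0, 0.0, 1.0, 2.0, -2.0, 2.0],
                "flag": "",
            }
        )
        out = standardize_ihs(df, n_bins=3)
        np.testing.assert_allclose(
            out.ihs_std, [-1, 1, -math.sqrt(1.5), 0, math.sqrt(1.5), -1, 1], atol=1e-12
        )

    def test_sparse_bin_flagged_unstandardized(self):
        df = pd.DataFrame({"daf": [0.15, 0.85], "ihs_raw": [1.0, 2.0], "flag": ""})
        out = standardize_ihs(df, n_bins=2)
        assert out.ihs_std.isna().all()
        assert (out.flag == "unstandardized").all()


class TestXPEHH:
    def test_identical_panels_give_zero(self, rng):
        panel = random_panel(rng, n_hap=8, n_sites=10)
        rec = xpehh(panel, panel, 5)
        if rec["flag"] in ("", "edge"):
            assert rec["xpehh_raw"] == pytest.approx(0.0, abs=1e-12)

    def test_swapping_panels_flips_sign(self, rng):
        found = 0
        for _ in range(10):
            p1 = random_panel(rng, n_hap=8, n_sites=12)
            p2 = HaplotypePanel(
                sites=p1.sites,
                haplotypes=rng.integers(0, 2, size=(10, 12)).astype(np.int8),
            )
            r12 = xpehh(p1, p2, 6)
            r21 = xpehh(p2, p1, 6)
            if not math.isnan(r12["xpehh_raw"]):
                assert r12["xpehh_raw"] == pytest.approx(-r21["xpehh_raw"], abs=1e-12)
                found += 1
        assert found >= 3

    def test_homogeneous_test_panel_scores_positive(self):
        rng = np.random.default_rng(5)
        sites = make_sites(11, cm_per_site=0.05)
        fixed = np.vstack([np.concatenate([np.ones(5), np.zeros(6)]).astype(np.int8)] * 8)
        diverse = rng.integers(0, 2, size=(8, 11)).astype(np.int8)
        pt = HaplotypePanel(sites=sites, haplotypes=fixed)
        pr = HaplotypePanel(sites=sites, haplotypes=diverse)
        rec = xpehh(pt, pr, 5)
        assert rec["xpehh_raw"] > 0

    def test_scan_matches_per_core_reference(self, rng):
        for _ in range(10):
            p1 = random_panel(rng, n_hap=8, n_sites=12)
            p2 = HaplotypePanel(
                sites=p1.sites,
                haplotypes=rng.integers(0, 2, size=(8, 12)).astype(np.int8),
            )
            fast = xpehh_scan(p1, p2)
            for j in range(12):
                ref = xpehh(p1, p2, j)
                row = fast.iloc[j]
                assert row["flag"] == ref["flag"]
                if not math.isnan(ref["xpehh_raw"]):
                    assert row["xpehh_raw"] == pytest.approx(ref["xpehh_raw"], abs=1e-12)


class TestNormalizeXPEHH:
    def test_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({"xpehh_raw": rng.normal(0.3, 0.7, size=200)})
        out = normalize_xpehh(df)
        assert out.xpehh_norm.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.xpehh_norm.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_two_tailed_p_values(self):
        # craft raw scores with mean 0 / sd 1 so norm equals raw: a +/-1.959964
        # pair embedded in a filler set scaled to keep unit variance
        b = 1.959964
        k = 48
        a = math.sqrt((2 * (k + 1) - 2 * b**2) / (2 * k))
        raw = [b, -b] + [a, -a] * k
        out = normalize_xpehh(pd.DataFrame({"xpehh_raw": raw}))
        assert out.xpehh_norm[0] == pytest.approx(b, abs=1e-12)
        assert out.p_value[0] == pytest.approx(0.05, abs=1e-6)
        # a zero score has p = 1
        raw0 = [0.0] + [1.0, -1.0] * 30
        out0 = normalize_xpehh(pd.DataFrame({"xpehh_raw": raw0}))
        assert out0.p_value[0] == pytest.approx(1.0, rel=1e-6)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            normalize_xpehh(pd.DataFrame({"xpehh_raw": [0.1] * 10}))


class TestXPEHHThreshold:
    def test_known_quantiles(self):
        assert xpehh_threshold(1) == pytest.approx(1.959964, abs=1e-6)
        # m=10: tail 0.0025 per side
        from scipy import stats

        assert xpehh_threshold(10) == pytest.approx(stats.norm.isf(0.0025), rel=1e-12)
        # the genome-wide m used in the study's scan gives ~5.51
        assert xpehh_threshold(1_373_755) == pytest.approx(5.5075, abs=2e-4)
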