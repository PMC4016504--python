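"""Scan statistic: zones, LLR, MLC maximization and Monte Carlo inference."""

import math

import numpy as np
import pytest

import scanpower as sp
from conftest import random_region


def _dataset(region, counts, incidence=None):
    counts = np.asarray(counts, dtype=np.int64)
    eps = (
        counts.sum() / region.total_population * region.populations
        if incidence is None
        else incidence * region.populations
    )
    return sp.CaseDataset(
        x=region.centroids[:, 0], y=region.centroids[:, 1],
        observed=counts, population=region.populations, expected=eps,
        su_ids=region.su_ids,
    )


# ---------------------------------------------------------------- zones


def test_zone_enumeration_three_collinear():
    """Equal populations, 50% cap: each center's zone stops at 1 SU."""
    units = [sp.SpatialUnit(f"x{k}", float(k), 0.0, 1.0) for k in range(3)]
    reg = sp.Region(units)
    zones = sp.enumerate_zones(reg, max_population_fraction=0.5)
    assert len(zones) == 3
    assert all(z.n_members == 1 for z in zones)


def test_zone_enumeration_full_fraction(grid3):
    zones = sp.enumerate_zones(grid3, max_population_fraction=1.0)
    assert len(zones) == 9 * 9
    by_center = {}
    for z in zones:
        by_center.setdefault(z.center_su, []).append(z)
    for center, zs in by_center.items():
        # nested distance prefixes, starting at the center itself
        assert [z.n_members for z in zs] == list(range(1, 10))
        assert zs[0].members == (center,)
        for a, b in zip(zs, zs[1:]):
            assert b.members[:-1] == a.members


def test_zone_population_cap(grid5):
    zones = sp.enumerate_zones(grid5, max_population_fraction=0.5)
    for z in zones:
        assert z.population <= 0.5 * grid5.total_population + 1e-9


def test_zone_size_cap(grid5):
    zones = sp.enumerate_zones(grid5, max_population_fraction=1.0, max_zone_size=3)
    assert max(z.n_members for z in zones) == 3
    assert len(zones) == 25 * 3


def test_zone_enumeration_bad_fraction(grid3):
    with pytest.raises(ValueError):
        sp.enumerate_zones(grid3, max_population_fraction=0.0)


# ---------------------------------------------------------------- LLR


def test_llr_hand_value():
    """30 of 50 cases on one third of the population: LLR = 7.4171."""
    got = sp.log_likelihood_ratio(30, 100.0, 50, 300.0, 50 / 300)
    want = 30 * math.log(30 / (50 / 300 * 100)) + 20 * math.log(20 / (50 / 300 * 200))
    assert got == pytest.approx(want, abs=1e-12)
    assert got == pytest.approx(7.4171, abs=1e-4)


def test_llr_indicator_boundary():
    # n_z exactly at expectation: not over-incident, statistic is 0
    assert sp.log_likelihood_ratio(10, 100.0, 30, 300.0, 0.1) == 0.0
    assert sp.log_likelihood_ratio(9, 100.0, 30, 300.0, 0.1) == 0.0


def test_llr_all_cases_inside():
    # n_z = n: the outside term vanishes by the 0 ln 0 convention
    lam = 0.1
    got = sp.log_likelihood_ratio(30, 100.0, 30, 300.0, lam)
    assert got == pytest.approx(30 * math.log(30 / (lam * 100.0)))


def test_llr_domain_errors():
    with pytest.raises(ValueError):
        sp.log_likelihood_ratio(5, 0.0, 10, 300.0, 0.1)
    with pytest.raises(ValueError):
        sp.log_likelihood_ratio(5, 300.0, 10, 300.0, 0.1)
    with pytest.raises(ValueError):
        sp.log_likelihood_ratio(11, 100.0, 10, 300.0, 0.1)
    with pytest.raises(ValueError):
        sp.log_likelihood_ratio(5, 100.0, 10, 300.0, 0.0)


def test_llr_monotone_in_cases():
    vals = [sp.log_likelihood_ratio(k, 100.0, 60, 300.0, 0.2) for k in range(21, 60)]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert all(v >= 0 for v in vals)


# ---------------------------------------------------------------- MLC


def test_mlc_three_su_hand_case():
    units = [sp.SpatialUnit(f"u{k}", float(k), 0.0, 100.0) for k in range(3)]
    reg = sp.Region(units)
    ds = _dataset(reg, [30, 10, 10])
    zones = sp.enumerate_zones(reg, max_population_fraction=0.5)
    members, llr = sp.find_most_likely_cluster(ds, zones)
    assert members == frozenset({"u0"})
    assert llr == pytest.approx(7.4171, abs=1e-4)


def test_mlc_homogeneous_data(grid3):
    ds = _dataset(grid3, np.full(9, 7))
    zones = sp.enumerate_zones(grid3)
    members, llr = sp.find_most_likely_cluster(ds, zones)
    assert llr == 0.0 and members == frozenset()


def test_mlc_zero_cases(grid3):
    ds = _dataset(grid3, np.zeros(9, dtype=int), incidence=0.01)
    zones = sp.enumerate_zones(grid3)
    assert sp.find_most_likely_cluster(ds, zones) == (frozenset(), 0.0)
    res = sp.KulldorffScan(ds, region=grid3).fit(mc_replicates=19, seed=0)
    assert res.log_lr == 0.0 and res.p_value == 1.0 and not res.significant


def test_mlc_invariant_to_zone_order(grid5):
    rng = np.random.default_rng(2)
    ds = _dataset(grid5, rng.poisson(3.0, 25))
    zones = sp.enumerate_zones(grid5)
    a = sp.find_most_likely_cluster(ds, zones)
    b = sp.find_most_likely_cluster(ds, list(reversed(zones)))
    assert a == b


def _brute_force_mlc(region, counts, frac=0.5):
    """Independent exhaustive maximization over every center x radius zone."""
    counts = np.asarray(counts)
    n, N = int(counts.sum()), region.total_population
    lam = n / N
    best = (0.0, None)  # (llr, members)
    cands = []
    for k in range(region.n_units):
        d = np.hypot(
            region.centroids[:, 0] - region.centroids[k, 0],
            region.centroids[:, 1] - region.centroids[k, 1],
        )
        order = sorted(range(region.n_units), key=lambda i: (d[i], region.su_ids[i]))
        members, nz, Nz = [], 0, 0.0
        for i in order:
            members.append(i)
            nz += int(counts[i])
            Nz += region.populations[i]
            if Nz > frac * N + 1e-9 * N:
                break
            if Nz < N and nz > lam * Nz:
                v = nz * math.log(nz / (lam * Nz))
                if n - nz > 0:
                    v += (n - nz) * math.log((n - nz) / (lam * (N - Nz)))
                cands.append((v, len(members), region.su_ids[k], frozenset(region.su_ids[i] for i in members)))
    if not cands:
        return frozenset(), 0.0
    vmax = max(c[0] for c in cands)
    ties = sorted((c for c in cands if c[0] == vmax), key=lambda c: (c[1], c[2]))
    return ties[0][3], vmax


def test_mlc_matches_brute_force_on_random_regions():
    """Optimized scan equals exhaustive zone maximization (<=12 SUs)."""
    rng = np.random.default_rng(123)
    for trial in range(200):
        n = int(rng.integers(3, 13))
        reg = random_region(rng, n)
        counts = rng.poisson(rng.uniform(0.5, 5.0), n)
        if counts.sum() == 0:
            counts[0] = 1
        ds = _dataset(reg, counts)
        want_members, want_llr = _brute_force_mlc(reg, counts)
        zones = sp.enumerate_zones(reg)
        got_members, got_llr = sp.find_most_likely_cluster(ds, zones)
        assert got_llr == pytest.approx(want_llr, abs=1e-9)
        if want_llr > 0:
            assert got_members == want_members
        # fast engine path agrees too
        zs = sp.ZoneSystem(reg)
        members, llr, nz, Nz = zs.most_likely(counts, counts.sum() / reg.total_population)
        assert llr == pytest.approx(want_llr, abs=1e-9)
        if want_llr > 0:
            assert frozenset(reg.su_ids[i] for i in members) == want_members


def test_batch_max_matches_single(grid5):
    """The Monte Carlo batch kernel agrees with zone-by-zone evaluation."""
    rng = np.random.default_rng(0)
    zs = sp.ZoneSystem(grid5)
    counts = rng.poisson(2.0, size=(40, 25))
    lam = counts.sum(axis=1) / grid5.total_population
    batch = zs.max_llr_batch(counts, lam)
    for r in range(40):
        single = zs.llr_all(counts[r], lam[r]).max()
        assert batch[r] == pytest.approx(single, abs=1e-10)


# ---------------------------------------------------------------- Monte Carlo


def test_p_value_rank_formula(grid5):
    cl = sp.build_cluster_collection(grid5, 4)[12]
    scen = sp.RiskScenario(incidence=0.05, relative_risk=10.0, cluster=cl)
    ds = sp.simulate_dataset(grid5, scen, rng=4)
    res = sp.KulldorffScan(ds, region=grid5).fit(mc_replicates=999, seed=1)
    # overwhelming cluster: observed beats every replicate
    assert res.p_value == pytest.approx(1 / 1000)
    assert res.significant
    assert res.mlc_members == cl.members


def test_p_values_on_lattice(grid3):
    ds = _dataset(grid3, np.full(9, 5))
    res = sp.KulldorffScan(ds, region=grid3).fit(mc_replicates=99, seed=0)
    assert res.p_value == 1.0  # homogeneous: every replicate ties or beats 0
    k = round(res.p_value * 100)
    assert res.p_value == pytest.approx(k / 100)


def test_fit_reproducible(grid5):
    ds = sp.simulate_dataset(grid5, sp.RiskScenario(0.03), rng=6)
    zs = sp.ZoneSystem(grid5)
    a = sp.KulldorffScan(ds, zones=zs).fit(mc_replicates=99, seed=5)
    b = sp.KulldorffScan(ds, zones=zs).fit(mc_replicates=99, seed=5)
    assert a.p_value == b.p_value and a.log_lr == b.log_lr


def test_fixed_lambda_mode(grid5):
    ds = sp.simulate_dataset(grid5, sp.RiskScenario(0.03), rng=7)
    res = sp.KulldorffScan(
        ds, region=grid5, lambda_mode="fixed", fixed_lambda=0.03
    ).fit(mc_replicates=49, seed=2)
    assert 0 < res.p_value <= 1
    with pytest.raises(ValueError):
        sp.KulldorffScan(ds, region=grid5, lambda_mode="fixed").fit(mc_replicates=9)


def test_poisson_null_mode(grid5):
    ds = sp.simulate_dataset(grid5, sp.RiskScenario(0.03), rng=8)
    res = sp.KulldorffScan(ds, region=grid5, null="poisson").fit(mc_replicates=49, seed=3)
    assert 0 < res.p_value <= 1


def test_summary_mentions_key_quantities(grid5):
    cl = sp.build_cluster_collection(grid5, 4)[7]
    ds = sp.simulate_dataset(grid5, sp.RiskScenario(0.05, 8.0, cluster=cl), rng=9)
    res = sp.KulldorffScan(ds, region=grid5).fit(mc_replicates=99, seed=0)
    text = res.summary()
    assert "p-value" in text and "likelihood ratio" in text
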