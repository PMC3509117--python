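import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import orthogonal_procrustes
from scipy.stats import spearmanr

from ystrpop import (
    Dataset, STRHaplotype, amova, amova_permutation_test, combined_distance_table,
    delta_mu_squared, mds_embed, pi_between, pi_within, rst_matrix,
    simulate_star_population,
)

from _oracles import amova_nested, amova_two_level


def test_pi_between_single_pair(make_pop):
    a = make_pop([(10, 10)], name="a")
    b = make_pop([(11, 12)], name="b")
    assert pi_between(a, b, "step") == pytest.approx(3.0)


def test_pi_between_identical_content_includes_self_pairs(make_pop):
    haps = [(10, 10), (11, 10), (11, 11)]
    a = make_pop(haps, name="a")
    b = make_pop(haps, name="b")
    # PiXY over nA*nB pairs includes self-comparisons, so it is the mean of
    # the full 3x3 distance table, not the within-population MPD
    d = [[sum(abs(x - y) for x, y in zip(u, v)) for v in haps] for u in haps]
    assert pi_between(a, b, "step") == pytest.approx(np.mean(d))


def test_pi_between_bounded_by_cross_pair_extremes(make_pop):
    rng = np.random.default_rng(3)
    a = make_pop([tuple(rng.integers(10, 14, 4)) for _ in range(5)], name="a")
    b = make_pop([tuple(rng.integers(10, 14, 4)) for _ in range(4)], name="b")
    ma, _ = a.to_arrays()
    mb, _ = b.to_arrays()
    from ystrpop import cross_distance_matrix

    d = cross_distance_matrix(ma, mb, "allele")
    val = pi_between(a, b, "allele")
    assert d.min() <= val <= d.max()


def test_delta_mu_squared_cases(make_pop):
    a = make_pop([(14,) * 15], name="a")
    assert delta_mu_squared(a, a) == 0.0
    b = make_pop([tuple([16] + [14] * 14)], name="b")
    assert delta_mu_squared(a, b) == pytest.approx(4 / 15)
    assert delta_mu_squared(b, a) == pytest.approx(4 / 15)


@given(st.lists(st.tuples(st.integers(10, 13), st.integers(20, 22)),
                min_size=1, max_size=6),
       st.permutations(range(6)))
@settings(derandomize=True, max_examples=40)
def test_delta_mu_invariant_to_ordering(haps, perm):
    from collections import Counter

    from ystrpop import PopulationSample

    idx = [i for i in perm if i < len(haps)]
    shuffled = [haps[i] for i in idx] + [h for i, h in enumerate(haps) if i not in idx]
    a = PopulationSample("a", Counter(STRHaplotype(h) for h in haps))
    b = PopulationSample("b", Counter(STRHaplotype(h) for h in shuffled))
    assert delta_mu_squared(a, a) == 0.0
    ref = PopulationSample("r", Counter({STRHaplotype((9, 19)): 1}))
    assert delta_mu_squared(a, ref) == pytest.approx(delta_mu_squared(b, ref))


def test_amova_phi_st_one_when_populations_fixed(make_dataset):
    ds = make_dataset({"a": [(10, 10)] * 4, "b": [(12, 13)] * 4})
    res = amova(ds, metric="allele")
    assert res.phi_st == pytest.approx(1.0)


def test_amova_errors(make_dataset):
    ds = make_dataset({"a": [(10, 10)], "b": [(12, 13)]})
    with pytest.raises(ValueError, match="within-population"):
        amova(ds)


def test_amova_matches_bruteforce_two_level(make_dataset):
    rng = np.random.default_rng(7)
    pops = {f"p{k}": [tuple(rng.integers(10, 14, 3)) for _ in range(4)] for k in range(3)}
    ds = make_dataset(pops)
    res = amova(ds, metric="allele")
    sa, sw, phi = amova_two_level(list(pops.values()), "allele")
    assert res.sigma["among_populations"] == pytest.approx(sa)
    assert res.sigma["within_populations"] == pytest.approx(sw)
    assert res.phi_st == pytest.approx(phi)


def test_amova_matches_bruteforce_nested(make_dataset):
    rng = np.random.default_rng(11)
    pops = {f"p{k}": [tuple(rng.integers(10, 14, 3)) for _ in range(rng.integers(3, 6))]
            for k in range(4)}
    groups = {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}
    ds = make_dataset(pops, groups=groups)
    res = amova(ds, grouping=groups, metric="allele")
    grouped = [[pops["p0"], pops["p1"]], [pops["p2"], pops["p3"]]]
    sa, sb, sc, phi_st, phi_sc, phi_ct = amova_nested(grouped, "allele")
    assert res.sigma["among_groups"] == pytest.approx(sa)
    assert res.sigma["among_populations"] == pytest.approx(sb)
    assert res.sigma["within_populations"] == pytest.approx(sc)
    assert (res.phi_st, res.phi_sc, res.phi_ct) == pytest.approx((phi_st, phi_sc, phi_ct))


def test_amova_permutation_pvalue_small_for_strong_structure(make_dataset):
    ds = make_dataset({"a": [(10, 10)] * 6, "b": [(13, 14)] * 6})
    res = amova_permutation_test(ds, n_permutations=99, seed=0)
    assert res.p_value is not None and res.p_value < 0.05


def test_rst_equals_two_pop_amova_squared(make_dataset):
    rng = np.random.default_rng(5)
    pops = {"a": [tuple(rng.integers(10, 15, 4)) for _ in range(5)],
            "b": [tuple(rng.integers(12, 17, 4)) for _ in range(6)]}
    ds = make_dataset(pops)
    rst = rst_matrix(ds, clamp=False)
    res = amova(ds, metric="squared")
    assert rst.raw[0, 1] == pytest.approx(res.phi_st)


def test_rst_zero_for_identical_populations(make_dataset):
    haps = [(10, 10), (11, 12), (10, 12)]
    ds = make_dataset({"a": haps, "b": haps})
    rst = rst_matrix(ds)
    assert rst.values[0, 1] == pytest.approx(0.0, abs=1e-9) or rst.values[0, 1] == 0.0


def test_rst_increases_with_divergence_time():
    """Populations split longer ago show larger Rst (rank correlation > 0)."""
    from collections import Counter

    from ystrpop import LocusPanel, PopulationSample

    mu, L = 0.002, 10
    founder = STRHaplotype(tuple([20] * L))
    times = [25, 50, 100, 200, 400]
    rng_seed = itertools.count(100)
    rsts = []
    for t in times:
        vals = []
        for _ in range(4):
            fa = simulate_star_population(1, t, founder, mu=mu, seed=next(rng_seed))
            fb = simulate_star_population(1, t, founder, mu=mu, seed=next(rng_seed))
            ha = next(iter(fa.haplotypes))
            hb = next(iter(fb.haplotypes))
            a = simulate_star_population(15, 20, ha, mu=mu, seed=next(rng_seed), name="a")
            b = simulate_star_population(15, 20, hb, mu=mu, seed=next(rng_seed), name="b")
            panel = LocusPanel(tuple(f"L{i}" for i in range(L)))
            ds = Dataset(panel, [PopulationSample("a", a.haplotypes, panel=panel),
                                 PopulationSample("b", b.haplotypes, panel=panel)])
            vals.append(rst_matrix(ds).values[0, 1])
        rsts.append(np.mean(vals))
    rho, _ = spearmanr(times, rsts)
    assert rho > 0


def test_delta_mu_grows_linearly_with_divergence():
    """E[(δμ)²] between diverged lineages is 2·mu·t per locus under SMM."""
    mu, L = 0.005, 15
    founder = STRHaplotype(tuple([20] * L))
    times = np.array([50, 100, 200, 400])
    seeds = itertools.count(1000)
    means = []
    for t in times:
        vals = []
        for _ in range(150):
            a = simulate_star_population(1, t, founder, mu=mu, seed=next(seeds), name="a")
            b = simulate_star_population(1, t, founder, mu=mu, seed=next(seeds), name="b")
            vals.append(delta_mu_squared(a, b))
        means.append(np.mean(vals))
    slope = np.polyfit(times, means, 1)[0]
    assert slope == pytest.approx(2 * mu, rel=0.2)


def test_combined_distance_table_layout(make_dataset):
    ds = make_dataset({"a": [(10, 10), (11, 10)], "b": [(12, 13), (12, 14)]})
    tab = combined_distance_table(ds, metric="allele")
    assert tab.loc["a", "a"] == pytest.approx(pi_within(ds.population("a")))
    assert tab.loc["a", "b"] == pytest.approx(pi_between(ds.population("a"), ds.population("b")))
    assert tab.loc["b", "a"] == pytest.approx(delta_mu_squared(ds.population("a"), ds.population("b")))


# ---------------------------------------------------------------------------
# MDS

def test_mds_recovers_planar_configuration():
    pts = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0], [-1.0, 2.0]])
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    res = mds_embed(D, dims=2)
    X = res.coords - res.coords.mean(0)
    Y = pts - pts.mean(0)
    R, _ = orthogonal_procrustes(X, Y)
    rms = np.sqrt(np.mean((X @ R - Y) ** 2))
    assert rms < 1e-8


def test_mds_zero_matrix_and_errors():
    res = mds_embed(np.zeros((3, 3)), dims=2)
    assert np.allclose(res.coords, 0.0)
    with pytest.raises(ValueError):
        mds_embed(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        mds_embed(np.zeros((3, 3)), dims=0)


def test_mds_reports_negative_eigenvalue_for_nonmetric_input():
    # d(a,c) > d(a,b) + d(b,c): not embeddable in Euclidean space
    D = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 1.0], [5.0, 1.0, 0.0]])
    res = mds_embed(D, dims=2)
    assert res.eigenvalues.min() < -1e-9
    assert res.coords.shape == (3, 2)
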