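"""Unit and property tests for the deterministic pollen-killer recursion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pollenkiller as pk
from pollenkiller.model import (
    DegeneratePopulationError,
    ParameterError,
    transition_update,
)

from conftest import invasion_theta0


def genotype_index(name: str) -> int:
    return pk.GENOTYPE_NAMES.index(name)


def theta_from(d: dict[str, float]) -> np.ndarray:
    theta = np.zeros(10)
    for name, val in d.items():
        theta[genotype_index(name)] = val
    return theta


# -- parameter and state validation -------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(r=-0.01, s=0.5),
        dict(r=0.6, s=0.5),
        dict(r=0.1, s=1.5),
        dict(r=0.1, s=0.5, k=-0.2),
        dict(r=0.1, s=0.5, R=0.5),
        dict(r=0.1, s=0.5, M_total=0.0),
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ParameterError):
        pk.ModelParams(**kwargs)


def test_selfing_rate_identity():
    p = pk.ModelParams(r=0.1, s=0.37, M_total=2.5)
    assert p.M_self / (p.M_self + p.M_pool) == pytest.approx(0.37, abs=1e-15)


# -- gamete-generating matrices ------------------------------------------------

@pytest.mark.parametrize(
    "genotype, r, k, expected",
    [
        # the one male row the source model prints: AB|ab under killing
        ("AB|ab", 0.2, 0.7,
         {"AB": 0.5 * 0.8, "ab": 0.5 * 0.8 * 0.3, "Ab": 0.5 * 0.2, "aB": 0.5 * 0.2 * 0.3}),
        ("AB|AB", 0.3, 1.0, {"AB": 1.0}),
        # hand enumeration: parental masses 0.45 each, recombinants 0.05 each,
        # then full killing of a-carriers because the plant carries b
        ("Ab|aB", 0.1, 1.0, {"Ab": 0.45, "AB": 0.05}),
        # no b allele anywhere: a-carrying pollen survives
        ("aB|aB", 0.25, 1.0, {"aB": 1.0}),
    ],
)
def test_male_gamete_rows(genotype, r, k, expected):
    G = pk.build_gamete_matrices(pk.ModelParams(r=r, s=0.5, k=k))
    row = G.Gm[genotype_index(genotype)]
    want = np.zeros(4)
    for hap, val in expected.items():
        want[pk.HAPLOTYPES.index(hap)] = val
    np.testing.assert_allclose(row, want, atol=1e-15)


@given(
    r=st.floats(0.0, 0.5),
    k=st.floats(0.0, 1.0),
    s=st.floats(0.0, 1.0),
)
@settings(deadline=None, max_examples=50)
def test_gamete_matrix_invariants(r, k, s):
    G = pk.build_gamete_matrices(pk.ModelParams(r=r, s=s, k=k))
    np.testing.assert_allclose(G.Gf.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(G.Gm.sum(axis=1) <= 1.0 + 1e-12)
    assert np.all((G.Gm >= 0) & (G.Gm <= 1)) and np.all((G.Gf >= 0) & (G.Gf <= 1))
    if k == 0.0:
        np.testing.assert_array_equal(G.Gm, G.Gf)


def test_female_matrix_unaffected_by_killing():
    pa = pk.build_gamete_matrices(pk.ModelParams(r=0.2, s=0.5, k=1.0))
    pb = pk.build_gamete_matrices(pk.ModelParams(r=0.2, s=0.5, k=0.0))
    np.testing.assert_array_equal(pa.Gf, pb.Gf)


# -- pollen pool, availability, fertility ---------------------------------------

def test_pollen_pool_monomorphic():
    params = pk.ModelParams(r=0.2, s=0.5, k=1.0)
    G = pk.build_gamete_matrices(params)
    f = pk.pollen_pool_frequencies(G, theta_from({"AB|AB": 1.0}))
    np.testing.assert_allclose(f, [1, 0, 0, 0], atol=1e-15)


def test_pollen_pool_homozygotes_unaffected_by_killing():
    theta = theta_from({"Ab|Ab": 0.5, "aB|aB": 0.5})
    for k in (0.0, 0.5, 1.0):
        G = pk.build_gamete_matrices(pk.ModelParams(r=0.0, s=0.2, k=k))
        f = pk.pollen_pool_frequencies(G, theta)
        np.testing.assert_allclose(f, [0, 0.5, 0.5, 0], atol=1e-15)


def test_pollen_pool_heterozygote_killing():
    # Ab|aB contributes only Ab (mass 0.25); aB|aB contributes aB (mass 0.5)
    theta = theta_from({"Ab|aB": 0.5, "aB|aB": 0.5})
    G = pk.build_gamete_matrices(pk.ModelParams(r=0.0, s=0.2, k=1.0))
    f = pk.pollen_pool_frequencies(G, theta)
    np.testing.assert_allclose(f, [0, 1 / 3, 2 / 3, 0], atol=1e-15)


def test_pollen_pool_zero_output_raises():
    # pure suicide population under complete killing produces no pollen
    G = pk.build_gamete_matrices(pk.ModelParams(r=0.0, s=0.5, k=1.0))
    with pytest.raises(DegeneratePopulationError):
        pk.pollen_pool_frequencies(G, theta_from({"ab|ab": 1.0}))


def test_pollen_availability():
    params = pk.ModelParams(r=0.0, s=1.0, k=1.0)
    G = pk.build_gamete_matrices(params)
    N = pk.pollen_availability(G, params)
    assert N[genotype_index("Ab|aB")] == pytest.approx(0.5)
    params0 = pk.ModelParams(r=0.3, s=0.4, k=0.0)
    G0 = pk.build_gamete_matrices(params0)
    np.testing.assert_allclose(pk.pollen_availability(G0, params0), 1.0, atol=1e-15)
    # fully self-killed genotype retains only the pool supply
    params9 = pk.ModelParams(r=0.0, s=0.9, k=1.0)
    G9 = pk.build_gamete_matrices(params9)
    assert pk.pollen_availability(G9, params9)[genotype_index("ab|ab")] == pytest.approx(0.1)


@pytest.mark.parametrize(
    "N, R, expected",
    [(0.5, 10.0, 1.0), (0.5, 1.0, 0.5), (0.0, 5.0, 0.0), (1.0, 1.0, 1.0)],
)
def test_fertility_piecewise(N, R, expected):
    params = pk.ModelParams(r=0.0, s=0.5, R=R)
    assert pk.fertility(np.array([N]), params)[0] == pytest.approx(expected)


# -- offspring distribution and one-generation step ----------------------------

def test_offspring_distribution_selfing_heterozygote():
    params = pk.ModelParams(r=0.0, s=1.0, k=1.0, R=10)
    G = pk.build_gamete_matrices(params)
    theta = theta_from({"Ab|aB": 1.0})
    f = pk.pollen_pool_frequencies(G, theta)
    N = pk.pollen_availability(G, params)
    i = genotype_index("Ab|aB")
    p = pk.offspring_distribution(i, G, f, N, params)
    want = theta_from({"Ab|Ab": 0.5, "Ab|aB": 0.5})
    np.testing.assert_allclose(p, want, atol=1e-12)


def test_offspring_distribution_monomorphic_outcrossing():
    params = pk.ModelParams(r=0.0, s=0.0, k=0.0)
    G = pk.build_gamete_matrices(params)
    theta = theta_from({"AB|AB": 1.0})
    f = pk.pollen_pool_frequencies(G, theta)
    N = pk.pollen_availability(G, params)
    p = pk.offspring_distribution(0, G, f, N, params)
    np.testing.assert_allclose(p, theta_from({"AB|AB": 1.0}), atol=1e-15)


@given(
    r=st.floats(0.0, 0.5),
    s=st.floats(0.0, 1.0),
    k=st.floats(0.0, 1.0),
    weights=st.lists(st.floats(0.01, 1.0), min_size=10, max_size=10),
)
@settings(deadline=None, max_examples=50)
def test_offspring_distributions_normalize(r, s, k, weights):
    params = pk.ModelParams(r=r, s=s, k=k)
    theta = np.array(weights) / np.sum(weights)
    G = pk.build_gamete_matrices(params)
    f = pk.pollen_pool_frequencies(G, theta)
    N = pk.pollen_availability(G, params)
    for i in range(10):
        p = pk.offspring_distribution(i, G, f, N, params)
        if N[i] > 0:
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
        else:
            np.testing.assert_array_equal(p, 0.0)


def test_step_selfing_heterozygote_doubles_killer_share():
    # complete selfing + full killing: only Ab pollen survives, so the
    # killer's male-gamete share is 1 and its frequency rises 0.5 -> 0.75
    params = pk.ModelParams(r=0.0, s=1.0, k=1.0, R=10)
    theta1 = pk.step(theta_from({"Ab|aB": 1.0}), params)
    np.testing.assert_allclose(
        theta1, theta_from({"Ab|Ab": 0.5, "Ab|aB": 0.5}), atol=1e-12
    )
    assert pk.haplotype_frequencies(theta1)[1] == pytest.approx(0.75)


@pytest.mark.parametrize("hom", ["AB|AB", "Ab|Ab", "aB|aB"])
def test_fixation_states_absorbing(hom):
    params = pk.ModelParams(r=0.2, s=0.3, k=1.0, R=2)
    theta = theta_from({hom: 1.0})
    np.testing.assert_allclose(pk.step(theta, params), theta, atol=1e-12)


@given(
    s=st.floats(0.0, 1.0),
    weights=st.lists(st.floats(0.01, 1.0), min_size=10, max_size=10),
)
@settings(deadline=None, max_examples=40)
def test_neutral_full_linkage_preserves_haplotypes(s, weights):
    """k = 0, r = 0: haplotype frequencies are invariant under the update."""
    params = pk.ModelParams(r=0.0, s=s, k=0.0, R=3)
    theta = np.array(weights) / np.sum(weights)
    h0 = pk.haplotype_frequencies(theta)
    h1 = pk.haplotype_frequencies(pk.step(theta, params))
    np.testing.assert_allclose(h1, h0, atol=1e-12)


@given(
    r=st.floats(0.0, 0.5),
    s=st.floats(0.0, 1.0),
    R=st.floats(1.0, 20.0),
    weights=st.lists(st.floats(0.01, 1.0), min_size=10, max_size=10),
)
@settings(deadline=None, max_examples=40)
def test_neutral_model_preserves_allele_frequencies(r, s, R, weights):
    """k = 0: per-locus allele frequencies are invariant for any r, s, R.

    Recombination redistributes haplotypes (toward linkage equilibrium) but
    cannot change allele frequencies without selection.
    """
    params = pk.ModelParams(r=r, s=s, k=0.0, R=R)
    theta = np.array(weights) / np.sum(weights)
    h0 = pk.haplotype_frequencies(theta)
    h1 = pk.haplotype_frequencies(pk.step(theta, params))
    # allele "a" rides on haplotypes aB, ab; allele "b" on Ab, ab
    assert h1[2] + h1[3] == pytest.approx(h0[2] + h0[3], abs=1e-12)
    assert h1[1] + h1[3] == pytest.approx(h0[1] + h0[3], abs=1e-12)


@given(weights=st.lists(st.floats(0.01, 1.0), min_size=10, max_size=10))
@settings(deadline=None, max_examples=40)
def test_step_conserves_probability(weights):
    params = pk.ModelParams(r=0.17, s=0.66, k=1.0, R=1.4)
    theta = np.array(weights) / np.sum(weights)
    out = pk.step(theta, params)
    assert out.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(out >= 0.0)


def test_step_deterministic():
    params = pk.ModelParams(r=0.07, s=0.4, k=1.0, R=1.5)
    theta = invasion_theta0(0.2)
    a = pk.step(theta, params)
    b = pk.step(theta, params)
    np.testing.assert_array_equal(a, b)


# -- haplotype frequency accounting ---------------------------------------------

@pytest.mark.parametrize(
    "theta_dict, expected",
    [
        ({"Ab|Ab": 0.1, "aB|aB": 0.9}, (0, 0.1, 0.9, 0)),
        ({"Ab|aB": 1.0}, (0, 0.5, 0.5, 0)),
        ({"AB|ab": 0.5, "Ab|aB": 0.5}, (0.25, 0.25, 0.25, 0.25)),
    ],
)
def test_haplotype_frequencies(theta_dict, expected):
    np.testing.assert_allclose(
        pk.haplotype_frequencies(theta_from(theta_dict)), expected, atol=1e-15
    )


# -- long-run iteration and classification --------------------------------------

def test_iterate_full_linkage_killer_fixes():
    report = pk.iterate(invasion_theta0(0.1), pk.ModelParams(r=0.0, s=1e-5, k=1, R=10))
    assert report.state == "killer_fixed"
    assert report.stop_reason == "threshold"


def test_iterate_recombination_with_selfing_neutral_killer_coexist():
    report = pk.iterate(invasion_theta0(0.1), pk.ModelParams(r=0.1, s=0.9, k=1, R=10))
    assert report.state == "neutral_killer_coexist"


def test_iterate_zero_generations_returns_start():
    theta0 = invasion_theta0(0.1)
    report = pk.iterate(
        theta0, pk.ModelParams(r=0.1, s=0.5), stop=pk.StopRule(max_generations=0)
    )
    np.testing.assert_array_equal(report.terminal_theta, theta0)
    assert report.generations_run == 0
    assert report.stop_reason == "max_generations"


def test_iterate_relative_stop_rule():
    # loss judged at 1% of each haplotype's own starting frequency
    stop = pk.StopRule(mode="relative_1pct")
    report = pk.iterate(
        invasion_theta0(0.1), pk.ModelParams(r=0.1, s=1e-5, k=1, R=10), stop=stop
    )
    h = report.terminal_haplotype_frequencies
    assert report.stop_reason == "threshold"
    assert h[1] < 0.01 * 0.1  # the killer fell below 1% of its start


def test_iterate_records_trajectory():
    report = pk.iterate(
        invasion_theta0(0.1),
        pk.ModelParams(r=0.0, s=1e-5, k=1, R=10),
        record_trajectory=True,
    )
    assert report.trajectory is not None
    assert report.trajectory.shape == (report.generations_run + 1, 10)
    np.testing.assert_allclose(report.trajectory.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize(
    "hap_freqs, expected",
    [
        ((0, 1, 0, 0), "killer_fixed"),
        ((0, 0, 1, 0), "sensitive_fixed"),
        ((1, 0, 0, 0), "neutral_fixed"),
        ((0.6, 0, 0.4, 0), "neutral_sensitive_coexist"),
        ((0.6, 0.4, 0, 0), "neutral_killer_coexist"),
        ((0.3, 0.3, 0.3, 0.1), "unresolved"),
        ((0, 0.5, 0.5, 0), "unresolved"),  # killer+sensitive: never an equilibrium
    ],
)
def test_classify_equilibrium(hap_freqs, expected):
    theta = pk.genotype_frequencies_from_haplotype_homozygotes(list(hap_freqs))
    assert pk.classify_equilibrium(theta) == expected


def test_transition_update_accepts_cached_matrices():
    params = pk.ModelParams(r=0.05, s=0.3, k=1.0)
    theta = invasion_theta0(0.3)
    G = pk.build_gamete_matrices(params)
    np.testing.assert_array_equal(
        transition_update(theta, params, G), pk.step(theta, params)
    )
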