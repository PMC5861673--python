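"""Radiative-transfer core against independent numerical oracles:
Fresnel quadrature for the interface transmissivity, quadrature of the
defining integral for the elementary-layer transmission, explicit
bounce-series summation for the single plate, and iterated
adding-doubling for the Stokes stack."""

import numpy as np
import pytest
from scipy.integrate import quad

from prospectwb import (
    LeafParams,
    Version,
    absorption_spectrum,
    active_variables,
    layer_transmission,
    leaf_volume_rt,
    plate_rt,
    stokes_extension,
    tav,
)
from prospectwb.prospect import validate_params


# ---------------------------------------------------------------------------
# independent oracles

def fresnel_transmissivity(theta, n):
    ci, si = np.cos(theta), np.sin(theta)
    ct = np.sqrt(1.0 - (si / n) ** 2)
    rs = ((ci - n * ct) / (ci + n * ct)) ** 2
    rp = ((n * ci - ct) / (n * ci + ct)) ** 2
    return 1.0 - 0.5 * (rs + rp)


def tav_quadrature(theta_deg, n):
    tm = np.deg2rad(theta_deg)
    num = quad(
        lambda t: fresnel_transmissivity(t, n) * np.sin(t) * np.cos(t),
        0.0, tm, limit=200,
    )[0]
    den = quad(lambda t: np.sin(t) * np.cos(t), 0.0, tm, limit=200)[0]
    return num / den


def tau_quadrature(k):
    return quad(
        lambda t: np.exp(-k / np.cos(t)) * 2.0 * np.sin(t) * np.cos(t),
        0.0, np.pi / 2 - 1e-12, limit=400,
    )[0]


def plate_bounce_series(tau, n, t_in, t_out, n_terms=10_000):
    t_in_int = 1.0 if t_in == 1.0 else t_in / n ** 2
    t_out_int = 1.0 if t_out == 1.0 else t_out / n ** 2
    r_top_ext = 0.0 if t_in == 1.0 else 1.0 - t_in
    r_top_int = 1.0 - t_in_int
    r_bot_int = 1.0 - t_out_int
    loop = r_bot_int * r_top_int * tau ** 2
    geom = sum(loop ** k for k in range(n_terms))
    T = t_in * tau * t_out_int * geom
    R = r_top_ext + t_in * tau * r_bot_int * tau * t_in_int * geom
    return R, T


def add_symmetric(stack, layer):
    """Adding-doubling of a symmetric layer below an existing stack."""
    rf, tf, rb, tb = stack
    r, t = layer
    d = 1.0 - rb * r
    return (
        rf + tf * r * tb / d,
        tf * t / d,
        r + t * rb * t / d,
        tb * t / d,
    )


def iterated_stack(r, t, n_layers):
    stack = (r, t, r, t)
    for _ in range(n_layers - 1):
        stack = add_symmetric(stack, (r, t))
    return stack[0], stack[1]


# ---------------------------------------------------------------------------

class TestTav:
    @pytest.mark.parametrize("theta", [90.0, 59.0, 40.0])
    @pytest.mark.parametrize("n", [1.2, 1.35, 1.45, 1.7])
    def test_matches_fresnel_quadrature(self, theta, n):
        assert tav(theta, n) == pytest.approx(
            tav_quadrature(theta, n), abs=1e-8
        )

    def test_rejects_invalid_index(self):
        with pytest.raises(ValueError):
            tav(90.0, 0.9)


class TestLayerTransmission:
    def test_no_absorption_is_fully_transmitting(self):
        assert layer_transmission(0.0) == 1.0

    def test_opaque_limit(self):
        assert layer_transmission(50.0) < 1e-10

    @pytest.mark.parametrize("k", [0.1, 0.5, 1.0, 2.0])
    def test_matches_defining_integral(self, k):
        assert layer_transmission(k) == pytest.approx(
            tau_quadrature(k), abs=1e-8
        )

    def test_strictly_decreasing(self):
        k = np.linspace(0.0, 5.0, 200)
        tau = layer_transmission(k)
        assert np.all(np.diff(tau) < 0)

    def test_negative_absorption_rejected(self):
        with pytest.raises(ValueError):
            layer_transmission(-0.1)


class TestPlate:
    def test_transparent_plate(self):
        r, t = plate_rt(1.0, 1.4, 1.0, 1.0)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert t == pytest.approx(1.0, abs=1e-15)

    def test_opaque_plate_shows_first_surface_only(self):
        r, t = plate_rt(0.0, 1.4, 0.9, 0.9)
        assert t == 0.0
        assert r == pytest.approx(0.1, abs=1e-15)

    @pytest.mark.parametrize(
        "tau,n,t_in,t_out",
        [
            (0.7, 1.4, 0.95, 0.90),
            (0.3, 1.5, 0.80, 1.00),
            (0.95, 1.3, 0.92, 0.92),
            (0.5, 1.45, 1.00, 0.85),
        ],
    )
    def test_matches_bounce_series(self, tau, n, t_in, t_out):
        r, t = plate_rt(tau, n, t_in, t_out)
        r_ref, t_ref = plate_bounce_series(tau, n, t_in, t_out)
        assert r == pytest.approx(r_ref, abs=1e-10)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert 0.0 <= r <= 1.0 and 0.0 <= t <= 1.0 and r + t <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            plate_rt(1.2, 1.4, 0.9, 0.9)
        with pytest.raises(ValueError):
            plate_rt(0.5, 1.4, 1.1, 0.9)


class TestStokes:
    def test_single_layer_identity(self):
        r, t = stokes_extension(0.2, 0.5, 1.0)
        assert r == pytest.approx(0.2, abs=1e-14)
        assert t == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("r1,t1", [(0.2, 0.5), (0.05, 0.9), (0.4, 0.35)])
    def test_two_layers_match_adding_doubling(self, r1, t1):
        r, t = stokes_extension(r1, t1, 2.0)
        r_ref = r1 + t1 ** 2 * r1 / (1.0 - r1 ** 2)
        t_ref = t1 ** 2 / (1.0 - r1 ** 2)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert t == pytest.approx(t_ref, abs=1e-12)

    @pytest.mark.parametrize("r1,t1", [(0.2, 0.5), (0.3, 0.69), (0.01, 0.98)])
    @pytest.mark.parametrize("n_layers", [2, 3, 5])
    def test_integer_stacks_match_iterated_adding(self, r1, t1, n_layers):
        r, t = stokes_extension(r1, t1, float(n_layers))
        r_ref, t_ref = iterated_stack(r1, t1, n_layers)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert t == pytest.approx(t_ref, abs=1e-12)

    def test_conservative_layer_matches_iterated_adding(self):
        r1, t1 = 0.3, 0.7
        r, t = stokes_extension(r1, t1, 3.0)
        r_ref, t_ref = iterated_stack(r1, t1, 3)
        assert r == pytest.approx(r_ref, abs=1e-9)
        assert t == pytest.approx(t_ref, abs=1e-9)

    def test_dark_layer_degenerate(self):
        r, t = stokes_extension(0.0, 0.0, 2.5)
        assert r == 0.0 and t == 0.0

    def test_continuous_in_layer_count(self):
        lo = stokes_extension(0.25, 0.6, 2.0 - 1e-7)
        mid = stokes_extension(0.25, 0.6, 2.0)
        hi = stokes_extension(0.25, 0.6, 2.0 + 1e-7)
        assert abs(lo[0] - mid[0]) < 1e-5 and abs(hi[1] - mid[1]) < 1e-5

    def test_energy_conserved_over_random_layers(self, rng):
        r1 = rng.uniform(0.0, 0.6, 300)
        t1 = rng.uniform(0.0, 1.0, 300) * (1.0 - r1)
        for n_layers in (1.0, 1.4, 2.7):
            r, t = stokes_extension(r1, t1, n_layers)
            assert np.all(r >= 0) and np.all(t >= 0)
            assert np.all(r + t <= 1.0 + 1e-12)


class TestAbsorption:
    def test_zero_contents_zero_absorption(self, coeffs_pd):
        p = LeafParams(n=1.5)
        k = absorption_spectrum(p, coeffs_pd).values
        np.testing.assert_array_equal(k, 0.0)

    def test_linear_in_contents(self, coeffs_pd):
        p1 = LeafParams(cab=20, cc=4, canth=1, cw=10, cm=4, n=1.5)
        p2 = LeafParams(cab=40, cc=8, canth=2, cw=20, cm=8, n=1.5)
        k1 = absorption_spectrum(p1, coeffs_pd).values
        k2 = absorption_spectrum(p2, coeffs_pd).values
        np.testing.assert_allclose(k2, 2.0 * k1, rtol=1e-12)

    def test_single_constituent_table_lookup(self, coeffs_pd):
        p = LeafParams(cw=10.0, n=2.0)
        k = absorption_spectrum(p, coeffs_pd)
        i = int(np.argmin(np.abs(coeffs_pd.wavelengths - 1450.0)))
        assert k.values[i] == pytest.approx(
            coeffs_pd.sac["cw"][i] * 10.0 / 2.0, rel=1e-14
        )

    def test_version_mismatch_rejected(self, coeffs_pd):
        with pytest.raises(ValueError, match="inactive"):
            absorption_spectrum(LeafParams(cabc=50.0, n=1.5), coeffs_pd)

    def test_negative_content_rejected(self, coeffs_pd):
        with pytest.raises(ValueError):
            validate_params(LeafParams(cab=-1.0), Version.PD, False)


class TestLeafVolume:
    def test_empty_single_layer_is_transparent(self, coeffs_p3):
        p = LeafParams(n=1.0)
        r, t = leaf_volume_rt(p, coeffs_p3)
        np.testing.assert_allclose(r.values, 0.0, atol=1e-14)
        np.testing.assert_allclose(t.values, 1.0, atol=1e-14)

    def test_water_absorption_reduces_transmittance(self, coeffs_pd):
        t_at_1450 = []
        for cw in (5.0, 10.0, 20.0):
            p = LeafParams(cw=cw, n=1.5)
            _, t = leaf_volume_rt(p, coeffs_pd)
            t_at_1450.append(t.value_at(1450.0))
        assert t_at_1450[0] > t_at_1450[1] > t_at_1450[2]

    @pytest.mark.parametrize("n_layers", [2.0, 3.0])
    def test_integer_stack_matches_brute_force_composition(
        self, coeffs_pd, n_layers
    ):
        p = LeafParams(cab=30, cc=6, cw=12, cm=5, n=n_layers)
        r, t = leaf_volume_rt(p, coeffs_pd)

        # independent composition: slab | (pair | slab)^(N-1)
        from prospectwb.prospect import absorption_coefficient
        k = absorption_coefficient(p, coeffs_pd)
        tau = layer_transmission(k)
        n_refr = coeffs_pd.refractive_index
        t12 = tav(90.0, n_refr)
        t21 = t12 / n_refr ** 2
        r12, r21 = 1.0 - t12, 1.0 - t21
        d = 1.0 - r12 * r12
        pair = (
            r21 + t21 * r12 * t12 / d,
            t21 * t12 / d,
            r21 + t21 * r12 * t12 / d,
            t21 * t12 / d,
        )
        slab = (np.zeros_like(tau), tau, np.zeros_like(tau), tau)

        def add(a, b):
            rf_a, tf_a, rb_a, tb_a = a
            rf_b, tf_b, rb_b, tb_b = b
            dd = 1.0 - rb_a * rf_b
            return (
                rf_a + tf_a * rf_b * tb_a / dd,
                tf_a * tf_b / dd,
                rb_b + tb_b * rb_a * tf_b / dd,
                tb_b * tb_a / dd,
            )

        stack = slab
        for _ in range(int(n_layers) - 1):
            stack = add(stack, add(pair, slab))
        np.testing.assert_allclose(r.values, stack[0], atol=1e-10)
        np.testing.assert_allclose(t.values, stack[1], atol=1e-10)

    def test_continuous_across_integer_layer_count(self, coeffs_pd):
        base = LeafParams(cab=30, cc=6, cw=12, cm=5, n=2.0)
        lo = LeafParams(cab=30, cc=6, cw=12, cm=5, n=2.0 - 1e-7)
        hi = LeafParams(cab=30, cc=6, cw=12, cm=5, n=2.0 + 1e-7)
        r0, t0 = leaf_volume_rt(base, coeffs_pd)
        for p in (lo, hi):
            r, t = leaf_volume_rt(p, coeffs_pd)
            assert np.max(np.abs(r.values - r0.values)) < 1e-5
            assert np.max(np.abs(t.values - t0.values)) < 1e-5

    def test_energy_conservation_random_draws(self, coeffs_pd, rng):
        for _ in range(25):
            p = LeafParams(
                cab=rng.uniform(0, 140), cc=rng.uniform(0, 80),
                canth=rng.uniform(0, 20), cw=rng.uniform(1, 30),
                cm=rng.uniform(1, 50), n=rng.uniform(1.01, 3.5),
            )
            r, t = leaf_volume_rt(p, coeffs_pd)
            assert np.all(r.values >= 0) and np.all(t.values >= 0)
            assert np.all(r.values + t.values <= 1.0 + 1e-12)

    def test_interface_free_stack_option(self, coeffs_pd):
        p = LeafParams(cw=15, n=2.3)
        r, t = leaf_volume_rt(p, coeffs_pd, internal_interfaces=False)
        from prospectwb.prospect import absorption_coefficient
        k = absorption_coefficient(p, coeffs_pd)
        np.testing.assert_allclose(
            t.values, layer_transmission(k) ** 2.3, atol=1e-12
        )
        np.testing.assert_array_equal(r.values, 0.0)

    def test_pooled_and_split_versions_both_run(self, coeffs_p4, coeffs_p5):
        pooled = LeafParams(cabc=48.0, cw=12, cm=5, n=1.5)
        split = LeafParams(cab=40.0, cc=8.0, cw=12, cm=5, n=1.5)
        for p, c in ((pooled, coeffs_p4), (split, coeffs_p5)):
            r, t = leaf_volume_rt(p, c)
            assert np.all(r.values + t.values <= 1.0 + 1e-12)


class TestActiveVariables:
    def test_pooled_versions_use_cabc(self):
        assert "cabc" in active_variables(Version.P3, False)
        assert "cab" not in active_variables(Version.P4, False)

    def test_split_and_anthocyanin_versions(self):
        assert set(("cab", "cc")) <= set(active_variables(Version.P5, False))
        assert "canth" in active_variables(Version.PD, False)
        assert "canth" not in active_variables(Version.P5, False)

    def test_brown_flag_adds_cbp(self):
        assert "cbp" not in active_variables(Version.PD, False)
        assert "cbp" in active_variables(Version.PD, True)
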