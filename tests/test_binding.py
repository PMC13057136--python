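"""Mass balance, occupancies and unit conversions of the binding layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnpaging import (
    BindingSystem,
    ReceptorState,
    bound_ligand,
    free_ligand,
    monomer_to_trimer,
    site_occupancies,
    trimer_to_monomer,
)


def bisect_free_ligand(l_total, active, kd, iters=200):
    """Independent bisection oracle for the free-ligand mass balance."""
    kd = np.asarray(kd)
    lo, hi = 0.0, l_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid + active * np.sum(mid / (kd + mid)) - l_total > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestFreeLigand:
    def test_zero_ligand_gives_zero(self, phosphate_system):
        assert free_ligand(0.0, ReceptorState(50.0), phosphate_system) == 0.0

    def test_zero_receptor_leaves_all_ligand_free(self, phosphate_system):
        assert free_ligand(10.0, ReceptorState(0.0), phosphate_system) == pytest.approx(10.0)
        # fully incompetent receptor behaves like no receptor
        state = ReceptorState(50.0, incompetent_fraction=0.999)
        near = free_ligand(10.0, state, phosphate_system)
        assert near == pytest.approx(10.0, rel=0.05)

    def test_agrees_with_bisection_oracle(self, phosphate_system):
        got = free_ligand(100.0, ReceptorState(50.0), phosphate_system)
        want = bisect_free_ligand(100.0, 50.0, phosphate_system.kd)
        assert got == pytest.approx(want, rel=1e-8)
        assert 0.0 <= got <= 100.0

    def test_one_site_matches_quadratic_closed_form(self):
        kd, active, l_tot = 25.0, 8.0, 30.0
        system = BindingSystem((kd,))
        b = kd + active - l_tot
        closed = (-b + np.sqrt(b * b + 4.0 * kd * l_tot)) / 2.0
        got = free_ligand(l_tot, ReceptorState(active), system)
        assert got == pytest.approx(closed, rel=1e-10)

    def test_monotone_in_total_ligand(self, phosphate_system):
        state = ReceptorState(50.0)
        grid = np.linspace(0, 500, 80)
        frees = [free_ligand(l, state, phosphate_system) for l in grid]
        assert np.all(np.diff(frees) >= 0)

    def test_rejects_negative_ligand(self, phosphate_system):
        with pytest.raises(ValueError):
            free_ligand(-1.0, ReceptorState(1.0), phosphate_system)


class TestOccupancies:
    def test_half_saturation_at_kd(self, phosphate_system):
        for i, kd in enumerate(phosphate_system.kd):
            assert site_occupancies(kd, phosphate_system)[i] == pytest.approx(0.5)

    def test_forced_values(self, phosphate_system):
        assert np.all(site_occupancies(0.0, phosphate_system) == 0.0)
        kd1 = phosphate_system.kd[0]
        assert site_occupancies(2 * kd1, phosphate_system)[0] == pytest.approx(2 / 3)

    def test_monotone_in_free_ligand(self, phosphate_system):
        grid = np.linspace(0, 1000, 50)
        theta = np.array([site_occupancies(l, phosphate_system) for l in grid])
        assert np.all(np.diff(theta, axis=0) >= 0)
        assert np.all(theta >= 0) and np.all(theta < 1)


class TestBoundLigand:
    def test_zero_and_saturation_limits(self, phosphate_system):
        state = ReceptorState(2.0)
        assert bound_ligand(0.0, state, phosphate_system) == 0.0
        sat = bound_ligand(1e7, state, phosphate_system)
        assert sat == pytest.approx(state.active_conc * phosphate_system.n_sites, rel=1e-3)

    def test_conservation_against_oracle(self, phosphate_system):
        state = ReceptorState(50.0, incompetent_fraction=0.1)
        l_tot = 140.0
        free = free_ligand(l_tot, state, phosphate_system)
        bound = bound_ligand(l_tot, state, phosphate_system)
        assert bound + free == pytest.approx(l_tot, rel=1e-9)
        assert free == pytest.approx(
            bisect_free_ligand(l_tot, state.active_conc, phosphate_system.kd), rel=1e-8
        )


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    n_sites=st.integers(1, 3),
    log_kd=st.lists(st.floats(-1, 4), min_size=3, max_size=3),
    active=st.floats(0.01, 1000.0),
    finc=st.floats(0.0, 0.9),
    l_total=st.floats(1e-6, 1e5),
)
def test_mass_conservation_property(n_sites, log_kd, active, finc, l_total):
    """free + bound always reconstructs total ligand to 1e-8 relative."""
    system = BindingSystem(tuple(10.0 ** k for k in log_kd[:n_sites]))
    state = ReceptorState(active, finc)
    free = free_ligand(l_total, state, system)
    bound = bound_ligand(l_total, state, system)
    assert abs(l_total - free - bound) / l_total < 1e-8


def test_unit_conversion_roundtrip():
    assert trimer_to_monomer(monomer_to_trimer(7.5)) == pytest.approx(7.5)
    assert monomer_to_trimer(3.0) == pytest.approx(1.0)


class TestValidation:
    def test_invalid_systems_rejected(self):
        with pytest.raises(ValueError):
            BindingSystem((1.0, -2.0))
        with pytest.raises(ValueError):
            BindingSystem((1.0,) * 4)
        with pytest.raises(ValueError):
            BindingSystem((1.0, 2.0), dh=(-1.0,))

    def test_invalid_receptor_rejected(self):
        with pytest.raises(ValueError):
            ReceptorState(-1.0)
        with pytest.raises(ValueError):
            ReceptorState(1.0, incompetent_fraction=1.0)

    def test_active_conc_never_exceeds_total(self):
        state = ReceptorState(10.0, 0.25)
        assert state.active_conc == pytest.approx(7.5)
        assert state.active_conc <= state.total_conc
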