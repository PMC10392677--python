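"""Deformation-energy model: fitting, evaluation, substates, mechanism."""

import numpy as np
import pytest

from dnamech import CONSTANTS, SyntheticSpec, generate_helical_ensemble
from dnamech import deformation_model as dm
from dnamech.helical_geometry import HelicalEnsemble
from dnamech.synthetic_data import VarianceScale, position_covariance


@pytest.fixture(scope="module")
def long_ensemble():
    spec = SyntheticSpec(n_frames=100_000, seed=42, ar1_tau=2.0)
    return spec, generate_helical_ensemble(spec)


@pytest.fixture(scope="module")
def harmonic_model(long_ensemble):
    _, ens = long_ensemble
    return dm.fit_model(ens, n_substates=1)


class TestFitting:
    def test_single_gaussian_parameter_recovery(self, long_ensemble, harmonic_model):
        spec, ens = long_ensemble
        contexts = dm.step_contexts(dm.annotated_sequence(ens))
        j = 20                               # interior step, unique context
        cm = harmonic_model.context_for(contexts[j - 1])
        assert cm.n_substates == 1
        truth_cov = position_covariance(spec, j)
        truth_F = CONSTANTS.kT_ref * np.linalg.inv(truth_cov)
        from dnamech.synthetic_data import equilibrium_means
        intra_mean, step_mean, _ = equilibrium_means(spec)
        truth_x0 = np.concatenate([intra_mean[j], step_mean[j - 1]])
        sub = cm.substates[0]
        scale = np.sqrt(np.diag(truth_cov))
        assert np.max(np.abs(sub.x0 - truth_x0) / scale) < 0.05
        rel = np.linalg.norm(sub.F - truth_F) / np.linalg.norm(truth_F)
        assert rel < 0.05

    def test_two_planted_substates_recovered(self):
        # hand-built bimodal ensemble: two well-separated Gaussian wells
        rng = np.random.default_rng(0)
        n, n_bp = 20_000, 6
        seq = "ATGATA"
        weights = (0.7, 0.3)
        step = np.zeros((n, n_bp - 1, 6))
        bp = np.zeros((n, n_bp, 8))
        which = rng.random(n) < weights[1]
        for j in range(n_bp - 1):
            base = np.array([0, 0, 3.3, 0, 2.0, 34.0])
            x = base + rng.normal(0, 0.3, size=(n, 6)) * [1, 1, 0.5, 5, 5, 5]
            x[which, 5] += 12.0               # second twist substate
            step[:, j, :] = x
        bp[:, :, :6] = rng.normal(0, 1.0, size=(n, n_bp, 6))
        ens = HelicalEnsemble(sequence=seq, times=np.arange(n, dtype=float),
                              step_params=step, bp_params=bp)
        model = dm.fit_model(ens, n_substates=2, min_frames=100)
        for cm in model.contexts.values():
            w = sorted(s.weight for s in cm.substates)
            assert w[0] == pytest.approx(0.3, abs=0.02)
            assert w[1] == pytest.approx(0.7, abs=0.02)

    def test_independent_neighbours_have_zero_coupling(self, long_ensemble):
        _, ens = long_ensemble
        model = dm.fit_model(ens.__class__(
            sequence=ens.sequence, times=ens.times[:20000],
            step_params=ens.step_params[:20000],
            bp_params=ens.bp_params[:20000]), n_substates=2)
        for J in model.coupling.values():
            assert np.max(J - J.min()) < 0.05 + 1e-9
            assert np.all(np.abs(J) < 0.1)

    def test_json_round_trip(self, harmonic_model, tmp_path):
        path = tmp_path / "model.json"
        harmonic_model.to_json(path)
        back = dm.DeformationModel.from_json(path)
        key = next(iter(harmonic_model.contexts))
        np.testing.assert_allclose(back.contexts[key].substates[0].F,
                                   harmonic_model.contexts[key].substates[0].F)
        assert back.temperature == harmonic_model.temperature


class TestEnergy:
    def _hand_model(self, F11=2.0):
        F = np.eye(12)
        F[0, 0] = F11
        sub = dm.Substate(weight=1.0, x0=np.zeros(12), F=F,
                          covariance=np.linalg.inv(F) * CONSTANTS.kT_ref,
                          offset=0.0)
        cm = dm.ContextModel("XXXX", [sub])
        return dm.DeformationModel(contexts={"XXXX": cm}, coupling={})

    def test_configuration_at_equilibrium_costs_nothing(self):
        model = self._hand_model()
        x = np.zeros((1, 1, 12))
        e = dm.evaluate_frames(model, x, ["XXXX"], np.array([0]))
        assert e[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_quadratic_form(self):
        # displacement (1, 0, ..., 0) against F with F11 = 2 -> 1 kcal/mol
        model = self._hand_model(F11=2.0)
        x = np.zeros((1, 1, 12))
        x[0, 0, 0] = 1.0
        e = dm.evaluate_frames(model, x, ["XXXX"], np.array([0]))
        assert e[0] == pytest.approx(1.0, abs=1e-12)

    def test_region_outside_sequence_rejected(self, long_ensemble, harmonic_model):
        _, ens = long_ensemble
        with pytest.raises(ValueError):
            dm.energy(harmonic_model, ens, (40, 60))

    def test_equipartition_anchor(self, long_ensemble, harmonic_model):
        # thermal sampling of the single-substate model: (12/2) k_B T per
        # bp, the analytic anchor behind the ~4 kcal/mol*bp figure
        _, ens = long_ensemble
        rng = np.random.default_rng(7)
        e_bp = dm.thermal_energy_per_bp(harmonic_model, ens, (6, 35),
                                        100_000, rng)
        assert e_bp == pytest.approx(6.0 * CONSTANTS.kT_ref, rel=0.02)

    def test_energy_monotone_along_stiffness_eigenvector(self):
        model = self._hand_model()
        scales = [0.0, 0.5, 1.0, 2.0, 4.0]
        energies = []
        for s in scales:
            x = np.zeros((1, 1, 12))
            x[0, 0, 0] = s
            energies.append(dm.evaluate_frames(model, x, ["XXXX"],
                                               np.array([0]))[0])
        assert all(b > a for a, b in zip(energies, energies[1:]))


class TestProfiles:
    def test_inflated_variance_region_has_largest_per_bp_energy(self):
        base = SyntheticSpec(n_frames=4000, seed=3, ar1_tau=2.0)
        ref = generate_helical_ensemble(base)
        model = dm.fit_model(ref, n_substates=1)
        hot = base.replace(
            variance_scales=(VarianceScale(tuple(range(6, 16)), 1.6),),
            seed=4)
        ens = generate_helical_ensemble(hot)
        regions = {"e2f1dp1_site": (6, 15), "linker": (15, 26),
                   "cebpb_site": (26, 35)}
        profiles = dm.profile_regions(model, ens, regions)
        per_bp = {k: p.mean_per_bp for k, p in profiles.items()}
        assert per_bp["e2f1dp1_site"] > per_bp["linker"]
        assert per_bp["e2f1dp1_site"] > per_bp["cebpb_site"]

    def test_standard_error_scales_inverse_sqrt_frames(self):
        spec = SyntheticSpec(n_frames=8000, seed=5, ar1_tau=1.0)
        ens = generate_helical_ensemble(spec)
        model = dm.fit_model(ens, n_substates=1)
        profiles = dm.profile_regions(model, ens, {"full": (6, 35)})
        prof = profiles["full"]
        assert prof.se == pytest.approx(prof.sd / np.sqrt(len(prof.energies)))
        short = dm.DeformationProfile(region=prof.region, label="short",
                                      energies=prof.energies[:2000],
                                      n_bp=prof.n_bp)
        assert short.se > 1.5 * prof.se


@pytest.mark.parametrize("e_bound,e_naked,expected", [
    (8.2, 4.0, dm.MECHANISM_INDUCED_FIT),
    (3.9, 4.0, dm.MECHANISM_CONFORMATIONAL_SELECTION),
    (4.5, 4.0, dm.MECHANISM_MIXED),
    (8.0, 4.0, dm.MECHANISM_INDUCED_FIT),        # exactly double
    (4.0, 4.0, dm.MECHANISM_CONFORMATIONAL_SELECTION),
])
def test_mechanism_trichotomy(e_bound, e_naked, expected):
    assert dm.classify_mechanism(e_bound, e_naked) == expected


def test_mechanism_rejects_negative_energies():
    with pytest.raises(ValueError):
        dm.classify_mechanism(-1.0, 4.0)
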