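import math

import numpy as np
import pytest

from soubakit.pre import (
    PREError,
    PREParams,
    PREPrediction,
    PREProfile,
    SpinLabelError,
    SpinLabelSite,
    attach_spin_label,
    compare_pre,
    gamma2,
    intensity_ratio,
    predict_attenuation,
    read_pre_profile,
    significant_regions,
    write_pre_profile,
)
from soubakit.synthetic import simulate_pre_observed


def _hand_ratio(r, params):
    """Independent closed-form evaluation of the attenuation model."""
    omega = 2 * math.pi * params.h_freq_mhz * 1e6
    g = (params.k_sb / r ** 6) * (4 * params.tau_c_s
                                  + 3 * params.tau_c_s
                                  / (1 + omega ** 2 * params.tau_c_s ** 2))
    return params.r2_s * math.exp(-g * params.total_time_s) / (params.r2_s + g)


def _ratio_threshold_radius(params, threshold):
    """Distance at which the predicted ratio crosses the threshold."""
    lo, hi = 1.0, 100.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if intensity_ratio(mid, params) < threshold:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# label placement
# ---------------------------------------------------------------------------

class TestAttachSpinLabel:
    def test_label_lies_on_the_ca_cb_ray(self, docked_model):
        site = attach_spin_label(docked_model, "U1", 6)
        ca = docked_model.structure.atom("U1", 6, "CA").coords
        cb = docked_model.structure.atom("U1", 6, "CB").coords
        direction = (cb - ca) / np.linalg.norm(cb - ca)
        np.testing.assert_allclose(site.position, cb + 6.0 * direction,
                                   atol=1e-9)
        assert (site.copy_id, site.residue) == ("U1", 6)

    def test_missing_residue_is_an_error(self, docked_model):
        with pytest.raises(SpinLabelError, match="999"):
            attach_spin_label(docked_model, "U1", 999)
        with pytest.raises(SpinLabelError, match="U9"):
            attach_spin_label(docked_model, "U9", 6)


# ---------------------------------------------------------------------------
# attenuation model
# ---------------------------------------------------------------------------

class TestAttenuationModel:
    def test_matches_hand_evaluation_at_15_A(self):
        params = PREParams()
        assert intensity_ratio(15.0, params) == pytest.approx(
            _hand_ratio(15.0, params), abs=1e-12)

    def test_far_nuclei_barely_attenuated(self):
        assert intensity_ratio(40.0, PREParams()) > 0.95

    def test_contact_limit_is_full_attenuation(self):
        assert intensity_ratio(0.0, PREParams()) == 0.0
        assert intensity_ratio(1e-6, PREParams()) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_strictly_increasing_in_distance(self):
        params = PREParams()
        # below ~5 Å the exponential underflows to exactly 0, so start
        # where the ratio is representable in double precision
        ratios = [intensity_ratio(r, params) for r in np.linspace(5, 60, 80)]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_strictly_decreasing_in_time(self):
        ratios = [intensity_ratio(18.0, PREParams(total_time_s=t))
                  for t in (0.002, 0.01, 0.05)]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_inactivated_probe_gives_unit_ratio(self, docked_model):
        """With the label reduced (K_SB -> 0), every residue keeps full
        intensity — the ascorbic-acid diamagnetic control."""
        site = attach_spin_label(docked_model, "U1", 6)
        pred = predict_attenuation(docked_model, site, PREParams(k_sb=0.0))
        unflagged = [v for r, v in pred.values.items()
                     if r not in pred.flagged]
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in unflagged)


# ---------------------------------------------------------------------------
# region calls
# ---------------------------------------------------------------------------

class TestSignificantRegions:
    def test_flat_profile_has_no_regions(self):
        profile = PREProfile({i: 1.0 for i in range(1, 50)})
        assert significant_regions(profile) == []

    def test_constructed_dips_are_found(self):
        values = {i: 1.0 for i in range(1, 100)}
        for span in (range(20, 25), range(50, 54), range(80, 86)):
            for i in span:
                values[i] = 0.3
        profile = PREProfile(values)
        assert significant_regions(profile) == [(20, 24), (50, 53), (80, 85)]

    def test_single_residue_dips_filtered_by_min_run(self):
        values = {i: 1.0 for i in range(1, 30)}
        values[10] = 0.1
        assert significant_regions(PREProfile(values), min_run=2) == []

    def test_invariant_under_renumbering_offset(self):
        values = {i: (0.3 if 10 <= i <= 14 else 1.0) for i in range(1, 30)}
        shifted = {i + 200: v for i, v in values.items()}
        a = significant_regions(PREProfile(values))
        b = significant_regions(PREProfile(shifted))
        assert [(s - 200, e - 200) for s, e in b] == a

    def test_predicted_regions_match_distance_field_oracle(self, docked_model):
        """Significant regions on the model equal the contiguous runs of
        receptor amides within the threshold-crossing radius of the label."""
        params = PREParams()
        threshold = 0.7
        site = attach_spin_label(docked_model, "U1", 6)
        pred = predict_attenuation(docked_model, site, params)
        regions = significant_regions(pred, threshold)

        radius = _ratio_threshold_radius(params, threshold)
        from soubakit.pre import _amide_position
        receptor = docked_model.receptor
        near = []
        for chain in receptor.chains():
            prev = None
            for rn in receptor.residue_numbers(chain):
                if receptor.residue_name(chain, rn) != "PRO":
                    amide = _amide_position(receptor, chain, rn, prev)
                    if np.linalg.norm(amide - site.position) < radius:
                        near.append(rn)
                prev = rn
        from .oracles import enumerate_regions
        expected = [(a, b) for a, b in enumerate_regions(sorted(near), 0)
                    if b - a + 1 >= 2] if near else []
        assert regions == expected
        assert regions, "the contact-face label should attenuate something"

    def test_far_label_produces_no_regions(self, docked_model):
        """Labels on the face opposite the binding patch (the D39C/S57C
        analogues) are > 25 Å from every receptor amide: no regions."""
        for residue in (39, 57):
            site = attach_spin_label(docked_model, "U1", residue)
            pred = predict_attenuation(docked_model, site)
            assert significant_regions(pred) == []


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

class TestComparePRE:
    def test_identical_profiles_agree_perfectly(self, docked_model):
        site = attach_spin_label(docked_model, "U1", 6)
        pred = predict_attenuation(docked_model, site)
        observed = PREProfile({r: pred.values[r] for r in pred.residues()
                               if r not in pred.flagged})
        residuals, jaccard = compare_pre(observed, pred)
        assert jaccard == 1.0
        assert all(v == 0.0 for v in residuals.values())

    def test_disjoint_region_sets_score_zero(self):
        n = 40
        obs = PREProfile({i: (0.2 if i < 10 else 1.0) for i in range(1, n)})
        pred_values = {i: (0.2 if i > 30 else 1.0) for i in range(1, n)}
        pred = PREPrediction(pred_values, PREParams(),
                             SpinLabelSite("U1", 6, np.zeros(3)))
        _, jaccard = compare_pre(obs, pred)
        assert jaccard == 0.0

    def test_noisy_recovery_jaccard(self, docked_model):
        site = attach_spin_label(docked_model, "U1", 6)
        pred = predict_attenuation(docked_model, site)
        observed = simulate_pre_observed(docked_model, site,
                                         noise_sigma=0.05, seed=17)
        _, jaccard = compare_pre(observed, pred)
        assert jaccard >= 0.8

    def test_insufficient_overlap_is_an_error(self):
        obs = PREProfile({i: 1.0 for i in range(5)})
        pred = PREPrediction({i: 1.0 for i in range(100, 105)}, PREParams(),
                             SpinLabelSite("U1", 6, np.zeros(3)))
        with pytest.raises(PREError, match="shared"):
            compare_pre(obs, pred)


def test_profile_tsv_roundtrip(tmp_path, docked_model):
    site = attach_spin_label(docked_model, "U1", 6)
    observed = simulate_pre_observed(docked_model, site, 0.05, seed=3)
    path = tmp_path / "pre.tsv"
    write_pre_profile(observed, path)
    back = read_pre_profile(path)
    assert back.residues() == observed.residues()
    for r in back.residues():
        assert back.values[r] == pytest.approx(observed.values[r], abs=5e-5)
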