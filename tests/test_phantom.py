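"""Digital phantom, scan sessions, and the conventional comparator arm."""

import numpy as np
import pytest

from mrfmorph.phantom import (
    CORTICAL_LABEL,
    SUBCORTICAL_LABELS,
    ConventionalBias,
    RigidTransform,
    conventional_arm,
    generate_phantom,
    session_signal_volume,
    simulate_session,
)
from mrfmorph.regions import region_volumes, shell_thickness
from mrfmorph.stats import bland_altman


@pytest.fixture(scope="module")
def phantom32():
    return generate_phantom((32, 32, 32), seed=11)


class TestGeneratePhantom:
    def test_deterministic_given_seed(self):
        a = generate_phantom((32, 32, 32), seed=3)
        b = generate_phantom((32, 32, 32), seed=3)
        assert np.array_equal(a.labels, b.labels)
        assert a.tissue_table.equals(b.tissue_table)

    def test_all_structures_populated(self, phantom32):
        present = set(np.unique(phantom32.labels)) - {0}
        assert present == set(phantom32.tissue_table.region_id)
        for lab in SUBCORTICAL_LABELS:
            assert (phantom32.labels == lab).sum() > 0

    def test_cohort_has_between_subject_variance(self):
        vols = []
        for seed in range(1, 13):
            p = generate_phantom((32, 32, 32), seed=seed)
            df = region_volumes(p.labels)
            vols.append(df.loc[df.region_id == 2, "volume_mm3"].item())
        vols = np.asarray(vols)
        assert vols.std() / vols.mean() > 0.0

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom((16, 16, 16), seed=0)

    def test_property_fields_cover_mask(self, phantom32):
        t1, t2 = phantom32.property_fields()
        assert np.all(t1[phantom32.mask] > 0)
        assert np.all(t2[phantom32.mask] > 0)
        assert np.all(t1[~phantom32.mask] == 0)


class TestSimulateSession:
    def test_noiseless_identity_sessions_are_identical(self, phantom32, short_schedule):
        s1 = simulate_session(phantom32, None, 0.0, seed=1)
        s2 = simulate_session(phantom32, None, 0.0, seed=99)
        v1 = session_signal_volume(s1, short_schedule)
        v2 = session_signal_volume(s2, short_schedule)
        assert np.array_equal(v1, v2)

    def test_identity_session_preserves_labels(self, phantom32):
        s = simulate_session(phantom32, None, 0.0, seed=0)
        assert np.array_equal(s.labels, phantom32.labels)

    def test_small_transform_small_volume_change(self):
        p = generate_phantom((48, 48, 48), seed=2)
        s = simulate_session(p, RigidTransform((1.0, 0, 0), (1.0, 0, 0)), 0.0, seed=0)
        v0 = region_volumes(p.labels).set_index("region_id").volume_mm3
        v1 = region_volumes(s.labels).set_index("region_id").volume_mm3
        for rid in (1, 2, 3):
            assert abs(v1[rid] - v0[rid]) / v0[rid] < 0.05

    def test_forward_then_match_recovers_truth(
        self, phantom32, short_schedule, reduced_dictionary
    ):
        """Noiseless identity session matched against the dictionary gives
        region-mean T1/T2 within one grid step of ground truth."""
        from mrfmorph.matching import match_volume
        from mrfmorph.regions import region_relaxometry

        session = simulate_session(phantom32, None, 0.0, seed=0)
        signals = session_signal_volume(session, short_schedule)
        maps = match_volume(signals, reduced_dictionary, session.mask)
        df = region_relaxometry(maps, session.labels).set_index("region_id")
        t1_axis = np.unique(reduced_dictionary.t1_lookup_ms)
        t2_axis = np.unique(reduced_dictionary.t2_lookup_ms)
        for row in phantom32.tissue_table.itertuples():
            step1 = np.max(np.diff(t1_axis[np.searchsorted(t1_axis, row.t1_ms) - 1 :][:3]))
            step2 = np.max(np.diff(t2_axis[np.searchsorted(t2_axis, row.t2_ms) - 1 :][:3]))
            assert abs(df.mean_t1_ms[row.region_id] - row.t1_ms) <= step1
            assert abs(df.mean_t2_ms[row.region_id] - row.t2_ms) <= step2


class TestConventionalArm:
    def test_zero_bias_equals_ground_truth(self, phantom32):
        bias = ConventionalBias(0.0, 0.0, 0.0, 0.0)
        df = conventional_arm(phantom32, bias, seed=0).set_index(["region_id", "metric"])
        vols = region_volumes(phantom32.labels).set_index("region_id")
        for rid in vols.index:
            assert df.loc[(rid, "volume_mm3"), "value"] == pytest.approx(
                vols.volume_mm3[rid]
            )
        gt_th = shell_thickness(phantom32.labels == CORTICAL_LABEL, 1.0)
        assert df.loc[(CORTICAL_LABEL, "thickness_mm"), "value"] == pytest.approx(gt_th)

    def test_injected_bias_is_exact_without_noise(self, phantom32):
        clean = conventional_arm(phantom32, ConventionalBias(0.0, 0.0, 0.0, 0.0), 0)
        biased = conventional_arm(phantom32, ConventionalBias(0.17, 0.0, 0.0, 0.0), 0)
        th0 = clean[clean.metric == "thickness_mm"].value.item()
        th1 = biased[biased.metric == "thickness_mm"].value.item()
        assert th1 - th0 == pytest.approx(0.17, abs=1e-12)

    def test_bias_recovered_within_ci_across_cohort(self):
        """n=20 subjects, noisy thickness: Bland-Altman bias estimate of the
        0.17 mm offset lies within its own 95% CI."""
        bias = ConventionalBias(0.17, 0.0, thickness_noise_sd_mm=0.05)
        pairs = []
        for seed in range(1, 21):
            p = generate_phantom((32, 32, 32), seed=seed)
            gt = shell_thickness(p.labels == CORTICAL_LABEL, 1.0)
            conv = conventional_arm(p, bias, seed=100 + seed)
            pairs.append((conv[conv.metric == "thickness_mm"].value.item(), gt))
        est, lo, hi = bland_altman(np.asarray(pairs))
        sd = (hi - est) / 1.96
        ci_half = 1.96 * sd / np.sqrt(len(pairs))
        assert abs(est - 0.17) <= ci_half
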