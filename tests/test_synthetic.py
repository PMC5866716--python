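"""Synthetic landscape generator: determinism, proportions, signatures,
reference-area placement."""

import numpy as np
import pytest

from wetlandchange.raster import Grid, HabitatMap
from wetlandchange.synthetic import (
    ClassSignature,
    SceneConfig,
    default_signatures,
    generate_label_map,
    render_reflectance,
    render_cube,
    sample_reference_areas,
    two_date_scenario,
)

SPEC_PROPS = {1: 0.08, 2: 0.0, 3: 0.06, 4: 0.15, 5: 0.03, 6: 0.27, 7: 0.25,
              8: 0.16}


def _cfg(**kw):
    kw.setdefault("classes", default_signatures())
    return SceneConfig(**kw)


class TestLabelMap:
    def test_single_class_is_uniform(self):
        sig = default_signatures()[:1]
        cfg = SceneConfig(rows=20, cols=20, classes=sig)
        m = generate_label_map(cfg)
        assert (m.labels == sig[0].class_id).all()

    def test_same_seed_bit_identical(self):
        cfg = _cfg(rows=60, cols=60, target_proportions=SPEC_PROPS, seed=3)
        a = generate_label_map(cfg)
        b = generate_label_map(cfg)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_different_seed_differs(self):
        a = generate_label_map(_cfg(rows=60, cols=60, seed=1))
        b = generate_label_map(_cfg(rows=60, cols=60, seed=2))
        assert (a.labels != b.labels).any()

    def test_proportions_recovered_within_5_points(self):
        """Brute-force pixel counting on a 200x200 eight-class map."""
        cfg = _cfg(rows=200, cols=200, target_proportions=SPEC_PROPS, seed=11)
        m = generate_label_map(cfg)
        n = m.labels.size
        for cid, target in SPEC_PROPS.items():
            realized = np.count_nonzero(m.labels == cid) / n
            assert abs(realized - target) <= 0.05, (cid, realized, target)
        # zero-target class gets no pixels at all
        assert np.count_nonzero(m.labels == 2) == 0

    def test_proportions_converge_at_400(self):
        cfg = _cfg(rows=400, cols=400, target_proportions=SPEC_PROPS, seed=5)
        m = generate_label_map(cfg)
        n = m.labels.size
        for cid, target in SPEC_PROPS.items():
            realized = np.count_nonzero(m.labels == cid) / n
            assert abs(realized - target) <= 0.02

    def test_patches_are_spatially_coherent(self):
        """Neighbouring pixels agree far more often than random labels would."""
        cfg = _cfg(rows=100, cols=100, seed=2, patch_scale=6)
        m = generate_label_map(cfg)
        agree = np.mean(m.labels[:, 1:] == m.labels[:, :-1])
        assert agree > 0.8

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            _cfg(rows=10, cols=10,
                 target_proportions={s.class_id: 0.5 for s in default_signatures()})

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError, match="class list"):
            SceneConfig(rows=10, cols=10, classes=[])


class TestReflectance:
    def test_zero_noise_equals_class_means(self):
        sigs = default_signatures(noise_sd=0.0)
        cfg = SceneConfig(rows=30, cols=30, classes=sigs, seed=4)
        truth = generate_label_map(cfg)
        img = render_reflectance(truth, cfg, season=0, seed=9)
        means = {s.class_id: s.means()[0] for s in sigs}
        for cid, mu in means.items():
            mask = truth.labels == cid
            if mask.any():
                for b in range(len(cfg.bands)):
                    assert np.allclose(img[b][mask], mu[b])

    def test_unknown_label_raises_with_label_name(self):
        cfg = _cfg(rows=5, cols=5)
        truth = HabitatMap(np.full((5, 5), 99), {99: "mystery"}, Grid(5, 5))
        with pytest.raises(ValueError, match="99"):
            render_reflectance(truth, cfg, season=0, seed=0)

    def test_noisy_sample_mean_near_class_mean(self):
        """Sampling-distribution check: mean within 3*sd/sqrt(n)."""
        sd = 0.02
        sigs = default_signatures(noise_sd=sd)
        cfg = SceneConfig(rows=60, cols=60, classes=sigs, seed=8)
        truth = generate_label_map(cfg)
        img = render_reflectance(truth, cfg, season=1, seed=21)
        for sig in sigs:
            mask = truth.labels == sig.class_id
            n = mask.sum()
            if n < 1000:
                continue
            for b, mu in enumerate(sig.means()[1]):
                tol = 3 * sd / np.sqrt(n)
                assert abs(img[b][mask].mean() - mu) < tol + 1e-12

    def test_reflectance_clipped_to_unit_interval(self):
        sigs = [ClassSignature(1, "x", ((0.99,) * 6, (0.01,) * 6), (0.5,) * 6)]
        cfg = SceneConfig(rows=20, cols=20, classes=sigs, seed=0)
        truth = generate_label_map(cfg)
        cube = render_cube(truth, cfg, seed=1)
        assert cube.values.min() >= 0.0 and cube.values.max() <= 1.0

    def test_signatures_separated_by_five_noise_sds(self):
        """Any two default classes differ by >= 5 x 0.02 in some season/band."""
        sigs = default_signatures(noise_sd=0.02)
        for i, a in enumerate(sigs):
            for b in sigs[i + 1:]:
                gap = np.abs(a.means() - b.means()).max()
                assert gap >= 5 * 0.02, (a.name, b.name, gap)


class TestReferenceAreas:
    # per-class (training, validation) counts of the published two-year design
    TABLE2_2003 = {1: (38, 30), 3: (48, 29), 4: (64, 61), 5: (21, 22),
                   6: (46, 29), 7: (31, 55), 8: (34, 33), 2: (0, 0)}

    def test_published_sampling_design_totals(self):
        """282 training and 259 validation areas, matched exactly."""
        cfg = _cfg(rows=220, cols=220, target_proportions=SPEC_PROPS, seed=13)
        truth = generate_label_map(cfg)
        areas = sample_reference_areas(truth, self.TABLE2_2003, min_area=1,
                                       max_area=9, seed=3)
        counts = areas.counts()
        n_train = sum(v for (c, r), v in counts.items() if r == "training")
        n_valid = sum(v for (c, r), v in counts.items() if r == "validation")
        assert (n_train, n_valid) == (282, 259)
        for cid, (nt, nv) in self.TABLE2_2003.items():
            assert counts.get((cid, "training"), 0) == nt
            assert counts.get((cid, "validation"), 0) == nv

    def test_polygons_homogeneous_exhaustive(self):
        """Every pixel covered by a polygon has that polygon's class."""
        from wetlandchange.sampling import covered_pixels

        cfg = _cfg(rows=90, cols=90, seed=6)
        truth = generate_label_map(cfg)
        areas = sample_reference_areas(truth, {c: 10 for c in truth.legend},
                                       seed=5)
        assert len(areas) == 10 * len(truth.legend)
        for poly in areas:
            rr, cc = covered_pixels(poly.geometry, truth.grid)
            assert len(rr) > 0
            assert (truth.labels[rr, cc] == poly.class_id).all()

    def test_absent_class_raises(self):
        cfg = _cfg(rows=40, cols=40, target_proportions=SPEC_PROPS, seed=1)
        truth = generate_label_map(cfg)  # class 2 has zero pixels
        with pytest.raises(ValueError, match="class 2"):
            sample_reference_areas(truth, {2: 3})

    def test_deterministic_given_seed(self):
        cfg = _cfg(rows=60, cols=60, seed=9)
        truth = generate_label_map(cfg)
        a = sample_reference_areas(truth, {c: 5 for c in truth.legend}, seed=2)
        b = sample_reference_areas(truth, {c: 5 for c in truth.legend}, seed=2)
        assert [(p.geometry.bounds, p.class_id, p.role) for p in a] == \
               [(p.geometry.bounds, p.class_id, p.role) for p in b]


def test_two_date_scenario_structure(small_scenario):
    assert set(small_scenario) == {"date1", "date2"}
    d1, d2 = small_scenario["date1"], small_scenario["date2"]
    assert d1.truth.grid == d2.truth.grid
    # burned areas only appear at the second date
    assert np.count_nonzero(d1.truth.labels == 2) == 0
    assert np.count_nonzero(d2.truth.labels == 2) > 0
    # correlated fields: most of the landscape persists between dates
    assert np.mean(d1.truth.labels == d2.truth.labels) > 0.5
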