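"""Section joining, masking, cohort cleaning and intensity correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sichml.cohort import LatentTruth, Side
from sichml.phantom import GridSpec, brain_mask, render_ct, render_template_sections
from sichml.preprocess import (
    CTSection,
    RegistrationError,
    SectionKind,
    UNSAMPLED,
    _rigid_resample,
    apply_brain_mask,
    clean_cohort,
    global_intensity_correct,
    join_sections,
    load_matrix,
    mask_voxel_index,
    normalize_section,
    save_matrix,
)


def _section(values, z0, kind=SectionKind.UPPER):
    return CTSection(voxels=np.asarray(values, dtype=float),
                     spacing=(1.0, 1.0, 1.0), origin_offset=z0,
                     section_kind=kind)


class TestJoin:
    def test_overlap_takes_mean(self):
        upper = _section(np.full((2, 2, 3), 30.0), z0=1)
        lower = _section(np.full((2, 2, 2), 34.0), z0=0, kind=SectionKind.LOWER)
        joined = join_sections(upper, lower)
        assert joined.voxels[0, 0, 1] == pytest.approx(32.0)   # sampled twice
        assert joined.sample_count[0, 0, 1] == 2

    def test_single_section_voxel_kept_verbatim(self):
        upper = _section(np.full((2, 2, 2), 30.0), z0=2)
        lower = _section(np.full((2, 2, 2), 41.0), z0=0, kind=SectionKind.LOWER)
        joined = join_sections(upper, lower)
        assert joined.voxels[1, 1, 0] == 41.0
        assert joined.sample_count[1, 1, 0] == 1

    def test_unsampled_gap_carries_sentinel(self):
        upper = _section(np.full((2, 2, 2), 30.0), z0=3)
        lower = _section(np.full((2, 2, 2), 41.0), z0=0, kind=SectionKind.LOWER)
        joined = join_sections(upper, lower)
        assert joined.sample_count[0, 0, 2] == 0
        assert np.isnan(joined.voxels[0, 0, 2])

    def test_full_overlap_identical_values_roundtrip(self):
        vals = np.arange(24, dtype=float).reshape(2, 3, 4) + 10
        upper = _section(vals, z0=0)
        lower = _section(vals.copy(), z0=0, kind=SectionKind.LOWER)
        joined = join_sections(upper, lower)
        mask = np.ones((2, 3, 4), dtype=bool)
        assert np.array_equal(apply_brain_mask(joined, mask),
                              vals.reshape(-1, order="F"))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            join_sections(_section(np.zeros((2, 2, 2)), 0),
                          _section(np.zeros((3, 2, 2)), 0, SectionKind.LOWER))


class TestMask:
    def test_empty_mask_rejected(self):
        joined = join_sections(_section(np.zeros((2, 2, 2)), 0),
                               _section(np.zeros((2, 2, 2)), 0, SectionKind.LOWER))
        with pytest.raises(ValueError):
            apply_brain_mask(joined, np.zeros((2, 2, 2), dtype=bool))

    def test_single_voxel_mask(self):
        vals = np.arange(8, dtype=float).reshape(2, 2, 2)
        joined = join_sections(_section(vals, 0),
                               _section(vals, 0, SectionKind.LOWER))
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[1, 0, 1] = True
        assert apply_brain_mask(joined, mask) == pytest.approx([vals[1, 0, 1]])

    def test_vector_length_equals_mask_cardinality(self, small_grid,
                                                   featureless_truth):
        mask = brain_mask(small_grid)
        upper, lower = render_ct(featureless_truth, small_grid, 0.0, seed=0)
        vec = apply_brain_mask(join_sections(upper, lower), mask)
        assert len(vec) == int(mask.sum())

    def test_voxel_index_order_is_x_fastest(self):
        mask = np.ones((3, 2, 2), dtype=bool)
        idx = mask_voxel_index(mask)
        assert idx[0].tolist() == [0, 0, 0]
        assert idx[1].tolist() == [1, 0, 0]   # x moves first
        assert idx[3].tolist() == [0, 1, 0]


def brute_force_clean(vectors, hu_low=0.0, hu_high=200.0, threshold=5):
    """Independent per-cell oracle for the cleaning rule."""
    vectors = np.asarray(vectors, dtype=float)
    n_subj, n_vox = vectors.shape
    is_anom = [[(np.isnan(vectors[s, v]) or vectors[s, v] < hu_low
                 or vectors[s, v] > hu_high) for v in range(n_vox)]
               for s in range(n_subj)]
    deleted = [v for v in range(n_vox)
               if sum(is_anom[s][v] for s in range(n_subj)) >= threshold]
    kept = [v for v in range(n_vox) if v not in deleted]
    out = np.empty((n_subj, len(kept)))
    for new_v, v in enumerate(kept):
        clean = [vectors[s, v] for s in range(n_subj) if not is_anom[s][v]]
        mean = sum(clean) / len(clean)
        for s in range(n_subj):
            out[s, new_v] = mean if is_anom[s][v] else vectors[s, v]
    return out, deleted


class TestClean:
    def test_column_anomalous_in_five_of_six_is_deleted(self):
        vectors = np.full((6, 3), 50.0)
        vectors[:5, 1] = 300.0
        matrix = clean_cohort(vectors, subject_threshold=5)
        assert matrix.values.shape == (6, 2)
        assert matrix.deleted_voxels[:, 0].tolist() == [1]

    def test_rare_anomalies_imputed_with_clean_mean(self):
        vectors = np.array([[10.0], [20.0], [30.0], [40.0], [-5.0], [250.0]])
        matrix = clean_cohort(vectors, subject_threshold=5)
        assert matrix.values[4, 0] == pytest.approx(25.0)
        assert matrix.values[5, 0] == pytest.approx(25.0)
        assert sorted(matrix.imputed_cells) == [(4, 0), (5, 0)]

    def test_all_clean_matrix_is_untouched(self):
        rng = np.random.default_rng(0)
        vectors = rng.uniform(10, 60, (8, 40))
        matrix = clean_cohort(vectors)
        assert np.array_equal(matrix.values, vectors)
        assert len(matrix.deleted_voxels) == 0
        assert matrix.imputed_cells == []

    def test_unsampled_sentinel_treated_as_anomalous(self):
        vectors = np.full((6, 2), 50.0)
        vectors[0, 0] = UNSAMPLED
        matrix = clean_cohort(vectors, subject_threshold=5)
        assert matrix.values[0, 0] == pytest.approx(50.0)
        assert matrix.imputed_cells == [(0, 0)]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            clean_cohort(np.zeros((3, 4)), subject_threshold=5)

    def test_cleaning_is_idempotent(self):
        rng = np.random.default_rng(1)
        vectors = rng.uniform(5, 190, (8, 30))
        vectors[0, 3] = -10.0
        vectors[1:6, 7] = 500.0
        once = clean_cohort(vectors)
        twice = clean_cohort(once.values)
        assert np.array_equal(once.values, twice.values)
        assert len(twice.deleted_voxels) == 0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_brute_force_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        vectors = rng.uniform(-50, 260, (8, 50))
        nan_cells = rng.random((8, 50)) < 0.05
        vectors[nan_cells] = UNSAMPLED
        matrix = clean_cohort(vectors, subject_threshold=5)
        expected, deleted = brute_force_clean(vectors, threshold=5)
        assert matrix.values == pytest.approx(expected)
        assert matrix.voxel_index.shape[0] + len(deleted) == 50

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_deletion_set_invariant_under_subject_permutation(self, seed):
        rng = np.random.default_rng(seed)
        vectors = rng.uniform(-40, 250, (8, 30))
        perm = rng.permutation(8)
        a = clean_cohort(vectors, subject_threshold=4)
        b = clean_cohort(vectors[perm], subject_threshold=4)
        assert np.array_equal(a.deleted_voxels, b.deleted_voxels)
        # imputation means are sums over subjects, so permuting the cohort
        # may change float summation order but nothing else
        assert b.values == pytest.approx(a.values[perm])


class TestIntensityCorrection:
    def test_rows_scaled_to_grand_mean(self):
        matrix = clean_cohort(np.array([[30.0] * 4, [60.0] * 4] * 3))
        corrected = global_intensity_correct(matrix)
        assert corrected.grand_mean == pytest.approx(45.0)
        assert corrected.values[0] == pytest.approx([45.0] * 4)
        assert corrected.values[1] == pytest.approx([45.0] * 4)

    def test_row_means_equalized_to_machine_precision(self):
        rng = np.random.default_rng(3)
        matrix = clean_cohort(rng.uniform(10, 90, (9, 25)))
        corrected = global_intensity_correct(matrix)
        means = corrected.values.mean(axis=1)
        assert np.all(np.abs(means / means[0] - 1) < 1e-9)

    def test_single_subject_unchanged(self):
        vectors = np.random.default_rng(0).uniform(10, 50, (5, 6))
        matrix = clean_cohort(vectors)
        corrected = global_intensity_correct(matrix)
        # every row lands on the grand mean; a cohort of identical rows is
        # left untouched
        uniform = clean_cohort(np.tile(vectors[:1], (5, 1)))
        assert global_intensity_correct(uniform).values == pytest.approx(
            uniform.values)


class TestRegistration:
    def test_zero_jitter_recovers_identity(self, small_grid, featureless_truth):
        template_upper, _ = render_template_sections(small_grid)
        upper, _ = render_ct(featureless_truth, small_grid, 0.5, seed=2,
                             jitter=False)
        _, transform = normalize_section(upper, template_upper,
                                         return_transform=True)
        assert np.all(np.abs(transform["shift"]) <= 0.5)

    def test_known_shift_recovered(self, small_grid, featureless_truth):
        template_upper, _ = render_template_sections(small_grid)
        upper, _ = render_ct(featureless_truth, small_grid, 0.5, seed=2,
                             jitter=False)
        shifted = CTSection(_rigid_resample(upper.voxels, np.array([2.0, 0, 0]), 0.0),
                            upper.spacing, upper.origin_offset, upper.section_kind)
        _, transform = normalize_section(shifted, template_upper,
                                         return_transform=True)
        assert transform["shift"][0] == pytest.approx(-2.0, abs=0.5)

    def test_structureless_input_fails(self, small_grid):
        template_upper, _ = render_template_sections(small_grid)
        rng = np.random.default_rng(0)
        noise = CTSection(rng.normal(0, 1, template_upper.shape),
                          (1.0, 1.0, 1.0), small_grid.upper_start,
                          SectionKind.UPPER)
        with pytest.raises(RegistrationError):
            normalize_section(noise, template_upper)


def test_matrix_roundtrip_through_disk(tmp_path):
    rng = np.random.default_rng(4)
    vectors = rng.uniform(0, 100, (6, 12))
    vectors[0, 0] = 300.0
    matrix = clean_cohort(vectors, subject_threshold=3)
    corrected = global_intensity_correct(matrix)
    save_matrix(corrected, tmp_path / "m")
    loaded = load_matrix(tmp_path / "m")
    assert loaded.values == pytest.approx(corrected.values)
    assert np.array_equal(loaded.voxel_index, corrected.voxel_index)
    assert loaded.imputed_cells == corrected.imputed_cells
    assert loaded.grand_mean == pytest.approx(corrected.grand_mean)
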