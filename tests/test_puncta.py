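"""Detection, synapse pairing, co-localization and the rotation null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from hdsynapse.puncta import (
    DetectionParams,
    PunctaField,
    SpotSet,
    coloc_fraction,
    count_synapses_per_plane,
    detect_puncta,
    pair_synapses,
    percent_of_reference,
    rotate_channel_90,
    summarize_animal,
)
from hdsynapse.synthgen import FieldSpec, gen_synapse_field
from hdsynapse.synthgen import _render_channel  # white-box rendering helper

from _oracles import max_matching_bruteforce


def spots(centers, field_id="f0", channel="x"):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        centers = np.empty((0, 3))
    return SpotSet(
        centers, np.full(len(centers), 0.1), np.ones(len(centers)),
        channel=channel, field_id=field_id,
    )


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_all_zero_channel_yields_empty_spotset():
    field = PunctaField(
        {"pre": np.zeros((4, 32, 32))}, voxel_size_um=(0.1, 0.1, 0.3)
    )
    with pytest.warns(UserWarning):
        assert len(detect_puncta(field, "pre")) == 0


def test_unknown_channel_raises():
    field = PunctaField({"pre": np.ones((2, 8, 8))}, voxel_size_um=(0.1, 0.1, 0.3))
    with pytest.raises(KeyError):
        detect_puncta(field, "post")


def test_detects_well_separated_spots_near_true_centers():
    """50 isolated spots at SNR 10: all found, centers within 0.1 μm."""
    rng = np.random.default_rng(0)
    # jittered grid guarantees >= 1 μm separation
    # stagger the two z-layers in-plane so no spot sits directly above another
    grid = [
        (1.0 + 1.8 * ix + 0.9 * iz, 1.0 + 1.8 * iy + 0.9 * iz, 0.6 + 0.8 * iz)
        for iz in range(2) for iy in range(5) for ix in range(5)
    ]
    centers = np.array(grid) + rng.uniform(-0.15, 0.15, (50, 3))
    voxel = (0.1, 0.1, 0.2)
    img = _render_channel(
        (12, 96, 96), centers, voxel, (0.08, 0.08, 0.16),
        snr=10.0, background=10.0, rng=rng,
    )
    field = PunctaField({"pre": img}, voxel_size_um=voxel)
    found = detect_puncta(field, "pre")
    assert len(found) == pytest.approx(50, abs=2)
    dist, _ = cKDTree(found.centers_um).query(centers, k=1)
    assert np.quantile(dist, 0.98) < 0.1


def test_component_below_min_volume_excluded():
    img = np.zeros((4, 24, 24))
    img[2, 12, 12] = 100.0          # one voxel = 0.003 μm³ < 0.02 μm³
    field = PunctaField({"c": img}, voxel_size_um=(0.1, 0.1, 0.3))
    params = DetectionParams(
        smoothing_sigma_um=0.0, threshold_method="fixed", threshold_value=50.0
    )
    assert len(detect_puncta(field, "c", params)) == 0
    # enlarge the blob past the minimum volume and it is kept
    img[2, 11:14, 11:14] = 100.0    # 9 voxels = 0.027 μm³
    assert len(detect_puncta(field, "c", params)) == 1


@pytest.mark.parametrize("method", ["otsu", "quantile"])
def test_counts_invariant_to_intensity_rescaling(small_field, method):
    field, _ = small_field
    params = DetectionParams(threshold_method=method, threshold_quantile=0.97)
    n_before = len(detect_puncta(field, "pre", params))
    scaled = PunctaField(
        {**field.intensities, "pre": field.intensities["pre"] * 7.5},
        voxel_size_um=field.voxel_size_um, field_id=field.field_id,
    )
    assert len(detect_puncta(scaled, "pre", params)) == n_before


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def test_pair_below_threshold_pairs():
    pairs = pair_synapses(spots([[0, 0, 0]]), spots([[0.25, 0, 0]]))
    assert pairs.count == 1


def test_pair_at_exact_threshold_is_excluded():
    """'Less than 0.3 μm' is strict: a pair at exactly 0.30 μm is no synapse."""
    pairs = pair_synapses(spots([[0, 0, 0]]), spots([[0.30, 0, 0]]))
    assert pairs.count == 0


def test_pairing_is_maximum_not_nearest_neighbor():
    """One pre near two posts plus a second pre: both pairs must be found."""
    pre = spots([[0, 0, 0], [0.45, 0, 0]])
    post = spots([[0.10, 0, 0], [0.20, 0, 0]])
    pairs = pair_synapses(pre, post)
    assert pairs.count == 2
    # pre1 must take the nearer post so pre2 can still reach post2
    assert dict(map(tuple, pairs.pairs)) == {0: 0, 1: 1}


def test_mismatched_field_ids_raise():
    with pytest.raises(ValueError):
        pair_synapses(spots([[0, 0, 0]], "f0"), spots([[0, 0, 0.1]], "f1"))


def test_pairing_matches_bruteforce_oracle(rng):
    """Assignment-based pairing equals exhaustive maximum matching."""
    for _ in range(100):
        na, nb = rng.integers(0, 13, size=2)
        a = rng.uniform(0, 1.5, (na, 3))
        b = rng.uniform(0, 1.5, (nb, 3))
        got = pair_synapses(spots(a), spots(b)).count
        assert got == max_matching_bruteforce(a, b, 0.3)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_pair_count_symmetric_and_monotone(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1.2, (rng.integers(1, 15), 3))
    b = rng.uniform(0, 1.2, (rng.integers(1, 15), 3))
    forward = pair_synapses(spots(a), spots(b)).count
    assert forward == pair_synapses(spots(b), spots(a)).count
    counts = [
        pair_synapses(spots(a), spots(b), d).count for d in (0.15, 0.3, 0.6)
    ]
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# co-localization
# ---------------------------------------------------------------------------

def test_coloc_empty_probe_is_zero_and_empty_reference_is_nan():
    ref = spots([[0, 0, 0]])
    assert coloc_fraction(ref, spots([])) == 0.0
    with pytest.warns(UserWarning):
        assert np.isnan(coloc_fraction(spots([]), ref))


def test_coloc_one_to_one_blocks_double_counting():
    ref = spots([[0, 0, 0], [0.1, 0, 0]])
    probe = spots([[0.05, 0, 0]])
    assert coloc_fraction(ref, probe) == 50.0
    assert coloc_fraction(ref, probe, mode="any_neighbor") == 100.0


def test_coloc_recovers_tag_fraction_above_chance():
    """Detected complement co-localization tracks the generated tag fraction.

    Across seeded fields the observed percentage must sit near tag fraction
    plus the small chance contribution from the complement background.
    """
    vals = []
    for s in range(15):
        spec = FieldSpec(seed=300 + s, complement_tag_fraction=0.5)
        field, _ = gen_synapse_field(spec)
        pre = detect_puncta(field, "pre")
        post = detect_puncta(field, "post")
        pairs = pair_synapses(pre, post)
        comp = detect_puncta(field, "complement")
        vals.append(coloc_fraction(pairs, comp))
    assert 40.0 < np.mean(vals) < 65.0


# ---------------------------------------------------------------------------
# rotation null
# ---------------------------------------------------------------------------

def test_four_rotations_restore_channel(small_field):
    field, _ = small_field
    rotated = field
    for _ in range(4):
        rotated = rotate_channel_90(rotated, "complement")
    np.testing.assert_array_equal(
        rotated.intensities["complement"], field.intensities["complement"]
    )
    np.testing.assert_array_equal(
        rotated.intensities["pre"], field.intensities["pre"]
    )


def test_rotation_center_crops_non_square():
    field = PunctaField(
        {"c": np.arange(2 * 10 * 16, dtype=float).reshape(2, 10, 16)},
        voxel_size_um=(0.1, 0.1, 0.3),
    )
    rotated = rotate_channel_90(field, "c")
    assert rotated.shape == (2, 10, 10)


def test_rotation_estimates_chance_level():
    """Rotating the complement channel destroys real co-localization.

    With a 0.5 tag fraction the rotated measurement must fall below the
    unrotated one in nearly all fields, and the rotated level must sit near
    the analytic chance rate for an independent probe.
    """
    below, rotated_levels = 0, []
    n_fields = 25
    for s in range(n_fields):
        spec = FieldSpec(
            field_size_um=(9.6, 9.6, 3.0), seed=600 + s,
            complement_tag_fraction=0.5,
        )
        field, _ = gen_synapse_field(spec)
        pre = detect_puncta(field, "pre")
        post = detect_puncta(field, "post")
        observed = coloc_fraction(pair_synapses(pre, post),
                                  detect_puncta(field, "complement"))
        rot = rotate_channel_90(field, "complement")
        chance = coloc_fraction(
            pair_synapses(detect_puncta(rot, "pre"), detect_puncta(rot, "post")),
            detect_puncta(rot, "complement"),
        )
        rotated_levels.append(chance)
        below += chance < observed
    assert below >= int(0.9 * n_fields)
    # chance of >= 1 independent probe within r of a synapse:
    # 1 - exp(-rho * 4/3 pi r^3), with rho = tagged + background density
    spec = FieldSpec(complement_tag_fraction=0.5)
    rho = (
        spec.complement_background_density
        + spec.pre_density * spec.coloc_fraction * spec.complement_tag_fraction
    )
    p_chance = 100 * (1 - np.exp(-rho * 4 / 3 * np.pi * 0.3**3))
    assert np.mean(rotated_levels) == pytest.approx(p_chance, abs=3.0)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summarize_nine_planes():
    counts = {"f1": [1, 2, 3], "f2": [4, 5, 6], "f3": [7, 8, 9]}
    summary = summarize_animal(counts)
    assert summary.per_animal_mean == 5.0
    assert summary.per_field_means["f2"] == 5.0


def test_summarize_missing_plane_raises_unless_overridden():
    counts = {"f1": [1, 2, 3], "f2": [4, 5], "f3": [7, 8, 9]}
    with pytest.raises(ValueError, match="f2"):
        summarize_animal(counts)
    summary = summarize_animal(counts, allow_missing=True)
    assert summary.per_animal_mean == pytest.approx(np.mean([1, 2, 3, 4, 5, 7, 8, 9]))


def test_percent_of_reference():
    np.testing.assert_allclose(
        percent_of_reference([5, 10], [10, 10]), [50.0, 100.0]
    )
    with pytest.raises(ValueError):
        percent_of_reference([1.0], [0.0, 0.0])


def test_per_plane_counting_mode(small_field):
    field, _ = small_field
    counts = count_synapses_per_plane(field, "pre", "post")
    assert len(counts) == field.shape[0]
    assert all(c >= 0 for c in counts)
    assert sum(counts) > 0
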