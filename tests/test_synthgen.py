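"""Generator contracts: determinism, realized statistics, ground-truth sanity."""

import numpy as np
import pytest
from scipy import stats

from hdsynapse.cohort import burden_score
from hdsynapse.synthgen import (
    CohortSpec,
    FieldSpec,
    GroupEffect,
    TrainSpec,
    gen_cohort,
    gen_engulfment_scene,
    gen_event_trains,
    gen_microglia_morphology,
    gen_synapse_field,
)

TINY_FIELD = dict(field_size_um=(6.4, 6.4, 2.0), voxel_size_um=(0.1, 0.1, 0.25))


# ---------------------------------------------------------------------------
# determinism: identical spec + seed -> bit-identical outputs
# ---------------------------------------------------------------------------

def test_synapse_field_deterministic():
    a_field, a_truth = gen_synapse_field(FieldSpec(seed=9, **TINY_FIELD))
    b_field, b_truth = gen_synapse_field(FieldSpec(seed=9, **TINY_FIELD))
    for ch in a_field.channel_names:
        np.testing.assert_array_equal(a_field.intensities[ch], b_field.intensities[ch])
    np.testing.assert_array_equal(a_truth.true_pre_centers, b_truth.true_pre_centers)
    np.testing.assert_array_equal(a_truth.true_pair_index, b_truth.true_pair_index)


def test_engulfment_scene_deterministic():
    a, _ = gen_engulfment_scene(seed=4)
    b, _ = gen_engulfment_scene(seed=4)
    np.testing.assert_array_equal(a.cell_channel, b.cell_channel)
    np.testing.assert_array_equal(a.cargo_channel, b.cargo_channel)


def test_morphology_deterministic():
    a = gen_microglia_morphology(2, seed=11)
    b = gen_microglia_morphology(2, seed=11)
    assert set(a.nodes) == set(b.nodes)
    for n in a.nodes:
        np.testing.assert_array_equal(a.nodes[n], b.nodes[n])
    assert [(e.node_a, e.node_b, e.thickness_um) for e in a.edges] == [
        (e.node_a, e.node_b, e.thickness_um) for e in b.edges
    ]


def test_events_and_cohort_deterministic():
    ta = gen_event_trains(TrainSpec(seed=3, n_cells=2, events_per_cell_mean=50))
    tb = gen_event_trains(TrainSpec(seed=3, n_cells=2, events_per_cell_mean=50))
    for x, y in zip(ta, tb):
        np.testing.assert_array_equal(x.times_s, y.times_s)
        np.testing.assert_array_equal(x.amplitudes_pa, y.amplitudes_pa)
    ca = gen_cohort(CohortSpec(seed=5))
    cb = gen_cohort(CohortSpec(seed=5))
    assert ca.equals(cb)


# ---------------------------------------------------------------------------
# synapse fields
# ---------------------------------------------------------------------------

def test_field_poisson_count_and_realized_coloc_fraction():
    """Mean pre count matches d·V; pooled pairing matches coloc_fraction.

    200 replicate fields: the mean presynaptic count must fall within three
    standard errors of density × volume, and the pooled fraction of paired
    pre puncta within the 99% binomial CI of the requested fraction.
    """
    density, frac = 0.3, 0.6
    counts, paired = [], 0
    for s in range(200):
        _, truth = gen_synapse_field(
            FieldSpec(seed=s, pre_density=density, coloc_fraction=frac, **TINY_FIELD)
        )
        counts.append(len(truth.true_pre_centers))
        paired += len(truth.true_pair_index)
    volume = 6.4 * 6.4 * 2.0
    expected = density * volume
    se = np.sqrt(expected / 200)
    assert abs(np.mean(counts) - expected) < 3 * se

    n_pre_total = int(np.sum(counts))
    lo, hi = stats.binom.interval(0.99, n_pre_total, frac)
    assert lo <= paired <= hi


def test_zero_coloc_fraction_gives_no_pairs():
    _, truth = gen_synapse_field(FieldSpec(seed=1, coloc_fraction=0.0, **TINY_FIELD))
    assert len(truth.true_pair_index) == 0


def test_true_pairs_within_pairing_radius():
    spec = FieldSpec(seed=2, **TINY_FIELD)
    _, truth = gen_synapse_field(spec)
    assert len(truth.true_pair_index) > 0
    d = np.linalg.norm(
        truth.true_pre_centers[truth.true_pair_index[:, 0]]
        - truth.true_post_centers[truth.true_pair_index[:, 1]],
        axis=1,
    )
    assert np.all(d < spec.pair_distance_max_um)


@pytest.mark.parametrize(
    "bad",
    [
        dict(coloc_fraction=1.5),
        dict(pre_density=-0.1),
        dict(voxel_size_um=(0.1, 0.1, 0.0)),
        dict(pair_distance_max_um=0.35),   # above the synapse-calling threshold
        dict(snr=0.5),
    ],
)
def test_field_spec_validation(bad):
    with pytest.raises(ValueError):
        FieldSpec(**bad)


# ---------------------------------------------------------------------------
# engulfment scenes
# ---------------------------------------------------------------------------

def test_scene_zero_fraction_puts_no_cargo_inside():
    scene, truth = gen_engulfment_scene(cargo_inside_fraction=0.0, seed=0)
    inside = scene.cell_channel > 100
    assert truth.engulfed_volume_um3 == 0
    assert not np.any((scene.cargo_channel > 0) & inside)


def test_scene_engulfed_volume_construction_arithmetic():
    """5% of a 1,000 μm³ cell is 50 μm³ of cargo, up to one voxel volume."""
    scene, truth = gen_engulfment_scene(
        cell_volume_um3=1000.0, cargo_inside_fraction=0.05, seed=1
    )
    assert truth.engulfed_volume_um3 == pytest.approx(
        0.05 * truth.cell_volume_um3, abs=truth.voxel_volume_um3
    )


def test_scene_unreachable_fraction_reports_quantum():
    with pytest.raises(ValueError, match="quantum"):
        gen_engulfment_scene(cargo_inside_fraction=1e-9, seed=0)


# ---------------------------------------------------------------------------
# morphologies
# ---------------------------------------------------------------------------

def test_morphology_intent_extremes():
    surveillant = gen_microglia_morphology(0, seed=0)
    assert surveillant.branch_point_count >= 4
    assert surveillant.mean_process_thickness_um < 0.7
    assert not surveillant.cd68_component_volumes_um3

    phagocytic = gen_microglia_morphology(5, seed=0)
    assert not phagocytic.edges
    assert max(phagocytic.cd68_component_volumes_um3) >= 1.0


# ---------------------------------------------------------------------------
# event trains
# ---------------------------------------------------------------------------

def test_event_train_isi_mean_matches_rate():
    """At 2 Hz the pooled mean ISI is 0.5 s within three standard errors."""
    trains = gen_event_trains(
        TrainSpec(n_cells=10, events_per_cell_mean=1000, isi_rate_hz=2.0, seed=0)
    )
    pooled = np.concatenate([np.diff(t.times_s) for t in trains])
    assert pooled.size >= 9000
    se = pooled.std(ddof=1) / np.sqrt(pooled.size)
    assert abs(pooled.mean() - 0.5) < 3 * se


def test_group_effect_halves_frequency():
    trains = gen_event_trains(
        TrainSpec(
            n_cells=8, events_per_cell_mean=800, isi_rate_hz=2.0,
            group_effect=GroupEffect(freq_mult=0.5), seed=1,
        )
    )
    isi = {
        g: np.concatenate(
            [np.diff(t.times_s) for t in trains if t.group == g]
        ).mean()
        for g in ("group1", "group2")
    }
    assert isi["group2"] / isi["group1"] == pytest.approx(2.0, rel=0.1)


def test_zero_event_train():
    (train,) = gen_event_trains(
        TrainSpec(n_cells=1, events_per_cell_mean=0, seed=0)
    )
    assert train.n_events == 0
    assert train.duration_s > 0


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def test_cohort_premanifest_criteria_hold():
    table = gen_cohort(CohortSpec(seed=2))
    early = table[table.group == "early_premanifest"]
    assert len(early) and (early.cag >= 40).all()
    assert all(burden_score(r.age, r.cag) < 250 for r in early.itertuples())
    late = table[table.group == "late_premanifest"]
    assert all(burden_score(r.age, r.cag) >= 250 for r in late.itertuples())


def test_cohort_noise_free_zero_slopes_constant_analyte():
    spec = CohortSpec(
        n_per_group={"healthy": 10},
        age_slope=0.0, cap_slope=0.0, noise_sd=0.0, seed=0,
    )
    table = gen_cohort(spec)
    assert np.allclose(table[spec.analyte], spec.intercept)


def test_cohort_age_slope_recovery():
    """OLS on 500 synthetic controls recovers the generating slope."""
    spec = CohortSpec(n_per_group={"healthy": 500}, age_slope=0.3, noise_sd=5.0, seed=3)
    table = gen_cohort(spec)
    fit = stats.linregress(table.age, table[spec.analyte])
    assert abs(fit.slope - 0.3) < 3 * fit.stderr


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(cag_range={"early_premanifest": (38, 42)})
    with pytest.raises(ValueError):
        CohortSpec(age_range={"healthy": (-5.0, 40.0)})
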