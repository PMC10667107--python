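"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be simulated here so each
downstream stage is testable without external data:

* :func:`gen_synapse_field` — 3D multi-channel puncta fields (pre, post,
  complement) with a controllable co-localized fraction, rendered as
  Gaussian spots over a constant background with Poisson shot noise;
* :func:`gen_engulfment_scene` — a blob-shaped glial cell containing a
  controlled engulfed-cargo fraction plus extracellular cargo;
* :func:`gen_microglia_morphology` — skeletonized microglia whose features
  fall inside the default phagocytic-score bands for a requested class;
* :func:`gen_event_trains` — sEPSC-like event trains with exponential
  inter-event intervals and log-normal amplitudes, with group effects;
* :func:`gen_cohort` — patient cohorts obeying the stratification criteria,
  with analyte concentrations linear in age (plus CAP score for carriers).

All generators are deterministic given (spec, seed): each derives an
independent stream from the root seed by stage name, so stages never
perturb each other's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import stage_rng
from .cohort import cap_score, stratify
from .engulfment import Scene
from .ephysboot import EventTrain
from .gliastate import CellMorphology, SkeletonEdge
from .puncta import PunctaField

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "SceneTruth",
    "TrainSpec",
    "GroupEffect",
    "CohortSpec",
    "gen_synapse_field",
    "gen_engulfment_scene",
    "gen_microglia_morphology",
    "gen_event_trains",
    "gen_cohort",
    "reduced_density_spec",
]


# ---------------------------------------------------------------------------
# synapse fields
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Recipe for one synthetic multi-channel puncta field.

    Sizes and voxel sizes are (x, y, z) μm.  ``pre_density`` is puncta per
    μm³; a ``coloc_fraction`` subset of presynaptic puncta receives a
    postsynaptic partner within ``pair_distance_max_um`` (default 0.15 μm,
    safely below the 0.3 μm synapse-calling threshold so every true pair is
    callable); ``complement_tag_fraction`` of true pairs carries a
    complement punctum, on top of an independent complement background at
    ``complement_background_density``.  ``snr`` is the spot peak over the
    constant background; shot noise is Poisson.
    """

    field_size_um: tuple[float, float, float] = (12.8, 12.8, 3.0)
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.3)
    pre_density: float = 0.3
    coloc_fraction: float = 0.6
    pair_distance_max_um: float = 0.15
    complement_tag_fraction: float = 0.4
    complement_background_density: float = 0.05
    psf_sigma_um: tuple[float, float, float] = (0.08, 0.08, 0.2)
    snr: float = 10.0
    background_level: float = 10.0
    seed: int = 0
    synapse_call_distance_um: float = 0.3

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")
        if any(v <= 0 for v in self.field_size_um):
            raise ValueError("field sizes must be > 0")
        for name in ("pre_density", "complement_background_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("coloc_fraction", "complement_tag_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.pair_distance_max_um < self.synapse_call_distance_um):
            raise ValueError(
                "pair_distance_max_um must be positive and below the "
                f"synapse-calling threshold ({self.synapse_call_distance_um} μm)"
            )
        if self.snr <= 1:
            raise ValueError("snr must be > 1 (peak over background)")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(z, y, x) voxel grid shape."""
        fx, fy, fz = self.field_size_um
        vx, vy, vz = self.voxel_size_um
        return (round(fz / vz), round(fy / vy), round(fx / vx))

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.field_size_um))


@dataclass
class GroundTruth:
    """True puncta positions and pairings of one generated field."""

    true_pre_centers: np.ndarray          # (n_pre, 3) (x, y, z) μm
    true_post_centers: np.ndarray
    true_complement_centers: np.ndarray
    true_pair_index: np.ndarray           # (n_pairs, 2): (pre idx, post idx)
    tagged_pair_rows: np.ndarray          # rows of true_pair_index with complement
    true_coloc_fraction: float
    scenario: str = "reference"

    def __post_init__(self) -> None:
        pairs = np.asarray(self.true_pair_index, dtype=int).reshape(-1, 2)
        for col in range(2):
            if len(set(pairs[:, col].tolist())) != len(pairs):
                raise ValueError("ground-truth pairing is not one-to-one")
        self.true_pair_index = pairs


def _uniform_points(rng: np.random.Generator, n: int, size_um) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(size_um)


def _ball_offset(rng: np.random.Generator, radius: float) -> np.ndarray:
    """Uniform random offset inside the ball of the given radius."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.uniform() ** (1.0 / 3.0)


def _offset_inside(
    rng: np.random.Generator, center: np.ndarray, radius: float, size_um
) -> np.ndarray:
    size = np.asarray(size_um)
    for _ in range(200):
        p = center + _ball_offset(rng, radius)
        if np.all(p >= 0) and np.all(p < size):
            return p
    # pathological corner: fall back to the clipped center itself
    return np.clip(center, 0, size - 1e-9)


def _splat(canvas: np.ndarray, pos_vox_zyx: np.ndarray, mass: float) -> None:
    """Trilinear deposition of ``mass`` at a fractional (z, y, x) position."""
    base = np.floor(pos_vox_zyx).astype(int)
    frac = pos_vox_zyx - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[0] if dz else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dx else 1 - frac[2])
                )
                z, y, x = base + (dz, dy, dx)
                if 0 <= z < canvas.shape[0] and 0 <= y < canvas.shape[1] \
                        and 0 <= x < canvas.shape[2]:
                    canvas[z, y, x] += mass * w


def _render_channel(
    shape: tuple[int, int, int],
    centers_um: np.ndarray,
    voxel_size_um,
    psf_sigma_um,
    snr: float,
    background: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian spots + constant background + Poisson shot noise."""
    vx, vy, vz = voxel_size_um
    sx, sy, sz = psf_sigma_um
    sigma_vox = np.array([sz / vz, sy / vy, sx / vx])
    peak_excess = (snr - 1.0) * background
    mass = peak_excess * float(np.prod(np.sqrt(2 * np.pi) * sigma_vox))

    canvas = np.zeros(shape)
    for c in np.atleast_2d(centers_um):
        if c.size == 0:
            continue
        pos_vox = np.array([c[2] / vz, c[1] / vy, c[0] / vx]) - 0.5
        _splat(canvas, pos_vox, mass)
    blurred = ndimage.gaussian_filter(canvas, sigma_vox)
    expected = blurred + background
    return rng.poisson(expected).astype(float)


def gen_synapse_field(spec: FieldSpec) -> tuple[PunctaField, GroundTruth]:
    """Generate one synthetic pre/post/complement field plus its truth.

    Presynaptic puncta follow a homogeneous Poisson process at
    ``pre_density``; a binomial ``coloc_fraction`` subset receives a
    postsynaptic partner at a uniform-random offset inside the ball of
    radius ``pair_distance_max_um``; remaining postsynaptic puncta are
    placed independently so the post channel matches the pre density.
    Complement puncta tag ``complement_tag_fraction`` of the true pairs
    (offset from the presynaptic center within the same ball) and an
    independent background is added at ``complement_background_density``.
    """
    rng = stage_rng(spec.seed, "synapse_field")
    size = np.asarray(spec.field_size_um)
    volume = spec.volume_um3

    n_pre = int(rng.poisson(spec.pre_density * volume))
    pre = _uniform_points(rng, n_pre, size)

    n_paired = int(rng.binomial(n_pre, spec.coloc_fraction)) if n_pre else 0
    paired_pre_idx = (
        rng.choice(n_pre, size=n_paired, replace=False) if n_paired else
        np.empty(0, dtype=int)
    )
    paired_post = np.array(
        [
            _offset_inside(rng, pre[i], spec.pair_distance_max_um, size)
            for i in paired_pre_idx
        ]
    ).reshape(-1, 3)

    n_free_post = int(rng.poisson(spec.pre_density * (1 - spec.coloc_fraction) * volume))
    free_post = _uniform_points(rng, n_free_post, size)
    post = np.vstack([paired_post, free_post]) if (n_paired + n_free_post) else \
        np.empty((0, 3))
    pair_index = np.stack(
        [paired_pre_idx, np.arange(n_paired)], axis=1
    ) if n_paired else np.empty((0, 2), dtype=int)

    n_tag = int(rng.binomial(n_paired, spec.complement_tag_fraction)) if n_paired else 0
    tagged_rows = (
        rng.choice(n_paired, size=n_tag, replace=False) if n_tag else
        np.empty(0, dtype=int)
    )
    tagged_comp = np.array(
        [
            _offset_inside(
                rng, pre[pair_index[r, 0]], spec.pair_distance_max_um, size
            )
            for r in tagged_rows
        ]
    ).reshape(-1, 3)
    n_bg_comp = int(rng.poisson(spec.complement_background_density * volume))
    comp = np.vstack([tagged_comp, _uniform_points(rng, n_bg_comp, size)])

    shape = spec.shape
    channels = {
        name: _render_channel(
            shape, centers, spec.voxel_size_um, spec.psf_sigma_um,
            spec.snr, spec.background_level, rng,
        )
        for name, centers in (("pre", pre), ("post", post), ("complement", comp))
    }
    field = PunctaField(
        intensities=channels,
        voxel_size_um=np.asarray(spec.voxel_size_um),
        field_id=f"sim-{spec.seed}",
    )
    truth = GroundTruth(
        true_pre_centers=pre,
        true_post_centers=post,
        true_complement_centers=comp,
        true_pair_index=pair_index,
        tagged_pair_rows=tagged_rows,
        true_coloc_fraction=(n_paired / n_pre) if n_pre else float("nan"),
    )
    return field, truth


def reduced_density_spec(
    spec: FieldSpec,
    density_effect: float = 0.5,
    tag_effect: float = 1.0,
    seed: int | None = None,
) -> FieldSpec:
    """Derive the disease-like scenario from a reference field spec.

    The disease scenario is the reference recipe with presynaptic density
    (hence synapse density) scaled by ``density_effect`` — default 0.5, the
    ballpark of the striatal synapse loss the pipeline is built to measure —
    and optionally the complement tag fraction scaled by ``tag_effect``.
    """
    return FieldSpec(
        field_size_um=spec.field_size_um,
        voxel_size_um=spec.voxel_size_um,
        pre_density=spec.pre_density * density_effect,
        coloc_fraction=spec.coloc_fraction,
        pair_distance_max_um=spec.pair_distance_max_um,
        complement_tag_fraction=min(1.0, spec.complement_tag_fraction * tag_effect),
        complement_background_density=spec.complement_background_density,
        psf_sigma_um=spec.psf_sigma_um,
        snr=spec.snr,
        background_level=spec.background_level,
        seed=spec.seed if seed is None else seed,
        synapse_call_distance_um=spec.synapse_call_distance_um,
    )


# ---------------------------------------------------------------------------
# engulfment scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneTruth:
    """Construction record of one engulfment scene."""

    cell_volume_um3: float            # realized (voxel-quantized)
    engulfed_volume_um3: float
    inside_fraction_requested: float
    inside_fraction_realized: float
    extracellular_volume_um3: float
    voxel_volume_um3: float


def gen_engulfment_scene(
    cell_volume_um3: float = 1000.0,
    cargo_inside_fraction: float = 0.05,
    cargo_field_density: float = 0.01,
    voxel_size_um: tuple[float, float, float] = (0.25, 0.25, 0.5),
    field_size_um: tuple[float, float, float] = (20.0, 20.0, 16.0),
    seed: int = 0,
    cell_type: str = "microglia",
    noise_sd: float = 0.0,
) -> tuple[Scene, SceneTruth]:
    """Generate a glial cell containing a controlled engulfed-cargo fraction.

    The cell is a randomly oriented ellipsoidal blob of approximately
    ``cell_volume_um3``; cargo voxels are placed inside it so the engulfed
    volume divided by the (realized) cell volume equals
    ``cargo_inside_fraction`` within voxel quantization, plus extracellular
    cargo occupying ``cargo_field_density`` of the field volume.  Channels
    are noise-free by default so volumetric recovery is exact; set
    ``noise_sd`` for additive Gaussian noise.
    """
    if not (0.0 <= cargo_inside_fraction <= 1.0):
        raise ValueError("cargo_inside_fraction must be in [0, 1]")
    rng = stage_rng(seed, "engulfment_scene")

    vx, vy, vz = voxel_size_um
    fx, fy, fz = field_size_um
    shape = (round(fz / vz), round(fy / vy), round(fx / vx))
    voxvol = float(np.prod(voxel_size_um))

    # ellipsoid with randomized axis ratios, volume-preserving
    r0 = (3.0 * cell_volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    scales = rng.uniform(0.85, 1.15, size=3)
    scales /= np.prod(scales) ** (1.0 / 3.0)
    axes = r0 * scales                              # (x, y, z) semi-axes, μm
    if np.any(2 * axes >= np.asarray(field_size_um)):
        raise ValueError("cell does not fit in the field of view")

    center = np.asarray(field_size_um) / 2.0
    zz, yy, xx = np.indices(shape)
    X = (xx + 0.5) * vx
    Y = (yy + 0.5) * vy
    Z = (zz + 0.5) * vz
    mask = (
        ((X - center[0]) / axes[0]) ** 2
        + ((Y - center[1]) / axes[1]) ** 2
        + ((Z - center[2]) / axes[2]) ** 2
    ) <= 1.0

    n_cell = int(mask.sum())
    if n_cell == 0:
        raise ValueError("cell volume below one voxel at this voxel size")
    n_in = int(round(cargo_inside_fraction * n_cell))
    if cargo_inside_fraction > 0 and n_in == 0:
        raise ValueError(
            f"cargo_inside_fraction {cargo_inside_fraction} unreachable at this "
            f"voxel size; achievable quantum is 1/{n_cell} = {1.0 / n_cell:.2e}"
        )

    inside_flat = np.flatnonzero(mask.ravel())
    cargo_flat = rng.choice(inside_flat, size=n_in, replace=False) if n_in else \
        np.empty(0, dtype=int)

    outside_flat = np.flatnonzero(~mask.ravel())
    n_out = int(round(cargo_field_density * mask.size))
    n_out = min(n_out, outside_flat.size)
    out_flat = rng.choice(outside_flat, size=n_out, replace=False) if n_out else \
        np.empty(0, dtype=int)

    cell_channel = np.where(mask, 200.0, 0.0)
    cargo_channel = np.zeros(shape)
    cargo_channel.ravel()[cargo_flat] = 180.0
    cargo_channel.ravel()[out_flat] = 180.0
    if noise_sd > 0:
        cell_channel = np.clip(
            cell_channel + rng.normal(0, noise_sd, shape), 0, None
        )
        cargo_channel = np.clip(
            cargo_channel + rng.normal(0, noise_sd, shape), 0, None
        )

    scene = Scene(
        cell_channel=cell_channel,
        cargo_channel=cargo_channel,
        voxel_size_um=np.asarray(voxel_size_um),
        seed_um=center,
        cell_type=cell_type,  # type: ignore[arg-type]
        scene_id=f"sim-{seed}",
    )
    truth = SceneTruth(
        cell_volume_um3=n_cell * voxvol,
        engulfed_volume_um3=n_in * voxvol,
        inside_fraction_requested=cargo_inside_fraction,
        inside_fraction_realized=n_in / n_cell,
        extracellular_volume_um3=n_out * voxvol,
        voxel_volume_um3=voxvol,
    )
    return scene, truth


# ---------------------------------------------------------------------------
# microglial morphologies
# ---------------------------------------------------------------------------

def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gen_microglia_morphology(intent: int, seed: int = 0) -> CellMorphology:
    """Generate a skeletonized microglia for a target phagocytic state 0–5.

    The intent decomposes canonically into a morphology class
    ``min(intent, 3)`` and a CD68 class ``intent − min(intent, 3)``; the
    generated skeleton and CD68 components fall inside the default
    :class:`~hdsynapse.gliastate.ScoringBands` for those classes:

    * morphology 0/1 — five primary processes with two bifurcation levels
      (rich branching), thin (≈0.4 μm) vs thick (≈1.0 μm);
    * morphology 2 — two short thick unbranched processes;
    * morphology 3 — no processes;
    * CD68 0 — none; 1 — a few small puncta; 2 — one large aggregate.
    """
    if not (0 <= intent <= 5):
        raise ValueError("intent must be in 0..5")
    morph = min(intent, 3)
    cd68 = intent - morph
    rng = stage_rng(seed, f"microglia_morphology_{intent}")

    nodes: dict[int, np.ndarray] = {0: np.zeros(3)}
    edges: list[SkeletonEdge] = []
    next_id = 1

    def add_node(pos: np.ndarray) -> int:
        nonlocal next_id
        nodes[next_id] = pos
        next_id += 1
        return next_id - 1

    if morph in (0, 1):
        thickness = 0.4 if morph == 0 else 1.0
        for _ in range(5):
            d = _unit(rng)
            a = add_node(nodes[0] + d * rng.uniform(12, 18))
            edges.append(SkeletonEdge(0, a, rng.normal(thickness, 0.03)))
            for _ in range(2):                       # first bifurcation
                d2 = _unit(rng) * 0.6 + d
                d2 /= np.linalg.norm(d2)
                b = add_node(nodes[a] + d2 * rng.uniform(8, 12))
                edges.append(SkeletonEdge(a, b, rng.normal(thickness, 0.03)))
                for _ in range(2):                   # second bifurcation
                    d3 = _unit(rng) * 0.6 + d2
                    d3 /= np.linalg.norm(d3)
                    c = add_node(nodes[b] + d3 * rng.uniform(5, 8))
                    edges.append(SkeletonEdge(b, c, rng.normal(thickness, 0.03)))
    elif morph == 2:
        for _ in range(2):
            d = _unit(rng)
            a = add_node(nodes[0] + d * rng.uniform(5, 9))
            edges.append(SkeletonEdge(0, a, rng.normal(1.8, 0.1)))
    # morph 3: no edges at all

    if cd68 == 0:
        comps: list[float] = []
    elif cd68 == 1:
        comps = list(rng.uniform(0.2, 0.4, size=5))
    else:
        comps = [float(rng.uniform(2.0, 4.0))] + list(rng.uniform(0.2, 0.4, size=3))

    return CellMorphology(
        nodes=nodes,
        edges=edges,
        cd68_component_volumes_um3=comps,
        cell_volume_um3=400.0,
        cell_id=f"sim-{intent}-{seed}",
    )


# ---------------------------------------------------------------------------
# event trains
# ---------------------------------------------------------------------------

@dataclass
class GroupEffect:
    """Multiplicative shifts applied to the second group's generator."""

    freq_mult: float = 1.0        # scales the ISI rate (events per second)
    amp_mult: float = 1.0         # scales amplitudes

    def __post_init__(self) -> None:
        if self.freq_mult <= 0 or self.amp_mult <= 0:
            raise ValueError("group-effect multipliers must be > 0")


@dataclass
class TrainSpec:
    """Recipe for sEPSC-like event trains.

    Inter-event intervals are exponential at ``isi_rate_hz`` (so a 2 Hz cell
    has mean ISI 0.5 s); amplitudes are log-normal in pA (defaults give a
    median near 15 pA).  Event counts per cell are Poisson around
    ``events_per_cell_mean``.  If ``group_effect`` is set, a second group is
    generated with the rate and amplitudes scaled by its multipliers.
    """

    n_cells: int = 12
    events_per_cell_mean: int = 600
    isi_rate_hz: float = 2.0
    amp_lognorm_mu: float = 2.7
    amp_lognorm_sigma: float = 0.4
    group_effect: GroupEffect | None = None
    group_names: tuple[str, str] = ("group1", "group2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.isi_rate_hz <= 0:
            raise ValueError("isi_rate_hz must be > 0")
        if self.amp_lognorm_sigma < 0:
            raise ValueError("amp_lognorm_sigma must be >= 0")
        if self.events_per_cell_mean < 0:
            raise ValueError("events_per_cell_mean must be >= 0")


def _gen_cell(
    rng: np.random.Generator,
    cell_id: str,
    group: str,
    mean_events: float,
    rate: float,
    mu: float,
    sigma: float,
    amp_mult: float,
) -> EventTrain:
    n = int(rng.poisson(mean_events))
    intervals = rng.exponential(1.0 / rate, size=n)
    times = np.cumsum(intervals)
    amps = rng.lognormal(mu, sigma, size=n) * amp_mult
    duration = float(times[-1] + 1.0 / rate) if n else max(mean_events / rate, 1.0)
    return EventTrain(
        cell_id=cell_id, group=group, times_s=times,
        amplitudes_pa=amps, duration_s=duration,
    )


def gen_event_trains(spec: TrainSpec) -> list[EventTrain]:
    """Generate per-cell event trains (one group, or two if an effect is set)."""
    rng = stage_rng(spec.seed, "event_trains")
    trains = [
        _gen_cell(
            rng, f"{spec.group_names[0]}-c{i}", spec.group_names[0],
            spec.events_per_cell_mean, spec.isi_rate_hz,
            spec.amp_lognorm_mu, spec.amp_lognorm_sigma, 1.0,
        )
        for i in range(spec.n_cells)
    ]
    if spec.group_effect is not None:
        eff = spec.group_effect
        trains += [
            _gen_cell(
                rng, f"{spec.group_names[1]}-c{i}", spec.group_names[1],
                spec.events_per_cell_mean, spec.isi_rate_hz * eff.freq_mult,
                spec.amp_lognorm_mu, spec.amp_lognorm_sigma, eff.amp_mult,
            )
            for i in range(spec.n_cells)
        ]
    return trains


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Recipe for a synthetic patient cohort.

    Group sizes default to the CSF study layout (controls plus 13 early
    premanifest, 18 late premanifest and 32 early manifest carriers).  The
    analyte concentration is ``intercept + age_slope·age`` for everyone,
    plus ``cap_slope·CAP`` for expansion carriers, plus Gaussian noise.
    Sampled CAG/age combinations always satisfy the group criteria,
    including the burden < 250 / ≥ 250 premanifest split.
    """

    n_per_group: dict = dc_field(
        default_factory=lambda: {
            "healthy": 20,
            "early_premanifest": 13,
            "late_premanifest": 18,
            "early_manifest": 32,
        }
    )
    age_range: dict = dc_field(
        default_factory=lambda: {
            "healthy": (25.0, 70.0),
            "early_premanifest": (20.0, 50.0),
            "late_premanifest": (30.0, 65.0),
            "early_manifest": (30.0, 70.0),
        }
    )
    cag_range: dict = dc_field(
        default_factory=lambda: {
            "healthy": (17, 26),
            "early_premanifest": (40, 46),
            "late_premanifest": (40, 50),
            "early_manifest": (40, 50),
        }
    )
    analyte: str = "c3_ng_ml"
    intercept: float = 300.0
    age_slope: float = 2.0          # units per year, applies to everyone
    cap_slope: float = 1.5          # units per CAP unit, carriers only
    noise_sd: float = 20.0
    fluid: str = "CSF"
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, (lo, hi) in self.cag_range.items():
            if lo > hi:
                raise ValueError(f"{grp}: empty CAG range")
            if grp in ("early_premanifest", "late_premanifest") and lo < 40:
                raise ValueError(f"{grp}: premanifest requires CAG >= 40")
            if grp == "early_manifest" and lo < 36:
                raise ValueError(f"{grp}: manifest placement requires CAG >= 36")
            if grp == "healthy" and hi > 35:
                raise ValueError("healthy controls must have CAG <= 35")
        for grp, (lo, hi) in self.age_range.items():
            if lo <= 0 or lo >= hi:
                raise ValueError(f"{grp}: invalid age range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sample_premanifest(
    rng: np.random.Generator,
    group: str,
    age_lo: float,
    age_hi: float,
    cag_lo: int,
    cag_hi: int,
) -> tuple[float, int]:
    """CAG and age satisfying the burden constraint of the given subgroup."""
    eps = 1e-6
    for _ in range(1000):
        cag = int(rng.integers(cag_lo, cag_hi + 1))
        split_age = 250.0 / (cag - 35.5)
        if group == "early_premanifest":
            hi = min(age_hi, split_age - eps)
            if hi <= age_lo:
                continue
            return float(rng.uniform(age_lo, hi)), cag
        else:
            lo = max(age_lo, split_age)
            if lo >= age_hi:
                continue
            return float(rng.uniform(lo, age_hi)), cag
    raise ValueError(
        f"{group}: age range ({age_lo}, {age_hi}) and CAG range "
        f"({cag_lo}, {cag_hi}) cannot satisfy the burden criterion"
    )


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a stratification-consistent cohort table.

    Columns: subject_id, group, fluid, sex, age, cag, dcl, tfc and the
    analyte concentration column named by ``spec.analyte``.  Every subject
    re-stratifies into its generated group (checked on construction).
    """
    rng = stage_rng(spec.seed, "cohort")
    rows = []
    for group, n in spec.n_per_group.items():
        if group not in spec.age_range or group not in spec.cag_range:
            raise ValueError(f"no ranges configured for group {group!r}")
        age_lo, age_hi = spec.age_range[group]
        cag_lo, cag_hi = spec.cag_range[group]
        for i in range(n):
            if group in ("early_premanifest", "late_premanifest"):
                age, cag = _sample_premanifest(
                    rng, group, age_lo, age_hi, cag_lo, cag_hi
                )
                dcl, tfc = int(rng.integers(0, 4)), 13
            elif group == "early_manifest":
                age = float(rng.uniform(age_lo, age_hi))
                cag = int(rng.integers(cag_lo, cag_hi + 1))
                dcl, tfc = 4, int(rng.integers(7, 14))
            else:
                age = float(rng.uniform(age_lo, age_hi))
                cag = int(rng.integers(cag_lo, cag_hi + 1))
                dcl, tfc = 0, 13

            carrier = cag >= 36
            conc = spec.intercept + spec.age_slope * age
            if carrier:
                conc += spec.cap_slope * cap_score(age, cag)
            conc += rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0

            assert stratify(age, cag, dcl, tfc) == group, (
                "generated subject fails to re-stratify into its group"
            )
            rows.append(
                {
                    "subject_id": f"{group[:2]}{i:03d}",
                    "group": group,
                    "fluid": spec.fluid,
                    "sex": str(rng.choice(["F", "M"])),
                    "age": age,
                    "cag": cag,
                    "dcl": dcl,
                    "tfc": tfc,
                    spec.analyte: conc,
                }
            )
    return pd.DataFrame(rows)
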