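"""Reading and writing the pipeline's on-disk formats.

Image stacks travel as OME-TIFF with voxel size and channel names in the
OME metadata (via tifffile); tabular data (spots, pairs, ground truth,
events, cohorts, per-cell engulfment) travel as plain CSV through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .engulfment import Scene
from .ephysboot import EventTrain
from .puncta import PairSet, PunctaField, SpotSet
from .synthgen import GroundTruth

__all__ = [
    "write_field_ome_tiff",
    "read_field_ome_tiff",
    "write_scene_ome_tiff",
    "read_scene_ome_tiff",
    "spots_to_csv",
    "pairs_to_csv",
    "ground_truth_to_csv",
    "events_to_csv",
    "events_from_csv",
]


def _write_ome(path, stack, channel_names, voxel_size_um) -> None:
    vx, vy, vz = map(float, voxel_size_um)
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(channel_names)},
            "PhysicalSizeX": vx,
            "PhysicalSizeY": vy,
            "PhysicalSizeZ": vz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def _read_ome(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        ome = tif.ome_metadata
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    voxel = np.array(
        [
            float(pixels.get("PhysicalSizeX", 1.0)),
            float(pixels.get("PhysicalSizeY", 1.0)),
            float(pixels.get("PhysicalSizeZ", 1.0)),
        ]
    )
    names = [
        ch.get("Name") or f"ch{i}"
        for i, ch in enumerate(root.findall(".//ome:Channel", ns))
    ]
    if stack.ndim == 3:
        stack = stack[None]
    if not names:
        names = [f"ch{i}" for i in range(stack.shape[0])]
    return stack, names, voxel


def write_field_ome_tiff(path: str | Path, field: PunctaField) -> None:
    names = field.channel_names
    stack = np.stack([field.intensities[c] for c in names]).astype(np.float32)
    _write_ome(path, stack, names, field.voxel_size_um)


def read_field_ome_tiff(
    path: str | Path, field_id: str | None = None
) -> PunctaField:
    stack, names, voxel = _read_ome(path)
    return PunctaField(
        intensities={n: stack[i].astype(float) for i, n in enumerate(names)},
        voxel_size_um=voxel,
        field_id=field_id or Path(path).stem,
    )


def write_scene_ome_tiff(path: str | Path, scene: Scene) -> None:
    stack = np.stack([scene.cell_channel, scene.cargo_channel]).astype(np.float32)
    _write_ome(path, stack, ["cell", "cargo"], scene.voxel_size_um)


def read_scene_ome_tiff(
    path: str | Path, seed_um, cell_type: str = "microglia"
) -> Scene:
    stack, names, voxel = _read_ome(path)
    by_name = {n: stack[i].astype(float) for i, n in enumerate(names)}
    return Scene(
        cell_channel=by_name.get("cell", stack[0].astype(float)),
        cargo_channel=by_name.get("cargo", stack[-1].astype(float)),
        voxel_size_um=voxel,
        seed_um=np.asarray(seed_um, dtype=float),
        cell_type=cell_type,  # type: ignore[arg-type]
        scene_id=Path(path).stem,
    )


def spots_to_csv(path: str | Path, spots: SpotSet) -> None:
    spots.to_frame().to_csv(path, index=False)


def pairs_to_csv(path: str | Path, pairs: PairSet) -> None:
    df = pd.DataFrame(
        {
            "pre_index": pairs.pairs[:, 0],
            "post_index": pairs.pairs[:, 1],
            "distance_um": pairs.distances_um,
        }
    )
    if pairs.pre is not None:
        pre = pairs.pre.centers_um[pairs.pairs[:, 0]]
        df[["x_um", "y_um", "z_um"]] = pre
    df.to_csv(path, index=False)


def ground_truth_to_csv(path: str | Path, truth: GroundTruth) -> None:
    """One row per true punctum: x_um,y_um,z_um,channel,pair_id."""
    frames = []
    pair_of_pre = {int(p): i for i, (p, _) in enumerate(truth.true_pair_index)}
    pair_of_post = {int(q): i for i, (_, q) in enumerate(truth.true_pair_index)}
    for channel, centers, pair_of in (
        ("pre", truth.true_pre_centers, pair_of_pre),
        ("post", truth.true_post_centers, pair_of_post),
        ("complement", truth.true_complement_centers, {}),
    ):
        c = np.atleast_2d(centers)
        if c.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "x_um": c[:, 0],
                    "y_um": c[:, 1],
                    "z_um": c[:, 2],
                    "channel": channel,
                    "pair_id": [pair_of.get(i, -1) for i in range(len(c))],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def events_to_csv(path: str | Path, trains: list[EventTrain]) -> None:
    rows = []
    for t in trains:
        for time, amp in zip(t.times_s, t.amplitudes_pa):
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "group": t.group,
                    "event_time_s": time,
                    "amplitude_pa": amp,
                    "duration_s": t.duration_s,
                }
            )
    pd.DataFrame(
        rows,
        columns=["cell_id", "group", "event_time_s", "amplitude_pa", "duration_s"],
    ).to_csv(path, index=False)


def events_from_csv(path: str | Path) -> list[EventTrain]:
    df = pd.read_csv(path)
    trains = []
    for (cell_id, group), sub in df.groupby(["cell_id", "group"], sort=False):
        sub = sub.sort_values("event_time_s")
        trains.append(
            EventTrain(
                cell_id=str(cell_id),
                group=str(group),
                times_s=sub["event_time_s"].to_numpy(),
                amplitudes_pa=sub["amplitude_pa"].to_numpy(),
                duration_s=float(sub["duration_s"].iloc[0]),
            )
        )
    return trains
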