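"""Microglial phagocytic-state scoring and Sholl analysis.

A resting ("surveillant") microglia is highly ramified — thin, long, richly
branched processes and little lysosomal content.  As cells shift toward a
phagocytic state, processes thicken and retract while the lysosomal marker
CD68 accumulates, first as scattered puncta and finally as large aggregates.
The scoring rubric sums a 0–3 morphology score and a 0–2 CD68 score into a
0–5 phagocytic state (0 least, 5 most phagocytic):

    morphology  0  thin long processes with multiple branches
                1  thicker processes but with similar branching
                2  thick retracted processes with few branches
                3  no clear processes
    CD68        0  no / scarce expression
                1  punctate expression
                2  aggregated expression, or punctate all over the cell

The original rubric is qualitative; here it is operationalized as explicit
threshold bands on skeleton and CD68 features so the assignment is
reproducible.  Every band is configurable — the defaults are declared
assumptions, not measured constants.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CellMorphology",
    "SkeletonEdge",
    "ScoringBands",
    "PhagocyticScore",
    "ShollProfile",
    "score_morphology",
    "score_cd68",
    "phagocytic_state",
    "sholl_profile",
    "morphology_from_json",
    "morphology_to_json",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SkeletonEdge:
    node_a: int
    node_b: int
    thickness_um: float

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("edge thickness must be > 0")


@dataclass
class CellMorphology:
    """Skeletonized glial cell: soma, process graph, CD68 label.

    ``nodes`` maps node id -> (x, y, z) μm; node 0 is the soma center.
    Edges are straight segments between nodes; lengths are derived from the
    node coordinates.  ``cd68_component_volumes_um3`` lists the volumes of
    connected CD68⁺ components; ``cell_volume_um3`` is the reference volume
    for expressing CD68 load as a fraction.
    """

    nodes: dict[int, np.ndarray]
    edges: list[SkeletonEdge]
    cd68_component_volumes_um3: list[float] = dc_field(default_factory=list)
    cell_volume_um3: float = 400.0
    cell_id: str = "cell0"
    animal_id: str = "animal0"
    soma_node: int = 0

    def __post_init__(self) -> None:
        self.nodes = {int(k): np.asarray(v, dtype=float) for k, v in self.nodes.items()}
        if self.soma_node not in self.nodes:
            raise ValueError("soma node missing from node set")
        if any(v <= 0 for v in self.cd68_component_volumes_um3):
            raise ValueError("CD68 component volumes must be > 0")
        if self.cell_volume_um3 <= 0:
            raise ValueError("cell volume must be > 0")
        for e in self.edges:
            if e.node_a not in self.nodes or e.node_b not in self.nodes:
                raise ValueError(f"edge references unknown node: {e}")
        if self.edges and not self._connected_to_soma():
            raise ValueError("skeleton graph is not connected to the soma")

    def _connected_to_soma(self) -> bool:
        adj: dict[int, list[int]] = {}
        for e in self.edges:
            adj.setdefault(e.node_a, []).append(e.node_b)
            adj.setdefault(e.node_b, []).append(e.node_a)
        seen = {self.soma_node}
        stack = [self.soma_node]
        while stack:
            for nb in adj.get(stack.pop(), []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        touched = {e.node_a for e in self.edges} | {e.node_b for e in self.edges}
        return touched <= seen

    # -- derived skeleton features -------------------------------------------

    @property
    def soma_um(self) -> np.ndarray:
        return self.nodes[self.soma_node]

    def edge_length_um(self, e: SkeletonEdge) -> float:
        return float(np.linalg.norm(self.nodes[e.node_a] - self.nodes[e.node_b]))

    def degree(self) -> dict[int, int]:
        deg = Counter()
        for e in self.edges:
            deg[e.node_a] += 1
            deg[e.node_b] += 1
        return dict(deg)

    @property
    def total_process_length_um(self) -> float:
        return float(sum(self.edge_length_um(e) for e in self.edges))

    @property
    def mean_process_thickness_um(self) -> float:
        if not self.edges:
            return 0.0
        lengths = np.array([self.edge_length_um(e) for e in self.edges])
        thick = np.array([e.thickness_um for e in self.edges])
        return float(np.average(thick, weights=lengths))

    @property
    def branch_point_count(self) -> int:
        """Nodes (other than the soma) where a process splits (degree ≥ 3)."""
        return sum(
            1
            for n, d in self.degree().items()
            if d >= 3 and n != self.soma_node
        )

    @property
    def terminal_count(self) -> int:
        return sum(
            1 for n, d in self.degree().items() if d == 1 and n != self.soma_node
        )

    @property
    def cd68_total_volume_um3(self) -> float:
        return float(sum(self.cd68_component_volumes_um3))

    @property
    def cd68_volume_fraction(self) -> float:
        return self.cd68_total_volume_um3 / self.cell_volume_um3


@dataclass
class ScoringBands:
    """Quantitative bands that operationalize the qualitative rubric.

    Morphology: a cell with no edges (or total process length under
    ``min_total_length_um``) has "no clear processes" (3); fewer than
    ``min_branch_points`` branch points means "few branches" (2); among
    well-branched cells the mean process thickness separates "thin" (0) from
    "thicker" (1) at ``thin_thickness_um``.

    CD68: total volume fraction under ``scarce_fraction`` scores 0; a largest
    aggregate of at least ``aggregate_volume_um3`` or a fraction of at least
    ``all_over_fraction`` scores 2; anything between is punctate (1).
    """

    min_total_length_um: float = 5.0
    min_branch_points: int = 4
    thin_thickness_um: float = 0.7
    scarce_fraction: float = 0.001
    aggregate_volume_um3: float = 1.0
    all_over_fraction: float = 0.02


@dataclass
class PhagocyticScore:
    morphology_score: int
    cd68_score: int

    def __post_init__(self) -> None:
        if not (0 <= self.morphology_score <= 3):
            raise ValueError("morphology score out of [0, 3]")
        if not (0 <= self.cd68_score <= 2):
            raise ValueError("CD68 score out of [0, 2]")

    @property
    def state(self) -> int:
        return self.morphology_score + self.cd68_score


@dataclass
class ShollProfile:
    radii_um: np.ndarray
    intersections: np.ndarray
    branch_points: np.ndarray
    terminals: np.ndarray


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_morphology(cell: CellMorphology, bands: ScoringBands | None = None) -> int:
    """Score process morphology 0–3 from skeleton features."""
    bands = bands or ScoringBands()
    if not cell.edges or cell.total_process_length_um < bands.min_total_length_um:
        return 3
    if cell.branch_point_count < bands.min_branch_points:
        return 2
    if cell.mean_process_thickness_um < bands.thin_thickness_um:
        return 0
    return 1


def score_cd68(cell: CellMorphology, bands: ScoringBands | None = None) -> int:
    """Score CD68 lysosomal load 0–2 from component volumes."""
    bands = bands or ScoringBands()
    comps = cell.cd68_component_volumes_um3
    if not comps or cell.cd68_volume_fraction < bands.scarce_fraction:
        return 0
    if max(comps) >= bands.aggregate_volume_um3:
        return 2
    if cell.cd68_volume_fraction >= bands.all_over_fraction:
        return 2
    return 1


def phagocytic_state(
    cells: Sequence[CellMorphology],
    bands: ScoringBands | None = None,
    *,
    recommended_population: tuple[int, int] = (30, 50),
    warn: bool = True,
) -> tuple[list[PhagocyticScore], dict[int, float]]:
    """Score a population and return per-cell scores + the state distribution.

    The distribution maps each state 0–5 to the percentage of cells at that
    state (percentages sum to 100).  Populations outside the recommended
    30–50 cells per animal trigger a warning, not an error.
    """
    if not cells:
        raise ValueError("empty cell population")
    if warn and not (
        recommended_population[0] <= len(cells) <= recommended_population[1]
    ):
        import warnings

        warnings.warn(
            f"population of {len(cells)} cells is outside the recommended "
            f"{recommended_population[0]}–{recommended_population[1]} per animal"
        )
    scores = [
        PhagocyticScore(score_morphology(c, bands), score_cd68(c, bands))
        for c in cells
    ]
    counts = Counter(s.state for s in scores)
    dist = {state: 100.0 * counts.get(state, 0) / len(scores) for state in range(6)}
    return scores, dist


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

def sholl_profile(
    cell: CellMorphology, radius_step_um: float = 5.0
) -> ShollProfile:
    """Concentric-shell profile of a skeletonized cell around its soma.

    For each radius r = step, 2·step, … up to the maximal process extent:

    * ``intersections`` — crossings of skeleton segments with the sphere of
      radius r, counted exactly (a segment entering and leaving the sphere
      counts twice; a terminal sitting exactly on the sphere counts zero);
    * ``branch_points`` / ``terminals`` — branch and terminal nodes whose
      somatic distance falls in the shell (r − step, r].
    """
    if radius_step_um <= 0:
        raise ValueError("radius step must be > 0")
    soma = cell.soma_um
    dist = {n: float(np.linalg.norm(p - soma)) for n, p in cell.nodes.items()}
    max_extent = max(dist.values()) if dist else 0.0
    n_shells = int(np.ceil(max_extent / radius_step_um)) if cell.edges else 0
    radii = radius_step_um * np.arange(1, n_shells + 1)

    deg = cell.degree()
    branch_nodes = [
        n for n, d in deg.items() if d >= 3 and n != cell.soma_node
    ]
    terminal_nodes = [
        n for n, d in deg.items() if d == 1 and n != cell.soma_node
    ]

    inter = np.zeros(len(radii), dtype=int)
    branch = np.zeros(len(radii), dtype=int)
    term = np.zeros(len(radii), dtype=int)
    for i, r in enumerate(radii):
        lo = r - radius_step_um
        for e in cell.edges:
            inter[i] += _segment_sphere_crossings(
                cell.nodes[e.node_a] - soma, cell.nodes[e.node_b] - soma, r
            )
        branch[i] = sum(1 for n in branch_nodes if lo < dist[n] <= r)
        term[i] = sum(1 for n in terminal_nodes if lo < dist[n] <= r)
    return ShollProfile(radii, inter, branch, term)


def _segment_sphere_crossings(a: np.ndarray, b: np.ndarray, r: float) -> int:
    """Number of times segment a→b (soma-centered coords) crosses |p| = r.

    Roots of |a + t(b−a)|² = r² strictly inside (0, 1); tangential grazes
    (double roots) count zero.
    """
    u = b - a
    qa = float(u @ u)
    if qa == 0.0:
        return 0
    qb = 2.0 * float(a @ u)
    qc = float(a @ a) - r * r
    disc = qb * qb - 4.0 * qa * qc
    if disc <= 0.0:
        return 0
    sq = np.sqrt(disc)
    return sum(1 for t in ((-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)) if 0 < t < 1)


# ---------------------------------------------------------------------------
# JSON round-trip (the on-disk morphology format)
# ---------------------------------------------------------------------------

def morphology_to_json(cell: CellMorphology, path: str | Path) -> None:
    payload = {
        "cell_id": cell.cell_id,
        "animal_id": cell.animal_id,
        "soma_node": cell.soma_node,
        "cell_volume_um3": cell.cell_volume_um3,
        "nodes": {str(k): list(map(float, v)) for k, v in cell.nodes.items()},
        "edges": [
            {"node_a": e.node_a, "node_b": e.node_b, "thickness_um": e.thickness_um}
            for e in cell.edges
        ],
        "cd68_component_volumes_um3": list(cell.cd68_component_volumes_um3),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def morphology_from_json(path: str | Path) -> CellMorphology:
    payload = json.loads(Path(path).read_text())
    return CellMorphology(
        nodes={int(k): np.array(v) for k, v in payload["nodes"].items()},
        edges=[SkeletonEdge(**e) for e in payload["edges"]],
        cd68_component_volumes_um3=payload["cd68_component_volumes_um3"],
        cell_volume_um3=payload["cell_volume_um3"],
        cell_id=payload["cell_id"],
        animal_id=payload["animal_id"],
        soma_node=payload["soma_node"],
    )
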