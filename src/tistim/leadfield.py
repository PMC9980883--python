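"""Lead fields, electrode layouts and stimulation targets.

The lead field is the linear map from electrode currents to the normal
component of the electric field at each cortical node.  With ``M`` electrodes
and electrode 0 as the current-return reference, the matrix has one column per
non-reference electrode: column ``m`` holds the field produced by +1 mA at
electrode ``m+1`` and -1 mA at the reference.  Any zero-sum current pattern is
a linear combination of these pairs, so the field of an arbitrary montage is a
single matrix-vector product.

Two generators are provided: an analytic multishell-sphere forward model
(see :mod:`tistim.sphere`) and a fast random smooth fixture whose per-column
magnitude decays with distance from the column's electrode, mimicking the
shallow bias of real scalp electrodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from . import sphere as _sphere
from .sphere import SphereModel

__all__ = [
    "ElectrodeLayout",
    "LeadField",
    "TargetSpec",
    "SchemaError",
    "fibonacci_cap_layout",
    "fibonacci_sphere_points",
    "compute_spherical_leadfield",
    "generate_random_leadfield",
    "default_spherical_leadfield",
    "select_depth_target",
    "save_leadfield",
    "load_leadfield",
    "export_leadfield_tsv",
]

FORMAT_VERSION = 1

#: Number of scalp electrodes in the high-definition layout.
DEFAULT_N_ELECTRODES = 69
#: Default number of cortex nodes in a target region.
DEFAULT_TARGET_SIZE = 50
#: Radius (mm) of the cortical evaluation surface in the default sphere model.
DEFAULT_CORTEX_RADIUS = 70.0


class SchemaError(ValueError):
    """A persisted lead-field container is missing a required field."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """Scalp electrode positions (unit vectors or 3-D points) and labels."""

    positions: np.ndarray
    labels: tuple[str, ...]
    reference_index: int = 0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (M, 3)")
        if pos.shape[0] < 2:
            raise ValueError("at least two electrodes are required")
        labels = tuple(self.labels)
        if len(labels) != pos.shape[0]:
            raise ValueError("one label per electrode required")
        if len(set(labels)) != len(labels):
            raise ValueError("electrode labels must be unique")
        if not 0 <= self.reference_index < pos.shape[0]:
            raise ValueError("reference_index out of range")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", labels)

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class LeadField:
    """Normal-field responses to unit reference-pair currents.

    ``matrix`` has shape (N nodes, M-1 electrodes) in V/m per mA; column ``m``
    corresponds to the pair (+1 mA at electrode ``m+1``, -1 mA at the
    reference electrode, index 0 by convention).
    """

    matrix: np.ndarray
    node_coords: np.ndarray
    node_normals: np.ndarray
    layout: ElectrodeLayout
    provenance: str = ""
    shell_radii: tuple[float, ...] = ()
    shell_conductivities: tuple[float, ...] = ()

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        coords = np.asarray(self.node_coords, dtype=float)
        normals = np.asarray(self.node_normals, dtype=float)
        if not np.all(np.isfinite(mat)):
            raise ValueError("lead-field matrix must be finite")
        if mat.shape[1] != self.layout.n_electrodes - 1:
            raise ValueError("column count must equal electrode count - 1")
        if coords.shape != (mat.shape[0], 3):
            raise ValueError("node_coords must be (N, 3)")
        if normals.shape != (mat.shape[0], 3):
            raise ValueError("node_normals must be (N, 3)")
        norms = np.linalg.norm(normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("node normals must be unit length (1e-6)")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "node_coords", coords)
        object.__setattr__(self, "node_normals", normals)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.layout.n_electrodes


@dataclass(frozen=True)
class TargetSpec:
    """Ordered node-index sets defining one or more target regions.

    ``target_field`` is the ideal normal-field vector used by least-squares
    targeting; by default 1 on target nodes and 0 elsewhere.
    """

    regions: tuple[tuple[int, ...], ...]
    n_nodes: int
    target_field: np.ndarray | None = None

    def __post_init__(self):
        regions = tuple(tuple(int(i) for i in r) for r in self.regions)
        if not regions or any(len(r) == 0 for r in regions):
            raise ValueError("each target region must be non-empty")
        flat = [i for r in regions for i in r]
        if len(set(flat)) != len(flat):
            raise ValueError("target regions must be disjoint")
        if any(i < 0 or i >= self.n_nodes for i in flat):
            raise ValueError("target index out of range")
        object.__setattr__(self, "regions", regions)
        if self.target_field is not None:
            tf = np.asarray(self.target_field, dtype=float)
            if tf.shape != (self.n_nodes,):
                raise ValueError("target_field must have one entry per node")
            object.__setattr__(self, "target_field", tf)

    @property
    def all_indices(self) -> np.ndarray:
        return np.asarray([i for r in self.regions for i in r], dtype=int)

    def binary_field(self) -> np.ndarray:
        if self.target_field is not None:
            return self.target_field
        v = np.zeros(self.n_nodes)
        v[self.all_indices] = 1.0
        return v

    def to_json(self) -> str:
        return json.dumps({"regions": [list(r) for r in self.regions]})

    @classmethod
    def from_json(cls, text: str, n_nodes: int) -> "TargetSpec":
        data = json.loads(text)
        return cls(regions=tuple(tuple(r) for r in data["regions"]),
                   n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def fibonacci_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform covering of the unit sphere (n points)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def fibonacci_cap_layout(n_electrodes: int = DEFAULT_N_ELECTRODES,
                         scalp_radius: float = 92.0,
                         cap_fraction: float = 0.75) -> ElectrodeLayout:
    """Electrode layout covering the upper portion of the scalp sphere.

    A Fibonacci lattice restricted to the spherical cap ``z > 1 - 2*cap_fraction``
    emulates a dense EEG-style montage without reproducing exact 10-10
    coordinates (the optimizers are layout-agnostic).
    """
    if n_electrodes < 2:
        raise ValueError("need at least two electrodes")
    # oversample the full sphere, keep the n highest-z points
    n_total = max(int(np.ceil(n_electrodes / cap_fraction)), n_electrodes)
    pts = fibonacci_sphere_points(n_total)
    keep = np.argsort(-pts[:, 2])[:n_electrodes]
    keep.sort()
    units = pts[keep]
    labels = tuple(f"E{i:02d}" for i in range(n_electrodes))
    return ElectrodeLayout(positions=units * scalp_radius, labels=labels)


def cortex_shell_nodes(n_nodes: int, outer_radius: float = DEFAULT_CORTEX_RADIUS,
                       inner_fraction: float = 1.0, seed: int = 0) -> np.ndarray:
    """Cortex node cloud: a sphere surface, or a volumetric shell.

    ``inner_fraction == 1`` gives a deterministic Fibonacci covering of the
    single sphere of ``outer_radius``.  ``inner_fraction < 1`` draws seeded
    quasi-random nodes filling the shell between ``inner_fraction*outer_radius``
    and ``outer_radius``, emulating cortical folds that reach depth.
    """
    if inner_fraction >= 1.0:
        return fibonacci_sphere_points(n_nodes) * outer_radius
    rng = np.random.default_rng(seed)
    units = fibonacci_sphere_points(n_nodes)
    lo, hi = inner_fraction ** 3, 1.0
    radii = outer_radius * rng.uniform(lo, hi, size=n_nodes) ** (1.0 / 3.0)
    return units * radii[:, None]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def compute_spherical_leadfield(model: SphereModel, layout: ElectrodeLayout,
                                cortex_nodes: np.ndarray,
                                provenance: str = "sphere") -> LeadField:
    """Lead field of the multishell-sphere model at the given cortex nodes.

    Node normals are radial (the sphere's stand-in for the cortical-surface
    normal).  Column ``m`` is the radial field for the pair (+1 mA at
    electrode ``m+1``, -1 mA at the reference electrode).
    """
    nodes = np.asarray(cortex_nodes, dtype=float)
    r = np.linalg.norm(nodes, axis=1)
    if np.any(r > model.scalp_radius):
        raise ValueError("cortex node outside the scalp radius")
    if np.any(r == 0):
        raise ValueError("cortex node at the sphere centre has no normal")
    elec_units = layout.positions / np.linalg.norm(layout.positions, axis=1,
                                                  keepdims=True)
    U = _sphere.radial_field_matrix(model, nodes, elec_units)
    ref = layout.reference_index
    cols = [m for m in range(layout.n_electrodes) if m != ref]
    matrix = U[:, cols] - U[:, [ref]]
    normals = nodes / r[:, None]
    return LeadField(matrix=matrix, node_coords=nodes, node_normals=normals,
                     layout=layout, provenance=provenance,
                     shell_radii=model.shell_radii,
                     shell_conductivities=model.shell_conductivities)


def generate_random_leadfield(n_nodes: int, n_electrodes: int,
                              smoothness_length: float = 25.0,
                              depth_decay: float = 0.02,
                              seed: int = 0,
                              cortex_radius: float = DEFAULT_CORTEX_RADIUS,
                              scalp_radius: float = 92.0) -> LeadField:
    """Random spatially smooth lead field for fast tests.

    Each column is a Gaussian-process-like field over node coordinates
    (random Fourier features with length scale ``smoothness_length`` mm)
    multiplied by ``exp(-depth_decay * d)`` where ``d`` is the distance (mm)
    from the node to the column's electrode; ``depth_decay = 0`` removes the
    distance trend entirely.
    """
    if n_nodes < 1 or n_electrodes < 2:
        raise ValueError("need n_nodes >= 1 and n_electrodes >= 2")
    rng = np.random.default_rng(seed)
    layout = fibonacci_cap_layout(n_electrodes, scalp_radius=scalp_radius)
    nodes = fibonacci_sphere_points(n_nodes) * cortex_radius
    n_feat = 64
    cols = []
    for m in range(1, n_electrodes):
        W = rng.normal(scale=1.0 / smoothness_length, size=(n_feat, 3))
        phase = rng.uniform(0, 2 * np.pi, size=n_feat)
        amp = rng.normal(size=n_feat) / np.sqrt(n_feat)
        smooth = np.cos(nodes @ W.T + phase) @ amp
        d = np.linalg.norm(nodes - layout.positions[m], axis=1)
        cols.append(smooth * np.exp(-depth_decay * d))
    matrix = np.column_stack(cols)
    normals = nodes / np.linalg.norm(nodes, axis=1, keepdims=True)
    return LeadField(matrix=matrix, node_coords=nodes, node_normals=normals,
                     layout=layout, provenance=f"random(seed={seed})")


def default_spherical_leadfield(n_nodes: int = 2000,
                                n_electrodes: int = DEFAULT_N_ELECTRODES,
                                inner_fraction: float = 1.0,
                                series_order: int = 120,
                                seed: int = 0) -> LeadField:
    """Convenience builder: default four-shell model, cap layout, cortex nodes."""
    model = SphereModel(series_order=series_order)
    layout = fibonacci_cap_layout(n_electrodes,
                                  scalp_radius=model.scalp_radius)
    nodes = cortex_shell_nodes(n_nodes, inner_fraction=inner_fraction,
                               seed=seed)
    return compute_spherical_leadfield(model, layout, nodes)


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------

def depth_anchor(leadfield: LeadField, depth_index: int,
                 direction: np.ndarray | None = None) -> np.ndarray:
    """Anchor point for a depth index in 1..5.

    Index ``i`` maps to a point at radius ``(1 - 0.12 i) * r_c`` along a fixed
    meridian direction, where ``r_c`` is the outermost cortex-node radius, so
    higher indices are strictly deeper.
    """
    if not 1 <= int(depth_index) <= 5:
        raise ValueError("depth_index must be in 1..5")
    r_c = float(np.max(np.linalg.norm(leadfield.node_coords, axis=1)))
    if direction is None:
        direction = np.array([1.0, 0.0, 0.35])
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    return direction * (1.0 - 0.12 * depth_index) * r_c


def select_depth_target(leadfield: LeadField, depth_index: int,
                        k: int = DEFAULT_TARGET_SIZE,
                        direction: np.ndarray | None = None) -> TargetSpec:
    """Target region: the ``k`` cortex nodes nearest the depth anchor."""
    if k > leadfield.n_nodes:
        raise ValueError("k exceeds the number of nodes")
    anchor = depth_anchor(leadfield, depth_index, direction)
    return nearest_node_target(leadfield, anchor, k)


def nearest_node_target(leadfield: LeadField, anchor: np.ndarray,
                        k: int = DEFAULT_TARGET_SIZE) -> TargetSpec:
    """Target region: ``k`` nodes nearest an arbitrary anchor point (mm)."""
    d = np.linalg.norm(leadfield.node_coords - np.asarray(anchor, float),
                       axis=1)
    idx = np.argsort(d, kind="stable")[:k]
    return TargetSpec(regions=(tuple(int(i) for i in idx),),
                      n_nodes=leadfield.n_nodes)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_REQUIRED_DATASETS = ("leadfield", "node_coords", "node_normals",
                      "electrode_positions", "electrode_labels")


def save_leadfield(leadfield: LeadField, path) -> None:
    """Write a lead field to a single-file HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["provenance"] = leadfield.provenance
        f.attrs["reference_index"] = leadfield.layout.reference_index
        f.create_dataset("leadfield", data=leadfield.matrix)
        f.create_dataset("node_coords", data=leadfield.node_coords)
        f.create_dataset("node_normals", data=leadfield.node_normals)
        f.create_dataset("electrode_positions", data=leadfield.layout.positions)
        f.create_dataset("electrode_labels", data=np.array(
            leadfield.layout.labels, dtype=h5py.string_dtype()))
        f.create_dataset("shell_radii", data=np.asarray(leadfield.shell_radii))
        f.create_dataset("shell_conductivities",
                         data=np.asarray(leadfield.shell_conductivities))


def load_leadfield(path) -> LeadField:
    """Read a lead field written by :func:`save_leadfield`.

    Raises :class:`SchemaError` naming the first missing required dataset and
    a :class:`ValueError` on format-version mismatch.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported lead-field container version {version} "
                f"(expected {FORMAT_VERSION})")
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise SchemaError(f"container is missing required "
                                  f"dataset '{name}'")
        labels = tuple(s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["electrode_labels"][()])
        layout = ElectrodeLayout(
            positions=f["electrode_positions"][()],
            labels=labels,
            reference_index=int(f.attrs.get("reference_index", 0)))
        return LeadField(
            matrix=f["leadfield"][()],
            node_coords=f["node_coords"][()],
            node_normals=f["node_normals"][()],
            layout=layout,
            provenance=str(f.attrs.get("provenance", "")),
            shell_radii=tuple(f["shell_radii"][()]) if "shell_radii" in f else (),
            shell_conductivities=tuple(f["shell_conductivities"][()])
            if "shell_conductivities" in f else ())


def export_leadfield_tsv(leadfield: LeadField, path) -> None:
    """TSV export: one row per node (coords, normals, per-electrode columns)."""
    import pandas as pd

    cols = {
        "x_mm": leadfield.node_coords[:, 0],
        "y_mm": leadfield.node_coords[:, 1],
        "z_mm": leadfield.node_coords[:, 2],
        "nx": leadfield.node_normals[:, 0],
        "ny": leadfield.node_normals[:, 1],
        "nz": leadfield.node_normals[:, 2],
    }
    ref = leadfield.layout.reference_index
    labels = [lab for i, lab in enumerate(leadfield.layout.labels) if i != ref]
    for j, lab in enumerate(labels):
        cols[f"E_{lab}"] = leadfield.matrix[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
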