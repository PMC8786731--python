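"""Parametric trussed-cage lattices.

The proprietary as-manufactured cage geometry is not publicly available, so
the cage is represented by a regular diagonal-braced strut lattice filling a
PLIF-class box footprint. The claims this package targets concern strain
statistics on a strut network, not one exact topology, so a parametric
stand-in is appropriate: vertical struts and crossing diagonals span the
caudal to the cranial face, both faces carry in-plane chord struts (these are
the contact surfaces), and a posterior screw-insertion block is emulated by a
sub-lattice of struts with an enlarged effective diameter, which makes that
region carry a disproportionate share of the load, as the real insertion
block does.

Geometry conventions (used package-wide): x is the anterior-posterior axis
(+x anterior), y the medio-lateral axis (midsagittal plane at y = 0), z the
cranio-caudal axis (+z cranial). Units are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

#: Ti-6Al-4V: Young's modulus (MPa) and Poisson ratio.
TITANIUM = (116_000.0, 0.32)


@dataclass(frozen=True)
class CageParams:
    """Parameters of the regular trussed-box cage generator.

    ``footprint_mm`` is (length, width) = (anterior-posterior, medio-lateral)
    extent. ``screw_block_fraction`` is the posterior fraction of the length
    whose struts get the enlarged block diameter.
    """

    footprint_mm: tuple[float, float] = (25.0, 10.0)
    height_mm: float = 11.0
    strut_diameter_mm: float = 0.6
    lattice_pitch_mm: float = 5.0
    screw_block_fraction: float = 0.25
    block_diameter_factor: float = 2.5
    material: tuple[float, float] = TITANIUM
    jitter_mm: float = 0.0

    def __post_init__(self) -> None:
        length, width = self.footprint_mm
        for name, v in [
            ("length", length),
            ("width", width),
            ("height_mm", self.height_mm),
            ("strut_diameter_mm", self.strut_diameter_mm),
            ("lattice_pitch_mm", self.lattice_pitch_mm),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not 0 <= self.screw_block_fraction <= 0.5:
            raise ValueError("screw_block_fraction must lie in [0, 0.5]")
        if self.lattice_pitch_mm > max(length, width):
            raise ValueError(
                "lattice_pitch_mm exceeds the footprint: no interior nodes"
            )


@dataclass
class CageLattice:
    """Node/strut graph of a trussed cage.

    ``struts`` holds ``(i, j, diameter_mm)`` triples indexing into ``nodes``.
    ``sets`` names the cranial/caudal contact-surface nodes and the
    screw-block nodes.
    """

    nodes: np.ndarray  # (n, 3) mm
    struts: list[tuple[int, int, float]]
    sets: dict[str, set[int]] = field(default_factory=dict)
    material: tuple[float, float] = TITANIUM

    def validate(self) -> None:
        n = len(self.nodes)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j, d in self.struts:
            if d <= 0:
                raise ValueError(f"strut ({i},{j}) has non-positive diameter")
            length = float(np.linalg.norm(self.nodes[j] - self.nodes[i]))
            if length < 1e-12:
                raise ValueError(f"zero-length strut ({i},{j})")
            g.add_edge(i, j)
        if n and not nx.is_connected(g):
            raise ValueError("strut graph is not a single connected component")
        cranial = self.sets.get("cranial_surface", set())
        caudal = self.sets.get("caudal_surface", set())
        if not cranial or not caudal:
            raise ValueError("cranial/caudal surface sets must be non-empty")
        if cranial & caudal:
            raise ValueError("cranial and caudal surface sets overlap")

    def strut_lengths(self) -> np.ndarray:
        return np.array(
            [np.linalg.norm(self.nodes[j] - self.nodes[i]) for i, j, _ in self.struts]
        )

    def lateral_surface_area(self) -> float:
        """Total lateral (cylindrical) strut surface, mm^2."""
        return float(
            sum(
                np.pi * d * np.linalg.norm(self.nodes[j] - self.nodes[i])
                for i, j, d in self.struts
            )
        )

    def mirrored(self) -> "CageLattice":
        """Reflection about the midsagittal (y = 0) plane."""
        nodes = self.nodes.copy()
        nodes[:, 1] *= -1.0
        return CageLattice(
            nodes=nodes,
            struts=list(self.struts),
            sets={k: set(v) for k, v in self.sets.items()},
            material=self.material,
        )


def _grid(extent: float, pitch: float) -> np.ndarray:
    n = max(2, int(round(extent / pitch)) + 1)
    return np.linspace(-extent / 2.0, extent / 2.0, n)


def generate_cage(params: CageParams = CageParams(), seed: int = 0) -> CageLattice:
    """Build the parametric trussed-box lattice.

    The node grid is symmetric about the midsagittal plane, so with
    ``jitter_mm == 0`` the lattice is bilaterally mirror-symmetric by
    construction. Seeded jitter (uniform per-coordinate perturbation of
    interior coordinates) is available to break that symmetry for robustness
    studies; it never moves nodes off the contact planes in z.
    """
    length, width = params.footprint_mm
    xs = _grid(length, params.lattice_pitch_mm)
    ys = _grid(width, params.lattice_pitch_mm)
    nx_, ny_ = len(xs), len(ys)
    h = params.height_mm

    nodes = []
    index: dict[tuple[int, int, int], int] = {}
    for layer, z in enumerate((0.0, h)):
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                index[(layer, i, j)] = len(nodes)
                nodes.append((x, y, z))
    nodes = np.asarray(nodes, dtype=float)

    if params.jitter_mm > 0:
        rng = np.random.default_rng(seed)
        jit = rng.uniform(-params.jitter_mm, params.jitter_mm, size=nodes.shape)
        jit[:, 2] = 0.0  # keep contact faces planar
        nodes = nodes + jit

    d = params.strut_diameter_mm
    edges: set[tuple[int, int]] = set()

    def add(a: int, b: int) -> None:
        edges.add((a, b) if a < b else (b, a))

    for i in range(nx_):
        for j in range(ny_):
            add(index[(0, i, j)], index[(1, i, j)])  # verticals
    # crossing diagonals in every x-bay and y-bay (X-bracing keeps the
    # lattice mirror-symmetric in y)
    for i in range(nx_ - 1):
        for j in range(ny_):
            add(index[(0, i, j)], index[(1, i + 1, j)])
            add(index[(0, i + 1, j)], index[(1, i, j)])
    for i in range(nx_):
        for j in range(ny_ - 1):
            add(index[(0, i, j)], index[(1, i, j + 1)])
            add(index[(0, i, j + 1)], index[(1, i, j)])
    # in-plane chords on both contact faces
    for layer in (0, 1):
        for i in range(nx_ - 1):
            for j in range(ny_):
                add(index[(layer, i, j)], index[(layer, i + 1, j)])
        for i in range(nx_):
            for j in range(ny_ - 1):
                add(index[(layer, i, j)], index[(layer, i, j + 1)])

    # posterior screw-insertion block: struts entirely within the posterior
    # screw_block_fraction of the length get the enlarged effective diameter
    x_thresh = -length / 2.0 + params.screw_block_fraction * length
    block_nodes = {
        k for k in range(len(nodes)) if nodes[k, 0] <= x_thresh + 1e-9
    }
    struts = []
    for a, b in sorted(edges):
        in_block = a in block_nodes and b in block_nodes
        struts.append((a, b, d * params.block_diameter_factor if in_block else d))

    sets = {
        "caudal_surface": {index[(0, i, j)] for i in range(nx_) for j in range(ny_)},
        "cranial_surface": {index[(1, i, j)] for i in range(nx_) for j in range(ny_)},
        "screw_block": block_nodes,
    }
    lattice = CageLattice(
        nodes=nodes, struts=struts, sets=sets, material=params.material
    )
    lattice.validate()
    return lattice


# ---------------------------------------------------------------------------
# plain-text and VTK IO
# ---------------------------------------------------------------------------

def write_lattice_txt(lattice: CageLattice, path) -> None:
    """Whitespace-delimited node/strut text format.

    ``# nodes: id x y z`` followed by one line per node, then
    ``# struts: id i j diameter`` followed by one line per strut, then
    ``# set: name id...`` lines for the named node sets.
    """
    with open(path, "w") as fh:
        fh.write("# nodes: id x y z\n")
        for k, (x, y, z) in enumerate(lattice.nodes):
            fh.write(f"{k} {x:.9g} {y:.9g} {z:.9g}\n")
        fh.write("# struts: id i j diameter\n")
        for k, (i, j, d) in enumerate(lattice.struts):
            fh.write(f"{k} {i} {j} {d:.9g}\n")
        for name, ids in sorted(lattice.sets.items()):
            fh.write(f"# set: {name} " + " ".join(map(str, sorted(ids))) + "\n")


def read_lattice_txt(path, material: tuple[float, float] = TITANIUM) -> CageLattice:
    nodes: list[list[float]] = []
    struts: list[tuple[int, int, float]] = []
    sets: dict[str, set[int]] = {}
    mode = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("nodes"):
                    mode = "nodes"
                elif body.startswith("struts"):
                    mode = "struts"
                elif body.startswith("set:"):
                    parts = body.split()
                    sets[parts[1]] = {int(t) for t in parts[2:]}
                continue
            parts = line.split()
            if mode == "nodes":
                nodes.append([float(p) for p in parts[1:4]])
            elif mode == "struts":
                struts.append((int(parts[1]), int(parts[2]), float(parts[3])))
    lattice = CageLattice(
        nodes=np.asarray(nodes, dtype=float),
        struts=struts,
        sets=sets,
        material=material,
    )
    lattice.validate()
    return lattice


def write_lattice_vtk(
    lattice: CageLattice,
    path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """VTK legacy ASCII unstructured grid: struts as line cells.

    ``point_data`` values are (n,) scalars or (n, 3) vectors per node;
    ``cell_data`` values are (n_struts,) scalars per strut.
    """
    n = len(lattice.nodes)
    m = len(lattice.struts)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntrusscage lattice\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} float\n")
        for x, y, z in lattice.nodes:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        fh.write(f"CELLS {m} {3 * m}\n")
        for i, j, _ in lattice.struts:
            fh.write(f"2 {i} {j}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("3\n" * m)  # VTK_LINE
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} float\n")
                    for row in arr:
                        fh.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n")
                else:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{v:.9g}\n")
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr, dtype=float):
                    fh.write(f"{v:.9g}\n")
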