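"""Small linear tetrahedral elasticity solver with error-energy post-processing.

The inlay (and optionally the patellar cartilage) can be analysed as a linear
elastostatic volume under mapped contact tractions: 4-node (linear) or 10-node
(quadratic) tetrahedra, isotropic material, direct sparse solve.

Post-processing provides the von Mises equivalent stress and a per-element
error energy used as a mesh-convergence indicator:

    e_i = 1/2 * integral_V  ds^T D^-1 ds  dV

where ds is the nodal stress error — the volume-averaged nodal stress minus
the element's own (unaveraged) nodal stress — interpolated over the element,
and D the elastic stress-strain matrix.  On a patch test (uniform stress
state) the averaged and unaveraged stresses coincide and every e_i vanishes;
under refinement of a smooth problem the total error energy decreases, which
is the convergence-study workflow implemented by :func:`convergence_study`.

Units: mm, N, MPa (N/mm^2); energies in N*mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# Voigt order: xx, yy, zz, xy, yz, xz (engineering shear strains)
_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]

#: tet10 edge definition (midside node k sits between corners EDGES[k])
EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]

# degree-2 quadrature (4 points) on the reference tetrahedron
_A4, _B4 = 0.5854101966249685, 0.1381966011250105
QUAD_DEG2 = (
    np.array(
        [
            [_A4, _B4, _B4],
            [_B4, _A4, _B4],
            [_B4, _B4, _A4],
            [_B4, _B4, _B4],
        ]
    ),
    np.full(4, 0.25),
)

# degree-5 quadrature (15 points, Keast) for quadratic error-energy integrands
def _keast15():
    from itertools import permutations

    pts = [(0.25, 0.25, 0.25, 0.25)]
    wts = [0.030283678097089]

    def add_perm(bary, w):
        seen = set()
        for p in permutations(bary):
            if p not in seen:
                seen.add(p)
                pts.append(p)
                wts.append(w)

    add_perm((0.0, 1 / 3, 1 / 3, 1 / 3), 0.006026785714286)
    add_perm((8 / 11, 1 / 11, 1 / 11, 1 / 11), 0.011645249086029)
    add_perm(
        (0.433449846426336, 0.433449846426336, 0.066550153573664, 0.066550153573664),
        0.010949141561386,
    )
    # barycentric (l0, l1, l2, l3) -> reference coords (l1, l2, l3); published
    # weights sum to 1/6 (the reference volume) so rescale to sum to 1
    return np.array([p[1:] for p in pts]), 6.0 * np.array(wts)


QUAD_DEG5 = _keast15()


def elastic_matrix(youngs: float, poisson: float) -> np.ndarray:
    """Isotropic stress-strain matrix D (6x6, Voigt, engineering shears)."""
    if youngs <= 0:
        raise ValueError("Young's modulus must be > 0")
    if not 0.0 <= poisson < 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    e, nu = youngs, poisson
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] += 2 * mu
    d[3:, 3:] = np.eye(3) * mu
    return d


@dataclass
class TetMesh:
    """Tetrahedral mesh: 4-node (linear) or 10-node (quadratic) elements."""

    nodes: np.ndarray  # (n, 3) mm
    tets: np.ndarray  # (m, 4) or (m, 10)
    youngs: float = 312.5  # MPa (PE inlay)
    poisson: float = 0.46
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.tets.ndim != 2 or self.tets.shape[1] not in (4, 10):
            raise ValueError("tets must be (m, 4) or (m, 10)")
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=int)

    @property
    def order(self) -> int:
        return 1 if self.tets.shape[1] == 4 else 2

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def corner_volumes(self) -> np.ndarray:
        c = self.nodes[self.tets[:, :4]]
        v = np.einsum(
            "ij,ij->i",
            np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0]),
            c[:, 3] - c[:, 0],
        ) / 6.0
        return v

    def validate(self) -> None:
        vols = self.corner_volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{int((vols <= 0).sum())} elements have non-positive Jacobian")


@dataclass
class TetMeshSolution:
    mesh: TetMesh
    displacements: np.ndarray  # (n, 3) mm
    element_nodal_stress: np.ndarray  # (m, nodes_per_el, 6) MPa, unaveraged
    element_stress: np.ndarray  # (m, 6) MPa, element mean
    von_mises: np.ndarray  # (m,) MPa, element mean stress
    strain_energy: float  # N*mm
    external_work: float  # N*mm (f . u)
    reactions: np.ndarray  # (n, 3) N, nonzero at fixed nodes
    error_energy: np.ndarray | None = None  # (m,) N*mm
    total_error_energy: float | None = None


# ---------------------------------------------------------------------------
# shape functions
# ---------------------------------------------------------------------------


def _tet10_shape(xi: np.ndarray):
    """Shape functions and reference gradients of the 10-node tetrahedron."""
    r, s, t = xi
    l0 = 1.0 - r - s - t
    l1, l2, l3 = r, s, t
    n = np.array(
        [
            l0 * (2 * l0 - 1),
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l0 * l1,
            4 * l1 * l2,
            4 * l0 * l2,
            4 * l0 * l3,
            4 * l1 * l3,
            4 * l2 * l3,
        ]
    )
    dl = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    dn = np.zeros((10, 3))
    lam = np.array([l0, l1, l2, l3])
    for a in range(4):
        dn[a] = (4 * lam[a] - 1) * dl[a]
    mid = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    for k, (a, b) in enumerate(mid):
        dn[4 + k] = 4 * (lam[a] * dl[b] + lam[b] * dl[a])
    return n, dn


def _tet4_shape(xi: np.ndarray):
    r, s, t = xi
    n = np.array([1.0 - r - s - t, r, s, t])
    dn = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    return n, dn


def _shape(order: int, xi: np.ndarray):
    return _tet4_shape(xi) if order == 1 else _tet10_shape(xi)


def _ref_nodes(order: int) -> np.ndarray:
    corners = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    if order == 1:
        return corners
    mids = np.array([(corners[a] + corners[b]) / 2 for a, b in EDGES])
    return np.vstack([corners, mids])


def _b_matrix(dn_xyz: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 3*nn) from shape gradients (nn, 3)."""
    nn = dn_xyz.shape[0]
    b = np.zeros((6, 3 * nn))
    b[0, 0::3] = dn_xyz[:, 0]
    b[1, 1::3] = dn_xyz[:, 1]
    b[2, 2::3] = dn_xyz[:, 2]
    b[3, 0::3] = dn_xyz[:, 1]
    b[3, 1::3] = dn_xyz[:, 0]
    b[4, 1::3] = dn_xyz[:, 2]
    b[4, 2::3] = dn_xyz[:, 1]
    b[5, 0::3] = dn_xyz[:, 2]
    b[5, 2::3] = dn_xyz[:, 0]
    return b


def assemble_and_solve(mesh: TetMesh, tractions=None, fixities=None, point_loads=None) -> TetMeshSolution:
    """Linear elastostatic solve under face tractions and nodal constraints.

    ``tractions``: list of (face_nodes, traction_vector) with face_nodes a
    3-tuple (linear faces) of node indices on the surface; the traction (MPa)
    is applied uniformly over the face and distributed consistently (equal
    thirds for linear faces; for quadratic meshes the face's midside nodes are
    located automatically and the 0/..., 1/3-per-midside consistent rule for a
    straight-sided quadratic triangle is used).
    ``fixities``: node indices fully clamped (defaults to mesh.fixed_nodes).
    ``point_loads``: list of (node, force_vector N).

    Raises a rank error naming the free rigid-body modes when the constraints
    are insufficient.
    """
    mesh.validate()
    order = mesh.order
    nn_el = 4 if order == 1 else 10
    n = mesh.n_nodes
    ndof = 3 * n
    d_mat = elastic_matrix(mesh.youngs, mesh.poisson)
    pts, wts = QUAD_DEG2

    rows, cols, vals = [], [], []
    for el in mesh.tets:
        xe = mesh.nodes[el]
        ke = np.zeros((3 * nn_el, 3 * nn_el))
        for xi, w in zip(pts, wts):
            _, dn = _shape(order, xi)
            jac = xe.T @ dn
            det = np.linalg.det(jac)
            if det <= 0:
                raise ValueError("negative Jacobian during assembly")
            b = _b_matrix(dn @ np.linalg.inv(jac))
            ke += b.T @ d_mat @ b * det * w / 6.0
        dof = np.repeat(el * 3, 3) + np.tile([0, 1, 2], nn_el)
        rows.append(np.repeat(dof, 3 * nn_el))
        cols.append(np.tile(dof, 3 * nn_el))
        vals.append(ke.ravel())
    k_mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(ndof, ndof)
    ).tocsr()

    f = np.zeros(ndof)
    if tractions:
        edge_lookup = _midside_lookup(mesh) if order == 2 else None
        for face, t_vec in tractions:
            face = tuple(int(i) for i in face)
            t_vec = np.asarray(t_vec, dtype=float)
            a, b_, c = (mesh.nodes[i] for i in face[:3])
            area = 0.5 * np.linalg.norm(np.cross(b_ - a, c - a))
            if order == 1:
                for i in face[:3]:
                    f[3 * i : 3 * i + 3] += t_vec * area / 3.0
            else:
                # consistent load vector for a straight-sided T6 face under
                # uniform traction: corners get 0, midsides get A/3 each
                mids = [
                    edge_lookup[frozenset((face[0], face[1]))],
                    edge_lookup[frozenset((face[1], face[2]))],
                    edge_lookup[frozenset((face[0], face[2]))],
                ]
                for i in mids:
                    f[3 * i : 3 * i + 3] += t_vec * area / 3.0
    if point_loads:
        for node, vec in point_loads:
            f[3 * node : 3 * node + 3] += np.asarray(vec, dtype=float)

    fixed = mesh.fixed_nodes if fixities is None else fixities
    fixed_dofs = _fixed_dofs(fixed)
    if len(fixed_dofs) < 6:
        raise _rank_error(mesh, fixed)
    free = np.setdiff1d(np.arange(ndof), fixed_dofs)
    k_ff = k_mat[np.ix_(free, free)]
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", spla.MatrixRankWarning)
            u_free = spla.spsolve(k_ff.tocsc(), f[free])
    except (spla.MatrixRankWarning, RuntimeError) as exc:
        raise _rank_error(mesh, fixed) from exc
    if not np.all(np.isfinite(u_free)):
        raise _rank_error(mesh, fixed)
    # a rank-deficient factorization can still return finite garbage: verify
    # the linear system is actually satisfied
    scale = max(1.0, float(np.abs(f[free]).max()) if len(free) else 1.0)
    if len(free) and float(np.abs(k_ff @ u_free - f[free]).max()) > 1e-6 * scale:
        raise _rank_error(mesh, fixed)
    u = np.zeros(ndof)
    u[free] = u_free
    reactions_vec = k_mat @ u - f
    reactions_vec[free] = 0.0
    reactions = reactions_vec.reshape(-1, 3)

    # element stresses at element nodes (unaveraged)
    ref = _ref_nodes(order)
    m = len(mesh.tets)
    el_nodal = np.zeros((m, nn_el, 6))
    el_mean = np.zeros((m, 6))
    for e, el in enumerate(mesh.tets):
        xe = mesh.nodes[el]
        ue = u.reshape(-1, 3)[el].ravel()
        for a, xi in enumerate(ref):
            _, dn = _shape(order, xi)
            jac = xe.T @ dn
            b = _b_matrix(dn @ np.linalg.inv(jac))
            el_nodal[e, a] = d_mat @ (b @ ue)
        el_mean[e] = el_nodal[e].mean(axis=0)
    strain_energy = 0.5 * float(u @ (k_mat @ u))
    external_work = float(f @ u)
    return TetMeshSolution(
        mesh=mesh,
        displacements=u.reshape(-1, 3),
        element_nodal_stress=el_nodal,
        element_stress=el_mean,
        von_mises=von_mises(el_mean),
        strain_energy=strain_energy,
        external_work=external_work,
        reactions=reactions,
    )


def _fixed_dofs(fixed) -> np.ndarray:
    """Normalize fixities: node indices (full clamp) or (node, component) pairs."""
    if fixed is None:
        return np.array([], dtype=int)
    fixed = list(np.atleast_1d(np.asarray(fixed, dtype=object)).tolist()) if not isinstance(fixed, (list, tuple)) else list(fixed)
    dofs = []
    for item in fixed:
        if isinstance(item, (tuple, list, np.ndarray)) and len(item) == 2:
            node, comp = int(item[0]), int(item[1])
            dofs.append(3 * node + comp)
        else:
            node = int(item)
            dofs.extend((3 * node, 3 * node + 1, 3 * node + 2))
    return np.unique(np.array(dofs, dtype=int))


def _rank_error(mesh: TetMesh, fixed) -> ValueError:
    n_dofs = len(_fixed_dofs(fixed))
    missing = max(0, 6 - n_dofs)
    return ValueError(
        f"singular stiffness system: {n_dofs} constrained DOFs leave at least {missing} "
        "rigid-body modes unconstrained (need fixities removing all 6 modes)"
    )


def _midside_lookup(mesh: TetMesh) -> dict:
    lookup = {}
    for el in mesh.tets:
        for k, (a, b) in enumerate(EDGES):
            lookup[frozenset((int(el[a]), int(el[b])))] = int(el[4 + k])
    return lookup


def von_mises(stress) -> np.ndarray:
    """Von Mises equivalent stress from Voigt stress (…, 6)."""
    s = np.asarray(stress, dtype=float)
    sq = (
        0.5 * ((s[..., 0] - s[..., 1]) ** 2 + (s[..., 1] - s[..., 2]) ** 2 + (s[..., 2] - s[..., 0]) ** 2)
        + 3.0 * (s[..., 3] ** 2 + s[..., 4] ** 2 + s[..., 5] ** 2)
    )
    return np.sqrt(np.maximum(sq, 0.0))


def averaged_nodal_stress(solution: TetMeshSolution) -> np.ndarray:
    """Volume-weighted average of element nodal stresses at each mesh node."""
    mesh = solution.mesh
    n = mesh.n_nodes
    acc = np.zeros((n, 6))
    wsum = np.zeros(n)
    vols = np.abs(mesh.corner_volumes())
    for e, el in enumerate(mesh.tets):
        for a, node in enumerate(el):
            acc[node] += vols[e] * solution.element_nodal_stress[e, a]
            wsum[node] += vols[e]
    wsum[wsum == 0] = 1.0
    return acc / wsum[:, None]


def error_energy(solution: TetMeshSolution) -> tuple[np.ndarray, float]:
    """Per-element error energy e_i = 1/2 int ds^T D^-1 ds dV and its total.

    ds is the averaged-minus-unaveraged nodal stress, interpolated over the
    element with its own shape functions; the integral uses a quadrature rule
    exact for the resulting polynomial degree.
    """
    mesh = solution.mesh
    order = mesh.order
    d_inv = np.linalg.inv(elastic_matrix(mesh.youngs, mesh.poisson))
    avg = averaged_nodal_stress(solution)
    pts, wts = QUAD_DEG2 if order == 1 else QUAD_DEG5
    e_i = np.zeros(len(mesh.tets))
    for e, el in enumerate(mesh.tets):
        ds_nodes = avg[el] - solution.element_nodal_stress[e]  # (nn, 6)
        xe = mesh.nodes[el]
        acc = 0.0
        for xi, w in zip(pts, wts):
            nvals, dn = _shape(order, xi)
            jac = xe.T @ dn
            det = abs(np.linalg.det(jac))
            ds = nvals @ ds_nodes
            acc += w * det / 6.0 * float(ds @ d_inv @ ds)
        e_i[e] = 0.5 * acc
    solution.error_energy = e_i
    solution.total_error_energy = float(e_i.sum())
    return e_i, solution.total_error_energy


# ---------------------------------------------------------------------------
# structured box meshing (for convergence studies and tests)
# ---------------------------------------------------------------------------

_CUBE_TETS = [
    (0, 1, 3, 7),
    (0, 1, 7, 5),
    (0, 5, 7, 4),
    (0, 3, 2, 7),
    (0, 2, 6, 7),
    (0, 6, 4, 7),
]


def box_mesh(lengths, size: float, order: int = 1, youngs: float = 312.5, poisson: float = 0.46) -> TetMesh:
    """Structured tetrahedral mesh of a box (6 tets per grid cell)."""
    lx, ly, lz = lengths
    nx = max(1, int(round(lx / size)))
    ny = max(1, int(round(ly / size)))
    nz = max(1, int(round(lz / size)))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = [
                    nid(i, j, k),
                    nid(i + 1, j, k),
                    nid(i, j + 1, k),
                    nid(i + 1, j + 1, k),
                    nid(i, j, k + 1),
                    nid(i + 1, j, k + 1),
                    nid(i, j + 1, k + 1),
                    nid(i + 1, j + 1, k + 1),
                ]
                for t in _CUBE_TETS:
                    tets.append([corner[a] for a in t])
    tets = np.array(tets, dtype=np.int64)
    # enforce positive Jacobian
    c = nodes[tets]
    vols = np.einsum("ij,ij->i", np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0]), c[:, 3] - c[:, 0])
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    mesh = TetMesh(nodes, tets, youngs=youngs, poisson=poisson)
    if order == 2:
        mesh = to_quadratic(mesh)
    return mesh


def to_quadratic(mesh: TetMesh) -> TetMesh:
    """Insert midside nodes, turning a linear mesh into a 10-node mesh."""
    if mesh.order != 1:
        return mesh
    nodes = [mesh.nodes]
    edge_ids: dict = {}
    next_id = mesh.n_nodes
    new_mids = []
    tets10 = []
    for el in mesh.tets:
        row = list(el)
        for a, b in EDGES:
            key = frozenset((int(el[a]), int(el[b])))
            if key not in edge_ids:
                edge_ids[key] = next_id
                new_mids.append(0.5 * (mesh.nodes[el[a]] + mesh.nodes[el[b]]))
                next_id += 1
            row.append(edge_ids[key])
        tets10.append(row)
    all_nodes = np.vstack([mesh.nodes, np.array(new_mids)]) if new_mids else mesh.nodes
    return TetMesh(all_nodes, np.array(tets10, dtype=np.int64), youngs=mesh.youngs, poisson=mesh.poisson)


def boundary_nodes(mesh: TetMesh, predicate) -> np.ndarray:
    """Node indices whose coordinates satisfy ``predicate(x, y, z)`` (vectorized)."""
    mask = predicate(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.nodes[:, 2])
    return np.nonzero(mask)[0]


def boundary_faces(mesh: TetMesh, predicate) -> list[tuple[int, int, int]]:
    """Corner-node surface triangles whose vertices all satisfy the predicate."""
    on = set(boundary_nodes(mesh, predicate).tolist())
    local_faces = [(0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)]
    from collections import Counter

    count: Counter = Counter()
    for el in mesh.tets:
        for lf in local_faces:
            tri = tuple(sorted(int(el[i]) for i in lf))
            count[tri] += 1
    faces = []
    for tri, c in count.items():
        if c == 1 and all(v in on for v in tri):
            faces.append(tri)
    return faces


# ---------------------------------------------------------------------------
# convergence study
# ---------------------------------------------------------------------------


def convergence_study(problem, sizes, threshold: float = 0.05):
    """Run ``problem(size) -> (mesh, tractions, fixities)`` over mesh sizes.

    Returns a pandas DataFrame with one row per size: peak von Mises stress,
    total error energy, and a convergence flag set when the change in peak
    stress relative to the previous (coarser) size falls below ``threshold``.
    Meshing or solve failures mark the row failed and the study continues.
    """
    import pandas as pd

    sizes = list(sizes)
    if len(sizes) < 1:
        raise ValueError("at least one mesh size required")
    rows = []
    prev_peak = None
    for size in sizes:
        row = {"size": float(size), "peak_von_mises": np.nan, "total_error_energy": np.nan,
               "n_elements": 0, "converged": False, "failed": False}
        try:
            mesh, tractions, fixities = problem(size)
            sol = assemble_and_solve(mesh, tractions=tractions, fixities=fixities)
            _, total = error_energy(sol)
            peak = float(sol.von_mises.max())
            row.update(peak_von_mises=peak, total_error_energy=total, n_elements=len(mesh.tets))
            if prev_peak is not None and prev_peak > 0:
                row["converged"] = abs(peak - prev_peak) / prev_peak < threshold
            prev_peak = peak
        except Exception as exc:
            row["failed"] = True
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# legacy-VTK exchange (ASCII)
# ---------------------------------------------------------------------------


def write_vtk(path, mesh: TetMesh, solution: TetMeshSolution | None = None) -> None:
    """Write the mesh (and optional solution fields) as legacy ASCII VTK."""
    cell_type = 10 if mesh.order == 1 else 24
    nn = mesh.tets.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntet mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {len(mesh.tets)} {len(mesh.tets) * (nn + 1)}\n")
        for el in mesh.tets:
            fh.write(" ".join([str(nn)] + [str(int(i)) for i in el]) + "\n")
        fh.write(f"CELL_TYPES {len(mesh.tets)}\n")
        fh.write("\n".join([str(cell_type)] * len(mesh.tets)) + "\n")
        if solution is not None:
            fh.write(f"POINT_DATA {mesh.n_nodes}\nVECTORS displacement double\n")
            for u in solution.displacements:
                fh.write(f"{u[0]:.9g} {u[1]:.9g} {u[2]:.9g}\n")
            fh.write(f"CELL_DATA {len(mesh.tets)}\nSCALARS von_mises double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.9g}" for v in solution.von_mises) + "\n")
            if solution.error_energy is not None:
                fh.write("SCALARS error_energy double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in solution.error_energy) + "\n")


def read_vtk(path) -> TetMesh:
    """Read a legacy ASCII VTK unstructured grid of tetrahedra."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
        n = int(lines[i].split()[1])
        vals = []
        j = i + 1
        while len(vals) < 3 * n:
            vals.extend(float(x) for x in lines[j].split())
            j += 1
        nodes = np.array(vals).reshape(n, 3)
        i = next(k for k, ln in enumerate(lines) if ln.startswith("CELLS"))
        m = int(lines[i].split()[1])
        cells = []
        for row in lines[i + 1 : i + 1 + m]:
            parts = [int(x) for x in row.split()]
            cells.append(parts[1 : 1 + parts[0]])
        tets = np.array(cells, dtype=np.int64)
    except (StopIteration, ValueError, IndexError) as exc:
        raise ValueError(f"malformed VTK file {path}: {exc}") from exc
    return TetMesh(nodes, tets)
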