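"""Finite-element forward solver for tDCS volume conduction.

Solves the anisotropic Laplace problem

    div(C grad u) = 0        in the head Omega
    -C grad u . n = g        on the boundary (injected current under the
                              anode, zero elsewhere; cathode = reference)

with first-order tetrahedral elements obtained from a fixed 6-tet Kuhn
decomposition of every non-air voxel.  Because the grid is regular, the six
per-tet gradient operators are identical across voxels, so the per-voxel
8x8 stiffness block is a linear combination of six precomputed matrices
contracted with the voxel's conductivity tensor — assembly is a single
einsum.  The linear system is solved with a Jacobi-preconditioned
conjugate-gradient iteration (relative tolerance 1e-6 by default); the
cathode patch is grounded (Dirichlet u = 0), which fixes the reference and
removes the Neumann null space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .containers import Grid, LabelVolume, TensorMap
from .phantom import ElectrodeMontage

__all__ = [
    "Mesh",
    "FaceSet",
    "StimulationProblem",
    "LinearSystem",
    "FieldSolution",
    "build_mesh",
    "exterior_faces",
    "plate_faces",
    "assemble_system",
    "solve_potential",
    "compute_fields",
    "check_current_conservation",
    "solve_problem",
]

# Voxel corner offsets, x fastest: corner k has offset CORNERS[k]
CORNERS = np.array(list(itertools.product((0, 1), repeat=3)))[:, ::-1].copy()
# -> [(0,0,0),(1,0,0),(0,1,0),(1,1,0),(0,0,1),(1,0,1),(0,1,1),(1,1,1)]
_CORNER_INDEX = {tuple(c): k for k, c in enumerate(CORNERS)}

# Kuhn split: one tet per permutation of the axes, walking the main diagonal
_PERMS = list(itertools.permutations(range(3)))


def _kuhn_tets() -> np.ndarray:
    """Local corner indices (6, 4) of the Kuhn 6-tet split of the unit cube."""
    tets = []
    for perm in _PERMS:
        v = [np.zeros(3, dtype=int)]
        for ax in perm:
            nxt = v[-1].copy()
            nxt[ax] = 1
            v.append(nxt)
        tets.append([_CORNER_INDEX[tuple(c)] for c in v])
    return np.array(tets)


KUHN_TETS = _kuhn_tets()


def _tet_gradients(voxel_size) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-tet P1 shape-function gradients on one voxel.

    Returns (tets (6,4) with positive orientation, grads (6,3,4), tet_volume).
    """
    h = np.asarray(voxel_size, float)
    tets = KUHN_TETS.copy()
    grads = np.zeros((6, 3, 4))
    vol = None
    for t in range(6):
        x = CORNERS[tets[t]] * h  # (4, 3)
        E = (x[1:] - x[0]).T  # (3, 3) edge matrix
        det = np.linalg.det(E)
        if det < 0:  # enforce positive orientation deterministically
            tets[t, [2, 3]] = tets[t, [3, 2]]
            x = CORNERS[tets[t]] * h
            E = (x[1:] - x[0]).T
            det = np.linalg.det(E)
        G = np.linalg.inv(E)  # row i-1 is grad of phi_i
        grads[t, :, 1:] = G.T  # columns 1..3
        grads[t, :, 0] = -grads[t, :, 1:].sum(axis=1)
        vol = det / 6.0
    return tets, grads, float(vol)


def _voxel_stiffness_basis(voxel_size) -> np.ndarray:
    """P[i, j] (3, 3, 8, 8): K_voxel = sum_ij C_ij P_ij for one voxel."""
    tets, grads, vol = _tet_gradients(voxel_size)
    P = np.zeros((3, 3, 8, 8))
    for t in range(6):
        idx = tets[t]
        G = grads[t]  # (3, 4)
        block = vol * np.einsum("ia,jb->ijab", G, G)  # (3,3,4,4)
        P[:, :, idx[:, None], idx[None, :]] += block
    # geometry is in mm: vol (mm^3) * grad^2 (1/mm^2) = mm = 1e-3 m, so this
    # factor puts K in siemens (C is S/m) and u in volts with f in amperes
    return P * 1e-3


def _voxel_gradient_operator(voxel_size) -> np.ndarray:
    """B (3, 8): volume-averaged gradient over the 6 tets of one voxel."""
    tets, grads, _ = _tet_gradients(voxel_size)
    B = np.zeros((3, 8))
    for t in range(6):
        B[:, tets[t]] += grads[t] / 6.0
    return B


@dataclass
class FaceSet:
    """A set of exterior voxel faces (quads) of the mesh.

    ``nodes`` are the 4 global node ids per face ordered (min, +u, +v,
    max); ``axis``/``side`` give the outward normal (+/- unit vector along
    ``axis``); ``owner`` is the flat index into the mesh's voxel list.
    """

    nodes: np.ndarray  # (Nf, 4) int
    areas: np.ndarray  # (Nf,)
    axis: np.ndarray  # (Nf,) in {0,1,2}
    side: np.ndarray  # (Nf,) in {-1,+1}
    owner: np.ndarray  # (Nf,) flat voxel index

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def node_loads(self, g: float) -> tuple[np.ndarray, np.ndarray]:
        """Consistent P1 nodal loads for a uniform flux density g over the set.

        Each quad is split along its min-max diagonal (matching the Kuhn
        tet faces); the diagonal nodes receive A/3 and the others A/6.
        """
        w = np.array([1 / 3, 1 / 6, 1 / 6, 1 / 3])
        loads = g * self.areas[:, None] * w[None, :]
        return self.nodes.ravel(), loads.ravel()

    def unique_nodes(self) -> np.ndarray:
        return np.unique(self.nodes)


@dataclass
class Mesh:
    """Tetrahedral mesh from the Kuhn split of every non-air voxel.

    Assembly and field evaluation use the per-voxel composite operators;
    :meth:`tetrahedra` materializes the individual elements (e.g. for VTK
    export or per-element checks).
    """

    grid: Grid
    voxel_index: np.ndarray  # (Nv, 3) integer voxel coords
    voxel_flat: np.ndarray  # (Nv,) flat index into grid arrays
    voxel_nodes: np.ndarray  # (Nv, 8) global node ids
    node_coords: np.ndarray  # (Nn, 3) mm
    face_sets: dict[str, FaceSet] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_flat)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def tetrahedra(self) -> tuple[np.ndarray, np.ndarray]:
        """(elements (6*Nv, 4) node ids, element->voxel map (6*Nv,))."""
        tets, _, _ = _tet_gradients(self.grid.voxel_size)
        elems = self.voxel_nodes[:, tets].reshape(-1, 4)  # (Nv, 6, 4) -> flat
        owner = np.repeat(np.arange(self.n_voxels), 6)
        return elems, owner

    def element_volumes(self) -> np.ndarray:
        elems, _ = self.tetrahedra()
        x = self.node_coords[elems]
        e = x[:, 1:] - x[:, :1]
        return np.linalg.det(np.swapaxes(e, 1, 2)) / 6.0

    def element_quality(self) -> np.ndarray:
        """Radius-ratio quality 3 r_in / r_circ per element (1 = regular)."""
        elems, _ = self.tetrahedra()
        x = self.node_coords[elems]
        vol = self.element_volumes()
        # face areas
        faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
        areas = np.zeros((len(elems), 4))
        for k, (a, b, c) in enumerate(faces):
            areas[:, k] = 0.5 * np.linalg.norm(
                np.cross(x[:, b] - x[:, a], x[:, c] - x[:, a]), axis=1
            )
        r_in = 3.0 * vol / areas.sum(axis=1)
        # circumradius from the standard determinant formula
        a = np.linalg.norm(x[:, 1] - x[:, 0], axis=1) * np.linalg.norm(x[:, 2] - x[:, 3], axis=1)
        b = np.linalg.norm(x[:, 2] - x[:, 0], axis=1) * np.linalg.norm(x[:, 1] - x[:, 3], axis=1)
        c = np.linalg.norm(x[:, 3] - x[:, 0], axis=1) * np.linalg.norm(x[:, 1] - x[:, 2], axis=1)
        p = np.sqrt((a + b + c) * (-a + b + c) * (a - b + c) * (a + b - c))
        r_circ = p / (24.0 * vol)
        return 3.0 * r_in / r_circ


def _exterior_face_arrays(
    inside: np.ndarray, node_id: np.ndarray, grid: Grid, restrict: Optional[np.ndarray]
) -> FaceSet:
    """Faces of ``inside`` voxels whose neighbor across the face is outside."""
    h = grid.voxel_size
    face_area = {0: h[1] * h[2], 1: h[0] * h[2], 2: h[0] * h[1]}
    shape = grid.shape
    sel = inside if restrict is None else (inside & restrict)
    all_nodes, all_area, all_axis, all_side, all_owner = [], [], [], [], []
    flat_index = np.arange(np.prod(shape)).reshape(shape)
    for axis in range(3):
        for side in (-1, 1):
            nb = np.roll(inside, -side, axis=axis)
            edge = [slice(None)] * 3
            edge[axis] = -1 if side == 1 else 0
            nb[tuple(edge)] = False
            exposed = sel & ~nb
            if not exposed.any():
                continue
            ii = np.argwhere(exposed)  # (M, 3)
            # corner offsets of the face: fixed coordinate along `axis`
            off_fixed = 1 if side == 1 else 0
            other = [a for a in range(3) if a != axis]
            corners = []
            for du, dv in ((0, 0), (1, 0), (0, 1), (1, 1)):
                off = np.zeros(3, dtype=int)
                off[axis] = off_fixed
                off[other[0]] = du
                off[other[1]] = dv
                corners.append(off)
            # order (min, +u, +v, max): corners already in that order
            quad = np.stack(
                [
                    node_id[tuple((ii + off[None, :]).T)]
                    for off in corners
                ],
                axis=1,
            )
            all_nodes.append(quad)
            all_area.append(np.full(len(ii), face_area[axis]))
            all_axis.append(np.full(len(ii), axis, dtype=int))
            all_side.append(np.full(len(ii), side, dtype=int))
            all_owner.append(flat_index[tuple(ii.T)])
    if not all_nodes:
        return FaceSet(
            np.zeros((0, 4), int), np.zeros(0), np.zeros(0, int), np.zeros(0, int), np.zeros(0, int)
        )
    return FaceSet(
        nodes=np.concatenate(all_nodes),
        areas=np.concatenate(all_area),
        axis=np.concatenate(all_axis),
        side=np.concatenate(all_side),
        owner=np.concatenate(all_owner),
    )


def build_mesh(labels: LabelVolume, montage: Optional[ElectrodeMontage] = None) -> Mesh:
    """Mesh every non-air voxel with the fixed 6-tet Kuhn split.

    If a montage is given, its electrode patches must already be present in
    the label volume; their exposed outer faces are stored as the named
    face sets ``anode`` and ``cathode``.
    """
    grid = labels.grid
    inside = labels.labels != labels.code("air")
    if not inside.any():
        raise ValueError("label volume has no non-air voxels to mesh")

    shape = grid.shape
    nshape = (shape[0] + 1, shape[1] + 1, shape[2] + 1)
    used = np.zeros(nshape, dtype=bool)
    vox = np.argwhere(inside)
    for off in CORNERS:
        used[tuple((vox + off[None, :]).T)] = True
    node_id = np.full(nshape, -1, dtype=np.int64)
    node_id[used] = np.arange(used.sum())
    nij = np.argwhere(used)
    node_coords = np.asarray(grid.origin) + (nij - 0.5) * np.asarray(grid.voxel_size)

    voxel_nodes = np.stack(
        [node_id[tuple((vox + off[None, :]).T)] for off in CORNERS], axis=1
    )
    flat = np.ravel_multi_index(tuple(vox.T), shape)

    mesh = Mesh(
        grid=grid,
        voxel_index=vox,
        voxel_flat=flat,
        voxel_nodes=voxel_nodes,
        node_coords=node_coords,
    )

    if montage is not None:
        for name, pmask in (("anode", montage.anode_mask), ("cathode", montage.cathode_mask)):
            fs = _exterior_face_arrays(inside, node_id, grid, restrict=pmask)
            if fs.nodes.shape[0] == 0:
                raise ValueError(
                    f"{name} patch of montage {montage.name!r} has no exposed faces; "
                    "montage is not attached to the mesh"
                )
            mesh.face_sets[name] = fs
    mesh._node_id = node_id  # kept for face extraction helpers
    mesh._inside = inside
    return mesh


def exterior_faces(mesh: Mesh, voxel_mask: Optional[np.ndarray] = None) -> FaceSet:
    """All exterior faces of the mesh (optionally restricted to a voxel mask)."""
    return _exterior_face_arrays(mesh._inside, mesh._node_id, mesh.grid, voxel_mask)


def plate_faces(mesh: Mesh, axis: int, side: int) -> FaceSet:
    """Exterior faces whose outward normal is +/- axis — an ideal plate electrode."""
    fs = exterior_faces(mesh)
    keep = (fs.axis == axis) & (fs.side == side)
    return FaceSet(fs.nodes[keep], fs.areas[keep], fs.axis[keep], fs.side[keep], fs.owner[keep])


@dataclass
class StimulationProblem:
    """Mesh + per-voxel conductivity tensors + electrode face sets + current.

    When ``anode_nodes``/``cathode_nodes`` are given (see
    :func:`montage_problem`), each electrode plate is treated as a perfect
    conductor: its nodes are condensed into one equipotential unknown and
    its elements are dropped from the stiffness (``excluded_voxels``).  The
    copper plate's internal resistance is ~1e-10 of the head's, so this is
    physically indistinguishable from meshing it at 5.99e7 S/m while
    removing a ~6e9 conductivity contrast from the linear system.
    """

    mesh: Mesh
    conductivity: TensorMap
    anode: FaceSet
    cathode: FaceSet
    current_I: float
    anode_nodes: Optional[np.ndarray] = None
    cathode_nodes: Optional[np.ndarray] = None
    excluded_voxels: Optional[np.ndarray] = None  # bool over mesh voxel list

    def __post_init__(self):
        if self.current_I <= 0:
            raise ValueError("current_I must be positive")
        if not self.conductivity.grid.same_geometry(self.mesh.grid):
            raise ValueError("conductivity grid does not match mesh grid")
        a = set(map(tuple, np.column_stack([self.anode.owner, self.anode.axis, self.anode.side])))
        c = set(map(tuple, np.column_stack([self.cathode.owner, self.cathode.axis, self.cathode.side])))
        if a & c:
            raise ValueError("anode and cathode face sets intersect")

    def element_tensors(self) -> np.ndarray:
        """(Nv, 3, 3) conductivity tensor per mesh voxel (checked symmetric PSD)."""
        C = self.conductivity.full().reshape(-1, 3, 3)[self.mesh.voxel_flat]
        ev = np.linalg.eigvalsh(C)
        bad = ev[:, 0] < -1e-12 * np.maximum(ev[:, 2], 1.0)
        if bad.any():
            k = int(np.argmax(bad))
            raise ValueError(
                f"non-positive-semidefinite conductivity tensor at mesh voxel {k} "
                f"(grid index {tuple(self.mesh.voxel_index[k])})"
            )
        return C


def montage_problem(
    mesh: Mesh,
    conductivity: TensorMap,
    montage: ElectrodeMontage,
    condense_electrodes: bool = True,
) -> StimulationProblem:
    """Stimulation problem for a sponge-pad montage attached to the mesh.

    Uses the ``anode``/``cathode`` face sets extracted by
    :func:`build_mesh`; with ``condense_electrodes`` (default) the metal
    plate voxels become equipotential super-nodes.
    """
    if "anode" not in mesh.face_sets or "cathode" not in mesh.face_sets:
        raise ValueError("mesh has no electrode face sets; build it with the montage")
    anode_nodes = cathode_nodes = excluded = None
    if condense_electrodes:
        sel_a = montage.anode_mask.ravel()[mesh.voxel_flat]
        sel_c = montage.cathode_mask.ravel()[mesh.voxel_flat]
        anode_nodes = np.unique(mesh.voxel_nodes[sel_a])
        cathode_nodes = np.unique(mesh.voxel_nodes[sel_c])
        excluded = sel_a | sel_c
    return StimulationProblem(
        mesh=mesh,
        conductivity=conductivity,
        anode=mesh.face_sets["anode"],
        cathode=mesh.face_sets["cathode"],
        current_I=montage.current_I,
        anode_nodes=anode_nodes,
        cathode_nodes=cathode_nodes,
        excluded_voxels=excluded,
    )


@dataclass
class LinearSystem:
    """Assembled FEM system on the (possibly condensed) unknowns.

    ``red`` maps each mesh node to its reduced unknown (electrode patches
    share one unknown when condensed); ``K``/``f`` live on the reduced
    space.  ``dirichlet``/``free`` refer to reduced indices.
    """

    K: sp.csr_matrix
    f: np.ndarray
    dirichlet: np.ndarray  # reduced ids fixed to 0 (empty for pure Neumann)
    free: np.ndarray  # boolean mask over reduced unknowns
    red: np.ndarray  # (n_nodes,) node -> reduced unknown
    n_nodes: int
    neumann_cathode: bool


def assemble_system(problem: StimulationProblem, cathode_dirichlet: bool = True) -> LinearSystem:
    """Assemble the P1 stiffness operator and electrode load vector.

    With ``cathode_dirichlet`` (default) the cathode is grounded (the
    voltage-reference convention) and only the anode carries a uniform
    Neumann influx I/area.  With ``cathode_dirichlet=False`` both
    electrodes are Neumann (influx/efflux), giving the pure-Neumann
    operator whose load sums to zero — the form used by the reciprocity
    checks.  Condensed electrode patches are merged into equipotential
    super-nodes before boundary conditions are applied.
    """
    mesh = problem.mesh
    C = problem.element_tensors()
    keep = np.ones(mesh.n_voxels, dtype=bool)
    if problem.excluded_voxels is not None:
        keep = ~np.asarray(problem.excluded_voxels, bool)

    # node -> reduced unknown map (identity unless electrodes are condensed)
    red = np.full(mesh.n_nodes, -1, dtype=np.int64)
    n_groups = 0
    for grp in (problem.anode_nodes, problem.cathode_nodes):
        if grp is not None and len(grp):
            red[grp] = n_groups
            n_groups += 1
    rest = red < 0
    red[rest] = n_groups + np.arange(int(rest.sum()))
    n_red = n_groups + int(rest.sum())

    P = _voxel_stiffness_basis(mesh.grid.voxel_size)  # (3,3,8,8)
    K8 = np.einsum("vij,ijab->vab", C[keep], P)
    nodes = red[mesh.voxel_nodes[keep]]
    rows = np.repeat(nodes, 8, axis=1).ravel()
    cols = np.tile(nodes, (1, 8)).ravel()
    K = sp.coo_matrix((K8.ravel(), (rows, cols)), shape=(n_red, n_red)).tocsr()

    f = np.zeros(n_red)
    g_a = problem.current_I / problem.anode.total_area
    nid, loads = problem.anode.node_loads(g_a)
    np.add.at(f, red[nid], loads)

    if cathode_dirichlet:
        dirichlet = np.unique(red[problem.cathode.unique_nodes()])
        free = np.ones(n_red, dtype=bool)
        free[dirichlet] = False
    else:
        g_c = problem.current_I / problem.cathode.total_area
        nid, loads = problem.cathode.node_loads(-g_c)
        np.add.at(f, red[nid], loads)
        dirichlet = np.zeros(0, dtype=int)
        free = np.ones(n_red, dtype=bool)

    return LinearSystem(
        K=K, f=f, dirichlet=dirichlet, free=free, red=red,
        n_nodes=mesh.n_nodes, neumann_cathode=not cathode_dirichlet,
    )


def solve_potential(
    system: LinearSystem,
    rel_tol: float = 1e-6,
    maxiter: int = 50000,
) -> tuple[np.ndarray, dict]:
    """Jacobi-preconditioned conjugate-gradient solve of the assembled system.

    The iteration is restarted until the *recomputed* residual
    ``||f - K u|| / ||f||`` meets ``rel_tol`` (the recursive CG residual can
    drift on ill-conditioned systems).  Returns the nodal potential (V) and
    diagnostics (iteration count, final relative residual); raises on
    non-convergence with the residual history attached.
    """
    free = system.free
    K = system.K[free][:, free].tocsr() if system.dirichlet.size else system.K
    f = system.f[free]

    diag = K.diagonal()
    diag = np.where(diag > 0, diag, 1.0)
    M = spla.LinearOperator(K.shape, matvec=lambda x: x / diag)

    fnorm = np.linalg.norm(f)
    history: list[float] = []
    iters = 0
    u_free = np.zeros_like(f)
    if fnorm > 0.0:
        converged = False
        for _ in range(10):
            n_it = [0]

            def cb(xk):
                n_it[0] += 1

            u_free, _ = spla.cg(
                K, f, x0=u_free, rtol=rel_tol, atol=0.25 * rel_tol * fnorm,
                maxiter=maxiter, M=M, callback=cb,
            )
            iters += n_it[0]
            res = float(np.linalg.norm(f - K @ u_free) / fnorm)
            history.append(res)
            if res <= rel_tol:
                converged = True
                break
            if iters >= maxiter:
                break
        if not converged:
            raise RuntimeError(
                f"conjugate gradient failed to reach rel_tol={rel_tol} within "
                f"{iters} iterations; relative residual history: {history}"
            )

    u_red = np.zeros(len(system.f))
    u_red[free] = u_free
    u = u_red[system.red]
    if system.neumann_cathode:
        u -= u.mean()  # pure-Neumann solution fixed to zero mean
    res = float(np.linalg.norm(f - K @ u_free) / fnorm) if fnorm else 0.0
    return u, {"iterations": iters, "relative_residual": res}


@dataclass
class FieldSolution:
    """Potential with element-wise electric field and current density.

    ``E`` and ``J`` are per-voxel-element constant vectors mapped onto the
    label grid (zero outside the mesh); ``J = C E`` holds exactly per
    element because the conductivity is constant within each voxel.
    """

    grid: Grid
    u: np.ndarray  # (Nn,) nodal potential, V
    E: np.ndarray  # (*shape, 3), V/m
    J: np.ndarray  # (*shape, 3), A/m^2
    mask: np.ndarray  # (*shape,) meshed voxels
    diagnostics: dict

    @property
    def E_mag(self) -> np.ndarray:
        return np.linalg.norm(self.E, axis=-1)

    @property
    def J_mag(self) -> np.ndarray:
        return np.linalg.norm(self.J, axis=-1)


def compute_fields(u: np.ndarray, problem: StimulationProblem, diagnostics: dict | None = None) -> FieldSolution:
    """Element-wise E = -grad u and J = -C grad u from the nodal potential.

    Gradients are P1-exact per tetrahedron; the stored per-voxel value is
    the volume average of the voxel's six tets.  Coordinates are mm, so the
    mm-based gradient is rescaled by 1e3 to yield V/m and (with C in S/m)
    A/m^2.
    """
    mesh = problem.mesh
    B = _voxel_gradient_operator(mesh.grid.voxel_size)  # (3, 8), per-mm
    u_corners = u[mesh.voxel_nodes]  # (Nv, 8)
    grad = u_corners @ B.T  # (Nv, 3) V/mm
    E_vox = -grad * 1e3  # V/m
    C = problem.element_tensors()
    J_vox = np.einsum("vij,vj->vi", C, E_vox)

    shape = mesh.grid.shape
    E = np.zeros(shape + (3,))
    J = np.zeros(shape + (3,))
    mask = np.zeros(shape, dtype=bool)
    E.reshape(-1, 3)[mesh.voxel_flat] = E_vox
    J.reshape(-1, 3)[mesh.voxel_flat] = J_vox
    mask.ravel()[mesh.voxel_flat] = True
    return FieldSolution(
        grid=mesh.grid, u=u, E=E, J=J, mask=mask, diagnostics=dict(diagnostics or {})
    )


def _face_flux(solution: FieldSolution, faces: FaceSet) -> float:
    """Integral of J . n over a face set, using the owner element's J (A)."""
    J = solution.J.reshape(-1, 3)[faces.owner]  # A/m^2
    n_comp = J[np.arange(len(faces.owner)), faces.axis] * faces.side
    return float((n_comp * faces.areas * 1e-6).sum())  # mm^2 -> m^2


def check_current_conservation(solution: FieldSolution, problem: StimulationProblem) -> dict:
    """Report anode/cathode flux vs the injected current and the net
    boundary flux (divergence-theorem check).  Report only; never raises."""
    I = problem.current_I
    anode_influx = -_face_flux(solution, problem.anode)  # current entering
    cathode_outflux = _face_flux(solution, problem.cathode)  # current leaving
    all_faces = exterior_faces(problem.mesh)
    net = _face_flux(solution, all_faces)
    return {
        "current_I": I,
        "anode_flux": anode_influx,
        "cathode_flux": cathode_outflux,
        "anode_flux_ratio": anode_influx / I,
        "cathode_flux_ratio": cathode_outflux / I,
        "net_boundary_flux": net,
        "net_flux_fraction": net / I,
    }


def box_problem(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    tensors: np.ndarray,
    current_I: float,
    axis: int = 2,
    patch_half_voxels: int | None = None,
) -> StimulationProblem:
    """Rectangular-box oracle problem with plate electrodes on opposite faces.

    ``tensors`` is a scalar, a (*shape,) scalar field, or a (*shape, 3, 3)
    tensor field (S/m).  Electrodes cover the full min/max faces along
    ``axis`` (anode at the max side) unless ``patch_half_voxels`` restricts
    them to a centered square patch (specified in voxels so that
    coordinate-stretched variants keep identical index-space patches) —
    the 3D spreading configuration used by the anisotropy
    stretch-equivalence check.
    """
    grid = Grid(shape=tuple(shape), voxel_size=tuple(voxel_size), origin=(0.0, 0.0, 0.0))
    labels = LabelVolume(grid, np.ones(shape, np.int16), {0: "air", 1: "scalp"})
    mesh = build_mesh(labels)

    t = np.asarray(tensors, dtype=float)
    if t.ndim == 0:
        C = TensorMap.isotropic(grid, np.full(shape, float(t)), np.ones(shape, bool), "S/m")
    elif t.shape == tuple(shape):
        C = TensorMap.isotropic(grid, t, np.ones(shape, bool), "S/m")
    else:
        C = TensorMap.from_full(grid, t, np.ones(shape, bool), "S/m")

    anode = plate_faces(mesh, axis, 1)
    cathode = plate_faces(mesh, axis, -1)
    if patch_half_voxels is not None:
        other = [a for a in range(3) if a != axis]
        vox_ijk = np.stack(np.unravel_index(np.arange(np.prod(shape)), shape), axis=1)

        def restrict(fs: FaceSet) -> FaceSet:
            ijk = vox_ijk[fs.owner]
            keep = np.ones(len(fs.areas), bool)
            for a in other:
                keep &= np.abs(ijk[:, a] + 0.5 - shape[a] / 2.0) <= patch_half_voxels
            return FaceSet(fs.nodes[keep], fs.areas[keep], fs.axis[keep], fs.side[keep], fs.owner[keep])

        anode, cathode = restrict(anode), restrict(cathode)
    return StimulationProblem(mesh=mesh, conductivity=C, anode=anode, cathode=cathode, current_I=current_I)


def solve_problem(
    problem: StimulationProblem,
    rel_tol: float = 1e-6,
    cathode_dirichlet: bool = True,
    maxiter: int = 50000,
) -> FieldSolution:
    """Assemble, solve and differentiate in one call."""
    system = assemble_system(problem, cathode_dirichlet=cathode_dirichlet)
    u, diag = solve_potential(system, rel_tol=rel_tol, maxiter=maxiter)
    return compute_fields(u, problem, diagnostics=diag)
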