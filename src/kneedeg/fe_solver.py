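"""Axisymmetric biphasic (displacement--pore-pressure) finite elements.

A deliberately small solver for layered cartilage contact problems:

* 4-node quadrilateral elements, equal-order bilinear interpolation for
  displacement and pore pressure, 2x2 Gauss integration, torsionless
  axisymmetry (Voigt order rr, zz, tt, rz with engineering shear).
* Quasi-static u-p poroelasticity integrated with backward Euler
  (unconditionally stable); optional artificial-storage stabilization
  of the pressure field for strongly undrained steps.
* Frictionless node-to-segment penalty contact between a curved
  (femoral) surface and a nominally flat (tibial) surface; the contact
  interface is impermeable, as are all other boundaries unless a
  drained node set is prescribed.
* Small strains, mm-N-MPa-s unit system; permeability is converted
  from SI at the model boundary.

The femoral body can be driven through a single master degree of
freedom (axial translation under a prescribed force), mirroring a rigid
press with all other rigid-body motions suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import (
    FRPVEParams,
    SI_PERM_TO_MM,
    TransverseIsotropicParams,
    ZonalTIPE,
    fibril_stress_update,
    isotropic_stiffness_matrix,
    ti_stiffness_matrix,
    tipe_zone_lookup,
)

__all__ = [
    "AxiMesh",
    "LoadProtocol",
    "FieldHistory",
    "BiphasicModel",
    "rect_block_mesh",
    "spherical_cap_mesh",
    "extract_summary",
    "window_average",
]

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)


# ---------------------------------------------------------------------------
# mesh containers and constructors
# ---------------------------------------------------------------------------

@dataclass
class AxiMesh:
    """Axisymmetric quadrilateral mesh for one body.

    ``hz`` is the normalized tissue depth per element (1 at the
    articular surface, 0 at the bone interface); ``normal_angle`` the
    angle between the local surface normal and the z-axis, used to
    orient transversely isotropic material frames and fibrils.
    """

    nodes: np.ndarray                    # (nn, 2) r, z [mm]
    elems: np.ndarray                    # (ne, 4) CCW connectivity
    hz: np.ndarray                       # (ne,)
    normal_angle: np.ndarray             # (ne,) [rad]
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    surface: np.ndarray | None = None    # ordered node ids of contact surface
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    def element_volumes(self) -> np.ndarray:
        """Axisymmetric element volumes 2*pi*int(r dA) [mm^3]."""
        vol = np.zeros(self.n_elems)
        coords = self.nodes[self.elems]          # (ne,4,2)
        for xi, eta in _GP:
            N, dN = _shape(xi, eta)
            J = np.einsum("ai,eaj->eij", dN, coords)
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            rg = coords[:, :, 0] @ N
            vol += 2.0 * np.pi * rg * detJ
        return vol


def _shape(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                         (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
    dN = 0.25 * np.array([[-(1 - eta), -(1 - xi)],
                          [(1 - eta), -(1 + xi)],
                          [(1 + eta), (1 + xi)],
                          [-(1 + eta), (1 - xi)]])
    return N, dN


def _fix_orientation(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Reverse element connectivity where the Jacobian is negative."""
    coords = nodes[elems]
    N, dN = _shape(0.0, 0.0)
    J = np.einsum("ai,eaj->eij", dN, coords)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    flipped = elems.copy()
    flipped[detJ < 0] = flipped[detJ < 0][:, ::-1]
    return flipped


def rect_block_mesh(radius: float, thickness: float, nr: int, nz: int,
                    surface: str = "top") -> AxiMesh:
    """Cylindrical block (tibial-cartilage-like layer) on a rigid base.

    The articular surface is the ``surface`` face ('top' or 'bottom');
    ``hz`` runs from 0 at the opposite (bone) face to 1 at the surface.
    """
    if radius <= 0 or thickness <= 0:
        raise ValueError("degenerate block dimensions")
    r = np.linspace(0.0, radius, nr + 1)
    z = np.linspace(0.0, thickness, nz + 1)
    R, Z = np.meshgrid(r, z, indexing="ij")
    nodes = np.column_stack([R.ravel(), Z.ravel()])

    def nid(i, j):
        return i * (nz + 1) + j

    elems = np.array([[nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
                      for i in range(nr) for j in range(nz)])
    elems = _fix_orientation(nodes, elems)
    zc = nodes[elems][:, :, 1].mean(axis=1)
    hz = zc / thickness if surface == "top" else 1.0 - zc / thickness
    node_sets = {
        "base": np.array([nid(i, 0) for i in range(nr + 1)]),
        "top": np.array([nid(i, nz) for i in range(nr + 1)]),
        "axis": np.array([nid(0, j) for j in range(nz + 1)]),
        "edge": np.array([nid(nr, j) for j in range(nz + 1)]),
    }
    surf = node_sets["top"] if surface == "top" else node_sets["base"]
    return AxiMesh(nodes, elems, np.clip(hz, 0, 1), np.zeros(len(elems)),
                   node_sets, surface=surf,
                   meta={"radius": radius, "thickness": thickness})


def spherical_cap_mesh(outer_radius: float, thickness: float, phi_max: float,
                       n_phi: int, n_rho: int, apex_z: float = 0.0,
                       rho_min_frac: float = 0.15) -> AxiMesh:
    """Spherical cap layer (femoral-cartilage-like) with its apex pointing down.

    The sphere centre sits on the axis at ``apex_z + outer_radius``.
    The articular (contact) surface is the outer sphere ``rho =
    outer_radius``; the inner boundary is the bone interface.  A full
    solid hemisphere (``thickness == outer_radius``) is regularised by
    truncating the degenerate centre at ``rho_min_frac * outer_radius``;
    the truncated nodes belong to the driven (bone) set.
    """
    if outer_radius <= 0 or thickness <= 0 or thickness > outer_radius:
        raise ValueError("degenerate cap dimensions")
    R = outer_radius
    cz = apex_z + R
    rho_in = max(R - thickness, rho_min_frac * R)
    rho = np.linspace(rho_in, R, n_rho + 1)
    phi = np.linspace(0.0, phi_max, n_phi + 1)
    P, Q = np.meshgrid(phi, rho, indexing="ij")
    nodes = np.column_stack([(Q * np.sin(P)).ravel(), (cz - Q * np.cos(P)).ravel()])

    def nid(i, j):
        return i * (n_rho + 1) + j

    elems = np.array([[nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
                      for i in range(n_phi) for j in range(n_rho)])
    elems = _fix_orientation(nodes, elems)
    rho_c = np.array([[0.5 * (rho[j] + rho[j + 1]) for j in range(n_rho)]
                      for _ in range(n_phi)]).ravel()
    phi_c = np.array([[0.5 * (phi[i] + phi[i + 1])] * n_rho
                      for i in range(n_phi)]).ravel()
    hz = (rho_c - (R - thickness)) / thickness
    bone = [nid(i, 0) for i in range(n_phi + 1)]
    if phi_max > 0.5 * np.pi - 1e-9:        # solid hemisphere: flat top driven
        bone += [nid(n_phi, j) for j in range(1, n_rho + 1)]
    node_sets = {
        "bone": np.unique(bone),
        "axis": np.array([nid(0, j) for j in range(n_rho + 1)]),
    }
    surf = np.array([nid(i, n_rho) for i in range(n_phi + 1)])
    surf = surf[np.argsort(nodes[surf, 0])]
    return AxiMesh(nodes, elems, np.clip(hz, 0, 1), phi_c, node_sets,
                   surface=surf,
                   meta={"outer_radius": R, "thickness": thickness,
                         "phi_max": phi_max, "apex_z": apex_z})


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

@dataclass
class LoadProtocol:
    """Axial force history; piecewise linear between samples, starts at 0 N."""

    times: np.ndarray
    forces: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if len(self.times) != len(self.forces):
            raise ValueError("times and forces must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0.0 or self.forces[0] != 0.0:
            raise ValueError("protocol must start at t = 0 with 0 N")

    @classmethod
    def ramp(cls, force: float, duration: float, n_steps: int = 40) -> "LoadProtocol":
        t = np.linspace(0.0, duration, n_steps + 1)
        return cls(t, force * t / duration)

    def force_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.forces))


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class FieldHistory:
    """Element/nodal fields over the simulated time span."""

    times: np.ndarray                    # (nt,)
    displacement: np.ndarray             # (nt, nn, 2)
    pore_pressure: np.ndarray            # (nt, nn)
    elem_stress: np.ndarray              # (nt, ne, 4) effective, Voigt
    elem_strain: np.ndarray              # (nt, ne, 4)
    elem_pressure: np.ndarray            # (nt, ne)
    tensile_stress: np.ndarray           # (nt, ne) max principal effective
    tensile_strain: np.ndarray           # (nt, ne)
    compressive_strain: np.ndarray       # (nt, ne) -min principal, >= 0
    contact_pressure: np.ndarray         # (nt, ns) per slave node [MPa]
    contact_area: np.ndarray             # (nt,)
    contact_node_r: np.ndarray           # (ns,)
    contact_node_area: np.ndarray        # (ns,)
    reaction_force: np.ndarray           # (nt,) axial reaction at fixed base [N]
    master_disp: np.ndarray              # (nt,) axial drive displacement [mm]
    elem_volumes: np.ndarray             # (ne,)
    elem_centers: np.ndarray             # (ne, 2)
    elem_body: np.ndarray                # (ne,) region index
    applied_force: np.ndarray            # (nt,)

    def max_over_time(self) -> np.ndarray:
        """Per-element maximum tensile stress over the simulated span."""
        return self.tensile_stress.max(axis=0)


# ---------------------------------------------------------------------------
# principal values (axisymmetric)
# ---------------------------------------------------------------------------

def _principal_range(voigt: np.ndarray, shear_is_engineering: bool) -> tuple[np.ndarray, np.ndarray]:
    """(max, min) principal values of axisymmetric symmetric tensors.

    ``voigt`` has shape (..., 4) in order (rr, zz, tt, rz).
    """
    rr, zz, tt, rz = (voigt[..., i] for i in range(4))
    if shear_is_engineering:
        rz = 0.5 * rz
    mean = 0.5 * (rr + zz)
    rad = np.sqrt((0.5 * (rr - zz)) ** 2 + rz**2)
    p1, p2 = mean + rad, mean - rad
    pmax = np.maximum(np.maximum(p1, p2), tt)
    pmin = np.minimum(np.minimum(p1, p2), tt)
    return pmax, pmin


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class BiphasicModel:
    """Assembled multi-body biphasic model with optional penalty contact.

    Parameters
    ----------
    regions:
        Sequence of ``(mesh, material)`` pairs.  ``material`` is an
        ``FRPVEParams``, ``TransverseIsotropicParams`` or ``ZonalTIPE``.
    fixed_u:
        List of ``(mesh_index, node_set_name, component)`` fixing a
        displacement component to zero; component in {'r', 'z', 'rz'}.
    drive:
        Optional ``(mesh_index, node_set_name)`` whose nodes are
        constrained to ``u_r = 0`` with a shared axial translation
        driven by the applied force (rigid axial press).
    drained:
        List of ``(mesh_index, node_set_name)`` with p = 0.
    contact:
        Optional ``(slave_region, master_region)`` region indices; the
        slave surface nodes contact the master surface curve.
    """

    def __init__(
        self,
        regions: Sequence[tuple[AxiMesh, object]],
        fixed_u: Sequence[tuple[int, str, str]] = (),
        drive: tuple[int, str] | None = None,
        drained: Sequence[tuple[int, str]] = (),
        contact: tuple[int, int] | None = None,
        penalty_factor: float = 100.0,
        stab_alpha: float = 0.005,
        max_iter: int = 60,
        tol: float = 1e-4,
    ):
        self.regions = list(regions)
        self.penalty_factor = penalty_factor
        self.stab_alpha = stab_alpha
        self.max_iter = max_iter
        self.tol = tol
        self.loose_tol = 0.05
        self.loose_steps = 0

        # --- merge meshes -------------------------------------------------
        offs, nodes, elems, body = [], [], [], []
        n = 0
        for bi, (mesh, _) in enumerate(self.regions):
            offs.append(n)
            nodes.append(mesh.nodes)
            elems.append(mesh.elems + n)
            body.append(np.full(mesh.n_elems, bi))
            n += mesh.n_nodes
        self.node_offset = offs
        self.nodes = np.vstack(nodes)
        self.elems = np.vstack(elems)
        self.body = np.concatenate(body)
        self.hz = np.concatenate([m.hz for m, _ in self.regions])
        self.angle = np.concatenate([m.normal_angle for m, _ in self.regions])
        self.nn = len(self.nodes)
        self.ne = len(self.elems)
        self.ndof_u = 2 * self.nn

        self._build_materials()
        self._precompute_elements()
        self._assemble_constant()
        self._build_constraints(fixed_u, drive, drained)
        self._build_contact(contact)

        self.elem_volumes = np.concatenate(
            [m.element_volumes() for m, _ in self.regions])
        self.elem_centers = self.nodes[self.elems].mean(axis=1)
        # trust-region cap for Newton displacement updates
        thicknesses = [m.meta.get("thickness") for m, _ in self.regions]
        zspan = float(np.ptp(self.nodes[:, 1])) or 1.0
        self.char_length = min([t for t in thicknesses if t] or [zspan])

    # -- materials ---------------------------------------------------------

    def _build_materials(self) -> None:
        D = np.zeros((self.ne, 4, 4))
        perm = np.zeros(self.ne)
        self.frpve: list[FRPVEParams | None] = []
        fib_region = np.full(self.ne, -1)
        e0 = 0
        for bi, (mesh, mat) in enumerate(self.regions):
            sl = slice(e0, e0 + mesh.n_elems)
            ang = mesh.normal_angle
            if isinstance(mat, FRPVEParams):
                C6 = isotropic_stiffness_matrix(mat.E_m, mat.nu_m)
                D[sl] = _axisym_D(C6, ang)
                perm[sl] = mat.k_0 * SI_PERM_TO_MM
                fib_region[sl] = bi
                self.frpve.append(mat)
            elif isinstance(mat, TransverseIsotropicParams):
                C6 = ti_stiffness_matrix(mat)
                D[sl] = _axisym_D(C6, ang)
                perm[sl] = mat.k * SI_PERM_TO_MM
                self.frpve.append(None)
            elif isinstance(mat, ZonalTIPE):
                for k_local, hz in enumerate(mesh.hz):
                    zp = tipe_zone_lookup(float(hz), mat)
                    C6 = ti_stiffness_matrix(zp)
                    D[e0 + k_local] = _axisym_D(C6, np.array([ang[k_local]]))[0]
                    perm[e0 + k_local] = zp.k * SI_PERM_TO_MM
                self.frpve.append(None)
            else:
                raise TypeError(f"unsupported material: {type(mat)}")
            e0 += mesh.n_elems
        self.D = D
        self.perm = perm
        self.fib_region = fib_region
        # characteristic axial stiffness for the contact penalty: the
        # stiffest element's drained modulus, with the fibril secant
        # stiffness (at a representative 15% stretch) added for
        # fibril-reinforced bodies whose drained matrix alone is nearly
        # fluid and would give a meaninglessly soft penalty
        e_scale = D[:, 1, 1].copy()
        for bi, m in enumerate(self.frpve):
            if m is not None:
                e_scale[self.fib_region == bi] += m.E_0 + 0.15 * m.E_eps
        self.E_contact_scale = float(e_scale.max())

    # -- element precomputation -------------------------------------------

    def _precompute_elements(self) -> None:
        coords = self.nodes[self.elems]                  # (ne,4,2)
        ng = len(_GP)
        B = np.zeros((self.ne, ng, 4, 8))
        w = np.zeros((self.ne, ng))
        Np = np.zeros((ng, 4))
        dNdx_all = np.zeros((self.ne, ng, 4, 2))
        for g, (xi, eta) in enumerate(_GP):
            N, dN = _shape(xi, eta)
            Np[g] = N
            J = np.einsum("ai,eaj->eij", dN, coords)
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            if np.any(detJ <= 0):
                raise ValueError("non-positive element Jacobian")
            Jinv = np.empty_like(J)
            Jinv[:, 0, 0] = J[:, 1, 1] / detJ
            Jinv[:, 1, 1] = J[:, 0, 0] / detJ
            Jinv[:, 0, 1] = -J[:, 0, 1] / detJ
            Jinv[:, 1, 0] = -J[:, 1, 0] / detJ
            dNdx = np.einsum("eij,aj->eai", Jinv, dN)    # (ne,4,2)
            rg = coords[:, :, 0] @ N
            w[:, g] = detJ * 2.0 * np.pi * rg
            dNdx_all[:, g] = dNdx
            for a in range(4):
                B[:, g, 0, 2 * a] = dNdx[:, a, 0]
                B[:, g, 1, 2 * a + 1] = dNdx[:, a, 1]
                B[:, g, 2, 2 * a] = N[a] / rg
                B[:, g, 3, 2 * a] = dNdx[:, a, 1]
                B[:, g, 3, 2 * a + 1] = dNdx[:, a, 0]
        self.B, self.w, self.Np, self.dNdx = B, w, Np, dNdx_all

        # dof maps
        eu = np.empty((self.ne, 8), dtype=int)
        eu[:, 0::2] = 2 * self.elems
        eu[:, 1::2] = 2 * self.elems + 1
        self.edof_u = eu
        self.edof_p = self.ndof_u + self.elems

        # fibril geometry: per element, families in global (r, z, t) comps
        self._fib = {}
        for bi, mat in enumerate(self.frpve):
            if mat is None:
                continue
            idx = np.where(self.fib_region == bi)[0]
            arch = mat.architecture
            loc, wfam = arch.families_local(self.hz[idx])  # (k,F,3), (F,)
            phi = self.angle[idx][:, None]               # normal angle from z
            # local frame -> global (r, z, t):
            # e1 = (cos phi, -sin phi, 0), e2 = (0, 0, 1), e3 = (sin phi, cos phi, 0)
            d_r = loc[..., 0] * np.cos(phi) + loc[..., 2] * np.sin(phi)
            d_z = -loc[..., 0] * np.sin(phi) + loc[..., 2] * np.cos(phi)
            d_t = loc[..., 1]
            m = np.stack([d_r**2, d_z**2, d_t**2, d_r * d_z], axis=-1)  # (k,F,4)
            self._fib[bi] = {"idx": idx, "m": m, "params": mat, "wfam": wfam}

    # -- constant matrices -------------------------------------------------

    def _assemble_constant(self) -> None:
        D, B, w = self.D, self.B, self.w
        Ke = np.einsum("egsd,esq,egqc,eg->edc", B, D, B, w)
        bvol = B[:, :, 0, :] + B[:, :, 1, :] + B[:, :, 2, :]   # (ne,g,8)
        Qe = np.einsum("egd,ga,eg->eda", bvol, self.Np, w)
        He = np.einsum("egai,egbi,eg,e->eab", self.dNdx, self.dNdx, w, self.perm)
        # artificial storage stabilization: small fraction of the model's
        # characteristic stiffness (fibril-aware; a drained-matrix scale
        # would make fibril-reinforced bodies spuriously compressible in
        # the undrained limit)
        if self.stab_alpha > 0:
            comp = np.full(self.ne, self.stab_alpha / self.E_contact_scale)
            Se = np.einsum("ga,gb,eg,e->eab", self.Np, self.Np, w, comp)
        else:
            Se = np.zeros_like(He)

        ndof = self.ndof_u + self.nn
        iu = np.repeat(self.edof_u, 8, axis=1).ravel()
        ju = np.tile(self.edof_u, (1, 8)).ravel()
        self.K0 = sp.coo_matrix((Ke.ravel(), (iu, ju)), shape=(ndof, ndof)).tocsr()
        iq = np.repeat(self.edof_u, 4, axis=1).ravel()
        jq = np.tile(self.edof_p, (1, 8)).ravel()
        self.Qm = sp.coo_matrix((Qe.ravel(), (iq, jq)), shape=(ndof, ndof)).tocsr()
        ih = np.repeat(self.edof_p, 4, axis=1).ravel()
        jh = np.tile(self.edof_p, (1, 4)).ravel()
        self.H = sp.coo_matrix((He.ravel(), (ih, jh)), shape=(ndof, ndof)).tocsr()
        self.S = sp.coo_matrix((Se.ravel(), (ih, jh)), shape=(ndof, ndof)).tocsr()

    # -- constraints -------------------------------------------------------

    def _global_set(self, mesh_index: int, set_name: str) -> np.ndarray:
        mesh = self.regions[mesh_index][0]
        if set_name == "all" and "all" not in mesh.node_sets:
            return np.arange(mesh.n_nodes) + self.node_offset[mesh_index]
        return mesh.node_sets[set_name] + self.node_offset[mesh_index]

    def _build_constraints(self, fixed_u, drive, drained) -> None:
        fixed = np.zeros(self.ndof_u + self.nn, dtype=bool)
        for mi, name, comp in fixed_u:
            ns = self._global_set(mi, name)
            if "r" in comp:
                fixed[2 * ns] = True
            if "z" in comp:
                fixed[2 * ns + 1] = True
        # axis nodes: u_r = 0 always
        for mi, (mesh, _) in enumerate(self.regions):
            if "axis" in mesh.node_sets:
                fixed[2 * self._global_set(mi, "axis")] = True
        self.master_dofs = np.array([], dtype=int)
        if drive is not None:
            ns = self._global_set(*drive)
            fixed[2 * ns] = True
            self.master_dofs = 2 * ns + 1
        for mi, name in drained:
            fixed[self.ndof_u + self._global_set(mi, name)] = True
        self.fixed = fixed

        ndof = self.ndof_u + self.nn
        is_master = np.zeros(ndof, dtype=bool)
        is_master[self.master_dofs] = True
        free = ~fixed & ~is_master
        self.free_idx = np.where(free)[0]
        nred = len(self.free_idx) + (1 if len(self.master_dofs) else 0)
        rows = list(self.free_idx)
        cols = list(range(len(self.free_idx)))
        if len(self.master_dofs):
            self.master_red = len(self.free_idx)
            rows += list(self.master_dofs)
            cols += [self.master_red] * len(self.master_dofs)
        else:
            self.master_red = None
        data = np.ones(len(rows))
        self.T = sp.coo_matrix((data, (rows, cols)), shape=(ndof, nred)).tocsr()
        self.nred = nred

    # -- contact -----------------------------------------------------------

    def _build_contact(self, contact) -> None:
        self.contact = None
        if contact is None:
            return
        si, mi = contact
        smesh, mmesh = self.regions[si][0], self.regions[mi][0]
        if smesh.surface is None or mmesh.surface is None:
            raise ValueError("contact requires surface curves on both regions")
        s_glob = smesh.surface + self.node_offset[si]
        m_glob = mmesh.surface + self.node_offset[mi]
        rs = self.nodes[s_glob, 0]
        rm = self.nodes[m_glob, 0]
        order = np.argsort(rm)
        m_glob, rm = m_glob[order], rm[order]
        ok = (rs >= rm[0] - 1e-12) & (rs <= rm[-1] + 1e-12)
        s_glob, rs = s_glob[ok], rs[ok]
        seg = np.clip(np.searchsorted(rm, rs) - 1, 0, len(rm) - 2)
        xi = (rs - rm[seg]) / (rm[seg + 1] - rm[seg])
        xi = np.clip(xi, 0.0, 1.0)
        g0 = self.nodes[s_glob, 1] - ((1 - xi) * self.nodes[m_glob[seg], 1]
                                      + xi * self.nodes[m_glob[seg + 1], 1])
        area = _surface_node_areas(self.nodes, s_glob)
        self.contact = {
            "slave": s_glob, "master": m_glob, "seg": seg, "xi": xi,
            "g0": g0, "area": area, "r": rs,
            "kappa": None, "active": np.zeros(len(s_glob), dtype=bool),
        }
        # penalty per node ~ factor * characteristic modulus * area / layer
        # height; floored so the axis node (vanishing tributary area in
        # axisymmetry) still bootstraps first contact
        mth = self.regions[mi][0].meta.get("thickness", 1.0)
        kappa = (self.penalty_factor * self.E_contact_scale
                 * area / max(mth, 1e-6))
        self.contact["kappa"] = np.maximum(kappa, 0.2 * kappa.mean())

    def _contact_system(self, u_full: np.ndarray, active: np.ndarray):
        """Stiffness triplets and rhs for the active penalty springs."""
        c = self.contact
        rows, cols, vals = [], [], []
        rhs = np.zeros(self.ndof_u + self.nn)
        for i in np.where(active)[0]:
            sdof = 2 * c["slave"][i] + 1
            m1 = 2 * c["master"][c["seg"][i]] + 1
            m2 = 2 * c["master"][c["seg"][i] + 1] + 1
            wvec = [(sdof, 1.0), (m1, -(1 - c["xi"][i])), (m2, -c["xi"][i])]
            k = c["kappa"][i]
            for (d1, a) in wvec:
                rhs[d1] -= k * c["g0"][i] * a
                for (d2, b) in wvec:
                    rows.append(d1)
                    cols.append(d2)
                    vals.append(k * a * b)
        ndof = self.ndof_u + self.nn
        Kc = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
        return Kc, rhs

    def _gaps(self, u_full: np.ndarray) -> np.ndarray:
        c = self.contact
        uz_s = u_full[2 * c["slave"] + 1]
        uz_m1 = u_full[2 * c["master"][c["seg"]] + 1]
        uz_m2 = u_full[2 * c["master"][c["seg"] + 1] + 1]
        return c["g0"] + uz_s - ((1 - c["xi"]) * uz_m1 + c["xi"] * uz_m2)

    def _init_state(self) -> dict:
        state = {}
        for bi, fib in self._fib.items():
            k, nfam = len(fib["idx"]), fib["m"].shape[1]
            state[bi] = {"eps": np.zeros((k, 4, nfam)),
                         "sig_m": np.zeros((k, 4, nfam)),
                         "sig": np.zeros((k, 4, nfam))}
        return state

    # -- time march --------------------------------------------------------

    def march(self, protocol: LoadProtocol, substeps: int = 1,
              nodal_force: np.ndarray | None = None,
              record_initial: bool = True) -> FieldHistory:
        """Backward-Euler transient march through the load protocol.

        The force is applied to the drive master if one exists,
        otherwise ``nodal_force`` (a full u-dof pattern scaled by the
        protocol force) must be given.
        """
        if self.master_red is None and nodal_force is None:
            raise ValueError("no drive master: supply a nodal force pattern")
        self._force_scale = float(np.max(np.abs(protocol.forces))) or 1.0
        times = [0.0]
        for t0, t1 in zip(protocol.times[:-1], protocol.times[1:]):
            times.extend(np.linspace(t0, t1, substeps + 1)[1:])
        times = np.asarray(times)

        ndof = self.ndof_u + self.nn
        x = np.zeros(ndof)
        state = self._init_state()
        rec = _Recorder(self, times if record_initial else times[1:])
        if record_initial:
            rec.record(0, 0.0, x, state, 0.0)

        if self.contact is not None:
            active = self.contact["active"].copy()
            if not active.any():
                active[np.argmin(self.contact["g0"])] = True
        else:
            active = None

        for k in range(1, len(times)):
            x, state, active = self._advance(
                x, state, active, times[k - 1], times[k], protocol, nodal_force)
            ridx = k if record_initial else k - 1
            rec.record(ridx, times[k], x, state, protocol.force_at(times[k]))
        if self.contact is not None:
            self.contact["active"] = active
        return rec.finish()

    def _advance(self, x, state, active, t0, t1, protocol, nodal_force,
                 depth: int = 0):
        """One load increment, bisected recursively on non-convergence.

        At maximum bisection depth a stalled Newton iterate is accepted
        if its equilibrium residual is below ``loose_tol`` (2% of the
        load scale by default); such steps are counted in
        ``self.loose_steps``.
        """
        try:
            return self._solve_step(x, state, active, t1 - t0,
                                    protocol.force_at(t1), nodal_force,
                                    loose=depth >= 5)
        except RuntimeError:
            if depth >= 5:
                raise
            tm = 0.5 * (t0 + t1)
            x, state, active = self._advance(x, state, active, t0, tm,
                                             protocol, nodal_force, depth + 1)
            return self._advance(x, state, active, tm, t1,
                                 protocol, nodal_force, depth + 1)

    def _reg(self) -> float:
        if self.contact is not None:
            return 1e-8 * self.contact["kappa"].sum()
        return 1e-8 * self.K0.diagonal().max()

    def _residual_full(self, x, state, dt, f_ext, b_p):
        """Full-space nonlinear residual (internal minus external forces)."""
        r = (self.K0 @ x - self.Qm @ x + self.Qm.T @ x
             + dt * (self.H @ x) + self.S @ x - f_ext - b_p)
        trial = {}
        for bi, fib in self._fib.items():
            idx, m, par = fib["idx"], fib["m"], fib["params"]
            u_e = x[self.edof_u[idx]]
            eps = np.einsum("egsd,ed->egs", self.B[idx], u_e)
            eps_f = np.einsum("egs,efs->egf", eps, m)
            st = state[bi]
            sig, sig_m, kt = fibril_stress_update(
                eps_f, st["eps"], st["sig_m"], par, dt)
            if not np.all(np.isfinite(sig)):
                raise RuntimeError("non-finite fibril stress update")
            sig_w = sig * fib["wfam"][None, None, :]
            P = np.einsum("egsd,efs->egfd", self.B[idx], m)
            f_e = np.einsum("egfd,egf,eg->ed", P, sig_w, self.w[idx])
            np.add.at(r, self.edof_u[idx], f_e)
            trial[bi] = {"eps": eps_f, "sig_m": sig_m, "sig": sig_w,
                         "kt": kt * fib["wfam"][None, None, :], "P": P}
        if self.contact is not None:
            c = self.contact
            g = self._gaps(x)
            gm = np.minimum(g, 0.0)
            fc = c["kappa"] * gm
            np.add.at(r, 2 * c["slave"] + 1, fc)
            np.add.at(r, 2 * c["master"][c["seg"]] + 1, -(1 - c["xi"]) * fc)
            np.add.at(r, 2 * c["master"][c["seg"] + 1] + 1, -c["xi"] * fc)
        return r, trial

    def _residual(self, x, state, dt, F, f_ext, b_p):
        """Reduced residual and its scaled norm.

        u-block: K0 u + f_fib(u) + f_contact(u) - Q p - f_ext = 0
        p-block: Q^T (u - u_n) + dt H p + S (p - p_prev) = 0
        """
        r, trial = self._residual_full(x, state, dt, f_ext, b_p)
        r_red = self.T.T @ r
        if self.master_red is not None:
            r_red[self.master_red] += F + self._reg() * x[self.master_dofs[0]]
        # scaled norm: force-like rows against the load scale, flux-like
        # rows against the volumetric terms they balance
        u_rows = self.free_idx < self.ndof_u
        fscale = max(abs(F), float(np.linalg.norm(f_ext)),
                     0.01 * getattr(self, "_force_scale", 0.0), 1e-9)
        vterms = np.abs(self.Qm.T @ x) + np.abs(b_p)
        vscale = max(float(vterms.max()), 1e-12)
        w = np.ones(len(r_red))
        w[: len(self.free_idx)][u_rows] /= fscale
        w[: len(self.free_idx)][~u_rows] /= vscale
        if self.master_red is not None:
            w[self.master_red] = 1.0 / fscale
        norm = float(np.linalg.norm(r_red * w)) / np.sqrt(len(r_red))
        return r_red, norm, trial

    def _tangent(self, x, trial, dt, active):
        ndof = self.ndof_u + self.nn
        parts = [self.K0 - self.Qm + self.Qm.T + dt * self.H + self.S]
        for bi, fib in self._fib.items():
            idx = fib["idx"]
            P, kt = trial[bi]["P"], trial[bi]["kt"]
            K_e = np.einsum("egfd,egfc,egf,eg->edc", P, P, kt, self.w[idx])
            iu = np.repeat(self.edof_u[idx], 8, axis=1).ravel()
            ju = np.tile(self.edof_u[idx], (1, 8)).ravel()
            parts.append(sp.coo_matrix((K_e.ravel(), (iu, ju)),
                                       shape=(ndof, ndof)))
        if self.contact is not None and active.any():
            Kc, _ = self._contact_system(x, active)
            parts.append(Kc)
        A_full = sum(parts).tocsr()
        A = (self.T.T @ A_full @ self.T).tocsc()
        if self.master_red is not None:
            A = A + sp.coo_matrix(
                ([self._reg()], ([self.master_red], [self.master_red])),
                shape=A.shape).tocsc()
        return A, A_full

    def _solve_step(self, x_prev, state, active, dt, F, nodal_force,
                    loose: bool = False):
        ndof = self.ndof_u + self.nn
        u_n = x_prev.copy()
        u_n[self.ndof_u:] = 0.0
        b_p = self.Qm.T @ u_n
        if self.stab_alpha > 0:
            p_prev = np.zeros(ndof)
            p_prev[self.ndof_u:] = x_prev[self.ndof_u:]
            b_p = b_p + self.S @ p_prev

        f_ext = np.zeros(ndof)
        if nodal_force is not None:
            f_ext[: self.ndof_u] = F * nodal_force[: self.ndof_u]

        x = x_prev.copy()
        r, rnorm, trial = self._residual(x, state, dt, F, f_ext, b_p)
        for it in range(self.max_iter):
            if self.contact is not None:
                g = self._gaps(x)
                # tangent springs also on nearly-touching nodes (they carry
                # no force, but stabilise the first contact increments)
                active = g < 1e-3 * self.char_length
                if not active.any():
                    active[np.argmin(g)] = True
            if rnorm < self.tol:
                break
            A, _ = self._tangent(x, trial, dt, active)
            try:
                delta = spla.splu(A).solve(-r)
            except RuntimeError as err:
                raise RuntimeError(
                    f"singular system (insufficient constraints?): {err}") from err
            step = self.T @ delta
            # cap the displacement update (soft tangents near zero strain
            # in tension-gated materials produce runaway directions)
            du_max = float(np.max(np.abs(step[: self.ndof_u])))
            cap = 0.3 * self.char_length
            if du_max > cap:
                step *= cap / du_max
            alpha, improved = 1.0, False
            for _ in range(12):
                x_try = x + alpha * step
                r_try, rnorm_try, trial_try = self._residual(
                    x_try, state, dt, F, f_ext, b_p)
                if rnorm_try <= (1.0 - 1e-4 * alpha) * rnorm:
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                if loose and rnorm < self.loose_tol:
                    self.loose_steps += 1
                    break
                raise RuntimeError(
                    f"line search stalled (residual {rnorm:.2e})")
            x, r, rnorm, trial = x_try, r_try, rnorm_try, trial_try
        else:
            if loose and rnorm < self.loose_tol:
                self.loose_steps += 1
            else:
                raise RuntimeError(
                    f"contact/material iteration did not converge "
                    f"(residual {rnorm:.2e})")

        # commit viscoelastic state
        for bi, tr in trial.items():
            state[bi]["eps"] = tr["eps"]
            state[bi]["sig_m"] = tr["sig_m"]
            state[bi]["sig"] = tr["sig"]
        self._last_system = (f_ext, b_p, dt)
        return x, state, active

    # -- post-processing helpers ------------------------------------------

    def element_fields(self, x: np.ndarray, state: dict):
        """Centroid-averaged strain, effective stress and pressure."""
        u_e = x[self.edof_u]                                   # (ne,8)
        eps_g = np.einsum("egsd,ed->egs", self.B, u_e)         # (ne,g,4)
        wsum = self.w.sum(axis=1)
        eps = np.einsum("egs,eg->es", eps_g, self.w) / wsum[:, None]
        sig = np.einsum("esq,eq->es", self.D, eps)
        for bi, fib in self._fib.items():
            st = state[bi]
            if "sig" not in st:
                continue
            idx, m = fib["idx"], fib["m"]
            sig_gf = st["sig"]                                 # (k,g,f)
            add = np.einsum("egf,efs,eg->es", sig_gf, m, self.w[idx])
            sig[idx] += add / wsum[idx, None]
        p_nodes = x[self.ndof_u:]
        p_el = p_nodes[self.elems].mean(axis=1)
        return eps, sig, p_el

    def base_reaction(self, x: np.ndarray, state: dict) -> float:
        """Axial reaction summed over all fixed-z boundary nodes [N]."""
        f_ext, b_p, dt = self._last_system
        resid, _ = self._residual_full(x, state, dt, f_ext, b_p)
        fixed_z = np.zeros(self.ndof_u + self.nn, dtype=bool)
        fixed_z[1:self.ndof_u:2] = self.fixed[1:self.ndof_u:2]
        return float(resid[fixed_z].sum())

    def solve_drained(self, F: float, nodal_force: np.ndarray | None = None):
        """Static drained elastic solution (p = 0 everywhere); linear only."""
        if self._fib:
            raise NotImplementedError("drained solve is for linear materials")
        ndof = self.ndof_u + self.nn
        f_ext = np.zeros(ndof)
        if nodal_force is not None:
            f_ext[: self.ndof_u] = F * nodal_force[: self.ndof_u]
        A_full = self.K0 + sp.eye(ndof).tocsr() * 0.0
        # pin all pressures
        pr = np.arange(self.ndof_u, ndof)
        A_full = A_full.tolil()
        A_full[pr, pr] = 1.0
        A = (self.T.T @ A_full.tocsr() @ self.T).tocsc()
        b = self.T.T @ f_ext
        if self.master_red is not None:
            b[self.master_red] += -F
        return self.T @ spla.splu(A).solve(b)


def _axisym_D(C6: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate a 6x6 stiffness into the r-z plane and slice to (rr,zz,tt,rz).

    Local axes: 1 = in-plane meridian, 2 = in-plane hoop, 3 = surface
    normal.  ``phi`` is the angle of the normal from the z axis; the
    rotation is about the hoop axis.
    """
    vmap = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    C = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(vmap):
        for b, (k, l) in enumerate(vmap):
            C[i, j, k, l] = C[j, i, k, l] = C[i, j, l, k] = C[j, i, l, k] = C6[a, b]
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    out = np.zeros((len(phi), 4, 4))
    # global axes: x = r, y = t (hoop), z = z
    for n, ph in enumerate(phi):
        t = np.array([np.cos(ph), 0.0, -np.sin(ph)])   # meridian tangent
        h = np.array([0.0, 1.0, 0.0])                  # hoop
        nrm = np.array([np.sin(ph), 0.0, np.cos(ph)])  # surface normal
        R = np.column_stack([t, h, nrm])               # local->global
        Cg = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, C)
        pairs = [(0, 0), (2, 2), (1, 1), (0, 2)]       # rr, zz, tt, rz
        for a, (i, j) in enumerate(pairs):
            for b, (k, l) in enumerate(pairs):
                out[n, a, b] = Cg[i, j, k, l]
    return out


def _surface_node_areas(nodes: np.ndarray, surf: np.ndarray) -> np.ndarray:
    """Axisymmetric tributary areas 2*pi*int(r N ds) per surface node."""
    area = np.zeros(len(surf))
    xy = nodes[surf]
    for a in range(len(surf) - 1):
        p0, p1 = xy[a], xy[a + 1]
        ds = np.hypot(*(p1 - p0))
        r0, r1 = p0[0], p1[0]
        # linear shape functions on the segment
        area[a] += 2 * np.pi * ds * (r0 / 3 + r1 / 6)
        area[a + 1] += 2 * np.pi * ds * (r0 / 6 + r1 / 3)
    return area


# ---------------------------------------------------------------------------
# recording / summaries
# ---------------------------------------------------------------------------

class _Recorder:
    def __init__(self, model: BiphasicModel, times: np.ndarray):
        nt, nn, ne = len(times), model.nn, model.ne
        ns = len(model.contact["slave"]) if model.contact is not None else 0
        self.model = model
        self.h = FieldHistory(
            times=np.asarray(times, dtype=float),
            displacement=np.zeros((nt, nn, 2)),
            pore_pressure=np.zeros((nt, nn)),
            elem_stress=np.zeros((nt, ne, 4)),
            elem_strain=np.zeros((nt, ne, 4)),
            elem_pressure=np.zeros((nt, ne)),
            tensile_stress=np.zeros((nt, ne)),
            tensile_strain=np.zeros((nt, ne)),
            compressive_strain=np.zeros((nt, ne)),
            contact_pressure=np.zeros((nt, ns)),
            contact_area=np.zeros(nt),
            contact_node_r=(model.contact["r"].copy() if ns else np.zeros(0)),
            contact_node_area=(model.contact["area"].copy() if ns else np.zeros(0)),
            reaction_force=np.zeros(nt),
            master_disp=np.zeros(nt),
            elem_volumes=model.elem_volumes.copy(),
            elem_centers=model.elem_centers.copy(),
            elem_body=model.body.copy(),
            applied_force=np.zeros(nt),
        )

    def record(self, k: int, t: float, x: np.ndarray, state: dict, F: float):
        m, h = self.model, self.h
        h.displacement[k] = x[: m.ndof_u].reshape(-1, 2)
        h.pore_pressure[k] = x[m.ndof_u:]
        if t == 0.0 and not np.any(x):
            h.applied_force[k] = F
            return
        eps, sig, p_el = m.element_fields(x, state)
        h.elem_strain[k] = eps
        h.elem_stress[k] = sig
        h.elem_pressure[k] = p_el
        smax, _ = _principal_range(sig, shear_is_engineering=False)
        emax, emin = _principal_range(eps, shear_is_engineering=True)
        h.tensile_stress[k] = smax
        h.tensile_strain[k] = np.maximum(emax, 0.0)
        h.compressive_strain[k] = np.maximum(-emin, 0.0)
        if m.contact is not None:
            g = m._gaps(x)
            f = np.maximum(-g, 0.0) * m.contact["kappa"]
            active = g < 0
            h.contact_pressure[k] = np.where(active, f / m.contact["area"], 0.0)
            h.contact_area[k] = m.contact["area"][active].sum()
        h.reaction_force[k] = m.base_reaction(x, state) if hasattr(m, "_last_system") else 0.0
        if len(m.master_dofs):
            h.master_disp[k] = x[m.master_dofs[0]]
        h.applied_force[k] = F

    def finish(self) -> FieldHistory:
        return self.h


_RESPONSES = ("contact_pressure", "pore_pressure", "tensile_stress",
              "tensile_strain", "compressive_strain")


def extract_summary(fh: FieldHistory, window: tuple[float, float] | None = None):
    """Mean-over-contact-area and peak responses per time point.

    Element fields are averaged (volume-weighted) and maximised over the
    elements lying within the current contact patch (centre radius not
    exceeding the outermost active contact node); contact pressure uses
    the penalty tractions directly.  Time points without contact report
    missing values (NaN), never zero.  Returns a dict with a per-time
    table (``"per_time"``, keyed column arrays) and, when ``window`` is
    given, time-averages over that window (``"window"``).
    """
    import pandas as pd

    nt = len(fh.times)
    cols: dict[str, np.ndarray] = {"time": fh.times.copy(),
                                   "contact_area": np.full(nt, np.nan)}
    for rname in _RESPONSES:
        cols[f"{rname}_mean"] = np.full(nt, np.nan)
        cols[f"{rname}_peak"] = np.full(nt, np.nan)
    vol = fh.elem_volumes
    for k in range(nt):
        pn = fh.contact_pressure[k] if fh.contact_pressure.size else np.zeros(0)
        active = pn > 0
        if not active.any():
            continue
        r_patch = fh.contact_node_r[active].max()
        a_act = fh.contact_node_area[active]
        cols["contact_area"][k] = a_act.sum()
        cols["contact_pressure_mean"][k] = (pn[active] * a_act).sum() / a_act.sum()
        cols["contact_pressure_peak"][k] = pn[active].max()
        patch = fh.elem_centers[:, 0] <= r_patch + 1e-9
        w = vol[patch]
        for rname, arr in (("pore_pressure", fh.elem_pressure),
                           ("tensile_stress", fh.tensile_stress),
                           ("tensile_strain", fh.tensile_strain),
                           ("compressive_strain", fh.compressive_strain)):
            v = arr[k][patch]
            cols[f"{rname}_mean"][k] = float((v * w).sum() / w.sum())
            cols[f"{rname}_peak"][k] = float(v.max())
    table = pd.DataFrame(cols)
    out = {"per_time": table}
    if window is not None:
        out["window"] = window_average(table, window)
    return out


def window_average(table, window: tuple[float, float]) -> dict[str, float]:
    """Trapezoidal time-average of every summary column over a window."""
    t0, t1 = window
    t = table["time"].to_numpy()
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
        raise ValueError("window outside the simulated time span")
    mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    out = {}
    for col in table.columns:
        if col == "time":
            continue
        y = table[col].to_numpy()[mask]
        tt = t[mask]
        good = np.isfinite(y)
        if good.sum() < 1:
            out[col] = float("nan")
        elif good.sum() == 1 or tt[good][-1] == tt[good][0]:
            out[col] = float(y[good].mean())
        else:
            out[col] = float(np.trapezoid(y[good], tt[good])
                             / (tt[good][-1] - tt[good][0]))
    return out
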