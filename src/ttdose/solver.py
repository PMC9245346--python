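"""Quasi-static volume-conductor solver on the voxel lattice.

The electric potential obeys the ohmic conduction equation
``div(sigma grad phi) = 0`` with zero-flux boundaries on the head surface
except at the transducer faces.  Discretisation is a cell-centred
finite-volume 7-point stencil with harmonic-mean face conductivities, which
is conservative by construction and matches the voxel input exactly.

Electrode contract: each 20 mm disc claims the outermost scalp voxels under
its footprint; those voxels get a high 'cap' conductivity and all nine caps
of an array are tied to one ideal terminal (a Dirichlet super-node).  The
pair is solved at unit terminal voltage and the whole solution rescaled so
the net injected current equals the requested drive (0.9 A by default),
valid by linearity.

Units: conductivity S/m, lengths mm internally, potentials V, fields V/m,
currents A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .electrodes import TransducerArray
from .volume import BACKGROUND, SCALP, ConductivityVolume

DEFAULT_CURRENT_A = 0.9
DEFAULT_CAP_SIGMA_S_PER_M = 500.0
DEFAULT_RTOL = 1e-8

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class SolverError(RuntimeError):
    """Raised when assembly preconditions fail or the iterative solve stalls."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class LinearSystem:
    """Assembled SPD system for the unknown (non-terminal) voxels."""

    A: sp.csr_matrix
    b: np.ndarray
    unknown_index: np.ndarray  # 3-D int map, -1 outside the unknown set
    cond: np.ndarray  # conductive domain actually solved (bool)
    face_g: tuple[np.ndarray, np.ndarray, np.ndarray]  # face conductances (S)
    dirichlet_phi: np.ndarray  # 3-D float, 0 outside terminals
    dirichlet_mask: np.ndarray
    spacing_mm: np.ndarray

    @property
    def n_unknowns(self) -> int:
        return self.A.shape[0]


@dataclass
class FieldSolution:
    """Potential, field vectors and field intensity on the lattice."""

    phi: np.ndarray  # V
    E: np.ndarray  # (nx, ny, nz, 3) V/m
    norm_E: np.ndarray  # V/m, the dose metric
    affine: np.ndarray
    domain: np.ndarray  # conductive mask
    I_injected_A: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phi.shape


def _face_conductance(sigma: np.ndarray, spacing: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean face conductance (S) between voxels adjacent along axis."""
    sl_l = [slice(None)] * 3
    sl_r = [slice(None)] * 3
    sl_l[axis] = slice(None, -1)
    sl_r[axis] = slice(1, None)
    a = sigma[tuple(sl_l)]
    b = sigma[tuple(sl_r)]
    s = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        harm = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
    d = spacing[axis]
    area = spacing[(axis + 1) % 3] * spacing[(axis + 2) % 3]
    # sigma [S/m] * area [mm^2] / d [mm] -> S after the 1e-3 mm->m factor
    return harm * (area / d) * 1e-3


def _adjacent(axis: int) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    sl_l = [slice(None)] * 3
    sl_r = [slice(None)] * 3
    sl_l[axis] = slice(None, -1)
    sl_r[axis] = slice(1, None)
    return tuple(sl_l), tuple(sl_r)


def assemble_system(
    sigma: np.ndarray,
    spacing_mm: np.ndarray,
    terminals: list[tuple[np.ndarray, float]],
) -> LinearSystem:
    """Assemble the finite-volume system with Dirichlet terminal voxels.

    ``terminals`` is a list of (mask, potential) pairs.  The conductive
    domain is restricted to the connected component containing the
    terminals; terminals in different components are rejected (no current
    path).  The returned matrix is symmetric positive definite with zero row
    sums on interior rows (discrete charge conservation).
    """
    sigma = np.asarray(sigma, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    cond = sigma > 0
    if not terminals:
        raise SolverError("at least one terminal is required")

    comp, _ = ndimage.label(cond, structure=_FACE_STRUCTURE)
    term_comps: set[int] = set()
    for mask, _phi in terminals:
        if not np.any(mask):
            raise SolverError("a terminal has no voxels")
        if not np.all(cond[mask]):
            raise SolverError("terminal voxels must be conductive")
        term_comps.update(np.unique(comp[mask]).tolist())
    if len(term_comps) > 1:
        raise SolverError(
            "conductive domain is disconnected: terminals lie in different components"
        )
    cond = comp == term_comps.pop()

    dmask = np.zeros_like(cond)
    dphi = np.zeros(sigma.shape, dtype=float)
    for mask, phi_val in terminals:
        if np.any(dmask & mask):
            raise SolverError("terminal masks overlap")
        dmask |= mask
        dphi[mask] = phi_val

    unknown = cond & ~dmask
    n = int(np.count_nonzero(unknown))
    if n == 0:
        raise SolverError("no unknown voxels between the terminals")
    idx = np.full(sigma.shape, -1, dtype=np.int64)
    idx[unknown] = np.arange(n)

    sigma_eff = np.where(cond, sigma, 0.0)
    face_g_list = [_face_conductance(sigma_eff, spacing, ax) for ax in range(3)]
    # Caps of different terminals must never conduct directly: transducer
    # discs are insulated, so a face between voxels of two different
    # terminals is an insulating interface, not a dead short.
    if len(terminals) > 1:
        term_id = np.zeros(sigma.shape, dtype=np.int8)
        for k, (mask, _phi) in enumerate(terminals, start=1):
            term_id[mask] = k
        for ax in range(3):
            sl_l, sl_r = _adjacent(ax)
            tL, tR = term_id[sl_l], term_id[sl_r]
            cross_term = (tL > 0) & (tR > 0) & (tL != tR)
            face_g_list[ax][cross_term] = 0.0
    face_g = tuple(face_g_list)

    diag = np.zeros(n)
    b = np.zeros(n)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for ax in range(3):
        sl_l, sl_r = _adjacent(ax)
        g = face_g[ax]
        iL, iR = idx[sl_l], idx[sl_r]
        dL, dR = dmask[sl_l], dmask[sl_r]
        act = g > 0
        uu = act & (iL >= 0) & (iR >= 0)
        rows.append(iL[uu])
        cols.append(iR[uu])
        vals.append(-g[uu])
        np.add.at(diag, iL[uu], g[uu])
        np.add.at(diag, iR[uu], g[uu])
        ud = act & (iL >= 0) & dR
        np.add.at(diag, iL[ud], g[ud])
        np.add.at(b, iL[ud], g[ud] * dphi[sl_r][ud])
        du = act & dL & (iR >= 0)
        np.add.at(diag, iR[du], g[du])
        np.add.at(b, iR[du], g[du] * dphi[sl_l][du])

    r = np.concatenate(rows + cols + [np.arange(n)])
    c = np.concatenate(cols + rows + [np.arange(n)])
    v = np.concatenate(vals + vals + [diag])
    A = sp.coo_matrix((v, (r, c)), shape=(n, n)).tocsr()
    return LinearSystem(A, b, idx, cond, face_g, dphi, dmask, spacing)


def _make_preconditioner(A: sp.csr_matrix, kind: str):
    if kind == "jacobi":
        inv_d = 1.0 / A.diagonal()
        return spla.LinearOperator(A.shape, matvec=lambda x: inv_d * x)
    if kind == "ilu":
        ilu = spla.spilu(A.tocsc(), drop_tol=1e-4, fill_factor=10.0)
        return spla.LinearOperator(A.shape, matvec=ilu.solve)
    if kind == "none":
        return None
    raise ValueError(f"unknown preconditioner {kind!r}")


def solve_system(
    system: LinearSystem,
    rtol: float = DEFAULT_RTOL,
    maxiter: int | None = None,
    x0: np.ndarray | None = None,
    preconditioner: str | spla.LinearOperator = "jacobi",
) -> tuple[np.ndarray, dict]:
    """Conjugate-gradient solve to the requested relative residual."""
    A, b = system.A, system.b
    M = (
        preconditioner
        if isinstance(preconditioner, spla.LinearOperator)
        else _make_preconditioner(A, preconditioner)
    )
    if maxiter is None:
        maxiter = 20000
    it = 0

    def cb(_xk):
        nonlocal it
        it += 1

    x, info = spla.cg(A, b, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
    res = float(np.linalg.norm(b - A @ x) / np.linalg.norm(b))
    diag = {"iterations": it, "relative_residual": res, "n_unknowns": A.shape[0]}
    if info != 0:
        raise SolverError(f"CG did not converge (info={info})", diag)
    return x, diag


def _gradient(phi: np.ndarray, cond: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """-grad(phi) in V/m: central differences inside the domain, one-sided at
    boundaries, zero outside."""
    E = np.zeros(phi.shape + (3,))
    for ax in range(3):
        h = spacing[ax]
        has_prev = np.zeros_like(cond)
        has_next = np.zeros_like(cond)
        sl_l, sl_r = _adjacent(ax)
        has_prev[sl_r] = cond[sl_l]
        has_next[sl_l] = cond[sl_r]
        phi_prev = np.zeros_like(phi)
        phi_next = np.zeros_like(phi)
        phi_prev[sl_r] = phi[sl_l]
        phi_next[sl_l] = phi[sl_r]
        d = np.zeros_like(phi)
        both = cond & has_prev & has_next
        fwd = cond & ~has_prev & has_next
        bwd = cond & has_prev & ~has_next
        d[both] = (phi_next[both] - phi_prev[both]) / (2.0 * h)
        d[fwd] = (phi_next[fwd] - phi[fwd]) / h
        d[bwd] = (phi[bwd] - phi_prev[bwd]) / h
        E[..., ax] = -d * 1000.0  # V/mm -> V/m
    E[~cond] = 0.0
    return E


def _terminal_current(phi: np.ndarray, system: LinearSystem, term_mask: np.ndarray) -> float:
    """Net current (A) flowing out of a terminal through its boundary faces."""
    I = 0.0
    for ax in range(3):
        sl_l, sl_r = _adjacent(ax)
        g = system.face_g[ax]
        tL, tR = term_mask[sl_l], term_mask[sl_r]
        out_l = tL & ~tR & (g > 0)
        out_r = tR & ~tL & (g > 0)
        I += float(np.sum(g[out_l] * (phi[sl_l][out_l] - phi[sl_r][out_l])))
        I += float(np.sum(g[out_r] * (phi[sl_r][out_r] - phi[sl_l][out_r])))
    return I


def electrode_voxel_masks(
    cv: ConductivityVolume, pair: tuple[TransducerArray, TransducerArray]
) -> tuple[np.ndarray, np.ndarray]:
    """Outermost scalp voxels under each disc footprint, per terminal.

    A voxel belongs to a disc when it is a surface scalp voxel (scalp with a
    background face-neighbour) whose centre lies within the disc radius of
    the disc axis and within two voxels of the disc plane.  A disc with no
    scalp contact is rejected by name.
    """
    if cv.source is None:
        raise SolverError("electrode placement requires the source LabelVolume")
    labels = cv.source.labels
    scalp = labels == SCALP
    bg = labels == BACKGROUND
    surface_scalp = scalp & ndimage.binary_dilation(bg, structure=_FACE_STRUCTURE)
    xs, ys, zs = cv.source.voxel_centers_world()
    h = float(np.max(cv.voxel_size_mm))
    masks = []
    for arr in pair:
        m = np.zeros(labels.shape, dtype=bool)
        r = arr.disc_diameter_mm / 2.0
        for k in range(9):
            p = arr.disc_centers[k]
            n = arr.disc_normals[k]
            dx = (xs - p[0])[:, None, None]
            dy = (ys - p[1])[None, :, None]
            dz = (zs - p[2])[None, None, :]
            s = dx * n[0] + dy * n[1] + dz * n[2]
            perp2 = (dx - s * n[0]) ** 2 + (dy - s * n[1]) ** 2 + (dz - s * n[2]) ** 2
            disc = surface_scalp & (perp2 <= r * r) & (s >= -2.0 * h) & (s <= h)
            if not np.any(disc):
                raise SolverError(
                    f"disc {k} of the {arr.polarity} array has zero scalp contact"
                )
            m |= disc
        masks.append(m)
    if np.any(masks[0] & masks[1]):
        raise SolverError("source and sink arrays overlap on the scalp")
    return masks[0], masks[1]


def assemble_pair_system(
    cv: ConductivityVolume,
    pair: tuple[TransducerArray, TransducerArray],
    cap_sigma_S_per_m: float = DEFAULT_CAP_SIGMA_S_PER_M,
) -> tuple[LinearSystem, np.ndarray, np.ndarray]:
    """Electrode caps + Dirichlet terminals for a transducer-array pair."""
    src, snk = pair
    pols = sorted((src.polarity, snk.polarity))
    if pols != ["sink", "source"]:
        raise SolverError("a pair needs exactly one source and one sink array")
    if src.polarity == "sink":
        src, snk = snk, src
    m_src, m_snk = electrode_voxel_masks(cv, (src, snk))
    sigma = cv.sigma.copy()
    sigma[m_src | m_snk] = cap_sigma_S_per_m
    system = assemble_system(
        sigma, cv.voxel_size_mm, [(m_src, 0.5), (m_snk, -0.5)]
    )
    return system, m_src, m_snk


def solve_masked(
    cv: ConductivityVolume,
    source_mask: np.ndarray,
    sink_mask: np.ndarray,
    current_A: float = DEFAULT_CURRENT_A,
    rtol: float = DEFAULT_RTOL,
    x0: np.ndarray | None = None,
    preconditioner: str | spla.LinearOperator = "jacobi",
) -> FieldSolution:
    """Solve with explicit terminal voxel masks (plates, caps, tests)."""
    if current_A <= 0:
        raise ValueError("drive current must be positive")
    system = assemble_system(cv.sigma, cv.voxel_size_mm, [(source_mask, 0.5), (sink_mask, -0.5)])
    return solve_assembled(system, source_mask, sink_mask, current_A, rtol, x0, preconditioner)


def solve_assembled(
    system: LinearSystem,
    m_src: np.ndarray,
    m_snk: np.ndarray,
    current_A: float = DEFAULT_CURRENT_A,
    rtol: float = DEFAULT_RTOL,
    x0: np.ndarray | None = None,
    preconditioner: str | spla.LinearOperator = "jacobi",
) -> FieldSolution:
    """Solve an already-assembled terminal system and post-process fields."""
    x, diag = solve_system(system, rtol=rtol, x0=x0, preconditioner=preconditioner)
    diag["unknown_vector"] = x
    phi = np.zeros(system.cond.shape)
    phi[system.unknown_index >= 0] = x[system.unknown_index[system.unknown_index >= 0]]
    phi[system.dirichlet_mask] = system.dirichlet_phi[system.dirichlet_mask]

    I_src = _terminal_current(phi, system, m_src)
    I_snk = _terminal_current(phi, system, m_snk)
    if I_src <= 0:
        raise SolverError("no net current leaves the source terminal", diag)
    balance = abs(I_src + I_snk) / abs(I_src)
    scale = current_A / I_src
    phi *= scale

    spacing = system.spacing_mm
    E = _gradient(phi, system.cond, spacing)
    norm_E = np.linalg.norm(E, axis=-1)
    diag.update(
        {
            "raw_terminal_current_A": I_src,
            "current_balance_rel": balance,
            "voltage_scale": scale,
        }
    )
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    return FieldSolution(
        phi=phi,
        E=E,
        norm_E=norm_E,
        affine=affine,
        domain=system.cond,
        I_injected_A=current_A,
        diagnostics=diag,
    )


def solve_fields(
    cv: ConductivityVolume,
    pair: tuple[TransducerArray, TransducerArray],
    current_A: float = DEFAULT_CURRENT_A,
    rtol: float = DEFAULT_RTOL,
    cap_sigma_S_per_m: float = DEFAULT_CAP_SIGMA_S_PER_M,
    x0: np.ndarray | None = None,
    preconditioner: str | spla.LinearOperator = "jacobi",
) -> FieldSolution:
    """Solve the conduction problem for an array pair at the given drive.

    The solution is scaled post-solve so the net terminal current equals
    ``current_A`` (0.9 A by default); the realized current is stored on the
    returned FieldSolution together with solver diagnostics.
    """
    if current_A <= 0:
        raise ValueError("drive current must be positive")
    system, m_src, m_snk = assemble_pair_system(cv, pair, cap_sigma_S_per_m)
    sol = solve_assembled(system, m_src, m_snk, current_A, rtol, x0, preconditioner)
    sol.affine = cv.affine.copy()
    return sol


def field_intensity(sol: FieldSolution, mask: np.ndarray) -> np.ndarray:
    """Field intensity |E| (V/m) at the masked voxels, no interpolation."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != sol.norm_E.shape:
        raise ValueError(
            f"mask lattice {mask.shape} does not match the solution lattice {sol.norm_E.shape}"
        )
    return sol.norm_E[mask]
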