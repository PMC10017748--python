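"""Cytokine reaction-diffusion-decay and receptor-ligand kinetics.

Four signaling species are tracked on the voxel lattice: OPG, RANKL and
sclerostin (Scl) diffuse and decay in the trabecular marrow and are produced
by cells; TGF-beta1 is stored in the bone matrix and released into the free
(diffusing) field when matrix is resorbed.  A fifth field carries the
solution-phase RANKL-OPG complex.  Concentrations are expressed as amount
per voxel (arbitrary concentration units fixed by the production-rate
scale).

Time stepping uses Strang operator splitting over the 40-min cell step,
subdivided into 10 substeps of 4 min: within each substep a reaction
half-step (production, binding, decay), a full diffusion step, and a second
reaction half-step.  Diffusion is an implicit theta-scheme on the 7-point
stencil restricted to the marrow domain with no-flux boundaries
(Crank-Nicolson by default, so the split scheme retains second-order
accuracy in the substep size); decay of free ligand is applied exactly as
``exp(-k dt)``; binding ODEs are integrated with sub-stepped RK4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

SPECIES = ("OPG", "RANKL", "Scl", "TGFb1", "RANKL_OPG")


@dataclass
class SpeciesParams:
    """Transport parameters of one diffusing species."""

    D: float  # diffusion coefficient, um^2/min
    k_decay: float  # first-order decay of the free ligand, 1/min


@dataclass
class ReceptorPool:
    """Binding sites of one receptor type on one cell.

    Occupancy obeys  d(bound)/dt = k_f (total - bound) L - k_r bound  with L
    the free-ligand amount in the cell's voxel; bound stays in
    [0, total_sites] for any step size under the sub-stepped integrator.
    """

    receptor: str  # "RANK", "LRP56" or "TGFBR"
    total_sites: float
    bound: float = 0.0
    k_f: float = 1e-3  # per concentration per min
    k_r: float = 1e-2  # 1/min

    @property
    def occupancy(self) -> float:
        return self.bound / self.total_sites if self.total_sites > 0 else 0.0


@dataclass
class CytokineState:
    """All signaling fields on one lattice."""

    conc: dict  # species -> (nz, ny, nx) float array
    params: dict  # species -> SpeciesParams
    bone_bound_store: np.ndarray = None  # stored TGF-beta1, bone voxels

    def __post_init__(self):
        shape = next(iter(self.conc.values())).shape
        if self.bone_bound_store is None:
            self.bone_bound_store = np.zeros(shape)

    @property
    def shape(self):
        return next(iter(self.conc.values())).shape

    def total(self, species: str) -> float:
        return float(self.conc[species].sum())

    def copy(self) -> "CytokineState":
        return CytokineState(
            conc={k: v.copy() for k, v in self.conc.items()},
            params=dict(self.params),
            bone_bound_store=self.bone_bound_store.copy(),
        )


def make_cytokine_state(shape, params: dict = None) -> CytokineState:
    if params is None:
        params = {s: SpeciesParams(D=60.0, k_decay=2e-3) for s in SPECIES}
        params["RANKL_OPG"] = SpeciesParams(D=60.0, k_decay=0.0)
    conc = {s: np.zeros(shape) for s in params}
    return CytokineState(conc=conc, params=params)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

class DiffusionOperator:
    """Implicit theta-scheme diffusion on a masked voxel domain.

    Solves ``(I - theta a L) c1 = (I + (1-theta) a L) c0`` with
    ``a = D dt / h^2`` and ``L`` the 7-point graph Laplacian of the domain
    (no-flux at every domain boundary, including the bone interface).  The
    operator conserves total mass to factorization accuracy and is
    unconditionally stable for theta >= 0.5.
    """

    def __init__(self, mask: np.ndarray, D: float, dt: float, h: float,
                 theta: float = 0.5):
        self.mask = np.asarray(mask, dtype=bool)
        self.theta = theta
        n = int(self.mask.sum())
        idx = -np.ones(self.mask.shape, dtype=np.int64)
        idx[self.mask] = np.arange(n)
        rows, cols = [], []
        for axis in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(None, -1)
            sl_b[axis] = slice(1, None)
            pair = self.mask[tuple(sl_a)] & self.mask[tuple(sl_b)]
            a = idx[tuple(sl_a)][pair]
            b = idx[tuple(sl_b)][pair]
            rows.extend([a, b])
            cols.extend([b, a])
        rows = np.concatenate(rows) if rows else np.zeros(0, dtype=np.int64)
        cols = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
        data = np.ones(len(rows))
        A = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        L = A - sparse.diags(deg)
        alpha = D * dt / h**2
        I = sparse.identity(n, format="csr")
        self._lhs = splu((I - theta * alpha * L).tocsc())
        self._rhs = I + (1 - theta) * alpha * L
        self._n = n

    def step(self, conc: np.ndarray) -> np.ndarray:
        """One diffusion step; values outside the domain are untouched."""
        out = conc.copy()
        c = conc[self.mask]
        out[self.mask] = self._lhs.solve(self._rhs @ c)
        return out


def diffuse(conc: np.ndarray, op: DiffusionOperator) -> np.ndarray:
    """Apply one implicit diffusion step with a prebuilt operator."""
    return op.step(conc)


# ---------------------------------------------------------------------------
# receptor-ligand kinetics
# ---------------------------------------------------------------------------

def _rk4(f, y, dt, nsub):
    hdt = dt / nsub
    for _ in range(nsub):
        k1 = f(y)
        k2 = f(y + 0.5 * hdt * k1)
        k3 = f(y + 0.5 * hdt * k2)
        k4 = f(y + hdt * k3)
        y = y + (hdt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def _n_substeps(dt, *rates):
    """Choose RK4 substeps so the fastest rate satisfies rate*h < 0.25."""
    fastest = max([1e-12, *[abs(float(np.max(r)) if np.ndim(r) else r) for r in rates]])
    return max(1, int(np.ceil(fastest * dt / 0.25)))


def bind_simple(pool: ReceptorPool, local_conc: float, dt: float):
    """Integrate simple receptor-ligand binding over ``dt`` minutes.

    Returns ``(new_bound, new_conc)``.  Ligand is consumed/released
    stoichiometrically, so ``bound + conc`` is conserved.
    """
    if local_conc < 0:
        raise ValueError("ligand concentration must be >= 0")
    total = pool.bound + local_conc

    def f(y):
        b, L = y
        r = pool.k_f * (pool.total_sites - b) * L - pool.k_r * b
        return np.array([r, -r])

    nsub = _n_substeps(dt, pool.k_f * max(total, pool.total_sites), pool.k_r)
    b, L = _rk4(f, np.array([pool.bound, local_conc], dtype=float), dt, nsub)
    b = float(np.clip(b, 0.0, pool.total_sites))
    L = float(max(total - b, 0.0))
    return b, L


def bind_simple_field(total_sites, bound, conc, k_f, k_r, dt):
    """Vectorized simple binding: arrays broadcast elementwise.

    Returns ``(bound, conc)`` with the sum conserved per element.
    """
    total = bound + conc

    def f(y):
        b, L = y
        r = k_f * (total_sites - b) * L - k_r * b
        return np.stack([r, -r])

    rate_scale = float(np.max(k_f * np.maximum(total, total_sites), initial=0.0))
    nsub = _n_substeps(dt, rate_scale, np.max(k_r) if np.ndim(k_r) else k_r)
    y = _rk4(f, np.stack([bound, conc]).astype(float), dt, nsub)
    b = np.clip(y[0], 0.0, total_sites)
    return b, np.maximum(total - b, 0.0)


def bind_competitive_rankl(
    rank_total: np.ndarray,
    rank_bound: np.ndarray,
    rankl: np.ndarray,
    opg: np.ndarray,
    complex_ro: np.ndarray,
    kf_rank: float,
    kr_rank: float,
    kf_opg: float,
    kr_opg: float,
    dt: float,
):
    """Competitive RANKL-RANK-OPG binding, elementwise over the lattice.

    Two coupled reversible reactions share the free RANKL pool:
    cell-surface ``RANKL + RANK <-> C1`` (``rank_bound``) and solution-phase
    ``RANKL + OPG <-> C2`` (``complex_ro``).  Total RANKL
    (free + C1 + C2) is conserved over the step.  Voxels without RANK sites
    simply run the solution reaction.

    Returns ``(rank_bound, rankl, opg, complex_ro)``.
    """

    def f(y):
        c1, R, O, c2 = y
        r1 = kf_rank * (rank_total - c1) * R - kr_rank * c1
        r2 = kf_opg * O * R - kr_opg * c2
        return np.stack([r1, -r1 - r2, -r2, r2])

    scale = float(
        max(
            kf_rank * np.max(rank_total, initial=0.0),
            kf_rank * np.max(rankl, initial=0.0),
            kf_opg * np.max(opg, initial=0.0),
            kf_opg * np.max(rankl, initial=0.0),
            kr_rank,
            kr_opg,
        )
    )
    nsub = _n_substeps(dt, scale)
    y0 = np.stack([rank_bound, rankl, opg, complex_ro]).astype(float)
    y = _rk4(f, y0, dt, nsub)
    c1 = np.clip(y[0], 0.0, rank_total)
    c2 = np.maximum(y[3], 0.0)
    O = np.maximum(y[2], 0.0)
    # enforce RANKL conservation exactly after clipping
    R = np.maximum((rank_bound + rankl + complex_ro) - c1 - c2, 0.0)
    return c1, R, O, c2


def tgfb_release(
    state: CytokineState,
    voxel,
    removed_matrix: float,
    matrix_before: float,
):
    """Release stored TGF-beta1 at a resorption site.

    The released amount is proportional to the resorbed matrix fraction:
    ``store * removed / matrix_before``, moved from the bone-bound store to
    the free field at ``voxel``.  Resorbing a voxel completely therefore
    releases exactly its whole store (the proportional releases telescope).
    """
    if removed_matrix <= 0 or matrix_before <= 0:
        return 0.0
    frac = min(removed_matrix / matrix_before, 1.0)
    released = float(state.bone_bound_store[voxel]) * frac
    state.bone_bound_store[voxel] -= released
    state.conc["TGFb1"][voxel] += released
    return released


# ---------------------------------------------------------------------------
# Strang splitting
# ---------------------------------------------------------------------------

def decay_step(state: CytokineState, dt: float):
    """Exact first-order decay of every free species over ``dt`` minutes."""
    for s, p in state.params.items():
        if p.k_decay > 0:
            state.conc[s] *= np.exp(-p.k_decay * dt)


def strang_step(
    state: CytokineState,
    diffusion_ops: dict,
    dt: float = 40.0,
    substeps: int = 10,
    reaction=None,
    strict: bool = False,
):
    """Advance the cytokine fields by one cell timestep (default 40 min).

    The step is subdivided into ``substeps`` equal substeps (default 10 of
    4 min); each substep applies reaction for dt/2, diffusion for dt, then
    reaction for dt/2 (Strang splitting).

    Parameters
    ----------
    diffusion_ops : species -> :class:`DiffusionOperator` built for the
        substep duration ``dt / substeps``.
    reaction : optional callable ``reaction(state, dt_half)`` applying
        production and binding over a half substep.  Decay of free ligand is
        always applied (exactly) as part of the reaction half-step.
    strict : if True, any negative concentration raises instead of being
        clamped to zero.
    """
    dt_sub = dt / substeps
    for _ in range(substeps):
        _reaction_half(state, reaction, dt_sub / 2.0, strict)
        for s, op in diffusion_ops.items():
            state.conc[s] = op.step(state.conc[s])
        _reaction_half(state, reaction, dt_sub / 2.0, strict)
    return state


def _reaction_half(state, reaction, dt_half, strict):
    if reaction is not None:
        reaction(state, dt_half)
    decay_step(state, dt_half)
    for s, c in state.conc.items():
        neg = c < 0
        if neg.any():
            if strict:
                raise ValueError(f"negative concentration in species {s}")
            c[neg] = 0.0
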