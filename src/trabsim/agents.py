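"""Single-cell agents: movement, proliferation, differentiation, remodeling.

Eight cell kinds are modeled.  Osteocytes (Ot) and preosteocytes (preOt)
are embedded in the bone phase and immobile; mesenchymal and hematopoietic
stem cells (MSC, HSC) and preosteoclasts (preOc) live in the marrow;
osteoblasts (Ob), lining cells and osteoclasts (Oc) occupy the bone surface
(bone voxels 6-adjacent to marrow).  At most one cell of the mobile kinds
occupies a voxel at a time.

The remodeling actions follow the mechanostat logic: osteoblasts deposit
osteoid at a rate given by an increasing Hill curve of the local dilated
effective strain; osteoclast clusters (>= 3 osteoclastic cells in the
26-neighborhood, RANK highly bound) resorb equal amounts of mineral and
osteoid at a rate given by a decreasing Hill curve.  Voxel mineralization
moves the mineral concentration toward the osteoid concentration with a
hyperbolic-sine law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Region, TissueGrid
from .signaling import ReceptorPool

CELL_KINDS = ("Ot", "preOt", "Ob", "lining", "MSC", "HSC", "preOc", "Oc")
MARROW_KINDS = frozenset({"MSC", "HSC", "preOc"})
SURFACE_KINDS = frozenset({"Ob", "lining", "Oc"})
BONE_KINDS = frozenset({"Ot", "preOt"})
OSTEOCLASTIC = frozenset({"preOc", "Oc"})

_NEIGH26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


@dataclass
class Cell:
    """One agent on the lattice."""

    id: int
    kind: str
    position: tuple  # (z, y, x)
    receptors: dict = field(default_factory=dict)  # receptor name -> ReceptorPool
    age: float = 0.0  # minutes

    def occupancy(self, receptor: str) -> float:
        pool = self.receptors.get(receptor)
        return pool.occupancy if pool is not None else 0.0


@dataclass
class RuleParams:
    """Behavioral parameters of the cell rules (per 40-min cell step unless
    stated otherwise)."""

    move_prob: dict = field(
        default_factory=lambda: {
            "MSC": 0.5, "HSC": 0.5, "preOc": 0.5, "Ob": 0.3, "Oc": 0.3,
            "lining": 0.0, "Ot": 0.0, "preOt": 0.0,
        }
    )
    prolif_rate: dict = field(
        default_factory=lambda: {"MSC": 2e-5, "HSC": 2e-5, "Ob": 1e-5}
    )  # 1/min
    apoptosis_rate: dict = field(
        default_factory=lambda: {
            "MSC": 2e-5, "HSC": 2e-5, "Ob": 1e-5, "Oc": 2e-5, "preOc": 1e-5,
        }
    )  # 1/min
    lrp_bound_threshold: float = 0.7
    rank_bound_threshold: float = 0.6
    tgfbr_bound_threshold: float = 0.5
    tgfb_prolif_factor: float = 2.0
    oc_cluster_min: int = 3
    ob_polarization: float = 1.0
    oc_polarization: float = 1.0
    r_mineral: float = 0.01  # 1/step scale of the mineralization law
    osteoid_voxel_threshold: float = 0.5
    mineral_voxel_threshold: float = 0.5
    msc_surface_distance: float = 1.0  # voxels
    msc_oc_radius: float = 2.0  # voxels
    sinh_form: str = "abs_half"  # or "squared"


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def _valid_targets(kind, pos, grid, bone, surface, occupied):
    """Neighbor voxels this cell kind may step into."""
    z, y, x = pos
    shape = grid.shape
    out = []
    for dz, dy, dx in _NEIGH26:
        q = (z + dz, y + dy, x + dx)
        if not (0 <= q[0] < shape[0] and 0 <= q[1] < shape[1] and 0 <= q[2] < shape[2]):
            continue
        if q in occupied:
            continue
        if kind in MARROW_KINDS:
            ok = grid.region[q] == Region.TRAB_MARROW
        elif kind in SURFACE_KINDS:
            ok = surface[q]
        else:
            ok = False
        if ok:
            out.append(q)
    return out


def move(cell: Cell, eps: np.ndarray, grid: TissueGrid, bone: np.ndarray,
         surface: np.ndarray, occupied: set, params: RuleParams,
         rng: np.random.Generator):
    """One movement attempt; returns the (possibly unchanged) position.

    With probability ``move_prob[kind]`` the cell steps to one of the valid
    26-neighbors.  Osteoblasts are biased toward higher and osteoclasts
    toward lower dilated strain via a softmax over standardized neighbor
    signals weighted by the polarization coefficient; all other kinds step
    uniformly.
    """
    p = params.move_prob.get(cell.kind, 0.0)
    if p <= 0.0 or rng.random() >= p:
        return cell.position
    targets = _valid_targets(cell.kind, cell.position, grid, bone, surface, occupied)
    if not targets:
        return cell.position
    if cell.kind == "Ob":
        pol = params.ob_polarization
    elif cell.kind == "Oc":
        pol = -params.oc_polarization
    else:
        pol = 0.0
    if pol == 0.0 or len(targets) == 1:
        return targets[rng.integers(len(targets))]
    vals = np.array([eps[q] for q in targets])
    sd = vals.std()
    if sd == 0.0:
        return targets[rng.integers(len(targets))]
    w = np.exp(pol * (vals - vals.mean()) / sd)
    w /= w.sum()
    return targets[rng.choice(len(targets), p=w)]


# ---------------------------------------------------------------------------
# proliferation / apoptosis
# ---------------------------------------------------------------------------

def proliferate_apoptose(cells, grid: TissueGrid, bone, surface,
                         occupied: set, params: RuleParams, dt: float,
                         rng: np.random.Generator, next_id: int):
    """Bernoulli birth/death events over one step of ``dt`` minutes.

    TGF-beta receptor occupancy above the threshold multiplies the
    proliferation rate by ``tgfb_prolif_factor``.  Daughters are placed in a
    free neighbor voxel valid for the kind; with no free target the division
    is skipped.  Returns ``(cells, next_id, n_births, n_deaths)``.
    """
    survivors, births = [], []
    n_deaths = 0
    for cell in cells:
        k_apo = params.apoptosis_rate.get(cell.kind, 0.0)
        if k_apo > 0 and rng.random() < -np.expm1(-k_apo * dt):
            occupied.discard(cell.position)
            n_deaths += 1
            continue
        survivors.append(cell)
        k_pro = params.prolif_rate.get(cell.kind, 0.0)
        if k_pro > 0:
            if cell.occupancy("TGFBR") >= params.tgfbr_bound_threshold:
                k_pro *= params.tgfb_prolif_factor
            if rng.random() < -np.expm1(-k_pro * dt):
                targets = _valid_targets(
                    cell.kind, cell.position, grid, bone, surface, occupied
                )
                if targets:
                    pos = targets[rng.integers(len(targets))]
                    daughter = Cell(
                        id=next_id,
                        kind=cell.kind,
                        position=pos,
                        receptors={
                            name: ReceptorPool(
                                receptor=p.receptor,
                                total_sites=p.total_sites,
                                bound=0.0,
                                k_f=p.k_f,
                                k_r=p.k_r,
                            )
                            for name, p in cell.receptors.items()
                        },
                    )
                    next_id += 1
                    occupied.add(pos)
                    births.append(daughter)
    return survivors + births, next_id, len(births), n_deaths


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _receptors_for(kind, defaults) -> dict:
    wanted = {
        "MSC": ("LRP56", "TGFBR"),
        "Ob": ("LRP56", "TGFBR"),
        "lining": ("LRP56",),
        "HSC": ("RANK",),
        "preOc": ("RANK",),
        "Oc": ("RANK",),
        "Ot": (),
        "preOt": (),
    }[kind]
    return {name: defaults[name]() for name in wanted}


def differentiate(cells, grid: TissueGrid, bone, surface, dist_to_bone,
                  params: RuleParams, receptor_factory, log=None):
    """Apply all cell-state transitions once, in a fixed order.

    Order: preOt->Ot; Ob->preOt; Ob->lining; HSC->preOc; preOc->HSC;
    preOc->Oc; MSC->(Ob | lining).  When a cell changes kind its receptor
    set is rebuilt for the new kind (existing pools of shared receptors are
    kept).  ``receptor_factory`` maps receptor name -> zero-bound
    :class:`ReceptorPool` factory.  ``log`` (optional list) records
    ``(cell id, old kind, new kind)`` tuples.
    """
    positions = {}
    for c in cells:
        positions.setdefault(c.position, []).append(c)

    def retype(cell, new_kind):
        if log is not None:
            log.append((cell.id, cell.kind, new_kind))
        old = cell.receptors
        cell.kind = new_kind
        cell.receptors = _receptors_for(new_kind, receptor_factory)
        for name in cell.receptors:
            if name in old:
                cell.receptors[name] = old[name]

    m, o = grid.mineral, grid.osteoid
    for cell in cells:
        k = cell.kind
        pos = cell.position
        if k == "preOt" and m[pos] >= params.mineral_voxel_threshold:
            retype(cell, "Ot")
        elif k == "Ob":
            if (
                o[pos] >= params.osteoid_voxel_threshold
                and _osteocyte_toward_bone(pos, dist_to_bone, bone, positions, grid.shape)
            ):
                retype(cell, "preOt")
            elif cell.occupancy("LRP56") >= params.lrp_bound_threshold:
                retype(cell, "lining")
        elif k == "HSC":
            if cell.occupancy("RANK") >= params.rank_bound_threshold:
                retype(cell, "preOc")
        elif k == "preOc":
            if cell.occupancy("RANK") < params.rank_bound_threshold:
                retype(cell, "HSC")
            elif _osteoclastic_neighbors(cell, positions) >= params.oc_cluster_min:
                retype(cell, "Oc")
        elif k == "MSC":
            if (
                dist_to_bone[pos] <= params.msc_surface_distance
                and _near_osteoclast(pos, positions, params.msc_oc_radius)
            ):
                if cell.occupancy("LRP56") >= params.lrp_bound_threshold:
                    retype(cell, "lining")
                else:
                    retype(cell, "Ob")
    return cells


def _osteoclastic_neighbors(cell, positions) -> int:
    z, y, x = cell.position
    n = 0
    for dz, dy, dx in _NEIGH26:
        for other in positions.get((z + dz, y + dy, x + dx), ()):
            if other.kind in OSTEOCLASTIC:
                n += 1
    return n


def _near_osteoclast(pos, positions, radius) -> bool:
    r = int(np.ceil(radius))
    z, y, x = pos
    r2 = radius * radius
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dz * dz + dy * dy + dx * dx > r2:
                    continue
                for other in positions.get((z + dz, y + dy, x + dx), ()):
                    if other.kind == "Oc":
                        return True
    return False


def _osteocyte_toward_bone(pos, dist_to_bone, bone, positions, shape) -> bool:
    """Is there an osteocyte in the nearest bone voxel along -grad(distance)?"""
    target = _step_toward_bone(pos, dist_to_bone, bone, shape)
    if target is None:
        return False
    return any(c.kind == "Ot" for c in positions.get(target, ()))


def _step_toward_bone(pos, dist_to_bone, bone, shape):
    """Nearest bone voxel reached by descending the distance-to-bone field."""
    cur = pos
    for _ in range(int(np.max(dist_to_bone)) + 2):
        if bone[cur]:
            return cur
        # steepest descent; ties prefer the shortest (face-adjacent) step
        best, best_key = None, (dist_to_bone[cur], 0)
        z, y, x = cur
        for dz, dy, dx in _NEIGH26:
            q = (z + dz, y + dy, x + dx)
            if 0 <= q[0] < shape[0] and 0 <= q[1] < shape[1] and 0 <= q[2] < shape[2]:
                key = (dist_to_bone[q], dz * dz + dy * dy + dx * dx)
                if key < best_key:
                    best, best_key = q, key
        if best is None:
            return None
        cur = best
    return None


# ---------------------------------------------------------------------------
# matrix remodeling
# ---------------------------------------------------------------------------

def _remodel_order(grid, candidates, partial_of):
    """Deterministic target order for deposition/resorption.

    Voxels already under remodeling (``partial_of`` value strictly between
    0 and 1) come first so a started voxel is finished before a new one is
    opened (pit digging / lamellar filling); then candidates follow the
    mineral-concentration gradient (higher mineral first), ties broken
    lexicographically.
    """
    m = grid.mineral
    return sorted(
        candidates,
        key=lambda q: (not (0.0 < partial_of[q] < 1.0), -m[q], q),
    )


def deposit_osteoid(ob: Cell, eps_local: float, grid: TissueGrid,
                    curve, params: RuleParams):
    """Deposit osteoid produced by one osteoblast over one cell step.

    The production budget is the anabolic Hill rate at the local dilated
    strain.  Deposition targets the neighbor (or own) voxel with the
    steepest mineral concentration (polarization toward the mineral
    gradient); a full voxel (o = 1) spills the overflow to the next
    candidate.  Returns the amount actually deposited.
    """
    budget = curve(eps_local)
    if budget <= 0.0:
        return 0.0
    z, y, x = ob.position
    shape = grid.shape
    cands = [ob.position] + [
        (z + dz, y + dy, x + dx)
        for dz, dy, dx in _NEIGH26
        if 0 <= z + dz < shape[0] and 0 <= y + dy < shape[1] and 0 <= x + dx < shape[2]
    ]
    cands = [q for q in cands if grid.region[q] in (Region.TRAB_BONE, Region.TRAB_MARROW)]
    deposited = 0.0
    for q in _remodel_order(grid, cands, grid.osteoid):
        room = 1.0 - grid.osteoid[q]
        if room <= 0.0:
            continue
        d = min(room, budget - deposited)
        grid.osteoid[q] += d
        deposited += d
        if deposited >= budget - 1e-15:
            break
    return deposited


def oc_in_cluster(oc: Cell, positions, params: RuleParams) -> bool:
    """Active-cluster rule: >= oc_cluster_min osteoclastic cells among the
    cell itself and its 26-neighbors."""
    return 1 + _osteoclastic_neighbors(oc, positions) >= params.oc_cluster_min


def resorb(oc: Cell, eps_local: float, grid: TissueGrid, curve,
           params: RuleParams, positions, events=None):
    """Resorb matrix by one active osteoclast over one cell step.

    Inactive osteoclasts (not in a cluster of >= ``oc_cluster_min``
    osteoclastic cells, or RANK not highly bound -- checked by the caller
    via ``oc_in_cluster`` and occupancy) resorb nothing.  The catabolic Hill
    rate at the local dilated strain is removed in equal amounts from
    mineral and osteoid of the candidate voxel with the highest mineral
    concentration (direction of the mineral gradient); leftover budget
    continues to the next candidate.  Events are appended as
    ``(voxel, removed_mineral, mineral_before)`` for TGF-beta1 release
    bookkeeping.  Returns ``(removed_mineral_total, removed_osteoid_total)``.
    """
    if not oc_in_cluster(oc, positions, params):
        return 0.0, 0.0
    if oc.occupancy("RANK") < params.rank_bound_threshold:
        return 0.0, 0.0
    budget = curve(eps_local)
    if budget <= 0.0:
        return 0.0, 0.0
    z, y, x = oc.position
    shape = grid.shape
    cands = [oc.position] + [
        (z + dz, y + dy, x + dx)
        for dz, dy, dx in _NEIGH26
        if 0 <= z + dz < shape[0] and 0 <= y + dy < shape[1] and 0 <= x + dx < shape[2]
    ]
    cands = [
        q for q in cands
        if grid.region[q] in (Region.TRAB_BONE, Region.TRAB_MARROW)
        and (grid.mineral[q] > 0 or grid.osteoid[q] > 0)
    ]
    rm_tot = ro_tot = 0.0
    for q in _remodel_order(grid, cands, grid.mineral):
        take = min(budget - rm_tot, max(grid.mineral[q], grid.osteoid[q]))
        if take <= 0.0:
            continue
        m_before = grid.mineral[q]
        rm = min(take, grid.mineral[q])
        ro = min(take, grid.osteoid[q])
        grid.mineral[q] -= rm
        grid.osteoid[q] -= ro
        rm_tot += rm
        ro_tot += ro
        if events is not None and rm > 0:
            events.append((q, rm, m_before))
        if rm_tot >= budget - 1e-15:
            break
    return rm_tot, ro_tot


def mineralize(m, o, r_mineral: float, dt_steps: float = 1.0,
               form: str = "abs_half"):
    """One mineralization update of the matrix, elementwise.

    ``m_{n+1} = m_n + r sinh(f(o - m)) sgn(o - m) dt`` with
    ``f(d) = |d| / 2`` (default) or ``f(d) = d**2`` (config alternative).
    The mineral concentration moves toward the osteoid concentration and is
    clamped so it never overshoots it; the result stays in [0, 1].
    ``dt_steps`` is the update interval in units of cell steps.
    """
    m = np.asarray(m, dtype=float)
    o = np.asarray(o, dtype=float)
    d = o - m
    if form == "abs_half":
        inner = np.abs(d) / 2.0
    elif form == "squared":
        inner = d * d
    else:
        raise ValueError(f"unknown sinh form {form!r}")
    step = r_mineral * np.sinh(inner) * np.sign(d) * dt_steps
    new = m + step
    # clamp: never cross o
    overshoot = (new - o) * (m - o) < 0
    new = np.where(overshoot, o, new)
    out = np.clip(new, 0.0, 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# cytokine production
# ---------------------------------------------------------------------------

def produce_cytokines(cells, eps: np.ndarray, role_table: dict, shape) -> dict:
    """Accumulate per-cell Hill production into voxel source fields.

    Osteocytes evaluate their curves (built on the bone mechanostat
    threshold) at the dilated strain of their bone voxel; osteoblasts and
    lining cells (marrow threshold) at their own voxel.  Returns
    ``species -> source array`` in amount per cell step.
    """
    sources = {}
    for cell in cells:
        for (kind, product), curve in role_table.items():
            if product in ("osteoid", "resorption") or kind != cell.kind:
                continue
            rate = curve(eps[cell.position])
            if rate == 0.0:
                continue
            if product not in sources:
                sources[product] = np.zeros(shape)
            sources[product][cell.position] += rate
    return sources
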