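"""Multiscale simulation loop, run phases, sensitivity harness, checkpointing.

Temporal structure: cells and cytokine reaction-diffusion-decay advance with
a 40-min step (``dt_cells_rdd``, subdivided into 10 Strang substeps of 4
min); the micro-FE mechanics and the sample-specific mechanostat thresholds
are refreshed every 8 h (``dt_micro_fe`` = 12 cell steps), emulating a
memory in the perception of the mechanical signal.  A run has three phases:

1. initialization -- 48 iterations with the bone microarchitecture frozen
   (cells and cytokines equilibrate spatially);
2. pre-remodeling -- active remodeling (default 5 days) to decouple from
   the seeding; its end state is the shared initial state;
3. experiment -- the production run (default 28 days) with snapshots.

The sensitivity harness perturbs the maximum osteocyte production of one
cytokine at a time (high = basal + delta, low = basal - delta), restarting
every arm from the same phase-2 end state with identical random streams so
arms are paired.
"""

from __future__ import annotations

import copy
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import agents, fe, mechanomics, signaling
from .grid import Region, TissueGrid, update_bone_phase
from .synthgen import SeedingSpec, bone_surface_mask, seed_all

STEPS_PER_DAY = 36  # 24 h / 40 min


@dataclass
class SimulationConfig:
    """All tunable parameters of a run (times in the units noted)."""

    # -- temporal discretization
    dt_cells_rdd: float = 40.0  # min
    rdd_substeps: int = 10  # 4-min substeps
    dt_micro_fe: float = 8.0  # h  (=> 12 cell steps per FE update)
    init_frozen_iters: int = 48
    pre_remodeling_days: float = 5.0
    experiment_days: float = 28.0
    snapshot_interval_days: float = 7.0
    rng_seed: int = 0

    # -- mechanics
    applied_axial_strain: float = 0.01
    target_force: float = 4.0  # N
    dilation_sigma: float = 2.5
    dilation_support: float = 7.5
    dilation_mode: str = "dilation"
    fe_tol: float = 1e-6
    E_bone: float = fe.E_BONE_MPA
    E_marrow: float = fe.E_MARROW_MPA
    E_ivd: float = fe.E_IVD_MPA

    # -- cytokine transport (um^2/min, 1/min)
    diffusion: dict = field(
        default_factory=lambda: {
            "OPG": 60.0, "RANKL": 60.0, "Scl": 60.0, "TGFb1": 60.0,
            "RANKL_OPG": 60.0,
        }
    )
    decay: dict = field(
        default_factory=lambda: {
            "OPG": 2e-3, "RANKL": 2e-3, "Scl": 2e-3, "TGFb1": 2e-3,
            "RANKL_OPG": 0.0,
        }
    )
    initial_conc: dict = field(
        default_factory=lambda: {"OPG": 0.004, "RANKL": 0.008, "Scl": 0.004}
    )
    diffuse_in_bone: bool = False

    # -- single-cell production: (kind, product) -> (y_max per step, Hill h)
    production: dict = field(
        default_factory=lambda: {
            ("Ot", "OPG"): (0.10, 2.0),
            ("Ot", "RANKL"): (0.10, 2.0),
            ("Ot", "Scl"): (0.10, 2.0),
            ("Ob", "OPG"): (0.03, 2.0),
            ("Ob", "RANKL"): (0.03, 2.0),
            ("lining", "OPG"): (0.03, 2.0),
            ("lining", "RANKL"): (0.03, 2.0),
            ("Ob", "osteoid"): (0.05, 2.0),
            ("Oc", "resorption"): (0.05, 2.0),
        }
    )

    # -- receptor-ligand kinetics (per concentration per min, 1/min)
    kf_rank: float = 1.0
    kr_rank: float = 0.01
    kf_opg: float = 1.0
    kr_opg: float = 0.005
    kf_lrp: float = 1.0
    kr_lrp: float = 0.01
    kf_tgfbr: float = 1.0
    kr_tgfbr: float = 0.01

    # -- matrix / TGF-beta1 store
    tgfb_store_per_voxel: float = 0.05

    # -- cell rules and seeding
    rules: agents.RuleParams = field(default_factory=agents.RuleParams)
    seeding: SeedingSpec = field(default_factory=SeedingSpec)

    @property
    def fe_interval_steps(self) -> int:
        ratio = self.dt_micro_fe * 60.0 / self.dt_cells_rdd
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt_micro_fe must be a multiple of dt_cells_rdd")
        return int(round(ratio))


@dataclass
class Snapshot:
    day: float
    bone_mask: np.ndarray
    bvtv: float
    cell_counts: dict
    cytokine_totals: dict


class Simulation:
    """One running instance of the coupled model."""

    def __init__(self, config: SimulationConfig, grid: TissueGrid, cells=None):
        self.config = config
        self.grid = grid
        self.step_count = 0
        self.transition_log = []
        self.mass_log = []
        ss = np.random.SeedSequence(config.rng_seed)
        streams = ss.spawn(4)
        self.rng_move = np.random.default_rng(streams[0])
        self.rng_prolif = np.random.default_rng(streams[1])
        self.rng_misc = np.random.default_rng(streams[2])
        if cells is None:
            seeding = replace(config.seeding, rng_seed=config.rng_seed)
            cells = seed_all(grid, seeding)
        self.cells = cells
        self.next_cell_id = 1 + max((c.id for c in cells), default=-1)
        # apply configured kinetic constants to the seeded pools
        for c in self.cells:
            for pool in c.receptors.values():
                pool.k_f, pool.k_r = self._kin(pool.receptor)
        self.cyto = self._init_cytokines()
        self.mech: fe.MechanicsField = None
        self.role_table = {}
        self._caches = {}
        self._domain_version = 0
        self._last_u = None

    # -- caches are derived state: rebuilt on demand, dropped on pickling
    def __getstate__(self):
        state = self.__dict__.copy()
        state["_caches"] = {}
        return state

    def _kin(self, receptor):
        c = self.config
        return {
            "RANK": (c.kf_rank, c.kr_rank),
            "LRP56": (c.kf_lrp, c.kr_lrp),
            "TGFBR": (c.kf_tgfbr, c.kr_tgfbr),
        }[receptor]

    def _init_cytokines(self) -> signaling.CytokineState:
        c = self.config
        params = {
            s: signaling.SpeciesParams(D=c.diffusion[s], k_decay=c.decay[s])
            for s in c.diffusion
        }
        state = signaling.CytokineState(
            conc={s: np.zeros(self.grid.shape) for s in params}, params=params
        )
        domain = self.diffusion_domain()
        for s, c0 in c.initial_conc.items():
            state.conc[s][domain] = c0
        bone = self.grid.region == Region.TRAB_BONE
        state.bone_bound_store[bone] = (
            c.tgfb_store_per_voxel * self.grid.mineral[bone]
        )
        return state

    # ------------------------------------------------------------------
    # derived geometry
    # ------------------------------------------------------------------

    def bone_mask(self) -> np.ndarray:
        return self.grid.region == Region.TRAB_BONE

    def diffusion_domain(self) -> np.ndarray:
        """Marrow plus the bone-surface interface (or all trabecular bone
        when ``diffuse_in_bone`` is set)."""
        marrow = self.grid.region == Region.TRAB_MARROW
        if self.config.diffuse_in_bone:
            return marrow | self.bone_mask()
        return marrow | bone_surface_mask(self.grid)

    def _geometry(self):
        key = ("geometry", self._domain_version)
        if key not in self._caches:
            domain = self.diffusion_domain()
            bone = self.bone_mask()
            surface = bone_surface_mask(self.grid)
            dist_to_bone = ndimage.distance_transform_edt(~bone)
            # nearest-domain-voxel map for relocating bone-interior sources
            _, inds = ndimage.distance_transform_edt(
                ~domain, return_indices=True
            )
            self._caches[key] = (domain, bone, surface, dist_to_bone, inds)
        return self._caches[key]

    def _diffusion_ops(self, domain):
        key = ("diffops", self._domain_version)
        if key not in self._caches:
            c = self.config
            dt_sub = c.dt_cells_rdd / c.rdd_substeps
            h = self.grid.resolution  # um
            ops = {
                s: signaling.DiffusionOperator(domain, p.D, dt_sub, h)
                for s, p in self.cyto.params.items()
                if p.D > 0
            }
            self._caches[key] = ops
        return self._caches[key]

    # ------------------------------------------------------------------
    # mechanics
    # ------------------------------------------------------------------

    def update_mechanics(self):
        c = self.config
        problem = fe.FEProblem(
            grid=self.grid,
            E_bone=c.E_bone,
            E_marrow=c.E_marrow,
            E_ivd=c.E_ivd,
            applied_axial_strain=c.applied_axial_strain,
            solver_tol=c.fe_tol,
            bc_mode="clamped",
        )
        # incremental stiffness update: remodeling changes few voxels
        h = self.grid.resolution * 1e-3
        E_new = problem.material_field()
        cached = self._caches.get("stiffness")
        if cached is None:
            K = fe.assemble_stiffness(E_new, problem.nu, h)
        else:
            K_old, E_old = cached
            K = fe.update_stiffness(K_old, E_old, E_new, problem.nu, h)
        self._caches["stiffness"] = (K, E_new)
        self.mech = fe.compute_mechanics(
            problem,
            target_force=c.target_force,
            sigma=c.dilation_sigma,
            support=c.dilation_support,
            dilation_mode=c.dilation_mode,
            K=K,
            x0=self._last_u,
        )
        self._last_u = self.mech.displacements
        self.role_table = mechanomics.build_role_table(
            c.production, self.mech.mechthres_bone, self.mech.mechthres_marrow
        )

    # ------------------------------------------------------------------
    # one cell step
    # ------------------------------------------------------------------

    def step(self, frozen: bool = False):
        """Advance one cell timestep (40 min).

        Update order: mechanics refresh (on its own cadence) -> cytokine
        production -> Strang-split RDD with binding -> differentiation ->
        movement -> proliferation/apoptosis -> deposition/resorption ->
        mineralization -> bone-phase update.  With ``frozen`` the
        microarchitecture-changing stages are skipped (initialization
        phase).
        """
        c = self.config
        if self.mech is None or self.step_count % c.fe_interval_steps == 0:
            self.update_mechanics()
        domain, bone, surface, dist_to_bone, nearest = self._geometry()
        eps = self.mech.eps

        # -- production sources (amount per cell step), relocated into the
        # diffusing domain for bone-embedded producers
        sources = agents.produce_cytokines(
            self.cells, eps, self.role_table, self.grid.shape
        )
        for s, src in sources.items():
            outside = (src > 0) & ~domain
            if outside.any():
                idx = np.argwhere(outside)
                tz, ty, tx = nearest[:, idx[:, 0], idx[:, 1], idx[:, 2]]
                np.add.at(src, (tz, ty, tx), src[tuple(idx.T)])
                src[tuple(idx.T)] = 0.0

        # -- Strang-split reaction-diffusion-decay with receptor binding
        self._rdd_step(sources, domain)

        # -- cell behavior
        receptor_factory = self._pool_factories()
        agents.differentiate(
            self.cells, self.grid, bone, surface, dist_to_bone,
            c.rules, receptor_factory, log=self.transition_log,
        )
        occupied = {
            cell.position for cell in self.cells if cell.kind not in agents.BONE_KINDS
        }
        for cell in self.cells:
            if cell.kind in agents.BONE_KINDS:
                continue
            occupied.discard(cell.position)
            cell.position = agents.move(
                cell, eps, self.grid, bone, surface, occupied, c.rules,
                self.rng_move,
            )
            occupied.add(cell.position)
        self.cells, self.next_cell_id, _, _ = agents.proliferate_apoptose(
            self.cells, self.grid, bone, surface, occupied, c.rules,
            c.dt_cells_rdd, self.rng_prolif, self.next_cell_id,
        )

        if not frozen:
            self._remodel(eps)
            self._mineralize_and_update()
        for cell in self.cells:
            cell.age += c.dt_cells_rdd
        counts = {}
        for cell in self.cells:
            counts[cell.kind] = counts.get(cell.kind, 0) + 1
        self.mass_log.append(
            {
                "step": self.step_count,
                "total_mineral": float(self.grid.mineral.sum()),
                "total_osteoid": float(self.grid.osteoid.sum()),
                "n_cells": len(self.cells),
                **{f"n_{k}": v for k, v in sorted(counts.items())},
                **{f"conc_{s}": self.cyto.total(s) for s in self.cyto.conc},
            }
        )
        self.step_count += 1

    def _pool_factories(self):
        s = self.config.seeding
        kin = self._kin
        return {
            name: (lambda name=name: signaling.ReceptorPool(
                name,
                {"RANK": s.rank_sites, "LRP56": s.lrp_sites,
                 "TGFBR": s.tgfbr_sites}[name],
                0.0, *kin(name),
            ))
            for name in ("RANK", "LRP56", "TGFBR")
        }

    def _rdd_step(self, sources, domain):
        c = self.config
        ops = self._diffusion_ops(domain)
        src_per_min = {
            s: src / c.dt_cells_rdd for s, src in sources.items()
        }
        shape = self.grid.shape

        rank_cells = [x for x in self.cells if "RANK" in x.receptors]
        lrp_cells = [x for x in self.cells if "LRP56" in x.receptors]
        tgf_cells = [x for x in self.cells if "TGFBR" in x.receptors]
        rank_pos = tuple(np.array([x.position for x in rank_cells]).T) if rank_cells else None
        rank_total = np.zeros(shape)
        rank_bound = np.zeros(shape)
        if rank_cells:
            rank_total[rank_pos] = [x.receptors["RANK"].total_sites for x in rank_cells]
            rank_bound[rank_pos] = [x.receptors["RANK"].bound for x in rank_cells]

        def reaction(state, dt_half):
            for s, rate in src_per_min.items():
                state.conc[s] += rate * dt_half
            # LRP5/6 <- Scl, TGFBR <- TGF-beta1: simple binding
            for cells_g, species, kf, kr, rname in (
                (lrp_cells, "Scl", c.kf_lrp, c.kr_lrp, "LRP56"),
                (tgf_cells, "TGFb1", c.kf_tgfbr, c.kr_tgfbr, "TGFBR"),
            ):
                if not cells_g:
                    continue
                pos = tuple(np.array([x.position for x in cells_g]).T)
                tot = np.array([x.receptors[rname].total_sites for x in cells_g])
                bnd = np.array([x.receptors[rname].bound for x in cells_g])
                conc = state.conc[species][pos]
                bnd, conc = signaling.bind_simple_field(tot, bnd, conc, kf, kr, dt_half)
                state.conc[species][pos] = conc
                for x, b in zip(cells_g, bnd):
                    x.receptors[rname].bound = float(b)
            # competitive RANKL-RANK-OPG
            c1, R, O, c2 = signaling.bind_competitive_rankl(
                rank_total, rank_bound, state.conc["RANKL"],
                state.conc["OPG"], state.conc["RANKL_OPG"],
                c.kf_rank, c.kr_rank, c.kf_opg, c.kr_opg, dt_half,
            )
            rank_bound[:] = c1
            state.conc["RANKL"] = R
            state.conc["OPG"] = O
            state.conc["RANKL_OPG"] = c2

        signaling.strang_step(
            self.cyto, ops, dt=c.dt_cells_rdd, substeps=c.rdd_substeps,
            reaction=reaction,
        )
        if rank_cells:
            vals = rank_bound[rank_pos]
            for x, b in zip(rank_cells, vals):
                x.receptors["RANK"].bound = float(b)

    def _remodel(self, eps):
        c = self.config
        positions = {}
        for cell in self.cells:
            positions.setdefault(cell.position, []).append(cell)
        ob_curve = self.role_table.get(("Ob", "osteoid"))
        oc_curve = self.role_table.get(("Oc", "resorption"))
        events = []
        for cell in self.cells:
            if cell.kind == "Ob" and ob_curve is not None:
                agents.deposit_osteoid(
                    cell, eps[cell.position], self.grid, ob_curve, c.rules
                )
            elif cell.kind == "Oc" and oc_curve is not None:
                agents.resorb(
                    cell, eps[cell.position], self.grid, oc_curve, c.rules,
                    positions, events,
                )
        for voxel, removed, before in events:
            signaling.tgfb_release(self.cyto, voxel, removed, before)

    def _mineralize_and_update(self):
        c = self.config
        trab = self.grid.trabecular_mask()
        m_old = self.grid.mineral.copy()
        self.grid.mineral[trab] = agents.mineralize(
            self.grid.mineral[trab], self.grid.osteoid[trab],
            c.rules.r_mineral, 1.0, form=c.rules.sinh_form,
        )
        gained = np.maximum(self.grid.mineral - m_old, 0.0)
        self.cyto.bone_bound_store += c.tgfb_store_per_voxel * gained

        old_bone = self.bone_mask()
        new_bone = update_bone_phase(self.grid)
        if not np.array_equal(old_bone, new_bone):
            self._domain_version += 1
            # geometry/diffusion caches are stale; the stiffness matrix is
            # updated incrementally from the stored material field instead
            stiff = self._caches.get("stiffness")
            self._caches = {} if stiff is None else {"stiffness": stiff}
            self._relocate_cells(new_bone)

    def _relocate_cells(self, bone):
        """Handle cells whose voxel changed phase."""
        marrow = self.grid.region == Region.TRAB_MARROW
        keep = []
        occupied = {
            c.position for c in self.cells if c.kind not in agents.BONE_KINDS
        }
        for cell in self.cells:
            pos = cell.position
            if cell.kind in agents.BONE_KINDS:
                # embedded cells die when their voxel is resorbed away
                if bone[pos]:
                    keep.append(cell)
                continue
            if cell.kind in agents.MARROW_KINDS and not marrow[pos]:
                moved = self._try_relocate(cell, marrow, occupied)
                if moved:
                    keep.append(cell)
                continue
            keep.append(cell)
        self.cells = keep

    def _try_relocate(self, cell, valid, occupied):
        z, y, x = cell.position
        shape = self.grid.shape
        for dz, dy, dx in agents._NEIGH26:
            q = (z + dz, y + dy, x + dx)
            if (
                0 <= q[0] < shape[0] and 0 <= q[1] < shape[1]
                and 0 <= q[2] < shape[2] and valid[q] and q not in occupied
            ):
                occupied.discard(cell.position)
                cell.position = q
                occupied.add(q)
                return True
        occupied.discard(cell.position)
        return False

    # ------------------------------------------------------------------
    # phases and runs
    # ------------------------------------------------------------------

    def snapshot(self) -> Snapshot:
        counts = {}
        for cell in self.cells:
            counts[cell.kind] = counts.get(cell.kind, 0) + 1
        trab = self.grid.trabecular_mask()
        bone = self.bone_mask()
        return Snapshot(
            day=self.step_count / STEPS_PER_DAY,
            bone_mask=bone.copy(),
            bvtv=float(bone.sum() / trab.sum()),
            cell_counts=counts,
            cytokine_totals={s: self.cyto.total(s) for s in self.cyto.conc},
        )

    def run_phase(self, n_steps: int, frozen: bool = False,
                  snapshot_every: int = None):
        snaps = []
        for i in range(n_steps):
            self.step(frozen=frozen)
            if snapshot_every and (i + 1) % snapshot_every == 0:
                snaps.append(self.snapshot())
        return snaps


def run(config: SimulationConfig, grid: TissueGrid, cells=None):
    """Full three-phase run.

    Returns ``(sim, snapshots)``; ``snapshots[0]`` is the initial state at
    the start of the experiment phase (after initialization and
    pre-remodeling) and subsequent entries follow the snapshot interval.
    """
    sim = Simulation(config, grid, cells)
    sim.run_phase(config.init_frozen_iters, frozen=True)
    sim.run_phase(int(round(config.pre_remodeling_days * STEPS_PER_DAY)))
    snapshots = [sim.snapshot()]
    if config.experiment_days > 0:
        every = max(1, int(round(config.snapshot_interval_days * STEPS_PER_DAY)))
        snapshots += sim.run_phase(
            int(round(config.experiment_days * STEPS_PER_DAY)),
            snapshot_every=every,
        )
        if snapshots[-1].day < sim.step_count / STEPS_PER_DAY:
            snapshots.append(sim.snapshot())
    return sim, snapshots


@dataclass
class SensitivitySpec:
    """One-variable-at-a-time perturbation of an osteocyte production rate."""

    cytokine: str  # "OPG", "RANKL" or "Scl"
    delta: float  # absolute change of beta_Ot (the curve y_max)

    def arms(self, basal: float):
        high = basal + self.delta
        low = basal - self.delta
        if low < 0:
            raise ValueError("low arm production would be negative")
        return {"high": high, "basal": basal, "low": low}


def prepare_initial_state(config: SimulationConfig, grid: TissueGrid,
                          cells=None) -> Simulation:
    """Run phases 1-2 and return the shared initial state for all arms."""
    sim = Simulation(config, grid, cells)
    sim.run_phase(config.init_frozen_iters, frozen=True)
    sim.run_phase(int(round(config.pre_remodeling_days * STEPS_PER_DAY)))
    return sim


def run_sensitivity(initial: Simulation, specs, experiment_days: float = None):
    """Run paired sensitivity arms from a shared initial state.

    ``specs`` is an iterable of :class:`SensitivitySpec`.  Returns a nested
    dict ``{cytokine: {level: final Snapshot}}`` plus the basal arm under
    key ``("basal",)``.  Every arm starts from a deep copy of ``initial``
    (identical random streams), so comparisons are paired.
    """
    cfg = initial.config
    days = experiment_days if experiment_days is not None else cfg.experiment_days
    n_steps = int(round(days * STEPS_PER_DAY))

    def run_arm(beta_overrides):
        sim = copy.deepcopy(initial)
        for (kind, product), y in beta_overrides.items():
            ymax, h = sim.config.production[(kind, product)]
            sim.config.production[(kind, product)] = (y, h)
        sim.run_phase(n_steps)
        return sim.snapshot()

    results = {("basal",): run_arm({})}
    for spec in specs:
        basal, _h = cfg.production[("Ot", spec.cytokine)]
        results[spec.cytokine] = {}
        for level, value in spec.arms(basal).items():
            if level == "basal":
                results[spec.cytokine][level] = results[("basal",)]
            else:
                results[spec.cytokine][level] = run_arm(
                    {("Ot", spec.cytokine): value}
                )
    return results


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def config_to_yaml(config: SimulationConfig, path):
    """Write the full parameter set as YAML.

    Tuple-keyed maps (the production table) are flattened to
    ``"kind/product"`` strings; nested rule and seeding blocks keep their
    field names.
    """
    import dataclasses

    import yaml

    doc = dataclasses.asdict(config)
    doc["production"] = {
        f"{kind}/{product}": list(v)
        for (kind, product), v in config.production.items()
    }
    doc["rules"] = dataclasses.asdict(config.rules)
    doc["seeding"] = dataclasses.asdict(config.seeding)
    doc["seeding"]["bound_fraction_range"] = list(
        config.seeding.bound_fraction_range
    )
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` written by :func:`config_to_yaml`.

    Missing keys keep their defaults, so partial override files work.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cfg = SimulationConfig()
    rules = doc.pop("rules", {})
    seeding = doc.pop("seeding", {})
    production = doc.pop("production", None)
    for key, value in doc.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown configuration key {key!r}")
        setattr(cfg, key, value)
    if production is not None:
        cfg.production = {
            tuple(k.split("/")): tuple(v) for k, v in production.items()
        }
    for key, value in rules.items():
        if not hasattr(cfg.rules, key):
            raise KeyError(f"unknown rule parameter {key!r}")
        setattr(cfg.rules, key, value)
    for key, value in seeding.items():
        if not hasattr(cfg.seeding, key):
            raise KeyError(f"unknown seeding parameter {key!r}")
        setattr(
            cfg.seeding, key,
            tuple(value) if key == "bound_fraction_range" else value,
        )
    return cfg


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(sim: Simulation, path):
    """Serialize the full simulation state (derived caches are dropped and
    rebuilt on resume, so a restored run continues bit-exactly)."""
    with open(path, "wb") as fh:
        pickle.dump(sim, fh)


def load_checkpoint(path) -> Simulation:
    with open(path, "rb") as fh:
        return pickle.load(fh)
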