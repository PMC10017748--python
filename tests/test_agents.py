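"""Cell rules: movement, proliferation, differentiation, remodeling,
mineralization."""

import numpy as np
import pytest

from trabsim.agents import (
    Cell,
    RuleParams,
    deposit_osteoid,
    differentiate,
    mineralize,
    move,
    oc_in_cluster,
    produce_cytokines,
    proliferate_apoptose,
    resorb,
)
from trabsim.grid import Region, TissueGrid, init_tissue_state
from trabsim.mechanomics import HillCurve
from trabsim.signaling import ReceptorPool


def _marrow_grid(shape=(7, 7, 7)):
    g = TissueGrid(grayscale=np.zeros(shape))
    return g


def _pool(name, occ, total=1.0):
    return ReceptorPool(name, total, bound=occ * total)


def _factories():
    return {
        "RANK": lambda: ReceptorPool("RANK", 1.0),
        "LRP56": lambda: ReceptorPool("LRP56", 1.0),
        "TGFBR": lambda: ReceptorPool("TGFBR", 1.0),
    }


class TestMove:
    def test_zero_probability_stays(self, rng):
        g = _marrow_grid()
        cell = Cell(0, "MSC", (3, 3, 3))
        params = RuleParams(move_prob={"MSC": 0.0})
        eps = np.zeros(g.shape)
        bone = np.zeros(g.shape, bool)
        for _ in range(50):
            assert move(cell, eps, g, bone, bone, set(), params, rng) == (3, 3, 3)

    def test_unbiased_steps_are_uniform(self, rng):
        """With zero polarization the empirical step distribution over the
        valid neighbors is uniform (chi-square at n=10^4)."""
        g = _marrow_grid()
        eps = np.linspace(0, 1, eps_size := g.shape[0] ** 3).reshape(g.shape)
        bone = np.zeros(g.shape, bool)
        params = RuleParams(move_prob={"MSC": 1.0})
        counts = {}
        for _ in range(10_000):
            cell = Cell(0, "MSC", (3, 3, 3))
            q = move(cell, eps, g, bone, bone, set(), params, rng)
            counts[q] = counts.get(q, 0) + 1
        assert len(counts) == 26
        observed = np.array(list(counts.values()))
        expected = 10_000 / 26.0
        chi2 = ((observed - expected) ** 2 / expected).sum()
        # 99.9% quantile of chi2 with 25 dof ~ 52.6
        assert chi2 < 52.6

    def test_osteoblast_drifts_up_strain_gradient(self, rng):
        g = _marrow_grid((5, 9, 5))
        surface = np.ones(g.shape, bool)
        eps = np.broadcast_to(
            np.linspace(0, 1e-2, 9)[None, :, None], g.shape
        ).copy()
        params = RuleParams(move_prob={"Ob": 1.0, "Oc": 1.0},
                            ob_polarization=8.0, oc_polarization=8.0)
        bone = np.zeros(g.shape, bool)

        def drift(kind):
            tot = 0
            for _ in range(300):
                cell = Cell(0, kind, (2, 4, 2))
                q = move(cell, eps, g, bone, surface, set(), params, rng)
                tot += q[1] - 4
            return tot

        assert drift("Ob") > 50  # toward higher strain
        assert drift("Oc") < -50  # toward lower strain

    def test_occupied_voxels_excluded(self, rng):
        g = _marrow_grid((3, 3, 3))
        params = RuleParams(move_prob={"MSC": 1.0})
        cell = Cell(0, "MSC", (1, 1, 1))
        occupied = {
            (z, y, x)
            for z in range(3) for y in range(3) for x in range(3)
            if (z, y, x) != (1, 1, 1)
        }
        eps = np.zeros(g.shape)
        bone = np.zeros(g.shape, bool)
        assert move(cell, eps, g, bone, bone, occupied, params, rng) == (1, 1, 1)


class TestProliferationApoptosis:
    def test_zero_rates_identity(self, rng):
        g = _marrow_grid()
        cells = [Cell(i, "MSC", (i % 5, 3, 3)) for i in range(5)]
        params = RuleParams(prolif_rate={}, apoptosis_rate={})
        out, _, births, deaths = proliferate_apoptose(
            cells, g, np.zeros(g.shape, bool), np.zeros(g.shape, bool),
            set(), params, 40.0, rng, 100,
        )
        assert out == cells and births == 0 and deaths == 0

    def test_apoptosis_decays_exponentially(self):
        """Survival over repeated steps tracks exp(-k t) within 3 sigma."""
        rng = np.random.default_rng(0)
        g = _marrow_grid((12, 12, 12))
        k = 5e-4  # 1/min
        params = RuleParams(prolif_rate={}, apoptosis_rate={"HSC": k})
        positions = [(z, y, x) for z in range(12) for y in range(12)
                     for x in range(12)][:1000]
        cells = [Cell(i, "HSC", p) for i, p in enumerate(positions)]
        steps, dt = 20, 40.0
        for _ in range(steps):
            cells, _, _, _ = proliferate_apoptose(
                cells, g, np.zeros(g.shape, bool), np.zeros(g.shape, bool),
                set(), params, dt, rng, 10_000,
            )
        p_survive = np.exp(-k * dt * steps)
        expected = 1000 * p_survive
        sigma = np.sqrt(1000 * p_survive * (1 - p_survive))
        assert abs(len(cells) - expected) < 3 * sigma

    def test_tgfb_occupancy_boosts_division(self, rng):
        """Receptor occupancy above threshold doubles realized divisions
        (paired seeds, 3 sigma)."""
        g = _marrow_grid((40, 14, 14))
        base_rate = 2e-4
        params = RuleParams(prolif_rate={"MSC": base_rate}, apoptosis_rate={},
                            tgfb_prolif_factor=2.0, tgfbr_bound_threshold=0.5)

        def births(occ, seed):
            r = np.random.default_rng(seed)
            cells = [
                Cell(i, "MSC", (2 * i % 39, 2 * (i // 20) % 13, 1),
                     receptors={"TGFBR": _pool("TGFBR", occ)})
                for i in range(500)
            ]
            total = 0
            for _ in range(10):
                cells, _, b, _ = proliferate_apoptose(
                    cells, g, np.zeros(g.shape, bool),
                    np.zeros(g.shape, bool), set(), params, 40.0, r, 10_000,
                )
                total += b
            return total

        lo = sum(births(0.0, s) for s in range(5))
        hi = sum(births(0.9, s) for s in range(5))
        # expectation ratio 2; allow 3 sigma of the Poisson-scale spread
        assert hi > lo + 3 * np.sqrt(hi + lo) / 2


class TestDifferentiate:
    def _run(self, cells, grid=None, params=None):
        if grid is None:
            grid = _marrow_grid()
        bone = grid.region == Region.TRAB_BONE
        from scipy import ndimage
        from trabsim.synthgen import bone_surface_mask

        surface = bone_surface_mask(grid)
        dist = ndimage.distance_transform_edt(~bone)
        differentiate(cells, grid, bone, surface, dist,
                      params or RuleParams(), _factories())
        return cells

    def test_preosteocyte_matures_at_half_mineral(self):
        g = init_tissue_state(np.zeros((3, 3, 3), bool))
        g.mineral[1, 1, 1] = 0.5
        c_lo = Cell(0, "preOt", (0, 0, 0))
        c_hi = Cell(1, "preOt", (1, 1, 1))
        self._run([c_lo, c_hi], g)
        assert c_hi.kind == "Ot"
        assert c_lo.kind == "preOt"

    def test_hsc_needs_high_rank_occupancy(self):
        g = _marrow_grid()
        low = Cell(0, "HSC", (1, 1, 1), receptors={"RANK": _pool("RANK", 0.3)})
        high = Cell(1, "HSC", (3, 3, 3), receptors={"RANK": _pool("RANK", 0.9)})
        self._run([low, high], g)
        assert low.kind == "HSC"
        assert high.kind == "preOc"

    def test_preoc_reverts_without_rank(self):
        g = _marrow_grid()
        c = Cell(0, "preOc", (1, 1, 1), receptors={"RANK": _pool("RANK", 0.1)})
        self._run([c], g)
        assert c.kind == "HSC"

    @pytest.mark.parametrize("n_neighbors,expected", [(2, "preOc"), (3, "Oc")])
    def test_cluster_rule_for_osteoclast_fusion(self, n_neighbors, expected):
        g = _marrow_grid()
        cells = [Cell(0, "preOc", (3, 3, 3),
                      receptors={"RANK": _pool("RANK", 0.9)})]
        spots = [(3, 3, 4), (3, 4, 3), (4, 3, 3)][:n_neighbors]
        for i, p in enumerate(spots):
            cells.append(Cell(i + 1, "Oc", p,
                              receptors={"RANK": _pool("RANK", 0.9)}))
        self._run(cells, g)
        assert cells[0].kind == expected

    def test_osteoblast_becomes_lining_under_sclerostin(self):
        g = _marrow_grid()
        c = Cell(0, "Ob", (1, 1, 1), receptors={"LRP56": _pool("LRP56", 0.9)})
        self._run([c], g)
        assert c.kind == "lining"

    def test_osteoblast_entombs_as_preosteocyte(self):
        """Ob in a voxel half full of osteoid with an osteocyte toward the
        bone becomes a preosteocyte."""
        mask = np.zeros((5, 5, 5), bool)
        mask[0:2] = True  # bone slab at low z
        g = init_tissue_state(mask)
        g.osteoid[2, 2, 2] = 0.5
        ob = Cell(0, "Ob", (2, 2, 2), receptors={"LRP56": _pool("LRP56", 0.0)})
        ot = Cell(1, "Ot", (1, 2, 2))
        self._run([ob, ot], g)
        assert ob.kind == "preOt"

    def test_msc_fate_near_surface_and_osteoclast(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0] = True
        g = init_tissue_state(mask)
        msc_ob = Cell(0, "MSC", (1, 2, 2),
                      receptors={"LRP56": _pool("LRP56", 0.0)})
        msc_lin = Cell(1, "MSC", (1, 2, 3),
                       receptors={"LRP56": _pool("LRP56", 0.9)})
        msc_far = Cell(2, "MSC", (3, 2, 2),
                       receptors={"LRP56": _pool("LRP56", 0.0)})
        oc = Cell(3, "Oc", (1, 1, 2), receptors={"RANK": _pool("RANK", 0.0)})
        self._run([msc_ob, msc_lin, msc_far, oc], g)
        assert msc_ob.kind == "Ob"
        assert msc_lin.kind == "lining"
        assert msc_far.kind == "MSC"  # too far from the surface


class TestDepositOsteoid:
    def _setup(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0:2] = True
        g = init_tissue_state(mask)
        ob = Cell(0, "Ob", (1, 2, 2))
        curve = HillCurve(y_max=0.3, h=2.0, theta=1e-3, increasing=True)
        return g, ob, curve

    def test_zero_strain_zero_deposition(self):
        g, ob, curve = self._setup()
        assert deposit_osteoid(ob, 0.0, g, curve, RuleParams()) == 0.0
        assert g.osteoid.sum() == pytest.approx(2 * 25.0)

    def test_budget_equals_hill_rate(self):
        g, ob, curve = self._setup()
        eps = 2e-3
        before = g.osteoid.sum()
        dep = deposit_osteoid(ob, eps, g, curve, RuleParams())
        assert dep == pytest.approx(curve(eps), abs=1e-10)
        assert g.osteoid.sum() - before == pytest.approx(curve(eps), abs=1e-10)

    def test_cap_and_spill(self):
        g, ob, curve = self._setup()
        # fill the preferred target to 0.9: a 0.2 budget must split 0.1/0.1
        g.osteoid[2, 1, 1] = 0.9  # partial voxel gets priority
        big = HillCurve(y_max=0.2, h=2.0, theta=1e-9, increasing=True)
        dep = deposit_osteoid(ob, 1.0, g, big, RuleParams())
        assert dep == pytest.approx(0.2, abs=1e-12)
        assert g.osteoid[2, 1, 1] == pytest.approx(1.0)
        assert g.osteoid.max() <= 1.0 + 1e-12


class TestResorb:
    def _setup(self, n_cluster=3):
        mask = np.zeros((5, 5, 5), bool)
        mask[0:2] = True
        g = init_tissue_state(mask)
        spots = [(1, 2, 2), (1, 2, 3), (1, 3, 2)]
        cells = [Cell(i, "Oc", spots[i],
                      receptors={"RANK": _pool("RANK", 0.9)})
                 for i in range(n_cluster)]
        positions = {}
        for c in cells:
            positions.setdefault(c.position, []).append(c)
        curve = HillCurve(y_max=0.5, h=2.0, theta=1e-3, increasing=False)
        return g, cells, positions, curve

    def test_isolated_osteoclast_inactive(self):
        g, cells, positions, curve = self._setup(n_cluster=1)
        assert not oc_in_cluster(cells[0], positions, RuleParams())
        rm, ro = resorb(cells[0], 0.0, g, curve, RuleParams(), positions)
        assert rm == 0.0 and ro == 0.0

    def test_low_rank_occupancy_inactive(self):
        g, cells, positions, curve = self._setup()
        cells[0].receptors["RANK"].bound = 0.1
        rm, _ = resorb(cells[0], 0.0, g, curve, RuleParams(), positions)
        assert rm == 0.0

    def test_high_strain_shuts_down_resorption(self):
        g, cells, positions, curve = self._setup()
        rm, _ = resorb(cells[0], 1.0, g, curve, RuleParams(), positions)
        assert rm < 1e-6

    def test_full_voxel_removal_bookkeeping(self):
        g, cells, positions, _ = self._setup()
        events = []
        big = HillCurve(y_max=1.0, h=2.0, theta=1e3, increasing=False)
        m0, o0 = g.mineral.sum(), g.osteoid.sum()
        rm, ro = resorb(cells[0], 0.0, g, big, RuleParams(), positions, events)
        assert rm == pytest.approx(1.0, abs=1e-12)
        assert ro == pytest.approx(1.0, abs=1e-12)
        assert m0 - g.mineral.sum() == pytest.approx(rm, abs=1e-12)
        assert o0 - g.osteoid.sum() == pytest.approx(ro, abs=1e-12)
        assert sum(e[1] for e in events) == pytest.approx(rm, abs=1e-12)


class TestMineralize:
    def test_fixed_point_at_equal_concentrations(self, rng):
        m = rng.random(50)
        assert np.allclose(mineralize(m, m, 0.05), m)

    def test_scalar_update_value(self):
        # m=0, o=1, r dt = 0.01 -> 0.01 sinh(0.5)
        out = mineralize(0.0, 1.0, 0.01, 1.0)
        assert out == pytest.approx(0.01 * np.sinh(0.5), abs=1e-15)

    def test_monotone_convergence_without_overshoot(self):
        """Iterating toward constant osteoid converges monotonically to it,
        never crossing (scalar ODE oracle: the update sign never flips)."""
        m = 0.0
        prev = m
        for _ in range(3000):
            m = mineralize(m, 1.0, 0.05, 1.0)
            assert prev <= m <= 1.0
            prev = m
        assert m == pytest.approx(1.0, abs=1e-3)

    def test_overshoot_clamped_to_osteoid(self):
        out = mineralize(0.4, 0.5, 10.0, 1.0)  # huge rate would overshoot
        assert out == pytest.approx(0.5)
        out = mineralize(0.6, 0.5, 10.0, 1.0)  # decreasing branch too
        assert out == pytest.approx(0.5)

    def test_alternative_sinh_form(self):
        out = mineralize(0.0, 0.8, 0.01, 1.0, form="squared")
        assert out == pytest.approx(0.01 * np.sinh(0.64), abs=1e-15)

    def test_demineralization_when_osteoid_lower(self):
        out = mineralize(1.0, 0.0, 0.01, 1.0)
        assert out == pytest.approx(1.0 - 0.01 * np.sinh(0.5), abs=1e-15)


class TestProduceCytokines:
    def _table(self, theta=1e-3):
        return {
            ("Ot", "OPG"): HillCurve(1.0, 2.0, theta, True),
            ("Ot", "RANKL"): HillCurve(1.0, 2.0, theta, False),
            ("Ot", "Scl"): HillCurve(1.0, 2.0, theta, False),
            ("Ob", "osteoid"): HillCurve(1.0, 2.0, theta, True),
        }

    def test_no_cells_no_sources(self):
        assert produce_cytokines([], np.zeros((3, 3, 3)), self._table(),
                                 (3, 3, 3)) == {}

    def test_half_max_identity(self):
        eps = np.full((3, 3, 3), 1e-3)
        cells = [Cell(0, "Ot", (1, 1, 1))]
        src = produce_cytokines(cells, eps, self._table(), (3, 3, 3))
        for s in ("OPG", "RANKL", "Scl"):
            assert src[s][1, 1, 1] == pytest.approx(0.5)
        assert "osteoid" not in src  # matrix products are not field sources

    def test_source_additivity(self):
        eps = np.full((3, 3, 3), 2e-3)
        one = produce_cytokines([Cell(0, "Ot", (1, 1, 1))], eps,
                                self._table(), (3, 3, 3))
        two = produce_cytokines(
            [Cell(0, "Ot", (1, 1, 1)), Cell(1, "Ot", (1, 1, 1))], eps,
            self._table(), (3, 3, 3),
        )
        for s in one:
            assert two[s].sum() == pytest.approx(2 * one[s].sum())
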