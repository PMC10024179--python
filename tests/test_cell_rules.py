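"""Per-cell-type behavioral rules: kill probability, macrophage secretion,
mutation, and the kernel-backed update rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from micromet import _kernels as _k
from micromet.cell_rules import (
    KillContext, accessory_cell_update, cancer_cell_update, compute_pkill,
    ctl_update, dc_update, macrophage_secretion_rates, mutate_genotype,
    pack_params,
)
from micromet.model_core import (
    CANCER, CTL, DC, HELPER, MACROPHAGE, SUPPRESSOR, AntigenGenotype,
)


class TestComputePkill:
    def test_no_cytokines_no_therapy_gives_base(self):
        assert compute_pkill(KillContext(0.3, 1.0, 1.0, 0.0, 0.0, 1.0)) \
            == pytest.approx(0.3)

    def test_closed_form_values(self):
        ctx = KillContext(0.1, 1.0, 1.0, np.log(2), 0.0, 1.0)
        assert compute_pkill(ctx) == pytest.approx(0.55)
        ctx_rx = KillContext(0.1, 1.0, 1.0, np.log(2), 0.0, 0.1)
        assert compute_pkill(ctx_rx) == pytest.approx(0.55 ** 0.1)
        assert compute_pkill(ctx_rx) > compute_pkill(ctx)  # therapy boosts killing

    @settings(deadline=None, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 5), st.floats(0, 5),
           st.floats(0, 50), st.floats(0, 50),
           st.floats(0.01, 1.0))
    def test_bounded_probability(self, pb, te, ts_, e, s, g):
        p = compute_pkill(KillContext(pb, te, ts_, e, s, g))
        assert 0.0 <= p <= 1.0

    def test_monotonicity_grid(self):
        """Increasing in [ENH], decreasing in [SUP], increasing as g drops."""
        es = np.linspace(0, 5, 11)
        for s in (0.0, 1.0, 3.0):
            vals = [compute_pkill(KillContext(0.1, 0.8, 0.8, e, s, 1.0)) for e in es]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        for e in (0.0, 1.0, 3.0):
            vals = [compute_pkill(KillContext(0.1, 0.8, 0.8, e, s, 1.0)) for s in es]
            assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        for e, s in [(0.0, 0.0), (2.0, 1.0), (0.5, 4.0)]:
            assert compute_pkill(KillContext(0.1, 0.8, 0.8, e, s, 0.1)) \
                >= compute_pkill(KillContext(0.1, 0.8, 0.8, e, s, 1.0))

    def test_kernel_and_python_agree(self):
        for args in [(0.1, 1.0, 2.0, 0.7, 0.3, 0.1), (0.5, 0.2, 0.2, 3.0, 5.0, 1.0)]:
            assert _k.pkill(*args) == pytest.approx(compute_pkill(KillContext(*args)))


class TestMacrophageSecretion:
    @pytest.mark.parametrize("enh,sup,r,expected", [
        (1.0, 1.0, 2.0, (1.0, 1.0)),
        (0.0, 3.0, 1.0, (0.0, 1.0)),
        (0.0, 0.0, 0.8, (0.4, 0.4)),   # neutral M0 convention
        (3.0, 1.0, 4.0, (3.0, 1.0)),
    ])
    def test_shares(self, enh, sup, r, expected):
        assert macrophage_secretion_rates(enh, sup, r) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 10))
    def test_rates_sum_exactly(self, enh, sup, r):
        re, rs = macrophage_secretion_rates(enh, sup, r)
        assert re + rs == pytest.approx(r, abs=1e-12)
        assert re >= 0 and rs >= 0


class TestMutation:
    def test_zero_probability_unchanged(self):
        g = AntigenGenotype.from_antigens([0, 5])
        for seed in range(50):
            assert mutate_genotype(g, 0.0, seed=seed).mask == g.mask

    def test_single_allele_toggle(self):
        g = AntigenGenotype.from_antigens([0, 5, 9])
        _k.seed_rng(99)
        for _ in range(10_000):
            m = mutate_genotype(g, 1.0)
            diff = m.antigens ^ g.antigens
            assert len(diff) == 1
            assert len(m) >= 1

    def test_toggle_uniform_over_alleles(self):
        g = AntigenGenotype.from_antigens([0, 15])  # no empty-set redraw possible? 0 or 15 removable
        # use a 2-antigen genotype: toggling any of 32 alleles never empties it
        counts = np.zeros(32)
        _k.seed_rng(7)
        for _ in range(100_000):
            m = mutate_genotype(g, 1.0)
            b = next(iter(m.antigens ^ g.antigens))
            counts[b] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_never_empties_single_antigen(self):
        g = AntigenGenotype.from_antigens([3])
        _k.seed_rng(11)
        for _ in range(5000):
            assert len(mutate_genotype(g, 1.0)) >= 1


class TestCancerRule:
    def test_certain_death_leaves_debris(self, state_factory):
        state = state_factory(p_death=1.0)
        i = state.add_agent(CANCER, (2, 2, 2), genotype_mask=0b1001)
        assert cancer_cell_update(state, i) == "died"
        v = state.lattice.flat_index((2, 2, 2))
        assert not state.alive[i]
        assert state.debris[v] == 0b1001
        assert state.occ[v] == -1

    def test_enclosed_cell_cannot_divide(self, state_factory):
        state = state_factory(p_death=0.0, p_mutation=0.0, t_proliferation=1)
        i = state.add_agent(CANCER, (1, 1, 1), genotype_mask=1)
        for nb in [(x, y, z) for x in range(3) for y in range(3) for z in range(3)
                   if (x, y, z) != (1, 1, 1)]:
            state.add_agent(CANCER, nb, genotype_mask=1)
        state.prolif[i] = 100  # timer long expired
        assert cancer_cell_update(state, i) == "none"
        assert state.counts()["cancer"] == 27
        assert state.prolif[i] > 100  # timer stays expired, retry next step

    def test_division_inherits_genotype_and_resets_timer(self, state_factory):
        state = state_factory(p_death=0.0, p_mutation=0.0, t_proliferation=5,
                              p_migration_cancer=0.0)
        i = state.add_agent(CANCER, (2, 2, 2), genotype_mask=0b110)
        state.prolif[i] = 4  # one step short; update increments then divides
        assert cancer_cell_update(state, i) == "divided"
        assert state.counts()["cancer"] == 2
        assert state.prolif[i] == 0
        j = [a for a in np.flatnonzero(state.alive) if a != i][0]
        assert state.geno[j] == 0b110
        assert state.occupancy_consistent()


class TestCtlRule:
    def _armed_state(self, state_factory, specificity=0, cancer_mask=1, **over):
        state = state_factory(**over)
        c = state.add_agent(CANCER, (2, 2, 3), genotype_mask=cancer_mask)
        t = state.add_agent(CTL, (2, 2, 2), specificity=specificity)
        return state, c, t

    def test_non_matching_antigen_never_attacked(self, state_factory):
        state, c, t = self._armed_state(state_factory, specificity=4,
                                        cancer_mask=0b1, p_base=1.0,
                                        p_migration_immune=0.0)
        for seed in range(200):
            _k.seed_rng(seed)
            assert ctl_update(state, t) == "moved"  # patrols, never attacks
            assert state.alive[c]

    def test_certain_kill_removes_target_and_immobilizes(self, state_factory):
        state, c, t = self._armed_state(state_factory, p_base=1.0, t_kill=4)
        state.step = 10
        assert ctl_update(state, t) == "killed"
        assert not state.alive[c]
        assert state.debris[state.lattice.flat_index((2, 2, 3))] == 1
        assert state.immobile[t] == 14
        # while immobile the CTL neither moves nor kills
        c2 = state.add_agent(CANCER, (2, 2, 3), genotype_mask=1)
        pos_before = state.pos[t]
        for step in range(11, 14):
            state.step = step
            assert ctl_update(state, t) == "moved"  # idle, classified as no-op move
            assert state.pos[t] == pos_before and state.alive[c2]

    def test_expiry_at_lifespan(self, state_factory):
        state = state_factory(t_life_ctl=10)
        t = state.add_agent(CTL, (2, 2, 2), specificity=0)
        state.age[t] = 10
        assert ctl_update(state, t) == "expired"
        assert not state.alive[t]

    def test_uniform_walk_without_enh(self, state_factory):
        """Zero ENH everywhere: movement uniform over the 26 neighbors."""
        state = state_factory()
        t = state.add_agent(CTL, (2, 2, 2), specificity=0)
        home = state.lattice.flat_index((2, 2, 2))
        counts = {}
        _k.seed_rng(5)
        for _ in range(13_000):
            ctl_update(state, t)
            counts[int(state.pos[t])] = counts.get(int(state.pos[t]), 0) + 1
            state.occ[state.pos[t]] = -1
            state.pos[t] = home
            state.occ[home] = t
        assert len(counts) == 26
        assert chisquare(list(counts.values())).pvalue > 0.001

    def test_chemotaxis_climbs_gradient(self, state_factory):
        state = state_factory(enh_chemotaxis_threshold=0.5)
        t = state.add_agent(CTL, (2, 2, 2), specificity=0)
        # linear ENH ramp along +x
        for v in range(state.lattice.n_voxels):
            x, _, _ = state.lattice.unflat(v)
            state.enh[v] = 1.0 + x
        for seed in range(50):
            _k.seed_rng(seed)
            ctl_update(state, t)
            x, y, z = state.lattice.unflat(int(state.pos[t]))
            assert x == 3  # steepest ascent
            assert state.activated[t]
            state.occ[state.pos[t]] = -1
            state.pos[t] = state.lattice.flat_index((2, 2, 2))
            state.occ[state.pos[t]] = t


class TestDcRule:
    def test_collects_debris_union_and_leaves(self, state_factory):
        state = state_factory(t_delay=7)
        d = state.add_agent(DC, (2, 2, 2))
        v = state.lattice.flat_index((2, 2, 2))
        state.debris[v] = 0b1001  # antigens {0, 3}
        assert dc_update(state, d) == "left"
        assert state.debris[v] == 0
        newest = (state.meta[_k.M_QHEAD] + 7 - 1) % 7
        assert state.queues[newest, 0] == 1.0
        assert state.queues[newest, 3] == 1.0
        assert state.queues[newest].sum() == 2.0
        # homeostasis: a naive replacement DC spawned at the border
        # (it may reuse the departed agent's array slot)
        assert state.counts()["dc"] == 1
        new_dc = np.flatnonzero(state.alive & (state.kind == DC))[0]
        assert state.lattice.is_border(state.lattice.unflat(int(state.pos[new_dc])))
        assert state.geno[new_dc] == 0
        assert int(state.pos[new_dc]) != v

    def test_without_debris_moves_and_stays(self, state_factory):
        state = state_factory()
        d = state.add_agent(DC, (2, 2, 2))
        for _ in range(50):
            assert dc_update(state, d) == "moved"
        assert state.counts()["dc"] == 1


class TestAccessoryRules:
    def test_helper_secretion_accumulates(self, state_factory):
        state = state_factory(r_enh=0.2)
        h = state.add_agent(HELPER, (1, 1, 1))
        v = state.lattice.flat_index((1, 1, 1))
        fp = pack_params(state.params, 10.0)[0]
        for _ in range(5):
            _k.secrete(state.occ, state.kind, state.pos, state.activated,
                       state.alive, state.enh, state.sup, fp,
                       state.kind.shape[0])
        assert state.enh[v] == pytest.approx(5 * 0.2 * 10.0)
        assert state.sup[v] == 0.0

    def test_suppressor_expires_at_lifespan(self, state_factory):
        state = state_factory(t_life_suppressor=20)
        s = state.add_agent(SUPPRESSOR, (2, 2, 2))
        state.age[s] = 20
        assert accessory_cell_update(state, s) == "expired"
        assert not state.alive[s]

    def test_macrophage_kill_reduces_to_base(self, state_factory):
        """Zero cytokines, g=1: macrophage kill probability equals its base."""
        state = state_factory(p_base_macrophage=1.0)
        c = state.add_agent(CANCER, (2, 2, 3), genotype_mask=0b100)
        m = state.add_agent(MACROPHAGE, (2, 2, 2))
        assert accessory_cell_update(state, m, g=1.0) == "killed"
        assert not state.alive[c]
        assert state.debris[state.lattice.flat_index((2, 2, 3))] == 0b100
        # and with base 0 it never kills, only engages
        state2 = state_factory(p_base_macrophage=0.0)
        state2.add_agent(CANCER, (2, 2, 3), genotype_mask=1)
        m2 = state2.add_agent(MACROPHAGE, (2, 2, 2))
        assert accessory_cell_update(state2, m2, g=1.0) == "engaged"
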