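import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magloop.sim import (
    DropletState,
    EngagementModel,
    ParticleClusterState,
    PlatformState,
    SurfaceEnergyTrap,
    anchor_check,
    cap_footprint_radius,
    contact_merge,
    disengagement_speed,
    extraction_speed,
    step,
)
from magloop.sim.model import POWER_HIGH, release_speed

from conftest import build_state


class TestThresholds:
    def test_no_particles_no_drag(self, model):
        assert disengagement_speed(model, 0.0) == 0.0

    def test_disengagement_default_example(self, model):
        # k_mag = 20, 0.5 μl, default power
        assert disengagement_speed(model, 0.5) == pytest.approx(10.0)

    def test_disengagement_linearity(self, model):
        for vp in (0.1, 0.7, 2.0):
            for power in ("default", "high"):
                assert disengagement_speed(model, 2 * vp, power) == pytest.approx(
                    2 * disengagement_speed(model, vp, power)
                )

    def test_disengagement_negative_volume_rejected(self, model):
        with pytest.raises(ValueError):
            disengagement_speed(model, -0.1)

    def test_extraction_default_example(self, model):
        # k_exit = 8, 1.0 μl, not anchored, default power
        assert extraction_speed(model, 1.0) == pytest.approx(8.0)

    def test_extraction_anchored_is_lower(self, model):
        assert extraction_speed(model, 1.0, anchored=True) < extraction_speed(model, 1.0, anchored=False)

    def test_extraction_nonpositive_volume_rejected(self, model):
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError):
                extraction_speed(model, bad)

    @given(
        vp=st.floats(min_value=0.01, max_value=10.0),
        anchored=st.booleans(),
        power=st.sampled_from(["default", "high"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_extraction_always_below_disengagement(self, vp, anchored, power):
        model = EngagementModel()
        assert extraction_speed(model, vp, anchored, power) < disengagement_speed(model, vp, power)

    def test_power_gain_raises_disengagement(self, model):
        assert disengagement_speed(model, 1.0, POWER_HIGH) > disengagement_speed(model, 1.0)

    def test_invalid_model_constants_rejected(self):
        with pytest.raises(ValueError):
            EngagementModel(k_mag=5.0, k_exit=8.0)
        with pytest.raises(ValueError):
            EngagementModel(set_factor=1.5)


def run_to(state, target, speed, model, dt=0.05, max_steps=20000):
    for _ in range(max_steps):
        state = step(state, target, speed, dt, model)
        if math.dist(state.magnet.cp, target) < 1e-9:
            return state
    raise AssertionError("magnet never arrived")


class TestStep:
    def test_transport_regime_moves_droplet_and_cluster(self, model):
        state = build_state(particle_volume=0.5)
        state.magnet.position = state.magnet.cp = (10.0, 20.0)  # engage at the cluster
        state.magnet.engaged = True
        state = run_to(state, (30.0, 20.0), 8.33, model)
        assert state.clusters["p1"].center == pytest.approx((30.0, 20.0))
        assert state.droplets["d1"].center == pytest.approx((30.0, 20.0), abs=0.2)

    def test_disengaged_speed_moves_nothing(self, model):
        state = build_state(particle_volume=0.3)  # v_mag = 6 < 12
        state.magnet.position = state.magnet.cp = (10.0, 20.0)
        state.magnet.engaged = True
        state = run_to(state, (30.0, 20.0), 12.0, model)
        assert state.clusters["p1"].center == pytest.approx((10.0, 20.0))
        assert state.droplets["d1"].center == pytest.approx((10.0, 20.0))

    def test_magnet_off_moves_nothing(self, model):
        state = build_state()
        state.magnet.position = state.magnet.cp = (10.0, 20.0)
        state.magnet.engaged = False
        state = run_to(state, (30.0, 20.0), 5.0, model)
        assert state.clusters["p1"].center == pytest.approx((10.0, 20.0))

    def test_extraction_regime_detaches_cluster(self, model):
        # 1.0 μl, unanchored: release threshold = max(8, k_drag=12) = 12 < v = 15 < v_mag = 20
        state = build_state(particle_volume=1.0)
        state.magnet.position = state.magnet.cp = (10.0, 20.0)
        state.magnet.engaged = True
        state = run_to(state, (25.0, 20.0), 15.0, model)
        cluster = state.clusters["p1"]
        assert cluster.host_droplet_id is None
        assert state.droplets["d1"].center == pytest.approx((10.0, 20.0))
        assert cluster.volume == pytest.approx(1.0 * (1 - model.residual_fraction))
        assert state.droplets["d1"].particle_volume_inside == pytest.approx(model.residual_fraction * 1.0)

    def test_anchored_droplet_does_not_translate(self, model):
        state = build_state(sets=[("s1", (10.0, 20.0), 1.5)])
        state = anchor_check(state)
        state.magnet.position = state.magnet.cp = (10.0, 20.0)
        state.magnet.engaged = True
        before = state.droplets["d1"].center
        # speed 3 >= anchored extraction threshold 2.0 -> extraction regime; droplet stays put
        moved = step(state, (14.0, 20.0), 3.0, 0.1, model)
        assert moved.droplets["d1"].center == pytest.approx(before)

    def test_bad_arguments(self, model):
        state = build_state()
        with pytest.raises(ValueError):
            step(state, (100.0, 0.0), 1.0, 0.1, model)
        with pytest.raises(ValueError):
            step(state, (10.0, 10.0), 1.0, 0.0, model)
        with pytest.raises(ValueError):
            step(state, (10.0, 10.0), -1.0, 0.1, model)

    def test_step_is_pure(self, model):
        state = build_state()
        state.magnet.engaged = True
        before = state.droplets["d1"].center
        step(state, (30.0, 20.0), 5.0, 0.5, model)
        assert state.droplets["d1"].center == before
        assert state.time == 0.0

    def test_determinism(self, model):
        def run():
            s = build_state()
            s.magnet.engaged = True
            s = run_to(s, (30.0, 25.0), 7.0, model)
            s = run_to(s, (12.0, 8.0), 4.0, model)
            return s

        a, b = run(), run()
        assert a.droplets["d1"].center == b.droplets["d1"].center
        assert a.clusters["p1"].center == b.clusters["p1"].center
        assert a.time == b.time

    def test_actuator_lag_delays_magnet(self, model):
        state = build_state(particle_volume=0.0)
        state.clusters.clear()
        state.magnet.lag = 1.0
        state = step(state, (20.0, 20.0), 8.33, 0.1, model)
        # the physical magnet trails the control point on the way to the target
        assert math.dist(state.magnet.position, (20.0, 20.0)) > math.dist(state.magnet.cp, (20.0, 20.0))


class TestContactMerge:
    def test_overlapping_droplets_merge_with_volume_sum(self):
        state = PlatformState()
        state.add_droplet(DropletState(id="a", center=(10.0, 10.0), volume=10.0))
        state.add_droplet(DropletState(id="b", center=(11.0, 10.0), volume=10.0))
        merged = contact_merge(state)
        assert len(merged.droplets) == 1
        assert merged.total_droplet_volume() == pytest.approx(20.0)

    def test_disjoint_droplets_unchanged(self):
        state = PlatformState()
        state.add_droplet(DropletState(id="a", center=(10.0, 10.0), volume=10.0))
        state.add_droplet(DropletState(id="b", center=(30.0, 10.0), volume=10.0))
        merged = contact_merge(state)
        assert set(merged.droplets) == {"a", "b"}

    def test_merged_radius_exceeds_parents(self):
        state = PlatformState()
        state.add_droplet(DropletState(id="a", center=(10.0, 10.0), volume=8.0))
        state.add_droplet(DropletState(id="b", center=(11.0, 10.0), volume=12.0))
        merged = contact_merge(state)
        radius = next(iter(merged.droplets.values())).footprint_radius
        assert radius > cap_footprint_radius(8.0)
        assert radius > cap_footprint_radius(12.0)

    def test_volume_weighted_centroid_and_color(self):
        state = PlatformState()
        state.add_droplet(DropletState(id="a", center=(10.0, 10.0), volume=10.0, color=(200, 40, 40)))
        state.add_droplet(DropletState(id="b", center=(11.0, 10.0), volume=10.0))
        merged = contact_merge(state)
        droplet = next(iter(merged.droplets.values()))
        assert droplet.center == pytest.approx((10.5, 10.0))
        assert droplet.color == (200, 40, 40)  # transparent parent dilutes no pigment

    def test_cluster_rehosted_to_merged_droplet(self):
        state = PlatformState()
        state.add_droplet(DropletState(id="a", center=(10.0, 10.0), volume=2.0, particle_volume_inside=0.1))
        state.add_cluster(ParticleClusterState(id="p", center=(10.0, 10.0), volume=0.1, host_droplet_id="a"))
        state.add_droplet(DropletState(id="b", center=(10.5, 10.0), volume=10.0))
        merged = contact_merge(state)
        assert merged.clusters["p"].host_droplet_id == "b"  # larger parent keeps its id

    def test_idempotent(self):
        state = PlatformState()
        state.add_droplet(DropletState(id="a", center=(10.0, 10.0), volume=10.0))
        state.add_droplet(DropletState(id="b", center=(11.0, 10.0), volume=10.0))
        once = contact_merge(state)
        twice = contact_merge(once)
        assert [d.center for d in twice.droplets.values()] == [d.center for d in once.droplets.values()]


class TestAnchorCheck:
    def test_droplet_on_set_is_anchored(self):
        state = build_state(center=(10.0, 20.0), sets=[("s1", (10.5, 20.0), 1.5)])
        anchored = anchor_check(state)
        assert anchored.droplets["d1"].anchored_set_id == "s1"
        assert anchored.droplets["d1"].center == (10.5, 20.0)

    def test_droplet_far_from_sets_not_anchored(self):
        state = build_state(center=(10.0, 20.0), sets=[("s1", (25.0, 20.0), 1.5)])
        assert anchor_check(state).droplets["d1"].anchored_set_id is None

    def test_anchored_droplet_fixed_under_transport_speed(self, model):
        state = anchor_check(build_state(sets=[("s1", (10.0, 20.0), 1.5)]))
        state.magnet.position = state.magnet.cp = (10.0, 20.0)
        state.magnet.engaged = True
        after = step(state, (15.0, 20.0), 1.5, 0.1, model)  # below anchored extraction threshold 2.0
        assert after.droplets["d1"].center == (10.0, 20.0)


class TestInvariants:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_volume_conserved_across_operations(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        state = PlatformState()
        for i in range(3):
            state.add_droplet(
                DropletState(id=f"d{i}", center=(float(rng.uniform(5, 35)), float(rng.uniform(5, 35))),
                             volume=float(rng.uniform(2, 15)))
            )
        state.add_cluster(ParticleClusterState(id="p", center=state.droplets["d0"].center, volume=0.5,
                                               host_droplet_id="d0"))
        state.add_set(SurfaceEnergyTrap(id="s", center=(20.0, 20.0), radius=1.5))
        state.magnet.engaged = True
        total = state.total_droplet_volume()
        model = EngagementModel()
        for _ in range(5):
            target = (float(rng.uniform(1, 39)), float(rng.uniform(1, 39)))
            state = step(state, target, float(rng.uniform(0.5, 15)), 0.2, model)
            state = contact_merge(state)
            state = anchor_check(state)
        assert state.total_droplet_volume() == pytest.approx(total)

    @given(vp=st.floats(min_value=0.05, max_value=5.0), power=st.sampled_from(["default", "high"]))
    @settings(max_examples=50, deadline=None)
    def test_release_window_nonempty_when_feasible(self, vp, power):
        model = EngagementModel()
        assert extraction_speed(model, vp, True, power) < disengagement_speed(model, vp, power)
        # unanchored window may be empty for tiny piles (k_drag floor), never inverted
        assert release_speed(model, vp, False, power) >= extraction_speed(model, vp, False, power)


class TestStateValidation:
    def test_duplicate_ids_rejected(self):
        state = PlatformState()
        state.add_droplet(DropletState(id="x", center=(5.0, 5.0), volume=1.0))
        with pytest.raises(ValueError):
            state.add_droplet(DropletState(id="x", center=(9.0, 9.0), volume=1.0))

    def test_cluster_outside_host_rejected(self):
        state = PlatformState()
        state.add_droplet(DropletState(id="d", center=(5.0, 5.0), volume=1.0))
        with pytest.raises(ValueError):
            state.add_cluster(ParticleClusterState(id="p", center=(20.0, 20.0), volume=0.2, host_droplet_id="d"))

    def test_nonpositive_volumes_rejected(self):
        with pytest.raises(ValueError):
            DropletState(id="d", center=(1.0, 1.0), volume=0.0)
        with pytest.raises(ValueError):
            ParticleClusterState(id="p", center=(1.0, 1.0), volume=-0.5)
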