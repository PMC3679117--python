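import math
from collections import deque
from dataclasses import replace

import numpy as np
import pytest

from seedscape.behaviour import ConsumptionModel, PerchModel, SpeciesTraits
from seedscape.landscape import Landscape
from seedscape.movement import MovementParams, destination_distribution
from seedscape.simulate import (
    EXPORTED,
    SimulationConfig,
    displacement_of,
    run_cohort,
    simulate_bird,
)

from conftest import uniform_landscape


def make_traits(name="bird", params=None, pi=0.5, lam=6.0, gpt_shape=2.0,
                gpt_scale=12.0, perch=(0.9, 2.5), abundance=1.0, spf=None):
    params = params or MovementParams(a_o=-1.5, b_o=0.02, eps_d=40.0, eta_d=1.5, combo="D")
    return SpeciesTraits(
        name=name, body_mass_g=80.0, relative_abundance=abundance,
        perch=PerchModel(*perch), consumption=ConsumptionModel(pi, lam),
        movement=params, gpt_shape=gpt_shape, gpt_scale=gpt_scale,
        seeds_per_fruit_by_plant=spf or {},
    )


class ScriptedRng:
    """Replays scripted draws per method; mirrors the simulator's call order:
    integers (initial cell), then per visit gamma (perch), random (ZIP gate),
    poisson, multivariate_hypergeometric, gamma (GPTs), random (leave),
    random (destination)."""

    def __init__(self, integers=(), gamma=(), poisson=(), random=(), mh=()):
        self._i = deque(integers)
        self._g = deque(gamma)
        self._p = deque(poisson)
        self._r = deque(random)
        self._m = deque(mh)

    def integers(self, *a, **k):
        return self._i.popleft()

    def gamma(self, shape, scale, size=None):
        v = self._g.popleft()
        if size is None:
            return v
        return np.asarray(v, dtype=float)

    def poisson(self, lam):
        return self._p.popleft()

    def random(self):
        return self._r.popleft()

    def multivariate_hypergeometric(self, colors, n):
        return np.asarray(self._m.popleft())


def _strip(n=5, fruits=100):
    return Landscape(1, n, 20.0, np.full(n, 200.0), ["p"],
                     np.full((n, 1), fruits, dtype=np.int64))


def test_hand_traced_event_timeline():
    """Fixed draws: perch 10 min, GPT 25 min, 20 m moves at 6 m/s.

    Two fruits ingested at t=0 in cell 0; the bird perches 10 min per cell and
    hops one cell right each move (flight 20/360 min), so both seeds (due
    t=25) drop during the third perch, in cell 2, displacement 40 m.
    """
    ls = _strip()
    params = MovementParams(a_o=-2.0, b_o=0.01, eps_d=30.0, eta_d=1.5, combo="D")
    traits = make_traits(params=params, pi=0.0)
    cfg = SimulationConfig(n_birds=1, n_replicates=1, burn_in_moves=0, flight_speed=6.0)

    # destination draws: u just below the cumulative mass of the wanted cell
    def u_for(cur, dest):
        k = destination_distribution(ls, cur, params).k
        return float(np.cumsum(k)[dest]) - 1e-12

    rng = ScriptedRng(
        integers=[0],
        gamma=[10.0, [25.0, 25.0], 10.0, 10.0],  # perch1, GPTs, perch2, perch3
        poisson=[2, 0, 0],
        mh=[[2]],
        random=[
            0.5, 0.99, u_for(0, 1),   # visit 1: feed gate, no-leave, go cell 1
            0.5, 0.99, u_for(1, 2),   # visit 2
            0.5, 0.0,                 # visit 3: feed gate, then leave
        ],
    )
    _, records, moves = simulate_bird(traits, ls, cfg, rng)
    ls.reset_fruits()
    assert len(records) == 2
    flight = 20.0 / 360.0
    for r in records:
        assert r.dep_cell == 2
        assert r.ingest_time == 0.0
        assert r.dep_time == pytest.approx(25.0)
        assert r.displacement == pytest.approx(40.0)
        # perch 3 spans [20 + 2*flight, 30 + 2*flight] which contains t=25
        assert 20 + 2 * flight < r.dep_time < 30 + 2 * flight


def test_midflight_deposition_interpolates_cell():
    """A seed due during a slow 80 m flight lands at the along-path cell."""
    ls = _strip()
    params = MovementParams(a_o=-2.0, b_o=0.01, eps_d=30.0, eta_d=1.5, combo="D")
    traits = make_traits(params=params, pi=0.0)
    cfg = SimulationConfig(n_birds=1, n_replicates=1, burn_in_moves=0, flight_speed=0.1)

    def u_for(cur, dest):
        k = destination_distribution(ls, cur, params).k
        return float(np.cumsum(k)[dest]) - 1e-12

    # perch 10 min; GPT 12 min; flight cell0 -> cell4 is 80 m at 6 m/min
    rng = ScriptedRng(
        integers=[0],
        gamma=[10.0, [12.0], 10.0],
        poisson=[1, 0],
        mh=[[1]],
        random=[0.5, 0.99, u_for(0, 4), 0.5, 0.0],
    )
    _, records, _ = simulate_bird(traits, ls, cfg, rng)
    ls.reset_fruits()
    assert len(records) == 1
    r = records[0]
    # due 2 min into a 13.33 min flight -> 12 m along from x=10 -> x=22, cell 1
    assert r.dep_cell == 1
    assert r.x == pytest.approx(22.0)
    assert r.displacement == pytest.approx(20.0)  # centroid-to-centroid


def test_exported_seed_distance_convention():
    """A seed carried out crosses at the nearest edge; distance is the origin
    centroid to the crossing point plus 1 m 'just outside'."""
    ls = _strip()
    params = MovementParams(a_o=-2.0, b_o=0.01, eps_d=30.0, eta_d=1.5, combo="D")
    traits = make_traits(params=params, pi=0.0)
    cfg = SimulationConfig(n_birds=1, n_replicates=1, burn_in_moves=0, flight_speed=6.0)
    rng = ScriptedRng(
        integers=[0],
        gamma=[10.0, [25.0]],
        poisson=[1],
        mh=[[1]],
        random=[0.5, 0.0],  # feed, then leave immediately after first perch
    )
    _, records, _ = simulate_bird(traits, ls, cfg, rng)
    ls.reset_fruits()
    assert len(records) == 1
    r = records[0]
    assert r.dep_cell == EXPORTED and r.exported
    # nearest boundary from centroid (10, 10) is the left edge at (0, 10)
    assert (r.x, r.y) == (0.0, 10.0)
    assert r.displacement == pytest.approx(11.0)


def test_displacement_of_convention(toy_landscape):
    assert displacement_of(0, 0, (10.0, 10.0), toy_landscape) == 0.0
    assert displacement_of(0, 2, (50.0, 10.0), toy_landscape) == pytest.approx(40.0)
    assert displacement_of(2, EXPORTED, (60.0, 10.0), toy_landscape) == pytest.approx(11.0)


def test_no_fruit_no_seed_records(rng):
    ls = Landscape(2, 2, 20.0, np.full(4, 100.0), ["p"], np.zeros((4, 1), dtype=np.int64))
    traits = make_traits(params=MovementParams(a_o=0.0, b_o=0.0, eps_d=30, eta_d=1.5, combo="D"))
    cfg = SimulationConfig(n_birds=1, n_replicates=1, burn_in_moves=0)
    for _ in range(20):
        _, records, _ = simulate_bird(traits, ls, cfg, rng)
        assert records == []


def test_single_cell_conservation(rng):
    """All ingested seeds end in the only cell or are exported; none vanish."""
    ls = Landscape(1, 1, 20.0, np.array([100.0]), ["p"], np.array([[500]]))
    traits = make_traits(
        params=MovementParams(a_o=1.0, b_o=0.0, eps_d=30, eta_d=1.5, combo="D"),
        pi=0.0, lam=8.0,
    )
    cfg = SimulationConfig(n_birds=1, n_replicates=1, burn_in_moves=0)
    for _ in range(10):
        ls.reset_fruits()
        _, records, _ = simulate_bird(traits, ls, cfg, rng)
        eaten = 500 - ls.total_fruits()
        assert len(records) == eaten  # one seed per fruit by default
        assert all(r.dep_cell in (0, EXPORTED) for r in records)
    ls.reset_fruits()


def test_cohort_conservation_ledgers(study_landscape, assemblage):
    """Fruit ledger and seed ledger balance exactly across a cohort run."""
    cfg = SimulationConfig(n_birds=40, n_replicates=2, seed=3)
    res = run_cohort(assemblage, study_landscape, cfg)
    # fruit conservation per run
    assert res.fruits_initial_total - res.fruits_final_total == res.fruits_eaten_total
    # seed conservation: every ingested fruit's seeds are deposited or exported
    spf = {t.name: t.seeds_per_fruit_by_plant for t in assemblage}
    expected = sum(
        r.fruits_eaten * spf[r.bird_species].get(r.plant_species, 1)
        for r in res.diet.itertuples()
    )
    assert len(res.seed_records) == expected
    # time consistency
    # (ingest/dep times are per-bird clocks; deposition never precedes ingestion)
    rec = res.seed_records
    assert (rec["displacement_m"] >= 0).all()
    assert rec["dep_cell"].isin(list(range(study_landscape.n_cells)) + [EXPORTED]).all()


def test_deposition_after_ingestion(study_landscape, assemblage, rng):
    cfg = SimulationConfig(n_birds=1, n_replicates=1, burn_in_moves=0)
    traits = assemblage[0]
    for _ in range(5):
        study_landscape.reset_fruits()
        _, records, _ = simulate_bird(traits, study_landscape, cfg, rng)
        for r in records:
            assert r.dep_time >= r.ingest_time
    study_landscape.reset_fruits()


def test_seeds_per_fruit_multiplier(rng):
    ls = _strip(fruits=1000)
    traits = make_traits(params=MovementParams(a_o=2.0, b_o=0.0, eps_d=30, eta_d=1.5, combo="D"),
                         pi=0.0, lam=5.0, spf={"p": 4})
    cfg = SimulationConfig(n_birds=1, n_replicates=1, burn_in_moves=0)
    _, records, _ = simulate_bird(traits, ls, cfg, rng)
    eaten = 5000 - ls.total_fruits()
    assert len(records) == 4 * eaten
    ls.reset_fruits()


def test_distance_only_ignores_cover(fit_landscape):
    """Permuting the cover map leaves the distance-only seed rain unchanged."""
    pool = np.array([0.0, 20.0, 28.3, 40.0, 60.0, 120.0])
    traits = make_traits()
    cfg = SimulationConfig(n_birds=30, n_replicates=2, seed=9,
                           mode="distance_only", empirical_moves=pool)
    res1 = run_cohort([traits], fit_landscape, cfg)
    shuffled = Landscape(
        fit_landscape.rows, fit_landscape.cols, fit_landscape.cell_size,
        np.random.default_rng(5).permutation(fit_landscape.cover_m2),
        fit_landscape.plant_species, fit_landscape.fruits,
    )
    res2 = run_cohort([traits], shuffled, cfg)
    assert res1.seed_records.equals(res2.seed_records)
    assert res1.move_lengths.equals(res2.move_lengths)


def test_species_sampling_matches_abundance(rng):
    """Bird identities across a cohort follow the binomial implied by the
    configured relative abundances."""
    ls = Landscape(2, 2, 20.0, np.zeros(4), ["p"], np.zeros((4, 1), dtype=np.int64))
    fast_exit = MovementParams(a_o=4.0, b_o=0.0, eps_d=30, eta_d=1.5, combo="D")
    a = make_traits("a", params=fast_exit, abundance=0.5)
    b = make_traits("b", params=fast_exit, abundance=0.5)
    n = 4000
    res = run_cohort([a, b], ls, SimulationConfig(n_birds=n, n_replicates=1, seed=1))
    counts = res.birds.set_index("bird_species")["n_birds"]
    assert counts.sum() == n
    se = math.sqrt(n * 0.25)
    assert abs(counts["a"] - n / 2) < 3 * se


def test_single_species_assemblage(rng):
    ls = Landscape(2, 2, 20.0, np.zeros(4), ["p"], np.zeros((4, 1), dtype=np.int64))
    t = make_traits(params=MovementParams(a_o=4.0, b_o=0.0, eps_d=30, eta_d=1.5, combo="D"))
    res = run_cohort([t], ls, SimulationConfig(n_birds=50, n_replicates=1, seed=2))
    assert (res.birds["n_birds"] == 50).all()


def test_run_cohort_validation(study_landscape, assemblage):
    with pytest.raises(ValueError):
        run_cohort([], study_landscape, SimulationConfig(n_birds=1, n_replicates=1))
    bad = [replace(t) for t in assemblage]
    bad[0].relative_abundance = 0.9
    with pytest.raises(ValueError):
        run_cohort(bad, study_landscape, SimulationConfig(n_birds=1, n_replicates=1))
    with pytest.raises(ValueError):
        run_cohort(assemblage, study_landscape,
                   SimulationConfig(n_birds=1, n_replicates=1, mode="distance_only"))


def test_default_config_is_study_protocol():
    cfg = SimulationConfig()
    assert cfg.n_birds == 5000
    assert cfg.n_replicates == 30
    assert cfg.burn_in_moves == 5
    assert cfg.flight_speed == 6.0
    assert cfg.mode == "full"


def test_burn_in_flags_first_moves(study_landscape, assemblage):
    cfg = SimulationConfig(n_birds=30, n_replicates=1, seed=4, burn_in_moves=5)
    res = run_cohort(assemblage, study_landscape, cfg)
    rec = res.seed_records
    assert rec["burn_in"].any()  # early ingestions flagged
    assert (~rec["burn_in"]).any()
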