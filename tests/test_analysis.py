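import itertools
import math

import numpy as np
import pandas as pd
import pytest

from seedscape.analysis import (
    diet_composition,
    distance_summary,
    export_for_sar,
    local_cluster_indices,
    sadie_ia,
    sadie_xp,
    seed_rain_grid,
    seed_shadow,
    transport_distance,
)
from seedscape.landscape import Landscape

from conftest import uniform_landscape


def _records(rows):
    cols = ["replicate", "plant_species", "bird_species", "origin_cell",
            "dep_cell", "exported", "x", "y", "displacement_m", "burn_in"]
    return pd.DataFrame(rows, columns=cols)


def _rec(origin, dep, disp, exported=False, bird="b", plant="p", burn=False):
    return [0, plant, bird, origin, dep, exported, 0.0, 0.0, disp, burn]


def test_distance_summary_arithmetic_fixture(toy_landscape):
    """Displacements (0, 50, 150, 250): mean 112.5, P>100 = .5, P>200 = .25."""
    df = _records([
        _rec(0, 0, 0.0),
        _rec(0, 2, 50.0),
        _rec(0, -1, 150.0, exported=True),
        _rec(0, -1, 250.0, exported=True),
    ])
    out = distance_summary(df, toy_landscape)
    assert len(out) == 1
    r = out.iloc[0]
    assert r["mean_m"] == pytest.approx(112.5)
    assert r["p_gt_100m"] == pytest.approx(0.5)
    assert r["p_gt_200m"] == pytest.approx(0.25)
    assert r["p_exported"] == pytest.approx(0.5)
    assert r["p_origin_cell"] == pytest.approx(0.25)
    assert r["n_seeds"] == 4


def test_distance_summary_all_in_origin(toy_landscape):
    df = _records([_rec(1, 1, 0.0), _rec(1, 1, 0.0)])
    r = distance_summary(df, toy_landscape).iloc[0]
    assert r["mean_m"] == 0.0
    assert r["p_origin_cell"] == 1.0
    # cell 0 has zero cover in the toy strip; deposits in cell 1 do not count
    assert r["p_zero_cover"] == 0.0


def test_distance_summary_excludes_burn_in(toy_landscape):
    df = _records([_rec(0, 0, 0.0), _rec(0, 2, 40.0, burn=True)])
    r = distance_summary(df, toy_landscape).iloc[0]
    assert r["n_seeds"] == 1


def test_seed_shadow_partitions_and_normalizes(toy_landscape):
    df = _records([
        _rec(0, 1, 20.0), _rec(0, 2, 40.0), _rec(0, 2, 40.0),
        _rec(1, 1, 0.0),
    ])
    shadow = seed_shadow(df, origin_cell=0, landscape=toy_landscape)
    assert shadow.sum() == pytest.approx(1.0)
    assert shadow[1] == pytest.approx(1 / 3)
    assert shadow[2] == pytest.approx(2 / 3)
    other = seed_shadow(df, origin_cell=1, landscape=toy_landscape)
    assert other[1] == 1.0
    # counts over both origins partition the full grid
    full = seed_rain_grid(df, toy_landscape)
    assert full.sum() == 4


def test_diet_composition_sums_to_one():
    diet = pd.DataFrame([
        {"replicate": 0, "bird_species": "b1", "plant_species": "A", "fruits_eaten": 30},
        {"replicate": 0, "bird_species": "b1", "plant_species": "B", "fruits_eaten": 10},
        {"replicate": 1, "bird_species": "b1", "plant_species": "A", "fruits_eaten": 20},
        {"replicate": 0, "bird_species": "b2", "plant_species": "A", "fruits_eaten": 5},
        {"replicate": 0, "bird_species": "b3", "plant_species": "A", "fruits_eaten": 0},
    ])
    out = diet_composition(diet)
    g = out.groupby("bird_species")["proportion"].sum()
    assert np.allclose(g.values, 1.0, atol=1e-9)
    b1 = out[out["bird_species"] == "b1"].set_index("plant_species")["proportion"]
    assert b1["A"] == pytest.approx(50 / 60)
    assert "b3" not in set(out["bird_species"])  # nothing eaten -> omitted


def test_diet_shifts_after_depletion(rng):
    """Once the scarce plant is eaten out, later birds eat the abundant one:
    the cumulative diet share of the scarce plant falls with cohort size."""
    from seedscape.simulate import SimulationConfig, run_cohort
    from test_simulator import make_traits

    n = 36
    ls = Landscape(6, 6, 20.0, np.full(n, 200.0), ["scarce", "rich"],
                   np.column_stack([np.full(n, 5), np.full(n, 5000)]).astype(np.int64))
    traits = make_traits(pi=0.0, lam=8.0)
    shares = []
    for n_birds in (30, 600):
        res = run_cohort([traits], ls, SimulationConfig(n_birds=n_birds, n_replicates=1, seed=8))
        d = diet_composition(res.diet).set_index("plant_species")["proportion"]
        shares.append(d.get("scarce", 0.0))
    assert shares[1] < shares[0]


# ---------------------------------------------------------------------------
# SADIE


def _brute_force_D(counts, coords):
    """Exhaustive integer-flow transportation optimum (tiny instances only).

    Requires the uniform target total/n to be an integer so all optimal flows
    are integral (transportation polytope integrality).
    """
    counts = np.asarray(counts, dtype=int)
    n = counts.size
    u, rem = divmod(int(counts.sum()), n)
    assert rem == 0, "fixture must have integer uniform target"
    resid = counts - u
    src = np.flatnonzero(resid > 0)
    snk = np.flatnonzero(resid < 0)
    if src.size == 0:
        return 0.0
    supply = resid[src]
    demand = -resid[snk]
    dist = np.sqrt(((coords[src][:, None] - coords[snk][None, :]) ** 2).sum(-1))

    best = [math.inf]

    def rec(i, remaining_demand, cost):
        if cost >= best[0]:
            return
        if i == len(supply):
            best[0] = cost
            return
        # enumerate all splits of supply[i] across sinks
        def split(j, left, c):
            if c >= best[0]:
                return
            if j == len(demand) - 1:
                if left <= remaining_demand[j]:
                    remaining_demand[j] -= left
                    rec(i + 1, remaining_demand, c + left * dist[i, j])
                    remaining_demand[j] += left
                return
            for f in range(min(left, remaining_demand[j]) + 1):
                remaining_demand[j] -= f
                split(j + 1, left - f, c + f * dist[i, j])
                remaining_demand[j] += f

        split(0, int(supply[i]), cost)

    rec(0, list(demand), 0.0)
    return best[0]


def test_transport_distance_two_cell_example():
    coords = np.array([[10.0, 10.0], [30.0, 10.0]])
    assert transport_distance([2, 0], coords) == pytest.approx(20.0)
    assert transport_distance([1, 1], coords) == 0.0


@pytest.mark.parametrize("seed", range(6))
def test_transport_matches_bruteforce_enumeration(seed):
    """LP transportation optimum equals exhaustive enumeration on <=6 cells."""
    r = np.random.default_rng(seed)
    n = int(r.integers(3, 7))
    coords = r.uniform(0, 100, (n, 2))
    # totals divisible by n, at most 6 moved units
    counts = np.full(n, 1, dtype=int)
    extra = n  # move n units around
    for _ in range(extra):
        counts[r.integers(n)] += 1
        counts[r.integers(n)] -= 1
    counts = np.clip(counts, 0, None)
    # rebalance to keep total divisible by n
    while counts.sum() % n:
        counts[r.integers(n)] += 1
    D_lp = transport_distance(counts, coords)
    D_bf = _brute_force_D(counts, coords)
    assert D_lp == pytest.approx(D_bf, abs=1e-8)


def test_ia_uniform_grid_is_zero(rng):
    coords = np.column_stack([np.repeat(np.arange(3), 3) * 20.0,
                              np.tile(np.arange(3), 3) * 20.0])
    res = sadie_ia(np.full(9, 4), coords, n_perm=99, rng=rng)
    assert res.D == 0.0 and res.Ia == 0.0


def test_ia_scale_invariance():
    """Multiplying all counts by a positive integer leaves Ia unchanged."""
    r = np.random.default_rng(12)
    coords = r.uniform(0, 100, (16, 2))
    counts = r.poisson(3, 16)
    counts[0] += 10
    ia1 = sadie_ia(counts, coords, n_perm=99, rng=np.random.default_rng(0)).Ia
    ia3 = sadie_ia(counts * 3, coords, n_perm=99, rng=np.random.default_rng(0)).Ia
    assert ia1 == pytest.approx(ia3, rel=1e-9)


def test_ia_flags_clustered_grid(rng):
    coords = np.column_stack([np.repeat(np.arange(5), 5) * 20.0,
                              np.tile(np.arange(5), 5) * 20.0])
    counts = np.zeros(25, dtype=int)
    counts[:3] = [30, 20, 10]
    res = sadie_ia(counts, coords, n_perm=99, rng=rng)
    assert res.Ia > 1.2
    assert res.p_Ia <= 0.05
    assert res.local_indices[0] > 0  # donor patch
    assert res.local_indices[24] < 0  # gap


def test_xp_self_association_is_exactly_one(rng):
    r = np.random.default_rng(4)
    coords = r.uniform(0, 100, (20, 2))
    counts = r.poisson(4, 20) + 1
    res = sadie_xp(counts, counts, coords, n_perm=99, rng=rng)
    assert res.Xp == 1.0
    assert res.p_Xp <= 0.05


def test_xp_mirror_is_less_than_one(rng):
    coords = np.column_stack([np.arange(8) * 20.0, np.zeros(8)])
    counts = np.array([40, 20, 10, 5, 2, 1, 1, 1])
    res = sadie_xp(counts, counts[::-1], coords, n_perm=99, rng=rng)
    assert res.Xp < 1.0


def test_xp_input_validation(rng):
    coords = np.zeros((3, 2))
    with pytest.raises(ValueError):
        sadie_xp([1, 2], [1, 2, 3], coords, rng=rng)
    with pytest.raises(ValueError):
        sadie_xp([0, 0, 0], [1, 2, 3], coords, rng=rng)


def test_sadie_ia_validation(rng):
    with pytest.raises(ValueError):
        sadie_ia([0, 0], np.zeros((2, 2)), rng=rng)
    with pytest.raises(ValueError):
        sadie_ia([1, 2], np.zeros((2, 2)), n_perm=10, rng=rng)


def test_sar_export_transforms(toy_landscape):
    df = _records([_rec(0, 1, 20.0), _rec(0, 1, 20.0)])
    out = export_for_sar(df, toy_landscape)
    assert len(out) == toy_landscape.n_cells
    # all seeds in cell 1: proportion 1 -> arcsin(sqrt(1)) = pi/2; others 0
    assert out.loc[1, "asin_sqrt_prop_seeds"] == pytest.approx(math.pi / 2)
    assert out.loc[0, "asin_sqrt_prop_seeds"] == 0.0
    assert out.loc[2, "log_fruits"] == pytest.approx(math.log1p(toy_landscape.fruits[2, 0]))
    assert out.loc[2, "asin_sqrt_cover"] == pytest.approx(
        math.asin(math.sqrt(toy_landscape.cover_fraction[2]))
    )
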