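"""Landscape-biased movement: plot-leaving, destination choice, MLE, AICc.

At the end of each perch the bird first decides whether to leave the plot,
with a logistic probability that decays with the distance B from the current
cell to the nearest plot edge:

    p_leave(B) = 1 / (1 + exp(-(a_o - b_o * B)))

If it stays, a destination cell (possibly the current one) is drawn from a
discrete distribution k over all cells. Each candidate cell i gets a weight
that is the product of up to three saturating tanh sigmoid factors —

    distance (always):  d_i = 1 - tanh((dist_i / eps_d) ** eta_d)
    cover (combo C):    c_i = tanh((cover_frac_i / eps_c) ** eta_c)
    fruit (combo F):    f_i = tanh((log1p(fruits_i) / eps_f) ** eta_f)

— each floored by a small constant so no observed move has exactly zero
likelihood; the product is normalized into k. The scale eps_* sets where each
response saturates and the shape eta_* how sharply. Factor combinations
{D, DC, DF, DCF} are fitted by maximum likelihood per bird species and
compared with AICc.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .landscape import Landscape

__all__ = [
    "COMBOS",
    "WEIGHT_FLOOR",
    "MovementParams",
    "DestinationDistribution",
    "Trajectory",
    "TrajectoryStep",
    "MovementEngine",
    "MovementFit",
    "leave_probability",
    "factor_weight",
    "destination_distribution",
    "step_loglik",
    "trajectory_loglik",
    "fit_movement",
    "select_model",
    "best_combo",
    "aicc",
    "trajectories_to_frame",
    "trajectories_from_frame",
]

COMBOS = ("D", "DC", "DF", "DCF")
WEIGHT_FLOOR = 1e-6


@dataclass
class MovementParams:
    """Parameters of the plot-leaving and destination-choice model.

    Factors absent from ``combo`` are ignored (their weight is identically 1).
    Units: eps_d in metres; eps_c on the cover fraction in [0, 1]; eps_f on
    log1p(fruit count per cell).
    """

    a_o: float
    b_o: float
    eps_d: float
    eta_d: float
    eps_c: float | None = None
    eta_c: float | None = None
    eps_f: float | None = None
    eta_f: float | None = None
    combo: str = "D"

    def __post_init__(self) -> None:
        if self.combo not in COMBOS:
            raise ValueError(f"combo must be one of {COMBOS}, got {self.combo!r}")
        for fac in self.factors:
            eps = getattr(self, f"eps_{fac.lower()}")
            if eps is None or eps <= 0:
                raise ValueError(f"eps_{fac.lower()} must be positive for combo {self.combo}")
            eta = getattr(self, f"eta_{fac.lower()}")
            if eta is None or eta <= 0:
                raise ValueError(f"eta_{fac.lower()} must be positive for combo {self.combo}")

    @property
    def factors(self) -> str:
        return self.combo  # combo string is exactly the factor set

    def free_names(self) -> list[str]:
        """Names of the destination-choice parameters free under this combo."""
        names = []
        for fac in self.combo.lower():
            names += [f"eps_{fac}", f"eta_{fac}"]
        return names

    @property
    def n_params(self) -> int:
        """Free parameters incl. the two plot-leaving ones (for AICc)."""
        return 2 + 2 * len(self.combo)


@dataclass
class DestinationDistribution:
    """Plot-leaving probability plus the choice distribution over cells."""

    p_leave: float
    k: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_leave <= 1.0:
            raise ValueError("p_leave must lie in [0, 1]")
        if abs(float(self.k.sum()) - 1.0) > 1e-9:
            raise ValueError("k must sum to 1")


@dataclass
class TrajectoryStep:
    cell_id: int
    perch_min: float = 0.0
    eaten: dict[str, int] = field(default_factory=dict)


@dataclass
class Trajectory:
    """An observed or simulated relocation sequence for one bird."""

    bird_species: str
    steps: list[TrajectoryStep]
    terminal: str = "lost"  # "left_plot" | "lost"

    def __post_init__(self) -> None:
        if self.terminal not in ("left_plot", "lost"):
            raise ValueError("terminal must be 'left_plot' or 'lost'")

    def decision_events(self) -> list[tuple[int, int]]:
        """(origin_cell, dest_cell) pairs; dest = -1 encodes a plot exit."""
        ev = [
            (self.steps[i].cell_id, self.steps[i + 1].cell_id)
            for i in range(len(self.steps) - 1)
        ]
        if self.terminal == "left_plot" and self.steps:
            ev.append((self.steps[-1].cell_id, -1))
        return ev


def leave_probability(edge_distance, a_o: float, b_o: float):
    """Probability of leaving the plot given distance B to the nearest edge."""
    return special.expit(a_o - b_o * np.asarray(edge_distance, dtype=float))


def factor_weight(x, eps: float, eta: float, direction: str = "increasing"):
    """Saturating sigmoid weight tanh((x/eps)**eta), or its complement.

    ``direction='increasing'`` gives 0 at x=0 rising to 1; ``'decreasing'``
    gives 1 at x=0 falling to 0. x must be non-negative.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        logr = np.log(np.maximum(x, 1e-300) / eps)
    t = np.where(x > 0, np.tanh(np.exp(np.clip(eta * logr, -745.0, 50.0))), 0.0)
    if direction == "increasing":
        return t
    if direction == "decreasing":
        return 1.0 - t
    raise ValueError("direction must be 'increasing' or 'decreasing'")


def _cover_covariate(landscape: Landscape) -> np.ndarray:
    return landscape.cover_fraction


def _fruit_covariate(landscape: Landscape) -> np.ndarray:
    # counts span orders of magnitude (FAI classes); compress before the sigmoid
    return np.log1p(landscape.fruit_totals())


class MovementEngine:
    """Cached destination-choice machinery for one species on one landscape.

    Distance and cover weights depend only on geometry and are precomputed;
    fruit weights are recomputed on demand because depletion mutates counts.
    """

    def __init__(self, landscape: Landscape, params: MovementParams):
        self.landscape = landscape
        self.params = params
        dw = factor_weight(
            landscape.distance_matrix, params.eps_d, params.eta_d, "decreasing"
        ) + WEIGHT_FLOOR
        if "C" in params.combo:
            cw = factor_weight(
                _cover_covariate(landscape), params.eps_c, params.eta_c, "increasing"
            ) + WEIGHT_FLOOR
            dw = dw * cw[None, :]
        self.base = dw
        self.p_leave_by_cell = leave_probability(
            landscape.edge_distance, params.a_o, params.b_o
        )

    def fruit_weights(self) -> np.ndarray:
        if "F" not in self.params.combo:
            return np.ones(self.landscape.n_cells)
        return factor_weight(
            _fruit_covariate(self.landscape),
            self.params.eps_f,
            self.params.eta_f,
            "increasing",
        ) + WEIGHT_FLOOR

    def k_row(self, current_cell: int, fruit_w: np.ndarray | None = None) -> np.ndarray:
        w = self.base[current_cell]
        if "F" in self.params.combo:
            if fruit_w is None:
                fruit_w = self.fruit_weights()
            w = w * fruit_w
        total = w.sum()
        if total <= 0:
            raise FloatingPointError("all destination weights are zero")
        return w / total

    def k_matrix(self) -> np.ndarray:
        """Full row-stochastic choice matrix for the current fruit state."""
        w = self.base
        if "F" in self.params.combo:
            w = w * self.fruit_weights()[None, :]
        return w / w.sum(axis=1, keepdims=True)


def destination_distribution(
    landscape: Landscape, current_cell: int, params: MovementParams
) -> DestinationDistribution:
    """Plot-leaving probability and destination distribution from one cell."""
    if not 0 <= current_cell < landscape.n_cells:
        raise IndexError(f"invalid cell {current_cell}")
    engine = MovementEngine(landscape, params)
    return DestinationDistribution(
        p_leave=float(engine.p_leave_by_cell[current_cell]),
        k=engine.k_row(current_cell),
    )


def step_loglik(
    origin_cell: int,
    dest_cell: int,
    landscape: Landscape,
    params: MovementParams,
) -> float:
    """Log-likelihood of one decision event; ``dest_cell = -1`` is an exit.

    A within-plot move contributes log(1 - p_leave) + log(k_dest); an exit
    contributes log(p_leave). A lost bird contributes no terminal term and is
    simply not passed here.
    """
    dist = destination_distribution(landscape, origin_cell, params)
    if dest_cell == -1:
        return float(np.log(dist.p_leave))
    ki = dist.k[dest_cell]
    if ki <= 0:
        return -np.inf
    return float(np.log1p(-dist.p_leave) + np.log(ki))


def _compile_events(trajectories) -> tuple[np.ndarray, np.ndarray]:
    origins, dests = [], []
    for tr in trajectories:
        for o, d in tr.decision_events():
            origins.append(o)
            dests.append(d)
    return np.asarray(origins, dtype=np.int64), np.asarray(dests, dtype=np.int64)


def trajectory_loglik(trajectories, landscape: Landscape, params: MovementParams) -> float:
    """Total log-likelihood of a set of trajectories (vectorized)."""
    origins, dests = _compile_events(trajectories)
    if origins.size == 0:
        raise ValueError("no decision events in trajectories")
    ll = _leave_loglik(landscape, origins, dests, params.a_o, params.b_o)
    moves = dests >= 0
    if moves.any():
        ll += -_dest_negloglik_factory(landscape, origins[moves], dests[moves], params.combo)(
            np.log(_pack_dest(params))
        )
    return float(ll)


def _leave_loglik(landscape, origins, dests, a_o, b_o) -> float:
    p = leave_probability(landscape.edge_distance[origins], a_o, b_o)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    exits = dests == -1
    return float(np.log(p[exits]).sum() + np.log1p(-p[~exits]).sum())


def _pack_dest(params: MovementParams) -> np.ndarray:
    return np.asarray([getattr(params, name) for name in params.free_names()])


def _dest_negloglik_factory(landscape, origins, dests, combo):
    """Build a fast negative log-likelihood over log destination parameters.

    Events are grouped by origin cell into a count matrix so each evaluation
    costs one weight-matrix pass over unique origins only.
    """
    uo, inv = np.unique(origins, return_inverse=True)
    counts = np.zeros((uo.size, landscape.n_cells))
    np.add.at(counts, (inv, dests), 1.0)
    d_uo = landscape.distance_matrix[uo]
    cov_c = _cover_covariate(landscape)
    cov_f = _fruit_covariate(landscape)
    row_tot = counts.sum(axis=1, keepdims=True)

    def nll(log_theta: np.ndarray) -> float:
        th = np.exp(log_theta)
        i = 0
        eps_d, eta_d = th[0], th[1]
        i = 2
        w = factor_weight(d_uo, eps_d, eta_d, "decreasing") + WEIGHT_FLOOR
        if "C" in combo:
            w = w * (factor_weight(cov_c, th[i], th[i + 1], "increasing") + WEIGHT_FLOOR)[None, :]
            i += 2
        if "F" in combo:
            w = w * (factor_weight(cov_f, th[i], th[i + 1], "increasing") + WEIGHT_FLOOR)[None, :]
            i += 2
        logk = np.log(w) - np.log(w.sum(axis=1, keepdims=True))
        return -float((counts * logk).sum())

    return nll


def _fit_leave(landscape, origins, dests):
    """MLE of (a_o, b_o) from exit indicators vs edge distance (logit link)."""
    import statsmodels.api as sm

    B = landscape.edge_distance[origins]
    y = (dests == -1).astype(float)
    if y.sum() == 0 or y.sum() == y.size or np.ptp(B) == 0:
        # no information on the slope; profile out a constant leave rate
        rate = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        a = float(special.logit(rate))
        ll = float(y.sum() * np.log(rate) + (y.size - y.sum()) * np.log1p(-rate))
        return a, 0.0, ll, {"a_o": np.nan, "b_o": np.nan}, False
    X = sm.add_constant(B)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=False, maxiter=200)
    a_o = float(res.params[0])
    b_o = float(-res.params[1])
    se = {"a_o": float(res.bse[0]), "b_o": float(res.bse[1])}
    return a_o, b_o, float(res.llf), se, bool(res.mle_retvals.get("converged", True))


def _numeric_se(nll, log_theta_hat: np.ndarray) -> np.ndarray:
    """Delta-method SEs on the natural scale from a central-difference Hessian."""
    n = log_theta_hat.size
    h = 1e-4
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            f = nll
            H[i, j] = H[j, i] = (
                f(log_theta_hat + ei + ej)
                - f(log_theta_hat + ei - ej)
                - f(log_theta_hat - ei + ej)
                + f(log_theta_hat - ei - ej)
            ) / (4 * h * h)
    try:
        cov_log = np.linalg.inv(H)
        var_log = np.clip(np.diag(cov_log), 0, np.inf)
        # var(theta) ~ theta^2 var(log theta)
        return np.exp(log_theta_hat) * np.sqrt(var_log)
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def aicc(loglik: float, n_params: int, n_events: int) -> float:
    """Small-sample corrected AIC; infinite when n <= p + 1."""
    if n_events - n_params - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2 * n_params + 2 * n_params * (n_params + 1) / (
        n_events - n_params - 1
    )


@dataclass
class MovementFit:
    params: MovementParams
    loglik: float
    aicc: float
    n_events: int
    n_params: int
    se: dict[str, float]
    converged: bool


def _dest_starts(landscape, origins, dests, combo) -> list[np.ndarray]:
    move_d = landscape.distance_matrix[origins, dests]
    pos = move_d[move_d > 0]
    med = float(np.median(pos)) if pos.size else landscape.cell_size
    starts_d = [(med, 1.0), (2 * med, 2.0), (max(landscape.cell_size, med / 2), 0.7)]
    cov_f = _fruit_covariate(landscape)
    f_mid = float(np.median(cov_f[cov_f > 0])) if (cov_f > 0).any() else 1.0
    out = []
    for sd in starts_d:
        theta = list(sd)
        if "C" in combo:
            theta += [0.4, 1.5]
        if "F" in combo:
            theta += [f_mid, 1.5]
        out.append(np.log(np.asarray(theta)))
    # one dispersed extra start for the richer combos
    if combo != "D":
        theta = [med, 1.5] + ([0.15, 3.0] if "C" in combo else []) + (
            [f_mid / 2, 3.0] if "F" in combo else []
        )
        out.append(np.log(np.asarray(theta)))
    return out


def fit_movement(
    trajectories,
    landscape: Landscape,
    combo: str = "D",
    n_starts: int | None = None,
) -> MovementFit:
    """Maximum-likelihood fit of one factor combination to trajectories.

    The likelihood factorizes: the plot-leaving parameters (a_o, b_o) enter
    only the exit/stay terms and are fitted by logistic regression of exit
    indicators on edge distance; the destination parameters enter only the
    within-plot choice terms and are fitted by bounded quasi-Newton search in
    log-parameter space from several starts.
    """
    if combo not in COMBOS:
        raise ValueError(f"combo must be one of {COMBOS}")
    if landscape.n_cells < 2:
        raise ValueError("single-cell landscape carries no destination-choice information")
    origins, dests = _compile_events(trajectories)
    moves = dests >= 0
    if moves.sum() == 0:
        raise ValueError("need at least one within-plot move to fit destination choice")
    n_events = int(origins.size)

    a_o, b_o, ll_leave, se_leave, conv_leave = _fit_leave(landscape, origins, dests)

    nll = _dest_negloglik_factory(landscape, origins[moves], dests[moves], combo)
    starts = _dest_starts(landscape, origins[moves], dests[moves], combo)
    if n_starts is not None:
        starts = starts[:n_starts]
    lo, hi = np.log(1e-4), np.log(1e5)
    eta_lo, eta_hi = np.log(0.05), np.log(20.0)
    k = len(starts[0])
    bounds = [(lo, hi), (eta_lo, eta_hi)] * (k // 2)
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"destination-choice MLE failed for combo {combo}")

    theta = np.exp(best.x)
    names = []
    kwargs = {"a_o": a_o, "b_o": b_o, "combo": combo}
    idx = 0
    for fac in combo.lower():
        kwargs[f"eps_{fac}"] = float(theta[idx])
        kwargs[f"eta_{fac}"] = float(theta[idx + 1])
        names += [f"eps_{fac}", f"eta_{fac}"]
        idx += 2
    params = MovementParams(**kwargs)
    se = dict(se_leave)
    se.update(zip(names, _numeric_se(nll, best.x)))
    ll = ll_leave - float(best.fun)
    p = params.n_params
    return MovementFit(
        params=params,
        loglik=ll,
        aicc=aicc(ll, p, n_events),
        n_events=n_events,
        n_params=p,
        se=se,
        converged=bool(best.success) and conv_leave,
    )


def select_model(
    trajectories, landscape: Landscape, combos=COMBOS
) -> tuple[str, dict[str, MovementFit | str]]:
    """Fit every factor combination and pick the AICc-best one.

    Ties break toward fewer parameters, then lexicographic combo order. Fit
    failures are recorded as error strings and excluded from selection.
    Returns (best_combo, {combo: MovementFit or error message}).
    """
    fits: dict[str, MovementFit | str] = {}
    for combo in combos:
        try:
            fits[combo] = fit_movement(trajectories, landscape, combo)
        except Exception as exc:  # propagate as annotation, keep selecting
            fits[combo] = f"fit failed: {exc}"
    ok = {c: f for c, f in fits.items() if isinstance(f, MovementFit)}
    if not ok:
        raise RuntimeError("all combination fits failed")
    return best_combo(ok), fits


def best_combo(fits: dict[str, MovementFit]) -> str:
    """Minimal-AICc combo; ties go to fewer parameters, then combo order."""
    return min(fits, key=lambda c: (round(fits[c].aicc, 9), fits[c].n_params, c))


def selection_table(fits: dict[str, MovementFit | str], best: str) -> pd.DataFrame:
    rows = []
    ok = {c: f for c, f in fits.items() if isinstance(f, MovementFit)}
    min_aicc = min(f.aicc for f in ok.values())
    for combo, f in fits.items():
        if isinstance(f, MovementFit):
            rows.append(
                {
                    "combo": combo,
                    "loglik": f.loglik,
                    "n_params": f.n_params,
                    "AICc": f.aicc,
                    "dAICc": f.aicc - min_aicc,
                    "chosen": combo == best,
                    "error": "",
                }
            )
        else:
            rows.append(
                {"combo": combo, "loglik": np.nan, "n_params": np.nan,
                 "AICc": np.nan, "dAICc": np.nan, "chosen": False, "error": f}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectory CSV round-trip


def trajectories_to_frame(trajectories, plant_species=None) -> pd.DataFrame:
    if plant_species is None:
        plant_species = sorted({sp for tr in trajectories for st in tr.steps for sp in st.eaten})
    rows = []
    for tid, tr in enumerate(trajectories):
        for i, st in enumerate(tr.steps):
            row = {
                "track_id": tid,
                "species": tr.bird_species,
                "step_index": i,
                "cell_id": st.cell_id,
                "perch_min": st.perch_min,
                "terminal": tr.terminal if i == len(tr.steps) - 1 else "",
            }
            for sp in plant_species:
                row[f"eaten_{sp}"] = st.eaten.get(sp, 0)
            rows.append(row)
    return pd.DataFrame(rows)


def read_trajectories_csv(path) -> list[Trajectory]:
    return trajectories_from_frame(pd.read_csv(path, float_precision="round_trip"))


def trajectories_from_frame(df: pd.DataFrame) -> list[Trajectory]:
    eaten_cols = [c for c in df.columns if c.startswith("eaten_")]
    plants = [c[len("eaten_"):] for c in eaten_cols]
    out = []
    for _, g in df.groupby("track_id", sort=True):
        g = g.sort_values("step_index")
        steps = [
            TrajectoryStep(
                cell_id=int(r.cell_id),
                perch_min=float(r.perch_min),
                eaten={p: int(getattr(r, f"eaten_{p}")) for p in plants
                       if int(getattr(r, f"eaten_{p}")) > 0},
            )
            for r in g.itertuples()
        ]
        terminal = str(g["terminal"].iloc[-1]) or "lost"
        out.append(Trajectory(str(g["species"].iloc[0]), steps, terminal))
    return out
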