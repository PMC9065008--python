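"""Synthetic fossil records with known ground truth.

This module forward-simulates everything the inference side estimates:
time-varying birth-death clade histories (exact, event-driven), Poisson
preservation sampling under the HPP/NHPP/TPP models, stage-style age
binning, coupled clades whose rates respond to another clade's diversity
(the forward counterpart of the diversity-dependent model), and covariate
series standing in for paleotemperature / sea-level curves.

Waiting times are drawn by inversion of the integrated hazard, so the
realized history depends only on the rate functions' *values*, not on how
their breakpoints are represented — two parameterizations that are equal
as functions produce identical histories under matched seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._piecewise import StepFunction, bin_index, merge_step, one_myr_bins
from .errors import ConfigError, DomainError, SimulationExplosionError
from .preservation import PreservationModel, epoch_overlaps
from .series import CovariateSeries, covariate_to_step

__all__ = [
    "SimParams",
    "TrueHistory",
    "simulate_bd",
    "simulate_preservation",
    "bin_ages",
    "simulate_coupled_clades",
    "simulate_covariate",
    "one_myr_bins",
]

logger = logging.getLogger(__name__)


def _as_step(rate) -> StepFunction:
    if isinstance(rate, StepFunction):
        return rate
    return StepFunction.constant(float(rate))


@dataclass(frozen=True)
class SimParams:
    """Parameters of one forward birth-death simulation.

    ``lam``/``mu`` are per-lineage rates per Myr, either scalars or
    :class:`StepFunction` objects of age; ``t_root`` is the clade's root
    age in Ma; ``n0`` the number of founder lineages; ``max_lineages``
    caps runaway radiations.
    """

    t_root: float
    lam: object
    mu: object
    n0: int = 1
    seed: int = 0
    family: str = "CladeA"
    max_lineages: int = 50_000

    def __post_init__(self):
        if self.t_root <= 0:
            raise DomainError("t_root must be > 0")
        if self.n0 < 1:
            raise DomainError("n0 must be >= 1")
        lam, mu = _as_step(self.lam), _as_step(self.mu)
        if np.any(lam.values_desc < 0) or np.any(mu.values_desc < 0):
            raise DomainError("rates must be >= 0")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)


@dataclass(frozen=True)
class TrueHistory:
    """Ground-truth lineage table: per-species origination (Ts) and
    extinction (Te) ages in Ma; extant lineages have Te = 0."""

    lineages: pd.DataFrame  # columns: species, family, ts, te, extant

    def __post_init__(self):
        df = self.lineages
        if len(df) and not ((df["ts"] > df["te"]) & (df["te"] >= 0)).all():
            raise DomainError("every lineage needs ts > te >= 0")
        if len(df) and not (df["extant"] == (df["te"] == 0)).all():
            raise DomainError("extant flag must mirror te == 0")

    def __len__(self):
        return len(self.lineages)

    @property
    def n_extant(self) -> int:
        return int(self.lineages["extant"].sum())

    def to_tsv(self, path) -> None:
        self.lineages.to_csv(path, sep="\t", index=False)


def simulate_bd(params: SimParams, rng=None) -> TrueHistory:
    """Exact event-driven simulation of the birth-death process.

    Runs from ``t_root`` to the present under the piecewise-constant
    rates; per-event waiting times come from inverting the integrated
    total hazard ``N(t) (lam(t) + mu(t))`` across rate segments.
    """
    lam, mu = params.lam, params.mu
    rng = np.random.default_rng(params.seed) if rng is None else rng
    breaks_asc = np.union1d(lam.breaks_desc, mu.breaks_desc)  # ascending
    ts, te = [], []
    alive = []  # indices into ts/te
    for _ in range(params.n0):
        ts.append(params.t_root)
        te.append(np.nan)
        alive.append(len(ts) - 1)

    t = params.t_root
    while t > 0 and alive:
        n = len(alive)
        if n > params.max_lineages:
            raise SimulationExplosionError(
                f"diversity exceeded cap of {params.max_lineages} lineages"
            )
        target = rng.exponential()
        # walk down through rate segments until the integrated hazard
        # reaches the exponential deviate (or the present)
        t_event = None
        seg_top = t
        while True:
            idx = np.searchsorted(breaks_asc, seg_top, side="left")
            seg_bottom = breaks_asc[idx - 1] if idx > 0 else 0.0
            if seg_bottom >= seg_top:  # seg_top sits exactly on a break
                seg_bottom = breaks_asc[idx - 2] if idx > 1 else 0.0
            rate = n * (lam.at(seg_top) + mu.at(seg_top))
            width = seg_top - seg_bottom
            if rate * width >= target:
                t_event = seg_top - target / rate
                break
            target -= rate * width
            seg_top = seg_bottom
            if seg_top <= 0:
                break
        if t_event is None or t_event <= 0:
            break
        t = t_event
        lam_t, mu_t = lam.at(t), mu.at(t)
        if rng.random() < lam_t / (lam_t + mu_t):
            ts.append(t)
            te.append(np.nan)
            alive.append(len(ts) - 1)
        else:
            victim = alive.pop(int(rng.integers(len(alive))))
            te[victim] = t

    te = [0.0 if np.isnan(x) else x for x in te]
    width = max(4, len(str(len(ts))))
    df = pd.DataFrame(
        {
            "species": [
                f"{params.family} sp{str(i + 1).zfill(width)}" for i in range(len(ts))
            ],
            "family": params.family,
            "ts": ts,
            "te": te,
        }
    )
    df["extant"] = df["te"] == 0.0
    return TrueHistory(df)


def simulate_preservation(
    history: TrueHistory,
    model: PreservationModel,
    seed: int,
    n_sites: int = 25,
    environment: str = "reef",
) -> pd.DataFrame:
    """Sample fossil occurrences from lineage lifespans.

    Occurrence times are drawn from the Poisson process the ``model``
    describes over each lineage's ``[Te, Ts]``; lineages with zero draws
    are omitted (unobserved).  True ages are stored with
    ``min_ma == max_ma``; apply :func:`bin_ages` to emulate stage-level
    age uncertainty.  Sites are assigned by random grouping.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ln = history.lineages
    ts_arr = ln["ts"].to_numpy(float)
    te_arr = ln["te"].to_numpy(float)
    for i in range(len(ln)):
        Ts, Te = ts_arr[i], te_arr[i]
        d = Ts - Te
        if model.kind == "HPP":
            kcount = rng.poisson(model.q * d)
            ages = Te + d * rng.random(kcount)
        elif model.kind == "NHPP":
            kcount = rng.poisson(model.q * d)
            u = rng.beta(model.shape, model.shape, size=kcount)
            ages = Ts - u * d
        elif model.kind == "TPP":
            e = np.asarray(model.epochs, dtype=float)
            if Ts > e[0]:
                raise DomainError("lifespan extends beyond oldest TPP epoch")
            overlaps = epoch_overlaps(Ts, Te, e)[0]
            ages_parts = []
            for j, q_j in enumerate(model.q_vec):
                if overlaps[j] <= 0:
                    continue
                lo = max(Te, e[j + 1])
                kcount = rng.poisson(q_j * overlaps[j])
                ages_parts.append(lo + overlaps[j] * rng.random(kcount))
            ages = np.concatenate(ages_parts) if ages_parts else np.empty(0)
        else:  # pragma: no cover
            raise DomainError(f"unknown model kind {model.kind!r}")
        for a in ages:
            rows.append((ln["species"].iat[i], ln["family"].iat[i], a, bool(ln["extant"].iat[i])))

    if not rows:
        cols = ["occurrence_id", "species", "genus", "family", "min_ma", "max_ma",
                "environment", "lng", "lat", "site", "qualifier", "accepted", "extant"]
        return pd.DataFrame(columns=cols)
    species, family, age, extant = map(np.asarray, zip(*rows))
    df = pd.DataFrame(
        {
            "occurrence_id": np.arange(len(rows)),
            "species": species,
            "genus": pd.Series(species).str.split().str[0].to_numpy(),
            "family": family,
            "min_ma": age.astype(float),
            "max_ma": age.astype(float),
            "environment": environment,
            "lng": rng.uniform(-180, 180, len(rows)),
            "lat": rng.uniform(-40, 40, len(rows)),
            "site": rng.integers(0, n_sites, len(rows)),
            "qualifier": "none",
            "accepted": True,
            "extant": extant.astype(bool),
        }
    )
    return df


def bin_ages(table: pd.DataFrame, bounds_desc) -> pd.DataFrame:
    """Replace point ages with their containing time bin's bounds.

    Bins follow the package-wide convention: half-open
    ``(younger, older]`` — an age equal to a boundary belongs to the bin
    whose older edge it is — with the youngest bin closed at 0.
    Requires point-valued ages (``min_ma == max_ma``).
    """
    if len(table) == 0:
        return table.copy()
    if not np.allclose(table["min_ma"], table["max_ma"]):
        raise DomainError("bin_ages requires point-valued ages (min_ma == max_ma)")
    bounds = np.asarray(bounds_desc, dtype=float)
    ages = table["min_ma"].to_numpy(float)
    asc = bounds[::-1]
    outside = (ages < asc[0]) | (ages > asc[-1])
    if outside.any():
        bad = table["occurrence_id"].to_numpy()[outside][0]
        raise DomainError(f"age outside bin span for occurrence_id {bad!r}")
    idx = bin_index(ages, bounds)
    out = table.copy()
    out["min_ma"] = asc[idx]
    out["max_ma"] = asc[idx + 1]
    return out


def _linked_rate(base: StepFunction, cov: StepFunction, gamma: float, link: str,
                 floor: float = 1e-5) -> StepFunction:
    if link == "exponential":
        return merge_step(base, cov, lambda b, x: b * np.exp(gamma * x))
    if link == "linear":
        def op(b, x):
            raw = b * (1.0 + gamma * x)
            clamped = np.maximum(raw, floor)
            if np.any(raw < floor):
                logger.info("linear link clamped %d rate segment(s) at floor %g",
                            int(np.sum(raw < floor)), floor)
            return clamped
        return merge_step(base, cov, op)
    raise ConfigError(f"unknown link: {link!r}")


def simulate_coupled_clades(
    paramsA: SimParams,
    baseB: SimParams,
    gamma_lambda: float,
    gamma_mu: float,
    link: str = "exponential",
    grid_step: float = 0.1,
):
    """Simulate clade A, then clade B with rates driven by A's diversity.

    Clade A evolves independently; its range-through diversity on a
    ``grid_step``-Myr grid, rescaled to [0, 1], becomes the covariate
    ``D_A(t)``.  Clade B's rates are the base rates modified through the
    requested link: ``rate * exp(gamma * D_A(t))`` (exponential) or
    ``rate * (1 + gamma * D_A(t))`` floored at 1e-5 (linear).

    Returns ``(historyA, historyB, D_A)``.
    """
    from .mbd import rescale01
    from .trajectories import range_through

    histA = simulate_bd(paramsA)
    traj = range_through(histA.lineages, step=grid_step)
    series = CovariateSeries(traj.ages, traj.counts.astype(float),
                             label=f"diversity_{paramsA.family}")
    d_a = rescale01(series)
    cov = covariate_to_step(d_a)
    lamB = _linked_rate(baseB.lam, cov, gamma_lambda, link)
    muB = _linked_rate(baseB.mu, cov, gamma_mu, link)
    paramsB = SimParams(
        t_root=baseB.t_root, lam=lamB, mu=muB, n0=baseB.n0, seed=baseB.seed,
        family=baseB.family, max_lineages=baseB.max_lineages,
    )
    histB = simulate_bd(paramsB)
    return histA, histB, d_a


def simulate_covariate(grid_desc, kind: str, params: dict = None, seed: int = 0,
                       label: str = "") -> CovariateSeries:
    """Deterministic-by-seed synthetic covariate series on a given age grid.

    Kinds: ``random_walk`` (Gaussian increments, ``sigma`` per step),
    ``sine`` (``amplitude``, ``period`` Myr, ``mean``, ``phase``),
    ``step`` (``change_age``, ``before``, ``after``).
    """
    grid = np.asarray(grid_desc, dtype=float)
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "random_walk":
        sigma = float(params.get("sigma", 1.0))
        start = float(params.get("start", 0.0))
        steps = rng.normal(0.0, 1.0, grid.size - 1) * sigma
        values = start + np.concatenate([[0.0], np.cumsum(steps)])
    elif kind == "sine":
        amplitude = float(params.get("amplitude", 1.0))
        period = float(params.get("period", 10.0))
        mean = float(params.get("mean", 0.0))
        phase = float(params.get("phase", 0.0))
        values = mean + amplitude * np.sin(2 * np.pi * grid / period + phase)
    elif kind == "step":
        change = float(params.get("change_age", grid[grid.size // 2]))
        before = float(params.get("before", 0.0))
        after = float(params.get("after", 1.0))
        values = np.where(grid > change, before, after)  # older = before
    else:
        raise ConfigError(f"unknown covariate kind: {kind!r}")
    return CovariateSeries(grid, values, label=label or kind)
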