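"""Birth-death inference from fossil lineage lifespans.

The likelihood treats lifespans as completely observed: every
origination time Ts contributes a speciation event at rate lambda(Ts),
every extinction time Te > 0 an extinction event at rate mu(Te), and the
exposure term integrates ``(lambda(t) + mu(t)) * N(t)`` exactly, where
``N(t)`` is the number of lineages alive at age ``t``.  Because the
exposure decomposes as a sum of per-lineage integrals, the conditional
posterior of one lineage's (Ts, Te) given the rates factorizes — the
samplers exploit this.

Two samplers share one reversible-jump engine over piecewise-constant
rate functions:

* :func:`rj_mcmc_rates` — lifespans fixed (the "fixed-times" mode),
  rjMCMC over the number, positions and values of rate shifts;
* :func:`sample_lifespans` — lifespans and preservation parameters
  sampled jointly with the rates, given one age replicate of the
  occurrence record.

Priors: rate and preservation values ~ Gamma(1.1, 1); number of shifts
per rate ~ Poisson(``rj_poisson_mean``); shift times uniform over the
data span; NHPP shape ~ Uniform(1, 50).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from ._piecewise import CENOZOIC_EPOCHS, StepFunction
from .errors import ConfigError, DomainError
from .preservation import epoch_counts, epoch_overlaps, log1mexp

__all__ = [
    "RateSeries",
    "MCMCConfig",
    "RatePosterior",
    "LifespanPosterior",
    "ConvergenceReport",
    "bd_loglik",
    "rj_mcmc_rates",
    "sample_lifespans",
    "summarize_rates",
    "ess",
    "hpd_interval",
]

_GAMMA_SHAPE = 1.1  # weakly informative Gamma(1.1, 1) on rates and q


@dataclass(frozen=True)
class RateSeries:
    """Piecewise-constant speciation and extinction rates.

    Shift times are descending ages (Ma); values are ordered oldest
    segment first, with one more value than shifts.
    """

    shift_times_lambda: np.ndarray
    lambda_values: np.ndarray
    shift_times_mu: np.ndarray
    mu_values: np.ndarray

    def __post_init__(self):
        for name in ("shift_times_lambda", "lambda_values", "shift_times_mu", "mu_values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lambda_values < 0) or np.any(self.mu_values < 0):
            raise DomainError("rates must be >= 0")

    @classmethod
    def constant(cls, lam: float, mu: float) -> "RateSeries":
        empty = np.empty(0)
        return cls(empty, [lam], empty, [mu])

    @property
    def lam(self) -> StepFunction:
        return StepFunction(self.shift_times_lambda, self.lambda_values)

    @property
    def mu(self) -> StepFunction:
        return StepFunction(self.shift_times_mu, self.mu_values)

    def net(self, ages) -> np.ndarray:
        return self.lam.at(ages) - self.mu.at(ages)


@dataclass(frozen=True)
class MCMCConfig:
    """Settings for the MCMC samplers (desk-scale defaults; production
    runs use far longer chains, e.g. tens of millions of generations
    sampled every 25-40 thousand)."""

    n_generations: int = 200_000
    sample_every: int = 100
    burn_in_fraction: float = 0.2
    seed: int = 0
    rj_poisson_mean: float = 1.0
    proposal_scales: dict = field(
        default_factory=lambda: {
            "rate": 0.75,
            "shift_time": 2.0,
            "lifespan": 1.0,
            "q": 0.3,
            "shape": 0.4,
        }
    )
    lifespan_block: int = 10
    ess_threshold: float = 200.0

    def __post_init__(self):
        if self.n_generations < self.sample_every:
            raise ConfigError("n_generations must be >= sample_every")
        if not 0 <= self.burn_in_fraction < 1:
            raise ConfigError("burn_in_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter effective sample sizes with low-ESS flags."""

    ess: dict
    flags: dict
    threshold: float
    zero_variance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not any(self.flags.values())


@dataclass
class RatePosterior:
    """Thinned, burned-in samples from a rate MCMC run."""

    samples: list  # dicts: iteration, rates (RateSeries), q, loglik, logprior
    cfg: MCMCConfig
    convergence: ConvergenceReport = None
    acceptance: dict = None
    n_total_samples: int = 0
    span: float = 0.0  # age span (Ma) the sampler operated on

    def __len__(self):
        return len(self.samples)

    def loglik_trace(self) -> np.ndarray:
        return np.array([s["loglik"] for s in self.samples])

    def n_shifts(self, which: str = "lambda") -> np.ndarray:
        key = "shift_times_lambda" if which == "lambda" else "shift_times_mu"
        return np.array([getattr(s["rates"], key).size for s in self.samples])

    def shift_times(self, which: str = "lambda") -> np.ndarray:
        key = "shift_times_lambda" if which == "lambda" else "shift_times_mu"
        parts = [getattr(s["rates"], key) for s in self.samples]
        return np.concatenate(parts) if parts else np.empty(0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            r = s["rates"]
            rows.append(
                {
                    "iteration": s["iteration"],
                    "logL": s["loglik"],
                    "logPrior": s["logprior"],
                    "n_shifts_lambda": r.shift_times_lambda.size,
                    "n_shifts_mu": r.shift_times_mu.size,
                    "lambda_shifts": ";".join(f"{x:.6g}" for x in r.shift_times_lambda),
                    "lambda_values": ";".join(f"{x:.6g}" for x in r.lambda_values),
                    "mu_shifts": ";".join(f"{x:.6g}" for x in r.shift_times_mu),
                    "mu_values": ";".join(f"{x:.6g}" for x in r.mu_values),
                    "q": ";".join(f"{x:.6g}" for x in np.atleast_1d(s["q"]))
                    if s.get("q") is not None
                    else "",
                }
            )
        return pd.DataFrame(rows)


@dataclass
class LifespanPosterior(RatePosterior):
    """Joint posterior over lifespans, preservation and rates."""

    species: list = None
    extant: np.ndarray = None

    def ts_matrix(self) -> np.ndarray:
        return np.stack([s["ts"] for s in self.samples])

    def te_matrix(self) -> np.ndarray:
        return np.stack([s["te"] for s in self.samples])

    def median_lifespans(self) -> pd.DataFrame:
        ts_med = np.median(self.ts_matrix(), axis=0)
        te_med = np.median(self.te_matrix(), axis=0)
        te_med[self.extant] = 0.0
        return pd.DataFrame(
            {
                "species": self.species,
                "ts": ts_med,
                "te": te_med,
                "extant": self.extant,
            }
        )

    def ts_hpd(self, mass: float = 0.95) -> np.ndarray:
        M = self.ts_matrix()
        return np.stack([hpd_interval(M[:, i], mass) for i in range(M.shape[1])])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _bd_terms(ts, te, lam: StepFunction, mu: StepFunction) -> np.ndarray:
    """Per-lineage birth-death log-likelihood contributions."""
    with np.errstate(divide="ignore"):
        terms = np.log(lam.at(ts))
        extinct = te > 0
        mu_at = np.where(extinct, mu.at(np.where(extinct, te, 1.0)), 1.0)
        terms = terms + np.where(extinct, np.log(mu_at), 0.0)
    exposure = lam.integral(te, ts) + mu.integral(te, ts)
    return terms - exposure


def bd_loglik(lifespans: pd.DataFrame, rates: RateSeries) -> float:
    """Birth-death log-likelihood of completely observed lifespans.

    ``lifespans`` needs columns ``ts``, ``te`` (Ma).  A zero rate at an
    event time yields ``-inf`` (with a warning) rather than an error.
    """
    ts = lifespans["ts"].to_numpy(float)
    te = lifespans["te"].to_numpy(float)
    if np.any(ts <= te):
        raise DomainError("every lifespan needs ts > te")
    terms = _bd_terms(ts, te, rates.lam, rates.mu)
    total = float(np.sum(terms))
    if not np.isfinite(total):
        warnings.warn("zero rate at an event time; log-likelihood is -inf", RuntimeWarning)
        return -np.inf
    return total


def _gamma_logpdf(v):
    return float(np.sum((_GAMMA_SHAPE - 1) * np.log(v) - v)) - v.size * float(
        special.gammaln(_GAMMA_SHAPE)
    )


def _poisson_logpmf(k, mean):
    return k * math.log(mean) - mean - math.lgamma(k + 1)


# ---------------------------------------------------------------------------
# preservation likelihood terms used inside the joint sampler
# ---------------------------------------------------------------------------


class _PresData:
    """Per-lineage occurrence summaries fixed within one age replicate."""

    def __init__(self, occ_by_lineage, model: str, epochs):
        self.model = model
        self.k = np.array([a.size for a in occ_by_lineage], dtype=float)
        self.max_occ = np.array([a.max() for a in occ_by_lineage])
        self.min_occ = np.array([a.min() for a in occ_by_lineage])
        if model == "TPP":
            self.epochs = np.asarray(epochs, dtype=float)
            self.K = np.stack(
                [epoch_counts(a, self.epochs) for a in occ_by_lineage]
            ).astype(float)
        elif model == "NHPP":
            self.flat = np.concatenate(occ_by_lineage)
            lens = [a.size for a in occ_by_lineage]
            self.slices = np.concatenate([[0], np.cumsum(lens)])

    def loglik(self, ts, te, q, shape=None, rows=None):
        """Vector of per-lineage conditioned preservation log-likelihoods.

        ``rows`` restricts the computation to a subset of lineages.
        """
        if rows is None:
            rows = slice(None)
        d = ts - te
        if self.model == "HPP":
            qd = q * d
            return self.k[rows] * np.log(q) - qd - log1mexp(qd)
        if self.model == "TPP":
            D = epoch_overlaps(ts, te, self.epochs)
            totals = D @ q
            return self.K[rows] @ np.log(q) - totals - log1mexp(totals)
        # NHPP
        qd = q * d
        base = self.k[rows] * np.log(q) - qd - log1mexp(qd)
        idx = np.arange(self.k.size)[rows]
        extra = np.empty(idx.size)
        lognorm = 2 * special.gammaln(shape) - special.gammaln(2 * shape)
        for j, i in enumerate(idx):
            ages = self.flat[self.slices[i] : self.slices[i + 1]]
            u = np.clip((ts[j] - ages) / d[j], 1e-12, 1 - 1e-12)
            extra[j] = np.sum((shape - 1) * (np.log(u) + np.log1p(-u))) - ages.size * lognorm
        return base + extra


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _Sampler:
    def __init__(self, ts, te, extant, cfg: MCMCConfig, pres: _PresData = None,
                 ts_cap: float = np.inf):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.ts = np.asarray(ts, dtype=float).copy()
        self.te = np.asarray(te, dtype=float).copy()
        self.extant = np.asarray(extant, dtype=bool)
        self.pres = pres
        self.ts_cap = ts_cap
        self.span = float(self.ts.max()) * 1.05
        self.L = self.ts.size
        if self.L == 0:
            raise DomainError("empty lifespan table")

        crude = self.L / max(float(np.sum(self.ts - self.te)), 1e-6)
        self.lam_breaks = np.empty(0)
        self.lam_vals = np.array([max(crude, 1e-3)])
        self.mu_breaks = np.empty(0)
        self.mu_vals = np.array([max(crude * 0.5, 1e-3)])
        if pres is not None:
            dur = float(np.sum(self.ts - self.te))
            q0 = max(pres.k.sum() / max(dur, 1e-6), 1e-2)
            if pres.model == "TPP":
                self.q = np.full(pres.epochs.size - 1, q0)
            else:
                self.q = q0
            self.shape = 1.5
        else:
            self.q = None
            self.shape = None

        self._refresh_bd()
        self._refresh_pres()
        self.accept = {}
        self.propose = {}

    # -- cached likelihood pieces ------------------------------------------
    def _rates(self):
        return (
            StepFunction(self.lam_breaks, self.lam_vals),
            StepFunction(self.mu_breaks, self.mu_vals),
        )

    def _refresh_bd(self):
        lam, mu = self._rates()
        self.bd_terms = _bd_terms(self.ts, self.te, lam, mu)
        self.bd_total = float(self.bd_terms.sum())

    def _refresh_pres(self):
        if self.pres is None:
            self.pres_terms = np.zeros(self.L)
        else:
            self.pres_terms = self.pres.loglik(self.ts, self.te, self.q, self.shape)
        self.pres_total = float(self.pres_terms.sum())

    def logprior(self):
        lp = _gamma_logpdf(self.lam_vals) + _gamma_logpdf(self.mu_vals)
        nu = self.cfg.rj_poisson_mean
        kl, km = self.lam_breaks.size, self.mu_breaks.size
        lp += _poisson_logpmf(kl, nu) + _poisson_logpmf(km, nu)
        lp -= (kl + km) * math.log(self.span)
        if self.q is not None:
            lp += _gamma_logpdf(np.atleast_1d(self.q))
        return lp

    # -- moves --------------------------------------------------------------
    def _bump(self, move, accepted):
        self.propose[move] = self.propose.get(move, 0) + 1
        if accepted:
            self.accept[move] = self.accept.get(move, 0) + 1

    def move_rate_scale(self):
        rng = self.rng
        which = "lam" if rng.random() < 0.5 else "mu"
        vals = self.lam_vals if which == "lam" else self.mu_vals
        i = int(rng.integers(vals.size))
        old = vals[i]
        new = old * math.exp(rng.uniform(-1, 1) * self.cfg.proposal_scales["rate"])
        vals_new = vals.copy()
        vals_new[i] = new
        lam = StepFunction(self.lam_breaks, vals_new if which == "lam" else self.lam_vals)
        mu = StepFunction(self.mu_breaks, self.mu_vals if which == "lam" else vals_new)
        terms = _bd_terms(self.ts, self.te, lam, mu)
        total = float(terms.sum())
        dprior = (_GAMMA_SHAPE - 1) * (math.log(new) - math.log(old)) - (new - old)
        log_alpha = total - self.bd_total + dprior + (math.log(new) - math.log(old))
        ok = np.isfinite(total) and math.log(rng.random()) < log_alpha
        if ok:
            if which == "lam":
                self.lam_vals = vals_new
            else:
                self.mu_vals = vals_new
            self.bd_terms, self.bd_total = terms, total
        self._bump("rate_scale", ok)

    def _try_rates(self, breaks, vals, which):
        lam = StepFunction(breaks if which == "lam" else self.lam_breaks,
                           vals if which == "lam" else self.lam_vals)
        mu = StepFunction(self.mu_breaks if which == "lam" else breaks,
                          self.mu_vals if which == "lam" else vals)
        terms = _bd_terms(self.ts, self.te, lam, mu)
        return terms, float(terms.sum())

    def move_rj_birth(self):
        rng = self.rng
        which = "lam" if rng.random() < 0.5 else "mu"
        breaks = self.lam_breaks if which == "lam" else self.mu_breaks
        vals = self.lam_vals if which == "lam" else self.mu_vals
        s_new = rng.uniform(0.0, self.span)
        h_new = rng.gamma(_GAMMA_SHAPE, 1.0)
        if s_new in breaks or h_new <= 0:
            self._bump("rj_birth", False)
            return
        j = int(np.sum(breaks > s_new))  # insertion position (descending order)
        breaks_new = np.insert(breaks, j, s_new)
        # keep the older part's value, draw the younger part from the prior
        vals_new = np.insert(vals, j + 1, h_new)
        terms, total = self._try_rates(breaks_new, vals_new, which)
        k = breaks.size
        log_alpha = (total - self.bd_total) + math.log(self.cfg.rj_poisson_mean) - math.log(k + 1)
        ok = np.isfinite(total) and math.log(rng.random()) < log_alpha
        if ok:
            if which == "lam":
                self.lam_breaks, self.lam_vals = breaks_new, vals_new
            else:
                self.mu_breaks, self.mu_vals = breaks_new, vals_new
            self.bd_terms, self.bd_total = terms, total
        self._bump("rj_birth", ok)

    def move_rj_death(self):
        rng = self.rng
        which = "lam" if rng.random() < 0.5 else "mu"
        breaks = self.lam_breaks if which == "lam" else self.mu_breaks
        vals = self.lam_vals if which == "lam" else self.mu_vals
        k = breaks.size
        if k == 0:
            self._bump("rj_death", False)
            return
        j = int(rng.integers(k))
        breaks_new = np.delete(breaks, j)
        vals_new = np.delete(vals, j + 1)  # drop the younger segment's value
        terms, total = self._try_rates(breaks_new, vals_new, which)
        log_alpha = (total - self.bd_total) + math.log(k) - math.log(self.cfg.rj_poisson_mean)
        ok = np.isfinite(total) and math.log(rng.random()) < log_alpha
        if ok:
            if which == "lam":
                self.lam_breaks, self.lam_vals = breaks_new, vals_new
            else:
                self.mu_breaks, self.mu_vals = breaks_new, vals_new
            self.bd_terms, self.bd_total = terms, total
        self._bump("rj_death", ok)

    def move_shift_slide(self):
        rng = self.rng
        which = "lam" if rng.random() < 0.5 else "mu"
        breaks = self.lam_breaks if which == "lam" else self.mu_breaks
        if breaks.size == 0:
            self._bump("shift_move", False)
            return
        j = int(rng.integers(breaks.size))
        new = breaks[j] + rng.uniform(-1, 1) * self.cfg.proposal_scales["shift_time"]
        upper = breaks[j - 1] if j > 0 else self.span
        lower = breaks[j + 1] if j < breaks.size - 1 else 0.0
        if not (lower < new < upper):
            self._bump("shift_move", False)
            return
        breaks_new = breaks.copy()
        breaks_new[j] = new
        vals = self.lam_vals if which == "lam" else self.mu_vals
        terms, total = self._try_rates(breaks_new, vals, which)
        ok = np.isfinite(total) and math.log(rng.random()) < (total - self.bd_total)
        if ok:
            if which == "lam":
                self.lam_breaks = breaks_new
            else:
                self.mu_breaks = breaks_new
            self.bd_terms, self.bd_total = terms, total
        self._bump("shift_move", ok)

    def move_lifespans(self):
        """Block update of (Ts, Te); per-lineage accept/reject is valid
        because the conditional posterior factorizes across lineages."""
        rng = self.rng
        b = min(self.cfg.lifespan_block, self.L)
        rows = rng.choice(self.L, size=b, replace=False)
        w = self.cfg.proposal_scales["lifespan"]
        ts_new = self.ts[rows] + rng.uniform(-w, w, b)
        te_old = self.te[rows]
        te_new = np.where(
            self.extant[rows], 0.0, te_old + rng.uniform(-w, w, b)
        )
        valid = (
            (ts_new >= self.pres.max_occ[rows])
            & (ts_new <= self.ts_cap)
            & (te_new >= 0.0)
            & (te_new <= self.pres.min_occ[rows])
            & (ts_new > te_new)
        )
        if not valid.any():
            self._bump("lifespan", False)
            return
        rows = rows[valid]
        ts_new, te_new = ts_new[valid], te_new[valid]
        lam, mu = self._rates()
        bd_new = _bd_terms(ts_new, te_new, lam, mu)
        pres_new = self.pres.loglik(ts_new, te_new, self.q, self.shape, rows=rows)
        delta = (bd_new - self.bd_terms[rows]) + (pres_new - self.pres_terms[rows])
        acc = np.log(rng.random(rows.size)) < delta
        if acc.any():
            r = rows[acc]
            self.ts[r] = ts_new[acc]
            self.te[r] = te_new[acc]
            self.bd_terms[r] = bd_new[acc]
            self.pres_terms[r] = pres_new[acc]
            self.bd_total = float(self.bd_terms.sum())
            self.pres_total = float(self.pres_terms.sum())
        self._bump("lifespan", bool(acc.any()))

    def move_q(self):
        rng = self.rng
        scale = self.cfg.proposal_scales["q"]
        if self.pres.model == "NHPP" and rng.random() < 0.3:
            old = self.shape
            new = 1.0 + (old - 1.0) * math.exp(rng.uniform(-1, 1) * self.cfg.proposal_scales["shape"])
            if not 1.0 <= new <= 50.0:
                self._bump("q", False)
                return
            terms = self.pres.loglik(self.ts, self.te, self.q, new)
            total = float(terms.sum())
            log_alpha = total - self.pres_total + math.log((new - 1.0) / (old - 1.0))
            ok = math.log(rng.random()) < log_alpha
            if ok:
                self.shape = new
                self.pres_terms, self.pres_total = terms, total
            self._bump("q", ok)
            return
        if np.ndim(self.q) == 0:
            old = self.q
            new = old * math.exp(rng.uniform(-1, 1) * scale)
            q_new = new
        else:
            i = int(rng.integers(len(self.q)))
            old = self.q[i]
            new = old * math.exp(rng.uniform(-1, 1) * scale)
            q_new = np.array(self.q)
            q_new[i] = new
        terms = self.pres.loglik(self.ts, self.te, q_new, self.shape)
        total = float(terms.sum())
        dprior = (_GAMMA_SHAPE - 1) * (math.log(new) - math.log(old)) - (new - old)
        log_alpha = total - self.pres_total + dprior + (math.log(new) - math.log(old))
        ok = np.isfinite(total) and math.log(rng.random()) < log_alpha
        if ok:
            self.q = q_new
            self.pres_terms, self.pres_total = terms, total
        self._bump("q", ok)

    # -- main loop ----------------------------------------------------------
    def run(self, record_lifespans: bool):
        cfg = self.cfg
        if self.pres is None:
            moves = [self.move_rate_scale, self.move_rj_birth, self.move_rj_death,
                     self.move_shift_slide]
            weights = np.array([0.45, 0.2, 0.2, 0.15])
        else:
            moves = [self.move_lifespans, self.move_q, self.move_rate_scale,
                     self.move_rj_birth, self.move_rj_death, self.move_shift_slide]
            weights = np.array([0.5, 0.12, 0.18, 0.08, 0.08, 0.04])
        weights = weights / weights.sum()
        choice = self.rng.choice(len(moves), size=cfg.n_generations, p=weights)
        samples = []
        for it in range(1, cfg.n_generations + 1):
            moves[choice[it - 1]]()
            if it % cfg.sample_every == 0:
                s = {
                    "iteration": it,
                    "rates": RateSeries(
                        self.lam_breaks.copy(), self.lam_vals.copy(),
                        self.mu_breaks.copy(), self.mu_vals.copy(),
                    ),
                    "loglik": self.bd_total + self.pres_total,
                    "logprior": self.logprior(),
                    "q": np.array(self.q) if np.ndim(self.q) else self.q,
                }
                if self.pres is not None and self.pres.model == "NHPP":
                    s["shape"] = self.shape
                if record_lifespans:
                    s["ts"] = self.ts.copy()
                    s["te"] = self.te.copy()
                samples.append(s)
        return samples


def _drop_burnin(samples, frac):
    n_burn = int(math.floor(len(samples) * frac))
    return samples[n_burn:]


def _convergence(samples, cfg, span) -> ConvergenceReport:
    traces = {"logL": np.array([s["loglik"] for s in samples])}
    probe_ages = np.array([0.125, 0.375, 0.625, 0.875]) * span
    lam_mat = np.stack([s["rates"].lam.at(probe_ages) for s in samples])
    mu_mat = np.stack([s["rates"].mu.at(probe_ages) for s in samples])
    for j, a in enumerate(probe_ages):
        traces[f"lambda@{a:.1f}Ma"] = lam_mat[:, j]
        traces[f"mu@{a:.1f}Ma"] = mu_mat[:, j]
    ess_d, flags, zero = {}, {}, {}
    for name, tr in traces.items():
        if tr.size < 10:
            ess_d[name], flags[name], zero[name] = float(tr.size), True, False
            continue
        e, zv = _ess_impl(tr)
        ess_d[name] = e
        zero[name] = zv
        flags[name] = (not zv) and e < cfg.ess_threshold
    return ConvergenceReport(ess=ess_d, flags=flags, threshold=cfg.ess_threshold,
                             zero_variance=zero)


def rj_mcmc_rates(lifespans: pd.DataFrame, cfg: MCMCConfig) -> RatePosterior:
    """Reversible-jump MCMC over piecewise-constant rates, lifespans fixed.

    ``lifespans`` needs columns ``ts``, ``te`` (``extant`` optional).
    Identical seed and input give an identical sample stream.
    """
    if len(lifespans) == 0:
        raise DomainError("empty lifespan table")
    extant = (
        lifespans["extant"].to_numpy(bool)
        if "extant" in lifespans.columns
        else (lifespans["te"].to_numpy(float) == 0)
    )
    s = _Sampler(lifespans["ts"].to_numpy(float), lifespans["te"].to_numpy(float),
                 extant, cfg)
    raw = s.run(record_lifespans=False)
    kept = _drop_burnin(raw, cfg.burn_in_fraction)
    conv = _convergence(kept, cfg, s.span)
    _warn_if_unconverged(conv)
    acc = {m: s.accept.get(m, 0) / max(s.propose.get(m, 1), 1) for m in s.propose}
    return RatePosterior(samples=kept, cfg=cfg, convergence=conv, acceptance=acc,
                         n_total_samples=len(raw), span=s.span)


def sample_lifespans(
    table: pd.DataFrame,
    cfg: MCMCConfig,
    replicate=None,
    model: str = "TPP",
    epochs=CENOZOIC_EPOCHS,
) -> LifespanPosterior:
    """Jointly sample lifespans (Ts, Te), preservation parameters and rates.

    ``table`` is an occurrence table; ``replicate`` optionally supplies
    replicate-resolved point ages (an :class:`AgeReplicate`), otherwise
    ``min_ma`` must equal ``max_ma``.  ``model`` picks the preservation
    process (``"HPP"``, ``"NHPP"``, ``"TPP"``).
    """
    if replicate is not None:
        ages = table["occurrence_id"].map(replicate.ages).to_numpy(float)
    else:
        if not np.allclose(table["min_ma"], table["max_ma"]):
            raise DomainError("need point ages (pass an AgeReplicate)")
        ages = table["min_ma"].to_numpy(float)
    df = pd.DataFrame({"species": table["species"].to_numpy(), "age": ages,
                       "extant": table["extant"].to_numpy(bool)})
    grouped = df.groupby("species", sort=True)
    species = list(grouped.groups)
    occ_by_lineage = [g["age"].to_numpy(float) for _, g in grouped]
    extant = np.array([bool(g["extant"].any()) for _, g in grouped])
    if extant.all() and max(a.size for a in occ_by_lineage) == 1:
        warnings.warn("all lineages extant with a single occurrence each; "
                      "the data carry very little information", RuntimeWarning)
    if model == "TPP":
        e = np.asarray(epochs, dtype=float)
        top = max(float(e[0]), float(ages.max()) * 1.1 + 1.0)
        e = np.concatenate([[top], e[e < top]]) if top > e[0] else e
        epochs = e
    pres = _PresData(occ_by_lineage, model, epochs)
    ts0 = pres.max_occ + 0.1
    te0 = np.where(extant, 0.0, np.maximum(pres.min_occ - 0.1, 0.0))
    te0 = np.minimum(te0, pres.min_occ)
    ts_cap = float(np.asarray(epochs, dtype=float)[0]) if model == "TPP" else np.inf
    s = _Sampler(ts0, te0, extant, cfg, pres=pres, ts_cap=ts_cap)
    raw = s.run(record_lifespans=True)
    kept = _drop_burnin(raw, cfg.burn_in_fraction)
    conv = _convergence(kept, cfg, s.span)
    _warn_if_unconverged(conv)
    acc = {m: s.accept.get(m, 0) / max(s.propose.get(m, 1), 1) for m in s.propose}
    return LifespanPosterior(samples=kept, cfg=cfg, convergence=conv, acceptance=acc,
                             n_total_samples=len(raw), span=s.span,
                             species=species, extant=extant)


def _warn_if_unconverged(conv: ConvergenceReport):
    low = [k for k, v in conv.flags.items() if v]
    if low:
        warnings.warn(f"low effective sample size (<{conv.threshold:g}) for: "
                      f"{', '.join(low)}", RuntimeWarning)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def hpd_interval(x, mass: float = 0.95) -> np.ndarray:
    """Shortest interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    m = max(int(math.ceil(mass * n)), 1)
    if m >= n:
        return np.array([x[0], x[-1]])
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return np.array([x[j], x[j + m - 1]])


def ess(samples) -> float:
    """Effective sample size via the initial-positive-sequence rule.

    ``ESS = n / (1 + 2 * sum of autocorrelations)``, truncating the sum
    at the first adjacent pair of autocorrelations with a negative sum.
    Constant sequences report ``ESS = n`` (zero-variance convention).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise DomainError("need at least 10 samples")
    return _ess_impl(x)[0]


def _ess_impl(x):
    n = x.size
    if np.all(x == x[0]):
        return float(n), True
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return float(n), True
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    total = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        total += pair
        t += 2
    return float(n / (1 + 2 * total)), False


def summarize_rates(posterior: RatePosterior, step: float = 0.1, grid=None,
                    mass: float = 0.95) -> pd.DataFrame:
    """Per-grid-age median and HPD of lambda, mu, and net rate r = lambda - mu.

    The grid defaults to a descending ``step``-Myr grid over the span
    seen by the sampler.
    """
    if len(posterior) == 0:
        raise DomainError("empty posterior")
    if grid is None:
        span = posterior.span or 10.0
        n_steps = int(round(span / step))
        grid = np.linspace(span, 0.0, max(n_steps, 1) + 1)
    grid = np.asarray(grid, dtype=float)
    lam = np.stack([s["rates"].lam.at(grid) for s in posterior.samples])
    mu = np.stack([s["rates"].mu.at(grid) for s in posterior.samples])
    r = lam - mu
    out = {"age": grid}
    for name, M in (("lambda", lam), ("mu", mu), ("r", r)):
        out[f"{name}_med"] = np.median(M, axis=0)
        hpds = np.stack([hpd_interval(M[:, j], mass) for j in range(grid.size)])
        out[f"{name}_lo"] = hpds[:, 0]
        out[f"{name}_hi"] = hpds[:, 1]
    return pd.DataFrame(out)
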