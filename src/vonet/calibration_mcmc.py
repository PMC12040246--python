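"""Two-stage Metropolis–Hastings/Gibbs calibration of network input weights.

The baseline weights of the hormone input reactions, a shared background
weight, and the strain-map gain Cmyo are calibrated against mean ± SD
observations of phosphoprotein activities and cell size during volume
overload. Each likelihood evaluation simulates a full VO time course with
freshly sampled stimulus curves (so the chain targets the curve-averaged
likelihood), compares predicted fold changes of node activities against the
observed fold changes under a normal error model, and adds a soft
preference for a baseline cell-size activity near 0.5 — the most responsive
region of the sigmoidal growth output.

Stage 1 samples under a uniform prior inside the physiologically plausible
bounds; its posterior, represented by a Gaussian kernel density, becomes the
prior for stage 2. Updates are one-parameter-at-a-time (Gibbs sweeps) with
bounded Gaussian proposals and Metropolis acceptance. After convergence,
physiologically implausible solutions — growth reversal below baseline and
runaway growth that never settles — are filtered from the ensemble. The
baseline strain weight is not sampled but scanned over a fixed grid,
choosing the value that maximizes mean likelihood while minimizing the
fraction of implausible solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .forward_validation import VOSystem
from .network_core import IntegrationError, SteadyStateError, integrate

__all__ = [
    "DEFAULT_BOUNDS",
    "PriorSpec",
    "StageConfig",
    "PosteriorEnsemble",
    "CalibrationProblem",
    "log_likelihood",
    "mh_gibbs_step",
    "run_mcmc",
    "filter_unlikely",
    "scan_wmyostrain",
    "posterior_summary",
]

#: Physiologically plausible bounds for the VO input weights: the ranges
#: over which the cell-size output is sensitive to each hormonal input,
#: plus a wide, weakly informative range for the strain-map gain.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "w_angii0": (0.01, 0.15),
    "w_ne0": (0.01, 0.24),
    "w_et10": (0.01, 0.17),
    "w_background": (0.01, 0.40),
    "cmyo": (0.5, 20.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter uniform bounds plus the fixed baseline strain weight."""

    bounds: Mapping[str, tuple[float, float]]
    w_myostrain0: float = 0.06

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"empty bounds for {name!r}: ({lo}, {hi})")
        if not 0.0 < self.w_myostrain0 < 0.2:
            raise ValueError(
                f"w_myostrain0 must lie in the (0, 0.2) working range, got {self.w_myostrain0}"
            )

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def contains(self, params: Mapping[str, float]) -> bool:
        return all(lo <= params[n] <= hi for n, (lo, hi) in self.bounds.items())

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        return {n: float(rng.uniform(lo, hi)) for n, (lo, hi) in self.bounds.items()}


@dataclass(frozen=True)
class StageConfig:
    """Chain lengths and proposal scales for the two MCMC stages."""

    n_iter_stage1: int = 10_000
    n_iter_stage2: int = 20_000
    proposal_frac: float = 0.05  # proposal SD as a fraction of each prior range
    check_every: int = 5_000
    converge_rtol: float = 0.05
    #: Re-evaluate the current state's log-target at the top of every sweep.
    #: The VO likelihood is stochastic (fresh stimulus-curve draws per
    #: evaluation); without the refresh a chain freezes on states that drew
    #: unusually favorable curves. A deterministic target is unaffected.
    refresh_loglik: bool = True


@dataclass
class PosteriorEnsemble:
    """Ordered MCMC samples (one row per saved sweep) with log-likelihoods."""

    samples: pd.DataFrame
    stage: int
    filtered: bool = False
    diagnostics: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def param_names(self) -> list[str]:
        return [c for c in self.samples.columns if c != "loglik"]

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

@dataclass
class CalibrationProblem:
    """Bind a VO-driven system to calibration data.

    ``data`` rows carry (variable, t_over_tau, mean, sd): the observed fold
    change of one node's activity relative to baseline at one normalized
    time. Every dataset row enters the likelihood with equal weight.
    """

    system: VOSystem
    data: pd.DataFrame
    sigma_baseline: float = 0.1

    def __post_init__(self):
        for col in ("variable", "t_over_tau", "mean", "sd"):
            if col not in self.data.columns:
                raise ValueError(f"calibration data missing column {col!r}")
        unknown = set(self.data["variable"]) - set(self.system.model.node_ids)
        if unknown:
            raise ValueError(f"calibration data references unknown node(s): {sorted(unknown)}")

    def log_likelihood(self, params: Mapping[str, float], rng: np.random.Generator) -> float:
        return log_likelihood(params, self, rng)


def log_likelihood(
    params: Mapping[str, float],
    problem: CalibrationProblem,
    rng: np.random.Generator,
) -> float:
    """Gaussian log-likelihood of one parameter set under one curve draw.

    Simulates VO from the baseline steady state, evaluates the predicted
    fold change of each observed node at each dataset's time, and sums
    normal log-densities; adds the baseline cell-size penalty
    ``-(y_base - 0.5)^2 / (2 sigma_b^2)``. Returns ``-inf`` if the model
    cannot be integrated for these parameters (the sample is rejected).
    """
    sys = problem.system
    data = problem.data
    try:
        y_base = sys.baseline_state(params)
        hormones, strain = sys.draw_vo_drives(params, rng)
        pert = sys.vo_perturbation(params, hormones, strain)
        t_data = np.unique(data["t_over_tau"].to_numpy(dtype=float))
        t_eval = np.unique(np.concatenate([[0.0], t_data, [sys.horizon]]))
        traj = integrate(sys.model, pert, t_span=(0.0, sys.horizon), t_eval=t_eval,
                         y_init=y_base, rtol=sys.rtol, atol=sys.atol)
    except (IntegrationError, SteadyStateError, RuntimeError):
        return -np.inf

    ll = 0.0
    for var, grp in data.groupby("variable"):
        idx = sys.model.index(var)
        base = y_base[idx]
        if base <= 0:
            return -np.inf
        pred = np.interp(grp["t_over_tau"].to_numpy(dtype=float), traj.times,
                         traj.activities[:, idx]) / base
        mean = grp["mean"].to_numpy(dtype=float)
        sd = grp["sd"].to_numpy(dtype=float)
        ll += float(np.sum(-0.5 * ((pred - mean) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))))
    g_base = y_base[sys.model.index(sys.growth_node)]
    ll += -((g_base - 0.5) ** 2) / (2.0 * problem.sigma_baseline**2)
    return ll


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def mh_gibbs_step(
    current: dict[str, float],
    current_logp: float,
    log_target: Callable[[Mapping[str, float]], float],
    bounds: Mapping[str, tuple[float, float]],
    scales: Mapping[str, float],
    rng: np.random.Generator,
    jump_prob: float = 0.1,
) -> tuple[dict[str, float], float, int]:
    """One Gibbs sweep: update each parameter in turn by Metropolis.

    Proposals are Gaussian steps mixed with occasional uniform draws over
    the parameter's bounds (probability ``jump_prob``) — the uniform
    independence component is symmetric, keeps the Metropolis rule exact,
    and lets the chain traverse directions where the likelihood is nearly
    flat. A proposal outside the prior bounds is rejected outright. A more
    likely proposal is always accepted; a less likely one is accepted with
    probability exp(delta log-target). Returns the new state, its
    log-target, and the number of accepted updates.
    """
    state = dict(current)
    logp = current_logp
    n_accept = 0
    for name in bounds:
        lo, hi = bounds[name]
        if rng.uniform() < jump_prob:
            prop = float(rng.uniform(lo, hi))
        else:
            prop = state[name] + rng.normal(0.0, scales[name])
        if not lo <= prop <= hi:
            continue
        cand = dict(state)
        cand[name] = prop
        cand_logp = log_target(cand)
        if np.log(rng.uniform()) < cand_logp - logp:
            state, logp = cand, cand_logp
            n_accept += 1
    return state, logp, n_accept


def _run_chain(
    log_target: Callable[[Mapping[str, float]], float],
    init: dict[str, float],
    bounds: Mapping[str, tuple[float, float]],
    n_iter: int,
    proposal_frac: float,
    check_every: int,
    converge_rtol: float,
    rng: np.random.Generator,
    refresh_loglik: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    scales = {n: proposal_frac * (hi - lo) for n, (lo, hi) in bounds.items()}
    state = dict(init)
    logp = log_target(state)
    rows = []
    n_accept_total = 0
    diagnostics = []
    prev_block_means = None
    for it in range(n_iter):
        if refresh_loglik and it:
            logp = log_target(state)
        state, logp, n_acc = mh_gibbs_step(state, logp, log_target, bounds, scales, rng)
        n_accept_total += n_acc
        rows.append({**state, "loglik": logp})
        if check_every and (it + 1) % check_every == 0:
            block = pd.DataFrame(rows[-check_every:])
            means = block.drop(columns="loglik").mean()
            entry = {
                "iteration": it + 1,
                "block_means": means.to_dict(),
                "mean_loglik": float(block["loglik"].mean()),
                "acceptance": n_accept_total / ((it + 1) * len(bounds)),
            }
            if prev_block_means is not None:
                rel = ((means - prev_block_means).abs()
                       / prev_block_means.abs().clip(lower=1e-12)).max()
                entry["max_rel_change"] = float(rel)
                entry["converged"] = bool(rel < converge_rtol)
            diagnostics.append(entry)
            prev_block_means = means
    df = pd.DataFrame(rows)
    if df["loglik"].replace(-np.inf, np.nan).isna().all():
        raise RuntimeError("chain never found a finite-likelihood state")
    return df, diagnostics


def run_mcmc(
    loglik: Callable[[Mapping[str, float], np.random.Generator], float],
    prior: PriorSpec,
    config: StageConfig,
    rng: np.random.Generator,
) -> PosteriorEnsemble:
    """Two-stage MCMC: uniform-prior stage, then posterior-as-prior stage.

    Stage 1 targets ``loglik`` under a uniform prior inside the bounds.
    Stage 2 re-runs the chain with the stage-1 posterior as its prior,
    represented by a Gaussian kernel density (Silverman bandwidth) over the
    stage-1 samples, and returns the stage-2 ensemble with convergence
    diagnostics recorded every ``check_every`` iterations.
    """
    names = prior.names

    def target1(p: Mapping[str, float]) -> float:
        return loglik(p, rng)

    init = prior.sample(rng)
    df1, diag1 = _run_chain(
        target1, init, prior.bounds, config.n_iter_stage1,
        config.proposal_frac, config.check_every, config.converge_rtol, rng,
        refresh_loglik=config.refresh_loglik,
    )

    mat = df1[names].to_numpy(dtype=float).T
    if np.linalg.matrix_rank(np.cov(mat)) < len(names):
        # degenerate stage-1 spread (e.g. flat likelihood in a corner):
        # jitter to keep the KDE well-defined
        mat = mat + rng.normal(0.0, 1e-6, size=mat.shape)
    kde = gaussian_kde(mat, bw_method="silverman")

    def target2(p: Mapping[str, float]) -> float:
        lp = float(kde.logpdf(np.array([[p[n]] for n in names]))[0])
        if not np.isfinite(lp):
            return -np.inf
        return loglik(p, rng) + lp

    start_idx = int(rng.integers(0, len(df1)))
    init2 = {n: float(df1[n].iloc[start_idx]) for n in names}
    df2, diag2 = _run_chain(
        target2, init2, prior.bounds, config.n_iter_stage2,
        config.proposal_frac, config.check_every, config.converge_rtol, rng,
        refresh_loglik=config.refresh_loglik,
    )
    return PosteriorEnsemble(samples=df2, stage=2, diagnostics=diag1 + diag2)


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def filter_unlikely(
    ensemble: PosteriorEnsemble,
    growth_curve: Callable[[Mapping[str, float], np.random.Generator], tuple[np.ndarray, np.ndarray, float]],
    rng: np.random.Generator,
    delta_reversal: float = 0.01,
    delta_runaway: float = 0.005,
) -> tuple[PosteriorEnsemble, dict[str, int]]:
    """Remove growth-reversal and runaway-growth solutions from an ensemble.

    ``growth_curve(params, rng)`` must return ``(times, cellarea, baseline)``
    for one VO run. A sample is a *reversal* if cell size falls below
    baseline by more than ``delta_reversal`` (fraction of baseline) at any
    time, and a *runaway* if the terminal slope exceeds ``delta_runaway``
    (fraction of baseline per unit t/tau) — growth that has not settled by
    the horizon. Monotone, settled trajectories are always kept.
    """
    keep, counts = [], {"kept": 0, "reversal": 0, "runaway": 0, "failed": 0}
    for i in range(len(ensemble.samples)):
        params = {k: float(v) for k, v in ensemble.samples.iloc[i].items() if k != "loglik"}
        try:
            t, y, base = growth_curve(params, rng)
        except (IntegrationError, SteadyStateError, RuntimeError):
            counts["failed"] += 1
            continue
        if np.min(y) < base * (1.0 - delta_reversal):
            counts["reversal"] += 1
            continue
        slope = (y[-1] - y[-2]) / (t[-1] - t[-2])
        if slope > delta_runaway * base:
            counts["runaway"] += 1
            continue
        counts["kept"] += 1
        keep.append(i)
    if not keep:
        raise RuntimeError(f"filtering removed every sample: {counts}")
    return (
        PosteriorEnsemble(
            samples=ensemble.samples.iloc[keep].reset_index(drop=True),
            stage=ensemble.stage,
            filtered=True,
            diagnostics=ensemble.diagnostics,
        ),
        counts,
    )


def vo_growth_curve_fn(
    problem: CalibrationProblem, n_times: int = 41
) -> Callable[[Mapping[str, float], np.random.Generator], tuple[np.ndarray, np.ndarray, float]]:
    """Build the ``growth_curve`` callable for :func:`filter_unlikely`."""
    sys = problem.system

    def fn(params, rng):
        y_base = sys.baseline_state(params)
        hormones, strain = sys.draw_vo_drives(params, rng)
        pert = sys.vo_perturbation(params, hormones, strain)
        t_eval = np.linspace(0.0, sys.horizon, n_times)
        traj = integrate(sys.model, pert, t_span=(0.0, sys.horizon), t_eval=t_eval,
                         y_init=y_base, rtol=sys.rtol, atol=sys.atol)
        gidx = sys.model.index(sys.growth_node)
        return traj.times, traj.activities[:, gidx], float(y_base[gidx])

    return fn


def scan_wmyostrain(
    values: Sequence[float],
    problem_factory: Callable[[float], CalibrationProblem],
    prior_bounds: Mapping[str, tuple[float, float]],
    config: StageConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Repeat the calibration over a grid of fixed baseline strain weights.

    Returns one row per scanned value with the ensemble's mean
    log-likelihood and the fraction of implausible (reversal/runaway)
    solutions, the two quantities used to choose the operating value.
    """
    rows = []
    for w0 in values:
        problem = problem_factory(w0)
        prior = PriorSpec(bounds=prior_bounds, w_myostrain0=w0)
        ens = run_mcmc(problem.log_likelihood, prior, config, rng)
        finite = ens.samples["loglik"].replace(-np.inf, np.nan).dropna()
        try:
            _, counts = filter_unlikely(ens, vo_growth_curve_fn(problem), rng)
            n_bad = counts["reversal"] + counts["runaway"]
            unlikely = n_bad / max(counts["kept"] + n_bad, 1)
        except RuntimeError:
            unlikely = 1.0
        rows.append(
            {"w_myostrain0": w0, "mean_loglik": float(finite.mean()), "unlikely_fraction": unlikely}
        )
    return pd.DataFrame(rows)


def posterior_summary(ensemble: PosteriorEnsemble) -> dict:
    """Per-parameter means and SDs plus the pairwise Pearson correlation matrix.

    Degenerate parameters (zero spread) get SD 0 and missing (NaN)
    correlation entries. Invariant to sample order.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    params = ensemble.samples[ensemble.param_names]
    means = params.mean()
    sds = params.std(ddof=1) if len(params) > 1 else params.std(ddof=0)
    pcc = params.corr()  # pandas yields NaN for zero-variance columns
    return {
        "mean": means.to_dict(),
        "sd": sds.fillna(0.0).to_dict(),
        "pcc": pcc,
        "n": len(params),
    }
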