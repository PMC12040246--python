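"""Monte Carlo scenario engine for volume overload, infusions and blockers.

A :class:`VOSystem` bundles a signaling network with the calibrated pieces
needed to drive it: stimulus curve families for circulating hormones, the
mass/volume fold-change families that determine end-diastolic strain, the
strain-to-input mapping, and the naming map from posterior parameters to
input reactions. Scenarios are simulated by ensembles of forward runs, one
per posterior draw:

* untreated volume overload — all hormonal inputs and the strain input
  follow sampled time-varying fold-change curves;
* agonist infusion — one input reaction raised to saturation (w = 1) or by
  a sampled concentration fold change, everything else at baseline;
* receptor blockade — the target receptor node's maximum activity forced to
  zero, alone or combined with either of the above.

Growth is quantified as normalized growth of the cell-size output,
``(final - initial) / initial``, and a drug effect as the paired difference
between with-drug and without-drug arms normalized to the initial size.
Ensemble outcomes are summarized by central CI50/CI90 percentile intervals,
a 75%-majority increase/decrease/mixed classification, coverage counts of
experimental means, and Pearson-correlation sensitivity to the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry_strain import MyoStrainMap, StrainCurve, lagrangian_strain, strain_trajectory
from .input_curves import CurveFamily, sample_curve
from .network_core import (
    IntegrationError,
    NetworkModel,
    Perturbation,
    SteadyStateError,
    fixed_point_state,
    integrate,
    steady_state,
)

__all__ = [
    "VOSystem",
    "Dose",
    "ScenarioSpec",
    "EnsembleResult",
    "simulate_scenario",
    "simulate_paired",
    "normalized_growth",
    "normalized_drug_effect",
    "confidence_intervals",
    "classify_change",
    "coverage_counts",
    "sensitivity_matrix",
]


# ---------------------------------------------------------------------------
# System wiring
# ---------------------------------------------------------------------------

@dataclass
class VOSystem:
    """A network plus everything needed to drive it through VO scenarios.

    ``input_map`` associates hormone input node ids with posterior parameter
    names (their baseline weights); ``background_inputs`` are input nodes
    that share the single background weight parameter. ``strain_node`` is
    the mechanical input driven through the exponential strain map with
    fixed baseline weight ``w_myostrain0``. The curve set must contain one
    family per hormone input plus ``"LVM"`` and ``"VED"`` fold-change
    families for the strain calculation.
    """

    model: NetworkModel
    curves: Mapping[str, CurveFamily]
    input_map: Mapping[str, str]  # input node id -> parameter name
    background_inputs: Sequence[str] = ()
    background_param: str = "w_background"
    strain_node: str | None = None
    w_myostrain0: float = 0.06
    cmyo_param: str = "cmyo"
    lambda_ed0_mean: float = 1.12
    lambda_ed0_sd: float = 0.03
    growth_node: str = "CellArea"
    outputs: Sequence[str] = ()
    horizon: float = 5.0
    #: ODE tolerances for ensemble/likelihood runs; looser than the solver
    #: defaults because the resulting 1e-5-level activity errors are far
    #: below the observational SDs these runs are compared against.
    rtol: float = 1e-4
    atol: float = 1e-6
    baseline_method: str = "fixed_point"  # or "integrate"

    def __post_init__(self):
        for node in list(self.input_map) + list(self.background_inputs):
            self.model.input_reaction_id(node)  # raises if absent/ambiguous
        missing = [n for n in self.input_map if n not in self.curves]
        if missing:
            raise ValueError(f"no curve family for hormone input(s): {missing}")
        if self.strain_node is not None:
            self.model.input_reaction_id(self.strain_node)
            for key in ("LVM", "VED"):
                if key not in self.curves:
                    raise ValueError(f"strain input requires a {key!r} curve family")

    # -- baseline ----------------------------------------------------------
    def baseline_weights(self, params: Mapping[str, float]) -> dict[str, float]:
        """Constant input-reaction weights implied by one parameter draw."""
        w = {self.model.input_reaction_id(node): float(params[p])
             for node, p in self.input_map.items()}
        for node in self.background_inputs:
            w[self.model.input_reaction_id(node)] = float(params[self.background_param])
        if self.strain_node is not None:
            w[self.model.input_reaction_id(self.strain_node)] = self.w_myostrain0
        return w

    def baseline_state(self, params: Mapping[str, float]) -> np.ndarray:
        """Pre-overload steady state under the baseline weights."""
        pert = Perturbation(weight_overrides=self.baseline_weights(params))
        if self.baseline_method == "fixed_point":
            try:
                return fixed_point_state(self.model, pert)
            except SteadyStateError:
                pass  # fall back to time integration below
        return steady_state(self.model, pert)

    # -- VO drives ---------------------------------------------------------
    def draw_vo_drives(
        self, params: Mapping[str, float], rng: np.random.Generator
    ) -> tuple[dict[str, Callable], StrainCurve | None]:
        """Sample one set of hormone fold-change curves and a strain curve."""
        hormones = {node: sample_curve(self.curves[node], rng) for node in self.input_map}
        strain = None
        if self.strain_node is not None:
            fc_lvm = sample_curve(self.curves["LVM"], rng)
            fc_ved = sample_curve(self.curves["VED"], rng)
            # baseline end-diastolic stretch must exceed 1 for the strain
            # map to have a positive anchor; truncate the normal draw there
            lam0 = 1.005
            for _ in range(100):
                draw = rng.normal(self.lambda_ed0_mean, self.lambda_ed0_sd)
                if draw > 1.005:
                    lam0 = draw
                    break
            grid = np.linspace(0.0, self.horizon, 201)
            strain = strain_trajectory(grid, fc_ved, fc_lvm, lam0)
        return hormones, strain

    def vo_perturbation(
        self,
        params: Mapping[str, float],
        hormone_curves: Mapping[str, Callable],
        strain_curve: StrainCurve | None,
        knockouts: frozenset[str] = frozenset(),
    ) -> Perturbation:
        """Time-varying perturbation for a volume-overload run.

        Each hormone input weight is its baseline weight times the sampled
        concentration fold change; the strain input follows the exponential
        map of the sampled strain trajectory.
        """
        overrides: dict[str, float | Callable] = {}
        for node, pname in self.input_map.items():
            w0 = float(params[pname])
            fc = hormone_curves[node]
            overrides[self.model.input_reaction_id(node)] = (
                lambda t, _w0=w0, _fc=fc: _w0 * float(_fc(t))
            )
        for node in self.background_inputs:
            overrides[self.model.input_reaction_id(node)] = float(params[self.background_param])
        if self.strain_node is not None:
            if strain_curve is None:
                raise ValueError("VO scenario requires a strain curve")
            eps_f0 = float(strain_curve.eps_f[0])
            smap = MyoStrainMap.solve(float(params[self.cmyo_param]), self.w_myostrain0, eps_f0)
            overrides[self.model.input_reaction_id(self.strain_node)] = (
                lambda t, _m=smap, _s=strain_curve: max(float(_m(_s(t))), 0.0)
            )
        return Perturbation(weight_overrides=overrides, knockouts=knockouts)


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dose:
    """Agonist dose: saturation (w = 1) or a concentration fold-change PDF.

    A fold-change dose multiplies the agonist's baseline input weight by a
    draw from Normal(fold_mean, fold_sd) truncated at fold >= 1; with
    ``fold_sd = 0`` the fold is fixed.
    """

    saturation: bool = False
    fold_mean: float | None = None
    fold_sd: float = 0.0

    def draw_fold(self, rng: np.random.Generator, max_tries: int = 100) -> float:
        if self.saturation:
            raise ValueError("saturation dose has no fold change")
        if self.fold_mean is None:
            raise ValueError("non-saturation dose requires fold_mean")
        if self.fold_sd == 0.0:
            return max(self.fold_mean, 1.0)
        for _ in range(max_tries):
            f = rng.normal(self.fold_mean, self.fold_sd)
            if f >= 1.0:
                return f
        raise RuntimeError("could not draw a fold change >= 1")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated experiment: VO and/or infusion, optionally with a blocker."""

    kind: str  # {"vo", "infusion", "infusion+blocker", "vo+blocker", "baseline"}
    agonist: str | None = None
    dose: Dose | None = None
    blocker: str | None = None
    horizon: float = 5.0
    n_iter: int = 1000

    KINDS = ("vo", "infusion", "infusion+blocker", "vo+blocker", "baseline")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        if "infusion" in self.kind and (self.agonist is None or self.dose is None):
            raise ValueError("infusion scenarios require an agonist and a dose")
        if "blocker" in self.kind and self.blocker is None:
            raise ValueError("blocker scenarios require a blocker node id")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


# ---------------------------------------------------------------------------
# Ensemble simulation
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Per-iteration trajectories and terminal activities of one ensemble."""

    times: np.ndarray
    growth_curves: np.ndarray       # (n_ok, n_times) normalized growth vs time
    growth: np.ndarray              # (n_ok,) terminal normalized growth
    terminal: pd.DataFrame          # terminal activity per output node
    baseline: pd.DataFrame          # baseline activity per output node
    draw_index: np.ndarray          # posterior row used per iteration
    n_failed: int = 0

    def deltas(self, output: str) -> np.ndarray:
        return self.terminal[output].to_numpy() - self.baseline[output].to_numpy()

    def summary(self) -> dict:
        ci = confidence_intervals(self.growth)
        return {
            "mean_growth": float(np.mean(self.growth)),
            "ci50": ci[50],
            "ci90": ci[90],
            "n": int(self.growth.size),
            "n_failed": self.n_failed,
        }

    def classification(self, threshold: float = 0.75) -> dict[str, str]:
        return {
            out: classify_change(self.deltas(out), threshold=threshold)
            for out in self.terminal.columns
        }


def _scenario_perturbation(
    system: VOSystem,
    spec: ScenarioSpec,
    params: Mapping[str, float],
    rng: np.random.Generator,
) -> Perturbation:
    knock = frozenset({spec.blocker}) if spec.blocker else frozenset()
    if spec.kind.startswith("vo"):
        hormones, strain = system.draw_vo_drives(params, rng)
        return system.vo_perturbation(params, hormones, strain, knockouts=knock)
    overrides = dict(system.baseline_weights(params))
    if "infusion" in spec.kind:
        rid = system.model.input_reaction_id(spec.agonist)
        if spec.dose.saturation:
            overrides[rid] = 1.0
        else:
            fold = spec.dose.draw_fold(rng)
            w0 = overrides.get(rid, 0.0)
            if w0 == 0.0:
                # exogenous agonist with a null baseline weight: scale the
                # background weight instead, so a fold change has an effect
                w0 = float(params.get(system.background_param, 0.0))
            overrides[rid] = min(w0 * fold, 1.0)
    return Perturbation(weight_overrides=overrides, knockouts=knock)


def _draw_params(posterior: pd.DataFrame, idx: int) -> dict[str, float]:
    row = posterior.iloc[idx]
    return {k: float(v) for k, v in row.items() if k != "loglik"}


def simulate_scenario(
    system: VOSystem,
    spec: ScenarioSpec,
    posterior: pd.DataFrame,
    rng: np.random.Generator,
    n_times: int = 51,
) -> EnsembleResult:
    """Run a Monte Carlo ensemble of one scenario.

    Each iteration draws one posterior parameter row (with replacement),
    builds the scenario perturbation, computes the pre-overload baseline
    steady state under those parameters, and integrates forward to the
    horizon. Iterations whose integration fails are excluded and counted.
    """
    if posterior.empty:
        raise ValueError("posterior ensemble is empty")
    t_eval = np.linspace(0.0, spec.horizon, n_times)
    gidx = system.model.index(system.growth_node)
    outputs = list(system.outputs) or [system.growth_node]

    rows_growth, rows_curves, rows_term, rows_base, used_idx = [], [], [], [], []
    n_failed = 0
    for _ in range(spec.n_iter):
        idx = int(rng.integers(0, len(posterior)))
        params = _draw_params(posterior, idx)
        try:
            pert = _scenario_perturbation(system, spec, params, rng)
            y_base = system.baseline_state(params)
            traj = integrate(
                system.model, pert, t_span=(0.0, spec.horizon), t_eval=t_eval,
                y_init=y_base, rtol=system.rtol, atol=system.atol,
            )
        except (IntegrationError, SteadyStateError):
            n_failed += 1
            continue
        g0 = y_base[gidx]
        rows_growth.append(normalized_growth(g0, traj.activities[-1, gidx]))
        rows_curves.append((traj.activities[:, gidx] - g0) / g0)
        rows_term.append({o: traj.activities[-1, system.model.index(o)] for o in outputs})
        rows_base.append({o: y_base[system.model.index(o)] for o in outputs})
        used_idx.append(idx)
    if not rows_growth:
        raise RuntimeError(f"all {spec.n_iter} iterations failed to integrate")
    return EnsembleResult(
        times=t_eval,
        growth_curves=np.asarray(rows_curves),
        growth=np.asarray(rows_growth),
        terminal=pd.DataFrame(rows_term),
        baseline=pd.DataFrame(rows_base),
        draw_index=np.asarray(used_idx),
        n_failed=n_failed,
    )


def simulate_paired(
    system: VOSystem,
    spec_treated: ScenarioSpec,
    spec_control: ScenarioSpec,
    posterior: pd.DataFrame,
    rng: np.random.Generator,
    n_times: int = 51,
) -> tuple[np.ndarray, EnsembleResult, EnsembleResult]:
    """Common-random-number paired arms for drug-effect estimation.

    Both arms share the posterior draw and stimulus-curve/dose draws on
    every iteration (the per-iteration random stream is reset for the
    second arm), so the paired difference isolates the intervention.
    Returns the per-iteration normalized drug effects plus both ensembles.
    """
    if spec_treated.horizon != spec_control.horizon:
        raise ValueError("paired arms must share the same endpoint time")
    one = replace(spec_treated, n_iter=1)
    two = replace(spec_control, n_iter=1)
    effects, res_t, res_c = [], [], []
    n_failed = 0
    for _ in range(spec_treated.n_iter):
        seed = int(rng.integers(0, 2**31 - 1))
        idx = int(rng.integers(0, len(posterior)))
        sub = posterior.iloc[[idx]]
        try:
            a = simulate_scenario(system, one, sub, np.random.default_rng(seed), n_times)
            b = simulate_scenario(system, two, sub, np.random.default_rng(seed), n_times)
        except RuntimeError:
            n_failed += 1
            continue
        initial = float(b.baseline[system.growth_node].iloc[0])
        final_t = float(a.terminal[system.growth_node].iloc[0])
        final_c = float(b.terminal[system.growth_node].iloc[0])
        effects.append(normalized_drug_effect(final_t, final_c, initial))
        res_t.append(a)
        res_c.append(b)
    if not effects:
        raise RuntimeError("all paired iterations failed")
    treated = _concat_results(res_t, n_failed)
    control = _concat_results(res_c, n_failed)
    return np.asarray(effects), treated, control


def _concat_results(results: list[EnsembleResult], n_failed: int) -> EnsembleResult:
    return EnsembleResult(
        times=results[0].times,
        growth_curves=np.vstack([r.growth_curves for r in results]),
        growth=np.concatenate([r.growth for r in results]),
        terminal=pd.concat([r.terminal for r in results], ignore_index=True),
        baseline=pd.concat([r.baseline for r in results], ignore_index=True),
        draw_index=np.concatenate([r.draw_index for r in results]),
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# Growth / drug-effect statistics
# ---------------------------------------------------------------------------

def normalized_growth(initial: float, final: float) -> float:
    """Relative growth of the cell-size output, ``(final - initial)/initial``."""
    if initial <= 0:
        raise ValueError(f"initial size must be positive, got {initial}")
    return (final - initial) / initial


def normalized_drug_effect(final_with_drug: float, final_without: float, initial: float) -> float:
    """Chronic with-drug minus without-drug size, normalized to initial size."""
    if initial <= 0:
        raise ValueError(f"initial size must be positive, got {initial}")
    return (final_with_drug - final_without) / initial


def confidence_intervals(
    samples: np.ndarray, levels: Sequence[int] = (50, 90), min_samples: int = 20
) -> dict[int, tuple[float, float]]:
    """Central percentile intervals of a Monte Carlo sample.

    CI50 = [25th, 75th] and CI90 = [5th, 95th] percentiles (linear
    interpolation), and generally [(100-L)/2, (100+L)/2] for level L.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {samples.size}")
    out = {}
    for lev in levels:
        lo, hi = np.percentile(samples, [(100 - lev) / 2, (100 + lev) / 2])
        out[int(lev)] = (float(lo), float(hi))
    return out


def classify_change(deltas: np.ndarray, threshold: float = 0.75) -> str:
    """Majority-vote classification of an ensemble of output changes.

    ``increase`` if at least ``threshold`` of iterations changed upward
    (inclusive at the boundary), ``decrease`` symmetrically, else
    ``mixed``. Exact-zero deltas count toward neither direction.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty delta sample")
    frac_up = np.mean(deltas > 0)
    frac_down = np.mean(deltas < 0)
    if frac_up >= threshold:
        return "increase"
    if frac_down >= threshold:
        return "decrease"
    return "mixed"


def coverage_counts(
    samples: np.ndarray, experimental_means: Mapping[str, float] | Sequence[float]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """How many reported study means fall inside the model's CI50 and CI90."""
    ci = confidence_intervals(samples)
    if not isinstance(experimental_means, Mapping):
        experimental_means = {f"study_{i}": m for i, m in enumerate(experimental_means)}
    rows = []
    for study, m in experimental_means.items():
        in50 = ci[50][0] <= m <= ci[50][1]
        in90 = ci[90][0] <= m <= ci[90][1]
        rows.append({"study": study, "mean": m, "in_ci50": in50, "in_ci90": in90})
    table = pd.DataFrame(rows)
    totals = {
        "n_studies": len(table),
        "in_ci50": int(table["in_ci50"].sum()),
        "in_ci90": int(table["in_ci90"].sum()),
    }
    return table, totals


def sensitivity_matrix(
    inputs: pd.DataFrame, outputs: pd.DataFrame, min_samples: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations (and linear-regression slopes) input-by-output.

    Correlations are computed across paired Monte Carlo iterations; an
    input or output with zero variance yields a missing (NaN) entry rather
    than propagating a division by zero.
    """
    if len(inputs) != len(outputs):
        raise ValueError("inputs and outputs must be paired iteration-wise")
    if len(inputs) < min_samples:
        raise ValueError(f"need >= {min_samples} paired samples, got {len(inputs)}")
    pcc = pd.DataFrame(index=inputs.columns, columns=outputs.columns, dtype=float)
    slope = pcc.copy()
    for xi in inputs.columns:
        x = inputs[xi].to_numpy(dtype=float)
        sx = x.std()
        for yo in outputs.columns:
            y = outputs[yo].to_numpy(dtype=float)
            sy = y.std()
            if sx == 0 or sy == 0:
                continue  # leaves NaN
            r = float(np.corrcoef(x, y)[0, 1])
            pcc.loc[xi, yo] = r
            slope.loc[xi, yo] = r * sy / sx
    return pcc, slope
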