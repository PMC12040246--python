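"""Synthetic ground truth: toy networks and literature-like observations.

Full-scale calibration runs against a published 100-plus-node signaling
network and dozens of digitized experimental datasets. For testing every
stage of the pipeline without any external file, this module generates

* small (<= 10 node) toy networks in the same rule dialect, with an
  agonist input, a background input, a mechanical strain input, a
  knockable receptor, AND/OR/NOT gates, gene outputs and a slow
  cell-size output whose constant-input steady states can be computed by
  hand (nested normalized-Hill composition in topological order);
* a synthetic "truth": known input weights, strain-map gain and stimulus
  curves, from which a deterministic reference VO trajectory follows;
* observation tables emulating the structure of the literature data: per
  variable and time point, several "studies" reporting mean ± SD fold
  changes, with between-study scatter on the means, assigned to dog or
  rat with raw-hour time axes derived from each species' growth time
  constant.

Noise is purely statistical (normal between-study offsets and a fixed
within-study SD); no attempt is made to emulate measurement physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .forward_validation import VOSystem
from .input_curves import CurveFamily, save_curve_set
from .network_core import NetworkModel, integrate, parse_model_tables
from .geometry_strain import StrainCurve

__all__ = [
    "ToyNetwork",
    "SyntheticTruth",
    "make_toy_network",
    "make_toy_curves",
    "make_toy_system",
    "toy_truth",
    "default_truth",
    "generate_vo_truth",
    "generate_observations",
    "generate_mass_growth_observations",
    "write_workspace",
]

TOY_VARIANTS = ("chain", "crosstalk", "runaway-prone")

#: Growth time constants (hours) matching the fitted mass-growth kinetics
#: of the two experimental models: canine mitral regurgitation and rat
#: aorto-caval shunt.
SPECIES_TAU_HOURS = {"dog": 1095.0, "rat": 283.0}


@dataclass(frozen=True)
class ToyNetwork:
    """A toy model plus the role names the pipeline needs to drive it."""

    model: NetworkModel
    variant: str
    agonist: str = "AGO"
    strain: str = "STR"
    background: str = "BG"
    receptor: str = "RA"
    orphan_receptor: str = "ORPH"
    growth: str = "CellArea"
    gene_outputs: tuple[str, ...] = ("GENE",)


def make_toy_network(variant: str = "chain") -> ToyNetwork:
    """Build one of the documented toy networks from its tables.

    ``chain``: agonist -> receptor -> kinase -> TF -> {gene, CellArea},
    with strain and background inputs OR-merged at the kinase, plus an
    orphan receptor with no path to the growth output.
    ``crosstalk``: the TF is AND-gated by receptor and strain, and the gene
    output is inhibited (NOT) by a kinase-driven repressor.
    ``runaway-prone``: the chain plus a positive feedback of CellArea onto
    the kinase, slowing settling enough that strong drives look like
    runaway growth at the horizon.
    """
    if variant not in TOY_VARIANTS:
        raise ValueError(f"variant must be one of {TOY_VARIANTS}, got {variant!r}")
    nodes = [
        {"id": "AGO", "ymax": 1, "tau": 0.02, "y0": 0.0, "category": "input"},
        {"id": "STR", "ymax": 1, "tau": 0.02, "y0": 0.0, "category": "input"},
        {"id": "BG", "ymax": 1, "tau": 0.02, "y0": 0.0, "category": "input"},
        {"id": "RA", "ymax": 1, "tau": 0.05, "y0": 0.0, "category": "intermediate"},
        {"id": "ORPH", "ymax": 1, "tau": 0.05, "y0": 0.0, "category": "intermediate"},
        {"id": "KIN", "ymax": 1, "tau": 0.05, "y0": 0.0, "category": "intermediate"},
        {"id": "TF", "ymax": 1, "tau": 0.05, "y0": 0.0, "category": "intermediate"},
        {"id": "GENE", "ymax": 1, "tau": 0.02, "y0": 0.0, "category": "gene-output"},
        {"id": "CellArea", "ymax": 1, "tau": 1.0, "y0": 0.0, "category": "growth-output"},
    ]
    base = [
        {"rule": "=> AGO", "w": 0.0, "n": 1.4, "EC50": 0.5},
        {"rule": "=> STR", "w": 0.0, "n": 1.4, "EC50": 0.5},
        {"rule": "=> BG", "w": 0.0, "n": 1.4, "EC50": 0.5},
        {"rule": "=> ORPH", "w": 0.05, "n": 1.4, "EC50": 0.5},
        {"rule": "AGO => RA", "w": 1.0, "n": 1.4, "EC50": 0.4},
        {"rule": "RA => KIN", "w": 1.0, "n": 1.4, "EC50": 0.3},
        {"rule": "STR => KIN", "w": 1.0, "n": 1.4, "EC50": 0.3},
        {"rule": "BG => KIN", "w": 1.0, "n": 1.4, "EC50": 0.3},
    ]
    if variant == "crosstalk":
        nodes.insert(7, {"id": "INH", "ymax": 1, "tau": 0.05, "y0": 0.0,
                         "category": "intermediate"})
        reactions = base + [
            {"rule": "RA & STR => TF", "w": 1.0, "n": 1.4, "EC50": 0.3},
            {"rule": "KIN => INH", "w": 0.5, "n": 1.4, "EC50": 0.3},
            {"rule": "!INH & TF => GENE", "w": 1.0, "n": 1.4, "EC50": 0.5},
            {"rule": "TF => CellArea", "w": 1.0, "n": 1.4, "EC50": 0.5},
        ]
    else:
        reactions = base + [
            {"rule": "KIN => TF", "w": 1.0, "n": 1.4, "EC50": 0.3},
            {"rule": "TF => GENE", "w": 1.0, "n": 1.4, "EC50": 0.5},
            {"rule": "TF => CellArea", "w": 1.0, "n": 1.4, "EC50": 0.5},
        ]
        if variant == "runaway-prone":
            reactions.append({"rule": "CellArea => KIN", "w": 0.9, "n": 1.4, "EC50": 0.5})
    model = parse_model_tables(pd.DataFrame(nodes), pd.DataFrame(reactions))
    return ToyNetwork(model=model, variant=variant)


def make_toy_curves(domain: tuple[float, float] = (0.0, 5.0)) -> dict[str, CurveFamily]:
    """Stimulus and geometry fold-change families for the toy VO scenario.

    The agonist concentration saturates at roughly 2.5-fold; end-diastolic
    volume jumps quickly (~1.67-fold) while mass follows slowly (~1.6-fold),
    so the implied strain rises acutely and then falls below baseline as
    growth catches up — the qualitative time course of volume overload.
    """
    return {
        "AGO": CurveFamily("saturating_exp", [1.5, 0.5], [[0.09, 0.0], [0.0, 0.01]], domain),
        "LVM": CurveFamily("saturating_exp", [0.60, 1.0], [[0.0225, 0.0], [0.0, 0.04]], domain),
        "VED": CurveFamily("saturating_exp", [0.67, 0.15], [[0.0225, 0.0], [0.0, 0.0009]], domain),
    }


@dataclass(frozen=True)
class SyntheticTruth:
    """Known parameter values a recovery test should reproduce."""

    weights: Mapping[str, float]
    w_myostrain0: float = 0.06
    between_study_sd: float = 0.08
    within_study_sd: float = 0.15
    species_tau: Mapping[str, float] = field(default_factory=lambda: dict(SPECIES_TAU_HOURS))
    lvm_amplitude: float = 0.36
    #: Between-study scatter of LVM/BM fold-change means: mass is measured
    #: far more precisely than hormone concentrations or blot densitometry.
    mass_scatter_sd: float = 0.02

    def __post_init__(self):
        if self.between_study_sd < 0 or self.within_study_sd <= 0:
            raise ValueError("noise scales must be positive (between-study may be 0)")
        for sp, tau in self.species_tau.items():
            if tau <= 0:
                raise ValueError(f"tau for {sp!r} must be positive")


def toy_truth() -> SyntheticTruth:
    """Ground truth for the toy system: responsive, non-degenerate weights."""
    return SyntheticTruth(weights={"w_ago0": 0.12, "w_background": 0.08, "cmyo": 5.86})


def default_truth() -> SyntheticTruth:
    """Full-model-style truth at the calibrated operating point.

    Uses the converged posterior means of the volume-overload calibration
    (AngII 0.010, NE 0.033, ET1 0.056, background 0.031, Cmyo 5.86, strain
    baseline weight 0.06) so synthetic behavior resembles the calibrated
    regime.
    """
    return SyntheticTruth(
        weights={
            "w_angii0": 0.010,
            "w_ne0": 0.033,
            "w_et10": 0.056,
            "w_background": 0.031,
            "cmyo": 5.86,
        }
    )


def make_toy_system(
    variant: str = "chain", w_myostrain0: float = 0.06, horizon: float = 5.0
) -> tuple[VOSystem, ToyNetwork]:
    """Wire a toy network into a ready-to-run VO system."""
    toy = make_toy_network(variant)
    system = VOSystem(
        model=toy.model,
        curves=make_toy_curves((0.0, horizon)),
        input_map={toy.agonist: "w_ago0"},
        background_inputs=(toy.background,),
        strain_node=toy.strain,
        w_myostrain0=w_myostrain0,
        growth_node=toy.growth,
        outputs=("GENE", "CellArea"),
        horizon=horizon,
    )
    return system, toy


# ---------------------------------------------------------------------------
# Reference trajectories and observation tables
# ---------------------------------------------------------------------------

@dataclass
class ReferenceRun:
    """Deterministic truth trajectory used as the oracle for recovery tests."""

    times: np.ndarray
    activities: np.ndarray
    node_ids: list[str]
    baseline: np.ndarray
    strain: StrainCurve | None

    def fold(self, node_id: str) -> np.ndarray:
        k = self.node_ids.index(node_id)
        return self.activities[:, k] / self.baseline[k]


def generate_vo_truth(
    truth: SyntheticTruth, system: VOSystem, n_times: int = 101
) -> ReferenceRun:
    """Run the VO scenario at the truth parameters with mean curves.

    Fully deterministic: stimulus curves are the family means, the baseline
    stretch is its mean, and the trajectory starts from the baseline steady
    state — identical inputs always give the identical reference.
    """
    params = dict(truth.weights)
    hormones = {node: system.curves[node].mean_curve() for node in system.input_map}
    strain = None
    if system.strain_node is not None:
        from .geometry_strain import strain_trajectory

        grid = np.linspace(0.0, system.horizon, 201)
        strain = strain_trajectory(
            grid,
            system.curves["VED"].mean_curve(),
            system.curves["LVM"].mean_curve(),
            system.lambda_ed0_mean,
        )
    y_base = system.baseline_state(params)
    pert = system.vo_perturbation(params, hormones, strain)
    t_eval = np.linspace(0.0, system.horizon, n_times)
    traj = integrate(system.model, pert, t_span=(0.0, system.horizon), t_eval=t_eval,
                     y_init=y_base)
    return ReferenceRun(
        times=traj.times,
        activities=traj.activities,
        node_ids=traj.node_ids,
        baseline=y_base,
        strain=strain,
    )


def generate_observations(
    truth: SyntheticTruth,
    system: VOSystem,
    timepoints: Sequence[float],
    n_studies: int,
    rng: np.random.Generator,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Emit literature-like observation tables from the truth trajectory.

    For each variable and t/tau point, ``n_studies`` synthetic studies each
    report mean = true fold change + Normal(0, between_study_sd) and
    sd = within_study_sd. Studies alternate between species, with the raw
    time axis in hours recovered through each species' growth time
    constant.
    """
    ref = generate_vo_truth(truth, system)
    if variables is None:
        variables = ["KIN", "TF", system.growth_node]
    species_cycle = sorted(truth.species_tau)
    rows = []
    for var in variables:
        fold = np.interp(np.asarray(timepoints, dtype=float), ref.times, ref.fold(var))
        for tt, f_true in zip(timepoints, fold):
            for j in range(n_studies):
                sp = species_cycle[j % len(species_cycle)]
                mean = f_true + rng.normal(0.0, truth.between_study_sd)
                rows.append(
                    {
                        "variable": var,
                        "species": sp,
                        "time_hours": tt * truth.species_tau[sp],
                        "mean": max(mean, 1e-3),
                        "sd": truth.within_study_sd,
                        "source": f"synthetic:{var}:t{tt:g}:{j}",
                        "t_over_tau": tt,
                    }
                )
    return pd.DataFrame(rows)


#: Default number of mass-growth datasets per species, matching the size of
#: the experimental literature corpus (41 canine, 45 rat datasets).
MASS_CORPUS_SIZE = {"dog": 41, "rat": 45}


def generate_mass_growth_observations(
    truth: SyntheticTruth,
    rng: np.random.Generator,
    n_datasets: Mapping[str, int] | int | None = None,
    max_t_over_tau: float = 4.0,
) -> pd.DataFrame:
    """Synthetic LVM/BM fold-change datasets for the time-constant fit.

    Each species gets observations of the saturating exponential
    ``1 + A (1 - e^{-t/tau})`` at its own tau, with between-study scatter
    (``mass_scatter_sd``) — the raw material for cross-species time
    normalization. Sampling times are geometrically spaced: experimental
    studies cover the early rise densely, and that is where the time
    constant is informed.
    """
    if n_datasets is None:
        n_datasets = MASS_CORPUS_SIZE
    if isinstance(n_datasets, int):
        n_datasets = {sp: n_datasets for sp in truth.species_tau}
    rows = []
    for sp, tau in truth.species_tau.items():
        tt = np.geomspace(0.05, max_t_over_tau, n_datasets[sp])
        for k, x in enumerate(tt):
            true = 1.0 + truth.lvm_amplitude * (1.0 - np.exp(-x))
            rows.append(
                {
                    "variable": "LVM/BM",
                    "species": sp,
                    "time_hours": x * tau,
                    "mean": max(true + rng.normal(0.0, truth.mass_scatter_sd), 1e-3),
                    "sd": truth.mass_scatter_sd,
                    "source": f"synthetic:LVM/BM:{sp}:{k}",
                }
            )
    return pd.DataFrame(rows)


def write_workspace(out_dir: str | Path, seed: int = 0, variant: str = "chain") -> Path:
    """Write a self-contained synthetic workspace (tables, curves, truth).

    Produces the toy model tables, the observation CSVs, the curve-set YAML
    and a JSON record of the generating truth, in the same formats the rest
    of the pipeline consumes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    system, toy = make_toy_system(variant)
    truth = toy_truth()

    nodes_df, reactions_df = toy.model.to_tables()
    nodes_df.to_csv(out / "nodes.csv", index=False)
    reactions_df.to_csv(out / "reactions.csv", index=False)
    save_curve_set(system.curves, out / "curves.yaml")

    obs = generate_observations(truth, system, timepoints=(0.25, 0.5, 1.0, 2.0, 4.0),
                                n_studies=3, rng=rng)
    obs.drop(columns="t_over_tau").to_csv(out / "observations.csv", index=False)
    growth = generate_mass_growth_observations(truth, rng)
    growth.to_csv(out / "mass_growth.csv", index=False)

    (out / "truth.json").write_text(
        json.dumps(
            {
                "variant": variant,
                "seed": seed,
                "weights": dict(truth.weights),
                "w_myostrain0": truth.w_myostrain0,
                "species_tau_hours": dict(truth.species_tau),
                "lvm_amplitude": truth.lvm_amplitude,
            },
            indent=2,
        )
    )
    return out
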