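"""Cross-species time normalization and time-varying stimulus curves.

Volume overload drives hypertrophy on very different absolute time scales
in different species (weeks in rats, months in dogs), but the shapes of the
fold-change time courses are congruent once time is expressed in units of
each species' growth time constant tau. Fitting the left-ventricular
mass-to-body-mass (LVM/BM) fold change with a saturating exponential
``FC(t) = 1 + A (1 - e^{-t/tau})`` per species yields the tau used to put
all observations on a common t/tau axis.

Serum hormone fold changes (AngII, NE, ET1, ANP, BNP) and the geometric
fold changes (LVM, VED) on that common axis are summarized as parametric
curve families fitted by weighted least squares; the Gaussian parameter
covariance of each fit defines a distribution over curves that downstream
Monte Carlo stages sample from. Every family is parameterized so the curve
equals 1 at t/tau = 0 (the pre-overload baseline anchor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

__all__ = [
    "OBSERVATION_COLUMNS",
    "FitError",
    "SpeciesTimeScale",
    "GrowthFit",
    "CurveFamily",
    "validate_observations",
    "load_observations",
    "fit_growth_timescale",
    "normalize_time",
    "fit_stimulus_curve",
    "sample_curve",
    "save_curve_set",
    "load_curve_set",
]

OBSERVATION_COLUMNS = ("variable", "species", "time_hours", "mean", "sd", "source")


class FitError(RuntimeError):
    """A least-squares fit could not be performed or is degenerate."""


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Check an observation table against the expected schema.

    Each row is one published "dataset": a mean ± SD fold change for one
    variable in one species at one time point.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise ValueError(f"observation table missing column(s): {missing}")
    if (df["sd"] <= 0).any():
        bad = df.index[df["sd"] <= 0].tolist()
        raise ValueError(f"sd must be positive (rows {bad})")
    if (df["mean"] <= 0).any():
        bad = df.index[df["mean"] <= 0].tolist()
        raise ValueError(f"fold changes must be positive (rows {bad})")
    return df


def load_observations(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return validate_observations(pd.read_csv(path, sep=sep))


# ---------------------------------------------------------------------------
# Growth time scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthFit:
    """Per-species saturating-exponential fit of the LVM/BM fold change."""

    tau_hours: float
    amplitude: float
    cov: np.ndarray  # 2x2 covariance of (amplitude, tau)


@dataclass(frozen=True)
class SpeciesTimeScale:
    """Growth time constants (hours) keyed by species."""

    tau_hours: Mapping[str, float]

    def __post_init__(self):
        for sp, tau in self.tau_hours.items():
            if tau <= 0:
                raise ValueError(f"tau for {sp!r} must be positive, got {tau}")

    def __getitem__(self, species: str) -> float:
        return self.tau_hours[species]

    def ratio(self, a: str, b: str) -> float:
        return self.tau_hours[a] / self.tau_hours[b]


def _sat_exp(t, a, tau):
    return 1.0 + a * (1.0 - np.exp(-t / tau))


def fit_growth_timescale(
    df: pd.DataFrame, min_amplitude: float = 1e-3
) -> tuple[SpeciesTimeScale, dict[str, GrowthFit]]:
    """Fit ``FC(t) = 1 + A (1 - e^{-t/tau})`` to mass-fold data per species.

    Weighted least squares with weights 1/sd^2. Requires at least three
    distinct time points per species; an essentially flat dataset
    (|A| < ``min_amplitude``) makes tau unidentifiable and raises
    :class:`FitError`.
    """
    validate_observations(df)
    fits: dict[str, GrowthFit] = {}
    for species, grp in df.groupby("species"):
        t = grp["time_hours"].to_numpy(dtype=float)
        if len(np.unique(t)) < 3:
            raise FitError(f"species {species!r}: need >= 3 distinct time points")
        y = grp["mean"].to_numpy(dtype=float)
        sd = grp["sd"].to_numpy(dtype=float)
        p0 = (max(y.max() - 1.0, 0.1), np.median(t[t > 0]) if (t > 0).any() else 1.0)
        try:
            popt, pcov = curve_fit(
                _sat_exp, t, y, p0=p0, sigma=sd, absolute_sigma=True, maxfev=20000
            )
        except RuntimeError as exc:
            raise FitError(f"species {species!r}: fit failed ({exc})") from exc
        a, tau = popt
        if abs(a) < min_amplitude:
            raise FitError(
                f"species {species!r}: amplitude {a:.2g} ~ 0, time constant unidentifiable"
            )
        fits[species] = GrowthFit(tau_hours=float(tau), amplitude=float(a), cov=pcov)
    scale = SpeciesTimeScale({sp: f.tau_hours for sp, f in fits.items()})
    return scale, fits


def normalize_time(df: pd.DataFrame, timescale: SpeciesTimeScale) -> pd.DataFrame:
    """Add a ``t_over_tau`` column dividing each row's time by its species tau.

    Refuses to run twice on the same table (the column's presence is the
    idempotence flag), which guards against double normalization.
    """
    if "t_over_tau" in df.columns:
        raise ValueError("table already carries t_over_tau; refusing to normalize twice")
    unknown = set(df["species"].unique()) - set(timescale.tau_hours)
    if unknown:
        raise ValueError(f"no time constant for species: {sorted(unknown)}")
    out = df.copy()
    out["t_over_tau"] = out["time_hours"] / out["species"].map(timescale.tau_hours)
    return out


# ---------------------------------------------------------------------------
# Stimulus curve families
# ---------------------------------------------------------------------------

def _f_constant(t):
    return np.ones_like(np.asarray(t, dtype=float))


def _f_linear(t, a):
    return 1.0 + a * np.asarray(t, dtype=float)


def _f_saturating_exp(t, a, theta):
    return 1.0 + a * (1.0 - np.exp(-np.asarray(t, dtype=float) / theta))


def _f_peak_decay(t, a, theta):
    """Rise to a peak of 1 + a at t = theta, then relax back toward 1."""
    t = np.asarray(t, dtype=float)
    return 1.0 + a * (t / theta) * np.exp(1.0 - t / theta)


CURVE_FORMS: dict[str, tuple[Callable, int]] = {
    "constant": (_f_constant, 0),
    "linear": (_f_linear, 1),
    "saturating_exp": (_f_saturating_exp, 2),
    "peak_decay": (_f_peak_decay, 2),
}


@dataclass
class CurveFamily:
    """A fitted fold-change curve form with a Gaussian parameter distribution."""

    form: str
    param_mean: np.ndarray
    param_cov: np.ndarray
    domain: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self):
        if self.form not in CURVE_FORMS:
            raise ValueError(f"unknown curve form {self.form!r}; known: {list(CURVE_FORMS)}")
        self.param_mean = np.atleast_1d(np.asarray(self.param_mean, dtype=float))
        self.param_cov = np.atleast_2d(np.asarray(self.param_cov, dtype=float))
        _, n_par = CURVE_FORMS[self.form]
        if self.param_mean.size != n_par:
            raise ValueError(f"form {self.form!r} takes {n_par} parameter(s)")
        if n_par and self.param_cov.shape != (n_par, n_par):
            raise ValueError(f"param_cov must be {n_par}x{n_par}")
        if n_par and not np.allclose(self.param_cov, self.param_cov.T):
            raise ValueError("param_cov must be symmetric")

    def evaluate(self, t, params: np.ndarray | None = None):
        fn, n_par = CURVE_FORMS[self.form]
        p = self.param_mean if params is None else np.atleast_1d(params)
        return fn(t, *p[:n_par])

    def mean_curve(self) -> Callable[[np.ndarray], np.ndarray]:
        return lambda t: self.evaluate(t)


def fit_stimulus_curve(
    df: pd.DataFrame, form: str, domain: tuple[float, float] = (0.0, 5.0)
) -> CurveFamily:
    """Weighted least-squares fit of one curve family to normalized data.

    ``df`` must carry ``t_over_tau``, ``mean`` and ``sd`` columns. The
    baseline anchor FC(0) = 1 is built into every parameterization rather
    than fitted. Parameter covariance comes from the linearized fit.
    """
    if form not in CURVE_FORMS:
        raise ValueError(f"unknown curve form {form!r}; known: {list(CURVE_FORMS)}")
    if "t_over_tau" not in df.columns:
        raise ValueError("data must be time-normalized first (missing t_over_tau)")
    t = df["t_over_tau"].to_numpy(dtype=float)
    y = df["mean"].to_numpy(dtype=float)
    sd = df["sd"].to_numpy(dtype=float)
    fn, n_par = CURVE_FORMS[form]
    if n_par == 0:
        return CurveFamily(form, np.empty(0), np.empty((0, 0)), domain)
    if len(t) < n_par:
        raise FitError(f"{len(t)} points cannot constrain {n_par} parameters")
    p0 = [0.1] * n_par
    if n_par == 2:
        p0 = [max(y.max() - 1.0, 0.1), max(np.median(t), 0.1)]
    try:
        popt, pcov = curve_fit(fn, t, y, p0=p0, sigma=sd, absolute_sigma=True, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"fit of form {form!r} failed: {exc}") from exc
    if not np.all(np.isfinite(pcov)):
        resid = (fn(t, *popt) - y) / sd
        if np.max(np.abs(resid)) < 1e-8:
            pcov = np.zeros((n_par, n_par))  # exact fit: no parameter spread
        else:
            raise FitError(f"singular design for form {form!r}: covariance not finite")
    return CurveFamily(form, popt, pcov, domain)


def sample_curve(
    family: CurveFamily,
    rng: np.random.Generator,
    max_tries: int = 100,
    n_check: int = 101,
) -> Callable[[np.ndarray], np.ndarray]:
    """Draw one curve from the family's Gaussian parameter distribution.

    Draws are rejected (and retried) if the resulting curve is not strictly
    positive everywhere on the family's domain — fold changes of
    concentrations and volumes cannot cross zero.
    """
    if family.param_mean.size == 0:
        return family.mean_curve()
    grid = np.linspace(family.domain[0], family.domain[1], n_check)
    for _ in range(max_tries):
        p = rng.multivariate_normal(family.param_mean, family.param_cov, method="svd")
        if np.all(family.evaluate(grid, p) > 0):
            return lambda t, _p=p: family.evaluate(t, _p)
    raise RuntimeError(
        f"could not draw a positive curve from form {family.form!r} in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_curve_set(curves: Mapping[str, CurveFamily], path: str | Path) -> None:
    """Serialize a named set of curve families to YAML."""
    payload = {
        name: {
            "form": fam.form,
            "param_mean": fam.param_mean.tolist(),
            "param_cov": fam.param_cov.tolist(),
            "domain": list(fam.domain),
        }
        for name, fam in curves.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_curve_set(path: str | Path) -> dict[str, CurveFamily]:
    payload = yaml.safe_load(Path(path).read_text())
    return {
        name: CurveFamily(
            form=spec["form"],
            param_mean=np.asarray(spec["param_mean"], dtype=float),
            param_cov=np.asarray(spec["param_cov"], dtype=float),
            domain=tuple(spec.get("domain", (0.0, 5.0))),
        )
        for name, spec in payload.items()
    }
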