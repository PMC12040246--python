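"""Logic-based signaling networks with normalized-Hill activation kinetics.

A network is a set of nodes (receptors, kinases, transcription factors,
genes, and phenotypic outputs such as cell size) connected by weighted
reactions written as Boolean-style rule strings, e.g. ``"!A & B => C"``.
Each node carries a continuous activity ``y`` in ``[0, ymax]`` that relaxes
toward a target set by its incoming reactions:

    dy/dt = (ymax * g(inputs, t) - y) / tau

where ``g`` OR-combines the activations of all reactions targeting the node.
A reaction's activation is its weight ``w`` times the product of its operand
activations, each passed through a normalized Hill function ``f`` with
``f(0) = 0``, ``f(EC50) = 0.5`` and ``f(1) = 1`` (inhibitory operands use
``1 - f``). Reactions with no operands ("``=> A``") are constant or
time-varying drives used to represent hormonal and mechanical inputs.

Model definitions are read from node/reaction tables in the tabular dialect
used by logic-based modeling tools (paired CSVs or a spreadsheet workbook).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "NodeSpec",
    "ReactionSpec",
    "NetworkModel",
    "Perturbation",
    "Trajectory",
    "ModelParseError",
    "IntegrationError",
    "SteadyStateError",
    "hill_activation",
    "parse_rule",
    "parse_model_tables",
    "read_model",
    "ode_rhs",
    "integrate",
    "fixed_point_state",
    "steady_state",
]

NODE_CATEGORIES = ("input", "intermediate", "gene-output", "growth-output")

#: Default per-category time constants, in normalized t/tau units: fast
#: intracellular reactions, slower gene expression, and a growth output on
#: the organ-scale growth time scale itself.
DEFAULT_TAU = {
    "input": 0.005,
    "intermediate": 0.005,
    "gene-output": 0.02,
    "growth-output": 1.0,
}


class ModelParseError(ValueError):
    """A node/reaction table or rule string could not be parsed or validated."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a trajectory."""


class SteadyStateError(RuntimeError):
    """No steady state was reached within the allotted horizon."""


# ---------------------------------------------------------------------------
# Activation functions
# ---------------------------------------------------------------------------

def hill_activation(x, ec50: float, n: float):
    """Normalized Hill function ``f(x) = B x^n / (K^n + x^n)``.

    The constants ``B = (EC50^n - 1) / (2 EC50^n - 1)`` and ``K^n = B - 1``
    are fixed so that ``f(0) = 0``, ``f(EC50) = 0.5`` and ``f(1) = 1``;
    in the limiting case ``EC50^n = 1/2`` the function reduces to ``x^n``.
    Monotone nondecreasing on [0, 1] for any valid (EC50, n).
    """
    if not 0.0 < ec50 < 1.0:
        raise ValueError(f"EC50 must lie in (0, 1); got {ec50!r}")
    if n <= 0:
        raise ValueError(f"Hill coefficient n must be positive; got {n!r}")
    x = np.asarray(x, dtype=float)
    xn = x**n
    e = ec50**n
    if abs(2.0 * e - 1.0) < 1e-12:
        out = xn
    else:
        b = (e - 1.0) / (2.0 * e - 1.0)
        kn = b - 1.0
        out = b * xn / (kn + xn)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeSpec:
    """One network node: maximum activity, time constant, initial activity."""

    id: str
    ymax: float = 1.0
    tau: float = 0.005
    y0: float = 0.0
    category: str = "intermediate"

    def __post_init__(self):
        if not 0.0 <= self.ymax <= 1.0:
            raise ModelParseError(f"node {self.id!r}: ymax must be in [0, 1], got {self.ymax}")
        if self.tau <= 0:
            raise ModelParseError(f"node {self.id!r}: tau must be positive, got {self.tau}")
        if not 0.0 <= self.y0 <= self.ymax:
            raise ModelParseError(f"node {self.id!r}: y0 must be in [0, ymax], got {self.y0}")
        if self.category not in NODE_CATEGORIES:
            raise ModelParseError(
                f"node {self.id!r}: unknown category {self.category!r}; "
                f"expected one of {NODE_CATEGORIES}"
            )


_RULE_RE = re.compile(r"^\s*(?P<lhs>[^=>]*)=>\s*(?P<target>\S+)\s*$")


def parse_rule(rule: str) -> tuple[list[tuple[str, bool]], str]:
    """Parse ``"!A & B => C"`` into ``([("A", True), ("B", False)], "C")``.

    An empty left-hand side (``"=> C"``) denotes an input drive with no
    operands. The boolean flags mark inhibitory (NOT) operands.
    """
    m = _RULE_RE.match(rule)
    if m is None:
        raise ModelParseError(f"malformed rule string: {rule!r}")
    target = m.group("target")
    lhs = m.group("lhs").strip()
    operands: list[tuple[str, bool]] = []
    if lhs:
        for raw in lhs.split("&"):
            tok = raw.strip()
            neg = tok.startswith("!")
            name = tok[1:].strip() if neg else tok
            if not re.fullmatch(r"[A-Za-z_][\w.+-]*", name or ""):
                raise ModelParseError(f"malformed operand {raw!r} in rule {rule!r}")
            operands.append((name, neg))
    return operands, target


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction: rule string plus (w, n, EC50) Hill parameters."""

    rule: str
    w: float = 1.0
    n: float = 1.4
    ec50: float = 0.5
    id: str = ""

    def __post_init__(self):
        operands, target = parse_rule(self.rule)
        object.__setattr__(self, "_operands", operands)
        object.__setattr__(self, "_target", target)
        if not 0.0 <= self.w <= 1.0:
            raise ModelParseError(f"reaction {self.rule!r}: w must be in [0, 1], got {self.w}")
        if not 0.0 < self.ec50 < 1.0:
            raise ModelParseError(
                f"reaction {self.rule!r}: EC50 must be in (0, 1), got {self.ec50}"
            )
        if self.n <= 0:
            raise ModelParseError(f"reaction {self.rule!r}: n must be positive, got {self.n}")

    @property
    def operands(self) -> list[tuple[str, bool]]:
        return list(self._operands)

    @property
    def target(self) -> str:
        return self._target

    @property
    def is_input(self) -> bool:
        return not self._operands


@dataclass(frozen=True)
class Perturbation:
    """Run-time modification of a model: weight overrides and knockouts.

    ``weight_overrides`` maps reaction id to either a constant weight in
    [0, 1] or a callable ``w(t)`` evaluated in t/tau units (values are
    clipped to [0, 1] at evaluation time). ``knockouts`` lists node ids whose
    ymax is forced to zero, emulating pharmacologic receptor blockade.
    """

    weight_overrides: Mapping[str, float | Callable[[float], float]] = field(default_factory=dict)
    knockouts: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        for rid, w in self.weight_overrides.items():
            if not callable(w) and not 0.0 <= float(w) <= 1.0:
                raise ValueError(f"override for {rid!r} must be in [0, 1], got {w}")

    def validate(self, model: "NetworkModel") -> None:
        unknown = self.knockouts - set(model.node_ids)
        if unknown:
            raise ValueError(f"knockout of undefined node(s): {sorted(unknown)}")
        known_rids = {r.id for r in model.reactions}
        bad = set(self.weight_overrides) - known_rids
        if bad:
            raise ValueError(f"weight override for undefined reaction(s): {sorted(bad)}")


class NetworkModel:
    """A validated node/reaction network ready for simulation."""

    def __init__(self, nodes: Sequence[NodeSpec], reactions: Sequence[ReactionSpec]):
        ids = [nd.id for nd in nodes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ModelParseError(f"duplicate node id(s): {sorted(dupes)}")
        self.nodes: dict[str, NodeSpec] = {nd.id: nd for nd in nodes}
        self._index = {nid: k for k, nid in enumerate(self.nodes)}
        # assign stable reaction ids where the table did not provide one
        rs = []
        for k, r in enumerate(reactions):
            rid = r.id or f"r{k + 1}"
            rs.append(ReactionSpec(rule=r.rule, w=r.w, n=r.n, ec50=r.ec50, id=rid))
        self.reactions: list[ReactionSpec] = rs
        for r in self.reactions:
            for name, _ in r.operands:
                if name not in self.nodes:
                    raise ModelParseError(
                        f"reaction {r.rule!r} references undefined node {name!r}"
                    )
            if r.target not in self.nodes:
                raise ModelParseError(
                    f"reaction {r.rule!r} targets undefined node {r.target!r}"
                )

    # -- lookups -----------------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return list(self.nodes)

    def index(self, node_id: str) -> int:
        return self._index[node_id]

    def input_reaction_id(self, target: str) -> str:
        """Id of the operand-free drive reaction targeting ``target``."""
        hits = [r.id for r in self.reactions if r.is_input and r.target == target]
        if len(hits) != 1:
            raise KeyError(
                f"expected exactly one input reaction for node {target!r}, found {len(hits)}"
            )
        return hits[0]

    @property
    def y0(self) -> np.ndarray:
        return np.array([nd.y0 for nd in self.nodes.values()], dtype=float)

    def state_dict(self, y: np.ndarray) -> dict[str, float]:
        return {nid: float(y[k]) for nid, k in self._index.items()}

    # -- tables ------------------------------------------------------------
    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes_df = pd.DataFrame(
            [
                {"id": nd.id, "ymax": nd.ymax, "tau": nd.tau, "y0": nd.y0,
                 "category": nd.category}
                for nd in self.nodes.values()
            ]
        )
        reactions_df = pd.DataFrame(
            [
                {"id": r.id, "rule": r.rule, "w": r.w, "n": r.n, "EC50": r.ec50}
                for r in self.reactions
            ]
        )
        return nodes_df, reactions_df


# ---------------------------------------------------------------------------
# Table parsing
# ---------------------------------------------------------------------------

_NODE_ALIASES = {
    "id": {"id", "node", "name", "species"},
    "ymax": {"ymax"},
    "tau": {"tau"},
    "y0": {"y0", "yinit", "yinitial"},
    "category": {"category", "type"},
}
_REACTION_ALIASES = {
    "rule": {"rule", "reaction"},
    "w": {"w", "weight"},
    "n": {"n"},
    "ec50": {"ec50"},
    "id": {"id", "rid"},
}


def _canonicalize(df: pd.DataFrame, aliases: dict[str, set[str]], what: str) -> pd.DataFrame:
    cols = {}
    for col in df.columns:
        key = str(col).strip().lower()
        for canon, names in aliases.items():
            if key in names:
                cols[col] = canon
    out = df.rename(columns=cols)
    required = "id" if what == "nodes" else "rule"
    if required not in out.columns:
        raise ModelParseError(f"{what} table lacks a recognizable {required!r} column")
    return out


def parse_model_tables(nodes_table: pd.DataFrame, reactions_table: pd.DataFrame) -> NetworkModel:
    """Build a validated :class:`NetworkModel` from node/reaction tables.

    Missing ``tau`` entries fall back to the category default
    (:data:`DEFAULT_TAU`); missing ``ymax``/``y0`` default to 1 and 0. A
    reaction row missing ``n`` or ``EC50`` is an error: Hill parameters are
    part of the published model definition, not something to guess.
    """
    ndf = _canonicalize(nodes_table, _NODE_ALIASES, "nodes")
    rdf = _canonicalize(reactions_table, _REACTION_ALIASES, "reactions")

    nodes = []
    for i, row in ndf.iterrows():
        cat = str(row.get("category", "intermediate") or "intermediate")
        tau = row.get("tau")
        if tau is None or (isinstance(tau, float) and np.isnan(tau)):
            tau = DEFAULT_TAU[cat] if cat in DEFAULT_TAU else DEFAULT_TAU["intermediate"]
        try:
            nodes.append(
                NodeSpec(
                    id=str(row["id"]).strip(),
                    ymax=float(row.get("ymax", 1.0)) if not pd.isna(row.get("ymax", 1.0)) else 1.0,
                    tau=float(tau),
                    y0=float(row.get("y0", 0.0)) if not pd.isna(row.get("y0", 0.0)) else 0.0,
                    category=cat,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ModelParseError(f"nodes table row {i}: {exc}") from exc

    reactions = []
    for i, row in rdf.iterrows():
        for p in ("n", "ec50"):
            if p not in rdf.columns or pd.isna(row[p]):
                raise ModelParseError(
                    f"reactions table row {i} ({row.get('rule', '?')!r}): missing {p!r}"
                )
        try:
            reactions.append(
                ReactionSpec(
                    rule=str(row["rule"]),
                    w=float(row.get("w", 1.0)) if not pd.isna(row.get("w", 1.0)) else 1.0,
                    n=float(row["n"]),
                    ec50=float(row["ec50"]),
                    id=str(row["id"]).strip() if "id" in rdf.columns and not pd.isna(row.get("id")) else "",
                )
            )
        except ModelParseError as exc:
            raise ModelParseError(f"reactions table row {i}: {exc}") from exc
    return NetworkModel(nodes, reactions)


def read_model(nodes_path: str | Path, reactions_path: str | Path | None = None) -> NetworkModel:
    """Read a model from a spreadsheet workbook or a pair of CSV files.

    A single ``.xlsx`` path is read as a workbook with ``nodes`` and
    ``reactions`` sheets (case-insensitive); otherwise two CSV paths are
    expected.
    """
    nodes_path = Path(nodes_path)
    if nodes_path.suffix.lower() in {".xlsx", ".xls"}:
        book = pd.read_excel(nodes_path, sheet_name=None)
        sheets = {str(k).strip().lower(): v for k, v in book.items()}
        try:
            ndf, rdf = sheets["nodes"], sheets["reactions"]
        except KeyError as exc:
            raise ModelParseError(
                f"workbook {nodes_path.name} must contain 'nodes' and 'reactions' sheets"
            ) from exc
    else:
        if reactions_path is None:
            raise ValueError("reactions_path is required when reading paired CSVs")
        ndf = pd.read_csv(nodes_path)
        rdf = pd.read_csv(reactions_path)
    return parse_model_tables(ndf, rdf)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _compile(model: NetworkModel, perturbation: Perturbation | None):
    """Precompute index arrays and effective parameters for fast RHS calls."""
    pert = perturbation or Perturbation()
    pert.validate(model)
    n_nodes = len(model.nodes)
    ymax = np.array([nd.ymax for nd in model.nodes.values()])
    tau = np.array([nd.tau for nd in model.nodes.values()])
    for nid in pert.knockouts:
        ymax[model.index(nid)] = 0.0
    compiled = []
    for r in model.reactions:
        ov = pert.weight_overrides.get(r.id)
        w = r.w if ov is None else ov
        ops = [(model.index(name), neg) for name, neg in r.operands]
        compiled.append((model.index(r.target), ops, w, r.n, r.ec50))
    return compiled, ymax, tau, n_nodes


def _gated_target(t: float, y: np.ndarray, compiled, ymax: np.ndarray) -> np.ndarray:
    """ymax * OR-combined reaction activations, per node."""
    one_minus = np.ones_like(ymax)
    for target, ops, w, n, ec50 in compiled:
        if callable(w):
            wv = min(max(float(w(t)), 0.0), 1.0)
        else:
            wv = w
        act = wv
        for idx, neg in ops:
            x = min(max(y[idx], 0.0), 1.0)
            f = hill_activation(x, ec50, n)
            act *= (1.0 - f) if neg else f
        one_minus[target] *= 1.0 - act
    return ymax * (1.0 - one_minus)


def ode_rhs(
    state: np.ndarray,
    model: NetworkModel,
    perturbation: Perturbation | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """Instantaneous activity rates ``dy/dt = (ymax*g - y)/tau``."""
    compiled, ymax, tau, _ = _compile(model, perturbation)
    y = np.asarray(state, dtype=float)
    return (_gated_target(t, y, compiled, ymax) - y) / tau


@dataclass
class Trajectory:
    """Node activities on a t/tau grid."""

    times: np.ndarray
    activities: np.ndarray  # shape (n_times, n_nodes)
    node_ids: list[str]

    def activity(self, node_id: str) -> np.ndarray:
        return self.activities[:, self.node_ids.index(node_id)]

    def final_state(self) -> np.ndarray:
        return self.activities[-1].copy()

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, node, activity) table."""
        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, len(self.node_ids)),
                "node": np.tile(self.node_ids, n_t),
                "activity": self.activities.ravel(),
            }
        )


def integrate(
    model: NetworkModel,
    perturbation: Perturbation | None = None,
    t_span: tuple[float, float] = (0.0, 5.0),
    t_eval: np.ndarray | None = None,
    y_init: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network ODEs over ``t_span`` (t/tau units).

    Time constants in a full-scale model span more than two orders of
    magnitude, so the default solver is stiff-capable (LSODA).
    """
    compiled, ymax, tau, n_nodes = _compile(model, perturbation)

    def rhs(t, y):
        return (_gated_target(t, y, compiled, ymax) - y) / tau

    y0 = model.y0 if y_init is None else np.asarray(y_init, dtype=float)
    if y0.shape != (n_nodes,):
        raise ValueError(f"initial state must have shape ({n_nodes},), got {y0.shape}")
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 201)
    sol = solve_ivp(rhs, t_span, y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    return Trajectory(times=sol.t, activities=sol.y.T, node_ids=model.node_ids)


def fixed_point_state(
    model: NetworkModel,
    perturbation: Perturbation | None = None,
    init_state: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> np.ndarray:
    """Algebraic steady state ``y = ymax * g(y)`` by damped fixed-point iteration.

    Valid only for constant perturbations. Starting from ``init_state``
    (default: the model's y0) this converges to the same equilibrium the
    dynamics reach from that state for the monotone networks used here,
    at a fraction of the cost of time integration; callers that cannot
    assume monotonicity should use :func:`steady_state`.
    """
    pert = perturbation or Perturbation()
    for w in pert.weight_overrides.values():
        if callable(w):
            raise ValueError("fixed_point_state requires a constant perturbation")
    compiled, ymax, tau, _ = _compile(model, pert)
    y = (model.y0 if init_state is None else np.asarray(init_state, dtype=float)).copy()
    for _ in range(max_iter):
        y_new = (1.0 - damping) * y + damping * _gated_target(0.0, y, compiled, ymax)
        if np.max(np.abs(y_new - y)) < tol:
            return y_new
        y = y_new
    raise SteadyStateError(f"fixed-point iteration did not converge in {max_iter} steps")


def steady_state(
    model: NetworkModel,
    perturbation: Perturbation | None = None,
    init_state: np.ndarray | None = None,
    tol: float = 1e-6,
    window: float = 0.1,
    chunk: float = 10.0,
    max_time: float = 500.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate under a constant perturbation until activities settle.

    The criterion is ``max |dy/dt| < tol`` sustained over a trailing window
    of ``window`` t/tau units. Raises :class:`SteadyStateError` if the
    criterion is not met by ``max_time`` (callers treat this as a "runaway"
    candidate).
    """
    pert = perturbation or Perturbation()
    for w in pert.weight_overrides.values():
        if callable(w):
            raise ValueError("steady_state requires a constant perturbation")
    compiled, ymax, tau, _ = _compile(model, pert)

    def rhs(t, y):
        return (_gated_target(t, y, compiled, ymax) - y) / tau

    y = model.y0 if init_state is None else np.asarray(init_state, dtype=float)
    t0 = 0.0
    n_check = 8
    while t0 < max_time:
        t1 = min(t0 + chunk, max_time)
        t_eval = np.linspace(max(t0, t1 - window), t1, n_check)
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"solver failed: {sol.message}")
        rates = np.array([rhs(t, sol.y[:, k]) for k, t in enumerate(sol.t)])
        if np.max(np.abs(rates)) < tol:
            return sol.y[:, -1].copy()
        y = sol.y[:, -1]
        t0 = t1
    raise SteadyStateError(
        f"no steady state within t/tau = {max_time} (max |dy/dt| still >= {tol})"
    )
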