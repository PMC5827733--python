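"""Reference-state construction for an organ-specific network.

Pipeline: gene expression → reaction activity scores (GPR evaluation,
AND→min / OR→max) → active/inactive sets at the 75th/25th percentiles of
the non-zero score distribution → iMAT MILP (maximize agreement between
flux activity and the expression sets, with a minimal biomass flux) →
context network pruning (flux-variability-blocked reactions only) →
intracellular flux-sum minimization with exchange rates and flux
directions held fixed.  The result is the unperturbed reference flux
distribution v_ref that anchors every dynamic MOMA step.

Defaults follow the workflow's published operating point: activity
threshold ε = 1e-5 µmol·liver⁻¹·min⁻¹ and a biomass minimum of
1e-4 µmol·liver⁻¹·min⁻¹.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from dynamoma.network import (
    FluxDistribution,
    MetabolicNetwork,
    build_stoichiometric_matrix,
)
from dynamoma import solvers

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-5
DEFAULT_BIOMASS_MIN = 1e-4


@dataclass
class ExpressionProfile:
    """Gene-level expression intensities (non-negative, finite)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        arr = np.array(list(self.values.values()), dtype=float)
        if arr.size == 0 or not np.all(np.isfinite(arr)):
            raise ValueError("expression profile must be finite and non-empty")
        if np.any(arr < 0):
            raise ValueError("expression intensities must be non-negative")
        if not np.any(arr > 0):
            raise ValueError("expression profile has no non-zero intensity")

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionProfile":
        """Read a gene_id ⇥ intensity TSV; multi-sample files are averaged."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        gene_col = df.columns[0]
        values = df.set_index(gene_col).mean(axis=1, numeric_only=True)
        return cls(values={str(g): float(v) for g, v in values.items()})


@dataclass
class ReactionScoreSet:
    """Reaction activity scores in [0, 1] plus active/inactive sets."""

    scores: dict[str, float]
    active: set[str] = field(default_factory=set)
    inactive: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# GPR evaluation

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _parse_gpr(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


class _GPREvaluator:
    """Tiny recursive-descent evaluator: OR → max, AND → min.

    Genes missing from the profile are unknown and drop out of their
    min/max; a (sub)expression with only unknowns evaluates to None.
    """

    def __init__(self, tokens: list[str], scores: dict[str, float]):
        self.tokens = tokens
        self.pos = 0
        self.scores = scores
        self.missing: set[str] = set()

    def _peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def expr(self) -> float | None:
        vals = [self.term()]
        while self._peek() is not None and self._peek().lower() == "or":
            self.pos += 1
            vals.append(self.term())
        known = [v for v in vals if v is not None]
        return max(known) if known else None

    def term(self) -> float | None:
        vals = [self.factor()]
        while self._peek() is not None and self._peek().lower() == "and":
            self.pos += 1
            vals.append(self.factor())
        known = [v for v in vals if v is not None]
        return min(known) if known else None

    def factor(self) -> float | None:
        tok = self._peek()
        if tok is None:
            raise ValueError("truncated GPR expression")
        if tok == "(":
            self.pos += 1
            val = self.expr()
            if self._peek() != ")":
                raise ValueError("unbalanced parentheses in GPR")
            self.pos += 1
            return val
        self.pos += 1
        if tok in self.scores:
            return self.scores[tok]
        self.missing.add(tok)
        return None


def evaluate_gpr(rule: str, gene_scores: dict[str, float]) -> tuple[float | None, set[str]]:
    """Evaluate one GPR rule; returns (score or None, missing gene ids)."""
    tokens = _parse_gpr(rule)
    if not tokens:
        return None, set()
    ev = _GPREvaluator(tokens, gene_scores)
    val = ev.expr()
    if ev.pos != len(tokens):
        raise ValueError(f"could not parse GPR rule {rule!r}")
    return val, ev.missing


def reaction_scores(net: MetabolicNetwork, expr: ExpressionProfile) -> ReactionScoreSet:
    """Translate gene intensities to reaction scores via the GPR rules.

    Intensities are normalized to a maximum of 1 first; reactions with an
    empty GPR receive no score and join neither set.
    """
    peak = max(expr.values.values())
    gene_scores = {g: v / peak for g, v in expr.values.items()}
    scores: dict[str, float] = {}
    all_missing: set[str] = set()
    for r in net.reactions:
        if not r.gpr.strip():
            continue
        val, missing = evaluate_gpr(r.gpr, gene_scores)
        all_missing |= missing
        if val is not None:
            scores[r.id] = val
    if all_missing:
        logger.warning(
            "genes in GPR rules missing from the expression profile: %s",
            sorted(all_missing),
        )
    return ReactionScoreSet(scores=scores)


def threshold_sets(score_set: ReactionScoreSet) -> ReactionScoreSet:
    """Fill active/inactive sets from the non-zero score distribution.

    Active: score ≥ 75th percentile of non-zero scores; inactive: score ≤
    25th percentile, plus all zero-scored reactions.  Percentiles use
    linear interpolation on the sorted non-zero score vector.  A reaction
    qualifying for both (degenerate, e.g. uniform scores) is assigned to
    the active set with a warning.
    """
    scores = score_set.scores
    if len(scores) < 4:
        nz = [r for r, s in scores.items() if s > 0]
        if not nz and scores:
            raise ValueError("all reaction scores are zero: no expression signal")
        active = set(nz)
        inactive = {r for r, s in scores.items() if s == 0}
        return ReactionScoreSet(scores=dict(scores), active=active, inactive=inactive)
    nonzero = np.array([s for s in scores.values() if s > 0], dtype=float)
    if nonzero.size == 0:
        raise ValueError("all reaction scores are zero: no expression signal")
    hi = float(np.percentile(nonzero, 75, method="linear"))
    lo = float(np.percentile(nonzero, 25, method="linear"))
    active = {r for r, s in scores.items() if s > 0 and s >= hi}
    inactive = {r for r, s in scores.items() if s == 0 or (s <= lo and r not in active)}
    overlap = {r for r, s in scores.items() if s > 0 and s >= hi and s <= lo}
    if overlap:
        logger.warning(
            "active/inactive thresholds overlap for %d reactions; assigned active",
            len(overlap),
        )
    return ReactionScoreSet(scores=dict(scores), active=active, inactive=inactive)


# ---------------------------------------------------------------------------
# physiological exchange constraints


def apply_fasted_state(
    net: MetabolicNetwork, utilization: dict[str, tuple[float, float]]
) -> MetabolicNetwork:
    """Apply a metabolite-utilization table to the exchange reactions.

    Every exchange reaction absent from the table is closed ([0, 0]);
    listed exchanges get the given (lb, ub) in the secretion-positive
    convention (lb < 0 permits uptake).  This encodes the physiological
    scenario — e.g. a fasted liver taking up gluconeogenic substrates,
    fatty acids, amino acids, gases and minerals while secreting glucose,
    urea, ketone bodies and export proteins.
    """
    out = net.copy()
    exchange_ids = {r.id for r in out.reactions if r.role == "exchange"}
    for rid in utilization:
        if rid not in exchange_ids:
            raise ValueError(f"utilization table id {rid!r} is not an exchange reaction")
    if not utilization:
        logger.warning("empty utilization table: every exchange reaction is closed")
    for r in out.reactions:
        if r.role != "exchange":
            continue
        if r.id in utilization:
            lb, ub = utilization[r.id]
            if lb > ub:
                raise ValueError(f"utilization bounds for {r.id!r}: lb {lb} > ub {ub}")
            r.lower_bound, r.upper_bound = float(lb), float(ub)
        else:
            r.lower_bound = r.upper_bound = 0.0
    return out


def read_utilization_table(path: str) -> dict[str, tuple[float, float]]:
    """Read an exchange-bounds CSV with columns exchange_id, lb, ub."""
    import pandas as pd

    df = pd.read_csv(path)
    return {
        str(row["exchange_id"]): (float(row["lb"]), float(row["ub"]))
        for _, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# iMAT


def _imat_milp(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    active_idx: list[int],
    inactive_idx: list[int],
    eps: float,
) -> tuple[np.ndarray, int]:
    """Solve the iMAT MILP; returns (flux vector, #satisfied reactions).

    Binary indicators y⁺/y⁻ force |v| ≥ ε through an active reaction
    (forward or, when reversible, backward) and z forces |v| ≤ ε through
    an inactive one.  The objective maximizes the number of satisfied
    indicators; a small index-weighted penalty on the binaries (total
    weight < 0.5, below the integrality gap) makes the chosen optimum
    deterministic across runs.
    """
    m, n = S.shape
    cols: list[np.ndarray] = []  # binary constraint columns appended after v
    rows_A: list[np.ndarray] = []
    rows_lo: list[float] = []
    rows_hi: list[float] = []
    binary_gain: list[float] = []  # +1 if the binary counts toward the objective

    def new_binary() -> int:
        cols.append(np.zeros(0))  # placeholder; width fixed later
        return len(cols) - 1

    entries: list[tuple[int, int, float]] = []  # (row, binary_index, coeff)

    def add_row(v_col: int, v_coeff: float, b_idx: int, b_coeff: float,
                lo: float, hi: float) -> None:
        row = np.zeros(n)
        row[v_col] = v_coeff
        rows_A.append(row)
        entries.append((len(rows_A) - 1, b_idx, b_coeff))
        rows_lo.append(lo)
        rows_hi.append(hi)

    pair_rows: list[tuple[int, int]] = []  # (y_plus, y_minus) exclusivity
    for j in active_idx:
        yp = new_binary()
        binary_gain.append(1.0)
        # v_j - (eps - lb_j)*yp >= lb_j  (yp = 1 -> v_j >= eps)
        add_row(j, 1.0, yp, -(eps - lb[j]), lb[j], np.inf)
        if lb[j] < -eps:
            ym = new_binary()
            binary_gain.append(1.0)
            # v_j + (eps + ub_j)*ym <= ub_j  (ym = 1 -> v_j <= -eps)
            add_row(j, 1.0, ym, (eps + ub[j]), -np.inf, ub[j])
            pair_rows.append((yp, ym))
    for j in inactive_idx:
        z = new_binary()
        binary_gain.append(1.0)
        # z = 1 -> v_j <= eps:   v_j + (ub_j - eps)*z <= ub_j
        add_row(j, 1.0, z, (ub[j] - eps), -np.inf, ub[j])
        # z = 1 -> v_j >= -eps:  v_j + (eps + lb_j)*z >= lb_j
        add_row(j, 1.0, z, (eps + lb[j]), lb[j], np.inf)

    nb = len(cols)
    n_rows = len(rows_A)
    A = np.zeros((n_rows + m + len(pair_rows), n + nb))
    lo = np.zeros(n_rows + m + len(pair_rows))
    hi = np.zeros_like(lo)
    for i, row in enumerate(rows_A):
        A[i, :n] = row
        lo[i], hi[i] = rows_lo[i], rows_hi[i]
    for i, b, coeff in entries:
        A[i, n + b] = coeff
    A[n_rows:n_rows + m, :n] = S
    lo[n_rows:n_rows + m] = 0.0
    hi[n_rows:n_rows + m] = 0.0
    for k, (yp, ym) in enumerate(pair_rows):
        A[n_rows + m + k, n + yp] = 1.0
        A[n_rows + m + k, n + ym] = 1.0
        lo[n_rows + m + k] = -np.inf
        hi[n_rows + m + k] = 1.0

    # objective: maximize satisfied binaries, deterministic tie-break
    c = np.zeros(n + nb)
    wsum = nb * (nb + 1) / 2.0 if nb else 1.0
    for b in range(nb):
        c[n + b] = -binary_gain[b] + 0.4 * (b + 1) / wsum
    integrality = np.concatenate([np.zeros(n), np.ones(nb)])
    bounds = Bounds(
        lb=np.concatenate([lb, np.zeros(nb)]),
        ub=np.concatenate([ub, np.ones(nb)]),
    )
    res = milp(
        c,
        constraints=[LinearConstraint(A, lo, hi)],
        integrality=integrality,
        bounds=bounds,
    )
    if res.status != 0 or res.x is None:
        raise solvers.LPInfeasibleError(f"iMAT MILP failed: {res.message}")
    v = res.x[:n]
    satisfied = int(round(np.sum(res.x[n:])))
    return v, satisfied


def imat_fit(
    net: MetabolicNetwork,
    sets: ReactionScoreSet,
    eps: float = DEFAULT_EPSILON,
    biomass_min: float = DEFAULT_BIOMASS_MIN,
) -> tuple[MetabolicNetwork, FluxDistribution, int]:
    """Extract the context network and its consistent flux distribution.

    Returns (context network, iMAT flux distribution, #satisfied
    indicators).  A reaction is pruned only when it carries |v| < ε in
    the MILP solution *and* flux variability analysis over the
    iMAT-constrained model shows it can never reach |v| ≥ ε — a solution
    that happens to leave a reaction idle is not enough, because the MILP
    optimum need not be unique.
    """
    S = build_stoichiometric_matrix(net)
    lb, ub = net.bounds_arrays()
    bio = net.biomass_id
    if bio is not None:
        jb = net.reaction_index(bio)
        lb[jb] = max(lb[jb], biomass_min)
        if lb[jb] > ub[jb]:
            raise solvers.LPInfeasibleError(
                f"biomass minimum {biomass_min} exceeds the biomass upper bound"
            )
    rid_index = {rid: k for k, rid in enumerate(net.reaction_ids)}
    active_idx = sorted(rid_index[r] for r in sets.active if r in rid_index)
    inactive_idx = sorted(rid_index[r] for r in sets.inactive if r in rid_index)

    if not active_idx and not inactive_idx:
        v = solvers.feasible_point(S, lb, ub)
        if v is None:
            raise solvers.LPInfeasibleError(
                "infeasible under the biomass minimum: "
                + solvers.diagnose_infeasibility(
                    S, lb, ub, net.metabolite_ids, net.reaction_ids
                )
            )
        return net.copy(), FluxDistribution.from_array(v, net), 0

    try:
        v, satisfied = _imat_milp(S, lb, ub, active_idx, inactive_idx, eps)
    except solvers.LPInfeasibleError:
        raise solvers.LPInfeasibleError(
            "iMAT infeasible under the biomass minimum: "
            + solvers.diagnose_infeasibility(S, lb, ub, net.metabolite_ids, net.reaction_ids)
        ) from None
    if satisfied == 0:
        logger.warning("iMAT satisfied no expression indicator (eps may be too large)")

    # prune reactions that are idle in the solution and FVA-blocked;
    # xenobiotic reactions are exempt — they are closed ([0, 0]) by
    # construction until the coupling loop pins them to the PK rates, so
    # FVA necessarily reports them blocked, yet they must stay in the
    # context network
    keep_roles = {"xenobiotic", "biomass"}
    idle = [
        j for j in range(S.shape[1])
        if abs(v[j]) < eps and net.reactions[j].role not in keep_roles
    ]
    vmin, vmax = solvers.fva(S, lb, ub, idle)
    blocked = {
        net.reaction_ids[j]
        for k, j in enumerate(idle)
        if max(abs(vmin[k]), abs(vmax[k])) < eps
    }
    ctx = net.copy()
    ctx.reactions = [r for r in ctx.reactions if r.id not in blocked]
    used = {mid for r in ctx.reactions for mid in r.stoichiometry}
    ctx.metabolites = [mm for mm in ctx.metabolites if mm.id in used]
    ctx.id = f"{net.id}_context"
    ctx._index()

    # re-project the MILP flux onto the pruned network so S·v = 0 holds
    # exactly without the (sub-ε) fluxes of removed reactions
    S_ctx = build_stoichiometric_matrix(ctx)
    lb_ctx, ub_ctx = ctx.bounds_arrays()
    if bio is not None and ctx.has_reaction(bio):
        jb = ctx.reaction_index(bio)
        lb_ctx[jb] = max(lb_ctx[jb], biomass_min)
    keep = [rid_index[rid] for rid in ctx.reaction_ids]
    qp = solvers.solve_box_qp(S_ctx, lb_ctx, ub_ctx, v[keep])
    return ctx, FluxDistribution.from_array(qp.x, ctx), satisfied


# ---------------------------------------------------------------------------
# flux-sum minimization and the reference state


@dataclass
class ReferenceState:
    """Context network + unperturbed reference flux distribution."""

    network: MetabolicNetwork
    v_ref: FluxDistribution
    epsilon: float = DEFAULT_EPSILON
    biomass_min: float = DEFAULT_BIOMASS_MIN
    fixed_directions: dict[str, int] = field(default_factory=dict)

    def v_ref_array(self) -> np.ndarray:
        return self.v_ref.as_array(self.network)

    def save(self, outdir: str) -> None:
        """Write the state as network JSON + flux CSV + metadata JSON."""
        import json
        import os

        import pandas as pd

        from dynamoma.network import write_network

        os.makedirs(outdir, exist_ok=True)
        write_network(self.network, os.path.join(outdir, "context_network.json"))
        pd.DataFrame(
            sorted(self.v_ref.values.items()), columns=["reaction_id", "flux"]
        ).to_csv(os.path.join(outdir, "v_ref.csv"), index=False)
        with open(os.path.join(outdir, "reference_state.json"), "w") as fh:
            json.dump(
                {
                    "epsilon": self.epsilon,
                    "biomass_min": self.biomass_min,
                    "fixed_directions": self.fixed_directions,
                },
                fh,
                indent=1,
            )
            fh.write("\n")

    @classmethod
    def load(cls, outdir: str) -> "ReferenceState":
        import json
        import os

        import pandas as pd

        from dynamoma.network import load_network

        net = load_network(os.path.join(outdir, "context_network.json"), "json")
        df = pd.read_csv(os.path.join(outdir, "v_ref.csv"))
        values = {str(r["reaction_id"]): float(r["flux"]) for _, r in df.iterrows()}
        with open(os.path.join(outdir, "reference_state.json")) as fh:
            meta = json.load(fh)
        return cls(
            network=net,
            v_ref=FluxDistribution(values=values, network_id=net.id),
            epsilon=float(meta["epsilon"]),
            biomass_min=float(meta["biomass_min"]),
            fixed_directions={k: int(v) for k, v in meta["fixed_directions"].items()},
        )


def minimize_intracellular_flux(
    ctx: MetabolicNetwork,
    v_imat: FluxDistribution,
    eps: float = DEFAULT_EPSILON,
    biomass_min: float = DEFAULT_BIOMASS_MIN,
) -> ReferenceState:
    """Minimize the intracellular flux sum around the iMAT solution.

    Exchange fluxes are fixed to their iMAT values; every reaction that
    carries |v| ≥ ε keeps its flux direction; biomass keeps its minimum.
    The L1 objective runs over all non-exchange reactions (biomass and
    xenobiotic reactions count as intracellular for flux-sum purposes).
    """
    S = build_stoichiometric_matrix(ctx)
    lb, ub = ctx.bounds_arrays()
    v0 = v_imat.as_array(ctx)
    fixed_directions: dict[str, int] = {}
    intracellular_idx: list[int] = []
    for j, r in enumerate(ctx.reactions):
        if r.role == "exchange":
            lb[j] = ub[j] = v0[j]
            continue
        intracellular_idx.append(j)
        if r.id == ctx.biomass_id:
            lb[j] = max(lb[j], biomass_min)
        if v0[j] >= eps:
            lb[j] = max(lb[j], 0.0)
            fixed_directions[r.id] = 1
        elif v0[j] <= -eps:
            ub[j] = min(ub[j], 0.0)
            fixed_directions[r.id] = -1
    try:
        v = solvers.minimize_l1(S, lb, ub, intracellular_idx)
    except solvers.LPInfeasibleError:
        raise solvers.LPInfeasibleError(
            "flux-sum minimization infeasible: "
            + solvers.diagnose_infeasibility(S, lb, ub, ctx.metabolite_ids, ctx.reaction_ids)
        ) from None
    return ReferenceState(
        network=ctx,
        v_ref=FluxDistribution.from_array(v, ctx),
        epsilon=eps,
        biomass_min=biomass_min,
        fixed_directions=fixed_directions,
    )


def build_reference_state(
    net: MetabolicNetwork,
    expr: ExpressionProfile,
    utilization: dict[str, tuple[float, float]],
    eps: float = DEFAULT_EPSILON,
    biomass_min: float = DEFAULT_BIOMASS_MIN,
) -> ReferenceState:
    """Full reference-state pipeline on an (already extended) network."""
    constrained = apply_fasted_state(net, utilization)
    sets = threshold_sets(reaction_scores(constrained, expr))
    ctx, v_imat, _ = imat_fit(constrained, sets, eps=eps, biomass_min=biomass_min)
    return minimize_intracellular_flux(ctx, v_imat, eps=eps, biomass_min=biomass_min)
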