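"""Perturbation analytics on a dynamic MOMA flux matrix.

Quantities, all relative to the unperturbed reference state v_ref:

* differential fluxes            Δv_it = v_it − v_ref
* integrated perturbations       P_rxn = ∫|Δv| dt (µmol·liver⁻¹), P_ex for
  exchange reactions (µmol), and P_PBPK for the xenobiotic driver
* significance                   a reaction is significantly altered when
  P_rxn exceeds the integrated activity threshold: P_rxn > ε·t
* pathway perturbation           P_MP = Σ P_rxn over a cluster's
  significant reactions
* attenuation                    AT_MP(t) = Σ_{j≤t} P_MP,j / P_MP, the
  cumulative normalized time course of a pathway's perturbation
* pathway score                  PS = P_MP / P_PBPK — >1 aggravation,
  (0,1) partial perturbation, 0 independence
* altered fraction               per-timepoint share of reactions with
  |Δv| > ε
* exometabolome pools            signed ∫Δv_ex dt classifies each
  exchanged metabolite's pool as increased or decreased

Integrals use left-rectangle sums with the coupling step dt — the QP
yields piecewise-constant fluxes per step, so the rectangle rule is the
discretization-consistent choice (trapezoid is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dynamoma.coupling import FluxMatrix
from dynamoma.network import MetabolicNetwork
from dynamoma.reference import ReferenceState

#: pool changes beyond this magnitude (µmol) are flagged as notable
POOL_FLAG_THRESHOLD = 50.0


@dataclass
class PathwayClustering:
    """Reaction → pathway-cluster labels (each reaction in ≤ 1 cluster)."""

    mapping: dict[str, str]

    def validate(self, net: MetabolicNetwork) -> None:
        unknown = [rid for rid in self.mapping if not net.has_reaction(rid)]
        if unknown:
            raise ValueError(f"clustered reactions absent from the network: {unknown}")

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def members(self, cluster: str) -> list[str]:
        return [rid for rid, cl in self.mapping.items() if cl == cluster]

    @classmethod
    def from_csv(cls, path: str) -> "PathwayClustering":
        df = pd.read_csv(path)
        return cls({str(r["reaction_id"]): str(r["cluster"]) for _, r in df.iterrows()})

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["reaction_id", "cluster"]
        ).to_csv(path, index=False)

    @classmethod
    def from_network(cls, net: MetabolicNetwork) -> "PathwayClustering":
        return cls({r.id: r.pathway_cluster for r in net.reactions if r.pathway_cluster})

    def restrict_to(self, net: MetabolicNetwork) -> "PathwayClustering":
        """Drop entries for reactions absent from `net`.

        A clustering prepared for the full input network may label
        reactions that contextualization pruned; those carry no flux and
        can be discarded safely.
        """
        return PathwayClustering(
            {rid: cl for rid, cl in self.mapping.items() if net.has_reaction(rid)}
        )


def differential_fluxes(fm: FluxMatrix, ref: ReferenceState) -> np.ndarray:
    """Δv_it = v_it − v_ref; positive means an increased flux."""
    if fm.reaction_ids != ref.network.reaction_ids:
        raise ValueError("flux matrix and reference cover different reaction sets")
    v_ref = ref.v_ref_array()
    return fm.values - v_ref[:, None]


def _step_weights(times: np.ndarray, rule: str) -> np.ndarray:
    dt = np.diff(times)
    if not np.allclose(dt, dt[0]):
        raise ValueError("non-uniform time grid")
    if rule == "rectangle":
        w = np.zeros(times.size)
        w[:-1] = dt[0]
    elif rule == "trapezoid":
        w = np.full(times.size, dt[0])
        w[0] = w[-1] = dt[0] / 2
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    return w


def integrate_perturbation(
    delta: np.ndarray,
    times: np.ndarray,
    which: str = "rxn",
    rule: str = "rectangle",
):
    """Time-integrated absolute perturbations.

    ``which="rxn"`` / ``"ex"``: per-row ∫|Δv| dt (the caller passes the
    appropriate row subset for exchanges).  ``which="pbpk"``: the rows are
    the xenobiotic reactions; their absolute deviations are summed first,
    yielding the scalar driver perturbation.
    """
    delta = np.atleast_2d(delta)
    w = _step_weights(np.asarray(times, dtype=float), rule)
    if which in ("rxn", "ex"):
        return np.abs(delta) @ w
    if which == "pbpk":
        return float(np.sum(np.abs(delta), axis=0) @ w)
    raise ValueError(f"unknown integration target {which!r}")


def significance_mask(p_rxn: dict[str, float], eps: float, t_total: float) -> set[str]:
    """Reactions whose accumulated perturbation exceeds ε·t (strictly)."""
    if eps <= 0 or t_total <= 0:
        raise ValueError("eps and t_total must be positive")
    threshold = eps * t_total
    return {rid for rid, p in p_rxn.items() if p > threshold}


def pathway_perturbation(
    p_rxn: dict[str, float], sig: set[str], clusters: PathwayClustering
) -> dict[str, float]:
    """P_MP per cluster: sum of P_rxn over its significantly altered members."""
    out = {cl: 0.0 for cl in clusters.clusters}
    for rid, cl in clusters.mapping.items():
        if rid in sig and rid in p_rxn:
            out[cl] += p_rxn[rid]
    return out


def attenuation_curve(p_mp_series: np.ndarray, p_mp_total: float) -> np.ndarray:
    """Cumulative normalized perturbation time course (AT_MP).

    Non-decreasing, in [0, 1], ending at 1.  Undefined for an unperturbed
    cluster (P_MP = 0): returns an empty array.
    """
    if p_mp_total <= 0:
        return np.array([])
    return np.cumsum(p_mp_series) / p_mp_total


def pathway_score(p_mp: dict[str, float], p_pbpk: float) -> dict[str, float]:
    """PS = P_MP / P_PBPK per cluster.

    A zero driver with a nonzero pathway perturbation signals an upstream
    inconsistency and raises; a fully null run scores every cluster 0.
    """
    if p_pbpk < 0:
        raise ValueError("P_PBPK must be non-negative")
    if p_pbpk == 0:
        if any(v > 0 for v in p_mp.values()):
            raise ValueError("nonzero pathway perturbation with a zero driver (P_PBPK=0)")
        return {cl: 0.0 for cl in p_mp}
    return {cl: v / p_pbpk for cl, v in p_mp.items()}


def altered_fraction(delta: np.ndarray, eps: float) -> np.ndarray:
    """Per-timepoint fraction of reactions with |Δv_it| > ε."""
    delta = np.atleast_2d(delta)
    return (np.abs(delta) > eps).sum(axis=0) / delta.shape[0]


def exometabolome_pools(
    delta_ex: np.ndarray,
    times: np.ndarray,
    exchange_ids: list[str],
    rule: str = "rectangle",
) -> pd.DataFrame:
    """Signed and absolute exometabolome pool changes per exchange.

    Internally positive exchange flux is secretion, so a positive signed
    integral means the extracellular pool *gains* the metabolite
    ("increased"); the ``uptake_positive`` column carries the opposite
    organ-centric sign convention used in hepatic mass-balance tables.
    """
    delta_ex = np.atleast_2d(delta_ex)
    w = _step_weights(np.asarray(times, dtype=float), rule)
    signed = delta_ex @ w
    absolute = np.abs(delta_ex) @ w
    df = pd.DataFrame(
        {
            "exchange_id": exchange_ids,
            "signed_change_umol": signed,
            "p_ex_umol": absolute,
            "uptake_positive_umol": -signed,
        }
    )
    df["direction"] = np.where(
        signed > 0, "increased", np.where(signed < 0, "decreased", "unchanged")
    )
    df["flagged"] = np.abs(signed) > POOL_FLAG_THRESHOLD
    return df


@dataclass
class PerturbationReport:
    """All downstream response quantities of one dynamic MOMA run."""

    p_rxn: dict[str, float]
    p_pbpk: float
    significant: set[str]
    p_mp: dict[str, float]
    at_mp: dict[str, np.ndarray]
    pathway_scores: dict[str, float]
    altered_fraction: np.ndarray
    pools: pd.DataFrame
    epsilon: float
    t_total: float
    times: np.ndarray = field(repr=False, default=None)

    @property
    def p_ex_abs(self) -> dict[str, float]:
        return dict(zip(self.pools["exchange_id"], self.pools["p_ex_umol"]))

    @property
    def p_ex_signed(self) -> dict[str, float]:
        return dict(zip(self.pools["exchange_id"], self.pools["signed_change_umol"]))

    def to_tables(self) -> dict[str, pd.DataFrame]:
        per_rxn = pd.DataFrame(
            {
                "reaction_id": list(self.p_rxn),
                "p_rxn_umol": list(self.p_rxn.values()),
                "significant": [r in self.significant for r in self.p_rxn],
            }
        )
        per_cluster = pd.DataFrame(
            {
                "cluster": list(self.p_mp),
                "p_mp_umol": list(self.p_mp.values()),
                "pathway_score": [self.pathway_scores[c] for c in self.p_mp],
            }
        )
        return {"reactions": per_rxn, "clusters": per_cluster, "exchanges": self.pools}

    def to_json_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "t_total_min": self.t_total,
            "p_pbpk": self.p_pbpk,
            "n_significant": len(self.significant),
            "pathway_scores": self.pathway_scores,
            "p_mp": self.p_mp,
        }


def perturbation_report(
    fm: FluxMatrix,
    ref: ReferenceState,
    clusters: PathwayClustering,
    rule: str = "rectangle",
) -> PerturbationReport:
    """Compute the full perturbation report for one run."""
    clusters.validate(ref.network)
    net = ref.network
    delta = differential_fluxes(fm, ref)
    times = fm.times
    t_total = float(times[-1] - times[0])
    eps = ref.epsilon

    p_vals = integrate_perturbation(delta, times, "rxn", rule)
    p_rxn = dict(zip(fm.reaction_ids, map(float, p_vals)))

    xen_rows = [fm.reaction_ids.index(r) for r in net.reactions_with_role("xenobiotic")]
    p_pbpk = integrate_perturbation(delta[xen_rows], times, "pbpk", rule) if xen_rows else 0.0

    sig = significance_mask(p_rxn, eps, t_total)
    p_mp = pathway_perturbation(p_rxn, sig, clusters)

    # per-step cluster perturbation for the attenuation curves; the
    # significance mask is the global one, so the curve's total equals P_MP
    w = _step_weights(times, rule)
    at_mp: dict[str, np.ndarray] = {}
    idx = {rid: i for i, rid in enumerate(fm.reaction_ids)}
    for cl in clusters.clusters:
        rows = [idx[r] for r in clusters.members(cl) if r in sig and r in idx]
        if rows and p_mp[cl] > 0:
            per_step = (np.abs(delta[rows]) * w[None, :]).sum(axis=0)[:-1]
            at_mp[cl] = attenuation_curve(per_step, p_mp[cl])
        else:
            at_mp[cl] = np.array([])

    scores = pathway_score(p_mp, p_pbpk)

    ex_ids = [r.id for r in net.reactions if r.role == "exchange"]
    ex_rows = [idx[r] for r in ex_ids]
    pools = exometabolome_pools(delta[ex_rows], times, ex_ids, rule)

    return PerturbationReport(
        p_rxn=p_rxn,
        p_pbpk=p_pbpk,
        significant=sig,
        p_mp=p_mp,
        at_mp=at_mp,
        pathway_scores=scores,
        altered_fraction=altered_fraction(delta, eps),
        pools=pools,
        epsilon=eps,
        t_total=t_total,
        times=times,
    )


def compare_reports(
    rep_a: PerturbationReport, rep_b: PerturbationReport
) -> dict[str, pd.DataFrame]:
    """Two-run comparison: pathway-score and pool differences (b − a).

    Clusters or exchanges present in only one run appear with an explicit
    zero on the other side.
    """
    clusters = sorted(set(rep_a.pathway_scores) | set(rep_b.pathway_scores))
    ps = pd.DataFrame(
        {
            "cluster": clusters,
            "score_a": [rep_a.pathway_scores.get(c, 0.0) for c in clusters],
            "score_b": [rep_b.pathway_scores.get(c, 0.0) for c in clusters],
        }
    )
    ps["score_diff_b_minus_a"] = ps["score_b"] - ps["score_a"]
    ex = sorted(set(rep_a.p_ex_signed) | set(rep_b.p_ex_signed))
    pools = pd.DataFrame(
        {
            "exchange_id": ex,
            "signed_a": [rep_a.p_ex_signed.get(e, 0.0) for e in ex],
            "signed_b": [rep_b.p_ex_signed.get(e, 0.0) for e in ex],
        }
    )
    pools["signed_diff_b_minus_a"] = pools["signed_b"] - pools["signed_a"]
    return {"pathway_scores": ps, "pools": pools}
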