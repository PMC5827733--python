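"""Deterministic toy fixtures emulating the workflow's four input kinds.

The generator produces, at toy scale, everything a real run needs from
external data: a compartmentalized liver-like network (JSON), a
gene-expression table (TSV), a fasted-state metabolite-utilization table
(CSV) and a pathway-clustering table (CSV).  The network is built so that

* all cofactor pools needed by the isoniazid xenobiotic preset exist at
  the right locations (cytosolic AcCoA/CoA, GSH, NADPH/NADP, O2, H2O;
  mitochondrial glycine),
* a biomass reaction is feasible (≥ 1e-4 µmol·liver⁻¹·min⁻¹) under the
  generated utilization table,
* an alternative gluconeogenic branch with low expression exercises the
  iMAT branch choice, and two dead-end reactions exercise the
  flux-variability pruning rule,
* a stoichiometrically disconnected two-reaction subnetwork (its own
  exchanges, transports and pathway cluster) provides a pathway that no
  xenobiotic perturbation can reach.

Everything is deterministic for a given seed; the "small" network is
fixed and the seed only randomizes the extra pathway chains of the
"medium" size.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dynamoma.network import (
    Metabolite,
    MetabolicNetwork,
    Reaction,
    write_network,
)

CYT, MIT, EXT = "cytosol", "mitochondria", "extracellular"


def _met(mid: str, comp: str) -> Metabolite:
    return Metabolite(id=mid, compartment=comp)


def _rxn(rid, stoich, lb=0.0, ub=1000.0, gpr="", cluster="", role="intracellular"):
    return Reaction(
        id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
        gpr=gpr, pathway_cluster=cluster, role=role,
    )


#: gene intensities (arbitrary units); max normalizes to 1
_EXPRESSION = {
    "g_gng": 1000.0,
    "g_rx": 950.0,
    "g_ldh": 900.0,
    "g_resp": 800.0,
    "g_ppp": 780.0,
    "g_acs": 750.0,
    "g_gshs": 700.0,
    "g_dead2": 120.0,
    "g_dead": 100.0,
    "g_alt": 50.0,
}

#: fasted-state utilization: uptake of a gluconeogenic substrate, amino
#: acid, gases; secretion of glucose (secretion-positive convention)
_UTILIZATION = {
    "EX_lac": (-20.0, 0.0),
    "EX_o2": (-10.0, 0.0),
    "EX_gly": (-5.0, 0.0),
    "EX_h2o": (-10.0, 10.0),
    "EX_glc": (0.0, 10.0),
    "EX_x1": (-1.0, 0.0),
    "EX_x2": (0.0, 1.0),
}


def _small_network() -> MetabolicNetwork:
    mets = [
        # extracellular
        _met("lac_e", EXT), _met("o2_e", EXT), _met("gly_e", EXT),
        _met("glc_e", EXT), _met("h2o_e", EXT), _met("x1_e", EXT), _met("x2_e", EXT),
        # cytosol
        _met("lac_c", CYT), _met("pyr_c", CYT), _met("glc_c", CYT),
        _met("accoa_c", CYT), _met("coa_c", CYT), _met("gsh_c", CYT),
        _met("nadph_c", CYT), _met("nadp_c", CYT), _met("o2_c", CYT),
        _met("h2o_c", CYT), _met("gly_c", CYT), _met("x1_c", CYT),
        _met("x2_c", CYT), _met("dead_c", CYT), _met("dead2_c", CYT),
        # mitochondria
        _met("gly_m", MIT),
    ]
    EXC = "exchange reactions"
    TRN = "intracellular transport"
    CCM = "central carbon metabolism"
    COF = "cofactor metabolism"
    GSH = "glutathione metabolism"
    ISO = "isolated pathway"
    rxns = [
        # exchanges (single extracellular metabolite, coefficient −1)
        _rxn("EX_lac", {"lac_e": -1}, -20, 0, cluster=EXC, role="exchange"),
        _rxn("EX_o2", {"o2_e": -1}, -10, 0, cluster=EXC, role="exchange"),
        _rxn("EX_gly", {"gly_e": -1}, -5, 0, cluster=EXC, role="exchange"),
        _rxn("EX_glc", {"glc_e": -1}, 0, 10, cluster=EXC, role="exchange"),
        _rxn("EX_h2o", {"h2o_e": -1}, -10, 10, cluster=EXC, role="exchange"),
        _rxn("EX_x1", {"x1_e": -1}, -1, 0, cluster=EXC, role="exchange"),
        _rxn("EX_x2", {"x2_e": -1}, 0, 1, cluster=EXC, role="exchange"),
        # transport
        _rxn("T_lac", {"lac_e": -1, "lac_c": 1}, 0, 1000, cluster=TRN),
        _rxn("T_o2", {"o2_e": -1, "o2_c": 1}, 0, 1000, cluster=TRN),
        _rxn("T_gly", {"gly_e": -1, "gly_c": 1}, 0, 1000, cluster=TRN),
        _rxn("T_glc", {"glc_c": -1, "glc_e": 1}, 0, 1000, cluster=TRN),
        _rxn("T_h2o", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000, cluster=TRN),
        _rxn("T_glym", {"gly_c": -1, "gly_m": 1}, 0, 1000, cluster=TRN),
        _rxn("T_x1", {"x1_e": -1, "x1_c": 1}, 0, 1000, cluster=ISO),
        _rxn("T_x2", {"x2_c": -1, "x2_e": 1}, 0, 1000, cluster=ISO),
        # central carbon
        _rxn("LDH", {"lac_c": -1, "pyr_c": 1}, 0, 1000, gpr="g_ldh", cluster=CCM),
        _rxn("GNG", {"pyr_c": -2, "glc_c": 1}, 0, 1000, gpr="g_gng", cluster=CCM),
        _rxn("GNG_ALT", {"pyr_c": -2, "glc_c": 1}, 0, 1000, gpr="g_alt", cluster=CCM),
        _rxn("RESP", {"pyr_c": -1, "o2_c": -1, "h2o_c": 1}, 0, 1000,
             gpr="g_resp", cluster=CCM),
        # cofactors
        _rxn("PPP", {"glc_c": -1, "nadp_c": -2, "pyr_c": 1, "nadph_c": 2},
             0, 1000, gpr="g_ppp", cluster=COF),
        _rxn("ACS", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1}, 0, 1000,
             gpr="g_acs", cluster=COF),
        # glutathione
        _rxn("GSHS", {"gly_c": -1, "accoa_c": -1, "gsh_c": 1, "coa_c": 1},
             0, 1000, gpr="g_gshs", cluster=GSH),
        # dead ends (flux-variability-blocked; low expression)
        _rxn("DEAD", {"pyr_c": -1, "dead_c": 1}, 0, 1000, gpr="g_dead", cluster=CCM),
        _rxn("DEAD2", {"dead_c": -1, "dead2_c": 1}, 0, 1000, gpr="g_dead2", cluster=CCM),
        # biomass: cofactor turnover + glycine and glutathione drain
        _rxn(
            "BIOMASS",
            {"accoa_c": -0.5, "gsh_c": -0.2, "nadph_c": -0.1, "gly_m": -0.2,
             "coa_c": 0.5, "nadp_c": 0.1},
            0, 1000, cluster="biomass", role="biomass",
        ),
        # disconnected subnetwork (own exchanges; shares no metabolite
        # with the rest of the network)
        _rxn("RX", {"x1_c": -1, "x2_c": 1}, 0, 1000, gpr="g_rx", cluster=ISO),
    ]
    return MetabolicNetwork(
        id="toy_liver_small",
        metabolites=mets,
        reactions=rxns,
        compartments={CYT, MIT, EXT},
        extracellular=EXT,
    )


def _medium_network(rng: np.random.Generator) -> MetabolicNetwork:
    """Small network plus randomized amino-acid-like degradation chains."""
    net = _small_network()
    net.id = "toy_liver_medium"
    n_chains = 12
    for k in range(n_chains):
        aa = f"aa{k}"
        net.metabolites.extend(
            [_met(f"{aa}_e", EXT), _met(f"{aa}_c", CYT), _met(f"{aa}int_c", CYT)]
        )
        cap = float(np.round(rng.uniform(1.0, 5.0), 3))
        expr_gene = f"g_{aa}"
        net.reactions.extend(
            [
                _rxn(f"EX_{aa}", {f"{aa}_e": -1}, -cap, 0,
                     cluster="exchange reactions", role="exchange"),
                _rxn(f"T_{aa}", {f"{aa}_e": -1, f"{aa}_c": 1}, 0, 1000,
                     cluster="intracellular transport"),
                _rxn(f"DEAM_{aa}", {f"{aa}_c": -1, f"{aa}int_c": 1}, 0, 1000,
                     gpr=expr_gene, cluster="amino acid metabolism"),
                _rxn(f"CAT_{aa}", {f"{aa}int_c": -1, "pyr_c": 1}, 0, 1000,
                     gpr=expr_gene, cluster="amino acid metabolism"),
            ]
        )
    net._index()
    return net


@dataclass
class ToyFixture:
    """In-memory fixture bundle plus writers for the on-disk formats."""

    network: MetabolicNetwork
    expression: dict[str, float]
    utilization: dict[str, tuple[float, float]]
    clusters: dict[str, str]

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "network": os.path.join(outdir, "network.json"),
            "expression": os.path.join(outdir, "expression.tsv"),
            "utilization": os.path.join(outdir, "utilization.csv"),
            "clusters": os.path.join(outdir, "clusters.csv"),
        }
        write_network(self.network, paths["network"])
        pd.DataFrame(
            sorted(self.expression.items()), columns=["gene_id", "intensity"]
        ).to_csv(paths["expression"], sep="\t", index=False)
        pd.DataFrame(
            [(rid, lb, ub) for rid, (lb, ub) in sorted(self.utilization.items())],
            columns=["exchange_id", "lb", "ub"],
        ).to_csv(paths["utilization"], index=False)
        pd.DataFrame(
            sorted(self.clusters.items()), columns=["reaction_id", "cluster"]
        ).to_csv(paths["clusters"], index=False)
        return paths


def generate_toy_fixture(seed: int = 42, size: str = "small") -> ToyFixture:
    """Build the toy input bundle (network, expression, utilization, clusters).

    ``size="small"`` is a fixed ~23-reaction network; ``"medium"`` adds
    seed-randomized amino-acid chains (~70 reactions).  The output is
    deterministic for a given (seed, size).
    """
    rng = np.random.default_rng(seed)
    if size == "small":
        net = _small_network()
        expression = dict(_EXPRESSION)
        utilization = dict(_UTILIZATION)
    elif size == "medium":
        net = _medium_network(rng)
        expression = dict(_EXPRESSION)
        utilization = dict(_UTILIZATION)
        for r in net.reactions:
            if r.id.startswith("EX_aa"):
                utilization[r.id] = (r.lower_bound, r.upper_bound)
            if r.gpr.startswith("g_aa") and r.gpr not in expression:
                expression[r.gpr] = float(np.round(rng.uniform(100.0, 990.0), 1))
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    clusters = {r.id: r.pathway_cluster for r in net.reactions if r.pathway_cluster}
    net.validate()
    return ToyFixture(
        network=net, expression=expression, utilization=utilization, clusters=clusters
    )
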