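"""Compartmentalized stoichiometric network container and I/O.

The network is the in-memory form of an organ-specific genome-scale
metabolic network (GSMN): metabolites live in declared compartments,
reactions carry flux bounds in µmol·liver⁻¹·min⁻¹, a gene–protein–reaction
(GPR) rule, an optional pathway-cluster label, and a typed *role* —
``intracellular``, ``exchange``, ``xenobiotic`` or ``biomass``.

Sign conventions
----------------
Exchange reactions are written with a single extracellular metabolite at
coefficient −1, so a *positive* exchange flux means secretion (the
metabolite leaves the system) and a negative flux means uptake.  Report
layers convert to the opposite "uptake (+) / secretion (−)" convention
used in hepatic mass-balance tables.

Two file formats are supported: a native JSON dialect (canonical; see
``docs/network-schema.md``) and SBML Level 3 with the ``fbc`` package
(read via cobrapy).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0

ROLES = ("intracellular", "exchange", "xenobiotic", "biomass")

#: compartment ids conventionally treated as extracellular if the file
#: does not name one explicitly
_EXTRACELLULAR_ALIASES = {"e", "ex", "extracellular", "interstitial", "s"}


class NetworkValidationError(ValueError):
    """Structural problem in a metabolic network (duplicate ids, bad bounds, ...)."""


class NetworkFormatError(ValueError):
    """A network file could not be parsed in the named format."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and a typed role.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed).  Reversibility is encoded purely through the
    bounds; there is no separate flag.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    pathway_cluster: str = ""
    role: str = "intracellular"

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicNetwork:
    """A validated, compartmentalized metabolic network."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    compartments: set[str] = field(default_factory=set)
    extracellular: str | None = None

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- convenience accessors -------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def reaction_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    def reactions_with_role(self, role: str) -> list[str]:
        return [r.id for r in self.reactions if r.role == role]

    @property
    def biomass_id(self) -> str | None:
        ids = self.reactions_with_role("biomass")
        return ids[0] if ids else None

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            compartments=set(self.compartments),
            extracellular=self.extracellular,
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Validate structural invariants.

        Returns a list of warning strings for non-fatal oddities (isolated
        metabolites, missing extracellular compartment) and raises
        :class:`NetworkValidationError` for fatal problems.
        """
        if not self.reactions:
            raise NetworkValidationError("network has no reactions")
        if len(self._met_index) != len(self.metabolites):
            raise NetworkValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise NetworkValidationError("duplicate reaction ids")
        for m in self.metabolites:
            if m.compartment not in self.compartments:
                raise NetworkValidationError(
                    f"metabolite {m.id!r}: compartment {m.compartment!r} "
                    "not in the declared compartment set"
                )
        for r in self.reactions:
            if not r.stoichiometry:
                raise NetworkValidationError(f"reaction {r.id!r}: empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            if r.role not in ROLES:
                raise NetworkValidationError(f"reaction {r.id!r}: unknown role {r.role!r}")
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
            if r.role == "exchange":
                if len(r.stoichiometry) != 1:
                    raise NetworkValidationError(
                        f"exchange reaction {r.id!r} must touch exactly one metabolite"
                    )
                (mid,) = r.stoichiometry
                if self.metabolite(mid).compartment != self.extracellular:
                    raise NetworkValidationError(
                        f"exchange reaction {r.id!r}: metabolite {mid!r} is not "
                        "in the extracellular compartment"
                    )
        warns: list[str] = []
        if self.extracellular is None:
            warns.append("no extracellular compartment declared or inferred")
        used = {mid for r in self.reactions for mid in r.stoichiometry}
        isolated = [m.id for m in self.metabolites if m.id not in used]
        if isolated:
            warns.append(f"isolated metabolites (all-zero rows in S): {isolated}")
        for w in warns:
            logger.warning("%s: %s", self.id, w)
        return warns


# ---------------------------------------------------------------------------
# role inference


def _infer_extracellular(compartments: set[str]) -> str | None:
    hits = sorted(c for c in compartments if c.lower() in _EXTRACELLULAR_ALIASES)
    return hits[0] if hits else None


def infer_roles(net: MetabolicNetwork, overwrite: bool = False) -> None:
    """Fill in reaction roles not set by the file.

    A single-metabolite reaction on an extracellular metabolite is an
    exchange; an id containing "biomass" marks the biomass reaction;
    everything else defaults to intracellular.
    """
    for r in net.reactions:
        if r.role != "intracellular" and not overwrite:
            continue
        if (
            net.extracellular is not None
            and len(r.stoichiometry) == 1
            and net.metabolite(next(iter(r.stoichiometry))).compartment == net.extracellular
        ):
            r.role = "exchange"
        elif "biomass" in r.id.lower():
            r.role = "biomass"


# ---------------------------------------------------------------------------
# flux distributions


@dataclass
class FluxDistribution:
    """A flux value for every reaction of one network, µmol·liver⁻¹·min⁻¹."""

    values: dict[str, float]
    network_id: str

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def as_array(self, net: MetabolicNetwork) -> np.ndarray:
        if set(self.values) != set(net.reaction_ids):
            raise NetworkValidationError(
                "flux distribution does not cover exactly the network's reactions"
            )
        return np.array([self.values[rid] for rid in net.reaction_ids], dtype=float)

    @classmethod
    def from_array(cls, v: np.ndarray, net: MetabolicNetwork) -> "FluxDistribution":
        return cls(values=dict(zip(net.reaction_ids, map(float, v))), network_id=net.id)


# ---------------------------------------------------------------------------
# matrix assembly and classification


def build_stoichiometric_matrix(net: MetabolicNetwork) -> np.ndarray:
    """Assemble the m × r stoichiometric matrix S.

    Row order follows ``net.metabolites``, column order ``net.reactions``.
    """
    S = np.zeros((len(net.metabolites), len(net.reactions)))
    for j, r in enumerate(net.reactions):
        for mid, coeff in r.stoichiometry.items():
            S[net._met_index[mid], j] = coeff
    return S


def classify_exchanges(net: MetabolicNetwork) -> tuple[list[str], list[str]]:
    """Partition reaction ids into (intracellular, exchange).

    Biomass and xenobiotic reactions count as intracellular here: only
    true metabolite-utilization reactions feed the exometabolome
    accounting.
    """
    exchange = [r.id for r in net.reactions if r.role == "exchange"]
    intracellular = [r.id for r in net.reactions if r.role != "exchange"]
    if not exchange:
        logger.warning("%s: no exchange reactions found", net.id)
    return intracellular, exchange


# ---------------------------------------------------------------------------
# JSON dialect


def _net_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "id": net.id,
        "compartments": sorted(net.compartments),
        "extracellular": net.extracellular,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "pathway_cluster": r.pathway_cluster,
                "role": r.role,
            }
            for r in net.reactions
        ],
    }


def _net_from_dict(doc: dict) -> MetabolicNetwork:
    try:
        compartments = set(doc["compartments"])
        extracellular = doc.get("extracellular") or _infer_extracellular(compartments)
        mets = [
            Metabolite(id=m["id"], name=m.get("name", ""), compartment=m["compartment"])
            for m in doc["metabolites"]
        ]
        rxns = []
        for r in doc["reactions"]:
            rxns.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                    gpr=r.get("gpr", ""),
                    pathway_cluster=r.get("pathway_cluster", ""),
                    role=r.get("role", "intracellular"),
                )
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkFormatError(f"malformed network JSON: {exc!r}") from exc
    net = MetabolicNetwork(
        id=doc.get("id", "network"),
        metabolites=mets,
        reactions=rxns,
        compartments=compartments,
        extracellular=extracellular,
    )
    infer_roles(net)
    return net


def _net_from_sbml(path: str) -> MetabolicNetwork:
    try:
        import cobra.io

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise NetworkFormatError(f"SBML parse failure for {path!r}: {exc}") from exc
    compartments = set(model.compartments) or {m.compartment for m in model.metabolites}
    extracellular = _infer_extracellular(compartments)
    mets = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment)
        for m in model.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=r.gene_reaction_rule or "",
        )
        for r in model.reactions
    ]
    net = MetabolicNetwork(
        id=model.id or "sbml_model",
        metabolites=mets,
        reactions=rxns,
        compartments=compartments,
        extracellular=extracellular,
    )
    infer_roles(net)
    return net


def load_network(path: str, format: str = "json") -> MetabolicNetwork:
    """Load and validate a network from ``json`` (native dialect) or ``sbml``."""
    if format == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkFormatError(f"invalid JSON in {path!r}: {exc}") from exc
        net = _net_from_dict(doc)
    elif format == "sbml":
        net = _net_from_sbml(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'json' or 'sbml')")
    net.validate()
    return net


def write_network(net: MetabolicNetwork, path: str) -> None:
    """Write the network in the native JSON dialect (round-trip exact)."""
    with open(path, "w") as fh:
        json.dump(_net_to_dict(net), fh, indent=1, sort_keys=False)
        fh.write("\n")
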