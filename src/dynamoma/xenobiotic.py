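"""Cofactor-based xenobiotic reaction templates.

A whole-body PBPK model balances the drug and its metabolites itself, so
when its xenobiotic reactions are spliced into a metabolic network only
their *endogenous* cofactor demand is represented: an acetylation step
appears as ``AcCoA → CoA``, a glutathione conjugation as ``GSH →``, and
so on.  Each template names the cofactor roles, their signed
stoichiometry, and the subcellular locations where the reaction class
occurs (phase I oxidation/hydrolysis/reduction; phase II conjugations;
phase III transport).

Instantiated reactions carry ``role="xenobiotic"`` and closed bounds
``[0, 0]``: they are inert until the dynamic coupling loop pins them to
PBPK-derived rates, so extending a network never changes its feasible
space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from dynamoma.network import MetabolicNetwork, Reaction

#: canonical location names accepted in templates, with common short ids
LOCATION_ALIASES = {
    "c": "cytosol",
    "cyt": "cytosol",
    "m": "mitochondria",
    "mito": "mitochondria",
    "x": "peroxisome",
    "p": "peroxisome",
    "n": "nucleus",
    "r": "endoplasmic_reticulum",
    "er": "endoplasmic_reticulum",
    "l": "lysosome",
    "g": "golgi",
}


def canonical_location(compartment: str) -> str:
    c = compartment.lower()
    return LOCATION_ALIASES.get(c, c)


class TemplateError(ValueError):
    """Bad template instantiation (unbound role, disallowed location, ...)."""


@dataclass(frozen=True)
class XenobioticTemplate:
    """A cofactor-only reaction template.

    ``cofactor_stoichiometry`` maps abstract cofactor *roles* (e.g.
    ``"AcCoA"``) to signed coefficients; the drug itself never appears.
    ``allowed_locations`` is a frozenset of canonical compartment names,
    or ``None`` for membrane transporters that may sit anywhere.
    """

    name: str
    cofactor_stoichiometry: dict[str, float] = field(hash=False)
    allowed_locations: frozenset[str] | None = None
    phase: str = ""

    def allows(self, compartment: str) -> bool:
        if self.allowed_locations is None:
            return True
        return canonical_location(compartment) in self.allowed_locations


_PHASE1_LOCS = frozenset({"cytosol", "mitochondria", "peroxisome"})

TEMPLATES: dict[str, XenobioticTemplate] = {
    t.name: t
    for t in [
        # phase I
        XenobioticTemplate("oxidation", {"O2": -1.0}, _PHASE1_LOCS, "I"),
        # NADPH-dependent variant for CYP-type monooxygenases
        XenobioticTemplate(
            "oxidation_nadph",
            {"O2": -1.0, "NADPH": -1.0, "NADP": 1.0},
            _PHASE1_LOCS,
            "I",
        ),
        XenobioticTemplate("hydrolysis", {"H2O": -1.0}, _PHASE1_LOCS, "I"),
        XenobioticTemplate(
            "reduction", {"NAD(P)H": -1.0, "NAD(P)": 1.0}, _PHASE1_LOCS, "I"
        ),
        # phase II
        XenobioticTemplate("gsh_conjugation", {"GSH": -1.0}, frozenset({"cytosol"}), "II"),
        XenobioticTemplate(
            "sulfation", {"PAPS": -1.0, "PAP": 1.0}, frozenset({"cytosol"}), "II"
        ),
        XenobioticTemplate(
            "acetylation", {"AcCoA": -1.0, "CoA": 1.0}, frozenset({"cytosol"}), "II"
        ),
        XenobioticTemplate(
            "sugar_conjugation",
            {"UDP-SUG": -1.0, "ADP": 1.0},
            frozenset({"microsome", "endoplasmic_reticulum"}),
            "II",
        ),
        XenobioticTemplate(
            "methylation",
            {"SAM": -1.0, "SAH": 1.0},
            frozenset({"mitochondria", "nucleus"}),
            "II",
        ),
        XenobioticTemplate(
            "aa_conjugation", {"AA": -1.0}, frozenset({"mitochondria"}), "II"
        ),
        # phase III
        XenobioticTemplate(
            "metabolic_integration",
            {"metabolite": 1.0},
            frozenset(
                {
                    "cytosol",
                    "mitochondria",
                    "peroxisome",
                    "nucleus",
                    "lysosome",
                    "endoplasmic_reticulum",
                }
            ),
            "III",
        ),
        XenobioticTemplate(
            "atp_transporter", {"ATP": -1.0, "ADP": 1.0, "Pi": 1.0}, None, "III"
        ),
        XenobioticTemplate(
            "sym_antiporter", {"ion_out": -1.0, "ion_in": 1.0}, None, "III"
        ),
    ]
}


@dataclass
class XenobioticReactionSpec:
    """Binds a template to concrete metabolites at one location.

    ``reaction_id`` must match a column of the PBPK rate table that will
    later drive the reaction.
    """

    reaction_id: str
    template: str
    location: str
    metabolite_binding: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "template": self.template,
            "location": self.location,
            "binding": self.metabolite_binding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "XenobioticReactionSpec":
        return cls(
            reaction_id=d["reaction_id"],
            template=d["template"],
            location=d["location"],
            metabolite_binding=dict(d["binding"]),
        )


def load_xenobiotic_specs(path: str) -> list[XenobioticReactionSpec]:
    with open(path) as fh:
        return [XenobioticReactionSpec.from_dict(d) for d in json.load(fh)]


def dump_xenobiotic_specs(specs: list[XenobioticReactionSpec], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in specs], fh, indent=1)
        fh.write("\n")


def instantiate_template(
    template: XenobioticTemplate | str,
    binding: dict[str, str],
    location: str,
    rid: str,
) -> Reaction:
    """Build a closed ([0, 0]) xenobiotic reaction from a template.

    Raises :class:`TemplateError` if a cofactor role is unbound or the
    location is not allowed for this reaction class.
    """
    if isinstance(template, str):
        try:
            template = TEMPLATES[template]
        except KeyError:
            raise TemplateError(f"unknown template {template!r}") from None
    if not template.allows(location):
        raise TemplateError(
            f"{rid!r}: template {template.name!r} is not allowed in "
            f"{canonical_location(location)!r} (allowed: "
            f"{sorted(template.allowed_locations or [])})"
        )
    stoich: dict[str, float] = {}
    for role, coeff in template.cofactor_stoichiometry.items():
        if role not in binding:
            raise TemplateError(f"{rid!r}: cofactor role {role!r} is unbound")
        mid = binding[role]
        stoich[mid] = stoich.get(mid, 0.0) + coeff
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=0.0,
        role="xenobiotic",
        pathway_cluster="xenobiotic metabolism",
    )


def extend_network(
    net: MetabolicNetwork, specs: list[XenobioticReactionSpec]
) -> MetabolicNetwork:
    """Return a copy of ``net`` with the xenobiotic reactions spliced in.

    All specs are checked (id collisions, dangling metabolite bindings,
    disallowed locations) before any reaction is added, so a failure
    never yields a half-extended network.
    """
    seen: set[str] = set()
    new_reactions: list[Reaction] = []
    for spec in specs:
        if net.has_reaction(spec.reaction_id) or spec.reaction_id in seen:
            raise TemplateError(f"reaction id {spec.reaction_id!r} already exists")
        seen.add(spec.reaction_id)
        rxn = instantiate_template(
            spec.template, spec.metabolite_binding, spec.location, spec.reaction_id
        )
        for role, mid in spec.metabolite_binding.items():
            try:
                met = net.metabolite(mid)
            except KeyError:
                raise TemplateError(
                    f"{spec.reaction_id!r}: bound metabolite {mid!r} (role "
                    f"{role!r}) does not exist in the network"
                ) from None
            if canonical_location(met.compartment) != canonical_location(spec.location):
                raise TemplateError(
                    f"{spec.reaction_id!r}: metabolite {mid!r} lives in "
                    f"{met.compartment!r}, not in the spec location {spec.location!r}"
                )
        new_reactions.append(rxn)
    out = net.copy()
    out.reactions.extend(new_reactions)
    out._index()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# isoniazid preset

#: cofactor roles the isoniazid cascade needs, and where they must live
_ISONIAZID_ROLES = {
    "AcCoA": "cytosol",
    "CoA": "cytosol",
    "H2O": "cytosol",
    "O2": "cytosol",
    "NADPH": "cytosol",
    "NADP": "cytosol",
    "glycine": "mitochondria",
}


def _find_cofactor(net: MetabolicNetwork, patterns: list[str], location: str) -> str | None:
    for m in net.metabolites:
        if canonical_location(m.compartment) != location:
            continue
        base = m.id.lower()
        if any(base == p or base.startswith(p + "_") or base.split("_")[0] == p for p in patterns):
            return m.id
    return None


_COFACTOR_PATTERNS = {
    "AcCoA": ["accoa", "acetylcoa", "acccoa"],
    "CoA": ["coa"],
    "H2O": ["h2o", "water"],
    "O2": ["o2", "oxygen"],
    "NADPH": ["nadph"],
    "NADP": ["nadp"],
    "glycine": ["gly", "glycine"],
}


def _preset_resource() -> list[dict]:
    with resources.files("dynamoma").joinpath("data/isoniazid_preset.json").open() as fh:
        return json.load(fh)


def isoniazid_preset(
    net: MetabolicNetwork, cofactor_ids: dict[str, str] | None = None
) -> list[XenobioticReactionSpec]:
    """Xenobiotic reaction specs for the hepatic isoniazid cascade.

    Eight cofactor-only reactions: NAT2 acetylation of isoniazid,
    hydrazine and acetylhydrazine (AcCoA → CoA, cytosol); amidase
    hydrolysis of isoniazid and acetylisoniazid (H2O, cytosol); CYP2E1
    oxidation of acetylhydrazine (O2 + NADPH → NADP, cytosol); glycine
    conjugation of isonicotinic acid (mitochondria); and NOS2-mediated
    hydrazine clearance (oxidation, cytosol).

    The per-reaction stoichiometries are an approximate reconstruction
    from the generic templates — they are shipped as a JSON resource
    (``dynamoma/data/isoniazid_preset.json``) so users can substitute an
    exact, curated table.  Cofactor metabolite ids are auto-detected by
    name unless given explicitly via ``cofactor_ids``.
    """
    binding: dict[str, str] = {}
    for role, location in _ISONIAZID_ROLES.items():
        if cofactor_ids and role in cofactor_ids:
            binding[role] = cofactor_ids[role]
            continue
        mid = _find_cofactor(net, _COFACTOR_PATTERNS[role], location)
        if mid is None:
            raise TemplateError(
                f"isoniazid preset: no metabolite found for cofactor role "
                f"{role!r} in {location!r}"
            )
        binding[role] = mid
    specs = []
    for entry in _preset_resource():
        roles = entry["roles"]
        specs.append(
            XenobioticReactionSpec(
                reaction_id=entry["reaction_id"],
                template=entry["template"],
                location=entry["location"],
                metabolite_binding={r: binding[roles[r]] for r in roles},
            )
        )
    return specs
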