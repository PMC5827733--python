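# Network JSON schema

The canonical on-disk form of a metabolic network (read/written by
`dynamoma.network.load_network` / `write_network`). SBML Level 3 + fbc is
also accepted for import; it is converted to this in-memory model.

```json
{
  "id": "toy_liver_small",
  "compartments": ["cytosol", "extracellular", "mitochondria"],
  "extracellular": "extracellular",
  "metabolites": [
    {"id": "lac_c", "name": "", "compartment": "cytosol"}
  ],
  "reactions": [
    {
      "id": "LDH",
      "stoichiometry": {"lac_c": -1.0, "pyr_c": 1.0},
      "lower_bound": 0.0,
      "upper_bound": 1000.0,
      "gpr": "g_ldh",
      "pathway_cluster": "central carbon metabolism",
      "role": "intracellular"
    }
  ]
}
```

Field notes:

* **`extracellular`** — which compartment is outside the cell/organ. If
  omitted, a compartment named `e`, `ex`, `extracellular`, `interstitial`
  or `s` is inferred.
* **`stoichiometry`** — metabolite id → signed coefficient (negative =
  consumed). All metabolite ids must be declared.
* **bounds** — µmol·organ⁻¹·min⁻¹; default ±1000 when omitted. `lower_bound`
  must not exceed `upper_bound`.
* **`gpr`** — gene–protein–reaction rule using `and` / `or` /
  parentheses, e.g. `"(g1 and g2) or g3"`. Empty string = no rule; the
  reaction gets no expression score.
* **`pathway_cluster`** — free-text label used by the perturbation
  metrics. Empty = unclustered.
* **`role`** — one of `intracellular`, `exchange`, `xenobiotic`,
  `biomass`. If omitted, single-metabolite reactions on extracellular
  metabolites are inferred to be exchanges and ids containing `biomass`
  mark the biomass reaction.

Sign convention: exchange reactions carry a single extracellular
metabolite with coefficient −1, so a **positive exchange flux is
secretion** and a negative one is uptake. The report tables additionally
provide an uptake-positive column.
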