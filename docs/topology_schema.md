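# Topology / parameter JSON schema

`molio.read_topology` / `molio.write_topology` use a single JSON document
describing a molecule's bonds and force-field parameters. Units: nm,
kJ/mol, radians, elementary charge.

```json
{
 "atoms": [
  {
   "name": "C1", "element": "C",
   "residue_name": "LIG", "residue_index": 1, "chain_id": "A",
   "position_nm": [0.0, 0.0, 0.0],
   "charge": -0.05,
   "sigma_nm": 0.34,
   "epsilon_kj": 0.36,
   "born_radius_nm": 0.20
  }
 ],
 "bonds": [[0, 1]],
 "bond_terms":    [{"i": 0, "j": 1, "k_b": 110000.0, "r0": 0.153}],
 "angle_terms":   [{"i": 0, "j": 1, "k": 2, "k_a": 250.0, "theta0": 1.937}],
 "torsion_terms": [{"i": 0, "j": 1, "k": 2, "l": 3, "k_t": 4.0,
                    "periodicity": 3, "phase": 0.0}],
 "scale14_lj": 0.5,
 "scale14_coulomb": 0.8333333,
 "eps_solute": 1.0,
 "eps_solvent": 78.5
}
```

Rules:

* `atoms` — ordered; the array index is the atom's 0-based id used by every
  other table. `charge`, `sigma_nm`, `epsilon_kj`, `born_radius_nm` are
  required per atom; `position_nm` is optional (defaults to the origin —
  pair the file with a PDB for coordinates). σ > 0, ε ≥ 0, Born radius > 0.
* `bonds` — unordered 0-based index pairs; out-of-range indices,
  self-bonds and duplicates are rejected.
* `bond_terms` — E = k_b (r − r0)², k_b in kJ/mol/nm².
* `angle_terms` — E = k_a (θ − θ0)², θ0 in radians; j is the vertex.
* `torsion_terms` — E = k_t (1 + cos(n φ − γ)); `periodicity` n is a
  positive integer, `phase` γ in radians.
* `scale14_*` — factors applied to 1-4 (bond-graph distance 3) nonbonded
  pairs; distance 1 and 2 pairs are always excluded.
* `eps_solute` / `eps_solvent` — dielectrics of the Generalized Born term.
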