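# Network / scenario document schema (version 1)

A network document is one JSON object (YAML accepted as the same
schema). All concentrations are µmol/L unbound, rates 1/h, clearances
L/h, capacities µmol/h, doses mg. Unknown top-level keys are ignored;
missing required keys raise a configuration error naming the JSON path.

```jsonc
{
  "version": 1,                      // required, must equal 1

  "enzymes": {                       // id -> enzyme spec
    "CYP2D6": {
      "sites": ["liver"],            // non-empty; "liver" | "gut_wall"
      "kdeg": 0.02,                  // > 0, turnover rate (1/h)
      "baseline_abundance": 1.0      // optional, > 0, reference = 1
    }
  },

  "compounds": {                     // id -> compound model
    "VIC_SENS": {
      "molar_mass": 280.0,           // g/mol, > 0
      "fu_plasma": 0.2,              // (0, 1]
      "ka": 1.0,                     // optional, 1/h, > 0
      "f_dissolved": 1.0,            // optional, (0, 1]
      "kp": {"liver": 2.0, "gut_wall": 1.5, "peripheral": 2.0},
      "renal_cl": 20.0,              // optional, L/h on unbound plasma
      "pgp_substrate": {             // optional; null if absent
        "vmax": 30.0, "km": 10.0
      },
      "pathways": [                  // enzymatic clearance routes
        {"id": "cyp2d6", "enzyme": "CYP2D6", "site": "liver",
         "vmax": 50.0, "km": 4.0, "metabolite": null}
      ],
      "interactions": []             // optional declarative perpetrator
                                     // constants (see edges); convenience
                                     // only — the engine reads edges
    }
  },

  "edges": [                         // perpetrator -> enzyme effects
    {"perpetrator": "INH_COMP", "target": "CYP2D6",
     "mechanism": "competitive",     // competitive | noncompetitive |
                                     // mbi | induction | downregulation
     "parameters": {"ki": 0.05}}
    // mechanism-specific parameters:
    //   competitive / noncompetitive: ki (µmol/L unbound, > 0)
    //   mbi:            ki (= KI, µmol/L), kinact (1/h, > 0)
    //   induction:      ec50 (µmol/L), emax (>= 0, dimensionless)
    //   downregulation: ic50 (µmol/L), imax ((0, 1])
  ],

  "metabolite_links": [              // parent pathway -> tracked product
    {"parent": "VIC_SENS", "pathway": "cyp2d6",
     "metabolite": "VIC_SENS_M1", "fraction": 1.0}   // (0, 1]; acyclic
  ],

  "scenarios": [                     // optional curated scenario list
    {"label": "ref_sens",
     "victim": "VIC_SENS",
     "victim_regimen": {
        "dose_amount_mg": 40.0, "route": "oral",   // "oral" | "iv"
        "interval_h": 24.0,            // null for single dose
        "n_doses": null,               // null = open-ended repetition
        "start_time_h": 0.0},          // may be negative (pretreatment)
     "perpetrators": [
        {"compound": "INH_COMP", "regimen": { /* same shape */ }}],
     "activity_score": 2.0,            // >= 0; 2 = NM reference
     "population": "reference"}        // "reference" or a population id
  ]
}
```

The dose-adaptation grid file (`ddginet adapt --grid`) is a reduced
document: `{"victim", "victim_regimen", "as_values": [...],
"perpetrator_sets": [[{"compound", "regimen"}...], ...]}` — perpetrator
combinations are explicit lists (use `[]` for monotherapy), mirroring a
curated scenario matrix rather than a powerset.
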