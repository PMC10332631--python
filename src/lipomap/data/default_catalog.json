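{
  "comment": "Editable profile-HMM catalog: accession -> functional label, trusted bitscore cutoff, and tie-break priority (lower wins). Real Pfam/TIGRFAM accessions are used where a public model exists; HMSSS_* are named placeholders for the sulfur-metabolism extension models, to be replaced with the curated accession list of the annotation toolkit in use.",
  "models": [
    {"acc": "TIGR00545", "label": "Lpl",   "trusted_cutoff": 100.0, "priority": 30},
    {"acc": "PF10437",   "label": "LplB",  "trusted_cutoff": 25.0,  "priority": 30},
    {"acc": "TIGR00214", "label": "LipB",  "trusted_cutoff": 90.0,  "priority": 20},
    {"acc": "HMSSS_LipM","label": "LipM",  "trusted_cutoff": 90.0,  "priority": 20},
    {"acc": "TIGR00510", "label": "LipA",  "trusted_cutoff": 120.0, "priority": 10},
    {"acc": "HMSSS_LipS1","label": "LipS1","trusted_cutoff": 100.0, "priority": 10},
    {"acc": "HMSSS_LipS2","label": "LipS2","trusted_cutoff": 100.0, "priority": 10},
    {"acc": "HMSSS_LipT", "label": "LipT", "trusted_cutoff": 80.0,  "priority": 10},
    {"acc": "HMSSS_LipL", "label": "LipL", "trusted_cutoff": 80.0,  "priority": 20},
    {"acc": "PF01597",   "label": "GcvH",  "trusted_cutoff": 40.0,  "priority": 40},
    {"acc": "HMSSS_LbpA","label": "LbpA",  "trusted_cutoff": 40.0,  "priority": 40},
    {"acc": "PF00364",   "label": "LD",    "trusted_cutoff": 30.0,  "priority": 50},
    {"acc": "HMSSS_sHdrA","label": "sHdr", "trusted_cutoff": 100.0, "priority": 20},
    {"acc": "TIGR00121", "label": "BirA",  "trusted_cutoff": 80.0,  "priority": 50},
    {"acc": "TIGR00433", "label": "BioB",  "trusted_cutoff": 120.0, "priority": 50}
  ]
}
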