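{
  "comment": "Minimal mtDNA haplogroup motif table covering the haplogroups observed in the bundled Iron Age series. Coding markers are mandatory diagnostic SNPs; hvr1 motifs are the control-region variants required in addition. Star labels (HV*, U*) are paragroup rules: they match when no nested child rule does.",
  "rules": [
    {"label": "A",      "parent": null,     "coding": ["663G"],                      "hvr1": ["16223T", "16290T", "16319A"],                       "macro": "East"},
    {"label": "A8",     "parent": "A",      "coding": ["663G"],                      "hvr1": ["16223T", "16242T", "16290T", "16319A"],             "macro": "East"},
    {"label": "C",      "parent": null,     "coding": ["10398G", "10400T", "13263G"], "hvr1": ["16223T", "16298C", "16327T"],                      "macro": "East"},
    {"label": "C4a2a",  "parent": "C",      "coding": ["10398G", "10400T", "13263G"], "hvr1": ["16223T", "16298C", "16327T", "16344T", "16357C"],  "macro": "East"},
    {"label": "C4a2a1", "parent": "C4a2a",  "coding": ["10398G", "10400T", "13263G"], "hvr1": ["16171G", "16223T", "16298C", "16327T", "16344T", "16357C"], "macro": "East"},
    {"label": "C5",     "parent": "C",      "coding": ["10398G", "10400T", "13263G"], "hvr1": ["16223T", "16288C", "16298C", "16327T"],            "macro": "East"},
    {"label": "D",      "parent": null,     "coding": ["10398G", "10400T", "5178A"],  "hvr1": ["16223T", "16362C"],                                "macro": "East"},
    {"label": "F1b",    "parent": null,     "coding": ["6392C"],                     "hvr1": ["16189C", "16232A", "16249C", "16304C", "16311C"],   "macro": "East"},
    {"label": "F1b1b",  "parent": "F1b",    "coding": ["6392C"],                     "hvr1": ["16172C", "16179T", "16189C", "16232A", "16249C", "16304C", "16311C"], "macro": "East"},
    {"label": "G2a",    "parent": null,     "coding": ["10398G", "10400T", "4833G"],  "hvr1": ["16223T", "16227G", "16278T", "16362C"],            "macro": "East"},
    {"label": "H",      "parent": null,     "coding": ["14766C", "7028C"],           "hvr1": [],                                                   "macro": "West"},
    {"label": "HV*",    "parent": null,     "coding": ["14766C", "7028T"],           "hvr1": [],                                                   "macro": "West"},
    {"label": "HV6",    "parent": "HV*",    "coding": ["14766C", "7028T"],           "hvr1": ["16172C", "16311C"],                                 "macro": "West"},
    {"label": "I",      "parent": null,     "coding": ["10034C"],                    "hvr1": ["16129A", "16223T", "16304C", "16391A"],             "macro": "West"},
    {"label": "K",      "parent": null,     "coding": ["12308G"],                    "hvr1": ["16224C", "16311C"],                                 "macro": "West"},
    {"label": "K1b1a",  "parent": "K",      "coding": ["12308G"],                    "hvr1": ["16093C", "16224C", "16311C", "16319A"],             "macro": "West"},
    {"label": "K1c2",   "parent": "K",      "coding": ["12308G"],                    "hvr1": ["16224C", "16311C", "16320T"],                       "macro": "West"},
    {"label": "T",      "parent": null,     "coding": ["4917G"],                     "hvr1": ["16126C", "16294T"],                                 "macro": "West"},
    {"label": "T1",     "parent": "T",      "coding": ["4917G"],                     "hvr1": ["16126C", "16163G", "16186T", "16189C", "16294T"],   "macro": "West"},
    {"label": "T2f7",   "parent": "T",      "coding": ["4917G"],                     "hvr1": ["16126C", "16189C", "16292T", "16294T", "16296T"],   "macro": "West"},
    {"label": "U2e",    "parent": null,     "coding": ["12308G"],                    "hvr1": ["16051G", "16129C", "16362C"],                       "macro": "West"},
    {"label": "U4",     "parent": null,     "coding": ["12308G"],                    "hvr1": ["16356C"],                                           "macro": "West"},
    {"label": "U4a3",   "parent": "U4",     "coding": ["12308G"],                    "hvr1": ["16356C", "16362C"],                                 "macro": "West"},
    {"label": "U5a",    "parent": null,     "coding": ["12308G"],                    "hvr1": ["16256T", "16270T"],                                 "macro": "West"},
    {"label": "U5a1",   "parent": "U5a",    "coding": ["12308G"],                    "hvr1": ["16256T", "16270T", "16399G"],                       "macro": "West"},
    {"label": "U5a1h",  "parent": "U5a1",   "coding": ["12308G"],                    "hvr1": ["16239T", "16256T", "16270T", "16399G"],             "macro": "West"},
    {"label": "U*",     "parent": null,     "coding": ["14766T", "7028T", "12308G"],  "hvr1": [],                                                  "macro": "West"}
  ]
}
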