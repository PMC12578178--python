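# Mapping from the seven comorbidity flags used in the sensitivity analysis to
# the MedDRA indication PTs (normalized form) that raise each flag.  The flag
# names are fixed; the PT lists are editable — in particular other_cns ships
# with a small illustrative list that users should replace with their own
# MedDRA query.
parkinsons_disease:
  - PARKINSONSDISEASE
  - PARKINSONISM
schizophrenia:
  - SCHIZOPHRENIA
  - SCHIZOAFFECTIVEDISORDER
affective_disorders:
  - DEPRESSION
  - MAJORDEPRESSION
  - BIPOLARDISORDER
  - BIPOLARIDISORDER
epilepsy:
  - EPILEPSY
  - SEIZURE
  - PARTIALSEIZURES
gastro_oesophageal_reflux:
  - GASTROOESOPHAGEALREFLUXDISEASE
nausea_vomiting:
  - NAUSEA
  - VOMITING
other_cns_disorders:
  - MIGRAINE
  - MULTIPLESCLEROSIS
  - RESTLESSLEGSSYNDROME
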