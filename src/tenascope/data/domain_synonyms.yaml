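# Maps external annotation-table domain names onto tenascope's domain kinds.
# Matching is case-insensitive.  Edit or extend without touching code.
EGF_TN:
  - EGF_TN
  - EGF_Tenascin
  - EGF_like_tenascin
  - Tenascin_EGF
FN3:
  - FN3
  - fn3
  - Fibronectin_type3
  - FN3_domain
FRED:
  - FRED
  - FReD
  - FBG
  - Fibrinogen_C
  - FBG_C
SIGNAL:
  - SIGNAL
  - SignalP
  - signal_peptide
COILED_COIL:
  - COILED_COIL
  - coiled_coil
  - CC
DISORDER:
  - DISORDER
  - consensus_disorder
  - IDR
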