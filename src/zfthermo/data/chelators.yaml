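# Zn(II) chelator stability constants for metal-buffer speciation.
#
# log_protonation_constants: log10 stepwise proton-association constants
#   (logK1 = log [HL]/[H][L], highest first).
# log_beta_znl: log10 formation constant of the 1:1 ZnL complex.
# log_beta_znhl: log10 formation constant of ZnHL referred to Zn + H + L
#   (omit when the ternary complex is negligible).
#
# Values are conditional at ~25 C, I ~ 0.1 M, compiled from the critical
# stability-constant literature (Martell & Smith, NIST 46); they are
# parameterization, not algorithm, and may be overridden by a user registry.
# Entries marked "approximate" are representative, not critically evaluated.

chelators:
  EDTA:
    log_protonation_constants: [10.19, 6.13, 2.69, 2.00]
    log_beta_znl: 16.5
    log_beta_znhl: 19.5
    reference: "Martell & Smith, Critical Stability Constants / NIST 46"
  EGTA:
    log_protonation_constants: [9.40, 8.78, 2.66, 2.00]
    log_beta_znl: 12.6
    log_beta_znhl: 17.8
    reference: "Martell & Smith, Critical Stability Constants / NIST 46"
  HEDTA:
    log_protonation_constants: [9.81, 5.37, 2.60]
    log_beta_znl: 14.6
    reference: "Martell & Smith, Critical Stability Constants / NIST 46"
  TPEN:
    log_protonation_constants: [7.19, 4.85, 3.32, 2.85]
    log_beta_znl: 15.6
    reference: "Martell & Smith, Critical Stability Constants / NIST 46"
  NDAP:
    log_protonation_constants: [9.60, 2.50]
    log_beta_znl: 10.5
    reference: "approximate; nitrilodiacetic-propionate-type chelator"
  EDDS:
    log_protonation_constants: [9.80, 6.80, 3.90, 2.90]
    log_beta_znl: 13.5
    reference: "approximate; (S,S)-ethylenediamine-N,N'-disuccinate"
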