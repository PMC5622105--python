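# Published initial receptor concentrations and binding rate parameters for
# the integrin receptors and ECM ligands carried as packaged fixtures.
# k_on in s^-1 M^-1, k_off in s^-1, receptor totals in nM.
receptors:
  a1b1:
    total_nM: 0.0001
  avb3:
    total_nM: 0.05
rate_pairs:
  col_i:
    k_on_per_M_s: 5.6e+4
    k_off_per_s: 1.3e-3
  col_iv:
    k_on_per_M_s: 8.0e+5
    k_off_per_s: 5.0e-3
  fibronectin:
    k_on_per_M_s: 1.6e+8
    k_off_per_s: 3.5e-1
  vwf:
    k_on_per_M_s: 1.6e+4
    k_off_per_s: 2.3e-2
# Collagen I and IV alpha chains run as separate scenarios with identical
# rates; fibrinogen carries no published pair here and is therefore not a
# fixture scenario (user-supplied rate configs are accepted instead).
pairings:
  - ligand: "Col 1a1"
    receptor: a1b1
    rates: col_i
  - ligand: "Col 1a2"
    receptor: a1b1
    rates: col_i
  - ligand: "Col 4a1"
    receptor: a1b1
    rates: col_iv
  - ligand: "Col 4a2"
    receptor: a1b1
    rates: col_iv
  - ligand: "Fibronectin"
    receptor: avb3
    rates: fibronectin
  - ligand: "von Willebrand factor A"
    receptor: avb3
    rates: vwf
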