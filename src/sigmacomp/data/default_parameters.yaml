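# Default stationary-phase parameter set for the sigma-factor competition
# model. Units: total pools in uM; DNA sites and promoters as copies per
# cell; cell_volume in L; dissociation constants in M; rates in 1/s;
# operon_length in nt (documentary only, not used in computation).
E_total: 4.3            # total core RNA polymerase, uM
sigma70_total: 12.0     # total sigma70, uM
sigma38_total: 2.7      # total sigma38, uM
Rsd_total: 10.4         # total anti-sigma factor Rsd, uM
RNA6S_total: 13.0       # total 6S RNA, uM
DNA_total_sites: 4.6e+6 # nonspecific chromosomal binding sites per cell
P70_count: 200          # sigma70-cognate promoters per cell
P38_count: 200          # sigma38-cognate promoters per cell
cell_volume: 1.0e-15    # L
K_E_sigma70: 3.3e-9     # E - sigma70, M
K_E_sigma38: 1.52e-8    # E - sigma38, M
K_Rsd: 3.2e-8           # Rsd - sigma70, M
K_6S: 1.31e-7           # 6S RNA - E.sigma70 holoenzyme, M
K_NS: 1.0e-4            # nonspecific polymerase-DNA binding, M
K_EsigmaP: 1.0e-7       # holoenzyme - cognate promoter, M
clearance_rate_c: 0.005           # promoter clearance, 1/s
elongation_escape_rate_e: 0.021   # escape from elongation, 1/s
operon_length: 1000     # nt
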