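>Eco-Lys-UUU E. coli tRNA-Lys(UUU); database sequence (all six chromosomal copies identical); 76 nt incl. CCA
GGGUCGUUAGCUCAGUUGGUAGAGCAGUUGACUUUUAAUCAAUUGGUCGCAGGUUCGAAUCCUGCACGACCCACCA
>Eco-Thr-UGU E. coli tRNA-Thr(UGU); RECONSTRUCTED (synthetic stand-in constrained to published positions: anticodon 34-36 UGU, site 36-41 UAAUCA, U16/U17, cloverleaf pairing)
GCUGAUAUAGCCCAGUUGGUAGGGCAGUUGACUUGUAAUCAAUGAGGUCGUGGUUCGAAUCCACGUAUCAGCACCA
>Eco-Thr-CGU E. coli tRNA-Thr(CGU); RECONSTRUCTED (synthetic stand-in constrained to published positions: anticodon 34-36 CGU, site 36-41 UAAUGC, U16/U17, cloverleaf pairing)
GCCGAUAUGCUCGAGUUGGUACGAGGAUGCACUCGUAAUGCAUACUCGGGCACUUCAAAUGUGCCUAUCGGCGCCA
>Eco-Asn-GUU E. coli tRNA-Asn(GUU); database sequence; 76 nt incl. CCA
UCCUCUGUAGUUCAGUCGGUAGAACGGCGGACUGUUAAUCCGUAUGUCACUGGUUCGAGUCCAGUCAGAGGAGCCA
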