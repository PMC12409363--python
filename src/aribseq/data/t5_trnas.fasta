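>T5-Lys-UUU phage T5 tRNA-Lys(UUU); RECONSTRUCTED synthetic stand-in: host sequence carrying the published escape substitutions Mut1 U39A, Mut2 A41C and D-loop U16C, plus neutral distal edits (20, 73); site 36-41 UAAACC
GGGUCGUUAGCUCAGCUGGAAGAGCAGUUGACUUUUAAACCAUUGGUCGCAGGUUCGAAUCCUGCACGACCCGCCA
>T5-Thr-UGU phage T5 tRNA-Thr(UGU); RECONSTRUCTED synthetic stand-in: host sequence with site substitution U39A and D-loop U16C, plus neutral distal edits (20, 73)
GCUGAUAUAGCCCAGCUGGAAGGGCAGUUGACUUGUAAACAAUGAGGUCGUGGUUCGAAUCCACGUAUCAGCGCCA
>T5-Asn-GUU phage T5 tRNA-Asn(GUU); RECONSTRUCTED synthetic stand-in: host sequence with site substitution U39A and D-loop U16C, plus neutral distal edit (20)
UCCUCUGUAGUUCAGCCGGAAGAACGGCGGACUGUUAAACCGUAUGUCACUGGUUCGAGUCCAGUCAGAGGAGCCA
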