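# aribseq

Computational analysis of tRNA cleavage by anticodon nucleases, built around
the AriB Toprim effector of the PARIS anti-phage system. AriB, once released
by its AriA sensor, nicks specific *E. coli* tRNAs in the anticodon stem —
between canonical positions 40 and 41, within the site hexamer
U<sub>36</sub>AAUC|A<sub>41</sub> — depleting the pool of charged tRNAs and
arresting translation. Phage tRNA variants escape cleavage through
substitutions at or near this site (Mut1 U39→A, Mut2 A41→C) and in the D-loop
(Mut3 U16→C).

The package is for researchers analysing small-RNA sequencing of nuclease
challenges (in vivo or in vitro): it identifies which tRNAs are depleted,
maps the nick position at single-nucleotide resolution, predicts cleavage
sites from sequence, predicts the mass-spectrometric signature of a nick,
and predicts where ribosomes stall once a decoder is gone.

## What it computes

- **Depletion analysis** (`quantify`): reads are mapped to tRNA references
  with a built-in unique-placement mapper (exact k-mer seeds + ungapped
  extension, ≤2 mismatches; ties across distinct tRNAs are dropped), classed
  into full-length proxies (aligned span ≥ 65 nt) vs anticodon-arm fragments
  (< 45 nt with 5′ end in canonical window 27–43), and counted as CPM.
  Depletion is flagged per tRNA from the residuals of an ordinary
  least-squares fit of log₁₀ treated CPM on log₁₀ control CPM: flagged when
  the residual falls below −k·MAD (k = 3, normal-consistent MAD).
- **Cleavage-site calling** (`cleavage_caller`): a nick between positions p
  and p+1 leaves downstream fragments whose 5′ ends pile up at p+1. Per-label
  5′-end fractions are scored against a control pileup (or the uniform
  in-window expectation), `score = log2((f_t + ε)/(f_c + ε))`.
- **Consensus scanning and escape annotation**: anchored scan of the hexamer
  at positions 36–41 (UAAUCA) predicts nicks; host-vs-phage comparisons are
  annotated with the named escape substitutions.
- **In-silico RNase T1 digestion + MALDI prediction** (`massfrag`): T1 cuts
  3′ of G (3′-phosphate / 5′-OH products); a nuclease nick leaves 3′-OH /
  5′-phosphate. Average MH⁺ masses are predicted per product and matched to
  observed peak lists within 1 Da.
- **Toeprint prediction** (`toeprint`): a depleted decoder stalls the
  ribosome with its codon in the A-site; the cDNA 3′ end (toeprint) falls
  13–14 nt downstream of the first A-site base.
- **Synthetic data** (`synthetic_data`): a seeded read simulator for the two
  library chemistries — protocol A (cDNA-adapter, reverse-transcriptase
  stalls at modified residues shorten apparent reads; 150 nt paired) and
  protocol B (RNA-end-ligated, read 5′ ends are true RNA 5′ ends; 50 nt
  single) — with configurable nicking, stall and error rates plus per-read
  ground truth.

Packaged fixtures provide the four host target tRNAs (Lys-UUU, Thr-UGU,
Thr-CGU, Asn-GUU), three phage T5 escape variants and the base-modification
table; see the FASTA headers for which sequences are database-derived and
which are constraint-based reconstructions.

## Worked example

```bash
cat > demo.yaml <<'YAML'
seed: 1
references: {packaged: true, n_filler: 8}
simulate:
  enabled: true
  protocol: B
  read_length: 80
  n_reads: 6000
  error_rate: 0.002
  nick_sites:
    - {trna_id: Eco-Lys-UUU, between: ["40", "41"], probability: 0.9}
    - {trna_id: Eco-Thr-UGU, between: ["40", "41"], probability: 0.7}
YAML
aribseq run --config demo.yaml --out demo_out
```

This simulates a skewed 12-tRNA pool with nicking of two targets, maps and
classifies the reads, and writes TSV reports plus `summary.json` to
`demo_out/`. Key fields of the printed summary:

```json
"cleavage_calls": [
  {"nick": "40|41", "score": 3.987, "trna_id": "Eco-Lys-UUU"},
  {"nick": "40|41", "score": 3.719, "trna_id": "Eco-Thr-UGU"}
],
"depletion": {"depleted": ["Eco-Lys-UUU", "Eco-Thr-UGU"], "slope": 1.191},
"toeprint": {"depleted_codons": ["AAA", "ACA"], "stall_codon": "AAA"}
```

Both simulated nicks are recovered exactly at 40|41, the two nicked tRNAs —
and only those — are flagged as depleted, and the predicted ribosome stall
sits on the lysine AAA codon. The consensus scan reads the same site from
sequence alone:

```
$ aribseq scan --max-mismatch 1
Eco-Asn-GUU   40|41  1     # one mismatch: U36AAUC|C41
Eco-Lys-UUU   40|41  0
Eco-Thr-CGU   -      -     # two site substitutions: not hit at <=1 mismatch
Eco-Thr-UGU   40|41  0
T5-Asn-GUU    -      -
T5-Lys-UUU    -      -     # escape variant U36AAACC41
T5-Thr-UGU    40|41  1
```

and the digestion module predicts the diagnostic masses: the T1 product
spanning the nick site of the Lys transcript (positions 31–45, MH⁺ 4763.8)
splits on nicking into a 3′-OH upstream piece (MH⁺ 3067.9) and a
5′-phosphate downstream piece (MH⁺ 1714.9).

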