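# Methods

## Canonical coordinates

All positional statements use canonical (Sprinzl-style) tRNA numbering:
labels "1"–"76" with insertion labels ("17a", "20a", "20b", "e1"–"e5") so
that structurally equivalent residues share a name across tRNAs. A 76-nt
tRNA maps label *i* to sequence index *i*−1. For 74–78-nt molecules the
package aligns to a fixed 76-label template, placing deletions (labels 17,
then 20) and insertions (17a, then 20a) in the D-loop only; anything outside
that range (class-II tRNAs with long variable arms) requires an explicit
sidecar numbering map, because variable-arm architecture is not inferable
from length. Regions follow the cloverleaf: acceptor stem 1–7/66–72, D-loop
14–21, anticodon stem 27–31/39–43, anticodon loop 32–38 with the anticodon
at 34–36, variable loop 44–48, T-loop 54–60. The anticodon stem–loop window
used for fragment filtering is labels 27–43.

## Packaged references and modification table

The host targets are the four *E. coli* tRNAs cleaved by the AriB nuclease.
Lys-UUU and Asn-GUU are the known database sequences; their site hexamers
(positions 36–41) read UAAUCA and UAAUCC. Thr-UGU and Thr-CGU, and the three
phage T5 escape variants, are **constraint-based reconstructions**: 76-nt
cloverleaf-paired sequences satisfying every published positional constraint
(anticodon at 34–36, site hexamer — UAAUCA for Thr-UGU, UAAUGC for Thr-CGU,
site substitutions U39A/A41C/U16C for the T5 variants — and D-loop U16/U17
where applicable). They are labelled as reconstructed in the FASTA headers
and should not be treated as database sequences.

The modification table is likewise a reconstruction from standard *E. coli*
modification knowledge, built so the documented summary holds: Lys-UUU
carries 10 modified positions of 7 types (s4U8, D16/17/20, mnm5s2U34,
ct6A37, Ψ39, m7G46, m5U54, Ψ55) and the union over the four targets spans 13
distinct types (adding Gm, mnm5U, t6A, Q, acp3U, m2A). The "13" is counted
as distinct modification *types* over the union of the four tRNAs.
Mass deltas are average-mass differences vs the unmodified residue.

## Read simulator

Each read derives from one molecule: a tRNA drawn from fixed positive
abundance weights (default: seeded log-normal, σ = 0.75 — a skewed mixed
pool; fixed weights keep expected counts analytic), nicked with its
configured probability at a between-labels site; when nicked, one of the two
fragments is sequenced with equal probability. Two library chemistries are
modelled:

- **Protocol A** (cDNA-adapter): reverse transcription can terminate
  immediately 3′ of a modified residue. Scanning modified positions 3′→5′,
  each fires independently with `stall_prob` (default 0.25 per site — a free
  parameter, as per-modification stall rates are not quantified); the first
  that fires sets the read's apparent 5′ bound. Default profile 150 nt
  paired-end; mate 2 is the reverse complement of the interval's 3′ portion,
  adapters pre-trimmed. No misincorporation or read-through mutation model.
- **Protocol B** (RNA-end-ligated): read 5′ ends are true RNA 5′ ends.
  Default profile 50 nt single-end.

Substitution errors are applied per base (default 0.002, a typical
short-read rate); no indels and no quality modelling. Degenerate empty reads
are dropped and redrawn, with the drop count logged. All randomness flows
from one integer seed (PCG64); outputs are byte-identical across runs.

What the simulator does **not** emulate: ligation and PCR bias, rRNA and
other non-tRNA background, partial/position-dependent RT processivity,
isodecoder families beyond exact duplicates, and base-call quality
structure. Passing the recovery benchmarks therefore demonstrates the
correctness of the pipeline's logic under the modelled read chemistry, not
performance on arbitrary real libraries.

## Mapping and uniqueness

tRNA references are ~76 nt, so gapped alignment is unnecessary; what matters
is uniqueness semantics. The mapper indexes exact k-mers and extends
ungapped with a mismatch budget (default ≤2 substitutions). Seed size is
chosen per read as `len // (max_mismatch + 1)` (capped at 20, minimum 4;
shorter reads fall back to a full scan), so by pigeonhole at least one seed
block is error-free for any in-budget placement — the mapper is exhaustively
equivalent to a brute-force all-positions scan, which the tests verify.
Reads whose best score is tied across distinct tRNAs are dropped; ties
within one tRNA resolve to the smallest offset. Reads are assumed
sense-strand (both library protocols are directional). SAM import via pysam
provides interoperability; uniqueness there is the absence of an
equal-scoring secondary alignment on another reference.

## Depletion analysis

Per-tRNA counts of the full-length proxy class (span ≥ 65 nt) are converted
to CPM; `log10(treated + 0.5 CPM)` is regressed on `log10(control + 0.5
CPM)` by ordinary least squares (the 0.5-CPM pseudo-count admits zeros). A
tRNA is flagged depleted when its residual is below −k·MAD with k = 3, where
MAD is the normal-consistent robust scale (median absolute deviation ×
1.4826), i.e. ≈ 4.4 σ under Gaussian noise. The raw (unscaled) MAD would put
the cut near 2 σ and flag ~1 tRNA in 40 by chance; the scaled form is the
field-standard robust sigma and keeps the false-flag rate negligible.
Depletion flags are threshold-based and config-exposed; no p-values are
attached.

## Nick calling

Fragment-class alignments (< 45 nt, 5′ end in window 27–43) are piled up per
canonical label. For a label L, the treated 5′-end fraction (count over that
tRNA's fragment total) is compared with the control fraction; when the
control has no fragment reads for that tRNA — or no control is supplied —
the uniform in-window expectation 1/|window| is used instead. The score is
`log2((f_t + ε)/(f_c + ε))` with ε = 1/(treated total + 1) to keep scores
finite; calls require fraction ≥ 0.05 and score ≥ 1, and a call at L reports
a nick between L−1 and L. 3′-end pileups are tabulated but not required for
calls, since protocol-A truncation corrupts upstream-fragment 3′ evidence.
A 5′ end at the molecule start is never called (it is not a nick). No
direct-vs-indirect distinction is attempted for called sites; the caller
reports positional evidence only.

## Consensus scanning and escape annotation

The cleavage-site consensus is the hexamer UAAUCA at labels 36–41; the nick
falls between its 5th and 6th residues (40|41). The scan is anchored at
label 36 by default because the site is positionally defined; an unanchored
mode scans the whole sequence for exploratory use. With one allowed
mismatch, Lys-UUU, Thr-UGU and Asn-GUU are hit; Thr-CGU differs at both 40
and 41 and needs a two-mismatch budget. Host-vs-phage substitutions over
shared labels are classified as Mut1 (U39→A), Mut2 (A41→C), Mut3 (U16→C),
other site-proximal (labels 36–43) or distal.

## Digestion and mass prediction

RNase T1 cleaves 3′ of every G, leaving 3′-phosphate upstream (2′,3′-cyclic
retained under `t1_cyclic=True`; the linear phosphate is the default) and
5′-OH downstream. A nuclease nick leaves 3′-OH / 5′-phosphate. Transcript
termini default to 5′-triphosphate / 3′-OH. Neutral masses are sums of
residue (NMP − H₂O) average masses plus water on a 5′-P/3′-OH baseline with
terminal adjustments (5′-OH −HPO₃; 5′-PPP +2 HPO₃; 3′-P +HPO₃; 3′-cP +HPO₃ −
H₂O); element averages follow NIST isotopic abundances, and monoisotopic
mode is available. MH⁺ = neutral + H. Mass conservation holds in formula
terms: each hydrolytic nick adds one water; linear-mode T1 cuts add one
water each, cyclic-mode cuts none. Modified residues enter as additive mass
deltas; in-vitro transcripts are digested without the table. Observed MALDI
peaks are matched to the nearest predicted MH⁺ within 1 Da (the stated
average-mass measurement accuracy); multiple predictions inside the
tolerance flag the match as ambiguous.

With the packaged Lys-UUU sequence, the T1 product spanning the nick site is
bounded by G30 and G45 and is therefore **15 nt** (positions 31–45,
ACUUUUAAUCAAUUG), splitting on nicking into 10-nt and 5-nt pieces. This is a
sequence-level consequence of the site U36AAUC|A41 plus T1 specificity; a
14-nt count for the same fragment corresponds to omitting its 3′-terminal G.

## Toeprint model

A depleted decoder stalls the ribosome with the cognate codon in the A-site.
Scanning in-frame codons from the start (AUG is codon 0), the first codon in
the depleted set stalls; the expected cDNA 3′ ends fall at the pair of
offsets {13, 14} nt downstream of the first A-site base (the offset is
reported as a pair, not a single value, and consumers use the union window
± 2 nt slack). The initiation control places the toeprint at the same
offsets from the start codon's first base — a documented simplification, as
the exact A-site geometry of an initiation-arrested ribosome is not
modelled. The demo template is a reconstructed short mRNA (AUG, alanine
spacers, AAA, then a downstream ACA) used for tests and demonstrations; it
is not a published sequence. Trace quantification integrates trapezoidally
inside windows with interpolated boundaries.

## Benchmark problem sizes

The replicated recovery benchmark simulates 40-tRNA pools (the four targets
plus 36 generated cloverleaf-consistent fillers), protocol B with 80-nt
reads so that intact molecules yield full-length-class reads while nick
products keep true 5′ ends, 50 000 reads per sample, nicks at 40|41 in
Lys/Thr-UGU/Asn at probabilities 0.9/0.7/0.3. The test suite runs 20 seeded
replicates; the acceptance script runs 10. At the 0.3 nick probability the
Asn target retains 70 % of its full-length signal and also falls below the
−3·MAD threshold alongside the two strong targets; its nick is likewise
called from the fragment pileup.

## Known limitations

- Host Thr-UGU/Thr-CGU and the T5 variants are reconstructions (above);
  analyses of real data should substitute genome-derived references.
- No multi-mapping rescue or EM reallocation across isodecoder families; a
  read matching two identical references is simply discarded.
- Cleavage calls carry scores, not calibrated error rates.
- No isotope envelopes, MS/MS fragment ions or spectrum-file parsing in the
  mass module; peak lists are plain m/z values.
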