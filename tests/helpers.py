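"""Independent oracles shared by the unit and acceptance tests."""

from collections import Counter

from pyteomics import mass as pmass

# elemental composition of chain residues (nucleoside monophosphate - H2O)
RESIDUE_COMPOSITION = {
    "A": {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1},
    "C": {"C": 9, "H": 12, "N": 3, "O": 7, "P": 1},
    "G": {"C": 10, "H": 12, "N": 5, "O": 7, "P": 1},
    "U": {"C": 9, "H": 11, "N": 2, "O": 8, "P": 1},
}
H2O = {"H": 2, "O": 1}
HPO3 = {"H": 1, "P": 1, "O": 3}


def oligo_composition(sequence, five_prime="P", three_prime="OH"):
    """Elemental composition of an oligo from first principles."""
    comp = Counter()
    for base in sequence:
        comp.update(RESIDUE_COMPOSITION[base])
    comp.update(H2O)
    if five_prime == "OH":
        comp.subtract(HPO3)
    elif five_prime == "PPP":
        comp.update(HPO3)
        comp.update(HPO3)
    if three_prime == "P":
        comp.update(HPO3)
    elif three_prime == "cP":
        comp.update(HPO3)
        comp.subtract(H2O)
    return {el: n for el, n in comp.items() if n}


def oracle_average_mass(sequence, five_prime="P", three_prime="OH"):
    """Average neutral mass via pyteomics from the elemental composition."""
    comp = oligo_composition(sequence, five_prime, three_prime)
    return pmass.calculate_mass(composition=pmass.Composition(comp), average=True)


def brute_force_map(read_seq, records, max_mismatch):
    """All-positions scan: best-scoring placements of one read.

    Returns ``(best_mismatches, placements)`` where placements is the sorted
    list of ``(trna_id, start)`` attaining the best score, or ``None`` when
    nothing is within the mismatch budget.
    """
    hits = []
    n = len(read_seq)
    for rec in records:
        seq = rec.sequence
        for pos in range(len(seq) - n + 1):
            mm = sum(a != b for a, b in zip(read_seq, seq[pos:pos + n]))
            if mm <= max_mismatch:
                hits.append((mm, rec.id, pos))
    if not hits:
        return None
    best = min(mm for mm, _, _ in hits)
    return best, sorted((tid, pos) for mm, tid, pos in hits if mm == best)
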