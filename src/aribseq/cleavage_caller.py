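"""5'-end pileups, nick calling, consensus-site scanning, escape annotation.

A nick between canonical positions p and p+1 is evidenced by fragment reads
whose 5' ends sit at label p+1 (the downstream cleavage product).  3'-end
counts are tabulated too but are not required for a call: in stall-prone
library chemistries the upstream fragment's apparent 3' boundary is
unreliable, whereas RNA-end-ligated protocols read true 5' ends.

The cleavage-site consensus is the hexamer at canonical labels 36-41
(UAAUCA on the primary target, nick between the 5th and 6th residues).
Escape annotation classifies host-vs-phage substitutions into the named
escape mutations (Mut1 U39A, Mut2 A41C, Mut3 U16C), other site-proximal
changes (labels 36-43), and distal changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import AlignmentRecord
from .reference import TRNAError, TRNARecord

__all__ = [
    "EndPileup",
    "end_pileup",
    "CleavageCall",
    "call_sites",
    "PredictedNick",
    "scan_consensus",
    "Substitution",
    "annotate_escape",
    "CONSENSUS_SITE",
]

#: cleavage-site hexamer at canonical labels 36-41 of the primary target
CONSENSUS_SITE = "UAAUCA"


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

class EndPileup:
    """Per-tRNA, per-canonical-label counts of read 5' and 3' termini."""

    def __init__(self, records: Sequence[TRNARecord]):
        self.by_id = {r.id: r for r in records}
        self.end5 = {r.id: np.zeros(len(r), dtype=int) for r in records}
        self.end3 = {r.id: np.zeros(len(r), dtype=int) for r in records}

    def add(self, aln: AlignmentRecord) -> None:
        self.end5[aln.trna_id][aln.start] += 1
        self.end3[aln.trna_id][aln.end - 1] += 1

    def total(self, trna_id: str) -> int:
        return int(self.end5[trna_id].sum())

    def count5(self, trna_id: str, label: str) -> int:
        return int(self.end5[trna_id][self.by_id[trna_id].index_of(label)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, rec in sorted(self.by_id.items()):
            for i, lab in enumerate(rec.numbering):
                c5, c3 = int(self.end5[tid][i]), int(self.end3[tid][i])
                if c5 or c3:
                    rows.append((tid, lab, c5, c3))
        return pd.DataFrame(rows, columns=["trna_id", "label", "end5_count", "end3_count"])


def end_pileup(fragment_alignments: Sequence[AlignmentRecord],
               records: Sequence[TRNARecord]) -> EndPileup:
    """Tabulate 5'/3' termini of (fragment-class) alignments per label."""
    pile = EndPileup(records)
    for aln in fragment_alignments:
        pile.add(aln)
    return pile


# ---------------------------------------------------------------------------
# nick calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageCall:
    trna_id: str
    nick_between: tuple[str, str]     # (p, p+1): 5' ends pile up at p+1
    treated_fraction: float
    control_fraction: float
    score: float                      # log2((treated+eps)/(control+eps))


def _window_labels(record: TRNARecord, window: tuple[int, int]) -> list[str]:
    lo, hi = window
    return [lab for lab in record.numbering
            if lab.isdigit() and lo <= int(lab) <= hi]


def call_sites(treated: EndPileup,
               control: EndPileup | None = None,
               window: tuple[int, int] = (27, 43),
               min_frac: float = 0.05,
               min_score: float = 1.0,
               ) -> list[CleavageCall]:
    """Call nick positions from in-window 5'-end enrichment over a control.

    For each in-window label L with treated 5'-end fraction >= ``min_frac``
    and enrichment score >= ``min_score``, a nick between (L-1, L) is
    emitted.  Fractions are per-tRNA (counts over that tRNA's fragment
    total); when no control pileup is given, or the control has no fragment
    reads for a tRNA, the control fraction falls back to the uniform
    in-window expectation 1/|window|.  Calls are sorted by score descending,
    ties broken by the smaller label.
    """
    if all(treated.total(tid) == 0 for tid in treated.by_id):
        warnings.warn("treated pileup has zero fragment reads; no calls")
        return []
    calls: list[CleavageCall] = []
    for tid, rec in treated.by_id.items():
        total_t = treated.total(tid)
        if total_t == 0:
            continue
        labels = _window_labels(rec, window)
        uniform = 1.0 / max(len(labels), 1)
        eps = 1.0 / (total_t + 1)
        total_c = control.total(tid) if control is not None and tid in control.by_id else 0
        for lab in labels:
            idx = rec.index_of(lab)
            if idx == 0:
                continue  # a 5' end at the molecule start is not a nick
            frac_t = treated.end5[tid][idx] / total_t
            if frac_t < min_frac:
                continue
            frac_c = control.end5[tid][idx] / total_c if total_c else uniform
            score = math.log2((frac_t + eps) / (frac_c + eps))
            if score >= min_score:
                calls.append(CleavageCall(
                    trna_id=tid,
                    nick_between=(rec.label_of(idx - 1), lab),
                    treated_fraction=float(frac_t),
                    control_fraction=float(frac_c),
                    score=float(score),
                ))
    calls.sort(key=lambda c: (-c.score, _label_rank(c.nick_between[1]), c.trna_id))
    return calls


def _label_rank(label: str) -> float:
    return int(label) if label.isdigit() else math.inf


# ---------------------------------------------------------------------------
# consensus scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictedNick:
    trna_id: str
    nick_between: tuple[str, str]
    start_label: str
    n_mismatches: int


def scan_consensus(record: TRNARecord,
                   consensus: str = CONSENSUS_SITE,
                   max_mismatch: int = 0,
                   anchor36: bool = True,
                   ) -> list[PredictedNick]:
    """Predict nicks from placements of the cleavage-site consensus.

    Each placement with <= ``max_mismatch`` mismatches yields a nick between
    the 5th and 6th matched residues.  ``anchor36`` restricts placements to
    start at canonical label 36 (the site is positionally defined);
    unanchored mode scans every start position for exploratory use.
    """
    m = len(consensus)
    if anchor36:
        if not record.has_label("36"):
            raise TRNAError(f"{record.id}: label 36 absent")
        starts = [record.index_of("36")]
    else:
        starts = range(len(record.sequence) - m + 1)
    hits = []
    for start in starts:
        segment = record.sequence[start:start + m]
        if len(segment) < m:
            continue
        mm = sum(a != b for a, b in zip(segment, consensus))
        if mm <= max_mismatch:
            hits.append(PredictedNick(
                trna_id=record.id,
                nick_between=(record.label_of(start + m - 2), record.label_of(start + m - 1)),
                start_label=record.label_of(start),
                n_mismatches=mm,
            ))
    return hits


# ---------------------------------------------------------------------------
# escape annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Substitution:
    label: str
    host_base: str
    phage_base: str
    mut_class: str    # Mut1 | Mut2 | Mut3 | site-proximal | distal


_NAMED_MUTS = {
    ("39", "U", "A"): "Mut1",
    ("41", "A", "C"): "Mut2",
    ("16", "U", "C"): "Mut3",
}


def annotate_escape(host: TRNARecord, phage: TRNARecord) -> list[Substitution]:
    """List host-vs-phage substitutions over shared canonical labels.

    Named escape substitutions get their Mut1/Mut2/Mut3 tags; any other
    difference at labels 36-43 is site-proximal, elsewhere distal.
    """
    shared = [lab for lab in host.numbering if phage.has_label(lab)]
    if not shared:
        raise TRNAError(f"{host.id} vs {phage.id}: no shared canonical labels")
    subs = []
    for lab in shared:
        hb, pb = host.base_at(lab), phage.base_at(lab)
        if hb == pb:
            continue
        mut_class = _NAMED_MUTS.get((lab, hb, pb))
        if mut_class is None:
            proximal = lab.isdigit() and 36 <= int(lab) <= 43
            mut_class = "site-proximal" if proximal else "distal"
        subs.append(Substitution(lab, hb, pb, mut_class))
    return subs
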