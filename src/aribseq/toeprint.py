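"""Ribosome toeprint (primer-extension stall) prediction and quantification.

When reverse transcriptase runs into a stalled ribosome, the cDNA 3' end
falls approximately 13 or 14 nt downstream of the first base of the
ribosomal A-site; the offset is therefore carried as the pair {13, 14} and
consumers use the union window.  Depletion of a tRNA stalls ribosomes with
the cognate codon in the A-site: the model scans in-frame codons from the
start and stalls at the first codon whose tRNA is depleted.  A codon is
either depleted or not — per-codon kinetics are deliberately out of scope,
matching how electropherogram toeprints are read qualitatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reference import TRNAError

__all__ = [
    "MRNATemplate",
    "StallPrediction",
    "TOEPRINT_OFFSETS",
    "predict_stall",
    "start_control",
    "stall_window",
    "quantify_peaks",
    "demo_template",
]

#: cDNA 3' ends fall ~13-14 nt downstream of the first A-site base
TOEPRINT_OFFSETS: tuple[int, int] = (13, 14)


@dataclass(frozen=True)
class MRNATemplate:
    """An mRNA with a fixed AUG start; codons are read in frame from it."""

    sequence: str
    start_codon: int  # 0-based index of the A of AUG

    def __post_init__(self) -> None:
        seq = self.sequence
        if set(seq) - set("ACGU"):
            raise TRNAError("mRNA sequence must be RNA alphabet")
        if len(seq) < self.start_codon + 3:
            raise TRNAError("sequence too short for the given start codon")
        if seq[self.start_codon:self.start_codon + 3] != "AUG":
            raise TRNAError(f"no AUG at index {self.start_codon}")

    @property
    def codons(self) -> list[str]:
        """In-frame codons from the start codon (AUG is codon 0)."""
        tail = self.sequence[self.start_codon:]
        rem = len(tail) % 3
        if rem:
            warnings.warn(f"{rem} trailing nt beyond the last full codon ignored")
            tail = tail[: len(tail) - rem]
        return [tail[i:i + 3] for i in range(0, len(tail), 3)]


@dataclass(frozen=True)
class StallPrediction:
    codon_index: int                    # codons from start; AUG is 0
    codon: str
    a_site_index: int                   # 0-based mRNA index of A-site first base
    toeprint_positions: tuple[int, int]

    @property
    def cdna_end_positions(self) -> tuple[int, int]:
        return self.toeprint_positions


def predict_stall(mrna: MRNATemplate, depleted_codons: set[str],
                  ) -> StallPrediction | None:
    """First in-frame codon (at or after the start) whose tRNA is depleted.

    Returns ``None`` when no depleted codon occurs in frame.
    """
    for i, codon in enumerate(mrna.codons):
        if codon in depleted_codons:
            a_site = mrna.start_codon + 3 * i
            return StallPrediction(
                codon_index=i,
                codon=codon,
                a_site_index=a_site,
                toeprint_positions=tuple(a_site + off for off in TOEPRINT_OFFSETS),
            )
    return None


def start_control(mrna: MRNATemplate) -> StallPrediction:
    """Initiation-stall control (e.g. thiostrepton-arrested ribosomes).

    Initiation geometry is simplified: the control toeprint is placed at the
    standard offsets from the start codon's first base; the exact A-site
    position of an initiating ribosome is not modelled.
    """
    a_site = mrna.start_codon
    return StallPrediction(
        codon_index=0,
        codon=mrna.codons[0],
        a_site_index=a_site,
        toeprint_positions=tuple(a_site + off for off in TOEPRINT_OFFSETS),
    )


def stall_window(prediction: StallPrediction, slack: int = 2) -> tuple[float, float]:
    """Quantification window around the expected toeprint positions."""
    return (min(prediction.toeprint_positions) - slack,
            max(prediction.toeprint_positions) + slack)


def quantify_peaks(trace: list[tuple[float, float]],
                   windows: dict[str, tuple[float, float]],
                   ) -> dict[str, float]:
    """Trapezoidal area under the trace inside each named window.

    The trace is a sorted list of (position, intensity) points; window
    boundaries are linearly interpolated so a unit rectangle spanning a
    window integrates exactly to the window width.
    """
    if not trace:
        raise TRNAError("empty trace")
    xs = np.array([p for p, _ in trace], dtype=float)
    ys = np.array([v for _, v in trace], dtype=float)
    if np.any(np.diff(xs) < 0):
        raise TRNAError("trace positions must be sorted")
    areas = {}
    for name, (lo, hi) in windows.items():
        lo_c, hi_c = max(lo, xs[0]), min(hi, xs[-1])
        if hi_c <= lo_c:
            areas[name] = 0.0
            continue
        inner = xs[(xs > lo_c) & (xs < hi_c)]
        grid = np.concatenate(([lo_c], inner, [hi_c]))
        vals = np.interp(grid, xs, ys)
        areas[name] = float(np.trapezoid(vals, grid))
    return areas


def demo_template(lysine_mutated: bool = False) -> MRNATemplate:
    """A short reconstructed all-target-codon template.

    Lays out AUG, alanine spacers, the lysine AAA codon and the downstream
    threonine ACA codon; ``lysine_mutated`` swaps AAA for an alanine codon
    (GCC) so the first depleted codon moves downstream.  This is a synthetic
    reconstruction for demonstrations and tests, not a published sequence.
    """
    lys = "GCC" if lysine_mutated else "AAA"
    utr5 = "GGGAGACCAC"                        # 10-nt leader
    orf = "AUG" + "GCU" + "GCA" + lys + "GCG" + "ACA" + "GCU" + "GCG" + "UAA"
    tail = "CGCAUCCGGAUACGGCAUCCG"             # room for toeprint offsets
    return MRNATemplate(sequence=utr5 + orf + tail, start_codon=len(utr5))
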