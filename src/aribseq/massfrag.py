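"""In-silico RNase T1 digestion and average-mass MH+ prediction.

RNase T1 cleaves 3' of guanosine, leaving a 3'-phosphate on the upstream
product (via a 2',3'-cyclic intermediate; both chemistries are supported)
and a 5'-OH on the downstream product.  An anticodon-nuclease nick is a
hydrolytic break leaving 3'-OH upstream and 5'-phosphate downstream.  Masses
are *average* masses (MALDI-TOF linear mode reads average MH+); monoisotopic
masses are exposed as an option.

The neutral mass of an oligo is the sum of residue (nucleoside-monophosphate
minus water) masses plus one water, computed on a 5'-phosphate / 3'-OH
baseline, with terminal adjustments:

===========  =================
terminus     adjustment
===========  =================
5'-OH        -HPO3
5'-PPP       +2 HPO3
3'-P         +HPO3
3'-cP        +HPO3 - H2O
===========  =================

Modified residues are handled as additive mass deltas; in-vitro transcripts
carry no modifications, so digestion of a transcript simply omits the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .reference import ModificationTable, TRNAError, TRNARecord

__all__ = [
    "Oligo",
    "DigestProduct",
    "PeakMatch",
    "average_mass",
    "mh_plus",
    "digest_t1",
    "nick_signature",
    "NickSignature",
    "match_peaks",
    "read_peak_list",
]

# average masses (standard atomic weights): internal residue = NMP - H2O
_RESIDUE_AVG = {"A": 329.20636, "C": 305.18162, "G": 345.20576, "U": 306.16638}
_H2O_AVG = 18.01529
_HPO3_AVG = 79.97992
_H_AVG = 1.00794

# monoisotopic counterparts
_RESIDUE_MONO = {"A": 329.05252, "C": 305.04129, "G": 345.04744, "U": 306.02530}
_H2O_MONO = 18.010565
_HPO3_MONO = 79.966331
_H_MONO = 1.0078250319

_FIVE_PRIME = {"OH", "P", "PPP"}
_THREE_PRIME = {"OH", "P", "cP"}


@dataclass(frozen=True)
class Oligo:
    """An RNA fragment with explicit terminal chemistries and mod deltas."""

    sequence: str
    five_prime: str = "P"
    three_prime: str = "OH"
    mod_deltas: tuple[tuple[str, float], ...] = ()   # (position label, delta Da)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise TRNAError("empty oligo")
        bad = set(self.sequence) - set(_RESIDUE_AVG)
        if bad:
            raise TRNAError(f"unknown residues {sorted(bad)}")
        if self.five_prime not in _FIVE_PRIME:
            raise TRNAError(f"unknown 5' chemistry {self.five_prime!r}")
        if self.three_prime not in _THREE_PRIME:
            raise TRNAError(f"unknown 3' chemistry {self.three_prime!r}")
        for _, delta in self.mod_deltas:
            if not (delta == delta and abs(delta) < 1e6):   # finite
                raise TRNAError("non-finite modification mass delta")

    def __len__(self) -> int:
        return len(self.sequence)


def average_mass(oligo: Oligo, monoisotopic: bool = False) -> float:
    """Neutral mass of the oligo in Da (average by default)."""
    residues, h2o, hpo3 = (
        (_RESIDUE_MONO, _H2O_MONO, _HPO3_MONO) if monoisotopic
        else (_RESIDUE_AVG, _H2O_AVG, _HPO3_AVG)
    )
    mass = sum(residues[b] for b in oligo.sequence) + h2o
    if oligo.five_prime == "OH":
        mass -= hpo3
    elif oligo.five_prime == "PPP":
        mass += 2 * hpo3
    if oligo.three_prime == "P":
        mass += hpo3
    elif oligo.three_prime == "cP":
        mass += hpo3 - h2o
    mass += sum(delta for _, delta in oligo.mod_deltas)
    return mass


def mh_plus(oligo: Oligo, monoisotopic: bool = False) -> float:
    """Singly protonated molecular-ion mass (neutral + H)."""
    return average_mass(oligo, monoisotopic) + (_H_MONO if monoisotopic else _H_AVG)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigestProduct:
    """A digestion product with its source interval and end provenance."""

    oligo: Oligo
    trna_id: str
    start_index: int
    end_index: int            # half-open on the parent
    start_label: str
    end_label: str
    five_from: str            # terminus | t1 | nick
    three_from: str

    def spans_labels(self, a: str, b: str, record: TRNARecord) -> bool:
        ia, ib = record.index_of(a), record.index_of(b)
        return self.start_index <= ia and ib < self.end_index

    def __len__(self) -> int:
        return len(self.oligo)


def _mod_deltas_for(record: TRNARecord, mods: ModificationTable | None,
                    start: int, end: int) -> tuple[tuple[str, float], ...]:
    if mods is None:
        return ()
    out = []
    for row in mods.for_trna(record.id):
        if row.mass_delta_avg_da is None or not record.has_label(row.position_label):
            continue
        idx = record.index_of(row.position_label)
        if start <= idx < end:
            out.append((row.position_label, row.mass_delta_avg_da))
    return tuple(out)


def digest_t1(record: TRNARecord,
              nicks: Sequence[tuple[str, str]] = (),
              mods: ModificationTable | None = None,
              t1_cyclic: bool = False,
              five_prime: str = "PPP",
              three_prime: str = "OH",
              ) -> list[DigestProduct]:
    """Complete RNase T1 digest of an (optionally nicked) tRNA.

    Cleaves 3' of every G; T1 boundaries carry 3'-P upstream (2',3'-cyclic
    when ``t1_cyclic``) and 5'-OH downstream.  Nicks (between adjacent
    canonical labels) carry 3'-OH upstream and 5'-P downstream.  Molecule
    termini keep the configured chemistries (transcript defaults 5'-PPP /
    3'-OH).  Products tile the parent sequence exactly.
    """
    seq = record.sequence
    t1_cuts = {i + 1 for i, b in enumerate(seq) if b == "G" and i + 1 < len(seq)}
    nick_cuts = set()
    for p, q in nicks:
        i, j = record.index_of(p), record.index_of(q)
        if j != i + 1:
            raise TRNAError(f"{record.id}: nick labels {p}|{q} not adjacent")
        if j in t1_cuts:
            raise TRNAError(f"{record.id}: nick {p}|{q} coincides with a T1 cut")
        nick_cuts.add(j)
    bounds = sorted({0, len(seq)} | t1_cuts | nick_cuts)
    t1_three = "cP" if t1_cyclic else "P"
    products = []
    for a, b in zip(bounds, bounds[1:]):
        five_from = "terminus" if a == 0 else ("nick" if a in nick_cuts else "t1")
        three_from = "terminus" if b == len(seq) else ("nick" if b in nick_cuts else "t1")
        chem5 = {"terminus": five_prime, "t1": "OH", "nick": "P"}[five_from]
        chem3 = {"terminus": three_prime, "t1": t1_three, "nick": "OH"}[three_from]
        products.append(DigestProduct(
            oligo=Oligo(seq[a:b], five_prime=chem5, three_prime=chem3,
                        mod_deltas=_mod_deltas_for(record, mods, a, b)),
            trna_id=record.id,
            start_index=a, end_index=b,
            start_label=record.label_of(a), end_label=record.label_of(b - 1),
            five_from=five_from, three_from=three_from,
        ))
    return products


@dataclass(frozen=True)
class NickSignature:
    """Diagnostic triple: T1 product spanning the nick site, and the two
    sub-products that replace it once the nick has fired."""

    spanning: DigestProduct
    upstream: DigestProduct
    downstream: DigestProduct

    def masses(self, monoisotopic: bool = False) -> dict[str, float]:
        return {
            "spanning_mh": mh_plus(self.spanning.oligo, monoisotopic),
            "upstream_mh": mh_plus(self.upstream.oligo, monoisotopic),
            "downstream_mh": mh_plus(self.downstream.oligo, monoisotopic),
        }


def nick_signature(record: TRNARecord, nick: tuple[str, str],
                   mods: ModificationTable | None = None,
                   t1_cyclic: bool = False,
                   ) -> NickSignature:
    """The mass-spectrometric signature of one nick under T1 digestion.

    Present-if-uncut: the T1 product spanning the nick site.  Present-if-cut:
    the two sub-products, upstream ending 3'-OH and downstream starting 5'-P.
    """
    intact = digest_t1(record, mods=mods, t1_cyclic=t1_cyclic)
    spanning = [pr for pr in intact if pr.spans_labels(nick[0], nick[1], record)]
    if not spanning:
        raise TRNAError(f"{record.id}: no single T1 product spans {nick[0]}|{nick[1]}")
    nicked = digest_t1(record, nicks=[nick], mods=mods, t1_cyclic=t1_cyclic)
    j = record.index_of(nick[1])
    upstream = next(pr for pr in nicked if pr.end_index == j)
    downstream = next(pr for pr in nicked if pr.start_index == j)
    return NickSignature(spanning[0], upstream, downstream)


# ---------------------------------------------------------------------------
# peak matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakMatch:
    observed_mz: float
    product: DigestProduct | None
    predicted_mh: float | None
    delta: float | None
    ambiguous: bool = False


def match_peaks(predicted: Sequence[DigestProduct], observed: Sequence[float],
                tol: float = 1.0, monoisotopic: bool = False) -> list[PeakMatch]:
    """Match observed m/z peaks to nearest predicted MH+ within ``tol`` Da.

    Unmatched peaks are reported with ``product=None``; peaks with several
    predictions inside the tolerance are flagged ambiguous (nearest kept).
    """
    if tol <= 0:
        raise TRNAError("tolerance must be positive")
    mhs = [(mh_plus(p.oligo, monoisotopic), p) for p in predicted]
    out = []
    for mz in observed:
        inside = sorted(((abs(mh - mz), mh, p) for mh, p in mhs
                         if abs(mh - mz) <= tol), key=lambda t: t[0])
        if not inside:
            out.append(PeakMatch(mz, None, None, None))
            continue
        d, mh, prod = inside[0]
        out.append(PeakMatch(mz, prod, mh, mh - mz, ambiguous=len(inside) > 1))
    return out


def read_peak_list(path: str | Path) -> list[float]:
    """Observed MALDI peak list CSV with an ``mz`` column."""
    df = pd.read_csv(path)
    if "mz" not in df.columns:
        raise TRNAError(f"{path}: peak list needs an 'mz' column")
    return [float(v) for v in df["mz"]]
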