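"""Synthetic small-RNA-seq read generator with nicking and RT-stall models.

Emulates two tRNA-seq library chemistries:

* **Protocol A** (cDNA-adapter libraries): adapters are ligated to the cDNA,
  so reverse-transcriptase stalls at modified residues are visible — a read's
  apparent 5' bound is the stall point, not the RNA 5' end.  Default profile
  150-nt paired-end.
* **Protocol B** (RNA-end-ligated libraries): adapters go onto RNA ends prior
  to RT, so read 5' ends are true RNA 5' ends — intact molecules start at
  position 1, nuclease cleavage products start at the nick.  Default profile
  50-nt single-end.

Nicking is applied per molecule with a configurable probability at a
configurable between-labels site (the AriB site is 40|41).  The generator
also provides ground truth per read and a filler-reference factory for
building mixed pools around the packaged target tRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import ModificationTable, TRNAError, TRNARecord, assign_canonical_numbering

__all__ = [
    "NickSite",
    "PoolSpec",
    "Fragment",
    "SimRead",
    "simulate_cleavage",
    "simulate_read",
    "simulate_pool",
    "make_filler_references",
    "write_fastq",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_BASES = "ACGU"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NickSite:
    """A nuclease nick between two adjacent canonical labels."""

    trna_id: str
    between: tuple[str, str] = ("40", "41")
    probability: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise TRNAError(f"nick probability {self.probability} outside [0, 1]")


@dataclass
class PoolSpec:
    """Conditions for one simulated library.

    ``abundances`` are fixed positive weights (not resampled), so expected
    per-tRNA read counts are analytic.  ``stall_prob`` is the per-modified-
    position probability that reverse transcription terminates immediately 3'
    of the residue (protocol A only).
    """

    abundances: dict[str, float]
    nick_sites: list[NickSite] = field(default_factory=list)
    protocol: str = "B"
    stall_prob: float = 0.25
    error_rate: float = 0.002
    read_length: int | None = None
    paired: bool | None = None
    n_reads: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.abundances.values()):
            raise TRNAError("abundance weights must be positive")
        if self.protocol not in ("A", "B"):
            raise TRNAError(f"unknown protocol {self.protocol!r}")
        if not 0.0 <= self.error_rate <= 1.0 or not 0.0 <= self.stall_prob <= 1.0:
            raise TRNAError("probabilities must lie in [0, 1]")
        if self.n_reads < 0:
            raise TRNAError("n_reads must be >= 0")
        # platform defaults: protocol A = 150 nt paired, protocol B = 50 nt single
        if self.read_length is None:
            self.read_length = 150 if self.protocol == "A" else 50
        if self.paired is None:
            self.paired = self.protocol == "A"


@dataclass(frozen=True)
class Fragment:
    """A contiguous piece of a tRNA (0-based half-open on the parent)."""

    record: TRNARecord
    start: int
    end: int
    nick_between: tuple[str, str] | None = None  # nick that created an end

    @property
    def sequence(self) -> str:
        return self.record.sequence[self.start:self.end]

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimRead:
    read_id: str
    trna_id: str
    sequence: str
    start: int            # 0-based offset of the read 5' end on the tRNA
    end: int
    frag_start_label: str
    frag_end_label: str
    nick_between: tuple[str, str] | None
    stall_label: str | None


def simulate_cleavage(record: TRNARecord, site: tuple[str, str], p: float,
                      rng: np.random.Generator,
                      ) -> tuple[Fragment, Fragment] | None:
    """With probability ``p``, nick between two adjacent labels.

    Returns the (5' fragment, 3' fragment) pair, or ``None`` when the
    molecule stays intact.  Fragment lengths always sum to the parent length.
    """
    i, j = record.index_of(site[0]), record.index_of(site[1])
    if j != i + 1:
        raise TRNAError(
            f"{record.id}: nick site {site} labels are not adjacent residues"
        )
    if rng.random() >= p:
        return None
    n = len(record)
    return (
        Fragment(record, 0, j, nick_between=tuple(site)),
        Fragment(record, j, n, nick_between=tuple(site)),
    )


def _modified_indices(record: TRNARecord, mods: ModificationTable | None) -> list[int]:
    if mods is None:
        return []
    return sorted(
        record.index_of(lab) for lab in mods.modified_labels(record.id)
        if record.has_label(lab)
    )


def simulate_read(fragment: Fragment, spec: PoolSpec, rng: np.random.Generator,
                  mods: ModificationTable | None = None,
                  ) -> tuple[int, int, str | None]:
    """Sequenced interval (start, end, stall label) for one fragment.

    Protocol B reads start at the fragment's true 5' end.  Protocol A reads
    start at the RT stall point: scanning modified positions 3'->5' from the
    fragment 3' end, the first that fires under ``stall_prob`` terminates the
    cDNA immediately 3' of itself; otherwise the fragment 5' end is reached.
    The interval is then truncated to ``read_length``.
    """
    start = fragment.start
    stall_label: str | None = None
    if spec.protocol == "A" and spec.stall_prob > 0:
        for idx in sorted(_modified_indices(fragment.record, mods), reverse=True):
            if not fragment.start <= idx < fragment.end - 1:
                continue
            if rng.random() < spec.stall_prob:
                start = idx + 1
                stall_label = fragment.record.label_of(idx)
                break
    end = min(fragment.end, start + int(spec.read_length))
    return start, end, stall_label


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_err, replace=False):
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def simulate_pool(spec: PoolSpec, references: Sequence[TRNARecord],
                  mods: ModificationTable | None = None,
                  ) -> tuple[list[SimRead], pd.DataFrame]:
    """Draw ``n_reads`` reads from the pool; returns reads plus ground truth.

    Each emitted read derives from one molecule: the tRNA is drawn from the
    abundance weights, nicked according to ``spec.nick_sites``, and (when
    nicked) one of the two fragments is sequenced with equal probability.
    Degenerate (empty) reads are dropped and redrawn so exactly ``n_reads``
    records are produced; the drop count is recorded in ``truth.attrs``.
    """
    by_id = {r.id: r for r in references}
    unknown = set(spec.abundances) - set(by_id)
    if unknown:
        raise TRNAError(f"abundance ids not in references: {sorted(unknown)}")
    for site in spec.nick_sites:
        if site.trna_id not in by_id:
            raise TRNAError(f"nick site names unknown tRNA {site.trna_id!r}")

    rng = np.random.default_rng(spec.seed)
    ids = sorted(spec.abundances)
    weights = np.array([spec.abundances[i] for i in ids], dtype=float)
    cumweights = np.cumsum(weights / weights.sum())
    nicks = {s.trna_id: s for s in spec.nick_sites}

    reads: list[SimRead] = []
    dropped = 0
    while len(reads) < spec.n_reads:
        tid = ids[min(int(np.searchsorted(cumweights, rng.random(), side="right")),
                      len(ids) - 1)]
        rec = by_id[tid]
        nick = nicks.get(tid)
        fragment = Fragment(rec, 0, len(rec))
        if nick is not None:
            pieces = simulate_cleavage(rec, nick.between, nick.probability, rng)
            if pieces is not None:
                fragment = pieces[int(rng.integers(2))]
        start, end, stall_label = simulate_read(fragment, spec, rng, mods)
        if end <= start:
            dropped += 1
            continue
        seq = _apply_errors(rec.sequence[start:end], spec.error_rate, rng)
        reads.append(SimRead(
            read_id=f"r{len(reads):07d}",
            trna_id=tid,
            sequence=seq,
            start=start,
            end=end,
            frag_start_label=rec.label_of(fragment.start),
            frag_end_label=rec.label_of(fragment.end - 1),
            nick_between=fragment.nick_between,
            stall_label=stall_label,
        ))

    truth = pd.DataFrame([
        {
            "read_id": r.read_id,
            "trna_id": r.trna_id,
            "frag_start_label": r.frag_start_label,
            "frag_end_label": r.frag_end_label,
            "nick": "|".join(r.nick_between) if r.nick_between else "",
            "stall_label": r.stall_label or "",
        }
        for r in reads
    ], columns=["read_id", "trna_id", "frag_start_label", "frag_end_label",
                "nick", "stall_label"])
    truth.attrs["dropped"] = dropped
    return reads, truth


def write_fastq(reads: Iterable[SimRead], out_prefix: str | Path,
                paired: bool = False, read_length: int | None = None,
                ) -> list[Path]:
    """Write reads as Phred+33 FASTQ with constant quality 'I'.

    Paired mode emits mate 1 as the interval 5' portion and mate 2 as the
    reverse complement of the interval's 3' portion (adapters are assumed
    pre-trimmed).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if paired:
        paths = [Path(f"{out_prefix}_1.fastq"), Path(f"{out_prefix}_2.fastq")]
        with open(paths[0], "w") as r1, open(paths[1], "w") as r2:
            for read in reads:
                rl = read_length or len(read.sequence)
                m1 = read.sequence[:rl]
                m2 = reverse_complement(read.sequence[-rl:])
                r1.write(f"@{read.read_id}/1\n{m1}\n+\n{'I' * len(m1)}\n")
                r2.write(f"@{read.read_id}/2\n{m2}\n+\n{'I' * len(m2)}\n")
        return paths
    path = Path(f"{out_prefix}.fastq")
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")
    return [path]


# ---------------------------------------------------------------------------
# filler references for mixed pools
# ---------------------------------------------------------------------------

_WC = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]

#: anticodons never assigned to filler tRNAs (the AriB target anticodons)
_RESERVED_ANTICODONS = {"UUU", "UGU", "CGU", "GUU"}


def make_filler_references(n: int, seed: int, prefix: str = "Sim-tRNA",
                           ) -> list[TRNARecord]:
    """Random 76-nt cloverleaf-consistent tRNAs for pool padding.

    Stems are Watson-Crick paired; the anticodon is drawn outside the AriB
    target set and the 36-41 window is kept clear of the cleavage-site
    consensus, so fillers are inert for the cleavage caller.
    """
    rng = np.random.default_rng(seed)
    records: list[TRNARecord] = []
    seen: set[str] = set()
    while len(records) < n:
        seq = _random_cloverleaf(rng)
        if seq[35:41] == "UAAUCA" or seq in seen:
            continue
        seen.add(seq)
        rec = TRNARecord(
            id=f"{prefix}-{len(records):02d}",
            sequence=seq,
            numbering=assign_canonical_numbering(76),
            amino_acid="Unk",
            source="host",
        )
        records.append(rec)
    return records


def _random_cloverleaf(rng: np.random.Generator) -> str:
    def bases(k: int) -> list[str]:
        return [_BASES[i] for i in rng.integers(0, 4, size=k)]

    def stem(k: int) -> tuple[list[str], list[str]]:
        five = bases(k)
        three = [dict(_WC)[b] for b in reversed(five)]
        return five, three

    acc5, acc3 = stem(7)
    d5, d3 = stem(4)
    ac5, ac3 = stem(5)
    t5, t3 = stem(5)
    anticodon = "UUU"
    while anticodon in _RESERVED_ANTICODONS:
        anticodon = "".join(bases(3))
    parts = (
        acc5 + bases(2)             # 1-7, 8-9
        + d5 + bases(8) + d3        # 10-13, 14-21, 22-25
        + bases(1)                  # 26
        + ac5 + bases(2) + list(anticodon) + bases(2) + ac3   # 27-43
        + bases(5)                  # 44-48 variable loop
        + t5 + ["U", "U", "C"] + bases(4) + t3                # 49-65
        + acc3 + bases(1) + ["C", "C", "A"]                   # 66-72, 73, 74-76
    )
    return "".join(parts)
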