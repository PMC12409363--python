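"""tRNA references in canonical (Sprinzl-style) coordinates.

A mature tRNA is modelled as a :class:`TRNARecord`: the RNA sequence plus an
ordered list of canonical position labels, one per residue.  Canonical labels
are text ("1".."76" with insertion labels such as "17a", "20a" and "e1".."e5"
for expanded loops), so that structurally equivalent positions — the anticodon
at 34-36, the anticodon-stem base pair 31:39, the D-loop dihydrouridine sites
16/17 — carry the same name in every tRNA regardless of loop-length
idiosyncrasies.

The module also houses the region map of the cloverleaf, the per-tRNA
base-modification table, and the packaged fixture sequences (the E. coli
tRNAs targeted by the AriB anticodon nuclease and the corresponding phage T5
escape variants; see ``data/*.fasta`` headers for provenance — two host
sequences and the T5 variants are constraint-based reconstructions).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "TRNAError",
    "TRNARecord",
    "RegionMap",
    "REGIONS",
    "ANTICODON_ARM_WINDOW",
    "ModificationTable",
    "assign_canonical_numbering",
    "load_trna_fasta",
    "load_numbering_map",
    "region_of",
    "site_hexamer",
    "modification_summary",
    "load_packaged_references",
    "load_packaged_modifications",
]

RNA_ALPHABET = frozenset("ACGU")


class TRNAError(ValueError):
    """Invalid tRNA record, numbering or modification table."""


# ---------------------------------------------------------------------------
# canonical numbering
# ---------------------------------------------------------------------------

def _master_label_order() -> list[str]:
    """Full ordered universe of canonical labels (core + insertion slots)."""
    order: list[str] = []
    for i in range(1, 77):
        order.append(str(i))
        if i == 17:
            order.append("17a")
        elif i == 20:
            order.extend(["20a", "20b"])
        elif i == 47:
            order.extend([f"e{j}" for j in range(1, 6)])
    return order


MASTER_ORDER: tuple[str, ...] = tuple(_master_label_order())
_ORDER_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(MASTER_ORDER)}

CORE_LABELS: tuple[str, ...] = tuple(str(i) for i in range(1, 77))

# automatic template edits, applied in order for lengths below/above 76;
# deletions and insertions are confined to the D-loop (labels 17/17a/20a)
_DELETION_ORDER = ("17", "20")
_INSERTION_ORDER = ("17a", "20a")


def assign_canonical_numbering(sequence_length: int) -> tuple[str, ...]:
    """Canonical labels for a tRNA of 74-78 nt.

    Exactly 76 nt maps label ``str(i + 1)`` to index ``i``.  Shorter (74-75)
    molecules drop D-loop labels 17 then 20; longer (77-78) molecules gain the
    insertion labels 17a then 20a.  Class-II tRNAs with long variable arms are
    not length-inferable and require an explicit sidecar map.
    """
    n = sequence_length
    if not 74 <= n <= 78:
        raise TRNAError(
            f"numbering required: cannot auto-assign canonical labels to a "
            f"{n}-nt tRNA (supported 74-78); supply a sidecar numbering map"
        )
    labels = list(CORE_LABELS)
    if n < 76:
        for lab in _DELETION_ORDER[: 76 - n]:
            labels.remove(lab)
    elif n > 76:
        for lab in _INSERTION_ORDER[: n - 76]:
            labels.insert(_label_sort_key(lab), lab)
        labels.sort(key=_label_sort_key)
    return tuple(labels)


def _label_sort_key(label: str) -> int:
    try:
        return _ORDER_INDEX[label]
    except KeyError:
        raise TRNAError(f"unknown canonical label {label!r}") from None


# ---------------------------------------------------------------------------
# record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRNARecord:
    """A tRNA sequence with canonical-position numbering.

    ``numbering`` holds one canonical label per residue, strictly increasing
    in canonical order.  ``source`` distinguishes host from phage tRNAs.
    """

    id: str
    sequence: str
    numbering: tuple[str, ...]
    amino_acid: str = "Unk"
    source: str = "host"
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise TRNAError(f"{self.id}: non-nucleotide characters {sorted(bad)}")
        if len(self.numbering) != len(seq):
            raise TRNAError(
                f"{self.id}: numbering length {len(self.numbering)} != "
                f"sequence length {len(seq)}"
            )
        keys = [_label_sort_key(lab) for lab in self.numbering]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise TRNAError(f"{self.id}: canonical labels not strictly increasing")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.numbering)})

    # -- coordinate helpers -------------------------------------------------
    def has_label(self, label: str) -> bool:
        return str(label) in self._index

    def index_of(self, label: str) -> int:
        """0-based sequence index of a canonical label."""
        try:
            return self._index[str(label)]
        except KeyError:
            raise TRNAError(f"{self.id}: label {label!r} not present") from None

    def label_of(self, index: int) -> str:
        return self.numbering[index]

    def base_at(self, label: str) -> str:
        return self.sequence[self.index_of(label)]

    @property
    def anticodon(self) -> str:
        if all(self.has_label(str(p)) for p in (34, 35, 36)):
            return "".join(self.base_at(str(p)) for p in (34, 35, 36))
        return ""

    @property
    def has_cca(self) -> bool:
        return self.sequence.endswith("CCA")

    def __len__(self) -> int:
        return len(self.sequence)


def _record_from_entry(name: str, seq: str,
                       numbering: Sequence[str] | None = None) -> TRNARecord:
    rna = seq.upper().replace("T", "U")
    nums = tuple(numbering) if numbering is not None else assign_canonical_numbering(len(rna))
    parts = name.split("-")
    aa = parts[1] if len(parts) >= 3 else "Unk"
    source = "phage" if parts[0].upper() in {"T5", "T4", "T7"} else "host"
    rec = TRNARecord(id=name, sequence=rna, numbering=nums, amino_acid=aa, source=source)
    ac_from_name = parts[2] if len(parts) >= 3 else ""
    if ac_from_name and rec.anticodon and set(ac_from_name) <= RNA_ALPHABET \
            and rec.anticodon != ac_from_name:
        raise TRNAError(
            f"{name}: anticodon in sequence ({rec.anticodon}) disagrees with id"
        )
    return rec


def load_numbering_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Sidecar numbering TSV: columns ``trna_id``, ``index0``, ``label``."""
    maps: dict[str, list[tuple[int, str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        for row in reader:
            maps.setdefault(row["trna_id"], []).append((int(row["index0"]), row["label"]))
    out: dict[str, tuple[str, ...]] = {}
    for tid, pairs in maps.items():
        pairs.sort()
        if [i for i, _ in pairs] != list(range(len(pairs))):
            raise TRNAError(f"{tid}: sidecar indices not contiguous from 0")
        out[tid] = tuple(lab for _, lab in pairs)
    return out


def load_trna_fasta(path: str | Path,
                    numbering_map: Mapping[str, Sequence[str]] | None = None,
                    ) -> list[TRNARecord]:
    """Read tRNA references from FASTA (RNA or DNA alphabet; T -> U).

    Numbering comes from the sidecar map when supplied, otherwise from
    :func:`assign_canonical_numbering`.  Records are returned sorted by id.
    """
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise TRNAError(f"no FASTA entries in {path}")
    seen: set[str] = set()
    records: list[TRNARecord] = []
    for entry in entries:
        if entry.id in seen:
            raise TRNAError(f"duplicate tRNA id {entry.id!r} in {path}")
        seen.add(entry.id)
        nums = numbering_map.get(entry.id) if numbering_map else None
        records.append(_record_from_entry(entry.id, str(entry.seq), nums))
    records.sort(key=lambda r: r.id)
    return records


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

class RegionMap:
    """Leaf-region assignment of canonical labels on the cloverleaf."""

    def __init__(self) -> None:
        self._by_label: dict[str, str] = {}
        spans = {
            "acceptor_stem": list(range(1, 8)) + list(range(66, 73)),
            "connector": [8, 9, 26],
            "D_stem": list(range(10, 14)) + list(range(22, 26)),
            "D_loop": list(range(14, 22)),
            "anticodon_stem": list(range(27, 32)) + list(range(39, 44)),
            "anticodon_loop": [32, 33, 37, 38],
            "anticodon": [34, 35, 36],
            "variable_loop": list(range(44, 49)),
            "T_stem": list(range(49, 54)) + list(range(61, 66)),
            "T_loop": list(range(54, 61)),
            "discriminator": [73],
            "cca_end": [74, 75, 76],
        }
        for name, labels in spans.items():
            for lab in labels:
                self._by_label[str(lab)] = name
        for lab in ("17a", "20a", "20b"):
            self._by_label[lab] = "D_loop"
        for j in range(1, 6):
            self._by_label[f"e{j}"] = "variable_loop"

    def region_of(self, label: str) -> str:
        try:
            return self._by_label[str(label)]
        except KeyError:
            raise TRNAError(f"unknown canonical label {label!r}") from None

    def labels_in(self, region: str) -> list[str]:
        return [lab for lab, reg in self._by_label.items() if reg == region]


REGIONS = RegionMap()

#: default fragment-filter window: the anticodon stem-loop, labels 27-43
#: (stem 27-31 / 39-43 plus loop 32-38)
ANTICODON_ARM_WINDOW: tuple[int, int] = (27, 43)


def region_of(label: str) -> str:
    """Leaf region of a canonical label (e.g. "40" -> "anticodon_stem")."""
    return REGIONS.region_of(label)


def site_hexamer(record: TRNARecord) -> str:
    """The six residues at canonical labels 36-41.

    This window brackets the AriB cleavage site (the nick falls between 40
    and 41, i.e. between the 5th and 6th residues of the hexamer).
    """
    labels = [str(p) for p in range(36, 42)]
    missing = [lab for lab in labels if not record.has_label(lab)]
    if missing:
        raise TRNAError(f"{record.id}: labels {missing} absent")
    idx = [record.index_of(lab) for lab in labels]
    if idx != list(range(idx[0], idx[0] + 6)):
        raise TRNAError(f"{record.id}: labels 36-41 are not contiguous")
    return record.sequence[idx[0]: idx[0] + 6]


# ---------------------------------------------------------------------------
# modifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModRecord:
    trna_id: str
    position_label: str
    mod_name: str
    mass_delta_avg_da: float | None = None


class ModificationTable:
    """Per-tRNA, per-canonical-position base-modification records."""

    def __init__(self, rows: Iterable[ModRecord]):
        self.rows: list[ModRecord] = list(rows)
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            key = (row.trna_id, row.position_label)
            if key in seen:
                raise TRNAError(f"duplicate modification entry for {key}")
            seen.add(key)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModificationTable":
        rows = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            )
            for row in reader:
                delta = row.get("mass_delta_avg_da", "")
                rows.append(ModRecord(
                    trna_id=row["trna_id"],
                    position_label=row["position_label"],
                    mod_name=row["mod_name"],
                    mass_delta_avg_da=float(delta) if delta not in ("", None) else None,
                ))
        return cls(rows)

    def validate_against(self, records: Iterable[TRNARecord]) -> None:
        by_id = {r.id: r for r in records}
        for row in self.rows:
            rec = by_id.get(row.trna_id)
            if rec is not None and not rec.has_label(row.position_label):
                raise TRNAError(
                    f"{row.trna_id}: modified position {row.position_label} "
                    f"not in numbering"
                )

    def trna_ids(self) -> set[str]:
        return {row.trna_id for row in self.rows}

    def for_trna(self, trna_id: str) -> list[ModRecord]:
        return [row for row in self.rows if row.trna_id == trna_id]

    def modified_labels(self, trna_id: str) -> list[str]:
        return [row.position_label for row in self.for_trna(trna_id)]

    def __len__(self) -> int:
        return len(self.rows)


def modification_summary(table: ModificationTable,
                         trna_ids: Sequence[str],
                         ) -> tuple[dict[str, int], int]:
    """Distinct modified positions per tRNA and distinct types over the set.

    Returns ``(positions_per_trna, n_distinct_mod_types)`` where the type
    count is taken over the union of all listed tRNAs (pseudouridine at 39
    and 55 counts once, etc.).
    """
    known = table.trna_ids()
    unknown = [tid for tid in trna_ids if tid not in known]
    if unknown:
        raise TRNAError(f"tRNA ids not in modification table: {unknown}")
    per = {tid: len({r.position_label for r in table.for_trna(tid)}) for tid in trna_ids}
    types = {r.mod_name for tid in trna_ids for r in table.for_trna(tid)}
    return per, len(types)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("aribseq").joinpath("data", name)))


def load_packaged_references(include_phage: bool = True) -> list[TRNARecord]:
    """The packaged host target tRNAs (and, optionally, the T5 variants)."""
    records = load_trna_fasta(_data_path("host_trnas.fasta"))
    if include_phage:
        records += load_trna_fasta(_data_path("t5_trnas.fasta"))
    records.sort(key=lambda r: r.id)
    return records


def load_packaged_modifications() -> ModificationTable:
    table = ModificationTable.from_tsv(_data_path("modifications.tsv"))
    table.validate_against(load_packaged_references(include_phage=False))
    return table
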