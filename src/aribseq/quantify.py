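"""Read mapping, read-class quantification and log-log depletion analysis.

tRNA references are short (~76 nt) and highly similar across isodecoders, so
the load-bearing behaviour is not gapped alignment but the *uniqueness*
semantics: a read whose best placement is tied across distinct tRNAs carries
no evidence and is dropped.  The built-in mapper is an exact k-mer seed index
with ungapped extension (<=2 substitutions by default, no indels); seed size
adapts to read length so that, by pigeonhole, any placement within the
mismatch budget is guaranteed to be found — the mapper is exhaustively
equivalent to a brute-force all-positions scan.  SAM import (pysam) provides
interoperability with external aligners.

Reads are classified into full-length proxies (aligned span >= 65 nt),
anticodon-arm fragments (span < 45 nt with the 5'-most residue inside the
anticodon stem-loop window, labels 27-43), or other.  Depletion is assessed
per tRNA by ordinary least squares of log10 treated CPM on log10 control CPM
and flagging strongly negative residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import TRNAError, TRNARecord

__all__ = [
    "AlignmentRecord",
    "ReferenceIndex",
    "map_reads",
    "import_alignments",
    "classify_reads",
    "READ_CLASSES",
    "abundance",
    "DepletionResult",
    "depletion_analysis",
    "plot_depletion",
]

READ_CLASSES = ("full_length", "anticodon_fragment", "other")


@dataclass(frozen=True)
class AlignmentRecord:
    """A read placement on one tRNA (0-based half-open offsets)."""

    read_id: str
    trna_id: str
    start: int
    end: int
    n_mismatches: int
    unique: bool = True


# ---------------------------------------------------------------------------
# built-in mapper
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Exact k-mer position index over a set of tRNA references."""

    def __init__(self, records: Sequence[TRNARecord]):
        if not records:
            raise TRNAError("empty reference set")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise TRNAError("duplicate reference ids")
        self.records = list(records)
        self.by_id = {r.id: r for r in records}
        self._kmer_cache: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def seeds(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._kmer_cache:
            index: dict[str, list[tuple[str, int]]] = {}
            for rec in self.records:
                seq = rec.sequence
                for pos in range(len(seq) - k + 1):
                    index.setdefault(seq[pos:pos + k], []).append((rec.id, pos))
            self._kmer_cache[k] = index
        return self._kmer_cache[k]


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _placements(index: ReferenceIndex, seq: str, max_mismatch: int,
                ) -> list[tuple[int, str, int]]:
    """All (mismatches, trna_id, start) placements within the budget."""
    n = len(seq)
    candidates: set[tuple[str, int]] = set()
    # seed size small enough that max_mismatch+1 disjoint seeds fit the read:
    # at least one seed is then error-free for any in-budget placement.
    k = n // (max_mismatch + 1)
    if k >= 4:
        k = min(k, 20)
        seeds = index.seeds(k)
        offsets = list(range(0, n - k + 1, k))
        if offsets[-1] != n - k:
            offsets.append(n - k)
        for off in offsets:
            for tid, pos in seeds.get(seq[off:off + k], ()):
                candidates.add((tid, pos - off))
    else:  # tiny read: brute-force every diagonal
        for rec in index.records:
            for pos in range(len(rec.sequence) - n + 1):
                candidates.add((rec.id, pos))
    out = []
    for tid, start in candidates:
        ref = index.by_id[tid].sequence
        if start < 0 or start + n > len(ref):
            continue
        mm = _count_mismatches(seq, ref[start:start + n], max_mismatch)
        if mm <= max_mismatch:
            out.append((mm, tid, start))
    return out


def map_reads(reads: Iterable[tuple[str, str]] | str | Path,
              references: Sequence[TRNARecord] | ReferenceIndex,
              max_mismatch: int = 2,
              unique_only: bool = True,
              ) -> list[AlignmentRecord]:
    """Place each read at its best-scoring ungapped location.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs or a FASTQ
    path.  Reads whose best score is tied across distinct tRNAs are dropped
    under ``unique_only`` (otherwise kept, flagged non-unique); ties within
    one tRNA resolve to the smallest offset.
    """
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    if isinstance(reads, (str, Path)):
        reads = _iter_fastq(reads)
    alignments: list[AlignmentRecord] = []
    for read_id, seq in reads:
        seq = seq.upper().replace("T", "U")
        if not seq:
            continue
        placements = _placements(index, seq, max_mismatch)
        if not placements:
            continue
        best = min(mm for mm, _, _ in placements)
        top = sorted(p for p in placements if p[0] == best)
        tids = {tid for _, tid, _ in top}
        unique = len(tids) == 1
        if unique_only and not unique:
            continue
        mm, tid, start = top[0]
        alignments.append(AlignmentRecord(read_id, tid, start, start + len(seq), mm, unique))
    return alignments


def _iter_fastq(path: str | Path):
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].split()[0], seq


def import_alignments(path: str | Path, references: Sequence[TRNARecord],
                      unique_only: bool = True) -> list[AlignmentRecord]:
    """Import mapped, primary, non-supplementary records from a SAM file.

    A primary record counts as unique unless an equal-scoring (same edit
    distance) secondary alignment on a different reference exists for the
    same read.
    """
    import pysam

    known = {r.id for r in references}
    primaries: dict[str, tuple[str, int, int, int]] = {}
    secondary_scores: dict[str, list[tuple[str, int]]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in known:
                raise TRNAError(f"SAM reference {ref!r} absent from loaded tRNAs")
        for rec in sam:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if rec.is_secondary:
                secondary_scores.setdefault(rec.query_name, []).append(
                    (rec.reference_name, int(nm)))
                continue
            primaries[rec.query_name] = (
                rec.reference_name, rec.reference_start, rec.reference_end, int(nm))
    out = []
    for read_id, (tid, start, end, nm) in primaries.items():
        ties = [t for t, s in secondary_scores.get(read_id, []) if s <= nm and t != tid]
        unique = not ties
        if unique_only and not unique:
            continue
        out.append(AlignmentRecord(read_id, tid, start, end, nm, unique))
    out.sort(key=lambda a: a.read_id)
    return out


# ---------------------------------------------------------------------------
# classification and abundance
# ---------------------------------------------------------------------------

def classify_reads(alignments: Sequence[AlignmentRecord],
                   records: Sequence[TRNARecord] | dict[str, TRNARecord],
                   min_full: int = 65,
                   max_frag: int = 45,
                   window: tuple[int, int] = (27, 43),
                   ) -> list[tuple[AlignmentRecord, str]]:
    """Assign each alignment to full_length / anticodon_fragment / other.

    Full-length proxies span >= ``min_full`` nt.  Anticodon fragments span
    < ``max_frag`` nt *and* start (5'-most aligned residue) at a canonical
    label inside the anticodon stem-loop window.
    """
    by_id = records if isinstance(records, dict) else {r.id: r for r in records}
    lo, hi = window
    out = []
    for aln in alignments:
        rec = by_id[aln.trna_id]
        span = aln.end - aln.start
        if span >= min_full:
            cls = "full_length"
        elif span < max_frag:
            label = rec.label_of(aln.start)
            in_window = label.isdigit() and lo <= int(label) <= hi
            cls = "anticodon_fragment" if in_window else "other"
        else:
            cls = "other"
        out.append((aln, cls))
    return out


def abundance(classified: Sequence[tuple[AlignmentRecord, str]],
              read_class: str,
              reference_ids: Sequence[str],
              sample: str = "",
              ) -> pd.DataFrame:
    """Per-tRNA raw counts and CPM for one read class.

    CPM is normalized to the total of the requested class, so it sums to 1e6
    whenever any read is counted.
    """
    if read_class not in READ_CLASSES:
        raise TRNAError(f"unknown read class {read_class!r}")
    counts = {tid: 0 for tid in reference_ids}
    for aln, cls in classified:
        if cls == read_class:
            counts[aln.trna_id] += 1
    df = pd.DataFrame({"count": pd.Series(counts, dtype=int)})
    df.index.name = "trna_id"
    total = int(df["count"].sum())
    if total == 0:
        warnings.warn(f"no reads in class {read_class!r}; CPM set to 0")
        df["cpm"] = 0.0
    else:
        df["cpm"] = df["count"] * 1e6 / total
    df = df.sort_index()
    df.attrs.update({"read_class": read_class, "sample": sample, "total": total})
    return df


# ---------------------------------------------------------------------------
# depletion
# ---------------------------------------------------------------------------

@dataclass
class DepletionResult:
    """OLS fit of log10 treated CPM on log10 control CPM plus outlier flags."""

    slope: float
    intercept: float
    residuals: pd.Series
    depleted: list[str]
    threshold: float
    pseudo: float
    k_mad: float
    table: pd.DataFrame = field(repr=False, default=None)


def depletion_analysis(control: pd.DataFrame, treated: pd.DataFrame,
                       pseudo: float = 0.5, k_mad: float = 3.0,
                       ) -> DepletionResult:
    """Flag tRNAs depleted in the treated sample relative to control.

    Fits ``log10(treated_cpm + pseudo) ~ log10(control_cpm + pseudo)`` by
    ordinary least squares and flags tRNAs whose residual falls below
    ``-k_mad`` times the robust residual scale (normal-consistent MAD).
    """
    if set(control.index) != set(treated.index):
        raise TRNAError("control and treated tables cover different tRNA sets")
    if int((control["count"] > 0).sum()) < 3:
        raise TRNAError("fewer than 3 tRNAs with nonzero control counts")
    ids = control.index.sort_values()
    x = np.log10(control.loc[ids, "cpm"].to_numpy() + pseudo)
    y = np.log10(treated.loc[ids, "cpm"].to_numpy() + pseudo)
    slope, intercept = np.polyfit(x, y, 1)
    residuals = pd.Series(y - (slope * x + intercept), index=ids, name="residual")
    mad = stats.median_abs_deviation(residuals.to_numpy(), scale="normal")
    threshold = -k_mad * mad
    depleted = sorted(residuals.index[residuals < threshold])
    table = pd.DataFrame({
        "control_cpm": control.loc[ids, "cpm"],
        "treated_cpm": treated.loc[ids, "cpm"],
        "log10_control": x,
        "log10_treated": y,
        "residual": residuals,
        "depleted": residuals < threshold,
    })
    return DepletionResult(float(slope), float(intercept), residuals, depleted,
                           float(threshold), pseudo, k_mad, table)


def plot_depletion(result: DepletionResult, path: str | Path,
                   highlight: Sequence[str] = ()) -> None:
    """Log-log scatter of treated vs control CPM with the fitted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(t["log10_control"], t["log10_treated"], s=14, c="tab:blue",
               label="tRNAs")
    marked = [tid for tid in highlight if tid in t.index] or result.depleted
    if marked:
        sub = t.loc[marked]
        ax.scatter(sub["log10_control"], sub["log10_treated"], s=26, c="tab:red",
                   label="flagged")
    xs = np.linspace(t["log10_control"].min(), t["log10_control"].max(), 10)
    ax.plot(xs, result.slope * xs + result.intercept, "--", c="grey",
            label=f"fit slope={result.slope:.2f}")
    ax.set_xlabel("log10 control CPM")
    ax.set_ylabel("log10 treated CPM")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
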