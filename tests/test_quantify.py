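"""Mapper semantics, SAM import, read classes, CPM and depletion."""

import numpy as np
import pandas as pd
import pytest

from aribseq import quantify as qt
from aribseq.reference import TRNAError, TRNARecord, assign_canonical_numbering
from aribseq.synthetic_data import NickSite, PoolSpec, make_filler_references, simulate_pool
from helpers import brute_force_map


def rec(rid, seq):
    return TRNARecord(rid, seq, assign_canonical_numbering(len(seq)))


class TestMapper:
    def test_unique_30mer_maps_uniquely(self, lys, host_records):
        read = lys.sequence[20:50]
        (aln,) = qt.map_reads([("r1", read)], host_records)
        assert (aln.trna_id, aln.start, aln.end, aln.n_mismatches, aln.unique) \
            == ("Eco-Lys-UUU", 20, 50, 0, True)

    def test_identical_isodecoders_tie_dropped(self, lys):
        twins = [rec("iso-a", lys.sequence), rec("iso-b", lys.sequence)]
        read = [("r1", lys.sequence[10:40])]
        assert qt.map_reads(read, twins, unique_only=True) == []
        (kept,) = qt.map_reads(read, twins, unique_only=False)
        assert not kept.unique

    def test_mismatch_budget_boundary(self, lys, host_records):
        read = list(lys.sequence[20:50])
        for i in (2, 10, 25):
            read[i] = {"A": "C"}.get(read[i], "A")
        over = "".join(read)
        assert qt.map_reads([("r", over)], host_records, max_mismatch=2) == []
        read2 = list(lys.sequence[20:50])
        for i in (2, 10):
            read2[i] = {"A": "C"}.get(read2[i], "A")
        (aln,) = qt.map_reads([("r", "".join(read2))], host_records, max_mismatch=2)
        assert aln.n_mismatches == 2 and aln.trna_id == "Eco-Lys-UUU"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(TRNAError, match="empty reference"):
            qt.ReferenceIndex([])

    def test_agrees_with_brute_force_scan(self, lys):
        # <=5 references x 200 reads, incl. a duplicated reference to
        # exercise the drop-on-tie uniqueness rule
        refs = [rec("dup-a", lys.sequence), rec("dup-b", lys.sequence)] \
            + make_filler_references(3, seed=21)
        rng = np.random.default_rng(99)
        reads = []
        for i in range(200):
            src = refs[rng.integers(len(refs))].sequence
            a = int(rng.integers(0, 50))
            b = int(rng.integers(a + 8, min(a + 60, 76) + 1))
            chars = list(src[a:b])
            for _ in range(rng.integers(0, 4)):   # 0-3 substitutions
                j = int(rng.integers(len(chars)))
                chars[j] = "ACGU"[rng.integers(4)]
            reads.append((f"r{i}", "".join(chars)))
        mapped = {a.read_id: a for a in qt.map_reads(reads, refs, max_mismatch=2)}
        for read_id, seq in reads:
            oracle = brute_force_map(seq, refs, max_mismatch=2)
            if oracle is None:
                assert read_id not in mapped
                continue
            best, placements = oracle
            unique = len({tid for tid, _ in placements}) == 1
            if not unique:
                assert read_id not in mapped
                continue
            aln = mapped[read_id]
            assert aln.n_mismatches == best
            assert (aln.trna_id, aln.start) == placements[0]


class TestSamImport:
    def make_sam(self, path, records, rows):
        import pysam
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": r.id, "LN": len(r)} for r in records]}
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for name, tid, pos, seq, flag, nm in rows:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.flag = flag
                if not a.is_unmapped:
                    a.reference_id = out.header.references.index(tid)
                    a.reference_start = pos
                    a.cigarstring = f"{len(seq)}M"
                    a.set_tag("NM", nm)
                a.query_sequence = seq
                out.write(a)
        return path

    def test_primary_mapped_line_imported(self, tmp_path, lys, host_records):
        sam = self.make_sam(tmp_path / "a.sam", host_records,
                            [("r1", "Eco-Lys-UUU", 20, lys.sequence[20:50], 0, 0)])
        (aln,) = qt.import_alignments(sam, host_records)
        assert (aln.trna_id, aln.start, aln.end) == ("Eco-Lys-UUU", 20, 50)

    def test_unmapped_line_skipped(self, tmp_path, host_records):
        sam = self.make_sam(tmp_path / "u.sam", host_records,
                            [("r1", None, 0, "ACGUACGUAC", 4, 0)])
        assert qt.import_alignments(sam, host_records) == []

    def test_equal_scoring_secondary_breaks_uniqueness(self, tmp_path, lys, host_records):
        rows = [("r1", "Eco-Lys-UUU", 20, lys.sequence[20:50], 0, 1),
                ("r1", "Eco-Asn-GUU", 20, lys.sequence[20:50], 256, 1)]
        sam = self.make_sam(tmp_path / "s.sam", host_records, rows)
        assert qt.import_alignments(sam, host_records, unique_only=True) == []
        (kept,) = qt.import_alignments(sam, host_records, unique_only=False)
        assert not kept.unique

    def test_foreign_reference_rejected(self, tmp_path, lys, host_records):
        stranger = rec("rRNA-16S", lys.sequence)
        sam = self.make_sam(tmp_path / "f.sam", host_records + [stranger],
                            [("r1", "rRNA-16S", 0, lys.sequence[:30], 0, 0)])
        with pytest.raises(TRNAError, match="absent from loaded"):
            qt.import_alignments(sam, host_records)


class TestClassify:
    @pytest.mark.parametrize("start, end, expected", [
        (0, 70, "full_length"),          # >= 65 nt span
        (40, 76, "anticodon_fragment"),  # 36 nt starting at label 41
        (10, 60, "other"),               # between thresholds
        (0, 44, "other"),                # short but 5' end outside the window
        (0, 65, "full_length"),          # boundary: exactly min_full
        (31, 76, "other"),               # 45 nt span: not < max_frag
    ])
    def test_span_and_window_rules(self, lys, start, end, expected):
        aln = qt.AlignmentRecord("r", lys.id, start, end, 0)
        ((_, cls),) = qt.classify_reads([aln], [lys])
        assert cls == expected


class TestAbundance:
    def make_classified(self, counts):
        out = []
        for tid, n in counts.items():
            out += [(qt.AlignmentRecord(f"{tid}.{i}", tid, 0, 70, 0), "full_length")
                    for i in range(n)]
        return out

    def test_cpm_arithmetic(self):
        classified = self.make_classified({"a": 3, "b": 1})
        table = qt.abundance(classified, "full_length", ["a", "b"])
        assert table.loc["a", "cpm"] == 750000.0
        assert table.loc["b", "cpm"] == 250000.0
        assert table["cpm"].sum() == 1e6

    def test_empty_input_zero_table_with_warning(self):
        with pytest.warns(UserWarning, match="no reads"):
            table = qt.abundance([], "full_length", ["a", "b"])
        assert (table["cpm"] == 0).all()

    def test_invariant_to_read_order(self):
        classified = self.make_classified({"a": 5, "b": 2, "c": 9})
        fwd = qt.abundance(classified, "full_length", list("abc"))
        rev = qt.abundance(classified[::-1], "full_length", list("abc"))
        pd.testing.assert_frame_equal(fwd, rev)


class TestDepletion:
    def table(self, counts):
        ids = [f"t{i:02d}" for i in range(len(counts))]
        df = pd.DataFrame({"count": counts}, index=pd.Index(ids, name="trna_id"))
        df["cpm"] = df["count"] * 1e6 / df["count"].sum()
        return df

    def test_identity_gives_unit_fit_and_no_flags(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(100, 5000, size=30)
        ctl = self.table(counts)
        res = qt.depletion_analysis(ctl, ctl.copy())
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.residuals, 0) and res.depleted == []

    def test_three_tenfold_reductions_flagged_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.integers(500, 5000, size=40)
        treated = base.copy()
        treated[[3, 17, 31]] //= 10
        # Poisson sampling noise on both sides
        ctl = self.table(rng.poisson(base))
        trt = self.table(rng.poisson(treated))
        res = qt.depletion_analysis(ctl, trt)
        assert res.depleted == ["t03", "t17", "t31"]

    def test_flags_invariant_under_relabelling(self):
        rng = np.random.default_rng(2)
        base = rng.integers(500, 5000, size=20)
        treated = base.copy()
        treated[5] //= 12
        ctl, trt = self.table(base), self.table(treated)
        res = qt.depletion_analysis(ctl, trt)
        perm = rng.permutation(20)
        remap = {f"t{i:02d}": f"x{j:02d}" for j, i in enumerate(perm)}
        res2 = qt.depletion_analysis(ctl.rename(index=remap), trt.rename(index=remap))
        assert {remap[t] for t in res.depleted} == set(res2.depleted)
        assert res.depleted == ["t05"]

    def test_too_few_nonzero_controls_rejected(self):
        ctl = self.table([5, 0, 0, 0])
        with pytest.raises(TRNAError, match="fewer than 3"):
            qt.depletion_analysis(ctl, ctl.copy())


class TestEndToEndRecovery:
    def test_simulated_target_depletion_is_recovered(self, host_records, mods):
        # the three main nuclease targets at nick probabilities 0.9/0.7/0.3
        refs = host_records + make_filler_references(36, seed=123)
        rng = np.random.default_rng(5)
        ab = {r.id: float(w) for r, w in zip(refs, rng.lognormal(0, 0.75, len(refs)))}
        nicks = [NickSite("Eco-Lys-UUU", ("40", "41"), 0.9),
                 NickSite("Eco-Thr-UGU", ("40", "41"), 0.7),
                 NickSite("Eco-Asn-GUU", ("40", "41"), 0.3)]
        common = dict(abundances=ab, protocol="B", read_length=80, n_reads=50000)
        ctl, _ = simulate_pool(PoolSpec(seed=11, nick_sites=[], **common), refs, mods)
        trt, _ = simulate_pool(PoolSpec(seed=12, nick_sites=nicks, **common), refs, mods)
        index = qt.ReferenceIndex(refs)
        ids = [r.id for r in refs]
        tables = {}
        for name, reads in (("ctl", ctl), ("trt", trt)):
            alns = qt.map_reads([(r.read_id, r.sequence) for r in reads], index)
            classified = qt.classify_reads(alns, refs)
            tables[name] = qt.abundance(classified, "full_length", ids)
        res = qt.depletion_analysis(tables["ctl"], tables["trt"])
        assert {"Eco-Lys-UUU", "Eco-Thr-UGU"} <= set(res.depleted)
        assert res.residuals["Eco-Asn-GUU"] < 0
        assert not set(res.depleted) - {"Eco-Lys-UUU", "Eco-Thr-UGU", "Eco-Asn-GUU"}
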