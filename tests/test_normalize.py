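import subprocess

import numpy as np
import pytest

from _oracles import apply_edit, best_alignment, leftmost_representation
from varbench.errors import ReferenceMismatchError
from varbench.formats import HALF, HET, HOM, Callset, VariantRecord, write_vcf
from varbench.normalize import (apply_edits, atomize, atoms_as_edits,
                                deduplicate, normalize_callset,
                                split_multiallelic, trim_and_left_align)


def rec(pos, ref, alt, contig="c", gt=(0, 1), zyg=None, src="r"):
    alts = (alt,) if isinstance(alt, str) else tuple(alt)
    return VariantRecord(contig=contig, pos=pos, ref=ref, alts=alts,
                         genotype=gt, zygosity=zyg, source_id=src)


class TestSplitMultiallelic:
    def test_single_alt_identity(self):
        r = rec(5, "A", "G")
        assert split_multiallelic(r) == [r]

    def test_two_alts_both_called(self):
        out = split_multiallelic(rec(5, "A", ["G", "T"], gt=(1, 2)))
        assert [(o.alts, o.zygosity) for o in out] == \
               [(("G",), HALF), (("T",), HALF)]

    def test_uncalled_alt_dropped(self):
        out = split_multiallelic(rec(5, "A", ["G", "T"], gt=(0, 1)))
        assert [(o.alts, o.zygosity) for o in out] == [(("G",), HET)]

    def test_no_genotype_emits_all_alts(self):
        out = split_multiallelic(rec(5, "A", ["G", "T"], gt=None))
        assert [o.alts for o in out] == [("G",), ("T",)]
        assert all(o.zygosity is None for o in out)


class TestTrimAndLeftAlign:
    # reference from the worked deletion examples: CACACA repeat
    REF = {"c": "GCACACAT"}

    def test_snv_unchanged(self):
        r = rec(3, "A", "G")
        out = trim_and_left_align(r, self.REF)
        assert (out.pos, out.ref, out.alts) == (3, "A", ("G",))

    def test_single_base_deletion_blocked_by_context(self):
        # deleting the A at pos 7 cannot shift: the preceding base is C
        out = trim_and_left_align(rec(6, "CA", "C"), self.REF)
        assert (out.pos, out.ref, out.alts) == (6, "CA", ("C",))
        p, r, a = leftmost_representation(self.REF["c"], 6, "CA", "C")
        assert (out.pos, out.ref, out.alts[0]) == (p, r, a)

    def test_two_base_deletion_shifts_home(self):
        # ACACAT>ACAT at pos 3 deletes CA from the repeat; leftmost is pos 1
        out = trim_and_left_align(rec(3, "ACACAT", "ACAT"), self.REF)
        p, r, a = leftmost_representation(self.REF["c"], 3, "ACACAT", "ACAT")
        assert (out.pos, out.ref, out.alts[0]) == (p, r, a) == (1, "GCA", "G")

    def test_idempotent(self):
        once = trim_and_left_align(rec(3, "ACACAT", "ACAT"), self.REF)
        twice = trim_and_left_align(once, self.REF)
        assert once == twice

    def test_reference_mismatch_names_locus(self):
        with pytest.raises(ReferenceMismatchError, match="c:3"):
            trim_and_left_align(rec(3, "T", "G"), self.REF)

    def test_matches_enumeration_oracle_on_random_indels(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            pos = int(rng.integers(6, 30))
            if rng.random() < 0.5:  # deletion
                d = int(rng.integers(1, 4))
                ref, alt = seq[pos - 1:pos + d], seq[pos - 1]
            else:  # insertion
                ref = seq[pos - 1]
                alt = ref + "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(1, 4))))
            out = trim_and_left_align(rec(pos, ref, alt), {"c": seq})
            p, r, a = leftmost_representation(seq, pos, ref, alt)
            assert (out.pos, out.ref, out.alts[0]) == (p, r, a), (seq, pos, ref, alt)


class TestAtomize:
    REF = {"c": "GACCGCGTA"}

    def test_snv_single_atom(self):
        (a,) = atomize(rec(2, "A", "G"), self.REF)
        assert (a.pos, a.ref, a.alt) == (2, "A", "G")

    def test_mnv_becomes_two_snvs(self):
        atoms = atomize(rec(2, "AC", "GT"), self.REF)
        assert [(a.pos, a.ref, a.alt) for a in atoms] == \
               [(2, "A", "G"), (3, "C", "T")]

    def test_complex_replacement_worked_example(self):
        # ACCGCGT>ACGCT: two single-base deletions, each left-aligned
        atoms = atomize(rec(2, "ACCGCGT", "ACGCT"), self.REF)
        assert [(a.pos, a.ref, a.alt) for a in atoms] == \
               [(2, "AC", "A"), (6, "CG", "C")]

    def test_reconstruction_property_random(self):
        rng = np.random.default_rng(7)
        for _ in range(250):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            pos = int(rng.integers(6, 30))
            k = int(rng.integers(2, 7))
            ref = seq[pos - 1:pos - 1 + k]
            alt = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(2, 7))))
            if alt == ref or alt[-1] == ref[-1] or alt[0] == ref[0]:
                continue
            atoms = atomize(rec(pos, ref, alt), {"c": seq})
            assert apply_edits(seq, atoms_as_edits(atoms)) == \
                apply_edit(seq, pos, ref, alt), (seq, pos, ref, alt)
            for a in atoms:
                assert a.is_snv or a.is_indel

    def test_gap_count_matches_alignment_oracle(self):
        # the decomposition uses a maximum-score alignment: SNV and indel
        # atom counts must match an exhaustive alignment search
        rng = np.random.default_rng(19)
        checked = 0
        while checked < 60:
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            pos = int(rng.integers(4, 15))
            ref = seq[pos - 1:pos - 1 + int(rng.integers(2, 6))]
            alt = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(2, 6))))
            if alt == ref or alt[0] == ref[0] or alt[-1] == ref[-1]:
                continue
            checked += 1
            atoms = atomize(rec(pos, ref, alt), {"c": seq})
            cols = best_alignment(ref, alt)
            n_snv = sum(1 for i, j in cols
                        if i is not None and j is not None and ref[i] != alt[j])
            gap_runs = 0
            in_gap = False
            for i, j in cols:
                gap = i is None or j is None
                if gap and not in_gap:
                    gap_runs += 1
                in_gap = gap
            assert sum(a.is_snv for a in atoms) == n_snv
            assert sum(a.is_indel for a in atoms) == gap_runs


class TestDeduplicate:
    def atom(self, zyg=HET, pos=5):
        from conftest import make_atom
        return make_atom(pos, "A", "G", zyg)

    def test_exact_duplicates_collapse(self):
        a = self.atom()
        assert deduplicate([a, a]) == [a]

    def test_genotype_distinguishes(self):
        assert len(deduplicate([self.atom(HET), self.atom(HOM)])) == 2

    def test_empty(self):
        assert deduplicate([]) == []


class TestNormalizeCallset:
    REF = {"c": "GCACACATGACCGCGTATTGCA"}

    def test_idempotent(self):
        cs = Callset(id="x", records=[rec(2, "C", "T"), rec(9, "GA", "G", gt=(1, 1))])
        once = normalize_callset(cs, self.REF)
        again = normalize_callset(Callset(id="x", records=once.records[:]), self.REF)
        assert [(a.pos, a.ref, a.alt, a.zygosity) for a in once.records] == \
               [(a.pos, a.ref, a.alt, a.zygosity) for a in again.records]

    def test_duplicate_records_shrink(self):
        cs = Callset(id="x", records=[rec(2, "C", "T"), rec(2, "C", "T")])
        assert len(normalize_callset(cs, self.REF).records) == 1

    def test_representation_invariance(self):
        # same two SNV edits encoded atomically vs as one complex replacement
        plain = Callset(id="a", records=[rec(10, "A", "T"), rec(12, "C", "G")])
        seq = self.REF["c"]
        complex_ref = seq[9:12]
        complex_alt = "T" + seq[10] + "G"
        merged = Callset(id="a", records=[rec(10, complex_ref, complex_alt)])
        key = lambda c: [(a.pos, a.ref, a.alt, a.zygosity) for a in c.records]
        assert key(normalize_callset(plain, self.REF)) == \
            key(normalize_callset(merged, self.REF))

    def test_non_pass_records_skipped_by_default(self):
        records = [rec(2, "C", "T").with_(passing=False, filter_text="q10")]
        cs = Callset(id="x", records=records)
        assert normalize_callset(cs, self.REF).records == []
        assert len(normalize_callset(cs, self.REF, passing_only=False).records) == 1


@pytest.mark.parametrize("pos,ref,alt", [
    (6, "CA", "C"),        # deletion in a CA repeat
    (4, "C", "CAC"),       # insertion in the repeat
    (10, "ACC", "A"),      # 2 bp deletion
])
def test_left_alignment_agrees_with_bcftools(tmp_path, pos, ref, alt):
    """bcftools norm is an independent oracle for left-alignment."""
    reference = {"c": "GCACACATGACCGCGTATTGCA"}
    fa = tmp_path / "ref.fa"
    fa.write_text(">c\n" + reference["c"] + "\n")
    vcf = tmp_path / "in.vcf"
    write_vcf([rec(pos, ref, alt)], vcf, {"c": len(reference["c"])})
    out = subprocess.run(
        ["bcftools", "norm", "-f", str(fa), str(vcf)],
        capture_output=True, text=True, check=True).stdout
    line = [l for l in out.splitlines() if not l.startswith("#")][0].split("\t")
    ours = trim_and_left_align(rec(pos, ref, alt), reference)
    assert (str(ours.pos), ours.ref, ours.alts[0]) == (line[1], line[3], line[4])
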