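"""ORF enumeration, NMD/Kozak annotation, conservation metrics, verdict."""

import itertools

import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id
from hypothesis import given, settings, strategies as st

from bidiscreen.coding_potential import (
    Alignment,
    MatureTranscript,
    OrfCall,
    coding_verdict,
    find_orfs,
    frameshift_indel_rate,
    kozak_class,
    nmd_uorf_flags,
    ns_s_counts,
    regional_identity,
)

_CODE = dict(unambiguous_dna_by_id[1].forward_table)
for stop in ("TAA", "TAG", "TGA"):
    _CODE[stop] = "*"
_STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq: str, min_aa: int):
    """Independent ORF enumeration: walk from each ATG to its first in-frame
    stop, then keep the 5'-most ATG per (frame, stop)."""
    seq = seq.upper().replace("U", "T")
    by_stop = {}
    for a in (i for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG"):
        for i in range(a, len(seq) - 2, 3):
            if seq[i : i + 3] in _STOPS:
                key = (a % 3, i)
                if key not in by_stop or a < by_stop[key]:
                    by_stop[key] = a
                break
    calls = []
    for (frame, stop), start in by_stop.items():
        aa = (stop - start) // 3
        if aa >= min_aa:
            calls.append((frame, start, stop + 3, aa))
    return sorted(calls, key=lambda c: (c[1], c[0]))


class TestFindOrfs:
    def test_constructed_single_orf(self):
        body = "GGC" * 35  # 35 glycine codons after the initiator Met
        seq = "N" * 10 + "ATG" + body + "TAA" + "N" * 10
        calls = find_orfs(MatureTranscript(id="t", sequence=seq), min_aa=30)
        assert len(calls) == 1
        assert calls[0].aa_length == 36

    def test_no_atg_means_no_orf(self):
        assert find_orfs(MatureTranscript(id="t", sequence="CCCGGGTTT" * 30)) == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            MatureTranscript(id="t", sequence="ACGTX")

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=600))
            t = MatureTranscript(id="t", sequence=seq)
            got = [(c.frame, c.start, c.end, c.aa_length) for c in find_orfs(t, 5)]
            assert got == orf_oracle(seq, 5)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=400), st.integers(1, 20))
    def test_bruteforce_equivalence_property(self, seq, min_aa):
        t = MatureTranscript(id="t", sequence=seq)
        got = [(c.frame, c.start, c.end, c.aa_length) for c in find_orfs(t, min_aa)]
        assert got == orf_oracle(seq, min_aa)


class TestNmdUorfFlags:
    def _orf(self, start, aa):
        return OrfCall(frame=start % 3, start=start, end=start + 3 * (aa + 1), aa_length=aa)

    def test_single_exon_transcript_never_nmd(self):
        t = MatureTranscript(id="t", sequence="A" * 400)
        flagged = nmd_uorf_flags([self._orf(30, 10)], t)
        assert not flagged[0].ends_before_last_junction

    def test_stop_before_last_junction_flagged(self):
        t = MatureTranscript(id="t", sequence="A" * 400, junctions=(100, 350))
        flagged = nmd_uorf_flags([self._orf(30, 10)], t)  # stop at 60 < 350
        assert flagged[0].ends_before_last_junction

    def test_50nt_rule_is_stricter(self):
        t = MatureTranscript(id="t", sequence="A" * 400, junctions=(100,))
        orf = self._orf(30, 18)  # stop codon at position 84: within 50 nt of 100
        assert nmd_uorf_flags([orf], t)[0].ends_before_last_junction
        assert not nmd_uorf_flags([orf], t, ptc_rule_50nt=True)[0].ends_before_last_junction

    def test_uorf_ordering(self):
        t = MatureTranscript(id="t", sequence="A" * 800)
        o1, o2 = self._orf(30, 10), self._orf(300, 10)
        f1, f2 = nmd_uorf_flags([o1, o2], t)
        assert not f1.has_uorf and f2.has_uorf


class TestKozak:
    @pytest.mark.parametrize(
        "context,expected",
        [
            ("GCCACCATGG", "strong"),  # canonical
            ("TTTTTTATGC", "weak"),
            ("TTTCTTATGG", "adequate"),  # only +4 matches
            ("GCCACCATGC", "adequate"),  # only -3 matches
        ],
    )
    def test_context_classes(self, context, expected):
        seq = context + "GGG" * 30 + "TAA"
        start = context.index("ATG")
        orf = OrfCall(frame=start % 3, start=start, end=start + 3 * 31, aa_length=30)
        t = MatureTranscript(id="t", sequence=seq)
        assert kozak_class(t, orf) == expected

    def test_start_at_position_zero_at_best_adequate(self):
        seq = "ATGG" + "GGC" * 30 + "TAA"
        orf = OrfCall(frame=0, start=0, end=3 * 32, aa_length=31)
        t = MatureTranscript(id="t", sequence=seq)
        assert kozak_class(t, orf) in ("adequate", "weak")


class TestFrameshiftIndelRate:
    def test_inframe_deletion_not_counted(self):
        aln = Alignment(
            ids=("ref", "sp1"),
            rows=("ACGTACGTACGT", "ACG---GTACGT"),
        )
        assert frameshift_indel_rate(aln, (0, 12)) == 0.0

    def test_single_frameshift_gap_arithmetic(self):
        ref = "A" * 100
        r1 = "A" * 50 + "-" + "A" * 49
        r2 = "A" * 100
        aln = Alignment(ids=("ref", "s1", "s2"), rows=(ref, r1, r2))
        assert frameshift_indel_rate(aln, (0, 100)) == pytest.approx(1 / 200)

    def test_rate_invariant_under_identical_gapfree_rows(self):
        ref = "ACGT" * 25
        row = "ACGT" * 12 + "--" + "GT" + "ACGT" * 12
        aln2 = Alignment(ids=("r", "a"), rows=(ref, row))
        aln3 = Alignment(ids=("r", "a", "b"), rows=(ref, row, ref))
        # one event over 1x100 vs one event over 2x100
        assert frameshift_indel_rate(aln2, (0, 100)) == pytest.approx(
            2 * frameshift_indel_rate(aln3, (0, 100))
        )

    def test_region_outside_alignment_rejected(self):
        aln = Alignment(ids=("r", "a"), rows=("ACGT", "ACGT"))
        with pytest.raises(ValueError):
            frameshift_indel_rate(aln, (0, 10))


def ns_s_oracle(ref_codon: str, alt_codon: str):
    """Independent per-codon syn/non-syn step counting over all orderings."""
    diff = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
    orders = list(itertools.permutations(diff))
    s = ns = 0.0
    for order in orders:
        cur = ref_codon
        for pos in order:
            nxt = cur[:pos] + alt_codon[pos] + cur[pos + 1 :]
            if _CODE[cur] == _CODE[nxt]:
                s += 1
            else:
                ns += 1
            cur = nxt
    return s / len(orders), ns / len(orders)


class TestNsSCounts:
    def _aln(self, ref, alt):
        return Alignment(ids=("r", "a"), rows=(ref, alt))

    def test_fourfold_site_synonymous(self):
        ns, s, ratio = ns_s_counts(self._aln("GCT", "GCC"), (0, 3))
        assert (ns, s) == (0.0, 1.0)

    def test_met_to_ile_nonsynonymous(self):
        ns, s, ratio = ns_s_counts(self._aln("ATG", "ATA"), (0, 3))
        assert (ns, s) == (1.0, 0.0)
        assert ratio is None

    def test_gapped_codons_skipped(self):
        ns, s, _ = ns_s_counts(self._aln("GCTAAA", "GC-AAG"), (0, 6))
        assert (ns, s) == (0.0, 1.0)  # only the AAA->AAG codon counts

    def test_region_not_codon_multiple_rejected(self):
        with pytest.raises(ValueError):
            ns_s_counts(self._aln("GCTA", "GCTA"), (0, 4))

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
        for _ in range(300):
            ref = codons[rng.integers(64)]
            alt = codons[rng.integers(64)]
            ns, s, _ = ns_s_counts(self._aln(ref, alt), (0, 3))
            s_exp, ns_exp = ns_s_oracle(ref, alt)
            assert (ns, s) == pytest.approx((ns_exp, s_exp))

    def test_fourfold_third_position_mutations_all_synonymous(self):
        # codons whose third position is fully degenerate
        fourfold = ["GCT", "GGT", "CCT", "ACT", "GTT", "CGT", "TCT", "CTT"]
        for base in fourfold:
            for alt3 in "ACGT":
                alt = base[:2] + alt3
                ns, s, _ = ns_s_counts(self._aln(base, alt), (0, 3))
                assert ns == 0.0


class TestRegionalIdentity:
    def test_identical_rows_everywhere_100(self):
        aln = Alignment(ids=("r", "a", "b"), rows=("ACGT" * 30,) * 3)
        out = regional_identity(aln, {"orf": (0, 60), "flank": (60, 120)})
        assert out == {"orf": 100.0, "flank": 100.0}

    def test_one_mismatch_in_fifty_columns(self):
        ref = "A" * 50
        alt = "A" * 25 + "C" + "A" * 24
        aln = Alignment(ids=("r", "a"), rows=(ref, alt))
        assert regional_identity(aln, {"x": (0, 50)})["x"] == pytest.approx(98.0)

    def test_empty_region_rejected(self):
        aln = Alignment(ids=("r", "a"), rows=("ACGT", "ACGT"))
        with pytest.raises(ValueError):
            regional_identity(aln, {"x": (2, 2)})


class TestCodingVerdict:
    def test_long_conserved_strong_kozak_orf_is_coding_leaning(self):
        orf = OrfCall(
            frame=0, start=0, end=3 * 501, aa_length=500, kozak_class="strong"
        )
        out = coding_verdict([orf])
        assert out["verdict"] == "coding_leaning"
        assert not any(v for v in out["reasons"].values() if v is True)

    def test_focal_profile_all_reasons_support_noncoding(self, focal):
        t = focal.transcript
        orfs = nmd_uorf_flags(find_orfs(t, min_aa=30), t)
        orfs = [
            OrfCall(**{**o.__dict__, "kozak_class": kozak_class(t, o)}) for o in orfs
        ]
        out = coding_verdict(orfs)
        assert out["verdict"] == "non_coding_leaning"
        assert out["reasons"]["no_orf_min_aa"]
        assert out["reasons"]["all_orfs_nmd_or_uorf_flagged"]
        assert out["reasons"]["no_strong_kozak"]

    def test_empty_orf_list_noncoding(self):
        out = coding_verdict([])
        assert out["verdict"] == "non_coding_leaning"
        assert out["reasons"]["no_orf_min_aa"]
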