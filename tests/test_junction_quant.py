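"""Junction reference construction, read matching, RPM and fold change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sctrace import junction_quant as jq

from conftest import ESC_LIBRARY, ICM_LIBRARY


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestBuildReference:
    def test_single_exon_variant_has_no_junctions(self):
        ref = jq.build_junction_reference([jq.GeneModel("g", "v", ("A" * 60,))])
        assert len(ref) == 0

    def test_three_exon_variant_has_two_junctions(self):
        rng = np.random.default_rng(0)
        exons = tuple(_random_seq(rng, 60) for _ in range(3))
        ref = jq.build_junction_reference([jq.GeneModel("g", "v", exons)])
        assert len(ref) == 2
        assert (ref.entries["sequence"].str.len() == 84).all()
        assert ref.entries["sequence"].iloc[0] == exons[0][-42:] + exons[1][:42]

    def test_cassette_exon_junctions_are_variant_specific(self):
        # 3-exon gene: inclusion variant e1-e2-e3 vs skipping variant e1-e3.
        # All three junction sequences must differ, so each is discriminating.
        rng = np.random.default_rng(1)
        exons = tuple(_random_seq(rng, 50) for _ in range(3))
        incl = jq.GeneModel("g", "v1", exons)
        skip = jq.GeneModel("g", "v2", (exons[0], exons[2]))
        ref = jq.build_junction_reference([incl, skip])
        seqs = ref.entries.set_index("junction_id")["sequence"]
        assert len(ref) == 3
        assert seqs.nunique() == 3
        assert not ref.entries["shared"].any()
        assert seqs["g|v2|J1"] == exons[0][-42:] + exons[2][:42]

    def test_shared_terminal_junction_flagged(self):
        # two variants agreeing on the first junction share its sequence
        rng = np.random.default_rng(2)
        e1, e2, e3a, e3b = (_random_seq(rng, 60) for _ in range(4))
        ref = jq.build_junction_reference(
            [jq.GeneModel("g", "v1", (e1, e2, e3a)), jq.GeneModel("g", "v2", (e1, e2, e3b))]
        )
        shared = ref.entries.set_index("junction_id")["shared"]
        assert shared["g|v1|J1"] and shared["g|v2|J1"]
        assert not shared["g|v1|J2"] and not shared["g|v2|J2"]

    def test_short_exon_junction_skipped_and_reported(self):
        rng = np.random.default_rng(3)
        exons = (_random_seq(rng, 30), _random_seq(rng, 60), _random_seq(rng, 60))
        ref = jq.build_junction_reference([jq.GeneModel("g", "v", exons)])
        assert len(ref) == 1  # only the e2-e3 junction survives
        assert len(ref.skipped) == 1
        assert ref.skipped.iloc[0]["donor_exon"] == 1

    def test_roundtrip_exon_tsv(self, tmp_path):
        path = tmp_path / "models.tsv"
        pd.DataFrame(
            {
                "gene": ["g", "g"],
                "variant": ["v", "v"],
                "exon_index": [2, 1],
                "sequence": ["C" * 50, "A" * 50],
            }
        ).to_csv(path, sep="\t", index=False)
        models = jq.load_gene_models(path)
        assert models[0].exons == ("A" * 50, "C" * 50)  # ordered by exon_index


def _brute_force_match(read, entries, max_mm, min_overhang=1, both_strands=True):
    """Independent all-offsets Hamming scan used as the matching oracle."""
    L = len(read)
    candidates = [read]
    if both_strands:
        candidates.append(jq.reverse_complement(read))
    best, winners = L + 1, []
    for j, seq in enumerate(entries):
        for r in candidates:
            for o in range(len(seq) - L + 1):
                if o > 42 - min_overhang or o + L < 42 + min_overhang:
                    continue
                d = sum(a != b for a, b in zip(r, seq[o : o + L]))
                if d < best:
                    best, winners = d, [j]
                elif d == best and j not in winners:
                    winners.append(j)
    if best > max_mm:
        return None
    if len(winners) > 1:
        return "ambiguous"
    return winners[0]


@pytest.fixture(scope="module")
def small_ref():
    rng = np.random.default_rng(7)
    models = [
        jq.GeneModel(f"g{i}", f"g{i}.v", tuple(_random_seq(rng, 60) for _ in range(3)))
        for i in range(4)
    ]
    return jq.build_junction_reference(models)


class TestMatchReads:
    def test_exact_substring_counted(self, small_ref):
        seq = small_ref.entries["sequence"].iloc[0][10:60]
        table = jq.match_reads([seq], small_ref)
        assert table.counts["sample"].sum() == 1
        assert table.counts["sample"].iloc[0] == 1

    def test_five_mismatches_unassigned(self, small_ref):
        seq = list(small_ref.entries["sequence"].iloc[0][10:60])
        for i in range(5):
            pos = 3 + 9 * i
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        table = jq.match_reads(["".join(seq)], small_ref)
        assert table.counts["sample"].sum() == 0
        assert table.stats.loc["sample", "unassigned"] == 1

    def test_four_mismatches_still_assigned(self, small_ref):
        seq = list(small_ref.entries["sequence"].iloc[2][5:55])
        for i in range(4):
            pos = 2 + 11 * i
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        table = jq.match_reads(["".join(seq)], small_ref)
        assert table.counts["sample"].iloc[2] == 1

    def test_equidistant_read_discarded_as_ambiguous(self):
        rng = np.random.default_rng(11)
        e1, e2a, e2b = (_random_seq(rng, 60) for _ in range(3))
        # two junctions sharing the donor flank; read from the shared part
        ref = jq.build_junction_reference(
            [jq.GeneModel("g", "v1", (e1, e2a)), jq.GeneModel("g", "v2", (e1, e2b))]
        )
        read = e1[-42:] + e2a[:8]  # full donor flank + 8 acceptor bases
        assert len(read) == 50
        # distance to v1 is 0; to v2 it depends on the 8 acceptor bases
        table = jq.match_reads([read], ref)
        if e2a[:8] == e2b[:8]:
            assert table.stats.loc["sample", "ambiguous"] == 1
        else:
            assert table.counts["sample"].loc["g|v1|J1"] == 1
        # force the tie: second acceptor agrees on the covered 8 bases
        ref2 = jq.build_junction_reference(
            [jq.GeneModel("g", "v1", (e1, e2a)), jq.GeneModel("g", "v2", (e1, e2a[:8] + e2b[8:]))]
        )
        t2 = jq.match_reads([read], ref2)
        assert t2.stats.loc["sample", "ambiguous"] == 1
        assert t2.counts["sample"].sum() == 0

    def test_non_spanning_exon_body_read_not_counted(self, small_ref):
        # a read lying entirely in the donor flank must not be assigned
        donor42 = small_ref.entries["sequence"].iloc[0][:42]
        read = donor42 + "A" * 8  # only touches the acceptor with 8 nt
        table = jq.match_reads([read[:50]], small_ref, jq.AlignmentParams(min_overhang=20))
        assert table.counts["sample"].sum() == 0

    def test_reverse_complement_read_counted(self, small_ref):
        seq = jq.reverse_complement(small_ref.entries["sequence"].iloc[1][17:67])
        table = jq.match_reads([seq], small_ref)
        assert table.counts["sample"].iloc[1] == 1
        strict = jq.match_reads([seq], small_ref, jq.AlignmentParams(both_strands=False))
        assert strict.counts["sample"].sum() == 0

    def test_wrong_length_read_skipped(self, small_ref):
        table = jq.match_reads(["ACGT"], small_ref)
        assert table.stats.loc["sample", "skipped"] == 1

    def test_conservation_of_reads(self, small_ref):
        rng = np.random.default_rng(13)
        reads = [
            small_ref.entries["sequence"].iloc[rng.integers(len(small_ref))][o : o + 50]
            for o in rng.integers(0, 35, size=40)
        ] + ["ACGT" * 13][:1]
        table = jq.match_reads([r[:50] for r in reads], small_ref)
        s = table.stats.loc["sample"]
        assert s["assigned"] + s["ambiguous"] + s["unassigned"] + s["skipped"] == s["total"]
        assert table.counts["sample"].sum() == s["assigned"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matcher_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_models = int(rng.integers(1, 6))
        models = [
            jq.GeneModel(
                f"g{i}", f"g{i}.v",
                tuple(_random_seq(rng, int(rng.integers(42, 80))) for _ in range(int(rng.integers(2, 4)))),
            )
            for i in range(n_models)
        ]
        ref = jq.build_junction_reference(models)
        if len(ref) == 0:
            return
        entries = list(ref.entries["sequence"])
        reads = []
        for _ in range(15):
            if rng.random() < 0.7:  # mutated junction read
                seq = entries[rng.integers(len(entries))]
                o = int(rng.integers(0, 35))
                read = list(seq[o : o + 50])
                for _ in range(int(rng.integers(0, 7))):
                    p = int(rng.integers(50))
                    read[p] = "ACGT"[rng.integers(4)]
                reads.append("".join(read))
            else:  # random sequence
                reads.append(_random_seq(rng, 50))
        table = jq.match_reads(reads, ref)
        expected = np.zeros(len(entries), dtype=int)
        n_amb = n_un = 0
        for read in reads:
            res = _brute_force_match(read, entries, max_mm=4)
            if res is None:
                n_un += 1
            elif res == "ambiguous":
                n_amb += 1
            else:
                expected[res] += 1
        assert list(table.counts["sample"]) == list(expected)
        assert table.stats.loc["sample", "ambiguous"] == n_amb
        assert table.stats.loc["sample", "unassigned"] == n_un


class TestRpmAndFold:
    def test_worked_example_pair(self):
        # 35 reads at the back-solved ICM library reproduce 59.72 RPM,
        # and 88 reads give ~150.16 within rounding
        assert jq.rpm_normalize(35, ICM_LIBRARY) == pytest.approx(59.72, abs=0.01)
        assert jq.rpm_normalize(88, ICM_LIBRARY) == pytest.approx(150.16, abs=0.01)
        assert jq.rpm_normalize(142, ESC_LIBRARY) == pytest.approx(131.43, abs=0.01)
        assert jq.rpm_normalize(13, ESC_LIBRARY) == pytest.approx(12.03, abs=0.005)

    def test_zero_count_and_zero_library(self):
        assert jq.rpm_normalize(0, 12345) == 0.0
        with pytest.raises(ValueError):
            jq.rpm_normalize(5, 0)
        with pytest.raises(ValueError):
            jq.rpm_normalize(pd.DataFrame({"s": [1]}), pd.Series({"s": 0}))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(0, 10_000),
        st.integers(1, 10_000_000),
        st.integers(1, 20),
    )
    def test_rpm_linear_in_counts_and_inverse_in_library(self, count, lib, k):
        base = jq.rpm_normalize(count, lib)
        assert jq.rpm_normalize(k * count, lib) == pytest.approx(k * base)
        assert jq.rpm_normalize(count, k * lib) == pytest.approx(base / k)

    def test_fold_change_worked_examples(self):
        assert jq.fold_change(150.16, 12.03) == pytest.approx(12.47, abs=0.02)
        assert jq.fold_change(131.43, 59.72) == pytest.approx(2.2, abs=0.01)
        assert jq.fold_change(3.7, 3.7) == 1.0

    def test_fold_change_floor_and_symmetry(self):
        assert jq.fold_change(5.0, 0.0) == 50.0  # denominator floored at 0.1
        assert jq.fold_change(0.0, 0.0) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.11, 1e5, allow_nan=False),
        st.floats(0.11, 1e5, allow_nan=False),
    )
    def test_log_fold_antisymmetric_away_from_floor(self, a, b):
        assert np.log(jq.fold_change(a, b)) == pytest.approx(-np.log(jq.fold_change(b, a)), abs=1e-9)

    def test_alignment_params_validation(self):
        with pytest.raises(ValueError):
            jq.AlignmentParams(max_mismatches=50, read_length=50)
        with pytest.raises(ValueError):
            jq.AlignmentParams(max_mismatches=-1)
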