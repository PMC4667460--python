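"""Tag-pair discovery and genotype-calling rules."""

import numpy as np
import pandas as pd
import pytest

from polygs.calling import (
    TAG_LEN,
    KeyTableError,
    TagCountTable,
    call_genotypes,
    call_snps,
    demultiplex_trim,
    discover_tag_pairs,
    snp_name,
)
from polygs.simdata import MISSING


def _tag(core: str) -> str:
    """Pad a short core out to a 64-bp tag."""
    return (core + "A" * TAG_LEN)[:TAG_LEN]


def _table(counts: dict[str, dict[str, int]]) -> TagCountTable:
    return TagCountTable(pd.DataFrame(counts).T.fillna(0).astype(np.int64))


def _write_fastq(path, reads):
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


@pytest.fixture()
def toy_key(tmp_path):
    key = tmp_path / "key.tsv"
    pd.DataFrame(
        {"flowcell_lane": "L1", "barcode": ["ACGTA", "TTACG"],
         "sample_id": ["S1", "S2"]}
    ).to_csv(key, sep="\t", index=False)
    return key


class TestDemultiplexTrim:
    def test_counts_trimming_and_unknown_barcodes(self, tmp_path, toy_key):
        tag = "CAGC" + "G" * 60
        reads = (
            ["ACGTA" + tag + "TTTTT"] * 3       # S1, same tag, extra bases trimmed
            + ["GGGGG" + tag]                   # unknown barcode
            + ["TTACG" + "TTTT" + "G" * 60]     # S2 but no cut-site remnant
        )
        fq = tmp_path / "in.fastq"
        _write_fastq(fq, reads)
        table = demultiplex_trim(fq, toy_key, "CWGC")
        assert all(len(t) == TAG_LEN for t in table.tags)
        assert int(table.counts.loc["S1", tag]) == 3
        assert table.counts.loc["S2"].sum() == 0
        assert table.counts.to_numpy().sum() == 3

    def test_ambiguous_base_in_tag_dropped(self, tmp_path, toy_key):
        fq = tmp_path / "in.fastq"
        _write_fastq(fq, ["ACGTA" + "CAGC" + "N" + "G" * 59])
        table = demultiplex_trim(fq, toy_key, "CWGC")
        assert table.counts.to_numpy().sum() == 0

    def test_duplicate_barcodes_rejected(self, tmp_path):
        key = tmp_path / "key.tsv"
        pd.DataFrame({"flowcell_lane": "L1", "barcode": ["AAAA", "AAAA"],
                      "sample_id": ["S1", "S2"]}).to_csv(key, sep="\t", index=False)
        fq = tmp_path / "in.fastq"
        _write_fastq(fq, [])
        with pytest.raises(KeyTableError):
            demultiplex_trim(fq, key, "CWGC")

    def test_empty_fastq_warns_and_returns_empty(self, tmp_path, toy_key):
        fq = tmp_path / "in.fastq"
        _write_fastq(fq, [])
        with pytest.warns(UserWarning):
            table = demultiplex_trim(fq, toy_key, "CWGC")
        assert table.counts.to_numpy().sum() == 0


class TestDiscoverTagPairs:
    def test_read_threshold_and_hamming_distance(self):
        a = _tag("CAGCAAAA")
        b = a[:10] + "C" + a[11:]       # distance 1 from a
        c = a[:20] + "CC" + a[22:]      # distance 2 from a
        d = _tag("CAGCTTTT")            # far from everything
        table = _table({"s1": {a: 6, b: 30, c: 15, d: 9}, "s2": {a: 5}})
        pairs = discover_tag_pairs(table, min_total_reads=10)
        assert pairs == [tuple(sorted((a, b)))]
        # brute-force oracle: no emitted pair at Hamming distance != 1
        for x, y in pairs:
            assert sum(p != q for p, q in zip(x, y)) == 1
        # the 9-read tag d never pairs
        assert all(d not in p for p in pairs)

    def test_tag_below_threshold_excluded_even_with_partner(self):
        a = _tag("CAGCAAAA")
        b = a[:10] + "C" + a[11:]
        table = _table({"s1": {a: 9, b: 100}})
        assert discover_tag_pairs(table, min_total_reads=10) == []

    def test_ambiguous_networks_discarded(self):
        a = _tag("CAGCAAAA")
        b = a[:10] + "C" + a[11:]
        c = a[:10] + "G" + a[11:]  # both b and c are 1 bp from a (and from each other)
        table = _table({"s1": {a: 50, b: 50, c: 50}})
        assert discover_tag_pairs(table, min_total_reads=10) == []

    def test_raising_threshold_never_adds_pairs_on_isolated_pairs(self):
        # monotonicity holds whenever pairing is unambiguous (no 1-bp
        # networks); build well-separated tag pairs and sweep the threshold
        rng = np.random.default_rng(5)
        tags = {}
        for i in range(12):
            core = "CAGC" + "".join(rng.choice(list("ACGT"), 12)) * 5
            a = _tag(core)
            b = a[:30] + ("C" if a[30] != "C" else "G") + a[31:]
            tags[a] = int(rng.integers(1, 60))
            tags[b] = int(rng.integers(1, 60))
        table = _table({"s1": tags})
        prev = None
        for thr in (1, 5, 10, 20, 40):
            pairs = set(discover_tag_pairs(table, min_total_reads=thr))
            totals = table.total_reads()
            assert all(totals[x] >= thr and totals[y] >= thr for x, y in pairs)
            if prev is not None:
                assert pairs <= prev
            prev = pairs


class TestCallGenotypes:
    @pytest.mark.parametrize(
        "ra,rb,expected",
        [(0, 0, MISSING), (12, 0, 0), (0, 12, 2), (10, 10, 1),
         (2, 0, MISSING), (3, 1, 0), (3, 2, 1)],
    )
    def test_calling_rules(self, ra, rb, expected):
        out = call_genotypes(np.array([ra]), np.array([rb]),
                             min_depth=3, het_min_minor_reads=2)
        assert out[0] == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_genotypes(np.array([-1]), np.array([2]))


class TestCallSnps:
    def _two_cohorts(self):
        a = _tag("CAGCAAAA")
        b = a[:10] + "C" + a[11:]
        # polymorphic in cohort A; cohort B carries only the reference tag,
        # at adequate depth
        ta = _table({"a1": {a: 20, b: 0}, "a2": {a: 8, b: 12}})
        tb = _table({"b1": {a: 20}, "b2": {a: 15}})
        return ta, tb, a, b

    def test_single_cohort_modes_identical(self):
        ta, _, _, _ = self._two_cohorts()
        sep = call_snps(ta, mode="separate")[0]
        joint = call_snps(ta, mode="joint")[0]
        np.testing.assert_array_equal(sep.codes, joint.codes)
        assert sep.marker_names == joint.marker_names

    def test_joint_mode_reports_marker_in_both_cohorts(self):
        ta, tb, a, b = self._two_cohorts()
        sep = call_snps([ta, tb], mode="separate")
        assert sep[0].n_markers == 1 and sep[1].n_markers == 0
        joint = call_snps([ta, tb], mode="joint")
        assert joint[0].marker_names == joint[1].marker_names == [snp_name(a, b)]
        # cohort B is monomorphic reference at that SNP
        assert set(joint[1].codes.ravel()) == {0}

    def test_joint_mode_sample_collision_rejected(self):
        a = _tag("CAGCAAAA")
        t1 = _table({"s1": {a: 10}})
        t2 = _table({"s1": {a: 10}})
        with pytest.raises(KeyTableError):
            call_snps([t1, t2], mode="joint")

    def test_emitted_codes_are_valid(self):
        ta, tb, _, _ = self._two_cohorts()
        for G in call_snps([ta, tb], mode="joint"):
            assert set(np.unique(G.codes)) <= {0, 1, 2, MISSING}
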