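import subprocess

import numpy as np
import pysam
import pytest

from hfrmap.classify import (
    CATEGORIES,
    classify_builtin,
    classify_from_sam,
    site_frequencies,
)
from hfrmap.distributions import FragmentLengthDistribution
from hfrmap.synthetic import (
    GenomePairConfig,
    ReadSet,
    build_pool,
    generate_genome_pair,
    simulate_reads,
    simulate_recombinant,
)

FIXED_20K = FragmentLengthDistribution("fixed", length=20_000)


@pytest.fixture(scope="module")
def core_pair():
    """50 kb accessory-free pair (donor and recipient frames coincide)."""
    return generate_genome_pair(GenomePairConfig(genome_length=50_000, divergence=0.01, seed=5))


@pytest.fixture(scope="module")
def clone_and_reads(core_pair):
    clone = simulate_recombinant(core_pair, 25_000, FIXED_20K, extra_count=0, seed=6)
    reads = simulate_reads(clone, depth=5.0, error_rate=0.0, seed=7)
    return clone, reads


class TestClassifyBuiltin:
    def test_every_read_gets_exactly_one_category(self, core_pair, clone_and_reads):
        clone, reads = clone_and_reads
        cl = classify_builtin(reads, core_pair)
        assert cl.category_counts().sum() == reads.n_reads
        assert set(cl.labels["category"].cat.categories) == set(CATEGORIES)

    def test_no_read_labeled_against_its_origin(self, core_pair, clone_and_reads):
        """Error-free reads fully inside a single-origin region never vote
        for the other parent."""
        clone, reads = clone_and_reads
        cl = classify_builtin(reads, core_pair)
        (fs, fe) = clone.truth.fragments[0]
        starts = reads.starts
        inside = (starts >= fs) & (starts + reads.read_length <= fe)
        outside = (starts + reads.read_length <= fs) | (starts >= fe)
        cats = cl.labels["category"].to_numpy()
        assert not np.any(cats[inside] == "RECIPIENT_BETTER")
        assert not np.any(cats[outside] == "DONOR_BETTER")
        # informative reads inside are all donor-better
        assert np.all(np.isin(cats[inside], ["DONOR_BETTER", "TIE"]))

    def test_read_covering_no_sites_is_tie(self, core_pair):
        spos = core_pair.truth_sites["recipient_pos"].to_numpy()
        gaps = np.diff(spos)
        i = int(np.argmax(gaps))
        assert gaps[i] > 160, "fixture needs a site-free 150 bp window"
        start = int(spos[i]) + 5
        seq = core_pair.recipient_codes[start : start + 150][None, :]
        rs = ReadSet(names=["gapread"], seqs=seq, starts=np.array([start]))
        cl = classify_builtin(rs, core_pair)
        assert cl.labels["category"].iloc[0] == "TIE"
        assert cl.labels["recipient_pos"].iloc[0] == start

    def test_unanimous_donor_votes(self, core_pair, clone_and_reads):
        clone, _ = clone_and_reads
        fs, fe = clone.truth.fragments[0]
        spos = core_pair.truth_sites["recipient_pos"].to_numpy()
        in_frag = spos[(spos >= fs) & (spos < fe)]
        # pick a window covering >= 3 sites, read taken from the recombinant
        for j in range(len(in_frag) - 3):
            if in_frag[j + 2] - in_frag[j] < 140:
                start = int(in_frag[j]) - 5
                break
        rs = ReadSet(
            names=["dread"],
            seqs=clone.codes[start : start + 150][None, :],
            starts=np.array([start]),
        )
        cl = classify_builtin(rs, core_pair)
        row = cl.labels.iloc[0]
        assert row.category == "DONOR_BETTER"
        assert row.score_margin >= 3
        assert row.first_site == in_frag[j]

    def test_swapping_references_swaps_labels_and_frequencies(self, core_pair, clone_and_reads):
        clone, reads = clone_and_reads
        cl = classify_builtin(reads, core_pair)
        cl_sw = classify_builtin(reads, core_pair.swapped())
        swap = {
            "DONOR_BETTER": "RECIPIENT_BETTER",
            "RECIPIENT_BETTER": "DONOR_BETTER",
            "TIE": "TIE",
            "DONOR_ONLY": "RECIPIENT_ONLY",
            "RECIPIENT_ONLY": "DONOR_ONLY",
            "UNMAPPED": "UNMAPPED",
        }
        expected = cl.labels["category"].astype(str).map(swap)
        assert (cl_sw.labels["category"].astype(str) == expected).all()
        f = site_frequencies(cl)
        f_sw = site_frequencies(cl_sw)
        cov = f["covered"] & f_sw["covered"]
        assert np.allclose(
            f_sw.loc[cov, "donor_frequency"], 1.0 - f.loc[cov, "donor_frequency"]
        )

    def test_donor_accessory_reads_are_donor_only(self, small_pair):
        s, e = small_pair.donor_accessory[0]
        reads = simulate_reads(small_pair.donor_codes, depth=2.0, error_rate=0.0, seed=8)
        cl = classify_builtin(reads, small_pair)
        inside = (reads.starts >= s) & (reads.starts + 150 <= e)
        assert inside.sum() > 0
        assert (cl.labels["category"].to_numpy()[inside] == "DONOR_ONLY").all()

    def test_recipient_accessory_reads_are_recipient_only(self, small_pair):
        s, e = small_pair.recipient_accessory[0]
        reads = simulate_reads(small_pair.recipient_codes, depth=2.0, error_rate=0.0, seed=9)
        cl = classify_builtin(reads, small_pair)
        inside = (reads.starts >= s) & (reads.starts + 150 <= e)
        assert inside.sum() > 0
        assert (cl.labels["category"].to_numpy()[inside] == "RECIPIENT_ONLY").all()

    def test_empty_site_list_all_tie_or_only(self, core_pair):
        reads = simulate_reads(core_pair.recipient_codes, depth=0.5, seed=10)
        empty = core_pair.truth_sites.iloc[0:0]
        cl = classify_builtin(reads, core_pair, sites=empty)
        assert (cl.labels["category"] == "TIE").all()


class TestSiteFrequencies:
    def test_clone_frequencies_follow_fragments(self, core_pair, clone_and_reads):
        clone, reads = clone_and_reads
        cl = classify_builtin(reads, core_pair)
        f = site_frequencies(cl)
        fs, fe = clone.truth.fragments[0]
        pos = f["recipient_pos"].to_numpy()
        inside = (pos >= fs) & (pos < fe) & f["covered"].to_numpy()
        outside = ((pos < fs) | (pos >= fe)) & f["covered"].to_numpy()
        assert np.allclose(f.loc[inside, "donor_frequency"], 1.0)
        assert np.allclose(f.loc[outside, "donor_frequency"], 0.0)
        assert f.loc[~f["covered"], "donor_frequency"].isna().all()

    def test_half_frequency_in_equal_two_clone_pool(self, core_pair):
        c1 = simulate_recombinant(core_pair, 25_000, FIXED_20K, extra_count=0, seed=21, clone_id="a")
        c2 = simulate_recombinant(
            core_pair,
            25_000,
            FragmentLengthDistribution("fixed", length=4_000),
            extra_count=0,
            seed=22,
            clone_id="b",
        )
        pool, _ = build_pool([c1, c2], [1, 1], total_depth=60.0, seed=23)
        cl = classify_builtin(pool, core_pair)
        f = site_frequencies(cl)
        # sites covered by c1's fragment but not c2's: expected frequency 1/2
        (s1, e1), (s2, e2) = c1.truth.fragments[0], c2.truth.fragments[0]
        pos = f["recipient_pos"].to_numpy()
        only1 = (pos >= s1) & (pos < e1) & ~((pos >= s2) & (pos < e2))
        sel = f[only1 & f["covered"]]
        n = (sel["donor_count"] + sel["recipient_count"]).to_numpy()
        se = np.sqrt(0.25 / np.maximum(n, 1))
        assert np.all(np.abs(sel["donor_frequency"] - 0.5) < 4 * se)


def _write_sam(path, records, refs):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": n, "LN": l} for n, l in refs]}
    with pysam.AlignmentFile(str(path), "w", header=pysam.AlignmentHeader.from_dict(header)) as fh:
        for name, ref_id, pos, mapq, score in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            a.query_sequence = "A" * 20
            a.flag = 0 if ref_id is not None else 4
            if ref_id is None:
                a.reference_id = -1
            else:
                a.reference_id = ref_id
                a.reference_start = pos
                a.cigarstring = "20M"
                a.mapping_quality = mapq
                if score is not None:
                    a.set_tag("AS", score)
            fh.write(a)


class TestClassifyFromSam:
    REFS = [("donor|chr", 10_000), ("recipient|chr", 10_000)]

    def test_categories_from_scores(self, tmp_path):
        sam = tmp_path / "reads.sam"
        _write_sam(
            sam,
            [
                ("tie", 0, 100, 60, 40), ("tie", 1, 100, 60, 40),
                ("dbetter", 0, 200, 60, 40), ("dbetter", 1, 200, 60, 35),
                ("rbetter", 0, 300, 60, 30), ("rbetter", 1, 300, 60, 40),
                ("donly", 0, 400, 60, 40),
                ("ronly", 1, 500, 60, 40),
                ("lost", None, 0, 0, None),
            ],
            self.REFS,
        )
        labels = classify_from_sam(sam_path=sam).set_index("read_id")
        assert labels.loc["tie", "category"] == "TIE"
        assert labels.loc["dbetter", "category"] == "DONOR_BETTER"
        assert labels.loc["dbetter", "score_margin"] == 5
        assert labels.loc["dbetter", "recipient_pos"] == 200
        assert labels.loc["rbetter", "category"] == "RECIPIENT_BETTER"
        assert labels.loc["donly", "category"] == "DONOR_ONLY"
        assert labels.loc["ronly", "category"] == "RECIPIENT_ONLY"
        assert labels.loc["lost", "category"] == "UNMAPPED"

    def test_mapq_floor_discards_alignments(self, tmp_path):
        sam = tmp_path / "mapq.sam"
        _write_sam(sam, [("r1", 0, 100, 3, 40), ("r1", 1, 100, 60, 30)], self.REFS)
        labels = classify_from_sam(sam_path=sam, mapq_floor=10).set_index("read_id")
        assert labels.loc["r1", "category"] == "RECIPIENT_ONLY"

    def test_missing_alignment_score_named_in_error(self, tmp_path):
        sam = tmp_path / "noscore.sam"
        _write_sam(sam, [("r1", 0, 100, 60, None)], self.REFS)
        with pytest.raises(ValueError, match="AS"):
            classify_from_sam(sam_path=sam)

    def test_bwa_competitive_mapping_agrees_with_builtin(self, tmp_path, core_pair):
        """End-to-end check against a real aligner: map error-free clone
        reads to each genome with bwa and compare the score-based labels
        with the vote-based builtin labels."""
        clone = simulate_recombinant(core_pair, 25_000, FIXED_20K, extra_count=0, seed=30)
        reads = simulate_reads(clone, depth=1.0, error_rate=0.0, seed=31)
        fq = tmp_path / "reads.fastq"
        reads.write_fastq(fq)
        core_pair.write_fasta(tmp_path)
        sams = {}
        for genome in ("donor", "recipient"):
            fa = tmp_path / f"{genome}.fasta"
            subprocess.run(["bwa", "index", str(fa)], check=True, capture_output=True)
            sam = tmp_path / f"{genome}.sam"
            with open(sam, "w") as out:
                subprocess.run(
                    ["bwa", "mem", "-v", "1", str(fa), str(fq)], check=True, stdout=out,
                    stderr=subprocess.DEVNULL,
                )
            sams[genome] = sam
        labels = classify_from_sam(
            donor_sam=sams["donor"], recipient_sam=sams["recipient"]
        ).set_index("read_id")
        builtin = classify_builtin(reads, core_pair).labels.set_index("read_id")
        joined = labels.join(builtin, lsuffix="_sam", rsuffix="_bi")
        informative = joined["category_bi"].isin(["DONOR_BETTER", "RECIPIENT_BETTER"])
        agree = (
            joined.loc[informative, "category_sam"].astype(str)
            == joined.loc[informative, "category_bi"].astype(str)
        )
        assert agree.mean() > 0.98
        # positions agree where both place the read on the recipient
        both = informative & (joined["recipient_pos_sam"] >= 0)
        assert (
            (joined.loc[both, "recipient_pos_sam"] == joined.loc[both, "recipient_pos_bi"]).mean()
            > 0.98
        )
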