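import numpy as np
import pytest

from _oracles import nearest_gap_scan
from pitsc.refextend import (
    FeatureInterval,
    extend_gtf,
    extend_three_prime,
    merge_annotations,
    read_gtf,
    write_gtf,
)


def gene(gid, start, end, strand="+", chrom="1", kind="gene"):
    return FeatureInterval(chrom=chrom, start=start, end=end, strand=strand,
                           gene_id=gid, feature_kind=kind)


def test_cap_limits_a_wide_gap():
    genes = [gene("a", 100, 1000), gene("b", 11000, 12000)]
    out, report = extend_three_prime(genes, cap=4000)
    row = report.set_index("gene_id").loc["a"]
    assert row["extension"] == 4000
    assert row["new_three_prime"] == 5000
    assert row["limiting"] == "cap"


def test_half_gap_and_facing_genes_never_overlap():
    # b on the minus strand extends its 3' end (start) toward a
    genes = [gene("a", 100, 1000), gene("b", 1201, 2000, strand="-")]
    out, report = extend_three_prime(genes, cap=4000)
    rep = report.set_index("gene_id")
    assert rep.loc["a", "extension"] == 100  # gap 200 -> floor(200/2)
    assert rep.loc["a", "new_three_prime"] == 1100
    assert rep.loc["b", "extension"] == 100
    assert rep.loc["b", "new_three_prime"] == 1101
    spans = sorted((f.start, f.end) for f in out)
    assert spans[0][1] < spans[1][0]


def test_abutting_gene_is_unchanged():
    genes = [gene("a", 100, 1000), gene("b", 1001, 2000)]
    out, report = extend_three_prime(genes, cap=4000)
    rep = report.set_index("gene_id")
    assert rep.loc["a", "extension"] == 0
    assert rep.loc["a", "limiting"] == "neighbor"


def test_overlapping_input_genes_are_flagged_not_extended():
    genes = [gene("a", 100, 1500), gene("b", 1000, 2000), gene("c", 9000, 9500)]
    out, report = extend_three_prime(genes, cap=4000)
    rep = report.set_index("gene_id")
    assert rep.loc["a", "overlapping_input"] and rep.loc["a", "extension"] == 0
    assert rep.loc["b", "overlapping_input"] and rep.loc["b", "extension"] == 0
    assert not rep.loc["c", "overlapping_input"]


def test_minus_strand_extends_start_and_clips_at_one():
    genes = [gene("a", 500, 1000, strand="-")]
    out, report = extend_three_prime(genes, cap=4000)
    assert out[0].start == 1  # clipped at the chromosome origin
    assert report.iloc[0]["extension"] == 499


def test_every_extension_matches_bruteforce_and_no_overlaps(rng):
    genes = []
    pos = 1
    for i in range(60):
        length = int(rng.integers(200, 3000))
        gap = int(rng.integers(0, 12000))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = "1" if i < 40 else "2"
        genes.append(gene(f"g{i}", pos, pos + length, strand=strand, chrom=chrom))
        pos += length + gap + 1
    out, report = extend_three_prime(genes, cap=4000)
    rep = report.set_index("gene_id")
    for g in genes:
        gap = nearest_gap_scan(genes, g)
        expected = 4000 if gap is None else min(4000, max(gap, 0) // 2)
        if g.strand == "-":
            expected = min(expected, g.start - 1)
        assert rep.loc[g.gene_id, "extension"] == expected, g.gene_id
    # global sweep: no overlaps after extension
    by_chrom = {}
    for f in out:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


def test_transcript_and_terminal_exon_move_with_the_gene():
    feats = [
        gene("a", 100, 1000),
        gene("a", 100, 1000, kind="transcript"),
        gene("a", 100, 300, kind="exon"),
        gene("a", 800, 1000, kind="exon"),  # terminal exon
        gene("b", 11001, 12000),
    ]
    out, report = extend_three_prime(feats, cap=4000)
    ends = {(f.feature_kind, f.start): f.end for f in out if f.gene_id == "a"}
    assert ends[("gene", 100)] == 5000
    assert ends[("transcript", 100)] == 5000
    assert ends[("exon", 100)] == 300  # inner exon untouched
    assert ends[("exon", 800)] == 5000


def test_merge_appends_contig_filtered_records_with_suffixes():
    primary = [gene(f"g{i}", 100 + 1000 * i, 500 + 1000 * i) for i in range(100)]
    mito = [gene(f"mt{i}", 10 + 100 * i, 60 + 100 * i, chrom="MT") for i in range(13)]
    merged = merge_annotations(primary, mito, contigs={"MT"})
    assert len(merged) == 113
    assert all(f.source == "secondary" for f in merged if f.chrom == "MT")
    # collision: a secondary record sharing a primary gene id is suffixed
    clash = [gene("g0", 5, 50, chrom="MT")]
    merged = merge_annotations(primary, clash, contigs={"MT"})
    ids = [f.gene_id for f in merged]
    assert "g0_2" in ids and ids.count("g0") == 1
    with pytest.warns(UserWarning, match="no secondary"):
        merge_annotations(primary, mito, contigs={"nope"})


def test_gtf_roundtrip_and_double_extension_refusal(tmp_path):
    feats = [gene("a", 100, 1000), gene("b", 11001, 12000)]
    src = tmp_path / "in.gtf"
    write_gtf(feats, src)
    back = read_gtf(src)
    assert [(f.gene_id, f.start, f.end) for f in back] == [("a", 100, 1000), ("b", 11001, 12000)]
    out = tmp_path / "out.gtf"
    report = extend_gtf(src, out, cap=4000)
    assert report.set_index("gene_id").loc["a", "extension"] == 4000
    reread = read_gtf(out)
    assert reread[0].end == 5000
    with pytest.raises(ValueError, match="already carries"):
        extend_gtf(out, tmp_path / "twice.gtf")
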