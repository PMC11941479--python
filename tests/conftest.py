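import numpy as np
import pytest

from mpindex import GenomicInterval, PreMirnaLocus, StrandedCoverage


def make_coverage(sample_id="s1", intervals=()):
    """Coverage from (chrom, strand, start, end, depth) tuples."""
    cov = StrandedCoverage(sample_id=sample_id)
    for chrom, strand, start, end, depth in intervals:
        cov.add_interval(chrom, strand, start, end, depth)
    return cov


@pytest.fixture
def locus_plus():
    return PreMirnaLocus("mir-plus", GenomicInterval("chr1", 1000, 1085, "+"))


def constant_locus_coverage(cov, locus, hairpin_depth, left_depth, right_depth,
                            flank_len=100):
    """Flat coverage over a locus's hairpin and both full flanks."""
    hp = locus.hairpin
    cov.add_interval(hp.chrom, hp.strand, hp.start - flank_len, hp.start, left_depth)
    cov.add_interval(hp.chrom, hp.strand, hp.start, hp.end, hairpin_depth)
    cov.add_interval(hp.chrom, hp.strand, hp.end, hp.end + flank_len, right_depth)


@pytest.fixture
def filter_fixture():
    """Five loci exercising each inclusion filter exactly once.

    A: mirtron; B: reference flank depth below 2; C: >4-fold flank
    imbalance; D: matures not detected; E: clean.  One reference sample.
    """
    loci = [
        PreMirnaLocus(name, GenomicInterval("chr1", start, start + 85, "+"))
        for name, start in [("A", 1000), ("B", 2000), ("C", 3000),
                            ("D", 4000), ("E", 5000)]
    ]
    cov = StrandedCoverage(sample_id="WT_rep1")
    by_id = {l.locus_id: l for l in loci}
    constant_locus_coverage(cov, by_id["A"], 3, 15, 15)
    constant_locus_coverage(cov, by_id["B"], 0, 1.5, 1.5)
    constant_locus_coverage(cov, by_id["C"], 10, 20, 110)
    constant_locus_coverage(cov, by_id["D"], 3, 15, 15)
    constant_locus_coverage(cov, by_id["E"], 3, 15, 15)
    return {
        "loci": loci,
        "coverages": {"WT_rep1": cov},
        "sample_conditions": {"WT_rep1": "WT"},
        "detected": {"A", "B", "C", "E"},
        "mirtrons": {"A"},
    }
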