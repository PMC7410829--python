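import numpy as np
import pysam
import pytest

from footprintkit.tracks_io import GenomeSequence, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_genome(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return GenomeSequence({"chr1": seq})


def write_bam(path, contigs, reads):
    """Build a coordinate-sorted, indexed BAM from read dicts.

    Each read dict: contig, start, and optionally seq/length, reverse,
    duplicate, qcfail, secondary, mapq, quals, name, cigar.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contigs.items()],
    }
    refs = list(contigs)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        ordered = sorted(reads, key=lambda r: (refs.index(r["contig"]), r["start"]))
        for i, r in enumerate(ordered):
            a = pysam.AlignedSegment()
            a.query_name = r.get("name", f"read{i}")
            seq = r.get("seq", "A" * r.get("length", 36))
            a.query_sequence = seq
            a.reference_id = refs.index(r["contig"])
            a.reference_start = r["start"]
            a.cigarstring = r.get("cigar", f"{len(seq)}M")
            a.mapping_quality = r.get("mapq", 60)
            flag = 0
            if r.get("reverse"):
                flag |= 16
            if r.get("duplicate"):
                flag |= 1024
            if r.get("qcfail"):
                flag |= 512
            if r.get("secondary"):
                flag |= 256
            a.flag = flag
            quals = r.get("quals")
            a.query_qualities = (
                pysam.qualitystring_to_array(quals)
                if quals is not None
                else pysam.qualitystring_to_array("I" * len(seq))
            )
            bam.write(a)
    pysam.index(str(path))
    return str(path)


@pytest.fixture
def bam_factory(tmp_path):
    def factory(name, contigs, reads):
        return write_bam(tmp_path / name, contigs, reads)

    return factory
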