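"""Shared fixtures: simulated scenario datasets and hand-built BAM helpers."""

import numpy as np
import pysam
import pytest
from hypothesis import settings

from cnvcurate import simulate

settings.register_profile("seeded", derandomize=True, max_examples=60)
settings.load_profile("seeded")

MINI = dict(ref_length=200_000, diploid_depth=10.0, het_snv_spacing=250)


@pytest.fixture(scope="session")
def scenarios(tmp_path_factory):
    """The four curation scenarios at their default study conditions."""
    out = {}
    for name in simulate.SCENARIOS:
        root = tmp_path_factory.mktemp(f"scenario_{name}")
        out[name] = simulate.simulate_scenario(name, root, seed=7)
    return out


@pytest.fixture(scope="session")
def mini_truth(tmp_path_factory):
    """A scaled-down supported-call dataset for fast module tests."""
    root = tmp_path_factory.mktemp("mini")
    cfg = simulate.SimConfig(cnv_events=(simulate.CnvEvent(80_000, 120_000, 1),),
                             seed=11, **MINI)
    return simulate.simulate_dataset(cfg, root)


def make_read(name, pos, cigar, flag=0, ref_id=0, mate_pos=-1, tlen=0,
              mapq=60, header=None):
    """Build one in-memory alignment record."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = ref_id
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    qlen = sum(n for op, n in rec.cigartuples or [] if op in (0, 1, 4))
    rec.query_sequence = "A" * qlen
    rec.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    if mate_pos >= 0:
        rec.next_reference_id = ref_id
        rec.next_reference_start = mate_pos
    rec.template_length = tlen
    return rec


def bam_header(ref_len=50_000, extra_refs=()):
    sq = [{"SN": "chrS", "LN": ref_len}]
    sq += [{"SN": name, "LN": 10_000} for name in extra_refs]
    return pysam.AlignmentHeader.from_dict({"HD": {"VN": "1.6", "SO": "coordinate"},
                                            "SQ": sq})


def write_bam(path, records, header):
    """Write coordinate-sorted records and index the result."""
    records = sorted(records, key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as fh:
        for rec in records:
            fh.write(rec)
    pysam.index(str(path))
    return str(path)


def concordant_pairs(header, n=30, start=100, spacing=50, insert=350, rl=100,
                     prefix="bg"):
    """Plain forward-reverse background pairs for padding test BAMs."""
    out = []
    for i in range(n):
        p1 = start + i * spacing
        p2 = p1 + insert - rl
        out.append(make_read(f"{prefix}{i}", p1, f"{rl}M", flag=99,
                             mate_pos=p2, tlen=insert, header=header))
        out.append(make_read(f"{prefix}{i}", p2, f"{rl}M", flag=147,
                             mate_pos=p1, tlen=-insert, header=header))
    return out
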