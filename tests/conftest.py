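import numpy as np
import pytest

from pairdel.models import CandidateGuide, GuidePair, TargetRegion


def make_guide(guide_id, cut_site, strand="+", protospacer=None, chrom="chr1",
               efficacy=0.9, top5=10.0, top10=10.0, seed=None):
    if protospacer is None:
        rng = np.random.default_rng(abs(hash(guide_id)) % (2**31) if seed is None else seed)
        protospacer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)])
    return CandidateGuide(guide_id=guide_id, chrom=chrom, cut_site=cut_site,
                          strand=strand, protospacer=protospacer,
                          efficacy=efficacy, top5_offtarget=top5,
                          top10_offtarget=top10)


def make_pair(pair_id="pair1", region_id="regionA", cut_u6=100, cut_h1=500,
              proto_u6=None, proto_h1=None, strategy="flanking"):
    gu = make_guide(f"{pair_id}_u6", cut_u6, protospacer=proto_u6)
    gh = make_guide(f"{pair_id}_h1", cut_h1, protospacer=proto_h1)
    return GuidePair(pair_id=pair_id, region_id=region_id, guide_u6=gu,
                     guide_h1=gh, expected_deletion=(cut_u6, cut_h1),
                     strategy=strategy)


@pytest.fixture
def region():
    return TargetRegion(region_id="regionA", chrom="chr1", start=1000, end=1300)


@pytest.fixture
def simple_library():
    from pairdel.simulate import make_simple_library
    return make_simple_library(20, 3, seed=11)
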