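import numpy as np
import pytest

import utrpresence as up
from utrpresence.site_presence import site_presence


@pytest.fixture(scope="session")
def reference_fixture():
    """The packaged 421-gene putative-target fixture plus its presence run."""
    sim, cov, roster = up.make_reference_fixture(seed=1)
    presences = [site_presence(m, cov) for m in sim.models]
    return {
        "sim": sim,
        "cov": cov,
        "roster": roster,
        "presences": presences,
        "pt50": up.build_pt50(presences),
    }


@pytest.fixture()
def toy_transcript():
    """3 exons of 10 bases each and a 40-base 3'-UTR with one 8-base site."""
    iv = up.GenomicInterval
    return up.TranscriptModel(
        gene_id="G1",
        transcript_id="G1.t1",
        exons=[iv("chr1", 0, 10), iv("chr1", 20, 30), iv("chr1", 40, 50)],
        utr3=iv("chr1", 50, 90),
        sites=[iv("chr1", 70, 78)],
    )


def constant_track(chrom: str, size: int, depth: float) -> up.CoverageTrack:
    return up.CoverageTrack({chrom: np.full(size, float(depth))})


@pytest.fixture()
def toy_track():
    return constant_track("chr1", 100, 100.0)
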