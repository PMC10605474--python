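import numpy as np
import pytest

from ogmrepeat import RFC1_LOCUS, SizingConfig


@pytest.fixture
def locus():
    return RFC1_LOCUS


@pytest.fixture
def config():
    return SizingConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


CMAP_HEADER = (
    "# CMAP File Version:\t0.2\n"
    "#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition\tStdDev\tCoverage\tOccurrence\n"
    "#f int\tfloat\tint\tint\tint\tfloat\tfloat\tint\tint\n"
)

XMAP_HEADER = (
    "# XMAP File Version:\t0.2\n"
    "#h XmapEntryID\tQryContigID\tRefContigID\tQryStartPos\tQryEndPos\tRefStartPos\tRefEndPos"
    "\tOrientation\tConfidence\tHitEnum\tQryLen\tRefLen\tLabelChannel\tAlignment\n"
)


def write_cmap(path, rows, header=CMAP_HEADER):
    """rows: list of (cmap_id, length, nsites, site_id, channel, position)."""
    with open(path, "w") as fh:
        fh.write(header)
        for cmap_id, length, nsites, site_id, channel, pos in rows:
            fh.write(f"{cmap_id}\t{length}\t{nsites}\t{site_id}\t{channel}\t{pos}\t0.0\t1\t1\n")
    return path


def write_xmap(path, rows, header=XMAP_HEADER):
    """rows: list of (entry_id, qry_id, ref_id, orientation, confidence, alignment_str)."""
    with open(path, "w") as fh:
        fh.write(header)
        for entry, qry, ref, orient, conf, aln in rows:
            fh.write(
                f"{entry}\t{qry}\t{ref}\t0.0\t1.0\t0.0\t1.0\t{orient}\t{conf}\t1M\t1.0\t1.0\t1\t{aln}\n"
            )
    return path
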