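import networkx as nx
import numpy as np
import pandas as pd
import pytest


def make_scored(edges):
    """Build a scored undirected graph from (u, v, confidence) triples."""
    g = nx.Graph()
    g.graph["provenance"] = "test"
    for u, v, c in edges:
        g.add_edge(u, v, confidence=c)
    return g


def random_regions(rng, chrom_length, n, chrom="chr1"):
    """n random intervals on one chromosome, as a chrom/start/end DataFrame."""
    starts = rng.integers(0, chrom_length - 1, size=n)
    lengths = rng.integers(1, max(2, chrom_length // 4), size=n)
    ends = np.minimum(starts + lengths, chrom_length)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def perbase_membership(regions, chrom_length, chrom="chr1"):
    """Boolean base mask for a region table on one chromosome."""
    mask = np.zeros(chrom_length, dtype=bool)
    for _, row in regions[regions["chrom"] == chrom].iterrows():
        mask[row["start"]:row["end"]] = True
    return mask


def mask_to_regions(mask, chrom="chr1"):
    """Run-length extraction of True runs into a sorted region table."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return pd.DataFrame({"chrom": pd.Series([chrom] * (len(edges) // 2), dtype=str),
                         "start": pd.Series(edges[::2], dtype="int64"),
                         "end": pd.Series(edges[1::2], dtype="int64")})


@pytest.fixture
def scored_star():
    """5-node star with the center 'C' and leaves L1..L4, all confidence 0.9."""
    return make_scored([("C", f"L{i}", 0.9) for i in range(1, 5)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
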