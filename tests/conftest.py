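import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_annotation() -> pd.DataFrame:
    """Four genes on two chromosomes, both strands."""
    return pd.DataFrame({
        "gene_id": ["gA", "gB", "gC", "gD"],
        "chrom": ["chr1", "chr1", "chr2", "chr2"],
        "tss": [10_000, 50_000, 20_000, 80_000],
        "strand": ["+", "-", "+", "-"],
    })


def make_peaks(rows, factor="F", condition="hypoxia") -> pd.DataFrame:
    """Peak frame from (chrom, start, end, summit) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"])
    df["name"] = [f"p{i}" for i in range(len(df))]
    df["score"] = 0.0
    df["strand"] = "."
    df["factor"] = factor
    df["condition"] = condition
    return df[["chrom", "start", "end", "name", "score", "strand",
               "summit", "factor", "condition"]]


def random_peaks(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                 span: int = 200_000, factor="F") -> pd.DataFrame:
    summits = rng.integers(500, span, size=n)
    starts = summits - rng.integers(50, 300, size=n)
    ends = summits + rng.integers(50, 300, size=n) + 1
    return make_peaks(
        [(chroms[i % len(chroms)], s, e, m)
         for i, (s, e, m) in enumerate(zip(starts, ends, summits))],
        factor=factor)


def random_annotation(rng: np.random.Generator, n: int,
                      chroms=("chr1", "chr2"), span: int = 200_000,
                      ) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(n)],
        "chrom": [chroms[int(i)] for i in rng.integers(0, len(chroms), n)],
        "tss": rng.integers(0, span, size=n),
        "strand": [("+", "-")[int(i)] for i in rng.integers(0, 2, n)],
    })
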