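import numpy as np
import pytest

from scmimpute.binning import RegionMatrix


def region_matrix_from_values(values, context="CG", window_length=100) -> RegionMatrix:
    """Build a RegionMatrix on one synthetic chromosome; NaN entries become NA."""
    values = np.asarray(values, dtype=float)
    n, r = values.shape
    starts = np.arange(r, dtype=np.int64) * window_length
    return RegionMatrix(
        cell_ids=[f"c{i}" for i in range(n)],
        region_chrom=np.array(["chr1"] * r, dtype=object),
        region_start=starts,
        region_end=starts + window_length,
        values=values,
        mask=np.isnan(values),
        context=context,
        window_length=window_length,
    )


@pytest.fixture
def matrix_factory():
    return region_matrix_from_values


@pytest.fixture
def random_masked_matrix():
    """Random matrices in [0,1] with ~30% NA and no all-missing column."""

    def make(seed: int, n: int = 8, r: int = 12, na_frac: float = 0.3) -> RegionMatrix:
        rng = np.random.default_rng(seed)
        values = rng.random((n, r))
        mask = rng.random((n, r)) < na_frac
        for j in range(r):  # keep at least one observed value per column
            if mask[:, j].all():
                mask[rng.integers(n), j] = False
        values[mask] = np.nan
        return region_matrix_from_values(values)

    return make


@pytest.fixture
def allc_file(tmp_path):
    """Write allc-style rows (1-based positions) to a temp file."""

    def write(rows, name="cellA.tsv"):
        path = tmp_path / name
        with open(path, "wt") as fh:
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    return write
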