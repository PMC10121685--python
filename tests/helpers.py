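import numpy as np
import pandas as pd
from locifold.contact_core import ContactMatrix, GenomicBins


def make_matrix(n_bins: int, pixels, bin_size: int = 2000, chrom: str = "chrT",
                weights=None) -> ContactMatrix:
    """Small contact matrix from an iterable of (i, j, count)."""
    bins = GenomicBins.from_region(chrom, 0, n_bins * bin_size, bin_size)
    df = pd.DataFrame(pixels, columns=["bin1_id", "bin2_id", "count"])
    return ContactMatrix(bins, df, weights=weights)


def random_matrix(n_bins: int, rng: np.random.Generator, density: float = 0.2,
                  bin_size: int = 2000) -> ContactMatrix:
    """Random sparse upper-triangle matrix with Poisson-like counts."""
    iu, ju = np.triu_indices(n_bins)
    keep = rng.random(len(iu)) < density
    i, j = iu[keep], ju[keep]
    counts = rng.integers(1, 20, size=len(i)).astype(float)
    return make_matrix(n_bins, list(zip(i, j, counts)), bin_size=bin_size)


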