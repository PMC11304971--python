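import numpy as np
import pytest

from sexscaff.core import DepthTrack, RegionClass, Sex
from sexscaff import synthetic_data as sd


@pytest.fixture(scope="session")
def small_layout():
    """Five-class layout with a mixed X+PAR contig, used across modules."""
    return sd.generate_layout(
        {
            RegionClass.AUTOSOME: 3,
            RegionClass.HAPLOTYPE: 1,
            RegionClass.X: 1,
            RegionClass.Y: 1,
            RegionClass.PAR: 1,
        },
        length_range=(100_000, 200_000),
        window_size=10_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def mixture_tracks():
    """Pooled male-like depth windows: half at 50, near-half at 100, 5% outliers."""
    rng = np.random.default_rng(7)
    n = 4000
    d = np.concatenate(
        [
            rng.normal(50, 5, size=int(0.50 * n)),
            rng.normal(100, 7, size=int(0.45 * n)),
            rng.gamma(2.0, 1.0, size=int(0.025 * n)),  # near zero
            160 + rng.pareto(2.5, size=int(0.025 * n)) * 40,  # heavy tail
        ]
    )
    d = np.clip(d, 0, None)
    rng.shuffle(d)
    return [DepthTrack("mix", Sex.MALE, 10_000, d, base_depth=100.0)]


def make_track(depths, base=100.0, sex=Sex.MALE, contig="ctg", window=10_000):
    return DepthTrack(contig, sex, window, np.asarray(depths, dtype=float), base)
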