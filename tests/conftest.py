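import numpy as np
import pytest

from regkit.intervals import GenomicInterval
from regkit.methylation import MethylationModel
from regkit.motifs import PWM


@pytest.fixture
def separated_model():
    """Well-separated mixture: methylated sites convert ~4% of reads
    (bisulfite non-conversion error), unmethylated ~96% (conversion
    efficiency), plus a 10% undetermined fraction."""
    return MethylationModel(5.0, 120.0, 120.0, 5.0, (0.45, 0.45, 0.10))


@pytest.fixture
def simple_pwm():
    """An 8-column PWM with a mix of sharp and degenerate columns;
    consensus ACGTACGT."""
    counts = np.array(
        [
            [90, 4, 3, 3],
            [2, 88, 5, 5],
            [5, 5, 85, 5],
            [1, 1, 1, 97],
            [60, 20, 10, 10],
            [10, 60, 20, 10],
            [10, 10, 70, 10],
            [25, 25, 24, 26],
        ]
    )
    return PWM(id="TST0001", name="testTF", counts=counts)


def random_intervals(rng, n, contigs=("chr1", "chr2"), max_pos=1000, max_len=50):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(str(rng.choice(contigs)), start, start + length))
    return out
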