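import numpy as np
import pytest

import phylogap as pg


@pytest.fixture
def toy_pair():
    """The hand-counted worked pair: 3 matches, one gap each way."""
    a = pg.AlignedSeqRecord("a", "ACDE-")
    b = pg.AlignedSeqRecord("b", "ACD-F")
    return a, b


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_gapped_alignment(rng, n=6, length=40, gap_frac=0.15,
                            alphabet=pg.Alphabet.AMINO_ACID, divergence=0.25):
    """Rows mutated from a common base (moderate divergence, no saturation)
    with scattered gaps."""
    letters = alphabet.canonical
    base = rng.integers(0, len(letters), size=length)
    rows = []
    for i in range(n):
        codes = base.copy()
        mutate = rng.random(length) < divergence
        codes[mutate] = rng.integers(0, len(letters), size=int(mutate.sum()))
        chars = [letters[k] for k in codes]
        for j in np.nonzero(rng.random(length) < gap_frac)[0]:
            chars[j] = "-"
        rows.append(pg.AlignedSeqRecord(f"s{i+1}", "".join(chars), alphabet))
    return pg.Alignment(tuple(rows))
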