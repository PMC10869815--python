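import numpy as np
import pytest

import cbekit as ck


def binom_3sd(p: float, n: int) -> float:
    """Three binomial standard deviations of an observed fraction."""
    return 3.0 * np.sqrt(p * (1.0 - p) / n)


@pytest.fixture(scope="session")
def small_genome() -> ck.ReferenceSequence:
    return ck.make_genome(50_000, gc_fraction=0.45, seed=11)


@pytest.fixture(scope="session")
def amplicon_ref() -> ck.AmpliconReference:
    """A 90-bp amplicon with arms [5,20) and [60,75), window [19,61),
    and a sense TGG target codon at 30 (inside the window)."""
    rng = np.random.default_rng(42)
    bases = list(rng.choice(list("ACGT"), size=90))
    bases[30:33] = list("TGG")
    bases[25] = "C"  # a window cytosine used by edit fixtures
    bases[2] = "C"   # an outside-window cytosine used by flag fixtures
    return ck.AmpliconReference(
        id="amp1", sequence="".join(bases),
        left_arm=(5, 20), right_arm=(60, 75),
        target_codon_start=30, codon_strand="sense",
    )
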