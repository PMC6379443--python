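"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Seeded i.i.d. uniform A/C/G/T string."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def is_dna(seq: str) -> bool:
    """True iff seq is non-empty and drawn from the strict {A,C,G,T} alphabet."""
    return len(seq) > 0 and set(seq) <= set(BASES)
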