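"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: transition partner of each base (A<->G, C<->T); a transition pair is
#: never an A/T or G/C pair, which matters for speculative codon probes.
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def is_at_or_gc(a: str, b: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {G,C}."""
    pair = frozenset((a.upper(), b.upper()))
    return pair == frozenset("AT") or pair == frozenset("GC")
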