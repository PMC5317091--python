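import numpy as np
import pytest

from palcore import GenomeRecord


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.5,
                  circular: bool = True, gid: str = "rand") -> GenomeRecord:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join("ACGT"[i] for i in rng.choice(4, size=length, p=probs))
    return GenomeRecord(id=gid, sequence=seq, circular=circular)


def naive_mismatches(pattern_text: str, window: str) -> int:
    """Reference Hamming-with-wildcards distance, independent of the
    package's vectorized scanner."""
    return sum(
        1
        for p, c in zip(pattern_text.upper(), window.upper())
        if p != "N" and c != p
    )


def naive_scan(sequence: str, pattern_text: str, budget: int, circular: bool = True):
    """Reference per-window enumeration scanner: list of (start, mismatches)."""
    w = len(pattern_text)
    ext = sequence + sequence[: w - 1] if circular else sequence
    n = len(sequence) if circular else len(sequence) - w + 1
    out = []
    for i in range(n):
        mm = naive_mismatches(pattern_text, ext[i : i + w])
        if mm <= budget:
            out.append((i + 1, mm))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
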