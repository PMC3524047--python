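"""Default genome layout: 31 equine autosomes plus X, ~2,376 Mb total.

Lengths are rounded Mb approximations of the EquCab2.0 assembly; the total
matches the number of 1 Mb windows the window analysis tiles over the
genotyping panel's span.
"""

from __future__ import annotations

DEFAULT_CHROMOSOMES: list[tuple[str, int]] = [
    ("1", 187), ("2", 121), ("3", 119), ("4", 109), ("5", 101),
    ("6", 85), ("7", 99), ("8", 94), ("9", 85), ("10", 85),
    ("11", 61), ("12", 33), ("13", 43), ("14", 94), ("15", 92),
    ("16", 87), ("17", 81), ("18", 82), ("19", 60), ("20", 64),
    ("21", 58), ("22", 50), ("23", 56), ("24", 47), ("25", 40),
    ("26", 42), ("27", 40), ("28", 46), ("29", 34), ("30", 31),
    ("31", 26), ("X", 124),
]

AUTOSOMES = frozenset(str(i) for i in range(1, 32))


def total_mb(chromosomes=DEFAULT_CHROMOSOMES) -> int:
    return sum(length for _, length in chromosomes)


def is_autosome(label: str) -> bool:
    return str(label) in AUTOSOMES
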