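"""Synthetic labeled protein datasets with controllable class structure.

The generator emulates a two-class sequence pool distinguishable by
amino-acid composition bias: negatives are drawn i.i.d. from a background
residue distribution (uniform by default), while positives enrich a chosen
residue set — by default the hydrophobic class C, V, L, I, M, F, W — by an
effect size delta added to that set's total probability.  At delta = 0 the
two classes are exchangeable; larger delta makes them separable by any
composition-sensitive encoder.  Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .datasets import SamplePool
from .seq_io import CANONICAL_ALPHABET, Label, ProteinRecord

#: Average residue frequencies of well-characterized proteins (order
#: ACDEFGHIKLMNPQRSTVWY), for the natural-background option.
NATURAL_FREQUENCIES = np.array(
    [
        0.0825, 0.0138, 0.0546, 0.0672, 0.0386, 0.0707, 0.0228, 0.0591,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0394, 0.0553, 0.0665,
        0.0535, 0.0686, 0.0110, 0.0292,
    ]
)
NATURAL_FREQUENCIES /= NATURAL_FREQUENCIES.sum()


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-class dataset."""

    n_positive: int = 500
    n_negative: int = 500
    length_range: tuple[int, int] = (50, 300)
    delta: float = 0.3
    biased_residues: str = "CVLIMFW"
    seed: int = 0
    background: str = "uniform"  # or "natural"

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("need at least one record per class")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length range must satisfy 2 <= min <= max")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        bad = set(self.biased_residues) - set(CANONICAL_ALPHABET)
        if bad or not self.biased_residues:
            raise ValueError(f"biased residues must be canonical letters, got {bad}")
        if self.background not in ("uniform", "natural"):
            raise ValueError("background must be 'uniform' or 'natural'")

    def background_frequencies(self) -> np.ndarray:
        if self.background == "natural":
            return NATURAL_FREQUENCIES.copy()
        return np.full(20, 1 / 20)

    def positive_frequencies(self) -> np.ndarray:
        """Background with the biased set's total probability raised by delta."""
        p = self.background_frequencies()
        mask = np.array([aa in self.biased_residues for aa in CANONICAL_ALPHABET])
        base_total = p[mask].sum()
        target_total = base_total + self.delta
        if target_total >= 1.0:
            raise ValueError(
                f"delta {self.delta} pushes the biased set's probability to "
                f"{target_total:.3f} >= 1"
            )
        p[mask] *= target_total / base_total
        p[~mask] *= (1 - target_total) / (1 - base_total)
        return p


def _draw_sequences(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    freqs: np.ndarray,
    prefix: str,
    label: Label,
) -> list[ProteinRecord]:
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    alphabet = np.frombuffer(CANONICAL_ALPHABET.encode("ascii"), dtype=np.uint8)
    records = []
    width = max(4, len(str(n)))
    for i, L in enumerate(lengths, start=1):
        residues = rng.choice(alphabet, size=int(L), p=freqs)
        records.append(
            ProteinRecord(f"{prefix}{i:0{width}d}", residues.tobytes().decode("ascii"), label)
        )
    return records


def generate_dataset(spec: SyntheticSpec) -> SamplePool:
    """Generate a labeled SamplePool according to the spec, fully seeded."""
    rng = np.random.default_rng(spec.seed)
    positives = _draw_sequences(
        rng, spec.n_positive, spec.length_range, spec.positive_frequencies(),
        "POS", Label.POSITIVE,
    )
    negatives = _draw_sequences(
        rng, spec.n_negative, spec.length_range, spec.background_frequencies(),
        "NEG", Label.NEGATIVE,
    )
    return SamplePool(positives, negatives)


def write_labels_tsv(pool: SamplePool, path: str | Path) -> None:
    """Write an id -> label table alongside the FASTA exports."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for r in pool.positives + pool.negatives:
            fh.write(f"{r.id}\t{r.label.value}\n")
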