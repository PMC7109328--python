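"""Dataset protocol: redundancy reduction and repeated balanced undersampling.

The protocol mirrors a common treatment of highly imbalanced protein
classification pools: first remove redundant sequences at a 0.6 pairwise
identity threshold, then repeatedly (10x by default) draw a random negative
subset the size of the positive set to form a balanced training set, with
the leftover negatives of each repetition held out as that repetition's
test set.

Redundancy reduction defaults to a built-in greedy representative
clustering (an approximation of CD-HIT's algorithm); an adapter can shell
out to an external ``cd-hit`` executable when exact behaviour is required.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seq_io import Label, ProteinRecord, check_unique_ids, read_fasta, write_fasta

logger = logging.getLogger(__name__)

_KMER = 3  # word size for the shared-k-mer screen of the built-in filter


class ConfigurationError(RuntimeError):
    """Raised when an external tool is requested but unavailable."""


@dataclass
class SamplePool:
    """The positive and negative record pools of one classification problem."""

    positives: list[ProteinRecord]
    negatives: list[ProteinRecord]

    def __post_init__(self) -> None:
        check_unique_ids(self.positives + self.negatives)
        for r in self.positives:
            if r.label is not Label.POSITIVE:
                raise ValueError(f"record {r.id!r} in positives has label {r.label}")
        for r in self.negatives:
            if r.label is not Label.NEGATIVE:
                raise ValueError(f"record {r.id!r} in negatives has label {r.label}")

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_negative(self) -> int:
        return len(self.negatives)


@dataclass
class BalancedSplit:
    """One (train, test) realization from repeated undersampling.

    ``train`` holds all positives plus an equally sized random negative
    subset; ``test`` holds the remaining negatives.  Held-out evaluation on
    such a test set measures specificity on unseen negatives only.
    """

    repetition: int
    train: list[ProteinRecord]
    test: list[ProteinRecord]
    seed: int

    @property
    def train_positives(self) -> list[ProteinRecord]:
        return [r for r in self.train if r.label is Label.POSITIVE]

    @property
    def train_negatives(self) -> list[ProteinRecord]:
        return [r for r in self.train if r.label is Label.NEGATIVE]

    def manifest(self) -> dict:
        """JSON-serializable description (ids only) of this split."""
        return {
            "repetition": self.repetition,
            "seed": self.seed,
            "train_positive_ids": [r.id for r in self.train_positives],
            "train_negative_ids": [r.id for r in self.train_negatives],
            "test_ids": [r.id for r in self.test],
        }

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def derive_seed(seed: int, index: int) -> int:
    """Deterministic sub-seed for repetition ``index``, below 2**31.

    A multiplicative hash keeps sub-streams decorrelated across repetitions
    while remaining reproducible from the master seed alone.
    """
    mix = (int(seed) & 0xFFFFFFFF) * 0x9E3779B1 + (int(index) & 0xFFFFFFFF) * 0x85EBCA6B
    mix ^= mix >> 16
    return int(mix % (2**31 - 1))


def _ungapped_identity(a: str, b: str) -> float:
    """Best ungapped identity: matches / length of the shorter sequence.

    Candidate offsets are those suggested by shared k-mers (diagonal
    voting); the best diagonal's match count defines the identity.
    """
    if len(a) > len(b):
        a, b = b, a
    # k-mer positions in the longer sequence
    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for j in range(len(b) - _KMER + 1):
        kmer_pos[b[j : j + _KMER]].append(j)
    offsets: set[int] = set()
    for i in range(len(a) - _KMER + 1):
        for j in kmer_pos.get(a[i : i + _KMER], ()):
            offsets.add(j - i)
    if not offsets:
        return 0.0
    best = 0
    for off in offsets:
        matches = 0
        for i, ch in enumerate(a):
            j = i + off
            if 0 <= j < len(b) and b[j] == ch:
                matches += 1
        best = max(best, matches)
    return best / len(a)


def _reduce_builtin(
    records: Sequence[ProteinRecord], threshold: float
) -> list[ProteinRecord]:
    # Greedy incremental clustering in descending length order, keeping the
    # first (longest) member of each cluster as representative.
    order = sorted(range(len(records)), key=lambda i: (-records[i].length, i))
    reps: list[ProteinRecord] = []
    rep_kmers: dict[str, set[int]] = defaultdict(set)  # kmer -> rep indices
    for i in order:
        rec = records[i]
        candidates: set[int] = set()
        for p in range(rec.length - _KMER + 1):
            candidates |= rep_kmers.get(rec.sequence[p : p + _KMER], set())
        redundant = any(
            _ungapped_identity(rec.sequence, reps[c].sequence) >= threshold
            for c in candidates
        )
        if redundant:
            continue
        rep_idx = len(reps)
        reps.append(rec)
        for p in range(rec.length - _KMER + 1):
            rep_kmers[rec.sequence[p : p + _KMER]].add(rep_idx)
    # restore original input order for determinism of downstream steps
    kept = {r.id for r in reps}
    return [r for r in records if r.id in kept]


def _reduce_cdhit(
    records: Sequence[ProteinRecord], threshold: float, executable: str
) -> list[ProteinRecord]:
    exe = shutil.which(executable)
    if exe is None:
        raise ConfigurationError(
            f"external clustering tool {executable!r} not found on PATH"
        )
    word = 4 if threshold >= 0.6 else 3  # cd-hit word-size rule for low thresholds
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        write_fasta(records, fin)
        subprocess.run(
            [exe, "-i", str(fin), "-o", str(fout), "-c", str(threshold), "-n", str(word)],
            check=True,
            capture_output=True,
        )
        by_id = {r.id: r for r in records}
        kept_ids = [r.id for r in read_fasta(fout)]
    kept = set(kept_ids)
    return [r for r in records if r.id in kept]


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    threshold: float = 0.6,
    method: str = "builtin",
    executable: str = "cd-hit",
) -> list[ProteinRecord]:
    """Remove sequences with pairwise identity >= ``threshold`` to a kept one.

    ``method='builtin'`` uses the greedy k-mer-screened ungapped filter;
    ``method='cdhit'`` delegates to an external CD-HIT binary; ``method='none'``
    returns the input unchanged.  Deterministic for fixed input order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    records = list(records)
    check_unique_ids(records)
    if method == "none":
        return records
    if method == "builtin":
        kept = _reduce_builtin(records, threshold)
    elif method == "cdhit":
        kept = _reduce_cdhit(records, threshold, executable)
    else:
        raise ValueError(f"unknown redundancy method {method!r}")
    logger.info(
        "reduce_redundancy(%s, %.2f): %d -> %d records",
        method,
        threshold,
        len(records),
        len(kept),
    )
    return kept


def make_balanced_splits(
    pool: SamplePool, repeats: int = 10, seed: int = 0
) -> list[BalancedSplit]:
    """Repeated random undersampling of negatives to match the positive count.

    Each repetition draws ``n_positive`` negatives without replacement using
    an independent sub-seed derived from ``seed``; the negatives not drawn
    form that repetition's test set.  Repetitions are independent, so a
    negative may appear in several training sets.
    """
    if pool.n_positive < 1:
        raise ValueError("pool has no positives")
    if pool.n_negative < pool.n_positive:
        raise ValueError(
            f"need at least as many negatives ({pool.n_negative}) as positives "
            f"({pool.n_positive}) for undersampling"
        )
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    splits: list[BalancedSplit] = []
    for rep in range(1, repeats + 1):
        sub_seed = derive_seed(seed, rep)
        rng = np.random.default_rng(sub_seed)
        chosen = np.sort(
            rng.choice(pool.n_negative, size=pool.n_positive, replace=False)
        )
        chosen_set = set(chosen.tolist())
        sampled = [pool.negatives[i] for i in chosen]
        held_out = [
            pool.negatives[i]
            for i in range(pool.n_negative)
            if i not in chosen_set
        ]
        split = BalancedSplit(
            repetition=rep,
            train=list(pool.positives) + sampled,
            test=held_out,
            seed=sub_seed,
        )
        assert len(split.train_negatives) == pool.n_positive
        assert len(split.test) == pool.n_negative - pool.n_positive
        splits.append(split)
    return splits
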