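"""The 188-dimensional sequence/physicochemical feature encoder.

The encoding combines 20 amino-acid-composition frequencies with 168
composition/transition/distribution (CTD) descriptors: for each of 8
physicochemical attributes the 20 residues are partitioned into 3 classes,
and per attribute the encoder emits

* 3 class-composition fractions (residues in class / L),
* 15 class-distribution values: for each class, the normalized 1-based chain
  position of the first occurrence and of the occurrences at the 25%, 50%,
  75% and 100% percentile ranks (r = ceil(q * m) over the m occurrences of
  the class); all five are 0 when the class is absent,
* 3 bivalent-transition frequencies: adjacent residue pairs whose classes
  are {1,2}, {1,3} and {2,3} in either order, divided by L - 1.

Total: 20 + 8 * (3 + 15 + 3) = 188 features, named F1..F188.  Every entry
lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seq_io import CANONICAL_ALPHABET, Label, ProteinRecord, check_unique_ids

N_FEATURES = 188
_QUANTILES = (0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class PropertyScheme:
    """A named 3-way partition of the 20 amino acids by a physicochemical attribute."""

    name: str
    class1: str
    class2: str
    class3: str

    def __post_init__(self) -> None:
        union = set(self.class1) | set(self.class2) | set(self.class3)
        total = len(self.class1) + len(self.class2) + len(self.class3)
        if union != set(CANONICAL_ALPHABET) or total != 20:
            raise ValueError(
                f"scheme {self.name!r}: classes must partition the 20 amino acids"
            )

    @property
    def classes(self) -> tuple[str, str, str]:
        return (self.class1, self.class2, self.class3)

    def class_index(self) -> np.ndarray:
        """Class (1, 2 or 3) of each residue, indexed by alphabet position."""
        idx = np.zeros(20, dtype=np.int8)
        for c, members in enumerate(self.classes, start=1):
            for aa in members:
                idx[CANONICAL_ALPHABET.index(aa)] = c
        return idx


#: The 8 built-in physicochemical partitions, in canonical row order.
PROPERTY_SCHEMES: tuple[PropertyScheme, ...] = (
    PropertyScheme("hydrophobicity", "RKEDQN", "GASTPHY", "CVLIMFW"),
    PropertyScheme("normalized_vdw_volume", "GASCTPD", "NVEQIL", "MHKFRYW"),
    PropertyScheme("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    PropertyScheme("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    PropertyScheme("charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
    PropertyScheme("surface_tension", "GQDNAHR", "KTSEC", "ILMFPWYV"),
    PropertyScheme("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
    PropertyScheme("solvent_accessibility", "ALFCGIVW", "RKQEND", "MPSTHY"),
)

_SCHEME_BY_NAME = {s.name: s for s in PROPERTY_SCHEMES}
_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}
_AA_LOOKUP = np.full(128, -1, dtype=np.int8)
for _aa, _i in _AA_INDEX.items():
    _AA_LOOKUP[ord(_aa)] = _i
@lru_cache(maxsize=64)
def _class_index_cached(scheme: PropertyScheme) -> np.ndarray:
    return scheme.class_index()


def get_scheme(name: str) -> PropertyScheme:
    """Look up a built-in property scheme by name."""
    try:
        return _SCHEME_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown property scheme {name!r}; known: {sorted(_SCHEME_BY_NAME)}"
        ) from None


def feature_names() -> list[str]:
    """The 188 canonical feature identifiers F1..F188, in frozen order."""
    return [f"F{i}" for i in range(1, N_FEATURES + 1)]


def describe_features() -> list[str]:
    """Human-readable description of each feature, aligned with feature_names()."""
    out = [f"aac_{aa}" for aa in CANONICAL_ALPHABET]
    for s in PROPERTY_SCHEMES:
        out += [f"{s.name}_comp{i}" for i in (1, 2, 3)]
        out += [
            f"{s.name}_dist{i}_{j}"
            for i in (1, 2, 3)
            for j in ("first", "q25", "q50", "q75", "q100")
        ]
        out += [f"{s.name}_trans{pair}" for pair in ("12", "13", "23")]
    return out


def _residue_indices(record: ProteinRecord) -> np.ndarray:
    idx = _AA_LOOKUP[np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)]
    # ProteinRecord guarantees canonical residues, so no -1 can appear.
    return idx.astype(np.intp)


def amino_acid_composition(record: ProteinRecord) -> np.ndarray:
    """Frequencies of the 20 amino acids (order ACDEFGHIKLMNPQRSTVWY)."""
    counts = np.bincount(_residue_indices(record), minlength=20)
    return counts / record.length


def class_composition(record: ProteinRecord, scheme: PropertyScheme) -> np.ndarray:
    """Fraction of residues in each of the scheme's three classes."""
    cls = _class_index_cached(scheme)[_residue_indices(record)]
    counts = np.bincount(cls, minlength=4)[1:4]
    return counts / record.length


def class_distribution(record: ProteinRecord, scheme: PropertyScheme) -> np.ndarray:
    """15 normalized positions: first and 25/50/75/100% occurrence per class.

    For class i with m occurrences at 1-based positions p_1 < ... < p_m the
    five entries are p_1/L and p_r/L with r = ceil(q*m) for q in
    {0.25, 0.5, 0.75, 1.0}; all zero when the class is absent.
    """
    cls = _class_index_cached(scheme)[_residue_indices(record)]
    L = record.length
    out = np.zeros(15)
    for i in (1, 2, 3):
        positions = np.flatnonzero(cls == i) + 1  # 1-based
        m = positions.size
        if m == 0:
            continue
        base = (i - 1) * 5
        out[base] = positions[0] / L
        for j, q in enumerate(_QUANTILES, start=1):
            r = int(np.ceil(q * m))
            out[base + j] = positions[r - 1] / L
    return out


def class_transition(record: ProteinRecord, scheme: PropertyScheme) -> np.ndarray:
    """Bivalent transition frequencies for class pairs {1,2}, {1,3}, {2,3}.

    Counts adjacent residue pairs whose classes differ, in either order,
    normalized by L - 1.
    """
    cls = _class_index_cached(scheme)[_residue_indices(record)]
    a, b = cls[:-1], cls[1:]
    diff = a != b
    # For differing classes the sum identifies the unordered pair:
    # 1+2=3, 1+3=4, 2+3=5.
    sums = (a + b)[diff]
    counts = np.bincount(sums, minlength=6)
    return counts[3:6] / (record.length - 1)


def encode_sequence(record: ProteinRecord) -> np.ndarray:
    """Encode one record into the 188-dimensional feature vector.

    Layout: F1-F20 amino-acid composition, then for each of the 8 property
    schemes in canonical order: 3 composition, 15 distribution, 3 transition.
    """
    parts = [amino_acid_composition(record)]
    for scheme in PROPERTY_SCHEMES:
        parts.append(class_composition(record, scheme))
        parts.append(class_distribution(record, scheme))
        parts.append(class_transition(record, scheme))
    vec = np.concatenate(parts)
    assert vec.shape == (N_FEATURES,)
    return vec


@dataclass
class FeatureMatrix:
    """An n x 188 feature matrix with row ids and optional class labels."""

    X: np.ndarray
    ids: list[str]
    labels: Optional[list[Label]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must be n x {N_FEATURES}")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("row count and id count differ")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("row ids must be unique")
        if self.labels is not None:
            if len(self.labels) != self.X.shape[0]:
                raise ValueError("label count and row count differ")
            self.labels = [Label(l) for l in self.labels]

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def y(self) -> np.ndarray:
        """Binary label vector (positive = 1, negative = 0)."""
        if self.labels is None:
            raise ValueError("matrix carries no labels")
        if any(l is Label.UNLABELED for l in self.labels):
            raise ValueError("matrix contains unlabeled rows")
        return np.array([1 if l is Label.POSITIVE else 0 for l in self.labels])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=feature_names())
        df.insert(0, "id", self.ids)
        if self.labels is not None:
            df.insert(1, "label", [l.value for l in self.labels])
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = (
            [Label(v) for v in df["label"]] if "label" in df.columns else None
        )
        X = df[feature_names()].to_numpy(dtype=float)
        return cls(X, list(df["id"].astype(str)), labels)

    def to_arff(self, path: str | Path, relation: str = "abcident188") -> None:
        """Write the matrix in ARFF, for interoperability with Weka."""
        with open(path, "w") as fh:
            fh.write(f"@RELATION {relation}\n\n")
            fh.write("@ATTRIBUTE id STRING\n")
            for name in feature_names():
                fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
            if self.labels is not None:
                fh.write("@ATTRIBUTE class {positive,negative,unlabeled}\n")
            fh.write("\n@DATA\n")
            for i, rid in enumerate(self.ids):
                row = ",".join(repr(v) for v in self.X[i])
                if self.labels is not None:
                    fh.write(f"{rid},{row},{self.labels[i].value}\n")
                else:
                    fh.write(f"{rid},{row}\n")


def encode_dataset(records: Sequence[ProteinRecord]) -> FeatureMatrix:
    """Encode records into a FeatureMatrix, preserving input order and labels."""
    if not records:
        raise ValueError("no records to encode")
    check_unique_ids(records)
    X = np.vstack([encode_sequence(r) for r in records])
    labels = [r.label for r in records]
    if all(l is Label.UNLABELED for l in labels):
        labels = None
    return FeatureMatrix(X, [r.id for r in records], labels)


def load_schemes_config(path: str | Path) -> tuple[PropertyScheme, ...]:
    """Load property schemes from a YAML config mapping name -> [class1, class2, class3].

    Intended for overriding or exporting the built-in partitions.
    """
    import yaml

    with open(path) as fh:
        raw: Mapping[str, Sequence[str]] = yaml.safe_load(fh)
    return tuple(PropertyScheme(name, *classes) for name, classes in raw.items())
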