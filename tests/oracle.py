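"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the feature definitions directly — plain
string scanning and arithmetic, no code shared with the package — so that
agreement between the two routes is meaningful.
"""

import math

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# 3-way residue partitions per physicochemical attribute, typed out
# independently of the package's table.
SCHEMES = [
    ("hydrophobicity", ("RKEDQN", "GASTPHY", "CVLIMFW")),
    ("normalized_vdw_volume", ("GASCTPD", "NVEQIL", "MHKFRYW")),
    ("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    ("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    ("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    ("surface_tension", ("GQDNAHR", "KTSEC", "ILMFPWYV")),
    ("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    ("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MPSTHY")),
]


def oracle_encode(seq: str) -> list[float]:
    """Position-scanning 188-feature encoder: 20 AAC + per scheme 3 + 15 + 3."""
    L = len(seq)
    feats = [seq.count(aa) / L for aa in ALPHABET]
    for _name, classes in SCHEMES:
        cls_of = {}
        for ci, members in enumerate(classes, start=1):
            for aa in members:
                cls_of[aa] = ci
        for members in classes:
            feats.append(sum(1 for ch in seq if ch in members) / L)
        for ci in (1, 2, 3):
            positions = [i + 1 for i, ch in enumerate(seq) if cls_of[ch] == ci]
            if not positions:
                feats.extend([0.0] * 5)
                continue
            m = len(positions)
            feats.append(positions[0] / L)
            for q in (0.25, 0.50, 0.75, 1.00):
                feats.append(positions[math.ceil(q * m) - 1] / L)
        for pair in ({1, 2}, {1, 3}, {2, 3}):
            count = sum(
                1
                for i in range(L - 1)
                if cls_of[seq[i]] != cls_of[seq[i + 1]]
                and {cls_of[seq[i]], cls_of[seq[i + 1]]} == pair
            )
            feats.append(count / (L - 1))
    return feats


def oracle_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float, float]:
    """ACC/SN/SP/MCC straight from the defining ratios (0 when undefined)."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return acc, sn, sp, mcc


def oracle_auc_mannwhitney(scores, labels) -> float:
    """AUC as the tie-corrected Mann-Whitney statistic: mean over all
    (positive, negative) pairs of 1 if the positive scores higher, 0.5 on ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
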