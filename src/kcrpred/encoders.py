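"""Fixed-length feature encodings of lysine-centred peptide windows.

Seven sequence-based encoders are provided, each mapping a 31-mer window to a
named numeric vector:

========  ====  =======================================================
encoder    dim  content
========  ====  =======================================================
AAC         20  residue frequencies over the window
AAPC       400  ordered dipeptide frequencies
BE         620  per-position one-hot (31 x 20)
CKSAAP    1600  k-spaced residue-pair frequencies, k = 1..4
EAAC       540  residue frequencies in 27 sliding 5-mers
EGAAC      135  5-group frequencies in the same 27 sliding 5-mers
PSSM       620  sigmoid-normalized position-specific scores (kcrpred.pssm)
========  ====  =======================================================

Their concatenation ("incorporated") is 3935-dimensional.  Residue order is
alphabetic one-letter code 'ACDEFGHIKLMNPQRSTVWY' throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from kcrpred.dataprep import CANONICAL, PeptideWindow

#: The 20 canonical residues in the fixed alphabetic order used everywhere.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Ordered residue pairs 'AA', 'AC', ..., 'YY' (first residue major).
AA_PAIRS = ["".join(p) for p in product(AMINO_ACIDS, repeat=2)]

#: Default physicochemical grouping for EGAAC: g1 aliphatic, g2 aromatic,
#: g3 positively charged, g4 negatively charged, g5 uncharged/polar.
DEFAULT_GROUPS: dict[str, str] = {
    "g1": "GAVLMI",
    "g2": "FYW",
    "g3": "KRH",
    "g4": "DE",
    "g5": "STCPNQ",
}

GROUP_DESCRIPTIONS = {
    "g1": "aliphatic",
    "g2": "aromatic",
    "g3": "positively charged",
    "g4": "negatively charged",
    "g5": "uncharged",
}


class EncodingError(ValueError):
    """Raised on invalid windows or encoder parameters."""


@dataclass
class FeatureVector:
    """Named numeric feature vector produced by one encoder."""

    values: np.ndarray
    names: list[str]
    encoder_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise EncodingError(
                f"{self.encoder_id}: {len(self.values)} values vs {len(self.names)} names"
            )

    def __len__(self) -> int:
        return len(self.values)


def _sequence_of(window) -> str:
    seq = window.sequence if isinstance(window, PeptideWindow) else str(window)
    bad = set(seq) - CANONICAL
    if bad:
        raise EncodingError(f"nonstandard residues {sorted(bad)} in window {seq!r}")
    if len(seq) % 2 == 0 or seq[len(seq) // 2] != "K":
        raise EncodingError(f"window {seq!r} is not an odd-length lysine-centred peptide")
    return seq


def _pos_label(offset: int) -> str:
    return f"pos{offset:+d}" if offset else "pos0"


def encode_aac(window) -> FeatureVector:
    """Amino-acid composition: frequency of each residue over the window."""
    seq = _sequence_of(window)
    vals = np.zeros(20)
    for c in seq:
        vals[_AA_INDEX[c]] += 1
    vals /= len(seq)
    return FeatureVector(vals, [f"AAC:{a}" for a in AMINO_ACIDS], "AAC")


def encode_aapc(window, mode: str = "adjacent") -> FeatureVector:
    """Amino-acid pair composition (400 ordered dipeptide frequencies).

    ``mode='adjacent'`` (default) counts the n-1 adjacent ordered dipeptides
    and divides by n-1.  ``mode='all_pairs'`` counts every ordered position
    pair (i != j, any separation) and divides by n(n-1).  Both sum to 1.
    """
    seq = _sequence_of(window)
    n = len(seq)
    vals = np.zeros(400)
    if mode == "adjacent":
        for i in range(n - 1):
            vals[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + 1]]] += 1
        vals /= n - 1
    elif mode == "all_pairs":
        counts = np.zeros(20)
        for c in seq:
            counts[_AA_INDEX[c]] += 1
        # ordered pairs of distinct positions: c_a * c_b for a != b residues,
        # c_a * (c_a - 1) on the diagonal
        vals = np.outer(counts, counts).ravel()
        for a in range(20):
            vals[a * 20 + a] = counts[a] * (counts[a] - 1)
        vals /= n * (n - 1)
    else:
        raise EncodingError(f"unknown AAPC mode {mode!r}")
    return FeatureVector(
        vals, [f"AAPC:{p}" for p in AA_PAIRS], "AAPC", metadata={"mode": mode}
    )


def encode_be(window) -> FeatureVector:
    """Binary (one-hot) encoding: 20 indicator bits per position, N- to C-."""
    seq = _sequence_of(window)
    n = (len(seq) - 1) // 2
    vals = np.zeros(20 * len(seq))
    names: list[str] = []
    for i, c in enumerate(seq):
        vals[i * 20 + _AA_INDEX[c]] = 1.0
        names.extend(f"BE:{_pos_label(i - n)}:{a}" for a in AMINO_ACIDS)
    return FeatureVector(vals, names, "BE")


def encode_cksaap(window, k_min: int = 1, k_max: int = 4, normalize: bool = True) -> FeatureVector:
    """Composition of k-spaced amino-acid pairs.

    For each gap k in ``k_min..k_max`` the ordered pairs (position i,
    position i+k+1) are counted; each 400-entry block is divided by its pair
    count n-k-1 (set ``normalize=False`` for raw counts).
    """
    seq = _sequence_of(window)
    n = len(seq)
    if not 1 <= k_min <= k_max:
        raise EncodingError(f"require 1 <= k_min <= k_max, got {k_min}, {k_max}")
    if n - k_max - 1 < 1:
        raise EncodingError(f"window of length {n} too short for k_max={k_max}")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for k in range(k_min, k_max + 1):
        block = np.zeros(400)
        for i in range(n - k - 1):
            block[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + k + 1]]] += 1
        if normalize:
            block /= n - k - 1
        blocks.append(block)
        names.extend(f"CKSAAP:k={k}:{p}" for p in AA_PAIRS)
    return FeatureVector(
        np.concatenate(blocks), names, "CKSAAP", metadata={"normalized": normalize}
    )


def encode_eaac(window, subwindow: int = 5) -> FeatureVector:
    """Enhanced AAC: residue frequencies in each sliding 5-mer sub-window.

    Only full sub-windows are used (31 - 5 + 1 = 27 of them), numbered by
    1-based start position.
    """
    seq = _sequence_of(window)
    if subwindow > len(seq):
        raise EncodingError(f"subwindow {subwindow} exceeds window length {len(seq)}")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for s in range(len(seq) - subwindow + 1):
        block = np.zeros(20)
        for c in seq[s : s + subwindow]:
            block[_AA_INDEX[c]] += 1
        blocks.append(block / subwindow)
        names.extend(f"EAAC:win{s + 1}:{a}" for a in AMINO_ACIDS)
    return FeatureVector(
        np.concatenate(blocks), names, "EAAC", metadata={"subwindow": subwindow}
    )


def _validate_grouping(grouping: Mapping[str, str]) -> dict[str, str]:
    seen: set[str] = set()
    for residues in grouping.values():
        overlap = seen & set(residues)
        if overlap:
            raise EncodingError(f"grouping is not disjoint: {sorted(overlap)}")
        seen |= set(residues)
    if seen != set(AMINO_ACIDS) or len(grouping) != 5:
        raise EncodingError("grouping must partition the 20 residues into exactly 5 groups")
    return dict(grouping)


def encode_egaac(
    window, subwindow: int = 5, grouping: Mapping[str, str] | None = None
) -> FeatureVector:
    """Enhanced grouped AAC: 5-group frequencies in each sliding 5-mer.

    The default grouping is by physicochemical class (aliphatic, aromatic,
    positively charged, negatively charged, uncharged); any disjoint covering
    5-group mapping may be supplied instead.
    """
    grouping = _validate_grouping(DEFAULT_GROUPS if grouping is None else grouping)
    seq = _sequence_of(window)
    if subwindow > len(seq):
        raise EncodingError(f"subwindow {subwindow} exceeds window length {len(seq)}")
    group_of = {res: g for g, residues in grouping.items() for res in residues}
    group_names = list(grouping)
    gidx = {g: i for i, g in enumerate(group_names)}
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for s in range(len(seq) - subwindow + 1):
        block = np.zeros(len(group_names))
        for c in seq[s : s + subwindow]:
            block[gidx[group_of[c]]] += 1
        blocks.append(block / subwindow)
        names.extend(f"EGAAC:win{s + 1}:{g}" for g in group_names)
    return FeatureVector(
        np.concatenate(blocks), names, "EGAAC", metadata={"subwindow": subwindow}
    )


#: Concatenation order of the incorporated feature.
INCORPORATED_ORDER = ("aac", "aapc", "be", "cksaap", "eaac", "egaac", "pssm")

_SIMPLE_ENCODERS: dict[str, Callable] = {
    "aac": encode_aac,
    "aapc": encode_aapc,
    "be": encode_be,
    "cksaap": encode_cksaap,
    "eaac": encode_eaac,
    "egaac": encode_egaac,
}


def encode_incorporated(
    window, pssm_vector: FeatureVector | None = None, no_pssm: bool = False
) -> FeatureVector:
    """Concatenate all encoders: AAC+AAPC+BE+CKSAAP+EAAC+EGAAC+PSSM = 3935.

    ``pssm_vector`` is the 620-dim PSSM feature from :mod:`kcrpred.pssm`;
    with ``no_pssm=True`` the PSSM block is omitted (3315 dims).
    """
    parts = [_SIMPLE_ENCODERS[name](window) for name in INCORPORATED_ORDER[:-1]]
    if no_pssm:
        if pssm_vector is not None:
            raise EncodingError("pssm_vector supplied together with no_pssm=True")
    else:
        if pssm_vector is None:
            raise EncodingError("incorporated encoding requires a PSSM vector (or no_pssm=True)")
        if len(pssm_vector) != 620:
            raise EncodingError(f"PSSM vector must have 620 entries, got {len(pssm_vector)}")
        parts.append(pssm_vector)
    values = np.concatenate([p.values for p in parts])
    names = [n for p in parts for n in p.names]
    return FeatureVector(values, names, "incorporated", metadata={"no_pssm": no_pssm})


def encode_windows(
    windows: Sequence[PeptideWindow],
    encoders: Sequence[str] = ("egaac",),
    pssm_provider: Callable[[PeptideWindow], FeatureVector] | None = None,
    aapc_mode: str = "adjacent",
) -> pd.DataFrame:
    """Encode windows into a feature matrix (rows = windows).

    The DataFrame carries key columns ``protein_id``, ``center_pos``,
    ``label`` followed by one column per feature dimension.  ``encoders`` is a
    list drawn from ``aac, aapc, be, cksaap, eaac, egaac, pssm,
    incorporated``; ``pssm`` and ``incorporated`` need a ``pssm_provider``
    (e.g. from :class:`kcrpred.pssm.InternalProfileModel`).
    """
    rows: list[np.ndarray] = []
    names: list[str] | None = None
    for w in windows:
        parts: list[FeatureVector] = []
        for enc in encoders:
            if enc == "pssm":
                if pssm_provider is None:
                    raise EncodingError("encoder 'pssm' requires a pssm_provider")
                parts.append(pssm_provider(w))
            elif enc == "incorporated":
                vec = None if pssm_provider is None else pssm_provider(w)
                parts.append(encode_incorporated(w, vec, no_pssm=pssm_provider is None))
            elif enc == "aapc":
                parts.append(encode_aapc(w, mode=aapc_mode))
            elif enc in _SIMPLE_ENCODERS:
                parts.append(_SIMPLE_ENCODERS[enc](w))
            else:
                raise EncodingError(f"unknown encoder {enc!r}")
        row_names = [n for p in parts for n in p.names]
        if names is None:
            names = row_names
        elif row_names != names:
            raise EncodingError("inconsistent feature columns across windows")
        rows.append(np.concatenate([p.values for p in parts]))
    if names is None:
        names = []
    df = pd.DataFrame(np.array(rows).reshape(len(rows), len(names)), columns=names)
    df.insert(0, "label", [1 if w.is_positive else 0 for w in windows])
    df.insert(0, "center_pos", [w.center_pos for w in windows])
    df.insert(0, "protein_id", [w.protein_id for w in windows])
    return df


KEY_COLUMNS = ["protein_id", "center_pos", "label"]


def matrix_features(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature matrix DataFrame into (X, y, feature names)."""
    names = [c for c in df.columns if c not in KEY_COLUMNS]
    X = df[names].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=int)
    return X, y, names
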