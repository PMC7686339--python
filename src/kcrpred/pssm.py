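"""Position-specific scoring matrix (PSSM) features for peptide windows.

A window's PSSM feature is a 31x20 matrix of per-position, per-residue
substitution scores, squashed entrywise through a logistic function
Phi(S) = 1 / (1 + exp(-S / w)) with scale w = 31, then flattened row-major
(position-major) into a 620-dim vector.

Scores come either from a PSI-BLAST ASCII profile of the parent protein
(``-out_ascii_pssm`` output; we read the first, log-odds, score block) or —
when no PSI-BLAST output is available — from an internal log-odds table
estimated from positive training windows against the corpus background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from kcrpred.dataprep import PeptideWindow
from kcrpred.encoders import AMINO_ACIDS, FeatureVector, _AA_INDEX

#: Residue column order of PSI-BLAST ASCII PSSM files.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"
_PSIBLAST_TO_ALPHA = [PSIBLAST_ORDER.index(a) for a in AMINO_ACIDS]


class PSSMError(ValueError):
    """Raised on malformed profiles or out-of-range windows."""


@dataclass
class PSSMProfile:
    """31x20 score matrix for one window (columns in alphabetic order)."""

    matrix: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise PSSMError(f"profile must be L x 20, got shape {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise PSSMError("profile contains non-finite scores")


def parse_psiblast_ascii(path) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM into an L x 20 log-odds array
    (columns reordered to the alphabetic residue order)."""
    rows: list[list[float]] = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not header_seen:
                # header line: 20 or 40 single-letter residue codes
                if len(fields) >= 20 and all(f in PSIBLAST_ORDER for f in fields[:20]):
                    if fields[:20] != list(PSIBLAST_ORDER):
                        raise PSSMError(f"{path}: unexpected residue column order")
                    header_seen = True
                continue
            if len(fields) < 22 or not fields[0].isdigit():
                continue
            try:
                rows.append([float(v) for v in fields[2:22]])
            except ValueError as exc:
                raise PSSMError(f"{path}: bad score row at position {fields[0]}") from exc
    if not header_seen or not rows:
        raise PSSMError(f"{path}: not a PSI-BLAST ASCII PSSM")
    raw = np.array(rows)
    return raw[:, _PSIBLAST_TO_ALPHA]


def read_psiblast_pssm(path, center_pos: int, n: int = 15) -> PSSMProfile:
    """Extract the (2n+1)-row window profile around a 1-based center position.

    The window [center-n, center+n] must lie inside the protein profile.
    """
    scores = parse_psiblast_ascii(path)
    length = scores.shape[0]
    if center_pos - n < 1 or center_pos + n > length:
        raise PSSMError(
            f"window [{center_pos - n}, {center_pos + n}] outside profile of length {length}"
        )
    return PSSMProfile(scores[center_pos - 1 - n : center_pos + n], source="psiblast_file")


def sigmoid_normalize(S, w: float = 31.0):
    """Logistic squashing Phi(S) = 1 / (1 + exp(-S/w)); elementwise on arrays."""
    arr = np.asarray(S, dtype=float)
    out = 1.0 / (1.0 + np.exp(-arr / w))
    return float(out) if out.ndim == 0 else out


def profile_feature(profile: PSSMProfile, w: float = 31.0) -> FeatureVector:
    """Sigmoid-normalize a window profile and flatten it position-major into
    the 620-dim PSSM feature vector."""
    mat = sigmoid_normalize(profile.matrix, w=w)
    n = (mat.shape[0] - 1) // 2
    names = [
        f"PSSM:pos{i - n:+d}:{a}" if i != n else f"PSSM:pos0:{a}"
        for i in range(mat.shape[0])
        for a in AMINO_ACIDS
    ]
    return FeatureVector(mat.ravel(), names, "PSSM", metadata={"source": profile.source, "w": w})


def row_summed_feature(profile: PSSMProfile, window, w: float = 31.0) -> FeatureVector:
    """400-dim variant: rows of the window profile sharing the same observed
    residue type are summed into a 20x20 matrix before normalization.

    Kept behind this explicit call; the 620-dim flattened profile is the
    canonical feature.
    """
    seq = window.sequence if isinstance(window, PeptideWindow) else str(window)
    if len(seq) != profile.matrix.shape[0]:
        raise PSSMError("window length does not match profile rows")
    summed = np.zeros((20, 20))
    for i, res in enumerate(seq):
        summed[_AA_INDEX[res]] += profile.matrix[i]
    mat = sigmoid_normalize(summed, w=w)
    names = [f"PSSM20:{a}:{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    return FeatureVector(mat.ravel(), names, "PSSM20", metadata={"source": profile.source})


class InternalProfileModel:
    """Log-odds substitution table estimated from positive training windows.

    For window position i and residue j,

        S(i, j) = log2( p_ij / q_j ),   p_ij = (c_ij + a) / (N + 20 a),

    with pseudo-count a = 1, c_ij the count of residue j at position i over
    the N positive windows, and q_j the (equally smoothed) overall residue
    frequency of the whole training corpus.  A window's profile is the table
    masked by its observed residues: entry (i, j) is S(i, j) where the window
    carries residue j at position i and 0 elsewhere, so that windows matching
    positionally enriched residues score high.
    """

    def __init__(
        self,
        positive_windows: Sequence,
        background_windows: Sequence | None = None,
        pseudo: float = 1.0,
    ) -> None:
        seqs = [w.sequence if isinstance(w, PeptideWindow) else str(w) for w in positive_windows]
        if not seqs:
            raise PSSMError("internal profile needs at least one positive training window")
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise PSSMError("training windows must share one length")
        bg_pool = positive_windows if background_windows is None else background_windows
        bg_seqs = [w.sequence if isinstance(w, PeptideWindow) else str(w) for w in bg_pool]

        counts = np.zeros((length, 20))
        for s in seqs:
            for i, c in enumerate(s):
                counts[i, _AA_INDEX[c]] += 1
        n = len(seqs)
        p = (counts + pseudo) / (n + 20 * pseudo)

        bg_counts = np.zeros(20)
        for s in bg_seqs:
            for c in s:
                bg_counts[_AA_INDEX[c]] += 1
        q = (bg_counts + pseudo) / (bg_counts.sum() + 20 * pseudo)

        self.length = length
        self.pseudo = pseudo
        self.table = np.log2(p / q)

    def table_profile(self) -> PSSMProfile:
        """The shared log-odds table itself, as a profile."""
        return PSSMProfile(self.table.copy(), source="internal_fallback")

    def profile_for(self, window) -> PSSMProfile:
        """Window-specific profile: table scores at observed residues, else 0."""
        seq = window.sequence if isinstance(window, PeptideWindow) else str(window)
        if len(seq) != self.length:
            raise PSSMError(f"window length {len(seq)} != profile length {self.length}")
        mat = np.zeros((self.length, 20))
        for i, c in enumerate(seq):
            j = _AA_INDEX[c]
            mat[i, j] = self.table[i, j]
        return PSSMProfile(mat, source="internal_fallback")

    def feature_for(self, window, w: float = 31.0) -> FeatureVector:
        """The 620-dim sigmoid-normalized PSSM feature for one window."""
        return profile_feature(self.profile_for(window), w=w)


def build_internal_profile(
    positive_windows: Sequence, background_windows: Sequence | None = None, pseudo: float = 1.0
) -> InternalProfileModel:
    """Convenience constructor for :class:`InternalProfileModel`."""
    return InternalProfileModel(positive_windows, background_windows, pseudo=pseudo)
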