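"""Dataset preparation: FASTA + site annotations to labelled peptide windows.

A modification-site predictor is trained on fixed-length peptide windows
centred on lysine (K) residues.  Windows centred on experimentally verified
crotonylation sites are positives; all other lysine-centred windows from the
same proteins are negatives.  This module reads sequences and annotations,
builds (2n+1)-mer windows (default n=15, i.e. 31-mers), removes homologous
proteins with a greedy clustering surrogate for CD-HIT, splits train/test and
balances classes by random undersampling.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from Bio import Align, SeqIO

logger = logging.getLogger(__name__)

#: Canonical residue alphabet, alphabetic order.
CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / nonstandard letters whose presence invalidates a window.
UNCERTAIN = set("BJOUXZ")

POSITIVE = "positive"
NEGATIVE = "negative"


class DataPrepError(ValueError):
    """Raised for malformed inputs or invalid parameters."""


@dataclass
class AnnotatedProtein:
    """A protein sequence plus its 1-based Kcr-positive lysine positions."""

    id: str
    sequence: str
    positive_sites: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def residue(self, pos: int) -> str:
        """Residue at a 1-based position."""
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class PeptideWindow:
    """A (2n+1)-mer centred on a lysine, with label and provenance."""

    sequence: str
    label: str
    protein_id: str
    center_pos: int

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE

    @property
    def n(self) -> int:
        return (len(self.sequence) - 1) // 2


@dataclass
class SplitDataset:
    train: list[PeptideWindow]
    test: list[PeptideWindow]
    seed: int


@dataclass
class RejectionReport:
    """Annotation rows that could not be attached, with reasons."""

    rejected: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, protein_id: str, position: int, reason: str) -> None:
        self.rejected.append((protein_id, position, reason))

    def __len__(self) -> int:
        return len(self.rejected)


def read_fasta(path) -> list[AnnotatedProtein]:
    """Read a FASTA file into :class:`AnnotatedProtein` records (no sites yet).

    Ids are the first whitespace-delimited token of each header; sequences are
    uppercased.  An empty file yields an empty list with a warning.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython names the offending record/line
        raise DataPrepError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return [AnnotatedProtein(id=rec.id, sequence=str(rec.seq)) for rec in records]


def read_annotations(path) -> list[tuple[str, int]]:
    """Read a two-column TSV of (protein_id, 1-based position).

    A header line is tolerated: a row whose second field is not an integer is
    skipped when it is the first row, rejected otherwise.
    """
    rows: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataPrepError(f"{path}:{lineno + 1}: expected 'protein_id<TAB>position'")
            try:
                pos = int(parts[1])
            except ValueError:
                if lineno == 0:  # header
                    continue
                raise DataPrepError(f"{path}:{lineno + 1}: position {parts[1]!r} is not an integer")
            rows.append((parts[0], pos))
    return rows


def attach_annotations(
    proteins: Sequence[AnnotatedProtein], table: Iterable[tuple[str, int]]
) -> tuple[list[AnnotatedProtein], RejectionReport]:
    """Attach (protein_id, position) site rows to their proteins.

    Rows pointing at an unknown protein, out-of-range position, or a
    non-lysine residue are collected in the returned
    :class:`RejectionReport`, never silently dropped.
    """
    by_id = {p.id: p for p in proteins}
    report = RejectionReport()
    for pid, pos in table:
        prot = by_id.get(pid)
        if prot is None:
            report.add(pid, pos, "unknown id")
            continue
        if not 1 <= pos <= len(prot.sequence):
            report.add(pid, pos, "position out of range")
            continue
        if prot.residue(pos) != "K":
            report.add(pid, pos, "not lysine")
            continue
        prot.positive_sites.add(pos)
    return list(proteins), report


def extract_windows(
    protein: AnnotatedProtein, n: int = 15, counts: dict | None = None
) -> list[PeptideWindow]:
    """Emit one labelled (2n+1)-mer per lysine with n clean residues each side.

    Lysines with an insufficient flank, or whose window contains an
    uncertain/nonstandard letter, are dropped; drop reasons are tallied into
    ``counts`` when a dict is supplied (keys ``short_flank``, ``uncertain``,
    ``emitted``).
    """
    seq = protein.sequence
    windows: list[PeptideWindow] = []
    if counts is None:
        counts = {}
    counts.setdefault("short_flank", 0)
    counts.setdefault("uncertain", 0)
    counts.setdefault("emitted", 0)
    for idx, res in enumerate(seq):  # idx 0-based
        if res != "K":
            continue
        pos = idx + 1
        if idx < n or idx + n >= len(seq):
            counts["short_flank"] += 1
            continue
        frag = seq[idx - n : idx + n + 1]
        if any(c not in CANONICAL for c in frag):
            counts["uncertain"] += 1
            continue
        label = POSITIVE if pos in protein.positive_sites else NEGATIVE
        windows.append(PeptideWindow(frag, label, protein.id, pos))
        counts["emitted"] += 1
    return windows


def _alignment_identity(a: str, b: str) -> float:
    """Global alignment identity: identical columns / alignment length."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / aln.length


def reduce_redundancy(
    proteins: Sequence[AnnotatedProtein],
    identity_threshold: float = 0.30,
    identity_fn: Callable[[str, str], float] | None = None,
    skip: bool = False,
) -> list[AnnotatedProtein]:
    """Greedy longest-first clustering; keep one representative per cluster.

    A protein joins the first retained representative whose pairwise global
    alignment identity is >= ``identity_threshold``; otherwise it becomes a
    new representative.  This is a simplified surrogate for CD-HIT at 30%
    (no word-filter heuristics).  Set ``skip=True`` for pre-clustered input.
    """
    if not 0 < identity_threshold <= 1:
        raise DataPrepError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    if skip:
        return list(proteins)
    if identity_fn is None:
        identity_fn = _alignment_identity
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    representatives: list[AnnotatedProtein] = []
    for prot in ordered:
        for rep in representatives:
            if identity_fn(rep.sequence, prot.sequence) >= identity_threshold:
                break
        else:
            representatives.append(prot)
    return representatives


def split_train_test(
    windows: Sequence[PeptideWindow],
    fraction: float = 0.8,
    seed: int = 0,
    by_protein: bool = False,
) -> SplitDataset:
    """Stratified random split of windows into train/test.

    Positives and negatives are split independently; train gets
    ``floor(fraction * class size)`` of each class.  With ``by_protein=True``
    whole proteins are assigned to one side (avoids homolog leakage between
    train and test; class balance then only approximate).
    """
    if not 0 < fraction < 1:
        raise DataPrepError(f"fraction must be in (0, 1), got {fraction}")
    pos = [w for w in windows if w.is_positive]
    neg = [w for w in windows if not w.is_positive]
    if len(pos) < 2 or len(neg) < 2:
        raise DataPrepError(
            f"need >=2 windows per class to split, got {len(pos)} positive / {len(neg)} negative"
        )
    rng = random.Random(seed)
    if by_protein:
        ids = sorted({w.protein_id for w in windows})
        rng.shuffle(ids)
        n_train = int(fraction * len(ids))
        train_ids = set(ids[:n_train])
        train = [w for w in windows if w.protein_id in train_ids]
        test = [w for w in windows if w.protein_id not in train_ids]
        return SplitDataset(train=train, test=test, seed=seed)
    train: list[PeptideWindow] = []
    test: list[PeptideWindow] = []
    for cls in (pos, neg):
        shuffled = cls[:]
        rng.shuffle(shuffled)
        k = int(fraction * len(cls))
        train.extend(shuffled[:k])
        test.extend(shuffled[k:])
    return SplitDataset(train=train, test=test, seed=seed)


def undersample(windows: Sequence[PeptideWindow], seed: int = 0) -> list[PeptideWindow]:
    """Balance classes by keeping all positives and an equal-size random
    sample of negatives.

    If negatives do not outnumber positives the input is returned unchanged
    (with a warning when positives are the majority).
    """
    pos = [w for w in windows if w.is_positive]
    neg = [w for w in windows if not w.is_positive]
    if not pos or not neg:
        raise DataPrepError("undersample needs at least one window in each class")
    if len(neg) <= len(pos):
        if len(neg) < len(pos):
            logger.warning(
                "negatives (%d) do not outnumber positives (%d); returning input unchanged",
                len(neg),
                len(pos),
            )
        return list(windows)
    rng = random.Random(seed)
    sampled = rng.sample(neg, len(pos))
    return pos + sampled


def write_windows(windows: Sequence[PeptideWindow], path) -> None:
    """Serialize windows as TSV: protein_id, center_pos, label, sequence."""
    with open(path, "w") as fh:
        fh.write("protein_id\tcenter_pos\tlabel\tsequence\n")
        for w in windows:
            fh.write(f"{w.protein_id}\t{w.center_pos}\t{w.label}\t{w.sequence}\n")


def read_windows(path) -> list[PeptideWindow]:
    """Read windows from the TSV written by :func:`write_windows`."""
    out: list[PeptideWindow] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise DataPrepError(f"{path}: missing window TSV header")
        for line in fh:
            if not line.strip():
                continue
            pid, pos, label, seq = line.rstrip("\n").split("\t")
            out.append(PeptideWindow(seq, label, pid, int(pos)))
    return out


def prepare_windows(
    proteins: Sequence[AnnotatedProtein],
    n: int = 15,
    cluster: bool = True,
    identity_threshold: float = 0.30,
) -> tuple[list[PeptideWindow], dict]:
    """Full preparation: redundancy reduction then window extraction.

    Returns the windows plus a report dict with drop tallies and counts.
    """
    kept = reduce_redundancy(proteins, identity_threshold, skip=not cluster)
    counts: dict = {}
    windows: list[PeptideWindow] = []
    for prot in kept:
        windows.extend(extract_windows(prot, n=n, counts=counts))
    counts["proteins_in"] = len(proteins)
    counts["proteins_kept"] = len(kept)
    counts["positives"] = sum(w.is_positive for w in windows)
    counts["negatives"] = sum(not w.is_positive for w in windows)
    return windows, counts
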