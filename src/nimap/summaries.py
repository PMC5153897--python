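"""Downstream products of an interference map.

Per-gene maxima/averages, safe read-length fractions, strict
positions-below counts, primer specificity reports, minimum-similarity
region finding, and the per-position length histogram.

The safe-read condition at position ``p`` with read length ``R`` is
``lss_max(p) <= R``: a read of length R mapping at p cannot be wholly
contained in a nuclear copy when the longest one-mismatch shared
subsequence covering p is no longer than the read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneAnnotation, Genome, NormalizedTarget, reverse_complement
from .interference import InterferenceMap, StartLengthProfile
from .match_engine import (
    BackgroundIndex,
    count_similar_occurrences,
    longest_onemm_extension,
)


@dataclass(frozen=True)
class PrimerReport:
    """Specificity report for one PCR primer against the background."""

    primer_id: str
    sequence: str
    n_similar_in_background: int
    primer_length: int
    lss_at_start: int
    n_positions_below: int
    pct_positions_below: float


def gene_summary(imap: InterferenceMap, annotations: list[GeneAnnotation],
                 average: str = "avg_track") -> pd.DataFrame:
    """Per-gene interference summary.

    For each annotation, ``max_*`` is the maximum of the corresponding
    max track over the gene's positions and ``avg_*`` the mean of the
    corresponding average track, reported to 1 decimal.  ``average`` may
    be set to ``"max_track"`` to average the max track instead.
    """
    if average not in ("avg_track", "max_track"):
        raise ValueError("average must be 'avg_track' or 'max_track'")
    L = imap.target_length
    rows = []
    for ann in annotations:
        try:
            pos = ann.positions0(L)
        except ValueError as exc:
            raise ValueError(f"annotation out of range: {exc}") from exc
        lcs_src = imap.lcs_avg if average == "avg_track" else imap.lcs_max
        lss_src = imap.lss_avg if average == "avg_track" else imap.lss_max
        rows.append(
            {
                "name": ann.name,
                "length": ann.length(L),
                "start": ann.start,
                "end": ann.end,
                "max_lcs": int(imap.lcs_max[pos].max()),
                "avg_lcs": round(float(lcs_src[pos].mean()), 1),
                "max_lss": int(imap.lss_max[pos].max()),
                "avg_lss": round(float(lss_src[pos].mean()), 1),
            }
        )
    return pd.DataFrame(rows)


def safe_fraction(imap: InterferenceMap, read_length: int) -> float:
    """Fraction of target positions where a read of ``read_length``
    bases escapes nuclear interference (``lss_max <= R``)."""
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    return float(np.mean(imap.lss_max <= read_length))


def positions_below(track, v) -> tuple[int, float]:
    """Count of positions with track value strictly below ``v`` and the
    corresponding percent of the track length, rounded to 2 decimals."""
    if v < 0:
        raise ValueError("threshold must be >= 0")
    track = np.asarray(track)
    count = int(np.count_nonzero(track < v))
    pct = round(100.0 * count / track.size, 2)
    return count, pct


def length_histogram(track) -> dict[int, int]:
    """Frequency distribution of per-position integer track values."""
    track = np.asarray(track)
    values = np.rint(track).astype(np.int64)
    counts = np.bincount(values)
    return {int(v): int(c) for v, c in enumerate(counts) if c > 0}


def _primer_query(target: Genome, start: int, strand: str, cap: int) -> str:
    """Target-strand sequence, 5'->3' from the primer's binding start,
    extended up to ``cap`` bases (wrapping when circular)."""
    L = len(target)
    circular = target.topology == "circular"
    s0 = start - 1
    if strand == "+":
        if circular:
            tiled = target.seq + target.seq[: cap - 1]
            return tiled[s0 : s0 + cap]
        return target.seq[s0 : s0 + cap]
    # reverse strand: read leftwards from s0 on the forward axis
    if circular:
        tiled = target.seq[-(cap - 1):] + target.seq if cap > 1 else target.seq
        seg = tiled[s0 : s0 + cap]  # forward window ending at s0 (shifted)
    else:
        lo = max(0, s0 - cap + 1)
        seg = target.seq[lo : s0 + 1]
    return reverse_complement(seg)


def evaluate_primer(primer_id: str, sequence: str, start: int, strand: str,
                    index: BackgroundIndex, imap: InterferenceMap,
                    target: Genome | NormalizedTarget,
                    budget: int = 1) -> PrimerReport:
    """Score a primer's nuclear specificity.

    ``start`` is the 1-based forward-strand coordinate of the primer's
    5' binding position: the leftmost bound base for a forward primer,
    the rightmost for a reverse primer (whose given sequence is the
    reverse complement of the forward-strand substring it covers).  The
    one-mismatch extension length is evaluated 5'->3' on the annealing
    strand, the direction in which an extension product grows.
    """
    if isinstance(target, NormalizedTarget):
        target = target.genome
    sequence = sequence.upper()
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    L = len(target)
    plen = len(sequence)
    cap = min(index.config.window, L)
    q = _primer_query(target, start, strand, cap)
    if q[:plen] != sequence:
        raise ValueError(
            f"primer {primer_id!r} does not match the target at position "
            f"{start} ({strand}); expected {q[:plen]!r}"
        )
    n_similar = count_similar_occurrences(index, sequence, budget)
    lss_at_start = longest_onemm_extension(index, q)
    n_below, pct = positions_below(imap.lss_max, lss_at_start)
    return PrimerReport(
        primer_id=primer_id,
        sequence=sequence,
        n_similar_in_background=n_similar,
        primer_length=plen,
        lss_at_start=lss_at_start,
        n_positions_below=n_below,
        pct_positions_below=pct,
    )


def find_min_regions(imap: InterferenceMap, window_len: int,
                     top_n: int = 10) -> list[dict]:
    """Rank length-``window_len`` target windows by how little nuclear
    similarity they carry.

    Windows (circular) are ordered ascending by (max lss_max within the
    window, mean lss_max, start position); the ``top_n`` returned windows
    are greedily chosen to be non-overlapping.
    """
    L = imap.target_length
    if not 1 <= window_len <= L:
        raise ValueError("window_len must be in 1..target_length")
    track = np.asarray(imap.lss_max, dtype=float)
    tiled = np.concatenate([track, track[: window_len - 1]])
    sw = np.lib.stride_tricks.sliding_window_view(tiled, window_len)[:L]
    wmax = sw.max(axis=1)
    wmean = sw.mean(axis=1)
    order = np.lexsort((np.arange(L), wmean, wmax))
    chosen: list[dict] = []
    covered = np.zeros(L, dtype=bool)
    for s0 in order:
        idx = (np.arange(s0, s0 + window_len)) % L
        if covered[idx].any():
            continue
        covered[idx] = True
        chosen.append(
            {
                "start": int(s0) + 1,
                "end": int((s0 + window_len - 1) % L) + 1,
                "max_lss": int(wmax[s0]),
                "mean_lss": float(wmean[s0]),
            }
        )
        if len(chosen) >= top_n:
            break
    return chosen
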