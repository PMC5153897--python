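"""Longest shared prefix search between a query and a windowed background.

The background (e.g. a nuclear genome) is conceptually decomposed into all
overlapping windows of length ``W`` on both strands, de-replicated with
occurrence multiplicities.  Queries ask for the longest prefix of a string
that occurs in the background within a mismatch budget of 0 (exact, "LCS")
or 1 ("LSS"), capped at ``W``.

Queries are answered from sentinel-separated encoded text arrays (one
forward and one reverse-complement copy per record) using a
Landau–Vishkin-style dynamic programme vectorized over all text offsets:
for each query column we maintain, per offset, the length of the exact
(and budget-1) extension beginning at that column.  Because every
background substring of length ``n <= W`` lies inside some window, this is
equivalent to searching the de-replicated window set.  The window multiset
itself is materialized lazily; it is only needed for multiplicity
accounting and occurrence counting semantics.

Two mismatch models are supported:

* ``substitution`` (default): Hamming distance at equal length.
* ``unit_edit``: Levenshtein distance <= 1, match length measured on the
  query side.

``N`` in either sequence never matches any base but may be consumed by the
mismatch budget.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from .genome_io import Genome, reverse_complement

# base encodings: background N and query N get distinct codes so they can
# never match each other while both remain budget-consumable.
_CODE_N_BG = 4
_CODE_N_Q = 5
_SENT = 6

_BG_LUT = np.full(256, _SENT, dtype=np.uint8)
_Q_LUT = np.full(256, _SENT, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _BG_LUT[ord(_c)] = _i
    _Q_LUT[ord(_c)] = _i
_BG_LUT[ord("N")] = _CODE_N_BG
_Q_LUT[ord("N")] = _CODE_N_Q

MISMATCH_MODELS = ("substitution", "unit_edit")


def encode_background(seq: str) -> np.ndarray:
    return _BG_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_query(seq: str) -> np.ndarray:
    return _Q_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class IndexConfig:
    """Window length and mismatch model of a background index."""

    window: int = 450
    mismatch_model: str = "substitution"

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window length must be >= 2")
        if self.mismatch_model not in MISMATCH_MODELS:
            raise ValueError(
                f"mismatch_model must be one of {MISMATCH_MODELS}"
            )


class BackgroundIndex:
    """Searchable window structure over a background genome set.

    Attributes
    ----------
    config : IndexConfig
    records : list of (id, length) for the indexed records.
    """

    def __init__(self, background: list[Genome], config: IndexConfig | None = None):
        if config is None:
            config = IndexConfig()
        if not background:
            raise ValueError("background must contain at least one record")
        self.config = config
        self.records = [(g.id, len(g)) for g in background]
        parts = []
        self._strand_seqs: list[str] = []
        for g in background:
            for s in (g.seq, reverse_complement(g.seq)):
                self._strand_seqs.append(s)
                parts.append(encode_background(s))
                parts.append(np.array([_SENT], dtype=np.uint8))
        self._text = np.concatenate(parts[:-1]) if parts else np.empty(0, np.uint8)
        self._windows: Counter | None = None

    # -- window multiset view -------------------------------------------------

    @property
    def windows(self) -> Counter:
        """De-replicated window multiset with occurrence multiplicities.

        Records shorter than ``W`` contribute their full length as a single
        window per strand.
        """
        if self._windows is None:
            W = self.config.window
            c: Counter = Counter()
            for s in self._strand_seqs:
                if len(s) <= W:
                    c[s] += 1
                else:
                    for i in range(len(s) - W + 1):
                        c[s[i : i + W]] += 1
            self._windows = c
        return self._windows

    @property
    def total_window_multiplicity(self) -> int:
        W = self.config.window
        return sum(2 * max(1, n - W + 1) for _, n in self.records)

    # -- core scan ------------------------------------------------------------

    def _scan(self, q: np.ndarray, model: str, collect_columns: bool = True):
        """Column dynamic programme over all text offsets.

        Returns (best0, best1, l0_rows, l1_rows): per-column maxima of the
        exact / budget-1 extension lengths starting at each query column,
        and the final per-row vectors for column 0.
        """
        n = q.size
        if n == 0:
            raise ValueError("empty query")
        pad = np.full(n, _SENT, dtype=np.uint8)
        T = np.concatenate([pad, self._text, pad])
        R = T.size - n + 1
        l0 = np.zeros(R, dtype=np.int32)
        l1 = np.zeros(R, dtype=np.int32)
        best0 = np.zeros(n, dtype=np.int64)
        best1 = np.zeros(n, dtype=np.int64)
        for i in range(n - 1, -1, -1):
            col = T[i : i + R]
            match = col == q[i]
            consumable = col < _CODE_N_Q  # real base or N, not a sentinel
            new_l0 = np.where(match, l0 + 1, 0).astype(np.int32)
            if model == "substitution":
                new_l1 = np.where(
                    match, l1 + 1, np.where(consumable, l0 + 1, 0)
                ).astype(np.int32)
            else:  # unit_edit: Landau–Vishkin with k=1
                sub = np.where(consumable, l0 + 1, 0)
                dele = np.empty_like(l0)
                dele[0] = 1
                dele[1:] = l0[:-1] + 1  # skip q[i]; text not consumed
                ins = np.zeros_like(l0)
                ins[:-1] = np.where(consumable[:-1], new_l0[1:], 0)
                cand = np.maximum(np.maximum(sub, dele), ins)
                new_l1 = np.where(match, l1 + 1, cand).astype(np.int32)
            l0, l1 = new_l0, new_l1
            if collect_columns:
                best0[i] = l0.max()
                best1[i] = l1.max()
        return best0, best1, l0, l1

    def extension_profiles(self, q: str | np.ndarray):
        """Per-start longest exact and budget-1 prefix match lengths.

        For every start ``s`` (0-based) of ``q``, returns the longest
        ``n`` such that ``q[s:s+n]`` occurs in the background within the
        budget, uncapped (caller applies the ``W``/topology caps).
        """
        qc = encode_query(q) if isinstance(q, str) else np.asarray(q, np.uint8)
        best0, best1, _, _ = self._scan(qc, self.config.mismatch_model)
        return best0, best1


def build_index(background: list[Genome], config: IndexConfig | None = None,
                **kwargs) -> BackgroundIndex:
    """Build a :class:`BackgroundIndex` (kwargs feed :class:`IndexConfig`)."""
    if config is None and kwargs:
        config = IndexConfig(**kwargs)
    return BackgroundIndex(background, config)


def _single_query(index: BackgroundIndex, q: str):
    if not q:
        raise ValueError("empty query")
    W = index.config.window
    q = q[:W]  # cap at window length
    qc = encode_query(q)
    best0, best1, _, _ = index._scan(qc, index.config.mismatch_model)
    return int(best0[0]), int(best1[0])


def longest_exact_extension(index: BackgroundIndex, q: str) -> int:
    """Longest prefix of ``q`` occurring exactly in the background
    (either strand), capped at the window length."""
    return _single_query(index, q)[0]


def longest_onemm_extension(index: BackgroundIndex, q: str) -> int:
    """Longest prefix of ``q`` within a 1-mismatch budget of some
    background substring (model per index config), capped at the window
    length.  Always >= :func:`longest_exact_extension`."""
    return _single_query(index, q)[1]


def count_similar_occurrences(index: BackgroundIndex, s: str,
                              max_mismatches: int) -> int:
    """Number of background locations (both strands, overlaps counted)
    whose length-``len(s)`` substring is within ``max_mismatches``
    substitutions of ``s``."""
    if not s:
        raise ValueError("empty query")
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    if len(s) > index.config.window:
        raise ValueError("query longer than window length")
    qc = encode_query(s)
    _, _, l0, l1 = index._scan(qc, "substitution", collect_columns=False)
    rows = l0 if max_mismatches == 0 else l1
    return int(np.count_nonzero(rows >= len(s)))


# -- independent brute-force oracle -------------------------------------------


def _oracle_substitution(strand_seqs: list[str], q: str):
    """Full scan of every offset of every strand; returns (L0, L1) under
    the Hamming model via cumulative mismatch counts."""
    qc = encode_query(q)
    n = qc.size
    best0 = best1 = 0
    for s in strand_seqs:
        B = np.concatenate(
            [encode_background(s), np.full(n, _SENT, dtype=np.uint8)]
        )
        sw = np.lib.stride_tricks.sliding_window_view(B, n)
        mm = sw != qc
        hard = sw == _SENT
        c_mm = np.cumsum(mm, axis=1)
        c_hard = np.cumsum(hard, axis=1)
        l0 = (c_mm == 0).sum(axis=1)
        l1 = ((c_mm <= 1) & (c_hard == 0)).sum(axis=1)
        best0 = max(best0, int(l0.max(initial=0)))
        best1 = max(best1, int(l1.max(initial=0)))
    return best0, best1


def _oracle_unit_edit(strand_seqs: list[str], q: str) -> int:
    """Longest prefix within Levenshtein distance 1 of some background
    substring, via edlib infix alignment (independent implementation).

    Background N is mapped to lowercase so that it can never match but is
    still consumable by an edit.
    """
    texts = [s.replace("N", "n") for s in strand_seqs]

    def within_one(m: int) -> bool:
        p = q[:m]
        return any(
            edlib.align(p, t, mode="HW", task="distance", k=1)["editDistance"]
            != -1
            for t in texts
        )

    lo, hi = 0, len(q)
    while lo < hi:  # largest m with within_one(m); predicate is monotone
        mid = (lo + hi + 1) // 2
        if within_one(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def oracle_longest_extension(background: list[Genome], q: str,
                             budget: int = 0,
                             model: str = "substitution") -> int:
    """Brute-force reference for the longest-extension queries.

    Scans every background offset on both strands with no index; intended
    for small backgrounds (~100 kb and below).
    """
    if not q:
        raise ValueError("empty query")
    if budget not in (0, 1):
        raise ValueError("budget must be 0 or 1")
    strand_seqs = []
    for g in background:
        strand_seqs.append(g.seq)
        strand_seqs.append(reverse_complement(g.seq))
    l0, l1 = _oracle_substitution(strand_seqs, q)
    if budget == 0:
        return l0
    if model == "substitution":
        return l1
    return _oracle_unit_edit(strand_seqs, q)


# -- serialization -------------------------------------------------------------


def save_index(index: BackgroundIndex, path) -> None:
    """Serialize an index to ``.npz`` (round-trips via :func:`load_index`)."""
    ids = [rid for rid, _ in index.records]
    lens = [n for _, n in index.records]
    np.savez_compressed(
        path,
        text=index._text,
        window=index.config.window,
        model=index.config.mismatch_model,
        record_ids=np.array(ids, dtype=object),
        record_lengths=np.array(lens, dtype=np.int64),
        strand_seqs=np.array(index._strand_seqs, dtype=object),
    )


def load_index(path) -> BackgroundIndex:
    dat = np.load(path, allow_pickle=True)
    idx = BackgroundIndex.__new__(BackgroundIndex)
    idx.config = IndexConfig(int(dat["window"]), str(dat["model"]))
    idx.records = list(
        zip([str(x) for x in dat["record_ids"]],
            [int(x) for x in dat["record_lengths"]])
    )
    idx._text = dat["text"]
    idx._strand_seqs = [str(s) for s in dat["strand_seqs"]]
    idx._windows = None
    return idx
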