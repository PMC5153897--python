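"""Per-start match profiles and per-position interference maps.

A *start profile* records, for every 1-based target position ``s``, the
length of the longest exact (``L0``, "LCS") and one-mismatch (``L1``,
"LSS") match of the target substring beginning at ``s`` against the
background, on either strand, wrapping past the origin for a circular
target and capped at the window length ``W``.

The *interference map* aggregates the profile into four per-position
tracks: a start ``s`` with ``L(s) >= 1`` covers positions
``s .. s+L(s)-1`` (modulo the target length when circular); for each
position the ``*_max`` track is the maximum covering length and the
``*_avg`` track the arithmetic mean of covering lengths (each start
counted once).  Positions covered by no start hold 0 in both tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import genome_io
from .genome_io import Genome, NormalizedTarget, normalize_target, restore_track
from .match_engine import (
    BackgroundIndex,
    IndexConfig,
    build_index,
    encode_query,
)


@dataclass
class StartLengthProfile:
    """Per-start longest exact (``l0``) and one-mismatch (``l1``) match
    lengths, as 0-based numpy arrays over target starts 1..L."""

    l0: np.ndarray
    l1: np.ndarray
    window: int
    topology: str
    capped_l0: bool = False
    capped_l1: bool = False

    def __len__(self) -> int:
        return len(self.l0)

    @property
    def capped(self) -> bool:
        return self.capped_l0 or self.capped_l1


@dataclass
class InterferenceMap:
    """Per-position max/average LCS and LSS tracks (1-based positions are
    array index + 1)."""

    lcs_max: np.ndarray
    lcs_avg: np.ndarray
    lss_max: np.ndarray
    lss_avg: np.ndarray
    target_length: int
    meta: dict = field(default_factory=dict)

    def track(self, name: str) -> np.ndarray:
        if name not in genome_io.TRACK_NAMES:
            raise ValueError(f"unknown track {name!r}")
        return getattr(self, name)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InterferenceMap):
            return NotImplemented
        return self.target_length == other.target_length and all(
            np.allclose(self.track(t), other.track(t))
            for t in genome_io.TRACK_NAMES
        )


def compute_start_profile(target: NormalizedTarget | Genome,
                          index: BackgroundIndex) -> StartLengthProfile:
    """Profile every target start against the background index.

    The target must be N-free (normalize first); circularity is handled
    by extending the query with the target's leading ``cap - 1`` bases.
    """
    g = target.genome if isinstance(target, NormalizedTarget) else target
    if "N" in g.seq:
        raise ValueError("target contains N; run normalize_target first")
    L = len(g)
    W = index.config.window
    circular = g.topology == "circular"
    cap = min(W, L)
    ext = g.seq + g.seq[: cap - 1] if circular else g.seq
    best0, best1 = index.extension_profiles(ext)
    if circular:
        allowed = np.full(L, cap, dtype=np.int64)
    else:
        allowed = np.minimum(W, L - np.arange(L))
    l0 = np.minimum(best0[:L], allowed)
    l1 = np.minimum(best1[:L], allowed)
    return StartLengthProfile(
        l0=l0,
        l1=l1,
        window=W,
        topology=g.topology,
        capped_l0=bool(np.any(l0 >= W)),
        capped_l1=bool(np.any(l1 >= W)),
    )


def _aggregate_track(lengths: np.ndarray, L: int, circular: bool):
    """Max and average covering length per position for one length track."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if len(lengths) != L:
        raise ValueError(f"profile length {len(lengths)} != target length {L}")
    starts = np.arange(L)
    active = lengths > 0
    s = starts[active]
    l = lengths[active]
    e = s + l  # exclusive 0-based end
    diff_cnt = np.zeros(L + 1, dtype=np.int64)
    diff_sum = np.zeros(L + 1, dtype=np.int64)
    wrap = e > L
    if np.any(wrap) and not circular:
        raise ValueError("linear profile extends past the target end")
    sn, ln, en = s[~wrap], l[~wrap], e[~wrap]
    np.add.at(diff_cnt, sn, 1)
    np.add.at(diff_cnt, en, -1)
    np.add.at(diff_sum, sn, ln)
    np.add.at(diff_sum, en, -ln)
    if np.any(wrap):
        sw, lw, ew = s[wrap], l[wrap], e[wrap] - L
        np.add.at(diff_cnt, sw, 1)
        np.add.at(diff_sum, sw, lw)
        np.add.at(diff_cnt, np.zeros_like(ew), 1)
        np.add.at(diff_cnt, ew, -1)
        np.add.at(diff_sum, np.zeros_like(ew), lw)
        np.add.at(diff_sum, ew, -lw)
    cnt = np.cumsum(diff_cnt[:L])
    tot = np.cumsum(diff_sum[:L])
    avg = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)
    mx = np.zeros(L, dtype=np.int64)
    for si, li in zip(s, l):
        ei = si + li
        if ei <= L:
            np.maximum(mx[si:ei], li, out=mx[si:ei])
        else:
            np.maximum(mx[si:], li, out=mx[si:])
            np.maximum(mx[: ei - L], li, out=mx[: ei - L])
    return mx, avg


def aggregate_map(profile: StartLengthProfile, target_length: int,
                  topology: str | None = None,
                  meta: dict | None = None) -> InterferenceMap:
    """Aggregate a start profile into per-position max/average tracks."""
    circular = (topology or profile.topology) == "circular"
    lcs_max, lcs_avg = _aggregate_track(profile.l0, target_length, circular)
    lss_max, lss_avg = _aggregate_track(profile.l1, target_length, circular)
    m = dict(meta or {})
    m.setdefault("window", profile.window)
    m.setdefault("capped", profile.capped)
    return InterferenceMap(lcs_max, lcs_avg, lss_max, lss_avg,
                           target_length, m)


class InterferenceMapper(BaseEstimator):
    """Background-to-target interference mapping as a fit/transform pair.

    ``fit`` indexes the background genomes; ``transform`` profiles a
    target genome and returns its :class:`InterferenceMap` in original
    coordinates (N positions restored).

    Parameters
    ----------
    window : int
        Background window length W; also the match-length cap.  If any
        per-start value reaches W and ``auto_rerun`` is set, the index is
        rebuilt with W doubled until uncapped (mirroring the stated
        re-run rule for an under-sized initial window).
    mismatch_model : "substitution" | "unit_edit"
    auto_rerun : bool
    max_reruns : int
    """

    def __init__(self, window: int = 450, mismatch_model: str = "substitution",
                 auto_rerun: bool = True, max_reruns: int = 8):
        self.window = window
        self.mismatch_model = mismatch_model
        self.auto_rerun = auto_rerun
        self.max_reruns = max_reruns

    def fit(self, X, y=None):
        """Index the background genomes (a list of :class:`Genome`)."""
        background = [X] if isinstance(X, Genome) else list(X)
        self.background_ = background
        self.index_ = build_index(
            background, IndexConfig(self.window, self.mismatch_model)
        )
        return self

    def profile(self, target: Genome | NormalizedTarget) -> StartLengthProfile:
        nt = target if isinstance(target, NormalizedTarget) else normalize_target(target)
        index = self.index_
        profile = compute_start_profile(nt, index)
        reruns = 0
        while (self.auto_rerun and profile.capped and reruns < self.max_reruns
               and index.config.window < len(nt.genome)):
            index = build_index(
                self.background_,
                IndexConfig(index.config.window * 2, self.mismatch_model),
            )
            profile = compute_start_profile(nt, index)
            reruns += 1
        self._last_index_ = index
        return profile

    def transform(self, target: Genome | NormalizedTarget) -> InterferenceMap:
        nt = target if isinstance(target, NormalizedTarget) else normalize_target(target)
        profile = self.profile(nt)
        imap = aggregate_map(profile, len(nt.genome))
        tracks = {
            name: restore_track(imap.track(name), nt)
            for name in genome_io.TRACK_NAMES
        }
        meta = {
            "target": nt.genome.id,
            "window": self._last_index_.config.window,
            "model": self.mismatch_model,
            "background": ",".join(rid for rid, _ in self.index_.records),
            "capped": profile.capped,
            "removed_positions": list(nt.removed_positions),
        }
        return InterferenceMap(
            tracks["lcs_max"], tracks["lcs_avg"],
            tracks["lss_max"], tracks["lss_avg"],
            nt.original_length, meta,
        )

    def fit_transform(self, X, y=None, *, target=None):
        if target is None:
            raise ValueError("fit_transform requires a target genome")
        return self.fit(X).transform(target)


def run_map(background, target, window: int = 450,
            mismatch_model: str = "substitution",
            auto_rerun: bool = True) -> InterferenceMap:
    """End-to-end map: normalize target, index background, profile,
    aggregate, restore.  ``background``/``target`` may be FASTA paths or
    Genome objects."""
    if isinstance(background, (str, bytes)) or hasattr(background, "__fspath__"):
        background = genome_io.read_fasta(background)
    if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
        target = genome_io.read_fasta(target, topology="circular")[0]
    mapper = InterferenceMapper(window=window, mismatch_model=mismatch_model,
                                auto_rerun=auto_rerun)
    return mapper.fit(background).transform(target)
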