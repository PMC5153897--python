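"""Genome, annotation and track input/output.

Conventions used throughout the package:

* User-facing coordinates are 1-based inclusive (mtDNA/rCRS numbering);
  BedGraph output converts to 0-based half-open intervals.
* Sequences are uppercased and restricted to the alphabet ``{A,C,G,T,N}``.
  Other IUPAC ambiguity codes are rejected by default, or mapped to ``N``
  when requested.
* The target genome may contain placeholder ``N`` bases (the mitochondrial
  reference keeps one at position 3106 purely to preserve historical
  numbering).  Such positions are removed before searching and restored
  afterwards, each restored position taking the value of the preceding
  original position (wrapping for a circular target).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_EXTRA = frozenset("RYSWKMBDHV")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A,C,G,T,N}."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence with linear or circular topology."""

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self):
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                "{A,C,G,T,N}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "Genome":
        return Genome(self.id, reverse_complement(self.seq), self.topology)


@dataclass(frozen=True)
class NormalizedTarget:
    """A target genome with its ``N`` placeholders removed.

    ``removed_positions`` holds the 1-based positions of the removed bases
    in the *original* coordinate system, in increasing order.
    """

    genome: Genome
    removed_positions: tuple[int, ...] = ()

    @property
    def original_length(self) -> int:
        return len(self.genome) + len(self.removed_positions)


@dataclass(frozen=True)
class GeneAnnotation:
    """A named 1-based inclusive interval on the target.

    ``start > end`` denotes an origin-spanning interval on a circular
    target.
    """

    name: str
    start: int
    end: int

    def length(self, target_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (target_length - self.start + 1) + self.end

    def positions0(self, target_length: int) -> np.ndarray:
        """0-based positions covered by the interval, in genomic order."""
        for v in (self.start, self.end):
            if not 1 <= v <= target_length:
                raise ValueError(
                    f"annotation {self.name!r}: position {v} outside "
                    f"1..{target_length}"
                )
        if self.start <= self.end:
            return np.arange(self.start - 1, self.end)
        return np.concatenate(
            [np.arange(self.start - 1, target_length), np.arange(0, self.end)]
        )


def _normalize_seq(seq: str, record_id: str, ambiguous: str, path, lineno):
    seq = seq.upper()
    if ambiguous == "map_to_n":
        seq = "".join("N" if c in _IUPAC_EXTRA else c for c in seq)
    bad = set(seq) - ALPHABET
    if bad:
        where = f" (file {path}, near line {lineno})" if path else ""
        raise AlphabetError(
            f"record {record_id!r}: characters {sorted(bad)} not in "
            f"{{A,C,G,T,N}}{where}"
        )
    return seq


def read_fasta(path, topology: str = "linear", ambiguous: str = "error") -> list[Genome]:
    """Read a FASTA file into a list of :class:`Genome`.

    Parameters
    ----------
    topology : "linear" or "circular"; circular is only allowed for
        single-record files (a circular target genome).
    ambiguous : "error" (default) rejects IUPAC codes other than N;
        "map_to_n" silently converts them to N.
    """
    with open(path) as fh:
        first = fh.readline()
        lineno = 1
        while first and not first.strip():
            first = fh.readline()
            lineno += 1
        if not first:
            raise FastaParseError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: expected '>' header, got "
                f"{first.strip()[:30]!r}"
            )
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records")
    genomes = []
    line_guess = 1
    for rec in records:
        seq = _normalize_seq(str(rec.seq), rec.id, ambiguous, path, line_guess)
        genomes.append(Genome(rec.id, seq, topology))
        line_guess += seq.count("\n") + 2
    if topology == "circular" and len(genomes) > 1:
        raise ValueError(
            "circular topology is only supported for single-record targets"
        )
    return genomes


def write_fasta(genomes, path, width: int = 70) -> None:
    """Write genomes as FASTA with deterministic line wrapping."""
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


def normalize_target(g: Genome) -> NormalizedTarget:
    """Remove every ``N`` from a target genome, recording its position."""
    removed = tuple(i + 1 for i, c in enumerate(g.seq) if c == "N")
    if not removed:
        return NormalizedTarget(g, ())
    seq = g.seq.replace("N", "")
    if not seq:
        raise AlphabetError(f"record {g.id!r}: all bases are N")
    return NormalizedTarget(Genome(g.id, seq, g.topology), removed)


def restore_track(track, nt: NormalizedTarget) -> np.ndarray:
    """Expand a per-position track from normalized to original coordinates.

    Each removed position receives the value of the preceding original
    position; a removed position 1 takes the last position's value on a
    circular target and the following position's value on a linear one.
    """
    track = np.asarray(track)
    removed = nt.removed_positions
    if len(track) != len(nt.genome):
        raise ValueError(
            f"track length {len(track)} != normalized length {len(nt.genome)}"
        )
    if not removed:
        return track.copy()
    n_out = nt.original_length
    out = np.empty(n_out, dtype=track.dtype)
    removed0 = np.array(removed) - 1
    keep = np.ones(n_out, dtype=bool)
    keep[removed0] = False
    out[keep] = track
    circular = nt.genome.topology == "circular"
    for p in removed0:  # ascending: earlier restored values are available
        if p > 0:
            out[p] = out[p - 1]
        elif circular:
            out[p] = out[n_out - 1]
        else:
            nxt = p + 1
            while not keep[nxt]:  # consecutive leading Ns
                nxt += 1
            out[p] = out[nxt]
    return out


TRACK_NAMES = ("lcs_max", "lcs_avg", "lss_max", "lss_avg")


def write_track(imap, path, format: str = "tsv", track: str | None = None) -> None:
    """Serialize an interference map.

    ``tsv`` writes all four tracks with a metadata comment header;
    ``bedgraph`` writes one run-length-merged BedGraph file for a single
    ``track`` (0-based half-open intervals).
    """
    if format == "tsv":
        meta = imap.meta
        with open(path, "w") as fh:
            fh.write(
                f"# target={meta.get('target', 'target')} "
                f"W={meta.get('window', 0)} model={meta.get('model', 'substitution')}\n"
            )
            fh.write("position\tlcs_max\tlcs_avg\tlss_max\tlss_avg\n")
            for i in range(imap.target_length):
                fh.write(
                    f"{i + 1}\t{int(imap.lcs_max[i])}\t{float(imap.lcs_avg[i])!r}"
                    f"\t{int(imap.lss_max[i])}\t{float(imap.lss_avg[i])!r}\n"
                )
    elif format == "bedgraph":
        if track not in TRACK_NAMES:
            raise ValueError(f"track must be one of {TRACK_NAMES}, got {track!r}")
        values = np.asarray(getattr(imap, track))
        name = imap.meta.get("target", "target")
        with open(path, "w") as fh:
            start = 0
            for i in range(1, len(values) + 1):
                if i == len(values) or values[i] != values[start]:
                    v = values[start]
                    v = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{name}\t{start}\t{i}\t{v}\n")
                    start = i
    else:
        raise ValueError(f"unknown format {format!r}")


def read_track(path):
    """Read a map TSV written by :func:`write_track` (inverse for tsv)."""
    from .interference import InterferenceMap  # local import avoids a cycle

    meta: dict = {}
    with open(path) as fh:
        header = fh.readline()
    if header.startswith("#"):
        for tok in header[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[{"W": "window"}.get(k, k)] = v
        if "window" in meta:
            meta["window"] = int(meta["window"])
    df = pd.read_csv(path, sep="\t", comment="#")
    return InterferenceMap(
        lcs_max=df["lcs_max"].to_numpy(dtype=np.int64),
        lcs_avg=df["lcs_avg"].to_numpy(dtype=float),
        lss_max=df["lss_max"].to_numpy(dtype=np.int64),
        lss_avg=df["lss_avg"].to_numpy(dtype=float),
        target_length=len(df),
        meta=meta,
    )


def read_annotations(path) -> list[GeneAnnotation]:
    """Read gene annotations from BED (0-based half-open) or TSV
    (1-based inclusive, columns name/start/end; start > end = wrap-around).
    """
    if str(path).lower().endswith(".bed"):
        out = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                out.append(GeneAnnotation(name, int(f[1]) + 1, int(f[2])))
        return out
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    missing = {"name", "start", "end"} - set(cols)
    if missing:
        raise ValueError(f"{path}: annotation TSV lacks columns {sorted(missing)}")
    return [
        GeneAnnotation(str(r[cols["name"]]), int(r[cols["start"]]), int(r[cols["end"]]))
        for _, r in df.iterrows()
    ]
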