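"""Synthetic background/target genome pairs with implanted target copies.

The simulator emulates the structure that makes nuclear interference
possible: segments of a circular target genome transposed into a random
background at some point in the past, accumulating substitutions since.
Each implant "age class" is characterized by a per-base substitution
rate (0 for recent, exact copies; higher for ancient, diverged copies);
implants land on either strand and at non-overlapping offsets.  Ground
truth is recorded so that pipeline output can be bounded from below
per position.

Base composition is uniform over {A,C,G,T}; no GC or repeat structure is
modelled — the generator exercises string algorithmics, not genome
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import Genome, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ImplantClass:
    """A group of implants sharing a length range and substitution rate.

    ``exact_n`` forces each implant of the class to carry exactly that
    many substitutions instead of the per-base Bernoulli rate.
    """

    count: int
    min_len: int
    max_len: int
    rate: float = 0.0
    exact_n: int | None = None
    label: str = ""

    def __post_init__(self):
        if not 0 <= self.rate < 1:
            raise ValueError("substitution rate must be in [0, 1)")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid implant length range")


@dataclass(frozen=True)
class ImplantTruth:
    """Ground truth for one placed implant (1-based coordinates)."""

    target_start: int
    target_end: int
    background_record: int
    background_offset: int
    strand: str
    length: int
    n_substitutions: int
    age_class: str
    mutated_positions: tuple[int, ...]  # 1-based offsets within the segment


def _random_seq(rng, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _mutate(rng, seg: str, rate: float, exact_n: int | None):
    arr = np.frombuffer(seg.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    if exact_n is not None:
        if exact_n > n:
            raise ValueError("more substitutions than segment bases")
        pos = rng.choice(n, size=exact_n, replace=False)
    else:
        pos = np.nonzero(rng.random(n) < rate)[0]
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), tuple(sorted(int(p) + 1 for p in pos))


def simulate_pair(seed: int, target_length: int = 16000,
                  background_length: int = 200000,
                  implants=((3, 150, 300, 0.0),),
                  target_id: str = "target",
                  background_id: str = "background"):
    """Generate a (circular target, background list, truth list) triple.

    ``implants`` is a sequence of :class:`ImplantClass` or tuples
    ``(count, min_len, max_len, rate)``.  Implant source intervals may
    wrap the target origin; implants are reverse-complemented with
    probability 1/2 and placed at non-overlapping background offsets.
    Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    classes = []
    for i, spec in enumerate(implants):
        if isinstance(spec, ImplantClass):
            c = spec
        else:
            c = ImplantClass(*spec)
        if not c.label:
            c = ImplantClass(c.count, c.min_len, c.max_len, c.rate,
                             c.exact_n, label=f"class{i}")
        classes.append(c)
    total_implant = sum(c.count * c.max_len for c in classes)
    if total_implant >= background_length / 2:
        raise ValueError(
            f"implants ({total_implant} bases at worst) must total less "
            f"than half the background length ({background_length})"
        )
    target_seq = _random_seq(rng, target_length)
    background = np.frombuffer(
        _random_seq(rng, background_length).encode("ascii"), dtype=np.uint8
    ).copy()
    occupied = np.zeros(background_length, dtype=bool)
    truths: list[ImplantTruth] = []
    tiled = target_seq + target_seq  # source intervals may wrap the origin
    for cls in classes:
        for _ in range(cls.count):
            seg_len = int(rng.integers(cls.min_len, cls.max_len + 1))
            if seg_len > target_length:
                raise ValueError("implant longer than the target")
            src0 = int(rng.integers(0, target_length))
            seg = tiled[src0 : src0 + seg_len]
            seg, mut = _mutate(rng, seg, cls.rate, cls.exact_n)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = seg if strand == "+" else reverse_complement(seg)
            for attempt in range(1000):
                off = int(rng.integers(0, background_length - seg_len + 1))
                if not occupied[off : off + seg_len].any():
                    break
            else:
                raise ValueError("infeasible packing of implants")
            occupied[off : off + seg_len] = True
            background[off : off + seg_len] = np.frombuffer(
                placed.encode("ascii"), dtype=np.uint8
            )
            truths.append(
                ImplantTruth(
                    target_start=src0 + 1,
                    target_end=(src0 + seg_len - 1) % target_length + 1,
                    background_record=0,
                    background_offset=off + 1,
                    strand=strand,
                    length=seg_len,
                    n_substitutions=len(mut),
                    age_class=cls.label,
                    mutated_positions=mut,
                )
            )
    bg = Genome(background_id, background.tobytes().decode("ascii"))
    return Genome(target_id, target_seq, "circular"), [bg], truths


def _segment_bounds(seg_len: int, mutated: tuple[int, ...]):
    """Per-offset maximal window lengths with 0 and <=1 mutated bases."""
    m = np.array([p - 1 for p in mutated], dtype=np.int64)
    b0 = np.zeros(seg_len, dtype=np.int64)
    b1 = np.zeros(seg_len, dtype=np.int64)
    bnd = np.concatenate([[-1], m, [seg_len]])
    # windows with no mutated base: between consecutive mutations
    for a, b in zip(bnd[:-1], bnd[1:]):
        lo, hi = a + 1, b - 1
        if hi >= lo:
            np.maximum(b0[lo : hi + 1], hi - lo + 1, out=b0[lo : hi + 1])
    # windows with at most one mutated base
    if m.size == 0:
        b1[:] = seg_len
    else:
        for j in range(m.size):
            lo = bnd[j] + 1
            hi = bnd[j + 2] - 1
            np.maximum(b1[lo : hi + 1], hi - lo + 1, out=b1[lo : hi + 1])
        np.maximum(b1, b0, out=b1)
    return b0, b1


def expected_bounds(truths, target_length: int):
    """Pointwise lower bounds on the map's lcs_max / lss_max tracks.

    For each implant, every target position gets at least the length of
    the largest window around it containing no mutated base (exact track)
    or at most one mutated base (one-mismatch track).
    """
    lcs = np.zeros(target_length, dtype=np.int64)
    lss = np.zeros(target_length, dtype=np.int64)
    for t in truths:
        b0, b1 = _segment_bounds(t.length, t.mutated_positions)
        idx = (t.target_start - 1 + np.arange(t.length)) % target_length
        np.maximum.at(lcs, idx, b0)
        np.maximum.at(lss, idx, b1)
    return lcs, lss


def write_truth_tsv(truths, path) -> None:
    cols = ("target_start", "target_end", "background_record",
            "background_offset", "strand", "length", "n_substitutions",
            "age_class", "mutated_positions")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            fh.write(
                "\t".join(
                    str(getattr(t, c)) if c != "mutated_positions"
                    else ",".join(map(str, t.mutated_positions))
                    for c in cols
                )
                + "\n"
            )
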