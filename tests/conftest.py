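"""Shared fixtures and the map-level brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

import nimap as nm
from nimap.interference import StartLengthProfile, aggregate_map

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES_N = np.frombuffer(b"ACGTN", dtype=np.uint8)


def random_seq(rng, n, with_n=False):
    if with_n:
        return rng.choice(
            _BASES_N, size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]
        ).tobytes().decode()
    return rng.choice(_BASES, size=n).tobytes().decode()


def oracle_map(target: nm.Genome, background, W=450, model="substitution"):
    """Interference map computed start-by-start with the brute-force
    oracle (no index), for cross-checking the pipeline."""
    L = len(target)
    circ = target.topology == "circular"
    cap = min(W, L)
    ext = target.seq + target.seq[: cap - 1] if circ else target.seq
    l0 = np.zeros(L, np.int64)
    l1 = np.zeros(L, np.int64)
    for s in range(L):
        q = ext[s : s + cap] if circ else ext[s : s + min(W, L - s)]
        l0[s] = nm.oracle_longest_extension(background, q, 0)
        l1[s] = nm.oracle_longest_extension(background, q, 1, model)
    prof = StartLengthProfile(l0, l1, W, target.topology)
    return aggregate_map(prof, L)


@pytest.fixture(scope="session")
def tiny_index():
    """Index over the worked-example background 'ACGTACGTTT'."""
    return nm.build_index([nm.Genome("b", "ACGTACGTTT")], nm.IndexConfig(450))


@pytest.fixture(scope="session")
def small_map():
    """A deterministic end-to-end map over a seeded synthetic pair with
    one exact and one single-substitution implant."""
    target, background, truths = nm.simulate_pair(
        202, target_length=500, background_length=5000,
        implants=[(1, 90, 120, 0.0), nm.ImplantClass(1, 90, 120, 0.0, exact_n=1)],
    )
    imap = nm.run_map(background, target)
    return target, background, truths, imap
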