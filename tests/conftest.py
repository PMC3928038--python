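"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive and self-contained
(their own IUPAC tables, their own per-position loops) so they stay
independent of the package code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from trescan import SimulationConfig, simulate_study

# Independent IUPAC tables for oracle matching (N matches anything
# including N; specific codes never match N).
ORACLE_SETS = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T", "N"},
}
ORACLE_COMP = dict(
    zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
)


def oracle_rc(pattern: str) -> str:
    return "".join(ORACLE_COMP[c] for c in reversed(pattern.upper()))


def oracle_match_at(seq: str, pattern: str, i: int) -> bool:
    if i < 0 or i + len(pattern) > len(seq):
        return False
    return all(seq[i + j] in ORACLE_SETS[pattern[j]] for j in range(len(pattern)))


def oracle_scan(seq: str, pattern: str, bidirectional: bool = True):
    """All (start, end, strand) occurrences by per-position brute force,
    with self-reverse-complementary patterns reported once (strand +)."""
    seq = seq.upper()
    pattern = pattern.upper()
    L = len(pattern)
    hits = [
        (i, i + L, "+") for i in range(len(seq)) if oracle_match_at(seq, pattern, i)
    ]
    rc = oracle_rc(pattern)
    if bidirectional and rc != pattern:
        hits += [
            (i, i + L, "-")
            for i in range(len(seq))
            if oracle_match_at(seq, rc, i)
        ]
    return sorted(hits)


def oracle_scan_dyad(
    seq: str, left: str, spacer_lo: int, spacer_hi: int, right: str
):
    """Brute-force dyad occurrences as (start, end, strand, spacer)."""
    seq = seq.upper()
    out = []
    for sp in range(spacer_lo, spacer_hi + 1):
        comp = left.upper() + "N" * sp + right.upper()
        for s, e, strand in oracle_scan(seq, comp):
            out.append((s, e, strand, sp))
    return sorted(out)


def random_dna(rng: np.random.Generator, n: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else [0.25] * 4
    return "".join(rng.choice(list(alphabet), size=n, p=probs))


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic study shared across tests."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_bundle_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    simulate_study(SimulationConfig(seed=1), outdir)
    return outdir
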