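"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (dict lookups, exhaustive window
scans, hand-rolled step-up adjustment, quadratic DP) and stay independent of
the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from editqc._sequence import IUPAC_SETS, revcomp
from editqc.io import SequenceRecord
from editqc.simulate import SyntheticScenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def small_scenario():
    """A reduced screening scenario that keeps unit tests fast.

    60-kb host, 6-kb construct with a 4-kb T-DNA, homology block 201-1000,
    decoy at 1200, 12x depth.
    """
    return SyntheticScenario(
        seed=5,
        host_length=60_000,
        construct_length=6_000,
        tdna_end=4_000,
        homology_length=800,
        homology_start=201,
        decoy_start=1_200,
        decoy_host_copies=8,
        depth=12.0,
        event="none",
    )


# ----------------------------------------------------------------- oracles


def naive_count_kmers(reads, construct: str, k: int):
    """Dict-based reference implementation of two-strand k-mer counting.

    Returns (counts array, total examined valid k-mers).
    """
    pos: dict[str, list[int]] = {}
    for i in range(len(construct) - k + 1):
        pos.setdefault(construct[i : i + k], []).append(i + 1)
    counts = np.zeros(len(construct) - k + 1, dtype=np.int64)
    total = 0
    for read in reads:
        seq = read.sequence if isinstance(read, SequenceRecord) else read
        if len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) - set("ACGT"):
                continue
            total += 1
            hit = set(pos.get(kmer, ())) | set(pos.get(revcomp(kmer), ()))
            for p in hit:
                counts[p - 1] += 1
    return counts, total


def bh_oracle(pvalues):
    """Hand-written Benjamini-Hochberg step-up adjustment."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def naive_offtarget_scan(seq: str, protospacer: str, pam: str, max_mm: int):
    """Exhaustive per-window scan, both strands; returns a set of hit tuples."""
    hits = set()
    w = len(protospacer) + len(pam)
    for strand in "+-":
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            site = window if strand == "+" else revcomp(window)
            pam_ok = all(
                IUPAC_SETS[q] & IUPAC_SETS[b] for q, b in zip(pam, site[len(protospacer):])
            )
            if not pam_ok:
                continue
            mm = sum(g not in IUPAC_SETS[b] for g, b in zip(protospacer, site))
            if mm <= max_mm:
                start = i + 1 if strand == "+" else i + len(pam) + 1
                hits.add((start, strand, mm))
    return hits


def gotoh_score(a: str, b: str, match=2.0, mismatch=-4.0, gap_open=-6.0, gap_extend=-1.0):
    """Quadratic-space affine-gap global alignment score (Gotoh DP).

    A length-L gap costs |gap_open| + L * |gap_extend|.
    """
    NEG = -1e18
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    M = np.full((m + 1,), NEG)
    X = np.full((m + 1,), NEG)  # gap in b (deletion from a's perspective)
    Y = np.full((m + 1,), NEG)  # gap in a
    M[0] = 0.0
    for j in range(1, m + 1):
        Y[j] = open_cost + (j - 1) * gap_extend
    for i in range(1, n + 1):
        prevM, prevX, prevY = M.copy(), X.copy(), Y.copy()
        M[0], Y[0] = NEG, NEG
        X[0] = open_cost + (i - 1) * gap_extend
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[j] = max(prevM[j - 1], prevX[j - 1], prevY[j - 1]) + s
            X[j] = max(prevM[j] + open_cost, prevX[j] + gap_extend, prevY[j] + open_cost)
            Y[j] = max(M[j - 1] + open_cost, Y[j - 1] + gap_extend, X[j - 1] + open_cost)
    return max(M[m], X[m], Y[m])


def dunnett_mc(q: float, lambdas, df: int, n: int, rng) -> float:
    """Monte-Carlo estimate of P(max_j |T_j| < q) for the shared-control t."""
    lam = np.asarray(lambdas, dtype=float)
    c = np.sqrt(1 - lam**2)
    z0 = rng.standard_normal(n)
    x = rng.standard_normal((n, lam.size))
    s = np.sqrt(rng.chisquare(df, n) / df)
    T = (lam * z0[:, None] + c * x) / s[:, None]
    return float((np.abs(T).max(axis=1) < q).mean())
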