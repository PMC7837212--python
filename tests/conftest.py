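"""Shared fixtures and the reference alignment oracle.

The session-scoped ``demo_report`` fixture runs the full demonstration
pipeline once (8 samples, 0-30% host contamination); most end-to-end
properties are asserted against it.
"""

from __future__ import annotations

import numpy as np
import pytest

from xenosnp.pipeline import demo_config, run_pipeline
from xenosnp.simulate import plant_variants, simulate_dual_reference

DEMO_SEED = 1234

# --- reference Smith-Waterman oracle (plain-Python dynamic programming) ----
#
# Mirrors the production tie-breaking contract exactly: end cell = maximal
# score with smallest target index then smallest query index; traceback
# prefers diagonal, then query-consuming gap, then target-consuming gap, and
# closes gaps as early as possible. Gap of length L costs open + (L-1)*extend.

NEG = float("-inf")


def sw_oracle(query: str, target: str, match=1, mismatch=-2, gap_open=-3, gap_extend=-1):
    """Return (score, cigar, n_mismatch) of the optimal local alignment."""

    def sub(a: str, b: str) -> int:
        return match if (a == b and a != "N" and b != "N") else mismatch

    m, n = len(query), len(target)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            h = max(0.0, H[i - 1][j - 1] + sub(query[i - 1], target[j - 1]), E[i][j], F[i][j])
            H[i][j] = h
            if h > best or (h == best and h > 0 and (j < bj or (j == bj and i < bi))):
                best, bi, bj = h, i, j

    ops: list[str] = []
    i, j, state = bi, bj, "H"
    if best > 0:
        while True:
            if state == "H":
                h = H[i][j]
                if h == 0:
                    break
                s = sub(query[i - 1], target[j - 1])
                if h == H[i - 1][j - 1] + s:
                    ops.append("=" if s == match else "X")
                    i -= 1
                    j -= 1
                elif h == E[i][j]:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":
                ops.append("I")
                if E[i][j] == H[i - 1][j] + gap_open:
                    state = "H"
                i -= 1
            else:
                ops.append("D")
                if F[i][j] == H[i][j - 1] + gap_open:
                    state = "H"
                j -= 1
    ops.reverse()

    parts = []
    if i > 0:
        parts.append(f"{i}S")
    run, run_len = "", 0
    for op in ops:
        if op == run:
            run_len += 1
        else:
            if run_len:
                parts.append(f"{run_len}{run}")
            run, run_len = op, 1
    if run_len:
        parts.append(f"{run_len}{run}")
    if m - bi > 0:
        parts.append(f"{m - bi}S")
    return int(best), "".join(parts), ops.count("X")


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))


# --- fixtures --------------------------------------------------------------


@pytest.fixture(scope="session")
def small_ref():
    """5 contigs x 800 bp at 6% divergence."""
    return simulate_dual_reference(5, 800, 0.06, seed=11)


@pytest.fixture(scope="session")
def small_variants(small_ref):
    return plant_variants(
        small_ref, 12, 0.5, seed=12, margin=100, min_spacing=36,
        guard_window=35, marker_band=(1, 46),
    )


@pytest.fixture(scope="session")
def demo_report(tmp_path_factory):
    """The full 8-sample demonstration run (shared across tests)."""
    outdir = tmp_path_factory.mktemp("demo")
    return run_pipeline(demo_config(outdir=outdir, seed=DEMO_SEED))
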