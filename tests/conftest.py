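"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from revecol.proteome import CANONICAL_AA, Proteome

UNIFORM_WEIGHTS = {aa: 1.0 for aa in CANONICAL_AA}


def grid_scan_pi(sequence: str, pka, step: float = 1e-4) -> float:
    """Independent pI oracle: dense pH grid scan of the charge curve.

    Reimplements the Henderson–Hasselbalch charge sum directly (no shared
    code with the bisection solver) and returns the grid pH of minimum
    absolute charge.
    """
    groups = []  # (pKa, sign, count)
    seq = "".join(c for c in sequence.upper() if c in CANONICAL_AA)
    for res, pk in pka.side_chain.items():
        n = seq.count(res)
        if n:
            sign = +1 if pka.polarity[res] == "basic" else -1
            groups.append((pk, sign, n))
    groups.append((pka.n_term, +1, 1))
    groups.append((pka.c_term, -1, 1))
    phs = np.arange(0.0, 14.0 + step / 2, step)
    q = np.zeros_like(phs)
    for pk, sign, n in groups:
        if sign > 0:
            q += n / (1.0 + 10.0 ** (phs - pk))
        else:
            q -= n / (1.0 + 10.0 ** (pk - phs))
    return float(phs[np.argmin(np.abs(q))])


def random_protein(rng: np.random.Generator, lo: int = 20, hi: int = 200) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_weights():
    return dict(UNIFORM_WEIGHTS)


def make_proteome(*seqs: str, genome_id: str = "g") -> Proteome:
    return Proteome(genome_id=genome_id,
                    records=[(f"p{i}", s) for i, s in enumerate(seqs)])
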