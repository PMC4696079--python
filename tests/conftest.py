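import numpy as np
import pytest

from coalabc.alignment import Alignment


@pytest.fixture
def toy_alignment():
    """4 sequences, S=2, all 6 pairs enumerable by hand.

    Pairwise differences: ab=1, ac=2, ad=0, bc=1, bd=1, cd=2 -> k=7/6.
    Haplotypes: {ACGT x2, ACGA, ACTA} -> 3.
    """
    return Alignment(
        ["a", "b", "c", "d"],
        ["ACGT", "ACGA", "ACTA", "ACGT"],
        {x: "T1" for x in "abcd"},
    )


@pytest.fixture
def two_deme_alignment():
    """Two demes fixed for haplotypes 5 sites apart; no within variation."""
    ids = ["p1", "p2", "p3", "q1", "q2", "q3"]
    seqs = ["AAAAA"] * 3 + ["TTTTT"] * 3
    return Alignment(ids, seqs, {i: ("P" if i.startswith("p") else "Q") for i in ids})


@pytest.fixture(scope="session")
def small_tables():
    """Four small reference tables under default priors (shared, seeded)."""
    from coalabc import abcsel, scenarios

    sizes = {"MEX": 70, "SAL": 71, "PER": 47}
    priors = scenarios.default_priors()
    return [
        abcsel.simulate_reference_table(m, priors, 800, sizes, 500 + i)
        for i, m in enumerate(scenarios.MODELS)
    ]


def random_alignment(n, L, n_demes=1, seed=0):
    rng = np.random.default_rng(seed)
    m = rng.integers(0, 4, size=(n, L))
    bases = np.array(list("ACGT"))
    ids = [f"s{i}" for i in range(n)]
    seqs = ["".join(bases[row]) for row in m]
    demes = {ids[i]: f"d{i % n_demes}" for i in range(n)}
    return Alignment(ids, seqs, demes)
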