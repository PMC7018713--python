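import numpy as np
import pytest

from ribodelim.structures import StructuredSequence, encode12


def random_structure(rng: np.random.Generator, n_pairs: int, n_unpaired: int) -> str:
    """Random pseudoknot-free dot-bracket by repeated balanced insertion."""
    s = ["."] * n_unpaired
    for _ in range(n_pairs):
        i = int(rng.integers(0, len(s) + 1))
        # insert a pair enclosing a random suffix slice starting at i
        j = int(rng.integers(i, len(s) + 1))
        s = s[:i] + ["("] + s[i:j] + [")"] + s[j:]
    return "".join(s)


def random_structured_pair(rng: np.random.Generator, length_pairs=(8, 14),
                           same_structure: bool = False):
    """Two equal-length structured sequences (independent structures unless
    ``same_structure``), returned as a gapless two-row alignment."""
    from ribodelim.alignment import SeqStructAlignment

    n_pairs = int(rng.integers(*length_pairs))
    n_un = int(rng.integers(4, 12))
    st_a = random_structure(rng, n_pairs, n_un)
    st_b = st_a if same_structure else random_structure(rng, n_pairs, n_un)
    L = len(st_a)
    nts = np.array(list("ACGU"))
    seq_a = "".join(nts[rng.integers(0, 4, L)])
    seq_b = "".join(nts[rng.integers(0, 4, L)])
    a = encode12(StructuredSequence("a", seq_a, st_a))
    b = encode12(StructuredSequence("b", seq_b, st_b))
    return SeqStructAlignment(["a", "b"], np.vstack([a.codes, b.codes]))


def brute_force_cbc(seq_a: str, st_a: str, seq_b: str, st_b: str):
    """Independent CBC/hemi counter: stack-parses each structure itself and
    enumerates every aligned pair couple."""
    def pairs(st):
        stack, out = [], set()
        for i, c in enumerate(st):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.add((stack.pop(), i))
        return out

    canonical = {"AU", "UA", "GC", "CG", "GU", "UG"}
    cbc = hemi = 0
    for (i, j) in pairs(st_a) & pairs(st_b):
        pa, pb = seq_a[i] + seq_a[j], seq_b[i] + seq_b[j]
        if pa in canonical and pb in canonical:
            diff = (pa[0] != pb[0]) + (pa[1] != pb[1])
            if diff == 2:
                cbc += 1
            elif diff == 1:
                hemi += 1
    return cbc, hemi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    from ribodelim.synth import SynthConfig

    return SynthConfig(strains_per_ribotype=2, seed=11)
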