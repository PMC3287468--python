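import random

import pytest

import chemtree as ct

CHO = {"C": 4, "O": 2, "H": 1}
CNOH = {"C": 4, "N": 3, "O": 2, "H": 1}


def formula_instance(formula, valences, K=0, upper_default="inf"):
    """Instance fixing only the molecular formula (plus optional level)."""
    order = [l for l in valences if formula.get(l, 0) or True]
    counts = {l: formula.get(l, 0) for l in valences}
    return ct.validate_instance(
        {
            "alphabet": dict(valences),
            "order": list(valences),
            "K": K,
            "g_L": dict(counts),
            "g_U": dict(counts),
            "g_U_default": upper_default,
        }
    )


@pytest.fixture
def cho_alphabet():
    return ct.Alphabet(("C", "O", "H"), CHO)


@pytest.fixture
def cnoh_alphabet():
    return ct.Alphabet(("C", "N", "O", "H"), CNOH)


@pytest.fixture
def rng():
    return random.Random(20260927)


@pytest.fixture(scope="session")
def synthetic_suite():
    """A reusable batch of random solvable instances with planted solutions."""
    rng = random.Random(11)
    alphabets = [
        ct.Alphabet(("C", "H"), {"C": 4, "H": 1}),
        ct.Alphabet(("C", "O", "H"), CHO),
        ct.Alphabet(("C", "N", "O", "H"), CNOH),
        ct.Alphabet(("P", "S", "H"), {"P": 5, "S": 2, "H": 1}),
    ]
    suite = []
    while len(suite) < 60:
        alpha = rng.choice(alphabets)
        n = rng.randint(2, 8)
        K = rng.randint(0, 4)
        w = rng.randint(0, 3)
        try:
            inst, planted = ct.synth_instance(rng, alpha, n, K, w)
        except ct.InstanceError:
            continue
        suite.append((inst, planted))
    return suite
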