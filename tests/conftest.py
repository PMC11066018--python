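import itertools

import numpy as np
import pytest

from synidp import codons, motifs


@pytest.fixture(scope="session")
def gqsgl_unit() -> str:
    """24-residue PG-phase repeat unit of the GQSGLP tag motif."""
    return motifs.build_repeat_unit(motifs.Motif(("Q", "S", "G", "L")), 4)


@pytest.fixture(scope="session")
def gqsgl_design(gqsgl_unit) -> codons.OligoDesign:
    return codons.reverse_translate_scrambled(gqsgl_unit, seed=1)


@pytest.fixture(scope="session")
def small_reference_library() -> dict[str, str]:
    """Three scrambled 72-nt reference units with distinct motifs."""
    units = {
        "AGLQ": ("Q", "S", "G", "L"),
        "AGST": ("A", "G", "S", "T"),
        "AEGQ": ("A", "E", "G", "Q"),
    }
    refs = {}
    for name, x in units.items():
        unit = motifs.build_repeat_unit(motifs.Motif(x), 4)
        refs[name] = codons.reverse_translate_scrambled(unit, seed=11).nt_seq
    return refs


def brute_force_motif_enumeration(spec: motifs.MotifSpec) -> set[str]:
    """Independent oracle: all ordered X tuples, filtered, multiset-collapsed."""
    keys = set()
    for tup in itertools.product(spec.x_alphabet, repeat=spec.n_x):
        if tup[-1] in spec.forbidden_at_x4:
            continue
        if tup.count(spec.required_residue) < spec.min_required_count:
            continue
        keys.add("".join(sorted(tup)))
    return keys


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
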