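import numpy as np
import pytest

from csindel.alignment import AlignedSequence, Alignment
from csindel.hydration import Atom, Frame

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_alignment(
    rng: np.random.Generator,
    n_rows: int | None = None,
    n_cols: int | None = None,
    gap_prob: float = 0.0,
) -> Alignment:
    n_rows = n_rows or int(rng.integers(2, 8))
    n_cols = n_cols or int(rng.integers(4, 40))
    rows = []
    for i in range(n_rows):
        chars = rng.choice(list(AA), size=n_cols)
        if gap_prob > 0:
            gaps = rng.random(n_cols) < gap_prob
            chars = np.where(gaps, "-", chars)
        rows.append(AlignedSequence(f"seq{i}", "".join(chars)))
    return Alignment(rows)


def random_frame(
    rng: np.random.Generator,
    n_waters: int = 500,
    n_ligand: int = 30,
    box: float = 40.0,
    time: float = 100.0,
) -> Frame:
    atoms = []
    serial = 1
    for j in range(n_ligand):
        pos = rng.uniform(-5, 5, size=3)
        atoms.append(Atom(serial, f"C{j+1}", "ADP", 1, "A", pos))
        serial += 1
    atoms.append(Atom(serial, "O", "GLU", 185, "A", rng.uniform(-box / 2, box / 2, 3)))
    serial += 1
    for j in range(n_waters):
        pos = rng.uniform(-box / 2, box / 2, size=3)
        atoms.append(Atom(serial, "OW", "HOH", 300 + j, "W", pos))
        serial += 1
    return Frame(time, atoms)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
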