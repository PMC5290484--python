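import numpy as np
import pytest

from phbind.model_io import Frame, Topology


def build_topology(roles, names=None, residue_ids=None, is_phosphate=None, masses=None):
    """Small hand-rolled topology for unit tests."""
    n = len(roles)
    names = names or ["BB" if r == "protein" else "PO4" for r in roles]
    residue_ids = residue_ids or list(range(1, n + 1))
    if is_phosphate is None:
        is_phosphate = [r in ("lipid:PIP2", "lipid:PIP3") for r in roles]
    # one molecule per residue; consecutive protein residues fuse into one
    mol_ids, current, prev_prot = [], -1, False
    for r in roles:
        if not (r == "protein" and prev_prot):
            current += 1
        mol_ids.append(current)
        prev_prot = r == "protein"
    return Topology(
        ids=np.arange(n),
        names=names,
        residue_ids=residue_ids,
        residue_names=["ALA" if r == "protein" else "POP3" for r in roles],
        molecule_ids=mol_ids,
        roles=roles,
        masses=masses or [1.0] * n,
        is_phosphate=is_phosphate,
        is_backbone=[r == "protein" for r in roles],
    )


def frame(coords, box=(10.0, 10.0, 10.0), time=0.0):
    return Frame(time=time, box=np.asarray(box), coords=np.asarray(coords, dtype=float))


@pytest.fixture(scope="session")
def tetrahedron_reference():
    """Four non-coplanar points, centred, for orientation tests."""
    coords = np.array(
        [[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [-1.0, -1.0, -1.0]]
    )
    return coords - coords.mean(axis=0)
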