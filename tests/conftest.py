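"""Shared fixtures: random geometry generators and synthetic PDB text."""

import numpy as np
import pytest

from chiracal import IdealHelixSpec, generate_helix


@pytest.fixture
def rng():
    return np.random.default_rng(20211203)


def random_rotation(rng) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR with det fixed to +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def random_chain_coords(rng, n: int) -> np.ndarray:
    """A random non-degenerate open chain with ~3.8 A steps (Calpha-like)."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    steps *= rng.uniform(3.6, 4.0, size=(n - 1, 1))
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def random_helix_spec(rng, handedness="right") -> IdealHelixSpec:
    return IdealHelixSpec(
        R=float(rng.uniform(0.5, 10.0)),
        H=float(rng.uniform(0.5, 10.0)),
        N=int(rng.integers(4, 40)),
        handedness=handedness,
    )


@pytest.fixture
def alpha_like_chain():
    """An ideal right-handed helix with alpha-helix-like dimensions."""
    return generate_helix(IdealHelixSpec(R=2.3, H=5.4, N=10))


def ca_pdb_text(coords, chain_id="A", start=1, resname="ALA",
                helix_records=()):
    """Hand-rolled fixed-format PDB text for synthetic test structures."""
    lines = list(helix_records)
    serial = 1
    for i, (x, y, z) in enumerate(coords):
        num = start + i
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname} {chain_id}{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def helix_record(serial, chain_id, start, end, helix_class):
    """A PDB HELIX header line with the given class code."""
    length = end - start + 1
    return (
        f"HELIX  {serial:3d} {serial:3d} ALA {chain_id} {start:4d}  "
        f"ALA {chain_id} {end:4d} {helix_class:2d}                      "
        f"         {length:5d}"
    )
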