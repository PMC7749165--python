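"""Shared fixtures: toy complexes and tiny hand-checked PDB files."""

from __future__ import annotations

import pytest

from xlstruct import ToyComplexSpec, make_toy_complex


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    element: str = "C",
    altloc: str = " ",
    record: str = "ATOM",
) -> str:
    """One fixed-column PDB coordinate record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written 3-residue single-chain PDB: 7 atoms, one chain.

    Residue 3 has no CA (truncated); a water and a zero-occupancy altloc
    exercise the exclusion rules.
    """
    lines = [
        pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_line(2, "CA", "GLY", "A", 1, 1.5, 0.0, 0.0),
        pdb_line(3, "C", "GLY", "A", 1, 2.2, 1.2, 0.0),
        pdb_line(4, "N", "LYS", "A", 2, 3.5, 1.2, 0.0, element="N"),
        # altloc pair: B has the higher occupancy and must win
        pdb_line(5, "CA", "LYS", "A", 2, 4.3, 2.4, 0.0, occ=0.4, altloc="A"),
        pdb_line(6, "CA", "LYS", "A", 2, 4.9, 2.9, 0.1, occ=0.6, altloc="B"),
        pdb_line(7, "N", "ALA", "A", 3, 6.0, 3.0, 0.0, element="N"),
        pdb_line(8, "CB", "ALA", "A", 3, 7.1, 3.5, 0.5),
        pdb_line(9, "O", "HOH", "A", 101, 9.0, 9.0, 9.0, element="O", record="HETATM"),
        "END\n",
    ]
    p = tmp_path / "three_res.pdb"
    p.write_text("".join(lines))
    return p


STANDARD_CHAINS = (
    ("beta_prime", 60, "ideal_helix"),
    ("beta", 60, "ideal_helix"),
    ("delta", 40, "straight_strand"),
)


@pytest.fixture
def toy_complex():
    """Three-chain toy complex (β′ 60, β 60, δ 40 residues)."""
    return make_toy_complex(ToyComplexSpec(chains=STANDARD_CHAINS, seed=3))


@pytest.fixture
def hinged_pair():
    """Closed (0°) and 60°-open copies of the hinged toy complex."""
    closed_spec = ToyComplexSpec(
        chains=STANDARD_CHAINS, hinge=("beta_prime", 30, 0.0), seed=7
    )
    open_spec = ToyComplexSpec(
        chains=STANDARD_CHAINS, hinge=("beta_prime", 30, 60.0), seed=7
    )
    return make_toy_complex(closed_spec), make_toy_complex(open_spec)
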