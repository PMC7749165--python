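"""Uniform atomic data model for multi-chain coordinate files.

Reads PDB/mmCIF into a light hierarchy (StructureModel > Chain > Residue >
Atom) keyed by *author* residue numbering, which is how residues are cited
throughout the structural literature on bacterial RNA polymerase (e.g. the
β2-lobe residue P242 or the β′ clamp-helix residue N283). Subunit identity
(α1, α2, β, β′, δ, ε, HelD, ...) is carried alongside the structure as a
:class:`SubunitMap` from role names to chain ids, because deposited chain
ids are arbitrary.

Parsing is delegated to :mod:`gemmi`; only the first coordinate model is
kept, waters are dropped by default, and alternate locations are resolved
to the highest-occupancy conformer (ties broken by file order). Hydrogens
are retained in the model but flagged for exclusion by radius assignment,
since surface and distance analyses operate on heavy atoms of
hydrogen-free deposited models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "SubunitMap",
    "RadiiTable",
    "StructureParseError",
    "read_structure",
    "write_pdb",
    "get_calpha",
    "assign_radius",
    "DEFAULT_RADII",
    "CANONICAL_ROLES",
]

#: Canonical subunit-role vocabulary for RNAP-family complexes. Free-form
#: role strings are accepted everywhere; these are the documented spellings.
CANONICAL_ROLES = (
    "alpha1",
    "alpha2",
    "beta",
    "beta_prime",
    "delta",
    "epsilon",
    "HelD",
    "omega",
    "sigma",
    "other",
)


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Atom:
    """A single atom: name, element symbol, position in Å, occupancy."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"atom coord must be a 3-vector, got {self.coord.shape}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name!r}")
        if not self.element:
            raise ValueError(f"empty element symbol for atom {self.name!r}")
        self.element = self.element.strip().upper()


@dataclass
class Residue:
    """A residue under author numbering; at most one atom per atom name."""

    name: str
    number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def calpha(self) -> Optional[Atom]:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class StructureModel:
    """One coordinate model of a (multi-chain) complex."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    model_number: int = 1

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in model {self.id!r}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model {self.id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


class SubunitMap:
    """Mapping from subunit role to one or more chain ids.

    A role may map to several chains (homodimers, dimeric assemblies); a
    chain belongs to at most one role.
    """

    def __init__(self, role_to_chains: Mapping[str, Sequence[str]]):
        self._map: dict[str, tuple[str, ...]] = {}
        seen: dict[str, str] = {}
        for role, chains in role_to_chains.items():
            if isinstance(chains, str):
                chains = [chains]
            chains = tuple(str(c) for c in chains)
            for cid in chains:
                if cid in seen:
                    raise ValueError(
                        f"chain {cid!r} mapped to both {seen[cid]!r} and {role!r}"
                    )
                seen[cid] = role
            self._map[str(role)] = chains

    def chains_for(self, role: str) -> tuple[str, ...]:
        return self._map.get(role, ())

    def role_of(self, chain_id: str) -> Optional[str]:
        for role, chains in self._map.items():
            if chain_id in chains:
                return role
        return None

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self._map)

    def items(self):
        return self._map.items()

    def validate(self, model: StructureModel) -> None:
        """Every mapped chain id must exist in *model*."""
        missing = [
            cid
            for chains in self._map.values()
            for cid in chains
            if cid not in model.chain_ids
        ]
        if missing:
            raise ValueError(f"mapped chains absent from model: {missing}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SubunitMap":
        """Load a role -> chain-id-list mapping from a YAML/plain-text file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a role -> chain-ids mapping")
        return cls(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({r: list(c) for r, c in self._map.items()}, fh)


# Bondi-type van der Waals radii (Å). Metals that occur in RNAP deposits
# (Mg, Zn) are included; unknown elements fall back to the default radius.
DEFAULT_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "MG": 1.73,
    "ZN": 1.39,
    "FE": 1.40,
    "MN": 1.40,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
}


@dataclass
class RadiiTable:
    """Element -> van der Waals radius (Å) plus probe radius for SASA."""

    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    default_radius: float = 1.70
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        if self.default_radius <= 0 or self.probe_radius <= 0:
            raise ValueError("radii must be positive")
        for el, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"non-positive radius for element {el!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RadiiTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        radii = {k.upper(): float(v) for k, v in data.get("radii", {}).items()}
        return cls(
            radii=radii or dict(DEFAULT_RADII),
            default_radius=float(data.get("default_radius", 1.70)),
            probe_radius=float(data.get("probe_radius", 1.4)),
        )


def assign_radius(atom: Atom, radii: RadiiTable) -> tuple[float, bool]:
    """Return (van der Waals radius in Å, excluded flag).

    Hydrogens are flagged excluded; unknown elements get the table default.
    """
    excluded = atom.element in ("H", "D")
    return radii.radii.get(atom.element, radii.default_radius), excluded


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations to the highest-occupancy conformer.

    Ties break toward the first occurrence in file order.
    """
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in res:
        if at.name not in by_name:
            by_name[at.name] = at
            order.append(at.name)
        elif at.occ > by_name[at.name].occ:
            by_name[at.name] = at
    return [by_name[n] for n in order]


def read_structure(
    path: str | Path,
    format: str = "auto",
    *,
    include_waters: bool = False,
    label: Optional[str] = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first coordinate model is kept; author residue numbering is
    preserved. Waters are excluded unless ``include_waters``; altlocs are
    resolved to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise StructureParseError(f"empty coordinate file: {path}")
    fmt = format.lower()
    if fmt not in ("pdb", "mmcif", "auto"):
        raise StructureParseError(f"unknown format {format!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no coordinate model in {path}")
    st.setup_entities()
    gmodel = st[0]

    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if not include_waters and gres.name in _WATER_NAMES:
                continue
            atoms = [
                Atom(
                    name=at.name,
                    element=at.element.name or "X",
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    is_hetero=gres.het_flag == "H",
                )
                for at in _pick_altloc(gres)
            ]
            if not atoms:
                continue
            residues.append(
                Residue(
                    name=gres.name,
                    number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    atoms=atoms,
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise StructureParseError(f"no atoms parsed from {path}")
    model_number = getattr(gmodel, "num", None) or 1
    return StructureModel(
        id=label or st.name or path.stem, chains=chains, model_number=model_number
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a single-model PDB file (round-trip safe)."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model(model.model_number)
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gr.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    doc_path = str(Path(path))
    st.write_pdb(doc_path)


def get_calpha(
    model: StructureModel, chain_id: str, resnum: int, insertion_code: str = ""
) -> Optional[np.ndarray]:
    """Cα coordinate of a residue, or None if the residue/Cα is unmodeled.

    Never substitutes another atom; an unknown chain raises ``KeyError``.
    """
    chain = model.chain(chain_id)  # KeyError for unknown chain
    res = chain.residue(resnum, insertion_code)
    if res is None:
        return None
    ca = res.calpha
    if ca is None:
        return None
    return ca.coord
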