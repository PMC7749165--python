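"""Rigid-body superposition, RMSD, and named-residue distance measurements.

Superposition uses the Kabsch closed-form least-squares solution: for
paired point sets A (reference) and B (mobile), the optimal proper
rotation comes from the SVD of the cross-covariance of the centred sets,
with the determinant sign corrected so no reflection is introduced.
RMSD is the post-fit root-mean-square deviation over the paired atoms.

Named distances implement conformation metrics of the kind used to
describe RNA polymerase channel geometry — e.g. the main-channel width
between the β2 lobe (P242) and the β′ clamp helices (N283), or the RNA
exit tunnel between β flap R800 and β′ lid D245 — and channel-width
deltas compare such a distance across two structures through a residue
equivalence (shared numbering, superposition-derived nearest Cα, or a
user-supplied mapping file).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import StructureModel, SubunitMap

__all__ = [
    "Superposition",
    "ResidueEquivalence",
    "pair_by_residue",
    "kabsch_superpose",
    "superpose_structures",
    "named_distance",
    "channel_width_delta",
    "equivalence_by_superposition",
]


@dataclass
class Superposition:
    """Least-squares rigid transform of B onto A with the post-fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    atom_selection: str = "calpha"

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ResidueEquivalence:
    """One-to-one residue pairing between two structures."""

    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    provenance: str = "by_number"  # by_number | by_superposition | user_file

    def __post_init__(self) -> None:
        lhs = [p[0] for p in self.pairs]
        rhs = [p[1] for p in self.pairs]
        if len(set(lhs)) != len(lhs) or len(set(rhs)) != len(rhs):
            raise ValueError("residue equivalence is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def map_site(self, chain: str, resnum: int) -> Optional[tuple[str, int]]:
        for (ca, ra), (cb, rb) in self.pairs:
            if ca == chain and ra == resnum:
                return cb, rb
        return None

    @classmethod
    def from_file(cls, path: str | Path) -> "ResidueEquivalence":
        """4-column delimited text: chain_a resnum_a chain_b resnum_b."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                ca, ra, cb, rb = line.split()[:4]
                pairs.append(((ca, int(ra)), (cb, int(rb))))
        return cls(pairs=pairs, provenance="user_file")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# chain_a resnum_a chain_b resnum_b\n")
            for (ca, ra), (cb, rb) in self.pairs:
                fh.write(f"{ca}\t{ra}\t{cb}\t{rb}\n")


def pair_by_residue(
    model_a: StructureModel,
    model_b: StructureModel,
    submap_a: SubunitMap,
    submap_b: SubunitMap,
    atom_selection: str = "calpha",
) -> ResidueEquivalence:
    """Pair residues sharing a subunit role and author number in both models.

    Only residues that carry the selected atoms (Cα for 'calpha'; any
    heavy atom for 'all_heavy') on both sides are paired. Roles mapping to
    several chains pair chains positionally (first with first, ...).
    """
    pairs = []
    shared_roles = [r for r in submap_a.roles if submap_b.chains_for(r)]
    for role in shared_roles:
        for cid_a, cid_b in zip(submap_a.chains_for(role), submap_b.chains_for(role)):
            chain_a = model_a.chain(cid_a)
            chain_b = model_b.chain(cid_b)
            b_index = {(r.number, r.insertion_code): r for r in chain_b.residues}
            for res_a in chain_a.residues:
                res_b = b_index.get((res_a.number, res_a.insertion_code))
                if res_b is None:
                    continue
                if atom_selection == "calpha":
                    ok = res_a.calpha is not None and res_b.calpha is not None
                else:
                    ok = any(a.element != "H" for a in res_a.atoms) and any(
                        a.element != "H" for a in res_b.atoms
                    )
                if ok:
                    pairs.append(((cid_a, res_a.number), (cid_b, res_b.number)))
    if not pairs:
        raise ValueError("no shared residues to pair")
    return ResidueEquivalence(pairs=pairs, provenance="by_number")


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray, atom_selection: str = "calpha"
) -> Superposition:
    """Optimal least-squares rigid superposition of B onto A (Kabsch).

    Requires >= 3 non-collinear point pairs. Returns a proper rotation
    (det +1) even when a reflection would fit better, plus the post-fit
    RMSD. Deterministic.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"need matching (n, 3) arrays, got {A.shape} and {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 point pairs, got {n}")
    cen_a = A.mean(axis=0)
    cen_b = B.mean(axis=0)
    A0 = A - cen_a
    B0 = B - cen_b
    # Collinearity: rank of the centred cloud < 2 leaves the rotation
    # underdetermined about the line.
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_a - R @ cen_b
    fitted = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - A) ** 2, axis=1))))
    return Superposition(
        rotation=R, translation=t, rmsd=rmsd, n_pairs=n, atom_selection=atom_selection
    )


def _equivalenced_coords(
    model_a: StructureModel,
    model_b: StructureModel,
    equivalence: ResidueEquivalence,
    atom_selection: str,
) -> tuple[np.ndarray, np.ndarray]:
    xa, xb = [], []
    for (cid_a, num_a), (cid_b, num_b) in equivalence.pairs:
        res_a = model_a.chain(cid_a).residue(num_a)
        res_b = model_b.chain(cid_b).residue(num_b)
        if res_a is None or res_b is None:
            continue
        if atom_selection == "calpha":
            ca_a, ca_b = res_a.calpha, res_b.calpha
            if ca_a is not None and ca_b is not None:
                xa.append(ca_a.coord)
                xb.append(ca_b.coord)
        else:  # all_heavy: pair atoms by name
            b_atoms = {a.name: a for a in res_b.atoms if a.element != "H"}
            for at in res_a.atoms:
                if at.element == "H":
                    continue
                other = b_atoms.get(at.name)
                if other is not None:
                    xa.append(at.coord)
                    xb.append(other.coord)
    if not xa:
        raise ValueError("equivalence yields no atom pairs")
    return np.asarray(xa), np.asarray(xb)


def superpose_structures(
    model_a: StructureModel,
    model_b: StructureModel,
    equivalence: ResidueEquivalence,
    atom_selection: str = "calpha",
) -> Superposition:
    """Kabsch superposition of model_b onto model_a over an equivalence."""
    xa, xb = _equivalenced_coords(model_a, model_b, equivalence, atom_selection)
    return kabsch_superpose(xa, xb, atom_selection=atom_selection)


def _resolve_site(
    model: StructureModel,
    submap: SubunitMap,
    site: tuple[str, int] | tuple[str, int, str],
) -> list[tuple[str, np.ndarray]]:
    """All (chain_id, coord) candidates for a (role, resnum[, atom]) site."""
    role, resnum = site[0], site[1]
    atom_name = site[2] if len(site) > 2 else "CA"
    chains = submap.chains_for(role) or (
        (role,) if role in model.chain_ids else ()
    )
    found = []
    for cid in chains:
        res = model.chain(cid).residue(resnum)
        if res is None:
            continue
        at = res.atom(atom_name)
        if at is not None:
            found.append((cid, at.coord))
    if not found:
        raise KeyError(
            f"site {role}:{resnum}:{atom_name} unresolvable; "
            f"candidate chains {list(chains) or 'none'}"
        )
    return found


def named_distance(
    model: StructureModel,
    submap: SubunitMap,
    site_a: tuple[str, int] | tuple[str, int, str],
    site_b: tuple[str, int] | tuple[str, int, str],
    *,
    return_all: bool = False,
):
    """Euclidean distance (Å) between two named sites, default atom Cα.

    With ambiguous chains every combination is evaluated; the minimum is
    the primary value. ``return_all`` also yields the full combination
    list as (chain_a, chain_b, distance) tuples.
    """
    cand_a = _resolve_site(model, submap, site_a)
    cand_b = _resolve_site(model, submap, site_b)
    combos = [
        (ca, cb, float(np.linalg.norm(pa - pb)))
        for ca, pa in cand_a
        for cb, pb in cand_b
        if not (ca == cb and site_a[1] == site_b[1])
    ]
    if not combos:
        raise KeyError("no valid site combination")
    primary = min(c[2] for c in combos)
    if return_all:
        return primary, combos
    return primary


def channel_width_delta(
    model_a: StructureModel,
    model_b: StructureModel,
    submap_a: SubunitMap,
    submap_b: SubunitMap,
    site_pair_a: tuple[tuple, tuple],
    equivalence: Optional[ResidueEquivalence] = None,
) -> float:
    """Width difference of a named site pair between two structures (Å).

    Measures the distance in model_a, maps both sites into model_b (same
    role/number by default, or through a residue equivalence keyed on
    model_a chains), and returns distance_a − distance_b. Positive means
    wider in model_a.
    """
    site_a1, site_a2 = site_pair_a
    d_a = named_distance(model_a, submap_a, site_a1, site_a2)
    if equivalence is None:
        site_b1, site_b2 = site_a1, site_a2
        d_b = named_distance(model_b, submap_b, site_b1, site_b2)
    else:
        mapped_sites = []
        for site in (site_a1, site_a2):
            cands = _resolve_site(model_a, submap_a, site)
            chain_a = cands[0][0]
            target = equivalence.map_site(chain_a, site[1])
            if target is None:
                raise KeyError(
                    f"site {site[0]}:{site[1]} has no equivalent in the target model"
                )
            mapped_sites.append(target)
        (cb1, rb1), (cb2, rb2) = mapped_sites
        p1 = model_b.chain(cb1).residue(rb1)
        p2 = model_b.chain(cb2).residue(rb2)
        if p1 is None or p1.calpha is None or p2 is None or p2.calpha is None:
            raise KeyError("equivalenced site lacks a modeled CA in the target model")
        d_b = float(np.linalg.norm(p1.calpha.coord - p2.calpha.coord))
    return d_a - d_b


def equivalence_by_superposition(
    model_a: StructureModel,
    model_b: StructureModel,
    submap_a: SubunitMap,
    submap_b: SubunitMap,
    anchor_roles: Sequence[str],
    cutoff: float = 3.5,
) -> ResidueEquivalence:
    """Structure-based residue equivalence via anchored superposition.

    Superposes model_b onto model_a on the shared-numbered Cα atoms of the
    anchor roles (e.g. the β subunit), then pairs each Cα of model_a with
    the nearest Cα of the transformed model_b within ``cutoff`` Å. Matching
    is greedy nearest-first and one-to-one; ties break toward the lower
    residue number of model_a.
    """
    anchor_map_a = SubunitMap({r: submap_a.chains_for(r) for r in anchor_roles})
    anchor_map_b = SubunitMap({r: submap_b.chains_for(r) for r in anchor_roles})
    anchor_eq = pair_by_residue(model_a, model_b, anchor_map_a, anchor_map_b)
    sup = superpose_structures(model_a, model_b, anchor_eq)

    sites_a, coords_a = [], []
    for chain in model_a.chains:
        for res in chain.residues:
            if res.calpha is not None:
                sites_a.append((chain.chain_id, res.number))
                coords_a.append(res.calpha.coord)
    sites_b, coords_b = [], []
    for chain in model_b.chains:
        for res in chain.residues:
            if res.calpha is not None:
                sites_b.append((chain.chain_id, res.number))
                coords_b.append(res.calpha.coord)
    coords_a = np.asarray(coords_a)
    coords_b = sup.apply(np.asarray(coords_b))

    tree = cKDTree(coords_b)
    # Candidate edges within cutoff, greedily matched nearest-first;
    # tie-break by lower model_a residue number, then model_b number.
    edges = []
    for ia, pa in enumerate(coords_a):
        for ib in tree.query_ball_point(pa, cutoff):
            d = float(np.linalg.norm(pa - coords_b[ib]))
            edges.append((d, sites_a[ia][1], sites_b[ib][1], ia, ib))
    edges.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, _, _, ia, ib in edges:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((sites_a[ia], sites_b[ib]))
    pairs.sort()
    return ResidueEquivalence(pairs=pairs, provenance="by_superposition")
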