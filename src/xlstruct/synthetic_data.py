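"""Synthetic structures and simulated sulfo-SDA crosslink sets.

The generator builds toy multi-chain complexes (ideal helices or straight
strands, optionally with a hinged chain whose distal half rotates away
from the rest of the complex by a configurable opening angle) and draws
crosslink tables from them with known ground truth: a controlled fraction
of planted over-length pairs, optional NHS-ester reactivity restriction
(one site K/S/T/Y or N-terminus, as for sulfo-SDA), and FDR values below
the conventional 5% threshold.

The point of the toys is statistical structure, not molecular realism:
they let every stage of the distance analysis be exercised against
parameters that are known by construction. The hinge mimics clamp-like
domain opening — crosslinks generated on the closed (0°) conformation
become over-length when mapped onto progressively opened copies, the
desk-scale analogue of probing an open complex with links formed in more
compact conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure_model import Atom, Chain, Residue, StructureModel, SubunitMap
from .xlink_table import Crosslink, CrosslinkSet

__all__ = [
    "ToyComplexSpec",
    "SimulatedCrosslinkSet",
    "make_toy_complex",
    "simulate_crosslinks",
]

# Ideal-helix CA trace parameters: 1.5 Å rise and 100 deg twist per
# residue on a 2.3 Å helical radius; strands use a 3.8 Å CA-CA step.
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
STRAND_STEP = 3.8

#: Residue-name cycle; 4 of 10 are NHS-reactive (K/S/T/Y).
_RESNAME_CYCLE = ("LYS", "ALA", "SER", "LEU", "THR", "GLY", "TYR", "GLU", "VAL", "ASP")

_REACTIVE = {"LYS", "SER", "THR", "TYR"}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Blueprint for a deterministic toy complex.

    chains : sequence of (role, n_residues, geometry) with geometry in
        {'ideal_helix', 'straight_strand'}; chains are laid side by side
        along x with ``chain_spacing`` Å between axes.
    hinge : optional (role, split_residue_index, opening_angle_deg); the
        part of that role's chain from the split index on rotates as a
        rigid body about an axis through the split-point CA, swinging
        away from the neighbouring chains.
    """

    chains: tuple[tuple[str, int, str], ...]
    hinge: Optional[tuple[str, int, float]] = None
    chain_spacing: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("toy complex needs at least one chain")
        for role, n, geom in self.chains:
            if n < 2:
                raise ValueError(f"chain {role!r}: need >= 2 residues, got {n}")
            if geom not in ("ideal_helix", "straight_strand"):
                raise ValueError(f"unknown geometry {geom!r}")
        if self.hinge is not None:
            role, split, angle = self.hinge
            if not (0.0 <= angle <= 180.0):
                raise ValueError(f"opening angle must be in [0, 180], got {angle}")
            if role not in [c[0] for c in self.chains]:
                raise ValueError(f"hinge role {role!r} not among chains")


@dataclass
class SimulatedCrosslinkSet:
    """A crosslink set plus per-link ground truth."""

    xset: CrosslinkSet
    truth: pd.DataFrame  # columns: true_distance, is_planted_violation

    def __len__(self) -> int:
        return len(self.xset)


def _chain_trace(n: int, geometry: str) -> np.ndarray:
    i = np.arange(n, dtype=float)
    if geometry == "ideal_helix":
        theta = np.deg2rad(HELIX_TWIST_DEG) * i
        return np.column_stack(
            [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
        )
    return np.column_stack([np.zeros(n), np.zeros(n), STRAND_STEP * i])


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def make_toy_complex(spec: ToyComplexSpec) -> tuple[StructureModel, SubunitMap]:
    """Build a deterministic CA-trace complex from a toy blueprint.

    Chain k sits at x = k * chain_spacing; each chain is rotated about its
    own axis by a seeded random phase so the arrangement is generic rather
    than symmetric. The hinged chain's distal body rotates about the y
    axis through its split-point CA, toward -x — away from the
    higher-index neighbouring chains — by the opening angle.
    """
    rng = np.random.default_rng(spec.seed)
    chains: list[Chain] = []
    role_map: dict[str, list[str]] = {}
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for k, (role, n_res, geometry) in enumerate(spec.chains):
        coords = _chain_trace(n_res, geometry)
        phase = rng.uniform(0, 2 * np.pi)
        Rz = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), phase)
        coords = coords @ Rz.T
        coords[:, 0] += k * spec.chain_spacing
        if spec.hinge is not None and spec.hinge[0] == role:
            _, split, angle = spec.hinge
            if not (0 < split < n_res):
                raise ValueError(f"hinge split {split} outside chain of {n_res}")
            if angle != 0.0:  # 0 deg is the exact identity, bit-for-bit
                pivot = coords[split].copy()
                R = _rotation_about_axis(np.array([0.0, 1.0, 0.0]), -np.deg2rad(angle))
                coords[split:] = (coords[split:] - pivot) @ R.T + pivot
        cid = chain_letters[k % len(chain_letters)]
        residues = [
            Residue(
                name=_RESNAME_CYCLE[i % len(_RESNAME_CYCLE)],
                number=i + 1,
                atoms=[Atom(name="CA", element="C", coord=coords[i])],
            )
            for i in range(n_res)
        ]
        chains.append(Chain(chain_id=cid, residues=residues))
        role_map.setdefault(role, []).append(cid)
    model = StructureModel(id=f"toy-{spec.seed}", chains=chains)
    return model, SubunitMap(role_map)


def _eligible_pairs(
    model: StructureModel, submap: SubunitMap, reactivity: bool
) -> tuple[list[tuple], np.ndarray]:
    """All unordered residue pairs with a modeled CA (optionally one side
    NHS-reactive), with their Cα–Cα distances."""
    sites = []  # (role, chain_id, resnum, coord, reactive)
    for chain in model.chains:
        role = submap.role_of(chain.chain_id) or chain.chain_id
        first = True
        for res in chain.residues:
            if res.calpha is None:
                continue
            sites.append(
                (role, chain.chain_id, res.number, res.calpha.coord,
                 first or res.name in _REACTIVE)
            )
            first = False
    coords = np.asarray([s[3] for s in sites])
    reactive = np.asarray([s[4] for s in sites])
    n = len(sites)
    ii, jj = np.triu_indices(n, k=1)
    if reactivity:
        mask = reactive[ii] | reactive[jj]
        ii, jj = ii[mask], jj[mask]
    dists = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    pairs = [(sites[a], sites[b]) for a, b in zip(ii, jj)]
    return pairs, dists


def simulate_crosslinks(
    model: StructureModel,
    submap: SubunitMap,
    n: int,
    d_max: float = 25.0,
    violation_fraction: float = 0.0,
    reactivity: bool = False,
    seed: int = 0,
    complex_label: str = "simulated",
) -> SimulatedCrosslinkSet:
    """Draw a crosslink table with a planted over-length fraction.

    round((1-f)*n) links come uniformly from residue pairs with Cα–Cα
    distance <= d_max in the generating conformation and round(f*n) from
    pairs beyond it. FDR values are uniform in (0, 0.05]; with
    ``reactivity`` one site of every eligible pair is K/S/T/Y or an
    N-terminus. Fully seeded and reproducible.
    """
    if not (0.0 <= violation_fraction <= 1.0):
        raise ValueError("violation_fraction must be in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    pairs, dists = _eligible_pairs(model, submap, reactivity)
    within_idx = np.flatnonzero(dists <= d_max)
    over_idx = np.flatnonzero(dists > d_max)
    n_over = int(round(violation_fraction * n))
    n_within = n - n_over
    if n_within > len(within_idx):
        raise ValueError(
            f"within-limit stratum has only {len(within_idx)} pairs, need {n_within}"
        )
    if n_over > len(over_idx):
        raise ValueError(
            f"over-length stratum has only {len(over_idx)} pairs, need {n_over}"
        )
    chosen_within = rng.choice(within_idx, size=n_within, replace=False)
    chosen_over = rng.choice(over_idx, size=n_over, replace=False)
    chosen = np.concatenate([chosen_within, chosen_over])
    violation = np.concatenate(
        [np.zeros(n_within, dtype=bool), np.ones(n_over, dtype=bool)]
    )
    order = rng.permutation(n)
    chosen, violation = chosen[order], violation[order]

    links, rows = [], []
    for idx, is_viol in zip(chosen, violation):
        (role_a, _, num_a, _, _), (role_b, _, num_b, _, _) = pairs[idx]
        links.append(
            Crosslink(
                protein_a=role_a,
                resnum_a=int(num_a),
                protein_b=role_b,
                resnum_b=int(num_b),
                # same role+number on two chains of a homodimer looks like
                # a self link at the residue-pair level
                is_self_link=(role_a == role_b and num_a == num_b),
                score=float(rng.uniform(5.0, 20.0)),
                fdr=float(rng.uniform(0.0, 0.05)),
                complex_label=complex_label,
            )
        )
        rows.append(
            {"true_distance": float(dists[idx]), "is_planted_violation": bool(is_viol)}
        )
    return SimulatedCrosslinkSet(
        xset=CrosslinkSet(complex_label=complex_label, links=links),
        truth=pd.DataFrame(rows),
    )
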