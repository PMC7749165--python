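"""Crosslink distance validation against a reference structure.

Sulfo-SDA, a heterobifunctional photo-crosslinker, bridges residues whose
Cα atoms lie within a theoretical limit of 25 Å. Mapping identified
crosslinks onto a reference structure and classifying each pair's Cα–Cα
distance against that limit separates links compatible with the modeled
conformation ("within") from over-length links that report on alternative
conformations sampled in solution. A null distribution of distances over
random residue pairs in the same structure calibrates what "random" looks
like, and region-pair counting (e.g. β1/2 lobes against the β′ shelf/jaw
across the main channel) localises where conformational differences
concentrate.

All distances are Cα–Cα; residues without a modeled Cα are reported as
unmapped, never imputed. Where a subunit role maps to several chains
(homodimers), every role-consistent chain combination is evaluated and the
minimum distance is assigned — the conservative convention of
crosslinking-MS practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure_model import StructureModel, SubunitMap, get_calpha
from .xlink_table import Crosslink, CrosslinkSet, deduplicate

__all__ = [
    "AnalysisConfig",
    "MappedCrosslink",
    "NullDistribution",
    "RegionDef",
    "RegionPairCounts",
    "ComplexComparison",
    "map_crosslinks",
    "classify",
    "overlength_fraction",
    "random_pair_null",
    "region_pair_counts",
    "compare_complexes",
]

#: One-letter-coded residue names whose side chains (or the N-terminus)
#: carry the NHS-ester-reactive groups of sulfo-SDA: Lys, Ser, Thr, Tyr.
NHS_REACTIVE_RESNAMES = frozenset({"LYS", "SER", "THR", "TYR"})


@dataclass
class AnalysisConfig:
    """Parameters of the distance analysis.

    distance_limit : Å, theoretical crosslinker Cα–Cα limit (sulfo-SDA: 25).
    null_mode : 'exhaustive' enumerates every unordered residue pair with a
        modeled Cα; 'sampled' draws a seeded uniform sample of that universe.
    reactivity_restricted_null : restrict the null to pairs where at least
        one side is NHS-reactive (K/S/T/Y or the chain N-terminus).
    """

    distance_limit: float = 25.0
    null_mode: str = "exhaustive"
    null_sample_size: int = 100_000
    reactivity_restricted_null: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_limit <= 0:
            raise ValueError("distance_limit must be positive")
        if self.null_mode not in ("exhaustive", "sampled"):
            raise ValueError(f"unknown null_mode {self.null_mode!r}")
        if self.null_mode == "sampled" and self.null_sample_size <= 0:
            raise ValueError("null_sample_size must be positive in sampled mode")


@dataclass
class MappedCrosslink:
    """A crosslink resolved onto the reference structure."""

    link: Crosslink
    chain_a: Optional[str]
    chain_b: Optional[str]
    distance: Optional[float]
    klass: str  # within | over_length | unmapped
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.distance is None) != (self.klass == "unmapped"):
            raise ValueError("distance must be present iff the link is mapped")


@dataclass
class NullDistribution:
    distances: np.ndarray
    mode: str
    seed: Optional[int]
    reactivity_restricted: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class RegionDef:
    """A named set of author-number intervals on one subunit role."""

    label: str
    role: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError(f"region {self.label!r} has no ranges")
        for lo, hi in self.ranges:
            if lo > hi:
                raise ValueError(f"region {self.label!r}: empty range {lo}-{hi}")

    def contains(self, role: str, resnum: int) -> bool:
        return self.role == role and any(lo <= resnum <= hi for lo, hi in self.ranges)


@dataclass
class RegionPairCounts:
    """Symmetric unique-link counts between regions, plus an 'other' bin."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    n_other: int

    def count(self, label_i: str, label_j: str) -> int:
        i = self.labels.index(label_i)
        j = self.labels.index(label_j)
        return int(self.matrix[i, j])


@dataclass
class ComplexComparison:
    """Fig-style per-complex summary table across crosslinked samples."""

    table: pd.DataFrame
    region_counts: dict[str, RegionPairCounts] = field(default_factory=dict)


def _resolve_protein(link_protein: str, submap: SubunitMap) -> tuple[str, ...]:
    """Chains consistent with a link's protein name (role or chain id)."""
    chains = submap.chains_for(link_protein)
    return chains


def map_crosslinks(
    xset: CrosslinkSet,
    model: StructureModel,
    submap: SubunitMap,
    cfg: AnalysisConfig,
) -> list[MappedCrosslink]:
    """Resolve each crosslink to Cα coordinates and a distance class.

    Every chain combination consistent with the two protein roles is
    evaluated and the minimum Cα–Cα distance assigned, with the chosen
    chain pair recorded. Links to proteins absent from the subunit map, or
    to residues without a modeled Cα, come back as klass='unmapped' with a
    reason string.
    """
    submap.validate(model)
    out: list[MappedCrosslink] = []
    for link in xset:
        chains_a = _resolve_protein(link.protein_a, submap)
        chains_b = _resolve_protein(link.protein_b, submap)
        if not chains_a or not chains_b:
            missing = [
                p
                for p, ch in ((link.protein_a, chains_a), (link.protein_b, chains_b))
                if not ch
            ]
            out.append(
                MappedCrosslink(
                    link, None, None, None, "unmapped",
                    reason=f"protein(s) not in subunit map: {missing}",
                )
            )
            continue
        best: Optional[tuple[float, str, str]] = None
        for ca_chain in chains_a:
            pa = get_calpha(model, ca_chain, link.resnum_a)
            if pa is None:
                continue
            for cb_chain in chains_b:
                if ca_chain == cb_chain and link.resnum_a == link.resnum_b:
                    continue
                pb = get_calpha(model, cb_chain, link.resnum_b)
                if pb is None:
                    continue
                d = float(np.linalg.norm(pa - pb))
                if best is None or d < best[0]:
                    best = (d, ca_chain, cb_chain)
        if best is None:
            out.append(
                MappedCrosslink(
                    link, None, None, None, "unmapped",
                    reason="residue or CA not modeled",
                )
            )
            continue
        d, cha, chb = best
        klass = "within" if d <= cfg.distance_limit else "over_length"
        out.append(MappedCrosslink(link, cha, chb, d, klass))
    return out


def classify(mapped: MappedCrosslink, cfg: AnalysisConfig) -> str:
    """Distance class of a mapped link; the boundary d == limit is 'within'."""
    if mapped.distance is None:
        raise ValueError("cannot classify an unmapped crosslink")
    return "within" if mapped.distance <= cfg.distance_limit else "over_length"


def overlength_fraction(mapped: Sequence[MappedCrosslink]) -> float:
    """Fraction of mapped links that exceed the distance limit."""
    n_within = sum(1 for m in mapped if m.klass == "within")
    n_over = sum(1 for m in mapped if m.klass == "over_length")
    if n_within + n_over == 0:
        raise ValueError("no mapped crosslinks: over-length fraction undefined")
    return n_over / (n_within + n_over)


def _calpha_table(
    model: StructureModel, submap: Optional[SubunitMap] = None
) -> tuple[np.ndarray, np.ndarray]:
    """All modeled Cα coordinates and a reactivity mask (K/S/T/Y/N-term)."""
    coords: list[np.ndarray] = []
    reactive: list[bool] = []
    for chain in model.chains:
        first = True
        for res in chain.residues:
            ca = res.calpha
            if ca is None:
                continue
            coords.append(ca.coord)
            reactive.append(first or res.name in NHS_REACTIVE_RESNAMES)
            first = False
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=bool)
    return np.asarray(coords), np.asarray(reactive, dtype=bool)


def random_pair_null(
    model: StructureModel,
    submap: Optional[SubunitMap] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> NullDistribution:
    """Cα–Cα distance distribution over random residue pairs.

    Exhaustive mode enumerates every unordered pair of residues with a
    modeled Cα (intra- and inter-chain); sampled mode draws a seeded
    uniform sample of that pair universe without replacement. With
    ``reactivity_restricted_null`` the universe shrinks to pairs where at
    least one side could carry the NHS-ester end (K/S/T/Y or N-terminus).
    """
    cfg = cfg or AnalysisConfig()
    coords, reactive = _calpha_table(model, submap)
    n = len(coords)
    if n < 2:
        raise ValueError(f"need >= 2 residues with CA for the null, got {n}")
    ii, jj = np.triu_indices(n, k=1)
    if cfg.reactivity_restricted_null:
        mask = reactive[ii] | reactive[jj]
        ii, jj = ii[mask], jj[mask]
        if len(ii) == 0:
            raise ValueError("no reactivity-eligible residue pairs")
    n_universe = len(ii)
    if cfg.null_mode == "sampled":
        k = min(cfg.null_sample_size, n_universe)
        rng = np.random.default_rng(cfg.seed)
        pick = rng.choice(n_universe, size=k, replace=False)
        ii, jj = ii[pick], jj[pick]
    d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    return NullDistribution(
        distances=d,
        mode=cfg.null_mode,
        seed=cfg.seed if cfg.null_mode == "sampled" else None,
        reactivity_restricted=cfg.reactivity_restricted_null,
    )


def _check_regions(regions: Sequence[RegionDef]) -> None:
    by_role: dict[str, list[RegionDef]] = {}
    for r in regions:
        by_role.setdefault(r.role, []).append(r)
    for role, rs in by_role.items():
        spans = [(lo, hi, r.label) for r in rs for lo, hi in r.ranges]
        spans.sort()
        for (lo1, hi1, l1), (lo2, hi2, l2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(
                    f"regions {l1!r} and {l2!r} overlap on role {role!r}"
                )


def region_pair_counts(
    mapped: Sequence[MappedCrosslink],
    regions: Sequence[RegionDef],
    submap: SubunitMap,
) -> RegionPairCounts:
    """Count unique mapped links with one site in region i, the other in j.

    Symmetric storage; links outside every region fall into the 'other'
    bin. Overlapping regions on one role are a configuration error.
    """
    _check_regions(regions)
    labels = tuple(r.label for r in regions)
    k = len(regions)
    mat = np.zeros((k, k), dtype=int)
    n_other = 0
    seen: set = set()
    for m in mapped:
        if m.klass == "unmapped":
            continue
        key = m.link.pair_key
        if key in seen:
            continue
        seen.add(key)
        role_a = submap.role_of(m.chain_a) or m.link.protein_a
        role_b = submap.role_of(m.chain_b) or m.link.protein_b
        idx_a = next(
            (i for i, r in enumerate(regions) if r.contains(role_a, m.link.resnum_a)),
            None,
        )
        idx_b = next(
            (i for i, r in enumerate(regions) if r.contains(role_b, m.link.resnum_b)),
            None,
        )
        if idx_a is None or idx_b is None:
            n_other += 1
            continue
        mat[idx_a, idx_b] += 1
        if idx_a != idx_b:
            mat[idx_b, idx_a] += 1
    return RegionPairCounts(labels=labels, matrix=mat, n_other=n_other)


def _role_pair_subset(
    mapped: Sequence[MappedCrosslink],
    submap: SubunitMap,
    role_x: str,
    role_y: str,
) -> list[MappedCrosslink]:
    out = []
    for m in mapped:
        if m.klass == "unmapped":
            continue
        ra = submap.role_of(m.chain_a) or m.link.protein_a
        rb = submap.role_of(m.chain_b) or m.link.protein_b
        if {ra, rb} == {role_x, role_y}:
            out.append(m)
    return out


def compare_complexes(
    sets: Sequence[CrosslinkSet],
    model: StructureModel,
    submap: SubunitMap,
    regions: Sequence[RegionDef],
    cfg: AnalysisConfig,
    *,
    subset_roles: tuple[str, str] = ("beta", "beta_prime"),
) -> ComplexComparison:
    """Per-complex crosslink summary against one reference structure.

    For each crosslinked sample: total links, mapped/within/over counts,
    the over-length fraction over all mapped links and over the β–β′
    subset (``subset_roles``), and the region-pair count matrix. Links are
    deduplicated to unique residue pairs before counting.
    """
    if not sets:
        raise ValueError("need at least one crosslink set")
    rows = []
    region_by_label: dict[str, RegionPairCounts] = {}
    for xset in sets:
        uniq = deduplicate(xset)
        mapped = map_crosslinks(uniq, model, submap, cfg)
        n_within = sum(1 for m in mapped if m.klass == "within")
        n_over = sum(1 for m in mapped if m.klass == "over_length")
        n_mapped = n_within + n_over
        sub = _role_pair_subset(mapped, submap, *subset_roles)
        n_sub = len(sub)
        n_sub_over = sum(1 for m in sub if m.klass == "over_length")
        rc = region_pair_counts(mapped, regions, submap)
        region_by_label[xset.complex_label] = rc
        row = {
            "label": xset.complex_label,
            "n_total": len(uniq),
            "n_mapped": n_mapped,
            "n_within": n_within,
            "n_over": n_over,
            "over_fraction": (n_over / n_mapped) if n_mapped else np.nan,
            "n_subset": n_sub,
            "n_subset_over": n_sub_over,
            "subset_over_fraction": (n_sub_over / n_sub) if n_sub else np.nan,
        }
        for i, li in enumerate(rc.labels):
            for j in range(i, len(rc.labels)):
                row[f"n[{li}|{rc.labels[j]}]"] = int(rc.matrix[i, j])
        row["n_region_other"] = rc.n_other
        rows.append(row)
    return ComplexComparison(
        table=pd.DataFrame(rows), region_counts=region_by_label
    )
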