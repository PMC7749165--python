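"""Crosslink residue-pair tables: reading, FDR filtering, deduplication.

The analysis unit throughout is the unique *unordered* residue pair
(protein_a, resnum_a) -- (protein_b, resnum_b), not the peptide-spectrum
match: identification and FDR estimation happen upstream (e.g. in an
xiSEARCH/xiFDR workflow) and this module only consumes their tabular
output. FDR filtering is plain thresholding of an existing residue-pair
FDR column, conventionally at 5%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "Crosslink",
    "CrosslinkSet",
    "DEFAULT_COLUMN_MAP",
    "read_crosslink_table",
    "write_crosslink_table",
    "filter_fdr",
    "deduplicate",
]

logger = logging.getLogger(__name__)

#: Default column names, matching common residue-pair FDR export headers.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "protein_a": "Protein1",
    "resnum_a": "Residue1",
    "protein_b": "Protein2",
    "resnum_b": "Residue2",
    "score": "Score",
    "fdr": "FDR",
}


@dataclass(frozen=True)
class Crosslink:
    """One crosslinked residue pair between two proteins (or within one)."""

    protein_a: str
    resnum_a: int
    protein_b: str
    resnum_b: int
    score: Optional[float] = None
    fdr: Optional[float] = None
    complex_label: str = ""
    is_self_link: bool = False

    def __post_init__(self) -> None:
        if self.resnum_a <= 0 or self.resnum_b <= 0:
            raise ValueError("residue numbers must be positive")
        if (
            not self.is_self_link
            and self.protein_a == self.protein_b
            and self.resnum_a == self.resnum_b
        ):
            raise ValueError(
                f"self-link {self.protein_a}:{self.resnum_a} without self-link flag"
            )

    @property
    def pair_key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Canonical unordered residue-pair identity."""
        a = (self.protein_a, self.resnum_a)
        b = (self.protein_b, self.resnum_b)
        return (a, b) if a <= b else (b, a)


@dataclass
class CrosslinkSet:
    """All crosslinks identified from one crosslinked complex sample."""

    complex_label: str
    links: list[Crosslink] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ln in self.links:
            if ln.complex_label and ln.complex_label != self.complex_label:
                raise ValueError(
                    f"link labelled {ln.complex_label!r} in set {self.complex_label!r}"
                )

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)


def read_crosslink_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    *,
    complex_label: str = "",
    sep: Optional[str] = None,
) -> CrosslinkSet:
    """Read a delimited residue-pair table into a :class:`CrosslinkSet`.

    ``column_map`` maps the logical fields (protein_a, resnum_a, protein_b,
    resnum_b, score, fdr) to header names in the file; score/fdr entries
    are optional. Rows whose residue numbers do not parse as positive
    integers are rejected, with the rejection count logged.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = ["protein_a", "resnum_a", "protein_b", "resnum_b"]
    missing = [cmap[k] for k in required if cmap[k] not in df.columns]
    if missing:
        raise KeyError(f"{path}: missing mapped columns {missing}")
    has_score = cmap.get("score") in df.columns
    has_fdr = cmap.get("fdr") in df.columns

    links: list[Crosslink] = []
    n_rejected = 0
    for _, row in df.iterrows():
        try:
            ra = int(row[cmap["resnum_a"]])
            rb = int(row[cmap["resnum_b"]])
            link = Crosslink(
                protein_a=str(row[cmap["protein_a"]]),
                resnum_a=ra,
                protein_b=str(row[cmap["protein_b"]]),
                resnum_b=rb,
                score=float(row[cmap["score"]]) if has_score else None,
                fdr=float(row[cmap["fdr"]]) if has_fdr else None,
                complex_label=complex_label,
            )
        except (ValueError, TypeError):
            n_rejected += 1
            continue
        links.append(link)
    if n_rejected:
        logger.warning("%s: rejected %d unparsable rows", path, n_rejected)
    if not links:
        warnings.warn(f"{path}: no crosslinks parsed", stacklevel=2)
    return CrosslinkSet(complex_label=complex_label, links=links)


def write_crosslink_table(
    xset: CrosslinkSet, path: str | Path, sep: str = "\t"
) -> None:
    """Write a crosslink set using the default export headers."""
    rows = [
        {
            "Protein1": ln.protein_a,
            "Residue1": ln.resnum_a,
            "Protein2": ln.protein_b,
            "Residue2": ln.resnum_b,
            "Score": ln.score,
            "FDR": ln.fdr,
        }
        for ln in xset.links
    ]
    pd.DataFrame(
        rows, columns=["Protein1", "Residue1", "Protein2", "Residue2", "Score", "FDR"]
    ).to_csv(path, sep=sep, index=False)


def filter_fdr(xset: CrosslinkSet, threshold: float = 0.05) -> CrosslinkSet:
    """Keep links with fdr <= threshold; links without an FDR pass (warned).

    Idempotent; preserves input order.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"FDR threshold must be in (0, 1], got {threshold}")
    n_missing = sum(1 for ln in xset.links if ln.fdr is None)
    if n_missing:
        warnings.warn(
            f"{xset.complex_label or 'crosslink set'}: {n_missing} links lack an FDR "
            "value and pass the filter unchecked",
            stacklevel=2,
        )
    kept = [ln for ln in xset.links if ln.fdr is None or ln.fdr <= threshold]
    return CrosslinkSet(complex_label=xset.complex_label, links=kept)


def deduplicate(xset: CrosslinkSet) -> CrosslinkSet:
    """Collapse to unique unordered residue pairs, keeping the lowest FDR.

    For duplicates the best (lowest) FDR and its score are retained; the
    first-seen orientation of the pair is kept. Idempotent.
    """
    best: dict[tuple, Crosslink] = {}
    order: list[tuple] = []
    for ln in xset.links:
        key = ln.pair_key
        if key not in best:
            best[key] = ln
            order.append(key)
        else:
            cur = best[key]
            cur_fdr = cur.fdr if cur.fdr is not None else float("inf")
            new_fdr = ln.fdr if ln.fdr is not None else float("inf")
            if new_fdr < cur_fdr:
                best[key] = replace(
                    cur, fdr=ln.fdr, score=ln.score
                )  # keep first orientation
    return CrosslinkSet(
        complex_label=xset.complex_label, links=[best[k] for k in order]
    )
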