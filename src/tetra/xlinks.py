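"""Cross-link derived distance restraints and interface maps.

Chemical cross-linking with DSS bridges lysine side chains; a detected
residue pair therefore constrains the side-chain anchor atoms to lie within
the linker span. Following the usual convention for DSS, restraints default
to a 3-24 Angstrom window between C-beta atoms (C-alpha for glycine),
configurable to C-alpha/C-alpha.

Cross-links on homodimeric molecules are ambiguous: the peptide evidence
cannot tell the two copies apart. Such links expand into OR-groups of
restraints, and a group counts as satisfied when ANY member is satisfied -
the same convention as the ambiguous interaction restraints consumed by
docking engines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .structio import AtomicModel, DomainMap

DEFAULT_BOUNDS = (3.0, 24.0)  # Angstrom, DSS window


class CrossLinkError(ValueError):
    pass


@dataclass(frozen=True)
class CrossLink:
    protein_1: str
    residue_1: int
    protein_2: str
    residue_2: int
    linker: str = "DSS"

    def __post_init__(self) -> None:
        if self.residue_1 < 1 or self.residue_2 < 1:
            raise CrossLinkError(
                f"residue indices must be >= 1 ({self.residue_1}, {self.residue_2})"
            )

    @property
    def kind(self) -> str:
        return "inter" if self.protein_1 != self.protein_2 else "intra"


@dataclass(frozen=True)
class Selector:
    """Residue-level anchor: (chain, residue, anchor rule)."""

    chain_id: str
    residue_index: int
    anchor: str = "CB"  # "CB" (C-alpha fallback for glycine) or "CA"


@dataclass(frozen=True)
class DistanceRestraint:
    selector_1: Selector
    selector_2: Selector
    lower_bound: float = DEFAULT_BOUNDS[0]
    upper_bound: float = DEFAULT_BOUNDS[1]
    group: int = 0  # members sharing a group are alternatives (OR)

    def __post_init__(self) -> None:
        if not (0 < self.lower_bound < self.upper_bound):
            raise CrossLinkError(
                f"need 0 < lower < upper, got ({self.lower_bound}, {self.upper_bound})"
            )


class CrossLinkTable(Sequence):
    """Parsed cross-links plus a summary of rejected rows."""

    def __init__(self, links: list[CrossLink], errors: list[str]):
        self.links = links
        self.errors = errors

    def __len__(self) -> int:
        return len(self.links)

    def __getitem__(self, i):
        return self.links[i]

    def __iter__(self) -> Iterator[CrossLink]:
        return iter(self.links)


_REQUIRED_COLUMNS = ("protein_1", "residue_1", "protein_2", "residue_2", "linker")


def load_crosslinks(path: str) -> CrossLinkTable:
    """Read a delimited cross-link table (comma or tab separated).

    The header must name protein_1, residue_1, protein_2, residue_2, linker.
    Malformed rows are collected into ``.errors``; a file with no parseable
    row raises.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CrossLinkError(f"missing columns: {missing}")
    links: list[CrossLink] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            links.append(
                CrossLink(
                    str(row["protein_1"]).strip(),
                    int(row["residue_1"]),
                    str(row["protein_2"]).strip(),
                    int(row["residue_2"]),
                    str(row["linker"]).strip(),
                )
            )
        except (CrossLinkError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if not links:
        raise CrossLinkError(f"no parseable cross-link rows in {path}: {errors}")
    return CrossLinkTable(links, errors)


def write_crosslinks(links: Sequence[CrossLink], path: str) -> None:
    df = pd.DataFrame(
        {
            "protein_1": [x.protein_1 for x in links],
            "residue_1": [x.residue_1 for x in links],
            "protein_2": [x.protein_2 for x in links],
            "residue_2": [x.residue_2 for x in links],
            "linker": [x.linker for x in links],
        }
    )
    df.to_csv(path, index=False)


def build_restraints(
    xls: Sequence[CrossLink],
    chain_assignment: Mapping[str, Sequence[str]],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    anchor: str = "CB",
) -> list[DistanceRestraint]:
    """One restraint per cross-link x chain-pair expansion.

    ``chain_assignment`` maps each protein id to the chain ids carrying a
    copy of it; a link touching a protein with several copies expands to all
    chain combinations under one ambiguity group.
    """
    restraints: list[DistanceRestraint] = []
    for g, xl in enumerate(xls):
        for pid in (xl.protein_1, xl.protein_2):
            if pid not in chain_assignment or not chain_assignment[pid]:
                raise CrossLinkError(f"protein {pid!r} has no chain assignment")
        for c1 in chain_assignment[xl.protein_1]:
            for c2 in chain_assignment[xl.protein_2]:
                restraints.append(
                    DistanceRestraint(
                        Selector(str(c1), xl.residue_1, anchor),
                        Selector(str(c2), xl.residue_2, anchor),
                        bounds[0],
                        bounds[1],
                        group=g,
                    )
                )
    return restraints


# -- evaluation -------------------------------------------------------------


def _anchor_index(model: AtomicModel, sel: Selector) -> int | None:
    if sel.anchor == "CA":
        return model.find_atom(sel.chain_id, sel.residue_index, "CA")
    idx = model.find_atom(sel.chain_id, sel.residue_index, "CB")
    if idx is None:  # glycine (or any residue without a C-beta)
        idx = model.find_atom(sel.chain_id, sel.residue_index, "CA")
    return idx


def restraint_distance(model: AtomicModel, restraint: DistanceRestraint) -> float | None:
    """Euclidean anchor-anchor distance, or None when unmappable."""
    i = _anchor_index(model, restraint.selector_1)
    j = _anchor_index(model, restraint.selector_2)
    if i is None or j is None:
        return None
    return float(np.linalg.norm(model.coords[i] - model.coords[j]))


@dataclass
class RestraintReport:
    n_total: int
    n_satisfied: int
    n_violated: int
    n_unmappable: int
    satisfaction_fraction: float | None
    details: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        assert self.n_satisfied + self.n_violated + self.n_unmappable == self.n_total


def evaluate_restraints(
    model: AtomicModel, restraints: Sequence[DistanceRestraint]
) -> RestraintReport:
    """Measure every restraint group on a model.

    A group is satisfied iff any member's anchor distance falls inside its
    bounds; groups whose members are all unmappable are excluded from the
    satisfaction fraction and counted separately.
    """
    groups: dict[int, list[DistanceRestraint]] = {}
    for r in restraints:
        groups.setdefault(r.group, []).append(r)
    rows = []
    n_sat = n_vio = n_unmap = 0
    for g in sorted(groups):
        members = groups[g]
        dists = [restraint_distance(model, r) for r in members]
        mapped = [(r, d) for r, d in zip(members, dists) if d is not None]
        if not mapped:
            status, best = "unmappable", np.nan
            n_unmap += 1
        else:
            sat = any(r.lower_bound <= d <= r.upper_bound for r, d in mapped)
            best = min(d for _, d in mapped)
            if sat:
                status = "satisfied"
                n_sat += 1
            else:
                status = "violated"
                n_vio += 1
        r0 = members[0]
        rows.append(
            {
                "group": g,
                "chain_1": r0.selector_1.chain_id,
                "residue_1": r0.selector_1.residue_index,
                "chain_2": r0.selector_2.chain_id,
                "residue_2": r0.selector_2.residue_index,
                "n_members": len(members),
                "distance": best,
                "lower": r0.lower_bound,
                "upper": r0.upper_bound,
                "status": status,
            }
        )
    n_scored = n_sat + n_vio
    fraction = n_sat / n_scored if n_scored else None
    return RestraintReport(
        n_total=len(groups),
        n_satisfied=n_sat,
        n_violated=n_vio,
        n_unmappable=n_unmap,
        satisfaction_fraction=fraction,
        details=pd.DataFrame(rows),
    )


# -- interface maps ---------------------------------------------------------


def domain_contact_matrix(
    xls: Sequence[CrossLink], domains: Mapping[str, DomainMap]
) -> pd.DataFrame:
    """Count cross-links by (domain, domain) pair.

    Labels are "protein:domain"; residues outside every range bucket into
    "protein:unassigned". Each link is counted once, under the
    lexicographically sorted label pair, so the grand total of the matrix
    equals the number of links.
    """
    counts: dict[tuple[str, str], int] = {}
    labels: set[str] = set()
    for xl in xls:
        l1 = f"{xl.protein_1}:{domains[xl.protein_1].domain_of_residue(xl.residue_1)}"
        l2 = f"{xl.protein_2}:{domains[xl.protein_2].domain_of_residue(xl.residue_2)}"
        key = tuple(sorted((l1, l2)))
        counts[key] = counts.get(key, 0) + 1
        labels.update(key)
    idx = sorted(labels)
    mat = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
    for (a, b), n in counts.items():
        mat.loc[a, b] += n
    return mat


# -- export -----------------------------------------------------------------


def _tbl_selector(sel: Selector) -> str:
    return f"segid {sel.chain_id} and resid {sel.residue_index} and name {sel.anchor}"


def export_restraints(
    restraints: Sequence[DistanceRestraint], dialect: str, path: str | None = None
) -> str:
    """Render restraints as text; deterministic for identical input.

    ``haddock_tbl`` emits CNS-style assign statements (distance, minus-, plus-
    corrections encode the [lower, upper] window); ambiguity groups become OR
    blocks. ``csv`` emits a flat table.
    """
    if not restraints:
        raise CrossLinkError("no restraints to export")
    groups: dict[int, list[DistanceRestraint]] = {}
    for r in restraints:
        groups.setdefault(r.group, []).append(r)

    def group_key(item):
        g, members = item
        r0 = min(
            members,
            key=lambda r: (r.selector_1.chain_id, r.selector_1.residue_index,
                           r.selector_2.chain_id, r.selector_2.residue_index),
        )
        return (r0.selector_1.chain_id, r0.selector_1.residue_index,
                r0.selector_2.chain_id, r0.selector_2.residue_index, g)

    ordered = sorted(groups.items(), key=group_key)

    if dialect == "haddock_tbl":
        blocks = []
        for _, members in ordered:
            members = sorted(
                members,
                key=lambda r: (r.selector_1.chain_id, r.selector_1.residue_index,
                               r.selector_2.chain_id, r.selector_2.residue_index),
            )
            r0 = members[0]
            d = r0.upper_bound
            dminus = r0.upper_bound - r0.lower_bound
            if len(members) == 1:
                block = (
                    f"assign ({_tbl_selector(r0.selector_1)})\n"
                    f"       ({_tbl_selector(r0.selector_2)}) "
                    f"{d:.1f} {dminus:.1f} 0.0"
                )
            else:
                alts = "\n     or ".join(
                    f"(({_tbl_selector(r.selector_1)}) and ({_tbl_selector(r.selector_2)}))"
                    for r in members
                )
                block = f"assign ({alts}\n       ) {d:.1f} {dminus:.1f} 0.0"
            blocks.append(block)
        text = "\n\n".join(blocks) + "\n"
    elif dialect == "csv":
        rows = []
        for g, members in ordered:
            for r in sorted(
                members,
                key=lambda r: (r.selector_1.chain_id, r.selector_1.residue_index,
                               r.selector_2.chain_id, r.selector_2.residue_index),
            ):
                rows.append(
                    {
                        "group": g,
                        "chain_1": r.selector_1.chain_id,
                        "residue_1": r.selector_1.residue_index,
                        "anchor_1": r.selector_1.anchor,
                        "chain_2": r.selector_2.chain_id,
                        "residue_2": r.selector_2.residue_index,
                        "anchor_2": r.selector_2.anchor,
                        "lower": r.lower_bound,
                        "upper": r.upper_bound,
                    }
                )
        buf = io.StringIO()
        pd.DataFrame(rows).to_csv(buf, index=False)
        text = buf.getvalue()
    else:
        raise CrossLinkError(f"unknown dialect {dialect!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
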