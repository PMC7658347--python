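"""Protein–protein interface contacts and physicochemical character.

Contacts are residue pairs from two selections whose closest heavy-atom
distance does not exceed a cutoff (4.5 Å by default, a common convention).
The interface's character is summarised as the fraction of hydrophobic
residues per side (Kyte–Doolittle hydropathy > 0) and as the list of salt
bridges (acidic side-chain oxygen to basic side-chain nitrogen within
4.0 Å).  This is the quantitative counterpart of surface-hydrophobicity and
charge-complementarity renderings of subunit interfaces; buried-surface-area
estimation is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Chain, Residue, Structure, StructureError

__all__ = [
    "InterfaceReport",
    "interface_contacts",
    "interface_character",
    "KYTE_DOOLITTLE",
    "HYDROPHOBIC_RESIDUES",
]

#: Kyte–Doolittle hydropathy index (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

HYDROPHOBIC_RESIDUES = frozenset(k for k, v in KYTE_DOOLITTLE.items() if v > 0)

ACIDIC_SIDE_CHAIN_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_SIDE_CHAIN_N = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

DEFAULT_CONTACT_CUTOFF = 4.5
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0

ResidueKey = tuple[str, int, str]  # (chain_id, seq_number, insertion_code)


@dataclass
class Contact:
    residue_a: ResidueKey
    residue_b: ResidueKey
    name_a: str
    name_b: str
    min_distance: float


@dataclass
class InterfaceReport:
    contacts: list[Contact]
    cutoff: float
    interface_residues_a: list[ResidueKey] = field(default_factory=list)
    interface_residues_b: list[ResidueKey] = field(default_factory=list)
    hydrophobic_fraction_a: float = float("nan")
    hydrophobic_fraction_b: float = float("nan")
    salt_bridge_pairs: list[tuple[ResidueKey, ResidueKey, float]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "chain_a": c.residue_a[0], "resnum_a": c.residue_a[1], "resname_a": c.name_a,
                "chain_b": c.residue_b[0], "resnum_b": c.residue_b[1], "resname_b": c.name_b,
                "min_distance_A": round(c.min_distance, 3),
            }
            for c in self.contacts
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        return (
            f"n_contacts={len(self.contacts)}\t"
            f"hydrophobic_fraction_A={self.hydrophobic_fraction_a:.3f}\t"
            f"hydrophobic_fraction_B={self.hydrophobic_fraction_b:.3f}\t"
            f"n_salt_bridges={len(self.salt_bridge_pairs)}"
        )


def _heavy_atoms(selection) -> list[tuple[Chain, Residue, "object"]]:
    """Flatten a Structure or a (chain, residue[, atom]) list to heavy atoms."""
    items: list[tuple[Chain, Residue, object]] = []
    if isinstance(selection, Structure):
        items = [(c, r, a) for c, r, a in selection.iter_atoms() if a.element != "H" and not r.is_water]
    else:
        for entry in selection:
            if len(entry) == 3:
                c, r, a = entry
                if a.element != "H":
                    items.append((c, r, a))
            else:
                c, r = entry
                items.extend((c, r, a) for a in r.atoms if a.element != "H")
    if not items:
        raise StructureError("interface_contacts: empty selection")
    return items


def interface_contacts(a, b, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> InterfaceReport:
    """All residue pairs across two selections within a heavy-atom cutoff.

    The cutoff is inclusive (a pair exactly at the cutoff counts).  Atom
    neighbour search uses a k-d tree, so cost is near-linear in atoms.
    """
    if not cutoff > 0:
        raise ValueError("interface_contacts: cutoff must be > 0")
    atoms_a = _heavy_atoms(a)
    atoms_b = _heavy_atoms(b)
    pos_a = np.array([at.position for _, _, at in atoms_a])
    pos_b = np.array([at.position for _, _, at in atoms_b])
    tree_a = cKDTree(pos_a)
    tree_b = cKDTree(pos_b)
    # small epsilon keeps pairs exactly at the cutoff despite FP rounding
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff * (1 + 1e-12))
    best: dict[tuple[ResidueKey, ResidueKey], tuple[float, str, str]] = {}
    for ia, neigh in enumerate(pairs):
        ca, ra, at_a = atoms_a[ia]
        key_a = (ca.chain_id, ra.seq_number, ra.insertion_code)
        for ib in neigh:
            cb, rb, at_b = atoms_b[ib]
            d = float(np.linalg.norm(at_a.position - at_b.position))
            if d > cutoff:
                continue
            key = (key_a, (cb.chain_id, rb.seq_number, rb.insertion_code))
            if key not in best or d < best[key][0]:
                best[key] = (d, ra.name, rb.name)
    contacts = [
        Contact(ka, kb, na, nb, d)
        for (ka, kb), (d, na, nb) in sorted(best.items())
    ]
    return InterfaceReport(contacts=contacts, cutoff=cutoff)


def interface_contacts_bruteforce(a, b, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> InterfaceReport:
    """All-pairs reference implementation (quadratic); used for validation."""
    atoms_a = _heavy_atoms(a)
    atoms_b = _heavy_atoms(b)
    best: dict[tuple[ResidueKey, ResidueKey], tuple[float, str, str]] = {}
    for ca, ra, at_a in atoms_a:
        for cb, rb, at_b in atoms_b:
            d = float(np.linalg.norm(at_a.position - at_b.position))
            if d <= cutoff:
                key = (
                    (ca.chain_id, ra.seq_number, ra.insertion_code),
                    (cb.chain_id, rb.seq_number, rb.insertion_code),
                )
                if key not in best or d < best[key][0]:
                    best[key] = (d, ra.name, rb.name)
    contacts = [Contact(ka, kb, na, nb, d) for (ka, kb), (d, na, nb) in sorted(best.items())]
    return InterfaceReport(contacts=contacts, cutoff=cutoff)


def interface_character(
    report: InterfaceReport,
    a,
    b,
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    hydropathy: dict[str, float] | None = None,
) -> InterfaceReport:
    """Annotate an interface report with hydrophobicity and salt bridges.

    The hydrophobic fraction per side is the fraction of interface residues
    with positive hydropathy; salt bridges pair Asp/Glu side-chain oxygens
    with Lys/Arg/His side-chain nitrogens within the cutoff, in either
    side-to-side orientation.
    """
    if not report.contacts:
        raise StructureError("interface_character: no contacts to characterise")
    hydropathy = hydropathy or KYTE_DOOLITTLE

    res_a: dict[ResidueKey, str] = {}
    res_b: dict[ResidueKey, str] = {}
    for c in report.contacts:
        res_a.setdefault(c.residue_a, c.name_a)
        res_b.setdefault(c.residue_b, c.name_b)
    report.interface_residues_a = sorted(res_a)
    report.interface_residues_b = sorted(res_b)

    def hydrophobic_fraction(residues: dict[ResidueKey, str]) -> float:
        vals = [hydropathy.get(name, 0.0) for name in residues.values()]
        return float(np.mean([v > 0 for v in vals])) if vals else float("nan")

    report.hydrophobic_fraction_a = hydrophobic_fraction(res_a)
    report.hydrophobic_fraction_b = hydrophobic_fraction(res_b)

    atoms_a = _heavy_atoms(a)
    atoms_b = _heavy_atoms(b)

    def charged_atoms(atoms, table):
        out = []
        for c, r, at in atoms:
            names = table.get(r.name)
            if names and at.name in names:
                out.append(((c.chain_id, r.seq_number, r.insertion_code), at.position))
        return out

    bridges: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for acid_side, base_side in ((atoms_a, atoms_b), (atoms_b, atoms_a)):
        acids = charged_atoms(acid_side, ACIDIC_SIDE_CHAIN_O)
        bases = charged_atoms(base_side, BASIC_SIDE_CHAIN_N)
        for key_o, pos_o in acids:
            for key_n, pos_n in bases:
                d = float(np.linalg.norm(pos_o - pos_n))
                if d <= salt_bridge_cutoff:
                    pair = (key_o, key_n)
                    if pair not in bridges or d < bridges[pair]:
                        bridges[pair] = d
    report.salt_bridge_pairs = [(ka, kb, d) for (ka, kb), d in sorted(bridges.items())]
    return report
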