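"""Atomic models: reading, writing, segment selection and residue correspondence.

The hierarchy is deliberately simple — a :class:`Structure` holds ordered
chains of residues of atoms, with coordinates in Å.  Residue identity follows
the author numbering of the source file (``seq_number`` + insertion code),
never a re-index, because published residue citations (e.g. the Spc98
insertion Asn626–Leu656) use deposited numbering.

File parsing and writing are delegated to :mod:`gemmi`; this module only
normalises altlocs and flattens the gemmi hierarchy into plain dataclasses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
import yaml
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.PDBData import protein_letters_3to1

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "AtomSubset",
    "SegmentSpec",
    "Correspondence",
    "read_structure",
    "write_pdb",
    "select_segment",
    "align_residues",
    "load_segment_config",
]

#: Standard three-letter amino-acid codes with a one-letter equivalent.
STANDARD_AA = {k: v for k, v in protein_letters_3to1.items() if len(v) == 1}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for unparseable files, empty models or failed selections."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    name: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return STANDARD_AA.get(self.name, "X")

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None


@dataclass
class Structure:
    """Hierarchical atomic model (chains → residues → atoms), Å coordinates."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coordinates(self) -> np.ndarray:
        """All atom positions as an (n, 3) array, in hierarchy order."""
        return np.array([a.position for _, _, a in self.iter_atoms()], dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every atom position mapped to R·x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [
                    replace(a, position=rotation @ a.position + translation)
                    for a in r.atoms
                ]
                residues.append(replace(r, atoms=atoms))
            chains.append(Chain(c.chain_id, residues))
        return Structure(self.id, chains)

    def copy(self) -> "Structure":
        return self.transformed(np.eye(3), np.zeros(3))


class AtomSubset(str, Enum):
    """Which atoms of each residue enter a selection."""

    CA_ONLY = "CA_ONLY"
    BACKBONE = "BACKBONE"
    ALL_HEAVY = "ALL_HEAVY"

    def atom_names(self) -> frozenset[str] | None:
        if self is AtomSubset.CA_ONLY:
            return frozenset({"CA"})
        if self is AtomSubset.BACKBONE:
            return frozenset({"N", "CA", "C", "O"})
        return None  # ALL_HEAVY: any non-hydrogen atom


@dataclass
class SegmentSpec:
    """Named residue-range selection, e.g. the Spc98 GRIP2 domain.

    ``selections`` is a list of ``(chain_id, first_seq_number,
    last_seq_number)`` inclusive ranges in deposited author numbering.
    """

    name: str
    selections: list[tuple[str, int, int]]
    atom_subset: AtomSubset = AtomSubset.CA_ONLY

    def __post_init__(self) -> None:
        if not self.selections:
            raise StructureError(f"segment {self.name!r}: empty selection list")
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain_id, lo, hi in self.selections:
            if hi < lo:
                raise StructureError(
                    f"segment {self.name!r}: empty range {lo}-{hi} on chain {chain_id}"
                )
            for plo, phi in by_chain.get(chain_id, []):
                if lo <= phi and plo <= hi:
                    raise StructureError(
                        f"segment {self.name!r}: overlapping ranges on chain {chain_id}"
                    )
            by_chain.setdefault(chain_id, []).append((lo, hi))

    def resolve_residues(self, s: Structure, include_non_protein: bool = False) -> list[tuple[Chain, Residue]]:
        """Residues of ``s`` covered by this spec, in range order.

        Waters and hetero ligands are excluded by default: superpositions and
        segment comparisons operate on the polypeptide only.
        """
        out: list[tuple[Chain, Residue]] = []
        unmatched: list[tuple[str, int, int]] = []
        for chain_id, lo, hi in self.selections:
            chain = s.chain(chain_id)
            hit = False
            if chain is not None:
                for r in chain.residues:
                    if lo <= r.seq_number <= hi:
                        if not include_non_protein and (r.is_water or all(a.is_hetero for a in r.atoms)):
                            continue
                        out.append((chain, r))
                        hit = True
            if not hit:
                unmatched.append((chain_id, lo, hi))
        if not out:
            raise StructureError(
                f"segment {self.name!r} matched no residues in {s.id!r}; "
                f"unmatched ranges: {unmatched}"
            )
        return out


@dataclass
class Correspondence:
    """One-to-one, order-preserving residue pairing between two selections."""

    pairs: list[tuple[tuple[Chain, Residue], tuple[Chain, Residue]]]
    alignment_score: float
    coverage_a: float
    coverage_b: float


# ---------------------------------------------------------------------------
# File IO


def _resolve_altlocs(gres: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, tie → alphabetically first altloc."""
    best: dict[str, gemmi.Atom] = {}
    for ga in gres:
        prev = best.get(ga.name)
        if prev is None:
            best[ga.name] = ga
            continue
        if ga.occ > prev.occ or (ga.occ == prev.occ and ga.altloc < prev.altloc):
            best[ga.name] = ga
    # preserve file order of first appearance
    seen: list[gemmi.Atom] = []
    names_done = set()
    for ga in gres:
        if ga.name not in names_done:
            seen.append(best[ga.name])
            names_done.add(ga.name)
    return seen


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Altlocs are resolved (highest occupancy, ties broken by altloc id);
    HETATM records are retained with ``is_hetero`` set.  Only the first model
    of multi-model files is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "PDB": gemmi.CoorFormat.Pdb,
        "mmCIF": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise StructureError(f"unknown format {format!r}")
    try:
        gst = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    gst.setup_entities()
    if len(gst) == 0:
        raise StructureError(f"{path}: file contains no model")
    model = gst[0]
    chains = []
    for gch in model:
        residues = []
        for gres in gch:
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    is_hetero=gres.het_flag == "H",
                )
                for ga in _resolve_altlocs(gres)
            ]
            residues.append(
                Residue(
                    name=gres.name,
                    seq_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    atoms=atoms,
                )
            )
        chains.append(Chain(gch.name, residues))
    st = Structure(path.stem, chains)
    if st.n_atoms == 0:
        raise StructureError(f"{path}: model contains no atoms")
    return st


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file (via gemmi; mmCIF writing is out of scope)."""
    gst = gemmi.Structure()
    gst.name = s.id
    model = gemmi.Model("1")
    for c in s.chains:
        gch = gemmi.Chain(c.chain_id)
        for r in c.residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seq_number, r.insertion_code or " ")
            gres.het_flag = "H" if (r.atoms and r.atoms[0].is_hetero) else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or a.name[:1])
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    gst.add_model(model)
    gst.setup_entities()
    gst.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Selection


def select_segment(s: Structure, spec: SegmentSpec) -> list[tuple[Chain, Residue, Atom]]:
    """Atoms of ``s`` selected by ``spec`` (ranges + atom subset), in residue order.

    Residues missing a requested atom (e.g. CA absent) are skipped with a
    logged warning; hydrogens are never included.
    """
    names = spec.atom_subset.atom_names()
    out: list[tuple[Chain, Residue, Atom]] = []
    for chain, res in spec.resolve_residues(s):
        if names is None:
            picked = [a for a in res.atoms if a.element != "H"]
        else:
            picked = [a for a in res.atoms if a.name in names]
            if len(picked) < len(names):
                missing = set(names) - {a.name for a in picked}
                logger.warning(
                    "segment %s: residue %s%d%s missing atoms %s",
                    spec.name, chain.chain_id, res.seq_number, res.insertion_code, sorted(missing),
                )
        out.extend((chain, res, a) for a in picked)
    return out


def segment_coordinates(atoms: Sequence[tuple[Chain, Residue, Atom]]) -> np.ndarray:
    return np.array([a.position for _, _, a in atoms], dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Residue correspondence (global sequence alignment)

_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def align_residues(
    a: Structure,
    b: Structure,
    chains_a: SegmentSpec | None = None,
    chains_b: SegmentSpec | None = None,
) -> Correspondence:
    """Pair residues of two selections by global sequence alignment.

    Needleman–Wunsch with BLOSUM62 and affine gaps (open 10, extend 1) on the
    one-letter sequences; non-standard residues map to ``X`` with a warning.
    The first (deterministic) optimal alignment is used, and gap positions are
    excluded from the returned pairs.
    """
    res_a = chains_a.resolve_residues(a) if chains_a else [(c, r) for c in a.chains for r in c.residues if not r.is_water]
    res_b = chains_b.resolve_residues(b) if chains_b else [(c, r) for c in b.chains for r in c.residues if not r.is_water]
    if len(res_a) < 2 or len(res_b) < 2:
        raise StructureError("align_residues: each selection needs >= 2 residues")
    seq_a = "".join(r.one_letter for _, r in res_a)
    seq_b = "".join(r.one_letter for _, r in res_b)
    for label, residues, seq in (("A", res_a, seq_a), ("B", res_b, seq_b)):
        n_x = seq.count("X")
        if n_x:
            logger.warning("align_residues: %d non-standard residues in %s mapped to X", n_x, label)
    aln = _aligner().align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((res_a[i], res_b[j]))
    return Correspondence(
        pairs=pairs,
        alignment_score=float(aln.score),
        coverage_a=len(pairs) / len(res_a),
        coverage_b=len(pairs) / len(res_b),
    )


# ---------------------------------------------------------------------------
# Segment config files


def _parse_ranges(raw: Iterable) -> list[tuple[str, int, int]]:
    out = []
    for item in raw:
        if isinstance(item, dict):
            out.append((str(item["chain"]), int(item["first"]), int(item["last"])))
        else:
            chain, lo, hi = item
            out.append((str(chain), int(lo), int(hi)))
    return out


def load_segment_config(path: str | Path) -> dict:
    """Load a YAML segment-definition config.

    Schema (see ``examples/``)::

        atom_subset: CA_ONLY          # CA_ONLY | BACKBONE | ALL_HEAVY
        anchor: [Spc97-GRIP1, ...]    # segment names forming the anchor spoke
        segments:
          - name: Spc97-GRIP1
            query:     [[A, 100, 400]]   # chain, first, last (inclusive)
            reference: [[B,  95, 390]]

    Returns a dict with keys ``segments`` (list of (query SegmentSpec,
    reference SegmentSpec) pairs), ``anchor`` (list of names) and
    ``atom_subset``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "segments" not in raw:
        raise StructureError(f"{path}: config must be a mapping with a 'segments' list")
    subset = AtomSubset(raw.get("atom_subset", "CA_ONLY"))
    seg_pairs = []
    names = []
    for seg in raw["segments"]:
        name = seg["name"]
        names.append(name)
        qspec = SegmentSpec(name, _parse_ranges(seg["query"]), subset)
        rspec = SegmentSpec(name, _parse_ranges(seg.get("reference", seg["query"])), subset)
        seg_pairs.append((qspec, rspec))
    anchor = list(raw.get("anchor", []))
    unknown = set(anchor) - set(names)
    if unknown:
        raise StructureError(f"{path}: anchor names not among segments: {sorted(unknown)}")
    return {"segments": seg_pairs, "anchor": anchor, "atom_subset": subset}
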