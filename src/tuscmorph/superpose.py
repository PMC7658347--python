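"""Rigid-body least-squares superposition and segment-wise morph comparison.

The morph-compare procedure quantifies how a multi-segment assembly changes
between two overall conformations: each segment of the query model is
independently superposed onto its counterpart in the reference model, the
placed segments are reassembled into a composite model, the composite is
re-anchored onto the original query using a designated anchor spoke, and the
residual per-segment Cα RMSD between composite and query measures how far
each segment moved relative to the anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structures import (
    AtomSubset,
    Chain,
    Residue,
    SegmentSpec,
    Structure,
    StructureError,
    align_residues,
    select_segment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "MorphCompareReport",
    "kabsch",
    "matched_superpose",
    "morph_compare",
]


@dataclass
class RigidTransform:
    """Proper rotation plus translation: x ↦ R·x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation matrix determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def angle_degrees(self) -> float:
        """Rotation angle of R, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    atom_subset: AtomSubset = AtomSubset.CA_ONLY
    coverage: float = 1.0


@dataclass
class MorphCompareReport:
    """Per-segment RMSD between a query model and a reference-conformation composite."""

    query_id: str
    reference_id: str
    anchor_segments: list[str]
    per_segment: dict[str, float]
    n_atoms: dict[str, int] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)
    composite: Structure | None = None
    anchor_transform: RigidTransform | None = None

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            {
                "segment": name,
                "n_atoms": self.n_atoms.get(name, 0),
                "coverage": round(self.coverage.get(name, 1.0), 4),
                "rmsd_A": round(rmsd, 4),
                "anchor": name in self.anchor_segments,
            }
            for name, rmsd in self.per_segment.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between two index-paired coordinate sets (no superposition)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``target``.

    Closed-form SVD solution; a reflection is corrected by flipping the sign
    of the smallest singular vector.  Coordinates are paired index-wise.

    Raises for n < 3 or a degenerate (rank < 2) point cloud, for which the
    rotation is not uniquely determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch: inputs must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"kabsch: need >= 3 paired atoms, got {n}")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    if min(np.linalg.matrix_rank(p, tol=1e-8), np.linalg.matrix_rank(q, tol=1e-8)) < 2:
        raise ValueError("kabsch: degenerate point cloud (collinear or coincident points)")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    transform = RigidTransform(rot, tc - rot @ mc)
    fitted = transform.apply(mobile)
    return SuperpositionResult(transform=transform, rmsd=rmsd_between(fitted, target), n_atoms=n)


def _paired_coordinates(
    query: Structure,
    qspec: SegmentSpec,
    reference: Structure,
    rspec: SegmentSpec,
    atom_subset: AtomSubset,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Residue-aligned coordinate pairs for one segment; returns (q, r, coverage)."""
    corr = align_residues(query, reference, qspec, rspec)
    names = atom_subset.atom_names() or None
    qpts, rpts = [], []
    for (qc, qr), (rc, rr) in corr.pairs:
        if names is None:
            shared = [a.name for a in qr.atoms if a.element != "H" and rr.atom(a.name)]
        else:
            shared = [nm for nm in sorted(names) if qr.atom(nm) and rr.atom(nm)]
        for nm in shared:
            qpts.append(qr.atom(nm).position)
            rpts.append(rr.atom(nm).position)
    if len(qpts) < 3:
        raise StructureError(
            f"segment {qspec.name!r}: only {len(qpts)} paired atoms after alignment (need >= 3)"
        )
    coverage = min(corr.coverage_a, corr.coverage_b)
    return np.asarray(qpts), np.asarray(rpts), coverage


def matched_superpose(
    mobile: Structure,
    mobile_spec: SegmentSpec,
    target: Structure,
    target_spec: SegmentSpec,
    atom_subset: AtomSubset = AtomSubset.CA_ONLY,
    prune: bool = False,
    prune_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Sequence-matched rigid superposition of one segment onto another.

    Residues are paired by global sequence alignment, the paired atoms of
    ``atom_subset`` are collected, and the optimal transform is computed.
    With ``prune=True`` a single pruning pass drops pairs farther than
    ``prune_cutoff`` Å after the first fit and refits once (off by default —
    the unpruned fit is the reproducible baseline).
    """
    mpts, tpts, coverage = _paired_coordinates(mobile, mobile_spec, target, target_spec, atom_subset)
    result = kabsch(mpts, tpts)
    if prune:
        fitted = result.transform.apply(mpts)
        keep = np.linalg.norm(fitted - tpts, axis=1) <= prune_cutoff
        if keep.sum() >= 3 and keep.sum() < len(keep):
            result = kabsch(mpts[keep], tpts[keep])
        elif keep.sum() < 3:
            logger.warning("matched_superpose: pruning would leave < 3 pairs; keeping unpruned fit")
    result.atom_subset = atom_subset
    result.coverage = coverage
    return result


def _segment_atom_map(
    s: Structure, spec: SegmentSpec, atom_subset: AtomSubset
) -> list[tuple[Chain, Residue, "np.ndarray"]]:
    spec = SegmentSpec(spec.name, spec.selections, atom_subset)
    return [(c, r, a.position) for c, r, a in select_segment(s, spec)]


def morph_compare(
    query: Structure,
    reference: Structure,
    segments: list[tuple[SegmentSpec, SegmentSpec]],
    anchor: list[str],
    atom_subset: AtomSubset = AtomSubset.CA_ONLY,
    prune: bool = False,
) -> MorphCompareReport:
    """Segment-wise conformational comparison of two multi-segment assemblies.

    1. each query segment is superposed onto its reference counterpart and a
       copy is placed there;
    2. the placed copies are assembled into a composite model (the query in
       the reference's overall conformation);
    3. the composite is superposed back onto the original query over the
       union of the ``anchor`` segments (e.g. one whole spoke);
    4. per-segment RMSD between the re-anchored composite and the query over
       ``atom_subset`` is reported.

    Anchor-segment RMSDs reflect only residual anchor misfit; non-anchor
    RMSDs measure conformational displacement relative to the anchor.
    """
    if not anchor:
        raise ValueError("morph_compare: anchor must name at least one segment")
    names = [q.name for q, _ in segments]
    missing = set(anchor) - set(names)
    if missing:
        raise ValueError(f"morph_compare: anchor names not among segments: {sorted(missing)}")

    # step 1: place each query segment in the reference conformation
    placed: dict[str, RigidTransform] = {}
    n_atoms: dict[str, int] = {}
    coverage: dict[str, float] = {}
    for qspec, rspec in segments:
        try:
            fit = matched_superpose(query, qspec, reference, rspec, atom_subset, prune=prune)
        except (StructureError, ValueError) as exc:
            raise StructureError(f"morph_compare: segment {qspec.name!r} failed: {exc}") from exc
        placed[qspec.name] = fit.transform
        n_atoms[qspec.name] = fit.n_atoms
        coverage[qspec.name] = fit.coverage

    # step 2+3: the composite is the set of query segments moved to their
    # reference placements; re-anchor the composite on the query over the anchor union
    def segment_coords(s: Structure, spec: SegmentSpec) -> np.ndarray:
        return np.array([p for _, _, p in _segment_atom_map(s, spec, atom_subset)], dtype=float)

    anchor_q, anchor_c = [], []
    for qspec, _ in segments:
        if qspec.name not in anchor:
            continue
        qc = segment_coords(query, qspec)
        anchor_q.append(qc)
        anchor_c.append(placed[qspec.name].apply(qc))
    anchor_fit = kabsch(np.vstack(anchor_c), np.vstack(anchor_q))

    # step 4: per-segment rmsd between re-anchored composite and query
    per_segment: dict[str, float] = {}
    displacement: dict[str, list] = {}
    composite_chains: dict[str, Chain] = {}
    for qspec, _ in segments:
        qatoms = _segment_atom_map(query, qspec, atom_subset)
        qc = np.array([p for _, _, p in qatoms], dtype=float)
        cc = anchor_fit.transform.apply(placed[qspec.name].apply(qc))
        per_segment[qspec.name] = rmsd_between(cc, qc)
        displacement[qspec.name] = [
            (chain.chain_id, res.seq_number, res.insertion_code, tuple(q), tuple(c - q))
            for (chain, res, _), q, c in zip(qatoms, qc, cc)
        ]
        # assemble composite structure: full segment residues, transformed
        seg_t = anchor_fit.transform.compose(placed[qspec.name])
        for chain, res in qspec.resolve_residues(query):
            gch = composite_chains.setdefault(chain.chain_id, Chain(chain.chain_id))
            moved_atoms = [
                type(a)(a.name, a.element, seg_t.apply(a.position[None, :])[0], a.occupancy, a.is_hetero)
                for a in res.atoms
            ]
            gch.residues.append(Residue(res.name, res.seq_number, res.insertion_code, moved_atoms))

    composite = Structure(f"{query.id}@{reference.id}", list(composite_chains.values()))
    report = MorphCompareReport(
        query_id=query.id,
        reference_id=reference.id,
        anchor_segments=list(anchor),
        per_segment=per_segment,
        n_atoms=n_atoms,
        coverage=coverage,
        composite=composite,
        anchor_transform=anchor_fit.transform,
    )
    report.displacements = displacement  # consumed by the displacement module
    return report
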