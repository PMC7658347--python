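"""Per-residue displacement fields and centroid-distance changes.

Given an original model and the composite produced by the morph-compare
procedure (the same model placed in a reference conformation and
re-anchored), the displacement field links each residue's representative
atom in the two models.  Mean arrows summarise the average direction and
magnitude of a segment's motion; the inter-γ-tubulin centroid distance
change measures whether a conformational transition moves the two
γ-tubulins closer together or further apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import AtomSubset, SegmentSpec, Structure, StructureError, select_segment

__all__ = [
    "DisplacementField",
    "CentroidReport",
    "displacement_field",
    "mean_arrow",
    "centroid_distance_change",
]

#: Distances changing by less than this (Å) count as "unchanged".
UNCHANGED_TOLERANCE = 0.05


@dataclass
class DisplacementEntry:
    chain_id: str
    seq_number: int
    insertion_code: str
    start: np.ndarray  # (3,) Å, position in the original model
    vector: np.ndarray  # (3,) Å, composite − original
    segment: str = ""

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass
class DisplacementField:
    entries: list[DisplacementEntry] = field(default_factory=list)

    def segment_names(self) -> list[str]:
        seen = dict.fromkeys(e.segment for e in self.entries)
        return list(seen)

    def for_segment(self, name: str) -> list[DisplacementEntry]:
        return [e for e in self.entries if e.segment == name]

    def magnitude_stats(self) -> pd.DataFrame:
        """min / mean / max displacement magnitude per segment."""
        rows = []
        for name in self.segment_names():
            mags = np.array([e.magnitude for e in self.for_segment(name)])
            rows.append({"segment": name, "min": mags.min(), "mean": mags.mean(), "max": mags.max()})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "chain": e.chain_id,
                "resnum": e.seq_number,
                "icode": e.insertion_code,
                "x0": e.start[0], "y0": e.start[1], "z0": e.start[2],
                "dx": e.vector[0], "dy": e.vector[1], "dz": e.vector[2],
                "magnitude": e.magnitude,
                "segment": e.segment,
            }
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


@dataclass
class CentroidReport:
    d_query: float
    d_reference: float
    delta: float  # d_query − d_reference; > 0 ⇒ the transition pulls them closer
    direction: str  # "closer" | "apart" | "unchanged"


def displacement_field(
    original: Structure,
    composite: Structure,
    atom_subset: AtomSubset = AtomSubset.CA_ONLY,
    segments: list[SegmentSpec] | None = None,
) -> DisplacementField:
    """One vector per shared residue: composite position − original position.

    Residues are matched by (chain, seq number, insertion code); the
    representative atom is the residue's CA (or first atom of the subset).
    When ``segments`` are given, entries are labelled by segment name and
    restricted to the segment residues.
    """
    rep_name = "CA" if atom_subset in (AtomSubset.CA_ONLY, AtomSubset.BACKBONE) else None

    def rep_positions(s: Structure, spec: SegmentSpec | None) -> dict:
        out = {}
        if spec is None:
            items = [(c, r) for c in s.chains for r in c.residues if not r.is_water]
        else:
            items = spec.resolve_residues(s)
        for c, r in items:
            a = r.atom(rep_name) if rep_name else (r.atoms[0] if r.atoms else None)
            if a is not None:
                out[(c.chain_id, r.seq_number, r.insertion_code)] = a.position
        return out

    specs: list[SegmentSpec | None] = list(segments) if segments else [None]
    entries: list[DisplacementEntry] = []
    for spec in specs:
        orig = rep_positions(original, spec)
        comp = rep_positions(composite, spec)
        shared = [k for k in orig if k in comp]
        for key in shared:
            entries.append(
                DisplacementEntry(
                    chain_id=key[0],
                    seq_number=key[1],
                    insertion_code=key[2],
                    start=orig[key],
                    vector=comp[key] - orig[key],
                    segment=spec.name if spec else "",
                )
            )
    if not entries:
        raise StructureError("displacement_field: the two models share no residues")
    return DisplacementField(entries)


def mean_arrow(field: DisplacementField, segment: str) -> tuple[np.ndarray, np.ndarray, bool]:
    """Average displacement arrow of one segment.

    Returns ``(anchor, vector, informative)``: the anchor is the centroid of
    the start positions, the vector the component-wise mean displacement.
    ``informative`` is False when the mean-vector magnitude is below 10% of
    the mean per-residue magnitude — the motion is predominantly rotational
    and a single arrow misrepresents it.
    """
    entries = field.for_segment(segment)
    if not entries:
        raise KeyError(f"mean_arrow: unknown segment {segment!r}")
    starts = np.array([e.start for e in entries])
    vectors = np.array([e.vector for e in entries])
    anchor = starts.mean(axis=0)
    vec = vectors.mean(axis=0)
    mean_mag = float(np.mean(np.linalg.norm(vectors, axis=1)))
    informative = mean_mag == 0.0 or float(np.linalg.norm(vec)) >= 0.1 * mean_mag
    return anchor, vec, informative


def write_arrows(path, arrows: dict[str, tuple[np.ndarray, np.ndarray, bool]]) -> None:
    """Plain-text arrow markers: one line per segment, anchor + vector."""
    with open(path, "w") as fh:
        fh.write("# segment\tax\tay\taz\tdx\tdy\tdz\tinformative\n")
        for name, (anchor, vec, ok) in arrows.items():
            fh.write(
                f"{name}\t" + "\t".join(f"{v:.4f}" for v in (*anchor, *vec)) + f"\t{ok}\n"
            )


def _centroid(s: Structure, spec: SegmentSpec, mass_weighted: bool = False) -> np.ndarray:
    ca_spec = SegmentSpec(spec.name, spec.selections, AtomSubset.CA_ONLY)
    atoms = select_segment(s, ca_spec)
    pos = np.array([a.position for _, _, a in atoms])
    if mass_weighted:
        from .densitymaps import ATOMIC_NUMBER

        w = np.array([ATOMIC_NUMBER.get(a.element, 6) for _, _, a in atoms], dtype=float)
        return (pos * w[:, None]).sum(axis=0) / w.sum()
    return pos.mean(axis=0)


def centroid_distance_change(
    query: Structure,
    composite: Structure,
    gamma1: SegmentSpec,
    gamma2: SegmentSpec,
    mass_weighted: bool = False,
) -> CentroidReport:
    """Change of the distance between two segment centroids across a transition.

    Centroids are unweighted CA centroids by default.  ``delta = d_query −
    d_composite``; a positive delta means the segments sit wider apart in the
    query than in the target conformation, i.e. the transition moves them
    closer together.
    """
    d_q = float(np.linalg.norm(_centroid(query, gamma1, mass_weighted) - _centroid(query, gamma2, mass_weighted)))
    d_r = float(np.linalg.norm(_centroid(composite, gamma1, mass_weighted) - _centroid(composite, gamma2, mass_weighted)))
    delta = d_q - d_r
    if abs(delta) < UNCHANGED_TOLERANCE:
        direction = "unchanged"
    elif delta > 0:
        direction = "closer"
    else:
        direction = "apart"
    return CentroidReport(d_query=d_q, d_reference=d_r, delta=delta, direction=direction)
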