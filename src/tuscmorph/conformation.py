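"""Straight-vs-curved tubulin classification against a density map.

αβ-tubulin dimers occur in two canonical conformations, 'straight' (as in
protofilaments of stable microtubules) and 'curved'; the positions of
helices α6 and α7 are the most discriminating feature.  To call the
conformation of a γ-tubulin subunit observed in a cryo-EM map, complete
reference β-tubulin models in each conformation are rigid-body docked into
the γ-tubulin density, and two independent scores are computed over the
α6/α7 helices only:

* Cα RMSD between each docked reference's helices and the corresponding
  helices of the γ-tubulin model, at the docked positions (no
  re-superposition — the docking itself carries the evidence);
* cross-correlation between density simulated from the docked helices and
  the experimental density restricted to a zone around those helices.

The label is 'straight' only when both scores agree (lower RMSD *and*
higher correlation for the straight reference), 'curved' when both agree
the other way, and 'indeterminate' otherwise, including exact ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densitymaps import (
    DensityMap,
    SimulationParams,
    atom_zone_mask,
    cross_correlation,
    rigid_body_fit,
    simulate_density,
)
from .structures import AtomSubset, SegmentSpec, Structure, StructureError, select_segment
from .superpose import rmsd_between

__all__ = ["HelixRanges", "ConformationCall", "conformation_label", "classify_tubulin"]

#: Radius (Å) of the density zone around the docked helices used for the
#: correlation score; the experimental segmentation convention is not unique,
#: so this is configurable.
DEFAULT_CC_ZONE_RADIUS = 3.0


@dataclass
class HelixRanges:
    """Residue ranges of tubulin helices α6 and α7 in a reference numbering."""

    helix_a6: tuple[str, int, int]  # (chain_id, first, last), inclusive
    helix_a7: tuple[str, int, int]

    def __post_init__(self) -> None:
        for label, (chain, lo, hi) in (("a6", self.helix_a6), ("a7", self.helix_a7)):
            if hi < lo:
                raise ValueError(f"helix {label}: empty range {lo}-{hi}")
        if self.helix_a6[0] == self.helix_a7[0]:
            a, b = sorted([self.helix_a6[1:], self.helix_a7[1:]])
            if b[0] <= a[1]:
                raise ValueError("helix ranges overlap")

    def spec(self, name: str = "a6a7", atom_subset: AtomSubset = AtomSubset.CA_ONLY) -> SegmentSpec:
        return SegmentSpec(name, [self.helix_a6, self.helix_a7], atom_subset)


@dataclass
class ConformationCall:
    label: str  # "straight" | "curved" | "indeterminate"
    rmsd_straight: float
    rmsd_curved: float
    cc_straight: float
    cc_curved: float


def conformation_label(
    rmsd_straight: float, rmsd_curved: float, cc_straight: float, cc_curved: float
) -> str:
    """The conjunctive label rule: both lines of evidence must agree."""
    if rmsd_straight < rmsd_curved and cc_straight > cc_curved:
        return "straight"
    if rmsd_curved < rmsd_straight and cc_curved > cc_straight:
        return "curved"
    return "indeterminate"


def _helix_ca_by_resid(docked: Structure, helices: HelixRanges) -> dict:
    spec = helices.spec(atom_subset=AtomSubset.CA_ONLY)
    return {
        (c.chain_id, r.seq_number, r.insertion_code): a.position
        for c, r, a in select_segment(docked, spec)
    }


def _score_reference(
    ref: Structure,
    ref_helices: HelixRanges,
    gamma_model: Structure,
    gamma_helices: HelixRanges,
    gamma_density: DensityMap,
    p: SimulationParams,
    zone_radius: float,
) -> tuple[float, float]:
    # (i) dock the complete reference into the density
    transform, _ = rigid_body_fit(ref.coordinates(), gamma_density)
    docked = ref.transformed(transform.rotation, transform.translation)

    # (ii) Cα RMSD over the helices at the docked positions, paired in range order
    ref_ca = [a.position for _, _, a in select_segment(docked, ref_helices.spec())]
    mod_ca = [a.position for _, _, a in select_segment(gamma_model, gamma_helices.spec())]
    n = min(len(ref_ca), len(mod_ca))
    if n < 3:
        raise StructureError("classify_tubulin: fewer than 3 paired helix Cα atoms")
    rmsd = rmsd_between(np.asarray(ref_ca[:n]), np.asarray(mod_ca[:n]))

    # (iii) correlation between simulated helix density and the zoned map
    helix_atoms = select_segment(docked, helices_all_heavy(ref_helices))
    sim = simulate_density(helix_atoms, p, gamma_density.voxel_size)
    zone = atom_zone_mask(gamma_density, helix_atoms, zone_radius)
    cc = cross_correlation(gamma_density, sim, mask=zone, about_mean=True).cc
    return rmsd, cc


def helices_all_heavy(h: HelixRanges) -> SegmentSpec:
    return SegmentSpec("a6a7", [h.helix_a6, h.helix_a7], AtomSubset.ALL_HEAVY)


def classify_tubulin(
    gamma_model: Structure,
    gamma_density: DensityMap,
    straight_ref: Structure,
    curved_ref: Structure,
    helices: HelixRanges,
    p: SimulationParams,
    gamma_helices: HelixRanges | None = None,
    zone_radius: float = DEFAULT_CC_ZONE_RADIUS,
) -> ConformationCall:
    """Call a tubulin subunit straight or curved against its density.

    ``helices`` gives the α6/α7 ranges in the reference structures'
    numbering; ``gamma_helices`` the corresponding ranges in the query model
    (defaults to the same ranges).
    """
    gamma_helices = gamma_helices or helices
    rmsd_s, cc_s = _score_reference(
        straight_ref, helices, gamma_model, gamma_helices, gamma_density, p, zone_radius
    )
    rmsd_c, cc_c = _score_reference(
        curved_ref, helices, gamma_model, gamma_helices, gamma_density, p, zone_radius
    )
    return ConformationCall(
        label=conformation_label(rmsd_s, rmsd_c, cc_s, cc_c),
        rmsd_straight=rmsd_s,
        rmsd_curved=rmsd_c,
        cc_straight=cc_s,
        cc_curved=cc_c,
    )
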