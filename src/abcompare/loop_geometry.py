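"""CDR-H3 orientation descriptors in a VH-anchored spherical frame.

The frame is built from the VH domain itself, so the descriptors are
invariant under rigid motion of the structure:

* origin — centroid of the Calpha atoms of the six CDR-H3 anchor residues
  (IMGT 102-104 and 118-120);
* z axis — unit vector from the framework Calpha centroid to the origin
  ("up", away from the body of the domain);
* y axis — component orthogonal to z of the vector from the origin toward
  the Calpha centroid of the FR2 positions forming the (former) VL
  interface (IMGT 42, 49, 50, 52);
* x axis — y cross z (right-handed).

For the CDR-H3 loop, rho is the distance from the origin to the loop's
backbone centre of geometry (its reach), theta the polar angle from z (high
theta: the loop folds down against the domain), phi the azimuth from x
toward y (high phi: the loop points at the FR2/VL-interface face), and
compactness = loop length / rho (residues per Angstrom of reach).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_model import BACKBONE_ATOMS, CDR_RANGES, Residue

#: IMGT positions of the CDR-H3 anchors (three residues each side)
ANCHOR_POSITIONS = (102, 103, 104, 118, 119, 120)
#: FR2 positions at the VL-interface face used to set the azimuth reference
FR2_INTERFACE_POSITIONS = (42, 49, 50, 52)


@dataclass
class VhFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray


@dataclass
class LoopOrientation:
    rho: float  # A
    theta: float  # degrees in [0, 180]
    phi: float  # degrees in (-180, 180]
    loop_length: int
    compactness: float  # residues / A


class FrameError(ValueError):
    """The chain cannot support frame construction (missing anchors/backbone)."""


def _ca(res: Residue) -> np.ndarray:
    atom = res.atom("CA")
    if atom is None:
        raise FrameError(f"residue {res.chain_id}{res.number} lacks a CA atom")
    return atom.position


def _by_position(vh: list[Residue], positions: tuple[int, ...]) -> list[Residue]:
    found = []
    for pos in positions:
        hits = [r for r in vh if r.imgt_position == pos and r.imgt_icode == ""]
        if not hits:
            raise FrameError(f"missing IMGT position {pos}")
        found.extend(hits)
    return found


def build_frame(vh: list[Residue]) -> VhFrame:
    """Construct the VH-anchored orthonormal right-handed frame.

    Requires complete backbone on the anchor residues; raises
    :class:`FrameError` when the chain cannot support the construction, so
    callers can exclude the structure with a logged reason.
    """
    anchors = _by_position(vh, ANCHOR_POSITIONS)
    for r in anchors:
        if not r.has_backbone:
            raise FrameError(
                f"anchor residue IMGT {r.imgt_position} has incomplete backbone"
            )
    origin = np.mean([_ca(r) for r in anchors], axis=0)

    cdr3_lo, cdr3_hi = CDR_RANGES["CDR3"]
    framework = [
        r
        for r in vh
        if r.imgt_position is not None and not (cdr3_lo <= r.imgt_position <= cdr3_hi)
        and r.atom("CA") is not None
    ]
    if len(framework) < 3:
        raise FrameError("too few framework residues to define the frame")
    fw_centroid = np.mean([_ca(r) for r in framework], axis=0)
    z = origin - fw_centroid
    norm = np.linalg.norm(z)
    if norm < 1e-6:
        raise FrameError("degenerate frame: anchors coincide with framework centroid")
    z = z / norm

    fr2 = _by_position(vh, FR2_INTERFACE_POSITIONS)
    toward_fr2 = np.mean([_ca(r) for r in fr2], axis=0) - origin
    y = toward_fr2 - np.dot(toward_fr2, z) * z
    norm = np.linalg.norm(y)
    if norm < 1e-6:
        raise FrameError("degenerate frame: FR2 direction parallel to z")
    y = y / norm
    x = np.cross(y, z)
    return VhFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def orient_loop(vh: list[Residue], frame: VhFrame) -> LoopOrientation:
    """Spherical descriptors of the CDR-H3 backbone centre of geometry."""
    lo, hi = CDR_RANGES["CDR3"]
    loop = [r for r in vh if r.imgt_position is not None and lo <= r.imgt_position <= hi]
    coords = [
        a.position for r in loop for a in r.atoms if a.name in BACKBONE_ATOMS
    ]
    if not coords:
        raise FrameError("CDR-H3 has no backbone atoms")
    center = np.mean(coords, axis=0)
    v = center - frame.origin
    rho = float(np.linalg.norm(v))
    if rho < 0.5:
        raise FrameError(f"degenerate loop placement: rho = {rho:.3f} A")
    theta = float(np.degrees(np.arccos(np.clip(np.dot(v, frame.z_axis) / rho, -1, 1))))
    phi = float(
        np.degrees(np.arctan2(np.dot(v, frame.y_axis), np.dot(v, frame.x_axis)))
    )
    if phi <= -180.0:
        phi += 360.0
    return LoopOrientation(
        rho=rho,
        theta=theta,
        phi=phi,
        loop_length=len(loop),
        compactness=len(loop) / rho,
    )
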