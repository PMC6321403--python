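"""Canonical 3D pharmacophore signatures, hashes and hashed fingerprints.

The representation is alignment-free.  A pharmacophore is treated as a
complete graph whose vertices are labelled feature points and whose
edges carry binned inter-feature distances.  Every 4-feature subset
(quadruplet — the smallest point set that can be chiral in 3D) receives
a canonical signature made of two parts:

* a *graph part*: the lexicographically sorted tuple of canonical
  feature identifiers, each identifier combining the feature's own label
  with the sorted (binned distance, label) pairs to the other three
  members (one round of Morgan-like refinement);
* a *stereo sign*: an integer encoding the handedness of the quadruplet
  via the sign of a scalar triple product, with a torsion-based ±10
  correction for the AABB identifier class whose trapeze- and
  parallelogram-like geometries are otherwise indistinguishable.

The multiset of quadruplet signatures, with counts, lexicographically
sorted and serialised in a fixed textual layout, is digested with md5:
equal digests identify equal pharmacophores without any alignment.
Hashed fingerprints do the same over feature *triplets* (which cannot be
chiral) and set one bit per distinct triplet signature; they support a
Bloom-filter subset prefilter for screening.

Serialisation layout (fixed so hashes are reproducible across runs and
machines): a canonical identifier is rendered ``label|b1:l1;b2:l2;b3:l3``
with the environment pairs sorted; a quadruplet is the four identifier
strings sorted and joined by ``/``, followed by ``#`` and the stereo
sign; the hash input is the sorted sequence of ``<quad>*<count>`` lines
joined by newlines and UTF-8 encoded.
"""

from __future__ import annotations

import hashlib
import itertools
import math
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .features import FeaturePoint, Pharmacophore

__all__ = [
    "bin_distance",
    "canonical_quad_ids",
    "chirality_class",
    "min_plane_angle",
    "stereo_sign",
    "quad_signature",
    "triplet_signature",
    "pharm_hash",
    "pharm_fingerprint",
    "QuadSignature",
    "PharmFingerprint",
]

#: Angle (degrees) below which a quadruplet is numerically coplanar.
PLANAR_EPS_DEG = 1e-6
#: Relative tolerance for real-distance ties in the AABB ranking rule.
_DIST_EPS = 1e-9


def bin_distance(d: float, bin_step: float) -> int:
    """Discretise a distance into half-open bins ``[k*step, (k+1)*step)``.

    Parameters
    ----------
    d : float
        Distance in Å; must be non-negative.
    bin_step : float
        Bin width in Å; must be positive.

    Returns
    -------
    int
        ``floor(d / bin_step)``.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if not bin_step > 0:
        raise ValueError("bin_step must be positive")
    return int(math.floor(d / bin_step))


# A canonical feature identifier is the nested tuple
#   (label, ((bin, neighbor_label), (bin, neighbor_label), ...))
# with the environment sorted; tuples compare lexicographically.
CanonicalFeatureId = tuple


def _canonical_ids(points: Sequence[FeaturePoint], bin_step: float) -> tuple:
    """Per-vertex canonical identifiers, in input order, for any tuple size."""
    n = len(points)
    coords = np.array([[p.x, p.y, p.z] for p in points], dtype=float)
    ids = []
    for i in range(n):
        env = []
        for j in range(n):
            if j == i:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            env.append((bin_distance(d, bin_step), points[j].label))
        env.sort()
        ids.append((points[i].label, tuple(env)))
    return tuple(ids)


def canonical_quad_ids(
    quad: Sequence[FeaturePoint], bin_step: float
) -> tuple:
    """Canonical identifiers of the four quadruplet members, in input order.

    Each identifier is ``(label, sorted ((binned distance, neighbor
    label)) over the other three members)``.  Sorting the returned tuple
    yields the quadruplet's canonical graph signature, invariant under
    any permutation of the input.
    """
    if len(quad) != 4:
        raise ValueError("a quadruplet must contain exactly 4 features")
    return _canonical_ids(quad, bin_step)


def chirality_class(ids: Sequence[CanonicalFeatureId]) -> str:
    """Classify a quadruplet by the equality pattern of its identifiers.

    Returns one of ``AAAA`` (all four identical — regular tetrahedron,
    achiral), ``AAAB`` (trigonal pyramid, achiral), ``AABC`` (achiral by
    a symmetry plane), ``AABB`` (chiral or achiral; axial chirality) or
    ``ABCD`` (all distinct; chiral unless planar).
    """
    if len(ids) != 4:
        raise ValueError("expected 4 canonical identifiers")
    counts = {}
    for i in ids:
        counts[i] = counts.get(i, 0) + 1
    pattern = sorted(counts.values(), reverse=True)
    return {
        (4,): "AAAA",
        (3, 1): "AAAB",
        (2, 2): "AABB",
        (2, 1, 1): "AABC",
        (1, 1, 1, 1): "ABCD",
    }[tuple(pattern)]


def min_plane_angle(coords) -> float:
    """Minimum angle (degrees) between any edge and the opposite plane.

    For each vertex, the plane through the remaining three points is
    formed and the angles between that plane and the three edges from
    the vertex to the plane's points are computed.  The minimum over all
    vertex/edge choices measures the deviation of the quadruplet from
    planarity: 0 for exactly coplanar points, up to 90° for a tall
    pyramid.  A degenerate plane (three collinear points) is treated as
    planar (angle 0), which conservatively assigns stereo sign 0.
    """
    c = np.asarray(coords, dtype=float)
    if c.shape != (4, 3):
        raise ValueError("expected 4 points in 3D")
    best = 90.0
    for v in range(4):
        others = [j for j in range(4) if j != v]
        p0, p1, p2 = c[others[0]], c[others[1]], c[others[2]]
        normal = np.cross(p1 - p0, p2 - p0)
        nn = np.linalg.norm(normal)
        span = max(np.linalg.norm(p1 - p0), np.linalg.norm(p2 - p0), 1.0)
        if nn <= 1e-12 * span * span:
            return 0.0  # collinear triple: degenerate plane
        normal = normal / nn
        h = abs(float(np.dot(c[v] - p0, normal)))
        for j in others:
            edge = np.linalg.norm(c[v] - c[j])
            if edge <= 1e-12:
                return 0.0  # coincident points are trivially coplanar
            s = min(1.0, h / edge)
            best = min(best, math.degrees(math.asin(s)))
    return best


def _triple_product_sign(c, order) -> int:
    """Sign of det[v2-v1, v3-v1, v4-v1] for ranked vertices ``order``."""
    a = c[order[1]] - c[order[0]]
    b = c[order[2]] - c[order[0]]
    d = c[order[3]] - c[order[0]]
    det = float(np.dot(a, np.cross(b, d)))
    scale = (
        np.linalg.norm(a) * np.linalg.norm(b) * np.linalg.norm(d)
    )
    if scale <= 0 or abs(det) <= 1e-9 * scale:
        return 0
    return 1 if det > 0 else -1


def _aabb_orders(c, a_pair, b_pair):
    """All vertex rankings consistent with the AABB tie-break rule.

    For each choice of first A, the B nearest (real distance) to it is
    ranked third and the remaining B fourth; an exact distance tie
    admits both B orders.
    """
    orders = []
    for a1, a2 in ((a_pair[0], a_pair[1]), (a_pair[1], a_pair[0])):
        d1 = np.linalg.norm(c[b_pair[0]] - c[a1])
        d2 = np.linalg.norm(c[b_pair[1]] - c[a1])
        scale = max(d1, d2, 1.0)
        if abs(d1 - d2) <= _DIST_EPS * scale:
            orders.append((a1, a2, b_pair[0], b_pair[1]))
            orders.append((a1, a2, b_pair[1], b_pair[0]))
        elif d1 < d2:
            orders.append((a1, a2, b_pair[0], b_pair[1]))
        else:
            orders.append((a1, a2, b_pair[1], b_pair[0]))
    return orders


def _torsion_cos(c, a_pair, b_pair) -> float:
    """Cosine of the B-A-A-B torsion about the A–A axis.

    Symmetric in both the A and the B ordering; returns 0 when a B lies
    on the A–A axis (undefined torsion).
    """
    a1, a2 = c[a_pair[0]], c[a_pair[1]]
    b1, b2 = c[b_pair[0]], c[b_pair[1]]
    axis = a2 - a1
    n1 = np.cross(a1 - b1, axis)  # normal of plane B1-A1-A2
    n2 = np.cross(axis, b2 - a2)  # normal of plane A1-A2-B2
    s1, s2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if s1 <= 1e-12 or s2 <= 1e-12:
        return 0.0
    return float(np.dot(n1, n2) / (s1 * s2))


def stereo_sign(
    quad: Sequence[FeaturePoint],
    ids: Sequence[CanonicalFeatureId],
    cls: str,
    tolerance: float = 0.0,
) -> int:
    """Stereoconfiguration sign of a quadruplet.

    Quadruplets in the achiral identifier classes (AAAA, AAAB, AABC) are
    assigned 0.  For AABB and ABCD, quadruplets whose minimum
    edge-to-plane angle is below ``tolerance`` degrees (or that are
    exactly planar) receive base sign 0; otherwise the base sign (±1) is
    the sign of the scalar triple product of the three vectors from the
    top-ranked vertex to the others, with vertices ranked by the
    lexicographic order of their canonical identifiers.  In the AABB
    class the identifier ranking is ambiguous; the tie is broken by
    placing the B feature nearest the first A third (see
    :func:`_aabb_orders`).  If the admissible rankings disagree on the
    sign — which happens only for near-symmetric geometries where the
    rule itself is ambiguous — the smaller sign is taken so the result
    stays deterministic and permutation-invariant.

    Every AABB quadruplet additionally receives ``+10 * sgn(cos θ)``
    where θ is the B-A-A-B torsion about the A–A axis; this separates
    trapeze-like (torsion 0°, +10) from parallelogram-like (torsion
    180°, −10) quadruplets that share a graph signature and base sign.

    Parameters
    ----------
    quad : four FeaturePoints
    ids : their canonical identifiers, in the same order
    cls : the identifier class of the quadruplet
    tolerance : planarity tolerance in degrees (default 0)
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if cls in ("AAAA", "AAAB", "AABC"):
        return 0
    if chirality_class(ids) != cls:
        raise RuntimeError("class inconsistent with identifiers")
    c = np.array([[p.x, p.y, p.z] for p in quad], dtype=float)
    angle = min_plane_angle(c)
    planar = angle < max(tolerance, PLANAR_EPS_DEG)

    if cls == "ABCD":
        if planar:
            return 0
        order = sorted(range(4), key=lambda i: ids[i])
        return _triple_product_sign(c, order)

    # AABB: identify the pair with the smaller identifier as "A".
    distinct = sorted(set(ids))
    a_id, b_id = distinct[0], distinct[1]
    a_pair = tuple(i for i in range(4) if ids[i] == a_id)
    b_pair = tuple(i for i in range(4) if ids[i] == b_id)

    if planar:
        base = 0
    else:
        signs = {_triple_product_sign(c, o) for o in _aabb_orders(c, a_pair, b_pair)}
        base = min(signs) if len(signs) > 1 else signs.pop()

    cos_t = _torsion_cos(c, a_pair, b_pair)
    if abs(cos_t) <= 1e-9:
        torsion_term = 0
    else:
        torsion_term = 10 if cos_t > 0 else -10
    return base + torsion_term


@dataclass(frozen=True)
class QuadSignature:
    """Canonical signature of one 4-feature subset.

    ``graph_part`` is the sorted tuple of four canonical identifiers
    (content + topology); ``stereo`` the integer configuration sign.
    """

    graph_part: tuple
    stereo: int

    def serialize(self) -> str:
        parts = "/".join(_id_str(i) for i in self.graph_part)
        return f"{parts}#{self.stereo}"

    @property
    def key(self):
        return (self.graph_part, self.stereo)


def _id_str(fid: CanonicalFeatureId) -> str:
    label, env = fid
    return label + "|" + ";".join(f"{b}:{l}" for b, l in env)


def quad_signature(
    quad: Sequence[FeaturePoint], bin_step: float, tolerance: float = 0.0
) -> QuadSignature:
    """Full canonical signature (graph part + stereo sign) of a quadruplet.

    Invariant under rigid motion of the coordinates and under any
    permutation of the four input features.
    """
    ids = canonical_quad_ids(quad, bin_step)
    cls = chirality_class(ids)
    sign = stereo_sign(quad, ids, cls, tolerance)
    return QuadSignature(tuple(sorted(ids)), sign)


def triplet_signature(
    triplet: Sequence[FeaturePoint], bin_step: float
) -> QuadSignature:
    """Canonical signature of a 3-feature subset.

    Uses the same canonicalisation as quadruplets with two-entry
    environments; the stereo sign is fixed at 0 because three points are
    always superimposable on their mirror image.
    """
    if len(triplet) != 3:
        raise ValueError("a triplet must contain exactly 3 features")
    ids = _canonical_ids(triplet, bin_step)
    return QuadSignature(tuple(sorted(ids)), 0)


def _signature_counts(p: Pharmacophore, tolerance: float) -> list:
    counts: dict = {}
    for quad in itertools.combinations(p.features, 4):
        sig = quad_signature(quad, p.bin_step, tolerance)
        s = sig.serialize()
        counts[s] = counts.get(s, 0) + 1
    return sorted(counts.items())


def pharm_hash(p: Pharmacophore, tolerance: float = 0.0) -> str:
    """md5 digest uniquely encoding a pharmacophore.

    All quadruplet signatures are computed, identical ones counted, the
    (signature, count) pairs lexicographically sorted, serialised in the
    fixed layout described in the module docstring and digested with
    md5.  Equal digests identify pharmacophores with identical content,
    topology (at the configured bin step) and stereoconfiguration; the
    digest is invariant under rigid motion and feature reordering.

    Requires at least four features.
    """
    if len(p) < 4:
        raise ValueError("pharmacophore hash requires at least 4 features")
    payload = "\n".join(f"{s}*{c}" for s, c in _signature_counts(p, tolerance))
    return hashlib.md5(payload.encode("utf-8")).hexdigest()


class PharmFingerprint:
    """Hashed triplet fingerprint of a pharmacophore.

    One bit per distinct triplet signature: the serialised signature is
    md5-digested, the first 8 digest bytes seed Python's Mersenne
    Twister, and the first draw modulo ``n_bits`` selects the bit.  The
    mapping is deterministic for a fixed ``n_bits``; bit-exactness
    across implementations is not a contract, the subset property is:
    the fingerprint of a sub-pharmacophore is a subset of the
    fingerprint of its parent.
    """

    __slots__ = ("n_bits", "bits")

    def __init__(self, bits: Iterable[int], n_bits: int = 2048):
        if not n_bits > 0:
            raise ValueError("n_bits must be positive")
        self.n_bits = int(n_bits)
        self.bits = frozenset(int(b) for b in bits)
        if self.bits and not all(0 <= b < self.n_bits for b in self.bits):
            raise ValueError("bit index out of range")

    def issubset(self, other: "PharmFingerprint") -> bool:
        if self.n_bits != other.n_bits:
            raise ValueError("fingerprint lengths differ")
        return self.bits <= other.bits

    def __eq__(self, other):
        return (
            isinstance(other, PharmFingerprint)
            and self.n_bits == other.n_bits
            and self.bits == other.bits
        )

    def __hash__(self):
        return hash((self.n_bits, self.bits))

    def __len__(self):
        return len(self.bits)

    def __repr__(self):
        return f"PharmFingerprint({len(self.bits)} bits set of {self.n_bits})"


def _triplet_bit(serialized: str, n_bits: int) -> int:
    seed = int.from_bytes(
        hashlib.md5(serialized.encode("utf-8")).digest()[:8], "big"
    )
    return random.Random(seed).randrange(n_bits)


def pharm_fingerprint(
    p: Pharmacophore, n_bits: int = 2048, tolerance: float = 0.0
) -> PharmFingerprint:
    """Hashed fingerprint over all feature triplets of a pharmacophore.

    Pharmacophores with fewer than three features yield an empty
    fingerprint.  ``tolerance`` is accepted for interface symmetry with
    :func:`pharm_hash`; triplet signatures carry no stereo information.
    """
    del tolerance  # triplets cannot be chiral
    bits = set()
    for triplet in itertools.combinations(p.features, 3):
        sig = triplet_signature(triplet, p.bin_step)
        bits.add(_triplet_bit(sig.serialize(), n_bits))
    return PharmFingerprint(bits, n_bits)
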