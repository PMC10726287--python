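"""Thalamocortical neuron geometry.

A cell is a rooted tree of unbranched dendritic sections hanging off a
cylindrical soma, plus a two-compartment axon initial segment (AIS).  Full
reconstructions of VM thalamocortical neurons typically lack usable dendritic
diameters, so diameters are assigned by three fitted laws:

* at terminal sections, ``diam = Q2 - M2 * depth`` (depth = number of branch
  points from the soma), clamped at a small positive floor;
* at branch points, the parent diameter follows a Rall-type 3/2-power
  recursion ``diam = (Q1 + M1 * sum_i d_i^1.5)^(2/3)`` applied tips-to-root;
* primary dendrites (sections emanating from the soma) additionally taper
  with path distance ``d`` from the soma surface by the factor
  ``max(DIAM_min, C3 + A3 * exp(-B3 * d))``.

The soma is a 36.9 x 24 um cylinder and the AIS two 1.5 x 35 um cylinders.
For simulation the tree is compiled into compartments of at most 40 um.
A seeded random skeleton generator stands in when no SWC reconstruction is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DiameterModel", "SkeletonNode", "Compartment", "MorphTree",
    "rall_parent_diameter", "leaf_diameter", "primary_taper_factor",
    "build_cell", "synth_skeleton", "read_swc", "write_swc",
    "SOMA_DIAMETER", "SOMA_LENGTH", "AIS_DIAMETER", "AIS_LENGTH",
    "COMPARTMENT_LENGTH",
]

SOMA_DIAMETER = 36.9     # um
SOMA_LENGTH = 24.0       # um
AIS_DIAMETER = 1.5       # um
AIS_LENGTH = 35.0        # um, each of the two AIS cylinders
COMPARTMENT_LENGTH = 40.0  # um, maximal compartment length


@dataclass(frozen=True)
class DiameterModel:
    """Constants of the three dendritic-diameter laws (least-squares fits)."""

    M1: float = 0.515
    Q1: float = 0.182
    M2: float = 0.004   # um per branch level
    Q2: float = 0.473   # um
    A3: float = 0.861
    B3: float = 0.045   # 1/um
    C3: float = 0.858
    DIAM_min: float = 1.0
    floor: float = 0.1  # um, clamp for the terminal-diameter law

    def __post_init__(self) -> None:
        for name in ("M1", "Q1", "M2", "Q2", "A3", "B3", "C3", "DIAM_min",
                     "floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class SkeletonNode:
    """One unbranched section of the skeleton.

    ``path_length_from_parent`` is the section length in um.  ``kind`` is
    'soma' for the root, 'dendrite' or 'axon' otherwise.  ``branch_depth``
    and ``is_primary`` are derived by :func:`build_cell`.
    """

    id: int
    parent_id: int | None
    kind: str
    path_length_from_parent: float = 0.0
    branch_depth: int = 0
    is_primary: bool = False
    xyz: tuple[float, float, float] | None = None  # distal endpoint


@dataclass
class Compartment:
    id: int
    parent_id: int | None
    length: float            # um
    diameter: float          # um
    membrane_area: float     # um^2, lateral cylinder area
    region: str              # soma | primary_dend | dend | ais_proximal | ais_distal
    distance_from_soma: float  # um, path distance of the midpoint from soma surface
    section_id: int | None = None

    REGIONS = ("soma", "primary_dend", "dend", "ais_proximal", "ais_distal")


@dataclass
class MorphTree:
    """Skeleton nodes, per-node diameters, and compiled compartments."""

    nodes: list[SkeletonNode]
    diameters: dict[int, float] = field(default_factory=dict)
    compartments: list[Compartment] = field(default_factory=list)

    def node(self, nid: int) -> SkeletonNode:
        return self._index()[nid]

    def _index(self) -> dict[int, SkeletonNode]:
        return {n.id: n for n in self.nodes}

    def children(self, nid: int) -> list[SkeletonNode]:
        return [n for n in self.nodes if n.parent_id == nid]

    @property
    def root(self) -> SkeletonNode:
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    def validate(self) -> None:
        idx = self._index()
        if len(idx) != len(self.nodes):
            raise ValueError("duplicate node ids")
        root = self.root
        if root.kind != "soma":
            raise ValueError("root node must be the soma")
        seen: set[int] = set()
        for n in self.nodes:
            if n.parent_id is not None:
                if n.parent_id not in idx:
                    raise ValueError(f"node {n.id} references unknown parent")
                if n.parent_id not in seen:
                    raise ValueError("parent must precede child in node order")
            seen.add(n.id)

    def total_dendritic_length(self) -> float:
        return sum(n.path_length_from_parent for n in self.nodes
                   if n.kind == "dendrite")

    def total_membrane_area(self) -> float:
        return sum(c.membrane_area for c in self.compartments)


def rall_parent_diameter(child_diameters, model: DiameterModel = DiameterModel()) -> float:
    """Parent diameter from its children via the 3/2-power recursion.

    ``(Q1 + M1 * sum_i d_i^1.5) ** (2/3)``; strictly increasing in every
    child diameter.
    """
    child_diameters = list(child_diameters)
    if not child_diameters:
        raise ValueError("no children: the leaf formula must be used")
    if any(d <= 0 for d in child_diameters):
        raise ValueError("child diameters must be positive")
    s = sum(d ** 1.5 for d in child_diameters)
    return (model.Q1 + model.M1 * s) ** (2.0 / 3.0)


def leaf_diameter(branch_depth: int, model: DiameterModel = DiameterModel()) -> float:
    """Terminal-section diameter ``Q2 - M2 * depth`` clamped at ``model.floor``."""
    if branch_depth < 0:
        raise ValueError("branch depth must be non-negative")
    return max(model.floor, model.Q2 - model.M2 * branch_depth)


def primary_taper_factor(distance_from_soma: float,
                         model: DiameterModel = DiameterModel()) -> float:
    """Taper multiplier for primary dendrites at path distance ``d`` (um)."""
    if distance_from_soma < 0:
        raise ValueError("distance must be non-negative")
    return max(model.DIAM_min,
               model.C3 + model.A3 * math.exp(-model.B3 * distance_from_soma))


def _annotate(tree: MorphTree) -> None:
    """Fill branch_depth and is_primary on dendritic sections."""
    idx = tree._index()
    children: dict[int, list[int]] = {}
    for n in tree.nodes:
        if n.parent_id is not None:
            children.setdefault(n.parent_id, []).append(n.id)
    root_id = tree.root.id
    for n in tree.nodes:
        if n.kind != "dendrite":
            continue
        p = idx[n.parent_id]
        if p.id == root_id:
            n.branch_depth = 0
            n.is_primary = True
        else:
            is_bp = len(children.get(p.id, [])) > 1
            n.branch_depth = p.branch_depth + (1 if is_bp else 0)
            # primary only if the whole path from the soma is branch-free
            n.is_primary = p.is_primary and not is_bp


def _assign_diameters(tree: MorphTree, model: DiameterModel) -> None:
    children: dict[int, list[int]] = {}
    for n in tree.nodes:
        if n.parent_id is not None and n.kind == "dendrite":
            children.setdefault(n.parent_id, []).append(n.id)
    # tips-to-root: reverse node order is a valid postorder because parents
    # precede children in the node list
    for n in reversed(tree.nodes):
        if n.kind != "dendrite":
            continue
        kids = children.get(n.id, [])
        if not kids:
            tree.diameters[n.id] = leaf_diameter(n.branch_depth, model)
        else:
            tree.diameters[n.id] = rall_parent_diameter(
                [tree.diameters[k] for k in kids], model)


def _compile(tree: MorphTree, model: DiameterModel) -> None:
    comps: list[Compartment] = []
    cid = 0

    def add(parent, length, diameter, region, dist_mid, section_id=None):
        nonlocal cid
        comps.append(Compartment(cid, parent, length, diameter,
                                 math.pi * diameter * length, region,
                                 dist_mid, section_id))
        cid += 1
        return cid - 1

    soma = add(None, SOMA_LENGTH, SOMA_DIAMETER, "soma", 0.0,
               tree.root.id)
    # axon initial segment: two cylinders off the soma
    prox = add(soma, AIS_LENGTH, AIS_DIAMETER, "ais_proximal", AIS_LENGTH / 2)
    add(prox, AIS_LENGTH, AIS_DIAMETER, "ais_distal", 1.5 * AIS_LENGTH)

    idx = tree._index()
    last_comp: dict[int, int] = {}     # section id -> its last compartment
    sec_dist: dict[int, float] = {}    # section id -> distance of its origin
    root_id = tree.root.id
    for n in tree.nodes:
        if n.kind != "dendrite":
            continue
        if n.parent_id == root_id:
            parent_comp, d0 = soma, 0.0
        else:
            parent_comp = last_comp[n.parent_id]
            d0 = sec_dist[n.parent_id] + idx[n.parent_id].path_length_from_parent
        sec_dist[n.id] = d0
        L = n.path_length_from_parent
        npieces = max(1, math.ceil(L / COMPARTMENT_LENGTH - 1e-9))
        piece = L / npieces
        base = tree.diameters[n.id]
        region = "primary_dend" if n.is_primary else "dend"
        for i in range(npieces):
            mid = d0 + (i + 0.5) * piece
            diam = base * primary_taper_factor(mid, model) if n.is_primary else base
            parent_comp = add(parent_comp, piece, diam, region, mid, n.id)
        last_comp[n.id] = parent_comp
    tree.compartments = comps


def build_cell(skeleton: MorphTree, model: DiameterModel = DiameterModel()) -> MorphTree:
    """Assign diameters and compile the skeleton into <=40-um compartments.

    Returns a new :class:`MorphTree`; the input skeleton is not modified.
    The soma is replaced by the standard cylinder and any axon sections by
    the two-compartment AIS.
    """
    skeleton.validate()
    if not any(n.kind == "dendrite" for n in skeleton.nodes):
        raise ValueError("skeleton has no dendrites")
    tree = MorphTree([replace(n) for n in skeleton.nodes
                      if n.kind != "axon"])
    _annotate(tree)
    _assign_diameters(tree, model)
    _compile(tree, model)
    return tree


def synth_skeleton(seed: int, n_primary: int = 5,
                   mean_branch_length: float = 75.0, max_depth: int = 5,
                   branch_prob: float = 0.9, branch_prob_decay: float = 0.75,
                   min_branch_length: float = 15.0) -> MorphTree:
    """Seeded random binary dendritic skeleton (no diameters).

    Section lengths are exponential with the given mean (clamped below at
    ``min_branch_length``); the probability that a section branches decays
    geometrically with branch depth and is zero beyond ``max_depth``.  The
    defaults target the qualitative distance/diameter spread and the
    ~5.8-mm total dendritic length of full VM thalamocortical
    reconstructions (the length at which the reference synapse totals
    apply).
    """
    if n_primary < 1 or max_depth < 1:
        raise ValueError("n_primary and max_depth must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = [SkeletonNode(0, None, "soma", 0.0, xyz=(0.0, 0.0, 0.0))]
    nid = 1

    def grow(parent_id: int, depth: int, origin: np.ndarray) -> None:
        nonlocal nid
        L = max(min_branch_length, rng.exponential(mean_branch_length))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        end = origin + L * direction
        me = nid
        nodes.append(SkeletonNode(me, parent_id, "dendrite", float(L),
                                  xyz=tuple(float(x) for x in end)))
        nid += 1
        if depth < max_depth and rng.random() < branch_prob * branch_prob_decay ** depth:
            grow(me, depth + 1, end)
            grow(me, depth + 1, end)

    for _ in range(n_primary):
        grow(0, 0, np.zeros(3))
    return MorphTree(nodes)


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column: id, type, x, y, z, radius, parent; 1-based ids)

_SWC_KIND = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}
_KIND_SWC = {"soma": 1, "axon": 2, "dendrite": 3}


def read_swc(path) -> MorphTree:
    """Read an SWC file into a section-level skeleton.

    Chains of SWC points between branch points are collapsed into single
    sections whose length is the summed Euclidean point-to-point distance.
    A single-point soma record is accepted (it becomes the standard soma
    cylinder on :func:`build_cell`).  Mean point radius becomes a provisional
    section diameter (diameter assignment normally overrides it).
    """
    pts: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            pts[int(f[0])] = (int(f[1]), float(f[2]), float(f[3]),
                              float(f[4]), float(f[5]), int(f[6]))
    children: dict[int, list[int]] = {}
    root = None
    for pid, rec in pts.items():
        if rec[5] == -1:
            root = pid
        else:
            children.setdefault(rec[5], []).append(pid)
    if root is None or pts[root][0] != 1:
        raise ValueError("SWC file must contain a soma root (type 1, parent -1)")

    nodes = [SkeletonNode(0, None, "soma", 0.0,
                          xyz=(pts[root][1], pts[root][2], pts[root][3]))]
    nid = 1

    def dist(a: int, b: int) -> float:
        ra, rb = pts[a], pts[b]
        return math.dist((ra[1], ra[2], ra[3]), (rb[1], rb[2], rb[3]))

    def walk(start: int, parent_node: int) -> None:
        nonlocal nid
        # collapse the unbranched chain starting at `start`
        chain = [start]
        while len(children.get(chain[-1], [])) == 1:
            chain.append(children[chain[-1]][0])
        length = 0.0
        prev = pts[start][5]
        for p in chain:
            length += dist(prev, p)
            prev = p
        kind = _SWC_KIND.get(pts[start][0], "dendrite")
        end = pts[chain[-1]]
        me = nid
        nodes.append(SkeletonNode(me, parent_node, kind, length,
                                  xyz=(end[1], end[2], end[3])))
        nid += 1
        for c in children.get(chain[-1], []):
            walk(c, me)

    for c in children.get(root, []):
        walk(c, 0)
    return MorphTree(nodes)


def write_swc(tree: MorphTree, path) -> None:
    """Write the skeleton as SWC, one point per section endpoint."""
    idx = {n.id: n for n in tree.nodes}
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        swc_id = {}
        for i, n in enumerate(tree.nodes, start=1):
            swc_id[n.id] = i
            x, y, z = n.xyz if n.xyz is not None else (0.0, 0.0, 0.0)
            radius = tree.diameters.get(n.id, 1.0) / 2.0
            if n.kind == "soma":
                radius = SOMA_DIAMETER / 2.0
            parent = -1 if n.parent_id is None else swc_id[idx[n.parent_id].id]
            fh.write(f"{i} {_KIND_SWC[n.kind]} {x:.4f} {y:.4f} {z:.4f} "
                     f"{radius:.4f} {parent}\n")
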