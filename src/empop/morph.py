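"""Morphology I/O, morphometrics, diametrization and exemplar construction.

A morphology is a rooted tree of typed sections (axon/AIS/myelin/basal/apical)
attached to a cylindrical soma.  The soma is always represented as an
equivalent-area cylinder: a single-point (spherical) SWC soma of radius ``r``
becomes a cylinder with ``radius = r`` and ``length = r`` so that its
lateral-plus-end surface ``2*pi*r*L + 2*pi*r**2`` equals the sphere area
``4*pi*r**2``; multi-point soma contours are converted to a cylinder with the
contour's mean radius and matching surface of revolution.

All lengths are in micrometers and areas in square micrometers.  SWC column 6
holds radii; diameters are doubled on read and halved on write.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "DiameterModel",
    "SurfaceProfile",
    "MorphologyError",
    "read_swc",
    "write_swc",
    "residual_path_distances",
    "fit_diameter_model",
    "apply_diametrization",
    "surface_area_profile",
    "proximal_surface_area",
    "build_exemplar",
    "total_dendrite_area",
]

#: section types; AIS and myelin only appear on constructed (exemplar-style) cells
STYPES = ("soma", "axon", "AIS", "myelin", "basal", "apical")

# SWC type-column mapping.  1-4 are the SWC standard; 6/7 are the custom codes
# used for constructed AIS and myelin sections.
_STYPE_TO_SWC = {"soma": 1, "axon": 2, "basal": 3, "apical": 4, "AIS": 6, "myelin": 7}
_SWC_TO_STYPE = {v: k for k, v in _STYPE_TO_SWC.items()}

DENDRITE_TYPES = ("basal", "apical")


class MorphologyError(ValueError):
    """Raised on malformed SWC input or invalid morphology operations."""


@dataclass
class Section:
    """A contiguous unbranched run of points of one neurite type.

    ``points`` is an (n, 4) float array of x, y, z, diameter rows.  Non-root
    sections start at their parent's branch point, so the cable between a
    branch point and the first child node belongs to the child.
    """

    id: int
    stype: str
    points: np.ndarray
    parent: int | None = None  # section id; None = attached to soma

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise MorphologyError(f"section {self.id}: points must be (n, 4)")
        if len(self.points) < 2:
            raise MorphologyError(f"section {self.id}: needs >= 2 points")
        if np.any(self.points[:, 3] <= 0):
            raise MorphologyError(f"section {self.id}: non-positive diameter")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points[:, :3], axis=0), axis=1)))

    @property
    def mean_diameter(self) -> float:
        return float(self.points[:, 3].mean())

    def arc_lengths(self) -> np.ndarray:
        """Cumulative path length at each point, starting at 0."""
        steps = np.linalg.norm(np.diff(self.points[:, :3], axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class Morphology:
    """Cylindrical soma plus a tree of neurite sections."""

    soma_radius: float
    soma_length: float
    sections: dict[int, Section] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def soma_area(self) -> float:
        """Lateral plus end-cap surface of the soma cylinder (um^2)."""
        r, length = self.soma_radius, self.soma_length
        return 2 * math.pi * r * length + 2 * math.pi * r**2

    def children(self, sec_id: int | None) -> list[Section]:
        return [s for s in self.sections.values() if s.parent == sec_id]

    def roots(self, stype: str | None = None) -> list[Section]:
        out = [s for s in self.sections.values() if s.parent is None]
        if stype is not None:
            out = [s for s in out if s.stype == stype]
        return out

    def iter_sections(self, stype: str | None = None):
        for sid in sorted(self.sections):
            s = self.sections[sid]
            if stype is None or s.stype == stype:
                yield s

    def has_type(self, stype: str) -> bool:
        return any(s.stype == stype for s in self.sections.values())

    def validate(self) -> None:
        seen: set[int] = set()
        for s in self.sections.values():
            if s.parent is not None and s.parent not in self.sections:
                raise MorphologyError(f"section {s.id}: missing parent {s.parent}")
        for root in self.roots():
            stack = [root.id]
            while stack:
                sid = stack.pop()
                if sid in seen:
                    raise MorphologyError(f"cycle through section {sid}")
                seen.add(sid)
                stack.extend(c.id for c in self.children(sid))
        if len(seen) != len(self.sections):
            raise MorphologyError("section tree has unreachable sections")
        if self.soma_area <= 0:
            raise MorphologyError("non-positive soma area")

    def copy(self) -> "Morphology":
        return Morphology(
            soma_radius=self.soma_radius,
            soma_length=self.soma_length,
            sections={
                sid: replace(s, points=s.points.copy()) for sid, s in self.sections.items()
            },
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    Radii are doubled into diameters.  A single-point soma is interpreted as a
    sphere and converted to the equivalent-area cylinder; a multi-point soma
    is converted via its surface of revolution.  Original SWC node ids of each
    section's own nodes are kept in ``metadata["swc_ids"]``.
    """
    path = Path(path)
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
        nid, ntype = int(cols[0]), int(cols[1])
        x, y, z, r = (float(c) for c in cols[2:6])
        parent = int(cols[6])
        if r <= 0:
            raise MorphologyError(f"{path}:{lineno}: non-positive radius for node {nid}")
        if nid in nodes:
            raise MorphologyError(f"{path}:{lineno}: duplicate node id {nid}")
        nodes[nid] = (ntype, x, y, z, r, parent)

    if not nodes:
        raise MorphologyError(f"{path}: empty SWC file")
    for nid, (_, _, _, _, _, parent) in nodes.items():
        if parent != -1 and parent not in nodes:
            raise MorphologyError(f"{path}: node {nid} references absent parent {parent}")

    soma_ids = [nid for nid, n in nodes.items() if n[0] == 1]
    if not soma_ids:
        raise MorphologyError(f"{path}: no soma node (type 1)")
    soma_set = set(soma_ids)

    # soma cylinder
    soma_pts = np.array([[nodes[i][1], nodes[i][2], nodes[i][3], nodes[i][4]] for i in soma_ids])
    if len(soma_ids) == 1:
        r = soma_pts[0, 3]
        soma_radius, soma_length = r, r  # sphere-equivalent cylinder
    else:
        radii = soma_pts[:, 3]
        seg = np.linalg.norm(np.diff(soma_pts[:, :3], axis=0), axis=1)
        lateral = np.sum(
            math.pi
            * (radii[:-1] + radii[1:])
            * np.sqrt(seg**2 + (radii[1:] - radii[:-1]) ** 2)
        )
        soma_radius = float(radii.mean())
        soma_length = max(float(lateral / (2 * math.pi * soma_radius)), soma_radius * 0.1)

    # children map over neurite nodes
    children: dict[int, list[int]] = {}
    for nid, n in sorted(nodes.items()):
        if n[0] == 1:
            continue
        parent = n[5]
        key = -1 if parent in soma_set or parent == -1 else parent
        children.setdefault(key, []).append(nid)

    def n_children(nid: int) -> int:
        return len(children.get(nid, []))

    sections: dict[int, Section] = {}
    swc_ids: dict[int, list[int]] = {}
    next_sid = 0

    def point_of(nid: int) -> list[float]:
        _, x, y, z, r, _ = nodes[nid]
        return [x, y, z, 2 * r]

    # walk chains: a section runs until a branch point or a terminal
    stack: list[tuple[int, int | None, list[list[float]], list[int]]] = []
    for root_nid in reversed(children.get(-1, [])):
        stack.append((root_nid, None, [], []))
    while stack:
        nid, parent_sid, prefix_pts, prefix_ids = stack.pop()
        pts = list(prefix_pts)
        own_ids = list(prefix_ids)
        stype = _SWC_TO_STYPE.get(nodes[nid][0], "basal")
        cur = nid
        while True:
            pts.append(point_of(cur))
            own_ids.append(cur)
            kids = children.get(cur, [])
            # a section ends at a branch point, a terminal, or a type change
            if len(kids) == 1 and nodes[kids[0]][0] == nodes[cur][0]:
                cur = kids[0]
            else:
                break
        if len(pts) < 2:
            raise MorphologyError(
                f"{path}: single-node neurite root {nid}; sections need >= 2 points"
            )
        sid = next_sid
        next_sid += 1
        sections[sid] = Section(id=sid, stype=stype, points=np.array(pts), parent=parent_sid)
        swc_ids[sid] = own_ids
        for kid in reversed(children.get(cur, [])):
            # child section starts at this branch point
            stack.append((kid, sid, [point_of(cur)], []))

    m = Morphology(
        soma_radius=soma_radius,
        soma_length=soma_length,
        sections=sections,
        metadata={"swc_ids": swc_ids, "source": str(path)},
    )
    m.validate()
    return m


def _fmt(x: float) -> str:
    return repr(float(x))


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write a morphology as 7-column SWC (soma as a single spherical node)."""
    path = Path(path)
    lines = ["# written by empop"]
    # sphere with the same lateral+end area as the soma cylinder
    r_eq = math.sqrt(m.soma_area / (4 * math.pi))
    lines.append(f"1 1 0.0 0.0 0.0 {_fmt(r_eq)} -1")
    next_id = 2
    last_node_of: dict[int, int] = {}

    def emit(sec: Section, parent_sid: int | None) -> None:
        nonlocal next_id
        start = 0 if sec.parent is None else 1  # skip inherited branch point
        parent_node = 1 if parent_sid is None else last_node_of[parent_sid]
        for i in range(start, len(sec.points)):
            x, y, z, d = sec.points[i]
            lines.append(
                f"{next_id} {_STYPE_TO_SWC[sec.stype]} {_fmt(x)} {_fmt(y)} {_fmt(z)} "
                f"{_fmt(d / 2)} {parent_node}"
            )
            parent_node = next_id
            next_id += 1
        last_node_of[sec.id] = parent_node

    stack = [(s, None) for s in sorted(m.roots(), key=lambda s: s.id, reverse=True)]
    while stack:
        sec, parent_sid = stack.pop()
        emit(sec, parent_sid)
        for child in sorted(m.children(sec.id), key=lambda s: s.id, reverse=True):
            stack.append((child, sec.id))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Residual path distances and the diameter model
# ---------------------------------------------------------------------------

def _raw_residuals(m: Morphology, neurite_type: str) -> tuple[dict[int, float], float]:
    """Path distance from each section END to its furthest downstream terminal,
    plus the largest root-to-terminal path length of that neurite type."""
    resid: dict[int, float] = {}
    secs = [s for s in m.iter_sections(neurite_type)]

    def residual(sec: Section) -> float:
        if sec.id in resid:
            return resid[sec.id]
        kids = [c for c in m.children(sec.id) if c.stype == neurite_type]
        r = 0.0 if not kids else max(residual(c) + c.length for c in kids)
        resid[sec.id] = r
        return r

    for s in secs:
        residual(s)
    max_len = 0.0
    for s in secs:
        if s.parent is None or m.sections[s.parent].stype != neurite_type:
            max_len = max(max_len, s.length + resid[s.id])
    return resid, max_len


def residual_path_distances(m: Morphology, neurite_type: str) -> dict[int, float]:
    """Normalized distance from each section's end to its furthest downstream
    terminal, divided by the largest root-to-terminal path length of the
    neurite type.  Terminal sections map to 0; values lie in [0, 1]."""
    resid, max_len = _raw_residuals(m, neurite_type)
    if not resid:
        return {}
    if max_len <= 0:
        raise MorphologyError(f"zero total path length for {neurite_type}")
    return {sid: r / max_len for sid, r in resid.items()}


@dataclass
class DiameterModel:
    """Polynomial of section diameter vs normalized residual path distance.

    The distance coordinate of a section is the normalized residual distance
    at the section's *first* point (residual at its end plus its own length,
    over the largest root-to-terminal path length).
    """

    neurite_type: str
    degree: int
    coefficients: np.ndarray  # numpy polyval order (highest power first)

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, x)

    def validate_positive(self, n: int = 101) -> None:
        xs = np.linspace(0.0, 1.0, n)
        if np.any(self(xs) <= 0):
            raise MorphologyError(
                f"diameter model for {self.neurite_type} is non-positive on [0, 1]"
            )


def _section_coordinates(m: Morphology, neurite_type: str) -> dict[int, float]:
    """Normalized residual distance at each section's first point."""
    resid, max_len = _raw_residuals(m, neurite_type)
    if not resid:
        return {}
    return {
        sid: min((r + m.sections[sid].length) / max_len, 1.0) for sid, r in resid.items()
    }


def fit_diameter_model(
    pop: list[Morphology], neurite_type: str, degree: int = 3
) -> DiameterModel:
    """Least-squares polynomial of section mean diameter vs normalized
    residual distance over a population.  Default degree 3."""
    xs: list[float] = []
    ys: list[float] = []
    for m in pop:
        coords = _section_coordinates(m, neurite_type)
        for sid, x in coords.items():
            xs.append(x)
            ys.append(m.sections[sid].mean_diameter)
    if len(xs) < degree + 1:
        raise MorphologyError(
            f"{len(xs)} data points cannot constrain a degree-{degree} polynomial"
        )
    coeffs = np.polyfit(np.array(xs), np.array(ys), degree)
    return DiameterModel(neurite_type=neurite_type, degree=degree, coefficients=coeffs)


def apply_diametrization(m: Morphology, model: DiameterModel) -> Morphology:
    """Re-assign diameters of one neurite type from a fitted diameter model.

    Each section's first diameter is read from the model at its normalized
    residual distance; its last diameter is the mean of that first diameter
    and the largest model-assigned first diameter among its children
    (terminals read the last diameter from the model at the section end);
    diameters taper linearly in between.  Geometry is unchanged and the
    operation is idempotent for a fixed model.
    """
    out = m.copy()
    t = model.neurite_type
    coords_first = _section_coordinates(out, t)
    resid_end = residual_path_distances(out, t)
    if not coords_first:
        return out

    d_first = {sid: float(model(x)) for sid, x in coords_first.items()}
    for sid, d in d_first.items():
        if d <= 0:
            raise MorphologyError(f"model assigned non-positive diameter to section {sid}")

    for sid in coords_first:
        sec = out.sections[sid]
        kids = [c for c in out.children(sid) if c.stype == t]
        if kids:
            d_last = 0.5 * (d_first[sid] + max(d_first[c.id] for c in kids))
        else:
            d_last = float(model(resid_end[sid]))
        if d_last <= 0:
            raise MorphologyError(f"model assigned non-positive diameter to section {sid}")
        arc = sec.arc_lengths()
        total = arc[-1] if arc[-1] > 0 else 1.0
        sec.points[:, 3] = d_first[sid] + (d_last - d_first[sid]) * arc / total
    return out


# ---------------------------------------------------------------------------
# Surface-area profiles
# ---------------------------------------------------------------------------

@dataclass
class SurfaceProfile:
    """Cumulative dendritic surface area binned by path distance from soma."""

    bin_edges: np.ndarray  # (n_bins + 1,) um
    cumulative_area: np.ndarray  # (n_bins,) um^2, non-decreasing

    @property
    def total(self) -> float:
        return float(self.cumulative_area[-1]) if len(self.cumulative_area) else 0.0


def _dendrite_segments(m: Morphology):
    """Yield (start_dist, end_dist, r_start, r_end, straight_len) per
    inter-point segment of every dendritic section, with path distance
    measured from the soma surface along the tree."""
    start_of: dict[int, float] = {}

    def section_start(sec: Section) -> float:
        if sec.id in start_of:
            return start_of[sec.id]
        if sec.parent is None:
            d = 0.0
        else:
            parent = m.sections[sec.parent]
            d = section_start(parent) + parent.length
        start_of[sec.id] = d
        return d

    for sec in m.iter_sections():
        if sec.stype not in DENDRITE_TYPES:
            continue
        base = section_start(sec)
        arc = sec.arc_lengths()
        radii = sec.points[:, 3] / 2
        for i in range(len(arc) - 1):
            seg_len = arc[i + 1] - arc[i]
            if seg_len <= 0:
                continue
            yield base + arc[i], base + arc[i + 1], radii[i], radii[i + 1], seg_len


def _frustum_partial_area(r0, r1, seg_len, a, b) -> float:
    """Lateral area of the sub-frustum between arc positions a and b in [0, L]."""
    slope = (r1 - r0) / seg_len
    ra, rb = r0 + slope * a, r0 + slope * b
    return math.pi * (ra + rb) * (b - a) * math.sqrt(1 + slope**2)


def surface_area_profile(m: Morphology, bin_width: float = 20.0) -> SurfaceProfile:
    """Total dendritic surface area as a function of path distance from the
    soma, as cumulative sums over bins of ``bin_width`` micrometers.  Frusta
    crossing bin boundaries are split analytically."""
    segments = list(_dendrite_segments(m))
    if not segments:
        return SurfaceProfile(np.array([0.0, bin_width]), np.array([0.0]))
    max_dist = max(s[1] for s in segments)
    n_bins = max(1, math.ceil(max_dist / bin_width - 1e-12))
    edges = np.arange(n_bins + 1) * bin_width
    areas = np.zeros(n_bins)
    for d0, d1, r0, r1, seg_len in segments:
        b0 = min(int(d0 / bin_width), n_bins - 1)
        b1 = min(int((d1 - 1e-12) / bin_width), n_bins - 1)
        for b in range(b0, b1 + 1):
            lo = max(d0, edges[b])
            hi = min(d1, edges[b + 1]) if b < n_bins - 1 else d1
            if hi <= lo:
                continue
            areas[b] += _frustum_partial_area(r0, r1, seg_len, lo - d0, hi - d0)
    return SurfaceProfile(bin_edges=edges, cumulative_area=np.cumsum(areas))


def proximal_surface_area(m: Morphology, cutoff: float = 500.0) -> float:
    """Dendritic surface area within ``cutoff`` micrometers of path distance
    from the soma (default 500 um)."""
    total = 0.0
    for d0, d1, r0, r1, seg_len in _dendrite_segments(m):
        if d0 >= cutoff:
            continue
        hi = min(d1, cutoff)
        total += _frustum_partial_area(r0, r1, seg_len, 0.0, hi - d0)
    return total


def total_dendrite_area(m: Morphology) -> float:
    """Total dendritic (basal + apical) lateral surface area in um^2."""
    return proximal_surface_area(m, cutoff=math.inf)


# ---------------------------------------------------------------------------
# Exemplar construction
# ---------------------------------------------------------------------------

AIS_LENGTH = 60.0  # um, constant-diameter stub replacing the reconstructed axon
MYELIN_LENGTH = 1000.0  # um, passive sink section after the AIS
DEFAULT_AIS_DIAMETER = 1.0  # um, used when a population carries no axons


def _mean_ais_diameter(pop: list[Morphology], length: float = AIS_LENGTH) -> float | None:
    """Population mean of axon point diameters within the first ``length`` um."""
    diams: list[float] = []
    for m in pop:
        for root in m.roots("axon"):
            arc = root.arc_lengths()
            mask = arc <= length
            if mask.any():
                diams.extend(root.points[mask, 3].tolist())
    return float(np.mean(diams)) if diams else None


def _profile_matrix(pop: list[Morphology], bin_width: float) -> np.ndarray:
    profiles = [surface_area_profile(m, bin_width) for m in pop]
    n = max(len(p.cumulative_area) for p in profiles)
    mat = np.zeros((len(pop), n))
    for i, p in enumerate(profiles):
        c = p.cumulative_area
        mat[i, : len(c)] = c
        mat[i, len(c):] = c[-1]  # profile saturates at its total
    return mat


def attach_ais_and_myelin(m: Morphology, ais_diameter: float) -> Morphology:
    """Replace reconstructed axons with a two-section 60 um constant-diameter
    AIS followed by a 1 mm myelin section (diameter equal to the AIS)."""
    out = m.copy()
    for sec in list(out.iter_sections()):
        if sec.stype in ("axon", "AIS", "myelin"):
            # drop the whole axonal subtree
            drop = {sec.id}
            stack = [sec.id]
            while stack:
                sid = stack.pop()
                for c in out.children(sid):
                    drop.add(c.id)
                    stack.append(c.id)
            for sid in drop:
                out.sections.pop(sid, None)
    nid = max(out.sections, default=-1) + 1
    half = AIS_LENGTH / 2
    d = ais_diameter

    def straight(sid, stype, parent, y0, y1):
        pts = np.array([[0.0, y0, 0.0, d], [0.0, y1, 0.0, d]])
        out.sections[sid] = Section(id=sid, stype=stype, points=pts, parent=parent)

    straight(nid, "AIS", None, 0.0, -half)
    straight(nid + 1, "AIS", nid, -half, -AIS_LENGTH)
    straight(nid + 2, "myelin", nid + 1, -AIS_LENGTH, -(AIS_LENGTH + MYELIN_LENGTH))
    out.metadata["ais_diameter"] = float(d)
    out.validate()
    return out


def build_exemplar(
    pop: list[Morphology],
    bin_width: float = 20.0,
    default_ais_diameter: float = DEFAULT_AIS_DIAMETER,
) -> Morphology:
    """Construct a representative cell from a morphology population.

    The soma is a cylinder with the population-mean radius whose length is set
    so its lateral+end surface equals the population-mean soma area.  The axon
    is replaced by a 60 um constant-diameter AIS (two sections, diameter =
    population mean over the first 60 um of reconstructed axons) plus a 1 mm
    myelin sink.  Dendrites are copied from the member whose surface-area
    profile is closest (L2 over bins) to the per-bin median profile.
    """
    if not pop:
        raise MorphologyError("empty population")
    mean_radius = float(np.mean([m.soma_radius for m in pop]))
    mean_area = float(np.mean([m.soma_area for m in pop]))
    # 2*pi*r*L + 2*pi*r^2 = mean_area
    soma_length = mean_area / (2 * math.pi * mean_radius) - mean_radius
    if soma_length <= 0:
        raise MorphologyError("population mean soma area incompatible with mean radius")

    mat = _profile_matrix(pop, bin_width)
    median = np.median(mat, axis=0)
    dists = np.linalg.norm(mat - median, axis=1)
    chosen = int(np.argmin(dists))

    ais_d = _mean_ais_diameter(pop)
    if ais_d is None:
        import warnings

        warnings.warn(
            "population has no axons; using the configured default AIS diameter",
            stacklevel=2,
        )
        ais_d = default_ais_diameter

    exemplar = pop[chosen].copy()
    exemplar.soma_radius = mean_radius
    exemplar.soma_length = soma_length
    exemplar = attach_ais_and_myelin(exemplar, ais_d)
    exemplar.metadata.update(
        {
            "exemplar": {
                "chosen_index": chosen,
                "chosen_source": pop[chosen].metadata.get("source"),
                "soma_radius": mean_radius,
                "soma_length": soma_length,
                "ais_diameter": ais_d,
            }
        }
    )
    return exemplar


def save_exemplar(m: Morphology, swc_path: str | Path) -> None:
    """Write an exemplar as SWC plus a JSON sidecar with its metadata."""
    write_swc(m, swc_path)
    sidecar = Path(swc_path).with_suffix(".json")
    sidecar.write_text(json.dumps(m.metadata.get("exemplar", {}), indent=2) + "\n")
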