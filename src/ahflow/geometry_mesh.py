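"""Parametric quarter anterior-segment geometry and tagged tet meshing.

The computational domain is one quarter (azimuth 0..90 deg) of an
idealized anterior segment in cylindrical layout:

* **AC** — anterior chamber: a dome bounded below by the iris/lens plane
  (z = 0) and above by a spherical-cap cornea falling from ``ac_depth``
  at the axis to the rim height at the angle; aqueous enters through an
  annular iris--lens slit in the floor.
* **TM / SC** — trabecular meshwork and Schlemm's canal: thin annular
  bands of rectangular cross-section on the outer wall at the angle.
* **CC** — collector channels: small radial ducts leaving the outer SC
  wall, evenly spaced in azimuth (square cross-section, area-matched to
  the nominal circular diameter).
* **CB** — ciliary body face: an annular porous slab under the TM/SC at
  the angle carrying the unconventional outflow.

Meshing is structured: a cylindrical grid of hexahedra (graded r-lines,
azimuth lines refined around the CC slots, z-levels following the dome
profile) is split into tetrahedra with the Freudenthal/Kuhn 6-tet
pattern, which is face-conforming when applied uniformly.  Cells
touching the axis collapse to wedges; their degenerate tets are dropped.
Every cell carries a region tag and every boundary facet exactly one
boundary tag.

Coordinates: z is the optical axis (anterior positive), origin at the
chamber center on the iris plane, azimuth theta in [0, 90] deg between
the two symmetry planes y = 0 (theta = 0) and x = 0 (theta = 90 deg).
All lengths are SI meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# region / boundary tag ids (stable across the package)
REGION_AC, REGION_TM, REGION_SC, REGION_CC, REGION_CB = 1, 2, 3, 4, 5
REGION_NAMES = {REGION_AC: "AC", REGION_TM: "TM", REGION_SC: "SC",
                REGION_CC: "CC", REGION_CB: "CB"}

(TAG_INFLOW, TAG_CORNEA, TAG_IRIS, TAG_LENS, TAG_CC_OUTLET,
 TAG_CB_OUTLET, TAG_SYMMETRY_X, TAG_SYMMETRY_Y, TAG_WALL) = range(1, 10)
BOUNDARY_NAMES = {
    TAG_INFLOW: "inflow", TAG_CORNEA: "cornea", TAG_IRIS: "iris",
    TAG_LENS: "lens", TAG_CC_OUTLET: "cc_outlet",
    TAG_CB_OUTLET: "cb_outlet", TAG_SYMMETRY_X: "symmetry_x",
    TAG_SYMMETRY_Y: "symmetry_y", TAG_WALL: "wall",
}


@dataclass
class GeometryParams:
    """Dimensions of the quarter anterior-segment model (SI meters).

    ``cb_face_height`` (axial height of the ciliary-body face exposed to
    the chamber) and ``lens_radius`` (pupil-margin radius locating the
    inflow slit) are not standard biometry outputs; their defaults are
    chosen so the lumped outflow model reproduces physiologic baseline
    IOP and a realistic ciliary-body face velocity (see docs/methods.md).
    """

    ac_depth: float = 3.5e-3
    ac_diameter: float = 11.3e-3
    tm_height_axial: float = 275e-6
    tm_thickness_radial: float = 100e-6
    sc_height_axial: float = 275e-6
    sc_thickness_radial: float = 30e-6
    n_collector_channels: int = 7
    cc_diameter: float = 50e-6
    cc_length: float = 200e-6
    cb_thickness_radial: float = 300e-6
    cb_face_height: float = 1.9e-3
    inflow_gap: float = 250e-6
    lens_radius: float = 2.5e-3
    cc_azimuth_offset_deg: float = 0.0

    def __post_init__(self):
        for name in ("ac_depth", "ac_diameter", "tm_height_axial",
                     "tm_thickness_radial", "sc_height_axial",
                     "sc_thickness_radial", "cc_diameter", "cc_length",
                     "cb_thickness_radial", "cb_face_height", "inflow_gap",
                     "lens_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GeometryParams.{name} must be positive")
        if self.n_collector_channels < 1:
            raise ValueError("need at least one collector channel")
        if self.sc_height_axial != self.tm_height_axial:
            raise ValueError("sc_height_axial must equal tm_height_axial")
        if self.cc_diameter >= self.sc_height_axial:
            raise ValueError("cc_diameter must be smaller than the SC height")

    @property
    def ac_radius(self) -> float:
        return self.ac_diameter / 2.0


@dataclass
class GeometrySpec:
    """Boundary representation of the quarter domain (derived values)."""

    params: GeometryParams
    r_angle: float            # AC radius: inner face of TM and CB
    r_tm_out: float
    r_sc_out: float
    r_cb_out: float
    r_cc_out: float
    h_cb: float               # ciliary body face height (z band [0, h_cb])
    h_rim: float              # total angle-wall height = h_cb + TM height
    dome_radius: float        # corneal sphere radius
    dome_zc: float            # corneal sphere center height
    cc_centers_rad: np.ndarray
    cc_half_width_rad: float
    slit_r_in: float
    slit_r_out: float
    volume_groups: tuple = ("AC", "TM", "SC", "CC", "CB")
    surface_groups: tuple = ("inflow", "cornea", "iris", "lens", "cc_outlet",
                             "cb_outlet", "symmetry_x", "symmetry_y", "wall")

    def dome_height(self, r):
        """Corneal (anterior) surface height z_top(r) for r <= r_angle."""
        r = np.asarray(r, dtype=float)
        return self.dome_zc + np.sqrt(self.dome_radius**2 - r**2)

    def analytic_ac_volume(self) -> float:
        """Exact quarter-chamber volume under the corneal cap (m^3)."""
        rho, zc, R = self.dome_radius, self.dome_zc, self.r_angle
        full = (math.pi * R**2 * zc
                + (2.0 * math.pi / 3.0) * (rho**3 - (rho**2 - R**2) ** 1.5))
        return full / 4.0


def build_geometry(params: GeometryParams) -> GeometrySpec:
    """Derive the boundary representation, validating consistency.

    Raises ``ValueError`` naming the violated constraint for
    geometrically impossible parameter sets.
    """
    p = params
    R = p.ac_radius
    h_rim = p.cb_face_height + p.tm_height_axial
    if h_rim >= p.ac_depth:
        raise ValueError(
            "cb_face_height + tm_height_axial must be smaller than ac_depth "
            "(angle wall taller than the chamber)")
    if p.lens_radius + p.inflow_gap >= R:
        raise ValueError(
            "lens_radius + inflow_gap must fit inside the chamber radius "
            "(no room for the iris annulus)")

    r_tm_out = R + p.tm_thickness_radial
    r_sc_out = r_tm_out + p.sc_thickness_radial
    r_cb_out = R + p.cb_thickness_radial
    r_cc_out = r_sc_out + p.cc_length
    if r_cb_out <= r_sc_out:
        raise ValueError(
            "cb_thickness_radial must exceed the TM + SC radial thickness "
            "(the ciliary body slab must underlie Schlemm's canal)")
    if r_cc_out <= r_cb_out:
        raise ValueError(
            "cc_length must reach beyond the ciliary body outer face")

    # corneal sphere through (r=0, z=ac_depth) with apex on the axis and
    # passing through (R, h_rim)
    d = p.ac_depth - h_rim
    rho = (R**2 + d**2) / (2.0 * d)
    zc = p.ac_depth - rho

    # collector channel slots: square duct of the same cross-sectional
    # area as the nominal circular diameter
    side = p.cc_diameter * math.sqrt(math.pi) / 2.0
    half_w = 0.5 * side / r_sc_out
    n = p.n_collector_channels
    centers = (np.arange(n) + 0.5) / n * (math.pi / 2.0)
    centers = centers + math.radians(p.cc_azimuth_offset_deg)
    if np.any(centers - half_w < 0.0) or np.any(centers + half_w > math.pi / 2):
        raise ValueError(
            "collector channel slots must lie inside the quarter azimuth")
    if np.any(np.diff(centers) < 2.0 * half_w):
        raise ValueError("collector channel slots must not overlap")

    return GeometrySpec(
        params=p, r_angle=R, r_tm_out=r_tm_out, r_sc_out=r_sc_out,
        r_cb_out=r_cb_out, r_cc_out=r_cc_out, h_cb=p.cb_face_height,
        h_rim=h_rim, dome_radius=rho, dome_zc=zc, cc_centers_rad=centers,
        cc_half_width_rad=half_w, slit_r_in=p.lens_radius,
        slit_r_out=p.lens_radius + p.inflow_gap,
    )


# ---------------------------------------------------------------------------
# mesh model
# ---------------------------------------------------------------------------

class MeshModel:
    """Tagged tetrahedral mesh of the quarter anterior segment.

    Attributes
    ----------
    nodes : (N, 3) float array of coordinates, m.
    cells : (M, 4) int array of tet connectivity (positive orientation).
    region_tags : (M,) int array of region ids (see ``REGION_NAMES``).
    boundary_faces : (B, 3) int array of boundary triangles.
    boundary_tags : (B,) int array of boundary ids (``BOUNDARY_NAMES``).
    boundary_owner : (B,) int array, owning cell of each boundary face.
    """

    def __init__(self, nodes, cells, region_tags, boundary_faces,
                 boundary_tags, boundary_owner, resolution_level, spec):
        self.nodes = np.asarray(nodes, dtype=float)
        self.cells = np.asarray(cells, dtype=np.int64)
        self.region_tags = np.asarray(region_tags, dtype=np.int32)
        self.boundary_faces = np.asarray(boundary_faces, dtype=np.int64)
        self.boundary_tags = np.asarray(boundary_tags, dtype=np.int32)
        self.boundary_owner = np.asarray(boundary_owner, dtype=np.int64)
        self.resolution_level = resolution_level
        self.spec = spec
        self._cache = {}

    # -- basic measures ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def cell_volumes(self) -> np.ndarray:
        if "vol" not in self._cache:
            x = self.nodes[self.cells]
            v = np.einsum("ij,ij->i",
                          np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                          x[:, 3] - x[:, 0]) / 6.0
            self._cache["vol"] = v
        return self._cache["vol"]

    def cell_centroids(self) -> np.ndarray:
        if "cent" not in self._cache:
            self._cache["cent"] = self.nodes[self.cells].mean(axis=1)
        return self._cache["cent"]

    def cell_azimuth_deg(self) -> np.ndarray:
        c = self.cell_centroids()
        return np.degrees(np.arctan2(c[:, 1], c[:, 0]))

    def porous_cell_mask(self) -> np.ndarray:
        return np.isin(self.region_tags, (REGION_TM, REGION_CB))

    def region_volume(self, region: int) -> float:
        return float(self.cell_volumes()[self.region_tags == region].sum())

    # -- boundary measures -------------------------------------------------
    def boundary_face_geometry(self):
        """(areas, outward unit normals, centroids) of all boundary faces."""
        if "bfgeo" not in self._cache:
            x = self.nodes[self.boundary_faces]
            cr = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
            areas = 0.5 * np.linalg.norm(cr, axis=1)
            normals = cr / np.linalg.norm(cr, axis=1)[:, None]
            centroids = x.mean(axis=1)
            own_cent = self.cell_centroids()[self.boundary_owner]
            flip = np.einsum("ij,ij->i", normals, centroids - own_cent) < 0
            normals[flip] *= -1.0
            self._cache["bfgeo"] = (areas, normals, centroids)
        return self._cache["bfgeo"]

    def boundary_nodes(self, tag: int) -> np.ndarray:
        """Sorted unique node ids on boundary facets with a given tag."""
        return np.unique(self.boundary_faces[self.boundary_tags == tag])

    # -- interior interfaces -----------------------------------------------
    def interface_faces(self, region_a: int, region_b: int):
        """Interior triangles between two regions.

        Returns ``(faces, owner_a)``: the (F, 3) node triples and for each
        face the id of the adjacent cell lying in ``region_a`` (normals
        oriented away from region_a are obtained from that owner).
        """
        key = ("iface", region_a, region_b)
        if key not in self._cache:
            faces = {}
            tri_idx = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))
            for c, tet in enumerate(self.cells):
                for t in tri_idx:
                    f = tuple(sorted(tet[list(t)]))
                    faces.setdefault(f, []).append(c)
            out_f, out_a = [], []
            for f, owners in faces.items():
                if len(owners) != 2:
                    continue
                ra, rb = self.region_tags[owners[0]], self.region_tags[owners[1]]
                if {ra, rb} == {region_a, region_b}:
                    out_f.append(f)
                    out_a.append(owners[0] if ra == region_a else owners[1])
            self._cache[key] = (np.array(out_f, dtype=np.int64).reshape(-1, 3),
                                np.array(out_a, dtype=np.int64))
        return self._cache[key]


# ---------------------------------------------------------------------------
# structured grid generation
# ---------------------------------------------------------------------------

def _segment(a, b, n):
    return np.linspace(a, b, n + 1)


def _resolution_counts(level: int) -> dict:
    """Subdivision counts at a given resolution level (>= 0)."""
    if level < 0:
        raise ValueError("resolution_level must be >= 0")
    s = 1.3 ** level
    return {
        "nr_ac": int(math.ceil(8 * s)),
        "theta_gap_rad": math.radians(4.0) / s,
        "n_cc_az": 2 if level < 3 else 3,
        "nr_tm": max(2, int(math.ceil(2 * s))),
        "nr_sc": max(2, int(math.ceil(1.5 * s))),
        "nr_cb_ext": max(2, int(math.ceil(1.5 * s))),
        "nr_cc_ext": max(1, int(math.ceil(0.8 * s))),
        "nz_cb": max(2, int(math.ceil(2 * s))),
        "nz_tm_outer": max(2, int(math.ceil(1.6 * s))),
    }


def generate_mesh(spec: GeometrySpec, resolution_level: int = 1) -> MeshModel:
    """Generate the tagged tet mesh at a given resolution level.

    Cell count increases strictly with ``resolution_level``; refinement
    is concentrated in the angle structures (TM/SC/CC), which are the
    smallest features.
    """
    p = spec.params
    cnt = _resolution_counts(resolution_level)
    R = spec.r_angle

    # ---- radial lines -----------------------------------------------------
    nr = cnt["nr_ac"]
    t = (np.arange(nr + 1) / nr) ** 0.8        # grade toward the angle
    ac_lines = list(R * t)
    # force lines on the inflow slit edges
    keep = [r for r in ac_lines
            if not (spec.slit_r_in - 0.5 * p.inflow_gap < r
                    < spec.slit_r_out + 0.5 * p.inflow_gap)
            and 0.0 <= r < R - 1e-12]
    # two cells across the slit so the inflow profile has an interior
    # node ring between the no-slip lens and iris edges
    ac_lines = sorted(set(keep) | {0.0, spec.slit_r_in, spec.slit_r_out,
                                   0.5 * (spec.slit_r_in + spec.slit_r_out)})
    r_lines = np.concatenate([
        np.asarray(ac_lines),
        _segment(R, spec.r_tm_out, cnt["nr_tm"]),
        _segment(spec.r_tm_out, spec.r_sc_out, cnt["nr_sc"])[1:],
        _segment(spec.r_sc_out, spec.r_cb_out, cnt["nr_cb_ext"])[1:],
        _segment(spec.r_cb_out, spec.r_cc_out, cnt["nr_cc_ext"])[1:],
    ])
    r_lines = np.unique(r_lines)
    i_R = int(np.searchsorted(r_lines, R))          # index of the angle line
    i_tm = int(np.searchsorted(r_lines, spec.r_tm_out))
    i_sc = int(np.searchsorted(r_lines, spec.r_sc_out))
    i_cb = int(np.searchsorted(r_lines, spec.r_cb_out))

    def rtype(i):
        if i < i_R:
            return "AC"
        if i < i_tm:
            return "TM"
        if i < i_sc:
            return "SC"
        if i < i_cb:
            return "CC1"
        return "CC2"

    # ---- azimuth lines ----------------------------------------------------
    w = spec.cc_half_width_rad
    edges = [0.0]
    slot_spans = []
    for c in spec.cc_centers_rad:
        slot_spans.append((c - w, c + w))
        edges.extend([c - w, c + w])
    edges.append(math.pi / 2.0)
    th_lines = []
    slot_of_cell = []        # per theta-cell: cc index or -1
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        in_slot = any(lo - 1e-15 <= mid <= hi + 1e-15 for lo, hi in slot_spans)
        if in_slot:
            nseg = cnt["n_cc_az"]
        else:
            nseg = max(1, int(math.ceil((b - a) / cnt["theta_gap_rad"])))
        seg = _segment(a, b, nseg)
        cc_id = -1
        if in_slot:
            cc_id = int(np.argmin(np.abs(spec.cc_centers_rad - mid)))
        for s0 in range(nseg):
            th_lines.append(seg[s0])
            slot_of_cell.append(cc_id)
    th_lines.append(math.pi / 2.0)
    th_lines = np.asarray(th_lines)
    slot_of_cell = np.asarray(slot_of_cell)

    # ---- axial levels (fractions of the angle-wall height) ----------------
    h_cb, h_rim = spec.h_cb, spec.h_rim
    cb_lines = _segment(0.0, h_cb, cnt["nz_cb"])
    # TM band in normalized [0, 1]; CC duct occupies the middle band
    side = p.cc_diameter * math.sqrt(math.pi) / 2.0
    c0 = 0.5 - 0.5 * side / p.tm_height_axial
    c1 = 0.5 + 0.5 * side / p.tm_height_axial
    tm_t = np.concatenate([
        _segment(0.0, c0, cnt["nz_tm_outer"]),
        _segment(c0, 0.5, 1)[1:],
        _segment(0.5, c1, 1)[1:],
        _segment(c1, 1.0, cnt["nz_tm_outer"])[1:],
    ])
    wall_lines = np.concatenate([cb_lines, h_cb + tm_t[1:] * p.tm_height_axial])
    f_levels = wall_lines / h_rim
    nz_cb = cnt["nz_cb"]
    # k-cells of the CC duct band (within the TM band)
    tm_cells_t = 0.5 * (tm_t[:-1] + tm_t[1:])
    cc_band_k = set(nz_cb + np.nonzero(
        (tm_cells_t > c0) & (tm_cells_t < c1))[0])
    tm_band_k = set(range(nz_cb, len(wall_lines) - 1))
    cb_band_k = set(range(nz_cb))

    ni, nj, nk = len(r_lines), len(th_lines), len(f_levels)

    # ---- hex existence and regions -----------------------------------------
    def hex_region(i, j, k):
        rt = rtype(i)
        if rt == "AC":
            return REGION_AC
        if rt == "TM":
            return REGION_TM if k in tm_band_k else REGION_CB
        if rt == "SC":
            return REGION_SC if k in tm_band_k else REGION_CB
        in_slot = slot_of_cell[j] >= 0
        if rt == "CC1":
            if k in cb_band_k:
                return REGION_CB
            return REGION_CC if (k in cc_band_k and in_slot) else 0
        # CC2
        return REGION_CC if (k in cc_band_k and in_slot) else 0

    hex_ids = []
    hex_regions = []
    for i in range(ni - 1):
        for k in range(nk - 1):
            reg_cache = None
            for j in range(nj - 1):
                reg = hex_region(i, j, k)
                if reg:
                    hex_ids.append((i, j, k))
                    hex_regions.append(reg)
    hex_ids = np.asarray(hex_ids, dtype=np.int64)
    hex_regions = np.asarray(hex_regions, dtype=np.int32)

    # ---- node numbering (merge axis nodes over theta) ----------------------
    node_key = {}
    coords = []

    def node_id(i, j, k):
        jj = 0 if i == 0 else j
        key = (i, jj, k)
        if key not in node_key:
            r = r_lines[i]
            th = th_lines[jj]
            if r <= R + 1e-15:
                z = f_levels[k] * float(spec.dome_height(min(r, R)))
            else:
                z = f_levels[k] * h_rim
            coords.append((r * math.cos(th), r * math.sin(th), z))
            node_key[key] = len(coords) - 1
        return node_key[key]

    corners = np.empty((len(hex_ids), 8), dtype=np.int64)
    for h, (i, j, k) in enumerate(hex_ids):
        for b, (di, dj, dk) in enumerate(
                ((0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
                 (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1))):
            corners[h, b] = node_id(i + di, j + dj, k + dk)
    nodes = np.asarray(coords)

    # ---- Freudenthal 6-tet split -------------------------------------------
    # corner index of offset (di,dj,dk) is di*4 + dj*2 + dk
    perms = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
    ev = {0: (1, 0, 0), 1: (0, 1, 0), 2: (0, 0, 1)}
    tet_patterns = []
    for perm in perms:
        d = [0, 0, 0]
        path = [tuple(d)]
        for axis in perm:
            d = [d[m] + ev[axis][m] for m in range(3)]
            path.append(tuple(d))
        tet_patterns.append([di * 4 + dj * 2 + dk for (di, dj, dk) in path])
    tet_patterns = np.asarray(tet_patterns)         # (6, 4)

    tets = corners[:, tet_patterns]                  # (H, 6, 4)
    tets = tets.reshape(-1, 4)
    regions = np.repeat(hex_regions, 6)

    # drop tets degenerated by axis merging (repeated node ids)
    s = np.sort(tets, axis=1)
    ok = np.all(np.diff(s, axis=1) != 0, axis=1)
    tets, regions = tets[ok], regions[ok]

    # enforce positive orientation
    x = nodes[tets]
    vol = np.einsum("ij,ij->i",
                    np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                    x[:, 3] - x[:, 0]) / 6.0
    neg = vol < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()
    if np.any(np.abs(vol) <= 0.0):
        raise RuntimeError("degenerate (zero-volume) tetrahedra generated")

    # ---- boundary faces ----------------------------------------------------
    tri_idx = np.array(((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)))
    all_faces = tets[:, tri_idx]                     # (M, 4, 3)
    flat = np.sort(all_faces.reshape(-1, 3), axis=1)
    owner = np.repeat(np.arange(tets.shape[0]), 4)
    order = np.lexsort((flat[:, 2], flat[:, 1], flat[:, 0]))
    flat, owner = flat[order], owner[order]
    dup_prev = np.zeros(len(flat), dtype=bool)
    dup_prev[1:] = np.all(flat[1:] == flat[:-1], axis=1)
    dup_next = np.zeros(len(flat), dtype=bool)
    dup_next[:-1] = dup_prev[1:]
    bmask = ~(dup_prev | dup_next)
    bfaces, bowner = flat[bmask], owner[bmask]

    btags = _classify_boundary(nodes, bfaces, bowner, regions, spec)

    return MeshModel(nodes, tets, regions, bfaces, btags, bowner,
                     resolution_level, spec)


def _classify_boundary(nodes, bfaces, bowner, regions, spec):
    """Assign exactly one boundary tag to every boundary triangle."""
    p = spec.params
    scale = spec.r_cc_out
    tol = 1e-9 * scale

    x = nodes[bfaces]                                # (B, 3, 3)
    r = np.hypot(x[..., 0], x[..., 1])               # nodal radii
    tags = np.full(bfaces.shape[0], TAG_WALL, dtype=np.int32)
    own_reg = regions[bowner]

    on_x0 = np.all(np.abs(x[..., 0]) < tol, axis=1)
    on_y0 = np.all(np.abs(x[..., 1]) < tol, axis=1)
    on_z0 = np.all(np.abs(x[..., 2]) < tol, axis=1)

    in_slit = np.all((r > spec.slit_r_in - tol)
                     & (r < spec.slit_r_out + tol), axis=1)
    on_lens = np.all(r < spec.slit_r_in + tol, axis=1)
    in_ac = np.all(r < spec.r_angle + tol, axis=1)
    at_cc_out = np.all(np.abs(r - spec.r_cc_out) < tol, axis=1)
    at_cb_out = np.all(np.abs(r - spec.r_cb_out) < tol, axis=1)

    tags[on_z0 & ~in_slit & ~on_lens & in_ac] = TAG_IRIS
    tags[on_z0 & on_lens] = TAG_LENS
    tags[on_z0 & in_slit] = TAG_INFLOW
    floor = on_z0
    tags[~floor & on_x0] = TAG_SYMMETRY_X
    tags[~floor & on_y0] = TAG_SYMMETRY_Y
    sym = on_x0 | on_y0
    # remaining AC-cell boundary faces are the corneal dome
    rest = ~floor & ~sym
    tags[rest & (own_reg == REGION_AC)] = TAG_CORNEA
    tags[rest & at_cc_out & (own_reg == REGION_CC)] = TAG_CC_OUTLET
    tags[rest & at_cb_out & (own_reg == REGION_CB)] = TAG_CB_OUTLET
    return tags


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2 ASCII export / import
# ---------------------------------------------------------------------------

def write_msh(mesh: MeshModel, path):
    """Write the tagged mesh in Gmsh MSH 2.2 ASCII format.

    Regions become 3D physical groups, boundary tags 2D physical groups.
    """
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(REGION_NAMES) + len(BOUNDARY_NAMES))]
    for tag, name in BOUNDARY_NAMES.items():
        lines.append(f'2 {100 + tag} "{name}"')
    for tag, name in REGION_NAMES.items():
        lines.append(f'3 {tag} "{name}"')
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_nodes)]
    for i, (xx, yy, zz) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {xx:.16e} {yy:.16e} {zz:.16e}")
    lines += ["$EndNodes", "$Elements",
              str(mesh.n_cells + len(mesh.boundary_faces))]
    e = 1
    for f, tag in zip(mesh.boundary_faces, mesh.boundary_tags):
        lines.append(f"{e} 2 2 {100 + tag} {100 + tag} "
                     f"{f[0] + 1} {f[1] + 1} {f[2] + 1}")
        e += 1
    for c, tag in zip(mesh.cells, mesh.region_tags):
        lines.append(f"{e} 4 2 {tag} {tag} "
                     f"{c[0] + 1} {c[1] + 1} {c[2] + 1} {c[3] + 1}")
        e += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path):
    """Read a mesh written by :func:`write_msh`.

    Returns ``(nodes, cells, region_tags, boundary_faces, boundary_tags)``
    with zero-based connectivity.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    nodes = cells = regions = bfaces = btags = None
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            nodes = np.empty((n, 3))
            for i in range(n):
                parts = next(it).split()
                nodes[i] = [float(v) for v in parts[1:4]]
        elif line.strip() == "$Elements":
            n = int(next(it))
            cl, rl, fl, tl = [], [], [], []
            for _ in range(n):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                phys = int(parts[3])
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 2:
                    fl.append(conn)
                    tl.append(phys - 100)
                elif etype == 4:
                    cl.append(conn)
                    rl.append(phys)
            cells = np.asarray(cl, dtype=np.int64)
            regions = np.asarray(rl, dtype=np.int32)
            bfaces = np.asarray(fl, dtype=np.int64)
            btags = np.asarray(tl, dtype=np.int32)
    return nodes, cells, regions, bfaces, btags
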