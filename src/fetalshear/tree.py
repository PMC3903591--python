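"""Parametric synthetic great-artery trees of the fetal mouse.

The generator builds the wildtype great-artery topology: ascending aorta and
aortic arch carrying the three head-and-neck branches (innominate, left common
carotid, left subclavian), the aortic isthmus, the pulmonary trunk with left
and right pulmonary arteries, the ductus arteriosus inserting into the
descending aorta, and the descending aorta itself.  Each vessel is a swept
elliptical tube along an analytic centerline (arcs, lines, one Hermite curve
for the ductus).

Stage dependence built into the defaults:

* all dimensions scale linearly with age from 55% of the near-term size at
  E14.5 to 100% at E18.5, anchored by the printed near-term descending-aorta
  width of 0.573 mm;
* the ductus insertion angle opens from ~100 deg (nearly perpendicular) at
  E14.5 toward ~150 deg (closer to a parallel merge) at E18.5;
* cross sections are elliptical (aspect ratio ``base_ellipticity``) and dip to
  ``branch_ellipticity`` near each ostium, elongated toward the branch.

Internal radii are *Murray-consistent*: each internal segment radius is the
cube-root of the sum of cubes of its downstream outlet radii.  Combined with
equal plug velocities at the two roots this makes flow proportional to radius
cubed on every segment, the condition under which Poiseuille wall shear stress
is identical throughout the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .stages import StageConfig, dimension_scale


class GeometryError(ValueError):
    """Raised when requested parameters produce a non-physical tree."""


# ----------------------------------------------------------------- base plan
# near-term (E18.5-scale) dimensions, mm
ARCH_RADIUS = 0.65            # radius of the aortic-arch arc
DAO_LENGTH = 1.6              # descending aorta below the ductus insertion
BRANCH_LENGTH = 0.7           # head-and-neck branch length
PT_LENGTH = 0.8               # pulmonary trunk, root to PA bifurcation
PA_LENGTH = 0.5               # left/right pulmonary artery length
PT_ROOT = np.array([-0.85, -0.10, 0.0])

OUTLET_RADII = {              # near-term outlet radii, mm (dao set from config)
    "innominate": 0.15,
    "left_common_carotid": 0.12,
    "left_subclavian": 0.12,
    "pulmonary_artery_left": 0.10,
    "pulmonary_artery_right": 0.10,
}
BRANCH_THETAS = {             # ostium position on the arch arc, degrees
    "innominate": 40.0,
    "left_common_carotid": 70.0,
    "left_subclavian": 100.0,
}
ISTHMUS_THETA = 105.0         # ascending/arch split, just distal to the LSC

DUCTUS_ANGLE_E145 = 100.0     # deg, insertion angle convention: 180 = parallel
DUCTUS_ANGLE_E185 = 150.0

BASE_ELLIPTICITY = 0.9
BRANCH_ELLIPTICITY = 0.7

_POINTS_PER_MM = 60           # centerline sampling density


def ductus_angle_for_age(age_days: float) -> float:
    """Imposed ductus-arteriosus insertion angle at a stage (degrees)."""
    return DUCTUS_ANGLE_E145 + (DUCTUS_ANGLE_E185 - DUCTUS_ANGLE_E145) * (
        age_days - 14.5
    ) / 4.0


@dataclass
class TubeSegment:
    """A swept elliptical tube: centerline samples plus per-point section data.

    ``radii`` is the nominal circular-equivalent radius r; the actual ellipse
    semi-axes are r/sqrt(e) (major, along ``elong_axis``) and r*sqrt(e)
    (minor), so the lumen area is always pi r^2 and the aspect ratio is e.
    """

    name: str
    role: str
    points: np.ndarray        # (N,3) mm
    radii: np.ndarray         # (N,)
    ellipticity: np.ndarray   # (N,) in (0,1]
    elong_axis: np.ndarray | None = None  # (N,3) unit, in-plane elongation

    def __post_init__(self) -> None:
        if np.any(self.radii <= 0):
            raise GeometryError(f"segment {self.name}: non-positive radius")
        if np.any(self.ellipticity <= 0) or np.any(self.ellipticity > 1):
            raise GeometryError(f"segment {self.name}: ellipticity must be in (0,1]")

    @property
    def arclength(self) -> np.ndarray:
        return geo.polyline_arclength(self.points)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def frames(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return geo.rotation_minimizing_frames(self.points)

    def mean_area(self) -> float:
        """Arclength-weighted mean lumen cross-sectional area, mm^2."""
        s = self.arclength
        a = np.pi * self.radii**2
        return float(np.trapezoid(a, s) / s[-1])


@dataclass(frozen=True)
class Junction:
    parent: str
    child: str
    parent_arclength: float
    point: np.ndarray
    angle_deg: float | None = None


@dataclass(frozen=True)
class Landmark:
    segment: str
    arclength: float
    point: np.ndarray


@dataclass(frozen=True)
class FlowEdge:
    """One Poiseuille resistor of the reduced-order network."""

    name: str
    node_u: str
    node_v: str
    radius: float   # mm
    length: float   # mm
    group: str      # AAo | DAo | PT | branch


@dataclass
class VesselTree:
    config: StageConfig
    segments: list[TubeSegment]
    junctions: list[Junction]
    landmarks: dict[str, Landmark]
    flow_edges_list: list[FlowEdge]
    inlet_nodes: dict[str, float]    # node name -> inlet radius
    outlet_nodes: dict[str, float]   # node name -> outlet radius
    ductus_angle_deg: float
    scale: float
    provenance: dict = field(default_factory=dict)

    def get(self, name: str) -> TubeSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def flow_edges(self) -> list[FlowEdge]:
        return list(self.flow_edges_list)

    def outlet_radii(self) -> dict[str, float]:
        return dict(self.outlet_nodes)

    @property
    def dao_radius(self) -> float:
        return self.outlet_nodes["out_descending_aorta"]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box of the lumen (with radius margin), mm."""
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for s in self.segments:
            r = s.radii.max()
            lo = np.minimum(lo, s.points.min(axis=0) - r)
            hi = np.maximum(hi, s.points.max(axis=0) + r)
        return lo, hi


def _npts(length: float) -> int:
    return max(8, int(round(length * _POINTS_PER_MM)))


def _smoothstep_radii(s: np.ndarray, knots: list[tuple[float, float]], width: float) -> np.ndarray:
    """Piecewise-constant radius profile with smooth (tanh) Murray steps.

    ``knots`` is [(s_transition, radius_after), ...]; radius before the first
    transition is knots[0]'s *pre* value passed as (s=-inf entry).
    """
    r = np.full_like(s, knots[0][1])
    for s_k, r_after in knots[1:]:
        w = 0.5 * (1.0 + np.tanh((s - s_k) / width))
        r = r * (1.0 - w) + r_after * w
    return r


def _ellipticity_profile(
    s: np.ndarray,
    ostia: list[tuple[float, float, np.ndarray]],
    base: float,
    dip: float,
    tangents: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Aspect-ratio profile dipping to ``dip`` at each ostium.

    ``ostia``: (arclength, branch_radius, branch_direction).  The elongation
    axis at each point is the nearest ostium's branch direction projected into
    the local section plane; elsewhere it is an arbitrary in-plane direction.
    """
    e = np.full_like(s, base)
    axis = np.zeros((len(s), 3))
    weight = np.zeros_like(s)
    for s_o, r_b, d_b in ostia:
        sig = max(r_b, 1e-6)
        g = np.exp(-0.5 * ((s - s_o) / sig) ** 2)
        e = e - (base - dip) * g
        upd = g > weight
        axis[upd] = d_b
        weight = np.maximum(weight, g)
    e = np.clip(e, dip, base)
    # project onto section planes; fall back where no ostium influence
    out = np.zeros_like(axis)
    for i in range(len(s)):
        a = axis[i]
        if np.linalg.norm(a) < 1e-12:
            out[i] = 0.0
            continue
        a = a - np.dot(a, tangents[i]) * tangents[i]
        n = np.linalg.norm(a)
        out[i] = a / n if n > 1e-9 else 0.0
    return e, out


def generate_vessel_tree(
    config: StageConfig,
    *,
    base_ellipticity: float = BASE_ELLIPTICITY,
    branch_ellipticity: float = BRANCH_ELLIPTICITY,
    jitter: float = 0.02,
    check_overlap: bool = True,
) -> VesselTree:
    """Deterministically generate the stage's great-artery tree.

    Pure function of (config, keyword parameters): the same seed yields a
    bitwise-identical tree.  ``jitter`` perturbs branch directions and lengths
    (never radii, so Murray consistency and the area growth law stay exact).
    """
    rng = np.random.default_rng(config.seed)
    scale = dimension_scale(config.age_days)
    A = ARCH_RADIUS * scale

    r_dao = 0.5 * config.dao_diameter * scale
    r_out = {k: v * scale for k, v in OUTLET_RADII.items()}
    r_out["descending_aorta"] = r_dao
    sum_cubes = sum(r**3 for r in r_out.values())
    # equal root plug velocities + Murray consistency force equal root radii
    r_root = (0.5 * sum_cubes) ** (1.0 / 3.0)
    r1 = (r_root**3 - r_out["innominate"] ** 3) ** (1.0 / 3.0)
    r2 = (r1**3 - r_out["left_common_carotid"] ** 3) ** (1.0 / 3.0)
    r_isthmus = (r2**3 - r_out["left_subclavian"] ** 3) ** (1.0 / 3.0)
    r_ductus = (
        r_root**3
        - r_out["pulmonary_artery_left"] ** 3
        - r_out["pulmonary_artery_right"] ** 3
    ) ** (1.0 / 3.0)

    def jit(x: float, lo_hi: float = 1.0) -> float:
        return x * (1.0 + lo_hi * jitter * rng.uniform(-1.0, 1.0))

    # ------------------------------------------------------------- aorta arc
    # arc in the x=0 plane: p(th) = (0, A(1-cos th), A sin th); starts at the
    # aortic root going +z (cranially), ends at the ductus junction going -z
    center = np.array([0.0, A, 0.0])
    u = np.array([0.0, -1.0, 0.0])
    v = np.array([0.0, 0.0, 1.0])

    def arch_point(theta_deg: float) -> np.ndarray:
        th = np.deg2rad(theta_deg)
        return center + A * (np.cos(th) * u + np.sin(th) * v)

    def arch_outward(theta_deg: float) -> np.ndarray:
        th = np.deg2rad(theta_deg)
        return np.cos(th) * u + np.sin(th) * v

    th_isth = ISTHMUS_THETA
    s_of_theta = lambda th: A * np.deg2rad(th)

    asc_pts = geo.sample_arc(center, A, u, v, 0.0, np.deg2rad(th_isth), _npts(s_of_theta(th_isth)))
    s_asc = geo.polyline_arclength(asc_pts)

    step_w = 0.10 * scale
    radius_knots = [
        (-1.0, r_root),
        (s_of_theta(BRANCH_THETAS["innominate"]), r1),
        (s_of_theta(BRANCH_THETAS["left_common_carotid"]), r2),
        (s_of_theta(BRANCH_THETAS["left_subclavian"]), r_isthmus),
    ]
    asc_radii = _smoothstep_radii(s_asc, radius_knots, step_w)

    # branch directions: outward arch normal tilted cranially, with lateral
    # spread; small seeded angular jitter
    lateral = {"innominate": 0.35, "left_common_carotid": 0.0, "left_subclavian": -0.35}
    branch_dirs = {}
    for nm, th in BRANCH_THETAS.items():
        d = arch_outward(th) + np.array([lateral[nm], 0.0, 1.0])
        d = d + jitter * rng.normal(size=3) * 0.5
        branch_dirs[nm] = d / np.linalg.norm(d)

    asc_tan = geo.polyline_tangents(asc_pts)
    ostia_asc = [
        (s_of_theta(BRANCH_THETAS[nm]), r_out[nm], branch_dirs[nm]) for nm in BRANCH_THETAS
    ]
    asc_ell, asc_axis = _ellipticity_profile(
        s_asc, ostia_asc, base_ellipticity, branch_ellipticity, asc_tan
    )
    segments = [
        TubeSegment("ascending_aorta", "ascending_aorta", asc_pts, asc_radii, asc_ell, asc_axis)
    ]

    arch_pts = geo.sample_arc(
        center, A, u, v, np.deg2rad(th_isth), np.pi, _npts(s_of_theta(180 - th_isth))
    )
    n_arch = len(arch_pts)
    segments.append(
        TubeSegment(
            "arch",
            "arch",
            arch_pts,
            np.full(n_arch, r_isthmus),
            np.full(n_arch, base_ellipticity),
            None,
        )
    )

    dao_junction = arch_point(180.0)
    dao_len = jit(DAO_LENGTH * scale)
    dao_pts = np.linspace(dao_junction, dao_junction + np.array([0, 0, -dao_len]), _npts(dao_len))
    n_dao = len(dao_pts)
    # the descending aorta is kept circular so its maximum cross-section width
    # equals the configured diameter anchor exactly (no branch ostia open into
    # it; the ductus is a merging vessel, not a branch)
    segments.append(
        TubeSegment(
            "descending_aorta", "descending_aorta", dao_pts,
            np.full(n_dao, r_dao), np.full(n_dao, 1.0), None,
        )
    )

    junctions: list[Junction] = []
    landmarks: dict[str, Landmark] = {}
    for nm, th in BRANCH_THETAS.items():
        p0 = arch_point(th)
        blen = jit(BRANCH_LENGTH * scale)
        pts = np.linspace(p0, p0 + branch_dirs[nm] * blen, _npts(blen))
        n = len(pts)
        segments.append(
            TubeSegment(nm, nm, pts, np.full(n, r_out[nm]), np.full(n, 1.0), None)
        )
        s_ost = s_of_theta(th)
        junctions.append(Junction("ascending_aorta", nm, s_ost, p0))
        landmarks[f"{nm}_ostium"] = Landmark("ascending_aorta", s_ost, p0)

    # -------------------------------------------------- pulmonary side
    pt_root = PT_ROOT * scale
    pt_len = jit(PT_LENGTH * scale)
    pa_bif = pt_root + np.array([0.0, 0.0, pt_len])
    pt_pts = np.linspace(pt_root, pa_bif, _npts(pt_len))
    n_pt = len(pt_pts)
    pa_dirs = {
        "pulmonary_artery_left": np.array([-1.0, -0.35, 0.25]),
        "pulmonary_artery_right": np.array([1.0, -0.65, 0.25]),
    }
    pt_tan = geo.polyline_tangents(pt_pts)
    s_pt = geo.polyline_arclength(pt_pts)
    ostia_pt = [
        (pt_len, r_out[nm], d / np.linalg.norm(d)) for nm, d in pa_dirs.items()
    ]
    pt_ell, pt_axis = _ellipticity_profile(
        s_pt, ostia_pt[:1], base_ellipticity, branch_ellipticity, pt_tan
    )
    segments.append(
        TubeSegment("pulmonary_trunk", "pulmonary_trunk", pt_pts, np.full(n_pt, r_root), pt_ell, pt_axis)
    )
    for nm, d in pa_dirs.items():
        d = d + jitter * rng.normal(size=3) * 0.5
        d = d / np.linalg.norm(d)
        plen = jit(PA_LENGTH * scale)
        pts = np.linspace(pa_bif, pa_bif + d * plen, _npts(plen))
        n = len(pts)
        segments.append(
            TubeSegment(nm, "pulmonary_artery", pts, np.full(n, r_out[nm]), np.full(n, 1.0), None)
        )
        junctions.append(Junction("pulmonary_trunk", nm, pt_len, pa_bif))
    landmarks["pa_bifurcation"] = Landmark("pulmonary_trunk", pt_len, pa_bif)

    # ductus arteriosus: Hermite from the PA bifurcation to the DAo junction,
    # arriving with the stage's insertion angle (180 deg = parallel merge)
    angle = ductus_angle_for_age(config.age_days)
    phi = np.deg2rad(180.0 - angle)       # angle between arrival tangent and -z
    approach = dao_junction - pa_bif
    uh = approach.copy()
    uh[2] = 0.0
    uh = uh / np.linalg.norm(uh)
    t1 = np.sin(phi) * uh + np.cos(phi) * np.array([0.0, 0.0, -1.0])
    t0 = approach + np.array([0.0, 0.0, 0.6 * scale])
    duct_pts = geo.sample_hermite(pa_bif, dao_junction, t0, t1, _npts(np.linalg.norm(approach) * 1.3))
    n_duct = len(duct_pts)
    segments.append(
        TubeSegment(
            "ductus", "ductus", duct_pts, np.full(n_duct, r_ductus),
            np.full(n_duct, base_ellipticity), None,
        )
    )
    junctions.append(
        Junction("descending_aorta", "ductus", 0.0, dao_junction, angle_deg=angle)
    )
    junctions.append(Junction("ascending_aorta", "arch", float(s_asc[-1]), arch_point(th_isth)))
    junctions.append(Junction("arch", "descending_aorta", float(geo.polyline_arclength(arch_pts)[-1]), dao_junction))
    landmarks["ductus_insertion"] = Landmark("descending_aorta", 0.0, dao_junction)
    landmarks["aortic_isthmus"] = Landmark("arch", 0.0, arch_point(th_isth))

    # ------------------------------------------------------------ flow edges
    s_in = s_of_theta(BRANCH_THETAS["innominate"])
    s_lcc = s_of_theta(BRANCH_THETAS["left_common_carotid"])
    s_lsc = s_of_theta(BRANCH_THETAS["left_subclavian"])
    arch_len = float(geo.polyline_arclength(arch_pts)[-1])
    edges = [
        FlowEdge("aao_root", "aortic_root", "n_innominate", r_root, s_in, "AAo"),
        FlowEdge("aao_mid1", "n_innominate", "n_lcc", r1, s_lcc - s_in, "AAo"),
        FlowEdge("aao_mid2", "n_lcc", "n_lsc", r2, s_lsc - s_lcc, "AAo"),
        FlowEdge(
            "isthmus", "n_lsc", "dao_junction", r_isthmus,
            (float(s_asc[-1]) - s_lsc) + arch_len, "AAo",
        ),
        FlowEdge("innominate", "n_innominate", "out_innominate", r_out["innominate"],
                 BRANCH_LENGTH * scale, "branch"),
        FlowEdge("left_common_carotid", "n_lcc", "out_left_common_carotid",
                 r_out["left_common_carotid"], BRANCH_LENGTH * scale, "branch"),
        FlowEdge("left_subclavian", "n_lsc", "out_left_subclavian",
                 r_out["left_subclavian"], BRANCH_LENGTH * scale, "branch"),
        FlowEdge("pulmonary_trunk", "pulmonary_root", "n_pa", r_root, pt_len, "PT"),
        FlowEdge("pulmonary_artery_left", "n_pa", "out_pulmonary_artery_left",
                 r_out["pulmonary_artery_left"], PA_LENGTH * scale, "branch"),
        FlowEdge("pulmonary_artery_right", "n_pa", "out_pulmonary_artery_right",
                 r_out["pulmonary_artery_right"], PA_LENGTH * scale, "branch"),
        FlowEdge("ductus", "n_pa", "dao_junction", r_ductus,
                 float(geo.polyline_arclength(duct_pts)[-1]), "PT"),
        FlowEdge("dao", "dao_junction", "out_descending_aorta", r_dao, dao_len, "DAo"),
    ]
    inlets = {"aortic_root": r_root, "pulmonary_root": r_root}
    outlets = {
        "out_innominate": r_out["innominate"],
        "out_left_common_carotid": r_out["left_common_carotid"],
        "out_left_subclavian": r_out["left_subclavian"],
        "out_pulmonary_artery_left": r_out["pulmonary_artery_left"],
        "out_pulmonary_artery_right": r_out["pulmonary_artery_right"],
        "out_descending_aorta": r_dao,
    }

    tree = VesselTree(
        config=config,
        segments=segments,
        junctions=junctions,
        landmarks=landmarks,
        flow_edges_list=edges,
        inlet_nodes=inlets,
        outlet_nodes=outlets,
        ductus_angle_deg=angle,
        scale=scale,
        provenance={
            "seed": config.seed,
            "age_days": config.age_days,
            "jitter": jitter,
            "base_ellipticity": base_ellipticity,
            "branch_ellipticity": branch_ellipticity,
        },
    )
    if check_overlap:
        _check_overlaps(tree)
    return tree


_CONNECTED = {
    frozenset(p)
    for p in [
        ("ascending_aorta", "arch"),
        ("arch", "descending_aorta"),
        ("ascending_aorta", "innominate"),
        ("ascending_aorta", "left_common_carotid"),
        ("ascending_aorta", "left_subclavian"),
        ("arch", "left_subclavian"),
        ("pulmonary_trunk", "pulmonary_artery_left"),
        ("pulmonary_trunk", "pulmonary_artery_right"),
        ("pulmonary_trunk", "ductus"),
        ("ductus", "descending_aorta"),
        ("ductus", "arch"),
        ("pulmonary_artery_left", "pulmonary_artery_right"),
        ("pulmonary_artery_left", "ductus"),
        ("pulmonary_artery_right", "ductus"),
    ]
}


def _check_overlaps(tree: VesselTree) -> None:
    """Reject trees whose unconnected vessels intersect.

    Points close to a junction are excluded: vessels legitimately converge
    there (e.g. the ductus and the aortic arch meet at the DAo junction), so
    only mid-segment proximity counts as a collision.
    """
    segs = tree.segments
    jpts = np.array([j.point for j in tree.junctions]).reshape(-1, 3)
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            a, b = segs[i], segs[j]
            if frozenset((a.name, b.name)) in _CONNECTED:
                continue
            clearance = 0.85 * (a.radii.max() + b.radii.max())
            excl = 2.5 * clearance

            def away_from_junctions(pts: np.ndarray) -> np.ndarray:
                if len(jpts) == 0:
                    return pts
                d = np.linalg.norm(pts[:, None, :] - jpts[None, :, :], axis=2)
                return pts[d.min(axis=1) > excl]

            pa, pb = away_from_junctions(a.points), away_from_junctions(b.points)
            if len(pa) == 0 or len(pb) == 0:
                continue
            d = geo.min_polyline_distance(pa, pb)
            if d < clearance:
                raise GeometryError(
                    f"segments {a.name} and {b.name} overlap "
                    f"(min centerline distance {d:.3f} mm < {clearance:.3f} mm)"
                )
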