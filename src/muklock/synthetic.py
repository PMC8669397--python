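"""Seeded generators for every input class the pipeline consumes.

Each generator records its ground truth so that the corresponding
inference stage can be tested as a round trip: a circular genome with two
replichores of opposite GC skew and planted degenerate palindromic sites,
gel lanes as Gaussian bands on a drifting polynomial background, EMSA
titrations from the depletion-aware equilibrium binding curve, normal
replicate sets, and ideal B-DNA two-duplex scenes at a chosen crossing
angle. Random streams are independent per generator call, keyed by
(seed, call-purpose tag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from muklock.binding import TitrationSeries, equilibrium_bound_fraction
from muklock.errors import DataError
from muklock.gelquant import LaneProfile, ReplicateSet
from muklock.genome import CircularGenome
from muklock.structgeom import AtomRecord, StructureModel

_BASES = np.array(list("ACGT"))


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent stream per (seed, purpose tag)."""
    return np.random.default_rng([seed & 0x7FFFFFFF] + [ord(c) for c in tag])


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class PlantedSite:
    position: int
    pattern: str
    n_mutations: int
    mutations: tuple  # of (offset, base)
    realized: str


@dataclass(frozen=True)
class GenomeTruth:
    genome: CircularGenome
    ori_pos: int
    ter_pos: int
    planted_sites: tuple
    skew_amplitude: float
    seed: int


def gen_genome(
    length: int,
    ori_pos: int = 0,
    skew_amplitude: float = 0.2,
    planted: Sequence[tuple] = (),
    seed: int = 0,
    gc_content: float = 0.5,
    name: str = "synthetic_chromosome",
) -> GenomeTruth:
    """Circular genome with two replichores of opposite GC skew.

    The terminus is placed diametrically opposite the origin. On the
    replichore running from ori to ter (increasing coordinate) bases are
    drawn with P(G) - P(C) = +skew_amplitude * (P(G) + P(C)); the sign
    flips on the other replichore. A+T fills the remaining probability
    mass uniformly. ``planted`` entries are (pattern, position,
    n_mutations) site specs; each pattern is written over the background
    with exactly n_mutations random substitutions, and the realized
    sequence plus mutation list is recorded in the truth.
    """
    if length < 1000:
        raise DataError("length must be >= 1000")
    if not 0 <= ori_pos < length:
        raise DataError("ori_pos must be in [0, length)")
    if not 0 < skew_amplitude <= 1:
        raise DataError("skew_amplitude must be in (0, 1]")
    if not 0 < gc_content < 1:
        raise DataError("gc_content must be in (0, 1)")

    rng = _rng(seed, "genome")
    ter_pos = (ori_pos + length // 2) % length

    gc = gc_content
    at = 1.0 - gc
    a = skew_amplitude
    p_plus = [at / 2, gc / 2 * (1 - a), gc / 2 * (1 + a), at / 2]  # A,C,G,T
    p_minus = [at / 2, gc / 2 * (1 + a), gc / 2 * (1 - a), at / 2]

    idx = np.arange(length)
    on_leading = ((idx - ori_pos) % length) < ((ter_pos - ori_pos) % length)
    bases = np.empty(length, dtype="<U1")
    bases[on_leading] = rng.choice(_BASES, size=int(on_leading.sum()), p=p_plus)
    bases[~on_leading] = rng.choice(_BASES, size=int((~on_leading).sum()),
                                    p=p_minus)

    # plant sites (substitution-only mutations keep positions exact)
    occupied: set[int] = set()
    planted_records = []
    for pattern, pos, n_mut in planted:
        pattern = pattern.upper()
        m = len(pattern)
        if not 0 <= pos < length:
            raise DataError(f"planted position {pos} outside genome")
        if n_mut > m:
            raise DataError("more mutations than pattern positions")
        span = [(pos + o) % length for o in range(m)]
        if occupied.intersection(span):
            raise DataError(f"planted sites overlap at position {pos}")
        occupied.update(span)

        concrete = list(pattern)
        for o, c in enumerate(concrete):
            if c == "N":
                concrete[o] = str(rng.choice(_BASES))
        mutable = [o for o in range(m)]
        muts = []
        if n_mut > 0:
            for o in rng.choice(mutable, size=n_mut, replace=False):
                o = int(o)
                alternatives = [b for b in "ACGT" if b != concrete[o]]
                new = str(rng.choice(alternatives))
                concrete[o] = new
                muts.append((o, new))
        realized = "".join(concrete)
        for o, q in enumerate(span):
            bases[q] = realized[o]
        planted_records.append(PlantedSite(
            position=pos, pattern=pattern, n_mutations=n_mut,
            mutations=tuple(sorted(muts)), realized=realized))

    genome = CircularGenome(name, "".join(bases), circular=True)
    return GenomeTruth(genome=genome, ori_pos=ori_pos, ter_pos=ter_pos,
                       planted_sites=tuple(planted_records),
                       skew_amplitude=skew_amplitude, seed=seed)


# ---------------------------------------------------------------------------
# gel lanes


@dataclass(frozen=True)
class Band:
    center: float
    width: float
    area: float


@dataclass(frozen=True)
class LaneTruth:
    profile: LaneProfile
    bands: tuple
    background_coefficients: tuple
    noise_sd: float
    seed: int

    def background(self) -> np.ndarray:
        x = self.profile.positions / self.profile.positions[-1]
        return np.polynomial.polynomial.polyval(
            x, np.asarray(self.background_coefficients, dtype=float))


def gen_lane_profile(
    bands: Sequence[tuple],
    background_coefficients: Sequence[float] = (0.0,),
    noise_sd: float = 0.0,
    length_px: int = 1000,
    seed: int = 0,
) -> LaneTruth:
    """Lane profile = polynomial background + Gaussian bands + noise.

    ``bands`` entries are (center_px, width_px, area) with unit-area
    Gaussian normalization, so the integral of a noise-free band over its
    support equals its area. The background polynomial is evaluated in
    the scaled coordinate x / length_px.
    """
    if length_px < 3:
        raise DataError("length_px must be >= 3")
    band_objs = []
    for center, width, area in bands:
        if not 0 <= center < length_px:
            raise DataError(f"band center {center} outside [0, length_px)")
        if width <= 0:
            raise DataError("band widths must be positive")
        if area < 0:
            raise DataError("band areas must be >= 0")
        band_objs.append(Band(float(center), float(width), float(area)))

    rng = _rng(seed, "lane")
    x = np.arange(length_px, dtype=float)
    intens = np.polynomial.polynomial.polyval(
        x / length_px, np.asarray(background_coefficients, dtype=float))
    intens = np.broadcast_to(intens, x.shape).astype(float).copy()
    for b in band_objs:
        intens += (b.area / (b.width * np.sqrt(2 * np.pi))
                   * np.exp(-0.5 * ((x - b.center) / b.width) ** 2))
    if noise_sd > 0:
        intens = intens + rng.normal(0.0, noise_sd, size=length_px)
    profile = LaneProfile(positions=x, intensities=intens)
    return LaneTruth(profile=profile, bands=tuple(band_objs),
                     background_coefficients=tuple(background_coefficients),
                     noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# titrations


@dataclass(frozen=True)
class TitrationTruth:
    series: TitrationSeries
    true_Kd: float
    true_baseline: float
    true_asymptote: float
    noise_sd: float
    seed: int


def gen_titration(
    true_Kd: float = 50.0,
    baseline: float = 0.05,
    asymptote: float = 0.95,
    protein_concs: Sequence[float] | None = None,
    dna_total: float = 2.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> TitrationTruth:
    """EMSA titration from the depletion-aware equilibrium curve.

    Defaults mirror a 2 nM labelled probe titrated over a broad protein
    range: a 12-point half-log series from 0.5 nM to 5 uM plus a
    zero-protein point.
    """
    if true_Kd <= 0:
        raise DataError("true_Kd must be positive")
    if asymptote == baseline:
        raise DataError("asymptote must differ from baseline (unidentifiable)")
    if protein_concs is None:
        protein_concs = np.concatenate([[0.0], np.geomspace(0.5, 5000.0, 12)])
    p = np.asarray(protein_concs, dtype=float)
    if np.any(p < 0):
        raise DataError("concentrations must be >= 0")
    rng = _rng(seed, "titration")
    frac = equilibrium_bound_fraction(p, dna_total, true_Kd)
    resp = baseline + (asymptote - baseline) * np.asarray(frac)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=p.size)
    series = TitrationSeries(protein_concs=p, dna_total=dna_total,
                             responses=resp)
    return TitrationTruth(series=series, true_Kd=true_Kd,
                          true_baseline=baseline, true_asymptote=asymptote,
                          noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# replicate sets


@dataclass(frozen=True)
class ReplicateTruth:
    replicates: ReplicateSet
    mu: float
    sigma: float
    seed: int


def gen_replicates(mu: float, sigma: float, n: int, seed: int = 0) -> ReplicateTruth:
    """n draws from Normal(mu, sigma) with the truth recorded."""
    if n < 2:
        raise DataError("n must be >= 2")
    if sigma < 0:
        raise DataError("sigma must be >= 0")
    rng = _rng(seed, "replicates")
    values = mu + sigma * rng.standard_normal(n)
    return ReplicateTruth(replicates=ReplicateSet(values), mu=mu,
                          sigma=sigma, seed=seed)


# ---------------------------------------------------------------------------
# helix scenes


@dataclass(frozen=True)
class HelixSceneTruth:
    scene: StructureModel
    true_angle: float
    rise_per_bp: float
    twist_per_bp: float
    n_bp: int
    seed: int
    axis_a: np.ndarray = field(default=None)
    axis_b: np.ndarray = field(default=None)


_C1_RADIUS = 9.4   # Angstrom, C1' distance from the helix axis
_P_RADIUS = 9.0
_C1_HALF_ANGLE = np.radians(-13.0)  # C1'-C1' separation across the pair: 154 deg


def _ideal_duplex(
    n_bp: int,
    rise: float,
    twist_deg: float,
    phase: float,
    chain_a: str,
    chain_b: str,
) -> list[AtomRecord]:
    """Ideal B-form duplex along +z, base-pair midplane centered at origin.

    Each residue carries C1' and P pseudo-backbone atoms on a cylinder;
    strand B runs antiparallel so residue j of chain B pairs with residue
    n_bp - 1 - j of chain A.
    """
    atoms = []
    z0 = -(n_bp - 1) * rise / 2.0
    twist = np.radians(twist_deg)
    d = _C1_HALF_ANGLE

    def ring(radius: float, ang: float, z: float) -> tuple[float, float, float]:
        return radius * np.cos(ang), radius * np.sin(ang), z

    for i in range(n_bp):
        phi = phase + twist * i
        z = z0 + i * rise
        # strand A residue i
        xa, ya, za = ring(_C1_RADIUS, phi - d, z)
        atoms.append(AtomRecord(chain_a, i + 1, "DA", "C1'", "C", xa, ya, za))
        xp, yp, zp = ring(_P_RADIUS, phi - d - np.radians(25.0), z - 1.0)
        atoms.append(AtomRecord(chain_a, i + 1, "DA", "P", "P", xp, yp, zp))
        # strand B residue n_bp - i (so B residue numbers ascend 5'->3')
        jb = n_bp - i
        xb, yb, zb = ring(_C1_RADIUS, phi + d + np.pi, z)
        atoms.append(AtomRecord(chain_b, jb, "DT", "C1'", "C", xb, yb, zb))
        xq, yq, zq = ring(_P_RADIUS, phi + d + np.pi + np.radians(25.0), z + 1.0)
        atoms.append(AtomRecord(chain_b, jb, "DT", "P", "P", xq, yq, zq))
    return atoms


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u to unit vector v."""
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis for a half-turn
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    w = np.cross(u, v)
    wx = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + wx + wx @ wx / (1.0 + c)


def gen_helix_scene(
    angle: float = 60.0,
    n_bp: int = 20,
    seed: int = 0,
    rise: float = 3.4,
    twist: float = 36.0,
    separation: float = 24.0,
) -> HelixSceneTruth:
    """Two ideal B-DNA duplexes whose axes subtend exactly ``angle`` degrees.

    Duplex 1 (chains A/B) and duplex 2 (chains C/D) are tilted by
    -angle/2 and +angle/2 about the x axis, displaced by ``separation``
    along x, and given random helical phases. The true axis directions
    are recorded in the truth.
    """
    if not 0 <= angle <= 90:
        raise DataError("angle must be in [0, 90] degrees")
    if n_bp < 8:
        raise DataError("n_bp must be >= 8")
    rng = _rng(seed, "helix_scene")

    half = np.radians(angle / 2.0)
    u1 = np.array([0.0, -np.sin(half), np.cos(half)])
    u2 = np.array([0.0, np.sin(half), np.cos(half)])

    atoms = []
    for (u, off, ca, cb) in ((u1, -separation / 2, "A", "B"),
                             (u2, +separation / 2, "C", "D")):
        phase = float(rng.uniform(0, 2 * np.pi))
        rot = _rotation_between(np.array([0.0, 0.0, 1.0]), u)
        shift = np.array([off, 0.0, 0.0])
        for a in _ideal_duplex(n_bp, rise, twist, phase, ca, cb):
            p = rot @ a.pos + shift
            atoms.append(AtomRecord(a.chain_id, a.residue_number,
                                    a.residue_name, a.atom_name, a.element,
                                    float(p[0]), float(p[1]), float(p[2])))
    scene = StructureModel(atoms=tuple(atoms), source_format="PDB",
                           name=f"helix_scene_{angle:g}deg")
    return HelixSceneTruth(scene=scene, true_angle=float(angle),
                           rise_per_bp=rise, twist_per_bp=twist, n_bp=n_bp,
                           seed=seed, axis_a=u1, axis_b=u2)
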