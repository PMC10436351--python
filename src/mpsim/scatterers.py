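"""Optical identities of the scatterers: Rayleigh spheres and atomistic
polarizability tensors.

A molecule enters the imaging model only through its excess polarizability
``alpha`` — the polarizability relative to the displaced buffer medium.  Two
descriptions are provided:

* a sphere of radius ``a`` and refractive index ``n_p`` in medium ``n_m``,
  with the Clausius–Mossotti volume polarizability
  ``alpha = 3V (n_p^2 - n_m^2) / (n_p^2 + 2 n_m^2)``;
* an atomistic coupled-dipole model: every atom carries an isotropic
  polarizability, mutual dipole-dipole interactions over all pairwise
  distances are solved exactly, and the response to a uniform field defines
  a molecular 3x3 tensor that encodes shape and orientation dependence.

Units: polarizabilities are "volume" polarizabilities (alpha_SI/epsilon_0)
in Å^3 throughout this module; conversion to m^3 happens in exactly one
constant (``A3_TO_M3``) consumed at the optics boundary.  Orientations use
the intrinsic z-y-x Euler convention ``R = Rz @ Ry @ Rx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "A3_TO_M3",
    "ATOMIC_POLARIZABILITY_A3",
    "ATOMIC_MASS_DA",
    "PROTEIN_EXCESS_SCALE",
    "SphereScatterer",
    "AtomicStructure",
    "PolarizabilityTensor",
    "Orientation",
    "sphere_polarizability",
    "tensor_from_structure",
    "coupled_dipole_tensor",
    "rotate_tensor",
    "sample_orientation",
    "effective_response",
    "mean_excess_polarizability",
    "read_pdb",
]

#: single point of unit conversion between the Å^3 polarizability volumes
#: used here and the SI m^3 consumed by the optics / budget modules.
A3_TO_M3 = 1e-30

#: Isotropic atomic polarizabilities (Å^3), static vacuum values after
#: Miller (J. Am. Chem. Soc. 112, 8533 (1990)) / CRC compilations.  Used for
#: the relative per-element response and the interaction solve; the absolute
#: excess-in-medium scale is applied afterwards (PROTEIN_EXCESS_SCALE).
ATOMIC_POLARIZABILITY_A3 = {
    "H": 0.667, "C": 1.76, "N": 1.10, "O": 0.802, "S": 2.90, "P": 3.63,
    "SE": 3.77, "F": 0.557, "CL": 2.18, "BR": 3.05, "I": 5.35,
    "FE": 8.4, "ZN": 7.1, "MG": 10.6, "CA": 22.8, "MN": 9.4, "CU": 6.2,
    "NA": 24.1, "K": 43.4,
}

#: Atomic masses (Da) for the elements above; structure masses follow the
#: convention that only atoms actually present in the structure count.
ATOMIC_MASS_DA = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "FE": 55.845, "ZN": 65.38, "MG": 24.305, "CA": 40.078,
    "MN": 54.938, "CU": 63.546, "NA": 22.990, "K": 39.098,
}

#: Conversion from the vacuum single-atom response to the excess-in-water
#: response of a folded protein.  Calibrated once on the average heavy-atom
#: composition of a protein residue (C4.94 N1.36 O1.48 S0.04 per 110.8 Da,
#: summed Miller polarizability 0.1038 Å^3/Da) against the mass slope of the
#: excess polarizability, delta_alpha = 724 Å^3/kDa including the medium
#: factor n_m^2, i.e. 407.4 Å^3/Da/1000 without it.
PROTEIN_EXCESS_SCALE = 0.40743 / 0.10378

#: default n_m^2 factor applied when quoting delta-alpha-style mean excess
#: polarizabilities (the convention that reproduces 724 Å^3/kDa).
MEDIUM_INDEX_DEFAULT = 1.333


class ParameterTableError(KeyError):
    """An element symbol has no entry in the polarizability/mass tables."""


class ConditioningError(ValueError):
    """The coupled-dipole system is singular or atoms violate the distance floor."""


@dataclass(frozen=True)
class SphereScatterer:
    """Homogeneous dielectric sphere in the Rayleigh regime."""

    radius: float                 # [m]
    n_particle: float = 1.480
    n_medium: float = 1.333
    wavelength: float = 445e-9    # used only for the validity flag

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.n_particle <= 0 or self.n_medium <= 0:
            raise ValueError("radius and refractive indices must be positive")

    @property
    def rayleigh_valid(self) -> bool:
        """Point-dipole treatment is trusted for radius < lambda/10."""
        return self.radius <= self.wavelength / 10.0


def sphere_polarizability(sph: SphereScatterer) -> float:
    """Excess polarizability volume [Å^3] of a Rayleigh sphere,

        alpha = 3 V (n_p^2 - n_m^2) / (n_p^2 + 2 n_m^2)

    (alpha_SI/epsilon_0 convention).  Vanishes for an index-matched particle
    and scales with the particle volume.
    """
    v = 4.0 / 3.0 * np.pi * sph.radius**3 / A3_TO_M3  # Å^3
    np2, nm2 = sph.n_particle**2, sph.n_medium**2
    return float(3.0 * v * (np2 - nm2) / (np2 + 2.0 * nm2))


@dataclass
class AtomicStructure:
    """Point-atom representation of a molecule (coordinates in Å)."""

    elements: np.ndarray          # (N,) str
    coords: np.ndarray            # (N, 3) float, Å
    source_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
            raise ValueError("coords must be a non-empty (N, 3) array")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def mass_kda(self) -> float:
        """Mass of the atoms actually present (kDa) — absent atoms (e.g.
        hydrogens missing from a crystal structure) are not imputed."""
        try:
            masses = [ATOMIC_MASS_DA[str(e).upper()] for e in self.elements]
        except KeyError as err:
            raise ParameterTableError(f"no atomic mass for element {err}") from None
        return float(np.sum(masses)) / 1000.0


@dataclass
class PolarizabilityTensor:
    """3x3 excess polarizability tensor [Å^3] with its reference frame."""

    matrix: np.ndarray
    frame: str = "structure"
    source_id: str = "synthetic"
    mass_kda: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        asym = np.abs(self.matrix - self.matrix.T).max()
        scale = max(np.abs(self.matrix).max(), 1e-300)
        if asym / scale > 1e-8:
            raise ValueError(f"tensor not symmetric (relative asymmetry {asym/scale:.2e})")

    @property
    def mean(self) -> float:
        """Mean excess polarizability <alpha> = trace/3 (rotation invariant)."""
        return float(np.trace(self.matrix) / 3.0)

    def to_json(self) -> str:
        return json.dumps({
            "matrix_A3": self.matrix.tolist(),
            "frame": self.frame,
            "source_id": self.source_id,
            "mass_kda": self.mass_kda,
            "mean_A3": self.mean,
        }, indent=2)


def mean_excess_polarizability(t: PolarizabilityTensor, *,
                               include_medium_factor: bool = True,
                               n_medium: float = MEDIUM_INDEX_DEFAULT) -> float:
    """<alpha> [Å^3], by default in the n_m^2-included convention in which the
    mass slope of folded proteins is ~724 Å^3/kDa (without it, ~460)."""
    f = n_medium**2 if include_medium_factor else 1.0
    return t.mean * f


@dataclass(frozen=True)
class Orientation:
    """Intrinsic z-y-x Euler angles; the composed matrix is R = Rz @ Ry @ Rx.

    Worked example: theta_z = 90 deg alone maps x -> y, y -> -x, so
    diag(1, 2, 3) rotates to diag(2, 1, 3).
    """

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            "ZYX", [self.theta_z, self.theta_y, self.theta_x]).as_matrix()


def sample_orientation(rng: np.random.Generator | int) -> Orientation:
    """Draw an orientation uniformly on SO(3) (reproducible under a seed)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # Haar-uniform rotation from a normalized random quaternion
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    tz, ty, tx = Rotation.from_quat(q).as_euler("ZYX")
    return Orientation(theta_x=tx, theta_y=ty, theta_z=tz)


def rotate_tensor(t: PolarizabilityTensor, o: Orientation) -> PolarizabilityTensor:
    """alpha_rot = R alpha R^T; eigenvalues and trace are invariant."""
    r = o.matrix
    return PolarizabilityTensor(r @ t.matrix @ r.T, frame="rotated",
                                source_id=t.source_id, mass_kda=t.mass_kda)


def _atomic_alphas(elements) -> np.ndarray:
    try:
        return np.array([ATOMIC_POLARIZABILITY_A3[str(e).upper()] for e in elements])
    except KeyError as err:
        raise ParameterTableError(f"no polarizability for element {err}") from None


def coupled_dipole_tensor(coords: np.ndarray, alphas: np.ndarray,
                          distance_floor: float = 1.0) -> np.ndarray:
    """Exact coupled-dipole solution for N interacting point polarizabilities.

    Builds the 3N x 3N interaction matrix A with blocks
    ``A_ii = I/alpha_i`` and ``A_ij = -T_ij`` where
    ``T_ij = (3 rr^T - I)/r^3`` is the quasi-static dipole field tensor,
    solves ``A p = E`` for three orthogonal unit fields and sums the induced
    dipoles.  In the limit of large separations this reduces to
    ``sum(alpha_i) * I``.  Distances below ``distance_floor`` (Å) indicate a
    near-singular (polarization-catastrophe) system and raise.
    """
    coords = np.asarray(coords, float)
    alphas = np.asarray(alphas, float)
    n = len(coords)
    if n == 1:
        return alphas[0] * np.eye(3)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if dist[off].min() < distance_floor:
        raise ConditioningError(
            f"atom pair closer than the {distance_floor} Å floor "
            f"({dist[off].min():.3f} Å): interaction system ill-conditioned")
    inv3 = np.where(off, 1.0 / np.where(off, dist, 1.0) ** 3, 0.0)
    inv5 = np.where(off, 1.0 / np.where(off, dist, 1.0) ** 5, 0.0)
    # T blocks: 3 r r^T / r^5 - I / r^3
    big = (3.0 * diff[:, :, :, None] * diff[:, :, None, :] * inv5[:, :, None, None]
           - np.eye(3)[None, None] * inv3[:, :, None, None])
    a = -big.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    idx = np.arange(3 * n)
    a[idx, idx] += np.repeat(1.0 / alphas, 3)
    rhs = np.tile(np.eye(3), (n, 1))
    try:
        p = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as err:
        raise ConditioningError(f"coupled-dipole system singular: {err}") from None
    tensor = p.reshape(n, 3, 3).sum(axis=0)
    return 0.5 * (tensor + tensor.T)


def _coarse_grain(structure: AtomicStructure, residue_ids: np.ndarray,
                  alphas: np.ndarray):
    """One interaction site per residue: mass-weighted centroid carrying the
    summed atomic polarizability of its constituents."""
    masses = np.array([ATOMIC_MASS_DA[str(e).upper()] for e in structure.elements])
    sites, site_alphas = [], []
    for rid in np.unique(residue_ids):
        sel = residue_ids == rid
        w = masses[sel] / masses[sel].sum()
        sites.append((structure.coords[sel] * w[:, None]).sum(axis=0))
        site_alphas.append(alphas[sel].sum())
    return np.array(sites), np.array(site_alphas)


def tensor_from_structure(structure: AtomicStructure, *,
                          coarse_grain: bool | None = None,
                          residue_ids: np.ndarray | None = None,
                          coarse_grain_threshold: int = 4000,
                          distance_floor: float = 1.0,
                          excess_scale: float = PROTEIN_EXCESS_SCALE,
                          parameters: dict | None = None) -> PolarizabilityTensor:
    """Molecular polarizability tensor from an atomic structure.

    Every atom carries an isotropic polarizability from ``parameters``
    (default table above); the coupled-dipole system over all pairwise
    distances is solved exactly, and the resulting tensor is scaled by
    ``excess_scale`` to the excess-in-medium convention.  Above
    ``coarse_grain_threshold`` atoms the solve is O((3N)^3)-prohibitive and a
    per-residue coarse-graining is used instead (requires ``residue_ids``).
    """
    table = ATOMIC_POLARIZABILITY_A3 if parameters is None else parameters
    try:
        alphas = np.array([table[str(e).upper()] for e in structure.elements])
    except KeyError as err:
        raise ParameterTableError(f"no polarizability for element {err}") from None
    coords = structure.coords
    n = len(coords)
    if coarse_grain is None:
        coarse_grain = n > coarse_grain_threshold and residue_ids is not None
    if coarse_grain:
        if residue_ids is None:
            raise ValueError("coarse graining requires residue_ids")
        coords, alphas = _coarse_grain(structure, np.asarray(residue_ids), alphas)
    elif n > coarse_grain_threshold:
        raise ConditioningError(
            f"{n} atoms exceed the {coarse_grain_threshold}-atom all-atom limit; "
            "pass residue_ids for per-residue coarse graining")
    mat = coupled_dipole_tensor(coords, alphas, distance_floor=distance_floor)
    return PolarizabilityTensor(mat * excess_scale, frame="structure",
                                source_id=structure.source_id,
                                mass_kda=structure.mass_kda)


def effective_response(response, polarization="circular",
                       orientation: Orientation | None = None) -> float:
    """Scalar coupling strength [Å^3] seen by the imaging model.

    * scalar (sphere) input: returned unchanged;
    * tensor + linear polarization along unit vector e (in-plane angle, rad):
      e^T alpha e;
    * tensor + circular polarization: azimuthal average of the in-plane
      linear responses, (alpha_xx + alpha_yy)/2.

    An orientation, if given, is applied to the tensor first; a tensor
    without an explicit orientation is used in its stored frame.
    """
    if np.isscalar(response):
        return float(response)
    t = response if orientation is None else rotate_tensor(response, orientation)
    m = t.matrix
    if polarization == "circular":
        return float((m[0, 0] + m[1, 1]) / 2.0)
    angle = float(polarization[1]) if isinstance(polarization, (tuple, list)) else float(polarization)
    e = np.array([np.cos(angle), np.sin(angle), 0.0])
    return float(e @ m @ e)


def read_pdb(path, source_id: str | None = None):
    """Read ATOM/HETATM records of the first model of a PDB file (altloc 'A'
    preferred) into an ``AtomicStructure`` plus per-atom residue ids."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1, altloc="first")
    atoms = atoms[atoms.element != ""]
    structure = AtomicStructure(
        elements=atoms.element.astype(object),
        coords=np.asarray(atoms.coord, float),
        source_id=source_id or str(path),
    )
    residue_ids = np.array([f"{c}:{r}" for c, r in zip(atoms.chain_id, atoms.res_id)],
                           dtype=object)
    return structure, residue_ids
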