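"""Synthetic fixtures with known ground truth.

Every pipeline stage can be exercised without downloads: toy acarbose-like
reference ligands laid out along +x with annotated subsite moieties, docked
poses as rigid-body displaced/rotated/jittered copies of the reference,
Michaelis-Menten initial-velocity datasets at the assay's acceptor
concentration design (0.32-10 mM), and exponential-phase growth curves.

Each generator is a pure function of its config (seed included): identical
configs give bitwise-identical outputs, and the generating parameters are
attached as ground truth for closed-loop recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .kinetics import GrowthCurve, KineticDataset, RatePoint, enzyme_molar_concentration
from .pose import DockedPose
from .structure import Atom, ReferenceLigand

__all__ = [
    "PoseGenConfig",
    "MMGenConfig",
    "GrowthGenConfig",
    "ASSAY_CONCENTRATIONS",
    "gen_reference_ligand",
    "gen_poses",
    "gen_mm_dataset",
    "gen_growth_curve",
]

# the assay's acceptor-concentration design, mM
ASSAY_CONCENTRATIONS = (0.32, 0.63, 1.25, 2.5, 5.0, 10.0)


@dataclass
class PoseGenConfig:
    n_poses: int = 20
    displacement_along_axis: float | tuple[float, ...] = 0.0  # A
    jitter_sd: float = 0.0  # A, isotropic Gaussian per atom
    rotation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class MMGenConfig:
    KM: float  # mM
    kcat: float  # min^-1
    enzyme_concentration: float = 0.097  # mg/ml
    enzyme_molar_mass: float = 76002.0  # Da
    concentrations: tuple[float, ...] = ASSAY_CONCENTRATIONS  # mM
    noise_cv: float = 0.0
    seed: int = 0
    acceptor: str = "acceptor"

    def __post_init__(self) -> None:
        if self.KM <= 0:
            raise ValueError("KM must be positive")
        if self.kcat < 0:
            raise ValueError("kcat must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class GrowthGenConfig:
    k: float  # h^-1
    N0: float = 1e6  # cells/ml
    lag_h: float = 0.0
    stationary_cap: float = np.inf  # cells/ml
    sample_times: tuple[float, ...] = tuple(np.arange(0.0, 8.0, 1.0))
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k):
            raise ValueError("k must be finite")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")


def gen_reference_ligand(
    n_moieties: int = 4,
    atoms_per_moiety: int = 6,
    spacing: float = 4.0,
    seed: int = 0,
) -> ReferenceLigand:
    """Toy acarbose analogue: moieties equally spaced along +x.

    Moiety centroids sit at x = 0, spacing, 2*spacing, ... and are assigned
    subsites -1, +1, +2, ... in order. Anchors make the binding axis +x with
    its origin midway between the -1 and +1 moiety centroids: the axis-start
    atom sits exactly at the first centroid, the axis-end atom at the
    second, and the origin (linker) atom halfway between them, slightly off
    axis so the projection is exercised.
    """
    if n_moieties < 2:
        raise ValueError("need at least 2 moieties")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if atoms_per_moiety < 3:
        raise ValueError("need >= 3 atoms per moiety to place the anchors")
    rng = np.random.default_rng(seed)
    subsite_labels = [-1] + list(range(1, n_moieties))
    atoms: list[Atom] = []
    moiety_map: dict[str, int] = {}
    serial = 1
    for m, subsite in enumerate(subsite_labels):
        centroid = np.array([m * spacing, 0.0, 0.0])
        fixed: list[tuple[str, np.ndarray]] = []
        if m == 0:
            fixed.append(("C4A", centroid.copy()))
            fixed.append(
                ("N4A", np.array([0.5 * spacing, 0.6 * spacing, -0.4 * spacing]))
            )
        elif m == 1:
            fixed.append(("C1", centroid.copy()))
        n_free = atoms_per_moiety - len(fixed)
        offsets = rng.normal(scale=0.35 * spacing, size=(n_free, 3))
        # shift the free atoms so the moiety centroid is exact
        fixed_sum = sum((pos for _, pos in fixed), np.zeros(3))
        target_sum = atoms_per_moiety * centroid - fixed_sum
        offsets = offsets - offsets.mean(axis=0) + target_sum / n_free
        placed = fixed + [
            (f"M{m}{chr(ord('A') + i)}", offsets[i]) for i in range(n_free)
        ]
        for name, pos in placed:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element="C" if not name.startswith("N") else "N",
                    residue_name="TOY",
                    residue_number=1,
                    chain_id="X",
                    position=pos,
                    is_hetero=True,
                )
            )
            moiety_map[name] = subsite
            serial += 1
    return ReferenceLigand(
        atoms=atoms,
        axis_start_name="C4A",
        axis_end_name="C1",
        origin_name="N4A",
        moiety_map=moiety_map,
    )


def gen_poses(reference: ReferenceLigand, config: PoseGenConfig) -> list[DockedPose]:
    """Rigid-body displaced/rotated/jittered copies of the reference ligand.

    Each pose is the reference translated by its displacement along the
    binding axis (+x for generated references), optionally rotated uniformly
    at random about its centroid, then perturbed per atom by isotropic
    Gaussian jitter. The true displacement is stored as ground truth.
    """
    from .pose import build_binding_axis  # local import to avoid cycle at import

    rng = np.random.default_rng(config.seed)
    axis = build_binding_axis(reference)
    ref_xyz = reference.coordinates()
    centroid = ref_xyz.mean(axis=0)
    disp = config.displacement_along_axis
    displacements = (
        [float(disp)] * config.n_poses
        if np.isscalar(disp)
        else [float(disp[i % len(disp)]) for i in range(config.n_poses)]
    )
    poses: list[DockedPose] = []
    for rank, t in enumerate(displacements, start=1):
        xyz = ref_xyz + t * axis.direction
        if config.rotation:
            rot = Rotation.random(rng=rng)
            center = xyz.mean(axis=0)
            xyz = (xyz - center) @ rot.as_matrix().T + center
        if config.jitter_sd > 0:
            xyz = xyz + rng.normal(scale=config.jitter_sd, size=xyz.shape)
        atoms = [
            Atom(
                serial=a.serial,
                name=a.name,
                element=a.element,
                residue_name=a.residue_name,
                residue_number=a.residue_number,
                chain_id=a.chain_id,
                position=xyz[i],
                is_hetero=True,
            )
            for i, a in enumerate(reference.atoms)
        ]
        poses.append(
            DockedPose(
                ligand_name="synthetic",
                model_rank=rank,
                docking_score=-7.0 + 0.1 * (rank - 1),  # placeholder energies
                atoms=atoms,
                ground_truth={
                    "displacement": t,
                    "jitter_sd": config.jitter_sd,
                    "rotated": config.rotation,
                    "reference_centroid_coordinate": float(
                        np.dot(centroid - axis.origin, axis.direction)
                    ),
                },
            )
        )
    return poses


def gen_mm_dataset(config: MMGenConfig) -> KineticDataset:
    """Michaelis-Menten initial velocities with optional multiplicative noise.

    v([S]) = Vmax [S] / (KM + [S]), Vmax = kcat * [E] with [E] in uM from
    the enzyme load, so velocities are in uM product / min.
    """
    rng = np.random.default_rng(config.seed)
    e_um = enzyme_molar_concentration(
        config.enzyme_concentration, config.enzyme_molar_mass
    )
    vmax = config.kcat * e_um
    points: list[RatePoint] = []
    for s in config.concentrations:
        v = vmax * s / (config.KM + s)
        if config.noise_cv > 0:
            v *= 1.0 + config.noise_cv * rng.standard_normal()
        points.append(RatePoint(acceptor_concentration=s, velocity=max(v, 1e-12)))
    return KineticDataset(
        acceptor=config.acceptor,
        points=points,
        ground_truth={
            "KM": config.KM,
            "kcat": config.kcat,
            "Vmax": vmax,
            "enzyme_concentration": config.enzyme_concentration,
            "enzyme_molar_mass": config.enzyme_molar_mass,
            "noise_cv": config.noise_cv,
            "seed": config.seed,
        },
    )


def gen_growth_curve(config: GrowthGenConfig) -> GrowthCurve:
    """Lag / exponential / stationary growth curve with multiplicative noise.

    Density stays at N0 until ``lag_h``, grows as N0 exp(k (t - lag))
    afterward, and saturates at ``stationary_cap``.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.sample_times, dtype=float)
    n = np.where(
        t < config.lag_h,
        config.N0,
        config.N0 * np.exp(config.k * np.maximum(t - config.lag_h, 0.0)),
    )
    n = np.minimum(n, config.stationary_cap)
    if config.noise_cv > 0:
        n = n * (1.0 + config.noise_cv * rng.standard_normal(size=n.shape))
        n = np.maximum(n, 1e-6 * config.N0)
    return GrowthCurve(
        times=t,
        densities=n,
        ground_truth={
            "k": config.k,
            "N0": config.N0,
            "lag_h": config.lag_h,
            "stationary_cap": config.stationary_cap,
            "noise_cv": config.noise_cv,
            "seed": config.seed,
        },
    )
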