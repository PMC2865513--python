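"""Synthetic tetramers and morphing trajectories with known ground truth.

The generator builds an abstract four-chain "tetramer" (helix-like
C-alpha traces plus small dummy heme groups — not a hemoglobin model) in
two endpoint conformations: the quaternary difference is a pure rigid
rotation of the alpha2/beta2 dimer, and each subunit additionally carries
a subunit-internal tertiary deformation field.  Morphing trajectories
interpolate between the endpoints with a tunable schedule; each subunit's
tertiary coordinate follows the quaternary schedule with a chosen
coupling strength and lag, mixed with an independent smooth
Ornstein-Uhlenbeck component, plus optional Gaussian coordinate noise.
This reproduces the statistical structure assumed by the
mutual-information analysis (beta subunits coupled to the quaternary
transition, alpha subunits largely independent) with exact ground truth.

Two construction details make the pipeline exactly verifiable:

* Tertiary deformation fields carry no net translation or rotation with
  respect to their subunit (the rigid component is projected out
  exactly), so subunit-internal superposition of a deformed subunit onto
  the undeformed one is the identity and the normalized tertiary
  projection of a noiseless frame equals ``1 - 2 c`` exactly.
* With ``quaternary_motion="rotation"`` (default) frames compose the
  dimer rotation per frame — physically meaningful, tertiary coordinates
  exact, quaternary projection follows the rotation arc (deviation from
  linearity bounded by theta^2/8).  With ``"linear"`` frames interpolate
  linearly between the mutually superposed endpoints, making the
  normalized quaternary projection exactly linear in the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .mutualinfo import PairedSeries
from .structure_io import (
    HEME_OF_SUBUNIT,
    SUBUNITS,
    SelectionSpec,
    TetramerModel,
    kabsch_superpose,
    select_atoms,
    write_multimodel_pdb,
)

__all__ = [
    "MorphSpec",
    "ToyTetramer",
    "make_toy_tetramer",
    "make_transition_trajectory",
    "make_gaussian_pairs",
    "write_multimodel_pdb",
]

_CHAIN_OF_SUBUNIT = {"alpha1": "A", "beta1": "B", "alpha2": "C",
                     "beta2": "D"}
_QUAT_AXIS = np.array([0.0, 0.0, 1.0])  # rotation axis of the alpha2/beta2 dimer
_ROTATED = ("alpha2", "beta2", "HEM3", "HEM4")


@dataclass(frozen=True)
class MorphSpec:
    """Recipe for one synthetic transition trajectory.

    ``tertiary_coupling`` maps each subunit to the fraction of its
    tertiary coordinate driven by the (lagged) quaternary schedule; the
    remainder follows an independent smooth random walk.  Defaults
    emulate the observed coupling pattern: beta subunits tightly coupled
    (0.9), alpha subunits largely independent (0.1), 0.02 nm coordinate
    noise.
    """

    n_frames: int = 1000
    schedule: str = "linear"  # linear | sigmoidal | piecewise
    piecewise_times: tuple[float, float] = (0.25, 0.75)
    quaternary_path: str = "T->R"  # or "T->partial"
    partial_extent: float = 0.5
    tertiary_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"alpha1": 0.1, "beta1": 0.9,
                                 "alpha2": 0.1, "beta2": 0.9})
    tertiary_lag: Mapping[str, int] = field(
        default_factory=lambda: {s: 0 for s in SUBUNITS})
    noise_sigma: float = 0.02  # nm
    quaternary_motion: str = "rotation"  # rotation | linear
    dt_ns: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for s, c in self.tertiary_coupling.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling[{s}] = {c} outside [0, 1]")
        for s, lag in self.tertiary_lag.items():
            if lag >= self.n_frames:
                raise ValueError(
                    f"lag[{s}] = {lag} >= n_frames = {self.n_frames}")
        if self.schedule not in ("linear", "sigmoidal", "piecewise"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.quaternary_motion not in ("rotation", "linear"):
            raise ValueError(
                f"unknown quaternary_motion {self.quaternary_motion!r}")
        if self.quaternary_path not in ("T->R", "T->partial"):
            raise ValueError(f"unknown path {self.quaternary_path!r}")


@dataclass
class ToyTetramer:
    """Endpoint pair with the displacement fields that generated it."""

    endpoint_T: TetramerModel
    endpoint_R: TetramerModel
    tert_fields: dict[str, np.ndarray]  # subunit -> (N_total, 3), nm
    quat_angle_deg: float
    quat_axis: np.ndarray
    quat_center: np.ndarray
    rotated_mask: np.ndarray  # atoms belonging to the alpha2/beta2 dimer


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _helix_chain(n_res: int, center: np.ndarray,
                 orient: np.ndarray) -> np.ndarray:
    """Helix-like C-alpha trace: 0.25 nm radius, 0.15 nm rise/residue."""
    j = np.arange(n_res)
    turn = np.deg2rad(100.0) * j
    local = np.stack([0.25 * np.cos(turn), 0.25 * np.sin(turn),
                      0.15 * (j - (n_res - 1) / 2)], axis=1)
    return local @ orient.T + center


def _vee(a: np.ndarray) -> np.ndarray:
    return np.array([a[2, 1], a[0, 2], a[1, 0]])


def _hat(w: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -w[2], w[1]],
                     [w[2], 0.0, -w[0]],
                     [-w[1], w[0], 0.0]])


def _remove_rigid_component(d0: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Remove net translation and rotation from a displacement field.

    Translation: subtract the mean.  Rotation: add the linear rotation
    field ``Omega r`` solving ``S Omega + Omega S = 2 antisym(M0)`` with
    ``S`` the coordinate scatter matrix and ``M0`` the cross-moment, which
    makes the Kabsch cross-covariance of (coords, coords + d) exactly
    symmetric, so the optimal superposition of the deformed structure onto
    the original is exactly the identity.
    """
    r = coords - coords.mean(axis=0)
    d = d0 - d0.mean(axis=0)
    s_mat = r.T @ r
    m0 = r.T @ d
    a = m0 - m0.T  # 2 * antisym(M0)
    basis = np.eye(3)
    lmat = np.column_stack([
        _vee(s_mat @ _hat(e) + _hat(e) @ s_mat) for e in basis])
    omega = np.linalg.solve(lmat, _vee(a))
    d = d + r @ _hat(omega).T
    return d - d.mean(axis=0)


def _smooth_field(n: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random displacement field over a chain of n atoms."""
    j = np.arange(n)
    out = np.zeros((n, 3))
    for m in (1, 2, 3):
        amp = rng.normal(size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        out += amp * np.sin(2 * np.pi * m * j[:, None] / n + phase)
    return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_toy_tetramer(n_res_per_subunit: int = 12,
                      quat_angle_deg: float = 14.0,
                      tert_amplitude: float = 0.1,
                      seed: int = 0) -> ToyTetramer:
    """Build endpoint conformations of an abstract tetramer.

    The R endpoint equals the T endpoint with the alpha2/beta2 dimer
    rotated by ``quat_angle_deg`` about the z axis through its center of
    mass, and every subunit (with its heme) internally deformed by a
    smooth field of per-atom RMS amplitude ``tert_amplitude`` (nm) that
    carries no rigid-body component relative to the subunit.
    """
    if n_res_per_subunit < 5:
        raise ValueError("need at least 5 residues per subunit")
    rng = np.random.default_rng(seed)

    centers = {"alpha1": np.array([-1.2, -1.2, 0.0]),
               "beta1": np.array([-1.2, 1.2, 0.0]),
               "alpha2": np.array([1.2, -1.2, 0.0]),
               "beta2": np.array([1.2, 1.2, 0.0])}
    name, res_name, chain_id, res_seq, element, subunit, coords = \
        [], [], [], [], [], [], []
    for sub in SUBUNITS:
        orient = Rotation.random(rng=rng).as_matrix()
        chain = _CHAIN_OF_SUBUNIT[sub]
        xyz = _helix_chain(n_res_per_subunit, centers[sub], orient)
        for jj in range(n_res_per_subunit):
            name.append("CA")
            res_name.append("ALA")
            chain_id.append(chain)
            res_seq.append(jj + 1)
            element.append("C")
            subunit.append(sub)
            coords.append(xyz[jj])
        # dummy 5-atom heme next to the chain center
        heme_center = centers[sub] + orient @ np.array([0.45, 0.0, 0.0])
        offsets = np.array([[0.0, 0.0, 0.0], [0.2, 0.0, 0.0],
                            [-0.2, 0.0, 0.0], [0.0, 0.2, 0.0],
                            [0.0, -0.2, 0.0]])
        for k, nm_ in enumerate(("FE", "NA", "NB", "NC", "ND")):
            name.append(nm_)
            res_name.append("HEM")
            chain_id.append(chain)
            res_seq.append(n_res_per_subunit + 1)
            element.append("FE" if nm_ == "FE" else "N")
            subunit.append(HEME_OF_SUBUNIT[sub])
            coords.append(heme_center + orient @ offsets[k])

    endpoint_t = TetramerModel.from_arrays(
        name=name, residue_name=res_name, chain_id=chain_id,
        residue_seq=res_seq, element=element, coords=np.array(coords),
        subunit=np.array(subunit))

    n_total = endpoint_t.n_atoms
    tert_fields: dict[str, np.ndarray] = {}
    for sub in SUBUNITS:
        mask = (endpoint_t.subunit == sub) | \
               (endpoint_t.subunit == HEME_OF_SUBUNIT[sub])
        d = np.zeros((n_total, 3))
        if tert_amplitude > 0:
            local = _smooth_field(int(mask.sum()), rng)
            local = _remove_rigid_component(local, endpoint_t.coords[mask])
            rms = np.sqrt(np.mean(np.sum(local ** 2, axis=1)))
            local *= tert_amplitude / rms
            d[mask] = local
        tert_fields[sub] = d

    rotated = np.isin(endpoint_t.subunit, _ROTATED)
    center = endpoint_t.coords[rotated].mean(axis=0)
    rot = Rotation.from_rotvec(
        np.deg2rad(quat_angle_deg) * _QUAT_AXIS).as_matrix()

    coords_r = endpoint_t.coords.copy()
    for sub in SUBUNITS:
        coords_r += tert_fields[sub]
    coords_r[rotated] = (coords_r[rotated] - center) @ rot.T + center
    endpoint_r = endpoint_t.with_coords(coords_r)

    return ToyTetramer(endpoint_T=endpoint_t, endpoint_R=endpoint_r,
                       tert_fields=tert_fields,
                       quat_angle_deg=float(quat_angle_deg),
                       quat_axis=_QUAT_AXIS.copy(), quat_center=center,
                       rotated_mask=rotated)


def _schedule_values(spec: MorphSpec) -> np.ndarray:
    u = np.linspace(0.0, 1.0, spec.n_frames)
    if spec.schedule == "linear":
        s = u
    elif spec.schedule == "sigmoidal":
        raw = 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5)))
        s = (raw - raw[0]) / (raw[-1] - raw[0])
    else:  # piecewise ramp between the two fractional times
        t0, t1 = spec.piecewise_times
        s = np.clip((u - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    if spec.quaternary_path == "T->partial":
        s = s * spec.partial_extent
    return s


def _ou_walk(n: int, rng: np.random.Generator,
             mean: float = 0.5, sd: float = 0.3,
             tau_frames: float | None = None) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck walk: smooth, seeded, bounded scale.

    The relaxation time defaults to n/20 frames so the walk decorrelates
    several times within a trajectory — MI against it reflects coupling,
    not the noise floor.
    """
    tau = tau_frames or max(n / 20.0, 2.0)
    step_sd = sd * np.sqrt(2.0 / tau)
    u = np.empty(n)
    u[0] = mean + sd * rng.normal()
    for i in range(1, n):
        u[i] = u[i - 1] + (mean - u[i - 1]) / tau + step_sd * rng.normal()
    return u


def make_transition_trajectory(toy: ToyTetramer, spec: MorphSpec
                               ) -> tuple[list[TetramerModel], pd.DataFrame]:
    """Morph the toy tetramer from T to R with per-subunit ground truth.

    Frame ``i`` carries the quaternary transition at schedule value
    ``s(i)`` and each subunit's tertiary deformation at
    ``c = coupling * s(i - lag) + (1 - coupling) * u(i)`` with ``u`` an
    independent OU walk; Gaussian noise of ``noise_sigma`` nm is added to
    every coordinate.  Returns the frames and a table with columns
    ``frame, time_ns, s, quat_true`` and ``c_<subunit>, tert_true_<subunit>``
    (the noiseless normalized coordinates ``1 - 2s`` / ``1 - 2c``).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    s = _schedule_values(spec)
    n = spec.n_frames

    c = {}
    for sub in SUBUNITS:
        coupling = float(spec.tertiary_coupling.get(sub, 0.0))
        lag = int(spec.tertiary_lag.get(sub, 0))
        lagged = np.concatenate([np.zeros(lag), s[:n - lag]])
        independent = _ou_walk(n, rng) if coupling < 1.0 else np.zeros(n)
        c[sub] = coupling * lagged + (1.0 - coupling) * independent

    base = toy.endpoint_T.coords
    rotated = toy.rotated_mask
    theta = np.deg2rad(toy.quat_angle_deg)

    if spec.quaternary_motion == "linear":
        # mutually superposed endpoints: quaternary displacement is the
        # aligned difference minus the tertiary fields
        sel = SelectionSpec("calpha_heme")
        _, idx = select_atoms(toy.endpoint_T, sel)
        tert_total = np.sum([toy.tert_fields[s_] for s_ in SUBUNITS], axis=0)
        tert1 = base + tert_total
        sup = kabsch_superpose(toy.endpoint_R.coords[idx], tert1[idx])
        aligned_r = sup.apply(toy.endpoint_R.coords)
        quat_field = aligned_r - tert1
        tert_aligned = {s_: toy.tert_fields[s_] for s_ in SUBUNITS}

    frames = []
    for i in range(n):
        coords = base.copy()
        if spec.quaternary_motion == "rotation":
            for sub in SUBUNITS:
                coords += c[sub][i] * toy.tert_fields[sub]
            rot = Rotation.from_rotvec(
                s[i] * theta * toy.quat_axis).as_matrix()
            coords[rotated] = ((coords[rotated] - toy.quat_center)
                               @ rot.T + toy.quat_center)
        else:
            for sub in SUBUNITS:
                coords += c[sub][i] * tert_aligned[sub]
            coords += s[i] * quat_field
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma,
                                         size=coords.shape)
        frames.append(toy.endpoint_T.with_coords(
            coords, frame_time=i * spec.dt_ns))

    truth = pd.DataFrame({"frame": np.arange(n),
                          "time_ns": np.arange(n) * spec.dt_ns,
                          "s": s, "quat_true": 1.0 - 2.0 * s})
    for sub in SUBUNITS:
        truth[f"c_{sub}"] = c[sub]
        truth[f"tert_true_{sub}"] = 1.0 - 2.0 * c[sub]
    return frames, truth


def make_gaussian_pairs(rho: float, n: int, seed: int = 0) -> PairedSeries:
    """Bivariate normal sample with unit variances and correlation rho.

    The closed-form MI of this distribution, ``-0.5 ln(1 - rho^2)`` nats,
    serves as the oracle for validating the histogram MI estimator.
    """
    if abs(rho) >= 1.0:
        raise ValueError("need |rho| < 1")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n,
                                 method="cholesky")
    return PairedSeries(xy[:, 0], xy[:, 1])
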