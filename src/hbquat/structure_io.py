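"""PDB input/output and geometric primitives for the hemoglobin tetramer.

This module reads single- or multi-model PDB files into a labeled
:class:`TetramerModel` (four globin subunits plus their heme groups),
resolves atom selections that are comparable across structures, and
provides the geometric building blocks used throughout the package:
Kabsch superposition, plain RMSD, the rotation-sensitive ``rotRMSD``
(superpose on the alpha1/beta1 dimer, measure on alpha2/beta2),
mass-weighted centers of mass, and salt-bridge detection.

All coordinates are handled in nanometres; PDB files (Angstrom) are
converted on read and write.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdb

__all__ = [
    "SUBUNITS",
    "HEME_OF_SUBUNIT",
    "SUBUNIT_OF_HEME",
    "DEFAULT_CHAIN_MAP",
    "BACKBONE_ATOMS",
    "AtomRecord",
    "TetramerModel",
    "SelectionSpec",
    "Superposition",
    "SaltBridge",
    "read_pdb",
    "write_multimodel_pdb",
    "select_atoms",
    "common_selection",
    "kabsch_superpose",
    "rmsd",
    "rot_rmsd",
    "center_of_mass",
    "detect_salt_bridges",
    "diff_salt_bridges",
    "T_STATE_BRIDGE_TYPES",
    "expand_symmetric_bridges",
]

#: Polymer subunit labels of the Hb tetramer (two alpha/beta dimers).
SUBUNITS = ("alpha1", "beta1", "alpha2", "beta2")

#: Heme group label belonging to each subunit.
HEME_OF_SUBUNIT = {
    "alpha1": "HEM1",
    "beta1": "HEM2",
    "alpha2": "HEM3",
    "beta2": "HEM4",
}
SUBUNIT_OF_HEME = {v: k for k, v in HEME_OF_SUBUNIT.items()}

#: Chain identifier -> subunit label. 2HHB/1IRD/1BBB convention.
DEFAULT_CHAIN_MAP = {"A": "alpha1", "B": "beta1", "C": "alpha2", "D": "beta2"}

#: Protein backbone heavy atoms.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_DIMER_1 = ("alpha1", "beta1")
_DIMER_2 = ("alpha2", "beta2")


@dataclass(frozen=True)
class AtomRecord:
    """One atom with the metadata needed for labeling and selection."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    element: str
    coordinates: np.ndarray  # (3,) nm
    mass: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.mass <= 0:
            raise ValueError(f"atom mass must be positive, got {self.mass}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class TetramerModel:
    """Labeled coordinates of one tetramer conformation.

    Atoms are stored column-wise in numpy arrays; the atom order is stable
    across every operation in the package.  ``subunit`` holds one label per
    atom: ``alpha1/beta1/alpha2/beta2`` for the globin chains,
    ``HEM1..HEM4`` for the heme groups, and ``other`` for anything else
    (solvent, ions).
    """

    serial: np.ndarray  # (N,) int
    name: np.ndarray  # (N,) str
    residue_name: np.ndarray  # (N,) str
    chain_id: np.ndarray  # (N,) str
    residue_seq: np.ndarray  # (N,) int
    element: np.ndarray  # (N,) str
    coords: np.ndarray  # (N, 3) float, nm
    mass: np.ndarray  # (N,) float, amu
    subunit: np.ndarray  # (N,) str
    frame_time: float = 0.0  # ns; 0 for static structures

    def __post_init__(self) -> None:
        n = len(self.coords)
        for attr in ("serial", "name", "residue_name", "chain_id",
                     "residue_seq", "element", "mass", "subunit"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"field {attr!r} length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom_keys(self) -> list[tuple[str, int, str]]:
        """Cross-structure matching keys ``(chain_id, residue_seq, name)``."""
        return list(zip(self.chain_id.tolist(), self.residue_seq.tolist(),
                        self.name.tolist()))

    def atom_records(self) -> list[AtomRecord]:
        return [
            AtomRecord(int(self.serial[i]), str(self.name[i]),
                       str(self.residue_name[i]), str(self.chain_id[i]),
                       int(self.residue_seq[i]), str(self.element[i]),
                       self.coords[i].copy(), float(self.mass[i]))
            for i in range(self.n_atoms)
        ]

    def subunit_mask(self, label: str) -> np.ndarray:
        return self.subunit == label

    def with_coords(self, coords: np.ndarray,
                    frame_time: float | None = None) -> "TetramerModel":
        """Copy of this model with replaced coordinates (same labeling)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate shape mismatch")
        return dataclasses.replace(
            self, coords=coords,
            frame_time=self.frame_time if frame_time is None else frame_time)

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "TetramerModel":
        """Apply a rigid transform ``x -> R x + t`` to all atoms."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return self.with_coords(new)

    @classmethod
    def from_arrays(cls, *, name, residue_name, chain_id, residue_seq,
                    element, coords, subunit, serial=None, mass=None,
                    frame_time: float = 0.0) -> "TetramerModel":
        """Build a model from plain sequences; masses default to element
        masses looked up in biotite's chemical component tables."""
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        element = np.asarray(element, dtype="U2")
        if mass is None:
            mass = np.array([_element_mass(e) for e in element])
        if serial is None:
            serial = np.arange(1, n + 1)
        return cls(
            serial=np.asarray(serial, dtype=int),
            name=np.asarray(name, dtype="U6"),
            residue_name=np.asarray(residue_name, dtype="U4"),
            chain_id=np.asarray(chain_id, dtype="U2"),
            residue_seq=np.asarray(residue_seq, dtype=int),
            element=element,
            coords=coords,
            mass=np.asarray(mass, dtype=float),
            subunit=np.asarray(subunit, dtype="U8"),
            frame_time=float(frame_time),
        )


def _element_mass(element: str) -> float:
    m = struc_info.mass(element.strip().upper() or "C")
    if m is None or m <= 0:
        raise ValueError(f"unknown element {element!r}")
    return float(m)


@dataclass(frozen=True)
class SelectionSpec:
    """Which atoms enter a geometric computation.

    ``calpha_heme`` selects the C-alpha trace plus all heme-group atoms of
    the requested subunits (the atom set used for the X-ray PCA subspace),
    ``backbone`` the N/CA/C/O atoms, ``all`` every heavy atom including the
    hemes of the requested subunits.
    """

    mode: str = "calpha_heme"
    subunits: tuple[str, ...] = SUBUNITS
    include_hemes: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("calpha_heme", "backbone", "all"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        unknown = set(self.subunits) - set(SUBUNITS)
        if unknown:
            raise ValueError(f"unknown subunits {sorted(unknown)}")
        object.__setattr__(self, "subunits", tuple(self.subunits))


@dataclass(frozen=True)
class Superposition:
    """A least-squares rigid-body fit ``x -> R (x - com_mobile) + com_ref``.

    ``rotation`` is proper orthonormal (det = +1); ``rmsd_fit`` is the
    (weighted) RMSD between the fitted mobile and the reference coordinates.
    """

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,), nm
    rmsd_fit: float  # nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SaltBridge:
    """A contact between oppositely charged groups of two residues."""

    partner_a: tuple[str, int, str, str]  # (chain, residue_seq, residue_name, atom)
    partner_b: tuple[str, int, str, str]
    distance: float  # nm
    inter_subunit: bool

    def residue_pair(self) -> frozenset:
        return frozenset(((self.partner_a[0], self.partner_a[1]),
                          (self.partner_b[0], self.partner_b[1])))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _label_subunits(chain_id, residue_name, hetero,
                    chain_map: Mapping[str, str]) -> np.ndarray:
    labels = np.full(len(chain_id), "other", dtype="U8")
    for i in range(len(chain_id)):
        sub = chain_map.get(chain_id[i])
        if sub is None:
            continue
        if residue_name[i] == "HEM":
            labels[i] = HEME_OF_SUBUNIT[sub]
        elif not hetero[i]:
            labels[i] = sub
    return labels


def _model_from_atom_array(arr, chain_map: Mapping[str, str],
                           frame_time: float) -> TetramerModel:
    heavy = arr.element != "H"
    arr = arr[heavy]
    subunit = _label_subunits(arr.chain_id, arr.res_name, arr.hetero,
                              chain_map)
    model = TetramerModel.from_arrays(
        serial=np.arange(1, arr.array_length() + 1),
        name=arr.atom_name,
        residue_name=arr.res_name,
        chain_id=arr.chain_id,
        residue_seq=arr.res_id,
        element=arr.element,
        coords=arr.coord * 0.1,  # Angstrom -> nm
        subunit=subunit,
        frame_time=frame_time,
    )
    for chain, sub in chain_map.items():
        mask = (model.subunit == sub) & (model.name == "CA")
        if not mask.any():
            raise ValueError(
                f"chain {chain!r} (subunit {sub}) missing or has no "
                f"C-alpha atoms")
    return model


def read_pdb(path: str | Path, model_index: int | str = "all",
             chain_map: Mapping[str, str] | None = None,
             dt_ns: float = 1.0) -> TetramerModel | list[TetramerModel]:
    """Read a (multi-model) PDB file into labeled tetramer model(s).

    Parameters
    ----------
    path:
        PDB file.  ATOM/HETATM coordinates are converted from Angstrom to
        nm; hydrogens are dropped; alternate locations are resolved by
        highest occupancy (ties by altloc identifier).
    model_index:
        1-based model number, or ``"all"`` to return every model as a
        trajectory with ``frame_time = (model - 1) * dt_ns``.
    chain_map:
        Chain-to-subunit mapping; defaults to A/B/C/D ->
        alpha1/beta1/alpha2/beta2.
    """
    chain_map = dict(chain_map or DEFAULT_CHAIN_MAP)
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: file contains no models")
    if model_index == "all":
        stack = pdb_file.get_structure(model=None, altloc="occupancy")
        return [
            _model_from_atom_array(stack[i], chain_map,
                                   frame_time=i * dt_ns)
            for i in range(stack.stack_depth())
        ]
    arr = pdb_file.get_structure(model=int(model_index), altloc="occupancy")
    return _model_from_atom_array(arr, chain_map, frame_time=0.0)


def write_multimodel_pdb(frames: Sequence[TetramerModel],
                         path: str | Path) -> None:
    """Write frames as a multi-model PDB file (coordinates nm -> Angstrom).

    All frames must share the same atom labeling; heme groups are emitted
    as HETATM records with residue name HEM so that :func:`read_pdb`
    round-trips the subunit labels.
    """
    if not frames:
        raise ValueError("no frames to write")
    first = frames[0]
    n = first.n_atoms
    arrays = []
    hetero = np.array([s.startswith("HEM") or s == "other"
                       for s in first.subunit])
    for f in frames:
        if f.n_atoms != n:
            raise ValueError("frames differ in atom count")
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(f.coords, dtype=np.float32) * 10.0
        arr.chain_id = first.chain_id
        arr.res_id = first.residue_seq
        arr.res_name = first.residue_name
        arr.atom_name = first.name
        arr.element = first.element
        arr.hetero = hetero
        arrays.append(arr)
    stack = struc.stack(arrays)
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _selection_mask(model: TetramerModel, spec: SelectionSpec) -> np.ndarray:
    requested = set(spec.subunits)
    missing = [s for s in requested
               if not (model.subunit == s).any()]
    if missing:
        raise ValueError(f"subunits missing from model: {missing}")
    protein = np.isin(model.subunit, sorted(requested))
    if spec.mode == "calpha_heme":
        mask = protein & (model.name == "CA")
    elif spec.mode == "backbone":
        mask = protein & np.isin(model.name, BACKBONE_ATOMS)
    else:  # all heavy atoms of the requested subunits
        mask = protein
    if spec.include_hemes and spec.mode != "backbone":
        hemes = [HEME_OF_SUBUNIT[s] for s in requested]
        mask = mask | np.isin(model.subunit, hemes)
    return mask


def select_atoms(model: TetramerModel,
                 spec: SelectionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a selection to ``(coords (N, 3) nm, atom indices)``.

    Atom order is ascending atom index, hence deterministic and stable for
    structures sharing residue numbering.
    """
    mask = _selection_mask(model, spec)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"selection {spec} matches no atoms")
    return model.coords[idx], idx


def common_selection(a: TetramerModel, b: TetramerModel,
                     spec: SelectionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the common atoms of a selection in two structures.

    Atoms are matched on the key ``(chain_id, residue_seq, atom_name)`` and
    intersected, so structures that resolve slightly different atom sets
    (e.g. different PDB entries) still yield equal-length coordinate
    arrays.  Order follows structure ``a``.
    """
    _, ia = select_atoms(a, spec)
    _, ib = select_atoms(b, spec)
    keys_a = [(a.chain_id[i], int(a.residue_seq[i]), a.name[i]) for i in ia]
    keys_b = {(b.chain_id[i], int(b.residue_seq[i]), b.name[i]): i
              for i in ib}
    pairs = [(i, keys_b[k]) for i, k in zip(ia, keys_a) if k in keys_b]
    if not pairs:
        raise ValueError("no common atoms between structures for selection")
    out_a = np.array([p[0] for p in pairs], dtype=int)
    out_b = np.array([p[1] for p in pairs], dtype=int)
    return out_a, out_b


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> Superposition:
    """Optimal weighted rigid-body fit of ``mobile`` onto ``reference``.

    Returns the proper rotation and translation minimizing the weighted
    RMSD (Kabsch).  For degenerate (e.g. collinear) point sets the rotation
    about the degenerate axis is underdetermined; the solver then returns
    one optimal representative, which is documented fallback behaviour.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference shapes differ")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mobile),) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("invalid weights")
    com_m = np.average(mobile, axis=0, weights=w)
    com_r = np.average(reference, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(reference - com_r, mobile - com_m,
                                    weights=w)
    matrix = rot.as_matrix()
    translation = com_r - matrix @ com_m
    # evaluate the residual explicitly: the solver's rssd suffers from
    # cancellation near zero
    moved = mobile @ matrix.T + translation
    rmsd_fit = float(np.sqrt(
        np.average(np.sum((moved - reference) ** 2, axis=1), weights=w)))
    return Superposition(rotation=matrix, translation=translation,
                         rmsd_fit=rmsd_fit)


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = True) -> float:
    """Root-mean-square deviation between two coordinate sets (nm).

    ``fit=True`` first performs the optimal whole-selection superposition
    of ``a`` onto ``b`` (the conventional RMSD); ``fit=False`` compares the
    raw coordinates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate shapes differ")
    if a.shape[0] == 0:
        raise ValueError("empty coordinate sets")
    if fit:
        return kabsch_superpose(a, b).rmsd_fit
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rot_rmsd(frame: TetramerModel, reference: TetramerModel,
             spec: SelectionSpec | None = None) -> float:
    """Rotation-sensitive RMSD between two tetramer conformations (nm).

    The frame's alpha1/beta1 dimer backbone is superposed onto the
    reference's alpha1/beta1 dimer; the backbone RMSD of the alpha2/beta2
    dimer is then evaluated against the same reference *without* refitting.
    Because a pure rotation of one dimer relative to the other survives the
    anchoring, this measure is far more sensitive to the quaternary T<->R
    transition than the standard fitted RMSD (0.53 nm versus 0.24 nm
    between the R and T crystal structures).
    """
    mode = spec.mode if spec is not None else "backbone"
    spec1 = SelectionSpec(mode=mode, subunits=_DIMER_1, include_hemes=False)
    spec2 = SelectionSpec(mode=mode, subunits=_DIMER_2, include_hemes=False)
    ia1, ir1 = common_selection(frame, reference, spec1)
    ia2, ir2 = common_selection(frame, reference, spec2)
    sup = kabsch_superpose(frame.coords[ia1], reference.coords[ir1])
    moved = sup.apply(frame.coords[ia2])
    return rmsd(moved, reference.coords[ir2], fit=False)


def center_of_mass(model: TetramerModel, subunit: str) -> np.ndarray:
    """Mass-weighted center of the heavy atoms of one subunit (nm).

    Heme atoms are not part of the polymer subunits and are excluded.
    """
    mask = model.subunit_mask(subunit)
    if not mask.any():
        raise ValueError(f"subunit {subunit!r} not present")
    return np.average(model.coords[mask], axis=0,
                      weights=model.mass[mask])


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

_NEGATIVE_SIDE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_POSITIVE_SIDE = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"),
                  "HIS": ("NE2", "ND1")}


def _charged_groups(model: TetramerModel):
    """Yield ``(sign, chain, residue_seq, residue_name, atom_indices)``.

    Charged groups are Asp/Glu carboxylates and C-terminal carboxylates
    (negative), Lys/Arg/His side-chain amines and N-terminal amines
    (positive).  His is treated as protonatable, hence positive.
    """
    groups = []
    protein = np.isin(model.subunit, SUBUNITS)
    termini_n: dict[str, int] = {}
    termini_c: dict[str, int] = {}
    for ch in np.unique(model.chain_id[protein]):
        seqs = model.residue_seq[protein & (model.chain_id == ch)]
        termini_n[ch] = int(seqs.min())
        termini_c[ch] = int(seqs.max())
    res_keys = {}
    for i in np.flatnonzero(protein):
        key = (model.chain_id[i], int(model.residue_seq[i]),
               model.residue_name[i])
        res_keys.setdefault(key, []).append(i)
    for (ch, seq, resn), idx in res_keys.items():
        names = {model.name[i]: i for i in idx}
        if resn in _NEGATIVE_SIDE:
            atoms = [names[a] for a in _NEGATIVE_SIDE[resn] if a in names]
            if atoms:
                groups.append((-1, ch, seq, resn, atoms))
        if resn in _POSITIVE_SIDE:
            atoms = [names[a] for a in _POSITIVE_SIDE[resn] if a in names]
            if atoms:
                groups.append((+1, ch, seq, resn, atoms))
        if seq == termini_n.get(ch) and "N" in names:
            groups.append((+1, ch, seq, resn, [names["N"]]))
        if seq == termini_c.get(ch):
            atoms = [names[a] for a in ("OXT", "O") if a in names]
            if atoms:
                groups.append((-1, ch, seq, resn, atoms))
    return groups


def detect_salt_bridges(model: TetramerModel,
                        cutoff: float = 0.4) -> list[SaltBridge]:
    """Salt bridges: oppositely charged groups within ``cutoff`` nm.

    The distance between two groups is the minimum heavy-atom distance
    between their charged atoms.  Bridges are de-duplicated per residue
    pair (the closest atom pair is kept).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    groups = _charged_groups(model)
    neg = [g for g in groups if g[0] < 0]
    pos = [g for g in groups if g[0] > 0]
    best: dict[tuple, SaltBridge] = {}
    for sp, chp, seqp, resnp, idxp in pos:
        for sn, chn, seqn, resnn, idxn in neg:
            if (chp, seqp) == (chn, seqn):
                continue
            d = cdist(model.coords[idxp], model.coords[idxn])
            k = np.unravel_index(np.argmin(d), d.shape)
            dmin = float(d[k])
            if dmin > cutoff:
                continue
            ap = idxp[k[0]]
            an = idxn[k[1]]
            bridge = SaltBridge(
                partner_a=(chp, seqp, resnp, str(model.name[ap])),
                partner_b=(chn, seqn, resnn, str(model.name[an])),
                distance=dmin,
                inter_subunit=model.subunit[ap] != model.subunit[an],
            )
            key = frozenset(((chp, seqp), (chn, seqn)))
            if key not in best or dmin < best[key].distance:
                best[key] = bridge
    return sorted(best.values(),
                  key=lambda b: (b.partner_a[:2], b.partner_b[:2]))


def diff_salt_bridges(present_in: Iterable[SaltBridge],
                      absent_in: Iterable[SaltBridge]) -> list[SaltBridge]:
    """Residue-pair set difference: bridges of the first list whose residue
    pair does not occur in the second list."""
    absent_keys = {b.residue_pair() for b in absent_in}
    return [b for b in present_in if b.residue_pair() not in absent_keys]


#: The four T-state-specific salt-bridge types released on the T->R
#: transition: Val(alpha)1-Arg(alpha)141 and Asp(alpha)126-Arg(alpha)141
#: across the two alpha subunits, Lys(alpha)40-His(beta)146 across the
#: alpha1/beta2 (and alpha2/beta1) interface, and the subunit-internal
#: Asp(beta)94-His(beta)146.  Partners are given as
#: (subunit kind, residue_seq, partner subunit kind, residue_seq, intra?).
T_STATE_BRIDGE_TYPES = (
    ("alpha", 1, "alpha*", 141, False),   # Val1 N-term -- Arg141 C-term
    ("alpha", 126, "alpha*", 141, False),  # Asp126 -- Arg141
    ("alpha", 40, "beta*", 146, False),    # Lys40 -- His146
    ("beta", 94, "beta", 146, True),       # Asp94 -- His146 (intra)
)

_SYMMETRY_COPIES = {
    "alpha": ("alpha1", "alpha2"),
    "beta": ("beta1", "beta2"),
}
_PARTNER_OF = {"alpha1": "alpha2", "alpha2": "alpha1",
               "beta1": "beta2", "beta2": "beta1"}
# the alpha(i) Lys40 pocket holds His146 of the beta subunit of the *other*
# dimer (alpha1-beta2, alpha2-beta1)
_CROSS_DIMER = {"alpha1": "beta2", "alpha2": "beta1"}


def expand_symmetric_bridges(bridge_types=T_STATE_BRIDGE_TYPES
                             ) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Expand per-type salt bridges over the two symmetric copies of the
    tetramer, yielding concrete (subunit, residue) pairs.

    A type involving two different subunit kinds (or the starred form of
    the same kind) crosses to the symmetry mate; an intra flag keeps both
    partners in the same subunit.  The four T-specific types expand to 8
    restrained pairs.
    """
    pairs = set()
    for kind_a, seq_a, kind_b, seq_b, intra in bridge_types:
        for sub_a in _SYMMETRY_COPIES[kind_a]:
            if intra:
                sub_b = sub_a if kind_b == kind_a else _PARTNER_OF[sub_a]
            elif kind_b.endswith("*"):
                base = kind_b.rstrip("*")
                if base == kind_a:
                    sub_b = _PARTNER_OF[sub_a]
                else:
                    sub_b = _CROSS_DIMER[sub_a]
            else:
                sub_b = sub_a
            pair = frozenset(((sub_a, seq_a), (sub_b, seq_b)))
            pairs.add(tuple(sorted(pair)))
    return sorted(pairs)
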