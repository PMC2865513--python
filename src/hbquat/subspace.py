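"""Reaction coordinates for the quaternary and tertiary transitions.

The quaternary state of the tetramer is located in the plane spanned by
the two principal components of the T, R and R2 crystal structures (the
"X-ray eigenvectors", computed from the C-alpha and heme atoms).  Scalar
reaction coordinates are obtained by projecting conformations onto
normalized difference vectors between two endpoint structures: the
quaternary coordinate connects the T and R tetramers, the tertiary
coordinate of each subunit connects its t and r conformations after a
subunit-internal superposition.  Coordinates are normalized so that the
endpoints map to +1 (T/t) and -1 (R/r); values beyond +-1 are legitimate
and do occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .structure_io import (
    SUBUNITS,
    HEME_OF_SUBUNIT,
    SelectionSpec,
    TetramerModel,
    common_selection,
    kabsch_superpose,
    select_atoms,
)

__all__ = [
    "PCBasis",
    "DifferenceVector",
    "ProjectionSeries",
    "StateAssignment",
    "PopulationHistogram",
    "build_xray_pca",
    "project_frames",
    "build_difference_vector",
    "normalized_projection",
    "project_series",
    "assign_quaternary_state",
    "tertiary_population",
]


@dataclass
class ProjectionSeries:
    """A scalar coordinate along a trajectory.

    ``kind`` records the scale: ``"normalized"`` (dimensionless, endpoints
    at +-1), ``"nm"`` (raw projections or RMSD-like distances) or
    ``"degrees"`` (rotation angles).
    """

    frame_times: np.ndarray  # (n,) ns
    values: np.ndarray  # (n,)
    coordinate_id: str
    kind: str = "nm"

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_times.shape != self.values.shape:
            raise ValueError("frame_times and values lengths differ")

    def __len__(self) -> int:
        return len(self.values)

    def truncated(self, n_keep: int) -> "ProjectionSeries":
        return replace(self, frame_times=self.frame_times[:n_keep],
                       values=self.values[:n_keep])


@dataclass
class PCBasis:
    """PCA subspace of a set of reference crystal structures.

    ``mean_coords`` and the eigenvectors live on the atoms identified by
    ``atom_keys`` (the common ``calpha_heme`` atoms of the references,
    keyed by chain/residue/atom name).  With three references exactly two
    eigenvalues are nonzero and the eigenvectors span the R-R2-T plane.
    """

    mean_coords: np.ndarray  # (N, 3) nm
    eigenvectors: np.ndarray  # (k, N, 3), rows orthonormal over 3N
    eigenvalues: np.ndarray  # (k,) nm^2, decreasing
    atom_keys: list
    selection: SelectionSpec
    reference_labels: list[str] = field(default_factory=list)
    reference_projections: np.ndarray | None = None  # (n_ref, k)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class DifferenceVector:
    """Normalized difference-vector reaction coordinate.

    ``direction`` is the unit 3N-vector from the minus endpoint (R/r,
    projection -1) to the plus endpoint (T/t, projection +1), computed
    after superposing the plus endpoint onto the minus endpoint over the
    coordinate's own selection.  ``half_span`` is half the coordinate-space
    distance between the endpoints, so raw projections divide by it to
    give the normalized coordinate; the midpoint of the endpoints defines
    zero, making the endpoints exactly symmetric about 0.
    """

    direction: np.ndarray  # (N, 3), unit norm over 3N
    half_span: float  # nm
    midpoint: np.ndarray  # (N, 3) nm, projection origin
    fit_coords: np.ndarray  # (N, 3) nm; frames are superposed onto these
    atom_keys: list
    endpoint_plus: str
    endpoint_minus: str
    scope: str  # "quaternary" | "tertiary:<subunit>"
    selection: SelectionSpec = field(
        default_factory=lambda: SelectionSpec("calpha_heme"))


@dataclass
class StateAssignment:
    """Per-frame quaternary state labels R / T / unassigned."""

    frame_times: np.ndarray
    state: np.ndarray  # (n,) of {"R", "T", "unassigned"}


@dataclass
class PopulationHistogram:
    """Unit-area histogram of a tertiary coordinate within one quaternary
    state class.  ``n_frames == 0`` flags an empty class."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_frames: int

    @property
    def empty(self) -> bool:
        return self.n_frames == 0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _keys_for(model: TetramerModel, idx: np.ndarray) -> list:
    return [(model.chain_id[i], int(model.residue_seq[i]), model.name[i])
            for i in idx]


def _match_keys(model: TetramerModel, spec: SelectionSpec,
                keys: Sequence) -> np.ndarray:
    """Indices in ``model`` of the given atom keys (all must be present)."""
    _, idx = select_atoms(model, spec)
    lookup = {k: i for k, i in zip(_keys_for(model, idx), idx)}
    try:
        return np.array([lookup[k] for k in keys], dtype=int)
    except KeyError as err:
        raise ValueError(
            f"frame lacks atom {err.args[0]} required by the basis/vector"
        ) from None


def _superpose_onto(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    return kabsch_superpose(coords, target).apply(coords)


# ---------------------------------------------------------------------------
# PCA subspace
# ---------------------------------------------------------------------------

def build_xray_pca(references: Sequence[TetramerModel],
                   spec: SelectionSpec | None = None,
                   labels: Sequence[str] | None = None,
                   max_iter: int = 50,
                   tol: float = 1e-12) -> PCBasis:
    """Principal components of a set of reference crystal structures.

    The references are iteratively superposed onto their running mean
    until the fit reaches its fixed point (each structure optimally
    aligned to the mean of the aligned set), the positional covariance
    over the common selected atoms is diagonalized, and the eigenvectors
    are returned sorted by decreasing eigenvalue.  ``k`` structures give
    at most ``k - 1`` nonzero eigenvalues.  The sign of each eigenvector
    is fixed so that the first reference (by convention the T structure)
    has a non-negative projection.
    """
    if len(references) < 2:
        raise ValueError("need at least 2 reference structures for a PCA")
    spec = spec or SelectionSpec("calpha_heme")
    labels = list(labels) if labels is not None else [
        f"ref{i}" for i in range(len(references))]

    # common atoms across all references, keyed on the first
    ref0 = references[0]
    _, idx0 = select_atoms(ref0, spec)
    keys = _keys_for(ref0, idx0)
    for other in references[1:]:
        ia, _ = common_selection(ref0, other, spec)
        other_keys = set(_keys_for(ref0, ia))
        keys = [k for k in keys if k in other_keys]
    coords = np.array([m.coords[_match_keys(m, spec, keys)]
                       for m in references])

    # iterative fit to the running mean, run to its fixed point so that
    # stored reference coordinates and later re-alignments onto the mean
    # agree to numerical precision
    mean = coords[0]
    for _ in range(max_iter):
        new = np.array([_superpose_onto(c, mean) for c in coords])
        mean = new.mean(axis=0)
        shift = float(np.max(np.abs(new - coords)))
        coords = new
        if shift < tol:
            break

    n_ref, n_atoms, _ = coords.shape
    centered = (coords - mean).reshape(n_ref, n_atoms * 3)
    # SVD of the configuration matrix == eigendecomposition of the 3N x 3N
    # covariance (divisor n_ref)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / n_ref
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = vt[order]

    ref_proj = centered @ eigenvectors.T  # (n_ref, k)
    anchor = labels.index("T") if "T" in labels else 0
    for j in range(len(eigenvalues)):
        if ref_proj[anchor, j] < 0:
            eigenvectors[j] *= -1
            ref_proj[:, j] *= -1

    return PCBasis(
        mean_coords=mean,
        eigenvectors=eigenvectors.reshape(-1, n_atoms, 3),
        eigenvalues=eigenvalues,
        atom_keys=keys,
        selection=spec,
        reference_labels=labels,
        reference_projections=ref_proj,
    )


def project_frames(frames: Sequence[TetramerModel],
                   basis: PCBasis,
                   n_components: int = 2
                   ) -> tuple[ProjectionSeries, ...]:
    """Project trajectory frames onto the leading X-ray eigenvectors.

    Each frame is superposed onto the basis mean over the whole basis
    selection before taking the dot product with the eigenvectors, so the
    projection is invariant under rigid transformations of the frame.
    Returns one nm-valued :class:`ProjectionSeries` per component.
    """
    n_components = min(n_components, basis.n_components)
    times = np.array([f.frame_time for f in frames])
    values = np.empty((len(frames), n_components))
    evecs = basis.eigenvectors[:n_components].reshape(n_components, -1)
    for i, frame in enumerate(frames):
        idx = _match_keys(frame, basis.selection, basis.atom_keys)
        fitted = _superpose_onto(frame.coords[idx], basis.mean_coords)
        values[i] = evecs @ (fitted - basis.mean_coords).ravel()
    return tuple(
        ProjectionSeries(frame_times=times, values=values[:, j],
                         coordinate_id=f"pc{j + 1}", kind="nm")
        for j in range(n_components)
    )


# ---------------------------------------------------------------------------
# difference-vector coordinates
# ---------------------------------------------------------------------------

def _scope_selection(scope: str, subunit: str | None,
                     spec: SelectionSpec | None) -> tuple[str, SelectionSpec]:
    if scope == "quaternary":
        sel = spec or SelectionSpec("calpha_heme")
        return "quaternary", sel
    if scope == "tertiary":
        if subunit not in SUBUNITS:
            raise ValueError(
                f"tertiary scope needs a subunit in {SUBUNITS}, "
                f"got {subunit!r}")
        mode = spec.mode if spec else "calpha_heme"
        include = spec.include_hemes if spec else True
        sel = SelectionSpec(mode=mode, subunits=(subunit,),
                            include_hemes=include)
        return f"tertiary:{subunit}", sel
    raise ValueError(f"unknown scope {scope!r}")


def build_difference_vector(endpoint_plus: TetramerModel,
                            endpoint_minus: TetramerModel,
                            scope: str = "quaternary",
                            subunit: str | None = None,
                            spec: SelectionSpec | None = None,
                            labels: tuple[str, str] = ("T", "R")
                            ) -> DifferenceVector:
    """Reaction coordinate from the displacement between two endpoints.

    For the quaternary coordinate the whole calpha_heme selection is used;
    a tertiary coordinate restricts the selection to one subunit (plus its
    heme) and superposes on that subunit only.  The plus endpoint is
    superposed onto the minus endpoint, whose coordinates define the fit
    frame for all later projections.
    """
    scope_id, sel = _scope_selection(scope, subunit, spec)
    ip, im = common_selection(endpoint_plus, endpoint_minus, sel)
    keys = _keys_for(endpoint_plus, ip)
    minus = endpoint_minus.coords[im]
    plus = _superpose_onto(endpoint_plus.coords[ip], minus)
    diff = plus - minus
    span = float(np.linalg.norm(diff))
    if span < 1e-12:
        raise ValueError(
            "endpoints are identical: difference vector has zero length")
    return DifferenceVector(
        direction=diff / span,
        half_span=span / 2.0,
        midpoint=(plus + minus) / 2.0,
        fit_coords=minus,
        atom_keys=keys,
        endpoint_plus=labels[0],
        endpoint_minus=labels[1],
        scope=scope_id,
        selection=sel,
    )


def normalized_projection(frame: TetramerModel,
                          dv: DifferenceVector) -> float:
    """Projection of a frame onto a difference vector, normalized so that
    the defining endpoints map exactly to +1 and -1.  Values beyond +-1
    indicate conformations beyond the crystal-structure endpoints."""
    idx = _match_keys(frame, dv.selection, dv.atom_keys)
    fitted = _superpose_onto(frame.coords[idx], dv.fit_coords)
    raw = float(np.sum((fitted - dv.midpoint) * dv.direction))
    return raw / dv.half_span


def project_series(frames: Sequence[TetramerModel],
                   dv: DifferenceVector,
                   coordinate_id: str | None = None) -> ProjectionSeries:
    """Normalized difference-vector projection along a trajectory."""
    times = np.array([f.frame_time for f in frames])
    values = np.array([normalized_projection(f, dv) for f in frames])
    return ProjectionSeries(
        frame_times=times, values=values,
        coordinate_id=coordinate_id or dv.scope, kind="normalized")


# ---------------------------------------------------------------------------
# state assignment and populations
# ---------------------------------------------------------------------------

def assign_quaternary_state(series: ProjectionSeries,
                            threshold: float = 0.5) -> StateAssignment:
    """Assign frames to the R or T quaternary state.

    A frame is R if its normalized quaternary projection is < -threshold
    and T if > +threshold (strict inequalities: boundary values remain
    unassigned), following the +-0.5 convention.
    """
    if series.kind != "normalized":
        raise ValueError(
            "state assignment requires a normalized projection series")
    state = np.full(len(series), "unassigned", dtype="U10")
    state[series.values < -threshold] = "R"
    state[series.values > threshold] = "T"
    return StateAssignment(frame_times=series.frame_times.copy(),
                           state=state)


def tertiary_population(series_tert: Mapping[str, ProjectionSeries],
                        states: StateAssignment,
                        bins: int = 40,
                        value_range: tuple[float, float] = (-2.0, 2.0)
                        ) -> dict[tuple[str, str], PopulationHistogram]:
    """Tertiary-coordinate distributions conditioned on quaternary state.

    Returns a unit-area histogram per (subunit, quaternary state R/T);
    unassigned frames are excluded.  An empty state class yields a
    zero-density histogram flagged via ``n_frames == 0``.
    """
    out: dict[tuple[str, str], PopulationHistogram] = {}
    for subunit, series in series_tert.items():
        if len(series) != len(states.state):
            raise ValueError("series and state assignment lengths differ")
        if not np.array_equal(series.frame_times, states.frame_times):
            raise ValueError("series and state assignment times differ")
        for q in ("R", "T"):
            vals = series.values[states.state == q]
            counts, edges = np.histogram(vals, bins=bins, range=value_range)
            if len(vals) == 0:
                density = np.zeros(bins)
            else:
                density = counts / (len(vals) * np.diff(edges))
            out[(subunit, q)] = PopulationHistogram(
                bin_edges=edges, density=density, n_frames=len(vals))
    return out
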