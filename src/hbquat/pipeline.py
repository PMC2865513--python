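"""End-to-end orchestration: references + trajectory -> analysis report.

Composes the full analysis chain — X-ray PCA projections, rotRMSD,
rigid-body rotation angles, normalized quaternary/tertiary coordinates,
state assignment, conditional tertiary populations, transition
classification, closest-approach truncation, and the mutual-information
matrix — and writes every table as TSV with a ``#``-prefixed metadata
header (config hash and seed), so a rerun with the same configuration
and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mutualinfo as mi
from . import rigidbody as rb
from . import structure_io as sio
from . import subspace as sub

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "classify_transition",
    "run_analysis",
    "write_tsv",
    "xray_anchor_report",
]

_TERT_IDS = {"alpha1": "tert_alpha1", "beta1": "tert_beta1",
             "alpha2": "tert_alpha2", "beta2": "tert_beta2"}


@dataclass
class AnalysisConfig:
    """Flat configuration of one analysis run.

    ``references`` maps state labels (at least ``T`` and ``R``; optionally
    ``R2`` etc.) to PDB paths.  Thresholds default to the published
    conventions: quaternary state assignment at +-0.5, full-transition
    rotRMSD cutoff 0.3 nm.
    """

    references: dict[str, str]
    trajectories: list[str]
    output_dir: str = "hbquat_out"
    chain_map: dict[str, str] = field(
        default_factory=lambda: dict(sio.DEFAULT_CHAIN_MAP))
    quat_threshold: float = 0.5
    rotrmsd_cutoff: float = 0.3  # nm
    population_bins: int = 40
    population_range: tuple[float, float] = (-2.0, 2.0)
    mi_bins: int = 10
    mi_fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125)
    mi_replicates: int = 10
    truncate_at_closest_approach: bool = True
    dt_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quat_threshold <= 0 or self.rotrmsd_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        if "T" not in self.references or "R" not in self.references:
            raise ValueError("references must include 'T' and 'R'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Parse a flat key=value config file.

        Recognized keys: ``ref.<LABEL>``, ``trajectory`` (repeatable,
        comma-separated), ``chain_map`` (``A:alpha1,...``), and any scalar
        field name such as ``quat_threshold`` or ``seed``.
        """
        refs: dict[str, str] = {}
        trajs: list[str] = []
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("ref."):
                refs[key[4:]] = value
            elif key == "trajectory":
                trajs.extend(v.strip() for v in value.split(",") if v.strip())
            elif key == "chain_map":
                kwargs["chain_map"] = dict(
                    item.split(":") for item in value.split(","))
            elif key == "mi_fractions":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key == "population_range":
                lo, hi = value.split(",")
                kwargs[key] = (float(lo), float(hi))
            elif key in ("population_bins", "mi_bins", "mi_replicates",
                         "seed"):
                kwargs[key] = int(value)
            elif key in ("quat_threshold", "rotrmsd_cutoff", "dt_ns"):
                kwargs[key] = float(value)
            elif key == "truncate_at_closest_approach":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key == "output_dir":
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(references=refs, trajectories=trajs, **kwargs)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in self.__dict__.items()
                   if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """All per-trajectory results of one analysis run."""

    tables: dict[str, pd.DataFrame]  # per-trajectory frame tables
    populations: dict  # (subunit, state) -> PopulationHistogram
    mi_quaternary: dict  # (id, id) -> MIEstimate
    mi_subunits: dict
    transition: dict[str, str]  # trajectory name -> full|partial|none
    config_digest: str = ""


def classify_transition(rotrmsd_to_R: sub.ProjectionSeries,
                        cutoff: float = 0.3) -> str:
    """Classify a trajectory by its closest rotRMSD approach to R.

    ``full`` if the series dips below ``cutoff`` (nm); ``partial`` if it
    at least halves its initial value without reaching the cutoff;
    ``none`` otherwise.  (The halving rule for partial transitions is a
    package convention.)
    """
    if len(rotrmsd_to_R) == 0:
        raise ValueError("empty rotRMSD series")
    lowest = float(np.min(rotrmsd_to_R.values))
    if lowest < cutoff:
        return "full"
    if lowest < rotrmsd_to_R.values[0] / 2.0:
        return "partial"
    return "none"


def write_tsv(frame_table: pd.DataFrame, path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    """Write a TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame_table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_analysis(config: AnalysisConfig,
                 references: Mapping[str, sio.TetramerModel] | None = None,
                 trajectories: Mapping[str, Sequence[sio.TetramerModel]]
                 | None = None,
                 write_outputs: bool = True) -> AnalysisReport:
    """Execute the full analysis described by ``config``.

    References and trajectories are read from the configured PDB paths
    unless already-loaded models are passed in (the synthetic generator
    produces models directly).  Each processing stage aborts with a
    stage-named error message on failure.
    """
    header = [f"hbquat config={config.digest()} seed={config.seed}"]

    with _stage("read references"):
        if references is None:
            references = {
                label: sio.read_pdb(path, model_index=1,
                                    chain_map=config.chain_map)
                for label, path in config.references.items()
            }
        ref_t, ref_r = references["T"], references["R"]

    with _stage("read trajectories"):
        if trajectories is None:
            trajectories = {
                Path(p).stem: sio.read_pdb(p, model_index="all",
                                           chain_map=config.chain_map,
                                           dt_ns=config.dt_ns)
                for p in config.trajectories
            }

    with _stage("X-ray PCA"):
        labels = list(references)
        basis = sub.build_xray_pca([references[k] for k in labels],
                                   labels=labels)

    with _stage("difference vectors"):
        dv_quat = sub.build_difference_vector(ref_t, ref_r, "quaternary")
        dv_tert = {
            s: sub.build_difference_vector(ref_t, ref_r, "tertiary",
                                           subunit=s, labels=("t", "r"))
            for s in sio.SUBUNITS
        }

    tables: dict[str, pd.DataFrame] = {}
    mi_inputs: list[dict[str, sub.ProjectionSeries]] = []
    transition: dict[str, str] = {}
    populations_all: dict = {}
    pop_counts: dict = {}

    for name, frames in trajectories.items():
        with _stage(f"project trajectory '{name}'"):
            pcs = sub.project_frames(frames, basis)
            quat = sub.project_series(frames, dv_quat, "quat")
            terts = {s: sub.project_series(frames, dv_tert[s], _TERT_IDS[s])
                     for s in sio.SUBUNITS}

        with _stage(f"rotRMSD/rigid-body '{name}'"):
            times = np.array([f.frame_time for f in frames])
            rot_to_r = sub.ProjectionSeries(
                times, [sio.rot_rmsd(f, ref_r) for f in frames],
                "rotrmsd_to_R", kind="nm")
            axis_angle = rb.rotation_timeseries(frames, ref_t)
            dimer_angle = sub.ProjectionSeries(
                times,
                [rb.dimer_rotation_angle(f, ref_t).angle for f in frames],
                "dimer_angle", kind="degrees")

        with _stage(f"states/populations '{name}'"):
            states = sub.assign_quaternary_state(
                quat, threshold=config.quat_threshold)
            pops = sub.tertiary_population(
                terts, states, bins=config.population_bins,
                value_range=config.population_range)
            for key, hist in pops.items():
                # pool across trajectories by frame-count weighting
                if key not in populations_all:
                    populations_all[key] = hist
                    pop_counts[key] = hist.n_frames
                else:
                    prev = populations_all[key]
                    tot = pop_counts[key] + hist.n_frames
                    if tot > 0:
                        dens = (prev.density * pop_counts[key]
                                + hist.density * hist.n_frames) / tot
                    else:
                        dens = prev.density
                    populations_all[key] = sub.PopulationHistogram(
                        prev.bin_edges, dens, tot)
                    pop_counts[key] = tot
            transition[name] = classify_transition(
                rot_to_r, cutoff=config.rotrmsd_cutoff)

        with _stage(f"MI truncation '{name}'"):
            coords = {"quat": quat, **{_TERT_IDS[s]: terts[s]
                                       for s in sio.SUBUNITS}}
            if config.truncate_at_closest_approach:
                coords = {k: mi.truncate_at_closest_approach(v, rot_to_r)
                          for k, v in coords.items()}
            mi_inputs.append(coords)

        table = pd.DataFrame({
            "frame_time_ns": times,
            "pc1_nm": pcs[0].values,
            "pc2_nm": pcs[1].values if len(pcs) > 1 else np.nan,
            "quat": quat.values,
            **{_TERT_IDS[s]: terts[s].values for s in sio.SUBUNITS},
            "rotrmsd_to_R_nm": rot_to_r.values,
            "axis_angle_deg": axis_angle.values,
            "dimer_angle_deg": dimer_angle.values,
            "state": states.state,
        })
        tables[name] = table

    with _stage("mutual information"):
        spec = mi.BinningSpec(bins_x=config.mi_bins, bins_y=config.mi_bins)
        tert_ids = [_TERT_IDS[s] for s in sio.SUBUNITS]
        quat_pairs = [("quat", t) for t in tert_ids]
        sub_pairs = [(a, b) for i, a in enumerate(tert_ids)
                     for b in tert_ids[i + 1:]]
        mi_quat = mi.mi_matrix(mi_inputs, quat_pairs, spec,
                               config.mi_fractions, config.mi_replicates,
                               seed=config.seed)
        mi_sub = mi.mi_matrix(mi_inputs, sub_pairs, spec,
                              config.mi_fractions, config.mi_replicates,
                              seed=config.seed + 1)

    report = AnalysisReport(tables=tables, populations=populations_all,
                            mi_quaternary=mi_quat, mi_subunits=mi_sub,
                            transition=transition,
                            config_digest=config.digest())

    if write_outputs:
        with _stage("write outputs"):
            out = Path(config.output_dir)
            for name, table in tables.items():
                write_tsv(table, out / f"{name}_series.tsv", header)
            pop_rows = []
            for (subunit, state), hist in populations_all.items():
                for b in range(len(hist.density)):
                    pop_rows.append((subunit, state, hist.bin_edges[b],
                                     hist.bin_edges[b + 1], hist.density[b]))
            write_tsv(pd.DataFrame(
                pop_rows, columns=["subunit", "state", "bin_left",
                                   "bin_right", "density"]),
                out / "populations.tsv", header)
            mi_rows = [(a, b, est.value)
                       for (a, b), est in {**mi_quat, **mi_sub}.items()]
            write_tsv(pd.DataFrame(mi_rows, columns=["x", "y", "mi_nats"]),
                      out / "mi.tsv", header)
            write_tsv(pd.DataFrame(
                sorted(transition.items()),
                columns=["trajectory", "transition"]),
                out / "transitions.tsv", header)

    return report


# ---------------------------------------------------------------------------
# crystal-structure anchor quantities
# ---------------------------------------------------------------------------

def xray_anchor_report(paths: Mapping[str, str | Path],
                       chain_map: Mapping[str, str] | None = None) -> dict:
    """Benchmark quantities from the real Hb crystal structures.

    ``paths`` maps state labels to PDB files; recognized labels are
    ``T`` (2HHB), ``R`` (1IRD), ``R2`` (1BBB) and ``R3`` (1YZI).  Computes
    whichever of the following the supplied structures allow: the
    R-vs-T rotRMSD and standard fitted backbone RMSD, the tertiary
    difference-vector half-spans of the alpha and beta subunits, the full
    dimer rotation angle, and beta-beta center-of-mass distances of the
    liganded forms relative to R.
    """
    models = {label: sio.read_pdb(p, model_index=1, chain_map=chain_map)
              for label, p in paths.items()}
    out: dict[str, float] = {}

    def beta_beta(m):
        return float(np.linalg.norm(sio.center_of_mass(m, "beta1")
                                    - sio.center_of_mass(m, "beta2")))

    if "T" in models and "R" in models:
        t, r = models["T"], models["R"]
        out["rotrmsd_R_vs_T_nm"] = sio.rot_rmsd(r, t)
        spec = sio.SelectionSpec("backbone", include_hemes=False)
        ia, ib = sio.common_selection(r, t, spec)
        out["backbone_rmsd_R_vs_T_nm"] = sio.rmsd(
            r.coords[ia], t.coords[ib], fit=True)
        out["dimer_rotation_R_vs_T_deg"] = rb.dimer_rotation_angle(
            r, t).angle
        for sub_kind, subunit in (("alpha", "alpha1"), ("beta", "beta1")):
            dv = sub.build_difference_vector(t, r, "tertiary",
                                             subunit=subunit,
                                             labels=("t", "r"))
            out[f"tertiary_half_span_{sub_kind}_nm"] = dv.half_span
    if "R" in models:
        out["beta_beta_com_R_nm"] = beta_beta(models["R"])
        if "R2" in models:
            out["beta_beta_com_R2_minus_R_A"] = 10.0 * (
                beta_beta(models["R2"]) - beta_beta(models["R"]))
        if "R3" in models:
            out["beta_beta_com_R_minus_R3_A"] = 10.0 * (
                beta_beta(models["R"]) - beta_beta(models["R3"]))
    return out
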