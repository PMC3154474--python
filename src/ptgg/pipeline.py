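"""End-to-end analysis orchestration with config, manifest and seeds.

``run_analyze`` drives the per-ensemble workflow (read -> topology ->
helical parameters -> equilibration trim -> hydrogen-bond classification
-> frequency table -> class-conditional histograms); ``run_compare``
produces heat-map matrices between labelled ensembles.  Every emitted
file is tab-separated text and is listed, with its SHA-256 checksum, in
the run report, so reruns of one config are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from . import __version__
from .compare import (ReferenceValue, SampleVector, class_histograms,
                      comparison_matrix, trim_equilibration)
from .errors import PtggError
from .hbonds import HBondCriteria, classify_frames, frequency_table
from .helix_params import ParamTable, compute_param_table, default_designation
from .structure_io import read_pdb_ensemble
from .superpose import family_rmsd

DEFAULT_HISTOGRAM_PARAMETERS = ("step_6_7_roll", "step_7_8_shift",
                                "pair_8_17_opening", "pair_7_18_propeller")


@dataclasses.dataclass
class RunConfig:
    """Declarative description of one analysis or comparison run."""

    inputs: dict[str, str]  # label -> multi-model PDB path
    output_dir: str = "ptgg_out"
    platinated_residues: tuple[int, int] | None = (6, 7)
    max_distance: float = 3.5
    min_angle: float = 135.0
    designation: str = "central"  # central | all
    statistic: str = "z"
    alpha: float = 0.05
    burn_in: float = 0.0
    histogram_parameters: tuple[str, ...] = DEFAULT_HISTOGRAM_PARAMETERS
    reference_values: dict[str, float] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def criteria(self) -> HBondCriteria:
        return HBondCriteria(self.max_distance, self.min_angle)

    def validate(self) -> None:
        if not self.inputs:
            raise PtggError("config lists no inputs")
        for label, path in self.inputs.items():
            if not Path(path).exists():
                raise PtggError(f"input {label!r}: {path} does not exist")
        if self.designation not in ("central", "all"):
            raise PtggError("designation must be 'central' or 'all'")
        if not (0 <= self.burn_in < 1):
            raise PtggError("burn_in must be a fraction in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "platinated_residues" in raw and raw["platinated_residues"] is not None:
            raw["platinated_residues"] = tuple(raw["platinated_residues"])
        if "histogram_parameters" in raw:
            raw["histogram_parameters"] = tuple(raw["histogram_parameters"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out["platinated_residues"] is not None:
            out["platinated_residues"] = list(out["platinated_residues"])
        out["histogram_parameters"] = list(out["histogram_parameters"])
        return out


@dataclasses.dataclass
class RunReport:
    """Provenance echo plus a checksummed manifest of emitted files."""

    config: dict
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    warnings: list[str] = dataclasses.field(default_factory=list)
    stages: list[dict] = dataclasses.field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Emitter:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, str] = {}

    def emit(self, name: str, writer) -> Path:
        path = self.out_dir / name
        writer(path)
        self.manifest[name] = _sha256(path)
        return path


def _designation_for(config: RunConfig, topology):
    if config.designation == "central":
        return default_designation(topology)
    n = topology.n_pairs
    return tuple(range(n)), tuple(range(n - 1))


def _load_table(config: RunConfig, label: str, stages: list[dict]) -> ParamTable:
    ensemble = read_pdb_ensemble(config.inputs[label], source_tag=label)
    from .structure_io import infer_duplex_topology
    topo = infer_duplex_topology(ensemble[0], config.platinated_residues)
    ensemble = ensemble.with_topology(topo)
    table = compute_param_table(ensemble, _designation_for(config, topo))
    stages.append({"stage": f"params:{label}", "frames_in": len(ensemble),
                   "frames_out": table.n_frames})
    if config.burn_in > 0:
        table = trim_equilibration(table, config.burn_in)
        stages.append({"stage": f"trim:{label}", "frames_in": len(ensemble),
                       "frames_out": table.n_frames})
    return table


def run_analyze(config: RunConfig) -> RunReport:
    """Per-ensemble pipeline: parameters, classes, frequencies, histograms."""
    config.validate()
    out = _Emitter(Path(config.output_dir))
    report = RunReport(config.to_dict(), __version__, out.manifest)
    criteria = config.criteria()
    for label, path in config.inputs.items():
        ensemble = read_pdb_ensemble(path, source_tag=label)
        from .structure_io import infer_duplex_topology
        topo = infer_duplex_topology(ensemble[0], config.platinated_residues)
        report.warnings.extend(topo.warnings)
        ensemble = ensemble.with_topology(topo)
        table = compute_param_table(ensemble, _designation_for(config, topo))
        report.stages.append({"stage": f"params:{label}",
                              "frames_in": len(ensemble), "frames_out": table.n_frames})
        if config.burn_in > 0:
            table = trim_equilibration(table, config.burn_in)
            report.stages.append({"stage": f"trim:{label}",
                                  "frames_in": len(ensemble),
                                  "frames_out": table.n_frames})
        out.emit(f"params_{label}.tsv", table.to_tsv)

        classes = classify_frames(ensemble, criteria=criteria)
        kept = set(table.data["frame_index"].astype(int))
        classes.labels = [l for i, l in enumerate(classes.labels) if i in kept]
        out.emit(f"classes_{label}.tsv", classes.to_tsv)
        freq = frequency_table(classes, precision=1)
        out.emit(f"frequencies_{label}.tsv", freq.to_tsv)
        report.stages.append({"stage": f"classify:{label}",
                              "frames_in": table.n_frames,
                              "frames_out": classes.n_frames})

        for param in config.histogram_parameters:
            if param not in table.data.columns:
                report.warnings.append(
                    f"{label}: histogram parameter {param} not in designation; skipped")
                continue
            ref = None
            if param in config.reference_values:
                ref = ReferenceValue(param, config.reference_values[param],
                                     "external reference")
            hist = class_histograms(SampleVector(table.column(param), label, param),
                                    classes, reference=ref)
            out.emit(f"hist_{label}_{param}.tsv", hist.to_tsv)
    report.write(Path(config.output_dir) / "run_report.yaml")
    return report


def run_compare(config: RunConfig, comparisons: list[tuple[str, str]] | None = None
                ) -> RunReport:
    """Heat-map matrix between labelled ensembles (all pairs by default)."""
    config.validate()
    labels = list(config.inputs)
    if len(labels) < 2:
        raise PtggError("run_compare needs at least two labelled inputs")
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    out = _Emitter(Path(config.output_dir))
    report = RunReport(config.to_dict(), __version__, out.manifest)
    tables = {label: _load_table(config, label, report.stages) for label in labels}
    matrix = comparison_matrix(tables, comparisons, config.statistic, config.alpha)
    out.emit(f"matrix_{config.statistic}.tsv", matrix.to_tsv)
    for label in labels:
        out.emit(f"params_{label}.tsv", tables[label].to_tsv)
    report.write(Path(config.output_dir) / "run_report.yaml")
    return report


def superpose_report(path: str | Path, selection: str = "heavy") -> dict:
    """Family RMSD summary of a multi-model PDB (Table-2D-style numbers)."""
    from .structure_io import heavy_atom_selector, central_four_selector, \
        infer_duplex_topology
    ensemble = read_pdb_ensemble(path)
    selector = None
    tag = "all atoms"
    if selection == "heavy":
        selector, tag = heavy_atom_selector, "non-H atoms"
    elif selection == "central4":
        topo = infer_duplex_topology(ensemble[0])
        selector, tag = central_four_selector(topo), "central four base pairs"
    elif selection != "all":
        raise PtggError("selection must be all, heavy or central4")
    rep = family_rmsd(ensemble, selector, selection_tag=tag)
    return {"selection": tag, "mean_rmsd": rep.mean, "sd_rmsd": rep.sd,
            "per_model": rep.per_model.tolist()}
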