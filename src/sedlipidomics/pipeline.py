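"""End-to-end orchestration: simulate/ingest → network → annotate → quantify
→ compose, with persisted intermediates and a deterministic run report."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import composition
from .annotation import Rulebook, annotate_spectra, annotations_to_frame, default_rulebook
from .network import NetworkParams, build_network, export_graph
from .quantify import fit_standards_table, quantify
from .simulate import (
    INTERNAL_STD_ID,
    RF_PROXY_MAP,
    GeneratorConfig,
    simulate_dataset,
    write_bundle,
)
from .spectra import (
    read_feature_table,
    read_mgf,
    read_sample_metadata,
    sample_columns,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "run_output"
    seed: int = 42
    # either generate synthetically (default) or read these inputs
    mgf_path: str | None = None
    feature_table_path: str | None = None
    metadata_path: str | None = None
    standards_path: str | None = None
    rulebook_path: str | None = None
    generator: GeneratorConfig | None = None
    network: NetworkParams = field(default_factory=NetworkParams)
    internal_std: str = INTERNAL_STD_ID
    ppm_tol: float = 5.0
    presence_threshold: float = 0.0002
    other_lump_fraction: float = 0.01

    def validate(self) -> None:
        if not 0.0 <= self.network.cosine_threshold <= 1.0:
            raise ValueError("cosine_threshold must be in [0, 1]")
        external = [self.mgf_path, self.feature_table_path, self.metadata_path, self.standards_path]
        if any(external) and not all(external):
            raise ValueError("external inputs require mgf, feature table, metadata and standards paths")
        for p in external + [self.rulebook_path]:
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; persist intermediates; return the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "parameters": {
        "network": asdict(config.network) if isinstance(config.network, NetworkParams) else dict(config.network),
        "ppm_tol": config.ppm_tol,
        "presence_threshold": config.presence_threshold,
        "other_lump_fraction": config.other_lump_fraction,
    }}

    stage = "ingest"
    try:
        if config.mgf_path:
            spectra = read_mgf(config.mgf_path)
            metadata = read_sample_metadata(config.metadata_path)
            features = read_feature_table(config.feature_table_path, metadata)
            standards = pd.read_csv(config.standards_path)
            truth = None
        else:
            gen = config.generator or GeneratorConfig(seed=config.seed)
            bundle = simulate_dataset(gen)
            write_bundle(bundle, out / "synthetic")
            spectra, features, metadata, standards, truth = (
                bundle.spectra,
                bundle.feature_table,
                bundle.metadata,
                bundle.standards,
                bundle.truth,
            )
        report["n_features"] = int(len(features))
        report["n_spectra"] = int(len(spectra))

        stage = "network"
        net = build_network(spectra, config.network)
        export_graph(net, out / "network.graphml", "graphml")
        export_graph(net, out / "network_edges.tsv", "tsv")
        n_comp = len(set(net.component_of.values()))
        report["n_edges"] = len(net.edges)
        report["n_subnetworks"] = n_comp

        stage = "annotate"
        rulebook = Rulebook.from_yaml(config.rulebook_path) if config.rulebook_path else default_rulebook()
        annotations = annotate_spectra(spectra, rulebook, ppm_tol=config.ppm_tol)
        ann_frame = annotations_to_frame(annotations)
        ann_frame.to_csv(out / "annotations.csv", index=False)
        per_class = ann_frame.drop_duplicates("shorthand").groupby("lipid_class").size()
        per_sub = (
            ann_frame[ann_frame["lipid_class"] == "sphingolipid"]
            .drop_duplicates("shorthand")
            .groupby("subclass")
            .size()
        )
        report["annotated_features"] = int(len(ann_frame))
        report["species_per_class"] = {k: int(v) for k, v in per_class.items()}
        report["species_per_sphingo_subclass"] = {k: int(v) for k, v in per_sub.items()}

        stage = "quantify"
        rf_table = fit_standards_table(standards)
        calibrated = quantify(
            features, annotations, rf_table, config.internal_std, metadata, proxy_map=RF_PROXY_MAP
        )
        calibrated.to_csv(out / "calibrated.csv")

        stage = "compose"
        props = composition.class_proportions(calibrated, config.other_lump_fraction)
        props.to_csv(out / "class_proportions.csv")
        zones = metadata.set_index("sample_id")["zone"]
        zone_groups = {z: list(zones[zones == z].index) for z in zones.unique()}
        presence = composition.presence_matrix(calibrated, config.presence_threshold, groups=zone_groups)
        presence.to_csv(out / "presence_by_zone.csv")
        counts = composition.intersection_counts(presence)
        counts_frame = pd.DataFrame(
            [{"groups": "&".join(sorted(k)), "count": v} for k, v in sorted(counts.items(), key=lambda kv: "&".join(sorted(kv[0])))]
        )
        counts_frame.to_csv(out / "intersection_counts.csv", index=False)
        samples = [c for c in sample_columns(calibrated) if c != "rf_source"]
        zone_means = {}
        for z, members in zone_groups.items():
            cols = [c for c in members if c in samples]
            if cols:
                zone_means[z] = props[cols].mean(axis=1).round(6).to_dict()
        report["per_zone_class_proportions"] = zone_means
        report["intersection_counts"] = {
            "&".join(sorted(k)): int(v) for k, v in counts.items() if v > 0
        }
        if truth is not None:
            report["truth_species_total"] = len(truth.catalog)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d features, %d edges, %d subnetworks",
                report["n_features"], report["n_edges"], report["n_subnetworks"])
    return report
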