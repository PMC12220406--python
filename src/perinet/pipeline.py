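"""End-to-end pipeline: registry -> filter -> rates -> network -> detection
-> concordance -> association, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__, io
from .association import collapse_sparse_levels, fit_logistic, label_inter_region
from .community import DetectionParams, detect_communities
from .concordance import mismatch_table
from .network import build_network, inter_region_metrics, loc_flow
from .rates import county_rates, quantile_bins, rurality_summary
from .records import (
    CHARACTERISTIC_COVARIATES,
    characteristics_table,
    filter_network_transports,
    read_counties,
    read_deliveries,
    read_facilities,
    rurality_of_records,
)
from .synthetic import GeneratorConfig, generate_registry

logger = logging.getLogger(__name__)

#: Default inter-region model: ordered (covariate, reference) pairs.
DEFAULT_MODEL_SPEC: tuple[tuple[str, str], ...] = (
    ("race", "White"),
    ("wic", "No"),
    ("steroid_lung_maturation", "No"),
    ("delivery_method", "Cesarean"),
    ("payor", "Medicaid"),
    ("maternal_transfusion", "No"),
    ("nicu_abnormal", "No"),
    ("rurality", "rural"),
    ("origin_level", "I"),
    ("destination_level", "I"),
    ("same_system", "No"),
)

PRESETS = {
    "georgia-like": lambda seed: GeneratorConfig(seed=seed),
    "georgia-like-large": lambda seed: GeneratorConfig(seed=seed,
                                                       n_deliveries=200_000),
    "zero-transport": lambda seed: GeneratorConfig(
        seed=seed, transport_intercept=-40.0, n_deliveries=5_000
    ),
}


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Exactly one of ``preset`` or (``deliveries_path``, ``facilities_path``,
    ``counties_path``) must be set.
    """

    outdir: str | Path = "perinet-out"
    seed: int = 0
    preset: str | None = None
    deliveries_path: str | Path | None = None
    facilities_path: str | Path | None = None
    counties_path: str | Path | None = None
    region_adjacency_path: str | Path | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    model_spec: Sequence[tuple[str, str]] = DEFAULT_MODEL_SPEC
    generator: GeneratorConfig | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_paths = all(
            p is not None
            for p in (self.deliveries_path, self.facilities_path,
                      self.counties_path)
        )
        have_preset = self.preset is not None or self.generator is not None
        if have_paths == have_preset:
            raise ValueError(
                "set exactly one of input paths or a synthetic preset"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    if config.preset is not None or config.generator is not None:
        gen = config.generator
        if gen is None:
            if config.preset not in PRESETS:
                raise ValueError(
                    f"unknown preset {config.preset!r}; "
                    f"choose from {sorted(PRESETS)}"
                )
            gen = PRESETS[config.preset](config.seed)
        facilities, counties, deliveries, truth = generate_registry(gen)
        adjacency = gen.adjacency()
        return facilities, counties, deliveries, adjacency, truth, {}
    facilities = read_facilities(config.facilities_path)
    counties = read_counties(config.counties_path)
    deliveries = read_deliveries(config.deliveries_path)
    if config.region_adjacency_path is not None:
        adjacency = io.read_region_adjacency(config.region_adjacency_path)
    else:
        regions = sorted(set(facilities["dpr"]))
        adjacency = {r: [x for x in regions if x != r] for r in regions}
        logger.warning("no region adjacency supplied; assuming all regions "
                       "adjacent")
    hashes = {
        "deliveries": _sha256(Path(config.deliveries_path)),
        "facilities": _sha256(Path(config.facilities_path)),
        "counties": _sha256(Path(config.counties_path)),
    }
    return facilities, counties, deliveries, adjacency, None, hashes


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all module outputs.

    Returns the manifest (also written to ``manifest.json``): seed, input
    hashes, package version, and record counts at every stage.  Two runs
    with identical config produce identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    facilities, counties, deliveries, adjacency, truth, hashes = _load_inputs(
        config
    )
    if truth is not None:
        io.write_registry(outdir / "registry", facilities, counties,
                          deliveries, truth, adjacency)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "input_hashes": hashes,
        "stages": {},
    }

    # records + characteristics
    deliveries = deliveries.copy()
    deliveries["rurality"] = rurality_of_records(deliveries, counties)
    table1 = characteristics_table(deliveries, CHARACTERISTIC_COVARIATES)
    io.write_characteristics_table(outdir / "table1.csv", table1)

    retained, report = filter_network_transports(deliveries, facilities)
    manifest["stages"]["filter"] = {
        "n_input": report.n_input,
        "n_transported": report.n_transported,
        "n_dropped_missing_endpoint": report.n_dropped_missing_endpoint,
        "n_dropped_non_obstetric": report.n_dropped_non_obstetric,
        "n_retained": report.n_retained,
    }

    # county rates (all transported deliveries, pre-network filter)
    rate_table = county_rates(deliveries, counties)
    bins = quantile_bins(rate_table)
    io.write_county_rates(outdir / "county_rates.csv", rate_table, bins)
    summary = rurality_summary(rate_table)
    summary.to_csv(outdir / "rurality_summary.csv", index=False)
    manifest["stages"]["rates"] = {
        "n_unknown_county": rate_table.n_unknown_county,
        "total_county_transports": int(
            rate_table.table["resident_transports"].sum()
        ),
    }

    if report.n_retained == 0:
        logger.warning("no network-eligible transports; downstream network "
                       "stages skipped")
        manifest["stages"]["network"] = {"skipped": True}
        _write_manifest(outdir, manifest)
        return manifest

    network = build_network(retained, facilities)
    flow = loc_flow(network)
    inter = inter_region_metrics(network, adjacency, roster=facilities)
    io.write_edge_list(outdir / "edges.csv", network)
    io.write_inter_region_report(outdir / "inter_region_report.json", inter)
    flow.matrix.to_csv(outdir / "loc_flow.csv")
    manifest["stages"]["network"] = {
        "n_nodes": len(network),
        "n_routes": network.n_routes,
        "total_volume": network.total_volume,
        "upward_count": flow.upward_count,
        "upward_to_rpc_count": flow.upward_to_rpc_count,
        "intra_volume": inter.intra_volume,
        "inter_volume": inter.inter_volume,
        "pct_volume_cross": inter.pct_volume_cross,
    }

    partition = detect_communities(network, config.detection)
    io.write_communities(outdir / "communities.csv", partition, facilities)
    io.write_graphml(outdir / "network.graphml", network, partition)
    manifest["stages"]["detection"] = {
        "n_communities": partition.n_communities,
        "modularity": partition.modularity,
    }

    try:
        mm = mismatch_table(partition, facilities)
        io.write_mismatch(outdir / "mismatch_table.csv",
                          outdir / "concordance.json", mm)
        manifest["stages"]["concordance"] = {
            "chi2": mm.chi2, "df": mm.df, "p_value": mm.p_value
        }
    except ValueError as exc:  # e.g. single community or single region
        logger.warning("concordance stage skipped: %s", exc)
        manifest["stages"]["concordance"] = {"skipped": True,
                                             "reason": str(exc)}

    # association: inter-region outcome on network-retained transports
    labeled = label_inter_region(retained, facilities)
    manifest["stages"]["association"] = {
        "n_inter_region": int(labeled["inter_region"].sum()),
        "n_intra_region": int((~labeled["inter_region"]).sum()),
    }
    fac = facilities.set_index("facility_id")
    labeled["origin_level"] = labeled["origin_facility"].map(fac["level"])
    labeled["destination_level"] = labeled["destination_facility"].map(
        fac["level"]
    )
    labeled["same_system"] = labeled["same_system"].map(
        {True: "Yes", False: "No"}
    )
    for cov, ref in config.model_spec:
        if cov in labeled.columns:
            labeled = collapse_sparse_levels(labeled, cov, keep=(ref,))
    spec = [
        (cov, ref)
        for cov, ref in config.model_spec
        if cov in labeled.columns and labeled[cov].nunique() > 1
    ]
    try:
        fit = fit_logistic(labeled, spec, outcome="inter_region")
        io.write_model_fit(outdir / "model_fit.json", fit)
        manifest["stages"]["association"].update(
            converged=fit.converged, separation=fit.separation,
            n_terms=len(fit.terms),
        )
    except (ValueError, FloatingPointError) as exc:
        logger.warning("association model skipped: %s", exc)
        manifest["stages"]["association"]["skipped"] = str(exc)

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: Mapping) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
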