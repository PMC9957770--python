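"""End-to-end orchestration: targets -> simulate/extract -> score -> report.

A :class:`PipelineConfig` (YAML-serializable) fully determines a run;
re-running with the same config and seed reproduces every output file.
Each run writes a manifest with the package version, a config hash and
the seed, alongside the target panel, design, intensity, per-combination
result and screen-summary CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import call_hits, hit_table, records_from_intensities, summarize_screen
from .chem import ProbeSpec, build_target_panel, default_panel, load_compound_panel, targets_to_frame
from .dataset import MSIDataset
from .msi import extract_spot_intensities, grid_from_design, ion_image, optimize_spot_centers
from .profiles import TAR1_RATIOS, TAT1_RATIOS, PROTEINOGENIC_DONORS, SCREEN_DONORS_31, SCREEN_ACCEPTORS, truth_from_observed_ratios
from .report import render_report
from .simulate import NoiseModel, TruthProfile, ion_amounts, make_design, render

logger = logging.getLogger("oximsi")

_PROFILES = {
    "TAT1": (PROTEINOGENIC_DONORS, ["alpha-KG"], TAT1_RATIOS),
    "TAR1": (SCREEN_DONORS_31, SCREEN_ACCEPTORS, TAR1_RATIOS),
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a screen analysis."""

    enzyme: str = "enzyme"
    donors: list[str] = field(default_factory=list)
    acceptors: list[str] = field(default_factory=list)
    panel_file: str | None = None  # None -> bundled default panel
    profile: str | None = None  # "TAT1" | "TAR1" named demo profiles
    planted_ratios: dict = field(default_factory=dict)  # {"donor|acceptor": ratio}
    tag_mz_contribution: float = 793.2365
    mz_tolerance: float = 0.05
    replicates: int = 3
    donor_mM: float = 10.0
    acceptor_mM: float = 6.0
    spot_efficiency_cv: float = 0.10
    ion_noise_cv: float = 0.03
    baseline_level: float = 2.0
    mz_jitter_sd: float = 0.005
    center_jitter_px: float = 1.0
    seed: int = 0
    spot_radius_px: int = 2
    search_radius_px: int = 2
    statistic: str = "mean"
    ratio_threshold: float = 0.1
    sd_multiplier: float = 10.0
    outdir: str | None = None
    write_imzml: bool = False
    imzml_input: str | None = None  # extract mode: read instead of simulating
    design_input: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.profile is not None and self.profile not in _PROFILES:
            raise ConfigError(f"unknown profile {self.profile!r}; choose from {sorted(_PROFILES)}")
        if self.profile is None and (not self.donors or not self.acceptors):
            raise ConfigError("config needs donors and acceptors (or a named profile)")
        if self.panel_file is not None and not Path(self.panel_file).exists():
            raise ConfigError(f"panel file not found: {self.panel_file}")
        if self.imzml_input is not None and not Path(self.imzml_input).exists():
            raise ConfigError(f"imzML input not found: {self.imzml_input}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def _stage(name):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screen analysis and return the result bundle.

    Bundle keys: targets (DataFrame), design, truth, intensities,
    records, calls, hits (DataFrame), summary, report (str),
    manifest (dict).  When ``config.outdir`` is set, all tables plus the
    report and manifest are written there.
    """
    config.validate()
    t_start = time.perf_counter()

    t0 = _stage("targets")
    panel = load_compound_panel(config.panel_file) if config.panel_file else default_panel()
    if config.profile is not None:
        donors_names, acceptors_names, ratios = _PROFILES[config.profile]
        planted = dict(ratios)
    else:
        donors_names, acceptors_names = config.donors, config.acceptors
        planted = {
            tuple(k.split("|")): v for k, v in config.planted_ratios.items()
        }
    missing = [n for n in list(donors_names) + list(acceptors_names) if n not in panel]
    if missing:
        raise ConfigError(f"compounds absent from panel: {missing}")
    probe = ProbeSpec(tag_mz_contribution=config.tag_mz_contribution,
                      mz_tolerance=config.mz_tolerance)
    targets = build_target_panel(
        [panel[n] for n in donors_names], [panel[n] for n in acceptors_names], probe
    )
    logger.info("targets: %d channels (%.2fs)", len(targets), time.perf_counter() - t0)

    t0 = _stage("design")
    design = make_design(
        [config.enzyme], list(donors_names), list(acceptors_names),
        replicates=config.replicates,
    )

    truth = TruthProfile(donor_mM=config.donor_mM, acceptor_mM=config.acceptor_mM)
    for (donor, acceptor), r in planted.items():
        truth.conversion[(config.enzyme, donor, acceptor)] = truth.for_observed_ratio(r)
    amounts = ion_amounts(design, truth, targets)

    if config.imzml_input is not None:
        t0 = _stage("load imzML")
        dataset = MSIDataset.read_imzml(config.imzml_input)
        truth_table = None
    else:
        t0 = _stage("simulate")
        noise = NoiseModel(
            spot_efficiency_cv=config.spot_efficiency_cv,
            ion_noise_cv=config.ion_noise_cv,
            baseline_level=config.baseline_level,
            mz_jitter_sd=config.mz_jitter_sd,
            center_jitter_px=config.center_jitter_px,
            seed=config.seed,
        )
        dataset, truth_table = render(design, amounts, noise, targets)
        logger.info("simulated %dx%d px (%.2fs)", *dataset.shape, time.perf_counter() - t0)

    t0 = _stage("extract")
    grid = grid_from_design(design, config.search_radius_px, config.spot_radius_px)
    # register on the summed image over all channels so control spots
    # (which have no product signal) still anchor the grid
    total = ion_image(dataset, targets[0].conjugate_mz, config.mz_tolerance)
    for t in targets[1:]:
        total.values = total.values + ion_image(dataset, t.conjugate_mz, config.mz_tolerance).values
    grid = optimize_spot_centers(total, grid)
    intensities = extract_spot_intensities(
        dataset, grid, targets, tol=config.mz_tolerance, statistic=config.statistic
    )
    logger.info("extracted %d wells x %d targets (%.2fs)",
                len(grid.well_ids), len(targets), time.perf_counter() - t0)

    t0 = _stage("score")
    records = records_from_intensities(intensities, design, targets, amounts)
    calls = call_hits(records, ratio_threshold=config.ratio_threshold,
                      sd_multiplier=config.sd_multiplier)
    hits = hit_table(calls)
    summary = summarize_screen(calls)
    report = render_report(calls, summary, targets)
    logger.info("scored %d combinations (%.2fs)", len(calls), time.perf_counter() - t0)

    manifest = {
        "oximsi_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_targets": len(targets),
        "n_wells": len(design.wells),
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }

    bundle = {
        "targets": targets,
        "targets_table": targets_to_frame(targets),
        "design": design,
        "truth_table": truth_table,
        "dataset": dataset,
        "intensities": intensities,
        "records": records,
        "calls": calls,
        "hits": hits,
        "summary": summary,
        "report": report,
        "manifest": manifest,
    }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["targets_table"].to_csv(out / "targets.csv", index=False)
        design.wells.to_csv(out / "design.csv", index=False)
        intensities.to_csv(out / "intensities.csv", index=False)
        drop_matrix = hits.drop(columns=[], errors="ignore")
        drop_matrix.to_csv(out / "results.csv", index=False)
        summary_rows = [
            {"enzyme": e, "n_active_donors": s["n_active_donors"],
             "n_active_acceptors": s["n_active_acceptors"],
             "active_donors": ";".join(s["active_donors"]),
             "active_acceptors": ";".join(s["active_acceptors"])}
            for e, s in summary.items()
        ]
        pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)
        (out / "report.txt").write_text(report)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "config.yaml").write_text(config.to_yaml())
        if truth_table is not None:
            truth_table.to_csv(out / "ground_truth.csv", index=False)
        if config.write_imzml and config.imzml_input is None:
            dataset.write_imzml(out / "simulated.imzML")
    return bundle
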