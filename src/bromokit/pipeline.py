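"""End-to-end orchestration: configuration, manifests, and reports.

A pipeline run designs a membrane, plants a seeded affinity landscape,
renders and quantifies synthetic membranes for each reader domain, applies
QC, calls Kac-dependent interactions, and writes a peptide × reader
category matrix.  Identical configuration + seeds reproduce byte-identical
tabular artifacts; all randomness is recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from . import __version__
from .arrays import DESIGNERS, ArrayLayout
from .quantify import (
    CallThresholds,
    InteractionCall,
    calls_to_frame,
    call_interactions,
    qc_filter,
    quantify_spots,
)
from .synth import (
    LandscapeRules,
    MembraneGeometry,
    NoiseModel,
    render_membrane,
    synth_affinity_landscape,
)

log = logging.getLogger("bromokit")


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


def _check_keys(section: Mapping[str, Any], allowed: Iterable[str], where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    seed: int = 0
    outdir: str = "bromokit-run"
    log_level: str = "INFO"
    design_class: str = "single_kac"
    length: int = 11
    cap: int | None = None
    brds: tuple[str, ...] = ("BRD-A", "BRD-B", "BRD-C")
    binder_fraction: float = 0.3
    kac_independent_fraction: float = 0.05
    kac_ab_failure_rate: float = 0.0
    probe_conc: float = 1e-6
    read_sd: float = 25.0
    background: float = 1000.0
    exposure_time: float = 5.0
    positive_threshold: float | None = None
    bins: tuple[float, float] | None = None

    _TOP = (
        "seed", "outdir", "log_level", "design", "landscape", "membrane", "calling",
    )
    _DESIGN = ("class", "length", "cap", "brds")
    _LANDSCAPE = ("binder_fraction", "kac_independent_fraction", "kac_ab_failure_rate")
    _MEMBRANE = ("probe_conc", "read_sd", "background", "exposure_time")
    _CALLING = ("positive_threshold", "bins")

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        _check_keys(raw, cls._TOP, "top level")
        design = raw.get("design", {}) or {}
        landscape = raw.get("landscape", {}) or {}
        membrane = raw.get("membrane", {}) or {}
        calling = raw.get("calling", {}) or {}
        _check_keys(design, cls._DESIGN, "design")
        _check_keys(landscape, cls._LANDSCAPE, "landscape")
        _check_keys(membrane, cls._MEMBRANE, "membrane")
        _check_keys(calling, cls._CALLING, "calling")
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "bromokit-run")),
            log_level=str(raw.get("log_level", "INFO")),
            design_class=str(design.get("class", "single_kac")),
            length=int(design.get("length", 11)),
            cap=design.get("cap"),
            brds=tuple(design.get("brds", ("BRD-A", "BRD-B", "BRD-C"))),
            binder_fraction=float(landscape.get("binder_fraction", 0.3)),
            kac_independent_fraction=float(
                landscape.get("kac_independent_fraction", 0.05)
            ),
            kac_ab_failure_rate=float(landscape.get("kac_ab_failure_rate", 0.0)),
            probe_conc=float(membrane.get("probe_conc", 1e-6)),
            read_sd=float(membrane.get("read_sd", 25.0)),
            background=float(membrane.get("background", 1000.0)),
            exposure_time=float(membrane.get("exposure_time", 5.0)),
            positive_threshold=calling.get("positive_threshold"),
            bins=tuple(calling["bins"]) if calling.get("bins") else None,
        )
        if cfg.design_class not in DESIGNERS:
            raise ConfigError(f"unknown design class {cfg.design_class!r}")
        if not cfg.brds:
            raise ConfigError("at least one reader domain required")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(raw)

    def resolved(self) -> dict:
        return asdict(self)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    started: float
    finished: float = 0.0
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    stage_summaries: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: RunManifest):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def demo_config() -> PipelineConfig:
    """A small complete run: H4 single-Kac membrane, three readers."""
    return PipelineConfig.from_mapping(
        {
            "seed": 0,
            "design": {"class": "single_kac", "length": 11, "brds": ["BRD-A", "BRD-B", "BRD-C"]},
            "landscape": {"binder_fraction": 0.4, "kac_independent_fraction": 0.05},
        }
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunManifest:
    """Execute design → synth → quantify → call → report; returns the
    manifest (also written beside the artifacts)."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = RunManifest(version=__version__, started=time.time())
    manifest.seeds["root"] = config.seed
    (outdir / "config.resolved.json").write_text(
        json.dumps(config.resolved(), indent=1, sort_keys=True)
    )
    stage = "design"
    try:
        log.info("[design] class=%s", config.design_class)
        designer = DESIGNERS[config.design_class]
        if config.design_class == "crosstalk":
            layout = designer(max_flanking_mods=config.cap)
        elif config.design_class == "linker_scan":
            layout = designer()
        else:
            layout = designer(length=config.length)
        layout.to_tsv(outdir / "layout.tsv")
        manifest.stage_summaries["design"] = {
            "class": config.design_class,
            "spots": len(layout),
            "probes": len(layout.probes),
        }

        rules = LandscapeRules(
            binder_fraction=config.binder_fraction,
            kac_independent_fraction=config.kac_independent_fraction,
        )
        noise = NoiseModel(read_sd=config.read_sd, background=config.background)
        geometry = MembraneGeometry()
        calls_by_brd: dict[str, list[InteractionCall]] = {}
        for idx, brd in enumerate(config.brds):
            stage = f"synth[{brd}]"
            seed = (config.seed * 1009 + idx) % (2**31)
            manifest.seeds[brd] = seed
            log.info("[synth] %s seed=%d", brd, seed)
            landscape = synth_affinity_landscape(layout, rules, seed=seed)
            landscape.to_frame().to_csv(
                outdir / f"landscape.{brd}.tsv", sep="\t", index=False
            )
            image = render_membrane(
                layout,
                landscape,
                probe_conc=config.probe_conc,
                noise_model=noise,
                geometry=geometry,
                seed=seed,
                exposure_time=config.exposure_time,
            )
            image.write_tiff(outdir / f"membrane.{brd}.tiff")
            stage = f"quantify[{brd}]"
            table = quantify_spots(image, layout, probe_id=brd)
            stage = f"call[{brd}]"
            table = qc_filter(table, layout)
            table.to_tsv(outdir / f"intensities.{brd}.tsv")
            thresholds = CallThresholds(
                positive=config.positive_threshold, bins=config.bins
            )
            calls = call_interactions(table, thresholds)
            calls_to_frame(calls).to_csv(
                outdir / f"calls.{brd}.tsv", sep="\t", index=False
            )
            calls_by_brd[brd] = calls
            manifest.stage_summaries[f"calls[{brd}]"] = {
                "positive": sum(c.category != "none" for c in calls),
                "kac_dependent": sum(c.kac_dependent for c in calls),
            }

        stage = "report"
        matrix = interaction_matrix_report(calls_by_brd)
        with open(outdir / "interaction_matrix.tsv", "w") as fh:
            fh.write("# codes: 0 none, 1 weak, 2 medium, 3 strong; g = Kac-independent (gray)\n")
            matrix.to_csv(fh, sep="\t")
        manifest.stage_summaries["report"] = {
            "peptides": matrix.shape[0],
            "readers": matrix.shape[1],
        }
    except Exception as exc:  # noqa: BLE001 - stage attribution
        manifest.finished = time.time()
        manifest.write(outdir / "manifest.partial.json")
        raise StageError(stage, exc, manifest) from exc

    for artifact in sorted(outdir.glob("*.tsv")):
        manifest.output_digests[artifact.name] = sha256_file(artifact)
    manifest.finished = time.time()
    manifest.write(outdir / "manifest.json")
    return manifest


_CATEGORY_CODE = {"none": "0", "weak": "1", "medium": "2", "strong": "3"}


def interaction_matrix_report(
    calls_by_brd: Mapping[str, Iterable[InteractionCall]],
) -> pd.DataFrame:
    """Peptide × reader category matrix with gray (Kac-independent) flags.

    Cell codes: 0/1/2/3 for none/weak/medium/strong, suffixed ``g`` when
    the interaction is positive but Kac-independent.  Rows and columns are
    sorted for deterministic output; duplicate conflicting calls raise.
    """
    cells: dict[str, dict[str, str]] = {}
    for brd in sorted(calls_by_brd):
        for call in calls_by_brd[brd]:
            code = _CATEGORY_CODE[call.category]
            if call.category != "none" and not call.kac_dependent:
                code += "g"
            row = cells.setdefault(call.label, {})
            if brd in row and row[brd] != code:
                raise ValueError(
                    f"conflicting duplicate calls for {call.label!r} / {brd!r}"
                )
            row[brd] = code
    labels = sorted(cells)
    brds = sorted(calls_by_brd)
    frame = pd.DataFrame(
        [[cells[l].get(b, "") for b in brds] for l in labels],
        index=labels,
        columns=brds,
    )
    frame.index.name = "peptide"
    return frame
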