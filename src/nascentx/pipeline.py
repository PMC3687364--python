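"""End-to-end orchestration helpers and run manifests.

These functions wire the stages together in the canonical order
(pileup -> normalise -> correct -> Z-score -> call -> metrics) so the
CLI, the examples and the validation scripts all run the identical
path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .genome import AnnotationSet
from .metrics import MetricsRecord, compute_metrics
from .signal import MappabilityTrack, SignalTrack, normalize_track
from .tss import (
    TssCall,
    TssCallerConfig,
    ZScoreTrack,
    call_all_tss,
    chromosome_zscores,
    corrected_grocap,
)


@dataclass
class StageResult:
    """Products of one stage's TSS-calling pass."""

    groseq_rpkm: SignalTrack
    corrected_cap: SignalTrack
    zscores: ZScoreTrack
    calls: dict[str, TssCall]
    reasons: dict[str, str]


def run_tss_stage(
    groseq_raw: SignalTrack,
    tap_plus_raw: SignalTrack,
    tap_minus_raw: SignalTrack,
    annotations: AnnotationSet,
    mappability: Optional[MappabilityTrack] = None,
    config: TssCallerConfig = TssCallerConfig(),
    stage_label: str = "",
) -> StageResult:
    """Normalise raw pileups, correct the cap signal, and call TSSs."""
    groseq = normalize_track(groseq_raw, "groseq_rpkm")
    tap_plus = normalize_track(tap_plus_raw, "grocap_rpm")
    tap_minus = normalize_track(tap_minus_raw, "grocap_rpm")
    corrected = corrected_grocap(tap_plus, tap_minus)
    z = chromosome_zscores(
        corrected,
        outlier_fraction=config.outlier_fraction,
        smoothing_window=config.smoothing_window,
        pool_strands=config.pool_strands,
    )
    calls, reasons = call_all_tss(
        annotations, z, groseq, mappability, config, stage_label
    )
    return StageResult(groseq, corrected, z, calls, reasons)


def stage_metrics(
    stage: StageResult,
    annotations: AnnotationSet,
    mappability: Optional[MappabilityTrack] = None,
) -> dict[str, MetricsRecord]:
    return compute_metrics(
        annotations, stage.calls, stage.groseq_rpkm, mappability, stage.corrected_cap
    )


# ---------------------------------------------------------------------------
# manifests


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, input digests, output rows."""

    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def add_inputs(self, **paths) -> None:
        for name, path in paths.items():
            if path is not None and Path(path).exists():
                self.inputs[name] = {"path": str(path), "sha256": file_digest(path)}

    def add_stage(self, name: str, outputs: Mapping[str, str],
                  row_counts: Optional[Mapping[str, int]] = None) -> None:
        entry = {"stage": name, "outputs": dict(outputs)}
        if row_counts:
            entry["row_counts"] = dict(row_counts)
        self.stages.append(entry)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "inputs": self.inputs, "stages": self.stages},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
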