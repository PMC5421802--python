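"""End-to-end demo workflow: image → enumeration → purity → somatic calls.

Chains the package's stages the way the bench workflow chains its assays:
render a synthetic enrichment-output slide, enumerate cells and estimate
CTC purity, feed that purity into the somatic caller's configuration,
simulate tumor/normal pileups for the panel, call consensus somatic
mutations across technical duplicates, and write a single JSON run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import enumeration, synthetic_fixtures
from .benchmarks import MINIMUM_PURITY
from .read_simulator import MixtureSpec, default_panel, simulate_replicates
from .somatic_caller import CallConfig, call_somatic, consensus_calls, write_vcf

__all__ = ["RunConfig", "run_end_to_end"]


@dataclasses.dataclass
class RunConfig:
    """Master configuration of the demo run."""

    seed: int = 0
    out_dir: str = "ctcflow_run"
    # fixture stage
    n_ctc: int = 8
    n_wbc: int = 40
    n_dual: int = 2
    n_negative: int = 2
    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5
    noise_sd: float = 2.0
    # gating
    gates: enumeration.GateConfig = dataclasses.field(default_factory=enumeration.GateConfig)
    # sequencing stage
    coverage: int = 400_000
    error_rate: float = 1e-4
    tumor_vf: float | None = None  # None: use the measured CTC purity
    n_replicates: int = 2
    truth_gene: str = "EGFR"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        gates = enumeration.GateConfig(**raw.pop("gates", {}))
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        return cls(gates=gates, **raw)

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")  # hash identifies the scientific run, not its location
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_end_to_end(config: RunConfig) -> dict[str, Any]:
    """Run all stages; on a stage failure, mark it and skip the rest.

    Returns (and writes to ``out_dir/report.json``) a report with per-stage
    status, artifact paths, the enumeration counts and purity, and the
    consensus somatic calls.  Fully reproducible from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "artifacts": {},
    }

    def fail(stage: str, exc: Exception) -> dict[str, Any]:
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_report(report, out)
        return report

    # stage 1: synthetic slide
    try:
        rng = np.random.default_rng(config.seed)
        fixture_config = synthetic_fixtures.random_fixture_config(
            rng,
            n_ctc=config.n_ctc,
            n_wbc=config.n_wbc,
            n_dual=config.n_dual,
            n_negative=config.n_negative,
            image_size=config.image_size,
            pixel_size=config.pixel_size,
            noise_sd=config.noise_sd,
        )
        fixture = synthetic_fixtures.generate_fixture(fixture_config)
        paths = synthetic_fixtures.write_fixture(fixture, out / "images")
        report["stages"]["simulate_images"] = {"status": "ok", "n_cells": len(fixture.ground_truth)}
        report["artifacts"]["images"] = {k: str(v) for k, v in paths.items()}
    except Exception as exc:  # pragma: no cover - defensive
        return fail("simulate_images", exc)

    # stage 2: enumeration and purity
    try:
        records, result, _ = enumeration.run_pipeline(
            fixture.dna_channel,
            fixture.ck_epcam_channel,
            fixture.cd45_channel,
            config.pixel_size,
            config.gates,
        )
        enumeration.export_measurements(records, out / "per_object.csv", out / "per_object.sqlite")
        report["stages"]["enumerate"] = {"status": "ok", **result.to_dict()}
        report["ctc_purity"] = result.ctc_purity
        report["artifacts"]["per_object_csv"] = str(out / "per_object.csv")
    except Exception as exc:
        return fail("enumerate", exc)

    # stage 3: purity-adjusted somatic calling on simulated pileups
    if not result.purity_defined or result.ctc_purity == 0:
        report["stages"]["somatic_calling"] = {
            "status": "skipped",
            "reason": "CTC purity undefined or zero; no tumor signal to call against",
        }
        _write_report(report, out)
        return report
    try:
        purity = max(result.ctc_purity, MINIMUM_PURITY)
        caller_config = CallConfig(purity=purity)
        # the enrichment output's variant frequency is set by its CTC
        # content: a clonal homozygous tumor variant appears at VF = purity
        tumor_vf = config.tumor_vf if config.tumor_vf is not None else purity
        panel = default_panel()
        rep_calls: list[list] = [[] for _ in range(config.n_replicates)]
        streams = np.random.SeedSequence(config.seed + 1).spawn(len(panel))
        for locus, stream in zip(panel, streams):
            present = locus.gene == config.truth_gene
            mix = MixtureSpec(
                tumor_fraction=tumor_vf,
                coverage=config.coverage,
                error_rate=config.error_rate,
                seed=int(stream.generate_state(1)[0] % (2**31 - 1)),
            )
            pairs = simulate_replicates(config.n_replicates, locus, mix, variant_present=present)
            for r, pair in enumerate(pairs):
                rep_calls[r].append(call_somatic(pair, caller_config))
        consensus = consensus_calls(rep_calls) if config.n_replicates >= 2 else []
        consensus_keys = {c.locus_key for c in consensus}
        write_vcf(
            [c for c in rep_calls[0] if c.called],
            out / "somatic_calls.vcf",
            consensus_keys=consensus_keys,
        )
        report["stages"]["somatic_calling"] = {
            "status": "ok",
            "purity_used": purity,
            "consensus_calls": sorted(consensus_keys),
            "consensus_call_count": len(consensus_keys),
        }
        report["artifacts"]["vcf"] = str(out / "somatic_calls.vcf")
    except Exception as exc:
        return fail("somatic_calling", exc)

    _write_report(report, out)
    return report


def _write_report(report: dict[str, Any], out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
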