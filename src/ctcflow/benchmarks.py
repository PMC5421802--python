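"""Sequencing-performance benchmarks: dilution linearity and replicate consensus.

Two validation experiments run entirely on the built-in pileup simulator:

* the dilution-series linearity assay — spike-in mixtures at expected VFs
  0.08%, 0.8%, 2.68% and 8% sequenced to deep coverage; detected VF is
  regressed on expected VF;
* the technical-replicate consensus assay — several simulated enrichment
  outputs each carrying one true mutation at 0.8% VF on a multi-locus
  panel; sensitivity, PPV and FDR are compared between single-replicate and
  consensus calling.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .read_simulator import (
    LocusSpec,
    MixtureSpec,
    default_panel,
    simulate_dilution_series,
    simulate_replicates,
)
from .somatic_caller import (
    CallConfig,
    EvalMetrics,
    LinearityFit,
    call_somatic,
    consensus_calls,
    evaluate_calls,
    fit_linearity,
)

__all__ = ["LinearityBenchmark", "ConsensusBenchmark", "linearity_benchmark", "consensus_benchmark"]

NONZERO_VF_LEVELS = (0.0008, 0.008, 0.0268, 0.08)
MINIMUM_PURITY = 1e-6  # caller purity floor for vanishingly small spike fractions


@dataclasses.dataclass
class LinearityBenchmark:
    fit: LinearityFit
    series: list[tuple[float, float]]  # (expected VF, detected VF)
    coverage: int
    error_rate: float


@dataclasses.dataclass
class ConsensusBenchmark:
    """Evaluation at each requested replicate depth.

    ``single`` holds first-replicate metrics pooled over samples; ``by_reps``
    maps a replicate count k (>= 2) to consensus-calling metrics.
    """

    single: EvalMetrics
    by_reps: dict[int, EvalMetrics]
    n_samples: int
    vf: float


def linearity_benchmark(
    seed: int = 0,
    vfs: tuple[float, ...] = NONZERO_VF_LEVELS,
    n_points: int = 10,
    coverage: int = 400_000,
    error_rate: float = 1e-4,
) -> LinearityBenchmark:
    """Run one dilution series and fit detected VF ~ expected VF.

    The zero-VF level is part of the full assay but carries no information
    for the regression slope, so the fit uses the nonzero levels.
    """
    series = simulate_dilution_series(
        vfs=vfs, n_points=n_points, coverage=coverage, error_rate=error_rate, seed=seed
    )
    points = [(vf, pair.vf_tumor) for vf, pair in series]
    return LinearityBenchmark(fit_linearity(points), points, coverage, error_rate)


def consensus_benchmark(
    seed: int = 0,
    n_samples: int = 5,
    vf: float = 0.008,
    coverage: int = 400_000,
    error_rate: float = 1e-4,
    rep_counts: tuple[int, ...] = (2,),
    panel: list[LocusSpec] | None = None,
    truth_gene: str = "EGFR",
) -> ConsensusBenchmark:
    """Simulate samples carrying one true panel mutation and compare
    single-replicate against consensus calling.

    Each sample covers the whole panel; only the ``truth_gene`` locus
    carries the variant, at expected VF ``vf``.  The caller's purity is set
    to the spike fraction (homozygous variant), mirroring purity flowing in
    from the enumeration pipeline.  Metrics pool calls over samples; truth
    keys are namespaced per sample.
    """
    panel = panel or default_panel()
    max_reps = max(max(rep_counts), 2)
    config = CallConfig(purity=max(vf, MINIMUM_PURITY))
    master = np.random.SeedSequence(seed)
    sample_streams = master.spawn(n_samples)

    truth_keys: set[str] = set()
    # per replicate index -> list of per-sample called sets
    rep_calls: list[list] = [[] for _ in range(max_reps)]
    for s, stream in enumerate(sample_streams):
        locus_seeds = stream.spawn(len(panel))
        per_rep_sample: list[list] = [[] for _ in range(max_reps)]
        for locus, lseed in zip(panel, locus_seeds):
            present = locus.gene == truth_gene
            if present:
                truth_keys.add(f"s{s}:{locus.key}")
            mix = MixtureSpec(
                tumor_fraction=vf if locus.zygosity == "hom" else min(2 * vf, 1.0),
                coverage=coverage,
                error_rate=error_rate,
                seed=int(lseed.generate_state(1)[0] % (2**31 - 1)),
            )
            pairs = simulate_replicates(max_reps, locus, mix, variant_present=present)
            for r, pair in enumerate(pairs):
                call = call_somatic(pair, config)
                call.locus_key = f"s{s}:{call.locus_key}"
                per_rep_sample[r].append(call)
        for r in range(max_reps):
            rep_calls[r].append(per_rep_sample[r])

    def flat(rep: int) -> list:
        return [c for sample in rep_calls[rep] for c in sample]

    single_called = [c.locus_key for c in flat(0) if c.called]
    single = evaluate_calls(single_called, truth_keys)

    by_reps: dict[int, EvalMetrics] = {}
    for k in rep_counts:
        if k < 2:
            raise ValueError("consensus replicate counts must be >= 2")
        consensus_keys: list[str] = []
        for s in range(n_samples):
            reps = [rep_calls[r][s] for r in range(k)]
            consensus_keys.extend(c.locus_key for c in consensus_calls(reps))
        by_reps[k] = evaluate_calls(consensus_keys, truth_keys)
    return ConsensusBenchmark(single, by_reps, n_samples, vf)
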