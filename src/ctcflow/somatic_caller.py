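"""Purity-adjusted somatic variant calling with replicate consensus.

The somatic test compares reference- and variant-supporting read counts in
the tumor (CTC-enrichment output) sample against the matched normal (WBC)
sample with a one-tailed Fisher's exact test for tumor enrichment.  Because
the enrichment output is mostly hematopoietic background, true somatic
variants appear at very low frequency; the minimum-VF threshold is scaled
by the sample's CTC purity (estimated upstream by the enumeration pipeline)
so that genuine low-frequency variants are not discarded.  Variants with a
significant somatic p value in every technical replicate are kept as
consensus somatic mutations, trading a little sensitivity for a large drop
in false discoveries.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .read_simulator import PileupPair

__all__ = [
    "CallConfig",
    "SomaticCall",
    "ConsensusCall",
    "EvalMetrics",
    "LinearityFit",
    "fisher_somatic_p",
    "effective_min_vf",
    "call_somatic",
    "consensus_calls",
    "evaluate_calls",
    "fit_linearity",
    "write_vcf",
]

MIN_VF_FLOOR = 1e-4


@dataclasses.dataclass
class CallConfig:
    """Somatic-calling thresholds.

    ``base_min_vf`` is the minimum tumor VF required of a call in a pure
    tumor sample; it is scaled down by ``purity`` (CTC fraction of the
    output) to give the effective threshold, floored at 1e-4.
    ``max_normal_vf`` guards against germline sites: at deep coverage even a
    germline variant shows a "significant" tumor/normal imbalance long
    before it is somatic.
    """

    purity: float = 1.0
    base_min_vf: float = 0.20
    somatic_p_threshold: float = 0.05
    max_normal_vf: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        for f in ("base_min_vf", "somatic_p_threshold", "max_normal_vf"):
            if not 0 <= getattr(self, f) <= 1:
                raise ValueError(f"{f} must be in [0, 1]")


@dataclasses.dataclass
class SomaticCall:
    locus_key: str
    somatic_p: float
    vf_tumor: float
    vf_normal: float
    called: bool
    pair: PileupPair | None = None


@dataclasses.dataclass
class ConsensusCall:
    locus_key: str
    replicate_p: list[float]
    vf_tumor_mean: float


@dataclasses.dataclass
class EvalMetrics:
    tp: int
    fp: int
    fn: int
    ppv: float | None
    fdr: float | None
    sensitivity: float


@dataclasses.dataclass
class LinearityFit:
    slope: float
    intercept: float
    r_squared: float


def fisher_somatic_p(ref_t: int, var_t: int, ref_n: int, var_n: int) -> float:
    """One-tailed Fisher's exact p for variant enrichment in the tumor.

    Exact hypergeometric upper tail, P(X >= var_t) with the 2x2 margins
    fixed, computed in log space via log-gamma so it stays exact-to-double
    at amplicon coverages of 1e5-1e6.
    """
    if min(ref_t, var_t, ref_n, var_n) < 0:
        raise ValueError("read counts must be nonnegative")
    n_t = ref_t + var_t
    n_n = ref_n + var_n
    if n_t == 0 or n_n == 0:
        raise ValueError("each sample must have coverage > 0")
    big_n = n_t + n_n
    k = var_t + var_n  # total variant reads across samples
    xs = np.arange(var_t, min(k, n_t) + 1)
    if xs.size == 0:
        return 1.0
    log_terms = (
        gammaln(k + 1) - gammaln(xs + 1) - gammaln(k - xs + 1)
        + gammaln(big_n - k + 1) - gammaln(n_t - xs + 1) - gammaln(big_n - k - n_t + xs + 1)
        - (gammaln(big_n + 1) - gammaln(n_t + 1) - gammaln(big_n - n_t + 1))
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def effective_min_vf(config: CallConfig) -> float:
    """Purity-scaled minimum tumor VF: base_min_vf * purity, floored at 1e-4.

    A variant clonal in the tumor cells appears in the mixed output at
    roughly its pure-tumor frequency times the CTC purity, so the pure-tumor
    threshold is scaled the same way.
    """
    return max(config.base_min_vf * config.purity, MIN_VF_FLOOR)


def call_somatic(pair: PileupPair, config: CallConfig) -> SomaticCall:
    """Call one locus: significant one-tailed Fisher p, tumor VF at or above
    the purity-scaled threshold, and normal VF within the germline guard."""
    p = fisher_somatic_p(pair.tumor_ref, pair.tumor_var, pair.normal_ref, pair.normal_var)
    vf_t = pair.vf_tumor
    vf_n = pair.vf_normal
    called = (
        p < config.somatic_p_threshold
        and vf_t >= effective_min_vf(config)
        and vf_n <= config.max_normal_vf
    )
    return SomaticCall(pair.locus.key, p, vf_t, vf_n, called, pair)


def consensus_calls(replicate_calls: Sequence[Sequence[SomaticCall]]) -> list[ConsensusCall]:
    """Keep loci called (p below threshold and all guards) in EVERY replicate.

    Generalizes the duplicate rule — a consistent somatic p < threshold in
    both technical repeats — to k >= 2 replicates.  Per-replicate p values
    are retained on the consensus record.
    """
    if len(replicate_calls) < 2:
        raise ValueError("consensus requires >= 2 replicates")
    per_rep = [{c.locus_key: c for c in calls if c.called} for calls in replicate_calls]
    keys = set(per_rep[0])
    for d in per_rep[1:]:
        keys &= set(d)
    out = []
    for key in sorted(keys):
        ps = [d[key].somatic_p for d in per_rep]
        vfs = [d[key].vf_tumor for d in per_rep]
        out.append(ConsensusCall(key, ps, float(np.mean(vfs))))
    return out


def evaluate_calls(called_keys: Iterable[str], truth_keys: Iterable[str]) -> EvalMetrics:
    """PPV, FDR and sensitivity of a call set against a truth set.

    With no calls PPV and FDR are undefined (None), not 0 or 1.
    """
    called = set(called_keys)
    truth = set(truth_keys)
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    n_calls = tp + fp
    ppv = tp / n_calls if n_calls else None
    fdr = fp / n_calls if n_calls else None
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    return EvalMetrics(tp, fp, fn, ppv, fdr, sens)


def fit_linearity(series: Sequence[tuple[float, float]]) -> LinearityFit:
    """OLS of detected VF on expected VF for a dilution series."""
    if len(series) < 3:
        raise ValueError("need >= 3 points")
    x = np.array([s[0] for s in series], dtype=float)
    y = np.array([s[1] for s in series], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct expected VFs")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearityFit(float(res.slope), float(res.intercept), r2)


def write_vcf(
    calls: Sequence[SomaticCall],
    path: str | Path,
    sample_names: tuple[str, str] = ("TUMOR", "NORMAL"),
    consensus_keys: Iterable[str] = (),
) -> None:
    """Write calls as a minimal VCF 4.2 with SOMATIC_P/VF_T/VF_N/CONSENSUS
    INFO fields.  Loci must carry a 'chrN:pos' position label."""
    consensus = set(consensus_keys)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=ctcflow",
        '##INFO=<ID=SOMATIC_P,Number=1,Type=Float,Description="One-tailed Fisher somatic p value">',
        '##INFO=<ID=VF_T,Number=1,Type=Float,Description="Tumor variant frequency">',
        '##INFO=<ID=VF_N,Number=1,Type=Float,Description="Normal variant frequency">',
        '##INFO=<ID=CONSENSUS,Number=0,Type=Flag,Description="Consensus across technical replicates">',
        f"##tumor_sample={sample_names[0]}",
        f"##normal_sample={sample_names[1]}",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        if c.pair is None:
            raise ValueError(f"call {c.locus_key} lacks locus coordinates")
        locus = c.pair.locus
        chrom, pos = locus.position.split(":")
        info = f"SOMATIC_P={c.somatic_p:.6g};VF_T={c.vf_tumor:.6g};VF_N={c.vf_normal:.6g}"
        if c.locus_key in consensus:
            info += ";CONSENSUS"
        lines.append(f"{chrom}\t{pos}\t{locus.gene}\t{locus.ref}\t{locus.alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")
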