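"""Tumor/normal pileup simulation for spike-in dilution series.

Emulates deep amplicon sequencing of a microfluidic CTC-enrichment output:
a small fraction of tumor DNA (the spiked cell line, carrying known point
mutations) diluted into a wild-type hematopoietic background, sequenced to
high coverage alongside a matched normal (WBC) sample.  Simulation is at
the pileup-count level — per-locus reference- and variant-supporting read
counts — since amplicon positions are known by construction and alignment
adds nothing.  Optional FASTQ emission goes through
:mod:`ctcflow.amplicon_library`.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LocusSpec",
    "MixtureSpec",
    "PileupPair",
    "default_panel",
    "expected_vf",
    "simulate_pileup",
    "simulate_dilution_series",
    "simulate_replicates",
    "pileup_table",
    "write_pileup_csv",
    "read_pileup_csv",
]

_NUCS = {"A", "C", "G", "T"}


@dataclasses.dataclass(frozen=True)
class LocusSpec:
    """One panel locus: a single-nucleotide somatic variant site."""

    gene: str
    position: str  # e.g. "chr7:55259524"
    ref: str
    alt: str
    zygosity: str = "hom"  # zygosity of the variant in the spiked tumor DNA

    def __post_init__(self) -> None:
        if self.ref not in _NUCS or self.alt not in _NUCS:
            raise ValueError("ref and alt must be single nucleotides")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.zygosity not in ("het", "hom"):
            raise ValueError("zygosity must be 'het' or 'hom'")

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.position}"


@dataclasses.dataclass
class MixtureSpec:
    """Spike-in mixture: tumor fraction, per-locus coverage, error rate."""

    tumor_fraction: float
    coverage: int = 400_000
    error_rate: float = 1e-4  # per-base probability of a specific substitution
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")


@dataclasses.dataclass
class PileupPair:
    """Tumor and matched-normal read counts at one locus."""

    locus: LocusSpec
    tumor_ref: int
    tumor_var: int
    normal_ref: int
    normal_var: int
    truth: bool  # variant truly present in the tumor mixture

    def __post_init__(self) -> None:
        if min(self.tumor_ref, self.tumor_var, self.normal_ref, self.normal_var) < 0:
            raise ValueError("read counts must be nonnegative")

    @property
    def vf_tumor(self) -> float:
        return self.tumor_var / (self.tumor_ref + self.tumor_var)

    @property
    def vf_normal(self) -> float:
        return self.normal_var / (self.normal_ref + self.normal_var)


def default_panel() -> list[LocusSpec]:
    """Six-gene hotspot panel of clinically relevant point mutations
    (hg19 coordinates).  The EGFR L861Q site doubles as the spike-in
    truth locus of the dilution benchmarks."""
    return [
        LocusSpec("EGFR", "chr7:55259524", "T", "A"),    # L861Q
        LocusSpec("TP53", "chr17:7573937", "G", "T"),    # A364S
        LocusSpec("ESR1", "chr6:152419988", "T", "G"),   # S559A
        LocusSpec("KRAS", "chr12:25398284", "C", "T"),   # G12D
        LocusSpec("BRAF", "chr7:140453136", "A", "T"),   # V600E
        LocusSpec("NRAS", "chr1:115256529", "T", "C"),   # Q61R
    ]


def expected_vf(tumor_fraction: float, zygosity: str = "hom") -> float:
    """Expected variant frequency of a tumor variant in the mixture.

    A homozygous variant contributes one variant allele per tumor genome
    copy (VF = fraction); a heterozygous variant contributes half.
    """
    if not 0 <= tumor_fraction <= 1:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if zygosity == "hom":
        return tumor_fraction
    if zygosity == "het":
        return tumor_fraction / 2.0
    raise ValueError("zygosity must be 'het' or 'hom'")


def simulate_pileup(
    locus: LocusSpec,
    mix: MixtureSpec,
    rng: np.random.Generator | None = None,
    variant_present: bool = True,
) -> PileupPair:
    """Draw one tumor/normal pileup pair at a locus.

    Tumor variant reads ~ Binomial(coverage, vf + e*(1 - vf)): sequencing
    errors hit only non-variant templates (errors on variant templates that
    would revert the allele are ignored).  Normal variant reads ~
    Binomial(coverage, e).  ``variant_present=False`` simulates a panel
    locus the spiked tumor line does not carry.
    """
    rng = rng if rng is not None else np.random.default_rng(mix.seed)
    vf = expected_vf(mix.tumor_fraction, locus.zygosity) if variant_present else 0.0
    p_t = vf + mix.error_rate * (1.0 - vf)
    tumor_var = int(rng.binomial(mix.coverage, p_t))
    normal_var = int(rng.binomial(mix.coverage, mix.error_rate))
    return PileupPair(
        locus,
        tumor_ref=mix.coverage - tumor_var,
        tumor_var=tumor_var,
        normal_ref=mix.coverage - normal_var,
        normal_var=normal_var,
        truth=variant_present and vf > 0,
    )


DEFAULT_VF_LEVELS = (0.0, 0.0008, 0.008, 0.0268, 0.08)


def simulate_dilution_series(
    vfs: Sequence[float] = DEFAULT_VF_LEVELS,
    n_points: int = 10,
    locus: LocusSpec | None = None,
    coverage: int = 400_000,
    error_rate: float = 1e-4,
    seed: int = 0,
) -> list[tuple[float, PileupPair]]:
    """Simulate ``n_points`` independent pileups spread round-robin over the
    requested expected-VF levels (defaults: 0%, 0.08%, 0.8%, 2.68%, 8%)."""
    if any(v < 0 for v in vfs):
        raise ValueError("expected VFs must be nonnegative")
    locus = locus or default_panel()[0]
    streams = np.random.SeedSequence(seed).spawn(n_points)
    out = []
    for i in range(n_points):
        vf = float(vfs[i % len(vfs)])
        mix = MixtureSpec(
            tumor_fraction=vf if locus.zygosity == "hom" else min(2 * vf, 1.0),
            coverage=coverage,
            error_rate=error_rate,
        )
        rng = np.random.default_rng(streams[i])
        out.append((vf, simulate_pileup(locus, mix, rng)))
    return out


def simulate_replicates(
    k: int,
    locus: LocusSpec,
    mix: MixtureSpec,
    variant_present: bool = True,
) -> list[PileupPair]:
    """k technical replicates: shared truth, independent sampling noise.

    Sub-seeds are derived deterministically from ``mix.seed``; ``k=1``
    reproduces a single :func:`simulate_pileup` draw exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return [simulate_pileup(locus, mix, variant_present=variant_present)]
    streams = np.random.SeedSequence(mix.seed).spawn(k)
    return [
        simulate_pileup(locus, mix, np.random.default_rng(s), variant_present)
        for s in streams
    ]


# --- tabular I/O ----------------------------------------------------------

def pileup_table(pairs: Sequence[PileupPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "gene": p.locus.gene,
                "position": p.locus.position,
                "ref": p.locus.ref,
                "alt": p.locus.alt,
                "zygosity": p.locus.zygosity,
                "tumor_ref": p.tumor_ref,
                "tumor_var": p.tumor_var,
                "normal_ref": p.normal_ref,
                "normal_var": p.normal_var,
                "truth": p.truth,
            }
        )
    return pd.DataFrame(rows)


def write_pileup_csv(pairs: Sequence[PileupPair], path: str | Path) -> None:
    pileup_table(pairs).to_csv(path, index=False)


def read_pileup_csv(path: str | Path) -> list[PileupPair]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        locus = LocusSpec(str(r["gene"]), str(r["position"]), str(r["ref"]), str(r["alt"]), str(r["zygosity"]))
        out.append(
            PileupPair(
                locus,
                int(r["tumor_ref"]),
                int(r["tumor_var"]),
                int(r["normal_ref"]),
                int(r["normal_var"]),
                bool(r["truth"]),
            )
        )
    return out
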