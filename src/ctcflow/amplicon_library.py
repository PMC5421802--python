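"""Two-step PCR amplicon library model with a random 10-bp diversifier.

Amplicon libraries are nearly monotemplate: every cluster on the flowcell
reads the same bases during the first sequencing cycles, which defeats
cluster identification on Illumina machines.  The construct modeled here
inserts a run of random nucleotides (the "diversifier") between the
sequencing adapter and the target-hybridizing primer so the first cycles of
every read are maximally diverse.  The first PCR adds partial adapters plus
the diversifier around the target insert; the second PCR extends the
adapters to full P5/P7.  This module builds those constructs with an exact
segment map, trims reads back to the insert, and scores per-cycle base
diversity (Shannon entropy).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PrimerDesign",
    "LibraryConstruct",
    "TrimResult",
    "build_first_pcr_construct",
    "build_second_pcr_construct",
    "sequencing_read",
    "trim_read",
    "per_cycle_diversity",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_fastq",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _check_alphabet(seq: str, name: str) -> None:
    if not seq or set(seq) - set(_BASES):
        raise ValueError(f"{name} must be a non-empty A/C/G/T string")


@dataclasses.dataclass
class PrimerDesign:
    """Primer and adapter sequences of the 2-step construct.

    Defaults use the generic Illumina P5/P7 flowcell adapters and arbitrary
    target-hybridizing primers; a real panel supplies its own sequences via
    config.  Partial adapters (carried by the first-PCR primers) must be
    suffixes of the full adapters so the second PCR can extend them.
    """

    target_forward: str = "TGGTCCATGTCTGGTTCTGG"
    target_reverse: str = "CCTGGCTGACCTAAAGCCAC"
    full_p5: str = "AATGATACGGCGACCACCGAGATCTACAC"  # 29 nt
    full_p7: str = "CAAGCAGAAGACGGCATACGAGAT"  # 24 nt
    partial_p5: str = "ACCACCGAGATCTACAC"
    partial_p7: str = "ACGGCATACGAGAT"
    diversifier_length: int = 10

    def __post_init__(self) -> None:
        for name in ("target_forward", "target_reverse", "full_p5", "full_p7", "partial_p5", "partial_p7"):
            _check_alphabet(getattr(self, name), name)
        if self.diversifier_length < 0:
            raise ValueError("diversifier_length must be >= 0")
        if not self.full_p5.endswith(self.partial_p5):
            raise ValueError("partial_p5 must be a suffix of full_p5")
        if not self.full_p7.endswith(self.partial_p7):
            raise ValueError("partial_p7 must be a suffix of full_p7")


@dataclasses.dataclass
class LibraryConstruct:
    """A library molecule (top strand, 5'->3') with its segment map.

    Segments are ``(name, start, end)`` in 0-based half-open coordinates and
    tile the sequence exactly:
    ``p5 | diversifier_5p | target_fwd | insert | target_rev_rc |
    diversifier_3p | p7_rc``.  Reverse-strand elements are stored as their
    reverse complement on the top strand.
    """

    sequence: str
    segments: list[tuple[str, int, int]]
    adapters: str  # "partial" after PCR 1, "full" after PCR 2

    def __post_init__(self) -> None:
        pos = 0
        for name, start, end in self.segments:
            if start != pos or end < start:
                raise ValueError(f"segment map does not tile at {name!r}")
            pos = end
        if pos != len(self.sequence):
            raise ValueError("segment map does not cover the full sequence")

    def segment(self, name: str) -> str:
        for n, s, e in self.segments:
            if n == name:
                return self.sequence[s:e]
        raise KeyError(name)


def build_first_pcr_construct(
    insert: str, design: PrimerDesign, seed: int | np.random.Generator = 0
) -> LibraryConstruct:
    """First PCR: target amplification plus diversifiers and partial adapters.

    The two diversifiers are instantiated independently as i.i.d. uniform
    random bases (the design calls only for "random" nucleotides) and are
    seed-deterministic.
    """
    _check_alphabet(insert, "insert")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.diversifier_length
    div5 = "".join(rng.choice(list(_BASES), size=n)) if n else ""
    div3 = "".join(rng.choice(list(_BASES), size=n)) if n else ""
    parts = [
        ("p5", design.partial_p5),
        ("diversifier_5p", div5),
        ("target_fwd", design.target_forward),
        ("insert", insert),
        ("target_rev_rc", revcomp(design.target_reverse)),
        ("diversifier_3p", div3),
        ("p7_rc", revcomp(design.partial_p7)),
    ]
    seq = "".join(p for _, p in parts)
    segments, pos = [], 0
    for name, p in parts:
        segments.append((name, pos, pos + len(p)))
        pos += len(p)
    return LibraryConstruct(seq, segments, adapters="partial")


def build_second_pcr_construct(construct: LibraryConstruct, design: PrimerDesign) -> LibraryConstruct:
    """Second PCR: extend partial adapters to full P5/P7.

    Interior segments (diversifiers, primers, insert) are untouched.
    Applying to an already-full construct raises.
    """
    if construct.adapters == "full":
        raise ValueError("construct already carries full adapters")
    if not construct.sequence.startswith(design.partial_p5) or not construct.sequence.endswith(
        revcomp(design.partial_p7)
    ):
        raise ValueError("construct lacks recognizable partial adapters")
    p5_ext = design.full_p5[: -len(design.partial_p5)]
    p7_ext_rc = revcomp(design.full_p7[: -len(design.partial_p7)])
    seq = p5_ext + construct.sequence + p7_ext_rc
    shift = len(p5_ext)
    segments = []
    for name, s, e in construct.segments:
        if name == "p5":
            segments.append(("p5", 0, e + shift))
        elif name == "p7_rc":
            segments.append(("p7_rc", s + shift, e + shift + len(p7_ext_rc)))
        else:
            segments.append((name, s + shift, e + shift))
    return LibraryConstruct(seq, segments, adapters="full")


def sequencing_read(construct: LibraryConstruct, read_length: int | None = None) -> str:
    """Read 1 as the sequencer delivers it: starts right after the P5-side
    sequencing primer (i.e. at the 5' diversifier), optionally truncated."""
    start = 0
    for name, s, e in construct.segments:
        if name == "p5":
            start = e
            break
    read = construct.sequence[start:]
    return read[:read_length] if read_length is not None else read


@dataclasses.dataclass
class TrimResult:
    insert: str | None
    trimmed: bool
    reason: str = ""


def _match_prefix(read: str, pattern: str, max_mismatches: int) -> bool:
    if len(read) < len(pattern):
        return False
    mm = sum(a != b for a, b in zip(read, pattern))
    return mm <= max_mismatches


def _find_with_mismatches(hay: str, needle: str, max_mismatches: int, min_overlap: int = 8) -> int:
    """Leftmost start of ``needle`` in ``hay`` (<= max_mismatches), allowing
    a 3'-truncated occurrence at the end if >= min_overlap bases overlap.
    Returns -1 when absent."""
    n, m = len(hay), len(needle)
    for i in range(0, max(n - m, -1) + 1):
        if sum(a != b for a, b in zip(hay[i : i + m], needle)) <= max_mismatches:
            return i
    for i in range(max(n - m + 1, 0), n - min_overlap + 1):
        tail = hay[i:]
        if sum(a != b for a, b in zip(tail, needle)) <= max_mismatches:
            return i
    return -1


def trim_read(read: str, design: PrimerDesign, max_mismatches: int = 2) -> TrimResult:
    """Strip adapter, diversifier and primers; return the insert region.

    Accepts reads that begin at the full adapter, the partial adapter, or
    directly at the diversifier (machine-trimmed), matching adapters as
    prefixes with up to ``max_mismatches`` substitutions.  On the 3' side the
    reverse primer (reverse complement) is located with the same tolerance;
    reads truncated before it simply keep their remaining insert bases.
    Reads without a recognizable 5' structure are flagged untrimmed.
    """
    offset = None
    for adapter in (design.full_p5, design.partial_p5):
        if _match_prefix(read, adapter, max_mismatches):
            offset = len(adapter)
            break
    if offset is None:
        # machine-delivered reads start at the diversifier; verify by
        # locating the forward primer right after it
        if _match_prefix(read[design.diversifier_length :], design.target_forward, max_mismatches):
            offset = 0
        else:
            return TrimResult(None, False, "adapter not found")
    body = read[offset + design.diversifier_length :]
    if not _match_prefix(body, design.target_forward, max_mismatches):
        return TrimResult(None, False, "forward primer not found")
    body = body[len(design.target_forward) :]
    rev_rc = revcomp(design.target_reverse)
    cut = _find_with_mismatches(body, rev_rc, max_mismatches)
    insert = body[:cut] if cut >= 0 else body
    return TrimResult(insert, True)


def per_cycle_diversity(reads: list[str], n_cycles: int = 5) -> np.ndarray:
    """Shannon entropy (bits) of base composition at each of the first
    ``n_cycles`` read positions.

    Reads are taken as sequenced (position 0 = first cycle); with the
    diversifier design the first cycles fall inside the random segment and
    approach the 2-bit maximum of a 4-letter alphabet.
    """
    if not reads:
        raise ValueError("empty read list")
    if any(len(r) < n_cycles for r in reads):
        raise ValueError(f"all reads must have length >= {n_cycles}")
    out = np.zeros(n_cycles)
    for c in range(n_cycles):
        counts = np.array([sum(1 for r in reads if r[c] == b) for b in _BASES], dtype=float)
        p = counts / counts.sum()
        nz = p[p > 0]
        out[c] = float(-(nz * np.log2(nz)).sum())
    return out


# --- FASTA / FASTQ I/O ----------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(sequences: dict[str, str], path: str | Path, quality: int = 37) -> None:
    records = []
    for name, s in sequences.items():
        rec = SeqRecord(Seq(s), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(s)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}
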