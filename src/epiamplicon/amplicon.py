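"""Amplicon definitions and CpG-site coordinate handling.

An amplicon is a short PCR-defined region of the top (OT) strand whose CpG
cytosines are the methylation-readout positions.  Coordinates are stored
0-based internally; every user-facing CpG label is relative to the
transcription start site (TSS = +1), negative upstream, with no position 0 —
the convention used throughout targeted bisulfite promoter studies.

Only the top strand is modelled: the bisulfite primers are strand-specific,
so reads from a library made with a given primer pair all present the same
(converted) top-strand sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = [
    "CpGSite",
    "AmpliconSpec",
    "BisulfiteReference",
    "define_amplicon",
    "bisulfite_reference",
    "derive_bisulfite_primers",
    "load_amplicons",
    "iupac_match",
    "primer_mismatches",
]

# IUPAC degenerate nucleotide codes -> the plain bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(pattern_char: str, base: str) -> bool:
    """True if ``base`` is compatible with the (possibly degenerate) ``pattern_char``."""
    return base in IUPAC.get(pattern_char.upper(), "")


def primer_mismatches(primer: str, window: str) -> int:
    """Mismatch count of a degenerate primer against an equal-length sequence window.

    Positions beyond the window (short read) count as mismatches.
    """
    n = 0
    for i, p in enumerate(primer):
        if i >= len(window) or not iupac_match(p, window[i]):
            n += 1
    return n


@dataclass(frozen=True)
class CpGSite:
    """One CpG dinucleotide: 0-based index of the C plus its TSS-relative label."""

    index: int
    label: int


@dataclass(frozen=True)
class AmpliconSpec:
    """A bisulfite amplicon: untreated top-strand reference plus CpG coordinates.

    ``tss_index`` is the 0-based index of the base defined as TSS (+1), or
    ``None`` when coordinates are amplicon-local (labels are then 1-based
    positions).  ``fw_primer``/``rv_primer`` are bisulfite primers and may
    contain the degenerate letters Y (C/T) and R (A/G) at original-C/G sites.
    """

    name: str
    reference_seq: str
    tss_index: int | None
    cpg_sites: tuple[CpGSite, ...]
    fw_primer: str = ""
    rv_primer: str = ""
    region_label: str = ""

    @property
    def n_sites(self) -> int:
        return len(self.cpg_sites)

    @property
    def site_indices(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.cpg_sites)

    @property
    def site_labels(self) -> tuple[int, ...]:
        return tuple(s.label for s in self.cpg_sites)

    def __len__(self) -> int:
        return len(self.reference_seq)


@dataclass(frozen=True)
class BisulfiteReference:
    """Fully-converted matching target for reads from bisulfite PCR.

    Every non-CpG C of the top strand is T (conversion assumed complete) and
    every CpG cytosine is the degenerate Y, matching both its methylated (C)
    and unmethylated (T) read-out.
    """

    parent: str
    converted_seq: str

    def __len__(self) -> int:
        return len(self.converted_seq)


def _tss_label(index: int, tss_index: int | None) -> int:
    # TSS convention: the TSS base is +1 and there is no position 0.
    if tss_index is None:
        return index + 1
    d = index - tss_index
    return d + 1 if d >= 0 else d


def define_amplicon(
    name: str,
    reference_seq: str,
    tss_index: int | None = None,
    fw_primer: str = "",
    rv_primer: str = "",
    region_label: str = "",
) -> AmpliconSpec:
    """Build an :class:`AmpliconSpec`, enumerating every CG dinucleotide.

    Parameters
    ----------
    reference_seq
        Untreated top-strand sequence, uppercase A/C/G/T only.
    tss_index
        0-based index of the TSS base, or ``None`` for amplicon-local labels.

    Raises
    ------
    ValueError
        On an empty sequence, a non-ACGT character (reported with its
        position), or an out-of-range ``tss_index``.
    """
    if not reference_seq:
        raise ValueError("reference_seq must be non-empty")
    seq = reference_seq.upper()
    for i, b in enumerate(seq):
        if b not in "ACGT":
            raise ValueError(f"non-ACGT character {b!r} at position {i} in {name!r}")
    if tss_index is not None and not (0 <= tss_index < len(seq)):
        raise ValueError(
            f"tss_index {tss_index} out of range for sequence of length {len(seq)}"
        )
    sites = tuple(
        CpGSite(index=i, label=_tss_label(i, tss_index))
        for i in range(len(seq) - 1)
        if seq[i] == "C" and seq[i + 1] == "G"
    )
    return AmpliconSpec(
        name=name,
        reference_seq=seq,
        tss_index=tss_index,
        cpg_sites=sites,
        fw_primer=fw_primer.upper() if fw_primer else "",
        rv_primer=rv_primer.upper() if rv_primer else "",
        region_label=region_label,
    )


def bisulfite_reference(spec: AmpliconSpec) -> BisulfiteReference:
    """In-silico fully bisulfite-converted reference: non-CpG C→T, CpG C→Y."""
    cpg = set(spec.site_indices)
    out = [
        ("Y" if i in cpg else "T") if b == "C" else b
        for i, b in enumerate(spec.reference_seq)
    ]
    return BisulfiteReference(parent=spec.name, converted_seq="".join(out))


_COMP = str.maketrans("ACGT", "TGCA")


def derive_bisulfite_primers(spec: AmpliconSpec, length: int = 20) -> tuple[str, str]:
    """Degenerate bisulfite primer pair spanning the amplicon ends.

    Forward primer: first ``length`` bases with every original C written Y
    (the primer must anneal whether or not conversion/methylation left a C).
    Reverse primer: reverse complement of the last ``length`` bases with every
    original C complemented to the degenerate R.
    """
    head = spec.reference_seq[:length]
    fw = "".join("Y" if b == "C" else b for b in head)
    tail = spec.reference_seq[-length:]
    rv = "".join(
        "R" if b == "C" else b.translate(_COMP) for b in reversed(tail)
    )
    return fw, rv


def load_amplicons(path: str | Path) -> list[AmpliconSpec]:
    """Read amplicon definitions from a JSON config.

    The file holds a list of objects with keys ``name``, either ``sequence``
    (inline) or ``fasta`` (path to a FASTA file whose first record is used),
    and optional ``tss_index``, ``fw_primer``, ``rv_primer``, ``region_label``.
    FASTA paths are resolved relative to the config file.
    """
    from Bio import SeqIO

    path = Path(path)
    entries = json.loads(path.read_text())
    specs = []
    for e in entries:
        if "sequence" in e:
            seq = e["sequence"]
        elif "fasta" in e:
            fasta = path.parent / e["fasta"]
            seq = str(next(SeqIO.parse(str(fasta), "fasta")).seq)
        else:
            raise ValueError(f"amplicon {e.get('name')!r}: need 'sequence' or 'fasta'")
        specs.append(
            define_amplicon(
                e["name"],
                seq,
                tss_index=e.get("tss_index"),
                fw_primer=e.get("fw_primer", ""),
                rv_primer=e.get("rv_primer", ""),
                region_label=e.get("region_label", ""),
            )
        )
    return specs


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
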