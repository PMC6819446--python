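"""Paired-read merging, amplicon assignment, per-read methylation calling, QC.

The pipeline stage that turns raw paired FASTQ into :class:`ReadProfile`
objects: one per sequenced molecule, holding its per-CpG methylation calls
and its own bisulfite-conversion efficiency measured on non-CpG cytosines.
Matching is strictly ungapped — amplicons have fixed length and indel reads
would scramble CpG indexing, so they are dropped rather than gap-aligned.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .amplicon import (
    AmpliconSpec,
    BisulfiteReference,
    bisulfite_reference,
    primer_mismatches,
)

__all__ = [
    "MergedRead",
    "ReadProfile",
    "ConversionReport",
    "merge_pairs",
    "assign_amplicon",
    "call_profile",
    "filter_profiles",
    "estimate_spikein_conversion",
]

AMBIGUOUS = -1  # call code for uncallable CpG positions (calls are int8: 1/0/-1)


@dataclass
class MergedRead:
    id: str
    sequence: str
    qualities: np.ndarray  # phred scores, int
    overlap_len: int


@dataclass
class ReadProfile:
    """Per-molecule methylation read-out.

    ``calls`` is aligned to the amplicon's CpG sites: 1 methylated (read C),
    0 unmethylated (read T), −1 ambiguous (other base, N, or not covered).
    ``conversion_rate_read`` is converted/(converted+unconverted) over the
    read's non-CpG reference-C positions (``None`` when none are covered) —
    the per-read bisulfite efficiency.  ``identity`` is the match fraction at
    non-variable positions (reference A/G/T outside primers).
    """

    read_id: str
    amplicon: str
    calls: np.ndarray
    conversion_rate_read: float | None
    identity: float | None
    passed_filters: bool = True
    fail_reason: str | None = None

    @property
    def n_ambiguous(self) -> int:
        return int((self.calls == AMBIGUOUS).sum())

    def pattern(self) -> str | None:
        """Epiallele string, or None if any call is ambiguous."""
        if self.n_ambiguous:
            return None
        return "".join("01"[c] for c in self.calls)


@dataclass
class ConversionReport:
    """Per-sample QC tally for :func:`filter_profiles`."""

    total: int
    passing: int
    failed_by_reason: dict[str, int] = field(default_factory=dict)
    mean_read_conversion: float | None = None
    spikein_conversion: float | None = None

    def __post_init__(self):
        if sum(self.failed_by_reason.values()) != self.total - self.passing:
            raise ValueError("failure-reason counts must sum to total - passing")


# ---------------------------------------------------------------------------
# FASTQ input
# ---------------------------------------------------------------------------

def _read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Minimal whole-file FASTQ reader (plain or gzip); rejects truncation."""
    opener = gzip.open if str(path).endswith(".gz") else open
    recs = []
    with opener(str(path), "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ after record {len(lines) // 4}")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed FASTQ at record {i // 4}")
        recs.append((head[1:].split()[0], seq.upper(), qual))
    return recs


def _as_records(src) -> list[tuple[str, str, str]]:
    if isinstance(src, (str, Path)):
        return _read_fastq(src)
    return [(r[0], r[1].upper(), r[2]) for r in src]


_RC_TBL = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC_TBL[_a] = _b


def _seq_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def _qual_matrix(quals: Sequence[str]) -> np.ndarray:
    return _seq_matrix(quals).astype(np.int16) - 33


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------

def merge_pairs(
    r1,
    r2,
    min_overlap: int = 40,
    min_overlap_identity: float = 0.9,
) -> tuple[list[MergedRead], dict[str, int]]:
    """Merge read pairs by their best ungapped 3′ overlap.

    ``r1``/``r2`` are FASTQ paths (gzip fine) or iterables of
    ``(id, sequence, quality)`` records in matching order.  For each pair the
    overlap of R1 with reverse-complement(R2) maximising the match count is
    found; pairs whose best overlap is shorter than ``min_overlap`` (default
    40 nt, the assembly threshold for this kind of amplicon data) or whose
    overlap identity is below ``min_overlap_identity`` are rejected and
    counted.  Overlap mismatches are resolved by the higher-quality base
    (tie → R1).

    Returns the merged reads plus a counter with keys ``total``, ``merged``,
    ``short_overlap``, ``low_overlap_identity``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rec1, rec2 = _as_records(r1), _as_records(r2)
    if len(rec1) != len(rec2):
        raise ValueError(
            f"unpaired FASTQ: {len(rec1)} R1 records vs {len(rec2)} R2 records"
        )
    counts = {"total": len(rec1), "merged": 0,
              "short_overlap": 0, "low_overlap_identity": 0}
    merged: list[MergedRead] = []

    # group pairs by (len1, len2) so each group is fully vectorised
    groups: dict[tuple[int, int], list[int]] = {}
    for i, (a, b) in enumerate(zip(rec1, rec2)):
        groups.setdefault((len(a[1]), len(b[1])), []).append(i)

    out: list[MergedRead | None] = [None] * len(rec1)
    for (l1, l2), idxs in groups.items():
        s1 = _seq_matrix([rec1[i][1] for i in idxs])
        q1 = _qual_matrix([rec1[i][2] for i in idxs])
        s2 = _seq_matrix([rec2[i][1] for i in idxs])
        q2 = _qual_matrix([rec2[i][2] for i in idxs])
        b2 = _RC_TBL[s2][:, ::-1]          # reverse complement of R2
        bq2 = q2[:, ::-1]
        n = len(idxs)
        max_o = min(l1, l2)
        best_o = np.zeros(n, dtype=int)
        best_m = np.full(n, -1, dtype=int)
        for o in range(max_o, 0, -1):
            m = (s1[:, l1 - o:] == b2[:, :o]).sum(axis=1)
            better = m > best_m
            best_m[better] = m[better]
            best_o[better] = o
        for k, i in enumerate(idxs):
            o = int(best_o[k])
            ident = best_m[k] / o if o else 0.0
            if o < min_overlap:
                counts["short_overlap"] += 1
                continue
            if ident < min_overlap_identity:
                counts["low_overlap_identity"] += 1
                continue
            a1, aq1 = s1[k], q1[k]
            a2, aq2 = b2[k], bq2[k]
            ov1, ovq1 = a1[l1 - o:], aq1[l1 - o:]
            ov2, ovq2 = a2[:o], aq2[:o]
            take2 = (ov1 != ov2) & (ovq2 > ovq1)
            cons = np.where(take2, ov2, ov1)
            consq = np.maximum(ovq1, ovq2)
            seq = np.concatenate([a1[: l1 - o], cons, a2[o:]])
            qual = np.concatenate([aq1[: l1 - o], consq, aq2[o:]])
            out[i] = MergedRead(
                id=rec1[i][0],
                sequence=seq.tobytes().decode(),
                qualities=qual,
                overlap_len=o,
            )
            counts["merged"] += 1
    merged = [m for m in out if m is not None]
    return merged, counts


# ---------------------------------------------------------------------------
# amplicon assignment
# ---------------------------------------------------------------------------

def _identity_vs_reference(seq: str, bsref: BisulfiteReference) -> float:
    n = min(len(seq), len(bsref))
    if n == 0:
        return 0.0
    match = 0
    conv = bsref.converted_seq
    for i in range(n):
        r = conv[i]
        b = seq[i]
        if r == "Y":
            match += b in "CT"
        else:
            match += b == r
    return match / len(bsref)


def assign_amplicon(
    read: MergedRead,
    specs: Sequence[AmpliconSpec],
    max_primer_mismatches: int = 2,
    min_identity: float = 0.8,
    _bsrefs: dict[str, BisulfiteReference] | None = None,
) -> tuple[str | None, int]:
    """Assign a merged read to an amplicon by its forward primer and identity.

    The (degenerate-aware) forward primer must match the read 5′ end with at
    most ``max_primer_mismatches`` mismatches; among matching specs the one
    with the highest full-length identity to its fully-converted reference
    wins, ties going to the lexicographically smallest name.  Identity below
    ``min_identity`` → ``(None, 0)`` (unassigned — a normal outcome).
    """
    if not specs:
        raise ValueError("need at least one AmpliconSpec")
    best: tuple[float, str] | None = None
    for spec in sorted(specs, key=lambda s: s.name):
        if spec.fw_primer:
            mm = primer_mismatches(spec.fw_primer, read.sequence[: len(spec.fw_primer)])
            if mm > max_primer_mismatches:
                continue
        bsref = (_bsrefs or {}).get(spec.name) or bisulfite_reference(spec)
        ident = _identity_vs_reference(read.sequence, bsref)
        if ident >= min_identity and (best is None or ident > best[0]):
            best = (ident, spec.name)
    if best is None:
        return None, 0
    return best[1], 0


# ---------------------------------------------------------------------------
# profile calling
# ---------------------------------------------------------------------------

def call_profile(read: MergedRead, spec: AmpliconSpec,
                 exclude_primers: bool = True) -> ReadProfile:
    """Call the per-CpG methylation profile of one merged read.

    At each CpG cytosine, read C → 1, T → 0, anything else (or a site the
    read does not reach) → ambiguous.  Non-CpG reference-C positions score
    the read's own conversion efficiency (C unconverted, T converted, other
    bases excluded); primer footprints are excluded from conversion and
    identity statistics by default since those bases come from the primer
    oligo, not the molecule.
    """
    seq = read.sequence
    ref = spec.reference_seq
    L = min(len(seq), len(ref))
    cpg = set(spec.site_indices)

    calls = np.full(spec.n_sites, AMBIGUOUS, dtype=np.int8)
    for k, i in enumerate(spec.site_indices):
        if i < L:
            b = seq[i]
            if b == "C":
                calls[k] = 1
            elif b == "T":
                calls[k] = 0

    lo = len(spec.fw_primer) if exclude_primers else 0
    hi = len(ref) - (len(spec.rv_primer) if exclude_primers else 0)
    hi = min(hi, L)

    converted = unconverted = 0
    ident_match = ident_total = 0
    for i in range(lo, hi):
        r = ref[i]
        b = seq[i]
        if r == "C":
            if i in cpg:
                continue
            if b == "T":
                converted += 1
            elif b == "C":
                unconverted += 1
        else:  # non-variable position: bisulfite leaves A/G/T untouched
            ident_total += 1
            ident_match += b == r

    conv = converted / (converted + unconverted) if converted + unconverted else None
    ident = ident_match / ident_total if ident_total else None
    return ReadProfile(
        read_id=read.id,
        amplicon=spec.name,
        calls=calls,
        conversion_rate_read=conv,
        identity=ident,
    )


def filter_profiles(
    profiles: Iterable[ReadProfile],
    min_conversion: float = 0.98,
    min_identity: float = 0.8,
    max_ambiguous: int = 0,
) -> tuple[list[ReadProfile], ConversionReport]:
    """Apply per-read QC and tally the outcome.

    A profile passes iff its read conversion is ≥ ``min_conversion``
    (undefined — no non-CpG C covered — treated as pass), identity ≥
    ``min_identity`` and it has at most ``max_ambiguous`` ambiguous CpG
    calls.  A read failing several checks is counted once, under the first
    failed check in the order conversion → identity → ambiguity.
    """
    profiles = list(profiles)
    passing: list[ReadProfile] = []
    failed = {"low_conversion": 0, "low_identity": 0, "ambiguous_calls": 0}
    convs = []
    for p in profiles:
        if p.conversion_rate_read is not None:
            convs.append(p.conversion_rate_read)
        if p.conversion_rate_read is not None and p.conversion_rate_read < min_conversion:
            reason = "low_conversion"
        elif p.identity is not None and p.identity < min_identity:
            reason = "low_identity"
        elif p.n_ambiguous > max_ambiguous:
            reason = "ambiguous_calls"
        else:
            reason = None
        p.passed_filters = reason is None
        p.fail_reason = reason
        if reason is None:
            passing.append(p)
        else:
            failed[reason] += 1
    report = ConversionReport(
        total=len(profiles),
        passing=len(passing),
        failed_by_reason={k: v for k, v in failed.items() if v},
        mean_read_conversion=float(np.mean(convs)) if convs else None,
    )
    return passing, report


def estimate_spikein_conversion(
    reads: Iterable[MergedRead],
    spikein_spec: AmpliconSpec,
    exclude_primers: bool = True,
) -> float | None:
    """Sample-level conversion efficiency from an unmethylated spike-in.

    The spike-in carries no true methylation, so *every* cytosine — CpG and
    non-CpG alike — should read T; the estimate is converted/(converted +
    unconverted) pooled over all covered reference-C positions of all reads.
    Returns ``None`` (with no covered C) rather than a fake number.
    """
    ref = spikein_spec.reference_seq
    lo = len(spikein_spec.fw_primer) if exclude_primers else 0
    hi = len(ref) - (len(spikein_spec.rv_primer) if exclude_primers else 0)
    c_positions = [i for i in range(lo, hi) if ref[i] == "C"]
    converted = unconverted = 0
    for read in reads:
        seq = read.sequence
        L = min(len(seq), len(ref))
        for i in c_positions:
            if i >= L:
                break
            b = seq[i]
            if b == "T":
                converted += 1
            elif b == "C":
                unconverted += 1
    total = converted + unconverted
    if total == 0:
        import warnings

        warnings.warn("spike-in conversion undefined: no covered C positions")
        return None
    return converted / total
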