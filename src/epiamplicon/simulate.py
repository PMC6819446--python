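"""Synthetic bisulfite / oxidative-bisulfite amplicon read generator.

Emulates a targeted deep bisulfite amplicon experiment with known ground
truth: mixtures of cell subpopulations with distinct per-CpG cytosine-state
distributions (C, 5mC, 5hmC), the two conversion chemistries, incomplete
conversion, sequencing error, and paired-end reads that overlap in the
middle of the amplicon.

Chemistry model (per CpG cytosine, independent across positions):

====== ============================ ============================
state  bisulfite (BS)               oxidative bisulfite (oxBS)
====== ============================ ============================
C      reads T w.p. conversion_rate reads T w.p. conversion_rate
5mC    reads T w.p. mc_failure_rate reads T w.p. mc_failure_rate
5hmC   reads C                      reads T w.p. oxbs_hmc_conversion
====== ============================ ============================

Non-CpG cytosines are unmethylated and read T w.p. ``conversion_rate``; this
is what per-read conversion QC measures.  The closed-form apparent
methylation these rules imply (see :class:`GroundTruth`) is the oracle every
downstream recovery test is checked against.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec, define_amplicon, derive_bisulfite_primers

__all__ = [
    "Population",
    "SimulationConfig",
    "GroundTruth",
    "simulate_molecules",
    "apply_chemistry",
    "emit_reads",
    "simulate_sample",
    "synthetic_promoter_amplicon",
    "synthetic_spikein_amplicon",
]

# integer state codes used in molecule matrices
STATE_C, STATE_5MC, STATE_5HMC = 0, 1, 2
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Population:
    """One cell subpopulation: mixture weight plus its epiallele make-up.

    Either ``site_probs`` — an (n_sites, 3) array of per-site probabilities
    over (C, 5mC, 5hmC), sites independent — or ``epiallele_probs`` — an
    explicit distribution over binary patterns ('1' = 5mC, '0' = C), which
    induces arbitrary between-site correlation.
    """

    fraction: float
    site_probs: np.ndarray | None = None
    epiallele_probs: Mapping[str, float] | None = None

    def __post_init__(self):
        if (self.site_probs is None) == (self.epiallele_probs is None):
            raise ValueError("give exactly one of site_probs / epiallele_probs")
        if self.site_probs is not None:
            p = np.asarray(self.site_probs, dtype=float)
            if p.ndim != 2 or p.shape[1] != 3:
                raise ValueError("site_probs must be (n_sites, 3)")
            if (p < 0).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("site_probs rows must be distributions")
            object.__setattr__(self, "site_probs", p)
        else:
            tot = sum(self.epiallele_probs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError("epiallele_probs must sum to 1")

    def n_sites(self) -> int:
        if self.site_probs is not None:
            return self.site_probs.shape[0]
        return len(next(iter(self.epiallele_probs)))

    def state_probs(self) -> np.ndarray:
        """(n_sites, 3) marginal state distribution."""
        if self.site_probs is not None:
            return self.site_probs
        n = self.n_sites()
        p = np.zeros((n, 3))
        for pat, w in self.epiallele_probs.items():
            for k, ch in enumerate(pat):
                p[k, STATE_5MC if ch == "1" else STATE_C] += w
        return p


@dataclass
class SimulationConfig:
    """Full generative description of one synthetic sample.

    Defaults mirror a typical targeted amplicon run on a MiSeq-class
    instrument: 281-cycle paired reads, ~10^4 molecules per sample,
    near-complete bisulfite conversion (0.995), rare conversion of 5mC
    (0.005), oxBS converting most but not all 5hmC (0.95), and a 0.1%
    per-base substitution error rate.
    """

    amplicon: AmpliconSpec
    populations: Sequence[Population]
    n_molecules: int = 10_000
    treatment: str = "BS"  # "BS" | "oxBS"
    conversion_rate: float = 0.995
    mc_failure_rate: float = 0.005
    oxbs_hmc_conversion: float = 0.95
    seq_error_rate: float = 0.001
    read_len: int = 281
    overlap_len: int | None = None  # derived from geometry when None
    seed: int | None = None

    def __post_init__(self):
        fr = sum(p.fraction for p in self.populations)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {fr}, not 1")
        for name in ("conversion_rate", "mc_failure_rate", "oxbs_hmc_conversion",
                     "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.treatment not in ("BS", "oxBS"):
            raise ValueError(f"treatment must be 'BS' or 'oxBS', got {self.treatment!r}")
        n = self.amplicon.n_sites
        for p in self.populations:
            if p.n_sites() != n:
                raise ValueError("population site count != amplicon CpG count")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Closed-form expectations implied by a :class:`SimulationConfig`.

    ``expected_bs`` / ``expected_oxbs`` are the apparent (read-out) per-site
    methylation fractions:

        E[BS]   = P(5mC)·(1−f_mC) + P(5hmC)            + P(C)·(1−c)
        E[oxBS] = P(5mC)·(1−f_mC) + P(5hmC)·(1−c_hmC)  + P(C)·(1−c)

    with c the conversion rate, f_mC the 5mC failure rate and c_hmC the
    oxBS 5hmC conversion rate.  The epiallele distribution is over the true
    methylated/unmethylated pattern, '1' meaning the site reads methylated
    under ideal BS chemistry (state 5mC or 5hmC).
    """

    mc_fraction: np.ndarray
    hmc_fraction: np.ndarray
    expected_bs: np.ndarray
    expected_oxbs: np.ndarray
    epiallele_probs: dict[str, float]
    states: np.ndarray = field(repr=False)  # (n_molecules, n_sites) int codes

    def true_patterns(self) -> list[str]:
        """Per-molecule ideal-BS epiallele strings ('1' = 5mC or 5hmC)."""
        meth = (self.states != STATE_C).astype(np.uint8)
        return ["".join("01"[v] for v in row) for row in meth]


def _mixture_state_probs(config: SimulationConfig) -> np.ndarray:
    n = config.amplicon.n_sites
    p = np.zeros((n, 3))
    for pop in config.populations:
        p += pop.fraction * pop.state_probs()
    return p


def _expected_epialleles(config: SimulationConfig) -> dict[str, float]:
    n = config.amplicon.n_sites
    out: dict[str, float] = {}
    for pop in config.populations:
        if pop.epiallele_probs is not None:
            for pat, w in pop.epiallele_probs.items():
                out[pat] = out.get(pat, 0.0) + pop.fraction * w
        else:
            p_meth = pop.site_probs[:, STATE_5MC] + pop.site_probs[:, STATE_5HMC]
            for bits in product("01", repeat=n):
                pat = "".join(bits)
                w = 1.0
                for k, ch in enumerate(pat):
                    w *= p_meth[k] if ch == "1" else 1.0 - p_meth[k]
                if w > 0:
                    out[pat] = out.get(pat, 0.0) + pop.fraction * w
    return out


def simulate_molecules(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, GroundTruth]:
    """Draw per-molecule CpG state vectors and their closed-form ground truth.

    Returns ``(states, truth)`` where ``states`` is an
    (n_molecules, n_sites) int array over {C=0, 5mC=1, 5hmC=2}.
    """
    rng = config.rng() if rng is None else rng
    n_mol, n_sites = config.n_molecules, config.amplicon.n_sites
    states = np.empty((n_mol, n_sites), dtype=np.int8)

    fracs = np.array([p.fraction for p in config.populations])
    assignment = rng.choice(len(fracs), size=n_mol, p=fracs)
    for pi, pop in enumerate(config.populations):
        idx = np.nonzero(assignment == pi)[0]
        if idx.size == 0:
            continue
        if pop.epiallele_probs is not None:
            pats = list(pop.epiallele_probs)
            probs = np.array([pop.epiallele_probs[p] for p in pats])
            # explicit patterns carry no 5hmC: '1' = 5mC, '0' = C
            pat_states = np.array(
                [[STATE_5MC if c == "1" else STATE_C for c in p] for p in pats],
                dtype=np.int8,
            )
            draw = rng.choice(len(pats), size=idx.size, p=probs / probs.sum())
            states[idx] = pat_states[draw]
        else:
            u = rng.random((idx.size, n_sites))
            cum = np.cumsum(pop.site_probs, axis=1)  # (n_sites, 3)
            states[idx] = (u[..., None] > cum[None, :, :2]).sum(axis=2)

    mix = _mixture_state_probs(config)
    p_c, p_mc, p_hmc = mix[:, STATE_C], mix[:, STATE_5MC], mix[:, STATE_5HMC]
    c, f, ox = config.conversion_rate, config.mc_failure_rate, config.oxbs_hmc_conversion
    truth = GroundTruth(
        mc_fraction=p_mc,
        hmc_fraction=p_hmc,
        expected_bs=p_mc * (1 - f) + p_hmc + p_c * (1 - c),
        expected_oxbs=p_mc * (1 - f) + p_hmc * (1 - ox) + p_c * (1 - c),
        epiallele_probs=_expected_epialleles(config),
        states=states,
    )
    return states, truth


def apply_chemistry(states: np.ndarray, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Convert molecules to post-treatment nucleotide sequences.

    Returns an (n_molecules, amplicon_length) uint8 array of ASCII bases.
    Non-CpG cytosines convert to T with probability ``conversion_rate``;
    CpG cytosines follow the state/treatment table in the module docstring.
    Sequencing error is *not* applied here (see :func:`emit_reads`).
    """
    rng = config.rng() if rng is None else rng
    spec = config.amplicon
    ref = np.frombuffer(spec.reference_seq.encode(), dtype=np.uint8)
    n_mol = states.shape[0]
    seqs = np.tile(ref, (n_mol, 1))

    cpg_idx = np.array(spec.site_indices, dtype=int)
    noncpg_c = np.array(
        [i for i, b in enumerate(spec.reference_seq) if b == "C"
         and i not in set(spec.site_indices)],
        dtype=int,
    )
    T, C = ord("T"), ord("C")

    if noncpg_c.size:
        conv = rng.random((n_mol, noncpg_c.size)) < config.conversion_rate
        block = np.where(conv, T, C).astype(np.uint8)
        seqs[:, noncpg_c] = block

    if cpg_idx.size:
        # per-state probability that the CpG cytosine reads T
        if config.treatment == "BS":
            p_t = np.array([config.conversion_rate, config.mc_failure_rate, 0.0])
        else:
            p_t = np.array([config.conversion_rate, config.mc_failure_rate,
                            config.oxbs_hmc_conversion])
        reads_t = rng.random(states.shape) < p_t[states]
        seqs[:, cpg_idx] = np.where(reads_t, T, C).astype(np.uint8)
    return seqs


def _inject_errors(reads: np.ndarray, rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform substitution errors: each base replaced by one of the 3 others."""
    if rate <= 0:
        return reads
    hit = rng.random(reads.shape) < rate
    if not hit.any():
        return reads
    reads = reads.copy()
    # draw an offset 1..3 in base space and rotate, guaranteeing a change
    base_idx = np.searchsorted(_BASES, reads[hit])
    offs = rng.integers(1, 4, size=base_idx.shape)
    reads[hit] = _BASES[(base_idx + offs) % 4]
    return reads


_RC = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _RC[a] = b


def emit_reads(seqs: np.ndarray, config: SimulationConfig,
               rng: np.random.Generator | None = None,
               out_prefix: str | Path | None = None,
               ) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Cut paired-end reads from full-length molecules.

    R1 is the 5′ window of the molecule, R2 the reverse complement of the 3′
    window; with read length ``r`` on a molecule of length ``L`` they overlap
    by ``2r − L``.  Substitution errors are injected at ``seq_error_rate``;
    qualities are a constant Q40 ('I').  Returns ``(r1, r2)`` as lists of
    ``(id, sequence, quality)`` records; when ``out_prefix`` is given the
    pairs are also written to ``<prefix>_R1.fastq.gz`` / ``_R2.fastq.gz``.

    Raises
    ------
    ValueError
        When the read geometry is impossible on this amplicon (read longer
        than the molecule, overlap shorter than requested).
    """
    rng = config.rng() if rng is None else rng
    L = seqs.shape[1] if seqs.size else len(config.amplicon)
    r = config.read_len
    if r > L:
        raise ValueError(f"read_len {r} exceeds amplicon length {L}")
    actual_overlap = 2 * r - L
    if config.overlap_len is not None and actual_overlap != config.overlap_len:
        raise ValueError(
            f"impossible geometry: read_len {r} on a {L}-nt amplicon overlaps "
            f"by {actual_overlap}, not the requested {config.overlap_len}"
        )
    if actual_overlap < 1:
        raise ValueError(
            f"impossible geometry: reads of {r} nt do not overlap on {L} nt"
        )

    n = seqs.shape[0]
    r1 = _inject_errors(seqs[:, :r], config.seq_error_rate, rng)
    r2w = _inject_errors(seqs[:, L - r:], config.seq_error_rate, rng)
    r2 = _RC[r2w][:, ::-1]  # reverse complement, read from the bottom strand 3'->5' end

    qual = "I" * r
    r1_recs = [(f"mol{i}", r1[i].tobytes().decode(), qual) for i in range(n)]
    r2_recs = [(f"mol{i}", r2[i].tobytes().decode(), qual) for i in range(n)]

    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        for suffix, recs in (("_R1.fastq.gz", r1_recs), ("_R2.fastq.gz", r2_recs)):
            # mtime=0 keeps seeded runs byte-identical
            with open(str(out_prefix) + suffix, "wb") as raw, \
                    gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                for rid, seq, q in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{q}\n".encode())
    return r1_recs, r2_recs


def simulate_sample(config: SimulationConfig, out_prefix: str | Path | None = None):
    """Full generator pass: molecules → chemistry → paired reads.

    Returns ``(r1_records, r2_records, truth)`` with one shared seeded RNG so
    a fixed ``config.seed`` reproduces the sample byte-for-byte.
    """
    rng = config.rng()
    states, truth = simulate_molecules(config, rng)
    seqs = apply_chemistry(states, config, rng)
    r1, r2 = emit_reads(seqs, config, rng, out_prefix=out_prefix)
    return r1, r2, truth


def truth_tables(truth: GroundTruth, spec: AmpliconSpec
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground truth as two tidy tables: per-site expectations, per-molecule states."""
    site = pd.DataFrame(
        {
            "site_label": spec.site_labels,
            "mc_fraction": truth.mc_fraction,
            "hmc_fraction": truth.hmc_fraction,
            "expected_bs": truth.expected_bs,
            "expected_oxbs": truth.expected_oxbs,
        }
    )
    mol = pd.DataFrame(
        truth.states,
        columns=[f"cpg_{lbl:+d}" for lbl in spec.site_labels],
    )
    mol.insert(0, "molecule", [f"mol{i}" for i in range(len(mol))])
    return site, mol


# ---------------------------------------------------------------------------
# synthetic reference constructs
# ---------------------------------------------------------------------------

def _random_seq_without_cpg(length: int, rng: np.random.Generator,
                            p: Sequence[float] = (0.28, 0.22, 0.22, 0.28)) -> list[str]:
    seq = list(rng.choice(list("ACGT"), size=length, p=list(p)))
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    return seq


def synthetic_promoter_amplicon(
    name: str = "DaoPR1_syn",
    length: int = 363,
    cpg_labels: Sequence[int] = (7, 101, 217, 334),
    seed: int = 20191028,
    primer_len: int = 20,
) -> AmpliconSpec:
    """Synthetic stand-in for a promoter bisulfite amplicon.

    A 363-nt construct starting at the TSS (+1) with CpG sites at exactly
    the TSS-relative labels given (defaults: +7, +101, +217, +334 — the
    configuration of a four-CpG promoter region downstream of a TSS) and no
    other CG dinucleotide.  The sequence itself is random (fixed seed) and is
    NOT the real promoter; it reproduces the coordinate geometry only.
    """
    rng = np.random.default_rng(seed)
    seq = _random_seq_without_cpg(length, rng)
    for lbl in cpg_labels:
        i = lbl - 1  # TSS at index 0 → label = index + 1
        if not 0 <= i < length - 1:
            raise ValueError(f"CpG label {lbl} outside the {length}-nt construct")
        seq[i], seq[i + 1] = "C", "G"
    # placing C/G may have created stray CpGs at the boundaries; scrub them
    wanted = {lbl - 1 for lbl in cpg_labels}
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in wanted:
            seq[i] = "T"
    ref = "".join(seq)
    spec = define_amplicon(name, ref, tss_index=0,
                           region_label=f"+1/+{length}")
    fw, rv = derive_bisulfite_primers(spec, primer_len)
    spec = define_amplicon(name, ref, tss_index=0, fw_primer=fw, rv_primer=rv,
                           region_label=f"+1/+{length}")
    assert spec.site_labels == tuple(cpg_labels), spec.site_labels
    return spec


def synthetic_spikein_amplicon(
    name: str = "M13_syn",
    length: int = 349,
    n_cpg: int = 8,
    seed: int = 5946,
    primer_len: int = 20,
) -> AmpliconSpec:
    """Synthetic stand-in for a fully unmethylated spike-in amplicon.

    Mirrors the role of an unmethylated phage double-strand control: a
    conversion-efficiency yardstick whose every cytosine (CpG and non-CpG)
    should read T after treatment.  Amplicon-local coordinates (no TSS).
    """
    rng = np.random.default_rng(seed)
    seq = _random_seq_without_cpg(length, rng)
    pos = np.sort(rng.choice(np.arange(primer_len + 2, length - primer_len - 2, 3),
                             size=n_cpg, replace=False))
    for i in pos:
        seq[i], seq[i + 1] = "C", "G"
    wanted = set(int(i) for i in pos)
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in wanted:
            seq[i] = "T"
    ref = "".join(seq)
    spec = define_amplicon(name, ref, tss_index=None)
    fw, rv = derive_bisulfite_primers(spec, primer_len)
    return define_amplicon(name, ref, tss_index=None, fw_primer=fw,
                           rv_primer=rv, region_label=f"1/{length}")


def unmethylated_config(spec: AmpliconSpec, n_molecules: int,
                        conversion_rate: float = 0.995,
                        seq_error_rate: float = 0.0,
                        read_len: int | None = None,
                        seed: int | None = None) -> SimulationConfig:
    """Convenience config for a fully unmethylated (spike-in style) sample."""
    n = spec.n_sites
    probs = np.zeros((n, 3))
    probs[:, STATE_C] = 1.0
    if read_len is None:
        read_len = (len(spec) + 41) // 2 + 1  # ≥41-nt overlap by default
    return SimulationConfig(
        amplicon=spec,
        populations=[Population(1.0, site_probs=probs)],
        n_molecules=n_molecules,
        treatment="BS",
        conversion_rate=conversion_rate,
        mc_failure_rate=0.0,
        seq_error_rate=seq_error_rate,
        read_len=read_len,
        seed=seed,
    )
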