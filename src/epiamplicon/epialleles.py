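"""Epiallele count tables, rarefaction, methylation summaries, PCA and HCA.

An *epiallele* is the arrangement of methylated (1) / unmethylated (0)
states across the CpG sites of one molecule, written as a binary string
with the leftmost character the most 5′ (upstream) site.  An amplicon with
n CpG sites has a pattern space of 2^n epialleles (16 for n = 4), and the
samples × patterns count table is the substrate for rarefaction, ordination
(PCA) and hierarchical clustering of samples by epiallelic composition.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec
from .reads import ReadProfile

__all__ = [
    "EpialleleTable",
    "SiteMethylationSummary",
    "OrdinationResult",
    "HCAResult",
    "ExpressionMeasurement",
    "all_patterns",
    "build_epiallele_table",
    "rarefy",
    "site_means",
    "group_summary",
    "pca_epialleles",
    "hca_epialleles",
    "delta_ct_expression",
]


def all_patterns(n_sites: int) -> list[str]:
    """The full 2^n binary pattern space, in ascending binary order."""
    return [format(i, f"0{n_sites}b") for i in range(2 ** n_sites)]


@dataclass
class EpialleleTable:
    """Samples × epiallele-pattern count matrix for one amplicon.

    ``counts`` is a pandas DataFrame indexed by sample with one column per
    pattern; all 2^n patterns are present (zero-filled), columns in binary
    order.  ``excluded_ambiguous`` counts profiles dropped because a pattern
    is a whole-molecule object and an ambiguous call leaves it undefined.
    """

    amplicon: str
    counts: pd.DataFrame
    excluded_ambiguous: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.patterns[0]) if len(self.patterns) else 0
        expected = all_patterns(n)
        if list(self.counts.columns) != expected:
            raise ValueError("columns must be the full pattern space in binary order")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def patterns(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_sites(self) -> int:
        return len(self.patterns[0])

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def proportions(self) -> pd.DataFrame:
        tot = self.totals()
        if (tot == 0).any():
            raise ValueError("cannot form proportions for a zero-total sample")
        return self.counts.div(tot, axis=0)

    # -- export ------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")

    def to_biom_json(self, path=None) -> str:
        """Serialise as a BIOM 1.0 (JSON dialect) dense table.

        BIOM stores observations (here epiallele patterns) as rows and
        samples as columns.  Hand-written against the published BIOM 1.0
        schema; no external dependency.
        """
        mat = self.counts.to_numpy().T  # observations x samples
        doc = {
            "id": self.amplicon,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "epiamplicon",
            "date": datetime.datetime.now().isoformat(),
            "rows": [{"id": p, "metadata": None} for p in self.patterns],
            "columns": [{"id": s, "metadata": None} for s in self.samples],
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [len(self.patterns), len(self.samples)],
            "data": mat.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_epiallele_table(
    profiles_by_sample: Mapping[str, Iterable[ReadProfile]],
    spec: AmpliconSpec,
) -> EpialleleTable:
    """Tally full-length epiallele patterns per sample.

    Profiles with any ambiguous CpG call are excluded (and counted in
    ``excluded_ambiguous``): the pattern is a property of the whole molecule.
    """
    pats = all_patterns(spec.n_sites)
    rows = {}
    excluded = {}
    for sample, profiles in profiles_by_sample.items():
        counts = dict.fromkeys(pats, 0)
        skipped = 0
        for p in profiles:
            if len(p.calls) != spec.n_sites:
                raise ValueError(
                    f"profile {p.read_id}: {len(p.calls)} calls vs "
                    f"{spec.n_sites} CpG sites in {spec.name}"
                )
            pat = p.pattern()
            if pat is None:
                skipped += 1
            else:
                counts[pat] += 1
        rows[sample] = counts
        excluded[sample] = skipped
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)[pats]
    df.index.name = "sample"
    return EpialleleTable(amplicon=spec.name, counts=df, excluded_ambiguous=excluded)


def rarefy(table: EpialleleTable, depth: int | None = None,
           seed: int | None = None) -> EpialleleTable:
    """Subsample every sample to a common depth, without replacement.

    Removes depth bias before composition analysis.  ``depth`` defaults to
    the smallest per-sample total; a depth above any sample's total is an
    error naming that sample.  Seeded and reproducible.
    """
    totals = table.totals()
    if depth is None:
        depth = int(totals.min())
    for s, t in totals.items():
        if depth > t:
            raise ValueError(f"depth {depth} exceeds total {t} of sample {s!r}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, s in enumerate(table.samples):
        row = table.counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return EpialleleTable(amplicon=table.amplicon, counts=df,
                          excluded_ambiguous=dict(table.excluded_ambiguous))


# ---------------------------------------------------------------------------
# per-CpG methylation summaries
# ---------------------------------------------------------------------------

@dataclass
class SiteMethylationSummary:
    """Per-sample, per-CpG coverage and mean methylation (percent).

    ``per_site``: tidy DataFrame (sample, site_label, coverage, methylated,
    mean_pct — NaN at zero coverage).  ``per_amplicon``: one row per sample
    with the amplicon mean, the *unweighted* average over site means.
    """

    amplicon: str
    per_site: pd.DataFrame
    per_amplicon: pd.DataFrame


def site_means(source, spec: AmpliconSpec,
               sample: str = "sample") -> SiteMethylationSummary:
    """Per-CpG methylation summary from profiles or from an epiallele table.

    ``source`` is either an :class:`EpialleleTable` (every molecule fully
    called, counts weighted by pattern) or a mapping sample → iterable of
    :class:`ReadProfile` (ambiguous calls excluded per site, not per read).
    Zero-coverage sites report a missing (NaN) mean, never 0.
    """
    labels = spec.site_labels
    rows = []
    if isinstance(source, EpialleleTable):
        pats = np.array([[c == "1" for c in p] for p in source.patterns], dtype=int)
        for s in source.samples:
            cnt = source.counts.loc[s].to_numpy()
            cov = int(cnt.sum())
            meth = cnt @ pats  # per-site methylated molecule counts
            for k, lbl in enumerate(labels):
                rows.append((s, lbl, cov, int(meth[k]),
                             100.0 * meth[k] / cov if cov else np.nan))
    else:
        for s, profiles in source.items():
            calls = np.array([p.calls for p in profiles], dtype=np.int8)
            if calls.size == 0:
                calls = np.empty((0, spec.n_sites), dtype=np.int8)
            for k, lbl in enumerate(labels):
                col = calls[:, k]
                cov = int((col != -1).sum())
                meth = int((col == 1).sum())
                rows.append((s, lbl, cov, meth,
                             100.0 * meth / cov if cov else np.nan))
    per_site = pd.DataFrame(
        rows, columns=["sample", "site_label", "coverage", "methylated", "mean_pct"]
    )
    per_amplicon = (
        per_site.groupby("sample", sort=False)["mean_pct"]
        .mean()  # unweighted over sites; NaN sites excluded by pandas
        .rename("amplicon_mean_pct")
        .reset_index()
    )
    return SiteMethylationSummary(amplicon=spec.name, per_site=per_site,
                                  per_amplicon=per_amplicon)


def group_summary(summary: SiteMethylationSummary,
                  groups: Mapping[str, str]) -> pd.DataFrame:
    """Group mean ± SEM across replicate samples (e.g. mice), per CpG site."""
    df = summary.per_site.copy()
    df["group"] = df["sample"].map(groups)
    out = (
        df.groupby(["group", "site_label"], sort=False)["mean_pct"]
        .agg(mean_pct="mean", sem_pct="sem", n="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# ordination and clustering
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCA of samples in epiallele-composition space.

    ``scores``: samples × PCs; ``loadings``: patterns × PCs; explained
    variance fractions are non-increasing and sum to ≤ 1.  ``degenerate``
    flags a zero-variance input (all samples identical).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    degenerate: bool = False


def pca_epialleles(table: EpialleleTable, scale: bool = False) -> OrdinationResult:
    """PCA on per-sample epiallele proportions.

    Counts are converted to proportions (so sequencing depth enters only via
    sampling noise), column-centered, and decomposed by SVD.  Unit-variance
    scaling is off by default — the biplot should weigh epialleles by their
    quantitative abundance, which scaling would erase — but is exposed for
    correlation-style PCA.  Each PC is oriented so its largest-magnitude
    loading is positive, making the output reproducible across BLAS builds.
    """
    if len(table.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = table.proportions().to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        nz = sd > 0
        X[:, nz] = X[:, nz] / sd[nz]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tot = float((S ** 2).sum())
    degenerate = tot <= 1e-300
    if degenerate:
        ratio = np.zeros_like(S)
    else:
        ratio = S ** 2 / tot
    scores = U * S
    loadings = Vt.T
    # sign convention: largest-|loading| entry of each PC is positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=table.counts.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=table.patterns, columns=pcs),
        explained_variance_ratio=ratio,
        degenerate=degenerate,
    )


@dataclass
class HCAResult:
    """Agglomerative clustering of samples by epiallele composition."""

    samples: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    def to_newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        root = to_tree(self.linkage)

        def walk(node, parent_dist):
            bl = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.samples[node.id]}:{bl:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{bl:.6g}"

        return walk(root, root.dist) + ";"

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()


def hca_epialleles(table: EpialleleTable, distance: str = "euclidean",
                   linkage: str = "average") -> HCAResult:
    """Hierarchical clustering of samples over epiallele proportion vectors.

    Defaults (Euclidean distance, average linkage) are declared package
    defaults; both are configurable.  Deterministic for a given input.
    """
    from scipy.cluster.hierarchy import linkage as scipy_linkage
    from scipy.spatial.distance import pdist

    if len(table.samples) < 2:
        raise ValueError("HCA needs at least 2 samples")
    X = table.proportions().to_numpy(dtype=float)
    Z = scipy_linkage(pdist(X, metric=distance), method=linkage)
    return HCAResult(samples=table.samples, linkage=Z)


# ---------------------------------------------------------------------------
# qPCR expression utility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMeasurement:
    """One qRT-PCR measurement normalised to two housekeeping genes."""

    ct_target: float
    ct_housekeeping_1: float
    ct_housekeeping_2: float

    @property
    def value(self) -> float:
        return delta_ct_expression(self.ct_target, self.ct_housekeeping_1,
                                   self.ct_housekeeping_2)


def delta_ct_expression(ct_target: float, ct_hk1: float, ct_hk2: float) -> float:
    """Relative expression as 2^−ΔCt against the mean of two housekeepers."""
    for v in (ct_target, ct_hk1, ct_hk2):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(ct_target - (ct_hk1 + ct_hk2) / 2.0)))
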