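"""5-hydroxymethylcytosine estimation by BS − oxBS subtraction.

Under plain bisulfite both 5mC and 5hmC read as methylated; oxidative
bisulfite first oxidises 5hmC so it converts and reads unmethylated.  The
per-CpG difference between the two apparent methylation levels therefore
estimates the 5hmC fraction:

    5hmC(site) ≈ mean_BS(site) − mean_oxBS(site)

Subtraction is done on per-sample means first and then averaged across
replicates, and the raw (possibly negative) difference is always reported
next to the zero-clamped value: a clearly negative difference is a QC
signal (arm imbalance, incomplete oxidation), not noise to hide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epialleles import SiteMethylationSummary

__all__ = ["HmCEstimate", "estimate_hmc"]


@dataclass
class HmCEstimate:
    """Per-CpG 5hmC estimates for one amplicon.

    ``per_site`` columns: site_label, bs_mean_pct, oxbs_mean_pct,
    hmc_raw_pct, hmc_clamped_pct, se_pct, n_bs, n_oxbs.  ``se_pct`` is the
    quadrature sum sqrt(SE_BS² + SE_oxBS²); with a single sample per arm the
    arm SE falls back to the binomial standard error from that arm's
    coverage.  Sites lacking coverage in either arm are NaN, not zero.
    """

    amplicon: str
    per_site: pd.DataFrame


def _arm_stats(summary: SiteMethylationSummary) -> pd.DataFrame:
    """Per-site mean across samples, SE, and replicate count for one arm."""
    df = summary.per_site.dropna(subset=["mean_pct"])
    rows = []
    for lbl, grp in df.groupby("site_label", sort=False):
        means = grp["mean_pct"].to_numpy(dtype=float)
        n = len(means)
        mean = means.mean() if n else np.nan
        if n > 1:
            se = means.std(ddof=1) / np.sqrt(n)
        elif n == 1:
            p = means[0] / 100.0
            cov = max(int(grp["coverage"].iloc[0]), 1)
            se = 100.0 * np.sqrt(p * (1 - p) / cov)
        else:
            se = np.nan
        rows.append((lbl, mean, se, n))
    return pd.DataFrame(rows, columns=["site_label", "mean", "se", "n"])


def estimate_hmc(bs: SiteMethylationSummary,
                 oxbs: SiteMethylationSummary) -> HmCEstimate:
    """Estimate per-CpG 5hmC (percent) from matched BS and oxBS summaries.

    Both summaries must describe the same amplicon and CpG labels; a site
    covered in only one arm is reported with an undefined (NaN) estimate.
    """
    if bs.amplicon != oxbs.amplicon:
        raise ValueError(
            f"amplicon mismatch: BS={bs.amplicon!r} vs oxBS={oxbs.amplicon!r}"
        )
    bs_labels = list(dict.fromkeys(bs.per_site["site_label"]))
    ox_labels = list(dict.fromkeys(oxbs.per_site["site_label"]))
    if bs_labels != ox_labels:
        raise ValueError(f"CpG label mismatch: {bs_labels} vs {ox_labels}")

    a = _arm_stats(bs).set_index("site_label")
    b = _arm_stats(oxbs).set_index("site_label")
    rows = []
    for lbl in bs_labels:
        bs_mean = a["mean"].get(lbl, np.nan)
        ox_mean = b["mean"].get(lbl, np.nan)
        if np.isnan(bs_mean) or np.isnan(ox_mean):
            raw = clamped = se = np.nan
        else:
            raw = bs_mean - ox_mean
            clamped = max(raw, 0.0)
            se = float(np.sqrt(np.nan_to_num(a["se"].get(lbl)) ** 2
                               + np.nan_to_num(b["se"].get(lbl)) ** 2))
        rows.append((lbl, bs_mean, ox_mean, raw, clamped, se,
                     int(a["n"].get(lbl, 0)), int(b["n"].get(lbl, 0))))
    per_site = pd.DataFrame(
        rows,
        columns=["site_label", "bs_mean_pct", "oxbs_mean_pct", "hmc_raw_pct",
                 "hmc_clamped_pct", "se_pct", "n_bs", "n_oxbs"],
    )
    return HmCEstimate(amplicon=bs.amplicon, per_site=per_site)
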