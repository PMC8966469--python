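"""Classification of distorted SNPs and regions into SA / SL / SD.

A SNP with evidence of sex-specific transmission distortion carries two
estimates, ``eps_m`` (distortion toward sons) and ``eps_f`` (toward
daughters).  The geometry of the pair determines the biological
reading:

* **sex-antagonistic (SA)** — distortion in both sexes, opposite
  directions (one allele favoured in sons, the other in daughters);
* **sex-limited (SL)** — distortion essentially confined to one sex;
* **sex-differential (SD)** — same direction in both sexes, different
  strengths.

The decision statistic is ``s = |eps_m + eps_f|`` compared with
``M = max(|eps_m|, |eps_f|)``: opposite signs shrink ``s`` below ``M``,
same signs push it above, and one near-zero epsilon leaves ``s ~ M``.
With a tolerance ``t`` (default 0.05, the genome-wide standard
deviation of the epsilon estimates) the partition is

    SA  if  s < M - t
    SL  if  |s - M| <= t
    SD  if  s > M + t

which is exhaustive and mutually exclusive.  Regions inherit the label
of their significant SNPs when a clear majority (default 75%) agrees,
and are labelled ``mixed`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClassifyConfig", "classify_snp", "classify_snps", "classify_region",
           "classify_regions"]

SA, SL, SD, MIXED = "SA", "SL", "SD", "mixed"


@dataclass
class ClassifyConfig:
    t: float = 0.05                # magnitude tolerance on |eps_m + eps_f|
    snp_alpha: float = 0.05        # per-SNP M2-vs-M0 significance cutoff
    region_majority: float = 0.75  # share of classified SNPs needed for a label

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if not 0 < self.snp_alpha < 1:
            raise ValueError("snp_alpha must lie in (0, 1)")
        if not 0.5 < self.region_majority <= 1:
            raise ValueError("region_majority must lie in (0.5, 1]")


def classify_snp(eps_m: float, eps_f: float,
                 config: ClassifyConfig | None = None) -> str:
    """Label one SNP as SA, SL or SD from its sex-specific estimates."""
    config = config or ClassifyConfig()
    if not (np.isfinite(eps_m) and np.isfinite(eps_f)):
        raise ValueError("both estimates must be finite")
    return classify_snps([eps_m], [eps_f], config)[0]


def classify_snps(eps_m, eps_f, config: ClassifyConfig | None = None):
    """Vectorized :func:`classify_snp`; returns an object array of labels."""
    config = config or ClassifyConfig()
    eps_m = np.asarray(eps_m, dtype=float)
    eps_f = np.asarray(eps_f, dtype=float)
    s = np.abs(eps_m + eps_f)
    m = np.maximum(np.abs(eps_m), np.abs(eps_f))
    labels = np.full(s.shape, SL, dtype=object)
    labels[s < m - config.t] = SA
    labels[s > m + config.t] = SD
    return labels


def classify_region(fits: pd.DataFrame,
                    config: ClassifyConfig | None = None) -> dict:
    """Label one local-score region from its per-SNP fits.

    Only SNPs whose M2-vs-M0 p-value (``p20``) is below ``snp_alpha``
    are classified.  If the modal category reaches ``region_majority``
    of the classified SNPs the region takes that label; otherwise it is
    ``mixed``.  A region with zero classifiable SNPs is ``mixed`` and
    flagged.

    Returns a dict with the label, per-category counts, and mean
    absolute-epsilon summaries over the classified SNPs.
    """
    config = config or ClassifyConfig()
    fits = pd.DataFrame(fits)
    if fits.empty:
        raise ValueError("region contains no SNPs")
    sig = fits[(fits["p20"] < config.snp_alpha)
               & fits["eps_m"].notna() & fits["eps_f"].notna()]
    result = {
        "n_snps": len(fits), "n_classified": len(sig),
        "n_sa": 0, "n_sl": 0, "n_sd": 0,
        "mean_abs_eps_m": np.nan, "mean_abs_eps_f": np.nan,
        "mean_abs_delta": np.nan, "no_classifiable_snps": sig.empty,
    }
    if sig.empty:
        result["label"] = MIXED
        return result
    labels = classify_snps(sig["eps_m"], sig["eps_f"], config)
    counts = pd.Series(labels).value_counts()
    result.update(n_sa=int(counts.get(SA, 0)), n_sl=int(counts.get(SL, 0)),
                  n_sd=int(counts.get(SD, 0)))
    result["mean_abs_eps_m"] = float(sig["eps_m"].abs().mean())
    result["mean_abs_eps_f"] = float(sig["eps_f"].abs().mean())
    result["mean_abs_delta"] = float((sig["eps_m"] - sig["eps_f"]).abs().mean())
    modal = counts.idxmax()
    share = counts.max() / counts.sum()
    result["label"] = modal if share >= config.region_majority else MIXED
    return result


def classify_regions(fits: pd.DataFrame, regions: pd.DataFrame,
                     config: ClassifyConfig | None = None) -> pd.DataFrame:
    """Label every called region.

    ``regions`` needs columns chrom/start/end (1-based inclusive);
    ``fits`` needs chrom/pos/eps_m/eps_f/p20.  SNP membership is by
    coordinate containment.
    """
    config = config or ClassifyConfig()
    rows = []
    for _, reg in pd.DataFrame(regions).iterrows():
        in_reg = fits[(fits["chrom"] == reg["chrom"])
                      & (fits["pos"] >= reg["start"])
                      & (fits["pos"] <= reg["end"])]
        if in_reg.empty:
            rows.append({"chrom": reg["chrom"], "start": reg["start"],
                         "end": reg["end"], "label": MIXED, "n_snps": 0,
                         "n_classified": 0, "n_sa": 0, "n_sl": 0, "n_sd": 0,
                         "mean_abs_eps_m": np.nan, "mean_abs_eps_f": np.nan,
                         "mean_abs_delta": np.nan, "no_classifiable_snps": True})
            continue
        res = classify_region(in_reg, config)
        res.update(chrom=reg["chrom"], start=reg["start"], end=reg["end"])
        rows.append(res)
    cols = ["chrom", "start", "end", "label", "n_snps", "n_classified",
            "n_sa", "n_sl", "n_sd", "mean_abs_eps_m", "mean_abs_eps_f",
            "mean_abs_delta", "no_classifiable_snps"]
    return pd.DataFrame(rows, columns=cols)
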