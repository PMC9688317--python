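"""Depletion-ratio hit calling for a pooled dropout screen.

Counts are depth-normalized to counts-per-million (CPM), each shRNA gets a
treated:control representation ratio r = (treated_cpm + c)/(control_cpm + c)
with pseudocount c, and a gene is called a sensitizing hit when at least
``min_concordant`` of its shRNA species are depleted below ``ratio_threshold``
(both criteria taken literally: "at least three" of five species, ratio
strictly "less than 0.3").
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .deconv import CountTable

__all__ = [
    "normalize_cpm",
    "representation_ratios",
    "call_hits",
    "write_hit_report",
    "read_hit_report",
    "HitCaller",
]


def normalize_cpm(count_table: CountTable) -> pd.DataFrame:
    """Counts-per-million over assigned reads; each column sums to 1e6."""
    totals = count_table.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-depth sample(s): {bad}")
    return count_table.counts / totals * 1e6


def representation_ratios(
    cpm_control: pd.Series,
    cpm_treated: pd.Series,
    genes: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-shRNA treated:control representation ratios.

    With pseudocount 0, shRNAs at zero control CPM have an undefined ratio;
    they are flagged ``usable == False`` and excluded from hit calling.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if not cpm_control.index.equals(cpm_treated.index):
        cpm_treated = cpm_treated.reindex(cpm_control.index)
        if cpm_treated.isna().any():
            raise ValueError("control and treated tables cover different shRNA sets")
    denom = cpm_control + pseudocount
    numer = cpm_treated + pseudocount
    usable = denom > 0
    ratio = pd.Series(np.nan, index=cpm_control.index)
    ratio[usable] = numer[usable] / denom[usable]
    return pd.DataFrame(
        {
            "gene": genes.reindex(cpm_control.index),
            "control_cpm": cpm_control,
            "treated_cpm": cpm_treated,
            "ratio": ratio,
            "usable": usable,
        }
    ).rename_axis("shrna_id")


def call_hits(
    ratios: pd.DataFrame,
    ratio_threshold: float = 0.3,
    min_concordant: int = 3,
) -> pd.DataFrame:
    """Call sensitizing hit genes from per-shRNA representation ratios.

    A gene is a hit when at least ``min_concordant`` of its shRNA species
    have ratio strictly below ``ratio_threshold``. Output is one row per gene
    (n_shrnas, n_depleted, is_hit, min_ratio, median_ratio), sorted by
    (n_depleted descending, median_ratio ascending, gene id) for stable
    reporting. Genes with no usable ratio are excluded with a warning.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be > 0")
    if min_concordant < 1:
        raise ValueError("min_concordant must be >= 1")
    usable = ratios[ratios.get("usable", True)] if "usable" in ratios else ratios
    dropped = set(ratios["gene"]) - set(usable["gene"])
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} gene(s) with no usable ratios: {sorted(dropped)[:5]}...",
            stacklevel=2,
        )
    grouped = usable.groupby("gene")["ratio"]
    out = pd.DataFrame(
        {
            "n_shrnas": grouped.size(),
            "n_depleted": grouped.apply(lambda r: int((r < ratio_threshold).sum())),
            "min_ratio": grouped.min(),
            "median_ratio": grouped.median(),
        }
    )
    out["is_hit"] = out["n_depleted"] >= min_concordant
    out = out.sort_values(
        by=["n_depleted", "median_ratio"], ascending=[False, True], kind="mergesort"
    )
    # stable tie-break on gene id
    out = (
        out.reset_index()
        .sort_values(by=["n_depleted", "median_ratio", "gene"], ascending=[False, True, True])
        .set_index("gene")
    )
    return out[["n_shrnas", "n_depleted", "is_hit", "min_ratio", "median_ratio"]]


def write_hit_report(results: pd.DataFrame, path) -> None:
    """TSV hit report, one row per gene."""
    results.rename_axis("gene").to_csv(path, sep="\t")


def read_hit_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if "is_hit" in df:
        df["is_hit"] = df["is_hit"].astype(bool)
    return df


class HitCaller(BaseEstimator):
    """Screen hit-calling estimator.

    Normalizes control and treated count tables to CPM, forms per-shRNA
    representation ratios with a pseudocount, and flags genes whose shRNAs
    are concordantly depleted.

    Parameters
    ----------
    ratio_threshold : float, default 0.3
        Strict upper bound on the treated:control ratio for a species to
        count as depleted.
    min_concordant : int, default 3
        Minimum number of depleted species for a gene to be a hit.
    pseudocount : float, default 0.5
        Added to both CPM values before forming the ratio.

    Attributes
    ----------
    ratios_ : pandas.DataFrame
        Per-shRNA ratios from the last fit.
    results_ : pandas.DataFrame
        Per-gene hit table.
    hit_genes_ : list of str
        Genes called as hits, in report order.
    """

    def __init__(
        self,
        ratio_threshold: float = 0.3,
        min_concordant: int = 3,
        pseudocount: float = 0.5,
    ):
        self.ratio_threshold = ratio_threshold
        self.min_concordant = min_concordant
        self.pseudocount = pseudocount

    def fit(self, control: CountTable, treated: CountTable):
        cpm_c = normalize_cpm(control).iloc[:, 0]
        cpm_t = normalize_cpm(treated).iloc[:, 0]
        self.ratios_ = representation_ratios(
            cpm_c, cpm_t, control.genes, pseudocount=self.pseudocount
        )
        self.results_ = call_hits(
            self.ratios_,
            ratio_threshold=self.ratio_threshold,
            min_concordant=self.min_concordant,
        )
        self.hit_genes_ = self.results_.index[self.results_["is_hit"]].tolist()
        return self

    def predict(self, control: CountTable, treated: CountTable) -> list[str]:
        """Fit and return the called hit genes."""
        return self.fit(control, treated).hit_genes_
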