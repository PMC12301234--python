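"""Quantitative assay analyses around the discovery campaign.

Three independent analyses share this module:

* **Epitope binning** from pairwise SPR cross-competition: relative binding
  responses (fraction of the no-competitor control) are binarized at a
  blocking threshold and antibodies with identical symmetrized blocking
  patterns share a bin.
* **Hydroxyl-radical footprinting protection**: per-peptide modification
  fractions (modified / total XIC area) in antibody-bound vs unbound states
  are compared by percent fold-change and a two-sample equal-variance
  Student's t-test; decreased modification on binding is "protection",
  increased is "deprotection".
* **Tumor growth inhibition**: TGI% = [1 - (Tt - T0)/(Ct - C0)] x 100
  comparing treated and control mean tumor-volume gains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------- binning

def binarize_competition(matrix: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Binarize a ligand x analyte relative-response matrix.

    A pair is *blocked* (competitive) when the analyte's response in the
    presence of the immobilized ligand falls below ``threshold`` of the
    no-competitor control. Missing cells stay missing (masked) and are
    excluded from pattern comparison downstream.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("relative responses must be non-negative")
    blocked = matrix < threshold
    return blocked.where(matrix.notna())  # keep NaN mask


@dataclass
class BinAssignment:
    bins: dict[str, int]  # antibody -> bin id (1-based)

    @property
    def n_bins(self) -> int:
        return len(set(self.bins.values()))

    def members(self, bin_id: int) -> list[str]:
        return sorted(ab for ab, b in self.bins.items() if b == bin_id)


def assign_bins(blocked: pd.DataFrame) -> BinAssignment:
    """Group antibodies with identical blocking patterns into bins.

    The matrix is restricted to antibodies present as both ligand and
    analyte and symmetrized by logical OR of the (ligand, analyte) and
    (analyte, ligand) cells (competition is mutual; either orientation
    suffices). Antibodies with identical symmetrized rows share a bin.
    Bins are numbered 1..n by decreasing size, ties by the lexicographically
    smallest member. Invariant to row/column permutation of the input.
    """
    common = sorted(set(blocked.index) & set(blocked.columns))
    if not common:
        raise ValueError("no antibodies present as both ligand and analyte")
    sub = blocked.loc[common, common]
    arr = sub.to_numpy(dtype=object)
    n = len(common)
    sym = np.empty((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            a, b = arr[i, j], arr[j, i]
            vals = [bool(v) for v in (a, b) if not pd.isna(v)]
            sym[i, j] = (any(vals) if vals else None)
    patterns: dict[tuple, list[str]] = {}
    for i, ab in enumerate(common):
        patterns.setdefault(tuple(sym[i]), []).append(ab)
    groups = sorted(patterns.values(), key=lambda g: (-len(g), sorted(g)[0]))
    bins = {ab: b + 1 for b, group in enumerate(groups) for ab in group}
    return BinAssignment(bins=bins)


# ----------------------------------------------------------- footprinting

def modification_fraction(xic_modified: float, xic_total: float) -> float:
    """Modified / total XIC peak area for one peptide observation."""
    if xic_total <= 0:
        raise ValueError("xic_total must be positive")
    if not (0 <= xic_modified <= xic_total):
        raise ValueError("xic_modified must lie in [0, xic_total]")
    return xic_modified / xic_total


@dataclass
class FootprintResult:
    peptide_id: str
    mean_bound: float
    mean_unbound: float
    log2_fold_change: float
    percent_fold_change: float
    t_statistic: float
    p_value: float
    call: str  # protected | deprotected | unchanged


def footprint_test(
    bound: Sequence[float],
    unbound: Sequence[float],
    alpha: float = 0.05,
    peptide_id: str = "",
    fold_change_mode: str = "percent_diff",
) -> FootprintResult:
    """Protection/deprotection call for one peptide.

    ``bound``/``unbound`` are replicate modification fractions in the two
    states. Percent fold-change is the signed difference over the unbound
    baseline, 100*(mean_bound - mean_unbound)/mean_unbound (``ratio`` mode
    reports 100*mean_bound/mean_unbound instead). Significance is a
    two-sided two-sample Student's t-test with pooled variance. Protection:
    negative change and p < alpha; deprotection: positive and p < alpha.
    """
    bound = np.asarray(bound, dtype=float)
    unbound = np.asarray(unbound, dtype=float)
    if len(bound) < 2 or len(unbound) < 2:
        raise ValueError("need >= 2 replicates per state")
    mb, mu = bound.mean(), unbound.mean()
    if mu == 0:
        raise ValueError("unbound mean is zero; fold-change undefined")
    if fold_change_mode == "percent_diff":
        pct = 100.0 * (mb - mu) / mu
    elif fold_change_mode == "ratio":
        pct = 100.0 * mb / mu
    else:
        raise ValueError(f"unknown fold_change_mode {fold_change_mode!r}")
    log2fc = float(np.log2(mb / mu)) if mb > 0 else float("-inf")
    t_stat, p_val = sps.ttest_ind(bound, unbound, equal_var=True)
    diff = mb - mu
    if p_val < alpha and diff < 0:
        call = "protected"
    elif p_val < alpha and diff > 0:
        call = "deprotected"
    else:
        call = "unchanged"
    return FootprintResult(peptide_id=peptide_id, mean_bound=float(mb),
                           mean_unbound=float(mu), log2_fold_change=log2fc,
                           percent_fold_change=float(pct),
                           t_statistic=float(t_stat), p_value=float(p_val),
                           call=call)


def footprint_table(
    records: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Run :func:`footprint_test` per peptide on a long-format table.

    ``records`` columns: peptide_id, state (bound|unbound), replicate,
    xic_modified, xic_total. With ``bh_correct`` the p-values are
    Benjamini-Hochberg adjusted before calls are made.
    """
    required = {"peptide_id", "state", "xic_modified", "xic_total"}
    if not required <= set(records.columns):
        raise ValueError(f"missing columns: {required - set(records.columns)}")
    fracs = records.assign(
        fraction=[modification_fraction(m, t) for m, t in
                  zip(records["xic_modified"], records["xic_total"])])
    results = []
    for pid, grp in fracs.groupby("peptide_id", sort=True):
        res = footprint_test(grp.loc[grp["state"] == "bound", "fraction"],
                             grp.loc[grp["state"] == "unbound", "fraction"],
                             alpha=alpha, peptide_id=str(pid))
        results.append(res.__dict__)
    df = pd.DataFrame(results)
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["p_adjusted"] = p_adj
        sign = np.sign(df["percent_fold_change"])
        df["call"] = np.where(p_adj >= alpha, "unchanged",
                              np.where(sign < 0, "protected", "deprotected"))
    return df


# -------------------------------------------------------------------- TGI

def compute_tgi(t0: float, tt: float, c0: float, ct: float) -> float:
    """Tumor growth inhibition percent.

    TGI% = [1 - (Tt - T0)/(Ct - C0)] x 100 with T/C the treated/control
    mean tumor volumes at baseline (0) and time t. Undefined when the
    control does not change (Ct == C0).
    """
    for name, v in (("T0", t0), ("Tt", tt), ("C0", c0), ("Ct", ct)):
        if v <= 0:
            raise ValueError(f"{name} must be a positive volume")
    if ct == c0:
        raise ValueError("TGI undefined: control volume unchanged (Ct == C0)")
    return (1.0 - (tt - t0) / (ct - c0)) * 100.0
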