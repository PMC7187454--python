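"""Integration of CpG methylation with chromatin-state segmentations.

CpG sites (array-style beta values before/after differentiation, with a
precomputed differential-methylation significance flag) are intersected
with a chromatin-state segmentation; per-state methylation summaries and
a permutation chi-square test of state/demethylation independence are
computed.  Significance calling itself is an input, not computed here.

Site coordinates are 1-based (array convention) and are converted once,
at assignment time, to the package's 0-based frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .segmentation import Segmentation

__all__ = [
    "CpGTable",
    "assign_cpgs",
    "summarize_states",
    "permutation_chisq",
    "ChiSquareResult",
]

_COLUMNS = ["chrom", "pos", "beta_before", "beta_after", "significant", "direction"]


@dataclass
class CpGTable:
    """CpG sites with paired-condition beta values and significance flags.

    ``pos`` is 1-based.  ``direction`` is ``"hypo"``/``"hyper"`` for
    significant sites and empty otherwise.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CpG table missing columns {missing}")
        if (df["pos"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        for col in ("beta_before", "beta_after"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("(chrom, pos) pairs must be unique")
        self.sites = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def delta_beta(self) -> pd.Series:
        return self.sites["beta_after"] - self.sites["beta_before"]

    def hypo_flags(self) -> np.ndarray:
        """Significant-and-hypomethylated (demethylated) flag per site."""
        df = self.sites
        return (df["significant"] & (df["direction"] == "hypo")).to_numpy()

    # -- TSV I/O ------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CpGTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["significant"] = df["significant"].astype(bool)
        df["direction"] = df["direction"].fillna("").astype(str)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)


def assign_cpgs(cpgs: CpGTable, seg: Segmentation) -> np.ndarray:
    """State index of the bin containing each site; -1 for unassigned.

    A 1-based site at ``pos`` is the 0-based point interval
    ``[pos-1, pos)``, so its bin is ``(pos-1) // bin_size``.  Sites on
    chromosomes absent from the layout, or beyond a chromosome end, are
    flagged unassigned rather than erroring.
    """
    layout = seg.layout
    out = np.full(len(cpgs), -1, dtype=np.int32)
    for chrom, grp in cpgs.sites.groupby("chrom", sort=False):
        if not layout.has_chrom(str(chrom)):
            continue
        ci = layout.chrom_index(str(chrom))
        pos0 = grp["pos"].to_numpy() - 1
        ok = pos0 < layout.chrom_lengths[ci]
        bins = layout.chrom_offsets[ci] + pos0[ok] // layout.bin_size
        out[grp.index[ok]] = seg.states[bins]
    return out


def summarize_states(
    cpgs: CpGTable, assignments: np.ndarray, seg: Segmentation
) -> pd.DataFrame:
    """Per-state methylation summary table.

    One row per model state with: CpG count, mean/median beta in each
    condition, mean delta beta, count and fraction of significant
    hypomethylated (demethylated) sites, plus the two headline
    percentages — ``pct_all`` (share of all assigned CpGs in the state)
    and ``pct_demeth`` (share of all demethylated CpGs in the state).
    """
    assignments = np.asarray(assignments)
    assigned = assignments >= 0
    if not assigned.any():
        raise ValueError("no CpG site falls inside the layout")
    df = cpgs.sites.loc[assigned]
    state = assignments[assigned]
    hypo = cpgs.hypo_flags()[assigned]
    n_total = len(df)
    n_hypo_total = int(hypo.sum())
    if n_hypo_total == 0:
        warnings.warn("no significant demethylated CpGs; pct_demeth is all zero")
    rows = []
    for k in range(seg.n_states):
        sel = state == k
        n = int(sel.sum())
        sub = df.loc[sel]
        nh = int(hypo[sel].sum())
        rows.append(
            {
                "state": seg.label_of(k),
                "n_cpgs": n,
                "mean_beta_before": sub["beta_before"].mean() if n else np.nan,
                "median_beta_before": sub["beta_before"].median() if n else np.nan,
                "mean_beta_after": sub["beta_after"].mean() if n else np.nan,
                "median_beta_after": sub["beta_after"].median() if n else np.nan,
                "mean_delta_beta": (
                    (sub["beta_after"] - sub["beta_before"]).mean() if n else np.nan
                ),
                "n_demethylated": nh,
                "frac_demethylated": nh / n if n else 0.0,
                "pct_all": 100.0 * n / n_total,
                "pct_demeth": (
                    100.0 * nh / n_hypo_total if n_hypo_total else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ChiSquareResult:
    """Pearson chi-square of the states x {significant, not} table."""

    statistic: float
    df: int
    p_perm: float
    p_asymptotic: float
    n_perm: int
    seed: int
    table: pd.DataFrame


def _pearson_stat(sig: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Chi-square statistic(s) for per-state significant counts.

    ``sig`` may be (K,) or (n_perm, K); ``totals`` is the per-state site
    count.  Margins are fixed, so expectations follow from totals alone.
    """
    sig = np.atleast_2d(sig).astype(np.float64)
    n = totals.sum()
    s_tot = sig.sum(axis=1)
    e_sig = totals * (s_tot[:, None] / n)
    e_not = totals - e_sig
    not_ = totals - sig
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = ((sig - e_sig) ** 2 / e_sig + (not_ - e_not) ** 2 / e_not).sum(axis=1)
    return stat


def permutation_chisq(
    assignments: np.ndarray,
    significant: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    state_labels: list[str] | None = None,
) -> ChiSquareResult:
    """Test independence of significance flags and chromatin state.

    The observed statistic is the Pearson chi-square on the states x
    {significant, not-significant} contingency table.  The null
    distribution permutes the significance flags across sites (margins
    preserved); per-state significant counts under a flag permutation
    follow the multivariate hypergeometric distribution, which is what is
    sampled.  The p-value uses the add-one estimator
    ``(1 + #{perm >= obs}) / (1 + n_perm)`` and is therefore never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    assignments = np.asarray(assignments)
    significant = np.asarray(significant, dtype=bool)
    keep = assignments >= 0
    a, s = assignments[keep], significant[keep]
    states_present = np.unique(a)
    if state_labels is not None:
        absent = [
            lab
            for k, lab in enumerate(state_labels)
            if k not in set(states_present.tolist())
        ]
        if absent:
            warnings.warn(f"states with zero sites dropped from table: {absent}")
    if len(states_present) < 2:
        raise ValueError("need at least 2 states with assigned sites")
    totals = np.array([(a == k).sum() for k in states_present], dtype=np.int64)
    sig_counts = np.array(
        [(s & (a == k)).sum() for k in states_present], dtype=np.int64
    )
    observed = float(_pearson_stat(sig_counts, totals)[0])

    rng = np.random.default_rng(seed)
    n_sig = int(sig_counts.sum())
    perm_sig = rng.multivariate_hypergeometric(totals, n_sig, size=n_perm)
    perm_stats = _pearson_stat(perm_sig, totals)
    p_perm = (1 + int((perm_stats >= observed).sum())) / (1 + n_perm)

    dof = len(states_present) - 1
    labels = (
        [state_labels[k] for k in states_present]
        if state_labels is not None
        else [str(k) for k in states_present]
    )
    table = pd.DataFrame(
        {
            "state": labels,
            "significant": sig_counts,
            "not_significant": totals - sig_counts,
        }
    )
    return ChiSquareResult(
        statistic=observed,
        df=dof,
        p_perm=p_perm,
        p_asymptotic=float(chi2.sf(observed, dof)),
        n_perm=n_perm,
        seed=seed,
        table=table,
    )
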