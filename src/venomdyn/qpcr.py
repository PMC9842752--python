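"""Diploid copy-number estimation from multiplex qPCR by delta-delta-Ct.

Each individual is amplified in triplicate multiplex reactions measuring
a target gene (the toxin cluster) and a single-copy control gene.
Reactions whose Cq deviates by more than 0.2 cycles within a triplicate
(for either gene) are dropped; per-reaction dCt = Cq_target - Cq_control
is averaged per individual; ddCt subtracts the mean dCt of a reference
calibrator of known copy number; and

    copies = calibrator_copies * 2 ** (-ddCt)

assuming both assays amplify with efficiency 2, validated beforehand on
a dilution series (slope of Cq on log10 input mass; efficiency
E = 10^(-1/slope) - 1 must lie in 90-110%). Population differences are
tested by two-way ANOVA (copies ~ population * plate, Type II sums of
squares for the unbalanced design) with Tukey HSD letters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from venomdyn.errors import CalibratorMissingError

__all__ = [
    "CqRecord",
    "CopyNumberEstimate",
    "EfficiencyFit",
    "filter_triplicates",
    "estimate_copy_number",
    "fit_efficiency",
    "population_anova",
]

REQUIRED_COLUMNS = ["individual", "population", "plate", "replicate", "cq_target", "cq_control"]


@dataclass
class CqRecord:
    individual: str
    population: str
    plate: str
    replicate: int
    cq_target: float
    cq_control: float


@dataclass
class CopyNumberEstimate:
    individual: str
    population: str
    mean_dct: float
    ddct: float
    copies: float


@dataclass
class EfficiencyFit:
    gene: str
    slope: float
    efficiency: float
    accepted: bool


def _spread(values: np.ndarray) -> float:
    return float(values.max() - values.min())


def _triplicate_drop(cq: np.ndarray, tol: float) -> int | None | str:
    """Index of the single reaction to drop, None to keep all, 'all' to drop all."""
    if _spread(cq) <= tol:
        return None
    candidates = []
    for i in range(len(cq)):
        rest = np.delete(cq, i)
        if len(rest) >= 2 and _spread(rest) <= tol:
            candidates.append((abs(cq[i] - rest.mean()), i))
    if not candidates:
        return "all"
    return max(candidates)[1]  # the most outlying restoring candidate


def filter_triplicates(
    records: pd.DataFrame, tol: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the triplicate-consistency filter per individual x plate.

    Within each triplicate and gene: keep all reactions when the maximum
    pairwise Cq difference is within ``tol``; otherwise drop the single
    most-outlying reaction whose removal restores tolerance; if no single
    removal suffices, drop the whole triplicate. Because reactions are
    multiplexed, a reaction dropped for one gene is dropped for both.
    Groups left with fewer than 2 consistent reactions are excluded.

    Returns (retained records, drop log with columns individual, plate,
    replicate, reason).
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    kept_parts = []
    dropped = []
    for (ind, plate), grp in records.groupby(["individual", "plate"], sort=False):
        grp = grp.sort_values("replicate")
        drop_idx: set[int] = set()
        reason = {}
        for gene in ("cq_target", "cq_control"):
            d = _triplicate_drop(grp[gene].to_numpy(float), tol)
            if d == "all":
                drop_idx = set(range(len(grp)))
                reason = {i: f"triplicate spread > {tol} for {gene}" for i in drop_idx}
                break
            if d is not None:
                drop_idx.add(d)
                reason[d] = f"outlier for {gene}"
        surviving = grp.iloc[[i for i in range(len(grp)) if i not in drop_idx]]
        # re-check both genes on the survivors (a drop for one gene may
        # leave the other still out of tolerance)
        if len(surviving) >= 2:
            for gene in ("cq_target", "cq_control"):
                if _spread(surviving[gene].to_numpy(float)) > tol:
                    for i in range(len(grp)):
                        if i not in drop_idx:
                            drop_idx.add(i)
                            reason[i] = f"residual spread > {tol} for {gene}"
                    surviving = surviving.iloc[0:0]
                    break
        if len(surviving) < 2:
            for i in range(len(grp)):
                reason.setdefault(i, "fewer than 2 surviving reactions")
            drop_idx = set(range(len(grp)))
            surviving = grp.iloc[0:0]
        kept_parts.append(surviving)
        for i in sorted(drop_idx):
            dropped.append(
                {
                    "individual": ind,
                    "plate": plate,
                    "replicate": grp.iloc[i]["replicate"],
                    "reason": reason.get(i, "dropped"),
                }
            )
    kept = pd.concat(kept_parts) if kept_parts else records.iloc[0:0]
    return kept, pd.DataFrame(dropped, columns=["individual", "plate", "replicate", "reason"])


def estimate_copy_number(
    records: pd.DataFrame,
    calibrator: str,
    calibrator_copies: float = 1.0,
) -> pd.DataFrame:
    """Per-individual diploid copy number by delta-delta-Ct.

    ``records`` should already be triplicate-filtered. Per-reaction
    dCt = cq_target - cq_control; mean dCt per individual; ddCt relative
    to the calibrator individual; copies = calibrator_copies * 2^(-ddCt).
    """
    df = records.copy()
    df["dct"] = df["cq_target"] - df["cq_control"]
    mean_dct = df.groupby("individual")["dct"].mean()
    if calibrator not in mean_dct.index:
        raise CalibratorMissingError(f"calibrator {calibrator!r} absent from records")
    ddct = mean_dct - mean_dct[calibrator]
    copies = calibrator_copies * np.power(2.0, -ddct)
    pops = df.groupby("individual")["population"].first()
    out = pd.DataFrame(
        {
            "population": pops,
            "mean_dct": mean_dct,
            "ddct": ddct,
            "copies": copies,
        }
    )
    out.index.name = "individual"
    return out


def fit_efficiency(masses_ng: np.ndarray, cq: np.ndarray, gene: str = "") -> EfficiencyFit:
    """Amplification efficiency from a dilution series.

    OLS of Cq on log10(input mass); E = 10^(-1/slope) - 1, accepted when
    0.90 <= E <= 1.10 (the perfect-doubling slope is -3.3219).
    """
    masses_ng = np.asarray(masses_ng, float)
    cq = np.asarray(cq, float)
    if len(np.unique(masses_ng)) < 3:
        raise ValueError("need at least 3 distinct input masses")
    slope, _ = np.polyfit(np.log10(masses_ng), cq, 1)
    if slope >= 0:
        warnings.warn(f"non-amplifying dilution series for {gene!r} (slope >= 0)")
    order = np.argsort(masses_ng)
    if np.any(np.diff(cq[order]) > 0):
        warnings.warn(f"non-monotonic dilution series for {gene!r}")
    eff = 10.0 ** (-1.0 / slope) - 1.0
    return EfficiencyFit(gene, float(slope), float(eff), bool(0.90 <= eff <= 1.10))


def _tukey_letters(groups: list[str], reject: dict[frozenset, bool]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb over pairwise rejections."""
    letters: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not reject.get(frozenset((a, b)), False):
            continue
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                sa, sb = s - {b}, s - {a}
                if not any(sa <= t for t in letters):
                    letters.append(sa)
                if not any(sb <= t for t in letters):
                    letters.append(sb)
    letters.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        for g in s:
            out[g] += alphabet[i]
    return out


def population_anova(
    estimates: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Two-way Type II ANOVA of copy number on population x plate, with Tukey HSD.

    ``estimates`` needs columns copies, population and plate (plate may be
    constant, in which case the plate terms are omitted). Populations with
    fewer than 2 individuals are excluded with a warning. Returns (ANOVA
    table, Tukey pairwise table, compact letter display).
    """
    df = estimates.reset_index()
    sizes = df.groupby("population")["copies"].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding populations with < 2 individuals: {small}")
        df = df[~df["population"].isin(small)]
    if df["population"].nunique() < 2:
        raise ValueError("need at least 2 populations with >= 2 individuals")
    if "plate" in df.columns and df["plate"].nunique() > 1:
        model = smf.ols("copies ~ C(population) * C(plate)", data=df).fit()
    else:
        model = smf.ols("copies ~ C(population)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    tukey = pairwise_tukeyhsd(df["copies"], df["population"], alpha=alpha)
    summary = tukey.summary().data
    tukey_df = pd.DataFrame(summary[1:], columns=summary[0])
    groups = sorted(df["population"].unique())
    reject = {
        frozenset((row["group1"], row["group2"])): bool(row["reject"])
        for _, row in tukey_df.iterrows()
    }
    letters = _tukey_letters(groups, reject)
    return anova, tukey_df, letters
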