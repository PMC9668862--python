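"""Per-cohort Wilcoxon differential abundance and cross-cohort consistency
voting.

The marker-discovery rule: a taxon is a "universal" marker for a contrast
(CRC vs HC, or CRC vs CA) when it is significant (two-sided Wilcoxon
rank-sum, p < alpha) in at least a voting-threshold number of cohorts AND the
direction of change — up or down in CRC, judged by group means — agrees in
every cohort where it is significant.  No multiple-testing correction is
applied by default (a Benjamini–Hochberg option exists); default thresholds
are alpha 0.05 for taxa and vote counts 3 (vs HC) / 2 (vs CA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CohortProfile, pool_profiles

CONTRASTS = {"CRC_vs_HC": ("CRC", "HC"), "CRC_vs_CA": ("CRC", "CA")}
PSEUDOCOUNT = 1e-6  # for log transforms of fraction abundances


@dataclass
class DifferentialRecord:
    taxon: str
    cohort_id: str
    contrast: str
    p_value: float
    mean_case: float
    mean_control: float

    @property
    def direction(self) -> str:
        return "up" if self.mean_case > self.mean_control else "down"


@dataclass
class ConsensusMarker:
    taxon: str
    contrast: str
    n_significant_cohorts: int
    direction: str
    member_cohorts: list


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null enumeration when the pooled size is <= 12 with no ties;
    tie-corrected normal approximation with continuity correction otherwise.
    Identical pooled values return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 values on each side")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= 12) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_i in range(n - 1, -1, -1):
        i = order[rank_i]
        running = min(running, p[i] * n / (rank_i + 1))
        adj[i] = running
    return adj


def cohort_differential(
    profile: CohortProfile,
    contrast: str = "CRC_vs_HC",
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[DifferentialRecord]:
    """Wilcoxon test of every taxon between the contrast's two groups.

    Returns one record per taxon with (adjusted, if ``fdr``) p < alpha,
    carrying the group means that define the direction call.
    """
    case, control = CONTRASTS[contrast]
    g = profile.groups()
    x_idx = g[g == case].index
    y_idx = g[g == control].index
    if len(x_idx) < 2 or len(y_idx) < 2:
        raise ValueError(
            f"cohort {profile.cohort_id}: contrast {contrast} needs >=2 samples "
            f"per group (got {len(x_idx)} {case}, {len(y_idx)} {control})"
        )
    ab = profile.abundance
    taxa = profile.taxa
    pvals, mcase, mctrl = [], [], []
    for t in taxa:
        xv = ab.loc[x_idx, t].to_numpy(dtype=float)
        yv = ab.loc[y_idx, t].to_numpy(dtype=float)
        pvals.append(wilcoxon_rank_sum(xv, yv))
        mcase.append(float(xv.mean()))
        mctrl.append(float(yv.mean()))
    pv = bh_adjust(pvals) if fdr else np.asarray(pvals)
    return [
        DifferentialRecord(t, profile.cohort_id, contrast, float(pv[j]), mcase[j], mctrl[j])
        for j, t in enumerate(taxa)
        if pv[j] < alpha
    ]


def consensus_markers(
    records: list[DifferentialRecord], min_cohorts: int = 3
) -> list[ConsensusMarker]:
    """Direction-consistent voting across cohorts.

    A taxon qualifies iff it is significant in >= ``min_cohorts`` cohorts and
    every significant cohort agrees on direction.  Duplicate records from the
    same cohort are collapsed, so the vote is idempotent per cohort.  Sorted
    by vote count descending, then taxon name.
    """
    if min_cohorts < 2:
        raise ValueError("min_cohorts must be >= 2")
    by_taxon: dict[tuple[str, str], dict[str, str]] = {}
    for r in records:
        key = (r.contrast, r.taxon)
        votes = by_taxon.setdefault(key, {})
        prev = votes.get(r.cohort_id)
        if prev is not None and prev != r.direction:
            # same cohort voting both ways can only come from conflicting
            # duplicate inputs
            raise ValueError(
                f"conflicting duplicate records for {r.taxon} in {r.cohort_id}"
            )
        votes[r.cohort_id] = r.direction
    out: list[ConsensusMarker] = []
    for (contrast, taxon), votes in by_taxon.items():
        dirs = set(votes.values())
        if len(votes) >= min_cohorts and len(dirs) == 1:
            out.append(
                ConsensusMarker(
                    taxon, contrast, len(votes), dirs.pop(), sorted(votes)
                )
            )
    out.sort(key=lambda m: (-m.n_significant_cohorts, m.taxon))
    return out


def filter_to_detectable(
    markers: list[ConsensusMarker], detectable_genera: list[str]
) -> list[ConsensusMarker]:
    """Keep markers whose genus appears in an externally detectable list
    (e.g. genera confirmed by 16S sequencing); order preserved."""
    if not detectable_genera:
        raise ValueError("detectable genus list is empty")
    allowed = set(detectable_genera)
    kept = [m for m in markers if m.taxon in allowed]
    if markers and not kept:
        warnings.warn("no consensus marker is in the detectable list")
    return kept


def phylum_composition_test(
    profile: CohortProfile, top_k: int = 8
) -> tuple[float, float]:
    """Chi-square test of group-mean phylum composition.

    Builds a groups x top_k table of group-mean percentages (each group row
    rescaled to sum 100 over the top_k most abundant phyla) and applies a
    chi-square test of homogeneity.  Returns (statistic, p).  Expected cells
    below 1 trigger a warning, not an error.
    """
    g = profile.groups()
    groups = [lvl for lvl in pd.unique(g) if (g == lvl).sum() > 0]
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    means = profile.abundance.groupby(g).mean()
    top = means.mean(axis=0).sort_values(ascending=False).index[:top_k]
    table = means.loc[groups, top]
    table = table.div(table.sum(axis=1), axis=0) * 100.0
    obs = table.to_numpy()
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 1).any():
        warnings.warn("chi-square expected cell < 1; test may be unreliable")
    return float(chi2), float(p)


def pooled_differential(
    profiles: list[CohortProfile],
    contrast: str = "CRC_vs_HC",
    alpha: float = 0.05,
    batch_adjust: bool = True,
) -> list[DifferentialRecord]:
    """Differential test on all cohorts pooled ("mixed data").

    With ``batch_adjust`` each taxon's log10(x + 1e-6) abundances are centered
    per cohort before pooling — a simple location-shift batch stand-in, not a
    full mixed-effects batch model.  Group means in the records are means of
    the tested (adjusted) values so the direction call matches the test input.
    """
    pooled = pool_profiles(profiles)
    if not pooled.taxa:
        raise ValueError("no shared taxa across profiles")
    if batch_adjust:
        vals = np.log10(pooled.values() + PSEUDOCOUNT)
        cohorts = pooled.metadata["cohort"].to_numpy()
        for c in pd.unique(cohorts):
            mask = cohorts == c
            vals[mask] -= vals[mask].mean(axis=0, keepdims=True)
        pooled = CohortProfile(
            "pooled",
            pd.DataFrame(
                vals - vals.min() + 0.0,  # shift nonnegative; ranks unaffected
                index=pooled.abundance.index,
                columns=pooled.abundance.columns,
            ),
            pooled.metadata,
        )
    return cohort_differential(pooled, contrast=contrast, alpha=alpha)


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "cohort": r.cohort_id,
                "contrast": r.contrast,
                "p_value": r.p_value,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
                "direction": r.direction,
            }
            for r in records
        ]
    )


def markers_to_frame(markers: list[ConsensusMarker]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": m.taxon,
                "contrast": m.contrast,
                "n_significant_cohorts": m.n_significant_cohorts,
                "direction": m.direction,
                "member_cohorts": ",".join(m.member_cohorts),
            }
            for m in markers
        ]
    )
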