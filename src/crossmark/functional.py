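"""KO gene-family screening, marker–KO correlation networks and pathway
fold-change screening.

KEGG-ortholog (KO) relative-abundance tables are screened per cohort with the
same Wilcoxon + direction machinery as taxa (alpha 0.01 for KOs), vote-merged
across cohorts, and the CRC-associated KOs are then correlated (Spearman)
with the signature marker genera to build an association network.  Pathway
tables are screened with a fold-change gate (FC > 5 or < 0.2 on group means,
with pseudocount) combined with a relaxed Wilcoxon threshold (p < 0.1),
followed by the same cross-cohort direction vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CohortProfile
from .differential import (
    CONTRASTS,
    DifferentialRecord,
    ConsensusMarker,
    cohort_differential,
    consensus_markers,
    wilcoxon_rank_sum,
)

FC_PSEUDOCOUNT = 1e-9


@dataclass
class FunctionalProfile:
    """One cohort's samples x features functional table (KO ids K##### or
    pathway names) with the same metadata conventions as CohortProfile."""

    cohort_id: str
    abundance: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.abundance.columns.duplicated().any():
            raise ValueError("duplicate feature identifiers")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("negative abundance values")

    def as_cohort_profile(self) -> CohortProfile:
        return CohortProfile(self.cohort_id, self.abundance, self.metadata)


def read_humann_table(path, cohort_id: str | None = None) -> FunctionalProfile:
    """Read a HUMAnN-style TSV (feature rows named in a '# Gene Family' or
    '# Pathway' header column, sample columns) into samples x features."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature"
    df = df.T
    df.index = df.index.astype(str)
    return FunctionalProfile(cohort_id or str(path), df.astype(float))


def read_ko_pathway_map(path) -> dict[str, list[str]]:
    """Two-column TSV (KO id, pathway id) -> pathway -> KO list.  No KEGG
    data is bundled (licensing); supply your own map or a toy one."""
    df = pd.read_csv(path, sep="\t", header=None, names=["ko", "pathway"],
                     comment="#", dtype=str)
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["pathway"], []).append(row["ko"])
    return out


def rollup_kos_to_pathways(
    fp: FunctionalProfile, pathway_map: dict[str, list[str]]
) -> FunctionalProfile:
    """Sum KO abundances into pathway abundances; KOs absent from the table
    contribute nothing, pathways with no present KO are dropped."""
    cols = {}
    for pathway, kos in pathway_map.items():
        present = [k for k in kos if k in fp.abundance.columns]
        if present:
            cols[pathway] = fp.abundance[present].sum(axis=1)
    if not cols:
        raise ValueError("no mapped KO present in the table")
    return FunctionalProfile(fp.cohort_id, pd.DataFrame(cols), fp.metadata)


@dataclass
class CorrelationEdge:
    marker_genus: str
    feature_id: str
    rho: float
    p_value: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho >= 0 else "negative"


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with t-approximation p
    (n - 2 df).  Constant input vectors are an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def ko_differential(
    fp: FunctionalProfile, contrast: str = "CRC_vs_HC", alpha: float = 0.01
) -> list[DifferentialRecord]:
    """Per-cohort Wilcoxon differential test over KO features (alpha 0.01)."""
    return cohort_differential(fp.as_cohort_profile(), contrast=contrast, alpha=alpha)


def ko_consensus(
    records: list[DifferentialRecord], min_cohorts: int = 3
) -> list[ConsensusMarker]:
    """Direction-consistent vote across cohorts for KO features (same rule as
    taxon consensus; default 3 cohorts vs HC, use 2 vs CA)."""
    return consensus_markers(records, min_cohorts=min_cohorts)


def marker_ko_network(
    marker_abundances: pd.DataFrame,
    ko_abundances: pd.DataFrame,
    alpha: float = 0.05,
    center_by: pd.Series | None = None,
) -> list[CorrelationEdge]:
    """Spearman edges between signature marker genera and CRC-associated KOs.

    Both tables are samples x features; they are aligned on shared samples.
    When ``center_by`` (a cohort label per sample) is given, each feature is
    rank-preservingly centered per cohort before pooling, damping batch
    offsets.  Edges with p < alpha are returned with rho and sign.
    """
    shared = marker_abundances.index.intersection(ko_abundances.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between marker and KO tables")
    mk = marker_abundances.loc[shared].astype(float)
    ko = ko_abundances.loc[shared].astype(float)
    if center_by is not None:
        lab = pd.Series(center_by).reindex(shared)
        mk = _center_per_cohort(mk, lab)
        ko = _center_per_cohort(ko, lab)
    edges: list[CorrelationEdge] = []
    for g in mk.columns:
        xv = mk[g].to_numpy()
        for k in ko.columns:
            yv = ko[k].to_numpy()
            try:
                rho, p = spearman(xv, yv)
            except ValueError:
                continue
            if p < alpha:
                edges.append(CorrelationEdge(g, k, rho, p))
    return edges


def _center_per_cohort(df: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    out = df.copy()
    for c in labels.dropna().unique():
        idx = labels[labels == c].index
        out.loc[idx] = df.loc[idx] - df.loc[idx].mean()
    return out


def pathway_screen(
    fps: list[FunctionalProfile] | FunctionalProfile,
    contrast: str = "CRC_vs_HC",
    fc_hi: float = 5.0,
    fc_lo: float = 0.2,
    alpha: float = 0.1,
    min_cohorts: int = 2,
) -> list[ConsensusMarker]:
    """Fold-change + Wilcoxon pathway screen with cross-cohort voting.

    Per cohort a pathway is kept when the ratio of group means (with a 1e-9
    pseudocount) exceeds ``fc_hi`` or falls below ``fc_lo`` AND its Wilcoxon
    p < ``alpha``; survivors are vote-merged across cohorts requiring
    ``min_cohorts`` agreeing directions.
    """
    if isinstance(fps, FunctionalProfile):
        fps = [fps]
    case, control = CONTRASTS[contrast]
    records: list[DifferentialRecord] = []
    for fp in fps:
        cp = fp.as_cohort_profile()
        g = cp.groups()
        x_idx = g[g == case].index
        y_idx = g[g == control].index
        if len(x_idx) < 2 or len(y_idx) < 2:
            raise ValueError(f"cohort {fp.cohort_id}: both groups needed")
        for feat in cp.taxa:
            xv = cp.abundance.loc[x_idx, feat].to_numpy(dtype=float)
            yv = cp.abundance.loc[y_idx, feat].to_numpy(dtype=float)
            fc = (xv.mean() + FC_PSEUDOCOUNT) / (yv.mean() + FC_PSEUDOCOUNT)
            if not (fc > fc_hi or fc < fc_lo):
                continue
            p = wilcoxon_rank_sum(xv, yv)
            if p < alpha:
                records.append(
                    DifferentialRecord(feat, fp.cohort_id, contrast, p,
                                       float(xv.mean()), float(yv.mean()))
                )
    if min_cohorts < 2:
        # single-cohort mode: return survivors directly as 1-vote consensus
        return [
            ConsensusMarker(r.taxon, r.contrast, 1, r.direction, [r.cohort_id])
            for r in records
        ]
    return consensus_markers(records, min_cohorts=min_cohorts)


def edges_to_frame(edges: list[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker_genus": e.marker_genus,
                "feature_id": e.feature_id,
                "rho": e.rho,
                "p_value": e.p_value,
                "sign": e.sign,
            }
            for e in edges
        ]
    )


def write_network(edges: list[CorrelationEdge], tsv_path=None, graphml_path=None) -> None:
    """Export the marker–KO network as edge-list TSV and/or GraphML."""
    if tsv_path is not None:
        edges_to_frame(edges).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        g = nx.Graph()
        for e in edges:
            g.add_node(e.marker_genus, kind="marker")
            g.add_node(e.feature_id, kind="ko")
            g.add_edge(e.marker_genus, e.feature_id, rho=e.rho,
                       p_value=e.p_value, sign=e.sign)
        nx.write_graphml(g, graphml_path)
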