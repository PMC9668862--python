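"""Variance explained by disease status versus confounding factors.

For each taxon, the fraction of abundance variance explained by a categorical
factor is the one-way ANOVA R^2 = SS_between / SS_total.  Disease status and
each confounder (age band, sex, BMI category, study) are fit univariately on
the same sample subset so the two R^2 values are directly comparable — the
classic "study effects dominate disease effects" diagnostic for multi-cohort
microbiome collections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import CohortProfile


@dataclass
class VarianceDecomposition:
    taxon: str
    confounder_name: str
    var_disease: float
    var_confounder: float
    mean_abundance: float


def bin_bmi(bmi) -> str:
    """BMI (kg/m^2) to the conventional categories.

    Cutoffs: thin < 20, normal 20-25, overweight 25-30, obese > 30; boundaries
    are taken left-closed ([20,25) normal, [25,30) overweight, >=30 obese).
    Missing stays missing; nonpositive BMI is an error.
    """
    if bmi is None or (isinstance(bmi, float) and np.isnan(bmi)):
        return "missing"
    bmi = float(bmi)
    if bmi <= 0:
        raise ValueError(f"nonpositive BMI {bmi}")
    if bmi < 20:
        return "thin"
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    return "obese"


def bin_age(age, edges=(50, 60, 70)) -> str:
    """Age (years) binned into decades for ANOVA (continuous age needs a
    categorical stand-in to match the factor-based decomposition)."""
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return "missing"
    age = float(age)
    lo = "<%d" % edges[0]
    if age < edges[0]:
        return lo
    for a, b in zip(edges[:-1], edges[1:]):
        if age < b:
            return f"{a}-{b}"
    return ">=%d" % edges[-1]


def variance_explained(abundance, factor) -> float:
    """One-way ANOVA R^2 of ``abundance`` on categorical ``factor``.

    Samples with a missing factor level are dropped pairwise.  Constant
    abundance returns 0 by convention.  Requires >=2 levels with >=2 samples.
    """
    x = np.asarray(abundance, dtype=float)
    f = pd.Series(factor).astype(object).to_numpy()
    keep = np.array([not _is_missing(v) for v in f]) & ~np.isnan(x)
    x, f = x[keep], f[keep]
    levels, counts = np.unique(f, return_counts=True)
    if len(levels) < 2 or (counts < 2).any():
        raise ValueError("need >=2 factor levels with >=2 samples each")
    ss_total = ((x - x.mean()) ** 2).sum()
    if ss_total <= 0:
        return 0.0
    ss_between = sum(
        (f == lvl).sum() * (x[f == lvl].mean() - x.mean()) ** 2 for lvl in levels
    )
    return float(ss_between / ss_total)


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return isinstance(v, str) and v.strip().lower() in ("", "missing", "nan", "na")


def confounder_report(
    profile: CohortProfile,
    confounders: list[str] = ("age", "sex", "bmi", "cohort"),
    log_transform: bool = False,
) -> list[VarianceDecomposition]:
    """One record per taxon x confounder: R^2 for disease status versus the
    confounder, computed on the same (non-missing) sample subset.

    ``profile`` is typically a pooled multi-cohort profile whose metadata
    carries a ``cohort`` column; continuous age/BMI are binned first.
    """
    md = profile.metadata
    if md is None or "group" not in md:
        raise ValueError("profile metadata with a group column is required")
    records: list[VarianceDecomposition] = []
    vals = profile.values()
    if log_transform:
        vals = np.log10(vals + 1e-6)
    group = md["group"].reindex(profile.sample_ids).to_numpy()
    for conf in confounders:
        if conf not in md.columns:
            continue
        raw = md[conf].reindex(profile.sample_ids)
        if conf == "bmi":
            fac = raw.map(bin_bmi).to_numpy()
        elif conf == "age":
            fac = raw.map(bin_age).to_numpy()
        else:
            fac = raw.astype(object).to_numpy()
        keep = np.array([not _is_missing(v) for v in fac])
        for j, taxon in enumerate(profile.taxa):
            x = vals[:, j]
            try:
                vd = variance_explained(x[keep], group[keep])
                vc = variance_explained(x[keep], fac[keep])
            except ValueError:
                continue
            records.append(
                VarianceDecomposition(
                    taxon=taxon,
                    confounder_name=conf,
                    var_disease=vd,
                    var_confounder=vc,
                    mean_abundance=float(np.asarray(profile.values()[:, j]).mean()),
                )
            )
    return records


def report_to_frame(records: list[VarianceDecomposition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "factor": r.confounder_name,
                "var_disease": r.var_disease,
                "var_confounder": r.var_confounder,
                "mean_abundance": r.mean_abundance,
            }
            for r in records
        ]
    )
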