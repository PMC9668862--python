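"""Reading, validation and harmonization of taxon relative-abundance profiles.

A :class:`CohortProfile` is one cohort's samples x taxa relative-abundance
matrix together with per-sample clinical metadata (diagnostic group, age, sex,
BMI, optional tumor stage).  Profiles are the common currency of every
downstream stage: diversity analysis, differential testing, signature fitting.

Abundances are stored as fractions (each sample row sums to 1 after
:func:`renormalize`), never percentages.  Taxa may carry full MetaPhlAn-style
lineages (``k__Bacteria|p__Firmicutes|...``) or bare names at a single rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIX_TO_RANK = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

GROUPS = ("HC", "CA", "CRC")


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered taxonomic lineage, possibly truncated (e.g. down to genus only).

    ``rank_labels`` maps rank name -> taxon name for a contiguous prefix of
    ``RANK_ORDER``.  Strain-level tokens are never stored.
    """

    rank_labels: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ranks = [r for r, _ in self.rank_labels]
        expected = list(RANK_ORDER[: len(ranks)])
        if ranks != expected:
            raise ValueError(
                f"lineage ranks {ranks} must form a contiguous prefix of {expected}"
            )
        for rank, name in self.rank_labels:
            if not name:
                raise ValueError(f"empty name at rank {rank!r}")

    @property
    def deepest_rank(self) -> str | None:
        return self.rank_labels[-1][0] if self.rank_labels else None

    def name_at(self, rank: str) -> str | None:
        for r, name in self.rank_labels:
            if r == rank:
                return name
        return None

    @property
    def name(self) -> str:
        """Name at the deepest populated rank."""
        return self.rank_labels[-1][1] if self.rank_labels else "unclassified"

    def __str__(self) -> str:
        return "|".join(f"{r[0]}__{n}" for r, n in self.rank_labels)


def parse_clade_string(s: str) -> TaxonLineage:
    """Parse a pipe-delimited MetaPhlAn clade string into a lineage.

    Strain tokens (``t__``) are dropped.  Unknown prefixes or out-of-order
    ranks raise ``ValueError``.
    """
    labels: list[tuple[str, str]] = []
    last_idx = -1
    for token in s.split("|"):
        token = token.strip()
        if not token:
            continue
        if len(token) < 3 or token[1:3] != "__":
            raise ValueError(f"malformed lineage token {token!r} in {s!r}")
        prefix, name = token[0], token[3:]
        if prefix == "t":  # strain level: below species, always dropped
            continue
        if prefix not in _PREFIX_TO_RANK:
            raise ValueError(f"unknown rank prefix {prefix!r} in {s!r}")
        rank = _PREFIX_TO_RANK[prefix]
        idx = RANK_ORDER.index(rank)
        if idx <= last_idx:
            raise ValueError(f"rank order violated at token {token!r} in {s!r}")
        last_idx = idx
        labels.append((rank, name))
    # contiguity: MetaPhlAn guarantees it; tolerate gaps only by erroring,
    # since aggregate_to_rank relies on prefix structure
    ranks = [r for r, _ in labels]
    if ranks != list(RANK_ORDER[: len(ranks)]):
        raise ValueError(f"lineage {s!r} skips ranks: {ranks}")
    return TaxonLineage(tuple(labels))


@dataclass
class CohortProfile:
    """One cohort's relative-abundance matrix plus sample metadata.

    Parameters
    ----------
    cohort_id : str
        Study identifier (e.g. a cohort name or accession).
    abundance : pandas.DataFrame
        Samples x taxa, nonnegative fractions.  Column labels are taxon names
        (bare names or full clade strings).
    metadata : pandas.DataFrame or None
        Indexed by sample id; expected columns ``group`` (HC/CA/CRC or an
        ``other:<label>`` string), ``age``, ``sex``, ``bmi``, optional
        ``stage``.  May be None for metadata-free tables.
    """

    cohort_id: str
    abundance: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.index.duplicated().any():
            dups = ab.index[ab.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if ab.columns.duplicated().any():
            dups = ab.columns[ab.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        if (ab.to_numpy() < 0).any():
            raise ValueError("negative abundance values")
        if self.metadata is not None:
            missing = self.metadata.index.difference(ab.index)
            if len(missing):
                raise ValueError(
                    f"metadata samples not in abundance table: {list(missing)[:5]}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    def groups(self) -> pd.Series:
        if self.metadata is None or "group" not in self.metadata:
            raise ValueError(f"cohort {self.cohort_id!r} has no group metadata")
        return self.metadata["group"].reindex(self.abundance.index)

    def subset_groups(self, groups: list[str]) -> "CohortProfile":
        """Restrict to samples whose group is in ``groups``."""
        g = self.groups()
        keep = g[g.isin(groups)].index
        return CohortProfile(
            self.cohort_id,
            self.abundance.loc[keep],
            self.metadata.loc[keep] if self.metadata is not None else None,
        )

    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_abundance_table(
    path,
    orientation: str = "samples_x_taxa",
    cohort_id: str | None = None,
) -> CohortProfile:
    """Read a delimited abundance table into a :class:`CohortProfile`.

    Raw values are preserved (no renormalization); ``orientation`` says
    whether rows are samples or taxa in the file.  MetaPhlAn merged tables
    (lineage strings in the first column) are read with
    ``orientation="taxa_x_samples"``.
    """
    if orientation not in ("samples_x_taxa", "taxa_x_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment=None)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate identifiers in {path}: {dups}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
    df = df.astype(float)
    if orientation == "taxa_x_samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    name = cohort_id if cohort_id is not None else str(path)
    return CohortProfile(name, df)


def read_metadata_table(path) -> pd.DataFrame:
    """Read a sample metadata table (columns sample_id, group, age, sex, bmi,
    cohort, stage; extra columns pass through)."""
    sep = _sniff_sep(path)
    md = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in md.columns:
        raise ValueError("metadata table must have a sample_id column")
    return md.set_index("sample_id")


def write_profile(profile: CohortProfile, abundance_path, metadata_path=None) -> None:
    """Write the canonical TSV pair (samples x taxa fractions + metadata)."""
    profile.abundance.to_csv(abundance_path, sep="\t", index_label="sample_id")
    if metadata_path is not None and profile.metadata is not None:
        profile.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------


def renormalize(profile: CohortProfile) -> CohortProfile:
    """Rescale every sample row to sum to 1.  All-zero samples are an error."""
    vals = profile.values()
    sums = vals.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = [profile.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample(s): {bad}")
    ab = pd.DataFrame(
        vals / sums[:, None], index=profile.abundance.index, columns=profile.abundance.columns
    )
    return replace(profile, abundance=ab)


def aggregate_to_rank(
    profile: CohortProfile,
    rank: str = "genus",
    keep_unclassified: bool = False,
) -> CohortProfile:
    """Sum abundances of taxa sharing the same name at ``rank``.

    Column labels are parsed as clade strings when they contain rank prefixes;
    bare names are treated as already being at the target rank.  Taxa with no
    name at ``rank`` are pooled into an ``"unclassified"`` column when
    ``keep_unclassified`` is true, otherwise dropped (their mass is lost, so
    renormalize afterwards if fractions are needed).
    """
    if rank not in RANK_ORDER:
        raise ValueError(f"unknown rank {rank!r}")
    names: list[str | None] = []
    any_at_rank = False
    for col in profile.taxa:
        if "__" in col:
            lin = parse_clade_string(col)
            # only keep taxa whose deepest rank is >= target (species under
            # genus aggregates; a phylum-only row has no genus)
            name = lin.name_at(rank)
        else:
            name = col
        if name is not None:
            any_at_rank = True
        names.append(name)
    if not any_at_rank:
        raise ValueError(f"rank {rank!r} absent from all taxa")
    frames: dict[str, np.ndarray] = {}
    vals = profile.values()
    for j, name in enumerate(names):
        key = name if name is not None else ("unclassified" if keep_unclassified else None)
        if key is None:
            continue
        frames[key] = frames.get(key, 0) + vals[:, j]
    ab = pd.DataFrame(frames, index=profile.abundance.index)
    return replace(profile, abundance=ab)


def harmonize_genus_names(
    profile: CohortProfile, synonym_map: dict[str, str] | None = None
) -> CohortProfile:
    """Map genus column names through a synonym table (e.g. to reconcile
    MetaPhlAn and Silva naming), summing columns that collapse onto the same
    name.  Names absent from the map pass through unchanged."""
    if not synonym_map:
        return profile
    renamed = profile.abundance.rename(columns=lambda c: synonym_map.get(c, c))
    ab = renamed.T.groupby(level=0).sum().T
    return replace(profile, abundance=ab)


def common_taxa(
    profiles: list[CohortProfile], detection_threshold: float = 0.0
) -> list[str]:
    """Taxa detected (abundance > threshold in >=1 sample) in EVERY cohort.

    Returned sorted lexicographically; invariant to cohort ordering.
    """
    if not profiles:
        raise ValueError("empty profile list")
    detected: set[str] | None = None
    for p in profiles:
        vals = p.values()
        here = {t for j, t in enumerate(p.taxa) if (vals[:, j] > detection_threshold).any()}
        detected = here if detected is None else detected & here
    return sorted(detected)


def pool_profiles(profiles: list[CohortProfile], taxa: list[str] | None = None) -> CohortProfile:
    """Concatenate cohorts into one pooled profile on shared taxa.

    Sample ids are prefixed with the cohort id to guarantee uniqueness, and a
    ``cohort`` column is added to the pooled metadata.
    """
    if not profiles:
        raise ValueError("empty profile list")
    if taxa is None:
        taxa = common_taxa(profiles)
    ab_parts, md_parts = [], []
    for p in profiles:
        missing = [t for t in taxa if t not in p.abundance.columns]
        if missing:
            warnings.warn(
                f"cohort {p.cohort_id}: {len(missing)} pooled taxa absent, filled with 0"
            )
        ab = p.abundance.reindex(columns=taxa, fill_value=0.0).copy()
        ab.index = [f"{p.cohort_id}:{s}" for s in ab.index]
        ab_parts.append(ab)
        md = p.metadata.copy() if p.metadata is not None else pd.DataFrame(index=p.abundance.index)
        md.index = [f"{p.cohort_id}:{s}" for s in md.index]
        md["cohort"] = p.cohort_id
        md_parts.append(md)
    return CohortProfile("pooled", pd.concat(ab_parts), pd.concat(md_parts))
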